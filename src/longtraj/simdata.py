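"""Synthetic cohort generators.

The analysis downstream compares allele frequencies across three
cross-sectional age groups of one population: Group 1 (adults up to 50 years,
taken as representative of the general gene pool), Group 2 (ages 50-85, i.e.
survivors of mid-life mortality) and Group 3 (centenarians, survivors of both
mid-life and late-life mortality).  Because older groups are survivors, alleles
that influence survival drift in frequency across groups even in a purely
cross-sectional sample — the mortality-selection signal the trajectory
classifier is built to detect.

:func:`simulate_cohort` implements that process explicitly: a birth cohort is
genotyped under Hardy-Weinberg proportions, each individual survives two age
windows with per-window logistic probabilities that are additive in dosage on
the log-odds scale, and the three groups are sampled (disjointly) from the
full cohort, the mid-window survivors and the late-window survivors
respectively.  The logistic survival model is a modelling choice of this
package; it matches the logistic association model used downstream and admits
the closed-form post-selection frequency expectations in
:func:`expected_group_freqs`, which both the tests and the class-planting
helper rely on.

Two auxiliary generators serve the structure and ancestry stages:
:func:`simulate_structured` draws subpopulation allele frequencies from a
Balding-Nichols distribution around an ancestral frequency (differentiation
controlled by FST), and :func:`simulate_ancestry` draws per-individual
ancestry fractions from group-specific Dirichlet distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .containers import AncestryMatrix, GenotypeDataset

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "simulate_structured",
    "simulate_ancestry",
    "expected_group_freqs",
    "planted_class_betas",
    "TRAJECTORY_CLASSES",
]

TRAJECTORY_CLASSES = ("A", "B", "C", "D", "E", "F")


@dataclass
class SimulationConfig:
    """All generator parameters.

    Attributes
    ----------
    n_birth_cohort
        Number of simulated newborns (before any mortality).
    n_snps
        Number of independent biallelic SNPs.
    baseline_freqs
        Per-SNP effect-allele frequency in [0.01, 0.99]; a scalar is broadcast,
        ``None`` draws each frequency uniformly from [0.05, 0.95].
    beta_mid, beta_late
        Per-SNP log-odds effect of one effect-allele copy on surviving the
        mid window (ages 50-85) and, conditional on that, the late window
        (85 to 100+).  Scalars broadcast; default 0 (no selection).
    base_surv_mid, base_surv_late
        Baseline per-window survival probabilities (dosage 0, female).  The
        defaults compress real human mortality so that a desk-scale birth
        cohort still yields a few hundred centenarian-aged survivors.
    sex_effect
        Log-odds effect of being male on survival in both windows; default
        -0.4 (male survival disadvantage).
    sample_sizes
        Target (G1, G2, G3) counts; defaults follow a cohort of 381 adults
        <=50y, 392 aged 50-85 and 333 centenarians.
    seed
        RNG seed; identical config + seed reproduces byte-identical output.
    fst
        Differentiation parameter in [0, 1) for :func:`simulate_structured`.
    k_components
        Number of ancestry components for :func:`simulate_ancestry`.
    missing_rate
        Fraction of dosage entries set missing uniformly at random.
    """

    n_birth_cohort: int = 8000
    n_snps: int = 100
    baseline_freqs: np.ndarray | float | None = None
    beta_mid: np.ndarray | float = 0.0
    beta_late: np.ndarray | float = 0.0
    base_surv_mid: float = 0.85
    base_surv_late: float = 0.2
    sex_effect: float = -0.4
    sample_sizes: tuple[int, int, int] = (381, 392, 333)
    seed: int = 0
    fst: float = 0.05
    k_components: int = 2
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_birth_cohort < 1 or self.n_snps < 1:
            raise ValueError("n_birth_cohort and n_snps must be positive")
        for name in ("base_surv_mid", "base_surv_late"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie strictly in (0, 1)")
        if len(self.sample_sizes) != 3 or any(s < 1 for s in self.sample_sizes):
            raise ValueError("sample_sizes must be three positive counts")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst={self.fst} must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.k_components < 1:
            raise ValueError("k_components must be >= 1")
        if self.baseline_freqs is not None:
            f = np.atleast_1d(np.asarray(self.baseline_freqs, dtype=float))
            if np.any(f < 0.01) or np.any(f > 0.99):
                raise ValueError("baseline_freqs must lie in [0.01, 0.99]")

    # broadcasting helpers -------------------------------------------------
    def resolved_freqs(self, rng: np.random.Generator) -> np.ndarray:
        if self.baseline_freqs is None:
            return rng.uniform(0.05, 0.95, self.n_snps)
        return np.broadcast_to(
            np.atleast_1d(np.asarray(self.baseline_freqs, dtype=float)),
            (self.n_snps,),
        ).copy()

    def resolved_betas(self) -> tuple[np.ndarray, np.ndarray]:
        bm = np.broadcast_to(
            np.atleast_1d(np.asarray(self.beta_mid, dtype=float)), (self.n_snps,)
        ).copy()
        bl = np.broadcast_to(
            np.atleast_1d(np.asarray(self.beta_late, dtype=float)), (self.n_snps,)
        ).copy()
        return bm, bl

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# --------------------------------------------------------------------------
# cohort generator
# --------------------------------------------------------------------------

_AGE_WINDOWS = {"G1": (19.0, 50.0), "G2": (50.0, 85.0), "G3": (100.0, 103.0)}


def _snp_meta(n_snps: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": [f"snp{i + 1:05d}" for i in range(n_snps)],
            "chrom": np.ones(n_snps, dtype=int),
            "pos": (np.arange(n_snps) + 1) * 10_000,
            "effect_allele": ["A"] * n_snps,
            "other_allele": ["G"] * n_snps,
        }
    )


def simulate_cohort(config: SimulationConfig) -> GenotypeDataset:
    """Simulate a three-group cross-sectional cohort under mortality selection.

    Genotypes of ``n_birth_cohort`` newborns are drawn per SNP in
    Hardy-Weinberg proportions at ``baseline_freqs``.  Each individual survives
    the mid window with probability
    ``expit(logit(base_surv_mid) + dosage @ beta_mid + sex_effect * male)``
    and, conditional on that, the late window analogously with ``beta_late``.
    Groups are then sampled without replacement and disjointly: G3 from
    late-window survivors, G2 from remaining mid-window survivors, G1 from the
    remaining birth cohort.  Ages are assigned uniformly within each group's
    window.

    Raises
    ------
    ValueError
        If a survivor pool is smaller than the requested group size (the
        message names the group) or a logistic argument is non-finite.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_birth_cohort, config.n_snps
    freqs = config.resolved_freqs(rng)
    beta_mid, beta_late = config.resolved_betas()

    geno = rng.binomial(2, freqs[None, :], size=(n, m)).astype(float)
    male = rng.integers(0, 2, n).astype(float)  # 1 = male

    eta_mid = logit(config.base_surv_mid) + geno @ beta_mid + config.sex_effect * male
    eta_late = logit(config.base_surv_late) + geno @ beta_late + config.sex_effect * male
    if not (np.all(np.isfinite(eta_mid)) and np.all(np.isfinite(eta_late))):
        raise ValueError("non-finite logistic argument in survival model")

    surv_mid = rng.random(n) < expit(eta_mid)
    surv_late = surv_mid & (rng.random(n) < expit(eta_late))

    n1, n2, n3 = config.sample_sizes
    taken = np.zeros(n, dtype=bool)
    chosen: dict[str, np.ndarray] = {}
    for label, size, pool_mask in (
        ("G3", n3, surv_late),
        ("G2", n2, surv_mid),
        ("G1", n1, np.ones(n, dtype=bool)),
    ):
        pool = np.nonzero(pool_mask & ~taken)[0]
        if pool.size < size:
            raise ValueError(
                f"survivor pool for {label} has {pool.size} individuals, "
                f"but {size} were requested; increase n_birth_cohort or "
                f"baseline survival"
            )
        pick = rng.choice(pool, size=size, replace=False)
        taken[pick] = True
        chosen[label] = np.sort(pick)

    order = np.concatenate([chosen["G1"], chosen["G2"], chosen["G3"]])
    groups = np.concatenate([["G1"] * n1, ["G2"] * n2, ["G3"] * n3])
    ages = np.concatenate(
        [
            rng.uniform(*_AGE_WINDOWS["G1"], n1),
            rng.uniform(*_AGE_WINDOWS["G2"], n2),
            rng.uniform(*_AGE_WINDOWS["G3"], n3),
        ]
    )

    dosages = geno[order]
    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages = dosages.copy()
        dosages[miss] = np.nan

    ind_meta = pd.DataFrame(
        {
            "id": [f"I{i + 1:06d}" for i in range(order.size)],
            "sex": np.where(male[order] == 1.0, "M", "F"),
            "age": ages,
            "group": groups,
            "center": ["C1"] * order.size,
        }
    )
    return GenotypeDataset(dosages, _snp_meta(m), ind_meta)


# --------------------------------------------------------------------------
# closed-form expectations and class planting
# --------------------------------------------------------------------------

def expected_group_freqs(
    p: float,
    beta_mid: float,
    beta_late: float,
    base_surv_mid: float,
    base_surv_late: float,
    sex_effect: float = 0.0,
    male_fraction: float = 0.5,
) -> tuple[float, float, float]:
    """Exact large-cohort effect-allele frequencies (f1, f2, f3) for one SNP.

    Averages the genotype-conditional survival weights over the two sexes and
    over the Hardy-Weinberg genotype distribution at frequency ``p``.  The
    late-window expectation weights the *birth* genotype distribution by the
    product of both windows' survival probabilities (survivors of the mid
    window are no longer in Hardy-Weinberg proportions, so the two stages do
    not factorise).
    """
    g = np.array([0.0, 1.0, 2.0])
    hw = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    sexes = np.array([0.0, 1.0])
    wsex = np.array([1.0 - male_fraction, male_fraction])
    s_mid = expit(logit(base_surv_mid) + beta_mid * g[:, None] + sex_effect * sexes)
    s_late = expit(logit(base_surv_late) + beta_late * g[:, None] + sex_effect * sexes)
    w_mid = (s_mid * wsex).sum(axis=1)
    w_joint = (s_mid * s_late * wsex).sum(axis=1)
    f2 = float((hw * w_mid * g / 2).sum() / (hw * w_mid).sum())
    f3 = float((hw * w_joint * g / 2).sum() / (hw * w_joint).sum())
    return float(p), f2, f3


def planted_class_betas(
    cls: str,
    strength: float,
    p: float,
    base_surv_mid: float,
    base_surv_late: float,
    sex_effect: float = 0.0,
) -> tuple[float, float]:
    """Survival effects (beta_mid, beta_late) that plant trajectory class ``cls``.

    Classes C-F use a single active window (``+/-strength`` in one window, 0 in
    the other).  Classes A and B are up-then-down / down-then-up trajectories
    that must *return to the baseline frequency* in centenarians; because
    selection response on the frequency scale is not antisymmetric in beta,
    the reverting late-window effect is obtained by solving the closed-form
    two-stage frequency map (:func:`expected_group_freqs`) for ``f3 = p``
    rather than by negating ``strength``.
    """
    if cls not in TRAJECTORY_CLASSES:
        raise ValueError(f"unknown trajectory class {cls!r}")
    s = float(strength)
    if s <= 0:
        raise ValueError("strength must be positive")
    if cls == "C":
        return s, 0.0
    if cls == "D":
        return -s, 0.0
    if cls == "E":
        return 0.0, -s
    if cls == "F":
        return 0.0, s
    bm = s if cls == "A" else -s

    def resid(bl: float) -> float:
        return expected_group_freqs(
            p, bm, bl, base_surv_mid, base_surv_late, sex_effect
        )[2] - p

    lo, hi = -12.0, 12.0
    if resid(lo) * resid(hi) > 0:
        # Upward reversion saturates: survival probabilities cannot exceed 1,
        # so the achievable late-window selection differential is bounded by
        # 1/base_surv_late.  A lower baseline late survival gives headroom.
        raise ValueError(
            f"class {cls} at strength {s} cannot revert to baseline with "
            f"base_surv_late={base_surv_late}; lower the baseline late survival"
        )
    bl = brentq(resid, lo, hi, xtol=1e-10)
    return bm, float(bl)


# --------------------------------------------------------------------------
# structured population generator
# --------------------------------------------------------------------------

def simulate_structured(
    config: SimulationConfig,
    pop_sizes,
    pop_labels=None,
) -> GenotypeDataset:
    """Simulate genotypes for >=2 subpopulations under the Balding-Nichols model.

    Per SNP an ancestral frequency is drawn (or taken from
    ``config.baseline_freqs``), then each subpopulation's frequency is drawn
    from ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with ``F = config.fst`` (at F=0 the
    subpopulation frequency equals the ancestral one exactly).  Genotypes are
    in Hardy-Weinberg proportions within each subpopulation; the subpopulation
    is recorded as the recruitment-center label and the group label is
    ``"none"``.
    """
    pop_sizes = [int(s) for s in np.atleast_1d(pop_sizes)]
    if len(pop_sizes) < 2:
        raise ValueError("need at least 2 subpopulations")
    if any(s < 1 for s in pop_sizes):
        raise ValueError(f"pop_sizes must be positive, got {pop_sizes}")
    if pop_labels is None:
        pop_labels = [f"POP{i + 1}" for i in range(len(pop_sizes))]
    if len(pop_labels) != len(pop_sizes):
        raise ValueError("pop_labels length mismatch")

    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    p_anc = config.resolved_freqs(rng)
    fst = config.fst
    blocks, labels = [], []
    for size, lab in zip(pop_sizes, pop_labels):
        if fst == 0.0:
            p_sub = p_anc
        else:
            a = p_anc * (1.0 - fst) / fst
            b = (1.0 - p_anc) * (1.0 - fst) / fst
            p_sub = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
        blocks.append(rng.binomial(2, p_sub[None, :], size=(size, m)).astype(float))
        labels.extend([lab] * size)

    dosages = np.vstack(blocks)
    n = dosages.shape[0]
    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = np.nan
    sex = np.where(rng.integers(0, 2, n) == 1, "M", "F")
    ind_meta = pd.DataFrame(
        {
            "id": [f"S{i + 1:06d}" for i in range(n)],
            "sex": sex,
            "age": rng.uniform(19, 85, n),
            "group": ["none"] * n,
            "center": labels,
        }
    )
    return GenotypeDataset(dosages, _snp_meta(m), ind_meta)


# --------------------------------------------------------------------------
# ancestry-fraction generator
# --------------------------------------------------------------------------

def simulate_ancestry(
    config: SimulationConfig,
    group_means,
    concentration: float,
    group_sizes,
    group_labels=None,
) -> AncestryMatrix:
    """Draw per-individual ancestry fractions from group-wise Dirichlet laws.

    Each group ``g`` has a mean vector ``group_means[g]`` (summing to 1); rows
    for its members are drawn from ``Dirichlet(concentration * mean)``, so the
    expected row equals the group mean and ``concentration`` controls the
    spread (variance of component k is ``m_k(1-m_k)/(concentration+1)``).
    """
    means = np.atleast_2d(np.asarray(group_means, dtype=float))
    if not np.all(np.abs(means.sum(axis=1) - 1.0) <= 1e-6):
        bad = int(np.argmax(np.abs(means.sum(axis=1) - 1.0)))
        raise ValueError(f"group_means row {bad} does not sum to 1")
    if np.any(means <= 0):
        raise ValueError("group_means entries must be strictly positive")
    if concentration <= 0:
        raise ValueError(f"concentration={concentration} must be positive")
    group_sizes = [int(s) for s in np.atleast_1d(group_sizes)]
    if len(group_sizes) != means.shape[0]:
        raise ValueError("group_sizes and group_means length mismatch")
    if any(s < 1 for s in group_sizes):
        raise ValueError("group_sizes must be positive")
    if group_labels is None:
        group_labels = [f"GRP{i + 1}" for i in range(len(group_sizes))]

    rng = np.random.default_rng(config.seed)
    rows, labels = [], []
    for mean, size, lab in zip(means, group_sizes, group_labels):
        rows.append(rng.dirichlet(concentration * mean, size=size))
        labels.extend([lab] * size)
    props = np.vstack(rows)
    # guard against float drift in dirichlet rows
    props = props / props.sum(axis=1, keepdims=True)
    return AncestryMatrix(
        props,
        component_labels=[f"K{i + 1}" for i in range(means.shape[1])],
        ids=[f"Q{i + 1:06d}" for i in range(props.shape[0])],
        groups=labels,
    )
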