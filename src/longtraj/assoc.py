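"""Covariate-adjusted logistic association between two age groups.

The association model is the one the downstream trajectory procedure uses for
every pairwise contrast: per SNP, a logistic regression of case/control status
on additive effect-allele dosage (0/1/2) with sex (F=0, M=1) as a covariate,
tested with the two-sided Wald statistic.  Missing dosages or covariates are
dropped per SNP (complete-case).  Genome-wide summaries are the genomic
inflation factor lambda (median association chi-square over its 1-df null
median) and QQ coordinates; candidate intersection filters nominally
significant records (default p < 1e-4) against a SNP-id list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

try:  # newer statsmodels also emits a warning flavour
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
except ImportError:  # pragma: no cover
    class PerfectSeparationWarning(UserWarning):
        pass

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "GroupGWAS",
    "GWASResults",
    "GwasSummary",
    "genomic_inflation",
    "qq_points",
    "intersect_candidates",
]

# Full-precision 1-df chi-square median used as the lambda denominator,
# computed via isf so that p = 0.5 maps to exactly lambda = 1.
CHI2_1DF_MEDIAN = float(stats.chi2.isf(0.5, df=1))

# effect sizes / standard errors beyond these are treated as quasi-separation
_MAX_ABS_BETA = 20.0
_MAX_SE = 100.0


@dataclass
class LogisticFit:
    """Wald inference for one logistic fit.

    ``beta/se/z/p`` refer to the dosage term; ``params``/``bse`` etc. carry all
    predictors in order (intercept, dosage, covariates).  ``status`` is ``"ok"``
    or a flag (``"separation"``, ``"non_convergence"``, ``"constant"``,
    ``"no_contrast"``); flagged fits have NaN estimates and the pipeline
    continues.
    """

    beta: float
    se: float
    z: float
    p: float
    n_used: int
    status: str = "ok"
    params: np.ndarray = field(default_factory=lambda: np.array([]))
    bse: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _na_fit(status: str, n_used: int = 0) -> LogisticFit:
    return LogisticFit(np.nan, np.nan, np.nan, np.nan, n_used, status)


def fit_logistic(dosage, covariates, labels) -> LogisticFit:
    """Maximum-likelihood logistic fit of ``labels`` on dosage (+ covariates).

    Parameters
    ----------
    dosage
        Additive genotype vector; NaN entries are dropped.
    covariates
        ``(n,)`` or ``(n, c)`` covariate array, or ``None``; NaN rows dropped.
    labels
        Binary case(1)/control(0) vector.

    Newton-Raphson with at most 100 iterations and tolerance 1e-10; perfect or
    quasi-complete separation and non-convergence yield a flagged NaN fit
    rather than an exception.
    """
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(labels, dtype=float)
    cols = [np.ones_like(dosage), dosage]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    X = np.column_stack(cols)
    mask = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    X, y = X[mask], y[mask]
    n_used = int(mask.sum())

    if n_used == 0 or y.min() == y.max():
        return _na_fit("no_contrast", n_used)
    if np.ptp(X[:, 1]) == 0:
        return _na_fit("constant", n_used)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=100, tol=1e-10, disp=0,
                warn_convergence=False,
            )
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return _na_fit("separation", n_used)
    if not res.mle_retvals.get("converged", False):
        return _na_fit("non_convergence", n_used)
    params, bse = np.asarray(res.params), np.asarray(res.bse)
    if (
        not np.all(np.isfinite(bse))
        or np.abs(params[1]) > _MAX_ABS_BETA
        or bse[1] > _MAX_SE
    ):
        return _na_fit("separation", n_used)
    z = params[1] / bse[1]
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return LogisticFit(
        float(params[1]), float(bse[1]), float(z), p, n_used, "ok", params, bse
    )


# --------------------------------------------------------------------------
# genome-wide summaries
# --------------------------------------------------------------------------

def genomic_inflation(pvalues) -> float:
    """Genomic inflation factor lambda.

    ``median(chi2_quantile(1 - p, df=1)) / median(chi2, df=1)``; NaN p-values
    are excluded, remaining values must lie in (0, 1].  With all p = 0.5 the
    factor is exactly 1.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values for lambda")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, df=1)
    return float(np.median(chisq) / CHI2_1DF_MEDIAN)


def qq_points(pvalues) -> pd.DataFrame:
    """Expected vs observed -log10 p coordinates, sorted ascending.

    Expected quantiles are ``-log10(rank / (n + 1))``.  Exact zeros are clamped
    to the smallest positive double with a warning.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values for QQ")
    if np.any(p == 0):
        warnings.warn("p-values of 0 clamped to the smallest positive double")
        p = np.maximum(p, np.nextafter(0.0, 1.0))
    n = p.size
    expected = -np.log10(np.arange(n, 0, -1) / (n + 1.0))
    observed = -np.log10(np.sort(p)[::-1])
    return pd.DataFrame({"expected": expected, "observed": observed})


@dataclass
class GwasSummary:
    lambda_gc: float
    qq: pd.DataFrame
    n_snps_tested: int


def intersect_candidates(
    records: pd.DataFrame, candidates, threshold: float = 1e-4
) -> pd.DataFrame:
    """Records with p below ``threshold`` whose id is in the candidate list.

    The default threshold 1e-4 is the nominal-significance cut used to screen
    small-effect longevity loci against adaptive candidates; the result is
    sorted by p (empty result allowed).
    """
    cand = set(candidates)
    hits = records[(records["p"] < threshold) & records["snp"].isin(cand)]
    return hits.sort_values("p", kind="mergesort").reset_index(drop=True)


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------

class GroupGWAS:
    """Genome-wide case/control logistic association between two group sets.

    Parameters
    ----------
    dataset
        :class:`~longtraj.containers.GenotypeDataset` with group labels.
    case_groups, control_groups
        Group label or iterable of labels (e.g. ``"G3"`` vs ``("G1", "G2")``).
        The sets must be disjoint and both non-empty in the data.
    covariates
        Names of individual covariates; only ``"sex"`` is defined.
    maf
        Minor-allele-frequency filter computed over the union of both groups
        (non-missing dosages); default 0.01.
    """

    def __init__(
        self,
        dataset,
        case_groups,
        control_groups,
        covariates=("sex",),
        maf: float = 0.01,
    ):
        self.dataset = dataset
        self.case_groups = (case_groups,) if isinstance(case_groups, str) else tuple(case_groups)
        self.control_groups = (
            (control_groups,) if isinstance(control_groups, str) else tuple(control_groups)
        )
        if set(self.case_groups) & set(self.control_groups):
            raise ValueError("case and control groups overlap")
        self.covariates = tuple(covariates or ())
        for c in self.covariates:
            if c != "sex":
                raise ValueError(f"unknown covariate {c!r}")
        self.maf = float(maf)
        self.case_mask = dataset.group_mask(self.case_groups)
        self.control_mask = dataset.group_mask(self.control_groups)
        if not self.case_mask.any():
            raise ValueError(f"no individuals in case groups {self.case_groups}")
        if not self.control_mask.any():
            raise ValueError(f"no individuals in control groups {self.control_groups}")

    def fit(self) -> "GWASResults":
        ds = self.dataset
        both = self.case_mask | self.control_mask
        sub = ds.subset_individuals(both)
        y = ds.group_mask(self.case_groups)[both].astype(float)
        cov = sub.sex_codes()[:, None] if "sex" in self.covariates else None

        pooled = sub.allele_freqs()
        with np.errstate(invalid="ignore"):
            keep = np.isfinite(pooled) & (np.minimum(pooled, 1 - pooled) >= self.maf)
        if not keep.any():
            raise ValueError(f"no SNPs pass the MAF >= {self.maf} filter")
        sub = sub.subset_snps(keep)

        case_local = y == 1.0
        freq_case = sub.allele_freqs(case_local)
        freq_ctrl = sub.allele_freqs(~case_local)

        rows = []
        for k in range(sub.n_snps):
            fit = fit_logistic(sub.dosages[:, k], cov, y)
            rows.append(
                (
                    sub.snp_meta["snp"].iat[k],
                    sub.snp_meta["effect_allele"].iat[k],
                    fit.beta,
                    fit.se,
                    fit.z,
                    fit.p,
                    fit.n_used,
                    freq_case[k],
                    freq_ctrl[k],
                    fit.status,
                )
            )
        records = pd.DataFrame(
            rows,
            columns=[
                "snp", "effect_allele", "beta", "se", "z", "p",
                "n_used", "freq_case", "freq_ctrl", "status",
            ],
        )
        return GWASResults(self, records)


class GWASResults:
    """Per-SNP association records plus genome-wide diagnostics."""

    def __init__(self, model: GroupGWAS, records: pd.DataFrame):
        self.model = model
        self.records = records

    @property
    def ok_pvalues(self) -> np.ndarray:
        """p-values of converged fits only (flagged SNPs excluded)."""
        ok = self.records["status"] == "ok"
        return self.records.loc[ok, "p"].to_numpy()

    @property
    def lambda_gc(self) -> float:
        return genomic_inflation(self.ok_pvalues)

    def qq(self) -> pd.DataFrame:
        return qq_points(self.ok_pvalues)

    def gwas_summary(self) -> GwasSummary:
        return GwasSummary(self.lambda_gc, self.qq(), int((self.records["status"] == "ok").sum()))

    def intersect_candidates(self, candidates, threshold: float = 1e-4) -> pd.DataFrame:
        return intersect_candidates(self.records, candidates, threshold)

    def summary(self) -> str:
        r = self.records
        n_ok = int((r["status"] == "ok").sum())
        lines = [
            "Group GWAS (logistic, Wald test)",
            f"  cases:    groups {self.model.case_groups} "
            f"(n={int(self.model.case_mask.sum())})",
            f"  controls: groups {self.model.control_groups} "
            f"(n={int(self.model.control_mask.sum())})",
            f"  covariates: {list(self.model.covariates)}   MAF filter: {self.model.maf}",
            f"  SNPs tested: {len(r)} ({n_ok} converged)",
            f"  genomic inflation lambda = {self.lambda_gc:.3f}",
        ]
        top = r[r["status"] == "ok"].nsmallest(5, "p")
        if len(top):
            lines.append("  top SNPs:")
            for _, row in top.iterrows():
                lines.append(
                    f"    {row['snp']}  beta={row['beta']:+.3f}  p={row['p']:.3g}"
                )
        return "\n".join(lines)
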