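"""In-memory containers shared across the pipeline.

A :class:`GenotypeDataset` holds an individuals x SNPs additive dosage matrix
(effect-allele copy counts 0/1/2, ``NaN`` for missing) together with per-SNP
and per-individual metadata, and is the universal input of every analysis
stage.  An :class:`AncestryMatrix` holds individuals x K ancestry fractions of
the kind produced by model-based clustering (rows sum to one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeDataset", "AncestryMatrix", "GROUP_LABELS"]

#: Valid cohort group labels: G1 = adults <=50y, G2 = 50-85y (mortality-selected),
#: G3 = centenarians (>=100y); "none" for individuals outside the age design.
GROUP_LABELS = ("G1", "G2", "G3", "none")

_SNP_META_COLS = ["snp", "chrom", "pos", "effect_allele", "other_allele"]
_IND_META_COLS = ["id", "sex", "age", "group", "center"]


@dataclass
class GenotypeDataset:
    """Dosage matrix plus SNP and individual metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_snps)`` float array counting effect-allele copies;
        entries in {0, 1, 2} or ``NaN`` for missing.
    snp_meta
        DataFrame with columns ``snp, chrom, pos, effect_allele, other_allele``.
    ind_meta
        DataFrame with columns ``id, sex, age, group, center``; ``sex`` is
        ``"F"``/``"M"`` (or ``None`` when unknown), ``group`` one of
        :data:`GROUP_LABELS`.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    ind_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x SNPs matrix")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self.ind_meta = self.ind_meta.reset_index(drop=True)
        for col in _SNP_META_COLS:
            if col not in self.snp_meta.columns:
                raise ValueError(f"snp_meta missing column {col!r}")
        for col in _IND_META_COLS:
            if col not in self.ind_meta.columns:
                raise ValueError(f"ind_meta missing column {col!r}")
        n, m = self.dosages.shape
        if len(self.ind_meta) != n:
            raise ValueError(
                f"ind_meta has {len(self.ind_meta)} rows for {n} dosage rows"
            )
        if len(self.snp_meta) != m:
            raise ValueError(
                f"snp_meta has {len(self.snp_meta)} rows for {m} dosage columns"
            )
        if self.snp_meta["snp"].duplicated().any():
            dups = self.snp_meta.loc[self.snp_meta["snp"].duplicated(), "snp"]
            raise ValueError(f"duplicate SNP ids: {sorted(set(dups))[:5]}")
        if self.ind_meta["id"].duplicated().any():
            dups = self.ind_meta.loc[self.ind_meta["id"].duplicated(), "id"]
            raise ValueError(f"duplicate individual ids: {sorted(set(dups))[:5]}")
        ages = self.ind_meta["age"].to_numpy(dtype=float)
        if np.any(ages[np.isfinite(ages)] < 0):
            raise ValueError("ages must be non-negative")
        with np.errstate(invalid="ignore"):
            bad = np.isfinite(self.dosages) & ~np.isin(self.dosages, (0.0, 1.0, 2.0))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    # ------------------------------------------------------------------ views
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["snp"].to_numpy()

    def group_mask(self, groups) -> np.ndarray:
        """Boolean individual mask for one group label or an iterable of them."""
        if isinstance(groups, str):
            groups = (groups,)
        return self.ind_meta["group"].isin(list(groups)).to_numpy()

    def sex_codes(self) -> np.ndarray:
        """Numeric sex covariate: F=0, M=1, NaN when unknown."""
        sex = self.ind_meta["sex"].to_numpy(dtype=object)
        out = np.full(len(sex), np.nan)
        out[sex == "F"] = 0.0
        out[sex == "M"] = 1.0
        return out

    def subset_individuals(self, mask) -> "GenotypeDataset":
        mask = np.asarray(mask)
        return GenotypeDataset(
            self.dosages[mask].copy(),
            self.snp_meta.copy(),
            self.ind_meta.loc[mask].reset_index(drop=True),
        )

    def subset_snps(self, mask) -> "GenotypeDataset":
        mask = np.asarray(mask)
        return GenotypeDataset(
            self.dosages[:, mask].copy(),
            self.snp_meta.loc[mask].reset_index(drop=True),
            self.ind_meta.copy(),
        )

    def allele_freqs(self, mask=None) -> np.ndarray:
        """Effect-allele frequency per SNP over non-missing dosages.

        ``mask`` optionally restricts to a subset of individuals.  SNPs with no
        observed genotypes get ``NaN``.
        """
        d = self.dosages if mask is None else self.dosages[np.asarray(mask)]
        with np.errstate(invalid="ignore"):
            obs = np.isfinite(d)
            n_obs = obs.sum(axis=0)
            tot = np.where(obs, d, 0.0).sum(axis=0)
        out = np.full(d.shape[1], np.nan)
        nz = n_obs > 0
        out[nz] = tot[nz] / (2.0 * n_obs[nz])
        return out

    def flip_snps(self, snp_ids) -> "GenotypeDataset":
        """Return a copy with the effect/other alleles of ``snp_ids`` swapped.

        Dosages of flipped SNPs become ``2 - dosage``; missingness is preserved.
        Used to verify that every downstream estimate is reported relative to
        the recorded effect allele.
        """
        snp_ids = set(np.atleast_1d(snp_ids).tolist())
        meta = self.snp_meta.copy()
        dos = self.dosages.copy()
        which = meta["snp"].isin(snp_ids).to_numpy()
        dos[:, which] = 2.0 - dos[:, which]
        ea = meta.loc[which, "effect_allele"].copy()
        meta.loc[which, "effect_allele"] = meta.loc[which, "other_allele"].to_numpy()
        meta.loc[which, "other_allele"] = ea.to_numpy()
        return GenotypeDataset(dos, meta, self.ind_meta.copy())

    def __eq__(self, other) -> bool:  # value equality, used by determinism tests
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            np.array_equal(self.dosages, other.dosages, equal_nan=True)
            and self.snp_meta.equals(other.snp_meta)
            and self.ind_meta.equals(other.ind_meta)
        )


@dataclass
class AncestryMatrix:
    """Individuals x K ancestry fractions; every row sums to 1.

    ``groups`` is an optional per-individual label vector (e.g. centenarians vs
    controls) used by the enrichment comparison.
    """

    proportions: np.ndarray
    component_labels: list[str] = field(default_factory=list)
    ids: list[str] = field(default_factory=list)
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.ndim != 2:
            raise ValueError("proportions must be 2-D")
        n, k = self.proportions.shape
        if not self.component_labels:
            self.component_labels = [f"K{i + 1}" for i in range(k)]
        if len(self.component_labels) != k:
            raise ValueError("component_labels length mismatch")
        if not self.ids:
            self.ids = [f"I{i + 1:06d}" for i in range(n)]
        if len(self.ids) != n:
            raise ValueError("ids length mismatch")
        if self.groups is not None and len(self.groups) != n:
            raise ValueError("groups length mismatch")
        if np.any(self.proportions < 0) or np.any(self.proportions > 1):
            raise ValueError("ancestry fractions must lie in [0, 1]")
        sums = self.proportions.sum(axis=1)
        bad = np.nonzero(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValueError(f"row {bad[0]} sums to {sums[bad[0]]:.8f}, not 1")

    @property
    def n_individuals(self) -> int:
        return self.proportions.shape[0]

    @property
    def k(self) -> int:
        return self.proportions.shape[1]

    def component_index(self, component) -> int:
        """Resolve a component given as index or label."""
        if isinstance(component, str):
            if component not in self.component_labels:
                raise KeyError(f"unknown ancestry component {component!r}")
            return self.component_labels.index(component)
        idx = int(component)
        if not 0 <= idx < self.k:
            raise IndexError(f"component index {idx} out of range for K={self.k}")
        return idx
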