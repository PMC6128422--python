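"""Allele-frequency trajectory classification across three age groups.

For every SNP, three pairwise sex-adjusted logistic contrasts are fitted
(G1 vs G2, G1 vs G3, G2 vs G3; the older group coded as case) and the SNP is
assigned one of six trajectory classes from the pattern of nominal
significance (p < alpha, default 0.01) and frequency-difference directions:

=====  =====================================================================
Class  Frequency trajectory (relative to the recorded effect allele)
=====  =====================================================================
A      up in G2, back down in centenarians; G1 ~ G3 ("from good to bad")
B      down in G2, back up in centenarians; G1 ~ G3 ("from bad to good")
C      increased in both G2 and centenarians vs the general population (G1)
D      decreased in both G2 and centenarians vs G1
E      decreased in centenarians only; G1 ~ G2
F      increased in centenarians only; G1 ~ G2
=====  =====================================================================

"Similar frequencies" is operationalised as non-significance at the same
alpha.  Directions come from raw frequency differences (defined even when a
fit is flagged); exact ties give direction 0 and leave the SNP unclassified.
The six predicates are mutually exclusive by construction — A/B require a
non-significant G1-G3 contrast while C/D require a significant one, E/F
require a non-significant G1-G2 contrast while A-D require a significant one,
and within each pair the directions conflict — so each SNP receives exactly
one label (or UNCLASSIFIED).

Per-SNP combined p-values aggregate the three contrasts with Fisher's method
by default (chi-square with 2k df on -2*sum(log p) over the k available
contrasts); a Stouffer option exists.  No multiple-testing correction is part
of the procedure (it is deliberately nominal); Benjamini-Hochberg q-values on
the combined p are emitted for information only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import gio
from .assoc import fit_logistic

__all__ = [
    "CLASS_LABELS",
    "pairwise_tests",
    "combine_pvalues",
    "classify_trajectory",
    "TrajectoryModel",
    "TrajectoryResults",
]

CLASS_LABELS = ("A", "B", "C", "D", "E", "F", "UNCLASSIFIED")

_CONTRASTS = (("G1", "G2", "12"), ("G1", "G3", "13"), ("G2", "G3", "23"))


def pairwise_tests(dataset, covariates=("sex",), maf: float = 0.01) -> pd.DataFrame:
    """Three pairwise logistic contrasts per SNP plus per-group frequencies.

    Returns a DataFrame with one row per SNP passing the MAF filter (computed
    over all three groups): columns ``snp, effect_allele, f1, f2, f3,
    p12, p13, p23, d12, d13, d23, status12, status13, status23``.  In each
    contrast the later age group is coded as the case, so a positive beta
    means the effect allele is enriched in the older group.
    """
    masks = {g: dataset.group_mask(g) for g in ("G1", "G2", "G3")}
    for g, msk in masks.items():
        if not msk.any():
            raise ValueError(f"group {g} is empty")
    pooled_mask = masks["G1"] | masks["G2"] | masks["G3"]
    pooled = dataset.allele_freqs(pooled_mask)
    with np.errstate(invalid="ignore"):
        keep = np.isfinite(pooled) & (np.minimum(pooled, 1 - pooled) >= maf)
    if not keep.any():
        raise ValueError(f"no SNPs pass the MAF >= {maf} filter")
    ds = dataset.subset_snps(keep)

    sex = ds.sex_codes()
    freqs = {g: ds.allele_freqs(masks[g]) for g in masks}

    rows = []
    for k in range(ds.n_snps):
        rec = {
            "snp": ds.snp_meta["snp"].iat[k],
            "effect_allele": ds.snp_meta["effect_allele"].iat[k],
            "f1": freqs["G1"][k],
            "f2": freqs["G2"][k],
            "f3": freqs["G3"][k],
        }
        for ctrl, case, tag in _CONTRASTS:
            sel = masks[ctrl] | masks[case]
            y = masks[case][sel].astype(float)
            cov = sex[sel][:, None] if "sex" in (covariates or ()) else None
            fit = fit_logistic(ds.dosages[sel, k], cov, y)
            rec[f"p{tag}"] = fit.p
            rec[f"status{tag}"] = fit.status
        rec["d12"] = _sign(rec["f2"] - rec["f1"])
        rec["d13"] = _sign(rec["f3"] - rec["f1"])
        rec["d23"] = _sign(rec["f3"] - rec["f2"])
        rows.append(rec)
    return pd.DataFrame(rows)


def _sign(x: float) -> int:
    if not np.isfinite(x) or x == 0:
        return 0
    return 1 if x > 0 else -1


def combine_pvalues(p12, p13, p23, method: str = "fisher") -> float:
    """Combine the pairwise p-values into one per-SNP summary.

    NaN contrasts are excluded with the degrees of freedom adjusted; with all
    three missing the result is NaN.  Inputs are clamped below at 1e-300.
    With a single available contrast Fisher's method reduces to that p-value.
    """
    ps = [p for p in (p12, p13, p23) if p is not None and np.isfinite(p)]
    if not ps:
        return float("nan")
    ps = [min(max(float(p), 1e-300), 1.0) for p in ps]
    k = len(ps)
    if method == "fisher":
        x = -2.0 * sum(math.log(p) for p in ps)
        return float(stats.chi2.sf(x, df=2 * k))
    if method == "stouffer":
        z = sum(stats.norm.isf(p) for p in ps) / math.sqrt(k)
        return float(min(max(stats.norm.sf(z), np.nextafter(0.0, 1.0)), 1.0))
    raise ValueError(f"unknown combination method {method!r}")


def classify_trajectory(p12, p13, p23, d12, d13, d23, alpha: float = 0.01) -> str:
    """Assign a trajectory class from significance and direction patterns.

    ``S_ij = p_ij < alpha`` where available (NaN p => unknown); ``d_ij`` are
    frequency-difference signs in {-1, 0, +1}.  A class is assigned only when
    every contrast its predicate needs is available; otherwise the SNP is
    UNCLASSIFIED.
    """
    def s(p):
        return None if p is None or not np.isfinite(p) else bool(p < alpha)

    s12, s13, s23 = s(p12), s(p13), s(p23)
    # A/B: significant rise-then-fall (or fall-then-rise), ends back near G1
    if s12 and s23 and s13 is False:
        if d12 == 1 and d23 == -1:
            return "A"
        if d12 == -1 and d23 == 1:
            return "B"
    # C/D: monotone shift already present in G2 and persisting in centenarians
    if s12 and s13:
        if d12 == 1 and d13 == 1:
            return "C"
        if d12 == -1 and d13 == -1:
            return "D"
    # E/F: centenarian-specific shift, G1 and G2 similar
    if s12 is False and s13 and s23:
        if d13 == -1 and d23 == -1:
            return "E"
        if d13 == 1 and d23 == 1:
            return "F"
    return "UNCLASSIFIED"


class TrajectoryModel:
    """Three-group trajectory analysis of a cohort dataset.

    Parameters
    ----------
    dataset
        Cohort with G1/G2/G3 group labels.
    alpha
        Nominal significance level for the pairwise contrasts (default 0.01).
    covariates
        Individual covariates for the logistic fits (default sex).
    combine
        Per-SNP p-value combination method, ``"fisher"`` or ``"stouffer"``.
    maf
        Minor-allele-frequency filter over the three groups pooled.
    """

    def __init__(
        self,
        dataset,
        alpha: float = 0.01,
        covariates=("sex",),
        combine: str = "fisher",
        maf: float = 0.01,
    ):
        if not 0 < alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if combine not in ("fisher", "stouffer"):
            raise ValueError(f"unknown combination method {combine!r}")
        self.dataset = dataset
        self.alpha = float(alpha)
        self.covariates = tuple(covariates or ())
        self.combine = combine
        self.maf = float(maf)

    def fit(self) -> "TrajectoryResults":
        rec = pairwise_tests(self.dataset, self.covariates, self.maf)
        rec["combined_p"] = [
            combine_pvalues(r.p12, r.p13, r.p23, self.combine)
            for r in rec.itertuples()
        ]
        rec["class"] = [
            classify_trajectory(
                r.p12, r.p13, r.p23, r.d12, r.d13, r.d23, self.alpha
            )
            for r in rec.itertuples()
        ]
        rec["fdr_combined"] = _benjamini_hochberg(rec["combined_p"].to_numpy())
        # direction consistency is part of the class contract; check on emit
        bad_a = rec[(rec["class"] == "A") & ~((rec.f2 > rec.f1) & (rec.f2 > rec.f3))]
        if len(bad_a):
            raise AssertionError("Class A record violates f2 > f1 and f2 > f3")
        return TrajectoryResults(self, rec)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    n = pv.size
    if n == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


@dataclass
class TrajectoryResults:
    """Per-SNP trajectory records plus class counts."""

    model: TrajectoryModel
    records: pd.DataFrame

    @property
    def class_counts(self) -> pd.Series:
        counts = self.records["class"].value_counts()
        return counts.reindex(CLASS_LABELS, fill_value=0)

    def to_table(self) -> pd.DataFrame:
        """Result table in the canonical column order (see gio)."""
        t = self.records.rename(
            columns={"f1": "freq_g1", "f2": "freq_g2", "f3": "freq_g3"}
        )
        cols = [
            "snp", "effect_allele", "freq_g1", "freq_g2", "freq_g3",
            "p12", "p13", "p23", "d12", "d13", "d23",
            "combined_p", "fdr_combined", "class",
        ]
        return t[cols]

    def write(self, path) -> None:
        gio.write_assoc_table(self.to_table(), path)

    def summary(self) -> str:
        counts = self.class_counts
        lines = [
            "Allele-frequency trajectory classification",
            f"  alpha = {self.model.alpha}   combination = {self.model.combine}",
            f"  SNPs analysed: {len(self.records)}",
            "  class counts: "
            + "  ".join(f"{c}={counts[c]}" for c in CLASS_LABELS),
        ]
        named = self.records[self.records["class"] != "UNCLASSIFIED"]
        top = named.nsmallest(5, "combined_p")
        if len(top):
            lines.append("  strongest classified SNPs (combined p):")
            for _, r in top.iterrows():
                lines.append(
                    f"    {r['snp']}  class {r['class']}  "
                    f"f1={r['f1']:.3f} f2={r['f2']:.3f} f3={r['f3']:.3f}  "
                    f"combined_p={r['combined_p']:.3g}"
                )
        return "\n".join(lines)
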