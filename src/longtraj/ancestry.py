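"""Ancestry-component comparisons between cohort groups.

Two operations: (i) test whether the mean fraction of one ancestry component
differs between two groups of individuals (e.g. centenarians vs controls) —
Welch's unequal-variance t test by default, with a Wilcoxon rank-sum option;
(ii) rank SNPs by how informative their dosage is of a component, scored as
the absolute Pearson correlation between dosage and the component fraction
across individuals (a documented stand-in for extracting the markers that tag
an ancestry signature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AncestryMatrix

__all__ = ["EnrichmentResult", "component_enrichment", "informative_snps"]

_TESTS = ("welch", "ranksum")


@dataclass
class EnrichmentResult:
    component: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    difference: float
    statistic: float
    pvalue: float
    test: str
    n_a: int
    n_b: int

    def summary(self) -> str:
        return (
            f"Ancestry component {self.component}: "
            f"{self.group_a} mean {self.mean_a:.4f} (n={self.n_a}) vs "
            f"{self.group_b} mean {self.mean_b:.4f} (n={self.n_b}); "
            f"difference {self.difference:+.4f}, {self.test} p = {self.pvalue:.3g}"
        )


def component_enrichment(
    q: AncestryMatrix,
    group_a: str,
    group_b: str,
    component,
    groups=None,
    test: str = "welch",
) -> EnrichmentResult:
    """Two-group comparison of one ancestry component's fractions.

    ``groups`` overrides the labels stored in ``q``; both selected groups need
    at least 2 members.  The two-sided p-value comes from Welch's t test
    (default) or the Wilcoxon rank-sum test.
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {_TESTS}")
    labels = np.asarray(groups if groups is not None else q.groups)
    if labels is None or labels.size != q.n_individuals:
        raise ValueError("group labels missing or misaligned")
    idx = q.component_index(component)
    frac = q.proportions[:, idx]
    xa = frac[labels == group_a]
    xb = frac[labels == group_b]
    if xa.size < 2 or xb.size < 2:
        small = group_a if xa.size < 2 else group_b
        raise ValueError(f"group {small!r} has fewer than 2 members")
    if test == "welch":
        stat, p = stats.ttest_ind(xa, xb, equal_var=False)
    else:
        stat, p = stats.ranksums(xa, xb)
    return EnrichmentResult(
        component=q.component_labels[idx],
        group_a=group_a,
        group_b=group_b,
        mean_a=float(xa.mean()),
        mean_b=float(xb.mean()),
        difference=float(xa.mean() - xb.mean()),
        statistic=float(stat),
        pvalue=float(p),
        test=test,
        n_a=int(xa.size),
        n_b=int(xb.size),
    )


def informative_snps(dataset, q: AncestryMatrix, component, top_n: int) -> pd.DataFrame:
    """Rank SNPs by |Pearson correlation| between dosage and a component.

    Missing dosages are dropped pairwise.  Scores lie in [0, 1] and are
    invariant to effect-allele flips; SNPs with constant dosage score 0.
    Returns the ``top_n`` SNPs sorted by score descending, ties broken by SNP
    id.
    """
    if dataset.n_individuals != q.n_individuals:
        raise ValueError("dataset and ancestry matrix are not aligned")
    if top_n < 0:
        raise ValueError("top_n must be >= 0")
    idx = q.component_index(component)
    frac = q.proportions[:, idx]
    if np.ptp(frac) == 0:
        raise ValueError("ancestry component is constant across individuals")

    D = dataset.dosages
    scores = np.zeros(D.shape[1])
    for k in range(D.shape[1]):
        obs = np.isfinite(D[:, k])
        x = D[obs, k]
        f = frac[obs]
        if x.size < 3 or np.ptp(x) == 0 or np.ptp(f) == 0:
            continue
        r = np.corrcoef(x, f)[0, 1]
        if np.isfinite(r):
            scores[k] = abs(r)
    out = pd.DataFrame({"snp": dataset.snp_meta["snp"], "score": scores})
    out = out.sort_values(
        ["score", "snp"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out.head(int(top_n)).reset_index(drop=True)
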