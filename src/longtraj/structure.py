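"""Population-structure analysis: reference PCA, least-squares projection, DAPC.

The design follows the supplementary-group convention used for longevity
cohorts: the PCA space is defined by the *reference* individuals only (the
general-population controls), and the group of interest (centenarians) is
placed into that fixed space afterwards, so that group-specific variants
cannot distort the axes.  Placement uses a per-individual least-squares fit
over the non-missing markers — with complete data this reduces exactly to
ordinary projection, and with missing data it is the behaviour known as
``lsqproject`` in the EIGENSOFT tradition.

Genotypes are normalised per SNP by mean-centering and dividing by
``sqrt(p_hat (1 - p_hat))`` where ``p_hat = (1 + sum dosage) / (2 + 2n)`` is
the shrunk allele-frequency estimate (Patterson normalisation); missing
entries are zeroed after centering.

Discriminant analysis of principal components (DAPC) then builds linear
discriminant axes on the retained reference PCs, models each class as a
multivariate normal with shared within-class covariance in discriminant
space, and yields posterior membership probabilities (priors proportional to
class sizes) for supplementary individuals, averaged per recruitment center.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import logsumexp

__all__ = ["GenotypePCA", "PCAResults", "DAPC", "DAPCResults"]

logger = logging.getLogger(__name__)


def _fix_signs(loadings: np.ndarray, scores: np.ndarray | None = None):
    """Make each loading column's largest-magnitude entry positive (in place)."""
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            if scores is not None:
                scores[:, j] *= -1


class GenotypePCA:
    """PCA of a reference genotype dataset.

    Parameters
    ----------
    reference
        Reference :class:`~longtraj.containers.GenotypeDataset`; SNPs that are
        monomorphic in it are dropped (logged).
    n_components
        Number of retained components (default 10); must not exceed the rank
        of the normalised matrix.
    scale
        ``"patterson"`` (default) for sqrt(p(1-p)) scaling with the shrunk
        frequency, ``"none"`` for plain centering.
    """

    def __init__(self, reference, n_components: int = 10, scale: str = "patterson"):
        if scale not in ("patterson", "none"):
            raise ValueError(f"unknown scale {scale!r}")
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.reference = reference
        self.n_components = int(n_components)
        self.scale = scale

    def fit(self) -> "PCAResults":
        ds = self.reference
        D = ds.dosages
        obs = np.isfinite(D)
        n_obs = obs.sum(axis=0)
        tot = np.where(obs, D, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = tot / n_obs
        # monomorphic = no variation among observed dosages
        var = np.nanvar(np.where(obs, D, np.nan), axis=0)
        poly = (n_obs > 0) & (var > 0)
        n_dropped = int((~poly).sum())
        if n_dropped:
            logger.info("dropping %d monomorphic/unobserved SNPs before PCA", n_dropped)
        if not poly.any():
            raise ValueError("all SNPs are monomorphic in the reference")

        ds = ds.subset_snps(poly)
        D, mean, n_obs, tot = D[:, poly], mean[poly], n_obs[poly], tot[poly]
        p_shrunk = (1.0 + tot) / (2.0 + 2.0 * n_obs)
        if self.scale == "patterson":
            scl = np.sqrt(p_shrunk * (1.0 - p_shrunk))
        else:
            scl = np.ones_like(p_shrunk)

        X = (D - mean) / scl
        X[~np.isfinite(X)] = 0.0
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        rank = int((S > S[0] * 1e-9).sum()) if S.size else 0
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds rank {rank} of the "
                f"normalised reference matrix"
            )
        k = self.n_components
        loadings = Vt[:k].T.copy()
        scores = (U[:, :k] * S[:k]).copy()
        _fix_signs(loadings, scores)
        eigenvalues = S[:k] ** 2 / max(ds.n_individuals - 1, 1)
        return PCAResults(
            snp_ids=ds.snp_meta["snp"].to_numpy(),
            effect_alleles=ds.snp_meta["effect_allele"].to_numpy(),
            other_alleles=ds.snp_meta["other_allele"].to_numpy(),
            means=mean,
            scales=scl,
            loadings=loadings,
            eigenvalues=eigenvalues,
            scores=scores,
            ref_ids=ds.ind_meta["id"].to_numpy(),
            ref_centers=ds.ind_meta["center"].to_numpy(),
        )


@dataclass
class PCAResults:
    """Reference-fitted projection space.

    ``loadings`` is SNPs x components with orthonormal columns;
    ``scores`` are the reference individuals' coordinates.
    """

    snp_ids: np.ndarray
    effect_alleles: np.ndarray
    other_alleles: np.ndarray
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    ref_ids: np.ndarray
    ref_centers: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def _align(self, dataset) -> np.ndarray:
        """Dosages of ``dataset`` aligned to the model's SNPs and alleles.

        SNP sets must match by id; allele flips are reconciled as
        ``2 - dosage`` (effect/other swapped).
        """
        meta = dataset.snp_meta.set_index("snp")
        missing = [s for s in self.snp_ids if s not in meta.index]
        if missing:
            raise ValueError(f"supplementary data lack model SNP {missing[0]!r}")
        # extra SNPs (e.g. ones dropped as monomorphic during the fit) are
        # simply ignored; the model's SNP set drives the projection
        order = [meta.index.get_loc(s) for s in self.snp_ids]
        D = dataset.dosages[:, order].copy()
        ea = meta["effect_allele"].to_numpy()[order]
        oa = meta["other_allele"].to_numpy()[order]
        same = (ea == self.effect_alleles)
        flipped = (ea == self.other_alleles) & (oa == self.effect_alleles)
        bad = ~(same | flipped)
        if bad.any():
            k = int(np.argmax(bad))
            raise ValueError(
                f"SNP {self.snp_ids[k]!r}: alleles {ea[k]}/{oa[k]} do not match "
                f"model alleles {self.effect_alleles[k]}/{self.other_alleles[k]}"
            )
        D[:, flipped] = 2.0 - D[:, flipped]
        return D

    def project(self, dataset) -> pd.DataFrame:
        """Least-squares placement of supplementary individuals.

        Per individual, the retained-component scores solve the least-squares
        regression of the normalised non-missing dosages on the corresponding
        loading rows; with no missingness this equals ordinary projection.
        Individuals with fewer non-missing SNPs than components get NaN scores
        (with a warning).
        """
        D = self._align(dataset)
        X = (D - self.means) / self.scales
        out = np.full((X.shape[0], self.n_components), np.nan)
        k = self.n_components
        for i in range(X.shape[0]):
            obs = np.isfinite(X[i])
            if int(obs.sum()) < k:
                warnings.warn(
                    f"individual {dataset.ind_meta['id'].iat[i]!r} has fewer "
                    f"non-missing SNPs than components; scores set to NaN"
                )
                continue
            if obs.all():
                out[i] = X[i] @ self.loadings
            else:
                sol, *_ = np.linalg.lstsq(self.loadings[obs], X[i, obs], rcond=None)
                out[i] = sol
        cols = [f"PC{j + 1}" for j in range(k)]
        return pd.DataFrame(out, columns=cols, index=dataset.ind_meta["id"].to_numpy())

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.n_components)]
        return pd.DataFrame(self.scores, columns=cols, index=self.ref_ids)


# --------------------------------------------------------------------------
# DAPC
# --------------------------------------------------------------------------

class DAPC:
    """Discriminant analysis of principal components.

    Parameters
    ----------
    scores
        Reference individuals x retained PCs (array or DataFrame).
    labels
        Per-individual class labels (>=2 classes, each with >=2 members).
    n_pcs
        Number of leading PCs to retain (default: all provided).
    n_discriminants
        Number of discriminant axes (default and maximum: n_classes - 1).
    """

    def __init__(self, scores, labels, n_pcs: int | None = None,
                 n_discriminants: int | None = None):
        self.scores = np.asarray(
            scores.to_numpy() if isinstance(scores, pd.DataFrame) else scores,
            dtype=float,
        )
        self.labels = np.asarray(labels)
        if self.scores.shape[0] != self.labels.shape[0]:
            raise ValueError("scores and labels length mismatch")
        self.n_pcs = int(n_pcs) if n_pcs is not None else self.scores.shape[1]
        if not 1 <= self.n_pcs <= self.scores.shape[1]:
            raise ValueError("n_pcs out of range")
        self.n_discriminants = n_discriminants

    def fit(self) -> "DAPCResults":
        X = self.scores[:, : self.n_pcs]
        classes, y = np.unique(self.labels, return_inverse=True)
        K = classes.size
        if K < 2:
            raise ValueError("DAPC needs at least 2 classes")
        counts = np.bincount(y)
        if counts.min() < 2:
            small = classes[int(np.argmin(counts))]
            raise ValueError(f"class {small!r} has fewer than 2 members")
        max_d = K - 1
        d = max_d if self.n_discriminants is None else int(self.n_discriminants)
        if not 1 <= d <= max_d:
            raise ValueError(f"n_discriminants must lie in [1, {max_d}]")

        grand = X.mean(axis=0)
        means = np.vstack([X[y == k].mean(axis=0) for k in range(K)])
        Sw = np.zeros((X.shape[1], X.shape[1]))
        for k in range(K):
            R = X[y == k] - means[k]
            Sw += R.T @ R
        Sw /= max(X.shape[0] - K, 1)
        Sb = np.zeros_like(Sw)
        for k in range(K):
            diff = (means[k] - grand)[:, None]
            Sb += counts[k] * (diff @ diff.T)
        Sb /= max(X.shape[0] - 1, 1)

        try:
            # generalized symmetric eigenproblem; eigvecs are Sw-orthonormal,
            # so within-class covariance in discriminant space is ~identity
            evals, evecs = linalg.eigh(Sb, Sw)
        except linalg.LinAlgError as exc:
            raise ValueError(
                "singular within-class covariance; retain fewer PCs"
            ) from exc
        order = np.argsort(evals)[::-1][:d]
        W = evecs[:, order].copy()
        _fix_signs(W)

        Z = X @ W
        zmeans = np.vstack([Z[y == k].mean(axis=0) for k in range(K)])
        Swz = np.zeros((d, d))
        for k in range(K):
            R = Z[y == k] - zmeans[k]
            Swz += R.T @ R
        Swz /= max(Z.shape[0] - K, 1)
        priors = counts / counts.sum()
        return DAPCResults(
            n_pcs=self.n_pcs,
            axes=W,
            class_labels=classes,
            class_means=zmeans,
            within_cov=Swz,
            priors=priors,
            eigenvalues=np.sort(evals)[::-1][:d],
        )


@dataclass
class DAPCResults:
    """Fitted discriminant model with Gaussian class-conditionals."""

    n_pcs: int
    axes: np.ndarray           # (n_pcs, d)
    class_labels: np.ndarray
    class_means: np.ndarray    # (K, d)
    within_cov: np.ndarray     # (d, d), shared
    priors: np.ndarray
    eigenvalues: np.ndarray

    def transform(self, scores) -> np.ndarray:
        X = np.asarray(
            scores.to_numpy() if isinstance(scores, pd.DataFrame) else scores,
            dtype=float,
        )[:, : self.n_pcs]
        return X @ self.axes

    def posterior(self, scores, centers=None):
        """Posterior class membership of supplementary individuals.

        Posterior proportional to ``prior x N(z; class mean, shared cov)`` at
        the individual's discriminant coordinates; rows sum to 1.  When
        ``centers`` is given, also returns the per-center mean posterior
        (individuals with a missing/unseen label grouped under ``"unknown"``).
        """
        Z = self.transform(scores)
        cov_inv = np.linalg.inv(self.within_cov)
        _, logdet = np.linalg.slogdet(self.within_cov)
        loglik = np.empty((Z.shape[0], self.class_labels.size))
        for k in range(self.class_labels.size):
            diff = Z - self.class_means[k]
            maha = np.einsum("ij,jk,ik->i", diff, cov_inv, diff)
            loglik[:, k] = -0.5 * (maha + logdet)
        logpost = loglik + np.log(self.priors)
        post = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))
        idx = (
            scores.index
            if isinstance(scores, pd.DataFrame)
            else np.arange(Z.shape[0])
        )
        post_df = pd.DataFrame(post, columns=self.class_labels, index=idx)
        if centers is None:
            return post_df
        cen = pd.Series(np.asarray(centers, dtype=object), index=post_df.index)
        cen = cen.where(cen.notna() & (cen != ""), "unknown")
        per_center = post_df.groupby(cen).mean()
        per_center.index.name = "center"
        return post_df, per_center

    def summary(self) -> str:
        lines = [
            "DAPC (shared-covariance Gaussian discriminant model)",
            f"  retained PCs: {self.n_pcs}   discriminant axes: {self.axes.shape[1]}",
            "  classes: "
            + "  ".join(
                f"{lab} (prior {pr:.3f})"
                for lab, pr in zip(self.class_labels, self.priors)
            ),
        ]
        return "\n".join(lines)
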