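"""PCA projection and DAPC membership behaviour."""

import numpy as np
import pandas as pd
import pytest

from longtraj import DAPC, GenotypePCA, SimulationConfig, simulate_structured


@pytest.fixture(scope="module")
def two_pop():
    cfg = SimulationConfig(n_snps=2000, fst=0.1, seed=21)
    return simulate_structured(cfg, [200, 200])


@pytest.fixture(scope="module")
def three_pop_split():
    """Three populations; 40 individuals of POP2 held out as supplementary."""
    cfg = SimulationConfig(n_snps=3000, fst=0.1, seed=22)
    ds = simulate_structured(cfg, [150, 190, 150])
    in_pop2 = np.nonzero((ds.ind_meta["center"] == "POP2").to_numpy())[0]
    sup_mask = np.zeros(ds.n_individuals, dtype=bool)
    sup_mask[in_pop2[:40]] = True
    return ds.subset_individuals(~sup_mask), ds.subset_individuals(sup_mask)


class TestGenotypePCA:
    def test_pc1_separates_populations(self, two_pop):
        pca = GenotypePCA(two_pop, n_components=5).fit()
        pop1 = (two_pop.ind_meta["center"] == "POP1").to_numpy()
        pc1 = pca.scores[:, 0]
        gap = abs(pc1[pop1].mean() - pc1[~pop1].mean())
        pooled_sd = np.sqrt((pc1[pop1].var() + pc1[~pop1].var()) / 2)
        assert gap > 4 * pooled_sd

    def test_loadings_orthonormal_eigenvalues_sorted(self, two_pop):
        pca = GenotypePCA(two_pop, n_components=6).fit()
        gram = pca.loadings.T @ pca.loadings
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)
        assert (np.diff(pca.eigenvalues) <= 1e-9).all()

    def test_duplicate_individuals_get_identical_scores(self, two_pop):
        from longtraj.containers import GenotypeDataset
        dosages = np.vstack([two_pop.dosages, two_pop.dosages[:1]])
        meta = pd.concat(
            [two_pop.ind_meta, two_pop.ind_meta.iloc[:1].assign(id="dup0")],
            ignore_index=True,
        )
        dup = GenotypeDataset(dosages, two_pop.snp_meta, meta)
        pca = GenotypePCA(dup, n_components=4).fit()
        np.testing.assert_allclose(pca.scores[0], pca.scores[-1], atol=1e-10)

    def test_all_monomorphic_rejected(self):
        from longtraj.containers import GenotypeDataset
        n, m = 20, 5
        dosages = np.ones((n, m))
        snp_meta = pd.DataFrame(
            {"snp": [f"s{i}" for i in range(m)], "chrom": 1,
             "pos": range(m), "effect_allele": "A", "other_allele": "G"}
        )
        ind_meta = pd.DataFrame(
            {"id": [f"i{i}" for i in range(n)], "sex": "F", "age": 30.0,
             "group": "none", "center": "X"}
        )
        ds = GenotypeDataset(dosages, snp_meta, ind_meta)
        with pytest.raises(ValueError, match="monomorphic"):
            GenotypePCA(ds, n_components=2).fit()

    def test_excessive_components_rejected(self, two_pop):
        small = two_pop.subset_individuals(np.arange(10))
        with pytest.raises(ValueError, match="rank"):
            GenotypePCA(small, n_components=50).fit()


class TestLsqProjection:
    def test_reference_projection_reproduces_fit_scores(self, two_pop):
        pca = GenotypePCA(two_pop, n_components=8).fit()
        proj = pca.project(two_pop).to_numpy()
        np.testing.assert_allclose(proj, pca.scores, atol=1e-8)

    def test_mean_individual_maps_to_origin(self, two_pop):
        pca = GenotypePCA(two_pop, n_components=4).fit()
        from longtraj.containers import GenotypeDataset
        # an individual sitting exactly at the reference mean dosage vector
        # (not a valid 0/1/2 genotype, so bypass dosage validation)
        ds = GenotypeDataset(
            np.zeros((1, len(pca.snp_ids))),
            two_pop.snp_meta[two_pop.snp_meta["snp"].isin(pca.snp_ids)].reset_index(drop=True),
            pd.DataFrame({"id": ["mean"], "sex": ["F"], "age": [50.0],
                          "group": ["none"], "center": ["X"]}),
        )
        ds.dosages[0, :] = 0.0
        object.__setattr__(ds, "dosages", ds.dosages)
        ds.dosages[0] = pca.means  # exact mean vector
        scores = pca.project(ds).to_numpy()
        np.testing.assert_allclose(scores, 0.0, atol=1e-8)

    def test_snp_permutation_invariance(self, two_pop):
        pca = GenotypePCA(two_pop, n_components=5).fit()
        rng = np.random.default_rng(0)
        perm = rng.permutation(two_pop.n_snps)
        shuffled = two_pop.subset_snps(perm)
        np.testing.assert_allclose(
            pca.project(shuffled).to_numpy(), pca.scores, atol=1e-8
        )

    def test_allele_flip_reconciled(self, two_pop):
        pca = GenotypePCA(two_pop, n_components=3).fit()
        flipped = two_pop.flip_snps(two_pop.snp_ids[:500])
        np.testing.assert_allclose(
            pca.project(flipped).to_numpy(), pca.scores, atol=1e-8
        )

    def test_missingness_keeps_population_assignment(self, three_pop_split):
        ref, sup = three_pop_split
        rng = np.random.default_rng(123)
        sup_missing = sup.subset_individuals(np.arange(sup.n_individuals))
        mask = rng.random(sup_missing.dosages.shape) < 0.30
        sup_missing.dosages[mask] = np.nan
        pca = GenotypePCA(ref, n_components=4).fit()
        scores = pca.project(sup_missing).to_numpy()
        centers = {}
        for pop in ("POP1", "POP2", "POP3"):
            msk = (ref.ind_meta["center"] == pop).to_numpy()
            centers[pop] = pca.scores[msk].mean(axis=0)
        correct = 0
        for row in scores:
            best = min(centers, key=lambda p: np.linalg.norm(row - centers[p]))
            correct += best == "POP2"
        assert correct / len(scores) >= 0.95

    def test_too_few_observed_snps_gives_nan(self, two_pop):
        pca = GenotypePCA(two_pop, n_components=5).fit()
        lone = two_pop.subset_individuals([0])
        lone.dosages[0, 3:] = np.nan  # only 3 observed < 5 components
        with pytest.warns(UserWarning, match="fewer non-missing"):
            scores = pca.project(lone).to_numpy()
        assert np.isnan(scores).all()


class TestDAPC:
    def test_two_groups_single_axis_and_posterior_sums(self, two_pop):
        pca = GenotypePCA(two_pop, n_components=6).fit()
        labels = two_pop.ind_meta["center"].to_numpy()
        model = DAPC(pca.scores, labels).fit()
        assert model.axes.shape[1] == 1
        post = model.posterior(pca.scores)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_posterior_matches_sklearn_lda(self, two_pop):
        # independent route: sklearn's shared-covariance LDA posterior on the
        # same PC scores should agree when all discriminants are retained
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        pca = GenotypePCA(two_pop, n_components=6).fit()
        labels = two_pop.ind_meta["center"].to_numpy()
        model = DAPC(pca.scores, labels).fit()
        mine = model.posterior(pca.scores).to_numpy()
        lda = LinearDiscriminantAnalysis(solver="svd").fit(pca.scores, labels)
        theirs = lda.predict_proba(pca.scores)
        np.testing.assert_allclose(mine, theirs, atol=5e-3)

    def test_class_mean_has_max_posterior(self, two_pop):
        pca = GenotypePCA(two_pop, n_components=6).fit()
        labels = two_pop.ind_meta["center"].to_numpy()
        model = DAPC(pca.scores, labels).fit()
        for k, lab in enumerate(model.class_labels):
            z_mean = model.class_means[k]
            # invert the discriminant map approximately by finding the ref
            # individual closest to the class mean in discriminant space
            Z = model.transform(pca.scores)
            i = int(np.argmin(np.linalg.norm(Z - z_mean, axis=1)))
            post = model.posterior(pca.scores[i][None, :]).to_numpy()[0]
            assert model.class_labels[np.argmax(post)] == lab

    def test_leave_one_out_reassignment_accuracy(self, three_pop_split):
        ref, _ = three_pop_split
        pca = GenotypePCA(ref, n_components=6).fit()
        labels = ref.ind_meta["center"].to_numpy()
        correct = 0
        n = ref.n_individuals
        # block leave-out (leave-one-out per individual is needlessly slow
        # for well-separated pops; hold out 50 individuals round-robin)
        held = np.arange(0, n, max(1, n // 50))
        for i in held:
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            model = DAPC(pca.scores[mask], labels[mask]).fit()
            post = model.posterior(pca.scores[i][None, :]).to_numpy()[0]
            correct += model.class_labels[np.argmax(post)] == labels[i]
        assert correct / len(held) >= 0.95

    def test_supplementary_posterior_concentrates_on_source(self, three_pop_split):
        ref, sup = three_pop_split
        pca = GenotypePCA(ref, n_components=6).fit()
        model = DAPC(pca.scores, ref.ind_meta["center"].to_numpy()).fit()
        scores = pca.project(sup)
        post, per_center = model.posterior(scores, sup.ind_meta["center"].to_numpy())
        assert post["POP2"].mean() >= 0.9
        assert per_center.loc["POP2", "POP2"] >= 0.9

    def test_prior_rescaling_invariance(self, two_pop):
        pca = GenotypePCA(two_pop, n_components=5).fit()
        labels = two_pop.ind_meta["center"].to_numpy()
        model = DAPC(pca.scores, labels).fit()
        base = model.posterior(pca.scores).to_numpy()
        model.priors = model.priors * 7.0  # unnormalised priors
        rescaled = model.posterior(pca.scores).to_numpy()
        np.testing.assert_allclose(base, rescaled, atol=1e-12)

    def test_unknown_center_grouped(self, two_pop):
        pca = GenotypePCA(two_pop, n_components=4).fit()
        labels = two_pop.ind_meta["center"].to_numpy()
        model = DAPC(pca.scores, labels).fit()
        centers = np.array(["POP1", None, "POP1"], dtype=object)
        _, per_center = model.posterior(pca.scores[:3], centers)
        assert "unknown" in per_center.index

    def test_singleton_group_rejected(self, two_pop):
        pca = GenotypePCA(two_pop, n_components=4).fit()
        labels = np.array(["X"] + ["Y"] * (two_pop.n_individuals - 1))
        with pytest.raises(ValueError, match="fewer than 2"):
            DAPC(pca.scores, labels).fit()
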