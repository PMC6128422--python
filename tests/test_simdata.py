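"""Generator behaviour: determinism, selection response, structured genotypes."""

import numpy as np
import pytest

from _oracles import hudson_fst, post_selection_freq, two_stage_freq
from longtraj import (
    SimulationConfig,
    expected_group_freqs,
    planted_class_betas,
    simulate_ancestry,
    simulate_cohort,
    simulate_structured,
)


def group_freq(ds, group, snp=0):
    return float(ds.allele_freqs(ds.group_mask(group))[snp])


class TestSimulateCohort:
    def test_requested_sample_sizes_and_age_windows(self):
        ds = simulate_cohort(SimulationConfig(n_birth_cohort=4000, n_snps=5, seed=3))
        counts = ds.ind_meta["group"].value_counts()
        assert (counts["G1"], counts["G2"], counts["G3"]) == (381, 392, 333)
        ages = ds.ind_meta.set_index("group")["age"]
        assert ages.loc["G1"].between(19, 50).all()
        assert ages.loc["G2"].between(50, 85).all()
        assert ages.loc["G3"].between(100, 103).all()
        # disjoint sampling: all ids unique (enforced by the container too)
        assert ds.ind_meta["id"].is_unique

    def test_determinism(self):
        cfg = SimulationConfig(n_birth_cohort=3000, n_snps=20, seed=11,
                               missing_rate=0.05)
        assert simulate_cohort(cfg) == simulate_cohort(cfg)
        cfg2 = cfg.replace(seed=12)
        assert not (simulate_cohort(cfg) == simulate_cohort(cfg2))

    def test_no_selection_means_no_trajectory(self):
        cfg = SimulationConfig(
            n_birth_cohort=200_000, n_snps=1, baseline_freqs=0.30,
            sample_sizes=(20_000, 20_000, 20_000), seed=5,
            base_surv_mid=0.85, base_surv_late=0.2,
        )
        ds = simulate_cohort(cfg)
        assert abs(group_freq(ds, "G1") - group_freq(ds, "G3")) < 0.02

    def test_mid_selection_matches_closed_form(self):
        # one SNP at freq 0.30 under beta_mid=+0.8, base survival 0.5:
        # G2 frequency must land within +-0.01 of the explicit genotype-sum
        # expectation (independent oracle).
        cfg = SimulationConfig(
            n_birth_cohort=500_000, n_snps=1, baseline_freqs=0.30,
            beta_mid=0.8, beta_late=0.0, base_surv_mid=0.5,
            base_surv_late=0.5, sex_effect=0.0,
            sample_sizes=(1000, 100_000, 1000), seed=17,
        )
        ds = simulate_cohort(cfg)
        expected = post_selection_freq(0.30, 0.8, 0.5)
        assert expected - 0.01 < group_freq(ds, "G2") < expected + 0.01

    @pytest.mark.parametrize("beta", [-0.8, 0.8])
    def test_selection_direction_law(self, beta):
        cfg = SimulationConfig(
            n_birth_cohort=100_000, n_snps=1, baseline_freqs=0.30,
            beta_mid=beta, base_surv_mid=0.5, base_surv_late=0.5,
            sex_effect=0.0, sample_sizes=(20_000, 20_000, 1000), seed=23,
        )
        ds = simulate_cohort(cfg)
        assert np.sign(group_freq(ds, "G2") - group_freq(ds, "G1")) == np.sign(beta)

    def test_two_stage_composition_unbiased(self):
        # with beta_mid = 0, f2 estimates the same frequency as f1: paired
        # differences over replicates average to 0 within 3 SE.
        diffs = []
        for seed in range(500):
            cfg = SimulationConfig(
                n_birth_cohort=1200, n_snps=1, baseline_freqs=0.30,
                beta_mid=0.0, beta_late=0.5, base_surv_mid=0.7,
                base_surv_late=0.5, sample_sizes=(250, 250, 100), seed=seed,
            )
            ds = simulate_cohort(cfg)
            diffs.append(group_freq(ds, "G2") - group_freq(ds, "G1"))
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(diffs.mean()) < 3 * se

    def test_pool_exhaustion_names_group(self):
        cfg = SimulationConfig(
            n_birth_cohort=500, n_snps=2, seed=1,
            base_surv_late=0.02, sample_sizes=(100, 100, 400),
        )
        with pytest.raises(ValueError, match="G3"):
            simulate_cohort(cfg)

    def test_missing_rate_injects_nan(self):
        cfg = SimulationConfig(n_birth_cohort=3000, n_snps=50, seed=9,
                               missing_rate=0.1)
        ds = simulate_cohort(cfg)
        frac = np.isnan(ds.dosages).mean()
        assert 0.07 < frac < 0.13

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(base_surv_mid=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(baseline_freqs=0.005)
        with pytest.raises(ValueError):
            SimulationConfig(fst=1.0)


class TestClosedFormHelpers:
    def test_expected_group_freqs_matches_independent_sum(self):
        f1, f2, f3 = expected_group_freqs(0.3, 0.8, -0.5, 0.6, 0.4)
        assert f1 == 0.3
        assert f2 == pytest.approx(post_selection_freq(0.3, 0.8, 0.6), abs=1e-12)
        assert f3 == pytest.approx(two_stage_freq(0.3, 0.8, -0.5, 0.6, 0.4), abs=1e-12)

    def test_planted_class_a_reverts_to_baseline(self):
        bm, bl = planted_class_betas("A", 1.0, 0.3, 0.5, 0.2)
        assert bm == 1.0 and bl < 0
        assert two_stage_freq(0.3, bm, bl, 0.5, 0.2) == pytest.approx(0.3, abs=1e-8)
        # naive negation does NOT revert (selection response is asymmetric)
        assert abs(two_stage_freq(0.3, 1.0, -1.0, 0.5, 0.2) - 0.3) > 0.02

    @pytest.mark.parametrize("cls,sig2,sig3", [
        ("A", 1, 0), ("B", -1, 0), ("C", 1, 1),
        ("D", -1, -1), ("E", 0, -1), ("F", 0, 1),
    ])
    def test_planted_classes_have_intended_trajectory_shape(self, cls, sig2, sig3):
        bm, bl = planted_class_betas(cls, 1.0, 0.3, 0.5, 0.2)
        f1, f2, f3 = expected_group_freqs(0.3, bm, bl, 0.5, 0.2)
        tol = 1e-6
        assert np.sign(round(f2 - f1, 8)) == sig2
        assert np.sign(round(f3 - f1, 8)) == sig3
        if cls in ("A", "B"):
            assert abs(f3 - f1) < tol


class TestSimulateStructured:
    def test_fst_zero_no_excess_variance(self):
        cfg = SimulationConfig(n_snps=1000, fst=0.0, seed=2)
        ds = simulate_structured(cfg, [400, 400])
        a = ds.group_mask  # noqa: F841  (centers, not groups, partition pops)
        pop1 = (ds.ind_meta["center"] == "POP1").to_numpy()
        f1 = ds.allele_freqs(pop1)
        f2 = ds.allele_freqs(~pop1)
        pbar = (f1 + f2) / 2
        binom_sd = np.sqrt(pbar * (1 - pbar) * (1 / 800 + 1 / 800))
        frac_ok = np.mean(np.abs(f1 - f2) <= 3 * binom_sd)
        assert frac_ok > 0.95

    def test_fst_recovered_by_hudson_estimator(self):
        cfg = SimulationConfig(n_snps=5000, fst=0.1, seed=4)
        ds = simulate_structured(cfg, [300, 300])
        pop1 = (ds.ind_meta["center"] == "POP1").to_numpy()
        est = hudson_fst(ds.dosages[pop1], ds.dosages[~pop1])
        assert 0.07 < est < 0.13

    def test_degenerate_inputs_rejected(self):
        cfg = SimulationConfig(n_snps=10, seed=1)
        with pytest.raises(ValueError):
            simulate_structured(cfg, [0, 100])
        with pytest.raises(ValueError):
            simulate_structured(cfg, [100])
        with pytest.raises(ValueError):
            SimulationConfig(n_snps=10, fst=-0.1)

    def test_determinism(self):
        cfg = SimulationConfig(n_snps=50, fst=0.05, seed=31)
        assert simulate_structured(cfg, [50, 60]) == simulate_structured(cfg, [50, 60])


class TestSimulateAncestry:
    def test_rows_sum_to_one_and_groups_recorded(self):
        q = simulate_ancestry(
            SimulationConfig(seed=1), [[0.2, 0.8], [0.5, 0.5]], 30.0, [100, 150]
        )
        assert q.proportions.shape == (250, 2)
        np.testing.assert_allclose(q.proportions.sum(axis=1), 1.0, atol=1e-12)
        assert q.groups.count("GRP1") == 100

    def test_null_groups_statistically_indistinguishable(self):
        q = simulate_ancestry(
            SimulationConfig(seed=2), [[0.3, 0.7], [0.3, 0.7]], 50.0, [400, 400]
        )
        a = q.proportions[:400, 0]
        b = q.proportions[400:, 0]
        se = np.sqrt(a.var(ddof=1) / 400 + b.var(ddof=1) / 400)
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_planted_shift_matches_dirichlet_moments(self):
        # component-1 means 0.038 vs 0.023 at concentration 50 and group sizes
        # 333/773: realised means within +-0.005 of targets.
        q = simulate_ancestry(
            SimulationConfig(seed=3),
            [[0.038, 0.481, 0.481], [0.023, 0.4885, 0.4885]],
            50.0,
            [333, 773],
        )
        m_cent = q.proportions[:333, 0].mean()
        m_ctrl = q.proportions[333:, 0].mean()
        assert abs(m_cent - 0.038) < 0.005
        assert abs(m_ctrl - 0.023) < 0.005

    def test_invalid_inputs_rejected(self):
        cfg = SimulationConfig(seed=1)
        with pytest.raises(ValueError):
            simulate_ancestry(cfg, [[0.6, 0.6]], 10.0, [10])
        with pytest.raises(ValueError):
            simulate_ancestry(cfg, [[0.5, 0.5]], -1.0, [10])
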