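"""Generator behaviour: divergence model moments, cline limits,
read-count noise model, microbial gradient, SAM materialization."""

import numpy as np
import pytest
from scipy import stats

from ednapop import (
    LakeScenario,
    TruthBundle,
    simulate_divergent_pops,
    simulate_edna_counts,
    simulate_fish,
    simulate_microbial,
    simulate_scenario,
    synthetic_panel,
    write_sam_reads,
)
from ednapop.scenario import STRATUM_MIDPOINTS, logistic_cline


class TestDivergentPops:
    def test_shapes_and_range(self):
        p1, p2 = simulate_divergent_pops(120, 0.3, seed=0)
        assert p1.shape == p2.shape == (120,)
        assert np.all((p1 >= 0) & (p1 <= 1)) and np.all((p2 >= 0) & (p2 <= 1))

    def test_no_divergence_limit(self):
        p1, p2 = simulate_divergent_pops(2000, 1e-6, seed=1)
        assert np.mean(np.abs(p1 - p2)) < 0.01

    @pytest.mark.parametrize("fst", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_fst(self, fst):
        with pytest.raises(ValueError):
            simulate_divergent_pops(10, fst, seed=0)

    def test_balding_nichols_moments(self):
        """Divergence variance matches the Beta model, cross-checked by an
        independent Monte-Carlo re-draw of one SNP."""
        fst, p_anc = 0.3, 0.4
        # independent oracle: 1e5 scipy Beta draws at a fixed ancestral p
        scale = (1 - fst) / fst
        draws = stats.beta.rvs(
            p_anc * scale, (1 - p_anc) * scale, size=(2, 100_000),
            random_state=np.random.RandomState(7),
        )
        mc_var = np.var(draws[0] - draws[1])
        theory = 2 * fst * p_anc * (1 - p_anc)
        assert mc_var == pytest.approx(theory, rel=0.02)
        # generator variance integrates the uniform ancestral density:
        # E[p(1-p)] over U[0.05, 0.95] is 0.1825
        p1, p2 = simulate_divergent_pops(120 * 200, fst, seed=5)
        assert np.var(p1 - p2) == pytest.approx(2 * fst * 0.1825, rel=0.05)


class TestFishCline:
    def test_step_cline_limit(self):
        gm, q = simulate_fish(
            (np.full(5, 0.9), np.full(5, 0.1)), [2] * 5,
            cline_steepness_m=0.0, seed=0,
        )
        assert set(np.unique(q)) <= {0.0, 1.0}
        shallow = np.array([s in ("0-5", "5-10", "10-15") for s in gm.strata])
        assert np.all(q[shallow] == 1.0) and np.all(q[~shallow] == 0.0)

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            simulate_fish((np.ones(3) * 0.5,) * 2, [2, 2, 0, 2, 2], seed=0)

    def test_null_model_depth_independent(self):
        """With p1 == p2 genotypes carry no depth signal: per-SNP
        genotype x stratum chi-square tests reject at the nominal rate."""
        p = np.random.default_rng(3).uniform(0.2, 0.8, 200)
        gm, _ = simulate_fish((p, p), [30] * 5, seed=4)
        n_sig = 0
        strata = np.asarray(gm.strata)
        for j in range(200):
            table = [
                np.bincount(gm.dosages[strata == s, j].astype(int), minlength=3)
                for s in np.unique(strata)
            ]
            table = np.array(table)
            table = table[:, table.sum(axis=0) > 0]
            p_val = stats.chi2_contingency(table + 1e-9)[1]
            n_sig += p_val < 0.01
        assert n_sig <= 8  # ~1% expected under the null; allow slack

    def test_stratum_mean_dosage_matches_closed_form(self):
        p1, p2 = simulate_divergent_pops(500, 0.3, seed=6)
        gm, q = simulate_fish((p1, p2), [20] * 5, seed=7)
        strata = np.asarray(gm.strata)
        for s in np.unique(strata):
            rows = strata == s
            q_s = q[rows][0]
            f = q_s * p1 + (1 - q_s) * p2
            mean_dosage = gm.dosages[rows].mean(axis=0)
            se = np.sqrt(2 * f * (1 - f) / rows.sum())
            within = np.abs(mean_dosage - 2 * f) <= 3 * np.maximum(se, 1e-9)
            assert within.mean() > 0.97


class TestEdnaCounts:
    def test_no_mixing_no_noise_limit(self):
        sc = LakeScenario(
            n_snps=60, n_loci=60, mixing_tau=0.0, overdispersion_rho=0.0,
            dropout_rate=0.0, mean_depth_per_snp=3000, seed=8,
        )
        _, counts, truth = simulate_scenario(sc)
        freq = counts.ref / counts.total()
        assert np.max(np.abs(freq - truth.pooled_freq)) < 0.05

    def test_fixed_allele_gives_no_alt_counts(self):
        sc = LakeScenario(n_snps=20, n_loci=20, seed=9)
        truth = TruthBundle(scenario=sc, pop_freqs=(np.ones(20), np.ones(20)))
        counts, pooled = simulate_edna_counts(truth)
        assert np.all(pooled == 1.0)
        assert counts.alt.sum() == 0

    def test_beta_binomial_variance_oracle(self):
        """Empirical mean of ref/depth stays within 3 SE of the pooled
        frequency, SE from the beta-binomial variance
        n f (1-f) (1 + (n-1) rho) / n^2."""
        sc = LakeScenario(
            n_snps=120, n_loci=98, samples_per_depth=(16, 0, 0, 0, 0),
            mean_depth_per_snp=100, overdispersion_rho=0.05,
            dropout_rate=0.0, mixing_tau=0.0, seed=10,
        )
        _, counts, truth = simulate_scenario(sc)
        n = counts.total().astype(float)
        f = truth.pooled_freq
        est = counts.ref / n
        cell_var = f * (1 - f) * (1 + (n - 1) * 0.05) / n
        se = np.sqrt(cell_var.mean(axis=0) / counts.n_samples)
        diff = np.abs(est.mean(axis=0) - f.mean(axis=0))
        assert (diff <= 3 * se).mean() > 0.97

    def test_pooled_truth_is_analytic_mixture(self, simulated):
        _, counts, truth = simulated
        sc = truth.scenario
        p1, p2 = truth.pop_freqs
        depths = sc.sample_depths()
        from ednapop.scenario import DEFAULT_STRATUM_MAP

        mids = np.array([STRATUM_MIDPOINTS[DEFAULT_STRATUM_MAP[d]] for d in depths])
        q = logistic_cline(mids, sc.cline_midpoint_m, sc.cline_steepness_m)
        expected = (
            ((1 - sc.mixing_tau) * q + sc.mixing_tau * (1 - q))[:, None] * p1
            + (1 - ((1 - sc.mixing_tau) * q + sc.mixing_tau * (1 - q)))[:, None] * p2
        )
        np.testing.assert_allclose(truth.pooled_freq, expected, atol=1e-12)

    def test_seed_reproducibility(self, default_scenario):
        g1, c1, t1 = simulate_scenario(default_scenario)
        g2, c2, t2 = simulate_scenario(default_scenario)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        np.testing.assert_array_equal(c1.ref, c2.ref)
        np.testing.assert_array_equal(c1.alt, c2.alt)


class TestMicrobial:
    def test_row_sums_conserved(self):
        comm, _ = simulate_microbial([3, 12, 22], total_reads=5000, seed=0)
        assert (comm.sum(axis=1) == 5000).all()

    def test_null_gradient_shares_one_profile(self):
        comm, _ = simulate_microbial(
            [3, 3, 3, 7, 12, 18, 22, 22, 22], gradient_sharpness=0.0,
            total_reads=200_000, seed=1,
        )
        props = comm.div(comm.sum(axis=1), axis=0)
        assert float((props.max() - props.min()).max()) < 0.02

    def test_too_few_depths_or_orders(self):
        with pytest.raises(ValueError):
            simulate_microbial([3], seed=0)
        with pytest.raises(ValueError):
            simulate_microbial([3, 22], n_orders=1, seed=0)


class TestSamWriter:
    def test_count_conservation(self, tmp_path, small_panel):
        from ednapop import AlleleCountMatrix

        counts = AlleleCountMatrix(
            np.full((1, 12), 2), np.full((1, 12), 1),
            ["s1"], small_panel.snp_ids, [3.0],
        )
        sam = tmp_path / "r.sam"
        write_sam_reads(counts, small_panel, sam, seed=0)
        n_reads = sum(1 for line in open(sam) if not line.startswith("@"))
        assert n_reads == 12 * 3

    def test_empty_matrix_header_only(self, tmp_path, small_panel):
        from ednapop import AlleleCountMatrix

        counts = AlleleCountMatrix(
            np.zeros((1, 12), int), np.zeros((1, 12), int),
            ["s1"], small_panel.snp_ids, [3.0],
        )
        sam = tmp_path / "empty.sam"
        write_sam_reads(counts, small_panel, sam, seed=0)
        assert all(line.startswith("@") for line in open(sam))

    def test_read_length_too_short(self, tmp_path, small_panel):
        from ednapop import AlleleCountMatrix

        counts = AlleleCountMatrix(
            np.ones((1, 12), int), np.zeros((1, 12), int),
            ["s1"], small_panel.snp_ids, [3.0],
        )
        with pytest.raises(ValueError):
            write_sam_reads(counts, small_panel, tmp_path / "x.sam", read_length=3)

    def test_byte_identical_given_seed(self, tmp_path, small_panel):
        sc = LakeScenario(n_snps=12, n_loci=10, mean_depth_per_snp=4, seed=3)
        _, counts, _ = simulate_scenario(sc)
        a, b = tmp_path / "a.sam", tmp_path / "b.sam"
        write_sam_reads(counts, small_panel, a, seed=5, indel_fraction=0.2)
        write_sam_reads(counts, small_panel, b, seed=5, indel_fraction=0.2)
        assert a.read_bytes() == b.read_bytes()
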