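"""Nested Monte Carlo propagation: pooling, degenerate limits, determinism,
monotonicity and the sampler validation utility."""

import dataclasses

import numpy as np
import pytest

import thermoprop as tp
from thermoprop.exceptions import InvalidInputError, ThermopropError
from thermoprop.montecarlo import _secondary_batch


def small_config(**kw):
    base = dict(n_outer=120, n_inner=120, seed=11)
    base.update(kw)
    return tp.MCConfig(**base)


class TestSummarizePooled:
    def test_constant_sequence(self):
        mean, sd, ci = tp.summarize_pooled([5.0, 5.0, 5.0], tp.MCConfig())
        assert (mean, sd, ci) == (5.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        mean, sd, ci = tp.summarize_pooled([0.0, 0.0, 2.0, 2.0], tp.MCConfig())
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(np.sqrt(4.0 / 3.0))
        assert ci == pytest.approx(2.0 * np.sqrt(4.0 / 3.0))

    def test_standard_normal_sample(self, rng):
        draws = rng.standard_normal(10_000)
        mean, sd, ci = tp.summarize_pooled(draws, tp.MCConfig())
        assert abs(mean) < 3.0 / np.sqrt(10_000)
        assert sd == pytest.approx(1.0, abs=0.05)
        assert ci == pytest.approx(2.0 * sd)

    def test_percentile_method(self, rng):
        draws = rng.standard_normal(50_000)
        cfg = tp.MCConfig(summary_method="percentile")
        _, _, ci = tp.summarize_pooled(draws, cfg)
        assert ci == pytest.approx(1.96, abs=0.05)

    def test_single_value_rejected(self):
        with pytest.raises(InvalidInputError):
            tp.summarize_pooled([1.0], tp.MCConfig())


class TestBatchSecondaryFit:
    def test_agrees_with_per_set_fit(self, rng):
        temps = np.array([80, 90, 100, 110, 120, 130], float)
        t_ref = 120.0
        d_sets = 10.0 ** (
            np.log10(50.0) + (t_ref - temps)[None, :] / 30.0
            + rng.normal(0, 0.04, (20, 6))
        )
        slope, d_tref, d_ci, z, z_ci = _secondary_batch(t_ref - temps, d_sets, 0.05)
        for i in range(20):
            table = tp.DTTable(
                [tp.DTEstimate(T, dv) for T, dv in zip(temps, d_sets[i])]
            )
            sec = tp.fit_secondary(table, t_ref)
            assert z[i] == pytest.approx(sec.z, rel=1e-10)
            assert d_tref[i] == pytest.approx(sec.d_tref, rel=1e-10)
            assert z_ci[i] == pytest.approx(sec.z_ci95_half, rel=1e-10)
            assert d_ci[i] == pytest.approx(sec.d_tref_ci95_half, rel=1e-10)

    def test_degenerate_rows_flagged_nan(self):
        # x = t_ref - T: larger x means lower temperature
        x = np.array([40.0, 20.0, 0.0])
        d_sets = np.array([[40.0, 20.0, 10.0],   # D falls with temperature: valid
                           [10.0, 20.0, 40.0],   # D rises with temperature: no z
                           [40.0, -5.0, 10.0]])  # non-positive D draw: no fit
        slope, d_tref, _, z, _ = _secondary_batch(x, d_sets, 0.05)
        assert np.isfinite(z[0]) and z[0] > 0
        assert np.isnan(slope[1]) and np.isnan(z[1])
        assert np.isnan(slope[2])


class TestRunTwoStageMC:
    def test_zero_sigma_outer_fits_collapse_to_deterministic(self, original_table):
        table = tp.DTTable(
            [dataclasses.replace(e, ci95_half=0.0, sigma=0.0) for e in original_table]
        )
        cfg = small_config()
        det = tp.fit_secondary(original_table, cfg.t_ref)
        res_d, res_z = tp.run_two_stage_mc(table, cfg)
        np.testing.assert_allclose(res_d.per_outer_estimates, det.d_tref, rtol=1e-12)
        np.testing.assert_allclose(res_z.per_outer_estimates, det.z, rtol=1e-12)
        # pooled spread now comes only from the single fit's regression CI
        assert res_d.mean == pytest.approx(det.d_tref, abs=3 * res_d.sd / np.sqrt(120))
        assert res_d.sd == pytest.approx(det.d_tref_ci95_half / 2.0, rel=0.15)
        assert res_z.sd == pytest.approx(det.z_ci95_half / 2.0, rel=0.15)

    def test_seeded_runs_are_bit_identical(self, original_table):
        cfg = small_config(seed=99)
        a_d, a_z = tp.run_two_stage_mc(original_table, cfg)
        b_d, b_z = tp.run_two_stage_mc(original_table, cfg)
        np.testing.assert_array_equal(a_d.pooled_values, b_d.pooled_values)
        np.testing.assert_array_equal(a_z.pooled_values, b_z.pooled_values)
        assert a_d.ci95_half == b_d.ci95_half

    def test_different_seeds_differ(self, original_table):
        a_d, _ = tp.run_two_stage_mc(original_table, small_config(seed=1))
        b_d, _ = tp.run_two_stage_mc(original_table, small_config(seed=2))
        assert not np.array_equal(a_d.pooled_values, b_d.pooled_values)

    def test_pooled_ci_monotone_in_input_ci_scale(self, original_table):
        widths_d, widths_z = [], []
        for c in (1.0, 2.0, 5.0):
            acc_d = acc_z = 0.0
            for seed in (0, 1, 2):
                res_d, res_z = tp.run_two_stage_mc(
                    original_table.scaled_ci(c), small_config(n_outer=200,
                                                              n_inner=200, seed=seed)
                )
                acc_d += res_d.ci95_half
                acc_z += res_z.ci95_half
            widths_d.append(acc_d / 3)
            widths_z.append(acc_z / 3)
        assert widths_d[0] < widths_d[1] < widths_d[2]
        assert widths_z[0] < widths_z[1] < widths_z[2]

    @pytest.mark.parametrize("which", ["original", "expanded"])
    def test_pooled_means_preserve_deterministic_estimates(self, which, request):
        table = request.getfixturevalue(f"{which}_table")
        cfg = tp.MCConfig(n_outer=500, n_inner=200, seed=5)
        det = tp.fit_secondary(table, cfg.t_ref)
        res_d, res_z = tp.run_two_stage_mc(table, cfg)
        se_d = res_d.per_outer_estimates.std(ddof=1) / np.sqrt(cfg.n_outer)
        se_z = res_z.per_outer_estimates.std(ddof=1) / np.sqrt(cfg.n_outer)
        assert abs(res_d.mean - det.d_tref) < 3 * max(se_d, 1e-9)
        assert abs(res_z.mean - det.z) < 3 * max(se_z, 1e-9)

    def test_pooled_samples_approximately_normal(self, original_table,
                                                 expanded_table):
        from scipy import stats

        # narrow input CIs: pooled samples are close to normal
        res_d, res_z = tp.run_two_stage_mc(original_table,
                                           tp.MCConfig(n_outer=500, n_inner=500,
                                                       seed=3))
        for res in (res_d, res_z):
            assert res.pooled_values.size == 250_000
            assert abs(stats.skew(res.pooled_values)) < 0.3
            assert abs(stats.kurtosis(res.pooled_values)) < 0.5
        # wide input CIs make the pooled sample a scale mixture of normals:
        # still unimodal and symmetric-ish, but mildly leptokurtic
        res_d, res_z = tp.run_two_stage_mc(expanded_table,
                                           tp.MCConfig(n_outer=500, n_inner=500,
                                                       seed=3))
        for res in (res_d, res_z):
            assert abs(stats.skew(res.pooled_values)) < 0.35
            assert abs(stats.kurtosis(res.pooled_values)) < 1.0

    def test_stage2_normal_sampling_agrees_with_discretized(self, expanded_table):
        res_disc, _ = tp.run_two_stage_mc(
            expanded_table, small_config(n_outer=300, n_inner=300, seed=8)
        )
        res_norm, _ = tp.run_two_stage_mc(
            expanded_table,
            small_config(n_outer=300, n_inner=300, seed=8,
                         stage2_sampling="normal"),
        )
        assert res_norm.ci95_half == pytest.approx(res_disc.ci95_half, rel=0.1)
        assert res_norm.mean == pytest.approx(res_disc.mean, rel=0.02)

    def test_excessive_rejection_rate_aborts(self):
        # nearly flat temperature dependence with enormous CIs: most outer
        # sets have a non-positive slope or non-positive D draws
        table = tp.DTTable(
            [tp.DTEstimate(100.0, 10.0, ci95_half=30.0),
             tp.DTEstimate(110.0, 9.5, ci95_half=30.0),
             tp.DTEstimate(120.0, 9.0, ci95_half=30.0)]
        )
        with pytest.raises(ThermopropError):
            tp.run_two_stage_mc(table, small_config())

    def test_error_policy_raises_immediately(self):
        table = tp.DTTable(
            [tp.DTEstimate(100.0, 50.0, ci95_half=60.0),
             tp.DTEstimate(110.0, 40.0, ci95_half=60.0),
             tp.DTEstimate(120.0, 30.0, ci95_half=60.0)]
        )
        with pytest.raises(ThermopropError):
            tp.run_two_stage_mc(table, small_config(degenerate_policy="error",
                                                    seed=0, n_outer=500))


class TestValidateSampler:
    def test_recovers_input_means_and_cis(self, expanded_table):
        cfg = tp.MCConfig(seed=21)
        frame = tp.validate_sampler(expanded_table, n=500, config=cfg)
        for _, row in frame.iterrows():
            sigma = row["CI95_half_min"] / 2.0
            assert abs(row["recovered_mean"] - row["D_min"]) <= 3 * sigma / np.sqrt(500)
            if sigma > 0:
                assert row["recovered_ci95_half"] == pytest.approx(
                    row["CI95_half_min"], rel=0.2
                )

    def test_zero_sigma_rows_recover_exactly(self):
        table = tp.DTTable(
            [tp.DTEstimate(80.0, 100.0, 0.0), tp.DTEstimate(90.0, 50.0, 0.0),
             tp.DTEstimate(100.0, 25.0, 0.0)]
        )
        frame = tp.validate_sampler(table, n=50, config=tp.MCConfig(seed=0))
        np.testing.assert_allclose(frame["recovered_mean"], frame["D_min"])
        np.testing.assert_allclose(frame["recovered_ci95_half"], 0.0)

    def test_large_n_matches_analytic_discrete_sd(self):
        table = tp.DTTable(
            [tp.DTEstimate(80.0, 896.3, 45.0), tp.DTEstimate(90.0, 573.8, 65.0),
             tp.DTEstimate(100.0, 238.2, 7.6)]
        )
        cfg = tp.MCConfig(seed=4)
        frame = tp.validate_sampler(table, n=50_000, config=cfg)
        for _, row in frame.iterrows():
            dist = tp.discretize_normal(row["D_min"], row["CI95_half_min"] / 2.0)
            assert row["recovered_ci95_half"] == pytest.approx(2.0 * dist.sd, rel=0.02)


class TestSensitivity:
    SIZES = [(25, 25), (50, 50), (100, 100)]

    def test_same_seed_same_table(self, expanded_table):
        cfg = tp.MCConfig(seed=17)
        a = tp.sensitivity_analysis(expanded_table, self.SIZES, cfg)
        b = tp.sensitivity_analysis(expanded_table, self.SIZES, cfg)
        assert a.table.equals(b.table)

    def test_one_row_per_size_and_parameter(self, expanded_table):
        res = tp.sensitivity_analysis(expanded_table, self.SIZES, tp.MCConfig(seed=1))
        assert len(res.table) == 2 * len(self.SIZES)
        assert res.row("25x25", "z")["n_outer"] == 25

    def test_empty_sizes_rejected(self, expanded_table):
        with pytest.raises(InvalidInputError):
            tp.sensitivity_analysis(expanded_table, [], tp.MCConfig())
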