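"""Two-pool mixing model, priming estimation, and Tukey HSD comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from isoprime import priming
from conftest import control_series, estimate_priming, quantify_default


class TestPartitionInterval:
    def test_unlabeled_limit(self):
        p = priming.partition_interval(10.0, f_sample=0.0111, f_sub=0.175,
                                       f_nat=0.0111)
        assert p.f_sub_fraction == 0.0
        assert p.c_soc == pytest.approx(10.0)

    def test_pure_substrate_limit(self):
        p = priming.partition_interval(10.0, f_sample=0.175, f_sub=0.175,
                                       f_nat=0.0111)
        assert p.f_sub_fraction == pytest.approx(1.0)
        assert p.c_sub == pytest.approx(10.0)

    def test_mixing_line_midpoint(self):
        p = priming.partition_interval(8.0, f_sample=0.09305, f_sub=0.175,
                                       f_nat=0.0111)
        assert p.f_sub_fraction == pytest.approx(0.5000, abs=1e-4)
        assert p.c_sub == pytest.approx(4.0, rel=1e-4)

    def test_unidentifiable_mixture_raises(self):
        with pytest.raises(priming.PartitionError, match="unidentifiable"):
            priming.partition_interval(1.0, 0.05, f_sub=0.0111, f_nat=0.0111)

    def test_out_of_range_sample_clamped_and_flagged(self):
        p = priming.partition_interval(5.0, f_sample=0.30, f_sub=0.175,
                                       f_nat=0.0111)
        assert p.clamped and p.f_sub_fraction == 1.0
        p = priming.partition_interval(5.0, f_sample=0.001, f_sub=0.175,
                                       f_nat=0.0111)
        assert p.clamped and p.f_sub_fraction == 0.0

    @settings(derandomize=True, max_examples=60)
    @given(
        total=st.floats(0.0, 1e3),
        f_sample=st.floats(0.0, 1.0),
        scale=st.floats(0.01, 100.0),
    )
    def test_conservation_and_scale_invariance(self, total, f_sample, scale):
        """C_sub + C_soc = total exactly; the split fraction is invariant to
        rescaling the units of total C."""
        p = priming.partition_interval(total, f_sample, f_sub=0.175, f_nat=0.0111)
        assert p.c_sub + p.c_soc == pytest.approx(p.total_c, abs=1e-12 * max(total, 1))
        q = priming.partition_interval(total * scale, f_sample, f_sub=0.175,
                                       f_nat=0.0111)
        assert q.f_sub_fraction == pytest.approx(p.f_sub_fraction, abs=1e-12)
        assert q.c_sub == pytest.approx(p.c_sub * scale, rel=1e-9, abs=1e-9)


class TestBaselineAndNet:
    def _controls(self, fracs, ecoplot="E1"):
        rows = []
        for i, f in enumerate(fracs):
            rows.append({"vial_id": f"c{i}", "ecoplot": ecoplot, "time_h": 24.0,
                         "umol12_per_g": 10.0 * (1 - f), "umol13_per_g": 10.0 * f})
        return pd.DataFrame(rows)

    def test_constant_controls(self):
        f = priming.natural_abundance_baseline(self._controls([0.0111] * 3))
        assert f.iloc[0] == pytest.approx(0.0111)

    def test_mean_of_two_controls(self):
        f = priming.natural_abundance_baseline(self._controls([0.010, 0.012]))
        assert f.iloc[0] == pytest.approx(0.011)

    def test_fallback_without_controls_warns(self):
        empty = pd.DataFrame(columns=["vial_id", "ecoplot", "time_h",
                                      "umol12_per_g", "umol13_per_g"])
        with pytest.warns(UserWarning, match="falling back"):
            f = priming.natural_abundance_baseline(empty)
        assert f.iloc[0] == pytest.approx(0.0111)

    def test_net_13co2_subtraction(self):
        labeled = pd.DataFrame([
            {"vial_id": "a", "ecoplot": "E", "time_h": 24.0,
             "umol12_per_g": 5.0, "umol13_per_g": 2.0},
        ])
        controls = pd.DataFrame([
            {"vial_id": "c1", "ecoplot": "E", "time_h": 24.0,
             "umol12_per_g": 5.0, "umol13_per_g": 0.4},
            {"vial_id": "c2", "ecoplot": "E", "time_h": 24.0,
             "umol12_per_g": 5.0, "umol13_per_g": 0.6},
        ])
        out = priming.net_13co2(labeled, controls)
        assert out["net_13co2"].iloc[0] == pytest.approx(1.5)
        same = priming.net_13co2(controls, controls)
        assert np.allclose(same["net_13co2"], [-0.1, 0.1])

    def test_net_13co2_missing_stratum_raises(self):
        labeled = pd.DataFrame([{"vial_id": "a", "ecoplot": "X", "time_h": 24.0,
                                 "umol12_per_g": 5.0, "umol13_per_g": 2.0}])
        controls = pd.DataFrame([{"vial_id": "c", "ecoplot": "Y", "time_h": 24.0,
                                  "umol12_per_g": 5.0, "umol13_per_g": 0.5}])
        with pytest.raises(priming.PartitionError, match="X"):
            priming.net_13co2(labeled, controls)


class TestAccumulate:
    def _parts(self, values, vial="v1"):
        return pd.DataFrame({
            "vial_id": vial, "time_h": 24.0 * np.arange(1, len(values) + 1),
            "t_start": 24.0 * np.arange(len(values)),
            "t_end": 24.0 * np.arange(1, len(values) + 1),
            "c_sub": values, "c_soc": values, "total_c": 2 * np.asarray(values),
        })

    def test_running_sums(self):
        out = priming.accumulate_series(self._parts([1.0, 1.0, 1.0]))
        assert list(out["cum_c_sub"]) == [1.0, 2.0, 3.0]

    def test_empty_is_empty(self):
        out = priming.accumulate_series(self._parts([])[:0])
        assert out.empty

    def test_overlapping_intervals_raise(self):
        df = self._parts([1.0, 1.0])
        df.loc[1, "t_start"] = 12.0
        with pytest.raises(priming.PartitionError, match="overlap"):
            priming.accumulate_series(df)

    def test_cumulative_monotone_for_nonnegative_intervals(self):
        out = priming.accumulate_series(self._parts([0.5, 0.0, 2.0, 0.1]))
        assert (np.diff(out["cum_total_c"]) >= 0).all()


class TestRecoveryFromSimulation:
    def test_noiseless_estimates_match_truth(self, noiseless_config):
        """On noiseless synthetic data the full estimation chain returns the
        injected cumulative substrate C and primed C to 1e-9 relative."""
        res = estimate_priming(noiseless_config)
        truth = res["pHB"]["truth"]
        for name in ("pHB", "glucose"):
            est = res[name]["cumulative"].groupby("vial_id")["cum_c_sub"].last()
            tr = truth.summary.set_index("vial_id").loc[est.index, "cum_sub_c"]
            assert np.allclose(est, tr, rtol=1e-9)
            primed_true = truth.summary.loc[
                truth.summary.treatment == name, "cum_primed_c"].iloc[0]
            assert res[name]["series"].cumulative_primed_c == pytest.approx(
                primed_true, rel=1e-9)

    def test_negative_priming_sign_recovered(self, noiseless_config):
        res = estimate_priming(noiseless_config, treatments=("glucose",))
        assert res["glucose"]["series"].cumulative_primed_c < 0

    def test_percent_priming_consistency(self, noiseless_config):
        """Cumulative primed 13 with control cumulative ~149 gives ~8.7 %."""
        res = estimate_priming(noiseless_config, treatments=("pHB",))
        s = res["pHB"]["series"]
        control_total = s.per_time["control_mean_total"].sum()
        assert s.cumulative_primed_c == pytest.approx(13.0, rel=1e-9)
        assert s.percent_priming == pytest.approx(
            100.0 * 13.0 / control_total, rel=1e-9)
        assert s.percent_priming == pytest.approx(8.7, abs=0.2)


class TestSubstrateRecovery:
    def test_limits(self):
        assert priming.substrate_recovery(41.63, 41.63)[0] == pytest.approx(100.0)
        assert priming.substrate_recovery(0.0, 41.63)[0] == 0.0

    def test_hand_value(self):
        pct, flagged = priming.substrate_recovery(39.96, 41.63)
        assert pct == pytest.approx(96.0, abs=0.05)
        assert not flagged

    def test_over_recovery_flagged_not_clipped(self):
        pct, flagged = priming.substrate_recovery(45.0, 41.63)
        assert pct > 100 and flagged

    def test_zero_dose_raises(self):
        with pytest.raises(priming.PartitionError):
            priming.substrate_recovery(1.0, 0.0)


def studentized_range_sf_oracle(q, k, df):
    """Survival function of the studentized range by direct double
    numerical integration (independent of scipy.stats.studentized_range)."""
    def inner(s):
        def f(z):
            return stats.norm.pdf(z) * (stats.norm.cdf(z) -
                                        stats.norm.cdf(z - q * s)) ** (k - 1)
        val, _ = integrate.quad(f, -8.0, 8.0, epsabs=1e-12, limit=200)
        return k * val

    # density of S = sqrt(chi2_df / df)
    from scipy.special import gammaln
    log_norm = (df / 2.0) * np.log(df) - gammaln(df / 2.0) \
        - (df / 2.0 - 1.0) * np.log(2.0)

    def outer(s):
        log_dens = log_norm + (df - 1.0) * np.log(s) - df * s * s / 2.0
        return np.exp(log_dens) * inner(s)

    cdf, _ = integrate.quad(outer, 1e-9, 10.0, epsabs=1e-12, limit=200)
    return 1.0 - cdf


class TestCompareTreatments:
    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 4)
        groups = {g: base + rng.normal(0, 1e-6, 4) for g in ("a1", "a2", "a3")}
        cmp = priming.compare_treatments(groups)
        assert len(set(cmp.letters.values())) == 1

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(1)
        groups = {"lo": rng.normal(0, 1, 4), "hi": rng.normal(100, 1, 4)}
        cmp = priming.compare_treatments(groups)
        assert cmp.letters["lo"] != cmp.letters["hi"]
        assert cmp.pairwise["p_adj"].iloc[0] < 1e-6

    def test_adjusted_p_matches_integration_oracle(self):
        groups = {
            "A": np.array([10.0, 12.0, 11.0]),
            "B": np.array([13.0, 15.0, 14.0]),
            "C": np.array([10.5, 11.5, 12.5]),
        }
        cmp = priming.compare_treatments(groups)
        k, df = 3, 6
        for _, row in cmp.pairwise.iterrows():
            oracle = studentized_range_sf_oracle(row["q_stat"], k, df)
            assert row["p_adj"] == pytest.approx(oracle, abs=1e-6)

    def test_matches_statsmodels_tukeyhsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(2)
        groups = {g: rng.normal(m, 1.0, 4)
                  for g, m in (("w", 0.0), ("g", 1.0), ("p", 3.0))}
        cmp = priming.compare_treatments(groups)
        data = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm = pairwise_tukeyhsd(data, labels)
        sm_p = {frozenset((row[0], row[1])): row[3]
                for row in sm._results_table.data[1:]}
        for _, row in cmp.pairwise.iterrows():
            assert row["p_adj"] == pytest.approx(
                sm_p[frozenset((row["group1"], row["group2"]))], abs=2e-3)

    def test_degenerate_zero_variance_raises(self):
        with pytest.raises(priming.PartitionError, match="degenerate"):
            priming.compare_treatments({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_letters_consistent_with_pairwise_significance(self):
        rng = np.random.default_rng(3)
        groups = {g: rng.normal(m, 1.0, 4)
                  for g, m in (("a", 0.0), ("b", 2.0), ("c", 4.0), ("d", 4.2))}
        cmp = priming.compare_treatments(groups, alpha=0.05)
        for _, row in cmp.pairwise.iterrows():
            shared = set(cmp.letters[row["group1"]]) & set(cmp.letters[row["group2"]])
            if row["p_adj"] < 0.05:
                assert not shared
            else:
                assert shared


class TestPrimedSoc:
    def test_identical_treatment_and_control_gives_zero(self, noiseless_config):
        from isoprime.simulate import simulate_microcosm

        readings, _ = simulate_microcosm(noiseless_config)
        meas = quantify_default(readings, noiseless_config)
        ctrl = control_series(meas)
        series = priming.primed_soc(ctrl, ctrl, treatment="water")
        assert series.cumulative_primed_c == pytest.approx(0.0, abs=1e-9)
        assert series.percent_priming == pytest.approx(0.0, abs=1e-9)

    def test_timepoint_mismatch_raises(self, noiseless_config):
        from isoprime.simulate import simulate_microcosm

        readings, _ = simulate_microcosm(noiseless_config)
        meas = quantify_default(readings, noiseless_config)
        ctrl = control_series(meas)
        with pytest.raises(priming.PartitionError, match="mismatch"):
            priming.primed_soc(ctrl, ctrl.loc[ctrl["time_h"] > 24.0])
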