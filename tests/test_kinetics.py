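"""Decay fitting: OLS slope recovery, the cv reliability rule, the
onset-delay model, and RT-qPCR slope inversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rifdecay import (
    DecaySeries,
    SimulationConfig,
    fit_decay_with_delay,
    fit_exponential_decay,
    generate_decay_experiment,
    generate_truth,
    halflife_from_ct_slope,
    intersect_reliable,
    reliability_filter,
)
from rifdecay.kinetics import (
    HalfLifeEstimate,
    InsufficientDataError,
    fit_decay_matrix,
)
from tests.conftest import summarize_and_fit

LN2 = np.log(2.0)


def _series(times, ln_values, gene="g", cond="P1"):
    return DecaySeries(gene, cond, np.asarray(times, float), np.asarray(ln_values, float))


class TestFitExponentialDecay:
    def test_noiseless_line_recovered_exactly(self):
        t = np.arange(0.0, 12.0)
        s = _series(t, np.log(100.0) - 0.1 * t)
        est = fit_exponential_decay(s)
        assert est.k_per_min == pytest.approx(0.1, abs=1e-12)
        assert est.se_k == pytest.approx(0.0, abs=1e-12)
        assert est.cv_percent == pytest.approx(0.0, abs=1e-9)
        assert est.halflife_min == pytest.approx(6.931, abs=1e-3)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)
        assert est.reliable

    def test_three_point_series_matches_closed_form_ols(self):
        # frozen from the closed-form OLS slope and 1-df residual SE
        est = fit_exponential_decay(
            _series([0.0, 1.0, 2.0], np.log([100.0, 80.0, 70.0]))
        )
        assert est.k_per_min == pytest.approx(0.17834, abs=1e-5)
        assert est.halflife_min == pytest.approx(3.887, abs=1e-3)
        assert est.se_k == pytest.approx(0.02587, abs=1e-5)
        assert est.cv_percent == pytest.approx(14.5, abs=0.1)
        assert est.reliable

    def test_rising_series_flagged_unreliable_with_negative_halflife(self):
        est = fit_exponential_decay(_series([0.0, 5.0, 10.0], np.log([10.0, 20.0, 40.0])))
        assert est.k_per_min < 0
        assert est.halflife_min < 0
        assert est.cv_percent < 0
        assert not est.reliable

    def test_too_few_distinct_times_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_exponential_decay(_series([0.0, 0.0, 1.0], [4.0, 4.1, 3.0]))

    @given(
        k=st.floats(0.05, 1.0),
        intercept=st.floats(1.0, 10.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_eq1_identity_halflife_times_k_is_ln2(self, k, intercept):
        t = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        est = fit_exponential_decay(_series(t, intercept - k * t))
        assert est.halflife_min * est.k_per_min == pytest.approx(LN2, abs=1e-12)


class TestDelayModel:
    def test_piecewise_series_recovers_generative_breakpoint(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        y = np.where(t <= 2.0, np.log(100.0), np.log(100.0) - 0.2 * (t - 2.0))
        est = fit_decay_with_delay(_series(t, y), delay_grid=np.arange(0, 3.1, 0.5))
        assert est.delay_min == pytest.approx(2.0)
        assert est.k_per_min == pytest.approx(0.2, abs=1e-10)
        assert est.halflife_min == pytest.approx(3.466, abs=1e-3)

    def test_zero_delay_series_reduces_to_plain_fit(self):
        rng = np.random.default_rng(0)
        t = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 9.0, 11.0])
        y = 5.0 - 0.3 * t + rng.normal(0, 0.02, t.size)
        plain = fit_exponential_decay(_series(t, y))
        delayed = fit_decay_with_delay(_series(t, y), delay_grid=[0.0])
        assert delayed.k_per_min == pytest.approx(plain.k_per_min, rel=1e-12)
        assert delayed.se_k == pytest.approx(plain.se_k, rel=1e-12)
        assert delayed.delay_min == 0.0

    def test_delay_model_never_fits_worse(self):
        # nested models: the delay fit's RSS <= the no-delay RSS, hence its
        # r-squared is at least as large
        rng = np.random.default_rng(5)
        for _ in range(20):
            t = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 9.0, 11.0])
            tau = rng.uniform(0, 1)
            y = 4.0 - 0.25 * np.maximum(0, t - tau) + rng.normal(0, 0.1, t.size)
            plain = fit_exponential_decay(_series(t, y))
            delayed = fit_decay_with_delay(_series(t, y))
            assert delayed.r_squared >= plain.r_squared - 1e-12

    def test_rss_ties_break_toward_smaller_delay(self):
        # a perfectly flat-free line fits exactly for every tau <= 0 region;
        # grid {0, 0.5} both give RSS 0 on a pure line through the origin
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = 3.0 - 0.2 * t
        est = fit_decay_with_delay(_series(t, y), delay_grid=[0.0, 0.5])
        assert est.delay_min == 0.0

    def test_all_candidates_skipped_raises(self):
        t = np.array([0.0, 1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            fit_decay_with_delay(_series(t, [3.0, 2.0, 1.0]), delay_grid=[1.5])


class TestReliabilityFilter:
    @pytest.mark.parametrize(
        "cv,k,expected",
        [
            (14.5, 0.2, True),
            (40.0, 0.2, True),
            (50.0, 0.2, False),  # cv above the window
            (-5.0, -0.1, False),  # rising series, negative cv
            (np.inf, 0.2, False),
            (0.0, 0.2, True),  # perfect noiseless fit
        ],
    )
    def test_cv_window(self, cv, k, expected):
        est = HalfLifeEstimate("g", "c", k, abs(cv * k / 100), cv, LN2 / k, 0.0, 1.0, 5, False)
        assert reliability_filter([est])[0].reliable is expected

    def test_matrix_and_scalar_paths_agree(self, small_config, small_experiment):
        per, expr, meta = summarize_and_fit(small_config, small_experiment)
        c = "P1"
        arrays = meta.index[meta["condition"] == c]
        times = meta.loc[arrays, "minutes_after_rifampin"].to_numpy(float)
        frame = per[c]
        for gene in list(frame.index)[:10]:
            est = fit_exponential_decay(
                DecaySeries(gene, c, times, (expr.loc[gene, list(arrays)] * LN2).to_numpy())
            )
            assert est.k_per_min == pytest.approx(frame.loc[gene, "k_per_min"], rel=1e-10)
            assert est.cv_percent == pytest.approx(frame.loc[gene, "cv_percent"], rel=1e-8)
            assert est.reliable == bool(frame.loc[gene, "reliable"])


class TestCtSlope:
    @pytest.mark.parametrize("slope,expected", [(0.2, 5.0), (0.1, 10.0)])
    def test_reciprocal(self, slope, expected):
        assert halflife_from_ct_slope(slope) == pytest.approx(expected)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            halflife_from_ct_slope(0.0)


class TestIntersectReliable:
    def test_single_condition_returns_own_set(self):
        df = pd.DataFrame({"reliable": [True, False, True]}, index=["a", "b", "c"])
        inter, counts = intersect_reliable({"P1": df})
        assert inter == {"a", "c"} and counts == {"P1": 2}

    def test_disjoint_sets_intersect_empty(self):
        d1 = pd.DataFrame({"reliable": [True, False]}, index=["a", "b"])
        d2 = pd.DataFrame({"reliable": [False, True]}, index=["a", "b"])
        inter, _ = intersect_reliable({"P1": d1, "P2": d2})
        assert inter == set()

    def test_matches_brute_force_set_logic(self, small_config, small_experiment):
        per, _, _ = summarize_and_fit(small_config, small_experiment)
        inter, counts = intersect_reliable(per)
        brute = None
        for c, frame in per.items():
            s = {g for g in frame.index if frame.loc[g, "reliable"]}
            assert counts[c] == len(s)
            brute = s if brute is None else brute & s
        assert inter == brute


class TestRecoveryProperties:
    def test_median_cv_increases_with_noise(self):
        medians = []
        for sd in (0.05, 0.2, 0.5):
            cfg = SimulationConfig(
                n_genes=200,
                noise_log_sd=sd,
                delay_range_min=(0.0, 0.0),
                probes_per_gene=8,
                seed=9,
            )
            truth = generate_truth(cfg)
            per, _, _ = summarize_and_fit(cfg, generate_decay_experiment(truth, cfg))
            medians.append(per["P1"]["cv_percent"].median())
        assert medians[0] < medians[1] < medians[2]

    def test_low_noise_halflife_nearly_unbiased(self):
        # balanced design using every sampling minute of the protocol
        times = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0)
        cfg = SimulationConfig(
            n_genes=300,
            conditions=("P1",),
            halflife_median_min={"P1": 5.0},
            yields_ug_per_mgDW={"P1": 45.2},
            timepoints_per_replicate={"P1": (times,) * 3},
            noise_log_sd=0.05,
            delay_range_min=(0.0, 0.0),
            probes_per_gene=8,
            stabilized_fraction=0.0,
            seed=21,
        )
        truth = generate_truth(cfg)
        per, _, _ = summarize_and_fit(cfg, generate_decay_experiment(truth, cfg))
        est = per["P1"]
        rel = est["reliable"]
        bias = est.loc[rel, "halflife_min"] / truth.halflife_min.loc[rel[rel].index, "P1"] - 1
        assert abs(bias.mean()) < 0.02

    def test_unreliable_fits_enriched_at_low_abundance(self):
        # weak signals sit near the scanner floor, so genes in the lowest
        # T0-concentration quartile should dominate the unreliable set
        cfg = SimulationConfig(n_genes=600, conditions=("P4",),
                               halflife_median_min={"P4": 9.5},
                               yields_ug_per_mgDW={"P4": 27.0},
                               timepoints_per_replicate={
                                   "P4": ((0.0, 1.0, 4.0, 11.0), (0.0, 1.5, 2.0, 7.0), (0.0, 0.5, 3.0, 5.0))
                               },
                               stabilized_fraction=0.0, probes_per_gene=8, seed=17)
        truth = generate_truth(cfg)
        per, _, _ = summarize_and_fit(cfg, generate_decay_experiment(truth, cfg))
        est = per["P4"]
        unreliable = est.index[~est["reliable"]]
        assert len(unreliable) >= 5
        conc = truth.t0_concentration["P4"]
        frac_low = (conc.loc[unreliable] <= conc.quantile(0.25)).mean()
        assert frac_low > 0.5  # strong enrichment over the 25% baseline
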