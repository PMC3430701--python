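"""Peak-to-protein rollup: filters, outlier rules, and the lognormal estimator."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielcycle.proteome import (LognormalRatio, build_protein_timecourse,
                                detect_peak_outliers_iir, estimate_protein_ratio,
                                filter_by_cv, gurland_cN, iir_scores,
                                normalize_timepoint_medians, orient_ratios,
                                quantify_proteome, remove_timepoint_outliers)


def _peaks(ratios, cvs=None, timepoints=None, protein="p1"):
    n = len(ratios)
    return pd.DataFrame({
        "peak_id": [f"k{i}" for i in range(n)],
        "protein_id": [protein] * n,
        "timepoint_index": timepoints if timepoints is not None else [0] * n,
        "time_h": [0.0] * n,
        "ratio": ratios,
        "cv": cvs if cvs is not None else [0.1] * n,
    })


class TestOrient:
    def test_heavy_over_light_reciprocal(self):
        out, n = orient_ratios(_peaks([2.0]), "heavy_over_light")
        assert out["ratio"].iloc[0] == pytest.approx(0.5)
        assert n == 0

    def test_already_oriented_identity(self):
        out, _ = orient_ratios(_peaks([2.0]), "light_over_heavy")
        assert out["ratio"].iloc[0] == 2.0

    def test_nonpositive_rejected_and_counted(self):
        with pytest.warns(UserWarning, match="rejected 1"):
            out, n = orient_ratios(_peaks([0.0, 1.0]), "heavy_over_light")
        assert n == 1 and len(out) == 1


class TestCvFilter:
    def test_linear_interpolated_percentile(self):
        cvs = [0.01 * k for k in range(1, 11)]
        out, thr = filter_by_cv(_peaks([1.0] * 10, cvs=cvs), 80)
        assert thr == pytest.approx(0.082)
        excluded = out.loc[out["excluded_by"] == "cv_filter", "cv"].tolist()
        assert sorted(excluded) == pytest.approx([0.09, 0.10])

    def test_ties_all_retained(self):
        out, thr = filter_by_cv(_peaks([1.0] * 5, cvs=[0.3] * 5), 80)
        assert (out["excluded_by"] == "none").all()
        assert thr == pytest.approx(0.3)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            filter_by_cv(_peaks([]))

    def test_retained_mass_matches_percentile_on_continuous_cvs(self):
        rng = np.random.default_rng(0)
        df = _peaks([1.0] * 10_000, cvs=rng.uniform(0, 1, 10_000))
        out, _ = filter_by_cv(df, 80)
        assert (out["excluded_by"] == "none").mean() == pytest.approx(0.80, abs=0.005)


class TestNormalize:
    def test_median_subtraction(self):
        df = _peaks([1.0, 2.0, 4.0])
        df["excluded_by"] = "none"
        out, offsets = normalize_timepoint_medians(df)
        np.testing.assert_allclose(sorted(out["log2_ratio"]), [-1, 0, 1])
        assert offsets[0] == pytest.approx(1.0)

    def test_idempotent(self):
        df = _peaks([1.0, 2.0, 4.0, 8.0])
        df["excluded_by"] = "none"
        once, _ = normalize_timepoint_medians(df)
        twice, offsets2 = normalize_timepoint_medians(once)
        assert offsets2[0] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(once["log2_ratio"], twice["log2_ratio"])

    def test_all_excluded_timepoint_skipped_with_warning(self):
        df = _peaks([1.0, 2.0])
        df["excluded_by"] = "cv_filter"
        with pytest.warns(UserWarning, match="no retained"):
            _, offsets = normalize_timepoint_medians(df)
        assert offsets == {}


class TestIIR:
    def test_zero_dispersion_guard(self):
        assert not detect_peak_outliers_iir([0.0, 0.0, 0.0, 0.0]).any()

    def test_single_gross_outlier_flagged(self):
        flags = detect_peak_outliers_iir([0.0, 0.1, -0.1, 5.0], cutoff=1.81)
        assert flags.tolist() == [False, False, False, True]

    def test_small_groups_unflagged(self):
        assert not detect_peak_outliers_iir([0.0, 0.0, 100.0]).any()

    @given(st.lists(st.floats(-5, 5).map(lambda x: round(x, 2)),
                    min_size=4, max_size=12),
           st.floats(0.1, 10), st.floats(-3, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_and_shift_invariance(self, vals, scale, shift):
        base = iir_scores(np.array(vals))
        trans = iir_scores(np.array(vals) * scale + shift)
        np.testing.assert_allclose(base, trans, atol=1e-6)


class TestGurland:
    @pytest.mark.parametrize("n,expected,tol", [
        (2, np.sqrt(np.pi / 2), 1e-12),
        (10, 1.0281, 1e-4),
        (10**6, 1.0, 1e-5),
    ])
    def test_closed_form_values(self, n, expected, tol):
        assert gurland_cN(n) == pytest.approx(expected, abs=tol)

    def test_monotone_decreasing_above_one(self):
        cs = [gurland_cN(n) for n in range(2, 60)]
        assert all(a > b for a, b in zip(cs, cs[1:]))
        assert all(c > 1 for c in cs)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            gurland_cN(1)


class TestLognormalRatio:
    def test_identical_ratios_zero_width(self):
        res = estimate_protein_ratio(np.full(5, np.log2(1.5)))
        assert res.log2_ratio == pytest.approx(np.log2(1.5))
        assert res.s == pytest.approx(0.0, abs=1e-12)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-12)
        assert res.ci_low == pytest.approx(np.log2(1.5), abs=1e-9)

    def test_large_sample_matches_closed_form_mean(self):
        rng = np.random.default_rng(0)
        draws = rng.lognormal(0.0, 0.3, 10_000)
        res = LognormalRatio(ratios=draws).fit()
        assert res.log2_ratio == pytest.approx(np.log2(np.exp(0.045)), abs=0.01)

    def test_single_peak_flagged(self):
        res = estimate_protein_ratio([0.7])
        assert res.log2_ratio == pytest.approx(0.7)
        assert not res.ci_defined

    def test_sd_correction_unbiased_on_log_scale(self):
        # E[c_N * sigma_hat] = sigma exactly for normal data; Monte-Carlo at N=8
        rng = np.random.default_rng(1)
        sigma, N, reps = 0.4, 8, 40_000
        x = rng.normal(0.0, sigma, (reps, N))
        shat = x.std(axis=1, ddof=1)
        assert (gurland_cN(N) * shat).mean() == pytest.approx(sigma, rel=0.01)

    def test_ci_ordering(self):
        rng = np.random.default_rng(2)
        res = LognormalRatio(ratios=rng.lognormal(0.2, 0.5, 12)).fit()
        assert res.ci_low <= res.log2_ratio <= res.ci_high


class TestTimecourseBuild:
    def test_full_threshold(self):
        counts = {t: 4 for t in range(10)}
        assert build_protein_timecourse(counts) == (4, list(range(10)))

    def test_threshold_lowered_to_three(self):
        counts = {t: 4 for t in range(7)}
        counts.update({7: 3, 8: 3})
        k, tps = build_protein_timecourse(counts)
        assert k == 3 and len(tps) == 9

    def test_unresolvable_returns_none(self):
        counts = {t: 1 for t in range(7)}
        assert build_protein_timecourse(counts) is None


class TestTimepointOutliers:
    def test_constant_series_unflagged(self):
        assert not remove_timepoint_outliers(np.zeros(14)).any()

    def test_ramp_unflagged(self):
        assert not remove_timepoint_outliers(np.arange(14.0)).any()

    def test_spike_flagged_neighbors_kept(self):
        y = np.zeros(14)
        y[6] = 3.0
        flags = remove_timepoint_outliers(y, factor=4.15)
        assert flags[6] and flags.sum() == 1

    def test_short_series_warns(self):
        with pytest.warns(UserWarning):
            flags = remove_timepoint_outliers(np.array([0.0, 5.0]))
        assert not flags.any()


def test_counting_identity_on_synthetic_run():
    from dielcycle.config import SimConfig
    from dielcycle.simulate import generate_diel_truth, simulate_peak_table, simulate_timecourses
    cfg = SimConfig(n_genes=25, seed=6)
    truth = generate_diel_truth(cfg)
    _, protein = simulate_timecourses(truth, cfg)
    peaks, _ = simulate_peak_table(protein, cfg)
    _, audit = quantify_proteome(peaks)
    assert (audit["retained"] + audit["cv_filtered"] + audit["iir_flagged"]
            + audit["rejected_nonpositive"]) == audit["peaks_in"]
    assert audit["realized_cv_threshold"] > 0


def test_normalization_recovers_injected_bias():
    from dielcycle.config import SimConfig
    from dielcycle.simulate import generate_diel_truth, simulate_peak_table, simulate_timecourses
    bias = [0.0] * 14
    bias[3] = 0.7
    cfg = SimConfig(n_genes=1250, seed=9, mixing_bias=bias, fraction_cyclers=0.0,
                    baseline_dist={"name": "point", "value": 0.0},
                    innovation_sd=0.0, outlier_peak_rate=0.0,
                    outlier_timepoint_rate=0.0)
    truth = generate_diel_truth(cfg)
    _, protein = simulate_timecourses(truth, cfg)
    peaks, _ = simulate_peak_table(protein, cfg)
    peaks, _ = orient_ratios(peaks, "heavy_over_light")
    peaks["excluded_by"] = "none"
    peaks["log2_ratio"] = np.log2(peaks["ratio"])
    _, offsets = normalize_timepoint_medians(peaks)
    assert offsets[3] - offsets[0] == pytest.approx(0.7, abs=0.02)
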