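"""Generator contracts: determinism, truth structure, and the statistical
properties the downstream stages assume."""
import numpy as np
import pandas as pd
import pytest

from dielcycle.config import ConfigError, SimConfig
from dielcycle.simulate import (antisense_assignment, ar1_noise,
                                generate_diel_truth, make_gene_models,
                                mixing_biases, simulate_coverage,
                                simulate_peak_table, simulate_timecourses,
                                truth_to_frame)


def test_cycler_count_is_exact_rounding():
    cfg = SimConfig(n_genes=100, fraction_cyclers=0.5, seed=1)
    truth = generate_diel_truth(cfg)
    assert sum(g.is_cycler for g in truth) == 50
    assert sum(not g.is_cycler for g in truth) == 50
    assert len({g.gene_id for g in truth}) == 100


def test_truth_invariants_and_determinism():
    cfg = SimConfig(n_genes=80, seed=7)
    t1, t2 = generate_diel_truth(cfg), generate_diel_truth(cfg)
    pd.testing.assert_frame_equal(truth_to_frame(t1), truth_to_frame(t2))
    for g in t1:
        assert 0.0 <= g.mrna_phase < 24.0
        assert g.mrna_halfamp >= 0 and g.protein_halfamp >= 0
        assert g.protein_halfamp <= g.mrna_halfamp  # damping enabled by default
        if not g.is_cycler:
            assert g.mrna_halfamp == 0 and g.protein_halfamp == 0


def test_point_mass_lag_shifts_protein_phase():
    cfg = SimConfig(n_genes=30, seed=2, lag_dist={"name": "point", "value": 12.0})
    for g in generate_diel_truth(cfg):
        assert g.protein_phase == pytest.approx((g.mrna_phase + 12.0) % 24.0)


def test_invalid_distribution_name_names_the_field():
    cfg = SimConfig(n_genes=5, lag_dist={"name": "zeta", "value": 1})
    with pytest.raises(ConfigError, match="lag_dist"):
        generate_diel_truth(cfg)


def test_adding_genes_preserves_existing_streams():
    # per-gene streams: gene i's draws identical whatever n_genes is
    small = SimConfig(n_genes=10, fraction_cyclers=1.0, seed=3)
    large = SimConfig(n_genes=40, fraction_cyclers=1.0, seed=3)
    t_small, t_large = generate_diel_truth(small), generate_diel_truth(large)
    for a, b in zip(t_small, t_large):
        assert a.mrna_phase == b.mrna_phase
        assert a.mrna_halfamp == b.mrna_halfamp
        assert a.lag == b.lag


def test_noise_free_timecourse_is_pure_cosine(noise_free_config):
    truth = generate_diel_truth(noise_free_config)
    mrna, protein = simulate_timecourses(truth, noise_free_config)
    g, tc = truth[0], mrna[0]
    assert g.is_cycler
    expected = g.mrna_baseline + g.mrna_halfamp * np.cos(
        2 * np.pi * (tc.times - g.mrna_phase) / 24.0)
    np.testing.assert_allclose(tc.values, expected, atol=1e-12)
    # non-cycler: flat at baseline
    flat = [tc for g2, tc in zip(truth, mrna) if not g2.is_cycler][0]
    assert np.ptp(flat.values) == 0.0


def test_ar1_noise_autocorrelation_matches_phi():
    rng = np.random.default_rng(0)
    for phi in (0.0, 0.6):
        e = ar1_noise(rng, 10_000, phi, 1.0)
        x = e - e.mean()
        r1 = (x[1:] @ x[:-1]) / (x @ x)
        assert r1 == pytest.approx(phi, abs=0.02)


def test_ar1_stationary_variance():
    rng = np.random.default_rng(1)
    e = ar1_noise(rng, 50_000, 0.6, 1.0)
    assert e.var() == pytest.approx(1.0 / (1 - 0.36), rel=0.05)


def test_peak_table_degenerate_dispersion_reproduces_truth(noise_free_config):
    truth = generate_diel_truth(noise_free_config)
    _, protein = simulate_timecourses(truth, noise_free_config)
    peaks, ptruth = simulate_peak_table(protein, noise_free_config)
    # heavy:light orientation: ratio = 2**(-true log2 sample:standard value)
    by_tc = {tc.id: tc for tc in protein}
    for _, row in peaks.iloc[:200].iterrows():
        v = by_tc[row["protein_id"]].values[int(row["timepoint_index"])]
        assert row["ratio"] == pytest.approx(2.0 ** (-v), rel=1e-12)
    assert (peaks["cv"] == 0).all()
    assert not ptruth["is_outlier_peak"].any()


def test_mixing_bias_shifts_timepoint_median():
    bias = [0.0] * 14
    bias[5] = 1.0
    cfg = SimConfig(n_genes=150, seed=4, mixing_bias=bias, fraction_cyclers=0.0,
                    baseline_dist={"name": "point", "value": 0.0},
                    innovation_sd=0.0, outlier_peak_rate=0.0,
                    outlier_timepoint_rate=0.0)
    truth = generate_diel_truth(cfg)
    _, protein = simulate_timecourses(truth, cfg)
    peaks, _ = simulate_peak_table(protein, cfg)
    log2 = -np.log2(peaks["ratio"])        # back to sample:standard
    med5 = log2[peaks["timepoint_index"] == 5].median()
    med0 = log2[peaks["timepoint_index"] == 0].median()
    assert med5 - med0 == pytest.approx(1.0, abs=0.05)


def test_outlier_peak_bookkeeping_matches_rows():
    cfg = SimConfig(n_genes=60, seed=8, outlier_peak_rate=0.05)
    truth = generate_diel_truth(cfg)
    _, protein = simulate_timecourses(truth, cfg)
    peaks, ptruth = simulate_peak_table(protein, cfg)
    assert len(peaks) == len(ptruth)
    assert (peaks["peak_id"] == ptruth["peak_id"]).all()
    flagged = ptruth["is_outlier_peak"]
    assert flagged.sum() > 0
    np.testing.assert_allclose(ptruth.loc[flagged, "displacement"].abs(),
                               cfg.outlier_peak_scale * cfg.peak_sigma)
    assert (ptruth.loc[~flagged, "displacement"] == 0).all()


def test_no_antisense_when_probability_zero():
    cfg = SimConfig(n_genes=10, seed=0, antisense_detect_prob=0.0, gene_length=200)
    truth = generate_diel_truth(cfg)
    mrna, _ = simulate_timecourses(truth, cfg)
    genes = make_gene_models(cfg)
    for cov in simulate_coverage(mrna, genes, cfg):
        for g in genes:
            opp = cov.minus if g.strand == "+" else cov.plus
            assert opp[g.start:g.end].sum() == 0


def test_antisense_assignment_fraction():
    cfg = SimConfig(n_genes=1000, seed=0, antisense_detect_prob=0.73)
    has_as, ratios = antisense_assignment(cfg)
    assert has_as.mean() == pytest.approx(0.73, abs=0.03)
    assert (ratios[has_as] > 0).all() and (ratios[~has_as] == 0).all()


def test_coverage_determinism(small_config):
    truth = generate_diel_truth(small_config)
    mrna, _ = simulate_timecourses(truth, small_config)
    genes = make_gene_models(small_config)
    c1 = next(iter(simulate_coverage(mrna, genes, small_config)))
    c2 = next(iter(simulate_coverage(mrna, genes, small_config)))
    np.testing.assert_array_equal(c1.plus, c2.plus)
    np.testing.assert_array_equal(c1.minus, c2.minus)
    assert c1.total_aligned_bp == c2.total_aligned_bp


def test_config_validation_errors():
    with pytest.raises(ConfigError, match="ar1_phi"):
        SimConfig(ar1_phi=1.5).validate()
    with pytest.raises(ConfigError, match="fraction_cyclers"):
        SimConfig(fraction_cyclers=1.2).validate()
    with pytest.raises(ConfigError, match="times"):
        SimConfig(times=[0.0, 0.0, 2.0]).validate()


def test_mixing_biases_reproducible():
    cfg = SimConfig(seed=11)
    np.testing.assert_array_equal(mixing_biases(cfg), mixing_biases(cfg))
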