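import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.mixture import GaussianMixture

from shgretina.axon_census import (axon_density_profile, classify_terminals,
                                   cohort_intensity_curve, colocalize_traces,
                                   detect_peaks1d, fit_intensity_gmm,
                                   intensity_along_trace, terminal_distribution)
from shgretina.layer_segmentation import LayerModel
from shgretina.neurite_tracing import summarize_trace, trace_volume
from shgretina.synthetic_scene import (OpticsParams, SceneParams,
                                       generate_scene, render_volume,
                                       sample_zero_depth_intensities,
                                       score_traces_against_truth)

_LM = LayerModel(boundaries_z_um={
    "GCL/IPL": 18.0, "IPL/INL": 54.0, "INL/OPL": 79.0, "OPL/ONL": 87.0})


class _SpanTrace:
    """Minimal stand-in trace: only the depth extent matters for counting."""

    def __init__(self, d_min, d_max):
        self.depth_span = (d_min, d_max)


class TestDensityProfile:
    def test_full_span_traces_give_flat_density(self):
        traces = [_SpanTrace(-0.2, 1.1) for _ in range(10)]
        prof = axon_density_profile(traces, _LM, field_area_mm2=0.001)
        np.testing.assert_allclose(prof.N, 10_000.0)

    def test_uniform_terminals_give_monotone_decrease(self):
        traces = [_SpanTrace(-0.1, d) for d in np.linspace(0.05, 0.95, 50)]
        prof = axon_density_profile(traces, _LM, field_area_mm2=0.001)
        in_ipl = prof.bin_centers >= 0
        assert np.all(np.diff(prof.N[in_ipl]) <= 0)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            axon_density_profile([], _LM, field_area_mm2=0.0)


class TestTerminalDistribution:
    def test_constant_density_gives_zero(self):
        prof = axon_density_profile([_SpanTrace(-0.2, 1.1)] * 5, _LM, 0.001)
        tdist = terminal_distribution(prof, smoothing_window=1)
        np.testing.assert_allclose(tdist.T, 0.0)

    def test_single_step_localized(self):
        traces = [_SpanTrace(-0.2, 1.1)] * 10 + [_SpanTrace(-0.2, 0.501)] * 5
        prof = axon_density_profile(traces, _LM, 0.001, bin_width=0.02)
        tdist = terminal_distribution(prof, smoothing_window=1)
        assert np.count_nonzero(tdist.T) == 1
        assert tdist.T.max() == pytest.approx(5 / 0.001 / 0.02)

    def test_piecewise_linear_slopes_recovered(self):
        # N(d) falling linearly: T equals the analytic negative slope
        edges = np.arange(0.0, 1.0001, 0.02)
        centers = 0.5 * (edges[:-1] + edges[1:])
        N = 40_000.0 * (1.0 - centers)
        from shgretina.axon_census import DensityProfile
        prof = DensityProfile(depth_bins=edges, N=N, field_area_mm2=0.01)
        tdist = terminal_distribution(prof, smoothing_window=1)
        np.testing.assert_allclose(tdist.T_raw, 40_000.0, rtol=1e-9)

    def test_conservation_exact_when_unsmoothed(self):
        rng = np.random.default_rng(3)
        traces = [_SpanTrace(-0.2, d) for d in rng.uniform(0, 1, 200)]
        prof = axon_density_profile(traces, _LM, 0.001)
        tdist = terminal_distribution(prof, smoothing_window=1)
        lhs = np.sum(tdist.T_raw * np.diff(prof.bin_centers))
        assert lhs == pytest.approx(prof.N[0] - prof.N[-1], abs=1e-9)

    def test_conservation_within_5pct_with_default_smoothing(self):
        rng = np.random.default_rng(4)
        traces = [_SpanTrace(-0.2, d) for d in rng.uniform(0, 1, 500)]
        prof = axon_density_profile(traces, _LM, 0.001)
        tdist = terminal_distribution(prof, smoothing_window=5)
        lhs = np.sum(tdist.T_raw * np.diff(prof.bin_centers))
        rhs = prof.N[0] - prof.N[-1]
        assert lhs == pytest.approx(rhs, rel=0.05)

    def test_oversized_window_rejected(self):
        prof = axon_density_profile([_SpanTrace(-0.2, 1.1)] * 3, _LM, 0.001)
        with pytest.raises(ValueError, match="window"):
            terminal_distribution(prof, smoothing_window=1000)


class TestPeaks:
    def test_monotone_signal_has_no_peaks(self):
        pos, _ = detect_peaks1d(np.linspace(0, 1, 50))
        assert pos.size == 0

    def test_five_gaussians_recovered(self):
        x = np.linspace(0, 1, 101)
        centers = [0.1, 0.3, 0.5, 0.7, 0.9]
        sig = sum(np.exp(-0.5 * ((x - c) / 0.03) ** 2) for c in centers)
        pos, _ = detect_peaks1d(sig, x=x, min_separation=0.08)
        assert len(pos) == 5
        np.testing.assert_allclose(np.sort(pos), centers, atol=0.005)

    def test_close_peaks_merge_to_higher(self):
        x = np.linspace(0, 1, 201)
        sig = (1.0 * np.exp(-0.5 * ((x - 0.48) / 0.01) ** 2)
               + 0.6 * np.exp(-0.5 * ((x - 0.52) / 0.01) ** 2))
        pos, _ = detect_peaks1d(sig, x=x, min_separation=0.1)
        assert len(pos) == 1
        assert abs(pos[0] - 0.48) < 0.01  # the higher of the two survives


class TestClassification:
    def test_default_bins(self):
        assert classify_terminals([0.1]) == ["OFF"]
        assert classify_terminals([0.4]) == ["ON"]      # half-open at the cut
        assert classify_terminals([0.85]) == ["ROD"]
        assert classify_terminals([float("nan")]) == [None]

    def test_bad_cut_points_rejected(self):
        with pytest.raises(ValueError):
            classify_terminals([0.5], boundaries=(0.8, 0.4))

    def test_confusion_against_scene_truth(self, census_field_bank):
        correct = total = 0
        for scene, vol, lm, traces in census_field_bank:
            s = score_traces_against_truth(traces, scene)
            pred = classify_terminals([traces[ti].terminal_depth
                                       for ti, ai, _ in s["matches"]])
            true = classify_terminals([scene.axons[ai].terminal_depth
                                       for ti, ai, _ in s["matches"]])
            correct += sum(p == t for p, t in zip(pred, true))
            total += len(pred)
        assert correct / total >= 0.9


class TestIntensityAlongTrace:
    def test_flat_trace_gives_flat_series(self):
        from shgretina.neurite_tracing import FiberPoint, NeuriteTrace
        pts = [FiberPoint(z_index=i, z_um=70.0 - i, y_um=1, x_um=1,
                          peak_intensity=50.0, radius_um=0.4, score=1.0)
               for i in range(20)]
        tr = summarize_trace(NeuriteTrace(id=0, points=pts), None, _LM)
        series = intensity_along_trace(tr, _LM)
        np.testing.assert_allclose(series[:, 1], 50.0)

    def test_caliber_ramp_recovered_with_high_rank_correlation(self, single_axon_factory):
        from conftest import lm_from_truth
        scene = single_axon_factory(terminal_depth=0.95, caliber_ramp=0.5)
        vol = render_volume(scene, OpticsParams(), channels=("shg",),
                            seed=0, noise=False)
        traces = trace_volume(vol, "shg", lm_from_truth(scene))
        assert len(traces) == 1
        prof = traces[0].intensity_profile
        sel = (prof[:, 0] > 0.05) & (prof[:, 0] < 0.85)  # clear of taper/edges
        truth = (1.0 + 0.5 * (1.0 - prof[sel, 0])) ** 2
        rho = spearmanr(prof[sel, 1], truth).statistic
        assert rho > 0.9

    def test_cohort_mean_curve_decreases_with_depth(self):
        # single-caliber cohort: without subtype-caliber selection effects
        # the axial caliber ramp makes the mean intensity fall with depth
        table = (("bc", 1.0, 0.5, 0.28, 0.8, 0.05, False),)
        params = SceneParams(field_size_um=(64.0, 64.0), subtype_table=table,
                             caliber_ramp=0.5, seed=6)
        scene = generate_scene(params)
        vol = render_volume(scene, OpticsParams(), channels=("shg",), seed=7)
        from shgretina.layer_segmentation import segment_layers
        lm = segment_layers(vol, "shg")
        traces = trace_volume(vol, "shg", lm)
        grid, mean = cohort_intensity_curve(traces, np.linspace(0.05, 0.8, 16))
        ok = np.isfinite(mean)
        slope = np.polyfit(grid[ok], mean[ok], 1)[0]
        assert slope < 0


class TestMixtureModel:
    def test_single_normal_selects_one_component(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = rng.normal(10.0, 1.0, size=500)
            fit = fit_intensity_gmm(vals, seed=seed)
            hits += fit.k == 1
        assert hits >= 17

    def test_two_separated_components_recovered(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0, 1, 300), rng.normal(5, 1, 300)])
        fit = fit_intensity_gmm(vals, seed=1)
        assert fit.k == 2
        se = 1.0 / np.sqrt(300)
        assert abs(fit.means[0] - 0.0) < 3 * se
        assert abs(fit.means[1] - 5.0) < 3 * se

    def test_log_likelihood_monotone_over_iterations(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0, 1, 200), rng.normal(4, 0.5, 200)])
        fit = fit_intensity_gmm(vals, k_range=(2,), seed=2)
        ll = fit.ll_trace
        assert np.all(np.diff(ll) >= -1e-6 * max(abs(ll[-1]), 1.0))

    def test_degenerate_sample_warns_and_floors_sd(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_intensity_gmm(np.full(50, 3.0))
        assert fit.k == 1 and fit.sds[0] > 0

    def test_matches_sklearn_on_clear_mixture(self):
        """Independent cross-check of the EM fit against scikit-learn."""
        vals = np.log(sample_zero_depth_intensities(SceneParams(), 600, seed=3))
        ours = fit_intensity_gmm(vals, k_range=(3,), seed=3, n_init=5)
        sk = GaussianMixture(n_components=3, n_init=5, random_state=3,
                             tol=1e-8).fit(vals[:, None])
        assert ours.log_likelihood / len(vals) == pytest.approx(
            sk.score(vals[:, None]), abs=0.01)
        np.testing.assert_allclose(ours.means, np.sort(sk.means_[:, 0]), atol=0.05)

    def test_bic_selects_three_caliber_classes(self):
        vals = np.log(sample_zero_depth_intensities(SceneParams(), 500, seed=7))
        assert fit_intensity_gmm(vals, seed=7).k == 3

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_intensity_gmm(np.arange(5.0))


class TestColocalization:
    def test_zero_fluorescence_flags_nothing(self, census_field_bank):
        scene, vol, lm, traces = census_field_bank[0]
        dark = vol.data.copy()
        dark[vol.channel_index("gfp")] = 0
        from shgretina.volume_io import Volume
        vol0 = Volume(data=dark, voxel_um=vol.voxel_um,
                      channel_names=vol.channel_names)
        flags, _, _ = colocalize_traces(traces, vol0, lm, "gfp")
        assert not flags.any()

    def test_flag_accuracy_against_truth(self, census_field_bank):
        correct = total = 0
        for scene, vol, lm, traces in census_field_bank:
            flags, _, _ = colocalize_traces(traces, vol, lm, "gfp")
            s = score_traces_against_truth(traces, scene)
            correct += sum(flags[ti] == scene.axons[ai].colabeled
                           for ti, ai, _ in s["matches"])
            total += len(s["matches"])
        assert correct / total >= 0.95

    def test_rule_swap_changes_only_between_thresholds(self, census_field_bank):
        scene, vol, lm, traces = census_field_bank[0]
        f1, samples, t1 = colocalize_traces(traces, vol, lm, "gfp",
                                            threshold_rule="otsu")
        f2, _, t2 = colocalize_traces(traces, vol, lm, "gfp",
                                      threshold_rule="k_median")
        lo, hi = sorted([t1, t2])
        changed = f1 != f2
        assert np.all((samples[changed] > lo) & (samples[changed] <= hi))
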