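import itertools
import math

import numpy as np
import pytest

from shgretina.layer_segmentation import LayerModel
from shgretina.neurite_tracing import (DetectionParams, FiberPoint, LinkParams,
                                       NeuriteTrace, detect_fiber_points,
                                       link_traces, match_point_sets,
                                       summarize_trace, trace_volume)
from shgretina.synthetic_scene import (OpticsParams, render_volume,
                                       score_traces_against_truth)
from shgretina.volume_io import Volume


def _point(z, y, x, intensity=100.0):
    return FiberPoint(z_index=int(z), z_um=float(z), y_um=float(y), x_um=float(x),
                      peak_intensity=float(intensity), radius_um=0.4, score=50.0)


def _plane_volume(plane):
    data = np.asarray(plane, float)[None, None]
    return Volume(data=data, voxel_um=(1.0, 0.5, 0.5), channel_names=["shg"])


def _gaussian_spot(shape, cy, cx, sigma_px, amp):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px ** 2))


_LM = LayerModel(boundaries_z_um={
    "GCL/IPL": 18.0, "IPL/INL": 54.0, "INL/OPL": 79.0, "OPL/ONL": 87.0})


class TestDetection:
    def test_blank_plane_gives_no_points(self):
        vol = _plane_volume(np.zeros((64, 64)))
        assert detect_fiber_points(vol, "shg", 0) == []

    def test_single_rendered_axon_subvoxel_position(self, single_axon_factory):
        scene = single_axon_factory(terminal_depth=0.9)
        vol = render_volume(scene, OpticsParams(), channels=("shg",),
                            seed=0, noise=False)
        zi = 40  # mid-IPL plane
        pts = detect_fiber_points(vol, "shg", zi)
        assert len(pts) == 1
        xa, ya = scene.axons[0].xy_at_z(vol.z_um()[zi])
        assert math.hypot(pts[0].y_um - ya, pts[0].x_um - xa) < 0.25  # half a voxel

    @pytest.mark.parametrize("sep_sigmas,expected", [(4.0, 2), (0.5, 1)])
    def test_two_spot_resolution(self, sep_sigmas, expected):
        # two Gaussian spots of PSF width; below ~1 sigma they merge into one
        sigma_px = 0.3 / 0.5
        sep = sep_sigmas * sigma_px
        plane = (_gaussian_spot((64, 64), 32, 30, sigma_px, 400)
                 + _gaussian_spot((64, 64), 32, 30 + sep, sigma_px, 400))
        pts = detect_fiber_points(_plane_volume(plane), "shg", 0)
        assert len(pts) == expected


class TestMatching:
    @staticmethod
    def _brute_force(prev, curr, r_max):
        """Exhaustive best matching: max cardinality, then min total disp."""
        n, m = len(prev), len(curr)
        feasible = {}
        for i, p in enumerate(prev):
            for j, c in enumerate(curr):
                d = math.hypot(p.y_um - c.y_um, p.x_um - c.x_um)
                if d <= r_max:
                    feasible[(i, j)] = d
        best = (0, 0.0)
        best_cost = None
        for k in range(min(n, m), -1, -1):
            costs = []
            for rows in itertools.combinations(range(n), k):
                for cols in itertools.permutations(range(m), k):
                    pairs = list(zip(rows, cols))
                    if all(pr in feasible for pr in pairs):
                        costs.append(sum(feasible[pr] for pr in pairs))
            if costs:
                return k, min(costs)
        return 0, 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_assignment_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 7, size=2)
        prev = [_point(1, *rng.uniform(0, 10, 2), intensity=rng.uniform(50, 200))
                for _ in range(n)]
        curr = [_point(0, *rng.uniform(0, 10, 2), intensity=rng.uniform(50, 200))
                for _ in range(m)]
        r_max = 3.0
        matches = match_point_sets(prev, curr, r_max)
        total = sum(math.hypot(prev[i].y_um - curr[j].y_um,
                               prev[i].x_um - curr[j].x_um) for i, j in matches)
        k_opt, cost_opt = self._brute_force(prev, curr, r_max)
        assert len(matches) == k_opt
        assert total == pytest.approx(cost_opt, abs=1e-9)

    def test_crossing_paths_resolved_optimally(self):
        # two trajectories crossing in y midway through four planes
        planes = {z: [_point(z, 1.0 + (3 - z), 2.0),
                      _point(z, 4.0 - (3 - z), 2.0)]
                  for z in range(4)}
        traces = link_traces(planes, LinkParams(min_length_planes=2,
                                                trim_dark_terminals=False))
        assert len(traces) == 2
        for tr in traces:
            zs = [p.z_index for p in tr.points]
            assert len(set(zs)) == len(zs)  # no two points in one plane


class TestLinking:
    def test_stationary_point_yields_single_full_trace(self):
        planes = {z: [_point(z, 5.0, 5.0)] for z in range(12)}
        traces = link_traces(planes, LinkParams(trim_dark_terminals=False))
        assert len(traces) == 1
        assert len(traces[0].points) == 12

    def test_two_parallel_axons_never_switch(self):
        planes = {z: [_point(z, 5.0, 5.0), _point(z, 5.0, 15.0)] for z in range(10)}
        traces = link_traces(planes, LinkParams(r_max_um_per_plane=3.0,
                                                trim_dark_terminals=False))
        assert len(traces) == 2
        for tr in traces:
            xs = {round(p.x_um, 3) for p in tr.points}
            assert len(xs) == 1  # each trace stays on its own fiber

    def test_gap_bridged_by_interpolation(self):
        planes = {z: [_point(z, 5.0, 5.0)] for z in range(10) if z != 5}
        planes[5] = []
        traces = link_traces(planes, LinkParams(trim_dark_terminals=False))
        assert len(traces) == 1
        gap_pts = [p for p in traces[0].points if p.interpolated]
        assert len(gap_pts) == 1 and gap_pts[0].z_index == 5

    def test_short_fragments_discarded(self):
        planes = {z: [_point(z, 5.0, 5.0)] for z in range(3)}
        assert link_traces(planes, LinkParams(min_length_planes=5)) == []


class TestSummaries:
    def _vertical_trace(self, z_start, z_end):
        zs = np.arange(z_start, z_end - 1, -1.0)
        return NeuriteTrace(id=0, points=[_point(z, 10.0, 10.0) for z in zs])

    def test_terminal_at_inl_ipl_interface_is_zero(self):
        tr = summarize_trace(self._vertical_trace(70, 54), None, _LM)
        assert tr.terminal_depth == pytest.approx(0.0, abs=1e-9)

    def test_terminal_mid_ipl(self):
        tr = summarize_trace(self._vertical_trace(70, 36), None, _LM)
        assert tr.terminal_depth == pytest.approx(0.5, abs=1.0 / 36.0)

    def test_trace_outside_ipl_flagged(self):
        tr = summarize_trace(self._vertical_trace(75, 60), None, _LM)
        assert math.isnan(tr.terminal_depth)

    def test_length_and_span(self):
        tr = summarize_trace(self._vertical_trace(60, 50), None, _LM)
        assert tr.length_um == pytest.approx(10.0)
        assert tr.lateral_span_um == pytest.approx(0.0)


class TestRecovery:
    def test_recall_and_precision_on_rendered_fields(self, census_field_bank):
        """Trace-level recovery against ground truth at the study density."""
        recalls, precisions = [], []
        for scene, vol, lm, traces in census_field_bank:
            s = score_traces_against_truth(traces, scene)
            recalls.append(s["recall"])
            precisions.append(s["precision"])
        assert min(recalls) >= 0.90
        assert min(precisions) >= 0.90

    def test_no_duplicate_planes_in_traces(self, census_field_bank):
        _, _, _, traces = census_field_bank[0]
        for tr in traces:
            zs = [p.z_index for p in tr.points]
            assert len(set(zs)) == len(zs)

    def test_recall_nondecreasing_in_photon_budget(self, census_field_bank):
        scene, _, _, traces_hi = census_field_bank[0]
        vol_lo = render_volume(scene, OpticsParams(photons_per_unit_emission=6.0),
                               channels=("shg",), seed=2001)
        from shgretina.layer_segmentation import segment_layers
        lm = segment_layers(vol_lo, "shg")
        traces_lo = trace_volume(vol_lo, "shg", lm)
        r_lo = score_traces_against_truth(traces_lo, scene)["recall"]
        r_hi = score_traces_against_truth(traces_hi, scene)["recall"]
        assert r_hi >= r_lo
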