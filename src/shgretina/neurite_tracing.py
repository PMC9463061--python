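"""Vertical-fiber detection and single-neurite tracing.

Bipolar-cell axons run nearly perpendicular to the imaging planes, so each
axon appears as a compact bright spot in every lateral plane it crosses.
Tracing therefore proceeds in two steps, in the spirit of single-particle
tracking:

1. per-plane spot detection with a scale-normalized Laplacian-of-Gaussian
   filter and sub-pixel localization by quadratic interpolation;
2. frame-to-frame linking from the sclerad (INL) side toward the GCL, so a
   trace's far end is the axon terminal. Each consecutive plane pair is
   matched by the assignment that maximizes the number of links within the
   gating radius and, among those, minimizes the total displacement
   (computed exactly with the Hungarian algorithm; small tie-break terms on
   intensity difference and point index make it deterministic). Detection
   drop-outs of up to ``max_gap_planes`` are bridged by linear
   interpolation.

Summaries (terminal depth, arc length, lateral span, intensity-versus-depth
profile) are attached per trace against a :class:`~shgretina.layer_segmentation.LayerModel`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .layer_segmentation import LayerModel, ipl_depth
from .volume_io import Volume

__all__ = [
    "FiberPoint",
    "NeuriteTrace",
    "DetectionParams",
    "LinkParams",
    "detect_fiber_points",
    "link_traces",
    "summarize_trace",
    "trace_volume",
]


@dataclass
class FiberPoint:
    """A fiber cross-section detected in one lateral plane."""

    z_index: int
    z_um: float
    y_um: float
    x_um: float
    peak_intensity: float
    radius_um: float
    score: float
    interpolated: bool = False

    @property
    def xy_um(self) -> tuple[float, float]:
        return (self.x_um, self.y_um)


@dataclass
class NeuriteTrace:
    """An ordered single-neurite trace (points in increasing IPL depth)."""

    id: int
    points: list[FiberPoint]
    terminal_depth: float | None = None
    length_um: float | None = None
    lateral_span_um: float | None = None
    mean_intensity: float | None = None
    intensity_profile: np.ndarray | None = None  # (n, 2): depth, intensity
    subtype_label: str | None = None
    colabeled: bool | None = None

    @property
    def depth_span(self) -> tuple[float, float] | None:
        if self.intensity_profile is None:
            return None
        d = self.intensity_profile[:, 0]
        return float(d.min()), float(d.max())


@dataclass(frozen=True)
class DetectionParams:
    log_sigma_um: float = 0.25     # LoG scale, finer than the PSF to split near-merged fibers
    score_threshold: float = 18.0  # scale-normalized LoG response, photon units
    upsample: int = 2              # lateral interpolation factor before LoG


@dataclass(frozen=True)
class LinkParams:
    r_max_um_per_plane: float = 1.5  # gating radius per 1 µm of z step
    max_gap_planes: int = 3          # bridges crowding drop-outs, not just noise
    min_length_planes: int = 5
    intensity_penalty: float = 0.5   # cost weight on relative intensity jumps
    tail_gate_frac: float = 0.6      # gap bridging needs a healthy (untapered) tail
    r_strict_um: float = 0.8         # larger jumps also need a healthy tail
    r_share_um: float = 0.8          # merge handling: unmatched tracks may share
                                     # a detection this close (two fibers, one blob)
    trim_dark_terminals: bool = True

    def gap_gate_um(self, gap_planes: float, dz_um: float) -> float:
        """Gating radius for a link skipping ``gap_planes - 1`` planes.

        Sublinear in the gap length: fiber drift is a correlated walk, so
        the search radius grows like sqrt of the skipped distance rather
        than linearly (a linear gate over-reaches at long bridges).
        """
        return self.r_max_um_per_plane * dz_um * math.sqrt(max(gap_planes, 1.0))


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _quadratic_offset(m: float, c: float, p: float) -> float:
    denom = m - 2.0 * c + p
    if denom >= -1e-12:
        return 0.0
    off = 0.5 * (m - p) / denom
    return float(np.clip(off, -0.5, 0.5))


def detect_fiber_points(
    volume: Volume,
    channel: int | str,
    z_index: int,
    params: DetectionParams = DetectionParams(),
) -> list[FiberPoint]:
    """LoG blob detection of fiber cross-sections in one lateral plane.

    The response is the negated, scale-normalized Laplacian of Gaussian at
    a scale matched to the expected fiber radius; local maxima above
    ``score_threshold`` become points, localized to sub-pixel precision by
    quadratic interpolation along each lateral axis. The returned radius is
    the LoG equivalent radius ``sqrt(2) * sigma``.
    """
    data = volume.channel_data(channel)
    plane = data[z_index].astype(np.float64)
    dz, dy, dx = volume.voxel_um
    up = max(int(params.upsample), 1)
    if up > 1:
        # cubic upsampling separates near-merged fibers below the voxel pitch
        plane = ndimage.zoom(plane, up, order=3, mode="nearest")
        dy, dx = dy / up, dx / up
    sig = (params.log_sigma_um / dy, params.log_sigma_um / dx)
    # scale-normalized LoG: sigma_px^2 * Laplacian_px is grid-pitch invariant
    response = -ndimage.gaussian_laplace(plane, sigma=sig) * sig[0] * sig[1]

    footprint = ndimage.maximum_filter(response, size=3, mode="nearest")
    maxima = (response >= footprint) & (response > params.score_threshold)
    ys, xs = np.nonzero(maxima)
    ny, nx = plane.shape
    points: list[FiberPoint] = []
    z_um = volume.origin_um[0] + z_index * dz
    for y, x in zip(ys, xs):
        if 0 < y < ny - 1:
            offy = _quadratic_offset(response[y - 1, x], response[y, x], response[y + 1, x])
        else:
            offy = 0.0
        if 0 < x < nx - 1:
            offx = _quadratic_offset(response[y, x - 1], response[y, x], response[y, x + 1])
        else:
            offx = 0.0
        yy, xx = y + offy, x + offx
        peak = float(ndimage.map_coordinates(plane, [[yy], [xx]], order=1, mode="nearest")[0])
        points.append(FiberPoint(
            z_index=int(z_index),
            z_um=z_um,
            y_um=volume.origin_um[1] + yy * dy,
            x_um=volume.origin_um[2] + xx * dx,
            peak_intensity=peak,
            radius_um=math.sqrt(2.0) * params.log_sigma_um,
            score=float(response[y, x]),
        ))
    # non-maximum suppression: response plateaus (exact ties) and shoulder
    # maxima can yield duplicate points closer than the resolution limit
    nms_radius = 1.5 * params.log_sigma_um
    points.sort(key=lambda p: (-p.score, p.y_um, p.x_um))
    kept: list[FiberPoint] = []
    for p in points:
        if all(math.hypot(p.y_um - q.y_um, p.x_um - q.x_um) > nms_radius
               for q in kept):
            kept.append(p)
    kept.sort(key=lambda p: (p.y_um, p.x_um))
    return kept


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

_INFEASIBLE = 1e9


def match_point_sets(
    prev: list[FiberPoint],
    curr: list[FiberPoint],
    r_max_um: float,
    intensity_penalty: float = 0.0,
) -> list[tuple[int, int]]:
    """Optimal one-to-one matching between two planes' point sets.

    Maximizes the number of pairs with lateral displacement <= ``r_max_um``
    and, among such matchings, minimizes the summed displacement (plus, when
    ``intensity_penalty`` > 0, a term penalizing relative intensity jumps —
    fiber brightness changes slowly along an axon, so a large jump flags a
    wrong link). Ties are broken toward smaller intensity difference, then
    lower point index, via infinitesimal cost terms, making the result
    deterministic.
    """
    if not prev or not curr:
        return []
    P = np.array([[p.y_um, p.x_um] for p in prev])
    C = np.array([[p.y_um, p.x_um] for p in curr])
    disp = np.linalg.norm(P[:, None, :] - C[None, :, :], axis=2)
    ints_p = np.array([p.peak_intensity for p in prev])
    ints_c = np.array([p.peak_intensity for p in curr])
    dint = np.abs(ints_p[:, None] - ints_c[None, :])
    rel = dint / np.maximum(ints_p[:, None] + ints_c[None, :], 1e-12)
    scale = max(dint.max(), 1.0)
    idx = np.arange(len(curr))[None, :] + np.zeros((len(prev), 1))
    cost = (disp + intensity_penalty * r_max_um * rel
            + 1e-7 * r_max_um * (dint / scale) + 1e-10 * r_max_um * idx)
    cost[disp > r_max_um] = _INFEASIBLE
    rows, cols = optimize.linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if disp[r, c] <= r_max_um]


class _Track:
    __slots__ = ("points", "last_z")

    def __init__(self, point: FiberPoint):
        self.points = [point]
        self.last_z = point.z_index

    def add(self, point: FiberPoint):
        self.points.append(point)
        self.last_z = point.z_index

    def tail_is_healthy(self, frac: float) -> bool:
        """True when the trailing detections are not fading toward the
        background — a faded tail marks an SHG-dark axon terminal, which
        must not be bridged across a detection gap."""
        detected = [p.peak_intensity for p in self.points if not p.interpolated]
        if len(detected) < 4:
            return True
        tail = np.mean(detected[-2:])
        return tail >= frac * float(np.median(detected))


def _interpolate_gap(a: FiberPoint, b: FiberPoint) -> list[FiberPoint]:
    """Linearly interpolated points for the skipped planes between a and b."""
    out = []
    nmiss = abs(a.z_index - b.z_index) - 1
    for k in range(1, nmiss + 1):
        t = k / (nmiss + 1)
        out.append(FiberPoint(
            z_index=a.z_index + int(math.copysign(k, b.z_index - a.z_index)),
            z_um=a.z_um + t * (b.z_um - a.z_um),
            y_um=a.y_um + t * (b.y_um - a.y_um),
            x_um=a.x_um + t * (b.x_um - a.x_um),
            peak_intensity=a.peak_intensity + t * (b.peak_intensity - a.peak_intensity),
            radius_um=a.radius_um,
            score=0.0,
            interpolated=True,
        ))
    return out


def link_traces(
    points_by_plane: dict[int, list[FiberPoint]],
    params: LinkParams = LinkParams(),
    dz_um: float = 1.0,
) -> list[NeuriteTrace]:
    """Link per-plane detections into single-neurite traces.

    Planes are processed from the sclerad side (largest z index) toward the
    GCL, so the last point of each trace is the candidate axon terminal.
    ``r_max_um_per_plane`` scales linearly with the z step and, for gap
    bridging, with the number of skipped planes.
    """
    z_planes = sorted(points_by_plane.keys(), reverse=True)
    active: list[_Track] = []
    done: list[_Track] = []
    r_per_plane = params.r_max_um_per_plane * dz_um

    for z in z_planes:
        pts = sorted(points_by_plane[z], key=lambda p: (p.y_um, p.x_um))
        # retire tracks whose gap exceeded the limit, and tracks that faded
        # out (their SHG-dark terminal was reached; bridging would only
        # graft a neighboring fiber onto them)
        still = []
        for tr in active:
            gap = tr.last_z - z - 1
            if gap > params.max_gap_planes:
                done.append(tr)
            elif gap >= 1 and not tr.tail_is_healthy(params.tail_gate_frac):
                done.append(tr)
            else:
                still.append(tr)
        active = still
        if active and pts:
            # gate each track by its own gap-scaled radius: use the widest
            # radius in the assignment, then enforce per-track gates
            pts_all = list(pts)
            last_pts = [tr.points[-1] for tr in active]
            gaps = np.array([tr.last_z - z for tr in active], dtype=float)
            matches = match_point_sets(last_pts, pts,
                                       params.gap_gate_um(gaps.max(), dz_um),
                                       params.intensity_penalty)
            used = set()
            matched_tracks: set[int] = set()
            for ti, pi in sorted(matches):
                tr = active[ti]
                p = pts[pi]
                d = math.hypot(tr.points[-1].y_um - p.y_um, tr.points[-1].x_um - p.x_um)
                ok = d <= params.gap_gate_um(tr.last_z - z, dz_um)
                # a faded (terminal-like) tail may only continue smoothly: a
                # sizable jump from a fading track is a switch onto a
                # neighboring fiber, not a continuation
                if ok and d > params.r_strict_um and not tr.tail_is_healthy(params.tail_gate_frac):
                    ok = False
                if ok:
                    tr.points.extend(_interpolate_gap(tr.points[-1], p))
                    tr.add(p)
                    used.add(pi)
                    matched_tracks.add(ti)
            # merge handling: two fibers closer than the resolution produce
            # one blob; an unmatched healthy track adjacent to a detection
            # shares it instead of dying, so both fibers survive the merge
            if params.r_share_um > 0:
                all_xy = np.array([[p.y_um, p.x_um] for p in pts_all])
                for ti, tr in enumerate(active):
                    if ti in matched_tracks or tr.last_z != z + 1:
                        continue
                    if not tr.tail_is_healthy(params.tail_gate_frac):
                        continue
                    last = tr.points[-1]
                    dists = np.hypot(all_xy[:, 0] - last.y_um, all_xy[:, 1] - last.x_um)
                    j = int(np.argmin(dists))
                    if dists[j] <= params.r_share_um:
                        tr.add(dataclasses.replace(pts_all[j]))
            pts = [p for i, p in enumerate(pts) if i not in used]
        for p in pts:
            active.append(_Track(p))
    done.extend(active)

    traces = []
    tid = 0
    for tr in done:
        if len(tr.points) < params.min_length_planes:
            continue
        traces.append(NeuriteTrace(id=tid, points=tr.points))
        tid += 1
    return traces


def trim_switched_terminals(
    traces: list[NeuriteTrace],
    dim_frac: float = 0.55,
    max_taper_planes: int = 2,
    min_length_planes: int = 5,
) -> list[NeuriteTrace]:
    """Cut trailing runs where a trace left its SHG-dark terminal behind.

    Axon terminals lack SHG: a genuine terminal fades over the final
    micrometres (at most ``max_taper_planes`` dim detections). A longer
    trailing run of points below ``dim_frac`` of the trace's median
    intensity means the linker wandered onto background noise or a dim
    neighbor past the true terminal — those points are removed, keeping
    the physiological taper. Traces falling below ``min_length_planes``
    afterwards are dropped.
    """
    out = []
    for tr in traces:
        I = np.array([p.peak_intensity for p in tr.points], dtype=float)
        med = float(np.median(I))
        n = I.size
        run = 0
        while run < n and I[n - 1 - run] < dim_frac * med:
            run += 1
        if run > max_taper_planes:
            tr.points = tr.points[:n - (run - max_taper_planes)]
        if len(tr.points) >= min_length_planes:
            out.append(tr)
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_trace(
    trace: NeuriteTrace,
    volume: Volume | None,
    layer_model: LayerModel,
) -> NeuriteTrace:
    """Fill the derived per-trace fields in place (and return the trace).

    The terminal depth is the IPL depth of the deepest traced point (the
    end of the trace on the GCL side); it is set to NaN when the trace
    never enters the IPL. Intensities come from the detected peak
    intensities (one sample per plane).
    """
    pts = trace.points
    zs = np.array([p.z_um for p in pts])
    depths = np.asarray(ipl_depth(zs, layer_model), dtype=float)
    order = np.argsort(depths)
    d_max = float(depths.max())
    trace.terminal_depth = d_max if d_max >= 0 else float("nan")

    xy = np.array([[p.y_um, p.x_um] for p in pts])
    steps = np.diff(np.column_stack([zs, xy]), axis=0)
    trace.length_um = float(np.linalg.norm(steps, axis=1).sum())
    diffs = xy[:, None, :] - xy[None, :, :]
    trace.lateral_span_um = float(np.sqrt((diffs ** 2).sum(axis=2)).max())
    intens = np.array([p.peak_intensity for p in pts], dtype=float)
    trace.mean_intensity = float(np.nanmean(intens))
    trace.intensity_profile = np.column_stack([depths[order], intens[order]])
    return trace


def trace_volume(
    volume: Volume,
    channel: int | str = "shg",
    layer_model: LayerModel | None = None,
    detection: DetectionParams = DetectionParams(),
    linking: LinkParams = LinkParams(),
    z_range_um: tuple[float, float] | None = None,
) -> list[NeuriteTrace]:
    """Detect fiber points in every plane of interest and link them.

    ``z_range_um`` restricts detection (default: from 2 µm vitreal of the
    GCL/IPL interface to the INL/OPL interface when a layer model is given,
    otherwise the whole stack). Traces are summarized when a layer model is
    available.
    """
    dz = volume.voxel_um[0]
    nz = volume.shape_zyx[0]
    z_um = volume.z_um()
    if z_range_um is None and layer_model is not None:
        z_range_um = (layer_model.boundaries_z_um["GCL/IPL"] - 2.0,
                      layer_model.boundaries_z_um["INL/OPL"])
    if z_range_um is None:
        sel = np.arange(nz)
    else:
        sel = np.nonzero((z_um >= z_range_um[0]) & (z_um <= z_range_um[1]))[0]
    points = {int(z): detect_fiber_points(volume, channel, int(z), detection) for z in sel}
    traces = link_traces(points, linking, dz_um=dz)
    if linking.trim_dark_terminals:
        traces = trim_switched_terminals(
            traces, min_length_planes=linking.min_length_planes)
        for i, tr in enumerate(traces):
            tr.id = i
    if layer_model is not None:
        for tr in traces:
            summarize_trace(tr, volume, layer_model)
    return traces
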