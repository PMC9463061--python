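"""Axon census statistics: density and terminal distributions, sublamina
peaks, subtype classification, intensity mixture model, co-localization.

The census logic follows the depth calculus of the method: the density
profile N(d) counts, per unit area, the traces whose axial extent crosses
the normalized IPL depth d; its negative derivative T(d) = -dN/dd is the
areal density of axon terminals per unit depth, whose maxima reveal the
IPL sublaminae. Terminal depth alone classifies a bipolar cell as OFF,
ON-cone or rod type. The distribution of axon intensities at zero IPL
depth is modelled by a maximum-likelihood Gaussian mixture with BIC model
selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from skimage.filters import threshold_otsu

from .layer_segmentation import LayerModel, ipl_depth_to_z
from .volume_io import Volume

__all__ = [
    "DensityProfile",
    "TerminalDistribution",
    "GMMFit",
    "axon_density_profile",
    "terminal_distribution",
    "detect_peaks1d",
    "classify_terminals",
    "intensity_along_trace",
    "cohort_intensity_curve",
    "fit_intensity_gmm",
    "colocalize_traces",
]


@dataclass
class DensityProfile:
    """Axons per mm² versus normalized IPL depth (evaluated at bin centers)."""

    depth_bins: np.ndarray  # bin edges
    N: np.ndarray           # one value per bin (len(edges) - 1)
    field_area_mm2: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.depth_bins[:-1] + self.depth_bins[1:])


@dataclass
class TerminalDistribution:
    """Terminals per mm² per unit depth: T = -dN/dd, clipped at zero.

    ``T`` lives on the staggered grid of bin-edge midpoints between
    consecutive density bins, so that the unsmoothed first difference obeys
    the discrete fundamental theorem of calculus exactly:
    sum(T_raw * delta_d) = N(first bin) - N(last bin).
    """

    depth_bins: np.ndarray   # staggered centers (len(N) - 1)
    T: np.ndarray            # clipped at 0
    T_raw: np.ndarray        # signed values
    smoothing_window: int


def axon_density_profile(
    traces: Sequence,
    layer_model: LayerModel,
    field_area_mm2: float,
    bin_width: float = 0.02,
    depth_range: tuple[float, float] = (-0.1, 1.0),
) -> DensityProfile:
    """Count traces crossing each depth, per unit area.

    A trace crosses depth d when d lies within the trace's [min, max]
    depth extent; extents are read from the summarized intensity profiles
    (or recomputed from the points when absent).
    """
    if field_area_mm2 <= 0:
        raise ValueError("field area must be positive")
    lo, hi = depth_range
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(nbins)
    for trace in traces:
        span = getattr(trace, "depth_span", None)
        if span is None:
            from .layer_segmentation import ipl_depth  # local to avoid cycle at import
            zs = np.array([p.z_um for p in trace.points])
            dd = np.asarray(ipl_depth(zs, layer_model), dtype=float)
            span = (float(dd.min()), float(dd.max()))
        counts += (centers >= span[0]) & (centers <= span[1])
    return DensityProfile(depth_bins=edges, N=counts / field_area_mm2,
                          field_area_mm2=field_area_mm2)


def terminal_distribution(
    profile: DensityProfile,
    smoothing_window: int = 5,
    polyorder: int = 2,
) -> TerminalDistribution:
    """Differentiate the density profile to get the terminal distribution.

    N is optionally smoothed with a moving polynomial (Savitzky-Golay)
    window before differencing; ``smoothing_window <= 1`` disables
    smoothing, in which case the discrete conservation identity holds
    exactly. Negative raw values (axons appearing with depth, i.e. tracing
    noise) are kept in ``T_raw`` and clipped to zero in ``T``.
    """
    N = profile.N
    if N.size < 3:
        raise ValueError("need at least 3 density bins")
    if smoothing_window > N.size:
        raise ValueError(
            f"smoothing window {smoothing_window} larger than profile ({N.size} bins)")
    if smoothing_window > 1:
        win = smoothing_window + 1 - smoothing_window % 2  # force odd
        Ns = signal.savgol_filter(N, window_length=win, polyorder=min(polyorder, win - 1))
    else:
        Ns = N
    centers = profile.bin_centers
    dd = np.diff(centers)
    T_raw = -np.diff(Ns) / dd
    mid = 0.5 * (centers[:-1] + centers[1:])
    return TerminalDistribution(
        depth_bins=mid, T=np.clip(T_raw, 0.0, None), T_raw=T_raw,
        smoothing_window=smoothing_window,
    )


# ---------------------------------------------------------------------------
# Peaks, classification
# ---------------------------------------------------------------------------

def detect_peaks1d(
    values: np.ndarray,
    x: np.ndarray | None = None,
    min_prominence_frac: float = 0.1,
    min_separation: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima with fractional prominence and minimum separation.

    ``min_separation`` is in units of ``x`` (or samples when ``x`` is
    omitted). Positions are refined by quadratic interpolation around each
    sample peak. Returns (positions, prominences); of two peaks closer
    than the separation, the higher survives (scipy's distance rule).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("signal too short for peak detection")
    vrange = values.max() - values.min()
    if vrange <= 0:
        return np.array([]), np.array([])
    if x is None:
        x = np.arange(values.size, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    dx = float(np.mean(np.diff(x)))
    distance = max(int(round(min_separation / dx)), 1) if min_separation > 0 else 1
    peaks, props = signal.find_peaks(
        values, prominence=min_prominence_frac * vrange, distance=distance)
    positions = []
    for p in peaks:
        if 0 < p < values.size - 1:
            denom = values[p - 1] - 2 * values[p] + values[p + 1]
            off = 0.5 * (values[p - 1] - values[p + 1]) / denom if denom < -1e-300 else 0.0
            off = float(np.clip(off, -0.5, 0.5))
        else:
            off = 0.0
        positions.append(x[p] + off * dx)
    return np.asarray(positions), props.get("prominences", np.array([]))


def classify_terminals(
    terminal_depths: Sequence[float],
    boundaries: tuple[float, ...] = (0.4, 0.8),
    labels: tuple[str, ...] = ("OFF", "ON", "ROD"),
) -> list[str | None]:
    """Assign a subtype label per terminal depth by half-open depth bins.

    Bins are [0, b1), [b1, b2), ... [bk, 1]; a depth exactly on a cut
    point falls into the deeper bin. NaN depths give ``None``.
    """
    bounds = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(bounds) <= 0) or np.any((bounds <= 0) | (bounds >= 1)):
        raise ValueError(f"cut points must be strictly increasing inside (0,1): {boundaries}")
    if len(labels) != len(bounds) + 1:
        raise ValueError(f"{len(bounds)} cut points need {len(bounds)+1} labels")
    out: list[str | None] = []
    for d in terminal_depths:
        if d is None or not np.isfinite(d):
            out.append(None)
        else:
            out.append(labels[int(np.searchsorted(bounds, d, side="right"))])
    return out


def intensity_along_trace(trace, layer_model: LayerModel) -> np.ndarray:
    """(depth, intensity) series of one summarized trace, ordered by depth."""
    if trace.intensity_profile is None:
        raise ValueError("trace is not summarized; call summarize_trace first")
    return trace.intensity_profile


def cohort_intensity_curve(
    traces: Sequence,
    depth_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity versus depth over a cohort of summarized traces."""
    if depth_grid is None:
        depth_grid = np.linspace(0.0, 1.0, 51)
    sums = np.zeros_like(depth_grid)
    counts = np.zeros_like(depth_grid)
    for tr in traces:
        prof = tr.intensity_profile
        if prof is None:
            continue
        d, i = prof[:, 0], prof[:, 1]
        sel = (depth_grid >= d.min()) & (depth_grid <= d.max())
        if not np.any(sel):
            continue
        sums[sel] += np.interp(depth_grid[sel], d, i)
        counts[sel] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return depth_grid, mean


# ---------------------------------------------------------------------------
# Gaussian mixture of terminal-zone intensities
# ---------------------------------------------------------------------------

@dataclass
class GMMFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    bic: float
    ll_trace: np.ndarray = field(default=None, repr=False)
    converged: bool = True


def _em_1d(values: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int, tol: float, var_floor: float) -> GMMFit:
    n = values.size
    # initialize from random quantile-ish centers
    means = rng.choice(values, size=k, replace=False) if n >= k else np.resize(values, k)
    means = means.astype(float)
    var = np.full(k, max(values.var(), var_floor))
    w = np.full(k, 1.0 / k)
    ll_prev = -np.inf
    lls = []
    converged = False
    for _ in range(max_iter):
        # E step (log domain)
        logp = (-0.5 * ((values[:, None] - means[None]) ** 2 / var[None])
                - 0.5 * np.log(2 * np.pi * var[None]) + np.log(w[None]))
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        lls.append(ll)
        resp = np.exp(logp - lse[:, None])
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        means = (resp * values[:, None]).sum(axis=0) / nk
        var = (resp * (values[:, None] - means[None]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)
        if ll - ll_prev < tol * max(abs(ll), 1.0) and ll_prev > -np.inf:
            converged = True
            break
        ll_prev = ll
    lls = np.asarray(lls)
    # EM on a well-defined model never decreases the likelihood; the variance
    # floor can nick this by a vanishing amount, so audit with a tolerance.
    if np.any(np.diff(lls) < -1e-6 * max(abs(lls[-1]), 1.0)):
        raise RuntimeError("EM log-likelihood decreased; numerical failure")
    order = np.argsort(means)
    n_params = 3 * k - 1
    bic = -2.0 * lls[-1] + n_params * math.log(n)
    return GMMFit(k=k, weights=w[order], means=means[order], sds=np.sqrt(var[order]),
                  log_likelihood=float(lls[-1]), bic=float(bic), ll_trace=lls,
                  converged=converged)


def fit_intensity_gmm(
    values: Sequence[float],
    k_range: Sequence[int] = (1, 2, 3, 4, 5, 6),
    n_init: int = 5,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-8,
    var_floor: float = 1e-6,
) -> GMMFit:
    """Maximum-likelihood 1D Gaussian mixture with BIC model selection.

    For each candidate component count, EM runs from ``n_init`` seeded
    random initializations and the best likelihood is kept; the fit
    minimizing BIC over ``k_range`` is returned. Components collapsing to
    degenerate variance are held at the variance floor and, when they carry
    (almost) no weight, pruned with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError(f"need at least 10 values, got {values.size}")
    if not set(k_range) <= set(range(1, 7)):
        raise ValueError(f"k_range must be within 1..6, got {k_range}")
    if float(values.var()) < var_floor:
        warnings.warn("degenerate sample (zero variance); returning k=1 at the sd floor")
        return GMMFit(k=1, weights=np.array([1.0]), means=np.array([values.mean()]),
                      sds=np.array([math.sqrt(var_floor)]), log_likelihood=float("nan"),
                      bic=float("inf"), ll_trace=np.array([]), converged=True)

    rng = np.random.default_rng(seed)
    best: GMMFit | None = None
    for k in sorted(k_range):
        best_k: GMMFit | None = None
        for _ in range(n_init):
            fit = _em_1d(values, k, rng, max_iter, tol, var_floor)
            if best_k is None or fit.log_likelihood > best_k.log_likelihood:
                best_k = fit
        assert best_k is not None
        # prune empty components (weight below 1/2n cannot explain a point)
        keep = best_k.weights > 0.5 / values.size
        if not np.all(keep):
            warnings.warn(
                f"pruned {int((~keep).sum())} empty mixture component(s) at k={k}")
            w = best_k.weights[keep]
            best_k = GMMFit(
                k=int(keep.sum()), weights=w / w.sum(), means=best_k.means[keep],
                sds=best_k.sds[keep], log_likelihood=best_k.log_likelihood,
                bic=-2.0 * best_k.log_likelihood + (3 * int(keep.sum()) - 1) * math.log(values.size),
                ll_trace=best_k.ll_trace, converged=best_k.converged)
        if best is None or best_k.bic < best.bic:
            best = best_k
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Co-localization with a fluorescence channel
# ---------------------------------------------------------------------------

def colocalize_traces(
    traces: Sequence,
    volume: Volume,
    layer_model: LayerModel,
    fluor_channel: int | str = "gfp",
    radius_um: float = 0.6,
    threshold_rule: str = "otsu",
    k_background: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Flag traces overlapping the fluorescence channel at zero IPL depth.

    Each trace is sampled in a disc of ``radius_um`` around its position
    in the plane nearest d = 0 (a tight disc: at bipolar-cell densities a
    wider one picks up bleed-through from colabeled neighbors).
    ``threshold_rule`` is ``"otsu"`` (Otsu over the per-trace samples) or
    ``"k_median"`` (k times the median background of the plane, falling
    back to the plane mean when the median is zero). Returns
    (flags, samples, threshold).
    """
    data = volume.channel_data(fluor_channel).astype(np.float64)
    dz, dy, dx = volume.voxel_um
    z0 = float(ipl_depth_to_z(0.0, layer_model))
    zi = int(np.clip(round((z0 - volume.origin_um[0]) / dz), 0, data.shape[0] - 1))
    plane = data[zi]
    ny, nx = plane.shape
    ry, rx = max(int(round(radius_um / dy)), 1), max(int(round(radius_um / dx)), 1)
    yy, xx = np.mgrid[-ry:ry + 1, -rx:rx + 1]
    disc = (yy * dy) ** 2 + (xx * dx) ** 2 <= radius_um ** 2

    samples = np.empty(len(traces))
    for i, tr in enumerate(traces):
        zs = np.array([p.z_um for p in tr.points])
        j = int(np.argmin(np.abs(zs - z0)))
        p = tr.points[j]
        cy = int(round((p.y_um - volume.origin_um[1]) / dy))
        cx = int(round((p.x_um - volume.origin_um[2]) / dx))
        ys = slice(max(cy - ry, 0), min(cy + ry + 1, ny))
        xs = slice(max(cx - rx, 0), min(cx + rx + 1, nx))
        sub = plane[ys, xs]
        dsub = disc[ys.start - (cy - ry):ys.stop - (cy - ry),
                    xs.start - (cx - rx):xs.stop - (cx - rx)]
        samples[i] = sub[dsub].mean() if np.any(dsub) else 0.0

    if threshold_rule == "otsu":
        if samples.size and np.ptp(samples) > 0:
            thr = float(threshold_otsu(samples))
        else:
            thr = float("inf")  # featureless: nothing is colabeled
    elif threshold_rule == "k_median":
        bg = float(np.median(plane)) or float(plane.mean())
        thr = k_background * bg
        if thr <= 0:
            thr = float("inf")
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    flags = samples > thr
    for tr, fl in zip(traces, flags):
        tr.colabeled = bool(fl)
    return flags, samples, thr
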