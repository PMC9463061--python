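"""Time-series analyses: intensity decay fits and axial kymographs.

Pharmacological depolymerization (nocodazole) and photobleaching both show
up as a gradual loss of SHG intensity; the package models this as an
exponential decay with an offset, I(t) = c + I0 * exp(-k t), fitted by
nonlinear least squares with a log-linear initialization. Axial swelling
under continuous illumination is detected on a kymograph (time x z grid of
axial mean profiles) by tracking the vitreal tissue boundary via its
half-maximum crossing and thresholding its cumulative displacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .layer_segmentation import axial_profile
from .volume_io import Volume

__all__ = [
    "TimeSeries",
    "DecayFit",
    "Kymograph",
    "fit_decay",
    "build_kymograph",
    "detect_swelling_onset",
]


@dataclass
class TimeSeries:
    times_min: np.ndarray
    values: np.ndarray
    region_label: str = ""

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times_min.size != self.values.size:
            raise ValueError("times and values must have equal length")


@dataclass
class DecayFit:
    I0: float
    rate_per_min: float
    offset: float
    residual_rms: float
    converged: bool


@dataclass
class Kymograph:
    grid: np.ndarray        # (time, z)
    times_min: np.ndarray
    dz_um: float

    @property
    def dt_min(self) -> float:
        return float(np.mean(np.diff(self.times_min)))


def _model(t, c, I0, k):
    return c + I0 * np.exp(-k * t)


def fit_decay(series: TimeSeries) -> DecayFit:
    """Fit I(t) = c + I0 exp(-k t) by nonlinear least squares.

    Initialized from a log-linear fit of I - min(I); a constant series
    returns the exact k = 0 fit. Non-convergence is flagged (NaN rate),
    never silent.
    """
    t, I = series.times_min, series.values
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    span = I.max() - I.min()
    if span <= 0:
        return DecayFit(I0=0.0, rate_per_min=0.0, offset=float(I[0]),
                        residual_rms=0.0, converged=True)
    c0 = float(I.min())
    resid0 = I - c0 + 1e-3 * span
    slope, logI0 = np.polyfit(t, np.log(resid0), 1)
    k0 = max(-slope, 1e-6)
    p0 = (c0, float(np.exp(logI0)), k0)
    try:
        popt, _ = optimize.curve_fit(
            _model, t, I, p0=p0,
            bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except (RuntimeError, ValueError):
        return DecayFit(I0=float("nan"), rate_per_min=float("nan"),
                        offset=float("nan"), residual_rms=float("nan"),
                        converged=False)
    resid = I - _model(t, *popt)
    return DecayFit(I0=float(popt[1]), rate_per_min=float(popt[2]),
                    offset=float(popt[0]),
                    residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                    converged=True)


def build_kymograph(
    volumes: Sequence[Volume],
    channel: int | str = 0,
    lateral_window=None,
    times_min: Sequence[float] | None = None,
) -> Kymograph:
    """Stack per-timepoint axial profiles into a (time x z) kymograph."""
    if not volumes:
        raise ValueError("need at least one volume")
    shape = volumes[0].shape_zyx
    voxel = volumes[0].voxel_um
    for v in volumes[1:]:
        if v.shape_zyx != shape or v.voxel_um != voxel:
            raise ValueError("all volumes must share shape and voxel size")
    rows = [axial_profile(v, channel, lateral_window) for v in volumes]
    times = np.arange(len(volumes), dtype=float) if times_min is None else \
        np.asarray(times_min, dtype=float)
    return Kymograph(grid=np.stack(rows), times_min=times, dz_um=voxel[0])


def _vitreal_half_max_crossing(row: np.ndarray) -> float:
    """Sub-voxel z index where the row first reaches half its maximum,
    scanning from the vitreal side. Uses the row minimum as baseline so
    the crossing is invariant to intensity offset and scale."""
    lo, hi = row.min(), row.max()
    if hi <= lo:
        return 0.0
    level = lo + 0.5 * (hi - lo)
    above = np.nonzero(row >= level)[0]
    if above.size == 0:
        return 0.0
    i = int(above[0])
    if i == 0:
        return 0.0
    frac = (level - row[i - 1]) / (row[i] - row[i - 1])
    return (i - 1) + float(frac)


def detect_swelling_onset(
    kymograph: Kymograph,
    displacement_threshold_um: float,
) -> float | None:
    """First time the vitreal boundary's cumulative displacement exceeds
    the threshold; ``None`` when it never does."""
    if kymograph.grid.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    edges = np.array([_vitreal_half_max_crossing(r) for r in kymograph.grid])
    disp_um = np.abs(edges - edges[0]) * kymograph.dz_um
    # reaching the threshold counts as onset (tolerate float rounding)
    beyond = np.nonzero(disp_um >= displacement_threshold_um - 1e-9)[0]
    if beyond.size == 0:
        return None
    return float(kymograph.times_min[int(beyond[0])])
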