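"""Synthetic SHG retina scenes: ground truth generation and rendering.

The generator produces scenes with the statistical structure the analysis
assumes, so every downstream stage (layer segmentation, tracing, census,
strata analysis, group metrics) can be scored by parameter recovery:

* vertical bipolar-cell axons enter the field at a homogeneous planar
  Poisson rate, descend through the INL into the IPL and terminate at a
  subtype-specific normalized IPL depth; SHG emission along an axon scales
  as ``caliber**gamma`` and ramps to zero over the final micrometres of the
  terminal (axon terminals themselves are SHG-dark);
* the IPL contains a diffuse neuropil whose axial profile carries fine
  sublaminar strata and two laterally coherent gaps; the fine strata
  undulate in depth across the field so that wide lateral averaging merges
  them while narrow windows resolve them;
* nuclear layers (INL, ONL) are near-dark, the OPL is a second bright
  band, and a nerve-fiber (RNFL) band sits on the vitreal side of the GCL;
* a fluorescence co-label channel carries a GUS-like subset of axons, and a
  band channel carries ChAT-like lateral bands at fixed IPL depths;
* rendering applies an anisotropic Gaussian PSF, Poisson shot noise and
  Gaussian read noise, then quantizes to the detector bit depth.

All randomness flows through explicit integer seeds; identical parameters
and seeds give bitwise-identical scenes and volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, stats

from .volume_io import Volume

__all__ = [
    "SubtypeSpec",
    "SceneParams",
    "OpticsParams",
    "AxonSpec",
    "SyntheticScene",
    "generate_scene",
    "render_volume",
    "sample_zero_depth_intensities",
    "score_traces_against_truth",
    "DEFAULT_SUBTYPES",
    "DEFAULT_STRATA",
]

LAYER_ORDER = ("GCL", "IPL", "INL", "OPL", "ONL")

#: Default bipolar-cell subtype populations. Terminal-depth means are evenly
#: spaced across the IPL (five sublaminae); the three colabeled entries
#: emulate the GUS-expressing species (CBC4, CBC7 cone types and the rod
#: bipolar cell). Axon calibers fall into three classes (OFF-type and rod
#: bipolar axons are thicker than ON cone axons), which is what makes the
#: terminal-zone intensity histogram a three-component mixture.
DEFAULT_SUBTYPES: tuple[tuple, ...] = (
    #  name    fraction  d_mean  d_sd   caliber_um  caliber_sd  colabeled
    ("bc_off_a", 0.20, 0.10, 0.035, 0.80, 0.06, False),
    ("cbc4",     0.20, 0.30, 0.035, 0.80, 0.06, True),
    ("bc_on_a",  0.20, 0.50, 0.035, 0.50, 0.06, False),
    ("cbc7",     0.20, 0.70, 0.035, 0.50, 0.06, True),
    ("rbc",      0.20, 0.90, 0.035, 1.30, 0.06, True),
)

#: Default diffuse-neuropil fine strata: five sublaminae of equal spacing.
#: The outermost sublaminae sit against the dark nuclear/ganglion layers and
#: carry less diffuse signal than the central ones; the sublaminae bordering
#: the intra-IPL gaps carry more, compensating the gap tails so the five
#: rendered sublayers show comparable contrast.
DEFAULT_STRATA: tuple[tuple[float, float, float], ...] = (
    (0.10, 0.035, 0.45),
    (0.30, 0.035, 1.5),
    (0.50, 0.035, 1.05),
    (0.70, 0.035, 1.2),
    (0.90, 0.035, 0.45),
)


@dataclass(frozen=True)
class SubtypeSpec:
    name: str
    fraction: float
    terminal_depth_mean: float
    terminal_depth_sd: float
    caliber_mean_um: float
    caliber_sd_um: float
    colabeled: bool

    def __post_init__(self):
        if not (0.0 <= self.terminal_depth_mean <= 1.0):
            raise ValueError(f"terminal depth mean {self.terminal_depth_mean} outside [0, 1]")


@dataclass(frozen=True)
class SceneParams:
    """Ground-truth scene description.

    ``field_size_um`` is the lateral (x, y) extent. ``layer_thicknesses_um``
    maps each retinal layer to its axial thickness; the default IPL is
    36 µm thick. Depth-like parameters (terminal depths, strata centers,
    gap and band depths) are in normalized IPL-depth units: 0 at the
    IPL/INL interface, 1 at the IPL/GCL interface.
    """

    field_size_um: tuple[float, float] = (128.0, 128.0)  # (x, y)
    layer_thicknesses_um: dict = field(
        default_factory=lambda: {"GCL": 15.0, "IPL": 36.0, "INL": 25.0, "OPL": 8.0, "ONL": 20.0}
    )
    axon_density_per_mm2: float = 42_500.0
    subtype_table: tuple = DEFAULT_SUBTYPES
    strata_spec: tuple = DEFAULT_STRATA
    gap_depths: tuple[float, ...] = (0.25, 0.62)
    band_depths: tuple[float, ...] = (0.25, 0.62)
    tortuosity_um: float = 1.0
    seed: int = 0

    # -- texture / amplitude knobs (placeholders where the source biology is
    #    unquantified; see docs/methods.md) -------------------------------
    neuropil_amplitude: float = 1.0          # envelope scale of the diffuse IPL signal
    gap_fraction: float = 0.6                # fractional dip of each intra-IPL gap
    gap_width_depth: float = 0.05            # Gaussian sigma of a gap, depth units
    undulation_slope_per_um: float = 0.005   # local tilt of the sublamination, depth/µm
    undulation_depth_sd: float = 0.02        # random lateral undulation on top of the tilt
    undulation_corr_um: float = 10.0         # correlation length of the random undulation
    envelope_edge_depth: float = 0.05        # taper width of the IPL envelope at d=0 and d=1
    axon_gain: float = 25.0                  # emission per unit caliber**gamma
    caliber_ramp: float = 0.5                # fractional caliber increase from d=1 to d=0
    terminal_taper_um: float = 2.0           # emission ramps to 0 over this terminal length
    tortuosity_corr_um: float = 10.0         # axial correlation length of lateral jitter
    opl_amplitude: float = 1.0
    rnfl_amplitude: float = 2.0
    rnfl_thickness_um: float = 5.0
    nuclear_background: float = 0.03
    band_amplitude: float = 5.0
    band_width_depth: float = 0.04
    colabel_gain: float = 10.0               # fluorescence per µm of colabeled axon
    margin_um: float = 3.0                   # dark axial margin on each side of the stack

    def __post_init__(self):
        fx, fy = self.field_size_um
        if fx <= 0 or fy <= 0:
            raise ValueError(f"field size must be positive, got {self.field_size_um}")
        if self.axon_density_per_mm2 < 0:
            raise ValueError("axon density must be >= 0")
        if any(t <= 0 for t in self.layer_thicknesses_um.values()):
            raise ValueError("layer thicknesses must be positive")
        subtypes = self.subtypes()
        total = sum(s.fraction for s in subtypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype fractions sum to {total}, expected 1")
        for d in list(self.gap_depths) + list(self.band_depths):
            if not (0.0 < d < 1.0):
                raise ValueError(f"depth {d} outside (0, 1)")
        for c, w, a in self.strata_spec:
            if not (0.0 <= c <= 1.0) or not (0.0 < w <= 1.0) or a < 0:
                raise ValueError(f"invalid stratum ({c}, {w}, {a})")

    def subtypes(self) -> list[SubtypeSpec]:
        return [s if isinstance(s, SubtypeSpec) else SubtypeSpec(*s) for s in self.subtype_table]

    # -- axial geometry ---------------------------------------------------
    def layer_boundaries_um(self) -> dict[str, float]:
        """Interface z positions in µm; z=0 is the vitreal (GCL) side."""
        z = self.margin_um
        bounds = {}
        names = iter(LAYER_ORDER)
        prev = next(names)
        z += self.layer_thicknesses_um[prev]
        for name in names:
            bounds[f"{prev}/{name}"] = z
            z += self.layer_thicknesses_um[name]
            prev = name
        bounds["ONL/end"] = z
        return bounds

    @property
    def z_extent_um(self) -> float:
        return 2 * self.margin_um + sum(self.layer_thicknesses_um.values())

    @property
    def ipl_thickness_um(self) -> float:
        return self.layer_thicknesses_um["IPL"]

    def depth_to_z(self, d) -> np.ndarray | float:
        """Normalized IPL depth -> z in µm (d=0 at IPL/INL, 1 at GCL/IPL)."""
        z_ipl_inl = self.layer_boundaries_um()["IPL/INL"]
        return z_ipl_inl - np.asarray(d, dtype=float) * self.ipl_thickness_um

    def z_to_depth(self, z) -> np.ndarray | float:
        z_ipl_inl = self.layer_boundaries_um()["IPL/INL"]
        return (z_ipl_inl - np.asarray(z, dtype=float)) / self.ipl_thickness_um

    def to_yaml(self, path: str | Path) -> Path:
        payload = {
            "field_size_um": list(self.field_size_um),
            "layer_thicknesses_um": dict(self.layer_thicknesses_um),
            "axon_density_per_mm2": self.axon_density_per_mm2,
            "subtype_table": [list(s) if not isinstance(s, SubtypeSpec) else
                              [s.name, s.fraction, s.terminal_depth_mean, s.terminal_depth_sd,
                               s.caliber_mean_um, s.caliber_sd_um, s.colabeled]
                              for s in self.subtype_table],
            "strata_spec": [list(s) for s in self.strata_spec],
            "gap_depths": list(self.gap_depths),
            "band_depths": list(self.band_depths),
            "tortuosity_um": self.tortuosity_um,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
        return Path(path)


@dataclass(frozen=True)
class OpticsParams:
    """Imaging model: sampling, PSF, photon budget, detector."""

    voxel_um: tuple[float, float, float] = (1.0, 0.5, 0.5)  # (dz, dy, dx)
    psf_sigma_lateral_um: float = 0.3
    psf_fwhm_axial_um: float = 1.5
    photons_per_unit_emission: float = 30.0
    read_noise_sd: float = 2.0
    bit_depth: int = 16
    emission_exponent: float = 2.0  # gamma: emission ~ caliber**gamma

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel sizes must be positive")
        if self.psf_sigma_lateral_um <= 0 or self.psf_fwhm_axial_um <= 0:
            raise ValueError("PSF widths must be positive")
        if self.photons_per_unit_emission <= 0:
            raise ValueError("photon budget must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit depth must be 8 or 16, got {self.bit_depth}")

    @property
    def psf_sigma_axial_um(self) -> float:
        return self.psf_fwhm_axial_um / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class AxonSpec:
    """A single vertical bipolar-cell axon of the ground truth."""

    id: int
    entry_xy_um: tuple[float, float]  # (x, y) at the INL/OPL side
    terminal_depth: float
    caliber_um: float
    subtype: str
    colabeled: bool
    path: np.ndarray  # (n, 3) points (z, y, x) in µm, z strictly decreasing

    def xy_at_z(self, z_um: float) -> tuple[float, float]:
        """Lateral position interpolated at a given z (path is monotone in z)."""
        z = self.path[:, 0][::-1]
        y = np.interp(z_um, z, self.path[:, 1][::-1])
        x = np.interp(z_um, z, self.path[:, 2][::-1])
        return float(x), float(y)


@dataclass
class SyntheticScene:
    params: SceneParams
    axons: list[AxonSpec]
    neuropil_profile_truth: Callable[[np.ndarray], np.ndarray]
    layer_boundaries_truth: dict[str, float]

    @property
    def field_area_mm2(self) -> float:
        fx, fy = self.params.field_size_um
        return fx * fy * 1e-6

    def axon_table(self) -> pd.DataFrame:
        rows = [
            (a.id, a.entry_xy_um[0], a.entry_xy_um[1], a.terminal_depth,
             a.caliber_um, a.subtype, a.colabeled)
            for a in self.axons
        ]
        return pd.DataFrame(
            rows, columns=["id", "x", "y", "terminal_depth", "caliber", "subtype", "colabeled"]
        )


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def _smooth_jitter(n: int, step_um: float, scale_um: float, corr_um: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Zero-anchored smooth lateral jitter with the given sd and correlation."""
    if scale_um <= 0 or n < 2:
        return np.zeros((n, 2))
    noise = rng.standard_normal((n, 2))
    sigma = max(corr_um / step_um, 1e-6)
    smooth = ndimage.gaussian_filter1d(noise, sigma=sigma, axis=0, mode="reflect")
    # normalize to unit pointwise sd, then scale; anchor the entry point at 0
    norm = 1.0 / (2.0 * math.sqrt(math.pi) * sigma) ** 0.5  # sd of filtered white noise
    smooth = smooth / norm * scale_um
    return smooth - smooth[0]


def _lamination(d: np.ndarray, params: SceneParams) -> np.ndarray:
    """Fine sublaminar modulation of the neuropil: strata bumps times gap
    dips. The whole lamination undulates laterally as one rigid pattern."""
    return _gap_factor(d, params) * (1.0 + _strata_bumps(d, params))


def _strata_bumps(d: np.ndarray, params: SceneParams) -> np.ndarray:
    fine = np.zeros_like(np.asarray(d, dtype=float))
    for c, w, a in params.strata_spec:
        fine += a * np.exp(-0.5 * ((d - c) / w) ** 2)
    return fine


def _anchor(d: np.ndarray) -> np.ndarray:
    """Undulation anchoring: the sublamination cannot shift off the IPL, so
    lateral depth offsets vanish at both interfaces and peak mid-IPL."""
    return np.sin(np.pi * np.clip(d, 0.0, 1.0))


def _make_neuropil_truth(params: SceneParams) -> Callable[[np.ndarray], np.ndarray]:
    """Ensemble-mean axial neuropil profile: the lamination pattern smeared
    by the marginal distribution of the lateral depth offset over the whole
    field (tilt plus random undulation, depth-dependent via the boundary
    anchoring), under the envelope tied to the layer boundaries."""
    fx, fy = params.field_size_um
    tilt_var = params.undulation_slope_per_um ** 2 * (fx ** 2 + fy ** 2) / 24.0
    sd = math.sqrt(tilt_var + params.undulation_depth_sd ** 2)

    def truth(d: np.ndarray) -> np.ndarray:
        d = np.atleast_1d(np.asarray(d, dtype=float))
        env = _envelope(d, params)
        if sd <= 0:
            return params.neuropil_amplitude * env * _lamination(d, params)
        # Gauss-Hermite style average over the undulation offset
        offs = np.linspace(-4 * sd, 4 * sd, 81)
        wts = np.exp(-0.5 * (offs / sd) ** 2)
        wts /= wts.sum()
        lam = np.zeros_like(d)
        for o, w in zip(offs, wts):
            lam += w * _lamination(d - o * _anchor(d), params)
        return params.neuropil_amplitude * env * lam

    return truth


def _envelope(d: np.ndarray, params: SceneParams) -> np.ndarray:
    """Smooth top-hat over the IPL, tapering at both interfaces."""
    e = params.envelope_edge_depth
    lo = 0.5 * (1.0 + np.tanh((d - 0.0) / (e / 2.0)))
    hi = 0.5 * (1.0 + np.tanh((1.0 - d) / (e / 2.0)))
    return lo * hi


def _gap_factor(d: np.ndarray, params: SceneParams) -> np.ndarray:
    g = np.ones_like(np.asarray(d, dtype=float))
    for gd in params.gap_depths:
        g *= 1.0 - params.gap_fraction * np.exp(-0.5 * ((d - gd) / params.gap_width_depth) ** 2)
    return g


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Draw a ground-truth scene from the scene parameters.

    Axon entry points follow a homogeneous planar Poisson process at
    ``axon_density_per_mm2``; each axon's subtype is categorical on the
    subtype fractions, its terminal depth is Normal (truncated to [0, 1])
    and its caliber lognormal with the subtype's mean/sd. Deterministic
    given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    fx, fy = params.field_size_um
    area_mm2 = fx * fy * 1e-6
    n = int(rng.poisson(params.axon_density_per_mm2 * area_mm2))

    subtypes = params.subtypes()
    fractions = np.array([s.fraction for s in subtypes])
    bounds = params.layer_boundaries_um()
    z_entry = bounds["INL/OPL"]

    xs = rng.uniform(0.0, fx, size=n)
    ys = rng.uniform(0.0, fy, size=n)
    kinds = rng.choice(len(subtypes), size=n, p=fractions)

    axons: list[AxonSpec] = []
    step = 0.5  # µm path discretization
    for i in range(n):
        s = subtypes[kinds[i]]
        a, b = (0.0 - s.terminal_depth_mean) / s.terminal_depth_sd, (
            1.0 - s.terminal_depth_mean) / s.terminal_depth_sd
        d_term = float(stats.truncnorm.rvs(
            a, b, loc=s.terminal_depth_mean, scale=s.terminal_depth_sd, random_state=rng))
        # lognormal parametrized by its own mean and sd
        sigma2 = math.log(1.0 + (s.caliber_sd_um / s.caliber_mean_um) ** 2)
        mu = math.log(s.caliber_mean_um) - sigma2 / 2.0
        caliber = float(rng.lognormal(mean=mu, sigma=math.sqrt(sigma2)))

        z_term = float(params.depth_to_z(d_term))
        n_pts = max(int(round((z_entry - z_term) / step)) + 1, 2)
        z = np.linspace(z_entry, z_term, n_pts)
        jitter = _smooth_jitter(n_pts, step, params.tortuosity_um,
                                params.tortuosity_corr_um, rng)
        path = np.column_stack([
            z,
            np.clip(ys[i] + jitter[:, 0], 0.0, fy),
            np.clip(xs[i] + jitter[:, 1], 0.0, fx),
        ])
        axons.append(AxonSpec(
            id=i, entry_xy_um=(float(xs[i]), float(ys[i])), terminal_depth=d_term,
            caliber_um=caliber, subtype=s.name, colabeled=s.colabeled, path=path,
        ))

    return SyntheticScene(
        params=params,
        axons=axons,
        neuropil_profile_truth=_make_neuropil_truth(params),
        layer_boundaries_truth=params.layer_boundaries_um(),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

KNOWN_CHANNELS = ("shg", "gfp", "chat")


def _undulation_field(params: SceneParams, ny: int, nx: int, dy: float, dx: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Lateral depth-offset field of the sublamination (depth units).

    Dominated by a deterministic local tilt (the sublaminae run at a small
    angle to the segmentation surface, as in a gently curved wholemount);
    the tilt's orientation is random per scene, but the within-window depth
    spread it induces is orientation-invariant and grows linearly with the
    window size — narrow windows see the lamination coherently, wide ones
    average across sublaminar depth. A weak smooth random field adds
    texture on top.
    """
    yy = (np.arange(ny) - (ny - 1) / 2.0) * dy
    xx = (np.arange(nx) - (nx - 1) / 2.0) * dx
    theta = rng.uniform(0.0, 2.0 * np.pi)
    phase = rng.uniform(-0.05, 0.05)
    fieldv = params.undulation_slope_per_um * (
        np.cos(theta) * xx[None, :] + np.sin(theta) * yy[:, None]) + phase
    if params.undulation_depth_sd > 0:
        sig_y = params.undulation_corr_um / dy
        sig_x = params.undulation_corr_um / dx
        noise = rng.standard_normal((ny, nx))
        smooth = ndimage.gaussian_filter(noise, sigma=(sig_y, sig_x), mode="wrap")
        # normalize by the theoretical pointwise sd of Gaussian-filtered
        # unit white noise (ensemble statistics, not the realization's)
        theo_sd = 1.0 / (2.0 * math.sqrt(math.pi) * math.sqrt(sig_y * sig_x))
        fieldv = fieldv + smooth / theo_sd * params.undulation_depth_sd
    return fieldv


def _splat(plane: np.ndarray, y: float, x: float, weight: float) -> None:
    """Bilinear deposition of a point emitter into a 2D plane."""
    ny, nx = plane.shape
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    fy, fx = y - y0, x - x0
    for dyi, wy in ((0, 1 - fy), (1, fy)):
        for dxi, wx in ((0, 1 - fx), (1, fx)):
            yy, xx = y0 + dyi, x0 + dxi
            if 0 <= yy < ny and 0 <= xx < nx:
                plane[yy, xx] += weight * wy * wx


def _caliber_factor(d: np.ndarray, ramp: float) -> np.ndarray:
    """Axial caliber modulation: axons thicken toward the INL (d -> 0)."""
    return 1.0 + ramp * np.clip(1.0 - d, 0.0, 1.0)


def render_volume(
    scene: SyntheticScene,
    optics: OpticsParams = OpticsParams(),
    channels: Sequence[str] = ("shg", "gfp", "chat"),
    seed: int = 0,
    noise: bool = True,
    psf: bool = True,
) -> Volume:
    """Rasterize a scene into a noisy multi-channel volume.

    Channels: ``shg`` (axons + neuropil + OPL/RNFL bands), ``gfp``
    (colabeled-axon fluorescence), ``chat`` (lateral fluorescence bands at
    the scene's band depths). Emission is convolved with an anisotropic
    Gaussian PSF, then Poisson shot noise at ``photons_per_unit_emission``
    and Gaussian read noise are applied and the result is quantized to the
    detector bit depth. ``noise=False`` returns the blurred emission scaled
    to photons; ``psf=False`` skips the blur (useful for oracle tests).
    """
    channels = tuple(channels)
    if not channels:
        raise ValueError("empty channel spec")
    unknown = set(channels) - set(KNOWN_CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}; known: {KNOWN_CHANNELS}")
    params = scene.params
    dz, dy, dx = optics.voxel_um
    fx, fy = params.field_size_um
    if dy > fy or dx > fx or dz > params.z_extent_um:
        raise ValueError("voxel size larger than the field extent")

    # voxel i sits at physical coordinate i * pitch (origin at zero)
    nz = int(round(params.z_extent_um / dz)) + 1
    ny = int(round(fy / dy)) + 1
    nx = int(round(fx / dx)) + 1
    rng = np.random.default_rng(seed)

    z_um = np.arange(nz) * dz
    d_of_z = params.z_to_depth(z_um)
    bounds = scene.layer_boundaries_truth
    gamma = optics.emission_exponent

    emission = {name: np.zeros((nz, ny, nx), dtype=np.float64) for name in channels}

    # --- diffuse structures ---------------------------------------------
    if "shg" in emission:
        vol = emission["shg"]
        in_ipl = (d_of_z >= -0.02) & (d_of_z <= 1.02)
        if np.any(in_ipl):
            undul = _undulation_field(params, ny, nx, dy, dx, rng)
            env = _envelope(d_of_z[in_ipl], params)
            d_sub = d_of_z[in_ipl]
            # the whole sublamination (strata + gaps) undulates laterally as
            # one pattern, anchored at the IPL interfaces; the envelope
            # stays tied to the layer boundaries
            d_local = d_sub[:, None, None] - undul[None] * _anchor(d_sub)[:, None, None]
            lam = _lamination(d_local, params)
            vol[in_ipl] += params.neuropil_amplitude * env[:, None, None] * lam
        # OPL: second bright band (tanh-edged top hat)
        z_inl_opl, z_opl_onl = bounds["INL/OPL"], bounds["OPL/ONL"]
        edge = 0.8  # µm
        opl = (0.5 * (1.0 + np.tanh((z_um - z_inl_opl) / edge))
               * 0.5 * (1.0 + np.tanh((z_opl_onl - z_um) / edge)))
        vol += params.opl_amplitude * opl[:, None, None]
        # RNFL: bright band on the vitreal side of the GCL
        z0 = params.margin_um
        rnfl = ((z_um >= z0) & (z_um < z0 + params.rnfl_thickness_um)).astype(float)
        vol += params.rnfl_amplitude * rnfl[:, None, None]
        # faint nuclear-layer background
        z_ipl_inl = bounds["IPL/INL"]
        nuclear = ((z_um >= z_ipl_inl) & (z_um < z_inl_opl)) | (
            (z_um >= z_opl_onl) & (z_um < bounds["ONL/end"]))
        vol += params.nuclear_background * nuclear[:, None, None]

    if "chat" in emission:
        vol = emission["chat"]
        prof = np.zeros(nz)
        for b in params.band_depths:
            prof += params.band_amplitude * np.exp(
                -0.5 * ((d_of_z - b) / params.band_width_depth) ** 2)
        vol += prof[:, None, None]

    # --- axons ------------------------------------------------------------
    for axon in scene.axons:
        path = axon.path
        seg = np.diff(path, axis=0)
        ds = np.linalg.norm(seg, axis=1)
        arc_from_end = np.concatenate([[0.0], np.cumsum(ds[::-1])])[::-1]  # µm to terminal
        taper = np.clip(arc_from_end / max(params.terminal_taper_um, 1e-9), 0.0, 1.0)
        d_pts = params.z_to_depth(path[:, 0])
        step_len = np.empty(len(path))
        step_len[1:] = ds
        step_len[0] = ds[0] if len(ds) else 0.0
        if "shg" in emission:
            c_eff = axon.caliber_um * _caliber_factor(d_pts, params.caliber_ramp)
            w_shg = params.axon_gain * c_eff ** gamma * taper * step_len
        for j, (zp, yp, xp) in enumerate(path):
            zi = int(round(zp / dz))
            if not (0 <= zi < nz):
                continue
            if "shg" in emission and w_shg[j] > 0:
                _splat(emission["shg"][zi], yp / dy, xp / dx, w_shg[j])
            if "gfp" in emission and axon.colabeled:
                _splat(emission["gfp"][zi], yp / dy, xp / dx,
                       params.colabel_gain * step_len[j])

    # --- optics and detection --------------------------------------------
    data = np.empty((len(channels), nz, ny, nx), dtype=np.float64)
    sig = (optics.psf_sigma_axial_um / dz,
           optics.psf_sigma_lateral_um / dy,
           optics.psf_sigma_lateral_um / dx)
    for k, name in enumerate(channels):
        e = emission[name]
        if psf:
            e = ndimage.gaussian_filter(e, sigma=sig, mode="nearest")
        photons = e * optics.photons_per_unit_emission
        if noise:
            counts = rng.poisson(photons).astype(np.float64)
            counts += rng.normal(0.0, optics.read_noise_sd, size=counts.shape)
            photons = counts
        data[k] = photons

    max_val = 2 ** optics.bit_depth - 1
    data = np.clip(np.round(data), 0, max_val)
    dtype = np.uint8 if optics.bit_depth == 8 else np.uint16
    return Volume(
        data=data.astype(dtype),
        voxel_um=optics.voxel_um,
        channel_names=list(channels),
    )


# ---------------------------------------------------------------------------
# Derived samples and recovery scoring
# ---------------------------------------------------------------------------

def sample_zero_depth_intensities(
    params: SceneParams,
    n: int,
    seed: int = 0,
    gamma: float = 2.0,
    measurement_cv: float = 0.08,
) -> np.ndarray:
    """Draw axon intensities at zero IPL depth implied by the caliber table.

    Intensity is ``(caliber * caliber_factor(0))**gamma`` with a lognormal
    measurement scatter of coefficient of variation ``measurement_cv``; the
    three caliber classes of the default table make this a three-component
    mixture.
    """
    rng = np.random.default_rng(seed)
    subtypes = params.subtypes()
    fractions = np.array([s.fraction for s in subtypes])
    kinds = rng.choice(len(subtypes), size=n, p=fractions)
    means = np.array([s.caliber_mean_um for s in subtypes])[kinds]
    sds = np.array([s.caliber_sd_um for s in subtypes])[kinds]
    sigma2 = np.log(1.0 + (sds / means) ** 2)
    calibers = rng.lognormal(np.log(means) - sigma2 / 2, np.sqrt(sigma2))
    intensity = (calibers * (1.0 + params.caliber_ramp)) ** gamma
    if measurement_cv > 0:
        s2 = math.log(1.0 + measurement_cv ** 2)
        intensity = intensity * rng.lognormal(-s2 / 2, math.sqrt(s2), size=n)
    return intensity


def score_traces_against_truth(
    traces: Sequence,
    scene: SyntheticScene,
    max_mean_dist_um: float = 2.0,
) -> dict:
    """Match recovered traces to ground-truth axons and score recovery.

    A trace matches an axon when the mean lateral distance between the
    trace points and the axon path (compared at the traces' z planes) is
    below ``max_mean_dist_um``; matching is one-to-one, closest pairs
    first. Returns recall, precision, and per-match terminal-depth errors.
    """
    pairs = []
    for ti, trace in enumerate(traces):
        pts = np.array([(p.z_um, p.y_um, p.x_um) for p in trace.points])
        for ai, axon in enumerate(scene.axons):
            # quick reject on entry position
            if (abs(axon.entry_xy_um[0] - pts[0, 2]) > 4 * max_mean_dist_um or
                    abs(axon.entry_xy_um[1] - pts[0, 1]) > 4 * max_mean_dist_um):
                continue
            zlo = max(pts[:, 0].min(), axon.path[:, 0].min())
            zhi = min(pts[:, 0].max(), axon.path[:, 0].max())
            sel = (pts[:, 0] >= zlo - 1e-9) & (pts[:, 0] <= zhi + 1e-9)
            if sel.sum() < 2:
                continue
            dists = []
            for zp, yp, xp in pts[sel]:
                xa, ya = axon.xy_at_z(zp)
                dists.append(math.hypot(yp - ya, xp - xa))
            mean_d = float(np.mean(dists))
            if mean_d < max_mean_dist_um:
                pairs.append((mean_d, ti, ai))
    pairs.sort()
    used_t, used_a, matches = set(), set(), []
    for mean_d, ti, ai in pairs:
        if ti in used_t or ai in used_a:
            continue
        used_t.add(ti)
        used_a.add(ai)
        matches.append((ti, ai, mean_d))
    n_axon = len(scene.axons)
    n_trace = len(traces)
    depth_err = []
    for ti, ai, _ in matches:
        td = getattr(traces[ti], "terminal_depth", None)
        if td is not None and np.isfinite(td):
            depth_err.append(td - scene.axons[ai].terminal_depth)
    return {
        "n_truth": n_axon,
        "n_traces": n_trace,
        "n_matched": len(matches),
        "recall": len(matches) / n_axon if n_axon else 1.0,
        "precision": len(matches) / n_trace if n_trace else 1.0,
        "terminal_depth_errors": np.asarray(depth_err),
        "matches": matches,
    }
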