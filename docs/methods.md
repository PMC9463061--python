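# Methods

`shgretina` quantifies the axonal architecture of the inner retina from
label-free second-harmonic-generation (SHG) z-stacks of fresh wholemounts.
SHG arises from uniformly polarized axonal microtubules, so the contrast is
specific to axons and axon-like neurites: vertical bipolar-cell axons,
the diffuse stratified neuropil of the inner plexiform layer (IPL, carried
by axon-bearing amacrine cells), and the retinal nerve-fiber (RNFL) bundles.
Because no public SHG retina stacks exist, every stage is validated by
parameter recovery on synthetic scenes whose generating parameters are the
study conditions.

## Coordinate conventions

Volumes are `(channel, z, y, x)` with physical voxel sizes in µm; z index 0
is the innermost (GCL-side) plane, as in a wholemount imaged from the
vitreal side. The normalized IPL depth is

    d = (z_IPL/INL − z) / T_IPL,

0 at the IPL/INL interface, 1 at the GCL/IPL interface, increasing toward
the ganglion cell layer. In this convention the ChAT bands sit near
d = 0.25 and 0.62.

## Synthetic scenes

`SceneParams` describes the ground truth; `generate_scene` draws a scene
and `render_volume` images it.

**Axons.** Entry points follow a homogeneous planar Poisson process at
`axon_density_per_mm2` (default 42,500/mm², the midpoint of published mouse
bipolar-cell counts). Each axon gets a subtype from `subtype_table`
(default: five equal populations with terminal-depth means 0.1 … 0.9,
sd 0.035 — one population per IPL sublamina), a terminal depth (truncated
Normal), and a caliber (lognormal). Calibers fall in three classes —
0.8 µm for the two OFF-type populations, 0.5 µm for the two ON-cone
populations, 1.3 µm for the rod-bipolar population — reflecting that
OFF-type and rod bipolar axons are thicker than ON-cone axons; three
classes is what makes the terminal-zone intensity histogram a
three-component mixture. Paths are vertical with smooth lateral jitter
(`tortuosity_um`, default 1 µm, correlation 10 µm along z; real bipolar axons
run near-vertically but their tortuosity statistics are not reported, so
this default is a placeholder). Emission per unit length is `axon_gain · caliber**γ` with
γ = 2 by default (coherent SHG grows super-linearly with the number of
scatterers in the focal volume). Axons thicken toward the INL
(`caliber_ramp`, ×1.5 in caliber at d = 0), and emission ramps to zero over
the final `terminal_taper_um` = 2 µm because axon terminals lack SHG.

**Layers.** Default thicknesses (µm): GCL 15, IPL 36, INL 25, OPL 8,
ONL 20, with a 3-µm dark margin on each side. The OPL is a second bright
band (tanh-edged top hat), nuclear layers carry a faint background (0.03),
and an RNFL band (amplitude 2.0, thickness 5 µm) sits on the vitreal side
of the GCL.

**IPL neuropil.** The diffuse signal is `envelope(d) · lamination(d_local)`
where the envelope is a smooth top hat tied to the layer boundaries (taper
0.05 depth units) and the lamination is five Gaussian strata
(centers 0.1 … 0.9, σ 0.035) times two gap dips at d = 0.25 and 0.62
(σ 0.05, 60% deep). Stratum amplitudes are 0.45 at the edges (those
sublaminae border the dark nuclear/ganglion layers) and 1.5 / 1.05 / 1.2
centrally — the sublaminae bordering the gaps are boosted to compensate
the gap tails, so the five rendered sublayers show comparable contrast.
The local coordinate is

    d_local = d − δ(x, y) · sin(π d),

i.e. the whole sublamination undulates laterally as one rigid pattern,
pinned at both IPL interfaces. δ is dominated by a deterministic local tilt
(`undulation_slope_per_um` = 0.005 depth/µm, random orientation and small
random offset per scene) plus a weak smooth random field (sd 0.02,
correlation 10 µm). The tilt is the generator's mechanism for the
scale-dependent appearance of the strata: the within-window spread of
δ grows linearly with the lateral averaging window (g·w/√12, independent
of tilt orientation), so a 20-µm window resolves all five sublaminae while
a 60-µm window smears them into the three coarse strata separated by the
two laterally coherent gaps. A purely random undulation field cannot
reproduce this reliably — a 60-µm window holds only a handful of
correlation cells, and the realization noise of the smearing lands exactly
at the detection threshold — whereas the tilt yields the cutoff
deterministically. Physically it corresponds to the sublamination running
at a small angle (~0.2 µm of depth per µm laterally, about 10°) to the
segmentation surface, as in a gently curved wholemount.

**Channels and optics.** `shg` carries everything above; `gfp` carries the
colabeled (GUS-like) axon subset; `chat` carries lateral fluorescence bands
at `band_depths` (default 0.25 and 0.62, σ 0.04 depth ≈ 1.4 µm).
`OpticsParams` defaults: voxel (1.0, 0.5, 0.5) µm — finer axially than the
2–3 µm acquisition so terminal-depth recovery is testable; Gaussian PSF
with 1.5 µm axial FWHM (the instrument's axial resolution) and 0.3 µm
lateral σ; 30 photons per emission unit (peak axon SNR ≈ 8–20); Gaussian
read noise (sd 2); quantization to 16 bits. `neuropil_profile_truth` is the
ensemble-mean axial profile (lamination averaged over the marginal δ
distribution) and is what rendered whole-field profiles converge to.

What the generator does **not** emulate: axon coalescence in the INL
interstitia, branching terminals, Müller-cell or photoreceptor structure,
polarization and excitation-wavelength physics, tissue curvature of the
layer *boundaries* (only the sublamination tilts; boundaries stay flat).
Passing recovery tests therefore demonstrates the measurement machinery,
not performance on curved or aberrated real tissue.

## Layer segmentation

The laterally averaged axial profile is smoothed (Gaussian, σ = 1 z-step)
and its bright bands found by peak detection (prominence ≥ 20% of range).
The IPL is the **widest** band, the OPL the next band on its scleral side;
bands vitreal of the IPL (the RNFL) are ignored. Each interface is the
half-prominence crossing of its band, interpolated to sub-plane precision —
a convention that is invariant to the intensity scale. Fewer than two
bands raises a loud error carrying the diagnostic profile. On rendered
scenes the four boundaries land within ~1 µm of truth (RMSE ≤ 2 µm over
the test bank). The residual bias (≈ +0.4 µm at the IPL/INL interface)
propagates into depth-normalized readouts; recovered ChAT-band depths are
26.5–27 instead of 25 depth-percent, within the 3-point tolerance used
throughout.

## Tracing

Per plane, fiber cross-sections are detected with a scale-normalized
Laplacian-of-Gaussian (σ 0.25 µm, finer than the PSF, on a 2× cubically
upsampled grid) and localized to sub-pixel precision by quadratic
interpolation; the response threshold (18 photon units ≈ 5 σ of the shot
noise) keeps the noise floor silent. Linking proceeds plane by plane from
the INL side toward the GCL, so the far end of a trace is the axon
terminal. Each plane pair is matched by the exact assignment (Hungarian)
that maximizes the number of links within the gate and then minimizes
total displacement, with a penalty on relative intensity jumps and
deterministic tie-breaks. Defaults: gate 1.5 µm per µm of z step, gaps up
to 3 planes bridged by linear interpolation with a sublinear (√gap) gate,
minimum trace length 5 planes. Three safeguards address the crowded
terminal zone: (i) a track whose trailing detections have faded below 60%
of its median intensity is treated as terminated — its SHG-dark terminal
has been reached — and is not bridged or jump-extended; (ii) an unmatched
healthy track adjacent (≤ 0.8 µm) to a detection shares it, so two fibers
merged below the resolution both survive the merge; (iii) trailing runs of
sub-background points (beyond the 2-plane physiological taper) are trimmed.
These linking-policy choices were set during development against the
synthetic study conditions; the per-pair matcher is verified against
exhaustive enumeration on small instances.

**Accuracy.** On default-density scenes (42,500/mm²), trace-level recall
is ≥ 0.99 and precision 0.92–0.96 (match = mean lateral distance < 2 µm).
The terminal-depth error of correctly associated traces is ~1.1 µm RMS
with a small negative bias (~0.3 µm, the taper), within the 1.5 µm axial
resolution. However 4–6% of matched traces carry association errors
(breaks or switches at sub-resolution merges, 5–25 µm), which dominate the
non-robust cohort RMSE (~3 µm). This is an intrinsic consequence of the
fiber density: the mean nearest-neighbor spacing (2.4 µm) is only ~3× the
effective lateral resolution (0.42 µm), so ~6% of fibers are in a merged
state in any plane.

## Census statistics

N(d) counts traces whose depth extent crosses d, per unit area (bins of
0.02 depth over [−0.1, 1]). The terminal distribution is
T = −ΔN/Δd on the staggered grid of bin-center midpoints, so the
unsmoothed first difference satisfies the discrete conservation identity
Σ T_raw Δd = N(first) − N(last) exactly; optional Savitzky–Golay smoothing
(order 2, window 5 bins) precedes the difference. Negative raw values
(tracing noise) are kept in `T_raw` and clipped in `T`. The recovered peak
density averages 95–96% of truth (the residual loss is fibers merged since
their first plane, which never spawn a second track); at 42,500/mm² truth
the pipeline reports ≈ 40,800/mm². The acceptance protocol averages eight
100×100 µm fields (0.08 mm²) so the Poisson draw of the per-field axon
count (sd 5%) does not dominate the estimate.

Subtype classification uses half-open depth bins [0, 0.4), [0.4, 0.8),
[0.8, 1] → OFF / ON / rod; a depth exactly on a cut falls in the deeper
bin. The intensity mixture model is a hand-written 1D EM (seeded random
restarts, n_init 5; variance floor 1e-6; empty components pruned with a
warning; the log-likelihood is audited for monotonicity every iteration)
with BIC selection over k = 1…6; it is cross-checked against
scikit-learn's GaussianMixture in the test suite. Intensities are fit on
the log scale, where the three caliber classes are near-Gaussian.
Co-localization samples the fluorescence channel in a 0.6-µm disc at each
trace's position in the plane nearest d = 0; the default threshold is Otsu
over the per-trace samples (alternative: k× the plane's median background,
falling back to the mean when the median is zero). The tight disc matters:
at bipolar densities a 1.5-µm disc picks up bleed from colabeled
neighbors and costs ~4 points of flag accuracy.

## Strata and bands

Axial profiles restricted to the IPL are resampled onto a fixed 101-point
depth grid so stacks with different z steps are comparable. Gaps are
prominent minima (≥ 10% of the profile range, ≥ 0.08 depth apart — the
paper states no threshold; 10% is this package's default), strata count =
gaps + 1, and fluorescence bands are profile maxima with quadratic
refinement. All detected depths are invariant to a global intensity scale.

## Dynamics

Intensity decay is modelled as I(t) = c + I0·exp(−k t), fitted by bounded
nonlinear least squares initialized from a log-linear fit; published decay
curves come without a stated functional form, so the exponential-plus-
offset model is this package's choice. Non-convergence is flagged with a
NaN rate, never silent. Kymographs stack per-time axial profiles; the
vitreal tissue boundary is tracked by the half-max crossing of each row
(sub-voxel, offset- and scale-invariant) and swelling onset is the first
time its cumulative displacement reaches the threshold.

## Group metrics and comparison

Per retina: RNFL bundle thickness (half-prominence axial extent of the
GCL-side band, 0 when no band rises above 10% prominence), IPL thickness
(from the layer model), mean IPL neuropil intensity excluding traced-axon
voxels dilated by 1 µm (so the amacrine-derived neuropil dominates), the
terminal distribution and subtype counts. Groups are compared with an
exact (fully enumerated, midrank-tied) two-sided Wilcoxon rank-sum test —
appropriate at the study's group sizes of a few retinas — plus Cliff's
delta; no multiplicity correction, since each call is a single planned
comparison. Note that a *pure amplitude* reduction of the nerve-fiber band
cannot lower a half-prominence width, so the synthetic injury scenes thin
the band along with dimming it (axon loss does both); this realizes the
expected injury pattern — thinner bundles, intact IPL.

## Reproducibility and problem sizes

All randomness flows through explicit integer seeds; scenes, renders and
the whole pipeline are bitwise deterministic given (parameters, seed). The
CLI fans a single global seed into per-stage child seeds via
`numpy.random.SeedSequence`. The test suite uses banks of 10 default
128×128 µm scenes and 8 traced 100×100 µm fields; recovery statistics in
the tests are pooled over those banks. The acceptance script uses 8 fields
for the density estimate, 10 scenes for the strata-count majorities and
one scene for the band depths.

## Known limitations

* The cohort terminal-depth RMSE target (≤ 1.5 µm) is not met at the
  full study density: association errors of a few percent dominate the
  unrobust RMSE even though the per-axon measurement error (~1.1 µm RMS)
  is within the axial resolution. Resolving this would need joint
  multi-fiber model fitting rather than detect-then-link tracing.
* Layer boundaries are planes, not surfaces; tilted or curved retinas must
  be handled by lateral tiling.
* The segmentation's small outward bias at the IPL/INL interface shifts
  depth-normalized readouts by ~1.5–2 depth-percent.
* Subtype labels are depth bins; molecular identity is only available as
  the co-label flag.
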