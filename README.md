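# shgretina

Quantification of the inner retina's axonal architecture from label-free
second-harmonic-generation (SHG) microscopy, with a synthetic-scene
simulator for end-to-end validation.

SHG is emitted by uniformly polarized axonal microtubules, so a fresh,
unlabeled wholemount retina images as: bright plexiform layers (IPL, OPL)
between dark nuclear layers; vertical bipolar-cell axons crossing the INL
and terminating at subtype-specific IPL depths; a diffuse, axially
stratified IPL neuropil carried by axon-bearing amacrine cells; and the
nerve-fiber bundles of the ganglion cells. This package turns such
z-stacks into the standard quantitative read-outs:

* **Layer segmentation** — the four interfaces (GCL/IPL, IPL/INL, INL/OPL,
  OPL/ONL) from the axial intensity profile, and the normalized IPL depth
  `d = (z_IPL/INL − z)/T_IPL` (0 at the IPL/INL interface, 1 at GCL/IPL).
* **3D vertical-axon tracing** — per-plane Laplacian-of-Gaussian detection
  linked across planes by optimal assignment (single-particle-tracking
  style), with gap bridging and merge handling.
* **Axon census** — the areal density profile N(d) (axons/mm² crossing
  depth d) and the terminal distribution T(d) = −dN/dd, whose maxima
  reveal the IPL sublaminae; depth-bin classification into OFF / ON / rod
  bipolar types; co-localization with a fluorescence co-label channel; and
  a maximum-likelihood Gaussian-mixture model (EM + BIC) of terminal-zone
  intensities, which scale as caliber².
* **Strata analysis** — IPL neuropil profiles over configurable lateral
  windows on a fixed 101-point depth grid; strata/gap detection;
  fluorescence-band localization (ChAT bands at ~25% and 62% depth).
* **Dynamics** — exponential decay fits I(t) = c + I₀e^(−kt) for
  pharmacological/photobleaching series, and kymograph-based detection of
  axial tissue swelling.
* **Group comparison** — per-retina morphometrics (nerve-fiber bundle
  thickness, IPL thickness, neuropil intensity, terminal distributions)
  compared with an exact Wilcoxon rank-sum test and Cliff's delta, suited
  to group sizes of a few retinas.

Because no public SHG retina stacks exist, the package ships a first-class
synthetic-scene module (`shgretina.synthetic_scene`) whose defaults encode
the study conditions — 42,500 axons/mm², five terminal sublaminae, three
axon-caliber classes, two intra-IPL gaps at depths 0.25/0.62, a 1.5-µm
axial PSF — so every stage is tested by parameter recovery. See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from shgretina import (SceneParams, OpticsParams, generate_scene,
                       render_volume, segment_layers, trace_volume,
                       axon_density_profile, terminal_distribution,
                       detect_peaks1d)

scene = generate_scene(SceneParams(field_size_um=(100.0, 100.0), seed=1))
volume = render_volume(scene, OpticsParams(), channels=("shg",), seed=2001)

layers = segment_layers(volume, "shg")
print({k: round(float(v), 1) for k, v in layers.boundaries_z_um.items()})

traces = trace_volume(volume, "shg", layers)
density = axon_density_profile(traces, layers, field_area_mm2=0.01)
n0 = density.N[np.argmin(np.abs(density.bin_centers))]
print(f"{len(traces)} traces; density at zero IPL depth: {n0:.0f}/mm^2")

tdist = terminal_distribution(density, smoothing_window=5)
peaks, _ = detect_peaks1d(tdist.T, x=tdist.depth_bins, min_separation=0.08)
print("terminal peaks at depths:", np.round(peaks, 2))
```

Output:

```
{'GCL/IPL': 18.8, 'IPL/INL': 54.6, 'INL/OPL': 78.8, 'OPL/ONL': 86.2}
463 traces; density at zero IPL depth: 40100/mm^2
terminal peaks at depths: [0.1  0.31 0.51 0.66 0.93]
```

The segmented boundaries land within ~1 µm of the generator's truth
(18 / 54 / 79 / 87 µm); the recovered peak density sits in the published
40,000–45,000 axons/mm² band for a 42,500/mm² ground truth; and the
terminal distribution resolves the five sublaminae the scene was built
with.

A command-line pipeline wraps the same functions:

```
shgretina run --seed 7 --out results/ --stages simulate,segment,trace,census
```

Each run writes the effective config (and its hash, stamped into every
output file), an OME-TIFF volume, SWC/CSV traces, census CSVs and JSON
reports; reruns with the same config and seed are bitwise identical.

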