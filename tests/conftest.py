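"""Shared fixtures: synthetic scenes rendered once per session.

Rendering is the expensive step, so the fixtures below are session-scoped
and shared between the module tests and the acceptance tests. All seeds
are fixed constants; every test in the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from shgretina.layer_segmentation import segment_layers
from shgretina.neurite_tracing import trace_volume
from shgretina.synthetic_scene import (OpticsParams, SceneParams,
                                       generate_scene, render_volume)

#: seeds for the default-scene render bank (strata statistics, boundaries)
RENDER_SEEDS = tuple(range(1, 11))

#: seeds for the census-field bank (100x100 µm, traced)
FIELD_SEEDS = (1, 2, 3, 4, 5, 6, 7, 8)


@pytest.fixture(scope="session")
def default_render_bank():
    """Ten renders of the default 128x128 µm scene (SHG channel only)."""
    bank = []
    for seed in RENDER_SEEDS:
        scene = generate_scene(SceneParams(seed=seed))
        vol = render_volume(scene, OpticsParams(), channels=("shg",), seed=1000 + seed)
        lm = segment_layers(vol, "shg")
        bank.append((scene, vol, lm))
    return bank


@pytest.fixture(scope="session")
def census_field_bank():
    """Three traced 100x100 µm fields at the study density, all channels."""
    bank = []
    for seed in FIELD_SEEDS:
        scene = generate_scene(SceneParams(field_size_um=(100.0, 100.0), seed=seed))
        vol = render_volume(scene, OpticsParams(), channels=("shg", "gfp", "chat"),
                            seed=2000 + seed)
        lm = segment_layers(vol, "shg")
        traces = trace_volume(vol, "shg", lm)
        bank.append((scene, vol, lm, traces))
    return bank


def lm_from_truth(scene):
    """LayerModel taken from the generator's ground truth (for constructed
    scenes whose profiles do not satisfy the two-bright-band assumption)."""
    from shgretina.layer_segmentation import LayerModel
    b = scene.layer_boundaries_truth
    return LayerModel(boundaries_z_um={k: b[k] for k in
                                       ("GCL/IPL", "IPL/INL", "INL/OPL", "OPL/ONL")})


@pytest.fixture(scope="session")
def single_axon_factory():
    """Scenes containing exactly one straight vertical axon."""

    def make(caliber_um=0.8, terminal_depth=0.8, caliber_ramp=0.0,
             terminal_taper_um=0.0, **scene_kw):
        params = SceneParams(
            field_size_um=(24.0, 24.0),
            axon_density_per_mm2=0.0,
            tortuosity_um=0.0,
            caliber_ramp=caliber_ramp,
            terminal_taper_um=terminal_taper_um,
            neuropil_amplitude=0.0,
            opl_amplitude=0.4,
            rnfl_amplitude=0.0,
            nuclear_background=0.0,
            seed=0,
            **scene_kw,
        )
        scene = generate_scene(params)
        z_entry = params.layer_boundaries_um()["INL/OPL"]
        z_term = float(params.depth_to_z(terminal_depth))
        n = int(round((z_entry - z_term) / 0.5)) + 1
        z = np.linspace(z_entry, z_term, n)
        path = np.column_stack([z, np.full(n, 12.0), np.full(n, 12.0)])
        from shgretina.synthetic_scene import AxonSpec
        scene.axons = [AxonSpec(id=0, entry_xy_um=(12.0, 12.0),
                                terminal_depth=terminal_depth,
                                caliber_um=caliber_um, subtype="test",
                                colabeled=True, path=path)]
        return scene

    return make
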