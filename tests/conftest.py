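"""Shared fixtures: coarse geometry and leadfield for fast solver tests."""

from __future__ import annotations

import numpy as np
import pytest

from cuffsim import forward as fwd
from cuffsim import geometry as geo
from cuffsim import simulate as sim


@pytest.fixture(scope="session")
def layout() -> geo.ElectrodeLayout:
    return geo.build_fine_electrode()


@pytest.fixture(scope="session")
def tiny_cross_section() -> geo.CrossSectionModel:
    """Coarse 3-fascicle slice (0.3 mm pixels) for fast forward solves."""
    return geo.synthesize_cross_section(
        seed=3,
        n_fascicles=3,
        pixel_pitch=0.3,
        fascicle_radius_range=(0.35, 0.45),
        min_centroid_separation=2.0,
    )


@pytest.fixture(scope="session")
def tiny_volume(tiny_cross_section, layout) -> geo.NerveVolume:
    return geo.extrude_volume(
        tiny_cross_section, layout, axial_length=20.0, axial_pitch=2.0
    )


@pytest.fixture(scope="session")
def tiny_problem(tiny_volume) -> fwd.VoxelForwardProblem:
    return fwd.VoxelForwardProblem(tiny_volume, tolerance=1e-10)


@pytest.fixture(scope="session")
def tiny_leadfield_raw(tiny_problem, layout) -> fwd.Leadfield:
    """Monopolar (unreferenced) leadfield on the coarse fixture."""
    return fwd.build_leadfield(tiny_problem, layout, montage=False)


@pytest.fixture(scope="session")
def tiny_leadfield(tiny_leadfield_raw) -> fwd.Leadfield:
    """Tripolar-referenced leadfield on the coarse fixture."""
    return tiny_leadfield_raw.with_montage()


@pytest.fixture(scope="session")
def small_bank() -> sim.WaveformBank:
    return sim.generate_waveform_bank(seed=11, n_templates=50)


@pytest.fixture(scope="session")
def homogeneous_problem() -> fwd.VoxelForwardProblem:
    """All-saline 61^3 grid at 1 mm pitch (analytic point-source checks)."""
    n = 61
    cs = geo.CrossSectionModel(
        label_image=np.zeros((n, n), dtype=np.uint8),
        fascicle_ids=np.zeros((n, n), dtype=np.int32),
        pixel_pitch=1.0,
        fascicle_centroids=[],
    )
    vol = geo.NerveVolume(
        label_grid=np.zeros((n, n, n), dtype=np.uint8),
        voxel_pitch=(1.0, 1.0, 1.0),
        layout=geo.build_fine_electrode(),
        cross_section=cs,
    )
    return fwd.VoxelForwardProblem(vol, tolerance=1e-10)
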