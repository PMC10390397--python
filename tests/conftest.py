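"""Shared fixtures: attenuation model, small phantoms and scout geometry.

Everything is generated programmatically; expensive objects are
session-scoped so the suite builds each of them once.
"""

import numpy as np
import pytest

from sdexa.attenuation import AttenuationModel
from sdexa.phantom import (
    LabeledVolume,
    PhantomSpec,
    ScoutAcquisition,
    build_phantom,
    default_vertebra_stack,
    label_value,
    simulate_scout,
)
from sdexa.projector import ScoutGeometry


@pytest.fixture(scope="session")
def model():
    return AttenuationModel.from_tabulation()


@pytest.fixture(scope="session")
def small_geometry():
    # 128 columns and coarse rows keep scout maps ~(21, 128): fast to
    # project and denoise while leaving the fan geometry intact
    return ScoutGeometry(n_columns=128, row_pitch=2.0)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(
        volume_shape=(112, 96, 48),
        vertebrae=default_vertebra_stack(2, vbmd=150.0),
    )


@pytest.fixture(scope="session")
def phantom_volume(phantom_spec):
    return build_phantom(phantom_spec)


@pytest.fixture(scope="session")
def noiseless_scout(phantom_volume, small_geometry, model):
    return simulate_scout(
        phantom_volume, small_geometry, ScoutAcquisition(seed=0), model, noiseless=True
    )


@pytest.fixture(scope="session")
def noisy_scout(phantom_volume, small_geometry, model):
    return simulate_scout(phantom_volume, small_geometry, ScoutAcquisition(seed=3), model)


@pytest.fixture(scope="session")
def body_only_volume():
    """Soft tissue only: for homogeneous-ROI noise studies."""
    spec = PhantomSpec(volume_shape=(112, 96, 32), vertebrae=())
    return build_phantom(spec)


@pytest.fixture(scope="session")
def slab_volume():
    """3 cm slab of 150 mg/mL hydroxyapatite inside a water box.

    The analytic areal density through the slab is 0.150 g/mL x 3 cm =
    0.45 g/cm^2.
    """
    shape = (60, 60, 24)
    spacing = (2.0, 2.0, 2.0)
    water = np.full(shape, 1.0)
    ha = np.zeros(shape)
    labels = np.ones(shape, dtype=np.int16)  # soft tissue
    lv = label_value("L1", "trabecular")
    # slab: 15 voxels (30 mm) thick along y, generous x/z extent
    sl = np.s_[10:50, 22:37, 4:20]
    ha[sl] = 150.0
    labels[sl] = lv
    return LabeledVolume(
        water_density=water,
        hydroxyapatite_density=ha,
        labels=labels,
        voxel_spacing=spacing,
        label_names={"trabecular_L1": lv},
    )


def siddon_trace(volume, spacing, src, direction, eps=1e-12):
    """Exact voxel-intersection line integral (value * mm) — the
    independent ray-tracing oracle."""
    shape = np.asarray(volume.shape)
    spacing = np.asarray(spacing, float)
    half = shape * spacing / 2.0
    tmins, tmaxs = [], []
    for ax in range(3):
        if abs(direction[ax]) < eps:
            if abs(src[ax]) > half[ax]:
                return 0.0
        else:
            t1 = (-half[ax] - src[ax]) / direction[ax]
            t2 = (half[ax] - src[ax]) / direction[ax]
            tmins.append(min(t1, t2))
            tmaxs.append(max(t1, t2))
    t0, t1 = max(tmins), min(tmaxs)
    if t1 <= t0:
        return 0.0
    ts = [t0, t1]
    for ax in range(3):
        if abs(direction[ax]) < eps:
            continue
        bounds = -half[ax] + spacing[ax] * np.arange(shape[ax] + 1)
        tt = (bounds - src[ax]) / direction[ax]
        ts += [t for t in tt if t0 < t < t1]
    ts = np.unique(np.asarray(ts))
    total = 0.0
    for a, b in zip(ts[:-1], ts[1:]):
        mid = src + (a + b) / 2 * direction
        idx = np.floor(mid / spacing + shape / 2).astype(int)
        if np.all(idx >= 0) and np.all(idx < shape):
            total += volume[tuple(idx)] * (b - a)
    return total
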