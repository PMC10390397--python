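"""Digital lumbar-spine phantom and dual-energy acquisition simulation.

The phantom is an abdomen-like soft-tissue ellipse containing up to four
lumbar vertebrae (L1-L4).  Each vertebra is a cylindrical body with a dense
cortical shell, a trabecular core (the quantification target) and a
posterior spinous-process block — the block is what makes AP and lateral
projections genuinely different, since it overlaps the vertebral body in
the AP ray path only.

Two acquisitions are simulated:

* virtual monoenergetic CT volumes at 50 and 200 keV (the input to
  image-domain material decomposition, which yields volumetric BMD);
* a low-dose two-channel spectral scout with Poisson counting noise, whose
  projection-domain decomposition produces the characteristic
  anticorrelated photoelectric/Compton noise that the denoiser targets.

The dual-layer detector response is modelled as two effective
monoenergetic channels (default 55 and 75 keV) with independent Poisson
counts — enough to reproduce the anticorrelation phenomenology without a
proprietary spectral response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .attenuation import AttenuationModel
from .decomp import SpectralProjectionPair, SpectralVolumePair
from .projector import MM_PER_CM, ScoutGeometry, forward_project
from .quantify import classify_status

__all__ = [
    "PhantomSpec",
    "VertebraSpec",
    "LabeledVolume",
    "ScoutAcquisition",
    "CohortMember",
    "default_vertebra_stack",
    "build_phantom",
    "simulate_monoenergetic",
    "simulate_scout",
    "generate_cohort",
    "label_value",
]

VERTEBRA_NAMES = ("L1", "L2", "L3", "L4")
LABEL_BACKGROUND = 0
LABEL_SOFT_TISSUE = 1
_COMPARTMENTS = ("trabecular", "cortical", "spinous")

#: expected photons per detector pixel in air.  Chosen so that the raw
#: photoelectric EPL map of an abdomen-sized phantom has a soft-tissue
#: SNR of about 5, the regime of a 30 mA clinical scout.
DEFAULT_FLUENCE = 1.7e4
DEFAULT_CHANNEL_ENERGIES = (55.0, 75.0)


def label_value(vertebra: str, compartment: str) -> int:
    """Integer label for one vertebra compartment, e.g. ('L2','cortical')."""
    k = VERTEBRA_NAMES.index(vertebra)
    c = _COMPARTMENTS.index(compartment)
    return 10 * (k + 1) + 1 + c


def label_dictionary(vertebrae) -> dict:
    d = {"background": LABEL_BACKGROUND, "soft_tissue": LABEL_SOFT_TISSUE}
    for v in vertebrae:
        for c in _COMPARTMENTS:
            d[f"{c}_{v.label}"] = label_value(v.label, c)
    return d


class PhantomError(ValueError):
    """Raised when a phantom specification violates its contracts."""


@dataclass(frozen=True)
class VertebraSpec:
    """Geometry and mineral content of one vertebra.

    Densities are hydroxyapatite concentrations in mg/mL; lengths in mm.
    """

    label: str
    center: tuple  # (x, y, z) mm
    body_radius: float = 17.0
    body_height: float = 27.0
    cortical_thickness: float = 2.5
    trabecular_hydroxyapatite: float = 120.0
    cortical_hydroxyapatite: float = 600.0
    spinous_process_length: float = 30.0
    spinous_hydroxyapatite: float = 350.0
    spinous_width: float = 10.0

    def __post_init__(self):
        if self.label not in VERTEBRA_NAMES:
            raise PhantomError(f"vertebra label {self.label!r} not one of {VERTEBRA_NAMES}")
        if not 0.0 <= self.trabecular_hydroxyapatite <= 400.0:
            raise PhantomError("trabecular hydroxyapatite must lie in [0, 400] mg/mL")
        if self.cortical_hydroxyapatite < self.trabecular_hydroxyapatite:
            raise PhantomError("cortical hydroxyapatite must be >= trabecular")
        if not self.body_radius > self.cortical_thickness > 0.0:
            raise PhantomError("need body_radius > cortical_thickness > 0")

    @property
    def z_extent(self) -> tuple:
        return (self.center[2] - self.body_height / 2, self.center[2] + self.body_height / 2)


@dataclass(frozen=True)
class PhantomSpec:
    """Digital phantom description: body ellipse plus vertebrae."""

    volume_shape: tuple = (112, 96, 80)
    voxel_spacing: tuple = (2.0, 2.0, 2.0)  # mm
    body_ellipse: tuple = (110.0, 80.0)  # semi-axes, mm
    soft_tissue_density: float = 1.0  # g/mL water-equivalent
    vertebrae: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if any(s < 16 for s in self.volume_shape):
            raise PhantomError("volume_shape components must all be >= 16")
        if any(s <= 0 for s in self.voxel_spacing):
            raise PhantomError("voxel_spacing must be positive")
        if not 0.8 < self.soft_tissue_density < 1.2:
            raise PhantomError("soft_tissue_density must lie in (0.8, 1.2) g/mL")
        if len(self.vertebrae) > 4:
            raise PhantomError("at most 4 vertebrae supported")
        labels = [v.label for v in self.vertebrae]
        if len(set(labels)) != len(labels):
            raise PhantomError("duplicate vertebra labels")
        # non-overlapping extents: conservative bounding-box test in z and xy
        for i, a in enumerate(self.vertebrae):
            for b in self.vertebrae[i + 1 :]:
                z_sep = abs(a.center[2] - b.center[2])
                if z_sep < (a.body_height + b.body_height) / 2:
                    xy = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                    if xy < a.body_radius + b.body_radius:
                        raise PhantomError(
                            f"vertebrae {a.label} and {b.label} overlap "
                            f"(z separation {z_sep:.1f} mm)"
                        )


@dataclass
class LabeledVolume:
    """Ground-truth phantom rasterisation.

    ``water_density`` in g/mL, ``hydroxyapatite_density`` in mg/mL, and an
    integer compartment label map, all on the same grid.
    """

    water_density: np.ndarray
    hydroxyapatite_density: np.ndarray
    labels: np.ndarray
    voxel_spacing: tuple
    label_names: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (
            self.water_density.shape
            == self.hydroxyapatite_density.shape
            == self.labels.shape
        ):
            raise PhantomError("LabeledVolume grids must share one shape")
        if np.any(self.hydroxyapatite_density < 0):
            raise PhantomError("hydroxyapatite density must be non-negative")
        bone_free = np.isin(self.labels, (LABEL_BACKGROUND, LABEL_SOFT_TISSUE))
        if np.any(self.hydroxyapatite_density[bone_free] != 0):
            raise PhantomError("hydroxyapatite must be zero outside bone labels")

    @property
    def shape(self):
        return self.labels.shape


@dataclass(frozen=True)
class ScoutAcquisition:
    """Two-channel scout acquisition settings."""

    channel_energies: tuple = DEFAULT_CHANNEL_ENERGIES  # keV (low, high)
    fluence_per_pixel: float = DEFAULT_FLUENCE
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.channel_energies
        if not (30.0 < lo < hi < 120.0):
            raise PhantomError("channel energies must satisfy 30 < low < high < 120 keV")
        if self.fluence_per_pixel <= 0:
            raise PhantomError("fluence must be positive")


# --------------------------------------------------------------------- #
# rasterisation


def _world_axes(shape, spacing):
    return tuple(
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    )


def build_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Voxelise a phantom specification.

    Deterministic given the spec: geometry carries no randomness (the seed
    field is reserved for optional texture).  Raises :class:`PhantomError`
    when vertebrae overlap or extend outside the body ellipse.
    """
    nx, ny, nz = spec.volume_shape
    x, y, z = _world_axes(spec.volume_shape, spec.voxel_spacing)
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]

    a, b = spec.body_ellipse
    body = np.broadcast_to((X / a) ** 2 + (Y / b) ** 2 <= 1.0, spec.volume_shape)

    labels = np.where(body, LABEL_SOFT_TISSUE, LABEL_BACKGROUND).astype(np.int16)
    water = np.where(labels == LABEL_SOFT_TISSUE, spec.soft_tissue_density, 0.0)
    ha = np.zeros(spec.volume_shape)

    for v in spec.vertebrae:
        cx, cy, cz = v.center
        r = np.hypot(X - cx, Y - cy)
        in_z = np.abs(Z - cz) <= v.body_height / 2.0
        cyl = (r <= v.body_radius) & in_z
        core = (r <= v.body_radius - v.cortical_thickness) & in_z
        shell = cyl & ~core
        spin = (
            (np.abs(X - cx) <= v.spinous_width / 2.0)
            & (Y >= cy + v.body_radius)
            & (Y <= cy + v.body_radius + v.spinous_process_length)
            & (np.abs(Z - cz) <= 0.3 * v.body_height)
        )
        for region, comp, dens in (
            (core, "trabecular", v.trabecular_hydroxyapatite),
            (shell, "cortical", v.cortical_hydroxyapatite),
            (spin, "spinous", v.spinous_hydroxyapatite),
        ):
            if region.any() and not body[region].all():
                raise PhantomError(
                    f"{comp} compartment of {v.label} extends outside the body ellipse"
                )
            if np.any(labels[region] >= 10):
                raise PhantomError(
                    f"vertebra {v.label} overlaps a previously placed structure"
                )
            labels[region] = label_value(v.label, comp)
            ha[region] = dens
            water[region] = spec.soft_tissue_density  # marrow/water component

    return LabeledVolume(
        water_density=water,
        hydroxyapatite_density=ha,
        labels=labels,
        voxel_spacing=spec.voxel_spacing,
        label_names=label_dictionary(spec.vertebrae),
    )


# --------------------------------------------------------------------- #
# acquisitions


def simulate_monoenergetic(
    volume: LabeledVolume,
    model: AttenuationModel,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> SpectralVolumePair:
    """Virtual monoenergetic volumes at 50 and 200 keV.

    mu_E = (mu/rho)_water(E) * rho_water + (mu/rho)_bone(E) * rho_bone,
    with densities in g/mL and mu in 1/cm.  Optional zero-mean Gaussian
    noise of standard deviation ``noise_sigma`` (1/cm) is added
    independently per volume.
    """
    rho_w = volume.water_density
    rho_b = volume.hydroxyapatite_density / 1000.0  # mg/mL -> g/mL
    mus = {}
    for e in (50.0, 200.0):
        mus[e] = model.mass_attenuation("water", e) * rho_w + model.mass_attenuation(
            "hydroxyapatite", e
        ) * rho_b
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        for e in mus:
            mus[e] = mus[e] + rng.normal(0.0, noise_sigma, size=mus[e].shape)
    return SpectralVolumePair(mu_50=mus[50.0], mu_200=mus[200.0], voxel_spacing=volume.voxel_spacing)


def simulate_scout(
    volume: LabeledVolume,
    geometry: ScoutGeometry,
    acq: ScoutAcquisition,
    model: AttenuationModel,
    noiseless: bool = False,
) -> SpectralProjectionPair:
    """Two-channel spectral scout with projection-domain decomposition.

    For every detector pixel the water and hydroxyapatite areal densities
    are ray-traced, converted to channel line integrals through the fitted
    photoelectric/Klein-Nishina basis, corrupted with Poisson counting
    noise (unless ``noiseless``), and decomposed back into photoelectric
    and Compton coefficients expressed as water-equivalent path lengths in
    cm.  Zero counts are clamped to 1 and the clamped fraction recorded in
    the QC block.
    """
    a_w = forward_project(volume.water_density, volume.voxel_spacing, geometry).values
    a_b = forward_project(
        volume.hydroxyapatite_density / 1000.0, volume.voxel_spacing, geometry
    ).values  # g/cm^2

    # basis coefficients of the noiseless object
    pc_true = np.einsum("ij,j...->i...", model.basis_coefficients, np.stack([a_w, a_b]))
    f = model.channel_matrix(acq.channel_energies)  # (2 energies, 2 bases)
    line_int = np.einsum("ej,j...->e...", f, pc_true)

    clamped_fraction = 0.0
    if noiseless:
        l_hat = line_int
    else:
        rng = np.random.default_rng(acq.seed)
        expected = acq.fluence_per_pixel * np.exp(-line_int)
        counts = rng.poisson(expected).astype(float)
        n_clamped = int((counts < 1).sum())
        clamped_fraction = n_clamped / counts.size
        counts = np.maximum(counts, 1.0)
        l_hat = -np.log(counts / acq.fluence_per_pixel)

    pc_hat = np.einsum("ij,j...->i...", np.linalg.inv(f), l_hat)
    w_ph, w_co = model.water_epl_coefficients
    geom_step = geometry.effective_table_step
    return SpectralProjectionPair(
        photoelectric_epl=pc_hat[0] / w_ph,
        compton_epl=pc_hat[1] / w_co,
        pixel_spacing=(geom_step, geometry.column_spacing),
        qc={"clamped_fraction": clamped_fraction, "seed": acq.seed, "noiseless": noiseless},
    )


# --------------------------------------------------------------------- #
# cohort generation


@dataclass
class CohortMember:
    """One synthetic patient: phantom, volumes, scout and ground truth."""

    patient_id: str
    spec: PhantomSpec
    volume: LabeledVolume
    volumes_ct: SpectralVolumePair
    scout: SpectralProjectionPair
    truth: dict


def default_vertebra_stack(
    n_vertebrae: int = 4,
    vbmd: float = 120.0,
    z_pitch: float = 35.0,
    posterior_offset: float = 20.0,
    **overrides,
) -> tuple:
    """A stack of L1..Ln vertebrae centred on the z axis."""
    names = VERTEBRA_NAMES[:n_vertebrae]
    z0 = -(n_vertebrae - 1) / 2.0 * z_pitch
    return tuple(
        VertebraSpec(
            label=name,
            center=(0.0, posterior_offset, z0 + k * z_pitch),
            trabecular_hydroxyapatite=vbmd,
            **overrides,
        )
        for k, name in enumerate(names)
    )


def generate_cohort(
    n: int,
    vbmd_range: tuple,
    geometry: ScoutGeometry,
    acq: ScoutAcquisition,
    seed: int,
    n_vertebrae: int = 4,
    volume_shape: tuple | None = None,
    voxel_spacing: tuple = (2.0, 2.0, 2.0),
    anatomy_jitter: float = 1.0,
    model: AttenuationModel | None = None,
) -> list:
    """Simulate a cohort with a controllable trabecular vBMD distribution.

    Per-patient trabecular vBMD is drawn uniformly over ``vbmd_range``
    (mg/mL); anatomy (body size, vertebra radius, spinous process length
    and mineralisation) is jittered around the defaults, scaled by
    ``anatomy_jitter``.  Ground truth records carry the true vBMD and the
    osteoporosis status from the QCT thresholds (80 / 120 mg/mL).
    """
    if n < 2:
        raise PhantomError("cohort size must be >= 2")
    lo, hi = vbmd_range
    if not (20.0 <= lo <= hi <= 300.0):
        raise PhantomError("vbmd_range must lie within [20, 300] mg/mL")
    model = model or AttenuationModel.from_tabulation()

    rng = np.random.default_rng(seed)
    members = []
    for i in range(n):
        vbmd = float(rng.uniform(lo, hi))
        j = anatomy_jitter
        body = (
            110.0 * (1 + j * rng.uniform(-0.10, 0.10)),
            80.0 * (1 + j * rng.uniform(-0.10, 0.10)),
        )
        vert_kwargs = dict(
            body_radius=17.0 * (1 + j * rng.uniform(-0.10, 0.10)),
            cortical_thickness=2.5 * (1 + j * rng.uniform(-0.15, 0.15)),
            cortical_hydroxyapatite=600.0 * (1 + j * rng.uniform(-0.15, 0.15)),
            spinous_process_length=25.0 * (1 + j * rng.uniform(-0.15, 0.15)),
            spinous_hydroxyapatite=350.0 * (1 + j * rng.uniform(-0.25, 0.25)),
        )
        if volume_shape is None:
            nz = int(np.ceil((n_vertebrae * 35.0 + 20.0) / voxel_spacing[2]))
            volume_shape = (
                int(np.ceil(250.0 / voxel_spacing[0])),
                int(np.ceil(190.0 / voxel_spacing[1])),
                nz,
            )
        spec = PhantomSpec(
            volume_shape=volume_shape,
            voxel_spacing=voxel_spacing,
            body_ellipse=body,
            vertebrae=default_vertebra_stack(n_vertebrae, vbmd=vbmd, **vert_kwargs),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        volume = build_phantom(spec)
        volumes_ct = simulate_monoenergetic(volume, model)
        member_acq = replace(acq, seed=int(rng.integers(0, 2**31 - 1)))
        scout = simulate_scout(volume, geometry, member_acq, model)
        truth = {
            "patient_id": f"P{i:03d}",
            "vbmd_per_vertebra": {v.label: vbmd for v in spec.vertebrae},
            "vbmd": vbmd,
            "status": classify_status(vbmd),
        }
        members.append(
            CohortMember(
                patient_id=truth["patient_id"],
                spec=spec,
                volume=volume,
                volumes_ct=volumes_ct,
                scout=scout,
                truth=truth,
            )
        )
    return members
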