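"""Material decomposition in the image and projection domains.

Image domain: per-voxel solution of the 2x2 linear system relating the
50/200 keV attenuation coefficients to water and hydroxyapatite densities,

    (mu_50, mu_200)^T = A . (rho_water, rho_bone)^T,

where A holds the mass attenuation coefficients of water and bone at the
two energies.  The solve is closed-form (adjugate); conditioning is checked
when the matrix is built.

Projection domain: change of basis from photoelectric/Compton
water-equivalent path lengths to (water, hydroxyapatite) areal densities.
The hydroxyapatite areal density *is* the areal BMD (aBMD) in g/cm^2.  No
soft-tissue correction factor is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attenuation import AttenuationModel

__all__ = [
    "DecompositionMatrix",
    "SpectralVolumePair",
    "MaterialVolumePair",
    "SpectralProjectionPair",
    "ABMDMap",
    "decompose_image_domain",
    "epl_to_abmd",
    "projection_noise_sigma",
    "virtual_monoenergetic_projection",
]


class DecompositionError(ValueError):
    """Raised when a decomposition contract is violated."""


@dataclass
class SpectralVolumePair:
    """Virtual monoenergetic attenuation volumes (1/cm) at 50 and 200 keV."""

    mu_50: np.ndarray
    mu_200: np.ndarray
    voxel_spacing: tuple

    def __post_init__(self):
        if self.mu_50.shape != self.mu_200.shape:
            raise DecompositionError("mu_50 and mu_200 must share one shape")


@dataclass
class MaterialVolumePair:
    """Decomposed density volumes: water in g/mL, hydroxyapatite (the vBMD
    map) in mg/mL.  Negative values from noise are preserved — clipping
    them would bias ROI means — and flagged via ``negative_fraction``."""

    water_density: np.ndarray
    hydroxyapatite_density: np.ndarray
    voxel_spacing: tuple

    def __post_init__(self):
        if self.water_density.shape != self.hydroxyapatite_density.shape:
            raise DecompositionError("material volumes must share one shape")

    @property
    def negative_fraction(self) -> float:
        return float((self.hydroxyapatite_density < 0).mean())


@dataclass
class SpectralProjectionPair:
    """Photoelectric and Compton maps of a spectral scout, expressed as
    water-equivalent path lengths (cm)."""

    photoelectric_epl: np.ndarray
    compton_epl: np.ndarray
    pixel_spacing: tuple
    qc: dict = field(default_factory=dict)

    def __post_init__(self):
        self.photoelectric_epl = np.asarray(self.photoelectric_epl, dtype=float)
        self.compton_epl = np.asarray(self.compton_epl, dtype=float)
        if self.photoelectric_epl.shape != self.compton_epl.shape:
            raise DecompositionError("EPL maps must share one shape")
        if any(s <= 0 for s in self.pixel_spacing):
            raise DecompositionError("pixel_spacing must be positive")

    @property
    def shape(self):
        return self.photoelectric_epl.shape


@dataclass
class ABMDMap:
    """Areal bone mineral density map in g/cm^2."""

    abmd: np.ndarray
    pixel_spacing: tuple
    provenance: str  # measured_scout | projected_AP | projected_lateral
    denoised: bool = False

    _PROVENANCES = ("measured_scout", "projected_AP", "projected_lateral")

    def __post_init__(self):
        self.abmd = np.asarray(self.abmd, dtype=float)
        if not np.all(np.isfinite(self.abmd)):
            raise DecompositionError("aBMD map must be finite everywhere")
        if self.provenance not in self._PROVENANCES:
            raise DecompositionError(
                f"provenance {self.provenance!r} not in {self._PROVENANCES}"
            )


@dataclass
class DecompositionMatrix:
    """2x2 mass-attenuation matrix of the 50/200 keV image-domain system.

    Rows are energies (50, 200 keV), columns materials (water, bone),
    entries in cm^2/g.
    """

    entries: np.ndarray
    energies: tuple = (50.0, 200.0)

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (2, 2):
            raise DecompositionError("decomposition matrix must be 2x2")
        if np.any(self.entries <= 0):
            raise DecompositionError("mass attenuation entries must be positive")
        self.condition_number = float(np.linalg.cond(self.entries))
        if not np.isfinite(self.condition_number) or self.condition_number > 1e6:
            raise DecompositionError(
                f"decomposition matrix ill-conditioned (cond={self.condition_number:.3g})"
            )

    @classmethod
    def from_model(cls, model: AttenuationModel, energies=(50.0, 200.0)) -> "DecompositionMatrix":
        entries = np.array(
            [
                [
                    model.mass_attenuation("water", e),
                    model.mass_attenuation("hydroxyapatite", e),
                ]
                for e in energies
            ]
        )
        return cls(entries=entries, energies=tuple(energies))

    @property
    def inverse(self) -> np.ndarray:
        """Closed-form (adjugate) inverse."""
        (a, b), (c, d) = self.entries
        det = a * d - b * c
        return np.array([[d, -b], [-c, a]]) / det


def decompose_image_domain(
    volumes: SpectralVolumePair, matrix: DecompositionMatrix
) -> MaterialVolumePair:
    """Per-voxel 2x2 solve of the dual-energy system.

    Inputs are attenuation volumes in 1/cm; the water output is in g/mL
    and hydroxyapatite in mg/mL (the conventional vBMD unit).
    """
    inv = matrix.inverse
    rho_w = inv[0, 0] * volumes.mu_50 + inv[0, 1] * volumes.mu_200
    rho_b = inv[1, 0] * volumes.mu_50 + inv[1, 1] * volumes.mu_200
    return MaterialVolumePair(
        water_density=rho_w,
        hydroxyapatite_density=rho_b * 1000.0,
        voxel_spacing=volumes.voxel_spacing,
    )


def _epl_to_basis(projections: SpectralProjectionPair, model: AttenuationModel):
    """Water-equivalent path lengths back to raw (p, c) basis coefficients."""
    w_ph, w_co = model.water_epl_coefficients
    return (
        projections.photoelectric_epl * w_ph,
        projections.compton_epl * w_co,
    )


def epl_to_abmd(
    projections: SpectralProjectionPair,
    model: AttenuationModel,
    provenance: str = "measured_scout",
    denoised: bool = False,
) -> ABMDMap:
    """Projection-domain decomposition of EPL maps into areal BMD.

    Solves the 2x2 basis-coefficient system per pixel for (water,
    hydroxyapatite) areal densities and returns the hydroxyapatite channel
    in g/cm^2.  No soft-tissue correction factor is applied.
    """
    p, c = _epl_to_basis(projections, model)
    m = model.basis_coefficients
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if abs(det) < 1e-12:
        raise DecompositionError("basis coefficient matrix is singular")
    a_b = (m[0, 0] * c - m[1, 0] * p) / det
    return ABMDMap(
        abmd=a_b,
        pixel_spacing=projections.pixel_spacing,
        provenance=provenance,
        denoised=denoised,
    )


def projection_noise_sigma(
    projections: SpectralProjectionPair,
    fluence_per_pixel: float,
    channel_energies,
    model: AttenuationModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel noise standard deviation of the EPL maps.

    First-order propagation of Poisson counting statistics: the variance
    of a measured log line integral is 1/counts = exp(L)/N0, which the
    channel inverse maps into the basis coefficients.  Evaluated from the
    scout's own EPL maps, so it needs no ground truth.

    Returns ``(sigma_photoelectric, sigma_compton)`` in EPL cm.
    """
    if fluence_per_pixel <= 0:
        raise DecompositionError("fluence must be positive")
    p, c = _epl_to_basis(projections, model)
    f = model.channel_matrix(channel_energies)
    line = np.einsum("ej,j...->e...", f, np.stack([p, c]))
    var_l = np.exp(line) / fluence_per_pixel
    finv = np.linalg.inv(f)
    w_ph, w_co = model.water_epl_coefficients
    sigma_p = np.sqrt(finv[0, 0] ** 2 * var_l[0] + finv[0, 1] ** 2 * var_l[1]) / abs(w_ph)
    sigma_c = np.sqrt(finv[1, 0] ** 2 * var_l[0] + finv[1, 1] ** 2 * var_l[1]) / abs(w_co)
    return sigma_p, sigma_c


def virtual_monoenergetic_projection(
    projections: SpectralProjectionPair, energy_kev: float, model: AttenuationModel
) -> np.ndarray:
    """Line-integral map synthesised at a single energy,
    L(E) = p * f_ph(E) + c * f_KN(E)."""
    if not 30.0 <= energy_kev <= 200.0:
        raise DecompositionError("virtual monoenergetic energy must lie in 30-200 keV")
    p, c = _epl_to_basis(projections, model)
    f_ph, f_kn = model.basis_functions(energy_kev)
    return p * f_ph + c * f_kn
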