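"""X-ray attenuation model for dual-energy bone densitometry.

Diagnostic-energy photon attenuation of any (bone, soft-tissue) mixture is
modelled as a linear combination of two physical interaction channels:

* a photoelectric-like basis function ``f_ph(E) = (E / E0)**-3``;
* the Klein-Nishina total cross-section ``f_KN(E)``, normalised to 1 at
  ``E0``.

Material basis coefficients are fitted by least squares to tabulated mass
attenuation values of water and hydroxyapatite over 30-150 keV.  The fitted
2x2 matrix maps areal densities (g/cm^2 of water and hydroxyapatite along a
ray) to photoelectric/Compton line-integral coefficients, and is the single
source of truth for both the scout forward model and the projection-domain
decomposition, making them exact inverses of one another.

Tabulated values are shipped as a versioned JSON data file; hydroxyapatite
is composed from elemental entries with the mixture rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "AttenuationModel",
    "klein_nishina",
    "load_tabulation",
    "photoelectric_basis",
]

_ELECTRON_REST_KEV = 511.0
#: reference energy (keV) at which both basis functions equal 1
DEFAULT_REFERENCE_ENERGY = 30.0
#: energy window (keV) over which material basis coefficients are fitted.
#: 30 keV is excluded: tabulated totals include coherent scattering, which
#: neither basis function represents and which is only appreciable for
#: calcium below ~40 keV; photons that soft are also absent from a filtered
#: diagnostic beam behind a patient.
BASIS_FIT_RANGE = (40.0, 150.0)


def load_tabulation() -> dict:
    """Load the shipped mass-attenuation tabulation (energies in keV,
    coefficients in cm^2/g) and derive the hydroxyapatite column."""
    with resources.files("sdexa.data").joinpath("mass_attenuation.json").open() as fh:
        raw = json.load(fh)
    energies = np.asarray(raw["energies_kev"], dtype=float)
    water = np.asarray(raw["materials"]["water"], dtype=float)
    fractions = raw["hydroxyapatite_mass_fractions"]
    ha = np.zeros_like(energies)
    for element, w in fractions.items():
        ha += w * np.asarray(raw["materials"][element], dtype=float)
    return {"energies": energies, "water": water, "hydroxyapatite": ha}


def photoelectric_basis(energy_kev, reference_kev: float = DEFAULT_REFERENCE_ENERGY):
    """Photoelectric energy dependence, (E/E0)^-3, equal to 1 at E0."""
    e = np.asarray(energy_kev, dtype=float)
    return (e / reference_kev) ** -3.0


def klein_nishina(energy_kev, reference_kev: float | None = DEFAULT_REFERENCE_ENERGY):
    """Klein-Nishina total cross-section as a function of energy.

    When ``reference_kev`` is given the curve is normalised to 1 there.
    """
    a = np.asarray(energy_kev, dtype=float) / _ELECTRON_REST_KEV

    def _kn(alpha):
        t = 1.0 + 2.0 * alpha
        return (
            (1.0 + alpha) / alpha**2 * (2.0 * (1.0 + alpha) / t - np.log(t) / alpha)
            + np.log(t) / (2.0 * alpha)
            - (1.0 + 3.0 * alpha) / t**2
        )

    out = _kn(a)
    if reference_kev is not None:
        out = out / _kn(reference_kev / _ELECTRON_REST_KEV)
    return out


def _loglog_interp(energy, grid, values):
    return np.exp(np.interp(np.log(energy), np.log(grid), np.log(values)))


class AttenuationError(ValueError):
    """Raised when the attenuation model violates its contracts."""


@dataclass
class AttenuationModel:
    """Two-material, two-basis attenuation model.

    Attributes
    ----------
    energies : (n,) array, keV grid of the tabulation.
    water_mass_attenuation, hydroxyapatite_mass_attenuation : (n,) arrays,
        cm^2/g on ``energies``.
    basis_coefficients : (2, 2) array mapping areal densities
        ``(A_water, A_ha)`` in g/cm^2 to ``(photoelectric, Compton)``
        line-integral coefficients; rows = bases, columns = materials.
    reference_energy : keV at which both basis functions equal 1.
    """

    energies: np.ndarray
    water_mass_attenuation: np.ndarray
    hydroxyapatite_mass_attenuation: np.ndarray
    basis_coefficients: np.ndarray
    reference_energy: float = DEFAULT_REFERENCE_ENERGY
    fit_residuals: dict = field(default_factory=dict)

    @classmethod
    def from_tabulation(
        cls, reference_kev: float = DEFAULT_REFERENCE_ENERGY
    ) -> "AttenuationModel":
        tab = load_tabulation()
        energies = tab["energies"]
        lo, hi = BASIS_FIT_RANGE
        sel = (energies >= lo) & (energies <= hi)
        design = np.column_stack(
            [
                photoelectric_basis(energies[sel], reference_kev),
                klein_nishina(energies[sel], reference_kev),
            ]
        )
        coeffs = np.empty((2, 2))
        residuals = {}
        for j, name in enumerate(("water", "hydroxyapatite")):
            mu = tab[name][sel]
            # relative weighting: equalise fractional error across the
            # ~10x dynamic range of the bone cross-section
            c, *_ = np.linalg.lstsq(design / mu[:, None], np.ones_like(mu), rcond=None)
            coeffs[:, j] = c
            rel = np.abs(design @ c - mu) / mu
            residuals[name] = float(rel.max())
            if residuals[name] >= 0.02:
                raise AttenuationError(
                    f"basis fit residual for {name} is {residuals[name]:.3%}, "
                    f"contract requires < 2% over {lo:g}-{hi:g} keV"
                )
        model = cls(
            energies=energies,
            water_mass_attenuation=tab["water"],
            hydroxyapatite_mass_attenuation=tab["hydroxyapatite"],
            basis_coefficients=coeffs,
            reference_energy=reference_kev,
            fit_residuals=residuals,
        )
        cond = np.linalg.cond(coeffs)
        if cond >= 1e6:
            raise AttenuationError(f"basis coefficient matrix condition {cond:.3g} >= 1e6")
        return model

    # ------------------------------------------------------------------ #
    # tabulated (image-domain) attenuation

    def mass_attenuation(self, material: str, energy_kev) -> np.ndarray:
        """Tabulated mass attenuation (cm^2/g), log-log interpolated."""
        table = {
            "water": self.water_mass_attenuation,
            "hydroxyapatite": self.hydroxyapatite_mass_attenuation,
        }[material]
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < self.energies[0]) or np.any(e > self.energies[-1]):
            raise AttenuationError(
                f"energy {e} outside tabulated range "
                f"[{self.energies[0]}, {self.energies[-1]}] keV"
            )
        return _loglog_interp(e, self.energies, table)

    # ------------------------------------------------------------------ #
    # basis-consistent (projection-domain) attenuation

    def basis_functions(self, energy_kev) -> np.ndarray:
        """Stacked (f_ph, f_KN) values at ``energy_kev`` (last axis 2)."""
        return np.stack(
            [
                photoelectric_basis(energy_kev, self.reference_energy),
                klein_nishina(energy_kev, self.reference_energy),
            ],
            axis=-1,
        )

    def channel_mass_attenuation(self, energy_kev) -> np.ndarray:
        """Mass attenuation of (water, hydroxyapatite) at ``energy_kev`` as
        represented by the fitted basis — the values the scout channels see.

        Returns an array of shape ``energy_shape + (2,)``.
        """
        return self.basis_functions(energy_kev) @ self.basis_coefficients

    def channel_matrix(self, energy_pair) -> np.ndarray:
        """2x2 matrix mapping (photoelectric, Compton) coefficients to the
        line integrals measured at the two channel energies."""
        e = np.asarray(energy_pair, dtype=float)
        if e.shape != (2,):
            raise AttenuationError("channel_matrix expects exactly two energies")
        mat = self.basis_functions(e)
        if abs(np.linalg.det(mat)) < 1e-12:
            raise AttenuationError("channel matrix is singular")
        return mat

    @property
    def water_epl_coefficients(self) -> np.ndarray:
        """(photoelectric, Compton) coefficients of 1 cm of water — the
        normalisation that expresses basis coefficients as water-equivalent
        path lengths."""
        return self.basis_coefficients[:, 0].copy()
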