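"""Analytical light propagation in brain tissue.

Irradiance below an optic fiber tip is modeled as the product of two
independent attenuation factors:

* a geometric cone-spread term from the fiber geometry,
  ``rho = r * sqrt((n/NA)^2 - 1)`` and ``I_geom(z) = rho^2 / (z + rho)^2``,
  where ``r`` is the fiber core radius, ``NA`` the numerical aperture and
  ``n`` the tissue refractive index; and
* a Kubelka-Munk-style scattering/absorption term
  ``I_tissue(z, lambda) = exp(-mu_a(lambda) z) / (S(lambda) z + 1)``,
  with scattering coefficient ``S`` and absorption coefficient ``mu_a``
  per wavelength.

Both factors equal 1 at the fiber tip (z = 0) and decrease monotonically
with depth.  Multiplying the depth-dependent transmittance with an opsin
action spectrum gives the wavelength maximizing opsin activation at a given
depth; because scattering falls with wavelength, the optimum red-shifts
with depth.

Default optical constants are order-of-magnitude mouse-cortex values
intended for exploration; quantitative use requires supplying measured
coefficients for the tissue and wavelengths at hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _default_scattering(wavelength_nm):
    """Synthetic default scattering coefficient S(lambda) in mm^-1.

    Power-law decrease with wavelength anchored at ~11 mm^-1 near 470 nm,
    the order of magnitude reported for mouse cortical gray matter.  A
    stand-in parameterization, not a measured spectrum.
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    return 11.2 * (lam / 473.0) ** -1.5


def _default_absorption(wavelength_nm):
    """Synthetic default absorption coefficient mu_a(lambda) in mm^-1
    (small relative to scattering in the visible range)."""
    lam = np.asarray(wavelength_nm, dtype=float)
    return 0.07 * (lam / 473.0) ** -0.5


@dataclass
class TissueOpticsModel:
    """Fiber + tissue parameters for the analytical attenuation model.

    Parameters
    ----------
    fiber_radius_mm : float
        Fiber core radius (default 0.1 mm = 200 um core).
    numerical_aperture : float
    tissue_index : float
        Refractive index of brain tissue.
    scattering_mm : callable or None
        ``S(lambda_nm) -> mm^-1``; None uses the synthetic default.
    absorption_mm : callable or None
        ``mu_a(lambda_nm) -> mm^-1``; None uses the synthetic default.
    """

    fiber_radius_mm: float = 0.1
    numerical_aperture: float = 0.37
    tissue_index: float = 1.36
    scattering_mm: object = None
    absorption_mm: object = None
    variant: str = "cone+kubelka-munk"

    def __post_init__(self):
        for name in ("fiber_radius_mm", "numerical_aperture", "tissue_index"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.numerical_aperture >= self.tissue_index:
            raise ValueError("NA must be < tissue refractive index")
        if self.scattering_mm is None:
            self.scattering_mm = _default_scattering
        if self.absorption_mm is None:
            self.absorption_mm = _default_absorption

    @property
    def rho_mm(self) -> float:
        """Cone-geometry length scale rho = r * sqrt((n/NA)^2 - 1)."""
        n_over_na = self.tissue_index / self.numerical_aperture
        return self.fiber_radius_mm * np.sqrt(n_over_na ** 2 - 1.0)

    def geometric_term(self, z_mm):
        z = np.asarray(z_mm, dtype=float)
        rho = self.rho_mm
        return rho ** 2 / (z + rho) ** 2

    def tissue_term(self, z_mm, wavelength_nm):
        z = np.asarray(z_mm, dtype=float)
        s = self.scattering_mm(wavelength_nm)
        mu_a = self.absorption_mm(wavelength_nm)
        return np.exp(-mu_a * z) / (s * z + 1.0)


@dataclass
class ActionSpectrum:
    """Peak-normalized opsin action spectrum on a wavelength grid."""

    wavelength_nm: np.ndarray
    response: np.ndarray
    opsin: str = ""

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.wavelength_nm.size == 0:
            raise ValueError("empty spectrum")
        if self.wavelength_nm.size != self.response.size:
            raise ValueError("wavelength/response length mismatch")
        if np.any(self.response < 0):
            raise ValueError("responses must be non-negative")
        peak = self.response.max()
        if peak <= 0:
            raise ValueError("spectrum must have a positive peak")
        self.response = self.response / peak

    @classmethod
    def gaussian_standin(cls, peak_nm: float, width_nm: float = 40.0,
                         opsin: str = "synthetic",
                         grid_nm=None) -> "ActionSpectrum":
        """Synthetic unimodal (Gaussian) stand-in spectrum for testing and
        demos; real opsin spectra should be loaded from measured tables."""
        if grid_nm is None:
            grid_nm = np.arange(400.0, 651.0, 1.0)
        grid_nm = np.asarray(grid_nm, dtype=float)
        resp = np.exp(-0.5 * ((grid_nm - peak_nm) / width_nm) ** 2)
        return cls(wavelength_nm=grid_nm, response=resp, opsin=opsin)

    @property
    def peak_wavelength_nm(self) -> float:
        return float(self.wavelength_nm[np.argmax(self.response)])


def fractional_irradiance(model: TissueOpticsModel, z_mm,
                          wavelength_nm) -> np.ndarray | float:
    """Irradiance at depth z as a fraction of the irradiance at the fiber
    tip: geometric cone spread times tissue scattering/absorption.  Equals 1
    at z = 0 and decreases strictly with z."""
    z = np.asarray(z_mm, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be >= 0")
    out = model.geometric_term(z) * model.tissue_term(z, wavelength_nm)
    return float(out) if np.isscalar(z_mm) else out


def lpd_at_depth(model: TissueOpticsModel, exit_lpd_mw_mm2: float, z_mm,
                 wavelength_nm):
    """Light power density (mW mm^-2) at depth z for a given fiber-exit LPD."""
    if exit_lpd_mw_mm2 < 0:
        raise ValueError("exit LPD must be >= 0")
    return exit_lpd_mw_mm2 * fractional_irradiance(model, z_mm, wavelength_nm)


def optimal_wavelength(model: TissueOpticsModel, spectrum: ActionSpectrum,
                       z_mm: float) -> float:
    """Wavelength maximizing opsin activation at depth z.

    Maximizes ``spectrum(lambda) * fractional_irradiance(z, lambda)`` over
    the spectrum's grid.  At z = 0 the transmittance is flat (=1), so this
    returns the spectrum peak; at depth the optimum shifts toward longer
    wavelengths wherever tissue attenuation decreases with wavelength.
    """
    if z_mm < 0:
        raise ValueError("depth must be >= 0")
    product = spectrum.response * fractional_irradiance(
        model, np.full_like(spectrum.wavelength_nm, float(z_mm)),
        spectrum.wavelength_nm)
    return float(spectrum.wavelength_nm[np.argmax(product)])


def transmittance_curve(model: TissueOpticsModel, wavelength_nm: float,
                        z_max_mm: float = 2.0, n_points: int = 201):
    """(depth, fractional irradiance) table for one wavelength."""
    z = np.linspace(0.0, z_max_mm, n_points)
    return z, fractional_irradiance(model, z, wavelength_nm)
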