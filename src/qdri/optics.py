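"""Chromophore absorption and Mie-sphere scattering models.

Maps physical composition (absorber concentrations, sphere suspensions) to
the absorption spectrum ``mu_a(lambda)`` and reduced scattering spectrum
``mu_s'(lambda)`` of a homogeneous medium layer.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .mie import mie_q_sca_g

LN10 = float(np.log(10.0))

#: default analysis band, nm
DEFAULT_BAND = (450.0, 600.0)
#: default wavelength support, nm
GRID_LIMITS = (420.0, 700.0)

#: refractive-index defaults (documented config values, not fitted)
N_WATER = 1.33
N_POLYSTYRENE = 1.59
N_TISSUE = 1.37
G_TISSUE_DEFAULT = 0.9


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths in nm within the supported window."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavelength grid needs at least 2 points")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if v[0] < GRID_LIMITS[0] - 1e-9 or v[-1] > GRID_LIMITS[1] + 1e-9:
            raise ValueError(
                f"wavelengths must lie within {GRID_LIMITS[0]:.0f}-{GRID_LIMITS[1]:.0f} nm"
            )
        object.__setattr__(self, "values", v)

    @classmethod
    def default(cls, start: float = 420.0, stop: float = 700.0, step: float = 1.0):
        return cls(np.arange(start, stop + 0.5 * step, step))

    @classmethod
    def analysis_band(cls, step: float = 1.0):
        return cls.default(DEFAULT_BAND[0], DEFAULT_BAND[1], step)

    def __len__(self):
        return self.values.size

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        if hi < lo:
            raise ValueError("band limits reversed")
        mask = (self.values >= lo) & (self.values <= hi)
        if not mask.any():
            raise ValueError("band contains no grid points")
        return mask


@dataclass(frozen=True)
class AbsorberSpectrum:
    """Molar extinction coefficient of one absorber, 1/(M cm)."""

    name: str
    wavelength_nm: np.ndarray
    extinction: np.ndarray
    source: str = "unspecified"

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        eps = np.asarray(self.extinction, dtype=float)
        if wl.shape != eps.shape:
            raise ValueError("wavelength and extinction arrays differ in shape")
        if np.any(eps < 0):
            raise ValueError(f"negative extinction for absorber {self.name!r}")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "extinction", eps)

    @classmethod
    def from_csv(cls, path, name: str, source: str | None = None):
        df = pd.read_csv(path)
        cols = {c.strip().lower(): c for c in df.columns}
        try:
            wl = df[cols["wavelength_nm"]].to_numpy(float)
            eps = df[cols["extinction_1_per_m_cm"]].to_numpy(float)
        except KeyError as exc:  # pragma: no cover - format guard
            raise ValueError(f"absorber CSV {path} missing column {exc}") from exc
        return cls(name, wl, eps, source or str(path))

    def on_grid(self, grid: WavelengthGrid) -> np.ndarray:
        """Linear interpolation of extinction onto ``grid``; extrapolation
        outside the tabulated support is an error."""
        g = grid.values
        if g[0] < self.wavelength_nm[0] - 1e-9 or g[-1] > self.wavelength_nm[-1] + 1e-9:
            raise ValueError(
                f"grid exceeds tabulated support of absorber {self.name!r}"
            )
        return np.interp(g, self.wavelength_nm, self.extinction)


@dataclass(frozen=True)
class ChromophoreConcentrations:
    """Molar concentrations in micromolar, keyed by absorber name."""

    concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name!r}")


@dataclass(frozen=True)
class SphereScattererSpec:
    """Monodisperse sphere suspension."""

    diameter_um: float
    sphere_refractive_index: float = N_POLYSTYRENE
    medium_refractive_index: float = N_WATER
    number_density_per_ml: float = 0.0

    def __post_init__(self):
        if self.diameter_um <= 0:
            raise ValueError("sphere diameter must be positive")
        if self.number_density_per_ml < 0:
            raise ValueError("number density must be non-negative")
        if self.sphere_refractive_index < 1 or self.medium_refractive_index < 1:
            raise ValueError("refractive indices must be >= 1")


@dataclass(frozen=True)
class OpticalProperties:
    """Per-wavelength optical properties of one homogeneous layer."""

    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    g: np.ndarray
    n_medium: float = N_TISSUE

    def __post_init__(self):
        mu_a = np.atleast_1d(np.asarray(self.mu_a, dtype=float))
        musp = np.atleast_1d(np.asarray(self.mu_s_prime, dtype=float))
        g = np.broadcast_to(np.asarray(self.g, dtype=float), musp.shape).copy()
        if np.any(mu_a < 0) or np.any(musp < 0):
            raise ValueError("mu_a and mu_s' must be non-negative")
        if np.any(g <= -1) or np.any(g >= 1):
            raise ValueError("anisotropy must lie in (-1, 1)")
        if mu_a.shape != musp.shape:
            raise ValueError("mu_a and mu_s' shapes differ")
        object.__setattr__(self, "mu_a", mu_a)
        object.__setattr__(self, "mu_s_prime", musp)
        object.__setattr__(self, "g", g)

    @property
    def mu_s(self) -> np.ndarray:
        """Full (unreduced) scattering coefficient."""
        return self.mu_s_prime / (1.0 - self.g)


def absorption_spectrum(
    concs: ChromophoreConcentrations,
    library: Mapping[str, AbsorberSpectrum],
    grid: WavelengthGrid,
) -> np.ndarray:
    """Beer-Lambert mixture absorption, cm^-1.

    ``mu_a(lambda) = ln(10) * sum_i eps_i(lambda) * C_i`` with C in molar
    (input concentrations are micromolar).
    """
    mu_a = np.zeros(len(grid))
    for name, c_um in concs.concentrations.items():
        if name not in library:
            raise KeyError(f"unknown absorber {name!r}")
        mu_a += LN10 * library[name].on_grid(grid) * (c_um * 1e-6)
    return mu_a


def mie_reduced_scattering(
    spec: SphereScattererSpec, grid: WavelengthGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Reduced scattering spectrum (cm^-1) and anisotropy spectrum of a
    sphere suspension under the independent-scatterer approximation."""
    radius_cm = spec.diameter_um * 1e-4 / 2.0
    geom_cross_section = np.pi * radius_cm**2
    m = spec.sphere_refractive_index / spec.medium_refractive_index
    musp = np.empty(len(grid))
    g = np.empty(len(grid))
    for i, wl_nm in enumerate(grid.values):
        x = np.pi * spec.diameter_um * spec.medium_refractive_index / (wl_nm * 1e-3)
        q_sca, gi = mie_q_sca_g(m, x)
        mu_s = spec.number_density_per_ml * q_sca * geom_cross_section  # cm^-1
        musp[i] = mu_s * (1.0 - gi)
        g[i] = gi
    return musp, g


def band_average(
    spectrum: np.ndarray, grid: WavelengthGrid, band: tuple[float, float] = DEFAULT_BAND
) -> float:
    """Mean of ``spectrum`` over grid points inside the closed band."""
    mask = grid.band_mask(band)
    return float(np.mean(np.asarray(spectrum, dtype=float)[mask]))


def load_default_absorbers() -> dict[str, AbsorberSpectrum]:
    """Bundled extinction compilations for hemoglobin and beta-carotene."""
    out = {}
    pkg = importlib.resources.files("qdri.data")
    for name, fname in [
        ("hemoglobin", "hemoglobin_extinction.csv"),
        ("beta_carotene", "beta_carotene_extinction.csv"),
    ]:
        with importlib.resources.as_file(pkg / fname) as path:
            out[name] = AbsorberSpectrum.from_csv(path, name, source=f"bundled:{fname}")
    return out
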