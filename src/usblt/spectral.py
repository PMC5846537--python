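"""Wavelength-dependent optical properties from a chromophore model.

Absorption follows Beer's law: mu_a(lambda) = sum_c C_c * eps_c(lambda),
with eps in mm^-1 per unit concentration (per mM for haemoglobins, per
volume fraction for water).  Reduced scattering follows the power law
mu_s'(lambda) = a * (lambda in micrometres)^(-b), the convention under
which a slab with a = 0.14, b = 2.8 has tissue-like mu_s' ~ 0.59 mm^-1
at 600 nm.  The diffusion coefficient is kappa = 1/(3 (mu_a + mu_s')).

The bundled extinction curves are smooth representative spectra for water,
oxyhaemoglobin and deoxyhaemoglobin; they can be replaced with measured
tables via :func:`load_extinction_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExtinctionSpectrum",
    "SpectralModel",
    "absorption_at",
    "scattering_at",
    "diffusion_coefficient",
    "default_tissue_model",
    "gaussian_emission_weights",
    "load_extinction_csv",
    "BUILTIN_EXTINCTION",
]


@dataclass
class ExtinctionSpectrum:
    """Tabulated extinction coefficient vs wavelength; linear interpolation
    inside the table range, no extrapolation."""

    wavelengths_nm: np.ndarray
    coefficients: np.ndarray  # mm^-1 per unit concentration

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        order = np.argsort(self.wavelengths_nm)
        self.wavelengths_nm = self.wavelengths_nm[order]
        self.coefficients = self.coefficients[order]

    def at(self, wavelength_nm: float) -> float:
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if not (lo <= wavelength_nm <= hi):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside the extinction table "
                f"range [{lo}, {hi}] nm; extrapolation is not allowed"
            )
        return float(np.interp(wavelength_nm, self.wavelengths_nm, self.coefficients))


# Representative smooth extinction curves (replaceable).  Haemoglobins in
# mm^-1 per mM; water in mm^-1 per unit volume fraction.
_TABLE_NM = np.array(
    [500, 550, 600, 610, 620, 630, 640, 650, 700, 750, 800, 850, 900, 950, 1000],
    dtype=float,
)
BUILTIN_EXTINCTION: dict[str, ExtinctionSpectrum] = {
    "water": ExtinctionSpectrum(
        _TABLE_NM,
        np.array([2.5e-5, 4.5e-5, 2.2e-4, 2.6e-4, 2.8e-4, 2.9e-4, 3.1e-4,
                  3.4e-4, 6.0e-4, 2.8e-3, 2.2e-3, 4.3e-3, 6.8e-3, 2.8e-2, 3.6e-2]),
    ),
    "oxyhemoglobin": ExtinctionSpectrum(
        _TABLE_NM,
        np.array([4.8, 12.0, 0.75, 0.52, 0.40, 0.34, 0.30,
                  0.28, 0.07, 0.12, 0.19, 0.24, 0.27, 0.29, 0.25]),
    ),
    "deoxyhemoglobin": ExtinctionSpectrum(
        _TABLE_NM,
        np.array([4.9, 12.5, 3.35, 2.65, 2.11, 1.70, 1.35,
                  0.85, 0.41, 0.32, 0.18, 0.17, 0.18, 0.15, 0.10]),
    ),
}


@dataclass
class SpectralModel:
    """Chromophore concentrations plus scattering power law for one tissue."""

    chromophores: list[tuple[str, float, ExtinctionSpectrum]] = field(default_factory=list)
    scatter_amplitude: float = 0.14   # a, NIRFAST convention
    scatter_power: float = 2.8        # b
    refractive_index: float = 1.33

    def __post_init__(self) -> None:
        if self.scatter_amplitude <= 0:
            raise ValueError("scatter amplitude must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")
        for name, conc, _ in self.chromophores:
            if conc < 0:
                raise ValueError(f"negative concentration for chromophore {name!r}")


def absorption_at(model: SpectralModel, wavelength_nm: float) -> float:
    """Beer's-law absorption mu_a (mm^-1) at one wavelength."""
    return float(sum(conc * spec.at(wavelength_nm) for _, conc, spec in model.chromophores))


def scattering_at(model: SpectralModel, wavelength_nm: float) -> float:
    """Reduced scattering mu_s' = a * (lambda_um)^(-b) (mm^-1)."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    lam_um = wavelength_nm / 1000.0
    return float(model.scatter_amplitude * lam_um ** (-model.scatter_power))


def diffusion_coefficient(mua: float, musp: float) -> float:
    """kappa = 1 / (3 (mu_a + mu_s')) in mm."""
    total = mua + musp
    if total <= 0:
        raise ValueError("mu_a + mu_s' must be positive")
    return 1.0 / (3.0 * total)


def default_tissue_model(
    water_fraction: float = 0.5,
    hbo_mM: float = 0.01,
    hb_mM: float = 0.005,
    scatter_amplitude: float = 0.14,
    scatter_power: float = 2.8,
    refractive_index: float = 1.33,
) -> SpectralModel:
    """Muscle-like slab tissue: water + oxy/deoxy-haemoglobin with the
    slab-model scattering parameters (a = 0.14, b = 2.8, n = 1.33)."""
    return SpectralModel(
        chromophores=[
            ("water", water_fraction, BUILTIN_EXTINCTION["water"]),
            ("oxyhemoglobin", hbo_mM, BUILTIN_EXTINCTION["oxyhemoglobin"]),
            ("deoxyhemoglobin", hb_mM, BUILTIN_EXTINCTION["deoxyhemoglobin"]),
        ],
        scatter_amplitude=scatter_amplitude,
        scatter_power=scatter_power,
        refractive_index=refractive_index,
    )


def gaussian_emission_weights(wavelengths_nm, peak_nm: float, fwhm_nm: float) -> np.ndarray:
    """Normalized per-wavelength emission weights for a Gaussian source
    spectrum (e.g. a chemiluminescent dye peaking at 640 nm, FWHM 60 nm)."""
    lam = np.asarray(wavelengths_nm, dtype=float)
    w = np.exp(-4.0 * np.log(2.0) * (lam - peak_nm) ** 2 / fwhm_nm**2)
    total = w.sum()
    if total <= 0:
        raise ValueError("emission weights sum to zero")
    return w / total


def load_extinction_csv(path) -> dict[str, ExtinctionSpectrum]:
    """Read extinction spectra from a CSV with a ``wavelength_nm`` column
    and one column per chromophore."""
    import pandas as pd

    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError("extinction CSV must have a 'wavelength_nm' column")
    lam = df["wavelength_nm"].to_numpy(dtype=float)
    return {
        col: ExtinctionSpectrum(lam, df[col].to_numpy(dtype=float))
        for col in df.columns
        if col != "wavelength_nm"
    }
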