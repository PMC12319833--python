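"""Optical conversion utilities for continuous-wave fNIRS.

The differential pathlength factor (DPF) is modeled as a function of
wavelength λ (nm) and age A (years),

    DPF(λ, A) = α + β·A^γ + δ·λ³ + η·λ² + ζ·λ,

with empirically fitted coefficients (defaults below); the partial pathlength
factor is PPF = DPF / 60.  The modified Beer–Lambert law relates optical
density change at wavelength λ to chromophore concentration changes

    ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · d · PPF(λ),

with ``d`` the source–detector distance; the two-wavelength system is solved
per sample.  Extinction coefficients are shipped as a documented config table
(standard compiled values, 1/(cm·M)); concentrations are therefore in molar
units times whatever scale the caller chooses for ΔOD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ConversionError(ValueError):
    """Raised when the Beer–Lambert system cannot be solved."""


@dataclass(frozen=True)
class OpticalConstants:
    """DPF polynomial coefficients and the instrument wavelength pair."""

    alpha: float = 223.3
    beta: float = 0.05624
    gamma: float = 0.8493
    delta: float = -5.723e-7
    eta: float = 0.001245
    zeta: float = -0.9025
    wavelengths: tuple[float, float] = (760.0, 850.0)


#: Molar extinction coefficients [1/(cm*M)] at the instrument wavelengths,
#: standard compiled spectra; override via config for other instruments.
DEFAULT_EXTINCTION: dict[float, tuple[float, float]] = {
    # wavelength nm: (epsilon_HbO, epsilon_HbR)
    760.0: (1486.5865, 3843.707),
    850.0: (2526.391, 1798.643),
}


def dpf(wavelength: float, age: float, constants: OpticalConstants | None = None) -> float:
    """Differential pathlength factor at one wavelength for a given age."""
    c = constants or OpticalConstants()
    if not 600.0 <= wavelength <= 1000.0:
        raise ValueError(f"wavelength {wavelength} nm outside the 600-1000 nm range")
    if age <= 0:
        raise ValueError("age must be positive")
    return float(
        c.alpha
        + c.beta * age**c.gamma
        + c.delta * wavelength**3
        + c.eta * wavelength**2
        + c.zeta * wavelength
    )


def ppf(wavelength: float, age: float, constants: OpticalConstants | None = None) -> float:
    """Partial pathlength factor: DPF / 60."""
    return dpf(wavelength, age, constants) / 60.0


def _extinction_matrix(
    wavelengths: tuple[float, float],
    extinction: dict[float, tuple[float, float]] | None,
) -> np.ndarray:
    table = extinction or DEFAULT_EXTINCTION
    try:
        E = np.array([table[w] for w in wavelengths], dtype=float)
    except KeyError as err:
        raise ConversionError(f"no extinction coefficients for wavelength {err}") from None
    if abs(np.linalg.det(E)) < 1e-12:
        raise ConversionError("extinction matrix is singular")
    return E


def od_to_hemoglobin(
    od: np.ndarray,
    ppf_pair: tuple[float, float],
    distance_cm: float = 3.0,
    wavelengths: tuple[float, float] = (760.0, 850.0),
    extinction: dict[float, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the modified Beer–Lambert law for a two-wavelength OD pair.

    ``od`` has shape (2, T), rows ordered like ``wavelengths``.  Returns
    ``(hbo, hbr)`` concentration-change series.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 2 or od.shape[0] != 2:
        raise ConversionError("od must have shape (2, n_samples)")
    E = _extinction_matrix(wavelengths, extinction)
    # per-wavelength effective pathlength
    L = distance_cm * np.asarray(ppf_pair, dtype=float)
    A = E * L[:, None]  # (2, 2): rows wavelengths, cols (HbO, HbR)
    conc = np.linalg.solve(A, od)
    return conc[0], conc[1]


def hemoglobin_to_od(
    hbo: np.ndarray,
    hbr: np.ndarray,
    ppf_pair: tuple[float, float],
    distance_cm: float = 3.0,
    wavelengths: tuple[float, float] = (760.0, 850.0),
    extinction: dict[float, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Forward modified Beer–Lambert model (used by the raw-signal simulator)."""
    E = _extinction_matrix(wavelengths, extinction)
    L = distance_cm * np.asarray(ppf_pair, dtype=float)
    conc = np.vstack([np.asarray(hbo, dtype=float), np.asarray(hbr, dtype=float)])
    return (E * L[:, None]) @ conc


def prune_channels(
    intensities: np.ndarray,
    snr_threshold: float = 6.67,
    drange: tuple[float, float] = (0.1, 10.0),
) -> np.ndarray:
    """Signal-quality mask over raw intensity channels.

    A channel passes when its mean intensity lies inside ``drange`` and its
    mean/SD ratio exceeds ``snr_threshold``.  ``intensities`` has shape
    (n_channels, n_samples); returns a boolean keep-mask.
    """
    x = np.asarray(intensities, dtype=float)
    mean = x.mean(axis=1)
    sd = x.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sd > 0, mean / sd, np.inf)
    return (mean >= drange[0]) & (mean <= drange[1]) & (snr >= snr_threshold)
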