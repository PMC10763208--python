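"""Spectral grids, optical-constants tables, resampling and smoothing.

The forward model works on a fixed 1 nm grid from 400 to 1000 nm (601 bands),
the working range of visible/NIR field spectrometers used for leaf-level
phenotyping.  An :class:`OpticalConstants` table carries, per wavelength, the
leaf refractive index ``n`` and the specific absorption coefficients of the
three absorbing constituents: chlorophyll a+b (cm^2 ug^-1), water (cm^2 g^-1)
and dry matter (cm^2 g^-1).

No coefficient table is bundled: any PROSPECT-lineage CSV can be loaded with
:func:`load_constants`, and :func:`make_synthetic_constants` builds a smooth,
physically plausible synthetic table (chlorophyll absorption bands centred at
450 and 650 nm, water absorption rising toward 1000 nm) used throughout the
test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "SpectralGrid",
    "OpticalConstants",
    "RawSpectrum",
    "default_grid",
    "load_constants",
    "save_constants",
    "make_synthetic_constants",
    "resample_to_1nm",
    "sg_smooth",
]

GRID_MIN_NM = 400
GRID_MAX_NM = 1000
N_BANDS = 601


@dataclass(frozen=True)
class SpectralGrid:
    """Strictly increasing wavelength grid in nanometres."""

    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(GRID_MIN_NM, GRID_MAX_NM + 1, dtype=float)
    )

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return self.wavelengths.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and np.array_equal(
            self.wavelengths, other.wavelengths
        )


def default_grid() -> SpectralGrid:
    """The 400..1000 nm grid at 1 nm (601 bands)."""
    return SpectralGrid()


@dataclass(frozen=True)
class OpticalConstants:
    """Per-wavelength refractive index and specific absorption coefficients.

    Attributes
    ----------
    grid : SpectralGrid
    n : ndarray
        Leaf refractive index relative to air, > 1 everywhere.
    k_cab, k_cw, k_cm : ndarray
        Specific absorption coefficients of chlorophyll (cm^2 ug^-1),
        water (cm^2 g^-1) and dry matter (cm^2 g^-1); all >= 0.
    """

    grid: SpectralGrid
    n: np.ndarray
    k_cab: np.ndarray
    k_cw: np.ndarray
    k_cm: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.grid)
        for name in ("n", "k_cab", "k_cw", "k_cm"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (m,):
                raise ValueError(f"{name} must have shape ({m},)")
            object.__setattr__(self, name, arr)
        if np.any(self.n <= 1.0):
            raise ValueError("refractive index must exceed 1 everywhere")
        for name in ("k_cab", "k_cw", "k_cm"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class RawSpectrum:
    """A reflectance (or transmittance) spectrum on an arbitrary grid."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or v.shape != wl.shape:
            raise ValueError("wavelengths and values must be matching 1-D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(v < -0.05) or np.any(v > 1.05):
            raise ValueError("reflectance outside the [-0.05, 1.05] sensor-noise band")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    def clipped(self) -> "RawSpectrum":
        """Clip values into the physical [0, 1] range."""
        return RawSpectrum(self.wavelengths, np.clip(self.values, 0.0, 1.0))


_COLUMNS = ("wavelength", "n", "Kcab", "Kcw", "Kcm")


def load_constants(path: str | Path) -> OpticalConstants:
    """Load an optical-constants table from CSV.

    Expected header: ``wavelength,n,Kcab,Kcw,Kcm`` with one row per nm.
    Rows are sorted by wavelength on load.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"constants table missing column(s): {', '.join(missing)}")
    df = df.sort_values("wavelength", kind="stable").reset_index(drop=True)
    wl = df["wavelength"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("duplicate or non-monotone wavelengths in constants table")
    for c in ("Kcab", "Kcw", "Kcm"):
        if np.any(df[c].to_numpy(dtype=float) < 0):
            raise ValueError(f"negative specific absorption coefficient in column {c}")
    return OpticalConstants(
        grid=SpectralGrid(wl),
        n=df["n"].to_numpy(dtype=float),
        k_cab=df["Kcab"].to_numpy(dtype=float),
        k_cw=df["Kcw"].to_numpy(dtype=float),
        k_cm=df["Kcm"].to_numpy(dtype=float),
    )


def save_constants(constants: OpticalConstants, path: str | Path) -> None:
    """Write a constants table as CSV (full float precision, round-trip safe)."""
    df = pd.DataFrame(
        {
            "wavelength": constants.grid.wavelengths,
            "n": constants.n,
            "Kcab": constants.k_cab,
            "Kcw": constants.k_cw,
            "Kcm": constants.k_cm,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def _gaussian(wl: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - centre) / width) ** 2)


def make_synthetic_constants(
    seed: int = 0, grid: SpectralGrid | None = None
) -> OpticalConstants:
    """Smooth synthetic optical constants for testing and simulation.

    Chlorophyll absorption is the sum of two Gaussian bands centred at 450 nm
    (blue) and 650 nm (red) — the two strong absorption bands of chlorophyll —
    so the green reflectance peak near 540 nm emerges naturally.  Water
    absorption rises monotonically toward 1000 nm, dry-matter absorption is
    small and nearly flat, and the refractive index drifts slowly within
    1.3–1.5.  Amplitudes are jittered slightly (but deterministically) by
    ``seed``; band centres are fixed.
    """
    if grid is None:
        grid = default_grid()
    wl = grid.wavelengths
    rng = np.random.default_rng(seed)
    # jitter factors within +-10% so maxima stay at 450/650 for every seed
    j = rng.uniform(0.9, 1.1, size=6)
    k_cab = 0.045 * j[0] * _gaussian(wl, 450.0, 35.0) + 0.035 * j[1] * _gaussian(
        wl, 650.0, 30.0
    )
    # water: smooth rise toward the NIR, ~10 cm^2/g at 1000 nm
    x = (wl - GRID_MIN_NM) / (GRID_MAX_NM - GRID_MIN_NM)
    k_cw = 10.0 * j[2] * x**3
    k_cm = 6.0 * j[3] * (1.0 + 0.05 * np.sin(2 * np.pi * x * j[4]))
    n = 1.45 - 0.1 * x + 0.02 * j[5] * np.cos(np.pi * x)
    return OpticalConstants(grid=grid, n=n, k_cab=k_cab, k_cw=k_cw, k_cm=k_cm)


def resample_to_1nm(spectrum: RawSpectrum, grid: SpectralGrid | None = None) -> RawSpectrum:
    """Linearly interpolate a spectrum onto the target grid (default 1 nm).

    Values at coincident wavelengths are preserved exactly.  Raises if the
    target grid extends beyond the measured range (no extrapolation).
    """
    if grid is None:
        grid = default_grid()
    wl_in = spectrum.wavelengths
    wl_out = grid.wavelengths
    if wl_out[0] < wl_in[0] or wl_out[-1] > wl_in[-1]:
        raise ValueError(
            "target grid extends beyond the measured wavelength range; "
            "refusing to extrapolate"
        )
    return RawSpectrum(wl_out, np.interp(wl_out, wl_in, spectrum.values))


def sg_smooth(spectrum: RawSpectrum, window: int = 11, order: int = 3) -> RawSpectrum:
    """Savitzky–Golay smoothing on a uniform grid.

    Defaults (window 11, order 3) give mild smoothing at 1 nm resolution.
    Output is clipped to [0, 1] (physical bound).
    """
    if window % 2 == 0:
        raise ValueError("SG window must be odd")
    if order >= window:
        raise ValueError("SG polynomial order must be smaller than the window")
    steps = np.diff(spectrum.wavelengths)
    if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-8):
        raise ValueError("SG smoothing requires a uniform wavelength grid")
    smoothed = savgol_filter(spectrum.values, window_length=window, polyorder=order)
    return RawSpectrum(spectrum.wavelengths, np.clip(smoothed, 0.0, 1.0))
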