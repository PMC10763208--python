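"""Inversion drivers, spectral error metrics and reporting utilities.

The accuracy metric is a relative RMSE: the root-mean-square difference
between modelled and measured reflectance over a wavelength band, divided by
the band-mean measured reflectance.  It is evaluated over the full
400–1000 nm range and over the three physiological bands

* blue-green  [400, 560] nm — pigment absorption,
* yellow-red  (560, 780] nm — red chlorophyll absorption and red edge,
* near-infrared (780, 1000] nm — water/dry-matter and structure scattering.

Band edges are owned by the left band (560 is blue-green, 780 yellow-red),
so the 601 bands partition deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants_io import OpticalConstants, SpectralGrid
from .forward import LayerPartition, LeafBiochem, LeafSpectrum
from .nsga3 import GAConfig

__all__ = [
    "BandDefinition",
    "default_bands",
    "band_mask",
    "rmse",
    "InversionResult",
    "invert_sample",
    "fit_uniform_baseline",
    "summarize_parameters",
    "compare_models",
    "parameter_correlations",
]

PARAM_NAMES = ("N1", "N2", "cab12", "cm12")
BIOCHEM_NAMES = ("cab", "cw", "cm", "N")


@dataclass(frozen=True)
class BandDefinition:
    """A named wavelength band, inclusive of ``hi``; ``lo`` exclusive except 400."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (400 <= self.lo < self.hi <= 1000):
            raise ValueError("band must satisfy 400 <= lo < hi <= 1000")


def default_bands() -> tuple[BandDefinition, ...]:
    return (
        BandDefinition("blue_green", 400, 560),
        BandDefinition("yellow_red", 560, 780),
        BandDefinition("near_infrared", 780, 1000),
    )


def band_mask(grid: SpectralGrid, band: BandDefinition | None) -> np.ndarray:
    """Boolean mask of grid wavelengths owned by ``band`` (None = full grid)."""
    wl = grid.wavelengths
    if band is None:
        return np.ones(wl.shape, dtype=bool)
    lo = band.lo
    if lo <= wl[0]:  # the leftmost band owns its lower edge
        return (wl >= lo) & (wl <= band.hi)
    return (wl > lo) & (wl <= band.hi)


def rmse(
    R_meas,
    R_mod,
    band: BandDefinition | None = None,
    grid: SpectralGrid | None = None,
    relative: bool = True,
) -> float:
    """Band RMSE between measured and modelled reflectance.

    With ``relative=True`` (default) the RMS difference is divided by the
    band-mean measured reflectance, giving the dimensionless relative RMSE
    used for model comparison; ``relative=False`` gives the plain RMS
    difference in reflectance units.
    """
    R_meas = np.asarray(R_meas, dtype=float)
    R_mod = np.asarray(R_mod, dtype=float)
    if grid is None:
        grid = SpectralGrid()
    mask = band_mask(grid, band)
    if not mask.any():
        raise ValueError("band contains no grid wavelengths")
    diff = R_meas[mask] - R_mod[mask]
    value = float(np.sqrt(np.mean(diff**2)))
    if not relative:
        return value
    denom = float(np.mean(R_meas[mask]))
    if denom == 0.0:
        raise ValueError("band-mean measured reflectance is zero")
    return value / denom


@dataclass(frozen=True)
class InversionResult:
    """Best partition for one sample plus its fit metrics."""

    sample_id: str
    partition: LayerPartition
    fitness: float
    rmse_full: float
    rmse_by_band: dict[str, float]
    trace: np.ndarray = field(repr=False)
    modelled: LeafSpectrum | None = field(default=None, repr=False)


def invert_sample(
    measured: LeafSpectrum,
    biochem: LeafBiochem,
    constants: OpticalConstants,
    config: GAConfig | None = None,
    sample_id: str = "sample",
    mode: str = "scalar",
) -> InversionResult:
    """Recover the two-layer partition of one leaf from its spectrum.

    Thin functional wrapper over :class:`leaflayers.model.TwoLayerLeafModel`.
    """
    from .model import TwoLayerLeafModel

    model = TwoLayerLeafModel(measured, biochem, constants, config=config, mode=mode)
    res = model.fit()
    return InversionResult(
        sample_id=sample_id,
        partition=res.partition,
        fitness=res.fitness,
        rmse_full=res.rmse_full,
        rmse_by_band=dict(res.rmse_by_band),
        trace=res.trace,
        modelled=res.fitted_spectrum,
    )


def fit_uniform_baseline(
    measured: LeafSpectrum,
    biochem: LeafBiochem,
    constants: OpticalConstants,
    config: GAConfig | None = None,
):
    """Fit the homogeneous-leaf baseline (N in [1, 3]) to one spectrum."""
    from .model import UniformLeafModel

    return UniformLeafModel(measured, biochem, constants, config=config).fit()


def summarize_parameters(results: list[InversionResult]) -> pd.DataFrame:
    """Min/Max/Mean/Variance table of the recovered partition parameters.

    Variance is the population variance (ddof = 0).
    """
    if not results:
        raise ValueError("no inversion results to summarize")
    data = {
        name: np.array([getattr(r.partition, name) for r in results])
        for name in PARAM_NAMES
    }
    rows = {}
    for stat, fn in (
        ("Min", np.min),
        ("Max", np.max),
        ("Mean", np.mean),
        ("Variance", lambda v: np.var(v, ddof=0)),
    ):
        rows[stat] = {name: float(fn(v)) for name, v in data.items()}
    return pd.DataFrame(rows).T[list(PARAM_NAMES)]


def compare_models(
    measured: list[LeafSpectrum],
    biochems: list[LeafBiochem],
    constants: OpticalConstants,
    config: GAConfig | None = None,
    sample_ids: list[str] | None = None,
    bands: tuple[BandDefinition, ...] | None = None,
) -> pd.DataFrame:
    """Two-layer vs homogeneous baseline, per sample and per band.

    Both models are fitted with the same optimizer budget; the table carries
    full-band and per-band relative RMSE for each plus the difference
    (two_layer - uniform; negative favours the stratified model).
    """
    if not measured:
        raise ValueError("empty sample set")
    if len(measured) != len(biochems):
        raise ValueError("measured spectra and biochemistry tables must match")
    if bands is None:
        bands = default_bands()
    if sample_ids is None:
        sample_ids = [f"sample_{i:03d}" for i in range(len(measured))]
    rows = []
    for sid, spec, bio in zip(sample_ids, measured, biochems):
        inv = invert_sample(spec, bio, constants, config, sample_id=sid)
        base = fit_uniform_baseline(spec, bio, constants, config)
        row: dict[str, float | str] = {"sample_id": sid}
        row["rmse_two_layer"] = inv.rmse_full
        row["rmse_uniform"] = base.rmse_full
        row["delta_rmse"] = inv.rmse_full - base.rmse_full
        for b in bands:
            rb = rmse(spec.R, base.fitted_spectrum.R, b, spec.grid)
            row[f"rmse_two_layer_{b.name}"] = inv.rmse_by_band[b.name]
            row[f"rmse_uniform_{b.name}"] = rb
            row[f"delta_rmse_{b.name}"] = inv.rmse_by_band[b.name] - rb
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def parameter_correlations(
    results: list[InversionResult], biochems: list[LeafBiochem]
) -> pd.DataFrame:
    """Pearson correlation between recovered partitions and input biochemistry.

    Rows are the partition parameters (N1, N2, Cab12, Cm12), columns the leaf
    biochemistry (Cab, Cw, Cm, N).  Zero-variance columns give NaN.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 samples for a correlation analysis")
    if len(results) != len(biochems):
        raise ValueError("results and biochemistry tables must match")
    P = pd.DataFrame(
        {name: [getattr(r.partition, name) for r in results] for name in PARAM_NAMES}
    )
    B = pd.DataFrame(
        {name: [getattr(b, name) for b in biochems] for name in BIOCHEM_NAMES}
    )
    out = pd.DataFrame(index=list(PARAM_NAMES), columns=list(BIOCHEM_NAMES), dtype=float)
    for pn in PARAM_NAMES:
        for bn in BIOCHEM_NAMES:
            x, y = P[pn].to_numpy(), B[bn].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                out.loc[pn, bn] = np.nan
            else:
                out.loc[pn, bn] = float(np.corrcoef(x, y)[0, 1])
    return out
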