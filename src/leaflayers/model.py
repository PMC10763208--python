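"""Model/Results interface for spectrum fitting.

Two model classes follow the familiar fit/Results pattern of statistical
modelling packages:

* :class:`TwoLayerLeafModel` — given a measured leaf spectrum and the leaf's
  (known) total biochemistry, estimates the two-layer stratification
  ``(N1, N2, Cab12, Cm12)`` by minimizing the summed relative deviation
  between modelled and measured reflectance with the in-repo NSGA-III.
* :class:`UniformLeafModel` — the homogeneous-leaf baseline; only the
  structure parameter ``N`` (in [1, 3]) is fitted with the same optimizer
  budget, so comparisons are like-for-like.

``fit()`` returns a Results object carrying the point estimate, a
population-dispersion diagnostic (the spread of each parameter across the
final elite population — the optimizer's analogue of a standard error, not a
frequentist one), per-band relative RMSE, the fitness trace and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants_io import OpticalConstants
from .forward import (
    LayerPartition,
    LeafBiochem,
    LeafSpectrum,
    two_layer_reflectance_batch,
    uniform_reflectance_batch,
)
from .inversion import BandDefinition, band_mask, default_bands, rmse
from .nsga3 import GAConfig, NSGA3Result, encode_partition, fitness_y_batch, nsga3_run
from .plate import DEFAULT_ALPHA

__all__ = [
    "TwoLayerLeafModel",
    "TwoLayerLeafResults",
    "UniformLeafModel",
    "UniformLeafResults",
]


def _as_measured(measured, constants) -> LeafSpectrum:
    if isinstance(measured, LeafSpectrum):
        return measured
    return LeafSpectrum(grid=constants.grid, R=np.asarray(measured, dtype=float))


class _LeafModelBase:
    def __init__(self, measured, biochem, constants, config=None, alpha=DEFAULT_ALPHA,
                 bands=None):
        self.constants = constants
        self.measured = _as_measured(measured, constants)
        if self.measured.grid != constants.grid:
            raise ValueError("measured spectrum and constants must share a grid")
        self.biochem = biochem
        self.config = config if config is not None else GAConfig()
        self.alpha = alpha
        self.bands: tuple[BandDefinition, ...] = (
            tuple(bands) if bands is not None else default_bands()
        )

    def _metrics(self, fitted_R: np.ndarray):
        full = rmse(self.measured.R, fitted_R, None, self.constants.grid)
        by_band = {
            b.name: rmse(self.measured.R, fitted_R, b, self.constants.grid)
            for b in self.bands
        }
        return full, by_band


@dataclass
class _ResultsBase:
    model: object = field(repr=False)
    params: pd.Series
    params_spread: pd.Series
    fitness: float
    rmse_full: float
    rmse_by_band: dict[str, float]
    trace: np.ndarray = field(repr=False)
    fitted_spectrum: LeafSpectrum = field(repr=False)
    optimizer_result: NSGA3Result = field(repr=False)

    def predict(self) -> LeafSpectrum:
        """The fitted spectrum (modelled reflectance/transmittance)."""
        return self.fitted_spectrum

    def summary(self) -> str:
        lines = [
            f"{type(self).__name__}",
            "=" * 58,
            f"{'parameter':<12}{'estimate':>12}{'pop. spread':>14}",
            "-" * 58,
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<12}{self.params[name]:>12.4f}{self.params_spread[name]:>14.4f}"
            )
        lines.append("-" * 58)
        lines.append(f"{'fitness y':<26}{self.fitness:>12.4f}")
        lines.append(f"{'relative RMSE (full)':<26}{self.rmse_full:>12.4f}")
        for band, v in self.rmse_by_band.items():
            lines.append(f"{'  ' + band:<26}{v:>12.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Measured vs fitted reflectance (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        wl = self.fitted_spectrum.grid.wavelengths
        ax.plot(wl, self.model.measured.R, label="measured", lw=1.0)
        ax.plot(wl, self.fitted_spectrum.R, label="fitted", lw=1.0)
        ax.set_xlabel("wavelength [nm]")
        ax.set_ylabel("reflectance")
        ax.legend()
        return ax


class TwoLayerLeafModel(_LeafModelBase):
    """Estimate the two-layer partition of a leaf from its reflectance.

    Parameters
    ----------
    measured : LeafSpectrum or array
        Measured reflectance on the constants' grid.
    biochem : LeafBiochem
        Known totals (Cab, Cw, Cm) and structure parameter N; these are
        inputs, not estimated.
    constants : OpticalConstants
    config : GAConfig, optional
        Optimizer budget and seed.
    mode : {"scalar", "bands"}
        "scalar" (default) minimizes the single summed-relative-deviation
        fitness; "bands" splits it into three per-band objectives
        (blue-green / yellow-red / near-infrared) and reports the
        best-compromise (minimal total) solution.
    """

    def __init__(self, measured, biochem, constants, config=None,
                 alpha=DEFAULT_ALPHA, mode="scalar", bands=None):
        super().__init__(measured, biochem, constants, config, alpha, bands)
        if mode not in ("scalar", "bands"):
            raise ValueError("mode must be 'scalar' or 'bands'")
        self.mode = mode
        n_obj = 1 if mode == "scalar" else len(self.bands)
        if self.config.n_obj != n_obj:
            self.config = GAConfig(
                pop_size=self.config.pop_size,
                generations=self.config.generations,
                n_obj=n_obj,
                eta_crossover=self.config.eta_crossover,
                eta_mutation=self.config.eta_mutation,
                mutation_prob=self.config.mutation_prob,
                divisions=self.config.divisions,
                seed=self.config.seed,
            )
        self._band_masks = [band_mask(constants.grid, b) for b in self.bands]

    def _decode(self, X: np.ndarray):
        N = self.biochem.N
        return (
            N * (2.0 + 0.01 * X[:, 0]),
            N * (0.1 + 2.9 * X[:, 1]),
            X[:, 2],
            X[:, 3],
        )

    def _objective(self, X: np.ndarray) -> np.ndarray:
        N1, N2, cab12, cm12 = self._decode(X)
        R = two_layer_reflectance_batch(
            self.constants, self.biochem, N1, N2, cab12, cm12, alpha=self.alpha
        )
        if self.mode == "scalar":
            return fitness_y_batch(R, self.measured.R)
        meas = np.maximum(self.measured.R, 1e-6)
        rel = np.abs(R - meas[None, :]) / meas[None, :]
        return np.stack([rel[:, m].sum(axis=1) for m in self._band_masks], axis=1)

    def fit(self) -> "TwoLayerLeafResults":
        res = nsga3_run(self._objective, d=4, config=self.config)
        partition = encode_partition(res.best_x, N=self.biochem.N)
        R, T = two_layer_reflectance_batch(
            self.constants,
            self.biochem,
            partition.N1,
            partition.N2,
            partition.cab12,
            partition.cm12,
            alpha=self.alpha,
            return_T=True,
        )
        fitted = LeafSpectrum(self.constants.grid, R[0], T[0])
        full, by_band = self._metrics(fitted.R)
        fitness = float(fitness_y_batch(fitted.R, self.measured.R)[0])
        N1, N2, cab12, cm12 = self._decode(res.X)
        names = ["N1", "N2", "cab12", "cm12"]
        params = pd.Series(
            [partition.N1, partition.N2, partition.cab12, partition.cm12], index=names
        )
        spread = pd.Series(
            [np.std(N1), np.std(N2), np.std(cab12), np.std(cm12)], index=names
        )
        return TwoLayerLeafResults(
            model=self,
            params=params,
            params_spread=spread,
            fitness=fitness,
            rmse_full=full,
            rmse_by_band=by_band,
            trace=res.trace,
            fitted_spectrum=fitted,
            optimizer_result=res,
            partition=partition,
        )


@dataclass
class TwoLayerLeafResults(_ResultsBase):
    partition: LayerPartition = None


class UniformLeafModel(_LeafModelBase):
    """Homogeneous-leaf baseline: fit the structure parameter N in [1, 3]."""

    N_BOUNDS = (1.0, 3.0)

    def _objective(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self.N_BOUNDS
        N = lo + (hi - lo) * X[:, 0]
        R = uniform_reflectance_batch(self.constants, self.biochem, N, alpha=self.alpha)
        return fitness_y_batch(R, self.measured.R)

    def fit(self) -> "UniformLeafResults":
        cfg = self.config
        if cfg.n_obj != 1:
            cfg = GAConfig(pop_size=cfg.pop_size, generations=cfg.generations,
                           n_obj=1, seed=cfg.seed)
        res = nsga3_run(self._objective, d=1, config=cfg)
        lo, hi = self.N_BOUNDS
        N_hat = float(lo + (hi - lo) * res.best_x[0])
        R, T = uniform_reflectance_batch(
            self.constants, self.biochem, N_hat, alpha=self.alpha, return_T=True
        )
        fitted = LeafSpectrum(self.constants.grid, R[0], T[0])
        full, by_band = self._metrics(fitted.R)
        fitness = float(fitness_y_batch(fitted.R, self.measured.R)[0])
        N_pop = lo + (hi - lo) * res.X[:, 0]
        return UniformLeafResults(
            model=self,
            params=pd.Series([N_hat], index=["N"]),
            params_spread=pd.Series([float(np.std(N_pop))], index=["N"]),
            fitness=fitness,
            rmse_full=full,
            rmse_by_band=by_band,
            trace=res.trace,
            fitted_spectrum=fitted,
            optimizer_result=res,
            N_fitted=N_hat,
        )


@dataclass
class UniformLeafResults(_ResultsBase):
    N_fitted: float = None
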