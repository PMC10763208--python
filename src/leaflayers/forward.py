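"""Leaf-level forward models.

Two forward simulators map leaf biochemistry to a 400–1000 nm reflectance /
transmittance spectrum:

* :func:`uniform_forward` — the classical generalized plate model of a
  homogeneous leaf (PROSPECT-style): ``N`` identical absorbing plates, the
  top one illuminated directionally within a cone of half-angle ``alpha``.
* :func:`two_layer_forward` — the stratified model: the leaf is split into an
  upper (illuminated, palisade-like) layer and a lower (spongy-like) layer
  with their own structure parameters ``N1``, ``N2``; the constituent totals
  ``Cab``, ``Cw``, ``Cm`` are divided between the layers by the partition
  ratios ``Cab12``, ``Cw12``, ``Cm12`` (fraction assigned to the upper
  layer).  Water is assigned entirely to the upper layer by default
  (``Cw12 = 1``), which is where inversion places it anyway.

Each layer's per-sublayer optical depth is

    k1 = (Kcab*Cab12*Cab + Kcw*Cw12*Cw + Kcm*Cm12*Cm) / N1
    k2 = (Kcab*(1-Cab12)*Cab + Kcw*(1-Cw12)*Cw + Kcm*(1-Cm12)*Cm) / N2

so that ``N1*k1 + N2*k2`` conserves the total absorber mass per band.  The
two layers are coupled by the adding-doubling closure over all inter-layer
bounces; with a uniform partition the model collapses exactly onto the
homogeneous plate model with ``N = N1 + N2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants_io import OpticalConstants, SpectralGrid
from .plate import (
    DEFAULT_ALPHA,
    LayerOptics,
    _elementary_from_interfaces,
    absorption_transmissivity,
    average_transmittance,
    average_transmittance_reverse,
    combine_two_layers,
    stokes_stack,
)

__all__ = [
    "LeafBiochem",
    "LayerPartition",
    "LeafSpectrum",
    "layer_absorption",
    "two_layer_forward",
    "two_layer_reflectance_batch",
    "uniform_forward",
    "uniform_reflectance_batch",
]


@dataclass(frozen=True)
class LeafBiochem:
    """Whole-leaf biochemistry: structure parameter and constituent totals.

    ``N`` is dimensionless (> 0), ``cab`` in ug cm^-2, ``cw`` and ``cm`` in
    g cm^-2.
    """

    N: float
    cab: float
    cw: float
    cm: float

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("structure parameter N must be positive")
        if min(self.cab, self.cw, self.cm) < 0:
            raise ValueError("constituent contents must be nonnegative")


@dataclass(frozen=True)
class LayerPartition:
    """Two-layer stratification: structure per layer and upper-layer fractions."""

    N1: float
    N2: float
    cab12: float
    cm12: float
    cw12: float = 1.0

    def __post_init__(self) -> None:
        if self.N1 <= 0 or self.N2 <= 0:
            raise ValueError("layer structure parameters must be positive")
        for name in ("cab12", "cm12", "cw12"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class LeafSpectrum:
    """Reflectance (and optionally transmittance) on a spectral grid."""

    grid: SpectralGrid
    R: np.ndarray
    T: np.ndarray | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.shape != (len(self.grid),):
            raise ValueError("R must match the grid length")
        object.__setattr__(self, "R", R)
        if self.T is not None:
            T = np.asarray(self.T, dtype=float)
            if T.shape != R.shape:
                raise ValueError("T must match the grid length")
            object.__setattr__(self, "T", T)


def layer_absorption(
    constants: OpticalConstants,
    biochem: LeafBiochem,
    partition: LayerPartition,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sublayer optical depths ``(k1, k2)`` of the two layers."""
    k1 = (
        constants.k_cab * partition.cab12 * biochem.cab
        + constants.k_cw * partition.cw12 * biochem.cw
        + constants.k_cm * partition.cm12 * biochem.cm
    ) / partition.N1
    k2 = (
        constants.k_cab * (1.0 - partition.cab12) * biochem.cab
        + constants.k_cw * (1.0 - partition.cw12) * biochem.cw
        + constants.k_cm * (1.0 - partition.cm12) * biochem.cm
    ) / partition.N2
    return k1, k2


class _Interfaces:
    """Cone-averaged interface transmittances, computed once per (grid, alpha)."""

    def __init__(self, n: np.ndarray, alpha: float):
        self.t_in_a = average_transmittance(alpha, n)
        self.t_in_90 = average_transmittance(90.0, n)
        self.t_out = average_transmittance_reverse(90.0, n)


_iface_cache: dict[tuple[int, float, bytes], _Interfaces] = {}


def _interfaces(constants: OpticalConstants, alpha: float) -> _Interfaces:
    key = (id(constants), float(alpha), constants.n.tobytes()[:64])
    hit = _iface_cache.get(key)
    if hit is None:
        hit = _Interfaces(constants.n, alpha)
        if len(_iface_cache) > 32:
            _iface_cache.clear()
        _iface_cache[key] = hit
    return hit


def _directional_layer(ifc: _Interfaces, k, n_sub, alpha_note: str = "layer") -> LayerOptics:
    """A layer of ``n_sub`` sublayers whose top plate sees directional light.

    ``k`` is the per-sublayer optical depth; ``n_sub`` may be non-integer.
    Built as one directional plate on top of a Stokes pile of ``n_sub - 1``
    diffuse plates.  ``n_sub < 1`` falls back to a purely diffuse pile with a
    warning (extrapolated-structure regime).
    """
    tau = absorption_transmissivity(k)
    n_sub = np.asarray(n_sub, dtype=float)
    if np.any(n_sub < 1.0):
        warnings.warn(
            f"{alpha_note}: structure parameter below 1; using a diffuse "
            "pile (extrapolated-structure regime)",
            stacklevel=3,
        )
        elem90 = _elementary_from_interfaces(ifc.t_in_90, ifc.t_in_90, ifc.t_out, tau)
        return stokes_stack(elem90, n_sub)
    elem_a = _elementary_from_interfaces(ifc.t_in_a, ifc.t_in_90, ifc.t_out, tau)
    elem90 = _elementary_from_interfaces(ifc.t_in_90, ifc.t_in_90, ifc.t_out, tau)
    return combine_two_layers(elem_a, stokes_stack(elem90, n_sub - 1.0))


def _diffuse_layer(ifc: _Interfaces, k, n_sub) -> LayerOptics:
    tau = absorption_transmissivity(k)
    elem90 = _elementary_from_interfaces(ifc.t_in_90, ifc.t_in_90, ifc.t_out, tau)
    return stokes_stack(elem90, n_sub)


def two_layer_reflectance_batch(
    constants: OpticalConstants,
    biochem: LeafBiochem,
    N1: np.ndarray,
    N2: np.ndarray,
    cab12: np.ndarray,
    cm12: np.ndarray,
    cw12: float | np.ndarray = 1.0,
    alpha: float = DEFAULT_ALPHA,
    return_T: bool = False,
):
    """Vectorized two-layer reflectance for a population of partitions.

    Parameter arrays have shape ``(P,)``; the result is ``(P, n_bands)``.
    This is the hot path of the evolutionary inversion: one call evaluates a
    whole GA population.
    """
    N1 = np.atleast_1d(np.asarray(N1, dtype=float))[:, None]
    N2 = np.atleast_1d(np.asarray(N2, dtype=float))[:, None]
    cab12 = np.atleast_1d(np.asarray(cab12, dtype=float))[:, None]
    cm12 = np.atleast_1d(np.asarray(cm12, dtype=float))[:, None]
    cw12 = np.atleast_1d(np.asarray(cw12, dtype=float))
    if cw12.size == 1:
        cw12 = np.full_like(cab12, float(cw12[0]))
    else:
        cw12 = cw12[:, None]
    ifc = _interfaces(constants, alpha)
    k1 = (
        constants.k_cab * cab12 * biochem.cab
        + constants.k_cw * cw12 * biochem.cw
        + constants.k_cm * cm12 * biochem.cm
    ) / N1
    k2 = (
        constants.k_cab * (1.0 - cab12) * biochem.cab
        + constants.k_cw * (1.0 - cw12) * biochem.cw
        + constants.k_cm * (1.0 - cm12) * biochem.cm
    ) / N2
    top = _directional_layer(ifc, k1, N1, "upper layer")
    bottom = _diffuse_layer(ifc, k2, N2)
    leaf = combine_two_layers(top, bottom)
    if return_T:
        return np.asarray(leaf.R_dn), np.asarray(leaf.T_dn)
    return np.asarray(leaf.R_dn)


def two_layer_forward(
    constants: OpticalConstants,
    biochem: LeafBiochem,
    partition: LayerPartition,
    alpha: float = DEFAULT_ALPHA,
) -> LeafSpectrum:
    """Two-layer leaf spectrum for one biochemistry/partition pair."""
    R, T = two_layer_reflectance_batch(
        constants,
        biochem,
        partition.N1,
        partition.N2,
        partition.cab12,
        partition.cm12,
        partition.cw12,
        alpha=alpha,
        return_T=True,
    )
    return LeafSpectrum(grid=constants.grid, R=R[0], T=T[0])


def uniform_reflectance_batch(
    constants: OpticalConstants,
    biochem: LeafBiochem,
    N: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    return_T: bool = False,
):
    """Vectorized homogeneous-leaf reflectance over an array of N values."""
    N = np.atleast_1d(np.asarray(N, dtype=float))[:, None]
    if np.any(N < 1.0):
        warnings.warn("structure parameter N below 1 is outside the calibrated range")
    ifc = _interfaces(constants, alpha)
    k = (
        constants.k_cab * biochem.cab
        + constants.k_cw * biochem.cw
        + constants.k_cm * biochem.cm
    ) / N
    leaf = _directional_layer(ifc, k, N, "uniform leaf")
    if return_T:
        return np.asarray(leaf.R_dn), np.asarray(leaf.T_dn)
    return np.asarray(leaf.R_dn)


def uniform_forward(
    constants: OpticalConstants,
    biochem: LeafBiochem,
    alpha: float = DEFAULT_ALPHA,
) -> LeafSpectrum:
    """Homogeneous generalized-plate leaf spectrum (PROSPECT-style baseline)."""
    R, T = uniform_reflectance_batch(
        constants, biochem, biochem.N, alpha=alpha, return_T=True
    )
    return LeafSpectrum(grid=constants.grid, R=R[0], T=T[0])
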