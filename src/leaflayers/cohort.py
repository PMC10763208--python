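"""Synthetic leaf cohorts emulating a multi-period field campaign.

The generator draws per-sample biochemistry within published per-growth-period
envelopes (tillering / jointing / heading / grouting), draws a ground-truth
two-layer partition within the envelope of inverted field values, runs the
two-layer forward model and adds i.i.d. Gaussian sensor noise.  Ground truth
is stored alongside the "measured" spectra, so recovery experiments are
self-contained.

Default envelopes (per period: count, Cab ug cm^-2, Cw and Cm g cm^-2):

=========  ==  =================  ================  ================
period      n  Cab                Cw                Cm
=========  ==  =================  ================  ================
tillering  38  6.1493–110.6944    0.0024–0.0596     0.0013–0.0131
jointing   60  6.2138–57.9034     0.0038–0.1498     0.0022–0.0130
heading    60  8.6600–61.8711     0.0042–0.0203     0.0026–0.0129
grouting   60  7.5908–57.6898     0.0036–0.0169     0.0023–0.0073
=========  ==  =================  ================  ================

Partition envelope: N1 in [2, 2.0373], N2 in [0.1, 3], Cab12 in [0.1157, 1],
Cm12 in [0, 1]; the structure input N defaults to 1.  Sampling is uniform by
default; a triangular mode (peak at the published per-period means) is
available for cohorts whose sample means should match the field campaign.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constants_io import OpticalConstants, SpectralGrid
from .forward import LayerPartition, LeafBiochem, two_layer_forward

__all__ = [
    "PeriodSpec",
    "CohortSpec",
    "SpectraSet",
    "default_cohort_spec",
    "simulate_cohort",
    "write_spectra",
    "read_spectra",
]


@dataclass(frozen=True)
class PeriodSpec:
    """Biochemistry envelope of one growth period."""

    name: str
    n_samples: int
    cab_range: tuple[float, float]
    cw_range: tuple[float, float]
    cm_range: tuple[float, float]
    cab_mean: float | None = None
    cw_mean: float | None = None
    cm_mean: float | None = None


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic cohort, fully seeded."""

    periods: tuple[PeriodSpec, ...]
    n1_range: tuple[float, float] = (2.0, 2.0373)
    n2_range: tuple[float, float] = (0.1, 3.0)
    cab12_range: tuple[float, float] = (0.1157, 1.0)
    cm12_range: tuple[float, float] = (0.0, 1.0)
    N: float = 1.0
    noise_sd: float = 0.01
    distribution: str = "uniform"  # or "triangular" (peak at period means)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.distribution not in ("uniform", "triangular"):
            raise ValueError("distribution must be 'uniform' or 'triangular'")


_DEFAULT_PERIODS = (
    PeriodSpec("tillering", 38, (6.1493, 110.6944), (0.0024, 0.0596),
               (0.0013, 0.0131), 29.3668, 0.0231, 0.0068),
    PeriodSpec("jointing", 60, (6.2138, 57.9034), (0.0038, 0.1498),
               (0.0022, 0.0130), 28.4896, 0.0107, 0.0040),
    PeriodSpec("heading", 60, (8.6600, 61.8711), (0.0042, 0.0203),
               (0.0026, 0.0129), 26.5721, 0.0103, 0.0055),
    PeriodSpec("grouting", 60, (7.5908, 57.6898), (0.0036, 0.0169),
               (0.0023, 0.0073), 31.1441, 0.0078, 0.0045),
)


def default_cohort_spec(
    n_samples: int | None = None, noise_sd: float = 0.01, seed: int = 0,
    distribution: str = "uniform",
) -> CohortSpec:
    """The default four-period cohort (218 samples: 38/60/60/60).

    ``n_samples`` overrides the total; samples are then spread over the
    periods proportionally (at least one each).
    """
    periods = _DEFAULT_PERIODS
    if n_samples is not None:
        total = sum(p.n_samples for p in periods)
        counts = [max(1, round(p.n_samples * n_samples / total)) for p in periods]
        while sum(counts) > n_samples:
            counts[counts.index(max(counts))] -= 1
        while sum(counts) < n_samples:
            counts[counts.index(min(counts))] += 1
        periods = tuple(
            replace(p, n_samples=c) for p, c in zip(periods, counts)
        )
    return CohortSpec(periods=periods, noise_sd=noise_sd, seed=seed,
                      distribution=distribution)


@dataclass
class SpectraSet:
    """A cohort: measured spectra plus biochemistry and (optionally) truth."""

    grid: SpectralGrid
    sample_ids: list[str]
    R: np.ndarray  # (n_bands, n_samples)
    biochem: pd.DataFrame  # sample_id, Cab, Cw, Cm, N, period
    truth: pd.DataFrame | None = None  # sample_id, N1, N2, cab12, cm12, cw12

    def __post_init__(self) -> None:
        if self.R.shape != (len(self.grid), len(self.sample_ids)):
            raise ValueError("spectra matrix must be (n_bands, n_samples)")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if list(self.biochem["sample_id"]) != list(self.sample_ids):
            raise ValueError("biochemistry table must match sample ids in order")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def biochem_of(self, i: int) -> LeafBiochem:
        row = self.biochem.iloc[i]
        return LeafBiochem(N=row["N"], cab=row["Cab"], cw=row["Cw"], cm=row["Cm"])

    def truth_of(self, i: int) -> LayerPartition:
        if self.truth is None:
            raise ValueError("this set carries no ground-truth partitions")
        row = self.truth.iloc[i]
        return LayerPartition(N1=row["N1"], N2=row["N2"], cab12=row["cab12"],
                              cm12=row["cm12"], cw12=row["cw12"])


def _draw(rng, lo, hi, mode, n, distribution):
    if distribution == "triangular" and mode is not None:
        return rng.triangular(lo, min(max(mode, lo), hi), hi, size=n)
    return rng.uniform(lo, hi, size=n)


def simulate_cohort(spec: CohortSpec, constants: OpticalConstants) -> SpectraSet:
    """Draw a cohort, run the forward model and add sensor noise.

    Fully deterministic given ``spec.seed``.  Noise is additive Gaussian in
    reflectance units, clipped to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    ids, bio_rows, truth_rows, spectra = [], [], [], []
    for period in spec.periods:
        n = period.n_samples
        cab = _draw(rng, *period.cab_range, period.cab_mean, n, spec.distribution)
        cw = _draw(rng, *period.cw_range, period.cw_mean, n, spec.distribution)
        cm = _draw(rng, *period.cm_range, period.cm_mean, n, spec.distribution)
        n1 = rng.uniform(*spec.n1_range, size=n)
        n2 = rng.uniform(*spec.n2_range, size=n)
        cab12 = rng.uniform(*spec.cab12_range, size=n)
        cm12 = rng.uniform(*spec.cm12_range, size=n)
        for j in range(n):
            sid = f"{period.name}_{j:03d}"
            bio = LeafBiochem(N=spec.N, cab=cab[j], cw=cw[j], cm=cm[j])
            part = LayerPartition(N1=n1[j], N2=n2[j], cab12=cab12[j],
                                  cm12=cm12[j], cw12=1.0)
            R = two_layer_forward(constants, bio, part).R
            if spec.noise_sd > 0:
                R = np.clip(R + rng.normal(0.0, spec.noise_sd, R.shape), 0.0, 1.0)
            ids.append(sid)
            spectra.append(R)
            bio_rows.append({"sample_id": sid, "Cab": cab[j], "Cw": cw[j],
                             "Cm": cm[j], "N": spec.N, "period": period.name})
            truth_rows.append({"sample_id": sid, "N1": n1[j], "N2": n2[j],
                               "cab12": cab12[j], "cm12": cm12[j], "cw12": 1.0})
    return SpectraSet(
        grid=constants.grid,
        sample_ids=ids,
        R=np.column_stack(spectra),
        biochem=pd.DataFrame(bio_rows),
        truth=pd.DataFrame(truth_rows),
    )


def write_spectra(sset: SpectraSet, outdir: str | Path) -> None:
    """Write a cohort as plain CSV: spectra, biochemistry and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec_df = pd.DataFrame(sset.R, columns=sset.sample_ids)
    spec_df.insert(0, "wavelength", sset.grid.wavelengths)
    spec_df.to_csv(outdir / "spectra.csv", index=False, float_format="%.17g")
    sset.biochem.to_csv(outdir / "biochemistry.csv", index=False,
                        float_format="%.17g")
    if sset.truth is not None:
        sset.truth.to_csv(outdir / "truth_partitions.csv", index=False,
                          float_format="%.17g")


def read_spectra(indir: str | Path) -> SpectraSet:
    """Read a cohort written by :func:`write_spectra` (lossless round trip)."""
    indir = Path(indir)
    spec_df = pd.read_csv(indir / "spectra.csv")
    bio = pd.read_csv(indir / "biochemistry.csv")
    ids = [c for c in spec_df.columns if c != "wavelength"]
    missing = set(ids) - set(bio["sample_id"])
    if missing:
        raise ValueError(f"biochemistry table missing sample(s): {sorted(missing)}")
    bio = bio.set_index("sample_id").loc[ids].reset_index()
    truth_path = indir / "truth_partitions.csv"
    truth = None
    if truth_path.exists():
        truth = pd.read_csv(truth_path).set_index("sample_id").loc[ids].reset_index()
    return SpectraSet(
        grid=SpectralGrid(spec_df["wavelength"].to_numpy(dtype=float)),
        sample_ids=ids,
        R=spec_df[ids].to_numpy(dtype=float),
        biochem=bio,
        truth=truth,
    )
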