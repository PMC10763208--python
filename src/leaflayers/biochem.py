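"""Wet-lab conversions from bench measurements to model biochemistry.

Chlorophyll is measured spectrophotometrically on a 95% ethanol extract
(absorbances at 665 and 649 nm), water and dry matter gravimetrically; leaf
area comes from length x width with a species-specific correction factor.
The outputs are exactly the quantities the forward model consumes: Cab in
ug cm^-2, Cw (equivalent water thickness) and Cm (dry matter) in g cm^-2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .forward import LeafBiochem

__all__ = [
    "LEAF_AREA_COEFF",
    "LabMeasurement",
    "leaf_area",
    "chlorophyll_ab",
    "chlorophyll_area_density",
    "equivalent_water_thickness",
    "dry_matter",
    "biochem_from_lab",
    "read_lab_sheet",
]

#: leaf-area correction coefficient for rice (area = length * width * coeff)
LEAF_AREA_COEFF = 0.7746


@dataclass(frozen=True)
class LabMeasurement:
    """One sample's bench measurements.

    ``leaf_len``/``leaf_wid`` in cm, absorbances dimensionless, masses in g,
    ``extract_volume`` in mL (the chlorophyll extract is made up to volume).
    """

    leaf_len: float
    leaf_wid: float
    A665: float
    A649: float
    fresh_mass: float
    dry_mass: float
    extract_volume: float = 50.0
    sample_mass_for_extract: float = 0.1

    def __post_init__(self) -> None:
        if self.leaf_len <= 0 or self.leaf_wid <= 0:
            raise ValueError("leaf dimensions must be positive")
        if self.A665 < 0 or self.A649 < 0:
            raise ValueError("absorbances must be nonnegative")
        if self.dry_mass > self.fresh_mass:
            raise ValueError("dry mass cannot exceed fresh mass")


def leaf_area(a: float, b: float) -> float:
    """Leaf area (cm^2) from maximum length and width (cm)."""
    if a <= 0 or b <= 0:
        raise ValueError("leaf dimensions must be positive")
    return a * b * LEAF_AREA_COEFF


def chlorophyll_ab(A665: float, A649: float) -> tuple[float, float]:
    """Chlorophyll a and b concentrations (mg L^-1) in a 95% ethanol extract.

    Ca = 13.95 A665 - 6.88 A649;  Cb = 24.96 A649 - 7.32 A665.
    Negative results (possible for extreme absorbance ratios) are clipped to
    zero with a warning.
    """
    if A665 < 0 or A649 < 0:
        raise ValueError("absorbances must be nonnegative")
    ca = 13.95 * A665 - 6.88 * A649
    cb = 24.96 * A649 - 7.32 * A665
    if ca < 0 or cb < 0:
        warnings.warn("negative chlorophyll concentration clipped to 0")
    return max(ca, 0.0), max(cb, 0.0)


def chlorophyll_area_density(
    ca: float, cb: float, extract_volume: float, leaf_area_equiv: float
) -> float:
    """Chlorophyll per leaf area, Cab in ug cm^-2.

    ``(Ca + Cb)`` mg L^-1 times the extract volume in mL is the extracted
    chlorophyll mass in ug; dividing by the leaf area the extract represents
    gives the areal density.
    """
    if leaf_area_equiv <= 0:
        raise ValueError("leaf area must be positive")
    return (ca + cb) * extract_volume / leaf_area_equiv


def equivalent_water_thickness(
    fresh_mass: float, dry_mass: float, area: float
) -> float:
    """Cw (g cm^-2): leaf water mass per unit area."""
    if dry_mass > fresh_mass:
        raise ValueError("dry mass cannot exceed fresh mass")
    if area <= 0:
        raise ValueError("leaf area must be positive")
    return (fresh_mass - dry_mass) / area


def dry_matter(dry_mass: float, area: float) -> float:
    """Cm (g cm^-2): dry matter per unit area."""
    if area <= 0:
        raise ValueError("leaf area must be positive")
    return dry_mass / area


def biochem_from_lab(m: LabMeasurement, N: float = 1.5) -> LeafBiochem:
    """Full conversion of one lab sheet row into forward-model inputs.

    The structure parameter ``N`` is not measurable at the bench; the caller
    supplies it (default 1.5, a typical monocot value).
    """
    area = leaf_area(m.leaf_len, m.leaf_wid)
    ca, cb = chlorophyll_ab(m.A665, m.A649)
    cab = chlorophyll_area_density(ca, cb, m.extract_volume, area)
    cw = equivalent_water_thickness(m.fresh_mass, m.dry_mass, area)
    cm = dry_matter(m.dry_mass, area)
    return LeafBiochem(N=N, cab=cab, cw=cw, cm=cm)


_LAB_COLUMNS = ("sample_id", "leaf_len", "leaf_wid", "A665", "A649",
                "fresh_mass", "dry_mass")


def read_lab_sheet(path, N: float = 1.5) -> pd.DataFrame:
    """Read a lab-sheet CSV and return the derived biochemistry table.

    Expected columns: sample_id, leaf_len, leaf_wid, A665, A649, fresh_mass,
    dry_mass and optionally extract_volume (default 50 mL).  Returns a
    DataFrame with columns sample_id, Cab, Cw, Cm, N.
    """
    df = pd.read_csv(path)
    missing = [c for c in _LAB_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lab sheet missing column(s): {', '.join(missing)}")
    rows = []
    for _, r in df.iterrows():
        m = LabMeasurement(
            leaf_len=r["leaf_len"],
            leaf_wid=r["leaf_wid"],
            A665=r["A665"],
            A649=r["A649"],
            fresh_mass=r["fresh_mass"],
            dry_mass=r["dry_mass"],
            extract_volume=r.get("extract_volume", 50.0),
        )
        b = biochem_from_lab(m, N=N)
        rows.append(
            {"sample_id": r["sample_id"], "Cab": b.cab, "Cw": b.cw, "Cm": b.cm, "N": b.N}
        )
    return pd.DataFrame(rows)
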