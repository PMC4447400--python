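"""Aperture-shape statistics for fossil "Globigerinoides" specimens.

Two dimensionless indices summarize the primary aperture of a specimen:

* PADR (primary aperture diameter ratio): maximum aperture width divided
  by aperture height. High values describe slit-like, elongated apertures
  (trilobus-like morphologies); low values describe high-arched, rounded
  apertures (ruber-like morphologies).
* SI (symmetry index): the larger of the two angles flanking the primary
  aperture divided by the smaller. SI = 1 is a perfectly symmetric
  aperture; SI is computed max/min regardless of column order, so it is
  always >= 1.

Both ratios are unit-free; measurements are taken as given (imaging and
landmark placement are upstream of this package).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .io_formats import MeasurementTable


@dataclass
class MorphospacePoint:
    """A specimen's position in (PADR, SI) morphospace."""

    specimen_id: str
    padr: float
    si: float
    zone: str = ""
    morphospecies: str = ""
    lineage: Optional[str] = None


def compute_padr(width: float, height: float) -> float:
    """Aperture width / height. Both arguments must be > 0 (micrometres)."""
    if width <= 0 or height <= 0:
        raise ValueError(
            f"width and height must be positive, got ({width}, {height})"
        )
    return width / height


def compute_si(angle_1: float, angle_2: float) -> float:
    """Larger flanking angle / smaller flanking angle (degrees in (0, 180)).

    Symmetric in its arguments and always >= 1; equals 1 iff the two
    angles are equal.
    """
    for a in (angle_1, angle_2):
        if not 0 < a < 180:
            raise ValueError(f"angles must lie in (0, 180), got {a}")
    hi, lo = (angle_1, angle_2) if angle_1 >= angle_2 else (angle_2, angle_1)
    return hi / lo


def build_morphospace(table: MeasurementTable) -> list[MorphospacePoint]:
    """Row-wise map of a validated measurement table into morphospace.

    Labels are carried through unchanged; output order equals input order.
    """
    points: list[MorphospacePoint] = []
    for row in table.data.itertuples(index=False):
        lineage = getattr(row, "lineage", None)
        if pd.isna(lineage):
            lineage = None
        points.append(
            MorphospacePoint(
                specimen_id=str(row.specimen_id),
                padr=compute_padr(row.width_um, row.height_um),
                si=compute_si(row.angle1_deg, row.angle2_deg),
                zone=str(row.zone),
                morphospecies=str(row.morphospecies),
                lineage=lineage,
            )
        )
    return points


def morphospace_frame(points: list[MorphospacePoint]) -> pd.DataFrame:
    """Tabular view of a morphospace (the CSV emitted by the pipeline)."""
    return pd.DataFrame(
        {
            "specimen_id": [p.specimen_id for p in points],
            "zone": [p.zone for p in points],
            "morphospecies": [p.morphospecies for p in points],
            "padr": [p.padr for p in points],
            "si": [p.si for p in points],
            "lineage": [p.lineage for p in points],
        }
    )
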