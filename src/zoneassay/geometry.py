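"""Parametric model of the three-section well-plate insert.

The insert that stamps the cell-free zone has three stacked sections: a
plus-shaped top (for pipette access and in-well imaging), a wide cylindrical
body that weighs the insert down, and a narrow cylindrical foot whose
footprint defines the circular cell-free zone on the well bottom.  All
dimensions are kept in millimetres; conversion to micrometres happens only at
the image boundary.

The module supplies the theoretical reference values (stack height, nominal
zone area) against which measured areas are validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class InsertGeometry:
    """Dimensions of the three-section insert, in millimetres.

    Attributes
    ----------
    top_length_mm:
        Arm span of the plus-shaped top section (sized to the well diameter
        so the insert cannot shift sideways).
    top_height_mm, mid_height_mm, bottom_height_mm:
        Heights of the three stacked sections.
    mid_diameter_mm:
        Diameter of the cylindrical body.
    bottom_diameter_mm:
        Diameter of the cylindrical foot; equals the diameter of the
        cell-free zone it stamps.
    """

    top_length_mm: float = 16.0
    top_height_mm: float = 3.0
    mid_diameter_mm: float = 9.0
    mid_height_mm: float = 10.0
    bottom_diameter_mm: float = 5.0
    bottom_height_mm: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "top_length_mm",
            "top_height_mm",
            "mid_diameter_mm",
            "mid_height_mm",
            "bottom_diameter_mm",
            "bottom_height_mm",
        ):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not self.bottom_diameter_mm < self.mid_diameter_mm:
            raise ValueError(
                "bottom_diameter_mm must be smaller than mid_diameter_mm "
                f"({self.bottom_diameter_mm} >= {self.mid_diameter_mm})"
            )


#: Default insert as used throughout: 16 mm plus top (3 mm high), 9 mm body
#: (10 mm high), 5 mm foot (4 mm high) -> 17 mm stack, 19.6 mm^2 zone.
DEFAULT_INSERT = InsertGeometry()


def total_height(geom: InsertGeometry) -> float:
    """Overall stack height of the insert in mm (sum of the three sections)."""
    return geom.top_height_mm + geom.mid_height_mm + geom.bottom_height_mm


def theoretical_zone_area(diameter_mm: float) -> float:
    """Nominal area (mm^2) of the circular cell-free zone, pi*d^2/4.

    Parameters
    ----------
    diameter_mm:
        Zone diameter in mm; must be non-negative.
    """
    if diameter_mm < 0:
        raise ValueError(f"diameter_mm must be >= 0, got {diameter_mm!r}")
    return math.pi * diameter_mm**2 / 4.0


def equivalent_diameter_mm(area_mm2: float) -> float:
    """Diameter (mm) of the circle with the given area: 2*sqrt(A/pi)."""
    if area_mm2 < 0:
        raise ValueError(f"area_mm2 must be >= 0, got {area_mm2!r}")
    return 2.0 * math.sqrt(area_mm2 / math.pi)
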