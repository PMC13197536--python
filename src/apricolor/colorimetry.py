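"""CIELAB hue-angle phenotyping of apricot fruit skin color.

Colorimeter readings (L*, a*, b*) are converted to the hue angle
h° = atan2(b*, a*) in degrees, replicate measurements are aggregated per
individual, and the mean hue is mapped onto the three skin-color classes
used for marker validation: orange (h° < 77), light orange (77 ≤ h° ≤ 83)
and yellow (h° > 83).  The seven UPOV peel base-color descriptor
categories collapse onto the same three classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HueClass",
    "UpovCategory",
    "ColorMeasurement",
    "PhenotypeRecord",
    "UndefinedHueError",
    "hue_angle",
    "classify_hue",
    "upov_to_class",
    "aggregate_replicates",
    "phenotype_table",
]

#: Hue-angle boundary between orange and light orange (degrees).
ORANGE_MAX_HUE = 77.0
#: Hue-angle boundary between light orange and yellow (degrees).
YELLOW_MIN_HUE = 83.0


class HueClass(str, Enum):
    """Three-class skin-color phenotype derived from the hue angle."""

    ORANGE = "orange"
    LIGHT_ORANGE = "light_orange"
    YELLOW = "yellow"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class UpovCategory(str, Enum):
    """UPOV peel base-color descriptor categories (TG/70/5)."""

    NOT_VISIBLE = "not_visible"
    WHITE = "white"
    YELLOWISH = "yellowish"
    YELLOW_GREEN = "yellow_green"
    LIGHT_ORANGE = "light_orange"
    MEDIUM_ORANGE = "medium_orange"
    DARK_ORANGE = "dark_orange"


_UPOV_GROUPING = {
    UpovCategory.NOT_VISIBLE: HueClass.YELLOW,
    UpovCategory.WHITE: HueClass.YELLOW,
    UpovCategory.YELLOWISH: HueClass.YELLOW,
    UpovCategory.YELLOW_GREEN: HueClass.YELLOW,
    UpovCategory.LIGHT_ORANGE: HueClass.LIGHT_ORANGE,
    UpovCategory.MEDIUM_ORANGE: HueClass.ORANGE,
    UpovCategory.DARK_ORANGE: HueClass.ORANGE,
}


class UndefinedHueError(ValueError):
    """Raised when the hue angle is requested at the achromatic point a*=b*=0."""


@dataclass(frozen=True)
class ColorMeasurement:
    """One colorimeter reading on one side of one fruit.

    ``L`` is CIELAB lightness in [0, 100]; ``a`` and ``b`` are the
    red–green and yellow–blue opponent axes (unitless).
    """

    individual_id: str
    fruit_index: int
    side_index: int
    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.L <= 100.0):
            raise ValueError(f"L*={self.L} outside [0, 100]")
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("a* and b* must be finite")

    @property
    def hue(self) -> float:
        return hue_angle(self.a, self.b)


@dataclass(frozen=True)
class PhenotypeRecord:
    """Aggregated hue phenotype of one individual."""

    individual_id: str
    hue_mean: float
    hue_sd: float
    n_measurements: int
    hue_class: HueClass


def hue_angle(a: float, b: float) -> float:
    """Hue angle h° in degrees from CIELAB a* (red–green) and b* (yellow–blue).

    Computed as the two-argument arctangent atan2(b*, a*) wrapped to
    [0, 360), so quadrants with a* ≤ 0 are well defined.  For fruit skin
    in the orange–yellow range (a* > 0, b* > 0) the result lies in (0, 90).

    Raises
    ------
    UndefinedHueError
        If both a* and b* are zero (achromatic; hue undefined).
    """
    if a == 0.0 and b == 0.0:
        raise UndefinedHueError("hue angle undefined at a*=b*=0")
    h = math.degrees(math.atan2(b, a)) % 360.0
    # a negative angle of vanishing magnitude can round to exactly 360.0
    return 0.0 if h == 360.0 else h


def classify_hue(h: float) -> HueClass:
    """Map a hue angle (degrees, [0, 360)) onto the three-class phenotype.

    orange for h° < 77, yellow for h° > 83, light orange in between.
    The boundary values 77 and 83 fall in the transitional light-orange
    class (the defining inequalities are strict on both sides).
    """
    if not (0.0 <= h < 360.0):
        raise ValueError(f"hue angle {h} outside [0, 360)")
    if h < ORANGE_MAX_HUE:
        return HueClass.ORANGE
    if h > YELLOW_MIN_HUE:
        return HueClass.YELLOW
    return HueClass.LIGHT_ORANGE


def upov_to_class(category: UpovCategory | str) -> HueClass:
    """Collapse a UPOV peel base-color category onto the three-class phenotype.

    not_visible/white/yellowish/yellow_green group as yellow; light_orange
    is kept; medium_orange and dark_orange group as orange.
    """
    try:
        category = UpovCategory(category)
    except ValueError:
        raise ValueError(f"unknown UPOV category: {category!r}") from None
    return _UPOV_GROUPING[category]


def aggregate_replicates(measurements: Sequence[ColorMeasurement]) -> PhenotypeRecord:
    """Aggregate replicate colorimeter readings of one individual.

    The hue angle is computed per measurement and then averaged; the
    spread is the sample (n-1) standard deviation, reported as 0 for a
    single measurement.  The class is assigned from the mean hue.
    """
    if len(measurements) == 0:
        raise ValueError("no measurements to aggregate")
    ids = {m.individual_id for m in measurements}
    if len(ids) != 1:
        raise ValueError(f"measurements mix individuals: {sorted(ids)}")
    keys = [(m.fruit_index, m.side_index) for m in measurements]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (fruit, side) replicate for one individual")
    hues = np.array([m.hue for m in measurements], dtype=float)
    mean = float(hues.mean())
    sd = float(hues.std(ddof=1)) if hues.size > 1 else 0.0
    return PhenotypeRecord(
        individual_id=next(iter(ids)),
        hue_mean=mean,
        hue_sd=sd,
        n_measurements=len(measurements),
        hue_class=classify_hue(mean),
    )


def phenotype_table(colorimeter: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a colorimeter table into a per-individual phenotype table.

    Parameters
    ----------
    colorimeter
        Table with columns ``individual_id, fruit, side, L, a, b`` (one
        row per reading).

    Returns
    -------
    DataFrame with columns ``individual_id, hue_mean, hue_sd, n, hue_class``
    in first-appearance order of the individuals.
    """
    required = {"individual_id", "fruit", "side", "L", "a", "b"}
    missing = required - set(colorimeter.columns)
    if missing:
        raise ValueError(f"colorimeter table missing columns: {sorted(missing)}")
    rows = []
    for ind, grp in colorimeter.groupby("individual_id", sort=False):
        ms = [
            ColorMeasurement(str(ind), int(r.fruit), int(r.side), float(r.L), float(r.a), float(r.b))
            for r in grp.itertuples(index=False)
        ]
        rec = aggregate_replicates(ms)
        rows.append(
            {
                "individual_id": rec.individual_id,
                "hue_mean": rec.hue_mean,
                "hue_sd": rec.hue_sd,
                "n": rec.n_measurements,
                "hue_class": rec.hue_class.value,
            }
        )
    return pd.DataFrame(rows)
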