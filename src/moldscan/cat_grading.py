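"""Catalase (CAT) activity from permanganate titration and mold-level grading.

CAT activity is the volume of 0.005 mol/L potassium permanganate consumed
per gram of sample per hour:

    value = (V1 - V2) / (M * T)        [mL/(h*g)]

where V1/V2 are the control/sample titration volumes (mL), M the sample
mass (g) and T the unit time (h).  Mold levels are assigned from the CAT
value: healthy at (numerically) zero, then mild/moderate/severe by interval
membership against increasing cut points.  The default cut points are the
midpoints between the adjacent grading-class means (1.57, 1.91, 2.24),
i.e. 1.74 and 2.075; values on a cut point grade to the higher level
(conservative for food safety).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import LEVELS

HEALTHY_EPS = 1e-6
DEFAULT_CUTS = (HEALTHY_EPS, (1.57 + 1.91) / 2, (1.91 + 2.24) / 2)


@dataclass
class TitrationRecord:
    """One titration measurement: control volume, sample volume, mass, time."""

    v1: float
    v2: float
    mass: float
    time: float

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.time <= 0:
            raise ValueError("sample mass and unit time must be positive")
        if self.v2 < 0 or self.v1 < self.v2:
            raise ValueError("need V1 >= V2 >= 0 (negative activity is nonphysical)")


@dataclass
class MoldLevelAssignment:
    value: float
    level: str
    thresholds: tuple[float, float, float]


def cat_activity(rec: TitrationRecord) -> float:
    """CAT activity value in mL/(h*g) from a titration record."""
    return (rec.v1 - rec.v2) / (rec.mass * rec.time)


def assign_level(value: float, thresholds=DEFAULT_CUTS) -> MoldLevelAssignment:
    """Grade a CAT value into healthy/mild/moderate/severe.

    Intervals are right-open: ``value <= eps0`` is healthy, then
    ``(eps0, c1)`` mild, ``[c1, c2)`` moderate, ``[c2, inf)`` severe — a
    value exactly on a cut point takes the higher level.
    """
    eps0, c1, c2 = thresholds
    if not (0 < eps0 < c1 < c2):
        raise ValueError("thresholds must be strictly increasing and positive")
    if value < 0:
        raise ValueError("CAT activity cannot be negative")
    if value <= eps0:
        level = LEVELS[0]
    elif value < c1:
        level = LEVELS[1]
    elif value < c2:
        level = LEVELS[2]
    else:
        level = LEVELS[3]
    return MoldLevelAssignment(float(value), level, tuple(thresholds))


def assign_levels(values, thresholds=DEFAULT_CUTS) -> np.ndarray:
    """Vectorized grading of many CAT values."""
    return np.array([assign_level(float(v), thresholds).level for v in np.asarray(values)])
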