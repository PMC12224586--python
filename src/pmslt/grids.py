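"""Age-by-sex grids and the fixed stratifications used throughout the model.

Everything downstream of preprocessing lives on a single-year-of-age grid,
ages 0 through 100 (the 100 bin absorbs 100+), stratified by sex.  The
coarser stratifications mirror the granularity of the usual national data
sources: 5-year vital-statistics groups, Dietary Reference Intake (DRI)
age/sex groups for sodium, survey blood-pressure bands, burden-of-illness
cost bands, and 10-year utility bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_AGE = 100
N_AGES = MAX_AGE + 1
AGES = np.arange(N_AGES)

SEXES = ("male", "female")
SEX_INDEX = {s: k for k, s in enumerate(SEXES)}

DISEASES = ("ihd", "stroke")

#: DRI adult age/sex groups used to stratify sodium intake (19-30, 31-50,
#: 51-70, 71+); ages below 19 receive no dietary intervention.
DRI_BANDS = ((19, 30), (31, 50), (51, 70), (71, MAX_AGE))
DRI_LABELS = ("19-30", "31-50", "51-70", "71+")

#: Survey blood-pressure bands; 80+ is filled by carrying the 60-79 value
#: forward (no measurements above 79 in the source survey).
SBP_BANDS = ((6, 11), (12, 19), (20, 39), (40, 59), (60, 79), (80, MAX_AGE))

#: Burden-of-illness cost bands (0-14, 15-34, 35-54, 55-64, 65-74, 75+).
COST_BANDS = ((0, 14), (15, 34), (35, 54), (55, 64), (65, 74), (75, MAX_AGE))

#: 10-year bands carrying background utility weights.
UTILITY_BANDS = tuple((lo, MAX_AGE if lo == 90 else lo + 9) for lo in range(0, 100, 10))


def band_of(age: int, bands) -> int | None:
    """Index of the band containing ``age`` (closed intervals), or None."""
    for k, (lo, hi) in enumerate(bands):
        if lo <= age <= hi:
            return k
    return None


def dri_group_of(age: int) -> int | None:
    return band_of(age, DRI_BANDS)


@dataclass
class AgeSexGrid:
    """A value per single year of age (0-100) per sex.

    The universal carrier for rates, counts, costs and utilities.  ``values``
    has shape (101, 2) with the sex axis ordered as :data:`SEXES`.
    """

    values: np.ndarray = field(default_factory=lambda: np.zeros((N_AGES, len(SEXES))))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_AGES, len(SEXES)):
            raise ValueError(f"expected shape {(N_AGES, len(SEXES))}, got {self.values.shape}")

    @classmethod
    def from_columns(cls, **by_sex: np.ndarray) -> "AgeSexGrid":
        vals = np.zeros((N_AGES, len(SEXES)))
        for sex, col in by_sex.items():
            vals[:, SEX_INDEX[sex]] = np.asarray(col, dtype=float)
        return cls(vals)

    @classmethod
    def full(cls, value: float) -> "AgeSexGrid":
        return cls(np.full((N_AGES, len(SEXES)), float(value)))

    def sex(self, sex: str) -> np.ndarray:
        """1-D view (length 101) of one sex's column."""
        return self.values[:, SEX_INDEX[sex]]

    def __getitem__(self, key):
        age, sex = key
        return self.values[age, SEX_INDEX[sex]]

    def total(self) -> float:
        return float(self.values.sum())

    def copy(self) -> "AgeSexGrid":
        return AgeSexGrid(self.values.copy())

    def to_frame(self, value_name: str = "value") -> pd.DataFrame:
        rows = []
        for sex in SEXES:
            rows.append(pd.DataFrame({"age": AGES, "sex": sex, value_name: self.sex(sex)}))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, value_name: str = "value") -> "AgeSexGrid":
        grid = cls()
        for sex in SEXES:
            sub = frame[frame["sex"] == sex].sort_values("age")
            if len(sub) != N_AGES:
                raise ValueError(f"expected {N_AGES} ages for sex {sex!r}, got {len(sub)}")
            grid.values[:, SEX_INDEX[sex]] = sub[value_name].to_numpy(dtype=float)
        return grid
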