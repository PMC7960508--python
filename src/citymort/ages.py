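"""Fixed age grids shared by every stage of the pipeline.

Mortality is tabulated on the standard 17-group abridged scheme
(0, 1-4, then 5-year groups up to the open-ended 75+ interval).
The death-distribution methods operate on the coarser 16-group grid
obtained by collapsing ages 0 and 1-4 into 0-4.
"""

from __future__ import annotations

import numpy as np

#: The 17 abridged age-group labels, in order.
AGE_GROUPS: tuple[str, ...] = (
    "0",
    "1-4",
    "5-9",
    "10-14",
    "15-19",
    "20-24",
    "25-29",
    "30-34",
    "35-39",
    "40-44",
    "45-49",
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75+",
)

N_AGE = len(AGE_GROUPS)

#: Lower bound of each group in exact years.
AGE_LOWER = np.array(
    [0, 1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75], dtype=float
)

#: Interval width in years; the open interval is infinite.
AGE_WIDTH = np.array(
    [1, 4, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, np.inf], dtype=float
)

#: Midpoints used when evaluating parametric hazards; the open 75+ group
#: uses a nominal midpoint of 82.5 years.
AGE_MID = np.array(
    [0.5, 3.0, 7.5, 12.5, 17.5, 22.5, 27.5, 32.5, 37.5, 42.5, 47.5, 52.5,
     57.5, 62.5, 67.5, 72.5, 82.5]
)

#: 16-group grid for the death-distribution methods: 0-4, 5-9, ..., 75+.
DDM_AGE_LOWER = np.arange(0, 80, 5, dtype=float)
DDM_AGE_GROUPS: tuple[str, ...] = tuple(
    f"{int(a)}-{int(a) + 4}" for a in DDM_AGE_LOWER[:-1]
) + ("75+",)

SEXES: tuple[str, ...] = ("F", "M")

#: Substantive cause groups (Global Health Estimates style, collapsed).
DISEASE_CAUSES: tuple[str, ...] = ("CMNN", "CANCER", "CVD_NCD")
INJURY_CAUSES: tuple[str, ...] = ("UNINTENTIONAL", "VIOLENT")
CAUSE_GROUPS: tuple[str, ...] = DISEASE_CAUSES + INJURY_CAUSES

#: Ill-defined codes that the preprocessing stage redistributes.
ILLDEF_DISEASE = "ILLDEF_DISEASE"
ILLDEF_INJURY = "ILLDEF_INJURY"
ALL_CAUSE_LABELS: tuple[str, ...] = CAUSE_GROUPS + (ILLDEF_DISEASE, ILLDEF_INJURY)

MISSING = "missing"

_AGE_INDEX = {a: i for i, a in enumerate(AGE_GROUPS)}


def age_index(label: str) -> int:
    """Position of an age-group label in the 17-group scheme."""
    return _AGE_INDEX[label]


def collapse_to_ddm(values_17: np.ndarray) -> np.ndarray:
    """Collapse a length-17 vector (ages 0 and 1-4 separate) to the
    16-group 0-4, ..., 75+ grid by summing the first two entries."""
    v = np.asarray(values_17, dtype=float)
    if v.shape[-1] != N_AGE:
        raise ValueError(f"expected last dimension {N_AGE}, got {v.shape[-1]}")
    return np.concatenate([v[..., :1] + v[..., 1:2], v[..., 2:]], axis=-1)
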