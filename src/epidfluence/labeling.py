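"""Classification labels for 3D setup errors.

Three label types drive the downstream classifiers:

* ``type1``  — binary: is the isocenter error (Euclidean norm of the 3D
  shift) over 3 mm?  1 = no, 2 = yes.
* ``type2``  — three binary labels, one per axis: is the LR / SI / AP
  component over 3 mm?
* ``type3``  — 8-way joint label encoding *which* axes are over 3 mm.

The 3 mm boundary is strict (exactly 3.00 mm counts as "not over").  The
type-3 class numbering is fixed:

====== =======================
class  axes over 3 mm
====== =======================
1      none
2      LR only
3      AP only
4      SI only
5      LR + AP
6      LR + SI
7      SI + AP
8      LR + SI + AP
====== =======================
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import ErrorVector

#: Decision boundary in mm; strictly greater counts as an error.
THRESHOLD_MM = 3.0

# (lr>3, si>3, ap>3) -> type-3 class
_TYPE3_CODE = {
    (False, False, False): 1,
    (True, False, False): 2,
    (False, False, True): 3,
    (False, True, False): 4,
    (True, False, True): 5,
    (True, True, False): 6,
    (False, True, True): 7,
    (True, True, True): 8,
}
_TYPE3_FLAGS = {v: k for k, v in _TYPE3_CODE.items()}

# The 27 error positions in their canonical serial order (serials 2-28;
# serial 1 is the baseline acquisition without an injected error).
# Each entry is (serial, direction group, (lr_mm, si_mm, ap_mm)).
SERIAL_TABLE: list[tuple[int, str, tuple[float, float, float]]] = [
    (2, "None", (0, 0, 0)),
    (3, "Single Direction", (2, 0, 0)),
    (4, "Single Direction", (4, 0, 0)),
    (5, "Single Direction", (0, 2, 0)),
    (6, "Single Direction", (0, 4, 0)),
    (7, "Single Direction", (0, 0, 2)),
    (8, "Single Direction", (0, 0, 4)),
    (9, "Double Directions", (2, 0, 4)),
    (10, "Double Directions", (4, 0, 4)),
    (11, "Double Directions", (4, 0, 2)),
    (12, "Double Directions", (2, 0, 2)),
    (13, "Double Directions", (2, 2, 0)),
    (14, "Double Directions", (2, 4, 0)),
    (15, "Double Directions", (4, 4, 0)),
    (16, "Double Directions", (4, 2, 0)),
    (17, "Double Directions", (0, 2, 2)),
    (18, "Double Directions", (0, 2, 4)),
    (19, "Double Directions", (0, 4, 4)),
    (20, "Double Directions", (0, 4, 2)),
    (21, "Triple Directions", (2, 2, 2)),
    (22, "Triple Directions", (2, 2, 4)),
    (23, "Triple Directions", (2, 4, 4)),
    (24, "Triple Directions", (2, 4, 2)),
    (25, "Triple Directions", (4, 4, 2)),
    (26, "Triple Directions", (4, 2, 2)),
    (27, "Triple Directions", (4, 2, 4)),
    (28, "Triple Directions", (4, 4, 4)),
]


@dataclass(frozen=True)
class LabelSet:
    """All classification labels for one error vector."""

    type1: int
    type2_lr: int
    type2_si: int
    type2_ap: int
    type3: int
    isocenter_mm: float

    def as_dict(self) -> dict[str, float]:
        return {
            "type1": self.type1,
            "type2_lr": self.type2_lr,
            "type2_si": self.type2_si,
            "type2_ap": self.type2_ap,
            "type3": self.type3,
            "isocenter_mm": self.isocenter_mm,
        }


def isocenter_error(e: ErrorVector) -> float:
    """Euclidean magnitude sqrt(lr^2 + si^2 + ap^2) of the shift, in mm."""
    return e.isocenter_mm


def assign_labels(e: ErrorVector, threshold_mm: float = THRESHOLD_MM) -> LabelSet:
    """Assign type-1/2/3 labels to an error vector.

    The boundary is exclusive: a component (or isocenter error) of exactly
    ``threshold_mm`` falls in the "no error" class.
    """
    iso = e.isocenter_mm
    flags = (e.lr_mm > threshold_mm, e.si_mm > threshold_mm, e.ap_mm > threshold_mm)
    return LabelSet(
        type1=2 if iso > threshold_mm else 1,
        type2_lr=2 if flags[0] else 1,
        type2_si=2 if flags[1] else 1,
        type2_ap=2 if flags[2] else 1,
        type3=_TYPE3_CODE[flags],
        isocenter_mm=iso,
    )


def type3_to_axis_flags(type3: int) -> tuple[bool, bool, bool]:
    """Decode a type-3 class back into (lr>3, si>3, ap>3) flags."""
    return _TYPE3_FLAGS[int(type3)]


def build_label_table() -> pd.DataFrame:
    """Enumerate the 27 error positions with serials, isocenter errors and labels.

    Isocenter errors are rounded to two decimals, matching the printed
    convention (e.g. sqrt(8) -> 2.83, sqrt(12) -> 3.46, sqrt(48) -> 6.93).
    """
    rows = []
    for serial, group, (lr, si, ap) in SERIAL_TABLE:
        e = ErrorVector(lr, si, ap)
        lab = assign_labels(e)
        rows.append(
            {
                "direction": group,
                "serial": serial,
                "lr_mm": lr,
                "si_mm": si,
                "ap_mm": ap,
                "isocenter_mm": round(lab.isocenter_mm, 2),
                "type1": lab.type1,
                "type2_lr": lab.type2_lr,
                "type2_si": lab.type2_si,
                "type2_ap": lab.type2_ap,
                "type3": lab.type3,
            }
        )
    return pd.DataFrame(rows)
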