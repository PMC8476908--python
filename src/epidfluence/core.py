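"""Core containers: error vectors and fluence maps.

Coordinate conventions used throughout the package:

* Patient axes: LR (left-right, x), AP (anterior-posterior, y),
  SI (superior-inferior, z).  A coplanar arc rotates the gantry in the
  LR-AP plane, so SI is perpendicular to the rotation plane.
* Image axes: row index runs along the SI imager axis, column index along
  the in-plane axis perpendicular to the beam.  Origin top-left, row-major.
* Dose values are in cGy on the fraction-dose scale (200 cGy full fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Default detector pixel pitch in mm (as1200-class imager).
DEFAULT_PITCH_MM = 0.336

#: Fraction dose in cGy; also the ``L`` dynamic-range constant of the
#: structural-similarity computation.
FRACTION_DOSE_CGY = 200.0


@dataclass(frozen=True)
class ErrorVector:
    """A 3D translational setup error in patient coordinates (mm)."""

    lr_mm: float = 0.0
    si_mm: float = 0.0
    ap_mm: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.lr_mm, self.si_mm, self.ap_mm):
            if not math.isfinite(v):
                raise ValueError(f"error components must be finite, got {self}")

    @property
    def isocenter_mm(self) -> float:
        """Euclidean magnitude of the 3D error (the isocenter error)."""
        return math.sqrt(self.lr_mm**2 + self.si_mm**2 + self.ap_mm**2)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.lr_mm, self.si_mm, self.ap_mm)

    def __iter__(self):
        return iter(self.as_tuple())


@dataclass
class FluenceMap:
    """A 2D transmission fluence (portal dose) image.

    Parameters
    ----------
    pixels
        ``(H, W)`` array of dose values in cGy, all non-negative.
    pitch_mm
        Detector pixel pitch in mm (square pixels).
    patient_id
        Identifier of the patient/plan the map belongs to.
    error
        The setup error injected when the map was acquired (``None`` for
        externally supplied maps of unknown provenance).
    meta
        Free-form acquisition metadata.
    validate
        When true (default) the full-size invariants are enforced:
        H, W >= 512 so the 512x512 analysis crop exists.
    """

    pixels: np.ndarray
    pitch_mm: float = DEFAULT_PITCH_MM
    patient_id: str = ""
    error: ErrorVector | None = None
    meta: dict[str, Any] = field(default_factory=dict)
    validate: bool = True

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if self.pitch_mm <= 0:
            raise ValueError(f"pixel pitch must be positive, got {self.pitch_mm}")
        if self.pixels.size and float(self.pixels.min()) < 0:
            raise ValueError("fluence maps must be non-negative everywhere")
        if self.validate:
            h, w = self.pixels.shape
            if h < 512 or w < 512:
                raise ValueError(
                    f"fluence maps must be at least 512x512, got {h}x{w}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def as_pixels(image: "FluenceMap | np.ndarray") -> np.ndarray:
    """Return the pixel matrix of a map-like object as a float array.

    Floating dtypes pass through unchanged (simulated maps are float32
    for speed; analyses fed float64 stay float64), anything else is
    promoted to float64.
    """
    a = image.pixels if isinstance(image, FluenceMap) else image
    a = np.asarray(a)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float64)
    return a
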