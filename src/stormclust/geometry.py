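"""Rectangular analysis regions for localization fields.

All coordinates in this package are continuous 2D positions in nanometres,
with the origin at the lower-left corner of the field. A field is either
``open`` (a plain crop of a larger sample) or ``toroidal`` (periodic; used
for synthetic fields so spatial statistics need no edge correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

NM_PER_UM = 1000.0
NM2_PER_UM2 = NM_PER_UM**2


@dataclass(frozen=True)
class FieldGeometry:
    """Rectangular field of ``width`` x ``height`` nm.

    Parameters
    ----------
    width, height : float
        Field extent in nm; must be positive.
    boundary : {"open", "toroidal"}
        Boundary topology. Toroidal fields wrap coordinates periodically.
    """

    width: float
    height: float
    boundary: str = "open"

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValidationError("field width and height must be positive")
        if self.boundary not in ("open", "toroidal"):
            raise ValidationError(f"unknown boundary mode {self.boundary!r}")

    @property
    def area_nm2(self) -> float:
        return self.width * self.height

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / NM2_PER_UM2

    @property
    def is_toroidal(self) -> bool:
        return self.boundary == "toroidal"

    @classmethod
    def square_um(cls, side_um: float, boundary: str = "open") -> "FieldGeometry":
        side = side_um * NM_PER_UM
        return cls(side, side, boundary)

    def wrap(self, xy: np.ndarray) -> np.ndarray:
        """Wrap positions into the field (toroidal only)."""
        box = np.array([self.width, self.height])
        return np.mod(xy, box)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return (
            (xy[..., 0] >= 0)
            & (xy[..., 0] <= self.width)
            & (xy[..., 1] >= 0)
            & (xy[..., 1] <= self.height)
        )

    def pairwise_displacement(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Displacement b - a under the field's metric (minimum image if toroidal)."""
        d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
        if self.is_toroidal:
            box = np.array([self.width, self.height])
            d = d - box * np.round(d / box)
        return d

    def distance(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Euclidean distance under the field's metric."""
        d = self.pairwise_displacement(a, b)
        return np.sqrt(np.sum(d * d, axis=-1))

    @staticmethod
    def from_bounding_box(xy: np.ndarray, boundary: str = "open") -> "FieldGeometry":
        """Smallest whole-micrometre field containing all points."""
        xy = np.asarray(xy, dtype=float)
        if xy.size == 0:
            return FieldGeometry(NM_PER_UM, NM_PER_UM, boundary)
        hi = xy.max(axis=0)
        width = max(np.ceil(hi[0] / NM_PER_UM), 1.0) * NM_PER_UM
        height = max(np.ceil(hi[1] / NM_PER_UM), 1.0) * NM_PER_UM
        return FieldGeometry(width, height, boundary)
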