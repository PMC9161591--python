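"""Core image containers: CT volumes, binary masks and region label maps.

Arrays are stored in ``(z, y, x)`` index order with ``z`` running from the
most superior slice (index 0) toward the inferior direction.  Spacing is the
matching ``(dz, dy, dx)`` voxel size in millimetres.  Intensities are
Hounsfield units (HU): air is about -1000 HU, water 0 HU, soft tissue
around +40 HU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AXIS_CONVENTION",
    "CTVolume",
    "Mask3D",
    "RegionLabelMap",
    "LOBE_NAMES",
    "DEFAULT_LABELS",
]

AXIS_CONVENTION = "zyx, z=0 superior"

#: The five lung lobes, in the reporting order used throughout the package.
LOBE_NAMES = (
    "right_upper_lobe",
    "right_middle_lobe",
    "right_lower_lobe",
    "left_upper_lobe",
    "left_lower_lobe",
)

#: Default integer codes for the region label map.
DEFAULT_LABELS = {
    "background": 0,
    "right_upper_lobe": 1,
    "right_middle_lobe": 2,
    "right_lower_lobe": 3,
    "left_upper_lobe": 4,
    "left_lower_lobe": 5,
    "airway": 6,
}


@dataclass
class CTVolume:
    """A 3-D CT intensity grid in Hounsfield units.

    Parameters
    ----------
    intensities
        3-D array of HU values, ``(z, y, x)`` order.
    spacing
        Voxel size ``(dz, dy, dx)`` in mm, all strictly positive.
    axis_convention
        Free-text record of the axis order and superior/inferior direction.
    window_level, window_width
        Display metadata (lung window is typically level -600 HU, width
        1500 HU).  Stored for provenance; never used in computation.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    axis_convention: str = AXIS_CONVENTION
    window_level: float | None = None
    window_width: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass
class Mask3D:
    """A binary grid aligned to a :class:`CTVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def volume_ml(self) -> float:
        """Mask volume in millilitres (1 mL = 1000 mm^3)."""
        return float(self.data.sum()) * self.voxel_volume_mm3 / 1000.0

    def check_aligned(self, ct: "CTVolume") -> None:
        if self.shape != ct.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match volume shape {ct.shape}"
            )


@dataclass
class RegionLabelMap:
    """Integer lobe/airway labels on the CT grid.

    ``labels`` maps region names (the five lobes, ``airway``, ``background``)
    to integer codes.  Lobe labels are mutually exclusive by construction of
    the integer grid.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    labels: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must hold integers")
        if self.data.ndim != 3:
            raise ValueError("label map must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        known = set(self.labels.values())
        present = set(np.unique(self.data).tolist())
        if not present <= known:
            raise ValueError(f"unknown label codes {sorted(present - known)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask_for(self, region: str) -> np.ndarray:
        """Boolean mask of a named region."""
        return self.data == self.labels[region]

    def lobe_code(self, lobe: str) -> int:
        if lobe not in LOBE_NAMES:
            raise KeyError(f"{lobe!r} is not a lobe")
        return self.labels[lobe]
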