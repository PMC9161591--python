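"""HU-threshold lung volumetry.

The lung is defined as the set of voxels whose CT number lies in a fixed
Hounsfield window (default -1000 HU to 0 HU, both ends inclusive) *inside
the patient's body*.  The body restriction is what separates lung air from
the exterior air surrounding the patient, which falls in the same HU range.
Soft-tissue structures — chest wall, mediastinum, large vessels — sit above
0 HU and are excluded by the threshold itself; the conducting airways down
to roughly the tertiary bronchi are removed explicitly, either from a label
map or by region growing from a tracheal seed.

Volumes are reported per lobe (given a lobe label map) in millilitres, with
right/left lung, upper/lower-lobe and total-lung aggregates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import AlignmentError, DegenerateInputError, SeedError
from .image import CTVolume, LOBE_NAMES, Mask3D, RegionLabelMap

__all__ = [
    "HU_LUNG_LOW",
    "HU_LUNG_HIGH",
    "VolumeReport",
    "extract_body_mask",
    "extract_lung_mask",
    "exclude_airways",
    "resample_slices",
    "compute_volumes",
]

#: Whole-lung HU window, inclusive on both ends.
HU_LUNG_LOW = -1000.0
HU_LUNG_HIGH = 0.0

#: Regions reported by :func:`compute_volumes`, in output order.
REPORT_REGIONS = (
    "total_lung",
    "right_lung",
    "right_upper_lobe",
    "right_middle_lobe",
    "right_lower_lobe",
    "left_lung",
    "left_upper_lobe",
    "left_lower_lobe",
    "upper_lobes",
    "lower_lobes",
)

_AGGREGATES = {
    "right_lung": ("right_upper_lobe", "right_middle_lobe", "right_lower_lobe"),
    "left_lung": ("left_upper_lobe", "left_lower_lobe"),
    "upper_lobes": ("right_upper_lobe", "left_upper_lobe"),
    "lower_lobes": ("right_lower_lobe", "left_lower_lobe"),
    "total_lung": LOBE_NAMES,
}


@dataclass
class VolumeReport:
    """Per-region lung volumes in mL, plus optional standardised percentages.

    ``volumes_ml`` always contains the five lobes; aggregate entries are the
    exact sums of their constituent lobes.  ``standardized_pct`` is filled by
    :func:`ctlungvol.scoring.standardized_lv`.
    """

    volumes_ml: dict[str, float]
    standardized_pct: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_lobes(cls, lobe_ml: dict[str, float]) -> "VolumeReport":
        """Build a report from the five lobe volumes, deriving all aggregates."""
        missing = [l for l in LOBE_NAMES if l not in lobe_ml]
        if missing:
            raise ValueError(f"missing lobes {missing}")
        if any(v < 0 for v in lobe_ml.values()):
            raise ValueError("volumes must be non-negative")
        vols = {l: float(lobe_ml[l]) for l in LOBE_NAMES}
        for agg, parts in _AGGREGATES.items():
            vols[agg] = float(sum(vols[p] for p in parts))
        return cls(volumes_ml={r: vols[r] for r in REPORT_REGIONS})

    def __getitem__(self, region: str) -> float:
        return self.volumes_ml[region]

    @property
    def total_ml(self) -> float:
        return self.volumes_ml["total_lung"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": r,
                "volume_mL": self.volumes_ml[r],
                "standardized_pct": self.standardized_pct.get(r, np.nan),
            }
            for r in REPORT_REGIONS
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VolumeReport":
        df = pd.read_csv(path)
        vols = dict(zip(df["region"], df["volume_mL"].astype(float)))
        rep = cls.from_lobes({l: vols[l] for l in LOBE_NAMES})
        if "standardized_pct" in df and df["standardized_pct"].notna().any():
            rep.standardized_pct = {
                r: float(v)
                for r, v in zip(df["region"], df["standardized_pct"])
                if np.isfinite(v)
            }
        return rep


def extract_body_mask(
    ct: CTVolume, body_threshold_hu: float = -500.0
) -> Mask3D:
    """Segment the patient body as the largest soft-tissue component.

    Voxels above ``body_threshold_hu`` are labelled tissue; the largest
    connected component is kept and its interior holes (lungs, bowel gas)
    are filled slice-by-slice in the axial plane.  Slice-wise filling keeps
    a trachea that opens to the exterior air above the patient *inside* the
    body mask, so it can be removed by the explicit airway-exclusion step
    rather than vanishing silently here.

    Raises
    ------
    DegenerateInputError
        If no voxel exceeds the threshold.
    """
    tissue = ct.intensities > body_threshold_hu
    if not tissue.any():
        raise DegenerateInputError(
            f"no voxel above body threshold {body_threshold_hu} HU"
        )
    labeled, n = ndimage.label(tissue)
    if n > 1:
        sizes = ndimage.sum_labels(tissue, labeled, index=np.arange(1, n + 1))
        tissue = labeled == (int(np.argmax(sizes)) + 1)
    body = np.empty_like(tissue)
    for k in range(tissue.shape[0]):
        body[k] = ndimage.binary_fill_holes(tissue[k])
    return Mask3D(body, ct.spacing)


def extract_lung_mask(
    ct: CTVolume,
    body: Mask3D,
    hu_low: float = HU_LUNG_LOW,
    hu_high: float = HU_LUNG_HIGH,
    min_component_ml: float = 1.0,
) -> Mask3D:
    """Extract lung voxels by the inclusive HU window, inside the body.

    Connected components smaller than ``min_component_ml`` are discarded as
    noise specks.  An empty result is legal (a warning is emitted and all
    downstream volumes are zero), e.g. for a volume of uniform soft tissue.
    """
    if not hu_low < hu_high:
        raise ValueError(f"hu_low ({hu_low}) must be < hu_high ({hu_high})")
    body.check_aligned(ct)
    in_range = (ct.intensities >= hu_low) & (ct.intensities <= hu_high)
    candidate = in_range & body.data
    if candidate.any():
        labeled, n = ndimage.label(candidate)
        min_vox = min_component_ml * 1000.0 / ct.voxel_volume_mm3
        sizes = ndimage.sum_labels(candidate, labeled, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes > min_vox) + 1
        candidate = np.isin(labeled, keep)
    if not candidate.any():
        warnings.warn("empty lung mask: no in-range component inside the body")
    return Mask3D(candidate, ct.spacing)


def exclude_airways(
    lung: Mask3D,
    ct: CTVolume,
    airway: RegionLabelMap | tuple[int, int, int] | None = None,
    hu_low: float = HU_LUNG_LOW,
    hu_high: float = HU_LUNG_HIGH,
    max_fraction: float = 0.05,
) -> Mask3D:
    """Remove conducting-airway voxels from the lung mask.

    With a :class:`RegionLabelMap` the airway label is subtracted directly.
    Otherwise the airway is grown by flood fill over the lung mask (the
    extracted "lung" initially contains the tracheal air column) from a
    tracheal seed ``(z, y, x)``; when no seed is given, a voxel of the most
    superior air region in the lung mask is used.  If growth exceeds
    ``max_fraction`` of the lung volume the grown region has leaked into
    the lung proper — no separable airway exists — and the mask is returned
    unchanged.
    """
    lung.check_aligned(ct)
    if isinstance(airway, RegionLabelMap):
        if airway.shape != lung.shape:
            raise AlignmentError(
                f"airway map shape {airway.shape} != lung shape {lung.shape}"
            )
        out = lung.data & ~airway.mask_for("airway")
        return Mask3D(out, lung.spacing)

    if not lung.data.any():
        return Mask3D(lung.data.copy(), lung.spacing)

    air = (ct.intensities >= hu_low) & (ct.intensities <= hu_high)
    if airway is None:
        z_top = int(np.argmax(lung.data.any(axis=(1, 2))))
        comp, n = ndimage.label(lung.data[z_top])
        sizes = ndimage.sum_labels(lung.data[z_top], comp, np.arange(1, n + 1))
        ys, xs = np.nonzero(comp == int(np.argmax(sizes)) + 1)
        seed = (z_top, int(ys[len(ys) // 2]), int(xs[len(xs) // 2]))
    else:
        seed = tuple(int(i) for i in airway)
    if not air[seed]:
        raise SeedError(f"seed {seed} is not within the air HU range")
    if not lung.data[seed]:
        raise SeedError(f"seed {seed} is outside the lung mask")

    budget = int(max_fraction * lung.data.sum())
    grown, leaked = _flood_fill_budget(lung.data, seed, budget)
    if leaked:
        return Mask3D(lung.data.copy(), lung.spacing)
    return Mask3D(lung.data & ~grown, lung.spacing)


def _flood_fill_budget(
    allowed: np.ndarray, seed: tuple[int, int, int], budget: int
) -> tuple[np.ndarray, bool]:
    """6-connected component of ``seed`` within ``allowed``.

    Returns the component mask and a leak flag that is set when the
    component size exceeds ``budget`` voxels.
    """
    struct = ndimage.generate_binary_structure(3, 1)
    labeled, _ = ndimage.label(allowed, structure=struct)
    grown = labeled == labeled[seed]
    size = int(grown.sum())
    return grown, size > budget


def resample_slices(ct: CTVolume, slice_thickness_mm: float) -> CTVolume:
    """Reconstruct the volume at a thicker through-plane spacing.

    Each output slice is the overlap-weighted mean of the native slices it
    covers — an idealisation of thick-slice reconstruction averaging.  The
    in-plane grid is unchanged.  ``slice_thickness_mm`` must be at least the
    native slice spacing.
    """
    t = float(slice_thickness_mm)
    if not np.isfinite(t) or t <= 0:
        raise ValueError(f"slice thickness must be positive and finite, got {t}")
    dz = ct.spacing[0]
    if t < dz * (1 - 1e-9):
        raise ValueError(f"thickness {t} mm is below native spacing {dz} mm")
    nz = ct.shape[0]
    if abs(t - dz) <= 1e-9 * dz:
        return CTVolume(ct.intensities.copy(), ct.spacing,
                        ct.axis_convention, ct.window_level, ct.window_width)
    extent = nz * dz
    n_out = max(1, int(round(extent / t)))
    out = np.empty((n_out,) + ct.shape[1:], dtype=np.float32)
    edges = np.arange(nz + 1) * dz  # native slice boundaries
    for k in range(n_out):
        lo, hi = k * t, min((k + 1) * t, extent)
        # overlap of [lo, hi) with each native slab
        w = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0, None)
        w /= w.sum()
        nz_idx = np.flatnonzero(w)
        i0, i1 = nz_idx[0], nz_idx[-1] + 1
        out[k] = np.tensordot(
            w[i0:i1].astype(np.float32), ct.intensities[i0:i1], axes=(0, 0)
        )
    return CTVolume(out, (t,) + ct.spacing[1:],
                    ct.axis_convention, ct.window_level, ct.window_width)


def compute_volumes(
    lung: Mask3D, lobes: RegionLabelMap, spacing: tuple[float, float, float] | None = None
) -> VolumeReport:
    """Count lung voxels per lobe and convert to millilitres.

    Every lung voxel must carry a lobe label; unlabeled lung voxels are
    assigned to the nearest labelled lobe by Euclidean distance (a
    documented fallback for small boundary mismatches between the lung mask
    and the label map).
    """
    if lobes.shape != lung.shape:
        raise AlignmentError(
            f"lobe map shape {lobes.shape} != lung mask shape {lung.shape}"
        )
    spacing = spacing if spacing is not None else lung.spacing
    voxel_ml = float(np.prod(spacing)) / 1000.0

    lobe_codes = {l: lobes.lobe_code(l) for l in LOBE_NAMES}
    labels = lobes.data
    is_lobe = np.isin(labels, list(lobe_codes.values()))
    unlabeled = lung.data & ~is_lobe
    if unlabeled.any() and is_lobe.any():
        # nearest-lobe assignment for lung voxels the label map missed
        _, (iz, iy, ix) = ndimage.distance_transform_edt(
            ~is_lobe, sampling=spacing, return_indices=True
        )
        labels = labels.copy()
        labels[unlabeled] = labels[iz[unlabeled], iy[unlabeled], ix[unlabeled]]

    lobe_ml = {
        name: float(np.count_nonzero(lung.data & (labels == code))) * voxel_ml
        for name, code in lobe_codes.items()
    }
    return VolumeReport.from_lobes(lobe_ml)
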