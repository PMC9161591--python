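"""Synthetic CT phantoms and simulated patient cohorts.

The phantom is a soft-tissue cylinder (the body) containing five disjoint
air-density ellipsoids (the lobes) and, optionally, a tracheal tube that
opens to the exterior air above the body.  Ellipsoids are used instead of
anatomical shapes because their volumes have closed forms, which makes the
volumetry oracle exact: the generator returns the analytic per-lobe volumes
alongside the voxel grid.

The cohort simulator draws demographics, standardised lung volumes (% of
predicted FVC), FVC% and CRP, and generates survival times from a Weibull
proportional-hazards model in which the hazard rises as the standardised
volume falls and as CRP rises, with independent right-censoring.  Every
draw is reproducible from the spec's seed, and the true simulation
parameters are returned alongside the table for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, fields as dataclass_fields

import numpy as np
import pandas as pd

from .errors import SpecError
from .image import CTVolume, DEFAULT_LABELS, LOBE_NAMES, Mask3D, RegionLabelMap
from .volumetry import (
    VolumeReport,
    compute_volumes,
    exclude_airways,
    extract_body_mask,
    extract_lung_mask,
    resample_slices,
)

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "PhantomTruth",
    "make_lung_phantom",
    "run_volumetry",
    "phantom_suite",
    "thick_slice_pair",
    "CohortSpec",
    "simulate_cohort",
]

HU_AIR = -1000.0
HU_LUNG_TISSUE = -850.0
HU_SOFT_TISSUE = 40.0


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and half-axes in mm, (z, y, x) order."""

    center: tuple[float, float, float]
    half_axes: tuple[float, float, float]

    def volume_ml(self) -> float:
        a, b, c = self.half_axes
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0

    def bbox(self) -> tuple[tuple[float, float], ...]:
        return tuple(
            (c - h, c + h) for c, h in zip(self.center, self.half_axes)
        )

    def membership(self, zz, yy, xx) -> np.ndarray:
        cz, cy, cx = self.center
        az, ay, ax = self.half_axes
        return (
            ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        ) <= 1.0


def _default_lobes() -> dict[str, Ellipsoid]:
    """Human-scale prolate lobes (total ~2.7 L).

    The body axis is at (y, x) = (150, 150) mm; the right lung sits at
    x = 90, the left at x = 210, with the right middle and lower lobes side
    by side in y.  Through-plane half-axes are kept large (>= 75 mm) so the
    lobes stay well resolved at a 5-mm slice reconstruction.
    """
    return {
        "right_upper_lobe": Ellipsoid((120.0, 150.0, 90.0), (90.0, 42.0, 40.0)),
        "right_middle_lobe": Ellipsoid((305.0, 195.0, 90.0), (80.0, 34.0, 30.0)),
        "right_lower_lobe": Ellipsoid((300.0, 105.0, 90.0), (80.0, 38.0, 40.0)),
        "left_upper_lobe": Ellipsoid((125.0, 150.0, 210.0), (85.0, 42.0, 40.0)),
        "left_lower_lobe": Ellipsoid((300.0, 150.0, 210.0), (80.0, 45.0, 42.0)),
    }


def _compact_lobes() -> dict[str, Ellipsoid]:
    # miniature layout for fast unit-test fixtures; body axis at (70, 70) mm
    return {
        "right_upper_lobe": Ellipsoid((45.0, 70.0, 44.0), (18.0, 16.0, 14.0)),
        "right_middle_lobe": Ellipsoid((80.0, 70.0, 44.0), (12.0, 14.0, 13.0)),
        "right_lower_lobe": Ellipsoid((110.0, 70.0, 44.0), (15.0, 17.0, 15.0)),
        "left_upper_lobe": Ellipsoid((55.0, 70.0, 96.0), (20.0, 16.0, 14.0)),
        "left_lower_lobe": Ellipsoid((100.0, 70.0, 96.0), (18.0, 16.0, 14.0)),
    }


@dataclass
class PhantomSpec:
    """Geometry and imaging parameters of a thoracic phantom.

    All geometry is in mm in a fixed physical frame, so the same spec can be
    rendered at any voxel spacing.  ``z`` runs from superior (0) down.
    """

    extent_mm: tuple[float, float, float] = (420.0, 300.0, 300.0)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    body_center_yx: tuple[float, float] = (150.0, 150.0)
    body_radius_mm: float = 120.0
    body_z_mm: tuple[float, float] = (30.0, 400.0)
    body_hu: float = HU_SOFT_TISSUE
    lobes: dict[str, Ellipsoid] = field(default_factory=_default_lobes)
    lobe_hu: float = HU_LUNG_TISSUE
    trachea_radius_mm: float | None = 8.0
    trachea_z_mm: tuple[float, float] = (0.0, 80.0)
    trachea_yx: tuple[float, float] | None = None  # defaults to body axis
    noise_sigma_hu: float = 0.0
    seed: int | None = None

    @classmethod
    def compact(cls, **overrides) -> "PhantomSpec":
        """A miniature phantom (~79 mL lungs) for fast unit-test fixtures."""
        defaults = dict(
            extent_mm=(140.0, 140.0, 140.0),
            body_center_yx=(70.0, 70.0),
            body_radius_mm=60.0,
            body_z_mm=(20.0, 135.0),
            lobes=_compact_lobes(),
            trachea_radius_mm=4.0,
            trachea_z_mm=(0.0, 55.0),
        )
        defaults.update(overrides)
        return cls(**defaults)

    def with_spacing(self, spacing: tuple[float, float, float]) -> "PhantomSpec":
        """The same physical phantom rendered at a different voxel spacing."""
        kwargs = {f.name: getattr(self, f.name) for f in dataclass_fields(self)}
        kwargs["spacing"] = spacing
        return PhantomSpec(**kwargs)

    def __post_init__(self) -> None:
        if set(self.lobes) != set(LOBE_NAMES):
            raise SpecError(f"lobes must be exactly {LOBE_NAMES}")
        if self.noise_sigma_hu > 0 and self.seed is None:
            raise SpecError("a seed is mandatory when noise_sigma_hu > 0")
        self._check_geometry()

    def _check_geometry(self) -> None:
        cy, cx = self.body_center_yx
        z0, z1 = self.body_z_mm
        for name, e in self.lobes.items():
            (ez0, ez1), (ey0, ey1), (ex0, ex1) = e.bbox()
            if ez0 < z0 or ez1 > z1:
                raise SpecError(f"lobe {name} extends outside the body in z")
            radial = math.hypot(e.center[1] - cy, e.center[2] - cx)
            if radial + max(e.half_axes[1], e.half_axes[2]) > self.body_radius_mm:
                raise SpecError(f"lobe {name} extends outside the body radius")
        names = list(self.lobes)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if _bboxes_overlap(self.lobes[a].bbox(), self.lobes[b].bbox()):
                    raise SpecError(f"lobes {a} and {b} overlap")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(
            int(round(e / s)) for e, s in zip(self.extent_mm, self.spacing)
        )


def _bboxes_overlap(a, b) -> bool:
    return all(lo1 < hi2 and lo2 < hi1 for (lo1, hi1), (lo2, hi2) in zip(a, b))


@dataclass
class PhantomTruth:
    """Closed-form volumes (mL) implied by a phantom spec."""

    lobes_ml: dict[str, float]
    airway_ml: float

    @property
    def report(self) -> VolumeReport:
        return VolumeReport.from_lobes(self.lobes_ml)

    @property
    def total_ml(self) -> float:
        return self.report.total_ml


def make_lung_phantom(
    spec: PhantomSpec,
) -> tuple[CTVolume, RegionLabelMap, PhantomTruth]:
    """Render a phantom spec to a HU grid, label map and analytic truth.

    Voxel membership is evaluated at voxel centers.  Exterior air is
    -1000 HU, the body ``body_hu``, lobes ``lobe_hu``; the tracheal tube is
    pure air and is labelled ``airway`` where it passes through the body.
    """
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    z = (np.arange(nz) + 0.5) * dz
    y = (np.arange(ny) + 0.5) * dy
    x = (np.arange(nx) + 0.5) * dx
    zz = z[:, None, None]
    yy = y[None, :, None]
    xx = x[None, None, :]

    hu = np.full((nz, ny, nx), HU_AIR, dtype=np.float32)
    labels = np.zeros((nz, ny, nx), dtype=np.int16)

    cy, cx = spec.body_center_yx
    z0, z1 = spec.body_z_mm
    body = (
        ((yy - cy) ** 2 + (xx - cx) ** 2 <= spec.body_radius_mm**2)
        & (zz >= z0)
        & (zz <= z1)
    )
    hu[body] = spec.body_hu

    claimed = np.zeros_like(body)
    for name, e in spec.lobes.items():
        m = e.membership(zz, yy, xx)
        if (m & claimed).any():
            raise SpecError(f"lobe {name} overlaps a previously stamped lobe")
        claimed |= m
        hu[m] = spec.lobe_hu
        labels[m] = DEFAULT_LABELS[name]

    airway_ml = 0.0
    if spec.trachea_radius_mm is not None:
        ty, tx = spec.trachea_yx or spec.body_center_yx
        tz0, tz1 = spec.trachea_z_mm
        tube = (
            ((yy - ty) ** 2 + (xx - tx) ** 2 <= spec.trachea_radius_mm**2)
            & (zz >= tz0)
            & (zz <= tz1)
        )
        if (tube & claimed).any():
            raise SpecError("trachea overlaps a lobe")
        hu[tube] = HU_AIR
        in_body = tube & body
        labels[in_body] = DEFAULT_LABELS["airway"]
        seg_lo = max(tz0, z0)
        seg_hi = min(tz1, z1)
        if seg_hi > seg_lo:
            airway_ml = math.pi * spec.trachea_radius_mm**2 * (seg_hi - seg_lo) / 1000.0

    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma_hu, hu.shape).astype(np.float32)

    ct = CTVolume(hu, spec.spacing, window_level=-600, window_width=1500)
    label_map = RegionLabelMap(labels, spec.spacing)
    truth = PhantomTruth(
        lobes_ml={n: e.volume_ml() for n, e in spec.lobes.items()},
        airway_ml=airway_ml,
    )
    return ct, label_map, truth


def run_volumetry(
    ct: CTVolume,
    lobes: RegionLabelMap,
    use_airway_labels: bool = True,
    **kwargs,
) -> VolumeReport:
    """Full pipeline: body mask -> lung mask -> airway exclusion -> volumes."""
    body = extract_body_mask(ct)
    lung = extract_lung_mask(ct, body, **kwargs)
    airway = lobes if use_airway_labels else None
    lung = exclude_airways(lung, ct, airway)
    return compute_volumes(lung, lobes)


def phantom_suite(
    n: int, seed: int, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> list[PhantomSpec]:
    """``n`` phantoms of varying lung size for concordance studies.

    Half-axes are shrunk by factors drawn in [0.68, 1.0], independently per
    phantom with a mild per-lobe jitter; shrinking only, so the default
    layout's containment and disjointness margins are preserved.
    """
    if n < 1:
        raise SpecError("n must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        scale = rng.uniform(0.68, 1.0)
        lobes = {}
        for name, e in _default_lobes().items():
            jitter = rng.uniform(0.94, 1.0, size=3)
            half = tuple(h * scale * j for h, j in zip(e.half_axes, jitter))
            lobes[name] = Ellipsoid(e.center, half)
        specs.append(PhantomSpec(spacing=spacing, lobes=lobes))
    return specs


def thick_slice_pair(
    spec: PhantomSpec, thick_mm: float = 5.0
) -> tuple[CTVolume, CTVolume, PhantomTruth]:
    """A phantom at its native fine spacing and resampled to thick slices.

    The native through-plane spacing must be at most 1 mm so the pair
    mirrors a thin-section acquisition reconstructed at ``thick_mm``.
    """
    if spec.spacing[0] > 1.0:
        raise SpecError("fine through-plane spacing must be <= 1 mm")
    ct, _, truth = make_lung_phantom(spec)
    thick = resample_slices(ct, thick_mm)
    return ct, thick, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Parameters of a simulated IPF cohort.

    The survival model is Weibull proportional hazards

        h(t | x) = h0(t) * exp(beta_lv * (stdLV - lv_mean)
                               + beta_crp * (CRP - crp_median))

    with baseline shape ``weibull_shape`` and scale chosen so the baseline
    median survival equals ``baseline_median_time`` in ``time_unit``.
    ``beta_lv`` defaults to ln(0.976) per percentage point — a hazard ratio
    of 0.976 per 1% of standardised volume.  FVC% is generated as a noisy
    linear function of stdLV% so calibration fits have realistic scatter.
    """

    n: int = 140
    timepoint: str = "diagnosis"  # or "ae"
    sex_male_prop: float = 0.85
    age_mean: float = 70.0
    age_sd: float = 7.0
    age_range: tuple[float, float] = (45.0, 90.0)
    height_mean_male: float = 165.0
    height_mean_female: float = 152.0
    height_sd: float = 6.0
    lv_mean: float = 108.0
    lv_sd: float = 25.0
    crp_log_median: float = math.log(0.17)
    crp_log_sd: float = 1.25
    fvc_slope: float = 0.8
    fvc_intercept: float = 10.0
    fvc_noise_sd: float = 22.0
    dlco_mean: float = 64.0
    dlco_sd: float = 18.0
    dlco_cannot_perform_prop: float = 0.04
    beta_lv: float = math.log(0.976)
    beta_crp: float = 0.08
    weibull_shape: float = 1.2
    baseline_median_time: float = 5.5
    time_unit: str = "years"
    censoring_rate: float = 0.3
    seed: int = 0

    @classmethod
    def ae(cls, **overrides) -> "CohortSpec":
        """Acute-exacerbation scenario: lower volumes, high CRP, months scale."""
        defaults = dict(
            timepoint="ae",
            lv_mean=74.0,
            lv_sd=20.0,
            crp_log_median=math.log(5.0),
            crp_log_sd=0.9,
            baseline_median_time=6.0,
            time_unit="months",
            beta_crp=0.05,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SpecError("cohort size n must be >= 1")
        if not 0 <= self.censoring_rate < 1:
            raise SpecError("censoring_rate must be in [0, 1)")
        for name in ("beta_lv", "beta_crp"):
            if not math.isfinite(getattr(self, name)):
                raise SpecError(f"{name} must be finite")
        if self.weibull_shape <= 0 or self.baseline_median_time <= 0:
            raise SpecError("Weibull parameters must be positive")
        if self.timepoint not in ("diagnosis", "ae"):
            raise SpecError("timepoint must be 'diagnosis' or 'ae'")


def _censor_scale(event_times: np.ndarray, rate: float) -> float:
    """Exponential censoring scale giving expected censored fraction ~ rate.

    P(C < T_i | T_i) = 1 - exp(-T_i / s); solve mean over the sample = rate
    by bisection.
    """
    if rate <= 0:
        return math.inf

    def frac(s: float) -> float:
        return float(np.mean(1.0 - np.exp(-event_times / s)))

    lo, hi = 1e-6, float(event_times.max()) * 100 + 1.0
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table and return it with the true parameters used.

    Columns: id, sex, age, height, fvc_pct, dlco_pct, dlco_cannot_perform,
    crp, std_lv_total_pct, time, event, timepoint.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    male = rng.random(n) < spec.sex_male_prop
    sex = np.where(male, "male", "female")
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), *spec.age_range)
    height = np.where(
        male,
        rng.normal(spec.height_mean_male, spec.height_sd, n),
        rng.normal(spec.height_mean_female, spec.height_sd, n),
    )
    lv = np.clip(rng.normal(spec.lv_mean, spec.lv_sd, n), 10.0, None)
    crp = np.exp(rng.normal(spec.crp_log_median, spec.crp_log_sd, n))
    fvc = np.clip(
        spec.fvc_slope * lv + spec.fvc_intercept + rng.normal(0, spec.fvc_noise_sd, n),
        15.0,
        None,
    )
    dlco = np.clip(rng.normal(spec.dlco_mean, spec.dlco_sd, n), 10.0, None)
    cannot = rng.random(n) < spec.dlco_cannot_perform_prop

    crp_median_true = math.exp(spec.crp_log_median)
    lp = spec.beta_lv * (lv - spec.lv_mean) + spec.beta_crp * (crp - crp_median_true)
    scale = spec.baseline_median_time / math.log(2) ** (1.0 / spec.weibull_shape)
    u = rng.random(n)
    t_event = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / spec.weibull_shape)

    if spec.censoring_rate > 0:
        s = _censor_scale(t_event, spec.censoring_rate)
        t_cens = rng.exponential(s, n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(n, dtype=int)
        time = t_event

    df = pd.DataFrame(
        {
            "id": [f"P{i:04d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "height": height,
            "fvc_pct": fvc,
            "dlco_pct": np.where(cannot, np.nan, dlco),
            "dlco_cannot_perform": cannot,
            "crp": crp,
            "std_lv_total_pct": lv,
            "time": time,
            "event": event,
            "timepoint": spec.timepoint,
        }
    )
    truth = asdict(spec)
    truth["weibull_scale"] = scale
    truth["event_fraction"] = float(event.mean())
    return df, truth
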