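"""Synthetic paired-session cohort: parametric pelvic phantom, bladder filling,
controlled auto-vs-clinical contour discrepancy, two-level SIB dose model.

The generator emulates the statistical structure of a paired adaptive-RT
study without any clinical data: 17 patients × 20 fractions, a bladder whose
online volume differs from the reference CT through day-to-day variation plus
filling during the session (1–4 ml/min), a rectum of varying caliber, a tumor
bed (GTV) on the bladder wall, margin-derived targets
(CTV_boost = GTV ⊕ 5 mm, PTV_boost = CTV_boost ⊕ 5 mm,
CTV_elective = bladder ∪ CTV_boost, PTV_elective = (bladder ⊕ 7 mm) ∪ PTV_boost),
and per arm a geometric dose model: the prescription inside each PTV with an
exponential falloff outside it, the boost level (2.75 Gy/fraction) layered
over the elective level (2.0 Gy/fraction) by taking the voxelwise maximum.

The "auto" arm is produced by a level-set perturbation of the clinical
contours: the signed distance of each mask is offset by a smooth,
unit-bounded, seeded noise field scaled to a per-session amplitude (plus an
optional systematic bias that shrinks or grows the auto boost), then
re-thresholded at zero.  The perturbation amplitude grows with the bladder
volume change, mimicking the degradation of influencer-guided propagation
for large anatomical changes.  D_auto is shaped around the auto PTVs,
D_clin around the clinical ones.

Everything is deterministic under the master seed; per-patient and
per-fraction child seeds make any single session reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import ndimage

from .core import (
    PrescriptionConfig,
    Session,
    StructureSet,
    ValidationError,
    VolumeGrid,
    mask_volume,
    voxel_volume,
)

__all__ = [
    "PhantomConfig",
    "GroundTruthLog",
    "expand_margin",
    "simulate_filling",
    "scale_mask_to_volume",
    "perturb_contour",
    "make_noise_field",
    "synth_dose",
    "generate_reference_anatomy",
    "generate_cohort",
    "iter_cohort",
]


@dataclass
class PhantomConfig:
    """Parameters of the synthetic cohort.

    Volumes in cm³, lengths in mm, rates in ml/min, times in minutes.
    """

    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    shape: tuple[int, int, int] = (96, 96, 88)

    # patient-level anatomy
    bladder_reference_volume_range: tuple[float, float] = (150.0, 280.0)
    bladder_axis_ratios: tuple[float, float, float] = (1.0, 0.9, 1.1)
    body_semiaxes: tuple[float, float, float] = (88.0, 80.0, 78.0)
    rectum_radius_range: tuple[float, float] = (9.0, 16.0)
    rectum_length: float = 94.0
    rectum_curve_amplitude: float = 8.0
    gtv_radius: float = 15.0

    # margins
    ctv_boost_margin: float = 5.0
    ptv_boost_margin: float = 5.0
    bladder_ptv_margin: float = 7.0

    # session-level variation
    filling_rate_range: tuple[float, float] = (1.0, 4.0)
    on_couch_time_range: tuple[float, float] = (10.0, 25.0)
    day_variation_sd: float = 55.0
    rectum_radius_jitter_sd: float = 2.5
    min_online_bladder_volume: float = 60.0

    # auto-contour discrepancy
    perturb_amplitude_range: tuple[float, float] = (1.0, 3.0)
    boost_amplitude_factor: float = 2.0
    boost_bias_mm: float = 1.7
    boost_shift_base_range: tuple[float, float] = (0.0, 2.0)
    boost_shift_per_100cm3: float = 5.0
    amplitude_volume_coupling: float = 1.5  # extra mm per 100 cm³ bladder change
    max_amplitude: float = 9.0
    noise_correlation_mm: float = 15.0

    # dose model
    dose_falloff_half_mm: float = 5.0

    # cohort shape and bookkeeping
    patients: int = 17
    fractions: int = 20
    correction_probabilities: dict = field(
        default_factory=lambda: {"bladder": 0.91, "rectum": 0.13, "GTV": 0.68}
    )
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ctv_boost_margin", "ptv_boost_margin", "bladder_ptv_margin"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.patients < 1 or self.fractions < 1:
            raise ValidationError("patients and fractions must be >= 1")
        lo, hi = self.filling_rate_range
        if lo < 0 or hi < lo:
            raise ValidationError("invalid filling_rate_range")
        if self.bladder_reference_volume_range[0] <= 0:
            raise ValidationError("bladder reference volume must be positive")


@dataclass
class GroundTruthLog:
    """Per-session generation truth, for parameter-recovery tests."""

    master_seed: int
    entries: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometric primitives


def _grid_axes(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sx, sy, sz = config.spacing
    nx, ny, nz = config.shape
    return (np.arange(nx) * sx, np.arange(ny) * sy, np.arange(nz) * sz)


def _grid_center(config: PhantomConfig) -> np.ndarray:
    return (np.array(config.shape, dtype=float) - 1) * np.array(config.spacing) / 2.0


def _empty_grid(config: PhantomConfig) -> VolumeGrid:
    return VolumeGrid(
        origin=(0.0, 0.0, 0.0),
        spacing=config.spacing,
        values=np.zeros(config.shape, dtype=bool),
    )


def _rasterize_ellipsoid(config: PhantomConfig, center, semiaxes) -> np.ndarray:
    x, y, z = _grid_axes(config)
    cx, cy, cz = center
    ax, ay, az = semiaxes
    q = (
        ((x[:, None, None] - cx) / ax) ** 2
        + ((y[None, :, None] - cy) / ay) ** 2
        + ((z[None, None, :] - cz) / az) ** 2
    )
    return q <= 1.0


def _rasterize_sphere(config: PhantomConfig, center, radius) -> np.ndarray:
    return _rasterize_ellipsoid(config, center, (radius, radius, radius))


def _bladder_semiaxes(config: PhantomConfig, volume_cm3: float) -> np.ndarray:
    """Semi-axes (mm) of a bladder ellipsoid of given volume with the
    configured axis ratios."""
    ratios = np.asarray(config.bladder_axis_ratios, dtype=float)
    s = (3.0 * volume_cm3 * 1000.0 / (4.0 * math.pi * float(np.prod(ratios)))) ** (1.0 / 3.0)
    return s * ratios


def _touches_boundary(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )


def _bbox_slices(mask: np.ndarray, pad: np.ndarray, shape) -> tuple[slice, slice, slice]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


# ---------------------------------------------------------------------------
# public mask operations


def expand_margin(mask: VolumeGrid, margin: float) -> VolumeGrid:
    """Isotropic margin expansion: set every voxel whose center lies within
    ``margin`` mm (Euclidean, anisotropic spacing respected) of a set voxel
    center.  Runs the distance transform on a padded bounding box only."""
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    m = mask.require_binary()
    if margin == 0 or not m.any():
        return mask.with_values(m.copy())
    spacing = mask.spacing
    pad = np.ceil(margin / spacing).astype(int) + 1
    sl = _bbox_slices(m, pad, m.shape)
    sub = m[sl]
    dist = ndimage.distance_transform_edt(~sub, sampling=spacing)
    out = np.zeros_like(m)
    out[sl] = dist <= margin + 1e-9
    return mask.with_values(out)


def scale_mask_to_volume(mask: VolumeGrid, target_volume: float) -> VolumeGrid:
    """Isotropically rescale a mask about its centroid (world mm) so that its
    volume matches ``target_volume`` cm³.

    The binary occupancy is trilinearly resampled at scaled coordinates and
    re-thresholded; the threshold is chosen as the occupancy quantile whose
    voxel count matches the target volume, so the achieved volume is exact to
    within one voxel (a fixed 0.5 threshold leaves a digitization bias of a
    few percent)."""
    m = mask.require_binary()
    v0 = mask_volume(mask)
    if v0 <= 0:
        raise ValidationError("cannot rescale an empty mask")
    if target_volume <= 0:
        raise ValidationError("target volume must be positive")
    f = (target_volume / v0) ** (1.0 / 3.0)
    centroid = np.array(ndimage.center_of_mass(m))  # index coords
    idx = np.indices(m.shape, dtype=float)
    # world-isotropic scaling expressed in index coordinates (spacing cancels
    # per-axis because the scaling is the same factor on every axis)
    coords = centroid[:, None, None, None] + (idx - centroid[:, None, None, None]) / f
    vals = ndimage.map_coordinates(
        m.astype(np.float32), coords, order=1, mode="constant", cval=0.0
    )
    n_target = int(round(target_volume / voxel_volume(mask)))
    n_target = max(1, min(n_target, vals.size))
    flat = vals.ravel()
    kth = np.partition(flat, flat.size - n_target)[flat.size - n_target]
    out = vals >= max(kth, 1e-4)
    if _touches_boundary(out):
        raise ValidationError("rescaled mask exceeds the grid extent")
    return mask.with_values(out)


def simulate_filling(bladder: VolumeGrid, rate: float, minutes: float) -> VolumeGrid:
    """Grow a bladder mask by ``rate`` ml/min over ``minutes`` min (isotropic
    rescaling about the centroid)."""
    if rate < 0 or minutes < 0:
        raise ValidationError("rate and time must be >= 0")
    delta = rate * minutes  # ml == cm³
    if delta == 0:
        return bladder.with_values(bladder.require_binary().copy())
    return scale_mask_to_volume(bladder, mask_volume(bladder) + delta)


def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Sub-voxel-accurate signed distance (mm, negative inside) of a mask.

    The two one-sided Euclidean distance transforms give distances between
    voxel *centers*, which are lattice-quantized: the closest attainable
    value is one voxel step, so the digitized interface (which runs between
    centers) cannot be localized below the voxel size.  Near the interface
    the signed distance is therefore re-estimated from a Gaussian-smoothed
    occupancy (for a smoothed half-space, occupancy o at signed distance d
    satisfies o = Φ(−d/σ), hence d ≈ (0.5 − o)·σ·√(2π) close to the zero
    level).  The two estimates are blended so the zero crossing is
    sub-voxel-accurate while far-field distances stay metric.
    """
    spacing = np.asarray(spacing, dtype=float)
    h = float(spacing.min()) / 2.0
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    d_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    sdf_edt = np.where(mask, -(d_in - h), d_out - h)

    sigma_mm = float(spacing.min()) * 0.6
    occ = ndimage.gaussian_filter(mask.astype(np.float32), sigma_mm / spacing)
    sdf_near = (0.5 - occ) * (sigma_mm * math.sqrt(2.0 * math.pi))

    w = np.clip((3.0 * h - np.abs(sdf_edt)) / (2.0 * h), 0.0, 1.0)
    return w * sdf_near + (1.0 - w) * sdf_edt


def make_noise_field(
    shape, spacing, correlation_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth, unit-bounded noise field on the grid.

    White noise is low-pass filtered to the requested correlation length,
    scaled to unit variance, and squashed through tanh so values stay in
    (−1, 1) with an O(1) typical magnitude everywhere.
    """
    field_ = rng.standard_normal(shape).astype(np.float32)
    sigma = [correlation_mm / s for s in spacing]
    field_ = ndimage.gaussian_filter(field_, sigma)
    rms = float(field_.std())
    if rms > 0:
        field_ = np.tanh(field_ / rms)
    return field_


def perturb_contour(
    mask: VolumeGrid,
    amplitude: float,
    seed: int | None = None,
    noise_field: np.ndarray | None = None,
    bias_mm: float = 0.0,
    shift_mm: np.ndarray | None = None,
    correlation_mm: float = 15.0,
) -> VolumeGrid:
    """Level-set contour perturbation.

    The signed distance of the mask (negative inside) is offset by
    ``amplitude × noise + bias`` (mm) and re-thresholded at zero.  The noise
    field is smooth and bounded in (−1, 1), so the surface never moves by
    more than ``amplitude + |bias|``.  A positive bias shrinks the contour;
    ``shift_mm`` additionally translates it rigidly (sub-voxel, via
    interpolation of the signed distance).  ``amplitude = 0`` with zero bias
    and shift returns the input exactly.
    """
    if amplitude < 0:
        raise ValidationError("amplitude must be >= 0")
    m = mask.require_binary()
    if not m.any():
        raise ValidationError("cannot perturb an empty mask")
    shift = None if shift_mm is None else np.asarray(shift_mm, dtype=float)
    if shift is not None and not np.any(shift):
        shift = None
    if amplitude == 0 and bias_mm == 0 and shift is None:
        return mask.with_values(m.copy())

    spacing = mask.spacing
    reach = amplitude + abs(bias_mm)
    if shift is not None:
        reach += float(np.linalg.norm(shift))
    pad = np.ceil(reach / spacing).astype(int) + 3
    sl = _bbox_slices(m, pad, m.shape)
    sub = m[sl]
    sdf = _signed_distance(sub, spacing)
    if shift is not None:
        # translated mask: new(x) = old(x − t), sampled on the SDF
        idx = np.indices(sub.shape, dtype=float)
        coords = idx - (shift / spacing)[:, None, None, None]
        sdf = ndimage.map_coordinates(sdf, coords, order=1, mode="nearest")

    if noise_field is None:
        rng = np.random.default_rng(seed)
        noise = make_noise_field(sub.shape, spacing, correlation_mm, rng)
    else:
        noise = noise_field[sl]
    new_sub = (sdf + amplitude * noise + bias_mm) < 0

    out = m.copy()
    out[sl] = new_sub
    if not out.any():
        raise ValidationError("perturbation emptied the mask")
    return mask.with_values(out)


def synth_dose(
    ptv_boost: VolumeGrid,
    ptv_elective: VolumeGrid,
    prescription: PrescriptionConfig | None = None,
    falloff_half_mm: float = 5.0,
) -> VolumeGrid:
    """Two-level SIB dose (Gy per fraction) on the structure grid.

    Each level delivers its prescription inside its PTV and decays by a
    factor 2 every ``falloff_half_mm`` mm of distance outside it; the voxel
    dose is the maximum over the two levels.
    """
    if not ptv_boost.same_frame(ptv_elective):
        raise ValidationError("PTVs must share one grid frame")
    rx = prescription or PrescriptionConfig()
    rx_boost = rx.boost_total / rx.fractions
    rx_elect = rx.elective_total / rx.fractions
    spacing = ptv_boost.spacing
    d_b = ndimage.distance_transform_edt(~ptv_boost.require_binary(), sampling=spacing)
    d_e = ndimage.distance_transform_edt(~ptv_elective.require_binary(), sampling=spacing)
    dose = np.maximum(
        rx_boost * np.exp2(-d_b / falloff_half_mm),
        rx_elect * np.exp2(-d_e / falloff_half_mm),
    ).astype(np.float32)
    return ptv_boost.with_values(dose)


# ---------------------------------------------------------------------------
# anatomy generation


def erode_margin(mask: VolumeGrid, margin: float) -> VolumeGrid:
    """Inverse of :func:`expand_margin`: keep voxels farther than ``margin``
    mm (Euclidean) from the background."""
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    m = mask.require_binary()
    if margin == 0 or not m.any():
        return mask.with_values(m.copy())
    sl = _bbox_slices(m, np.array([1, 1, 1]), m.shape)
    d_in = ndimage.distance_transform_edt(m[sl], sampling=mask.spacing)
    out = np.zeros_like(m)
    out[sl] = d_in > margin + 1e-9
    return mask.with_values(out)


def _gtv_center(bladder_center, semiaxes, direction) -> np.ndarray:
    """Point on the bladder ellipsoid surface along ``direction`` (unit)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    t = 1.0 / math.sqrt(float(np.sum((d / np.asarray(semiaxes)) ** 2)))
    return np.asarray(bladder_center) + t * d


def _build_structures(
    config: PhantomConfig,
    arm: str,
    bladder_mask: np.ndarray,
    rectum_mask: np.ndarray,
    gtv_mask: np.ndarray,
    body_grid: VolumeGrid,
    ctv_boost_mask: np.ndarray | None = None,
) -> StructureSet:
    """Derive the margin-based targets from organ masks and assemble a set.

    By default CTV_boost is GTV expanded by the boost CTV margin; an explicit
    ``ctv_boost_mask`` (e.g. a propagated/perturbed one) overrides that, in
    which case it must already contain the GTV.
    """
    frame = body_grid
    as_grid = lambda a: frame.with_values(a)
    gtv = as_grid(gtv_mask & body_grid.require_binary())
    bladder = as_grid(bladder_mask)
    if ctv_boost_mask is None:
        ctv_boost = expand_margin(gtv, config.ctv_boost_margin)
    else:
        ctv_boost = as_grid(ctv_boost_mask)
    ptv_boost = expand_margin(ctv_boost, config.ptv_boost_margin)
    ctv_elective = as_grid(bladder.values | ctv_boost.values)
    ptv_elective = as_grid(
        expand_margin(bladder, config.bladder_ptv_margin).values | ptv_boost.values
    )
    body = body_grid.require_binary()
    masks = {
        "bladder": bladder,
        "rectum": as_grid(rectum_mask & body),
        "GTV": gtv,
        "CTV_boost": as_grid(ctv_boost.values & body),
        "CTV_elective": as_grid(ctv_elective.values & body),
        "PTV_boost": as_grid(ptv_boost.values & body),
        "PTV_elective": as_grid(ptv_elective.values & body),
        "body": body_grid,
    }
    for role, grid in masks.items():
        if role != "body" and _touches_boundary(grid.require_binary()):
            raise ValidationError(f"structure {role!r} exceeds the grid extent")
    return StructureSet(arm=arm, masks=masks)


def _patient_params(config: PhantomConfig, rng: np.random.Generator) -> dict:
    center = _grid_center(config)
    v_ref = float(rng.uniform(*config.bladder_reference_volume_range))
    r_rect = float(rng.uniform(*config.rectum_radius_range))
    theta = rng.uniform(-0.35, 0.35)  # wobble of the tumor-bed direction
    direction = np.array([math.sin(theta), 0.5, -0.85])
    return {
        "bladder_center": np.array([center[0], center[1] - 15.0, center[2] - 3.0]),
        "bladder_reference_volume": v_ref,
        "rectum_reference_radius": r_rect,
        "rectum_y": center[1] + 37.0,
        "rectum_phase": float(rng.uniform(0, 2 * math.pi)),
        "gtv_direction": direction / np.linalg.norm(direction),
    }


def _rectum_mask(config: PhantomConfig, params: dict, radius: float) -> np.ndarray:
    x, y, z = _grid_axes(config)
    center = _grid_center(config)
    z0 = center[2] - config.rectum_length / 2.0
    z1 = center[2] + config.rectum_length / 2.0
    amp = config.rectum_curve_amplitude
    phase = params["rectum_phase"]
    cx = center[0] + 0.5 * amp * np.sin(2 * math.pi * z / 180.0 + phase)
    cy = params["rectum_y"] + amp * np.sin(2 * math.pi * z / 140.0 + phase)
    in_z = (z >= z0) & (z <= z1)
    r2 = (x[:, None, None] - cx[None, None, :]) ** 2 + (
        y[None, :, None] - cy[None, None, :]
    ) ** 2
    return (r2 <= radius**2) & in_z[None, None, :]


def generate_reference_anatomy(
    config: PhantomConfig, patient_seed: int | np.random.Generator
) -> tuple[StructureSet, dict[str, float]]:
    """Reference-CT anatomy of one synthetic patient.

    Returns the clinical structure set on the reference anatomy and the
    reference influencer volumes (cm³) used later by the stratification.
    """
    rng = (
        patient_seed
        if isinstance(patient_seed, np.random.Generator)
        else np.random.default_rng(patient_seed)
    )
    params = _patient_params(config, rng)
    sset, _ = _anatomy_from_params(
        config,
        params,
        bladder_volume=params["bladder_reference_volume"],
        rectum_radius=params["rectum_reference_radius"],
    )
    ref_volumes = {
        "bladder": mask_volume(sset["bladder"]),
        "rectum": mask_volume(sset["rectum"]),
    }
    return sset, ref_volumes


def _anatomy_from_params(
    config: PhantomConfig, params: dict, bladder_volume: float, rectum_radius: float
) -> tuple[StructureSet, dict]:
    center = _grid_center(config)
    body_mask = _rasterize_ellipsoid(config, center, config.body_semiaxes)
    body_grid = VolumeGrid((0.0, 0.0, 0.0), config.spacing, body_mask)
    semi = _bladder_semiaxes(config, bladder_volume)
    bladder = _rasterize_ellipsoid(config, params["bladder_center"], semi)
    rectum = _rectum_mask(config, params, rectum_radius)
    gtv_c = _gtv_center(params["bladder_center"], semi, params["gtv_direction"])
    gtv = _rasterize_sphere(config, gtv_c, config.gtv_radius)
    sset = _build_structures(config, "clin", bladder, rectum, gtv, body_grid)
    return sset, {"bladder_semiaxes": semi, "gtv_center": gtv_c}


# ---------------------------------------------------------------------------
# cohort generation


def _make_session(
    config: PhantomConfig,
    patient_id: str,
    fraction: int,
    params: dict,
    ref_volumes: dict[str, float],
    rng: np.random.Generator,
    compute_dose: bool,
    prescription: PrescriptionConfig,
) -> tuple[Session, dict]:
    # online anatomy: day-to-day variation plus on-couch filling
    rate = float(rng.uniform(*config.filling_rate_range))
    minutes = float(rng.uniform(*config.on_couch_time_range))
    day_var = float(rng.normal(0.0, config.day_variation_sd))
    v_online = max(
        config.min_online_bladder_volume,
        params["bladder_reference_volume"] + day_var + rate * minutes,
    )
    r_online = float(
        np.clip(
            params["rectum_reference_radius"]
            + rng.normal(0.0, config.rectum_radius_jitter_sd),
            1.0,
            config.rectum_radius_range[1] + 2.0,
        )
    )
    clin, _extras = _anatomy_from_params(
        config, params, bladder_volume=v_online, rectum_radius=r_online
    )

    # auto arm: level-set perturbation, amplitude coupled to the bladder
    # change; the propagated boost additionally picks up a rigid positioning
    # error that grows with the influencer volume change, and a systematic
    # shrinking bias
    dv_bladder = abs(mask_volume(clin["bladder"]) - ref_volumes["bladder"])
    amplitude = float(
        np.clip(
            rng.uniform(*config.perturb_amplitude_range)
            + config.amplitude_volume_coupling * dv_bladder / 100.0,
            0.0,
            config.max_amplitude,
        )
    )
    amp_boost = min(config.boost_amplitude_factor * amplitude, config.max_amplitude)
    shift_mag = float(
        rng.uniform(*config.boost_shift_base_range)
        + config.boost_shift_per_100cm3 * dv_bladder / 100.0
    )
    direction = rng.standard_normal(3)
    direction /= max(float(np.linalg.norm(direction)), 1e-12)
    shift = shift_mag * direction
    noise = make_noise_field(
        config.shape, config.spacing, config.noise_correlation_mm, rng
    )
    bladder_auto = perturb_contour(clin["bladder"], amplitude, noise_field=noise)
    rectum_auto = perturb_contour(clin["rectum"], amplitude, noise_field=noise)
    ctv_boost_auto = perturb_contour(
        clin["CTV_boost"],
        amp_boost,
        noise_field=noise,
        bias_mm=config.boost_bias_mm,
        shift_mm=shift,
    )
    gtv_auto = erode_margin(ctv_boost_auto, config.ctv_boost_margin)
    if not gtv_auto.require_binary().any():
        # degenerate heavy shrink: keep a one-voxel GTV at the boost centroid
        com = np.round(ndimage.center_of_mass(ctv_boost_auto.require_binary()))
        seed_mask = np.zeros(config.shape, dtype=bool)
        seed_mask[tuple(int(c) for c in com)] = True
        gtv_auto = gtv_auto.with_values(seed_mask & ctv_boost_auto.require_binary())
    auto = _build_structures(
        config,
        "auto",
        bladder_auto.require_binary(),
        rectum_auto.require_binary(),
        gtv_auto.require_binary(),
        clin["body"],
        ctv_boost_mask=ctv_boost_auto.require_binary(),
    )

    if compute_dose:
        dose_clin = synth_dose(
            clin["PTV_boost"], clin["PTV_elective"], prescription,
            config.dose_falloff_half_mm,
        )
        dose_auto = synth_dose(
            auto["PTV_boost"], auto["PTV_elective"], prescription,
            config.dose_falloff_half_mm,
        )
    else:
        # placeholder uniform elective-level dose keeps sessions valid
        per_fx = prescription.elective_total / prescription.fractions
        flat = np.full(config.shape, per_fx, dtype=np.float32)
        dose_clin = clin["body"].with_values(flat)
        dose_auto = clin["body"].with_values(flat.copy())

    probs = config.correction_probabilities
    corrections = {role: bool(rng.random() < p) for role, p in probs.items()}
    session = Session(
        patient_id=patient_id,
        fraction=fraction,
        contours_clin=clin,
        contours_auto=auto,
        dose_clin=dose_clin,
        dose_auto=dose_auto,
        corrections=corrections,
        reference_volumes=dict(ref_volumes),
    )
    truth = {
        "patient_id": patient_id,
        "fraction": fraction,
        "amplitude_mm": amplitude,
        "boost_amplitude_mm": amp_boost,
        "boost_bias_mm": config.boost_bias_mm,
        "boost_shift_mm": shift_mag,
        "bladder_volume_change_cm3": dv_bladder,
        "online_bladder_volume_cm3": mask_volume(clin["bladder"]),
        "filling_rate_ml_min": rate,
        "on_couch_min": minutes,
    }
    return session, truth


def iter_cohort(
    config: PhantomConfig,
    compute_dose: bool = True,
    prescription: PrescriptionConfig | None = None,
    validate: bool = True,
) -> Iterator[tuple[Session, dict]]:
    """Stream ``(session, ground-truth entry)`` pairs for the whole cohort.

    Sessions are yielded one at a time so a 17 × 20 cohort never has to be
    held in memory at once.
    """
    prescription = prescription or PrescriptionConfig(fractions=config.fractions)
    root = np.random.SeedSequence(config.master_seed)
    patient_seeds = root.spawn(config.patients)
    for p, pseed in enumerate(patient_seeds):
        child = pseed.spawn(config.fractions + 1)
        patient_rng = np.random.default_rng(child[0])
        patient_id = f"P{p + 1:02d}"
        params = _patient_params(config, patient_rng)
        ref_sset, _ = _anatomy_from_params(
            config,
            params,
            bladder_volume=params["bladder_reference_volume"],
            rectum_radius=params["rectum_reference_radius"],
        )
        ref_volumes = {
            "bladder": mask_volume(ref_sset["bladder"]),
            "rectum": mask_volume(ref_sset["rectum"]),
        }
        for f in range(config.fractions):
            rng = np.random.default_rng(child[f + 1])
            session, truth = _make_session(
                config, patient_id, f + 1, params, ref_volumes, rng,
                compute_dose, prescription,
            )
            if validate:
                session.validate()
            yield session, truth


def generate_cohort(
    config: PhantomConfig,
    compute_dose: bool = True,
    prescription: PrescriptionConfig | None = None,
) -> tuple[list[Session], GroundTruthLog]:
    """Materialize the full cohort (use :func:`iter_cohort` for large runs)."""
    log = GroundTruthLog(master_seed=config.master_seed)
    sessions: list[Session] = []
    for session, truth in iter_cohort(config, compute_dose, prescription):
        sessions.append(session)
        log.entries.append(truth)
    return sessions, log
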