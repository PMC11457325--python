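"""DVH-based dosimetric evaluation: V95% coverage, dose spill, requirement check.

All coverage records are computed on the *clinical* contours (the ground
truth) for both dose arms: the question answered is whether the dose
distribution re-optimized on the automatically proposed contours (D_auto)
would still have covered the clinically approved targets.

Boost targets (GTV, CTV_boost, PTV_boost) are judged against 95% of the
boost prescription; elective targets (CTV_elective, PTV_elective) against
95% of the elective prescription.  Dose spill is

    V95_out = V95_body − V95_target   (absolute volumes, cm³),

the body volume above threshold that lies outside the target.  The
prescription level defining V95_body is the elective one by default
(``body_level='elective'``); per-target thresholds are available with
``body_level='own'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    BOOST_ROLES,
    ELECTIVE_ROLES,
    PrescriptionConfig,
    Session,
    ValidationError,
    VolumeGrid,
    voxel_volume,
)

__all__ = [
    "DosimetricRecord",
    "resample_dose",
    "coverage_threshold",
    "v_at_threshold",
    "v95_out",
    "dosimetric_record",
    "cumulative_dvh",
]


@dataclass
class DosimetricRecord:
    """V95 coverage of one clinical structure under one dose arm."""

    structure: str
    arm: str  # 'clin' (D_clin) or 'auto' (D_auto)
    v95_percent: float  # percent of the structure volume above threshold
    v95_abs: float  # cm³
    v95_body_abs: float  # cm³
    v95_out_abs: float  # cm³, = v95_body_abs − v95_abs
    meets_requirement: bool
    threshold_gy: float
    n_outside_dose_grid: int = 0


def resample_dose(dose: VolumeGrid, frame: VolumeGrid) -> tuple[np.ndarray, int]:
    """Trilinearly interpolate a dose grid at the voxel centers of ``frame``.

    Returns ``(values, n_outside)`` where ``values`` has the frame's shape and
    ``n_outside`` counts query points falling outside the dose grid's node
    range; those receive 0 Gy.
    """
    if dose.same_frame(frame):
        return np.asarray(dose.values, dtype=float), 0
    idx = np.indices(frame.shape, dtype=float)
    world = frame.origin[:, None, None, None] + idx * frame.spacing[:, None, None, None]
    coords = (world - dose.origin[:, None, None, None]) / dose.spacing[:, None, None, None]
    upper = (np.array(dose.shape, dtype=float) - 1)[:, None, None, None]
    outside = np.any((coords < 0) | (coords > upper), axis=0)
    values = ndimage.map_coordinates(
        np.asarray(dose.values, dtype=float), coords, order=1, mode="constant", cval=0.0
    )
    values[outside] = 0.0
    return values, int(outside.sum())


def coverage_threshold(role: str, config: PrescriptionConfig) -> float:
    """Coverage dose threshold (Gy) for a target role: the coverage fraction
    (default 95%) of the role's prescription on the configured scale."""
    if role in BOOST_ROLES:
        level = "boost"
    elif role in ELECTIVE_ROLES:
        level = "elective"
    else:
        raise ValidationError(f"{role!r} is not a target role; no coverage threshold defined")
    return config.coverage_fraction * config.prescription(level)


def v_at_threshold(
    mask: VolumeGrid, dose_values: np.ndarray, threshold: float
) -> tuple[float, float]:
    """(percent, cm³) of a structure receiving at least ``threshold`` Gy."""
    m = mask.require_binary()
    n = int(m.sum())
    if n == 0:
        raise ValidationError("V-at-threshold undefined for an empty mask")
    covered = int(np.count_nonzero(np.asarray(dose_values)[m] >= threshold))
    return 100.0 * covered / n, covered * voxel_volume(mask)


def v95_out(
    body: VolumeGrid, target: VolumeGrid, dose_values: np.ndarray, threshold: float
) -> float:
    """Dose spill in cm³: body volume above threshold minus target volume
    above threshold.  Requires target ⊆ body."""
    if np.any(target.require_binary() & ~body.require_binary()):
        raise ValidationError("v95_out requires the target to be contained in the body")
    _, body_abs = v_at_threshold(body, dose_values, threshold)
    _, target_abs = v_at_threshold(target, dose_values, threshold)
    return body_abs - target_abs


def dosimetric_record(
    session: Session,
    role: str,
    arm: str,
    config: PrescriptionConfig,
    body_level: str = "elective",
    evaluate_on: str = "clin",
) -> DosimetricRecord:
    """Full coverage record for one (structure, dose arm) pair.

    ``evaluate_on='clin'`` (the default and the evaluation's ground truth)
    scores the clinical contours; ``'auto'`` is a diagnostic alternative.
    """
    contours = session.contours_clin if evaluate_on == "clin" else session.contours_auto
    if role not in contours:
        raise ValidationError(f"role {role!r} missing from {evaluate_on} contours")
    mask = contours[role]
    body = contours["body"]
    dose_values, n_outside = resample_dose(session.dose(arm), mask)

    threshold = coverage_threshold(role, config)
    if body_level == "elective":
        body_threshold = config.coverage_fraction * config.prescription("elective")
    elif body_level == "own":
        body_threshold = threshold
    else:
        raise ValidationError(f"body_level must be 'elective' or 'own', got {body_level!r}")

    pct, v_abs = v_at_threshold(mask, dose_values, threshold)
    _, body_abs = v_at_threshold(body, dose_values, body_threshold)
    # definitional identity: spill = body coverage minus target coverage
    out_abs = body_abs - v_abs
    return DosimetricRecord(
        structure=role,
        arm=arm,
        v95_percent=pct,
        v95_abs=v_abs,
        v95_body_abs=body_abs,
        v95_out_abs=out_abs,
        meets_requirement=bool(pct >= config.coverage_requirement),
        threshold_gy=threshold,
        n_outside_dose_grid=n_outside,
    )


def cumulative_dvh(
    mask: VolumeGrid, dose_values: np.ndarray, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative dose-volume histogram of a structure.

    Returns ``(dose_edges, percent)`` where ``percent[i]`` is the percent of
    the structure receiving at least ``dose_edges[i]`` Gy; the curve starts at
    100% at 0 Gy and is non-increasing.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    m = mask.require_binary()
    n = int(m.sum())
    if n == 0:
        raise ValidationError("DVH undefined for an empty mask")
    d = np.asarray(dose_values)[m]
    top = float(d.max()) if d.size else 0.0
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    percent = np.array([100.0 * np.count_nonzero(d >= e) / n for e in edges])
    return edges, percent
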