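"""Core domain model: voxel grids, structure sets, treatment sessions, configuration.

Everything downstream (geometric contour comparison, DVH-based coverage,
cohort statistics, stratification) operates on these types.  A session pairs
two structure sets — the clinically corrected contours (``clin``) and the
automatically proposed contours (``auto``) — with the two dose distributions
optimized on each of them (``D_clin``, ``D_auto``).

Conventions
-----------
* Voxel indices are 0-based; the world position of voxel ``(i, j, k)`` is
  ``origin + index * spacing`` (voxel-center convention).
* All masks of one session live on one common grid frame; dose grids may
  differ and are resampled to the structure frame by :mod:`oarteval.dosimetry`.
* Binary masks are boolean arrays; dose grids are non-negative floats in Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ARMS",
    "ROLES",
    "INFLUENCER_ROLES",
    "TARGET_ROLES",
    "BOOST_ROLES",
    "ELECTIVE_ROLES",
    "ValidationError",
    "VolumeGrid",
    "StructureSet",
    "Session",
    "PrescriptionConfig",
    "StatsConfig",
    "StratificationConfig",
    "voxel_volume",
    "mask_volume",
]

ARMS = ("clin", "auto")

#: Structure roles a complete session carries.
ROLES = (
    "bladder",
    "rectum",
    "GTV",
    "CTV_boost",
    "CTV_elective",
    "PTV_boost",
    "PTV_elective",
    "body",
)

#: Organs whose automatic delineation guides target propagation.
INFLUENCER_ROLES = ("bladder", "rectum")

#: Roles receiving the boost prescription (elective + SIB).
BOOST_ROLES = ("GTV", "CTV_boost", "PTV_boost")

#: Roles receiving the elective prescription only.
ELECTIVE_ROLES = ("CTV_elective", "PTV_elective")

TARGET_ROLES = BOOST_ROLES + ELECTIVE_ROLES

MM3_PER_CM3 = 1000.0


class ValidationError(ValueError):
    """A domain invariant is violated (inconsistent frames, empty required
    structure, broken containment chain, non-binary mask, ...)."""


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise ValidationError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


@dataclass
class VolumeGrid:
    """A regular axis-aligned 3D grid carrying a binary mask or a dose in Gy.

    Parameters
    ----------
    origin : array-like of 3 floats
        World coordinates (mm) of the center of voxel (0, 0, 0).
    spacing : array-like of 3 floats
        Voxel edge lengths (mm), strictly positive, possibly anisotropic.
    values : ndarray, 3-D
        Boolean occupancy for masks, or non-negative finite dose in Gy.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = _as_vec3(self.origin, "origin")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(f"values must be 3-D, got {self.values.ndim}-D")
        if not np.all(self.spacing > 0):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")
        if min(self.values.shape) < 1:
            raise ValidationError(f"shape must be strictly positive, got {self.values.shape}")
        if self.values.dtype != bool:
            vals = self.values
            if not np.all(np.isfinite(vals)):
                raise ValidationError("grid values must be finite")
            if np.any(vals < 0):
                raise ValidationError("dose values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_binary(self) -> bool:
        if self.values.dtype == bool:
            return True
        u = np.unique(self.values)
        return bool(np.all(np.isin(u, (0, 1))))

    def require_binary(self) -> np.ndarray:
        """Return the mask as a boolean array, or raise for non-binary values."""
        if self.values.dtype == bool:
            return self.values
        if not self.is_binary:
            raise ValidationError("mask contains values other than {0, 1}")
        return self.values.astype(bool)

    def same_frame(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
        )

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World (mm) positions of voxel-index rows (n, 3)."""
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def bounding_box_world(self) -> tuple[np.ndarray, np.ndarray] | None:
        """(min, max) world coordinates of set voxel centers, or None if empty."""
        mask = self.require_binary()
        idx = np.argwhere(mask)
        if idx.size == 0:
            return None
        return self.world_coordinates(idx.min(axis=0)), self.world_coordinates(idx.max(axis=0))

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(self.origin.copy(), self.spacing.copy(), values)


def voxel_volume(grid: VolumeGrid) -> float:
    """Volume of one voxel in cm³ (product of spacings, mm³ → cm³)."""
    return float(np.prod(grid.spacing)) / MM3_PER_CM3


def mask_volume(mask: VolumeGrid) -> float:
    """Volume of a binary mask in cm³ (set-voxel count × voxel volume)."""
    return int(mask.require_binary().sum()) * voxel_volume(mask)


@dataclass
class StructureSet:
    """Named binary masks for one arm (clin or auto) of one session.

    All masks must share one grid frame.  Required invariants (checked by
    :meth:`validate`): the body is a superset of every target mask, and the
    boost chain GTV ⊆ CTV_boost ⊆ PTV_boost holds.
    """

    arm: str
    masks: dict[str, VolumeGrid]

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"arm must be one of {ARMS}, got {self.arm!r}")

    def __getitem__(self, role: str) -> VolumeGrid:
        return self.masks[role]

    def __contains__(self, role: str) -> bool:
        return role in self.masks

    @property
    def frame(self) -> VolumeGrid:
        return next(iter(self.masks.values()))

    def validate(self, required_roles: Iterable[str] = ROLES) -> None:
        problems: list[str] = []
        required = tuple(required_roles)
        for role in required:
            if role not in self.masks:
                problems.append(f"missing role {role!r}")
        if problems:
            raise ValidationError(f"{self.arm} structure set: " + "; ".join(problems))

        frame = self.frame
        for role, grid in self.masks.items():
            if not grid.is_binary:
                problems.append(f"{role}: non-binary mask")
            if not grid.same_frame(frame):
                problems.append(f"{role}: grid frame differs from the set's frame")
        if problems:
            raise ValidationError(f"{self.arm} structure set: " + "; ".join(problems))

        for role in required:
            if not self.masks[role].require_binary().any():
                problems.append(f"{role}: empty mask for a required role")
        if problems:
            raise ValidationError(f"{self.arm} structure set: " + "; ".join(problems))

        body = self.masks["body"].require_binary() if "body" in self.masks else None
        if body is not None:
            for role in TARGET_ROLES + INFLUENCER_ROLES:
                if role in self.masks and np.any(self.masks[role].require_binary() & ~body):
                    problems.append(f"{role}: not contained in body")
        for inner, outer in (("GTV", "CTV_boost"), ("CTV_boost", "PTV_boost")):
            if inner in self.masks and outer in self.masks:
                if np.any(self.masks[inner].require_binary() & ~self.masks[outer].require_binary()):
                    problems.append(f"containment {inner} ⊆ {outer} violated")
        if problems:
            raise ValidationError(f"{self.arm} structure set: " + "; ".join(problems))


@dataclass
class Session:
    """One treatment fraction: paired structure sets, paired dose grids, metadata.

    ``corrections`` flags which roles were manually adjusted in the clinical
    workflow; ``reference_volumes`` carries the influencer volumes (cm³)
    delineated on the reference CT, used by the stratification analysis.
    """

    patient_id: str
    fraction: int
    contours_clin: StructureSet
    contours_auto: StructureSet
    dose_clin: VolumeGrid
    dose_auto: VolumeGrid
    corrections: dict[str, bool] = field(default_factory=dict)
    reference_volumes: dict[str, float] = field(default_factory=dict)

    def dose(self, arm: str) -> VolumeGrid:
        if arm == "clin":
            return self.dose_clin
        if arm == "auto":
            return self.dose_auto
        raise ValidationError(f"unknown dose arm {arm!r}")

    def validate(self, required_roles: Iterable[str] = ROLES) -> None:
        if not 1 <= int(self.fraction):
            raise ValidationError(f"fraction must be >= 1, got {self.fraction}")
        if self.contours_clin.arm != "clin" or self.contours_auto.arm != "auto":
            raise ValidationError(
                f"session {self.patient_id}/fx{self.fraction}: arms mislabelled "
                f"({self.contours_clin.arm!r}, {self.contours_auto.arm!r})"
            )
        self.contours_clin.validate(required_roles)
        self.contours_auto.validate(required_roles)
        self._check_dose_coverage(required_roles)

    def _check_dose_coverage(self, required_roles: Iterable[str]) -> None:
        """Both dose grids must cover the union of all target bounding boxes."""
        lo = None
        hi = None
        for sset in (self.contours_clin, self.contours_auto):
            for role in TARGET_ROLES:
                if role not in tuple(required_roles) or role not in sset:
                    continue
                bb = sset[role].bounding_box_world()
                if bb is None:
                    continue
                lo = bb[0] if lo is None else np.minimum(lo, bb[0])
                hi = bb[1] if hi is None else np.maximum(hi, bb[1])
        if lo is None:
            return
        for name, dose in (("D_clin", self.dose_clin), ("D_auto", self.dose_auto)):
            d_lo = dose.origin
            d_hi = dose.origin + (np.array(dose.shape) - 1) * dose.spacing
            # allow half a voxel of slack at the dose-grid edge
            slack = dose.spacing / 2
            if np.any(lo < d_lo - slack) or np.any(hi > d_hi + slack):
                raise ValidationError(
                    f"session {self.patient_id}/fx{self.fraction}: dose grid {name} "
                    f"does not cover the target bounding box"
                )


@dataclass
class PrescriptionConfig:
    """Prescription and coverage-evaluation settings.

    Defaults reflect a 40 Gy elective prescription with a 15 Gy simultaneous
    integrated boost, delivered in 20 fractions; target coverage is judged as
    V95% (volume receiving ≥ 95% of the prescribed dose) against a clinical
    requirement of at least 98%.
    """

    elective_total: float = 40.0
    boost_extra: float = 15.0
    fractions: int = 20
    evaluation_scale: str = "per_fraction"
    coverage_fraction: float = 0.95
    coverage_requirement: float = 98.0

    def __post_init__(self) -> None:
        if not 0 < self.coverage_fraction < 1:
            raise ValidationError("coverage_fraction must lie in (0, 1)")
        if self.fractions < 1:
            raise ValidationError("fractions must be >= 1")
        if self.evaluation_scale not in ("per_fraction", "total"):
            raise ValidationError(
                f"evaluation_scale must be 'per_fraction' or 'total', got {self.evaluation_scale!r}"
            )

    @property
    def boost_total(self) -> float:
        return self.elective_total + self.boost_extra

    def prescription(self, level: str) -> float:
        """Prescribed dose (Gy) for a level ('boost' or 'elective') on the
        configured evaluation scale."""
        total = {"boost": self.boost_total, "elective": self.elective_total}[level]
        if self.evaluation_scale == "per_fraction":
            return total / self.fractions
        return total


@dataclass
class StatsConfig:
    """Multiplicity and exact-test settings for the paired cohort statistics."""

    family_alpha: float = 0.05
    family_size: int = 10
    exact_n_max: int = 20

    def __post_init__(self) -> None:
        if self.family_size < 1:
            raise ValidationError("family_size must be >= 1")
        if not 0 < self.family_alpha < 1:
            raise ValidationError("family_alpha must lie in (0, 1)")

    @property
    def corrected_alpha(self) -> float:
        return self.family_alpha / self.family_size


@dataclass
class StratificationConfig:
    """Binning of reference-to-online influencer volume differences (cm³)."""

    bladder_bin_width: float = 50.0
    rectum_bin_width: float = 25.0
    max_bins: int = 4
    signed: bool = False

    def __post_init__(self) -> None:
        if self.bladder_bin_width <= 0 or self.rectum_bin_width <= 0:
            raise ValidationError("bin widths must be strictly positive")
        if self.max_bins < 1:
            raise ValidationError("max_bins must be >= 1")

    def bin_width(self, influencer_role: str) -> float:
        if influencer_role == "bladder":
            return self.bladder_bin_width
        if influencer_role == "rectum":
            return self.rectum_bin_width
        raise ValidationError(f"no bin width defined for role {influencer_role!r}")
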