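"""Session I/O: DICOM-RT inputs, an internal session bundle, report writing.

Three surfaces:

* **DICOM-RT (read)** — RTSTRUCT contour polygons are rasterized onto a
  target grid frame (voxel-center even-odd rule, holes via XOR); RTDOSE
  grids are loaded with the dose-grid-scaling factor applied.
* **Internal bundle (read/write)** — one compressed array file per mask or
  dose plus a JSON manifest; self-contained, no DICOM machinery needed for
  tests or synthetic cohorts.  Masks can additionally be exported as NIfTI
  for external viewing.
* **Reports (write)** — per-session CSV tables plus a JSON summary in the
  median [min–max] reporting convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ROLES, Session, StructureSet, ValidationError, VolumeGrid

__all__ = [
    "SessionManifest",
    "rasterize_polygon_slice",
    "rasterize_contours",
    "read_session",
    "write_session",
    "export_mask_nifti",
    "read_rtdose",
    "read_rtstruct",
    "write_report",
]


# ---------------------------------------------------------------------------
# rasterization


def rasterize_polygon_slice(
    polygons: Sequence[np.ndarray],
    x_centers: np.ndarray,
    y_centers: np.ndarray,
) -> np.ndarray:
    """Even-odd rasterization of planar polygons onto one grid slice.

    A pixel is set iff its center lies inside an odd number of the polygon
    rings (XOR combination supports holes).  Points exactly on an edge follow
    a half-open convention: inside on the minimum-coordinate edge, outside on
    the maximum, so adjacent polygons tile without overlap.
    """
    out = np.zeros((x_centers.size, y_centers.size), dtype=bool)
    px = np.asarray(x_centers, dtype=float)[:, None]
    py = np.asarray(y_centers, dtype=float)[None, :]
    for ring in polygons:
        ring = np.asarray(ring, dtype=float)
        if ring.shape[0] < 3:
            raise ValidationError("polygon ring needs at least 3 vertices")
        inside = np.zeros_like(out)
        x1, y1 = ring[:, 0], ring[:, 1]
        x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
        for ax, ay, bx, by in zip(x1, y1, x2, y2):
            if ay == by:
                continue  # horizontal edge never crosses a scanline half-open in y
            crosses = ((ay <= py) & (py < by)) | ((by <= py) & (py < ay))
            x_int = ax + (py - ay) * (bx - ax) / (by - ay)
            inside ^= crosses & (px < x_int)
        out ^= inside
    return out


def rasterize_contours(
    contours: Mapping[float, Sequence[np.ndarray]] | Sequence[tuple[float, Sequence[np.ndarray]]],
    frame: VolumeGrid,
    slice_tolerance: float | None = None,
) -> VolumeGrid:
    """Rasterize per-slice planar polygons (world mm) onto a grid frame.

    ``contours`` maps slice z-position (mm) to a list of closed (n, 2) rings
    in world x/y.  Each slice position must match a grid slice within half a
    slice spacing (or ``slice_tolerance``).
    """
    items = contours.items() if isinstance(contours, Mapping) else contours
    nx, ny, nz = frame.shape
    xc = frame.origin[0] + np.arange(nx) * frame.spacing[0]
    yc = frame.origin[1] + np.arange(ny) * frame.spacing[1]
    tol = slice_tolerance if slice_tolerance is not None else frame.spacing[2] / 2.0
    mask = np.zeros(frame.shape, dtype=bool)
    for z, rings in items:
        k_float = (z - frame.origin[2]) / frame.spacing[2]
        k = int(round(k_float))
        if not 0 <= k < nz or abs(z - (frame.origin[2] + k * frame.spacing[2])) > tol:
            raise ValidationError(
                f"contour slice at z = {z:g} mm matches no grid slice "
                f"(tolerance {tol:g} mm)"
            )
        mask[:, :, k] ^= rasterize_polygon_slice(rings, xc, yc)
    return frame.with_values(mask)


# ---------------------------------------------------------------------------
# internal bundle


@dataclass
class SessionManifest:
    """Paths and metadata of one serialized session."""

    patient_id: str
    fraction: int
    grid: dict  # origin / spacing / shape of the structure frame
    masks: dict  # arm -> role -> relative path
    doses: dict  # arm -> relative path
    corrections: dict = field(default_factory=dict)
    reference_volumes: dict = field(default_factory=dict)
    prescription: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "fraction": self.fraction,
            "grid": self.grid,
            "masks": self.masks,
            "doses": self.doses,
            "corrections": self.corrections,
            "reference_volumes": self.reference_volumes,
            "prescription": self.prescription,
        }

    @classmethod
    def from_json(cls, d: Mapping) -> "SessionManifest":
        return cls(
            patient_id=d["patient_id"],
            fraction=int(d["fraction"]),
            grid=dict(d["grid"]),
            masks={arm: dict(m) for arm, m in d["masks"].items()},
            doses=dict(d["doses"]),
            corrections=dict(d.get("corrections", {})),
            reference_volumes=dict(d.get("reference_volumes", {})),
            prescription=dict(d.get("prescription", {})),
        )


def _save_array(path: Path, values: np.ndarray) -> None:
    np.savez_compressed(path, values=values)


def _load_array(path: Path) -> np.ndarray:
    with np.load(path) as npz:
        return npz["values"]


def write_session(session: Session, out_dir: str | Path) -> Path:
    """Serialize a session to ``out_dir`` (one .npz per mask/dose plus
    ``manifest.json``); returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = session.contours_clin.frame
    masks: dict[str, dict[str, str]] = {}
    for sset in (session.contours_clin, session.contours_auto):
        paths = {}
        for role, grid in sset.masks.items():
            rel = f"{sset.arm}_{role}.npz"
            _save_array(out / rel, grid.require_binary())
            paths[role] = rel
        masks[sset.arm] = paths
    doses = {}
    for arm, dose in (("clin", session.dose_clin), ("auto", session.dose_auto)):
        rel = f"dose_{arm}.npz"
        _save_array(out / rel, np.asarray(dose.values, dtype=np.float32))
        doses[arm] = {
            "path": rel,
            "origin": list(map(float, dose.origin)),
            "spacing": list(map(float, dose.spacing)),
        }
    manifest = SessionManifest(
        patient_id=session.patient_id,
        fraction=session.fraction,
        grid={
            "origin": list(map(float, frame.origin)),
            "spacing": list(map(float, frame.spacing)),
            "shape": list(frame.shape),
        },
        masks=masks,
        doses=doses,
        corrections={k: bool(v) for k, v in session.corrections.items()},
        reference_volumes={k: float(v) for k, v in session.reference_volumes.items()},
    )
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest.to_json(), indent=1, sort_keys=True))
    return manifest_path


def read_session(manifest_path: str | Path, validate: bool = True) -> Session:
    """Load and (by default) validate a session bundle."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ValidationError(f"manifest not found: {manifest_path}")
    manifest = SessionManifest.from_json(json.loads(manifest_path.read_text()))
    base = manifest_path.parent
    origin = manifest.grid["origin"]
    spacing = manifest.grid["spacing"]

    sets = {}
    for arm in ("clin", "auto"):
        roles = manifest.masks.get(arm, {})
        missing = [r for r in ROLES if r not in roles]
        if missing:
            raise ValidationError(
                f"manifest {manifest_path}: {arm} arm missing roles {missing}"
            )
        grids = {}
        for role, rel in roles.items():
            values = _load_array(base / rel)
            if values.dtype != bool:
                raise ValidationError(f"{arm}/{role}: stored mask is not boolean")
            grids[role] = VolumeGrid(origin, spacing, values)
        sets[arm] = StructureSet(arm=arm, masks=grids)

    doses = {}
    for arm in ("clin", "auto"):
        if arm not in manifest.doses:
            raise ValidationError(f"manifest {manifest_path}: missing dose arm {arm!r}")
        entry = manifest.doses[arm]
        doses[arm] = VolumeGrid(
            entry.get("origin", origin),
            entry.get("spacing", spacing),
            _load_array(base / entry["path"]).astype(np.float32),
        )

    session = Session(
        patient_id=manifest.patient_id,
        fraction=manifest.fraction,
        contours_clin=sets["clin"],
        contours_auto=sets["auto"],
        dose_clin=doses["clin"],
        dose_auto=doses["auto"],
        corrections=manifest.corrections,
        reference_volumes=manifest.reference_volumes,
    )
    if validate:
        session.validate()
    return session


def export_mask_nifti(mask: VolumeGrid, path: str | Path) -> Path:
    """Export a binary mask as NIfTI (affine from origin/spacing)."""
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(mask.spacing)
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.require_binary().astype(np.uint8), affine)
    path = Path(path)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# DICOM-RT


def read_rtdose(path: str | Path) -> VolumeGrid:
    """Load a DICOM RTDOSE grid (Gy), applying DoseGridScaling.

    The returned array is indexed (x, y, z); the DICOM frame offsets supply
    the z spacing (uniform offsets required).
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    raw = ds.pixel_array.astype(np.float64) * scaling  # (frames, rows, cols)
    values = np.transpose(raw, (2, 1, 0))  # -> (x, y, z)
    origin = np.array([float(v) for v in ds.ImagePositionPatient])
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz, dz[0]):
        raise ValidationError(f"{path}: non-uniform GridFrameOffsetVector")
    z_spacing = float(dz[0]) if offsets.size > 1 else 1.0
    spacing = np.array([col_spacing, row_spacing, z_spacing])
    origin = origin + np.array([0.0, 0.0, offsets[0]])
    return VolumeGrid(origin, spacing, values)


def read_rtstruct(
    path: str | Path,
    frame: VolumeGrid,
    role_map: Mapping[str, str] | None = None,
) -> dict[str, VolumeGrid]:
    """Rasterize the contours of a DICOM RTSTRUCT onto ``frame``.

    ``role_map`` maps DICOM ROI names to structure roles; unmapped ROIs keep
    their DICOM name.  Returns role → binary mask.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds, "StructureSetROISequence", [])
    }
    out: dict[str, VolumeGrid] = {}
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        number = int(roi_contour.ReferencedROINumber)
        name = names.get(number, f"ROI{number}")
        role = (role_map or {}).get(name, name)
        per_slice: dict[float, list[np.ndarray]] = {}
        for contour in getattr(roi_contour, "ContourSequence", []):
            pts = np.array([float(v) for v in contour.ContourData]).reshape(-1, 3)
            z = float(np.mean(pts[:, 2]))
            per_slice.setdefault(round(z, 3), []).append(pts[:, :2])
        out[role] = rasterize_contours(per_slice, frame)
    return out


# ---------------------------------------------------------------------------
# reports


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_report(
    tables: Mapping[str, pd.DataFrame],
    summary: Mapping,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write cohort tables as CSV plus the JSON summary; returns the paths.

    Float formatting is fixed so identical inputs give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g", lineterminator="\n")
        paths[name] = p
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=1, sort_keys=True, default=_json_default))
    paths["summary"] = p
    return paths
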