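"""Readers and writers for the interchange formats the toolkit touches.

DICOM RT-STRUCT structure sets are parsed into planar polygon sets in
patient coordinates (mm); DICOM RT-DOSE grids are parsed into cGy dose
volumes on axis-aligned grids.  Binary masks round-trip through NIfTI
(and NRRD) with an axis-aligned positive-spacing affine, carrying the
structure name in a JSON sidecar.  Cohort reports are written as
deterministic CSV/JSON.

Only axis-aligned head-first-supine geometry is supported; oblique
orientations are rejected at read time.  The RT-STRUCT/RT-DOSE *writers*
exist to build test fixtures and phantom exports — they emit minimal but
standard-conformant objects and are not a clinical export path.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .dvh import DoseGrid
from .errors import FormatError, UnsupportedOrientationError
from .grid import ContourPolygonSet, ImageGrid, StructureMask
from .stats import COHORT_COLUMNS, GroupComparison

__all__ = [
    "RTStudy",
    "read_rtstruct",
    "write_rtstruct",
    "read_rtdose",
    "write_rtdose",
    "read_mask",
    "write_mask",
    "read_dose_volume",
    "write_dose_volume",
    "write_report",
    "validate_report",
]

_RTSTRUCT_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
_RTDOSE_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
_AXIAL_ORIENTATION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


@dataclass
class RTStudy:
    """One patient's data bundle: frame grid, contours and optional dose."""

    patient_id: str
    grid: ImageGrid
    structures: list[ContourPolygonSet] = field(default_factory=list)
    dose: DoseGrid | None = None


# ---------------------------------------------------------------------------
# DICOM RT-STRUCT


def _new_file_dataset(sop_class: str, patient_id: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientName = patient_id
    ds.PatientID = patient_id
    now = datetime.datetime(2000, 1, 1)  # fixed stamp keeps fixtures stable
    ds.ContentDate = now.strftime("%Y%m%d")
    ds.ContentTime = now.strftime("%H%M%S")
    return ds


def write_rtstruct(
    path, structures: list[ContourPolygonSet], patient_id: str = "ANON"
) -> None:
    """Write planar polygon sets as a minimal DICOM RT Structure Set."""
    ds = _new_file_dataset(_RTSTRUCT_CLASS, patient_id)
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "contourqa"
    frame_uid = generate_uid()
    ssroi_seq = []
    roic_seq = []
    for num, cps in enumerate(structures, start=1):
        ssroi = Dataset()
        ssroi.ROINumber = num
        ssroi.ROIName = cps.name
        ssroi.ReferencedFrameOfReferenceUID = frame_uid
        ssroi.ROIGenerationAlgorithm = "AUTOMATIC"
        ssroi_seq.append(ssroi)
        roic = Dataset()
        roic.ReferencedROINumber = num
        contour_seq = []
        for z, polys in cps.planes:
            for poly in polys:
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = poly.shape[0]
                flat = np.column_stack(
                    [poly[:, 0], poly[:, 1], np.full(poly.shape[0], z)]
                ).ravel()
                c.ContourData = [f"{v:.6f}" for v in flat]
                contour_seq.append(c)
        roic.ContourSequence = contour_seq
        roic_seq.append(roic)
    ds.StructureSetROISequence = ssroi_seq
    ds.ROIContourSequence = roic_seq
    ds.save_as(str(path), enforce_file_format=True)


def read_rtstruct(path) -> list[ContourPolygonSet]:
    """Parse a DICOM RT Structure Set into planar polygon sets.

    ROI names are preserved verbatim.  Non-planar contour items are
    skipped with a warning; ROIs without any usable contour data are
    skipped with a warning.  Corrupt files raise :class:`FormatError`.
    """
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pydicom raises several unrelated types
        raise FormatError(f"cannot read RT-STRUCT '{path}': {exc}") from exc
    if getattr(ds, "SOPClassUID", None) != _RTSTRUCT_CLASS and not hasattr(
        ds, "StructureSetROISequence"
    ):
        raise FormatError(f"'{path}' is not an RT Structure Set")
    names = {
        int(item.ROINumber): str(item.ROIName)
        for item in getattr(ds, "StructureSetROISequence", [])
    }
    out: list[ContourPolygonSet] = []
    for roic in getattr(ds, "ROIContourSequence", []):
        num = int(roic.ReferencedROINumber)
        name = names.get(num, f"ROI_{num}")
        planes: dict[float, list[np.ndarray]] = {}
        for c in getattr(roic, "ContourSequence", []):
            gtype = getattr(c, "ContourGeometricType", "")
            if gtype != "CLOSED_PLANAR":
                warnings.warn(
                    f"ROI '{name}': skipping non-planar contour ({gtype})",
                    stacklevel=2,
                )
                continue
            pts = np.array([float(v) for v in c.ContourData]).reshape(-1, 3)
            if pts.shape[0] < 3:
                warnings.warn(
                    f"ROI '{name}': skipping degenerate contour", stacklevel=2
                )
                continue
            z = round(float(pts[:, 2].mean()), 3)
            planes.setdefault(z, []).append(pts[:, :2])
        if not planes:
            warnings.warn(f"ROI '{name}': no usable contour data", stacklevel=2)
            continue
        out.append(
            ContourPolygonSet(
                name=name, planes=[(z, polys) for z, polys in sorted(planes.items())]
            )
        )
    return out


# ---------------------------------------------------------------------------
# DICOM RT-DOSE


def write_rtdose(path, dose: DoseGrid, patient_id: str = "ANON") -> None:
    """Write a dose grid as a minimal DICOM RT Dose (32-bit, Gy scaling)."""
    g = dose.grid
    ds = _new_file_dataset(_RTDOSE_CLASS, patient_id)
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    gy = dose.dose / 100.0
    max_gy = float(gy.max())
    scaling = max_gy / (2**32 - 1) if max_gy > 0 else 1e-8
    # quantize against the value as serialized (DS caps at 16 characters);
    # pad so the 10-digit rounding can never push the top value past uint32
    scaling = float(f"{scaling * (1 + 1e-9):.9e}")
    stored = np.minimum(np.round(gy / scaling), 2**32 - 1).astype(np.uint32)
    ds.DoseGridScaling = f"{scaling:.9e}"
    ds.ImagePositionPatient = [f"{v:.6f}" for v in g.origin]
    ds.ImageOrientationPatient = [f"{v:.1f}" for v in _AXIAL_ORIENTATION]
    ds.PixelSpacing = [f"{g.spacing[1]:.6f}", f"{g.spacing[0]:.6f}"]  # row(y), col(x)
    ds.GridFrameOffsetVector = [f"{g.spacing[2] * k:.6f}" for k in range(g.shape[2])]
    ds.Rows = g.shape[1]
    ds.Columns = g.shape[0]
    ds.NumberOfFrames = g.shape[2]
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    # stored order is (frame=z, row=y, col=x)
    ds.PixelData = np.ascontiguousarray(stored.transpose(2, 1, 0)).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_rtdose(path) -> DoseGrid:
    """Parse a DICOM RT Dose into a cGy :class:`DoseGrid`.

    Stored integers are scaled by DoseGridScaling and converted to cGy.
    Oblique orientations and missing scaling are rejected.
    """
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read RT-DOSE '{path}': {exc}") from exc
    if "DoseGridScaling" not in ds:
        raise FormatError(f"'{path}' has no DoseGridScaling")
    orient = np.array([float(v) for v in ds.ImageOrientationPatient])
    if not np.allclose(orient, _AXIAL_ORIENTATION, atol=1e-6):
        raise UnsupportedOrientationError(
            f"'{path}' stores an oblique orientation {orient.tolist()}"
        )
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    if offsets.size > 1:
        steps = np.diff(offsets)
        if not np.allclose(steps, steps[0], atol=1e-6) or steps[0] <= 0:
            raise FormatError(f"'{path}' has a non-uniform grid frame offset vector")
        sz = float(steps[0])
    else:
        sz = 1.0
    pos = [float(v) for v in ds.ImagePositionPatient]
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    arr = ds.pixel_array  # (frames=z, rows=y, cols=x) or (rows, cols)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    scaled = arr.astype(float) * float(ds.DoseGridScaling)
    if str(getattr(ds, "DoseUnits", "GY")).upper() == "GY":
        scaled *= 100.0
    grid = ImageGrid(
        origin=(pos[0], pos[1], pos[2] + offsets[0] if offsets.size else pos[2]),
        spacing=(col_sp, row_sp, sz),
        shape=(arr.shape[2], arr.shape[1], arr.shape[0]),
    )
    return DoseGrid(grid=grid, dose=np.ascontiguousarray(scaled.transpose(2, 1, 0)))


# ---------------------------------------------------------------------------
# Scalar volumes: NIfTI / NRRD


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii", ".nrrd"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def _affine_to_grid(affine: np.ndarray, shape) -> ImageGrid:
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-6):
        raise UnsupportedOrientationError("volume affine is not axis-aligned")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise UnsupportedOrientationError(
            "volume affine must have positive spacing on the diagonal"
        )
    return ImageGrid(
        origin=tuple(affine[:3, 3]), spacing=tuple(spacing), shape=tuple(shape)
    )


def _grid_to_affine(grid: ImageGrid) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def _read_volume(path: Path) -> tuple[np.ndarray, ImageGrid]:
    if path.name.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        if not np.allclose(np.array(img.GetDirection()), np.eye(3).ravel(), atol=1e-6):
            raise UnsupportedOrientationError(f"'{path}' is not axis-aligned")
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x)->(x,y,z)
        grid = ImageGrid(
            origin=tuple(img.GetOrigin()),
            spacing=tuple(img.GetSpacing()),
            shape=data.shape,
        )
        return data, grid
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"'{path}' is not a 3D volume")
    return data, _affine_to_grid(img.affine, data.shape)


def _write_volume(path: Path, data: np.ndarray, grid: ImageGrid) -> None:
    if path.name.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in grid.spacing))
        img.SetOrigin(tuple(float(o) for o in grid.origin))
        sitk.WriteImage(img, str(path))
        return
    import nibabel as nib

    nib.save(nib.Nifti1Image(data, _grid_to_affine(grid)), str(path))


def write_mask(mask: StructureMask, path) -> None:
    """Write a binary mask as NIfTI/NRRD plus a JSON name sidecar."""
    path = Path(path)
    _write_volume(path, mask.data.astype(np.uint8), mask.grid)
    _sidecar_path(path).write_text(
        json.dumps({"structure": mask.name}, indent=2) + "\n"
    )


def read_mask(path, name: str | None = None) -> StructureMask:
    """Read a binary mask volume; the name comes from the JSON sidecar,
    the ``name`` argument, or the file stem, in that order of preference."""
    path = Path(path)
    data, grid = _read_volume(path)
    sidecar = _sidecar_path(path)
    if name is None and sidecar.exists():
        name = json.loads(sidecar.read_text()).get("structure")
    if name is None:
        name = path.name.split(".")[0]
    return StructureMask(name=name, grid=grid, data=data > 0)


def write_dose_volume(dose: DoseGrid, path) -> None:
    """Write a dose grid (cGy) as a scalar NIfTI/NRRD volume."""
    _write_volume(Path(path), dose.dose.astype(np.float32), dose.grid)


def read_dose_volume(path, units: str = "cgy") -> DoseGrid:
    """Read a scalar volume as a dose grid; ``units`` is ``cgy`` or ``gy``."""
    data, grid = _read_volume(Path(path))
    data = data.astype(float)
    u = units.lower()
    if u == "gy":
        data = data * 100.0
    elif u != "cgy":
        raise FormatError(f"unknown dose units '{units}'")
    return DoseGrid(grid=grid, dose=data)


# ---------------------------------------------------------------------------
# Reports


def write_report(
    cohort: pd.DataFrame,
    comparisons: list[GroupComparison] | None,
    out_dir,
    stem: str = "cohort",
) -> dict[str, Path]:
    """Write a cohort table (CSV) and group-comparison report (JSON).

    Output is byte-stable for fixed input: fixed column order, fixed float
    formatting, sorted JSON keys, ``\\n`` line endings.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns] + [
        c for c in cohort.columns if c not in COHORT_COLUMNS
    ]
    cohort.to_csv(
        csv_path, index=False, columns=cols, float_format="%.6g", lineterminator="\n"
    )
    report = {
        "toolkit": "contourqa",
        "n_rows": int(len(cohort)),
        "cohort_columns": list(map(str, cols)),
        "comparisons": [c.as_dict() for c in (comparisons or [])],
    }
    json_path = out_dir / f"{stem}_comparisons.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return {"csv": csv_path, "json": json_path}


def _check_schema(obj, schema, path="$") -> list[str]:
    errors = []
    t = schema.get("type")
    type_map = {
        "object": dict,
        "array": list,
        "string": str,
        "number": (int, float),
        "integer": int,
        "boolean": bool,
    }
    if t and not isinstance(obj, type_map[t]):
        return [f"{path}: expected {t}, got {type(obj).__name__}"]
    if t == "object":
        for key in schema.get("required", []):
            if key not in obj:
                errors.append(f"{path}: missing required key '{key}'")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                errors.extend(_check_schema(obj[key], sub, f"{path}.{key}"))
    elif t == "array" and "items" in schema:
        for i, item in enumerate(obj):
            errors.extend(_check_schema(item, schema["items"], f"{path}[{i}]"))
    return errors


def validate_report(report: dict) -> list[str]:
    """Validate a JSON report against the shipped schema.

    Returns a list of violation messages (empty when valid).  The check is
    a minimal structural validation: types, required keys, array items.
    """
    schema = json.loads(
        resources.files("contourqa").joinpath("report_schema.json").read_text()
    )
    return _check_schema(report, schema)
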