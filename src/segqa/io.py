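"""Readers and writers for the supported contour file formats.

Three formats are supported for structure input:

* ``contour-json`` — a plain JSON planar-contour format defined by this
  package: ``{"organ": str, "slices": [{"z": float, "polygons":
  [[[x, y], ...], ...]}]}`` with exact float round-trip.
* ``dicom-rt`` — DICOM-RT Structure Sets; each ROI's CLOSED_PLANAR
  contours map to one :class:`~segqa.geometry.ContourStack` (mm, patient
  coordinates).
* ``nifti-masks`` — one binary NIfTI volume per structure; the affine is
  consumed for spacing/origin (axis-aligned affines only) and the mask is
  converted to contours by per-slice boundary tracing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ._exceptions import FrameConsistencyError, GeometryError, StructureLookupError
from .geometry import (
    BinaryMask,
    ContourSlice,
    ContourStack,
    StructurePair,
    VoxelGrid,
    trace_mask_to_contours,
)

__all__ = [
    "read_contour_json",
    "write_contour_json",
    "read_dicom_rt",
    "write_dicom_rt",
    "read_nifti_mask",
    "read_structure_pair",
    "FORMATS",
]

FORMATS = ("contour-json", "dicom-rt", "nifti-masks")


# ---------------------------------------------------------------- contour-json

def write_contour_json(stack: ContourStack, path) -> None:
    payload = {
        "organ": stack.organ_name,
        "slices": [
            {"z": float(s.z), "polygons": [p.tolist() for p in s.polygons]}
            for s in stack.slices
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_contour_json(path) -> ContourStack:
    payload = json.loads(Path(path).read_text())
    slices = tuple(
        ContourSlice(
            z=float(s["z"]), polygons=tuple(np.asarray(p, float) for p in s["polygons"])
        )
        for s in payload["slices"]
    )
    return ContourStack(organ_name=payload["organ"], slices=slices)


# -------------------------------------------------------------------- DICOM-RT

def _require_pydicom():
    import pydicom  # local import keeps DICOM optional at call time

    return pydicom


def read_dicom_rt(path, roi_name: str) -> tuple[ContourStack, str]:
    """Read one named ROI from an RT Structure Set.

    Returns the contour stack and the structure set's frame-of-reference
    UID (used to check gold/auto consistency).
    """
    pydicom = _require_pydicom()
    ds = pydicom.dcmread(path)
    roi_number = None
    frame_uid = ""
    for roi in getattr(ds, "StructureSetROISequence", []):
        if str(roi.ROIName) == roi_name:
            roi_number = roi.ROINumber
            frame_uid = str(getattr(roi, "ReferencedFrameOfReferenceUID", ""))
            break
    if roi_number is None:
        available = [str(r.ROIName) for r in getattr(ds, "StructureSetROISequence", [])]
        raise StructureLookupError(
            f"ROI {roi_name!r} not found in {path}; available: {available}"
        )
    by_z: dict[float, list[np.ndarray]] = {}
    for rc in ds.ROIContourSequence:
        if rc.ReferencedROINumber != roi_number:
            continue
        for c in getattr(rc, "ContourSequence", []):
            if str(getattr(c, "ContourGeometricType", "CLOSED_PLANAR")) != "CLOSED_PLANAR":
                raise GeometryError(
                    f"unsupported contour type {c.ContourGeometricType!r}"
                )
            data = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            zs = data[:, 2]
            if not np.allclose(zs, zs[0]):
                raise GeometryError("non-planar contour: vertices span multiple z")
            by_z.setdefault(float(zs[0]), []).append(data[:, :2])
    if not by_z:
        raise StructureLookupError(f"ROI {roi_name!r} has no contour data")
    slices = tuple(
        ContourSlice(z=z, polygons=tuple(polys)) for z, polys in sorted(by_z.items())
    )
    return ContourStack(organ_name=roi_name, slices=slices), frame_uid


def write_dicom_rt(stacks, path, patient_id: str = "anon", frame_uid: str | None = None):
    """Write contour stacks as a minimal RT Structure Set (one ROI each)."""
    pydicom = _require_pydicom()
    from pydicom.dataset import Dataset, FileDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    frame_uid = frame_uid or generate_uid()
    meta = Dataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTStructureSetStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = pydicom.uid.RTStructureSetStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientID = patient_id
    ds.PatientName = patient_id
    ds.StructureSetLabel = "segqa"
    ds.FrameOfReferenceUID = frame_uid

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for i, stack in enumerate(stacks, start=1):
        roi = Dataset()
        roi.ROINumber = i
        roi.ROIName = stack.organ_name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = ""
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = i
        rc.ContourSequence = []
        for sl in stack.slices:
            for poly in sl.polygons:
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = len(poly)
                xyz = np.column_stack([poly, np.full(len(poly), sl.z)])
                c.ContourData = [float(v) for v in xyz.ravel()]
                rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)


# ----------------------------------------------------------------------- NIfTI

def read_nifti_mask(path, organ_name: str) -> ContourStack:
    """Read a binary NIfTI volume and trace it into per-slice contours.

    Only axis-aligned affines (diagonal rotation block, positive spacing)
    are supported; anything else is a geometry error.
    """
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise GeometryError("NIfTI affine is not axis-aligned")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise GeometryError("NIfTI affine must have positive diagonal spacing")
    data = np.asanyarray(img.dataobj)
    grid = VoxelGrid(
        origin=tuple(affine[:3, 3]), spacing=tuple(spacing), shape=data.shape
    )
    mask = BinaryMask(grid=grid, voxels=data > 0.5)
    return trace_mask_to_contours(mask, organ_name=organ_name)


# ----------------------------------------------------------------- pair reader

def read_structure_pair(
    gold_path,
    auto_path,
    fmt: str,
    patient_id: str,
    organ_name: str | None = None,
) -> StructurePair:
    """Read a gold/auto structure pair in any supported format.

    ``organ_name`` selects the ROI for ``dicom-rt`` and names the
    structure for ``nifti-masks``; for ``contour-json`` it defaults to the
    organ recorded in the files.
    """
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    if fmt == "contour-json":
        gold = read_contour_json(gold_path)
        auto = read_contour_json(auto_path)
    elif fmt == "dicom-rt":
        if organ_name is None:
            raise ValueError("dicom-rt input needs an organ (ROI) name")
        gold, gold_frame = read_dicom_rt(gold_path, organ_name)
        auto, auto_frame = read_dicom_rt(auto_path, organ_name)
        if gold_frame and auto_frame and gold_frame != auto_frame:
            raise FrameConsistencyError(
                "gold and auto structure sets reference different frames "
                f"({gold_frame} vs {auto_frame})"
            )
    else:  # nifti-masks
        if organ_name is None:
            raise ValueError("nifti-masks input needs an organ name")
        gold = read_nifti_mask(gold_path, organ_name)
        auto = read_nifti_mask(auto_path, organ_name)
    return StructurePair(
        patient_id=patient_id,
        organ_name=organ_name or gold.organ_name,
        gold=gold,
        auto=auto,
    )
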