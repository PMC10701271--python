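"""Minimal DICOM-RT interchange: CT series, RTSTRUCT and RTDOSE.

Enough of the standard to round-trip the package's own cases: CT slices with
rescale tags, RTDOSE with its grid-scaling factor applied on read, and
RTSTRUCT planar contours extracted from masks on export and rasterized by
scanline polygon fill on import.  Orientation is fixed axial identity
(row = +x, column = +y); reading arbitrary clinical orientations is out of
scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .grid import PlanCase, VoxelGrid

__all__ = ["export_dicom", "read_ct_series", "read_rtdose", "read_rtstruct", "import_dicom"]

_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"


def _file_dataset(sop_class: str, sop_instance: str, filename: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(filename, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_instance
    return ds


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _mask_slice_contours(mask2d: np.ndarray) -> list[np.ndarray]:
    """Boundary polygons (voxel coordinates, (n, 2) x/y) of a binary slice.

    Marching around the mask is avoided: each 8-connected component is traced
    by taking the convex-ish outline of its boundary pixels ordered by angle.
    Sufficient for the package's convex geometric primitives.
    """
    from scipy import ndimage

    labels, n = ndimage.label(mask2d)
    polys = []
    for comp in range(1, n + 1):
        pts = np.argwhere(labels == comp).astype(float)  # (n, 2) in (x, y)
        if len(pts) < 3:
            continue
        c = pts.mean(axis=0)
        ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
        # outermost pixel per angular bin approximates the outline
        bins = np.round(ang / (2 * np.pi / 72)).astype(int)
        outline = []
        for b in np.unique(bins):
            sel = pts[bins == b]
            r = ((sel - c) ** 2).sum(axis=1)
            outline.append(sel[np.argmax(r)])
        if len(outline) >= 3:
            polys.append(np.asarray(outline))
    return polys


def export_dicom(case: PlanCase, directory: str | Path) -> None:
    """Write a CT series, an RTSTRUCT and (if present) an RTDOSE."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    study_uid = generate_uid()
    frame_uid = generate_uid()
    series_uid = generate_uid()
    nx, ny, nz = case.ct.shape
    sx, sy, sz = case.ct.spacing

    ct_uids = []
    for k in range(nz):
        uid = generate_uid()
        ct_uids.append(uid)
        ds = _file_dataset(_CT_SOP, uid, f"ct_{k:03d}.dcm")
        ds.Modality = "CT"
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [sy, sx]  # row spacing (y), column spacing (x)
        ds.SliceThickness = sz
        ds.ImagePositionPatient = [case.ct.origin[0], case.ct.origin[1],
                                   case.ct.origin[2] + k * sz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.InstanceNumber = k + 1
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -2048.0
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        px = np.round(case.ct.data[:, :, k].T - ds.RescaleIntercept)
        ds.PixelData = np.clip(px, 0, 65535).astype(np.uint16).tobytes()
        ds.save_as(d / f"ct_{k:03d}.dcm", enforce_file_format=True)

    # RTSTRUCT
    ds = _file_dataset(_RTSTRUCT_SOP, generate_uid(), "rtstruct.dcm")
    ds.Modality = "RTSTRUCT"
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = generate_uid()
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, (name, mask) in enumerate(case.structures.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for k in range(nz):
            sl = mask.data[:, :, k].astype(bool)
            if not sl.any():
                continue
            z = case.ct.origin[2] + k * sz
            for poly in _mask_slice_contours(sl):
                contour = Dataset()
                contour.ContourGeometricType = "CLOSED_PLANAR"
                world = poly * np.array([sx, sy]) + np.array(case.ct.origin[:2])
                data = np.column_stack([world, np.full(len(world), z)]).ravel()
                contour.NumberOfContourPoints = len(poly)
                contour.ContourData = [f"{v:.3f}" for v in data]
                rc.ContourSequence.append(contour)
        ds.ROIContourSequence.append(rc)
    ds.save_as(d / "rtstruct.dcm", enforce_file_format=True)

    if case.reference_dose is not None:
        dose = case.reference_dose
        ds = _file_dataset(_RTDOSE_SOP, generate_uid(), "rtdose.dcm")
        ds.Modality = "RTDOSE"
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = generate_uid()
        ds.FrameOfReferenceUID = frame_uid
        ds.Rows, ds.Columns = ny, nx
        ds.NumberOfFrames = nz
        ds.PixelSpacing = [sy, sx]
        ds.ImagePositionPatient = list(dose.origin)
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.GridFrameOffsetVector = [k * sz for k in range(nz)]
        ds.DoseUnits = "GY"
        ds.DoseType = "PHYSICAL"
        ds.DoseSummationType = "PLAN"
        scaling = float(dose.data.max()) / (2**31 - 1) or 1.0
        ds.DoseGridScaling = scaling
        ds.BitsAllocated = ds.BitsStored = 32
        ds.HighBit = 31
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        frames = np.round(dose.data.transpose(2, 1, 0) / scaling)
        ds.PixelData = frames.astype(np.uint32).tobytes()
        ds.save_as(d / "rtdose.dcm", enforce_file_format=True)


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def read_ct_series(directory: str | Path) -> VoxelGrid:
    files = sorted(Path(directory).glob("ct_*.dcm"))
    if not files:
        raise FileNotFoundError(f"no CT slices under {directory}")
    slices = sorted((pydicom.dcmread(f) for f in files), key=lambda s: float(s.ImagePositionPatient[2]))
    first = slices[0]
    sy, sx = (float(v) for v in first.PixelSpacing)
    sz = abs(float(slices[1].ImagePositionPatient[2]) - float(first.ImagePositionPatient[2])) if len(slices) > 1 else float(first.SliceThickness)
    data = np.stack(
        [
            s.pixel_array.T.astype(float) * float(s.RescaleSlope) + float(s.RescaleIntercept)
            for s in slices
        ],
        axis=2,
    )
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    return VoxelGrid(data, origin=origin, spacing=(sx, sy, sz))


def read_rtdose(path: str | Path) -> VoxelGrid:
    ds = pydicom.dcmread(str(path))
    sy, sx = (float(v) for v in ds.PixelSpacing)
    offsets = [float(v) for v in ds.GridFrameOffsetVector]
    sz = offsets[1] - offsets[0] if len(offsets) > 1 else 1.0
    data = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    return VoxelGrid(
        data.transpose(2, 1, 0),
        origin=tuple(float(v) for v in ds.ImagePositionPatient),
        spacing=(sx, sy, sz),
    )


def _fill_polygon(poly_xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Scanline fill (even-odd rule) of a closed polygon in voxel coords."""
    out = np.zeros(shape, dtype=bool)
    x, y = poly_xy[:, 0], poly_xy[:, 1]
    for row in range(shape[0]):  # row index = x voxel coordinate
        crossings = []
        for i in range(len(poly_xy)):
            x0, y0 = x[i], y[i]
            x1, y1 = x[(i + 1) % len(poly_xy)], y[(i + 1) % len(poly_xy)]
            if (x0 <= row < x1) or (x1 <= row < x0):
                t = (row - x0) / (x1 - x0)
                crossings.append(y0 + t * (y1 - y0))
        crossings.sort()
        for a, b in zip(crossings[::2], crossings[1::2]):
            out[row, int(np.ceil(a)) : int(np.floor(b)) + 1] = True
    return out


def read_rtstruct(path: str | Path, ref: VoxelGrid) -> dict[str, VoxelGrid]:
    """Rasterize RTSTRUCT contours onto the reference CT grid."""
    ds = pydicom.dcmread(str(path))
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    out: dict[str, VoxelGrid] = {}
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        mask = np.zeros(ref.shape, dtype=bool)
        for contour in getattr(rc, "ContourSequence", []):
            pts = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            vox = ref.world_to_voxel(pts)
            k = int(round(float(vox[0, 2])))
            if 0 <= k < ref.shape[2]:
                mask[:, :, k] |= _fill_polygon(vox[:, :2], ref.shape[:2])
        out[name] = VoxelGrid(mask.astype(np.uint8), ref.origin, ref.spacing)
    return out


def import_dicom(directory: str | Path) -> PlanCase:
    """Rebuild a PlanCase from an exported DICOM directory."""
    d = Path(directory)
    ct = read_ct_series(d)
    structures = read_rtstruct(d / "rtstruct.dcm", ct)
    dose = read_rtdose(d / "rtdose.dcm") if (d / "rtdose.dcm").exists() else None
    return PlanCase(ct=ct, structures=structures, reference_dose=dose)
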