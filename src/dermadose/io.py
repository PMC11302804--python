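"""Readers and writers for the formats the pipeline touches.

Dose maps travel as self-describing CSV (header comment lines carry pixel
spacing and provenance; invalid pixels are NaN) or 32-bit float TIFF with DPI
tags; scans as RGB TIFF; grids and masks as compressed ``.npz`` containers or
DICOM-RT (CT series, RTDOSE, RTSTRUCT); configs as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import tifffile
import yaml

from .core import DoseGrid, FilmDoseMap, RigidTransform2D, StructureMask, VoxelGrid

INCH_CM = 2.54


# ---------------------------------------------------------------------------
# film dose maps: CSV and TIFF
# ---------------------------------------------------------------------------


def write_film_csv(film: FilmDoseMap, path) -> None:
    path = Path(path)
    header = (
        f"# dermadose film dose map\n"
        f"# pixel_spacing_cm: {film.pixel_spacing!r}\n"
        f"# provenance: {film.provenance}\n"
        f"# units: percent_of_prescription\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, film.masked(), fmt="%.6g", delimiter=",")


def read_film_csv(path) -> FilmDoseMap:
    path = Path(path)
    spacing, provenance = None, ""
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            if "pixel_spacing_cm:" in line:
                spacing = float(line.split(":", 1)[1])
            elif "provenance:" in line:
                provenance = line.split(":", 1)[1].strip()
        else:
            data_lines.append(line)
    if spacing is None:
        raise ValueError(f"{path} lacks a pixel_spacing_cm header")
    dose = np.loadtxt(data_lines, delimiter=",", ndmin=2)
    return FilmDoseMap(dose, spacing, np.isfinite(dose), provenance=provenance)


def write_film_tiff(film: FilmDoseMap, path) -> None:
    """32-bit float TIFF with resolution tags (NaN outside the valid mask)."""
    dpi = INCH_CM / film.pixel_spacing
    tifffile.imwrite(
        Path(path),
        film.masked().astype(np.float32),
        resolution=(dpi, dpi),
        resolutionunit="INCH",
        metadata={"provenance": film.provenance,
                  "units": "percent_of_prescription"},
    )


def read_film_tiff(path) -> FilmDoseMap:
    with tifffile.TiffFile(Path(path)) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        xres = page.tags.get("XResolution")
        if xres is None:
            raise ValueError("TIFF lacks resolution tags")
        num, den = xres.value
        dpi = num / den
    return FilmDoseMap(data, INCH_CM / dpi, np.isfinite(data))


def write_scan_tiff(pixels: np.ndarray, path, dpi: float = 72.0) -> None:
    """16-bit RGB film scan with DPI tags."""
    arr = np.asarray(pixels)
    tifffile.imwrite(Path(path), arr.astype(np.uint16),
                     resolution=(dpi, dpi), resolutionunit="INCH",
                     photometric="rgb")


def read_scan_tiff(path):
    from .film import FilmScanImage

    with tifffile.TiffFile(Path(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        xres = page.tags.get("XResolution")
        num, den = (xres.value if xres is not None else (72, 1))
        dpi = num / den
    bit_depth = 16 if data.dtype.itemsize >= 2 else 8
    return FilmScanImage(data, dpi=dpi, bit_depth=bit_depth)


# ---------------------------------------------------------------------------
# transforms and calibration tables
# ---------------------------------------------------------------------------


def write_transform(transform: RigidTransform2D, path) -> None:
    with open(Path(path), "w") as fh:
        json.dump(
            {"rotation_deg": transform.rotation_deg,
             "translation_cm": list(transform.translation)},
            fh, indent=1,
        )


def read_transform(path) -> RigidTransform2D:
    with open(Path(path)) as fh:
        d = json.load(fh)
    return RigidTransform2D(d["rotation_deg"], tuple(d["translation_cm"]))


def read_calibration_csv(path) -> Tuple[np.ndarray, np.ndarray]:
    """Calibration set: CSV columns (dose_Gy, mean_green_response)."""
    arr = np.loadtxt(Path(path), delimiter=",", skiprows=1, ndmin=2)
    return arr[:, 0], arr[:, 1]


def write_calibration_csv(doses, responses, path) -> None:
    arr = np.column_stack([doses, responses])
    np.savetxt(Path(path), arr, delimiter=",", fmt="%.8g",
               header="dose_Gy,mean_green_response", comments="")


# ---------------------------------------------------------------------------
# grids and masks: npz container
# ---------------------------------------------------------------------------


def write_grid_npz(grid, path) -> None:
    """VoxelGrid / DoseGrid / StructureMask as a compressed array container."""
    path = Path(path)
    if isinstance(grid, VoxelGrid):
        np.savez_compressed(path, kind="voxelgrid", values=grid.values,
                            spacing=grid.spacing, origin=grid.origin)
    elif isinstance(grid, DoseGrid):
        np.savez_compressed(path, kind="dosegrid", values=grid.dose,
                            spacing=grid.spacing, origin=grid.origin,
                            prescription=grid.prescription, label=grid.label)
    elif isinstance(grid, StructureMask):
        np.savez_compressed(path, kind="mask", values=grid.mask,
                            spacing=grid.spacing, origin=grid.origin,
                            label=grid.label)
    else:
        raise TypeError(f"cannot serialise {type(grid)}")


def read_grid_npz(path):
    with np.load(Path(path), allow_pickle=False) as d:
        kind = str(d["kind"])
        spacing = tuple(float(s) for s in d["spacing"])
        origin = tuple(float(s) for s in d["origin"])
        if kind == "voxelgrid":
            return VoxelGrid(d["values"], spacing, origin)
        if kind == "dosegrid":
            return DoseGrid(d["values"], spacing, origin,
                            float(d["prescription"]), str(d["label"]))
        if kind == "mask":
            return StructureMask(d["values"], spacing, origin, str(d["label"]))
    raise ValueError(f"unknown container kind {kind!r}")


# ---------------------------------------------------------------------------
# DICOM-RT
# ---------------------------------------------------------------------------


def _base_dataset(sop_class_uid: str, modality: str):
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.PatientName = "SYNTHETIC^PHANTOM"
    ds.PatientID = "DERMADOSE"
    return ds


def write_ct_series(ct: VoxelGrid, outdir) -> List[Path]:
    """Write a CT grid (HU) as an axial DICOM series, one file per z slice."""
    from pydicom.uid import generate_uid

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    nx, ny, nz = ct.shape
    paths = []
    for iz in range(nz):
        ds = _base_dataset("1.2.840.10008.5.1.4.1.1.2", "CT")
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = iz + 1
        ds.Rows = ny
        ds.Columns = nx
        # DICOM pixel spacing is (row spacing, column spacing) in mm
        ds.PixelSpacing = [ct.spacing[1] * 10.0, ct.spacing[0] * 10.0]
        ds.SliceThickness = ct.spacing[2] * 10.0
        ds.ImagePositionPatient = [
            ct.origin[0] * 10.0,
            ct.origin[1] * 10.0,
            (ct.origin[2] + iz * ct.spacing[2]) * 10.0,
        ]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        # slice array: rows = y, cols = x
        sl = np.round(ct.values[:, :, iz].T).astype(np.int16)
        ds.PixelData = sl.tobytes()
        p = outdir / f"ct_{iz:04d}.dcm"
        ds.save_as(p, enforce_file_format=True)
        paths.append(p)
    return paths


def read_ct_series(indir) -> VoxelGrid:
    import pydicom

    files = sorted(Path(indir).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {indir}")
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    first = slices[0]
    dy, dx = (float(v) / 10.0 for v in first.PixelSpacing)
    dz = float(first.SliceThickness) / 10.0
    origin = tuple(float(v) / 10.0 for v in first.ImagePositionPatient)
    vol = np.stack(
        [
            s.pixel_array.astype(float) * float(s.RescaleSlope)
            + float(s.RescaleIntercept)
            for s in slices
        ],
        axis=-1,
    )  # (rows=y, cols=x, z)
    return VoxelGrid(vol.transpose(1, 0, 2), (dx, dy, dz), origin)


def write_rtdose(dose: DoseGrid, path) -> Path:
    path = Path(path)
    ds = _base_dataset("1.2.840.10008.5.1.4.1.1.481.2", "RTDOSE")
    nx, ny, nz = dose.shape
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [dose.spacing[1] * 10.0, dose.spacing[0] * 10.0]
    ds.GridFrameOffsetVector = [iz * dose.spacing[2] * 10.0 for iz in range(nz)]
    ds.ImagePositionPatient = [o * 10.0 for o in dose.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    scale = float(dose.dose.max()) / (2 ** 32 - 1) if dose.dose.max() > 0 else 1.0
    ds.DoseGridScaling = scale
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    # frames along z, each frame rows=y cols=x
    arr = np.round(dose.dose.transpose(2, 1, 0) / scale).astype(np.uint32)
    ds.PixelData = arr.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def read_rtdose(path, prescription: float = 42.5) -> DoseGrid:
    import pydicom

    ds = pydicom.dcmread(Path(path))
    dy, dx = (float(v) / 10.0 for v in ds.PixelSpacing)
    offs = [float(v) for v in ds.GridFrameOffsetVector]
    dz = (offs[1] - offs[0]) / 10.0 if len(offs) > 1 else 1.0
    origin = tuple(float(v) / 10.0 for v in ds.ImagePositionPatient)
    arr = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    # pydicom frames: (z, rows=y, cols=x)
    return DoseGrid(arr.transpose(2, 1, 0), (dx, dy, dz), origin, prescription)


def write_rtstruct(masks: List[StructureMask], path) -> Path:
    """Write masks as planar contours (marching squares per z slice)."""
    from pydicom.dataset import Dataset
    from pydicom.sequence import Sequence
    from pydicom.uid import generate_uid
    from skimage import measure

    path = Path(path)
    ds = _base_dataset("1.2.840.10008.5.1.4.1.1.481.3", "RTSTRUCT")
    ds.StructureSetLabel = "dermadose"
    roi_seq, contour_seq = Sequence(), Sequence()
    for number, mask in enumerate(masks, start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = mask.label or f"ROI{number}"
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        roi_seq.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = Sequence()
        for iz in range(mask.shape[2]):
            sl = mask.mask[:, :, iz].T.astype(float)  # rows=y, cols=x
            if not sl.any():
                continue
            for contour in measure.find_contours(sl, 0.5):
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                pts = []
                for ry, cx in contour:
                    pts.extend([
                        (mask.origin[0] + cx * mask.spacing[0]) * 10.0,
                        (mask.origin[1] + ry * mask.spacing[1]) * 10.0,
                        (mask.origin[2] + iz * mask.spacing[2]) * 10.0,
                    ])
                c.NumberOfContourPoints = len(pts) // 3
                c.ContourData = [f"{v:.4f}" for v in pts]
                rc.ContourSequence.append(c)
        contour_seq.append(rc)
    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.save_as(path, enforce_file_format=True)
    return path


def read_rtstruct(path, like: VoxelGrid) -> Dict[str, StructureMask]:
    """Rasterise RTSTRUCT contours onto the lattice of ``like``."""
    import pydicom
    from skimage.draw import polygon

    ds = pydicom.dcmread(Path(path))
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    out: Dict[str, StructureMask] = {}
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        mask = np.zeros(like.shape, dtype=bool)
        for c in getattr(rc, "ContourSequence", []):
            data = np.array([float(v) for v in c.ContourData]).reshape(-1, 3) / 10.0
            iz = int(round((data[0, 2] - like.origin[2]) / like.spacing[2]))
            if not 0 <= iz < like.shape[2]:
                continue
            cols = (data[:, 0] - like.origin[0]) / like.spacing[0]
            rows = (data[:, 1] - like.origin[1]) / like.spacing[1]
            rr, cc = polygon(rows, cols, shape=(like.shape[1], like.shape[0]))
            mask[cc, rr, iz] = True
        out[name] = StructureMask(mask, like.spacing, like.origin, name)
    return out


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def load_yaml(path) -> dict:
    with open(Path(path)) as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(obj: dict, path) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
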