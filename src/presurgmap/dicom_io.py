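"""DICOM series discovery, sorting, and conversion to volumes.

A study directory exported from a scanner or PACS is scanned recursively;
every Part-10 DICOM file is assigned to its series (by SeriesInstanceUID)
and a filesystem-safe folder name is derived from the embedded header
fields using one of three naming options.  Series are converted to
:class:`~presurgmap.volumes.Volume3D` / ``Volume4D`` with the DICOM LPS
geometry mapped to a RAS+ affine.

A small synthetic-series writer is included so the import path can be
exercised without scanner data.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .volumes import Volume3D, Volume4D

__all__ = [
    "DicomSeriesEntry",
    "DicomSeriesIndex",
    "DicomFormatError",
    "NAMING_OPTIONS",
    "sort_dicom_directory",
    "dicom_series_to_volume",
    "write_volume_as_dicom_series",
    "LPS_TO_RAS",
]

#: world-coordinate handedness flip between DICOM (LPS) and NIfTI (RAS+)
LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0, 1.0])

NAMING_OPTIONS = ("description", "id_description", "id_description_number")


class DicomFormatError(ValueError):
    """Raised for inconsistent or incomplete DICOM series."""


def _sanitize(text: str) -> str:
    """Replace filesystem-unsafe characters with underscores."""
    out = re.sub(r"[^A-Za-z0-9._-]+", "_", str(text)).strip("_")
    return out or "unnamed"


@dataclass
class DicomSeriesEntry:
    series_uid: str
    series_description: str
    series_number: int
    patient_id: str
    file_paths: list[Path]

    def folder_name(self, naming_option: str) -> str:
        desc = _sanitize(self.series_description)
        pid = _sanitize(self.patient_id)
        if naming_option == "description":
            return desc
        if naming_option == "id_description":
            return f"{pid}_{desc}"
        if naming_option == "id_description_number":
            return f"{pid}_{desc}_{self.series_number}"
        raise ValueError(f"naming_option must be one of {NAMING_OPTIONS}")


@dataclass
class DicomSeriesIndex:
    entries: list[DicomSeriesEntry]
    naming_option: str = "description"
    n_files_scanned: int = 0
    n_files_ignored: int = 0

    def folder_names(self) -> list[str]:
        return [e.folder_name(self.naming_option) for e in self.entries]


def _is_dicom(path: Path) -> bool:
    """Part-10 magic-number check: 'DICM' at byte offset 128."""
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def sort_dicom_directory(root, naming_option: str = "description"
                         ) -> DicomSeriesIndex:
    """Recursively index every DICOM file under ``root`` by series.

    Non-DICOM files are skipped; files within a series are ordered by
    InstanceNumber.  An empty result is returned with a warning (not an
    error) when no DICOM file is found.
    """
    root = Path(root)
    if naming_option not in NAMING_OPTIONS:
        raise ValueError(f"naming_option must be one of {NAMING_OPTIONS}")
    if not root.is_dir():
        raise IOError(f"not a readable directory: {root}")
    groups: dict[str, list[tuple[int, Path, Dataset]]] = {}
    meta: dict[str, Dataset] = {}
    scanned = ignored = 0
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        scanned += 1
        if not _is_dicom(path):
            ignored += 1
            continue
        try:
            ds = pydicom.dcmread(path, stop_before_pixels=True)
        except Exception:
            ignored += 1
            continue
        uid = str(getattr(ds, "SeriesInstanceUID", ""))
        if not uid:
            ignored += 1
            continue
        inst = int(getattr(ds, "InstanceNumber", 0) or 0)
        groups.setdefault(uid, []).append((inst, path, ds))
        meta.setdefault(uid, ds)
    entries = []
    for uid in sorted(groups):
        files = sorted(groups[uid], key=lambda x: (x[0], str(x[1])))
        ds = meta[uid]
        entries.append(DicomSeriesEntry(
            series_uid=uid,
            series_description=str(getattr(ds, "SeriesDescription", "")
                                   or "unnamed"),
            series_number=int(getattr(ds, "SeriesNumber", 0) or 0),
            patient_id=str(getattr(ds, "PatientID", "") or "unknown"),
            file_paths=[f[1] for f in files]))
    if not entries:
        warnings.warn(f"no DICOM files found under {root}")
    return DicomSeriesIndex(entries, naming_option, scanned, ignored)


def _slice_geometry(ds: Dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                          np.ndarray]:
    if "ImagePositionPatient" not in ds or "ImageOrientationPatient" not in ds:
        raise DicomFormatError("missing position/orientation tags")
    ipp = np.asarray([float(v) for v in ds.ImagePositionPatient])
    iop = np.asarray([float(v) for v in ds.ImageOrientationPatient])
    row_cos, col_cos = iop[:3], iop[3:]
    return ipp, row_cos, col_cos, np.cross(row_cos, col_cos)


def dicom_series_to_volume(entry: DicomSeriesEntry):
    """Convert one series to a Volume3D (or Volume4D for multi-timepoint).

    Slices are ordered by their position along the slice normal; DICOM LPS
    world coordinates are converted to a RAS+ affine.  Files that disagree
    on matrix size or orientation, or lack position tags, raise
    :class:`DicomFormatError`.
    """
    datasets = [pydicom.dcmread(p) for p in entry.file_paths]
    if not datasets:
        raise DicomFormatError("series has no files")
    ref = datasets[0]
    shape2d = (int(ref.Rows), int(ref.Columns))
    ipp0, row_cos, col_cos, normal = _slice_geometry(ref)
    for ds in datasets[1:]:
        if (int(ds.Rows), int(ds.Columns)) != shape2d:
            raise DicomFormatError("inconsistent matrix size across files")
        _, rc, cc, _ = _slice_geometry(ds)
        if not (np.allclose(rc, row_cos, atol=1e-4)
                and np.allclose(cc, col_cos, atol=1e-4)):
            raise DicomFormatError("inconsistent orientation across files")

    # group slices by spatial position; repeats at a position are timepoints
    keyed = []
    for ds in datasets:
        ipp, *_ = _slice_geometry(ds)
        loc = float(np.dot(ipp, normal))
        tpos = int(getattr(ds, "TemporalPositionIdentifier", 0)
                   or getattr(ds, "AcquisitionNumber", 0) or 0)
        keyed.append((round(loc, 4), tpos, int(getattr(ds, "InstanceNumber",
                                                       0) or 0), ds))
    locs = sorted({k[0] for k in keyed})
    n_z = len(locs)
    per_loc = {loc: sorted([k for k in keyed if k[0] == loc],
                           key=lambda k: (k[1], k[2])) for loc in locs}
    n_t = len(per_loc[locs[0]])
    if any(len(v) != n_t for v in per_loc.values()):
        raise DicomFormatError("unequal timepoint counts across slices")

    rescale = (float(getattr(ref, "RescaleSlope", 1.0) or 1.0),
               float(getattr(ref, "RescaleIntercept", 0.0) or 0.0))
    data = np.empty((shape2d[0], shape2d[1], n_z, n_t))
    for zi, loc in enumerate(locs):
        for ti, (_, _, _, ds) in enumerate(per_loc[loc]):
            data[:, :, zi, ti] = (ds.pixel_array.astype(float) * rescale[0]
                                  + rescale[1])

    spacing = [float(v) for v in ref.PixelSpacing]  # [row, col]
    first_ipp = None
    for ds in datasets:
        ipp, *_ = _slice_geometry(ds)
        if round(float(np.dot(ipp, normal)), 4) == locs[0]:
            first_ipp = ipp
            break
    if n_z > 1:
        step = locs[1] - locs[0]
        slice_vec = normal * step
    else:
        thickness = float(getattr(ref, "SliceThickness", 1.0) or 1.0)
        slice_vec = normal * thickness
    affine_lps = np.eye(4)
    affine_lps[:3, 0] = col_cos * spacing[0]   # array axis 0 = image rows
    affine_lps[:3, 1] = row_cos * spacing[1]   # array axis 1 = image cols
    affine_lps[:3, 2] = slice_vec
    affine_lps[:3, 3] = first_ipp
    affine = LPS_TO_RAS @ affine_lps

    # canonicalize to closest-to-RAS+ axis order/direction
    import nibabel as nib
    ornt = nib.orientations.io_orientation(affine)
    spatial_shape = data.shape[:3]
    data = nib.orientations.apply_orientation(data, ornt)
    affine = affine @ nib.orientations.inv_ornt_aff(ornt, spatial_shape)

    if n_t == 1:
        return Volume3D(data[..., 0], affine)
    tr = float(getattr(ref, "RepetitionTime", 0.0) or 0.0) / 1000.0
    return Volume4D(data, affine, tr if tr > 0 else 1.0)


# ---------------------------------------------------------------------------
# Synthetic series writer (fixture generation and the export back-end)

def _base_dataset(patient_id: str, patient_name: str, study_uid: str,
                  series_uid: str, series_number: int,
                  series_description: str, modality: str = "MR") -> Dataset:
    file_meta = FileMetaDataset()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    file_meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = pydicom.uid.MRImageStorage
    ds.Modality = modality
    ds.PatientID = patient_id
    ds.PatientName = patient_name
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.SeriesNumber = series_number
    ds.SeriesDescription = series_description
    ds.StudyID = "1"
    return ds


def write_volume_as_dicom_series(vol, out_dir, series_description: str,
                                 patient_id: str = "PHANTOM001",
                                 patient_name: str = "Phantom^Synthetic",
                                 study_uid: str | None = None,
                                 series_number: int = 1,
                                 n_timepoints: int = 1) -> list[Path]:
    """Write a Volume3D as an axial MR DICOM series (synthetic data only).

    ``n_timepoints > 1`` duplicates the volume at successive temporal
    positions, producing a multi-timepoint series.  Returns the file paths
    written.  Geometry is taken from the RAS+ affine and stored as LPS.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = np.asarray(vol.data, float)
    if data.ndim != 3:
        raise ValueError("expected a 3D volume")
    lo, hi = data.min(), data.max()
    scale = (hi - lo) / 4000.0 if hi > lo else 1.0
    pix = np.round((data - lo) / scale).astype(np.uint16)

    affine_lps = np.linalg.inv(LPS_TO_RAS) @ vol.affine
    col_cos = affine_lps[:3, 0] / np.linalg.norm(affine_lps[:3, 0])
    row_cos = affine_lps[:3, 1] / np.linalg.norm(affine_lps[:3, 1])
    row_spacing = float(np.linalg.norm(affine_lps[:3, 0]))
    col_spacing = float(np.linalg.norm(affine_lps[:3, 1]))
    study_uid = study_uid or generate_uid()
    series_uid = generate_uid()
    paths = []
    inst = 1
    for t in range(n_timepoints):
        for z in range(data.shape[2]):
            ds = _base_dataset(patient_id, patient_name, study_uid,
                               series_uid, series_number,
                               series_description)
            ds.SOPInstanceUID = generate_uid()
            ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
            ds.InstanceNumber = inst
            ds.TemporalPositionIdentifier = t + 1
            ds.Rows, ds.Columns = data.shape[0], data.shape[1]
            ds.PixelSpacing = [f"{row_spacing:.6f}", f"{col_spacing:.6f}"]
            ds.SliceThickness = f"{np.linalg.norm(affine_lps[:3, 2]):.6f}"
            ipp = affine_lps[:3, 3] + z * affine_lps[:3, 2]
            ds.ImagePositionPatient = [f"{v:.6f}" for v in ipp]
            ds.ImageOrientationPatient = (
                [f"{v:.6f}" for v in row_cos] + [f"{v:.6f}" for v in col_cos])
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.RescaleSlope = f"{scale:.8g}"
            ds.RescaleIntercept = f"{lo:.8g}"
            ds.PixelData = np.ascontiguousarray(pix[:, :, z]).tobytes()
            path = out_dir / f"IM_{series_number:04d}_{inst:05d}.dcm"
            ds.save_as(path, enforce_file_format=True)
            paths.append(path)
            inst += 1
    return paths
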