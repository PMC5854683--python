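"""Export fused statistical overlays as PACS-ready DICOM series.

A thresholded statistic map is fused onto one or more anatomical underlays
and written back out as DICOM so results can live in the patient's PACS
study and be picked up by surgical-navigation systems:

* one **gray-scale** series in the acquisition (axial) orientation, with
  suprathreshold overlay voxels burned in at the display maximum ("white"),
  the format navigation systems import, and
* three **color-coded** series, one per orthogonal plane (axial, coronal,
  sagittal), with the overlay alpha-blended in a chosen color scale.

Patient and study identity are copied from a user-selected template DICOM;
series identifiers and numbers are newly generated so exported series never
collide with acquired ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import (ExplicitVRLittleEndian, SecondaryCaptureImageStorage,
                         generate_uid)

from .dicom_io import LPS_TO_RAS
from .volumes import GeometryError, StatMap, Volume3D

__all__ = ["OverlayExportSpec", "ExportReport", "export_overlay_to_dicom"]

PLANES = ("axial", "coronal", "sagittal")
_PLANE_AXIS = {"axial": 2, "coronal": 1, "sagittal": 0}

#: study/patient identity fields copied from the template header
TEMPLATE_FIELDS = (
    "PatientID", "PatientName", "PatientBirthDate", "PatientSex",
    "StudyInstanceUID", "StudyID", "StudyDate", "StudyTime",
    "AccessionNumber", "ReferringPhysicianName", "StudyDescription",
)


class HeaderError(ValueError):
    """Raised when the template DICOM header is missing or unusable."""


def _colormap(name: str, v: np.ndarray) -> np.ndarray:
    """Map normalized magnitudes in [0,1] to RGB in [0,1]."""
    v = np.clip(v, 0.0, 1.0)
    rgb = np.zeros(v.shape + (3,))
    if name == "hot":
        rgb[..., 0] = np.clip(3 * v, 0, 1)
        rgb[..., 1] = np.clip(3 * v - 1, 0, 1)
        rgb[..., 2] = np.clip(3 * v - 2, 0, 1)
    elif name == "winter":
        rgb[..., 1] = v
        rgb[..., 2] = 1.0 - 0.5 * v
    elif name == "gray":
        rgb[...] = v[..., None]
    else:
        raise ValueError(f"unknown colormap {name!r}")
    return rgb


@dataclass
class OverlayExportSpec:
    """What to export: underlays + thresholded overlay + display settings."""

    underlays: list[Volume3D]
    overlay: StatMap
    threshold: float
    window: tuple[float, float] | None = None
    colormap: str = "hot"
    opacity: float = 1.0
    template_header: Dataset | str | Path | None = None
    series_number_base: int = 1000
    series_description: str = "fMRI overlay"

    def __post_init__(self) -> None:
        if not self.underlays:
            raise ValueError("at least one underlay required")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0 (applied to |stat|)")
        if not 0 <= self.opacity <= 1:
            raise ValueError("opacity must be in [0, 1]")
        for u in self.underlays:
            if u.data.shape != self.overlay.data.shape \
                    or not np.allclose(u.affine, self.overlay.affine,
                                       atol=1e-4):
                raise GeometryError(
                    "underlay and overlay must share one grid; resample "
                    "before export")


@dataclass
class ExportReport:
    """What was written: per-series metadata and file counts."""

    series: list[dict] = field(default_factory=list)

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def n_files(self) -> int:
        return sum(s["n_files"] for s in self.series)

    def by_kind(self, kind: str) -> list[dict]:
        return [s for s in self.series if s["kind"] == kind]


def _load_template(spec: OverlayExportSpec) -> Dataset:
    th = spec.template_header
    if th is None:
        raise HeaderError("template_header is required: patient and study "
                          "identity must come from an acquired image")
    if isinstance(th, (str, Path)):
        th = pydicom.dcmread(th, stop_before_pixels=True)
    if not getattr(th, "PatientID", None) \
            or not getattr(th, "StudyInstanceUID", None):
        raise HeaderError("template header lacks PatientID/StudyInstanceUID")
    return th


def _new_dataset(template: Dataset, series_uid: str, series_number: int,
                 description: str) -> Dataset:
    file_meta = FileMetaDataset()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.Modality = "MR"
    for name in TEMPLATE_FIELDS:
        if name in template:
            setattr(ds, name, template.data_element(name).value)
    ds.SeriesInstanceUID = series_uid
    ds.SeriesNumber = series_number
    ds.SeriesDescription = description
    ds.ConversionType = "WSD"
    return ds


def _plane_geometry(affine_ras: np.ndarray, axis: int,
                    slice_index: int, shape) -> tuple[list, list, list]:
    """LPS ImagePosition/Orientation/PixelSpacing for one exported slice.

    The 2D image keeps the two in-plane array axes in ascending order:
    image rows run along the first in-plane axis, columns along the second.
    """
    affine = np.linalg.inv(LPS_TO_RAS) @ affine_ras
    inplane = [a for a in range(3) if a != axis]
    row_axis, col_axis = inplane  # array axes mapped to image rows/cols
    origin_idx = np.zeros(4)
    origin_idx[axis] = slice_index
    origin_idx[3] = 1.0
    ipp = (affine @ origin_idx)[:3]
    row_dir = affine[:3, col_axis]   # direction across image columns
    col_dir = affine[:3, row_axis]   # direction down image rows
    row_spacing = float(np.linalg.norm(col_dir))
    col_spacing = float(np.linalg.norm(row_dir))
    iop = list(row_dir / np.linalg.norm(row_dir)) \
        + list(col_dir / np.linalg.norm(col_dir))
    return ([f"{v:.6f}" for v in ipp],
            [f"{v:.6f}" for v in iop],
            [f"{row_spacing:.6f}", f"{col_spacing:.6f}"])


def _slice2d(volume: np.ndarray, axis: int, k: int) -> np.ndarray:
    sl = [slice(None)] * 3
    sl[axis] = k
    return volume[tuple(sl)]


def _window_normalize(data: np.ndarray,
                      window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        lo, hi = float(data.min()), float(data.max())
    else:
        lo, hi = window
    if hi <= lo:
        hi = lo + 1.0
    return np.clip((data - lo) / (hi - lo), 0.0, 1.0)


def export_overlay_to_dicom(spec: OverlayExportSpec, out_dir) -> ExportReport:
    """Write the gray-scale fused series and three color-coded series.

    Gray series: every underlay windowed to 12-bit MONOCHROME2 with
    suprathreshold overlay voxels set to the display maximum; all underlays
    share one series (interleaved volume by volume).  Color series: one per
    orthogonal plane, 8-bit RGB, overlay alpha-blended with the chosen
    color scale.  Returns an :class:`ExportReport`.
    """
    template = _load_template(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    overlay_hot = np.abs(spec.overlay.data) > spec.threshold
    ov_abs = np.abs(spec.overlay.data)
    ov_max = float(ov_abs.max())
    ov_norm = np.zeros_like(ov_abs)
    if ov_max > spec.threshold:
        ov_norm = (ov_abs - spec.threshold) / (ov_max - spec.threshold)
    affine = spec.underlays[0].affine
    shape = spec.underlays[0].data.shape
    report = ExportReport()

    # ---- gray-scale fused series (axial, navigation-system import) ----
    series_uid = generate_uid()
    series_number = spec.series_number_base
    gray_dir = out_dir / "gray_fused"
    gray_dir.mkdir(exist_ok=True)
    inst = 1
    n_files = 0
    for ui, under in enumerate(spec.underlays):
        gray = _window_normalize(under.data, spec.window)
        fused = gray.copy()
        fused[overlay_hot] = 1.0  # burn in as white
        pix = np.round(fused * 4095).astype(np.uint16)
        for k in range(shape[2]):
            ds = _new_dataset(template, series_uid, series_number,
                              f"{spec.series_description} gray fused")
            ds.SOPInstanceUID = generate_uid()
            ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
            ds.InstanceNumber = inst
            img = _slice2d(pix, 2, k)
            ds.Rows, ds.Columns = img.shape
            ipp, iop, ps = _plane_geometry(affine, 2, k, shape)
            ds.ImagePositionPatient = ipp
            ds.ImageOrientationPatient = iop
            ds.PixelSpacing = ps
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 12
            ds.HighBit = 11
            ds.PixelRepresentation = 0
            ds.PixelData = np.ascontiguousarray(img).tobytes()
            ds.save_as(gray_dir / f"IM_{inst:05d}.dcm",
                       enforce_file_format=True)
            inst += 1
            n_files += 1
    report.series.append({"kind": "gray", "series_uid": series_uid,
                          "series_number": series_number,
                          "n_files": n_files, "path": str(gray_dir)})

    # ---- three color series, one per orthogonal plane ------------------
    under = spec.underlays[0]
    gray = _window_normalize(under.data, spec.window)
    base_rgb = np.repeat(gray[..., None], 3, axis=3)
    color = _colormap(spec.colormap, ov_norm)
    fused_rgb = base_rgb.copy()
    fused_rgb[overlay_hot] = ((1 - spec.opacity) * base_rgb[overlay_hot]
                              + spec.opacity * color[overlay_hot])
    rgb8 = np.round(np.clip(fused_rgb, 0, 1) * 255).astype(np.uint8)
    for pi, plane in enumerate(PLANES):
        axis = _PLANE_AXIS[plane]
        series_uid = generate_uid()
        series_number = spec.series_number_base + 1 + pi
        plane_dir = out_dir / f"color_{plane}"
        plane_dir.mkdir(exist_ok=True)
        n_files = 0
        for k in range(shape[axis]):
            ds = _new_dataset(template, series_uid, series_number,
                              f"{spec.series_description} color {plane}")
            ds.SOPInstanceUID = generate_uid()
            ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
            ds.InstanceNumber = k + 1
            img = _slice2d(rgb8, axis, k)
            ds.Rows, ds.Columns = img.shape[0], img.shape[1]
            ipp, iop, ps = _plane_geometry(affine, axis, k, shape)
            ds.ImagePositionPatient = ipp
            ds.ImageOrientationPatient = iop
            ds.PixelSpacing = ps
            ds.SamplesPerPixel = 3
            ds.PhotometricInterpretation = "RGB"
            ds.PlanarConfiguration = 0
            ds.BitsAllocated = 8
            ds.BitsStored = 8
            ds.HighBit = 7
            ds.PixelRepresentation = 0
            ds.PixelData = np.ascontiguousarray(img).tobytes()
            ds.save_as(plane_dir / f"IM_{k + 1:05d}.dcm",
                       enforce_file_format=True)
            n_files += 1
        report.series.append({"kind": "color", "plane": plane,
                              "series_uid": series_uid,
                              "series_number": series_number,
                              "n_files": n_files, "path": str(plane_dir)})
    return report
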