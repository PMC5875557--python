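"""Grid geometry, DICOM CT / RTDOSE / RTSTRUCT I/O, and contour rasterization.

Conventions used throughout the package
---------------------------------------
* All patient coordinates are DICOM LPS millimetres.
* Voxel indices are 0-based and refer to voxel *centers*.
* Scalar volumes are stored as ``array[i, j, k]`` with shape ``(nx, ny, nz)``
  where ``i`` runs along the image row direction (columns of a DICOM slice),
  ``j`` along the column direction (rows of a slice) and ``k`` along the
  slice normal.  DICOM pixel arrays are transposed accordingly on read/write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import (
    CTImageStorage,
    ExplicitVRLittleEndian,
    RTDoseStorage,
    RTStructureSetStorage,
    generate_uid,
)
import shapely

log = logging.getLogger(__name__)

_IDENTITY = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

MAX_UINT32 = 2**32 - 1


class GeometryError(ValueError):
    """Raised for inconsistent grid geometry or DICOM spatial metadata."""


@dataclass(frozen=True)
class GridGeometry:
    """Regular 3D grid in patient millimetres.

    Parameters
    ----------
    origin : tuple of float
        Patient coordinate (mm, LPS) of the center of voxel ``(0, 0, 0)``.
    spacing : tuple of float
        ``(dx, dy, dz)`` voxel pitch in mm along the three grid axes.
    shape : tuple of int
        ``(nx, ny, nz)`` voxel counts.
    direction : nested tuple
        Rows of the 3x3 matrix whose *columns* are the unit direction
        cosines of the grid axes.  Defaults to the identity (axis-aligned).
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    direction: tuple = _IDENTITY

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise GeometryError("origin, spacing and shape must have length 3")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacings must be positive, got {self.spacing}")
        if any(int(n) < 1 or int(n) != n for n in self.shape):
            raise GeometryError(f"shape entries must be integers >= 1, got {self.shape}")
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3, 3) or not np.allclose(d.T @ d, np.eye(3), atol=1e-6):
            raise GeometryError("direction cosines must form an orthonormal 3x3 matrix")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        object.__setattr__(self, "direction", tuple(tuple(float(v) for v in row) for row in d))

    # -- coordinate transforms -------------------------------------------------
    @property
    def direction_matrix(self) -> np.ndarray:
        """3x3 matrix whose columns are the grid axis unit vectors."""
        return np.asarray(self.direction, dtype=float)

    def index_to_mm(self, index) -> np.ndarray:
        """Map (continuous) voxel indices ``(..., 3)`` to patient mm."""
        idx = np.asarray(index, dtype=float)
        local = idx * np.asarray(self.spacing)
        return np.asarray(self.origin) + local @ self.direction_matrix.T

    def mm_to_index(self, points) -> np.ndarray:
        """Map patient mm coordinates ``(..., 3)`` to continuous voxel indices."""
        p = np.asarray(points, dtype=float) - np.asarray(self.origin)
        local = p @ self.direction_matrix  # == D.T applied to each point
        return local / np.asarray(self.spacing)

    def contains_index(self, index, tol: float = 1e-7) -> np.ndarray:
        """Boolean: continuous index lies within the voxel-center extent."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        hi = np.asarray(self.shape) - 1
        ok = np.all((idx >= -tol) & (idx <= hi + tol), axis=-1)
        return ok

    # -- derived quantities ----------------------------------------------------
    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def slice_positions(self) -> np.ndarray:
        """Positions of slice planes along the slice normal, relative to origin."""
        return np.arange(self.shape[2]) * self.spacing[2]

    def voxel_centers_mm(self) -> np.ndarray:
        """All voxel centers in raster (C) order, shape ``(nx*ny*nz, 3)``."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.index_to_mm(idx)

    def approx_equal(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class ImageVolume:
    """Scalar CT volume (Hounsfield units) on a :class:`GridGeometry`."""

    geometry: GridGeometry
    intensities: np.ndarray
    phase_label: float | str | None = None
    frame_of_reference: str | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != tuple(self.geometry.shape):
            raise GeometryError(
                f"intensity array shape {self.intensities.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise GeometryError("intensities must be finite")


@dataclass
class DoseGrid:
    """Dose values in Gy on a :class:`GridGeometry`."""

    geometry: GridGeometry
    dose: np.ndarray
    phase_label: float | str | None = None
    frame_of_reference: str | None = None

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != tuple(self.geometry.shape):
            raise GeometryError(
                f"dose array shape {self.dose.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.dose)):
            raise GeometryError("dose must be finite")
        if np.any(self.dose < 0):
            raise GeometryError("dose must be non-negative")


@dataclass
class BinaryMask:
    """Boolean voxel mask on a :class:`GridGeometry`."""

    geometry: GridGeometry
    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != tuple(self.geometry.shape):
            raise GeometryError("mask shape does not match geometry shape")

    @property
    def volume_cc(self) -> float:
        return float(self.inside.sum()) * self.geometry.voxel_volume_mm3 / 1000.0


@dataclass
class StructureROI:
    """One region of interest: closed planar polygons in patient mm."""

    name: str
    contours: list = field(default_factory=list)  # list of (N, 3) float arrays

    def __post_init__(self) -> None:
        cleaned = []
        for c in self.contours:
            arr = np.asarray(c, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise GeometryError(f"contour of ROI {self.name!r} must be (N, 3)")
            if arr.shape[0] < 3:
                raise GeometryError(f"contour of ROI {self.name!r} has < 3 vertices")
            cleaned.append(arr)
        self.contours = cleaned


@dataclass
class StructureSet:
    """Named ROIs delineated on a reference CT."""

    rois: dict = field(default_factory=dict)  # name -> StructureROI
    frame_of_reference: str | None = None

    def __getitem__(self, name: str) -> StructureROI:
        return self.rois[name]

    def __contains__(self, name: str) -> bool:
        return name in self.rois

    @property
    def names(self) -> list[str]:
        return list(self.rois)


# ---------------------------------------------------------------------------
# DICOM CT series
# ---------------------------------------------------------------------------

def _dicom_files(directory) -> list[Dataset]:
    directory = Path(directory)
    out = []
    for f in sorted(directory.iterdir()):
        if not f.is_file():
            continue
        try:
            out.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    return out


def _parse_phase_label(ds: Dataset):
    desc = str(ds.get("SeriesDescription", "") or "")
    if desc.startswith("phase "):
        try:
            return float(desc.split()[1])
        except ValueError:
            return desc
    return desc or None


def read_ct_series(directory) -> ImageVolume:
    """Read a single-frame CT series from a directory into an :class:`ImageVolume`.

    Slices are sorted by their projected position along the slice normal
    (robust to export order); rescale slope/intercept are applied so the
    volume is in Hounsfield units.

    Raises
    ------
    GeometryError
        If the directory mixes series UIDs, contains no CT instances, or the
        slice gaps deviate from uniform by more than 1%.
    """
    slices = [ds for ds in _dicom_files(directory) if getattr(ds, "Modality", None) == "CT"]
    if not slices:
        raise GeometryError(f"no CT instances found in {directory}")
    uids = sorted({ds.SeriesInstanceUID for ds in slices})
    if len(uids) > 1:
        raise GeometryError(f"directory mixes CT series UIDs: {uids[0]} and {uids[1]}")

    iop = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    slices.sort(key=lambda ds: float(np.dot(normal, np.asarray(ds.ImagePositionPatient, float))))

    positions = np.array(
        [np.dot(normal, np.asarray(ds.ImagePositionPatient, float)) for ds in slices]
    )
    if len(slices) > 1:
        gaps = np.diff(positions)
        mean_gap = float(np.mean(gaps))
        if mean_gap <= 0:
            raise GeometryError("duplicate or non-increasing slice positions")
        if np.max(np.abs(gaps - mean_gap)) > 0.01 * abs(mean_gap):
            raise GeometryError(
                f"non-uniform slice gap: gaps range {gaps.min():.4f}..{gaps.max():.4f} mm"
            )
        dz = mean_gap
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0) or 1.0)

    ps = np.asarray(slices[0].PixelSpacing, dtype=float)  # [row pitch (dy), col pitch (dx)]
    dx, dy = float(ps[1]), float(ps[0])
    ny, nx = int(slices[0].Rows), int(slices[0].Columns)

    vol = np.empty((nx, ny, len(slices)), dtype=float)
    for k, ds in enumerate(slices):
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        vol[:, :, k] = (ds.pixel_array.astype(float) * slope + intercept).T

    geom = GridGeometry(
        origin=tuple(np.asarray(slices[0].ImagePositionPatient, float)),
        spacing=(dx, dy, dz),
        shape=(nx, ny, len(slices)),
        direction=tuple(map(tuple, np.column_stack([row_dir, col_dir, normal]))),
    )
    return ImageVolume(
        geometry=geom,
        intensities=vol,
        phase_label=_parse_phase_label(slices[0]),
        frame_of_reference=str(getattr(slices[0], "FrameOfReferenceUID", "") or "") or None,
    )


def _file_meta(sop_class, sop_instance) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def write_ct_series(
    volume: ImageVolume,
    directory,
    series_description: str | None = None,
    frame_of_reference: str | None = None,
    study_uid: str | None = None,
) -> list[Path]:
    """Write an :class:`ImageVolume` as a single-frame CT series (one file per slice)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    geom = volume.geometry
    d = geom.direction_matrix
    series_uid = generate_uid()
    study_uid = study_uid or generate_uid()
    for_uid = frame_of_reference or volume.frame_of_reference or generate_uid()
    stored = np.rint(volume.intensities).astype(np.int16)
    paths = []
    for k in range(geom.shape[2]):
        ds = Dataset()
        sop_uid = generate_uid()
        ds.file_meta = _file_meta(CTImageStorage, sop_uid)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = for_uid
        ds.SeriesDescription = series_description or (
            f"phase {volume.phase_label}" if volume.phase_label is not None else "CT"
        )
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [*d[:, 0], *d[:, 1]]
        ds.ImagePositionPatient = list(geom.index_to_mm([0, 0, k]))
        ds.PixelSpacing = [geom.spacing[1], geom.spacing[0]]
        ds.SliceThickness = geom.spacing[2]
        ds.Rows, ds.Columns = geom.shape[1], geom.shape[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        path = directory / f"ct_{k:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# RTDOSE
# ---------------------------------------------------------------------------

def read_rtdose(file) -> DoseGrid:
    """Read a multiframe DICOM-RT RTDOSE file into a :class:`DoseGrid`.

    The stored integer grid is scaled by ``DoseGridScaling``; geometry comes
    from ``ImagePositionPatient``, ``PixelSpacing`` and the
    ``GridFrameOffsetVector``.
    """
    ds = pydicom.dcmread(str(file))
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise GeometryError(f"{file}: not an RTDOSE instance")
    if str(getattr(ds, "DoseUnits", "")).upper() != "GY":
        raise GeometryError(f"{file}: DoseUnits must be GY, got {getattr(ds, 'DoseUnits', None)!r}")
    if "DoseGridScaling" not in ds:
        raise GeometryError(f"{file}: missing DoseGridScaling")
    scaling = float(ds.DoseGridScaling)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if len(offsets) > 1:
        gaps = np.diff(offsets)
        if np.max(np.abs(gaps - gaps[0])) > 1e-6 * max(1.0, abs(gaps[0])):
            raise GeometryError(f"{file}: non-uniform GridFrameOffsetVector")
        dz = float(gaps[0])
    else:
        dz = float(getattr(ds, "SliceThickness", 1.0) or 1.0)
    iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    ps = np.asarray(ds.PixelSpacing, dtype=float)
    arr = ds.pixel_array.astype(float) * scaling  # (nz, ny, nx)
    if arr.ndim == 2:
        arr = arr[None]
    dose = np.ascontiguousarray(arr.transpose(2, 1, 0))
    geom = GridGeometry(
        origin=tuple(np.asarray(ds.ImagePositionPatient, float)),
        spacing=(float(ps[1]), float(ps[0]), dz),
        shape=dose.shape,
        direction=tuple(map(tuple, np.column_stack([row_dir, col_dir, normal]))),
    )
    return DoseGrid(
        geometry=geom,
        dose=dose,
        phase_label=_parse_phase_label(ds),
        frame_of_reference=str(getattr(ds, "FrameOfReferenceUID", "") or "") or None,
    )


def write_rtdose(dose: DoseGrid, path, frame_of_reference: str | None = None) -> Path:
    """Write a :class:`DoseGrid` as multiframe RTDOSE.

    Values are stored as 32-bit unsigned integers with
    ``DoseGridScaling = max(dose) / (2**32 - 1)`` (1.0 for an all-zero grid),
    so a read-back reproduces the dose within one scaling quantum per voxel.
    """
    arr = np.asarray(dose.dose, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise GeometryError("dose must be finite to export")
    if np.any(arr < 0):
        raise GeometryError("dose must be non-negative to export")
    dmax = float(arr.max())
    scaling = dmax / MAX_UINT32 if dmax > 0 else 1.0
    stored = np.rint(arr / scaling).astype(np.uint32)

    geom = dose.geometry
    d = geom.direction_matrix
    ds = Dataset()
    sop_uid = generate_uid()
    ds.file_meta = _file_meta(RTDoseStorage, sop_uid)
    ds.SOPClassUID = RTDoseStorage
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = frame_of_reference or dose.frame_of_reference or generate_uid()
    if dose.phase_label is not None:
        ds.SeriesDescription = f"phase {dose.phase_label}"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.NumberOfFrames = geom.shape[2]
    ds.GridFrameOffsetVector = [k * geom.spacing[2] for k in range(geom.shape[2])]
    ds.ImageOrientationPatient = [*d[:, 0], *d[:, 1]]
    ds.ImagePositionPatient = list(geom.origin)
    ds.PixelSpacing = [geom.spacing[1], geom.spacing[0]]
    ds.SliceThickness = geom.spacing[2]
    ds.Rows, ds.Columns = geom.shape[1], geom.shape[0]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.ascontiguousarray(stored.transpose(2, 1, 0)).tobytes()
    path = Path(path)
    ds.save_as(str(path), enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# RTSTRUCT
# ---------------------------------------------------------------------------

def read_rtstruct(file, ct: ImageVolume) -> StructureSet:
    """Read an RTSTRUCT contour set referencing the given CT.

    Raises on a frame-of-reference mismatch; contours with fewer than 3
    points are skipped with a logged warning.  Each contour's slice position
    must coincide with a CT slice within half the slice spacing.
    """
    ds = pydicom.dcmread(str(file))
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise GeometryError(f"{file}: not an RTSTRUCT instance")

    ref_for = None
    if "ReferencedFrameOfReferenceSequence" in ds and len(ds.ReferencedFrameOfReferenceSequence):
        ref_for = str(ds.ReferencedFrameOfReferenceSequence[0].FrameOfReferenceUID)
    if ct.frame_of_reference and ref_for and ref_for != ct.frame_of_reference:
        raise GeometryError(
            f"RTSTRUCT frame of reference {ref_for} does not match CT {ct.frame_of_reference}"
        )

    names = {}
    for item in ds.get("StructureSetROISequence", []):
        names[int(item.ROINumber)] = str(item.ROIName)

    geom = ct.geometry
    dz = geom.spacing[2]
    structure_set = StructureSet(frame_of_reference=ref_for)
    for roi_item in ds.get("ROIContourSequence", []):
        number = int(roi_item.ReferencedROINumber)
        name = names.get(number, f"ROI_{number}")
        contours = []
        for c in roi_item.get("ContourSequence", []):
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            if pts.shape[0] < 3:
                log.warning("skipping contour with %d point(s) in ROI %r", pts.shape[0], name)
                continue
            k = geom.mm_to_index(pts)[:, 2]
            if np.max(np.abs(k - np.round(np.mean(k)))) > 0.5 + 1e-6:
                raise GeometryError(
                    f"contour of ROI {name!r} does not lie on a CT slice within dz/2={dz / 2} mm"
                )
            contours.append(pts)
        structure_set.rois[name] = StructureROI(name=name, contours=contours)
    return structure_set


def write_rtstruct(
    structures: StructureSet,
    ct: ImageVolume,
    path,
    frame_of_reference: str | None = None,
) -> Path:
    """Write a :class:`StructureSet` as a minimal RTSTRUCT referencing the CT."""
    for_uid = frame_of_reference or ct.frame_of_reference or generate_uid()
    ds = Dataset()
    sop_uid = generate_uid()
    ds.file_meta = _file_meta(RTStructureSetStorage, sop_uid)
    ds.SOPClassUID = RTStructureSetStorage
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTSTRUCT"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.StructureSetLabel = "dose4d"

    ref = Dataset()
    ref.FrameOfReferenceUID = for_uid
    ds.ReferencedFrameOfReferenceSequence = [ref]

    roi_seq, contour_seq = [], []
    for number, (name, roi) in enumerate(structures.rois.items(), start=1):
        item = Dataset()
        item.ROINumber = number
        item.ROIName = name
        item.ReferencedFrameOfReferenceUID = for_uid
        item.ROIGenerationAlgorithm = "MANUAL"
        roi_seq.append(item)

        citem = Dataset()
        citem.ReferencedROINumber = number
        seq = []
        for pts in roi.contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = pts.shape[0]
            c.ContourData = [float(v) for v in np.asarray(pts, float).ravel()]
            seq.append(c)
        citem.ContourSequence = seq
        contour_seq.append(citem)
    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    path = Path(path)
    ds.save_as(str(path), enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize(roi: StructureROI, geometry: GridGeometry) -> BinaryMask:
    """Rasterize a planar-contour ROI onto a grid by the even-odd rule.

    A voxel is inside iff its center lies inside the polygon of its slice
    (points exactly on the boundary count as inside).  Multiple contours on
    one slice combine by XOR, so nested contours form holes.  An ROI whose
    contours all fall outside the grid yields an all-false mask with a
    logged warning.
    """
    nx, ny, nz = geometry.shape
    mask = np.zeros((nx, ny, nz), dtype=bool)
    # in-plane voxel-center coordinates in the grid's own frame
    u = np.arange(nx) * geometry.spacing[0]
    v = np.arange(ny) * geometry.spacing[1]
    uu, vv = np.meshgrid(u, v, indexing="ij")

    d = geometry.direction_matrix
    origin = np.asarray(geometry.origin)
    any_hit = False
    for pts in roi.contours:
        local = (pts - origin) @ d  # project onto grid axes
        k = int(np.round(np.mean(local[:, 2]) / geometry.spacing[2]))
        if k < 0 or k >= nz:
            continue
        poly = shapely.Polygon(local[:, :2])
        inside = shapely.intersects_xy(poly, uu.ravel(), vv.ravel()).reshape(nx, ny)
        if inside.any():
            any_hit = True
        mask[:, :, k] ^= inside
    if not any_hit:
        log.warning("ROI %r rasterized to an empty mask on the given grid", roi.name)
    return BinaryMask(geometry=geometry, inside=mask)


__all__ = [
    "GridGeometry",
    "ImageVolume",
    "DoseGrid",
    "BinaryMask",
    "StructureROI",
    "StructureSet",
    "GeometryError",
    "read_ct_series",
    "write_ct_series",
    "read_rtdose",
    "write_rtdose",
    "read_rtstruct",
    "write_rtstruct",
    "rasterize",
]
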