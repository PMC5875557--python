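"""Deformable voxel-dose registration: align phase dose grids to the CT
lattice, refine craniocaudal resolution, and trace each reference voxel's
temporal dose through a deformation field into a 1D per-phase array (TDX).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .deformation import DeformationField
from .geometry_io import BinaryMask, DoseGrid, GeometryError, GridGeometry

_IDX_TOL = 1e-7  # continuous-index tolerance for in-grid tests


@dataclass
class PhaseDose:
    """Temporal dose at one respiratory phase over traced reference voxels (TDX).

    ``doses[i]`` is the dose (Gy) received, during this phase, by the tissue
    element that sits at reference-grid voxel ``voxel_index_map[i]`` (a linear
    C-order index into ``reference_shape``).  ``out_of_grid_flags`` marks
    voxels whose displaced position left the phase dose grid.
    """

    phase_label: float | str | None
    doses: np.ndarray
    voxel_index_map: np.ndarray
    reference_shape: tuple[int, int, int]
    out_of_grid_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.voxel_index_map = np.asarray(self.voxel_index_map, dtype=np.int64)
        if self.out_of_grid_flags is None:
            self.out_of_grid_flags = np.zeros(self.doses.shape, dtype=bool)
        self.out_of_grid_flags = np.asarray(self.out_of_grid_flags, dtype=bool)
        if not (len(self.doses) == len(self.voxel_index_map) == len(self.out_of_grid_flags)):
            raise GeometryError("doses, voxel_index_map and flags must share one length")
        if not np.all(np.isfinite(self.doses)) or np.any(self.doses < 0):
            raise GeometryError("traced doses must be finite and non-negative")


def _sample_trilinear(dose: DoseGrid, points_mm, policy: str = "zero",
                      sampling: str = "trilinear") -> tuple[np.ndarray, np.ndarray]:
    """Sample a dose grid at mm points; returns (values, out_of_grid flags)."""
    ci = dose.geometry.mm_to_index(np.atleast_2d(points_mm))
    inside = dose.geometry.contains_index(ci, tol=_IDX_TOL)
    hi = np.asarray(dose.geometry.shape) - 1
    coords = np.clip(ci, 0, hi).T
    order = 1 if sampling == "trilinear" else 0
    vals = map_coordinates(dose.dose, coords, order=order, mode="nearest")
    out = ~inside
    if policy == "zero":
        vals = np.where(out, 0.0, vals)
    elif policy == "error":
        if out.any():
            raise GeometryError(f"{int(out.sum())} displaced voxel(s) left the dose grid")
    elif policy != "nearest":
        raise ValueError(f"unknown out-of-grid policy {policy!r}")
    return vals, out


def align_dose_to_ct(dose: DoseGrid, ct: GridGeometry) -> DoseGrid:
    """Resample a dose grid onto the CT voxel lattice by trilinear interpolation.

    If the two lattices already coincide the values pass through unchanged.
    CT voxels outside the dose grid's extent receive 0 Gy; fully disjoint
    extents raise.
    """
    if dose.geometry.approx_equal(ct):
        return DoseGrid(geometry=ct, dose=dose.dose.copy(), phase_label=dose.phase_label,
                        frame_of_reference=dose.frame_of_reference)
    centers = ct.voxel_centers_mm()
    ci = dose.geometry.mm_to_index(centers)
    inside = dose.geometry.contains_index(ci, tol=_IDX_TOL)
    if not inside.any():
        raise GeometryError("dose grid and CT grid extents are disjoint")
    vals, _ = _sample_trilinear(dose, centers, policy="zero")
    return DoseGrid(geometry=ct, dose=vals.reshape(ct.shape), phase_label=dose.phase_label,
                    frame_of_reference=dose.frame_of_reference)


def refine_cc(dose: DoseGrid, target_dz: float = 1.0) -> DoseGrid:
    """Refine the craniocaudal (slice-axis) resolution by linear interpolation.

    New slice planes are laid at ``target_dz`` pitch across the original
    extent; values are interpolated along the slice axis only, so original
    planes keep their exact values whenever the old pitch is a multiple of
    the new one.
    """
    if target_dz <= 0:
        raise ValueError(f"target_dz must be positive, got {target_dz}")
    dz = dose.geometry.spacing[2]
    if target_dz > dz + 1e-9:
        raise ValueError(f"target_dz={target_dz} mm exceeds current slice pitch {dz} mm")
    nz = dose.geometry.shape[2]
    extent = (nz - 1) * dz
    n_new = int(np.floor(extent / target_dz + 1e-9)) + 1
    frac = np.arange(n_new) * target_dz / dz
    lo = np.floor(frac).astype(int)
    hi = np.minimum(lo + 1, nz - 1)
    w = frac - lo
    new = dose.dose[:, :, lo] * (1.0 - w) + dose.dose[:, :, hi] * w
    geom = GridGeometry(
        origin=dose.geometry.origin,
        spacing=(dose.geometry.spacing[0], dose.geometry.spacing[1], float(target_dz)),
        shape=(dose.geometry.shape[0], dose.geometry.shape[1], n_new),
        direction=dose.geometry.direction,
    )
    return DoseGrid(geometry=geom, dose=new, phase_label=dose.phase_label,
                    frame_of_reference=dose.frame_of_reference)


def _selected_indices(reference: GridGeometry, roi_mask) -> np.ndarray:
    if isinstance(roi_mask, str):
        if roi_mask != "all":
            raise ValueError(f"unknown voxel selection {roi_mask!r}")
        return np.arange(int(np.prod(reference.shape)), dtype=np.int64)
    if isinstance(roi_mask, BinaryMask):
        if not roi_mask.geometry.approx_equal(reference):
            raise GeometryError("ROI mask geometry does not match the reference grid")
        return np.flatnonzero(roi_mask.inside.ravel()).astype(np.int64)
    raise TypeError("roi_mask must be a BinaryMask or the string 'all'")


def _field_row_order(field: DeformationField, reference: GridGeometry,
                     selected: np.ndarray) -> np.ndarray | None:
    """If the field's correspondence rows coincide with the selected reference
    voxel centers, return the linear indices in M-matrix row order."""
    if field.kind != "correspondence":
        return None
    ci = reference.mm_to_index(field.sources)
    rounded = np.round(ci)
    if np.max(np.abs(ci - rounded)) > 1e-6:
        return None
    rounded = rounded.astype(np.int64)
    if np.any(rounded < 0) or np.any(rounded >= np.asarray(reference.shape)):
        return None
    lin = np.ravel_multi_index(rounded.T, reference.shape)
    if len(np.unique(lin)) != len(lin):
        return None
    if not np.array_equal(np.sort(lin), selected):
        return None
    return lin


def trace_phase_dose(
    reference: GridGeometry,
    roi_mask,
    field: DeformationField,
    phase_dose: DoseGrid,
    policy: str = "zero",
    sampling: str = "trilinear",
) -> PhaseDose:
    """Trace the temporal dose of reference voxels through a deformation field.

    Each selected reference voxel center ``p`` is displaced to
    ``q = field(p)`` and the phase dose is interpolated at ``q`` (trilinear
    by default; ``sampling="nearest"`` rounds to the nearest dose voxel as a
    compatibility mode).  Voxels whose ``q`` leaves the dose grid follow the
    out-of-grid ``policy`` — ``"zero"`` (default, flagged), ``"nearest"``
    (clamped, flagged) or ``"error"``.

    The entry order is the deformation field's source-row order when the
    field's correspondences coincide with the selected voxel centers
    (M-matrix convention), else raster (C) order of the reference grid.
    """
    selected = _selected_indices(reference, roi_mask)
    order = _field_row_order(field, reference, selected)
    voxel_map = order if order is not None else selected
    ijk = np.stack(np.unravel_index(voxel_map, reference.shape), axis=1)
    centers = reference.index_to_mm(ijk)
    displaced, _ = field.displace(centers)
    vals, out = _sample_trilinear(phase_dose, displaced, policy=policy, sampling=sampling)
    return PhaseDose(
        phase_label=field.phase_label if field.phase_label is not None else phase_dose.phase_label,
        doses=vals,
        voxel_index_map=voxel_map,
        reference_shape=tuple(reference.shape),
        out_of_grid_flags=out,
    )


# ---------------------------------------------------------------------------
# TDX table persistence
# ---------------------------------------------------------------------------

def write_tdx(phase_dose: PhaseDose, path) -> Path:
    """Persist a traced 1D dose array as a two-column (index, Gy) text table."""
    path = Path(path)
    nx, ny, nz = phase_dose.reference_shape
    lines = [
        f"# dose4d TDX phase={phase_dose.phase_label}",
        f"# reference_shape={nx},{ny},{nz}",
    ]
    flagged = np.flatnonzero(phase_dose.out_of_grid_flags)
    if len(flagged):
        lines.append("# out_of_grid_indices=" + ",".join(str(int(i)) for i in flagged))
    for idx, d in zip(phase_dose.voxel_index_map, phase_dose.doses):
        lines.append(f"{int(idx)}\t{d:.17g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_tdx(path) -> PhaseDose:
    """Read a TDX table written by :func:`write_tdx`."""
    phase_label = None
    shape = None
    flagged_rows: set[int] = set()
    idx, dose = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "phase=" in body:
                    raw = body.split("phase=", 1)[1].strip()
                    try:
                        phase_label = float(raw)
                    except ValueError:
                        phase_label = raw or None
                elif body.startswith("reference_shape="):
                    shape = tuple(int(v) for v in body.split("=", 1)[1].split(","))
                elif body.startswith("out_of_grid_indices="):
                    flagged_rows = {int(v) for v in body.split("=", 1)[1].split(",") if v}
                continue
            fields = line.split()
            idx.append(int(fields[0]))
            dose.append(float(fields[1]))
    if shape is None:
        raise ValueError(f"{path}: missing reference_shape header")
    idx = np.asarray(idx, dtype=np.int64)
    flags = np.zeros(len(idx), dtype=bool)
    if flagged_rows:
        flags = np.isin(np.arange(len(idx)), sorted(flagged_rows))
    return PhaseDose(
        phase_label=phase_label,
        doses=np.asarray(dose, dtype=float),
        voxel_index_map=idx,
        reference_shape=shape,
        out_of_grid_flags=flags,
    )


__all__ = [
    "PhaseDose",
    "align_dose_to_ct",
    "refine_cc",
    "trace_phase_dose",
    "write_tdx",
    "read_tdx",
]
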