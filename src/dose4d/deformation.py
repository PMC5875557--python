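"""Per-phase deformation fields: the M-matrix point-correspondence format,
dense displacement volumes, rigid phantom fields and respiratory trajectories.

A deformation field maps *reference* CT coordinates (the source frame) to the
coordinates of the same tissue element in one respiratory phase (the target
frame).  Dose is later *pulled* from the phase dose grid at the displaced
position; no Jacobian / energy-mass correction is applied (pointwise dose
tracing), which is a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .geometry_io import GeometryError, GridGeometry

_HULL_TOL = 1e-9  # mm tolerance when flagging out-of-hull queries


class MMatrixError(ValueError):
    """Raised for malformed M-matrix correspondence files."""


@dataclass
class DeformationField:
    """Reference-to-phase mapping, as n x 6 correspondences or dense displacements.

    Exactly one representation is populated:

    * ``sources`` / ``targets`` — n x 3 mm coordinate pairs (the M-matrix rows,
      row order preserved);
    * ``geometry`` / ``displacements`` — displacement vectors (mm) of shape
      ``(nx, ny, nz, 3)`` on a :class:`GridGeometry`.
    """

    phase_label: float | str | None = None
    sources: np.ndarray | None = None
    targets: np.ndarray | None = None
    geometry: GridGeometry | None = None
    displacements: np.ndarray | None = None
    source_frame: str = "reference CT"
    _grid_axes: tuple | None = field(default=None, repr=False, compare=False)
    _grid_disp: np.ndarray | None = field(default=None, repr=False, compare=False)
    _tree: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.sources is not None:
            self.sources = np.atleast_2d(np.asarray(self.sources, dtype=float))
            self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
            if self.sources.shape != self.targets.shape or self.sources.shape[1] != 3:
                raise GeometryError("correspondence sources/targets must both be (n, 3)")
            if not (np.all(np.isfinite(self.sources)) and np.all(np.isfinite(self.targets))):
                raise GeometryError("correspondence coordinates must be finite")
            self._build_grid()
        elif self.displacements is not None:
            if self.geometry is None:
                raise GeometryError("dense displacements require a geometry")
            self.displacements = np.asarray(self.displacements, dtype=float)
            if self.displacements.shape != (*self.geometry.shape, 3):
                raise GeometryError("dense displacement shape must be (nx, ny, nz, 3)")
            if not np.all(np.isfinite(self.displacements)):
                raise GeometryError("dense displacements must be finite")
        else:
            raise GeometryError("a DeformationField needs correspondences or displacements")

    # -- representation ----------------------------------------------------
    @property
    def kind(self) -> str:
        return "correspondence" if self.sources is not None else "dense"

    def _build_grid(self) -> None:
        """Detect a regular rectilinear source grid; else keep a KD-tree fallback."""
        src = self.sources
        axes = []
        for d in range(3):
            vals = np.unique(np.round(src[:, d], 9))
            axes.append(vals)
        n_expected = int(np.prod([len(a) for a in axes]))
        if n_expected == src.shape[0]:
            idx = np.stack(
                [np.searchsorted(axes[d], np.round(src[:, d], 9)) for d in range(3)], axis=1
            )
            lin = np.ravel_multi_index(idx.T, [len(a) for a in axes])
            if len(np.unique(lin)) == src.shape[0]:
                disp = np.zeros((*[len(a) for a in axes], 3))
                dvec = self.targets - src
                disp.reshape(-1, 3)[lin] = dvec
                self._grid_axes = tuple(axes)
                self._grid_disp = disp
                return
        self._tree = cKDTree(src)

    # -- evaluation --------------------------------------------------------
    def displacement_vectors(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Displacement vectors (mm) at arbitrary points; returns (vectors, out_of_hull).

        Regular-grid correspondence fields and dense fields interpolate
        trilinearly (exact at grid nodes); queries outside the source hull
        clamp to the nearest in-hull position and are flagged.  Scattered
        correspondences fall back to nearest-neighbour lookup.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "dense":
            ci = self.geometry.mm_to_index(pts)
            hi = np.asarray(self.geometry.shape) - 1
            out = ~self.geometry.contains_index(ci)
            coords = np.clip(ci, 0, hi).T
            vec = np.stack(
                [
                    map_coordinates(self.displacements[..., d], coords, order=1, mode="nearest")
                    for d in range(3)
                ],
                axis=1,
            )
            return vec, out
        if self._grid_disp is not None:
            axes = self._grid_axes
            frac, out = [], np.zeros(len(pts), dtype=bool)
            for d in range(3):
                ax = axes[d]
                out |= (pts[:, d] < ax[0] - _HULL_TOL) | (pts[:, d] > ax[-1] + _HULL_TOL)
                if len(ax) == 1:
                    frac.append(np.zeros(len(pts)))
                else:
                    frac.append(np.interp(pts[:, d], ax, np.arange(len(ax))))
            coords = np.asarray(frac)
            vec = np.stack(
                [
                    map_coordinates(self._grid_disp[..., d], coords, order=1, mode="nearest")
                    for d in range(3)
                ],
                axis=1,
            )
            return vec, out
        # scattered fallback: nearest source point's displacement
        _, idx = self._tree.query(pts)
        vec = (self.targets - self.sources)[idx]
        lo = self.sources.min(axis=0) - _HULL_TOL
        hi = self.sources.max(axis=0) + _HULL_TOL
        out = np.any((pts < lo) | (pts > hi), axis=1)
        return vec, out

    def displacement_at(self, points) -> np.ndarray:
        """Displaced (target-frame) mm coordinates of the given reference points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vec, _ = self.displacement_vectors(pts)
        return pts + vec

    def displace(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Displaced coordinates plus the out-of-hull flag per point."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vec, out = self.displacement_vectors(pts)
        return pts + vec, out


# ---------------------------------------------------------------------------
# M-matrix text I/O
# ---------------------------------------------------------------------------

def load_mmatrix(file, mode: str = "mm", ct: GridGeometry | None = None,
                 phase_label=None) -> DeformationField:
    """Load an n x 6 correspondence file (source xyz, target xyz per row).

    ``mode="mm"`` takes the six columns as patient millimetres; ``mode="voxel-index"``
    takes them as 1-based voxel indices of ``ct`` and converts to mm.  Row order
    is preserved — downstream traced-dose arrays follow it.  Lines starting
    with ``#`` (and an optional non-numeric one-line header) are skipped.
    """
    if mode not in ("mm", "voxel-index"):
        raise ValueError(f"mode must be 'mm' or 'voxel-index', got {mode!r}")
    if mode == "voxel-index" and ct is None:
        raise ValueError("voxel-index mode requires the CT grid geometry")

    rows = []
    header_allowance = 1
    with open(file) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            fields = text.replace(",", " ").split()
            try:
                values = [float(v) for v in fields]
            except ValueError:
                if header_allowance and not rows:
                    header_allowance = 0
                    continue
                raise MMatrixError(f"{file}: non-numeric value at line {lineno}")
            if len(values) != 6:
                raise MMatrixError(
                    f"{file}: expected 6 fields at line {lineno}, got {len(values)}"
                )
            if not all(np.isfinite(values)):
                raise MMatrixError(f"{file}: non-finite value at line {lineno}")
            rows.append(values)
    if not rows:
        raise MMatrixError(f"{file}: no correspondence rows found")
    arr = np.asarray(rows, dtype=float)
    src, tgt = arr[:, :3], arr[:, 3:]
    if mode == "voxel-index":
        src = ct.index_to_mm(src - 1.0)
        tgt = ct.index_to_mm(tgt - 1.0)
    return DeformationField(phase_label=phase_label, sources=src, targets=tgt)


def save_mmatrix(field_: DeformationField, path) -> Path:
    """Write a correspondence field as 6-column mm-mode text."""
    if field_.kind != "correspondence":
        raise ValueError("only correspondence fields can be written as an M-matrix")
    path = Path(path)
    arr = np.hstack([field_.sources, field_.targets])
    header = f"# dose4d M-matrix mode=mm phase={field_.phase_label}"
    np.savetxt(path, arr, fmt="%.17g", header=header, comments="")
    return path


# ---------------------------------------------------------------------------
# Synthetic fields and trajectories
# ---------------------------------------------------------------------------

def make_rigid_field(
    translation,
    geometry: GridGeometry,
    phase_label=None,
    grid_points: int = 5,
    margin_mm: float = 0.0,
) -> DeformationField:
    """Rigid-translation field covering a grid's extent.

    Stored as correspondences on a coarse ``grid_points^3`` lattice spanning
    the geometry's voxel-center bounding box (optionally expanded by
    ``margin_mm``); trilinear interpolation of a constant displacement is
    exact everywhere, including under out-of-hull clamping.
    """
    t = np.asarray(translation, dtype=float)
    if t.shape != (3,) or not np.all(np.isfinite(t)):
        raise GeometryError("translation must be a finite 3-vector")
    lo = np.asarray(geometry.origin) - margin_mm
    hi = geometry.index_to_mm(np.asarray(geometry.shape) - 1) + margin_mm
    axes = [np.linspace(lo[d], hi[d], grid_points) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    src = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    return DeformationField(phase_label=phase_label, sources=src, targets=src + t)


def make_respiratory_trajectory(amplitude, n_phases: int) -> np.ndarray:
    """Per-phase rigid translations of a sin^2 respiratory surrogate.

    ``translation_k = amplitude * sin^2(pi * k / K)`` for ``k = 0..K-1``:
    phase 0 (end-inhale convention) has zero displacement, phase K/2
    (end-exhale) the full amplitude, so the peak-to-peak excursion equals
    ``|amplitude|``.  Returns an array of shape ``(K, 3)``.
    """
    if n_phases < 2:
        raise ValueError(f"need at least 2 phase bins, got {n_phases}")
    a = np.asarray(amplitude, dtype=float)
    k = np.arange(n_phases)
    return np.sin(np.pi * k / n_phases)[:, None] ** 2 * a[None, :]


def phase_labels(n_phases: int) -> list[float]:
    """Phase labels in percent of the respiratory cycle (0, 10, ... for K=10)."""
    return [100.0 * k / n_phases for k in range(n_phases)]


@dataclass(frozen=True)
class FieldReport:
    """Quality summary of a deformation field against a phase dose grid."""

    n_voxels: int
    n_out_of_grid: int
    max_displacement_mm: float
    mean_displacement_mm: float

    @property
    def fraction_out_of_grid(self) -> float:
        return self.n_out_of_grid / self.n_voxels if self.n_voxels else 0.0


def validate_field(
    field_: DeformationField,
    reference: GridGeometry,
    phase_dose: GridGeometry,
) -> FieldReport:
    """Report how many reference voxels a field displaces off the phase dose grid,
    plus displacement magnitude statistics."""
    centers = reference.voxel_centers_mm()
    vec, _ = field_.displacement_vectors(centers)
    displaced = centers + vec
    inside = phase_dose.contains_index(phase_dose.mm_to_index(displaced))
    mag = np.linalg.norm(vec, axis=1)
    return FieldReport(
        n_voxels=len(centers),
        n_out_of_grid=int((~inside).sum()),
        max_displacement_mm=float(mag.max()) if len(mag) else 0.0,
        mean_displacement_mm=float(mag.mean()) if len(mag) else 0.0,
    )


__all__ = [
    "DeformationField",
    "FieldReport",
    "MMatrixError",
    "load_mmatrix",
    "save_mmatrix",
    "make_rigid_field",
    "make_respiratory_trajectory",
    "phase_labels",
    "validate_field",
]
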