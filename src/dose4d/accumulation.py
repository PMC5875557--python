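"""Time-weighted dose accumulation over respiratory phases and embedding of
traced 1D dose arrays back onto the reference CT grid."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_registration import PhaseDose
from .geometry_io import DoseGrid, GeometryError, GridGeometry

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PhaseWeights:
    """Per-phase dimensionless fractions of cycle time; must sum to 1.

    Equal phase binning of the respiratory cycle implies uniform weights
    ``1/K`` (:meth:`uniform`); non-uniform weights accommodate irregular
    breathing.  Construction enforces non-negativity and normalization to
    within 1e-9; :meth:`normalized` rescales explicitly.
    """

    values: tuple

    def __init__(self, values):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or len(arr) == 0:
            raise ValueError("weights must be a non-empty 1D sequence")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("weights must be finite and non-negative")
        if abs(arr.sum() - 1.0) > _SUM_TOL:
            raise ValueError(
                f"weights sum to {arr.sum():.12g}, not 1 (use PhaseWeights.normalized)"
            )
        object.__setattr__(self, "values", tuple(float(v) for v in arr))

    @classmethod
    def uniform(cls, n_phases: int) -> "PhaseWeights":
        if n_phases < 1:
            raise ValueError("need at least one phase")
        return cls(np.full(n_phases, 1.0 / n_phases))

    @classmethod
    def normalized(cls, values) -> "PhaseWeights":
        arr = np.asarray(values, dtype=float)
        total = arr.sum()
        if total <= 0:
            raise ValueError("weights must have a positive sum to normalize")
        return cls(arr / total)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AccumulatedDose:
    """Time-weighted 4D dose over the traced voxel set of the reference grid."""

    doses: np.ndarray
    voxel_index_map: np.ndarray
    reference_shape: tuple[int, int, int]
    phases_included: list
    weights_used: PhaseWeights
    out_of_grid_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.voxel_index_map = np.asarray(self.voxel_index_map, dtype=np.int64)
        if self.out_of_grid_flags is None:
            self.out_of_grid_flags = np.zeros(self.doses.shape, dtype=bool)
        if len(self.doses) != len(self.voxel_index_map):
            raise GeometryError("doses and voxel_index_map must share one length")
        if not np.all(np.isfinite(self.doses)) or np.any(self.doses < 0):
            raise GeometryError("accumulated doses must be finite and non-negative")


def _check_compatible(phase_doses: list[PhaseDose]) -> None:
    if not phase_doses:
        raise ValueError("need at least one phase dose")
    first = phase_doses[0]
    for pd in phase_doses[1:]:
        if pd.reference_shape != first.reference_shape or not np.array_equal(
            pd.voxel_index_map, first.voxel_index_map
        ):
            raise GeometryError("phase doses do not share an identical voxel index map")


def accumulate(phase_doses: list[PhaseDose], weights: PhaseWeights) -> AccumulatedDose:
    """Time-weighted summation ``dose_v = sum_x w_x * TDX_x[v]`` over all phases.

    Voxels flagged out-of-grid in a phase contribute that phase's policy value
    (0 Gy under the default zero policy); the output voxel carries the union
    of the per-phase flags.
    """
    _check_compatible(phase_doses)
    if len(weights) != len(phase_doses):
        raise ValueError(
            f"{len(weights)} weights for {len(phase_doses)} phases"
        )
    stack = np.stack([pd.doses for pd in phase_doses])
    flags = np.stack([pd.out_of_grid_flags for pd in phase_doses]).any(axis=0)
    total = weights.array @ stack
    return AccumulatedDose(
        doses=total,
        voxel_index_map=phase_doses[0].voxel_index_map.copy(),
        reference_shape=phase_doses[0].reference_shape,
        phases_included=[pd.phase_label for pd in phase_doses],
        weights_used=weights,
        out_of_grid_flags=flags,
    )


def accumulate_subrange(
    phase_doses: list[PhaseDose],
    weights: PhaseWeights,
    phases_selected,
) -> AccumulatedDose:
    """Accumulate over a gated sub-range (duty cycle) of the breathing cycle.

    ``phases_selected`` lists phase labels to keep; their weights are
    renormalized to 1 before summation, so the result is the conditional
    time-average over the selected window.
    """
    labels = [pd.phase_label for pd in phase_doses]
    selected = list(phases_selected)
    if not selected:
        raise ValueError("phases_selected must be non-empty")
    missing = [s for s in selected if s not in labels]
    if missing:
        raise ValueError(f"unknown phase label(s): {missing}")
    keep = [i for i, lab in enumerate(labels) if lab in selected]
    sub_weights = PhaseWeights.normalized(weights.array[keep])
    return accumulate([phase_doses[i] for i in keep], sub_weights)


def embed_on_reference(
    doses,
    reference: GridGeometry,
    fill: float = 0.0,
) -> DoseGrid:
    """Embed a traced 1D dose array (PhaseDose or AccumulatedDose) onto the
    reference lattice; untraced voxels carry ``fill`` Gy."""
    n = int(np.prod(reference.shape))
    idx = np.asarray(doses.voxel_index_map, dtype=np.int64)
    if np.any(idx < 0) or np.any(idx >= n):
        raise GeometryError("voxel index out of range for the reference grid")
    if doses.reference_shape != tuple(reference.shape):
        raise GeometryError("traced array was built for a different reference shape")
    flat = np.full(n, float(fill))
    flat[idx] = doses.doses
    label = getattr(doses, "phase_label", None) or "accumulated"
    return DoseGrid(geometry=reference, dose=flat.reshape(reference.shape), phase_label=label)


def extract_from_grid(grid: DoseGrid, voxel_index_map) -> np.ndarray:
    """Inverse of :func:`embed_on_reference`: pull traced-voxel doses off a grid."""
    return grid.dose.ravel()[np.asarray(voxel_index_map, dtype=np.int64)]


__all__ = [
    "PhaseWeights",
    "AccumulatedDose",
    "accumulate",
    "accumulate_subrange",
    "embed_on_reference",
    "extract_from_grid",
]
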