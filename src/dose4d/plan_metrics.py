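"""Plan-quality evaluation: cumulative DVH, V_D, Dmin/Dmax, target coverage
index (TCI), conformity index (CI), heterogeneity index (HI) and the
Matching Index (Jaccard overlap of two contoured volumes).

Definitions
-----------
TCI
    Percentage of target voxels receiving at least the prescription dose D_p.
CI
    With D_RI the highest isodose level covering the requested fraction of
    the target (default 99.5%), CI = (body voxels with dose >= D_RI) /
    (target voxels).  Values well above 1 indicate prescription dose spilling
    outside the target.
HI
    Maximum target dose divided by D_p (point maximum, not a percentile);
    >= 1 whenever the plan reaches prescription inside the target.
Matching Index
    |A intersect B| / |A union B| by voxel count — the Jaccard index of two
    masks, used to score deformably mapped contours against manual ones.

All dose thresholds use ">=" (dose at least d).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np

from .geometry_io import BinaryMask, DoseGrid, GeometryError


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram on uniform dose bins."""

    edges: np.ndarray  # bin edges, Gy
    cumulative_pct: np.ndarray  # % of structure receiving >= edge
    structure: str = ""
    volume_cc: float = 0.0

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.cumulative_pct = np.asarray(self.cumulative_pct, dtype=float)
        if self.edges.shape != self.cumulative_pct.shape:
            raise ValueError("edges and cumulative curve must align")


@dataclass
class PlanIndices:
    """Flat report of the dosimetric indices of one structure."""

    structure: str
    prescription_dose: float
    tci_pct: float
    ci: float
    hi: float
    dmin: float
    dmax: float
    v_at: dict = dataclass_field(default_factory=dict)  # Gy -> % volume

    def as_dict(self) -> dict:
        out = {
            "structure": self.structure,
            "prescription_dose_gy": self.prescription_dose,
            "tci_pct": self.tci_pct,
            "ci": self.ci,
            "hi": self.hi,
            "dmin_gy": self.dmin,
            "dmax_gy": self.dmax,
        }
        for d, v in self.v_at.items():
            out[f"v{d:g}gy_pct"] = v
        return out


def _masked_doses(dose: DoseGrid, mask: BinaryMask) -> np.ndarray:
    if not dose.geometry.approx_equal(mask.geometry):
        raise GeometryError("dose and mask are on different grids")
    vals = dose.dose[mask.inside]
    if vals.size == 0:
        raise GeometryError("mask selects no voxels")
    return vals


def compute_dvh(dose: DoseGrid, mask: BinaryMask, bin_width: float = 0.05,
                structure: str = "") -> DVHCurve:
    """Cumulative DVH of the masked voxels.

    The curve value at each edge is the exact percentage of structure voxels
    with dose >= that edge; the structure volume derives from the voxel
    volume times the voxel count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = np.sort(_masked_doses(dose, mask))
    n = len(vals)
    n_edges = int(np.ceil(vals[-1] / bin_width)) + 2
    edges = np.arange(n_edges) * bin_width
    cum = 100.0 * (n - np.searchsorted(vals, edges, side="left")) / n
    return DVHCurve(
        edges=edges,
        cumulative_pct=cum,
        structure=structure,
        volume_cc=n * mask.geometry.voxel_volume_mm3 / 1000.0,
    )


def v_at_dose(dvh: DVHCurve, d: float) -> float:
    """Percent of structure volume receiving at least ``d`` Gy, linearly
    interpolated between DVH bin edges."""
    if d < 0:
        raise ValueError("dose threshold must be >= 0")
    return float(np.interp(d, dvh.edges, dvh.cumulative_pct, right=0.0))


def dmin_dmax(dose: DoseGrid, mask: BinaryMask) -> tuple[float, float]:
    """Exact voxel minimum and maximum dose over the structure (no percentile
    smoothing — sensitive to single voxels by design)."""
    vals = _masked_doses(dose, mask)
    return float(vals.min()), float(vals.max())


def tci(dose: DoseGrid, target_mask: BinaryMask, prescription_dose: float) -> float:
    """Target coverage index: % of target voxels with dose >= D_p."""
    vals = _masked_doses(dose, target_mask)
    return float(100.0 * np.count_nonzero(vals >= prescription_dose) / len(vals))


def ci(
    dose: DoseGrid,
    target_mask: BinaryMask,
    body_mask: BinaryMask | None = None,
    coverage: float = 0.995,
) -> float:
    """Conformity index at the isodose that covers ``coverage`` of the target.

    D_RI is the largest dose level such that at least the coverage fraction
    of target voxels receive >= D_RI (the ceil(coverage*N)-th largest target
    dose); CI is the count of body voxels at or above D_RI divided by the
    target voxel count.  Without a body mask the whole grid is the body.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    target = _masked_doses(dose, target_mask)
    m = int(np.ceil(coverage * len(target)))
    d_ri = float(np.sort(target)[::-1][m - 1])
    if body_mask is None:
        body = dose.dose.ravel()
    else:
        if not dose.geometry.approx_equal(body_mask.geometry):
            raise GeometryError("dose and body mask are on different grids")
        body = dose.dose[body_mask.inside]
    return float(np.count_nonzero(body >= d_ri) / len(target))


def hi(dose: DoseGrid, target_mask: BinaryMask, prescription_dose: float) -> float:
    """Heterogeneity index: maximum target dose over the prescription dose."""
    if prescription_dose <= 0:
        raise ValueError("prescription dose must be positive")
    return float(_masked_doses(dose, target_mask).max() / prescription_dose)


def matching_index(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Jaccard overlap |A∩B| / |A∪B| of two masks on the same grid."""
    if not mask_a.geometry.approx_equal(mask_b.geometry):
        raise GeometryError("masks are on different grids")
    union = np.count_nonzero(mask_a.inside | mask_b.inside)
    if union == 0:
        raise GeometryError("both masks are empty")
    inter = np.count_nonzero(mask_a.inside & mask_b.inside)
    return float(inter / union)


def evaluate_plan(
    dose: DoseGrid,
    target_mask: BinaryMask,
    prescription_dose: float,
    body_mask: BinaryMask | None = None,
    thresholds=(20.0,),
    coverage: float = 0.995,
    bin_width: float = 0.05,
    structure: str = "",
) -> tuple[PlanIndices, DVHCurve]:
    """One-stop evaluation of a structure: DVH plus all indices."""
    dvh = compute_dvh(dose, target_mask, bin_width=bin_width, structure=structure)
    lo, hi_ = dmin_dmax(dose, target_mask)
    indices = PlanIndices(
        structure=structure,
        prescription_dose=prescription_dose,
        tci_pct=tci(dose, target_mask, prescription_dose),
        ci=ci(dose, target_mask, body_mask, coverage=coverage),
        hi=hi(dose, target_mask, prescription_dose),
        dmin=lo,
        dmax=hi_,
        v_at={float(d): v_at_dose(dvh, float(d)) for d in thresholds},
    )
    return indices, dvh


def write_dvh(dvh: DVHCurve, path) -> Path:
    """Export a DVH as two-column delimited text (dose Gy, % volume)."""
    path = Path(path)
    header = f"# dose4d DVH structure={dvh.structure} volume_cc={dvh.volume_cc:.6g}"
    np.savetxt(path, np.column_stack([dvh.edges, dvh.cumulative_pct]),
               fmt="%.6g", header=header, comments="")
    return path


__all__ = [
    "DVHCurve",
    "PlanIndices",
    "compute_dvh",
    "v_at_dose",
    "dmin_dmax",
    "tci",
    "ci",
    "hi",
    "matching_index",
    "evaluate_plan",
    "write_dvh",
]
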