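"""Synthetic 4D respiratory phantom with analytic ground truth.

The phantom emulates free-breathing delivery of a static conformal plan: a
spherical target (+HU offset in a lung-like background) translates along a
periodic sin^2 trajectory sampled at K equal phase bins, while the planned
dose distribution stays fixed in patient coordinates (the beam does not
track).  Each phase bin gets a CT series with the sphere at its displaced
position, an RTDOSE grid carrying the static plan dose, and a rigid
M-matrix deformation field mapping reference voxels to that phase.  Because
the motion is rigid, the exact time-weighted accumulated dose at any point
is the static dose profile averaged over the displaced sample positions —
equivalently, the static profile blurred by the discrete motion probability
mass function — and is available in closed form for oracle comparisons.

The dose profile encodes a prescription of ``D_p`` Gy at isodose fraction
``f`` (default 20 Gy at 85%): a plateau of ``D_p / f`` inside the target
radius falling off as a half-Gaussian penumbra of width ``sigma`` outside,
so the ``D_p`` surface sits at the ``f`` isodose level and the static plan's
heterogeneity index is ``1/f`` by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydicom.uid import generate_uid

from .accumulation import PhaseWeights, accumulate, embed_on_reference
from .deformation import make_respiratory_trajectory, make_rigid_field, phase_labels, save_mmatrix
from .dose_registration import trace_phase_dose
from .geometry_io import (
    BinaryMask,
    DoseGrid,
    GridGeometry,
    ImageVolume,
    StructureROI,
    StructureSet,
    write_ct_series,
    write_rtdose,
    write_rtstruct,
)

MANIFEST_NAME = "manifest.json"


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the moving-sphere phantom.

    Defaults model a small peripheral lung tumor: 10 mm radius sphere, 9 mm
    peak-to-peak craniocaudal excursion (the upper end of clinically
    observed lung-tumor motion), 10 phase bins, 20 Gy prescribed at the 85%
    isodose, 3 mm penumbra.  In-plane spacing is finer than the slice pitch,
    as in clinical thoracic CT.
    """

    shape: tuple = (48, 48, 26)
    spacing: tuple = (1.25, 1.25, 3.0)
    radius_mm: float = 10.0
    amplitude_mm: tuple = (0.0, 0.0, 9.0)
    n_phases: int = 10
    prescription_dose: float = 20.0
    isodose_fraction: float = 0.85
    penumbra_sigma_mm: float = 3.0
    hu_background: float = -800.0
    hu_target_offset: float = 1000.0
    hu_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("target radius must be positive")
        if self.n_phases < 2:
            raise ValueError("need at least 2 phase bins")
        if not 0 < self.isodose_fraction <= 1:
            raise ValueError("isodose fraction must be in (0, 1]")
        if self.penumbra_sigma_mm < 0:
            raise ValueError("penumbra width must be >= 0")

    @property
    def geometry(self) -> GridGeometry:
        """Grid centered on the patient origin; target center at (0, 0, 0)."""
        shape = np.asarray(self.shape)
        spacing = np.asarray(self.spacing)
        origin = -(shape - 1) * spacing / 2.0
        return GridGeometry(origin=tuple(origin), spacing=tuple(self.spacing),
                            shape=tuple(int(n) for n in self.shape))

    @property
    def plateau_dose(self) -> float:
        return self.prescription_dose / self.isodose_fraction

    @property
    def target_center(self) -> np.ndarray:
        return np.zeros(3)

    def translations(self) -> np.ndarray:
        return make_respiratory_trajectory(self.amplitude_mm, self.n_phases)

    def labels(self) -> list[float]:
        return phase_labels(self.n_phases)


def dose_profile(spec: PhantomSpec, distance_mm) -> np.ndarray:
    """Static radial dose profile: plateau inside the radius, half-Gaussian outside."""
    d = np.asarray(distance_mm, dtype=float)
    excess = np.maximum(d - spec.radius_mm, 0.0)
    if spec.penumbra_sigma_mm == 0:
        fall = np.where(excess > 0, 0.0, 1.0)
    else:
        fall = np.exp(-(excess**2) / (2.0 * spec.penumbra_sigma_mm**2))
    return spec.plateau_dose * fall


def static_dose(spec: PhantomSpec) -> DoseGrid:
    """The planned (phase-independent) dose grid, fixed at the target's
    reference position."""
    geom = spec.geometry
    centers = geom.voxel_centers_mm()
    dist = np.linalg.norm(centers - spec.target_center, axis=1)
    return DoseGrid(geometry=geom, dose=dose_profile(spec, dist).reshape(geom.shape))


def phase_ct(spec: PhantomSpec, phase_index: int, rng: np.random.Generator | None = None) -> ImageVolume:
    """CT of one phase bin: the sphere displaced to its trajectory position."""
    geom = spec.geometry
    t = spec.translations()[phase_index]
    centers = geom.voxel_centers_mm()
    dist = np.linalg.norm(centers - (spec.target_center + t), axis=1)
    hu = np.full(len(centers), spec.hu_background)
    hu[dist <= spec.radius_mm] += spec.hu_target_offset
    if rng is not None and spec.hu_noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.hu_noise_sd, size=hu.shape)
    return ImageVolume(
        geometry=geom,
        intensities=hu.reshape(geom.shape),
        phase_label=spec.labels()[phase_index],
    )


def sphere_mask(spec: PhantomSpec, center=None) -> BinaryMask:
    """Voxel-center rasterization of the target sphere (analytic, no contours)."""
    geom = spec.geometry
    c = spec.target_center if center is None else np.asarray(center, dtype=float)
    dist = np.linalg.norm(geom.voxel_centers_mm() - c, axis=1)
    return BinaryMask(geometry=geom, inside=(dist <= spec.radius_mm).reshape(geom.shape))


def gtv_structure(spec: PhantomSpec, n_vertices: int = 64) -> StructureSet:
    """GTV contours on the reference CT: one circle per slice the sphere crosses."""
    geom = spec.geometry
    c = spec.target_center
    contours = []
    for k in range(geom.shape[2]):
        z = geom.index_to_mm([0, 0, k])[2]
        h2 = spec.radius_mm**2 - (z - c[2]) ** 2
        if h2 <= 0:
            continue
        r = float(np.sqrt(h2))
        theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
        pts = np.column_stack(
            [c[0] + r * np.cos(theta), c[1] + r * np.sin(theta), np.full(n_vertices, z)]
        )
        contours.append(pts)
    roi = StructureROI(name="GTV", contours=contours)
    return StructureSet(rois={"GTV": roi})


@dataclass
class PhantomSet:
    """Paths of one written phantom fixture set."""

    root: Path
    manifest: Path
    ct_dirs: list
    dose_files: list
    dvf_files: list
    rtstruct: Path
    spec: PhantomSpec = field(repr=False, default=None)


def build_phantom(spec: PhantomSpec, out_dir) -> PhantomSet:
    """Write the complete 4D fixture set: K phase CT series, K RTDOSE grids,
    K rigid M-matrix DVF files, the reference-phase RTSTRUCT and a manifest
    with uniform 1/K weights."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    frame_of_reference = generate_uid()
    geom = spec.geometry
    translations = spec.translations()
    labels = spec.labels()
    dose = static_dose(spec)

    ct_dirs, dose_files, dvf_files, phases = [], [], [], []
    for k, (label, t) in enumerate(zip(labels, translations)):
        tag = f"{k:02d}"
        ct_dir = out_dir / f"ct_phase{tag}"
        vol = phase_ct(spec, k, rng=rng)
        vol.frame_of_reference = frame_of_reference
        write_ct_series(vol, ct_dir, series_description=f"phase {label}")
        dose_path = out_dir / f"rtdose_phase{tag}.dcm"
        write_rtdose(
            DoseGrid(geometry=geom, dose=dose.dose, phase_label=label,
                     frame_of_reference=frame_of_reference),
            dose_path,
        )
        dvf_path = out_dir / f"dvf_phase{tag}.txt"
        save_mmatrix(make_rigid_field(t, geom, phase_label=label), dvf_path)
        ct_dirs.append(ct_dir)
        dose_files.append(dose_path)
        dvf_files.append(dvf_path)
        phases.append(
            {
                "label": label,
                "ct_dir": ct_dir.name,
                "dose": dose_path.name,
                "dvf": dvf_path.name,
                "weight": 1.0 / spec.n_phases,
                "translation_mm": [float(v) for v in t],
            }
        )

    reference_ct = ImageVolume(
        geometry=geom, intensities=phase_ct(spec, 0).intensities, phase_label="reference",
        frame_of_reference=frame_of_reference,
    )
    rtstruct_path = out_dir / "rtstruct.dcm"
    write_rtstruct(gtv_structure(spec), reference_ct, rtstruct_path,
                   frame_of_reference=frame_of_reference)

    manifest = {
        "format": "dose4d-phantom",
        "version": 1,
        "seed": spec.seed,
        "frame_of_reference": frame_of_reference,
        "reference_phase_index": 0,
        "dvf_mode": "mm",
        "rtstruct": rtstruct_path.name,
        "roi": "GTV",
        "prescription_dose_gy": spec.prescription_dose,
        "isodose_fraction": spec.isodose_fraction,
        "phases": phases,
        "spec": {
            "shape": list(spec.shape),
            "spacing": list(spec.spacing),
            "radius_mm": spec.radius_mm,
            "amplitude_mm": list(spec.amplitude_mm),
            "n_phases": spec.n_phases,
            "prescription_dose": spec.prescription_dose,
            "isodose_fraction": spec.isodose_fraction,
            "penumbra_sigma_mm": spec.penumbra_sigma_mm,
            "hu_background": spec.hu_background,
            "hu_target_offset": spec.hu_target_offset,
            "hu_noise_sd": spec.hu_noise_sd,
            "seed": spec.seed,
        },
    }
    manifest_path = out_dir / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return PhantomSet(
        root=out_dir,
        manifest=manifest_path,
        ct_dirs=ct_dirs,
        dose_files=dose_files,
        dvf_files=dvf_files,
        rtstruct=rtstruct_path,
        spec=spec,
    )


def analytic_accumulated_dose(spec: PhantomSpec, points_mm) -> np.ndarray:
    """Exact time-weighted accumulated dose at arbitrary points.

    A tissue element at reference position ``p`` sits at ``p + t_k`` during
    phase ``k`` and receives the static profile there, so the accumulated
    dose is ``sum_k (1/K) * profile(|p + t_k - c0|)`` — the static dose
    blurred by the discrete motion probability mass function.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    total = np.zeros(len(pts))
    w = 1.0 / spec.n_phases
    for t in spec.translations():
        dist = np.linalg.norm(pts + t - spec.target_center, axis=1)
        total += w * dose_profile(spec, dist)
    return total


def make_displaced_plan_example(spec: PhantomSpec):
    """Per-phase and accumulated target coverage of the reference GTV.

    Runs the in-memory pipeline (rigid fields, tracing, uniform-weight
    accumulation) and tabulates V(D_p) of the GTV for each phase plus the
    accumulated dose.  Returns a DataFrame with one row per phase and a
    final ``"accumulated"`` row.
    """
    geom = spec.geometry
    dose = static_dose(spec)
    mask = sphere_mask(spec)
    n_target = int(mask.inside.sum())
    phase_doses = []
    rows = []
    for label, t in zip(spec.labels(), spec.translations()):
        fld = make_rigid_field(t, geom, phase_label=label)
        pd_ = trace_phase_dose(geom, mask, fld, dose)
        phase_doses.append(pd_)
        v = 100.0 * np.count_nonzero(pd_.doses >= spec.prescription_dose) / n_target
        rows.append({"phase": label, "v_dp_pct": v})
    acc = accumulate(phase_doses, PhaseWeights.uniform(spec.n_phases))
    v_acc = 100.0 * np.count_nonzero(acc.doses >= spec.prescription_dose) / n_target
    rows.append({"phase": "accumulated", "v_dp_pct": v_acc})
    return pd.DataFrame(rows)


def run_pipeline_in_memory(spec: PhantomSpec, roi_mask="all"):
    """Trace and accumulate the phantom without file I/O; returns
    (AccumulatedDose, embedded DoseGrid, list of PhaseDose)."""
    geom = spec.geometry
    dose = static_dose(spec)
    phase_doses = [
        trace_phase_dose(geom, roi_mask, make_rigid_field(t, geom, phase_label=label), dose)
        for label, t in zip(spec.labels(), spec.translations())
    ]
    acc = accumulate(phase_doses, PhaseWeights.uniform(spec.n_phases))
    return acc, embed_on_reference(acc, geom), phase_doses


__all__ = [
    "PhantomSpec",
    "PhantomSet",
    "MANIFEST_NAME",
    "dose_profile",
    "static_dose",
    "phase_ct",
    "sphere_mask",
    "gtv_structure",
    "build_phantom",
    "analytic_accumulated_dose",
    "make_displaced_plan_example",
    "run_pipeline_in_memory",
]
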