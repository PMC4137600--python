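"""Synthetic 4-D chest phantom with known ground truth.

Emulates a bench validation setup: an anthropomorphic chest section —
a soft-tissue body shell enclosing a low-HU lung cavity — containing a
water-equivalent tumor sphere (default 6 cm diameter) that moves on a
known periodic trajectory across 10 breathing phases, with additive
Gaussian noise.  Because the motion is rigid, the ground-truth volume is
constant across phases, so any volume variation a segmentation reports
on the phantom is pure algorithmic/noise error.

Geometry (all configurable): the body is a circular cylinder of
soft-tissue HU; inside it a coaxial cylindrical lung cavity spans most
of the z extent; the tumor sphere sits in the cavity.  Optional extras
reproduce the classical failure-mode geometries: a tissue neck attaching
the tumor to the chest wall, and a diaphragm-like dome of tumor-equal
intensity rising from the cavity floor.

Voxelization rule: a voxel belongs to a shape iff its center lies inside
the analytic surface.  Noise streams are derived from (rng_seed, phase)
so phases are independent yet bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import PhantomSpecificationError
from .motion_metrics import Trajectory, TrajectoryEntry
from .mpsl_core import IntensityRange, MPSLConfig
from .volume_io import BinaryMask, PhaseVolume, Series4D

__all__ = ["Motion", "Attachment", "Diaphragm", "PhantomSpec",
           "generate_phantom", "phantom_suite", "SuiteCase"]

N_PHASES = 10
PHASE_LABELS = tuple(range(0, 100, 10))


@dataclass(frozen=True)
class Motion:
    """Tumor displacement waveform over the 10 phases.

    * ``none`` — static target.
    * ``sinusoid`` — displacement(p) = amplitude · cos(2π·p/100) for
      phase label p, so the sampled COG span is exactly twice the
      amplitude peak-to-peak.
    * ``custom`` — an explicit list of 10 per-phase (dx, dy, dz) mm.
    """

    kind: str = "sinusoid"
    amplitude_mm: Tuple[float, float, float] = (0.0, 0.0, 10.0)
    displacements_mm: Optional[Tuple[Tuple[float, float, float], ...]] = None

    def __post_init__(self):
        if self.kind not in ("none", "sinusoid", "custom"):
            raise PhantomSpecificationError(f"unknown motion kind {self.kind!r}")
        if self.kind == "custom":
            if self.displacements_mm is None or len(self.displacements_mm) != N_PHASES:
                raise PhantomSpecificationError(
                    f"custom motion needs {N_PHASES} displacement triples"
                )
            object.__setattr__(
                self, "displacements_mm",
                tuple(tuple(float(v) for v in d) for d in self.displacements_mm))

    def displacement(self, phase_label: int) -> np.ndarray:
        if self.kind == "none":
            return np.zeros(3)
        if self.kind == "custom":
            return np.array(self.displacements_mm[PHASE_LABELS.index(phase_label)])
        return np.array(self.amplitude_mm) * math.cos(2.0 * math.pi * phase_label / 100.0)


@dataclass(frozen=True)
class Attachment:
    """Tissue neck of tumor-equal HU bridging the sphere to the body wall
    along +x (rigidly attached to the moving tumor)."""

    neck_radius_mm: float = 3.0

    def __post_init__(self):
        if self.neck_radius_mm <= 0:
            raise PhantomSpecificationError("neck_radius_mm must be > 0")


@dataclass(frozen=True)
class Diaphragm:
    """Half-ellipsoid dome of tumor-equal HU rising from the cavity floor."""

    semiaxes_mm: Tuple[float, float, float] = (55.0, 55.0, 35.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic 4-D phantom realization."""

    dims: Tuple[int, int, int] = (120, 120, 64)
    spacing: Tuple[float, float, float] = (1.5, 1.5, 2.5)
    body_hu: float = 40.0
    wall_hu: Optional[float] = None          # lining near the cavity; body_hu if None
    lung_hu: float = -800.0
    tumor_hu: float = 0.0
    air_hu: float = -1000.0
    noise_sd: float = 20.0
    tumor_diameter_mm: float = 60.0
    tumor_center_mm: Optional[Tuple[float, float, float]] = None
    motion: Motion = field(default_factory=Motion)
    attachment: Optional[Attachment] = None
    diaphragm: Optional[Diaphragm] = None
    body_radius_mm: float = 86.0
    lung_radius_mm: float = 70.0
    lung_z_margin_mm: float = 12.5
    wall_lining_mm: float = 6.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise PhantomSpecificationError("noise_sd must be ≥ 0")
        if self.tumor_diameter_mm <= 0:
            raise PhantomSpecificationError("tumor_diameter_mm must be > 0")
        if any(d < 8 for d in self.dims):
            raise PhantomSpecificationError(f"grid too small: {self.dims}")

    @property
    def extent_mm(self) -> Tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.dims, self.spacing))

    def default_tumor_center(self) -> Tuple[float, float, float]:
        ex, ey, ez = self.extent_mm
        return (ex / 2.0, ey / 2.0, ez / 2.0)


def _grids(spec: PhantomSpec):
    """Physical voxel-center coordinate grids (sparse broadcastable)."""
    axes = [np.arange(n) * s for n, s in zip(spec.dims, spec.spacing)]
    return np.ix_(axes[0], axes[1], axes[2])


def generate_phantom(spec: PhantomSpec):
    """Generate (Series4D, ground-truth masks, truth trajectory).

    The truth trajectory carries the *analytic* tumor centers and the
    voxelized truth volumes; truth masks are the exact voxelized sphere
    plus, when a wall attachment is configured, the neck up to the wall.
    Raises :class:`PhantomSpecificationError` naming the first phase at
    which the tumor sphere leaves the lung cavity.
    """
    X, Y, Z = _grids(spec)
    ex, ey, ez = spec.extent_mm
    cx, cy = ex / 2.0, ey / 2.0
    r2_xy = (X - cx) ** 2 + (Y - cy) ** 2
    body = np.broadcast_to(r2_xy <= spec.body_radius_mm ** 2, spec.dims)
    z_lo = spec.lung_z_margin_mm
    z_hi = ez - spec.lung_z_margin_mm
    cavity = (r2_xy <= spec.lung_radius_mm ** 2) & (Z >= z_lo) & (Z <= z_hi)
    cavity = cavity & body

    base = np.full(spec.dims, spec.air_hu, dtype=np.float32)
    base[body] = spec.body_hu
    if spec.wall_hu is not None:
        lining = (body & ~cavity
                  & (r2_xy <= (spec.lung_radius_mm + spec.wall_lining_mm) ** 2)
                  & (Z >= z_lo - spec.wall_lining_mm)
                  & (Z <= z_hi + spec.wall_lining_mm))
        base[lining] = spec.wall_hu
    base[cavity] = spec.lung_hu

    if spec.diaphragm is not None:
        ax_, ay_, az_ = spec.diaphragm.semiaxes_mm
        dome = (((X - cx) / ax_) ** 2 + ((Y - cy) / ay_) ** 2
                + ((Z - z_lo) / az_) ** 2 <= 1.0) & (Z >= z_lo) & cavity
        base[dome] = spec.tumor_hu

    center0 = np.array(spec.tumor_center_mm or spec.default_tumor_center())
    R = spec.tumor_diameter_mm / 2.0

    phases: List[PhaseVolume] = []
    truth_masks: List[BinaryMask] = []
    entries: List[TrajectoryEntry] = []
    voxel_cc = float(np.prod(spec.spacing)) / 1000.0
    for p_idx, label in enumerate(PHASE_LABELS):
        c = center0 + spec.motion.displacement(label)
        sphere = ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) <= R ** 2
        if np.any(sphere & ~cavity):
            raise PhantomSpecificationError(
                f"tumor sphere leaves the lung cavity at phase {label} "
                f"(center {tuple(np.round(c, 1))} mm)"
            )
        truth = sphere
        vol = base.copy()
        vol[sphere] = spec.tumor_hu
        if spec.attachment is not None:
            nr = spec.attachment.neck_radius_mm
            neck = (((Y - c[1]) ** 2 + (Z - c[2]) ** 2) <= nr ** 2) & (X >= c[0])
            vol[neck & cavity] = spec.tumor_hu
            truth = truth | (neck & cavity)
        if spec.noise_sd > 0:
            rng = np.random.default_rng([spec.rng_seed, p_idx])
            vol = vol + rng.normal(0.0, spec.noise_sd, spec.dims).astype(np.float32)
        phases.append(PhaseVolume(vol, spec.spacing, (0.0, 0.0, 0.0), label))
        truth_masks.append(BinaryMask(truth, spec.spacing))
        entries.append(TrajectoryEntry(label, tuple(float(v) for v in c),
                                       float(truth.sum() * voxel_cc)))

    return Series4D(phases), truth_masks, Trajectory(entries)


# ---------------------------------------------------------------------------
# Named suite mirroring the classical validation / failure-mode geometries.

@dataclass(frozen=True)
class SuiteCase:
    name: str
    spec: PhantomSpec
    config: MPSLConfig
    expected_behavior: str


def _soft_tissue_config(**overrides) -> MPSLConfig:
    base = dict(
        tumor_range=IntensityRange(-150.0, 150.0),
        surround_range=IntensityRange(-150.0, 150.0),
        volume_min_cc=30.0,
        volume_max_cc=200.0,
        radius_mm=4.0,
        element_shape="ball",
        mode="3d",
        connectivity="face",
    )
    base.update(overrides)
    return MPSLConfig(**base)


def phantom_suite(rng_seed: int = 0) -> List[SuiteCase]:
    """Named phantom specs with matched segmentation configurations.

    * ``baseline`` — free-floating 6-cm water sphere with 10 mm sinusoidal
      z-motion and 20 HU noise: the pipeline should recover it with Dice
      ≥ 0.95 and track volume/COG motion within a few percent.
    * ``wall_attached`` — the same sphere joined to the chest wall by a
      3-mm-radius tissue neck: plain thresholding merges tumor and wall
      into one component, whereas a 4-mm erosion disconnects them and the
      selected GTV excludes the wall.
    * ``diaphragm`` — a dome of tumor-equal HU rising from the cavity
      floor near the moving sphere: the volume filter rejects the dome
      (it exceeds the window), so the selection excludes the
      diaphragm analog.
    * ``small_low_contrast`` — a 1.5-cm sphere at −400 HU over −800 HU
      lung: recoverable with a tighter range, a smaller radius and a
      smaller volume window.
    """
    baseline = PhantomSpec(rng_seed=rng_seed)
    cases = [
        SuiteCase(
            "baseline", baseline, _soft_tissue_config(),
            "sphere recovered, Dice ≥ 0.95, volume/COG-motion error within 5%",
        ),
        SuiteCase(
            "wall_attached",
            replace(baseline, motion=Motion(kind="none"),
                    attachment=Attachment(neck_radius_mm=3.0)),
            _soft_tissue_config(),
            "thresholding alone merges tumor and wall into one component; "
            "erosion disconnects them and the GTV excludes the wall",
        ),
        SuiteCase(
            "diaphragm",
            replace(baseline, diaphragm=Diaphragm(),
                    tumor_center_mm=(90.0, 90.0, 100.0)),
            _soft_tissue_config(),
            "the diaphragm-like dome exceeds the volume window and is not "
            "included in the selected GTV",
        ),
        SuiteCase(
            "small_low_contrast",
            replace(baseline, tumor_diameter_mm=15.0, tumor_hu=-400.0),
            _soft_tissue_config(
                tumor_range=IntensityRange(-550.0, -250.0),
                surround_range=IntensityRange(-550.0, -250.0),
                volume_min_cc=0.05, volume_max_cc=10.0, radius_mm=2.0,
            ),
            "small low-contrast sphere recovered with a tighter range, "
            "smaller radius and smaller volume window",
        ),
    ]
    return cases


def suite_case(name: str, rng_seed: int = 0) -> SuiteCase:
    for case in phantom_suite(rng_seed):
        if case.name == name:
            return case
    names = [c.name for c in phantom_suite(rng_seed)]
    raise KeyError(f"unknown phantom suite case {name!r}; choose from {names}")
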