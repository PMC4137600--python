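"""Target-motion trajectories and segmentation-overlap metrics.

The center of geometry (COG) of the segmented gross target volume (GTV)
is tracked across breathing phases as the motion trajectory; overlap
between a test segmentation and ground truth is summarized with the Dice
similarity coefficient, sensitivity (fraction of ground-truth voxels the
test segmentation captured) and positive predictive value (fraction of
test voxels that are true positives).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, MPSLError

__all__ = [
    "TrajectoryEntry",
    "Trajectory",
    "OverlapMetrics",
    "mask_cog",
    "compute_trajectory",
    "overlap_metrics",
    "metrics_table",
    "trajectory_error",
    "max_errors",
]


@dataclass(frozen=True)
class TrajectoryEntry:
    phase_label: int
    cog_mm: Tuple[float, float, float]
    volume_cc: float


@dataclass
class Trajectory:
    """Per-phase COG positions (mm) and volumes (cc) of the segmented GTV."""

    entries: List[TrajectoryEntry]

    def __post_init__(self):
        if not self.entries:
            raise ConfigurationError("trajectory must be non-empty")
        labels = [e.phase_label for e in self.entries]
        if any(b <= a for a, b in zip(labels, labels[1:])):
            raise ConfigurationError(
                f"phase labels must be strictly increasing, got {labels}"
            )
        if any(e.volume_cc < 0 for e in self.entries):
            raise ConfigurationError("volumes must be non-negative")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def phase_labels(self) -> List[int]:
        return [e.phase_label for e in self.entries]

    def cogs(self) -> np.ndarray:
        return np.array([e.cog_mm for e in self.entries], dtype=float)

    def volumes(self) -> np.ndarray:
        return np.array([e.volume_cc for e in self.entries], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        cog = self.cogs()
        return pd.DataFrame({
            "phase": self.phase_labels,
            "cog_x_mm": cog[:, 0],
            "cog_y_mm": cog[:, 1],
            "cog_z_mm": cog[:, 2],
            "volume_cc": self.volumes(),
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Trajectory":
        entries = [
            TrajectoryEntry(int(row["phase"]),
                            (float(row["cog_x_mm"]), float(row["cog_y_mm"]),
                             float(row["cog_z_mm"])),
                            float(row["volume_cc"]))
            for _, row in df.iterrows()
        ]
        return cls(entries)


def mask_cog(mask) -> Tuple[float, ...]:
    """Mean physical position (mm) of a mask's foreground voxels."""
    arr = np.asarray(mask.voxels, dtype=bool)
    if not arr.any():
        raise MPSLError("cannot compute COG of an empty mask")
    idx = np.nonzero(arr)
    return tuple(float(o + s * np.mean(c))
                 for o, s, c in zip(mask.origin, mask.spacing, idx))


def compute_trajectory(results: Sequence, phases: Sequence[int]) -> Trajectory:
    """Trajectory of COG and volume from per-phase segmentation results.

    ``results`` holds objects with a ``gtv_mask`` attribute (one per
    phase); an empty mask raises an error naming the offending phase.
    """
    if len(results) != len(phases):
        raise ConfigurationError(
            f"{len(results)} results for {len(phases)} phase labels"
        )
    entries = []
    for res, ph in zip(results, phases):
        mask = res.gtv_mask if hasattr(res, "gtv_mask") else res
        arr = np.asarray(mask.voxels, dtype=bool)
        if not arr.any():
            raise MPSLError(f"empty GTV mask at phase {ph}")
        entries.append(TrajectoryEntry(int(ph), mask_cog(mask),
                                       float(mask.volume_cc)))
    return Trajectory(entries)


@dataclass(frozen=True)
class OverlapMetrics:
    """Dice / sensitivity / PPV plus the raw voxel counts they derive from."""

    dice: float
    sensitivity: float
    ppv: float
    n_truth: int
    n_test: int
    n_intersect: int

    @classmethod
    def from_counts(cls, n_truth: int, n_test: int, n_intersect: int) -> "OverlapMetrics":
        if n_truth == 0 and n_test == 0:
            # perfect agreement on absence
            return cls(1.0, 1.0, 1.0, 0, 0, 0)
        if n_truth == 0 or n_test == 0:
            return cls(0.0, 0.0, 0.0, n_truth, n_test, n_intersect)
        return cls(
            dice=2.0 * n_intersect / (n_truth + n_test),
            sensitivity=n_intersect / n_truth,
            ppv=n_intersect / n_test,
            n_truth=n_truth, n_test=n_test, n_intersect=n_intersect,
        )


def _check_same_grid(truth, test):
    if np.asarray(truth.voxels).shape != np.asarray(test.voxels).shape:
        raise ConfigurationError(
            f"grid mismatch: {np.asarray(truth.voxels).shape} vs "
            f"{np.asarray(test.voxels).shape}"
        )
    if not np.allclose(truth.spacing, test.spacing) or \
            not np.allclose(truth.origin, test.origin):
        raise ConfigurationError("masks are on different physical grids")


def overlap_metrics(truth, test) -> OverlapMetrics:
    """Dice, sensitivity and PPV of ``test`` against ``truth`` (same grid).

    Conventions: both masks empty → all three metrics are 1 (agreement on
    absence); exactly one empty → all three are 0.
    """
    _check_same_grid(truth, test)
    a = np.asarray(truth.voxels, dtype=bool)
    b = np.asarray(test.voxels, dtype=bool)
    return OverlapMetrics.from_counts(
        int(a.sum()), int(b.sum()), int((a & b).sum())
    )


def metrics_table(pairs: Sequence[Tuple[str, object, object]]) -> pd.DataFrame:
    """Per-case overlap metrics plus trailing average and st.dev. rows.

    The standard deviation is the sample SD (n−1 denominator).  With a
    single case the SD row is reported as 0 and the frame carries
    ``attrs["sd_defined"] = False``.
    """
    if not pairs:
        raise ConfigurationError("metrics_table needs at least one pair")
    rows = []
    for case_id, truth, test in pairs:
        m = overlap_metrics(truth, test)
        rows.append({"case_id": str(case_id), "dice": m.dice,
                     "sensitivity": m.sensitivity, "ppv": m.ppv})
    df = pd.DataFrame(rows, columns=["case_id", "dice", "sensitivity", "ppv"])
    vals = df[["dice", "sensitivity", "ppv"]].to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    if len(rows) > 1:
        sd = vals.std(axis=0, ddof=1)
        sd_defined = True
    else:
        sd = np.zeros(3)
        sd_defined = False
    out = pd.concat([
        df,
        pd.DataFrame([{"case_id": "average", "dice": mean[0],
                       "sensitivity": mean[1], "ppv": mean[2]},
                      {"case_id": "st_dev", "dice": sd[0],
                       "sensitivity": sd[1], "ppv": sd[2]}]),
    ], ignore_index=True)
    out.attrs["sd_defined"] = sd_defined
    return out


def trajectory_error(
    est: Trajectory,
    truth: Trajectory,
    eps_mm: float = 1e-9,
) -> pd.DataFrame:
    """Per-phase volume and COG-motion errors of ``est`` against ``truth``.

    Columns per phase:

    * ``volume_rel_err`` — |v_est − v_true| / v_true
    * ``cog_abs_err_mm`` — ‖COG_est − COG_true‖
    * ``disp_rel_err``   — ‖d_est − d_true‖ / max(‖d_true‖, eps_mm), where
      d is the COG displacement from the phase-0 COG (the motion profile)
    * ``disp_below_eps`` — flag: true displacement below eps_mm, so the
      relative number is effectively an absolute error in units of eps_mm

    ``eps_mm`` should typically be one voxel diagonal of the grid the
    masks live on.
    """
    if est.phase_labels != truth.phase_labels:
        raise ConfigurationError(
            f"phase labels differ: {est.phase_labels} vs {truth.phase_labels}"
        )
    if eps_mm <= 0:
        raise ConfigurationError("eps_mm must be positive")
    ce, ct = est.cogs(), truth.cogs()
    ve, vt = est.volumes(), truth.volumes()
    de = ce - ce[0]
    dt = ct - ct[0]
    dt_norm = np.linalg.norm(dt, axis=1)
    rows = pd.DataFrame({
        "phase": est.phase_labels,
        "volume_rel_err": np.abs(ve - vt) / vt,
        "cog_abs_err_mm": np.linalg.norm(ce - ct, axis=1),
        "disp_rel_err": np.linalg.norm(de - dt, axis=1) / np.maximum(dt_norm, eps_mm),
        "disp_below_eps": dt_norm < eps_mm,
    })
    return rows


def max_errors(err: pd.DataFrame) -> Tuple[float, float]:
    """Max-over-phase (relative volume error, relative displacement error)."""
    return float(err["volume_rel_err"].max()), float(err["disp_rel_err"].max())
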