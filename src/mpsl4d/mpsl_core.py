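"""Contour-free GTV segmentation by morphological processing and
successive localization.

The per-phase pipeline:

1. **Dual-range intensity mask** — a voxel is foreground iff its HU lies
   in the tumor range *or* the surrounding-tissue range (closed
   intervals).  Two ranges are used because tumor and surrounding-tissue
   intensities generally overlap, so a single threshold cannot isolate
   the tumor.
2. **Erosion** with a structuring element built from a physical radius,
   disconnecting the tumor from attached structures (chest wall,
   diaphragm) whose connecting necks are thinner than the radius.
3. **Union-find labeling** of the disjoint regions plus per-region
   volume/centroid statistics.
4. **Volume filter** — regions whose (post-erosion) volume falls outside
   a plausible tumor-volume window are discarded.
5. **Selection** of one survivor (seed containment, localization box, or
   the default largest-volume rule).
6. **Dilation** of the selected region by the *same* element, reversing
   the erosion to restore the tumor to its approximate original size.
7. **Intersection** with the stage-1 mask, so dilation never annexes
   voxels outside the thresholded tissue; the connected component
   containing the selected region is kept so the result is a single
   component.

Across phases, *successive localization* restricts candidate selection
in each phase to regions whose centroid falls inside the previous
phase's GTV bounding box expanded by a margin, so the target is tracked
through the breathing cycle without re-seeding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import ConfigurationError, NoTargetFoundError
from .labeling import (CONNECTIVITIES, RegionTable, label_regions,
                       region_statistics)
from .morphology import dilate, erode, make_structuring_element
from .volume_io import BinaryMask, PhaseVolume, Series4D

__all__ = [
    "IntensityRange",
    "MPSLConfig",
    "SegmentationResult",
    "build_mask",
    "segment_phase",
    "segment_phase_with_seed",
    "segment_series",
    "threshold_baseline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntensityRange:
    """Closed HU interval [lo, hi]."""

    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise ConfigurationError(
                f"intensity range lower bound {self.lo} exceeds upper {self.hi}"
            )

    def contains(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.lo) & (values <= self.hi)


@dataclass(frozen=True)
class MPSLConfig:
    """All tunable inputs of the segmentation pipeline.

    Parameters
    ----------
    tumor_range, surround_range
        HU intervals for the tumor and for surrounding tissue whose
        intensities overlap the tumor's; the stage-1 mask is their union.
    volume_min_cc, volume_max_cc
        Plausible tumor-volume window applied to post-erosion region
        volumes.
    radius_mm
        Erosion/dilation radius in mm (same element for both).
    element_shape
        ``ball`` (anisotropy-aware ellipsoid in voxels) or ``box``.
    mode
        ``3d`` (default) or ``2d`` (pipeline applied per slice, then
        stacked; the volume window is then a per-slice slab volume).
    connectivity
        Labeling connectivity; face-only by default (maximizes the
        disconnecting power of erosion).
    seed_point
        Optional (i, j, k) voxel index inside the tumor; enables the
        click-seeded mode.
    seed_neighborhood_halfwidth
        Half-width (voxels) of the cube around the seed whose HU min/max
        replace the tumor range in seeded mode.
    localization_margin_mm
        Expansion of the previous phase's GTV bounding box used by
        successive localization (and the seed-to-region distance limit).
    """

    tumor_range: IntensityRange
    surround_range: IntensityRange
    volume_min_cc: float
    volume_max_cc: float
    radius_mm: float
    element_shape: str = "ball"
    mode: str = "3d"
    connectivity: str = "face"
    seed_point: Optional[Tuple[int, int, int]] = None
    seed_neighborhood_halfwidth: int = 2
    localization_margin_mm: float = 15.0

    def __post_init__(self):
        if not (0 <= self.volume_min_cc < self.volume_max_cc):
            raise ConfigurationError(
                f"need 0 ≤ volume_min_cc < volume_max_cc, got "
                f"[{self.volume_min_cc}, {self.volume_max_cc}]"
            )
        if self.radius_mm <= 0:
            raise ConfigurationError(f"radius_mm must be > 0, got {self.radius_mm}")
        if self.element_shape not in ("ball", "box"):
            raise ConfigurationError(f"element_shape: {self.element_shape!r}")
        if self.mode not in ("2d", "3d"):
            raise ConfigurationError(f"mode: {self.mode!r}")
        if self.connectivity not in CONNECTIVITIES:
            raise ConfigurationError(f"connectivity: {self.connectivity!r}")
        if self.seed_point is not None:
            object.__setattr__(self, "seed_point",
                               tuple(int(v) for v in self.seed_point))
            if self.seed_neighborhood_halfwidth < 1:
                raise ConfigurationError(
                    "seed_neighborhood_halfwidth must be ≥ 1 when a seed is given"
                )
        if self.localization_margin_mm < 0:
            raise ConfigurationError("localization_margin_mm must be ≥ 0")

    def to_dict(self) -> Dict:
        return {
            "tumor_range": [self.tumor_range.lo, self.tumor_range.hi],
            "surround_range": [self.surround_range.lo, self.surround_range.hi],
            "volume_min_cc": self.volume_min_cc,
            "volume_max_cc": self.volume_max_cc,
            "radius_mm": self.radius_mm,
            "element_shape": self.element_shape,
            "mode": self.mode,
            "connectivity": self.connectivity,
            "seed_point": list(self.seed_point) if self.seed_point else None,
            "seed_neighborhood_halfwidth": self.seed_neighborhood_halfwidth,
            "localization_margin_mm": self.localization_margin_mm,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "MPSLConfig":
        d = dict(d)
        for key in ("tumor_range", "surround_range"):
            if key in d and not isinstance(d[key], IntensityRange):
                lo, hi = d[key]
                d[key] = IntensityRange(float(lo), float(hi))
        if d.get("seed_point") is not None:
            d["seed_point"] = tuple(int(v) for v in d["seed_point"])
        return cls(**d)


@dataclass
class SegmentationResult:
    """Output of one per-phase segmentation.

    ``diagnostics`` records per-stage voxel counts plus warnings and the
    successive-localization fallback flag; ``candidate_table`` is the
    post-erosion region table (all labeled regions, with statistics), so
    callers can see everything the volume filter accepted or rejected.
    """

    gtv_mask: BinaryMask
    candidate_table: RegionTable
    selected_label: Optional[int]
    diagnostics: Dict

    @property
    def volume_cc(self) -> float:
        return self.gtv_mask.volume_cc


def build_mask(vol: PhaseVolume, tumor_range: IntensityRange,
               surround_range: IntensityRange) -> BinaryMask:
    """Stage-1 dual-range intensity mask (union of two closed HU intervals)."""
    v = np.asarray(vol.voxels)
    return BinaryMask(tumor_range.contains(v) | surround_range.contains(v),
                      vol.spacing, vol.origin)


def threshold_baseline(vol: PhaseVolume, threshold: float) -> BinaryMask:
    """Single-threshold baseline: voxel foreground iff HU strictly above
    ``threshold``.  No morphology is applied; this is the initialization
    used by semi-automated contouring workflows (classically −83 HU)."""
    return BinaryMask(np.asarray(vol.voxels) > threshold, vol.spacing, vol.origin)


def _voxel_diagonal(spacing) -> float:
    return float(np.linalg.norm(spacing))


def _keep_component_containing(gtv: np.ndarray, region: np.ndarray,
                               spacing, origin, connectivity: str) -> np.ndarray:
    """Restrict ``gtv`` to its connected component containing ``region``.

    ``region ⊆ gtv`` and region is connected, so exactly one component
    qualifies.
    """
    rt = label_regions(gtv, connectivity)
    if rt.n_regions <= 1:
        return gtv
    seed_labels = np.unique(rt.label_map[region])
    seed_labels = seed_labels[seed_labels > 0]
    keep = int(seed_labels[0])
    return rt.label_map == keep


def _select_candidate(candidates, cfg, vol, seed_point=None, restrict_box=None,
                      diagnostics=None):
    """Apply seed / localization-box / largest-volume selection rules.

    Returns the chosen Region.  Raises NoTargetFoundError when nothing
    qualifies (the caller attaches the candidate table).
    """
    pool = list(candidates)
    diag = diagnostics if diagnostics is not None else {}

    if restrict_box is not None:
        lo, hi = restrict_box
        inside = [r for r in pool
                  if all(lo[ax] <= r.centroid_mm[ax] <= hi[ax] for ax in range(3))]
        if inside:
            pool = inside
        else:
            diag["localization_fallback"] = True
            logger.warning("no candidate inside the localization box; "
                           "falling back to unrestricted selection")

    if seed_point is not None:
        seed_mm = np.array([o + s * i for o, s, i
                            in zip(vol.origin, vol.spacing, seed_point)])
        containing = [r for r in pool
                      if all(r.bounding_box[ax][0] <= seed_point[ax] <= r.bounding_box[ax][1]
                             for ax in range(3))
                      and r._contains_seed]
        if containing:
            return containing[0]
        dists = [(float(np.linalg.norm(np.array(r.centroid_mm) - seed_mm)), r)
                 for r in pool]
        dists.sort(key=lambda t: t[0])
        if dists and dists[0][0] <= cfg.localization_margin_mm:
            return dists[0][1]
        raise NoTargetFoundError(
            "no surviving region contains or lies within "
            f"{cfg.localization_margin_mm} mm of the seed"
        )

    if not pool:
        raise NoTargetFoundError("no region survived the volume filter")
    if len(pool) > 1:
        msg = ("multiple regions survive the volume filter: "
               + ", ".join(f"label {r.label} ({r.volume_cc:.2f} cc)" for r in pool)
               + "; selecting the largest")
        warnings.warn(msg, stacklevel=2)
        diag.setdefault("warnings", []).append(msg)
    return max(pool, key=lambda r: r.volume_cc)


def _segment_3d(vol, cfg, seed_point=None, restrict_box=None) -> SegmentationResult:
    mask = build_mask(vol, cfg.tumor_range, cfg.surround_range)
    se = make_structuring_element(cfg.element_shape, cfg.radius_mm,
                                  vol.spacing, "3d")
    eroded = erode(mask.voxels, se)
    rt = region_statistics(label_regions(eroded, cfg.connectivity),
                           vol.spacing, vol.origin)
    diagnostics = {
        "mask_voxels": mask.voxel_count,
        "post_erosion_voxels": int(eroded.sum()),
        "n_regions": rt.n_regions,
    }
    candidates = [r for r in rt.regions
                  if cfg.volume_min_cc <= r.volume_cc <= cfg.volume_max_cc]
    diagnostics["n_filter_survivors"] = len(candidates)
    if not candidates:
        raise NoTargetFoundError(
            f"no region survived the volume filter "
            f"[{cfg.volume_min_cc}, {cfg.volume_max_cc}] cc "
            f"({rt.n_regions} labeled regions)",
            candidate_table=rt,
        )
    # mark seed containment exactly (bounding boxes are only a prefilter)
    if seed_point is not None:
        for r in candidates:
            r._contains_seed = rt.label_map[tuple(seed_point)] == r.label
    try:
        selected = _select_candidate(candidates, cfg, vol, seed_point,
                                     restrict_box, diagnostics)
    except NoTargetFoundError as exc:
        exc.candidate_table = rt
        raise
    finally:
        if seed_point is not None:
            for r in candidates:
                if hasattr(r, "_contains_seed"):
                    del r._contains_seed

    region = rt.label_map == selected.label
    dilated = dilate(region, se)
    diagnostics["post_dilation_voxels"] = int(dilated.sum())
    gtv = dilated & mask.voxels
    gtv = _keep_component_containing(gtv, region, vol.spacing, vol.origin,
                                     cfg.connectivity)
    diagnostics["gtv_voxels"] = int(gtv.sum())
    logger.info("segment_phase: %s", diagnostics)
    return SegmentationResult(
        gtv_mask=BinaryMask(gtv, vol.spacing, vol.origin),
        candidate_table=rt,
        selected_label=selected.label,
        diagnostics=diagnostics,
    )


def _segment_2d(vol, cfg, seed_point=None, restrict_box=None) -> SegmentationResult:
    """2-D mode: the whole pipeline per axial slice, results stacked.

    The volume window is interpreted per slice as a slab volume
    (pixel count · dx·dy·dz / 1000, i.e. area × slice thickness).
    Slices with no filter survivor contribute empty planes; only an
    all-empty stack is a failure.
    """
    dx, dy, dz = vol.spacing
    mask = build_mask(vol, cfg.tumor_range, cfg.surround_range)
    se = make_structuring_element(cfg.element_shape, cfg.radius_mm,
                                  vol.spacing, "2d")
    nx, ny, nz = vol.shape
    out = np.zeros(vol.shape, dtype=bool)
    eroded3d = np.zeros(vol.shape, dtype=bool)
    slab_cc = dx * dy * dz / 1000.0
    xy_box = None
    if restrict_box is not None:
        lo, hi = restrict_box
        xy_box = ((lo[0], lo[1]), (hi[0], hi[1]))
        z_lo, z_hi = lo[2], hi[2]
    n_selected = 0
    for k in range(nz):
        plane = mask.voxels[:, :, k]
        if restrict_box is not None:
            zk = vol.origin[2] + dz * k
            if not (z_lo <= zk <= z_hi):
                continue
        er = erode(plane, se)
        eroded3d[:, :, k] = er
        rt = region_statistics(label_regions(er, cfg.connectivity),
                               (dx, dy), vol.origin[:2])
        cand = [r for r in rt.regions
                if cfg.volume_min_cc <= r.voxel_count * slab_cc <= cfg.volume_max_cc]
        if xy_box is not None:
            inside = [r for r in cand
                      if xy_box[0][0] <= r.centroid_mm[0] <= xy_box[1][0]
                      and xy_box[0][1] <= r.centroid_mm[1] <= xy_box[1][1]]
            if inside:
                cand = inside
        if seed_point is not None and seed_point[2] == k:
            lab = rt.label_map[seed_point[0], seed_point[1]]
            cand = [r for r in cand if r.label == lab] or cand
        if not cand:
            continue
        sel = max(cand, key=lambda r: r.voxel_count)
        region = rt.label_map == sel.label
        out[:, :, k] = dilate(region, se) & plane
        n_selected += 1
    if n_selected == 0:
        rt3 = region_statistics(label_regions(eroded3d, cfg.connectivity),
                                vol.spacing, vol.origin)
        raise NoTargetFoundError("no slice produced a filter survivor (2d mode)",
                                 candidate_table=rt3)
    rt3 = region_statistics(label_regions(eroded3d, cfg.connectivity),
                            vol.spacing, vol.origin)
    diagnostics = {
        "mask_voxels": mask.voxel_count,
        "post_erosion_voxels": int(eroded3d.sum()),
        "n_regions": rt3.n_regions,
        "slices_with_target": n_selected,
        "gtv_voxels": int(out.sum()),
        "mode": "2d",
    }
    return SegmentationResult(BinaryMask(out, vol.spacing, vol.origin),
                              rt3, None, diagnostics)


def segment_phase(vol: PhaseVolume, cfg: MPSLConfig,
                  _restrict_box=None) -> SegmentationResult:
    """Run the full morphological pipeline on a single phase volume.

    Raises :class:`NoTargetFoundError` (carrying the candidate table)
    when no labeled region survives the volume filter.
    """
    if cfg.mode == "2d":
        return _segment_2d(vol, cfg, restrict_box=_restrict_box)
    return _segment_3d(vol, cfg, restrict_box=_restrict_box)


def segment_phase_with_seed(vol: PhaseVolume, cfg: MPSLConfig,
                            _restrict_box=None) -> SegmentationResult:
    """Click-seeded segmentation: the tumor HU range is replaced by the
    [min, max] of intensities in the cubic neighborhood around the seed,
    and among volume-filter survivors the region containing the seed (or
    nearest to it within ``localization_margin_mm``) is selected."""
    if cfg.seed_point is None:
        raise ConfigurationError("segment_phase_with_seed needs cfg.seed_point")
    seed = cfg.seed_point
    if any(not (0 <= seed[ax] < vol.shape[ax]) for ax in range(3)):
        raise ConfigurationError(
            f"seed point {seed} outside volume of shape {vol.shape}"
        )
    h = cfg.seed_neighborhood_halfwidth
    sl = tuple(slice(max(0, seed[ax] - h), min(vol.shape[ax], seed[ax] + h + 1))
               for ax in range(3))
    neigh = np.asarray(vol.voxels)[sl]
    derived = IntensityRange(float(neigh.min()), float(neigh.max()))
    logger.info("seed neighborhood HU range: [%.1f, %.1f]", derived.lo, derived.hi)
    seeded_cfg = replace(cfg, tumor_range=derived)
    if cfg.mode == "2d":
        return _segment_2d(vol, seeded_cfg, seed_point=seed,
                           restrict_box=_restrict_box)
    return _segment_3d(vol, seeded_cfg, seed_point=seed,
                       restrict_box=_restrict_box)


def _expanded_bbox(mask: BinaryMask, margin_mm: float):
    """Physical-coordinate bounding box of a mask, expanded per axis."""
    idx = np.nonzero(mask.voxels)
    lo = [mask.origin[ax] + mask.spacing[ax] * idx[ax].min() - margin_mm
          for ax in range(3)]
    hi = [mask.origin[ax] + mask.spacing[ax] * idx[ax].max() + margin_mm
          for ax in range(3)]
    return lo, hi


def segment_series(series: Series4D, cfg: MPSLConfig) -> List[SegmentationResult]:
    """Segment all phases with successive localization.

    Phase 0 is segmented unrestricted (seeded if a seed is configured);
    each subsequent phase restricts candidate selection to regions whose
    centroid lies inside the previous phase's GTV bounding box expanded
    by ``localization_margin_mm``.  If nothing lies inside the box the
    phase falls back to unrestricted selection and sets the
    ``localization_fallback`` diagnostic flag.  Failures propagate with
    the phase label attached.
    """
    results: List[SegmentationResult] = []
    box = None
    for vol in series.phases:
        try:
            if box is None:
                if cfg.seed_point is not None:
                    res = segment_phase_with_seed(vol, cfg)
                else:
                    res = segment_phase(vol, cfg)
            else:
                res = segment_phase(vol, cfg, _restrict_box=box)
        except NoTargetFoundError as exc:
            exc.phase_label = vol.phase_label
            raise NoTargetFoundError(
                f"phase {vol.phase_label}: {exc}",
                candidate_table=exc.candidate_table,
                phase_label=vol.phase_label,
            ) from exc
        results.append(res)
        box = _expanded_bbox(res.gtv_mask, cfg.localization_margin_mm)
    return results
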