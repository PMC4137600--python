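"""Set-theoretic binary morphology on voxel grids.

Dilation and erosion of a voxel set ``A`` by a structuring element ``B``
(a finite set of integer offsets) follow the classical Minkowski
definitions:

* dilation:  ``c`` is foreground iff ``c = a + b`` for some foreground
  ``a`` in ``A`` and some offset ``b`` in ``B``;
* erosion:   ``x`` is foreground iff ``x + b`` is foreground in ``A`` for
  *every* offset ``b`` in ``B``.

Boundary convention: the grid is never grown.  Dilation results falling
outside the array are discarded; for erosion, positions outside the array
count as background, so erosion can only shrink the set.  With the origin
contained in ``B`` this gives ``erode(A, B) ⊆ A ⊆ dilate(A, B)``.

Structuring elements are built either from a physical radius in mm (so a
configuration is independent of voxel spacing — important with 2.5 mm CT
slices versus ~1 mm in-plane pixels) or from explicit offset lists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "StructuringElement",
    "make_structuring_element",
    "dilate",
    "erode",
]


@dataclass(frozen=True)
class StructuringElement:
    """A finite set of integer offsets defining a morphological neighborhood.

    Parameters
    ----------
    offsets
        Integer array of shape ``(m, ndim)``.  Must be non-empty and must
        contain the origin so that erosion is anti-extensive and dilation
        extensive.
    description
        Human-readable provenance, e.g. ``"ball(r_vox=(3, 3, 2))"``.
    """

    offsets: np.ndarray
    description: str = "explicit"

    def __post_init__(self):
        off = np.atleast_2d(np.asarray(self.offsets, dtype=np.int64))
        if off.size == 0:
            raise ConfigurationError("structuring element must be non-empty")
        if off.ndim != 2:
            raise ConfigurationError("offsets must be a (m, ndim) array")
        if not (off == 0).all(axis=1).any():
            raise ConfigurationError(
                "structuring element must contain the origin "
                "(required for erode(A,B) ⊆ A ⊆ dilate(A,B))"
            )
        # de-duplicate, deterministic order
        off = np.unique(off, axis=0)
        object.__setattr__(self, "offsets", off)

    @property
    def ndim(self) -> int:
        return int(self.offsets.shape[1])

    def __len__(self) -> int:
        return int(self.offsets.shape[0])

    def reflect(self) -> "StructuringElement":
        """The reflected element −B (used by the erosion/dilation duality)."""
        return StructuringElement(-self.offsets, f"reflect({self.description})")

    @classmethod
    def from_offsets(cls, offsets: Iterable[Sequence[int]]) -> "StructuringElement":
        return cls(np.asarray(list(offsets), dtype=np.int64), "explicit")

    @classmethod
    def box(cls, halfwidths: Sequence[int]) -> "StructuringElement":
        """All offsets with |o_axis| ≤ halfwidth_axis (a filled box)."""
        hw = [int(h) for h in halfwidths]
        if any(h < 0 for h in hw):
            raise ConfigurationError("box halfwidths must be non-negative")
        grids = np.meshgrid(*[np.arange(-h, h + 1) for h in hw], indexing="ij")
        off = np.stack([g.ravel() for g in grids], axis=1)
        return cls(off, f"box(halfwidths={tuple(hw)})")

    @classmethod
    def ball(cls, radii_vox: Sequence[int]) -> "StructuringElement":
        """Ellipsoidal ball: offsets with Σ (o_axis / r_axis)² ≤ 1.

        Axes with radius 0 contribute only the zero offset (the ellipsoid
        degenerates to a lower-dimensional disc on that axis).
        """
        r = [int(x) for x in radii_vox]
        if any(x < 0 for x in r):
            raise ConfigurationError("ball radii must be non-negative")
        grids = np.meshgrid(*[np.arange(-x, x + 1) for x in r], indexing="ij")
        q = np.zeros(grids[0].shape, dtype=float)
        for g, rad in zip(grids, r):
            if rad > 0:
                q += (g / rad) ** 2
            # rad == 0: only o = 0 exists on that axis, contributes 0
        keep = q <= 1.0 + 1e-12
        off = np.stack([g[keep] for g in grids], axis=1)
        return cls(off, f"ball(r_vox={tuple(r)})")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def make_structuring_element(
    shape: str,
    radius_mm: float,
    spacing: Sequence[float],
    mode: str = "3d",
) -> StructuringElement:
    """Build a structuring element from a physical radius.

    The per-axis voxel radius is ``round(radius_mm / spacing_axis)``
    (round-half-up), so one radius in mm yields an anisotropy-aware
    element.  In ``2d`` mode only the first two spacing components are
    used and a 2-D element is returned.

    A radius so small that every per-axis radius rounds to zero degrades
    to the single-offset ``{origin}`` element with a warning.
    """
    if radius_mm <= 0:
        raise ConfigurationError(f"radius_mm must be > 0, got {radius_mm}")
    spacing = [float(s) for s in spacing]
    if any(s <= 0 for s in spacing):
        raise ConfigurationError(f"spacing must be positive, got {spacing}")
    if mode == "2d":
        spacing = spacing[:2]
    elif mode != "3d":
        raise ConfigurationError(f"mode must be '2d' or '3d', got {mode!r}")
    radii = [_round_half_up(radius_mm / s) for s in spacing]
    if all(r == 0 for r in radii):
        warnings.warn(
            f"radius {radius_mm} mm rounds to zero voxels on every axis for "
            f"spacing {tuple(spacing)}; returning the degenerate {{origin}} element",
            stacklevel=2,
        )
        return StructuringElement(np.zeros((1, len(spacing)), dtype=np.int64),
                                  "degenerate{origin}")
    if shape == "ball":
        return StructuringElement.ball(radii)
    if shape == "box":
        return StructuringElement.box(radii)
    raise ConfigurationError(f"shape must be 'ball' or 'box', got {shape!r}")


def _translate(a: np.ndarray, t: Sequence[int]) -> np.ndarray:
    """Return array with result[x] = a[x - t], background-filled at borders."""
    out = np.zeros_like(a)
    src = []
    dst = []
    for n, o in zip(a.shape, t):
        o = int(o)
        if abs(o) >= n:
            return out
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _as_bool_array(a) -> np.ndarray:
    arr = a.voxels if hasattr(a, "voxels") else a
    return np.asarray(arr, dtype=bool)


def _wrap_like(template, voxels: np.ndarray):
    if hasattr(template, "voxels"):
        return template.replace_voxels(voxels)
    return voxels


def _check_dims(a: np.ndarray, B: StructuringElement):
    if a.ndim != B.ndim:
        raise ConfigurationError(
            f"array is {a.ndim}-D but structuring element is {B.ndim}-D"
        )


def dilate(A, B: StructuringElement):
    """Minkowski dilation A ⊕ B, clipped to the array bounds.

    ``A`` may be a boolean array or a :class:`~mpsl4d.volume_io.BinaryMask`;
    the return type matches the input.
    """
    a = _as_bool_array(A)
    _check_dims(a, B)
    out = np.zeros_like(a)
    for b in B.offsets:
        out |= _translate(a, b)
    return _wrap_like(A, out)


def erode(A, B: StructuringElement):
    """Minkowski erosion A ⊖ B; positions outside the array are background."""
    a = _as_bool_array(A)
    _check_dims(a, B)
    out = np.ones_like(a)
    for b in B.offsets:
        # x is kept iff a[x + b] is foreground, i.e. translate a by -b
        out &= _translate(a, -b)
    return _wrap_like(A, out)
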