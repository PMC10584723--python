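"""Geometry of the circular morph continuum.

The stimulus space is a closed wheel of face images obtained by morphing
between three anchor identities. Positions are integer "morph steps" on the
wheel; with the default 46 morphs between each pair of anchors the wheel has
3 + 3*46 = 141 positions. Each anchor is the prototype of one category whose
extent is ``boundary_halfwidth`` steps to either side; with a halfwidth of 23
the three categories tile the 141-position wheel exactly (3 * 47 = 141).

Indexing is 0-based internally; the three anchor faces conventionally
labelled 1/2/3 sit at indices 0, 47 and 94. "Clockwise" is defined as
increasing index with wraparound and carries the positive sign. The pictorial
rotation direction is arbitrary; every statistic downstream is symmetric
under reflecting the wheel, so only consistency matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MorphWheel", "build_wheel", "signed_distance", "category_of"]


@dataclass(frozen=True)
class MorphWheel:
    """Circular stimulus space with three equally spaced prototype anchors.

    Attributes
    ----------
    n_positions
        Total number of images on the wheel.
    anchor_positions
        0-based wheel indices of the three original (anchor) faces.
    boundary_halfwidth
        Category extent in morph steps to either side of each anchor.
    partitions
        True when the three categories tile the wheel with no gap or overlap.
    """

    n_positions: int
    anchor_positions: tuple[int, int, int]
    boundary_halfwidth: int
    partitions: bool = True

    @property
    def half_range(self) -> int:
        """Largest attainable |signed distance| (70 on the 141 wheel)."""
        return self.n_positions // 2


def build_wheel(
    n_between: int = 46,
    boundary_halfwidth: int = 23,
    *,
    allow_nonpartition: bool = False,
) -> MorphWheel:
    """Construct the morph wheel for ``n_between`` morphs per anchor pair.

    Parameters
    ----------
    n_between
        Number of morphed images between each pair of anchors; the wheel has
        ``3 + 3 * n_between`` positions. Default 46 (the 141-image wheel).
    boundary_halfwidth
        Category halfwidth in morph steps. Default 23, which makes the three
        categories an exact partition of the 141 wheel.
    allow_nonpartition
        Accept a halfwidth whose categories do not tile the wheel exactly.
        Off by default because the classification-error index assumes the
        partition.
    """
    if n_between < 1:
        raise ValueError(f"n_between must be >= 1, got {n_between}")
    if boundary_halfwidth < 0:
        raise ValueError(f"boundary_halfwidth must be >= 0, got {boundary_halfwidth}")
    n_positions = 3 + 3 * n_between
    spacing = n_between + 1
    partitions = 3 * (2 * boundary_halfwidth + 1) == n_positions
    if not partitions and not allow_nonpartition:
        raise ValueError(
            f"categories of halfwidth {boundary_halfwidth} do not partition a "
            f"{n_positions}-position wheel; pass allow_nonpartition=True to override"
        )
    return MorphWheel(
        n_positions=n_positions,
        anchor_positions=(0, spacing, 2 * spacing),
        boundary_halfwidth=boundary_halfwidth,
        partitions=partitions,
    )


def _check_pos(pos, n: int) -> None:
    p = np.asarray(pos)
    if np.any((p < 0) | (p >= n)):
        raise ValueError(f"wheel index out of range [0, {n}): {pos!r}")


def signed_distance(from_pos, to_pos, wheel: MorphWheel):
    """Signed shortest circular distance in morph steps.

    Clockwise (increasing index, with wraparound) is positive. The result
    lies in ``(-n/2, +n/2]``; on the odd 141-position wheel this is
    ``[-70, +70]`` and the shortest path is always unique. Accepts scalars or
    arrays and broadcasts.
    """
    n = wheel.n_positions
    _check_pos(from_pos, n)
    _check_pos(to_pos, n)
    raw = (np.asarray(to_pos) - np.asarray(from_pos)) % n
    # map [0, n) -> (-n/2, n/2]: distances strictly greater than n/2 wrap negative
    signed = np.where(raw * 2 > n, raw - n, raw)
    if np.isscalar(from_pos) and np.isscalar(to_pos):
        return int(signed)
    return signed.astype(int)


def category_of(pos, wheel: MorphWheel):
    """Category id (1, 2 or 3) of a wheel position.

    A position belongs to the category whose anchor lies within
    ``boundary_halfwidth`` steps of it on the circle. Requires a partitioning
    wheel. Accepts scalars or arrays.
    """
    if not wheel.partitions:
        raise ValueError("category_of requires a partitioning wheel")
    n = wheel.n_positions
    _check_pos(pos, n)
    p = np.asarray(pos)
    # distance from anchor 0, folded onto the circle; categories are
    # contiguous arcs of width (2*halfwidth + 1) centred on each anchor
    width = 2 * wheel.boundary_halfwidth + 1
    shifted = (p + wheel.boundary_halfwidth) % n
    cat = shifted // width + 1
    if np.isscalar(pos):
        return int(cat)
    return cat.astype(int)
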