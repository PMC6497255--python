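"""Skeleton analysis: crossing numbers, junction counts, branch tracing.

The vessel map is reduced to a 1-pixel-wide, topology-preserving skeleton.
Each skeleton pixel is classified by its *crossing number* (CN): half the
number of 0/1 transitions met when walking the 8-neighbourhood in cyclic
order.  CN = 1 marks a terminal point, CN = 2 a ridge (branch interior),
CN = 3 a bifurcation, and CN >= 4 a crossing.  Junction pixels that touch
(a thinning artifact at thick forks) merge into one counted junction.

Branches are the maximal skeleton paths between junction/terminal pixels,
returned as ordered point sequences suitable for tortuosity measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "Skeleton",
    "JunctionSummary",
    "Branch",
    "skeletonize",
    "crossing_number",
    "crossing_number_map",
    "count_junctions",
    "extract_branches",
]

# 8-neighbour offsets in cyclic (clockwise) order starting at north.
_CYCLIC_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_EIGHT_CONN = np.ones((3, 3), dtype=int)

#: Branches shorter than this many skeleton pixels are excluded from
#: tortuosity (finite-difference curvature needs ~5 samples) but still
#: count for caliber and junction purposes.
MIN_TORTUOSITY_LENGTH = 5


@dataclass
class Skeleton:
    """A 1-px-wide centerline as a boolean grid."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass
class JunctionSummary:
    """Junction counts: j1 terminals, j2 bifurcations, j3 crossings."""

    j1: int
    j2: int
    j3: int


@dataclass
class Branch:
    """An ordered run of 8-adjacent skeleton pixels between two anchors.

    ``points`` is an (n, 2) float array of (row, col) coordinates running
    from one end (terminal or junction) to the other.  ``closed`` flags
    cycles whose endpoints coincide.
    """

    points: np.ndarray
    closed: bool = False
    mean_caliber: float = float("nan")
    branch_id: int = -1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)

    def __len__(self) -> int:
        return len(self.points)


def skeletonize(mask: np.ndarray) -> Skeleton:
    """Topology-preserving medial-axis thinning of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    return Skeleton(pixels=_sk_skeletonize(mask))


def crossing_number(window: np.ndarray) -> int:
    """Crossing number of the center pixel of a 3x3 binary neighbourhood.

    CN = 1/2 * sum over the cyclic 8-neighbour sequence of |p_i - p_{i+1}|
    (with p_9 = p_1).  The center pixel must be foreground.
    """
    win = np.asarray(window).astype(bool).astype(int)
    if win.shape != (3, 3):
        raise ValueError(f"expected a 3x3 window, got {win.shape}")
    if not win[1, 1]:
        raise ValueError("crossing number is undefined for a background center pixel")
    seq = np.array([win[1 + dr, 1 + dc] for dr, dc in _CYCLIC_OFFSETS])
    return int(np.abs(np.diff(np.append(seq, seq[0]))).sum() // 2)


def crossing_number_map(skeleton: Skeleton | np.ndarray) -> np.ndarray:
    """Crossing number at every skeleton pixel (-1 on background)."""
    skel = skeleton.pixels if isinstance(skeleton, Skeleton) else np.asarray(skeleton, bool)
    padded = np.pad(skel.astype(np.int8), 1)
    h, w = skel.shape
    # Accumulate |p_i - p_{i+1}| over the cyclic neighbour sequence without
    # materializing the full 9-plane stack.
    closed = _CYCLIC_OFFSETS + [_CYCLIC_OFFSETS[0]]
    total = np.zeros((h, w), dtype=np.int8)
    for (r0, c0), (r1, c1) in zip(closed[:-1], closed[1:]):
        a = padded[1 + r0 : 1 + r0 + h, 1 + c0 : 1 + c0 + w]
        b = padded[1 + r1 : 1 + r1 + h, 1 + c1 : 1 + c1 + w]
        total += a != b
    cn = total >> 1
    return np.where(skel, cn, -1).astype(np.int8)


def count_junctions(
    skeleton: Skeleton | np.ndarray, cn: np.ndarray | None = None
) -> JunctionSummary:
    """Count terminal (j1), bifurcation (j2), and crossing (j3) points.

    Same-type junction pixels that are 8-adjacent merge into a single
    counted junction, which avoids double counting where thinning leaves
    a small cluster at a thick fork.  ``cn`` may pass in a precomputed
    crossing-number map for the same skeleton.
    """
    if cn is None:
        cn = crossing_number_map(skeleton)

    def n_clusters(mask: np.ndarray) -> int:
        _, n = ndimage.label(mask, structure=_EIGHT_CONN)
        return int(n)

    return JunctionSummary(
        j1=n_clusters(cn == 1),
        j2=n_clusters(cn == 3),
        j3=n_clusters(cn >= 4),
    )


def _chain_neighbors(
    p: tuple[int, int], on: set[tuple[int, int]]
) -> list[tuple[int, int]]:
    """8-neighbours of ``p`` within the chain pixel set ``on``."""
    r, c = p
    return [(r + dr, c + dc) for dr, dc in _CYCLIC_OFFSETS if (r + dr, c + dc) in on]


def extract_branches(
    skeleton: Skeleton | np.ndarray, cn: np.ndarray | None = None
) -> list[Branch]:
    """Trace ordered branches between junction/terminal anchors.

    Junction pixels (CN >= 3) are removed; each remaining connected chain
    becomes one branch, ordered by walking from one chain end to the other,
    and extended by one adjacent junction pixel at each end so branches stay
    anchored at the forks they meet.  A chain with no free end is a cycle
    and is flagged ``closed`` (its first point repeated at the end).
    """
    skel = skeleton.pixels if isinstance(skeleton, Skeleton) else np.asarray(skeleton, bool)
    if not skel.any():
        return []
    if cn is None:
        cn = crossing_number_map(skel)
    junction = cn >= 3
    chains = skel & ~junction
    labels, n_chains = ndimage.label(chains, structure=_EIGHT_CONN)
    if n_chains == 0:
        return []

    junction_set = set(map(tuple, np.argwhere(junction)))

    # Bucket chain pixels by label.
    by_label: list[list[tuple[int, int]]] = [[] for _ in range(n_chains + 1)]
    for r, c in zip(*np.nonzero(chains)):
        by_label[labels[r, c]].append((int(r), int(c)))

    branches: list[Branch] = []
    for lab in range(1, n_chains + 1):
        pixels = by_label[lab]
        if len(pixels) == 1:
            ordered = [pixels[0]]
            closed = False
        else:
            on = set(pixels)
            ends = [p for p in pixels if len(_chain_neighbors(p, on)) <= 1]
            closed = not ends
            start = min(ends) if ends else min(pixels)
            ordered = _walk_chain(start, on)
            if closed:
                ordered.append(ordered[0])

        if not closed:
            ordered = _attach_junction_anchors(ordered, junction_set)
        if len(ordered) < 2 and not _has_junction_anchor(ordered, junction_set):
            # an isolated single pixel: not a usable branch
            continue
        branches.append(
            Branch(points=np.asarray(ordered, dtype=float), closed=closed, branch_id=len(branches))
        )
    return branches


def _walk_chain(
    start: tuple[int, int], on: set[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Order a degree-<=2 chain by walking from ``start``."""
    ordered = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [p for p in _chain_neighbors(cur, on) if p not in seen]
        if not nxt:
            break
        # Chains are degree <= 2 so at most one unvisited neighbour, except
        # at diagonal "staircase" corners; prefer the 4-adjacent pixel there.
        cur = min(nxt, key=lambda p: abs(p[0] - ordered[-1][0]) + abs(p[1] - ordered[-1][1]))
        ordered.append(cur)
        seen.add(cur)
    return ordered


def _attach_junction_anchors(
    ordered: list[tuple[int, int]], junction_set: set[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Prepend/append one adjacent junction pixel at each open end."""

    def adjacent_junction(p: tuple[int, int], exclude: tuple[int, int] | None):
        for dr, dc in _CYCLIC_OFFSETS:
            q = (p[0] + dr, p[1] + dc)
            if q in junction_set and q != exclude:
                return q
        return None

    head = adjacent_junction(ordered[0], None)
    tail = adjacent_junction(ordered[-1], head if len(ordered) == 1 else None)
    out = list(ordered)
    if head is not None:
        out.insert(0, head)
    if tail is not None:
        out.append(tail)
    return out


def _has_junction_anchor(
    ordered: list[tuple[int, int]], junction_set: set[tuple[int, int]]
) -> bool:
    return bool(ordered) and (ordered[0] in junction_set or ordered[-1] in junction_set)
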