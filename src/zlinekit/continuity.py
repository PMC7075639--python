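"""Continuous z-line detection by orientation-aware pixel linking.

Z-lines of neighboring myofibrils that abut end-to-end (possibly shifted
laterally by one pixel) form one *continuous z-line*.  Each z-line skeleton
pixel looks at its 8 neighbors, discards the two lying perpendicular to its
own orientation ("candidate neighbors" are the remaining six), prefers the
most parallel occupied candidate on each side of itself, and links are kept
when two pixels prefer each other.  Connected chains of mutual links are the
continuous z-lines; a lateral shift of one pixel is bridged by the diagonal
neighbors, a shift of two or more never is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .angles import nematic_cos
from .types import BinarySkeleton, ContinuousLine, LineSet, OrientationField

__all__ = [
    "candidate_neighbors",
    "link_neighbors",
    "group_lines",
    "detect_lines",
    "line_lengths",
    "median_czl",
    "LinkGraph",
]

log = logging.getLogger(__name__)

Coord = tuple[int, int]

# 8 compass offsets (drow, dcol) indexed by math-frame angle k·π/4 measured
# counter-clockwise from +x (column) axis, y-up: E, NE, N, NW, W, SW, S, SE.
_COMPASS = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def _nearest_compass(angle: float) -> int:
    """Index of the compass direction nearest to a math-frame angle.

    Exact midway ties round up to the next counter-clockwise direction.
    """
    return int(np.floor(angle / (np.pi / 4.0) + 0.5)) % 8


def candidate_neighbors(pixel: Coord, theta: float,
                        shape: tuple[int, int] | None = None) -> set[Coord]:
    """The ≤ 6 neighbor pixels that could continue a z-line of direction θ.

    Of the 8 neighbors, the two lying in the compass directions nearest to
    θ + π/2 and θ − π/2 (perpendicular to the z-line, i.e. along the
    myofibril) are excluded.  With a `shape`, out-of-bounds neighbors are
    dropped as well.
    """
    if not np.isfinite(theta):
        raise ValueError("candidate_neighbors requires a valid orientation")
    excluded = {_nearest_compass(theta + np.pi / 2.0),
                _nearest_compass(theta - np.pi / 2.0)}
    r, c = pixel
    out: set[Coord] = set()
    for k, (dr, dc) in enumerate(_COMPASS):
        if k in excluded:
            continue
        q = (r + dr, c + dc)
        if shape is not None and not (0 <= q[0] < shape[0] and 0 <= q[1] < shape[1]):
            continue
        out.add(q)
    return out


@dataclass
class LinkGraph:
    """Mutual preference links between z-line skeleton pixels."""

    links: dict[tuple[Coord, Coord], float] = field(default_factory=dict)
    pixels: list[Coord] = field(default_factory=list)
    resolution: float = 6.0

    def neighbors_of(self) -> dict[Coord, list[Coord]]:
        adj: dict[Coord, list[Coord]] = {p: [] for p in self.pixels}
        for (a, b) in self.links:
            adj[a].append(b)
            adj[b].append(a)
        return adj


def _step_angle(dr: int, dc: int) -> float:
    # math frame: x = +col, y = −row
    return float(np.arctan2(-dr, dc))


def link_neighbors(skeleton: BinarySkeleton, field_: OrientationField) -> LinkGraph:
    """Per-pixel neighbor preferences, kept only when mutual.

    Candidates are split into the two half-planes along ±θ of the pixel; in
    each half the occupied candidate with the highest |cos Δθ| (most parallel
    orientation) is preferred.  Ties prefer the straighter geometric
    continuation, then the lexicographically smaller coordinate.  A link
    survives only if each pixel is among the other's preferences, which
    guarantees simple paths.
    """
    if skeleton.shape != field_.shape:
        raise ValueError("skeleton and orientation field shapes differ")
    coords = [tuple(rc) for rc in skeleton.coordinates()]
    occupied = {p for p in coords if field_.valid[p]}

    preference: dict[Coord, dict[bool, tuple] ] = {}
    for p in occupied:
        th = float(field_.theta[p])
        best: dict[bool, tuple] = {}
        for q in candidate_neighbors(p, th, skeleton.shape):
            if q not in occupied:
                continue
            dr, dc = q[0] - p[0], q[1] - p[1]
            dot = dc * np.cos(th) + (-dr) * np.sin(th)
            side = bool(dot >= 0)
            score = float(nematic_cos(th, float(field_.theta[q])))
            straightness = float(nematic_cos(_step_angle(dr, dc), th))
            key = (score, straightness, (-q[0], -q[1]))
            if side not in best or key > best[side]:
                best[side] = key + (q,)
        preference[p] = best

    graph = LinkGraph(pixels=coords, resolution=skeleton.resolution)
    for p, sides in preference.items():
        for key in sides.values():
            q, score = key[3], key[0]
            if any(entry[3] == p for entry in preference.get(q, {}).values()):
                pair = (p, q) if p <= q else (q, p)
                graph.links[pair] = score
    return graph


def group_lines(links: LinkGraph) -> LineSet:
    """Group mutually linked pixels into continuous z-lines.

    Every skeleton pixel lands in exactly one line (isolated pixels form
    single-pixel lines).  Closed cycles — possible only through rare
    orientation artifacts — are broken at their weakest link and logged.
    Each path is ordered starting from its lexicographically smaller
    endpoint.
    """
    adj = links.neighbors_of()
    # break cycles: components where every node has degree 2
    weights = dict(links.links)
    seen: set[Coord] = set()
    for start in sorted(adj):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.append(v)
                    stack.append(v)
        if comp and all(len(adj[u]) == 2 for u in comp):
            comp_links = [(w, pair) for pair, w in weights.items() if pair[0] in comp]
            w, weakest = min(comp_links, key=lambda t: (t[0], t[1]))
            log.info("breaking cycle of %d pixels at weakest link %s (|cos| = %.3f)",
                     len(comp), weakest, w)
            a, b = weakest
            adj[a].remove(b)
            adj[b].remove(a)

    lines: list[ContinuousLine] = []
    visited: set[Coord] = set()
    endpoints = sorted(p for p, nb in adj.items() if len(nb) <= 1)
    for start in endpoints:
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        cur, prev = start, None
        while True:
            nxt = [q for q in adj[cur] if q != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            path.append(cur)
            visited.add(cur)
        lines.append(ContinuousLine(path=np.array(path), resolution=links.resolution))
    # pixels without a valid orientation never enter adj; they are singletons
    for p in links.pixels:
        if p not in visited and p not in adj:
            lines.append(ContinuousLine(path=np.array([p]), resolution=links.resolution))
            visited.add(p)
    return LineSet(lines=lines, resolution=links.resolution)


def detect_lines(skeleton: BinarySkeleton, field_: OrientationField) -> LineSet:
    """Convenience: link neighbors and group into continuous z-lines."""
    return group_lines(link_neighbors(skeleton, field_))


def line_lengths(lines: LineSet) -> list[tuple[int, float]]:
    """(pixel_count, length_um) per line; μm uses the Euclidean path length."""
    return [(ln.pixel_count, ln.length_um) for ln in lines.lines]


def median_czl(lines: LineSet, min_pixels: int = 2) -> float:
    """Median continuous z-line length (μm) over lines of ≥ `min_pixels` pixels.

    Continuous z-line length distributions are strongly right-skewed, so the
    median, not the mean, summarizes a condition.  NaN (with a warning) when
    no line qualifies.
    """
    qualifying = [ln.length_um for ln in lines.lines if ln.pixel_count >= min_pixels]
    if not qualifying:
        warnings.warn("no continuous z-line meets the minimum pixel count")
        return float("nan")
    return float(np.median(qualifying))
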