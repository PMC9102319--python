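"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's kd-tree and traversal
code paths: clustering oracles work on plain point lists with O(n) or
O(n^2) scans, and the filtering oracle is a literal per-pixel double loop.
They define the expected behaviour that the optimized implementations are
checked against.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from depthmask import DepthFrame, Point3D


# -- point-list helpers ------------------------------------------------------

def points_from_arrays(coords: np.ndarray) -> list[Point3D]:
    return [Point3D(float(x), float(y), float(z), i, 0)
            for i, (x, y, z) in enumerate(coords)]


def in_box(p: Point3D, box) -> bool:
    return (box[0] <= p.x <= box[1] and box[2] <= p.y <= box[3]
            and box[4] <= p.z <= box[5])


def hull_box(points: list[Point3D], b: float):
    xs = [p.x for p in points]
    ys = [p.y for p in points]
    zs = [p.z for p in points]
    return (min(xs) - b, max(xs) + b, min(ys) - b, max(ys) + b,
            min(zs) - b, max(zs) + b)


# -- clustering oracles ------------------------------------------------------

def box_closure_oracle(points: list[Point3D], seed: Point3D, b: float,
                       removed: set[int] | None = None) -> set[int]:
    """Fixpoint of the bounding-box closure, by plain list iteration.

    Returns indices (ids) of the cluster's points.  ``removed`` point ids
    are treated as already assigned (the artificial wall) and can never
    join the cluster.
    """
    removed = removed or set()
    available = [p for p in points if id(p) not in removed]
    members = [seed]
    member_ids = {id(seed)}
    box = (seed.x - b, seed.x + b, seed.y - b, seed.y + b,
           seed.z - b, seed.z + b)
    while True:
        added = False
        for p in available:
            if id(p) not in member_ids and in_box(p, box):
                members.append(p)
                member_ids.add(id(p))
                added = True
        if not added:
            return member_ids
        box = hull_box(members, b)


def euclidean_bfs_oracle(points: list[Point3D], seed: Point3D,
                         b: float) -> set[int]:
    """BFS over the pairwise <= b Euclidean distance graph (O(n^2))."""
    coords = np.array([[p.x, p.y, p.z] for p in points])
    ids = [id(p) for p in points]
    idx = {id(p): i for i, p in enumerate(points)}
    b2 = b * b
    visited = {idx[id(seed)]}
    frontier = [idx[id(seed)]]
    while frontier:
        i = frontier.pop()
        d2 = ((coords - coords[i]) ** 2).sum(axis=1)
        for j in np.nonzero(d2 <= b2)[0]:
            if j not in visited:
                visited.add(int(j))
                frontier.append(int(j))
    return {ids[i] for i in visited}


def linear_nn_oracle(points: list[Point3D], target: Point3D) -> Point3D:
    return min(points, key=lambda p: (p.x - target.x) ** 2
               + (p.y - target.y) ** 2 + (p.z - target.z) ** 2)


# -- filtering oracle --------------------------------------------------------

def bilateral_oracle(values: np.ndarray, sigma_d: float, sigma_r: float,
                     radius: int) -> np.ndarray:
    """Literal per-pixel double-loop bilateral filter with hole exclusion
    and truncated borders."""
    h, w = values.shape
    out = np.zeros_like(values, dtype=float)
    for py in range(h):
        for px in range(w):
            if values[py, px] == 0:
                continue
            num = den = 0.0
            for qy in range(max(0, py - radius), min(h, py + radius + 1)):
                for qx in range(max(0, px - radius), min(w, px + radius + 1)):
                    iq = values[qy, qx]
                    if iq == 0:
                        continue
                    d2 = (px - qx) ** 2 + (py - qy) ** 2
                    r = values[py, px] - iq
                    wgt = (math.exp(-d2 / (2 * sigma_d ** 2))
                           * math.exp(-(r * r) / (2 * sigma_r ** 2)))
                    num += wgt * iq
                    den += wgt
            out[py, px] = num / den
    return out


def gaussian_blur_oracle(values: np.ndarray, sigma_d: float,
                         radius: int) -> np.ndarray:
    """Spatial-only normalized blur (the sigma_r -> infinity limit)."""
    h, w = values.shape
    out = np.zeros_like(values, dtype=float)
    for py in range(h):
        for px in range(w):
            if values[py, px] == 0:
                continue
            num = den = 0.0
            for qy in range(max(0, py - radius), min(h, py + radius + 1)):
                for qx in range(max(0, px - radius), min(w, px + radius + 1)):
                    if values[qy, qx] == 0:
                        continue
                    d2 = (px - qx) ** 2 + (py - qy) ** 2
                    wgt = math.exp(-d2 / (2 * sigma_d ** 2))
                    num += wgt * values[qy, qx]
                    den += wgt
            out[py, px] = num / den
    return out


# -- fixtures ----------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_frame():
    return DepthFrame(np.array([[1.0, 2.0], [3.0, 4.0]]), index=0)
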