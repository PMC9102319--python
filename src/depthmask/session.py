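"""Mask-editing sessions: selection actions, undo, and video propagation.

A frame's mask is defined by an ordered stack of user actions:

``manual``
    a set of brush pixels added to the mask by hand;
``auto``
    a seeded bounding-box cluster with margin ``b``;
``erase``
    a set of brush pixels explicitly excluded from the mask.

Replay is a pure function of (frame, stack).  Manually marked and erased
points are flagged as already-assigned in the kd-tree *before* any auto
action runs, so they act as an artificial wall: automatic cluster growth
cannot pass through a human-marked border, which is how a "bleeding edge"
into the background is contained.

Propagation to the next frame transfers each action by kind: manual/erase
keep their exact pixel sets (depth is irrelevant to them), while an auto
action's seed is recomputed — the realized seed point of the previous frame
is looked up in the next frame's cloud by kd-tree nearest-neighbour search,
so the seed follows the object as it moves.  A seed whose recomputed point
jumped implausibly far (more than ``seed_jump_limit``, default ``10*b``) is
recorded as failed and contributes nothing to the mask; this is what makes
an object leaving the scene produce empty auto masks instead of latching
onto the background.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from .clustering import Cluster, cluster_expanding_box
from .errors import ContractError
from .filtering import BilateralParams, bilateral_filter
from .io import DepthFrame, MaskFrame, Point3D, frame_to_points, plan_chunks
from .kdtree import PointCloudTree, build_tree, nearest_neighbor

KINDS = ("manual", "auto", "erase")


@dataclass(frozen=True)
class SelectionAction:
    """One user gesture; exactly the fields its kind requires."""

    kind: str
    pixels: frozenset[tuple[int, int]] = frozenset()  # manual / erase centres
    brush: int = 0  # square selector half-width for manual / erase
    seed_pixel: Optional[tuple[int, int]] = None  # auto
    b: Optional[float] = None  # auto

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ContractError(f"unknown action kind {self.kind!r}")
        if self.kind == "auto":
            if self.seed_pixel is None or self.b is None or self.b <= 0:
                raise ContractError("auto actions need seed_pixel and b > 0")
        else:
            if not self.pixels:
                raise ContractError(f"{self.kind} actions need a pixel set")
            if self.brush < 0:
                raise ContractError("brush half-width must be >= 0")

    def selector_pixels(self, width: int, height: int) -> set[tuple[int, int]]:
        """The square-selector footprint, clipped to the frame."""
        out: set[tuple[int, int]] = set()
        r = self.brush
        for cx, cy in self.pixels:
            for py in range(max(0, cy - r), min(height, cy + r + 1)):
                for px in range(max(0, cx - r), min(width, cx + r + 1)):
                    out.add((px, py))
        return out


@dataclass
class ActionStack:
    """The ordered, replayable list of actions defining one frame's mask."""

    actions: list[SelectionAction] = field(default_factory=list)

    def push(self, action: SelectionAction) -> None:
        self.actions.append(action)

    def pop(self) -> SelectionAction:
        if not self.actions:
            raise ContractError("pop from an empty action stack")
        return self.actions.pop()

    def __len__(self) -> int:
        return len(self.actions)


@dataclass
class FrameSegmentation:
    """The realized segmentation of one frame: stack, mask and clusters.

    ``realized_seeds[i]`` is the cloud point actually used by action ``i``
    (None for non-auto or failed actions); ``failed_actions`` lists the
    indices of auto actions whose seed could not be recovered.
    """

    frame: DepthFrame
    frame_index: int
    stack: ActionStack
    mask: MaskFrame
    clusters: list[Cluster] = field(default_factory=list)
    realized_seeds: list[Optional[Point3D]] = field(default_factory=list)
    failed_actions: list[int] = field(default_factory=list)
    tree: Optional[PointCloudTree] = None


def _nearest_active_pixel(tree: PointCloudTree,
                          pixel: tuple[int, int]) -> Optional[Point3D]:
    """Fallback seed lookup: the active point nearest in 2D pixel distance
    (ties to row-major order)."""
    sx, sy = pixel
    best = None
    best_key = None
    for p in tree.points:
        if not tree.is_active(p):
            continue
        d2 = (p.px - sx) ** 2 + (p.py - sy) ** 2
        key = (d2, p.py, p.px)
        if best_key is None or key < best_key:
            best, best_key = p, key
    return best


def _resolve_seed(tree: PointCloudTree, action: SelectionAction,
                  prev_seed: Optional[Point3D],
                  seed_jump_limit: Optional[float]) -> Optional[Point3D]:
    if prev_seed is not None:
        # propagation: follow the previous frame's realized point
        found = nearest_neighbor(tree, prev_seed, active_only=True)
        if found is None:
            return None
        if seed_jump_limit is not None:
            dx = found.x - prev_seed.x
            dy = found.y - prev_seed.y
            dz = found.z - prev_seed.z
            if dx * dx + dy * dy + dz * dz > seed_jump_limit ** 2:
                return None
        return found
    px, py = action.seed_pixel
    p = tree.point_at_pixel(px, py)
    if p is not None and tree.is_active(p):
        return p
    return _nearest_active_pixel(tree, (px, py))


def apply_stack(frame: DepthFrame, stack: ActionStack,
                params: Optional[BilateralParams] = None,
                scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
                prev_seeds: Optional[list[Optional[Point3D]]] = None,
                seed_jump_limit: Optional[float] = None
                ) -> FrameSegmentation:
    """Replay an action stack on one frame and render its mask.

    The frame is bilateral-filtered (pass ``params=None`` to skip), lifted
    to a point cloud and indexed in a kd-tree.  All manual and erase points
    are flagged removed first (the artificial wall), then auto actions run
    in stack order.  The mask is the union of manual selector pixels and
    auto cluster pixels, minus every erase selector pixel.

    ``prev_seeds`` (aligned with the stack) carries realized seed points
    from a previous frame during propagation; when given, an auto seed is
    recomputed by nearest-neighbour search from that point instead of the
    stored click pixel.
    """
    filtered = bilateral_filter(frame, params) if params is not None else frame
    tree = build_tree(frame_to_points(filtered, scale))
    w, h = frame.width, frame.height

    actions = stack.actions
    if prev_seeds is not None and len(prev_seeds) != len(actions):
        raise ContractError("prev_seeds must align with the action stack")

    clusters: list[Cluster] = []
    include: set[tuple[int, int]] = set()
    exclude: set[tuple[int, int]] = set()

    # pass 1: realize every manual/erase selection and build the wall
    wall_points: dict[int, list[Point3D]] = {}
    for i, action in enumerate(actions):
        if action.kind == "auto":
            continue
        selector = action.selector_pixels(w, h)
        realized = []
        for px, py in sorted(selector, key=lambda q: (q[1], q[0])):
            p = tree.point_at_pixel(px, py)
            if p is not None and tree.is_active(p):
                tree.node_for(p).removed = True
                realized.append(p)
        wall_points[i] = realized
        if action.kind == "manual":
            include |= selector
        else:
            exclude |= selector

    # pass 2: auto actions grow clusters against the walled tree
    realized_seeds: list[Optional[Point3D]] = [None] * len(actions)
    failed: list[int] = []
    for i, action in enumerate(actions):
        if action.kind != "auto":
            if wall_points.get(i):
                clusters.append(Cluster(points=wall_points[i],
                                        origin=action.kind))
            continue
        if prev_seeds is not None:
            prev = prev_seeds[i]
            if prev is None:
                # the seed was already lost in an earlier frame; it stays
                # lost rather than re-latching onto whatever now occupies
                # the original click pixel
                failed.append(i)
                continue
        else:
            prev = None
        limit = seed_jump_limit
        if limit is None and prev is not None:
            limit = 10.0 * action.b
        seed = _resolve_seed(tree, action, prev, limit)
        if seed is None:
            failed.append(i)
            continue
        # halfspace pruning: pure speed, identical cluster
        cluster = cluster_expanding_box(tree, seed, action.b, halfspace=True)
        clusters.append(cluster)
        realized_seeds[i] = seed
        include |= cluster.pixel_set

    mask = MaskFrame.from_pixels(w, h, include - exclude)
    return FrameSegmentation(frame=frame, frame_index=frame.index,
                             stack=stack, mask=mask, clusters=clusters,
                             realized_seeds=realized_seeds,
                             failed_actions=failed, tree=tree)


def undo(seg: FrameSegmentation,
         params: Optional[BilateralParams] = None) -> FrameSegmentation:
    """Pop the last action and re-render the frame from the rest."""
    if not seg.stack.actions:
        warnings.warn("undo on an empty action stack is a no-op")
        return seg
    remaining = ActionStack(seg.stack.actions[:-1])
    return apply_stack(seg.frame, remaining, params)


def propagate(prev: FrameSegmentation, next_frame: DepthFrame,
              params: Optional[BilateralParams] = None,
              seed_jump_limit: Optional[float] = None) -> FrameSegmentation:
    """Transfer a frame's segmentation to the next frame.

    Manual and erase actions keep their exact pixel sets; auto seeds are
    recomputed from the previous frame's realized points (see module
    docstring).  Erase walls are rebuilt before any auto action replays,
    so a human-marked border keeps protecting subsequent frames.
    """
    if (prev.frame.width, prev.frame.height) != (next_frame.width,
                                                 next_frame.height):
        raise ContractError("frame dimensions differ")
    return apply_stack(next_frame, prev.stack, params,
                       prev_seeds=list(prev.realized_seeds),
                       seed_jump_limit=seed_jump_limit)


def propagate_batch(seed_seg: FrameSegmentation,
                    frames: list[DepthFrame], batch_size: int = 12,
                    params: Optional[BilateralParams] = None
                    ) -> list[FrameSegmentation]:
    """Propagate through ``frames`` in order, chaining frame to frame.

    ``batch_size`` mirrors the page size of an interactive tool (how many
    frames are prepared per page); because every frame's segmentation
    derives from its predecessor, results are defined by sequential
    chaining and are independent of the batch size.
    """
    if batch_size < 1:
        raise ContractError("batch_size must be >= 1")
    out: list[FrameSegmentation] = []
    current = seed_seg
    for start in range(0, len(frames), batch_size):
        for frame in frames[start:start + batch_size]:
            current = propagate(current, frame, params)
            out.append(current)
    return out


def propagate_sequence(seed_seg: FrameSegmentation,
                       frames: list[DepthFrame], window_frames: int,
                       batch_size: int = 12,
                       params: Optional[BilateralParams] = None
                       ) -> list[FrameSegmentation]:
    """Windowed propagation for long sequences.

    Frames are processed window by window (the memory-bounded loading
    pattern for long recordings); chaining continues across window
    boundaries, so the output is identical to one whole-sequence run.
    """
    if not frames:
        return []
    plan = plan_chunks(len(frames), window_frames)
    out: list[FrameSegmentation] = []
    current = seed_seg
    for start, end in plan.windows:
        segs = propagate_batch(current, frames[start:end], batch_size, params)
        out.extend(segs)
        current = segs[-1]
    return out


# -- session files ----------------------------------------------------------

def action_to_json(action: SelectionAction) -> dict:
    d: dict = {"kind": action.kind}
    if action.kind == "auto":
        d["seed_pixel"] = list(action.seed_pixel)
        d["b"] = action.b
    else:
        d["pixels"] = sorted([list(p) for p in action.pixels])
        if action.brush:
            d["brush"] = action.brush
    return d


def action_from_json(d: dict) -> SelectionAction:
    kind = d.get("kind")
    if kind == "auto":
        return SelectionAction(kind="auto", seed_pixel=tuple(d["seed_pixel"]),
                               b=float(d["b"]))
    return SelectionAction(kind=kind,
                           pixels=frozenset(tuple(p) for p in d["pixels"]),
                           brush=int(d.get("brush", 0)))


def save_session(stacks: dict[int, ActionStack], path: str | Path) -> Path:
    """Write per-frame action stacks as a session JSON file."""
    payload = {"frames": [
        {"index": idx, "actions": [action_to_json(a) for a in stack.actions]}
        for idx, stack in sorted(stacks.items())]}
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_session(path: str | Path) -> dict[int, ActionStack]:
    """Read a session JSON file into per-frame action stacks."""
    try:
        payload = json.loads(Path(path).read_text())
        frames = payload["frames"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ContractError(f"{path}: not a valid session file: {exc}") from exc
    return {int(f["index"]): ActionStack([action_from_json(a)
                                          for a in f.get("actions", [])])
            for f in frames}
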