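"""Deterministic synthetic depth scenes, adversarial clouds and random clouds.

Real depth recordings of people in closed rooms are not redistributable, so
the test substrate is generated: a closed-room scene (far wall, floor with a
depth gradient towards the camera) containing a human-like figure composed
of simple primitives (head, torso, arms, legs), optionally connected to the
floor by a thin depth "bridge" that makes box clustering bleed into the
background, moved per frame, or removed from a chosen frame onward.
Kinect-style artifacts are emulated as additive Gaussian depth noise,
outlier spikes, zero-depth holes and a per-frame flicker offset; ground
truth is captured before any noise, so masks are exact regardless of the
noise channel.

Depth values are in arbitrary sensor units on a u16-compatible scale; the
figure sits ~60 units in front of the nearest background surface, so box
clustering with any margin ``b <= 9`` cannot cross the gap unless a bridge
is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ContractError, FixtureError
from .io import DepthFrame, DepthSequence, MaskFrame, Point3D
from .kdtree import build_tree_inserted
from .clustering import cluster_expanding_box, cluster_fixed_box


@dataclass(frozen=True)
class NoiseSpec:
    """Kinect-style noise channel, applied after ground-truth capture in
    the order: Gaussian -> spikes -> holes -> flicker (flicker shifts only
    valid pixels, so holes survive)."""

    gaussian_sigma: float = 0.0
    hole_prob: float = 0.0
    spike_prob: float = 0.0
    spike_magnitude: float = 40.0
    flicker_sigma: float = 0.0


@dataclass(frozen=True)
class SceneSpec:
    """A closed-room scene with one human-like figure.

    Geometry is parameterised in pixels relative to ``width``/``height``;
    the defaults draw a standing figure roughly two thirds of the frame
    height, centred, with legs ending just above the floor region.
    """

    width: int = 160
    height: int = 120
    frame_count: int = 1
    rng_seed: int = 0
    figure_origin: tuple[int, int] | None = None  # figure centre (px, py)
    figure_depth: float = 100.0
    figure_bulge: float = 2.0
    wall_depth: float = 200.0
    floor_near_depth: float = 140.0
    floor_fraction: float = 0.3  # bottom fraction of rows that is floor
    bridge: bool = False
    motion: tuple[int, int] = (0, 0)  # per-frame (dx, dy) in pixels
    exit_frame: int | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)


PRESETS = {
    "clean": SceneSpec(),
    "noisy": SceneSpec(noise=NoiseSpec(gaussian_sigma=1.5, hole_prob=0.02,
                                       spike_prob=0.005, spike_magnitude=40.0,
                                       flicker_sigma=0.5)),
    "bridged": SceneSpec(bridge=True),
    "moving": SceneSpec(frame_count=24, motion=(2, 0),
                        figure_origin=(55, 60)),
    "exit": SceneSpec(frame_count=8, exit_frame=5),
}


def scene_preset(name: str, **overrides) -> SceneSpec:
    if name not in PRESETS:
        raise ContractError(f"unknown preset {name!r}; "
                            f"expected one of {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


def _figure_primitives(spec: SceneSpec) -> list[dict]:
    """Figure parts as pixel-space primitives relative to the figure centre.

    Returned dicts: {'kind': 'ellipse'|'rect', geometry..., 'depth', 'bulge'}.
    Parts overlap slightly so the silhouette is 4-connected.
    """
    h = spec.height
    head_r = max(3, round(0.055 * h))
    torso_rx = max(4, round(0.10 * h))
    torso_ry = max(5, round(0.16 * h))
    arm_t = max(2, round(0.035 * h))
    arm_len = max(4, round(0.16 * h))
    leg_t = max(2, round(0.04 * h))
    leg_len = max(5, round(0.20 * h))
    d = spec.figure_depth
    # torso centred at the origin; head above; arms at the shoulders;
    # legs below the torso
    return [
        {"kind": "ellipse", "cx": 0, "cy": 0, "rx": torso_rx, "ry": torso_ry,
         "depth": d, "bulge": spec.figure_bulge},
        {"kind": "ellipse", "cx": 0, "cy": -(torso_ry + head_r - 1),
         "rx": head_r, "ry": head_r, "depth": d - 1.0,
         "bulge": spec.figure_bulge * 0.5},
        {"kind": "rect", "x0": -(torso_rx + arm_len), "x1": -torso_rx + 1,
         "y0": -torso_ry + 2, "y1": -torso_ry + 2 + arm_t, "depth": d + 1.0},
        {"kind": "rect", "x0": torso_rx - 1, "x1": torso_rx + arm_len,
         "y0": -torso_ry + 2, "y1": -torso_ry + 2 + arm_t, "depth": d + 1.0},
        {"kind": "rect", "x0": -torso_rx + 2, "x1": -torso_rx + 2 + leg_t,
         "y0": torso_ry - 1, "y1": torso_ry - 1 + leg_len, "depth": d + 1.0},
        {"kind": "rect", "x0": torso_rx - 2 - leg_t, "x1": torso_rx - 2,
         "y0": torso_ry - 1, "y1": torso_ry - 1 + leg_len, "depth": d + 1.0},
    ]


def _render_figure(spec: SceneSpec, origin: tuple[int, int]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Render the figure depth surface at ``origin``; returns (depth, owned)
    where non-owned pixels hold +inf."""
    w, h = spec.width, spec.height
    ox, oy = origin
    ys, xs = np.mgrid[0:h, 0:w]
    depth = np.full((h, w), np.inf)
    for prim in _figure_primitives(spec):
        if prim["kind"] == "ellipse":
            u = (((xs - ox - prim["cx"]) / prim["rx"]) ** 2
                 + ((ys - oy - prim["cy"]) / prim["ry"]) ** 2)
            inside = u <= 1.0
            surf = np.full((h, w), np.inf)
            surf[inside] = prim["depth"] - prim["bulge"] * np.sqrt(
                np.clip(1.0 - u[inside], 0.0, 1.0))
        else:
            inside = ((xs >= ox + prim["x0"]) & (xs < ox + prim["x1"])
                      & (ys >= oy + prim["y0"]) & (ys < oy + prim["y1"]))
            surf = np.where(inside, prim["depth"], np.inf)
        depth = np.minimum(depth, surf)
    return depth, np.isfinite(depth)


def _render_background(spec: SceneSpec) -> np.ndarray:
    w, h = spec.width, spec.height
    bg = np.full((h, w), spec.wall_depth)
    floor_rows = int(round(spec.floor_fraction * h))
    if floor_rows > 0:
        y0 = h - floor_rows
        ramp = np.linspace(spec.wall_depth, spec.floor_near_depth, floor_rows)
        bg[y0:, :] = ramp[:, None]
    return bg


def _figure_extent(spec: SceneSpec, origin: tuple[int, int]) -> tuple:
    """Analytic pixel bounding box of the figure (unclipped)."""
    ox, oy = origin
    xs, ys = [], []
    for prim in _figure_primitives(spec):
        if prim["kind"] == "ellipse":
            xs += [ox + prim["cx"] - prim["rx"], ox + prim["cx"] + prim["rx"]]
            ys += [oy + prim["cy"] - prim["ry"], oy + prim["cy"] + prim["ry"]]
        else:
            xs += [ox + prim["x0"], ox + prim["x1"] - 1]
            ys += [oy + prim["y0"], oy + prim["y1"] - 1]
    return min(xs), max(xs), min(ys), max(ys)


def torso_seed_pixel(spec: SceneSpec, frame: int = 0) -> tuple[int, int]:
    """The figure-centre pixel (middle of the torso) at a given frame."""
    ox, oy = spec.figure_origin or (spec.width // 2, spec.height // 2 - 2)
    return ox + frame * spec.motion[0], oy + frame * spec.motion[1]


def bridge_pixels(spec: SceneSpec) -> set[tuple[int, int]]:
    """The pixel set of the figure-to-floor bridge (frame-0 geometry)."""
    if not spec.bridge:
        return set()
    _, _, strip = _bridge_surface(spec, torso_seed_pixel(spec, 0))
    return strip


def _bridge_surface(spec: SceneSpec, origin: tuple[int, int]):
    """A thin depth ramp from the left leg's foot down into the floor."""
    w, h = spec.width, spec.height
    bg = _render_background(spec)
    prims = _figure_primitives(spec)
    leg = prims[4]  # left leg rectangle
    ox, oy = origin
    x0 = ox + leg["x0"]
    x1 = ox + leg["x1"]
    y0 = oy + leg["y1"]  # first row below the foot
    surf = np.full((h, w), np.inf)
    strip: set[tuple[int, int]] = set()
    for x in range(max(0, x0), min(w, x1)):
        y = y0
        d = spec.figure_depth + 1.0
        while y < h and d < bg[y, x]:
            surf[y, x] = d
            strip.add((x, y))
            d += 3.0  # ramp step: small enough for any margin b >= 3
            y += 1
    return surf, np.isfinite(surf), strip


def generate_scene(spec: SceneSpec) -> tuple[DepthSequence, list[MaskFrame]]:
    """Render a scene to depth frames plus per-frame ground-truth masks.

    Deterministic for a given ``rng_seed``.  Ground truth marks exactly the
    pixels owned by figure primitives (bridge and background excluded) and
    is captured before noise, so holes or spikes never alter it.
    """
    w, h = spec.width, spec.height
    origin0 = spec.figure_origin or (w // 2, h // 2 - 2)
    x0, x1, y0, y1 = _figure_extent(spec, origin0)
    if x0 < 0 or y0 < 0 or x1 >= w or y1 >= h:
        raise ContractError("figure out of frame at start")
    gap = min(spec.floor_near_depth, spec.wall_depth) - (spec.figure_depth + 1.0)
    if spec.noise.gaussian_sigma > 0 and gap < 5.0 * spec.noise.gaussian_sigma:
        raise ContractError("figure/background depth gap below 5*sigma margin")

    rng = np.random.default_rng(spec.rng_seed)
    bg = _render_background(spec)
    frames: list[DepthFrame] = []
    masks: list[MaskFrame] = []
    for t in range(spec.frame_count):
        depth = bg.copy()
        owned = np.zeros((h, w), dtype=bool)
        present = spec.exit_frame is None or t < spec.exit_frame
        origin = (origin0[0] + t * spec.motion[0],
                  origin0[1] + t * spec.motion[1])
        if present:
            fig, fig_owned = _render_figure(spec, origin)
            visible = fig_owned & (fig < depth)
            depth[visible] = fig[visible]
            owned = visible
            if spec.bridge:
                br, br_owned, _ = _bridge_surface(spec, origin)
                take = br_owned & (br < depth)
                depth[take] = br[take]
                owned &= ~take  # bridge pixels are not ground truth
        masks.append(MaskFrame(owned.astype(np.uint8)))

        noise = spec.noise
        if noise.gaussian_sigma > 0:
            depth = depth + rng.normal(0.0, noise.gaussian_sigma, depth.shape)
        if noise.spike_prob > 0:
            hits = rng.random(depth.shape) < noise.spike_prob
            depth = depth + hits * rng.normal(0.0, noise.spike_magnitude,
                                              depth.shape)
        if noise.hole_prob > 0:
            depth = np.where(rng.random(depth.shape) < noise.hole_prob,
                             0.0, depth)
        if noise.flicker_sigma > 0:
            offset = rng.normal(0.0, noise.flicker_sigma)
            depth = np.where(depth > 0, depth + offset, depth)
        depth = np.clip(depth, 0.0, None)
        frames.append(DepthFrame(depth, index=t))
    return DepthSequence(frames), masks


@dataclass(frozen=True)
class AdversarialCloudSpec:
    """A collinear chain tuned so every bounding-box growth pass adds
    exactly one point, for both the fixed and the expanding algorithm."""

    n: int = 20
    b: float = 1.0
    spacing_factor: float = 0.9
    insertion_order: str = "descending"  # or "ascending" / "identity"


_ORDERS = ("descending", "ascending", "identity")


def _chain_points(spec: AdversarialCloudSpec) -> list[Point3D]:
    s = spec.spacing_factor * spec.b
    return [Point3D(i * s, 0.0, 0.0, i, 0) for i in range(spec.n)]


def _ordered(points: list[Point3D], order: str) -> list[Point3D]:
    if order == "descending":
        return list(reversed(points))
    if order == "ascending":
        return list(points)
    return list(points)  # identity: chain construction order


def generate_worst_case(spec: AdversarialCloudSpec
                        ) -> tuple[list[Point3D], Point3D]:
    """Build the worst-case cloud where the expanding box buys nothing.

    Points form a chain spaced ``spacing_factor * b`` apart along x.  The
    fixture is self-validating: both box algorithms are actually run on a
    tree built in the returned insertion order, and the generator asserts
    (n - 1) productive passes for each with identical node-visit counts,
    trying a bounded set of insertion orders before giving up.
    """
    if spec.n < 2:
        raise ContractError("worst-case chain needs n >= 2")
    if spec.b <= 0:
        raise ContractError("margin b must be > 0")
    points = _chain_points(spec)
    orders = [spec.insertion_order] + [o for o in _ORDERS
                                       if o != spec.insertion_order]
    tried = []
    for order in orders:
        ordered = _ordered(points, order)
        seed = points[0]

        tree_f = build_tree_inserted(ordered)
        cf = cluster_fixed_box(tree_f, seed, spec.b)
        visits_f = tree_f.visit_counter

        tree_e = build_tree_inserted(ordered)
        ce = cluster_expanding_box(tree_e, seed, spec.b)
        visits_e = tree_e.visit_counter

        ok = (len(cf.points) == spec.n and len(ce.points) == spec.n
              and cf.productive_passes == spec.n - 1
              and ce.productive_passes == spec.n - 1
              and visits_f == visits_e)
        if ok:
            return ordered, seed
        tried.append((order, len(cf.points), cf.productive_passes,
                      ce.productive_passes, visits_f, visits_e))
    raise FixtureError(
        "no insertion order yields the equal-pass worst case; tried "
        + "; ".join(f"{o}: |C|={c}, passes fixed={pf}/exp={pe}, "
                    f"visits {vf} vs {ve}"
                    for o, c, pf, pe, vf, ve in tried))


def worst_case_tree(spec: AdversarialCloudSpec):
    """The validated worst-case fixture as a ready-to-segment tree.

    The tree is built in the adversarial insertion order, while the seed-
    selection order (``tree.points``) walks the chain from its leaf end —
    seeding at the chain root would let the expanding traversal cascade
    down the whole chain in one pass, which is the algorithm's best case,
    not its worst.  Returns ``(tree, seed)``.
    """
    ordered, seed = generate_worst_case(spec)
    chain_order = sorted(ordered, key=lambda p: p.x)
    tree = build_tree_inserted(ordered, seed_order=chain_order)
    return tree, seed


def generate_random_cloud(n: int, extent: tuple[float, float, float],
                          rng_seed: int) -> list[Point3D]:
    """Uniform random points in ``[0, ex] x [0, ey] x (0, ez]``.

    Pixel indices are assigned row-major-style from the point order so the
    points can seed full segmentations deterministically.
    """
    if n < 0:
        raise ContractError("n must be >= 0")
    rng = np.random.default_rng(rng_seed)
    ex, ey, ez = extent
    coords = rng.random((n, 3)) * np.array([ex, ey, ez])
    return [Point3D(float(x), float(y), float(z) + 1e-9, i % 65536, i // 65536)
            for i, (x, y, z) in enumerate(coords)]
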