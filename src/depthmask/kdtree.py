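"""A 3D binary search tree over depth points with lazy removal.

The tree splits on x, y, z cyclically.  Points extracted by a search are
never structurally deleted; they are flagged ``removed`` so each point can
join exactly one cluster, and a per-node ``subtree_active`` flag lets later
searches skip fully-consumed subtrees.  Every search counts the nodes it
actually tests (containment or distance test executed) in
``tree.visit_counter`` — pruned subtrees contribute nothing — which gives a
platform-independent cost measure for the benchmark harness.

Two range searches are provided over an axis-aligned box:

``fcp_fixed``
    collects all active points inside a fixed box;
``fcp_expanding``
    additionally grows the box by the margin ``b`` around every point the
    moment it is collected, while the traversal is still running, so a
    single pass can sweep up points the initial box did not cover.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ContractError
from .io import Point3D


@dataclass
class BoundingBox3D:
    """Axis-aligned box; containment is a constant-cost comparison."""

    min_x: float
    max_x: float
    min_y: float
    max_y: float
    min_z: float
    max_z: float

    def __post_init__(self) -> None:
        if self.min_x > self.max_x or self.min_y > self.max_y or self.min_z > self.max_z:
            raise ContractError("box min must not exceed max in any dimension")

    @classmethod
    def around(cls, p: Point3D, b: float) -> "BoundingBox3D":
        return cls(p.x - b, p.x + b, p.y - b, p.y + b, p.z - b, p.z + b)

    @classmethod
    def hull(cls, points: list[Point3D], b: float = 0.0) -> "BoundingBox3D":
        if not points:
            raise ContractError("hull of an empty point list")
        xs = [p.x for p in points]
        ys = [p.y for p in points]
        zs = [p.z for p in points]
        return cls(min(xs) - b, max(xs) + b, min(ys) - b, max(ys) + b,
                   min(zs) - b, max(zs) + b)

    def contains(self, p: Point3D) -> bool:
        return (self.min_x <= p.x <= self.max_x
                and self.min_y <= p.y <= self.max_y
                and self.min_z <= p.z <= self.max_z)

    def expand(self, p: Point3D, b: float) -> None:
        """Grow the box so it covers ``p`` plus a margin ``b`` per axis."""
        if p.x - b < self.min_x:
            self.min_x = p.x - b
        if p.x + b > self.max_x:
            self.max_x = p.x + b
        if p.y - b < self.min_y:
            self.min_y = p.y - b
        if p.y + b > self.max_y:
            self.max_y = p.y + b
        if p.z - b < self.min_z:
            self.min_z = p.z - b
        if p.z + b > self.max_z:
            self.max_z = p.z + b

    def copy(self) -> "BoundingBox3D":
        return BoundingBox3D(self.min_x, self.max_x, self.min_y, self.max_y,
                             self.min_z, self.max_z)


class KdNode:
    """One tree node: a point, its split axis and the removal flags."""

    __slots__ = ("point", "axis", "left", "right", "removed",
                 "subtree_active", "inorder")

    def __init__(self, point: Point3D, axis: int):
        self.point = point
        self.axis = axis  # 0 = x, 1 = y, 2 = z
        self.left: KdNode | None = None
        self.right: KdNode | None = None
        self.removed = False
        self.subtree_active = True
        self.inorder = 0  # rank used only as a deterministic NN tie-break


class PointCloudTree:
    """The kd-tree together with point bookkeeping and the visit counter."""

    def __init__(self, root: KdNode | None, points: list[Point3D]):
        self.root = root
        self.points = points  # original input order (row-major for frames)
        self.size = len(points)
        self.visit_counter = 0
        self._node_of: dict[int, KdNode] = {}
        self._pixel_node: dict[tuple[int, int], KdNode] = {}
        self._index_nodes()

    def _index_nodes(self) -> None:
        rank = 0
        stack: list[tuple[KdNode, bool]] = [(self.root, False)] if self.root else []
        while stack:
            node, expanded = stack.pop()
            if node is None:
                continue
            if expanded:
                node.inorder = rank
                rank += 1
                self._node_of[id(node.point)] = node
                self._pixel_node[(node.point.px, node.point.py)] = node
            else:
                stack.append((node.right, False))
                stack.append((node, True))
                stack.append((node.left, False))

    # -- point bookkeeping -------------------------------------------------

    def node_for(self, point: Point3D) -> KdNode:
        try:
            return self._node_of[id(point)]
        except KeyError:
            raise ContractError("point is not a member of this tree") from None

    def is_active(self, point: Point3D) -> bool:
        return not self.node_for(point).removed

    def point_at_pixel(self, px: int, py: int) -> Point3D | None:
        """The cloud point generated by pixel (px, py), if any."""
        node = self._pixel_node.get((px, py))
        return node.point if node is not None else None

    def active_points(self) -> list[Point3D]:
        return [p for p in self.points if not self._node_of[id(p)].removed]


def build_tree(points: list[Point3D]) -> PointCloudTree:
    """Build a balanced tree by recursive median split on the cycling axis.

    The median of ties is resolved by input order (stable sort), making the
    tree a deterministic function of the input list.
    """
    def build(pts: list[Point3D], depth: int) -> KdNode | None:
        if not pts:
            return None
        axis = depth % 3
        if axis == 0:
            pts = sorted(pts, key=lambda p: p.x)
        elif axis == 1:
            pts = sorted(pts, key=lambda p: p.y)
        else:
            pts = sorted(pts, key=lambda p: p.z)
        mid = len(pts) // 2
        node = KdNode(pts[mid], axis)
        node.left = build(pts[:mid], depth + 1)
        node.right = build(pts[mid + 1:], depth + 1)
        return node

    return PointCloudTree(build(list(points), 0), list(points))


def build_tree_inserted(points: list[Point3D],
                        seed_order: list[Point3D] | None = None
                        ) -> PointCloudTree:
    """Build by classic sequential kd-insertion (ties go left).

    Produces order-dependent, possibly degenerate trees; used to construct
    adversarial fixtures, not for production clouds.  ``seed_order``, if
    given, sets the bookkeeping order of ``tree.points`` (and hence the
    seed-selection order of full segmentation) independently of the
    insertion order; it must hold the same point objects.
    """
    if seed_order is not None and set(map(id, seed_order)) != set(map(id, points)):
        raise ContractError("seed_order must be a permutation of points")
    root: KdNode | None = None
    for p in points:
        if root is None:
            root = KdNode(p, 0)
            continue
        node = root
        while True:
            c = (p.x, p.y, p.z)[node.axis]
            v = (node.point.x, node.point.y, node.point.z)[node.axis]
            if c <= v:
                if node.left is None:
                    node.left = KdNode(p, (node.axis + 1) % 3)
                    break
                node = node.left
            else:
                if node.right is None:
                    node.right = KdNode(p, (node.axis + 1) % 3)
                    break
                node = node.right
    return PointCloudTree(root, list(seed_order if seed_order is not None
                                     else points))


def reset_removal(tree: PointCloudTree) -> PointCloudTree:
    """Clear all removal flags so the same cloud can be re-segmented.

    The visit counter is deliberately left untouched (it is cumulative)."""
    stack = [tree.root] if tree.root else []
    while stack:
        node = stack.pop()
        if node is None:
            continue
        node.removed = False
        node.subtree_active = True
        stack.append(node.left)
        stack.append(node.right)
    return tree


def nearest_neighbor(tree: PointCloudTree, target: Point3D,
                     active_only: bool = False) -> Point3D | None:
    """Euclidean nearest neighbour with splitting-plane pruning.

    A subtree is skipped when the distance from the target to its splitting
    plane exceeds the best distance so far.  Exact ties are broken towards
    the earlier node in in-order traversal.  With ``active_only`` removed
    points are not candidates (subtrees with no active point are skipped).
    """
    if tree.root is None:
        return None
    tx, ty, tz = target.x, target.y, target.z
    best: list = [None, float("inf"), -1]  # node, squared distance, rank

    def visit(node: KdNode) -> None:
        if node is None or (active_only and not node.subtree_active):
            return
        tree.visit_counter += 1
        p = node.point
        if not (active_only and node.removed):
            dx, dy, dz = p.x - tx, p.y - ty, p.z - tz
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < best[1] or (d2 == best[1] and node.inorder < best[2]):
                best[0], best[1], best[2] = p, d2, node.inorder
        axis = node.axis
        tc = (tx, ty, tz)[axis]
        v = (p.x, p.y, p.z)[axis]
        near, far = (node.left, node.right) if tc <= v else (node.right, node.left)
        visit(near)
        if (tc - v) * (tc - v) <= best[1]:
            visit(far)

    visit(tree.root)
    return best[0]


def _collect_box(tree: PointCloudTree, box: BoundingBox3D,
                 b: float | None, prune: bool,
                 halfspace: bool) -> list[Point3D]:
    """Shared traversal for the two box searches.

    ``b`` is the expansion margin; ``None`` means a fixed box.  Preorder:
    the node is tested (and, for the expanding search, the box grown)
    before its children are explored; ``subtree_active`` is recomputed
    bottom-up on the unwind.

    The reference traversal descends into every child that still holds an
    active point, which is what makes node-visit counts a fair cost model:
    with this traversal, a pass costs the same for the fixed and the
    expanding search given the same removal state, so the expanding
    variant's pass savings translate directly into visit savings.
    ``halfspace=True`` additionally skips children whose half-space cannot
    intersect the current box — a pure accelerator that never changes the
    result, but whose interaction with mid-pass box growth makes visit
    counts incomparable between the two searches.
    """
    result: list[Point3D] = []
    if tree.root is None:
        return result

    def visit(node: KdNode) -> None:
        tree.visit_counter += 1
        p = node.point
        if not node.removed and box.contains(p):
            node.removed = True
            result.append(p)
            if b is not None:
                box.expand(p, b)
        left, right = node.left, node.right
        if halfspace:
            axis = node.axis
            v = (p.x, p.y, p.z)[axis]
            # left subtree holds coords <= v, right holds >= v; descend
            # only where the (current) box overlaps that half-space
            bmin = (box.min_x, box.min_y, box.min_z)[axis]
            if left is not None and left.subtree_active and bmin <= v:
                visit(left)
            bmax = (box.max_x, box.max_y, box.max_z)[axis]
            if right is not None and right.subtree_active and bmax >= v:
                visit(right)
        elif prune:
            if left is not None and left.subtree_active:
                visit(left)
            if right is not None and right.subtree_active:
                visit(right)
        else:
            if left is not None:
                visit(left)
            if right is not None:
                visit(right)
        node.subtree_active = (not node.removed
                               or (left is not None and left.subtree_active)
                               or (right is not None and right.subtree_active))

    if tree.root.subtree_active or not prune:
        visit(tree.root)
    return result


def fcp_fixed(tree: PointCloudTree, box: BoundingBox3D, prune: bool = True,
              halfspace: bool = False) -> list[Point3D]:
    """Collect and remove all active points inside a fixed box."""
    return _collect_box(tree, box, None, prune, halfspace)


def fcp_expanding(tree: PointCloudTree, box: BoundingBox3D, b: float,
                  prune: bool = True, halfspace: bool = False
                  ) -> tuple[list[Point3D], BoundingBox3D]:
    """Collect active points while growing the box by ``b`` around each hit.

    Containment (and, with ``halfspace``, pruning) is always tested against
    the current, possibly already grown box.  A single pass may still miss
    points that only became reachable after the traversal passed their
    subtree; callers iterate to the fixpoint.  Returns the collected
    points and the final box.
    """
    if b <= 0:
        raise ContractError("expansion margin b must be > 0")
    points = _collect_box(tree, box, b, prune, halfspace)
    return points, box


def fcp_radius(tree: PointCloudTree, center: Point3D, radius: float,
               prune: bool = True) -> list[Point3D]:
    """Collect and remove active points within Euclidean ``radius`` of
    ``center`` (the per-point search primitive of classic region growing)."""
    if radius <= 0:
        raise ContractError("radius must be > 0")
    result: list[Point3D] = []
    if tree.root is None:
        return result
    cx, cy, cz = center.x, center.y, center.z
    r2 = radius * radius

    def visit(node: KdNode) -> None:
        tree.visit_counter += 1
        p = node.point
        if not node.removed:
            dx, dy, dz = p.x - cx, p.y - cy, p.z - cz
            if dx * dx + dy * dy + dz * dz <= r2:
                node.removed = True
                result.append(p)
        axis = node.axis
        v = (p.x, p.y, p.z)[axis]
        c = (cx, cy, cz)[axis]
        left, right = node.left, node.right
        if prune:
            if left is not None and left.subtree_active and c - radius <= v:
                visit(left)
            if right is not None and right.subtree_active and c + radius >= v:
                visit(right)
        else:
            if left is not None:
                visit(left)
            if right is not None:
                visit(right)
        node.subtree_active = (not node.removed
                               or (left is not None and left.subtree_active)
                               or (right is not None and right.subtree_active))

    if tree.root.subtree_active or not prune:
        visit(tree.root)
    return result
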