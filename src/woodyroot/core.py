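"""Core containers for digitized and simulated root systems.

A root system is a tree of polyline *axes*.  Each axis carries an ordered
sequence of 3-D nodes in the soil frame (right-handed, ``z = 0`` at the soil
surface, ``z < 0`` below ground, coordinates in cm), a per-axis radius, and a
topological attachment to a node of its parent axis.  Axes are typed:

====  =========================================================
type  meaning
====  =========================================================
0     stem (grafting point down to the basal node of the cutting)
1     static, 1-year-old woody adventitious roots
2     first-order laterals that emerge after planting
3     second-order / fine laterals
====  =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "AxisId",
    "PointRecord",
    "Axis",
    "RootSystem",
    "axis_root_type",
]

#: An axis identity: the tuple of integers of its ID-path prefix.  The stem is
#: the empty tuple; an axis ``(2, 1, 3)`` branches at point "2.1.3", i.e. point
#: 3 of axis ``(2, 1)``.
AxisId = tuple[int, ...]


def axis_root_type(axis_id: AxisId) -> int:
    """Root type implied by the hierarchy depth of an axis ID.

    The stem (empty prefix) is type 0; depth-1 axes are the adventitious
    type-1 roots, depth 2 the first-order laterals, and anything deeper is
    lumped into type 3 (fine roots).
    """
    return min(len(axis_id), 3)


@dataclass(frozen=True)
class PointRecord:
    """One digitized point: hierarchical dot-ID, organ code, position (cm)."""

    id_path: tuple[int, ...]
    organ: str  # "stem" | "root"
    position: np.ndarray  # shape (3,), digitizer frame, cm
    line_no: int

    def __post_init__(self) -> None:
        if len(self.id_path) == 0:
            raise ValueError(f"line {self.line_no}: empty ID path")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"line {self.line_no}: non-finite coordinates")


@dataclass
class Axis:
    """A polyline root (or stem) axis.

    ``parent`` is the :class:`AxisId` of the parent axis and ``parent_node``
    the index of the parent node this axis is attached to; both are ``None``
    for the stem.  After double-point merging, ``nodes[0]`` coincides exactly
    with ``parent.nodes[parent_node]``.
    """

    axis_id: AxisId
    nodes: np.ndarray  # shape (n, 3), soil frame, cm
    root_type: int = -1
    node_ages: Optional[np.ndarray] = None  # days since node creation
    radius: Optional[float] = None  # cm
    parent: Optional[AxisId] = None
    parent_node: Optional[int] = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("axis nodes must be an (n, 3) array")
        if len(self.nodes) < 2:
            raise ValueError(f"axis {self.axis_id}: needs >= 2 nodes")
        if self.root_type < 0:
            self.root_type = axis_root_type(self.axis_id)
        if self.node_ages is None:
            self.node_ages = np.zeros(len(self.nodes))
        else:
            self.node_ages = np.asarray(self.node_ages, dtype=float)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def segment_lengths(self) -> np.ndarray:
        """Euclidean length of each consecutive node pair (cm)."""
        return np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)

    @property
    def length(self) -> float:
        """Total axis length (cm): sum of segment lengths."""
        return float(self.segment_lengths().sum())

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each node, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths())])

    @property
    def tip(self) -> np.ndarray:
        return self.nodes[-1]


class RootSystem:
    """A tree of :class:`Axis` objects with exactly one stem (type 0).

    Axes are keyed by :class:`AxisId`.  Every non-stem axis must be reachable
    from the stem through its parent chain, and no two children may share the
    same (parent axis, parent node) attachment.
    """

    def __init__(
        self,
        axes: Sequence[Axis] = (),
        genotype: Optional[str] = None,
        age_days: Optional[float] = None,
    ) -> None:
        self.axes: dict[AxisId, Axis] = {}
        self.genotype = genotype
        self.age_days = age_days
        for ax in axes:
            self.add_axis(ax)

    # -- construction -----------------------------------------------------
    def add_axis(self, axis: Axis) -> None:
        if axis.axis_id in self.axes:
            raise ValueError(f"duplicate axis {axis.axis_id}")
        if axis.parent is not None:
            attach = (axis.parent, axis.parent_node)
            for other in self.axes.values():
                if (other.parent, other.parent_node) == attach:
                    raise ValueError(
                        f"axes {other.axis_id} and {axis.axis_id} share the "
                        f"attachment {attach}"
                    )
        self.axes[axis.axis_id] = axis

    # -- queries ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.axes)

    def __iter__(self) -> Iterator[Axis]:
        return iter(self.axes.values())

    def __getitem__(self, axis_id: AxisId) -> Axis:
        return self.axes[axis_id]

    @property
    def stem(self) -> Axis:
        stems = [a for a in self.axes.values() if a.root_type == 0]
        if len(stems) != 1:
            raise ValueError(f"expected exactly one stem axis, found {len(stems)}")
        return stems[0]

    def roots(self) -> list[Axis]:
        """All non-stem axes, in sorted axis-id order."""
        return [self.axes[k] for k in sorted(self.axes) if self.axes[k].root_type > 0]

    def axes_of_type(self, root_type: int) -> list[Axis]:
        return [self.axes[k] for k in sorted(self.axes) if self.axes[k].root_type == root_type]

    def children_of(self, axis_id: AxisId) -> list[Axis]:
        """Child axes sorted by attachment node index."""
        kids = [a for a in self.axes.values() if a.parent == axis_id]
        return sorted(kids, key=lambda a: (a.parent_node, a.axis_id))

    def total_length(self, root_type: Optional[int] = None) -> float:
        axs = self.roots() if root_type is None else self.axes_of_type(root_type)
        return float(sum(a.length for a in axs))

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        stem = self.stem  # raises if not exactly one
        for ax in self.axes.values():
            if ax is stem:
                if ax.parent is not None:
                    raise ValueError("stem must not have a parent")
                continue
            if ax.parent is None:
                raise ValueError(f"non-stem axis {ax.axis_id} has no parent")
            if ax.parent not in self.axes:
                raise ValueError(f"axis {ax.axis_id}: parent {ax.parent} missing")
            parent = self.axes[ax.parent]
            if not (0 <= ax.parent_node < parent.n_nodes):
                raise ValueError(f"axis {ax.axis_id}: parent node index out of range")
            if not np.allclose(ax.nodes[0], parent.nodes[ax.parent_node], atol=1e-9):
                raise ValueError(
                    f"axis {ax.axis_id}: first node does not coincide with its "
                    f"parent attachment node"
                )
            # acyclic parent chain terminating at the stem
            seen = {ax.axis_id}
            cur = ax
            while cur.parent is not None:
                if cur.parent in seen:
                    raise ValueError(f"cycle in parent chain at {cur.axis_id}")
                seen.add(cur.parent)
                cur = self.axes[cur.parent]
            if cur is not stem:
                raise ValueError(f"axis {ax.axis_id} not reachable from the stem")

    def copy(self) -> "RootSystem":
        import copy as _copy

        return _copy.deepcopy(self)
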