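"""Architectural trait extraction and growth-parameter estimation.

Computes the standard whole-root-system trait set from a digitized or
simulated :class:`~woodyroot.core.RootSystem` — per-type lengths, counts,
surface areas and volumes, system height and width, convex-hull occupancy
measures, and the root-length depth profile — and estimates the growth-model
parameters (basal/apical zone lengths, interlateral distance, insertion
angle, radius, asymptotic length and elongation rate, plagiotropism
probability) that drive the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import ConvexHull, QhullError

from .core import Axis, RootSystem
from .growth_sim import growth_length

__all__ = [
    "TraitReport",
    "ParamStats",
    "EstimatedParams",
    "compute_traits",
    "depth_profile",
    "distribute_by_depth",
    "branching_parameters",
    "estimate_lmax_r",
    "estimate_tropism_probability",
    "growth_length",
]

ROOT_TYPES = (1, 2, 3)


# ---------------------------------------------------------------------------
# depth binning


def distribute_by_depth(
    depths0: np.ndarray,
    depths1: np.ndarray,
    values: np.ndarray,
    layer_thickness: float = 1.0,
) -> pd.Series:
    """Apportion per-segment values to depth bins by linear clipping.

    Bins are half-open ``[k*h, (k+1)*h)`` in depth (positive downward); a
    segment's value is split across the bins its depth extent crosses, in
    proportion to the depth extent inside each bin.  Segments with zero
    vertical extent fall entirely into the bin containing their depth (a
    boundary point belongs to the deeper bin).  The returned Series is
    indexed by bin lower-bound depth (cm) and conserves ``sum(values)``.
    """
    h = float(layer_thickness)
    if h <= 0:
        raise ValueError("layer_thickness must be positive")
    acc: dict[int, float] = {}
    for d0, d1, v in zip(depths0, depths1, values):
        lo, hi = (d0, d1) if d0 <= d1 else (d1, d0)
        if hi - lo < 1e-12:
            k = math.floor(lo / h)
            acc[k] = acc.get(k, 0.0) + v
            continue
        k0 = math.floor(lo / h)
        k1 = math.ceil(hi / h)
        span = hi - lo
        for k in range(k0, k1):
            overlap = min(hi, (k + 1) * h) - max(lo, k * h)
            if overlap > 0:
                acc[k] = acc.get(k, 0.0) + v * overlap / span
    if not acc:
        return pd.Series(dtype=float)
    keys = sorted(acc)
    return pd.Series([acc[k] for k in keys], index=[k * h for k in keys], dtype=float)


def _root_segments(rs: RootSystem) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack (start, end, length) over all non-stem segments."""
    starts, ends = [], []
    for ax in rs.roots():
        starts.append(ax.nodes[:-1])
        ends.append(ax.nodes[1:])
    if not starts:
        z = np.zeros((0, 3))
        return z, z, np.zeros(0)
    p0 = np.vstack(starts)
    p1 = np.vstack(ends)
    return p0, p1, np.linalg.norm(p1 - p0, axis=1)


def depth_profile(rs: RootSystem, layer_thickness: float = 1.0) -> pd.Series:
    """Root length per depth layer (cm per layer), summed over all root types."""
    p0, p1, lengths = _root_segments(rs)
    return distribute_by_depth(-p0[:, 2], -p1[:, 2], lengths, layer_thickness)


# ---------------------------------------------------------------------------
# trait report


@dataclass
class TraitReport:
    """Whole-root-system trait summary (lengths in cm, areas cm^2, volumes cm^3)."""

    per_type: pd.DataFrame  # index: root type; columns: length, count, ...
    total_length: float
    total_surface_area: float
    total_volume: float
    height: float  # cm, vertical extent of root nodes below the surface
    width: float  # cm, max pairwise horizontal-projection distance
    bbox_extent: tuple[float, float, float]  # axis-aligned extents (cm)
    hull_volume_m3: float
    hull_area_xy_cm2: float
    hull_area_xz_cm2: float
    hull_degenerate: bool
    depth_profile: pd.Series  # root length (cm) per layer, index = layer top depth
    layer_thickness: float

    def to_dict(self) -> dict:
        d = {
            "per_type": self.per_type.to_dict(orient="index"),
            "total_length_cm": self.total_length,
            "total_surface_area_cm2": self.total_surface_area,
            "total_volume_cm3": self.total_volume,
            "height_cm": self.height,
            "width_cm": self.width,
            "bbox_extent_cm": list(self.bbox_extent),
            "hull_volume_m3": self.hull_volume_m3,
            "hull_area_xy_cm2": self.hull_area_xy_cm2,
            "hull_area_xz_cm2": self.hull_area_xz_cm2,
            "hull_degenerate": self.hull_degenerate,
            "depth_profile": {float(k): float(v) for k, v in self.depth_profile.items()},
            "layer_thickness_cm": self.layer_thickness,
        }
        return d


def _hull_volume(points: np.ndarray) -> tuple[float, bool]:
    if len(points) < 4:
        return 0.0, True
    try:
        return float(ConvexHull(points).volume), False
    except QhullError:
        return 0.0, True


def _hull_area_2d(points: np.ndarray) -> float:
    if len(points) < 3:
        return 0.0
    try:
        return float(ConvexHull(points).volume)  # in 2-D, .volume is the area
    except QhullError:
        return 0.0


def _max_pairwise_distance_2d(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 16:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # (near-)collinear clouds: brute force below
    d = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((d**2).sum(-1)).max())


def compute_traits(rs: RootSystem, layer_thickness: float = 1.0) -> TraitReport:
    """Compute the trait report for a root system in the soil frame.

    Surface and volume use the constant per-axis radius ``a``:
    per segment of length l, surface = 2*pi*a*l and volume = pi*a^2*l.
    Height is the vertical extent of root nodes below the soil surface;
    width the maximum pairwise distance between horizontal projections.
    The 3-D convex-hull volume is reported in m^3, planar hull areas in cm^2.
    """
    rows = {}
    for t in ROOT_TYPES:
        axes = rs.axes_of_type(t)
        lengths = np.array([a.length for a in axes])
        radii = np.array([a.radius for a in axes if a.radius is not None], dtype=float)
        surface = sum(
            2.0 * np.pi * a.radius * a.length for a in axes if a.radius is not None
        )
        volume = sum(
            np.pi * a.radius**2 * a.length for a in axes if a.radius is not None
        )
        rows[t] = {
            "length": float(lengths.sum()),
            "count": len(axes),
            "mean_length": float(lengths.mean()) if len(axes) else 0.0,
            "mean_diameter": float(2 * radii.mean()) if len(radii) else 0.0,
            "surface_area": float(surface),
            "volume": float(volume),
        }
    per_type = pd.DataFrame.from_dict(rows, orient="index")

    nodes = (
        np.vstack([a.nodes for a in rs.roots()])
        if rs.roots()
        else np.zeros((0, 3))
    )
    if len(nodes):
        depths = -nodes[:, 2]
        height = float(depths.max() - max(depths.min(), 0.0))
        width = _max_pairwise_distance_2d(nodes[:, :2])
        bbox = tuple(float(e) for e in np.ptp(nodes, axis=0))
        hull_cm3, degenerate = _hull_volume(nodes)
        area_xy = _hull_area_2d(nodes[:, [0, 1]])
        area_xz = _hull_area_2d(nodes[:, [0, 2]])
    else:
        height = width = 0.0
        bbox = (0.0, 0.0, 0.0)
        hull_cm3, degenerate = 0.0, True
        area_xy = area_xz = 0.0

    return TraitReport(
        per_type=per_type,
        total_length=float(per_type["length"].sum()),
        total_surface_area=float(per_type["surface_area"].sum()),
        total_volume=float(per_type["volume"].sum()),
        height=height,
        width=width,
        bbox_extent=bbox,
        hull_volume_m3=hull_cm3 / 1e6,
        hull_area_xy_cm2=area_xy,
        hull_area_xz_cm2=area_xz,
        hull_degenerate=degenerate,
        depth_profile=depth_profile(rs, layer_thickness),
        layer_thickness=layer_thickness,
    )


# ---------------------------------------------------------------------------
# parameter estimation


@dataclass
class ParamStats:
    mean: float
    sd: float
    n: int

    @property
    def se(self) -> float:
        return self.sd / math.sqrt(self.n) if self.n > 0 else float("nan")


def _stats(values: Sequence[float]) -> ParamStats:
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        return ParamStats(float("nan"), float("nan"), 0)
    sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    return ParamStats(float(v.mean()), sd, len(v))


@dataclass
class EstimatedParams:
    """Per-root-type branching statistics estimated from a root system.

    ``lb``/``la``/``ln`` are keyed by the *parent* axis type (the zones and
    spacings live on the mother root); ``theta`` and ``radius`` by the axis's
    own type.  Angles are in degrees, all lengths in cm.
    """

    lb: dict[int, ParamStats] = field(default_factory=dict)
    la: dict[int, ParamStats] = field(default_factory=dict)
    ln: dict[int, ParamStats] = field(default_factory=dict)
    theta: dict[int, ParamStats] = field(default_factory=dict)
    radius: dict[int, ParamStats] = field(default_factory=dict)


def _parent_direction(axis: Axis, node: int) -> np.ndarray:
    """Local direction of an axis at a node (central difference; one-sided at ends)."""
    i0 = max(node - 1, 0)
    i1 = min(node + 1, axis.n_nodes - 1)
    d = axis.nodes[i1] - axis.nodes[i0]
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError(f"degenerate direction at node {node} of axis {axis.axis_id}")
    return d / n


def insertion_angle(parent: Axis, child: Axis) -> float:
    """Angle (degrees) between the parent's local direction at the branch
    node and the child's first segment."""
    pd_ = _parent_direction(parent, child.parent_node)
    cd = child.nodes[1] - child.nodes[0]
    cd = cd / np.linalg.norm(cd)
    return float(np.degrees(np.arccos(np.clip(np.dot(pd_, cd), -1.0, 1.0))))


def branching_parameters(rs: RootSystem) -> EstimatedParams:
    """Estimate lb, la, ln, insertion angle and radius statistics per type.

    For each parent axis with >= 1 lateral: lb is the arc length from base to
    the first branch, la from the last branch to the tip, and ln the
    successive branch spacings (axes with >= 2 laterals).  Axes without
    laterals contribute nothing to lb/la/ln.
    """
    lb: dict[int, list] = {}
    la: dict[int, list] = {}
    ln: dict[int, list] = {}
    theta: dict[int, list] = {}
    radius: dict[int, list] = {}

    for ax in rs.roots():
        if ax.radius is not None:
            radius.setdefault(ax.root_type, []).append(ax.radius)
        kids = rs.children_of(ax.axis_id)
        if kids:
            arcs = ax.arc_lengths()
            s = [float(arcs[k.parent_node]) for k in kids]
            lb.setdefault(ax.root_type, []).append(s[0])
            la.setdefault(ax.root_type, []).append(ax.length - s[-1])
            if len(s) >= 2:
                ln.setdefault(ax.root_type, []).extend(np.diff(s).tolist())
        for k in kids:
            theta.setdefault(k.root_type, []).append(insertion_angle(ax, k))
    # laterals of the stem (type-1 insertions)
    stem = rs.stem
    for k in rs.children_of(stem.axis_id):
        theta.setdefault(k.root_type, []).append(insertion_angle(stem, k))

    return EstimatedParams(
        lb={t: _stats(v) for t, v in lb.items()},
        la={t: _stats(v) for t, v in la.items()},
        ln={t: _stats(v) for t, v in ln.items()},
        theta={t: _stats(v) for t, v in theta.items()},
        radius={t: _stats(v) for t, v in radius.items()},
    )


def estimate_lmax_r(
    root_lengths: Sequence[float],
    age: float,
    lmax_quantile: Optional[float] = None,
) -> tuple[float, float]:
    """Estimate (lmax, r) of the negative-exponential growth law.

    ``lmax`` is the observed maximum axis length (or the given quantile);
    ``r`` solves ``mean(length) = lmax * (1 - exp(-r*age/lmax))`` by root
    bracketing on (0, 10] cm/day.
    """
    lengths = np.asarray(list(root_lengths), dtype=float)
    if len(lengths) == 0:
        raise ValueError("need at least one root length")
    if age <= 0:
        raise ValueError("age must be positive")
    lmax = float(
        lengths.max() if lmax_quantile is None else np.quantile(lengths, lmax_quantile)
    )
    mean_len = float(lengths.mean())
    if mean_len <= 0:
        return lmax, 0.0
    if mean_len >= lmax:
        raise ValueError(
            f"mean length {mean_len:.3g} >= lmax {lmax:.3g}: r is unbounded"
        )

    def f(r: float) -> float:
        return growth_length(age, lmax, r) - mean_len

    r_hi = 10.0
    if f(r_hi) < 0:
        raise ValueError("r exceeds the search bound of 10 cm/day")
    return lmax, float(brentq(f, 1e-12, r_hi, xtol=1e-12, rtol=1e-12))


def estimate_tropism_probability(
    rs: RootSystem,
    length_threshold: float = 40.0,
    depth_threshold: float = 50.0,
) -> float:
    """Plagiotropism probability for type-2 roots from the tip distribution.

    Returns the fraction of type-2 roots longer than ``length_threshold``
    (cm) whose tip lies shallower than ``depth_threshold`` (cm depth).
    """
    qualifying = [a for a in rs.axes_of_type(2) if a.length > length_threshold]
    if not qualifying:
        raise ValueError(
            f"no type-2 axis longer than {length_threshold} cm; "
            "tropism probability undefined"
        )
    shallow = sum(1 for a in qualifying if -a.tip[2] < depth_threshold)
    return shallow / len(qualifying)
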