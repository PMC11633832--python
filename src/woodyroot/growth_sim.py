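"""Genotype-specific root growth simulation from a static initial system.

The simulator starts from a measured, immutable stem + adventitious root
skeleton (types 0 and 1), lets first-order laterals (type 2) emerge at the
attachment points where roots were present in the field data, and grows
type-2 and type-3 roots by the negative-exponential elongation law with a
probabilistic tropism: at each growth step a type-2 root is gravitropic
with probability ``p_gravi`` and plagiotropic otherwise, and the new
heading is the best of ``N`` randomly deflected candidates under the
assigned objective (gravitropism minimizes the heading's z component, i.e.
most downward wins; plagiotropism minimizes ``|z|``).

Node emergence times follow from inverting the growth law, so node ages are
exact rather than step-quantized.  Runs are fully reproducible for a fixed
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

from .core import Axis, AxisId, RootSystem
from .genotypes import GenotypeParams, RootTypeParams

__all__ = [
    "growth_length",
    "growth_time",
    "emergence_schedule",
    "tropism_next_heading",
    "TropismDiagnostics",
    "SimulationState",
    "SimulationResult",
    "initialize_static",
    "simulate",
]

GRAVI = "gravi"
PLAGIO = "plagio"


# ---------------------------------------------------------------------------
# elongation law


def growth_length(t: float, lmax: float, r: float) -> float:
    """Negative-exponential elongation: ``lmax * (1 - exp(-r*t/lmax))`` (cm).

    ``t`` in days since emergence, ``lmax`` the asymptotic length (cm), ``r``
    the initial elongation rate (cm/day).  Monotone increasing and bounded
    by ``lmax``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if lmax <= 0 or r <= 0:
        raise ValueError("lmax and r must be positive")
    return lmax * (1.0 - math.exp(-r * t / lmax))


def growth_time(length: float, lmax: float, r: float) -> float:
    """Inverse of :func:`growth_length`: days until the root reaches ``length``.

    Returns ``inf`` for ``length >= lmax`` (never reached).
    """
    if length <= 0:
        return 0.0
    if length >= lmax:
        return math.inf
    return -lmax / r * math.log(1.0 - length / lmax)


# ---------------------------------------------------------------------------
# branching schedule


def emergence_schedule(
    lb: float,
    ln_draws: Union[Iterable[float], Callable[[], float]],
    la: float,
    lmax_realized: float,
) -> list[float]:
    """Arc-length positions of lateral emergence points along a parent root.

    Positions start at the end of the basal zone (``s1 = lb``) and advance
    by successive interlateral-distance draws, truncated where the apical
    zone begins (``s <= lmax_realized - la``).  An empty schedule (basal and
    apical zones covering the whole root) is valid.
    """
    if lb < 0 or la < 0:
        raise ValueError("lb and la must be non-negative")
    limit = lmax_realized - la
    draw: Callable[[], float]
    if callable(ln_draws):
        draw = ln_draws
    else:
        it = iter(ln_draws)
        draw = lambda: next(it)
    positions: list[float] = []
    s = lb
    while s <= limit + 1e-12:
        positions.append(s)
        step = draw()
        if step <= 0:
            raise ValueError("interlateral distances must be positive")
        s += step
    return positions


# ---------------------------------------------------------------------------
# tropism


@dataclass
class TropismDiagnostics:
    """Counts of segment-level objective draws (type-2, per-segment mode)."""

    gravi_draws: int = 0
    plagio_draws: int = 0

    @property
    def total(self) -> int:
        return self.gravi_draws + self.plagio_draws

    @property
    def gravi_fraction(self) -> float:
        return self.gravi_draws / self.total if self.total else float("nan")


def _perp_basis(heading: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(heading[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(heading, ref)
    u /= np.linalg.norm(u)
    v = np.cross(heading, u)
    return u, v


def tropism_next_heading(
    old_heading: np.ndarray,
    root_type: int,
    params: RootTypeParams,
    rng: np.random.Generator,
    dx: float = 0.5,
    mode: str = "per_segment",
    assigned_objective: Optional[str] = None,
    diagnostics: Optional[TropismDiagnostics] = None,
) -> np.ndarray:
    """Draw the next unit growth heading for one segment.

    ``N`` candidate headings are generated, each the old heading deflected
    by an angle ``|N(0, sigma*sqrt(dx))|`` about a uniformly random azimuth;
    the candidate minimizing the tropism objective is returned.  For type-2
    roots in ``per_segment`` mode the objective is redrawn per call
    (gravitropic with probability ``p_gravi``); otherwise the fixed
    ``assigned_objective`` (or gravitropism) applies.
    """
    old = np.asarray(old_heading, dtype=float)
    norm = np.linalg.norm(old)
    if norm == 0:
        raise ValueError("old_heading must be a non-zero vector")
    old = old / norm

    if root_type == 2 and mode == "per_segment":
        u = rng.uniform()
        objective = GRAVI if u < params.p_gravi else PLAGIO
        if diagnostics is not None:
            if objective == GRAVI:
                diagnostics.gravi_draws += 1
            else:
                diagnostics.plagio_draws += 1
    else:
        objective = assigned_objective or GRAVI

    sigma_eff = params.sigma * math.sqrt(dx)
    u1, u2 = _perp_basis(old)
    best = None
    best_score = math.inf
    for _ in range(params.N):
        alpha = abs(rng.normal(0.0, sigma_eff)) if sigma_eff > 0 else 0.0
        beta = rng.uniform(0.0, 2.0 * math.pi)
        cand = math.cos(alpha) * old + math.sin(alpha) * (
            math.cos(beta) * u1 + math.sin(beta) * u2
        )
        score = cand[2] if objective == GRAVI else abs(cand[2])
        if score < best_score:
            best_score = score
            best = cand
    return best / np.linalg.norm(best)


# ---------------------------------------------------------------------------
# static initialization


@dataclass
class SimulationState:
    """Immutable starting point of a simulation: the static system (types 0
    and 1) plus the scheduled type-2 emergence attachments."""

    static_system: RootSystem
    emergence_points: list[tuple[AxisId, int]]
    params: GenotypeParams


def initialize_static(
    source: Union[RootSystem, str], params: GenotypeParams
) -> SimulationState:
    """Build the simulation state from a measured root system (or RSML path).

    The stem and type-1 axes are copied verbatim and never grow (persistent
    woody roots); each attachment where a type-2 root existed in the source
    becomes a scheduled lateral emergence point.  Measured type-2/3 geometry
    is discarded — the simulation regenerates it.
    """
    if not isinstance(source, RootSystem):
        from .rsml_io import read_rsml

        source = read_rsml(source)
    source.validate()
    if not source.axes_of_type(1):
        raise ValueError("static initialization needs at least one type-1 axis")

    static = RootSystem(genotype=source.genotype, age_days=source.age_days)
    for ax in [source.stem] + source.axes_of_type(1):
        axis = Axis(
            axis_id=ax.axis_id,
            nodes=ax.nodes.copy(),
            root_type=ax.root_type,
            node_ages=ax.node_ages.copy(),
            radius=ax.radius,
            parent=ax.parent,
            parent_node=ax.parent_node,
        )
        static.add_axis(axis)

    emergence: list[tuple[AxisId, int]] = []
    for ax in source.axes_of_type(2):
        if ax.parent not in static.axes:
            raise ValueError(
                f"type-2 axis {ax.axis_id} attaches to {ax.parent}, which is "
                f"not part of the static system"
            )
        if not 0 <= ax.parent_node < static[ax.parent].n_nodes:
            raise ValueError(f"type-2 axis {ax.axis_id}: emergence point off-axis")
        emergence.append((ax.parent, ax.parent_node))
    emergence.sort()
    static.validate()
    return SimulationState(static, emergence, params)


# ---------------------------------------------------------------------------
# simulation


@dataclass
class _GrowingRoot:
    axis_id: AxisId
    root_type: int
    parent: AxisId
    parent_node: int
    t0: float  # emergence time (days)
    lmax: float
    r: float
    radius: float
    heading: np.ndarray  # current unit heading
    assigned_objective: Optional[str]
    schedule: list[float]  # pending branch arc positions (ascending)
    la: float
    nodes: list[np.ndarray] = field(default_factory=list)
    node_times: list[float] = field(default_factory=list)
    grown: float = 0.0  # emitted arc length
    next_branch: int = 0  # index into schedule


@dataclass
class SimulationResult:
    root_system: RootSystem
    diagnostics: TropismDiagnostics
    days: float
    seed: int


def _initial_heading(
    parent_nodes: np.ndarray,
    parent_node: int,
    theta_deg: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Parent heading at the attachment node rotated by the insertion angle
    about a uniformly random azimuth."""
    i0 = max(parent_node - 1, 0)
    i1 = min(parent_node + 1, len(parent_nodes) - 1)
    d = parent_nodes[i1] - parent_nodes[i0]
    n = np.linalg.norm(d)
    d = d / n if n > 0 else np.array([0.0, 0.0, -1.0])
    u, v = _perp_basis(d)
    beta = rng.uniform(0.0, 2.0 * math.pi)
    th = math.radians(theta_deg)
    h = math.cos(th) * d + math.sin(th) * (math.cos(beta) * u + math.sin(beta) * v)
    return h / np.linalg.norm(h)


def simulate(
    state: SimulationState,
    days: float = 180.0,
    dt: float = 1.0,
    seed: int = 0,
) -> SimulationResult:
    """Grow the root system for ``days`` days from the static system.

    Type-2 laterals emerge at the scheduled static attachment points (all at
    ``emergence_time``, each with probability ``emergence_prob``); type-3
    laterals emerge along type-2 parents once the parent length has passed
    their scheduled position plus the apical-zone delay.  Each root's
    per-axis parameters (radius, insertion angle, branching zones) are
    sampled once at creation from positive-truncated normals.

    Returns a :class:`SimulationResult` whose root system carries per-node
    ages (days since node creation at the end of the run).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if days < 0:
        raise ValueError("days must be non-negative")
    params = state.params
    rng = np.random.default_rng(seed)
    diag = TropismDiagnostics()

    rs = state.static_system.copy()
    growing: list[_GrowingRoot] = []

    def spawn(
        parent_id: AxisId,
        parent_node: int,
        root_type: int,
        t0: float,
        parent_nodes: np.ndarray,
        attach_point: np.ndarray,
    ) -> None:
        tp = params.for_type(root_type)
        if params.emergence_prob < 1.0 and rng.uniform() >= params.emergence_prob:
            return
        radius = tp.a.sample(rng)
        theta = tp.theta.sample(rng, upper=180.0)
        heading = _initial_heading(parent_nodes, parent_node, theta, rng)
        if root_type == 2 and params.tropism_mode == "per_root":
            assigned = GRAVI if rng.uniform() < tp.p_gravi else PLAGIO
        elif root_type == 2:
            assigned = None  # redrawn per segment
        else:
            assigned = GRAVI  # type 3 fixed gravitropic
        schedule: list[float] = []
        la = 0.0
        if root_type == 2 and tp.lb is not None and tp.ln is not None and tp.la is not None:
            lb = tp.lb.sample(rng)
            la = tp.la.sample(rng)
            if lb < tp.lmax - la:
                schedule = emergence_schedule(lb, lambda: tp.ln.sample(rng), la, tp.lmax)
        axis_id = parent_id + (parent_node + 1,)
        while axis_id in rs.axes or any(g.axis_id == axis_id for g in growing):
            axis_id = axis_id[:-1] + (axis_id[-1] + 1000,)
        growing.append(
            _GrowingRoot(
                axis_id=axis_id,
                root_type=root_type,
                parent=parent_id,
                parent_node=parent_node,
                t0=t0,
                lmax=tp.lmax,
                r=tp.r,
                radius=radius,
                heading=heading,
                assigned_objective=assigned,
                schedule=schedule,
                la=la,
                nodes=[np.asarray(attach_point, dtype=float).copy()],
                node_times=[t0],
            )
        )

    # type-2 laterals at the static emergence points, all at emergence_time
    for parent_id, node_idx in state.emergence_points:
        parent = rs[parent_id]
        spawn(
            parent_id,
            node_idx,
            2,
            params.emergence_time,
            parent.nodes,
            parent.nodes[node_idx],
        )

    def extend(g: _GrowingRoot, target: float) -> None:
        """Emit full-dx segments up to ``target`` arc length (cm)."""
        tp = params.for_type(g.root_type)
        while g.grown + params.dx <= target + 1e-12:
            _advance(g, params.dx, tp)

    def _advance(g: _GrowingRoot, step: float, tp: RootTypeParams) -> None:
        if len(g.nodes) > 1:
            # the first segment is laid down along the sampled insertion
            # heading; tropism steers from the second segment onward
            g.heading = tropism_next_heading(
                g.heading,
                g.root_type,
                tp,
                rng,
                dx=params.dx,
                mode=params.tropism_mode,
                assigned_objective=g.assigned_objective,
                diagnostics=diag,
            )
        end = g.grown + step
        # split the segment at any emergence positions it crosses
        while (
            g.next_branch < len(g.schedule)
            and g.schedule[g.next_branch] <= end + 1e-12
        ):
            s_pos = g.schedule[g.next_branch]
            g.next_branch += 1
            if s_pos - g.grown > 1e-12:
                _emit_node(g, s_pos)
            # activation once the parent length first reaches s + la
            t_active = g.t0 + growth_time(s_pos + g.la, g.lmax, g.r)
            if math.isfinite(t_active) and g.root_type == 2:
                spawn(
                    g.axis_id,
                    len(g.nodes) - 1,
                    3,
                    t_active,
                    np.asarray(g.nodes),
                    g.nodes[-1],
                )
        if end - g.grown > 1e-12:
            _emit_node(g, end)

    def _emit_node(g: _GrowingRoot, s: float) -> None:
        step = s - g.grown
        g.nodes.append(g.nodes[-1] + g.heading * step)
        g.node_times.append(g.t0 + growth_time(s, g.lmax, g.r))
        g.grown = s

    t = 0.0
    while t < days - 1e-12:
        step = min(dt, days - t)
        t += step
        i = 0
        while i < len(growing):  # new roots spawned mid-step join this pass
            g = growing[i]
            age = t - g.t0
            if age > 0:
                extend(g, growth_length(age, g.lmax, g.r))
            i += 1

    # final partial segments so each arc length equals growth_length exactly
    for g in growing:
        age = days - g.t0
        if age <= 0:
            continue
        target = growth_length(age, g.lmax, g.r)
        extend(g, target)
        if target - g.grown > 1e-9:
            _advance(g, target - g.grown, params.for_type(g.root_type))

    # materialize grown axes (roots that never produced a segment are dropped)
    for g in growing:
        if len(g.nodes) < 2:
            continue
        ages = days - np.asarray(g.node_times)
        rs.add_axis(
            Axis(
                axis_id=g.axis_id,
                nodes=np.vstack(g.nodes),
                root_type=g.root_type,
                node_ages=np.clip(ages, 0.0, None),
                radius=g.radius,
                parent=g.parent,
                parent_node=g.parent_node,
            )
        )
    rs.age_days = days
    rs.validate()
    return SimulationResult(root_system=rs, diagnostics=diag, days=days, seed=seed)
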