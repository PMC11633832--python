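"""Synthetic test-input generation: digitizer files from simulated ground
truth, calibration-object records, and xylem vessel tables.

No field dataset ships with this package; every pipeline stage is instead
exercised against data generated here.  The generator runs the growth
simulator, down-samples each axis polyline to digitization-like vertex
density (vertices kept where the heading changes by more than a threshold,
plus all branch points — mimicking the field protocol of placing points at
direction changes and branchings), emits the digitizer text dialect
including double points at branchings, and optionally applies a noise
model emulating technical jitter, operator double-point error, and fine
root loss during excavation.

What it does *not* emulate: soil occlusion, root breakage/reattachment,
electromagnetic field distortion, or operator annotation mistakes.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .accuracy import CalibrationRecord
from .core import Axis, AxisId, RootSystem
from .genotypes import GenotypeParams
from .growth_sim import SimulationResult, initialize_static, simulate
from .hydraulics import CrossSection

__all__ = [
    "NoiseModel",
    "SynthResult",
    "make_static_template",
    "synth_root_system",
    "write_digitizer_text",
    "downsample",
    "synth_calibration",
    "synth_vessels",
    "vessel_dataframe",
]


@dataclass(frozen=True)
class NoiseModel:
    """Digitization noise: per-coordinate point jitter (cm), expected
    double-point deviation magnitude (cm), and the fraction of fine-root
    (type 3) length lost to excavation.

    Defaults follow the error magnitudes of the digitization validation:
    ~0.15 cm technical jitter and ~0.18 cm mean double-point deviation;
    fine-root loss defaults to zero (it is a scenario, not a constant).
    """

    point_jitter_sd: float = 0.15
    double_point_deviation: float = 0.18
    fine_root_loss: float = 0.0

    def __post_init__(self) -> None:
        if self.point_jitter_sd < 0 or self.double_point_deviation < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.fine_root_loss <= 1.0:
            raise ValueError("fine_root_loss must lie in [0, 1]")


ZERO_NOISE = NoiseModel(0.0, 0.0, 0.0)


def _iso_offset(rng: np.random.Generator, expected_norm: float) -> np.ndarray:
    """Random 3-vector with uniformly random direction and E||v|| = expected_norm."""
    if expected_norm == 0:
        return np.zeros(3)
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    mag = abs(rng.normal(0.0, expected_norm * math.sqrt(math.pi / 2.0)))
    return d * mag


# ---------------------------------------------------------------------------
# static template


def make_static_template(
    n_type1: int = 8,
    type1_length: float = 13.0,
    n_emergence_per_axis: int = 3,
    basal_depth: float = 20.0,
    seed: int = 0,
    type1_radius: float = 0.2,
) -> RootSystem:
    """Build a plausible static initial root system (stem + type-1 roots).

    Mimics a mechanically planted rooted cutting: the stem runs from the
    grafting point through the soil surface down to ~``basal_depth`` cm,
    where ``n_type1`` woody adventitious roots of ~``type1_length`` cm
    radiate outward and downward.  Each type-1 axis carries
    ``n_emergence_per_axis`` short type-2 stubs marking the lateral
    emergence points that the simulator will regrow.
    """
    rng = np.random.default_rng(seed)
    rs = RootSystem(genotype="synthetic")
    # stem: grafting point, soil horizon, then one basal node per type-1 root
    zs = np.concatenate(
        [[15.0, 0.0], np.linspace(-basal_depth + 2.0, -basal_depth, n_type1)]
    )
    stem_nodes = np.column_stack([np.zeros_like(zs), np.zeros_like(zs), zs])
    rs.add_axis(Axis(axis_id=(), nodes=stem_nodes, root_type=0, radius=0.5))

    n_nodes = max(6, n_emergence_per_axis + 2)
    for k in range(n_type1):
        azim = 2.0 * math.pi * k / n_type1 + rng.normal(0, 0.15)
        dip = math.radians(rng.uniform(20.0, 60.0))  # below horizontal
        heading = np.array(
            [math.cos(azim) * math.cos(dip), math.sin(azim) * math.cos(dip), -math.sin(dip)]
        )
        stem_node = 2 + k
        base = stem_nodes[stem_node]
        step = type1_length / (n_nodes - 1)
        nodes = [base]
        h = heading.copy()
        for _ in range(n_nodes - 1):
            wiggle = rng.normal(0, 0.08, size=3)
            h = h + wiggle
            h /= np.linalg.norm(h)
            nodes.append(nodes[-1] + h * step)
        axis_id: AxisId = (stem_node,)
        rs.add_axis(
            Axis(
                axis_id=axis_id,
                nodes=np.vstack(nodes),
                root_type=1,
                radius=type1_radius,
                parent=(),
                parent_node=stem_node,
            )
        )
        # type-2 emergence stubs at distinct interior nodes
        interior = list(range(1, n_nodes))
        picks = sorted(
            rng.choice(interior, size=min(n_emergence_per_axis, len(interior)), replace=False)
        )
        for j, node_idx in enumerate(picks):
            stub_dir = np.array([math.cos(azim + 1.0 + j), math.sin(azim + 1.0 + j), -0.5])
            stub_dir /= np.linalg.norm(stub_dir)
            p0 = rs[axis_id].nodes[node_idx]
            rs.add_axis(
                Axis(
                    axis_id=axis_id + (node_idx + 1,),
                    nodes=np.vstack([p0, p0 + stub_dir * 1.0]),
                    root_type=2,
                    radius=0.1,
                    parent=axis_id,
                    parent_node=int(node_idx),
                )
            )
    rs.validate()
    return rs


# ---------------------------------------------------------------------------
# down-sampling


def _keep_indices(nodes: np.ndarray, branch_nodes: set[int], angle_deg: float) -> list[int]:
    keep = {0, len(nodes) - 1} | branch_nodes
    cos_thresh = math.cos(math.radians(angle_deg))
    last_dir = None
    prev_kept = 0
    for i in range(1, len(nodes) - 1):
        d = nodes[i] - nodes[prev_kept]
        n = np.linalg.norm(d)
        if n == 0:
            continue
        d /= n
        if last_dir is None:
            last_dir = d
            continue
        if float(np.dot(last_dir, d)) < cos_thresh or i in keep:
            keep.add(i)
            prev_kept = i
            last_dir = None
    return sorted(keep)


def downsample(
    rs: RootSystem,
    angle_deg: float = 10.0,
    fine_root_loss: float = 0.0,
    min_fine_length: float = 0.5,
) -> RootSystem:
    """Reduce each polyline to digitization-like vertex density.

    Keeps every branch node and endpoints, plus vertices where the heading
    has turned by more than ``angle_deg`` since the last kept vertex.
    ``fine_root_loss`` truncates each type-3 axis to that fraction less of
    its length (excavation loss: length shrinks, counts are preserved).
    """
    out = RootSystem(genotype=rs.genotype, age_days=rs.age_days)
    remap: dict[AxisId, dict[int, int]] = {}
    new_id: dict[AxisId, AxisId] = {}
    for aid in sorted(rs.axes, key=lambda a: (len(a), a)):
        ax = rs[aid]
        branch_nodes = {c.parent_node for c in rs.children_of(aid)}
        nodes = ax.nodes
        ages = ax.node_ages
        if ax.root_type == 3 and fine_root_loss > 0:
            arcs = ax.arc_lengths()
            target = max((1.0 - fine_root_loss) * arcs[-1], min(min_fine_length, arcs[-1]))
            k = int(np.searchsorted(arcs, target))
            k = max(k, 1)
            nodes = nodes[: k + 1].copy()
            ages = ages[: k + 1].copy()
            if arcs[k] > target:  # cut the last segment at the exact arc position
                frac = (target - arcs[k - 1]) / (arcs[k] - arcs[k - 1])
                nodes[k] = nodes[k - 1] + frac * (nodes[k] - nodes[k - 1])
        if ax.root_type == 0:
            # the stem is digitized point-by-point; never thin it, so the
            # soil-reference point survives
            keep = list(range(len(nodes)))
        else:
            keep = _keep_indices(
                nodes, {b for b in branch_nodes if b < len(nodes)}, angle_deg
            )
        remap[aid] = {old: new for new, old in enumerate(keep)}
        parent = ax.parent
        pnode = ax.parent_node
        if parent is not None:
            pnode = remap[parent][ax.parent_node]
        # re-derive the axis ID from the thinned parent polyline so it keeps
        # encoding the parent branch point per the digitizer dialect
        if ax.root_type == 0:
            nid: AxisId = ()
        elif parent == ():
            nid = (pnode,)
        else:
            nid = new_id[parent] + (pnode + 1,)
        new_id[aid] = nid
        out.add_axis(
            Axis(
                axis_id=nid,
                nodes=nodes[keep],
                root_type=ax.root_type,
                node_ages=ages[keep],
                radius=ax.radius,
                parent=None if parent is None else new_id[parent],
                parent_node=pnode,
            )
        )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# digitizer text emission


def _soil_to_digitizer(p: np.ndarray) -> np.ndarray:
    """Inverse frame map: soil (x, y, z) -> digitizer (-z, x, y)."""
    return np.array([-p[2], p[0], p[1]])


def write_digitizer_text(
    rs: RootSystem,
    noise: NoiseModel = ZERO_NOISE,
    rng: Optional[np.random.Generator] = None,
    digitizer_offset: Sequence[float] = (60.0, 25.0, -40.0),
) -> str:
    """Emit the digitizer point-file dialect for a root system.

    Stem nodes become points 0..n-1; each root axis is written under the
    full ID of its parent branch point, its first point being the double
    point that duplicates the branch point (displaced by the double-point
    noise).  Coordinates are written in the digitizer frame shifted by
    ``digitizer_offset``.
    """
    rng = rng or np.random.default_rng(0)
    offset = np.asarray(digitizer_offset, dtype=float)
    buf = io.StringIO()
    buf.write("# synthetic digitizer export\n")
    buf.write("# soil_ref=1\n")

    def emit(id_path: tuple[int, ...], organ: str, p_soil: np.ndarray) -> None:
        p = _soil_to_digitizer(p_soil) + offset
        buf.write(
            f"{'.'.join(map(str, id_path))} {organ} "
            f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n"
        )

    def jitter() -> np.ndarray:
        if noise.point_jitter_sd == 0:
            return np.zeros(3)
        return rng.normal(0.0, noise.point_jitter_sd, size=3)

    stem = rs.stem
    # stem point ids must be the node positions (dialect: plain integers)
    for i, node in enumerate(stem.nodes):
        emit((i,), "stem", node + (jitter() if i > 1 else np.zeros(3)))
        # points 0/1 kept exact so the soil reference stays clean

    point_id: dict[tuple[AxisId, int], tuple[int, ...]] = {
        ((), i): (i,) for i in range(stem.n_nodes)
    }

    for aid in sorted(rs.axes, key=lambda a: (len(a), a)):
        ax = rs[aid]
        if ax.root_type == 0:
            continue
        prefix = point_id[(ax.parent, ax.parent_node)]
        # double point: duplicates the branch point, displaced by operator error
        emit(
            prefix + (1,),
            "root",
            ax.nodes[0] + _iso_offset(rng, noise.double_point_deviation) + jitter(),
        )
        point_id[(aid, 0)] = prefix + (1,)
        for i in range(1, ax.n_nodes):
            pid = prefix + (i + 1,)
            emit(pid, "root", ax.nodes[i] + jitter())
            point_id[(aid, i)] = pid
    return buf.getvalue()


@dataclass
class SynthResult:
    """Ground truth and digitizer file from one synthetic run."""

    full_truth: RootSystem  # simulator output, full resolution
    digitized_truth: RootSystem  # down-sampled (and loss-applied), noise-free
    text: str  # digitizer file content (noise applied)
    simulation: SimulationResult


def synth_root_system(
    params: GenotypeParams,
    static_template: Optional[RootSystem] = None,
    days: float = 180.0,
    seed: int = 0,
    noise: NoiseModel = NoiseModel(),
    angle_deg: float = 10.0,
) -> SynthResult:
    """Simulate a root system and emit its digitizer point file.

    Runs the growth simulator on the (default or given) static template,
    down-samples to digitization density, applies the noise model, and
    returns ground truth alongside the file text.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 929]))
    template = static_template or make_static_template(seed=seed)
    state = initialize_static(template, params)
    sim = simulate(state, days=days, dt=1.0, seed=seed)
    truth = downsample(sim.root_system, angle_deg=angle_deg, fine_root_loss=noise.fine_root_loss)
    text = write_digitizer_text(truth, noise=noise, rng=rng)
    return SynthResult(
        full_truth=sim.root_system,
        digitized_truth=truth,
        text=text,
        simulation=sim,
    )


# ---------------------------------------------------------------------------
# calibration records


def synth_calibration(
    n_poses: int = 30,
    true_lengths: Sequence[float] = (5.0, 10.0),
    noise_sd: float = 0.15,
    max_distance: float = 180.0,
    seed: int = 0,
    distance_noise_slope: float = 0.0,
) -> list[CalibrationRecord]:
    """Synthetic standard-object digitizations at random poses.

    Each pose yields one record per known segment length; the digitized
    length carries additive N(0, sd) noise, with ``sd = noise_sd +
    distance_noise_slope * distance`` for the distance-dependent option.
    """
    if n_poses < 1:
        raise ValueError("need at least one pose")
    rng = np.random.default_rng(seed)
    records = []
    for pose in range(n_poses):
        distance = float(rng.uniform(20.0, max_distance))
        for L in true_lengths:
            sd = noise_sd + distance_noise_slope * distance
            x = float(L + rng.normal(0.0, sd)) if sd > 0 else float(L)
            records.append(
                CalibrationRecord(
                    digitized_length=x,
                    true_length=float(L),
                    distance_to_transmitter=distance,
                    pose=pose,
                )
            )
    return records


# ---------------------------------------------------------------------------
# vessel tables


def synth_vessels(
    n_sections: int = 33,
    diameter_range: tuple[float, float] = (0.05, 0.5),
    mean_vessels: float = 25.0,
    seed: int = 0,
    genotype: str = "synthetic",
) -> list[CrossSection]:
    """Synthetic xylem cross-sections with lognormal vessel dimensions.

    Vessel size scales with root diameter so the resulting Kh-diameter
    cloud follows a power-law mean, as real conductivity allometries do.
    Minor <= major is enforced by sorting each drawn pair.
    """
    if n_sections < 1:
        raise ValueError("need at least one section")
    rng = np.random.default_rng(seed)
    lo, hi = diameter_range
    out = []
    for k in range(n_sections):
        d = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        n_v = max(1, int(rng.poisson(mean_vessels)))
        mean_um = 15.0 + 80.0 * d  # vessel calibre grows with root diameter
        draws = rng.lognormal(math.log(mean_um), 0.3, size=(n_v, 2))
        minor = draws.min(axis=1)
        major = draws.max(axis=1)
        zone = ("type1", "type2_suberized", "type2_unsuberized")[k % 3]
        out.append(
            CrossSection.from_micrometres(
                minor, major, root_diameter_cm=d, genotype=genotype, zone=zone
            )
        )
    return out


def vessel_dataframe(sections: Sequence[CrossSection]) -> pd.DataFrame:
    """Flatten cross-sections into the CSV table schema."""
    rows = []
    for i, cs in enumerate(sections):
        for minor, major in cs.vessels * 1e6:
            rows.append(
                {
                    "genotype": cs.genotype,
                    "zone": cs.zone,
                    "root_diameter_cm": cs.root_diameter_cm,
                    "section": i,
                    "minor_um": minor,
                    "major_um": major,
                }
            )
    return pd.DataFrame(rows)
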