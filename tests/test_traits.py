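import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.spatial import ConvexHull

from woodyroot import (
    Axis,
    RootSystem,
    branching_parameters,
    compute_traits,
    depth_profile,
    distribute_by_depth,
    estimate_lmax_r,
    insertion_angle,
)
from woodyroot.growth_sim import growth_length

from conftest import straight_system


# ---------------------------------------------------------------------------
# depth distribution


def test_distribute_simple_split():
    # a 2 cm segment from 0.5 to 1.5 cm depth splits half and half
    out = distribute_by_depth([0.5], [1.5], [2.0], layer_thickness=1.0)
    assert out[0.0] == pytest.approx(1.0)
    assert out[1.0] == pytest.approx(1.0)


def test_distribute_zero_extent_goes_to_own_bin():
    out = distribute_by_depth([2.0], [2.0], [3.0], layer_thickness=1.0)
    assert out[2.0] == pytest.approx(3.0)


def test_distribute_conserves_mass_randomized():
    rng = np.random.default_rng(42)
    d0 = rng.uniform(-5, 120, size=500)
    d1 = d0 + rng.normal(0, 7, size=500)
    v = rng.uniform(0, 3, size=500)
    for h in (0.5, 1.0, 2.5):
        out = distribute_by_depth(d0, d1, v, layer_thickness=h)
        assert out.sum() == pytest.approx(v.sum(), rel=1e-12)
        assert (out >= -1e-12).all()


def test_depth_profile_conserves_total_length(sim_180):
    rs = sim_180.root_system
    total = sum(a.length for a in rs.roots())
    prof = depth_profile(rs, layer_thickness=1.0)
    assert prof.sum() == pytest.approx(total, rel=1e-9)
    # refining the layers never changes the total
    assert depth_profile(rs, layer_thickness=0.25).sum() == pytest.approx(
        total, rel=1e-9
    )


# ---------------------------------------------------------------------------
# trait report


def test_traits_straight_root_exact():
    rs = straight_system(stem_len=10.0, root_len=50.0, n_seg=10, radius=0.05)
    rep = compute_traits(rs)
    row = rep.per_type.loc[1]
    assert row["length"] == pytest.approx(50.0)
    assert row["count"] == 1
    assert row["mean_diameter"] == pytest.approx(0.1)
    assert row["surface_area"] == pytest.approx(2 * math.pi * 0.05 * 50.0)
    assert row["volume"] == pytest.approx(math.pi * 0.05**2 * 50.0)
    assert rep.height == pytest.approx(50.0)
    assert rep.width == pytest.approx(0.0)
    assert rep.hull_degenerate  # a line has no 3-D hull


def test_traits_hull_against_scipy_oracle(sim_180):
    rs = sim_180.root_system
    rep = compute_traits(rs)
    pts = np.vstack([a.nodes for a in rs.roots()])
    hull = ConvexHull(pts)
    assert rep.hull_volume_m3 == pytest.approx(hull.volume / 1e6, rel=1e-9)
    assert rep.hull_area_xy_cm2 == pytest.approx(
        ConvexHull(pts[:, :2]).volume, rel=1e-9
    )
    # width equals the brute-force max pairwise horizontal distance
    d = pts[:, None, :2] - pts[None, :, :2]
    assert rep.width == pytest.approx(np.sqrt((d**2).sum(-1)).max(), rel=1e-9)


def test_traits_counts_match_axes(sim_180):
    rs = sim_180.root_system
    rep = compute_traits(rs)
    for t in (1, 2, 3):
        assert rep.per_type.loc[t, "count"] == len(rs.axes_of_type(t))
    assert rep.total_length == pytest.approx(sum(a.length for a in rs.roots()))


# ---------------------------------------------------------------------------
# parameter estimation


def test_insertion_angle_constructed():
    # parent along +x, child rising at 30 degrees in the x-z plane
    parent = Axis(
        axis_id=(1,),
        nodes=np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float),
        root_type=1,
        parent=(),
        parent_node=0,
    )
    ang = math.radians(30)
    child = Axis(
        axis_id=(1, 2),
        nodes=np.array([[1, 0, 0], [1 + math.cos(ang), 0, math.sin(ang)]]),
        root_type=2,
        parent=(1,),
        parent_node=1,
    )
    assert insertion_angle(parent, child) == pytest.approx(30.0, abs=1e-9)


def test_branching_parameters_hand_built():
    rs = RootSystem()
    rs.add_axis(Axis(axis_id=(), nodes=np.array([[0, 0, 5], [0, 0, 0.0]]), root_type=0))
    # type-1 parent: 10 nodes, 1 cm spacing along x at depth 0
    x = np.arange(10.0)
    nodes = np.column_stack([x, np.zeros(10), np.zeros(10)])
    nodes[0] = [0, 0, 0]
    rs.add_axis(
        Axis(axis_id=(1,), nodes=nodes, root_type=1, parent=(), parent_node=1)
    )
    # two laterals at arc 2.0 and 5.0
    for node in (2, 5):
        p0 = nodes[node]
        rs.add_axis(
            Axis(
                axis_id=(1, node + 1),
                nodes=np.vstack([p0, p0 + [0, 1.0, 0]]),
                root_type=2,
                parent=(1,),
                parent_node=node,
            )
        )
    est = branching_parameters(rs)
    assert est.lb[1].mean == pytest.approx(2.0)
    assert est.ln[1].mean == pytest.approx(3.0)
    assert est.la[1].mean == pytest.approx(9.0 - 5.0)
    assert est.theta[2].mean == pytest.approx(90.0)


def test_estimate_lmax_r_worked_example():
    # mean 40.7 cm over 180 d with observed max 99.5 cm
    lengths = [99.5, 40.7 * 3 - 99.5 - 20.0, 20.0]  # mean exactly 40.7
    lmax, r = estimate_lmax_r(lengths, age=180.0)
    assert lmax == pytest.approx(99.5)
    # independent oracle: solve the growth law directly
    r_oracle = brentq(
        lambda rr: 99.5 * (1 - math.exp(-rr * 180.0 / 99.5)) - 40.7, 1e-9, 5.0
    )
    assert r == pytest.approx(r_oracle, rel=1e-9)
    assert r == pytest.approx(0.2907, abs=5e-4)


def test_estimate_lmax_r_recovers_simulated(sim_180):
    rs = sim_180.root_system
    lengths = [a.length for a in rs.axes_of_type(2)]
    lmax, r = estimate_lmax_r(lengths, age=180.0)
    # lengths are deterministic under the growth law, so r is recovered from
    # mean == growth_length(180) given the estimated lmax
    assert growth_length(180.0, lmax, r) == pytest.approx(np.mean(lengths), rel=1e-9)


def test_estimate_lmax_r_errors():
    with pytest.raises(ValueError):
        estimate_lmax_r([], age=100.0)
    with pytest.raises(ValueError):
        estimate_lmax_r([10.0, 10.0], age=0.0)
    with pytest.raises(ValueError):
        estimate_lmax_r([10.0, 10.0], age=100.0)  # mean == lmax
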