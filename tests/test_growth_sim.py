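import dataclasses
import math

import numpy as np
import pytest

from woodyroot import GENOTYPES, growth_length, growth_time
from woodyroot.growth_sim import (
    GRAVI,
    PLAGIO,
    TropismDiagnostics,
    emergence_schedule,
    initialize_static,
    simulate,
    tropism_next_heading,
)
from woodyroot.synthetic_fixtures import make_static_template


# ---------------------------------------------------------------------------
# growth law


def test_growth_law_shape():
    lmax, r = 99.5, 0.28
    assert growth_length(0.0, lmax, r) == 0.0
    # initial slope is r
    assert growth_length(1e-6, lmax, r) / 1e-6 == pytest.approx(r, rel=1e-4)
    # monotone, saturating at lmax
    t = np.linspace(0, 2000, 200)
    l = np.array([growth_length(ti, lmax, r) for ti in t])
    assert (np.diff(l) > 0).all()
    assert l[-1] < lmax
    assert growth_length(1e7, lmax, r) == pytest.approx(lmax, rel=1e-9)


def test_growth_time_inverts_growth_length():
    lmax, r = 47.2, 0.07
    for t in (0.5, 10.0, 100.0, 700.0):
        l = growth_length(t, lmax, r)
        assert growth_time(l, lmax, r) == pytest.approx(t, rel=1e-9)
    assert math.isinf(growth_time(lmax, lmax, r))


def test_growth_length_180d_matches_printed_means():
    # closed-form lengths under the published elongation parameters sit
    # within 10% of the matching empirical means
    for (lmax, r), expected in [
        ((99.5, 0.28), 40.7),
        ((89.9, 0.29), 40.3),
        ((110.1, 0.37), 48.3),
    ]:
        assert growth_length(180.0, lmax, r) == pytest.approx(expected, rel=0.10)


# ---------------------------------------------------------------------------
# emergence schedule


def test_emergence_schedule_constant_spacing():
    # lb 8.4, constant spacing 4.1, la 11.8, lmax 99.5 -> positions
    # 8.4, 12.5, ... up to the last position <= 99.5 - 11.8 = 87.7
    s = emergence_schedule(8.4, lambda: 4.1, 11.8, 99.5)
    assert s[0] == pytest.approx(8.4)
    assert len(s) == 20
    assert s[-1] == pytest.approx(8.4 + 19 * 4.1)  # 86.3
    assert all(x <= 99.5 - 11.8 + 1e-9 for x in s)
    # independent oracle: arithmetic progression truncated at the bound
    oracle = [8.4 + 4.1 * k for k in range(100) if 8.4 + 4.1 * k <= 87.7 + 1e-9]
    np.testing.assert_allclose(s, oracle)


def test_emergence_schedule_empty_when_lb_beyond_bound():
    assert emergence_schedule(90.0, lambda: 4.0, 15.0, 99.5) == []


# ---------------------------------------------------------------------------
# tropism


def _tp(genotype="101-14", root_type=2):
    return GENOTYPES[genotype].for_type(root_type)


def test_tropism_zero_sigma_keeps_heading():
    tp = dataclasses.replace(_tp(), sigma=0.0, N=1)
    rng = np.random.default_rng(0)
    h = np.array([0.6, 0.0, -0.8])
    out = tropism_next_heading(h, 3, tp, rng, mode="per_segment")
    np.testing.assert_allclose(out, h, atol=1e-12)


def test_tropism_output_is_unit_vector():
    tp = _tp()
    rng = np.random.default_rng(1)
    h = np.array([1.0, 0.0, 0.0])
    for _ in range(100):
        h = tropism_next_heading(h, 3, tp, rng)
        assert np.linalg.norm(h) == pytest.approx(1.0, abs=1e-12)


def test_tropism_gravi_pushes_down_plagio_stays_level():
    tp = dataclasses.replace(_tp(), N=4, sigma=0.4)
    rng = np.random.default_rng(2)
    # gravitropic: starting horizontal, z component drifts negative
    h = np.array([1.0, 0.0, 0.0])
    for _ in range(200):
        h = tropism_next_heading(h, 2, tp, rng, mode="per_root", assigned_objective=GRAVI)
    assert h[2] < -0.8
    # plagiotropic: starting at a dip, z component returns toward 0
    h = np.array([0.8, 0.0, -0.6])
    for _ in range(200):
        h = tropism_next_heading(h, 2, tp, rng, mode="per_root", assigned_objective=PLAGIO)
    assert abs(h[2]) < 0.2


def test_tropism_draw_fraction_matches_p_gravi():
    tp = _tp("101-14")  # p_gravi = 0.85
    rng = np.random.default_rng(3)
    diag = TropismDiagnostics()
    h = np.array([1.0, 0.0, 0.0])
    n = 20000
    for _ in range(n):
        tropism_next_heading(h, 2, tp, rng, mode="per_segment", diagnostics=diag)
    assert diag.gravi_draws + diag.plagio_draws == n
    se = math.sqrt(0.85 * 0.15 / n)
    assert diag.gravi_fraction == pytest.approx(0.85, abs=3 * se)


def test_type3_never_counts_tropism_draws():
    tp = _tp("101-14", 3)
    rng = np.random.default_rng(4)
    diag = TropismDiagnostics()
    tropism_next_heading(np.array([0, 0, -1.0]), 3, tp, rng, diagnostics=diag)
    assert diag.gravi_draws == 0 and diag.plagio_draws == 0


# ---------------------------------------------------------------------------
# simulation


@pytest.fixture(scope="module")
def sim_result():
    template = make_static_template(seed=9)
    state = initialize_static(template, GENOTYPES["R110"])
    return template, simulate(state, days=180.0, seed=9)


def test_static_axes_unchanged(sim_result):
    template, res = sim_result
    rs = res.root_system
    for aid in template.axes:
        ax = template[aid]
        if ax.root_type in (0, 1):
            np.testing.assert_array_equal(rs[aid].nodes, ax.nodes)


def test_type2_arc_length_matches_growth_law(sim_result):
    _, res = sim_result
    tp = GENOTYPES["R110"].type2
    expected = growth_length(180.0, tp.lmax, tp.r)
    for ax in res.root_system.axes_of_type(2):
        assert ax.length == pytest.approx(expected, abs=1e-6)


def test_node_ages_consistent_with_arc(sim_result):
    _, res = sim_result
    tp = GENOTYPES["R110"].type2
    for ax in res.root_system.axes_of_type(2)[:5]:
        arcs = ax.arc_lengths()
        for arc, age in zip(arcs, ax.node_ages):
            # node created when the root reached this arc position
            expected_age = 180.0 - growth_time(arc, tp.lmax, tp.r)
            assert age == pytest.approx(max(expected_age, 0.0), abs=1e-6)


def test_type3_attach_on_parent_nodes(sim_result):
    _, res = sim_result
    rs = res.root_system
    rs.validate()
    t3 = rs.axes_of_type(3)
    assert len(t3) > 20
    for ax in t3:
        parent = rs[ax.parent]
        assert parent.root_type == 2
        np.testing.assert_array_equal(ax.nodes[0], parent.nodes[ax.parent_node])


def test_simulation_deterministic_per_seed():
    template = make_static_template(seed=1)
    params = GENOTYPES["SO4"]
    a = simulate(initialize_static(template, params), days=60.0, seed=3)
    b = simulate(initialize_static(template, params), days=60.0, seed=3)
    c = simulate(initialize_static(template, params), days=60.0, seed=4)
    assert set(a.root_system.axes) == set(b.root_system.axes)
    for aid in a.root_system.axes:
        np.testing.assert_array_equal(
            a.root_system[aid].nodes, b.root_system[aid].nodes
        )
    # a different seed produces different geometry
    diff = any(
        not np.array_equal(a.root_system[aid].nodes, c.root_system[aid].nodes)
        for aid in a.root_system.axes
        if aid in c.root_system.axes
    )
    assert diff


def test_initialize_static_requires_type1():
    from woodyroot import Axis, RootSystem

    rs = RootSystem()
    rs.add_axis(
        Axis(axis_id=(), nodes=np.array([[0, 0, 5], [0, 0, 0.0]]), root_type=0)
    )
    with pytest.raises(ValueError):
        initialize_static(rs, GENOTYPES["101-14"])
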