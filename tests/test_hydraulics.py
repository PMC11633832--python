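import math

import numpy as np
import pytest

from woodyroot import (
    CrossSection,
    GENOTYPES,
    HydraulicParams,
    KrTable,
    convert_kh_units,
    default_kr_table,
    fit_kx_vs_diameter,
    kh_theoretical,
    load_vessel_table,
    solve_suf_krs,
    suf_profile,
    synth_root_system,
)
from woodyroot.hydraulics import (
    ETA_WATER_20C,
    KH_M4_PER_S_MPA_TO_CM3_PER_D,
    PowerLawFit,
    convert_kh_units_inverse,
)

from conftest import straight_system


# ---------------------------------------------------------------------------
# axial conductivity


def test_kh_elliptical_worked_example():
    # one vessel, minor 20 um, major 40 um
    cs = CrossSection.from_micrometres([20.0], [40.0], root_diameter_cm=0.1)
    a, b = 20e-6, 40e-6
    oracle = math.pi / (64 * ETA_WATER_20C) * (a**3 * b**3) / (a**2 + b**2)
    got = kh_theoretical(cs)
    assert got == pytest.approx(oracle, rel=1e-12)
    assert got == pytest.approx(1.254e-11, rel=1e-3)


def test_kh_circular_limit_property():
    # for a = b = d the elliptical formula reduces to pi d^4 / (128 eta)
    for d in np.geomspace(5e-6, 5e-4, 25):
        got = kh_theoretical(np.array([[d, d]]))
        assert got == pytest.approx(
            math.pi * d**4 / (128 * ETA_WATER_20C), rel=1e-12
        )


def test_kh_circular_worked_example():
    d = 50e-6
    assert kh_theoretical(np.array([[d, d]])) == pytest.approx(1.531e-10, rel=1e-3)


def test_kh_additive_over_vessels():
    rng = np.random.default_rng(0)
    minor = rng.uniform(10e-6, 30e-6, 20)
    major = minor * rng.uniform(1.0, 2.0, 20)
    v = np.column_stack([minor, major])
    total = kh_theoretical(v)
    parts = sum(kh_theoretical(v[i : i + 1]) for i in range(20))
    assert total == pytest.approx(parts, rel=1e-12)


def test_unit_conversion_factor_from_first_principles():
    # m^4 s^-1 MPa^-1 -> cm^3 d^-1 per (cm head / cm):
    # 1 m head = 9.80665e-3 MPa; 1 d = 86400 s; 1 m^3 = 1e6 cm^3;
    # head gradient is dimensionless, so per-metre and per-cm cancel
    factor = 9.80665e-3 * 86400.0 * 1e6
    assert KH_M4_PER_S_MPA_TO_CM3_PER_D == pytest.approx(factor, rel=1e-12)
    assert convert_kh_units(1e-11) == pytest.approx(1e-11 * factor, rel=1e-12)
    assert convert_kh_units_inverse(convert_kh_units(3.7e-12)) == pytest.approx(
        3.7e-12, rel=1e-12
    )


def test_fit_power_law_exact_recovery():
    d = np.linspace(0.05, 0.5, 12)
    kh = 16.0 * d**2.5
    fit = fit_kx_vs_diameter(np.column_stack([d, kh]))
    assert fit.alpha == pytest.approx(16.0, rel=1e-6)
    assert fit.beta == pytest.approx(2.5, rel=1e-6)
    assert fit.rss == pytest.approx(0.0, abs=1e-12)


def test_load_vessel_table(tmp_path):
    p = tmp_path / "vessels.csv"
    p.write_text(
        "genotype,zone,root_diameter_cm,section,minor_um,major_um\n"
        "g,type1,0.4,0,20,40\n"
        "g,type1,0.4,0,25,30\n"
        "g,type2_suberized,0.1,1,10,12\n"
    )
    sections = load_vessel_table(p)
    assert len(sections) == 2
    assert sorted(len(s.vessels) for s in sections) == [1, 2]


# ---------------------------------------------------------------------------
# kr table


def test_kr_table_age_classes():
    table = default_kr_table()
    assert table(0, 10.0) == 0.0  # stem takes up no water
    assert table(2, 10.0) > table(2, 40.0)  # suberization reduces kr
    assert table(2, 29.999) == table(3, 0.0)
    assert table(1, 5.0) == table(1, 500.0)  # woody: single class


def test_kr_table_validation():
    with pytest.raises(ValueError):
        KrTable(classes={2: [(30.0, 1.0)]})  # must end at inf
    with pytest.raises(ValueError):
        KrTable(classes={2: [(math.inf, -1.0)]})


# ---------------------------------------------------------------------------
# network solve


def _uniform_params(kx0: float, kr: float) -> HydraulicParams:
    return HydraulicParams(
        kx_fit=PowerLawFit(kx0, 0.0),  # constant axial conductivity
        kr_table=KrTable(classes={0: [(math.inf, 0.0)], 1: [(math.inf, kr)]}),
    )


def test_krs_matches_closed_form_single_root():
    # uniform straight root of length L with constant kx and kr, stem of
    # length Ls in series: continuous solution
    # Krs_root = sqrt(kx * kr * 2 pi a) * tanh(L * sqrt(kr * 2 pi a / kx))
    L, Ls, a = 50.0, 10.0, 0.05
    kx0, kr = 0.1, 8.5e-5
    rs = straight_system(stem_len=Ls, root_len=L, n_seg=2000, radius=a)
    sol = solve_suf_krs(rs, _uniform_params(kx0, kr))
    kr2pa = kr * 2 * math.pi * a
    krs_root = math.sqrt(kx0 * kr2pa) * math.tanh(L * math.sqrt(kr2pa / kx0))
    krs_total = 1.0 / (1.0 / krs_root + Ls / kx0)
    assert abs(sol.krs - krs_total) / krs_total < 1e-6


def test_suf_profile_matches_closed_form_density():
    # uptake density of the continuous solution ~ cosh(tau * (L - x));
    # compare the numeric per-segment inflow at the root tip vs base
    L, a, kx0, kr = 50.0, 0.05, 0.1, 8.5e-5
    rs = straight_system(stem_len=10.0, root_len=L, n_seg=1000, radius=a)
    sol = solve_suf_krs(rs, _uniform_params(kx0, kr))
    root_rows = sol.segments[sol.segments["type"] == 1]
    suf = root_rows["suf"].to_numpy()
    tau = math.sqrt(kr * 2 * math.pi * a / kx0)
    x = np.linspace(0, L, 1001)
    xm = 0.5 * (x[1:] + x[:-1])
    density = np.cosh(tau * (L - xm))
    expected = density / density.sum()
    np.testing.assert_allclose(suf, expected, rtol=5e-4)


def test_suf_sums_to_one_on_random_trees():
    for seed in (0, 1, 2):
        res = synth_root_system(GENOTYPES["101-14"], days=120.0, seed=seed)
        sol = solve_suf_krs(res.full_truth, HydraulicParams())
        assert sol.suf.sum() == pytest.approx(1.0, abs=1e-9)
        assert (sol.suf >= -1e-12).all()
        assert sol.krs > 0


def test_suf_krs_invariant_to_boundary_potentials(vertical_root):
    hp = _uniform_params(0.1, 8.5e-5)
    s1 = solve_suf_krs(vertical_root, hp, psi_soil=0.0, psi_collar=-1000.0)
    s2 = solve_suf_krs(vertical_root, hp, psi_soil=-300.0, psi_collar=-15000.0)
    np.testing.assert_allclose(s1.suf, s2.suf, atol=1e-12)
    assert s1.krs == pytest.approx(s2.krs, rel=1e-9)


def test_solve_rejects_no_uptake(vertical_root):
    hp = HydraulicParams(
        kx_fit=PowerLawFit(0.1, 0.0),
        kr_table=KrTable(classes={0: [(math.inf, 0.0)], 1: [(math.inf, 0.0)]}),
    )
    with pytest.raises(ValueError):
        solve_suf_krs(vertical_root, hp)


def test_suf_profile_conserves_and_respects_horizons():
    res = synth_root_system(GENOTYPES["SO4"], days=150.0, seed=3)
    sol = solve_suf_krs(res.full_truth, HydraulicParams())
    layers, horizons = suf_profile(sol, layer_thickness=1.0)
    assert layers.sum() == pytest.approx(1.0, abs=1e-9)
    assert horizons.sum() == pytest.approx(1.0, abs=1e-9)
    # refining the layer thickness never changes the totals
    layers2, horizons2 = suf_profile(sol, layer_thickness=0.25)
    assert layers2.sum() == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(
        horizons.reindex(horizons2.index, fill_value=0.0), horizons2, atol=1e-9
    )
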