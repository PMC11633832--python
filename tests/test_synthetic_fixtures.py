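import io
import math

import numpy as np
import pytest

from woodyroot import (
    GENOTYPES,
    NoiseModel,
    build_root_system,
    kh_theoretical,
    make_static_template,
    parse_points,
    rmse_bias_accuracy,
    synth_calibration,
    synth_root_system,
    synth_vessels,
)
from woodyroot.digitizer_io import read_digitizer_file
from woodyroot.synthetic_fixtures import ZERO_NOISE, downsample, vessel_dataframe


def _rebuild(text):
    records, soil_ref = read_digitizer_file(io.StringIO(text))
    return build_root_system(records, soil_ref=soil_ref), records


# ---------------------------------------------------------------------------
# static template


def test_template_shape():
    rs = make_static_template(n_type1=8, type1_length=13.0, seed=0)
    rs.validate()
    t1 = rs.axes_of_type(1)
    assert len(t1) == 8
    for ax in t1:
        assert ax.length == pytest.approx(13.0, rel=0.02)
    # soil reference: stem point 1 at the surface; basal node ~20 cm deep
    assert rs.stem.nodes[1][2] == pytest.approx(0.0)
    assert rs.stem.nodes[-1][2] == pytest.approx(-20.0)
    # distinct stem attachment per type-1 root
    assert len({ax.parent_node for ax in t1}) == 8


def test_template_emergence_count_scales():
    rs = make_static_template(n_type1=8, n_emergence_per_axis=13, seed=1)
    assert len(rs.axes_of_type(2)) == 104


# ---------------------------------------------------------------------------
# digitizer file emission


def test_zero_noise_roundtrip_exact():
    res = synth_root_system(GENOTYPES["101-14"], days=150.0, seed=2, noise=ZERO_NOISE)
    (rs, deviations), records = _rebuild(res.text)
    truth = res.digitized_truth
    assert set(rs.axes) == set(truth.axes)
    for aid in truth.axes:
        np.testing.assert_allclose(rs[aid].nodes, truth[aid].nodes, atol=1e-9)
        assert rs[aid].root_type == truth[aid].root_type
    assert max(deviations) == pytest.approx(0.0, abs=1e-9)


def test_point_count_invariant():
    res = synth_root_system(GENOTYPES["SO4"], days=150.0, seed=4, noise=ZERO_NOISE)
    (rs, _), records = _rebuild(res.text)
    # every shared branch node appears in both polylines and as two records
    assert len(records) == sum(a.n_nodes for a in rs)


def test_downsample_keeps_branch_nodes_and_length():
    res = synth_root_system(GENOTYPES["101-14"], days=150.0, seed=5, noise=ZERO_NOISE)
    full, thin = res.full_truth, res.digitized_truth
    assert len(full) == len(thin)
    thin.validate()
    for ax in thin.roots():
        fax = full[_match(full, ax)]
        # chords only shorten; zig-zag stochastic paths can lose up to a few
        # percent under a 10-degree cumulative-turn threshold
        assert ax.length <= fax.length + 1e-9
        assert ax.length >= 0.90 * fax.length
        assert ax.n_nodes <= fax.n_nodes


def _match(full, ax):
    # thin axes share their tip with exactly one full axis
    for aid, fax in full.axes.items():
        if np.allclose(fax.tip, ax.tip, atol=1e-9):
            return aid
    raise AssertionError("no matching full axis")


def test_double_point_deviation_calibrated():
    noise = NoiseModel(point_jitter_sd=0.0, double_point_deviation=0.18, fine_root_loss=0.0)
    res = synth_root_system(GENOTYPES["101-14"], days=180.0, seed=6, noise=noise)
    (_, deviations), _ = _rebuild(res.text)
    n = len(deviations)
    assert n >= 100
    # magnitudes are half-normal with mean 0.18 and sd 0.18*sqrt(pi/2 - 1)
    se = 0.18 * math.sqrt(math.pi / 2.0 - 1.0) / math.sqrt(n)
    assert np.mean(deviations) == pytest.approx(0.18, abs=3 * se + 0.01)


def test_fine_root_loss_shrinks_length_not_count():
    base = synth_root_system(GENOTYPES["101-14"], days=180.0, seed=7, noise=ZERO_NOISE)
    lossy = downsample(base.full_truth, fine_root_loss=0.5)
    full_t3 = base.full_truth.axes_of_type(3)
    lossy_t3 = lossy.axes_of_type(3)
    assert len(lossy_t3) == len(full_t3)
    full_len = sum(a.length for a in full_t3)
    lossy_len = sum(a.length for a in lossy_t3)
    # each axis keeps at least the minimum excavable stub, so slightly > 0.5
    assert 0.45 * full_len <= lossy_len <= 0.62 * full_len


# ---------------------------------------------------------------------------
# calibration and vessels


def test_synth_calibration_recovers_noise_level():
    records = synth_calibration(n_poses=200, noise_sd=0.15, seed=8)
    assert len(records) == 400
    rep = rmse_bias_accuracy(records)
    # rmse estimates the injected sd; se(rmse) ~ sd / sqrt(2n)
    se = 0.15 / math.sqrt(2 * len(records))
    assert rep.rmse == pytest.approx(0.15, abs=4 * se)
    assert abs(rep.bias) <= 4 * 0.15 / math.sqrt(len(records))
    assert all(20.0 <= r.distance_to_transmitter <= 180.0 for r in records)


def test_synth_calibration_distance_dependent_noise():
    records = synth_calibration(
        n_poses=300, noise_sd=0.05, distance_noise_slope=0.002, seed=9
    )
    near = [r for r in records if r.distance_to_transmitter < 80]
    far = [r for r in records if r.distance_to_transmitter > 140]
    assert rmse_bias_accuracy(far).rmse > rmse_bias_accuracy(near).rmse


def test_synth_vessels_valid_and_scaling():
    sections = synth_vessels(n_sections=33, seed=10)
    assert len(sections) == 33
    for cs in sections:
        assert np.all(cs.vessels[:, 0] <= cs.vessels[:, 1] + 1e-18)
        assert np.all(cs.vessels > 0)
    df = vessel_dataframe(sections)
    assert set(df.columns) >= {"genotype", "zone", "root_diameter_cm", "minor_um", "major_um"}
    # Kh increases with root diameter on average (power-law cloud)
    kh = np.array([kh_theoretical(cs) for cs in sections])
    d = np.array([cs.root_diameter_cm for cs in sections])
    r = np.corrcoef(np.log(d), np.log(kh))[0, 1]
    assert r > 0.5


def test_kh_doubles_with_vessel_count_in_expectation():
    # additivity: a section holding two copies of the same vessels has
    # exactly twice the conductivity
    cs = synth_vessels(n_sections=1, seed=11)[0]
    doubled = np.vstack([cs.vessels, cs.vessels])
    assert kh_theoretical(doubled) == pytest.approx(2 * kh_theoretical(cs), rel=1e-12)


def test_noise_model_validation():
    with pytest.raises(ValueError):
        NoiseModel(point_jitter_sd=-0.1)
    with pytest.raises(ValueError):
        NoiseModel(fine_root_loss=1.5)
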