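"""Diffusion forward model, lookup inversion and hemoglobin arithmetic."""

import numpy as np
import pytest

from ipdtmon.geometry import CDFPair, CDFSection, parallel_pair
from ipdtmon.optics import (
    CAPILLARY_FRACTIONS,
    LookupTable,
    OpticalProperties,
    build_lookup,
    delta_mua,
    fit_P0,
    hemoglobin_mua,
    invert_mua,
    min_mua_for_threshold,
    mu_eff,
    mua_post_from_ratio,
    pair_transmission,
    point_fluence,
    transmission_curve,
)
from ipdtmon.synthetic import generate_phantom_set


def brute_force_transmission(pair: CDFPair, props: OpticalProperties, p0: float) -> float:
    """Independent double-loop oracle over every point combination."""
    total = 0.0
    for e in pair.emitter_points:
        for d in pair.detector_points:
            r = float(np.linalg.norm(e - d))
            total += (
                3.0 * (props.mu_a + props.mu_s_prime) / (4 * np.pi * r)
                * np.exp(-r * np.sqrt(3 * props.mu_a * (props.mu_a + props.mu_s_prime)))
            )
    return p0 * (pair.emitter.length_mm / 10.0) / pair.n_combinations * total


def random_pair(rng) -> CDFPair:
    def section(fid):
        prox = rng.uniform(-15, 15, 3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = float(rng.choice([20.0, 30.0]))
        return CDFSection(fid, prox, prox + length * direction, length)

    while True:
        pair = CDFPair(section("E"), section("D"))
        if pair.min_distance > 2.0:
            return pair


class TestPointFluence:
    def test_closed_form_value(self):
        phi = point_fluence(10.0, OpticalProperties(0.02, 2.0))
        assert phi == pytest.approx(1.48e-3, rel=0.01)

    def test_zero_absorption_limit(self):
        # mu_a = 0: pure 1/r decay with prefactor 3 mu_s' / (4 pi)
        props = OpticalProperties(0.0, 2.0)
        r = np.array([1.0, 5.0, 25.0])
        assert point_fluence(r, props) == pytest.approx(3 * 2.0 / (4 * np.pi * r))

    def test_monotone_decay(self):
        props = OpticalProperties(0.05, 2.0)
        r1 = np.array([1.0, 3.0, 8.0])
        assert np.all(point_fluence(r1, props) / point_fluence(2 * r1, props) > 2.0)

    def test_singularity_rejected(self):
        with pytest.raises(ValueError):
            point_fluence(0.0, OpticalProperties(0.02))


class TestPairTransmission:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pair = random_pair(rng)
            props = OpticalProperties(float(rng.uniform(0.005, 0.2)), 2.0)
            fast = pair_transmission(pair, props, p0=3.0)
            slow = brute_force_transmission(pair, props, p0=3.0)
            assert fast == pytest.approx(slow, rel=1e-12)

    def test_linear_in_p0(self):
        pair = parallel_pair(10.0)
        props = OpticalProperties(0.02)
        assert pair_transmission(pair, props, p0=2.0) == pytest.approx(
            2 * pair_transmission(pair, props, p0=1.0), rel=1e-12
        )

    def test_asymptotic_log_slope_is_mu_eff(self):
        # far from the source arrays the extended-source decay approaches the
        # point-source attenuation coefficient
        props = OpticalProperties(0.1, 2.0)
        d = np.arange(30.0, 41.0, 1.0)
        vals = [np.log(pair_transmission(parallel_pair(x), props)) for x in d]
        slope = -np.polyfit(d, vals, 1)[0]
        assert slope == pytest.approx(mu_eff(0.1, 2.0), rel=0.05)


class TestHemoglobin:
    def test_zero_bvf(self):
        assert hemoglobin_mua(0.0) == 0.0

    def test_methb_15_percent(self):
        assert hemoglobin_mua(15.0, {"MetHb": 1.0}) == pytest.approx(1.2, abs=0.05)

    def test_tumor_preset(self):
        assert hemoglobin_mua(3.8) == pytest.approx(0.02, abs=5e-4)

    def test_capillary_per_percent(self):
        assert hemoglobin_mua(1.0, CAPILLARY_FRACTIONS) == pytest.approx(0.0053, abs=5e-5)

    def test_species_ratios(self):
        hb = hemoglobin_mua(100.0, {"Hb": 1.0})
        hbo2 = hemoglobin_mua(100.0, {"HbO2": 1.0})
        methb = hemoglobin_mua(100.0, {"MetHb": 1.0})
        assert hb / hbo2 == pytest.approx(8.5, abs=0.1)
        assert methb / hbo2 == pytest.approx(33, abs=0.5)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            hemoglobin_mua(10.0, {"Hb": 0.5, "HbO2": 0.3})


class TestTransmissionCurve:
    def test_self_normalization(self):
        curve = transmission_curve([0.02], [10.0])
        assert curve[0, 0] == pytest.approx(1.0, rel=1e-12)

    def test_ordering_in_mu_a(self):
        curves = transmission_curve([0.02, 0.06, 0.2], np.arange(4.0, 25.0, 2.0))
        assert np.all(curves[0] > curves[1])
        assert np.all(curves[1] > curves[2])

    def test_p0_invariance(self):
        # normalization cancels the calibration factor by construction: the
        # same curve results from intensities computed at any p0
        pair = parallel_pair(14.0)
        props = OpticalProperties(0.06)
        ref_pair = parallel_pair(10.0)
        ref_props = OpticalProperties(0.02)
        for p0 in (1.0, 123.0):
            ratio = pair_transmission(pair, props, p0) / pair_transmission(
                ref_pair, ref_props, p0
            )
            assert ratio == pytest.approx(
                transmission_curve([0.06], [14.0])[0, 0], rel=1e-9
            )


@pytest.fixture(scope="module")
def table():
    return build_lookup(parallel_pair(10.0), p0=2.0)


class TestLookup:
    def test_grid_and_monotonicity(self, table):
        assert table.mu_a.size == 7500
        assert table.mu_a[0] == pytest.approx(1e-4)
        assert table.mu_a[-1] == pytest.approx(0.75)
        assert np.all(np.diff(table.intensity) < 0)

    def test_consistency_with_forward_model(self, table):
        k = int(np.argmin(np.abs(table.mu_a - 0.05)))
        direct = pair_transmission(parallel_pair(10.0), OpticalProperties(0.05), p0=2.0)
        assert table.intensity[k] == pytest.approx(direct, rel=1e-12)

    @pytest.mark.parametrize("mu_a", [0.01, 0.05, 0.068, 0.22])
    def test_roundtrip_within_one_grid_step(self, table, mu_a):
        i_t = pair_transmission(parallel_pair(10.0), OpticalProperties(mu_a), p0=2.0)
        assert invert_mua(i_t, table) == pytest.approx(mu_a, abs=1e-4 + 1e-9)

    def test_clipping_with_warning(self, table):
        with pytest.warns(UserWarning, match="above table range"):
            assert invert_mua(10 * table.intensity[0], table) == pytest.approx(1e-4)
        with pytest.warns(UserWarning, match="below table range"):
            assert invert_mua(0.1 * table.intensity[-1], table) == pytest.approx(0.75)

    def test_nonpositive_intensity_rejected(self, table):
        with pytest.raises(ValueError):
            invert_mua(0.0, table)

    def test_threshold_mua_exact_grid_hit(self, table):
        k = int(np.argmin(np.abs(table.mu_a - 0.30)))
        assert min_mua_for_threshold(table.intensity[k], table) == pytest.approx(
            table.mu_a[k]
        )

    def test_threshold_below_table_saturates(self, table):
        with pytest.warns(UserWarning, match="saturates"):
            assert min_mua_for_threshold(0.5 * table.intensity[-1], table) == 0.75

    def test_threshold_above_table_rejected(self, table):
        with pytest.raises(ValueError):
            min_mua_for_threshold(2 * table.intensity[0], table)

    def test_ratio_anchored_inversion(self, table):
        # case without absolute calibration: solve I(mu_post) = I(mu_pre)/R
        i_pre = pair_transmission(parallel_pair(10.0), OpticalProperties(0.03), p0=2.0)
        i_post = pair_transmission(parallel_pair(10.0), OpticalProperties(0.09), p0=2.0)
        assert mua_post_from_ratio(0.03, i_pre / i_post, table) == pytest.approx(
            0.09, abs=2e-4
        )


class TestDeltaMua:
    def test_plain_difference(self):
        assert delta_mua(0.05, 0.08) == (pytest.approx(0.03), "measured")

    def test_post_lower_bound_propagates(self):
        value, q = delta_mua(0.05, 0.20, post_qualifier="lower-bound")
        assert value == pytest.approx(0.15)
        assert q == "lower-bound"

    def test_pre_undetectable_is_undefined(self):
        value, q = delta_mua(0.30, 0.4, pre_qualifier="lower-bound")
        assert np.isnan(value) and q == "undefined"


class TestFitP0:
    def test_noiseless_exact_recovery(self):
        data = generate_phantom_set(5.0, noise_fraction=0.0)
        p0, resid = fit_P0(data.to_dict("records"))
        assert p0 == pytest.approx(5.0, rel=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_8_percent(self):
        data = generate_phantom_set(5.0, noise_fraction=0.08, seed=11)
        assert len(data) == 12
        p0, _ = fit_P0(data.to_dict("records"))
        assert p0 == pytest.approx(5.0, abs=0.4)

    def test_single_measurement_warns_exact_ratio(self):
        data = generate_phantom_set(3.0, noise_fraction=0.0).iloc[:1]
        with pytest.warns(UserWarning, match="single"):
            p0, _ = fit_P0(data.to_dict("records"))
        assert p0 == pytest.approx(3.0, rel=1e-12)
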