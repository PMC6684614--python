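"""PRE quantification: CSPs, peak heights, ratio errors, relaxation fits,
Gamma2 inversion, distance conversion, restraint rules, tau_c calibration."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from presans.pre import (
    PeakQuantification,
    PREPhysics,
    RelaxationSeries,
    TagSite,
    build_restraints,
    calibrate_tauc,
    classify_ratio,
    compute_csp,
    distance_to_gamma2,
    fit_exponential_decay,
    gamma2_to_distance,
    intensity_ratio_model,
    peak_height,
    quantify_pre,
    ratio_with_error,
    solve_gamma2,
    IntensityRatioRecord,
)
from presans.synthetic import DELAYS_DIAHC, simulate_pre_gamma2


class TestCSP:
    def test_zero_case(self):
        assert compute_csp(0.0, 0.0, "N") == 0.0

    def test_hand_evaluated_amide_csp(self):
        # sqrt(0.5*(0.1^2 + (0.15*0.5)^2))
        assert compute_csp(0.1, 0.5, "N") == pytest.approx(0.0883883, abs=1e-6)

    def test_carbon_weight_is_twice_nitrogen_weight(self):
        assert compute_csp(0.1, 0.5, "C") == pytest.approx(compute_csp(0.1, 1.0, "N"))

    def test_unknown_nucleus(self):
        with pytest.raises(ValueError):
            compute_csp(0.1, 0.1, "P")

    @settings(derandomize=True, max_examples=50)
    @given(dh=st.one_of(st.just(0.0), st.floats(0.01, 5), st.floats(-5, -0.01)),
           dx=st.one_of(st.just(0.0), st.floats(0.01, 5), st.floats(-5, -0.01)))
    def test_nonnegative_and_zero_iff_both_zero(self, dh, dx):
        d = compute_csp(dh, dx, "N")
        assert d >= 0
        assert (d == 0) == (dh == 0 and dx == 0)


class TestPeakHeight:
    def test_identity(self):
        assert peak_height(1, 1, 1) == 1

    def test_hand_value(self):
        assert peak_height(200, 20, 25) == pytest.approx(0.4)

    def test_homogeneity_in_linewidth(self):
        assert peak_height(200, 40, 25) == pytest.approx(0.5 * peak_height(200, 20, 25))

    def test_nonpositive_linewidth(self):
        with pytest.raises(ValueError):
            peak_height(1.0, 0.0, 1.0)


class TestRatioWithError:
    def test_equal_noiseless(self):
        p = PeakQuantification(100, 10, 10, 0.0)
        r = ratio_with_error(p, p)
        assert r.ratio == 1.0 and r.sigma == 0.0

    def test_hand_propagation(self):
        # heights 5 +/- 1 and 10 +/- 1
        para = PeakQuantification(5, 1, 1, 1.0)
        dia = PeakQuantification(10, 1, 1, 1.0)
        r = ratio_with_error(para, dia)
        assert r.ratio == pytest.approx(0.5)
        assert r.sigma == pytest.approx(0.5 * np.sqrt(0.04 + 0.01), rel=1e-12)

    def test_broadened_out_peak_floors_at_zero(self):
        para = PeakQuantification(-2, 1, 1, 1.0)
        dia = PeakQuantification(10, 1, 1, 1.0)
        r = ratio_with_error(para, dia)
        assert r.ratio == 0.0
        assert r.sigma > 0
        assert classify_ratio(r.ratio) == "near"

    def test_nonpositive_dia_raises(self):
        with pytest.raises(ValueError):
            ratio_with_error(PeakQuantification(1, 1, 1), PeakQuantification(0, 1, 1))


class TestExponentialFit:
    def test_exact_recovery_on_standard_delays(self):
        h = 100 * np.exp(-30.0 * DELAYS_DIAHC)
        fit = fit_exponential_decay(RelaxationSeries(DELAYS_DIAHC, h, "diaHC"))
        assert fit.rate == pytest.approx(30.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(100.0, abs=1e-6)

    def test_noise_recovery_within_three_se(self):
        rng = np.random.default_rng(7)
        inside = 0
        n = 300
        for _ in range(n):
            h = 100 * np.exp(-30.0 * DELAYS_DIAHC) + rng.normal(0, 1, len(DELAYS_DIAHC))
            fit = fit_exponential_decay(RelaxationSeries(DELAYS_DIAHC, h, "diaHC"))
            inside += abs(fit.rate - 30.0) < 3 * fit.rate_se
        assert inside / n > 0.95

    def test_constant_series_flags_boundary(self):
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_exponential_decay(
                RelaxationSeries(DELAYS_DIAHC, np.full(len(DELAYS_DIAHC), 50.0), "diaHC"))
        assert fit.rate == pytest.approx(0.0, abs=1e-6)
        assert fit.at_boundary

    def test_too_few_delays(self):
        with pytest.raises(ValueError):
            RelaxationSeries(np.array([0.0, 0.002]), np.array([10.0, 5.0]))


class TestGamma2Inversion:
    def test_forward_model_round_trip(self, physics):
        r = intensity_ratio_model(100.0, 30.0, 40.0, 7.7e-3)
        assert r == pytest.approx(0.03053, abs=2e-5)
        assert solve_gamma2(r, 30.0, 40.0, physics) == pytest.approx(100.0, rel=1e-6)

    def test_unity_at_zero_rate(self, physics):
        for r2h, r2hc in [(10, 10), (30, 45), (100, 200)]:
            assert intensity_ratio_model(0.0, r2h, r2hc, physics.tau_hmqc) == 1.0
        with pytest.warns(UserWarning):
            assert solve_gamma2(1.0, 30.0, 40.0, physics) == 0.0

    def test_round_trip_over_working_range(self, physics):
        for gamma in np.geomspace(1.0, 5000.0, 25):
            r = intensity_ratio_model(gamma, 30.0, 45.0, physics.tau_hmqc)
            if r < 1e-300:
                continue
            assert solve_gamma2(r, 30.0, 45.0, physics) == pytest.approx(gamma, rel=1e-6)

    def test_monotonicity(self, physics):
        rng = np.random.default_rng(3)
        ratios = np.sort(rng.uniform(0.01, 0.99, 20))
        gammas = [solve_gamma2(r, 30.0, 45.0, physics) for r in ratios]
        assert all(a > b for a, b in zip(gammas, gammas[1:]))

    def test_nonpositive_ratio_rejected(self, physics):
        with pytest.raises(ValueError, match="near"):
            solve_gamma2(0.0, 30.0, 45.0, physics)


class TestDistanceConversion:
    def test_sixth_root_scaling_law(self, physics):
        d1, _ = gamma2_to_distance(128.0, physics)
        d2, _ = gamma2_to_distance(2.0, physics)
        assert d2 == pytest.approx(2.0 * d1, rel=1e-12)

    def test_independent_single_expression_oracle(self):
        physics = PREPhysics(tau_hmqc=7.7e-3, tau_c=81e-9,
                             omega=2 * np.pi * 850e6, K=1.23e-32)
        d, _ = gamma2_to_distance(50.0, physics)
        tc, w, K, g = 81e-9, 2 * np.pi * 850e6, 1.23e-32, 50.0
        expected = (K / g * (4 * tc + 3 * tc / (1 + w**2 * tc**2))) ** (1 / 6) * 1e8
        assert d == pytest.approx(expected, rel=1e-9)

    def test_strictly_decreasing_in_gamma2(self, physics):
        ds = [gamma2_to_distance(g, physics)[0] for g in np.geomspace(0.1, 1e4, 30)]
        assert all(a > b for a, b in zip(ds, ds[1:]))

    def test_inverse_consistency(self, physics):
        assert distance_to_gamma2(gamma2_to_distance(37.0, physics)[0], physics) == \
            pytest.approx(37.0, rel=1e-12)

    def test_error_propagation_first_order(self, physics):
        d, sd = gamma2_to_distance(50.0, physics, sigma_gamma2=5.0)
        assert sd == pytest.approx(d * 5.0 / (6 * 50.0), rel=1e-12)


def _tag_and_structure(toy_complex):
    from presans.synthetic import default_tag_site
    return default_tag_site(toy_complex, "A", 15), toy_complex


class TestRestraintRules:
    def _build(self, toy_complex, physics, ratio, rates=None):
        tag, structure = _tag_and_structure(toy_complex)
        rec = IntensityRatioRecord(("C", 1, "CD1"), 1.0, 1.0, ratio, 0.01)
        rates = rates if rates is not None else {("C", 1, "CD1"): (40.0, 60.0)}
        rs, prs = build_restraints([rec], rates, physics, tag, structure)
        return rs, prs

    def test_near_band(self, toy_complex, physics):
        rs, _ = self._build(toy_complex, physics, 0.1)
        assert (rs[0].lower, rs[0].upper, rs[0].klass) == (2.0, 18.0, "near")

    def test_far_band(self, toy_complex, physics):
        rs, _ = self._build(toy_complex, physics, 0.9)
        assert (rs[0].lower, rs[0].upper, rs[0].klass) == (24.0, 99.0, "far")

    def test_boundaries_are_quantitative(self):
        assert classify_ratio(0.2) == "quantitative"
        assert classify_ratio(0.8) == "quantitative"
        assert classify_ratio(0.19999) == "near"
        assert classify_ratio(0.80001) == "far"

    def test_quantitative_band_padding_by_hand(self, toy_complex, physics):
        """A ratio engineered to give d = 22 A and sigma_d = 1 A must yield
        bounds (15, 29) = d -/+ (sigma_d + 6)."""
        r2h, r2hc = 40.0, 60.0
        gamma = distance_to_gamma2(22.0, physics)
        ratio = intensity_ratio_model(gamma, r2h, r2hc, physics.tau_hmqc)
        assert 0.2 < ratio < 0.8
        # choose sigma_ratio so that sigma_d = 1 A: sigma_G = 6*G*sigma_d/d
        sigma_gamma = 6 * gamma * 1.0 / 22.0
        h = 1e-5
        dgdr = (solve_gamma2(ratio + h, r2h, r2hc, physics)
                - solve_gamma2(ratio - h, r2h, r2hc, physics)) / (2 * h)
        sigma_ratio = sigma_gamma / abs(dgdr)
        tag, structure = _tag_and_structure(toy_complex)
        rec = IntensityRatioRecord(("C", 1, "CD1"), 1.0, 1.0, ratio, sigma_ratio)
        rs, _ = build_restraints([rec], {("C", 1, "CD1"): (r2h, r2hc)},
                                 physics, tag, structure)
        assert rs[0].lower == pytest.approx(15.0, abs=1e-3)
        assert rs[0].upper == pytest.approx(29.0, abs=1e-3)

    def test_anchors_are_tag_cb_and_methyl(self, toy_complex, physics):
        rs, _ = self._build(toy_complex, physics, 0.5)
        r = rs[0]
        assert (r.chain_a, r.resid_a, r.atom_a) == ("A", 15, "CB")
        assert (r.chain_b, r.resid_b, r.atom_b) == ("C", 1, "CD1")

    def test_quantitative_without_rates_is_unusable(self, toy_complex, physics):
        rs, prs = self._build(toy_complex, physics, 0.5, rates={})
        assert rs == []
        assert prs[0].klass == "unusable"

    def test_unresolvable_anchor_raises(self, toy_complex, physics):
        tag, structure = _tag_and_structure(toy_complex)
        rec = IntensityRatioRecord(("Z", 1, "CD1"), 1.0, 1.0, 0.5, 0.01)
        with pytest.raises(KeyError, match="Z"):
            build_restraints([rec], {}, physics, tag, structure)

    def test_bounds_always_ordered(self, toy_complex, physics):
        rng = np.random.default_rng(5)
        tag, structure = _tag_and_structure(toy_complex)
        recs = [IntensityRatioRecord(("C", i + 1, "CD1"), 1.0, 1.0,
                                     float(r), 0.02)
                for i, r in enumerate(rng.uniform(0.01, 0.99, 25))]
        rates = {r.methyl_id: (40.0, 60.0) for r in recs}
        rs, _ = build_restraints(recs, rates, physics, tag, structure)
        assert all(0 < r.lower < r.upper for r in rs)


class TestTaucCalibration:
    def test_noiseless_single_point_cloud_exact(self, toy_complex, tag_site, physics):
        obs = simulate_pre_gamma2(toy_complex, tag_site, physics, 0.0, seed=0,
                                  chains=["A"])
        start = dataclasses.replace(physics, tau_c=40e-9)
        tau, se, _ = calibrate_tauc(obs, toy_complex, tag_site, start)
        assert tau == pytest.approx(81e-9, rel=1e-3)

    def test_two_point_cloud_weight_recovery(self, toy_complex, physics):
        cb = toy_complex.coords[toy_complex.atom_index("A", 15, "CB")]
        outward = cb - toy_complex.coords.mean(axis=0)
        outward /= np.linalg.norm(outward)
        perp = np.cross(outward, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        cloud = np.array([cb + 6 * outward, cb + 4 * outward + 5 * perp])
        tag = TagSite("A", 15, cb, cloud, np.array([0.7, 0.3]))
        obs = simulate_pre_gamma2(toy_complex, tag, physics, 0.0, seed=0, chains=["A"])
        start = dataclasses.replace(physics, tau_c=40e-9)
        tau, _, weights = calibrate_tauc(obs, toy_complex, tag, start)
        assert tau == pytest.approx(81e-9, rel=0.01)
        np.testing.assert_allclose(weights, [0.7, 0.3], atol=0.05)

    def test_too_few_quantitative_methyls(self, toy_complex, tag_site, physics):
        obs = simulate_pre_gamma2(toy_complex, tag_site, physics, 0.0, seed=0,
                                  chains=["A"])[:3]
        with pytest.raises(ValueError, match="uninformative"):
            calibrate_tauc(obs, toy_complex, tag_site, physics)
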