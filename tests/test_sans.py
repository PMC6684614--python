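"""Bead contrasts, Debye intensities, Guinier fits, chi^2 and consensus fitness."""

import numpy as np
import pytest
from scipy.optimize import brentq

from presans import tables
from presans.sans import (
    LabelingScheme,
    SANSCurve,
    ScatteringBeads,
    bead_model,
    chi2_fit,
    consensus_fitness,
    contrast_weighted_rg,
    debye_intensity,
    guinier_rg,
    normalize_chi2_set,
    read_sans_curve,
    write_sans_curve,
)
from presans.synthetic import make_toy_complex, simulate_sans


def naive_debye(xyz, b, q_grid):
    """Brute-force double-loop oracle for the Debye sum."""
    out = np.zeros(len(q_grid))
    for k, q in enumerate(q_grid):
        s = 0.0
        for i in range(len(b)):
            for j in range(len(b)):
                r = np.linalg.norm(xyz[i] - xyz[j])
                s += b[i] * b[j] * (1.0 if q * r == 0 else np.sin(q * r) / (q * r))
        out[k] = s
    return out


class TestBeadContrast:
    def test_glycine_hand_summation(self):
        # protonated glycine residue in H2O: 2C + N + O + 2 H(nonexch) +
        # 1 H(exch) minus displaced solvent
        b = tables.residue_scattering_length("GLY", 0.0, 0.0)
        hand = (2 * 6.646 + 9.360 + 5.803 + 3 * (-3.739)
                - ((2 * -3.739 + 5.803) / 30.0) * 60.1)
        assert b == pytest.approx(hand, rel=1e-12)

    def test_contrast_is_linear_with_a_root(self):
        for resname in ("GLY", "ALA", "LYS", "TRP"):
            f = lambda x: tables.residue_scattering_length(resname, 0.0, x,
                                                           exchange_efficiency=0.9)
            assert f(0.0) * f(1.0) < 0  # protonated residues cross zero
            root = brentq(f, 0.0, 1.0, xtol=1e-15)
            assert abs(f(root)) < 1e-12

    def test_perdeuterated_exceeds_protonated_for_every_residue(self):
        for resname in tables.RESIDUES:
            bd = tables.residue_scattering_length(resname, 1.0, 0.42)
            bh = tables.residue_scattering_length(resname, 0.0, 0.42)
            assert bd > bh

    def test_unknown_residue_raises(self):
        with pytest.raises(KeyError, match="XYZ"):
            tables.residue_scattering_length("XYZ", 0.0, 0.0)

    def test_bead_model_places_one_bead_per_residue(self, toy_complex):
        scheme = LabelingScheme.make({"A": 1.0, "B": 1.0, "C": 0.0}, 0.42)
        beads = bead_model(toy_complex, scheme)
        assert len(beads.b) == 90
        # perdeuterated chains scatter more strongly than the protonated one
        assert beads.b[np.asarray(beads.chain) == "A"].mean() > \
            beads.b[np.asarray(beads.chain) == "C"].mean()


class TestDebye:
    def test_single_bead_is_flat(self):
        beads = ScatteringBeads(np.zeros((1, 3)), np.array([2.5]),
                                np.array(["A"], dtype=object), np.array([1]))
        curve = debye_intensity(beads, np.linspace(0, 0.5, 10))
        np.testing.assert_allclose(curve.intensity, 6.25)

    def test_two_bead_closed_form(self):
        r = 10.0
        beads = ScatteringBeads(np.array([[0.0, 0, 0], [r, 0, 0]]), np.ones(2),
                                np.array(["A", "A"], dtype=object), np.array([1, 2]))
        q = np.linspace(0.01, 0.5, 20)
        curve = debye_intensity(beads, q)
        expected = 2.0 * (1.0 + np.sin(q * r) / (q * r))
        np.testing.assert_allclose(curve.intensity, expected, rtol=1e-12)

    def test_matches_naive_double_loop(self, rng):
        xyz = rng.uniform(-20, 20, (50, 3))
        b = rng.uniform(-2, 3, 50)
        beads = ScatteringBeads(xyz, b, np.array(["A"] * 50, dtype=object),
                                np.arange(50))
        q = np.linspace(0.0, 0.4, 15)
        curve = debye_intensity(beads, q)
        oracle = naive_debye(xyz, b, q)
        np.testing.assert_allclose(curve.intensity, oracle, rtol=1e-10)

    def test_zero_angle_limit(self, rng):
        xyz = rng.uniform(-15, 15, (20, 3))
        b = rng.uniform(0.5, 2, 20)
        beads = ScatteringBeads(xyz, b, np.array(["A"] * 20, dtype=object),
                                np.arange(20))
        curve = debye_intensity(beads, np.array([0.0]))
        assert curve.intensity[0] == pytest.approx(b.sum() ** 2, rel=1e-12)

    def test_empty_beads_raise(self):
        beads = ScatteringBeads(np.zeros((0, 3)), np.zeros(0),
                                np.array([], dtype=object), np.array([], dtype=int))
        with pytest.raises(ValueError):
            debye_intensity(beads, np.array([0.1]))


class TestContrastMatching:
    def test_matched_component_vanishes_from_forward_scattering(self, toy_complex):
        """At the protonated chain's match point it contributes <1% of I(0)."""
        f = brentq(lambda x: tables.residue_scattering_length("ILE", 0.0, x), 0.0, 1.0)
        scheme = LabelingScheme.make({"A": 1.0, "B": 1.0, "C": 0.0}, f)
        beads = bead_model(toy_complex, scheme)
        mask = np.asarray(beads.chain) == "C"
        i0_total = beads.b.sum() ** 2
        i0_without = beads.b[~mask].sum() ** 2
        assert abs(i0_total - i0_without) / i0_total < 0.01


class TestGuinier:
    def _positive_beads(self):
        s = make_toy_complex(3, 30, seed=4)
        scheme = LabelingScheme.make({"A": 1.0, "B": 1.0, "C": 1.0}, 0.0)
        return bead_model(s, scheme)

    def test_guinier_matches_direct_moment(self):
        beads = self._positive_beads()
        assert np.all(beads.b > 0)
        q = np.linspace(0.002, 0.2, 200)
        curve = debye_intensity(beads, q)
        rg_direct = contrast_weighted_rg(beads)
        rg_fit = guinier_rg(curve)
        assert rg_fit == pytest.approx(rg_direct, rel=0.02)

    def test_isotropic_scaling_doubles_rg(self):
        beads = self._positive_beads()
        q = np.linspace(0.001, 0.1, 300)
        rg1 = guinier_rg(debye_intensity(beads, q))
        big = ScatteringBeads(2.0 * beads.xyz, beads.b, beads.chain, beads.resid)
        rg2 = guinier_rg(debye_intensity(big, q))
        assert rg2 == pytest.approx(2.0 * rg1, rel=0.02)

    def test_single_bead_has_no_size(self):
        beads = ScatteringBeads(np.zeros((1, 3)), np.ones(1),
                                np.array(["A"], dtype=object), np.array([1]))
        curve = debye_intensity(beads, np.linspace(0.01, 0.3, 30))
        with pytest.raises(ValueError, match="Guinier"):
            guinier_rg(curve)


class TestChi2:
    def _calc(self):
        q = np.linspace(0.01, 0.3, 40)
        return SANSCurve(q, 100 * np.exp(-(q * 30) ** 2 / 3))

    def test_exact_scaled_match(self):
        calc = self._calc()
        exp = SANSCurve(calc.q, 3.7 * calc.intensity, np.ones_like(calc.q))
        chi2, c = chi2_fit(calc, exp)
        assert c == pytest.approx(3.7, rel=1e-12)
        assert chi2 == pytest.approx(0.0, abs=1e-20)

    def test_unit_chi2_for_matched_noise(self):
        calc = self._calc()
        n = len(calc.q)
        bound = 3 * np.sqrt(2.0 / (n - 1))
        rng = np.random.default_rng(11)
        chis = []
        for _ in range(20):
            sigma = 0.03 * calc.intensity
            exp = SANSCurve(calc.q, calc.intensity + rng.normal(0, 1, n) * sigma, sigma)
            chis.append(chi2_fit(calc, exp)[0])
        assert np.mean(chis) == pytest.approx(1.0, abs=bound)

    def test_scale_invariance(self):
        calc = self._calc()
        rng = np.random.default_rng(2)
        sigma = 0.05 * calc.intensity
        exp = SANSCurve(calc.q, calc.intensity + rng.normal(0, 1, len(calc.q)) * sigma,
                        sigma)
        chi2a, _ = chi2_fit(calc, exp)
        exp2 = SANSCurve(exp.q, 7.0 * exp.intensity, 7.0 * exp.sigma)
        chi2b, _ = chi2_fit(calc, exp2)
        assert chi2a == pytest.approx(chi2b, rel=1e-10)

    def test_background_variant_absorbs_offset(self):
        calc = self._calc()
        exp = SANSCurve(calc.q, 2.0 * calc.intensity + 5.0, np.ones_like(calc.q))
        chi2, c = chi2_fit(calc, exp, fit_background=True)
        assert chi2 == pytest.approx(0.0, abs=1e-16)
        assert c == pytest.approx(2.0, rel=1e-8)


class TestNormalizationAndFitness:
    def test_affine_mapping(self):
        np.testing.assert_allclose(normalize_chi2_set([2.0, 4.0, 6.0]), [0, 0.5, 1])

    def test_invariance_under_affine_rescaling(self):
        v = np.array([3.0, 9.0, 4.5, 7.2])
        np.testing.assert_allclose(normalize_chi2_set(v),
                                   normalize_chi2_set(2.5 * v + 1.0), atol=1e-12)

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning, match="equal"):
            out = normalize_chi2_set([5.0, 5.0, 5.0])
        np.testing.assert_array_equal(out, 0.0)

    def test_fitness_single_dataset_passthrough(self):
        norms = np.array([[0.0], [0.3], [1.0]])
        np.testing.assert_allclose(consensus_fitness(norms), [0.0, 0.3, 1.0])

    def test_everywhere_best_structure_has_zero_fitness(self):
        norms = np.array([[0.0, 0.0], [0.5, 0.2], [1.0, 1.0]])
        assert consensus_fitness(norms)[0] == 0.0

    def test_hand_summed_table(self):
        norms = [[0.0, 1.0], [0.5, 0.0], [1.0, 0.4]]
        np.testing.assert_allclose(consensus_fitness(norms), [1.0, 0.5, 1.4])

    def test_ragged_matrix_rejected(self):
        with pytest.raises(ValueError):
            consensus_fitness([[0.1, 0.2], [0.3]])

    def test_ranking_invariant_under_per_dataset_affine_chi2(self):
        rng = np.random.default_rng(8)
        chi2 = rng.uniform(1, 30, (12, 3))
        f1 = consensus_fitness(np.column_stack(
            [normalize_chi2_set(chi2[:, j]) for j in range(3)]))
        scaled = chi2 * np.array([2.0, 0.3, 11.0]) + np.array([1.0, 5.0, 0.0])
        f2 = consensus_fitness(np.column_stack(
            [normalize_chi2_set(scaled[:, j]) for j in range(3)]))
        np.testing.assert_array_equal(np.argsort(f1), np.argsort(f2))


class TestCurveIO:
    def test_round_trip_and_nm_units(self, tmp_path):
        q = np.linspace(0.01, 0.3, 10)
        curve = SANSCurve(q, np.exp(-q), 0.01 * np.ones_like(q))
        p = tmp_path / "c.dat"
        write_sans_curve(curve, p, header="test curve")
        back = read_sans_curve(p)
        np.testing.assert_allclose(back.q, q, rtol=1e-6)
        np.testing.assert_allclose(back.intensity, curve.intensity, rtol=1e-6)
        back_nm = read_sans_curve(p, q_units="nm")
        np.testing.assert_allclose(back_nm.q, q / 10.0, rtol=1e-6)


class TestTruthWinsFitness:
    def test_ground_truth_has_best_fitness_in_most_seeds(self, toy_complex):
        """Truth + 5 decoys, 2 contrasts, 3% noise: truth ranks first >= 95/100."""
        from presans.pipeline import sans_score_ensemble
        from presans.synthetic import make_decoys

        schemes = [LabelingScheme.make({"A": 1.0, "B": 1.0, "C": 0.0}, 0.42, name="a"),
                   LabelingScheme.make({"A": 1.0, "B": 1.0, "C": 1.0}, 0.0, name="b")]
        wins = 0
        for seed in range(100):
            decoys, _ = make_decoys(toy_complex, 5, 15.0, 40.0, ["C"],
                                    seed=seed, include_truth=True)
            datasets = [(s, simulate_sans(toy_complex, s, noise_frac=0.03,
                                          seed=1000 + 2 * seed + k))
                        for k, s in enumerate(schemes)]
            _, fitness = sans_score_ensemble(decoys, datasets)
            wins += int(np.argmin(fitness) == 0)
        assert wins >= 95
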