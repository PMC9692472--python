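"""NMR quantification, fractional enrichment and isotopomer modeling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdxmet.isotopomer import (CARBONS, COMPONENTS, IsotopomerFit,
                               MultipletSet, aicc_score,
                               anderson_darling_pvalue, fit_isotopomer,
                               select_model, simulate_multiplets)
from pdxmet.nmr import (absolute_concentration, add_fractional_enrichment,
                        fractional_enrichment, quantify_1d,
                        relative_concentration)
from pdxmet.synthetic import MetabolitePool, NMRGroundTruth, make_nmr_tables


class TestAbsoluteConcentration:
    def test_unit_arithmetic(self):
        # area == TSP area, 9 protons, 100 nmol TSP, 10 mg tissue
        assert absolute_concentration(1000.0, 1000.0, 9, 100.0, 10.0) == 10.0

    def test_zero_area(self):
        assert absolute_concentration(0.0, 1000.0, 3, 100.0, 10.0) == 0.0

    def test_rejections(self):
        with pytest.raises(ValueError, match="TSP area"):
            absolute_concentration(1.0, 0.0, 3, 100.0, 10.0)
        with pytest.raises(ValueError, match="tissue mass"):
            absolute_concentration(1.0, 10.0, 3, 100.0, 0.0)

    def test_generator_round_trip(self):
        truth = NMRGroundTruth(
            metabolites={"x": MetabolitePool(pool=7.5, fe=0.0, protons=5)})
        tables = make_nmr_tables(truth)
        out = quantify_1d(tables.peaks_1d, truth.tsp_amount_nmol,
                          truth.tissue_mass_mg)
        assert out["absolute_nmol_mg"].iloc[0] == pytest.approx(7.5, rel=1e-9)


class TestRelativeConcentration:
    def test_ratio(self):
        assert relative_concentration(2.0, 4.0) == 0.5

    def test_zero_volume(self):
        assert relative_concentration(0.0, 4.0) == 0.0

    def test_linearity(self):
        assert relative_concentration(6.0, 4.0) == 2 * relative_concentration(3.0, 4.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="TSP reference"):
            relative_concentration(1.0, 0.0)


class TestFractionalEnrichment:
    def test_quarter(self):
        assert fractional_enrichment(2.0, 8.0) == 0.25

    def test_fully_labeled(self):
        assert fractional_enrichment(5.0, 5.0) == 1.0

    def test_zero_total_undefined(self):
        assert np.isnan(fractional_enrichment(0.0, 0.0))

    def test_scale_invariance(self):
        assert fractional_enrichment(2.0, 8.0) == fractional_enrichment(20.0, 80.0)

    def test_table_flags_above_threshold(self):
        table = pd.DataFrame({"metabolite": ["a", "b"],
                              "absolute_nmol_mg": [10.0, 10.0],
                              "area": [1.0, 1.0], "protons": [1, 1],
                              "relative_ru": [0.1, 0.1]})
        hsqc = pd.DataFrame({"metabolite": ["a", "b"],
                             "labeled_nmol_mg": [4.0, 10.5]})
        out = add_fractional_enrichment(table, hsqc)
        assert list(out["fe_flagged"]) == [False, True]
        assert out["fe"].iloc[0] == pytest.approx(0.4)


def first_turn_enumeration_oracle(f_pdh):
    """Exhaustive first-turn oracle, independent of the package.

    Enumerate acetyl-CoA label states (both carbons labeled with
    probability f, else unlabeled) condensing with unlabeled
    oxaloacetate. Chemistry: glutamate C4 <- acetyl methyl, C5 <- acetyl
    carbonyl, C1-C3 <- oxaloacetate (unlabeled on the first turn).
    Returns P(C4 labeled) and the conditional C4 neighbor pattern.
    """
    states = [(f_pdh, 1, 1), (1.0 - f_pdh, 0, 0)]  # (prob, C4, C5)
    p_c4 = sum(p for p, c4, _ in states if c4)
    if p_c4 == 0:
        return 0.0, None
    pattern = {"S": 0.0, "D34": 0.0, "D45": 0.0, "Q": 0.0}
    for p, c4, c5 in states:
        if not c4:
            continue
        c3 = 0  # from unlabeled OAA
        key = {(0, 0): "S", (1, 0): "D34", (0, 1): "D45", (1, 1): "Q"}[(c3, c5)]
        pattern[key] += p / p_c4
    return p_c4, pattern


class TestMultipletForwardModel:
    def test_first_turn_pdh_only_is_pure_d45(self):
        m = simulate_multiplets(1.0, 0.0, 0.0, n_turns=1)
        p_c4, expected = first_turn_enumeration_oracle(1.0)
        assert m.labeled["C4"] == pytest.approx(p_c4)
        for comp, val in expected.items():
            assert m.fractions["C4"][comp] == pytest.approx(val)
        assert m.labeled["C3"] == 0.0

    def test_first_turn_partial_enrichment_against_oracle(self):
        f = 0.6
        m = simulate_multiplets(f, 0.0, 0.0, n_turns=1)
        p_c4, expected = first_turn_enumeration_oracle(f)
        assert m.labeled["C4"] == pytest.approx(p_c4)
        for comp, val in expected.items():
            assert m.fractions["C4"][comp] == pytest.approx(val)

    def test_no_labeled_acetyl_means_c4_unlabeled(self):
        m = simulate_multiplets(0.0, 0.0, 0.0)
        assert m.labeled["C4"] == 0.0
        assert all(v == 0.0 for v in m.fractions["C4"].values())

    @given(st.floats(0.05, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_fractions_form_a_simplex(self, f, y_pc, y_s):
        m = simulate_multiplets(f, y_pc, y_s)
        for carbon in CARBONS:
            total = sum(m.fractions[carbon].values())
            assert total == pytest.approx(1.0, abs=1e-6) or total == 0.0
            assert all(v >= 0 for v in m.fractions[carbon].values())

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="f_pdh"):
            simulate_multiplets(1.5)
        with pytest.raises(ValueError, match="n_turns"):
            simulate_multiplets(0.5, n_turns=0)


class TestIsotopomerFitting:
    def test_forward_inverse_closure_over_grid(self):
        for f, y_pc in itertools.product((0.25, 0.5, 0.75, 1.0),
                                         (0.0, 0.25, 0.5)):
            obs = simulate_multiplets(f, y_pc, 0.0)
            fit = fit_isotopomer(obs, models=("pdh_pc",), seed=0)[0]
            assert fit.params["f_pdh"] == pytest.approx(f, abs=0.02)
            assert fit.params["y_pc"] == pytest.approx(y_pc, abs=0.02)

    def test_aicc_prefers_parsimony_at_equal_fit(self):
        obs = simulate_multiplets(0.6, 0.0, 0.0)  # PDH-only truth
        fits = fit_isotopomer(obs, models=("pdh", "pdh_pc"), seed=0)
        assert fits[0].ssr < 1e-10 and fits[1].ssr < 1e-10
        best, _ = select_model(fits)
        assert best.model == "pdh"

    def test_aicc_formula_orderings(self):
        # equal SSR, fewer parameters wins; equal k, lower SSR wins
        a1, _ = aicc_score(0.01, 12, 1)
        a2, _ = aicc_score(0.01, 12, 2)
        assert a1 < a2
        b1, _ = aicc_score(0.005, 12, 2)
        assert b1 < a2
        nan_aicc, reason = aicc_score(0.01, 3, 2)
        assert np.isnan(nan_aicc) and "undefined" in reason

    def test_select_model_lowest_aicc_and_overfit_flag(self):
        def fake_fit(model, aicc, adp, k):
            return IsotopomerFit(model=model, params={"f_pdh": 0.5, "y_pc": 0,
                                                      "y_s": 0},
                                 ssr=0.1, aicc=aicc, ln_residual=-2.3,
                                 adp=adp, n_points=12, k_params=k,
                                 residuals=np.zeros(12))
        best, table = select_model([fake_fit("a", -10.0, 0.5, 1),
                                    fake_fit("b", -3.0, 0.5, 2)])
        assert best.model == "a" and not best.overfit_flag
        best2, _ = select_model([fake_fit("c", -10.0, 0.01, 1)])
        assert best2.overfit_flag

        with pytest.raises(ValueError, match="finite AICc"):
            select_model([fake_fit("d", np.nan, 0.5, 1)])

    def test_anderson_darling_flags_structured_residuals(self):
        # one dominant structured deviation among near-constant residuals
        structured = np.array([0.01] * 11 + [0.5])
        assert anderson_darling_pvalue(structured) < 0.05
        assert np.isnan(anderson_darling_pvalue(np.zeros(12)))

    def test_paper_scenario_equal_pc_and_pdh_contributions(self):
        # flux scenario where carboxylase anaplerosis matches the
        # dehydrogenase route: Y_PC recovered equal to its true value and
        # the PC:PDH contribution ratio is ~1
        obs = simulate_multiplets(0.5, 0.5, 0.0)
        fits = fit_isotopomer(obs, seed=2)
        best, _ = select_model(fits)
        assert best.model == "pdh_pc"
        assert best.params["f_pdh"] == pytest.approx(0.5, abs=0.02)
        assert best.params["y_pc"] == pytest.approx(0.5, abs=0.02)


class TestMultipletSetContainer:
    def test_vector_round_trip(self):
        m = simulate_multiplets(0.7, 0.3, 0.1)
        again = MultipletSet.from_vector(m.as_vector())
        assert np.allclose(again.as_vector(), m.as_vector())

    def test_frame_round_trip(self):
        m = simulate_multiplets(0.7, 0.3, 0.1)
        again = MultipletSet.from_frame(m.to_frame())
        assert np.allclose(again.as_vector(), m.as_vector())

    def test_invalid_fractions_rejected(self):
        bad = {c: {comp: 0.5 for comp in COMPONENTS[c]} for c in CARBONS}
        with pytest.raises(ValueError, match="sum"):
            MultipletSet(fractions=bad)
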