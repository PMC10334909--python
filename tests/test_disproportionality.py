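"""Disproportionality statistics: frozen oracle values, independent
cross-checks (scipy / statsmodels / gamma-posterior quantiles), and the
algebraic invariants that tie PRR, ROR and chi-square together."""

import math

import numpy as np
import pytest
from scipy import stats

from helpers import make_case

from pvsignal.disproportionality import (
    ContingencyTable,
    Disproportionality,
    build_contingency,
    chi_square,
    evaluate_signal,
    ic025_gamma_quantile,
    information_component,
    prr,
    ror,
    screen_all_pairs,
)

TOL = 1e-12


class TestContingencyTable:
    def test_enumeration_of_four_cases(self, study_queries):
        drug_q, event_q = study_queries
        cases = [
            make_case(drugs=[("AVAPRITINIB", "PS")],
                      reactions=["Photosensitivity reaction"]),
            make_case(drugs=[("AVAPRITINIB", "PS")], reactions=["Rash"]),
            make_case(drugs=[("IMATINIB", "PS")],
                      reactions=["Photosensitivity reaction"]),
            make_case(drugs=[("IMATINIB", "PS")], reactions=["Rash"]),
        ]
        t = build_contingency(cases, drug_q, event_q)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_degenerate_all_exposed_all_event(self, study_queries):
        drug_q, event_q = study_queries
        cases = [make_case(drugs=[("AVAPRITINIB", "PS")],
                           reactions=["Photosensitivity reaction"])] * 5
        t = build_contingency(cases, drug_q, event_q)
        assert (t.a, t.b, t.c, t.d) == (5, 0, 0, 0)

    def test_empty_case_list_is_an_error(self, study_queries):
        with pytest.raises(ValueError):
            build_contingency([], *study_queries)

    def test_negative_cell_is_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)


class TestPrr:
    # hand-evaluated fractions, frozen
    @pytest.mark.parametrize("cells, expected", [
        ((10, 10, 10, 10), 1.0),
        ((10, 90, 10, 890), 9.0),       # (10/100) / (10/900)
        ((4, 1, 1, 4), 4.0),            # (4/5) / (1/5)
        ((13, 187, 146, 24562), 13 * 24708 / (200 * 146)),
    ])
    def test_hand_computed_values(self, cells, expected):
        assert prr(ContingencyTable(*cells)) == pytest.approx(expected, abs=TOL)

    def test_zero_c_is_flagged_infinite(self):
        assert math.isinf(prr(ContingencyTable(5, 5, 0, 10)))

    def test_zero_drug_margin_is_flagged_nan(self):
        assert math.isnan(prr(ContingencyTable(0, 0, 5, 10)))


class TestChiSquare:
    @pytest.mark.parametrize("cells, yates, expected", [
        ((10, 10, 10, 10), False, 0.0),
        ((10, 10, 10, 10), True, 0.0),
        ((4, 1, 1, 4), False, 3.6),   # 10*(16-1)^2 / 5^4
        ((4, 1, 1, 4), True, 1.6),    # 10*(15-5)^2 / 625
    ])
    def test_hand_computed_values(self, cells, yates, expected):
        assert chi_square(ContingencyTable(*cells), yates=yates) == \
            pytest.approx(expected, abs=TOL)

    def test_yates_floors_at_zero_below_half_n(self):
        # |ad-bc| = 21 = n/2 -> corrected numerator floors at exactly 0
        t = ContingencyTable(11, 10, 10, 11)
        assert chi_square(t, yates=True) == 0.0

    def test_zero_marginal_is_flagged_nan(self):
        assert math.isnan(chi_square(ContingencyTable(0, 0, 5, 5)))

    @pytest.mark.parametrize("cells", [(4, 1, 1, 4), (13, 187, 146, 24562),
                                       (3, 50, 7, 1000)])
    @pytest.mark.parametrize("yates", [False, True])
    def test_agrees_with_scipy(self, cells, yates):
        t = ContingencyTable(*cells)
        ref = stats.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=yates).statistic
        assert chi_square(t, yates=yates) == pytest.approx(ref, rel=1e-10)


class TestRor:
    def test_symmetric_table_is_unity(self):
        assert ror(ContingencyTable(10, 10, 10, 10)).ror == pytest.approx(1.0, abs=TOL)

    def test_hand_computed_value(self):
        assert ror(ContingencyTable(4, 1, 1, 4)).ror == pytest.approx(16.0, abs=TOL)

    def test_zero_cell_gets_haldane_anscombe_correction(self):
        est = ror(ContingencyTable(4, 0, 1, 4))
        assert est.corrected
        # (4.5 * 4.5) / (0.5 * 1.5) = 27.0 exactly
        assert est.ror == pytest.approx(27.0, abs=TOL)

    def test_ci_brackets_the_estimate(self):
        est = ror(ContingencyTable(13, 187, 146, 24562))
        assert est.ci95[0] < est.ror < est.ci95[1]
        assert not est.corrected

    def test_ci_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        t = ContingencyTable(13, 187, 146, 24562)
        table = sm.stats.Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
        est = ror(t)
        assert est.ror == pytest.approx(table.oddsratio, rel=1e-10)
        lo, hi = table.oddsratio_confint(0.05)
        # statsmodels uses the same Wald interval with z from the normal ppf
        assert est.ci95[0] == pytest.approx(lo, rel=1e-3)
        assert est.ci95[1] == pytest.approx(hi, rel=1e-3)


class TestInformationComponent:
    def test_independence_with_shrinkage_cancelling(self):
        ic, _ = information_component(ContingencyTable(10, 10, 10, 10))
        assert ic == pytest.approx(0.0, abs=TOL)

    def test_hand_computed_ic025(self):
        # 0 - 3.3/sqrt(10.5) - 2/10.5^1.5 = -1.0771...
        _, ic025 = information_component(ContingencyTable(10, 10, 10, 10))
        assert ic025 == pytest.approx(-1.077, abs=5e-4)

    def test_closed_form_tracks_gamma_posterior_quantile_across_grid(self):
        # IC025 approximates the 2.5th percentile of the shrinkage gamma
        # posterior; audit it across a in 1..50 and a spread of expecteds
        worst = 0.0
        for a in range(1, 51):
            for e in (0.5, 1.0, 2.0, 0.5 * a, 1.0 * a, 2.0 * a):
                exact = ic025_gamma_quantile(a, e)
                ic = math.log2((a + 0.5) / (e + 0.5))
                approx = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
                worst = max(worst, abs(exact - approx))
        assert worst < 0.15

    def test_monte_carlo_percentile_matches_closed_form(self):
        # 10^6 gamma draws, fixed seed: the sampled 2.5th percentile of
        # log2(G/E) sits within 0.15 of the closed-form bound
        rng = np.random.default_rng(20200131)
        t = ContingencyTable(13, 187, 146, 24562)
        e = t.expected
        g = rng.gamma(t.a + 0.5, e / (e + 0.5), size=10**6)
        mc = np.percentile(np.log2(g / e), 2.5)
        _, ic025 = information_component(t)
        assert abs(mc - ic025) < 0.15

    def test_defined_even_with_zero_cells(self):
        ic, ic025 = information_component(ContingencyTable(0, 0, 0, 5))
        assert math.isfinite(ic) and math.isfinite(ic025)


def random_tables(rng, size):
    cells = rng.integers(1, 500, size=(size, 4))
    return [ContingencyTable(*map(int, row)) for row in cells]


class TestInvariants:
    def test_sign_concordance_on_random_tables(self):
        # sign(PRR-1) == sign(ROR-1) == sign(ad-bc) whenever defined
        rng = np.random.default_rng(99)
        for t in random_tables(rng, 1000):
            s = np.sign(t.a * t.d - t.b * t.c)
            assert np.sign(prr(t) - 1) == s
            assert np.sign(ror(t).ror - 1) == s

    def test_chi_square_invariant_under_row_column_swap(self):
        rng = np.random.default_rng(100)
        for t in random_tables(rng, 1000):
            for yates in (False, True):
                assert chi_square(t, yates) == pytest.approx(
                    chi_square(t.swapped(), yates), rel=1e-9)

    def test_ror_bounds_prr_when_positive_association(self):
        rng = np.random.default_rng(101)
        for t in random_tables(rng, 500):
            ad_bc = t.a * t.d - t.b * t.c
            if ad_bc > 0:
                assert ror(t).ror >= prr(t) - 1e-12
            elif ad_bc < 0:
                assert ror(t).ror <= prr(t) + 1e-12

    def test_ic025_below_ic_and_increasing_in_a(self):
        rng = np.random.default_rng(102)
        for t in random_tables(rng, 200):
            ic, ic025 = information_component(t)
            assert ic025 < ic
        # IC increases in a with margins (approximately) held fixed
        ics = [information_component(ContingencyTable(a, 200 - a, 50, 5000))[0]
               for a in range(1, 50)]
        assert all(x < y for x, y in zip(ics, ics[1:]))


class TestEvaluateSignal:
    def test_published_scale_statistics_meet_all_three(self):
        crit = evaluate_signal(11.0, 107.0, 13, 11.0, 2.1)
        assert crit.evans and crit.ror_rule and crit.ic_rule
        assert crit.all_three

    def test_evans_thresholds_are_inclusive(self):
        assert evaluate_signal(2.0, 4.0, 3, 2.0, 1.0).evans

    def test_evans_fails_below_prr_threshold(self):
        crit = evaluate_signal(1.9, 10.0, 5, 2.0, 1.0)
        assert not crit.evans
        assert not crit.all_three

    def test_undefined_statistic_fails_with_note(self):
        crit = evaluate_signal(math.nan, 10.0, 5, 2.0, 1.0)
        assert not crit.evans
        assert any("undefined" in n for n in crit.notes)

    def test_infinite_prr_still_satisfies_evans(self):
        assert evaluate_signal(math.inf, 10.0, 5, 2.0, 1.0).evans


class TestModelResults:
    def test_results_expose_table_and_criteria(self):
        res = Disproportionality(ContingencyTable(13, 187, 146, 24562)).fit()
        assert res.n_events == 13
        assert res.prr == pytest.approx(13 * 24708 / (200 * 146), abs=TOL)
        assert res.criteria.all_three
        d = res.to_dict()
        assert d["a"] == 13 and d["signal_all_three"] is True

    def test_summary_renders_every_statistic(self):
        res = Disproportionality(ContingencyTable(4, 1, 1, 4)).fit(yates=False)
        text = res.summary()
        for token in ("PRR", "ROR", "IC025", "chi2", "Evans"):
            assert token in text


class TestScreening:
    def test_single_pair_dataset_yields_one_hit(self, study_queries):
        cases = [make_case(drugs=[("AVAPRITINIB", "PS")],
                           reactions=["Photosensitivity reaction"])] * 4 + \
                [make_case(drugs=[("IMATINIB", "PS")], reactions=["Rash"])] * 8
        hits = screen_all_pairs(cases, min_a=3)
        pairs = {(g, e) for g, e, _ in hits}
        assert ("AVAPRITINIB", "Photosensitivity reaction") in pairs

    def test_min_a_drops_sparse_pairs(self):
        cases = [make_case(drugs=[("AVAPRITINIB", "PS")],
                           reactions=["Photosensitivity reaction"])] * 2 + \
                [make_case(drugs=[("IMATINIB", "PS")], reactions=["Rash"])] * 8
        hits = screen_all_pairs(cases, min_a=3)
        assert ("AVAPRITINIB", "Photosensitivity reaction") not in \
            {(g, e) for g, e, _ in hits}

    def test_ranked_descending_by_ic025(self, fixture_cases):
        hits = screen_all_pairs(fixture_cases, min_a=3)
        scores = [r.ic025 for _, _, r in hits]
        assert scores == sorted(scores, reverse=True)
        # the planted association ranks first
        assert (hits[0][0], hits[0][1]) == ("AVAPRITINIB", "Photosensitivity reaction")
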