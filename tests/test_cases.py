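"""Case deduplication, drug-name normalisation, and membership queries."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import demo, make_case
from pvsignal.cases import (
    DrugQuery,
    EventQuery,
    case_has_drug,
    case_has_event,
    deduplicate,
    normalize_drugname,
)
from pvsignal.io import DrugRecord, QuarterlyDataset, ReactionRecord


class TestNormalizeDrugname:
    @pytest.mark.parametrize("raw, expected", [
        (" avapritinib 300 MG ", "AVAPRITINIB"),
        ("AYVAKIT", "AYVAKIT"),
        ("Insulin  Glargine", "INSULIN GLARGINE"),
        ("METFORMIN HCL 500 MG TABLETS", "METFORMIN"),
        ("  ", ""),           # nothing survives -> unmatched flag
        ("500 MG", ""),
    ])
    def test_normalisation_rules(self, raw, expected):
        assert normalize_drugname(raw) == expected


class TestDeduplicate:
    def test_highest_version_is_retained(self):
        ds = QuarterlyDataset(
            demo=[demo("1001", "100", 1), demo("1002", "100", 2)],
            drug=[], reac=[], outc=[])
        result = deduplicate(ds)
        assert len(result.cases) == 1
        assert result.cases[0].chosen_primaryid == "1002"
        assert result.n_discarded == 1

    def test_version_tie_breaks_on_latest_receipt_date(self):
        ds = QuarterlyDataset(
            demo=[demo("1001", "100", 2, dt.date(2021, 1, 1)),
                  demo("1002", "100", 2, dt.date(2021, 6, 1))],
            drug=[], reac=[], outc=[])
        assert deduplicate(ds).cases[0].chosen_primaryid == "1002"

    def test_full_tie_breaks_on_greatest_primaryid(self):
        d = dt.date(2021, 1, 1)
        ds = QuarterlyDataset(
            demo=[demo("1009", "100", 2, d), demo("1001", "100", 2, d)],
            drug=[], reac=[], outc=[])
        assert deduplicate(ds).cases[0].chosen_primaryid == "1009"

    def test_children_come_from_retained_version_only(self):
        ds = QuarterlyDataset(
            demo=[demo("1001", "100", 1), demo("1002", "100", 2)],
            drug=[DrugRecord("1001", 1, "PS", "OLDNAME"),
                  DrugRecord("1002", 1, "PS", "NEWNAME")],
            reac=[ReactionRecord("1001", "Rash")],
            outc=[])
        case = deduplicate(ds).cases[0]
        assert [d.drugname for d in case.drugs] == ["NEWNAME"]
        assert case.reactions == []  # the old version's reaction is gone

    def test_dedup_is_idempotent(self, fixture_universe):
        dataset, _ = fixture_universe
        from pvsignal.cases import cases_to_dataset

        first = deduplicate(dataset)
        second = deduplicate(cases_to_dataset(first.cases))
        assert len(second.cases) == len(first.cases)
        assert second.n_discarded == 0
        assert [c.chosen_primaryid for c in second.cases] == \
               [c.chosen_primaryid for c in first.cases]

    @settings(max_examples=30, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(1, 30), st.integers(1, 4),
                  st.dates(dt.date(2020, 1, 1), dt.date(2021, 12, 31))),
        min_size=1, max_size=60))
    def test_one_case_per_distinct_caseid_on_fuzzed_versions(self, reports):
        ds = QuarterlyDataset(
            demo=[demo(f"{cid}{ver}{i}", str(cid), ver, date)
                  for i, (cid, ver, date) in enumerate(reports)],
            drug=[], reac=[], outc=[])
        result = deduplicate(ds)
        assert len(result.cases) == len({cid for cid, _, _ in reports})
        assert len(result.cases) + result.n_discarded == len(reports)
        # retained report carries the maximal version of its case
        best = {}
        for cid, ver, _ in reports:
            best[cid] = max(best.get(cid, 0), ver)
        for case in result.cases:
            assert case.demographics.caseversion == best[int(case.caseid)]


class TestQueries:
    def test_suspect_role_matches(self):
        case = make_case(drugs=[("AVAPRITINIB", "PS")])
        q = DrugQuery(names=frozenset({"AVAPRITINIB"}), roles=frozenset({"PS", "SS"}))
        assert case_has_drug(case, q)

    def test_concomitant_role_does_not_match_suspect_query(self):
        case = make_case(drugs=[("AVAPRITINIB", "C")])
        q = DrugQuery(names=frozenset({"AVAPRITINIB"}), roles=frozenset({"PS", "SS"}))
        assert not case_has_drug(case, q)

    def test_substring_mode_matches_formulation_suffix(self):
        case = make_case(drugs=[("AVAPRITINIB FILM-COATED", "PS")])
        q = DrugQuery(names=frozenset({"AVAPRITINIB"}), match_mode="substring",
                      roles=frozenset({"PS"}))
        assert case_has_drug(case, q)

    def test_trade_name_matches_via_synonym_set(self):
        case = make_case(drugs=[("Ayvakit 100 mg", "PS")])
        q = DrugQuery(names=frozenset({"AVAPRITINIB", "AYVAKIT"}),
                      roles=frozenset({"PS"}))
        assert case_has_drug(case, q)

    def test_event_match_is_case_insensitive_exact(self):
        case = make_case(reactions=["PHOTOSENSITIVITY REACTION"])
        q = EventQuery(preferred_terms=frozenset({"Photosensitivity reaction"}))
        assert case_has_event(case, q)
        assert not case_has_event(
            make_case(reactions=["Photophobia"]), q)
        assert not case_has_event(make_case(), q)

    def test_adding_names_never_unmatches_a_case(self):
        # monotonicity of the name set
        case = make_case(drugs=[("AVAPRITINIB", "PS"), ("LORATADINE", "C")])
        roles = frozenset({"PS", "SS", "C", "I"})
        small = DrugQuery(names=frozenset({"AVAPRITINIB"}), roles=roles)
        big = DrugQuery(names=frozenset({"AVAPRITINIB", "LORATADINE", "OTHER"}),
                        roles=roles)
        assert case_has_drug(case, small)
        assert case_has_drug(case, big)

    def test_empty_query_sets_are_rejected(self):
        with pytest.raises(ValueError):
            DrugQuery(names=frozenset())
        with pytest.raises(ValueError):
            EventQuery(preferred_terms=frozenset())


class TestSeriousness:
    @pytest.mark.parametrize("codes, expected", [
        ((), False),
        (("HO",), True),
        (("OT",), True),
        (("DE", "HO"), True),
    ])
    def test_serious_iff_any_outcome_code(self, codes, expected):
        assert make_case(outcomes=codes).serious is expected
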