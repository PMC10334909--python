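"""Shared construction helpers for the test suite."""

from pvsignal.cases import CaseReport
from pvsignal.io import DemoRecord, DrugRecord, OutcomeRecord, ReactionRecord


def demo(pid, caseid, version=1, date=None):
    return DemoRecord(primaryid=pid, caseid=caseid, caseversion=version,
                      fda_receipt_date=date)


def make_case(drugs=(), reactions=(), outcomes=()):
    """A one-off deduplicated case from (name, role) drugs and PT strings."""
    return CaseReport(
        caseid="1", chosen_primaryid="11", demographics=demo("11", "1"),
        drugs=[DrugRecord("11", i + 1, role, name)
               for i, (name, role) in enumerate(drugs)],
        reactions=[ReactionRecord("11", pt) for pt in reactions],
        outcomes=[OutcomeRecord("11", c) for c in outcomes],
    )
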