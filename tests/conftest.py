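"""Shared fixtures and the independent brute-force counting oracle."""

from __future__ import annotations

from typing import Iterable

import pytest
from hypothesis import HealthCheck, settings

from pvsignal.icsr import DrugEntry, IcsrDatabase, IcsrReport
from pvsignal.synthetic import default_paper_profile, generate

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


def make_report(report_id: str, drugs, events, **kw) -> IcsrReport:
    """Compact report builder: drugs as (name, role) pairs."""
    defaults = dict(
        sex="female",
        age_band="18-44",
        reporter="physician",
        region="americas",
        year=2019,
        serious="no",
        outcome="unknown",
        action_taken="unknown",
        outcome_after_action="unknown",
    )
    defaults.update(kw)
    return IcsrReport(
        report_id=report_id,
        drugs=tuple(DrugEntry(n, r) for n, r in drugs),
        events=tuple(events),
        **defaults,
    )


@pytest.fixture()
def toy_db() -> IcsrDatabase:
    """Four reports: X+event, X alone, Y+event, Y alone (X a mAb)."""
    reports = [
        make_report("t1", [("x", "suspect")], ["ptev", "other"]),
        make_report("t2", [("x", "suspect")], ["other"]),
        make_report("t3", [("y", "suspect")], ["ptev"]),
        make_report("t4", [("y", "suspect")], ["other"]),
    ]
    db = IcsrDatabase(reports=reports, drug_catalog={"x": True, "y": False})
    db.validate()
    return db


@pytest.fixture(scope="session")
def small_db():
    """An 800-report synthetic database with the default planted pattern."""
    cfg = default_paper_profile(n_reports=800, seed=7)
    db, truth = generate(cfg)
    return db, truth


def brute_force_cells(
    db: IcsrDatabase,
    drug: str,
    terms: Iterable[str],
    roles: Iterable[str],
    comparator: str = "all_drugs",
) -> tuple[int, int, int, int]:
    """Single-pass per-report counting loop, independent of build_table."""
    terms = set(terms)
    roles = set(roles)
    a = b = c = d = 0
    for rep in db.reports:
        has_drug = any(
            e.drug_name == drug and e.role in roles for e in rep.drugs
        )
        if comparator == "all_mabs":
            in_universe = has_drug or any(
                db.drug_catalog.get(e.drug_name, False) for e in rep.drugs
            )
        else:
            in_universe = True
        if not in_universe:
            continue
        has_event = any(pt in terms for pt in rep.events)
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return a, b, c, d
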