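"""SMQ-style case definition.

A standardized MedDRA query (SMQ) is a curated set of preferred terms
(PTs) that together define a clinical concept. The bundled default is
the narrow-scope anaphylactic-reaction query (ten high-specificity PTs);
a report is a *case* when at least one of its events matches the query.
Matching is exact label matching after case/whitespace normalization —
no LLT-to-PT rollup, since the whole analysis operates at PT level.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from ._util import norm_label, percent
from .icsr import ALL_ROLES, IcsrDatabase, ValidationError


@dataclass(frozen=True)
class SmqDefinition:
    """A named PT set with scope (``narrow`` or ``broad``)."""

    name: str
    scope: str
    pt_terms: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", norm_label(self.name))
        object.__setattr__(
            self, "pt_terms", frozenset(norm_label(t) for t in self.pt_terms)
        )
        if not self.pt_terms:
            raise ValidationError(f"SMQ {self.name!r}: empty term list")
        if self.scope not in ("narrow", "broad"):
            raise ValidationError(f"SMQ {self.name!r}: unknown scope {self.scope!r}")


@dataclass(frozen=True)
class CaseClassification:
    """Per-report case status against an SMQ."""

    report_id: str
    is_case: bool
    matched_terms: frozenset[str]

    def __post_init__(self) -> None:
        if self.is_case != bool(self.matched_terms):
            raise ValidationError(
                f"report {self.report_id}: is_case must mirror matched_terms"
            )


def load_smq(path: str | Path) -> SmqDefinition:
    """Load an SMQ definition from a ``smq_name,scope,pt_term`` CSV.

    Duplicate term rows are deduplicated after normalization; an empty
    term list is fatal. The file must describe a single query.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("smq_name", "scope", "pt_term"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise ValidationError(f"{path}: SMQ file has no terms")
    names = {norm_label(n) for n in df["smq_name"]}
    scopes = {s.strip().lower() for s in df["scope"]}
    if len(names) != 1 or len(scopes) != 1:
        raise ValidationError(f"{path}: expected a single (smq_name, scope)")
    return SmqDefinition(
        name=next(iter(names)),
        scope=next(iter(scopes)),
        pt_terms=frozenset(df["pt_term"]),
    )


def default_anaphylaxis_smq() -> SmqDefinition:
    """The bundled narrow-scope anaphylactic-reaction query (10 PTs)."""
    ref = resources.files("pvsignal.data") / "smq_anaphylactic_narrow.csv"
    with resources.as_file(ref) as p:
        return load_smq(p)


def classify_reports(
    db: IcsrDatabase, smq: SmqDefinition
) -> list[CaseClassification]:
    """One classification per report, in database order.

    Report-level: a report listing several matching PTs is one case.
    Insensitive to event ordering within a report.
    """
    out = []
    for rep in db.reports:
        matched = frozenset(rep.events) & smq.pt_terms
        out.append(
            CaseClassification(
                report_id=rep.report_id,
                is_case=bool(matched),
                matched_terms=matched,
            )
        )
    return out


def case_ids(db: IcsrDatabase, smq: SmqDefinition) -> set[str]:
    """Report ids of the SMQ cases (convenience over classify_reports)."""
    return {c.report_id for c in classify_reports(db, smq) if c.is_case}


def case_term_breakdown(
    db: IcsrDatabase,
    smq: SmqDefinition,
    drug: str,
    roles: Iterable[str] = ALL_ROLES,
) -> pd.DataFrame:
    """Per-PT report counts for one drug, as a share of its filtered total.

    For each PT in the SMQ: the number of role-filtered reports of the
    drug listing that PT, and that count as a percentage of the drug's
    filtered report total (1 decimal, half-up). Counts are report-level,
    so a report naming a PT twice counts once.
    """
    drug_ids = db.reports_with_drug(drug, roles)
    n_drug = len(drug_ids)
    ev = db.event_frame()
    ev_drug = ev[ev["report_id"].isin(drug_ids)]
    rows = []
    for pt in sorted(smq.pt_terms):
        n = ev_drug.loc[ev_drug["pt_term"] == pt, "report_id"].nunique()
        rows.append(
            {
                "drug": norm_label(drug),
                "pt_term": pt,
                "count": int(n),
                "denominator": n_drug,
                "percent": percent(int(n), n_drug),
            }
        )
    return pd.DataFrame(rows)
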