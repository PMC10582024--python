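"""2x2 disproportionality analysis: PRR, ROR, IC/IC025, signal rule.

Each drug-event pair in a spontaneous-report database is summarized by a
two-by-two contingency table of report counts::

                      event of interest   all other events
    drug of interest          A                  B
    comparator drugs          C                  D

with the comparator universe either every report in the database
(``all_drugs``) or the reports mentioning any monoclonal antibody
(``all_mabs``) — the two tracks of a two-track screen. From the table:

* PRR = [A/(A+B)] / [C/(C+D)]        (proportional reporting ratio)
* ROR = (A/B) / (C/D)                (reporting odds ratio)
* IC  = log2( (O+1/2) / (E+1/2) )    (shrinkage information component)

where O = A and E = (A+B)(A+C)/(A+B+C+D) is the count expected under
independence. The IC shrinkage (+1/2 in numerator and denominator) pulls
small-count estimates toward zero; the lower end of its 95% credibility
interval is, by default, the published closed-form approximation

    IC025 = IC - 3.3*(O+1/2)^(-1/2) - 2.363*(O+1/2)^(-3/4)

with an exact gamma-posterior quantile available via ``ic_method=
"gamma_quantile"``. A pair is a *signal* when, conjunctively, it has at
least ``min_reports`` reports (default 3), PRR >= 2, ROR >= 2 and
IC025 >= 0. Undefined metrics (zero cells) are reported as NaN and never
count as positive; no silent continuity correction is applied, though a
Haldane-corrected ROR can be requested explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import pandas as pd
from scipy import stats

from ._util import norm_label
from .icsr import DISPRO_ROLES, IcsrDatabase
from .smq import SmqDefinition

COMPARATORS = ("all_drugs", "all_mabs")
IC_METHODS = ("approx", "gamma_quantile")


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 counts with provenance."""

    a: int
    b: int
    c: int
    d: int
    drug: str = ""
    event_label: str = ""
    comparator: str = "all_drugs"
    roles: frozenset[str] = frozenset(DISPRO_ROLES)

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Count expected in cell A under row/column independence."""
        if self.n == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class SignalCriteria:
    """Conjunctive signal-detection thresholds."""

    min_reports: int = 3
    prr_threshold: float = 2.0
    ror_threshold: float = 2.0
    ic025_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.min_reports < 1:
            raise ValueError("min_reports must be >= 1")
        for v in (self.prr_threshold, self.ror_threshold, self.ic025_threshold):
            if not math.isfinite(v):
                raise ValueError("thresholds must be finite")


@dataclass(frozen=True)
class DisproportionalityResult:
    """All statistics for one drug-event pair."""

    table: ContingencyTable
    prr: float
    ror: float
    ic: float
    ic025: float
    signal_positive: bool
    ror_corrected: float = math.nan  # Haldane 0.5-corrected, informational

    @property
    def n_reports(self) -> int:
        return self.table.a


def prr(t: ContingencyTable) -> float:
    """Proportional reporting ratio, exactly per formula.

    NaN when undefined (no drug reports, no comparator reports, or a
    comparator that never saw the event while the drug did).
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        return math.nan
    if t.a == 0:
        return 0.0
    if t.c == 0:
        return math.nan
    return (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))


def ror(t: ContingencyTable, corrected: bool = False) -> float:
    """Reporting odds ratio (A/B)/(C/D).

    With ``corrected=True`` returns the Haldane-Anscombe value with 0.5
    added to every cell — an explicitly flagged alternative, never a
    silent fallback. Uncorrected ROR is NaN when b, c or d is zero
    (a == 0 with the rest positive gives 0.0).
    """
    if corrected:
        return ((t.a + 0.5) / (t.b + 0.5)) / ((t.c + 0.5) / (t.d + 0.5))
    if t.b == 0 or t.c == 0 or t.d == 0:
        return math.nan
    return (t.a / t.b) / (t.c / t.d)


def ic(t: ContingencyTable, method: str = "approx") -> tuple[float, float]:
    """Shrinkage information component and its 95% credibility lower bound.

    Returns ``(ic, ic025)`` in bits. ``method="approx"`` uses the
    closed-form credibility approximation; ``"gamma_quantile"`` the exact
    2.5% quantile of the Gamma(O+1/2, rate E+1/2) posterior for the
    observed-to-expected ratio. The shrinkage makes every table
    admissible, including all-zero cells (IC = 0 there).
    """
    if method not in IC_METHODS:
        raise ValueError(f"unknown IC method {method!r}")
    o = t.a
    e = t.expected
    ic_point = math.log2((o + 0.5) / (e + 0.5))
    if method == "approx":
        ic025 = ic_point - 3.3 * (o + 0.5) ** -0.5 - 2.363 * (o + 0.5) ** -0.75
    else:
        q = stats.gamma.ppf(0.025, a=o + 0.5, scale=1.0 / (e + 0.5))
        ic025 = math.log2(q)
    return ic_point, ic025


def classify_signal(
    n_reports: int,
    prr_value: float,
    ror_value: float,
    ic025_value: float,
    criteria: SignalCriteria = SignalCriteria(),
) -> bool:
    """Conjunctive signal rule; undefined (NaN) metrics are never positive."""
    values = (prr_value, ror_value, ic025_value)
    if any(isinstance(v, float) and math.isnan(v) for v in values):
        return False
    return (
        n_reports >= criteria.min_reports
        and prr_value >= criteria.prr_threshold
        and ror_value >= criteria.ror_threshold
        and ic025_value >= criteria.ic025_threshold
    )


def ror_from_prr(a: int, n_drug: int, prr_value: float) -> float:
    """Back-solve the ROR implied by (A, drug total, PRR).

    Useful as an internal-consistency check on published result rows
    when the underlying database is not available: the comparator
    reporting proportion is p = (a/n_drug)/PRR, the comparator odds
    p/(1-p), the drug odds a/(n_drug-a), and the ROR their ratio.
    """
    if not (0 < a < n_drug):
        raise ValueError("need 0 < a < n_drug")
    if prr_value <= 0:
        raise ValueError("prr must be positive")
    p = (a / n_drug) / prr_value
    if p >= 1:
        raise ValueError("inconsistent inputs: implied comparator proportion >= 1")
    drug_odds = a / (n_drug - a)
    comparator_odds = p / (1 - p)
    return drug_odds / comparator_odds


def build_table(
    db: IcsrDatabase,
    drug: str,
    event: Union[str, SmqDefinition],
    comparator: str = "all_drugs",
    roles: Iterable[str] = DISPRO_ROLES,
) -> ContingencyTable:
    """Build the report-level 2x2 table for one drug-event pair.

    A and B count the role-filtered reports of the drug (with/without
    the event); C and D split the rest of the comparator universe. Under
    ``all_mabs`` the universe is every report mentioning at least one
    monoclonal antibody in any role; the drug itself must be flagged as
    a mAb. All counts are deduplicated report counts, so the four cells
    always partition the universe.
    """
    drug = norm_label(drug)
    roles = frozenset(roles)
    if comparator not in COMPARATORS:
        raise ValueError(f"unknown comparator {comparator!r}")

    if isinstance(event, SmqDefinition):
        terms: frozenset[str] = event.pt_terms
        # "smq:" prefix keeps the aggregate row distinguishable from a PT
        # that happens to share the query's name
        event_label = f"smq:{event.name}"
    else:
        event_label = norm_label(event)
        terms = frozenset({event_label})

    drug_ids = db.reports_with_drug(drug, roles)  # KeyError if absent

    if comparator == "all_mabs":
        if not db.drug_catalog.get(drug, False):
            raise ValueError(
                f"drug {drug!r} is not flagged is_mab; cannot screen "
                "against the all-mAbs comparator"
            )
        universe = db.reports_with_drug_class(db.mab_drugs)
        universe |= drug_ids
    else:
        universe = set(db.report_ids())

    event_ids = db.reports_with_event(terms)
    other_ids = universe - drug_ids
    if not other_ids:
        raise ValueError(
            f"empty comparator universe for drug {drug!r} under {comparator!r}"
        )

    a = len(drug_ids & event_ids)
    c = len(other_ids & event_ids)
    return ContingencyTable(
        a=a,
        b=len(drug_ids) - a,
        c=c,
        d=len(other_ids) - c,
        drug=drug,
        event_label=event_label,
        comparator=comparator,
        roles=roles,
    )


def analyze_table(
    t: ContingencyTable,
    criteria: SignalCriteria = SignalCriteria(),
    ic_method: str = "approx",
) -> DisproportionalityResult:
    """Compute every statistic plus signal status for one table."""
    prr_v = prr(t)
    ror_v = ror(t)
    ic_v, ic025_v = ic(t, method=ic_method)
    return DisproportionalityResult(
        table=t,
        prr=prr_v,
        ror=ror_v,
        ic=ic_v,
        ic025=ic025_v,
        signal_positive=classify_signal(t.a, prr_v, ror_v, ic025_v, criteria),
        ror_corrected=ror(t, corrected=True),
    )


def screen(
    db: IcsrDatabase,
    drugs: Sequence[str],
    smq: SmqDefinition,
    criteria: SignalCriteria = SignalCriteria(),
    comparator: str = "all_drugs",
    roles: Iterable[str] = DISPRO_ROLES,
    ic_method: str = "approx",
) -> list[DisproportionalityResult]:
    """Screen each drug against every SMQ PT plus the SMQ aggregate.

    Emits one result per (drug, PT) with at least one co-report, plus
    one aggregate result per drug for the SMQ as a whole. Ordering is
    deterministic: drugs in the given order, then descending A, then
    event label.
    """
    results: list[DisproportionalityResult] = []
    for drug in drugs:
        per_drug: list[DisproportionalityResult] = []
        agg = build_table(db, drug, smq, comparator=comparator, roles=roles)
        per_drug.append(analyze_table(agg, criteria, ic_method))
        for pt in sorted(smq.pt_terms):
            t = build_table(db, drug, pt, comparator=comparator, roles=roles)
            if t.a >= 1:
                per_drug.append(analyze_table(t, criteria, ic_method))
        per_drug.sort(key=lambda r: (-r.table.a, r.table.event_label))
        results.extend(per_drug)
    return results


def results_frame(results: Sequence[DisproportionalityResult]) -> pd.DataFrame:
    """Tidy frame of screening results, one row per drug-event pair."""
    rows = [
        {
            "drug": r.table.drug,
            "event_label": r.table.event_label,
            "comparator": r.table.comparator,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "prr": r.prr,
            "ror": r.ror,
            "ic": r.ic,
            "ic025": r.ic025,
            "signal_positive": r.signal_positive,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "drug",
            "event_label",
            "comparator",
            "a",
            "b",
            "c",
            "d",
            "prr",
            "ror",
            "ic",
            "ic025",
            "signal_positive",
        ],
    )
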