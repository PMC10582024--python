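"""Descriptive safety tabulations.

Two table families mirror how spontaneous-report safety studies present
their data:

* a demographics table, stratifying all reports and the SMQ case
  reports side by side over sex, age band, reporter type, seriousness,
  deaths, continent of the primary source, year, indication and drug;
* a per-drug seriousness table over the *serious case* reports,
  breaking down seriousness categories (multi-select), outcome, action
  taken, and outcome after action (dechallenge).

Exhaustive single-select blocks sum to their denominator; the drug and
indication blocks are non-exclusive (one report may carry several) and
are exempt from that invariant, as is the multi-select seriousness
block. Percentages are recomputed from counts at 1 decimal, half-up.
The "deaths" stratum counts reports with a fatal outcome OR a death
seriousness category, deduplicated at report level.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from ._util import norm_label, percent
from .icsr import (
    ACTION_LEVELS,
    AGE_BANDS,
    IcsrDatabase,
    IcsrReport,
    OUTCOME_AFTER_ACTION_LEVELS,
    OUTCOME_LEVELS,
    REGION_LEVELS,
    REPORTER_LEVELS,
    SERIOUSNESS_CATEGORIES,
    SEX_LEVELS,
)
from .smq import CaseClassification

#: Calendar-year strata: everything up to 2015 pooled, then single years.
YEAR_BANDS = ("<=2015", "2016", "2017", "2018", "2019", "unknown")

TABLE_COLUMNS = ["population", "block", "stratum", "count", "denominator", "percent"]


def year_band(year: Optional[int]) -> str:
    if year is None:
        return "unknown"
    if year <= 2015:
        return "<=2015"
    if year <= 2019:
        return str(year)
    return ">2019"


def _block_rows(
    population: str,
    block: str,
    strata: Sequence[str],
    counts: dict[str, int],
    denominator: int,
) -> list[dict]:
    return [
        {
            "population": population,
            "block": block,
            "stratum": s,
            "count": int(counts.get(s, 0)),
            "denominator": denominator,
            "percent": percent(int(counts.get(s, 0)), denominator),
        }
        for s in strata
    ]


def _tabulate(reports: list[IcsrReport], population: str, db: IcsrDatabase) -> list[dict]:
    n = len(reports)
    rows: list[dict] = []

    def counted(values: Iterable[str]) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in values:
            out[v] = out.get(v, 0) + 1
        return out

    rows += _block_rows(population, "sex", SEX_LEVELS, counted(r.sex for r in reports), n)
    rows += _block_rows(
        population, "age_band", AGE_BANDS, counted(r.age_band for r in reports), n
    )
    rows += _block_rows(
        population, "reporter", REPORTER_LEVELS, counted(r.reporter for r in reports), n
    )
    rows += _block_rows(
        population,
        "serious",
        ("yes",),
        {"yes": sum(r.serious == "yes" for r in reports)},
        n,
    )
    rows += _block_rows(
        population, "deaths", ("deaths",), {"deaths": sum(r.is_fatal for r in reports)}, n
    )
    rows += _block_rows(
        population, "region", REGION_LEVELS, counted(r.region for r in reports), n
    )
    year_bands_seen = counted(year_band(r.year) for r in reports)
    bands = YEAR_BANDS + tuple(b for b in year_bands_seen if b not in YEAR_BANDS)
    rows += _block_rows(population, "year", bands, year_bands_seen, n)

    # non-exclusive blocks: one report may name several indications/drugs;
    # an empty indication list is the explicit "unknown" stratum
    ind_counts: dict[str, int] = {}
    for r in reports:
        labels = set(r.indications) or {"unknown"}
        for lab in labels:
            ind_counts[lab] = ind_counts.get(lab, 0) + 1
    rows += _block_rows(
        population, "indication", tuple(sorted(ind_counts)), ind_counts, n
    )

    drug_counts: dict[str, int] = {}
    for r in reports:
        for name in {e.drug_name for e in r.drugs}:
            drug_counts[name] = drug_counts.get(name, 0) + 1
    rows += _block_rows(population, "drug", tuple(sorted(drug_counts)), drug_counts, n)
    return rows


def demographics_table(
    db: IcsrDatabase, case_flags: Sequence[CaseClassification]
) -> pd.DataFrame:
    """Paired stratified counts for all reports and the case reports.

    Returns a tidy frame (population, block, stratum, count, denominator,
    percent) where ``population`` is ``all`` or ``cases``. Exhaustive
    blocks (sex, age_band, reporter, region, year) sum to the population
    denominator; drug and indication blocks are non-exclusive.
    """
    case_ids = {c.report_id for c in case_flags if c.is_case}
    case_reports = [r for r in db.reports if r.report_id in case_ids]
    rows = _tabulate(db.reports, "all", db) + _tabulate(case_reports, "cases", db)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def seriousness_table(
    db: IcsrDatabase,
    case_flags: Sequence[CaseClassification],
    per_drug: Sequence[str],
) -> pd.DataFrame:
    """Per-drug breakdown of the serious case reports.

    For each drug, over the serious SMQ-case reports mentioning it (any
    role): seriousness categories (multi-select, so the block can sum
    past its denominator), outcome, action taken, and outcome after
    action. The per-drug serious-case denominator is emitted on every
    row because published tables rarely print it.
    """
    case_ids = {c.report_id for c in case_flags if c.is_case}
    rows: list[dict] = []
    for drug in per_drug:
        drug_ids = db.reports_with_drug(drug)  # any role for descriptives
        subset = [
            r
            for r in db.reports
            if r.report_id in drug_ids
            and r.report_id in case_ids
            and r.serious == "yes"
        ]
        n = len(subset)
        drug = norm_label(drug)

        cat_counts = {
            cat: sum(cat in r.seriousness_categories for r in subset)
            for cat in SERIOUSNESS_CATEGORIES
        }
        blocks = [
            ("seriousness_category", SERIOUSNESS_CATEGORIES, cat_counts),
            (
                "outcome",
                OUTCOME_LEVELS,
                _value_counts([r.outcome for r in subset]),
            ),
            (
                "action_taken",
                ACTION_LEVELS,
                _value_counts([r.action_taken for r in subset]),
            ),
            (
                "outcome_after_action",
                OUTCOME_AFTER_ACTION_LEVELS,
                _value_counts([r.outcome_after_action for r in subset]),
            ),
        ]
        for block, strata, counts in blocks:
            for s in strata:
                c = int(counts.get(s, 0))
                rows.append(
                    {
                        "drug": drug,
                        "block": block,
                        "stratum": s,
                        "count": c,
                        "denominator": n,
                        "percent": percent(c, n),
                    }
                )
    return pd.DataFrame(
        rows, columns=["drug", "block", "stratum", "count", "denominator", "percent"]
    )


def _value_counts(values: Sequence[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for v in values:
        out[v] = out.get(v, 0) + 1
    return out
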