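"""Data model and tabular I/O for a spontaneous-report (ICSR) database.

The counting unit throughout the package is the individual case safety
report (ICSR): one report carries demographics, one or more drugs (each
with a reporting role), one or more MedDRA-PT-coded adverse events, and
seriousness/outcome fields. The on-disk layout is three normalized CSV
tables keyed by ``report_id`` plus a drug catalog:

* ``reports.csv``       — one row per report (demographics + flags)
* ``report_drugs.csv``  — one row per report-drug mention (with role)
* ``report_events.csv`` — one row per report-PT mention
* ``drug_catalog.csv``  — drug_name, is_mab

Every demographic field admits an explicit ``unknown`` level rather than
a missing cell, so percentages are always over the full denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._util import norm_label

SEX_LEVELS = ("male", "female", "unknown")
AGE_BANDS = ("<18", "18-44", "45-64", "65-74", ">=75", "unknown")
REPORTER_LEVELS = (
    "consumer",
    "physician",
    "other_hcp",
    "pharmacist",
    "lawyer",
    "unknown",
)
REGION_LEVELS = ("americas", "europe", "asia", "oceania", "africa", "unknown")
SERIOUS_LEVELS = ("yes", "no", "unknown")
SERIOUSNESS_CATEGORIES = (
    "hospitalization",
    "life_threatening",
    "death",
    "disabling",
    "congenital_anomaly",
    "other",
)
OUTCOME_LEVELS = (
    "recovered",
    "recovering",
    "recovered_with_sequelae",
    "not_recovered",
    "fatal",
    "unknown",
)
ACTION_LEVELS = (
    "withdrawn",
    "dose_not_changed",
    "dose_reduced",
    "dose_increased",
    "not_applicable",
    "unknown",
)
OUTCOME_AFTER_ACTION_LEVELS = ("abated", "no_effect", "unknown", "fatal")
ROLE_LEVELS = ("suspect", "concomitant", "interacting")

#: Default role filter for disproportionality: only drugs reported as
#: suspect or interacting contribute to a drug's case counts.
DISPRO_ROLES = frozenset({"suspect", "interacting"})
ALL_ROLES = frozenset(ROLE_LEVELS)


class ValidationError(ValueError):
    """A report, database, or input file violates the data contract."""


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report.

    ``role`` is the reporter's causality assessment slot: ``suspect``,
    ``concomitant`` or ``interacting``. ``drug_name`` is stored
    normalized (lowercase, collapsed whitespace).
    """

    drug_name: str
    role: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_name", norm_label(self.drug_name))
        if self.role not in ROLE_LEVELS:
            raise ValidationError(f"unknown drug role {self.role!r}")


@dataclass
class IcsrReport:
    """One spontaneous report."""

    report_id: str
    sex: str = "unknown"
    age_band: str = "unknown"
    reporter: str = "unknown"
    region: str = "unknown"
    year: Optional[int] = None
    serious: str = "unknown"
    seriousness_categories: frozenset[str] = frozenset()
    outcome: str = "unknown"
    action_taken: str = "unknown"
    outcome_after_action: str = "unknown"
    indications: tuple[str, ...] = ()
    drugs: tuple[DrugEntry, ...] = ()
    events: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.seriousness_categories = frozenset(self.seriousness_categories)
        self.drugs = tuple(self.drugs)
        self.events = tuple(norm_label(e) for e in self.events)
        self.indications = tuple(norm_label(i) for i in self.indications)

    def validate(self) -> None:
        checks = (
            (self.sex in SEX_LEVELS, f"sex {self.sex!r}"),
            (self.age_band in AGE_BANDS, f"age_band {self.age_band!r}"),
            (self.reporter in REPORTER_LEVELS, f"reporter {self.reporter!r}"),
            (self.region in REGION_LEVELS, f"region {self.region!r}"),
            (self.serious in SERIOUS_LEVELS, f"serious {self.serious!r}"),
            (self.outcome in OUTCOME_LEVELS, f"outcome {self.outcome!r}"),
            (
                self.action_taken in ACTION_LEVELS,
                f"action_taken {self.action_taken!r}",
            ),
            (
                self.outcome_after_action in OUTCOME_AFTER_ACTION_LEVELS,
                f"outcome_after_action {self.outcome_after_action!r}",
            ),
        )
        for ok, what in checks:
            if not ok:
                raise ValidationError(
                    f"report {self.report_id}: unknown value for {what}"
                )
        bad = self.seriousness_categories - set(SERIOUSNESS_CATEGORIES)
        if bad:
            raise ValidationError(
                f"report {self.report_id}: unknown seriousness categories {sorted(bad)}"
            )
        if not self.drugs:
            raise ValidationError(f"report {self.report_id}: no drugs")
        if not self.events:
            raise ValidationError(f"report {self.report_id}: no events")
        # A report flagged serious must say in what way, and vice versa.
        if (self.serious == "yes") != bool(self.seriousness_categories):
            raise ValidationError(
                f"report {self.report_id}: seriousness_categories must be "
                "non-empty exactly when serious = yes"
            )

    @property
    def is_fatal(self) -> bool:
        """Death at report level: fatal outcome or a death seriousness flag."""
        return self.outcome == "fatal" or "death" in self.seriousness_categories


@dataclass
class IcsrDatabase:
    """A collection of validated reports plus the drug catalog.

    ``drug_catalog`` maps normalized drug name to its monoclonal-antibody
    flag, which defines the restricted comparator class for two-track
    disproportionality screening.
    """

    reports: list[IcsrReport] = field(default_factory=list)
    drug_catalog: dict[str, bool] = field(default_factory=dict)
    _drug_frame: Optional[pd.DataFrame] = field(
        default=None, repr=False, compare=False
    )
    _event_frame: Optional[pd.DataFrame] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.drug_catalog = {norm_label(k): bool(v) for k, v in self.drug_catalog.items()}

    @property
    def n_total(self) -> int:
        return len(self.reports)

    @property
    def mab_drugs(self) -> frozenset[str]:
        return frozenset(d for d, flag in self.drug_catalog.items() if flag)

    def validate(self) -> None:
        seen: set[str] = set()
        for rep in self.reports:
            if rep.report_id in seen:
                raise ValidationError(f"duplicate report_id {rep.report_id}")
            seen.add(rep.report_id)
            rep.validate()
            for entry in rep.drugs:
                if entry.drug_name not in self.drug_catalog:
                    raise ValidationError(
                        f"report {rep.report_id}: drug {entry.drug_name!r} "
                        "absent from catalog"
                    )

    # -- long-format views used by the counting code ----------------------

    def drug_frame(self) -> pd.DataFrame:
        """Long table (report_id, drug_name, role, is_mab), one row per mention."""
        if self._drug_frame is None:
            rows = [
                (r.report_id, e.drug_name, e.role, self.drug_catalog.get(e.drug_name, False))
                for r in self.reports
                for e in r.drugs
            ]
            self._drug_frame = pd.DataFrame(
                rows, columns=["report_id", "drug_name", "role", "is_mab"]
            )
        return self._drug_frame

    def event_frame(self) -> pd.DataFrame:
        """Long table (report_id, pt_term), one row per event mention."""
        if self._event_frame is None:
            rows = [
                (r.report_id, pt) for r in self.reports for pt in r.events
            ]
            self._event_frame = pd.DataFrame(rows, columns=["report_id", "pt_term"])
        return self._event_frame

    def report_ids(self) -> list[str]:
        return [r.report_id for r in self.reports]

    def reports_with_drug(
        self, drug: str, roles: Iterable[str] = ALL_ROLES
    ) -> set[str]:
        """Report ids mentioning ``drug`` with a role in ``roles`` (deduplicated)."""
        drug = norm_label(drug)
        if drug not in self.drug_catalog:
            raise KeyError(f"drug {drug!r} not in catalog")
        df = self.drug_frame()
        mask = (df["drug_name"] == drug) & df["role"].isin(set(roles))
        return set(df.loc[mask, "report_id"])

    def reports_with_drug_class(self, drugs: Iterable[str]) -> set[str]:
        """Report ids mentioning any of ``drugs`` in any role."""
        wanted = {norm_label(d) for d in drugs}
        df = self.drug_frame()
        return set(df.loc[df["drug_name"].isin(wanted), "report_id"])

    def reports_with_event(self, terms: Iterable[str]) -> set[str]:
        """Report ids listing at least one of the PT ``terms``."""
        wanted = {norm_label(t) for t in terms}
        df = self.event_frame()
        return set(df.loc[df["pt_term"].isin(wanted), "report_id"])


def filter_by_role(
    db: IcsrDatabase, drug: str, roles: Iterable[str] = DISPRO_ROLES
) -> list[IcsrReport]:
    """Reports where ``drug`` appears with a role in ``roles``.

    Report-level: a report is returned once even if the drug is listed
    twice. Order follows the database. Raises ``KeyError`` for a drug
    absent from the catalog.
    """
    ids = db.reports_with_drug(drug, roles)
    return [r for r in db.reports if r.report_id in ids]


# -- CSV I/O ---------------------------------------------------------------

_REPORT_COLUMNS = [
    "report_id",
    "sex",
    "age_band",
    "reporter",
    "region",
    "year",
    "serious",
    "seriousness_categories",
    "outcome",
    "action_taken",
    "outcome_after_action",
    "indications",
]


def _read_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing required columns {missing}")
    return df


def read_database(path: str | Path) -> IcsrDatabase:
    """Read a database from a directory holding the four-table CSV layout.

    The returned database is validated; a row that breaks the contract
    (unknown enumeration value, drug missing from the catalog, duplicate
    report id) raises :class:`ValidationError` naming the offender.
    """
    path = Path(path)
    catalog_df = _read_csv(path / "drug_catalog.csv", ["drug_name", "is_mab"])
    catalog = {
        norm_label(row.drug_name): str(row.is_mab).strip().lower() in ("true", "1", "yes")
        for row in catalog_df.itertuples()
    }

    reports_df = _read_csv(path / "reports.csv", _REPORT_COLUMNS)
    drugs_df = _read_csv(path / "report_drugs.csv", ["report_id", "drug_name", "role"])
    events_df = _read_csv(path / "report_events.csv", ["report_id", "pt_term"])

    drugs_by_report: dict[str, list[DrugEntry]] = {}
    for i, row in enumerate(drugs_df.itertuples(), start=2):
        try:
            entry = DrugEntry(row.drug_name, row.role)
        except ValidationError as exc:
            raise ValidationError(f"report_drugs.csv line {i}: {exc}") from None
        drugs_by_report.setdefault(row.report_id, []).append(entry)

    events_by_report: dict[str, list[str]] = {}
    for row in events_df.itertuples():
        events_by_report.setdefault(row.report_id, []).append(row.pt_term)

    reports: list[IcsrReport] = []
    for i, row in enumerate(reports_df.itertuples(), start=2):
        year = None if row.year in ("", "unknown") else int(row.year)
        cats = frozenset(c for c in row.seriousness_categories.split("|") if c)
        inds = tuple(s for s in row.indications.split("|") if s)
        rep = IcsrReport(
            report_id=row.report_id,
            sex=row.sex,
            age_band=row.age_band,
            reporter=row.reporter,
            region=row.region,
            year=year,
            serious=row.serious,
            seriousness_categories=cats,
            outcome=row.outcome,
            action_taken=row.action_taken,
            outcome_after_action=row.outcome_after_action,
            indications=inds,
            drugs=tuple(drugs_by_report.get(row.report_id, ())),
            events=tuple(events_by_report.get(row.report_id, ())),
        )
        try:
            rep.validate()
        except ValidationError as exc:
            raise ValidationError(f"reports.csv line {i}: {exc}") from None
        reports.append(rep)

    db = IcsrDatabase(reports=reports, drug_catalog=catalog)
    db.validate()
    return db


def write_database(db: IcsrDatabase, path: str | Path) -> None:
    """Write ``db`` to ``path`` in the four-table CSV layout (round-trippable)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    report_rows = [
        {
            "report_id": r.report_id,
            "sex": r.sex,
            "age_band": r.age_band,
            "reporter": r.reporter,
            "region": r.region,
            "year": "unknown" if r.year is None else str(r.year),
            "serious": r.serious,
            "seriousness_categories": "|".join(sorted(r.seriousness_categories)),
            "outcome": r.outcome,
            "action_taken": r.action_taken,
            "outcome_after_action": r.outcome_after_action,
            "indications": "|".join(r.indications),
        }
        for r in db.reports
    ]
    pd.DataFrame(report_rows, columns=_REPORT_COLUMNS).to_csv(
        path / "reports.csv", index=False
    )

    drug_rows = [
        {"report_id": r.report_id, "drug_name": e.drug_name, "role": e.role}
        for r in db.reports
        for e in r.drugs
    ]
    pd.DataFrame(drug_rows, columns=["report_id", "drug_name", "role"]).to_csv(
        path / "report_drugs.csv", index=False
    )

    event_rows = [
        {"report_id": r.report_id, "pt_term": pt}
        for r in db.reports
        for pt in r.events
    ]
    pd.DataFrame(event_rows, columns=["report_id", "pt_term"]).to_csv(
        path / "report_events.csv", index=False
    )

    catalog_rows = [
        {"drug_name": name, "is_mab": str(flag).lower()}
        for name, flag in sorted(db.drug_catalog.items())
    ]
    pd.DataFrame(catalog_rows, columns=["drug_name", "is_mab"]).to_csv(
        path / "drug_catalog.csv", index=False
    )
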