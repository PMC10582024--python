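"""Synthetic spontaneous-report database generator with ground truth.

The generator emulates the structure of a large ICSR database: each
report draws one to a few drugs from a catalog (each with a reporting
role), demographics from configurable categorical marginals, and a set
of PT-coded adverse events. Drug-event dependence is planted
multiplicatively: event ``pt`` enters a report with probability

    background(pt) * max(rho(drug, pt) for the report's
                         suspect/interacting drugs, default 1)

so in the rare-event regime the expected proportional reporting ratio
of a planted pair is approximately its relative reporting rate ``rho``.
Only suspect/interacting drugs transmit the signal — concomitant
mentions do not — mirroring the analysis-side role filter. Seriousness,
outcome and action fields are drawn conditionally on whether the report
is a case (carries a case-defining PT).

Every generated database comes with a :class:`GroundTruth` record of
the realized 2x2 cells for each planted pair, counted directly from the
generation arrays (independently of the analysis code), so parameter
recovery and cell bookkeeping are testable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._util import norm_label
from .icsr import DISPRO_ROLES, ROLE_LEVELS, DrugEntry, IcsrDatabase, IcsrReport

#: The ten narrow-scope anaphylactic-reaction PTs (case definition).
ANAPHYLAXIS_PTS = (
    "anaphylactic reaction",
    "anaphylactic shock",
    "anaphylactic transfusion reaction",
    "anaphylactoid reaction",
    "circulatory collapse",
    "kounis syndrome",
    "procedural shock",
    "shock",
    "shock syndrome",
    "type 1 hypersensitivity",
)

ASTHMA_BIOLOGICS = {
    "omalizumab": True,
    "mepolizumab": True,
    "benralizumab": True,
    "reslizumab": True,
    "dupilumab": True,
}


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class SeriousnessModel:
    """Conditional seriousness/outcome model given case status."""

    p_serious_case: float = 0.962
    p_serious_noncase: float = 0.35
    category_marginals: dict[str, float] = field(
        default_factory=lambda: {
            "hospitalization": 0.219,
            "life_threatening": 0.128,
            "death": 0.006,
            "disabling": 0.005,
            "congenital_anomaly": 0.001,
            "other": 0.641,
        }
    )
    p_second_category: float = 0.05
    outcome_marginals: dict[str, float] = field(
        default_factory=lambda: {
            "recovered": 0.36,
            "recovering": 0.045,
            "recovered_with_sequelae": 0.01,
            "not_recovered": 0.017,
            "fatal": 0.004,
            "unknown": 0.564,
        }
    )
    action_marginals: dict[str, float] = field(
        default_factory=lambda: {
            "withdrawn": 0.38,
            "dose_not_changed": 0.055,
            "dose_reduced": 0.008,
            "dose_increased": 0.007,
            "not_applicable": 0.012,
            "unknown": 0.538,
        }
    )
    outcome_after_action_marginals: dict[str, float] = field(
        default_factory=lambda: {
            "abated": 0.41,
            "no_effect": 0.017,
            "unknown": 0.57,
            "fatal": 0.003,
        }
    )


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic database."""

    n_reports: int = 10_000
    drug_marginals: dict[str, float] = field(default_factory=dict)
    mab_drugs: set[str] = field(default_factory=set)
    event_marginals: dict[str, float] = field(default_factory=dict)
    #: (drug, pt) -> relative reporting rate rho (1 = no signal)
    signal_matrix: dict[tuple[str, str], float] = field(default_factory=dict)
    demographic_marginals: dict[str, dict] = field(default_factory=dict)
    role_distribution: dict[str, float] = field(
        default_factory=lambda: {"suspect": 0.8, "concomitant": 0.18, "interacting": 0.02}
    )
    n_drugs_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.75, 2: 0.20, 3: 0.05}
    )
    case_terms: set[str] = field(default_factory=lambda: set(ANAPHYLAXIS_PTS))
    seriousness: SeriousnessModel = field(default_factory=SeriousnessModel)
    #: PT assigned when the event draw comes up empty, so every report
    #: has at least one event; must not be a case-defining term.
    filler_term: str = "drug ineffective"
    seed: int = 0

    def __post_init__(self) -> None:
        self.drug_marginals = {norm_label(k): float(v) for k, v in self.drug_marginals.items()}
        self.mab_drugs = {norm_label(d) for d in self.mab_drugs}
        self.event_marginals = {norm_label(k): float(v) for k, v in self.event_marginals.items()}
        self.signal_matrix = {
            (norm_label(d), norm_label(p)): float(r)
            for (d, p), r in self.signal_matrix.items()
        }
        self.case_terms = {norm_label(t) for t in self.case_terms}
        self.filler_term = norm_label(self.filler_term)

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ConfigError("n_reports must be non-negative")
        if not self.drug_marginals:
            raise ConfigError("drug_marginals is empty")
        if not self.event_marginals:
            raise ConfigError("event_marginals is empty")
        for name, probs in [
            ("drug_marginals", self.drug_marginals),
            ("event_marginals", self.event_marginals),
            ("role_distribution", self.role_distribution),
            ("n_drugs_distribution", self.n_drugs_distribution),
        ]:
            for k, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name}[{k!r}] = {p} outside [0, 1]")
        for field_name, probs in self.demographic_marginals.items():
            total = sum(probs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ConfigError(
                    f"demographic marginal {field_name!r} sums to {total}, not 1"
                )
        for (drug, pt), rho in self.signal_matrix.items():
            if not (math.isfinite(rho) and rho >= 0):
                raise ConfigError(f"rho for ({drug}, {pt}) must be finite and >= 0")
            if drug not in self.drug_marginals:
                raise ConfigError(f"signal drug {drug!r} not in drug_marginals")
            if pt not in self.event_marginals:
                raise ConfigError(f"signal PT {pt!r} not in event_marginals")
            scaled = self.event_marginals[pt] * rho
            if scaled > 1.0:
                raise ConfigError(
                    f"probability overflow for ({drug}, {pt}): "
                    f"background {self.event_marginals[pt]} * rho {rho} = {scaled} > 1"
                )
        if self.filler_term in self.case_terms:
            raise ConfigError("filler_term must not be a case-defining PT")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_reports": self.n_reports,
            "drug_marginals": dict(self.drug_marginals),
            "mab_drugs": sorted(self.mab_drugs),
            "event_marginals": dict(self.event_marginals),
            "signal_matrix": [
                {"drug": drug, "pt_term": pt, "rho": rho}
                for (drug, pt), rho in sorted(self.signal_matrix.items())
            ],
            "demographic_marginals": {
                k: {str(kk): vv for kk, vv in v.items()}
                for k, v in self.demographic_marginals.items()
            },
            "role_distribution": dict(self.role_distribution),
            "n_drugs_distribution": {str(k): v for k, v in self.n_drugs_distribution.items()},
            "case_terms": sorted(self.case_terms),
            "seriousness": {
                "p_serious_case": self.seriousness.p_serious_case,
                "p_serious_noncase": self.seriousness.p_serious_noncase,
                "category_marginals": dict(self.seriousness.category_marginals),
                "p_second_category": self.seriousness.p_second_category,
                "outcome_marginals": dict(self.seriousness.outcome_marginals),
                "action_marginals": dict(self.seriousness.action_marginals),
                "outcome_after_action_marginals": dict(
                    self.seriousness.outcome_after_action_marginals
                ),
            },
            "filler_term": self.filler_term,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        sm = {
            (row["drug"], row["pt_term"]): float(row["rho"])
            for row in d.get("signal_matrix", [])
        }
        demo: dict[str, dict] = {}
        for fname, marg in d.get("demographic_marginals", {}).items():
            demo[fname] = {
                (int(k) if fname == "year" and k != "unknown" else k): float(v)
                for k, v in marg.items()
            }
        ser = d.get("seriousness", {})
        return cls(
            n_reports=int(d.get("n_reports", 10_000)),
            drug_marginals=d.get("drug_marginals", {}),
            mab_drugs=set(d.get("mab_drugs", [])),
            event_marginals=d.get("event_marginals", {}),
            signal_matrix=sm,
            demographic_marginals=demo,
            role_distribution=d.get(
                "role_distribution", {"suspect": 0.8, "concomitant": 0.18, "interacting": 0.02}
            ),
            n_drugs_distribution={
                int(k): float(v)
                for k, v in d.get("n_drugs_distribution", {1: 0.75, 2: 0.2, 3: 0.05}).items()
            },
            case_terms=set(d.get("case_terms", ANAPHYLAXIS_PTS)),
            seriousness=SeriousnessModel(**ser) if ser else SeriousnessModel(),
            filler_term=d.get("filler_term", "drug ineffective"),
            seed=int(d.get("seed", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Realized planted-pair cells, counted during generation."""

    cells: pd.DataFrame  # drug, pt_term, rho, a, b, c, d, expected_prr

    def save(self, path: str | Path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls(cells=pd.read_csv(path))


def _choice(rng: np.random.Generator, marginal: dict, n: int) -> np.ndarray:
    keys = list(marginal.keys())
    probs = np.array([marginal[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=n, p=probs)
    return np.array(keys, dtype=object)[idx]


def generate(
    config: GeneratorConfig, seed: Optional[int] = None
) -> tuple[IcsrDatabase, GroundTruth]:
    """Generate a database and its ground truth. Deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_reports

    drug_names = list(config.drug_marginals.keys())
    drug_probs = np.array([config.drug_marginals[d] for d in drug_names], dtype=float)
    drug_probs = drug_probs / drug_probs.sum()

    pt_names = list(config.event_marginals.keys())
    base = np.array([config.event_marginals[p] for p in pt_names], dtype=float)
    pt_index = {p: i for i, p in enumerate(pt_names)}
    drug_index = {d: i for i, d in enumerate(drug_names)}

    # -- drugs and roles ---------------------------------------------------
    ks = sorted(config.n_drugs_distribution)
    k_probs = np.array([config.n_drugs_distribution[k] for k in ks], dtype=float)
    k_probs = k_probs / k_probs.sum()
    kmax = max(ks) if ks else 1
    n_drugs = np.array(ks)[rng.choice(len(ks), size=n, p=k_probs)]
    drug_idx = rng.choice(len(drug_names), size=(n, kmax), p=drug_probs)
    role_probs = np.array([config.role_distribution[r] for r in ROLE_LEVELS], dtype=float)
    role_probs = role_probs / role_probs.sum()
    role_idx = rng.choice(len(ROLE_LEVELS), size=(n, kmax), p=role_probs)

    active = np.arange(kmax)[None, :] < n_drugs[:, None]
    transmitting_roles = np.array(
        [ROLE_LEVELS.index(r) for r in sorted(DISPRO_ROLES)]
    )
    transmits = active & np.isin(role_idx, transmitting_roles)

    # -- events: background rate scaled by the strongest transmitted rho ---
    prob = np.broadcast_to(base, (n, len(pt_names))).copy()
    planted_pts = {pt for (_, pt) in config.signal_matrix}
    for pt in planted_pts:
        pi = pt_index[pt]
        rho_by_drug = np.ones(len(drug_names))
        for (drug, pt2), rho in config.signal_matrix.items():
            if pt2 == pt:
                rho_by_drug[drug_index[drug]] = rho
        slot_rho = np.where(transmits, rho_by_drug[drug_idx], -np.inf)
        eff = slot_rho.max(axis=1)  # -inf when no transmitting drug
        eff = np.where(np.isfinite(eff), eff, 1.0)
        prob[:, pi] = base[pi] * eff
    events = rng.random((n, len(pt_names))) < prob

    # guarantee >= 1 event per report: a filler PT, never case-defining
    filler_draw = rng.random(n)  # reserved draw keeps the stream stable
    empty = ~events.any(axis=1)

    # -- demographics ------------------------------------------------------
    demo = config.demographic_marginals
    sex = _choice(rng, demo.get("sex", {"unknown": 1.0}), n)
    age = _choice(rng, demo.get("age_band", {"unknown": 1.0}), n)
    reporter = _choice(rng, demo.get("reporter", {"unknown": 1.0}), n)
    region = _choice(rng, demo.get("region", {"unknown": 1.0}), n)
    year = _choice(rng, demo.get("year", {"unknown": 1.0}), n)
    indication = _choice(rng, demo.get("indication", {"unknown": 1.0}), n)

    # -- seriousness model conditioned on case status ----------------------
    case_cols = [pt_index[t] for t in config.case_terms if t in pt_index]
    is_case = events[:, case_cols].any(axis=1) if case_cols else np.zeros(n, bool)
    p_serious = np.where(
        is_case, config.seriousness.p_serious_case, config.seriousness.p_serious_noncase
    )
    serious = rng.random(n) < p_serious
    cat_primary = _choice(rng, config.seriousness.category_marginals, n)
    second = rng.random(n) < config.seriousness.p_second_category
    cat_secondary = _choice(rng, config.seriousness.category_marginals, n)
    outcome = _choice(rng, config.seriousness.outcome_marginals, n)
    action = _choice(rng, config.seriousness.action_marginals, n)
    oaa = _choice(rng, config.seriousness.outcome_after_action_marginals, n)

    # -- assemble ----------------------------------------------------------
    filler = config.filler_term
    pt_array = np.array(pt_names, dtype=object)
    width = len(str(max(n - 1, 1)))
    reports: list[IcsrReport] = []
    for i in range(n):
        # duplicate draws of one drug merge into a single mention; a
        # transmitting role (suspect/interacting) wins over concomitant so
        # the emitted role agrees with the slot-level signal transmission
        seen: dict[str, DrugEntry] = {}
        for j in range(int(n_drugs[i])):
            name = drug_names[drug_idx[i, j]]
            role = ROLE_LEVELS[role_idx[i, j]]
            prev = seen.get(name)
            if prev is None or (prev.role == "concomitant" and role in DISPRO_ROLES):
                seen[name] = DrugEntry(name, role)
        evs = tuple(pt_array[events[i]]) if not empty[i] else (filler,)
        cats: frozenset[str] = frozenset()
        if serious[i]:
            cats = frozenset(
                {cat_primary[i], cat_secondary[i]} if second[i] else {cat_primary[i]}
            )
        yr = year[i]
        reports.append(
            IcsrReport(
                report_id=f"r{i:0{width}d}",
                sex=sex[i],
                age_band=age[i],
                reporter=reporter[i],
                region=region[i],
                year=None if yr == "unknown" else int(yr),
                serious="yes" if serious[i] else "no",
                seriousness_categories=cats,
                outcome=outcome[i] if serious[i] else "unknown",
                action_taken=action[i],
                outcome_after_action=oaa[i],
                indications=() if indication[i] == "unknown" else (indication[i],),
                drugs=tuple(seen.values()),
                events=evs,
            )
        )

    catalog = {d: d in config.mab_drugs for d in drug_names}
    db = IcsrDatabase(reports=reports, drug_catalog=catalog)
    db.validate()

    # -- ground truth: recount cells straight from the draw arrays ---------
    rows = []
    for (drug, pt), rho in sorted(config.signal_matrix.items()):
        di, pi = drug_index[drug], pt_index[pt]
        drug_mask = (transmits & (drug_idx == di)).any(axis=1)
        event_mask = events[:, pi].copy()
        if pt == filler:
            event_mask |= empty
        a = int((drug_mask & event_mask).sum())
        b = int(drug_mask.sum()) - a
        c = int((~drug_mask & event_mask).sum())
        d = int((~drug_mask).sum()) - c
        rows.append(
            {
                "drug": drug,
                "pt_term": pt,
                "rho": rho,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "expected_prr": rho,
            }
        )
    truth = GroundTruth(
        cells=pd.DataFrame(
            rows, columns=["drug", "pt_term", "rho", "a", "b", "c", "d", "expected_prr"]
        )
    )
    return db, truth


def default_paper_profile(
    n_reports: int = 100_000, n_background_drugs: int = 20, seed: int = 0
) -> GeneratorConfig:
    """A profile shaped like a large biologics safety database.

    Demographic marginals follow the published all-report distribution
    for the five asthma biologics (e.g. 60.9% female, 31.9% physician
    reporters, 80.8% Americas); the drug catalog holds the five
    biologics (flagged as monoclonal antibodies, with slot weights
    proportional to their published report shares) plus
    ``n_background_drugs`` generic comparator drugs; the signal matrix
    plants the published anaphylaxis disproportionality pattern
    (strong for omalizumab, moderate for benralizumab and mepolizumab,
    protective for dupilumab).
    """
    biologic_share = {
        "omalizumab": 0.516,
        "dupilumab": 0.325,
        "mepolizumab": 0.116,
        "benralizumab": 0.038,
        "reslizumab": 0.005,
    }
    drug_marginals = {d: 0.5 * w for d, w in biologic_share.items()}
    for i in range(n_background_drugs):
        drug_marginals[f"drug{i:02d}"] = 0.5 / n_background_drugs

    event_marginals = {
        "anaphylactic reaction": 0.0046,
        "anaphylactic shock": 0.0038,
        "anaphylactic transfusion reaction": 2e-5,
        "anaphylactoid reaction": 0.0024,
        "circulatory collapse": 0.0012,
        "kounis syndrome": 5e-5,
        "procedural shock": 5e-5,
        "shock": 0.0007,
        "shock syndrome": 5e-5,
        "type 1 hypersensitivity": 1.7e-4,
        "headache": 0.05,
        "dyspnoea": 0.04,
        "urticaria": 0.03,
        "pruritus": 0.025,
        "rash": 0.03,
        "fatigue": 0.03,
        "nausea": 0.03,
        "dizziness": 0.02,
        "cough": 0.02,
        "pyrexia": 0.015,
        "injection site reaction": 0.04,
        "asthma": 0.05,
        "drug ineffective": 0.06,
        "vomiting": 0.015,
        "arthralgia": 0.02,
    }

    signal_matrix = {
        ("omalizumab", "anaphylactic reaction"): 9.61,
        ("omalizumab", "type 1 hypersensitivity"): 6.12,
        ("omalizumab", "anaphylactic shock"): 1.51,
        ("mepolizumab", "anaphylactic reaction"): 2.47,
        ("benralizumab", "anaphylactic reaction"): 4.90,
        ("reslizumab", "anaphylactic reaction"): 2.74,
        ("dupilumab", "anaphylactic reaction"): 0.39,
    }

    demographic_marginals = {
        "sex": {"male": 0.312, "female": 0.609, "unknown": 0.079},
        "age_band": {
            "<18": 0.040,
            "18-44": 0.190,
            "45-64": 0.231,
            "65-74": 0.067,
            ">=75": 0.031,
            "unknown": 0.441,
        },
        "reporter": {
            "consumer": 0.464,
            "physician": 0.319,
            "other_hcp": 0.154,
            "pharmacist": 0.038,
            "lawyer": 0.0002,
            "unknown": 0.0248,
        },
        "region": {
            "americas": 0.808,
            "europe": 0.154,
            "asia": 0.027,
            "oceania": 0.009,
            "africa": 0.002,
        },
        "year": {2015: 0.159, 2016: 0.071, 2017: 0.145, 2018: 0.204, 2019: 0.421},
        "indication": {
            "asthma": 0.331,
            "urticaria": 0.095,
            "dermatitis": 0.165,
            "others": 0.059,
            "unknown": 0.350,
        },
    }

    return GeneratorConfig(
        n_reports=n_reports,
        drug_marginals=drug_marginals,
        mab_drugs=set(biologic_share),
        event_marginals=event_marginals,
        signal_matrix=signal_matrix,
        demographic_marginals=demographic_marginals,
        seed=seed,
    )
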