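"""Descriptive safety tables on a synthetic database.

Builds the demographics table (all reports vs anaphylaxis cases side by
side) and the per-drug seriousness breakdown of the serious cases, the
two standard companions of a disproportionality screen.
"""

from pvsignal import (
    classify_reports,
    case_term_breakdown,
    default_anaphylaxis_smq,
    default_paper_profile,
    demographics_table,
    generate,
    seriousness_table,
)

db, _ = generate(default_paper_profile(n_reports=30_000, seed=4))
smq = default_anaphylaxis_smq()
flags = classify_reports(db, smq)
n_cases = sum(c.is_case for c in flags)
print(f"{db.n_total} reports, {n_cases} anaphylaxis cases "
      f"({100 * n_cases / db.n_total:.1f}%)")

demo = demographics_table(db, flags)
sex = demo[demo.block == "sex"]
print("\nsex distribution (count, % of population):")
print(sex.pivot(index="stratum", columns="population",
                values=["count", "percent"]).to_string())

serious = seriousness_table(db, flags, ["omalizumab"])
actions = serious[serious.block == "action_taken"]
print("\nomalizumab serious cases - action taken "
      f"(denominator {actions.denominator.iloc[0]}):")
print(actions[["stratum", "count", "percent"]].to_string(index=False))

breakdown = case_term_breakdown(db, smq, "omalizumab")
print("\nomalizumab per-PT anaphylaxis reporting shares:")
print(breakdown[breakdown["count"] > 0][["pt_term", "count", "percent"]]
      .to_string(index=False))

# Percentages are over the full population denominator (unknowns are a
# stratum, not missing data); the per-drug seriousness denominators are
# the drug's serious case reports.
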