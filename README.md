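# pvsignal

Disproportionality-based signal detection for spontaneous adverse-event
report databases, built around the question of anaphylactic-reaction
risk with asthma biologics (omalizumab, mepolizumab, benralizumab,
reslizumab, dupilumab), and usable for any drug/event screen in the same
data model.

Spontaneous-report (ICSR) databases cannot estimate incidence, but they
can flag drug–event pairs that are reported *disproportionately* often.
`pvsignal` implements that pipeline for pharmacoepidemiologists and
safety scientists:

* a validated data model and CSV dialect for report-level ICSR data
  (demographics, drugs with suspect/concomitant/interacting roles,
  MedDRA-PT-coded events, seriousness/outcome/dechallenge fields);
* SMQ-style case definition — the bundled default is the ten-PT
  narrow-scope anaphylactic-reaction query;
* two-track 2×2 disproportionality (comparator: all drugs, or all
  monoclonal antibodies) with PRR, ROR, shrinkage IC and its IC₀₂₅
  credibility bound, and a conjunctive signal rule;
* the descriptive demographics and seriousness tables that accompany
  such screens;
* a synthetic ICSR generator with planted signals and exact ground-truth
  bookkeeping, so every statistical claim in the package is testable.

## The statistics

For a drug–event pair, reports are cross-classified at report level:

|                    | event of interest | all other events |
|--------------------|-------------------|------------------|
| drug of interest   | A                 | B                |
| comparator drugs   | C                 | D                |

with A+B the drug's reports after the role filter (suspect/interacting
by default) and C+D the rest of the comparator universe. Then

* PRR = [A/(A+B)] / [C/(C+D)]
* ROR = (A/B) / (C/D)
* IC  = log₂((O+½)/(E+½)), with O = A and E = (A+B)(A+C)/N the count
  expected under independence; IC₀₂₅ is the lower 95% credibility bound,
  by default the closed-form approximation
  IC − 3.3(O+½)^(−1/2) − 2.363(O+½)^(−3/4), or the exact
  Gamma-posterior quantile with `ic_method="gamma_quantile"`.

A pair is a **signal** when, jointly: A ≥ 3, PRR ≥ 2, ROR ≥ 2 and
IC₀₂₅ ≥ 0. Zero cells leave PRR/ROR undefined (reported as NaN, never
positive); a Haldane-corrected ROR is available explicitly, never
silently.

## Worked example

Published screens of the five asthma biologics print, per drug–PT row,
the report count, PRR, ROR and IC₀₂₅. Those rows can be checked for
internal consistency without the restricted source database, because
the ROR is algebraically determined by (count, drug total, PRR):

```bash
python examples/02_published_row_consistency.py
```

```
drug           n      PRR   ROR(printed)  ROR(back-solved)
omalizumab      1437   9.61     10.01          10.01
mepolizumab       84   2.47      2.49           2.49
benralizumab      54   4.90      4.99           4.99
reslizumab         4   2.74      2.76           2.76
dupilumab         37   0.39      0.38           0.39

signal rule (n>=3, PRR>=2, ROR>=2, IC025>=0) flags 4 of 29 published rows:
  omalizumab: anaphylactic reaction
  omalizumab: type 1 hypersensitivity
  mepolizumab: anaphylactic reaction
  benralizumab: anaphylactic reaction
```

The back-solved RORs reproduce the printed ones to two decimals, and the
conjunctive rule recovers exactly the four rows flagged as positive in
the publication — including the instructive negative: reslizumab's
anaphylactic-reaction row clears the PRR/ROR thresholds but fails
IC₀₂₅ ≥ 0 at only 4 reports, so it is (correctly) not a signal.

An end-to-end synthetic run — generate 50,000 reports with planted
anaphylaxis disproportionality, screen both comparator tracks:

```bash
python examples/01_simulate_and_screen.py
```

```
comparator=all_drugs: 32 pairs screened, 4 positive
        drug               event_label   a  prr  ror  ic025
benralizumab     anaphylactic reaction  36 2.18 2.23   0.36
  omalizumab smq:anaphylactic reaction 764 4.12 4.31   1.05
  omalizumab     anaphylactic reaction 616 7.91 8.25   1.34
  omalizumab   type 1 hypersensitivity  16 5.04 5.05   0.13
```

Strongly planted pairs surface; in the all-mAbs track the comparator
itself carries planted anaphylaxis, so weaker signals attenuate — the
same masking behaviour expected of a restricted comparator on real data.

The same pipeline is available from the shell:

```bash
pvsignal simulate --out db/ --seed 7 --n-reports 100000
pvsignal screen   --db db/ --out signals.csv --comparator both
pvsignal tables   --db db/ --out tables/
```

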