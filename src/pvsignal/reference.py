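"""Published anaphylaxis disproportionality results for asthma biologics.

A global spontaneous-report study of the five asthma biologics
(omalizumab, mepolizumab, benralizumab, reslizumab, dupilumab) published
per-drug, per-PT disproportionality rows (report count, PRR, ROR, IC025,
and which rows were flagged as positive signals) together with headline
counts. The underlying database is access-restricted, but the printed
rows themselves are enough for two kinds of internal-consistency checks:

* re-deriving each row's ROR from its (count, drug total, PRR) triple
  via :func:`pvsignal.disproportionality.ror_from_prr`;
* re-applying the signal rule to each row's printed statistics and
  comparing with the published flags.

This module ships those printed rows as data and exposes the headline
counts as constants.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Reports in the full database, all drugs.
N_ALL_DRUGS = 21_161_249
#: Reports naming at least one of the five biologics.
N_BIOLOGICS = 62_883
#: Anaphylaxis (narrow SMQ) case reports among them.
N_CASES = 1_964
#: Serious reports among all biologic reports.
N_SERIOUS = 22_995
#: Serious reports among the case reports.
N_SERIOUS_CASES = 1_889
#: Omalizumab report total used in the disproportionality table
#: (suspect/interacting role filter applied).
N_OMALIZUMAB = 32_457
#: Omalizumab reports listing the PT "anaphylactic reaction".
N_OMALIZUMAB_ANAPHYLAXIS = 1_437


def published_signal_rows() -> pd.DataFrame:
    """The published per-drug per-PT result rows.

    Columns: drug, drug_total, pt_term, n_reports, prr, ror, ic025,
    signal_positive (the published positivity flag).
    """
    ref = resources.files("pvsignal.data") / "reference_signals.csv"
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    df["signal_positive"] = df["signal_positive"].map(
        {"true": True, "false": False, True: True, False: False}
    )
    return df
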