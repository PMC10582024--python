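"""Contingency construction, PRR/ROR/IC formulas, and the signal rule."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import brute_force_cells, make_report
from pvsignal.disproportionality import (
    ContingencyTable,
    SignalCriteria,
    analyze_table,
    build_table,
    classify_signal,
    ic,
    prr,
    results_frame,
    ror,
    ror_from_prr,
    screen,
)
from pvsignal.icsr import DISPRO_ROLES, IcsrDatabase
from pvsignal.reference import published_signal_rows
from pvsignal.smq import SmqDefinition, default_anaphylaxis_smq

# Cells back-solved from the published omalizumab anaphylactic-reaction
# row (a=1437 of 32,457 drug reports, PRR 9.61, database N=21,161,249).
OMALIZUMAB_CELLS = ContingencyTable(a=1437, b=31020, c=97341, d=21031451)


class TestFormulas:
    def test_prr_null_and_zero(self):
        assert prr(ContingencyTable(1, 1, 1, 1)) == 1.0
        assert prr(ContingencyTable(0, 5, 7, 11)) == 0.0
        assert math.isnan(prr(ContingencyTable(3, 5, 0, 11)))

    def test_prr_matches_published_row(self):
        assert prr(OMALIZUMAB_CELLS) == pytest.approx(9.61, abs=0.005)

    def test_ror_matches_published_row(self):
        assert ror(OMALIZUMAB_CELLS) == pytest.approx(10.01, abs=0.005)

    def test_ror_null_when_odds_balance(self):
        assert ror(ContingencyTable(6, 3, 10, 5)) == 1.0

    def test_ror_zero_cells_nan_but_corrected_finite(self):
        t = ContingencyTable(3, 0, 5, 7)
        assert math.isnan(ror(t))
        assert math.isfinite(ror(t, corrected=True))

    def test_ic_independence_and_shrinkage_fixed_point(self):
        # O == E at large counts: IC ~ 0 but its lower bound is negative
        big = ContingencyTable(a=1000, b=9000, c=10000, d=90000)
        ic_v, ic025_v = ic(big)
        assert abs(ic_v) < 0.01
        assert ic025_v < 0
        # all-zero table: shrinkage gives log2(0.5/0.5) = 0 exactly
        assert ic(ContingencyTable(0, 0, 0, 0))[0] == 0.0

    def test_ic_published_row_within_sanity_band(self):
        ic_v, ic025_v = ic(OMALIZUMAB_CELLS)
        assert ic_v == pytest.approx(3.24, abs=0.01)
        assert ic025_v == pytest.approx(3.14, abs=0.01)
        # the published lower bound (3.17) came from an unstated variant;
        # agreement is only expected within a formula-variant band
        assert ic025_v == pytest.approx(3.17, abs=0.15)

    def test_ic_gamma_quantile_variant(self):
        # at large counts the two credibility bounds agree closely, and
        # the exact-posterior variant lands on the published 3.17
        _, exact = ic(OMALIZUMAB_CELLS, method="gamma_quantile")
        _, approx = ic(OMALIZUMAB_CELLS, method="approx")
        assert round(exact, 2) == 3.17
        assert approx == pytest.approx(exact, abs=0.05)
        # at small counts the closed form is the more conservative bound
        small = ContingencyTable(5, 100, 50, 10000)
        assert ic(small, method="approx")[1] < ic(small, method="gamma_quantile")[1]


cells = st.integers(min_value=0, max_value=2000)


class TestProperties:
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ic025_below_ic_for_both_methods(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        for method in ("approx", "gamma_quantile"):
            ic_v, ic025_v = ic(t, method=method)
            assert ic025_v < ic_v

    @given(
        a=st.integers(1, 500),
        b=st.integers(1, 500),
        c=st.integers(1, 500),
        d=st.integers(1, 500),
        k=st.integers(1, 50),
    )
    def test_comparator_scaling_leaves_ratios_unchanged(self, a, b, c, d, k):
        t1 = ContingencyTable(a, b, c, d)
        t2 = ContingencyTable(a, b, c * k, d * k)
        assert prr(t2) == pytest.approx(prr(t1), rel=1e-12)
        assert ror(t2) == pytest.approx(ror(t1), rel=1e-12)

    def test_sign_concordance_exhaustive_small_tables(self):
        # (ror - prr) shares the sign of (prr - 1) on every all-positive
        # table with cells <= 20; equality only at prr == 1
        rng = np.arange(1, 21)
        a, b, c, d = np.meshgrid(rng, rng, rng, rng, indexing="ij", sparse=True)
        prr_v = (a / (a + b)) / (c / (c + d))
        ror_v = (a / b) / (c / d)
        diff = ror_v - prr_v
        assert np.all(np.sign(diff)[prr_v != 1] == np.sign(prr_v - 1)[prr_v != 1])
        assert np.all(diff[np.isclose(prr_v, 1)] == pytest.approx(0))

    def test_ic_large_count_limit(self):
        # with shrinkage removed analytically 2^IC = a*n / ((a+b)(a+c));
        # the implemented IC converges to this as counts grow
        for scale in (10, 100):
            t = ContingencyTable(
                a=1437 * scale, b=31020 * scale, c=97341 * scale, d=21031451 * scale
            )
            assert t.a >= 10_000
            limit = math.log2(t.a * t.n / ((t.a + t.b) * (t.a + t.c)))
            ic_v, _ = ic(t)
            assert abs(ic_v - limit) / abs(limit) < 0.001

    @given(
        a=st.integers(3, 200),
        mult=st.integers(2, 20),
    )
    def test_classify_signal_monotone_in_count(self, a, mult):
        # scaling every cell preserves PRR/ROR and can only raise IC025,
        # so a positive pair stays positive as its counts grow
        t1 = ContingencyTable(a, 10 * a, 5 * a, 500 * a)
        t2 = ContingencyTable(a * mult, 10 * a * mult, 5 * a * mult, 500 * a * mult)
        r1, r2 = analyze_table(t1), analyze_table(t2)
        if r1.signal_positive:
            assert r2.signal_positive


class TestSignalRule:
    @pytest.mark.parametrize(
        "n,prr_v,ror_v,ic025_v,expected",
        [
            (1437, 9.61, 10.01, 3.17, True),
            (1, 18.50, 18.51, -2.36, False),  # too few reports, IC negative
            (193, 1.51, 1.51, 0.38, False),  # PRR/ROR below 2
            (4, 2.74, 2.76, -0.54, False),  # IC025 negative despite PRR/ROR
            (3, 2.0, 2.0, 0.0, True),  # thresholds are inclusive
            (2, 9.0, 9.0, 2.0, False),  # minimum-count rule
        ],
    )
    def test_conjunctive_rule(self, n, prr_v, ror_v, ic025_v, expected):
        assert classify_signal(n, prr_v, ror_v, ic025_v) is expected

    def test_nan_metrics_never_positive(self):
        assert not classify_signal(10, math.nan, 5.0, 1.0)
        assert not classify_signal(10, 5.0, math.nan, 1.0)

    def test_custom_criteria(self):
        loose = SignalCriteria(min_reports=1, prr_threshold=1.0, ror_threshold=1.0,
                               ic025_threshold=-10.0)
        assert classify_signal(1, 1.2, 1.2, -5.0, loose)


class TestRorFromPrr:
    def test_published_rows_reconstruct(self):
        rows = published_signal_rows()
        row = rows[(rows.drug == "omalizumab") & (rows.pt_term == "anaphylactic reaction")]
        got = ror_from_prr(int(row.n_reports.iloc[0]), int(row.drug_total.iloc[0]),
                           float(row.prr.iloc[0]))
        assert round(got, 2) == 10.01

    def test_prr_one_gives_unit_ror(self):
        # when PRR = 1 the implied drug and comparator proportions
        # coincide, so the back-solved odds ratio is exactly 1
        assert ror_from_prr(50, 1000, 1.0) == pytest.approx(1.0)

    def test_ror_exceeds_prr_above_one(self):
        # the odds transform inflates any PRR > 1
        assert ror_from_prr(50, 1000, 3.0) > 3.0

    def test_inconsistent_inputs_fatal(self):
        with pytest.raises(ValueError):
            ror_from_prr(90, 100, 0.5)  # implied comparator proportion > 1
        with pytest.raises(ValueError):
            ror_from_prr(0, 100, 2.0)


class TestBuildTable:
    def test_toy_enumeration(self, toy_db):
        t = build_table(toy_db, "x", "ptev", comparator="all_drugs")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
        assert t.n == toy_db.n_total

    def test_all_mabs_degenerate_universe_fatal(self, toy_db):
        # y is not a mAb, so the mAb universe is exactly x's reports
        with pytest.raises(ValueError, match="comparator"):
            build_table(toy_db, "x", "ptev", comparator="all_mabs")

    def test_non_mab_drug_cannot_use_mab_comparator(self, toy_db):
        with pytest.raises(ValueError, match="is_mab"):
            build_table(toy_db, "y", "ptev", comparator="all_mabs")

    def test_absent_drug_fatal(self, toy_db):
        with pytest.raises(KeyError):
            build_table(toy_db, "nosuch", "ptev")

    def test_matches_brute_force_oracle_all_pairs(self, small_db):
        db, _ = small_db
        pts = sorted({pt for r in db.reports for pt in r.events})
        for drug in sorted(db.drug_catalog):
            for pt in pts:
                t = build_table(db, drug, pt, roles=DISPRO_ROLES)
                assert (t.a, t.b, t.c, t.d) == brute_force_cells(
                    db, drug, {pt}, DISPRO_ROLES
                )

    def test_matches_brute_force_under_mab_comparator(self, small_db):
        db, _ = small_db
        smq = default_anaphylaxis_smq()
        for drug in sorted(db.mab_drugs):
            t = build_table(db, drug, smq, comparator="all_mabs")
            assert (t.a, t.b, t.c, t.d) == brute_force_cells(
                db, drug, smq.pt_terms, DISPRO_ROLES, comparator="all_mabs"
            )


class TestScreen:
    def test_toy_screen_single_null_pair(self, toy_db):
        smq = SmqDefinition(name="toy", scope="narrow", pt_terms=frozenset({"ptev"}))
        results = screen(toy_db, ["x"], smq)
        frame = results_frame(results)
        pt_rows = frame[frame.event_label == "ptev"]
        assert len(pt_rows) == 1
        assert pt_rows.prr.iloc[0] == 1.0
        assert not pt_rows.signal_positive.any()

    def test_deterministic_ordering(self, small_db):
        db, _ = small_db
        smq = default_anaphylaxis_smq()
        f1 = results_frame(screen(db, sorted(db.mab_drugs), smq))
        f2 = results_frame(screen(db, sorted(db.mab_drugs), smq))
        assert f1.equals(f2)
        for _, grp in f1.groupby("drug", sort=False):
            assert list(grp.a) == sorted(grp.a, reverse=True) or (
                grp.a.is_monotonic_decreasing
            )

    def test_aggregate_row_present_per_drug(self, small_db):
        db, _ = small_db
        smq = default_anaphylaxis_smq()
        frame = results_frame(screen(db, sorted(db.mab_drugs), smq))
        agg = frame[frame.event_label.str.startswith("smq:")]
        assert len(agg) == len(db.mab_drugs)
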