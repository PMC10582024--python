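"""Data model, CSV round-trip, and role filtering."""

import pytest

from conftest import make_report
from pvsignal.icsr import (
    ALL_ROLES,
    DISPRO_ROLES,
    IcsrDatabase,
    ValidationError,
    filter_by_role,
    read_database,
    write_database,
)


class TestValidation:
    def test_report_count_matches_rows(self, toy_db):
        assert toy_db.n_total == 4

    def test_unknown_catalog_drug_is_named(self):
        db = IcsrDatabase(
            reports=[make_report("r1", [("ghostdrug", "suspect")], ["ptev"])],
            drug_catalog={"x": False},
        )
        with pytest.raises(ValidationError, match="ghostdrug"):
            db.validate()

    def test_duplicate_report_id_rejected(self):
        reports = [
            make_report("r1", [("x", "suspect")], ["ptev"]),
            make_report("r1", [("x", "suspect")], ["ptev"]),
        ]
        db = IcsrDatabase(reports=reports, drug_catalog={"x": False})
        with pytest.raises(ValidationError, match="duplicate"):
            db.validate()

    @pytest.mark.parametrize(
        "kw",
        [
            {"sex": "nonbinary?"},
            {"serious": "maybe"},
            {"outcome": "vanished"},
        ],
    )
    def test_unknown_enum_value_rejected(self, kw):
        rep = make_report("r1", [("x", "suspect")], ["ptev"], **kw)
        with pytest.raises(ValidationError):
            rep.validate()

    def test_seriousness_categories_iff_serious(self):
        # flagged serious but no category
        rep = make_report("r1", [("x", "suspect")], ["ptev"], serious="yes")
        with pytest.raises(ValidationError, match="seriousness_categories"):
            rep.validate()
        # category without the flag
        rep = make_report(
            "r2",
            [("x", "suspect")],
            ["ptev"],
            serious="no",
            seriousness_categories=frozenset({"other"}),
        )
        with pytest.raises(ValidationError):
            rep.validate()

    def test_labels_normalized_case_insensitively(self):
        rep = make_report("r1", [("  OmaLizumab ", "suspect")], ["Anaphylactic  REACTION"])
        assert rep.drugs[0].drug_name == "omalizumab"
        assert rep.events == ("anaphylactic reaction",)


class TestRoundTrip:
    def test_round_trip_equality(self, small_db, tmp_path):
        db, _ = small_db
        write_database(db, tmp_path)
        back = read_database(tmp_path)
        assert back.n_total == db.n_total
        assert back.drug_catalog == db.drug_catalog
        for orig, rt in zip(db.reports, back.reports):
            assert orig == rt

    def test_missing_column_is_fatal_with_name(self, toy_db, tmp_path):
        write_database(toy_db, tmp_path)
        reports = (tmp_path / "reports.csv").read_text().splitlines()
        header = reports[0].replace("sex,", "")
        rows = [line.split(",", 2)[0] + "," + line.split(",", 2)[2] for line in reports[1:]]
        (tmp_path / "reports.csv").write_text("\n".join([header] + rows) + "\n")
        with pytest.raises(ValidationError, match="sex"):
            read_database(tmp_path)

    def test_bad_enum_row_is_fatal_with_line(self, toy_db, tmp_path):
        write_database(toy_db, tmp_path)
        path = tmp_path / "report_drugs.csv"
        path.write_text(path.read_text().replace("suspect", "bystander", 1))
        with pytest.raises(ValidationError, match="line 2"):
            read_database(tmp_path)

    def test_empty_database_writes_header_only(self, tmp_path):
        write_database(IcsrDatabase(), tmp_path)
        for name in ("reports.csv", "report_drugs.csv", "report_events.csv"):
            lines = (tmp_path / name).read_text().strip().splitlines()
            assert len(lines) == 1  # header only


class TestRoleFilter:
    def make_db(self):
        reports = [
            make_report("r1", [("x", "suspect")], ["ptev"]),
            make_report("r2", [("x", "suspect"), ("z", "concomitant")], ["ptev"]),
            make_report("r3", [("x", "concomitant")], ["ptev"]),
            make_report("r4", [("z", "suspect")], ["ptev"]),
            make_report("r5", [("x", "interacting"), ("x", "concomitant")], ["ptev"]),
        ]
        db = IcsrDatabase(reports=reports, drug_catalog={"x": True, "z": False})
        db.validate()
        return db

    def test_hand_counted_subset(self):
        db = self.make_db()
        got = {r.report_id for r in filter_by_role(db, "x", DISPRO_ROLES)}
        assert got == {"r1", "r2", "r5"}

    def test_concomitant_only_excluded(self):
        db = self.make_db()
        ids = {r.report_id for r in filter_by_role(db, "x", {"suspect", "interacting"})}
        assert "r3" not in ids

    def test_monotone_in_role_set_and_no_duplicates(self):
        db = self.make_db()
        all_roles = filter_by_role(db, "x", ALL_ROLES)
        ids_all = [r.report_id for r in all_roles]
        assert len(ids_all) == len(set(ids_all))  # dedup despite r5 double entry
        for single in ({"suspect"}, {"concomitant"}, {"interacting"}):
            sub = {r.report_id for r in filter_by_role(db, "x", single)}
            assert sub <= set(ids_all)

    def test_unknown_drug_fatal(self):
        db = self.make_db()
        with pytest.raises(KeyError):
            filter_by_role(db, "nosuchdrug", ALL_ROLES)
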