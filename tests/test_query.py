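"""Filter chain: study/subject filters, age and phase derivations."""

import datetime as dt
import itertools
import random

import pytest

from sendhc import db as dbm
from sendhc import fixtures, query
from sendhc.errors import (
    InvalidRangeError,
    InvalidStudyDayError,
    UnsupportedDomainError,
)

from conftest import control_chain


class TestStudyFilters:
    def test_sdesign_match(self, default_db):
        handle, _ = default_db
        got = query.get_studies_sdesign(handle, "parallel")
        assert sorted(got.STUDYID) == ["CTR2016", "CTR2018"]

    def test_sdesign_null_is_identity(self, default_db):
        handle, truths = default_db
        got = query.get_studies_sdesign(handle, None)
        assert sorted(got.STUDYID) == sorted(truths)

    def test_sdesign_missing_uncertain(self, tmp_path, make_db):
        spec = fixtures.StudySpec(seed=5, studyid="NODESIGN", design="")
        fixtures.make_study(spec, tmp_path / "r")
        handle = make_db(tmp_path / "r")
        assert query.get_studies_sdesign(handle, "PARALLEL").empty
        got = query.get_studies_sdesign(handle, "PARALLEL", incl_uncertain=True)
        assert list(got.UNCERTAIN_MSG) == ["SDESIGN missing"]

    def test_date_window(self, default_db):
        handle, _ = default_db
        got = query.get_studies_ststdtc(handle, "2017-01-01", "2019-12-31")
        assert list(got.STUDYID) == ["CTR2018"]

    def test_date_null_bounds_identity(self, default_db):
        handle, truths = default_db
        got = query.get_studies_ststdtc(handle, None, None)
        assert sorted(got.STUDYID) == sorted(truths)

    def test_partial_month_date_interval_semantics(self, tmp_path, make_db):
        """A study dated 2017-06 matches any window overlapping June 2017."""
        from sendhc.xpt import DomainTable, VariableMeta, write_xpt

        folder = tmp_path / "r" / "PARTIAL"
        folder.mkdir(parents=True)
        write_xpt(
            DomainTable(
                "TS",
                [VariableMeta("STUDYID", "", "character", 8),
                 VariableMeta("DOMAIN", "", "character", 2),
                 VariableMeta("TSPARMCD", "", "character", 8),
                 VariableMeta("TSVAL", "", "character", 8)],
                [{"STUDYID": "PARTIAL", "DOMAIN": "TS",
                  "TSPARMCD": "STSTDTC", "TSVAL": "2017-06"}],
            ),
            folder / "ts.xpt",
        )
        handle = make_db(tmp_path / "r")
        assert len(query.get_studies_ststdtc(handle, "2017-01-01", None)) == 1
        assert len(query.get_studies_ststdtc(handle, "2017-06-15", "2017-06-20")) == 1
        assert query.get_studies_ststdtc(handle, "2017-07-01", None).empty

    def test_inverted_range_rejected(self, default_db):
        handle, _ = default_db
        with pytest.raises(InvalidRangeError):
            query.get_studies_ststdtc(handle, "2022", "2021")


class TestControlSubjects:
    def test_vehicle_sets_selected(self, default_db):
        handle, truths = default_db
        subj = query.get_control_subj(handle, query.get_studies_sdesign(handle))
        expected = sorted(
            uid for t in truths.values() for uid in t.control_ids
        )
        assert sorted(subj.USUBJID) == expected
        assert set(subj.TCNTRL) == {"VEHICLE CONTROL"}

    def test_uncertain_includes_unlabelled_sets(self, default_db):
        handle, truths = default_db
        subj = query.get_control_subj(
            handle, query.get_studies_sdesign(handle), incl_uncertain=True
        )
        expected = sorted(
            uid
            for t in truths.values()
            for uid in itertools.chain(t.control_ids, t.uncertain_ids)
        )
        assert sorted(subj.USUBJID) == expected
        flagged = subj[subj.UNCERTAIN_MSG != ""]
        assert set(flagged.UNCERTAIN_MSG) == {"TCNTRL missing"}

    @pytest.mark.parametrize(
        "value,expected",
        [
            ("PLACEBO", True),
            ("Vehicle control", True),
            ("UNTREATED", True),
            ("POSITIVE CONTROL", False),
            ("WATER", None),
            (None, None),
        ],
    )
    def test_negative_control_patterns(self, value, expected):
        assert query.is_negative_control(value) is expected

    def test_positive_control_never_included(self, tmp_path, make_db):
        sets = (
            fixtures.TrialSetSpec("VEH", "Vehicle", 4, "VEHICLE CONTROL"),
            fixtures.TrialSetSpec("POS", "Positive", 4, "POSITIVE CONTROL"),
        )
        spec = fixtures.StudySpec(seed=9, studyid="POSCTL", sets=sets,
                                  mi_plans=(), n_not_done=0)
        fixtures.make_study(spec, tmp_path / "r")
        handle = make_db(tmp_path / "r")
        subj = query.get_control_subj(
            handle, query.get_studies_sdesign(handle), incl_uncertain=True
        )
        assert set(subj.SETCD) == {"VEH"}


class TestSubjectFilters:
    def test_sex_split(self, default_db, ct_vocab):
        handle, truths = default_db
        _, vmap = ct_vocab
        subj = query.get_control_subj(handle, query.get_studies_sdesign(handle))
        males = query.get_subj_sex(handle, subj, "Male", vocab=vmap)
        truth_males = {
            uid
            for t in truths.values()
            for uid in t.control_ids
            if t.subjects[uid]["sex"] == "M"
        }
        assert set(males.USUBJID) == truth_males
        assert len(males) == len(subj) // 2

    def test_sex_null_identity(self, default_db):
        handle, _ = default_db
        subj = query.get_control_subj(handle, query.get_studies_sdesign(handle))
        assert query.get_subj_sex(handle, subj, None).equals(subj)

    def test_species_strain_with_ts_fallback(self, default_db):
        """CTR2021 stores species/strain only in TS; fallback resolves it."""
        handle, _ = default_db
        subj = query.get_control_subj(handle, query.get_studies_sdesign(handle))
        kept = query.get_subj_species_strain(
            handle, subj, "RAT", "SPRAGUE-DAWLEY"
        )
        assert sorted(kept.USUBJID) == sorted(subj.USUBJID)
        assert set(kept.SPECIES) == {"RAT"}  # resolved value written back

    def test_wrong_species_empty(self, default_db):
        handle, _ = default_db
        subj = query.get_control_subj(handle, query.get_studies_sdesign(handle))
        assert query.get_subj_species_strain(handle, subj, "DOG", None).empty

    def test_route_from_ex_and_miss(self, default_db):
        handle, _ = default_db
        subj = query.get_control_subj(handle, query.get_studies_sdesign(handle))
        kept = query.get_subj_route(handle, subj, "ORAL GAVAGE")
        assert len(kept) == len(subj)
        assert query.get_subj_route(handle, subj, "INTRAVENOUS").empty

    def test_filters_commute(self, default_db, ct_vocab):
        """Any permutation of the subject-level filters gives the same set."""
        handle, _ = default_db
        _, vmap = ct_vocab
        base = query.get_control_subj(handle, query.get_studies_sdesign(handle))
        steps = {
            "sex": lambda s: query.get_subj_sex(handle, s, "F", vocab=vmap),
            "species": lambda s: query.get_subj_species_strain(
                handle, s, "RAT", "SPRAGUE-DAWLEY", vocab=vmap
            ),
            "route": lambda s: query.get_subj_route(
                handle, s, "ORAL GAVAGE", vocab=vmap
            ),
        }
        results = []
        for order in itertools.permutations(steps):
            subj = base
            for name in order:
                subj = steps[name](subj)
            results.append(sorted(zip(subj.STUDYID, subj.USUBJID)))
        assert all(r == results[0] for r in results[1:])
        assert results[0]  # non-empty


class TestFindingsExtraction:
    def test_bw_record_count(self, default_db):
        handle, truths = default_db
        subj = query.get_control_subj(handle, query.get_studies_sdesign(handle))
        bw = query.get_subj_data(handle, subj, "BW")
        assert len(bw) == len(subj) * 8  # 8 weighings per animal

    def test_empty_subjects_empty_findings(self, default_db):
        handle, _ = default_db
        import pandas as pd

        empty = pd.DataFrame(columns=query.SUBJECT_COLUMNS)
        assert query.get_subj_data(handle, empty, "MI").empty

    def test_ts_is_not_subject_level(self, default_db):
        handle, _ = default_db
        subj = query.get_control_subj(handle, query.get_studies_sdesign(handle))
        with pytest.raises(UnsupportedDomainError):
            query.get_subj_data(handle, subj, "TS")


class TestAgeDerivation:
    def test_dtc_priority_calendar_difference(self):
        subject = {"BRTHDTC": "2020-01-01", "RFSTDTC": "2020-03-01"}
        finding = {"MIDTC": "2020-03-28", "MIDY": 28.0}
        assert query.derive_age_days(subject, finding, "MI") == 87

    def test_rfstdtc_plus_day_offset(self):
        subject = {"BRTHDTC": "2020-01-01", "RFSTDTC": "2020-03-01"}
        finding = {"MIDY": 28.0}
        assert query.derive_age_days(subject, finding, "MI") == 60 + 27

    def test_age_units_conversion(self):
        subject = {"AGE": 8.0, "AGEU": "WEEKS"}
        assert query.derive_age_days(subject, {"MIDY": 1.0}, "MI") == 56
        subject = {"AGE": 3.0, "AGEU": "MONTHS"}
        assert query.derive_age_days(subject, {"LBDY": 1.0}, "LB") == 91

    def test_negative_study_day_offset(self):
        # day -7 is seven days before the reference start (no day 0)
        subject = {"BRTHDTC": "2020-01-01", "RFSTDTC": "2020-03-01"}
        assert query.derive_age_days(subject, {"LBDY": -7.0}, "LB") == 53

    def test_no_information_returns_null(self):
        assert query.derive_age_days({}, {"MIDY": 5.0}, "MI") is None

    def test_day_zero_rejected(self):
        with pytest.raises(InvalidStudyDayError):
            query.derive_age_days(
                {"BRTHDTC": "2020-01-01", "RFSTDTC": "2020-03-01"},
                {"MIDY": 0.0}, "MI",
            )

    def test_against_calendar_oracle(self):
        """1000 random date/day combinations vs direct calendar arithmetic."""
        rng = random.Random(424242)
        base = dt.date(2015, 1, 1)
        for _ in range(1000):
            birth = base + dt.timedelta(days=rng.randint(0, 1000))
            ref = birth + dt.timedelta(days=rng.randint(30, 400))
            dy = rng.choice([None, rng.randint(1, 180), -rng.randint(1, 14)])
            use_dtc = rng.random() < 0.5
            finding = {}
            if dy is not None:
                finding["MIDY"] = float(dy)
            offset = 0 if dy is None else (dy - 1 if dy >= 1 else dy)
            if use_dtc and dy is not None:
                finding["MIDTC"] = (ref + dt.timedelta(days=offset)).isoformat()
            subject = {"BRTHDTC": birth.isoformat(), "RFSTDTC": ref.isoformat()}
            expected = (ref - birth).days + offset
            got = query.derive_age_days(subject, finding, "MI")
            assert got == expected, (subject, finding)

    def test_age_filter_inclusive_bounds(self, tmp_path, make_db):
        """Planted ages {87, 130, 250} at the finding; 60-120 keeps only 87."""
        spec = fixtures.StudySpec(
            seed=4, studyid="AGES", ages=(60, 103, 223), mi_day=28,
            sets=(fixtures.TrialSetSpec("VEH", "Vehicle", 3, "VEHICLE CONTROL"),),
            mi_plans=(), n_not_done=0,
            examined_specimens=("LIVER",),
        )
        fixtures.make_study(spec, tmp_path / "r")
        handle = make_db(tmp_path / "r")
        subj = query.get_control_subj(handle, query.get_studies_sdesign(handle))
        mi = query.get_subj_data(handle, subj, "MI")
        aged = query.get_findings_subj_age(mi, subj, None, None)
        assert sorted(aged.AGEDAYS) == [87, 130, 250]
        kept = query.get_findings_subj_age(mi, subj, 60, 120)
        assert list(kept.AGEDAYS) == [87]
        with pytest.raises(InvalidRangeError):
            query.get_findings_subj_age(mi, subj, 200, 100)


class TestPhase:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("TREATMENT", "Treatment"),
            ("RECOVERY", "Recovery"),
            ("SCREENING", "Screening"),
            ("PRETREATMENT", "Screening"),  # screening rule ordered first
            ("POST-TREATMENT RECOVERY", "Recovery"),
            ("DOSING PERIOD", "Treatment"),
            ("WEEK 3", "Uncertain"),
        ],
    )
    def test_classify_epoch(self, label, expected):
        assert query.classify_epoch(label) == expected

    def test_findings_phase_from_se(self, default_db):
        handle, truths = default_db
        subj = query.get_control_subj(handle, query.get_studies_sdesign(handle))
        mi = query.get_subj_data(handle, subj, "MI")
        phased = query.get_findings_phase(handle, mi, None)
        # CTR2018 has SE: findings at day 28 sit in the treatment epoch;
        # CTR2021 omits SE: everything uncertain
        by_study = phased.groupby("STUDYID").PHASE.unique().to_dict()
        assert set(by_study["CTR2018"]) <= {"Treatment", "Uncertain"}
        assert "Treatment" in by_study["CTR2018"]
        assert set(by_study["CTR2021"]) == {"Uncertain"}

    def test_phase_filter_drops_uncertain(self, default_db):
        handle, _ = default_db
        subj = query.get_control_subj(handle, query.get_studies_sdesign(handle))
        mi = query.get_subj_data(handle, subj, "MI")
        kept = query.get_findings_phase(handle, mi, "Treatment")
        assert set(kept.STUDYID) == {"CTR2018"}
        both = query.get_findings_phase(handle, mi, "Treatment",
                                        incl_uncertain=True)
        assert set(both.STUDYID) == {"CTR2018", "CTR2021"}


def test_planted_truth_full_chain(default_db, ct_vocab):
    """The complete filter chain returns exactly the planted control set."""
    handle, truths = default_db
    _, vmap = ct_vocab
    subj = control_chain(handle, vmap=vmap, design=None, sex=None,
                         species="RAT", strain="SPRAGUE-DAWLEY",
                         route="ORAL GAVAGE")
    expected = sorted(uid for t in truths.values() for uid in t.control_ids)
    assert sorted(subj.USUBJID) == expected
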