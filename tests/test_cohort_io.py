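import dataclasses

import pytest

from isend.cohort import (
    CohortError,
    HaematologyUndefinedError,
    PatientRecord,
    apply_exclusions,
    derive_haematology,
    read_cohort,
    write_cohort,
)


def make_record(**overrides) -> PatientRecord:
    base = dict(
        patient_id="p1", sex="female", age=64, smoking="any", ecog=1,
        histology="non_squamous", egfr_alk="no", nlr1=4.5, nlr2=4.6,
        pdl1="p1_49", prior_lines=1, treatment="pd1_mono",
        line_setting="post_platinum", cohort="training",
        os_time=12.0, os_event=1, pfs_time=6.0, pfs_event=1,
    )
    base.update(overrides)
    return PatientRecord(**base)


HEADER = ("patient_id,sex,age,smoking,ecog,histology,egfr_alk,nlr1,nlr2,pdl1,"
          "prior_lines,treatment,line_setting,cohort,os_time,os_event,"
          "pfs_time,pfs_event")


def write_csv(tmp_path, rows, header=HEADER):
    path = tmp_path / "cohort.csv"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


class TestReadCohort:
    def test_well_formed_rows_all_accepted(self, tmp_path):
        rows = [
            "a,male,70,any,0,squamous,no,5.1,5.2,p0,1,pd1_mono,post_platinum,training,10,1,5,1",
            "b,female,55,never,2,non_squamous,yes,3.2,2.9,p50plus,2,pd1_mono,post_platinum,validation,8,0,8,0",
            "c,male,61,unknown,1,non_squamous,unknown,4.0,4.4,unknown,1,chemo_only,post_platinum,chemo,14,1,7,1",
        ]
        records, diagnostics = read_cohort(write_csv(tmp_path, rows))
        assert len(records) == 3 and diagnostics == []
        assert records[0].nlr1 == 5.1 and records[1].pdl1 == "p50plus"

    def test_negative_nlr1_rejected_with_diagnostic(self, tmp_path):
        rows = ["a,male,70,any,0,squamous,no,-2,5.2,p0,1,pd1_mono,post_platinum,training,10,1,5,1"]
        records, diagnostics = read_cohort(write_csv(tmp_path, rows))
        assert records == []
        assert len(diagnostics) == 1 and "nlr1 must be positive" in diagnostics[0]

    def test_empty_nlr2_accepted_as_missing(self, tmp_path):
        rows = ["a,male,70,any,0,squamous,no,4.0,,p0,1,pd1_mono,post_platinum,training,10,1,5,1"]
        records, diagnostics = read_cohort(write_csv(tmp_path, rows))
        assert len(records) == 1 and diagnostics == []
        assert records[0].nlr2 is None
        with pytest.raises(HaematologyUndefinedError):
            derive_haematology(records[0])

    def test_unmapped_mandatory_column_is_fatal(self, tmp_path):
        path = write_csv(tmp_path, ["a,male"], header="patient_id,sex")
        with pytest.raises(CohortError, match="mandatory"):
            read_cohort(path)

    def test_schema_remapping(self, tmp_path):
        header = HEADER.replace("nlr1", "baseline_nlr")
        rows = ["a,male,70,any,0,squamous,no,5.1,5.2,p0,1,pd1_mono,post_platinum,training,10,1,5,1"]
        records, diags = read_cohort(write_csv(tmp_path, rows, header=header),
                                     schema_config={"nlr1": "baseline_nlr"})
        assert diags == [] and records[0].nlr1 == 5.1

    def test_pfs_after_os_rejected(self, tmp_path):
        rows = ["a,male,70,any,0,squamous,no,4.0,4.1,p0,1,pd1_mono,post_platinum,training,10,1,11,1"]
        records, diagnostics = read_cohort(write_csv(tmp_path, rows))
        assert records == [] and any("pfs_time" in d for d in diagnostics)


class TestRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        originals = [
            make_record(patient_id="r1", nlr1=4.123456789012345, nlr2=4.2),
            make_record(patient_id="r2", nlr2=None, pfs_time=None, pfs_event=None),
            make_record(patient_id="r3", os_time=0.1234567890123456, os_event=0,
                        pfs_time=0.0617283945061728, pfs_event=0),
        ]
        path = tmp_path / "out.csv"
        write_cohort(originals, path)
        recovered, diagnostics = read_cohort(path)
        assert diagnostics == []
        assert recovered == originals


class TestDeriveHaematology:
    @pytest.mark.parametrize("nlr1, nlr2, dnlr, flag", [
        (4.5, 4.6, 0.1, 0),    # nlr1 below 5 breaks the conjunction
        (5.0, 5.0, 0.0, 1),    # both boundaries inclusive
        (6.0, 5.9, -0.1, 0),   # negative delta breaks the conjunction
        (5.0, 7.5, 2.5, 1),
    ])
    def test_dnlr_and_composite_flag(self, nlr1, nlr2, dnlr, flag):
        haem = derive_haematology(make_record(nlr1=nlr1, nlr2=nlr2))
        assert haem.dnlr == pytest.approx(dnlr)
        assert haem.composite_flag == flag

    def test_dnlr_identity_exact(self):
        # dnlr + nlr1 == nlr2 holds exactly, not approximately
        for nlr1, nlr2 in [(4.5, 4.6), (0.7, 13.2), (5.55, 5.55), (57.0, 0.5)]:
            haem = derive_haematology(make_record(nlr1=nlr1, nlr2=nlr2))
            assert haem.dnlr + nlr1 == nlr2


class TestExclusions:
    def test_duplicates_keep_first(self):
        records = [make_record(patient_id=f"p{i}") for i in range(8)]
        records += [make_record(patient_id="p0", age=80),
                    make_record(patient_id="p3", age=81)]
        kept, tally = apply_exclusions(records)
        assert len(kept) == 8
        assert tally == {"first_line": 0, "combination": 0, "duplicate": 2,
                         "missing_nlr": 0}
        assert next(r for r in kept if r.patient_id == "p0").age == 64

    def test_reason_order_first_line_before_missing_nlr(self):
        # a first-line record with missing NLR counts under first_line only
        records = [make_record(patient_id="fl", line_setting="first_line", nlr2=None),
                   make_record(patient_id="ok")]
        kept, tally = apply_exclusions(records)
        assert [r.patient_id for r in kept] == ["ok"]
        assert tally["first_line"] == 1 and tally["missing_nlr"] == 0

    def test_combination_and_missing_nlr(self):
        records = [make_record(patient_id="c", line_setting="combination"),
                   make_record(patient_id="m", nlr1=None),
                   make_record(patient_id="ok")]
        kept, tally = apply_exclusions(records)
        assert len(kept) == 1
        assert tally["combination"] == 1 and tally["missing_nlr"] == 1

    def test_idempotent(self):
        records = [make_record(patient_id=f"p{i % 5}") for i in range(9)]
        once, _ = apply_exclusions(records)
        twice, tally2 = apply_exclusions(once)
        assert twice == once
        assert sum(tally2.values()) == 0

    def test_chemo_nlr2_exemption_flag(self):
        records = [make_record(patient_id="ch", cohort="chemo",
                               treatment="chemo_only", nlr2=None)]
        kept_default, _ = apply_exclusions(records)
        assert kept_default == []
        kept_exempt, _ = apply_exclusions(records, exempt_chemo_from_nlr2=True)
        assert len(kept_exempt) == 1

    def test_empty_result_is_legal(self):
        records = [make_record(line_setting="first_line")]
        kept, tally = apply_exclusions(records)
        assert kept == [] and tally["first_line"] == 1
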