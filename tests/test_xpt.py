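"""Transport v5 reader/writer: round-trip fidelity, format errors, folders."""

import random
import string

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sendhc import fixtures
from sendhc.errors import (
    EmptyLibraryError,
    EmptyStudyError,
    StudyConsistencyError,
    UnsupportedFormatError,
    ValidationError,
    XptFormatError,
)
from sendhc.xpt import (
    DomainTable,
    VariableMeta,
    ibm_to_ieee,
    ieee_to_ibm,
    read_study_folder,
    read_xpt,
    write_xpt,
)


def random_table(rng: random.Random) -> DomainTable:
    """A random but valid mixed-type table, including edge values."""
    nvars = rng.randint(1, 8)
    variables, pool = [], list(string.ascii_uppercase)
    for i in range(nvars):
        name = rng.choice(pool) + "".join(
            rng.choice(string.ascii_uppercase + string.digits + "_")
            for _ in range(rng.randint(0, 6))
        )
        if any(v.name == name for v in variables):
            name = f"V{i}X{name}"[:8]
        kind = rng.choice(["character", "numeric"])
        variables.append(
            VariableMeta(name[:8], f"label {i}", kind, rng.randint(1, 12))
        )
    records = []
    for _ in range(rng.randint(0, 25)):
        rec = {}
        for v in variables:
            if v.kind == "numeric":
                rec[v.name] = rng.choice(
                    [None, 0.0, float(rng.randint(-999, 999)),
                     round(rng.uniform(-1e6, 1e6), 4), 1e-30, 2.5e20]
                )
            else:
                rec[v.name] = "".join(
                    rng.choice(string.ascii_uppercase + string.digits + " ,/-")
                    for _ in range(rng.randint(0, v.length))
                ).rstrip()
        records.append(rec)
    if all(v.kind == "character" for v in variables):
        # a trailing all-blank record in a char-only table is, by the v5
        # format itself, indistinguishable from card-image padding
        while records and all(val == "" for val in records[-1].values()):
            records.pop()
    return DomainTable("DM", variables, records)


@pytest.mark.parametrize("seed", range(10))
def test_roundtrip_random_tables(tmp_path, seed):
    """Any valid table survives write->read with records, order, labels, kinds."""
    rng = random.Random(seed)
    for i in range(10):
        table = random_table(rng)
        path = tmp_path / f"t{seed}_{i}.xpt"
        write_xpt(table, path)
        back = read_xpt(path)
        assert back.records == table.records
        assert [v.name for v in back.variables] == table.variable_names
        assert [v.label for v in back.variables] == [v.label for v in table.variables]
        assert [v.kind for v in back.variables] == [v.kind for v in table.variables]


@settings(max_examples=300, derandomize=True)
@given(
    st.one_of(
        st.just(0.0),
        st.floats(allow_nan=False, allow_infinity=False,
                  min_value=1e-70, max_value=1e60),
        st.floats(allow_nan=False, allow_infinity=False,
                  min_value=-1e60, max_value=-1e-70),
    )
)
def test_ibm_float_codec_exact(value):
    """IEEE->IBM->IEEE is exact within the IBM-representable magnitude range:
    the 56-bit IBM fraction absorbs the 53-bit significand plus up to three
    normalisation bits."""
    assert ibm_to_ieee(ieee_to_ibm(value)) == value


def test_missing_and_zero_numerics():
    assert ibm_to_ieee(ieee_to_ibm(None)) is None
    assert ibm_to_ieee(ieee_to_ibm(0.0)) == 0.0
    assert ibm_to_ieee(b"." + b"\x00" * 7) is None
    assert ibm_to_ieee(b"A" + b"\x00" * 7) is None  # special missing .A


def test_empty_table_roundtrip(tmp_path):
    """A 0-record dataset keeps its five variable descriptors."""
    variables = [VariableMeta(f"V{i}", f"var {i}", "character", 4) for i in range(5)]
    table = DomainTable("LB", variables, [])
    back = read_xpt(write_xpt(table, tmp_path / "lb.xpt"))
    assert len(back.variables) == 5
    assert back.records == []


def test_type_preservation_mixed_dm(tmp_path):
    table = DomainTable(
        "DM",
        [VariableMeta("USUBJID", "Subject", "character", 10),
         VariableMeta("AGE", "Age", "numeric", 8)],
        [{"USUBJID": "A-1", "AGE": 8.0}, {"USUBJID": "A-2", "AGE": None}],
    )
    back = read_xpt(write_xpt(table, tmp_path / "dm.xpt"))
    assert [v.kind for v in back.variables] == ["character", "numeric"]
    assert back.records == table.records


def test_trim_only_guarantee(tmp_path):
    """Reading strips trailing padding but never interior characters."""
    table = DomainTable(
        "CO",
        [VariableMeta("COVAL", "Comment", "character", 20)],
        [{"COVAL": ""}, {"COVAL": "A  B,C/D"}],
    )
    back = read_xpt(write_xpt(table, tmp_path / "co.xpt"))
    assert back.records[0]["COVAL"] == ""
    assert back.records[1]["COVAL"] == "A  B,C/D"


def test_char_length_auto_widened(tmp_path):
    """Values longer than the declared length widen the variable, capped at 200."""
    table = DomainTable(
        "MI",
        [VariableMeta("MISTRESC", "Result", "character", 4)],
        [{"MISTRESC": "CELLULARITY, INCREASED"}],
    )
    back = read_xpt(write_xpt(table, tmp_path / "mi.xpt"))
    assert back.variables[0].length == len("CELLULARITY, INCREASED")
    assert back.records == table.records
    too_long = DomainTable(
        "MI",
        [VariableMeta("MISTRESC", "Result", "character", 4)],
        [{"MISTRESC": "X" * 201}],
    )
    with pytest.raises(ValidationError):
        write_xpt(too_long, tmp_path / "bad.xpt")
    assert not (tmp_path / "bad.xpt").exists()  # validated before writing


def test_validation_before_any_bytes(tmp_path):
    with pytest.raises(ValidationError):
        VariableMeta("TOOLONGNAME1", "x", "character", 1)
    with pytest.raises(ValidationError):
        VariableMeta("OK", "y" * 41, "character", 1)


def test_pandas_reads_our_files(tmp_path):
    """Independent oracle: pandas' transport reader sees identical content."""
    table = DomainTable(
        "BW",
        [VariableMeta("USUBJID", "Subject", "character", 8),
         VariableMeta("BWSTRESN", "Result", "numeric", 8),
         VariableMeta("BWDY", "Day", "numeric", 8)],
        [{"USUBJID": f"S-{i}", "BWSTRESN": 200.0 + i * 0.5, "BWDY": float(i)}
         for i in range(1, 21)],
    )
    path = write_xpt(table, tmp_path / "bw.xpt")
    df = pd.read_sas(path, format="xport", encoding="latin-1")
    assert list(df.columns) == ["USUBJID", "BWSTRESN", "BWDY"]
    assert list(df["USUBJID"]) == [f"S-{i}" for i in range(1, 21)]
    assert list(df["BWSTRESN"]) == [200.0 + i * 0.5 for i in range(1, 21)]


def test_malformed_header_reports_offset(tmp_path):
    bad = tmp_path / "bad.xpt"
    bad.write_bytes(b"X" * 240)
    with pytest.raises(XptFormatError) as err:
        read_xpt(bad)
    assert err.value.offset == 0


def test_v8_transport_rejected(tmp_path):
    bad = tmp_path / "v8.xpt"
    header = b"HEADER RECORD*******LIBV8   HEADER RECORD!!!!!!!".ljust(80, b"0")
    bad.write_bytes(header + b" " * 160)
    with pytest.raises(UnsupportedFormatError):
        read_xpt(bad)


def test_empty_library_error(tmp_path):
    good = tmp_path / "good.xpt"
    write_xpt(DomainTable("TS", [VariableMeta("TSVAL", "", "character", 2)], []),
              good)
    truncated = tmp_path / "empty.xpt"
    truncated.write_bytes(good.read_bytes()[:240] + b" " * 80)
    with pytest.raises(EmptyLibraryError):
        read_xpt(truncated)


class TestStudyFolder:
    def test_nine_domains(self, tmp_path):
        folder, _ = fixtures.make_study(
            fixtures.StudySpec(seed=3, studyid="FOLD1"), tmp_path
        )
        bundle = read_study_folder(folder)
        assert set(bundle.domains) == {
            "TS", "TX", "DM", "EX", "DS", "SE", "BW", "LB", "MI"
        }
        assert bundle.studyid == "FOLD1"

    def test_ts_only_study(self, tmp_path):
        write_xpt(
            DomainTable(
                "TS",
                [VariableMeta("STUDYID", "", "character", 6),
                 VariableMeta("DOMAIN", "", "character", 2),
                 VariableMeta("TSPARMCD", "", "character", 8),
                 VariableMeta("TSVAL", "", "character", 10)],
                [{"STUDYID": "TSONLY", "DOMAIN": "TS",
                  "TSPARMCD": "SDESIGN", "TSVAL": "PARALLEL"}],
            ),
            tmp_path / "ts.xpt",
        )
        assert read_study_folder(tmp_path).studyid == "TSONLY"

    def test_conflicting_studyid(self, tmp_path):
        for domain, sid, fname in (("DM", "A", "dm.xpt"), ("LB", "B", "lb.xpt")):
            write_xpt(
                DomainTable(
                    domain,
                    [VariableMeta("STUDYID", "", "character", 2),
                     VariableMeta("DOMAIN", "", "character", 2)],
                    [{"STUDYID": sid, "DOMAIN": domain}],
                ),
                tmp_path / fname,
            )
        with pytest.raises(StudyConsistencyError) as err:
            read_study_folder(tmp_path)
        assert "DM" in str(err.value) and "LB" in str(err.value)

    def test_empty_folder(self, tmp_path):
        with pytest.raises(EmptyStudyError):
            read_study_folder(tmp_path)

    def test_split_domain_concatenated(self, tmp_path):
        variables = [VariableMeta("STUDYID", "", "character", 2),
                     VariableMeta("DOMAIN", "", "character", 2),
                     VariableMeta("USUBJID", "", "character", 6),
                     VariableMeta("LBSTRESN", "", "numeric", 8)]
        for part, n in (("lb1.xpt", 3), ("lb2.xpt", 2)):
            write_xpt(
                DomainTable("LB", variables, [
                    {"STUDYID": "S", "DOMAIN": "LB", "USUBJID": f"{part}-{i}",
                     "LBSTRESN": float(i)} for i in range(n)
                ]),
                tmp_path / part,
            )
        bundle = read_study_folder(tmp_path)
        assert len(bundle.domains["LB"].records) == 5
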