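"""Historical-control extraction: the study/subject filter chain.

A query is a chain of composable filters over the SQLite store. Study-level
filters narrow on trial-summary parameters (study design, start date);
subject-level filters identify negative-control animals via TX trial sets and
narrow on sex, species/strain and route; findings-level steps pull one
domain's records for the surviving animals and filter on derived animal age
(days) and study phase (Screening/Treatment/Recovery from SE epochs).

Conventions shared by every filter:

* null criteria are the identity (nothing dropped, derived columns still
  populated);
* comparisons are case-insensitive, applied after controlled-terminology
  mapping when a :class:`~sendhc.vocab.VocabMap` is supplied;
* rows whose deciding value is missing are "uncertain": dropped by default,
  kept with a short message in UNCERTAIN_MSG when ``incl_uncertain=True``
  (messages from successive filters concatenate with "; ");
* with ``incl_uncertain=False`` every filter's output is a subset of its
  input, and the subject-level filters commute.

Result containers are plain :class:`pandas.DataFrame` objects with fixed
column sets (StudySet, SubjectSet, findings tables), so they export to CSV
and feed the aggregation layer directly.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import re

import pandas as pd

from .db import DbHandle, _table_columns, _user_tables, list_studies
from .errors import (
    InvalidRangeError,
    InvalidStudyDayError,
    UnsupportedDomainError,
)
from .vocab import VocabMap

STUDY_COLUMNS = ["STUDYID", "SDESIGN", "STSTDTC", "UNCERTAIN_MSG"]
SUBJECT_COLUMNS = [
    "STUDYID", "USUBJID", "SETCD", "TCNTRL", "SEX", "SPECIES", "STRAIN",
    "ROUTE", "BRTHDTC", "RFSTDTC", "AGE", "AGEU", "UNCERTAIN_MSG",
]

#: TCNTRL substrings marking a negative control set (after uppercasing);
#: a value containing POSITIVE is never a negative control.
NEGATIVE_CONTROL_PATTERNS = (
    "VEHICLE", "PLACEBO", "SHAM", "UNTREATED", "NO TREATMENT", "NEGATIVE",
)

PHASE_SCREENING = "Screening"
PHASE_TREATMENT = "Treatment"
PHASE_RECOVERY = "Recovery"
PHASE_UNCERTAIN = "Uncertain"

# Ordered keyword rules; first match wins, so "PRETREATMENT" is Screening.
_PHASE_RULES = (
    (PHASE_SCREENING, ("screen", "pre-treat", "pretreat", "acclimat", "baseline")),
    (PHASE_RECOVERY, ("recovery", "post-treat", "posttreat", "washout")),
    (PHASE_TREATMENT, ("treat", "dos", "exposure")),
)

#: Mean Gregorian month/year lengths for AGE unit conversion.
AGE_UNIT_DAYS = {
    "DAYS": 1.0, "DAY": 1.0, "D": 1.0,
    "WEEKS": 7.0, "WEEK": 7.0, "W": 7.0,
    "MONTHS": 30.4375, "MONTH": 30.4375, "MO": 30.4375,
    "YEARS": 365.25, "YEAR": 365.25, "Y": 365.25,
}

_PARTIAL_DATE_RE = re.compile(r"\A(\d{4})(?:-(\d{2}))?(?:-(\d{2}))?")


# ---------------------------------------------------------------------------
# small shared helpers
# ---------------------------------------------------------------------------

def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) \
        or str(value).strip() == ""


def _mapped(value, codelist_key: str, vocab: VocabMap | None) -> str:
    """Uppercased comparison form of a value, CT-mapped when possible."""
    text = "" if _is_missing(value) else str(value).strip()
    if vocab is not None:
        try:
            text, _ = vocab.apply(text, codelist_key)
        except Exception:
            pass
    return text.upper()


def partial_date_interval(text) -> tuple[_dt.date, _dt.date] | None:
    """Interval of calendar dates consistent with a (partial) ISO 8601 value.

    ``2017`` spans the year, ``2017-06`` the month, a full date a single day.
    Returns None when unparseable.
    """
    if _is_missing(text):
        return None
    m = _PARTIAL_DATE_RE.match(str(text).strip())
    if not m:
        return None
    year = int(m.group(1))
    try:
        if m.group(2) is None:
            return _dt.date(year, 1, 1), _dt.date(year, 12, 31)
        month = int(m.group(2))
        if m.group(3) is None:
            last = calendar.monthrange(year, month)[1]
            return _dt.date(year, month, 1), _dt.date(year, month, last)
        d = _dt.date(year, month, int(m.group(3)))
        return d, d
    except ValueError:
        return None


def parse_full_date(text) -> _dt.date | None:
    """Strict YYYY-MM-DD (a leading datetime prefix is accepted)."""
    iv = partial_date_interval(text)
    if iv is None or iv[0] != iv[1]:
        return None
    return iv[0]


def parse_datetime_floor(text) -> _dt.datetime | None:
    """ISO datetime with missing parts floored (for half-open comparisons)."""
    if _is_missing(text):
        return None
    s = str(text).strip()
    m = _PARTIAL_DATE_RE.match(s)
    if not m:
        return None
    try:
        date = _dt.date(
            int(m.group(1)), int(m.group(2) or 1), int(m.group(3) or 1)
        )
    except ValueError:
        return None
    tm = _dt.time(0, 0, 0)
    if "T" in s:
        try:
            tm = _dt.time.fromisoformat(s.split("T", 1)[1])
        except ValueError:
            pass
    return _dt.datetime.combine(date, tm)


def _append_msg(frame: pd.DataFrame, mask, message: str) -> None:
    prev = frame.loc[mask, "UNCERTAIN_MSG"]
    frame.loc[mask, "UNCERTAIN_MSG"] = [
        f"{p}; {message}" if isinstance(p, str) and p else message for p in prev
    ]


def _sql_in(values) -> str:
    return ", ".join("?" for _ in values)


# ---------------------------------------------------------------------------
# study-level filters
# ---------------------------------------------------------------------------

def _ts_param(db: DbHandle, parmcd: str) -> dict[str, str]:
    rows = db.connection.execute(
        "SELECT STUDYID, TSVAL FROM TS WHERE UPPER(TSPARMCD)=?", (parmcd.upper(),)
    ).fetchall()
    out: dict[str, str] = {}
    for sid, val in rows:
        if sid not in out and not _is_missing(val):
            out[sid] = str(val).strip()
    return out


def _base_study_set(db: DbHandle, prior: pd.DataFrame | None) -> pd.DataFrame:
    if prior is not None:
        frame = prior.copy()
        for col in STUDY_COLUMNS:
            if col not in frame.columns:
                frame[col] = None
        return frame[STUDY_COLUMNS]
    ids = list_studies(db)
    if not ids:  # fall back to whatever TS/DM mention
        ids = sorted(
            {r[0] for r in db.connection.execute("SELECT DISTINCT STUDYID FROM TS")}
            | {r[0] for r in db.connection.execute("SELECT DISTINCT STUDYID FROM DM")}
        )
    designs = _ts_param(db, "SDESIGN")
    starts = _ts_param(db, "STSTDTC")
    return pd.DataFrame(
        {
            "STUDYID": ids,
            "SDESIGN": [designs.get(s) for s in ids],
            "STSTDTC": [starts.get(s) for s in ids],
            "UNCERTAIN_MSG": ["" for _ in ids],
        }
    )


def get_studies_sdesign(db: DbHandle, design: str | None = None,
                        prior: pd.DataFrame | None = None,
                        incl_uncertain: bool = False) -> pd.DataFrame:
    """Keep studies whose TS SDESIGN equals ``design`` (case-insensitive)."""
    studies = _base_study_set(db, prior)
    if design is None:
        return studies.reset_index(drop=True)
    want = str(design).strip().upper()
    have = studies["SDESIGN"].map(
        lambda v: "" if _is_missing(v) else str(v).strip().upper()
    )
    keep = have == want
    uncertain = have == ""
    if incl_uncertain:
        _append_msg(studies, uncertain, "SDESIGN missing")
        keep = keep | uncertain
    return studies[keep].reset_index(drop=True)


def get_studies_ststdtc(db: DbHandle, from_date=None, to_date=None,
                        prior: pd.DataFrame | None = None,
                        incl_uncertain: bool = False) -> pd.DataFrame:
    """Keep studies whose TS STSTDTC can fall in [from_date, to_date].

    Bounds and stored values may be partial ISO dates; a partial study date
    matches when any completion of it lies in the interval.
    """
    studies = _base_study_set(db, prior)
    if from_date is None and to_date is None:
        return studies.reset_index(drop=True)
    lo = partial_date_interval(from_date)[0] if from_date is not None else _dt.date.min
    hi = partial_date_interval(to_date)[1] if to_date is not None else _dt.date.max
    if lo > hi:
        raise InvalidRangeError(f"from_date {from_date!r} is after to_date {to_date!r}")
    keep, uncertain = [], []
    for val in studies["STSTDTC"]:
        iv = partial_date_interval(val)
        if iv is None:
            keep.append(False)
            uncertain.append(True)
        else:
            keep.append(iv[1] >= lo and iv[0] <= hi)
            uncertain.append(False)
    keep = pd.Series(keep, index=studies.index)
    uncertain = pd.Series(uncertain, index=studies.index)
    if incl_uncertain:
        _append_msg(studies, uncertain, "STSTDTC missing")
        keep = keep | uncertain
    return studies[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# subject-level filters
# ---------------------------------------------------------------------------

def is_negative_control(tcntrl, vocab: VocabMap | None = None) -> bool | None:
    """Classify a TCNTRL value: True negative, False positive/other, None missing."""
    if _is_missing(tcntrl):
        return None
    text = _mapped(tcntrl, "send control type", vocab)
    if "POSITIVE" in text:
        return False
    if any(pat in text for pat in NEGATIVE_CONTROL_PATTERNS):
        return True
    return None  # ambiguous: neither recognizably negative nor positive


def get_control_subj(db: DbHandle, studies: pd.DataFrame,
                     incl_uncertain: bool = False,
                     vocab: VocabMap | None = None) -> pd.DataFrame:
    """All subjects of negative-control trial sets in the given studies.

    Trial sets are classified from the TX parameter TCNTRL; subjects are DM
    rows matched on SETCD, with the set's TCNTRL value carried onto each row.
    Sets with a missing or unrecognized TCNTRL — and whole studies lacking TX
    — are uncertain; explicit positive controls are always excluded.
    """
    conn = db.connection
    ids = list(studies["STUDYID"])
    if not ids:
        return pd.DataFrame(columns=SUBJECT_COLUMNS)
    tx = conn.execute(
        f"SELECT STUDYID, SETCD, TXVAL FROM TX "
        f"WHERE UPPER(TXPARMCD)='TCNTRL' AND STUDYID IN ({_sql_in(ids)})",
        ids,
    ).fetchall()
    tcntrl: dict[tuple[str, str], str] = {
        (sid, set_): val for sid, set_, val in tx
    }
    studies_with_tx = {
        r[0]
        for r in conn.execute(
            f"SELECT DISTINCT STUDYID FROM TX WHERE STUDYID IN ({_sql_in(ids)})", ids
        )
    }
    dm_cols = [
        "STUDYID", "USUBJID", "SETCD", "SEX", "SPECIES", "STRAIN",
        "BRTHDTC", "RFSTDTC", "AGE", "AGEU",
    ]
    have = set(_table_columns(conn, "DM"))
    sel = ", ".join(c if c in have else f"NULL AS {c}" for c in dm_cols)
    dm = pd.read_sql_query(
        f"SELECT {sel} FROM DM WHERE STUDYID IN ({_sql_in(ids)}) "
        f"ORDER BY STUDYID, USUBJID",
        conn,
        params=ids,
    )
    rows = []
    for rec in dm.to_dict("records"):
        sid, setcd = rec["STUDYID"], rec.get("SETCD")
        msg = ""
        if sid not in studies_with_tx:
            cls, msg = None, "TX missing"
        else:
            val = tcntrl.get((sid, setcd))
            cls = is_negative_control(val, vocab)
            if cls is None:
                msg = "TCNTRL missing" if _is_missing(val) else "TCNTRL ambiguous"
            rec["TCNTRL"] = val
        if cls is False:
            continue  # explicit positive control: never included
        if cls is None and not incl_uncertain:
            continue
        rec.setdefault("TCNTRL", None)
        rec["UNCERTAIN_MSG"] = msg
        rows.append(rec)
    out = pd.DataFrame(rows, columns=SUBJECT_COLUMNS)
    return out.reset_index(drop=True)


def get_subj_sex(db: DbHandle, subjects: pd.DataFrame, sex: str | None = None,
                 incl_uncertain: bool = False,
                 vocab: VocabMap | None = None) -> pd.DataFrame:
    """Filter on DM.SEX (codelist-mapped, case-insensitive)."""
    if sex is None or subjects.empty:
        return subjects.reset_index(drop=True)
    subjects = subjects.copy()
    want = _mapped(sex, "sex", vocab)
    have = subjects["SEX"].map(lambda v: _mapped(v, "sex", vocab))
    keep = have == want
    missing = have == ""
    if incl_uncertain:
        _append_msg(subjects, missing, "SEX missing")
        keep = keep | missing
    return subjects[keep].reset_index(drop=True)


def _tx_param(db: DbHandle, ids, parmcd: str) -> dict[tuple[str, str], str]:
    rows = db.connection.execute(
        f"SELECT STUDYID, SETCD, TXVAL FROM TX "
        f"WHERE UPPER(TXPARMCD)=? AND STUDYID IN ({_sql_in(ids)})",
        [parmcd.upper(), *ids],
    ).fetchall()
    return {
        (sid, set_): str(val).strip()
        for sid, set_, val in rows
        if not _is_missing(val)
    }


def get_subj_species_strain(db: DbHandle, subjects: pd.DataFrame,
                            species: str | None = None, strain: str | None = None,
                            incl_uncertain: bool = False,
                            vocab: VocabMap | None = None) -> pd.DataFrame:
    """Filter on species/strain, resolved DM > TX set parameter > TS parameter."""
    if subjects.empty:
        return subjects.reset_index(drop=True)
    subjects = subjects.copy()
    ids = sorted(set(subjects["STUDYID"]))
    fallback = {
        "SPECIES": (_tx_param(db, ids, "SPECIES"), _ts_param(db, "SPECIES")),
        "STRAIN": (_tx_param(db, ids, "STRAIN"), _ts_param(db, "STRAIN")),
    }
    for col, (tx_map, ts_map) in fallback.items():
        resolved = []
        for rec in subjects[["STUDYID", "SETCD", col]].itertuples(index=False):
            val = rec[2]
            if _is_missing(val):
                val = tx_map.get((rec[0], rec[1]))
            if _is_missing(val):
                val = ts_map.get(rec[0])
            resolved.append(None if _is_missing(val) else str(val).strip())
        subjects[col] = resolved
    keep = pd.Series(True, index=subjects.index)
    missing = pd.Series(False, index=subjects.index)
    for col, want, key in (
        ("SPECIES", species, "species"),
        ("STRAIN", strain, "strain/substrain"),
    ):
        if want is None:
            continue
        have = subjects[col].map(lambda v, k=key: _mapped(v, k, vocab))
        keep &= have == _mapped(want, key, vocab)
        this_missing = have == ""
        missing |= this_missing
        if incl_uncertain:
            _append_msg(subjects, this_missing, f"{col} missing")
    if incl_uncertain:
        keep |= missing
    return subjects[keep].reset_index(drop=True)


def get_subj_route(db: DbHandle, subjects: pd.DataFrame, route: str | None = None,
                   incl_uncertain: bool = False,
                   vocab: VocabMap | None = None) -> pd.DataFrame:
    """Filter on dose route, resolved EX.EXROUTE (any record) > TS ROUTE."""
    if subjects.empty:
        return subjects.reset_index(drop=True)
    subjects = subjects.copy()
    ids = sorted(set(subjects["STUDYID"]))
    ex_routes: dict[tuple[str, str], list[str]] = {}
    if "EX" in _user_tables(db.connection):
        rows = db.connection.execute(
            f"SELECT STUDYID, USUBJID, EXROUTE FROM EX "
            f"WHERE STUDYID IN ({_sql_in(ids)}) ORDER BY EXSEQ",
            ids,
        ).fetchall()
        for sid, usubjid, val in rows:
            if not _is_missing(val):
                lst = ex_routes.setdefault((sid, usubjid), [])
                if str(val).strip() not in lst:
                    lst.append(str(val).strip())
    ts_route = _ts_param(db, "ROUTE")
    resolved, candidates = [], []
    for rec in subjects[["STUDYID", "USUBJID"]].itertuples(index=False):
        routes = ex_routes.get((rec[0], rec[1]))
        if not routes:
            routes = [ts_route[rec[0]]] if rec[0] in ts_route else []
        resolved.append(routes[0] if routes else None)
        candidates.append(routes)
    subjects["ROUTE"] = resolved
    if route is None:
        return subjects.reset_index(drop=True)
    key = "route of administration response"
    want = _mapped(route, key, vocab)
    keep = pd.Series(
        [any(_mapped(r, key, vocab) == want for r in routes) for routes in candidates],
        index=subjects.index,
    )
    missing = pd.Series([not routes for routes in candidates], index=subjects.index)
    if incl_uncertain:
        _append_msg(subjects, missing, "ROUTE missing")
        keep |= missing
    return subjects[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# findings extraction and derivations
# ---------------------------------------------------------------------------

def get_subj_data(db: DbHandle, subjects: pd.DataFrame, domain: str) -> pd.DataFrame:
    """All rows of ``domain`` for the subjects, plus null AGEDAYS/PHASE columns."""
    conn = db.connection
    domain = domain.upper()
    if domain not in _user_tables(conn):
        raise UnsupportedDomainError(f"no table for domain {domain!r}")
    if "USUBJID" not in _table_columns(conn, domain):
        raise UnsupportedDomainError(
            f"domain {domain!r} has no USUBJID variable; not a subject-level domain"
        )
    ids = sorted(set(subjects["STUDYID"])) if not subjects.empty else []
    if ids:
        frame = pd.read_sql_query(
            f'SELECT * FROM "{domain}" WHERE STUDYID IN ({_sql_in(ids)}) '
            f"ORDER BY STUDYID, USUBJID",
            conn,
            params=ids,
        )
        pairs = set(zip(subjects["STUDYID"], subjects["USUBJID"]))
        frame = frame[
            [pair in pairs for pair in zip(frame["STUDYID"], frame["USUBJID"])]
        ]
    else:
        frame = pd.read_sql_query(f'SELECT * FROM "{domain}" WHERE 0', conn)
    frame = frame.reset_index(drop=True)
    frame["AGEDAYS"] = pd.Series([None] * len(frame), dtype="object")
    frame["PHASE"] = pd.Series([None] * len(frame), dtype="object")
    frame.attrs["domain"] = domain
    return frame


def _day_offset(dy) -> int | None:
    """SEND study day -> offset in days from RFSTDTC (day 1 is offset 0)."""
    if _is_missing(dy):
        return None
    dy = int(float(dy))
    if dy == 0:
        raise InvalidStudyDayError("--DY of 0 encountered; SEND has no study day 0")
    return dy - 1 if dy >= 1 else dy


def derive_age_days(subject_row, finding_row, domain: str | None = None) -> int | None:
    """Animal age in whole days at the time of one finding.

    Resolution order: finding --DTC minus BRTHDTC; else RFSTDTC minus BRTHDTC
    plus the --DY offset; else DM.AGE/AGEU converted to days plus the --DY
    offset; else None. Negative results (data errors) return None.
    """
    get_s = (lambda k: subject_row.get(k)) if isinstance(subject_row, dict) \
        else (lambda k: subject_row[k] if k in subject_row.index else None)
    get_f = (lambda k: finding_row.get(k)) if isinstance(finding_row, dict) \
        else (lambda k: finding_row[k] if k in finding_row.index else None)

    if domain is None:
        keys = finding_row.keys() if isinstance(finding_row, dict) \
            else finding_row.index
        domain = next(
            (k[:-3] for k in keys if k.endswith("DTC") and len(k) > 3), None
        ) or next((k[:-2] for k in keys if k.endswith("DY") and len(k) > 2), "")
    dy = get_f(f"{domain}DY")
    offset = _day_offset(dy)  # raises on day 0

    birth = parse_full_date(get_s("BRTHDTC"))
    dtc = parse_full_date(get_f(f"{domain}DTC"))
    if birth is not None and dtc is not None:
        age = (dtc - birth).days
        return age if age >= 0 else None

    ref = parse_full_date(get_s("RFSTDTC"))
    if birth is not None and ref is not None:
        age = (ref - birth).days + (offset or 0)
        return age if age >= 0 else None

    age_val, ageu = get_s("AGE"), get_s("AGEU")
    if not _is_missing(age_val) and not _is_missing(ageu):
        unit = AGE_UNIT_DAYS.get(str(ageu).strip().upper())
        if unit is not None:
            age = round(float(age_val) * unit) + (offset or 0)
            return age if age >= 0 else None
    return None


def get_findings_subj_age(findings: pd.DataFrame, subjects: pd.DataFrame,
                          min_days: int | None = None, max_days: int | None = None,
                          incl_uncertain: bool = False) -> pd.DataFrame:
    """Populate AGEDAYS and keep findings inside [min_days, max_days] (inclusive)."""
    if min_days is not None and max_days is not None and min_days > max_days:
        raise InvalidRangeError(f"min_days {min_days} exceeds max_days {max_days}")
    findings = findings.copy()
    domain = findings.attrs.get("domain", "")
    subj_index = {
        (r["STUDYID"], r["USUBJID"]): r for r in subjects.to_dict("records")
    }
    ages = []
    for rec in findings.to_dict("records"):
        subj = subj_index.get((rec.get("STUDYID"), rec.get("USUBJID")))
        ages.append(None if subj is None else derive_age_days(subj, rec, domain))
    findings["AGEDAYS"] = pd.Series(ages, index=findings.index, dtype="object")
    if min_days is None and max_days is None:
        return findings.reset_index(drop=True)
    lo = min_days if min_days is not None else 0
    hi = max_days if max_days is not None else float("inf")
    keep = pd.Series(
        [a is not None and lo <= a <= hi for a in ages], index=findings.index
    )
    if incl_uncertain:
        unknown = pd.Series([a is None for a in ages], index=findings.index)
        if "UNCERTAIN_MSG" not in findings.columns:
            findings["UNCERTAIN_MSG"] = ""
        _append_msg(findings, unknown, "AGE unknown")
        keep |= unknown
    return findings[keep].reset_index(drop=True)


def classify_epoch(epoch_label) -> str:
    """Phase class of an epoch label by ordered keyword rules."""
    text = "" if _is_missing(epoch_label) else str(epoch_label).lower()
    for phase, keywords in _PHASE_RULES:
        if any(k in text for k in keywords):
            return phase
    return PHASE_UNCERTAIN


def get_findings_phase(db: DbHandle, findings: pd.DataFrame,
                       phase: str | None = None,
                       incl_uncertain: bool = False) -> pd.DataFrame:
    """Populate PHASE from SE epochs and filter on it.

    A finding's epoch is the SE row with SESTDTC <= --DTC < SEENDTC
    (half-open; a null SEENDTC on the last epoch extends to infinity). With no
    --DTC, the --DY is compared against epoch study-day bounds derived from
    RFSTDTC. Findings with no usable SE data classify as Uncertain.
    """
    findings = findings.copy()
    domain = findings.attrs.get("domain", "")
    conn = db.connection
    ids = sorted(set(findings["STUDYID"])) if not findings.empty else []
    epochs: dict[tuple[str, str], list[tuple]] = {}
    rfst: dict[tuple[str, str], _dt.date] = {}
    if ids and "SE" in _user_tables(conn):
        se_cols = set(_table_columns(conn, "SE"))
        label_col = "EPOCH" if "EPOCH" in se_cols else "ELEMENT"
        rows = conn.execute(
            f'SELECT STUDYID, USUBJID, "{label_col}", SESTDTC, SEENDTC FROM SE '
            f"WHERE STUDYID IN ({_sql_in(ids)}) ORDER BY STUDYID, USUBJID, SESTDTC",
            ids,
        ).fetchall()
        for sid, usubjid, label, start, end in rows:
            epochs.setdefault((sid, usubjid), []).append(
                (label, parse_datetime_floor(start), parse_datetime_floor(end))
            )
    if ids:
        for sid, usubjid, ref in conn.execute(
            f"SELECT STUDYID, USUBJID, RFSTDTC FROM DM "
            f"WHERE STUDYID IN ({_sql_in(ids)})",
            ids,
        ):
            d = parse_full_date(ref)
            if d is not None:
                rfst[(sid, usubjid)] = d

    def send_day(date: _dt.date, ref: _dt.date) -> int:
        diff = (date - ref).days
        return diff + 1 if diff >= 0 else diff

    phases = []
    for rec in findings.to_dict("records"):
        key = (rec.get("STUDYID"), rec.get("USUBJID"))
        subject_epochs = epochs.get(key, [])
        assigned = PHASE_UNCERTAIN
        dtc = parse_datetime_floor(rec.get(f"{domain}DTC"))
        if subject_epochs and dtc is not None:
            for i, (label, start, end) in enumerate(subject_epochs):
                if start is None:
                    continue
                last = i == len(subject_epochs) - 1
                if start <= dtc and (end is None and last or end is not None
                                     and dtc < end):
                    assigned = classify_epoch(label)
                    break
        elif subject_epochs and not _is_missing(rec.get(f"{domain}DY")):
            ref = rfst.get(key)
            if ref is not None:
                dy = int(float(rec[f"{domain}DY"]))
                for i, (label, start, end) in enumerate(subject_epochs):
                    if start is None:
                        continue
                    sday = send_day(start.date(), ref)
                    last = i == len(subject_epochs) - 1
                    eday = None if end is None else send_day(end.date(), ref)
                    if sday <= dy and (eday is None and last or eday is not None
                                       and dy < eday):
                        assigned = classify_epoch(label)
                        break
        phases.append(assigned)
    findings["PHASE"] = pd.Series(phases, index=findings.index, dtype="object")
    if phase is None:
        return findings.reset_index(drop=True)
    keep = findings["PHASE"] == phase
    if incl_uncertain:
        keep |= findings["PHASE"] == PHASE_UNCERTAIN
    return findings[keep].reset_index(drop=True)
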