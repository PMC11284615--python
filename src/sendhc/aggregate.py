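"""Aggregate surfaces over extracted control findings.

Two statistics summarize historical control data:

* **Background incidence** (MI): per specimen, the fraction of distinct
  examined control animals exhibiting each finding. The denominator is the
  number of distinct animals with at least one examination record for that
  specimen whose status is not NOT DONE — the pathology convention of
  "affected / examined", which reduces to "affected / all selected" when
  every animal was examined.
* **Reference ranges** (LB/BW): per test (and unit, specimen, optionally
  sex), n, arithmetic mean and sample standard deviation of the numeric
  standardized results.

Percentages are rounded half-up at two decimals. Groups never pool across
units; non-numeric results are excluded from ranges and tallied.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .errors import WrongDomainError

INCIDENCE_COLUMNS = ["SPECIMEN", "FINDING", "N_AFFECTED", "N_EXAMINED",
                     "INCIDENCE_PCT"]
RANGE_COLUMNS = ["TESTCD", "TEST", "SPEC", "UNITS", "SEX", "N", "MEAN", "SD"]

_NOT_DONE = "NOT DONE"


def round_half_up_pct(numerator: int, denominator: int) -> float:
    """100*numerator/denominator, rounded half-up to 2 decimals."""
    pct = Decimal(numerator * 100) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _clean(value) -> str:
    return "" if value is None or (isinstance(value, float) and pd.isna(value)) \
        else str(value).strip()


def incidence_table(findings: pd.DataFrame, subjects: pd.DataFrame | None = None,
                    group_by_severity: bool = False) -> pd.DataFrame:
    """Background incidence of each (specimen, finding) among examined animals.

    ``findings`` must be MI-domain records (MISPEC/MISTRESC present).
    Affected and examined counts are distinct-animal counts, so repeated
    records of one finding in one animal count once.
    """
    required = {"MISPEC", "MISTRESC", "STUDYID", "USUBJID"}
    if not required.issubset(findings.columns):
        raise WrongDomainError(
            "incidence_table requires MI findings (MISPEC/MISTRESC)"
        )
    cols = INCIDENCE_COLUMNS.copy()
    if group_by_severity:
        cols.insert(2, "SEVERITY")
    if findings.empty:
        return pd.DataFrame(columns=cols)

    examined: dict[str, set] = {}
    affected: dict[tuple, set] = {}
    for rec in findings.to_dict("records"):
        spec = _clean(rec.get("MISPEC")).upper()
        if not spec:
            continue
        subject = (rec["STUDYID"], rec["USUBJID"])
        status = _clean(rec.get("MISTAT")).upper()
        if status == _NOT_DONE:
            continue
        examined.setdefault(spec, set()).add(subject)
        finding = _clean(rec.get("MISTRESC")).upper()
        if not finding:
            continue
        key = (spec, finding, _clean(rec.get("MISEV")) or None) \
            if group_by_severity else (spec, finding)
        affected.setdefault(key, set()).add(subject)

    rows = []
    for key in sorted(affected, key=lambda k: tuple(str(x) for x in k)):
        spec = key[0]
        n_aff = len(affected[key])
        n_exam = len(examined[spec])
        row = {
            "SPECIMEN": spec,
            "FINDING": key[1],
            "N_AFFECTED": n_aff,
            "N_EXAMINED": n_exam,
            "INCIDENCE_PCT": round_half_up_pct(n_aff, n_exam),
        }
        if group_by_severity:
            row["SEVERITY"] = key[2]
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def reference_ranges(findings: pd.DataFrame, subjects: pd.DataFrame | None = None,
                     group_by_sex: bool = False) -> pd.DataFrame:
    """Mean/SD/n of numeric standardized results per test and unit.

    Works on LB or BW findings (prefix detected from columns). SD is the
    sample standard deviation (n-1) and null for singleton groups. The count
    of rows excluded for a non-numeric --STRESN is reported in
    ``frame.attrs["n_excluded"]``.
    """
    prefix = next(
        (p for p in ("LB", "BW") if f"{p}TESTCD" in findings.columns), None
    )
    if prefix is None:
        raise WrongDomainError(
            "reference_ranges requires LB or BW findings (--TESTCD/--STRESN)"
        )
    if group_by_sex:
        if subjects is None:
            raise WrongDomainError("group_by_sex requires the SubjectSet")
        sex_of = {
            (r["STUDYID"], r["USUBJID"]): _clean(r.get("SEX")).upper() or None
            for r in subjects.to_dict("records")
        }

    groups: dict[tuple, list[float]] = {}
    names: dict[tuple, str] = {}
    excluded = 0
    for rec in findings.to_dict("records"):
        value = rec.get(f"{prefix}STRESN")
        if value is None or (isinstance(value, float) and pd.isna(value)):
            excluded += 1
            continue
        try:
            value = float(value)
        except (TypeError, ValueError):
            excluded += 1
            continue
        testcd = _clean(rec.get(f"{prefix}TESTCD"))
        spec = _clean(rec.get(f"{prefix}SPEC")) or None
        units = _clean(rec.get(f"{prefix}STRESU"))
        sex = sex_of.get((rec["STUDYID"], rec["USUBJID"])) if group_by_sex else None
        key = (testcd, spec, units, sex)
        groups.setdefault(key, []).append(value)
        names.setdefault(key, _clean(rec.get(f"{prefix}TEST")))

    rows = []
    for key in sorted(groups, key=lambda k: tuple(str(x) for x in k)):
        values = pd.Series(groups[key], dtype=float)
        n = len(values)
        rows.append(
            {
                "TESTCD": key[0],
                "TEST": names[key],
                "SPEC": key[1],
                "UNITS": key[2],
                "SEX": key[3],
                "N": n,
                "MEAN": float(values.mean()),
                "SD": float(values.std(ddof=1)) if n > 1 else None,
            }
        )
    out = pd.DataFrame(rows, columns=RANGE_COLUMNS)
    out.attrs["n_excluded"] = excluded
    return out


def export_table(frame: pd.DataFrame, path, format: str = "csv") -> Path:
    """Write an aggregate (or any result) table as RFC 4180 CSV.

    Percent columns are serialized with two decimals; everything else at full
    precision.
    """
    if format != "csv":
        raise ValueError(f"unsupported export format {format!r}")
    path = Path(path)
    frame = frame.copy()
    for col in frame.columns:
        if str(col).endswith("_PCT") and not frame.empty:
            frame[col] = [
                "" if v is None or (isinstance(v, float) and pd.isna(v))
                else f"{v:.2f}"
                for v in frame[col]
            ]
    frame.to_csv(path, index=False, lineterminator="\r\n", encoding="utf-8")
    return path
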