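"""SAS Transport (XPORT) v5 reading and writing, plus SEND study-folder discovery.

The transport v5 format is the FDA exchange container for SEND domains: a
sequence of 80-byte card-image records — library header, member (dataset)
headers, 140-byte NAMESTR variable descriptors, then fixed-length observation
records with numerics in IBM System/360 hexadecimal floating point.

This module reads and writes that format bit-faithfully for the subset SEND
uses: one dataset per file, character and 8-byte numeric variables, ASCII
text. Reading right-trims only padding (spaces/NULs) from character values and
maps SAS missing numerics to ``None``; writing is deterministic (fixed header
timestamp by default) so identical tables produce byte-identical files.
"""

from __future__ import annotations

import math
import re
import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import (
    EmptyLibraryError,
    EmptyStudyError,
    StudyConsistencyError,
    UnsupportedFormatError,
    ValidationError,
    XptFormatError,
)

__all__ = [
    "VariableMeta",
    "DomainTable",
    "StudyBundle",
    "read_xpt",
    "write_xpt",
    "read_study_folder",
]

_NAME_RE = re.compile(r"[A-Z][A-Z0-9_]*\Z")

# Fixed stamp makes writes reproducible; pass created= to override.
_DEFAULT_STAMP = "01JAN20:12:00:00"

_LIB_HEADER = (
    b"HEADER RECORD*******LIBRARY HEADER RECORD!!!!!!!"
    b"000000000000000000000000000000  "
)
_V8_MARKERS = (b"LIBV8", b"MEMBV8")
_MEMBER_HEADER = (
    b"HEADER RECORD*******MEMBER  HEADER RECORD!!!!!!!"
    b"000000000000000001600000000140  "
)
_DSCRPTR_HEADER = (
    b"HEADER RECORD*******DSCRPTR HEADER RECORD!!!!!!!"
    b"000000000000000000000000000000  "
)
_NAMESTR_PREFIX = b"HEADER RECORD*******NAMESTR HEADER RECORD!!!!!!!000000"
_OBS_HEADER = (
    b"HEADER RECORD*******OBS     HEADER RECORD!!!!!!!"
    b"000000000000000000000000000000  "
)
_NAMESTR_FMT = ">hhhh8s40s8shhh2s8shhl52s"
assert struct.calcsize(_NAMESTR_FMT) == 140


@dataclass(frozen=True)
class VariableMeta:
    """Metadata for one transport variable (one SEND column)."""

    name: str
    label: str = ""
    kind: str = "character"  # "character" | "numeric"
    length: int = 8

    def __post_init__(self):
        if not _NAME_RE.match(self.name) or len(self.name) > 8:
            raise ValidationError(
                f"variable name {self.name!r} must match [A-Z][A-Z0-9_]* and be <=8 chars"
            )
        if len(self.label) > 40:
            raise ValidationError(f"label for {self.name} exceeds 40 chars")
        if self.kind not in ("character", "numeric"):
            raise ValidationError(f"kind must be character|numeric, got {self.kind!r}")
        if self.length < 1:
            raise ValidationError(f"length for {self.name} must be >=1")


@dataclass
class DomainTable:
    """One SEND domain: ordered variables with metadata plus ordered records.

    Records are plain dicts keyed by variable name; character values are
    strings, numeric values floats or ``None`` (missing).
    """

    domain: str
    variables: list[VariableMeta]
    records: list[dict]
    source_path: str = ""

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate variable names in {self.domain}")

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records, columns=self.variable_names)

    def __eq__(self, other):
        if not isinstance(other, DomainTable):
            return NotImplemented
        return (
            self.domain == other.domain
            and self.variables == other.variables
            and self.records == other.records
        )


@dataclass
class StudyBundle:
    """One SEND study: a folder of domain tables keyed by domain code."""

    studyid: str
    folder: str
    domains: dict[str, DomainTable] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# IBM System/360 hexadecimal floating point <-> IEEE 754 double
# ---------------------------------------------------------------------------

def ieee_to_ibm(value: float | None) -> bytes:
    """Encode a double (or None => SAS missing '.') as 8 IBM-float bytes.

    Exact for every finite double whose base-16 exponent fits the IBM range:
    the 56-bit IBM fraction absorbs the 53-bit IEEE significand plus up to
    three normalisation bits without rounding.
    """
    if value is None:
        return b"." + b"\x00" * 7
    value = float(value)
    if math.isnan(value):
        return b"." + b"\x00" * 7
    if math.isinf(value):
        raise ValidationError("cannot encode infinity in transport format")
    if value == 0.0:
        return b"\x00" * 8
    sign = 0x80 if value < 0 else 0x00
    m, e = math.frexp(abs(value))  # abs = m * 2**e, 0.5 <= m < 1
    k, r = divmod(e, 4)
    if r:
        k += 1
    # abs = f * 16**k with 1/16 <= f < 1
    frac = int(round(m * 2.0 ** (e - 4 * k + 56)))
    if frac >= 1 << 56:  # rounding carried over
        frac >>= 4
        k += 1
    exponent = k + 64
    if exponent > 127:
        raise ValidationError(f"value {value!r} overflows IBM float range")
    if exponent < 0:
        return b"\x00" * 8  # underflow to zero
    return bytes([sign | exponent]) + frac.to_bytes(7, "big")


def ibm_to_ieee(raw: bytes) -> float | None:
    """Decode 2–8 IBM-float bytes; SAS missing values decode to ``None``."""
    b = bytes(raw)
    if len(b) < 8:
        b = b + b"\x00" * (8 - len(b))
    if b == b"\x00" * 8:
        return 0.0
    first, rest = b[0], b[1:]
    if rest == b"\x00" * 7 and (first in (0x2E, 0x5F) or 0x41 <= first <= 0x5A):
        return None  # '.', '_' and '.A'-'.Z' missing codes
    sign = -1.0 if first & 0x80 else 1.0
    exponent = (first & 0x7F) - 64
    frac = int.from_bytes(rest, "big")
    return sign * frac * 2.0 ** (4 * exponent - 56)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_xpt(path) -> DomainTable:
    """Read the first dataset of an XPT v5 library into a :class:`DomainTable`.

    Records come back in file order; numeric missings become ``None``;
    character values are right-trimmed of padding (spaces/NULs) only.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 240 or len(data) % 80 != 0:
        raise XptFormatError(
            f"{path}: not an XPT library (size {len(data)} not a multiple of 80)",
            offset=0,
        )
    if any(m in data[:80] for m in _V8_MARKERS):
        raise UnsupportedFormatError(
            f"{path}: XPT v8/v9 transport is not supported; SEND uses v5", offset=0
        )
    if data[:80] != _LIB_HEADER:
        raise XptFormatError(f"{path}: bad library header", offset=0)

    # records 1-2: library descriptor + modified stamp (not validated further)
    pos = 240
    if pos >= len(data) or not data[pos : pos + 48] == _MEMBER_HEADER[:48]:
        raise EmptyLibraryError(f"{path}: library contains no datasets", offset=pos)
    if data[pos : pos + 80] != _MEMBER_HEADER:
        raise XptFormatError(f"{path}: bad member header", offset=pos)
    pos += 80
    if data[pos : pos + 80] != _DSCRPTR_HEADER:
        raise XptFormatError(f"{path}: bad member descriptor header", offset=pos)
    pos += 80
    member = data[pos : pos + 80]
    dsname = member[8:16].decode("latin-1").strip()
    pos += 160  # member data record + modified-date record
    nam_hdr = data[pos : pos + 80]
    if not nam_hdr.startswith(_NAMESTR_PREFIX):
        raise XptFormatError(f"{path}: bad NAMESTR header", offset=pos)
    try:
        nvars = int(nam_hdr[54:58])
    except ValueError:
        raise XptFormatError(f"{path}: unreadable variable count", offset=pos + 54)
    pos += 80

    nsize = ((nvars * 140) + 79) // 80 * 80
    block = data[pos : pos + nsize]
    if len(block) < nvars * 140:
        raise XptFormatError(f"{path}: truncated NAMESTR block", offset=pos)
    variables: list[tuple[VariableMeta, int, int]] = []  # (meta, npos, varnum)
    non_ascii = False
    for i in range(nvars):
        fields = struct.unpack_from(_NAMESTR_FMT, block, i * 140)
        ntype, _, nlng, nvar0, nname, nlabel = fields[:6]
        npos = fields[14]
        name = nname.decode("latin-1").strip().upper()
        label = nlabel.decode("latin-1").rstrip("\x00 ")
        kind = "numeric" if ntype == 1 else "character"
        variables.append((VariableMeta(name, label, kind, nlng), npos, nvar0))
    pos += nsize

    if data[pos : pos + 80] != _OBS_HEADER:
        raise XptFormatError(f"{path}: bad OBS header", offset=pos)
    pos += 80

    variables.sort(key=lambda t: t[2])  # declaration order
    reclen = sum(v.length for v, _, _ in variables)
    body = data[pos:]
    records: list[dict] = []
    if reclen > 0:
        nobs = len(body) // reclen
        # trailing all-blank records are card-image padding, not data
        while nobs > 0 and body[(nobs - 1) * reclen : nobs * reclen].strip(b" ") == b"":
            nobs -= 1
        for r in range(nobs):
            base = r * reclen
            rec: dict = {}
            for meta, npos, _ in variables:
                raw = body[base + npos : base + npos + meta.length]
                if meta.kind == "numeric":
                    rec[meta.name] = ibm_to_ieee(raw)
                else:
                    if any(byte >= 0x80 for byte in raw):
                        non_ascii = True
                    rec[meta.name] = raw.decode("latin-1").rstrip("\x00 ")
            records.append(rec)
    if non_ascii:
        warnings.warn(
            f"{path}: non-ASCII bytes passed through unmodified", stacklevel=2
        )

    metas = [v for v, _, _ in variables]
    domain = _infer_domain(dsname, metas, records, path)
    return DomainTable(domain=domain, variables=metas, records=records,
                       source_path=str(path))


def _infer_domain(dsname: str, metas, records, path: Path) -> str:
    names = [m.name for m in metas]
    if "DOMAIN" in names:
        for rec in records:
            val = str(rec.get("DOMAIN") or "").strip()
            if val:
                return val.upper()
    if dsname:
        return dsname.upper()
    return path.stem.upper()


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("latin-1")
    if any(byte >= 0x80 for byte in b):
        warnings.warn("non-ASCII bytes written through unmodified", stacklevel=3)
    return b[:width].ljust(width, b" ")


def write_xpt(table: DomainTable, path, created: str = _DEFAULT_STAMP):
    """Write a :class:`DomainTable` to ``path`` as an XPT v5 library.

    Character lengths are auto-widened to the longest value present (cap 200);
    numeric variables are written at 8 bytes. Validation happens before any
    bytes reach disk, and ``read_xpt(write_xpt(t)) == t`` for conforming
    tables.
    """
    path = Path(path)
    var_order = table.variable_names
    widened: list[VariableMeta] = []
    for meta in table.variables:
        if meta.kind == "numeric":
            widened.append(replace(meta, length=8))
            continue
        longest = meta.length
        for rec in table.records:
            val = rec.get(meta.name)
            if val is None:
                continue
            longest = max(longest, len(str(val)))
        if longest > 200:
            raise ValidationError(
                f"{table.domain}.{meta.name}: value exceeds 200-byte transport cap"
            )
        widened.append(replace(meta, length=longest))
    for rec in table.records:
        extra = set(rec) - set(var_order)
        missing = set(var_order) - set(rec)
        if extra or missing:
            raise ValidationError(
                f"record keys do not match declared variables "
                f"(extra={sorted(extra)}, missing={sorted(missing)})"
            )

    out = bytearray()
    out += _LIB_HEADER
    out += (
        _pad("SAS", 8) + _pad("SAS", 8) + _pad("SASLIB", 8)
        + _pad("9.4", 8) + _pad("Linux", 8) + b" " * 24 + _pad(created, 16)
    )
    out += _pad(created, 16) + b" " * 64
    out += _MEMBER_HEADER
    out += _DSCRPTR_HEADER
    dsname = (table.domain or "DATA")[:8].upper()
    out += (
        _pad("SAS", 8) + _pad(dsname, 8) + _pad("SASDATA", 8)
        + _pad("9.4", 8) + _pad("Linux", 8) + b" " * 24 + _pad(created, 16)
    )
    out += _pad(created, 16) + b" " * 16 + _pad(f"{table.domain} domain", 40) + b" " * 8
    out += _NAMESTR_PREFIX + f"{len(widened):04d}".encode() + b"0" * 20 + b"  "

    npos = 0
    namestrs = bytearray()
    for i, meta in enumerate(widened):
        namestrs += struct.pack(
            _NAMESTR_FMT,
            1 if meta.kind == "numeric" else 2,
            0,
            meta.length,
            i + 1,
            _pad(meta.name, 8),
            _pad(meta.label, 40),
            b" " * 8, 0, 0, 0, b"  ", b" " * 8, 0, 0,
            npos,
            b" " * 52,
        )
        npos += meta.length
    if len(namestrs) % 80:
        namestrs += b" " * (80 - len(namestrs) % 80)
    out += namestrs
    out += _OBS_HEADER

    for rec in table.records:
        for meta in widened:
            val = rec.get(meta.name)
            if meta.kind == "numeric":
                if isinstance(val, str):
                    val = float(val) if val.strip() else None
                out += ieee_to_ibm(val)
            else:
                out += _pad("" if val is None else str(val), meta.length)
    if len(out) % 80:
        out += b" " * (80 - len(out) % 80)

    path.write_bytes(bytes(out))
    return path


# ---------------------------------------------------------------------------
# Study folders
# ---------------------------------------------------------------------------

def read_study_folder(folder) -> StudyBundle:
    """Read every ``*.xpt`` in ``folder`` into one :class:`StudyBundle`.

    Domain codes come from the DOMAIN variable when present, else the
    uppercased filename stem; split files sharing a domain code are
    concatenated in filename order. STUDYID is resolved from DM, else TS, and
    checked for consistency across all domains that carry it.
    """
    folder = Path(folder)
    files = sorted(
        (p for p in folder.iterdir() if p.is_file() and p.suffix.lower() == ".xpt"),
        key=lambda p: p.name.lower(),
    )
    if not files:
        raise EmptyStudyError(f"{folder}: no XPT files found")

    domains: dict[str, DomainTable] = {}
    for f in files:
        table = read_xpt(f)
        code = table.domain
        if code in domains:  # split dataset (e.g. lb1/lb2): concatenate
            prev = domains[code]
            if prev.variable_names != table.variable_names:
                raise StudyConsistencyError(
                    f"{folder}: split domain {code} has inconsistent variables"
                )
            merged_vars = [
                replace(a, length=max(a.length, b.length))
                for a, b in zip(prev.variables, table.variables)
            ]
            domains[code] = DomainTable(
                domain=code,
                variables=merged_vars,
                records=prev.records + table.records,
                source_path=f"{prev.source_path};{table.source_path}",
            )
        else:
            domains[code] = table

    ids: dict[str, str] = {}
    for code, table in domains.items():
        if "STUDYID" not in table.variable_names:
            continue
        vals = {str(r.get("STUDYID") or "").strip() for r in table.records}
        vals.discard("")
        if len(vals) > 1:
            raise StudyConsistencyError(
                f"{folder}: domain {code} carries multiple STUDYID values {sorted(vals)}"
            )
        if vals:
            ids[code] = vals.pop()
    if len(set(ids.values())) > 1:
        offenders = ", ".join(f"{k}={v}" for k, v in sorted(ids.items()))
        raise StudyConsistencyError(f"{folder}: conflicting STUDYID values: {offenders}")

    studyid = ids.get("DM") or ids.get("TS") or next(iter(ids.values()), "")
    return StudyBundle(studyid=studyid, folder=str(folder), domains=domains)
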