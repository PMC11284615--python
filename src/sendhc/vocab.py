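"""Controlled-terminology harmonization: CT files -> JSON vocabulary -> cleaned XPT.

SEND submissions from different labs spell the same concept differently
("SD" vs "SPRAGUE-DAWLEY"; "ALVEOLAR MACROPHAGES, INCREASED" folded into
"CELLULARITY, INCREASED" for a cross-cell-type analysis). Cross-study
statistics are only meaningful after such synonyms collapse onto one
preferred submission value per codelist. This module builds a synonym ->
preferred-term vocabulary from tab-delimited controlled-terminology (CT)
files, persists it as JSON, and rewrites SEND XPT files with the bound
variables harmonized.

Matching is exact after uppercasing and trimming — deliberately no fuzzy
matching, so every substitution is auditable. Preferred values always map to
themselves, which makes cleaning idempotent. Values with no mapping are
passed through verbatim and tallied as unmapped.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import xpt
from .errors import SendhcError, VocabError

logger = logging.getLogger(__name__)

#: The ten supported codelists (canonical keys, lowercase).
CODELIST_KEYS = (
    "sex",
    "strain/substrain",
    "species",
    "send severity",
    "route of administration response",
    "standardized disposition term",
    "specimen",
    "anatomical location",
    "non-neoplastic finding type",
    "send control type",
)

#: (domain, variable) -> codelist key, for plain columns.
COLUMN_BINDINGS: dict[tuple[str, str], str] = {
    ("DM", "SEX"): "sex",
    ("DM", "STRAIN"): "strain/substrain",
    ("DM", "SPECIES"): "species",
    ("MI", "MISPEC"): "specimen",
    ("MI", "MIANTREG"): "anatomical location",
    ("MI", "MISTRESC"): "non-neoplastic finding type",
    ("MI", "MISEV"): "send severity",
    ("EX", "EXROUTE"): "route of administration response",
    ("DS", "DSDECOD"): "standardized disposition term",
    ("LB", "LBSPEC"): "specimen",
}

#: (domain, PARMCD) -> codelist key, applied to the value column of
#: parameter-shaped domains (TX.TXVAL, TS.TSVAL).
PARAM_BINDINGS: dict[tuple[str, str], str] = {
    ("TX", "TCNTRL"): "send control type",
    ("TX", "SPECIES"): "species",
    ("TX", "STRAIN"): "strain/substrain",
    ("TS", "SPECIES"): "species",
    ("TS", "STRAIN"): "strain/substrain",
    ("TS", "ROUTE"): "route of administration response",
    ("TS", "TCNTRL"): "send control type",
}

# Tolerant header aliases for published CDISC CT exports.
_HEADER_ALIASES = {
    "codelist name": "codelist",
    "codelist": "codelist",
    "cdisc submission value": "submission",
    "submission value": "submission",
    "cdisc synonym(s)": "synonyms",
    "synonyms": "synonyms",
    "codelist extensible": "extensible",
    "extensible": "extensible",
    "extensible flag": "extensible",
}


def _norm(value) -> str:
    return str(value or "").strip().upper()


@dataclass
class VocabMap:
    """codelist key -> (uppercased trimmed synonym -> preferred value)."""

    codelists: dict[str, dict[str, str]] = field(default_factory=dict)
    extensible: dict[str, bool] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def lookup_key(self, codelist_key: str) -> str:
        key = str(codelist_key).strip().lower()
        if key not in CODELIST_KEYS:
            raise VocabError(f"unknown codelist {codelist_key!r}")
        return key

    def apply(self, value: str, codelist_key: str) -> tuple[str, bool]:
        """Map ``value`` through a codelist; miss returns it unchanged."""
        key = self.lookup_key(codelist_key)
        norm = _norm(value)
        if not norm:
            return value or "", False
        table = self.codelists.get(key, {})
        if norm in table:
            return table[norm], True
        return value, False

    def to_json(self, path) -> Path:
        path = Path(path)
        payload: dict = {
            key: dict(sorted(self.codelists[key].items()))
            for key in sorted(self.codelists)
        }
        payload["_meta"] = {
            "provenance": self.provenance,
            "extensible": {k: self.extensible.get(k, True) for k in sorted(self.codelists)},
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n",
                        encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path) -> "VocabMap":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        meta = data.pop("_meta", {})
        return cls(
            codelists={k: dict(v) for k, v in data.items()},
            extensible=dict(meta.get("extensible", {})),
            provenance=list(meta.get("provenance", [])),
        )


def apply_map(value: str, codelist_key: str, vocab: VocabMap) -> tuple[str, bool]:
    """Functional form of :meth:`VocabMap.apply`."""
    return vocab.apply(value, codelist_key)


def _read_ct_file(path: Path):
    """Yield (codelist_key, preferred, synonyms, extensible) rows; None key => unknown."""
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return
        cols: dict[str, int] = {}
        for i, h in enumerate(header):
            alias = _HEADER_ALIASES.get(h.strip().lower())
            if alias and alias not in cols:
                cols[alias] = i
        for needed in ("codelist", "submission"):
            if needed not in cols:
                raise VocabError(
                    f"{path}: CT file lacks a recognizable '{needed}' column"
                )
        for row in reader:
            if not any(cell.strip() for cell in row):
                continue

            def cell(name, default=""):
                i = cols.get(name)
                return row[i] if i is not None and i < len(row) else default

            raw_key = cell("codelist").strip().lower()
            key = raw_key if raw_key in CODELIST_KEYS else None
            preferred = _norm(cell("submission"))
            synonyms = [
                _norm(s) for s in cell("synonyms").split(";") if _norm(s)
            ]
            ext = _norm(cell("extensible", "YES")) in ("YES", "Y", "TRUE", "1", "")
            yield key, raw_key, preferred, synonyms, ext


def gen_vocab(ct_files, extra_files=(), json_out=None) -> VocabMap:
    """Build a :class:`VocabMap` from tab-delimited CT files.

    ``extra_files`` (user extensible-term mappings, same format) merge after
    the CT files and override on conflict with a logged warning; a synonym
    mapped to two different preferred terms *within* one tier is a hard error.
    When ``json_out`` is given the vocabulary is also written there.
    """
    vocab = VocabMap()
    for tier, paths in (("ct", ct_files), ("extra", extra_files)):
        for path in paths:
            path = Path(path)
            vocab.provenance.append(path.name)
            for key, raw_key, preferred, synonyms, ext in _read_ct_file(path):
                if key is None:
                    warnings.warn(
                        f"{path.name}: unknown codelist {raw_key!r} skipped",
                        stacklevel=2,
                    )
                    continue
                if not preferred:
                    continue
                table = vocab.codelists.setdefault(key, {})
                vocab.extensible.setdefault(key, ext)
                for syn in [preferred, *synonyms]:
                    existing = table.get(syn)
                    if existing is not None and existing != preferred:
                        if tier == "extra":
                            logger.warning(
                                "%s: %s: synonym %r remapped %r -> %r by extra file",
                                path.name, key, syn, existing, preferred,
                            )
                        else:
                            raise VocabError(
                                f"{path.name}: codelist {key!r}: synonym {syn!r} maps to "
                                f"both {existing!r} and {preferred!r}"
                            )
                    table[syn] = preferred
    # every preferred value maps to itself
    for table in vocab.codelists.values():
        for preferred in list(table.values()):
            table.setdefault(preferred, preferred)
    if json_out is not None:
        vocab.to_json(json_out)
    return vocab


@dataclass
class CleanEntry:
    file: str
    variable: str
    original: str
    mapped: str
    count: int


@dataclass
class CleanReport:
    """Audit trail of a standardize_file run: one entry per changed value."""

    entries: list[CleanEntry] = field(default_factory=list)
    unmapped: dict[str, int] = field(default_factory=dict)   # per-file tallies
    failed: list[str] = field(default_factory=list)

    def total_changed(self, file: str | None = None) -> int:
        return sum(
            e.count for e in self.entries if file is None or e.file == file
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(e.file, e.variable, e.original, e.mapped, e.count) for e in self.entries],
            columns=["FILE", "VARIABLE", "ORIGINAL", "MAPPED", "COUNT"],
        )

    def write_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, lineterminator="\r\n")
        return path


def _bindings_for(domain: str, bindings) -> dict[str, str]:
    cols = {}
    for (dom, var), key in (bindings or COLUMN_BINDINGS).items():
        if dom == domain.upper():
            cols[var] = key
    return cols


def standardize_file(in_dir, out_dir, vocab, bindings=None,
                     param_bindings=None) -> CleanReport:
    """Rewrite every XPT in ``in_dir`` to ``out_dir`` with harmonized terms.

    Bound variables are looked up uppercased/trimmed; hits are replaced by the
    preferred submission value, misses preserved verbatim and tallied.
    Unbound variables round-trip byte-identically. Study subfolders are
    mirrored (a hierarchy root cleans in one call). A CleanReport CSV is
    written beside the outputs. Refuses ``out_dir == in_dir``.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    if in_dir.resolve() == out_dir.resolve():
        raise SendhcError("refusing to clean in place: out_dir must differ from in_dir")
    if isinstance(vocab, (str, Path)):
        vocab = VocabMap.from_json(vocab)
    out_dir.mkdir(parents=True, exist_ok=True)
    if param_bindings is None:
        param_bindings = PARAM_BINDINGS

    report = CleanReport()
    changes: dict[tuple[str, str, str, str], int] = {}
    files = sorted(
        (p for p in in_dir.rglob("*") if p.is_file() and p.suffix.lower() == ".xpt"),
        key=lambda p: str(p.relative_to(in_dir)).lower(),
    )
    for path in files:
        rel = path.relative_to(in_dir)
        relname = str(rel.parent / rel.name.lower()) if rel.parent != Path(".") \
            else rel.name.lower()
        try:
            table = xpt.read_xpt(path)
        except SendhcError as exc:
            logger.warning("skipping unreadable %s: %s", path.name, exc)
            report.failed.append(relname)
            continue
        domain = table.domain
        col_map = _bindings_for(domain, bindings)
        parm_col, val_col = f"{domain}PARMCD", f"{domain}VAL"
        has_params = (
            parm_col in table.variable_names and val_col in table.variable_names
        )
        unmapped = 0
        for rec in table.records:
            for var, key in col_map.items():
                if var not in rec:
                    continue
                original = rec[var]
                mapped, hit = vocab.apply(original, key)
                if hit and mapped != original:
                    rec[var] = mapped
                    changes[(relname, var, str(original), mapped)] = (
                        changes.get((relname, var, str(original), mapped), 0) + 1
                    )
                elif not hit and _norm(original):
                    unmapped += 1
            if has_params:
                parmcd = _norm(rec.get(parm_col))
                key = param_bindings.get((domain, parmcd))
                if key:
                    original = rec[val_col]
                    mapped, hit = vocab.apply(original, key)
                    if hit and mapped != original:
                        rec[val_col] = mapped
                        changes[(relname, val_col, str(original), mapped)] = (
                            changes.get((relname, val_col, str(original), mapped), 0)
                            + 1
                        )
                    elif not hit and _norm(original):
                        unmapped += 1
        report.unmapped[relname] = unmapped
        dest = out_dir / relname
        dest.parent.mkdir(parents=True, exist_ok=True)
        xpt.write_xpt(table, dest)

    report.entries = [
        CleanEntry(f, v, o, m, c) for (f, v, o, m), c in sorted(changes.items())
    ]
    report.write_csv(out_dir / "clean_report.csv")
    return report
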