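"""Packaged SEND domain manifest: which tables the database schema carries.

The manifest is a versioned tab-delimited resource listing, for each SEND
domain the package models (SEND IG 3.1 variable subset), the variable order,
kind and label. Domains found in study folders but absent from the manifest
are still imported (db layer creates tables dynamically); the manifest just
fixes the guaranteed baseline schema.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

MANIFEST_VERSION = "SEND-IG-3.1/sendhc-1"

#: Domains whose records are per-subject (carry USUBJID).
SUBJECT_LEVEL = frozenset(
    {"DM", "EX", "DS", "SE", "BW", "LB", "MI", "CO", "SUPPQUAL"}
)


@lru_cache(maxsize=1)
def load_manifest() -> dict[str, list[tuple[str, str, str]]]:
    """Return ``{domain: [(variable, kind, label), ...]}`` in declared order."""
    text = (
        resources.files("sendhc.resources")
        .joinpath("send_ig_manifest.tsv")
        .read_text(encoding="utf-8")
    )
    out: dict[str, list[tuple[str, str, str]]] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        out.setdefault(row["domain"], []).append(
            (row["variable"], row["kind"], row["label"])
        )
    return out


def manifest_domains() -> list[str]:
    return list(load_manifest())


def storage_table(domain: str) -> str:
    """Map a file-level domain code to its database table (SUPP-- pools)."""
    d = domain.upper()
    if d.startswith("SUPP"):
        return "SUPPQUAL"
    return d
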