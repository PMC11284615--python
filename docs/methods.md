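# Methods

This note records the conventions, derivations and design choices behind
`sendhc`, in the spirit of a statistical-software methods appendix. Nothing
here states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Transport v5 I/O

SEND domains travel as SAS Transport (XPORT) v5 libraries: a sequence of
80-byte card-image records — library header, member headers, 140-byte
NAMESTR variable descriptors, then fixed-length observations with numeric
values in IBM System/360 hexadecimal floating point (sign bit, 7-bit base-16
exponent biased by 64, 56-bit fraction).

* **Float codec.** IEEE→IBM→IEEE is exact for every finite double whose
  base-16 exponent fits the IBM range (|x| ≳ 16⁻⁶⁵): the 56-bit IBM fraction
  absorbs the 53-bit IEEE significand plus at most three normalisation bits,
  so no rounding occurs in either direction. Magnitudes below the IBM range
  underflow to zero; infinities are rejected. SAS missing values (`.`, `._`,
  `.A`–`.Z`) map to `None`.
* **Character data.** ASCII in/out; bytes ≥ 0x80 pass through unmodified
  with a warning (the format predates Unicode). Reading right-trims padding
  (spaces and NULs) only. Character lengths are auto-widened on write to the
  longest value present, capped at the format's 200-byte limit.
* **Version policy.** v5 only, the FDA submission container; v8/v9 input
  raises an explicit unsupported-format error.
* **A format ambiguity, documented.** The v5 format stores no observation
  count; files are padded to a multiple of 80 bytes with blanks. A trailing
  record whose fields are *all* blank in a character-only dataset is
  therefore indistinguishable from padding, and the reader drops it (the
  behaviour of SAS itself). Tables containing any numeric variable are
  immune: a valid numeric field is never all blanks. Every table the
  synthetic generator emits carries numeric fields.
* **Determinism.** The writer stamps a fixed header timestamp by default
  instead of wall-clock time, so identical tables produce byte-identical
  files. This is what makes the generator's same-seed ⇒ same-bytes guarantee
  possible; callers who want real timestamps pass `created=`.
* **Folders.** Domain codes resolve from the DOMAIN variable first, falling
  back to the uppercased filename stem (filename casing is unreliable across
  sponsors). Split datasets (`lb1.xpt`, `lb2.xpt`) sharing a domain code are
  concatenated in filename order. Supplemental qualifiers (`supp--.xpt`) are
  read and stored into a pooled SUPPQUAL table but not queried.

## 2. Database

One SQLite table per domain in the packaged manifest (a SEND IG 3.1 variable
subset covering TS, TA, TE, TX, DM, EX, DS, SE, BW, LB, MI, CO and
SUPPQUAL; the manifest version is recorded in a metadata table). Loading is
verbatim: character → TEXT, numeric → REAL, dates kept as ISO 8601 text
exactly as submitted; all interpretation is deferred to the query layer.
Variables not in the manifest are added dynamically as columns rather than
dropped, so the verbatim-load property holds for sponsor extensions; unknown
domains get tables of their own.

Imports are per-study transactions (a study lands complete or not at all);
batch imports continue past failing folders and return a per-folder report.
Re-import requires an explicit `replace=True` — refusing silent overwrite is
the safer default. Indexes: STUDYID on every domain table, (STUDYID,
USUBJID) on subject-level domains; indexing never changes query results and
re-running is a no-op. Every import/delete is appended with a timestamp to a
plain-text log beside the database file.

## 3. The filter chain

Filters are composable and share fixed conventions:

* null criteria are the identity (derived columns still populated);
* comparisons are case-insensitive and applied after controlled-terminology
  mapping when a vocabulary is supplied (so `"SD"` matches
  `"SPRAGUE-DAWLEY"` through the strain codelist), raw case-insensitive
  otherwise;
* rows whose deciding value is missing are *uncertain*: dropped by default,
  kept with a short message (`"SDESIGN missing"`, `"TCNTRL missing"`, …)
  when `incl_uncertain=True`; messages from successive filters concatenate
  with `"; "`;
* with `incl_uncertain=False`, every filter's output is a subset of its
  input and the subject-level filters commute (a tested invariant).

**Study filters.** Design compares against the TS parameter SDESIGN. Date
filtering uses *interval semantics for partial ISO 8601 dates*: a study
dated `2017-06` denotes the interval [2017-06-01, 2017-06-30] and matches a
query window iff the intervals overlap; query bounds may themselves be
partial (`from=2017` means 2017-01-01). This avoids silently dropping
month-precision studies.

**Control identification.** Trial sets are classified from the TX parameter
TCNTRL: after optional codelist mapping and uppercasing, a value containing
any of VEHICLE, PLACEBO, SHAM, UNTREATED, NO TREATMENT, NEGATIVE — and not
containing POSITIVE — is a negative control. Explicit positives are always
excluded; sets with missing or unrecognized TCNTRL are uncertain. Because
treated sets in real SEND data simply lack TCNTRL, `incl_uncertain=True`
deliberately includes them (flagged); the default excludes them. Subjects
are DM rows joined on SETCD, with the set's TCNTRL carried onto each row.

**Attribute resolution precedence.** Species/strain: DM value → TX set
parameter → TS parameter. Route: any EX.EXROUTE record for the subject → TS
ROUTE parameter. EX is preferred over TS because the dosing record is the
per-animal observation while TS is a study-level declaration.

## 4. Age derivation

`derive_age_days` returns whole days at the time of a finding, using the
first applicable rule:

1. finding `--DTC` and BRTHDTC both present (full dates): calendar-day
   difference;
2. BRTHDTC and RFSTDTC present: `(RFSTDTC − BRTHDTC)` + day offset, where
   the offset from `--DY` is `DY − 1` for `DY ≥ 1` and `DY` for `DY < 0`
   (SEND has no day 0; a `--DY` of 0 raises an error). A missing `--DY`
   contributes offset 0, i.e. age at the reference start;
3. DM.AGE/AGEU converted to days (DAYS ×1, WEEKS ×7, MONTHS ×30.4375,
   YEARS ×365.25 — mean Gregorian month and year — rounded to the nearest
   integer) + the same day offset;
4. otherwise null.

Negative computed ages (data errors) return null rather than violating the
AGEDAYS ≥ 0 contract. The age window filter is inclusive on both ends; a
boundary animal therefore satisfies two adjacent windows, and analyses using
contiguous windows should choose boundaries between attained ages.

## 5. Phase assignment

A finding's epoch is the subject's SE row with `SESTDTC ≤ --DTC < SEENDTC`
(half-open, so epoch boundaries are unambiguous; a null SEENDTC on the last
epoch extends to infinity). Without a `--DTC`, the `--DY` is compared
against epoch study-day bounds derived from RFSTDTC. Epoch labels classify
by ordered keyword rules — screening keywords (screen, pre-treat, pretreat,
acclimat, baseline) are tested before recovery (recovery, post-treat,
posttreat, washout) before treatment (treat, dos, exposure) — so
"PRETREATMENT" classifies as Screening, not Treatment. Findings with no
usable SE data are Uncertain.

## 6. Aggregation

**Incidence.** Per specimen, the denominator is the number of *distinct*
animals with at least one examination record for that specimen whose status
is not NOT DONE; the numerator per (specimen, finding) is the distinct
animals with a matching record, so duplicate records never double-count.
This "affected / examined" rule is the pathology convention and reduces to
"affected / all selected" when every animal was examined. Percentages are
rounded **half-up** at two decimals (computed in exact decimal arithmetic,
not binary floating point): on the worked-example fractions this yields
6/873 → 0.69, 21/873 → 2.41, 56/873 → 6.41, 24/873 → 2.75. Severity
grouping is off by default; when on, rows are additionally keyed by MISEV
with unharmonized severities passed through.

**Reference ranges.** Grouping key (testcd, specimen, units[, sex]); mean is
the arithmetic mean and SD the sample standard deviation (n − 1), null for
singleton groups. Mixed units split groups, never pool. Rows without a
numeric `--STRESN` are excluded and tallied in `attrs["n_excluded"]`.

Exports are RFC 4180 CSV (CRLF, header row, UTF-8), percent columns with two
decimals. RDS output is out of scope (R-specific serialization).

## 7. Terminology harmonization

`gen_vocab` reads tab-delimited CT files (tolerant of the published CDISC CT
export headers: "CDISC Submission Value", "CDISC Synonym(s)", "Codelist
Extensible") into per-codelist maps of uppercased/trimmed synonym →
preferred submission value, for ten codelists: sex, strain/substrain,
species, SEND severity, route of administration response, standardized
disposition term, specimen, anatomical location, non-neoplastic finding
type, SEND control type. Identity rows (preferred → itself) are always
present, which is what makes cleaning idempotent. Extra files (user
extensible-term mappings) merge after CT files and override on conflict with
a logged warning; a synonym mapped to two preferred terms within one tier is
a hard error — user mappings are intentional, silent ambiguity is not.

The JSON layout is a top-level object keyed by codelist, flat synonym →
preferred objects, with a `_meta` object for provenance and extensible
flags; keys are sorted for diffability.

`standardize_file` rewrites every XPT under the input directory (study
subtrees mirrored) to the output directory: bound variables — e.g. DM.SEX →
sex, MI.MISPEC → specimen, MI.MISTRESC → non-neoplastic finding type,
EX.EXROUTE → route, DS.DSDECOD → disposition, and the parameter-shaped
bindings TX.TXVAL where TXPARMCD = TCNTRL → SEND control type (plus TS
SPECIES/STRAIN/ROUTE) — are looked up uppercased/trimmed; hits are replaced
by the preferred value, misses preserved *verbatim* (no case change) and
tallied as unmapped. Unbound variables round-trip unchanged. Matching is
exact by design: harmonization must be auditable, so no fuzzy matching. The
variable→codelist bindings and the JSON schema are implementation-defined
and fixed here. In-place cleaning is refused. A CleanReport (file, variable,
original, mapped, count — entries only where original ≠ mapped) is written
beside the outputs as CSV.

## 8. The synthetic generator

Real SEND submissions are confidential, so the package carries a generator
whose defaults describe a plausible repeat-dose rat study: four trial sets
(vehicle control + three dose groups, 10 animals each, balanced sexes), a
screening/treatment/recovery epoch structure (days −14/1/29, recovery
open-ended), oral gavage dosing to day 28, eight weekly body weights,
clinical chemistry drawn from stated normals (ALT ~ N(50, 5) U/L by
default), terminal microscopic findings on day 28 in two specimens with
planted per-finding counts, ages at day 1 uniform on 60–240 days, and one
control animal's first-specimen exam marked NOT DONE to exercise the
denominator rule. The default three-study root varies start dates
(2016/2018/2021) and designs, omits TCNTRL in one study and SE in another,
and keeps species/strain only in TS in a third, so the uncertain and
fallback code paths are exercised by construction.

The harmonization cohort fixture realizes the worked example exactly: 873
control animals across three studies, each examined in lung/bronchus and
spleen, with 6 + 48 + 2 lung findings and 21 + 3 spleen findings on
distinct animals (one record per affected animal). The seed permutes which
animals are affected; counts are invariant.

Every planted quantity is serialized as a GroundTruth JSON beside the study
folder, and generation is byte-deterministic per seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: correlated pathology across organs, dose–response
structure, body-weight growth curves beyond a linear drift, unscheduled
deaths, partial or malformed dates, multi-record dosing schedules, and the
long tail of sponsor-specific terminology. The harmonization and query logic
is exercised against clean, well-formed inputs plus targeted corruptions;
robustness to arbitrarily malformed submissions is not claimed.

## 9. Problem sizes and numerics

The test suite runs the transport round-trip on 100 randomized tables, the
filter-chain planted-truth recovery and the incidence brute-force comparison
over 20 seeded studies (40 animals each), the age oracle on 1000 random
date/day combinations, and the full 873-animal harmonization pipeline; the
whole suite completes in a few seconds on one CPU. Reference-range recovery
is asserted within 3σ/√n of the planted mean under fixed seeds. All
percentage arithmetic goes through `decimal` with explicit half-up
quantization; equality assertions on round-tripped floats are exact, not
approximate, because the codec is exact.

## 10. Design choices where the design was open

* CLI instead of a web dashboard: the query surface is scripted/batch by
  nature here; a `demo` subcommand builds the synthetic root and database in
  one step as the zero-download quickstart.
* Negative-control patterns are a fixed list mirroring the control-type
  codelist split into negative/positive, configurable through the
  vocabulary rather than code.
* The SQLite backend is the only one supported; concurrent multi-writer
  access and schema migration between manifest versions are non-goals.
* Treated-group extraction, dose–response queries, TK/PC domains, XPT
  v8/v9, Dataset-JSON and define.xml parsing are out of scope.
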