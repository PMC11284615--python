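# sendhc

Historical-control extraction and terminology harmonization for CDISC SEND
toxicology studies.

## The problem

Nonclinical toxicology studies are exchanged in the CDISC SEND standard: one
study is a folder of SAS Transport v5 (XPT) files, one per *domain* — trial
summary (TS), trial sets (TX), demographics (DM), exposure (EX), disposition
(DS), subject elements (SE), body weights (BW), laboratory results (LB),
microscopic findings (MI). When a study turns up an ambiguous finding (say,
liver necrosis in 1/10 high-dose rats), the key contextual statistic is the
**background incidence rate**: how often the same finding occurs in control
animals of matched species, strain, sex, age and dose route, pooled across
many past studies.

Computing that statistic across submissions is hard for two reasons. First,
the control animals have to be found and matched: which trial sets are
negative controls, what was each animal's age at the time of the finding,
which study phase (screening/treatment/recovery) was it observed in. Second,
different labs spell the same concept differently — the same pathology
finding may be recorded under several synonymous terms — so counts computed
on raw data are wrong until the terminology is harmonized onto a single
preferred controlled-terminology (CT) value per codelist.

`sendhc` addresses both. It is aimed at toxicologists and study data
scientists who hold a collection of SEND study folders and want reproducible
pooled control statistics.

## What it does

* **`sendhc.xpt`** — bit-faithful reading and writing of XPT v5 (80-byte
  records, IBM hexadecimal floating point), plus study-folder discovery.
* **`sendhc.db`** — an SQLite database with one table per SEND domain,
  loaded *verbatim* (no transformation at load time), with study-granular
  transactional import/delete and indexing.
* **`sendhc.query`** — a composable filter chain: study design and start
  date (TS), negative-control trial sets (TX `TCNTRL`), sex, species/strain
  and route (DM with TX/TS/EX fallbacks), then per-finding derived **age in
  days** and **study phase** from SE epochs.
* **`sendhc.aggregate`** — background incidence per (specimen, finding),

      incidence% = 100 · n_affected / n_examined,

  with distinct-animal counting and an examined-animals denominator
  (records whose status is NOT DONE are excluded), rounded half-up at two
  decimals; and reference ranges (n, mean, sample SD) for LB/BW results per
  test and unit.
* **`sendhc.vocab`** — the harmonization pipeline: tab-delimited CT files →
  JSON vocabulary (uppercased/trimmed synonym → preferred submission value,
  ten supported codelists) → cleaned XPT files with an audit report.
  Matching is exact, never fuzzy; cleaning is idempotent.
* **`sendhc.fixtures`** — deterministic synthetic study bundles with planted
  ground truth (control ids, ages, phases, finding counts, lab-test normal
  parameters), since real submissions are confidential.
* **`sendhc` CLI** — `db create/import/index/delete/status`, `clean`,
  `query`, `report`, `demo`.

## Worked example

The harmonization cohort: 873 control animals over three studies, each
examined in lung/bronchus and spleen. Before cleaning, `CELLULARITY,
INCREASED` appears on 6 lung records and 21 spleen records, but 48 lung
records say `ALVEOLAR MACROPHAGES, INCREASED`, 2 say `AGGREGATE`, and 3
spleen records say `FOLLICLES, INCREASED` — synonyms that the vocabulary
folds onto `CELLULARITY, INCREASED`.

```python
from pathlib import Path
import tempfile

from sendhc import aggregate, db, fixtures, query, vocab

work = Path(tempfile.mkdtemp())

# 1. generate the 873-animal control cohort and the CT file
raw, truth = fixtures.make_usecase2_fixture(work / "raw", seed=0)
ct = fixtures.make_ct_fixture(work / "ct.tsv")

# 2. build the vocabulary and clean the transport files
vmap = vocab.gen_vocab([ct], json_out=work / "vocabulary.json")
report = vocab.standardize_file(work / "raw", work / "clean", vmap)
print(f"{report.total_changed()} values harmonized")

# 3. load the cleaned studies and extract control MI findings
handle = db.init_environment(work / "hc.sqlite", create=True)
db.create_schema(handle)
db.import_studies(handle, work / "clean")
studies = query.get_studies_sdesign(handle)          # no design filter
controls = query.get_control_subj(handle, studies)   # vehicle-control animals
findings = query.get_subj_data(handle, controls, "MI")

# 4. background incidence per specimen
table = aggregate.incidence_table(findings, controls)
print(table[table.FINDING == "CELLULARITY, INCREASED"].to_string(index=False))
db.disconnect(handle)
```

Output:

```
53 values harmonized
     SPECIMEN                FINDING  N_AFFECTED  N_EXAMINED  INCIDENCE_PCT
LUNG/BRONCHUS CELLULARITY, INCREASED          56         873           6.41
       SPLEEN CELLULARITY, INCREASED          24         873           2.75
```

The 53 harmonized values are the 48 + 2 lung records and 3 spleen records
whose finding term changed. On the *raw* data the same query reports 6/873
(0.69%) for lung/bronchus and 21/873 (2.41%) for spleen — harmonization
flips which tissue has the higher background rate, which is exactly why it
matters.

The same pipeline from a shell:

```sh
sendhc demo --db hc.sqlite --dir studies/          # synthetic quickstart
sendhc clean --in studies/ --out cleaned/ --ct ct.tsv
sendhc report incidence --db hc.sqlite --species RAT --route "ORAL GAVAGE" \
    --min-age-days 60 --max-age-days 120 --out incidence.csv
```

## Documentation

`docs/methods.md` describes the models and conventions in detail: the
filter-chain semantics, age and phase derivation rules, incidence
denominator, rounding, the transport-format edge cases, and what the
synthetic generator does and does not emulate.
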