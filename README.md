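# noticelink

Entity resolution of medical-device safety notices against a device
registry, with hierarchical nomenclature (EMDN/CND-style) code assignment,
linkage-quality validation, surveillance aggregation and a synthetic-data
generator so every stage runs offline.

Safety notices scraped from vigilance websites are often incomplete: only a
minority carry the device directory identifier that would let the notice be
joined to the national device registry directly. `noticelink` resolves the
rest in two phases:

1. **Manufacturer blocking** — registry manufacturers similar to the
   notice's manufacturer are found either by TF-IDF cosine similarity on
   normalized, legal-suffix-stripped names (threshold 0.90, the `cos`
   method) or by exact equality of extracted named entities (`ner`).
2. **Device matching** — within the block, the notice's device and
   commercial-name fields are compared with each candidate's commercial
   name and catalogue code using a Levenshtein-based token-set ratio
   (0–100). A descending threshold schedule (95, 90, …, 60) accepts the
   highest-scoring candidate at the first threshold any candidate clears.

A linked notice inherits the registry row's hierarchical nomenclature code
(one category letter plus up to six two-digit pairs, max seven levels), so
notices can be aggregated per category/group/type for signal surveillance.

## Layout

| Module | Purpose |
| --- | --- |
| `records_io` | Record schemas (registry rows, notices, links) and CSV I/O |
| `textprep` | Cleaning operators, tokenization, POS tagging, suffix stripping |
| `emdn` | Nomenclature code parsing and level-wise agreement depth |
| `manufacturer_match` | Phase-1 blocking (TF-IDF cosine / named entity) |
| `device_match` | Phase-2 fuzzy matching and the threshold schedule |
| `pipeline` | Orchestration (direct + ER), surveillance summaries |
| `validation` | Four-test evaluation and the mid-p McNemar comparison |
| `synthetic` | Ground-truth generator with parameterized name corruption |

## CLI

```bash
# synthetic registry + notices + ground truth
noticelink simulate --out-dir data/ --seed 7 --manufacturers 50 --notices 200

# link notices to the registry (cos or ner blocking)
noticelink resolve --devices data/dod.csv --notices data/don.csv \
    --method cos --out links.csv --summary summary.json

# evaluate on the identifier-bearing subset (identifiers hidden), with the
# mid-p McNemar comparison of the two blocking methods
noticelink validate --devices data/dod.csv --notices data/don.csv \
    --report report.json --compare

# static HTML summary of a link table
noticelink report --links links.csv --level 2 --html report.html
```

Thresholds are configurable (`--cos-threshold`, `--sth-start`, `--sth-step`,
`--sth-floor`); column names and date formats accept overrides through the
`records_io` API.

## Validation protocol

`noticelink validate` uses the notices that already carry a resolvable
directory identifier as the reference: the identifier is hidden, the notice
is re-resolved by entity resolution, and four criteria are scored —
manufacturer correctness, exact identifier correctness, nomenclature
correctness at levels 1–4, and nomenclature correctness restricted to
notices with a wrongly assigned identifier (the same physical device is
sometimes registered twice under different progressive numbers, in which
case the identifier is wrong but the code is still right).

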