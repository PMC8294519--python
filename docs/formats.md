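# File formats

All coordinates are 1-based, inclusive. A signal-peptidase cleavage site
"between residue k and k+1" is encoded as position k. Absent values are
written as `.` in TSV files.

## FASTA input

Amino-acid FASTA. Sequences are uppercased on read; a single trailing `*`
stop is stripped. Allowed alphabet: the 20 canonical residues plus `X`.
`B`, `Z` and `U` are rejected with a positional message, because the motif
scanners are defined on the canonical alphabet. Duplicate record ids and
empty files are errors.

## Normalized evidence schema

TSV with header:

```
protein_id	source	kind	start	end	score	label
```

or a JSON list of objects with the same keys (absent values `null` or
omitted). `kind` is one of `SP_SEC`, `SP_LIPO`, `SP_TAT`, `TM_HELIX`,
`SIGNATURE_HIT`, `GO_COMPARTMENT`, `SCL_VOTE`, `CLEAVAGE_SITE`. `source`
is one of:

| source | may report |
|---|---|
| `sp_predictor_a`, `sp_predictor_b` | SP_SEC, SP_LIPO, SP_TAT, CLEAVAGE_SITE |
| `phobius_like` | SP_SEC, TM_HELIX, CLEAVAGE_SITE |
| `predisi_like` | SP_SEC, CLEAVAGE_SITE |
| `lipo_predictor` | SP_LIPO, SP_SEC, CLEAVAGE_SITE |
| `tat_predictor` | SP_TAT, CLEAVAGE_SITE |
| `tm_predictor` | TM_HELIX |
| `signature_scanner` | SIGNATURE_HIT, GO_COMPARTMENT |
| `go_compartment` | GO_COMPARTMENT |
| `builtin` | SP_SEC, SP_LIPO, SP_TAT, TM_HELIX, SIGNATURE_HIT, CLEAVAGE_SITE |
| `generic_scl_predictor` | SCL_VOTE |

`label` holds a signature accession (SIGNATURE_HIT), a GO term
(GO_COMPARTMENT), a localization tag (SCL_VOTE), or a context flag such
as `possible_sp_overlap` (TM_HELIX). Spans must lie inside the sequence
when sequences are supplied.

## Predictor "short" dialects

Each dialect file starts with the mandatory header line `# <dialect>`;
further `#` lines are comments; rows are tab-separated. One canonical
example file per dialect ships under `tests/data/dialects/`. These are
fixed grammars modeled on the published short output formats of the tool
families; adapters for real, version-specific tool outputs are a separate
concern.

### `sp_short` (Sec-SP caller, default source `sp_predictor_a`)

```
name  sp(YES|NO)  score  cleavage(int|-)
```

`YES` emits `SP_SEC` span 1..cleavage plus `CLEAVAGE_SITE` at cleavage.

### `lipo_short` (lipoprotein caller, default source `lipo_predictor`)

```
name  class(SpII|SpI|TMH|CYT)  score  cleavage(int|-)
```

`SpII` emits `SP_LIPO` (cleavage before the lipidated Cys, i.e. at C-1);
`SpI` emits `SP_SEC`; `TMH`/`CYT` emit nothing.

### `tat_short` (twin-arginine caller, default source `tat_predictor`)

Same shape as `sp_short`; `YES` emits `SP_TAT` plus `CLEAVAGE_SITE`.

### `tm_short` (TM-topology caller, default source `tm_predictor`)

```
name  nhelix(int)  topology(a-b,c-d,...|-)
```

One `TM_HELIX` per span; the span count must equal `nhelix`.

### `phobius_short` (combined SP/TM caller, default source `phobius_like`)

```
name  tm(int)  sp(Y|0)  prediction
```

`sp=Y` requires a `c<k>/<k+1>` cleavage token in the prediction string and
emits `SP_SEC` 1..k plus `CLEAVAGE_SITE` at k; `tm>0` reads the helix
spans `a-b` from the prediction string.

### `signature_tsv` (domain-signature scanner, default source `signature_scanner`)

```
name  accession  start  end  score(float|.)  go_terms(GO:...|GO:...| or .)
```

Emits one `SIGNATURE_HIT` (label = accession) plus one `GO_COMPARTMENT`
per `|`-separated GO term.

## Signature catalog directory

One accession list per category, `<category>.txt`, one accession per
line, `#` comments allowed. The nine fixed categories: `secretion`,
`tat`, `lipoprotein`, `cw_covalent`, `cw_noncovalent`, `cw_spore`,
`surface`, `pilin_fimbrilin`, `short_secreted_peptide`. An accession may
appear in at most one `cw_*` subcategory. `secretion.txt` entries may
carry a second tab-separated column naming the non-classical route
(`SecA2`, `Wss/T7SSb` or `FEA`) used for "-like" pathway annotation.
`go_compartments.tsv` maps `go_id<TAB>tag` with tags from
{CW, CYTO, EXTRA, LIPO, TM}. Unknown extra files are ignored with a
warning.

## Prediction table

TSV, fixed column order:

```
protein_id	true_tags	predicted_tags	pathway	cleavage_site	wall_interaction	evidence_summary
```

Tag sets are `;`-joined and lexically sorted; `Unknown` never co-occurs
with another tag. `pathway` is one of `Sec`, `Tat`, `SecA2-like`,
`Wss/T7SSb-like`, `FEA-like`, `FPE-like`, `bacteriocin-like`, `none`.
`wall_interaction` is `covalent`, `non-covalent`, `spore` or `none` and
is only set together with the CW tag. `evidence_summary` counts evidence
rows per kind (`KIND:n;...`). Writing then reading reproduces the table
exactly.

## Metrics table

TSV, fixed column order:

```
class	n	sensitivity	specificity	precision	accuracy	mcc	unknown_rate
```

One row per class plus one `overall` row. Undefined metrics (zero
denominators) are written as `NA`, never 0. Floats are written with six
decimals.

## Truth table

TSV with columns `protein_id` and `true_tags` (`;`-joined tag sets).
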