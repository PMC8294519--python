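# Methods

## The problem

In Gram-positive bacteria a protein's final compartment is decided by the
sorting signals embedded in its sequence: a Sec signal peptide exports it
across the membrane, a lipobox retains it as a membrane-anchored
lipoprotein, transmembrane helices keep it in the membrane, and cell-wall
proteins either carry a C-terminal LPXTG sortase motif (covalent
peptidoglycan attachment) or wall-binding domains (transient,
non-covalent interaction). `gramloc` mimics that sorting process: it
collects heterogeneous signal evidence per protein and folds it through
an explicit, inspectable rule engine into one of five localization tags —
CYTO (cytoplasm), TM (integral membrane), LIPO (lipoprotein), CW (cell
wall), EXTRA (extracellular) — or `Unknown` when the evidence conflicts
or is insufficient. Peripheral membrane proteins are deliberately not a
class: lacking TM or SP evidence they fall to CYTO.

The engine is WYSIWYG by design: it predicts only what the query sequence
itself supports. Remove the signal peptide from a secreted ribonuclease
and the prediction moves from EXTRA/Sec to CYTO, regardless of what
homologs do. This makes the tool suitable for engineered and synthetic
constructs, at the price of not rescuing mis-annotated wild-type entries.

## Evidence integration

Per protein the engine maintains 14 variables: five numeric compartment
scores (EXTRA, LIPO, TM, CW, CYTO — evidence-weighted counts) and nine
Boolean flags, one per curated signature category (secretion, tat,
lipoprotein, cw_covalent, cw_noncovalent, cw_spore, surface,
pilin_fimbrilin, short_secreted_peptide). Accumulation is additive and
therefore independent of evidence order; flags are monotone. Default
weights (config section `weights`, all config-exposed):

| evidence | effect |
|---|---|
| SP_SEC (external source) | +1 EXTRA |
| SP_SEC (builtin detector) | +2 EXTRA (see below) |
| SP_LIPO | +1 LIPO |
| SP_TAT | +1 EXTRA, sets the Tat flag |
| TM_HELIX | +1 TM |
| SIGNATURE_HIT (catalogued) | sets the category flag, +1 to its compartment |
| GO_COMPARTMENT (mapped) | +1 to the hinted compartment |
| SCL_VOTE | +1 to the voted compartment |
| lone SP-overlapping helix | −1 TM (suppression) |

The single negative weight handles the classic artefact that the
hydrophobic h-region of a signal peptide looks like a TM helix: when a
protein has an SP and exactly one helix labelled `possible_sp_overlap`,
that helix's contribution is removed. Scores floor at 0.

The builtin Sec-SP detector carries weight 2 because it is a single
scanner standing in for the whole family of concordant Sec-SP predictors
that a full tool panel would supply; with weight 1 a builtin-only run
could never clear the two-evidence EXTRA threshold and a bare
SP-plus-mature construct would be unpredictable from sequence alone.

Tag assignment compares scores to per-compartment thresholds (defaults:
EXTRA ≥ 2, LIPO ≥ 1, TM ≥ 1, CW ≥ 1). The lipoprotein, cell-wall and
secretion-signature flags override their thresholds: a curated signature
is treated as unequivocal. CYTO is never assigned positively — it is the
fallback of the consistency step.

## Consistency resolution

The provisional tag set is rewritten by an ordered rule table (new rules
are appended, never reordered):

1. EXTRA+CW → CW — cell-wall proteins are intrinsically extracellular,
   the EXTRA tag is redundant.
2. EXTRA+LIPO → LIPO — a lipid-retained protein is not freely
   extracellular.
3. CYTO with any non-CYTO tag → Unknown — no combination of signals can
   support both.
4. TM+EXTRA → TM if two or more independent helices were observed, else
   EXTRA — a lone N-terminal helix alongside an SP is usually the SP's
   h-region.
5. Empty set → CYTO only when every upstream detector affirmatively came
   back negative (or only cytoplasmic votes exist) and no sorting-signal
   evidence was seen at all; any sub-threshold signal evidence yields
   Unknown instead.

CW+TM survives resolution: multi-location cell-wall/membrane proteins are
a real class. `Unknown` is exclusive. Resolution is idempotent over every
subset of the tag vocabulary (verified exhaustively in the tests).

The distinction inside rule 5 is carried by an explicit
`EvidenceState.no_evidence` field set only when the accumulator received
an empty evidence list. A protein whose panel produced *some* signal
evidence that failed every threshold is an abstention (Unknown), not a
cytoplasmic call; a protein whose panel was entirely negative is called
CYTO. This separates "we saw nothing" from "we saw something we cannot
place".

## Secondary annotations

Extracellular calls carry the most likely export route: Tat when the
twin-arginine flag is set, Sec for any Sec or lipobox SP (lipoprotein SPs
are Sec/SpII substrates), and signature-only "-like" calls otherwise
(SecA2-like, Wss/T7SSb-like, FEA-like from the secretion catalog's
subtype column; FPE-like for pilin signatures; bacteriocin-like for short
secreted peptides). The "-like" suffix marks calls supported only by a
signature, not by a detected signal peptide. Pathway hints are reported
even when the final tag is Unknown. The reported cleavage site is the
highest-scoring CLEAVAGE_SITE observation and only appears together with
a pathway. CW calls carry the interaction type (covalent >
non-covalent > spore, by flag precedence).

## Builtin detectors

Five sequence-only scanners provide evidence when no external panel is
available (config: run them for records lacking evidence, always, or
never). All windows below are 1-based defaults in `DetectorConfig`:

- **Sec SP** — ≥1 K/R in the first 5 residues; a maximal hydrophobic run
  (alphabet AFILMVW) of ≥7 residues starting at positions 2–12; the first
  position 15–45 after the h-region whose −3/−1 residues are small
  (AGSTV) is the cleavage site.
- **Lipobox** — `[LVI][ASTVI][GAS]C` with the Cys at positions 15–40 and
  ≥6 of the 10 preceding residues hydrophobic; cleavage before the Cys.
- **Twin-arginine** — mandatory RR starting within the first 35 residues,
  ≥2 matches among the S/T-R-R-x-F-L-K flanking consensus positions, and
  a hydrophobic stretch (≥6 of 8 within 25 residues downstream).
- **LPXTG** — `LP.TG` starting within the last 50 residues, ≥15
  hydrophobic residues after the motif and ≥2 K/R in the final 10.
- **TM helices** — mean Kyte–Doolittle hydropathy over a 19-residue
  window ≥ 1.6; qualifying windows are merged into maximal runs, one
  helix each; helices overlapping a detected SP span are labelled
  `possible_sp_overlap` rather than dropped. `X` is scored 0.

These detectors are deliberately simple, deterministic heuristics; they
are not probabilistic SP models and do not predict membrane topology
orientation. Each is position-faithful (the reported span re-matches its
rule), which the tests verify against naive brute-force re-scans.

## Evaluation

Each class is scored one-vs-rest: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), accuracy (TP+TN)/total, and
MCC = (TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FP)(TN+FN)). Undefined ratios
are NaN, never 0. Abstentions are governed by an explicit policy:
`negative` (default — Unknown counts against the true class as an FN and
as a TN everywhere else) or `exclude` (abstaining rows leave the counts;
the abstention rate is always reported separately as `unknown_rate`).
Multi-label truths and predictions count as positive for each of their
classes; this is one defensible reading for the rare multi-location
CW-TM proteins and is kept switchable precisely because it is a policy,
not a fact. Overall values are class-size-weighted means; classes with
an undefined metric are dropped from that metric's average with weights
renormalized.

## Synthetic benchmark generator

`FixtureSpec` defaults describe a benchmark-shaped proteome (class counts
CW 58, CYTO 88, EXTRA 133, LIPO 9, TM 84), an evidence panel of 3
signal-peptide predictors, and an evidence noise level of 0.1 — roughly
the per-call error a reasonable SP predictor shows on bacterial
sequences. Sequences carry their class's detectable architecture;
mature regions are drawn from a polar-biased residue distribution that
excludes the hydrophobic and small-residue alphabets, so detector motifs
cannot arise by chance. This is a deliberate simplification: real
proteomes contain hydrophobic patches in soluble proteins, signal
peptides of variable length, and correlated tool errors. Passing the
recovery tests therefore demonstrates the engine's logic (exact recovery
from clean evidence, graceful degradation with noise), not field accuracy
on real proteomes — the latter depends on the external predictor panel.

Noise semantics: each SP source independently drops its true call with
probability `noise` and emits a contradictory SP call (wrong SP type)
with probability `noise`; the TM predictor drops true helices and
hallucinates spurious ones the same way; the signature scanner drops
hits with probability `noise` but never invents them (curated signature
lists are high-precision). Everything is driven by a single seed;
identical seeds give byte-identical FASTA/TSV outputs.

## Numerical and degenerate-input choices

- Scores are floats, compared to thresholds with `>=`; all weights and
  thresholds are config keys, so a verbatim replacement scheme can be
  dropped in without code changes.
- First-match-wins tie-breaks in all motif scanners (most N-terminal
  hit); the cleavage search takes the first qualifying position after the
  h-region.
- Sequences shorter than the hydropathy window yield no helices, with a
  warning.
- Cleavage-site ties are broken by score, then by the more N-terminal
  position.
- Empty prediction tables evaluate to all-NaN metrics rather than
  raising, except `overall`, which requires at least one non-empty class.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
proteomes of 372 proteins (the default class shape) for end-to-end
recovery, five seeds per noise level on the noise grid {0, 0.1, 0.3,
0.5}, and 100 replicates of 10,000 proteins for the random-prediction
calibration of the MCC. These sizes give Monte-Carlo error well inside
the asserted tolerances.

## Known limitations

- The builtin detectors trade accuracy for transparency; they are
  fallbacks, not replacements for a real predictor panel.
- Actinobacterial outer-membrane (mycomembrane) proteins are outside the
  model's vocabulary and will surface as EXTRA.
- The starter signature catalog is representative, not exhaustive; it is
  plain-text configuration intended to be extended or replaced wholesale.
- Real predictor output formats drift between versions; only the fixed
  "short" dialects documented in formats.md are parsed.
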