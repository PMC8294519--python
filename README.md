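# gramloc

Rule-based meta-prediction of protein subcellular localization (SCL) in
Gram-positive bacteria.

Gram-positive cells sort proteins by signals embedded in the sequence:
Sec and Tat signal peptides export proteins across the membrane, a
lipobox (`[LVI][ASTVI][GAS]C`) retains them as lipid-anchored
lipoproteins, hydrophobic α-helices keep them in the membrane, and
cell-wall proteins carry either a C-terminal LPXTG sortase motif
(covalent peptidoglycan anchoring) or wall-binding domains (transient
interaction). `gramloc` mimics that sorting decision: it integrates
heterogeneous evidence about these signals — from a panel of external
predictors, from curated domain-signature and GO-compartment catalogs,
or from its own builtin sequence scanners — and assigns one or more of
five tags: **CYTO** (cytoplasm), **TM** (integral membrane), **LIPO**
(lipoprotein), **CW** (cell wall), **EXTRA** (extracellular), or
**Unknown** when the evidence conflicts or is insufficient.

The engine is intentionally transparent rather than probabilistic. Per
protein it maintains five compartment scores $s_c$ (evidence-weighted
counts) and nine Boolean signature flags. A tag is assigned when
$s_c \ge \theta_c$ (defaults $\theta_{EXTRA}=2$, others $1$) or when an
unequivocal signature flag overrides the threshold; an ordered
consistency table then rewrites redundant combinations (EXTRA+CW → CW,
EXTRA+LIPO → LIPO) and turns contradictions (CYTO plus anything) into
Unknown. Secondary annotations report the likely export route (Sec,
Tat, or "-like" calls for SecA2/Wss-T7SSb/FEA/FPE/bacteriocin routes),
the signal-peptidase cleavage site, and the cell-wall interaction type
(covalent / non-covalent / spore). Because predictions use only the
query sequence and its evidence, deleting a signal peptide from a
secreted protein moves the call from EXTRA/Sec to CYTO — useful for
engineered constructs.

Predictions are scored one-vs-rest per class with sensitivity,
specificity, precision, accuracy and the Matthews correlation
coefficient

$$\mathrm{MCC} = \frac{TP \cdot TN - FP \cdot FN}
{\sqrt{(TP+FN)(TP+FP)(TN+FP)(TN+FN)}},$$

with explicit, switchable handling of Unknown predictions and
class-size-weighted overall averages. See `docs/methods.md` for the full
model description and `docs/formats.md` for every file format.

## Worked example

Generate a small labeled synthetic proteome with a noisy simulated
predictor panel, predict, and evaluate:

```sh
cat > spec.yaml <<'EOF'
n_per_class: {CW: 6, CYTO: 8, EXTRA: 10, LIPO: 4, TM: 6}
noise: 0.1
seed: 42
EOF
gramloc fixtures --spec spec.yaml -o fx
gramloc predict --fasta fx/proteome.fasta --evidence fx/evidence.tsv -o pred.tsv
gramloc evaluate --truth fx/truth.tsv --pred pred.tsv -o metrics.tsv
```

`pred.tsv` holds one row per protein, e.g.

```
protein_id  true_tags  predicted_tags  pathway  cleavage_site  wall_interaction  evidence_summary
cw_0001     .          CW              Sec      18             non-covalent      CLEAVAGE_SITE:3;SIGNATURE_HIT:1;SP_SEC:3
```

— this cell-wall protein was called CW via a wall-binding signature on
top of three concordant Sec-SP observations (the redundant EXTRA tag was
removed by the consistency step), exported via Sec with cleavage after
residue 18, and interacting non-covalently with the wall. Each `predict`
run also writes an effective-config dump (`pred.tsv.config.yaml`) and a
per-protein rule trail (`pred.tsv.rationale.json`).

`metrics.tsv` from the same run:

```
class    n   sensitivity  specificity  precision  accuracy  mcc       unknown_rate
CW       6   1.000000     1.000000     1.000000   1.000000  1.000000  0.000000
CYTO     8   0.750000     1.000000     1.000000   0.941176  0.834523  0.000000
EXTRA    10  0.500000     1.000000     1.000000   0.852941  0.643268  0.000000
LIPO     4   1.000000     0.666667     0.285714   0.705882  0.436436  0.000000
TM       6   1.000000     0.857143     0.600000   0.882353  0.717137  0.000000
overall  34  0.794118     0.935574     0.845378   0.887543  0.739924  0.000000
```

At 10% per-call evidence noise the engine keeps an overall MCC of 0.74
on this small proteome; the characteristic failure mode is visible in
the LIPO row (spurious lipobox calls pull secreted proteins into LIPO,
lowering its precision while EXTRA loses sensitivity). With `noise: 0.0`
every metric is exactly 1. Predictions from bare sequence also work
without an evidence table — `gramloc predict --fasta proteins.fasta -o
out.tsv` falls back to the builtin motif and hydropathy scanners, and
`gramloc scan` exports their evidence directly.

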