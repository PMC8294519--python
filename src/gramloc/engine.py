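"""The decision engine: fold per-protein evidence into compartment scores
and Boolean override flags, assign localization tags by thresholds,
resolve inconsistent tag sets, and attach secondary annotations
(secretion pathway, cleavage site, cell-wall interaction type).

The integration state holds 14 variables: five numeric compartment scores
(evidence-weighted counts for EXTRA, LIPO, TM, CW, CYTO) and nine Boolean
flags, one per signature category.  Scores accumulate additively, so the
state is independent of evidence order; flags are monotone (once set,
never reset within one protein's evaluation).  A flag marks a feature that
indicates a localization unequivocally and therefore overrides the
score thresholds.

Tag semantics: CYTO is never assigned positively by the threshold step; it
is the fallback of the consistency resolution when every upstream detector
came back negative (peripheral membrane proteins, lacking TM or SP
evidence, fall to CYTO as well).  ``Unknown`` is exclusive and returned
either on conflicting tags or when evidence exists but nothing reaches
its threshold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .catalog import SignatureCatalog, classify_hit, go_to_tag
from .detectors import CW_COVALENT_MOTIF, SP_OVERLAP_LABEL, DetectorConfig, scan_all
from .errors import InputError
from .io_formats import (
    Evidence,
    SequenceRecord,
    TAGS,
    UNKNOWN,
    join_tags,
)

log = logging.getLogger(__name__)

SP_KINDS = ("SP_SEC", "SP_LIPO", "SP_TAT")

#: evidence kinds that count as positive sorting-signal observations;
#: their presence blocks the CYTO fallback
SIGNAL_KINDS = SP_KINDS + ("TM_HELIX", "SIGNATURE_HIT")


@dataclass(frozen=True)
class Weights:
    """Per-evidence score increments (config section ``weights``)."""

    sp_sec: float = 1.0
    sp_lipo: float = 1.0
    sp_tat: float = 1.0
    tm_helix: float = 1.0
    signature: float = 1.0
    go: float = 1.0
    scl_vote: float = 1.0
    #: suppression of a lone N-terminal helix that overlaps a signal peptide
    sp_tm_overlap: float = -1.0
    #: the builtin Sec-SP detector aggregates the whole Sec-predictor
    #: family, so one builtin hit carries the weight of two concordant
    #: external predictors
    builtin_sp_sec: float = 2.0


@dataclass(frozen=True)
class Thresholds:
    """Minimum compartment scores for tag assignment (section ``thresholds``)."""

    extra: float = 2.0
    lipo: float = 1.0
    tm: float = 1.0
    cw: float = 1.0


DEFAULT_WEIGHTS = Weights()
DEFAULT_THRESHOLDS = Thresholds()

#: signature category -> Boolean flag attribute
CATEGORY_FLAG = {
    "secretion": "flag_secretion_signature",
    "tat": "flag_tat",
    "lipoprotein": "flag_lipoprotein",
    "cw_covalent": "flag_cw_covalent",
    "cw_noncovalent": "flag_cw_noncovalent",
    "cw_spore": "flag_spore",
    "surface": "flag_surface",
    "pilin_fimbrilin": "flag_pilin",
    "short_secreted_peptide": "flag_short_peptide",
}

#: signature category -> compartment score it supports
CATEGORY_SCORE = {
    "secretion": "score_extra",
    "tat": "score_extra",
    "lipoprotein": "score_lipo",
    "cw_covalent": "score_cw",
    "cw_noncovalent": "score_cw",
    "cw_spore": "score_cw",
    "surface": "score_cw",
    "pilin_fimbrilin": "score_extra",
    "short_secreted_peptide": "score_extra",
}

#: builtin motif labels that bypass the accession catalog
BUILTIN_LABEL_CATEGORY = {CW_COVALENT_MOTIF: "cw_covalent"}

TAG_SCORE = {
    "EXTRA": "score_extra",
    "LIPO": "score_lipo",
    "TM": "score_tm",
    "CW": "score_cw",
    "CYTO": "score_cyto",
}


@dataclass
class EvidenceState:
    """Per-protein integration state: 5 scores + 9 Boolean flags.

    ``no_evidence`` records the affirmative observation that every
    upstream detector came back negative (the accumulator received an
    empty evidence list); only then may the consistency resolution fall
    back to CYTO.  ``has_signal_evidence`` and ``n_tm_helices`` are
    bookkeeping for the resolution rules, not part of the 14-variable
    inventory.
    """

    score_extra: float = 0.0
    score_lipo: float = 0.0
    score_tm: float = 0.0
    score_cw: float = 0.0
    score_cyto: float = 0.0

    flag_secretion_signature: bool = False
    flag_tat: bool = False
    flag_lipoprotein: bool = False
    flag_cw_covalent: bool = False
    flag_cw_noncovalent: bool = False
    flag_spore: bool = False
    flag_surface: bool = False
    flag_pilin: bool = False
    flag_short_peptide: bool = False

    no_evidence: bool = False
    has_signal_evidence: bool = False
    n_tm_helices: int = 0


@dataclass(frozen=True)
class PredictionResult:
    """Final tag set plus secondary annotations and the evidence trail."""

    protein_id: str
    tags: frozenset
    pathway: str = "none"
    cleavage_site: int | None = None
    wall_interaction: str = "none"
    rationale: tuple = ()
    evidence_summary: str = ""

    def __post_init__(self) -> None:
        if not self.tags:
            raise InputError(f"{self.protein_id}: empty tag set")
        if UNKNOWN in self.tags and len(self.tags) > 1:
            raise InputError(
                f"{self.protein_id}: {UNKNOWN} may not co-occur with other tags"
            )
        if self.wall_interaction != "none" and "CW" not in self.tags:
            raise InputError(
                f"{self.protein_id}: wall_interaction without CW tag"
            )
        if self.cleavage_site is not None and self.pathway == "none":
            raise InputError(
                f"{self.protein_id}: cleavage site without a secretion pathway"
            )


# ---------------------------------------------------------------------------
# Score accumulation


def accumulate(
    evidence: Sequence[Evidence],
    catalog: SignatureCatalog,
    weights: Weights = DEFAULT_WEIGHTS,
) -> EvidenceState:
    """Fold one protein's evidence into an :class:`EvidenceState`.

    Purely additive, hence independent of evidence order.  The only
    negative contribution is the signal-peptide/helix overlap suppression:
    when a signal peptide co-occurs with a single N-terminal helix carrying
    the overlap label, that helix's score contribution is removed (the
    hydrophobic h-region of an SP mimics a TM helix).  Scores floor at 0.
    """
    ids = {ev.protein_id for ev in evidence}
    if len(ids) > 1:
        raise InputError(f"evidence for mixed protein ids: {sorted(ids)}")
    state = EvidenceState(no_evidence=not evidence)

    def bump(attr: str, delta: float) -> None:
        setattr(state, attr, getattr(state, attr) + delta)

    for ev in evidence:
        if ev.kind in SIGNAL_KINDS:
            state.has_signal_evidence = True
        if ev.kind == "SP_SEC":
            w = weights.builtin_sp_sec if ev.source == "builtin" else weights.sp_sec
            bump("score_extra", w)
        elif ev.kind == "SP_LIPO":
            bump("score_lipo", weights.sp_lipo)
        elif ev.kind == "SP_TAT":
            bump("score_extra", weights.sp_tat)
            state.flag_tat = True
        elif ev.kind == "TM_HELIX":
            bump("score_tm", weights.tm_helix)
            state.n_tm_helices += 1
        elif ev.kind == "SIGNATURE_HIT":
            category = BUILTIN_LABEL_CATEGORY.get(ev.label) or (
                classify_hit(ev.label, catalog) if ev.label else None
            )
            if category is not None:
                setattr(state, CATEGORY_FLAG[category], True)
                bump(CATEGORY_SCORE[category], weights.signature)
        elif ev.kind == "GO_COMPARTMENT":
            tag = go_to_tag(ev.label, catalog) if ev.label else None
            if tag is not None:
                bump(TAG_SCORE[tag], weights.go)
        elif ev.kind == "SCL_VOTE":
            if ev.label not in TAGS:
                raise InputError(
                    f"{ev.protein_id}: SCL_VOTE with invalid tag {ev.label!r}"
                )
            bump(TAG_SCORE[ev.label], weights.scl_vote)
        # CLEAVAGE_SITE carries no score weight

    has_sp = any(ev.kind in SP_KINDS for ev in evidence)
    overlap_helices = [
        ev
        for ev in evidence
        if ev.kind == "TM_HELIX" and ev.label == SP_OVERLAP_LABEL
    ]
    if has_sp and state.n_tm_helices == 1 and len(overlap_helices) == 1:
        state.score_tm += weights.sp_tm_overlap

    for attr in TAG_SCORE.values():
        setattr(state, attr, max(0.0, getattr(state, attr)))
    return state


# ---------------------------------------------------------------------------
# Tag assignment


def assign_tags(
    state: EvidenceState, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> set[str]:
    """Provisional tags: every compartment whose score meets its threshold
    or whose unequivocal flag is set.  CYTO is never assigned here (it is
    the fallback of :func:`resolve`); an empty set means nothing fired.
    """
    tags: set[str] = set()
    if state.score_extra >= thresholds.extra or state.flag_secretion_signature:
        tags.add("EXTRA")
    if state.score_lipo >= thresholds.lipo or state.flag_lipoprotein:
        tags.add("LIPO")
    if state.score_tm >= thresholds.tm:
        tags.add("TM")
    if (
        state.score_cw >= thresholds.cw
        or state.flag_cw_covalent
        or state.flag_cw_noncovalent
        or state.flag_spore
    ):
        tags.add("CW")
    return tags


# ---------------------------------------------------------------------------
# Consistency resolution

# The rule table is evaluated top-to-bottom in this order; new rules must
# be appended, never reordered.


def resolve(tags: Iterable[str], state: EvidenceState) -> tuple[frozenset, list[str]]:
    """Rewrite a provisional tag set into a consistent final one.

    Returns the final tags and the list of fired rule ids.  Idempotent
    over every subset of the tag vocabulary.

    Rules, in order:

    1. EXTRA+CW -> CW (cell-wall proteins are intrinsically extracellular)
    2. EXTRA+LIPO -> LIPO (a retained lipoprotein is not free extracellular)
    3. CYTO plus any non-CYTO tag -> Unknown (no signal combination can
       place a protein both inside and outside the cytoplasm)
    4. TM+EXTRA -> TM when two or more independent helices were observed,
       else EXTRA (a lone helix next to an SP is usually the SP itself)
    5. empty set -> CYTO only when every detector was negative (or only
       cytoplasmic votes were seen) and no sorting-signal evidence exists;
       otherwise Unknown

    CW+TM is left untouched: multi-location cell-wall/membrane proteins
    are a real class.
    """
    tags = set(tags)
    trail: list[str] = []
    if UNKNOWN in tags:
        return frozenset({UNKNOWN}), trail
    if {"EXTRA", "CW"} <= tags:
        tags.discard("EXTRA")
        trail.append("consistency:EXTRA+CW->CW")
    if {"EXTRA", "LIPO"} <= tags:
        tags.discard("EXTRA")
        trail.append("consistency:EXTRA+LIPO->LIPO")
    if "CYTO" in tags and tags - {"CYTO"}:
        trail.append("consistency:CYTO+noncytosolic->Unknown")
        return frozenset({UNKNOWN}), trail
    if {"TM", "EXTRA"} <= tags:
        if state.n_tm_helices >= 2:
            tags.discard("EXTRA")
            trail.append("consistency:TM+EXTRA->TM(multi-helix)")
        else:
            tags.discard("TM")
            trail.append("consistency:TM+EXTRA->EXTRA(single-helix)")
    if not tags:
        if (state.score_cyto > 0 or state.no_evidence) and not state.has_signal_evidence:
            trail.append("fallback:no-signal->CYTO")
            return frozenset({"CYTO"}), trail
        trail.append("fallback:subthreshold->Unknown")
        return frozenset({UNKNOWN}), trail
    return frozenset(tags), trail


# ---------------------------------------------------------------------------
# Secondary annotations


def annotate_secondary(
    protein_id: str,
    tags: frozenset,
    state: EvidenceState,
    evidence: Sequence[Evidence],
    catalog: SignatureCatalog,
    trail: Sequence[str] = (),
) -> PredictionResult:
    """Attach pathway, cleavage site and wall-interaction annotations.

    Pathway hints from Tat/pilin/signature motifs are reported even when
    the final tag is Unknown; the "-like" suffix marks signature-only
    calls.  The cleavage site is the highest-scoring CLEAVAGE_SITE
    observation and is only reported alongside a pathway.
    """
    rationale = list(trail)
    has_sp_sec = any(ev.kind == "SP_SEC" for ev in evidence)
    has_sp_lipo = any(ev.kind == "SP_LIPO" for ev in evidence)
    pathway = "none"
    if state.flag_tat:
        pathway = "Tat"
    elif has_sp_sec or has_sp_lipo:
        # lipoprotein signal peptides are Sec-dependent (Sec/SpII)
        pathway = "Sec"
    elif state.flag_secretion_signature:
        subtype = None
        for ev in evidence:
            if ev.kind == "SIGNATURE_HIT" and ev.label in catalog.secretion_subtypes:
                subtype = catalog.secretion_subtypes[ev.label]
                break
        if subtype is not None:
            pathway = f"{subtype}-like"
    elif state.flag_pilin:
        pathway = "FPE-like"
    elif state.flag_short_peptide:
        pathway = "bacteriocin-like"
    if pathway != "none":
        rationale.append(f"pathway:{pathway}")

    cleavage = None
    sites = [ev for ev in evidence if ev.kind == "CLEAVAGE_SITE"]
    if sites and pathway != "none":
        best = max(sites, key=lambda ev: (ev.score or 0.0, -(ev.start or 0)))
        cleavage = best.start

    wall = "none"
    if "CW" in tags:
        if state.flag_cw_covalent:
            wall = "covalent"
        elif state.flag_cw_noncovalent:
            wall = "non-covalent"
        elif state.flag_spore:
            wall = "spore"
        if wall != "none":
            rationale.append(f"wall_interaction:{wall}")

    counts: dict[str, int] = {}
    for ev in evidence:
        counts[ev.kind] = counts.get(ev.kind, 0) + 1
    summary = TAG_SUMMARY_SEP.join(f"{k}:{counts[k]}" for k in sorted(counts)) or "-"

    return PredictionResult(
        protein_id=protein_id,
        tags=tags,
        pathway=pathway,
        cleavage_site=cleavage,
        wall_interaction=wall,
        rationale=tuple(rationale),
        evidence_summary=summary,
    )


TAG_SUMMARY_SEP = ";"


# ---------------------------------------------------------------------------
# End-to-end prediction


def predict(
    records: Sequence[SequenceRecord],
    evidence: Sequence[Evidence],
    catalog: SignatureCatalog,
    config=None,
) -> list[PredictionResult]:
    """Predict the localization of every record.

    ``config`` is a :class:`gramloc.config.RunConfig` (or any object with
    ``weights``, ``thresholds``, ``detectors`` and ``builtin_detectors``
    attributes); defaults are used when omitted.  Depending on
    ``builtin_detectors`` ("missing", "always", "never"), the builtin
    sequence scanners supply evidence for records without any, for all
    records, or not at all.
    """
    if config is None:
        from .config import RunConfig

        config = RunConfig()
    ids = {rec.id for rec in records}
    orphans = sorted({ev.protein_id for ev in evidence} - ids)
    if orphans:
        raise InputError(f"evidence references unknown proteins: {orphans}")
    by_protein: dict[str, list[Evidence]] = {rec.id: [] for rec in records}
    for ev in evidence:
        by_protein[ev.protein_id].append(ev)

    results = []
    for rec in records:
        evs = list(by_protein[rec.id])
        mode = config.builtin_detectors
        if mode == "always" or (mode == "missing" and not evs):
            evs.extend(scan_all(rec, config.detectors))
        state = accumulate(evs, catalog, config.weights)
        provisional = assign_tags(state, config.thresholds)
        rationale = [
            f"{TAG_SCORE[t]}={getattr(state, TAG_SCORE[t]):g}" for t in sorted(provisional)
        ]
        rationale.extend(
            flag for flag in CATEGORY_FLAG.values() if getattr(state, flag)
        )
        tags, trail = resolve(provisional, state)
        for rule in rationale + trail:
            log.debug("%s: %s", rec.id, rule)
        results.append(
            annotate_secondary(
                rec.id, tags, state, evs, catalog, trail=rationale + trail
            )
        )
    return results


def predictions_to_frame(
    results: Sequence[PredictionResult],
    truth: Mapping[str, frozenset] | None = None,
):
    """Render prediction results as the fixed-column prediction table."""
    import pandas as pd

    rows = []
    for res in results:
        rows.append(
            {
                "protein_id": res.protein_id,
                "true_tags": join_tags(truth[res.protein_id])
                if truth and res.protein_id in truth
                else ".",
                "predicted_tags": join_tags(res.tags),
                "pathway": res.pathway,
                "cleavage_site": "." if res.cleavage_site is None else str(res.cleavage_site),
                "wall_interaction": res.wall_interaction,
                "evidence_summary": res.evidence_summary,
            }
        )
    from .io_formats import PREDICTION_COLUMNS

    return pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))
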