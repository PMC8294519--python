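"""Decision-engine tests: accumulation, thresholds/overrides, consistency
resolution, secondary annotations and end-to-end prediction."""
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from gramloc import (
    EvidenceState,
    InputError,
    RunConfig,
    SequenceRecord,
    Thresholds,
    accumulate,
    annotate_secondary,
    assign_tags,
    predict,
    resolve,
)
from gramloc.engine import Weights
from gramloc.io_formats import Evidence, TAGS, UNKNOWN


def sp_sec(pid="p1", source="sp_predictor_a", end=24):
    return Evidence(pid, source, "SP_SEC", 1, end, 0.9)


# ---------------------------------------------------------------------------
# accumulate


def test_three_sp_sources_count_three(catalog):
    evs = [sp_sec(source=s) for s in ("sp_predictor_a", "sp_predictor_b", "predisi_like")]
    state = accumulate(evs, catalog)
    assert state.score_extra == 3
    assert not any(
        getattr(state, f) for f in vars(state) if f.startswith("flag_")
    )


def test_lipoprotein_signature_sets_flag_and_score(catalog):
    acc = min(catalog.categories["lipoprotein"])
    state = accumulate(
        [Evidence("p1", "signature_scanner", "SIGNATURE_HIT", 1, 20, None, acc)],
        catalog,
    )
    assert state.flag_lipoprotein and state.score_lipo == 1


def test_mixed_protein_ids_rejected(catalog):
    with pytest.raises(InputError, match="mixed"):
        accumulate([sp_sec("p1"), sp_sec("p2")], catalog)


def test_sp_overlap_suppresses_lone_helix(catalog):
    evs = [
        Evidence("p1", "builtin", "SP_SEC", 1, 20, 1.0),
        Evidence("p1", "builtin", "TM_HELIX", 2, 20, 2.0, "possible_sp_overlap"),
    ]
    state = accumulate(evs, catalog)
    assert state.score_tm == 0
    # two helices: the suppression no longer applies (real membrane protein)
    evs.append(Evidence("p1", "builtin", "TM_HELIX", 60, 80, 2.0))
    assert accumulate(evs, catalog).score_tm == 2


def test_go_and_votes_accumulate_to_hinted_compartments(catalog):
    evs = [
        Evidence("p1", "go_compartment", "GO_COMPARTMENT", label="GO:0005618"),
        Evidence("p1", "generic_scl_predictor", "SCL_VOTE", label="CYTO"),
    ]
    state = accumulate(evs, catalog)
    assert state.score_cw == 1 and state.score_cyto == 1


_ev_strategy = st.lists(
    st.sampled_from(
        [
            sp_sec(),
            sp_sec(source="sp_predictor_b"),
            Evidence("p1", "lipo_predictor", "SP_LIPO", 1, 19, 0.8),
            Evidence("p1", "tat_predictor", "SP_TAT", 1, 30, 0.7),
            Evidence("p1", "tm_predictor", "TM_HELIX", 30, 50),
            Evidence("p1", "tm_predictor", "TM_HELIX", 80, 100),
            Evidence("p1", "signature_scanner", "SIGNATURE_HIT", 1, 9, None, "PF00746"),
            Evidence("p1", "go_compartment", "GO_COMPARTMENT", label="GO:0005576"),
            Evidence("p1", "generic_scl_predictor", "SCL_VOTE", label="TM"),
        ]
    ),
    max_size=9,
)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(evs=_ev_strategy, seed=st.randoms(use_true_random=False))
def test_accumulate_is_order_independent(catalog, evs, seed):
    shuffled = list(evs)
    seed.shuffle(shuffled)
    assert accumulate(evs, catalog) == accumulate(shuffled, catalog)


# ---------------------------------------------------------------------------
# assign_tags


def test_all_zero_state_assigns_nothing():
    assert assign_tags(EvidenceState()) == set()


def test_scores_meet_thresholds():
    assert assign_tags(EvidenceState(score_extra=3)) == {"EXTRA"}
    assert assign_tags(EvidenceState(score_lipo=1, score_tm=1)) == {"LIPO", "TM"}


def test_flags_override_subthreshold_scores():
    st1 = EvidenceState(score_extra=1, flag_secretion_signature=True)
    assert assign_tags(st1) == {"EXTRA"}
    assert assign_tags(EvidenceState(flag_lipoprotein=True)) == {"LIPO"}
    assert assign_tags(EvidenceState(flag_cw_covalent=True)) == {"CW"}


def test_raised_thresholds_respected_but_flags_still_fire():
    th = Thresholds(extra=5, lipo=5, tm=5, cw=5)
    assert assign_tags(EvidenceState(score_extra=4), th) == set()
    assert assign_tags(EvidenceState(score_extra=4, flag_secretion_signature=True), th) == {"EXTRA"}


# ---------------------------------------------------------------------------
# resolve


def test_redundant_extra_removed():
    assert resolve({"EXTRA", "CW"}, EvidenceState())[0] == {"CW"}
    assert resolve({"EXTRA", "LIPO"}, EvidenceState())[0] == {"LIPO"}


def test_cyto_conflict_is_unknown():
    assert resolve({"EXTRA", "CYTO"}, EvidenceState())[0] == {UNKNOWN}
    assert resolve({"CYTO", "TM"}, EvidenceState())[0] == {UNKNOWN}


def test_cyto_alone_is_identity():
    assert resolve({"CYTO"}, EvidenceState())[0] == {"CYTO"}


def test_tm_extra_arbitration_by_helix_count():
    assert resolve({"TM", "EXTRA"}, EvidenceState(n_tm_helices=2))[0] == {"TM"}
    assert resolve({"TM", "EXTRA"}, EvidenceState(n_tm_helices=1))[0] == {"EXTRA"}


def test_cw_tm_multilocation_preserved():
    assert resolve({"CW", "TM"}, EvidenceState())[0] == {"CW", "TM"}


def test_empty_set_fallback_semantics(catalog):
    # all detectors affirmatively negative -> cytoplasmic
    assert resolve(set(), accumulate([], catalog))[0] == {"CYTO"}
    # sub-threshold signal evidence -> abstain
    state = accumulate([sp_sec()], catalog)
    assert resolve(set(), state)[0] == {UNKNOWN}
    # a default-constructed all-zero state carries no negative-scan
    # observation either -> abstain
    assert resolve(set(), EvidenceState())[0] == {UNKNOWN}
    # cytoplasmic votes only -> cytoplasmic
    vote = Evidence("p1", "generic_scl_predictor", "SCL_VOTE", label="CYTO")
    assert resolve(set(), accumulate([vote], catalog))[0] == {"CYTO"}


@pytest.mark.parametrize(
    "state",
    [
        EvidenceState(),
        EvidenceState(no_evidence=True),
        EvidenceState(has_signal_evidence=True, n_tm_helices=1),
        EvidenceState(score_cyto=2, n_tm_helices=3),
    ],
)
def test_resolve_idempotent_over_all_tag_subsets(state):
    for r in range(len(TAGS) + 1):
        for subset in itertools.combinations(TAGS, r):
            once, _ = resolve(set(subset), state)
            twice, _ = resolve(set(once), state)
            assert once == twice
            assert UNKNOWN not in once or once == {UNKNOWN}


def test_override_dominance_lipo_before_resolution():
    """Setting the lipoprotein flag forces LIPO into the provisional tags
    regardless of the rest of the state."""
    for score in (0, 1, 5):
        state = EvidenceState(score_extra=score, flag_lipoprotein=True)
        assert "LIPO" in assign_tags(state)


# ---------------------------------------------------------------------------
# annotate_secondary


def test_wall_interaction_requires_cw(catalog):
    state = EvidenceState(flag_cw_covalent=True)
    res = annotate_secondary("p1", frozenset({"CW"}), state, [], catalog)
    assert res.wall_interaction == "covalent"
    res2 = annotate_secondary("p1", frozenset({"EXTRA"}), state, [], catalog)
    assert res2.wall_interaction == "none"


def test_tat_flag_wins_pathway(catalog):
    state = EvidenceState(flag_tat=True)
    evs = [sp_sec(), Evidence("p1", "tat_predictor", "SP_TAT", 1, 30, 0.7)]
    res = annotate_secondary("p1", frozenset({"EXTRA"}), state, evs, catalog)
    assert res.pathway == "Tat"


def test_pilin_hint_retained_under_unknown(catalog):
    state = EvidenceState(flag_pilin=True)
    res = annotate_secondary("p1", frozenset({UNKNOWN}), state, [], catalog)
    assert res.pathway == "FPE-like"


def test_secretion_signature_pathway_subtype(catalog):
    acc = next(iter(catalog.secretion_subtypes))
    subtype = catalog.secretion_subtypes[acc]
    evs = [Evidence("p1", "signature_scanner", "SIGNATURE_HIT", 1, 50, None, acc)]
    state = accumulate(evs, catalog)
    res = annotate_secondary("p1", frozenset({"EXTRA"}), state, evs, catalog)
    assert res.pathway == f"{subtype}-like"


def test_cleavage_site_picks_highest_score(catalog):
    evs = [
        sp_sec(),
        Evidence("p1", "sp_predictor_a", "CLEAVAGE_SITE", 24, 24, 0.7),
        Evidence("p1", "sp_predictor_b", "CLEAVAGE_SITE", 23, 23, 0.95),
    ]
    state = accumulate(evs, catalog)
    res = annotate_secondary("p1", frozenset({"EXTRA"}), state, evs, catalog)
    assert res.cleavage_site == 23 and res.pathway == "Sec"


# ---------------------------------------------------------------------------
# predict (end-to-end)

SP = "MKKLLLLLLLLLAVAAQA"
MATURE = "DQNSTEGKH" * 14


def test_sp_from_two_sources_is_extracellular(catalog):
    recs = [SequenceRecord("p1", SP + MATURE)]
    evs = [sp_sec(source="sp_predictor_a"), sp_sec(source="sp_predictor_b")]
    (res,) = predict(recs, evs, catalog)
    assert res.tags == {"EXTRA"} and res.pathway == "Sec"


def test_sp_truncation_flips_to_cytoplasmic(catalog):
    """Sequence-only behavior: the same mature protein with and without
    its signal peptide lands extracellular vs cytoplasmic."""
    full = SequenceRecord("full", SP + MATURE)
    trunc = SequenceRecord("trunc", "M" + MATURE)
    res = {r.protein_id: r for r in predict([full, trunc], [], catalog)}
    assert res["full"].tags == {"EXTRA"} and res["full"].pathway == "Sec"
    assert res["trunc"].tags == {"CYTO"}


def test_soluble_sequence_without_hits_is_cytoplasmic(catalog):
    (res,) = predict([SequenceRecord("p1", "M" + MATURE)], [], catalog)
    assert res.tags == {"CYTO"}


def test_evidence_for_unknown_protein_rejected(catalog):
    with pytest.raises(InputError, match="unknown proteins"):
        predict([SequenceRecord("p1", "M" + MATURE)], [sp_sec("ghost")], catalog)


def test_adding_concordant_sp_never_demotes_to_cyto(catalog):
    """Monotonicity: one more agreeing Sec-SP observation can never move a
    protein from EXTRA to CYTO."""
    recs = [SequenceRecord("p1", SP + MATURE)]
    base = [sp_sec(source="sp_predictor_a"), sp_sec(source="sp_predictor_b")]
    extra = base + [sp_sec(source="predisi_like")]
    (before,) = predict(recs, base, catalog)
    (after,) = predict(recs, extra, catalog)
    assert not (before.tags == {"EXTRA"} and after.tags == {"CYTO"})
    assert after.tags == {"EXTRA"}


def test_builtin_modes(catalog):
    recs = [SequenceRecord("p1", SP + MATURE)]
    never = RunConfig(builtin_detectors="never")
    (res,) = predict(recs, [], catalog, never)
    assert res.tags == {"CYTO"}  # nothing scanned, no evidence at all
    always = RunConfig(builtin_detectors="always")
    evs = [sp_sec(source="sp_predictor_a")]
    (res2,) = predict(recs, evs, catalog, always)
    assert res2.tags == {"EXTRA"}  # builtin adds the second observation


def test_prediction_is_deterministic_under_evidence_permutation(catalog):
    recs = [SequenceRecord("p1", SP + MATURE)]
    evs = [
        sp_sec(source="sp_predictor_a"),
        sp_sec(source="sp_predictor_b"),
        Evidence("p1", "tm_predictor", "TM_HELIX", 40, 60),
    ]
    (fwd,) = predict(recs, evs, catalog)
    (rev,) = predict(recs, evs[::-1], catalog)
    assert fwd == rev
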