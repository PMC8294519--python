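"""Builtin sorting-signal detectors: rule examples, brute-force oracle
equivalence, and position-faithfulness."""
import numpy as np
import pytest

from gramloc import SequenceRecord
from gramloc.detectors import (
    DEFAULT_DETECTORS as CFG,
    HYDROPHOBIC,
    KYTE_DOOLITTLE,
    SMALL,
    SP_OVERLAP_LABEL,
    find_lpxtg,
    scan_all,
    scan_lipobox,
    scan_lpxtg,
    scan_sec_sp,
    scan_tm_hydropathy,
    scan_twin_arginine,
)

POLAR = "DENQSTGKRHPY"


def rec(seq, pid="t"):
    return SequenceRecord(pid, seq)


def _random_seq(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=n))


# ---------------------------------------------------------------------------
# Lipobox


def test_lipobox_canonical_hit_and_cleavage():
    seq = "MK" + "L" * 16 + "LAGC" + "A" * 20
    hits = scan_lipobox(rec(seq))
    kinds = {h.kind for h in hits}
    assert kinds == {"SP_LIPO", "CLEAVAGE_SITE"}
    sp = next(h for h in hits if h.kind == "SP_LIPO")
    c_pos = seq.index("C") + 1
    assert sp.span == (1, c_pos - 1)
    cs = next(h for h in hits if h.kind == "CLEAVAGE_SITE")
    assert cs.span == (c_pos - 1, c_pos - 1)


def test_lipobox_requires_cysteine():
    assert scan_lipobox(rec("A" * 60)) == []


def test_lipobox_position_window_enforced():
    seq = "M" + "D" * 290 + "L" * 8 + "LAGC" + "A" * 97
    assert len(seq) == 400 and seq.index("C") + 1 > CFG.lipobox_c_max
    assert scan_lipobox(rec(seq)) == []


def test_lipobox_requires_hydrophobic_context():
    # box in window but preceded by polar residues only
    seq = "MK" + "D" * 14 + "LAGC" + "A" * 20
    assert scan_lipobox(rec(seq)) == []


# ---------------------------------------------------------------------------
# Twin-arginine


def test_tat_consensus_hit():
    seq = "MSRRQFLK" + "L" * 10 + "D" * 40
    hits = scan_twin_arginine(rec(seq))
    assert len(hits) == 1 and hits[0].kind == "SP_TAT"
    assert hits[0].start == 1


def test_tat_requires_rr():
    assert scan_twin_arginine(rec("MSKQFLK" + "L" * 10 + "D" * 20)) == []


def test_tat_rr_position_window():
    seq = "M" + "D" * 199 + "SRRQFLK" + "L" * 10 + "D" * 20
    assert scan_twin_arginine(rec(seq)) == []


def test_tat_requires_downstream_hydrophobic_stretch():
    assert scan_twin_arginine(rec("MSRRQFLK" + "D" * 60)) == []


# ---------------------------------------------------------------------------
# LPXTG


def _lpxtg_protein():
    return "M" + "E" * 170 + "LPKTGE" + "L" * 18 + "KRK"


def test_lpxtg_hit_with_all_context_flags():
    hit = find_lpxtg(rec(_lpxtg_protein()))
    assert hit is not None
    assert hit.matched.startswith("LP") and hit.matched.endswith("G")
    assert hit.flags == {
        "near_c_terminus",
        "followed_by_hydrophobic_stretch",
        "positive_c_tail",
    }
    (ev,) = scan_lpxtg(rec(_lpxtg_protein()))
    assert ev.label == "CW_COVALENT_MOTIF"
    seq = _lpxtg_protein()
    assert seq[ev.start - 1 : ev.end] == "LPKTG"


def test_lpxtg_outside_c_terminal_window_ignored():
    seq = "M" + "E" * 8 + "LPKTG" + "E" * 280 + "L" * 18 + "KRK"
    assert scan_lpxtg(rec(seq)) == []


def test_lpxtg_absent_without_proline():
    assert scan_lpxtg(rec("M" + "LETG".join(["E" * 30] * 5))) == []


def test_lpxtg_requires_positive_tail():
    seq = "M" + "E" * 170 + "LPKTGE" + "L" * 18 + "QSQ"
    assert scan_lpxtg(rec(seq)) == []


# ---------------------------------------------------------------------------
# TM hydropathy


def test_tm_single_block_single_helix():
    seq = "S" * 15 + "L" * 19 + "S" * 15
    hits = scan_tm_hydropathy(rec(seq))
    assert len(hits) == 1
    start, end = hits[0].span
    assert start <= 16 and end >= 16 + 18  # covers the Leu block


def test_tm_polar_sequence_no_helix():
    assert scan_tm_hydropathy(rec("DE" * 30)) == []


def test_tm_two_blocks_two_helices():
    seq = "S" * 10 + "L" * 19 + "S" * 30 + "L" * 19 + "S" * 10
    assert len(scan_tm_hydropathy(rec(seq))) == 2


def test_tm_short_sequence_warns_and_returns_empty():
    with pytest.warns(UserWarning, match="shorter"):
        assert scan_tm_hydropathy(rec("MKL")) == []


def test_tm_sp_overlap_labelled_not_dropped():
    seq = "S" * 2 + "L" * 19 + "S" * 40
    hits = scan_tm_hydropathy(rec(seq), sp_spans=[(1, 21)])
    assert len(hits) == 1 and hits[0].label == SP_OVERLAP_LABEL


def _naive_tm(seq, window=19, threshold=1.6):
    """Brute-force re-scan: all window means, merged qualifying spans."""
    spans = []
    for i in range(len(seq) - window + 1):
        mean = sum(KYTE_DOOLITTLE[aa] for aa in seq[i : i + window]) / window
        if mean >= threshold:
            span = (i + 1, i + window)
            if spans and span[0] <= spans[-1][1]:
                spans[-1] = (spans[-1][0], span[1])
            else:
                spans.append(span)
    return spans


@pytest.mark.parametrize("seed", range(8))
def test_tm_matches_bruteforce_on_random_sequences(seed):
    rng = np.random.default_rng(seed)
    seq = _random_seq(rng, 400)
    got = [h.span for h in scan_tm_hydropathy(rec(seq))]
    assert got == _naive_tm(seq)


# ---------------------------------------------------------------------------
# Sec SP


def test_sec_sp_canonical_architecture():
    seq = "MKKLLLLLLLLLAVAAQA" + "D" * 100
    hits = scan_sec_sp(rec(seq))
    assert {h.kind for h in hits} == {"SP_SEC", "CLEAVAGE_SITE"}
    sp = next(h for h in hits if h.kind == "SP_SEC")
    # cleavage at the A-x-A following the h-region, position 18
    assert sp.span == (1, 18)


def test_sec_sp_acidic_start_no_hit():
    assert scan_sec_sp(rec("MDE" + "L" * 10 + "AVAAQA" + "D" * 50)) == []


def test_sec_sp_mature_domain_alone_no_hit():
    # the same mature region without its signal peptide
    mature = "D" * 100
    assert scan_sec_sp(rec("M" + mature)) == []


def _naive_sec(seq, cfg=CFG):
    """Independent re-derivation of the n/h/c rule."""
    if not any(a in "KR" for a in seq[: cfg.sec_n_region]):
        return None
    h = None
    for i in range(cfg.sec_h_start_min - 1, min(cfg.sec_h_start_max, len(seq))):
        if seq[i] in HYDROPHOBIC and (i == 0 or seq[i - 1] not in HYDROPHOBIC):
            j = i
            while j + 1 < len(seq) and seq[j + 1] in HYDROPHOBIC:
                j += 1
            if j - i + 1 >= cfg.sec_h_min_len:
                h = (i + 1, j + 1)
                break
    if h is None:
        return None
    for cs in range(max(cfg.sec_c_min, h[1] + 1), min(cfg.sec_c_max, len(seq) - 1) + 1):
        if cs >= 3 and seq[cs - 1] in SMALL and seq[cs - 3] in SMALL:
            return cs
    return None


@pytest.mark.parametrize("seed", range(8))
def test_sec_sp_matches_bruteforce_on_random_sequences(seed):
    rng = np.random.default_rng(100 + seed)
    seq = _random_seq(rng, 120)
    hits = scan_sec_sp(rec(seq))
    expected = _naive_sec(seq)
    if expected is None:
        assert hits == []
    else:
        sp = next(h for h in hits if h.kind == "SP_SEC")
        assert sp.span == (1, expected)


def test_detectors_are_pure_and_deterministic():
    seq = "MKKLLLLLLLLLAVAAQA" + "D" * 80 + "LPKTG" + "L" * 18 + "KRK"
    r = rec(seq)
    assert scan_all(r) == scan_all(r)
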