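"""Sequence-only detectors for Gram-positive sorting signals.

These scanners let the pipeline run end-to-end from bare FASTA input:
a tripartite Sec signal-peptide heuristic (positively charged n-region,
hydrophobic h-region, small-residue c-region with an A-x-A-like cleavage
pattern), a lipobox scan for Sec/SpII lipoprotein signals, a twin-arginine
(Tat) consensus scan, a C-terminal LPXTG sortase-motif scan, and a
Kyte-Doolittle sliding-window transmembrane-helix scan.

All detectors are pure and deterministic; every reported span re-matches
the stated rule on the reported substring.  Windows and thresholds are
package defaults exposed through :class:`DetectorConfig`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .io_formats import Evidence, SequenceRecord

#: Residues counted as hydrophobic by the motif-context rules.
HYDROPHOBIC = frozenset("AFILMVW")

#: Small residues accepted at the -3/-1 positions of a SpI cleavage site.
SMALL = frozenset("AGSTV")

#: Label attached to LPXTG motif hits; the decision engine maps it to the
#: covalent cell-wall category.
CW_COVALENT_MOTIF = "CW_COVALENT_MOTIF"

#: Label flagging a TM helix that overlaps a detected signal peptide.
SP_OVERLAP_LABEL = "possible_sp_overlap"


def _load_kd_scale() -> dict[str, float]:
    scale: dict[str, float] = {}
    text = (resources.files("gramloc") / "data" / "kyte_doolittle.tsv").read_text()
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        aa, value = line.split("\t")
        scale[aa] = float(value)
    return scale


KYTE_DOOLITTLE = _load_kd_scale()


@dataclass(frozen=True)
class DetectorConfig:
    """Windows and thresholds of the builtin detectors (1-based positions)."""

    # lipobox: [LVI][ASTVI][GAS]C with the C inside the position window,
    # preceded by a hydrophobic-rich stretch
    lipobox_c_min: int = 15
    lipobox_c_max: int = 40
    lipobox_context_len: int = 10
    lipobox_context_min: int = 6

    # twin-arginine consensus S/T-R-R-x-F-L-K
    tat_rr_max_start: int = 35
    tat_flank_min: int = 2
    tat_h_search: int = 25
    tat_h_window: int = 8
    tat_h_min: int = 6

    # C-terminal LPXTG sortase motif
    lpxtg_window: int = 50
    lpxtg_tail_hydrophobic_min: int = 15
    lpxtg_basic_tail_len: int = 10
    lpxtg_basic_min: int = 2

    # transmembrane hydropathy scan
    tm_window: int = 19
    tm_threshold: float = 1.6

    # Sec signal peptide (n/h/c architecture)
    sec_n_region: int = 5
    sec_h_start_min: int = 2
    sec_h_start_max: int = 12
    sec_h_min_len: int = 7
    sec_c_min: int = 15
    sec_c_max: int = 45


DEFAULT_DETECTORS = DetectorConfig()


@dataclass(frozen=True)
class MotifHit:
    """A positional motif match with its context flags."""

    name: str
    start: int  # 1-based inclusive
    end: int
    matched: str
    flags: frozenset = frozenset()


# ---------------------------------------------------------------------------
# Sec signal peptide


def _h_region(seq: str, cfg: DetectorConfig) -> tuple[int, int] | None:
    """Earliest maximal hydrophobic run of sufficient length starting in
    the allowed n/h boundary window.  Returns a 1-based (start, end)."""
    n = len(seq)
    for i in range(cfg.sec_h_start_min - 1, min(cfg.sec_h_start_max, n)):
        if seq[i] not in HYDROPHOBIC:
            continue
        if i > 0 and seq[i - 1] in HYDROPHOBIC:
            continue  # not the start of a maximal run
        j = i
        while j + 1 < n and seq[j + 1] in HYDROPHOBIC:
            j += 1
        if j - i + 1 >= cfg.sec_h_min_len:
            return (i + 1, j + 1)
    return None


def scan_sec_sp(rec: SequenceRecord, cfg: DetectorConfig = DEFAULT_DETECTORS) -> list[Evidence]:
    """Detect a Sec/SpI signal peptide.

    Requires a charged n-region (>=1 K/R in the first residues), a
    hydrophobic h-region starting near the N-terminus, and the first
    A-x-A-like small-residue pattern after the h-region inside the
    cleavage window.  Emits SP_SEC spanning 1..cleavage plus a
    CLEAVAGE_SITE at the -1 residue.
    """
    seq = rec.seq
    if not any(aa in "KR" for aa in seq[: cfg.sec_n_region]):
        return []
    h = _h_region(seq, cfg)
    if h is None:
        return []
    cs_lo = max(cfg.sec_c_min, h[1] + 1)
    cs_hi = min(cfg.sec_c_max, len(seq) - 1)  # keep a non-empty mature region
    for cs in range(cs_lo, cs_hi + 1):
        if cs < 3:
            continue
        if seq[cs - 1] in SMALL and seq[cs - 3] in SMALL:
            return [
                Evidence(rec.id, "builtin", "SP_SEC", 1, cs, 1.0),
                Evidence(rec.id, "builtin", "CLEAVAGE_SITE", cs, cs, 1.0),
            ]
    return []


# ---------------------------------------------------------------------------
# Lipobox


def _is_lipobox(window: str) -> bool:
    return (
        len(window) == 4
        and window[0] in "LVI"
        and window[1] in "ASTVI"
        and window[2] in "GAS"
        and window[3] == "C"
    )


def scan_lipobox(rec: SequenceRecord, cfg: DetectorConfig = DEFAULT_DETECTORS) -> list[Evidence]:
    """Detect a Sec/SpII lipoprotein signal (lipobox [LVI][ASTVI][GAS]C).

    The lipidated cysteine must fall in the configured position window and
    be preceded by a hydrophobic-rich stretch.  Cleavage is before the C,
    so the signal spans 1..C-1.  First (most N-terminal) hit wins.
    """
    seq = rec.seq
    for i in range(len(seq) - 3):
        c_pos = i + 4  # 1-based position of the cysteine
        if c_pos < cfg.lipobox_c_min or c_pos > cfg.lipobox_c_max:
            continue
        if not _is_lipobox(seq[i : i + 4]):
            continue
        ctx = seq[max(0, c_pos - 1 - cfg.lipobox_context_len) : c_pos - 1]
        if sum(aa in HYDROPHOBIC for aa in ctx) < cfg.lipobox_context_min:
            continue
        return [
            Evidence(rec.id, "builtin", "SP_LIPO", 1, c_pos - 1, 1.0),
            Evidence(rec.id, "builtin", "CLEAVAGE_SITE", c_pos - 1, c_pos - 1, 1.0),
        ]
    return []


# ---------------------------------------------------------------------------
# Twin-arginine motif


def _has_hydrophobic_stretch(seq: str, start0: int, cfg: DetectorConfig) -> int | None:
    """1-based end of the first qualifying hydrophobic window at or after
    ``start0`` (0-based) within the search range, else None."""
    w, need = cfg.tat_h_window, cfg.tat_h_min
    for j in range(start0, min(start0 + cfg.tat_h_search, len(seq) - w) + 1):
        window = seq[j : j + w]
        if len(window) == w and sum(aa in HYDROPHOBIC for aa in window) >= need:
            return j + w  # 1-based end of the window
    return None


def scan_twin_arginine(rec: SequenceRecord, cfg: DetectorConfig = DEFAULT_DETECTORS) -> list[Evidence]:
    """Detect a twin-arginine (Tat) signal peptide.

    Requires the mandatory RR dipeptide near the N-terminus, at least
    ``tat_flank_min`` matches among the S/T-R-R-x-F-L-K flanking consensus
    positions, and a downstream hydrophobic stretch.
    """
    seq = rec.seq
    limit = min(cfg.tat_rr_max_start, len(seq) - 1)
    for i in range(limit):  # i = 0-based index of the first R
        if seq[i : i + 2] != "RR":
            continue
        flanks = 0
        if i >= 1 and seq[i - 1] in "ST":
            flanks += 1
        if i + 3 < len(seq) and seq[i + 3] == "F":
            flanks += 1
        if i + 4 < len(seq) and seq[i + 4] == "L":
            flanks += 1
        if i + 5 < len(seq) and seq[i + 5] == "K":
            flanks += 1
        if flanks < cfg.tat_flank_min:
            continue
        h_end = _has_hydrophobic_stretch(seq, i + 2, cfg)
        if h_end is None:
            continue
        return [Evidence(rec.id, "builtin", "SP_TAT", 1, h_end, 1.0)]
    return []


# ---------------------------------------------------------------------------
# LPXTG sortase motif


def find_lpxtg(rec: SequenceRecord, cfg: DetectorConfig = DEFAULT_DETECTORS) -> MotifHit | None:
    """Locate a C-terminal LPXTG sortase motif with anchoring context.

    The motif must start within the last ``lpxtg_window`` residues, be
    followed by a hydrophobic-rich membrane-spanning stretch, and end in a
    positively charged tail.
    """
    seq = rec.seq
    n = len(seq)
    for i in range(max(0, n - cfg.lpxtg_window), n - 4):
        window = seq[i : i + 5]
        if not (
            window[0] == "L"
            and window[1] == "P"
            and window[3] == "T"
            and window[4] == "G"
        ):
            continue
        tail = seq[i + 5 :]
        hydrophobic = sum(aa in HYDROPHOBIC for aa in tail)
        basic = sum(aa in "KR" for aa in seq[-cfg.lpxtg_basic_tail_len :])
        flags = {"near_c_terminus"}
        if hydrophobic >= cfg.lpxtg_tail_hydrophobic_min:
            flags.add("followed_by_hydrophobic_stretch")
        if basic >= cfg.lpxtg_basic_min:
            flags.add("positive_c_tail")
        if {"followed_by_hydrophobic_stretch", "positive_c_tail"} <= flags:
            return MotifHit("LPXTG", i + 1, i + 5, window, frozenset(flags))
    return None


def scan_lpxtg(rec: SequenceRecord, cfg: DetectorConfig = DEFAULT_DETECTORS) -> list[Evidence]:
    """LPXTG motif as SIGNATURE_HIT evidence (label CW_COVALENT_MOTIF)."""
    hit = find_lpxtg(rec, cfg)
    if hit is None:
        return []
    return [
        Evidence(rec.id, "builtin", "SIGNATURE_HIT", hit.start, hit.end, 1.0, CW_COVALENT_MOTIF)
    ]


# ---------------------------------------------------------------------------
# Transmembrane hydropathy scan


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def scan_tm_hydropathy(
    rec: SequenceRecord,
    cfg: DetectorConfig = DEFAULT_DETECTORS,
    sp_spans: Sequence[tuple[int, int]] = (),
) -> list[Evidence]:
    """Transmembrane helices by mean Kyte-Doolittle hydropathy.

    Window positions whose mean hydropathy meets the threshold are merged
    into maximal runs; each merged run is one TM_HELIX.  Runs overlapping
    a detected signal-peptide span (``sp_spans``) are labelled
    ``possible_sp_overlap`` rather than dropped.  Sequences shorter than
    the window yield an empty result with a warning.
    """
    seq = rec.seq
    w = cfg.tm_window
    if len(seq) < w:
        warnings.warn(
            f"sequence {rec.id!r} shorter than the hydropathy window ({w})"
        )
        return []
    values = np.array([KYTE_DOOLITTLE[aa] for aa in seq])
    means = np.convolve(values, np.ones(w) / w, mode="valid")
    qualifying = np.flatnonzero(means >= cfg.tm_threshold)
    if qualifying.size == 0:
        return []
    # merge window starts whose spans overlap into maximal runs
    spans: list[list[int]] = []
    scores: list[float] = []
    for idx in qualifying:
        start, end = int(idx) + 1, int(idx) + w  # 1-based span of this window
        if spans and start <= spans[-1][1]:
            spans[-1][1] = end
            scores[-1] = max(scores[-1], float(means[idx]))
        else:
            spans.append([start, end])
            scores.append(float(means[idx]))
    out = []
    for (start, end), score in zip(spans, scores):
        label = (
            SP_OVERLAP_LABEL
            if any(_spans_overlap((start, end), sp) for sp in sp_spans)
            else None
        )
        out.append(
            Evidence(rec.id, "builtin", "TM_HELIX", start, end, round(score, 4), label)
        )
    return out


# ---------------------------------------------------------------------------
# Combined scan


def scan_all(rec: SequenceRecord, cfg: DetectorConfig = DEFAULT_DETECTORS) -> list[Evidence]:
    """Run every builtin detector on one record.

    Signal-peptide spans found by the SP scanners are passed to the
    hydropathy scan so helices inside them carry the overlap label.
    """
    out: list[Evidence] = []
    out.extend(scan_sec_sp(rec, cfg))
    out.extend(scan_lipobox(rec, cfg))
    out.extend(scan_twin_arginine(rec, cfg))
    sp_spans = [ev.span for ev in out if ev.kind in ("SP_SEC", "SP_LIPO", "SP_TAT")]
    out.extend(scan_tm_hydropathy(rec, cfg, sp_spans=sp_spans))
    out.extend(scan_lpxtg(rec, cfg))
    return out
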