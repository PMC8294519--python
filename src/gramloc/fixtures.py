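"""Labeled synthetic proteomes with matching noisy evidence.

Each class of the generated proteome carries the sequence architecture
its sorting signal implies, so the builtin detectors can recover it from
sequence alone:

EXTRA   Sec signal peptide (charged n-region, Leu-rich h-region,
        A-x-A cleavage) followed by a soluble polar mature region.
LIPO    lipobox signal ([LVI][ASTVI][GAS]C) with the cysteine at
        position 21, polar mature region.
TM      polar N-terminus, then 1-3 internal 21-residue hydrophobic
        helices separated by polar loops (no signal peptide).
CW      Sec SP plus either a C-terminal LPXTG sortase anchor (covalent,
        even indices) or a cell-wall binding signature in the evidence
        table (non-covalent, odd indices).
CYTO    polar sequence without any sorting signal.

Mature-region composition is a polar-biased categorical distribution that
excludes the hydrophobic and small-residue alphabets the detectors key
on, so classes cannot collide by chance.  Identical seed, identical
output, byte for byte.

The evidence generator emulates the meta-predictor's tool panel:
``n_sources`` independent signal-peptide predictors each report the
truth-consistent call with probability 1-noise and a spurious
contradictory call with probability noise; a TM predictor reports each
true helix with probability 1-noise and hallucinates one with probability
noise; the signature scanner reports the catalog signature of CW/LIPO
proteins with drop probability noise (curated signatures are modeled as
high-precision, so it emits no spurious hits).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .catalog import SignatureCatalog, load_default_catalog
from .errors import InputError
from .io_formats import Evidence, SequenceRecord, SOURCE_KINDS, TAGS

#: Benchmark-shaped default class composition (CW/CYTO/EXTRA/LIPO/TM).
DEFAULT_CLASS_COUNTS: Mapping[str, int] = {
    "CW": 58,
    "CYTO": 88,
    "EXTRA": 133,
    "LIPO": 9,
    "TM": 84,
}

#: Polar-biased residue distribution for mature regions.  Deliberately
#: free of the hydrophobic set {A,F,I,L,M,V,W} and of C, so detector
#: motifs cannot arise by chance in a mature region.
POLAR_RESIDUES = "DENQSTGKRHPY"
POLAR_WEIGHTS = (0.08, 0.09, 0.07, 0.07, 0.12, 0.10, 0.12, 0.10, 0.07, 0.04, 0.07, 0.07)

SEC_SP = "MKKLLLLLLLLLAVAAQA"  # cleavage after position 18
SEC_SP_LEN = len(SEC_SP)
LIPO_SP = "MK" + "L" * 16 + "AG"  # lipobox ends with C at position 21
LIPO_C_POS = 21

#: SP-predictor sources cycled by the evidence generator.
SP_SOURCES = (
    "sp_predictor_a",
    "sp_predictor_b",
    "lipo_predictor",
    "predisi_like",
    "phobius_like",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of one synthetic benchmark (counts, noise, panel size, seed)."""

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    noise: float = 0.1
    n_sources: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise <= 1.0:
            raise InputError(f"noise must be in [0, 1], got {self.noise}")
        for cls, n in self.n_per_class.items():
            if cls not in TAGS:
                raise InputError(f"unknown class {cls!r} in n_per_class")
            if n < 0:
                raise InputError(f"negative count for class {cls!r}")
        if not 1 <= self.n_sources <= len(SP_SOURCES):
            raise InputError(
                f"n_sources must be in [1, {len(SP_SOURCES)}], got {self.n_sources}"
            )


def _polar(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(POLAR_RESIDUES), size=length, p=POLAR_WEIGHTS)
    return "".join(POLAR_RESIDUES[i] for i in idx)


def _hydrophobic(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("LIVF"), size=length))


def _make_sequence(cls: str, index: int, rng: np.random.Generator) -> str:
    if cls == "EXTRA":
        return SEC_SP + _polar(rng, int(rng.integers(120, 250)))
    if cls == "LIPO":
        return LIPO_SP + "C" + _polar(rng, int(rng.integers(100, 200)))
    if cls == "TM":
        n_helix = int(rng.integers(1, 4))
        parts = ["M" + _polar(rng, 30)]
        for _ in range(n_helix):
            parts.append(_hydrophobic(rng, 21))
            parts.append(_polar(rng, 25))
        return "".join(parts)
    if cls == "CW":
        body = SEC_SP + _polar(rng, int(rng.integers(100, 200)))
        if index % 2 == 0:  # covalent: LPXTG + A/W anchor + charged tail
            anchor = "AW" * 8  # hydrophobic-rich but below the helix threshold
            return body + "LPKTG" + anchor[:15] + "KRKKR"
        return body  # non-covalent: signature evidence marks the class
    if cls == "CYTO":
        return "M" + _polar(rng, int(rng.integers(150, 300)))
    raise InputError(f"unknown class {cls!r}")


def generate_proteome(
    spec: FixtureSpec,
) -> tuple[list[SequenceRecord], dict[str, frozenset]]:
    """Generate records and their truth labels, deterministically."""
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    truth: dict[str, frozenset] = {}
    for cls in sorted(spec.n_per_class):
        for i in range(spec.n_per_class[cls]):
            pid = f"{cls.lower()}_{i:04d}"
            records.append(SequenceRecord(pid, _make_sequence(cls, i, rng)))
            truth[pid] = frozenset({cls})
    return records, truth


def _tm_spans(seq: str) -> list[tuple[int, int]]:
    """True helix spans of a generated TM sequence (runs of L/I/V/F)."""
    spans = []
    start = None
    for i, aa in enumerate(seq):
        if aa in "LIVF":
            if start is None:
                start = i
        elif start is not None:
            if i - start >= 15:
                spans.append((start + 1, i))
            start = None
    if start is not None and len(seq) - start >= 15:
        spans.append((start + 1, len(seq)))
    return spans


def generate_evidence(
    records: Sequence[SequenceRecord],
    truth: Mapping[str, frozenset],
    spec: FixtureSpec,
    catalog: SignatureCatalog | None = None,
) -> list[Evidence]:
    """Simulate the tool panel's evidence table for a labeled proteome."""
    missing = sorted({rec.id for rec in records} - set(truth))
    if missing:
        raise InputError(f"records without truth labels: {missing}")
    if catalog is None:
        catalog = load_default_catalog()
    rng = np.random.default_rng(spec.seed + 1)
    sources = SP_SOURCES[: spec.n_sources]
    sig_lipo = min(catalog.categories["lipoprotein"])
    sig_cw_cov = min(catalog.categories["cw_covalent"])
    sig_cw_noncov = min(catalog.categories["cw_noncovalent"])

    out: list[Evidence] = []
    for rec in records:
        cls = next(iter(truth[rec.id]))
        has_sec_sp = cls in ("EXTRA", "CW")
        for source in sources:
            score = round(float(rng.uniform(0.80, 0.99)), 4)
            emit_truth = rng.random() >= spec.noise
            emit_spurious = rng.random() < spec.noise
            if emit_truth:
                if has_sec_sp:
                    out.append(
                        Evidence(rec.id, source, "SP_SEC", 1, SEC_SP_LEN, score)
                    )
                    out.append(
                        Evidence(
                            rec.id, source, "CLEAVAGE_SITE", SEC_SP_LEN, SEC_SP_LEN, score
                        )
                    )
                elif cls == "LIPO" and "SP_LIPO" in SOURCE_KINDS[source]:
                    # only SP_LIPO-capable sources report lipoboxes
                    out.append(
                        Evidence(
                            rec.id, source, "SP_LIPO", 1, LIPO_C_POS - 1, score
                        )
                    )
                    out.append(
                        Evidence(
                            rec.id,
                            source,
                            "CLEAVAGE_SITE",
                            LIPO_C_POS - 1,
                            LIPO_C_POS - 1,
                            score,
                        )
                    )
            if emit_spurious:
                bad_score = round(float(rng.uniform(0.5, 0.9)), 4)
                if has_sec_sp and "SP_LIPO" in SOURCE_KINDS[source]:
                    out.append(
                        Evidence(rec.id, source, "SP_LIPO", 1, 20, bad_score)
                    )
                elif not has_sec_sp:
                    out.append(
                        Evidence(rec.id, source, "SP_SEC", 1, 18, bad_score)
                    )
        # TM predictor
        if cls == "TM":
            for start, end in _tm_spans(rec.seq):
                if rng.random() >= spec.noise:
                    out.append(Evidence(rec.id, "tm_predictor", "TM_HELIX", start, end))
        if rng.random() < spec.noise:
            pos = int(rng.integers(1, max(2, len(rec.seq) - 21)))
            out.append(
                Evidence(rec.id, "tm_predictor", "TM_HELIX", pos, pos + 20)
            )
        # signature scanner: curated, high precision
        if cls == "LIPO" and rng.random() >= spec.noise:
            out.append(
                Evidence(rec.id, "signature_scanner", "SIGNATURE_HIT", 1, 20, None, sig_lipo)
            )
        if cls == "CW" and rng.random() >= spec.noise:
            idx = int(rec.id.split("_")[-1])
            acc = sig_cw_cov if idx % 2 == 0 else sig_cw_noncov
            a = max(1, len(rec.seq) - 30)
            out.append(
                Evidence(rec.id, "signature_scanner", "SIGNATURE_HIT", a, len(rec.seq), None, acc)
            )
    return out
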