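"""Input/output layer: FASTA proteomes, the normalized evidence schema,
the fixed "short" dialects of the wrapped predictor families, and the
prediction / metrics tables.

All sequence coordinates are 1-based, inclusive.  A signal-peptidase
cleavage site "between residue k and k+1" is encoded as position k.

The normalized evidence schema (TSV columns, ``.`` for an absent value)::

    protein_id  source  kind  start  end  score  label

The same rows may be given as a JSON list of objects with those keys
(absent values as ``null`` or omitted).  Dialect grammars are documented
in docs/formats.md.
"""
from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import InputError

# ---------------------------------------------------------------------------
# Vocabulary

TAGS = ("CW", "CYTO", "EXTRA", "LIPO", "TM")
UNKNOWN = "Unknown"
TAG_VOCAB = frozenset(TAGS) | {UNKNOWN}

#: 20 canonical residues plus X (unknown).  B/Z/U are rejected: the motif
#: scans downstream are defined on the canonical alphabet only.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

EVIDENCE_KINDS = (
    "SP_SEC",
    "SP_LIPO",
    "SP_TAT",
    "TM_HELIX",
    "SIGNATURE_HIT",
    "GO_COMPARTMENT",
    "SCL_VOTE",
    "CLEAVAGE_SITE",
)

#: Which feature kinds each evidence source may report.  The two generic SP
#: predictors model multiclass SP callers and may therefore also report
#: lipoprotein and Tat signal peptides.
SOURCE_KINDS: Mapping[str, frozenset] = {
    "sp_predictor_a": frozenset({"SP_SEC", "SP_LIPO", "SP_TAT", "CLEAVAGE_SITE"}),
    "sp_predictor_b": frozenset({"SP_SEC", "SP_LIPO", "SP_TAT", "CLEAVAGE_SITE"}),
    "phobius_like": frozenset({"SP_SEC", "TM_HELIX", "CLEAVAGE_SITE"}),
    "predisi_like": frozenset({"SP_SEC", "CLEAVAGE_SITE"}),
    "lipo_predictor": frozenset({"SP_LIPO", "SP_SEC", "CLEAVAGE_SITE"}),
    "tat_predictor": frozenset({"SP_TAT", "CLEAVAGE_SITE"}),
    "tm_predictor": frozenset({"TM_HELIX"}),
    "signature_scanner": frozenset({"SIGNATURE_HIT", "GO_COMPARTMENT"}),
    "go_compartment": frozenset({"GO_COMPARTMENT"}),
    "builtin": frozenset(
        {"SP_SEC", "SP_LIPO", "SP_TAT", "TM_HELIX", "SIGNATURE_HIT", "CLEAVAGE_SITE"}
    ),
    "generic_scl_predictor": frozenset({"SCL_VOTE"}),
}
EVIDENCE_SOURCES = tuple(SOURCE_KINDS)


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class SequenceRecord:
    """One amino-acid sequence with a unique identifier."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record with empty id")
        if not self.seq:
            raise InputError(f"empty sequence for record {self.id!r}")
        if self.seq != self.seq.upper():
            raise InputError(f"sequence for {self.id!r} is not uppercase")
        for pos, aa in enumerate(self.seq, start=1):
            if aa not in AMINO_ACIDS:
                raise InputError(
                    f"record {self.id!r}: invalid residue {aa!r} at position {pos} "
                    "(allowed: 20 canonical amino acids plus X)"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Evidence:
    """One normalized feature observation on a protein.

    ``span`` (start/end) is 1-based inclusive; a cleavage site is a
    single-position span at the last residue of the signal peptide.
    """

    protein_id: str
    source: str
    kind: str
    start: int | None = None
    end: int | None = None
    score: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCE_KINDS:
            raise InputError(f"unknown evidence source {self.source!r}")
        if self.kind not in EVIDENCE_KINDS:
            raise InputError(f"unknown evidence kind {self.kind!r}")
        if self.kind not in SOURCE_KINDS[self.source]:
            raise InputError(
                f"source {self.source!r} may not report kind {self.kind!r}"
            )
        if (self.start is None) != (self.end is None):
            raise InputError(
                f"evidence for {self.protein_id!r}: start and end must both be "
                "present or both absent"
            )
        if self.start is not None:
            if self.start < 1 or self.end < self.start:
                raise InputError(
                    f"evidence for {self.protein_id!r}: invalid span "
                    f"{self.start}-{self.end}"
                )

    @property
    def span(self) -> tuple[int, int] | None:
        if self.start is None:
            return None
        return (self.start, self.end)


#: Fixed column order of the prediction table.
PREDICTION_COLUMNS = (
    "protein_id",
    "true_tags",
    "predicted_tags",
    "pathway",
    "cleavage_site",
    "wall_interaction",
    "evidence_summary",
)

#: Fixed column order of the metrics table.
METRICS_COLUMNS = (
    "class",
    "n",
    "sensitivity",
    "specificity",
    "precision",
    "accuracy",
    "mcc",
    "unknown_rate",
)

MISSING = "."
TAG_SEP = ";"


def join_tags(tags: Iterable[str]) -> str:
    """Render a tag set deterministically: lexically sorted, ';'-joined."""
    tags = sorted(set(tags))
    bad = [t for t in tags if t not in TAG_VOCAB]
    if bad:
        raise InputError(f"tags outside vocabulary: {bad}")
    if UNKNOWN in tags and len(tags) > 1:
        raise InputError(f"{UNKNOWN} may not co-occur with other tags: {tags}")
    return TAG_SEP.join(tags)


def parse_tags(cell: str) -> frozenset[str]:
    """Parse a ';'-joined tag cell back into a tag set."""
    if cell is None or cell == "" or cell == MISSING:
        return frozenset()
    tags = frozenset(cell.split(TAG_SEP))
    bad = sorted(t for t in tags if t not in TAG_VOCAB)
    if bad:
        raise InputError(f"tags outside vocabulary: {bad}")
    if UNKNOWN in tags and len(tags) > 1:
        raise InputError(f"{UNKNOWN} may not co-occur with other tags: {sorted(tags)}")
    return tags


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read an amino-acid FASTA file into validated records.

    Sequences are uppercased and a single trailing '*' stop is stripped.
    Raises :class:`InputError` on empty files, duplicate ids, or
    non-amino-acid characters (with position).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if rec.id in seen:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc == rec.id:
            desc = ""
        elif desc.startswith(rec.id + " "):
            desc = desc[len(rec.id) + 1 :]
        records.append(SequenceRecord(rec.id, seq, desc))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as plain FASTA, 60 residues per line, in given order."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Normalized evidence schema

_EVIDENCE_COLUMNS = ("protein_id", "source", "kind", "start", "end", "score", "label")


def _evidence_from_fields(fields: Mapping, where: str) -> Evidence:
    def opt_int(v):
        if v in (None, "", MISSING):
            return None
        try:
            return int(v)
        except (TypeError, ValueError):
            raise InputError(f"{where}: non-integer coordinate {v!r}") from None

    def opt_float(v):
        if v in (None, "", MISSING):
            return None
        try:
            return float(v)
        except (TypeError, ValueError):
            raise InputError(f"{where}: non-numeric score {v!r}") from None

    label = fields.get("label")
    if label in ("", MISSING):
        label = None
    try:
        return Evidence(
            protein_id=str(fields["protein_id"]),
            source=str(fields["source"]),
            kind=str(fields["kind"]),
            start=opt_int(fields.get("start")),
            end=opt_int(fields.get("end")),
            score=opt_float(fields.get("score")),
            label=label,
        )
    except InputError as exc:
        raise InputError(f"{where}: {exc}") from None


def read_evidence_table(
    path: str | Path,
    sequences: Sequence[SequenceRecord] | None = None,
) -> list[Evidence]:
    """Read evidence rows from TSV or JSON (by file extension).

    When ``sequences`` is supplied, spans are checked against sequence
    lengths and unknown protein ids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"evidence file not found: {path}")
    rows: list[Evidence] = []
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        if not isinstance(data, list):
            raise InputError(f"{path}: JSON evidence must be a list of objects")
        for i, obj in enumerate(data):
            if not isinstance(obj, dict):
                raise InputError(f"{path}: entry {i} is not an object")
            rows.append(_evidence_from_fields(obj, f"{path} entry {i}"))
    else:
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if header.split("\t") != list(_EVIDENCE_COLUMNS):
                raise InputError(
                    f"{path}: bad evidence header; expected "
                    + "\t".join(_EVIDENCE_COLUMNS)
                )
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != len(_EVIDENCE_COLUMNS):
                    raise InputError(
                        f"{path} line {lineno}: expected "
                        f"{len(_EVIDENCE_COLUMNS)} columns, got {len(parts)}"
                    )
                rows.append(
                    _evidence_from_fields(
                        dict(zip(_EVIDENCE_COLUMNS, parts)), f"{path} line {lineno}"
                    )
                )
    if sequences is not None:
        lengths = {rec.id: len(rec) for rec in sequences}
        for ev in rows:
            if ev.protein_id not in lengths:
                raise InputError(
                    f"evidence references unknown protein {ev.protein_id!r}"
                )
            if ev.start is not None and ev.end > lengths[ev.protein_id]:
                raise InputError(
                    f"evidence span {ev.start}-{ev.end} outside sequence "
                    f"{ev.protein_id!r} (length {lengths[ev.protein_id]})"
                )
    return rows


def _fmt_opt(value, is_float: bool = False) -> str:
    if value is None:
        return MISSING
    if is_float:
        return format(value, ".6g")
    return str(value)


def write_evidence_table(evidence: Sequence[Evidence], path: str | Path) -> None:
    """Write evidence rows as TSV or JSON (by file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = [
            {
                "protein_id": ev.protein_id,
                "source": ev.source,
                "kind": ev.kind,
                "start": ev.start,
                "end": ev.end,
                "score": None if ev.score is None else float(format(ev.score, ".6g")),
                "label": ev.label,
            }
            for ev in evidence
        ]
        path.write_text(json.dumps(data, indent=1) + "\n")
        return
    with open(path, "w") as fh:
        fh.write("\t".join(_EVIDENCE_COLUMNS) + "\n")
        for ev in evidence:
            fh.write(
                "\t".join(
                    (
                        ev.protein_id,
                        ev.source,
                        ev.kind,
                        _fmt_opt(ev.start),
                        _fmt_opt(ev.end),
                        _fmt_opt(ev.score, is_float=True),
                        _fmt_opt(ev.label),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Predictor "short" dialects

_SPAN_RE = re.compile(r"(\d+)-(\d+)")
_CLEAVAGE_RE = re.compile(r"c(\d+)/(\d+)")


def _num(value: str, where: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise InputError(f"{where}: non-numeric score {value!r}") from None


def _cleave(value: str, where: str) -> int | None:
    if value == "-":
        return None
    try:
        pos = int(value)
    except ValueError:
        raise InputError(f"{where}: bad cleavage position {value!r}") from None
    if pos < 1:
        raise InputError(f"{where}: cleavage position must be >= 1")
    return pos


def _parse_sp_like(name, parts, source, kind, where, yes_token="YES"):
    """Shared grammar: name <call> <score> <cleavage|->."""
    call, score, cleavage = parts
    out = []
    if call == yes_token:
        sc = _num(score, where)
        cs = _cleave(cleavage, where)
        if cs is None:
            raise InputError(f"{where}: positive call without cleavage position")
        out.append(Evidence(name, source, kind, 1, cs, sc))
        out.append(Evidence(name, source, "CLEAVAGE_SITE", cs, cs, sc))
    return out


def _parse_sp_short(name, parts, source, where):
    return _parse_sp_like(name, parts, source, "SP_SEC", where)


def _parse_tat_short(name, parts, source, where):
    return _parse_sp_like(name, parts, source, "SP_TAT", where)


def _parse_lipo_short(name, parts, source, where):
    call, score, cleavage = parts
    kind = {"SpII": "SP_LIPO", "SpI": "SP_SEC"}.get(call)
    if call not in ("SpII", "SpI", "TMH", "CYT"):
        raise InputError(f"{where}: unknown lipoprotein-predictor class {call!r}")
    if kind is None:
        return []
    return _parse_sp_like(name, (call, score, cleavage), source, kind, where, yes_token=call)


def _parse_tm_short(name, parts, source, where):
    nhelix, topology = parts
    try:
        n = int(nhelix)
    except ValueError:
        raise InputError(f"{where}: bad helix count {nhelix!r}") from None
    if n == 0:
        return []
    spans = _SPAN_RE.findall(topology)
    if len(spans) != n:
        raise InputError(
            f"{where}: helix count {n} does not match topology {topology!r}"
        )
    return [
        Evidence(name, source, "TM_HELIX", int(a), int(b)) for a, b in spans
    ]


def _parse_phobius_short(name, parts, source, where):
    tm, sp, prediction = parts
    try:
        n = int(tm)
    except ValueError:
        raise InputError(f"{where}: bad helix count {tm!r}") from None
    out = []
    if sp == "Y":
        m = _CLEAVAGE_RE.search(prediction)
        if not m:
            raise InputError(
                f"{where}: SP call without c<k>/<k+1> cleavage in {prediction!r}"
            )
        cs = int(m.group(1))
        out.append(Evidence(name, source, "SP_SEC", 1, cs))
        out.append(Evidence(name, source, "CLEAVAGE_SITE", cs, cs))
    if n > 0:
        spans = _SPAN_RE.findall(prediction)
        if len(spans) != n:
            raise InputError(
                f"{where}: helix count {n} does not match prediction {prediction!r}"
            )
        out.extend(
            Evidence(name, source, "TM_HELIX", int(a), int(b)) for a, b in spans
        )
    return out


def _parse_signature_tsv(name, parts, source, where):
    accession, start, end, score, go_terms = parts
    try:
        a, b = int(start), int(end)
    except ValueError:
        raise InputError(f"{where}: bad signature span {start!r}-{end!r}") from None
    sc = None if score == MISSING else _num(score, where)
    out = [Evidence(name, source, "SIGNATURE_HIT", a, b, sc, accession)]
    if go_terms != MISSING:
        for go in go_terms.split("|"):
            if not go.startswith("GO:"):
                raise InputError(f"{where}: malformed GO term {go!r}")
            out.append(Evidence(name, source, "GO_COMPARTMENT", label=go))
    return out


#: dialect -> (default source, fields per row after the name, row parser)
_DIALECTS = {
    "sp_short": ("sp_predictor_a", 3, _parse_sp_short),
    "lipo_short": ("lipo_predictor", 3, _parse_lipo_short),
    "tat_short": ("tat_predictor", 3, _parse_tat_short),
    "tm_short": ("tm_predictor", 2, _parse_tm_short),
    "phobius_short": ("phobius_like", 3, _parse_phobius_short),
    "signature_tsv": ("signature_scanner", 5, _parse_signature_tsv),
}

DIALECTS = tuple(_DIALECTS)


def parse_predictor_output(
    path: str | Path, dialect: str, source: str | None = None
) -> list[Evidence]:
    """Parse one predictor "short"-format file into Evidence rows.

    The first line of the file must be the header ``# <dialect>``; further
    ``#`` lines are comments.  Grammars are documented in docs/formats.md
    with one canonical example file each under tests/data/dialects/.
    """
    if dialect not in _DIALECTS:
        raise InputError(
            f"unrecognized dialect {dialect!r}; known: {', '.join(DIALECTS)}"
        )
    default_source, n_fields, row_parser = _DIALECTS[dialect]
    source = source or default_source
    path = Path(path)
    if not path.exists():
        raise InputError(f"predictor output not found: {path}")
    out: list[Evidence] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"# {dialect}":
            raise InputError(
                f"{path}: header mismatch; expected '# {dialect}', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != n_fields + 1:
                raise InputError(
                    f"{path} line {lineno}: expected {n_fields + 1} columns, "
                    f"got {len(parts)}"
                )
            out.extend(
                row_parser(parts[0], parts[1:], source, f"{path} line {lineno}")
            )
    return out


# ---------------------------------------------------------------------------
# Prediction and metrics tables


def write_predictions(table: pd.DataFrame, path: str | Path) -> None:
    """Write a prediction table as TSV with the fixed column order."""
    missing = [c for c in PREDICTION_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"prediction table missing columns: {missing}")
    for cell in table["predicted_tags"]:
        parse_tags(cell)  # validates vocabulary and Unknown exclusivity
    table = table.loc[:, list(PREDICTION_COLUMNS)]
    table.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a prediction TSV back; all cells kept as strings."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"prediction table not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PREDICTION_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"{path}: prediction table missing columns: {missing}")
    return table


def _fmt_metric(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    return format(float(v), ".6f")


def write_metrics(table: pd.DataFrame, path: str | Path) -> None:
    """Write a metrics table as TSV; undefined metrics rendered as ``NA``."""
    missing = [c for c in METRICS_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"metrics table missing columns: {missing}")
    out = table.loc[:, list(METRICS_COLUMNS)].copy()
    for col in METRICS_COLUMNS[2:]:
        out[col] = [_fmt_metric(v) for v in out[col]]
    out["n"] = out["n"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    """Read a metrics TSV; ``NA`` becomes NaN."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"metrics table not found: {path}")
    table = pd.read_csv(path, sep="\t", keep_default_na=False)
    for col in METRICS_COLUMNS[2:]:
        table[col] = pd.to_numeric(table[col].replace("NA", None), errors="coerce")
    return table


def read_truth(path: str | Path) -> pd.DataFrame:
    """Read a truth table TSV with columns ``protein_id`` and ``true_tags``."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"truth table not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("protein_id", "true_tags"):
        if col not in table.columns:
            raise InputError(f"{path}: truth table missing column {col!r}")
    for cell in table["true_tags"]:
        parse_tags(cell)
    return table


def write_truth(truth: Mapping[str, frozenset], path: str | Path) -> None:
    """Write a truth mapping (id -> tag set) as a deterministic TSV."""
    with open(path, "w") as fh:
        fh.write("protein_id\ttrue_tags\n")
        for pid in truth:
            fh.write(f"{pid}\t{join_tags(truth[pid])}\n")
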