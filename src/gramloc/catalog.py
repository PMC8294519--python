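"""Curated signature and GO-compartment catalogs.

The catalog is configuration, not code: one plain-text accession list per
category (one accession per line, ``#`` comments) plus a GO-term mapping
TSV (``go_id<TAB>tag``).  The nine category names are fixed; an accession
may appear in at most one of the three cell-wall subcategories.

Entries in ``secretion.txt`` may carry an optional second column naming
the non-classical export route the signature diagnoses (``SecA2``,
``Wss/T7SSb`` or ``FEA``); it drives the "-like" pathway annotation for
signature-only secretion calls.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import InputError
from .io_formats import TAGS

log = logging.getLogger(__name__)

#: The fixed category names, in classification precedence order.
CATEGORIES = (
    "secretion",
    "tat",
    "lipoprotein",
    "cw_covalent",
    "cw_noncovalent",
    "cw_spore",
    "surface",
    "pilin_fimbrilin",
    "short_secreted_peptide",
)

CW_CATEGORIES = ("cw_covalent", "cw_noncovalent", "cw_spore")

GO_FILE = "go_compartments.tsv"

#: Pathway subtypes allowed in the secretion list's optional second column.
SECRETION_SUBTYPES = ("SecA2", "Wss/T7SSb", "FEA")


@dataclass(frozen=True)
class SignatureCatalog:
    """Loaded category lists plus the GO-compartment mapping."""

    categories: Mapping[str, frozenset]
    go_compartments: Mapping[str, str]
    secretion_subtypes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(sorted(self.categories)) != tuple(sorted(CATEGORIES)):
            raise InputError(
                f"catalog must have exactly the categories {CATEGORIES}"
            )
        seen: dict[str, str] = {}
        for cat in CW_CATEGORIES:
            for acc in self.categories[cat]:
                if acc in seen:
                    raise InputError(
                        f"accession {acc!r} listed in both {seen[acc]!r} and "
                        f"{cat!r}"
                    )
                seen[acc] = cat
        for go, tag in self.go_compartments.items():
            if tag not in TAGS:
                raise InputError(f"GO mapping {go!r} -> invalid tag {tag!r}")


def _read_accession_file(path: Path, with_subtype: bool) -> tuple[frozenset, dict]:
    accessions: set[str] = set()
    subtypes: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        acc = parts[0].strip()
        accessions.add(acc)
        if len(parts) > 1 and with_subtype:
            subtype = parts[1].strip()
            if subtype not in SECRETION_SUBTYPES:
                raise InputError(
                    f"{path} line {lineno}: unknown secretion subtype "
                    f"{subtype!r}; allowed: {SECRETION_SUBTYPES}"
                )
            subtypes[acc] = subtype
        elif len(parts) > 1:
            raise InputError(
                f"{path} line {lineno}: unexpected extra column {parts[1]!r}"
            )
    return frozenset(accessions), subtypes


def load_catalog(directory: str | Path) -> SignatureCatalog:
    """Load and validate a catalog directory.

    Missing category files are an error; unknown extra files are ignored
    with a warning.  Per-category counts are logged.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"catalog directory not found: {directory}")
    categories: dict[str, frozenset] = {}
    subtypes: dict[str, str] = {}
    expected = {f"{cat}.txt" for cat in CATEGORIES} | {GO_FILE}
    for entry in sorted(directory.iterdir()):
        if entry.name not in expected:
            warnings.warn(f"ignoring unknown catalog file {entry.name!r}")
    for cat in CATEGORIES:
        path = directory / f"{cat}.txt"
        if not path.exists():
            raise InputError(f"missing catalog category file: {path}")
        accessions, subs = _read_accession_file(path, with_subtype=(cat == "secretion"))
        categories[cat] = accessions
        subtypes.update(subs)
        log.debug("catalog category %s: %d accessions", cat, len(accessions))
    go_path = directory / GO_FILE
    if not go_path.exists():
        raise InputError(f"missing GO mapping file: {go_path}")
    go_map: dict[str, str] = {}
    for lineno, raw in enumerate(go_path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputError(f"{go_path} line {lineno}: expected go_id<TAB>tag")
        go_id, tag = parts[0].strip(), parts[1].strip()
        if not go_id.startswith("GO:"):
            raise InputError(f"{go_path} line {lineno}: malformed GO id {go_id!r}")
        go_map[go_id] = tag
    return SignatureCatalog(categories, go_map, subtypes)


def classify_hit(accession: str, catalog: SignatureCatalog) -> str | None:
    """Category of a signature accession, or None if uncatalogued.

    Categories are searched in the fixed precedence order of
    :data:`CATEGORIES`.
    """
    for cat in CATEGORIES:
        if accession in catalog.categories[cat]:
            return cat
    return None


def go_to_tag(go_id: str, catalog: SignatureCatalog) -> str | None:
    """Localization tag hinted by a GO compartment term, or None."""
    return catalog.go_compartments.get(go_id)


def default_catalog_dir() -> Path:
    """Path to the starter catalog shipped with the package."""
    return Path(resources.files("gramloc") / "data" / "catalog")


def load_default_catalog() -> SignatureCatalog:
    return load_catalog(default_catalog_dir())
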