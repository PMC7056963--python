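"""Chemical-gene interaction annotations in the CTD ``chem_gene_ixns`` dialect.

The Comparative Toxicogenomics Database distributes curated chemical-gene
interactions as a tab-separated file whose data rows carry eleven columns::

    ChemicalName  ChemicalID  CasRN  GeneSymbol  GeneID  GeneForms
    Organism  OrganismID  Interaction  InteractionActions  PubMedIDs

This module parses that dialect, filters records to the organisms of
interest (human and mouse by default), and aggregates the surviving rows
into per-chemical gene sets.  Mouse gene symbols are matched to human ones
by case-normalized string identity; no ortholog table is consulted.
"""

from __future__ import annotations

import gzip
import io
import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: NCBI taxonomy IDs kept by default: Homo sapiens and Mus musculus.
DEFAULT_ORGANISMS = frozenset({"9606", "10090"})

#: Column order of the CTD ``chem_gene_ixns`` file.
CTD_COLUMNS = (
    "ChemicalName",
    "ChemicalID",
    "CasRN",
    "GeneSymbol",
    "GeneID",
    "GeneForms",
    "Organism",
    "OrganismID",
    "Interaction",
    "InteractionActions",
    "PubMedIDs",
)


@dataclass(frozen=True)
class ChemGeneRecord:
    """One chemical-gene interaction row after ingest normalization."""

    chemical_name: str
    chemical_id: str
    gene_symbol: str
    gene_id: str = ""
    organism_id: str = ""
    interaction_actions: tuple[str, ...] = ()

    @property
    def chemical_key(self) -> str:
        """Stable chemical identity: the MeSH-style accession when present,
        otherwise the chemical name (names are not unique across CTD
        revisions, so the accession wins)."""
        return self.chemical_id or self.chemical_name


@dataclass(frozen=True)
class ChemicalGeneSet:
    """A chemical's gene set C: the genes it interacts with (set semantics).

    ``original_size`` records the annotated size before any restriction to
    a ranked universe; it equals ``size`` for freshly built sets.
    """

    chemical_key: str
    chemical_name: str
    members: frozenset[str]
    original_size: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.original_size < 0:
            object.__setattr__(self, "original_size", len(self.members))

    @property
    def size(self) -> int:
        return len(self.members)


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def read_ctd(
    path: str | Path,
    organism_filter: Iterable[str] = DEFAULT_ORGANISMS,
    expression_only: bool = False,
) -> list[ChemGeneRecord]:
    """Parse a CTD-dialect interaction file into normalized records.

    Lines starting with ``#`` are comments/header and skipped.  Data rows
    with fewer than 11 tab-separated fields are skipped with a counted
    warning.  Only rows whose OrganismID is in ``organism_filter`` are kept
    (rows with an empty OrganismID are dropped).  With ``expression_only``,
    a row survives only if some InteractionActions token contains the
    substring ``"expression"``.  Gene symbols are uppercased on ingest.
    """
    organisms = frozenset(organism_filter)
    records: list[ChemGeneRecord] = []
    n_short = 0
    try:
        handle = _open_text(path)
    except OSError as exc:
        raise InputError(f"cannot read annotation file {path!r}: {exc}") from exc
    with handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(CTD_COLUMNS):
                n_short += 1
                logger.warning(
                    "%s:%d: %d fields (expected >= %d), row skipped",
                    path, lineno, len(fields), len(CTD_COLUMNS),
                )
                continue
            (name, chem_id, _casrn, symbol, gene_id, _forms,
             _organism, organism_id, _ixn, actions, _pmids) = fields[:11]
            symbol = symbol.strip().upper()
            if not symbol or not (chem_id.strip() or name.strip()):
                n_short += 1
                logger.warning("%s:%d: empty chemical or gene field, row skipped",
                               path, lineno)
                continue
            if organism_id.strip() not in organisms:
                continue
            tokens = tuple(t for t in actions.strip().split("|") if t)
            if expression_only and not any("expression" in t for t in tokens):
                continue
            records.append(
                ChemGeneRecord(
                    chemical_name=name.strip(),
                    chemical_id=chem_id.strip(),
                    gene_symbol=symbol,
                    gene_id=gene_id.strip(),
                    organism_id=organism_id.strip(),
                    interaction_actions=tokens,
                )
            )
    if n_short:
        logger.warning("%s: skipped %d malformed rows", path, n_short)
    logger.info("%s: %d interaction records kept", path, len(records))
    return records


def build_gene_sets(
    records: Sequence[ChemGeneRecord],
    min_size: int = 5,
    max_size: int | None = None,
) -> dict[str, ChemicalGeneSet]:
    """Group records by chemical into gene sets, applying size bounds.

    Duplicate (chemical, gene) pairs collapse to a single membership.  The
    result is independent of the input record order: membership uses set
    semantics and the chemical name attached to a key is the
    lexicographically smallest name observed for it.
    """
    if min_size < 1:
        raise ConfigurationError(f"min_size must be >= 1, got {min_size}")
    if max_size is not None and max_size < min_size:
        raise ConfigurationError(
            f"max_size ({max_size}) must be >= min_size ({min_size})"
        )
    members: dict[str, set[str]] = defaultdict(set)
    names: dict[str, str] = {}
    for rec in records:
        key = rec.chemical_key
        members[key].add(rec.gene_symbol)
        name = rec.chemical_name or key
        if key not in names or name < names[key]:
            names[key] = name
    out: dict[str, ChemicalGeneSet] = {}
    for key in sorted(members):
        genes = members[key]
        if len(genes) < min_size or (max_size is not None and len(genes) > max_size):
            continue
        out[key] = ChemicalGeneSet(
            chemical_key=key, chemical_name=names[key], members=frozenset(genes)
        )
    return out


def restrict_to_universe(
    gene_set: ChemicalGeneSet, universe: Iterable[str]
) -> ChemicalGeneSet:
    """Intersect a gene set with the ranked-universe gene symbols.

    The enrichment score is only defined over genes present in the ranked
    list, so membership outside it is discarded.  The returned set keeps
    the pre-restriction size in ``original_size``; an empty restricted set
    is legal here (the pipeline skips it with a reason downstream).
    """
    universe = frozenset(universe)
    if not universe:
        raise ConfigurationError("universe must be non-empty")
    return replace(
        gene_set,
        members=gene_set.members & universe,
        original_size=gene_set.original_size,
    )


def write_gmt(
    gene_sets: Mapping[str, ChemicalGeneSet], path: str | Path
) -> None:
    """Export gene sets in GMT format (key, description=name, members)."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(gene_sets):
            gs = gene_sets[key]
            fh.write("\t".join([gs.chemical_key, gs.chemical_name,
                                *sorted(gs.members)]) + "\n")
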