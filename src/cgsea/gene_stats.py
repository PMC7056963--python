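"""Gene-level association statistics: ingest, de-duplication, ranking.

Accepts either FUSION-style TWAS output (whitespace-delimited, column-name
driven: a gene identifier column ``ID`` or ``GENE`` plus ``TWAS.Z``) or a
generic two-column gene/statistic table.  One gene may carry several
statistics when multiple expression panels are analysed; a collapse policy
reduces them to one value per gene before ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

RANKING_MODES = ("signed", "absolute")
COLLAPSE_POLICIES = ("max_abs", "mean", "first")

_GENE_COLUMNS = ("ID", "GENE")  # accepted FUSION gene-identifier headers
_STAT_COLUMN = "TWAS.Z"


@dataclass(frozen=True)
class GeneStat:
    """One gene's association statistic (a TWAS Z-score or analogue)."""

    gene_symbol: str
    statistic: float
    source_panel: str = ""


class RankedGeneList:
    """Genes ordered by their statistic: the list L^s walked by the
    running-sum score.

    Parameters
    ----------
    genes, stats
        Parallel sequences; genes must be unique.
    ranking_mode
        ``"signed"`` if the order key is the raw statistic, ``"absolute"``
        if it is the magnitude.  Informational; the constructor does not
        re-sort.
    """

    def __init__(self, genes: Sequence[str], stats: Sequence[float],
                 ranking_mode: str = "signed") -> None:
        self.genes = tuple(genes)
        self.stats = np.asarray(stats, dtype=float)
        self.ranking_mode = ranking_mode
        if len(self.genes) != self.stats.size:
            raise ValueError("genes and stats must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked gene list contains duplicate symbols")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def N(self) -> int:
        return len(self.genes)

    def positions(self, members: Iterable[str]) -> np.ndarray:
        """Sorted rank positions (0-based) of the given genes; symbols
        absent from the list are ignored."""
        idx = [self._index[g] for g in members if g in self._index]
        return np.asarray(sorted(idx), dtype=np.intp)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __len__(self) -> int:
        return self.N


def _frame_to_stats(df: pd.DataFrame, gene_col: str, stat_col: str,
                    panel: pd.Series, origin: str) -> list[GeneStat]:
    z = pd.to_numeric(df[stat_col], errors="coerce")
    z = z.where(np.isfinite(z))
    bad = z.isna()
    if bad.any():
        logger.warning("%s: skipped %d rows with missing/non-numeric %s",
                       origin, int(bad.sum()), stat_col)
    out = []
    for sym, val, pan in zip(df[gene_col], z, panel):
        if pd.isna(val):
            continue
        sym = str(sym).strip().upper()
        if not sym:
            continue
        out.append(GeneStat(sym, float(val), str(pan)))
    return out


def read_fusion_twas(paths: Sequence[str | Path] | str | Path) -> list[GeneStat]:
    """Read FUSION TWAS output files (column-name driven, not positional).

    Each file needs a gene-identifier column (``ID`` preferred, ``GENE``
    accepted) and a ``TWAS.Z`` column; rows with missing or non-numeric Z
    are skipped with a counted warning.  The source panel is taken from a
    ``PANEL`` column when present, else the file name.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    stats: list[GeneStat] = []
    for path in paths:
        try:
            df = pd.read_csv(path, sep=r"\s+", dtype=str)
        except (OSError, pd.errors.ParserError) as exc:
            raise InputError(f"cannot read TWAS file {path!r}: {exc}") from exc
        gene_col = next((c for c in _GENE_COLUMNS if c in df.columns), None)
        if gene_col is None or _STAT_COLUMN not in df.columns:
            missing = ([] if gene_col else ["ID/GENE"]) + \
                      ([] if _STAT_COLUMN in df.columns else [_STAT_COLUMN])
            raise InputError(
                f"{path}: header lacks required column(s): {', '.join(missing)}"
            )
        panel = df["PANEL"] if "PANEL" in df.columns \
            else pd.Series([Path(path).name] * len(df))
        stats.extend(_frame_to_stats(df, gene_col, _STAT_COLUMN, panel, str(path)))
    if not stats:
        raise InputError("no usable gene statistics after filtering")
    return stats


def read_generic_stats(path: str | Path) -> list[GeneStat]:
    """Read a two-column gene/statistic TSV with optional header.

    The header is auto-detected: a first row whose second field is not
    numeric is treated as a header and skipped.  Non-numeric statistics on
    data rows are skipped with a counted warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read statistics file {path!r}: {exc}") from exc
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["gene", "stat"]
    first = pd.to_numeric(df["stat"].iloc[:1], errors="coerce")
    if len(df) and first.isna().iloc[0]:
        df = df.iloc[1:]
    panel = pd.Series([Path(path).name] * len(df), index=df.index)
    stats = _frame_to_stats(df, "gene", "stat", panel, str(path))
    if not stats:
        raise InputError("no usable gene statistics after filtering")
    return stats


def collapse_duplicates(stats: Sequence[GeneStat],
                        policy: str = "max_abs") -> list[GeneStat]:
    """Reduce multiple statistics per gene to one.

    ``max_abs`` keeps the entry with the largest magnitude (first
    encountered on ties), ``mean`` averages the values, ``first`` keeps
    the first occurrence.  Output order is first occurrence of each gene.
    """
    if policy not in COLLAPSE_POLICIES:
        raise ConfigurationError(
            f"unknown collapse policy {policy!r}; choose from {COLLAPSE_POLICIES}"
        )
    grouped: dict[str, list[GeneStat]] = {}
    order: list[str] = []
    for s in stats:
        if s.gene_symbol not in grouped:
            grouped[s.gene_symbol] = []
            order.append(s.gene_symbol)
        grouped[s.gene_symbol].append(s)
    out = []
    for sym in order:
        entries = grouped[sym]
        if policy == "first" or len(entries) == 1:
            out.append(entries[0])
        elif policy == "max_abs":
            out.append(max(entries, key=lambda e: abs(e.statistic)))
        else:  # mean
            mean = float(np.mean([e.statistic for e in entries]))
            out.append(GeneStat(sym, mean, entries[0].source_panel))
    return out


def rank_genes(stats: Sequence[GeneStat],
               ranking_mode: str = "signed") -> RankedGeneList:
    """Sort genes by their statistic from maximum to minimum.

    ``signed`` sorts on the raw value L_i (so strongly negative genes sit
    at the bottom); ``absolute`` sorts on |L_i|.  Ties break by ascending
    gene symbol so results are bit-reproducible across platforms.
    """
    if ranking_mode not in RANKING_MODES:
        raise ConfigurationError(
            f"unknown ranking mode {ranking_mode!r}; choose from {RANKING_MODES}"
        )
    if not stats:
        raise InputError("cannot rank an empty statistic table")
    symbols = [s.gene_symbol for s in stats]
    if len(set(symbols)) != len(symbols):
        raise InputError(
            "duplicate gene symbols in statistics; run collapse_duplicates first"
        )
    key = (lambda s: (-s.statistic, s.gene_symbol)) if ranking_mode == "signed" \
        else (lambda s: (-abs(s.statistic), s.gene_symbol))
    ordered = sorted(stats, key=key)
    return RankedGeneList(
        [s.gene_symbol for s in ordered],
        [s.statistic for s in ordered],
        ranking_mode=ranking_mode,
    )
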