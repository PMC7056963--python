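"""Weighted Kolmogorov-Smirnov-like enrichment scoring with a gene-label
permutation null.

The enrichment score of a chemical's gene set C against a ranked list of N
gene statistics L^s is

    ES_C = max_{1<=j<=N} [ sum_{g_i in C, i<=j} |L_i^s|^w / NR
                           - sum_{g_i not in C, i<=j} 1 / (N - N_C) ]

with NR = sum_{g_i in C} |L_i^s|^w: the running sum rises by the gene's
weighted statistic share at members and falls by a constant at
non-members, and the full walk returns exactly to zero.  The null is
obtained by shuffling which gene identity carries which ranked statistic;
the observed ES is standardized by the null's mean and standard deviation
(NES), and the empirical P is the add-one-corrected upper-tail fraction of
null NES values at or above the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .ctd import ChemicalGeneSet
from .errors import (
    ConfigurationError,
    DegenerateNullError,
    DegenerateSetError,
    DegenerateWeightError,
    InputError,
)
from .gene_stats import RANKING_MODES, RankedGeneList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentConfig:
    """Run parameters.

    w
        Weight exponent on |statistic| for hit increments; 1 by default
        (0 recovers the classic unweighted KS-like statistic).
    permutations
        Number of gene-label shuffles P for the null; 5000 by default.
    seed
        Seed for the single RNG driving all shuffles.
    ranking_mode
        ``"signed"`` or ``"absolute"`` (see :func:`~cgsea.gene_stats.rank_genes`).
    min_set_size / max_set_size
        Bounds on annotated set size; sets outside them are not tested.
    per_set_null
        If true, each chemical gets its own P independent shuffles instead
        of sharing one shuffle per permutation round across chemicals.
    """

    w: float = 1.0
    permutations: int = 5000
    seed: int = 0
    ranking_mode: str = "signed"
    min_set_size: int = 5
    max_set_size: int | None = None
    per_set_null: bool = False

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ConfigurationError(f"weight exponent must be >= 0, got {self.w}")
        if self.permutations < 1:
            raise ConfigurationError(
                f"permutation count must be >= 1, got {self.permutations}"
            )
        if self.min_set_size < 1:
            raise ConfigurationError(
                f"min_set_size must be >= 1, got {self.min_set_size}"
            )
        if self.max_set_size is not None and self.max_set_size < self.min_set_size:
            raise ConfigurationError("max_set_size must be >= min_set_size")
        if self.ranking_mode not in RANKING_MODES:
            raise ConfigurationError(f"unknown ranking mode {self.ranking_mode!r}")


@dataclass(frozen=True)
class NullDistribution:
    """Per-chemical permutation null: raw and standardized ES values."""

    es_null: np.ndarray
    nes_null: np.ndarray
    mean_es: float
    sd_es: float


@dataclass(frozen=True)
class EnrichmentResult:
    """One chemical's enrichment outcome."""

    chemical_key: str
    chemical_name: str
    set_size_annotated: int
    set_size_used: int
    es: float
    nes: float
    p_empirical: float
    q_bh: float = field(default=float("nan"))


# ---------------------------------------------------------------------------
# Enrichment score


def _hit_weights(stats: np.ndarray, w: float) -> np.ndarray:
    # |L|^w; note 0**0 == 1, so w=0 gives unit hit weights as intended
    return np.abs(stats) ** w


def _increments(stats_pow: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-position running-sum increments for one membership mask."""
    n = mask.size
    n_c = int(mask.sum())
    if n_c == 0 or n_c == n:
        raise DegenerateSetError(
            f"set has {n_c} of {n} universe genes; ES is undefined"
        )
    nr = float(stats_pow[mask].sum())
    if nr == 0.0:
        raise DegenerateWeightError(
            "all member statistics are zero; hit normalizer NR = 0"
        )
    inc = np.where(mask, stats_pow / nr, -1.0 / (n - n_c))
    return inc


def running_sum(ranked: RankedGeneList, members: Iterable[str],
                w: float = 1.0) -> np.ndarray:
    """The full running-sum trajectory over the ranked list (length N).

    Useful for enrichment plots; ``compute_es`` is its maximum.
    """
    mask = np.zeros(ranked.N, dtype=bool)
    mask[ranked.positions(members)] = True
    stats_pow = _hit_weights(ranked.stats, w)
    return np.cumsum(_increments(stats_pow, mask))


def compute_es(ranked: RankedGeneList, members: Iterable[str],
               w: float = 1.0) -> float:
    """The enrichment score ES of one gene set: max of the running sum.

    The maximum is taken over the first N-1 prefixes of the walk: the full
    walk ends at exactly zero by construction (hit mass 1 minus miss mass
    1), so the final prefix carries no information, and excluding it lets
    a set concentrated at the bottom of the ranking score negative instead
    of being clipped to zero.  ES therefore lies in (-1, 1].

    Requires at least one member and one non-member inside the ranked
    universe; raises :class:`DegenerateSetError` otherwise, and
    :class:`DegenerateWeightError` when every member statistic is exactly
    zero with w > 0.
    """
    return float(np.max(running_sum(ranked, members, w)[:-1]))


def _es_matrix(stats_pow: np.ndarray, masks: np.ndarray,
               nr: np.ndarray, miss: np.ndarray) -> np.ndarray:
    """Vectorized ES for S sets at once; masks is (S, N) boolean."""
    inc = np.where(masks, stats_pow[np.newaxis, :] / nr[:, np.newaxis],
                   -miss[:, np.newaxis])
    # final prefix is identically zero; exclude it (see compute_es)
    return np.cumsum(inc, axis=1)[:, :-1].max(axis=1)


# ---------------------------------------------------------------------------
# Permutation null


def permute_null(
    ranked: RankedGeneList,
    gene_sets: Mapping[str, ChemicalGeneSet],
    config: EnrichmentConfig,
) -> dict[str, np.ndarray]:
    """Null ES distributions by shuffling gene labels.

    Shuffling which gene carries which ranked statistic is equivalent to
    permuting the member positions, so each permutation round draws one
    random position permutation and re-scores every set against it.  By
    default the same shuffle serves all chemicals within a round (the
    per-set marginal null is unchanged and the cost drops from
    O(chemicals x P x N) to O(P x N) shuffles); ``config.per_set_null``
    switches to fully independent shuffles per chemical.

    Returns a mapping from chemical key to the P null ES values, in a
    deterministic order (chemicals sorted by key) for a given seed.
    """
    if not gene_sets:
        return {}
    keys = sorted(gene_sets)
    n = ranked.N
    masks = np.zeros((len(keys), n), dtype=bool)
    for row, key in enumerate(keys):
        pos = ranked.positions(gene_sets[key].members)
        if pos.size == 0 or pos.size == n:
            raise DegenerateSetError(
                f"{key}: {pos.size} of {n} universe genes; cannot permute"
            )
        masks[row, pos] = True
    stats_pow = _hit_weights(ranked.stats, config.w)
    n_c = masks.sum(axis=1)
    miss = 1.0 / (n - n_c)
    p = config.permutations
    rng = np.random.default_rng(config.seed)
    es_null = np.empty((p, len(keys)))
    if config.per_set_null:
        for row in range(len(keys)):
            for t in range(p):
                perm = rng.permutation(n)
                m = masks[row:row + 1, perm]
                nr_row = np.array([stats_pow[m[0]].sum()])
                es_null[t, row] = _es_matrix(stats_pow, m, nr_row,
                                             miss[row:row + 1])[0]
    else:
        for t in range(p):
            perm = rng.permutation(n)
            m = masks[:, perm]
            nr = m @ stats_pow
            es_null[t] = _es_matrix(stats_pow, m, nr, miss)
    return {key: es_null[:, row].copy() for row, key in enumerate(keys)}


# ---------------------------------------------------------------------------
# Normalization and inference


def normalize_es(
    es_obs: float, es_null: Sequence[float]
) -> tuple[float, np.ndarray]:
    """Standardize the observed ES and its null by the null mean and SD.

    The standard deviation uses the n-1 (sample) divisor; a null with zero
    spread raises :class:`DegenerateNullError`.
    """
    es_null = np.asarray(es_null, dtype=float)
    if es_null.size < 2:
        raise ConfigurationError("need at least 2 null values to normalize")
    mean = float(es_null.mean())
    sd = float(es_null.std(ddof=1))
    # identical null values leave only rounding noise around the mean
    if sd <= 1e-12 * max(1.0, abs(mean)):
        raise DegenerateNullError("permutation null has zero standard deviation")
    return (es_obs - mean) / sd, (es_null - mean) / sd


def empirical_p(nes_obs: float, nes_null: Sequence[float]) -> float:
    """Upper-tail permutation p-value with add-one correction:
    (1 + #{null >= observed}) / (P + 1), never zero."""
    nes_null = np.asarray(nes_null, dtype=float)
    if nes_null.size < 1:
        raise ConfigurationError("empty null distribution")
    count = int(np.sum(nes_null >= nes_obs))
    return (1 + count) / (nes_null.size + 1)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted values, same order as the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
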