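"""End-to-end orchestration: annotations + gene statistics -> results table.

``run_cgsea`` wires the stages together (parse annotations, build gene
sets, ingest and rank statistics, restrict each set to the ranked
universe, score, permute, normalize, test, adjust) and accounts for every
chemical: each one in the annotation input lands exactly once in either
the results or the skipped list (with a reason).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import __version__
from .ctd import (
    DEFAULT_ORGANISMS,
    build_gene_sets,
    read_ctd,
    restrict_to_universe,
)
from .enrichment import (
    EnrichmentConfig,
    EnrichmentResult,
    bh_fdr,
    compute_es,
    empirical_p,
    normalize_es,
    permute_null,
)
from .errors import DegenerateNullError, DegenerateWeightError, InputError
from .gene_stats import (
    collapse_duplicates,
    rank_genes,
    read_fusion_twas,
    read_generic_stats,
)

logger = logging.getLogger(__name__)

RESULT_COLUMNS = (
    "chemical_id", "chemical_name", "set_size_annotated", "set_size_used",
    "es", "nes", "p_empirical", "q_bh",
)


@dataclass(frozen=True)
class SkippedChemical:
    chemical_key: str
    chemical_name: str
    set_size_annotated: int
    reason: str


@dataclass
class RunManifest:
    """Provenance record written next to the results table."""

    annotation_path: str
    annotation_sha256: str
    stats_paths: list[str]
    stats_sha256: list[str]
    config: dict
    n_genes_ranked: int
    n_chemicals_annotated: int
    n_chemicals_tested: int
    n_chemicals_skipped: int
    skip_reasons: dict[str, int]
    wall_time_s: float
    version: str = __version__


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_stats(path: str | Path, stats_format: str):
    """Dispatch on declared or sniffed format (FUSION header has TWAS.Z)."""
    if stats_format == "fusion":
        return read_fusion_twas(path)
    if stats_format == "generic":
        return read_generic_stats(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if "TWAS.Z" in header.split():
        return read_fusion_twas(path)
    return read_generic_stats(path)


def run_cgsea(
    annotation_path: str | Path,
    stats_paths: Sequence[str | Path] | str | Path,
    config: EnrichmentConfig | None = None,
    *,
    organism_filter: Iterable[str] = DEFAULT_ORGANISMS,
    expression_only: bool = False,
    collapse_policy: str = "max_abs",
    stats_format: str = "auto",
) -> tuple[list[EnrichmentResult], list[SkippedChemical], RunManifest]:
    """Run the full chemical-enrichment analysis.

    Returns results sorted by empirical P ascending (ties by |NES|
    descending, then chemical key), the skipped-chemical list, and a run
    manifest.  Raises :class:`InputError` if no chemical is testable.
    """
    t0 = time.monotonic()
    config = config or EnrichmentConfig()
    if isinstance(stats_paths, (str, Path)):
        stats_paths = [stats_paths]

    records = read_ctd(annotation_path, organism_filter=organism_filter,
                       expression_only=expression_only)
    # build with no size bounds so out-of-bounds chemicals can be reported
    all_sets = build_gene_sets(records, min_size=1, max_size=None)
    logger.info("annotations: %d chemicals with >=1 gene", len(all_sets))

    stats = []
    for path in stats_paths:
        stats.extend(_read_stats(path, stats_format))
    collapsed = collapse_duplicates(stats, policy=collapse_policy)
    ranked = rank_genes(collapsed, ranking_mode=config.ranking_mode)
    logger.info("ranked %d unique genes", ranked.N)

    results_raw: list[EnrichmentResult] = []
    skipped: list[SkippedChemical] = []
    testable = {}
    for key in sorted(all_sets):
        gs = all_sets[key]

        def skip(reason: str) -> None:
            skipped.append(SkippedChemical(key, gs.chemical_name,
                                           gs.original_size, reason))

        if gs.size < config.min_set_size or (
            config.max_set_size is not None and gs.size > config.max_set_size
        ):
            skip("set_size_out_of_bounds")
            continue
        restricted = restrict_to_universe(gs, ranked.genes)
        if restricted.size == 0:
            skip("empty_after_restriction")
            continue
        if restricted.size == ranked.N:
            skip("set_spans_universe")
            continue
        testable[key] = restricted

    es_obs: dict[str, float] = {}
    for key, gs in list(testable.items()):
        try:
            es_obs[key] = compute_es(ranked, gs.members, config.w)
        except DegenerateWeightError:
            skipped.append(SkippedChemical(key, gs.chemical_name,
                                           gs.original_size, "zero_hit_weight"))
            del testable[key]

    null_by_key = permute_null(ranked, testable, config)
    for key in sorted(testable):
        gs = testable[key]
        try:
            nes, nes_null = normalize_es(es_obs[key], null_by_key[key])
        except DegenerateNullError:
            skipped.append(SkippedChemical(key, gs.chemical_name,
                                           gs.original_size, "degenerate_null"))
            continue
        results_raw.append(EnrichmentResult(
            chemical_key=key,
            chemical_name=gs.chemical_name,
            set_size_annotated=gs.original_size,
            set_size_used=gs.size,
            es=es_obs[key],
            nes=nes,
            p_empirical=empirical_p(nes, nes_null),
        ))

    if not results_raw:
        raise InputError("no testable chemicals after filtering and restriction")

    q = bh_fdr([r.p_empirical for r in results_raw])
    results = [dataclasses.replace(r, q_bh=float(qi))
               for r, qi in zip(results_raw, q)]
    results.sort(key=lambda r: (r.p_empirical, -abs(r.nes), r.chemical_key))

    reasons: dict[str, int] = {}
    for s in skipped:
        reasons[s.reason] = reasons.get(s.reason, 0) + 1
    manifest = RunManifest(
        annotation_path=str(annotation_path),
        annotation_sha256=_sha256(annotation_path),
        stats_paths=[str(p) for p in stats_paths],
        stats_sha256=[_sha256(p) for p in stats_paths],
        config=dataclasses.asdict(config),
        n_genes_ranked=ranked.N,
        n_chemicals_annotated=len(all_sets),
        n_chemicals_tested=len(results),
        n_chemicals_skipped=len(skipped),
        skip_reasons=reasons,
        wall_time_s=round(time.monotonic() - t0, 3),
    )
    assert manifest.n_chemicals_tested + manifest.n_chemicals_skipped \
        == manifest.n_chemicals_annotated
    logger.info("tested %d chemicals, skipped %d, %.1fs",
                len(results), len(skipped), manifest.wall_time_s)
    return results, skipped, manifest


def write_results(
    results: Sequence[EnrichmentResult],
    skipped: Sequence[SkippedChemical],
    manifest: RunManifest,
    out_prefix: str | Path,
) -> dict[str, Path]:
    """Write the results TSV, skipped-chemicals TSV, and manifest JSON.

    Floats are printed at 6 significant digits.  Returns the paths keyed
    by role.
    """
    out_prefix = Path(out_prefix)
    if out_prefix.parent != Path("."):
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": Path(f"{out_prefix}.results.tsv"),
        "skipped": Path(f"{out_prefix}.skipped.tsv"),
        "manifest": Path(f"{out_prefix}.manifest.json"),
    }
    try:
        with open(paths["results"], "w", encoding="utf-8") as fh:
            fh.write("\t".join(RESULT_COLUMNS) + "\n")
            for r in results:
                fh.write("\t".join([
                    r.chemical_key, r.chemical_name,
                    str(r.set_size_annotated), str(r.set_size_used),
                    format(r.es, ".6g"), format(r.nes, ".6g"),
                    format(r.p_empirical, ".6g"), format(r.q_bh, ".6g"),
                ]) + "\n")
        with open(paths["skipped"], "w", encoding="utf-8") as fh:
            fh.write("chemical_id\tchemical_name\tset_size_annotated\treason\n")
            for s in skipped:
                fh.write(f"{s.chemical_key}\t{s.chemical_name}\t"
                         f"{s.set_size_annotated}\t{s.reason}\n")
        with open(paths["manifest"], "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(manifest), fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise InputError(f"cannot write outputs at {out_prefix}: {exc}") from exc
    return paths
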