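"""Synthetic inputs with known structure for testing and calibration.

Emits a chemical-gene annotation file in the CTD dialect and a matching
generic gene-statistic table, plus a truth table naming which chemicals
carry a planted signal.  Non-planted gene statistics are standard normal;
planting adds a constant shift to the statistics of a chemical's member
genes before ranking, which concentrates them near the top of a signed
ranking.  Everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic study.

    Defaults describe the planted-signal benchmark used throughout the
    test suite: 1000 genes, 50 chemicals with 20-gene sets, one planted
    chemical whose members receive a +2 shift on their Z-scores.
    """

    n_genes: int = 1000
    n_chemicals: int = 50
    set_size_range: tuple[int, int] = (20, 20)
    planted_chemical_count: int = 1
    effect_delta: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi <= self.n_genes - 1):
            raise ConfigurationError(
                f"set sizes must satisfy 1 <= min <= max <= n_genes-1, "
                f"got {self.set_size_range} with n_genes={self.n_genes}"
            )
        if not (0 <= self.planted_chemical_count <= self.n_chemicals):
            raise ConfigurationError(
                "planted_chemical_count must be between 0 and n_chemicals"
            )
        if self.n_genes < 2 or self.n_chemicals < 1:
            raise ConfigurationError("need >= 2 genes and >= 1 chemical")


@dataclass(frozen=True)
class FixturePaths:
    annotations: Path
    stats: Path
    truth: Path


def _gene_symbol(i: int) -> str:
    return f"G{i + 1:05d}"


def _chemical(i: int) -> tuple[str, str]:
    # MeSH-style accession and a name; both synthetic
    return f"D{i + 1:06d}", f"CHEMICAL{i + 1:04d}"


def make_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixturePaths:
    """Generate annotation, statistics, and truth files under ``out_dir``.

    The annotation file parses through :func:`cgsea.ctd.read_ctd` with
    zero skipped rows (all rows are human, tagged as expression
    interactions).  Planted chemicals are the first
    ``planted_chemical_count`` chemicals; overlapping planted sets shift
    shared genes once per planted membership.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    stats = rng.standard_normal(spec.n_genes)
    lo, hi = spec.set_size_range
    members: list[np.ndarray] = []
    for _ in range(spec.n_chemicals):
        size = int(rng.integers(lo, hi + 1))
        members.append(np.sort(rng.choice(spec.n_genes, size=size,
                                          replace=False)))
    for c in range(spec.planted_chemical_count):
        stats[members[c]] += spec.effect_delta

    paths = FixturePaths(
        annotations=out_dir / "annotations.tsv",
        stats=out_dir / "gene_stats.tsv",
        truth=out_dir / "truth.tsv",
    )
    with open(paths.annotations, "w", encoding="utf-8") as fh:
        fh.write("# Synthetic chemical-gene interactions "
                 "(CTD chem_gene_ixns column order)\n")
        fh.write("# ChemicalName\tChemicalID\tCasRN\tGeneSymbol\tGeneID\t"
                 "GeneForms\tOrganism\tOrganismID\tInteraction\t"
                 "InteractionActions\tPubMedIDs\n")
        for c in range(spec.n_chemicals):
            chem_id, chem_name = _chemical(c)
            for g in members[c]:
                fh.write("\t".join([
                    chem_name, chem_id, "", _gene_symbol(int(g)),
                    str(int(g) + 1), "gene", "Homo sapiens", "9606",
                    f"{chem_name} affects expression of {_gene_symbol(int(g))}",
                    "increases^expression", "",
                ]) + "\n")
    with open(paths.stats, "w", encoding="utf-8") as fh:
        fh.write("gene\tzscore\n")
        for g in range(spec.n_genes):
            fh.write(f"{_gene_symbol(g)}\t{stats[g]:.10g}\n")
    with open(paths.truth, "w", encoding="utf-8") as fh:
        fh.write("chemical_id\tchemical_name\teffect_delta\tset_size\n")
        for c in range(spec.planted_chemical_count):
            chem_id, chem_name = _chemical(c)
            fh.write(f"{chem_id}\t{chem_name}\t{spec.effect_delta:.10g}\t"
                     f"{members[c].size}\n")
    return paths
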