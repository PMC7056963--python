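# Methods

## Model and procedure

`cgsea` tests, for each chemical, whether the genes it interacts with
are over-represented at the top of a gene list ranked by a genome-wide
association statistic. The inputs are (a) a chemical–gene interaction
table in the CTD `chem_gene_ixns` dialect and (b) one or more gene-level
statistic tables (FUSION TWAS output or a generic two-column TSV). The
statistic is treated as exchangeable across genes under the null: the
permutation scheme shuffles which gene identity carries which ranked
statistic, which breaks the set-membership/statistic association while
preserving the statistic distribution and the set sizes. This is a
*gene-label* permutation; it does not model inter-gene correlation
(e.g. co-regulation or LD leakage between neighbouring genes' TWAS
scores), which is the main caveat when interpreting P values on real
data.

The score walks the ranked list L^s of N statistics, rising by
|L_i^s|^w / N_R at members of the chemical's set C (N_R = Σ_C |L_i^s|^w)
and falling by 1/(N−N_C) at non-members; ES is the maximum of the walk.
Because hit mass and miss mass both total exactly one, the walk always
returns to zero at the last gene. We therefore take the maximum over
the first N−1 prefixes: the final prefix is identically zero and
carries no information, and excluding it lets a set concentrated at the
bottom of the ranking score negative (ES ∈ (−1, 1]) instead of being
clipped to zero. The statistic remains one-sided — only the maximum of
the walk is taken, never the maximum deviation — so the test detects
enrichment at the top of the ranking.

Per chemical, the observed ES is standardized by the mean and sample
standard deviation (n−1 divisor; immaterial at the default P = 5000) of
its permutation null, the null is standardized the same way, and the
empirical P is (1 + #{null NES ≥ observed NES}) / (P + 1). The add-one
correction keeps P strictly positive with floor 1/(P+1); at P = 5000
that floor is ≈ 0.0002. Because standardization is per chemical and
monotone, counting exceedances on NES or on raw ES gives the same P; we
count on NES. Benjamini–Hochberg adjustment across chemicals (via
statsmodels) is reported as a convenience column.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `w` | 1.0 | weight exponent on \|statistic\| for hit increments; 0 recovers the classic unweighted KS-like statistic, larger values emphasize extreme genes |
| `permutations` | 5000 | gene-label shuffles per run; sets the P floor 1/(P+1) |
| `seed` | 0 | seed of the single RNG driving all shuffles |
| `ranking_mode` | `signed` | sort key: raw statistic (signed) or magnitude (absolute) |
| `min_set_size` / `max_set_size` | 5 / unbounded | annotated-size bounds; tiny sets give coarse, unstable nulls |
| `collapse_policy` | `max_abs` | how duplicate genes across tissue panels merge: strongest signal, mean, or first seen |
| organism filter | 9606, 10090 | NCBI taxonomy IDs kept from the annotation file (human, mouse) |
| `expression_only` | off | restrict annotation rows to interactions whose action string mentions expression |
| `per_set_null` | off | independent shuffles per chemical instead of one shared shuffle per round |

Signed ranking follows the sorted-list definition literally; with it, a
set whose genes concentrate at the *negative* extreme lands at the
bottom and scores a negative ES rather than a significant one. The
`absolute` mode is provided for users who want two-tailed sensitivity;
the choice is a modelling decision, not a tuning knob.

Mouse gene symbols are matched to human ones by case-normalized string
identity only; no ortholog table is consulted. This is a documented
limitation: symbols that differ between the species are silently
treated as distinct genes.

## Numerical and design choices

- **Shared null across chemicals.** Each permutation round draws one
  random label permutation and re-scores every set against it. Per set,
  the marginal null is identical to independent shuffling (the null of a
  set depends only on where its members land), while the shuffle cost
  drops from O(chemicals × P × N) to O(P × N). P values of different
  chemicals become weakly dependent within a run; `per_set_null`
  restores full independence at the original cost.
- **Chemical identity.** Sets are keyed on the MeSH-style ChemicalID
  when present, else the chemical name; both are reported.
- **Ties and ordering.** Ranking ties break by ascending gene symbol;
  result rows sort by empirical P, then |NES| descending, then chemical
  key; chemicals are processed in sorted-key order. Together with the
  single seeded generator this makes outputs byte-identical across runs
  and platforms.
- **Degenerate cases.** A set with no members in the ranked universe,
  or spanning the whole universe, or with all-zero member statistics
  (N_R = 0), or with a zero-spread null is excluded from the results
  and reported in the skipped table with a reason, rather than failing
  the run. Rows with missing or non-numeric statistics, and malformed
  annotation rows, are skipped with counted warnings.
- **Zero-spread detection.** The null SD is compared against a 1e-12
  relative tolerance because identical ES values leave rounding noise
  around their mean.

## Synthetic data

The fixture generator emulates the structure of a real study without
any download: gene statistics are standard normal (the approximate null
behaviour of TWAS Z-scores), chemicals draw member sets uniformly at
random, and a planted chemical's members receive a constant additive
shift δ before ranking — the simplest mechanism that concentrates a set
at the top of a signed ranking. Defaults (1000 genes, 50 chemicals,
20-gene sets, one planted chemical with δ = 2) are the benchmark
conditions used throughout the test suite. The generator does **not**
emulate inter-gene correlation, heavy-tailed or inflated statistics,
set-size heterogeneity of real CTD annotations, or ortholog ambiguity;
passing tests therefore establish correctness and calibration of the
algorithm under exchangeability, not robustness to those real-data
features.

Problem sizes in the test and acceptance runs (e.g. 500 permutations
and 20 replicates for the calibration and power studies, 5000
permutations for the floor check) were chosen so the whole suite
completes in seconds while leaving the binomial tolerances of the
checks meaningful.

## Known limitations

- Gene-label permutation ignores inter-gene correlation; P values on
  real TWAS input are anti-conservative to the extent that member genes
  are co-located or co-regulated.
- No ortholog mapping beyond symbol-case normalization.
- The signed default cannot flag bottom-concentrated (protective-like)
  sets as significant; use `absolute` ranking if that is the question.
- Leading-edge gene extraction and enrichment plots are out of scope;
  `running_sum` exposes the trajectory for ad-hoc plotting only.
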