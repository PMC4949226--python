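# Methods

This note documents the statistical procedures implemented in `cotarget`,
the conventions and defaults behind them, what the synthetic-data generators
do and do not emulate, and the numerical choices that matter for
reproducibility.

## Coordinates, windows and representative points

All coordinates are 0-based half-open internally; GFF3's 1-based closed
convention is converted only at the file boundary, and writing back restores
it bit-exactly. The TSS and TES are strand-aware single-base anchors (for a
`+` gene, `start` and `end − 1`; swapped for `−`).

Each peak is reduced to one representative point: the summit when the peak
caller reported one, else the interval midpoint `floor((start+end)/2)`.
This keeps ChIP-chip (no summits) and ChIP-seq peaks on one footing and
makes inter-peak distances well defined.

A peak belongs to a gene when its point falls in the composite window,
measured as a signed strand-aware offset `o` from the TSS:

| region      | offsets                      |
|-------------|------------------------------|
| promoter    | `−promoter_bp ≤ o < 0`       |
| gene body   | `0 ≤ o < L`, `L = |TES−TSS|` |
| 3′          | `L ≤ o < L + downstream_bp`  |

Defaults are `promoter_bp = 5000`, `downstream_bp = 1000`. All sub-window
boundaries are half-open on the downstream edge (so the TES base itself
opens the 3′ region — one convention had to be picked; this one keeps every
boundary rule identical). Under the default `nearest_tss` policy a point
inside several genes' windows goes to the gene minimizing `|o|`, ties broken
by lexicographic gene id, which makes assignment deterministic and
order-independent. The `all` policy keeps every containing gene. Overlapping
gene windows are allowed and never merged: in a genome as gene-dense as
*Arabidopsis*, promoter windows routinely overlap neighboring genes.

## Overlap significance

For target sets of sizes `n_a` and `n_b` with `k` shared genes in a
universe of `N` annotated genes, the test is the upper tail
`P(X ≥ k)` for `X ~ Hypergeometric(N, n_a, n_b)`. The tail is accumulated
from exact log-pmf terms (log-gamma binomials combined with logsumexp) and
reported as log10. This matters because realistic genome-scale overlaps
produce p-values far below the smallest positive double; the log-space path
is exact there, and is verified in the tests against exhaustive rational
enumeration (all universes ≤ 12) and against an independent library tail
implementation at larger sizes. Fold enrichment is `k / (n_a·n_b/N)`.

The universe is a parameter, never a constant: class sizes and p-values
depend on which annotation (and which upstream target definitions) produced
the inputs, so published counts from other annotations are not comparable
surfaces.

## Inter-peak proximity and the random-target-promoter null

On each shared gene the observed statistic uses the *nearest* cross-factor
pair, `d_g = min_{a,b} |o_a − o_b|` (one distance per shared promoter;
`all_pairs` is available). The default summary is the median distance;
`fraction_within(200 bp)` is reported alongside as the conventional
close-binding summary.

The null asks: how close would the two factors' peaks be if each factor kept
its own positional preferences but there were no within-promoter coupling?
Each permutation re-pairs gene `g`'s factor-A offsets with the factor-B
offsets of a different shared gene drawn uniformly (self-pairing excluded;
derangements are not enforced — the resulting bias is O(1/n) and accepted
for simplicity). Working on TSS-relative offsets makes re-pairing
well-defined across genes of different lengths and preserves each factor's
marginal offset distribution. The empirical p-value is the add-one
estimator `(1 + b)/(1 + m)` — never exactly zero — lower-tailed for the
median (closer than chance), upper-tailed for `fraction_within`. The test
requires ≥ 5 shared genes; below that the null support is too coarse to
mean anything. Calibration is verified: with no planted coupling, p-values
across 200 seeded replicates are uniform (KS test).

## Metagene profile

Promoter and 3′ regions are binned at fixed bp width; body positions are
rescaled to `[0,1)` by `(point − TSS)/(TES − TSS)` strand-aware before
binning, so genes of different lengths contribute comparably. Genes with
`TES = TSS` are skipped and counted. Counts are conserved (every assigned
peak lands in exactly one bin when the profile layout matches the
assignment windows) and per-factor densities sum to 1.

## Expression integration

`merge_experiments` pivots per-experiment DE tables into gene × experiment
matrices and filters at `p < α` in **every** experiment
(`all_significant`, the "significant in both microarrays" construction) or
in **at least one** (`any_significant`, with missing entries kept as NaN).
Fold-change clamping to ±2 log2 is a display-scale convention and is
idempotent.

Sign concordance between two experiments multiplies each column by an
explicit ±1 convention before comparing signs — a loss-of-function contrast
can be flipped so that "inverse correlation" counts as concordant
regulation; the tool never guesses direction semantics. Zeros are excluded;
significance is the exact two-sided binomial test of the concordant count
against 0.5.

Hierarchical clustering is average-linkage on `1 − Pearson` (or Euclidean)
row distances via scipy; a constant row under the correlation metric is a
validation error naming the gene, since its correlation is undefined.

### GSEA

The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum: walking down the ranking, the sum rises by `|s_i|^w / Σ_hits |s|^w` at
set members and falls by `1/(N − |S|)` otherwise; ES is the deviation of
maximum magnitude (ties between the positive and negative extreme, within
1e-12, break toward the positive deviation; ES is clipped to [−1, 1]
against last-digit float drift). The ranking is taken exactly as supplied —
callers rank by whatever statistic they trust (a moderated-t column if
available, else signed log2FC); the engine never re-sorts or recomputes it.

Significance uses **gene-set permutation**: null ES values from random
matched-size gene sets drawn from the ranking. Phenotype permutation is not
offered because the motivating use case has two arrays per contrast —
nothing to shuffle. NES is ES divided by the mean |null ES| of the same
sign; the nominal p is the same-sign null exceedance with add-one
smoothing; FDR q follows the sign-stratified pooled-NES scheme of the
original GSEA procedure (Benjamini–Hochberg over nominal p-values is
available as `fdr_method="bh"`). Permutations use an O(|S|) extrema
computation at the sorted hit positions, which the tests pin to the full
running sum exactly. Per-set RNG streams are spawned from the master seed
in declaration order, so a run is bit-reproducible for a fixed seed and
gene-set collection; adding or reordering sets changes later streams.

### qPCR helpers

`relative_expression` is the Livak `2^(−ΔΔCt)` convention (target vs.
reference gene, sample vs. calibrator); `chip_fold_enrichment` is
`2^(−ΔCt_target) / 2^(−ΔCt_control)` (IP/input at the target region over
IP/input at a non-bound control region). These are standard conventions,
stated here because sources often leave the formula implicit.

## Regulatory-mode classification

Panels carry ≥ 2 positive replicate values for WT, mutA, mutB and mutAB.
All tests are one-sided Welch t on log2 values ("below") at `α = 0.05`,
uncorrected within a gene (four planned contrasts; BH across genes can be
applied by the caller). A variance floor of 1e-6 on the log2 scale keeps
the statistic finite for near-constant replicates. The decision rule:

1. neither single mutant significantly below WT → **not_coactivated**;
2. double significantly below **both** singles → **additive**
   (the "further decreased" pattern — each factor contributes
   independently);
3. otherwise, if the double is significantly below WT → **interdependent**
   (loss of either factor is as bad as loss of both); the
   **residual flag** is set when the double is below exactly one single —
   the pattern expected when a residual paralog props up expression in one
   single mutant;
4. otherwise → **ambiguous** (a single mutant is down but the double is
   not below WT: inconsistent with joint activation).

Ordering the additive test before the interdependent test is deliberate:
a residual-paralog panel (say WT 1.0 / mutA 0.45 / mutB 0.30 / mutAB 0.30)
has the double significantly below *one* single, and the verbal logic of
the field still calls that interdependent-with-residual rather than
additive. Requiring "below both singles" for additive and "below WT" for
interdependent encodes exactly that. The rule is a formalization of
qualitative descriptions — no formal criterion separates "equally
repressed" from "further decreased" in the source experiments, so the rule
is declared here rather than reproduced. Calls are invariant under
mutA↔mutB swap and global positive rescaling (log-scale contrasts).

## Synthetic data

The generators plant exactly the structures the pipeline detects, with the
truth serialized next to the outputs:

- **Genome**: non-overlapping genes, random strands, gene lengths uniform
  in 1–3 kb (typical compact plant genes), intergenic gaps uniform in
  10.5–15 kb. The gap floor exceeds two facing 5 kb promoter windows, so
  composite windows never collide and noiseless recovery is exact — the
  point of the default configuration is a clean truth table, not realistic
  gene density (real *Arabidopsis* promoters overlap constantly; the
  assignment code handles that, the default simulation deliberately avoids
  it).
- **Co-occupancy**: target sets drawn without replacement; each target gets
  one 200 bp peak with a summit, its point uniform in the promoter window
  (margins keep truncation and the peak interval inside it). On shared
  genes factor B's offset = factor A's offset + `Normal(0, σ)` truncated to
  the window; `σ = 50 bp` by default (the "most peaks within 200 bp"
  regime), `σ = None` draws B independently — the calibration null.
- **Expression**: shared targets get `±effect` log2 with experiment-1 sign
  per gene and later experiments agreeing with probability
  `concordance_prob`; everything gets `Normal(0, noise_sd)` noise and
  two-sided z p-values against the noise law (so null p-values are uniform
  by construction). Defaults: effect 1.5 log2, concordance 0.9, noise 0.3 —
  strong, clearly-detectable regulation with visible discordance, the
  regime the motivating experiments report.
- **Genotype panels**: interdependent genes put singles and double at
  `WT·2^−1.5`; additive genes drop the double a further 1.0 log2;
  multiplicative lognormal replicate noise at CV 10%, n = 3 — ordinary
  qPCR-scale effects and noise.

What the generators do **not** emulate: background/noise peaks, peak-width
and score distributions, overlapping gene models, missing genes on arrays,
correlated noise between experiments, and upstream differences in target
definitions between published ChIP studies. Green tests therefore
demonstrate correctness of the statistical machinery on its stated model,
not robustness to every artifact of real ChIP data.

Seeding: a master seed fans out to per-component child seeds via
`SeedSequence([seed, component_index])`, so each generator is independently
reproducible. Every stochastic stage in the package is bit-identical under
a fixed seed.

## Problem sizes and numerics

The shipped study runs at 2000 genes, 500/130 targets with 60 shared,
999 permutations, 1000 GSEA permutations and a 500-gene panel; the full
suite plus the acceptance script completes in seconds on one CPU, and the
sizes were chosen as the smallest at which every planted effect is
decisively detectable (permutation floor 1/1000, recovery ≥ 95%).
Known numerical choices: hypergeometric tails in log space; ES tie-break
and clipping as above; the empirical-p add-one estimator bounds p away
from 0; Welch variance floor 1e-6; float-valued TSVs are written with
`repr` and read with round-trip float parsing so write→read→write is
byte-identical.

## Limitations

- The classifier's `ambiguous` bucket absorbs patterns the verbal model
  does not cover (e.g. one factor down, double unchanged); it makes no
  attempt at a full two-way interaction ANOVA.
- Gene-set permutation GSEA understates between-gene correlation relative
  to phenotype permutation; with two arrays per contrast there is no
  alternative, and FDR values should be read accordingly.
- The proximity null conditions on the observed per-gene peak sets; it
  tests within-promoter coupling, not peak calling quality.
- Distal/enhancer assignment, motif analysis, read-level data and raw
  microarray preprocessing are out of scope; the pipeline consumes peak
  calls and DE tables.
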