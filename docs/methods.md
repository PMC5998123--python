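# Methods

## The scoring model

The paradigm treats every curated perturbed-vs-control comparison as a weak,
noisy classifier of process membership and integrates them by vote counting.
Its assumptions are deliberately minimal:

- each comparison's DEG calls are exchangeable evidence — no weighting by
  effect size, sample size or platform (votes are strictly ±1/0);
- the curation-time process direction `s_c` is correct; flipping every
  direction negates every score (antisymmetry), so a mis-curated direction
  corrupts only its own column;
- comparisons are treated as independent; shared samples or labs violate this
  and inflate consensus scores — the comparison-clustering stage exists
  precisely to surface groups of near-duplicate comparisons.

A gene's vote in a comparison is `sign(log2FC) · s_c` when it passes the DEG
thresholds, `0` when measured but not significant, and `NA` when unmeasured.
The consensus score is the plain sum of non-NA votes; |S_g| ≤ number of
measured comparisons. Genes measured nowhere are retained with score 0 and an
`all_na` flag rather than dropped, so downstream tables can filter them
explicitly. Ranking is dense on descending score with lexicographic
tie-break — equal scores carry no internal order and the tie-break only makes
output deterministic.

### Thresholds

- `q_max = 0.05`, inclusive (a gene exactly at q = 0.05 is significant).
- `abs_log2fc_min = 0` by default; the comparison is strict (`>`), so with a
  0.5 floor a gene at exactly |log2FC| = 0.5 is *not* called. The 0.5 floor
  with q < 0.05 is shipped as `RNASEQ_PROFILE`, the stricter profile
  appropriate for well-powered RNA-Seq validation data.
- `log2FC = 0` with small q maps to vote 0: no direction, no vote.
- A score cutoff of ≥ 6 (or ≤ −5 for the negative side) is a pragmatic
  operating point for ~24 comparisons, not a universal constant; with more
  comparisons the cutoff should grow. The empirical null (below) turns any
  cutoff into a p-value.

## Permutation null

The null model must preserve each comparison's DEG rate and missingness while
destroying cross-comparison coherence — that coherence is exactly what the
consensus score measures. Default scheme: every permutation independently
shuffles each comparison column across genes (sampling without replacement,
so the column marginal over {+1, −1, 0, NA} is preserved exactly). The
alternative `resample_columns` scheme draws cells from the column marginal
with replacement, for sensitivity analysis. An analytic null under arbitrary
marginals is out of scope.

Per-gene scores from all permutations are pooled: with G genes and R
permutations the resolution is 1/(G·R), which is how empirical p-values on
the 1e-8 scale become reachable at practical R (e.g. G = 10⁴, R = 10⁴). The
default R targets a 1e-6 resolution and is logged at run time. p-values carry
a +1 pseudocount by default ((hits+1)/(total+1)) so they are never exactly 0;
positive scores are tested on the ≥ side, negative on the ≤ side. Because the
null is discrete, calibration statements are one-sided: the fraction of null
genes with p ≤ α equals the largest *achievable* level below α, which is at
most α and often well below it (conservative).

## Tail quantile test

The package tests whether positive consensus scores have a heavier upper tail
than the magnitudes of negative ones: `stat = Q_q(positives) −
Q_q(|negatives|)` at q = 0.95. The reference construction for this comparison
is not pinned down in the literature we build on, so the implementation is an
explicit percentile bootstrap: resample both vectors, recompute the quantile
difference `n_boot` times, and report the +1-smoothed fraction of replicates
at or below 0 as the one-sided p-value for H0: stat ≤ 0. q-level, n_boot and
seed are all explicit configuration.

## Enrichment

Screening a strong gene list against hundreds of sets makes the ordinary
Fisher null (odds ratio 1) uninformative, so the test is against a composite
null "odds ratio < ψ₀" evaluated at the boundary: one-sided
P(X ≥ a) under Fisher's noncentral hypergeometric distribution with weights
`C(K,k)·C(N−K,n−k)·ψ₀^k`, summed in log space (stable for margins in the
10⁴ range). ψ₀ = 1 reduces exactly to the one-sided Fisher exact test. The
default ψ₀ = 2 reads the conventional "log-odds-ratio < 2" phrasing as an
odds-ratio threshold on the log-reported scale; because the log base in that
phrasing is genuinely ambiguous (2, e or 10 give thresholds 4, ~7.4, 100),
ψ₀ is surfaced as mandatory-to-log configuration, never silently assumed.
The reported sample odds ratio is ad/bc with Haldane–Anscombe 0.5 added only
when a zero cell exists, and only for reporting — the exact test never uses
it. BH correction is applied across the sets that survive the size filters
(defaults 5–2000 members within the background; standard practice, not a
derived constant). The background defaults to the union of affinity-matrix
genes and can be any gene-list file; GO-style graph propagation is out of
scope (sets are flat).

## Comparison clustering

Distance between two affinity columns: 1 minus the fraction of identical
nonzero votes among co-measured genes where at least one column votes; 1 when
no gene qualifies. This Jaccard-style agreement distance lives on [0, 1],
is 0 iff the columns' nonzero calls coincide on co-measured genes, and makes
a small flat-cut height (e.g. 0.05) meaningful as "≥ 95% vote agreement".
The metric is pluggable (`pearson` = (1 − r)/2 over co-measured genes is
included) since reasonable alternatives exist. Linkage default is average;
the flat cut at `cut_height` gives clusters labelled 1..k in column order,
so results are deterministic. Cluster count is monotone nonincreasing in the
cut height.

## Synthetic data generator

The generator emulates the structure the paradigm assumes: C comparisons with
directions, a planted gene set voting concordantly (+1) with probability
`p_signal` per comparison and discordantly with `p_discord`, background genes
voting ±1 with total probability `p_noise` (sign symmetric — emulating the
roughly balanced up/down calls normalised DEG analyses produce), and
independent per-cell missingness `p_missing`. Defaults — 10⁴ genes,
24 comparisons, 50 planted, `p_signal = 0.4`, `p_discord = 0`,
`p_noise = 0.05`, `p_missing = 0.1` — model a realistic curation: two dozen
comparisons from heterogeneous platforms, a planted gene detected in ~40% of
them, a few percent background DEG rate, and one in ten genes absent from any
given platform's universe. Under these conditions a planted gene's consensus
is Binomial(24, 0.36)-distributed (mean 8.64), so a cutoff of 6 recovers most
planted genes while background genes (net drift of ~24 · 0.045 split votes)
essentially never reach it.

The expression-level generator realises the same scheduled votes as two-group
Gaussian log-scale matrices (baseline N(7, 2) per gene, noise sd `sigma`,
mean shift ±`effect_size` signed so the induced log2FC reproduces the
scheduled vote; genes missing from a comparison are omitted from its matrix).
Noise is homoscedastic and Gaussian by design — the built-in DEG stage is a
Welch t-test, and the point of this level is to exercise the pipeline
end to end, not to emulate count overdispersion, batch effects or platform
artefacts. Consequently, passing tests demonstrate the *integration*
machinery (scoring, null, enrichment, clustering) and the wiring of the DEG
stage; they do not certify performance on real microarray/RNA-Seq data,
where DEG calling is done by dedicated external tools and their tables are
imported via the column-mapping reader.

All stochastic operations take explicit seeds; there is no hidden global
random state. Identifier matching is case-sensitive after whitespace
trimming; symbol aliasing/ortholog mapping is out of scope.

## Problem sizes and numerical choices

- Tests and the acceptance script run the full study conditions (10⁴ × 24)
  for scoring and recovery; the permutation null uses R = 200–2000 (pooled
  totals 2×10⁶–2×10⁷), the expression path 10³ genes × 8 comparisons, and
  clustering recovery 2 × 5 comparisons over 500 genes — sizes chosen so the
  whole suite re-runs in minutes on one core while keeping Monte-Carlo error
  well inside the asserted margins.
- Degenerate inputs: zero-variance/zero-difference genes get p = 1 (never
  NaN) so they map to vote 0; zero variance with a nonzero difference gets
  p = 0; degenerate enrichment margins give p = 1 with a warning; an empty
  planted set makes recovery an explicit error, not NaN.
- Bootstrap and permutation p-values use +1 smoothing, so reported p ∈ (0, 1].

## Known limitations

- Votes are unweighted; a single large, well-powered comparison counts the
  same as a small noisy one.
- The permutation null breaks gene–gene correlation within a comparison
  column's reassignment but keeps no gene-level covariance structure across
  comparisons; correlated comparisons (shared controls) make it optimistic.
- The agreement distance ignores the *number* of co-measured genes, so
  distances from comparison pairs with tiny co-measured overlap are noisy.
- The built-in DEG stage is intentionally simple; real studies should import
  tables from DESeq2/limma-class tools.
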