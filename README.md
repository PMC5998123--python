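# degvote

Vote-counting integration of perturbation-experiment differential-expression
results into per-gene **consensus scores**, for identifying candidate key
factors of a biological process (epidermal development and cold-induced
thermogenesis are the motivating applications; the machinery is generic).

Public repositories hold many expression datasets in which a biological
process of interest has been perturbed — a driver gene knocked down or
overexpressed, a tissue cold-challenged. Each such *comparison* (perturbed vs
control) is curated with a **process direction** `s_c ∈ {+1, −1}`: whether the
perturbation increases or decreases the process. For gene *g* in comparison
*c* with log2 fold change `fc_gc` and BH-adjusted q-value `q_gc`, the
**affinity score** is

```
a_gc = NA                      if g is unmeasured in c
     = 0                       if q_gc > q_max  or |fc_gc| ≤ f_min  or fc_gc = 0
     = sign(fc_gc) · s_c       otherwise
```

(defaults `q_max = 0.05`, `f_min = 0`; an RNA-Seq profile with
`f_min = 0.5` is provided). The **consensus score** is the sum of the non-NA
votes, `S_g = Σ_c a_gc`; genes with high positive consensus move coherently
with the process across independent experiments and are candidate key
factors. Around this core the package provides:

- a permutation **empirical null**: each comparison column is shuffled across
  genes (preserving per-comparison DEG rates and missingness, destroying
  cross-comparison coherence); scores from all genes and permutations are
  pooled, giving p-value resolution ~1/(G·R);
- a **threshold-odds-ratio Fisher test** for gene-set enrichment: one-sided
  exact p-value under Fisher's noncentral hypergeometric distribution at a
  composite null boundary ψ₀ (ψ₀ = 1 is the ordinary Fisher test), BH across
  sets;
- **comparison clustering** by an affinity agreement distance
  `d(x,y) = 1 − |{g: x_g = y_g ≠ 0}| / |{g: x_g ≠ 0 or y_g ≠ 0}|` over
  co-measured genes, with average-linkage hierarchical clustering and a flat
  cut;
- a bootstrap **tail quantile test** of whether positive consensus scores have
  a heavier upper tail than |negative| ones;
- a **synthetic-data generator** with planted process genes, at both the
  affinity level and the raw two-group expression level (Welch-test DEG stage
  included), so the full pipeline is testable end to end.

## Worked example

```python
from degvote import (GeneratorParams, generate_affinity, consensus_scores,
                     simulate_null, empirical_pvalue, evaluate_recovery)

params = GeneratorParams(seed=1)        # 10^4 genes, 24 comparisons,
am, truth = generate_affinity(params)   # 50 planted genes, p_signal 0.4
ct = consensus_scores(am)
m = evaluate_recovery(ct, truth, cutoff=6, am=am)
print(f"recall={m.recall:.2f} precision={m.precision:.2f} "
      f"best_single={m.best_individual_recall:.2f}")
nd = simulate_null(am, n_perm=2000, seed=2)
print(f"P(score >= 6 | null) = {empirical_pvalue(nd, 6, 'ge'):.3g}")
```

prints

```
recall=0.90 precision=1.00 best_single=0.44
P(score >= 6 | null) = 1.32e-05
```

A consensus cutoff of 6 recovers 90% of the planted genes with no false
positives, while the best single comparison alone recovers 44% — the gain
from integrating many weak, noisy comparisons. The pooled permutation null
puts a score of 6 deep in the tail.

The same pipeline runs from the shell on on-disk TSV inputs:

```
degvote simulate --seed 1 --outdir data/
degvote score data/manifest.tsv --outdir out/
degvote null out/ --n-perm 2000 --seed 2
degvote enrich out/ --gmt sets.gmt --cutoff 6
degvote cluster out/ --cut-height 0.05
```

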