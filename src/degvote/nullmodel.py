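"""Permutation-based empirical null for consensus scores.

The observed consensus of a process gene is driven by *coherence* of its
votes across comparisons.  The null destroys exactly that coherence:
each permutation shuffles every comparison's affinity column
independently across genes, preserving each comparison's marginal counts
of {+1, -1, 0, NA} (its DEG rate and missingness) while breaking any
cross-comparison gene dependence.  Consensus scores of all genes in all
permutations are pooled into one histogram, so with G genes and R
permutations the p-value resolution is ~1/(G*R) — this pooling is what
makes p-values on the 1e-8 scale reachable at practical R.

An alternative ``resample_columns`` scheme draws each cell from its
column's marginal with replacement, for sensitivity analysis.

The module also provides the positive-versus-|negative| tail comparison:
a bootstrap test of whether the upper quantile of positive consensus
scores exceeds that of the absolute negative scores, formalising the
observation that process-concordant genes have the longer tail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import validate_affinity_matrix

SCHEMES = ("permute_columns", "resample_columns")


@dataclass
class NullDistribution:
    """Pooled histogram of simulated consensus scores."""

    histogram: dict[int, int]
    n_perm: int
    n_genes: int
    n_comparisons: int
    seed: int
    scheme: str = "permute_columns"
    pooled_total: int = field(init=False)

    def __post_init__(self) -> None:
        self.pooled_total = self.n_perm * self.n_genes
        if sum(self.histogram.values()) != self.pooled_total:
            raise ValueError("histogram counts do not sum to n_perm * n_genes")
        if any(abs(s) > self.n_comparisons for s in self.histogram):
            raise ValueError("score outside +/- n_comparisons in histogram")


def default_n_perm(n_genes: int, target_resolution: float = 1e-6) -> int:
    """Permutation count giving ~``target_resolution`` pooled p-value
    resolution: ceil(1 / (target_resolution * n_genes)), at least 100."""
    return max(100, int(np.ceil(1.0 / (target_resolution * max(n_genes, 1)))))


def simulate_null(am: pd.DataFrame, n_perm: int, seed: int,
                  scheme: str = "permute_columns") -> NullDistribution:
    """Simulate the empirical null of consensus scores.

    Each of ``n_perm`` replicates independently permutes (or resamples)
    every comparison column across genes and recomputes every gene's
    consensus; all scores are pooled.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    validate_affinity_matrix(am)
    vals = am.to_numpy(float)
    n_genes, n_comp = vals.shape
    rng = np.random.default_rng(seed)
    # NA contributes 0 to the consensus sum, so replace once up front
    cols = [np.nan_to_num(vals[:, j], nan=0.0) for j in range(n_comp)]
    counts = np.zeros(2 * n_comp + 1, dtype=np.int64)
    for _ in range(n_perm):
        total = np.zeros(n_genes)
        for col in cols:
            if scheme == "permute_columns":
                total += rng.permutation(col)
            else:
                total += col[rng.integers(0, n_genes, size=n_genes)]
        scores = np.rint(total).astype(np.int64)
        counts += np.bincount(scores + n_comp, minlength=2 * n_comp + 1)
    histogram = {int(s - n_comp): int(c)
                 for s, c in enumerate(counts) if c > 0}
    return NullDistribution(histogram=histogram, n_perm=n_perm,
                            n_genes=n_genes, n_comparisons=n_comp,
                            seed=seed, scheme=scheme)


def empirical_pvalue(nd: NullDistribution, cutoff: int, side: str = "ge",
                     pseudocount: int = 1) -> float:
    """Pooled empirical p-value of a consensus-score cutoff.

    side="ge": P(score >= cutoff); side="le": P(score <= cutoff).  With
    the default pseudocount of 1 the p-value is never exactly 0:
    p = (exceedances + s) / (pooled_total + s).
    """
    if side not in ("ge", "le"):
        raise ValueError("side must be 'ge' or 'le'")
    if pseudocount not in (0, 1):
        raise ValueError("pseudocount must be 0 or 1")
    if side == "ge":
        hits = sum(c for s, c in nd.histogram.items() if s >= cutoff)
    else:
        hits = sum(c for s, c in nd.histogram.items() if s <= cutoff)
    denom = nd.pooled_total + pseudocount
    return (hits + pseudocount) / denom


def annotate_empirical_p(ct: pd.DataFrame, nd: NullDistribution,
                         pseudocount: int = 1) -> pd.DataFrame:
    """Attach each gene's empirical p-value at its own consensus score.

    Positive (and zero) scores are tested on the >= side, negative
    scores on the <= side; the p-value is a function of the score alone.
    """
    n_comp = ct.attrs.get("n_comparisons")
    if n_comp is not None and n_comp != nd.n_comparisons:
        raise ValueError(
            f"consensus table built from {n_comp} comparisons but null "
            f"from {nd.n_comparisons}")
    out = ct.copy()
    out.attrs.update(ct.attrs)
    cache = {
        int(s): empirical_pvalue(nd, int(s), "ge" if s >= 0 else "le",
                                 pseudocount)
        for s in out["consensus_score"].unique()
    }
    out["empirical_p"] = out["consensus_score"].map(cache)
    return out


@dataclass(frozen=True)
class QuantileTestResult:
    q_level: float
    stat: float          # Q_q(positives) - Q_q(|negatives|)
    pvalue: float
    n_boot: int
    seed: int


def quantile_tail_test(positive_scores, negative_scores,
                       q_level: float = 0.95, n_boot: int = 10000,
                       seed: int = 0) -> QuantileTestResult:
    """Bootstrap test that positive consensus scores have a heavier
    upper tail than the magnitudes of negative ones.

    stat = Q_q(positives) - Q_q(|negatives|); the one-sided p-value for
    H0: stat <= 0 is the (+1-smoothed) fraction of percentile-bootstrap
    replicates of the difference that fall at or below 0.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.abs(np.asarray(negative_scores, dtype=float))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("score vectors must be nonempty")
    if not (0 < q_level < 1):
        raise ValueError("q_level must be in (0, 1)")
    stat = float(np.quantile(pos, q_level) - np.quantile(neg, q_level))
    rng = np.random.default_rng(seed)
    bp = pos[rng.integers(0, pos.size, size=(n_boot, pos.size))]
    bn = neg[rng.integers(0, neg.size, size=(n_boot, neg.size))]
    boot = np.quantile(bp, q_level, axis=1) - np.quantile(bn, q_level, axis=1)
    pvalue = (1 + int(np.sum(boot <= 0))) / (n_boot + 1)
    return QuantileTestResult(q_level=q_level, stat=stat, pvalue=pvalue,
                              n_boot=n_boot, seed=seed)


def write_null(nd: NullDistribution, tsv_path: str | Path,
               meta_path: str | Path | None = None) -> None:
    rows = sorted(nd.histogram.items())
    pd.DataFrame(rows, columns=["score", "count"]).to_csv(
        tsv_path, sep="\t", index=False)
    meta = {"n_perm": nd.n_perm, "n_genes": nd.n_genes,
            "n_comparisons": nd.n_comparisons, "pooled_total": nd.pooled_total,
            "seed": nd.seed, "scheme": nd.scheme}
    meta_path = meta_path or Path(tsv_path).with_suffix(".json")
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def read_null(tsv_path: str | Path,
              meta_path: str | Path | None = None) -> NullDistribution:
    df = pd.read_csv(tsv_path, sep="\t")
    meta_path = meta_path or Path(tsv_path).with_suffix(".json")
    with open(meta_path) as fh:
        meta = json.load(fh)
    hist = {int(s): int(c) for s, c in zip(df["score"], df["count"])}
    return NullDistribution(histogram=hist, n_perm=meta["n_perm"],
                            n_genes=meta["n_genes"],
                            n_comparisons=meta["n_comparisons"],
                            seed=meta["seed"], scheme=meta["scheme"])
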