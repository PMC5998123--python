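"""Affinity matrix construction and consensus scoring.

Each comparison perturbs a biological process in a known direction
(+1 increased, -1 decreased).  A gene's *affinity score* in a comparison
is a vote in {+1, -1, 0, NA}: the sign of its significant expression
change multiplied by the process direction, so +1 always means "moves
with the process".  Summing the non-NA votes across comparisons yields
the *consensus score*; genes with high positive consensus are candidate
key factors for the process.

Thresholds: a gene is called differentially expressed when its q-value
is at or below ``q_max`` and |log2FC| strictly exceeds
``abs_log2fc_min``.  The default profile uses q <= 0.05 with no fold-
change floor; :data:`RNASEQ_PROFILE` additionally requires
|log2FC| > 0.5, the stricter profile used for RNA-Seq validation data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .degio import ComparisonManifest, DegTable


@dataclass(frozen=True)
class AffinityThresholds:
    """Differential-expression call thresholds for the affinity stage.

    q_max: significance ceiling (inclusive) on the BH q-value.
    abs_log2fc_min: strict lower bound on |log2 fold change|.
    """

    q_max: float = 0.05
    abs_log2fc_min: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.q_max <= 1):
            raise ValueError("q_max must be in (0, 1]")
        if self.abs_log2fc_min < 0:
            raise ValueError("abs_log2fc_min must be >= 0")


DEFAULT_THRESHOLDS = AffinityThresholds()
#: stricter call profile for RNA-Seq data: |log2FC| > 0.5 and q <= 0.05
RNASEQ_PROFILE = AffinityThresholds(q_max=0.05, abs_log2fc_min=0.5)


def affinity_score(log2fc: float, qvalue: float, measured: bool,
                   direction: int,
                   thresholds: AffinityThresholds = DEFAULT_THRESHOLDS) -> float:
    """Single-cell affinity vote: +1, -1, 0 or NaN (unmeasured).

    Unmeasured -> NaN; not differentially expressed (q above q_max, or
    |log2FC| at/below the floor, or log2FC exactly 0) -> 0; otherwise
    sign(log2FC) * direction.
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    if not measured:
        return float("nan")
    if not (0 <= qvalue <= 1):
        raise ValueError("qvalue must be in [0, 1]")
    if qvalue > thresholds.q_max or abs(log2fc) <= thresholds.abs_log2fc_min \
            or log2fc == 0:
        return 0.0
    return float(np.sign(log2fc) * direction)


def _column_votes(table: DegTable, direction: int,
                  thresholds: AffinityThresholds) -> pd.Series:
    lfc = table.frame["log2fc"].to_numpy(float)
    q = table.frame["qvalue"].to_numpy(float)
    de = (q <= thresholds.q_max) & (np.abs(lfc) > thresholds.abs_log2fc_min) \
        & (lfc != 0)
    votes = np.where(de, np.sign(lfc) * direction, 0.0)
    return pd.Series(votes, index=table.frame["gene"].to_numpy())


def build_affinity_matrix(manifest: ComparisonManifest,
                          tables: dict[str, DegTable] | list[DegTable],
                          thresholds: AffinityThresholds = DEFAULT_THRESHOLDS,
                          ) -> pd.DataFrame:
    """Genes x comparisons matrix of affinity votes.

    Rows are the lexicographically sorted union of all comparison
    universes; a cell is NaN exactly when the gene is absent from that
    comparison's universe.  Returned as a float DataFrame with values in
    {-1, 0, +1, NaN}; ``attrs["directions"]`` records each comparison's
    process direction.
    """
    if isinstance(tables, list):
        tables = {t.comparison_id: t for t in tables}
    missing = [cid for cid in manifest.ids if cid not in tables]
    if missing:
        raise KeyError(f"manifest comparisons without DEG tables: {missing}")
    genes = sorted(set().union(*(tables[cid].universe for cid in manifest.ids)))
    if not genes:
        raise ValueError("union of comparison universes is empty")
    cols = {}
    for spec in manifest:
        votes = _column_votes(tables[spec.comparison_id], spec.direction,
                              thresholds)
        cols[spec.comparison_id] = votes.reindex(genes)
    am = pd.DataFrame(cols, index=pd.Index(genes, name="gene"),
                      columns=manifest.ids)
    am.attrs["directions"] = manifest.directions
    return am


def validate_affinity_matrix(am: pd.DataFrame) -> None:
    vals = am.to_numpy(float)
    ok = np.isnan(vals) | np.isin(vals, (-1.0, 0.0, 1.0))
    if not ok.all():
        raise ValueError("affinity matrix entries must be in {-1, 0, +1, NA}")


def consensus_scores(am: pd.DataFrame) -> pd.DataFrame:
    """Per-gene consensus table from an affinity matrix.

    consensus_score = sum of non-NA votes; rank is dense over descending
    score with ties broken lexicographically by gene identifier.  Genes
    measured in no comparison are kept with score 0 and all_na=True so
    callers can filter them explicitly.
    """
    validate_affinity_matrix(am)
    vals = am.to_numpy(float)
    n_measured = (~np.isnan(vals)).sum(axis=1)
    n_positive = np.nansum(vals == 1, axis=1).astype(int)
    n_negative = np.nansum(vals == -1, axis=1).astype(int)
    score = n_positive - n_negative
    ct = pd.DataFrame({
        "consensus_score": score,
        "n_measured": n_measured.astype(int),
        "n_positive": n_positive,
        "n_negative": n_negative,
        "all_na": n_measured == 0,
    }, index=am.index.copy())
    ct["empirical_p"] = np.nan
    # dense rank over descending score; ties share a rank, rows ordered
    # lexicographically within a tie when the table is sorted
    ct["rank"] = ct["consensus_score"].rank(method="dense",
                                            ascending=False).astype(int)
    ct.attrs["n_comparisons"] = am.shape[1]
    return ct


def select_by_score(ct: pd.DataFrame, cutoff: int,
                    side: str = "positive") -> list[str]:
    """Genes passing a consensus-score cutoff.

    side="positive": score >= cutoff (candidate process drivers);
    side="negative": score <= cutoff.  Deterministic order: score
    (extreme first), then gene identifier.
    """
    if side == "positive":
        hits = ct[ct["consensus_score"] >= cutoff]
        hits = hits.sort_index().sort_values("consensus_score",
                                             ascending=False, kind="mergesort")
    elif side == "negative":
        hits = ct[ct["consensus_score"] <= cutoff]
        hits = hits.sort_index().sort_values("consensus_score",
                                             ascending=True, kind="mergesort")
    else:
        raise ValueError("side must be 'positive' or 'negative'")
    return [str(g) for g in hits.index]


def write_affinity_matrix(am: pd.DataFrame, path) -> None:
    out = am.copy()
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_affinity_matrix(path) -> pd.DataFrame:
    am = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    am.index.name = "gene"
    validate_affinity_matrix(am)
    return am


def write_consensus_table(ct: pd.DataFrame, path) -> None:
    cols = ["consensus_score", "n_measured", "n_positive", "n_negative",
            "empirical_p", "rank", "all_na"]
    ct[cols].to_csv(path, sep="\t", na_rep="NA")


def read_consensus_table(path) -> pd.DataFrame:
    ct = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    ct.index.name = "gene"
    return ct
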