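"""Synthetic multi-comparison data with planted process genes.

The generator emulates the structure the scoring paradigm assumes: a set
of curated perturbation comparisons, each with a process direction, in
which a small set of *planted* genes votes concordantly with the process
(affinity +1) with probability ``p_signal`` per comparison (and
discordantly with probability ``p_discord``), while background genes
produce spurious +/-1 votes at rate ``p_noise``; each cell is unmeasured
(NA) with probability ``p_missing``, independently.

Two levels are provided.  :func:`generate_affinity` draws the affinity
matrix directly, which is the right level for testing the scoring,
null-model and clustering stages.  :func:`generate_expression` realises
the same scheduled votes as two-group log-scale expression matrices with
a Gaussian mean shift of ``effect_size`` (sign chosen so that the Welch
test recovers the scheduled vote), exercising the full pipeline from raw
matrices through DEG calling to consensus scores.

Defaults mirror a realistic curation: 24 comparisons over ~10^4 genes,
a planted gene voting in ~40% of comparisons, a 5% background DE rate
and 10% missingness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .degio import ComparisonManifest, ComparisonSpec, DegTable, simple_deg

DEFAULT_DIRECTIONS_SEED = 20180613  # fixed so default manifests are stable


@dataclass
class GeneratorParams:
    """Study conditions for the synthetic generator."""

    n_genes: int = 10000
    n_comparisons: int = 24
    n_planted: int = 50
    p_signal: float = 0.4     # planted gene votes with the process
    p_discord: float = 0.0    # planted gene votes against the process
    p_noise: float = 0.05     # background gene is DE (sign uniform)
    p_missing: float = 0.1    # per-cell NA rate
    seed: int = 0
    directions: list[int] | None = None

    def __post_init__(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted cannot exceed n_genes")
        if self.p_signal + self.p_discord > 1:
            raise ValueError("p_signal + p_discord must be <= 1")
        for name in ("p_signal", "p_discord", "p_noise", "p_missing"):
            v = getattr(self, name)
            if not (0 <= v <= 1) or (name == "p_missing" and v == 1):
                raise ValueError(f"{name} out of range: {v}")
        if self.directions is None:
            rng = np.random.default_rng(DEFAULT_DIRECTIONS_SEED)
            self.directions = [int(d) for d in
                               rng.choice([1, -1], size=self.n_comparisons)]
        if len(self.directions) != self.n_comparisons or \
                any(d not in (1, -1) for d in self.directions):
            raise ValueError("directions must be +/-1 of length n_comparisons")


@dataclass
class SyntheticTruth:
    planted_genes: frozenset[str]
    params: GeneratorParams

    def to_json(self, path: str | Path) -> None:
        payload = {"planted_genes": sorted(self.planted_genes),
                   "params": asdict(self.params)}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(frozenset(payload["planted_genes"]),
                   GeneratorParams(**payload["params"]))


def _gene_names(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _comparison_ids(n: int) -> list[str]:
    return [f"CMP{i:02d}" for i in range(1, n + 1)]


def _scheduled_votes(params: GeneratorParams,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray,
                                                        np.ndarray]:
    """Draw the scheduled affinity votes, missingness mask and planted
    row indicator.  votes[g, c] in {-1, 0, +1}; missing[g, c] boolean."""
    g, c = params.n_genes, params.n_comparisons
    planted_idx = rng.choice(g, size=params.n_planted, replace=False)
    is_planted = np.zeros(g, dtype=bool)
    is_planted[planted_idx] = True
    u = rng.random((g, c))
    votes = np.zeros((g, c), dtype=np.int8)
    # planted rows: +1 w.p. p_signal, -1 w.p. p_discord, else 0
    votes[is_planted] = np.select(
        [u[is_planted] < params.p_signal,
         u[is_planted] < params.p_signal + params.p_discord],
        [1, -1], default=0)
    # background rows: +/-1 each w.p. p_noise/2
    bg = ~is_planted
    votes[bg] = np.select(
        [u[bg] < params.p_noise / 2, u[bg] < params.p_noise],
        [1, -1], default=0)
    missing = rng.random((g, c)) < params.p_missing
    return votes, missing, is_planted


def generate_affinity(params: GeneratorParams,
                      ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw an affinity matrix with planted process genes.

    Deterministic given ``params.seed``.  Returns the genes x
    comparisons matrix (NaN where unmeasured) and the ground truth.
    """
    rng = np.random.default_rng(params.seed)
    votes, missing, is_planted = _scheduled_votes(params, rng)
    mat = votes.astype(float)
    mat[missing] = np.nan
    genes = _gene_names(params.n_genes)
    am = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                      columns=_comparison_ids(params.n_comparisons))
    am.attrs["directions"] = dict(zip(am.columns, params.directions))
    truth = SyntheticTruth(
        frozenset(np.asarray(genes)[is_planted]), params)
    return am, truth


def generate_expression(params: GeneratorParams, n_per_group: int = 4,
                        effect_size: float = 5.0, sigma: float = 0.5,
                        baseline_mean: float = 7.0, baseline_sd: float = 2.0,
                        ) -> tuple[dict[str, tuple[pd.DataFrame, list[str]]],
                                   ComparisonManifest, SyntheticTruth]:
    """Realise the scheduled votes as two-group expression matrices.

    Per comparison: genes measured there form the universe; the
    perturbed group's mean is shifted by ``+/-effect_size`` so that the
    induced log2FC sign equals scheduled_vote * direction (a +1 vote in
    a process-decreasing comparison shows as down-regulation).  Noise is
    homoscedastic Gaussian on the log2 scale with sd ``sigma``.

    Returns {comparison_id: (expr genes x samples, group labels)}, a
    manifest (deg_path fields point at "<id>.deg.tsv") and the truth.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(params.seed)
    votes, missing, is_planted = _scheduled_votes(params, rng)
    genes = np.array(_gene_names(params.n_genes))
    cmp_ids = _comparison_ids(params.n_comparisons)
    baseline = rng.normal(baseline_mean, baseline_sd, size=params.n_genes)
    labels = ["perturbed"] * n_per_group + ["control"] * n_per_group
    matrices: dict[str, tuple[pd.DataFrame, list[str]]] = {}
    specs = []
    for j, cid in enumerate(cmp_ids):
        keep = ~missing[:, j]
        idx = np.where(keep)[0]
        shift = votes[idx, j] * params.directions[j] * effect_size
        n_g = idx.size
        pert = (baseline[idx, None] + shift[:, None]
                + rng.normal(0, sigma, size=(n_g, n_per_group)))
        ctrl = (baseline[idx, None]
                + rng.normal(0, sigma, size=(n_g, n_per_group)))
        expr = pd.DataFrame(
            np.hstack([pert, ctrl]),
            index=pd.Index(genes[idx], name="gene"),
            columns=[f"{cid}_P{i+1}" for i in range(n_per_group)]
            + [f"{cid}_C{i+1}" for i in range(n_per_group)])
        matrices[cid] = (expr, labels)
        specs.append(ComparisonSpec(cid, f"DS{j + 1:02d}",
                                    params.directions[j], f"{cid}.deg.tsv"))
    truth = SyntheticTruth(frozenset(genes[is_planted]), params)
    return matrices, ComparisonManifest(specs), truth


def deg_tables_from_expression(matrices: dict[str, tuple[pd.DataFrame,
                                                         list[str]]],
                               ) -> dict[str, DegTable]:
    """Run the built-in two-group DEG stage on every comparison."""
    return {cid: simple_deg(expr, labels, comparison_id=cid,
                            levels=("perturbed", "control"))
            for cid, (expr, labels) in matrices.items()}


@dataclass(frozen=True)
class RecoveryMetrics:
    recall: float
    precision: float
    f1: float
    n_selected: int
    cutoff: int
    individual_recall: dict[str, float] = field(default_factory=dict)

    @property
    def best_individual_recall(self) -> float:
        return max(self.individual_recall.values()) \
            if self.individual_recall else float("nan")

    @property
    def consensus_beats_individual(self) -> bool:
        return self.recall > self.best_individual_recall


def evaluate_recovery(ct: pd.DataFrame, truth: SyntheticTruth, cutoff: int,
                      am: pd.DataFrame | None = None) -> RecoveryMetrics:
    """Planted-gene recovery of the consensus selection at ``cutoff``.

    recall = |selected & planted| / n_planted; precision over the
    selected list.  When ``am`` is given, each comparison's individual
    recall is the fraction of planted genes it alone calls concordantly
    (affinity +1) — the single-comparison baseline the consensus is
    meant to beat.
    """
    planted = set(truth.planted_genes)
    if not planted:
        raise ValueError("empty planted gene set: recovery is undefined")
    genes = set(map(str, ct.index))
    if not planted <= genes:
        raise ValueError("consensus table gene axis does not cover the "
                         "planted genes")
    selected = set(map(str, ct.index[ct["consensus_score"] >= cutoff]))
    tp = len(selected & planted)
    recall = tp / len(planted)
    precision = tp / len(selected) if selected else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    individual: dict[str, float] = {}
    if am is not None:
        if set(map(str, am.index)) != genes:
            raise ValueError("affinity matrix and consensus table gene axes "
                             "differ")
        for cid in am.columns:
            col = am[cid]
            concordant = set(map(str, col.index[col == 1]))
            individual[str(cid)] = len(concordant & planted) / len(planted)
    return RecoveryMetrics(recall=recall, precision=precision, f1=f1,
                           n_selected=len(selected), cutoff=cutoff,
                           individual_recall=individual)


def write_synthetic_run(outdir: str | Path, params: GeneratorParams,
                        n_per_group: int = 4, effect_size: float = 5.0,
                        sigma: float = 0.5) -> Path:
    """Write DEG tables, manifest and truth JSON for a synthetic run, in
    the exact on-disk formats the scoring pipeline reads."""
    from .degio import write_deg_table, write_manifest
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrices, manifest, truth = generate_expression(
        params, n_per_group=n_per_group, effect_size=effect_size, sigma=sigma)
    tables = deg_tables_from_expression(matrices)
    for spec in manifest:
        write_deg_table(tables[spec.comparison_id], outdir / spec.deg_path)
    write_manifest(manifest, outdir / "manifest.tsv")
    truth.to_json(outdir / "truth.json")
    return outdir


__all__ = [
    "GeneratorParams", "SyntheticTruth", "RecoveryMetrics",
    "generate_affinity", "generate_expression", "deg_tables_from_expression",
    "evaluate_recovery", "write_synthetic_run",
]
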