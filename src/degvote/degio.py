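"""Reading and writing of DEG tables, comparison manifests and gene-set
collections, plus a minimal two-group differential-expression stage.

A *DEG table* is one comparison's differential-expression result: one row
per gene with its log2 fold change (perturbed vs control), p-value and
BH-adjusted q-value.  A *comparison manifest* lists the curated
comparisons, each with the direction (+1/-1) in which the perturbation
moves the biological process under study.  Gene sets use the standard
GMT format.

The built-in :func:`simple_deg` is a plain Welch two-sample test on
log-scale expression, so synthetic expression matrices can be pushed
through the full scoring pipeline; it deliberately does not attempt to
emulate moderated-variance or count-based models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEG_COLUMNS = ("gene", "log2fc", "pvalue", "qvalue")

#: accepted spellings for the process direction in a manifest
DIRECTION_SYNONYMS = {
    "+1": 1, "1": 1, "up": 1, "increased": 1,
    "-1": -1, "−1": -1, "down": -1, "decreased": -1,
}


class DegIOError(ValueError):
    """Malformed DEG table, manifest or GMT input."""


@dataclass
class DegTable:
    """One comparison's differential-expression result.

    ``frame`` has columns gene, log2fc, pvalue, qvalue; the universe is
    the set of genes measured in this comparison.
    """

    comparison_id: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DEG_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DegIOError(f"DEG table missing columns {missing}")
        genes = self.frame["gene"]
        dup = genes[genes.duplicated()]
        if len(dup):
            raise DegIOError(
                f"duplicate gene in DEG table {self.comparison_id!r}: {dup.iloc[0]!r}")
        if len(self.frame) == 0:
            raise DegIOError(f"DEG table {self.comparison_id!r} is empty")
        for col in ("pvalue", "qvalue"):
            vals = self.frame[col].to_numpy(float)
            if np.any((vals < 0) | (vals > 1)):
                raise DegIOError(f"{col} outside [0, 1] in {self.comparison_id!r}")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.frame["gene"])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class ComparisonSpec:
    comparison_id: str
    dataset_id: str
    direction: int  # +1: process increased by the perturbation; -1: decreased
    deg_path: str

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise DegIOError(
                f"direction must be +1 or -1, got {self.direction!r} "
                f"for comparison {self.comparison_id!r}")


@dataclass
class ComparisonManifest:
    comparisons: list[ComparisonSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.comparisons:
            raise DegIOError("manifest is empty")
        ids = [c.comparison_id for c in self.comparisons]
        seen: set[str] = set()
        for cid in ids:
            if cid in seen:
                raise DegIOError(f"duplicate comparison_id {cid!r} in manifest")
            seen.add(cid)

    @property
    def ids(self) -> list[str]:
        return [c.comparison_id for c in self.comparisons]

    @property
    def directions(self) -> dict[str, int]:
        return {c.comparison_id: c.direction for c in self.comparisons}

    def __len__(self) -> int:
        return len(self.comparisons)

    def __iter__(self):
        return iter(self.comparisons)


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def items(self):
        return self.sets.items()


def read_deg_table(path: str | Path,
                   comparison_id: str | None = None,
                   dialect: Mapping[str, str] | None = None,
                   sep: str = "\t") -> DegTable:
    """Read a delimited DEG table.

    ``dialect`` maps the canonical column names (gene, log2fc, pvalue,
    qvalue) to the file's own header names, so exports from foreign
    tools can be read without rewriting them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str}, na_values=["NA"])
    if dialect:
        rename = {src: dst for dst, src in dialect.items()}
        missing = [src for src in rename if src not in df.columns]
        if missing:
            raise DegIOError(f"{path}: mapped columns {missing} not present")
        df = df.rename(columns=rename)
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise DegIOError(f"{path}: missing columns {missing}")
    df = df[list(DEG_COLUMNS)].copy()
    df["gene"] = df["gene"].astype(str).str.strip()
    if (df["gene"] == "").any():
        raise DegIOError(f"{path}: empty gene identifier")
    for col in ("log2fc", "pvalue", "qvalue"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise DegIOError(
                f"{path}: unparseable {col} value {df.loc[row, col]!r} "
                f"(gene {df.loc[row, 'gene']!r})")
        if parsed.isna().any():
            row = df.index[parsed.isna()][0]
            raise DegIOError(
                f"{path}: missing required {col} (gene {df.loc[row, 'gene']!r})")
        df[col] = parsed.astype(float)
    return DegTable(comparison_id or path.stem, df.reset_index(drop=True))


def write_deg_table(table: DegTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, na_rep="NA",
                       float_format="%.10g")


def read_manifest(path: str | Path, sep: str = "\t") -> ComparisonManifest:
    """Read a comparison manifest (TSV with header comparison_id,
    dataset_id, direction, deg_path).  Direction accepts +1/-1 and the
    synonyms up/increased and down/decreased.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = ["comparison_id", "dataset_id", "direction", "deg_path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DegIOError(f"{path}: manifest missing columns {missing}")
    specs = []
    for _, row in df.iterrows():
        token = str(row["direction"]).strip().lower()
        if token not in DIRECTION_SYNONYMS:
            raise DegIOError(
                f"{path}: invalid direction {row['direction']!r} for "
                f"comparison {row['comparison_id']!r}")
        specs.append(ComparisonSpec(
            comparison_id=str(row["comparison_id"]).strip(),
            dataset_id=str(row["dataset_id"]).strip(),
            direction=DIRECTION_SYNONYMS[token],
            deg_path=str(row["deg_path"]).strip(),
        ))
    return ComparisonManifest(specs)


def write_manifest(manifest: ComparisonManifest, path: str | Path) -> None:
    rows = [(c.comparison_id, c.dataset_id, f"{c.direction:+d}", c.deg_path)
            for c in manifest]
    pd.DataFrame(rows, columns=["comparison_id", "dataset_id", "direction",
                                "deg_path"]).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name TAB description TAB member..."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DegIOError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields (<3)")
            name, desc = fields[0].strip(), fields[1]
            if name in sets:
                raise DegIOError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [g.strip() for g in fields[2:] if g.strip()]
            if not members:
                raise DegIOError(f"{path}:{lineno}: set {name!r} has no members")
            uniq = frozenset(members)
            if len(uniq) < len(members):
                logger.info("GMT set %s: %d duplicate members deduplicated",
                            name, len(members) - len(uniq))
            sets[name] = (desc, uniq)
    if not sets:
        raise DegIOError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def adjust_bh(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def simple_deg(expr: pd.DataFrame,
               group_labels: Sequence[str],
               comparison_id: str = "simple_deg",
               levels: tuple[str, str] | None = None) -> DegTable:
    """Two-group Welch test per gene on a log-scale expression matrix.

    ``expr`` is genes x samples; ``group_labels`` assigns each sample
    column to one of two groups.  log2fc is mean(first level) minus
    mean(second level); ``levels`` fixes which group is "perturbed"
    (defaults to order of first appearance).  Genes with zero variance
    and zero mean difference get p = 1 so that downstream affinity is 0.
    """
    labels = pd.Series(list(group_labels))
    if len(labels) != expr.shape[1]:
        raise ValueError("group_labels length must match sample count")
    if levels is None:
        levels = tuple(labels.drop_duplicates())  # type: ignore[assignment]
    if len(set(labels)) != 2 or set(levels) != set(labels):
        raise ValueError("exactly two groups required")
    a_idx = (labels == levels[0]).to_numpy()
    b_idx = (labels == levels[1]).to_numpy()
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    mat = expr.to_numpy(float)
    if not np.all(np.isfinite(mat)):
        raise ValueError("expression matrix contains non-finite values")
    a, b = mat[:, a_idx], mat[:, b_idx]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    pvals = np.where(zero_var & (log2fc == 0), 1.0, pvals)
    pvals = np.where(zero_var & (log2fc != 0), 0.0, pvals)
    pvals = np.nan_to_num(pvals, nan=1.0)
    frame = pd.DataFrame({
        "gene": [str(g) for g in expr.index],
        "log2fc": log2fc,
        "pvalue": pvals,
        "qvalue": adjust_bh(pvals),
    })
    return DegTable(comparison_id, frame)
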