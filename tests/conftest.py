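import numpy as np
import pandas as pd
import pytest

from degvote.degio import ComparisonManifest, ComparisonSpec, DegTable


def make_deg_table(comparison_id, rows):
    """rows: list of (gene, log2fc, pvalue, qvalue)."""
    frame = pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue", "qvalue"])
    return DegTable(comparison_id, frame)


@pytest.fixture
def two_cmp_manifest(tmp_path):
    """Two comparisons with opposite process directions plus their DEG
    tables, written to disk in the package's own formats."""
    t1 = make_deg_table("CMP1", [("GENEA", 1.2, 0.001, 0.01),
                                 ("GENEB", -0.8, 0.002, 0.02),
                                 ("GENEC", 0.3, 0.5, 0.8)])
    t2 = make_deg_table("CMP2", [("GENEA", 0.9, 0.001, 0.01),
                                 ("GENEB", -1.1, 0.003, 0.03),
                                 ("GENED", 0.1, 0.9, 0.95)])
    manifest = ComparisonManifest([
        ComparisonSpec("CMP1", "DS1", 1, "cmp1.deg.tsv"),
        ComparisonSpec("CMP2", "DS1", -1, "cmp2.deg.tsv"),
    ])
    from degvote.degio import write_deg_table, write_manifest
    write_deg_table(t1, tmp_path / "cmp1.deg.tsv")
    write_deg_table(t2, tmp_path / "cmp2.deg.tsv")
    write_manifest(manifest, tmp_path / "manifest.tsv")
    return tmp_path, manifest, {"CMP1": t1, "CMP2": t2}


def random_affinity_matrix(rng, n_genes=50, n_comparisons=8, p_na=0.15):
    """Random matrix over {+1, -1, 0, NaN} for oracle comparisons."""
    vals = rng.choice([-1.0, 0.0, 1.0], size=(n_genes, n_comparisons),
                      p=[0.2, 0.6, 0.2])
    vals[rng.random((n_genes, n_comparisons)) < p_na] = np.nan
    genes = [f"G{i:04d}" for i in range(n_genes)]
    cols = [f"C{j:02d}" for j in range(n_comparisons)]
    return pd.DataFrame(vals, index=pd.Index(genes, name="gene"),
                        columns=cols)
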