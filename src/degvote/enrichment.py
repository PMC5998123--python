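"""Gene-set enrichment with a threshold-odds-ratio Fisher exact test.

The standard one-sided Fisher test rejects when the selected list
overlaps a gene set more than chance (odds ratio 1) allows.  Screening
hundreds of sets against a strong gene list makes that null too easy;
here the null is the composite "odds ratio < psi0" with psi0 > 1, and
the p-value is computed at the boundary under Fisher's noncentral
hypergeometric distribution:

    P(X >= a | psi0) with weights  C(K, k) C(N-K, n-k) psi0^k,

where N is the background size, K the set size within the background,
n the selected-list size and a the observed overlap.  psi0 = 1 recovers
the ordinary one-sided Fisher exact test.  The weight sums are done in
log space so large margins stay stable.

BH correction is applied across the tested sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .degio import GeneSetCollection, adjust_bh

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap table: a = selected&set, b = selected only,
    c = set only, d = neither — all within the background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def background_size(self) -> int:
        return self.a + self.b + self.c + self.d


def make_table(selected: set[str], gene_set: set[str],
               background: set[str]) -> ContingencyTable:
    """Overlap table of a selected gene list with one gene set, both
    restricted to the background universe."""
    if not background:
        raise ValueError("background is empty")
    sel = set(selected) & set(background)
    dropped = len(set(selected)) - len(sel)
    if dropped:
        logger.info("make_table: %d selected genes outside background dropped",
                    dropped)
    if not sel:
        raise ValueError("no selected genes inside the background")
    gs = set(gene_set) & set(background)
    a = len(sel & gs)
    b = len(sel) - a
    c = len(gs) - a
    d = len(background) - a - b - c
    return ContingencyTable(a, b, c, d)


def _log_weights(t: ContingencyTable, psi0: float) -> tuple[np.ndarray, np.ndarray]:
    n = t.a + t.b          # draws (selected size)
    big_k = t.a + t.c      # successes (set size)
    big_n = t.background_size
    kmin = max(0, n + big_k - big_n)
    kmax = min(n, big_k)
    k = np.arange(kmin, kmax + 1)
    logw = (gammaln(big_k + 1) - gammaln(k + 1) - gammaln(big_k - k + 1)
            + gammaln(big_n - big_k + 1) - gammaln(n - k + 1)
            - gammaln(big_n - big_k - n + k + 1))
    if psi0 != 1.0:
        logw = logw + k * np.log(psi0)
    return k, logw


def fisher_threshold_test(t: ContingencyTable, psi0: float = 1.0) -> float:
    """One-sided exact p-value P(X >= a) under the noncentral
    hypergeometric distribution with odds-ratio parameter ``psi0``.

    Degenerate margins (empty selected list or empty set) give p = 1
    with a warning.  psi0 = 0 puts all mass at the minimum overlap.
    """
    if psi0 < 0:
        raise ValueError("psi0 must be >= 0")
    if t.a + t.b == 0 or t.a + t.c == 0:
        warnings.warn("degenerate contingency margins; p = 1", stacklevel=2)
        return 1.0
    if psi0 == 0.0:
        kmin = max(0, (t.a + t.b) + (t.a + t.c) - t.background_size)
        return 1.0 if t.a <= kmin else 0.0
    k, logw = _log_weights(t, psi0)
    total = logsumexp(logw)
    tail = logw[k >= t.a]
    if tail.size == 0:  # a below support: X >= a always
        return 1.0
    return float(min(1.0, np.exp(logsumexp(tail) - total)))


def noncentral_pmf(t: ContingencyTable, psi0: float) -> pd.Series:
    """Normalised noncentral hypergeometric pmf over the table's support
    (diagnostic; sums to 1)."""
    k, logw = _log_weights(t, psi0)
    p = np.exp(logw - logsumexp(logw))
    return pd.Series(p, index=k)


def sample_odds_ratio(t: ContingencyTable) -> float:
    """ad/bc, with Haldane–Anscombe 0.5 added to every cell only when
    some cell is zero.  Reporting only — never used inside the test."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def enrich(selected: set[str], collection: GeneSetCollection,
           background: set[str], psi0: float = 2.0,
           min_set: int = 5, max_set: int = 2000) -> pd.DataFrame:
    """Test every gene set in ``collection`` for enrichment in
    ``selected`` against ``background``.

    Sets are intersected with the background and kept when their size is
    within [min_set, max_set].  Rows report counts, the sample odds
    ratio, the threshold-Fisher p-value at ``psi0`` and the BH q-value
    across surviving sets, sorted by ascending p then set name.
    """
    rows = []
    for name, (_desc, members) in collection.items():
        gs = set(members) & set(background)
        if not (min_set <= len(gs) <= max_set):
            continue
        t = make_table(selected, gs, background)
        rows.append({
            "set_name": name, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "odds_ratio": sample_odds_ratio(t),
            "pvalue": fisher_threshold_test(t, psi0),
        })
    if not rows:
        warnings.warn("no gene sets survive the size filters", stacklevel=2)
        return pd.DataFrame(columns=["set_name", "a", "b", "c", "d",
                                     "odds_ratio", "pvalue", "qvalue"])
    df = pd.DataFrame(rows)
    df["qvalue"] = adjust_bh(df["pvalue"].to_numpy())
    df = df.sort_values(["pvalue", "set_name"], kind="mergesort")
    return df.reset_index(drop=True)


def write_enrichment(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
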