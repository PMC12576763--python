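"""Overrepresentation tests: Fisher/hypergeometric GO enrichment and
TAP-family composition.

Per term, a one-sided hypergeometric upper-tail p-value (equivalent to
one-sided Fisher's exact test on the 2x2 table) asks whether the gene set
contains more term-annotated genes than expected from the universe;
Benjamini-Hochberg adjustment is applied across terms within a gene set.
The TAP composition test asks, per family, whether the observed family count
among a set of TAPs exceeds a background frequency, via an exact binomial
upper tail.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def fisher_enrichment(
    gene_set: set[str],
    annotations: pd.DataFrame,
    universe: set[str] | None = None,
    alpha: float = 0.05,
    term_type: str | None = None,
) -> pd.DataFrame:
    """Per-term overrepresentation of ``gene_set`` within ``universe``.

    ``annotations`` has columns gene_id, term_id (term_type optional filter).
    The universe defaults to all annotated genes united with the gene set.
    Returns a table with the 2x2 counts (a = set & term, b = set only,
    c = term only, d = neither), hypergeometric upper-tail ``pvalue``,
    BH-adjusted ``padj`` and ``enriched`` (padj < alpha).
    """
    ann = annotations
    if term_type is not None and "term_type" in ann.columns:
        ann = ann[ann["term_type"] == term_type]
    if universe is None:
        universe = set(ann["gene_id"]) | set(gene_set)
    if not universe:
        raise ValueError("empty universe")
    if not set(gene_set) <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    ann = ann[ann["gene_id"].isin(universe)]
    N = len(universe)
    n = len(gene_set)
    rows = []
    for term, sub in ann.groupby("term_id"):
        term_genes = set(sub["gene_id"])
        K = len(term_genes)
        a = len(term_genes & gene_set)
        p = float(stats.hypergeom.sf(a - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "a": a,
                "b": n - a,
                "c": K - a,
                "d": N - n - K + a,
                "pvalue": min(1.0, p),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "a", "b", "c", "d", "pvalue", "padj", "enriched"]
        )
    res = pd.DataFrame(rows)
    res["padj"] = multipletests(res["pvalue"].to_numpy(), method="fdr_bh")[1]
    res["enriched"] = res["padj"] < alpha
    return res.sort_values("pvalue", ignore_index=True)


def tap_composition_test(
    tap_families: pd.Series | dict[str, str],
    background_freqs: dict[str, float],
) -> pd.DataFrame:
    """Exact binomial composition test of TAP families.

    ``tap_families`` maps gene_id -> family label for the observed TAPs.
    ``background_freqs`` (family -> expected proportion) must sum to 1 and
    cover every observed family. Returns per observed family the count,
    exact observed proportion, background frequency and upper-tail binomial
    p-value for overrepresentation.
    """
    fams = pd.Series(tap_families)
    total = float(sum(background_freqs.values()))
    if not np.isclose(total, 1.0):
        raise ValueError("background frequencies must sum to 1")
    n = len(fams)
    if n == 0:
        raise ValueError("no TAP genes supplied")
    counts = fams.value_counts()
    missing = set(counts.index) - set(background_freqs)
    if missing:
        raise ValueError(f"families missing from background: {sorted(missing)}")
    rows = []
    for fam, k in counts.items():
        p0 = background_freqs[fam]
        rows.append(
            {
                "family": fam,
                "count": int(k),
                "total": n,
                "proportion": k / n,
                "background": p0,
                "pvalue": float(stats.binom.sf(k - 1, n, p0)),
            }
        )
    return pd.DataFrame(rows).sort_values("pvalue", ignore_index=True)
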