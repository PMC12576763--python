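"""Gene filtering, nitrogen-contrast differential expression, set intersections.

The differential-expression step is a deliberate surrogate: a per-gene Welch
two-sample t-test on the variance-stabilized values with Benjamini-Hochberg
adjustment and an effect-size gate (|mean difference| > 1 on the log-like
scale), mirroring the "two-fold above/below background, FDR < 0.05" decision
rule without re-fitting a negative-binomial count model. It operates on the
same matrix the network stage consumes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import GENOTYPES, NITROGEN_LEVELS, SEGMENTS


class EmptyExpressionError(ValueError):
    """Raised when a filtering step removes every gene."""


def filter_genes(X: pd.DataFrame, max_missing_fraction: float = 0.5) -> pd.DataFrame:
    """Drop genes with too many missing entries or zero variance.

    A gene is removed if its missing fraction exceeds ``max_missing_fraction``
    OR its variance over non-missing entries is zero. Samples are untouched.
    Idempotent.
    """
    if X.empty:
        raise ValueError("expression matrix is empty")
    missing_frac = X.isna().mean(axis=1)
    var = X.var(axis=1, ddof=0, skipna=True)
    keep = (missing_frac <= max_missing_fraction) & (var > 0) & var.notna()
    if not keep.any():
        raise EmptyExpressionError("filtering removed every gene")
    return X.loc[keep]


def default_contrasts() -> list[tuple[str, str]]:
    """The eight within-genotype, within-segment nitrogen contrasts."""
    return list(itertools.product(GENOTYPES, SEGMENTS))


def contrast_id(genotype: str, segment: str) -> str:
    lo, hi = NITROGEN_LEVELS
    return f"{genotype}-{segment}-{lo} vs {genotype}-{segment}-{hi}"


def select_degs(
    X: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str],
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential expression for one nitrogen contrast.

    ``contrast`` fixes (genotype, segment); the two nitrogen levels are
    compared with a Welch t-test per gene. Returns a per-gene table with
    columns ``effect`` (mean at high N minus mean at low N), ``pvalue``,
    ``padj`` (BH), ``deg`` (|effect| strictly > ``lfc_threshold`` AND
    padj < ``alpha``) and ``direction`` (``up`` = higher at 270 mg N kg^-1).
    """
    genotype, segment = contrast
    lo, hi = NITROGEN_LEVELS
    sel = (design["genotype"] == genotype) & (design["segment"] == segment)
    lo_ids = design.loc[sel & (design["nitrogen"] == lo), "sample_id"]
    hi_ids = design.loc[sel & (design["nitrogen"] == hi), "sample_id"]
    if len(lo_ids) < 2 or len(hi_ids) < 2:
        raise ValueError(
            f"contrast {contrast_id(genotype, segment)} needs >= 2 samples per side"
        )
    a = X.loc[:, hi_ids].to_numpy()
    b = X.loc[:, lo_ids].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(p, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)
    effect = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    padj = multipletests(p, method="fdr_bh")[1]
    deg = (np.abs(effect) > lfc_threshold) & (padj < alpha)
    return pd.DataFrame(
        {
            "gene_id": X.index,
            "contrast_id": contrast_id(genotype, segment),
            "effect": effect,
            "pvalue": p,
            "padj": padj,
            "deg": deg,
            "direction": np.where(effect > 0, "up", "down"),
        }
    ).set_index("gene_id")


def run_all_contrasts(
    X: pd.DataFrame,
    design: pd.DataFrame,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """``select_degs`` over all eight default contrasts, keyed by contrast id."""
    out = {}
    for g, s in default_contrasts():
        res = select_degs(X, design, (g, s), lfc_threshold, alpha)
        out[contrast_id(g, s)] = res
    return out


def deg_union(results: dict[str, pd.DataFrame]) -> set[str]:
    """Genes flagged in at least one contrast (the network input set)."""
    union: set[str] = set()
    for res in results.values():
        union |= set(res.index[res["deg"]])
    return union


def deg_sets(results: dict[str, pd.DataFrame]) -> dict[str, set[str]]:
    """Directional DEG sets, one per contrast x direction (e.g. ``R-P_up``)."""
    sets = {}
    for cid, res in results.items():
        genotype, segment = cid.split(" vs ")[0].rsplit("-", 1)[0].split("-", 1)
        for direction in ("up", "down"):
            mask = res["deg"] & (res["direction"] == direction)
            sets[f"{genotype}-{segment}_{direction}"] = set(res.index[mask])
    return sets


@dataclass
class SetIntersection:
    """Exclusive (UpSet-style) intersections of named gene sets.

    ``exclusive`` maps a frozenset of set names to the genes found in exactly
    those sets; the exclusive cells partition the union of all sets.
    """

    sets: dict[str, set[str]]
    exclusive: dict[frozenset[str], set[str]]

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out

    def core(self, names: list[str] | None = None) -> set[str]:
        """Genes present in ALL of the named sets (default: all sets)."""
        names = list(self.sets) if names is None else names
        if not names:
            return set()
        out = set(self.sets[names[0]])
        for n in names[1:]:
            out &= self.sets[n]
        return out

    def sizes(self) -> pd.DataFrame:
        rows = [
            {"combination": "&".join(sorted(k)), "size": len(v)}
            for k, v in self.exclusive.items()
        ]
        return pd.DataFrame(rows).sort_values("size", ascending=False, ignore_index=True)


def intersect_sets(sets: dict[str, set[str]]) -> SetIntersection:
    """Compute exclusive intersections via per-gene membership signatures."""
    if not sets:
        raise ValueError("need at least one set")
    exclusive: dict[frozenset[str], set[str]] = {}
    union: set[str] = set()
    for s in sets.values():
        union |= s
    for gene in union:
        key = frozenset(name for name, s in sets.items() if gene in s)
        exclusive.setdefault(key, set()).add(gene)
    return SetIntersection(sets={k: set(v) for k, v in sets.items()}, exclusive=exclusive)
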