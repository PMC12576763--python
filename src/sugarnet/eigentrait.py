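"""Module eigengenes and eigengene-trait correlation screening.

The eigengene of a module is the first principal component of its
gene-standardized expression submatrix: the per-sample score vector that
captures the largest share of the module's expression variance. Eigengenes
are screened against sample traits with Spearman correlation; a module is
selected for a trait when |rho| exceeds the cut (default 0.7) and the
Bonferroni-adjusted p-value (family = modules x variables) is below alpha.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mcl import ModulePartition


@dataclass
class Eigengene:
    """First-PC summary profile of one module.

    ``scores`` is the unit-norm per-sample vector, oriented so its Pearson
    correlation with the module's mean standardized profile is >= 0 (when the
    mean profile is constant — e.g. two perfectly anti-correlated members —
    the first nonzero score entry is made positive instead).
    ``variance_explained`` is the first-PC share of total variance.
    """

    module: int
    scores: pd.Series
    variance_explained: float
    sign: int


def eigengene(X: pd.DataFrame, members: list[str], module: int = 0) -> Eigengene:
    """Compute a module eigengene from a genes x samples matrix.

    Genes are standardized (mean 0, SD 1) before the decomposition, so no
    single high-amplitude gene dominates.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("a module needs at least 2 member genes")
    missing = [g for g in members if g not in X.index]
    if missing:
        raise KeyError(f"module members absent from matrix: {missing[:5]}")
    sub = X.loc[members].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant gene in module; filter first")
    Z = (sub - mu) / sd
    # first right singular vector = per-sample PC scores direction
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = Vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = Z.mean(axis=0)
    sign = 1
    if mean_profile.std() > 1e-12:
        c = np.corrcoef(scores, mean_profile)[0, 1]
        if c < 0:
            sign = -1
    else:
        nz = np.flatnonzero(np.abs(scores) > 1e-12)
        if nz.size and scores[nz[0]] < 0:
            sign = -1
    scores = sign * scores
    return Eigengene(
        module=module,
        scores=pd.Series(scores, index=X.columns, name=f"ME{module}"),
        variance_explained=var_explained,
        sign=sign,
    )


def module_eigengenes(
    X: pd.DataFrame, partition: ModulePartition, min_size: int = 2
) -> list[Eigengene]:
    """Eigengenes for every module of the partition with >= min_size members."""
    out = []
    for label, members in sorted(partition.members.items()):
        if len(members) >= min_size:
            out.append(eigengene(X, members, module=label))
    return out


def eigengene_matrix(eigengenes: list[Eigengene]) -> pd.DataFrame:
    """Modules x samples matrix of eigengene scores."""
    return pd.DataFrame({e.module: e.scores for e in eigengenes}).T.rename_axis("module")


def _exact_spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided exact permutation p-value for Spearman rho at small n."""
    ranks = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(range(n))), dtype=int)
    x = ranks - ranks.mean()
    null = (x @ (ranks[perms] - ranks.mean()).T) / (x @ x)
    return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))


def spearman(x: np.ndarray, y: np.ndarray, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and two-sided p-value.

    Uses an exhaustive permutation null for n <= ``exact_max_n`` (untied data);
    the t-approximation otherwise.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return math.nan, math.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    tied = len(set(rx)) < n or len(set(ry)) < n
    if n <= exact_max_n and not tied:
        return rho, _exact_spearman_pvalue(rho, n)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(1.0, p))


def interaction_variable(design: pd.DataFrame) -> pd.Series:
    """Genotype x nitrogen interaction as the product of centered codings.

    In a balanced design the result is orthogonal to both main effects;
    (R, 270) and (NR, 10) samples get +0.25, the other cells -0.25.
    """
    g = (design["genotype"].to_numpy() == "R").astype(float)
    n = (design["nitrogen"].to_numpy() == design["nitrogen"].max()).astype(float)
    v = (g - g.mean()) * (n - n.mean())
    return pd.Series(v, index=design["sample_id"].tolist(), name="genotype_x_nitrogen")


def screen_modules(
    eigengenes: list[Eigengene],
    traits: pd.DataFrame,
    rho_cut: float = 0.7,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Spearman screen of every eigengene against every trait column.

    Bonferroni family size defaults to (#modules x #variables). A module is
    ``selected`` for a variable iff |rho| > rho_cut AND bonferroni p < alpha.
    Constant variables yield undefined rho and are flagged, never selected.
    Returns a tidy table (module, variable, rho, pvalue, p_bonf, selected,
    constant).
    """
    if not eigengenes:
        raise ValueError("no eigengenes to screen")
    if traits.shape[1] == 0:
        raise ValueError("no trait variables")
    m = bonferroni_m if bonferroni_m is not None else len(eigengenes) * traits.shape[1]
    rows = []
    for e in eigengenes:
        scores = e.scores.loc[traits.index].to_numpy()
        for var in traits.columns:
            y = traits[var].to_numpy(dtype=float)
            rho, p = spearman(scores, y)
            constant = math.isnan(rho)
            p_bonf = math.nan if constant else min(1.0, p * m)
            selected = (not constant) and abs(rho) > rho_cut and p_bonf < alpha
            rows.append(
                {
                    "module": e.module,
                    "variable": var,
                    "rho": rho,
                    "pvalue": p,
                    "p_bonf": p_bonf,
                    "selected": selected,
                    "constant": constant,
                }
            )
    return pd.DataFrame(rows)


def modules_per_variable(screen: pd.DataFrame) -> dict[str, set[int]]:
    """Selected-module sets per variable (inputs for intersection displays)."""
    out: dict[str, set[int]] = {}
    for var, sub in screen.groupby("variable"):
        out[str(var)] = set(sub.loc[sub["selected"], "module"].astype(int))
    return out
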