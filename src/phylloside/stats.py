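"""Permutation-based inference: sequential-term PERMANOVA, Mantel, rank tests.

The PERMANOVA follows the distance-based linear-model formulation: the
distance matrix D is Gower-centred to an inner-product matrix
G = -1/2 * J D^2 J, terms enter in a fixed order, and each term's sum of
squares is the increment in tr(H G) when the term's columns join the
cumulative design (sequential / Type-I decomposition, the convention of
vegan's adonis2 with ``by="terms"``).  Significance comes from free
permutation of sample identities with the observed statistic included in
the null set.  Nested factors are encoded by entering the concatenated
parent:child labels after the parent term, so the child absorbs only
within-parent variation; interactions are products of the two factors'
dummy codings.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, mannwhitneyu, rankdata, wilcoxon
from skbio import DistanceMatrix

from ._util import rng_from
from .tables import SampleSheet

__all__ = ["PermanovaResult", "permanova", "mantel", "rank_tests"]


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # term, df, sum_of_squares, r_squared, pseudo_F, p_value
    n_permutations: int

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def _encode_term(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy-code one model term; ``a:b`` builds the interaction of a and b."""
    if ":" in term:
        parts = term.split(":")
        combo = meta[parts[0]].astype(str)
        for p in parts[1:]:
            combo = combo + "\x1f" + meta[p].astype(str)
        return pd.get_dummies(combo, dtype=float).to_numpy()
    col = meta[term]
    if col.dtype == object or str(col.dtype) in ("category", "bool"):
        levels = pd.unique(col)
        if len(levels) < 2:
            raise ValueError(f"term {term!r} has a single level")
        return pd.get_dummies(col.astype(str), dtype=float).to_numpy()
    return col.to_numpy(dtype=float).reshape(-1, 1)


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto col(X) and its rank, via SVD."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    r = int((s > tol).sum())
    Ur = U[:, :r]
    return Ur @ Ur.T, r


def permanova(
    D: DistanceMatrix,
    sheet: SampleSheet,
    terms: list[str],
    n_perm: int = 9999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Sequential-term PERMANOVA of a distance matrix on metadata terms.

    ``terms`` is an ordered list of metadata columns; ``a:b`` denotes an
    interaction.  Earlier terms absorb variation shared with later ones.
    With ``exhaustive=True`` all n! relabelings are enumerated instead of
    sampling (only sensible for tiny n); p then equals the exact fraction
    of relabelings with F >= F_observed.
    """
    ids = list(D.ids)
    meta = sheet.aligned_to(ids)
    n = len(ids)
    if n_perm < 99 and not exhaustive:
        warnings.warn(f"n_perm = {n_perm} gives coarse p-values")

    d2 = np.asarray(D.data) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ d2 @ J
    total_ss = float(np.trace(G))

    # cumulative designs: intercept, then each term joined in order
    X_cum = np.ones((n, 1))
    hats = []
    ranks = [1]
    for term in terms:
        X_cum = np.column_stack([X_cum, _encode_term(meta, term)])
        H, r = _hat(X_cum)
        hats.append(H)
        ranks.append(r)
    dfs = np.diff(ranks)
    if (dfs == 0).any():
        bad = [t for t, df in zip(terms, dfs) if df == 0]
        warnings.warn(f"terms with zero marginal df (fully absorbed): {bad}")
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")

    H_stack = np.stack(hats)  # K x n x n

    def stats_for(Gp: np.ndarray) -> tuple[np.ndarray, float]:
        traces = np.einsum("kij,ij->k", H_stack, Gp)
        ss = np.diff(np.concatenate([[0.0], traces]))
        ss_res = float(np.trace(Gp)) - traces[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / dfs) / (ss_res / df_res)
        return ss, F

    ss_obs, F_obs = stats_for(G)
    ss_res = total_ss - ss_obs.sum()

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration only supported for n <= 8")
        count = np.zeros(len(terms))
        n_total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.asarray(perm)
            _, F_p = stats_for(G[np.ix_(idx, idx)])
            count += F_p >= F_obs - 1e-12
            n_total += 1
        p = count / n_total
        n_perm_eff = n_total - 1
    else:
        rng = rng_from(seed)
        count = np.ones(len(terms))  # observed statistic included
        for _ in range(n_perm):
            idx = rng.permutation(n)
            _, F_p = stats_for(G[np.ix_(idx, idx)])
            count += F_p >= F_obs - 1e-12
        p = count / (n_perm + 1)
        n_perm_eff = n_perm

    rows = [
        {
            "term": t,
            "df": int(df),
            "sum_of_squares": float(ss),
            "r_squared": float(ss / total_ss),
            "pseudo_F": float(F),
            "p_value": float(pv),
        }
        for t, df, ss, F, pv in zip(terms, dfs, ss_obs, F_obs, p)
    ]
    rows.append(
        {
            "term": "Residual",
            "df": int(df_res),
            "sum_of_squares": float(ss_res),
            "r_squared": float(ss_res / total_ss),
            "pseudo_F": np.nan,
            "p_value": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "sum_of_squares": total_ss,
            "r_squared": 1.0,
            "pseudo_F": np.nan,
            "p_value": np.nan,
        }
    )
    return PermanovaResult(table=pd.DataFrame(rows), n_permutations=n_perm_eff)


def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test: correlation of two distance matrices over the same samples.

    The statistic is the (rank) correlation of the lower-triangle entries;
    the null distribution permutes rows and columns of ``D2`` simultaneously.
    Returns (rho, p) with the two-sided permutation p-value.
    """
    if list(D1.ids) != list(D2.ids):
        if set(D1.ids) != set(D2.ids):
            raise ValueError("distance matrices cover different samples")
        D2 = D2.filter(D1.ids)
    A = np.asarray(D1.data)
    B = np.asarray(D2.data)
    n = A.shape[0]
    ii, jj = np.tril_indices(n, k=-1)

    if method == "spearman":
        # rank once; permuting D2's rows/cols permutes the same entry multiset,
        # so the rank matrix can be permuted directly
        a = rankdata(A[ii, jj])
        Br = np.zeros_like(B)
        Br[ii, jj] = rankdata(B[ii, jj])
        Br = Br + Br.T
        B_use = Br
    elif method == "pearson":
        a = A[ii, jj]
        B_use = B
    else:
        raise ValueError(f"unknown method {method!r}")

    a = a - a.mean()
    denom_a = np.sqrt((a**2).sum())

    def corr(Bp: np.ndarray) -> float:
        b = Bp[ii, jj]
        b = b - b.mean()
        return float((a * b).sum() / (denom_a * np.sqrt((b**2).sum())))

    rho_obs = corr(B_use)
    rng = rng_from(seed)
    count = 1
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if abs(corr(B_use[np.ix_(idx, idx)])) >= abs(rho_obs) - 1e-12:
            count += 1
    return rho_obs, count / (n_perm + 1)


def rank_tests(x, y, kind: str) -> tuple[float, float]:
    """Classical rank tests used throughout the analysis.

    ``wilcoxon_paired`` (signed-rank), ``wilcoxon_unpaired`` (rank-sum /
    Mann-Whitney), or ``kendall`` (tau-b).  Delegates to scipy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind == "wilcoxon_paired":
        if len(x) != len(y):
            raise ValueError("paired test needs equal-length vectors")
        if np.all(x == y):
            return math.nan, 1.0  # no nonzero differences: degenerate test
        res = wilcoxon(x, y, zero_method="wilcox")
    elif kind == "wilcoxon_unpaired":
        res = mannwhitneyu(x, y)
    elif kind == "kendall":
        res = kendalltau(x, y)
        return float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return float(res.statistic), float(res.pvalue)
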