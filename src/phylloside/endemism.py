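"""Degree of endemism and weighted endemism of leaf samples.

A taxon's degree of endemism e_i is the proportion of sampled host plant
species on which it was never detected (0 = found on every species,
(n-1)/n = private to one species).  Per-sample weighted endemism is the
abundance-weighted mean of e over the sample's community,
W_s = sum_i relabund_{i,s} * e_i, so a sample dominated by host-restricted
taxa scores high.  Taxa seen in at most one sample are excluded before
computing e (their endemism is unidentifiable from a single record).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import wilcoxon

from .tables import CountTable, SampleSheet

__all__ = [
    "EndemismResult",
    "endemism_degrees",
    "weighted_endemism",
    "endemism_regression",
    "side_comparison",
]


@dataclass
class EndemismResult:
    degrees: pd.Series  # e_i per retained taxon
    excluded_taxa: tuple[str, ...]
    n_species: int


def endemism_degrees(
    t: CountTable, sheet: SampleSheet, min_samples: int = 2
) -> EndemismResult:
    """Per-taxon proportion of host species with zero detections.

    Detection is count > 0 on the supplied (typically filtered, unrarefied)
    table.  Taxa detected in fewer than ``min_samples`` samples are
    excluded.
    """
    meta = sheet.aligned_to(t.sample_ids)
    species = meta["plant_species"].to_numpy()
    uniq = np.unique(species)
    if len(uniq) < 2:
        raise ValueError("endemism needs at least 2 host plant species")
    detected = t.counts > 0
    n_samples_detected = detected.sum(axis=1)
    keep = n_samples_detected >= min_samples
    excluded = tuple(np.asarray(t.taxon_ids)[~keep])
    # species x taxa detection
    det_by_species = np.vstack([
        detected[:, species == sp].any(axis=1) for sp in uniq
    ])  # n_species x n_taxa
    e = 1.0 - det_by_species.mean(axis=0)
    degrees = pd.Series(e[keep], index=np.asarray(t.taxon_ids)[keep], name="endemism")
    return EndemismResult(degrees=degrees, excluded_taxa=excluded, n_species=len(uniq))


def weighted_endemism(
    t: CountTable, e: EndemismResult | pd.Series, log_floor: float | None = None
) -> pd.DataFrame:
    """Per-sample weighted endemism W and its natural-log transform.

    W_s = sum over retained taxa of (relative abundance in s) x e_i, with
    relative abundance renormalised over the retained taxa.  Samples whose
    retained-taxon counts are all zero get W = NaN and are flagged.  The
    log transform floors W = 0 at ``log_floor`` (default: half the smallest
    positive W).
    """
    degrees = e.degrees if isinstance(e, EndemismResult) else e
    idx = [t.taxon_ids.index(x) for x in degrees.index]
    sub = t.counts[idx, :].astype(float)
    totals = sub.sum(axis=0)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"weighted endemism undefined for {int(empty.sum())} samples with no retained taxa"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = sub / np.where(empty, np.nan, totals)
    W = np.einsum("ts,t->s", rel, degrees.to_numpy())
    pos = W[np.isfinite(W) & (W > 0)]
    if log_floor is None:
        log_floor = float(pos.min()) / 2.0 if len(pos) else np.nan
    logW = np.log(np.where(W > 0, W, log_floor))
    return pd.DataFrame(
        {"sample_id": list(t.sample_ids), "W": W, "log_W": logW}
    ).set_index("sample_id", drop=False)


@dataclass
class RegressionSummary:
    final_terms: list[str]
    coefficients: pd.Series
    p_values: pd.Series
    adj_r_squared: float
    elimination_trace: list[dict] = field(default_factory=list)
    full_model: object = None
    final_model: object = None


def _design(meta: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=meta.index)
    for term in terms:
        col = meta[term]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=term, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[term] = col.astype(float)
    return X


def endemism_regression(
    W: pd.DataFrame,
    sheet: SampleSheet,
    terms: tuple[str, ...] = ("ph", "leaf_side", "stomatal_density"),
    alpha: float = 0.05,
) -> RegressionSummary:
    """OLS of log weighted endemism on covariates with backward elimination.

    Starting from the full model, the largest-p term is dropped until every
    remaining term has p < ``alpha``.  The full pre-elimination model is
    reported alongside the optimised one.
    """
    meta = sheet.aligned_to(W["sample_id"])
    y = W["log_W"].to_numpy()
    ok = np.isfinite(y)
    y = y[ok]
    meta = meta[ok]
    X_full = _design(meta, list(terms))
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X_full)), X_full.to_numpy()]))
    if rank < X_full.shape[1] + 1:
        corr = X_full.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pair = corr.stack().idxmax() if len(corr) else ("?", "?")
        raise ValueError(f"rank-deficient design; near-collinear columns {pair}")
    full_model = sm.OLS(y, sm.add_constant(X_full)).fit()

    remaining = list(terms)
    trace = []
    model = full_model
    while remaining:
        X = _design(meta, remaining)
        model = sm.OLS(y, sm.add_constant(X)).fit()
        # p per term: worst p over the term's dummy columns
        term_p = {
            term: max(
                model.pvalues[c]
                for c in model.pvalues.index
                if c == term or str(c).startswith(f"{term}_")
            )
            for term in remaining
        }
        worst = max(term_p, key=term_p.get)
        if term_p[worst] < alpha:
            break
        trace.append({"dropped": worst, "p": float(term_p[worst])})
        remaining.remove(worst)
    if not remaining:
        model = sm.OLS(y, np.ones((len(y), 1))).fit()
    return RegressionSummary(
        final_terms=remaining,
        coefficients=model.params,
        p_values=model.pvalues,
        adj_r_squared=float(model.rsquared_adj) if remaining else 0.0,
        elimination_trace=trace,
        full_model=full_model,
        final_model=model,
    )


def side_comparison(
    W: pd.DataFrame,
    sheet: SampleSheet,
    alternative: str = "greater",
    min_pairs: int = 6,
) -> dict:
    """Paired Wilcoxon on W_lower - W_upper, paired by plant individual.

    ``alternative='greater'`` tests the assembly-hypothesis direction
    (endemism higher on the lower leaf side).  Unpaired plants are dropped
    with a warning.
    """
    meta = sheet.aligned_to(W["sample_id"])
    df = W.join(meta[["plant_individual", "leaf_side"]])
    wide = df.pivot_table(index="plant_individual", columns="leaf_side", values="W")
    complete = wide.dropna()
    if len(complete) < len(wide):
        warnings.warn(f"dropped {len(wide) - len(complete)} unpaired plants")
    if len(complete) < min_pairs:
        raise ValueError(f"need >= {min_pairs} complete pairs, got {len(complete)}")
    diffs = complete["lower"] - complete["upper"]
    if np.all(diffs == 0):
        return {"statistic": np.nan, "p_value": 1.0, "n_pairs": int(len(complete))}
    res = wilcoxon(complete["lower"], complete["upper"], alternative=alternative,
                   zero_method="wilcox")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_pairs": int(len(complete)),
        "median_diff": float(diffs.median()),
    }
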