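"""Abundance-occupancy core-microbiome selection.

Taxa are ranked by occupancy (ties: mean relative abundance, then ID) and
added one at a time; the cumulative contribution of the top-k taxa to the
Bray-Curtis structure between samples is tracked, and the core is the
shortest prefix after which the relative gain in explained beta-diversity
falls below a threshold (the "last 2% increase" rule).  This is the spatial
variant of the ranking: the study has no time series, so no temporal
grouping enters the rank index.

The subset Bray-Curtis for a prefix keeps the full-composition values of
the top-k taxa in the numerator over the full-composition denominator, so
contribution(k) is the fraction of each pair's dissimilarity mass carried
by the prefix: non-decreasing in k, bounded by 1, and exactly 1 at k = all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .tables import CountTable, SampleSheet, to_relative_abundance

__all__ = [
    "CoreSelection",
    "rank_taxa",
    "bc_contribution_curve",
    "select_core",
    "core_side_summary",
]


@dataclass
class CoreSelection:
    ranked_taxa: tuple[str, ...]
    bc_contribution: np.ndarray  # cumulative contribution at prefix sizes 1..K
    threshold: float
    core_ids: tuple[str, ...]

    @property
    def core_size(self) -> int:
        return len(self.core_ids)

    def to_frame(self, occupancy=None, mean_relabund=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "taxon_id": list(self.ranked_taxa),
                "rank": np.arange(1, len(self.ranked_taxa) + 1),
                "cumulative_contribution": self.bc_contribution,
                "is_core": [t in set(self.core_ids) for t in self.ranked_taxa],
            }
        )
        if occupancy is not None:
            df["occupancy"] = [occupancy[t] for t in self.ranked_taxa]
        if mean_relabund is not None:
            df["mean_relabund"] = [mean_relabund[t] for t in self.ranked_taxa]
        return df


def rank_taxa(t: CountTable, sheet: SampleSheet | None = None) -> list[str]:
    """Order taxa by decreasing occupancy, then mean relative abundance, then ID."""
    occ = (t.counts > 0).mean(axis=1)
    mean_ra = to_relative_abundance(t).values.mean(axis=1)
    order = sorted(
        range(t.n_taxa), key=lambda i: (-occ[i], -mean_ra[i], t.taxon_ids[i])
    )
    return [t.taxon_ids[i] for i in order]


def bc_contribution_curve(t: CountTable, ranked: list[str]) -> np.ndarray:
    """Cumulative Bray-Curtis contribution of the top-k ranked taxa, k = 1..K.

    contribution(k) = mean over sample pairs of
    (sum over top-k |a_i - b_i|) / (sum over all taxa |a_i - b_i|);
    pairs with zero full dissimilarity are skipped.
    """
    if set(ranked) != set(t.taxon_ids):
        raise ValueError("ranking must cover exactly the table's taxa")
    comp = to_relative_abundance(t)
    idx = [t.taxon_ids.index(x) for x in ranked]
    vals = comp.values[idx, :]  # ranked taxa x samples
    n = vals.shape[1]
    ii, jj = np.triu_indices(n, k=1)
    diffs = np.abs(vals[:, ii] - vals[:, jj])  # taxa x pairs
    full = diffs.sum(axis=0)
    keep = full > 0
    if not keep.any():
        return np.zeros(len(ranked))
    cum = np.cumsum(diffs[:, keep], axis=0)  # prefix numerators
    return (cum / full[keep]).mean(axis=1)


def select_core(
    curve: np.ndarray, ranked: list[str], threshold: float = 0.02
) -> CoreSelection:
    """Shortest prefix after which relative gains stay below ``threshold``.

    The core ends at the last rank whose step still increases the explained
    beta-diversity by at least ``threshold`` (relative); a flat curve falls
    back to the minimal prefix with nonzero contribution.
    """
    curve = np.asarray(curve, dtype=float)
    if np.any(np.diff(curve) < -1e-12):
        raise ValueError("contribution curve must be non-decreasing")
    if len(curve) != len(ranked):
        raise ValueError("curve and ranking length mismatch")
    with np.errstate(divide="ignore", invalid="ignore"):
        gains = np.where(curve[:-1] > 0, curve[1:] / curve[:-1] - 1.0, np.inf)
    big = np.flatnonzero(gains > threshold)
    if len(big):
        k_star = int(big[-1]) + 2  # prefix includes the last qualifying step
    else:
        nz = np.flatnonzero(curve > 0)
        k_star = int(nz[0]) + 1 if len(nz) else len(ranked)
    return CoreSelection(
        ranked_taxa=tuple(ranked),
        bc_contribution=curve,
        threshold=threshold,
        core_ids=tuple(ranked[:k_star]),
    )


def core_side_summary(
    core: CoreSelection, t: CountTable, sheet: SampleSheet
) -> tuple[pd.DataFrame, dict]:
    """Per-sample core abundance/occupancy and the paired side contrasts.

    Returns a per-sample table (summed relative abundance of core taxa and
    fraction of core taxa detected) and one-sided paired Wilcoxon tests
    between leaf sides, paired by plant individual: core relative abundance
    is tested lower > upper, core occupancy upper > lower (the directions
    the assembly hypothesis predicts).
    """
    if not core.core_ids:
        raise ValueError("empty core")
    comp = to_relative_abundance(t)
    meta = sheet.aligned_to(t.sample_ids)
    in_core = np.array([tid in set(core.core_ids) for tid in t.taxon_ids])
    core_ab = comp.values[in_core].sum(axis=0)
    core_occ = (t.counts[in_core] > 0).mean(axis=0)
    per_sample = pd.DataFrame(
        {
            "sample_id": list(t.sample_ids),
            "plant_individual": meta["plant_individual"].to_numpy(),
            "leaf_side": meta["leaf_side"].to_numpy(),
            "core_relabund": core_ab,
            "core_occupancy": core_occ,
        }
    ).set_index("sample_id", drop=False)

    wide_ab = per_sample.pivot_table(
        index="plant_individual", columns="leaf_side", values="core_relabund"
    ).dropna()
    wide_occ = per_sample.pivot_table(
        index="plant_individual", columns="leaf_side", values="core_occupancy"
    ).dropna()
    def _paired_greater(a, b, name, n):
        if np.all(a.to_numpy() == b.to_numpy()):
            return {"statistic": np.nan, "p_value": 1.0, "n_pairs": n}
        res = wilcoxon(a, b, alternative="greater", zero_method="wilcox")
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue), "n_pairs": n}

    tests = {}
    if len(wide_ab) >= 6:
        tests["core_relabund_lower_gt_upper"] = _paired_greater(
            wide_ab["lower"], wide_ab["upper"], "relabund", int(len(wide_ab))
        )
        tests["core_occupancy_upper_gt_lower"] = _paired_greater(
            wide_occ["upper"], wide_occ["lower"], "occupancy", int(len(wide_occ))
        )
    return per_sample, tests
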