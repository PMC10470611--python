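"""End-to-end study pipeline: simulate/load -> filter -> rarefy -> analyses.

``run_pipeline`` reproduces the full leaf-side analysis on a feature table
and metadata sheet (either supplied or simulated): low-count and abundance
filters, rarefaction, alpha diversity, Bray-Curtis PERMANOVA and the
distance-decay Mantel test, per-side neutral-model fits, abundance-occupancy
core selection with per-side contrasts, and weighted endemism with its
regression and paired side test.  The four headline directional findings
(neutral fit closer on upper; alpha diversity higher on upper; core taxa
more abundant on lower; endemism higher on lower) are each given a proper
one-sided test so null designs stay null: the alpha/core/endemism contrasts
use paired Wilcoxon tests and the R-squared contrast uses a within-plant
side-label sign-flip permutation test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import rng_from
from . import __version__
from .core import bc_contribution_curve, core_side_summary, rank_taxa, select_core
from .diversity import alpha_diversity_table, bray_curtis_matrix, geo_distance_matrix
from .endemism import endemism_degrees, endemism_regression, side_comparison, weighted_endemism
from .neutral import fit_neutral, occupancy_abundance
from .simulate import StudyDesign, simulate_study
from .stats import mantel, permanova, rank_tests
from .tables import (
    CountTable,
    SampleSheet,
    filter_low_counts,
    rarefy,
    read_feature_table,
    read_sample_sheet,
    to_relative_abundance,
    write_feature_table,
    write_sample_sheet,
)

__all__ = ["PipelineConfig", "run_pipeline", "directional_findings", "delta_r2_test"]

DEFAULT_TERMS = (
    "ph",
    "stomatal_density",
    "leaf_side",
    "plant_species",
    "plant_individual",
    "leaf_side:plant_species",
)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (round-trips through YAML)."""

    table_path: str | None = None
    metadata_path: str | None = None
    design: StudyDesign | None = None
    depth: int = 4000
    low_count_max: int = 2
    total_relabund_min: float = 0.001
    core_threshold: float = 0.02
    permanova_terms: tuple[str, ...] = DEFAULT_TERMS
    n_perm: int = 9999
    r2_n_perm: int = 199
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.table_path is None and self.design is None:
            self.design = StudyDesign(seed=self.seed)
        if not (0 <= self.total_relabund_min < 1) or self.low_count_max < 0:
            raise ValueError("thresholds out of range")
        if self.core_threshold < 0:
            raise ValueError("core_threshold must be >= 0")

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        if self.design is not None:
            doc["design"] = dataclasses.asdict(self.design)
        doc["permanova_terms"] = list(self.permanova_terms)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc.get("design") is not None:
            doc["design"] = StudyDesign(**doc["design"])
        if "permanova_terms" in doc:
            doc["permanova_terms"] = tuple(doc["permanova_terms"])
        return cls(**doc)


def _group_mean_distance(D, groups: pd.Series):
    """Collapse a sample-level distance matrix to group means of cross-entries."""
    from skbio import DistanceMatrix

    labels = pd.unique(groups)
    mat = np.zeros((len(labels), len(labels)))
    data = np.asarray(D.data)
    idx_of = {g: np.flatnonzero(groups.to_numpy() == g) for g in labels}
    for i, gi in enumerate(labels):
        for j in range(i + 1, len(labels)):
            sub = data[np.ix_(idx_of[gi], idx_of[labels[j]])]
            mat[i, j] = mat[j, i] = sub.mean()
    return DistanceMatrix(mat, ids=[str(g) for g in labels])


def delta_r2_test(
    t: CountTable,
    sheet: SampleSheet,
    N: float,
    n_perm: int = 199,
    seed: int = 0,
    detection: str = "exact",
) -> dict:
    """Sign-flip permutation test of R2_upper - R2_lower > 0.

    Within each plant with both leaf sides sampled, the two side labels are
    swapped with probability 1/2; both per-side neutral fits are recomputed
    per permutation.  Plants missing a side keep their labels (they carry no
    pairing information).
    """
    meta = sheet.aligned_to(t.sample_ids)
    side = meta["leaf_side"].to_numpy().copy()
    ind = meta["plant_individual"].to_numpy()

    def r2_gap(side_labels: np.ndarray) -> tuple[float, float, float, float, float]:
        fits = {}
        for lab in ("upper", "lower"):
            mask = side_labels == lab
            sub = CountTable(
                t.taxon_ids, tuple(np.asarray(t.sample_ids)[mask]), t.counts[:, mask]
            ).drop_empty_taxa()
            fits[lab] = fit_neutral(occupancy_abundance(sub), N=N, detection=detection)
        return (
            fits["upper"].r_squared - fits["lower"].r_squared,
            fits["upper"].r_squared,
            fits["lower"].r_squared,
            fits["upper"].m,
            fits["lower"].m,
        )

    gap_obs, r2_u, r2_l, m_u, m_l = r2_gap(side)
    rng = rng_from(seed)
    pairs = [np.flatnonzero(ind == g) for g in pd.unique(ind)]
    pairs = [p for p in pairs if len(p) == 2 and set(side[p]) == {"upper", "lower"}]
    count = 1
    for _ in range(n_perm):
        flipped = side.copy()
        for p in pairs:
            if rng.random() < 0.5:
                flipped[p] = flipped[p][::-1]
        if r2_gap(flipped)[0] >= gap_obs - 1e-12:
            count += 1
    return {
        "r2_upper": r2_u,
        "r2_lower": r2_l,
        "m_upper": m_u,
        "m_lower": m_l,
        "delta_r2": gap_obs,
        "p_value": count / (n_perm + 1),
        "n_pairs": len(pairs),
        "n_permutations": n_perm,
    }


def directional_findings(
    rarefied: CountTable,
    detection_table: CountTable,
    sheet: SampleSheet,
    depth: int,
    core_threshold: float = 0.02,
    r2_n_perm: int = 199,
    seed: int = 0,
) -> dict:
    """The four headline leaf-side contrasts, each as a one-sided test.

    Returns per-contrast dictionaries with the direction, the statistic and
    the p-value: neutral-fit R2 (upper > lower), alpha diversity
    (upper > lower, richness and inverse Simpson), core relative abundance
    (lower > upper), and weighted endemism (lower > upper).
    """
    out: dict = {}

    # 1. neutral fit quality per side
    out["neutral_r2"] = delta_r2_test(
        rarefied, sheet, N=float(depth), n_perm=r2_n_perm, seed=seed
    )

    # 2. alpha diversity per side, paired by plant
    alpha = alpha_diversity_table(rarefied)
    meta = sheet.aligned_to(rarefied.sample_ids)
    alpha = alpha.join(meta[["plant_individual", "leaf_side"]])
    out["alpha"] = {}
    for metric in ("richness", "inverse_simpson"):
        wide = alpha.pivot_table(
            index="plant_individual", columns="leaf_side", values=metric
        ).dropna()
        stat, p = rank_tests(wide["upper"], wide["lower"], "wilcoxon_paired")
        # one-sided: upper > lower
        from scipy.stats import wilcoxon as _wx

        if np.all(wide["upper"] == wide["lower"]):
            p_one = 1.0
        else:
            p_one = float(
                _wx(wide["upper"], wide["lower"], alternative="greater",
                    zero_method="wilcox").pvalue
            )
        out["alpha"][metric] = {
            "mean_upper": float(wide["upper"].mean()),
            "mean_lower": float(wide["lower"].mean()),
            "p_upper_gt_lower": p_one,
            "n_pairs": int(len(wide)),
        }

    # 3. core selection and per-side core contrasts
    ranked = rank_taxa(rarefied)
    curve = bc_contribution_curve(rarefied, ranked)
    core = select_core(curve, ranked, threshold=core_threshold)
    per_sample, core_tests = core_side_summary(core, rarefied, sheet)
    out["core"] = {
        "core_size": core.core_size,
        "core_ids": list(core.core_ids),
        "core_read_fraction": float(
            to_relative_abundance(rarefied)
            .values[[rarefied.taxon_ids.index(c) for c in core.core_ids], :]
            .mean(axis=1)
            .sum()
        ),
        "tests": core_tests,
    }

    # 4. weighted endemism (detection on the unrarefied filtered table)
    e = endemism_degrees(detection_table, sheet)
    W = weighted_endemism(detection_table, e)
    out["endemism"] = {
        "n_excluded_taxa": len(e.excluded_taxa),
        "mean_W_upper": float(
            W.join(sheet.aligned_to(W["sample_id"])["leaf_side"])
            .groupby("leaf_side")["W"].mean()["upper"]
        ),
        "mean_W_lower": float(
            W.join(sheet.aligned_to(W["sample_id"])["leaf_side"])
            .groupby("leaf_side")["W"].mean()["lower"]
        ),
        "side_test": side_comparison(W, sheet, alternative="greater"),
    }
    out["_endemism_W"] = W
    out["_endemism_degrees"] = e
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis and return (and optionally write) the report."""
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    # --- inputs ---------------------------------------------------------
    truth = None
    if cfg.table_path is not None:
        table = read_feature_table(cfg.table_path)
        sheet = read_sample_sheet(cfg.metadata_path)
        log.append(f"loaded table {cfg.table_path}: {table.n_taxa} taxa x {table.n_samples} samples")
    else:
        table, sheet, truth = simulate_study(cfg.design)
        log.append(
            f"simulated study (seed {cfg.design.seed}): "
            f"{table.n_taxa} taxa x {table.n_samples} samples"
        )
        if out_dir:
            write_feature_table(table, out_dir / "feature_table.tsv")
            write_sample_sheet(sheet, out_dir / "metadata.tsv")
            truth.to_json(out_dir / "truth.json")

    # --- filtering and rarefaction -------------------------------------
    filtered, rep = filter_low_counts(table, per_sample_max=cfg.low_count_max)
    log.append(
        f"low-count filter (<= {cfg.low_count_max}): zeroed {rep.entries_zeroed} entries, "
        f"dropped {len(rep.taxa_dropped)} taxa"
    )
    rare_seed = cfg.seed + 1
    rarefied, rrep = rarefy(filtered, depth=cfg.depth, seed=rare_seed)
    log.append(
        f"rarefied to {cfg.depth} reads (seed {rare_seed}); "
        f"dropped {len(rrep.dropped_samples)} shallow samples"
    )
    sheet_r = SampleSheet(sheet.aligned_to(rarefied.sample_ids).reset_index(drop=True))

    # --- beta diversity inference ---------------------------------------
    comp = to_relative_abundance(rarefied)
    D = bray_curtis_matrix(comp)
    perma = permanova(
        D, sheet_r, list(cfg.permanova_terms), n_perm=cfg.n_perm, seed=cfg.seed + 2
    )
    meta_r = sheet_r.aligned_to(rarefied.sample_ids)
    D_ind = _group_mean_distance(D, meta_r["plant_individual"])
    geo = geo_distance_matrix(sheet_r, collapse="per_individual").filter(D_ind.ids)
    rho, mantel_p = mantel(geo, D_ind, method="spearman", n_perm=cfg.n_perm, seed=cfg.seed + 3)
    log.append(f"PERMANOVA ({perma.n_permutations} permutations); Mantel rho={rho:.3f} p={mantel_p:.3f}")

    # --- headline contrasts ---------------------------------------------
    findings = directional_findings(
        rarefied,
        filtered,
        sheet_r,
        depth=cfg.depth,
        core_threshold=cfg.core_threshold,
        r2_n_perm=cfg.r2_n_perm,
        seed=cfg.seed + 4,
    )
    W = findings.pop("_endemism_W")
    e = findings.pop("_endemism_degrees")
    try:
        reg = endemism_regression(W, sheet_r)
        reg_doc = {
            "final_terms": reg.final_terms,
            "coefficients": {str(k): float(v) for k, v in reg.coefficients.items()},
            "p_values": {str(k): float(v) for k, v in reg.p_values.items()},
            "adj_r_squared": reg.adj_r_squared,
            "eliminated": reg.elimination_trace,
        }
    except ValueError as exc:  # e.g. rank deficiency on degenerate input
        reg_doc = {"error": str(exc)}

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "phylloside_version": __version__,
        "seed": cfg.seed,
        "n_samples": rarefied.n_samples,
        "n_taxa": rarefied.n_taxa,
        "depth": cfg.depth,
        "alpha": findings["alpha"],
        "neutral": findings["neutral_r2"],
        "core": {k: v for k, v in findings["core"].items() if k != "core_ids"},
        "endemism": findings["endemism"],
        "endemism_regression": reg_doc,
        "permanova": perma.table.to_dict(orient="records"),
        "mantel": {"rho": rho, "p_value": mantel_p},
        "log": log,
    }
    if truth is not None:
        report["truth"] = {
            "m_upper": cfg.design.m_upper,
            "m_lower": cfg.design.m_lower,
            "n_core_taxa": cfg.design.n_core_taxa,
        }
    if out_dir:
        with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out_dir / "endemism_taxa.tsv", "w", encoding="utf-8") as fh:
            e.degrees.rename_axis("taxon_id").to_csv(fh, sep="\t")
        W.drop(columns="sample_id").to_csv(out_dir / "endemism_samples.tsv", sep="\t")
        perma.table.to_csv(out_dir / "permanova.tsv", sep="\t", index=False)
    return report
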