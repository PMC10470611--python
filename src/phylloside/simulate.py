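"""Synthetic two-leaf-side phyllosphere community generator.

Every leaf sample is drawn from a shared metacommunity through a
neutral-dispersal kernel: the latent within-sample relative abundance of
taxon i is Beta(N*m*q_i, N*m*(1-q_i)), independently per taxon and
renormalised, and reads are multinomial at depth N.  This is the exact
generative dual of the Sloan occupancy-abundance model fitted by
:mod:`phylloside.neutral`, so the migration parameter m is recoverable from
the generated tables.  Deterministic host filtering enters as multiplicative
boosts on the source pool applied before the neutral draw, so dispersal
strength (m) and selection strength are independently tunable.

The default study frame mirrors a botanical-garden survey: 24 plant species
x 3 individuals x 2 leaf sides, ~14,000 reads per sample, with the lower
(abaxial) surface receiving less immigration (smaller m) but stronger,
species-specific host filtering, a ~0.21-unit more acidic surface, and
essentially all of the stomata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ._util import rng_from
from .tables import CountTable, SampleSheet

__all__ = [
    "Metacommunity",
    "HostFilterProfile",
    "StudyDesign",
    "TruthRecord",
    "build_metacommunity",
    "simulate_sample",
    "simulate_study",
    "planted_core_table",
]

def rng_from_seq(ss: np.random.SeedSequence) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(ss))


# Botanical garden at Berkeley: ~0.14 km^2 frame around these coordinates.
_GARDEN_LAT = 37.8750
_GARDEN_LON = -122.2375
_FRAME_M = 374.0  # sqrt(0.14 km^2)
_PH_RANGE = (4.89, 7.16)  # observed leaf-surface pH range being emulated


@dataclass(frozen=True)
class Metacommunity:
    """Source pool: lognormal-shaped relative abundances summing to 1."""

    taxon_ids: tuple[str, ...]
    source_props: np.ndarray
    sigma_log: float

    def __post_init__(self):
        p = np.asarray(self.source_props, dtype=float)
        if (p <= 0).any():
            raise ValueError("source proportions must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("source proportions must sum to 1")
        object.__setattr__(self, "source_props", p)


@dataclass(frozen=True)
class HostFilterProfile:
    """Multiplicative selection factors one plant species applies to the pool.

    ``boost[i] = 1`` is neutral; ``endemic_set`` lists taxa boosted in this
    species only.
    """

    species: str
    boost: np.ndarray
    endemic_set: tuple[str, ...] = ()

    def __post_init__(self):
        b = np.asarray(self.boost, dtype=float)
        if not np.isfinite(b).all() or (b < 0).any():
            raise ValueError("boosts must be finite and >= 0")
        object.__setattr__(self, "boost", b)


@dataclass
class StudyDesign:
    """Tunable frame of the simulated survey (defaults = the emulated study)."""

    n_species: int = 24
    n_individuals_per_species: int = 3
    n_taxa: int = 500
    sigma_log: float = 2.0
    reads_per_sample: int = 14_000
    m_upper: float = 0.15
    m_lower: float = 0.05
    filter_strength_upper: float = 0.5
    filter_strength_lower: float = 1.0
    n_core_taxa: int = 20
    core_boost: float = 5.0
    n_endemic_per_species: int = 12
    endemic_mass: float = 0.10  # boosted endemic share of each species' source pool
    endemic_boost: float | None = None  # explicit boost overrides the mass target
    endemic_exclusive: bool = False  # boost 0 in all other species' profiles
    individual_effect_sd: float = 0.12
    ph_upper_mean: float = 6.2
    ph_upper_sd: float = 0.45
    ph_offset: float = 0.21
    ph_noise_sd: float = 0.15
    clip_ph: bool = True
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 plant species")
        for m in (self.m_upper, self.m_lower):
            if not (0 < m <= 1):
                raise ValueError("migration parameter m must be in (0, 1]")
        if self.filter_strength_lower < self.filter_strength_upper or self.filter_strength_upper < 0:
            raise ValueError("require filter_strength_lower >= filter_strength_upper >= 0")


@dataclass
class TruthRecord:
    """Ground truth exported with every simulated study."""

    design: StudyDesign
    metacommunity: Metacommunity
    profiles: dict[str, HostFilterProfile]
    core_taxa: tuple[str, ...]
    expected_compositions: pd.DataFrame  # taxa x samples, E[relative abundance]

    def to_json(self, path) -> None:
        doc = {
            "design": asdict(self.design),
            "taxon_ids": list(self.metacommunity.taxon_ids),
            "source_props": self.metacommunity.source_props.tolist(),
            "sigma_log": self.metacommunity.sigma_log,
            "core_taxa": list(self.core_taxa),
            "profiles": {
                sp: {"boost": pr.boost.tolist(), "endemic_set": list(pr.endemic_set)}
                for sp, pr in self.profiles.items()
            },
            "expected_compositions": {
                "samples": list(self.expected_compositions.columns),
                "values": self.expected_compositions.round(10).to_numpy().tolist(),
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)


def build_metacommunity(S: int, sigma_log: float, seed) -> Metacommunity:
    """Draw a lognormal source pool of ``S`` taxa (sigma_log=0 → uniform)."""
    if S < 2:
        raise ValueError("need at least 2 taxa")
    if sigma_log < 0:
        raise ValueError("sigma_log must be >= 0")
    rng = rng_from(seed)
    raw = rng.lognormal(mean=0.0, sigma=sigma_log, size=S) if sigma_log > 0 else np.ones(S)
    p = raw / raw.sum()
    width = len(str(S - 1))
    ids = tuple(f"ASV{str(i).zfill(width)}" for i in range(S))
    return Metacommunity(ids, p, sigma_log)


def simulate_sample(
    meta: Metacommunity,
    profile: HostFilterProfile | None,
    m: float,
    N_reads: int,
    seed,
    strength: float = 1.0,
) -> np.ndarray:
    """Draw one sample's count vector through the neutral kernel.

    Effective source q = normalize(p * boost**strength); latent abundances
    x_i ~ Beta(N*m*q_i, N*m*(1-q_i)) independently, renormalised; reads are
    Multinomial(N_reads, x).  Taxa with q_i = 0 are deterministically absent.
    """
    if not (0 < m <= 1):
        raise ValueError("m must be in (0, 1]")
    rng = rng_from(seed)
    q = meta.source_props.copy()
    if profile is not None:
        q = q * np.power(profile.boost, strength)
        total = q.sum()
        if total == 0:
            raise ValueError("host filter removed every taxon")
        q = q / total
    return _draw_counts(q, m, N_reads, rng)


def _draw_counts(q: np.ndarray, m: float, N_reads: int, rng) -> np.ndarray:
    """Neutral kernel: independent Betas on source q, renormalised, multinomial."""
    nm = N_reads * m
    x = np.zeros_like(q)
    pos = q > 0
    x[pos] = rng.beta(nm * q[pos], nm * (1.0 - q[pos]))
    total = x.sum()
    if total == 0:  # vanishingly unlikely; resample as uniform over q
        x = q
        total = 1.0
    return rng.multinomial(N_reads, x / total)


def _default_profiles(design: StudyDesign, meta: Metacommunity, rng) -> tuple[dict, tuple]:
    """Host-filter profiles: a shared plant-associated core + per-species endemics.

    Core taxa are drawn from the upper abundance ranks (plant-associated taxa
    are common in the pool).  Endemic taxa are drawn from the rarest ranks —
    host-specific taxa are scarce in the shared air pool, which is what makes
    them undetectable on other hosts — and are disjoint across species so
    each species has a private signature.  Unless an explicit
    ``endemic_boost`` is given, each species' endemic boost is set so the
    boosted endemic set makes up ``endemic_mass`` of that species' filtered
    source pool.
    """
    S = design.n_taxa
    order = np.argsort(meta.source_props)[::-1]
    core_pool = order[: max(design.n_core_taxa * 3, 50)]
    core_idx = rng.choice(core_pool, size=design.n_core_taxa, replace=False)
    non_core = order[~np.isin(order, core_idx)]
    n_endemic = min(design.n_endemic_per_species, len(non_core) // design.n_species)
    if n_endemic < 1:
        raise ValueError("not enough taxa for disjoint endemic sets")
    need = n_endemic * design.n_species
    endem_pool = rng.permutation(non_core[-need:])  # rarest ranks
    profiles: dict[str, HostFilterProfile] = {}
    species = [f"species_{i:02d}" for i in range(design.n_species)]
    endemic_of = {
        sp: endem_pool[k * n_endemic : (k + 1) * n_endemic]
        for k, sp in enumerate(species)
    }
    taxa = np.asarray(meta.taxon_ids)
    p = meta.source_props
    for sp in species:
        boost = np.ones(S)
        boost[core_idx] = design.core_boost
        idx = endemic_of[sp]
        if design.endemic_boost is not None:
            boost[idx] = design.endemic_boost
        else:
            # solve B so that B*mass_e = endemic_mass * (total after boosting)
            mass_e = p[idx].sum()
            rest = (p * boost).sum() - (p[idx] * boost[idx]).sum()
            f = design.endemic_mass
            boost[idx] = f * rest / (mass_e * (1.0 - f))
        if design.endemic_exclusive:
            for other, oidx in endemic_of.items():
                if other != sp:
                    boost[oidx] = 0.0
        profiles[sp] = HostFilterProfile(
            species=sp, boost=boost, endemic_set=tuple(taxa[endemic_of[sp]])
        )
    return profiles, tuple(taxa[np.sort(core_idx)])


def simulate_study(design: StudyDesign) -> tuple[CountTable, SampleSheet, TruthRecord]:
    """Simulate the full two-sided survey: one sample per (species, individual, side)."""
    master = np.random.SeedSequence(design.seed)
    setup_ss, covar_ss, drop_ss, samples_ss = master.spawn(4)
    rng_setup = rng_from_seq(setup_ss)
    rng_covar = rng_from_seq(covar_ss)
    rng_drop = rng_from_seq(drop_ss)

    meta = build_metacommunity(design.n_taxa, design.sigma_log, rng_setup)
    profiles, core_taxa = _default_profiles(design, meta, rng_setup)

    species = list(profiles)
    rows = []
    expected = {}
    count_cols = {}
    n_total = design.n_species * design.n_individuals_per_species * 2
    sample_rngs = [rng_from_seq(s) for s in samples_ss.spawn(n_total)]
    k = 0
    for si, sp in enumerate(species):
        # species-level covariates
        hardness = int(rng_covar.integers(0, 4))
        pubescent = bool(rng_covar.random() < 0.4)
        for ind in range(design.n_individuals_per_species):
            individual = f"{sp}_plant{ind}"
            lat = _GARDEN_LAT + (rng_covar.random() - 0.5) * _FRAME_M / 111_195.0
            lon = _GARDEN_LON + (rng_covar.random() - 0.5) * _FRAME_M / (
                111_195.0 * np.cos(np.radians(_GARDEN_LAT))
            )
            leaf_area = float(rng_covar.uniform(94, 276))
            ph_upper = float(rng_covar.normal(design.ph_upper_mean, design.ph_upper_sd))
            ph_lower = float(
                ph_upper - design.ph_offset + rng_covar.normal(0.0, design.ph_noise_sd)
            )
            if design.clip_ph:
                ph_upper = float(np.clip(ph_upper, *_PH_RANGE))
                ph_lower = float(np.clip(ph_lower, *_PH_RANGE))
            # per-plant random effect on the source pool (plants differ a bit)
            if design.individual_effect_sd > 0:
                jitter = rng_covar.lognormal(0.0, design.individual_effect_sd, design.n_taxa)
            else:
                jitter = np.ones(design.n_taxa)
            for side in ("upper", "lower"):
                sample_id = f"{individual}_{side}"
                m = design.m_upper if side == "upper" else design.m_lower
                strength = (
                    design.filter_strength_upper
                    if side == "upper"
                    else design.filter_strength_lower
                )
                boost = np.power(profiles[sp].boost, strength) * jitter
                q = meta.source_props * boost
                q = q / q.sum()
                counts = _draw_counts(q, m, design.reads_per_sample, sample_rngs[k])
                k += 1
                count_cols[sample_id] = counts
                expected[sample_id] = q
                stomata = (
                    float(rng_covar.exponential(2.0))
                    if side == "upper"
                    else float(rng_covar.lognormal(np.log(150.0), 0.5))
                )
                rows.append(
                    {
                        "sample_id": sample_id,
                        "plant_species": sp,
                        "plant_individual": individual,
                        "leaf_side": side,
                        "ph": round(ph_upper if side == "upper" else ph_lower, 3),
                        "stomatal_density": round(stomata, 2),
                        "latitude": round(lat, 7),
                        "longitude": round(lon, 7),
                        "leaf_hardness": hardness,
                        "pubescence": pubescent,
                        "leaf_area": round(leaf_area, 1),
                    }
                )

    sheet_df = pd.DataFrame(rows)
    if design.dropout_rate > 0:
        keep = rng_drop.random(len(sheet_df)) >= design.dropout_rate
        sheet_df = sheet_df[keep].reset_index(drop=True)
        count_cols = {s: count_cols[s] for s in sheet_df["sample_id"]}
        expected = {s: expected[s] for s in sheet_df["sample_id"]}

    table = CountTable(
        meta.taxon_ids,
        tuple(sheet_df["sample_id"]),
        np.column_stack([count_cols[s] for s in sheet_df["sample_id"]]),
    )
    truth = TruthRecord(
        design=design,
        metacommunity=meta,
        profiles=profiles,
        core_taxa=core_taxa,
        expected_compositions=pd.DataFrame(
            expected, index=list(meta.taxon_ids)
        ),
    )
    return table, SampleSheet(sheet_df), truth


def planted_core_table(
    n_core: int = 20,
    n_transient: int = 480,
    n_samples: int = 60,
    depth: int = 4000,
    core_boost: float = 10.0,
    seed: int = 0,
) -> tuple[CountTable, tuple[str, ...]]:
    """Toy table with a planted ubiquitous, high-abundance core.

    Core taxa occur in every sample at ``core_boost``-fold the abundance of
    the transient taxa; each transient taxon appears in a random minority of
    samples.  Used to validate core-selection recovery.
    """
    rng = rng_from(seed)
    ids = tuple(f"CORE{i:03d}" for i in range(n_core)) + tuple(
        f"TRANS{i:03d}" for i in range(n_transient)
    )
    w = np.zeros((n_core + n_transient, n_samples))
    w[:n_core] = core_boost * rng.lognormal(0, 0.5, size=(n_core, n_samples))
    present = rng.random((n_transient, n_samples)) < 0.25
    w[n_core:] = np.where(present, rng.lognormal(0, 0.5, size=(n_transient, n_samples)), 0.0)
    counts = np.column_stack(
        [rng.multinomial(depth, w[:, j] / w[:, j].sum()) for j in range(n_samples)]
    )
    return CountTable(ids, tuple(f"S{j:02d}" for j in range(n_samples)), counts), ids[:n_core]
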