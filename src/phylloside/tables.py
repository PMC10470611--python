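"""Feature tables, sample metadata, count filters and rarefaction.

The on-disk dialect is a dense taxa-by-samples TSV with a ``#TaxonID``
header cell (BIOM v1 JSON is accepted read-only).  Counts are integer read
counts per amplicon sequence variant (ASV); filters implement the study's
denoising conventions: per-sample removal of ASVs at <=2 reads, a 0.1%
total-relative-abundance floor, and rarefaction to a common depth by
multivariate-hypergeometric subsampling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import rng_from

__all__ = [
    "CountTable",
    "CompositionTable",
    "SampleSheet",
    "FilterReport",
    "RarefactionReport",
    "read_feature_table",
    "write_feature_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "filter_low_counts",
    "filter_total_relabund",
    "rarefy",
    "to_relative_abundance",
]

_HEADER_CELL = "#TaxonID"

REQUIRED_METADATA = ("sample_id", "plant_species", "plant_individual", "leaf_side")
LEAF_SIDES = ("upper", "lower")


class TableValidationError(ValueError):
    """Raised when a table violates its structural contract."""


def _check_unique(ids, kind: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise TableValidationError(f"duplicate {kind} identifiers: {dupes[:5]}")
    return ids


@dataclass(frozen=True)
class CountTable:
    """Integer ASV-by-sample read counts (taxa as rows, samples as columns)."""

    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "taxon_ids", _check_unique(self.taxon_ids, "taxon"))
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample"))
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.asarray(counts) == np.floor(counts)):
                raise TableValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise TableValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    # -- container conveniences -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def taxon_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.taxon_ids), columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy())

    def select_samples(self, sample_ids) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(self.taxon_ids, tuple(sample_ids), self.counts[:, idx])

    def select_taxa(self, taxon_ids) -> "CountTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return CountTable(tuple(taxon_ids), self.sample_ids, self.counts[idx, :])

    def drop_empty_taxa(self) -> "CountTable":
        keep = self.taxon_sums() > 0
        return CountTable(
            tuple(np.asarray(self.taxon_ids)[keep]), self.sample_ids, self.counts[keep]
        )


@dataclass(frozen=True)
class CompositionTable:
    """Within-sample relative abundances; each column sums to 1 (or is all-zero)."""

    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    zero_samples: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "taxon_ids", _check_unique(self.taxon_ids, "taxon"))
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample"))
        values = np.asarray(self.values, dtype=float)
        sums = values.sum(axis=0)
        zero = sums == 0
        if not np.allclose(sums[~zero], 1.0, atol=1e-9):
            raise TableValidationError("composition columns must sum to 1")
        flagged = tuple(np.asarray(self.sample_ids)[zero])
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "zero_samples", flagged)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.taxon_ids), columns=list(self.sample_ids))


class SampleSheet:
    """Per-sample covariates: host species, individual, leaf side, pH, ..."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in REQUIRED_METADATA if c not in df.columns]
        if missing:
            raise TableValidationError(f"sample sheet missing required columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"], "sample")
        bad_side = set(df["leaf_side"]) - set(LEAF_SIDES)
        if bad_side:
            raise TableValidationError(f"leaf_side must be one of {LEAF_SIDES}, got {bad_side}")
        if "ph" in df.columns:
            ph = df["ph"].dropna()
            if ((ph < 3) | (ph > 12)).any():
                raise TableValidationError("pH outside plausible range [3, 12]")
        # each plant individual belongs to exactly one species
        per_ind = df.groupby("plant_individual")["plant_species"].nunique()
        if (per_ind > 1).any():
            offenders = per_ind[per_ind > 1].index.tolist()
            raise TableValidationError(f"plant individuals mapped to >1 species: {offenders}")
        self.df = df.set_index("sample_id", drop=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.df["sample_id"])

    def aligned_to(self, sample_ids) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.df.index]
        if missing:
            raise TableValidationError(f"samples absent from sheet: {missing[:5]}")
        return self.df.loc[list(sample_ids)]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path, dialect: str = "tsv_dense") -> CountTable:
    """Read a feature table; ``tsv_dense`` (canonical) or ``biom_json``."""
    path = Path(path)
    if dialect == "tsv_dense":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        try:
            values = df.astype(float).to_numpy()
        except ValueError as exc:
            raise TableValidationError(f"non-numeric cell in {path}: {exc}") from exc
        if not np.all(values == np.floor(values)):
            raise TableValidationError(f"non-integer counts in {path}")
        return CountTable(tuple(df.index), tuple(df.columns), values.astype(np.int64))
    if dialect == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_biom_json(path: Path) -> CountTable:
    # BIOM v1 is plain JSON; supports both dense and sparse matrix_type.
    with open(path) as fh:
        doc = json.load(fh)
    taxa = tuple(row["id"] for row in doc["rows"])
    samples = tuple(col["id"] for col in doc["columns"])
    counts = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = v
    else:
        counts[:] = np.asarray(doc["data"], dtype=float)
    if not np.all(counts == np.floor(counts)):
        raise TableValidationError(f"non-integer counts in {path}")
    return CountTable(taxa, samples, counts.astype(np.int64))


def write_feature_table(t: CountTable, path) -> None:
    """Write the canonical dense TSV dialect (UTF-8, newline-terminated)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_HEADER_CELL + "\t" + "\t".join(t.sample_ids) + "\n")
        for taxon, row in zip(t.taxon_ids, t.counts):
            fh.write(taxon + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t"))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.df.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    entries_zeroed: int = 0
    taxa_dropped: tuple[str, ...] = ()
    note: str = ""


def filter_low_counts(
    t: CountTable, per_sample_max: int = 2, mode: str = "per_entry"
) -> tuple[CountTable, FilterReport]:
    """Remove low-count observations (ASVs at ``<= per_sample_max`` reads).

    ``mode='per_entry'`` (default) zeroes each cell at or below the threshold
    — per-sample singleton/doubleton denoising.  ``mode='max_anywhere'``
    drops an ASV outright when its count never exceeds the threshold in any
    sample.  Taxa whose rows become all-zero are dropped either way.
    """
    if per_sample_max < 0:
        raise ValueError("per_sample_max must be >= 0")
    counts = t.counts.copy()
    if mode == "per_entry":
        mask = (counts > 0) & (counts <= per_sample_max)
        n_zeroed = int(mask.sum())
        counts[mask] = 0
    elif mode == "max_anywhere":
        weak = counts.max(axis=1) <= per_sample_max
        n_zeroed = int((counts[weak] > 0).sum())
        counts[weak] = 0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = counts.sum(axis=1) > 0
    dropped = tuple(np.asarray(t.taxon_ids)[~keep])
    out = CountTable(tuple(np.asarray(t.taxon_ids)[keep]), t.sample_ids, counts[keep])
    return out, FilterReport(entries_zeroed=n_zeroed, taxa_dropped=dropped, note=mode)


def filter_total_relabund(t: CountTable, min_frac: float = 0.001) -> CountTable:
    """Drop taxa whose share of the grand total is strictly below ``min_frac``."""
    if not (0 <= min_frac < 1):
        raise ValueError("min_frac must be in [0, 1)")
    grand = t.counts.sum()
    if grand == 0:
        raise TableValidationError("cannot filter an empty table")
    keep = (t.taxon_sums() / grand) >= min_frac
    return CountTable(tuple(np.asarray(t.taxon_ids)[keep]), t.sample_ids, t.counts[keep])


@dataclass
class RarefactionReport:
    depth: int
    dropped_samples: tuple[str, ...] = field(default_factory=tuple)


def rarefy(
    t: CountTable, depth: int = 4000, seed: int | np.random.Generator = 0
) -> tuple[CountTable, RarefactionReport]:
    """Subsample every sample to ``depth`` reads without replacement.

    One multivariate-hypergeometric draw per sample; samples with fewer than
    ``depth`` total reads are dropped and reported.  Deterministic given
    ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = rng_from(seed)
    sums = t.sample_sums()
    keep = sums >= depth
    if not keep.any():
        raise TableValidationError(f"no sample has >= {depth} reads")
    dropped = tuple(np.asarray(t.sample_ids)[~keep])
    if dropped:
        warnings.warn(f"rarefy: dropped {len(dropped)} samples below depth {depth}")
    cols = []
    for j in np.flatnonzero(keep):
        cols.append(rng.multivariate_hypergeometric(t.counts[:, j], depth))
    out = CountTable(
        t.taxon_ids, tuple(np.asarray(t.sample_ids)[keep]), np.column_stack(cols)
    ).drop_empty_taxa()
    return out, RarefactionReport(depth=depth, dropped_samples=dropped)


def to_relative_abundance(t: CountTable, allow_zero: bool = False) -> CompositionTable:
    """Column-normalise read counts to within-sample relative abundances."""
    sums = t.sample_sums().astype(float)
    if not allow_zero and (sums == 0).any():
        bad = list(np.asarray(t.sample_ids)[sums == 0])
        raise TableValidationError(f"all-zero samples: {bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(sums > 0, t.counts / np.where(sums == 0, 1, sums), 0.0)
    return CompositionTable(t.taxon_ids, t.sample_ids, values)
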