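#!/usr/bin/env python
"""Apply the read-count filters and rarefy to 4,000 reads per sample.

Low-count denoising zeroes any ASV observation of two or fewer reads in a
sample; rarefaction subsamples each remaining sample to a common depth
without replacement.  Writes filtered.tsv and rarefied.tsv.
"""

import warnings
from pathlib import Path

from phylloside.tables import (
    filter_low_counts,
    rarefy,
    read_feature_table,
    write_feature_table,
)

STUDY = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 2
DEPTH = 4000


def main() -> None:
    table = read_feature_table(STUDY / "feature_table.tsv")
    filtered, rep = filter_low_counts(table, per_sample_max=2)
    print(f"low-count filter: zeroed {rep.entries_zeroed} entries, "
          f"dropped {len(rep.taxa_dropped)} ASVs entirely")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rare, rrep = rarefy(filtered, depth=DEPTH, seed=SEED)
    print(f"rarefied to {DEPTH} reads; dropped {len(rrep.dropped_samples)} shallow samples; "
          f"{rare.n_taxa} ASVs remain in {rare.n_samples} samples")
    write_feature_table(filtered, STUDY / "filtered.tsv")
    write_feature_table(rare, STUDY / "rarefied.tsv")


if __name__ == "__main__":
    main()
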