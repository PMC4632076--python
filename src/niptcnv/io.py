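"""Tab-separated bin-count tables and JSON call reports.

All genomic tables are 0-based half-open TSVs; bin counts are keyed by
interval, so row order in the file is irrelevant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import BinCounts, GenomeModel

__all__ = ["write_bin_counts", "read_bin_counts"]


def write_bin_counts(counts: BinCounts, genome: GenomeModel, path) -> None:
    """TSV with header ``chrom  start  end  count`` (valid bins only)."""
    rows = np.flatnonzero(genome.valid)
    df = genome.bins.iloc[rows][["chrom", "start", "end"]].copy()
    df["count"] = counts.raw[rows]
    with open(path, "w") as fh:
        fh.write(f"#sample_id={counts.sample_id}\ttotal_reads={counts.total_reads}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_bin_counts(path, genome: GenomeModel) -> BinCounts:
    """Parse a bin-count TSV and validate it against the genome's grid.

    Malformed rows (negative or non-integer counts) are reported with their
    line number; intervals not on the genome's valid-bin grid are rejected.
    """
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(kv.split("=", 1) for kv in first[1:].strip().split("\t"))
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    required = {"chrom", "start", "end", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    bad = df.index[(df["count"] < 0) | (df["count"] % 1 != 0)]
    if len(bad):
        # +2 for header line, +1 if a comment line preceded it
        offset = 2 + int(bool(meta))
        raise ValueError(f"{path}: invalid count at line {bad[0] + offset}")

    raw = np.zeros(genome.n_bins, dtype=np.int64)
    key_to_row = {(c, s): i for i, (c, s) in
                  enumerate(zip(genome.bins["chrom"], genome.bins["start"]))}
    valid = genome.valid
    for rec in df.itertuples(index=False):
        row = key_to_row.get((rec.chrom, rec.start))
        if row is None or int(genome.bins["end"].iloc[row]) != rec.end:
            raise ValueError(f"{path}: interval {rec.chrom}:{rec.start}-{rec.end} "
                             "not on the genome's bin grid")
        if valid[row]:
            raw[row] = int(rec.count)
    expected = int(valid.sum())
    if len(df) < expected:
        raise ValueError(f"{path}: {len(df)} bins but genome has {expected} valid bins")
    total = int(meta.get("total_reads", raw.sum()))
    return BinCounts(meta.get("sample_id", str(path)), raw,
                     total_reads=max(total, int(raw.sum())))
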