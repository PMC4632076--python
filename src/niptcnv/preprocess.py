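"""Bin-count preprocessing: counting, GC/mappability correction, Z-scores.

The correction chain mirrors standard read-depth NIPT practice: unique
reads are counted into 100-kb bins, bin counts are rescaled by a LOWESS fit
of count on GC fraction, divided by mappability, normalized to the sample
total, and standardized against a euploid reference panel.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import BinCounts, GenomeModel

log = logging.getLogger(__name__)

__all__ = [
    "count_reads_in_bins",
    "correct_gc",
    "correct_mappability",
    "normalized_counts",
    "bin_zscores",
    "chromosome_coverage",
]


def count_reads_in_bins(alignment_path, genome: GenomeModel,
                        min_mapq: int = 30) -> BinCounts:
    """Count uniquely mapped reads into the genome's bins.

    "Unique mapped" is operationalized as primary, non-duplicate, mapped
    alignments with mapping quality >= ``min_mapq``.  Each retained read
    increments the bin containing its leftmost aligned base; reads in gap
    bins and on contigs absent from the genome model are discarded (the
    latter reported once per contig).
    """
    import pysam

    raw = np.zeros(genome.n_bins, dtype=np.int64)
    valid = genome.valid
    total = 0
    skipped_contigs: dict[str, int] = {}
    dropped_gap = 0
    with pysam.AlignmentFile(str(alignment_path)) as fh:
        for read in fh.fetch(until_eof=True):
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_duplicate or read.mapping_quality < min_mapq):
                continue
            chrom = read.reference_name
            try:
                row = genome.bin_row(chrom, read.reference_start)
            except (KeyError, IndexError):
                skipped_contigs[chrom] = skipped_contigs.get(chrom, 0) + 1
                continue
            total += 1
            if not valid[row]:
                dropped_gap += 1
                continue
            raw[row] += 1
    for contig, n in skipped_contigs.items():
        log.warning("skipped %d reads on contig %r absent from genome model", n, contig)
    if total == 0:
        log.warning("%s: no usable reads; all-zero bin counts", alignment_path)
    return BinCounts(str(alignment_path), raw, total_reads=max(total, 1),
                     meta={"skipped_contigs": skipped_contigs, "dropped_in_gaps": dropped_gap})


def correct_gc(counts: BinCounts, genome: GenomeModel, frac: float = 0.3,
               it: int = 1) -> BinCounts:
    """Rescale bin counts by a LOWESS fit of count on GC fraction.

    ``corrected_i = count_i * median(count) / fit(gc_i)`` over valid bins.
    The curve is fitted on counts pre-scaled to each chromosome's median,
    so a chromosome-wide dosage shift (a trisomy, a large CNV) cannot bend
    the GC curve and silently regress away part of its own signal.  Where
    the fit is non-positive it is replaced by the nearest (in GC) positive
    fitted value.  The total corrected mass stays within ~10% of the input
    mass for any realistic bias.
    """
    rows = np.flatnonzero(genome.valid)
    if len(rows) < 100:
        raise ValueError(f"need >= 100 valid bins for a stable LOWESS fit, got {len(rows)}")
    values = counts.working
    y = values[rows]
    gc = genome.bins["gc"].to_numpy()[rows]
    global_med = np.median(y)
    y_fit = y.astype(float).copy()
    chroms = genome.bins["chrom"].to_numpy()[rows]
    for chrom in genome.chrom_names:
        sel = chroms == chrom
        med = np.median(y[sel]) if sel.any() else 0.0
        if med > 0:
            y_fit[sel] *= global_med / med
    if np.ptp(gc) == 0:
        # degenerate GC track: the fit is the global mean, a constant rescale
        fit = np.full_like(y, y_fit.mean(), dtype=float)
    else:
        fit = lowess(y_fit, gc, frac=frac, it=it, xvals=gc)
    bad = ~(fit > 0)
    if bad.any():
        good = np.flatnonzero(~bad)
        if good.size == 0:
            raise ValueError("LOWESS fit non-positive everywhere")
        log.warning("LOWESS fit non-positive at %d bins; using nearest positive fit", bad.sum())
        nearest = good[np.abs(gc[bad, None] - gc[good][None, :]).argmin(axis=1)]
        fit[bad] = fit[nearest]
    corrected = np.zeros(genome.n_bins)
    corrected[rows] = y * np.median(y) / fit
    ratio = corrected[rows].sum() / max(y.sum(), 1e-12)
    if not 0.9 <= ratio <= 1.1:
        log.warning("GC correction changed total mass by %+.1f%%", 100 * (ratio - 1))
    return counts.replace(corrected=corrected)


def correct_mappability(counts: BinCounts, genome: GenomeModel) -> BinCounts:
    """Divide counts by per-bin mappability (valid bins have mappability > 0)."""
    rows = np.flatnonzero(genome.valid)
    values = counts.working
    corrected = np.zeros(genome.n_bins)
    corrected[rows] = values[rows] / genome.bins["mappability"].to_numpy()[rows]
    return counts.replace(corrected=corrected)


def normalized_counts(counts: BinCounts, genome: GenomeModel) -> np.ndarray:
    """Counts divided by the sample's total over valid bins (sums to 1)."""
    rows = np.flatnonzero(genome.valid)
    values = counts.working
    total = values[rows].sum()
    if total <= 0:
        raise ValueError("sample has zero total count")
    out = np.zeros(genome.n_bins)
    out[rows] = values[rows] / total
    return out


def bin_zscores(counts: BinCounts, panel, genome: GenomeModel) -> np.ndarray:
    """Per-bin Z of totals-normalized counts against the panel (NaN where
    the bin is invalid or the panel SD is zero)."""
    norm = normalized_counts(counts, genome)
    z = np.full(genome.n_bins, np.nan)
    rows = np.flatnonzero(genome.valid)
    sd = panel.bin_sd[rows]
    usable = sd > 0
    if (~usable).any():
        log.warning("excluding %d bins with zero panel SD", int((~usable).sum()))
    r = rows[usable]
    z[r] = (norm[r] - panel.bin_mean[r]) / panel.bin_sd[r]
    return z


def chromosome_coverage(counts: BinCounts, genome: GenomeModel) -> pd.DataFrame:
    """Coverage proportion and valid length per chromosome.

    Proportion = sum of (corrected) counts on the chromosome's valid bins
    divided by the sum over all valid *autosomal* bins, so autosomal
    proportions sum to 1.  The autosomal denominator keeps the statistic
    independent of fetal sex: a male fetus depresses chrX coverage, which
    would otherwise inflate every autosomal proportion against a female
    reference panel.  The X chromosome is still reported on the same
    denominator.
    """
    values = counts.working
    recs = []
    for chrom in genome.chrom_names:
        rows = genome.valid_rows(chrom)
        if rows.size == 0:
            log.warning("%s has zero valid bins; excluded from coverage", chrom)
            continue
        recs.append((chrom, values[rows].sum(), genome.valid_length_mb(chrom)))
    df = pd.DataFrame(recs, columns=["chrom", "count", "m_mb"])
    denom = df.loc[df["chrom"].isin(genome.autosomes), "count"].sum()
    df["proportion"] = df["count"] / denom
    return df.drop(columns="count")
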