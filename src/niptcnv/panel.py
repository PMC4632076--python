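"""Euploid reference panel: per-bin and per-chromosome means and SDs.

The panel supplies the standardization used everywhere downstream: per-bin
statistics of totals-normalized corrected counts (for window Z-scores and
CNV segmentation) and per-chromosome statistics of coverage proportions
(for the aneuploidy Z-score).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinCounts, GenomeModel
from .preprocess import (chromosome_coverage, correct_gc, correct_mappability,
                         normalized_counts)

log = logging.getLogger(__name__)

__all__ = ["ReferencePanel", "build_reference_panel"]

#: absolute floor for per-chromosome coverage-proportion SDs
CHROM_SD_FLOOR = 1e-6
#: absolute floor for per-bin normalized-count SDs
BIN_SD_FLOOR = 1e-12


@dataclass
class ReferencePanel:
    """Panel statistics aligned to a genome's bin rows."""

    bin_mean: np.ndarray
    bin_sd: np.ndarray
    chrom_stats: pd.DataFrame  # chrom, mean, sd
    n_samples: int
    grid: pd.DataFrame  # chrom, start, end of the bin grid (for validation)

    def chrom_mean(self, chrom: str) -> float:
        return float(self._row(chrom)["mean"])

    def chrom_sd(self, chrom: str) -> float:
        return float(self._row(chrom)["sd"])

    def _row(self, chrom: str) -> pd.Series:
        sub = self.chrom_stats[self.chrom_stats["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} not in panel")
        return sub.iloc[0]

    def check_grid(self, genome: GenomeModel) -> None:
        g = genome.bins[["chrom", "start", "end"]].reset_index(drop=True)
        if len(g) != len(self.grid) or not g.equals(self.grid.reset_index(drop=True)):
            raise ValueError("panel bin grid does not match the genome model")

    # -- serialization: per-bin TSV plus per-chromosome JSON ---------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        bins = self.grid.copy()
        bins["bin_mean"] = self.bin_mean
        bins["bin_sd"] = self.bin_sd
        bins.to_csv(d / "bins.tsv", sep="\t", index=False)
        payload = {
            "n_samples": self.n_samples,
            "chromosomes": {r.chrom: {"mean": r.mean, "sd": r.sd}
                            for r in self.chrom_stats.itertuples(index=False)},
        }
        (d / "chromosomes.json").write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, directory) -> "ReferencePanel":
        d = Path(directory)
        bins = pd.read_csv(d / "bins.tsv", sep="\t")
        payload = json.loads((d / "chromosomes.json").read_text())
        chrom_stats = pd.DataFrame(
            [(c, v["mean"], v["sd"]) for c, v in payload["chromosomes"].items()],
            columns=["chrom", "mean", "sd"])
        return cls(bins["bin_mean"].to_numpy(), bins["bin_sd"].to_numpy(),
                   chrom_stats, int(payload["n_samples"]),
                   bins[["chrom", "start", "end"]])


def build_reference_panel(samples: list[BinCounts], genome: GenomeModel,
                          gc_frac: float = 0.3) -> ReferencePanel:
    """Build panel statistics from euploid samples.

    Each sample runs through the same GC + mappability correction as a test
    sample; per-bin statistics are computed on totals-normalized corrected
    counts and per-chromosome statistics on coverage proportions.  SDs are
    floored at a small epsilon (with a warning) so degenerate panels cannot
    divide by zero.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 panel samples")
    if len(samples) < 10:
        log.warning("panel of %d samples is small; SDs will be noisy", len(samples))
    norms, covs = [], []
    for s in samples:
        c = correct_mappability(correct_gc(s, genome, frac=gc_frac), genome)
        norms.append(normalized_counts(c, genome))
        covs.append(chromosome_coverage(c, genome).set_index("chrom")["proportion"])
    norm = np.vstack(norms)
    bin_mean = norm.mean(axis=0)
    bin_sd = norm.std(axis=0, ddof=1)
    floored = genome.valid & (bin_sd < BIN_SD_FLOOR)
    if floored.any():
        warnings.warn(f"{int(floored.sum())} bins had panel SD below floor "
                      f"{BIN_SD_FLOOR}; floored", stacklevel=2)
        bin_sd = np.maximum(bin_sd, BIN_SD_FLOOR)
    bin_sd[~genome.valid] = 0.0

    cov = pd.concat(covs, axis=1)
    sd = cov.std(axis=1, ddof=1)
    if (sd < CHROM_SD_FLOOR).any():
        warnings.warn("per-chromosome panel SD below floor "
                      f"{CHROM_SD_FLOOR}; floored", stacklevel=2)
        sd = sd.clip(lower=CHROM_SD_FLOOR)
    chrom_stats = pd.DataFrame({"chrom": cov.index, "mean": cov.mean(axis=1).to_numpy(),
                                "sd": sd.to_numpy()})
    return ReferencePanel(bin_mean, bin_sd, chrom_stats, len(samples),
                          genome.bins[["chrom", "start", "end"]].copy())
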