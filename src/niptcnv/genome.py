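"""Genome bin grid and per-sample bin-count containers.

Read-depth NIPT works on fixed-width genomic windows ("bins", 100 kb by
default).  :class:`GenomeModel` holds the bin grid for a genome together
with the per-bin GC fraction, mappability and a validity mask (bins inside
assembly gaps or centromeres carry no unique reads and are excluded from
every statistic).  The *valid chromosome length* ``m`` — total chromosome
length minus the vacant area unique reads cannot cover — is the length that
enters the maternal-CNV coverage coefficient.

:func:`make_genome_fixture` builds a synthetic genome model so that the
whole pipeline can run without downloading a reference assembly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeModel", "BinCounts", "make_genome_fixture", "default_genome"]

#: columns of the bin table, in serialization order
BIN_COLUMNS = ["chrom", "start", "end", "gc", "mappability", "valid"]


@dataclass
class GenomeModel:
    """Bin grid over an ordered set of chromosomes.

    Parameters
    ----------
    bins
        One row per bin with columns ``chrom, start, end, gc, mappability,
        valid``.  Coordinates are 0-based half-open; bins are sorted by
        chromosome (in input order) and start.  ``gc`` and ``mappability``
        are defined (finite, in range) for every valid bin.
    bin_size
        Bin width in bp.
    x_chrom
        Name of the X-like chromosome used for fetal-fraction estimation,
        or ``None`` if the genome has no sex chromosome.
    """

    bins: pd.DataFrame
    bin_size: int
    x_chrom: str | None = "chrX"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        missing = [c for c in BIN_COLUMNS if c not in self.bins.columns]
        if missing:
            raise ValueError(f"bin table lacks columns {missing}")
        self.bins = self.bins.reset_index(drop=True)
        if int(self.bins["valid"].sum()) == 0:
            raise ValueError("genome model has zero valid bins")
        g = self.bins.loc[self.bins["valid"], "gc"]
        mp = self.bins.loc[self.bins["valid"], "mappability"]
        if not (np.isfinite(g).all() and (g >= 0).all() and (g <= 1).all()):
            raise ValueError("gc must be in [0, 1] on valid bins")
        if not (np.isfinite(mp).all() and (mp > 0).all() and (mp <= 1).all()):
            raise ValueError("mappability must be in (0, 1] on valid bins")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask over bin rows."""
        return self.bins["valid"].to_numpy()

    @property
    def chromosomes(self) -> list[tuple[str, int]]:
        """``(name, length_bp)`` in genome order."""
        out = []
        for chrom in self.chrom_names:
            sub = self.bins[self.bins["chrom"] == chrom]
            out.append((chrom, int(sub["end"].max())))
        return out

    @property
    def chrom_names(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chrom_names if c != self.x_chrom]

    def chrom_rows(self, chrom: str) -> np.ndarray:
        """Row indices of all bins of ``chrom``."""
        idx = np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return idx

    def valid_rows(self, chrom: str | None = None) -> np.ndarray:
        mask = self.valid.copy()
        if chrom is not None:
            cm = (self.bins["chrom"] == chrom).to_numpy()
            if not cm.any():
                raise KeyError(f"unknown chromosome {chrom!r}")
            mask &= cm
        return np.flatnonzero(mask)

    def valid_length_mb(self, chrom: str) -> float:
        """Valid chromosome length ``m`` in Mb (gap bins excluded)."""
        return len(self.valid_rows(chrom)) * self.bin_size / 1e6

    def bin_row(self, chrom: str, pos: int) -> int:
        """Row index of the bin containing genomic position ``pos``.

        A read at an exact bin boundary ``b * bin_size`` belongs to bin
        ``b`` (half-open convention).
        """
        rows = self.chrom_rows(chrom)
        starts = self.bins["start"].to_numpy()[rows]
        if pos < 0 or pos >= int(self.bins["end"].to_numpy()[rows].max()):
            raise IndexError(f"position {pos} outside {chrom}")
        return int(rows[np.searchsorted(starts, pos, side="right") - 1])

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path) -> None:
        df = self.bins[BIN_COLUMNS].copy()
        df["valid"] = df["valid"].astype(int)
        with open(path, "w") as fh:
            fh.write(f"#bin_size={self.bin_size}\tx_chrom={self.x_chrom or '.'}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenomeModel":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing genome header line")
            meta = dict(kv.split("=", 1) for kv in header[1:].strip().split("\t"))
            df = pd.read_csv(fh, sep="\t")
        df["valid"] = df["valid"].astype(bool)
        x = meta.get("x_chrom", ".")
        return cls(df, bin_size=int(meta["bin_size"]), x_chrom=None if x == "." else x)


@dataclass
class BinCounts:
    """Per-bin unique-read counts for one plasma sample.

    ``raw`` holds integer counts aligned to the genome's bin rows (zero in
    gap bins); ``corrected`` is filled by the GC / mappability correction
    stages and stays ``None`` until then.
    """

    sample_id: str
    raw: np.ndarray
    total_reads: int
    corrected: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)
        if (self.raw < 0).any():
            raise ValueError("negative raw counts")
        if int(self.raw.sum()) > self.total_reads:
            raise ValueError("sum(raw) exceeds total_reads")

    @property
    def working(self) -> np.ndarray:
        """Corrected counts if available, else raw counts (as float)."""
        return self.raw.astype(float) if self.corrected is None else self.corrected

    def replace(self, **kw) -> "BinCounts":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# synthetic genome fixture


def _gc_profile(n: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth GC track: long-range waves plus small bin-level jitter."""
    i = np.arange(n)
    waves = np.zeros(n)
    for period in (n / 2.7, n / 7.3, n / 19.0):
        waves += rng.uniform(0.02, 0.05) * np.sin(2 * np.pi * i / max(period, 2.0)
                                                  + rng.uniform(0, 2 * np.pi))
    gc = 0.42 + waves + rng.normal(0.0, 0.015, n)
    return np.clip(gc, 0.30, 0.60)


def make_genome_fixture(
    chrom_lengths: dict[str, int],
    bin_size: int = 100_000,
    gap_fraction: float = 0.05,
    seed: int = 0,
    x_chrom: str | None = "chrX",
) -> GenomeModel:
    """Build a synthetic genome model with gap masks, GC and mappability.

    Each chromosome gets one contiguous gap block of ``gap_fraction`` of its
    bins (a centromere proxy) placed around 40% of its length, a smooth GC
    profile centred at 0.42 and a mappability track near 0.95.  The model is
    deterministic for a fixed ``seed``.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp; every chromosome must span
        at least 10 bins.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not 0 <= gap_fraction < 1:
        raise ValueError("gap_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, length in chrom_lengths.items():
        n = int(np.ceil(length / bin_size))
        if n < 10:
            raise ValueError(f"{chrom}: need >= 10 bins, got {n}")
        starts = np.arange(n) * bin_size
        ends = np.minimum(starts + bin_size, length)
        valid = np.ones(n, bool)
        n_gap = int(round(gap_fraction * n))
        if n_gap:
            g0 = int(0.4 * n) - n_gap // 2
            valid[g0 : g0 + n_gap] = False
        # last bin may be short; drop it from statistics if truncated
        if ends[-1] - starts[-1] < bin_size:
            valid[-1] = False
        gc = _gc_profile(n, rng)
        mappability = np.clip(1.0 - rng.beta(2.0, 30.0, n), 0.5, 1.0)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "gc": gc, "mappability": mappability, "valid": valid,
        }))
    bins = pd.concat(frames, ignore_index=True)
    if x_chrom is not None and x_chrom not in chrom_lengths:
        x_chrom = None
    return GenomeModel(bins, bin_size=bin_size, x_chrom=x_chrom)


#: synthetic stand-ins for the screened chromosomes; lengths chosen so the
#: valid lengths order like the real targets (chr21 shortest, chr13 longest)
DEFAULT_CHROM_LENGTHS_BP = {
    "chr13": 100_000_000,
    "chr18": 75_000_000,
    "chr21": 40_000_000,
    "chrX": 60_000_000,
}


def default_genome(seed: int = 0, bin_size: int = 100_000,
                   gap_fraction: float = 0.05) -> GenomeModel:
    """Synthetic four-chromosome genome (chr13/18/21-like plus chrX-like)."""
    return make_genome_fixture(DEFAULT_CHROM_LENGTHS_BP, bin_size=bin_size,
                               gap_fraction=gap_fraction, seed=seed)
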