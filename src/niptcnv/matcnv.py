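"""Maternal-CNV detection and the coverage-effect coefficient alpha.

A constitutional maternal CNV shifts a chromosome's plasma read count
independently of the fetus and can push the aneuploidy Z-score across the
call threshold.  The coefficient

    alpha = coverage_with_CNV / coverage_without_CNV

quantifies that shift from the CNV's size ``n`` (Mb), copy number ``cn``
and the chromosome's valid length ``m`` (Mb):

    inherited CNV:      alpha = 1 + n (cn - 2) / (2 m)
    not inherited:      alpha = 1 + (1 - f) n (cn - 2) / (2 m)

where ``f`` is the fetal fraction.  Dividing the observed chromosome
coverage by alpha restores the CNV-free value.  The closed forms above are
a reconstruction: the source describes alpha's defining ratio, its limits
(alpha = 1 at cn = 2 or n = 0, > 1 for duplications, < 1 for deletions)
and the sign of the inherited/non-inherited difference, but prints the
formulas only as figures; the reconstruction satisfies every stated
property and matches the simulator's coverage ratios exactly.  See
docs/methods.md.

To avoid false negatives, duplications are adjusted with the non-inherited
form (the smaller correction) and deletions with the inherited form (the
smaller upward correction) — the conservative choice in each direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import BinCounts, GenomeModel
from .panel import ReferencePanel
from .segment import overlap_grid, segment_windows, window_stats

log = logging.getLogger(__name__)

__all__ = [
    "CnvCall", "AlphaResult",
    "alpha_inherited", "alpha_not_inherited",
    "call_maternal_cnvs", "select_alpha", "adjust_coverage",
]

#: CNVs below this genomic span do not trigger coverage calibration
MIN_CNV_SIZE_MB = 0.3


@dataclass
class CnvCall:
    """A called maternal CNV with its estimated integer copy number."""

    chrom: str
    start: int
    end: int
    size_mb: float
    cn: int
    mean_z: float

    @property
    def direction(self) -> str:
        return "dup" if self.cn > 2 else "del"


@dataclass
class AlphaResult:
    """Per-chromosome coverage-effect coefficient and its provenance."""

    chrom: str
    alpha: float
    m_mb: float
    f: float | None
    cnvs: list[CnvCall] = field(default_factory=list)
    function_used: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# the coefficient


def _check_mn(m: float, n: float, cn: int) -> None:
    if m <= 0:
        raise ValueError(f"valid chromosome length m must be positive, got {m}")
    if n < 0 or n > m:
        raise ValueError(f"CNV size n must satisfy 0 <= n <= m, got n={n}, m={m}")
    if cn < 0 or int(cn) != cn:
        raise ValueError(f"copy number must be a non-negative integer, got {cn}")


def alpha_inherited(m: float, n: float, cn: int) -> float:
    """Coverage-effect coefficient when the fetus inherits the maternal CNV.

    Both compartments carry ``cn`` copies, so the full excess applies:
    ``alpha = 1 + n (cn - 2) / (2 m)``; equals 1 at ``cn = 2`` or ``n = 0``.
    """
    _check_mn(m, n, cn)
    return 1.0 + n * (cn - 2) / (2.0 * m)


def alpha_not_inherited(m: float, n: float, cn: int, f: float) -> float:
    """Coverage-effect coefficient when the CNV is purely maternal.

    Only the maternal fraction ``1 - f`` carries the CNV:
    ``alpha = 1 + (1 - f) n (cn - 2) / (2 m)``; reduces to the inherited
    form at ``f = 0``.
    """
    _check_mn(m, n, cn)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fetal fraction must be in [0, 1], got {f}")
    return 1.0 + (1.0 - f) * n * (cn - 2) / (2.0 * m)


def adjust_coverage(coverage: float, alpha: float) -> float:
    """Remove the maternal-CNV effect: ``adjusted = coverage / alpha``."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return coverage / alpha


def select_alpha(cnv_calls: list[CnvCall], chrom: str, m: float,
                 f: float | None, min_size_mb: float = MIN_CNV_SIZE_MB) -> AlphaResult:
    """Aggregate a chromosome's CNV calls into one alpha.

    Per CNV: duplications use the non-inherited form (excess attenuated by
    ``1 - f``) and deletions the inherited form — the conservative pairing
    in each direction.  Multiple CNVs combine additively in the excess
    term.  With no qualifying CNV, alpha = 1.  A missing fetal fraction
    with a duplication present falls back to the inherited form with a
    warning.
    """
    result = AlphaResult(chrom=chrom, alpha=1.0, m_mb=m, f=f)
    excess = 0.0
    for call in cnv_calls:
        if call.chrom != chrom or call.size_mb < min_size_mb or call.cn == 2:
            continue
        if call.cn > 2:
            if f is None:
                log.warning("%s: fetal fraction unavailable for duplication; "
                            "falling back to the inherited-form alpha", chrom)
                k, fn = 1.0, 1
            else:
                k, fn = 1.0 - f, 2
        else:
            k, fn = 1.0, 1
        excess += k * call.size_mb * (call.cn - 2) / (2.0 * m)
        result.cnvs.append(call)
        result.function_used.append(fn)
    result.alpha = 1.0 + excess
    return result


# ---------------------------------------------------------------------------
# CNV calling


def _refine_bins(rel: np.ndarray, rows: np.ndarray, lo: int, hi: int,
                 margin: int = 2) -> tuple[int, int, float] | None:
    """Refine a candidate CNV to base-bin resolution.

    ``rows`` are the chromosome's valid bin rows, ``lo..hi`` (inclusive,
    positions within ``rows``) the candidate range from the window segment.
    The plateau is the median relative excess inside the candidate; bins
    are kept while their excess exceeds half the plateau, growing into the
    margin.  Returns (lo, hi, plateau) or None if the signal vanishes.
    """
    plateau = float(np.median(rel[rows[lo:hi + 1]]))
    if plateau == 0:
        return None
    half = plateau / 2.0
    sign = np.sign(plateau)

    def above(i: int) -> bool:
        return sign * rel[rows[i]] > sign * half

    while lo > 0 and above(lo - 1) and hi - lo < len(rows):
        lo -= 1
    while hi < len(rows) - 1 and above(hi + 1):
        hi += 1
    while lo <= hi and not above(lo):
        lo += 1
    while hi >= lo and not above(hi):
        hi -= 1
    if hi < lo:
        return None
    plateau = float(np.median(rel[rows[lo:hi + 1]]))
    return lo, hi, plateau


def _estimate_cn(plateau: float) -> int:
    """Integer copy number from the relative count excess.

    ``cn = 2 (1 + plateau)`` rounded half away from 2 (conservative toward
    calling a CNV).  The plateau of a non-inherited CNV is attenuated by
    ``1 - f``, which never moves the rounded estimate at screening-range
    fetal fractions.
    """
    raw = 2.0 * (1.0 + plateau)
    if raw > 2:
        return int(np.floor(raw + 0.5))
    return max(int(np.ceil(raw - 0.5)), 0)


def call_maternal_cnvs(counts: BinCounts, panel: ReferencePanel,
                       genome: GenomeModel, sd_coefficient: float = 4.0,
                       min_size_mb: float = MIN_CNV_SIZE_MB,
                       chroms: list[str] | None = None,
                       perm_alpha: float = 0.01,
                       rng: np.random.Generator | None = None) -> list[CnvCall]:
    """Detect maternal CNVs from corrected bin counts.

    Pipeline: overlap-window Z-scores -> CBS-style segmentation (undo
    coefficient ``sd_coefficient``) -> segments whose mean |Z| exceeds
    ``sd_coefficient`` times the chromosome's robust window-noise SD become
    candidates -> boundaries refined on the base bin grid -> calls with
    span > ``min_size_mb`` and estimated cn != 2 are emitted.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    grid = overlap_grid(genome)
    z, _ = window_stats(grid, counts, panel, genome)

    from .preprocess import normalized_counts
    norm = normalized_counts(counts, genome)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(panel.bin_mean > 0, norm / panel.bin_mean - 1.0, 0.0)

    calls: list[CnvCall] = []
    target = chroms if chroms is not None else genome.autosomes
    for chrom in target:
        wrows = np.flatnonzero((grid["chrom"] == chrom).to_numpy())
        if wrows.size == 0:
            continue
        zc = z[wrows]
        finite = zc[np.isfinite(zc)]
        if finite.size < 4:
            continue
        noise_sd = float(np.median(np.abs(np.diff(finite))) / 0.9539) or 1.0
        segs = segment_windows(grid.iloc[wrows].reset_index(drop=True), zc,
                               sd_coefficient=sd_coefficient, alpha=perm_alpha,
                               rng=rng)
        rows = genome.valid_rows(chrom)
        starts = genome.bins["start"].to_numpy()
        intervals: list[tuple[int, int]] = []
        for seg in segs:
            if abs(seg.mean_z) <= sd_coefficient * noise_sd:
                continue
            # map window span to candidate base bins (each window covers the
            # right half of its left bin and the left half of its right bin)
            left_bin = int(grid["left"].iloc[wrows[seg.first_win]])
            right_bin = int(grid["right"].iloc[wrows[seg.last_win]])
            lo = int(np.searchsorted(rows, left_bin))
            hi = int(np.searchsorted(rows, right_bin))
            refined = _refine_bins(rel, rows, lo, hi)
            if refined is not None:
                intervals.append(refined[:2])
        # adjacent window segments can refine to overlapping bin ranges;
        # merge them so no CNV is counted twice in the alpha aggregation
        for lo, hi in _merge_intervals(intervals):
            plateau = float(np.median(rel[rows[lo:hi + 1]]))
            cn = _estimate_cn(plateau)
            if cn == 2:
                continue
            size_mb = (hi - lo + 1) * genome.bin_size / 1e6
            if size_mb <= min_size_mb:
                continue
            zvals = z[wrows]
            inside = ((grid["left"].iloc[wrows].to_numpy() >= rows[lo])
                      & (grid["right"].iloc[wrows].to_numpy() <= rows[hi]))
            mean_z = float(np.nanmean(zvals[inside])) if inside.any() else float("nan")
            calls.append(CnvCall(chrom, int(starts[rows[lo]]),
                                 int(starts[rows[hi]] + genome.bin_size),
                                 size_mb, cn, mean_z))
    return calls


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of inclusive index intervals, merging overlap or adjacency."""
    merged: list[list[int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]
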