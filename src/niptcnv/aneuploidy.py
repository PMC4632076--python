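"""Chromosome Z-scores against the euploid panel and trisomy calls.

The aneuploidy statistic is the standardized deviation of a sample's
chromosome coverage proportion from the euploid panel; after division by
the maternal-CNV coefficient alpha the adjusted Z reflects the fetal state
alone.  A trisomy is called when the adjusted Z exceeds +3; a Z below -3
raises a monosomy flag (reported, not auto-called, since the screening
scope is T13/T18/T21).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .panel import ReferencePanel

__all__ = ["AneuploidyCall", "zscore_chromosome", "call_aneuploidy"]

Z_THRESHOLD = 3.0


@dataclass
class AneuploidyCall:
    chrom: str
    raw_z: float
    adjusted_z: float
    call: str           # euploid | trisomy | monosomy-flag | no-call
    threshold: float = Z_THRESHOLD


def zscore_chromosome(proportion: float, panel: ReferencePanel, chrom: str,
                      alpha: float = 1.0) -> tuple[float, float]:
    """Raw and alpha-adjusted chromosome Z-scores.

    ``raw = (p - mean) / sd``; ``adjusted = (p / alpha - mean) / sd`` with
    the panel's coverage-proportion statistics.
    """
    mean, sd = panel.chrom_mean(chrom), panel.chrom_sd(chrom)
    if sd <= 0:
        raise ValueError(f"{chrom}: panel SD must be positive")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return (proportion - mean) / sd, (proportion / alpha - mean) / sd


def call_aneuploidy(adjusted_z: float, threshold: float = Z_THRESHOLD,
                    chrom: str = "", raw_z: float | None = None) -> AneuploidyCall:
    """Trisomy iff adjusted Z > +threshold; Z < -threshold flags a possible
    monosomy; NaN yields a no-call."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if math.isnan(adjusted_z):
        call = "no-call"
    elif adjusted_z > threshold:
        call = "trisomy"
    elif adjusted_z < -threshold:
        call = "monosomy-flag"
    else:
        call = "euploid"
    return AneuploidyCall(chrom, adjusted_z if raw_z is None else raw_z,
                          adjusted_z, call, threshold)
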