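"""Fetal-concentration-difference (FCD) false-positive filter.

For a male fetus two independent fetal-fraction estimates exist: from the
under-representation of chromosome X,

    f_X = 2 (1 - xbar),

with ``xbar`` the average reads per chrX bin normalized to the global
average, and from the over-representation of the trisomy-called
chromosome,

    f_aneu = 2 (rbar - 1).

In a true non-mosaic trisomy the two agree (they fall on y = x and their
difference is normally distributed across positives); a discrepancy marks
a call whose extra coverage did not come from a trisomic feto-placental
compartment.  The statistic

    Z_fetal = (f_X - f_aneu) / sd

with ``sd`` the cohort SD of the difference among positive samples flags a
potential false positive at |Z_fetal| >= 3.  Under a mosaicism model the
ratio f_aneu / f_X estimates the trisomic cell fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "FetalFractions",
    "fetal_fraction_from_x",
    "fetal_fraction_from_trisomy",
    "estimate_fcd_sd",
    "z_fetal",
    "mosaic_ratio",
]

Z_FETAL_THRESHOLD = 3.0


@dataclass
class FetalFractions:
    f_x: float | None
    f_aneu: float | None
    sd_used: float | None
    z_fetal: float | None
    flagged: bool | None
    mosaic_ratio_pct: float | None
    note: str = ""


def fetal_fraction_from_x(xbar: float) -> float:
    """Fetal fraction from chrX under-representation (male fetus).

    A male fetus contributes one X where the mother contributes two, so
    ``xbar = 1 - f/2`` and ``f = 2 (1 - xbar)``, clipped to [0, 1].
    """
    if xbar <= 0:
        raise ValueError(f"xbar must be positive, got {xbar}")
    if xbar > 1.02:
        raise ValueError(f"chrX not under-represented (xbar={xbar:.3f}); "
                         "female fetus or uninformative sample")
    return float(np.clip(2.0 * (1.0 - xbar), 0.0, 1.0))


def fetal_fraction_from_trisomy(rbar: float) -> float:
    """Fetal fraction from the aneuploid chromosome's over-representation.

    A trisomic fetus contributes three copies where the mother has two, so
    ``rbar = 1 + f/2`` and ``f = 2 (rbar - 1)``, clipped to [0, 1].
    """
    if rbar < 0:
        raise ValueError(f"rbar must be non-negative, got {rbar}")
    if rbar < 0.98:
        import logging
        logging.getLogger(__name__).warning(
            "aneuploid chromosome not over-represented (rbar=%.3f) despite a "
            "positive call", rbar)
    return float(np.clip(2.0 * (rbar - 1.0), 0.0, 1.0))


def estimate_fcd_sd(positive_pairs) -> float:
    """Sample SD of ``f_X - f_aneu`` over concordant positive samples.

    Needs at least 5 pairs; a degenerate cohort (sd = 0) disables scoring.
    """
    pairs = np.asarray(list(positive_pairs), float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected (f_x, f_aneu) pairs")
    if len(pairs) < 5:
        raise ValueError(f"need >= 5 positive pairs to estimate sd, got {len(pairs)}; "
                         "configure a cohort sd instead")
    sd = float(np.std(pairs[:, 0] - pairs[:, 1], ddof=1))
    if sd == 0:
        raise ValueError("degenerate cohort: sd of fraction differences is 0")
    return sd


def z_fetal(f_x: float, f_aneu: float, sd: float,
            threshold: float = Z_FETAL_THRESHOLD) -> tuple[float, bool]:
    """``Z_fetal = (f_X - f_aneu) / sd``; flagged iff |Z_fetal| >= threshold."""
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    z = (f_x - f_aneu) / sd
    return z, abs(z) >= threshold


def mosaic_ratio(f_aneu: float, f_x: float) -> float:
    """Inferred trisomic cell fraction ``f_aneu / f_X`` in percent.

    Reported to one decimal, rounding half up; 100% means full trisomy and
    the euploid cell fraction is the complement to 100%.
    """
    if f_x <= 0:
        raise ValueError("f_X must be positive to compute a mosaic ratio")
    pct = Decimal(100 * f_aneu / f_x).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(pct)
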