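"""Poisson simulator for maternal-plasma bin counts.

Maternal plasma cell-free DNA is a two-compartment mixture: a maternal
fraction ``1 - f`` and a feto-placental fraction ``f``.  Each valid bin
``i`` receives a Poisson count with mean

    lambda_i = base_i * dosage_i,
    dosage_i = f * cn_f_i / 2 + (1 - f) * cn_m_i / 2,

where ``base_i`` is the expected euploid count (proportional to
mappability times a smooth GC-bias multiplier, normalized so the bases sum
to ``total_reads``), ``cn_m`` is the maternal copy number (2 outside
declared CNVs) and ``cn_f`` the fetal copy number (2, plus trisomy, one X
for a male fetus, and the maternal CNV copy number where the CNV is
inherited).

A maternal duplication therefore inflates the affected chromosome's
expected read count by the factor

    1 + k * n * (cn - 2) / (2 m),   k = 1 - f if not inherited, else 1,

with CNV size ``n`` and valid chromosome length ``m`` in Mb — exactly the
coverage-effect coefficient the caller estimates, which makes paired
simulations (with / without the CNV) the natural validation of that
coefficient (:func:`paired_cnv_effect`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import BinCounts, GenomeModel

__all__ = [
    "MaternalCnv",
    "SimulationParams",
    "gc_bias_multiplier",
    "place_cnv",
    "simulate_sample",
    "simulate_reference_panel",
    "grid_conditions",
    "paired_cnv_effect",
]


def gc_bias_multiplier(gc, amplitude: float = 0.2, peak: float = 0.42,
                       half_width: float = 0.25) -> np.ndarray:
    """Smooth unimodal GC-bias multiplier (quadratic, peak at ``peak``).

    Equals ``1 + amplitude`` at the peak and ``1 - amplitude`` at a GC
    deviation of ``half_width``; clipped below at 0.2 so extreme bins keep
    positive means.
    """
    dev = (np.asarray(gc, float) - peak) / half_width
    return np.clip(1.0 + amplitude * (1.0 - 2.0 * dev**2), 0.2, None)


@dataclass(frozen=True)
class MaternalCnv:
    """A constitutional maternal CNV: ``cn`` copies over ``size_mb`` Mb."""

    chrom: str
    start: int          # bp, 0-based
    size_mb: float
    cn: int
    inherited: bool = False

    def __post_init__(self):
        if self.size_mb <= 0:
            raise ValueError("CNV size must be positive")
        if self.cn < 0 or int(self.cn) != self.cn or self.cn == 2:
            raise ValueError(f"CNV copy number must be a non-negative integer != 2, got {self.cn}")


@dataclass(frozen=True)
class SimulationParams:
    """One simulated pregnancy.

    ``fetal_fraction`` is the feto-placental share ``f`` of plasma DNA;
    ``total_reads`` defaults to 6 million unique reads, inside the 5-10
    million range typical for shallow-WGS NIPT.
    """

    fetal_fraction: float = 0.10
    fetus_sex: str = "female"
    trisomy_chrom: str | None = None
    maternal_cnvs: tuple[MaternalCnv, ...] = ()
    total_reads: int = 6_000_000
    seed: int = 0
    gc_bias_amplitude: float = 0.2
    chrom_dispersion: float = 0.0035
    allow_cnv_on_trisomy: bool = False
    sample_id: str = "sim"

    def __post_init__(self):
        if not 0.0 <= self.fetal_fraction <= 1.0:
            raise ValueError(f"fetal_fraction must be in [0, 1], got {self.fetal_fraction}")
        if self.fetus_sex not in ("male", "female"):
            raise ValueError(f"fetus_sex must be 'male' or 'female', got {self.fetus_sex!r}")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        object.__setattr__(self, "maternal_cnvs", tuple(self.maternal_cnvs))


def place_cnv(genome: GenomeModel, chrom: str, size_mb: float, cn: int,
              inherited: bool = False, start_mb: float | None = None) -> MaternalCnv:
    """Place a CNV of ``size_mb`` on a contiguous run of valid bins.

    By default the CNV starts a few bins into the longest contiguous valid
    run of the chromosome, away from gap edges.
    """
    n_bins = max(1, int(round(size_mb * 1e6 / genome.bin_size)))
    rows = genome.valid_rows(chrom)
    starts = genome.bins["start"].to_numpy()[rows]
    if start_mb is not None:
        start = int(start_mb * 1e6)
    else:
        # longest contiguous run of valid bins
        breaks = np.flatnonzero(np.diff(rows) > 1)
        run_edges = np.concatenate([[0], breaks + 1, [len(rows)]])
        lens = np.diff(run_edges)
        k = int(np.argmax(lens))
        if lens[k] < n_bins + 4:
            raise ValueError(f"{chrom}: no valid run long enough for a {size_mb} Mb CNV")
        start = int(starts[run_edges[k] + 2])
    return MaternalCnv(chrom, start, size_mb, cn, inherited)


def _cnv_rows(genome: GenomeModel, cnv: MaternalCnv) -> np.ndarray:
    rows = genome.valid_rows(cnv.chrom)
    starts = genome.bins["start"].to_numpy()[rows]
    n_bins = max(1, int(round(cnv.size_mb * 1e6 / genome.bin_size)))
    sel = rows[(starts >= cnv.start)][:n_bins]
    if len(sel) < n_bins:
        raise ValueError(f"CNV on {cnv.chrom} at {cnv.start} extends past valid bins")
    return sel


def _validate(genome: GenomeModel, params: SimulationParams) -> None:
    names = set(genome.chrom_names)
    if params.trisomy_chrom is not None and params.trisomy_chrom not in names:
        raise ValueError(f"unknown trisomy chromosome {params.trisomy_chrom!r}")
    for cnv in params.maternal_cnvs:
        if cnv.chrom not in names:
            raise ValueError(f"CNV on unknown chromosome {cnv.chrom!r}")
        if cnv.chrom == params.trisomy_chrom and not params.allow_cnv_on_trisomy:
            raise ValueError(
                f"maternal CNV on trisomy chromosome {cnv.chrom}; "
                "set allow_cnv_on_trisomy=True to combine them")


def expected_counts(genome: GenomeModel, params: SimulationParams) -> np.ndarray:
    """Per-bin Poisson means ``lambda_i`` (zero on invalid bins)."""
    _validate(genome, params)
    valid = genome.valid
    gc = genome.bins["gc"].to_numpy()
    mapp = genome.bins["mappability"].to_numpy()
    weight = np.where(valid, mapp * gc_bias_multiplier(gc, params.gc_bias_amplitude), 0.0)
    base = params.total_reads * weight / weight.sum()

    f = params.fetal_fraction
    cn_m = np.full(genome.n_bins, 2.0)
    cn_f = np.full(genome.n_bins, 2.0)
    if params.trisomy_chrom is not None:
        cn_f[genome.chrom_rows(params.trisomy_chrom)] = 3.0
    if params.fetus_sex == "male" and genome.x_chrom is not None:
        cn_f[genome.chrom_rows(genome.x_chrom)] = 1.0
    for cnv in params.maternal_cnvs:
        rows = _cnv_rows(genome, cnv)
        cn_m[rows] += cnv.cn - 2
        if cnv.inherited:
            cn_f[rows] += cnv.cn - 2
    dosage = f * cn_f / 2.0 + (1.0 - f) * cn_m / 2.0
    return base * dosage


def simulate_sample(genome: GenomeModel, params: SimulationParams,
                    rng: np.random.Generator | None = None) -> BinCounts:
    """Draw one plasma sample: independent Poisson counts per valid bin.

    On top of Poisson sampling, each chromosome's mean is scaled by a
    lognormal factor with sigma ``chrom_dispersion`` (default 0.35%),
    modelling the residual inter-sample chromosomal coverage variation
    (library preparation, mapping, uncorrected GC structure) that
    shallow-WGS plasma panels show after correction; pure Poisson counts
    would make reference panels unrealistically tight.
    """
    lam = expected_counts(genome, params)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.chrom_dispersion > 0:
        for chrom in genome.chrom_names:
            lam[genome.chrom_rows(chrom)] *= rng.lognormal(0.0, params.chrom_dispersion)
    raw = rng.poisson(lam)
    # Poisson totals can exceed the nominal read budget; the container takes
    # total_reads as the budget, so carry the realized total alongside.
    return BinCounts(params.sample_id, raw, total_reads=int(max(params.total_reads, raw.sum())),
                     meta={"params": params, "nominal_reads": params.total_reads})


def simulate_reference_panel(genome: GenomeModel, n_samples: int = 100,
                             total_reads: int = 6_000_000, seed: int = 0,
                             gc_bias_amplitude: float = 0.2,
                             chrom_dispersion: float = 0.0035) -> list[BinCounts]:
    """Euploid, CNV-free, female-pregnancy profiles (dosage 1 everywhere).

    Per-sample RNG streams are spawned deterministically from the master
    seed, so panels are reproducible and samples independent.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 panel samples (SD undefined below that)")
    base = SimulationParams(fetal_fraction=0.0, fetus_sex="female",
                            total_reads=total_reads,
                            gc_bias_amplitude=gc_bias_amplitude,
                            chrom_dispersion=chrom_dispersion)
    streams = np.random.SeedSequence(seed).spawn(n_samples)
    out = []
    for i, ss in enumerate(streams):
        p = replace(base, sample_id=f"panel{i:03d}", seed=seed)
        out.append(simulate_sample(genome, p, rng=np.random.default_rng(ss)))
    return out


# ---------------------------------------------------------------------------
# the standard simulation grid: 3 chromosomes x dup/del, sizes 0.5-5 Mb in
# 0.25 Mb steps, fetal fractions 5/10/15%

GRID_SIZES_MB = tuple(np.arange(0.5, 5.0 + 1e-9, 0.25).round(2))
GRID_FRACTIONS = (0.05, 0.10, 0.15)
GRID_KINDS = {"dup": 3, "del": 1}


def grid_conditions(chroms=("chr13", "chr18", "chr21"), kinds=("dup", "del"),
                    sizes_mb=GRID_SIZES_MB, fractions=GRID_FRACTIONS):
    """Yield ``(chrom, kind, cn, size_mb, f)`` over the simulation grid."""
    for chrom in chroms:
        for kind in kinds:
            for size in sizes_mb:
                for f in fractions:
                    yield chrom, kind, GRID_KINDS[kind], float(size), float(f)


def paired_cnv_effect(genome: GenomeModel, chrom: str, size_mb: float, cn: int,
                      f: float, n_rep: int, seed: int = 0,
                      total_reads: int = 6_000_000, inherited: bool = False,
                      gc_bias_amplitude: float = 0.0) -> tuple[float, np.ndarray]:
    """Truth coefficient and paired empirical coverage ratios.

    Simulates ``n_rep`` pairs of samples with and without a maternal CNV
    (euploid fetus, fetal fraction ``f``) and returns ``(alpha_truth,
    ratios)`` where each ratio is the affected chromosome's summed read
    count with the CNV divided by the paired CNV-free count.

    GC bias defaults to zero here: this experiment isolates the
    CNV-dosage -> coverage relation that the coefficient models (which
    assumes uniform read density over the valid length), while GC bias and
    its correction are exercised in the full calling pipeline.  With bias
    on, a CNV landing on a low-density stretch has a proportionally
    smaller coverage effect than the uniform-density coefficient predicts.
    """
    from .matcnv import alpha_inherited, alpha_not_inherited

    cnv = place_cnv(genome, chrom, size_mb, cn, inherited=inherited)
    m = genome.valid_length_mb(chrom)
    alpha = (alpha_inherited(m, size_mb, cn) if inherited
             else alpha_not_inherited(m, size_mb, cn, f))
    with_p = SimulationParams(fetal_fraction=f, maternal_cnvs=(cnv,),
                              total_reads=total_reads,
                              gc_bias_amplitude=gc_bias_amplitude)
    without_p = SimulationParams(fetal_fraction=f, total_reads=total_reads,
                                 gc_bias_amplitude=gc_bias_amplitude)
    rows = genome.valid_rows(chrom)
    ratios = np.empty(n_rep)
    streams = np.random.SeedSequence(seed).spawn(n_rep)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        s_with = simulate_sample(genome, with_p, rng=rng)
        s_without = simulate_sample(genome, without_p, rng=rng)
        ratios[i] = s_with.raw[rows].sum() / s_without.raw[rows].sum()
    return float(alpha), ratios
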