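"""End-to-end calling pipeline and the JSON call report.

Stage order: (count) -> GC correction -> mappability correction ->
chromosome coverage and window Z-scores -> segmentation -> maternal-CNV
calls -> fetal fraction -> alpha -> adjusted Z -> aneuploidy call -> FCD
on positives.  ``general_mode`` disables the maternal-CNV correction and
the FCD filter, reproducing a plain read-count NIPT for comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .aneuploidy import call_aneuploidy, zscore_chromosome
from .fcd import (FetalFractions, fetal_fraction_from_trisomy,
                  fetal_fraction_from_x, mosaic_ratio, z_fetal)
from .genome import BinCounts, GenomeModel
from .matcnv import call_maternal_cnvs, select_alpha
from .panel import ReferencePanel
from .preprocess import (chromosome_coverage, correct_gc, correct_mappability,
                         normalized_counts)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "CallReport", "run_pipeline"]

#: xbar below this is taken as chrX under-representation, i.e. a male fetus
MALE_XBAR_MAX = 0.99


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and policies for one pipeline run."""

    z_threshold: float = 3.0
    z_fetal_threshold: float = 3.0
    min_cnv_size_mb: float = 0.3
    sd_coefficient: float = 4.0
    fcd_sd: float | None = None
    general_mode: bool = False
    target_chroms: tuple[str, ...] = ("chr13", "chr18", "chr21")
    fetus_sex: str = "auto"      # auto | male | female
    #: externally supplied fetal fraction (e.g. chrY-derived or from an
    #: orthogonal assay); overrides the chrX estimate when set
    fetal_fraction: float | None = None
    gc_frac: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("z_threshold", "z_fetal_threshold", "min_cnv_size_mb",
                     "sd_coefficient"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fetus_sex not in ("auto", "male", "female"):
            raise ValueError(f"bad fetus_sex {self.fetus_sex!r}")
        if self.fetal_fraction is not None and not 0 <= self.fetal_fraction <= 1:
            raise ValueError("fetal_fraction must be in [0, 1]")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CallReport:
    sample_id: str
    chromosomes: dict = field(default_factory=dict)
    fcd: dict = field(default_factory=dict)
    fetal_fraction_x: float | None = None
    fetus_sex: str = "unknown"
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "CallReport":
        return cls(**json.loads(Path(path).read_text()))


def _mean_ratio(norm: np.ndarray, panel: ReferencePanel, rows: np.ndarray) -> float:
    """Sample/panel ratio of mean per-bin normalized counts over ``rows``."""
    return float(norm[rows].mean() / panel.bin_mean[rows].mean())


def _representation(norm, panel, genome, chrom, baseline_rows) -> float:
    """Double ratio: (sample/panel on ``chrom``) over (sample/panel on the
    baseline), cancelling residual bin effects and total-count scale."""
    return (_mean_ratio(norm, panel, genome.valid_rows(chrom))
            / _mean_ratio(norm, panel, baseline_rows))


def run_pipeline(sample: BinCounts, panel: ReferencePanel, genome: GenomeModel,
                 config: RunConfig = RunConfig()) -> CallReport:
    """Run the full calling workflow on one sample.

    Deterministic for a fixed ``(sample, panel, config)``; the report embeds
    the package version, seed and a config hash.
    """
    panel.check_grid(genome)
    log.info("[preprocess] %s: GC + mappability correction", sample.sample_id)
    corrected = correct_mappability(correct_gc(sample, genome, frac=config.gc_frac),
                                    genome)
    coverage = chromosome_coverage(corrected, genome).set_index("chrom")
    norm = normalized_counts(corrected, genome)

    # maternal CNVs on all autosomes (skipped entirely in general mode)
    cnv_calls = []
    if not config.general_mode:
        cnv_calls = call_maternal_cnvs(
            corrected, panel, genome, sd_coefficient=config.sd_coefficient,
            min_size_mb=config.min_cnv_size_mb,
            rng=np.random.default_rng(config.seed))
        log.info("[matcnv] %d maternal CNV call(s)", len(cnv_calls))

    # raw Z per target chromosome (pre-alpha), used both for calling in
    # general mode and for excluding aberrant chromosomes from the
    # fetal-fraction baseline
    raw_z = {c: zscore_chromosome(float(coverage.loc[c, "proportion"]), panel, c)[0]
             for c in config.target_chroms}

    # fetal-fraction baseline: autosomal valid bins, minus over-represented
    # chromosomes (trisomy or dup candidates) and minus detected CNV regions
    flagged = {c for c, z in raw_z.items() if z > config.z_threshold}
    cnv_bins: set[int] = set()
    for call in cnv_calls:
        rows = genome.valid_rows(call.chrom)
        starts = genome.bins["start"].to_numpy()[rows]
        cnv_bins.update(rows[(starts >= call.start) & (starts < call.end)].tolist())
    baseline = [r for c in genome.autosomes if c not in flagged
                for r in genome.valid_rows(c) if r not in cnv_bins]
    if not baseline:
        baseline = [r for c in genome.autosomes for r in genome.valid_rows(c)]
    baseline_rows = np.asarray(baseline, dtype=int)

    f_x = None
    sex = config.fetus_sex
    if genome.x_chrom is not None and sex != "female":
        xbar = _representation(norm, panel, genome, genome.x_chrom, baseline_rows)
        if sex == "auto":
            sex = "male" if xbar < MALE_XBAR_MAX else "female"
        if sex == "male":
            try:
                f_x = fetal_fraction_from_x(xbar)
            except ValueError as err:
                log.warning("fetal fraction from chrX unavailable: %s", err)
                sex = "female"
    if config.fetal_fraction is not None:
        f_x = config.fetal_fraction
        if sex == "auto":
            sex = "male"
    log.info("[fetal-fraction] sex=%s f_X=%s", sex, f_x)

    report = CallReport(
        sample_id=sample.sample_id, fetal_fraction_x=f_x, fetus_sex=sex,
        provenance={"version": __version__, "seed": config.seed,
                    "config": config.hash(), "panel_n": panel.n_samples})

    # per-autosome alpha; a CNV on any autosome also contaminates the
    # coverage denominator, so adjusted proportions renormalize by the
    # alpha-corrected autosomal total
    alpha_results = {}
    for chrom in genome.autosomes:
        if config.general_mode:
            continue
        alpha_results[chrom] = select_alpha(
            [c for c in cnv_calls if c.chrom == chrom], chrom,
            float(coverage.loc[chrom, "m_mb"]), f_x, config.min_cnv_size_mb)
    adj_total = sum(float(coverage.loc[c, "proportion"])
                    / (alpha_results[c].alpha if c in alpha_results else 1.0)
                    for c in genome.autosomes)

    positives = []
    for chrom in config.target_chroms:
        prop = float(coverage.loc[chrom, "proportion"])
        alpha_res = alpha_results.get(chrom)
        alpha = alpha_res.alpha if alpha_res is not None else 1.0
        rz, _ = zscore_chromosome(prop, panel, chrom)
        adj_prop = (prop / alpha) / adj_total
        _, az = zscore_chromosome(adj_prop, panel, chrom)
        call = call_aneuploidy(az, config.z_threshold, chrom, raw_z=rz)
        log.info("[call] %s raw_z=%.2f alpha=%.4f adjusted_z=%.2f -> %s",
                 chrom, rz, alpha, az, call.call)
        report.chromosomes[chrom] = {
            "raw_z": rz, "adjusted_z": az, "alpha": alpha, "call": call.call,
            "cnv_calls": [{"start": c.start, "end": c.end, "size_mb": c.size_mb,
                           "cn": c.cn, "mean_z": c.mean_z}
                          for c in (alpha_res.cnvs if alpha_res else [])],
        }
        if call.call == "trisomy":
            positives.append(chrom)

    if positives and not config.general_mode:
        report.fcd = _fcd_block(positives, norm, panel, genome, f_x, sex,
                                cnv_bins, config)
    elif positives:
        report.fcd = {"note": "FCD disabled in general mode"}
    return report


def _fcd_block(positives, norm, panel, genome, f_x, sex, cnv_bins, config) -> dict:
    if sex != "male" or f_x is None:
        return {"note": "FCD not applicable: requires a male fetus with a "
                        "chrX fetal-fraction estimate"}
    if config.fcd_sd is None:
        return {"note": "FCD skipped: no cohort sd configured (--fcd-sd)"}
    block = {}
    for chrom in positives:
        baseline = [r for c in genome.autosomes if c not in positives
                    for r in genome.valid_rows(c) if r not in cnv_bins]
        rbar = _representation(norm, panel, genome, chrom, np.asarray(baseline))
        f_aneu = fetal_fraction_from_trisomy(rbar)
        zf, flag = z_fetal(f_x, f_aneu, config.fcd_sd, config.z_fetal_threshold)
        entry = FetalFractions(
            f_x=round(f_x, 3), f_aneu=round(f_aneu, 3), sd_used=config.fcd_sd,
            z_fetal=zf, flagged=flag,
            mosaic_ratio_pct=mosaic_ratio(f_aneu, f_x) if f_x > 0 else None,
            note=("potential false positive - recommend karyotyping" if flag else ""))
        block[chrom] = dataclasses.asdict(entry)
    return block
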