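# Methods

`niptcnv` implements a read-depth workflow for noninvasive prenatal
aneuploidy screening (T13/T18/T21) from maternal-plasma shallow
whole-genome sequencing, with two refinements over the plain Z-score
test: removal of the coverage effect of constitutional **maternal CNVs**
(the coefficient α) and a **fetal-concentration-difference** (FCD) filter
that flags positive calls whose coverage excess is not feto-placental.
This note records the model, the parameters that matter, the numerical
choices, and what the synthetic-data experiments do and do not show.

## The counting model

Plasma cell-free DNA is a two-compartment mixture: a maternal fraction
`1 − f` and a feto-placental fraction `f` (the *fetal fraction*).  Unique
reads are counted into fixed 100-kb bins; bin `i` of a simulated sample is
Poisson with mean

```
λ_i = base_i · [ f · cn_f,i / 2 + (1 − f) · cn_m,i / 2 ]
```

where `base_i` is the expected euploid count (proportional to mappability
times a smooth GC-bias multiplier, normalized to the read budget),
`cn_m` the maternal copy number (2 outside declared CNVs) and `cn_f` the
fetal copy number (2, plus one on a trisomic chromosome, one X for a male
fetus, and the maternal copy number inside an inherited CNV).  On top of
Poisson sampling, every chromosome's mean is scaled per sample by a
lognormal factor with σ = `chrom_dispersion` (default 0.35%); see
"Generator realism" below.

Defaults: 6×10⁶ reads per sample (shallow-WGS screening scale), GC-bias
amplitude ±20% peaking at GC 0.42, bin size 100 kb.  The built-in genome
model is synthetic: chr13/18/21-like autosomes of 100/75/40 Mb and a
chrX-like chromosome of 60 Mb, each with a 5% contiguous gap block
(centromere proxy), a smooth GC track in [0.30, 0.60] and mappability
near 0.95.  The *valid chromosome length* `m` is the chromosome length
minus the gap — the length unique reads can actually cover.

## Preprocessing

1. **Counting** — primary, non-duplicate alignments with MAPQ ≥ 30, keyed
   by leftmost base, 0-based half-open bins; gap-bin reads are discarded.
2. **GC correction** — LOWESS of bin count on GC (span 0.3, one
   robustness iteration); corrected count = raw × median / fit(GC).  The
   curve is fitted on counts pre-scaled to each chromosome's median so a
   chromosome-wide dosage shift (a trisomy, a large CNV) cannot bend the
   fit and regress away part of its own signal.  Non-positive fitted
   values fall back to the nearest positive fit.
3. **Mappability correction** — division by per-bin mappability.
4. **Normalization** — per-sample division by the total corrected count
   (bin level); *chromosome coverage* is the chromosome's share of the
   corrected counts over **autosomal** valid bins.  The autosomal
   denominator keeps the statistic independent of fetal sex: a male
   fetus's chrX under-representation would otherwise inflate every
   autosomal proportion against a female reference panel.
5. **Reference panel** — per-bin mean/SD of normalized counts and
   per-chromosome mean/SD of coverage proportions over ≥ 10 simulated (or
   supplied) euploid pregnancies; SDs floored at 10⁻⁶ (proportions) and
   10⁻¹² (bins).  Panel-based standardization was chosen over within-run
   statistics; the panel default in tests is 100 samples.

## Maternal CNV detection

Bin counts are re-expressed on 100-kb windows stepped every 50 kb (the
staggered window between adjacent bins takes half of each), standardized
against the panel, and segmented with a native circular-binary-
segmentation-style algorithm: recursive splitting at the maximal mean
difference standardized by the robust noise SD (median absolute first
difference — the pooled SD is avoided because a strong CNV inflates it
enough to mask its own breakpoint), a permutation stopping rule
(199 permutations, p ≤ 0.01, with a shortcut for |t| ≥ 10), and an
"undo" pass merging adjacent segments whose means differ by less than
`sd_coefficient` × noise SD.  `sd_coefficient` defaults to **4** rather
than the customary 3: a miscalled maternal CNV moves the aneuploidy
Z-score the wrong way, so calls must be conservative.

Candidate segments (|mean Z| > `sd_coefficient` × noise SD) are refined to
base-bin resolution — contiguous bins whose relative excess stays above
half the segment's median excess — because the 50%-overlap footprint
quantizes CNV size by ±0.1 Mb, which would leak into α.  Copy number is
`round(2·(1 + r̂))` with `r̂` the median relative excess, rounding half
away from 2; estimates of exactly 2 are dropped, as are calls below
0.3 Mb (the minimum size that triggers coverage calibration).

## The coverage coefficient α

α is defined as chromosome coverage with the maternal CNV divided by
coverage without it.  For CNV size `n` (Mb), copy number `cn`, valid
length `m` (Mb) and fetal fraction `f`:

```
inherited by the fetus:   α = 1 + n (cn − 2) / (2 m)          (full effect)
not inherited:            α = 1 + (1 − f) n (cn − 2) / (2 m)  (maternal share only)
```

> **Reconstruction caveat.** The source describing this method shows the
> two formulas only as figure placeholders.  The closed forms above are
> reconstructed from the surrounding prose — the defining ratio, the
> limits (α = 1 at cn = 2 or n = 0; > 1 for duplications, < 1 for
> deletions), the (1 − f) attenuation for non-inherited CNVs and the sign
> of their difference — and they reproduce the simulator's coverage
> ratios exactly and the printed per-sample α values under plausible `m`.
> They should not be read as a verbatim transcription.

Selection rule (chosen to avoid false negatives in both directions):
**duplications** use the non-inherited form — the smaller downward
correction — and **deletions** the inherited form — the smaller upward
correction.  Multiple CNVs on one chromosome combine additively in the
excess term, yielding a single α per chromosome.  With no qualifying CNV,
α = 1.  If no fetal-fraction estimate exists (female fetus), duplications
fall back to the inherited form with a warning.

The deletion rule deliberately over-adjusts upward by `f·n/(2m)` in
relative coverage.  Against a clinical-CV panel this residual is
sub-sigma; against a very tight panel it becomes visible (see "Generator
realism").

**Adjusted Z.**  Raw Z is `(p − μ)/σ` with panel proportion statistics.
For the adjusted Z the pipeline divides every autosome's coverage by its
α and renormalizes: `p'_c = (C_c/α_c) / Σ_a (C_a/α_a)`.  Dividing only
the numerator (the literal `p/α`) would leave the CNV's contribution in
the proportion denominator and bias the adjusted Z of the CNV chromosome
by −excess × weight — several sigma for multi-Mb CNVs.  A trisomy is
called at adjusted Z > 3; Z < −3 raises a monosomy review flag, never an
automatic call.

## Fetal fractions and the FCD filter

For a male fetus (auto-detected when the chrX representation ratio falls
below 0.99):

```
f_X    = 2 (1 − x̄)    chrX under-representation (fetus has one X)
f_aneu = 2 (r̄ − 1)    called chromosome's excess (fetus has three copies)
```

Representation ratios are double ratios against the panel's per-bin
means — (sample/panel on the chromosome) over (sample/panel on the
baseline) — which cancels residual bin effects.  The baseline is the
autosomal valid bins minus chromosomes whose raw Z exceeds the call
threshold and minus detected CNV bins; including the trisomic chromosome
would bias `f_X` upward by roughly `f` times that chromosome's autosomal
weight and destroy the y = x concordance of the two estimates.

For a positive call, `Z_fetal = (f_X − f_aneu) / sd`, with `sd` the
cohort standard deviation of the difference among concordant positives
(estimated from ≥ 5 pairs via `estimate_fcd_sd`, or supplied with
`--fcd-sd`).  |Z_fetal| ≥ 3 marks a *potential false positive —
recommend karyotyping*; the pipeline reports the flag and never deletes
the positive call.  Under a mosaicism model, `f_aneu / f_X` (percent, one
decimal, half-up) estimates the trisomic cell fraction, and the euploid
fraction is its complement to 100%.

## Generator realism: what the simulations do and do not show

The simulator reproduces the statistical structure the method needs —
Poisson counting noise, GC/mappability bias with real work for the
correction stages, compartment dosage, maternal CNVs, trisomy, fetal sex
— plus one deliberate addition: **per-chromosome lognormal dispersion**
(default σ = 0.35%).  Purely Poisson panels would have chromosome CVs
near 0.1%, an order tighter than clinical shallow-WGS panels (the
documented duplication sizes that first push Z past 3 — about 1.5 Mb on
chr21 — imply clinical chromosome CVs around 0.6%).  Under a 0.1% CV the
deletion rule's intentional `f·n/(2m)` residual would read as up to 9σ
and every denominator interaction would flag; at 0.35% the worst-case
residual stays below 3σ while trisomy detection at f = 5% retains a mean
Z near 6.

Consequences worth knowing:

- At f = 5% the per-replicate miss probability is of order 0.1–0.8%, so
  sensitivity is asserted as ≥ 97% per condition (≥ 99% pooled), not as a
  literal 100%.
- With only three autosomes, the trisomic chromosome absorbs 27–46% of
  its own excess through the coverage denominator and pushes the other
  autosomes' Z negative (sometimes past −3, raising spurious monosomy
  review flags).  Both effects shrink to ~2% on a real 22-autosome
  genome.
- The absolute false-positive CNV size thresholds depend on the panel
  CV and are therefore checked only as an ordering across chromosome
  lengths (shortest chromosome → smallest threshold), not as values.
- The generator does not model fragment-length or read-level effects,
  sequencing error, mosaicism dosage, or batch structure; passing tests
  say nothing about those failure modes on real data.

The α-validation experiment (`paired_cnv_effect`) runs with GC bias off:
the coefficient models a uniform-density chromosome, and a CNV pinned to
a low-density GC stretch would show a proportionally smaller empirical
effect — a property of the placement site, not of the coefficient.  GC
bias and its correction are exercised by the full-pipeline grid instead.

## Numerical and policy details

| parameter | default | meaning |
|---|---|---|
| bin size | 100 kb | counting unit; CNV windows overlap 50% |
| reads/sample | 6×10⁶ | shallow-WGS screening depth |
| `z_threshold` | 3 | trisomy call / monosomy flag boundary |
| `sd_coefficient` | 4 | segmentation undo + CNV candidate gate |
| `min_cnv_size_mb` | 0.3 | smallest CNV that triggers calibration |
| `z_fetal_threshold` | 3 | FCD false-positive flag |
| GC LOWESS span | 0.3 | one robustness iteration |
| panel size | 100 | simulated euploid pregnancies |
| `chrom_dispersion` | 0.0035 | per-chromosome lognormal σ |
| MAPQ cutoff | 30 | "unique mapped" policy for SAM/BAM input |
| SD floors | 10⁻⁶ / 10⁻¹² | chromosome / bin panel SDs |
| male call | x̄ < 0.99 | chrX representation threshold |

Degenerate inputs: all-equal windows segment to a single segment; a
constant GC track reduces the correction to a rescale; zero-SD panel
bins are excluded with a warning; identical panel samples hit the SD
floor with a warning; an empty alignment yields all-zero counts with a
warning.  Determinism: one master seed, per-sample streams spawned via
`numpy.random.SeedSequence`; reports embed the package version, seed and
a config hash and are byte-identical across reruns.

## Known limitations

- The α formulas are a reconstruction (see caveat above).
- CNVs below ~100 kb are invisible at this bin size, and 0.3 Mb is the
  calibration floor.
- FCD requires a male fetus and a positive call; chrY-based estimation is
  not implemented (chrX is the primary route; a supplied estimate can be
  used instead).
- Sex-chromosome aneuploidies, microdeletion syndromes and fetal-only
  CNVs are out of scope.
- The clinical-cohort quantities (accuracy tables, specific patient
  Z-score revisions, the clinical FCD sd) require patient data and are
  not reproduced here.
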