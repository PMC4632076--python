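# niptcnv

Read-depth noninvasive prenatal testing (NIPT) for trisomies 13/18/21
that is robust to **maternal copy-number variants**, plus a
**fetal-concentration-difference** filter for false positives — with a
Poisson plasma simulator to validate both.

## The problem

NIPT screens maternal-plasma cell-free DNA, a mixture of maternal DNA
(fraction 1 − *f*) and feto-placental DNA (the fetal fraction *f*).
Unique reads are counted in 100-kb bins, GC- and mappability-corrected,
and each chromosome's coverage proportion is standardized against a
euploid reference panel; |Z| > 3 calls an aneuploidy.  A constitutional
duplication or deletion in the *mother's* genome shifts that coverage
independently of the fetus: a duplication of a few megabases on
chromosome 21 mimics a fetal trisomy (false positive), a deletion can
mask one (false negative).

`niptcnv` removes that effect.  Maternal CNVs are detected by
circular-binary-segmentation-style changepoint analysis of bin Z-scores
on 50%-overlapping windows, and the chromosome coverage is divided by the
coefficient

```
α = 1 + n (cn − 2) / (2 m)            CNV inherited by the fetus
α = 1 + (1 − f) n (cn − 2) / (2 m)    CNV not inherited
```

where *n* is the CNV size and *m* the valid chromosome length (both Mb)
and *cn* the maternal copy number.  Duplications use the non-inherited
form and deletions the inherited form — the conservative pairing against
false negatives.  (The closed forms are reconstructed from the method's
prose description; see `docs/methods.md`.)

For positive calls with a male fetus, two independent fetal-fraction
estimates — `f_X = 2(1 − x̄)` from chrX under-representation and
`f_aneu = 2(r̄ − 1)` from the called chromosome's excess — must agree in
a true trisomy.  `Z_fetal = (f_X − f_aneu)/sd ≥ 3` flags the call as a
potential false positive (maternal material, or mosaicism at a fraction
of `f_aneu/f_X`).

## A worked example

```bash
python examples/02_maternal_cnv_correction.py
```

simulates a euploid male pregnancy (f = 10%) carrying a 2 Mb maternal
duplication (cn = 3) on the chr21-like chromosome and scores it both
ways:

```
general NIPT (no correction):
  chr21 raw Z = 5.84, alpha = 1.0000, adjusted Z = 5.84 -> trisomy

corrected workflow:
  chr21 raw Z = 5.84, alpha = 1.0239, adjusted Z = 0.07 -> euploid
  detected maternal CNV: 2.0 Mb, cn = 3
```

The plain workflow mistakes the duplication for a trisomy; the corrected
workflow finds the CNV (right size and copy number), computes
α = 1 + 0.9·2/(2·38) ≈ 1.024 and brings the Z-score back to panel noise.
`examples/01_simulate_and_call.py` shows the basic simulate → panel →
call loop, and `examples/03_fcd_false_positive_filter.py` shows the FCD
filter separating a true T21 (Z_fetal = −1.21) from a duplication-driven
positive (Z_fetal = +3.74, flagged).

## Command line

```bash
niptcnv simulate --config sim.json --out data/ --seed 1
niptcnv panel --samples data/p00.tsv --samples data/p01.tsv ... \
              --genome data/genome.tsv --out panel/
niptcnv call --sample data/case.tsv --panel panel/ \
             --genome data/genome.tsv --out report.json \
             [--general-mode] [--fcd-sd 0.017] [--sd-coefficient 4]
```

Bin counts and genome models are plain TSV (0-based half-open); reports
are JSON with per-chromosome raw/adjusted Z, α, CNV calls, the call, and
an FCD block for positives.  `--general-mode` disables both refinements
for side-by-side comparison.

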