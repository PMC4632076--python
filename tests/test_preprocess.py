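import numpy as np
import pytest
from scipy import stats

import niptcnv as nc
from niptcnv.preprocess import normalized_counts

from conftest import SMALL_READS, small_params


# ---------------------------------------------------------------------------
# read counting from alignments

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chrA\tLN:1000000\n@SQ\tSN:chrB\tLN:1000000\n"


def _sam_line(name, chrom, pos, flag=0, mapq=60):
    return (f"{name}\t{flag}\t{chrom}\t{pos + 1}\t{mapq}\t35M\t*\t0\t0\t"
            f"{'A' * 35}\t{'I' * 35}\n")


@pytest.fixture()
def tiny_genome():
    import pandas as pd
    from niptcnv.genome import GenomeModel
    rows = []
    for chrom in ("chrA", "chrB"):
        for i in range(10):
            rows.append((chrom, i * 100_000, (i + 1) * 100_000, 0.42, 1.0,
                         not (chrom == "chrA" and i == 5)))  # one gap bin
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc",
                                       "mappability", "valid"])
    return GenomeModel(bins, bin_size=100_000, x_chrom=None)


def test_count_reads_matches_hand_tally(tiny_genome, tmp_path):
    """Ten uniquely mapped reads land in the bins a hand tally predicts;
    non-unique, low-quality, gap and unknown-contig reads are dropped."""
    reads = [
        _sam_line("r1", "chrA", 0),             # bin 0
        _sam_line("r2", "chrA", 99_999),        # still bin 0 (leftmost base)
        _sam_line("r3", "chrA", 100_000),       # exact boundary -> bin 1
        _sam_line("r4", "chrA", 250_000),       # bin 2
        _sam_line("r5", "chrA", 250_001),       # bin 2
        _sam_line("r6", "chrA", 930_000),       # bin 9
        _sam_line("r7", "chrB", 10),            # chrB bin 0
        _sam_line("r8", "chrB", 450_000),       # chrB bin 4
        _sam_line("r9", "chrB", 450_010),       # chrB bin 4
        _sam_line("r10", "chrB", 999_000),      # chrB bin 9
        _sam_line("bad_mapq", "chrA", 300_000, mapq=5),
        _sam_line("secondary", "chrA", 300_000, flag=256),
        _sam_line("duplicate", "chrA", 300_000, flag=1024),
        _sam_line("in_gap", "chrA", 550_000),   # gap bin, discarded
        _sam_line("offgrid", "chrZ", 100),      # unknown contig
    ]
    sam = tmp_path / "toy.sam"
    sam.write_text(SAM_HEADER.replace("chrZ", "chrB")
                   + "@SQ\tSN:chrZ\tLN:1000000\n" + "".join(reads))
    counts = nc.count_reads_in_bins(sam, tiny_genome)
    a = counts.raw[tiny_genome.chrom_rows("chrA")]
    b = counts.raw[tiny_genome.chrom_rows("chrB")]
    assert a.tolist() == [2, 1, 2, 0, 0, 0, 0, 0, 0, 1]
    assert b.tolist() == [1, 0, 0, 0, 2, 0, 0, 0, 0, 1]
    assert counts.meta["skipped_contigs"] == {"chrZ": 1}
    assert counts.meta["dropped_in_gaps"] == 1


def test_count_reads_empty_file_warns(tiny_genome, tmp_path, caplog):
    sam = tmp_path / "empty.sam"
    sam.write_text(SAM_HEADER)
    with caplog.at_level("WARNING", logger="niptcnv.preprocess"):
        counts = nc.count_reads_in_bins(sam, tiny_genome)
    assert counts.raw.sum() == 0
    assert any("no usable reads" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# GC and mappability correction

class TestGcCorrection:
    def test_flat_counts_left_nearly_unchanged(self, genome_small):
        rng = np.random.default_rng(0)
        raw = np.where(genome_small.valid,
                       rng.poisson(50_000, genome_small.n_bins), 0)
        counts = nc.BinCounts("flat", raw, total_reads=int(raw.sum()))
        out = nc.correct_gc(counts, genome_small)
        rows = np.flatnonzero(genome_small.valid)
        ratio = out.corrected[rows] / raw[rows]
        # no GC dependence: the fit is ~flat, so each bin moves < 1%
        assert np.abs(ratio - np.median(ratio)).max() < 0.01

    def test_removes_injected_quadratic_bias(self, genome_small):
        """Regression slope of count on GC shrinks >= 90% after LOWESS."""
        s = nc.simulate_sample(genome_small, small_params(seed=31))
        out = nc.correct_gc(s, genome_small)
        rows = np.flatnonzero(genome_small.valid)
        gc = genome_small.bins["gc"].to_numpy()[rows]
        before = stats.linregress(gc, s.raw[rows]).slope
        after = stats.linregress(gc, out.corrected[rows]).slope
        assert abs(after) < 0.1 * abs(before)
        # total mass conserved within 10%
        assert 0.9 < out.corrected[rows].sum() / s.raw[rows].sum() < 1.1

    def test_constant_gc_track_gives_constant_rescale(self):
        g = nc.make_genome_fixture({"chrA": 30_000_000}, seed=0)
        g.bins["gc"] = 0.42
        rng = np.random.default_rng(1)
        raw = np.where(g.valid, rng.poisson(2000, g.n_bins), 0)
        out = nc.correct_gc(nc.BinCounts("c", raw, int(raw.sum())), g)
        rows = np.flatnonzero(g.valid)
        ratio = out.corrected[rows] / raw[rows]
        assert np.allclose(ratio, ratio[0])

    def test_requires_enough_bins(self):
        g = nc.make_genome_fixture({"chrA": 3_000_000}, seed=0)  # 30 bins
        raw = np.where(g.valid, 100, 0)
        with pytest.raises(ValueError, match="100 valid bins"):
            nc.correct_gc(nc.BinCounts("s", raw, int(raw.sum())), g)

    def test_idempotent_within_one_percent(self, genome_small):
        s = nc.simulate_sample(genome_small, small_params(seed=8))
        once = nc.correct_gc(s, genome_small)
        twice = nc.correct_gc(once, genome_small)
        rows = np.flatnonzero(genome_small.valid)
        rel = np.abs(twice.corrected[rows] - once.corrected[rows]) \
            / np.maximum(once.corrected[rows], 1)
        assert np.median(rel) < 0.01


class TestMappabilityCorrection:
    def test_unit_mappability_is_noop(self, genome_small):
        g = nc.make_genome_fixture({"chrA": 20_000_000}, seed=3)
        g.bins["mappability"] = 1.0
        raw = np.where(g.valid, 123, 0)
        out = nc.correct_mappability(nc.BinCounts("s", raw, int(raw.sum())), g)
        rows = np.flatnonzero(g.valid)
        assert np.allclose(out.corrected[rows], raw[rows])

    def test_divides_by_mappability(self):
        g = nc.make_genome_fixture({"chrA": 20_000_000}, seed=3)
        g.bins["mappability"] = 0.5
        raw = np.where(g.valid, 100, 0)
        out = nc.correct_mappability(nc.BinCounts("s", raw, int(raw.sum())), g)
        assert np.allclose(out.corrected[np.flatnonzero(g.valid)], 200.0)

    def test_coverage_insensitive_to_mappability_dip(self):
        """A dipped mappability track changes chromosome coverage < 0.5%
        after correction, compared with the undipped genome."""
        lengths = {"chrA": 30_000_000, "chrB": 30_000_000}
        plain = nc.make_genome_fixture(lengths, seed=4)
        plain.bins["mappability"] = 1.0
        dipped = nc.make_genome_fixture(lengths, seed=4)
        dipped.bins["mappability"] = 1.0
        rows_b = dipped.chrom_rows("chrB")[50:80]
        dipped.bins.loc[rows_b, "mappability"] = 0.6
        covs = {}
        for tag, g in [("plain", plain), ("dipped", dipped)]:
            s = nc.simulate_sample(g, nc.SimulationParams(
                total_reads=3_000_000, seed=77, chrom_dispersion=0.0))
            c = nc.correct_mappability(nc.correct_gc(s, g), g)
            covs[tag] = nc.chromosome_coverage(c, g).set_index("chrom")["proportion"]
        assert abs(covs["dipped"]["chrB"] / covs["plain"]["chrB"] - 1) < 0.005


# ---------------------------------------------------------------------------
# standardization and coverage

class TestBinZscores:
    def test_held_out_euploid_is_standard_normal(self, genome_small, panel_small):
        s = nc.simulate_sample(genome_small, small_params(seed=555))
        c = nc.correct_mappability(nc.correct_gc(s, genome_small), genome_small)
        z = nc.bin_zscores(c, panel_small, genome_small)
        z = z[np.isfinite(z)]
        assert abs(z.mean()) < 0.1
        assert 0.8 < z.std() < 1.2

    def test_heavy_tail_guard(self, genome_small, panel_small):
        """Held-out euploid samples rarely produce |bin Z| > 4."""
        fracs = []
        for seed in range(600, 605):
            s = nc.simulate_sample(genome_small, small_params(seed=seed))
            c = nc.correct_mappability(nc.correct_gc(s, genome_small), genome_small)
            z = nc.bin_zscores(c, panel_small, genome_small)
            z = z[np.isfinite(z)]
            fracs.append((np.abs(z) > 4).mean())
        assert max(fracs) < 0.01

    def test_bin_at_panel_mean_scores_zero(self, genome_small, panel_small):
        raw = np.zeros(genome_small.n_bins)
        rows = np.flatnonzero(genome_small.valid)
        raw[rows] = panel_small.bin_mean[rows] * 1e6
        c = nc.BinCounts("mean", np.zeros(genome_small.n_bins, int), 1,
                         corrected=raw)
        z = nc.bin_zscores(c, panel_small, genome_small)
        assert np.nanmax(np.abs(z)) < 1e-8

    def test_maternal_dup_region_shifts_by_half_over_cv(self, genome_small,
                                                        panel_small):
        """A cn=3 duplication lifts relative bin counts by ~50%, i.e. a
        mean bin Z of about 0.5 / CV."""
        cnv = nc.place_cnv(genome_small, "chr13", 2.0, 3)
        s = nc.simulate_sample(genome_small, small_params(
            fetal_fraction=0.0, maternal_cnvs=(cnv,), seed=91))
        c = nc.correct_mappability(nc.correct_gc(s, genome_small), genome_small)
        z = nc.bin_zscores(c, panel_small, genome_small)
        rows = genome_small.valid_rows("chr13")
        starts = genome_small.bins["start"].to_numpy()[rows]
        region = rows[(starts >= cnv.start) & (starts < cnv.start + 2_000_000)]
        cv = panel_small.bin_sd[region] / panel_small.bin_mean[region]
        predicted = float(np.mean(0.5 / cv))
        observed = float(np.nanmean(z[region]))
        assert observed > 0
        assert 0.8 < observed / predicted < 1.2


class TestChromosomeCoverage:
    def test_autosomal_proportions_sum_to_one(self, genome_small):
        s = nc.simulate_sample(genome_small, small_params(seed=1))
        cov = nc.chromosome_coverage(s, genome_small).set_index("chrom")
        assert cov.loc[genome_small.autosomes, "proportion"].sum() \
            == pytest.approx(1.0, abs=1e-9)

    def test_equal_counts_give_bin_count_proportions(self, genome_small):
        raw = np.where(genome_small.valid, 7, 0)
        cov = nc.chromosome_coverage(
            nc.BinCounts("u", raw, int(raw.sum())), genome_small).set_index("chrom")
        n_auto = sum(len(genome_small.valid_rows(c))
                     for c in genome_small.autosomes)
        for chrom in genome_small.autosomes:
            expect = len(genome_small.valid_rows(chrom)) / n_auto
            assert cov.loc[chrom, "proportion"] == pytest.approx(expect)

    def test_single_chromosome_counts(self, genome_small):
        raw = np.zeros(genome_small.n_bins, dtype=int)
        raw[genome_small.valid_rows("chr18")] = 10
        cov = nc.chromosome_coverage(
            nc.BinCounts("s", raw, int(raw.sum())), genome_small).set_index("chrom")
        assert cov.loc["chr18", "proportion"] == pytest.approx(1.0)
        assert cov.loc["chr13", "proportion"] == 0.0

    def test_trisomy_lifts_proportion_by_expected_factor(self, genome_small,
                                                         panel_small):
        """Simulated T18 at f=0.10: the proportion rises by (1 + f/2) in the
        numerator, attenuated by the trisomy's weight in the denominator."""
        ratios = []
        for seed in range(100):
            s = nc.simulate_sample(genome_small, small_params(
                fetal_fraction=0.10, trisomy_chrom="chr18", seed=7000 + seed))
            cov = nc.chromosome_coverage(s, genome_small).set_index("chrom")
            ratios.append(cov.loc["chr18", "proportion"]
                          / panel_small.chrom_mean("chr18"))
        n_auto = {c: len(genome_small.valid_rows(c))
                  for c in genome_small.autosomes}
        w = n_auto["chr18"] / sum(n_auto.values())
        expected = 1.05 / (1 + 0.05 * w)
        assert np.mean(ratios) == pytest.approx(expected, abs=0.004)

    def test_normalized_counts_sum_to_one(self, genome_small):
        s = nc.simulate_sample(genome_small, small_params(seed=12))
        norm = normalized_counts(s, genome_small)
        assert norm.sum() == pytest.approx(1.0, abs=1e-12)
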