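"""Binned coverage statistics against base-resolution and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from xdamp.coverage import (
    BinnedTrack,
    bin_track,
    enrichment_over_control,
    mean_enrichment_per_chromosome,
    percent_occupancy,
    percent_reads_per_chromosome,
    read_bedgraph,
    track_correlation,
    tss_counts,
    tss_profile,
    write_bedgraph,
)
from xdamp.synthetic import DomainSpec, build_genome, simulate_coverage

SIZES = {"chrX": 1000, "chr7": 800}


def _intervals(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def _track(values, chrom="chrX", length=None, width=100, label="t"):
    values = {chrom: np.asarray(values, float)}
    length = length or len(values[chrom]) * width
    return BinnedTrack(width, {chrom: length}, values, label)


def _per_base_oracle(intervals, length, bin_width):
    base = np.zeros(length)
    for r in intervals.itertuples():
        base[r.start : r.end] += r.value
    n = -(-length // bin_width)
    return np.array([base[i * bin_width : (i + 1) * bin_width].mean() for i in range(n)])


class TestBinning:
    def test_uniform_value_fills_every_bin(self):
        trk = bin_track(_intervals([("chrX", 0, 1000, 2.5)]), {"chrX": 1000}, 100)
        assert np.allclose(trk.values["chrX"], 2.5)

    def test_partial_interval_is_length_weighted(self):
        trk = bin_track(_intervals([("chrX", 0, 5000, 2.0)]), {"chrX": 10_000}, 10_000)
        assert trk.values["chrX"][0] == pytest.approx(1.0)

    def test_random_intervals_match_per_base_oracle(self):
        rng = np.random.default_rng(10)
        rows = []
        cursor = 0
        while cursor < 900:
            length = int(rng.integers(20, 180))
            rows.append(("chrX", cursor, min(cursor + length, 1000), float(rng.uniform(0, 5))))
            cursor += length + int(rng.integers(0, 60))
        df = _intervals(rows)
        trk = bin_track(df, {"chrX": 1000}, 100)
        assert np.allclose(trk.values["chrX"], _per_base_oracle(df, 1000, 100), atol=1e-9)

    def test_short_last_bin_normalized_by_its_own_length(self):
        trk = bin_track(_intervals([("chrX", 0, 250, 4.0)]), {"chrX": 250}, 100)
        assert np.allclose(trk.values["chrX"], [4.0, 4.0, 4.0])


class TestBedgraphIO:
    def test_round_trip_at_bin_resolution(self, tmp_path):
        rng = np.random.default_rng(11)
        trk = BinnedTrack(
            100, dict(SIZES),
            {"chrX": rng.uniform(0, 3, 10).round(3), "chr7": rng.uniform(0, 3, 8).round(3)},
        )
        p = tmp_path / "t.bedgraph"
        write_bedgraph(trk, p)
        back = read_bedgraph(p, dict(SIZES), 100)
        for c in SIZES:
            assert np.allclose(back.values[c], trk.values[c], atol=1e-9)

    def test_unsorted_file_is_an_error(self, tmp_path):
        p = tmp_path / "u.bedgraph"
        p.write_text("chrX\t500\t600\t1\nchrX\t0\t100\t2\n")
        with pytest.raises(ValueError, match="sorted"):
            read_bedgraph(p, SIZES, 100)

    def test_overlapping_intervals_are_an_error(self, tmp_path):
        p = tmp_path / "o.bedgraph"
        p.write_text("chrX\t0\t200\t1\nchrX\t100\t300\t2\n")
        with pytest.raises(ValueError, match="overlap"):
            read_bedgraph(p, SIZES, 100)

    def test_chromosome_absent_from_file_gets_zero_bins(self, tmp_path):
        p = tmp_path / "z.bedgraph"
        p.write_text("chrX\t0\t100\t1\n")
        back = read_bedgraph(p, SIZES, 100)
        assert np.allclose(back.values["chr7"], 0.0)


class TestEnrichment:
    def test_mean_per_chromosome(self):
        trk = BinnedTrack(100, dict(SIZES), {"chrX": np.full(10, 1.0), "chr7": np.full(8, 3.0)})
        assert mean_enrichment_per_chromosome(trk) == {"chrX": 1.0, "chr7": 3.0}

    def test_target_equal_control_gives_unit_fold(self):
        t = _track([1, 2, 3])
        fc = enrichment_over_control(t, t)
        assert np.allclose(fc.values["chrX"], 1.0)
        log = enrichment_over_control(t, t, log2=True)
        assert np.allclose(log.values["chrX"], 0.0)

    def test_pseudocount_bounds_division_by_zero(self):
        fc = enrichment_over_control(_track([1.0]), _track([0.0]), pseudocount=0.01)
        assert fc.values["chrX"][0] == pytest.approx(101.0)

    def test_log2_consistent_with_linear(self):
        a, b = _track([1, 2, 4.0]), _track([2, 2, 2.0])
        lin = enrichment_over_control(a, b)
        log = enrichment_over_control(a, b, log2=True)
        assert np.allclose(2.0 ** log.values["chrX"], lin.values["chrX"])

    def test_grid_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="grid"):
            enrichment_over_control(_track([1, 2]), _track([1, 2], width=50))


class TestOccupancy:
    def test_inclusive_threshold_on_equal_bins(self):
        fc = _track([2.0, 1.0, 1.3, 0.5], width=100)
        assert percent_occupancy(fc, 1.2)["chrX"] == pytest.approx(50.0)
        assert percent_occupancy(fc, 10)["chrX"] == 0.0
        assert percent_occupancy(fc, 1.3)["chrX"] == pytest.approx(50.0)  # >= not >

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(12)
        fc = _track(rng.uniform(0, 5, 50), width=100)
        occ = [percent_occupancy(fc, t)["chrX"] for t in np.linspace(0.2, 5, 25)]
        assert all(a >= b for a, b in zip(occ, occ[1:]))
        assert all(0 <= o <= 100 for o in occ)

    def test_planted_domains_recovered_within_bin_tolerance(self):
        genome = build_genome(10, 10, 2e6, 2e6, 1, seed=13, gene_length=5000)
        spec = DomainSpec(n_domains=6, length_mean=1e5, chromosome="chrX")
        target, control, truth = simulate_coverage(genome, spec, seed=13)
        width = 10_000
        fc = enrichment_over_control(
            bin_track(target, genome.chromosomes, width),
            bin_track(control, genome.chromosomes, width),
        )
        got = percent_occupancy(fc, 1.2)["chrX"]
        expected = 100.0 * truth["union_length"] / genome.chromosomes["chrX"]
        tol = 100.0 * width * len(truth["intervals"]) / genome.chromosomes["chrX"]
        assert abs(got - expected) <= tol


class TestTss:
    GENES = pd.DataFrame(
        [
            {"gene_id": "plus", "chrom": "chrX", "start": 400, "end": 600, "strand": "+"},
            {"gene_id": "minus", "chrom": "chrX", "start": 100, "end": 300, "strand": "-"},
        ]
    )

    def test_uniform_track_counts_proportional_to_window(self):
        trk = _track(np.full(10, 2.0), width=100)
        counts = tss_counts(trk, self.GENES, flank=50)
        assert counts["plus"] == pytest.approx(2.0 * 101)
        assert counts["minus"] == pytest.approx(2.0 * 101)

    def test_minus_strand_tss_is_the_three_prime_coordinate(self):
        values = np.zeros(10)
        values[2] = 5.0  # bases 200-299 cover the minus gene's TSS at 299
        trk = _track(values, width=100)
        counts = tss_counts(trk, self.GENES, flank=10)
        assert counts["minus"] > 0
        assert counts["plus"] == 0.0

    def test_window_clipped_at_chromosome_edge(self):
        trk = _track(np.full(10, 1.0), width=100)
        genes = pd.DataFrame(
            [{"gene_id": "edge", "chrom": "chrX", "start": 0, "end": 200, "strand": "+"}]
        )
        assert tss_counts(trk, genes, flank=500)["edge"] == pytest.approx(501.0)

    def test_uniform_track_profile_is_flat(self):
        trk = _track(np.full(10, 3.0), width=100)
        prof = tss_profile(trk, self.GENES, flank=200, step=50)
        assert np.allclose(prof["mean_signal"], 3.0)

    def test_minus_strand_upstream_signal_appears_left(self):
        values = np.zeros(10)
        values[3] = 7.0  # bases 300-399: downstream of the minus-gene TSS (299)
        trk = _track(values, width=100)
        genes = self.GENES[self.GENES["gene_id"] == "minus"]
        prof = tss_profile(trk, genes, flank=100, step=50).set_index("offset")
        assert prof.loc[-100, "mean_signal"] == 7.0  # upstream offsets read rightward coords
        assert prof.loc[100, "mean_signal"] == 0.0

    def test_symmetric_signal_gives_symmetric_profile(self):
        # signal symmetric about the TSS bin: bins at +/-100 bp carry 2, TSS bin 9
        values = np.zeros(11)
        values[4] = values[6] = 2.0
        values[5] = 9.0
        trk = _track(values, width=100)
        genes = pd.DataFrame(
            [{"gene_id": "mid", "chrom": "chrX", "start": 550, "end": 800, "strand": "+"}]
        )
        prof = tss_profile(trk, genes, flank=200, step=100)
        sig = prof["mean_signal"].to_numpy()
        assert np.allclose(sig, sig[::-1])
        assert sig[len(sig) // 2] == 9.0


class TestCorrelationAndReadShares:
    def test_self_and_anti_correlation(self):
        a = _track([1, 2, 3, 4, 5.0])
        b = _track([-1, -2, -3, -4, -5.0])
        assert track_correlation(a, a) == pytest.approx(1.0)
        assert track_correlation(a, b) == pytest.approx(-1.0)

    def test_hand_computed_five_bin_fixture(self):
        a = _track([1, 2, 3, 4, 5.0])
        b = _track([2, 1, 4, 3, 5.0])
        assert track_correlation(a, b, "pearson") == pytest.approx(0.8)
        assert track_correlation(a, b, "spearman") == pytest.approx(0.8)

    def test_percent_reads_per_chromosome(self):
        assert percent_reads_per_chromosome({"chrX": 10})["chrX"] == 100.0
        shares = percent_reads_per_chromosome({"chrX": 60, "chr7": 40})
        assert shares == {"chrX": 60.0, "chr7": 40.0}
        reads = ["chrX"] * 3 + ["chr7"] * 1
        got = percent_reads_per_chromosome(reads)
        assert got["chrX"] == pytest.approx(75.0)
        assert sum(got.values()) == pytest.approx(100.0)
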