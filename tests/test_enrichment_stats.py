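import numpy as np
import pytest
from scipy import stats

from quadchip import (
    BinTrack,
    ContingencyTable2x2,
    Genome,
    bh_fdr,
    bin_enrichment,
    fisher_exact_2x2,
    motif_count_enrichment,
    peak_presence_enrichment,
    sample_control_regions,
)
from quadchip.g4_scanner import PATTERNS
from quadchip.peak_analytics import ReadPlacement
from quadchip.sequence_model import GenomicInterval

from _oracles import oracle_fisher_two_sided
from conftest import make_peak


class TestFisher:
    def test_worked_hypergeometric_values(self):
        assert fisher_exact_2x2(ContingencyTable2x2(3, 1, 1, 3)) == pytest.approx(34 / 70)
        assert fisher_exact_2x2(ContingencyTable2x2(5, 0, 0, 5)) == pytest.approx(2 / 252)

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_balanced_table_is_the_mode(self, k):
        assert fisher_exact_2x2(ContingencyTable2x2(k, k, k, k)) == 1.0

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4)) == 1.0
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2x2(ContingencyTable2x2(0, 3, 0, 4)) == 1.0

    def test_matches_enumeration_oracle_small_tables(self):
        # exhaustive sweep over modest totals; the full <= 40 sweep runs in
        # the acceptance suite
        for n in range(1, 17):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
                        assert p == pytest.approx(
                            oracle_fisher_two_sided(a, b, c, d), rel=1e-6
                        )

    def test_odds_ratio_one_iff_rows_proportional(self):
        assert ContingencyTable2x2(3, 6, 5, 10).odds_ratio == 1.0
        assert ContingencyTable2x2(4, 6, 5, 10).odds_ratio != 1.0
        # continuity correction keeps zero-cell tables finite and nonzero
        assert 0 < ContingencyTable2x2(5, 0, 3, 4).odds_ratio < np.inf


class TestControlSampling:
    SIZES = {"chr1": 50_000, "chr2": 150_000}

    def test_exact_length_and_count(self):
        peaks = [make_peak("chr1", 100, 400), make_peak("chr2", 1000, 1500)]
        controls = sample_control_regions(peaks, self.SIZES, n_per_peak=100, seed=7)
        assert len(controls) == 200
        assert all(c.length == 300 for c in controls[:100])
        assert all(c.length == 500 for c in controls[100:])

    def test_deterministic_for_fixed_seed(self):
        peaks = [make_peak("chr1", 100, 400)]
        a = sample_control_regions(peaks, self.SIZES, n_per_peak=50, seed=3)
        b = sample_control_regions(peaks, self.SIZES, n_per_peak=50, seed=3)
        assert a == b
        c = sample_control_regions(peaks, self.SIZES, n_per_peak=50, seed=4)
        assert a != c

    def test_controls_avoid_exclusions(self):
        peaks = [make_peak("chr1", 0, 25_000)]
        controls = sample_control_regions(peaks, self.SIZES, n_per_peak=200, seed=1)
        for region in controls:
            assert not region.overlaps(peaks[0].interval)

    def test_nearly_chromosome_length_peak_pins_start(self):
        sizes = {"only": 1000}
        peaks = [make_peak("only", 0, 999)]
        controls = sample_control_regions(peaks, sizes, n_per_peak=30, seed=2,
                                          exclusions=[])
        assert {c.start for c in controls} <= {0, 1}

    def test_budget_exhaustion_names_peak(self):
        sizes = {"only": 1000}
        peaks = [make_peak("only", 0, 999, name="big_peak")]
        with pytest.raises(RuntimeError, match="big_peak"):
            sample_control_regions(peaks, sizes, n_per_peak=5, seed=0,
                                   budget_per_region=10)

    def test_chromosome_share_proportional_to_length(self):
        peaks = [make_peak("chr1", 0, 100)]
        controls = sample_control_regions(
            peaks, self.SIZES, n_per_peak=10_000, seed=11, exclusions=[]
        )
        observed = np.array(
            [sum(c.chrom == name for c in controls) for name in self.SIZES]
        )
        expected = len(controls) * np.array([0.25, 0.75])
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_high_n_regions_rejected(self):
        genome = Genome({"chr1": "N" * 5_000 + "A" * 5_000})
        peaks = [make_peak("chr1", 6_000, 6_100)]
        controls = sample_control_regions(
            peaks, genome.sizes, n_per_peak=100, seed=5, exclusions=[], genome=genome
        )
        for region in controls:
            frac_n = genome.fetch(region).count("N") / region.length
            assert frac_n <= 0.1


def _motif_genome():
    """A toy genome with all PG4 motifs confined to [0, 2000)."""
    rng = np.random.default_rng(42)
    motif = "GGGTTAGGGTTAGGGTTAGGG"
    background = "".join(
        np.array(list("ACT"))[rng.integers(0, 3, 10_000)]
    )
    seq = list(background)
    for start in (50, 300, 700, 1100, 1600):
        seq[start : start + len(motif)] = motif
    return Genome({"chr1": "".join(seq)})


class TestEnrichmentTests:
    def test_direction_and_table_symmetry(self):
        genome = _motif_genome()
        pattern = PATTERNS["G3L1-7"]
        rich = [make_peak("chr1", 0, 500, "rich")]          # 2 motifs
        poor = [GenomicInterval("chr1", 5000, 5500)]        # none
        report = motif_count_enrichment(rich, poor, genome, pattern)
        assert report.odds_ratio > 1
        inverted = motif_count_enrichment(
            [make_peak("chr1", 5000, 5500)], [rich[0].interval], genome, pattern
        )
        assert inverted.odds_ratio < 1

    def test_presence_swap_inverts_odds_ratio(self):
        genome = _motif_genome()
        pattern = PATTERNS["G3L1-7"]
        peaks = [make_peak("chr1", 0, 500), make_peak("chr1", 600, 1200),
                 make_peak("chr1", 4000, 4500)]
        controls = [GenomicInterval("chr1", 1400, 1900),
                    GenomicInterval("chr1", 6000, 6500),
                    GenomicInterval("chr1", 7000, 7500)]
        fwd = peak_presence_enrichment(peaks, controls, genome, pattern)
        rev = peak_presence_enrichment(
            [make_peak(c.chrom, c.start, c.end) for c in controls],
            [p.interval for p in peaks], genome, pattern,
        )
        assert fwd.odds_ratio == pytest.approx(1 / rev.odds_ratio)

    def test_all_regions_hit_gives_degenerate_p_one(self):
        genome = _motif_genome()
        pattern = PATTERNS["G3L1-7"]
        peaks = [make_peak("chr1", 40, 100), make_peak("chr1", 290, 340)]
        controls = [GenomicInterval("chr1", 690, 740), GenomicInterval("chr1", 1090, 1140)]
        with pytest.warns(UserWarning, match="degenerate"):
            report = peak_presence_enrichment(peaks, controls, genome, pattern)
        assert report.p_two_sided == 1.0

    def test_empty_peak_set_rejected(self):
        genome = _motif_genome()
        with pytest.raises(ValueError):
            motif_count_enrichment([], [], genome, PATTERNS["G3L1-7"])

    def test_report_records_metadata(self):
        genome = _motif_genome()
        peaks = [make_peak("chr1", 0, 500)]
        controls = sample_control_regions(peaks, genome.sizes, 10, seed=9, genome=genome)
        report = motif_count_enrichment(
            peaks, controls, genome, PATTERNS["G3L1-7"],
            n_controls_per_peak=10, seed=9,
        )
        payload = report.to_dict()
        assert payload["seed"] == 9 and payload["n_controls_per_peak"] == 10
        assert payload["pattern"] == "G3L1-7"


class TestBhFdr:
    def test_step_up_rule(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04], 0.05).all()
        assert not bh_fdr([0.5, 0.6], 0.05).any()
        assert bh_fdr([0.05], 0.05).all()  # boundary of the step-up rule

    def test_partial_rejection(self):
        flags = bh_fdr([0.001, 0.02, 0.9], 0.05)
        assert flags.tolist() == [True, True, False]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5], 0.05)


class TestBinEnrichment:
    SIZES = {"chr1": 50_000}  # 1000 bins of 50 bp

    @staticmethod
    def _uniform_reads(n, rng, chrom_len=50_000):
        return [ReadPlacement("chr1", int(p), 36)
                for p in rng.integers(0, chrom_len - 36, n)]

    def test_matched_chip_and_input_not_significant(self, rng):
        reads = self._uniform_reads(10_000, rng)
        track = BinTrack.from_reads(reads, reads, self.SIZES, bin_size=50)
        pvalues, fraction = bin_enrichment(track, fdr=0.05)
        assert fraction == 0.0
        assert pvalues.size == 1000

    def test_single_loaded_bin_detected(self, rng):
        chip = [ReadPlacement("chr1", 25_000, 36) for _ in range(500)]
        inp = self._uniform_reads(10_000, rng)
        track = BinTrack.from_reads(chip, inp, self.SIZES, bin_size=50)
        pvalues, fraction = bin_enrichment(track, fdr=0.05)
        assert fraction == pytest.approx(1 / 1000)
        assert np.argmin(pvalues) == (25_000 + 18) // 50

    def test_fraction_bounds(self, rng):
        chip = self._uniform_reads(2_000, rng)
        inp = self._uniform_reads(2_000, rng)
        _, fraction = bin_enrichment(BinTrack.from_reads(chip, inp, self.SIZES))
        assert 0.0 <= fraction <= 1.0

    def test_zero_totals_rejected(self):
        track = BinTrack.from_reads([], [], self.SIZES)
        with pytest.raises(ValueError):
            bin_enrichment(track)
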