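import numpy as np
import pandas as pd
import pytest

from canosa import synthetic
from canosa.genomic_io import (
    GeneModel,
    GenomeBuild,
    GenomicInterval,
    Segment,
    SiteReadcount,
)
from canosa.loh import (
    HetMarker,
    annotate_segments,
    call_somatic_loh,
    classify_loh,
    germline_loh_bins,
    LohSegment,
    segment_deviation,
    select_germline_hets,
    tumor_deviation_track,
)

from conftest import small_scenario


def site(chrom, pos, ref, depth, **counts):
    return SiteReadcount(chrom, pos, ref, depth, dict(counts))


class TestHetSelection:
    def test_balanced_site_selected(self):
        markers = select_germline_hets([site("1", 100, "A", 25, A=13, G=12)])
        assert len(markers) == 1
        assert markers[0].alt == "G"

    def test_depth_below_20_rejected(self):
        assert select_germline_hets([site("1", 100, "A", 19, A=10, G=9)]) == []

    def test_vaf_outside_window_rejected(self):
        markers = select_germline_hets([site("1", 100, "A", 100, A=61, G=39)])
        assert markers == []  # VAF 0.39 < 0.40

    def test_window_bounds_inclusive(self):
        markers = select_germline_hets([site("1", 100, "A", 100, A=60, G=40)])
        assert len(markers) == 1


class TestDeviationTrack:
    def _markers(self):
        return [HetMarker("1", p, "A", "G", 0.5, 30) for p in (100, 200, 300)]

    def test_deviation_values(self):
        tumor = [
            site("1", 100, "A", 10, A=1, G=9),
            site("1", 200, "A", 10, A=5, G=5),
            site("1", 300, "A", 10, A=10, G=0),
        ]
        track, dropped = tumor_deviation_track(self._markers(), tumor)
        assert dropped == 0
        assert list(track["deviation"]) == pytest.approx([0.4, 0.0, 0.5])

    def test_uncovered_markers_dropped_and_counted(self):
        tumor = [site("1", 100, "A", 10, A=5, G=5), site("1", 200, "A", 0)]
        track, dropped = tumor_deviation_track(self._markers(), tumor)
        assert dropped == 2
        assert len(track) == 1

    def test_no_overlap_raises(self):
        with pytest.raises(ValueError, match="no markers"):
            tumor_deviation_track(self._markers(), [site("2", 5, "A", 10, A=5, G=5)])


class TestSegmentDeviation:
    def _track(self, devs, chrom="1", spacing=2000):
        positions = np.arange(1, len(devs) + 1) * spacing
        return pd.DataFrame(
            {"chrom": chrom, "pos": positions, "deviation": devs, "vaf": 0.5}
        )

    def test_constant_zero_gives_single_zero_segment(self):
        track = self._track(np.zeros(500))
        segments = segment_deviation(track)
        assert len(segments) == 1
        assert segments[0].value == 0.0
        assert segments[0].n_markers == 500

    @staticmethod
    def _binomial_devs(rng, vaf, n, coverage=60):
        """Marker deviations as the method sees them: binomial VAF noise."""
        return np.abs(rng.binomial(coverage, vaf, size=n) / coverage - 0.5)

    def test_planted_block_recovered_with_tight_boundaries(self):
        rng = np.random.default_rng(7)
        spacing = 2000
        devs = np.concatenate(
            [
                self._binomial_devs(rng, 0.5, 200),
                self._binomial_devs(rng, 0.9, 150),
                self._binomial_devs(rng, 0.5, 200),
            ]
        )
        segments = segment_deviation(self._track(devs, spacing=spacing))
        assert len(segments) == 3
        # middle-segment boundaries within 2 marker spacings of truth
        mid = segments[1]
        assert abs(mid.interval.start - 200 * spacing) <= 2 * spacing
        assert abs(mid.interval.end - 350 * spacing) <= 2 * spacing

    def test_two_planted_blocks_give_five_segments(self):
        rng = np.random.default_rng(8)
        devs = np.concatenate(
            [
                self._binomial_devs(rng, 0.5, 200),
                self._binomial_devs(rng, 0.9, 120),
                self._binomial_devs(rng, 0.5, 200),
                self._binomial_devs(rng, 0.9, 120),
                self._binomial_devs(rng, 0.5, 200),
            ]
        )
        assert len(segment_deviation(self._track(devs))) == 5

    def test_chromosome_below_min_markers_skipped(self):
        track = self._track(np.zeros(5))
        with pytest.warns(UserWarning, match="skipped"):
            assert segment_deviation(track, min_markers=10) == []


class TestCallSomaticLoh:
    def _segment(self, value, chrom="1", start=0, end=1_000_000):
        return Segment(GenomicInterval(chrom, start, end), value, 100, "LOH")

    @pytest.mark.parametrize("value,called", [(0.12, True), (0.0, False), (0.1, True)])
    def test_threshold_is_inclusive(self, value, called):
        calls = call_somatic_loh([self._segment(value)])
        assert bool(calls) is called

    def test_blind_spot_masking_trims_calls(self):
        blind = [GenomicInterval("1", 400_000, 600_000)]
        calls = call_somatic_loh([self._segment(0.3)], blind_spots=blind)
        intervals = [(c.interval.start, c.interval.end) for c in calls]
        assert intervals == [(0, 400_000), (600_000, 1_000_000)]
        for call in calls:
            for spot in blind:
                assert not call.interval.overlaps(spot)


class TestGermlineBins:
    def _genome(self, length=1_600_000):
        return GenomeBuild(["1"], {"1": length})

    def test_bin_with_four_hets_flagged(self):
        positions = {"1": [1, 2, 3, 4] + list(range(500_001, 500_101))}
        flagged = germline_loh_bins(positions, self._genome())
        starts = [iv.start for iv in flagged]
        assert 0 in starts  # 4 hets < 5
        assert 500_000 not in starts  # 100 hets
        assert 1_000_000 in starts and 1_500_000 in starts  # zero hets

    def test_bin_with_five_hets_not_flagged(self):
        positions = {"1": [10, 20, 30, 40, 50]}
        flagged = germline_loh_bins(positions, self._genome(500_000))
        assert flagged == []

    def test_zero_hets_flags_every_bin(self):
        flagged = germline_loh_bins({}, self._genome(1_200_000))
        assert [iv.start for iv in flagged] == [0, 500_000, 1_000_000]
        assert flagged[-1].end == 1_200_000  # trailing partial bin included


class TestClassifyLoh:
    def _loh(self, chrom="1", start=0, end=100_000):
        return call_somatic_loh(
            [Segment(GenomicInterval(chrom, start, end), 0.3, 50, "LOH")]
        )

    def _cn(self, value, chrom="1", start=0, end=100_000):
        return Segment(GenomicInterval(chrom, start, end), value, 10, "CN")

    @pytest.mark.parametrize(
        "cn,expected",
        [(2.0, "CN-neutral-LOH"), (1.2, "deletion-LOH"), (3.1, "gain-LOH")],
    )
    def test_three_class_rule(self, cn, expected):
        classified = classify_loh(self._loh(), [self._cn(cn)])
        assert classified[0].loh_class == expected

    def test_length_weighted_mean_across_overlaps(self):
        cn_segments = [
            self._cn(1.0, end=50_000),
            self._cn(3.0, start=50_000, end=100_000),
        ]
        classified = classify_loh(self._loh(), cn_segments)
        assert classified[0].loh_class == "CN-neutral-LOH"  # mean 2.0

    def test_no_cn_coverage_warns_and_leaves_class_unset(self):
        with pytest.warns(UserWarning, match="no copy-number"):
            classified = classify_loh(self._loh(), [self._cn(2.0, chrom="9")])
        assert classified[0].loh_class is None


class TestAnnotateSegments:
    def _call(self):
        return LohSegment(
            Segment(GenomicInterval("1", 100_000, 200_000), 0.3, 50, "LOH")
        )

    def _gene(self, symbol, start, end):
        return GeneModel(symbol, GenomicInterval("1", start, end))

    def test_flank_inclusion_rules(self):
        genes = [
            self._gene("NEAR", 203_000, 204_000),  # 3 kb past the end
            self._gene("FAR", 215_000, 216_000),  # 15 kb past the end
            self._gene("SPAN", 50_000, 400_000),  # spans everything
        ]
        annotated = annotate_segments([self._call()], genes)
        assert annotated[0].genes == ["NEAR", "SPAN"]


class TestRecoveryProperties:
    def _run(self, scenario, ref_seed, noise_seed):
        genome, seqs = synthetic.simulate_reference(
            scenario.chrom_lengths, gc=scenario.gc, seed=ref_seed
        )
        truth = synthetic.plant_truth(genome, seqs, scenario, seed=ref_seed + 1)
        normal = synthetic.simulate_readcounts(truth, "normal", seed=noise_seed)
        tumor = synthetic.simulate_readcounts(truth, "primary", seed=noise_seed + 1)
        markers = select_germline_hets(normal)
        track, _ = tumor_deviation_track(markers, tumor)
        return truth, segment_deviation(track)

    def test_raising_threshold_never_increases_loh_length(self):
        truth, segments = self._run(small_scenario(), 51, 52)
        lengths = []
        for threshold in (0.05, 0.1, 0.2, 0.3):
            calls = call_somatic_loh(segments, threshold=threshold)
            lengths.append(sum(len(c.interval) for c in calls))
        assert lengths == sorted(lengths, reverse=True)

    def test_near_zero_purity_called_loh_length_vanishes(self):
        truth, segments = self._run(synthetic.Scenario(purity=0.02), 61, 62)
        called = sum(len(c.interval) for c in call_somatic_loh(segments))
        planted = sum(s.end - s.start for s in truth.loh_truth)
        genome_length = truth.genome.total_length
        assert called < 0.005 * genome_length
        assert called < 0.05 * planted
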