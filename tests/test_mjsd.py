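import math

import numpy as np
import pytest

from smmtax.mjsd import (
    CountProfile,
    MJSDSegmenter,
    Segment,
    SegmentationConfig,
    best_split,
    cluster_segments,
    count_contexts,
    divergence_profile,
    filter_clusters,
    markov_entropy,
    mjsd,
    segment_genome,
    split_significance,
    split_significance_mc,
)
from smmtax.synth import MosaicSpec, generate_mosaic_genome, make_source


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _entropy_oracle(profile):
    """Direct double-sum evaluation of H = -sum_w P(w) sum_x P(x|w) log2 P(x|w)."""
    counts = profile.counts
    total = counts.sum()
    h = 0.0
    for w in range(counts.shape[0]):
        row = counts[w].sum()
        if row == 0:
            continue
        pw = row / total
        for x in range(4):
            pxw = counts[w, x] / row
            if pxw > 0:
                h -= pw * pxw * math.log2(pxw)
    return h


class TestCountProfile:
    def test_hand_count_order1(self):
        profile = count_contexts("AAAA", m=1)
        assert profile.counts[0, 0] == 3
        assert profile.total == 3

    def test_additivity(self):
        p = count_contexts("ACGTACGT", m=0)
        doubled = p.add(p)
        assert (doubled.counts == 2 * p.counts).all()
        assert (doubled.subtract(p).counts == p.counts).all()

    def test_ambiguous_windows_skipped(self):
        assert count_contexts("AANAA", m=1).total == count_contexts("AA", m=1).total + 1

    def test_interval_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            count_contexts("ACGT", m=2, start=0, end=2)

    def test_order_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            count_contexts("ACGT", 0).add(count_contexts("ACGT", 1))


class TestEntropy:
    def test_zero_entropy_limit(self):
        assert markov_entropy(count_contexts("AAAAAA", m=0)) == 0.0

    def test_uniform_limit_two_bits(self):
        assert markov_entropy(count_contexts("ACGTACGTACGTACGT", m=0)) == pytest.approx(2.0)

    @pytest.mark.parametrize("m", [0, 1, 2])
    def test_matches_formula_oracle(self, rng, m):
        for n in (50, 500):
            profile = count_contexts(_random_seq(rng, n), m=m)
            assert markov_entropy(profile) == pytest.approx(_entropy_oracle(profile), abs=1e-12)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            markov_entropy(CountProfile(0, np.zeros((1, 4), dtype=np.int64)))

    def test_bounded_zero_two(self, rng):
        for _ in range(20):
            h = markov_entropy(count_contexts(_random_seq(rng, 100), m=1))
            assert 0.0 <= h <= 2.0


class TestMJSD:
    def test_identity_is_zero(self, rng):
        p = count_contexts(_random_seq(rng, 300), m=1)
        assert mjsd(p, p) == 0.0

    def test_homopolymer_halves_give_one_bit(self):
        left = count_contexts("A" * 100, m=0)
        right = count_contexts("C" * 100, m=0)
        assert mjsd(left, right) == pytest.approx(1.0)

    def test_symmetric_and_nonnegative_sweep(self, rng):
        for _ in range(50):
            a = count_contexts(_random_seq(rng, int(rng.integers(10, 200))), m=1)
            b = count_contexts(_random_seq(rng, int(rng.integers(10, 200))), m=1)
            assert mjsd(a, b) >= 0.0
            assert mjsd(a, b) == pytest.approx(mjsd(b, a), abs=1e-15)


class TestBestSplit:
    def test_planted_homopolymer_boundary(self):
        res = best_split("A" * 500 + "C" * 500, m=0, lo=0, hi=1000, min_segment_len=100)
        assert res.split == 500
        assert res.D == pytest.approx(1.0, abs=1e-9)
        assert res.p_value < 1e-100

    @pytest.mark.parametrize("m", [0, 1, 2])
    def test_incremental_equals_fresh_everywhere(self, rng, m):
        """The slider's adjusted entropies must match fresh recomputation."""
        seq = _random_seq(rng, 800)
        d, s0 = divergence_profile(seq, m, 0, 800, 50)
        fresh = np.array(
            [
                mjsd(count_contexts(seq, m, 0, s), count_contexts(seq, m, s, 800))
                for s in range(s0, s0 + d.size)
            ]
        )
        assert np.abs(d - fresh).max() < 1e-9

    def test_short_interval_no_split(self):
        res = best_split("ACGT" * 50, m=0, lo=0, hi=200, min_segment_len=150)
        assert res.split == -1
        assert res.D == 0.0
        assert res.p_value == 1.0


class TestSignificance:
    def test_zero_divergence_p_one(self):
        assert split_significance(0.0, 1000, 2, 50) == 1.0

    def test_monotone_decreasing_in_divergence(self):
        ps = [split_significance(d, 2000, 1, 100) for d in (0.001, 0.01, 0.05, 0.2)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert all(0 <= p <= 1 for p in ps)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            split_significance(0.1, 0, 1)

    @pytest.mark.parametrize("m", [0, 2])
    def test_type_one_error_near_nominal(self, m):
        """Analytic max-corrected p vs the permutation-null ground truth."""
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(200):
            seq = _random_seq(rng, 10_000)
            rejections += best_split(seq, m, 0, 10_000, 500).p_value < 0.05
        assert 0.01 <= rejections / 200 <= 0.15

    def test_monte_carlo_agrees_on_null_and_signal(self, rng):
        null = _random_seq(rng, 2000)
        res = best_split(null, 0, 0, 2000, 100)
        p_mc = split_significance_mc(null, 0, 0, 2000, 100, res.D, n_replicates=99, rng=rng)
        assert (res.p_value < 0.05) == (p_mc < 0.05) or p_mc > 0.01
        signal = "A" * 1000 + "C" * 1000
        res = best_split(signal, 0, 0, 2000, 100)
        p_mc = split_significance_mc(signal, 0, 0, 2000, 100, res.D, n_replicates=99, rng=rng)
        assert res.p_value < 0.01 and p_mc == pytest.approx(0.01, abs=1e-12)


class TestSegmentation:
    def test_alpha_zero_gives_single_segment(self, rng):
        seq = _random_seq(rng, 3000)
        segs = segment_genome(seq, SegmentationConfig(m=0, alpha_segment=0.0, min_segment_len=100))
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, 3000)

    def test_tiling_and_profile_conservation(self, rng):
        source_a = make_source(rng, divergence_knob=0.9, label="a")
        source_b = make_source(rng, divergence_knob=0.9, label="b")
        rec, _ = generate_mosaic_genome(
            MosaicSpec(blocks=[(source_a, 8000), (source_b, 8000), (source_a, 8000)]), rng
        )
        config = SegmentationConfig(m=2, min_segment_len=1000)
        segs = segment_genome(rec.residues, config)
        edges = [0] + [s.end for s in segs]
        assert edges[-1] == len(rec.residues)
        assert all(s.start == e for s, e in zip(segs, edges[:-1]))  # no gaps/overlaps
        whole = count_contexts(rec.residues, 2)
        summed = segs[0].profile
        for s in segs[1:]:
            summed = summed.add(s.profile)
        assert (summed.counts == whole.counts).all()

    def test_planted_boundary_recovered(self, rng):
        source_a = make_source(rng, divergence_knob=0.8, label="a")
        source_b = make_source(rng, divergence_knob=0.8, label="b")
        rec, _ = generate_mosaic_genome(
            MosaicSpec(blocks=[(source_a, 20_000), (source_b, 20_000)]), rng
        )
        segs = segment_genome(rec.residues, SegmentationConfig(m=2, min_segment_len=1000))
        assert len(segs) >= 2
        assert min(abs(s.start - 20_000) for s in segs) <= 300


class TestClustering:
    def test_single_segment_single_cluster(self, rng):
        seg = Segment(0, 500, count_contexts(_random_seq(rng, 500), 2))
        clusters = cluster_segments([seg])
        assert len(clusters) == 1
        assert clusters[0].total_length == 500

    def test_alternating_sources_give_two_clusters(self, rng):
        source_a = make_source(rng, divergence_knob=0.8, label="a")
        source_b = make_source(rng, divergence_knob=0.8, label="b")
        blocks = [(source_a if i % 2 == 0 else source_b, 10_000) for i in range(6)]
        rec, truth = generate_mosaic_genome(MosaicSpec(blocks=blocks), rng)
        segs = [Segment(s, e, count_contexts(rec.residues, 2, s, e)) for s, e, _ in truth]
        clusters = cluster_segments(segs, SegmentationConfig())
        assert len(clusters) == 2
        starts = sorted(tuple(sorted(s.start for s in c.members)) for c in clusters)
        assert starts == [(0, 20_000, 40_000), (10_000, 30_000, 50_000)]

    def test_tiny_threshold_merges_everything(self, rng):
        segs = [
            Segment(i * 100, (i + 1) * 100, count_contexts(_random_seq(rng, 100), 0))
            for i in range(4)
        ]
        clusters = cluster_segments(segs, SegmentationConfig(p_cluster=1e-300))
        assert len(clusters) == 1
        profile_sum = sum(s.profile.counts.sum() for s in segs)
        assert clusters[0].profile.counts.sum() == profile_sum


class TestClusterFilter:
    @pytest.mark.parametrize("length, kept", [(40, False), (50, True), (60, True)])
    def test_strict_size_threshold(self, rng, length, kept):
        # 5 Mb genome at 0.001% -> 50 bp threshold; "less than" is strict
        seg = Segment(0, length, count_contexts("A" * length, 0))
        cluster_list = filter_clusters([_cluster_of(seg)], 5_000_000, SegmentationConfig())
        assert (len(cluster_list) == 1) == kept

    def test_predicate_hook(self, rng):
        seg = Segment(0, 1000, count_contexts("A" * 1000, 0))
        clusters = [_cluster_of(seg)]
        assert filter_clusters(clusters, 1000) == clusters
        assert filter_clusters(clusters, 1000, predicate=lambda c: False) == []


def _cluster_of(seg):
    from smmtax.mjsd import Cluster

    return Cluster([seg], seg.profile)


class TestSegmenterEstimator:
    def test_fit_exposes_segments_clusters_labels(self, rng):
        source_a = make_source(rng, divergence_knob=0.9, label="a")
        source_b = make_source(rng, divergence_knob=0.9, label="b")
        rec, _ = generate_mosaic_genome(
            MosaicSpec(blocks=[(source_a, 6000), (source_b, 6000)]), rng
        )
        seg = MJSDSegmenter(min_segment_len=1000).fit(rec.residues)
        assert seg.labels_.shape == (len(seg.segments_),)
        assert len(seg.retained_clusters_) <= len(seg.clusters_)
        assert sum(s.length for s in seg.segments_) == 12_000

    def test_params_roundtrip(self):
        seg = MJSDSegmenter()
        params = seg.get_params()
        assert params["m"] == 2
        seg.set_params(min_segment_len=123)
        assert seg.get_params()["min_segment_len"] == 123
        with pytest.raises(ValueError):
            seg.set_params(bogus=1)
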