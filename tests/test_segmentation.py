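"""Random split points, weak-labeled segmentation and corpus assembly."""

import numpy as np
import pytest

from repcount import (
    ConfigurationError,
    DenseLabelTrack,
    MultichannelSeries,
    build_corpus,
    derive_end_markers,
    draw_split_points,
    segment,
    synthesize_series,
)
from repcount.series import minmax_normalize


def normalized_series(T, C=2, rate=10.0):
    x = np.linspace(0.0, 1.0, T)[:, None] * np.ones((1, C))
    return MultichannelSeries(samples=x, sample_rate_hz=rate, normalized=True)


class TestDrawSplitPoints:
    def test_single_point_in_range(self, rng):
        pts = draw_split_points(1, 100, 1, rng)
        assert pts.shape == (1,) and 0 < pts[0] <= 100

    def test_deterministic_under_seed(self):
        a = draw_split_points(5, 1000, 10, np.random.default_rng(42))
        b = draw_split_points(5, 1000, 10, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_gap_constraints_hold_across_many_seeds(self):
        for seed in range(200):
            pts = draw_split_points(10, 200, 10, np.random.default_rng(seed))
            gaps = np.diff(np.concatenate([[0], pts]))
            assert (gaps >= 10).all()
            assert pts[-1] <= 200 and pts[0] > 0

    def test_infeasible_raises(self, rng):
        with pytest.raises(ConfigurationError):
            draw_split_points(10, 50, 10, rng)


class TestSegment:
    def test_counts_split_between_ends(self):
        series = normalized_series(10)
        ends = derive_end_markers(
            DenseLabelTrack(labels=np.array([0, 0, 0, 1, 0, 0, 0, 0, 0, 1]))
        )
        seqs = segment(series, ends, [4, 10])
        assert [s.weak_count for s in seqs] == [1, 1]
        assert [(s.start, s.end) for s in seqs] == [(0, 4), (4, 10)]

    def test_whole_series_single_sequence(self):
        series = normalized_series(10)
        ends = derive_end_markers(
            DenseLabelTrack(labels=np.array([0, 0, 0, 1, 0, 0, 0, 0, 0, 1]))
        )
        (seq,) = segment(series, ends, [10])
        assert seq.weak_count == 2 and len(seq) == 10

    def test_empty_points_rejected(self):
        series = normalized_series(10)
        ends = derive_end_markers(DenseLabelTrack(labels=np.zeros(10, dtype=int)))
        with pytest.raises(ConfigurationError):
            segment(series, ends, [])

    def test_requires_normalized_series(self):
        series = MultichannelSeries(samples=np.ones((5, 1)), sample_rate_hz=10.0)
        ends = derive_end_markers(DenseLabelTrack(labels=np.zeros(5, dtype=int)))
        with pytest.raises(ValueError):
            segment(series, ends, [5])

    def test_conservation_and_exact_reconstruction(self, small_cfg):
        series, track = synthesize_series(small_cfg)
        series = minmax_normalize(series)
        ends = derive_end_markers(track)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = draw_split_points(8, series.n_samples, 30, rng)
            seqs = segment(series, ends, pts)
            # conservation: weak counts sum to the end markers before the cut
            assert sum(s.weak_count for s in seqs) == ends.count_in(0, int(pts[-1]))
            # contiguity: concatenating the slices rebuilds the series prefix
            rebuilt = np.concatenate([s.samples for s in seqs], axis=0)
            assert np.array_equal(rebuilt, series.samples[: int(pts[-1])])
            starts_ends = [(s.start, s.end) for s in seqs]
            assert all(a[1] == b[0] for a, b in zip(starts_ends, starts_ends[1:]))


class TestBuildCorpus:
    def test_split_arithmetic_small(self, small_cfg):
        series, track = synthesize_series(small_cfg)
        corpus = build_corpus(
            minmax_normalize(series), track,
            n_sequences=20, replication=1, n_test=5, val_fraction=0.0,
            rng=0, min_len=20,
        )
        assert corpus.split_sizes() == {"train": 15, "test": 5}

    def test_deterministic_corpus(self, small_cfg):
        series, track = synthesize_series(small_cfg)
        series = minmax_normalize(series)
        kwargs = dict(n_sequences=20, replication=2, n_test=4, val_fraction=0.1,
                      min_len=20)
        a = build_corpus(series, track, rng=5, **kwargs)
        b = build_corpus(series, track, rng=5, **kwargs)
        assert a.splits == b.splits
        assert [s.weak_count for s in a.sequences] == [s.weak_count for s in b.sequences]
        assert all(
            np.array_equal(x.samples, y.samples)
            for x, y in zip(a.sequences, b.sequences)
        )

    def test_count_distribution_not_degenerate(self, small_corpus):
        counts = {s.weak_count for s in small_corpus.sequences}
        assert len(counts) >= 2

    def test_replicates_tagged_in_source_id(self, small_corpus):
        reps = {s.source_id for s in small_corpus.sequences}
        assert len(reps) == 2  # replication=2 in the fixture

    def test_n_test_must_be_smaller(self, small_cfg):
        series, track = synthesize_series(small_cfg)
        with pytest.raises(ConfigurationError):
            build_corpus(minmax_normalize(series), track,
                         n_sequences=10, n_test=10, rng=0, min_len=20)

    def test_subset_returns_ragged_arrays_and_counts(self, small_corpus):
        X, y = small_corpus.subset("train")
        assert len(X) == len(y) > 0
        assert len({x.shape[1] for x in X}) == 1
        assert (y >= 0).all()
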