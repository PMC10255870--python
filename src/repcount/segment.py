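"""Variable-length sequence segmentation with weak count labels.

A labeled recording is cut at random boundary points into contiguous
half-open segments ``[b_{i-1}, b_i)``.  Each segment receives a *weak
label*: the number of activity end markers it contains, i.e. how many
repetitions completed inside it.  No position or duration information
survives — the count is the only supervision downstream models see.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .series import (
    ConfigurationError,
    DenseLabelTrack,
    EndMarkerTrack,
    MultichannelSeries,
    derive_end_markers,
)

__all__ = ["WeakSequence", "SequenceCorpus", "draw_split_points", "segment", "build_corpus"]


@dataclass
class WeakSequence:
    """One variable-length slice of a recording plus its weak count label."""

    samples: np.ndarray  # (L, C), slice of a normalized series
    start: int  # inclusive, 0-based index into the parent series
    end: int  # exclusive
    weak_count: int
    source_id: str = "series"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.end - self.start != self.samples.shape[0] or self.samples.shape[0] < 1:
            raise ValueError("sequence length must equal end - start and be >= 1")
        if self.weak_count < 0:
            raise ValueError("weak_count must be non-negative")

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass
class SequenceCorpus:
    """An ordered collection of weak sequences with train/val/test tags."""

    sequences: list[WeakSequence]
    splits: list[str]
    rng_seed: int | None = None
    channel_names: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.splits):
            raise ValueError("one split tag per sequence required")
        widths = {seq.samples.shape[1] for seq in self.sequences}
        if len(widths) > 1:
            raise ValueError(f"all sequences must share a channel count, got {sorted(widths)}")

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, split: str) -> tuple[list[np.ndarray], np.ndarray]:
        """Return ``(X, y)`` for one split: ragged sample list and counts."""
        X = [s.samples for s, tag in zip(self.sequences, self.splits) if tag == split]
        y = np.array(
            [s.weak_count for s, tag in zip(self.sequences, self.splits) if tag == split],
            dtype=np.int64,
        )
        return X, y

    def split_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for tag in self.splits:
            sizes[tag] = sizes.get(tag, 0) + 1
        return sizes


def draw_split_points(
    n: int, max_index: int, min_len: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` strictly increasing cut points in ``(0, max_index]``.

    Every gap between consecutive points (including the implicit leading
    boundary at 0) is at least ``min_len`` samples.  Points are sampled
    uniformly over the feasible set by drawing the slack above the
    mandatory minimum gaps directly (sorted uniform offsets), which is
    distribution-equivalent to rejection-resampling independent uniform
    cuts until the gap constraints hold, but cannot fail for feasible
    configurations.

    Raises
    ------
    ConfigurationError
        If ``n * min_len > max_index`` (no feasible placement).
    """
    if n < 1 or min_len < 1 or max_index < 1:
        raise ConfigurationError("n, min_len and max_index must be positive")
    slack = max_index - n * min_len
    if slack < 0:
        raise ConfigurationError(
            f"cannot place {n} segments of at least {min_len} samples in {max_index}"
        )
    offsets = np.sort(rng.integers(0, slack + 1, size=n))
    points = min_len * (1 + np.arange(n, dtype=np.int64)) + offsets
    return points


def segment(
    series: MultichannelSeries, ends: EndMarkerTrack, points: np.ndarray | list[int]
) -> list[WeakSequence]:
    """Cut a normalized series at ``points`` into weak-labeled sequences.

    With boundaries ``b_0 = 0 < b_1 < ... < b_n`` taken from ``points``,
    returns ``n`` sequences ``[b_{i-1}, b_i)``; samples after the final
    point are discarded.  Each sequence's ``weak_count`` is the number of
    end markers in its half-open interval, so an activity cut by a
    boundary is credited to the sequence containing its final sample.
    """
    points = np.asarray(points, dtype=np.int64)
    if points.size == 0:
        raise ConfigurationError("points must be non-empty")
    if not series.normalized:
        raise ValueError("series must be normalized before segmentation")
    T = series.n_samples
    if (np.diff(points) <= 0).any() or points[0] <= 0 or points[-1] > T:
        raise ValueError("points must be strictly increasing within (0, T]")
    boundaries = np.concatenate([[0], points])
    out = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        out.append(
            WeakSequence(
                samples=series.samples[a:b],
                start=int(a),
                end=int(b),
                weak_count=ends.count_in(int(a), int(b)),
            )
        )
    return out


def build_corpus(
    series: MultichannelSeries,
    track: DenseLabelTrack,
    n_sequences: int,
    replication: int = 1,
    n_test: int = 0,
    val_fraction: float = 0.1,
    rng: np.random.Generator | int | None = None,
    min_len: int | None = None,
    source_id: str = "series",
) -> SequenceCorpus:
    """Segment a recording ``replication`` times and assemble a tagged corpus.

    Each replicate draws its own independent split points over the same
    recording, so replicates contribute sequences with fresh lengths and
    counts rather than verbatim copies.  The pooled sequences are shuffled
    (seeded), exactly ``n_test`` go to the test split, ``val_fraction`` of
    the remainder to validation, and the rest to training.

    Parameters
    ----------
    n_sequences : int
        Total corpus size; each replicate contributes
        ``ceil(n_sequences / replication)`` sequences and any excess from
        rounding is dropped after the shuffle.
    min_len : int, optional
        Minimum sequence length in samples; defaults to one second of
        samples (``ceil(sample_rate_hz)``).
    """
    if len(track) != series.n_samples:
        raise ValueError("label track length must match the series")
    if replication < 1:
        raise ConfigurationError("replication must be >= 1")
    if not 0 <= val_fraction < 1:
        raise ConfigurationError("val_fraction must lie in [0, 1)")
    if n_test >= n_sequences:
        raise ConfigurationError("n_test must be smaller than n_sequences")
    if isinstance(rng, np.random.Generator):
        generator = rng
        seed = None
    else:
        seed = rng
        generator = np.random.default_rng(rng)
    if min_len is None:
        min_len = int(math.ceil(series.sample_rate_hz))

    ends = derive_end_markers(track)
    per_replicate = math.ceil(n_sequences / replication)
    pooled: list[WeakSequence] = []
    for rep in range(replication):
        points = draw_split_points(per_replicate, series.n_samples, min_len, generator)
        for seq in segment(series, ends, points):
            seq.source_id = f"{source_id}/rep{rep}"
            pooled.append(seq)
    if len(pooled) < n_sequences:
        raise ConfigurationError(
            f"pooled {len(pooled)} sequences but {n_sequences} were requested"
        )
    order = generator.permutation(len(pooled))[:n_sequences]
    chosen = [pooled[i] for i in order]

    n_val = int(round(val_fraction * (n_sequences - n_test)))
    splits = ["test"] * n_test + ["val"] * n_val + ["train"] * (n_sequences - n_test - n_val)
    return SequenceCorpus(
        sequences=chosen,
        splits=splits,
        rng_seed=seed if isinstance(seed, int) else None,
        channel_names=list(series.channel_names),
        manifest={
            "n_sequences": n_sequences,
            "replication": replication,
            "n_test": n_test,
            "val_fraction": val_fraction,
            "min_len": min_len,
            "source_id": source_id,
        },
    )
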