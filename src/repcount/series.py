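"""Core multichannel time-series and label-track types.

A recording is a ``T x C`` matrix of calibrated acceleration values
(milli-g; 1000 = one earth gravity) with a per-sample dense label track
in which class 0 is the null (background) class.  The weak supervision
used elsewhere in the package is derived from the *ends* of activity
runs: the final sample of every maximal run of a non-null class marks
one completed repetition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MultichannelSeries",
    "DenseLabelTrack",
    "EndMarkerTrack",
    "minmax_normalize",
    "derive_end_markers",
    "merge_classes",
]


class InvalidDataError(ValueError):
    """Raised when input data violate a structural precondition."""


class ConfigurationError(ValueError):
    """Raised when configuration values are inconsistent or infeasible."""


@dataclass
class MultichannelSeries:
    """A ``T x C`` real-valued recording.

    Parameters
    ----------
    samples : ndarray of shape (T, C)
        Acceleration values; milli-g before normalization, dimensionless
        in ``[0, 1]`` afterwards.
    sample_rate_hz : float
        Sampling rate (about 98 Hz for the wrist/arm sensor network this
        package targets).
    channel_names : list of str
        One name per column.
    normalized : bool
        Whether :func:`minmax_normalize` has been applied.
    """

    samples: np.ndarray
    sample_rate_hz: float
    channel_names: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise InvalidDataError(
                f"samples must be a T x C matrix with T,C >= 1, got shape {self.samples.shape}"
            )
        if self.sample_rate_hz <= 0:
            raise InvalidDataError("sample_rate_hz must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch_{i}" for i in range(self.samples.shape[1])]
        if len(self.channel_names) != self.samples.shape[1]:
            raise InvalidDataError("channel_names length must equal the channel count")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class DenseLabelTrack:
    """Per-sample integer activity class; 0 is the null class."""

    labels: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise InvalidDataError("labels must be a non-empty 1-D integer vector")
        if (self.labels < 0).any():
            raise InvalidDataError("labels must be non-negative (0 = null class)")

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class EndMarkerTrack:
    """Boolean track that is true exactly at the last sample of each
    maximal run of a non-null class — the "completed repetition" events."""

    is_end: np.ndarray

    def __post_init__(self) -> None:
        self.is_end = np.asarray(self.is_end, dtype=bool)
        if self.is_end.ndim != 1:
            raise InvalidDataError("is_end must be a 1-D boolean vector")

    @property
    def n_ends(self) -> int:
        return int(self.is_end.sum())

    def count_in(self, start: int, end: int) -> int:
        """Number of end markers in the half-open interval ``[start, end)``."""
        return int(self.is_end[start:end].sum())


def minmax_normalize(series: MultichannelSeries) -> MultichannelSeries:
    """Rescale each channel independently to ``[0, 1]``.

    Applies the affine map ``(x - min_c) / (max_c - min_c)`` per channel,
    fitted on the whole recording.  Channels with zero range (dead
    sensors) map to all-zeros rather than raising.

    Raises
    ------
    InvalidDataError
        If the series is already normalized or contains non-finite values.
    """
    if series.normalized:
        raise InvalidDataError("series is already normalized")
    if not np.isfinite(series.samples).all():
        raise InvalidDataError("series contains non-finite values")
    lo = series.samples.min(axis=0)
    rng = series.samples.max(axis=0) - lo
    # the direct quotient pins channel extremes to exactly 0 and 1;
    # zero-range (dead) channels divide by 1 and land on all-zeros
    scaled = (series.samples - lo) / np.where(rng == 0, 1.0, rng)
    return replace(series, samples=scaled, normalized=True)


def derive_end_markers(track: DenseLabelTrack) -> EndMarkerTrack:
    """Mark the final sample of every maximal constant run of a non-null label.

    A direct class change ``k1 -> k2`` (both non-null) ends the ``k1`` run:
    back-to-back distinct activities each count as completed.
    """
    labels = track.labels
    nxt = np.empty_like(labels)
    nxt[:-1] = labels[1:]
    nxt[-1] = -1  # sentinel: the recording ends, closing any open run
    is_end = (labels > 0) & (labels != nxt)
    return EndMarkerTrack(is_end=is_end)


def merge_classes(track: DenseLabelTrack, mapping: dict[int, int]) -> DenseLabelTrack:
    """Relabel classes through ``mapping`` (old id -> new id).

    Adjacent runs whose classes map to the same new id merge into one run,
    so their shared boundary no longer produces an end marker.  Useful for
    activities that always occur consecutively (e.g. opening then closing
    the same object) and should count as one repetition.

    Raises
    ------
    ConfigurationError
        If the mapping misses a class present in the track, or maps the
        null class to a non-null one.
    """
    present = np.unique(track.labels)
    missing = [int(k) for k in present if int(k) not in mapping]
    if missing:
        raise ConfigurationError(f"mapping does not cover present class ids {missing}")
    if mapping.get(0, 0) != 0:
        raise ConfigurationError("the null class (0) must map to itself")
    lut_size = int(present.max()) + 1
    lut = np.zeros(lut_size, dtype=np.int64)
    for old in present:
        lut[old] = mapping[int(old)]
    new_labels = lut[track.labels]
    new_names = {
        mapping[int(old)]: track.class_names.get(int(old), str(mapping[int(old)]))
        for old in present
    }
    return DenseLabelTrack(labels=new_labels, class_names=new_names)
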