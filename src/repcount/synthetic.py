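"""Synthetic wearable-accelerometer recordings with dense labels.

Emulates the structure of a multi-sensor arm-worn accelerometer study of
repetitive manipulative gestures: repeated activity motifs of variable
duration, separated by null-class background, on many channels sampled
at ~98 Hz in milli-g units.  Motifs are amplitude-windowed sinusoids —
analytically controllable and seedable, which is what the counting task
needs (variable event durations with known ground truth), though they do
not reproduce the morphology of real arm motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .segment import SequenceCorpus, build_corpus
from .series import DenseLabelTrack, MultichannelSeries, minmax_normalize

__all__ = ["SyntheticConfig", "sample_motif", "synthesize_series", "generate_corpus"]


@dataclass
class SyntheticConfig:
    """Generator settings.

    Defaults mirror the sensor geometry of a 20-sensor (60-channel)
    arm-worn network at ~98 Hz with gesture-scale accelerations of about
    one gravity and a modest sensor noise floor.
    """

    channels: int = 60
    sample_rate_hz: float = 98.0
    n_instances: int = 50
    motif_duration_s: tuple[float, float] = (0.5, 1.5)
    gap_duration_s: tuple[float, float] = (1.0, 3.0)
    motif_freq_hz: tuple[float, float] = (2.0, 5.0)
    amplitude_milli_g: float = 1000.0
    noise_sd_milli_g: float = 30.0
    active_channel_fraction: float = 0.5
    seed: int = 0
    class_names: dict[int, str] = field(default_factory=lambda: {0: "null", 1: "motif"})

    def __post_init__(self) -> None:
        for name in ("motif_duration_s", "gap_duration_s", "motif_freq_hz"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < min <= max")
        if self.channels < 1 or self.n_instances < 0:
            raise ValueError("channels must be >= 1 and n_instances >= 0")
        if self.amplitude_milli_g <= 0 or self.noise_sd_milli_g < 0:
            raise ValueError("amplitude must be > 0 and noise_sd >= 0")
        if not 0 < self.active_channel_fraction <= 1:
            raise ValueError("active_channel_fraction must lie in (0, 1]")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")


def _duration_to_samples(duration_s: float, rate_hz: float) -> int:
    return max(2, int(round(duration_s * rate_hz)))


def sample_motif(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    active: np.ndarray | None = None,
    phase_pattern: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one noise-free activity motif as an ``L x C`` matrix.

    A subset of channels carries a sinusoid of random frequency under a
    Hann window, so the motif ramps up from exactly zero and returns to
    exactly zero; inactive channels stay 0.  A gesture class has a
    stereotyped structure across sensors: the engaged-channel subset
    (``active``) and the relative phase pattern across those channels
    (``phase_pattern``) are properties of the class, drawn once per
    recording by :func:`synthesize_series`, while duration, frequency
    and a global phase offset vary per repetition.  When omitted, both
    are drawn fresh for this motif.
    """
    duration = rng.uniform(*cfg.motif_duration_s)
    freq = rng.uniform(*cfg.motif_freq_hz)
    L = _duration_to_samples(duration, cfg.sample_rate_hz)
    n_active = int(math.ceil(cfg.active_channel_fraction * cfg.channels))
    if active is None:
        active = rng.choice(cfg.channels, size=n_active, replace=False)
    if phase_pattern is None:
        phase_pattern = rng.uniform(0.0, 2.0 * np.pi, size=len(active))
    phases = phase_pattern + rng.uniform(0.0, 2.0 * np.pi)

    t = np.arange(L) / cfg.sample_rate_hz
    window = np.hanning(L)
    motif = np.zeros((L, cfg.channels))
    motif[:, active] = (
        cfg.amplitude_milli_g
        * window[:, None]
        * np.sin(2.0 * np.pi * freq * t[:, None] + phases[None, :])
    )
    return motif


def synthesize_series(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[MultichannelSeries, DenseLabelTrack]:
    """Generate one labeled recording: motifs separated by null gaps.

    The label track is class 1 over each motif span and 0 elsewhere;
    Gaussian noise of sd ``noise_sd_milli_g`` is added to every sample.
    The returned series is unnormalized (milli-g scale).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    pieces: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    def add_gap() -> None:
        g = _duration_to_samples(rng.uniform(*cfg.gap_duration_s), cfg.sample_rate_hz)
        pieces.append(np.zeros((g, cfg.channels)))
        labels.append(np.zeros(g, dtype=np.int64))

    n_active = int(math.ceil(cfg.active_channel_fraction * cfg.channels))
    active = rng.choice(cfg.channels, size=n_active, replace=False)
    phase_pattern = rng.uniform(0.0, 2.0 * np.pi, size=n_active)

    add_gap()
    for _ in range(cfg.n_instances):
        motif = sample_motif(cfg, rng, active=active, phase_pattern=phase_pattern)
        pieces.append(motif)
        labels.append(np.ones(motif.shape[0], dtype=np.int64))
        add_gap()

    samples = np.concatenate(pieces, axis=0)
    if cfg.noise_sd_milli_g > 0:
        samples = samples + rng.normal(0.0, cfg.noise_sd_milli_g, size=samples.shape)
    series = MultichannelSeries(
        samples=samples,
        sample_rate_hz=cfg.sample_rate_hz,
        channel_names=[f"ch_{i}" for i in range(cfg.channels)],
    )
    track = DenseLabelTrack(labels=np.concatenate(labels), class_names=dict(cfg.class_names))
    return series, track


def generate_corpus(
    cfg: SyntheticConfig,
    n_sequences: int,
    n_test: int = 0,
    val_fraction: float = 0.1,
    rng: np.random.Generator | int | None = None,
    replication: int = 1,
    min_len: int | None = None,
) -> SequenceCorpus:
    """End-to-end corpus: synthesize -> min-max normalize -> segment/split.

    Sizing ``cfg.n_instances`` against ``n_sequences`` controls the range
    of per-sequence counts (roughly ``n_instances * replication /
    n_sequences`` on average).
    """
    if rng is None or isinstance(rng, int):
        seed = cfg.seed if rng is None else rng
        generator = np.random.default_rng(seed)
    else:
        generator = rng
        seed = None
    series, track = synthesize_series(cfg, generator)
    normalized = minmax_normalize(series)
    corpus = build_corpus(
        normalized,
        track,
        n_sequences=n_sequences,
        replication=replication,
        n_test=n_test,
        val_fraction=val_fraction,
        rng=generator,
        min_len=min_len,
        source_id="synthetic",
    )
    corpus.rng_seed = seed if isinstance(seed, int) else None
    corpus.manifest["synthetic_config"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(cfg).items()
        if k != "class_names"
    }
    return corpus
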