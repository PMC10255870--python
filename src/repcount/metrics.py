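"""Evaluation metrics for count predictions over a test corpus.

Three summary numbers are reported: exact-count accuracy (fraction of
sequences whose predicted count equals the weak label), mean absolute
error, and a mean per-sequence percentage accuracy, plus a signed-error
histogram.  The percentage accuracy of one sequence is

    100 * max(0, 1 - |pred - truth| / max(truth, 1))

the ``max(truth, 1)`` guard keeps zero-count sequences well defined
(any miss on a zero-count sequence scores 0%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import InvalidDataError

__all__ = [
    "EvalReport",
    "exact_accuracy",
    "mae",
    "mean_percent_accuracy",
    "error_histogram",
    "evaluate",
    "plot_predictions",
]


def _check_pair(preds, truths) -> tuple[np.ndarray, np.ndarray]:
    preds = np.asarray(preds, dtype=np.int64)
    truths = np.asarray(truths, dtype=np.int64)
    if preds.ndim != 1 or truths.ndim != 1 or preds.size != truths.size or preds.size < 1:
        raise InvalidDataError("preds and truths must be equal-length non-empty vectors")
    return preds, truths


def exact_accuracy(preds, truths) -> float:
    """Fraction of sequences with an exactly correct count."""
    preds, truths = _check_pair(preds, truths)
    return float(np.mean(preds == truths))


def mae(preds, truths) -> float:
    """Mean absolute count error."""
    preds, truths = _check_pair(preds, truths)
    return float(np.mean(np.abs(preds - truths)))


def mean_percent_accuracy(preds, truths) -> float:
    """Mean per-sequence relative accuracy, as a percentage in [0, 100]."""
    preds, truths = _check_pair(preds, truths)
    rel = 1.0 - np.abs(preds - truths) / np.maximum(truths, 1)
    return float(100.0 * np.mean(np.maximum(rel, 0.0)))


def error_histogram(preds, truths) -> dict[int, int]:
    """Counts of signed errors ``pred - truth``."""
    preds, truths = _check_pair(preds, truths)
    errors, counts = np.unique(preds - truths, return_counts=True)
    return {int(e): int(c) for e, c in zip(errors, counts)}


@dataclass
class EvalReport:
    """Summary of count predictions over one test corpus."""

    n_sequences: int
    exact_accuracy: float
    mae: float
    mean_percent_accuracy: float
    error_histogram: dict[int, int]

    def __post_init__(self) -> None:
        # internal consistency: the three summary numbers are recomputable
        # from the signed-error histogram alone
        n = sum(self.error_histogram.values())
        if n != self.n_sequences:
            raise InvalidDataError("histogram mass must equal n_sequences")
        hist_mae = sum(abs(e) * c for e, c in self.error_histogram.items()) / n
        hist_acc = self.error_histogram.get(0, 0) / n
        if abs(hist_mae - self.mae) > 1e-9 or abs(hist_acc - self.exact_accuracy) > 1e-9:
            raise InvalidDataError("report is inconsistent with its error histogram")

    @property
    def abs_error_histogram(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for e, c in self.error_histogram.items():
            out[abs(e)] = out.get(abs(e), 0) + c
        return out

    @property
    def within_one_fraction(self) -> float:
        n = sum(c for e, c in self.error_histogram.items() if abs(e) <= 1)
        return n / self.n_sequences

    def to_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "exact_accuracy": self.exact_accuracy,
            "mae": self.mae,
            "mean_percent_accuracy": self.mean_percent_accuracy,
            "within_one_fraction": self.within_one_fraction,
            "error_histogram": {str(k): v for k, v in sorted(self.error_histogram.items())},
        }


def evaluate(preds, truths) -> EvalReport:
    """Compute the full evaluation report for one prediction set."""
    preds, truths = _check_pair(preds, truths)
    return EvalReport(
        n_sequences=int(preds.size),
        exact_accuracy=exact_accuracy(preds, truths),
        mae=mae(preds, truths),
        mean_percent_accuracy=mean_percent_accuracy(preds, truths),
        error_histogram=error_histogram(preds, truths),
    )


def plot_predictions(preds, truths, ax=None, title: str | None = None):
    """Ground-truth vs. prediction dot plot: truth and prediction per
    sequence, with a connecting line where they disagree."""
    import matplotlib.pyplot as plt

    preds, truths = _check_pair(preds, truths)
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.5))
    x = np.arange(preds.size)
    for xi, p, t in zip(x, preds, truths):
        if p != t:
            ax.plot([xi, xi], [t, p], color="0.7", lw=1, zorder=1)
    ax.scatter(x, truths, s=14, color="tab:red", label="ground truth", zorder=2)
    ax.scatter(x, preds, s=14, color="tab:blue", label="prediction", zorder=3)
    ax.set_xlabel("test sequence")
    ax.set_ylabel("repetition count")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    return ax
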