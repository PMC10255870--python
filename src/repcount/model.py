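"""The weakly-supervised counting network and its training loop.

Architecture, applied to one variable-length sequence of shape ``L x C``:

1. two time-distributed dense layers (``C -> dense1 -> dense2``, ReLU on
   the second) compress each sample to a low-dimensional feature,
2. a single-unit LSTM with linear cell activation integrates the feature
   stream into one scalar per time step (the *step signal*),
3. a masking layer thresholds the step signal at ``tau`` into a
   near-binary square wave, and
4. a counting layer returns the number of maximal non-zero regions
   (rising edges) of the masked signal — the predicted repetition count.

Steps 3-4 are not differentiable, so training works through a logistic
relaxation ``s_t = sigma(k (x_t - tau))`` of the mask, in three stages:

* **Warm-up** fits the *mask mass* ``sum_t s_t / D`` (with ``D`` an
  expected event duration in samples) to the weak count.  This density
  objective has gradients everywhere and none of the degenerate optima
  of region counting; it positions activity bumps over the events.
* **Threshold calibration** picks ``tau`` by grid search on the training
  split.  The threshold is treated as a fitted parameter: the counting
  layer needs *a* threshold, but nothing pins its numeric value, and the
  warm-up fixes the signal's scale only up to an offset.
* **Fine-tuning** minimizes the Huber loss between the *soft count* —
  the rising-edge sum of ``s``, which converges to the hard region count
  as ``k`` grows — plus a mask-binarization penalty ``mean(s (1 - s))``
  that forbids the degenerate sub-threshold solutions in which many
  partial rises sum to the label without the signal ever crossing
  ``tau``.  The threshold is re-calibrated periodically, and the
  parameters giving the best validation hard-path error are restored.

Inference always uses the hard threshold-and-count path, so predictions
are non-negative integers by construction.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError

from . import _net
from .series import ConfigurationError, InvalidDataError

__all__ = [
    "CountingRegressor",
    "TrainingHistory",
    "hard_mask",
    "count_regions",
    "soft_count",
]

logger = logging.getLogger("repcount")


def hard_mask(signal: np.ndarray, tau: float) -> np.ndarray:
    """Threshold a step signal: 1 where ``signal > tau``, else 0."""
    signal = np.asarray(signal, dtype=np.float64)
    return (signal > tau).astype(np.int64)


def count_regions(mask: np.ndarray) -> int:
    """Number of maximal runs of ones in a binary vector.

    Counts rising edges, with a leading 1 counting as an edge.
    """
    mask = np.asarray(mask)
    if mask.size == 0:
        return 0
    if not np.isin(mask, (0, 1)).all():
        raise InvalidDataError("count_regions expects a binary vector")
    mask = mask.astype(np.int64)
    return int(mask[0] + np.sum((mask[1:] == 1) & (mask[:-1] == 0)))


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def soft_count(signal: np.ndarray, tau: float, k: float) -> float:
    """Differentiable surrogate of ``count_regions(hard_mask(signal, tau))``.

    With ``s_t = logistic(k (x_t - tau))``, returns
    ``s_1 + sum_t max(0, s_t - s_{t-1})`` — a smooth rising-edge sum that
    converges to the hard region count as ``k`` grows (for signals that
    never equal ``tau`` exactly).
    """
    if k <= 0:
        raise ValueError("steepness k must be positive")
    s = _logistic(k * (np.asarray(signal, dtype=np.float64) - tau))
    if s.size == 0:
        return 0.0
    return float(s[0] + np.maximum(np.diff(s), 0.0).sum())


def _huber(e: float, delta: float) -> tuple[float, float]:
    """Huber loss value and derivative at residual ``e``."""
    a = abs(e)
    if a <= delta:
        return 0.5 * e * e, e
    return delta * (a - 0.5 * delta), delta * np.sign(e)


@dataclass
class TrainingHistory:
    """Per-epoch training record.

    ``train_loss`` holds the epoch's mean batch objective (mass loss
    during warm-up, count loss plus binarization penalty afterwards);
    ``val_loss`` the hard-path mean absolute count error on the
    monitoring split; ``steepness`` the logistic steepness in force.
    """

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    steepness: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def __len__(self) -> int:
        return len(self.train_loss)


class CountingRegressor(RegressorMixin, BaseEstimator):
    """Weakly-supervised repetition counter for ragged sequence batches.

    ``X`` is a list of ``L_i x C`` arrays (variable ``L_i``, common
    channel count ``C``); ``y`` holds the per-sequence repetition counts.

    Parameters
    ----------
    dense1_units : int or None
        Width of the first time-distributed dense layer; ``None`` means
        "same as the channel count" (the conventional choice here).
    dense2_units : int
        Width of the second (ReLU) dense layer; the dimensionality
        handed to the recurrence.
    lstm_units : int
        LSTM hidden size.  With 1 unit the hidden state itself is the
        step signal; larger sizes add a linear read-out to one scalar.
    mask_threshold : float
        Initial threshold ``tau`` of the masking layer.  When
        ``tune_threshold`` is on, :meth:`fit` calibrates it on the
        training split and stores the result in ``mask_threshold_``.
    tune_threshold : bool
        Whether to calibrate the threshold during :meth:`fit`.
    steepness, steepness_growth, max_steepness : float
        Logistic steepness ``k``: warm-up runs at ``steepness``;
        fine-tuning anneals ``k`` from ``steepness`` by a factor
        ``steepness_growth`` per epoch, capped at ``max_steepness``.
        The cap keeps every sample within gradient reach of the mask —
        at large ``k`` the logistic saturates and training freezes.
    warmup_epochs : int
        Epochs of the mass warm-up stage (0 disables it).
    warmup_learning_rate, learning_rate : float
        Adam step sizes for warm-up and fine-tuning.  Fine-tuning also
        halves its rate after repeated epochs without validation
        improvement.
    expected_event_samples : float
        ``D`` of the warm-up objective: a prior on the typical event
        duration in samples (~1 s of samples by default).
    binarize_weight : float
        Weight of the mask-binarization penalty ``mean(s (1 - s))``.
    batch_size, huber_delta : int, float
        Mini-batch size and Huber transition point.
    cell_clip : float
        Symmetric bound on the LSTM cell state.  The linear cell
        activation makes the candidate feedback loop an unbounded linear
        system; a small clip both stabilizes it and keeps plateaus close
        enough to the threshold for gradients to reach them.
    grad_clip : float
        Global gradient-norm bound per optimizer step.
    max_epochs : int
        Total epoch budget (warm-up plus fine-tuning).
    patience : int
        Fine-tuning stops after this many epochs without validation
        improvement; the best-epoch parameters are restored either way.
    validation_fraction : float
        Fraction of training sequences held out for early stopping when
        no explicit validation set is passed to :meth:`fit`.
    random_state : int or None
        Seed for parameter initialization, shuffling and the internal
        validation split.

    Attributes
    ----------
    params_ : dict of arrays
        Network parameters.
    mask_threshold_ : float
        Calibrated masking threshold used by :meth:`predict`.
    history_ : TrainingHistory
    n_features_in_, n_parameters_ : int
    """

    def __init__(
        self,
        dense1_units: int | None = None,
        dense2_units: int = 2,
        lstm_units: int = 1,
        mask_threshold: float = 0.5,
        tune_threshold: bool = True,
        steepness: float = 5.0,
        steepness_growth: float = 2.0,
        max_steepness: float = 20.0,
        warmup_epochs: int = 40,
        warmup_learning_rate: float = 1e-3,
        learning_rate: float = 1e-4,
        expected_event_samples: float = 98.0,
        binarize_weight: float = 0.3,
        batch_size: int = 2,
        huber_delta: float = 1.0,
        cell_clip: float = 1.2,
        grad_clip: float = 1.0,
        max_epochs: int = 170,
        patience: int = 60,
        validation_fraction: float = 0.1,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.dense1_units = dense1_units
        self.dense2_units = dense2_units
        self.lstm_units = lstm_units
        self.mask_threshold = mask_threshold
        self.tune_threshold = tune_threshold
        self.steepness = steepness
        self.steepness_growth = steepness_growth
        self.max_steepness = max_steepness
        self.warmup_epochs = warmup_epochs
        self.warmup_learning_rate = warmup_learning_rate
        self.learning_rate = learning_rate
        self.expected_event_samples = expected_event_samples
        self.binarize_weight = binarize_weight
        self.batch_size = batch_size
        self.huber_delta = huber_delta
        self.cell_clip = cell_clip
        self.grad_clip = grad_clip
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------ #
    # validation helpers

    def _check_config(self) -> None:
        if self.dense2_units < 1 or self.lstm_units < 1 or (
            self.dense1_units is not None and self.dense1_units < 1
        ):
            raise ConfigurationError("all layer widths must be >= 1")
        if self.mask_threshold <= 0:
            raise ConfigurationError("mask_threshold must be positive")
        if self.steepness <= 0 or self.max_steepness <= 0 or self.steepness_growth < 1:
            raise ConfigurationError("steepness parameters must be positive (growth >= 1)")
        if self.learning_rate <= 0 or self.warmup_learning_rate <= 0:
            raise ConfigurationError("learning rates must be positive")
        if self.batch_size < 1 or self.huber_delta <= 0:
            raise ConfigurationError("batch_size and huber_delta must be positive")
        if self.expected_event_samples <= 0 or self.cell_clip <= 0 or self.grad_clip <= 0:
            raise ConfigurationError(
                "expected_event_samples, cell_clip and grad_clip must be positive"
            )
        if self.binarize_weight < 0 or self.warmup_epochs < 0:
            raise ConfigurationError("binarize_weight and warmup_epochs must be >= 0")

    def _check_X(self, X, n_channels: int | None = None) -> list[np.ndarray]:
        if not isinstance(X, (list, tuple)):
            raise InvalidDataError("X must be a list of L x C arrays (ragged batch)")
        out = []
        for i, x in enumerate(X):
            x = np.asarray(x, dtype=np.float64)
            if x.ndim != 2 or x.shape[0] < 1:
                raise InvalidDataError(f"sequence {i} must be a 2-D L x C array with L >= 1")
            if n_channels is None:
                n_channels = x.shape[1]
            if x.shape[1] != n_channels:
                raise InvalidDataError(
                    f"sequence {i} has {x.shape[1]} channels, expected {n_channels}"
                )
            out.append(x)
        return out

    # ------------------------------------------------------------------ #
    # construction

    def build(self, n_channels: int) -> "CountingRegressor":
        """Initialize (seeded) parameters for ``n_channels`` inputs
        without training; used by :meth:`fit` and by checkpoint loading."""
        self._check_config()
        rng = np.random.default_rng(self.random_state)
        self._build_with_rng(rng, n_channels)
        return self

    def _build_with_rng(self, rng: np.random.Generator, n_channels: int) -> None:
        d1 = self.dense1_units if self.dense1_units is not None else n_channels
        self.params_ = _net.init_params(rng, n_channels, d1, self.dense2_units, self.lstm_units)
        self.n_features_in_ = n_channels
        self.n_parameters_ = _net.n_parameters(self.params_)
        self.mask_threshold_ = float(self.mask_threshold)

    # ------------------------------------------------------------------ #
    # loss/gradient kernels (per padded batch)

    def _mass_loss_grads(self, Xb, yb, k, tau):
        """Warm-up: Huber(mask mass / D - y) per sequence."""
        Xpad, lengths = _net.pad_batch(Xb)
        signal, cache = _net.forward(self.params_, Xpad, lengths, self.cell_clip)
        B = len(Xb)
        D = self.expected_event_samples
        dsignal = np.zeros_like(signal)
        total = 0.0
        for i in range(B):
            L = lengths[i]
            s = _logistic(k * (signal[i, :L] - tau))
            loss_i, dloss = _huber(float(s.sum() / D) - yb[i], self.huber_delta)
            total += loss_i
            dsignal[i, :L] = (dloss / D) * k * s * (1.0 - s) / B
        grads = _net.backward(self.params_, cache, dsignal)
        _net.clip_grads(grads, self.grad_clip)
        return total / B, grads

    def _count_loss_grads(self, Xb, yb, k, tau):
        """Fine-tuning: Huber(soft count - y) + binarization penalty."""
        Xpad, lengths = _net.pad_batch(Xb)
        signal, cache = _net.forward(self.params_, Xpad, lengths, self.cell_clip)
        B = len(Xb)
        lam = self.binarize_weight
        dsignal = np.zeros_like(signal)
        total = 0.0
        for i in range(B):
            L = lengths[i]
            s = _logistic(k * (signal[i, :L] - tau))
            ds = k * s * (1.0 - s)
            rising = np.diff(s) > 0
            value = float(s[0] + np.maximum(np.diff(s), 0.0).sum())
            coef = np.zeros(L)
            coef[0] = 1.0
            coef[1:][rising] += 1.0
            coef[:-1][rising] -= 1.0
            loss_i, dloss = _huber(value - yb[i], self.huber_delta)
            total += loss_i + lam * float(np.mean(s * (1.0 - s)))
            dsignal[i, :L] = (coef * ds * dloss + (lam / L) * ds * (1.0 - 2.0 * s)) / B
        grads = _net.backward(self.params_, cache, dsignal)
        _net.clip_grads(grads, self.grad_clip)
        return total / B, grads

    # ------------------------------------------------------------------ #
    # hard-path helpers

    def _signals(self, X: list[np.ndarray], batch_size: int = 64) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for b0 in range(0, len(X), batch_size):
            Xb = X[b0 : b0 + batch_size]
            Xpad, lengths = _net.pad_batch(Xb)
            signal, _ = _net.forward(self.params_, Xpad, lengths, self.cell_clip)
            out.extend(signal[i, : lengths[i]].copy() for i in range(len(Xb)))
        return out

    @staticmethod
    def _counts_at(signals: list[np.ndarray], tau: float) -> np.ndarray:
        return np.array(
            [count_regions(hard_mask(s, tau)) for s in signals], dtype=np.int64
        )

    def _tune_threshold(self, X, y) -> tuple[float, float]:
        """Grid-search the mask threshold minimizing hard-count MAE."""
        signals = self._signals(X)
        grid = np.arange(0.05, 1.16, 0.025)
        best_mae, best_tau = np.inf, float(self.mask_threshold)
        for tau in grid:
            mae = float(np.mean(np.abs(self._counts_at(signals, float(tau)) - y)))
            if mae < best_mae - 1e-12:
                best_mae, best_tau = mae, float(tau)
        return best_tau, best_mae

    def _hard_mae(self, X, y, tau: float) -> float:
        return float(np.mean(np.abs(self._counts_at(self._signals(X), tau) - y)))

    # ------------------------------------------------------------------ #
    # training

    def fit(self, X, y, validation_data=None):
        """Train on weakly labeled ragged sequences.

        Parameters
        ----------
        X : list of (L_i, C) arrays
        y : array of non-negative integer counts, one per sequence
        validation_data : (X_val, y_val), optional
            Explicit validation set for early stopping; if omitted, a
            ``validation_fraction`` share of ``X`` is held out.
        """
        self._check_config()
        X = self._check_X(X)
        y = np.asarray(y, dtype=np.float64)
        if len(X) == 0:
            raise ConfigurationError("training set is empty")
        if y.ndim != 1 or y.size != len(X):
            raise InvalidDataError("y must hold one count per sequence")
        if (y < 0).any():
            raise InvalidDataError("counts must be non-negative")

        rng = np.random.default_rng(self.random_state)
        n_channels = X[0].shape[1]
        self._build_with_rng(rng, n_channels)

        if validation_data is not None:
            X_val = self._check_X(validation_data[0], n_channels)
            y_val = np.asarray(validation_data[1], dtype=np.float64)
        elif self.validation_fraction > 0 and len(X) >= 5:
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            order = rng.permutation(len(X))
            val_idx, train_idx = order[:n_val], order[n_val:]
            X_val = [X[i] for i in val_idx]
            y_val = y[val_idx]
            X = [X[i] for i in train_idx]
            y = y[train_idx]
        else:
            X_val, y_val = [], np.zeros(0)
        has_val = len(X_val) > 0
        X_mon, y_mon = (X_val, y_val) if has_val else (X, y)

        history = TrainingHistory()
        tau = float(self.mask_threshold)

        def run_epoch(loss_fn, optimizer, k, epoch, batch_tag):
            batch_losses = []
            for b0 in range(0, len(X), self.batch_size):
                idx = order[b0 : b0 + self.batch_size]
                loss, grads = loss_fn([X[i] for i in idx], y[idx], k, tau)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite {batch_tag} loss at epoch {epoch}, "
                        f"batch {b0 // self.batch_size}"
                    )
                optimizer.step(self.params_, grads)
                batch_losses.append(loss)
            return float(np.mean(batch_losses))

        # --- stage 1: mass warm-up ------------------------------------ #
        optimizer = _net.Adam(self.params_, lr=self.warmup_learning_rate)
        for epoch in range(self.warmup_epochs):
            order = rng.permutation(len(X))
            train_loss = run_epoch(self._mass_loss_grads, optimizer, self.steepness,
                                   epoch, "warm-up")
            history.train_loss.append(train_loss)
            history.val_loss.append(self._hard_mae(X_mon, y_mon, tau))
            history.steepness.append(self.steepness)
            if self.verbose:
                logger.info("warmup %3d  mass=%.5f  val=%.3f",
                            epoch, train_loss, history.val_loss[-1])

        # --- stage 2: threshold calibration --------------------------- #
        if self.tune_threshold:
            tau, train_mae = self._tune_threshold(X, y)
            if self.verbose:
                logger.info("calibrated mask threshold %.3f (train MAE %.3f)",
                            tau, train_mae)

        # --- stage 3: count fine-tuning ------------------------------- #
        optimizer = _net.Adam(self.params_, lr=self.learning_rate)
        best_monitor = self._hard_mae(X_mon, y_mon, tau)
        best_params = copy.deepcopy(self.params_)
        best_tau = tau
        best_epoch = self.warmup_epochs - 1
        stall = 0
        decays = 0
        for epoch in range(self.warmup_epochs, self.max_epochs):
            e = epoch - self.warmup_epochs
            k = min(self.steepness * self.steepness_growth**e, self.max_steepness)
            order = rng.permutation(len(X))
            train_loss = run_epoch(self._count_loss_grads, optimizer, k, epoch, "training")
            if self.tune_threshold and e % 5 == 4:
                tau, _ = self._tune_threshold(X, y)
            monitor = self._hard_mae(X_mon, y_mon, tau)
            history.train_loss.append(train_loss)
            history.val_loss.append(monitor)
            history.steepness.append(k)
            if self.verbose:
                logger.info("epoch %3d  k=%5.1f  tau=%.3f  count=%.5f  val=%.3f",
                            epoch, k, tau, train_loss, monitor)
            if monitor < best_monitor - 1e-12:
                best_monitor = monitor
                best_params = copy.deepcopy(self.params_)
                best_tau = tau
                best_epoch = epoch
                stall = 0
            else:
                stall += 1
                if stall % 15 == 0 and decays < 4:
                    optimizer.lr *= 0.5
                    decays += 1
                if stall > self.patience:
                    break

        self.params_ = best_params
        self.mask_threshold_ = float(best_tau)
        history.best_epoch = best_epoch
        self.history_ = history
        return self

    # ------------------------------------------------------------------ #
    # inference

    def _require_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise NotFittedError(
                "this CountingRegressor has no parameters; call fit or build first"
            )

    def step_signals(self, X, batch_size: int = 64) -> list[np.ndarray]:
        """Per-step LSTM output (before masking) for each sequence."""
        self._require_fitted()
        X = self._check_X(X, self.n_features_in_)
        return self._signals(X, batch_size=batch_size)

    def step_signal(self, x: np.ndarray) -> np.ndarray:
        return self.step_signals([x])[0]

    def predict(self, X, batch_size: int = 64) -> np.ndarray:
        """Hard-path counts: threshold the step signal at the calibrated
        ``mask_threshold_`` and count its non-zero regions.  Padded batch
        processing is output-equivalent to per-sequence processing."""
        signals = self.step_signals(X, batch_size=batch_size)
        tau = getattr(self, "mask_threshold_", self.mask_threshold)
        return self._counts_at(signals, tau)

    def predict_count(self, x: np.ndarray) -> int:
        """Count for a single sequence."""
        return int(self.predict([x])[0])


def fit_on_corpus(estimator: CountingRegressor, corpus) -> CountingRegressor:
    """Train an estimator on a corpus's train split, early-stopping on
    its validation split (if present)."""
    X_train, y_train = corpus.subset("train")
    X_val, y_val = corpus.subset("val")
    validation = (X_val, y_val) if len(X_val) else None
    return estimator.fit(X_train, y_train, validation_data=validation)
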