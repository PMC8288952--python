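"""The anticipated-learning neural network realizing the unified map Psi.

A single feed-forward network takes one observed state ``X(t_m)`` (n inputs)
and emits the whole delay vector ``Z(t_m)`` (L outputs); output row i realizes
the component map ``Psi_i`` with ``Psi_i(X(t_j)) = x_k(t_{i+j-1})``.  Training
is *anticipated*: label columns include cells whose values lie in the future.
Those cells carry no data term, but every anti-diagonal of the output matrix
is tied together by the consistency constraint
``Psi_i(X(t_j)) = Psi_{i-1}(X(t_{j+1}))``, so the unknown future values are
resolved jointly from the network's smoothness and the observed cells.

Four mechanisms drive the training:

* **Input dropout** — each epoch drops every input variable with probability
  p, so the epoch trains one sampled nondelay attractor (a random variable
  subset); across epochs the network averages over many such subsets.
* **Two-phase training** — a pairwise phase fits the known Hankel cells by
  masked mean squared error, then a consistent phase adds the quadratic
  consistency penalty (weight lambda) over all anti-diagonals, including the
  anticipated region past ``t_M``.
* **Anticipation rehearsal** — the newest few anti-diagonals are held out of
  the training labels; after the two phases, each delay row's error on those
  cells measures its genuine one-column extrapolation reliability.  Short
  rows extrapolate well; long-horizon rows, which memorize their few labeled
  cells, do not — and the inverse-square of this rehearsal error provides the
  fusion weights.
* **Predict-then-feed-back** — the per-step estimates on an anti-diagonal are
  fused by a weighted sum; the fused value is inserted into the label matrix
  as a known cell and a short consistent refinement runs before the next
  step, extending every row's labeled support column by column.

Everything is plain numpy: full-batch gradients (M is small by assumption),
hand-written backpropagation, Adam updates.  All randomness derives from the
single integer seed in :class:`ALMConfig`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np

from .embedding import (
    MultivariateSeries,
    NormalizationStats,
    TrainingSet,
    build_delay_matrix,
    make_training_set,
    normalize_series,
)

__all__ = [
    "ALMConfig",
    "ALMNetwork",
    "StepEstimates",
    "PredictionResult",
    "EnsembleResult",
    "TrainingDivergenceError",
    "init_network",
    "pairwise_phase",
    "consistent_phase",
    "consistency_residual",
    "collect_step_estimates",
    "fuse_estimates",
    "predict_multistep",
    "train_alm",
    "fit_predict",
    "ensemble_predict",
]

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, phase: str, epoch: int, seed: int):
        self.phase, self.epoch, self.seed = phase, epoch, seed
        super().__init__(
            f"training diverged (non-finite loss) in phase {phase!r} at epoch {epoch}, seed {seed}"
        )


@dataclass
class ALMConfig:
    """Hyperparameters of the anticipated-learning machine.

    L
        delay length; one trained network can anticipate up to L-1 steps.
    horizon
        steps to predict (must be <= L-1).
    dropout_p
        probability of dropping each input variable per epoch; realizes the
        random sampling of variable subsets.
    hidden_sizes
        widths of the hidden tanh layers; None selects ``(max(64, 2n),) * 2``
        at init time; ``()`` gives a direct linear map.
    consistency_weight
        lambda, the weight of the squared consistency penalty.
    fusion_mode
        'error_weighted' (weights proportional to the inverse squared per-row
        anticipation-rehearsal error, see ``rehearsal_diagonals``) or
        'uniform' (arithmetic mean).
    rehearsal_diagonals
        number of newest anti-diagonals held out during the two training
        phases to measure each delay row's genuine extrapolation error
        ("anticipation rehearsal"); those cells rejoin the labels in a final
        refit of ``refit_epochs`` epochs.
    refine_epochs
        consistent-refinement epochs after inserting each predicted value;
        None selects ``epochs_consistent // horizon``.
    """

    L: int
    horizon: int = 1
    dropout_p: float = 0.5
    hidden_sizes: tuple[int, ...] | None = None
    epochs_pairwise: int = 2000
    epochs_consistent: int = 2000
    learning_rate: float = 1e-3
    consistency_weight: float = 1.0
    fusion_mode: str = "error_weighted"
    rehearsal_diagonals: int = 3
    refit_epochs: int = 500
    ensemble_size: int = 1
    seed: int = 0
    refine_epochs: int | None = None
    early_stop_window: int = 200
    early_stop_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("L must be at least 2")
        if self.horizon < 1:
            raise ValueError("horizon must be at least 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.hidden_sizes is not None:
            self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
            if any(h < 1 for h in self.hidden_sizes):
                raise ValueError("hidden layer widths must be positive")
        if self.epochs_pairwise < 1 or self.epochs_consistent < 1:
            raise ValueError("epoch counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.consistency_weight < 0:
            raise ValueError("consistency_weight must be nonnegative")
        if self.fusion_mode not in ("uniform", "error_weighted"):
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")
        if self.rehearsal_diagonals < 0:
            raise ValueError("rehearsal_diagonals must be nonnegative")
        if self.refit_epochs < 0:
            raise ValueError("refit_epochs must be nonnegative")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be at least 1")

    def resolved_hidden(self, n: int) -> tuple[int, ...]:
        if self.hidden_sizes is not None:
            return self.hidden_sizes
        w = max(64, 2 * n)
        return (w, w)


class ALMNetwork:
    """Feed-forward realization of Psi: n inputs -> tanh hidden layers ->
    linear output of width L.  Deterministic at inference (dropout off)."""

    def __init__(self, n_inputs: int, config: ALMConfig,
                 weights: list[np.ndarray], biases: list[np.ndarray]):
        self.n_inputs = n_inputs
        self.config = config
        self.weights = weights
        self.biases = biases
        self.stats: NormalizationStats | None = None
        self.target_index: int | None = None
        self.training_log: list[dict] = []
        self.row_rmse: np.ndarray | None = None

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        """Map a (batch, n) input block to (batch, L) outputs, dropout off."""
        a = np.asarray(X, dtype=float)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ W + b)
        return a @ self.weights[-1] + self.biases[-1]

    def _forward_cache(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [np.asarray(X, dtype=float)]
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            acts.append(np.tanh(acts[-1] @ W + b))
        acts.append(acts[-1] @ self.weights[-1] + self.biases[-1])
        return acts

    def _backward(self, acts: list[np.ndarray], grad_out: np.ndarray):
        """Gradients of a scalar loss wrt all parameters, given dLoss/dY."""
        gW = [np.empty(0)] * len(self.weights)
        gb = [np.empty(0)] * len(self.biases)
        delta = grad_out
        for layer in range(len(self.weights) - 1, -1, -1):
            gW[layer] = acts[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (1.0 - acts[layer] ** 2)
        return gW, gb

    def parameter_checksum(self) -> float:
        return float(sum(np.abs(W).sum() for W in self.weights)
                     + sum(np.abs(b).sum() for b in self.biases))

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        """Self-describing JSON archive: parameters, config, normalization
        statistics and the training log, version-tagged."""
        obj = {
            "format": "alm-model",
            "version": 1,
            "n_inputs": self.n_inputs,
            "config": asdict(self.config),
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "target_index": self.target_index,
            "row_rmse": None if self.row_rmse is None else self.row_rmse.tolist(),
            "stats": None if self.stats is None else {
                "mean": self.stats.mean.tolist(),
                "scale": self.stats.scale.tolist(),
                "zero_variance": self.stats.zero_variance.tolist(),
            },
            "training_log": self.training_log,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)

    @classmethod
    def load(cls, path) -> "ALMNetwork":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        if obj.get("format") != "alm-model":
            raise ValueError(f"{path}: not an alm model archive")
        cfg_d = obj["config"]
        if cfg_d.get("hidden_sizes") is not None:
            cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
        net = cls(
            obj["n_inputs"],
            ALMConfig(**cfg_d),
            [np.asarray(W) for W in obj["weights"]],
            [np.asarray(b) for b in obj["biases"]],
        )
        net.target_index = obj["target_index"]
        if obj["row_rmse"] is not None:
            net.row_rmse = np.asarray(obj["row_rmse"])
        if obj["stats"] is not None:
            net.stats = NormalizationStats(
                mean=np.asarray(obj["stats"]["mean"]),
                scale=np.asarray(obj["stats"]["scale"]),
                zero_variance=np.asarray(obj["stats"]["zero_variance"], dtype=bool),
            )
        net.training_log = obj["training_log"]
        return net


@dataclass
class StepEstimates:
    """All anti-diagonal estimates of the target at one future time t_{M+h}.

    ``entries`` holds (delay row i, source column j, value) with 1-based
    indices satisfying i + j - 1 = M + h; values are on the original scale.
    """

    step: int
    time_index: int
    entries: list[tuple[int, int, float]]
    fused: float | None = None
    weights: np.ndarray | None = None


@dataclass
class PredictionResult:
    """Fused multistep predictions (original scale) with their per-step
    estimate families."""

    values: np.ndarray
    step_estimates: list[StepEstimates]
    target_index: int
    times: np.ndarray


@dataclass
class EnsembleResult:
    """Per-step mean/sd over k independently initialized+trained networks."""

    mean: np.ndarray
    sd: np.ndarray
    trajectories: np.ndarray  # (k, H), sorted by seed offset
    seeds: list[int]
    times: np.ndarray
    target_index: int


# ---------------------------------------------------------------------------
# Construction and training
# ---------------------------------------------------------------------------

def init_network(n: int, config: ALMConfig) -> ALMNetwork:
    """Glorot-initialized network, deterministic in config.seed."""
    if n < 1:
        raise ValueError("need at least one input variable")
    rng = np.random.default_rng([config.seed, 0])
    sizes = [n, *config.resolved_hidden(n), config.L]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return ALMNetwork(n, config, weights, biases)


def _train(
    net: ALMNetwork,
    inputs: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    *,
    lam: float,
    epochs: int,
    rng: np.random.Generator,
    phase: str,
) -> None:
    """Full-batch Adam on masked MSE + lambda * consistency penalty.

    ``inputs`` is (M, n) on the normalized scale, ``labels``/``mask`` the
    L x M Hankel matrix.  One fresh dropout mask per epoch (one sampled
    variable subset per epoch); inverted-dropout scaling keeps inference
    consistent.  Early stopping watches an exponentially smoothed loss (the
    raw per-epoch loss is noisy across dropout masks) and breaks once the
    smoothed loss stops improving relatively by early_stop_tol for
    early_stop_window consecutive epochs.
    """
    cfg = net.config
    M, n = inputs.shape
    L = labels.shape[0]
    labels0 = np.where(mask, labels, 0.0)
    n_known = int(mask.sum())
    if n_known == 0:
        raise ValueError("training labels contain no known cells")
    p = cfg.dropout_p
    adam_m = [np.zeros_like(W) for W in net.weights] + [np.zeros_like(b) for b in net.biases]
    adam_v = [np.zeros_like(x) for x in adam_m]
    best = np.inf
    stall = 0
    ema = None
    ema_alpha = 0.05
    for epoch in range(epochs):
        if p > 0.0:
            keep = rng.random(n) >= p
            if not keep.any():
                keep[rng.integers(n)] = True
            X = inputs * (keep / (1.0 - p))
        else:
            X = inputs
        acts = net._forward_cache(X)
        Y = acts[-1]  # (M, L)
        E = (Y.T - labels0) * mask
        loss_data = float((E ** 2).sum() / n_known)
        G = (2.0 / n_known) * E.T
        loss_cons = 0.0
        if lam > 0.0 and L >= 2 and M >= 2:
            D = Y[:-1, 1:] - Y[1:, :-1]
            loss_cons = float((D ** 2).mean())
            G = G.copy()
            G[:-1, 1:] += (2.0 * lam / D.size) * D
            G[1:, :-1] -= (2.0 * lam / D.size) * D
        loss = loss_data + lam * loss_cons
        if not np.isfinite(loss):
            raise TrainingDivergenceError(phase, epoch, cfg.seed)
        net.training_log.append(
            {"phase": phase, "epoch": epoch, "loss": loss,
             "data": loss_data, "consistency": loss_cons}
        )
        gW, gb = net._backward(acts, G)
        grads = gW + gb
        params = net.weights + net.biases
        t = epoch + 1
        for i, (prm, g) in enumerate(zip(params, grads)):
            adam_m[i] = _ADAM_B1 * adam_m[i] + (1 - _ADAM_B1) * g
            adam_v[i] = _ADAM_B2 * adam_v[i] + (1 - _ADAM_B2) * g * g
            mhat = adam_m[i] / (1 - _ADAM_B1 ** t)
            vhat = adam_v[i] / (1 - _ADAM_B2 ** t)
            prm -= cfg.learning_rate * mhat / (np.sqrt(vhat) + _ADAM_EPS)
        ema = loss if ema is None else (1 - ema_alpha) * ema + ema_alpha * loss
        if not np.isfinite(best) or best - ema > cfg.early_stop_tol * max(best, 1e-30):
            best, stall = ema, 0
        else:
            stall += 1
            if stall >= cfg.early_stop_window:
                break


def _update_row_errors(net: ALMNetwork, inputs: np.ndarray,
                       labels: np.ndarray, mask: np.ndarray) -> None:
    """Final per-row training RMSE on known cells (feeds error-weighted fusion)."""
    Y = net.forward(inputs).T  # (L, M)
    err2 = np.where(mask, (Y - np.where(mask, labels, 0.0)) ** 2, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # rows with no cells
        net.row_rmse = np.sqrt(np.nanmean(err2, axis=1))


def pairwise_phase(net: ALMNetwork, train: TrainingSet, config: ALMConfig) -> ALMNetwork:
    """Phase 1: fit the known Hankel cells only (masked MSE, input dropout)."""
    rng = np.random.default_rng([config.seed, 1])
    _train(net, train.inputs, train.labels, train.label_mask,
           lam=0.0, epochs=config.epochs_pairwise, rng=rng, phase="pairwise")
    _update_row_errors(net, train.inputs, train.labels, train.label_mask)
    return net


def consistent_phase(net: ALMNetwork, train: TrainingSet, config: ALMConfig) -> ALMNetwork:
    """Phase 2: add the consistency penalty across all anti-diagonals,
    including those reaching past t_M (the anticipated region)."""
    rng = np.random.default_rng([config.seed, 2])
    _train(net, train.inputs, train.labels, train.label_mask,
           lam=config.consistency_weight, epochs=config.epochs_consistent,
           rng=rng, phase="consistent")
    _update_row_errors(net, train.inputs, train.labels, train.label_mask)
    return net


def consistency_residual(net: ALMNetwork, series: MultivariateSeries,
                         L: int | None = None) -> float:
    """RMS violation of Psi_i(X(t_j)) = Psi_{i-1}(X(t_{j+1})) over all valid
    (i, j), dropout disabled.  Zero by convention when L = 1 or M = 1."""
    L = net.config.L if L is None else L
    values = series.values
    if net.stats is not None:
        values = net.stats.transform(values)
    Y = net.forward(values.T)[:, :L]
    if L < 2 or Y.shape[0] < 2:
        return 0.0
    D = Y[:-1, 1:] - Y[1:, :-1]
    return float(np.sqrt((D ** 2).mean()))


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def collect_step_estimates(net: ALMNetwork, series: MultivariateSeries, h: int) -> StepEstimates:
    """Evaluate every Hankel cell predicting t_{M+h}: Psi_i(X(t_j)) for all
    (i, j) with i + j - 1 = M + h, 2 <= i <= L, 1 <= j <= M (1-based)."""
    L = net.config.L
    if not 1 <= h <= L - 1:
        raise ValueError(
            f"step h={h} outside the anticipation range 1..L-1 = {L - 1}; enlarge L"
        )
    M = series.M
    values = series.values
    if net.stats is not None:
        values = net.stats.transform(values)
    Y = net.forward(values.T)  # (M, L)
    k = net.target_index
    entries = []
    for i in range(h + 1, min(L, M + h) + 1):  # 1-based delay row
        j = M + h + 1 - i
        v = float(Y[j - 1, i - 1])
        if net.stats is not None and k is not None:
            v = float(net.stats.inverse_target(k, v))
        entries.append((i, j, v))
    return StepEstimates(step=h, time_index=M + h, entries=entries)


def fuse_estimates(est: StepEstimates, mode: str = "uniform",
                   row_errors: np.ndarray | None = None) -> float:
    """Weighted sum of one step's estimates; weights sum to 1.

    'uniform' is the arithmetic mean; 'error_weighted' weights each estimate
    by the inverse *squared* per-row error (the anticipation-rehearsal error
    stored on the network after training).  Long-horizon delay rows fit their
    few labeled cells almost perfectly, so raw training error carries no
    reliability signal; the rehearsal error — each row's error extrapolating
    to held-out newest anti-diagonals — does, and squaring sharpens the
    contrast so a handful of unreliable rows cannot swamp the reliable ones.
    """
    if not est.entries:
        raise ValueError("cannot fuse an empty estimate set")
    vals = np.array([v for (_, _, v) in est.entries])
    if mode == "uniform":
        w = np.full(len(vals), 1.0 / len(vals))
    elif mode == "error_weighted":
        if row_errors is None:
            raise ValueError("error_weighted fusion needs per-row error estimates")
        inv = np.array([1.0 / (row_errors[i - 1] ** 2 + 1e-9) for (i, _, _) in est.entries])
        w = inv / inv.sum()
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")
    est.fused = float(w @ vals)
    est.weights = w
    return est.fused


def predict_multistep(net: ALMNetwork, series: MultivariateSeries,
                      config: ALMConfig | None = None) -> PredictionResult:
    """Sequential anticipated prediction of H future values.

    For h = 1..H: collect the anti-diagonal estimates of t_{M+h}, fuse them,
    insert the fused value into the Hankel label matrix as a known cell, and
    run a short consistent-training refinement (warm-started) before moving
    to h+1.  Predictions are returned on the original scale.
    """
    cfg = net.config if config is None else config
    L, H = cfg.L, cfg.horizon
    if H > L - 1:
        raise ValueError(
            f"horizon {H} exceeds the single-cycle anticipation range L-1={L - 1}; enlarge L"
        )
    if net.target_index is None or net.stats is None:
        raise ValueError("network is not bound to a series (train with train_alm first)")
    k = net.target_index
    stats = net.stats
    M = series.M
    Xn = stats.transform(series.values).T
    normed = MultivariateSeries(stats.transform(series.values), list(series.variable_names),
                                tau=series.tau, start_time=series.start_time)
    delay = build_delay_matrix(normed, k, L)
    Z = np.where(delay.known_mask, delay.matrix, 0.0)
    mask = delay.known_mask.copy()
    refine = cfg.refine_epochs if cfg.refine_epochs is not None else cfg.epochs_consistent // H
    rng = np.random.default_rng([cfg.seed, 3])
    steps: list[StepEstimates] = []
    preds = np.empty(H)
    for h in range(1, H + 1):
        est = collect_step_estimates(net, series, h)
        fused = fuse_estimates(est, cfg.fusion_mode, net.row_rmse)
        steps.append(est)
        preds[h - 1] = fused
        fused_n = (fused - stats.mean[k]) / stats.scale[k]
        for i0 in range(h, min(L, M + h)):  # 0-based rows on the anti-diagonal
            j0 = M + h - 1 - i0
            Z[i0, j0] = fused_n
            mask[i0, j0] = True
        if refine > 0 and h < H:
            # row_rmse (the fusion weights) is intentionally left untouched:
            # the rehearsal errors keep ranking row reliability.
            _train(net, Xn, Z, mask, lam=cfg.consistency_weight,
                   epochs=refine, rng=rng, phase=f"refine_{h}")
    if not np.all(np.isfinite(preds)):
        raise TrainingDivergenceError("predict", -1, cfg.seed)
    times = series.start_time + series.tau * (M + np.arange(1, H + 1) - 1)
    return PredictionResult(values=preds, step_estimates=steps,
                            target_index=k, times=times)


# ---------------------------------------------------------------------------
# High-level pipeline
# ---------------------------------------------------------------------------

def train_alm(series: MultivariateSeries, target: str | int, config: ALMConfig) -> ALMNetwork:
    """Normalize, build the Hankel labels, and run the training pipeline.

    The two phases (pairwise, then consistent) run with the newest
    ``rehearsal_diagonals`` anti-diagonals held out of the labels; the
    network's error on those held-out cells is measured per delay row — a
    genuine per-row extrapolation ("anticipation rehearsal") error that feeds
    error-weighted fusion — and the held-out cells then rejoin the labels for
    a short consistent refit before prediction.
    """
    k = series.variable_index(target)
    normed, stats = normalize_series(series)
    delay = build_delay_matrix(normed, k, config.L)
    train = make_training_set(normed, delay)
    net = init_network(series.n, config)
    net.stats = stats
    net.target_index = k

    M, L = series.M, config.L
    V = min(config.rehearsal_diagonals, max(M - 2, 0))
    held = None
    if V > 0:
        ad = np.add.outer(np.arange(L), np.arange(M))  # 0-based anti-diagonal index
        held = train.label_mask & (ad > M - 1 - V)
        train.label_mask = train.label_mask & (ad <= M - 1 - V)
    pairwise_phase(net, train, config)
    consistent_phase(net, train, config)
    if held is not None:
        Y = net.forward(train.inputs).T
        err2 = np.where(held, (Y - np.where(held, train.labels, 0.0)) ** 2, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # rows with no cells
            rehearsal = np.sqrt(np.nanmean(err2, axis=1))
        worst = np.nanmax(rehearsal) if np.any(np.isfinite(rehearsal)) else 1.0
        net.row_rmse = np.where(np.isfinite(rehearsal), rehearsal, worst)
        train.label_mask = train.label_mask | held
        if config.refit_epochs > 0:
            _train(net, train.inputs, train.labels, train.label_mask,
                   lam=config.consistency_weight, epochs=config.refit_epochs,
                   rng=np.random.default_rng([config.seed, 4]), phase="refit")
    return net


def fit_predict(series: MultivariateSeries, target: str | int,
                config: ALMConfig) -> PredictionResult:
    """End-to-end: train on the full series, predict config.horizon steps."""
    net = train_alm(series, target, config)
    return predict_multistep(net, series)


def ensemble_predict(series: MultivariateSeries, target: str | int,
                     config: ALMConfig, k: int) -> EnsembleResult:
    """Train k networks from seeds seed+0..seed+k-1 through the full pipeline
    and summarize the prediction distribution per step."""
    if k < 2:
        raise ValueError("an ensemble needs k >= 2 members")
    seeds = [config.seed + i for i in range(k)]
    trajs, times, tgt = [], None, None
    for s in seeds:
        cfg = replace(config, seed=s)
        try:
            res = fit_predict(series, target, cfg)
        except TrainingDivergenceError as exc:
            raise TrainingDivergenceError(exc.phase, exc.epoch, s) from exc
        trajs.append(res.values)
        times, tgt = res.times, res.target_index
    T = np.vstack(trajs)
    return EnsembleResult(mean=T.mean(axis=0), sd=T.std(axis=0),
                          trajectories=T, seeds=seeds, times=times, target_index=tgt)
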