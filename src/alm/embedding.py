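"""Delay embedding of a target variable and sampling of nondelay attractors.

The observed multivariate series traces the *nondelay attractor*: the cloud of
state vectors ``X(t_m) = [x_1(t_m), ..., x_n(t_m)]`` for ``m = 1..M``.  The
*delay attractor* of a chosen target variable ``x_k`` is traced by the delay
coordinates ``Z(t_m) = [x_k(t_m), ..., x_k(t_{m+L-1})]``.  For delay length
``L`` exceeding twice the attractor's box-counting dimension the two attractors
are topologically conjugate, so a smooth one-to-one map Psi with
``Psi_i(X(t_j)) = x_k(t_{i+j-1})`` exists.  Stacking Psi over all observed
times yields a matrix identity between network outputs and the L x M Hankel
matrix of the target: its lower-right anti-diagonals reach past ``t_M`` and
hold the L-1 unknown future values.  This module builds that Hankel structure,
samples random variable subsets (sampled nondelay attractors), normalizes the
data and assembles training pairs; solving for Psi lives in
:mod:`alm.network`.

Time indices are 1-based in documentation, mirroring the conventional matrix
notation; arrays are 0-based.  Columns are time points, rows delay offsets.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MultivariateSeries",
    "DelayTarget",
    "IndexTuple",
    "EmbeddingParams",
    "ValidationReport",
    "TrainingSet",
    "NormalizationStats",
    "build_delay_matrix",
    "validate_embedding_params",
    "count_sampled_attractors",
    "sample_index_tuples",
    "make_training_set",
    "normalize_series",
    "read_series_csv",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MultivariateSeries:
    """An n-variable series observed at M uniformly spaced time points.

    ``values`` has shape (n, M): one row per variable, one column per time
    point.  ``tau`` is the sampling interval in the data's native time units.
    """

    values: np.ndarray
    variable_names: list[str]
    tau: float = 1.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n x M) array")
        n, M = self.values.shape
        if n < 1 or M < 2:
            raise ValueError(f"need n >= 1 and M >= 2, got n={n}, M={M}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite entries; missing values are not accepted")
        if len(self.variable_names) != n:
            raise ValueError("variable_names length must equal the number of variables")
        if len(set(self.variable_names)) != n:
            raise ValueError("variable_names must be unique")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.tau * np.arange(self.M)

    def variable_index(self, name_or_index: str | int) -> int:
        """Resolve a variable given its name or 0-based integer index."""
        if isinstance(name_or_index, (int, np.integer)):
            k = int(name_or_index)
            if not 0 <= k < self.n:
                raise IndexError(f"variable index {k} out of range [0, {self.n})")
            return k
        try:
            return self.variable_names.index(str(name_or_index))
        except ValueError:
            raise KeyError(f"unknown variable {name_or_index!r}") from None

    def window(self, start: int, stop: int) -> "MultivariateSeries":
        """Contiguous time slice [start, stop) as a new series."""
        if not (0 <= start < stop <= self.M):
            raise IndexError(f"window [{start}, {stop}) invalid for M={self.M}")
        return MultivariateSeries(
            self.values[:, start:stop].copy(),
            list(self.variable_names),
            tau=self.tau,
            start_time=self.start_time + self.tau * start,
        )

    def to_csv(self, path) -> None:
        """Write the standard CSV dialect: header row, leading ``time`` column,
        rows = time points.  Floats use repr so a read round-trips exactly."""
        times = self.times
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["time", *self.variable_names])
            for j in range(self.M):
                w.writerow([repr(float(times[j]))] + [repr(float(v)) for v in self.values[:, j]])


def read_series_csv(path) -> MultivariateSeries:
    """Read the standard CSV dialect (see :meth:`MultivariateSeries.to_csv`).

    The first column is treated as time when named ``time``; otherwise all
    columns are variables and tau defaults to 1.  Missing cells are rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing cells are not accepted")
    tau, start = 1.0, 0.0
    if len(df.columns) and str(df.columns[0]).strip().lower() == "time":
        t = df.iloc[:, 0].to_numpy(dtype=float)
        df = df.iloc[:, 1:]
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError(f"{path}: time column must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9 * max(1.0, abs(dt[0]))):
                raise ValueError(f"{path}: non-uniform sampling interval")
            tau, start = float(dt[0]), float(t[0])
    names = [str(c) for c in df.columns]
    return MultivariateSeries(df.to_numpy(dtype=float).T, names, tau=tau, start_time=start)


@dataclass
class DelayTarget:
    """The target variable's delay attractor as an L x M Hankel matrix.

    ``matrix[i, j]`` holds ``x_k(t_{i+j+1-1})`` (0-based i, j), i.e.
    anti-diagonals are constant.  Entries beyond the observed window
    (``i + j >= M``) are the unknown future values: NaN in ``matrix`` and
    False in ``known_mask``.  There are exactly L-1 distinct unknowns,
    ``x_k(t_{M+1}) .. x_k(t_{M+L-1})``.
    """

    target_index: int
    L: int
    matrix: np.ndarray
    known_mask: np.ndarray

    @property
    def M(self) -> int:
        return self.matrix.shape[1]

    def unknown_count(self) -> int:
        """Number of distinct unknown future values (anti-diagonals past t_M)."""
        i, j = np.nonzero(~self.known_mask)
        return len(np.unique(i + j)) if len(i) else 0

    def check_hankel(self, atol: float = 0.0) -> bool:
        """True iff every pair of known entries on an anti-diagonal agrees."""
        a = self.matrix[1:, :-1]
        b = self.matrix[:-1, 1:]
        both = self.known_mask[1:, :-1] & self.known_mask[:-1, 1:]
        return bool(np.all(np.abs(a[both] - b[both]) <= atol))

    def to_csv(self, path) -> None:
        """Rows = delay offsets; unknown cells written as empty fields."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            for i in range(self.L):
                w.writerow(
                    [repr(float(self.matrix[i, j])) if self.known_mask[i, j] else ""
                     for j in range(self.M)]
                )


@dataclass(frozen=True)
class IndexTuple:
    """A sorted set of S distinct variable indices (0-based) defining one
    sampled nondelay attractor."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(idx) < 1:
            raise ValueError("an index tuple needs at least one index")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("indices must be strictly increasing")
        if idx[0] < 0:
            raise ValueError("indices must be nonnegative")

    @property
    def S(self) -> int:
        return len(self.indices)


@dataclass
class EmbeddingParams:
    """Delay length L, sample dimension S and an optional user-supplied
    estimate of the attractor's box-counting dimension."""

    L: int
    S: int
    d_est: float | None = None

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("L must be at least 2")
        if self.S < 1:
            raise ValueError("S must be at least 1")
        if self.d_est is not None and self.d_est <= 0:
            raise ValueError("d_est must be positive when provided")


@dataclass
class ValidationReport:
    """Advisory pass/fail per embedding condition, plus warnings."""

    checks: dict[str, bool] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


@dataclass
class TrainingSet:
    """M (input, label-column) pairs realizing the spatial-temporal identity.

    ``inputs`` has shape (M, k) with k = n for dropout-based sampling or k = S
    when restricted to an index tuple; ``labels``/``label_mask`` are the
    DelayTarget matrix and mask; ``pair_index`` maps sample m to time t_m.
    """

    inputs: np.ndarray
    labels: np.ndarray
    label_mask: np.ndarray
    pair_index: np.ndarray
    index_tuple: IndexTuple | None = None

    @property
    def M(self) -> int:
        return self.inputs.shape[0]


@dataclass
class NormalizationStats:
    """Per-variable location/scale from the training window (population sd);
    zero-variance variables are centered, given scale 1 and flagged."""

    mean: np.ndarray
    scale: np.ndarray
    zero_variance: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean[:, None]) / self.scale[:, None]

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return values * self.scale[:, None] + self.mean[:, None]

    def inverse_target(self, k: int, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) * self.scale[k] + self.mean[k]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_delay_matrix(series: MultivariateSeries, target_k: int, L: int) -> DelayTarget:
    """Delay-coordinate map of the target variable.

    Column m (0-based) holds ``x_k(t_{m}), ..., x_k(t_{m+L-1})``; cells that
    would require values past ``t_M`` are unknown (NaN, mask False).
    """
    k = series.variable_index(target_k)
    M = series.M
    if L < 2:
        raise ValueError(f"delay length L={L} must be at least 2")
    x = series.values[k]
    mat = np.full((L, M), np.nan)
    mask = np.zeros((L, M), dtype=bool)
    # L may exceed M (e.g. predicting as many steps as there are training
    # points): rows beyond the observed window then hold no known cells and
    # are pinned purely by the consistency constraints during training.
    for i in range(L):
        m = max(M - i, 0)  # known columns in row i
        if m:
            mat[i, :m] = x[i:]
            mask[i, :m] = True
    return DelayTarget(target_index=k, L=L, matrix=mat, known_mask=mask)


def validate_embedding_params(params: EmbeddingParams, n: int) -> ValidationReport:
    """Advisory check of the embedding conditions L > 2d and S > 2d.

    ``S > n`` is a structural violation and raises; a missing dimension
    estimate produces warnings, not failures.
    """
    if params.S > n:
        raise ValueError(f"S={params.S} exceeds the number of variables n={n}")
    rep = ValidationReport()
    rep.checks["S_le_n"] = True
    if params.d_est is None:
        rep.warnings.append(
            "no box-counting dimension estimate supplied; conditions L > 2d and S > 2d not checked"
        )
    else:
        rep.checks["L_gt_2d"] = params.L > 2 * params.d_est
        rep.checks["S_gt_2d"] = params.S > 2 * params.d_est
    return rep


def count_sampled_attractors(n: int, S: int) -> int:
    """Exact number of S-variable sampled nondelay attractors, C(n, S)."""
    if S > n:
        raise ValueError(f"S={S} exceeds n={n}")
    if S < 0 or n < 0:
        raise ValueError("n and S must be nonnegative")
    return math.comb(n, S)


def sample_index_tuples(n: int, S: int, count: int, seed: int) -> list[IndexTuple]:
    """Draw ``count`` index tuples uniformly (with replacement at tuple level).

    Each tuple is S distinct variables out of n, sorted.  Deterministic given
    the seed.
    """
    if not 1 <= S <= n:
        raise ValueError(f"need 1 <= S <= n, got S={S}, n={n}")
    if count < 1:
        raise ValueError("count must be at least 1")
    rng = np.random.default_rng(seed)
    return [
        IndexTuple(tuple(sorted(rng.choice(n, size=S, replace=False).tolist())))
        for _ in range(count)
    ]


def make_training_set(
    series: MultivariateSeries,
    delay: DelayTarget,
    index_tuple: IndexTuple | None = None,
) -> TrainingSet:
    """Pair each observed state (input) with the delay-attractor column (label).

    With ``index_tuple`` given, inputs are restricted to those variables (one
    sampled nondelay attractor); with None, inputs carry all n variables and
    the sampling over tuples is realized by input dropout during training.
    """
    if delay.M != series.M:
        raise ValueError(f"delay matrix has M={delay.M} columns but series has M={series.M}")
    if index_tuple is None:
        inputs = series.values.T.copy()
    else:
        if index_tuple.indices[-1] >= series.n:
            raise IndexError("index tuple refers to variables beyond n")
        inputs = series.values[list(index_tuple.indices), :].T.copy()
    return TrainingSet(
        inputs=inputs,
        labels=delay.matrix.copy(),
        label_mask=delay.known_mask.copy(),
        pair_index=series.times,
        index_tuple=index_tuple,
    )


def normalize_series(series: MultivariateSeries) -> tuple[MultivariateSeries, NormalizationStats]:
    """Zero-mean, unit-sd transform per variable over the training window.

    Uses the population convention (divisor M).  Zero-variance variables are
    centered, given scale 1 and flagged rather than dropped, so the input
    dimensionality stays fixed for dropout sampling.
    """
    mean = series.values.mean(axis=1)
    sd = series.values.std(axis=1)  # ddof=0
    zero = sd < 1e-12
    scale = np.where(zero, 1.0, sd)
    stats = NormalizationStats(mean=mean, scale=scale, zero_variance=zero)
    normed = MultivariateSeries(
        stats.transform(series.values),
        list(series.variable_names),
        tau=series.tau,
        start_time=series.start_time,
    )
    return normed, stats
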