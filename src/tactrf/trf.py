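"""Forward (encoding) temporal response functions by time-lagged ridge.

The TRF is the set of per-channel linear weights over stimulus-to-response
lags that best predicts the EEG from the stimulus envelope. Weights are
estimated by ridge regression on a lagged design matrix (lags -400..600 ms
at 64 Hz: 66 columns plus an unpenalized intercept), with the regularization
parameter selected by leave-one-out cross-validation over a fixed grid
(1e-6..1e8 by decades) using a majority vote of per-fold MSE minimizers.
The per-subject TRF is the unweighted average of the leave-one-out fold
models; grand averages are means across subjects within condition.

Fitting goes through cached sufficient statistics (X'X per envelope, X'y
per envelope/EEG pairing), which makes leave-one-out refits and the
permutation nulls in :mod:`tactrf.stats` cheap: each refit is one 67x67
solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envelope import TARGET_FS, TactileEnvelope
from .preprocessing import EEGSegment

#: ridge parameter the pipeline fixes across subjects and conditions
DEFAULT_LAMBDA = 1e2


@dataclass(frozen=True)
class LagWindow:
    """Integer lag range on the analysis sample grid.

    Lags run from ``floor(tmin_ms*fs/1000)`` to ``ceil(tmax_ms*fs/1000)``
    inclusive (the window never shrinks): -26..39 at 64 Hz, 66 lags.
    Positive lags mean the response follows the stimulus.
    """

    tmin_ms: float = -400.0
    tmax_ms: float = 600.0
    fs: float = TARGET_FS

    @property
    def lag_samples(self) -> np.ndarray:
        lo = int(np.floor(self.tmin_ms * self.fs / 1000.0))
        hi = int(np.ceil(self.tmax_ms * self.fs / 1000.0))
        return np.arange(lo, hi + 1)

    @property
    def lag_axis_ms(self) -> np.ndarray:
        return self.lag_samples * 1000.0 / self.fs

    @property
    def n_lags(self) -> int:
        return self.lag_samples.size

    def window_indices(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        """Indices of lags whose latency lies in [lo_ms, hi_ms]."""
        axis = self.lag_axis_ms
        return np.flatnonzero((axis >= lo_ms - 1e-9) & (axis <= hi_ms + 1e-9))


def default_ridge_grid() -> np.ndarray:
    """Decade grid 1e-6 .. 1e8 (15 values)."""
    return 10.0 ** np.arange(-6, 9, dtype=float)


@dataclass
class TRFModel:
    """Per-channel weight vectors over lags, plus the ridge parameter."""

    weights: np.ndarray            # (n_channels, n_lags), z-units per envelope unit
    intercept: np.ndarray          # (n_channels,)
    lam: float
    lag_axis_ms: np.ndarray
    subject: int | str = 0
    condition: str = ""
    n_folds_averaged: int = 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.intercept = np.asarray(self.intercept, dtype=float)
        self.lag_axis_ms = np.asarray(self.lag_axis_ms, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("TRF weights must be finite")
        if self.weights.shape[1] != self.lag_axis_ms.size:
            raise ValueError("weights/lag axis mismatch")


@dataclass
class CVResult:
    """Leave-one-out MSE table and the majority-vote ridge selection."""

    mse: np.ndarray                # (n_folds, n_lambdas, n_channels)
    lambdas: np.ndarray
    selected_lambda: float
    fold_winners: np.ndarray       # per-fold argmin lambda values


def build_lagged_design(
    envelope: TactileEnvelope | np.ndarray, lags: LagWindow
) -> np.ndarray:
    """Time x (lags + intercept) design matrix with zero padding.

    Column ``j`` holds the envelope delayed by ``lag_samples[j]``:
    ``X[t, j] = env[t - lag_j]`` (zero outside the segment), so positive
    lags place the stimulus before the response. The last column is the
    constant intercept term.
    """
    values = envelope.values if isinstance(envelope, TactileEnvelope) else np.asarray(envelope, float)
    n = values.size
    lag_samples = lags.lag_samples
    if n <= lag_samples.max() - lag_samples.min():
        raise ValueError(f"envelope ({n} samples) shorter than the lag span")
    X = np.zeros((n, lag_samples.size + 1))
    for j, lag in enumerate(lag_samples):
        if lag >= 0:
            X[lag:, j] = values[: n - lag] if lag else values
        else:
            X[: n + lag, j] = values[-lag:]
    X[:, -1] = 1.0
    return X


def fit_ridge(
    design: np.ndarray, response: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the penalized normal equations, intercept unpenalized.

    Minimizes ``||X w - y||^2 + lam ||w_-intercept||^2`` per channel, i.e.
    solves ``(X'X + lam P) w = X'y`` with ``P`` the identity zeroed at the
    intercept (last) column.

    Returns
    -------
    weights : (n_channels, n_lags)
    intercept : (n_channels,)
    """
    X = np.asarray(design, float)
    Y = np.atleast_2d(np.asarray(response, float).T).T  # (time, channels)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in design or response")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    xtx = X.T @ X
    xty = X.T @ Y
    return _solve_ridge(xtx, xty, lam)


def _solve_ridge(xtx: np.ndarray, xty: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Ridge solve from sufficient statistics X'X and X'y."""
    penalty = np.eye(xtx.shape[0]) * lam
    penalty[-1, -1] = 0.0  # intercept column is never shrunk
    try:
        coef = np.linalg.solve(xtx + penalty, xty)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular system at lambda={lam}; use lambda > 0"
        ) from err
    return coef[:-1].T, coef[-1]


def predict_response(model: TRFModel, envelope: TactileEnvelope, lags: LagWindow) -> np.ndarray:
    """Predicted EEG (time x channels) = lagged design @ weights + intercept."""
    X = build_lagged_design(envelope, lags)
    if X.shape[1] - 1 != model.weights.shape[1]:
        raise ValueError("lag window does not match model weights")
    return X[:, :-1] @ model.weights.T + model.intercept


def mse(predicted: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Per-channel mean squared error between time x channel arrays."""
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape:
        raise ValueError(f"shape mismatch {predicted.shape} vs {observed.shape}")
    return np.mean((predicted - observed) ** 2, axis=0)


# ---------------------------------------------------------------------------
# sufficient statistics for fast leave-one-out / permutation refits

class LaggedStats:
    """Cached X'X and X'y over a set of (envelope, EEG segment) pairings.

    ``xtx[i]`` depends only on envelope ``i``; ``xty(i, j)`` pairs envelope
    ``i`` with EEG segment ``j`` and is computed lazily and memoized, which
    is what makes the mismatched-pairing permutation null affordable.
    """

    def __init__(self, envelopes: list[TactileEnvelope], eeg: list[np.ndarray],
                 lags: LagWindow):
        if len(envelopes) != len(eeg):
            raise ValueError("need one EEG segment per envelope")
        self.lags = lags
        self._designs = [build_lagged_design(env, lags) for env in envelopes]
        self.eeg = [np.asarray(e, float) for e in eeg]  # (channels, time) each
        self.xtx = [X.T @ X for X in self._designs]
        self._xty_cache: dict[tuple[int, int], np.ndarray] = {}

    @property
    def n(self) -> int:
        return len(self._designs)

    def xty(self, env_i: int, eeg_j: int) -> np.ndarray:
        key = (env_i, eeg_j)
        if key not in self._xty_cache:
            self._xty_cache[key] = self._designs[env_i].T @ self.eeg[eeg_j].T
        return self._xty_cache[key]

    def fit(self, pairs: list[tuple[int, int]], lam: float) -> tuple[np.ndarray, np.ndarray]:
        """Ridge fit pooling the given (envelope, eeg) pairings."""
        xtx = sum(self.xtx[i] for i, _ in pairs)
        xty = sum(self.xty(i, j) for i, j in pairs)
        return _solve_ridge(xtx, xty, lam)

    def loo_average(self, pairs: list[tuple[int, int]], lam: float
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Average of leave-one-out fold models over the given pairings."""
        xtx_all = sum(self.xtx[i] for i, _ in pairs)
        xty_all = sum(self.xty(i, j) for i, j in pairs)
        w_sum = None
        b_sum = None
        for i, j in pairs:
            w, b = _solve_ridge(xtx_all - self.xtx[i], xty_all - self.xty(i, j), lam)
            w_sum = w if w_sum is None else w_sum + w
            b_sum = b if b_sum is None else b_sum + b
        return w_sum / len(pairs), b_sum / len(pairs)


def _as_arrays(segments: list[tuple[TactileEnvelope, EEGSegment]]
               ) -> tuple[list[TactileEnvelope], list[np.ndarray]]:
    envs = [env for env, _ in segments]
    eeg = [seg.data if isinstance(seg, EEGSegment) else np.asarray(seg) for _, seg in segments]
    return envs, eeg


def crossval(
    segments: list[tuple[TactileEnvelope, EEGSegment]],
    grid: np.ndarray | None = None,
    lags: LagWindow | None = None,
) -> CVResult:
    """Leave-one-out CV over the ridge grid.

    For each held-out segment, models are fit on the remaining segments at
    every grid value and the held-out per-channel MSE recorded. The selected
    lambda is the one with the lowest channel-mean MSE on the majority of
    folds (ties toward the smaller value).
    """
    if len(segments) < 2:
        raise ValueError("cross-validation needs at least 2 segments")
    grid = default_ridge_grid() if grid is None else np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0) or np.any(grid <= 0):
        raise ValueError("ridge grid must be strictly increasing and positive")
    lags = LagWindow() if lags is None else lags
    envs, eeg = _as_arrays(segments)
    stats = LaggedStats(envs, eeg, lags)
    n = stats.n
    n_channels = eeg[0].shape[0]
    table = np.empty((n, grid.size, n_channels))
    xtx_all = sum(stats.xtx)
    xty_all = sum(stats.xty(i, i) for i in range(n))
    for f in range(n):
        X_test = build_lagged_design(envs[f], lags)
        y_test = eeg[f].T
        xtx_train = xtx_all - stats.xtx[f]
        xty_train = xty_all - stats.xty(f, f)
        for g, lam in enumerate(grid):
            w, b = _solve_ridge(xtx_train, xty_train, lam)
            pred = X_test[:, :-1] @ w.T + b
            table[f, g] = mse(pred, y_test)
    selected, winners = select_lambda_from_table(table, grid)
    return CVResult(mse=table, lambdas=grid, selected_lambda=selected, fold_winners=winners)


def select_lambda_from_table(table: np.ndarray, grid: np.ndarray) -> tuple[float, np.ndarray]:
    """Majority vote over per-fold MSE minimizers; ties toward smaller lambda."""
    fold_mean = table.mean(axis=2)                # (folds, lambdas)
    winner_idx = np.argmin(fold_mean, axis=1)     # argmin takes the first (smallest) on ties
    counts = np.bincount(winner_idx, minlength=grid.size)
    best = int(np.flatnonzero(counts == counts.max())[0])
    return float(grid[best]), grid[winner_idx]


def select_lambda(cv: CVResult) -> float:
    """The grid value winning the most leave-one-out folds."""
    selected, _ = select_lambda_from_table(cv.mse, cv.lambdas)
    return selected


def fit_subject_trf(
    segments: list[tuple[TactileEnvelope, EEGSegment]],
    lam: float = DEFAULT_LAMBDA,
    lags: LagWindow | None = None,
    subject: int | str = 0,
    condition: str = "",
) -> TRFModel:
    """Subject TRF: unweighted mean of the leave-one-out fold models.

    Each fold model is fit on all-but-one segment at the fixed ridge
    parameter (the pipeline default is 1e2, shared across subjects and
    conditions); the subject model averages the fold weights and intercepts.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments")
    lags = LagWindow() if lags is None else lags
    envs, eeg = _as_arrays(segments)
    stats = LaggedStats(envs, eeg, lags)
    pairs = [(i, i) for i in range(stats.n)]
    weights, intercept = stats.loo_average(pairs, lam)
    return TRFModel(
        weights=weights, intercept=intercept, lam=lam,
        lag_axis_ms=lags.lag_axis_ms, subject=subject, condition=condition,
        n_folds_averaged=len(segments),
    )


def grand_average_trf(models: list[TRFModel]) -> TRFModel:
    """Element-wise mean of subject TRFs within one condition."""
    if not models:
        raise ValueError("no models to average")
    condition = models[0].condition
    lag_axis = models[0].lag_axis_ms
    for m in models:
        if m.condition != condition:
            raise ValueError(f"mixed conditions: {m.condition!r} vs {condition!r}")
        if m.lag_axis_ms.shape != lag_axis.shape or not np.allclose(m.lag_axis_ms, lag_axis):
            raise ValueError("mixed lag windows")
    return TRFModel(
        weights=np.mean([m.weights for m in models], axis=0),
        intercept=np.mean([m.intercept for m in models], axis=0),
        lam=models[0].lam,
        lag_axis_ms=lag_axis,
        subject="grand",
        condition=condition,
        n_folds_averaged=len(models),
    )
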