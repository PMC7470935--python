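"""Kernel convolution and kernel regression decoders.

Two linear decoders with ridge (L2) regularization, both solved through the
dual (Gram-matrix) form familiar from kernel ridge regression, which is the
efficient route when lagged MEG features outnumber observations:

* convolution decoder -- reconstructs each time-varying stimulus feature
  ``f`` (a spectrogram band, the envelope, a phoneme row) at frame ``t``
  from the response at lags ``t + lag_min .. t + lag_max``:
  ``s_f(t) = sum_x sum_tau g_f(tau, x) r(t + tau, x)``;
* regression decoder -- reconstructs each static feature (FFT bin, MPS cell,
  semantic entry) from the response in a fixed post-stimulus time window:
  ``s_f = sum_x sum_t w_f(t, x) r(t, x)``.

Each feature is decoded independently with its own regularization strength
selected on a grid by closed-form leave-one-out error within the training
data; for the convolution decoder the leave-one-out unit is one stimulus
(all of its frames), respecting within-item dependence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import OutOfEpochError
from .neural import EvokedResponse

logger = logging.getLogger(__name__)

FRAME_STEP_MS = 10
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 6, 10))
_COND_WARN = 1e12
_JITTER = 1e-10


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LagWindow:
    """Inclusive lag range (ms) from stimulus frame to MEG response.

    Lags enumerate ``lag_min, lag_min + step, ..., lag_max``; the sweep
    windows (20-100, 100-180, ...) therefore share one boundary lag. The
    backward control window (-80, 0) is permitted.
    """

    lag_min: int
    lag_max: int
    step: int = FRAME_STEP_MS

    def __post_init__(self):
        if self.lag_min > self.lag_max:
            raise ValueError("lag_min must be <= lag_max")
        if (self.lag_max - self.lag_min) % self.step:
            raise ValueError("lag range must be a multiple of step")

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.lag_min, self.lag_max + 1, self.step)

    def __str__(self):
        return f"{self.lag_min}-{self.lag_max}ms"


@dataclass(frozen=True)
class TimeWindow:
    """Half-open response window [start, end) ms relative to stimulus onset."""

    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end <= 1000):
            raise ValueError("require 0 <= start < end <= 1000 ms")

    def __str__(self):
        return f"{self.start}-{self.end}ms"


# ---------------------------------------------------------------------------
# feature standardization
# ---------------------------------------------------------------------------

_ZERO_SD_TOL = 1e-15


class FeatureScaler:
    """Per-axis z-scoring of stimulus features across items.

    Static vectors (FFT, MPS, semantic) are standardized per entry; the MPS
    entry grid is (band, scale, rate) so this is per rate, scale and band.
    Time-varying matrices (spectrogram, envelope) are standardized per band,
    pooling all frames of that band across items. Categorical features
    (phoneme tracks) pass through unchanged.
    """

    def __init__(self, kind: str = "static", categorical: bool = False):
        if kind not in ("static", "time_varying"):
            raise ValueError(f"unknown kind {kind!r}")
        self.kind = kind
        self.categorical = categorical
        self.mean_ = None
        self.scale_ = None

    def fit(self, features) -> "FeatureScaler":
        if self.categorical:
            return self
        if self.kind == "static":
            X = np.stack([np.asarray(f, dtype=float) for f in features])
            if X.shape[0] < 2:
                raise ValueError("need >= 2 items")
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
        else:
            pooled = np.concatenate(
                [np.asarray(f, dtype=float) for f in features], axis=1)
            self.mean_ = pooled.mean(axis=1)
            sd = pooled.std(axis=1)
        n_zero = int((sd <= _ZERO_SD_TOL).sum())
        if n_zero:
            logger.warning("%d zero-variance feature(s) set to 0", n_zero)
        self.scale_ = np.where(sd <= _ZERO_SD_TOL, 1.0, sd)
        return self

    def transform(self, f):
        f = np.asarray(f, dtype=float)
        if self.categorical:
            return f
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        if self.kind == "static":
            return (f - self.mean_) / self.scale_
        return (f - self.mean_[:, None]) / self.scale_[:, None]

    def fit_transform(self, features):
        self.fit(features)
        return [self.transform(f) for f in features]


def standardize_features(features, kind: str = "static",
                         categorical: bool = False):
    """Fit a :class:`FeatureScaler` and transform; returns
    ``(standardized, scaler)``. Categorical inputs pass through bit-identical.
    """
    scaler = FeatureScaler(kind, categorical)
    return scaler.fit_transform(features), scaler


# ---------------------------------------------------------------------------
# lagged design
# ---------------------------------------------------------------------------

@dataclass
class LaggedDesign:
    """Design matrix for the convolution decoder.

    One row per (item, stimulus frame); one column per (channel, lag),
    channel-major. ``row_items`` maps each row to its item index.
    """

    matrix: np.ndarray
    row_items: np.ndarray
    n_channels: int
    lags: np.ndarray

    @property
    def item_row_groups(self):
        return [np.flatnonzero(self.row_items == i)
                for i in np.unique(self.row_items)]


def _lagged_rows(e: EvokedResponse, n_frames: int,
                 lags: np.ndarray) -> np.ndarray:
    """(n_frames, channels * lags) lagged copy of one response."""
    t0 = e.times[0]
    step = e.step_ms
    frame_times = FRAME_STEP_MS * np.arange(n_frames)
    idx_f = (frame_times[:, None] + lags[None, :] - t0) / step
    idx = np.rint(idx_f).astype(int)
    if np.max(np.abs(idx_f - idx)) > 1e-6:
        raise OutOfEpochError(
            f"item {e.item_id!r}: lags do not align with the "
            f"{step}-ms response grid")
    if idx.min() < 0 or idx.max() >= e.times.size:
        bad = np.argwhere((idx < 0) | (idx >= e.times.size))[0]
        raise OutOfEpochError(
            f"item {e.item_id!r}: frame {bad[0]} with lag "
            f"{lags[bad[1]]} ms falls outside the epoch")
    # (C, T, L) -> (T, C, L) -> (T, C*L): channel-major columns
    arr = e.values[:, idx]
    return arr.transpose(1, 0, 2).reshape(n_frames, -1)


def build_lagged_design(responses, n_frames_per_item,
                        lw: LagWindow) -> LaggedDesign:
    """Stack lagged response copies for all items into one design matrix."""
    lags = lw.lags
    blocks, row_items = [], []
    for i, (e, T) in enumerate(zip(responses, n_frames_per_item)):
        blocks.append(_lagged_rows(e, int(T), lags))
        row_items.append(np.full(int(T), i))
    return LaggedDesign(np.vstack(blocks), np.concatenate(row_items),
                        responses[0].n_channels, lags)


# ---------------------------------------------------------------------------
# ridge machinery
# ---------------------------------------------------------------------------

def kernel_ridge_solve(R: np.ndarray, S: np.ndarray, lam: float):
    """Dual-form ridge: ``alpha = (R R^T + lam I)^{-1} S``, weights
    ``R^T alpha``. Returns ``(alpha, weights)``.

    Ill-conditioned Gram matrices (condition number above 1e12, checked for
    systems up to 512 rows) get a warning and a trace-scaled jitter.
    """
    R = np.asarray(R, dtype=float)
    S = np.asarray(S, dtype=float)
    if lam <= 0:
        raise ValueError("lam must be positive")
    if R.ndim != 2 or R.shape[0] < 1:
        raise ValueError("R must have >= 1 row")
    if not (np.all(np.isfinite(R)) and np.all(np.isfinite(S))):
        raise ValueError("non-finite entries in R or S")
    K = R @ R.T + lam * np.eye(R.shape[0])
    if R.shape[0] <= 512:
        cond = np.linalg.cond(K)
        if cond > _COND_WARN:
            logger.warning("Gram matrix condition number %.2e; adding "
                           "jitter", cond)
            K = K + (_JITTER * np.trace(K) / K.shape[0]) * np.eye(K.shape[0])
    alpha = scipy.linalg.solve(K, S, assume_a="pos")
    return alpha, R.T @ alpha


class RidgeSystem:
    """SVD-factored ridge solver shared across a regularization grid.

    Factoring the design once makes per-lambda weights, dual coefficients,
    fitted values and closed-form leave-one-out (single rows or whole-item
    row blocks) cheap to evaluate for every grid value.
    """

    def __init__(self, R: np.ndarray):
        R = np.asarray(R, dtype=float)
        if not np.all(np.isfinite(R)):
            raise ValueError("non-finite entries in design matrix")
        self.R = R
        U, s, Vt = np.linalg.svd(R, full_matrices=False)
        keep = s > (s[0] * 1e-14 if s.size and s[0] > 0 else 0)
        self.U, self.s, self.Vt = U[:, keep], s[keep], Vt[keep]

    def weights(self, lam: float, S: np.ndarray) -> np.ndarray:
        c = self.U.T @ S
        return self.Vt.T @ ((self.s / (self.s ** 2 + lam))[:, None] * c)

    def dual_coef(self, lam: float, S: np.ndarray) -> np.ndarray:
        c = self.U.T @ S
        inside = self.U @ ((1.0 / (self.s ** 2 + lam))[:, None] * c)
        return inside + (S - self.U @ c) / lam

    def fitted(self, lam: float, S: np.ndarray) -> np.ndarray:
        c = self.U.T @ S
        return self.U @ ((self.s ** 2 / (self.s ** 2 + lam))[:, None] * c)

    def loo_sse(self, grid, S: np.ndarray, groups=None) -> np.ndarray:
        """Leave-one-out squared error summed over units, per (lambda, target).

        ``groups=None`` leaves out single rows (PRESS); otherwise each group
        (an array of row indices, e.g. all frames of one stimulus) is left
        out jointly, using the block identity
        ``e_I = (I - H_II)^{-1} (y_I - yhat_I)``.

        Systems above 512 rows run in single precision: the error is used
        only to rank regularization candidates (decades apart on the grid),
        where float32 resolution is ample; small systems keep the identity
        exact to double precision.
        """
        dtype = np.float32 if self.R.shape[0] > 512 else np.float64
        S = np.asarray(S, dtype=dtype)
        S2 = S[:, None] if S.ndim == 1 else S
        U = self.U.astype(dtype, copy=False)
        s = self.s.astype(dtype, copy=False)
        c = U.T @ S2
        out = np.empty((len(grid), S2.shape[1]))
        if groups is not None:
            t_max = max(len(g) for g in groups)
            U3 = np.zeros((len(groups), t_max, s.size), dtype=dtype)
            sel = np.zeros((len(groups), t_max), dtype=int)
            pad = np.zeros((len(groups), t_max), dtype=bool)
            for k, g in enumerate(groups):
                U3[k, :len(g)] = U[g]
                sel[k, :len(g)] = g
                pad[k, len(g):] = True
            eye = np.eye(t_max, dtype=dtype)
        for li, lam in enumerate(grid):
            d = (s ** 2 / (s ** 2 + dtype(lam))).astype(dtype)
            resid = S2 - U @ (d[:, None] * c)
            if groups is None:
                h = (U ** 2 * d).sum(axis=1)
                e = resid / np.clip(1.0 - h, 1e-12, None)[:, None]
                out[li] = (e ** 2).sum(axis=0)
            else:
                # padded rows of U3 are zero, so A already has unit rows
                # and columns there and the padded residuals are zeroed
                H = (U3 * d) @ U3.transpose(0, 2, 1)
                A = eye[None] - H
                r3 = resid[sel]
                r3[pad] = 0.0
                e = np.linalg.solve(A, r3)
                out[li] = (e ** 2).sum(axis=(0, 1))
        return out


def loo_select_lambda(R, S, grid=DEFAULT_LAMBDA_GRID, groups=None):
    """Grid value minimizing closed-form leave-one-out error, per target.

    Ties resolve to the smallest lambda. Returns a scalar for 1-D targets,
    else one lambda per target column.
    """
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    S = np.asarray(S, dtype=float)
    n_units = len(groups) if groups is not None else R.shape[0]
    if n_units < 2:
        raise ValueError("need >= 2 training units for leave-one-out")
    sse = RidgeSystem(R).loo_sse(grid, S, groups)
    best = grid[np.argmin(sse, axis=0)]
    return float(best[0]) if S.ndim == 1 else best


# ---------------------------------------------------------------------------
# trained decoders
# ---------------------------------------------------------------------------

@dataclass
class TrainedDecoder:
    """Fitted decoder: one weight map and one lambda per decoded feature.

    Weights are stored factored as ``basis @ coef`` (right singular vectors
    times per-feature spectral coefficients), which keeps high-dimensional
    regression designs cheap; :attr:`weights` materializes the full
    (design columns, features) map, whose column axis unstacks to
    (channel, lag) -- ``g_f(tau, x)`` -- in convolution mode and to
    (channel, time) -- ``w_f(t, x)`` -- in regression mode.
    """

    mode: str
    basis: np.ndarray            # (design columns, rank)
    coef: np.ndarray             # (rank, features)
    lambdas: np.ndarray
    window: object
    channel_ids: list = field(default_factory=list)
    feature_scaler: object = None
    response_scaler: object = None

    @property
    def weights(self) -> np.ndarray:
        return self.basis @ self.coef

    @property
    def n_features(self) -> int:
        return self.coef.shape[1]


def _fit_with_per_feature_lambda(system: RidgeSystem, S, grid, groups,
                                 shared_lambda):
    grid = np.sort(np.asarray(grid, dtype=float))
    sse = system.loo_sse(grid, S, groups)
    if shared_lambda:
        lam = grid[int(np.argmin(sse.sum(axis=1)))]
        lambdas = np.full(S.shape[1], lam)
    else:
        lambdas = grid[np.argmin(sse, axis=0)]
    c = system.U.T @ S
    coef = np.empty((system.s.size, S.shape[1]))
    for lam in np.unique(lambdas):
        cols = lambdas == lam
        coef[:, cols] = ((system.s / (system.s ** 2 + lam))[:, None]
                         * c[:, cols])
    return coef, lambdas


def fit_convolution_decoder(responses, features, lw: LagWindow,
                            grid=DEFAULT_LAMBDA_GRID,
                            shared_lambda: bool = False,
                            feature_scaler=None,
                            response_scaler=None) -> TrainedDecoder:
    """Fit the lagged (convolution) decoder on standardized training data.

    ``features`` is one (F, T_n) matrix per item on the 10-ms frame grid;
    responses and features must already be on the training-standardized
    scale. Leave-one-out lambda selection leaves out one stimulus at a time.
    """
    if len(responses) != len(features):
        raise ValueError("responses and features must share the item set")
    n_frames = [np.asarray(f).shape[1] for f in features]
    design = build_lagged_design(responses, n_frames, lw)
    S = np.vstack([np.asarray(f, dtype=float).T for f in features])
    system = RidgeSystem(design.matrix)
    coef, lambdas = _fit_with_per_feature_lambda(
        system, S, grid, design.item_row_groups, shared_lambda)
    return TrainedDecoder("convolution", system.Vt.T, coef, lambdas, lw,
                          list(responses[0].channel_ids),
                          feature_scaler, response_scaler)


def _regression_row(e: EvokedResponse, tw: TimeWindow) -> np.ndarray:
    mask = (e.times >= tw.start) & (e.times < tw.end)
    if not mask.any():
        raise OutOfEpochError(
            f"item {e.item_id!r}: window {tw} outside the epoch")
    return e.values[:, mask].ravel()     # channel-major columns


def fit_regression_decoder(responses, features, tw: TimeWindow,
                           grid=DEFAULT_LAMBDA_GRID,
                           shared_lambda: bool = False,
                           feature_scaler=None,
                           response_scaler=None) -> TrainedDecoder:
    """Fit the static-feature decoder: design rows are items, columns are
    (channel, time within ``tw``)."""
    if len(responses) < 3:
        raise ValueError("need >= 3 training items")
    if len(responses) != len(features):
        raise ValueError("responses and features must share the item set")
    R = np.vstack([_regression_row(e, tw) for e in responses])
    S = np.vstack([np.asarray(f, dtype=float).ravel() for f in features])
    system = RidgeSystem(R)
    coef, lambdas = _fit_with_per_feature_lambda(system, S, grid, None,
                                                 shared_lambda)
    return TrainedDecoder("regression", system.Vt.T, coef, lambdas, tw,
                          list(responses[0].channel_ids),
                          feature_scaler, response_scaler)


def predict(decoder: TrainedDecoder, response: EvokedResponse,
            n_frames: int | None = None) -> np.ndarray:
    """Reconstruct features for one (training-standardized) response.

    Convolution mode returns an (F, ``n_frames``) matrix; regression mode a
    length-F vector. The reconstruction lives on the standardized feature
    scale of the training set.
    """
    if list(response.channel_ids) != list(decoder.channel_ids):
        raise ValueError("response channels do not match the decoder's "
                         "channel set")
    if decoder.mode == "convolution":
        if n_frames is None:
            raise ValueError("n_frames required for the convolution decoder")
        X = _lagged_rows(response, int(n_frames), decoder.window.lags)
        return ((X @ decoder.basis) @ decoder.coef).T
    row = _regression_row(response, decoder.window)
    return (row @ decoder.basis) @ decoder.coef
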