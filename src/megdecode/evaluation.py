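"""Evaluation and statistical inference for the decoders.

Leave-two-out pairwise classification: a decoder is trained on all but two
items; the held-out pair is called correctly when

    sim(s1, p1) + sim(s2, p2) > sim(s1, p2) + sim(s2, p1)

with ``sim`` the Pearson correlation between true (s) and reconstructed (p)
features, all feature axes concatenated. Accuracy averages this outcome over
all admissible pairs (all unordered pairs at the item level; different
category and optionally same speaker at the category level). The layer also
provides leave-one-out reconstruction fidelity, lag- and time-window sweeps,
label-permutation nulls, Fisher combination across datasets, FDR correction
over time, and the Wilcoxon signed-rank comparison between models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .decoders import (
    DEFAULT_LAMBDA_GRID,
    FeatureScaler,
    LagWindow,
    TimeWindow,
    fit_convolution_decoder,
    fit_regression_decoder,
    predict,
)
from .errors import (
    DegenerateTestError,
    EmptySchemeError,
    UndefinedCorrelationError,
)
from .neural import ResponseScaler

logger = logging.getLogger(__name__)

TIME_VARYING_MODELS = ("convolution", "regression_per_frame")

# default lag windows: overview, five non-overlapping 80-ms steps, and the
# backward (causality-control) window
DEFAULT_LAG_WINDOWS = (
    LagWindow(0, 420),
    LagWindow(20, 100), LagWindow(100, 180), LagWindow(180, 260),
    LagWindow(260, 340), LagWindow(340, 420),
    LagWindow(-80, 0),
)
DEFAULT_TIME_WINDOWS = tuple(TimeWindow(50 * k, 50 * (k + 1))
                             for k in range(20))


# ---------------------------------------------------------------------------
# pairing schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairingScheme:
    """Constraints on which held-out pairs are evaluated.

    ``level="item"`` enumerates all unordered pairs. ``level="category"``
    keeps pairs from two different semantic categories and, with
    ``same_speaker``, only pairs spoken by the same speaker.
    """

    level: str = "item"
    different_category: bool = True
    same_speaker: bool = False


def enumerate_pairs(metadata: pd.DataFrame,
                    scheme: PairingScheme) -> list:
    """Deterministically ordered unordered index pairs under ``scheme``."""
    n = len(metadata)
    all_pairs = list(combinations(range(n), 2))
    if scheme.level == "item":
        pairs = all_pairs
    elif scheme.level == "category":
        cat = metadata["category"].to_numpy()
        spk = (metadata["speaker"].to_numpy()
               if "speaker" in metadata else None)
        pairs = []
        for i, j in all_pairs:
            if scheme.different_category and cat[i] == cat[j]:
                continue
            if scheme.same_speaker:
                if spk is None or spk[i] != spk[j]:
                    continue
            pairs.append((i, j))
    else:
        raise ValueError(f"unknown pairing level {scheme.level!r}")
    if not pairs:
        raise EmptySchemeError("no valid item pair under the scheme")
    return pairs


# ---------------------------------------------------------------------------
# pair classification
# ---------------------------------------------------------------------------

def equalize_lengths(f1: np.ndarray, f2: np.ndarray):
    """Truncate both time-varying feature arrays to the shorter length."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    t = min(f1.shape[-1], f2.shape[-1])
    return f1[..., :t], f2[..., :t]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError("zero-variance vector")
    return float(np.corrcoef(a, b)[0, 1])


def pairwise_classify(s1, s2, p1, p2) -> float:
    """1 if the correct labeling wins, 0 if it loses, 0.5 on an exact tie."""
    correct = _pearson(s1, p1) + _pearson(s2, p2)
    swapped = _pearson(s1, p2) + _pearson(s2, p1)
    if correct > swapped:
        return 1.0
    if correct < swapped:
        return 0.0
    return 0.5


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class DecodingResult:
    accuracy: float
    per_pair: np.ndarray
    pairs: list
    model: str
    window: object
    n_skipped: int = 0
    dataset_id: str = ""
    p_value: float | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.per_pair)


@dataclass
class FidelityResult:
    mean_r: float
    per_item: np.ndarray
    model: str
    window: object


@dataclass
class PermutationResult:
    observed: DecodingResult
    null_accuracies: np.ndarray
    p_value: float


@dataclass
class FisherResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class WilcoxonResult:
    statistic: float
    z: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# fit/predict plumbing
# ---------------------------------------------------------------------------

def _fit_and_predict(model, train_resp, train_feat, test_resp, window,
                     lambda_grid, shared_lambda, n_frames=None):
    """Fit the requested decoder on one training fold and reconstruct the
    held-out responses. Returns a list of reconstructions."""
    if model == "convolution":
        dec = fit_convolution_decoder(train_resp, train_feat, window,
                                      lambda_grid,
                                      shared_lambda=shared_lambda)
        return [predict(dec, e, n_frames) for e in test_resp]
    if model == "regression":
        dec = fit_regression_decoder(train_resp, train_feat, window,
                                     lambda_grid,
                                     shared_lambda=shared_lambda)
        return [predict(dec, e) for e in test_resp]
    if model == "regression_per_frame":
        # control analysis: all response time points predict each stimulus
        # frame separately (one static regression per frame)
        n_feat = np.asarray(train_feat[0]).shape[0]
        outs = [np.empty((n_feat, n_frames)) for _ in test_resp]
        lengths = np.array([np.asarray(f).shape[1] for f in train_feat])
        for t in range(n_frames):
            usable = np.flatnonzero(lengths > t)
            if usable.size < 3:
                for o in outs:
                    o[:, t] = 0.0
                continue
            dec = fit_regression_decoder(
                [train_resp[k] for k in usable],
                [np.asarray(train_feat[k])[:, t] for k in usable],
                window, lambda_grid, shared_lambda=shared_lambda)
            for o, e in zip(outs, test_resp):
                o[:, t] = predict(dec, e)
        return outs
    raise ValueError(f"unknown model {model!r}")


def _standardize_fold(responses, features, train_idx, time_varying,
                      categorical):
    rscaler = ResponseScaler().fit([responses[k] for k in train_idx])
    resp_std = [rscaler.transform(e) for e in responses]
    fscaler = FeatureScaler("time_varying" if time_varying else "static",
                            categorical)
    fscaler.fit([features[k] for k in train_idx])
    feat_std = [fscaler.transform(f) for f in features]
    return resp_std, feat_std


# ---------------------------------------------------------------------------
# headline evaluation loops
# ---------------------------------------------------------------------------

def leave_two_out_accuracy(responses, features, *, model, window, pairs,
                           lambda_grid=DEFAULT_LAMBDA_GRID,
                           categorical=False, shared_lambda=False,
                           reconstructor=None, dataset_id="",
                           ) -> DecodingResult:
    """Pairwise leave-two-out classification accuracy.

    For every held-out pair the decoder (and both standardization scalers)
    is re-fit on the remaining items; reconstructions of the two held-out
    items are matched to the true features with the pairwise rule. Pairs
    with undefined correlations are skipped and counted. ``reconstructor``
    is a testing hook ``(train_idx, (i, j), s_i, s_j) -> (p_i, p_j)`` that
    replaces the decoder.
    """
    n = len(responses)
    time_varying = model in TIME_VARYING_MODELS
    outcomes, n_skipped = [], 0
    kept_pairs = []
    for i, j in pairs:
        train_idx = [k for k in range(n) if k not in (i, j)]
        resp_std, feat_std = _standardize_fold(
            responses, features, train_idx, time_varying, categorical)
        if time_varying:
            s1, s2 = equalize_lengths(feat_std[i], feat_std[j])
            n_frames = s1.shape[-1]
        else:
            s1, s2 = feat_std[i], feat_std[j]
            n_frames = None
        if reconstructor is not None:
            p1, p2 = reconstructor(train_idx, (i, j), s1, s2)
        else:
            p1, p2 = _fit_and_predict(
                model, [resp_std[k] for k in train_idx],
                [feat_std[k] for k in train_idx],
                [resp_std[i], resp_std[j]], window, lambda_grid,
                shared_lambda, n_frames)
        try:
            outcomes.append(pairwise_classify(s1, s2, p1, p2))
            kept_pairs.append((i, j))
        except UndefinedCorrelationError:
            n_skipped += 1
            logger.warning("pair (%d, %d): undefined correlation, skipped",
                           i, j)
    if not outcomes:
        raise EmptySchemeError("all pairs skipped")
    per_pair = np.asarray(outcomes)
    return DecodingResult(float(per_pair.mean()), per_pair, kept_pairs,
                          model, window, n_skipped, dataset_id)


def loo_reconstruction_fidelity(responses, features, *, model, window,
                                lambda_grid=DEFAULT_LAMBDA_GRID,
                                categorical=False, shared_lambda=False,
                                reconstructor=None) -> FidelityResult:
    """Leave-one-out reconstruction: train on n-1 items, reconstruct the
    held-out item, report the Pearson correlation with its true features
    (flattened), per item and on average."""
    n = len(responses)
    if n < 3:
        raise ValueError("need >= 3 items")
    time_varying = model in TIME_VARYING_MODELS
    rs = []
    for i in range(n):
        train_idx = [k for k in range(n) if k != i]
        resp_std, feat_std = _standardize_fold(
            responses, features, train_idx, time_varying, categorical)
        truth = feat_std[i]
        n_frames = truth.shape[-1] if time_varying else None
        if reconstructor is not None:
            p = reconstructor(train_idx, i, truth)
        else:
            (p,) = _fit_and_predict(
                model, [resp_std[k] for k in train_idx],
                [feat_std[k] for k in train_idx],
                [resp_std[i]], window, lambda_grid, shared_lambda, n_frames)
        rs.append(_pearson(np.asarray(truth), np.asarray(p)))
    per_item = np.asarray(rs)
    return FidelityResult(float(per_item.mean()), per_item, model, window)


def lag_sweep(responses, features, windows=DEFAULT_LAG_WINDOWS, *,
              pairs, **kwargs) -> list:
    """Leave-two-out accuracy of the convolution decoder per lag window."""
    return [leave_two_out_accuracy(responses, features,
                                   model="convolution", window=lw,
                                   pairs=pairs, **kwargs)
            for lw in windows]


def window_sweep(responses, features, windows=DEFAULT_TIME_WINDOWS, *,
                 pairs, **kwargs) -> list:
    """Leave-two-out accuracy of the regression decoder per 50-ms window."""
    return [leave_two_out_accuracy(responses, features,
                                   model="regression", window=tw,
                                   pairs=pairs, **kwargs)
            for tw in windows]


# ---------------------------------------------------------------------------
# permutation testing
# ---------------------------------------------------------------------------

def permutation_null(responses, features, *, model, window, pairs, n_perm,
                     seed, lambda_grid=DEFAULT_LAMBDA_GRID,
                     categorical=False, shared_lambda=False,
                     ) -> PermutationResult:
    """Empirical p value from item-label permutations.

    Each permutation shuffles which response goes with which item and
    re-runs the full leave-two-out evaluation (including per-fold lambda
    re-selection). ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    kwargs = dict(model=model, window=window, pairs=pairs,
                  lambda_grid=lambda_grid, categorical=categorical,
                  shared_lambda=shared_lambda)
    observed = leave_two_out_accuracy(responses, features, **kwargs)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(len(responses))
        shuffled = [responses[p] for p in perm]
        nulls[k] = leave_two_out_accuracy(shuffled, features,
                                          **kwargs).accuracy
    p = (1.0 + np.sum(nulls >= observed.accuracy)) / (1.0 + n_perm)
    observed.p_value = p
    return PermutationResult(observed, nulls, float(p))


def permutation_null_pooled(datasets, *, model, window, n_perm, seed,
                            **kwargs) -> np.ndarray:
    """Null accuracies drawn from a pool of datasets (participants): each
    permutation run picks one dataset at random, shuffles its item labels,
    and re-runs the evaluation. Returns the null accuracy distribution."""
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for k in range(n_perm):
        responses, features, pairs = datasets[rng.integers(len(datasets))]
        perm = rng.permutation(len(responses))
        shuffled = [responses[p] for p in perm]
        nulls[k] = leave_two_out_accuracy(
            shuffled, features, model=model, window=window, pairs=pairs,
            **kwargs).accuracy
    return nulls


# ---------------------------------------------------------------------------
# statistical layer
# ---------------------------------------------------------------------------

def fisher_combine(p_values, zero_floor: float | None = None
                   ) -> FisherResult:
    """Fisher's method: ``chi2 = -2 sum(ln p)`` on 2k degrees of freedom."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        raise ValueError("no p values to combine")
    if np.any(ps > 1) or np.any(~np.isfinite(ps)):
        raise ValueError("p values must lie in (0, 1]")
    if np.any(ps <= 0):
        if zero_floor is None:
            raise ValueError("p == 0 encountered; pass zero_floor "
                             "(e.g. 1 / (n_perm + 1)) to clamp")
        logger.warning("clamping %d zero p value(s) to %g",
                       int((ps <= 0).sum()), zero_floor)
        ps = np.clip(ps, zero_floor, 1.0)
    stat = float(-2.0 * np.sum(np.log(ps)))
    df = 2 * ps.size
    return FisherResult(stat, df, float(scipy.stats.chi2.sf(stat, df)))


def fdr_correct(p_values, alpha: float = 0.01):
    """Benjamini-Hochberg step-up; returns (significance mask, adjusted p)."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any(~np.isfinite(ps)):
        raise ValueError("p values must be finite")
    reject, p_adj = multipletests(ps, alpha=alpha, method="fdr_bh")[:2]
    return reject, p_adj


def compare_models_wilcoxon(acc_a, acc_b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired accuracies.

    Zero differences are dropped; ties get average ranks. The p value is
    exact (sign-flip enumeration over ranks, valid with ties) for n <= 25,
    otherwise from the normal approximation whose Z is always reported.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateTestError("all differences are zero")
    if d.size < 5:
        raise ValueError("need >= 5 non-zero differences")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    sigma = np.sqrt(np.sum(ranks ** 2)) / 2.0
    z = (w_plus - mu) / sigma
    if d.size <= 25:
        # exact null: each rank signed +/- with probability 1/2; DP over
        # doubled ranks keeps sums integral even with .5 average ranks
        r2 = np.rint(2 * ranks).astype(int)
        dist = np.zeros(int(r2.sum()) + 1)
        dist[0] = 1.0
        for r in r2:
            dist[r:] += dist[:-r].copy() if r else dist.copy()
        dist /= dist.sum()
        support = np.arange(dist.size)
        dev = np.abs(support - 2 * mu)
        p = float(dist[dev >= abs(2 * w_plus - 2 * mu) - 1e-9].sum())
    else:
        p = float(2 * scipy.stats.norm.sf(abs(z)))
    return WilcoxonResult(w_plus, float(z), min(p, 1.0), int(d.size))
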