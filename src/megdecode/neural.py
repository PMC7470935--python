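"""Evoked MEG response container and preprocessing contract.

Fixed pipeline order: average trials (with artifact rejection), baseline
correct to the 300-ms prestimulus window, downsample to the 10-ms grid,
then -- inside each cross-validation training fold -- standardize every
(channel, time-bin) cell across items. Standardization statistics are kept
so held-out items are transformed with training-fold statistics only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import BaselineError, EmptyAverageError, ResamplingError

logger = logging.getLogger(__name__)

EPOCH_START_MS = -300
EPOCH_END_MS = 2000
TARGET_STEP_MS = 10
REJECT_THRESHOLD = 3000.0       # |signal| above this drops the trial (fT/cm)
_ZERO_SD_TOL = 1e-15


@dataclass
class EvokedResponse:
    """Trial-averaged response: ``values`` is channels x time, ``times`` in ms
    relative to stimulus onset."""

    item_id: str
    values: np.ndarray
    times: np.ndarray
    channel_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.times.size:
            raise ValueError("values must be (channels, len(times))")
        if np.any(~np.isfinite(self.values)):
            raise ValueError(f"item {self.item_id!r}: non-finite values")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:03d}"
                                for i in range(self.values.shape[0])]

    @property
    def step_ms(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def copy_with(self, values=None, times=None) -> "EvokedResponse":
        return EvokedResponse(
            self.item_id,
            self.values.copy() if values is None else values,
            self.times.copy() if times is None else times,
            list(self.channel_ids))


@dataclass(frozen=True)
class ChannelSet:
    """Named subset of channels (e.g. gradiometers over auditory cortex)."""

    name: str
    channel_ids: tuple

    def __post_init__(self):
        if not self.channel_ids:
            raise ValueError(f"channel set {self.name!r} is empty")

    def select(self, e: EvokedResponse) -> EvokedResponse:
        idx = [e.channel_ids.index(c) for c in self.channel_ids]
        out = e.copy_with(values=e.values[idx])
        out.channel_ids = list(self.channel_ids)
        return out


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def average_epochs(epochs: np.ndarray, times: np.ndarray,
                   reject_threshold: float = REJECT_THRESHOLD,
                   item_id: str = "", channel_ids=None) -> EvokedResponse:
    """Mean over artifact-free trials (trial x channel x time input).

    Trials containing any sample with absolute value above
    ``reject_threshold`` are dropped; the retained count is logged.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] < 1:
        raise ValueError("epochs must be (trial, channel, time) with >= 1 "
                         "trial")
    keep = np.max(np.abs(epochs), axis=(1, 2)) <= reject_threshold
    if not keep.any():
        raise EmptyAverageError(
            f"item {item_id!r}: all {epochs.shape[0]} trial(s) rejected")
    logger.info("item %r: averaging %d/%d trials", item_id,
                int(keep.sum()), epochs.shape[0])
    return EvokedResponse(item_id, epochs[keep].mean(axis=0),
                          np.asarray(times, dtype=float),
                          list(channel_ids) if channel_ids else [])


def baseline_correct(e: EvokedResponse,
                     window_ms=(EPOCH_START_MS, 0)) -> EvokedResponse:
    """Subtract, per channel, the mean over the prestimulus window
    ``[window_ms[0], window_ms[1])``. Idempotent."""
    lo, hi = window_ms
    if e.times[0] > lo:
        raise BaselineError(
            f"item {e.item_id!r}: epoch starts at {e.times[0]} ms, "
            f"baseline needs {lo} ms")
    mask = (e.times >= lo) & (e.times < hi)
    if not mask.any():
        raise BaselineError(f"item {e.item_id!r}: empty baseline window")
    return e.copy_with(values=e.values
                       - e.values[:, mask].mean(axis=1, keepdims=True))


def downsample_evoked(e: EvokedResponse,
                      target_step_ms: float = TARGET_STEP_MS
                      ) -> EvokedResponse:
    """Anti-alias low-pass then decimate to the ``target_step_ms`` grid."""
    ratio = target_step_ms / e.step_ms
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ResamplingError(
            f"source step {e.step_ms} ms does not divide "
            f"{target_step_ms} ms")
    if q == 1:
        return e.copy_with()
    values = sps.resample_poly(e.values, 1, q, axis=1, padtype="line")
    return e.copy_with(values=values, times=e.times[::q])


class ResponseScaler:
    """Per-(channel, time-bin) z-scoring across items (population SD).

    Cells with zero variance over the training items are set to zero and
    counted in a logged warning.
    """

    def __init__(self):
        self.mean_ = None
        self.scale_ = None

    def fit(self, responses) -> "ResponseScaler":
        if len(responses) < 2:
            raise ValueError("need >= 2 items to standardize")
        stack = np.stack([r.values for r in responses])
        self.mean_ = stack.mean(axis=0)
        sd = stack.std(axis=0)          # population (n) convention
        n_zero = int((sd <= _ZERO_SD_TOL).sum())
        if n_zero:
            logger.warning("%d zero-variance response cell(s) set to 0",
                           n_zero)
        self.scale_ = np.where(sd <= _ZERO_SD_TOL, 1.0, sd)
        return self

    def transform(self, e: EvokedResponse) -> EvokedResponse:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        return e.copy_with(values=(e.values - self.mean_) / self.scale_)

    def fit_transform(self, responses):
        self.fit(responses)
        return [self.transform(r) for r in responses]


def standardize_responses(responses):
    """Convenience wrapper: fit a :class:`ResponseScaler` and transform.

    Returns ``(standardized_responses, scaler)``; the scaler is retained so
    held-out items can be transformed with training-set statistics.
    """
    scaler = ResponseScaler()
    return scaler.fit_transform(responses), scaler
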