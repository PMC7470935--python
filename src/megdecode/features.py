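"""Acoustic stimulus representations.

Audio preprocessing and the four acoustic feature sets used for decoding:

* whole-sound frequency spectrum (``fft``): 128 log-spaced bands, 180-7246 Hz;
* auditory spectrogram: the same 128 bands in 10-ms frames integrated over
  16-ms windows -- the time-varying representation the convolution decoder
  reconstructs;
* amplitude envelope: the across-band mean of the spectrogram;
* modulation power spectrum (``mps``): spectrogram energy decomposed on a
  4 x 4 grid of spectral scales (cycles/octave) and temporal modulation
  rates (Hz), time-averaged and averaged over up-/downward directions.

Also houses the sound-complexity measures (spectral flatness per frame, SFM,
and its across-time variability, SSI) and the correlation-based feature
distance used to compare items.

The cochlear filter bank is approximated by 128 overlapping raised-cosine
band-pass filters on a log-frequency axis; only the band count, center
spacing, frame geometry and band-selectivity behaviour are contractual,
not any particular toolbox's transfer functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .errors import (
    EmptySpectrogramError,
    InsufficientDurationError,
    InvalidWaveformError,
    UndefinedDistanceError,
    UndefinedSFMError,
    UnsupportedRateError,
)

logger = logging.getLogger(__name__)

SAMPLE_RATE = 16_000          # working rate after preprocessing (Hz)
LOWPASS_HZ = 8_000.0          # anti-alias / band-limit cutoff
FRAME_STEP_MS = 10            # spectrogram hop
INTEGRATION_MS = 16           # spectrogram integration window
N_BANDS = 128
FMIN_HZ = 180.0
FMAX_HZ = 7246.0
SCALES_CYC_PER_OCT = (0.5, 1.0, 2.0, 4.0)
RATES_HZ = (1.0, 3.0, 9.0, 27.0)
DEFAULT_TARGET_RMS = 0.05     # full-scale RMS after normalization

_SAMPLES_PER_MS = SAMPLE_RATE // 1000
_FRAME_LEN = INTEGRATION_MS * _SAMPLES_PER_MS    # 256 samples
_HOP = FRAME_STEP_MS * _SAMPLES_PER_MS           # 160 samples
_FRAME_NFFT = 4096            # zero-padded so low bands resolve (~3.9 Hz bins)
_SFM_EPS = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Waveform:
    """Mono audio signal; ``rate`` in samples/second."""

    samples: np.ndarray
    rate: int
    item_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))


@dataclass
class Spectrogram:
    """Non-negative band-energy matrix, ``N_BANDS`` bands x T frames."""

    values: np.ndarray
    band_centers_hz: np.ndarray
    frame_step_ms: int = FRAME_STEP_MS
    integration_ms: int = INTEGRATION_MS
    item_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class Envelope:
    """Across-band mean of a spectrogram; one value per 10-ms frame."""

    values: np.ndarray
    frame_step_ms: int = FRAME_STEP_MS
    item_id: str = ""


@dataclass
class StaticAcousticVector:
    """Whole-sound feature vector: ``kind`` is ``"fft"`` (128) or ``"mps"`` (2048).

    For the MPS the values are indexed band-major as
    ``(band, scale, rate)`` flattened in C order.
    """

    kind: str
    values: np.ndarray
    band_centers_hz: np.ndarray = field(
        default_factory=lambda: band_centers())
    scales: tuple = SCALES_CYC_PER_OCT
    rates: tuple = RATES_HZ
    item_id: str = ""


# ---------------------------------------------------------------------------
# filter bank
# ---------------------------------------------------------------------------

def band_centers(n_bands: int = N_BANDS, fmin: float = FMIN_HZ,
                 fmax: float = FMAX_HZ) -> np.ndarray:
    """Log-spaced filter center frequencies (Hz), ``fmin`` .. ``fmax``."""
    return fmin * (fmax / fmin) ** (np.arange(n_bands) / (n_bands - 1))


def filterbank_weights(freqs_hz: np.ndarray,
                       n_bands: int = N_BANDS) -> np.ndarray:
    """Raised-cosine band weights on a log-frequency axis.

    Each filter spans one inter-center spacing to either side, so adjacent
    filters overlap and their responses sum to ~1 across the passband.
    Returns an ``(n_bands, len(freqs_hz))`` weight matrix.
    """
    centers = band_centers(n_bands)
    log_c = np.log2(centers)
    half_width = log_c[1] - log_c[0]
    freqs = np.asarray(freqs_hz, dtype=float)
    pos = freqs > 0
    log_f = np.full_like(freqs, -np.inf)
    log_f[pos] = np.log2(freqs[pos])
    d = (log_f[None, :] - log_c[:, None]) / half_width
    w = np.zeros_like(d)
    inside = np.abs(d) < 1.0
    w[inside] = np.cos(0.5 * np.pi * d[inside]) ** 2
    return w


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def lowpass_8k(samples: np.ndarray, rate: int,
               numtaps: int = 1025) -> np.ndarray:
    """Linear-phase 8-kHz low-pass FIR (Blackman-Harris window)."""
    if rate <= 2 * LOWPASS_HZ:
        return np.asarray(samples, dtype=float)
    taps = sps.firwin(numtaps, LOWPASS_HZ, window="blackmanharris", fs=rate)
    return sps.fftconvolve(samples, taps, mode="same")


def preprocess_audio(raw: Waveform,
                     target_rms: float = DEFAULT_TARGET_RMS) -> Waveform:
    """Low-pass at 8 kHz, resample to 16 kHz, normalize to ``target_rms``.

    Inputs differing only by a gain factor map to identical outputs.
    """
    x = np.asarray(raw.samples, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise InvalidWaveformError(
            f"item {raw.item_id!r}: empty or non-finite samples")
    if raw.rate < SAMPLE_RATE:
        raise UnsupportedRateError(
            f"item {raw.item_id!r}: rate {raw.rate} < {SAMPLE_RATE}")
    if x.size < 1600 * raw.rate // SAMPLE_RATE:
        raise InvalidWaveformError(
            f"item {raw.item_id!r}: shorter than 0.1 s")
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")

    if raw.rate != SAMPLE_RATE:
        x = lowpass_8k(x, raw.rate)
        frac = Fraction(SAMPLE_RATE, int(raw.rate))
        x = sps.resample_poly(x, frac.numerator, frac.denominator)

    rms = np.sqrt(np.mean(np.square(x)))
    if rms == 0:
        raise InvalidWaveformError(f"item {raw.item_id!r}: silent input")
    x = x * (target_rms / rms)
    out = Waveform(x, SAMPLE_RATE, raw.item_id)
    if out.duration_ms > 3000:
        logger.warning("item %r: duration %.0f ms exceeds 3 s",
                       raw.item_id, out.duration_ms)
    return out


# ---------------------------------------------------------------------------
# static spectrum
# ---------------------------------------------------------------------------

def compute_fft_spectrum(w: Waveform) -> StaticAcousticVector:
    """Whole-sound power per filter-bank band (128 non-negative values)."""
    x = np.asarray(w.samples, dtype=float)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / w.rate)
    values = filterbank_weights(freqs) @ spec
    if not np.any(values):
        logger.warning("item %r: all-zero spectrum", w.item_id)
    return StaticAcousticVector("fft", values, item_id=w.item_id)


# ---------------------------------------------------------------------------
# spectrogram and envelope
# ---------------------------------------------------------------------------

def compute_auditory_spectrogram(w: Waveform) -> Spectrogram:
    """128-band auditory spectrogram at a 10-ms hop, 16-ms integration.

    Frame ``t`` covers ``[10 t, 10 t + 16)`` ms; the frame count is
    ``floor(duration_ms / 10)``. Values are non-negative band magnitudes.
    """
    if w.rate != SAMPLE_RATE:
        raise UnsupportedRateError("spectrogram expects a preprocessed "
                                   f"16-kHz waveform, got {w.rate} Hz")
    x = np.asarray(w.samples, dtype=float)
    n_frames = int((1000.0 * x.size / w.rate) // FRAME_STEP_MS)
    if n_frames < 1:
        raise EmptySpectrogramError(
            f"item {w.item_id!r}: shorter than one {FRAME_STEP_MS}-ms frame")
    needed = (n_frames - 1) * _HOP + _FRAME_LEN
    if needed > x.size:
        x = np.pad(x, (0, needed - x.size))
    idx = np.arange(_FRAME_LEN)[None, :] + _HOP * np.arange(n_frames)[:, None]
    frames = x[idx] * sps.windows.hann(_FRAME_LEN, sym=False)
    power = np.abs(np.fft.rfft(frames, n=_FRAME_NFFT, axis=1)) ** 2
    freqs = np.fft.rfftfreq(_FRAME_NFFT, d=1.0 / SAMPLE_RATE)
    values = np.sqrt(filterbank_weights(freqs) @ power.T)
    return Spectrogram(values, band_centers(), item_id=w.item_id)


def compute_amplitude_envelope(s: Spectrogram) -> Envelope:
    """Across-band mean of the spectrogram, frame by frame."""
    return Envelope(s.values.mean(axis=0), s.frame_step_ms, s.item_id)


# ---------------------------------------------------------------------------
# modulation power spectrum
# ---------------------------------------------------------------------------

def _modulation_sigmas():
    # Gaussian half-widths growing like sqrt(center): keeps channels
    # selective while making the DC response strictly decrease with rate,
    # so an unmodulated spectrogram loads the slowest channel most.
    sig_scale = 0.4 * np.sqrt(SCALES_CYC_PER_OCT)
    sig_rate = 0.8 * np.sqrt(RATES_HZ)
    return sig_scale, sig_rate


def compute_mps(s: Spectrogram, log_compress: bool = True) -> StaticAcousticVector:
    """Modulation power spectrum: (band, scale, rate) -> 2048 values.

    The (optionally log-compressed) spectrogram is 2-D Fourier transformed
    over (log-frequency, time); Gabor-type Gaussian transfer functions select
    each of the 4 x 4 scale-rate channels, separately for upward- and
    downward-going ripples; filtered magnitudes are averaged over time and
    the two directions, leaving one value per frequency band and channel.
    """
    x = np.asarray(s.values, dtype=float)
    n_bands, n_frames = x.shape
    if n_frames < 32:
        raise InsufficientDurationError(
            f"item {s.item_id!r}: {n_frames} frames < 32 needed for the "
            "slowest modulation-rate filters")

    if log_compress:
        ref = x.mean()
        y = np.log1p(x / ref) if ref > 0 else np.zeros_like(x)
    else:
        y = x.copy()
    y = y - y.mean()

    delta_oct = np.log2(FMAX_HZ / FMIN_HZ) / (n_bands - 1)
    omega = np.fft.fftfreq(n_bands, d=delta_oct)       # cyc/oct
    wfreq = np.fft.fftfreq(n_frames, d=FRAME_STEP_MS / 1000.0)  # Hz
    F2 = np.fft.fft2(y)

    sign = np.sign(omega)[:, None] * np.sign(wfreq)[None, :]
    mask_up = sign >= 0
    mask_down = sign <= 0

    sig_scale, sig_rate = _modulation_sigmas()
    out = np.empty((n_bands, len(SCALES_CYC_PER_OCT), len(RATES_HZ)))
    for i, (sc, ss) in enumerate(zip(SCALES_CYC_PER_OCT, sig_scale)):
        h_sc = np.exp(-((np.abs(omega) - sc) ** 2) / (2 * ss ** 2))
        for j, (rt, sr) in enumerate(zip(RATES_HZ, sig_rate)):
            h_rt = np.exp(-((np.abs(wfreq) - rt) ** 2) / (2 * sr ** 2))
            h = h_sc[:, None] * h_rt[None, :]
            up = np.abs(np.fft.ifft2(F2 * (h * mask_up))).mean(axis=1)
            down = np.abs(np.fft.ifft2(F2 * (h * mask_down))).mean(axis=1)
            out[:, i, j] = 0.5 * (up + down)
    return StaticAcousticVector("mps", out.ravel(), item_id=s.item_id)


# ---------------------------------------------------------------------------
# sound complexity
# ---------------------------------------------------------------------------

def compute_sfm(frame: np.ndarray) -> float:
    """Spectral flatness of one frame: geometric / arithmetic mean, in [0, 1].

    A small floor (1e-12) is added before the geometric mean so zero bins do
    not collapse the logarithm; flat spectra give 1, single-peak spectra -> 0.
    """
    v = np.asarray(frame, dtype=float)
    if v.ndim != 1 or np.any(v < 0):
        raise ValueError("frame must be a non-negative 1-D vector")
    if not np.any(v > 0):
        raise UndefinedSFMError("all-zero frame")
    v = v + _SFM_EPS
    return float(np.exp(np.mean(np.log(v))) / np.mean(v))


def compute_ssi(s: Spectrogram, statistic: str = "sd") -> float:
    """Spectral structure index: variability of per-frame flatness over time.

    ``statistic="sd"`` (default) is the population standard deviation of the
    per-frame SFM series; ``"var"`` its variance. Silent frames are skipped
    (count logged). Larger values denote more variable spectral structure.
    """
    x = np.asarray(s.values, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("SSI needs at least 2 frames")
    silent = ~np.any(x > 0, axis=0)
    if silent.any():
        logger.warning("item %r: skipping %d silent frame(s) in SSI",
                       s.item_id, int(silent.sum()))
    kept = x[:, ~silent]
    if kept.shape[1] < 2:
        raise UndefinedSFMError("fewer than 2 non-silent frames")
    sfm = np.array([compute_sfm(kept[:, t]) for t in range(kept.shape[1])])
    if statistic == "sd":
        return float(np.std(sfm))
    if statistic == "var":
        return float(np.var(sfm))
    raise ValueError(f"unknown statistic {statistic!r}")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def feature_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Pearson correlation between flattened feature arrays, in [0, 2].

    Matrices are flattened by concatenating their feature axes (all frequency
    bands considered together).
    """
    av = np.asarray(a, dtype=float).ravel()
    bv = np.asarray(b, dtype=float).ravel()
    if av.size != bv.size or av.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    if np.std(av) == 0 or np.std(bv) == 0:
        raise UndefinedDistanceError("zero-variance input")
    r = np.corrcoef(av, bv)[0, 1]
    return float(1.0 - r)


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

def read_wav(path, item_id: str | None = None) -> Waveform:
    """Read a mono WAV file (PCM or float); multi-channel input is rejected."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise InvalidWaveformError(f"{path}: expected mono, got "
                                   f"{data.shape[1]} channels")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    if item_id is None:
        import os
        item_id = os.path.splitext(os.path.basename(str(path)))[0]
    return Waveform(data, int(rate), item_id)


def write_wav(path, w: Waveform) -> None:
    wavfile.write(path, int(w.rate), w.samples.astype(np.float32))
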