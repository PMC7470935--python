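"""Phoneme segmentations and semantic feature vectors.

Time-aligned phoneme annotations are read from Praat TextGrid files (long or
short text format) or from a tabular CSV, filtered to a frequency-thresholded
inventory, and rasterized to binary phoneme-by-frame tracks on the 10-ms
stimulus grid (at most one phoneme active per frame). Semantic vectors are
the concatenation of questionnaire scores (Q values, 0-5 scale) and corpus
word-embedding coordinates (D values); the study dimensions are Q=99, D=300.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SegmentationError, TextGridParseError

logger = logging.getLogger(__name__)

FRAME_STEP_MS = 10
DEFAULT_MIN_COUNT = 10      # phonemes with >= 10 instances are retained
DEFAULT_Q = 99              # questionnaire dimensions
DEFAULT_D = 300             # word-embedding dimensions

_SILENCE_LABELS = {"", "sil", "sp", "<sil>", "#"}


@dataclass(frozen=True)
class PhonemeSegment:
    label: str
    start_ms: float
    end_ms: float


@dataclass
class PhonemeSegmentation:
    """Ordered, non-overlapping phoneme intervals for one item (times in ms)."""

    item_id: str
    segments: list

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start_ms)
        prev_end = None
        for s in segs:
            if s.start_ms < 0 or s.end_ms <= s.start_ms:
                raise SegmentationError(
                    f"item {self.item_id!r}: bad interval "
                    f"[{s.start_ms}, {s.end_ms})")
            if prev_end is not None and s.start_ms < prev_end - 1e-9:
                raise SegmentationError(
                    f"item {self.item_id!r}: overlapping intervals at "
                    f"{s.start_ms} ms")
            prev_end = s.end_ms
        self.segments = segs

    @property
    def labels(self):
        return [s.label for s in self.segments]


@dataclass
class PhonemeTrack:
    """Binary phoneme-by-frame matrix; column sums are 0 or 1."""

    values: np.ndarray           # (P, T) of {0, 1}
    inventory: list
    frame_step_ms: int = FRAME_STEP_MS
    item_id: str = ""


@dataclass
class SemanticVector:
    """Concatenated questionnaire (first) and embedding coordinates."""

    values: np.ndarray
    q_dim: int = DEFAULT_Q
    d_dim: int = DEFAULT_D
    item_id: str = ""


# ---------------------------------------------------------------------------
# TextGrid I/O
# ---------------------------------------------------------------------------

_NUM = r"-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?"


def _parse_textgrid_tokens(text: str):
    """Token stream of numbers and quoted strings, Praat short/long agnostic.

    In the long format every value is preceded by ``name =``; stripping the
    field names reduces both formats to the same value sequence.
    """
    tokens = []
    for line in text.splitlines():
        line = line.split("!")[0]
        line = re.sub(r"\[\s*\d*\s*\]", "", line)   # item [3]: indices
        for m in re.finditer(rf'"(?:[^"]|"")*"|{_NUM}', line):
            tok = m.group(0)
            if tok.startswith('"'):
                tokens.append(("str", tok[1:-1].replace('""', '"')))
            else:
                tokens.append(("num", float(tok)))
    return tokens


def read_textgrid(path, item_id: str | None = None,
                  tier: int = 0) -> PhonemeSegmentation:
    """Read interval tier ``tier`` of a Praat TextGrid (long or short format).

    Empty / silence labels are dropped; times are converted from seconds to
    milliseconds.
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    if "TextGrid" not in text:
        raise TextGridParseError(f"{path}: not a TextGrid file")
    tokens = _parse_textgrid_tokens(text)
    # drop the file-type and object-class strings
    tokens = [t for t in tokens if t[1] not in ("ooTextFile", "TextGrid")]
    try:
        it = iter(tokens)

        def num():
            kind, val = next(it)
            if kind != "num":
                raise TextGridParseError(
                    f"{path}: expected number, got {val!r}")
            return val

        def string():
            kind, val = next(it)
            if kind != "str":
                raise TextGridParseError(
                    f"{path}: expected string, got {val!r}")
            return val

        num()  # global xmin
        num()  # global xmax
        n_tiers = int(num())
        if n_tiers < 1:
            raise TextGridParseError(f"{path}: no tiers")
        found = -1
        for _ in range(n_tiers):
            tier_class = string()
            string()  # tier name
            num()     # tier xmin
            num()     # tier xmax
            n_items = int(num())
            intervals = []
            for _ in range(n_items):
                if tier_class == "IntervalTier":
                    xmin, xmax, label = num(), num(), string()
                    intervals.append((xmin, xmax, label))
                else:  # TextTier point: time, mark
                    num(), string()
            if tier_class == "IntervalTier":
                found += 1
                if found == tier:
                    segs = [
                        PhonemeSegment(lab.strip(), 1000.0 * a, 1000.0 * b)
                        for a, b, lab in intervals
                        if lab.strip().lower() not in _SILENCE_LABELS
                    ]
                    if not segs:
                        logger.warning("%s: tier %d has only empty labels",
                                       path, tier)
                    iid = item_id if item_id is not None else str(path)
                    return PhonemeSegmentation(iid, segs)
        raise TextGridParseError(f"{path}: no interval tier found")
    except StopIteration:
        raise TextGridParseError(f"{path}: truncated file") from None


def write_textgrid(path, seg: PhonemeSegmentation,
                   tier_name: str = "phonemes") -> None:
    """Write a long-format TextGrid with one interval tier (times in s)."""
    xmax = (seg.segments[-1].end_ms / 1000.0) if seg.segments else 1.0
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        "        xmin = 0",
        f"        xmax = {xmax:.6f}",
        f"        intervals: size = {len(seg.segments)}",
    ]
    for k, s in enumerate(seg.segments, 1):
        lines += [
            f"        intervals [{k}]:",
            f"            xmin = {s.start_ms / 1000.0:.6f}",
            f"            xmax = {s.end_ms / 1000.0:.6f}",
            f'            text = "{s.label}"',
        ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_segments_csv(path) -> dict:
    """Read a segment table (item_id,label,start_ms,end_ms) into
    a ``{item_id: PhonemeSegmentation}`` dict."""
    df = pd.read_csv(path)
    out = {}
    for item_id, grp in df.groupby("item_id", sort=True):
        segs = [PhonemeSegment(str(r.label), float(r.start_ms),
                               float(r.end_ms))
                for r in grp.itertuples()]
        out[str(item_id)] = PhonemeSegmentation(str(item_id), segs)
    return out


def write_segments_csv(path, segmentations) -> None:
    rows = [
        {"item_id": seg.item_id, "label": s.label,
         "start_ms": s.start_ms, "end_ms": s.end_ms}
        for seg in segmentations for s in seg.segments
    ]
    pd.DataFrame(rows, columns=["item_id", "label", "start_ms",
                                "end_ms"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# inventory and track encoding
# ---------------------------------------------------------------------------

def filter_phoneme_inventory(segmentations,
                             min_count: int = DEFAULT_MIN_COUNT) -> list:
    """Phonemes with >= ``min_count`` instances across the stimulus set,
    in alphabetical order (fixed, reproducible feature indices)."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = Counter(lab for seg in segmentations for lab in seg.labels)
    if not counts:
        logger.warning("empty corpus: empty phoneme inventory")
        return []
    return sorted(lab for lab, c in counts.items() if c >= min_count)


def encode_phoneme_track(seg: PhonemeSegmentation, inventory,
                         n_frames: int) -> PhonemeTrack:
    """Rasterize a segmentation to a binary P x T track on 10-ms frames.

    Frame ``t`` is assigned the phoneme whose half-open interval
    ``[start, end)`` covers the frame midpoint ``10 t + 5`` ms; phonemes
    outside the inventory leave their frames all-zero.
    """
    if not inventory:
        raise ValueError("inventory must be non-empty")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    index = {lab: i for i, lab in enumerate(inventory)}
    values = np.zeros((len(inventory), n_frames), dtype=np.uint8)
    horizon = n_frames * FRAME_STEP_MS
    truncated = False
    for s in seg.segments:
        # the fractional tail shorter than one frame is dropped silently
        if s.end_ms > horizon + FRAME_STEP_MS:
            truncated = True
        row = index.get(s.label)
        if row is None:
            continue
        for t in range(n_frames):
            mid = FRAME_STEP_MS * t + FRAME_STEP_MS / 2.0
            if s.start_ms <= mid < s.end_ms:
                values[row, t] = 1
    if truncated:
        logger.warning("item %r: segmentation extends beyond %d ms; "
                       "truncated", seg.item_id, horizon)
    return PhonemeTrack(values, list(inventory), item_id=seg.item_id)


# ---------------------------------------------------------------------------
# semantic features
# ---------------------------------------------------------------------------

def assemble_semantic_vector(question_scores, embedding,
                             q_dim: int = DEFAULT_Q,
                             d_dim: int = DEFAULT_D,
                             item_id: str = "") -> SemanticVector:
    """Concatenate questionnaire scores (first) and embedding coordinates."""
    q = np.asarray(question_scores, dtype=float)
    d = np.asarray(embedding, dtype=float)
    if q.shape != (q_dim,):
        raise ValueError(f"expected {q_dim} question scores, got {q.shape}")
    if d.shape != (d_dim,):
        raise ValueError(f"expected {d_dim} embedding values, got {d.shape}")
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(d))):
        raise ValueError("semantic features contain missing values")
    return SemanticVector(np.concatenate([q, d]), q_dim, d_dim, item_id)


def read_semantic_csv(path) -> pd.DataFrame:
    """Semantic table: one row per item, header of feature names,
    ``item_id`` column as index."""
    return pd.read_csv(path, index_col="item_id")
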