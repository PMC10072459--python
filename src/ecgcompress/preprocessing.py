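"""Beat-level preprocessing: normalization, R-centered segmentation, AAMI
class mapping, class balancing and train/test splitting.

The segmentation convention follows the usual R-centered interception: for an
annotated R location ``r`` the beat window is the half-open interval
``[r - half_width, r + half_width)``, 0-based, R at position ``half_width`` —
with the default ``half_width = 130`` this yields 260-sample beats.  Windows
crossing a record boundary are skipped and tallied, never padded.

No filtering or denoising is performed anywhere in this module: beats keep the
raw morphology of the recording, which is what the downstream networks are
trained on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .io import BeatDataset, ECGRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AAMI_CLASSES",
    "AAMI_MAPPING",
    "NON_BEAT_SYMBOLS",
    "SplitConfig",
    "SegmentationResult",
    "normalize_beat",
    "normalize_beats",
    "segment_beats",
    "map_aami",
    "balance_dataset",
    "split_train_test",
]

AAMI_CLASSES = ["N", "S", "V", "F", "Q"]

#: MIT-BIH beat-annotation symbol -> AAMI super-class.
#: N additionally absorbs paced (/) and paced-fusion (f) beats, the grouping
#: used when the four-class problem keeps only N/S/V/F and discards Q.
AAMI_MAPPING: dict[str, str] = {
    # N: normal and bundle-branch-block beats plus escapes and paced beats
    "N": "N", "L": "N", "R": "N", "B": "N", "e": "N", "j": "N", "n": "N",
    "/": "N", "f": "N",
    # S: supraventricular premature / ectopic beats
    "S": "S", "A": "S", "J": "S", "a": "S",
    # V: ventricular ectopy
    "V": "V", "E": "V", "r": "V",
    # F: fusion of ventricular and normal
    "F": "F",
    # Q: unclassifiable
    "Q": "Q", "?": "Q",
}

#: Rhythm-change, signal-quality and waveform-boundary marks: not beats,
#: excluded from mapping rather than tallied as unknown.
NON_BEAT_SYMBOLS = frozenset('+~|"=*@x!()pt u^sTD[]'.replace(" ", ""))


@dataclass(frozen=True)
class SplitConfig:
    """Train/test partition: fraction of beats assigned to training and the
    RNG seed that fixes the shuffle."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0,1), got {self.train_fraction}")


@dataclass
class SegmentationResult:
    """A segmented dataset plus bookkeeping tallies."""

    dataset: BeatDataset
    skipped_boundary: int = 0
    unmapped: dict[str, int] = field(default_factory=dict)
    non_beat: int = 0


def normalize_beat(samples: np.ndarray) -> np.ndarray:
    """Min-max normalize one beat into [0, 1].

    A constant beat maps to all zeros.  Idempotent: normalizing an already
    normalized beat returns it unchanged.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot normalize an empty sequence")
    lo, hi = samples.min(), samples.max()
    if hi == lo:
        return np.zeros_like(samples)
    return (samples - lo) / (hi - lo)


def normalize_beats(beats: np.ndarray) -> np.ndarray:
    """Row-wise min-max normalization of a beat matrix."""
    beats = np.asarray(beats, dtype=float)
    lo = beats.min(axis=1, keepdims=True)
    hi = beats.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(beats)
    np.divide(beats - lo, span, out=out, where=span != 0)
    return out


def _refine_r_peak(signal: np.ndarray, index: int, radius: int) -> int:
    lo = max(0, index - radius)
    hi = min(len(signal), index + radius + 1)
    return lo + int(np.argmax(signal[lo:hi]))


def segment_beats(
    record: ECGRecord,
    half_width: int = 130,
    normalize: bool = True,
    refine_r: bool = False,
    refine_radius: int = 10,
) -> SegmentationResult:
    """Cut one fixed-length beat per beat annotation, centered on the R peak.

    The annotation sample index is taken as the R location (optionally refined
    to the local maximum within ``refine_radius`` samples).  Each kept beat is
    ``2 * half_width`` samples; windows that would cross the record boundary
    are skipped and counted.  Non-beat annotations (rhythm and quality marks)
    are ignored; beat symbols outside the AAMI mapping are tallied as
    unmapped.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    signal = np.asarray(record.signal, dtype=float)
    beats: list[np.ndarray] = []
    labels: list[str] = []
    skipped = 0
    non_beat = 0
    unmapped: dict[str, int] = {}
    for index, symbol in record.annotations:
        if symbol in NON_BEAT_SYMBOLS:
            non_beat += 1
            continue
        aami = AAMI_MAPPING.get(symbol)
        if aami is None:
            unmapped[symbol] = unmapped.get(symbol, 0) + 1
            continue
        r = _refine_r_peak(signal, index, refine_radius) if refine_r else index
        start, stop = r - half_width, r + half_width
        if start < 0 or stop > len(signal):
            skipped += 1
            continue
        beats.append(signal[start:stop])
        labels.append(aami)
    if skipped:
        logger.info("record %s: skipped %d boundary beats", record.record_id, skipped)
    if unmapped:
        logger.info("record %s: unmapped beat symbols %s", record.record_id, unmapped)
    if beats:
        matrix = np.vstack(beats)
        if normalize:
            matrix = normalize_beats(matrix)
    else:
        matrix = np.empty((0, 2 * half_width))
    present = [c for c in AAMI_CLASSES if c in labels]
    dataset = BeatDataset(matrix, np.array(labels, dtype=str), 2 * half_width, present)
    return SegmentationResult(dataset, skipped, unmapped, non_beat)


def map_aami(symbols) -> tuple[list[str | None], dict[str, int]]:
    """Map annotation symbols to AAMI classes.

    Returns ``(labels, unmapped_tally)``; non-beat symbols and unknown beat
    symbols yield ``None`` in the label list, the latter also counted in the
    tally.
    """
    labels: list[str | None] = []
    unmapped: dict[str, int] = {}
    for symbol in symbols:
        if symbol in NON_BEAT_SYMBOLS:
            labels.append(None)
        elif symbol in AAMI_MAPPING:
            labels.append(AAMI_MAPPING[symbol])
        else:
            labels.append(None)
            unmapped[symbol] = unmapped.get(symbol, 0) + 1
    return labels, unmapped


def balance_dataset(
    dataset: BeatDataset, per_class_targets: dict[str, int], seed: int = 0
) -> BeatDataset:
    """Subsample to exact per-class counts by seeded sampling without
    replacement.

    Classes absent from ``per_class_targets`` are dropped entirely (this is
    how the unclassifiable Q beats are discarded).  Classes are emitted in
    sorted order of class name, so the result is a pure function of the input
    and the seed.
    """
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    kept_classes: list[str] = []
    for name in sorted(per_class_targets):
        target = per_class_targets[name]
        pool = np.flatnonzero(dataset.labels == str(name))
        if len(pool) < target:
            raise ValueError(
                f"class {name!r}: requested {target} beats but only {len(pool)} available "
                f"(short by {target - len(pool)})"
            )
        pick = rng.choice(pool, size=target, replace=False)
        chosen.append(np.sort(pick))
        kept_classes.append(str(name))
    indices = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
    return BeatDataset(
        dataset.beats[indices], dataset.labels[indices], dataset.beat_length, kept_classes
    )


def split_train_test(
    dataset: BeatDataset, config: SplitConfig = SplitConfig()
) -> tuple[BeatDataset, BeatDataset]:
    """Random, reproducible train/test partition.

    Backed by scikit-learn's ``train_test_split`` with ``random_state`` set to
    the configured seed.  The train size is ``round(train_fraction * n)`` with
    Python's round-half-to-even rule, so 3802 beats at 0.8 give 3042 train /
    760 test.
    """
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    n_train = int(round(config.train_fraction * len(dataset)))
    n_train = min(max(n_train, 1), len(dataset) - 1)
    indices = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        indices,
        train_size=n_train,
        random_state=config.seed,
        shuffle=True,
    )
    return dataset.subset(train_idx), dataset.subset(test_idx)
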