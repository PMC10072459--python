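"""Reading and writing the formats the pipeline touches.

Two kinds of on-disk data are supported:

* **WFDB records** (PhysioNet ``.hea`` header / ``.dat`` signal / ``.atr``
  beat annotations), the format of the MIT-BIH Arrhythmia Database.  A
  self-contained reader/writer is included covering signal formats 212
  (packed 12-bit, the MIT-BIH encoding) and 16 (little-endian int16), plus
  the MIT annotation byte format.  Samples are returned in physical units
  (mV) using the header's gain and baseline.
* **Beat tables**: comma-separated text, one beat per row — ``beat_length``
  sample values followed by a class label in the last column, with an
  optional header row.  This is the shape of pre-segmented beat archives
  such as the Tianchi heartbeat-classification distribution (205 samples,
  labels 0–3).
"""

from __future__ import annotations

import csv
import os
import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FormatError",
    "ECGRecord",
    "BeatDataset",
    "read_wfdb_record",
    "write_wfdb_record",
    "read_beat_table",
    "write_beat_table",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# MIT annotation code <-> symbol tables (beat and non-beat annotations).
ANNOTATION_SYMBOLS: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
ANNOTATION_CODES: dict[str, int] = {s: c for c, s in ANNOTATION_SYMBOLS.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class ECGRecord:
    """One annotated ambulatory ECG recording (a single chosen channel).

    ``annotations`` is an ordered list of ``(sample_index, symbol)`` pairs
    with strictly increasing indices inside the signal.
    """

    record_id: str
    sampling_rate: float
    signal: np.ndarray
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        prev = -1
        for idx, sym in self.annotations:
            if not 0 <= idx < len(self.signal):
                raise ValueError(
                    f"annotation index {idx} outside signal of length {len(self.signal)}"
                )
            if idx <= prev:
                raise ValueError("annotation indices must be strictly increasing")
            if len(sym) != 1:
                raise ValueError(f"annotation symbol must be one character, got {sym!r}")
            prev = idx

    def __len__(self) -> int:
        return len(self.signal)


@dataclass
class BeatDataset:
    """Fixed-length labelled heartbeat segments, the pipeline's unit of work."""

    beats: np.ndarray
    labels: np.ndarray
    beat_length: int
    class_names: list[str]

    def __post_init__(self) -> None:
        self.beats = np.asarray(self.beats, dtype=float).reshape(-1, self.beat_length)
        self.labels = np.asarray([str(label) for label in np.atleast_1d(self.labels)])
        if len(self.labels) != len(self.beats):
            raise ValueError(
                f"{len(self.beats)} beats but {len(self.labels)} labels"
            )
        known = set(self.class_names)
        for label in self.labels:
            if label not in known:
                raise ValueError(f"label {label!r} not in class_names {self.class_names}")

    def __len__(self) -> int:
        return len(self.beats)

    def class_counts(self) -> dict[str, int]:
        return {name: int((self.labels == name).sum()) for name in self.class_names}

    def subset(self, indices: np.ndarray) -> "BeatDataset":
        indices = np.asarray(indices)
        return BeatDataset(
            self.beats[indices], self.labels[indices], self.beat_length, list(self.class_names)
        )

    def label_indices(self) -> np.ndarray:
        """Integer-encode labels by their position in ``class_names``."""
        lookup = {name: i for i, name in enumerate(self.class_names)}
        return np.array([lookup[label] for label in self.labels], dtype=int)


# ---------------------------------------------------------------------------
# WFDB records
# ---------------------------------------------------------------------------

def _parse_header(header_path: str):
    try:
        with open(header_path, "r") as fh:
            lines = [
                line.strip()
                for line in fh
                if line.strip() and not line.startswith("#")
            ]
    except OSError as exc:
        raise FormatError(f"cannot read WFDB header {header_path}: {exc}") from exc
    if not lines:
        raise FormatError(f"empty WFDB header {header_path}")
    head = lines[0].split()
    if len(head) < 2:
        raise FormatError(f"malformed record line in {header_path}: {lines[0]!r}")
    record_name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else None
    signal_specs = []
    for line in lines[1 : 1 + n_sig]:
        fields = line.split()
        if len(fields) < 2:
            raise FormatError(f"malformed signal line in {header_path}: {line!r}")
        fmt = int(fields[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = 200.0, None
        if len(fields) > 2:
            gain_field = fields[2].split("/")[0]
            if "(" in gain_field:
                gain_part, base_part = gain_field.split("(")
                gain = float(gain_part)
                baseline = int(base_part.rstrip(")"))
            else:
                gain = float(gain_field)
        adc_zero = int(fields[4]) if len(fields) > 4 else 0
        if gain == 0:
            gain = 200.0
        if baseline is None:
            baseline = adc_zero
        signal_specs.append({"filename": fields[0], "format": fmt, "gain": gain, "baseline": baseline})
    return record_name, n_sig, fs, n_samples, signal_specs


def _read_dat(dat_path: str, fmt: int, n_sig: int, n_samples: int | None) -> np.ndarray:
    try:
        raw = np.fromfile(dat_path, dtype=np.uint8)
    except OSError as exc:
        raise FormatError(f"cannot read WFDB signal file {dat_path}: {exc}") from exc
    if fmt == 16:
        data = raw.view("<i2").astype(int)
        usable = (len(data) // n_sig) * n_sig
        digital = data[:usable].reshape(-1, n_sig)
    elif fmt == 212:
        usable = (len(raw) // 3) * 3
        b = raw[:usable].reshape(-1, 3).astype(int)
        first = b[:, 0] + ((b[:, 1] & 0x0F) << 8)
        second = b[:, 2] + ((b[:, 1] & 0xF0) << 4)
        pairs = np.empty(2 * len(b), dtype=int)
        pairs[0::2] = first
        pairs[1::2] = second
        pairs[pairs > 2047] -= 4096
        usable = (len(pairs) // n_sig) * n_sig
        digital = pairs[:usable].reshape(-1, n_sig)
    else:
        raise FormatError(f"unsupported WFDB signal format {fmt} in {dat_path}")
    if n_samples is not None:
        digital = digital[:n_samples]
    return digital


def _read_annotations(ann_path: str) -> list[tuple[int, str]]:
    try:
        raw = open(ann_path, "rb").read()
    except OSError as exc:
        raise FormatError(f"cannot read WFDB annotation file {ann_path}: {exc}") from exc
    annotations: list[tuple[int, str]] = []
    time = 0
    i = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if code == 0 and delta == 0:
            break
        if code == _SKIP:
            if i + 3 >= len(raw):
                raise FormatError(f"truncated SKIP annotation in {ann_path}")
            high = raw[i] | (raw[i + 1] << 8)
            low = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            time += struct.unpack("<i", struct.pack("<I", (high << 16) | low))[0]
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += delta + (delta & 1)
            continue
        time += delta
        symbol = ANNOTATION_SYMBOLS.get(code)
        if symbol is None:
            raise FormatError(f"unknown annotation code {code} in {ann_path}")
        annotations.append((time, symbol))
    return annotations


def read_wfdb_record(path: str, channel: int = 0, annotator: str = "atr") -> ECGRecord:
    """Read one WFDB record, returning the chosen channel in physical units.

    Parameters
    ----------
    path
        Record path without extension (``.../100`` for ``100.hea`` etc.).
    channel
        Signal channel to extract (0 is lead MLII for most MIT-BIH records).
    annotator
        Annotation file extension, ``atr`` by default.
    """
    base, ext = os.path.splitext(path)
    if ext == ".hea":
        path = base
    header_path = path + ".hea"
    if not os.path.exists(header_path):
        raise FormatError(f"WFDB header not found: {header_path}")
    record_name, n_sig, fs, n_samples, specs = _parse_header(header_path)
    if not 0 <= channel < n_sig:
        raise IndexError(f"channel {channel} out of range for {n_sig}-channel record")
    dat_path = os.path.join(os.path.dirname(path) or ".", specs[channel]["filename"])
    digital = _read_dat(dat_path, specs[channel]["format"], n_sig, n_samples)
    spec = specs[channel]
    physical = (digital[:, channel] - spec["baseline"]) / spec["gain"]
    ann_path = path + "." + annotator
    annotations = _read_annotations(ann_path) if os.path.exists(ann_path) else []
    annotations = [(t, s) for t, s in annotations if 0 <= t < len(physical)]
    return ECGRecord(record_name, fs, physical, annotations)


def write_wfdb_record(
    path: str,
    record: ECGRecord,
    gain: float = 200.0,
    annotator: str = "atr",
) -> None:
    """Write an :class:`ECGRecord` as a single-channel format-16 WFDB record.

    Primarily a fixture/round-trip utility: amplitudes are quantized to
    ``round(gain * mV)`` ADC units, the resolution of the stored format.
    """
    record_name = os.path.basename(path)
    digital = np.clip(np.round(record.signal * gain), -32768, 32767).astype("<i2")
    with open(path + ".hea", "w") as fh:
        fh.write(f"{record_name} 1 {record.sampling_rate:g} {len(digital)}\n")
        fh.write(f"{record_name}.dat 16 {gain:g}(0)/mV 16 0 {int(digital[0]) if len(digital) else 0} 0 0 ECG\n")
    digital.tofile(path + ".dat")
    out = bytearray()
    prev = 0
    for idx, symbol in record.annotations:
        code = ANNOTATION_CODES.get(symbol)
        if code is None:
            raise FormatError(f"symbol {symbol!r} has no MIT annotation code")
        delta = idx - prev
        if delta >= 1024:
            unsigned = struct.unpack("<I", struct.pack("<i", delta))[0]
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<HH", (unsigned >> 16) & 0xFFFF, unsigned & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        prev = idx
    out += struct.pack("<H", 0)
    with open(path + "." + annotator, "wb") as fh:
        fh.write(bytes(out))


# ---------------------------------------------------------------------------
# Beat tables (CSV)
# ---------------------------------------------------------------------------

def _looks_like_header(row: list[str]) -> bool:
    for token in row[:-1]:
        try:
            float(token)
        except ValueError:
            return True
    return False


def read_beat_table(path: str, beat_length: int) -> BeatDataset:
    """Read a delimited beat table: ``beat_length`` samples then a label."""
    beats: list[np.ndarray] = []
    labels: list[str] = []
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh)
        for row_number, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row_number == 1 and len(row) == beat_length + 1 and _looks_like_header(row):
                continue
            if len(row) != beat_length + 1:
                raise FormatError(
                    f"{path}: row {row_number} has {len(row)} fields, "
                    f"expected {beat_length} samples + 1 label"
                )
            try:
                beats.append(np.array(row[:-1], dtype=float))
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric sample in row {row_number}: {exc}"
                ) from exc
            labels.append(row[-1].strip())
    if not beats:
        return BeatDataset(
            np.empty((0, beat_length)), np.empty(0, dtype=str), beat_length, []
        )
    class_names = sorted(set(labels))
    return BeatDataset(np.vstack(beats), np.array(labels), beat_length, class_names)


def write_beat_table(dataset: BeatDataset, path: str, precision: int = 8) -> None:
    """Write a dataset as CSV readable by :func:`read_beat_table`.

    Samples are printed with ``repr``-faithful precision (default 8 significant
    digits after the point) so a round-trip reproduces the matrix on that
    printed precision.
    """
    fmt = f"%.{precision}g"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for beat, label in zip(dataset.beats, dataset.labels):
            writer.writerow([fmt % value for value in beat] + [label])
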