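"""Reading and writing ECG records and tabular artifacts.

Supported formats:

* WFDB (PhysioNet waveform database): ``.hea`` text header, ``.dat`` signal
  in 16-bit two's-complement little-endian interleaved format ("format 16"),
  and the ``.atr`` MIT annotation stream.  Only format 16 is handled; this is
  the format the MIT-BIH Arrhythmia Database ships in and the only one this
  package writes.
* CSV tables (RFC-4180, header row required) for labeled signal windows and
  feature matrices.

All sample indices exposed by this module are 0-based; WFDB files are
natively 0-based as well, so no shifting is required, but any 1-based source
added later must convert here and only here.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, SchemaError

__all__ = [
    "AnnotationEvent",
    "ECGRecord",
    "read_wfdb_record",
    "write_wfdb_record",
    "read_csv_dataset",
    "write_csv_dataset",
    "write_table",
]

# Default analog-to-digital gain used when writing: 200 ADC units per mV,
# the gain the MIT-BIH recordings themselves use.
_DEFAULT_GAIN = 200.0

# MIT annotation code <-> symbol table (beat and rhythm codes actually used
# by PhysioNet databases; a label outside this table is stored via an AUX
# string attached to a 'Q' (unclassifiable) annotation, which keeps the
# round trip exact for arbitrary text labels such as synthetic class codes).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class AnnotationEvent:
    """A labeled event at a sample position (beat, rhythm change, ...)."""

    sample_index: int
    label: str


@dataclass
class ECGRecord:
    """A single-channel ECG waveform with its sampling rate and annotations.

    ``signal`` is in millivolts.  Multi-channel sources are reduced to one
    user-selected channel at read time; all downstream computation is
    single-signal.
    """

    record_id: str
    signal: np.ndarray
    fs: float
    annotations: list[AnnotationEvent] = field(default_factory=list)
    source: str = "synthetic"  # one of {"wfdb", "csv", "synthetic"}

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1:
            raise ValueError("ECGRecord signal must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.size and not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains NaN/Inf samples; rejected at ingestion")
        n = self.signal.size
        prev = -1
        for ev in self.annotations:
            if not 0 <= ev.sample_index < n:
                raise ValueError(
                    f"annotation index {ev.sample_index} outside [0, {n})"
                )
            if ev.sample_index < prev:
                raise ValueError("annotation indices must be nondecreasing")
            prev = ev.sample_index

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.fs


# ---------------------------------------------------------------------------
# WFDB header + signal
# ---------------------------------------------------------------------------

def _parse_header(hea_path: Path):
    try:
        lines = [
            ln.strip()
            for ln in hea_path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    except OSError as exc:
        raise FormatError(f"cannot read WFDB header {hea_path}: {exc}") from exc
    if not lines:
        raise FormatError(f"empty WFDB header {hea_path}")
    rec_tokens = lines[0].split()
    if len(rec_tokens) < 3:
        raise FormatError(f"malformed record line in {hea_path!s}: {lines[0]!r}")
    name = rec_tokens[0].split("/")[0]
    try:
        n_sig = int(rec_tokens[1])
        fs = float(rec_tokens[2].split("/")[0])
        n_samp = int(rec_tokens[3]) if len(rec_tokens) > 3 else None
    except ValueError as exc:
        raise FormatError(f"malformed record line in {hea_path!s}") from exc
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise FormatError(f"malformed signal line in {hea_path!s}: {ln!r}")
        fname, fmt = tok[0], tok[1].split("x")[0].split(":")[0].split("+")[0]
        if fmt != "16":
            raise FormatError(
                f"unsupported WFDB signal format {fmt!r} in {hea_path!s} "
                "(only format 16 is handled)"
            )
        gain, baseline = _DEFAULT_GAIN, None
        if len(tok) > 2:
            gtok = tok[2].split("/")[0]
            if "(" in gtok:
                gpart, bpart = gtok.split("(")
                gain = float(gpart) if gpart else _DEFAULT_GAIN
                baseline = int(bpart.rstrip(")"))
            elif gtok:
                gain = float(gtok)
        if gain == 0:
            gain = _DEFAULT_GAIN
        adczero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adczero
        signals.append({"file": fname, "gain": gain, "baseline": baseline})
    if len(signals) != n_sig:
        raise FormatError(f"header {hea_path!s} declares {n_sig} signals, "
                          f"found {len(signals)} signal lines")
    return name, n_sig, fs, n_samp, signals


def read_wfdb_record(path: str | Path, channel: int = 0) -> ECGRecord:
    """Read one channel of a WFDB record (``.hea`` + format-16 ``.dat``).

    ``path`` may name the header file or the record stem.  Annotations are
    loaded from a ``.atr`` sidecar when one exists; a missing sidecar yields
    an empty annotation list.  Raises :class:`FormatError` for missing or
    corrupt files and ``ValueError`` for a channel out of range.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"WFDB header not found: {hea}")
    name, n_sig, fs, n_samp, signals = _parse_header(hea)
    if not 0 <= channel < n_sig:
        raise ValueError(f"channel {channel} out of range for {n_sig}-channel record")
    dat = hea.parent / signals[channel]["file"]
    if not dat.exists():
        raise FormatError(f"WFDB signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size % n_sig:
        raise FormatError(
            f"signal file {dat} length {raw.size} not divisible by {n_sig} channels"
        )
    if n_samp is not None and raw.size // n_sig != n_samp:
        raise FormatError(
            f"signal file {dat} holds {raw.size // n_sig} samples per channel, "
            f"header declares {n_samp}"
        )
    adc = raw.reshape(-1, n_sig)[:, channel].astype(float)
    sig = (adc - signals[channel]["baseline"]) / signals[channel]["gain"]

    atr = hea.with_suffix(".atr")
    annotations = _read_annotations(atr) if atr.exists() else []
    annotations = [a for a in annotations if 0 <= a.sample_index < sig.size]
    return ECGRecord(record_id=name, signal=sig, fs=fs,
                     annotations=annotations, source="wfdb")


def write_wfdb_record(record: ECGRecord, path: str | Path) -> None:
    """Write ``record`` as WFDB format 16 (``.hea``/``.dat``; ``.atr`` when
    annotations exist).  ``read_wfdb_record`` inverts this up to one ADC
    quantum (1/gain mV) of quantization."""
    path = Path(path)
    if path.suffix == ".hea":
        path = path.with_suffix("")
    if record.signal.size == 0:
        raise ValueError("cannot write an empty signal")
    path.parent.mkdir(parents=True, exist_ok=True)
    name = path.name
    adc = np.clip(np.rint(record.signal * _DEFAULT_GAIN), -32768, 32767).astype("<i2")
    try:
        adc.tofile(path.with_suffix(".dat"))
        fs_txt = f"{record.fs:g}"
        header = (
            f"{name} 1 {fs_txt} {adc.size}\n"
            f"{name}.dat 16 {_DEFAULT_GAIN:g}(0)/mV 16 0 {int(adc[0])} 0 0 ch0\n"
        )
        path.with_suffix(".hea").write_text(header)
        if record.annotations:
            path.with_suffix(".atr").write_bytes(
                _encode_annotations(record.annotations)
            )
    except OSError as exc:
        raise OSError(f"cannot write WFDB record at {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# MIT annotation stream (.atr)
# ---------------------------------------------------------------------------

def _encode_annotations(annotations: list[AnnotationEvent]) -> bytes:
    out = bytearray()
    prev = 0
    for ev in sorted(annotations, key=lambda a: a.sample_index):
        delta = ev.sample_index - prev
        prev = ev.sample_index
        code = _SYMBOL_TO_CODE.get(ev.label)
        aux = None if code is not None else ev.label.encode("utf-8")
        if code is None:
            code = _SYMBOL_TO_CODE["Q"]
        if delta > 1023 or delta < 0:
            # SKIP: code 59 with zero time, followed by the 4-byte interval
            # (high 16 bits first, each word little-endian), then the
            # annotation word with a zero time field.
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | (delta & 0x3FF))
        if aux is not None:
            out += struct.pack("<H", (_AUX << 10) | len(aux))
            out += aux
            if len(aux) % 2:
                out += b"\x00"
    out += struct.pack("<H", 0)  # terminator
    return bytes(out)


def _read_annotations(path: Path) -> list[AnnotationEvent]:
    try:
        data = path.read_bytes()
    except OSError as exc:
        raise FormatError(f"cannot read annotation file {path}: {exc}") from exc
    events: list[AnnotationEvent] = []
    pos, prev, pending = 0, 0, 0
    while pos + 2 <= len(data):
        (word,) = struct.unpack_from("<H", data, pos)
        pos += 2
        if word == 0:
            break
        code, t = word >> 10, word & 0x3FF
        if code == _SKIP:
            if pos + 4 > len(data):
                raise FormatError(f"truncated SKIP in {path}")
            (hi,) = struct.unpack_from("<H", data, pos)
            (lo,) = struct.unpack_from("<H", data, pos + 2)
            pos += 4
            interval = (hi << 16) | lo
            if interval >= 1 << 31:
                interval -= 1 << 32
            pending += interval
        elif code == _AUX:
            n = t
            aux = data[pos : pos + n].decode("utf-8",
                                             errors="replace").rstrip("\x00")
            pos += n + (n % 2)
            if events:
                events[-1].label = aux
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            prev = prev + pending + t
            pending = 0
            events.append(
                AnnotationEvent(sample_index=prev,
                                label=_CODE_TO_SYMBOL.get(code, "Q"))
            )
    return events


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def read_csv_dataset(path: str | Path) -> list[tuple[np.ndarray, int]]:
    """Read a CSV of labeled signal windows: one row per window, a ``label``
    column in {1..5}, remaining columns numeric samples (or features).

    Returns an ordered list of ``(values, label)`` pairs.  A missing label
    column raises :class:`SchemaError`; any non-numeric or NaN cell raises
    :class:`ParseError` naming the row and column (NaN inputs are rejected
    at ingestion, never imputed).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read CSV {path}: {exc}") from exc
    if "label" not in df.columns:
        raise SchemaError(f"{path}: missing required 'label' column")
    value_cols = [c for c in df.columns if c != "label"]
    rows: list[tuple[np.ndarray, int]] = []
    for i, (_, row) in enumerate(df.iterrows()):
        vals = pd.to_numeric(row[value_cols], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ParseError(
                f"{path}: non-numeric or NaN cell at row {i}, "
                f"column {value_cols[bad[0]]!r}"
            )
        lab = row["label"]
        try:
            lab = int(lab)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: bad label at row {i}: {row['label']!r}") from exc
        rows.append((vals, lab))
    return rows


def write_csv_dataset(rows: list[tuple[np.ndarray, int]], path: str | Path) -> None:
    """Inverse of :func:`read_csv_dataset` (sample columns ``s0..s{W-1}``)."""
    path = Path(path)
    if rows:
        w = len(rows[0][0])
        cols = [f"s{i}" for i in range(w)]
        df = pd.DataFrame([list(v) for v, _ in rows], columns=cols)
        df["label"] = [lab for _, lab in rows]
    else:
        df = pd.DataFrame(columns=["label"])
    df.to_csv(path, index=False)


def write_table(rows, path: str | Path) -> None:
    """Write generic tabular rows (list of dicts or a DataFrame) as CSV,
    preserving column order and header."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(Path(path), index=False)
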