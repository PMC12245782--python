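"""Signal conditioning: normalization, band-pass filtering, QRS detection,
segmentation, and segment fusion.

Conventions
-----------
* Amplitude normalization is min-max to [0, 1]; an optional rescale to
  [-1, 1] is available for users who prefer a symmetric range.
* The band-pass filter is a 4th-order Butterworth applied forward-backward
  (zero phase), default passband 0.5–40 Hz — the standard ECG band that keeps
  QRS morphology while removing baseline wander and mains/muscle noise.
* Windows are 0-based, half-open ``[start, start + W)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DegenerateInputError
from .io_formats import ECGRecord

__all__ = [
    "FilterSpec",
    "Segment",
    "normalize",
    "bandpass",
    "detect_r_peaks",
    "segment",
    "fuse_segments",
]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter specification (Butterworth, zero-phase)."""

    low_hz: float = 0.5
    high_hz: float = 40.0
    order: int = 4
    fs: float = 360.0

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"need 0 < low_hz < high_hz, got [{self.low_hz}, {self.high_hz}]"
            )
        if self.high_hz >= self.fs / 2:
            raise ValueError(
                f"high cutoff {self.high_hz} Hz >= Nyquist {self.fs / 2} Hz"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass
class Segment:
    """A fixed-length window of samples, the unit of feature extraction."""

    samples: np.ndarray
    fs: float
    label: int | None = None
    record_id: str = ""
    start_index: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.label is not None and self.label not in (1, 2, 3, 4, 5):
            raise ValueError(f"segment label must be in 1..5, got {self.label}")


def normalize(x, out_range: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """Min-max normalize ``x`` so its amplitude spans ``out_range`` exactly.

    The default maps to [0, 1]: ``(x - min x) / (max x - min x)``.  A
    constant signal makes the denominator zero and raises
    :class:`DegenerateInputError`.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("normalize requires at least 2 samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateInputError(
            "constant signal: min-max normalization denominator is zero"
        )
    y = (x - lo) / (hi - lo)
    a, b = out_range
    return a + (b - a) * y


def _min_len_for(sos: np.ndarray) -> int:
    # sosfiltfilt pads with 3 * (2 * n_sections + 1) samples on each side.
    return 3 * (2 * len(sos) + 1)


def bandpass(x, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output has the same length as the
    input, unit passband gain, and strong stopband attenuation."""
    if spec is None:
        spec = FilterSpec()
    x = np.asarray(x, dtype=float)
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz],
                     btype="bandpass", fs=spec.fs, output="sos")
    if x.size <= max(3 * spec.order, _min_len_for(sos)):
        raise ValueError(
            f"signal of length {x.size} too short for order-{spec.order} "
            "zero-phase band-pass"
        )
    return sps.sosfiltfilt(sos, x)


def detect_r_peaks(x, fs: float) -> np.ndarray:
    """Detect R peaks by amplitude threshold on the differentiated, squared,
    moving-averaged signal, with a 0.2 s refractory period
    (Pan–Tompkins-style, without the adaptive thresholding machinery; the
    derivative stage suppresses the wide, low-slope T wave).

    Expects a filtered signal; returns strictly increasing 0-based indices
    (possibly empty).  Each reported index is snapped to the local maximum of
    the raw input within ±0.1 s of the detected energy peak.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return np.array([], dtype=int)
    d = x - np.median(x)
    slope = np.gradient(d)
    energy = slope * slope
    win = max(1, int(round(0.15 * fs)))
    ma = np.convolve(energy, np.ones(win) / win, mode="same")
    peak = ma.max()
    if peak <= 0:
        return np.array([], dtype=int)
    refractory = max(1, int(round(0.2 * fs)))
    locs, _ = sps.find_peaks(ma, height=0.1 * peak, distance=refractory)
    if locs.size == 0:
        return np.array([], dtype=int)
    snap = max(1, int(round(0.1 * fs)))
    refined = []
    for p in locs:
        lo, hi = max(0, p - snap), min(x.size, p + snap + 1)
        refined.append(lo + int(np.argmax(d[lo:hi])))
    # Snapping can collapse neighbours; re-enforce the refractory period,
    # keeping the larger-amplitude peak of any conflicting pair.
    out: list[int] = []
    for p in sorted(set(refined)):
        if out and p - out[-1] < refractory:
            if d[p] > d[out[-1]]:
                out[-1] = p
        else:
            out.append(p)
    return np.array(out, dtype=int)


def segment(record: ECGRecord, mode: str = "fixed",
            window_s: float = 1.0, stride_s: float = 1.0) -> list[Segment]:
    """Cut a record into equal-length labeled windows.

    ``fixed`` mode tiles the record: ``floor((N - W) / S) + 1`` windows of
    ``W = round(window_s * fs)`` samples at stride ``S``; a window longer
    than the record yields an empty list.  ``rpeak_centered`` mode places one
    window centered on every detected R peak far enough from the edges.

    A window's label is inherited from the annotation nearest to the window
    center among annotations inside the window (ties break toward the earlier
    annotation); windows containing no annotation are unlabeled.  Only
    annotation labels that parse as a class code 1–5 are used.
    """
    fs = record.fs
    W = int(round(window_s * fs))
    if W < 2:
        raise ValueError(f"window of {W} samples is too short")
    N = record.signal.size
    ann_idx = np.array([a.sample_index for a in record.annotations], dtype=int)
    ann_lab = [a.label for a in record.annotations]

    def label_for(start: int) -> int | None:
        center = start + (W - 1) / 2
        inside = np.flatnonzero((ann_idx >= start) & (ann_idx < start + W))
        best, best_d = None, None
        for k in inside:
            try:
                lab = int(ann_lab[k])
            except ValueError:
                continue
            if lab not in (1, 2, 3, 4, 5):
                continue
            dist = abs(ann_idx[k] - center)
            if best is None or dist < best_d:  # tie keeps earlier annotation
                best, best_d = lab, dist
        return best

    starts: list[int]
    if mode == "fixed":
        S = max(1, int(round(stride_s * fs)))
        starts = list(range(0, N - W + 1, S)) if N >= W else []
    elif mode == "rpeak_centered":
        peaks = detect_r_peaks(record.signal, fs)
        starts = [int(p) - W // 2 for p in peaks
                  if p - W // 2 >= 0 and p - W // 2 + W <= N]
    else:
        raise ValueError(f"unknown segmentation mode {mode!r}")

    return [
        Segment(samples=record.signal[s : s + W].copy(), fs=fs,
                label=label_for(s), record_id=record.record_id, start_index=s)
        for s in starts
    ]


def fuse_segments(segments: list[Segment]) -> Segment:
    """Fuse equal-length segments into one comprehensive segment by
    point-wise arithmetic mean; sampling rate and provenance are taken from
    the first segment, and the label is kept only if all inputs agree."""
    if not segments:
        raise ValueError("cannot fuse an empty list of segments")
    n = segments[0].samples.size
    if any(s.samples.size != n for s in segments):
        raise ValueError("segments must all have equal length to fuse")
    stacked = np.stack([s.samples for s in segments])
    labels = {s.label for s in segments}
    return Segment(
        samples=stacked.mean(axis=0),
        fs=segments[0].fs,
        label=labels.pop() if len(labels) == 1 else None,
        record_id=segments[0].record_id,
        start_index=segments[0].start_index,
    )
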