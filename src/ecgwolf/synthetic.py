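"""Seeded generator of five-class synthetic ECG records and planted-structure
feature tables, so every pipeline stage is testable without downloads.

Each beat is a sum of Gaussian bumps (P, Q, R, S, T waves) placed on a beat
train whose RR intervals are log-normal with a class-specific mean and
coefficient of variation.  The five rhythm classes:

====  ============================  =====================================
code  class                         generator behaviour
====  ============================  =====================================
1     Atrial Fibrillation           irregular RR (CV 0.25), no P waves
2     Supraventricular Tachycardia  fast regular rhythm (RR 0.35 s)
3     Bradycardia                   slow rhythm (RR 1.333 s)
4     Premature Ventricular         sinus base rhythm with wide-QRS
      Contractions                  ectopic beats (no P, inverted T)
5     Atrial Flutter                fast rhythm, 5 Hz sawtooth baseline
                                    (≈300/min atrial rate, 2:1 conduction),
                                    no distinct P waves
====  ============================  =====================================

This is a phenomenological model, not a dynamical one: it is rich enough to
exercise filtering, QRS detection, segmentation, and class-separable window
features, and simple enough that beat times and class structure are known
exactly.  R-peak times are recorded as annotations labeled with the class
code.  Every artifact is a pure function of (profile, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .features import FeatureMatrix
from .io_formats import AnnotationEvent, ECGRecord
from .preprocess import FilterSpec, Segment, bandpass, normalize, segment

__all__ = [
    "ClassProfile",
    "SynthConfig",
    "CLASS_PROFILES",
    "CLASS_NAMES",
    "generate_record",
    "generate_dataset",
    "generate_feature_table",
    "split_70_15_15",
]

CLASS_NAMES = {
    1: "Atrial Fibrillation",
    2: "Supraventricular Tachycardia",
    3: "Bradycardia",
    4: "Premature Ventricular Contractions",
    5: "Atrial Flutter",
}


@dataclass(frozen=True)
class ClassProfile:
    """Rhythm statistics and beat-morphology flags for one class."""

    class_id: int
    rr_mean_s: float
    rr_cv: float
    suppress_p: bool = False
    widen_qrs: bool = False
    sawtooth_baseline: bool = False
    ectopic_rate: float = 0.0

    def __post_init__(self):
        if self.rr_mean_s <= 0.25:
            raise ValueError("rr_mean_s must exceed 0.25 s")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be nonnegative")


CLASS_PROFILES: dict[int, ClassProfile] = {
    1: ClassProfile(1, rr_mean_s=0.75, rr_cv=0.25, suppress_p=True),
    2: ClassProfile(2, rr_mean_s=0.35, rr_cv=0.02),
    3: ClassProfile(3, rr_mean_s=1.333, rr_cv=0.05),
    4: ClassProfile(4, rr_mean_s=0.80, rr_cv=0.05, widen_qrs=True,
                    ectopic_rate=0.3),
    5: ClassProfile(5, rr_mean_s=0.40, rr_cv=0.03, suppress_p=True,
                    sawtooth_baseline=True),
}


@dataclass(frozen=True)
class SynthConfig:
    fs: float = 360.0
    duration_s: float = 30.0
    n_per_class: int = 100
    noise_sd: float = 0.05           # mV, additive Gaussian observation noise
    seed: int = 0
    planted_informative: int = 5     # feature-table mode
    planted_noise: int = 45
    window_s: float = 5.0            # dataset segmentation window
    stride_s: float = 2.5

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


# (time offset from R in s, width in s, amplitude in mV)
_NORMAL_WAVES = {
    "P": (-0.20, 0.025, 0.15),
    "Q": (-0.04, 0.010, -0.15),
    "R": (0.00, 0.012, 1.00),
    "S": (0.035, 0.012, -0.25),
    "T": (0.30, 0.060, 0.35),
}
_ECTOPIC_WAVES = {                  # wide-QRS ventricular ectopic: no P wave
    "R": (0.00, 0.050, 1.20),
    "S": (0.09, 0.040, -0.40),
    "T": (0.35, 0.070, -0.30),      # discordant (inverted) T
}
_SAWTOOTH_HZ = 5.0                  # flutter waves, ~300/min atrial rate
_SAWTOOTH_MV = 0.20


def _add_bump(sig: np.ndarray, fs: float, t0: float, width: float,
              amp: float) -> None:
    lo = max(0, int((t0 - 4 * width) * fs))
    hi = min(sig.size, int((t0 + 4 * width) * fs) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    sig[lo:hi] += amp * np.exp(-((t - t0) ** 2) / (2 * width ** 2))


def _draw_rr(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0:
        return mean
    sigma2 = np.log(1.0 + cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def generate_record(profile: ClassProfile, cfg: SynthConfig,
                    rng: np.random.Generator | None = None,
                    record_id: str | None = None) -> ECGRecord:
    """One synthetic single-channel record for the given rhythm class.

    RR intervals are log-normal with the profile's mean and CV; beat
    morphologies and class flags are applied per beat; R-peak times become
    annotations labeled with the class code.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t_total = n / cfg.fs
    sig = np.zeros(n)

    beat_times = []
    t = 0.35                         # lead-in before the first beat
    while t < t_total - 0.35:
        beat_times.append(t)
        t += max(0.26, _draw_rr(rng, profile.rr_mean_s, profile.rr_cv))
    if not beat_times:
        raise ValueError(
            f"duration {cfg.duration_s} s too short for one beat of class "
            f"{profile.class_id}"
        )

    annotations = []
    for bt in beat_times:
        ectopic = (profile.ectopic_rate > 0
                   and rng.random() < profile.ectopic_rate)
        waves = _ECTOPIC_WAVES if ectopic else _NORMAL_WAVES
        for name, (off, width, amp) in waves.items():
            if name == "P" and profile.suppress_p:
                continue
            if name == "R" and profile.widen_qrs and ectopic:
                width *= 1.1
            _add_bump(sig, cfg.fs, bt + off, width, amp)
        annotations.append(
            AnnotationEvent(sample_index=int(round(bt * cfg.fs)),
                            label=str(profile.class_id))
        )

    if profile.sawtooth_baseline:
        tv = np.arange(n) / cfg.fs
        sig += _SAWTOOTH_MV * sps.sawtooth(2 * np.pi * _SAWTOOTH_HZ * tv,
                                           width=0.7)
    if cfg.noise_sd > 0:
        sig += rng.normal(0.0, cfg.noise_sd, size=n)

    return ECGRecord(
        record_id=record_id or f"synth_c{profile.class_id}",
        signal=sig, fs=cfg.fs, annotations=annotations, source="synthetic",
    )


def generate_dataset(cfg: SynthConfig,
                     preprocessed: bool = True
                     ) -> tuple[list[Segment], np.ndarray]:
    """Balanced labeled segments across the five classes, shuffled with the
    seed and ready for feature extraction.

    Each class contributes ``cfg.n_per_class`` fixed windows
    (``cfg.window_s`` s long, stride ``cfg.stride_s``) cut from as many
    records as needed.  When ``preprocessed`` (the default) each record is
    min-max normalized and band-pass filtered (0.5–40 Hz) before
    segmentation, mirroring the analysis pipeline.
    """
    rng = np.random.default_rng(cfg.seed)
    spec = FilterSpec(fs=cfg.fs)
    segments: list[Segment] = []
    for class_id, profile in CLASS_PROFILES.items():
        collected: list[Segment] = []
        rec_idx = 0
        while len(collected) < cfg.n_per_class:
            rec = generate_record(profile, cfg, rng=rng,
                                  record_id=f"synth_c{class_id}_r{rec_idx}")
            if preprocessed:
                rec = ECGRecord(
                    record_id=rec.record_id,
                    signal=bandpass(normalize(rec.signal), spec),
                    fs=rec.fs, annotations=rec.annotations,
                    source="synthetic",
                )
            collected += segment(rec, mode="fixed", window_s=cfg.window_s,
                                 stride_s=cfg.stride_s)
            rec_idx += 1
        segments += collected[: cfg.n_per_class]
    order = rng.permutation(len(segments))
    segments = [segments[i] for i in order]
    labels = np.array([s.label for s in segments], dtype=int)
    return segments, labels


def generate_feature_table(cfg: SynthConfig
                           ) -> tuple[FeatureMatrix, np.ndarray]:
    """Feature table with planted ground truth for selection-recovery tests.

    Informative columns carry class-dependent Gaussian means (separation 6
    within-class standard deviations, one discriminative class per column in
    a one-hot layout); noise columns are class-independent standard normals.
    Column order is shuffled; returns the matrix and the true informative
    mask in the shuffled order.
    """
    if cfg.planted_informative < 1:
        raise ValueError("planted_informative must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    n_classes = 5
    n = cfg.n_per_class * n_classes
    labels = np.repeat(np.arange(1, n_classes + 1), cfg.n_per_class)
    d = cfg.planted_informative + cfg.planted_noise
    X = rng.normal(0.0, 1.0, size=(n, d))
    separation = 6.0
    for j in range(cfg.planted_informative):
        target_class = (j % n_classes) + 1
        X[labels == target_class, j] += separation
    true_mask = np.zeros(d, dtype=bool)
    true_mask[: cfg.planted_informative] = True

    perm = rng.permutation(d)
    X = X[:, perm]
    true_mask = true_mask[perm]
    row_order = rng.permutation(n)
    fm = FeatureMatrix(
        values=X[row_order],
        feature_names=[f"f{j:02d}" for j in range(d)],
        labels=labels[row_order],
    )
    return fm, true_mask


def split_70_15_15(items, seed: int, stratify_labels=None):
    """Seeded randomized 70–15–15 partition into (train, validation, test).

    Sizes are ``round(0.70 n)``, ``round(0.15 n)``, remainder; the three
    parts are disjoint and exhaustive.  With ``stratify_labels`` the split
    is applied per class, preserving class proportions within ±1 item.
    Returns three lists of items.
    """
    items = list(items)
    n = len(items)
    if n < 20:
        raise ValueError("need at least 20 items to split 70-15-15")
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        perm = rng.permutation(n)
        n_tr = round(0.70 * n)
        n_va = round(0.15 * n)
        tr, va, te = (perm[:n_tr], perm[n_tr : n_tr + n_va],
                      perm[n_tr + n_va :])
    else:
        stratify_labels = np.asarray(stratify_labels)
        if stratify_labels.size != n:
            raise ValueError("stratify_labels length must match items")
        tr, va, te = [], [], []
        for c in np.unique(stratify_labels):
            idx = np.flatnonzero(stratify_labels == c)
            idx = idx[rng.permutation(idx.size)]
            n_tr = round(0.70 * idx.size)
            n_va = round(0.15 * idx.size)
            tr += list(idx[:n_tr])
            va += list(idx[n_tr : n_tr + n_va])
            te += list(idx[n_tr + n_va :])
        tr, va, te = np.array(tr), np.array(va), np.array(te)
    return ([items[i] for i in tr], [items[i] for i in va],
            [items[i] for i in te])
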