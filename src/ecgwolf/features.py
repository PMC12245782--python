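"""Formula-defined feature extraction and LDA dimensionality reduction.

Per segment the registry is, in fixed order:

1. signal energy  ``E = sum |x[n]|^2``,
2. six basic statistics (mean, population variance, median, max, min, RMS),
3. discrete-wavelet sub-band energy and variance for detail levels
   ``d1..dL`` and the final approximation (default db4, 4 levels,
   periodized so the orthogonal transform conserves energy),
4. four texture features (contrast, energy, homogeneity, correlation) from a
   1-D gray-level co-occurrence matrix of the amplitude-quantized segment.

The co-occurrence matrix is usually an image technique; here it is applied
to a single signal as co-occurrence of quantized amplitude pairs at a fixed
sample lag (default 1, symmetric, 8 levels).

Variance is the population form (divisor N) throughout this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import linalg as sla

from .errors import DegenerateInputError
from .preprocess import Segment

__all__ = [
    "FeatureMatrix",
    "WaveletSpec",
    "GLCMSpec",
    "energy",
    "basic_stats",
    "wavelet_features",
    "glcm_features",
    "extract_all",
    "lda_reduce",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Named feature columns per segment; the feature-selection search space."""

    values: np.ndarray          # (n_segments, n_features)
    feature_names: list[str]
    labels: np.ndarray          # (n_segments,) int class codes

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D matrix")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("column count must match feature_names length")
        if self.values.shape[0] != self.labels.size:
            raise ValueError("row count must match labels length")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN/Inf entries")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, bits: np.ndarray) -> "FeatureMatrix":
        bits = np.asarray(bits, dtype=bool)
        return FeatureMatrix(
            values=self.values[:, bits],
            feature_names=[n for n, b in zip(self.feature_names, bits) if b],
            labels=self.labels.copy(),
        )

    def to_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        import pandas as pd
        df = pd.read_csv(path)
        if "label" not in df.columns:
            from .errors import SchemaError
            raise SchemaError(f"{path}: missing required 'label' column")
        labels = df.pop("label").to_numpy(dtype=int)
        return cls(values=df.to_numpy(dtype=float),
                   feature_names=list(df.columns), labels=labels)


@dataclass(frozen=True)
class WaveletSpec:
    """Discrete wavelet decomposition settings."""

    mother: str = "db4"
    levels: int = 4

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


@dataclass(frozen=True)
class GLCMSpec:
    """1-D co-occurrence settings: quantization levels and sample lag."""

    levels: int = 8
    lag: int = 1
    symmetric: bool = True

    def __post_init__(self):
        if not 2 <= self.levels <= 256:
            raise ValueError("levels must be in [2, 256]")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")


def energy(x) -> float:
    """Signal energy ``sum |x[n]|^2`` over the segment; >= 0, and 0 iff the
    segment is all-zero."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("energy of an empty segment is undefined")
    return float(np.sum(np.abs(x) ** 2))


def basic_stats(x) -> dict[str, float]:
    """Mean, population variance (divisor N), median, max, min and RMS."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("statistics of an empty segment are undefined")
    mu = float(np.mean(x))
    return {
        "mean": mu,
        "variance": float(np.mean((x - mu) ** 2)),
        "median": float(np.median(x)),
        "max": float(np.max(x)),
        "min": float(np.min(x)),
        "rms": float(np.sqrt(np.mean(x ** 2))),
    }


def wavelet_feature_names(spec: WaveletSpec) -> list[str]:
    names = []
    for lev in range(1, spec.levels + 1):
        names += [f"wl_d{lev}_energy", f"wl_d{lev}_var"]
    names += [f"wl_a{spec.levels}_energy", f"wl_a{spec.levels}_var"]
    return names


def wavelet_features(x, spec: WaveletSpec | None = None) -> dict[str, float]:
    """Sub-band energy and variance from a discrete wavelet decomposition.

    The signal is decomposed to ``spec.levels`` scales (periodized boundary,
    so for an orthogonal mother wavelet the sub-band energies sum to the
    total signal energy).  Keys encode band and statistic, e.g.
    ``wl_d1_energy`` for the finest detail band.
    """
    if spec is None:
        spec = WaveletSpec()
    x = np.asarray(x, dtype=float)
    if x.size < 2 ** spec.levels:
        raise ValueError(
            f"segment of {x.size} samples too short for a "
            f"{spec.levels}-level decomposition"
        )
    coeffs = pywt.wavedec(x, spec.mother, level=spec.levels,
                          mode="periodization")
    # wavedec returns [aL, dL, ..., d1]; report d1..dL then the approximation.
    approx, details = coeffs[0], coeffs[1:][::-1]
    out: dict[str, float] = {}
    for lev, d in enumerate(details, start=1):
        out[f"wl_d{lev}_energy"] = energy(d)
        out[f"wl_d{lev}_var"] = basic_stats(d)["variance"]
    out[f"wl_a{spec.levels}_energy"] = energy(approx)
    out[f"wl_a{spec.levels}_var"] = basic_stats(approx)["variance"]
    return out


def glcm_features(x, spec: GLCMSpec | None = None) -> dict[str, float]:
    """Texture features of the amplitude co-occurrence matrix.

    The (min-max normalized) segment is quantized to ``spec.levels`` integer
    levels; co-occurrences of ``(q[t], q[t+lag])`` are counted (plus the
    transpose when symmetric) and normalized to probabilities ``P(i, j)``.
    Returns::

        contrast    = sum P(i,j) (i-j)^2
        energy      = sum P(i,j)^2
        homogeneity = sum P(i,j) / (1 + (i-j)^2)
        correlation = (sum i*j*P(i,j) - mu_i*mu_j) / (sigma_i*sigma_j)

    A constant segment occupies the single cell (0, 0): contrast 0,
    energy 1, homogeneity 1, and an undefined (NaN) correlation because both
    marginal standard deviations vanish; callers drop such rows upstream.
    """
    if spec is None:
        spec = GLCMSpec()
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("co-occurrence of an empty segment is undefined")
    if spec.lag >= x.size:
        raise ValueError(f"lag {spec.lag} >= segment length {x.size}")
    lo, hi = x.min(), x.max()
    if hi > lo:
        q = np.minimum(((x - lo) / (hi - lo) * spec.levels).astype(int),
                       spec.levels - 1)
    else:
        q = np.zeros(x.size, dtype=int)
    counts = np.zeros((spec.levels, spec.levels), dtype=float)
    np.add.at(counts, (q[:-spec.lag], q[spec.lag:]), 1.0)
    if spec.symmetric:
        counts = counts + counts.T
    P = counts / counts.sum()
    i = np.arange(spec.levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(np.sum(P * (ii - jj) ** 2))
    energy_ = float(np.sum(P ** 2))
    homogeneity = float(np.sum(P / (1.0 + (ii - jj) ** 2)))
    p_i, p_j = P.sum(axis=1), P.sum(axis=0)
    mu_i, mu_j = float(i @ p_i), float(i @ p_j)
    sd_i = float(np.sqrt((i - mu_i) ** 2 @ p_i))
    sd_j = float(np.sqrt((i - mu_j) ** 2 @ p_j))
    if sd_i > 0 and sd_j > 0:
        corr = float((np.sum(ii * jj * P) - mu_i * mu_j) / (sd_i * sd_j))
    else:
        corr = float("nan")
    return {"contrast": contrast, "energy": energy_,
            "homogeneity": homogeneity, "correlation": corr}


def feature_names(wspec: WaveletSpec, gspec: GLCMSpec) -> list[str]:
    """The deterministic column order used by :func:`extract_all`."""
    return (
        ["energy", "mean", "variance", "median", "max", "min", "rms"]
        + wavelet_feature_names(wspec)
        + ["glcm_contrast", "glcm_energy", "glcm_homogeneity", "glcm_correlation"]
    )


def extract_all(segments: list[Segment],
                wspec: WaveletSpec | None = None,
                gspec: GLCMSpec | None = None) -> FeatureMatrix:
    """One feature row per labeled segment.

    Rows with any undefined feature (e.g. a constant segment's correlation)
    are dropped with a logged count; if every row is dropped an error is
    raised.
    """
    if wspec is None:
        wspec = WaveletSpec()
    if gspec is None:
        gspec = GLCMSpec()
    if not segments:
        raise ValueError("no segments to extract features from")
    names = feature_names(wspec, gspec)
    rows, labels = [], []
    dropped = 0
    for seg in segments:
        if seg.label is None:
            raise ValueError("extract_all requires labeled segments")
        x = seg.samples
        row = [energy(x)]
        st = basic_stats(x)
        row += [st["mean"], st["variance"], st["median"],
                st["max"], st["min"], st["rms"]]
        wf = wavelet_features(x, wspec)
        row += [wf[n] for n in wavelet_feature_names(wspec)]
        gf = glcm_features(x, gspec)
        row += [gf["contrast"], gf["energy"], gf["homogeneity"],
                gf["correlation"]]
        if not np.all(np.isfinite(row)):
            dropped += 1
            continue
        rows.append(row)
        labels.append(seg.label)
    if dropped:
        logger.warning("extract_all: dropped %d segment(s) with undefined features",
                       dropped)
    if not rows:
        raise DegenerateInputError("all segments produced undefined features")
    return FeatureMatrix(values=np.array(rows), feature_names=names,
                         labels=np.array(labels))


def lda_reduce(fm: FeatureMatrix, n_components: int = 4) -> FeatureMatrix:
    """Supervised linear projection onto the top discriminant directions.

    Solves the generalized symmetric eigenproblem ``S_b v = lambda S_w v``
    for the between- and within-class scatter matrices; the within-class
    scatter is regularized by ``eps * I`` with ``eps = 1e-6`` times its trace
    scale so the problem stays well posed on small fixtures.  At most
    ``C - 1`` components exist for ``C`` classes.
    """
    classes = np.unique(fm.labels)
    if classes.size < 2:
        raise ValueError("LDA requires at least 2 classes")
    max_comp = classes.size - 1
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}] for {classes.size} classes"
        )
    X, y = fm.values, fm.labels
    d = X.shape[1]
    mu = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        Sw += (Xc - mc).T @ (Xc - mc)
        diff = (mc - mu)[:, None]
        Sb += Xc.shape[0] * (diff @ diff.T)
    eps = 1e-6 * (np.trace(Sw) / d if np.trace(Sw) > 0 else 1.0)
    Sw += eps * np.eye(d)
    evals, evecs = sla.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1][:n_components]
    W = evecs[:, order]
    return FeatureMatrix(
        values=X @ W,
        feature_names=[f"LD{k + 1}" for k in range(n_components)],
        labels=y.copy(),
    )
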