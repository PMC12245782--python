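"""End-to-end orchestration: load → normalize → band-pass → segment →
extract features → (optional LDA) → wrapper feature selection → LSTM
training → one-shot test evaluation, with a randomized 70–15–15 split.

Leakage discipline: the feature-selection fitness and all model fitting see
only the training split (validation rows are used solely for early
stopping); the test split is touched exactly once, by the final evaluation.
Feature standardization is fit on training rows only.

A run writes its artifacts (selected mask, convergence curves, model
checkpoint, evaluation report, resolved config, manifest) into an output
directory and is bit-reproducible from the resolved config snapshot.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import gwo, lstm
from .errors import EcgWolfError
from .features import (FeatureMatrix, GLCMSpec, WaveletSpec, extract_all,
                       lda_reduce)
from .io_formats import ECGRecord, read_csv_dataset, read_wfdb_record
from .preprocess import FilterSpec, Segment, bandpass, normalize, segment
from .synthetic import SynthConfig, generate_dataset, split_70_15_15

__all__ = ["PipelineConfig", "RunArtifacts", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    source: str = "synthetic"          # synthetic | csv | wfdb
    data_path: str | None = None       # for csv / wfdb sources
    seed: int = 0
    norm_range: tuple[float, float] = (0.0, 1.0)
    window_s: float = 5.0
    stride_s: float = 2.5
    lda: bool = False
    lda_components: int = 4
    stratified_split: bool = True
    run_pso_baseline: bool = False
    sequence_mode: str = "static"      # static | raw
    synth: SynthConfig = field(default_factory=SynthConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    glcm: GLCMSpec = field(default_factory=GLCMSpec)
    egwo: gwo.EGWOConfig = field(default_factory=gwo.EGWOConfig)
    train: lstm.TrainConfig = field(default_factory=lstm.TrainConfig)

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Re-derive every component seed from one master seed (all derived
        seeds stay below 2**31)."""
        ss = np.random.SeedSequence(seed).generate_state(4) % (2 ** 31)
        return replace(
            self,
            seed=int(seed),
            synth=replace(self.synth, seed=int(ss[0])),
            egwo=replace(self.egwo, seed=int(ss[1])),
            train=replace(self.train, seed=int(ss[2])),
        )

    @property
    def split_seed(self) -> int:
        return int(np.random.SeedSequence(self.seed).generate_state(4)[3]
                   % (2 ** 31))

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        return enc(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        nested = {
            "synth": SynthConfig, "filter": FilterSpec,
            "wavelet": WaveletSpec, "glcm": GLCMSpec,
            "egwo": gwo.EGWOConfig, "train": lstm.TrainConfig,
        }
        kwargs = {}
        for key, val in d.items():
            if key in nested:
                kwargs[key] = nested[key](**val)
            elif key == "norm_range":
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


def load_config(path_or_name: str | Path) -> PipelineConfig:
    """Load a pipeline config from a JSON file, or one of the bundled
    presets ("paper", "fast")."""
    p = Path(path_or_name)
    if not p.exists():
        from importlib import resources
        candidate = resources.files("ecgwolf.configs") / f"{path_or_name}.json"
        if candidate.is_file():
            return PipelineConfig.from_dict(json.loads(candidate.read_text()))
        raise FileNotFoundError(f"config file not found: {path_or_name}")
    return PipelineConfig.from_dict(json.loads(p.read_text()))


@dataclass
class RunArtifacts:
    out_dir: Path
    manifest: dict
    report: ev.EvaluationReport
    selected_mask: gwo.FeatureMask
    egwo_result: gwo.EGWOResult
    model: lstm.TrainedClassifier
    feature_matrix: FeatureMatrix
    split_sizes: tuple[int, int, int]


def _load_segments(cfg: PipelineConfig) -> tuple[list[Segment], np.ndarray]:
    if cfg.source == "synthetic":
        return generate_dataset(cfg.synth)
    if cfg.source == "csv":
        if not cfg.data_path:
            raise ValueError("csv source requires data_path")
        rows = read_csv_dataset(cfg.data_path)
        segs = [Segment(samples=v, fs=cfg.filter.fs, label=lab)
                for v, lab in rows]
        return segs, np.array([lab for _, lab in rows], dtype=int)
    if cfg.source == "wfdb":
        if not cfg.data_path:
            raise ValueError("wfdb source requires data_path")
        segs: list[Segment] = []
        for hea in sorted(Path(cfg.data_path).glob("*.hea")):
            rec = read_wfdb_record(hea)
            rec = ECGRecord(record_id=rec.record_id,
                            signal=bandpass(normalize(rec.signal,
                                                      cfg.norm_range),
                                            cfg.filter),
                            fs=rec.fs, annotations=rec.annotations,
                            source="wfdb")
            segs += [s for s in segment(rec, "fixed", cfg.window_s,
                                        cfg.stride_s) if s.label is not None]
        if not segs:
            raise EcgWolfError(f"no labeled segments found under {cfg.data_path}")
        return segs, np.array([s.label for s in segs], dtype=int)
    raise ValueError(f"unknown data source {cfg.source!r}")


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> RunArtifacts:
    """Execute the full pipeline and write all artifacts plus a manifest.

    Any stage failure writes a ``FAILED`` marker naming the stage (partial
    artifacts are retained) and re-raises.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    stage = "configure"

    def emit(name: str, writer) -> None:
        writer(out / name)
        files.append(name)

    try:
        emit("resolved_config.json",
             lambda p: p.write_text(json.dumps(cfg.to_dict(), indent=2)))

        stage = "load+preprocess+segment"
        segments, labels = _load_segments(cfg)
        logger.info("loaded %d labeled segments", len(segments))

        stage = "feature extraction"
        fm = extract_all(segments, cfg.wavelet, cfg.glcm)
        if cfg.lda:
            fm = lda_reduce(fm, cfg.lda_components)
        logger.info("feature matrix: %d rows x %d features",
                    fm.values.shape[0], fm.n_features)

        stage = "split"
        idx_tr, idx_va, idx_te = split_70_15_15(
            np.arange(fm.values.shape[0]), cfg.split_seed,
            stratify_labels=fm.labels if cfg.stratified_split else None,
        )
        idx_tr, idx_va, idx_te = map(np.array, (idx_tr, idx_va, idx_te))

        stage = "standardize"
        mu = fm.values[idx_tr].mean(axis=0)
        sd = fm.values[idx_tr].std(axis=0)
        sd[sd == 0] = 1.0
        Z = (fm.values - mu) / sd
        zfm = FeatureMatrix(values=Z, feature_names=fm.feature_names,
                            labels=fm.labels)
        train_fm = FeatureMatrix(values=Z[idx_tr],
                                 feature_names=fm.feature_names,
                                 labels=fm.labels[idx_tr])

        stage = "feature selection"
        result = gwo.run_egwo(train_fm, cfg.egwo)
        mask = result.best_mask
        logger.info("selected %d/%d features, CV fitness %.4f",
                    mask.popcount, fm.n_features, mask.fitness)
        emit("selected_mask.json", lambda p: p.write_text(json.dumps({
            "bits": mask.bits.astype(int).tolist(),
            "feature_names": [n for n, b in zip(fm.feature_names, mask.bits)
                              if b],
            "fitness": mask.fitness,
            "n_evaluations": result.n_evaluations,
        }, indent=2)))
        emit("convergence_egwo.csv", lambda p: pd.DataFrame({
            "iteration": np.arange(1, result.convergence.size + 1),
            "best_fitness": result.convergence,
        }).to_csv(p, index=False))
        if cfg.run_pso_baseline:
            pso = gwo.run_bpso(train_fm, cfg.egwo)
            emit("convergence_pso.csv", lambda p: pd.DataFrame({
                "iteration": np.arange(1, pso.convergence.size + 1),
                "best_fitness": pso.convergence,
            }).to_csv(p, index=False))

        stage = "sequence conversion"
        if cfg.sequence_mode == "static":
            X, y = lstm.to_sequences(zfm, mask)
        elif cfg.sequence_mode == "raw":
            X, y = lstm.segments_to_sequences(segments)
        else:
            raise ValueError(f"unknown sequence_mode {cfg.sequence_mode!r}")

        stage = "train"
        model = lstm.train(
            X[idx_tr], y[idx_tr], cfg.train, X[idx_va], y[idx_va],
            feature_names=[n for n, b in zip(fm.feature_names, mask.bits)
                           if b] if cfg.sequence_mode == "static" else None,
        )
        emit("training_history.csv", lambda p: pd.DataFrame(
            model.training_history).to_csv(p, index=False))
        emit("model.npz", lambda p: np.savez(
            p, **model.params.arrays(),
            class_labels=model.class_labels))
        emit("model_meta.json", lambda p: p.write_text(json.dumps({
            "feature_names": model.feature_names,
            "class_labels": [int(c) for c in model.class_labels],
            "standardize_mean": mu.tolist(),
            "standardize_sd": sd.tolist(),
            "train_config": dataclasses.asdict(cfg.train),
        }, indent=2)))

        stage = "evaluate"
        pred, probs = lstm.predict(model, X[idx_te])
        class_labels = [int(c) for c in model.class_labels]
        report = ev.evaluate(y[idx_te], pred, probs, class_labels)
        emit("evaluation.json", lambda p: report.to_json(p))
        emit("confusion.csv", lambda p: pd.DataFrame(
            report.confusion.counts,
            index=[f"true_{c}" for c in class_labels],
            columns=[f"pred_{c}" for c in class_labels]).to_csv(p))
        for k, roc in enumerate(report.roc):
            emit(f"roc_class{class_labels[k]}.csv",
                 lambda p, roc=roc: pd.DataFrame({
                     "fpr": roc.fpr, "tpr": roc.tpr,
                     "threshold": roc.thresholds}).to_csv(p, index=False))

        stage = "manifest"
        manifest = {
            "files": files + ["manifest.json"],
            "split_sizes": [int(idx_tr.size), int(idx_va.size),
                            int(idx_te.size)],
            "n_segments": len(segments),
            "n_features": int(fm.n_features),
            "selected_features": int(mask.popcount),
            "test_accuracy": report.accuracy,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return RunArtifacts(
            out_dir=out, manifest=manifest, report=report,
            selected_mask=mask, egwo_result=result, model=model,
            feature_matrix=fm,
            split_sizes=(idx_tr.size, idx_va.size, idx_te.size),
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise
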