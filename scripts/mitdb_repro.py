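"""Full-scale reproduction against the MIT-BIH Arrhythmia Database.

Requires a local copy of the database (not downloaded by this script):

    wget -r -np -nd -A '*.hea,*.dat,*.atr' \
        https://physionet.org/files/mitdb/1.0.0/ -P mitdb/
    python scripts/mitdb_repro.py --data mitdb/ --seed 0 --out mitdb_report.json

IMPORTANT — label-mapping interpretation.  The source recordings carry beat
and rhythm annotations, not the five class codes this package predicts.  The
mapping used here is one defensible reading, not a ground truth:

* windows inside an ``(AFIB`` rhythm episode  -> class 1 (AFib)
* windows inside ``(SVTA``                     -> class 2 (SVT)
* windows inside ``(SBR``                      -> class 3 (bradycardia)
* windows containing a ``V`` beat              -> class 4 (PVC), overriding
  the rhythm label, since ectopy is a beat-level phenomenon
* windows inside ``(AFL``                      -> class 5 (flutter)

Windows outside these episodes (normal sinus rhythm and every other rhythm)
are discarded, as are records contributing no mapped windows.  Reported
accuracy/sensitivity/specificity therefore quantify THIS mapping and are not
directly comparable with numbers derived from a different (unpublished)
selection of 3000 signals.
"""

from __future__ import annotations

import argparse
import json
import sys
from pathlib import Path

import numpy as np

from ecgwolf.evaluation import evaluate
from ecgwolf.features import extract_all
from ecgwolf.gwo import EGWOConfig, run_egwo
from ecgwolf.io_formats import read_wfdb_record
from ecgwolf.lstm import TrainConfig, predict, to_sequences, train
from ecgwolf.features import FeatureMatrix
from ecgwolf.preprocess import FilterSpec, Segment, bandpass, normalize
from ecgwolf.synthetic import split_70_15_15

RHYTHM_TO_CLASS = {"(AFIB": 1, "(SVTA": 2, "(SBR": 3, "(AFL": 5}
WINDOW_S = 5.0
STRIDE_S = 2.5


def label_windows(record) -> list[Segment]:
    """Cut one record into labeled windows under the mapping above."""
    fs = record.fs
    W = int(round(WINDOW_S * fs))
    S = int(round(STRIDE_S * fs))
    sig = bandpass(normalize(record.signal), FilterSpec(fs=fs))

    # rhythm episodes: '+' annotations carry the rhythm string as aux label
    episodes = []  # (start_sample, class or None)
    current = None
    events = sorted(record.annotations, key=lambda a: a.sample_index)
    for ev in events:
        if ev.label.startswith("("):
            current = RHYTHM_TO_CLASS.get(ev.label)
            episodes.append((ev.sample_index, current))
    v_beats = np.array([ev.sample_index for ev in events if ev.label == "V"],
                       dtype=int)

    def rhythm_at(sample: int):
        active = None
        for start, cls in episodes:
            if start <= sample:
                active = cls
            else:
                break
        return active

    out = []
    for start in range(0, sig.size - W + 1, S):
        label = rhythm_at(start + W // 2)
        if v_beats.size and np.any((v_beats >= start) & (v_beats < start + W)):
            label = 4
        if label is not None:
            out.append(Segment(sig[start:start + W], fs, label=label,
                               record_id=record.record_id,
                               start_index=start))
    return out


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, required=True,
                        help="Directory with the .hea/.dat/.atr files")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--max-per-class", type=int, default=600)
    parser.add_argument("--out", type=Path, default=Path("mitdb_report.json"))
    args = parser.parse_args(argv)

    segments: list[Segment] = []
    for hea in sorted(args.data.glob("*.hea")):
        try:
            segments += label_windows(read_wfdb_record(hea, channel=0))
        except Exception as exc:  # noqa: BLE001 - skip unreadable records
            print(f"skipping {hea.name}: {exc}", file=sys.stderr)
    if not segments:
        print("no mappable windows found; is --data a mitdb copy?",
              file=sys.stderr)
        return 1

    # balance classes up to --max-per-class
    rng = np.random.default_rng(args.seed)
    by_class: dict[int, list[Segment]] = {}
    for s in segments:
        by_class.setdefault(s.label, []).append(s)
    kept = []
    for cls, group in sorted(by_class.items()):
        idx = rng.permutation(len(group))[: args.max_per_class]
        kept += [group[i] for i in idx]
        print(f"class {cls}: {len(group)} windows, keeping {min(len(group), args.max_per_class)}",
              file=sys.stderr)
    rng.shuffle(kept)

    fm = extract_all(kept)
    idx_tr, idx_va, idx_te = map(np.array, split_70_15_15(
        np.arange(fm.values.shape[0]), args.seed,
        stratify_labels=fm.labels))
    mu = fm.values[idx_tr].mean(axis=0)
    sd = fm.values[idx_tr].std(axis=0)
    sd[sd == 0] = 1.0
    zfm = FeatureMatrix((fm.values - mu) / sd, fm.feature_names, fm.labels)

    train_fm = FeatureMatrix(zfm.values[idx_tr], fm.feature_names,
                             fm.labels[idx_tr])
    res = run_egwo(train_fm, EGWOConfig(seed=args.seed))
    X, y = to_sequences(zfm, res.best_mask)
    model = train(X[idx_tr], y[idx_tr], TrainConfig(seed=args.seed),
                  X[idx_va], y[idx_va])
    pred, probs = predict(model, X[idx_te])
    report = evaluate(y[idx_te], pred, probs,
                      [int(c) for c in model.class_labels])

    summary = {
        "note": "label mapping is an interpretation; see module docstring",
        "n_windows": int(fm.values.shape[0]),
        "accuracy_pct": round(100 * report.accuracy, 2),
        "macro_sensitivity_pct": round(100 * report.macro_sensitivity, 2),
        "macro_specificity_pct": round(100 * report.macro_specificity, 2),
        "selected_features": int(res.best_mask.popcount),
    }
    args.out.write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))
    return 0


if __name__ == "__main__":
    sys.exit(main())
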