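"""End-to-end orchestration: preprocessing, feature extraction, SI, LOTO grid.

The pipeline reproduces the experiment grid of the study design at desk
scale: sensor conditions (emg, emg+acc, merged) x window lengths
(50/100/150 ms) x shallow classifiers, evaluated leave-one-trial-out per
subject, with separability indices per trial and Wilcoxon rank-sum
comparisons between conditions.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .astw import AttentionConfig, extract_features
from .classifiers_eval import (
    ClassifierSpec,
    EvalReport,
    compare_conditions,
    loto_evaluate,
)
from .dtw_core import DtwConfig
from .errors import ConfigError
from .io_preprocess import (
    ACC_BAND,
    EMG_BAND,
    FilterSpec,
    TrialRecording,
    channel_stats,
    filter_trial,
    read_trial,
    segment_windows,
    standardize_trial,
)
from .separability import separability_index

log = logging.getLogger("astw")

_TRIAL_FILE = re.compile(r"subject(\d+)_trial(\d+)\.csv$")


@dataclass
class RunConfig:
    """Resolved settings for one experiment run; embedded in every report."""

    condition: str = "emg+acc"
    mode: str = "astw"
    wl_ms: float = 150.0
    stride_ms: float | None = None
    beta: float = 0.75
    band: float = 1.0
    dk_sqrt: bool = False
    normalize: bool = True
    filter_acc: bool = False
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["classifier"] = asdict(self.classifier)
        return d


def load_trials(input_dir) -> list:
    """Load every ``subject<S>_trial<T>.csv`` under a directory."""
    input_dir = Path(input_dir)
    trials = []
    for path in sorted(input_dir.glob("*.csv")):
        m = _TRIAL_FILE.search(path.name)
        if not m:
            continue
        trials.append(
            read_trial(path, subject_id=int(m.group(1)), trial_id=int(m.group(2)))
        )
    if not trials:
        raise ConfigError(f"no trial files found under {input_dir}")
    return trials


def preprocess_trials(trials, cfg: RunConfig) -> list:
    """Band-pass filter and (optionally) standardize each channel.

    EMG channels are always filtered to 30-450 Hz.  The 2-20 Hz ACC band
    filter is available (``filter_acc=True``) but off by default: it would
    remove the quasi-static gravity projection that distinguishes held
    postures, which is exactly the component the fused features exploit.
    Channel standardization uses statistics pooled over each subject's
    trials, bringing EMG (mV) and ACC (g) onto a common scale before DTW.
    """
    acc_band = ACC_BAND if cfg.filter_acc else None
    filtered = [filter_trial(t, emg_band=EMG_BAND, acc_band=acc_band) for t in trials]
    if not cfg.normalize:
        return filtered
    out = []
    for subject in sorted({t.subject_id for t in filtered}):
        subject_trials = [t for t in filtered if t.subject_id == subject]
        mean, std = channel_stats(subject_trials)
        out.extend(standardize_trial(t, mean, std) for t in subject_trials)
    return out


def features_per_trial(trials, cfg: RunConfig) -> list:
    """Extract fused features for each trial; state resets at trial boundaries.

    Returns ``[(features, labels, (subject_id, trial_id)), ...]``.
    """
    dtw_cfg = DtwConfig(band=cfg.band)
    attn_cfg = AttentionConfig(sqrt_scale=cfg.dk_sqrt)
    out = []
    for trial in trials:
        stream = segment_windows(trial, cfg.wl_ms, cfg.stride_ms)
        F, y = extract_features(
            stream,
            condition=cfg.condition,
            mode=cfg.mode,
            dtw_cfg=dtw_cfg,
            beta=cfg.beta,
            attn_cfg=attn_cfg,
        )
        out.append((F, y, (trial.subject_id, trial.trial_id)))
        log.debug(
            "features subject=%s trial=%s shape=%s", trial.subject_id, trial.trial_id, F.shape
        )
    return out


def si_per_trial(feature_trials) -> list:
    """Separability index computed independently for every trial."""
    return [
        {"subject_id": tid[0], "trial_id": tid[1], "si": separability_index(F, y).si}
        for F, y, tid in feature_trials
    ]


def evaluate_subjects(feature_trials, spec: ClassifierSpec) -> dict:
    """LOTO per subject; returns per-subject reports plus pooled summaries."""
    subjects = sorted({tid[0] for _, _, tid in feature_trials})
    reports = {}
    for s in subjects:
        subset = [(F, y, tid[1]) for F, y, tid in feature_trials if tid[0] == s]
        reports[s] = loto_evaluate(subset, spec)
        log.info(
            "LOTO subject=%s folds=%d mean=%.4f", s, len(subset), reports[s].mean_accuracy
        )
    return reports


def run_experiment(trials, cfg: RunConfig) -> dict:
    """One grid cell: features -> per-trial SI -> LOTO evaluation -> report."""
    log.info(
        "run condition=%s mode=%s wl=%sms classifier=%s seed=%d",
        cfg.condition, cfg.mode, cfg.wl_ms, cfg.classifier.kind, cfg.seed,
    )
    prepped = preprocess_trials(trials, cfg)
    feats = features_per_trial(prepped, cfg)
    si_rows = si_per_trial(feats)
    reports = evaluate_subjects(feats, cfg.classifier)
    fold_acc = [a for r in reports.values() for a in r.fold_accuracies]
    pooled_confusion = np.sum([r.confusion for r in reports.values()], axis=0)
    return {
        "config": cfg.to_dict(),
        "si": {"per_trial": si_rows, "mean": float(np.mean([r["si"] for r in si_rows]))},
        "per_subject": {str(s): r.to_dict() for s, r in reports.items()},
        "mean_accuracy": float(np.mean(fold_acc)),
        "std_accuracy": float(np.std(fold_acc)),
        "fold_accuracies": fold_acc,
        "confusion": pooled_confusion.tolist(),
    }


def run_grid(
    trials,
    wl_ms_list=(50.0, 100.0, 150.0),
    conditions=("emg", "emg+acc", "merged"),
    mode: str = "astw",
    classifier: ClassifierSpec | None = None,
    base: RunConfig | None = None,
) -> dict:
    """Full conditions x WL grid with rank-sum comparisons per WL.

    Comparisons follow the study design: emg vs emg+acc and emg+acc vs
    merged, on the fold-accuracy samples, two-sided rank-sum at alpha=0.05.
    """
    base = base or RunConfig()
    classifier = classifier or base.classifier
    results = {}
    for wl in wl_ms_list:
        for cond in conditions:
            cfg = RunConfig(
                condition=cond,
                mode=mode,
                wl_ms=wl,
                stride_ms=base.stride_ms,
                beta=base.beta,
                band=base.band,
                dk_sqrt=base.dk_sqrt,
                normalize=base.normalize,
                filter_acc=base.filter_acc,
                classifier=classifier,
                seed=base.seed,
            )
            results[(cond, wl)] = run_experiment(trials, cfg)
    comparisons = []
    for wl in wl_ms_list:
        for pair in (("emg", "emg+acc"), ("emg+acc", "merged")):
            if pair[0] in conditions and pair[1] in conditions:
                res = compare_conditions(
                    results[(pair[0], wl)]["fold_accuracies"],
                    results[(pair[1], wl)]["fold_accuracies"],
                )
                comparisons.append(
                    {
                        "wl_ms": wl,
                        "a": pair[0],
                        "b": pair[1],
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "significant": res.significant,
                    }
                )
    return {"cells": results, "comparisons": comparisons}


def grid_summary_frame(grid: dict) -> pd.DataFrame:
    """Flatten grid results into the summary table the CLI writes."""
    rows = [
        {
            "condition": cond,
            "wl_ms": wl,
            "mode": cell["config"]["mode"],
            "classifier": cell["config"]["classifier"]["kind"],
            "mean_accuracy": cell["mean_accuracy"],
            "std_accuracy": cell["std_accuracy"],
            "mean_si": cell["si"]["mean"],
        }
        for (cond, wl), cell in grid["cells"].items()
    ]
    return pd.DataFrame(rows).sort_values(["wl_ms", "condition"]).reset_index(drop=True)


def save_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
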