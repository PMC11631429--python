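"""End-to-end orchestration: configuration, feature building, evaluation runs.

The evaluation workflow converts DNA sequences into signals, extracts
window-level magnitude spectra, trains a UBM-GMM on the training-fold
windows of each cross-validation fold, MAP-adapts it per sequence into mean
supervectors, and feeds those (or the distance-matrix baseline features) to
a classifier.  The UBM and any feature scaling are always fitted on training
folds only, so no test information leaks into the representation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import baseline as _baseline
from . import classify as _classify
from . import seq_signal as _sig
from . import ubm_gmm as _ubm

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PRESETS",
    "compute_frame_sets",
    "supervector_features",
    "baseline_distance_features",
    "evaluate_dataset",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Resolved run settings; serializes round-trip to/from JSON or YAML."""

    encoder: str = "pp"
    winlen: int = 351
    winshift: int = 99
    fft_order: int = 512
    K: int = 5
    relevance_r: float = _ubm.DEFAULT_RELEVANCE
    classifier: str = "ld"
    folds: int = 4
    seed: int = 0
    feature_kind: str = "specgmm"  # specgmm | baseline | hvr-posterior
    standardize: bool = True
    max_iter: int = 100
    tol: float = 1e-6
    n_init: int = 3
    fasta: str | None = None
    manifest: str | None = None
    hvr: str | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if self.fft_order < self.winlen:
            raise ValueError("fft_order must be >= winlen")
        if self.fft_order & (self.fft_order - 1):
            raise ValueError("fft_order must be a power of two")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: named hyperparameter presets: `default` is the benchmark setting
#: (window 351, shift 99, FFT order 512, K=5); `16s` is the short-window
#: setting used for 16S rRNA and region-level analysis (63 / 9 / 64, K=5).
PRESETS = {
    "default": dict(winlen=351, winshift=99, fft_order=512, K=5),
    "16s": dict(winlen=63, winshift=9, fft_order=64, K=5),
}


# ---------------------------------------------------------------------------
# Feature construction


def compute_frame_sets(records, config: RunConfig) -> list[_sig.SpectralFrameSet]:
    """Per-sequence window spectra (fold independent, computed once)."""
    out = []
    for rec in records:
        signal = _sig.encode(rec, config.encoder)
        out.append(
            _sig.sequence_frame_set(
                signal, config.winlen, config.winshift, config.fft_order,
                label=rec.label,
            )
        )
    return out


def supervector_features(frame_sets, config: RunConfig):
    """Feature builder: per-fold UBM on pooled training windows + MAP supervectors.

    Returns a callable (train_idx, test_idx) -> (X_train, X_test) plus a dict
    collecting the fitted per-fold UBMs for provenance.
    """
    fitted: dict[int, _ubm.GMMParams] = {}

    def build(train_idx, test_idx):
        fold_no = len(fitted)
        pooled = np.vstack([frame_sets[i].frames for i in train_idx])
        ubm = _ubm.fit_ubm(
            pooled, config.K, seed=config.seed + fold_no,
            max_iter=config.max_iter, tol=config.tol, n_init=config.n_init,
        )
        fitted[fold_no] = ubm
        svs = {}
        for i in np.concatenate([train_idx, test_idx]):
            fs = frame_sets[i]
            _, sv = _ubm.map_adapt_means(
                ubm, fs.frames, relevance_r=config.relevance_r, sequence_id=fs.id
            )
            svs[int(i)] = sv.vector
        X_train = np.stack([svs[int(i)] for i in train_idx])
        X_test = np.stack([svs[int(i)] for i in test_idx])
        return X_train, X_test

    return build, fitted


def baseline_distance_features(records, config: RunConfig):
    """Feature builder for the distance-matrix baseline.

    Per fold: the target length is the median of training-fold signal lengths
    (lower median), every signal is normalized and reduced to one
    whole-sequence magnitude spectrum, and features are distances to the
    training spectra (dimension = n_train).
    """
    signals = [_sig.encode(rec, config.encoder) for rec in records]

    def build(train_idx, test_idx):
        target = _baseline.lower_median_length(
            [signals[i].length for i in train_idx]
        )
        order = _sig.next_power_of_two(target)
        spectra = {
            int(i): _baseline.whole_sequence_spectrum(signals[i], target, order)
            for i in np.concatenate([train_idx, test_idx])
        }
        train_spec = np.stack([spectra[int(i)] for i in train_idx])
        test_spec = np.stack([spectra[int(i)] for i in test_idx])
        feats = _baseline.baseline_features(
            train_spec, test_spec, reference_ids=[signals[i].id for i in train_idx]
        )
        return feats.train_matrix, feats.test_matrix

    return build


# ---------------------------------------------------------------------------
# Evaluation and end-to-end run


def evaluate_dataset(records, config: RunConfig):
    """Cross-validated evaluation of a labelled dataset under one config.

    Returns ``(report, artifacts)``: artifacts holds the fold assignment and,
    for supervector features, the per-fold UBMs.
    """
    labels = [rec.label for rec in records]
    ids = [rec.id for rec in records]
    folds = _classify.stratified_folds(labels, k=config.folds, seed=config.seed)
    artifacts: dict = {"folds": folds}

    if config.feature_kind == "specgmm":
        frame_sets = compute_frame_sets(records, config)
        builder, fitted = supervector_features(frame_sets, config)
        artifacts["ubms"] = fitted
    elif config.feature_kind == "baseline":
        builder = baseline_distance_features(records, config)
    else:
        raise ValueError(
            f"unknown feature_kind {config.feature_kind!r} "
            "(use 'specgmm' or 'baseline'; region features via hvr_analysis)"
        )

    report = _classify.train_and_eval(
        config.classifier, builder, labels, folds,
        feature_kind=config.feature_kind, standardize=config.standardize,
        seed=config.seed, sample_ids=ids,
    )
    return report, artifacts


def run_pipeline(config: RunConfig):
    """File-level entry point: read inputs, evaluate, write artifacts.

    Writes the resolved config, the JSON report, per-fold predictions TSV and
    (for supervector runs) serialized per-fold UBMs under ``config.out_dir``.
    """
    if not config.fasta or not config.manifest:
        raise ValueError("config.fasta and config.manifest are required")
    out_dir = Path(config.out_dir or "specgmm_run")
    out_dir.mkdir(parents=True, exist_ok=True)

    records = _sig.read_fasta_with_labels(config.fasta, config.manifest)
    report, artifacts = evaluate_dataset(records, config)

    with open(out_dir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
    report.to_json(out_dir / "report.json")

    import pandas as pd

    if report.fold_predictions:
        pd.DataFrame(report.fold_predictions).to_csv(
            out_dir / "predictions.tsv", sep="\t", index=False
        )
    for fold, ubm in artifacts.get("ubms", {}).items():
        _ubm.save_gmm(ubm, out_dir / f"ubm_fold{fold}.json", config=config.to_dict())
        logger.info(
            "fold %d: %d EM iterations, final log-likelihood %.4f",
            fold, len(ubm.log_likelihoods) - 1, ubm.log_likelihoods[-1],
        )
    logger.info(
        "%s/%s mean accuracy %.2f%% (chance %.2f%%)",
        config.feature_kind, config.classifier,
        report.mean_accuracy, report.chance_accuracy,
    )
    return report, artifacts
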