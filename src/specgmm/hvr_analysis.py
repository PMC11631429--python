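"""Hypervariable-region analysis: window assignment and per-region posteriors.

Each sliding window of a sequence is attributed to the named region (e.g.
16S rRNA V2-V7) with which its interval shares the most bases; the
K-dimensional UBM posterior vectors of the windows assigned to a region are
averaged into one simplex feature per sequence and region.  Classifying with
those K-dim features, region by region, ranks the regions' discriminative
power against a whole-sequence supervector reference.  Averaged posteriors
(rather than per-region supervectors) are used because single regions
contain too few windows to support a stable per-region adaptation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify as _classify
from . import ubm_gmm as _ubm
from .pipeline import RunConfig, compute_frame_sets

logger = logging.getLogger(__name__)

__all__ = [
    "HVRAnnotation",
    "HVRFeatureVector",
    "read_hvr_table",
    "assign_windows",
    "hvr_posterior_features",
    "rank_regions",
    "plot_region_ranking",
]


@dataclass(frozen=True)
class HVRAnnotation:
    """One named interval on the N-reduced signal, 0-based half-open."""

    sequence_id: str
    region_name: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"region {self.region_name!r} of {self.sequence_id!r}: "
                f"start {self.start} must be < end {self.end}"
            )


@dataclass(frozen=True)
class HVRFeatureVector:
    """Average posterior over the windows assigned to one region."""

    sequence_id: str
    region_name: str
    posterior: np.ndarray  # (K,), sums to 1
    n_windows: int


def read_hvr_table(path, one_based_inclusive: bool = False) -> pd.DataFrame:
    """Read a region table TSV: sequence_id, region, start, end.

    Coordinates are 0-based half-open by default; pass
    ``one_based_inclusive=True`` for 1-based inclusive exports, which are
    converted on read.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "region": str})
    required = {"sequence_id", "region", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"HVR table missing column(s): {sorted(missing)}")
    df = df.copy()
    if one_based_inclusive:
        df["start"] = df["start"] - 1
    return df


def assign_windows(
    window_starts: np.ndarray, winlen: int, annotations: list[HVRAnnotation]
) -> list[str | None]:
    """Assign each window to the region of maximum base overlap.

    Windows overlapping no region get ``None``.  Exact overlap ties resolve
    to the leftmost (smallest-start) region and are logged.
    """
    regions = sorted(annotations, key=lambda a: a.start)
    out: list[str | None] = []
    for s in np.asarray(window_starts, dtype=np.int64):
        w_start, w_end = int(s), int(s) + winlen
        best_name, best_ov = None, 0
        for ann in regions:
            ov = min(w_end, ann.end) - max(w_start, ann.start)
            if ov > best_ov:  # strict: first (leftmost) region wins ties
                best_ov, best_name = ov, ann.region_name
            elif ov == best_ov and ov > 0 and best_name is not None:
                logger.debug(
                    "window at %d ties between %s and %s; keeping leftmost %s",
                    w_start, best_name, ann.region_name, best_name,
                )
        out.append(best_name)
    return out


def hvr_posterior_features(
    post_vectors: np.ndarray, assignments: list[str | None], sequence_id: str = ""
) -> list[HVRFeatureVector]:
    """Average the posteriors of each region's windows into one simplex vector.

    Regions with no assigned windows are absent from the output; unassigned
    windows contribute to no region.
    """
    post_vectors = np.atleast_2d(np.asarray(post_vectors, dtype=np.float64))
    by_region: dict[str, list[int]] = {}
    for idx, region in enumerate(assignments):
        if region is not None:
            by_region.setdefault(region, []).append(idx)
    return [
        HVRFeatureVector(
            sequence_id=sequence_id,
            region_name=region,
            posterior=post_vectors[idxs].mean(axis=0),
            n_windows=len(idxs),
        )
        for region, idxs in sorted(by_region.items())
    ]


def _annotations_by_sequence(hvr_df: pd.DataFrame) -> dict[str, list[HVRAnnotation]]:
    out: dict[str, list[HVRAnnotation]] = {}
    for row in hvr_df.itertuples(index=False):
        out.setdefault(row.sequence_id, []).append(
            HVRAnnotation(row.sequence_id, row.region, int(row.start), int(row.end))
        )
    return out


def rank_regions(
    records, hvr_df: pd.DataFrame, config: RunConfig
) -> tuple[pd.DataFrame, dict]:
    """Per-region classification accuracy table plus a whole-sequence reference.

    Per cross-validation fold: a UBM is trained on training-fold windows only;
    every window's posterior vector is computed under it; windows are assigned
    to regions by maximum overlap; region features are the per-sequence
    average posteriors; a classifier is fitted per region on training-fold
    sequences that have the region and scored on the held-out fold.  Whole
    sequences are scored with mean supervectors under the same per-fold UBMs.
    Returns ``(table, details)`` where the table holds mean metrics and chance
    accuracy per region (and a ``whole_sequence`` row).
    """
    labels = np.asarray([rec.label for rec in records])
    classes = sorted(set(labels.tolist()))
    folds = _classify.stratified_folds(labels, k=config.folds, seed=config.seed)
    frame_sets = compute_frame_sets(records, config)
    ann_by_seq = _annotations_by_sequence(hvr_df)
    region_names = sorted(hvr_df["region"].unique().tolist())

    region_cms: dict[str, list[np.ndarray]] = {r: [] for r in region_names}
    whole_cms: list[np.ndarray] = []
    skipped: dict[str, int] = {r: 0 for r in region_names}
    ubms = {}

    for fold in range(config.folds):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        pooled = np.vstack([frame_sets[i].frames for i in train_idx])
        ubm = _ubm.fit_ubm(
            pooled, config.K, seed=config.seed + fold,
            max_iter=config.max_iter, tol=config.tol, n_init=config.n_init,
        )
        ubms[fold] = ubm

        # per-sequence region features + supervectors under this fold's UBM
        region_feats: dict[int, dict[str, np.ndarray]] = {}
        supervectors: dict[int, np.ndarray] = {}
        for i, fs in enumerate(frame_sets):
            post = np.exp(_ubm.log_posteriors(ubm, fs.frames))
            anns = ann_by_seq.get(fs.id, [])
            assignments = assign_windows(fs.window_starts, config.winlen, anns)
            feats = hvr_posterior_features(post, assignments, sequence_id=fs.id)
            region_feats[i] = {f.region_name: f.posterior for f in feats}
            _, sv = _ubm.map_adapt_means(
                ubm, fs.frames, relevance_r=config.relevance_r, sequence_id=fs.id
            )
            supervectors[i] = sv.vector

        for region in region_names:
            tr = [i for i in train_idx if region in region_feats[i]]
            te = [i for i in test_idx if region in region_feats[i]]
            n_missing = (len(train_idx) - len(tr)) + (len(test_idx) - len(te))
            skipped[region] += n_missing
            if not tr or not te or len(set(labels[tr])) < 2:
                logger.warning("region %s skipped in fold %d (too few sequences)",
                               region, fold)
                continue
            cm = _fit_score(
                np.stack([region_feats[i][region] for i in tr]),
                np.stack([region_feats[i][region] for i in te]),
                labels[tr], labels[te], classes, config, fold,
            )
            region_cms[region].append(cm)

        whole_cms.append(
            _fit_score(
                np.stack([supervectors[i] for i in train_idx]),
                np.stack([supervectors[i] for i in test_idx]),
                labels[train_idx], labels[test_idx], classes, config, fold,
            )
        )

    counts = [int((labels == c).sum()) for c in classes]
    chance = _classify.chance_accuracy(counts)
    rows = []
    for region in region_names:
        cms = region_cms[region]
        if not cms:
            logger.warning("region %s absent from all folds; skipped", region)
            continue
        rows.append(_summarize(region, cms, chance, skipped[region]))
    rows.append(_summarize("whole_sequence", whole_cms, chance, 0))
    table = pd.DataFrame(rows)
    return table, {"folds": folds, "ubms": ubms, "skipped": skipped}


def _fit_score(X_train, X_test, y_train, y_test, classes, config, fold):
    from sklearn.metrics import confusion_matrix
    from sklearn.preprocessing import StandardScaler

    if config.standardize:
        scaler = StandardScaler()
        X_train = scaler.fit_transform(X_train)
        X_test = scaler.transform(X_test)
    clf = _classify.make_classifier(config.classifier, seed=config.seed + fold)
    clf.fit(X_train, y_train)
    return confusion_matrix(y_test, clf.predict(X_test), labels=classes)


def _summarize(name, cms, chance, n_skipped):
    fold_metrics = [_classify.compute_metrics(cm) for cm in cms]
    row = {"region": name}
    for key in ("accuracy", "precision", "recall", "specificity", "f1"):
        row[key] = float(np.mean([m[key] for m in fold_metrics]))
    row["accuracy_std"] = float(np.std([m["accuracy"] for m in fold_metrics]))
    row["chance_accuracy"] = chance
    row["n_folds"] = len(cms)
    row["n_excluded_sequences"] = n_skipped
    return row


def plot_region_ranking(table: pd.DataFrame, path) -> None:
    """Bar plot of per-region accuracies with the chance-accuracy line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(table["region"], table["accuracy"], color="steelblue")
    ax.axhline(
        table["chance_accuracy"].iloc[0], color="brown", linestyle=":",
        label="chance accuracy",
    )
    ax.set_ylabel("mean CV accuracy (%)")
    ax.set_xlabel("region")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
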