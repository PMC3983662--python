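"""Window-level feature matrices, correlation clustering and permutation
feature importance for bound/unbound window classification."""

from __future__ import annotations

import logging
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from peakscape.core import (
    CoverageTrack,
    GenomeModel,
    Interval,
    PeakSet,
    ValidationError,
    hit_flags,
)

logger = logging.getLogger(__name__)


def genome_windows(genome: GenomeModel, window: int) -> list[Interval]:
    """Contiguous non-overlapping tiling of the included chromosomes.

    The final partial window of each chromosome is kept (its shorter length is
    visible in the interval itself).
    """
    tiles = []
    for chrom in genome.included_chroms:
        length = genome.length(chrom)
        for s in range(0, length, window):
            tiles.append(Interval(chrom, s, min(s + window, length)))
    return tiles


def window_feature_matrix(
    tracks: Mapping[str, CoverageTrack],
    genome: GenomeModel,
    window: int = 1000,
) -> pd.DataFrame:
    """Per-window median of each named track.

    Index carries (chrom, start, end); columns are the track names.
    """
    tiles = genome_windows(genome, window)
    index = pd.MultiIndex.from_tuples(
        [(t.chrom, t.start, t.end) for t in tiles], names=["chrom", "start", "end"]
    )
    data = {}
    for name, track in tracks.items():
        col = np.empty(len(tiles))
        for i, t in enumerate(tiles):
            col[i] = np.median(track.data[t.chrom][t.start : t.end])
        data[name] = col
    return pd.DataFrame(data, index=index)


def correlation_heatmap_order(
    matrix: pd.DataFrame, method: str = "average"
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson matrix over windows plus a hierarchical leaf order.

    Clustering runs on the distance 1 - r with the given linkage.  Constant
    columns make Pearson undefined and raise, naming the column.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 feature columns")
    for col in matrix.columns:
        if matrix[col].nunique() <= 1:
            raise ValidationError(f"column {col!r} is constant; correlation undefined")
    corr = matrix.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # enforce exact symmetry for squareform
    link = hierarchy.linkage(squareform(dist, checks=False), method=method)
    order = [matrix.columns[i] for i in hierarchy.leaves_list(link)]
    return corr, order


def label_windows(
    genome: GenomeModel,
    peaks: Sequence[Interval] | PeakSet,
    window: int = 250,
) -> tuple[list[Interval], np.ndarray]:
    """Tile the genome and flag each window bound iff it intersects a peak (>= 1 bp)."""
    tiles = genome_windows(genome, window)
    peak_ivs = peaks.intervals if isinstance(peaks, PeakSet) else list(peaks)
    return tiles, hit_flags(tiles, peak_ivs)


class Classifier(Protocol):
    """Anything with sklearn-style fit/predict works as the plug-in classifier."""

    def fit(self, X, y): ...

    def predict(self, X): ...


def default_classifier(rng_seed: int = 0, n_estimators: int = 200):
    """Recommended plug-in: a random forest (the published analysis used a
    10,000-tree forest; the default here is smaller for desk-scale runs)."""
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(
        n_estimators=n_estimators, random_state=rng_seed, n_jobs=1
    )


def permutation_importance(
    features: pd.DataFrame,
    labels: np.ndarray,
    classifier: Classifier | None = None,
    n_repeats: int = 5,
    test_size: float = 0.3,
    rng_seed: int = 0,
    mode: str = "holdout",
) -> pd.DataFrame:
    """Rank features by mean decrease in held-out accuracy after permuting each.

    A stratified 70/30 split preserves class balance; for each feature the
    decrease is (baseline accuracy - accuracy with that feature's held-out
    values permuted), averaged over ``n_repeats`` permutations.
    ``mode='oob'`` uses out-of-bag predictions instead of a held-out split
    (requires a forest with ``oob_score``).
    """
    from sklearn.model_selection import train_test_split

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    if classifier is None:
        classifier = default_classifier(rng_seed)
    rng = np.random.default_rng(rng_seed)
    X = features.to_numpy()
    if mode == "holdout":
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, labels, test_size=test_size, stratify=labels, random_state=rng_seed
        )
    elif mode == "oob":
        X_tr = X_te = X
        y_tr = y_te = labels
    else:
        raise ValueError(f"unknown mode {mode!r}")
    classifier.fit(X_tr, y_tr)
    baseline = float(np.mean(classifier.predict(X_te) == y_te))
    rows = []
    for j, name in enumerate(features.columns):
        drops = []
        for _ in range(n_repeats):
            Xp = X_te.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            acc = float(np.mean(classifier.predict(Xp) == y_te))
            drops.append(baseline - acc)
        rows.append(
            {
                "feature": name,
                "mean_decrease_accuracy": float(np.mean(drops)),
                "sd": float(np.std(drops)),
            }
        )
    out = (
        pd.DataFrame(rows)
        .sort_values("mean_decrease_accuracy", ascending=False)
        .reset_index(drop=True)
    )
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["baseline_accuracy"] = baseline
    out.attrs["mode"] = mode
    out.attrs["rng_seed"] = rng_seed
    return out
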