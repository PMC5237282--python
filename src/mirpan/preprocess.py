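"""Expression preprocessing: missingness filter, k-NN imputation, log
transform and standardization.

The pipeline order is filter -> impute -> log -> standardize.  A feature is
removed when it is missing in strictly more than the threshold fraction of
samples (default 0.2).  Imputation replaces each missing entry with the
unweighted mean of the k nearest samples, where nearness is plain Euclidean
distance over the features both samples observe, and only samples that
observe the target feature are eligible neighbors; ties in distance are
broken by sample order, and a sample with no mutually observed features
falls back to the feature mean.  Standardization can fit on the data at
hand (global mode) or apply statistics fitted on a training fold to held-out
or external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, PreprocessConfig

__all__ = [
    "FeatureStatistics",
    "filter_features_by_missingness",
    "knn_impute",
    "log_transform",
    "standardize",
    "preprocess_pipeline",
]


@dataclass
class FeatureStatistics:
    """Per-feature mean/SD fitted during standardization."""

    mean: pd.Series
    sd: pd.Series
    dropped_zero_variance: list[str] = field(default_factory=list)


def filter_features_by_missingness(
    data: ExpressionDataset, threshold: float = 0.2
) -> tuple[ExpressionDataset, list[str]]:
    """Drop features missing in strictly more than ``threshold`` of samples.

    Returns the filtered dataset and the list of removed feature ids
    (provenance).  Raises if no feature survives.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    frac = data.missing_fraction()
    keep = frac <= threshold  # boundary: exactly-threshold features are retained
    removed = list(frac.index[~keep])
    if not keep.any():
        raise ValueError(
            f"missingness filter at threshold {threshold} removed every feature"
        )
    return data.subset_features(list(frac.index[keep])), removed


def knn_impute(data: ExpressionDataset, k: int = 10) -> tuple[ExpressionDataset, list[str]]:
    """Fill every missing entry with the mean over the k nearest samples.

    Distance between two samples is the Euclidean norm over the features
    both observe; candidate neighbors must observe the feature being
    imputed.  Returns the completed dataset and a log of fallbacks (sample
    ids imputed from the feature mean for lack of mutually observed
    features / neighbors).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = data.values.to_numpy(dtype=float, copy=True)
    observed = ~np.isnan(X)
    if not observed.any(axis=0).all():
        bad = [data.feature_ids[j] for j in np.flatnonzero(~observed.any(axis=0))]
        raise ValueError(f"features with no observed value cannot be imputed: {bad[:5]}")
    feature_means = np.nanmean(X, axis=0)  # per-feature mean over observing samples
    out = X.copy()
    fallbacks: list[str] = []
    missing_rows = np.flatnonzero(~observed.all(axis=1))
    for i in missing_rows:
        shared = observed & observed[i]  # features mutually observed with sample i
        diffs = np.where(shared, X - X[i], 0.0)
        with np.errstate(invalid="ignore"):
            dists = np.sqrt(np.nansum(diffs**2, axis=1))
        dists[i] = np.inf
        dists[~shared.any(axis=1)] = np.inf  # no overlap at all
        for j in np.flatnonzero(~observed[i]):
            candidates = np.flatnonzero(observed[:, j] & np.isfinite(dists))
            if candidates.size == 0:
                out[i, j] = feature_means[j]
                fallbacks.append(data.sample_ids[i])
                continue
            order = np.lexsort((candidates, dists[candidates]))  # ties -> sample order
            chosen = candidates[order[: min(k, candidates.size)]]
            out[i, j] = X[chosen, j].mean()
    frame = pd.DataFrame(out, index=data.values.index, columns=data.values.columns)
    return data.with_values(frame), sorted(set(fallbacks))


def log_transform(
    data: ExpressionDataset, base: float = 2.0, offset: float = 1.0
) -> ExpressionDataset:
    """Elementwise log_base(value + offset); missing entries stay missing."""
    shifted = data.values + offset
    bad = (shifted <= 0).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "log transform undefined: value "
            f"{data.values.iat[i, j]} + offset {offset} <= 0 at sample "
            f"{data.sample_ids[i]!r}, feature {data.feature_ids[j]!r}"
        )
    return data.with_values(np.log(shifted) / np.log(base))


def standardize(
    data: ExpressionDataset, statistics: FeatureStatistics | None = None
) -> tuple[ExpressionDataset, FeatureStatistics]:
    """Z-score per feature; fit statistics unless supplied.

    Zero-variance features are dropped during fitting (recorded in the
    returned statistics).  When statistics are supplied — e.g. fitted on a
    training fold and applied to a test fold, or to an external dataset —
    only the features they cover are kept.
    """
    if statistics is None:
        mean = data.values.mean(axis=0)
        sd = data.values.std(axis=0, ddof=0)
        dropped = list(sd.index[sd == 0])
        keep = list(sd.index[sd > 0])
        statistics = FeatureStatistics(mean=mean[keep], sd=sd[keep], dropped_zero_variance=dropped)
    cols = list(statistics.mean.index)
    values = (data.values[cols] - statistics.mean) / statistics.sd
    return data.with_values(values), statistics


def preprocess_pipeline(
    data: ExpressionDataset,
    config: PreprocessConfig = PreprocessConfig(),
    statistics: FeatureStatistics | None = None,
) -> tuple[ExpressionDataset, FeatureStatistics, dict]:
    """filter -> impute -> log -> standardize, returning provenance."""
    filtered, removed = filter_features_by_missingness(data, config.missing_threshold)
    imputed, fallbacks = knn_impute(filtered, config.knn_k)
    logged = log_transform(imputed, base=config.log_base, offset=config.log_offset)
    standardized, stats = standardize(logged, statistics)
    provenance = {
        "removed_features": removed,
        "imputation_fallback_samples": fallbacks,
        "dropped_zero_variance": stats.dropped_zero_variance,
    }
    return standardized, stats, provenance
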