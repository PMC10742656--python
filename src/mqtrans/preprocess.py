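"""Cohort preprocessing: annotation/partition, [0,1] normalization, control splits.

Normalization is per-feature min-max computed within one dataset at a time,
so no statistic of an evaluation cohort ever enters the training cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CONTROL, AnnotatedExpression, ExpressionMatrix, FeatureAnnotation

logger = logging.getLogger(__name__)


def annotate_and_partition(
    matrix: ExpressionMatrix,
    annotation: FeatureAnnotation,
    include_tf_targets: bool = False,
) -> AnnotatedExpression:
    """Drop unannotated probes and partition the rest into TFs and targets.

    A retained probe is a TF feature iff its gene symbol is in the TF list,
    otherwise a target feature; file order is preserved within each subset.
    With ``include_tf_targets`` TF probes are additionally modeled as
    regression targets (each excluded from its own predictor set downstream).
    """
    if not annotation.probe_to_gene:
        raise ValueError("annotation covers no probes")
    annotated = [f for f in matrix.feature_ids if annotation.gene_symbol(f) is not None]
    n_dropped = matrix.n_features - len(annotated)
    if n_dropped:
        logger.info("dropped %d unannotated features", n_dropped)
    tf_features = pd.Index([f for f in annotated if annotation.is_tf_probe(f)])
    target_features = pd.Index([f for f in annotated if not annotation.is_tf_probe(f)])
    if len(tf_features) == 0:
        raise ValueError("no TF features after annotation: nothing to use as predictors")
    if len(target_features) == 0 and not include_tf_targets:
        raise ValueError("no target features after annotation: nothing to model")
    keep = tf_features.append(target_features)
    return AnnotatedExpression(matrix.subset_features(keep), tf_features, target_features, annotation)


def minmax_normalize(data):
    """Rescale every feature to [0, 1] by its per-dataset min/max.

    Features that are constant (normalization undefined) or carry missing
    values (downstream regression and t-tests need complete vectors) are
    dropped with a logged warning.  Accepts and returns either an
    :class:`ExpressionMatrix` or an :class:`AnnotatedExpression`.
    """
    if isinstance(data, AnnotatedExpression):
        norm = minmax_normalize(data.matrix)
        kept = norm.feature_ids
        return AnnotatedExpression(
            norm,
            data.tf_features[data.tf_features.isin(kept)],
            data.target_features[data.target_features.isin(kept)],
            data.annotation,
        )
    values = data.values
    has_missing = values.isna().any(axis=1)
    if has_missing.any():
        logger.warning("dropping %d features with missing values", int(has_missing.sum()))
        values = values.loc[~has_missing]
    lo = values.min(axis=1)
    hi = values.max(axis=1)
    constant = hi == lo
    if constant.any():
        logger.warning("dropping %d constant features (min-max undefined)", int(constant.sum()))
        values = values.loc[~constant]
        lo, hi = lo[~constant], hi[~constant]
    if values.shape[0] == 0:
        raise ValueError("no features left after normalization")
    scaled = values.sub(lo, axis=0).div(hi - lo, axis=0)
    return ExpressionMatrix(scaled, data.labels)


def split_controls(data, train_fraction: float = 0.7, seed: int = 0):
    """Split a labeled cohort into a control-only training set and the rest.

    The training set holds ``floor(train_fraction * n_controls)`` controls
    drawn uniformly without replacement under ``seed``; the evaluation set
    holds every case sample plus the remaining controls.  Original sample
    order is preserved in both outputs.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    matrix = data.matrix if isinstance(data, AnnotatedExpression) else data
    controls = matrix.control_samples()
    n_train = int(np.floor(train_fraction * len(controls)))
    if n_train < 1 or n_train >= len(controls):
        raise ValueError(
            f"cannot split {len(controls)} controls with fraction {train_fraction}: "
            "both the training and evaluation control sets must be non-empty"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(controls), size=n_train, replace=False).tolist())
    train_ids = pd.Index([c for i, c in enumerate(controls) if i in chosen])
    train_set = set(train_ids)
    eval_ids = pd.Index([s for s in matrix.sample_ids if s not in train_set])
    logger.info("control split: %d training controls, %d evaluation samples", len(train_ids), len(eval_ids))
    return data.subset_samples(train_ids), data.subset_samples(eval_ids)


__all__ = ["annotate_and_partition", "minmax_normalize", "split_controls", "CONTROL"]
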