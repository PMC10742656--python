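import numpy as np
import pandas as pd
import pytest

from mqtrans.containers import AnnotatedExpression, ExpressionMatrix, FeatureAnnotation
from mqtrans.screen import STAT_COLUMNS, DatasetScreenResult, ScreenPolicy


def build_annotated(tf_values, target_values, labels=None, tf_ids=None, target_ids=None):
    """Assemble an AnnotatedExpression from raw TF and target arrays.

    Arrays are features x samples; labels is an optional list of
    'case'/'control' strings aligned to columns.
    """
    tf_values = np.atleast_2d(np.asarray(tf_values, float))
    target_values = np.atleast_2d(np.asarray(target_values, float))
    tf_ids = pd.Index(tf_ids or [f"TF{i:03d}_at" for i in range(tf_values.shape[0])])
    target_ids = pd.Index(target_ids or [f"G{i:03d}_at" for i in range(target_values.shape[0])])
    sample_ids = pd.Index([f"S{i:03d}" for i in range(tf_values.shape[1])])
    values = pd.DataFrame(
        np.vstack([tf_values, target_values]), index=tf_ids.append(target_ids), columns=sample_ids
    )
    lab = pd.Series(labels, index=sample_ids, name="label") if labels is not None else None
    annotation = FeatureAnnotation(
        {p: p.removesuffix("_at") for p in values.index},
        frozenset(p.removesuffix("_at") for p in tf_ids),
    )
    return AnnotatedExpression(ExpressionMatrix(values, lab), tf_ids, target_ids, annotation)


def make_screen_result(dataset_id, rows, policy=None):
    """Build a DatasetScreenResult from a {feature: dict} mapping.

    Unspecified statistics default to unremarkable values; the dark/detour
    flags are derived from the supplied p-values and the policy, mirroring
    the screen's own logic.
    """
    policy = policy or ScreenPolicy()
    defaults = {
        "gene_symbol": "GENE", "pcc": 0.9, "p_original": 0.5, "p_mqtrans": 0.5,
        "p_mqtrans_bh": 0.5, "pn_original": 1.0, "pn_mqtrans": 1.0, "evaluable": True,
    }
    table = {}
    for feature, spec in rows.items():
        row = {**defaults, **spec}
        row["evaluable"] = bool(row["evaluable"]) and row["pcc"] > policy.pcc_threshold
        row["is_detour"] = row["evaluable"] and row["p_mqtrans"] < policy.alpha_detour
        row["is_dark"] = row["is_detour"] and row["p_original"] > policy.alpha_original
        table[feature] = row
    df = pd.DataFrame.from_dict(table, orient="index")[STAT_COLUMNS]
    df.index.name = "feature_id"
    return DatasetScreenResult(dataset_id, df, policy)


@pytest.fixture
def rng():
    return np.random.default_rng(20230921)
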