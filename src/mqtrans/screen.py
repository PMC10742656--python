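"""Two-level differential screening and dark-biomarker classification.

Each eligible target is tested case-vs-control twice: once on its original
expression values and once on its mqTrans residual magnitudes.  A target
whose mqTrans values differ significantly (p < alpha) is a DeTouR feature
(differential transcription regulation); a DeTouR feature whose original
expression is NOT differential (p > alpha) is a dark biomarker in that
dataset — it carries disease signal a conventional differential-expression
screen would discard.  Across datasets, a feature dark everywhere is a
strong dark biomarker; one dark in some but not all datasets, with a very
stable original expression (p > 0.5) in at least one dataset where it is
dark, is a weak dark biomarker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnnotatedExpression, split_case_control

logger = logging.getLogger(__name__)

STAT_COLUMNS = [
    "gene_symbol", "pcc", "p_original", "p_mqtrans", "p_mqtrans_bh",
    "pn_original", "pn_mqtrans", "evaluable", "is_detour", "is_dark",
]


@dataclass
class ScreenPolicy:
    """Thresholds governing eligibility and the two-level screen.

    All comparisons are strict inequalities: dark requires
    ``p_mqtrans < alpha_detour`` and ``p_original > alpha_original``; the
    weak call additionally requires ``p_original > weak_original_floor``
    in at least one dataset where the feature is dark.
    """

    alpha_detour: float = 0.05
    alpha_original: float = 0.05
    weak_original_floor: float = 0.5
    pcc_threshold: float = 0.5
    equal_variance: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha_detour < self.weak_original_floor <= 1):
            raise ValueError("need 0 < alpha_detour < weak_original_floor <= 1")
        if not (0 < self.alpha_original < self.weak_original_floor):
            raise ValueError("need 0 < alpha_original < weak_original_floor")
        if not (-1 < self.pcc_threshold < 1):
            raise ValueError("pcc_threshold must lie in (-1, 1)")


def two_sample_ttest(case_values, control_values, equal_variance: bool = True) -> tuple[float, float]:
    """Two-sided independent two-sample t-test (Student pooled or Welch).

    Two identical constant groups give ``(0.0, 1.0)`` by convention
    (no evidence of any difference, logged); two distinct constant groups
    give ``p = 0``.
    """
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size < 2 or control_values.size < 2:
        raise ValueError("each group needs at least two values")
    t, p = _ttest_arrays(case_values[None, :], control_values[None, :], equal_variance)
    return float(t[0]), float(p[0])


def _ttest_arrays(case: np.ndarray, control: np.ndarray, equal_variance: bool) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise t-tests with the degenerate-variance conventions applied."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(case, control, axis=1, equal_var=equal_variance)
    t, p = np.atleast_1d(np.asarray(t, float)), np.atleast_1d(np.asarray(p, float))
    undef = ~np.isfinite(t)
    if undef.any():
        same = np.isclose(case.mean(axis=1), control.mean(axis=1))
        n_equal = int((undef & same).sum())
        if n_equal:
            logger.warning("%d features constant and identical in both groups; p set to 1", n_equal)
        t[undef & same] = 0.0
        p[undef & same] = 1.0
        t[undef & ~same] = np.sign(case.mean(axis=1) - control.mean(axis=1))[undef & ~same] * np.inf
        p[undef & ~same] = 0.0
    return t, p


def pn_ratio(case_values, control_values) -> float:
    """P/N ratio: mean of the case group over the mean of the control group."""
    r = _pn_ratio_arrays(
        np.asarray(case_values, float)[None, :], np.asarray(control_values, float)[None, :]
    )
    return float(r[0])


def _pn_ratio_arrays(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    cm = control.mean(axis=1)
    zero = cm == 0
    if zero.any():
        logger.warning("%d features have zero control mean; P/N ratio undefined (NaN)", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(zero, np.nan, case.mean(axis=1) / np.where(zero, 1.0, cm))


@dataclass
class DatasetScreenResult:
    """Per-feature two-level statistics and dark flags for one dataset.

    ``table`` is indexed by feature ID with columns ``gene_symbol, pcc,
    p_original, p_mqtrans, p_mqtrans_bh, pn_original, pn_mqtrans,
    evaluable, is_detour, is_dark``.  ``p_mqtrans_bh`` is the
    Benjamini-Hochberg adjusted mqTrans p-value, reported for information
    only and never used in any call.
    """

    dataset_id: str
    table: pd.DataFrame
    policy: ScreenPolicy = field(default_factory=ScreenPolicy)

    def __post_init__(self) -> None:
        missing = [c for c in STAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"screen table missing columns {missing}")
        bad_detour = self.table["is_detour"] & ~self.table["evaluable"]
        bad_dark = self.table["is_dark"] & ~self.table["is_detour"]
        if bad_detour.any() or bad_dark.any():
            raise ValueError("inconsistent flags: is_dark => is_detour => evaluable must hold")

    @property
    def feature_ids(self) -> pd.Index:
        return self.table.index

    def dark_features(self) -> pd.Index:
        return self.table.index[self.table["is_dark"]]


def screen_dataset(
    dataset_id: str,
    original: AnnotatedExpression,
    mqtrans: pd.DataFrame,
    pcc: pd.Series,
    policy: ScreenPolicy | None = None,
) -> DatasetScreenResult:
    """Run the two-level case-vs-control screen on one evaluation dataset.

    Parameters
    ----------
    original
        Normalized annotated cohort with case/control labels.
    mqtrans
        Residual-magnitude matrix (targets x samples) from
        :meth:`RegulationResults.mqtrans`, on the same samples.
    pcc
        Per-target predicted-vs-observed correlations on this dataset;
        the eligibility gate is ``pcc > policy.pcc_threshold`` (NaN fails).

    Targets failing the gate are marked not evaluable with all flags false
    ("not evaluable" is distinct from "not dark") but their statistics are
    still reported.
    """
    policy = policy or ScreenPolicy()
    if original.labels is None:
        raise ValueError("screening requires case/control labels")
    if not original.sample_ids.equals(mqtrans.columns):
        raise ValueError("original and mqTrans matrices cover different samples")
    universe = pcc.index
    if not universe.isin(mqtrans.index).all():
        raise ValueError("pcc index must be a subset of the mqTrans targets")
    if not universe.isin(original.matrix.feature_ids).all():
        raise ValueError("pcc index must be a subset of the dataset features")

    labels = original.labels
    orig_case, orig_ctrl = split_case_control(original.matrix.values.loc[universe], labels)
    mq_case, mq_ctrl = split_case_control(mqtrans.loc[universe], labels)
    if orig_case.shape[1] < 2 or orig_ctrl.shape[1] < 2:
        raise ValueError("each group needs at least two samples")

    _, p_orig = _ttest_arrays(orig_case, orig_ctrl, policy.equal_variance)
    _, p_mq = _ttest_arrays(mq_case, mq_ctrl, policy.equal_variance)
    evaluable = (pcc > policy.pcc_threshold).fillna(False).to_numpy()
    is_detour = evaluable & (p_mq < policy.alpha_detour)
    is_dark = is_detour & (p_orig > policy.alpha_original)

    table = pd.DataFrame(
        {
            "gene_symbol": original.gene_symbols(universe),
            "pcc": pcc.to_numpy(),
            "p_original": p_orig,
            "p_mqtrans": p_mq,
            "p_mqtrans_bh": stats.false_discovery_control(np.clip(p_mq, 0, 1), method="bh"),
            "pn_original": _pn_ratio_arrays(orig_case, orig_ctrl),
            "pn_mqtrans": _pn_ratio_arrays(mq_case, mq_ctrl),
            "evaluable": evaluable,
            "is_detour": is_detour,
            "is_dark": is_dark,
        },
        index=universe,
    )
    logger.info(
        "dataset %s: %d targets, %d eligible, %d DeTouR, %d dark",
        dataset_id, len(universe), int(evaluable.sum()), int(is_detour.sum()), int(is_dark.sum()),
    )
    return DatasetScreenResult(dataset_id, table, policy)


def count_detour_features(result: DatasetScreenResult, alpha: float | None = None) -> int:
    """Number of evaluable features with mqTrans p below ``alpha``."""
    alpha = result.policy.alpha_detour if alpha is None else alpha
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    t = result.table
    return int((t["evaluable"] & (t["p_mqtrans"] < alpha)).sum())


def rank_features_by_p(result: DatasetScreenResult, level: str = "original") -> pd.DataFrame:
    """Rank all screened features by ascending p-value at one level.

    ``level`` is ``"original"`` or ``"mqtrans"``.  Ties are broken by
    feature ID (stable and deterministic); ranks are 1-based and
    contiguous.
    """
    if level not in ("original", "mqtrans"):
        raise ValueError("level must be 'original' or 'mqtrans'")
    col = f"p_{level}"
    out = result.table[[col]].copy()
    order = np.lexsort((out.index.to_numpy(), out[col].to_numpy()))
    out = out.iloc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def classify_dark_biomarkers(
    results: list[DatasetScreenResult], policy: ScreenPolicy | None = None
) -> pd.DataFrame:
    """Cross-dataset strong/weak dark-biomarker classification.

    Over the union of screened features:

    * ``strong`` — dark in every analyzed dataset;
    * ``weak``   — dark in at least one but not all datasets AND original
      p > ``weak_original_floor`` in at least one dataset where dark;
    * ``none``   — everything else, kept with a reason code.

    Returns a DataFrame indexed by feature with columns ``gene_symbol,
    call, reason`` plus per-dataset ``dark_<id>`` and ``pcc_<id>``
    columns, ordered strong first, then weak, then none, by feature ID
    within each block.
    """
    if not results:
        raise ValueError("need at least one dataset result")
    policy = policy or results[0].policy
    universe = results[0].feature_ids
    for r in results[1:]:
        universe = universe.union(r.feature_ids, sort=False)
    universe = pd.Index(sorted(universe))

    dark = pd.DataFrame(index=universe)
    pcc = pd.DataFrame(index=universe)
    floor_ok = pd.DataFrame(index=universe)
    genes = pd.Series(index=universe, dtype=object)
    for r in results:
        t = r.table.reindex(universe)
        dark[r.dataset_id] = t["is_dark"].fillna(False).astype(bool)
        pcc[r.dataset_id] = t["pcc"]
        floor_ok[r.dataset_id] = dark[r.dataset_id] & (t["p_original"] > policy.weak_original_floor)
        genes = genes.fillna(t["gene_symbol"])

    n_dark = dark.sum(axis=1)
    strong = n_dark == len(results)
    weak = (n_dark > 0) & ~strong & floor_ok.any(axis=1)
    call = np.where(strong, "strong", np.where(weak, "weak", "none"))
    reason = np.where(
        strong, "dark in every dataset",
        np.where(
            weak, "dark in a strict subset with original p above the weak floor",
            np.where(n_dark > 0, "dark in a subset but never above the weak floor", "not dark in any dataset"),
        ),
    )
    out = pd.DataFrame({"gene_symbol": genes, "call": call, "reason": reason}, index=universe)
    for ds in dark.columns:
        out[f"dark_{ds}"] = dark[ds]
        out[f"pcc_{ds}"] = pcc[ds]
    order = pd.Categorical(out["call"], categories=["strong", "weak", "none"], ordered=True)
    out = out.iloc[np.lexsort((out.index, order.codes))]
    out.index.name = "feature_id"
    return out


def write_report(calls: pd.DataFrame, results: list[DatasetScreenResult], summary_path, stats_path=None) -> None:
    """Write the dark-biomarker summary TSV plus the full statistics table.

    The summary mirrors the call table layout (Type, Feature, Gene, then
    one dark flag and one PCC column per dataset) and contains only strong
    and weak calls; the statistics file is long-format with one row per
    feature and dataset.
    """
    ds_ids = [r.dataset_id for r in results]
    hits = calls[calls["call"].isin(["strong", "weak"])]
    summary = pd.DataFrame({
        "Type": hits["call"].str.capitalize(),
        "Feature": hits.index,
        "Gene": hits["gene_symbol"],
    })
    for ds in ds_ids:
        summary[f"db_{ds}"] = hits[f"dark_{ds}"].astype(int).to_numpy()
        summary[f"PCC_{ds}"] = hits[f"pcc_{ds}"].to_numpy()
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.4f")
    if stats_path is not None:
        frames = []
        for r in results:
            t = r.table.copy()
            t.insert(0, "dataset", r.dataset_id)
            t.insert(0, "feature_id", t.index)
            frames.append(t)
        pd.concat(frames).to_csv(stats_path, sep="\t", index=False, float_format="%.6g")


def read_report(summary_path) -> pd.DataFrame:
    """Read a summary report back (inverse of the summary half of write_report)."""
    return pd.read_csv(summary_path, sep="\t", dtype={"Feature": str})


def pca_coordinates(values: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Project samples onto the top principal components of a feature submatrix.

    ``values`` is features x samples (e.g. the dark-biomarker mqTrans
    submatrix); returns samples x components coordinates suitable for a
    dot plot.
    """
    from sklearn.decomposition import PCA

    n_components = min(n_components, min(values.shape))
    coords = PCA(n_components=n_components).fit_transform(values.to_numpy().T)
    return pd.DataFrame(
        coords, index=values.columns, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
    )
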