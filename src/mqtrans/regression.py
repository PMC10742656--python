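"""Transcription-regulation regression: predict each target gene from TF expression.

The model of transcription regulation is one ordinary-least-squares linear
regression per target gene,

    mRNA'(F) = W0 + W1*TF_1 + ... + Wn*TF_n,

fitted on healthy control samples only.  The residual magnitude

    mqTrans(F, s) = | mRNA'(F, s) - mRNA(F, s) |

quantifies, for a query sample ``s``, how far gene ``F`` departs from the
healthy regulatory pattern: if the TF->target mapping learned in health
still holds, the prediction tracks the observation and mqTrans is near
zero; if the regulation has been rewired, the residual grows even when the
marginal expression of ``F`` is unchanged.

With more TFs than training samples the least-squares system is
under-determined; the minimum-norm solution (pseudo-inverse) is used, with
the intercept obtained by centering predictors and response before
solving.  Model quality is gated per evaluation dataset by the Pearson
correlation between predicted and observed target expression (strictly
greater than 0.5 by default); only gated targets are screened there.
Predictions are deliberately not clipped to [0, 1]: extrapolation failures
are exactly the signal the residual is meant to carry.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AnnotatedExpression, CONTROL

logger = logging.getLogger(__name__)

DEFAULT_PCC_THRESHOLD = 0.5


def _minnorm_ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-norm OLS of the centered system.

    X is samples x predictors, Y samples x responses.  Returns
    ``(weights, intercepts)`` with weights of shape predictors x responses.
    In the over-determined regime this is the unique OLS solution; in the
    under-determined regime it is the least-squares solution of minimum
    Euclidean norm (the pseudo-inverse solution).
    """
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite values in the regression inputs")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    W, *_ = np.linalg.lstsq(X - x_mean, Y - y_mean, rcond=None)
    intercepts = y_mean - x_mean @ W
    return W, intercepts


def _ridge_ols(X: np.ndarray, Y: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    from sklearn.linear_model import Ridge

    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite values in the regression inputs")
    est = Ridge(alpha=alpha, fit_intercept=True).fit(X, Y)
    coef = est.coef_ if est.coef_.ndim == 2 else est.coef_[None, :]
    return coef.T, np.atleast_1d(est.intercept_)


def pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equal-shape matrices.

    Rows where either vector is constant yield NaN.
    """
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(r, -1.0, 1.0)


@dataclass
class GeneRegressionModel:
    """A single target gene's TF regression: intercept plus one weight per TF."""

    target_id: str
    intercept: float
    weights: np.ndarray
    tf_order: pd.Index

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.tf_order = pd.Index(self.tf_order)
        if self.weights.shape != (len(self.tf_order),):
            raise ValueError("weights and tf_order lengths differ")
        if not np.isfinite(self.weights).all() or not np.isfinite(self.intercept):
            raise ValueError("non-finite model coefficients")

    def predict(self, tf_values) -> np.ndarray:
        """Predict target expression for TFs x samples values (rows = tf_order)."""
        tf_values = np.asarray(tf_values, dtype=float)
        if tf_values.shape[0] != len(self.tf_order):
            raise ValueError(
                f"TF matrix has {tf_values.shape[0]} rows; model expects {len(self.tf_order)}"
            )
        return self.intercept + self.weights @ tf_values


def fit_gene_model(tf_train, target_train, target_id: str = "target", tf_order=None) -> GeneRegressionModel:
    """Fit one target's OLS model from TFs x samples training values.

    Returns the minimum-norm least-squares solution; a constant target
    yields all-zero weights with intercept equal to its mean.
    """
    tf_train = np.asarray(tf_train, dtype=float)
    y = np.asarray(target_train, dtype=float)
    if tf_train.ndim != 2 or tf_train.shape[1] != y.shape[0]:
        raise ValueError("tf_train column count must equal target_train length")
    if y.shape[0] < 2:
        raise ValueError("need at least two training samples")
    W, b = _minnorm_ols(tf_train.T, y[:, None])
    if tf_order is None:
        tf_order = pd.Index([f"TF{i}" for i in range(tf_train.shape[0])])
    return GeneRegressionModel(target_id, float(b[0]), W[:, 0], tf_order)


class TranscriptionRegulationModel:
    """Per-target TF regression models trained on healthy control samples.

    Parameters
    ----------
    train
        Annotated, normalized training cohort.  Must contain only control
        samples (this is the reference regulatory state being learned).
    include_tf_targets
        Also model TF probes as targets, excluding each from its own
        predictor set.  Off by default: a TF probe is a predictor, not a
        response.
    ridge
        Optional L2 penalty for stability studies; 0 (off) keeps the plain
        minimum-norm OLS reading of the protocol.
    """

    def __init__(self, train: AnnotatedExpression, include_tf_targets: bool = False, ridge: float = 0.0):
        if train.labels is not None and (train.labels == "case").any():
            raise ValueError("training cohort must contain only control samples")
        if train.matrix.n_samples < 2:
            raise ValueError("need at least two training samples")
        if len(train.tf_features) == 0:
            raise ValueError("training cohort has no TF features")
        self.train = train
        self.include_tf_targets = include_tf_targets
        self.ridge = float(ridge)

    def fit(self) -> "RegulationResults":
        """Fit every target's model and score in-sample prediction quality."""
        train = self.train
        X = train.tf_values().to_numpy().T          # samples x TFs
        Y = train.target_values().to_numpy().T      # samples x targets
        solver = (lambda A, B: _ridge_ols(A, B, self.ridge)) if self.ridge > 0 else _minnorm_ols
        W, b = solver(X, Y)
        target_ids = train.target_features
        weights = pd.DataFrame(W.T, index=target_ids, columns=train.tf_features)
        intercepts = pd.Series(b, index=target_ids, name="intercept")

        if self.include_tf_targets:
            tf_ids = train.tf_features
            rows, bs = [], []
            for i, t in enumerate(tf_ids):
                others = np.delete(np.arange(len(tf_ids)), i)
                Wt, bt = solver(X[:, others], X[:, [i]])
                full = np.zeros(len(tf_ids))
                full[others] = Wt[:, 0]
                rows.append(full)
                bs.append(bt[0])
            extra_w = pd.DataFrame(rows, index=tf_ids, columns=tf_ids)
            weights = pd.concat([weights, extra_w])
            intercepts = pd.concat([intercepts, pd.Series(bs, index=tf_ids)])
            target_ids = target_ids.append(tf_ids)

        pred = weights.to_numpy() @ X.T + intercepts.to_numpy()[:, None]
        obs = train.matrix.values.loc[target_ids].to_numpy()
        training_pcc = pd.Series(pearson_rows(pred, obs), index=target_ids, name="training_pcc")
        training_rmse = pd.Series(
            np.sqrt(((pred - obs) ** 2).mean(axis=1)), index=target_ids, name="training_rmse"
        )
        n_degenerate = int(training_pcc.isna().sum())
        if n_degenerate:
            logger.warning("%d degenerate targets (constant in training); excluded from screening", n_degenerate)
        return RegulationResults(
            tf_order=train.tf_features,
            weights=weights,
            intercepts=intercepts,
            training_pcc=training_pcc,
            training_rmse=training_rmse,
            n_train=train.matrix.n_samples,
            annotation=train.annotation,
        )


class RegulationResults:
    """Fitted TF->target regressions plus training diagnostics.

    Attributes
    ----------
    tf_order : pd.Index
        Shared ordered TF probe list every model's weights align to.
    weights : pd.DataFrame
        Targets x TFs coefficient matrix.
    intercepts, training_pcc, training_rmse : pd.Series
        Per-target intercept and in-sample prediction quality.
    """

    def __init__(self, tf_order, weights, intercepts, training_pcc, training_rmse, n_train, annotation=None):
        self.tf_order = pd.Index(tf_order)
        self.weights = weights
        self.intercepts = intercepts
        self.training_pcc = training_pcc
        self.training_rmse = training_rmse
        self.n_train = int(n_train)
        self.annotation = annotation
        if not self.weights.columns.equals(self.tf_order):
            raise ValueError("weight columns must follow the shared tf_order")
        if not np.isfinite(self.weights.to_numpy()).all():
            raise ValueError("non-finite fitted weights")

    @property
    def target_ids(self) -> pd.Index:
        return self.weights.index

    def model_for(self, target_id: str) -> GeneRegressionModel:
        """Single-gene view of one fitted model."""
        return GeneRegressionModel(
            target_id,
            float(self.intercepts.loc[target_id]),
            self.weights.loc[target_id].to_numpy(),
            self.tf_order,
        )

    # -- prediction ----------------------------------------------------

    def _tf_matrix(self, data) -> pd.DataFrame:
        if isinstance(data, AnnotatedExpression):
            missing = self.tf_order[~self.tf_order.isin(data.matrix.feature_ids)]
            if len(missing):
                raise ValueError(f"dataset is missing TF features: {missing[:5].tolist()}")
            return data.matrix.values.loc[self.tf_order]
        data = pd.DataFrame(data)
        if data.shape[0] != len(self.tf_order):
            raise ValueError(f"TF matrix has {data.shape[0]} rows; model expects {len(self.tf_order)}")
        return data

    def predict(self, data) -> pd.DataFrame:
        """Predicted expression mRNA'(F) for every modeled target (targets x samples)."""
        tf = self._tf_matrix(data)
        pred = self.weights.to_numpy() @ tf.to_numpy() + self.intercepts.to_numpy()[:, None]
        return pd.DataFrame(pred, index=self.target_ids, columns=tf.columns)

    def mqtrans(self, data) -> pd.DataFrame:
        """mqTrans residual magnitudes |mRNA'(F) - mRNA(F)| (targets x samples).

        ``data`` must be an :class:`AnnotatedExpression` containing both the
        shared TFs and the modeled targets.
        """
        if not isinstance(data, AnnotatedExpression):
            raise TypeError("mqtrans needs an AnnotatedExpression (observed targets required)")
        missing = self.target_ids[~self.target_ids.isin(data.matrix.feature_ids)]
        if len(missing):
            raise ValueError(f"dataset is missing modeled targets: {missing[:5].tolist()}")
        pred = self.predict(data)
        obs = data.matrix.values.loc[self.target_ids]
        return (pred - obs).abs()

    def pcc(self, data) -> pd.Series:
        """Per-target Pearson correlation of predicted vs observed expression.

        Computed over all samples of ``data`` (cases and controls together);
        NaN when either vector is constant.
        """
        if not isinstance(data, AnnotatedExpression):
            raise TypeError("pcc needs an AnnotatedExpression (observed targets required)")
        missing = self.target_ids[~self.target_ids.isin(data.matrix.feature_ids)]
        if len(missing):
            raise ValueError(f"dataset is missing modeled targets: {missing[:5].tolist()}")
        pred = self.predict(data).to_numpy()
        obs = data.matrix.values.loc[self.target_ids].to_numpy()
        return pd.Series(pearson_rows(pred, obs), index=self.target_ids, name="pcc")

    def eligible_targets(self, data, threshold: float = DEFAULT_PCC_THRESHOLD) -> pd.Index:
        """Targets whose predicted/observed PCC strictly exceeds ``threshold``.

        A NaN correlation (degenerate target) never passes the gate.
        """
        if not -1.0 < threshold < 1.0:
            raise ValueError("threshold must lie in (-1, 1)")
        r = self.pcc(data)
        return r.index[(r > threshold).fillna(False)]

    # -- reporting -----------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary."""
        r = self.training_pcc.dropna()
        lines = [
            "Transcription regulation model (OLS on healthy controls)",
            "=" * 58,
            f"targets modeled        {len(self.target_ids)}",
            f"TF predictors          {len(self.tf_order)}",
            f"training samples       {self.n_train}",
            f"degenerate targets     {int(self.training_pcc.isna().sum())}",
            f"training PCC  median   {r.median():.4f}" if len(r) else "training PCC  median   n/a",
            f"training PCC  min/max  {r.min():.4f} / {r.max():.4f}" if len(r) else "",
            f"training RMSE median   {self.training_rmse.median():.4g}",
        ]
        return "\n".join(line for line in lines if line)

    # -- serialization -------------------------------------------------

    def tf_order_hash(self) -> str:
        return hashlib.sha256("\n".join(map(str, self.tf_order)).encode()).hexdigest()[:16]

    def save(self, path) -> None:
        """Write the model set as a weight TSV plus a JSON metadata sidecar.

        Floats are printed with 17 significant digits, so load() restores
        them bit-exactly.
        """
        path = Path(path)
        table = pd.concat(
            [self.intercepts.rename("intercept"),
             self.training_pcc.rename("training_pcc"),
             self.training_rmse.rename("training_rmse"),
             self.weights],
            axis=1,
        )
        table.to_csv(path, sep="\t", index_label="target_id", float_format="%.17g")
        meta = {
            "n_train": self.n_train,
            "n_targets": int(len(self.target_ids)),
            "tf_order_hash": self.tf_order_hash(),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "RegulationResults":
        path = Path(path)
        table = pd.read_csv(path, sep="\t", index_col="target_id", float_precision="round_trip")
        table.index = table.index.astype(str)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        tf_cols = [c for c in table.columns if c not in ("intercept", "training_pcc", "training_rmse")]
        res = cls(
            tf_order=pd.Index(tf_cols),
            weights=table[tf_cols],
            intercepts=table["intercept"],
            training_pcc=table["training_pcc"],
            training_rmse=table["training_rmse"],
            n_train=meta["n_train"],
        )
        if res.tf_order_hash() != meta["tf_order_hash"]:
            raise ValueError("TF order hash mismatch: weight file does not match its sidecar")
        return res
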