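"""Core in-memory containers for probe-level expression cohorts.

An :class:`ExpressionMatrix` is a features x samples table of expression
intensities with optional binary case/control labels.  A
:class:`FeatureAnnotation` maps probe identifiers to gene symbols and
designates which symbols are transcription factors (TFs).  An
:class:`AnnotatedExpression` is an expression matrix whose annotated
features have been partitioned into TF features (regression predictors)
and target features (regression responses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"
VALID_LABELS = frozenset({CASE, CONTROL})


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with per-sample group labels.

    Parameters
    ----------
    values
        DataFrame with probe IDs as the index and sample IDs as columns.
        Missing measurements are NaN.
    labels
        Optional Series mapping sample ID to ``"case"`` or ``"control"``.
        Must cover every sample when present.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe IDs: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.columns)
            if self.labels.isna().any():
                missing = self.labels.index[self.labels.isna()].tolist()
                raise ValueError(f"samples without a group label: {missing[:5]}")
            bad = set(self.labels.unique()) - VALID_LABELS
            if bad:
                raise ValueError(f"labels must be in {sorted(VALID_LABELS)}, got {sorted(bad)}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def control_samples(self) -> pd.Index:
        self._require_labels()
        return self.sample_ids[self.labels.to_numpy() == CONTROL]

    def case_samples(self) -> pd.Index:
        self._require_labels()
        return self.sample_ids[self.labels.to_numpy() == CASE]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        labels = self.labels.loc[sample_ids] if self.labels is not None else None
        return ExpressionMatrix(self.values.loc[:, sample_ids], labels)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[feature_ids], self.labels)

    def _require_labels(self) -> None:
        if self.labels is None:
            raise ValueError("this operation requires sample group labels")


@dataclass
class FeatureAnnotation:
    """Probe -> gene-symbol mapping plus the set of TF gene symbols."""

    probe_to_gene: dict[str, str]
    tf_symbols: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        # empty symbols mean "unannotated"; normalise them away
        self.probe_to_gene = {
            str(p): str(g) for p, g in self.probe_to_gene.items()
            if g is not None and str(g).strip() != "" and not pd.isna(g)
        }
        self.tf_symbols = frozenset(str(s) for s in self.tf_symbols)

    def gene_symbol(self, probe_id: str) -> str | None:
        return self.probe_to_gene.get(probe_id)

    def is_tf_probe(self, probe_id: str) -> bool:
        sym = self.probe_to_gene.get(probe_id)
        return sym is not None and sym in self.tf_symbols


@dataclass
class AnnotatedExpression:
    """Expression matrix with features partitioned into TFs and targets.

    ``tf_features`` and ``target_features`` are disjoint ordered subsets of
    ``matrix.feature_ids``; every member carries a gene-symbol annotation
    recorded in ``annotation``.
    """

    matrix: ExpressionMatrix
    tf_features: pd.Index
    target_features: pd.Index
    annotation: FeatureAnnotation

    def __post_init__(self) -> None:
        self.tf_features = pd.Index(self.tf_features)
        self.target_features = pd.Index(self.target_features)
        if len(self.tf_features.intersection(self.target_features)) > 0:
            raise ValueError("tf_features and target_features overlap")
        all_ids = self.matrix.feature_ids
        for name, idx in (("tf", self.tf_features), ("target", self.target_features)):
            if not idx.isin(all_ids).all():
                raise ValueError(f"{name}_features not contained in the matrix features")

    @property
    def labels(self) -> pd.Series | None:
        return self.matrix.labels

    @property
    def sample_ids(self) -> pd.Index:
        return self.matrix.sample_ids

    def tf_values(self) -> pd.DataFrame:
        """TF expression sub-matrix (TFs x samples)."""
        return self.matrix.values.loc[self.tf_features]

    def target_values(self) -> pd.DataFrame:
        """Target expression sub-matrix (targets x samples)."""
        return self.matrix.values.loc[self.target_features]

    def gene_symbols(self, feature_ids=None) -> pd.Series:
        if feature_ids is None:
            feature_ids = self.tf_features.append(self.target_features)
        return pd.Series(
            [self.annotation.gene_symbol(f) for f in feature_ids],
            index=pd.Index(feature_ids), name="gene_symbol",
        )

    def subset_samples(self, sample_ids) -> "AnnotatedExpression":
        return AnnotatedExpression(
            self.matrix.subset_samples(sample_ids),
            self.tf_features, self.target_features, self.annotation,
        )


def split_case_control(values: pd.DataFrame, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Return (case_matrix, control_matrix) as numpy arrays, rows = features."""
    lab = labels.reindex(values.columns).to_numpy()
    return values.to_numpy()[:, lab == CASE], values.to_numpy()[:, lab == CONTROL]
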