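"""Readers and writers for the plain-text cohort formats.

Formats
-------
* expression matrix: tab-separated, features in rows, first column = probe
  ID, header row = sample IDs; ``#``-prefixed comment lines are skipped;
  non-numeric cells (``NA``, ``null``, blanks, ...) become missing values.
* labels: two-column TSV ``sample_id<TAB>{case|control}``.
* probe annotation: TSV with columns ``probe_id`` and ``gene_symbol``
  (empty gene_symbol = unannotated probe).
* TF list: plain text, one gene symbol per line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, FeatureAnnotation, VALID_LABELS

logger = logging.getLogger(__name__)

_NA_VALUES = ["NA", "N/A", "NaN", "nan", "null", ""]


def read_expression_matrix(path, labels=None) -> ExpressionMatrix:
    """Read a features x samples TSV into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    path
        Expression TSV; rows/columns are kept in file order.
    labels
        Optional label source: a path to a two-column label TSV or a
        pandas Series indexed by sample ID.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, comment="#",
        na_values=_NA_VALUES, keep_default_na=True, float_precision="round_trip",
    )
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    df = df.apply(pd.to_numeric, errors="coerce")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate probe IDs {dups[:5]}")
    if isinstance(labels, (str, Path)):
        labels = read_labels(labels)
    return ExpressionMatrix(df, labels)


def write_expression_matrix(matrix: ExpressionMatrix, path, float_format: str = "%.17g") -> None:
    """Write an expression matrix as TSV (value round-trip is exact)."""
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format=float_format)


def read_labels(path) -> pd.Series:
    """Read a two-column ``sample_id<TAB>label`` table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: label table must have exactly two columns")
    # tolerate an optional header row ("sample_id<TAB>label")
    if str(df.iloc[0, 1]).strip().lower() == "label":
        df = df.iloc[1:]
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty label table")
    labels = pd.Series(
        df.iloc[:, 1].str.lower().to_numpy(),
        index=pd.Index(df.iloc[:, 0], name="sample_id"), name="label",
    )
    bad = set(labels.unique()) - VALID_LABELS
    if bad:
        raise ValueError(f"{path}: invalid group labels {sorted(bad)}")
    if labels.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample IDs in label table")
    return labels


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("label").to_csv(path, sep="\t", header=True, index_label="sample_id")


def read_probe_annotation(path) -> dict[str, str]:
    """Read the probe -> gene-symbol table; unannotated probes are dropped."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation table needs (probe_id, gene_symbol) columns")
    probes, symbols = df.iloc[:, 0], df.iloc[:, 1]
    if probes.duplicated().any():
        raise ValueError(f"{path}: a probe maps to more than one gene symbol")
    return {p: g for p, g in zip(probes, symbols) if g.strip() != ""}


def read_tf_list(path) -> frozenset[str]:
    """Read a one-symbol-per-line TF gene-symbol list."""
    with open(path, encoding="utf-8") as fh:
        symbols = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    return frozenset(symbols)


def read_annotation(annotation_path, tf_list_path) -> FeatureAnnotation:
    """Assemble a :class:`FeatureAnnotation` from its two source files."""
    return FeatureAnnotation(read_probe_annotation(annotation_path), read_tf_list(tf_list_path))


def write_annotation(annotation: FeatureAnnotation, annotation_path, tf_list_path) -> None:
    pd.DataFrame(
        {"probe_id": list(annotation.probe_to_gene), "gene_symbol": list(annotation.probe_to_gene.values())}
    ).to_csv(annotation_path, sep="\t", index=False)
    with open(tf_list_path, "w", encoding="utf-8") as fh:
        for sym in sorted(annotation.tf_symbols):
            fh.write(sym + "\n")
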