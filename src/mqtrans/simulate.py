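"""Synthetic multi-dataset case/control cohorts with planted ground truth.

The generator emulates the statistical structure the screening protocol
assumes: TF expression values are i.i.d. uniform on [0, 1] (the normalized
scale), and each target gene is a sparse linear function of the TFs plus
Gaussian noise.  Four planted gene classes exercise every pipeline stage:

* ``NULL``   — identical generative process in cases and controls;
* ``DARK``   — regulation rewired in cases: the nonzero TF weights are
  permuted (a derangement) across the gene's TF support.  Because the TFs
  are exchangeable, the marginal distribution of the gene is exactly
  unchanged — the gene is invisible to an expression-level test — while
  the TF->target mapping, and hence the healthy-model residual, changes;
* ``DE``     — classically differentially expressed: cases shifted by
  ``de_effect * noise_sd``;
* ``LOWFIT`` — pure noise uncorrelated with every TF; such genes should
  fail the model-quality (PCC) gate and never be screened.

Multiple datasets share one :class:`GroundTruth` (the same regulatory
weights) but are sampled independently, emulating a multi-cohort
screening-plus-validation design.  Everything is deterministic under the
spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import AnnotatedExpression, ExpressionMatrix, FeatureAnnotation
from . import io as mqio

GENE_CLASSES = ("NULL", "DARK", "DE", "LOWFIT")

_SQRT_2_OVER_PI = float(np.sqrt(2.0 / np.pi))
_TF_VAR = 1.0 / 12.0  # variance of U(0, 1)


@dataclass
class CohortSpec:
    """Parameters of a synthetic multi-dataset cohort.

    Defaults describe the standard well-determined benchmark: 20 TFs and
    1000 target genes over three datasets of 100 cases + 100 controls,
    with 5% of targets in each planted non-NULL class.  With the usual
    0.7 control split this leaves 70 training controls, 3.5x the TF
    count, so the healthy regression is well-determined and its
    prediction noise stays well below the residual noise.  Use
    :meth:`underdetermined_stress` for the more-TFs-than-samples regime.
    """

    n_tf: int = 20
    n_targets: int = 1000
    n_datasets: int = 3
    n_case: int = 100
    n_control: int = 100
    weight_sparsity: int = 5
    weight_low: float = 0.2
    weight_high: float = 1.8
    noise_sd: float = 0.35
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"NULL": 0.85, "DARK": 0.05, "DE": 0.05, "LOWFIT": 0.05}
    )
    de_effect: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tf", "n_targets", "n_datasets", "n_case", "n_control"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes {sorted(unknown)}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be nonnegative")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if not 2 <= self.weight_sparsity <= self.n_tf:
            raise ValueError("weight_sparsity must lie in [2, n_tf]")
        if self.class_counts()["NULL"] < 0:
            raise ValueError("class fractions leave no room for NULL genes")

    def class_counts(self) -> dict[str, int]:
        """Integer per-class gene counts (NULL absorbs rounding remainder)."""
        counts = {
            c: int(round(self.class_fractions.get(c, 0.0) * self.n_targets))
            for c in GENE_CLASSES if c != "NULL"
        }
        counts["NULL"] = self.n_targets - sum(counts.values())
        return counts

    @classmethod
    def underdetermined_stress(cls, seed: int = 0) -> "CohortSpec":
        """Stress configuration with more TFs than training samples."""
        return cls(n_tf=200, seed=seed)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class GroundTruth:
    """Planted truth: per-gene class and healthy/disease weight vectors."""

    gene_class: pd.Series
    healthy_weights: pd.DataFrame
    disease_weights: pd.DataFrame
    noise_sd: float

    def __post_init__(self) -> None:
        same = self.gene_class.isin(["NULL", "DE", "LOWFIT"])
        hw, dw = self.healthy_weights.to_numpy(), self.disease_weights.to_numpy()
        if not np.array_equal(hw[same.to_numpy()], dw[same.to_numpy()]):
            raise ValueError("disease weights must equal healthy weights for non-DARK genes")
        dark = (self.gene_class == "DARK").to_numpy()
        if not np.allclose(np.sort(hw[dark], axis=1), np.sort(dw[dark], axis=1)):
            raise ValueError("DARK disease weights must be a permutation of the healthy weights")

    @property
    def target_ids(self) -> pd.Index:
        return self.gene_class.index

    def genes_of_class(self, cls: str) -> pd.Index:
        return self.gene_class.index[self.gene_class == cls]


def _derange(rng: np.random.Generator, k: int) -> np.ndarray:
    """A uniform random derangement of range(k) by rejection (k >= 2)."""
    while True:
        perm = rng.permutation(k)
        if not np.any(perm == np.arange(k)):
            return perm


def _make_truth(spec: CohortSpec, rng: np.random.Generator) -> GroundTruth:
    counts = spec.class_counts()
    classes = np.concatenate([np.repeat(c, counts[c]) for c in GENE_CLASSES])
    rng.shuffle(classes)
    target_ids = pd.Index([f"G{i:05d}_at" for i in range(spec.n_targets)])
    tf_ids = pd.Index([f"TF{i:04d}_at" for i in range(spec.n_tf)])
    hw = np.zeros((spec.n_targets, spec.n_tf))
    dw = np.zeros((spec.n_targets, spec.n_tf))
    for g, cls in enumerate(classes):
        if cls == "LOWFIT":
            continue
        support = rng.choice(spec.n_tf, size=spec.weight_sparsity, replace=False)
        # distinct, evenly spread regulator strengths: any derangement of
        # them displaces substantial weight, so rewiring is never a no-op
        w = rng.permutation(np.linspace(spec.weight_low, spec.weight_high, spec.weight_sparsity))
        hw[g, support] = w
        dw[g, support] = w[_derange(rng, spec.weight_sparsity)] if cls == "DARK" else w
    return GroundTruth(
        gene_class=pd.Series(classes, index=target_ids, name="gene_class"),
        healthy_weights=pd.DataFrame(hw, index=target_ids, columns=tf_ids),
        disease_weights=pd.DataFrame(dw, index=target_ids, columns=tf_ids),
        noise_sd=spec.noise_sd,
    )


def _annotation_for(truth: GroundTruth) -> FeatureAnnotation:
    tf_ids = truth.healthy_weights.columns
    probe_to_gene = {p: p.removesuffix("_at") for p in list(tf_ids) + list(truth.target_ids)}
    tf_symbols = frozenset(p.removesuffix("_at") for p in tf_ids)
    return FeatureAnnotation(probe_to_gene, tf_symbols)


def _sample_dataset(
    ds_id: str, spec: CohortSpec, truth: GroundTruth, annotation: FeatureAnnotation,
    rng: np.random.Generator,
) -> AnnotatedExpression:
    tf_ids = truth.healthy_weights.columns
    de_mask = (truth.gene_class == "DE").to_numpy()

    def draw(n: int, weights: np.ndarray, shift: float) -> tuple[np.ndarray, np.ndarray]:
        tf = rng.uniform(0.0, 1.0, size=(n, spec.n_tf))
        y = tf @ weights.T + rng.normal(0.0, spec.noise_sd, size=(n, spec.n_targets))
        y[:, de_mask] += shift
        return tf, y

    tf_case, y_case = draw(spec.n_case, truth.disease_weights.to_numpy(), spec.de_effect * spec.noise_sd)
    tf_ctrl, y_ctrl = draw(spec.n_control, truth.healthy_weights.to_numpy(), 0.0)

    sample_ids = [f"{ds_id}_case_{i:03d}" for i in range(spec.n_case)] + [
        f"{ds_id}_ctrl_{i:03d}" for i in range(spec.n_control)
    ]
    values = pd.DataFrame(
        np.vstack([np.hstack([tf_case.T, tf_ctrl.T]), np.hstack([y_case.T, y_ctrl.T])]),
        index=tf_ids.append(truth.target_ids),
        columns=pd.Index(sample_ids),
    )
    labels = pd.Series(
        ["case"] * spec.n_case + ["control"] * spec.n_control, index=values.columns, name="label"
    )
    matrix = ExpressionMatrix(values, labels)
    return AnnotatedExpression(matrix, tf_ids, truth.target_ids, annotation)


def generate_cohort(spec: CohortSpec) -> tuple[list[AnnotatedExpression], GroundTruth]:
    """Generate ``spec.n_datasets`` independent cohorts sharing one truth.

    Dataset IDs are ``D1, D2, ...``; within each, case samples come first.
    Values are raw (normalizable to [0, 1] downstream, not yet normalized).
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_datasets + 1)
    truth = _make_truth(spec, np.random.default_rng(seeds[0]))
    annotation = _annotation_for(truth)
    datasets = [
        _sample_dataset(f"D{d + 1}", spec, truth, annotation, np.random.default_rng(seeds[d + 1]))
        for d in range(spec.n_datasets)
    ]
    return datasets, truth


def folded_normal_mean(mu: float, sd: float) -> float:
    """E|X| for X ~ N(mu, sd^2)."""
    from scipy import stats

    if sd == 0:
        return abs(mu)
    return float(sd * _SQRT_2_OVER_PI * np.exp(-(mu**2) / (2 * sd**2))
                 + mu * (1 - 2 * stats.norm.cdf(-mu / sd)))


def expected_detectability(spec: CohortSpec, truth: GroundTruth | None = None, per_gene: bool = False):
    """Analytic expected separations, assuming the healthy model is known.

    For each gene, the expected mean mqTrans residual magnitude in
    controls and in cases, and the expected case-control shift of the
    original expression.  For a DARK gene with weight displacement
    ``d = w_healthy - w_disease`` the case residual is
    ``d . tf + noise`` with mean zero (a derangement preserves the weight
    sum) and variance ``|d|^2 / 12 + noise_sd^2``, so its expected
    magnitude exceeds the control value ``noise_sd * sqrt(2/pi)``.

    Returns a per-class summary DataFrame, or the per-gene table when
    ``per_gene`` is set.
    """
    if truth is None:
        truth = _make_truth(spec, np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0]))
    d = truth.healthy_weights.to_numpy() - truth.disease_weights.to_numpy()
    resid_var_case = (d**2).sum(axis=1) * _TF_VAR + spec.noise_sd**2
    e_mq_control = np.full(len(truth.target_ids), spec.noise_sd * _SQRT_2_OVER_PI)
    de_shift = spec.de_effect * spec.noise_sd
    is_de = (truth.gene_class == "DE").to_numpy()
    e_mq_case = np.where(
        is_de,
        [folded_normal_mean(de_shift, spec.noise_sd)] * len(truth.target_ids),
        np.sqrt(resid_var_case) * _SQRT_2_OVER_PI,
    )
    table = pd.DataFrame(
        {
            "gene_class": truth.gene_class,
            "e_mqtrans_control": e_mq_control,
            "e_mqtrans_case": e_mq_case,
            "e_mqtrans_gap": e_mq_case - e_mq_control,
            "e_original_shift": np.where(is_de, de_shift, 0.0),
        },
        index=truth.target_ids,
    )
    if per_gene:
        return table
    summary = table.groupby("gene_class").mean()
    summary["n_genes"] = table.groupby("gene_class").size()
    return summary


def write_cohort(datasets: list[AnnotatedExpression], truth: GroundTruth, outdir) -> None:
    """Write a generated cohort in the exact formats the readers consume.

    Layout: ``<outdir>/D<k>/expression.tsv`` + ``labels.tsv`` per dataset,
    plus shared ``annotation.tsv``, ``tf_list.txt`` and ``truth.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = datasets[0].annotation
    mqio.write_annotation(annotation, outdir / "annotation.tsv", outdir / "tf_list.txt")
    for k, ds in enumerate(datasets, start=1):
        ds_dir = outdir / f"D{k}"
        ds_dir.mkdir(exist_ok=True)
        mqio.write_expression_matrix(ds.matrix, ds_dir / "expression.tsv")
        mqio.write_labels(ds.matrix.labels, ds_dir / "labels.tsv")
    hw, dw = truth.healthy_weights, truth.disease_weights
    support = [",".join(hw.columns[hw.loc[t].to_numpy() != 0]) for t in truth.target_ids]
    rows = pd.DataFrame(
        {
            "target_id": truth.target_ids,
            "gene_class": truth.gene_class.to_numpy(),
            "tf_support": support,
            "healthy_weights": [
                ",".join(f"{v:.17g}" for v in hw.loc[t][hw.loc[t] != 0]) for t in truth.target_ids
            ],
            "disease_weights": [
                ",".join(f"{v:.17g}" for v in dw.loc[t][hw.loc[t] != 0]) for t in truth.target_ids
            ],
        }
    )
    rows.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def read_truth_classes(path) -> pd.Series:
    """Read back the per-gene class column of a written truth table."""
    # keep_default_na: the class label "NULL" is data, not a missing value
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return pd.Series(df["gene_class"].to_numpy(), index=pd.Index(df["target_id"]), name="gene_class")
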