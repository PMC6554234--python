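"""Cross-validated benchmarking: confusion metrics, ROC/AUC, composition.

The evaluation protocol is the field's standard one for small peptide
benchmarks: stratified 5-fold cross-validation, reporting accuracy,
sensitivity, specificity, precision and the Matthews correlation
coefficient as percentages (mean ± sample SD over folds) plus the ROC AUC.

From the confusion counts TP/TN/FP/FN:

    Acc  = (TP+TN) / (TP+TN+FP+FN)
    Sens = TP / (TP+FN)
    Spec = TN / (TN+FP)
    Prec = TP / (TP+FP)
    MCC  = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Any metric whose denominator is zero is reported as 0 with a logged
warning, so degenerate folds never abort a run.
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .features import encode_dataset, feature_matrix
from .peptides import AMINO_ACIDS, LabeledDataset

logger = logging.getLogger(__name__)

METRIC_NAMES = ("acc", "sens", "spec", "prec", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts for a binary classifier."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """One evaluation's metric suite; percentages except AUC (in [0, 1])."""

    acc: float
    sens: float
    spec: float
    prec: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass(frozen=True)
class FoldSplit:
    """A k-fold partition: disjoint test-index sets covering 0..n−1."""

    test_indices: tuple[np.ndarray, ...]
    n: int
    seed: int
    stratified: bool

    @property
    def n_folds(self) -> int:
        return len(self.test_indices)

    def folds(self):
        """Yield (train_indices, test_indices) pairs."""
        all_idx = np.arange(self.n)
        for test in self.test_indices:
            mask = np.ones(self.n, dtype=bool)
            mask[test] = False
            yield all_idx[mask], test


def kfold_split(
    n: int,
    labels=None,
    n_folds: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> FoldSplit:
    """Seeded shuffle-and-partition into folds of near-equal size.

    With ``stratified`` (the default) class ratios are balanced across
    folds, which stabilises cross-validation on small datasets; pass
    ``stratified=False`` for a plain random partition.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n < n_folds:
        raise ValueError(f"cannot split {n} samples into {n_folds} folds")
    if stratified:
        if labels is None:
            raise ValueError("stratified splitting requires labels")
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        groups = np.asarray(labels)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        groups = None
    tests = tuple(
        np.sort(test) for _, test in splitter.split(np.zeros(n), groups)
    )
    return FoldSplit(tests, n=n, seed=seed, stratified=stratified)


def confusion(labels, predicted) -> ConfusionCounts:
    """Count the four truth/prediction combinations."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (p == 1))),
        TN=int(np.sum((y == 0) & (p == 0))),
        FP=int(np.sum((y == 0) & (p == 1))),
        FN=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("zero denominator for %s: reporting 0 by convention", name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision and MCC as percentages."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return MetricsReport(
        acc=100.0 * (tp + tn) / c.total,
        sens=100.0 * _ratio(tp, tp + fn, "sensitivity"),
        spec=100.0 * _ratio(tn, tn + fp, "specificity"),
        prec=100.0 * _ratio(tp, tp + fp, "precision"),
        mcc=100.0 * _ratio(tp * tn - fp * fn, mcc_den, "MCC"),
        auc=auc,
    )


def roc_auc(labels, scores) -> tuple[np.ndarray, float]:
    """ROC curve (FPR, TPR columns) and its trapezoidal area.

    Thresholds sweep every distinct score; tied scores collapse into a
    single threshold step.  Requires both classes to be present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC/AUC requires both classes to be present")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class CVReport:
    """Per-fold and aggregated cross-validation results for one model.

    ``mean(m)`` / ``sd(m)`` give the across-fold mean and sample standard
    deviation (n−1 denominator, the ± reporting convention) of metric
    ``m``; :meth:`summary` renders the conventional fold-by-fold table.
    """

    per_fold: list[MetricsReport]
    model_name: str
    dataset_name: str
    seed: int
    parameters: dict = field(default_factory=dict)

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(m, metric) for m in self.per_fold]))

    def sd(self, metric: str) -> float:
        values = [getattr(m, metric) for m in self.per_fold]
        return float(statistics.stdev(values)) if len(values) > 1 else 0.0

    def as_frame(self) -> pd.DataFrame:
        rows = [m.as_dict() for m in self.per_fold]
        df = pd.DataFrame(rows, index=[f"fold{i+1}" for i in range(len(rows))])
        df.loc["mean"] = [self.mean(m) for m in METRIC_NAMES]
        df.loc["sd"] = [self.sd(m) for m in METRIC_NAMES]
        return df

    def summary(self) -> str:
        header = (
            f"{self.model_name} on {self.dataset_name} "
            f"({len(self.per_fold)}-fold CV, seed {self.seed})"
        )
        cols = ["Acc (%)", "Sens (%)", "Spec (%)", "Prec (%)", "MCC (%)", "AUC"]
        lines = [header, "=" * 78]
        lines.append("Fold   " + "".join(f"{c:>12}" for c in cols))
        for i, m in enumerate(self.per_fold, 1):
            vals = [m.acc, m.sens, m.spec, m.prec, m.mcc]
            row = "".join(f"{v:>12.2f}" for v in vals)
            row += f"{m.auc:>12.3f}" if m.auc is not None else f"{'-':>12}"
            lines.append(f"{i:<7}" + row)
        mean_row = "".join(
            f"{self.mean(m):>12.2f}" for m in ("acc", "sens", "spec", "prec", "mcc")
        ) + f"{self.mean('auc'):>12.3f}"
        sd_row = "".join(
            f"{self.sd(m):>12.2f}" for m in ("acc", "sens", "spec", "prec", "mcc")
        ) + f"{self.sd('auc'):>12.3f}"
        lines.append("Mean   " + mean_row)
        lines.append("SD     " + sd_row)
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t", index_label="fold")

    def to_json(self, path=None):
        payload = {
            "model": self.model_name,
            "dataset": self.dataset_name,
            "seed": self.seed,
            "parameters": self.parameters,
            "per_fold": [m.as_dict() for m in self.per_fold],
            "mean": {m: self.mean(m) for m in METRIC_NAMES},
            "sd": {m: self.sd(m) for m in METRIC_NAMES},
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def cross_validate(
    dataset: LabeledDataset,
    model,
    n_folds: int = 5,
    seed: int = 0,
    stratified: bool = True,
    split: FoldSplit | None = None,
    bpf_k: int = 7,
    kmer_k: int = 3,
    svd_strategy: str = "leading",
    threshold: float = 0.5,
) -> CVReport:
    """k-fold cross-validation of one model on one peptide dataset.

    ``model`` is a registered model name (``lstm``, ``svm``, ``rf``,
    ``nb``) or any factory ``f(seed) -> classifier`` with the
    fit/predict_scores contract.  Features are encoded once up front —
    the encoders are deterministic and label-free, so there is no
    train/test leakage — and a fresh model is trained per fold on the
    remaining folds.  Pass a precomputed ``split`` to evaluate several
    models on byte-identical fold assignments.
    """
    from .baselines import resolve_model  # late import; baselines imports us

    factory, model_name, parameters = resolve_model(model)
    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation requires both classes in the dataset")
    features = encode_dataset(
        dataset, bpf_k=bpf_k, kmer_k=kmer_k, svd_strategy=svd_strategy
    )
    X, _ = feature_matrix(features)
    if split is None:
        split = kfold_split(
            len(dataset), labels=y, n_folds=n_folds, seed=seed, stratified=stratified
        )
    per_fold: list[MetricsReport] = []
    for fold_no, (train_idx, test_idx) in enumerate(split.folds()):
        classifier = factory(seed + fold_no)
        results = classifier.fit(X[train_idx], y[train_idx])
        scores = np.asarray(results.predict_scores(X[test_idx]), dtype=float)
        predicted = (scores >= threshold).astype(int)
        _, auc = roc_auc(y[test_idx], scores)
        per_fold.append(compute_metrics(confusion(y[test_idx], predicted), auc=auc))
    return CVReport(
        per_fold=per_fold,
        model_name=model_name,
        dataset_name=dataset.name,
        seed=split.seed,
        parameters=parameters,
    )


def aa_composition(peptides) -> np.ndarray:
    """Pooled amino acid composition: residue counts over total residues.

    Returns a 20-vector in alphabetical residue order summing to 1.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("cannot compute composition of an empty collection")
    counts = np.zeros(20)
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for p in peptides:
        for aa in p.residues:
            counts[index[aa]] += 1
    return counts / counts.sum()


def composition_comparison(dataset: LabeledDataset) -> pd.DataFrame:
    """Residue-by-residue composition of positives, negatives and all.

    One row per residue (alphabetical), with the positive−negative
    difference; this is the classical enrichment comparison showing which
    residues are over-represented in anticancer peptides.
    """
    pos, neg = dataset.positives(), dataset.negatives()
    if not pos or not neg:
        raise ValueError("composition comparison requires both classes")
    table = pd.DataFrame(
        {
            "residue": list(AMINO_ACIDS),
            "positive": aa_composition(pos),
            "negative": aa_composition(neg),
            "total": aa_composition(dataset),
        }
    )
    table["difference"] = table["positive"] - table["negative"]
    return table


def plot_composition(table: pd.DataFrame, path=None, title=None):
    """Grouped bar chart of the composition comparison (optional matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(table))
    width = 0.27
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(x - width, table["positive"], width, label="anticancer")
    ax.bar(x, table["negative"], width, label="non-anticancer")
    ax.bar(x + width, table["total"], width, label="all")
    ax.set_xticks(x, table["residue"])
    ax.set_ylabel("fraction of residues")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
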