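"""Classical baselines (SVM, random forest, naive Bayes) and model registry.

Thin adapters over scikit-learn at library defaults, exposing the same
fit → results → predict_scores contract as the LSTM so every model can be
benchmarked on byte-identical cross-validation folds.  The backing
library's effective parameters are recorded verbatim into each report for
provenance — "default parameters" drift across library versions, so the
report pins what was actually used.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .evaluation import CVReport, cross_validate, kfold_split
from .lstm import LSTMClassifier, LSTMConfig
from .peptides import LabeledDataset


class BaselineResults:
    """A fitted baseline exposing scores in [0, 1] and hard labels."""

    def __init__(self, estimator, threshold: float = 0.5):
        self.estimator = estimator
        self.threshold = threshold

    def predict_scores(self, X) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, 1]
        # min–max-scaled decision values as a fallback score
        d = est.decision_function(X)
        span = d.max() - d.min()
        if span == 0:
            return np.full(len(d), 0.5)
        return (d - d.min()) / span

    def predict(self, X) -> np.ndarray:
        return (self.predict_scores(X) >= self.threshold).astype(int)


class BaselineClassifier:
    """Adapter giving sklearn estimators the Model.fit() -> Results shape."""

    def __init__(self, name: str, estimator):
        self.name = name
        self.estimator = estimator

    @property
    def parameters(self) -> dict:
        return self.estimator.get_params()

    def fit(self, X, y) -> BaselineResults:
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels must contain both classes")
        self.estimator.fit(np.asarray(X, dtype=float), y)
        return BaselineResults(self.estimator)


def _make_svm(seed: int) -> BaselineClassifier:
    # probability=True is required by the score contract (ROC needs scores)
    return BaselineClassifier("svm", SVC(probability=True, random_state=seed))


def _make_rf(seed: int) -> BaselineClassifier:
    return BaselineClassifier("rf", RandomForestClassifier(random_state=seed))


def _make_nb(seed: int) -> BaselineClassifier:
    return BaselineClassifier("nb", GaussianNB())


def _make_lstm(seed: int) -> LSTMClassifier:
    return LSTMClassifier(LSTMConfig(seed=seed))


MODEL_REGISTRY: dict[str, Callable[[int], object]] = {
    "lstm": _make_lstm,
    "svm": _make_svm,
    "rf": _make_rf,
    "nb": _make_nb,
}


def resolve_model(model) -> tuple[Callable[[int], object], str, dict]:
    """Resolve a model spec into (factory, name, recorded parameters).

    Accepts a registered name, a factory callable ``f(seed) -> classifier``,
    or a ready classifier instance (reused across folds only if refittable).
    """
    if isinstance(model, str):
        if model not in MODEL_REGISTRY:
            raise ValueError(
                f"unknown model {model!r}; available: {sorted(MODEL_REGISTRY)}"
            )
        factory = MODEL_REGISTRY[model]
        probe = factory(0)
        params = getattr(probe, "parameters", None)
        if params is None and hasattr(probe, "config"):
            from dataclasses import asdict

            params = asdict(probe.config)
        return factory, model, dict(params or {})
    if callable(model) and not hasattr(model, "fit"):
        probe = model(0)
        name = getattr(probe, "name", type(probe).__name__)
        params = getattr(probe, "parameters", {})
        return model, name, dict(params or {})
    if hasattr(model, "fit"):
        name = getattr(model, "name", type(model).__name__)
        params = getattr(model, "parameters", {})
        return (lambda seed: model), name, dict(params or {})
    raise TypeError(f"cannot interpret model spec {model!r}")


def train_baseline(name: str, features, labels, seed: int = 0) -> BaselineResults:
    """Fit one named baseline on a flat 2D feature matrix."""
    factory, _, _ = resolve_model(name)
    return factory(seed).fit(features, labels)


def compare_models(
    dataset: LabeledDataset,
    models: list,
    n_folds: int = 5,
    seed: int = 0,
    stratified: bool = True,
    **encode_kwargs,
) -> dict[str, CVReport]:
    """Cross-validate several models on identical fold assignments.

    The fold split is computed once from the seed and shared, so every
    model trains and tests on exactly the same peptides per fold.
    Returns ``{model_name: CVReport}`` in input order.
    """
    if not models:
        raise ValueError("model list must be non-empty")
    split = kfold_split(
        len(dataset), labels=dataset.labels, n_folds=n_folds, seed=seed,
        stratified=stratified,
    )
    reports: dict[str, CVReport] = {}
    for model in models:
        report = cross_validate(dataset, model, split=split, **encode_kwargs)
        reports[report.model_name] = report
    return reports


def comparison_table(reports: dict[str, CVReport]) -> pd.DataFrame:
    """Mean metrics per model, with the best value per metric flagged."""
    from .evaluation import METRIC_NAMES

    rows = {
        name: {m: report.mean(m) for m in METRIC_NAMES}
        for name, report in reports.items()
    }
    df = pd.DataFrame(rows).T
    best = df.idxmax()
    flagged = df.copy().astype(object)
    for metric in df.columns:
        for model in df.index:
            value = df.loc[model, metric]
            digits = 3 if metric == "auc" else 2
            text = f"{value:.{digits}f}"
            if model == best[metric]:
                text += "*"
            flagged.loc[model, metric] = text
    return flagged
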