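"""Benchmark classifiers that predict a word's energy-density class.

The feature matrix is the raw embedding vectors of the seed words; the target
is the binary L-ED/H-ED label. Ten standard model families are compared under
stratified fivefold cross-validation with identical fold splits, the top five
by mean accuracy are grid-search tuned on the same folds, and the best tuned
model labels the newly harvested words (serialized 1 = L-ED, 2 = H-ED).

No feature scaling is applied by default — the initial comparison is run at
library defaults — but a scaling flag is available since several of the
families (SVM, KNN, ANN, GP) are scale-sensitive.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .embedding import EmbeddingSpace

__all__ = [
    "MODEL_NAMES",
    "L_ED_CODE",
    "H_ED_CODE",
    "make_default_models",
    "default_tuning_grids",
    "cross_validate_models",
    "tune_top_models",
    "fit_final_model",
    "predict_ed",
]

logger = logging.getLogger(__name__)

MODEL_NAMES = ("ANN", "SVM", "GP", "AB", "NB", "QDA", "GB", "KNN", "RF", "DT")

#: Serialization codes for the binary classes.
L_ED_CODE, H_ED_CODE = 1, 2

N_FOLDS = 5


def make_default_models(seed: int = 0) -> dict[str, BaseEstimator]:
    """The ten benchmark families at library-default hyperparameters."""
    return {
        "ANN": MLPClassifier(random_state=seed, max_iter=500),
        "SVM": SVC(random_state=seed),
        "GP": GaussianProcessClassifier(random_state=seed),
        "AB": AdaBoostClassifier(random_state=seed),
        "NB": GaussianNB(),
        "QDA": QuadraticDiscriminantAnalysis(),
        "GB": GradientBoostingClassifier(random_state=seed),
        "KNN": KNeighborsClassifier(),
        "RF": RandomForestClassifier(random_state=seed),
        "DT": DecisionTreeClassifier(random_state=seed),
    }


def default_tuning_grids() -> dict[str, list[dict]]:
    """Small grids over each family's most influential hyperparameters."""
    return {
        "SVM": [
            {"C": c, "gamma": g}
            for c in (0.1, 1.0, 10.0, 100.0)
            for g in ("auto", 1e-3, 1e-2)
        ],
        "KNN": [{"n_neighbors": k} for k in (3, 5, 11, 21)],
        "RF": [
            {"n_estimators": n, "max_depth": d}
            for n in (100, 300, 600)
            for d in (None, 10, 20)
        ],
        "ANN": [
            {"hidden_layer_sizes": h, "alpha": a}
            for h in ((50,), (100,), (100, 50))
            for a in (1e-4, 1e-3)
        ],
        "GP": [
            {"kernel": RBF(length_scale=s), "optimizer": None} for s in (0.5, 1.0, 2.0)
        ],
    }


def _encode_labels(y: Sequence) -> np.ndarray:
    """Map L_ED/H_ED labels (strings or 1/2 codes) to {1, 2} integers."""
    mapping = {"L_ED": L_ED_CODE, "H_ED": H_ED_CODE, L_ED_CODE: L_ED_CODE, H_ED_CODE: H_ED_CODE}
    try:
        return np.array([mapping[v] for v in y], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unrecognized energy-density label {exc.args[0]!r}") from None


def _folds(seed: int) -> StratifiedKFold:
    # one shared shuffled splitter → identical folds for every model
    return StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)


def _maybe_scale(est: BaseEstimator, scale: bool) -> BaseEstimator:
    return make_pipeline(StandardScaler(), est) if scale else est


def cross_validate_models(
    X: np.ndarray,
    y: Sequence,
    seed: int = 0,
    *,
    scale: bool = False,
    models: "Mapping[str, BaseEstimator] | None" = None,
) -> pd.DataFrame:
    """Stratified fivefold CV of the ten families on shared fold splits.

    Returns one row per model — name, mean_accuracy_pct, std_accuracy_pct,
    folds, seed — sorted by mean accuracy descending.
    """
    X = np.asarray(X, dtype=float)
    y = _encode_labels(y)
    if len(X) < 10:
        raise ValueError("need at least 10 samples for fivefold CV")
    if len(np.unique(y)) < 2:
        raise ValueError("both energy-density classes must be present")
    if models is None:
        models = make_default_models(seed)
    cv = _folds(seed)
    rows = []
    for name, est in models.items():
        scores = cross_val_score(_maybe_scale(clone(est), scale), X, y, cv=cv)
        rows.append(
            {
                "name": name,
                "mean_accuracy_pct": 100.0 * float(np.mean(scores)),
                "std_accuracy_pct": 100.0 * float(np.std(scores)),
                "folds": N_FOLDS,
                "seed": seed,
            }
        )
    report = pd.DataFrame(rows).sort_values(
        ["mean_accuracy_pct", "name"], ascending=[False, True]
    )
    return report.reset_index(drop=True)


def tune_top_models(
    X: np.ndarray,
    y: Sequence,
    report: pd.DataFrame,
    k: int = 5,
    grids: "Mapping[str, list[dict]] | None" = None,
    seed: int = 0,
    *,
    scale: bool = False,
) -> pd.DataFrame:
    """Grid-search the top-k models of an untuned CV report on the same folds.

    For each candidate parameter set the model is re-scored with the shared
    fivefold splitter; the best mean accuracy becomes the "after" column.
    A model with no grid keeps its defaults (noted in the ``note`` column).
    Rows are sorted by tuned accuracy descending, ties broken by lower σ.
    """
    if len(report) < k:
        raise ValueError(f"report has {len(report)} rows, need at least {k}")
    X = np.asarray(X, dtype=float)
    y = _encode_labels(y)
    if grids is None:
        grids = default_tuning_grids()
    cv = _folds(seed)
    base = make_default_models(seed)
    top = report.nlargest(k, "mean_accuracy_pct")
    rows = []
    for rec in top.itertuples(index=False):
        name = rec.name
        best_params: dict = {}
        best_mean = rec.mean_accuracy_pct
        best_std = rec.std_accuracy_pct
        note = ""
        grid = grids.get(name, [])
        if not grid:
            note = "no grid; kept defaults"
        for params in grid:
            est = clone(base[name]).set_params(**params)
            scores = cross_val_score(_maybe_scale(est, scale), X, y, cv=cv)
            mean, std = 100.0 * float(np.mean(scores)), 100.0 * float(np.std(scores))
            if mean > best_mean or (mean == best_mean and std < best_std):
                best_mean, best_std, best_params = mean, std, params
        rows.append(
            {
                "name": name,
                "accuracy_before_pct": rec.mean_accuracy_pct,
                "accuracy_after_pct": best_mean,
                "std_after_pct": best_std,
                "best_params": best_params,
                "note": note,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["accuracy_after_pct", "std_after_pct"], ascending=[False, True]
    )
    return out.reset_index(drop=True)


def fit_final_model(
    X: np.ndarray,
    y: Sequence,
    name: str,
    params: "dict | None" = None,
    seed: int = 0,
    *,
    scale: bool = False,
) -> BaseEstimator:
    """Fit one named family on all data with the given (tuned) parameters."""
    est = clone(make_default_models(seed)[name])
    if params:
        est.set_params(**params)
    est = _maybe_scale(est, scale)
    return est.fit(np.asarray(X, dtype=float), _encode_labels(y))


def predict_ed(
    model: BaseEstimator, words: Sequence[str], space: EmbeddingSpace
) -> dict[str, int]:
    """Label each in-vocabulary word with its predicted class code (1/2).

    Out-of-vocabulary words are skipped with a logged count.
    """
    kept, X = space.subset(words)
    n_oov = len(list(words)) - len(kept)
    if n_oov:
        logger.info("skipped %d out-of-vocabulary words", n_oov)
    if not kept:
        return {}
    labels = model.predict(X)
    return {w: int(c) for w, c in zip(kept, labels)}
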