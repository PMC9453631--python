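"""Classifier registry shared by feature selection and benchmarking.

The four families benchmarked are a linear support vector machine, a
multilayer perceptron, LightGBM and XGBoost.  Hyperparameters are library
defaults with fixed seeds; single-threaded for reproducibility.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError, UnsupportedEstimatorError

CLASSIFIER_NAMES = ("linear_svm", "mlp", "lgbm", "xgb")


def make_estimator(spec, seed: int = 0):
    """Instantiate a classifier from a registry name, or pass one through."""
    if not isinstance(spec, str):
        return spec  # an already-constructed estimator
    if spec == "linear_svm":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        # standardisation is mandatory for libsvm: with raw feature scales
        # (wavelengths in nm next to unit reflectances) its SMO solver can
        # take effectively unbounded time on some training subsets
        return make_pipeline(
            StandardScaler(), SVC(kernel="linear", random_state=seed)
        )
    if spec == "mlp":
        from sklearn.neural_network import MLPClassifier
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        return make_pipeline(
            StandardScaler(), MLPClassifier(random_state=seed, max_iter=500)
        )
    if spec == "lgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1)
    if spec == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
    if spec == "logreg":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(random_state=seed, max_iter=1000)
    raise ConfigError(f"unknown classifier spec {spec!r}")


def feature_importances(fitted) -> np.ndarray:
    """Per-feature importance: |coef| for linear models, gain for trees."""
    if hasattr(fitted, "coef_"):
        coef = np.asarray(fitted.coef_)
        return np.abs(coef).sum(axis=0) if coef.ndim > 1 else np.abs(coef)
    if hasattr(fitted, "feature_importances_"):
        return np.asarray(fitted.feature_importances_, dtype=float)
    raise UnsupportedEstimatorError(
        f"{type(fitted).__name__} exposes neither coef_ nor "
        "feature_importances_"
    )


def decision_scores(fitted, X) -> np.ndarray:
    """Continuous score for the positive (tumor) class, for ROC curves."""
    if hasattr(fitted, "predict_proba"):
        return np.asarray(fitted.predict_proba(X))[:, 1]
    if hasattr(fitted, "decision_function"):
        return np.asarray(fitted.decision_function(X))
    raise UnsupportedEstimatorError(
        f"{type(fitted).__name__} exposes neither predict_proba nor "
        "decision_function"
    )
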