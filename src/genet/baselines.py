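"""Reference regressors run on the concatenated two-view features.

Five comparison models: ordinary linear regression, a 100-tree random
forest, gradient boosting with 100 stages, RBF-kernel support vector
regression, and a one-hidden-layer (64 ReLU units) neural network.  All
consume ``X = [tf | h3k27ac]`` bin features row-aligned with the expression
labels, fit on the training mask and report test metrics, so any
comparison with the graph model uses identical splits and information.
Hyperparameters not pinned here are the scikit-learn defaults, recorded in
the run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .train_eval import MetricsReport, compute_metrics

__all__ = ["BaselineSpec", "BASELINE_NAMES", "run_baseline", "run_all_baselines"]

BASELINE_NAMES = ("linreg", "rf", "gbm", "svm_rbf", "simple_nn")


@dataclass(frozen=True)
class BaselineSpec:
    name: str
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ValueError(
                f"unknown baseline {self.name!r}; expected one of {BASELINE_NAMES}"
            )


def _make_estimator(spec: BaselineSpec, seed: int):
    kw = dict(spec.overrides)
    if spec.name == "linreg":
        return LinearRegression(**kw)
    if spec.name == "rf":
        kw.setdefault("n_estimators", 100)
        return RandomForestRegressor(random_state=seed, **kw)
    if spec.name == "gbm":
        kw.setdefault("n_estimators", 100)
        return GradientBoostingRegressor(random_state=seed, **kw)
    if spec.name == "svm_rbf":
        kw.setdefault("kernel", "rbf")
        return SVR(**kw)
    kw.setdefault("hidden_layer_sizes", (64,))
    kw.setdefault("activation", "relu")
    kw.setdefault("max_iter", 2000)
    return MLPRegressor(random_state=seed, **kw)


def run_baseline(
    spec: BaselineSpec | str,
    X: np.ndarray,
    y: np.ndarray,
    masks: dict[str, np.ndarray],
    seed: int = 0,
) -> tuple[MetricsReport, np.ndarray]:
    """Fit one baseline on the train mask, report test-mask metrics.

    Returns (test MetricsReport, predictions for all samples).
    """
    if isinstance(spec, str):
        spec = BaselineSpec(spec)
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    est = _make_estimator(spec, seed)
    est.fit(X[masks["train"]], y[masks["train"]])
    y_pred = np.asarray(est.predict(X), float)
    report = compute_metrics(y[masks["test"]], y_pred[masks["test"]])
    return report, y_pred


def run_all_baselines(
    X: np.ndarray,
    y: np.ndarray,
    masks: dict[str, np.ndarray],
    seed: int = 0,
    genet_report: MetricsReport | None = None,
):
    """Comparison table (model x MSE/RMSE/MAE/R2) over all five baselines.

    A per-model failure is logged into the table, not raised, so one bad
    fit does not void the comparison.  When a trained graph-model report is
    supplied it is appended as the final row.
    """
    import pandas as pd

    rows = []
    for name in BASELINE_NAMES:
        try:
            report, _ = run_baseline(name, X, y, masks, seed)
            rows.append(
                {"model": name, "MSE": report.mse, "RMSE": report.rmse,
                 "MAE": report.mae, "R2": report.r2}
            )
        except Exception as exc:
            rows.append(
                {"model": name, "MSE": float("nan"), "RMSE": float("nan"),
                 "MAE": float("nan"), "R2": float("nan"), "error": str(exc)}
            )
    if genet_report is not None:
        rows.append(
            {"model": "genet", "MSE": genet_report.mse, "RMSE": genet_report.rmse,
             "MAE": genet_report.mae, "R2": genet_report.r2}
        )
    return pd.DataFrame(rows).set_index("model")
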