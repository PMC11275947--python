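"""Splits, regression metrics, hyperparameter grid search and TSS sweep.

Samples are split 70/15/15 into train/validation/test by seeded random
permutation (floor counts; remainder samples go to train).  Metrics follow
the standard definitions: MSE, RMSE = sqrt(MSE), MAE, R^2 = 1 - SSres/SStot
and the Pearson correlation.  The hyperparameter grid is the 3 x 3 cross of
learning rates {0.001, 0.01, 0.1} and hidden sizes {64, 128, 256}, each
trained for 100 epochs and ranked by validation loss; the TSS-window sweep
re-runs the whole pipeline at flanks {200, 500, 1000, 2000} bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from .config import RunConfig

__all__ = [
    "SplitMasks",
    "MetricsReport",
    "split_samples",
    "compute_metrics",
    "grid_search",
    "tss_range_sweep",
    "DEFAULT_LR_GRID",
    "DEFAULT_HIDDEN_GRID",
    "DEFAULT_TSS_RANGES",
]

logger = logging.getLogger(__name__)

DEFAULT_LR_GRID: tuple[float, ...] = (0.001, 0.01, 0.1)
DEFAULT_HIDDEN_GRID: tuple[int, ...] = (64, 128, 256)
DEFAULT_TSS_RANGES: tuple[int, ...] = (200, 500, 1000, 2000)


@dataclass
class SplitMasks:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float]
    seed: int

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"train": self.train, "val": self.val, "test": self.test}

    @property
    def counts(self) -> tuple[int, int, int]:
        return (int(self.train.sum()), int(self.val.sum()), int(self.test.sum()))


@dataclass
class MetricsReport:
    mse: float
    rmse: float
    mae: float
    r2: float
    pearson_r: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mse": self.mse,
            "rmse": self.rmse,
            "mae": self.mae,
            "r2": self.r2,
            "pearson_r": self.pearson_r,
        }


def split_samples(
    n: int,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitMasks:
    """Random train/val/test masks with floor counts, remainder to train."""
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    fr = tuple(fractions)
    if len(fr) != 3 or abs(sum(fr) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_val = int(np.floor(fr[1] * n))
    n_test = int(np.floor(fr[2] * n))
    n_train = n - n_val - n_test  # remainder goes to train
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n={n} too small for nonempty splits at {fr}")
    perm = np.random.default_rng(seed).permutation(n)
    masks = {k: np.zeros(n, dtype=bool) for k in ("train", "val", "test")}
    masks["train"][perm[:n_train]] = True
    masks["val"][perm[n_train : n_train + n_val]] = True
    masks["test"][perm[n_train + n_val :]] = True
    return SplitMasks(masks["train"], masks["val"], masks["test"], fr, seed)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """MSE/RMSE/MAE/R^2/Pearson for one prediction vector.

    With a constant ``y_true`` the variance-normalized metrics are
    undefined; they are reported as NaN (flagged in the log) while the
    error metrics are still computed.
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length vectors")
    if y_true.size < 2:
        raise ValueError("need at least 2 samples for metrics")
    mse = float(mean_squared_error(y_true, y_pred))
    mae = float(mean_absolute_error(y_true, y_pred))
    if np.ptp(y_true) == 0:
        logger.warning("constant y_true: r2 and pearson_r undefined (NaN)")
        r2, pr = float("nan"), float("nan")
    else:
        r2 = float(r2_score(y_true, y_pred))
        if np.ptp(y_pred) == 0:
            pr = float("nan")
        else:
            pr = float(stats.pearsonr(y_true, y_pred).statistic)
    return MetricsReport(mse=mse, rmse=float(np.sqrt(mse)), mae=mae, r2=r2, pearson_r=pr)


def grid_search(
    train_fn: Callable[[RunConfig], float],
    base_config: RunConfig,
    lr_grid: Sequence[float] = DEFAULT_LR_GRID,
    hidden_grid: Sequence[int] = DEFAULT_HIDDEN_GRID,
) -> tuple[RunConfig, list[dict]]:
    """Exhaustive search over lr x hidden_size, ranked by validation loss.

    ``train_fn`` maps a config to its validation loss (same seed for every
    configuration).  Returns the winning config and the full result table.
    Ties break toward the smaller learning rate, then the smaller hidden
    size; divergent configs (NaN/inf or raised FloatingPointError) are
    recorded but cannot win.
    """
    if not lr_grid or not hidden_grid:
        raise ValueError("empty grid")
    table: list[dict] = []
    for lr in sorted(lr_grid):
        for hidden in sorted(hidden_grid):
            cfg = base_config.replace(lr=lr, hidden_size=hidden)
            try:
                val_loss = float(train_fn(cfg))
            except FloatingPointError as exc:
                logger.warning("config lr=%s hidden=%s diverged: %s", lr, hidden, exc)
                val_loss = float("nan")
            table.append({"lr": lr, "hidden_size": hidden, "val_loss": val_loss})
    finite = [row for row in table if np.isfinite(row["val_loss"])]
    if not finite:
        raise RuntimeError("every grid configuration diverged")
    # enumeration above is already sorted (lr, hidden); min is the tie-break
    best = min(finite, key=lambda r: (r["val_loss"],))
    for row in finite:  # first minimal row in (lr, hidden) order wins ties
        if row["val_loss"] == best["val_loss"]:
            best = row
            break
    return base_config.replace(lr=best["lr"], hidden_size=best["hidden_size"]), table


def tss_range_sweep(
    pipeline_fn: Callable[[int], MetricsReport],
    ranges: Sequence[int] = DEFAULT_TSS_RANGES,
) -> list[dict]:
    """Test metrics per TSS flank; failures are recorded, others continue."""
    if any(r <= 0 for r in ranges):
        raise ValueError("TSS ranges must be positive")
    rows: list[dict] = []
    for r in ranges:
        try:
            report = pipeline_fn(int(r))
            rows.append({"tss_range": int(r), **report.as_dict(), "error": None})
        except Exception as exc:  # propagate per-range, continue others
            logger.error("TSS range %d failed: %s", r, exc)
            rows.append(
                {"tss_range": int(r), "mse": float("nan"), "rmse": float("nan"),
                 "mae": float("nan"), "r2": float("nan"), "pearson_r": float("nan"),
                 "error": str(exc)}
            )
    return rows
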