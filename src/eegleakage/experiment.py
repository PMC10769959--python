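"""Sweep runner: preprocess -> split -> train -> evaluate over a grid.

Materialises the study's result surfaces — accuracy / F1 / confusion as a
function of the transfer rate ``beta``, the sequence ratio ``rho``, the
segment duration ``T`` and the segment overlap — as a tidy
:class:`pandas.DataFrame` with one row per (cell, fold, seed). Failed
cells (e.g. an empty training window at small ``rho`` with long segments)
are recorded with their cause rather than dropped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, f1_score

from ._seeds import spawn_rng
from .dataset import Dataset
from .models import CNNSegmentClassifier, LinearSegmentBaseline
from .partition import SplitSpec, TimeBasedSplitter, TransferRateSplitter
from .preprocess import prepare

logger = logging.getLogger(__name__)

__all__ = ["Metrics", "evaluate", "run_sweep", "summarize", "plot_sweep"]

CELL_KEYS = ["mode", "T", "overlap", "F", "beta", "rho", "direction"]


@dataclass
class Metrics:
    """Binary classification metrics for one evaluated partition.

    ``confusion`` rows are true (negative, positive), columns predicted.
    F1 is reported for the positive class, with the 0/0 case defined as 0.
    """

    confusion: np.ndarray
    accuracy: float
    f1: float
    n_test: int


def evaluate(y_pred: np.ndarray, y_true: np.ndarray) -> Metrics:
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if len(y_pred) != len(y_true):
        raise ValueError(
            f"prediction length {len(y_pred)} != truth length {len(y_true)}"
        )
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
    acc = float(np.trace(cm) / cm.sum()) if cm.sum() else float("nan")
    f1 = float(f1_score(y_true, y_pred, pos_label=1, zero_division=0))
    return Metrics(confusion=cm, accuracy=acc, f1=f1, n_test=len(y_true))


def _make_model(model: str, seed: int, model_params: dict | None):
    params = dict(model_params or {})
    if model == "linear":
        return LinearSegmentBaseline(random_state=seed, **params)
    if model == "cnn":
        return CNNSegmentClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model {model!r}")


def run_sweep(
    dataset: Dataset,
    grid: dict,
    *,
    model: str = "cnn",
    model_params: dict | None = None,
    n_seeds: int = 1,
    seed: int = 0,
    label_dimension: str = "valence",
) -> pd.DataFrame:
    """Run every grid cell across folds and seeds.

    ``grid`` maps cell axes to value lists: ``mode`` (split modes), ``T``
    (segment seconds), ``overlap``, ``F``, ``beta``, ``rho``,
    ``direction``; scalar entries ``k`` and ``test_tail`` apply to every
    cell. Per replicate seed, fold assignment, test draw, transfer
    permutation and model initialisation all derive from one stream that
    does not depend on the cell, so cells sharing a mechanism (e.g. the
    combined mode at rho=1 vs the plain subject-independent split) see
    identical draws. The whole sweep is deterministic under ``seed``.
    """
    modes = list(grid.get("mode", ["subject_independent"]))
    Ts = list(grid.get("T", [1.0]))
    overlaps = list(grid.get("overlap", [0.0]))
    Fs = list(grid.get("F", [0.04]))
    betas = list(grid.get("beta", [0.0]))
    rhos = list(grid.get("rho", [1.0]))
    directions = list(grid.get("direction", ["forward"]))
    k = int(grid.get("k", 5))
    test_tail = float(grid.get("test_tail", 0.2))

    segsets: dict[tuple, object] = {}
    rows = []
    for rep in range(n_seeds):
        rep_seed = int(spawn_rng(seed, "sweep", rep).integers(2**31))
        for mode, T, overlap, F, beta, rho, direction in itertools.product(
            modes, Ts, overlaps, Fs, betas, rhos, directions
        ):
            cell = {
                "mode": mode,
                "T": T,
                "overlap": overlap,
                "F": F,
                "beta": beta,
                "rho": rho,
                "direction": direction,
            }
            key = (T, overlap)
            if key not in segsets:
                segsets[key] = prepare(
                    dataset, T, overlap, label_dimension=label_dimension
                )
            segset = segsets[key]
            spec = SplitSpec(
                mode=mode,
                k=k,
                F=F,
                beta=beta,
                rho=rho,
                direction=direction,
                test_tail=test_tail,
                seed=rep_seed,
            )
            try:
                if mode == "time_based":
                    splitter = TimeBasedSplitter(spec)
                    partitions = [splitter.partition(segset)]
                else:
                    splitter = TransferRateSplitter(spec)
                    folds = splitter.folds(segset)
                    partitions = [
                        splitter.partition(segset, i, folds) for i in range(k)
                    ]
            except ValueError as exc:
                logger.warning("cell %s failed to split: %s", cell, exc)
                rows.append(
                    {**cell, "fold": -1, "seed": rep, "status": str(exc)}
                )
                continue
            for part in partitions:
                assert (
                    np.intersect1d(part.train_idx, part.test_idx).size == 0
                )
                try:
                    est = _make_model(model, rep_seed, model_params)
                    est.fit(
                        segset.X[part.train_idx], segset.y[part.train_idx]
                    )
                    pred = est.predict(segset.X[part.test_idx])
                except ValueError as exc:
                    logger.warning("cell %s fold %d failed: %s",
                                   cell, part.fold, exc)
                    rows.append(
                        {
                            **cell,
                            "fold": part.fold,
                            "seed": rep,
                            "status": str(exc),
                        }
                    )
                    continue
                m = evaluate(pred, segset.y[part.test_idx])
                rows.append(
                    {
                        **cell,
                        "fold": part.fold,
                        "seed": rep,
                        "status": "ok",
                        "accuracy": m.accuracy,
                        "f1": m.f1,
                        "n_test": m.n_test,
                        "n_train": len(part.train_idx),
                        "n_transfer": len(part.transfer_idx),
                        "tn": int(m.confusion[0, 0]),
                        "fp": int(m.confusion[0, 1]),
                        "fn": int(m.confusion[1, 0]),
                        "tp": int(m.confusion[1, 1]),
                    }
                )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation over folds and seeds, per grid cell."""
    ok = results[results["status"] == "ok"]
    agg = (
        ok.groupby(CELL_KEYS, dropna=False)
        .agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_sd=("accuracy", "std"),
            f1_mean=("f1", "mean"),
            f1_sd=("f1", "std"),
            n_test_total=("n_test", "sum"),
            n_runs=("accuracy", "size"),
        )
        .reset_index()
    )
    return agg


def plot_sweep(
    summary: pd.DataFrame,
    x: str = "beta",
    series: str = "T",
    metric: str = "accuracy_mean",
    ax=None,
):
    """Line plot of one result surface (one series per value of ``series``)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for value, sub in summary.groupby(series):
        sub = sub.sort_values(x)
        sd_col = metric.replace("_mean", "_sd")
        yerr = sub[sd_col] if sd_col in sub else None
        ax.errorbar(
            sub[x], sub[metric], yerr=yerr, marker="o",
            label=f"{series}={value}",
        )
    ax.set_xlabel(x)
    ax.set_ylabel(metric)
    ax.axhline(0.5, color="grey", lw=0.8, ls="--")
    ax.legend()
    return ax
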