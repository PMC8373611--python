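"""Binned model-vs-data comparison: cell rates, correlations, HDIs, reports.

Observed responses and model predictions are binned by age in years, by
condition and by familiar object (72 cells for the Experiment-3 design:
12 objects x 2 alignments x 3 age years). Model fit is summarised by the
Pearson correlation between per-cell predicted and observed correct-choice
rates; cells are weighted equally by default (an n-weighted option exists).
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["bin_responses", "bin_predictions", "pearson_r", "hdi", "compare_report"]

_CELL_KEYS = ["age_bin", "condition", "object_id"]


def bin_responses(trials: pd.DataFrame) -> pd.DataFrame:
    """Observed correct-choice rate per (age year, condition, object) cell.

    Ages bin half-open by floor: age 3.0 falls in bin 3 = [3, 4). Cells
    without trials simply do not appear (their count is logged).
    """
    if len(trials) == 0:
        raise ValueError("cannot bin an empty trial table")
    df = trials.copy()
    df["age_bin"] = np.floor(df["age"].to_numpy(dtype=float)).astype(int)
    df["object_id"] = df["object_id"].fillna("").astype(str)
    grouped = (
        df.groupby(_CELL_KEYS, as_index=False)
        .agg(n_trials=("correct", "size"), observed_rate=("correct", "mean"))
        .sort_values(_CELL_KEYS, ignore_index=True)
    )
    n_possible = df["age_bin"].nunique() * df["condition"].nunique() * df["object_id"].nunique()
    n_empty = n_possible - len(grouped)
    if n_empty > 0:
        logger.info("dropped %d empty cells out of %d possible", n_empty, n_possible)
    return grouped


def bin_predictions(
    trials: pd.DataFrame,
    prediction_draws: np.ndarray,
    hdi_mass: float = 0.95,
) -> pd.DataFrame:
    """Attach per-cell predicted mean and HDI to the observed binned table.

    ``prediction_draws`` has shape ``(S, N)``: one predicted probability per
    posterior draw and trial row (aligned with ``trials``). Within each cell
    the per-draw prediction is the mean over the cell's trials, so the HDI
    reflects posterior uncertainty about the cell rate.
    """
    if prediction_draws.ndim != 2 or prediction_draws.shape[1] != len(trials):
        raise ValueError("prediction_draws must be (n_draws, n_trials)")
    binned = bin_responses(trials)
    df = trials.copy()
    df["age_bin"] = np.floor(df["age"].to_numpy(dtype=float)).astype(int)
    df["object_id"] = df["object_id"].fillna("").astype(str)
    means = np.empty(len(binned))
    lows = np.empty(len(binned))
    highs = np.empty(len(binned))
    groups = df.groupby(_CELL_KEYS).indices
    for i, row in binned.iterrows():
        idx = groups[(row["age_bin"], row["condition"], row["object_id"])]
        cell_draws = prediction_draws[:, idx].mean(axis=1)
        means[i] = cell_draws.mean()
        lows[i], highs[i] = hdi(cell_draws, hdi_mass)
    binned["predicted_mean"] = means
    binned["predicted_hdi_low"] = lows
    binned["predicted_hdi_high"] = highs
    return binned


def pearson_r(
    predicted: Sequence[float],
    observed: Sequence[float],
    weights: Optional[Sequence[float]] = None,
) -> Tuple[float, float]:
    """Product-moment correlation and its square (variance explained).

    ``weights`` (for example cell trial counts) switches to the weighted
    correlation; the default weights cells equally.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predicted and observed must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if weights is None:
        r = float(stats.pearsonr(x, y).statistic)
    else:
        w = np.asarray(weights, dtype=float)
        mx, my = np.average(x, weights=w), np.average(y, weights=w)
        cov = np.average((x - mx) * (y - my), weights=w)
        r = float(cov / np.sqrt(np.average((x - mx) ** 2, weights=w)
                                * np.average((y - my) ** 2, weights=w)))
    return r, r * r


def hdi(samples: Sequence[float], mass: float = 0.95) -> Tuple[float, float]:
    """Highest-density interval: shortest contiguous window of sorted samples.

    For multimodal samples the single contiguous interval is still reported
    (with a logged warning); degenerate all-equal input returns a point.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 samples for an HDI, got {n}")
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must lie in (0, 1]")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    _warn_if_multimodal(x)
    return float(x[i]), float(x[i + k])


def _warn_if_multimodal(sorted_x: np.ndarray, bins: int = 20) -> None:
    if sorted_x[0] == sorted_x[-1]:
        return
    counts, _ = np.histogram(sorted_x, bins=bins)
    peak = counts.max()
    high = np.flatnonzero(counts >= 0.5 * peak)
    if high.size >= 2 and np.any(counts[high[0] : high[-1] + 1] < 0.1 * peak):
        logger.warning(
            "sample distribution looks multimodal; contiguous HDI reported"
        )


def compare_report(
    binned_by_model: Mapping[str, pd.DataFrame],
    evidences: Optional[Mapping[str, object]] = None,
    weighted: bool = False,
) -> pd.DataFrame:
    """One row per model: Pearson r, r^2 and (when supplied) log evidence.

    All models must be evaluated on the same cell set; a mismatch raises.
    """
    report = []
    reference_cells = None
    for name, binned in binned_by_model.items():
        cells = list(map(tuple, binned[_CELL_KEYS].itertuples(index=False)))
        if reference_cells is None:
            reference_cells = cells
        elif cells != reference_cells:
            raise ValueError(f"model {name!r} is binned on a different cell set")
        weights = binned["n_trials"] if weighted else None
        r, r2 = pearson_r(binned["predicted_mean"], binned["observed_rate"], weights)
        row = {"model": name, "r": r, "r_squared": r2, "n_cells": len(binned)}
        if evidences is not None and name in evidences:
            ev = evidences[name]
            row["log_marginal_likelihood"] = ev.log_marginal_likelihood
            row["evidence_se"] = ev.standard_error
        report.append(row)
    return pd.DataFrame(report)
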