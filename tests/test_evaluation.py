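"""Binning, correlations, HDIs and the model-comparison report."""

import numpy as np
import pandas as pd
import pytest

from pragmalex.evaluation import (
    bin_predictions,
    bin_responses,
    compare_report,
    hdi,
    pearson_r,
)
from pragmalex.inference import ModelEvidence


def trials_frame(rows):
    return pd.DataFrame(
        rows, columns=["child_id", "age", "experiment", "condition", "object_id", "correct"]
    )


def test_bin_responses_counts():
    t = trials_frame(
        [
            ("a", 2.1, "exp3", "congruent", "obj01", 1),
            ("b", 2.9, "exp3", "congruent", "obj01", 0),
            ("c", 3.0, "exp3", "congruent", "obj01", 1),  # age 3.0 -> bin 3
        ]
    )
    binned = bin_responses(t)
    assert len(binned) == 2
    cell2 = binned[binned["age_bin"] == 2].iloc[0]
    assert cell2["n_trials"] == 2 and cell2["observed_rate"] == pytest.approx(0.5)
    cell3 = binned[binned["age_bin"] == 3].iloc[0]
    assert cell3["n_trials"] == 1 and cell3["observed_rate"] in (0.0, 1.0)


def test_binning_partitions_all_trials(small_study):
    binned = bin_responses(small_study)
    assert binned["n_trials"].sum() == len(small_study)
    again = bin_responses(small_study)
    pd.testing.assert_frame_equal(binned, again)


def test_bin_responses_empty_rejected():
    with pytest.raises(ValueError):
        bin_responses(trials_frame([]))


def test_pearson_r_against_textbook_formula():
    x = np.array([0.2, 0.5, 0.9])
    y = np.array([0.1, 0.6, 0.8])
    r, r2 = pearson_r(x, y)
    # independent oracle: raw product-moment formula
    xc, yc = x - x.mean(), y - y.mean()
    r_hand = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    assert r == pytest.approx(r_hand, abs=1e-12)
    assert r2 == pytest.approx(r_hand**2, abs=1e-12)


def test_pearson_r_limits_and_errors():
    y = np.array([0.1, 0.4, 0.7, 0.9])
    assert pearson_r(y, y)[0] == pytest.approx(1.0)
    assert pearson_r(-y, y)[0] == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        pearson_r(np.ones(4), y)
    with pytest.raises(ValueError):
        pearson_r(y[:2], y[:2])


def test_pearson_r_agrees_with_bruteforce_covariance():
    rng = np.random.default_rng(0)
    x, y = rng.random(50), rng.random(50)
    r, _ = pearson_r(x, y)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    r_brute = cov / (x.std() * y.std())
    assert r == pytest.approx(r_brute, abs=1e-12)


def test_hdi_examples():
    assert hdi(np.full(500, 3.7)) == (3.7, 3.7)
    rng = np.random.default_rng(1)
    low, high = hdi(rng.uniform(0, 1, 10_000), 0.95)
    assert 0.94 < high - low < 0.96
    x = rng.standard_normal(5000)
    low, high = hdi(x, mass=1.0)
    assert (low, high) == (x.min(), x.max())
    with pytest.raises(ValueError):
        hdi(np.arange(50))


def test_hdi_agrees_with_arviz():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        rng = np.random.default_rng(5)
        x = rng.standard_normal(20_000)
        lo, hi = hdi(x, 0.95)
        ref = az.hdi(x, hdi_prob=0.95)
    assert lo == pytest.approx(ref[0], abs=0.01)
    assert hi == pytest.approx(ref[1], abs=0.01)


def test_hdi_multimodal_warns(caplog):
    rng = np.random.default_rng(2)
    x = np.concatenate([rng.normal(-5, 0.3, 500), rng.normal(5, 0.3, 500)])
    with caplog.at_level("WARNING", logger="pragmalex.evaluation"):
        hdi(x)
    assert any("multimodal" in r.message for r in caplog.records)


def test_bin_predictions_attaches_cells():
    rng = np.random.default_rng(3)
    t = trials_frame(
        [("c%d" % i, 2.5 + (i % 2), "exp3", "congruent", "obj01", i % 2) for i in range(20)]
    )
    draws = np.clip(rng.normal(0.6, 0.05, size=(300, 20)), 0, 1)
    binned = bin_predictions(t, draws)
    assert {"predicted_mean", "predicted_hdi_low", "predicted_hdi_high"} <= set(binned)
    assert (binned["predicted_hdi_low"] <= binned["predicted_mean"]).all()
    assert (binned["predicted_mean"] <= binned["predicted_hdi_high"]).all()


def test_compare_report():
    base = pd.DataFrame(
        {
            "age_bin": [2, 2, 3, 3],
            "condition": ["congruent", "incongruent"] * 2,
            "object_id": ["obj01"] * 4,
            "n_trials": [10, 10, 10, 10],
            "observed_rate": [0.5, 0.4, 0.8, 0.5],
            "predicted_mean": [0.55, 0.42, 0.75, 0.52],
        }
    )
    other = base.copy()
    ev = {"a": ModelEvidence(-10.0, 0.1, 2000), "b": ModelEvidence(-12.0, 0.1, 2000)}
    report = compare_report({"a": base, "b": other}, ev)
    assert len(report) == 2
    assert report["r"].iloc[0] == pytest.approx(report["r"].iloc[1])
    assert report["log_marginal_likelihood"].tolist() == [-10.0, -12.0]
    mismatched = other.iloc[:3]
    with pytest.raises(ValueError):
        compare_report({"a": base, "b": mismatched})
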