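"""Proliferation quantification: bootstrap AUC fold changes of growth curves.

Luminescence traces are normalized by subtracting each replicate's reading
at the initial timepoint, fitted with a continuous piecewise-linear (linear
spline) model, and summarized by the trapezoid area under the curve.
Uncertainty comes from a residual bootstrap: residuals are resampled with
replacement, added back to the fitted values, the model refit, and the AUC
recomputed; each bootstrap AUC is divided by the reference line's AUC from
the same run and replicate index, ratios are averaged over runs, and the
95% confidence interval is taken from the 2.5% and 97.5% empirical
quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

GROWTH_COLUMNS = ["sample", "run", "time_h", "replicate", "rlu"]


def normalize_luminescence(curves: pd.DataFrame) -> pd.DataFrame:
    """Subtract each replicate trace's value at its earliest timepoint.

    Expects a tidy table with columns sample, run, time_h, replicate, rlu;
    normalization is per (sample, run, replicate) so every trace starts at 0.
    """
    df = pd.DataFrame(curves)[GROWTH_COLUMNS].copy()
    trace = ["sample", "run", "replicate"]
    at_t0 = df.groupby(trace)["time_h"].transform("min") == df["time_h"]
    base = (df[at_t0].drop_duplicates(trace)[trace + ["rlu"]]
            .rename(columns={"rlu": "_t0_rlu"}))
    df = df.merge(base, on=trace, how="left")
    df["rlu"] = df["rlu"] - df["_t0_rlu"]
    return df.drop(columns="_t0_rlu")


def spline_design(times: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Design matrix of a continuous piecewise-linear model: 1, t, (t-k)+."""
    cols = [np.ones_like(times), times]
    for k in knots:
        cols.append(np.maximum(times - k, 0.0))
    return np.column_stack(cols)


@dataclass
class LinearSplineFit:
    times: np.ndarray
    knots: np.ndarray
    coef: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return spline_design(t, self.knots) @ self.coef


def fit_linear_spline(times, values, knots=None) -> LinearSplineFit:
    """Least-squares continuous piecewise-linear fit with given knots.

    ``knots=None`` places a knot at every interior distinct timepoint, the
    maximum-flexibility fit (fitted value at each timepoint equals the mean
    of its replicates).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    unique_t = np.unique(times)
    if knots is None:
        knots = unique_t[1:-1]
    knots = np.asarray(knots, dtype=float)
    if knots.size and (knots.min() <= times.min() or knots.max() >= times.max()):
        raise ValueError("knots must lie strictly inside the time range")
    X = spline_design(times, knots)
    if times.size < X.shape[1]:
        raise ValueError("fewer observations than spline parameters")
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    fitted = X @ coef
    return LinearSplineFit(times=times, knots=knots, coef=coef,
                           fitted=fitted, residuals=values - fitted)


def auc_trapezoid(times, values=None) -> float:
    """Trapezoid area under a curve given (times, values) or an (n, 2) array."""
    if values is None:
        pts = np.asarray(times, dtype=float)
        times, values = pts[:, 0], pts[:, 1]
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 timepoints")
    order = np.argsort(times)
    return float(np.trapezoid(values[order], times[order]))


def _bootstrap_aucs(times: np.ndarray, values: np.ndarray, n_boot: int,
                    rng: np.random.Generator, knots=None) -> np.ndarray:
    """Residual-bootstrap AUC draws for one curve (all replicates pooled)."""
    fit = fit_linear_spline(times, values, knots=knots)
    X = spline_design(times, fit.knots)
    pinv = np.linalg.pinv(X)
    idx = rng.integers(0, len(fit.residuals), size=(n_boot, len(fit.residuals)))
    boot_y = fit.fitted[None, :] + fit.residuals[idx]
    coefs = boot_y @ pinv.T                         # (n_boot, n_params)
    grid = np.unique(times)
    preds = coefs @ spline_design(grid, fit.knots).T
    return np.trapezoid(preds, grid, axis=1)


def bootstrap_auc_ratio(curves: pd.DataFrame, reference_id: str,
                        n_boot: int = 10_000, seed: int = 0,
                        knots=None) -> pd.DataFrame:
    """Bootstrap AUC fold changes of every sample versus a reference line.

    Parameters
    ----------
    curves : tidy table (sample, run, time_h, replicate, rlu), raw RLU.
    reference_id : sample whose AUC is the denominator; must be present in
        every run.
    n_boot : bootstrap replicates (paired between sample and reference
        within a run, then averaged across runs).
    seed : master seed; one substream per (sample, run).

    Returns
    -------
    DataFrame indexed by sample with mean_auc_fold_change, ci_low, ci_high
    (95%), n_bootstrap (replicates retained) and n_dropped (replicates with
    non-positive reference AUC).
    """
    df = normalize_luminescence(curves)
    runs = sorted(df["run"].unique())
    samples = sorted(df["sample"].unique())
    for run in runs:
        present = df.loc[df["run"] == run, "sample"].unique()
        if reference_id not in present:
            raise ValueError(f"reference {reference_id} missing from run {run}")

    seedseq = np.random.SeedSequence(seed)
    streams = {key: np.random.default_rng(child) for key, child in
               zip([(s, r) for s in samples for r in runs],
                   seedseq.spawn(len(samples) * len(runs)))}

    boot_aucs: dict[tuple[str, str], np.ndarray] = {}
    for (sample, run), rng in streams.items():
        sub = df[(df["sample"] == sample) & (df["run"] == run)]
        if sub.empty:
            continue
        boot_aucs[(sample, run)] = _bootstrap_aucs(
            sub["time_h"].to_numpy(), sub["rlu"].to_numpy(),
            n_boot, rng, knots=knots)

    rows = []
    for sample in samples:
        per_run = []
        for run in runs:
            if (sample, run) not in boot_aucs:
                continue
            per_run.append(boot_aucs[(sample, run)]
                           / boot_aucs[(reference_id, run)])
        ratios = np.mean(per_run, axis=0)
        ok = np.all([boot_aucs[(reference_id, run)] > 0 for run in runs
                     if (sample, run) in boot_aucs], axis=0)
        n_dropped = int((~ok).sum())
        if n_dropped > 0.01 * n_boot:
            warnings.warn(
                f"{n_dropped} bootstrap replicate(s) dropped for {sample} "
                "(non-positive reference AUC)", stacklevel=2)
        ratios = ratios[ok]
        rows.append({
            "sample_id": sample,
            "mean_auc_fold_change": float(ratios.mean()),
            "ci_low": float(np.quantile(ratios, 0.025)),
            "ci_high": float(np.quantile(ratios, 0.975)),
            "n_bootstrap": int(ratios.size),
            "n_dropped": n_dropped,
        })
    return pd.DataFrame(rows).set_index("sample_id")
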