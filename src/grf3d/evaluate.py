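"""Waveform accuracy metrics and model comparison.

Per trial and axis: RMSE in BW, range-normalized rRMSE (%), Pearson r;
for the vertical axis additionally the absolute active-peak error (%).
The default evaluation domain is the stance samples inside the stride
window; including flight is available as ``domain="full"`` (and lowers
rRMSE, since the flight force is trivially zero). Trial metrics average
to per-subject values, which average to cohort mean ± sd; model pairs are
compared with a dependent t-test over per-subject means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import GaitEvents, GRF_AXES

STANCE_DOMAIN = "stance_only"
FULL_DOMAIN = "full_signal"


def _masked(e, m, mask):
    e = np.asarray(e, dtype=float)
    m = np.asarray(m, dtype=float)
    if e.shape != m.shape:
        raise ValueError("series lengths differ")
    if mask is None:
        return e, m
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != e.shape:
        raise ValueError("mask length differs from series length")
    if not mask.any():
        raise ValueError("empty evaluation mask")
    return e[mask], m[mask]


def rmse_bw(e, m, mask=None) -> float:
    """Root-mean-square error over the masked samples, in BW."""
    ee, mm = _masked(e, m, mask)
    return float(np.sqrt(np.mean((ee - mm) ** 2)))


def rrmse(e, m, mask=None) -> float:
    """RMSE normalized by the measured signal's range over the same
    evaluation domain, as a percentage."""
    ee, mm = _masked(e, m, mask)
    rng = mm.max() - mm.min()
    if rng <= 0:
        raise ValueError("measured signal has zero range")
    return float(np.sqrt(np.mean((ee - mm) ** 2)) / rng * 100.0)


def pearson_r(e, m, mask=None) -> float:
    """Product-moment correlation between estimate and measurement."""
    ee, mm = _masked(e, m, mask)
    if np.std(ee) == 0 or np.std(mm) == 0:
        raise ValueError("constant input: correlation undefined")
    return float(np.corrcoef(ee, mm)[0, 1])


def peak_error_pct(e_vertical, m_vertical, events: GaitEvents,
                   window=None) -> float:
    """Mean absolute vertical peak error over steps, as a percentage.

    Per stance interval the peak is the maximum of each signal within the
    interval; ``window`` (half-open sample pair) restricts which stance
    intervals count.
    """
    e = np.asarray(e_vertical, dtype=float)
    m = np.asarray(m_vertical, dtype=float)
    errs = []
    for a, b in events.stance_intervals():
        if window is not None and (a < window[0] or b > window[1]):
            continue
        if b > len(e):
            continue
        mp = m[a:b].max()
        ep = e[a:b].max()
        if mp <= 0:
            continue
        errs.append(abs(ep - mp) / mp * 100.0)
    if not errs:
        raise ValueError("no stance intervals to evaluate")
    return float(np.mean(errs))


@dataclass
class PairedTestResult:
    t_stat: float
    p_value: float
    n: int
    mean_difference: float
    significant: bool          # at alpha = 0.05
    degenerate: bool = False   # zero-variance, non-zero differences


def compare_models(per_subject_a: Dict[str, float],
                   per_subject_b: Dict[str, float],
                   alpha: float = 0.05) -> PairedTestResult:
    """Two-sided dependent t-test for paired samples over subjects."""
    if set(per_subject_a) != set(per_subject_b):
        raise ValueError("subject sets differ between models")
    keys = sorted(per_subject_a)
    if len(keys) < 3:
        raise ValueError("need at least 3 paired subjects")
    a = np.array([per_subject_a[k] for k in keys])
    b = np.array([per_subject_b[k] for k in keys])
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return PairedTestResult(0.0, 1.0, len(keys), 0.0, False)
        # constant non-zero difference: t undefined, report as degenerate
        return PairedTestResult(np.inf if d.mean() > 0 else -np.inf, 0.0,
                                len(keys), float(d.mean()), True, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(float(t), float(p), len(keys), float(d.mean()),
                            bool(p < alpha))


def evaluate_trial(estimate: np.ndarray, measured: np.ndarray,
                   stance_mask: Optional[np.ndarray],
                   events: Optional[GaitEvents] = None,
                   window=None, domain: str = STANCE_DOMAIN) -> dict:
    """Metrics for one trial: per-axis RMSE/rRMSE/r (+ vertical peak error).

    ``estimate`` and ``measured`` are (n, 3) in BW over the stride window;
    ``stance_mask`` is over the same samples. Axes whose estimate is
    unavailable (all-NaN, e.g. ML/AP of the physical model) yield NaN.
    """
    estimate = np.asarray(estimate, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if domain == STANCE_DOMAIN:
        if stance_mask is None:
            raise ValueError("stance-only evaluation needs a stance mask")
        mask = np.asarray(stance_mask, dtype=bool)
    elif domain == FULL_DOMAIN:
        mask = None
    else:
        raise ValueError(f"unknown evaluation domain: {domain}")
    out = {"domain": domain}
    for j, axis in enumerate(GRF_AXES):
        if np.all(np.isnan(estimate[:, j])):
            out[f"rmse_bw_{axis}"] = np.nan
            out[f"rrmse_pct_{axis}"] = np.nan
            out[f"pearson_r_{axis}"] = np.nan
            continue
        out[f"rmse_bw_{axis}"] = rmse_bw(estimate[:, j], measured[:, j], mask)
        out[f"rrmse_pct_{axis}"] = rrmse(estimate[:, j], measured[:, j], mask)
        out[f"pearson_r_{axis}"] = pearson_r(estimate[:, j], measured[:, j], mask)
    if events is not None:
        out["peak_error_pct"] = peak_error_pct(estimate[:, 2], measured[:, 2],
                                               events, window=window)
    return out


def build_report(trial_rows: List[dict]) -> Dict[str, pd.DataFrame]:
    """Aggregate per-trial metric rows into Table-style reports.

    Each row needs 'subject', 'model' plus metric columns. Returns
    per-trial, per-subject (mean over trials) and overall (mean ± sd over
    subjects) tables with deterministic ordering.
    """
    per_trial = pd.DataFrame(trial_rows).sort_values(
        ["model", "subject"] + (["trial"] if "trial" in trial_rows[0] else []),
        kind="mergesort").reset_index(drop=True)
    metric_cols = [c for c in per_trial.columns
                   if c.split("_")[0] in ("rmse", "rrmse", "pearson", "peak")]
    per_subject = (per_trial.groupby(["model", "subject"], sort=True)[metric_cols]
                   .mean().reset_index())
    overall = (per_subject.groupby("model", sort=True)[metric_cols]
               .agg(["mean", "std"]))
    overall.columns = [f"{m}_{s}" for m, s in overall.columns]
    return {"per_trial": per_trial, "per_subject": per_subject,
            "overall": overall.reset_index()}


def paired_tests(per_subject: pd.DataFrame, model_a: str, model_b: str,
                 metrics: Sequence[str]) -> pd.DataFrame:
    """Dependent t-tests between two models for each requested metric."""
    rows = []
    for metric in metrics:
        sub = per_subject.pivot(index="subject", columns="model", values=metric)
        if model_a not in sub or model_b not in sub:
            continue
        pair = sub[[model_a, model_b]].dropna()
        res = compare_models(pair[model_a].to_dict(), pair[model_b].to_dict())
        rows.append({"metric": metric, "model_a": model_a, "model_b": model_b,
                     "t": res.t_stat, "p": res.p_value, "n": res.n,
                     "mean_difference": res.mean_difference,
                     "significant": res.significant})
    return pd.DataFrame(rows)
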