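"""Scoring metrics and the multi-subject comparison harness.

RMSE, MAE and R² are computed exactly as defined for the estimator
comparison: RMSE = sqrt(mean((y - yhat)^2)), MAE = mean(|yhat - y|),
R² = 1 - SS_res/SS_tot with SS_tot about the truth mean. The cohort
harness runs a set of estimator tags over synthetic subjects with known
ground truth and reports a long-format per-subject, per-target table
(RMSE >= MAE always holds for a single dataset, and the harness
enforces that invariant rather than emulating published tables that
violate it).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MetricReport", "rmse", "mae", "r2", "metric_report", "run_cohort"]

#: Sentinel reported when the truth sequence has zero variance.
UNDEFINED_R2 = np.nan


@dataclass
class MetricReport:
    rmse: float
    mae: float
    r2: float
    n: int
    target: str
    subject_id: str = ""
    method: str = ""


def _check(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty sequences")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean squared error sqrt(mean((y - yhat)^2))."""
    y, yhat = _check(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y, yhat) -> float:
    """Mean absolute error mean(|yhat - y|)."""
    y, yhat = _check(y, yhat)
    return float(np.mean(np.abs(yhat - y)))


def r2(y, yhat) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    SS_tot is the total sum of squares about the mean of the truth
    sequence. Zero-variance truth makes the statistic undefined: a NaN
    sentinel is returned with a warning.
    """
    y, yhat = _check(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("zero-variance truth: R^2 undefined", stacklevel=2)
        return UNDEFINED_R2
    ss_res = float(np.sum((yhat - y) ** 2))
    return 1.0 - ss_res / ss_tot


def metric_report(y, yhat, target: str, subject_id: str = "", method: str = "") -> MetricReport:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r2v = r2(y, yhat)
    return MetricReport(
        rmse=rmse(y, yhat), mae=mae(y, yhat), r2=r2v,
        n=len(np.asarray(y)), target=target, subject_id=subject_id, method=method,
    )


def run_cohort(methods: list[str], cohort: list, seed: int = 0, **pipeline_kwargs) -> pd.DataFrame:
    """Score estimator tags over a synthetic cohort.

    ``cohort`` is a list of subject records from
    :func:`bcgvitals.pipeline.simulate_cohort`. Each method tag maps to
    a feature/estimator route (see ``pipeline.fit_and_score``); the
    special tag "oracle" returns the ground truth and is used for
    harness self-checks. Estimator failures on a subject are recorded as
    missing rows with the reason, and the run continues.

    Returns a long-format frame with columns subject, method, target,
    rmse, mae, r2, n, error — plus a per-method mean-MAE ranking
    attached as ``frame.attrs['ranking']``.
    """
    from . import pipeline  # deferred: pipeline imports evaluation

    rows = []
    for method in methods:
        try:
            reports = pipeline.fit_and_score(method, cohort, seed=seed, **pipeline_kwargs)
        except Exception as exc:  # noqa: BLE001 — harness must keep running
            for subj in cohort:
                for target in ("HR", "RR"):
                    rows.append(dict(subject=subj.subject_id, method=method, target=target,
                                     rmse=np.nan, mae=np.nan, r2=np.nan, n=0, error=str(exc)))
            continue
        for rep in reports:
            rows.append(dict(subject=rep.subject_id, method=rep.method, target=rep.target,
                             rmse=rep.rmse, mae=rep.mae, r2=rep.r2, n=rep.n, error=""))
    frame = pd.DataFrame(rows)
    if not frame.empty:
        ranking = (
            frame[frame.error == ""]
            .groupby("method")["mae"].mean()
            .sort_values()
        )
        frame.attrs["ranking"] = ranking
    return frame
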