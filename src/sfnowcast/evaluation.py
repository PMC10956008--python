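"""Outcome metrics and per-model, per-state reporting.

Metrics follow surveillance-evaluation conventions for a weekly nowcast over
one evaluation year:

* ESR / ASR — estimated vs actual crude suicide rate per 100,000 population
  (annual death total x 100,000 / population; no age adjustment),
* annual error rate — 100 x (ESR - ASR) / ASR, sign-preserving (negative
  means underestimation),
* RMSE — root mean squared error of weekly counts,
* MAD — the *median* of the weekly absolute differences,
* Pearson correlation between weekly predicted and actual counts; if either
  series has zero variance the correlation is undefined and is reported as
  NA (never silently 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def _check_pair(predicted, actual, min_len=1):
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.ndim != 1 or a.ndim != 1:
        raise ValueError("weekly vectors must be one-dimensional")
    if len(p) != len(a):
        raise ValueError(f"length mismatch: {len(p)} vs {len(a)}")
    if len(p) < min_len:
        raise ValueError(f"need at least {min_len} weeks, got {len(p)}")
    return p, a


def rmse(predicted, actual) -> float:
    """Root mean squared weekly error."""
    p, a = _check_pair(predicted, actual)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def mad(predicted, actual) -> float:
    """Median absolute weekly difference (even length: mean of the two
    central order statistics)."""
    p, a = _check_pair(predicted, actual)
    return float(np.median(np.abs(p - a)))


def pearson(predicted, actual) -> float:
    """Product-moment correlation; NaN (the NA flag) when either vector has
    zero variance."""
    p, a = _check_pair(predicted, actual, min_len=2)
    if np.std(p) == 0 or np.std(a) == 0:
        return float("nan")
    return float(np.corrcoef(p, a)[0, 1])


def annual_rate(weekly_deaths, population: float) -> float:
    """Crude rate per 100,000: total deaths over the year / population."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    d = np.asarray(weekly_deaths, dtype=float)
    return float(100_000.0 * d.sum() / population)


def annual_error(esr: float, asr: float) -> float:
    """Annual percentage error 100*(ESR-ASR)/ASR; underestimates are negative."""
    if asr <= 0:
        raise ValueError(f"actual rate must be positive, got {asr}")
    return 100.0 * (esr - asr) / asr


@dataclass
class EvaluationReport:
    """Per-(state, model) metric bundle with the weekly pairs it was computed
    from, renderable as one row of the study-style report table."""

    state: str
    model_name: str
    esr_per_100k: float
    asr_per_100k: float
    annual_error_pct: float
    rmse: float
    mad: float
    pearson: float  # NaN = undefined (NA)
    predicted: np.ndarray
    actual: np.ndarray

    def to_row(self) -> dict:
        return {
            "state": self.state,
            "model": self.model_name,
            "esr": self.esr_per_100k,
            "asr": self.asr_per_100k,
            "annual_error_pct": self.annual_error_pct,
            "rmse": self.rmse,
            "mad": self.mad,
            "pearson": self.pearson,
        }


def evaluate_model(
    predictions,
    actual,
    population: float,
    state: str = "",
    model_name: str = "",
    asr: float | None = None,
) -> EvaluationReport:
    """Compute the full metric bundle for one model's test-year predictions.

    ``asr`` defaults to the rate implied by the actual weekly counts; pass an
    externally reported rate to mirror an official denominator instead.
    """
    p, a = _check_pair(predictions, actual)
    if (p < 0).any():
        raise ValueError("predictions must be nonnegative (clamp upstream)")
    esr = annual_rate(p, population)
    if asr is None:
        asr = annual_rate(a, population)
    return EvaluationReport(
        state=state,
        model_name=model_name,
        esr_per_100k=esr,
        asr_per_100k=asr,
        annual_error_pct=annual_error(esr, asr),
        rmse=rmse(p, a),
        mad=mad(p, a),
        pearson=pearson(p, a) if len(p) >= 2 else float("nan"),
        predicted=p,
        actual=a,
    )


def reports_to_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Stack reports into the report-table layout
    (state, model, esr, asr, annual_error_pct, rmse, mad, pearson)."""
    return pd.DataFrame([r.to_row() for r in reports])


def write_report_csv(reports: list[EvaluationReport], path) -> str:
    df = reports_to_frame(reports)
    df.to_csv(path, index=False, lineterminator="\n", na_rep="NA")
    return str(path)
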