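"""Exponential stage-weight growth models.

Fits W = a * exp(b * stage) to egg or embryo wet weights (log-linear OLS
by default, optional nonlinear least squares) and back-predicts weights at
unmeasurable early stages with explicit extrapolation flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DomainError, InsufficientDataError
from .staging import STAGE_MIN, STAGE_MAX

LOG_LINEAR = "log-linear"
NONLINEAR = "nonlinear"


@dataclass
class GrowthModel:
    subject: str  # "egg" | "embryo"
    a_mg: float
    b_per_stage: float
    fit_method: str
    r2: float
    n: int
    residual_sd_log: float
    stage_domain: tuple[float, float]

    def __post_init__(self) -> None:
        if self.a_mg <= 0:
            raise DomainError("scale parameter a must be positive")
        lo, hi = self.stage_domain
        if lo < STAGE_MIN or hi > STAGE_MAX:
            raise DomainError(
                f"stage domain {self.stage_domain} outside {STAGE_MIN}..{STAGE_MAX}"
            )

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["stage_domain"] = list(self.stage_domain)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "GrowthModel":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        payload["stage_domain"] = tuple(payload["stage_domain"])
        return cls(**payload)


def fit_exponential(
    stages,
    weights_mg,
    method: str = LOG_LINEAR,
    subject: str = "embryo",
) -> GrowthModel:
    """Fit W = a * exp(b * stage).

    Log-linear OLS (default) regresses log W on stage, which stabilizes the
    stage-increasing variance of the weights; r2 is reported on the fitting
    scale.  Nonlinear least squares refines the log-linear start values on
    the original scale.
    """
    stages = np.asarray(stages, dtype=float)
    weights = np.asarray(weights_mg, dtype=float)
    if stages.shape != weights.shape:
        raise DomainError("stages and weights must have equal length")
    if np.any(weights <= 0):
        raise DomainError("weights must be positive")
    if len(np.unique(stages)) < 3:
        raise InsufficientDataError("need >=3 distinct stages")

    logw = np.log(weights)
    b, loga = np.polyfit(stages, logw, 1)
    a = float(np.exp(loga))

    if method == LOG_LINEAR:
        fitted = loga + b * stages
        resid = logw - fitted
        ss_tot = float(np.sum((logw - logw.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    elif method == NONLINEAR:
        popt, _ = curve_fit(
            lambda s, aa, bb: aa * np.exp(bb * s), stages, weights, p0=(a, b)
        )
        a, b = float(popt[0]), float(popt[1])
        fitted_w = a * np.exp(b * stages)
        resid_w = weights - fitted_w
        ss_tot = float(np.sum((weights - weights.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid_w**2)) / ss_tot if ss_tot > 0 else 1.0
        resid = logw - np.log(fitted_w)
    else:
        raise DomainError(f"unknown fit method {method!r}")

    residual_sd = float(np.std(resid, ddof=2)) if len(stages) > 2 else 0.0
    return GrowthModel(
        subject=subject,
        a_mg=a,
        b_per_stage=float(b),
        fit_method=method,
        r2=float(r2),
        n=len(stages),
        residual_sd_log=residual_sd,
        stage_domain=(float(stages.min()), float(stages.max())),
    )


def predict_weight(model: GrowthModel, stages) -> pd.DataFrame:
    """Predict wet weights (mg) at stages; out-of-domain stages are flagged
    extrapolated rather than refused (early-stage back-prediction is the
    intended use of that mode)."""
    stages = np.atleast_1d(np.asarray(stages, dtype=float))
    weights = model.a_mg * np.exp(model.b_per_stage * stages)
    lo, hi = model.stage_domain
    extrapolated = (stages < lo) | (stages > hi)
    return pd.DataFrame({
        "stage": stages,
        "weight_mg": weights,
        "extrapolated": extrapolated,
    })
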