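"""MO2-weight smoothing and thermal metabolic scope.

Fits locally weighted polynomial regressions (loess: tricube kernel,
degree 2, nearest-neighbour span) of per-embryo MO2 on wet weight at each
exposure temperature, then derives pointwise

    TMS = high - low        (thermal metabolic scope)
    FMS = high / low        (factorial metabolic scope)

on the common weight interval, plus simple curve features (local maxima,
global maximum, terminal trend).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError

DEFAULT_SPAN = 0.5
DEFAULT_GRID = 200


def loess(x, y, x_eval, span: float = DEFAULT_SPAN, degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression.

    For each evaluation point the ``ceil(span * n)`` nearest observations
    are fit with a weighted polynomial of ``degree`` using tricube weights;
    the local fit is evaluated at the point.  No extrapolation logic here —
    callers enforce range restrictions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
    n = len(x)
    if n != len(y):
        raise DomainError("x and y must have equal length")
    if not 0 < span <= 1:
        raise DomainError("span must be in (0, 1]")
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)

    out = np.empty(len(x_eval))
    for m, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dloc = d[idx]
        dmax = dloc.max()
        if dmax == 0:
            out[m] = y[idx].mean()
            continue
        w = (1.0 - np.minimum(dloc / dmax, 1.0) ** 3) ** 3
        pos = w > 0
        xc = x[idx][pos] - x0
        yloc = y[idx][pos]
        wloc = w[pos]
        deg = min(degree, len(np.unique(xc)) - 1)
        coef = np.polyfit(xc, yloc, deg, w=np.sqrt(wloc))
        out[m] = coef[-1]  # local fit evaluated at x0
    if not np.all(np.isfinite(out)):
        raise DomainError("loess produced non-finite predictions")
    return out


@dataclass
class SmoothFit:
    """A loess fit of per-embryo MO2 on wet weight at one temperature."""

    temperature_class: str
    span: float
    weight_grid: np.ndarray
    predicted_mo2: np.ndarray
    n_points: int
    degree: int = 2
    method: str = "loess"
    x: np.ndarray = field(default=None, repr=False)
    y: np.ndarray = field(default=None, repr=False)

    @property
    def weight_range(self) -> tuple[float, float]:
        return float(self.x.min()), float(self.x.max())

    def predict(self, weights) -> np.ndarray:
        """Predict MO2 at new weights; extrapolation is refused."""
        weights = np.atleast_1d(np.asarray(weights, dtype=float))
        lo, hi = self.weight_range
        if np.any(weights < lo) or np.any(weights > hi):
            raise DomainError(
                f"prediction outside observed weight range [{lo:g}, {hi:g}]"
            )
        return loess(self.x, self.y, weights, span=self.span, degree=self.degree)

    def residual_ss(self) -> float:
        """In-sample residual sum of squares."""
        fitted = loess(self.x, self.y, self.x, span=self.span, degree=self.degree)
        return float(np.sum((self.y - fitted) ** 2))


def fit_mo2_weight(
    rates: pd.DataFrame,
    temperature_class: str | None = None,
    span: float = DEFAULT_SPAN,
    *,
    grid_points: int = DEFAULT_GRID,
    response: str = "mo2_per_embryo",
) -> SmoothFit:
    """Loess fit of per-embryo MO2 against wet weight for one temperature class."""
    df = rates
    if temperature_class is not None:
        df = df[df["temperature_class"] == temperature_class]
    if len(df) < 10:
        raise InsufficientDataError(
            f"need >=10 rates for a loess fit, got {len(df)}"
        )
    x = df["mass_g"].to_numpy(float)
    y = df[response].to_numpy(float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    grid = np.linspace(x.min(), x.max(), grid_points)
    pred = loess(x, y, grid, span=span)
    return SmoothFit(
        temperature_class=temperature_class or "all",
        span=span,
        weight_grid=grid,
        predicted_mo2=pred,
        n_points=len(x),
        x=x,
        y=y,
    )


@dataclass
class ScopeCurve:
    """TMS/FMS curves on the common weight grid of a low and a high fit."""

    weight_grid: np.ndarray
    lmr: np.ndarray  # predicted MO2 at the low (TIMR-min) temperature
    hmr: np.ndarray  # predicted MO2 at the high (TIMR-max) temperature

    @property
    def tms(self) -> np.ndarray:
        return self.hmr - self.lmr

    @property
    def fms(self) -> np.ndarray:
        """Pointwise high/low ratio; NaN where the low rate is <= 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.lmr > 0, self.hmr / self.lmr, np.nan)
        return r

    @property
    def fms_mean(self) -> float:
        """Mean of the pointwise ratios over the grid (ignoring NaN)."""
        return float(np.nanmean(self.fms))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "weight_g": self.weight_grid,
            "lmr": self.lmr,
            "hmr": self.hmr,
            "tms": self.tms,
            "fms": self.fms,
        })


def thermal_scope(
    low: SmoothFit, high: SmoothFit, grid_points: int = DEFAULT_GRID
) -> ScopeCurve:
    """Evaluate both fits on the intersection of their weight ranges."""
    lo = max(low.weight_range[0], high.weight_range[0])
    hi = min(low.weight_range[1], high.weight_range[1])
    if lo >= hi:
        raise DomainError("fits cover disjoint weight ranges")
    grid = np.linspace(lo, hi, grid_points)
    return ScopeCurve(
        weight_grid=grid, lmr=low.predict(grid), hmr=high.predict(grid)
    )


@dataclass(frozen=True)
class Feature:
    kind: str  # "local_max" | "global_max" | "terminal_trend"
    weight: float
    value: float


def locate_scope_features(curve: ScopeCurve, smooth_points: int = 0) -> list[Feature]:
    """Report TMS curve features: interior local maxima (weight order),
    the global maximum, and the sign of the trend over the last decile."""
    grid = curve.weight_grid
    tms = np.asarray(curve.tms, dtype=float)
    if len(grid) < 5:
        raise InsufficientDataError("grid too short for feature detection")
    if smooth_points > 1:
        kernel = np.ones(smooth_points) / smooth_points
        tms = np.convolve(tms, kernel, mode="same")

    features: list[Feature] = []
    for i in range(1, len(tms) - 1):
        if tms[i] > tms[i - 1] and tms[i] >= tms[i + 1]:
            features.append(Feature("local_max", float(grid[i]), float(tms[i])))

    gi = int(np.argmax(tms))
    features.append(Feature("global_max", float(grid[gi]), float(tms[gi])))

    tail = max(2, len(grid) // 10)
    slope = np.polyfit(grid[-tail:], tms[-tail:], 1)[0]
    features.append(Feature("terminal_trend", float(grid[-tail]), float(np.sign(slope))))
    return features


def plot_scope(low: SmoothFit, high: SmoothFit, curve: ScopeCurve, path: str) -> None:
    """Two-panel figure: MO2-weight fits with raw points, and the TMS curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 8), sharex=True)
    for fit, color, label in ((low, "tab:blue", "low T"), (high, "tab:red", "high T")):
        ax1.plot(fit.x, fit.y, ".", color=color, alpha=0.3)
        ax1.plot(fit.weight_grid, fit.predicted_mo2, color=color, label=label)
    ax1.set_ylabel("MO2 (mg O2 h$^{-1}$ embryo$^{-1}$)")
    ax1.legend()
    ax2.plot(curve.weight_grid, curve.tms, color="k")
    ax2.set_xlabel("embryo wet weight (g)")
    ax2.set_ylabel("TMS (mg O2 h$^{-1}$ embryo$^{-1}$)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
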