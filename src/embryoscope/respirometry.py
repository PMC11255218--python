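"""Closed-chamber respirometry.

Turns raw dissolved-oxygen traces into per-embryo metabolic rates:
linear-segment selection, ordinary-least-squares slope, blank-vial
correction, the closed-chamber MO2 equation

    MO2 = (O2_A - O2_B) * (V / t) / M

with V the chamber water volume minus the embryo-displaced volume, and
the Q10 temperature coefficient

    Q10 = (rate2 / rate1) ** (10 / (t2 - t1)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError

logger = logging.getLogger(__name__)

#: label -> nominal exposure temperature (deg C)
TEMPERATURE_CLASSES = {"LMR": 11.0, "RMR": 24.0, "HMR": 30.0}

#: assumed embryo tissue density used to derive displaced volume (g mL-1)
TISSUE_DENSITY_G_PER_ML = 1.0


def temperature_class(temp_c: float, tol: float = 1.0) -> str:
    """Map a measurement temperature onto the LMR/RMR/HMR class labels.

    Temperatures further than ``tol`` deg C from every nominal class are
    labelled by their numeric value (arbitrary temperatures are accepted).
    """
    for label, ref in TEMPERATURE_CLASSES.items():
        if abs(temp_c - ref) <= tol:
            return label
    return f"{temp_c:g}C"


@dataclass
class OxygenTrace:
    """One vial's dissolved-O2 time series plus chamber metadata."""

    vial_id: str
    times: np.ndarray  # seconds, strictly increasing
    o2: np.ndarray  # mg O2 L-1
    temperature: float  # deg C
    chamber_volume_l: float
    is_blank: bool = False
    embryo_id: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.o2.shape:
            raise DomainError("times and o2 must be 1-d arrays of equal length")
        if len(self.times) < 2:
            raise InsufficientDataError("trace needs at least 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(self.o2 < 0):
            raise DomainError("o2 concentrations must be non-negative")
        if self.chamber_volume_l <= 0:
            raise DomainError("chamber volume must be positive")

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0


@dataclass(frozen=True)
class WindowConfig:
    """Admissible linear-window lengths (minutes) and selection criterion."""

    min_minutes: float = 5.0
    max_minutes: float = 10.0
    criterion: str = "max_r2"  # or "min_residual_sd"

    def __post_init__(self) -> None:
        if not 0 < self.min_minutes <= self.max_minutes:
            raise DomainError("require 0 < min_minutes <= max_minutes")
        if self.criterion not in ("max_r2", "min_residual_sd"):
            raise DomainError(f"unknown criterion {self.criterion!r}")


@dataclass(frozen=True)
class WindowFit:
    """OLS fit over the selected window of a trace."""

    start_index: int
    end_index: int  # inclusive
    start_s: float
    end_s: float
    slope_mg_l_h: float
    intercept: float  # mg L-1 at t = 0 h
    r2: float
    residual_sd: float
    n: int

    def fitted_endpoints(self) -> tuple[float, float]:
        """Fitted O2 values at the window start/end (mg L-1)."""
        a = self.intercept + self.slope_mg_l_h * self.start_s / 3600.0
        b = self.intercept + self.slope_mg_l_h * self.end_s / 3600.0
        return a, b


def _window_stats(t_h, y, i, j, pre):
    """O(1) OLS stats for samples i..j (inclusive) from prefix sums."""
    st, stt, sy, syy, sty = (p[j + 1] - p[i] for p in pre)
    n = j - i + 1
    sxx = stt - st * st / n
    sxy = sty - st * sy / n
    ss_tot = syy - sy * sy / n
    slope = sxy / sxx  # times strictly increasing -> sxx > 0
    ss_res = ss_tot - slope * slope * sxx
    ss_res = max(ss_res, 0.0)
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        # all-constant trace: slope 0 and r2 defined as 0 by convention
        r2 = 0.0
    resid_sd = np.sqrt(ss_res / (n - 2)) if n > 2 else 0.0
    intercept = (sy - slope * st) / n
    return slope, intercept, r2, resid_sd, n


def find_linear_window(trace: OxygenTrace, cfg: WindowConfig | None = None) -> WindowFit:
    """Select the best linear segment of a trace and return its OLS fit.

    All contiguous windows aligned to sample points whose span lies in
    ``[min_minutes, max_minutes]`` are enumerated; the window maximizing
    r-squared (or minimizing residual SD) wins, ties broken toward the
    latest-starting, then longest, window.  Traces shorter than
    ``max_minutes`` have the admissible range clamped to the trace length;
    traces barely longer than ``min_minutes`` fall back to the whole trace
    with a warning.
    """
    cfg = cfg or WindowConfig()
    t = trace.times
    y = trace.o2
    dur_s = trace.duration_s
    min_s = cfg.min_minutes * 60.0
    max_s = cfg.max_minutes * 60.0
    if dur_s < min_s:
        raise InsufficientDataError(
            f"trace {trace.vial_id}: duration {dur_s / 60:.2f} min "
            f"< minimum window {cfg.min_minutes} min"
        )
    max_s = min(max_s, dur_s)

    if np.ptp(y) == 0:
        # all-constant trace: slope 0 with r2 defined as 0 by convention
        return WindowFit(0, len(t) - 1, 0.0, float(t[-1] - t[0]),
                         0.0, float(y[0]), 0.0, 0.0, len(t))

    t_h = (t - t[0]) / 3600.0
    pre = [
        np.concatenate(([0.0], np.cumsum(v)))
        for v in (t_h, t_h * t_h, y, y * y, t_h * y)
    ]
    t0 = t - t[0]

    median_dt = float(np.median(np.diff(t)))
    if dur_s < min_s + 2 * median_dt:
        warnings.warn(
            f"trace {trace.vial_id}: barely exceeds the minimum window; "
            "using the whole trace",
            stacklevel=2,
        )
        stats = _window_stats(t_h, y, 0, len(t) - 1, pre)
        return WindowFit(0, len(t) - 1, float(t0[0]), float(t0[-1]), *stats[:4], stats[4])

    best = None
    best_key = None
    n = len(t)
    for i in range(n):
        lo = np.searchsorted(t0, t0[i] + min_s, side="left")
        hi = np.searchsorted(t0, t0[i] + max_s, side="right") - 1
        for j in range(max(lo, i + 1), hi + 1):
            slope, intercept, r2, resid_sd, m = _window_stats(t_h, y, i, j, pre)
            crit = r2 if cfg.criterion == "max_r2" else -resid_sd
            key = (crit, i, j)  # ties -> latest start, then longest
            if best_key is None or key > best_key:
                best_key = key
                best = WindowFit(
                    i, j, float(t0[i]), float(t0[j]), slope, intercept, r2, resid_sd, m
                )
    if best is None:  # pragma: no cover - guarded by duration check
        raise InsufficientDataError(f"trace {trace.vial_id}: no admissible window")
    logger.debug(
        "trace %s: window [%.0f, %.0f] s slope=%.5g r2=%.5f",
        trace.vial_id, best.start_s, best.end_s, best.slope_mg_l_h, best.r2,
    )
    return best


@dataclass(frozen=True)
class Mo2Inputs:
    """Symbols of the closed-chamber MO2 equation."""

    o2_a: float  # initial O2, mg L-1
    o2_b: float  # final O2, mg L-1
    volume_l: float  # chamber volume minus embryo-displaced volume
    elapsed_h: float
    mass_g: float  # wet weight

    def __post_init__(self) -> None:
        if self.volume_l <= 0:
            raise DomainError("volume must be positive")
        if self.elapsed_h <= 0:
            raise DomainError("elapsed time must be positive")
        if self.mass_g <= 0:
            raise DomainError("mass must be positive")


def compute_mo2(inputs: Mo2Inputs) -> float:
    """MO2 = (O2_A - O2_B) * (V / t) / M, in mg O2 h-1 g-1 wet weight.

    A negative result (net O2 production) is allowed but logged: it
    indicates a blank/sensor artefact rather than biology.
    """
    mo2 = (inputs.o2_a - inputs.o2_b) * (inputs.volume_l / inputs.elapsed_h) / inputs.mass_g
    if mo2 < 0:
        logger.warning("negative MO2 (%.4g): apparent O2 production", mo2)
    return mo2


def blank_correct(
    embryo_slope: float,
    blank_slopes,
    *,
    require_blanks: bool = False,
) -> tuple[float, float]:
    """Subtract the mean blank-vial slope from an embryo-vial slope.

    Returns ``(corrected_slope, correction)`` where
    ``correction = mean(blank_slopes)``.  With no blanks the slope passes
    through unchanged with a warning (or raises if ``require_blanks``).
    """
    blank_slopes = list(blank_slopes)
    if not blank_slopes:
        if require_blanks:
            raise InsufficientDataError("no blank slopes available")
        warnings.warn("no blank slopes: returning uncorrected slope", stacklevel=2)
        return float(embryo_slope), 0.0
    correction = float(np.mean(blank_slopes))
    return float(embryo_slope) - correction, correction


def q10(rate1: float, t1: float, rate2: float, t2: float) -> float:
    """Q10 temperature coefficient: (rate2/rate1) ** (10 / (t2 - t1))."""
    if rate1 <= 0 or rate2 <= 0:
        raise DomainError("rates must be positive")
    if t1 == t2:
        raise DomainError("temperatures must differ")
    return float((rate2 / rate1) ** (10.0 / (t2 - t1)))


def effective_volume_l(
    chamber_volume_l: float,
    mass_g: float,
    density_g_per_ml: float = TISSUE_DENSITY_G_PER_ML,
) -> float:
    """Chamber volume minus embryo-displaced volume (density ~1 g mL-1)."""
    v = chamber_volume_l - (mass_g / density_g_per_ml) * 1e-3
    if v <= 0:
        raise DomainError("embryo displaces the whole chamber volume")
    return v


def process_run(
    traces,
    cohort: pd.DataFrame,
    cfg: WindowConfig | None = None,
    *,
    blank_correction: bool = True,
    require_blanks: bool = False,
    tissue_density: float = TISSUE_DENSITY_G_PER_ML,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process a respirometry run into a table of metabolic rates.

    Blank vials are fitted with the same window selection and averaged per
    temperature.  Each embryo vial is matched to the cohort table by
    ``embryo_id``; unmatched or massless vials go to the rejects report and
    the run continues.

    Returns ``(rates, rejects)`` data frames.  Rates carry per-embryo
    (mg O2 h-1 embryo-1) and mass-specific (mg O2 h-1 g-1) MO2 plus full
    window/blank provenance.
    """
    cfg = cfg or WindowConfig()
    cohort = cohort.set_index("embryo_id", drop=False) if "embryo_id" in cohort else cohort

    # blank slopes come from the whole trace: window selection on a nearly
    # flat noisy trace would systematically pick the steepest spurious
    # segment and bias the correction
    blank_slopes_by_temp: dict[float, list[float]] = {}
    for tr in traces:
        if tr.is_blank:
            slope = float(np.polyfit(tr.times / 3600.0, tr.o2, 1)[0])
            blank_slopes_by_temp.setdefault(tr.temperature, []).append(slope)

    rows = []
    rejects = []
    for tr in traces:
        if tr.is_blank:
            continue
        if tr.embryo_id is None or tr.embryo_id not in cohort.index:
            rejects.append({"vial_id": tr.vial_id, "embryo_id": tr.embryo_id,
                            "reason": "no matching cohort row"})
            continue
        row = cohort.loc[tr.embryo_id]
        mass_mg = float(row["embryo_ww_mg"])
        if not mass_mg > 0:
            rejects.append({"vial_id": tr.vial_id, "embryo_id": tr.embryo_id,
                            "reason": "non-positive embryo wet weight"})
            continue
        mass_g = mass_mg / 1000.0

        fit = find_linear_window(tr, cfg)
        blanks = blank_slopes_by_temp.get(tr.temperature, [])
        if blank_correction:
            slope, correction = blank_correct(
                fit.slope_mg_l_h, blanks, require_blanks=require_blanks
            )
        else:
            slope, correction = fit.slope_mg_l_h, 0.0

        v_eff = effective_volume_l(tr.chamber_volume_l, mass_g, tissue_density)
        elapsed_h = (fit.end_s - fit.start_s) / 3600.0
        # fitted endpoints shifted by the blank correction, so the MO2
        # equation is evaluated on the corrected decline
        o2_a, _ = fit.fitted_endpoints()
        o2_b = o2_a + slope * elapsed_h
        mo2_specific = compute_mo2(
            Mo2Inputs(o2_a=o2_a, o2_b=o2_b, volume_l=v_eff,
                      elapsed_h=elapsed_h, mass_g=mass_g)
        )
        rows.append({
            "embryo_id": tr.embryo_id,
            "vial_id": tr.vial_id,
            "stage": int(row["stage"]),
            "phase": row.get("phase", ""),
            "temperature": tr.temperature,
            "temperature_class": temperature_class(tr.temperature),
            "mass_g": mass_g,
            "mo2_per_embryo": mo2_specific * mass_g,
            "mo2_specific": mo2_specific,
            "window_start_s": fit.start_s,
            "window_end_s": fit.end_s,
            "window_r2": fit.r2,
            "raw_slope_mg_l_h": fit.slope_mg_l_h,
            "blank_correction_mg_l_h": correction,
            "blank_corrected": blank_correction and bool(blanks),
            "n_blanks": len(blanks),
        })
    rates = pd.DataFrame(rows)
    rejects_df = pd.DataFrame(rejects, columns=["vial_id", "embryo_id", "reason"])
    if not rejects_df.empty:
        logger.warning("%d vials rejected", len(rejects_df))
    return rates, rejects_df
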