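"""Oxidative-stress biomarker profiles.

Normalization (per mg tissue / per mg protein), group summaries across
ovary (OV), un-spawned eggs (USE) and embryo stages, and bootstrap
fold-ratios between groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

logger = logging.getLogger(__name__)

ANALYTES = ("SOD", "CAT", "GST", "GSH", "LPO", "PO")
TISSUES = ("OV", "USE", "embryo")

PER_MG_TISSUE = "per-mg-tissue"
PER_MG_PROTEIN = "per-mg-protein"


def normalize(value: float, basis: str, *, protein_mg: float | None = None,
              tissue_mg: float | None = None) -> float:
    """Divide a raw value by its normalization denominator."""
    if value < 0:
        raise DomainError("biomarker values must be non-negative")
    if basis == PER_MG_PROTEIN:
        denom = protein_mg
        what = "protein_mg"
    elif basis == PER_MG_TISSUE:
        denom = tissue_mg
        what = "tissue_mg"
    else:
        raise DomainError(f"unknown basis {basis!r}")
    if denom is None:
        raise DomainError(f"{what} required for basis {basis!r}")
    if denom <= 0:
        raise DomainError(f"{what} must be positive")
    return value / denom


def denormalize(value: float, basis: str, *, protein_mg: float | None = None,
                tissue_mg: float | None = None) -> float:
    """Inverse of :func:`normalize`."""
    denom = protein_mg if basis == PER_MG_PROTEIN else tissue_mg
    if denom is None or denom <= 0:
        raise DomainError("positive denominator required")
    return value * denom


def _group_label(row) -> str:
    if row["tissue"] in ("OV", "USE"):
        return str(row["tissue"])
    return str(int(row["stage"]))


def _group_sort_key(label: str):
    # OV first, USE second, then stages ascending
    order = {"OV": (0, 0), "USE": (1, 0)}
    if label in order:
        return order[label]
    return (2, int(label))


def stage_profile(table: pd.DataFrame, analyte: str) -> pd.DataFrame:
    """Per-group mean/SD/n of one analyte, groups ordered OV, USE, stages.

    SD uses the n-1 denominator and is reported as null (NaN) for
    single-observation groups. Empty groups are simply absent.
    """
    df = table[table["analyte"] == analyte].copy()
    if df.empty:
        raise DomainError(f"no measurements for analyte {analyte!r}")
    bad = df["tissue"].eq("embryo") & df["stage"].isna()
    if bad.any():
        raise DomainError("embryo measurements must carry a stage")
    df["group"] = df.apply(_group_label, axis=1)
    rows = []
    for group, sub in df.groupby("group"):
        vals = sub["value"].to_numpy(float)
        rows.append({
            "analyte": analyte,
            "group": group,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            "n": len(vals),
        })
    rows.sort(key=lambda r: _group_sort_key(r["group"]))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FoldRatio:
    analyte: str
    group_a: str
    group_b: str
    ratio: float
    ci_low: float
    ci_high: float
    n_boot: int


def fold_ratio(
    table: pd.DataFrame,
    analyte: str,
    group_a: str,
    group_b: str,
    *,
    n_boot: int = 2000,
    ci: float = 0.95,
    seed: int = 0,
) -> FoldRatio:
    """mean(group_a) / mean(group_b) with a seeded percentile-bootstrap CI."""
    df = table[table["analyte"] == analyte].copy()
    df["group"] = df.apply(_group_label, axis=1)
    a = df.loc[df["group"] == str(group_a), "value"].to_numpy(float)
    b = df.loc[df["group"] == str(group_b), "value"].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise DomainError("both groups need at least one measurement")
    if b.mean() <= 0 or a.mean() <= 0:
        raise DomainError("group means must be positive for a fold ratio")

    ratio = float(a.mean() / b.mean())
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    boot = a[ia].mean(axis=1) / b[ib].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return FoldRatio(analyte, str(group_a), str(group_b), ratio,
                     float(lo), float(hi), n_boot)


def all_profiles(table: pd.DataFrame) -> pd.DataFrame:
    """stage_profile for every analyte present, concatenated."""
    frames = [stage_profile(table, a) for a in sorted(table["analyte"].unique())]
    return pd.concat(frames, ignore_index=True)
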