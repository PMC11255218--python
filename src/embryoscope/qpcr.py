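"""Efficiency-corrected relative qPCR expression.

Standard-curve amplification efficiency from serial dilutions

    E = -1 + 10 ** (-1 / slope)

relative quantities RQ = (1+E) ** (Cq_cal - Cq), normalization factors as
the geometric mean of reference-gene RQs, normalized relative quantities
NRQ = RQ / NF reported on the natural-log scale, reference-gene stability
ranking (pairwise log-ratio SD and delta-Ct SD, combined by geometric mean
of ranks), and one-way stage/phase comparisons of ln NRQ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_GENES = ("TufM", "GPAM")

#: efficiencies outside this band trigger a warning, not an error
EFFICIENCY_WARN_BAND = (0.80, 1.10)


@dataclass(frozen=True)
class EfficiencyEstimate:
    gene: str
    slope: float  # cycles per log10 input
    e_fraction: float
    r2: float
    n_points: int
    valid: bool = True

    @property
    def e_percent(self) -> float:
        return 100.0 * self.e_fraction

    @property
    def e_percent_rounded(self) -> float:
        """Reporting convention: one decimal; full precision kept internally."""
        return round(self.e_percent, 1)


def efficiency_from_slope(slope: float, gene: str = "", *, r2: float = np.nan,
                          n_points: int = 0) -> EfficiencyEstimate:
    """E = -1 + 10 ** (-1/slope). Positive slopes yield an invalid estimate."""
    if slope == 0:
        raise DomainError("zero standard-curve slope: efficiency undefined")
    e = -1.0 + 10.0 ** (-1.0 / slope)
    valid = slope < 0
    if not valid:
        warnings.warn(
            f"gene {gene or '?'}: positive standard-curve slope {slope:.4g}; "
            "efficiency estimate flagged invalid",
            stacklevel=2,
        )
    if valid and not EFFICIENCY_WARN_BAND[0] <= e <= EFFICIENCY_WARN_BAND[1]:
        warnings.warn(
            f"gene {gene or '?'}: amplification efficiency {100 * e:.1f}% "
            "outside the 80-110% band",
            stacklevel=2,
        )
    return EfficiencyEstimate(gene=gene, slope=float(slope), e_fraction=float(e),
                              r2=float(r2), n_points=n_points, valid=valid)


def efficiency_from_dilution(series: pd.DataFrame, gene: str | None = None) -> EfficiencyEstimate:
    """Efficiency from a dilution-series table (columns gene, log10_input, rep, cq).

    Technical replicates are averaged per input level, then the slope is the
    OLS slope of mean Cq on log10 relative input.
    """
    df = series
    if gene is not None:
        df = df[df["gene"] == gene]
    elif df["gene"].nunique() == 1:
        gene = str(df["gene"].iloc[0])
    else:
        raise DomainError("series contains multiple genes; pass gene=")
    if df.empty:
        raise InsufficientDataError(f"no dilution points for gene {gene!r}")
    if np.any(df["cq"].to_numpy(float) <= 0):
        raise DomainError("Cq values must be positive")
    means = df.groupby("log10_input")["cq"].mean()
    if len(means) < 3:
        raise InsufficientDataError("need >=3 distinct dilution levels")
    x = means.index.to_numpy(float)
    y = means.to_numpy(float)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return efficiency_from_slope(float(slope), gene=gene, r2=r2, n_points=len(x))


def efficiencies_table(dilution: pd.DataFrame) -> pd.DataFrame:
    """EfficiencyEstimate for every gene in a long dilution table."""
    rows = []
    for gene in dilution["gene"].unique():
        est = efficiency_from_dilution(dilution, gene=gene)
        rows.append({
            "gene": est.gene, "slope": est.slope, "e_fraction": est.e_fraction,
            "e_percent": est.e_percent_rounded, "r2": est.r2,
            "n_points": est.n_points, "valid": est.valid,
        })
    return pd.DataFrame(rows)


def relative_quantity(cq, cq_cal, e_fraction: float):
    """RQ = (1+E) ** (Cq_cal - Cq)."""
    if e_fraction <= -1:
        raise DomainError("efficiency fraction must exceed -1")
    return (1.0 + e_fraction) ** (np.asarray(cq_cal, dtype=float) - np.asarray(cq, dtype=float))


def normalization_factor(ref_rqs) -> float:
    """Geometric mean of a sample's reference-gene relative quantities."""
    rqs = np.asarray(list(ref_rqs), dtype=float)
    if len(rqs) == 0:
        raise DomainError("need at least one reference RQ")
    if np.any(rqs <= 0):
        raise DomainError("reference RQs must be positive")
    return float(np.exp(np.mean(np.log(rqs))))


def collapse_replicates(cq_long: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of technical-replicate Cq per sample x gene.

    All downstream math runs on these means. Missing Cq values are dropped
    with a warning.
    """
    df = cq_long.copy()
    n_missing = int(df["cq"].isna().sum())
    if n_missing:
        warnings.warn(f"dropping {n_missing} missing Cq readings", stacklevel=2)
        df = df.dropna(subset=["cq"])
    keys = [c for c in ("sample_id", "stage", "phase", "gene", "is_reference")
            if c in df.columns]
    return df.groupby(keys, as_index=False, sort=False)["cq"].mean()


def normalized_expression(
    cq_long: pd.DataFrame,
    efficiencies: dict[str, float] | None = None,
    reference_genes=DEFAULT_REFERENCE_GENES,
    calibrator: str = "gene-mean",
) -> pd.DataFrame:
    """Hellemans-style normalized relative quantities.

    Per gene: RQ = (1+E) ** (Cq_cal - Cq) with the calibrator Cq being the
    gene's mean Cq across samples (default) or a named calibrator sample.
    Per sample: NF = geometric mean of the reference-gene RQs, and
    NRQ = RQ / NF, reported with its natural log (per-group summaries
    should stay on the ln scale; they are not back-transformable).
    """
    df = collapse_replicates(cq_long)
    genes = list(df["gene"].unique())
    reference_genes = [g for g in reference_genes if g in genes]
    if not reference_genes:
        raise DomainError("no reference genes present in the Cq table")
    if efficiencies is None:
        warnings.warn("no efficiencies supplied: assuming E=1 for all genes",
                      stacklevel=2)
        efficiencies = {g: 1.0 for g in genes}
    missing_e = [g for g in genes if g not in efficiencies]
    if missing_e:
        raise DomainError(f"missing efficiencies for genes: {missing_e}")

    wide = df.pivot_table(index="sample_id", columns="gene", values="cq")
    meta_cols = [c for c in ("stage", "phase") if c in df.columns]
    meta = df.drop_duplicates("sample_id").set_index("sample_id")[meta_cols]

    incomplete = wide[reference_genes].isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"dropping {int(incomplete.sum())} samples lacking a reference-gene Cq",
            stacklevel=2,
        )
        wide = wide[~incomplete]

    rq = pd.DataFrame(index=wide.index, columns=genes, dtype=float)
    for gene in genes:
        cq = wide[gene]
        if calibrator == "gene-mean":
            cq_cal = cq.mean()
        else:
            if calibrator not in wide.index:
                raise DomainError(f"calibrator sample {calibrator!r} not found")
            cq_cal = wide.loc[calibrator, gene]
        rq[gene] = relative_quantity(cq, cq_cal, efficiencies[gene])

    nf = np.exp(np.mean(np.log(rq[reference_genes]), axis=1))

    out = []
    for gene in genes:
        sub = pd.DataFrame({
            "sample_id": wide.index,
            "gene": gene,
            "is_reference": gene in reference_genes,
            "rq": rq[gene].to_numpy(),
            "nf": nf.to_numpy(),
        })
        out.append(sub)
    expr = pd.concat(out, ignore_index=True).dropna(subset=["rq"])
    expr["nrq"] = expr["rq"] / expr["nf"]
    expr["ln_nrq"] = np.log(expr["nrq"])
    expr = expr.merge(meta, left_on="sample_id", right_index=True, how="left")
    return expr


def reference_stability(
    cq_long: pd.DataFrame,
    candidates=None,
    efficiencies: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Rank candidate reference genes by expression stability.

    Two published components are combined: a geNorm-style M value (mean,
    over partner genes, of the SD of the pairwise log2 expression ratio)
    and the mean SD of pairwise delta-Ct.  The combined rank is the
    geometric mean of the two component ranks; smaller = more stable.
    This approximates the closed RefFinder web tool.
    """
    df = collapse_replicates(cq_long)
    if candidates is None:
        if "is_reference" in df.columns:
            candidates = sorted(df.loc[df["is_reference"].astype(bool), "gene"].unique())
        else:
            candidates = sorted(df["gene"].unique())
    candidates = list(candidates)
    if len(candidates) < 3:
        raise InsufficientDataError("need >=3 candidate reference genes")
    wide = df[df["gene"].isin(candidates)].pivot_table(
        index="sample_id", columns="gene", values="cq"
    )[candidates].dropna()
    if len(wide) < 8:
        raise InsufficientDataError("need >=8 samples with complete Cq data")

    eff = {g: (efficiencies or {}).get(g, 1.0) for g in candidates}
    # log2 relative quantity up to a per-gene constant (which cancels in SDs)
    log2q = pd.DataFrame({
        g: -wide[g].to_numpy(float) * np.log2(1.0 + eff[g]) for g in candidates
    }, index=wide.index)

    rows = []
    for g in candidates:
        ratio_sds = []
        dct_sds = []
        for h in candidates:
            if h == g:
                continue
            ratio_sds.append(float((log2q[g] - log2q[h]).std(ddof=1)))
            dct_sds.append(float((wide[g] - wide[h]).std(ddof=1)))
        rows.append({
            "gene": g,
            "genorm_m": float(np.mean(ratio_sds)),
            "deltact_sd": float(np.mean(dct_sds)),
        })
    out = pd.DataFrame(rows)
    out["rank_genorm"] = out["genorm_m"].rank(method="average")
    out["rank_deltact"] = out["deltact_sd"].rank(method="average")
    out["combined"] = np.sqrt(out["rank_genorm"] * out["rank_deltact"])
    out = out.sort_values(["combined", "genorm_m", "gene"], kind="stable",
                          ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class StageComparison:
    gene: str
    method: str
    statistic: float
    p_value: float
    group_sizes: dict
    pairwise: pd.DataFrame | None = None
    note: str = ""

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < 0.05)


def stage_comparison(
    expr: pd.DataFrame,
    gene: str,
    group_col: str = "phase",
    *,
    method: str = "anova",
    pairwise: bool = False,
) -> StageComparison:
    """Omnibus comparison of ln NRQ across developmental groups.

    One-way ANOVA by default (Kruskal-Wallis available); Tukey HSD pairwise
    comparisons on request.  Fully degenerate data (zero variance
    everywhere) is reported as no-evidence rather than an error.
    """
    df = expr[expr["gene"] == gene].dropna(subset=["ln_nrq", group_col])
    groups = [sub["ln_nrq"].to_numpy(float) for _, sub in df.groupby(group_col)]
    sizes = {str(k): len(sub) for k, sub in df.groupby(group_col)}
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DomainError("need >=2 groups with >=2 samples each")

    values = np.concatenate(groups)
    if np.ptp(values) == 0:
        return StageComparison(gene, method, np.nan, np.nan, sizes,
                               note="degenerate: zero variance; no evidence either way")

    if method == "anova":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            stat, p = stats.f_oneway(*groups)
    elif method == "kruskal":
        stat, p = stats.kruskal(*groups)
    else:
        raise DomainError(f"unknown method {method!r}")

    pw = None
    if pairwise:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        res = pairwise_tukeyhsd(df["ln_nrq"].to_numpy(float),
                                df[group_col].astype(str).to_numpy())
        pw = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return StageComparison(gene, method, float(stat), float(p), sizes, pw)
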