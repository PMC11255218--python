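"""Seeded synthetic-data generators with known ground truth.

Emulates every pipeline input: an embryo cohort with exponential
stage-weight growth and stage-increasing lognormal scatter, closed-chamber
oxygen-depletion traces (embryo + blank vials, optional settling
transient), qPCR dilution series and sample Cq matrices with designed
efficiencies and stage fold-changes, and biomarker tables with designed
group profiles.  Every generator returns the ground truth needed to score
the downstream estimators, and a fixed seed yields byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .respirometry import OxygenTrace, effective_volume_l
from .staging import PHASE_STAGES, PHASE_ORDER, phase_for_stage, validate_stage

# independent deterministic RNG streams per generator
_STREAM_COHORT = 0
_STREAM_TRACES = 1
_STREAM_QPCR = 2
_STREAM_BIOMARKERS = 3


@dataclass(frozen=True)
class GeneSpec:
    """Designed truth for one qPCR assay."""

    name: str
    efficiency: float = 1.0  # fraction E
    base_cq: float = 20.0
    #: designed log2 quantity offset per developmental phase (targets only)
    phase_log2: dict = field(default_factory=dict)
    #: gene-specific instability (log2 quantity SD) beyond Cq noise
    wobble_sd_log2: float = 0.0
    cq_noise_sd: float | None = None  # None -> config default
    is_reference: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.efficiency <= 1.2:
            raise ConfigurationError(
                f"gene {self.name}: efficiency must be in (0, 1.2]"
            )
        if self.wobble_sd_log2 < 0 or (self.cq_noise_sd or 0) < 0:
            raise ConfigurationError(f"gene {self.name}: SDs must be >= 0")


@dataclass(frozen=True)
class AnalyteSpec:
    """Designed group profile for one biomarker analyte."""

    name: str
    unit: str
    profile: dict  # group ("OV"/"USE"/stage int) -> mean
    sd: float | dict = 0.0
    n_per_group: int = 5

    def sd_for(self, group) -> float:
        if isinstance(self.sd, dict):
            return float(self.sd.get(group, 0.0))
        return float(self.sd)


def default_gene_panel(cq_noise_sd: float | None = None) -> tuple[GeneSpec, ...]:
    """Eight-gene panel mirroring the study design: two designed-stable
    references, two wobblier reference candidates, four stage-varying
    targets with efficiencies spanning the reported 82.3-106.6% range."""
    return (
        GeneSpec("TufM", efficiency=0.885, base_cq=19.0, is_reference=True),
        GeneSpec("GPAM", efficiency=0.908, base_cq=21.0, is_reference=True),
        GeneSpec("EF1b", efficiency=0.991, base_cq=18.0, is_reference=True,
                 wobble_sd_log2=0.4),
        GeneSpec("hnRNP", efficiency=0.974, base_cq=20.5, is_reference=True,
                 wobble_sd_log2=0.6),
        GeneSpec("CAT", efficiency=0.823, base_cq=24.0,
                 phase_log2={"blastulation": 0.0, "organogenesis": 0.5,
                             "activation": 1.0, "growth": 1.5}),
        GeneSpec("MnSOD", efficiency=1.066, base_cq=23.0,
                 phase_log2={"blastulation": 0.0, "organogenesis": 0.8,
                             "activation": 1.5, "growth": 2.2}),
        GeneSpec("SOD", efficiency=0.905, base_cq=22.0,
                 phase_log2={"blastulation": 0.5, "organogenesis": 1.2,
                             "activation": 0.8, "growth": 0.3}),
        GeneSpec("HIF1A", efficiency=0.905, base_cq=25.0,
                 phase_log2={"blastulation": 0.0, "organogenesis": 1.2,
                             "activation": 1.0, "growth": 0.8}),
    )


def default_analyte_panel(stages) -> tuple[AnalyteSpec, ...]:
    """Profiles shaped like the reported figures: enzyme activities high in
    ovary (SOD ~350x, CAT ~150x the un-spawned eggs), rising from the
    activation phase in embryos; GSH flat; oxidative damage (LPO, PO) high
    early and below 0.5 nmol mg-1 just before hatch."""
    stages = sorted(int(s) for s in stages)

    def ramp(lo, hi, onset=14):
        prof = {}
        for s in stages:
            if s < onset:
                prof[s] = lo
            else:
                frac = (s - onset + 1) / (max(stages) - onset + 1)
                prof[s] = lo + (hi - lo) * frac
        return prof

    def decline(hi, lo, knee=12):
        prof = {}
        for s in stages:
            if s <= knee:
                prof[s] = hi
            else:
                frac = (s - knee) / (max(stages) - knee)
                prof[s] = hi + (lo - hi) * frac
        return prof

    return (
        AnalyteSpec("SOD", "U mg-1 protein",
                    {"OV": 350.0, "USE": 1.0, **ramp(1.0, 20.0)}, sd=0.0),
        AnalyteSpec("CAT", "U mg-1 protein",
                    {"OV": 150.0, "USE": 1.0, **ramp(1.0, 12.0)}, sd=0.0),
        AnalyteSpec("GST", "U mg-1 protein",
                    {"OV": 8.0, "USE": 2.0, **ramp(2.0, 10.0)}, sd=0.0),
        AnalyteSpec("GSH", "nmol mg-1 tissue",
                    {"OV": 0.15, "USE": 0.15,
                     **{s: 0.15 for s in stages}}, sd=0.0),
        AnalyteSpec("LPO", "nmol mg-1 tissue",
                    {"OV": 4.0, "USE": 3.5, **decline(3.0, 0.3)}, sd=0.0),
        AnalyteSpec("PO", "nmol mg-1 tissue",
                    {"OV": 5.0, "USE": 4.0, **decline(3.5, 0.4)}, sd=0.0),
    )


def default_mo2_profile(temp_c: float, weight_g, peak_weight_g: float = 0.06):
    """Designed per-embryo MO2 truth (mg O2 h-1 embryo-1).

    A gentle linear rise with weight, scaled up with temperature, plus a
    Gaussian surge centred at the activation weight whose amplitude grows
    with temperature — so the high-minus-low scope curve peaks near the
    designed activation weight.
    """
    w = np.asarray(weight_g, dtype=float)
    # scaled so a 1.75 mL chamber starting at ~7.4 mg O2 L-1 depletes a
    # measurable but un-exhausted fraction over a 20-min trace
    base = 0.002 + 0.05 * w
    if abs(temp_c - 11.0) <= 1.0:
        scale, bump_amp = 1.0, 0.0
    elif abs(temp_c - 24.0) <= 1.0:
        scale, bump_amp = 1.45, 0.002
    elif abs(temp_c - 30.0) <= 1.0:
        scale, bump_amp = 1.6, 0.003
    else:
        scale = 2.0 ** ((temp_c - 11.0) / 10.0)
        bump_amp = 0.003 * max(0.0, min(1.0, (temp_c - 11.0) / 19.0))
    bump = np.exp(-((w - peak_weight_g) ** 2) / (2 * 0.015**2))
    return scale * base + bump_amp * bump


def designed_tms_peak_weight(config: "SimulationConfig",
                             low: float = 11.0, high: float = 30.0,
                             n_grid: int = 2001) -> float:
    """Argmax of the designed high-minus-low per-embryo MO2 truth over the
    cohort's noiseless weight range (the ground truth for scope recovery)."""
    w_lo = config.growth_a_mg * np.exp(config.growth_b * min(config.stages)) / 1000.0
    w_hi = config.growth_a_mg * np.exp(config.growth_b * max(config.stages)) / 1000.0
    grid = np.linspace(w_lo, w_hi, n_grid)
    profile = config.profile()
    tms = profile(high, grid) - profile(low, grid)
    return float(grid[int(np.argmax(tms))])


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort/trace/qPCR/biomarker generators."""

    seed: int = 0
    stages: tuple = tuple(range(10, 20))
    n_embryos_per_stage: int = 10

    # respirometry
    chamber_volume_ul: float = 1750.0
    interval_s: float = 15.0
    duration_min: float = 20.0
    o2_start: float = 7.4  # mg L-1
    noise_sd_o2: float = 0.0  # mg L-1
    blank_drift: float = 0.02  # background O2 decline, mg L-1 h-1
    n_blanks: int = 3
    temperatures: tuple = (11.0, 30.0)
    transient_amp: float = 0.0  # mg L-1 added at t=0, decays exponentially
    transient_tau_s: float = 60.0
    tms_peak_weight_g: float = 0.06
    mo2_profile: object = None  # callable (temp_c, weight_g) -> mg O2 h-1 embryo-1

    # growth truth
    growth_a_mg: float = 1.5
    growth_b: float = 0.22
    egg_a_mg: float = 55.0
    egg_b: float = 0.07
    weight_sigma0: float = 0.0  # lognormal sigma at the first stage
    weight_sigma_slope: float = 0.0  # increase per stage (>= 0)

    # qPCR truth
    genes: tuple = None
    qpcr_n_per_phase: int = 10
    qpcr_reps: int = 3
    dilution_levels: int = 5
    dilution_factor: float = 5.0
    dilution_reps: int = 3
    cq_noise_sd: float = 0.0
    loading_sd_log2: float = 0.0  # per-sample input-amount scatter

    # biomarker truth
    analytes: tuple = None

    def __post_init__(self) -> None:
        self.stages = tuple(validate_stage(s) for s in self.stages)
        if self.n_embryos_per_stage < 1:
            raise ConfigurationError("n_embryos_per_stage must be >= 1")
        if self.chamber_volume_ul <= 0 or self.interval_s <= 0:
            raise ConfigurationError("volumes and intervals must be positive")
        if self.duration_min <= 0:
            raise ConfigurationError("trace duration must be positive")
        for name in ("noise_sd_o2", "weight_sigma0", "weight_sigma_slope",
                     "cq_noise_sd", "loading_sd_log2"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.genes is None:
            self.genes = default_gene_panel()
        if self.analytes is None:
            self.analytes = default_analyte_panel(self.stages)

    def profile(self):
        if self.mo2_profile is not None:
            return self.mo2_profile
        return lambda t, w: default_mo2_profile(t, w, self.tms_peak_weight_g)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def weight_sigma(self, stage: int) -> float:
        return self.weight_sigma0 + self.weight_sigma_slope * (stage - min(self.stages))

    # -- YAML round trip (callable profile and panels use defaults on load) --

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d.pop("mo2_profile")
        d["genes"] = [asdict(g) for g in self.genes]
        d["analytes"] = [asdict(a) for a in self.analytes]
        d["stages"] = list(self.stages)
        d["temperatures"] = list(self.temperatures)
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, text_or_path: str) -> "SimulationConfig":
        try:
            with open(text_or_path) as fh:
                d = yaml.safe_load(fh)
        except (OSError, ValueError):
            d = yaml.safe_load(text_or_path)
        if "genes" in d and d["genes"] is not None:
            d["genes"] = tuple(GeneSpec(**g) for g in d["genes"])
        if "analytes" in d and d["analytes"] is not None:
            d["analytes"] = tuple(AnalyteSpec(**a) for a in d["analytes"])
        for key in ("stages", "temperatures"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Embryo metadata table plus growth ground truth.

    Wet weight per embryo is a*exp(b*stage)*exp(eps) with
    eps ~ Normal(0, sigma(stage)), sigma non-decreasing in stage.
    """
    rng = config.rng(_STREAM_COHORT)
    rows = []
    for stage in config.stages:
        sigma = config.weight_sigma(stage)
        for i in range(config.n_embryos_per_stage):
            eps_embryo = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            eps_egg = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            rows.append({
                "embryo_id": f"E{stage:02d}-{i:03d}",
                "stage": stage,
                "phase": phase_for_stage(stage),
                "egg_ww_mg": config.egg_a_mg * np.exp(config.egg_b * stage + eps_egg),
                "embryo_ww_mg": config.growth_a_mg * np.exp(config.growth_b * stage + eps_embryo),
            })
    cohort = pd.DataFrame(rows)
    truth = pd.DataFrame([
        {"subject": "embryo", "a_mg": config.growth_a_mg, "b_per_stage": config.growth_b,
         "sigma0": config.weight_sigma0, "sigma_slope": config.weight_sigma_slope},
        {"subject": "egg", "a_mg": config.egg_a_mg, "b_per_stage": config.egg_b,
         "sigma0": config.weight_sigma0, "sigma_slope": config.weight_sigma_slope},
    ])
    return cohort, truth


def generate_traces(
    cohort: pd.DataFrame, config: SimulationConfig
) -> tuple[list[OxygenTrace], pd.DataFrame]:
    """Oxygen traces for every embryo at every configured temperature, plus
    blank vials and a per-vial ground-truth table.

    Embryo vials decline at trueMO2*M/V_eff + blank_drift (mg L-1 h-1) with
    optional exponential settling transient and Gaussian sensor noise; blank
    vials carry drift and noise only.  O2 is truncated at zero with a warning.
    """
    rng = config.rng(_STREAM_TRACES)
    times = np.arange(0.0, config.duration_min * 60.0 + config.interval_s / 2,
                      config.interval_s)
    if len(times) < 2:
        raise ConfigurationError("duration/interval give fewer than 2 samples")
    t_h = times / 3600.0
    v_chamber_l = config.chamber_volume_ul * 1e-6
    profile = config.profile()

    traces: list[OxygenTrace] = []
    truth_rows = []
    clipped = 0
    for temp in config.temperatures:
        for _, row in cohort.iterrows():
            mass_g = float(row["embryo_ww_mg"]) / 1000.0
            v_eff = effective_volume_l(v_chamber_l, mass_g)
            mo2_emb = float(profile(temp, mass_g))  # mg O2 h-1 embryo-1
            rate = mo2_emb / v_eff + config.blank_drift  # mg L-1 h-1
            o2 = config.o2_start - rate * t_h
            if config.transient_amp:
                o2 = o2 + config.transient_amp * np.exp(-times / config.transient_tau_s)
            if config.noise_sd_o2 > 0:
                o2 = o2 + rng.normal(0.0, config.noise_sd_o2, len(times))
            if np.any(o2 < 0):
                clipped += 1
                o2 = np.clip(o2, 0.0, None)
            vial_id = f"V{temp:g}-{row['embryo_id']}"
            traces.append(OxygenTrace(
                vial_id=vial_id, times=times.copy(), o2=o2, temperature=float(temp),
                chamber_volume_l=v_chamber_l, is_blank=False,
                embryo_id=str(row["embryo_id"]),
            ))
            truth_rows.append({
                "vial_id": vial_id, "embryo_id": row["embryo_id"],
                "temperature": float(temp), "mass_g": mass_g,
                "true_mo2_per_embryo": mo2_emb,
                "true_mo2_specific": mo2_emb / mass_g,
                "blank_drift": config.blank_drift,
            })
        for k in range(config.n_blanks):
            o2 = config.o2_start - config.blank_drift * t_h
            if config.noise_sd_o2 > 0:
                o2 = o2 + rng.normal(0.0, config.noise_sd_o2, len(times))
            o2 = np.clip(o2, 0.0, None)
            traces.append(OxygenTrace(
                vial_id=f"B{temp:g}-{k:02d}", times=times.copy(), o2=o2,
                temperature=float(temp), chamber_volume_l=v_chamber_l,
                is_blank=True,
            ))
    if clipped:
        warnings.warn(f"{clipped} traces hit zero O2 and were truncated",
                      stacklevel=2)
    return traces, pd.DataFrame(truth_rows)


def _qpcr_cq(gene: GeneSpec, log2_quantity: float) -> float:
    # Cq = base - log_(1+E)(quantity)
    return gene.base_cq - log2_quantity * np.log(2.0) / np.log(1.0 + gene.efficiency)


def generate_qpcr(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Dilution-series table, sample Cq matrix (long) and truth table.

    Dilution Cq follows Cq = c0 - log_(1+E)(relative input) + noise; sample
    Cq encodes the designed per-phase fold-changes on the target genes, a
    shared per-sample loading offset (removed by normalization) and optional
    per-gene instability wobble.
    """
    rng = config.rng(_STREAM_QPCR)
    if config.dilution_levels < 3:
        raise ConfigurationError("need >=3 dilution levels")

    dil_rows = []
    for gene in config.genes:
        noise_sd = gene.cq_noise_sd if gene.cq_noise_sd is not None else config.cq_noise_sd
        for k in range(config.dilution_levels):
            log10_input = -k * np.log10(config.dilution_factor)
            log2_q = log10_input / np.log10(2.0)
            cq_true = _qpcr_cq(gene, log2_q)
            for rep in range(config.dilution_reps):
                cq = cq_true + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                dil_rows.append({"gene": gene.name, "log10_input": log10_input,
                                 "rep": rep + 1, "cq": cq})
    dilution = pd.DataFrame(dil_rows)

    phase_stages = {p: [s for s in config.stages if s in PHASE_STAGES[p]]
                    for p in PHASE_ORDER}
    cq_rows = []
    for phase in PHASE_ORDER:
        stages = phase_stages[phase] or [min(PHASE_STAGES[phase])]
        for i in range(config.qpcr_n_per_phase):
            sample_id = f"S-{phase[:4]}-{i:02d}"
            stage = stages[i % len(stages)]
            loading = (rng.normal(0.0, config.loading_sd_log2)
                       if config.loading_sd_log2 > 0 else 0.0)
            for gene in config.genes:
                noise_sd = (gene.cq_noise_sd if gene.cq_noise_sd is not None
                            else config.cq_noise_sd)
                wobble = (rng.normal(0.0, gene.wobble_sd_log2)
                          if gene.wobble_sd_log2 > 0 else 0.0)
                log2_q = gene.phase_log2.get(phase, 0.0) + loading + wobble
                cq_true = _qpcr_cq(gene, log2_q)
                for rep in range(config.qpcr_reps):
                    cq = cq_true + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    cq_rows.append({
                        "sample_id": sample_id, "stage": stage, "phase": phase,
                        "gene": gene.name, "rep": rep + 1, "cq": cq,
                        "is_reference": gene.is_reference,
                    })
    cq_matrix = pd.DataFrame(cq_rows)

    truth_rows = []
    for gene in config.genes:
        for phase in PHASE_ORDER:
            truth_rows.append({
                "gene": gene.name, "phase": phase,
                "true_log2_quantity": gene.phase_log2.get(phase, 0.0),
                "efficiency": gene.efficiency,
                "is_reference": gene.is_reference,
            })
    return dilution, cq_matrix, pd.DataFrame(truth_rows)


def generate_biomarkers(config: SimulationConfig) -> pd.DataFrame:
    """Biomarker table: values ~ Normal(designed group mean, SD), truncated
    at zero, with units carried through."""
    rng = config.rng(_STREAM_BIOMARKERS)
    rows = []
    for spec in config.analytes:
        for group, mean in spec.profile.items():
            sd = spec.sd_for(group)
            if group in ("OV", "USE"):
                tissue, stage = group, None
            else:
                tissue, stage = "embryo", validate_stage(group)
            for i in range(spec.n_per_group):
                value = float(mean) if sd == 0 else float(rng.normal(mean, sd))
                value = max(value, 0.0)
                rows.append({
                    "sample_id": f"{spec.name}-{group}-{i:02d}",
                    "tissue": tissue,
                    "stage": stage,
                    "analyte": spec.name,
                    "value": value,
                    "unit": spec.unit,
                    "protein_mg": 1.0,
                })
    return pd.DataFrame(rows)


def generate_all(config: SimulationConfig) -> dict:
    """Run every generator; returns a dict of tables/traces plus truth."""
    cohort, growth_truth = generate_cohort(config)
    traces, trace_truth = generate_traces(cohort, config)
    dilution, cq_matrix, qpcr_truth = generate_qpcr(config)
    biomarker_table = generate_biomarkers(config)
    return {
        "cohort": cohort,
        "growth_truth": growth_truth,
        "traces": traces,
        "trace_truth": trace_truth,
        "dilution": dilution,
        "cq_matrix": cq_matrix,
        "qpcr_truth": qpcr_truth,
        "biomarkers": biomarker_table,
    }
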