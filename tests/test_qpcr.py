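"""Tests for qPCR efficiency, Hellemans normalization, stability and ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from embryoscope.errors import DomainError, InsufficientDataError
from embryoscope.qpcr import (
    collapse_replicates,
    efficiency_from_dilution,
    efficiency_from_slope,
    normalization_factor,
    normalized_expression,
    reference_stability,
    relative_quantity,
    stage_comparison,
)
from embryoscope.synthetic import GeneSpec, SimulationConfig, generate_qpcr

# Printed worked examples: slope obtained by inverting the reported
# efficiency through slope = -1 / log10(1 + E).
TABLE1_CASES = [
    (-3.8346, 82.3),
    (-3.1733, 106.6),
    (-3.5728, 90.5),
    (-3.3426, 99.1),
]


def noiseless_panel(n_per_phase=4, fold_log2=None, genes=None):
    cfg = SimulationConfig(
        seed=1, stages=range(6, 20),
        genes=genes or (
            GeneSpec("RefA", efficiency=1.0, base_cq=19.0, is_reference=True),
            GeneSpec("RefB", efficiency=1.0, base_cq=21.0, is_reference=True),
            GeneSpec("Tgt", efficiency=1.0, base_cq=24.0,
                     phase_log2=fold_log2 or {"activation": 0.0, "growth": 1.0}),
        ),
        qpcr_n_per_phase=n_per_phase,
    )
    return generate_qpcr(cfg)


class TestEfficiency:
    def test_analytic_slope_gives_100_percent(self):
        est = efficiency_from_slope(-1.0 / math.log10(2.0))
        assert est.e_percent == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize("slope,expected", TABLE1_CASES)
    def test_printed_worked_examples(self, slope, expected):
        est = efficiency_from_slope(slope)
        assert est.e_percent_rounded == pytest.approx(expected, abs=0.05)

    def test_zero_slope_error(self):
        with pytest.raises(DomainError):
            efficiency_from_slope(0.0)

    def test_positive_slope_flagged_invalid(self):
        with pytest.warns(UserWarning, match="positive"):
            est = efficiency_from_slope(3.3)
        assert not est.valid

    def test_out_of_band_warns(self):
        with pytest.warns(UserWarning, match="80-110%"):
            efficiency_from_slope(-1.0 / math.log10(1.5))  # 50%

    def test_from_noiseless_dilution_series(self):
        cfg = SimulationConfig(seed=1, genes=(
            GeneSpec("G", efficiency=0.823, base_cq=24.0),))
        dilution, _, _ = generate_qpcr(cfg)
        est = efficiency_from_dilution(dilution, gene="G")
        assert est.e_fraction == pytest.approx(0.823, rel=1e-9)
        assert est.r2 == pytest.approx(1.0)

    def test_perfect_doubling_cq_step(self):
        """E=1, 1:5 dilution: Cq rises by log2(5) per step."""
        cfg = SimulationConfig(seed=1, genes=(
            GeneSpec("G", efficiency=1.0, base_cq=20.0),))
        dilution, _, _ = generate_qpcr(cfg)
        cq = dilution.groupby("log10_input")["cq"].mean().sort_index(ascending=False)
        steps = np.diff(cq.to_numpy())
        np.testing.assert_allclose(steps, math.log2(5.0), rtol=1e-12)

    def test_too_few_levels(self):
        df = pd.DataFrame({"gene": "G", "log10_input": [0.0, -0.7],
                           "rep": 1, "cq": [20.0, 22.3]})
        with pytest.raises(InsufficientDataError):
            efficiency_from_dilution(df, gene="G")

    @given(slope=st.floats(-5.0, -2.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_slope(self, slope):
        e = efficiency_from_slope(slope).e_fraction
        back = -1.0 / math.log10(1.0 + e)
        assert back == pytest.approx(slope, rel=1e-9)


class TestRelativeQuantity:
    def test_calibrator_is_one(self):
        assert relative_quantity(20.0, 20.0, 0.9) == 1.0

    def test_doubling(self):
        assert relative_quantity(17.0, 20.0, 1.0) == pytest.approx(8.0)

    def test_fractional_efficiency(self):
        assert relative_quantity(19.0, 20.0, 0.823) == pytest.approx(1.823)

    def test_invalid_efficiency(self):
        with pytest.raises(DomainError):
            relative_quantity(19.0, 20.0, -1.0)


class TestNormalizationFactor:
    def test_geometric_mean(self):
        assert normalization_factor([2.0, 8.0]) == pytest.approx(4.0)

    def test_single_ref(self):
        assert normalization_factor([3.0]) == pytest.approx(3.0)

    def test_all_ones(self):
        assert normalization_factor([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_nonpositive_error(self):
        with pytest.raises(DomainError):
            normalization_factor([1.0, 0.0])


class TestNormalizedExpression:
    def test_noiseless_two_fold_ln2_exact(self):
        _, cq, _ = noiseless_panel()
        expr = normalized_expression(cq, efficiencies=None,
                                     reference_genes=("RefA", "RefB"))
        tgt = expr[expr["gene"] == "Tgt"]
        means = tgt.groupby("phase")["ln_nrq"].mean()
        diff = means["growth"] - means["activation"]
        assert diff == pytest.approx(math.log(2.0), rel=1e-12)

    def test_constant_references_nf_constant(self):
        _, cq, _ = noiseless_panel()
        expr = normalized_expression(cq, reference_genes=("RefA", "RefB"))
        assert expr["nf"].nunique() == 1

    def test_cq_shift_invariance(self):
        """Adding a constant to every Cq of one gene leaves NRQ unchanged
        (the calibrator shifts identically)."""
        _, cq, _ = noiseless_panel()
        expr1 = normalized_expression(cq, reference_genes=("RefA", "RefB"))
        shifted = cq.copy()
        shifted.loc[shifted["gene"] == "Tgt", "cq"] += 2.5
        expr2 = normalized_expression(shifted, reference_genes=("RefA", "RefB"))
        t1 = expr1[expr1["gene"] == "Tgt"].set_index("sample_id")["nrq"]
        t2 = expr2[expr2["gene"] == "Tgt"].set_index("sample_id")["nrq"]
        np.testing.assert_allclose(t1, t2, rtol=1e-9)

    def test_missing_cq_drops_sample_with_warning(self):
        _, cq, _ = noiseless_panel()
        cq = cq.copy()
        cq.loc[(cq["sample_id"] == cq["sample_id"].iloc[0])
               & (cq["gene"] == "RefA"), "cq"] = np.nan
        with pytest.warns(UserWarning):
            expr = normalized_expression(cq, reference_genes=("RefA", "RefB"))
        assert cq["sample_id"].iloc[0] not in set(expr["sample_id"])

    def test_matches_ddct_with_unit_efficiencies(self, rng):
        """Equivalence oracle: with E=1 and reference genes, NRQ reproduces
        the classic ddCt computation on random small matrices."""
        samples = [f"s{i}" for i in range(6)]
        genes = ["R1", "R2", "T"]
        cq_vals = {g: rng.uniform(18, 26, 6) for g in genes}
        rows = [{"sample_id": s, "stage": 10, "phase": "organogenesis",
                 "gene": g, "rep": 1, "cq": cq_vals[g][i],
                 "is_reference": g != "T"}
                for g in genes for i, s in enumerate(samples)]
        expr = normalized_expression(pd.DataFrame(rows),
                                     reference_genes=("R1", "R2"))
        t = expr[expr["gene"] == "T"].set_index("sample_id")
        # independent ddCt: 2^-(cqT - mean(cqRefs)) normalized to its mean shift
        for i, s in enumerate(samples):
            dct = cq_vals["T"][i] - 0.5 * (cq_vals["R1"][i] + cq_vals["R2"][i])
            ddct_rq = 2.0 ** (-dct)
            cal = (np.mean(cq_vals["T"]) - 0.5 * (np.mean(cq_vals["R1"])
                                                  + np.mean(cq_vals["R2"])))
            expected = ddct_rq / 2.0 ** (-cal)
            assert t.loc[s, "nrq"] == pytest.approx(expected, rel=1e-9)

    def test_missing_efficiency_raises(self):
        _, cq, _ = noiseless_panel()
        with pytest.raises(DomainError):
            normalized_expression(cq, efficiencies={"RefA": 1.0},
                                  reference_genes=("RefA", "RefB"))

    def test_noisy_fold_change_recovery(self):
        """SD 0.15 cycles, n=10/phase: fold change within 15% of truth in
        >=90% of replicates."""
        hits = 0
        reps = 60
        for k in range(reps):
            cfg = SimulationConfig(
                seed=3000 + k, stages=range(6, 20), qpcr_n_per_phase=10,
                cq_noise_sd=0.15,
                genes=(
                    GeneSpec("RefA", efficiency=0.9, base_cq=19, is_reference=True),
                    GeneSpec("RefB", efficiency=0.95, base_cq=21, is_reference=True),
                    GeneSpec("Tgt", efficiency=1.0, base_cq=24,
                             phase_log2={"activation": 0.0, "growth": 1.0}),
                ))
            _, cq, _ = generate_qpcr(cfg)
            expr = normalized_expression(
                cq, efficiencies={"RefA": 0.9, "RefB": 0.95, "Tgt": 1.0},
                reference_genes=("RefA", "RefB"))
            tgt = expr[expr["gene"] == "Tgt"]
            means = tgt.groupby("phase")["ln_nrq"].mean()
            fold = math.exp(means["growth"] - means["activation"])
            if abs(fold - 2.0) / 2.0 <= 0.15:
                hits += 1
        assert hits / reps >= 0.90


class TestReferenceStability:
    def test_proportional_genes_zero_ratio_sd(self, rng):
        cqs = rng.uniform(18, 24, 10)
        rows = []
        for i, base in enumerate(cqs):
            for gene, off in (("A", 0.0), ("B", 1.5), ("C", None)):
                cq = base + off if off is not None else rng.uniform(18, 30)
                rows.append({"sample_id": f"s{i}", "gene": gene, "rep": 1,
                             "cq": cq})
        out = reference_stability(pd.DataFrame(rows), candidates=["A", "B", "C"])
        # A and B differ by a constant Cq: their pairwise ratio SD is 0, so
        # they rank above the unrelated gene C
        assert out["rank"].tolist() == sorted(out["rank"].tolist())
        assert set(out.iloc[:2]["gene"]) == {"A", "B"}

    def test_designed_stable_genes_rank_top2(self, noisy_config):
        _, cq, _ = generate_qpcr(noisy_config)
        out = reference_stability(cq)
        assert set(out.iloc[:2]["gene"]) == {"TufM", "GPAM"}

    def test_sample_permutation_invariance(self, noisy_config):
        _, cq, _ = generate_qpcr(noisy_config)
        out1 = reference_stability(cq)
        shuffled = cq.sample(frac=1.0, random_state=5).reset_index(drop=True)
        out2 = reference_stability(shuffled)
        pd.testing.assert_frame_equal(
            out1.sort_values("gene").reset_index(drop=True),
            out2.sort_values("gene").reset_index(drop=True))

    def test_too_few_candidates(self, noisy_config):
        _, cq, _ = generate_qpcr(noisy_config)
        with pytest.raises(InsufficientDataError):
            reference_stability(cq, candidates=["TufM", "GPAM"])


class TestStageComparison:
    def _expr(self, groups):
        rows = []
        for phase, values in groups.items():
            for i, v in enumerate(values):
                rows.append({"sample_id": f"{phase}-{i}", "gene": "T",
                             "phase": phase, "ln_nrq": v})
        return pd.DataFrame(rows)

    def test_degenerate_reported_not_raised(self):
        expr = self._expr({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        res = stage_comparison(expr, "T")
        assert math.isnan(res.p_value)
        assert "degenerate" in res.note
        assert not res.significant

    def test_matches_hand_computed_f(self):
        """Two groups of 4: F computed equals the hand-worked ANOVA."""
        a = [1.0, 2.0, 3.0, 4.0]
        b = [3.0, 4.0, 5.0, 6.0]
        res = stage_comparison(self._expr({"a": a, "b": b}), "T")
        # hand ANOVA: grand mean 3.5; SSB = 4*(2.5-3.5)^2 + 4*(4.5-3.5)^2 = 8
        # SSW = 2 * (2.25+0.25+0.25+2.25) = 10; F = (8/1)/(10/6) = 4.8
        assert res.statistic == pytest.approx(4.8, rel=1e-12)
        f_oracle = stats.f_oneway(a, b)
        assert res.p_value == pytest.approx(f_oracle.pvalue, rel=1e-12)

    def test_tukey_pairwise_available(self, rng):
        expr = self._expr({p: list(rng.normal(m, 1.0, 6))
                           for p, m in [("bl", 0), ("org", 0.5), ("gr", 3.0)]})
        res = stage_comparison(expr, "T", pairwise=True)
        assert res.pairwise is not None
        assert len(res.pairwise) == 3  # 3 choose 2

    def test_kruskal_alternative(self, rng):
        expr = self._expr({"a": list(rng.normal(0, 1, 8)),
                           "b": list(rng.normal(2, 1, 8))})
        res = stage_comparison(expr, "T", method="kruskal")
        assert res.p_value < 0.05

    def test_degenerate_groups_error(self):
        expr = self._expr({"a": [1.0], "b": [2.0, 3.0]})
        with pytest.raises(DomainError):
            stage_comparison(expr, "T")

    def test_type_i_error_calibrated(self):
        """Null simulation: rejection rate at alpha=0.05 in [0.03, 0.07]."""
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 400
        for _ in range(reps):
            expr = self._expr({p: list(rng.normal(0.0, 1.0, 5))
                               for p in ("bl", "org", "act", "gr")})
            res = stage_comparison(expr, "T")
            if res.p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestCollapseReplicates:
    def test_triplicate_mean(self):
        df = pd.DataFrame({"sample_id": ["s"] * 3, "gene": ["g"] * 3,
                           "rep": [1, 2, 3], "cq": [20.0, 20.3, 20.6]})
        out = collapse_replicates(df)
        assert len(out) == 1
        assert out["cq"].iloc[0] == pytest.approx(20.3)
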