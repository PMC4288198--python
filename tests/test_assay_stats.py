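"""Assay quantification: probing ratios, fold calls, luciferase scale,
melting Tm and qPCR normalization, each against generator ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g4switch import (
    CqTable,
    LuciferasePlate,
    ProbingTable,
    accessibility_profile,
    construct_ratio,
    fraction_folded,
    g4_fold_call,
    make_artificial_g4,
    make_cq_table,
    make_luciferase_plate,
    make_melting_curve,
    make_probing_table,
    melting_tm,
    qpcr_relative_levels,
    relative_g4_formation,
)
from g4switch.assay_stats import AssayError


class TestAccessibilityProfile:
    def test_identical_lanes_give_unit_ratio(self):
        table = ProbingTable(
            (1, 2, 3), {"K_0": (1.0, 2.0, 3.0), "Li_0": (1.0, 2.0, 3.0)}
        )
        profile = accessibility_profile(table)
        assert profile.rho == pytest.approx((1.0, 1.0, 1.0))

    def test_generator_arithmetic_raw(self, artg4):
        seq, motif = artg4
        table = make_probing_table(motif, folded_fraction=1.0, noise_sd=0.0,
                                   seq_len=len(seq))
        profile = accessibility_profile(table, normalize=False)
        rho = dict(zip(profile.positions, profile.rho))
        for p in motif.loop_positions():
            assert rho[p + 1] == pytest.approx(2.0)
        for p in motif.tract_positions():
            assert rho[p + 1] == pytest.approx(0.5)

    def test_zero_li_flagged_not_dropped(self):
        table = ProbingTable((1, 2), {"K_0": (1.0, 1.0), "Li_0": (1.0, 0.0)})
        profile = accessibility_profile(table, normalize=False)
        assert profile.undefined == (2,)
        assert np.isnan(profile.rho[1]) and profile.rho[0] == pytest.approx(1.0)

    def test_missing_lane_named(self):
        table = ProbingTable((1,), {"K_0": (1.0,)})
        with pytest.raises(AssayError, match="Li_0"):
            accessibility_profile(table)

    def test_lane_scaling_invariance_when_normalized(self, artg4):
        """Multiplying a whole lane by a constant leaves ρ unchanged."""
        seq, motif = artg4
        table = make_probing_table(motif, 0.8, 0.05, seed=4, seq_len=len(seq))
        scaled = ProbingTable(
            table.positions,
            {
                "K_0": tuple(7.3 * v for v in table.lanes["K_0"]),
                "Li_0": table.lanes["Li_0"],
            },
        )
        a = accessibility_profile(table, normalize=True)
        b = accessibility_profile(scaled, normalize=True)
        assert np.allclose(a.rho, b.rho)


class TestFoldCall:
    def test_folded_pattern_called(self, artg4):
        seq, motif = artg4
        table = make_probing_table(motif, 0.9, 0.02, seed=0, seq_len=len(seq))
        call = g4_fold_call(accessibility_profile(table), motif)
        assert call.call == "folded"

    def test_flat_profile_unfolded(self, artg4):
        """G/A-mutant emulation: no K+/Li+ difference anywhere."""
        seq, motif = artg4
        table = make_probing_table(motif, 0.0, 0.0, seq_len=len(seq))
        call = g4_fold_call(accessibility_profile(table), motif)
        assert call.call == "unfolded"

    def test_saturating_aso_unfolded(self, artg4):
        """Equalized lanes at saturating anti-G4 oligo: folding abolished."""
        seq, motif = artg4
        table = make_probing_table(
            motif, 0.0, 0.03, seed=1, seq_len=len(seq), aso_conc=5.0
        )
        profile = accessibility_profile(table, aso_conc=5.0)
        assert g4_fold_call(profile, motif).call == "unfolded"

    def test_too_few_loop_positions_ambiguous(self, artg4):
        seq, motif = artg4
        table = make_probing_table(motif, 0.9, 0.0, seq_len=len(seq))
        profile = accessibility_profile(table)
        # mask all but two loop positions
        keep = sorted(motif.loop_positions())[:2]
        rho = [
            r if (p - 1 not in motif.loop_positions() or p - 1 in keep) else float("nan")
            for p, r in zip(profile.positions, profile.rho)
        ]
        from g4switch.assay_stats import AccessibilityProfile

        masked = AccessibilityProfile(profile.positions, tuple(rho), ())
        call = g4_fold_call(masked, motif)
        assert call.call == "ambiguous"
        assert "loop positions" in call.reason

    def test_detection_rate_under_noise(self, artg4):
        seq, motif = artg4
        n_folded = 0
        for s in range(100):
            table = make_probing_table(motif, 0.8, 0.05, seed=s, seq_len=len(seq))
            call = g4_fold_call(accessibility_profile(table), motif)
            n_folded += call.call == "folded"
        assert n_folded >= 95


class TestRelativeScale:
    def test_control_ratio_scores_100(self):
        assert relative_g4_formation(2.0, 2.0).S == pytest.approx(100.0)

    def test_unit_ratio_scores_0(self):
        assert relative_g4_formation(1.0, 2.0).S == pytest.approx(0.0)

    def test_linear_midpoint(self):
        assert relative_g4_formation(1.5, 2.0).S == pytest.approx(50.0)

    def test_undefined_scale_rejected(self):
        with pytest.raises(AssayError, match="scale undefined"):
            relative_g4_formation(1.5, 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0.0, 1.0),
        r=st.floats(1.05, 5.0),
        r_ctrl=st.floats(1.1, 5.0),
    )
    def test_scale_linearity(self, alpha, r, r_ctrl):
        """S(αR + (1-α)·1) = α·S(R) for fixed control."""
        lhs = relative_g4_formation(alpha * r + (1 - alpha) * 1.0, r_ctrl).S
        rhs = alpha * relative_g4_formation(r, r_ctrl).S
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestConstructRatio:
    def test_identical_arms(self):
        plate = make_luciferase_plate(true_R=1.0, cv=0.0, n_replicates=3)
        res = construct_ratio(plate)
        assert res.R == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_exact_twofold_no_noise(self):
        plate = make_luciferase_plate(true_R=2.0, cv=0.0, n_replicates=3)
        assert construct_ratio(plate).R == pytest.approx(2.0)

    def test_parameter_recovery_within_three_se(self):
        plate = make_luciferase_plate(true_R=1.5, cv=0.10, n_replicates=9, seed=11)
        res = construct_ratio(plate)
        se = res.sd / np.sqrt(res.n_wt)
        assert abs(res.R - 1.5) < 3 * se

    def test_unbiased_on_multiplicative_noise(self):
        """Mean over 1000 simulated plates within 1% of the true ratio."""
        rs = [
            construct_ratio(
                make_luciferase_plate(true_R=1.5, cv=0.10, n_replicates=9, seed=s)
            ).R
            for s in range(1000)
        ]
        assert abs(np.mean(rs) / 1.5 - 1.0) < 0.01

    def test_nonpositive_fluc_rejected(self):
        plate = make_luciferase_plate(true_R=2.0, cv=0.0, n_replicates=3)
        df = plate.wells.copy()
        df.loc[0, "fluc"] = 0.0
        with pytest.raises(AssayError, match="well"):
            construct_ratio(LuciferasePlate(df))


class TestMelting:
    def test_clean_curve_theta_half_at_tm(self):
        curve = fraction_folded(make_melting_curve(tm=60.0, noise=0.0))
        tm = melting_tm(curve)
        assert tm == pytest.approx(60.0, abs=0.2)
        i = int(np.argmin(np.abs(np.asarray(curve.temperature) - tm)))
        assert curve.theta[i] == pytest.approx(0.5, abs=0.02)

    def test_theta_recovery_with_sloped_baselines(self):
        curve = make_melting_curve(
            tm=55.0,
            folded_baseline=(12.0, -0.05),
            unfolded_baseline=(3.0, -0.02),
            noise=0.0,
        )
        corrected = fraction_folded(curve)
        t = np.asarray(curve.temperature)
        true_theta = 1.0 / (1.0 + np.exp((t - 55.0) / 2.5))
        mid = (t > 35) & (t < 75)
        assert np.max(np.abs(np.asarray(corrected.theta)[mid] - true_theta[mid])) < 0.02

    def test_flat_curve_rejected(self):
        flat = make_melting_curve(tm=60.0, folded_baseline=(5.0, 0.0),
                                  unfolded_baseline=(5.0, 0.0))
        with pytest.raises(AssayError, match="no melting transition"):
            fraction_folded(flat)

    def test_interpolated_between_grid_points(self):
        curve = fraction_folded(make_melting_curve(tm=60.07, noise=0.0))
        tm = melting_tm(curve)
        t = np.asarray(curve.temperature)
        below = t[t < tm].max()
        above = t[t > tm].min()
        assert below < tm < above

    def test_tm_recovery_median_over_range(self):
        """Median |Tm error| <= 0.5 °C over 100 melts with Tm in [40, 80]."""
        rng = np.random.default_rng(42)
        errors = []
        for s in range(100):
            true_tm = float(rng.uniform(40.0, 80.0))
            curve = make_melting_curve(tm=true_tm, noise=0.02, seed=s)
            errors.append(abs(melting_tm(fraction_folded(curve)) - true_tm))
        assert np.median(errors) <= 0.5

    def test_tm_recovery_within_one_degree_per_seed(self):
        """A σ = 2% curve recovers its Tm within 1 °C over 100 noise seeds."""
        for s in range(100):
            curve = make_melting_curve(tm=60.0, noise=0.02, seed=s)
            assert abs(melting_tm(fraction_folded(curve)) - 60.0) <= 1.0


class TestQpcr:
    def test_all_equal_cq_gives_unit_levels(self):
        table = make_cq_table(levels={"H2AFY": {"a": 1.0, "b": 1.0}}, noise=0.0)
        levels = qpcr_relative_levels(table)
        assert np.allclose(levels["level"], 1.0)

    def test_doubling_law(self):
        table = make_cq_table(levels={"H2AFY": {"cal": 1.0, "trt": 2.0}}, noise=0.0)
        levels = qpcr_relative_levels(table, calibrator="cal")
        trt = levels[(levels["gene"] == "H2AFY") & (levels["sample"] == "trt")]
        assert float(trt["level"].iloc[0]) == pytest.approx(2.0)

    def test_geometric_mean_normalization_factor(self):
        """References at RQ (1, 2, 4) give NF = 2: a target at RQ 2 lands at 1."""
        rows = []
        for gene, cq in (("R1", 20.0), ("R2", 19.0), ("R3", 18.0), ("T", 19.0)):
            rows.append({"gene": gene, "sample": "only", "cq": cq})
            rows.append({"gene": gene, "sample": "ref", "cq": 20.0})
        table = CqTable(pd.DataFrame(rows), ("R1", "R2", "R3"))
        levels = qpcr_relative_levels(table, calibrator="ref")
        t = levels[(levels["gene"] == "T") & (levels["sample"] == "only")]
        assert float(t["level"].iloc[0]) == pytest.approx(2.0 / 2.0 * 1.0)

    def test_missing_reference_rejected(self):
        df = pd.DataFrame(
            [
                {"gene": "T", "sample": "a", "cq": 20.0},
                {"gene": "R1", "sample": "a", "cq": 20.0},
                {"gene": "T", "sample": "b", "cq": 20.0},
            ]
        )
        table = CqTable(df, ("R1",))
        with pytest.raises(AssayError, match="R1"):
            qpcr_relative_levels(table)

    def test_reference_conservation(self):
        """Each reference gene normalized by its own NF has geometric mean 1
        across samples when references are stable."""
        table = make_cq_table(
            levels={"H2AFY": {"a": 1.0, "b": 3.0, "c": 0.5}}, noise=0.0
        )
        levels = qpcr_relative_levels(table)
        from scipy.stats import gmean

        for ref in table.reference_genes:
            vals = levels[levels["gene"] == ref]["level"]
            assert gmean(vals) == pytest.approx(1.0)
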