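"""Pixel-population statistics: OLS, MAD/COV, percentile subsets, summary tables."""

import numpy as np
import pytest

from mimsquant import (
    DegenerateDesignError,
    RatioDefinition,
    ROI,
    TRACERS,
    build_scene,
    condition_contrast,
    dispersion,
    pixel_regression,
    pooled_roi_ratio,
    pulse_chase_table,
    sample_counts,
    top_percentile_subset,
)

from conftest import flat_scene_spec, make_stack


def ols_by_sums(x, y):
    """Independent closed-form OLS oracle using raw sums only."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy, syy = (x * x).sum(), (x * y).sum(), (y * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    r2 = (n * sxy - sx * sy) ** 2 / ((n * sxx - sx * sx) * (n * syy - sy * sy))
    return slope, intercept, r2


class TestPixelRegression:
    def test_exact_linear_relation(self):
        x = np.linspace(0, 10, 100).reshape(10, 10)
        fit = pixel_regression(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n == 100

    def test_constant_response(self):
        x = np.linspace(0, 10, 100).reshape(10, 10)
        fit = pixel_regression(x, np.full_like(x, 7.0))
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_constant_regressor_raises(self):
        y = np.random.default_rng(0).random((5, 5))
        with pytest.raises(DegenerateDesignError):
            pixel_regression(np.ones((5, 5)), y)

    def test_matches_closed_form_sums(self):
        rng = np.random.default_rng(42)
        x = rng.random((20, 20)) * 100
        y = -0.5 * x + rng.normal(0, 10, size=x.shape) + 50
        fit = pixel_regression(x, y)
        slope, intercept, r2 = ols_by_sums(x.ravel(), y.ravel())
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)

    def test_null_slope_simulation_is_flat(self):
        """With no true DNA-RNA coupling, per-cell slopes straddle zero with tiny R^2."""
        from mimsquant import ChromatinTexture

        slopes, r2s = [], []
        for seed in range(6):
            spec = flat_scene_spec(
                chromatin_texture=ChromatinTexture(amplitude=0.4, correlation_length_px=4.0),
                rna_dna_slope=0.0,
                seed=seed,
            )
            truth = build_scene(spec)
            stack = sample_counts(truth, seed=100 + seed)
            from mimsquant import enrichment_image

            x = enrichment_image(stack, TRACERS["13C_DNA"])
            y = enrichment_image(stack, TRACERS["15N_RNA"])
            fit = pixel_regression(x, y, truth.compartment_mask("nucleoplasm"))
            slopes.append(fit.slope)
            r2s.append(fit.r_squared)
        assert min(slopes) < 0 < max(slopes) or max(np.abs(slopes)) < 0.05
        assert max(r2s) < 0.1


class TestDispersion:
    def test_hand_computed_mad(self):
        d = dispersion([1, 2, 3, 4, 5])
        assert d.median == 3 and d.mad == 1

    def test_outlier_robustness(self):
        d = dispersion([1, 2, 3, 4, 100])
        assert d.mad == 1.0          # unmoved by the outlier
        assert d.sd > 40.0           # classical SD explodes

    def test_degenerate_distribution(self):
        d = dispersion([2, 2, 2])
        assert d.mad == 0.0 and d.cov == 0.0

    def test_cov_undefined_for_nonpositive_mean(self):
        d = dispersion([-1.0, 1.0, -3.0])
        assert d.cov is None
        with pytest.raises(ValueError, match="COV undefined"):
            dispersion([-1.0, 1.0, -3.0], require_cov=True)

    def test_mad_invariant_to_one_sided_extreme_replacement(self):
        """Replacing already-extreme values with arbitrary outliers leaves MAD fixed."""
        base = np.arange(1.0, 10.0)  # mad = 2
        assert dispersion(base).mad == 2.0
        corrupted = base.copy()
        corrupted[-2:] = [1e9, 1e12]
        assert dispersion(corrupted).mad == 2.0


class TestTopPercentileSubset:
    def test_nearest_rank(self):
        density = np.arange(1.0, 101.0).reshape(10, 10)
        res = top_percentile_subset(density, np.ones((10, 10), bool), pct=5.0)
        assert sorted(density[res.roi.mask]) == [96, 97, 98, 99, 100]
        assert res.cutoff == 96

    def test_ties_at_cutoff_included(self):
        density = np.concatenate([np.arange(1.0, 96.0), np.full(5, 95.0)]).reshape(10, 10)
        res = top_percentile_subset(density, np.ones((10, 10), bool), pct=5.0)
        assert res.n_subset == 6  # the five 95s plus the original 95
        assert res.n_subset >= int(np.ceil(5 * 100 / 100))

    def test_subset_too_small_raises(self):
        with pytest.raises(ValueError, match="subset"):
            top_percentile_subset(np.arange(16.0).reshape(4, 4), np.ones((4, 4), bool), pct=5.0)

    def test_bad_pct_rejected(self):
        with pytest.raises(ValueError):
            top_percentile_subset(np.ones((4, 4)), np.ones((4, 4), bool), pct=0.0)

    def test_companion_recovery_in_densest_pixels(self):
        """Densest-DNA pixels carrying RNA multiplier 0.5 report ~50% companion enrichment."""
        rng = np.random.default_rng(1)
        shape = (40, 40)
        density = rng.normal(100, 10, size=shape)
        dense = np.zeros(shape, bool)
        dense[:8, :10] = True
        density[dense] += 200
        r0 = 0.0037
        den = np.full(shape, 10_000, int)
        num = rng.poisson(np.where(dense, 1.5 * r0, 1.0 * r0) * den)
        stack = make_stack({"12C15N": num, "12C14N": den})
        res = top_percentile_subset(
            density, np.ones(shape, bool), pct=5.0,
            stack=stack, companion_rd=TRACERS["15N_RNA"],
        )
        assert res.roi.mask.sum() == int(0.05 * density.size)
        assert (res.roi.mask <= dense).all()
        assert res.companion_pooled_enrichment_pct == pytest.approx(50.0, abs=10.0)
        assert res.background_reference_scaled == pytest.approx(37.0)


class TestPulseChaseTable:
    def test_single_record_flags_undefined_sd(self):
        table = pulse_chase_table([("c1", "15min", "nucleus", 42.0)])
        row = table.iloc[0]
        assert row["mean"] == 42.0 and row["n"] == 1
        assert np.isnan(row["sd"])

    def test_pulse_series_recovers_monotone_truth(self):
        """Nuclear means rise with the pulse multiplier, within 3 SE of truth."""
        multipliers = {"15min": 0.3, "60min": 0.8, "120min": 1.2}
        records = []
        for j, (tp, mult) in enumerate(multipliers.items()):
            for i in range(3):
                spec = flat_scene_spec(seed=10 * j + i)
                spec.compartment_enrichment = {
                    c: dict(m) for c, m in spec.compartment_enrichment.items()
                }
                spec.compartment_enrichment["nucleoplasm"]["15N_RNA"] = mult
                spec.compartment_enrichment["nucleolus"]["15N_RNA"] = mult
                spec.compartment_enrichment["lamina"]["15N_RNA"] = mult
                truth = build_scene(spec)
                stack = sample_counts(truth, seed=1000 + 10 * j + i)
                pooled = pooled_roi_ratio(stack, truth.nucleus_mask, TRACERS["15N_RNA"])
                records.append((f"c{i}", tp, "nucleus", pooled.enrichment_pct))
        table = pulse_chase_table(records).set_index("timepoint")
        means = table.loc[list(multipliers), "mean"]
        assert means.is_monotonic_increasing
        for tp, mult in multipliers.items():
            se = table.loc[tp, "se"]
            pooled_se_floor = 1.0  # Poisson SE dominates when cell scatter is tiny
            assert abs(table.loc[tp, "mean"] - 100 * mult) <= 3 * max(se, pooled_se_floor)

    def test_chase_pattern_stable_nucleus_declining_cytoplasm(self):
        records = [
            ("c1", 0, "nucleus", 100.0), ("c1", 0, "cytoplasm", 60.0),
            ("c1", 1, "nucleus", 98.0), ("c1", 1, "cytoplasm", 30.0),
            ("c1", 2, "nucleus", 101.0), ("c1", 2, "cytoplasm", 12.0),
        ]
        table = pulse_chase_table(records)
        cyt = table[table["compartment"] == "cytoplasm"].sort_values("timepoint")["mean"]
        nuc = table[table["compartment"] == "nucleus"].sort_values("timepoint")["mean"]
        assert cyt.is_monotonic_decreasing
        assert nuc.max() - nuc.min() < 5.0


class TestConditionContrast:
    def test_fifty_percent_increase(self):
        table = condition_contrast({"ctrl": [100.0], "stim": [150.0]}, reference="ctrl")
        stim = table.set_index("condition").loc["stim"]
        assert stim["pct_change_vs_ref"] == pytest.approx(50.0)

    def test_identical_groups_zero_change(self):
        table = condition_contrast({"a": [5.0, 6.0], "b": [5.0, 6.0]}, reference="a")
        assert table.set_index("condition").loc["b", "pct_change_vs_ref"] == 0.0

    def test_unknown_reference(self):
        with pytest.raises(KeyError):
            condition_contrast({"a": [1.0], "b": [2.0]}, reference="zz")

    def test_simulated_two_group_recovery(self):
        """Scenes at multiplier ratio 1.5 recover ~+50% within the group CI."""
        groups = {}
        for name, mult, base_seed in [("ctrl", 1.0, 0), ("stim", 1.5, 100)]:
            vals = []
            for i in range(8):
                spec = flat_scene_spec(seed=base_seed + i)
                spec.compartment_enrichment = {
                    c: dict(m) for c, m in spec.compartment_enrichment.items()
                }
                for comp in ("nucleoplasm", "nucleolus", "lamina"):
                    spec.compartment_enrichment[comp]["15N_RNA"] *= mult
                truth = build_scene(spec)
                stack = sample_counts(truth, seed=7000 + base_seed + i)
                vals.append(
                    pooled_roi_ratio(stack, truth.nucleus_mask, TRACERS["15N_RNA"]).enrichment_pct
                )
            groups[name] = vals
        table = condition_contrast(groups, reference="ctrl").set_index("condition")
        assert table.loc["stim", "pct_change_vs_ref"] == pytest.approx(50.0, abs=10.0)
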