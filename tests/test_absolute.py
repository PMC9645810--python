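import numpy as np
import pandas as pd
import pytest

from evoexpr.absolute import (
    AbsoluteAbundance,
    CalibrationFit,
    absolute_fold_changes,
    cell_volumes,
    fit_spikein_calibration,
    line_totals,
    molecules_per_cfu,
    spherocylinder_volume,
    total_mrna_vs_volume,
    tpm_to_molecules,
)
from evoexpr.simulate import default_spikein_design, simulate_spikein_counts


class TestSpherocylinderVolume:
    @pytest.mark.parametrize(
        "l,w,expected",
        [
            (1.0, 1.0, 0.5235988),  # degenerate sphere (4/3) pi 0.5^3
            (2.0, 1.0, 1.3089969),
            (3.0, 2.0, 7.3303829),
        ],
    )
    def test_reference_values(self, l, w, expected):
        assert spherocylinder_volume(l, w) == pytest.approx(expected, abs=1e-6)

    def test_length_shorter_than_width_rejected(self):
        with pytest.raises(ValueError, match="length"):
            spherocylinder_volume(0.5, 1.0)

    def test_vectorized_and_line_medians(self):
        geo = pd.DataFrame(
            {
                "line": ["A", "A", "B"],
                "length_um": [2.0, 3.0, 1.0],
                "width_um": [1.0, 1.0, 1.0],
            }
        )
        out = cell_volumes(geo)
        assert out["volume_um3"].iloc[0] == pytest.approx(1.3089969, abs=1e-6)
        assert out.loc[out["line"] == "B", "median_volume_um3"].iloc[0] == pytest.approx(0.5235988, abs=1e-6)


class TestSpikeinCalibration:
    def exact_design(self):
        design = pd.DataFrame(
            {
                "spikein_id": ["e1", "e2", "e3"],
                "sample_id": "s1",
                "molecules": [10.0, 100.0, 1000.0],
            }
        )
        tpm = pd.DataFrame({"s1": [1.0, 10.0, 100.0]}, index=["e1", "e2", "e3"])
        return design, tpm

    def test_exact_line_recovered(self):
        design, tpm = self.exact_design()
        fit = fit_spikein_calibration(tpm, design, "s1")
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(-1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_molecules_rejected(self):
        design, tpm = self.exact_design()
        design["molecules"] = 50.0
        with pytest.raises(ValueError, match="constant"):
            fit_spikein_calibration(tpm, design, "s1")

    def test_zero_tpm_spikeins_excluded(self):
        design = pd.DataFrame(
            {
                "spikein_id": [f"e{i}" for i in range(5)],
                "sample_id": "s1",
                "molecules": [10.0, 100.0, 1000.0, 1e4, 1e5],
            }
        )
        tpm = pd.DataFrame({"s1": [0.0, 10.0, 100.0, 1000.0, 0.0]}, index=design["spikein_id"])
        fit = fit_spikein_calibration(tpm, design, "s1")
        assert fit.n_used == 3
        assert fit.n_zero_excluded == 2

    def test_slope_recovery_within_sampling_error(self):
        # OLS sampling theory: mean slope over seeds close to truth
        slopes = []
        for seed in range(40):
            design = default_spikein_design(["s1"], n_spikeins=92, seed=seed)
            obs = simulate_spikein_counts(design, slope=0.9, intercept=-2.0, noise_sd=0.1, seed=seed)
            slopes.append(fit_spikein_calibration(obs, design, "s1").slope)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 0.9) < 3 * se + 1e-3


class TestTpmToMolecules:
    def test_simple_inversion(self):
        fit = CalibrationFit("s1", 1.0, -1.0, 1.0, 3)
        mol = tpm_to_molecules(pd.Series({"g1": 10.0}), fit)
        assert mol["g1"] == pytest.approx(100.0)

    def test_zero_noise_round_trip_exact(self):
        design = default_spikein_design(["s1"], n_spikeins=30, seed=3)
        obs = simulate_spikein_counts(design, slope=1.1, intercept=-2.5, noise_sd=0.0, seed=3)
        fit = fit_spikein_calibration(obs, design, "s1")
        mol = tpm_to_molecules(obs["s1"], fit)
        truth = design.set_index("spikein_id")["molecules"]
        assert np.allclose(mol, truth.loc[mol.index], rtol=1e-9)

    def test_zero_tpm_maps_to_zero(self):
        fit = CalibrationFit("s1", 1.0, -1.0, 1.0, 3)
        assert tpm_to_molecules(pd.Series({"g1": 0.0}), fit)["g1"] == 0.0

    def test_non_positive_slope_rejected(self):
        fit = CalibrationFit("s1", -0.5, -1.0, 0.5, 3)
        with pytest.raises(ValueError, match="slope"):
            tpm_to_molecules(pd.Series({"g1": 1.0}), fit)


class TestMoleculesPerCfu:
    def test_simple_ratio(self):
        ab = molecules_per_cfu(pd.Series({"g": 1e9}), 1e6, [1.0])
        assert ab.molecules_per_cfu["g"] == pytest.approx(1000.0)

    def test_sampling_fractions_multiply(self):
        ab = molecules_per_cfu(pd.Series({"g": 1e9}), 1e6, [0.5, 0.5])
        assert ab.molecules_per_cfu["g"] == pytest.approx(4000.0)
        assert ab.effective_cfu == pytest.approx(2.5e5)

    def test_empty_fraction_list_is_identity(self):
        ab = molecules_per_cfu(pd.Series({"g": 1e9}), 1e6, [])
        assert ab.molecules_per_cfu["g"] == pytest.approx(1000.0)

    @pytest.mark.parametrize("fractions", [[0.0], [1.5], [-0.1]])
    def test_bad_fractions_rejected(self, fractions):
        with pytest.raises(ValueError, match="fractions"):
            molecules_per_cfu(pd.Series({"g": 1.0}), 1.0, fractions)

    def test_linear_in_molecules_inverse_in_cfu(self):
        base = molecules_per_cfu(pd.Series({"g": 100.0}), 10.0)
        doubled = molecules_per_cfu(pd.Series({"g": 200.0}), 10.0)
        halved_cells = molecules_per_cfu(pd.Series({"g": 100.0}), 5.0)
        assert doubled.molecules_per_cfu["g"] == pytest.approx(2 * base.molecules_per_cfu["g"])
        assert halved_cells.molecules_per_cfu["g"] == pytest.approx(2 * base.molecules_per_cfu["g"])


def make_abundance(sid, values):
    return AbsoluteAbundance(sid, pd.Series(values), 1.0)


class TestAbsoluteFoldChanges:
    def test_mean_ratio(self):
        ev = [make_abundance("e1", {"g": 200.0}), make_abundance("e2", {"g": 220.0})]
        an = [make_abundance(f"a{i}", {"g": v}) for i, v in enumerate([100.0, 105.0, 95.0, 100.0])]
        res = absolute_fold_changes(ev, an)
        assert res["fold_change"]["g"] == pytest.approx(2.1)

    def test_identical_replicates_null_at_one(self):
        vals = {f"g{i}": float(i + 1) for i in range(20)}
        ev = [make_abundance("e1", vals), make_abundance("e2", vals)]
        an = [make_abundance("a1", vals), make_abundance("a2", vals)]
        res = absolute_fold_changes(ev, an)
        assert np.allclose(res["replicate_null"], 1.0)

    def test_replicate_null_log_symmetric_for_exchangeable_replicates(self, rng):
        base = rng.lognormal(3, 1, size=4000)
        noise = lambda: rng.lognormal(0, 0.1, size=4000)
        genes = [f"g{i}" for i in range(4000)]
        ev = [make_abundance("e1", dict(zip(genes, base * noise()))),
              make_abundance("e2", dict(zip(genes, base * noise())))]
        an = [make_abundance("a1", dict(zip(genes, base * noise()))),
              make_abundance("a2", dict(zip(genes, base * noise())))]
        res = absolute_fold_changes(ev, an)
        logs = np.log2(res["replicate_null"].to_numpy())
        assert abs(np.mean(logs)) < 3 * np.std(logs) / np.sqrt(len(logs))

    def test_global_doubling_detected_against_replicate_null(self, rng):
        base = rng.lognormal(3, 1, size=4000)
        genes = [f"g{i}" for i in range(4000)]
        noise = lambda: rng.lognormal(0, 0.1, size=4000)
        ev = [make_abundance("e1", dict(zip(genes, 2 * base * noise()))),
              make_abundance("e2", dict(zip(genes, 2 * base * noise())))]
        an = [make_abundance("a1", dict(zip(genes, base * noise()))),
              make_abundance("a2", dict(zip(genes, base * noise())))]
        res = absolute_fold_changes(ev, an)
        assert res["ks_pvalue"] < 1e-4
        assert res["fold_change"].median() == pytest.approx(2.0, rel=0.1)

    def test_disjoint_gene_sets_rejected(self):
        ev = [make_abundance("e1", {"g1": 1.0}), make_abundance("e2", {"g1": 1.0})]
        an = [make_abundance("a1", {"g2": 1.0}), make_abundance("a2", {"g2": 1.0})]
        with pytest.raises(ValueError, match="overlapping"):
            absolute_fold_changes(ev, an)


class TestTotalMrnaVsVolume:
    def test_proportional_totals_correlate_perfectly(self):
        vol = pd.Series({"L1": 1.0, "L2": 2.0, "L3": 3.0, "L4": 4.0})
        totals = 5000.0 * vol
        res = total_mrna_vs_volume(totals, vol)
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(5000.0)

    def test_constant_totals_give_zero_slope(self):
        vol = pd.Series({"L1": 1.0, "L2": 2.0, "L3": 3.0})
        totals = pd.Series({"L1": 10.0, "L2": 10.0, "L3": 10.0})
        res = total_mrna_vs_volume(totals, vol)
        assert res["slope"] == pytest.approx(0.0)

    def test_slope_recovery_with_noise(self, rng):
        a, b = 1000.0, 800.0
        slopes = []
        for seed in range(50):
            local = np.random.default_rng(seed)
            vol = pd.Series(local.uniform(0.5, 4.0, size=12), index=[f"L{i}" for i in range(12)])
            totals = a + b * vol + local.normal(0, 100, size=12)
            slopes.append(total_mrna_vs_volume(totals, vol)["slope"])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - b) < 3 * se + 1.0

    def test_too_few_lines_rejected(self):
        vol = pd.Series({"L1": 1.0, "L2": 2.0})
        with pytest.raises(ValueError, match="3 lines"):
            total_mrna_vs_volume(5000 * vol, vol)

    def test_line_totals_sum_replicate_means(self):
        per_sample = {
            "L1_r1": make_abundance("L1_r1", {"g1": 10.0, "g2": 20.0}),
            "L1_r2": make_abundance("L1_r2", {"g1": 30.0, "g2": 40.0}),
        }
        totals = line_totals(per_sample, {"L1_r1": "L1", "L1_r2": "L1"})
        assert totals["L1"] == pytest.approx((10 + 30) / 2 + (20 + 40) / 2)
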