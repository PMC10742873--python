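"""Fold change, Student's t-test and verdict rules, against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import stdtr

from senolytica import senolysis
from senolytica.errors import (
    InsufficientReplicationError,
    SchemaError,
    UndefinedBaselineError,
)


def make_table(counts_by_condition: dict[str, dict[str, list[int]]]) -> pd.DataFrame:
    rows = []
    for condition, channels in counts_by_condition.items():
        for channel, counts in channels.items():
            for rep, count in enumerate(counts):
                rows.append(
                    {
                        "well_id": f"{condition}_r{rep}",
                        "condition": condition,
                        "replicate": rep,
                        "channel": channel,
                        "count": count,
                    }
                )
    return pd.DataFrame(rows)


class TestFoldChange:
    def test_identical_condition_has_unit_fold_change(self):
        table = make_table(
            {"DMSO": {"RFP": [100, 100, 100]}, "drug": {"RFP": [100, 100, 100]}}
        )
        fc = senolysis.fold_change(table, "DMSO")
        assert (fc["fold_change"] == 1.0).all()

    def test_halved_counts_give_exactly_half(self):
        table = make_table(
            {"DMSO": {"RFP": [100, 100, 100]}, "drug": {"RFP": [50, 50, 50]}}
        )
        fc = senolysis.fold_change(table, "DMSO")
        drug = fc[fc["condition"] == "drug"].iloc[0]
        assert drug["fold_change"] == 0.5
        assert drug["sd"] == 0.0

    def test_zero_vehicle_baseline_is_an_error(self):
        table = make_table({"DMSO": {"RFP": [0, 0, 0]}, "drug": {"RFP": [5, 5, 5]}})
        with pytest.raises(UndefinedBaselineError):
            senolysis.fold_change(table, "DMSO")

    def test_scale_equivariance_per_channel(self):
        rng = np.random.default_rng(0)
        counts = {
            "DMSO": {"RFP": list(rng.integers(80, 120, 3))},
            "drug": {"RFP": list(rng.integers(30, 60, 3))},
        }
        fc1 = senolysis.fold_change(make_table(counts), "DMSO")
        scaled = {
            cond: {ch: [7 * c for c in v] for ch, v in chans.items()}
            for cond, chans in counts.items()
        }
        fc2 = senolysis.fold_change(make_table(scaled), "DMSO")
        np.testing.assert_allclose(fc1["fold_change"], fc2["fold_change"])

    def test_simulated_survival_recovered_within_sampling_error(self):
        from senolytica import synthgen
        from senolytica.synthgen import CocultureSimConfig

        base = CocultureSimConfig(n_quiescent=200, n_senescent=200)
        _, truth = synthgen.simulate_senolysis_experiment(
            base, 1.0, 0.4, n_replicates=3, seed=21, well_cv=0.0, render=False
        )
        fc = senolysis.fold_change(synthgen.senolysis_assay_table(truth), "DMSO")
        rfp = fc[(fc["condition"] == "treated") & (fc["channel"] == "RFP")].iloc[0]
        sd = np.sqrt(200 * 0.4 * 0.6) / 200 / np.sqrt(3)  # binomial SE of the FC
        assert abs(rfp["fold_change"] - 0.4) < 3 * sd


class TestSignificance:
    def test_matches_hand_computed_pooled_t(self):
        a = np.array([10.0, 12.0, 11.0])
        b = np.array([30.0, 28.0, 32.0])
        # closed-form pooled-variance two-sample t with df = 4
        sp2 = ((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_oracle = 2 * stdtr(4, -abs(t))
        table = make_table({"DMSO": {"RFP": [30, 28, 32]}, "drug": {"RFP": [10, 12, 11]}})
        pv = senolysis.significance(table, "DMSO")
        p = pv.loc[pv["condition"] == "drug", "p_value"].iloc[0]
        assert p == pytest.approx(p_oracle, rel=1e-12)

    def test_zero_variance_identical_groups_p_is_one(self):
        table = make_table({"DMSO": {"RFP": [10, 10, 10]}, "drug": {"RFP": [10, 10, 10]}})
        pv = senolysis.significance(table, "DMSO")
        assert pv.loc[pv["condition"] == "drug", "p_value"].iloc[0] == 1.0

    def test_group_order_symmetry(self):
        t1 = make_table({"DMSO": {"RFP": [30, 28, 32]}, "drug": {"RFP": [10, 12, 11]}})
        t2 = make_table({"DMSO": {"RFP": [10, 12, 11]}, "drug": {"RFP": [30, 28, 32]}})
        p1 = senolysis.significance(t1, "DMSO")
        p2 = senolysis.significance(t2, "DMSO")
        assert (
            p1.loc[p1["condition"] == "drug", "p_value"].iloc[0]
            == p2.loc[p2["condition"] == "drug", "p_value"].iloc[0]
        )

    def test_single_replicate_is_insufficient(self):
        table = make_table({"DMSO": {"RFP": [10, 11]}, "drug": {"RFP": [5]}})
        with pytest.raises(InsufficientReplicationError):
            senolysis.significance(table, "DMSO")

    def test_welch_differs_under_unequal_variance(self):
        table = make_table(
            {"DMSO": {"RFP": [100, 101, 99]}, "drug": {"RFP": [10, 80, 40]}}
        )
        pooled = senolysis.significance(table, "DMSO")
        welch = senolysis.significance(table, "DMSO", welch=True)
        assert not np.isclose(
            pooled.loc[pooled["condition"] == "drug", "p_value"].iloc[0],
            welch.loc[welch["condition"] == "drug", "p_value"].iloc[0],
        )


def stats_row(condition, channel, fc, p):
    return {"condition": condition, "channel": channel, "fold_change": fc, "p_value": p}


class TestClassify:
    def test_navitoclax_pattern_is_senolytic(self):
        stats = pd.DataFrame(
            [
                stats_row("navi", "RFP", 0.4, 0.003),
                stats_row("navi", "GFP", 0.98, 0.6),
            ]
        )
        assert senolysis.classify(stats)["navi"] == "senolytic"

    def test_both_channels_reduced_is_toxic(self):
        stats = pd.DataFrame(
            [
                stats_row("drug", "RFP", 0.3, 0.001),
                stats_row("drug", "GFP", 0.3, 0.001),
            ]
        )
        assert senolysis.classify(stats)["drug"] == "toxic"

    def test_unchanged_counts_are_inert(self):
        stats = pd.DataFrame(
            [stats_row("drug", "RFP", 1.0, 1.0), stats_row("drug", "GFP", 1.0, 1.0)]
        )
        assert senolysis.classify(stats)["drug"] == "inert"

    def test_only_gfp_reduced_is_quiescent_selective(self):
        stats = pd.DataFrame(
            [
                stats_row("drug", "RFP", 1.02, 0.8),
                stats_row("drug", "GFP", 0.5, 0.002),
            ]
        )
        assert senolysis.classify(stats)["drug"] == "quiescent-selective"

    def test_missing_channel_is_schema_error(self):
        stats = pd.DataFrame([stats_row("drug", "RFP", 0.4, 0.01)])
        with pytest.raises(SchemaError):
            senolysis.classify(stats)


class TestScorePipeline:
    def test_end_to_end_senolytic_call(self):
        table = make_table(
            {
                "DMSO": {"RFP": [200, 195, 205], "GFP": [200, 210, 190]},
                "navi": {"RFP": [80, 78, 85], "GFP": [198, 205, 192]},
            }
        )
        result = senolysis.score(table, "DMSO")
        assert result.verdicts["navi"] == "senolytic"
        assert result.verdicts["DMSO"] == "vehicle"
        out = result.table()
        veh = out[out["condition"] == "DMSO"]
        assert (veh["fold_change"] == 1.0).all()
        assert out["p_value"].between(0, 1).all()

    def test_bh_correction_only_raises_pvalues(self):
        table = make_table(
            {
                "DMSO": {"RFP": [200, 195, 205], "GFP": [200, 210, 190]},
                "a": {"RFP": [80, 78, 85], "GFP": [198, 205, 192]},
                "b": {"RFP": [150, 160, 149], "GFP": [201, 207, 188]},
            }
        )
        plain = senolysis.score(table, "DMSO").stats
        corrected = senolysis.score(table, "DMSO", bh_correct=True).stats
        merged = plain.merge(
            corrected, on=["condition", "channel"], suffixes=("", "_bh")
        )
        nonveh = merged[merged["condition"] != "DMSO"]
        assert (nonveh["p_value_bh"] >= nonveh["p_value"] - 1e-12).all()
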