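"""Simulator contracts: determinism, planted-truth fidelity, distributions."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from senolytica import synthgen
from senolytica.errors import PlacementError
from senolytica.synthgen import CocultureSimConfig


class TestCocultureField:
    def test_same_seed_gives_bit_identical_images(self):
        cfg = CocultureSimConfig(n_quiescent=20, n_senescent=20, seed=7)
        f1, t1 = synthgen.simulate_coculture_field(cfg)
        f2, t2 = synthgen.simulate_coculture_field(cfg)
        for name in f1.channels:
            np.testing.assert_array_equal(f1.channels[name], f2.channels[name])
        assert t1.objects == t2.objects

    def test_ground_truth_counts_and_pairwise_separation(self):
        cfg = CocultureSimConfig(
            n_quiescent=50, n_senescent=50, allow_touching=False, seed=7
        )
        _, truth = synthgen.simulate_coculture_field(cfg)
        assert truth.count("GFP") == 50
        assert truth.count("RFP") == 50
        # brute-force pairwise check: center distance > sum of radii
        centers = np.array([o["center"] for o in truth.objects])
        radii = np.array([o["radius"] for o in truth.objects])
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                dist = np.hypot(*(centers[i] - centers[j]))
                assert dist > radii[i] + radii[j]

    def test_empty_field_is_pure_background(self):
        cfg = CocultureSimConfig(
            n_quiescent=0, n_senescent=0, background_level=100.0, noise_sd=5.0, seed=3
        )
        field, truth = synthgen.simulate_coculture_field(cfg)
        assert truth.objects == []
        for plane in field.channels.values():
            assert abs(plane.mean() - 100.0) < 1.0
            assert plane.max() < 100.0 + 6 * 5.0

    def test_impossible_density_raises_placement_error(self):
        cfg = CocultureSimConfig(
            field_size=64, n_quiescent=200, n_senescent=0, seed=0
        )
        with pytest.raises(PlacementError):
            synthgen.simulate_coculture_field(cfg)

    def test_autofluor_bleed_adds_halo_to_named_channel(self):
        base = dict(n_quiescent=0, n_senescent=5, noise_sd=0.0, seed=4)
        clean, _ = synthgen.simulate_coculture_field(CocultureSimConfig(**base))
        bled, _ = synthgen.simulate_coculture_field(
            CocultureSimConfig(**base, autofluor_bleed={"GFP": 0.5})
        )
        extra = bled.channels["GFP"] - clean.channels["GFP"]
        np.testing.assert_allclose(
            extra, 0.5 * (clean.channels["autofluor"] - 100.0), atol=1e-9
        )


class TestSenolysisExperiment:
    def test_full_survival_keeps_expected_counts_equal(self):
        base = CocultureSimConfig(n_quiescent=100, n_senescent=100)
        _, truth = synthgen.simulate_senolysis_experiment(
            base, 1.0, 1.0, n_replicates=4, seed=1, well_cv=0.0, render=False
        )
        for well in truth.extra["wells"]:
            assert well["counts"] == {"GFP": 100, "RFP": 100}

    def test_zero_survival_leaves_no_rfp_objects(self):
        base = CocultureSimConfig(n_quiescent=10, n_senescent=50)
        images, truth = synthgen.simulate_senolysis_experiment(
            base, 1.0, 0.0, n_replicates=2, seed=2, render=True
        )
        for well in truth.extra["wells"]:
            if well["condition"] == "treated":
                assert well["counts"]["RFP"] == 0
        for fld in images["treated"]:
            # the RFP channel of a treated field carries no planted disks
            assert fld.channels["RFP"].max() < 200

    def test_binomial_survival_mean(self):
        # survival 0.5 on 200 cells: mean of 100 replicates within 3 binomial SEs
        base = CocultureSimConfig(n_quiescent=10, n_senescent=200)
        _, truth = synthgen.simulate_senolysis_experiment(
            base, 1.0, 0.5, n_replicates=100, seed=5, well_cv=0.0, render=False
        )
        treated = [
            w["counts"]["RFP"] for w in truth.extra["wells"]
            if w["condition"] == "treated"
        ]
        se_mean = np.sqrt(200 * 0.25) / np.sqrt(len(treated))
        assert abs(np.mean(treated) - 100.0) < 3 * se_mean

    def test_assay_table_matches_ground_truth(self):
        base = CocultureSimConfig(n_quiescent=30, n_senescent=30)
        _, truth = synthgen.simulate_senolysis_experiment(
            base, 1.0, 0.4, n_replicates=3, seed=9, render=False
        )
        table = synthgen.senolysis_assay_table(truth)
        assert len(table) == 2 * 3 * 2  # conditions x replicates x channels
        assert set(table["condition"]) == {"DMSO", "treated"}


class TestSABGField:
    def test_no_clusters_gives_uniform_background(self):
        image, truth = synthgen.simulate_sabg_field(0, total_cells=10, seed=1)
        assert truth.objects == []
        assert image.as_array().std() < 0.02

    def test_flood_fill_oracle_recovers_cluster_count(self):
        image, truth = synthgen.simulate_sabg_field(12, total_cells=40, seed=1)
        from senolytica.sabg import rgb_to_hsb

        sat = rgb_to_hsb(image).saturation
        labeled, n = ndi.label(sat > 0.25)
        assert n == 12
        assert len(truth.objects) == 12

    def test_core_hue_matches_configuration(self):
        image, truth = synthgen.simulate_sabg_field(
            4, cluster_hue=240.0, total_cells=8, seed=2, noise_sd=0.0
        )
        from senolytica.sabg import rgb_to_hsb

        hue = rgb_to_hsb(image).hue
        for obj in truth.objects:
            r, c = (int(round(v)) for v in obj["center"])
            assert abs(hue[r, c] - 240.0) < 2.0

    def test_determinism(self):
        a, _ = synthgen.simulate_sabg_field(6, total_cells=12, seed=3)
        b, _ = synthgen.simulate_sabg_field(6, total_cells=12, seed=3)
        np.testing.assert_array_equal(a.as_array(), b.as_array())


class TestSpectralStack:
    def test_zero_amplitude_is_noise_around_background(self):
        stack, _ = synthgen.simulate_spectral_stack(
            {"cytoplasmic": (510.0, 40.0, 0.0)},
            background_level=5.0, noise_sd=1.0, seed=1,
        )
        means = [p.mean() for p in stack.planes]
        assert np.allclose(means, 5.0, atol=0.5)

    def test_planted_peak_lands_on_nearest_grid_channel(self):
        stack, rois = synthgen.simulate_spectral_stack(
            {"cytoplasmic": (510.0, 40.0, 50.0)}, noise_sd=0.0, seed=2
        )
        cyt = rois.by_compartment("cytoplasmic")[0].mask
        mfi = np.array([p[cyt].mean() for p in stack.planes])
        expected = np.argmin(np.abs(stack.wavelengths - 510.0))
        assert int(np.argmax(mfi)) == int(expected)

    def test_disjoint_compartments_are_independent(self):
        kwargs = dict(noise_sd=0.0, seed=3)
        a, rois = synthgen.simulate_spectral_stack(
            {"nuclear": (460.0, 30.0, 20.0), "cytoplasmic": (510.0, 40.0, 10.0)}, **kwargs
        )
        b, _ = synthgen.simulate_spectral_stack(
            {"nuclear": (460.0, 30.0, 20.0), "cytoplasmic": (510.0, 40.0, 90.0)}, **kwargs
        )
        nuc = rois.by_compartment("nuclear")[0].mask
        for pa, pb in zip(a.planes, b.planes):
            np.testing.assert_array_equal(pa[nuc], pb[nuc])

    def test_peak_outside_range_rejected(self):
        with pytest.raises(ValueError):
            synthgen.simulate_spectral_stack({"cytoplasmic": (900.0, 40.0, 1.0)})


class TestFlowEvents:
    def test_pure_gfp_population(self):
        table, truth = synthgen.simulate_flow_events(500, 1.0, 0.0, seed=1)
        assert all(lab == "gfp_pos" for lab in truth.extra["labels"])
        assert (table["gfp"] > table["rfp"]).mean() > 0.999

    def test_midpoint_threshold_recovers_labels(self):
        table, truth = synthgen.simulate_flow_events(
            10_000, 0.5, 0.5, separation=2.0, seed=2
        )
        mid = 10.0 ** (1.5 + 1.0)  # halfway between the log-cluster centers
        pred = np.where(table["gfp"] > mid, "gfp_pos", "rfp_pos")
        truth_labels = np.array(truth.extra["labels"])
        confusion = np.mean(pred != truth_labels)
        assert confusion < 0.001

    def test_determinism_and_fraction_validation(self):
        a, _ = synthgen.simulate_flow_events(100, 0.4, 0.4, seed=5)
        b, _ = synthgen.simulate_flow_events(100, 0.4, 0.4, seed=5)
        assert a.equals(b)
        with pytest.raises(ValueError):
            synthgen.simulate_flow_events(10, 0.7, 0.7)
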