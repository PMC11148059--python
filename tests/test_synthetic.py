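"""Synthetic-data generators: planted ground truth, determinism, cohort copula."""

import numpy as np
import pytest
from scipy import stats as sps

from octachorio.ccfd import binarize_large_vessels
from octachorio.synthetic import (CCImageSpec, CohortConfig, InfeasibleDensityError,
                                  VariableSpec, default_cohort_config,
                                  generate_bscan_stack, generate_cc_enface,
                                  generate_cohort, generate_retina_enface)

from conftest import simple_config


class TestCCEnface:
    def test_zero_density_is_empty(self):
        spec = CCImageSpec(target_fd_density_pct=0.0, image_size_px=(128, 128),
                           noise_sd=0.0)
        image, truth = generate_cc_enface(spec)
        assert truth.fd_table.empty
        assert (truth.fd_label_map == 0).all()
        assert np.allclose(image.data, spec.background_intensity)

    @pytest.mark.parametrize("density", [2.0, 6.03, 8.05])
    def test_planted_density_within_half_point(self, density):
        spec = CCImageSpec(image_size_px=(256, 256), noise_sd=0.0,
                           target_fd_density_pct=density, seed=3)
        _, truth = generate_cc_enface(spec)
        assert abs(truth.planted_density_pct - density) <= 0.5

    def test_ground_truth_areas_match_label_map(self):
        spec = CCImageSpec(image_size_px=(256, 256), seed=5)
        _, truth = generate_cc_enface(spec)
        counts = np.bincount(truth.fd_label_map.ravel())
        for row in truth.fd_table.itertuples():
            assert row.area_um2 == counts[row.label] * spec.scale_um_per_px**2

    def test_blobs_are_disjoint_labels(self):
        spec = CCImageSpec(image_size_px=(256, 256), seed=7)
        _, truth = generate_cc_enface(spec)
        from skimage.measure import label as sklabel
        relabelled = sklabel(truth.fd_label_map > 0, connectivity=2)
        assert relabelled.max() == len(truth.fd_table)

    def test_determinism(self):
        spec = CCImageSpec(image_size_px=(128, 128), seed=9)
        img1, t1 = generate_cc_enface(spec)
        img2, t2 = generate_cc_enface(spec)
        assert np.array_equal(img1.data, img2.data)
        assert np.array_equal(t1.fd_label_map, t2.fd_label_map)

    def test_infeasible_density_raises(self):
        spec = CCImageSpec(image_size_px=(96, 96), target_fd_density_pct=75.0,
                           fd_diameter_mean_um=200.0, fd_diameter_sd_um=20.0,
                           seed=1)
        with pytest.raises(InfeasibleDensityError):
            generate_cc_enface(spec)

    def test_fd_must_be_darker_than_background(self):
        with pytest.raises(ValueError):
            CCImageSpec(fd_intensity=0.8, background_intensity=0.7)


class TestRetinaEnface:
    def test_zero_branches_uniform(self):
        spec = CCImageSpec(image_size_px=(128, 128), n_branches=0, noise_sd=0.0)
        image, truth = generate_retina_enface(spec)
        assert not truth.vessel_mask.any()
        assert np.ptp(image.data) == 0

    def test_noise_free_binarization_recovers_mask(self):
        spec = CCImageSpec(image_size_px=(256, 256), n_branches=5,
                           noise_sd=0.0, seed=13)
        image, truth = generate_retina_enface(spec)
        mask = binarize_large_vessels(image)
        assert np.array_equal(mask.mask, truth.vessel_mask)
        assert truth.vessel_mask.any()

    def test_determinism(self):
        spec = CCImageSpec(image_size_px=(128, 128), n_branches=5, seed=21)
        img1, _ = generate_retina_enface(spec)
        img2, _ = generate_retina_enface(spec)
        assert np.array_equal(img1.data, img2.data)


class TestBScanStack:
    def test_constant_profile_thickness(self):
        stack, truth = generate_bscan_stack(np.full(64, 300.0), 0.3,
                                            n_bscans=8, seed=0)
        assert np.allclose(truth.thickness_map_um, 300.0)
        assert np.all(stack.csi_trace - stack.bruch_trace == 100)  # 3 µm axial

    def test_luminal_fraction_bounds(self):
        with pytest.raises(ValueError):
            generate_bscan_stack(np.full(16, 300.0), 1.5)
        with pytest.raises(ValueError):
            generate_bscan_stack(np.full(16, 300.0), -0.1)

    def test_zero_and_full_lumen(self):
        stack0, t0 = generate_bscan_stack(np.full(64, 240.0), 0.0, n_bscans=8)
        assert t0.luminal_fraction == 0.0
        stack1, t1 = generate_bscan_stack(np.full(64, 240.0), 1.0, n_bscans=8)
        assert t1.luminal_fraction == 1.0
        assert np.array_equal(t1.luminal_mask, stack1.band_mask())

    def test_requested_fraction_achieved(self):
        _, truth = generate_bscan_stack(np.full(256, 300.0), 0.42,
                                        n_bscans=32, seed=4)
        assert abs(truth.luminal_fraction - 0.42) <= 0.01

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError):
            generate_bscan_stack(np.array([300.0, -5.0, 200.0]), 0.3)


class TestCohort:
    def test_zero_sd_gives_exact_means(self):
        config = CohortConfig(
            n_per_group=10,
            variables={"amt6s_pg_ml": VariableSpec(
                mean={"pop1": 100.0, "pop2": 200.0},
                sd={"pop1": 0.0, "pop2": 0.0})},
        )
        table = generate_cohort(config)
        assert (table.loc[table.group == "pop1", "amt6s_pg_ml"] == 100.0).all()
        assert (table.loc[table.group == "pop2", "amt6s_pg_ml"] == 200.0).all()

    def test_determinism(self):
        config = default_cohort_config(seed=42)
        t1 = generate_cohort(config)
        t2 = generate_cohort(config)
        assert t1.equals(t2)

    def test_unit_correlation_gives_exact_linear_dependence(self):
        # equal group means, so the pooled relation is a single line
        config = simple_config(r=1.0, anchor_mean=(5.0, 2.0),
                               mean1=(10.0, 3.0), mean2=(10.0, 3.0), n=200)
        table = generate_cohort(config)
        r = np.corrcoef(table.amt6s_pg_ml, table.metric)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_pooled_correlation_converges(self):
        config = simple_config(r=0.5, anchor_mean=(0.0, 1.0),
                               mean1=(10.0, 2.0), mean2=(14.0, 2.0),
                               n=5000, seed=2)
        table = generate_cohort(config)
        r = np.corrcoef(table.amt6s_pg_ml, table.metric)[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_invalid_correlation_rejected(self):
        config = simple_config(r=1.2)
        with pytest.raises(ValueError, match="invalid correlation"):
            generate_cohort(config)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            VariableSpec(mean={"pop1": 0, "pop2": 0},
                         sd={"pop1": -1.0, "pop2": 1.0})

    def test_marginals_preserved_under_copula(self):
        """KS distance to the configured normal < 0.02 at n = 10,000 for a
        variable whose physical bounds do not bind (choroidal thickness)."""
        config = default_cohort_config(seed=6, n_per_group=10_000)
        table = generate_cohort(config)
        spec = config.variables["ct_fovea"]
        for group in ("pop1", "pop2"):
            values = table.loc[table.group == group, "ct_fovea"]
            d, _ = sps.kstest(values, "norm",
                              args=(spec.mean[group], spec.sd[group]))
            assert d < 0.02

    def test_binding_bound_clips_and_preserves_mean(self):
        """A mean 1.5 SD above a lower bound: draws are clipped at the bound
        yet the sample mean still matches the configured mean."""
        config = simple_config(mean1=(3.0, 2.0), mean2=(3.0, 2.0),
                               bounds=(0.0, None), n=20_000, seed=8)
        table = generate_cohort(config)
        assert table.metric.min() >= 0.0
        assert (table.metric == 0.0).any()  # the bound genuinely binds
        assert table.metric.mean() == pytest.approx(3.0, abs=0.05)

    def test_sex_counts_follow_configured_fraction(self):
        table = generate_cohort(default_cohort_config(seed=1))
        males = table[table.sex == "M"].groupby(table.group).size()
        assert males["pop1"] == 10 and males["pop2"] == 12

    def test_column_layout(self):
        table = generate_cohort(default_cohort_config(seed=0))
        assert list(table.columns[:8]) == ["subject_id", "group", "age", "sex",
                                           "iop_mmHg", "ser_D", "al_mm",
                                           "amt6s_pg_ml"]
        assert len(table) == 50
        assert not table.subject_id.duplicated().any()
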