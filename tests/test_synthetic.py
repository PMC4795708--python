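"""Generator tests: bolus model, cohort calibration, determinism, readers."""

import numpy as np
import pytest
from scipy import stats as sps

from cctpipe import (
    ALL_INDEXES, CT_INDEXES, CohortConfig, GammaVariateParams,
    GenerationError, GROUP_CONTROL, GROUP_VASOSPASM,
    gamma_variate, sample_truths, simulate_reader, synthesize_cohort,
    synthesize_subject,
)
from cctpipe.synthetic import truncated_cct_moments, derive_subject_seed


class TestGammaVariate:
    def test_zero_before_and_at_arrival(self):
        p = GammaVariateParams(t0=2.0, alpha=3.0, beta=1.5, amplitude=100.0)
        assert gamma_variate(2.0, p) == 0.0
        assert gamma_variate(0.0, p) == 0.0

    def test_peak_amplitude_at_analytic_mode(self):
        p = GammaVariateParams(t0=2.0, alpha=3.0, beta=1.5, amplitude=100.0)
        assert gamma_variate(p.mode, p) == pytest.approx(100.0)

    def test_fine_grid_argmax_and_pointwise_formula(self):
        # oracle: direct formula evaluation, independent of the vector path
        p = GammaVariateParams(t0=2.0, alpha=3.0, beta=1.5, amplitude=100.0)
        t = np.linspace(0.0, 59.0, 59001)
        y = gamma_variate(t, p)
        assert t[np.argmax(y)] == pytest.approx(6.5, abs=2e-3)
        u = (4.0 - 2.0) / (3.0 * 1.5)
        expected = 100.0 * u ** 3.0 * np.exp(3.0 - (4.0 - 2.0) / 1.5)
        assert gamma_variate(4.0, p) == pytest.approx(expected, rel=1e-12)

    def test_single_peak(self, rng):
        p = GammaVariateParams(t0=float(rng.uniform(0, 5)),
                               alpha=float(rng.uniform(1, 6)),
                               beta=float(rng.uniform(0.5, 4)),
                               amplitude=50.0)
        y = gamma_variate(np.linspace(0, 80, 8000), p)
        d = np.sign(np.diff(y[y > 0]))
        # one sign change: strictly rising then strictly falling
        assert (np.diff(d) != 0).sum() == 1

    @pytest.mark.parametrize("field,value", [
        ("alpha", -1.0), ("beta", 0.0), ("amplitude", 0.0), ("t0", -0.1)])
    def test_invalid_params_name_the_field(self, field, value):
        kwargs = dict(t0=1.0, alpha=2.0, beta=1.0, amplitude=10.0)
        kwargs[field] = value
        with pytest.raises(ValueError, match=field):
            GammaVariateParams(**kwargs)


class TestTruthSampling:
    def test_default_cohort_composition(self):
        truths = sample_truths(CohortConfig(seed=1))
        assert len(truths) == 41
        assert sum(t.group == GROUP_CONTROL for t in truths) == 19
        assert sum(t.group == GROUP_VASOSPASM for t in truths) == 22

    def test_true_cct_equals_mode_difference(self):
        for truth in sample_truths(CohortConfig(n_control=3, n_vasospasm=3,
                                                seed=2)):
            for name in CT_INDEXES:
                art = truth.ctp_params[name.split("_")[1]]
                ven = truth.ctp_params["SSS"]
                assert ven.mode - art.mode == pytest.approx(
                    truth.true_cct_per_index[name], abs=1e-9)
            assert (truth.dsa_params["SSS_right"].mode
                    - truth.dsa_params["RA2"].mode) == pytest.approx(
                truth.true_cct_per_index["XA-CCT_RA2"], abs=1e-9)

    def test_central_volume_identity_in_truth(self):
        for truth in sample_truths(CohortConfig(n_control=2, n_vasospasm=2,
                                                seed=3)):
            assert truth.true_mtt == pytest.approx(
                60.0 * truth.true_cbv / truth.true_cbf, rel=1e-12)
            assert 3 <= truth.gcs <= 15
            assert truth.fisher_grade in ("I", "II", "III", "IV")

    def test_group_calibration_converges_at_n2000(self):
        """Sample moments of true CCTs match the truncated-normal law the
        generator draws from, within 3 standard errors at n = 2000."""
        cfg = CohortConfig(n_control=2000, n_vasospasm=2000, seed=4)
        truths = sample_truths(cfg)
        for group, col in ((GROUP_CONTROL, 0), (GROUP_VASOSPASM, 2)):
            vals = np.array([t.true_cct_per_index["CT-CCT_A2"]
                             for t in truths if t.group == group])
            mu, sd = cfg.group_cct["CT-CCT_A2"][col], cfg.group_cct["CT-CCT_A2"][col + 1]
            tmean, tsd = truncated_cct_moments(mu, sd, cfg.cct_floor)
            se = tsd / np.sqrt(len(vals))
            assert abs(vals.mean() - tmean) < 3 * se
            assert abs(vals.std(ddof=1) - tsd) < 3 * tsd / np.sqrt(2 * len(vals))

    def test_cct_floor_respected(self):
        cfg = CohortConfig(n_control=200, n_vasospasm=0, seed=5)
        truths = sample_truths(cfg)
        assert min(min(t.true_cct_per_index.values()) for t in truths) >= 0.5


class TestSubjectSynthesis:
    def test_determinism_bit_identical(self, noiseless_config):
        truth = sample_truths(noiseless_config)[0]
        a = synthesize_subject(truth, noiseless_config, seed=9)
        cfg2 = CohortConfig(**{**noiseless_config.__dict__})
        b = synthesize_subject(truth, cfg2, seed=9)
        assert np.array_equal(a.ctp.data, b.ctp.data)
        assert np.array_equal(a.dsa.data, b.dsa.data)
        assert np.array_equal(a.masks_ctp.data, b.masks_ctp.data)

    def test_noisy_determinism_and_seed_sensitivity(self, small_config):
        truth = sample_truths(small_config)[0]
        a = synthesize_subject(truth, small_config, seed=9)
        b = synthesize_subject(truth, small_config, seed=9)
        c = synthesize_subject(truth, small_config, seed=10)
        assert np.array_equal(a.ctp.data, b.ctp.data)
        assert not np.array_equal(a.ctp.data, c.ctp.data)

    def test_dsa_mask_frame_is_zero(self, noiseless_subject):
        assert np.all(noiseless_subject.dsa.data[..., 0] == 0.0)

    def test_shapes_follow_config(self, noiseless_subject, noiseless_config):
        cfg = noiseless_config
        assert noiseless_subject.ctp.data.shape == cfg.grid_ctp + (cfg.n_frames_ctp,)
        assert noiseless_subject.dsa.data.shape == cfg.grid_dsa + (cfg.n_frames_dsa,)

    def test_labels_cover_both_conventions(self, noiseless_subject):
        assert set(noiseless_subject.masks_ctp.labels) == {
            "A2", "RM2", "LM2", "SSS", "TISSUE"}
        assert set(noiseless_subject.masks_dsa.labels) == {
            "RA2", "LA2", "RM2", "LM2", "SSS_right", "SSS_left"}

    def test_too_small_grid_raises(self):
        cfg = CohortConfig(grid_ctp=(16, 16, 2))
        with pytest.raises(GenerationError):
            cfg.validate()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_frames_ctp=1).validate()
        with pytest.raises(ValueError):
            CohortConfig(noise_sd=-1.0).validate()

    def test_cohort_subject_seeds_are_reproducible_subsets(self):
        cfg = CohortConfig(n_control=2, n_vasospasm=1, noise_sd=0.0, seed=6)
        cohort = synthesize_cohort(cfg)
        truth = sample_truths(cfg)[1]
        solo = synthesize_subject(truth, cfg, derive_subject_seed(cfg.seed, 1))
        assert np.array_equal(cohort[1].ctp.data, solo.ctp.data)


class TestSimulateReader:
    def test_zero_jitter_is_identity(self, noiseless_subject):
        masks = noiseless_subject.masks_ctp
        moved = simulate_reader(masks, 0.0, seed=3)
        assert np.array_equal(moved.data, masks.data)

    def test_same_seed_same_displacement(self, noiseless_subject):
        masks = noiseless_subject.masks_ctp
        a = simulate_reader(masks, 2.0, seed=3)
        b = simulate_reader(masks, 2.0, seed=3)
        assert np.array_equal(a.data, b.data)

    def test_mask_sizes_preserved_for_vessels(self, noiseless_subject):
        masks = noiseless_subject.masks_dsa
        moved = simulate_reader(masks, 2.0, seed=11)
        for name, value in masks.labels.items():
            assert (moved.data == value).sum() == (masks.data == value).sum()

    def test_edge_mask_clamps_and_flags(self):
        """A displacement that would push an ROI over the grid edge is
        clamped so the mask stays whole, and the label is flagged."""
        from cctpipe.tdc import LabeledMasks
        data = np.zeros((16, 16), dtype=np.int16)
        data[1:4, 1:4] = 1
        masks = LabeledMasks(data=data, labels={"A2": 1})
        moved = simulate_reader(masks, 50.0, seed=1)
        assert "A2" in moved.clipped
        assert moved.mask_for("A2").sum() == 9    # never loses voxels

    def test_negative_jitter_rejected(self, noiseless_subject):
        with pytest.raises(ValueError):
            simulate_reader(noiseless_subject.masks_ctp, -1.0, seed=0)
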