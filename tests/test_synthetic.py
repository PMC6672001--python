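"""Generator contracts: determinism, validation, planted-truth fidelity."""

import numpy as np
import pytest

from callosal import synthetic
from callosal.errors import ValidationError


class TestRoiTimeseries:
    LABELS = ["A_L", "A_R", "B_L", "B_R"]

    def test_deterministic_given_seed(self):
        c = np.eye(4)
        kw = dict(n_subjects_per_group={"WT": 2}, roi_labels=self.LABELS,
                  group_correlations={"WT": c}, seed=11)
        s1, _ = synthetic.gen_roi_timeseries(**kw)
        s2, _ = synthetic.gen_roi_timeseries(**kw)
        assert all(np.array_equal(a.data, b.data) for a, b in zip(s1, s2))

    def test_identity_correlation_gives_small_sample_r(self):
        subs, _ = synthetic.gen_roi_timeseries(
            {"WT": 1}, self.LABELS, {"WT": np.eye(4)}, 150, 2.0, seed=2)
        r = np.corrcoef(subs[0].data)
        off = r[~np.eye(4, dtype=bool)]
        # 95% Fisher bound for 150 points is |z| < 2/sqrt(147) ~ 0.165;
        # band-limiting reduces the effective dof, so allow the stated 0.35
        assert np.abs(off).max() < 0.35

    def test_signals_are_band_limited(self):
        subs, _ = synthetic.gen_roi_timeseries(
            {"WT": 1}, self.LABELS, {"WT": np.eye(4)}, 150, 2.0, seed=3)
        spec = np.abs(np.fft.rfft(subs[0].data, axis=1)) ** 2
        freqs = np.fft.rfftfreq(150, 2.0)
        out_of_band = spec[:, (freqs < 0.01) | (freqs > 0.1)].sum()
        assert out_of_band < 1e-18 * spec.sum()

    def test_group_ordering_recovered_across_seeds(self):
        """Homotopic r = 0.8 (WT) vs 0.5 (mutant): group means keep their
        order in >= 95% of reseeded runs."""
        c_wt, c_mut = np.eye(2), np.eye(2)
        c_wt[0, 1] = c_wt[1, 0] = 0.8
        c_mut[0, 1] = c_mut[1, 0] = 0.5
        from callosal import fc

        wins = 0
        n_runs = 200
        for seed in range(n_runs):
            subs, _ = synthetic.gen_roi_timeseries(
                {"WT": 5, "MUT": 5}, ["X_L", "X_R"],
                {"WT": c_wt, "MUT": c_mut}, 150, 2.0, seed=seed)
            z = {g: np.mean([fc.fc_matrix(s).z[0, 1] for s in subs
                             if s.group == g]) for g in ("WT", "MUT")}
            wins += z["WT"] > z["MUT"]
        assert wins >= 0.95 * n_runs

    def test_validation(self):
        bad = np.array([[1.0, 0.99], [0.99, 0.5]])  # diagonal not 1
        with pytest.raises(ValidationError):
            synthetic.gen_roi_timeseries({"WT": 1}, ["a", "b"], {"WT": bad})
        notpd = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValidationError):
            synthetic.gen_roi_timeseries({"WT": 1}, ["a", "b"], {"WT": notpd})
        with pytest.raises(ValidationError):
            synthetic.gen_roi_timeseries({"WT": 1}, ["a", "b"],
                                         {"WT": np.eye(2)}, n_timepoints=0)


class TestDwi:
    def test_isotropic_closed_form(self, acquisition):
        ev = np.array([[0.7e-3, 0.7e-3, 0.7e-3]])
        signal, _ = synthetic.gen_dwi(ev, None, 1000.0, acquisition)
        weighted = signal[0][~acquisition.is_b0]
        assert np.allclose(weighted / 1000.0, np.exp(-0.56), rtol=1e-12)

    def test_b0_equals_s0_exactly(self, acquisition):
        signal, _ = synthetic.gen_dwi(np.array([[1e-3, 2e-4, 1e-4]]), None,
                                      1234.5, acquisition)
        assert signal[0][acquisition.is_b0] == pytest.approx(1234.5, abs=0)

    def test_stick_orthogonal_direction_unattenuated(self):
        from callosal.io import Acquisition

        acq = Acquisition([0.0, 800.0], [[0, 0, 0], [0, 1, 0]])
        signal, _ = synthetic.gen_dwi(np.array([[1.7e-3, 0.0, 0.0]]),
                                      [[1.0, 0.0, 0.0]], 1000.0, acq)
        assert signal[0][1] == pytest.approx(1000.0)

    def test_negative_eigenvalue_rejected(self, acquisition):
        with pytest.raises(ValidationError):
            synthetic.gen_dwi(np.array([[1e-3, -1e-4, 0.0]]), None, 1.0,
                              acquisition)

    def test_noise_sd_scales_with_snr(self, acquisition):
        ev = np.tile([0.7e-3, 0.7e-3, 0.7e-3], (2000, 1))
        clean, _ = synthetic.gen_dwi(ev, None, 1000.0, acquisition)
        noisy, _ = synthetic.gen_dwi(ev, None, 1000.0, acquisition, snr=20,
                                     seed=1)
        assert (noisy - clean).std() == pytest.approx(50.0, rel=0.05)


class TestEmImage:
    def test_single_annulus_hole_area(self):
        spec = synthetic.AxonSpec((60.0, 60.0), 40.0, 60.0)
        img, _ = synthetic.gen_em_image([spec], (120, 120))
        # inner hole: pixels above the mid-intensity cut (where the 1-px
        # anti-aliased edge crosses the true radius) inside the outer radius
        yy, xx = np.mgrid[:120, :120]
        inside = np.hypot(yy - 60, xx - 60) < 25
        hole = (img > 130.0) & inside
        assert hole.sum() == pytest.approx(np.pi * 20 ** 2, rel=0.02)

    def test_zero_axons_blank(self):
        img, truth = synthetic.gen_em_image([], (30, 30))
        assert np.all(img == 200.0) and len(truth["axons"]) == 0

    def test_overlap_enforcement(self):
        specs = [synthetic.AxonSpec((50.0, 50.0), 30.0, 50.0),
                 synthetic.AxonSpec((60.0, 60.0), 30.0, 50.0)]
        with pytest.raises(ValidationError):
            synthetic.gen_em_image(specs, (120, 120))
        img, _ = synthetic.gen_em_image(specs, (120, 120),
                                        enforce_non_overlap=False)
        assert img.min() < 200.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.AxonSpec((10, 10), 50.0, 40.0)

    def test_truth_g_in_unit_interval(self, rng):
        specs, size = synthetic.random_axon_specs(12, rng)
        _, truth = synthetic.gen_em_image(specs, size)
        assert ((truth["axons"].g_ratio > 0) & (truth["axons"].g_ratio < 1)).all()


class TestMeaTrace:
    def test_pure_noise_stays_under_threshold(self):
        """60 s of Gaussian noise: P(|x| > 5.5 sd) ~ 2e-8 per sample, so
        ~0.02 expected exceedances per trace."""
        exceed = 0
        for seed in range(5):
            trace, _ = synthetic.gen_mea_trace(60.0, 10_000.0, 7.0, [], seed=seed)
            exceed += int((trace < -5.5 * 7.0).sum())
        assert exceed <= 1

    def test_planted_burst_truth(self):
        times = 1.0 + np.arange(5) * 0.010
        _, truth = synthetic.gen_mea_trace(5.0, 10_000.0, 5.0, times, 8.0)
        assert len(truth["bursts"]) == 1
        assert truth["bursts"][0][2] == 5

    def test_zero_duration_empty(self):
        trace, truth = synthetic.gen_mea_trace(0.0, 10_000.0, 1.0, [])
        assert trace.size == 0

    def test_low_sampling_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.gen_mea_trace(1.0, 500.0, 1.0, [])

    def test_spike_outside_duration_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.gen_mea_trace(1.0, 10_000.0, 1.0, [2.0])


class TestBehaviourTables:
    def test_zero_noise_ppi_exact(self):
        from callosal import behaviour as bh

        tables, truth = synthetic.gen_behaviour_tables(
            {"ppi": {"true_ppi_per_db": {7: 60.0}, "startle_sd": 0.0}}, seed=0)
        per_db, avg = bh.ppi_percent(tables["startle"], "s1")
        assert per_db[7.0] == pytest.approx(60.0, abs=0)

    def test_certain_alternation_scores_100(self):
        from callosal import behaviour as bh

        tables, _ = synthetic.gen_behaviour_tables(
            {"visits": {"alternation_probability": 1.0, "walk_length": 20}},
            seed=1)
        arms = tables["visits"].sort_values("order").arm.tolist()
        score, _ = bh.alternation_score(arms)
        assert score == 100.0

    def test_zero_slip_probability(self):
        tables, _ = synthetic.gen_behaviour_tables(
            {"slips": {"slip_probability": 0.0, "n_steps": 30}}, seed=2)
        assert (tables["slips"].n_slips == 0).all()

    def test_preference_truth_exact(self):
        from callosal import behaviour as bh

        tables, _ = synthetic.gen_behaviour_tables(
            {"exploration": {"preference_index": 65.0}}, seed=3)
        row = tables["exploration"].iloc[0]
        assert bh.preference_index(row.time_novel_s, row.time_familiar_s) == \
            pytest.approx(65.0)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.gen_behaviour_tables(
                {"ppi": {"true_ppi_per_db": {7: 60}, "n_trials": 0}})
        with pytest.raises(ValidationError):
            synthetic.gen_behaviour_tables(
                {"visits": {"alternation_probability": 1.5}})
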