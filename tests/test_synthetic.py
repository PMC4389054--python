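"""Ground-truth fidelity of the synthetic EEG cohort generator."""

import numpy as np
import pytest
from scipy import stats

import phantomcoupling as pc
from phantomcoupling.nesting import hilbert_envelope


def _cfg(**kw):
    base = dict(duration_s=30.0, rate_hz=128.0, seed=1)
    base.update(kw)
    return pc.CouplingConfig(**base)


class TestSimulateSources:
    def test_determinism(self):
        a = pc.simulate_subject_sources(_cfg(mod_depth=0.5))
        b = pc.simulate_subject_sources(_cfg(mod_depth=0.5))
        np.testing.assert_array_equal(a.source_currents, b.source_currents)

    def test_truth_labels_cover_all_sources(self):
        sim = pc.simulate_subject_sources(_cfg())
        assert len(sim.truth) == sim.source_currents.shape[0]
        assert sim.truth[sim.theta_index] == "theta-carrier"
        assert sim.truth[sim.gamma_index] == "gamma-modulated"

    def test_no_modulation_means_constant_envelope(self):
        sim = pc.simulate_subject_sources(_cfg(mod_depth=0.0))
        g = sim.source_currents[sim.gamma_index, 2]
        env = hilbert_envelope(g)[50:-50]
        assert np.ptp(env) < 0.02 * env.mean()

    def test_full_modulation_envelope_tracks_theta(self):
        sim = pc.simulate_subject_sources(_cfg(mod_depth=1.0))
        theta = sim.source_currents[sim.theta_index, 2]
        g = sim.source_currents[sim.gamma_index, 2]
        env = hilbert_envelope(g)
        r = np.corrcoef(theta[100:-100], env[100:-100])[0, 1]
        assert r > 0.99

    @pytest.mark.parametrize("depth", [0.3, 0.8])
    def test_modulation_depth_recovered_by_regression(self, depth):
        # envelope = 1 - d + d*(theta+1)/2 for a unit sinusoid carrier, so
        # the slope of envelope on theta is d/2
        cfg = _cfg(mod_depth=depth, duration_s=120.0)
        sim = pc.simulate_subject_sources(cfg)
        theta = sim.source_currents[sim.theta_index, 2]
        env = hilbert_envelope(sim.source_currents[sim.gamma_index, 2])
        slope = stats.linregress(theta[100:-100], env[100:-100]).slope
        assert abs(2 * slope - depth) < 0.05

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            _cfg(mod_depth=1.5)
        with pytest.raises(ValueError):
            _cfg(gamma_hz=40.0, rate_hz=64.0)
        with pytest.raises(ValueError):
            _cfg(theta_hz=9.0)


class TestProjectToSensors:
    def test_zero_currents_give_unit_variance_noise(self, leadfield16):
        sim = pc.simulate_subject_sources(_cfg())
        sim.source_currents[:] = 0.0
        rec = pc.project_to_sensors(sim, leadfield16, snr_db=10.0, seed=0)
        assert rec.data.var() == pytest.approx(1.0, rel=0.05)

    def test_single_source_matches_gain_column_pattern(self, leadfield16):
        sim = pc.simulate_subject_sources(_cfg())
        sim.source_currents[:] = 0.0
        wave = np.sin(np.linspace(0, 20, sim.source_currents.shape[2]))
        sim.source_currents[3, 2] = wave  # z-component of source 3 only
        rec = pc.project_to_sensors(sim, leadfield16, snr_db=np.inf, seed=0)
        expected = np.outer(leadfield16.gain[:, 3 * 3 + 2], wave)
        np.testing.assert_allclose(rec.data, expected, atol=1e-12)

    def test_determinism(self, leadfield16):
        sim = pc.simulate_subject_sources(_cfg())
        a = pc.project_to_sensors(sim, leadfield16, 10.0, seed=7)
        b = pc.project_to_sensors(sim, leadfield16, 10.0, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_snr_sets_noise_variance(self, leadfield16):
        sim = pc.simulate_subject_sources(_cfg(duration_s=60.0))
        clean = pc.project_to_sensors(sim, leadfield16, np.inf, seed=0)
        noisy = pc.project_to_sensors(sim, leadfield16, 0.0, seed=0)
        resid_power = np.mean((noisy.data - clean.data) ** 2)
        assert resid_power == pytest.approx(np.mean(clean.data**2), rel=0.05)


class TestStaircase:
    def test_start_frequency_terminates_immediately(self):
        rec = pc.simulate_matching_staircase(1000.0, 30.0, 20.0)
        assert rec.matched_hz == 1000.0

    def test_start_level_terminates_immediately(self):
        rec = pc.simulate_matching_staircase(1000.0, 30.0, 20.0)
        assert rec.matched_db_hl == 30.0
        assert rec.matched_db_sl == 10.0

    def test_octave_ascent_to_4khz(self):
        rec = pc.simulate_matching_staircase(4000.0, 30.0, 20.0)
        assert rec.matched_hz == 4000.0

    def test_db_sl_identity(self):
        rec = pc.simulate_matching_staircase(3000.0, 47.0, 25.0)
        assert rec.matched_db_sl == rec.matched_db_hl - rec.threshold_db_hl

    def test_exhaustive_grid_convergence(self):
        """Pitch within a half-octave and level within 2 dB for every truth
        on a grid spanning the staircase bounds."""
        for true_hz in np.geomspace(100.0, 12000.0, 25):
            for true_db in [3.0, 17.0, 30.5, 52.0, 79.0]:
                for thr in [0.0, 15.0, 40.0]:
                    rec = pc.simulate_matching_staircase(true_hz, true_db, thr)
                    assert abs(np.log2(rec.matched_hz / true_hz)) <= 0.5 + 1e-9
                    assert abs(rec.matched_db_hl - true_db) <= 2.0 + 1e-9
                    assert rec.matched_db_hl <= 80.0
                    assert rec.matched_hz <= 12000.0

    def test_rejects_truth_outside_bounds(self):
        with pytest.raises(ValueError):
            pc.simulate_matching_staircase(20000.0, 30.0, 20.0)
        with pytest.raises(ValueError):
            pc.simulate_matching_staircase(1000.0, 95.0, 20.0)


class TestCohort:
    def test_three_subjects_unique_ids(self):
        _, behavior, truth = pc.generate_cohort(3, seed=0, make_recordings=False)
        assert len(behavior) == 3
        assert behavior.subject_id.is_unique
        assert set(behavior.subject_id) == set(truth.subject_id)

    def test_perfect_link_noise_free(self):
        _, behavior, truth = pc.generate_cohort(
            50, behavior_link_r=1.0, seed=3, make_recordings=False
        )
        r = np.corrcoef(truth.mod_depth, behavior.nrs)[0, 1]
        assert r == pytest.approx(1.0, abs=0.02)  # only clipping can dent it

    def test_link_recovery_monte_carlo(self):
        """Mean recovered corr(mod_depth, nrs) over 50 seeds at n=200 lands
        within +/-0.1 of the 0.5 target."""
        rs = []
        for seed in range(50):
            _, behavior, truth = pc.generate_cohort(
                200, behavior_link_r=0.5, seed=seed, make_recordings=False
            )
            rs.append(np.corrcoef(truth.mod_depth, behavior.nrs)[0, 1])
        assert abs(np.mean(rs) - 0.5) < 0.1

    def test_matched_level_independent_of_coupling(self):
        rs = []
        for seed in range(30):
            _, behavior, truth = pc.generate_cohort(
                136, behavior_link_r=0.45, seed=seed, make_recordings=False
            )
            rs.append(np.corrcoef(truth.mod_depth, behavior.db_sl)[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_db_sl_identity_on_every_record(self):
        _, behavior, _ = pc.generate_cohort(20, seed=5, make_recordings=False)
        np.testing.assert_allclose(
            behavior.db_sl, behavior.db_hl - behavior.threshold_db, atol=1e-12
        )

    def test_recordings_deterministic(self, leadfield16):
        cfg = pc.CouplingConfig(duration_s=5.0, rate_hz=128.0)
        a = pc.generate_cohort(3, seed=9, coupling=cfg, leadfield=leadfield16)
        b = pc.generate_cohort(3, seed=9, coupling=cfg, leadfield=leadfield16)
        for ra, rb in zip(a[0], b[0]):
            np.testing.assert_array_equal(ra.data, rb.data)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            pc.generate_cohort(10, mod_depth_range=(0.5, 1.5), make_recordings=False)
        with pytest.raises(ValueError):
            pc.generate_cohort(2, make_recordings=False)


def test_cohort_roundtrip_through_text(tmp_path, leadfield16):
    cfg = pc.CouplingConfig(duration_s=5.0, rate_hz=128.0)
    recs, behavior, truth = pc.generate_cohort(
        3, seed=2, coupling=cfg, leadfield=leadfield16
    )
    pc.write_cohort(tmp_path, recs, behavior, truth)
    rec = pc.read_recording(tmp_path / f"{behavior.subject_id[0]}.tsv")
    assert rec.rate_hz == 128.0
    assert rec.channel_labels == recs[0].channel_labels
    np.testing.assert_allclose(rec.data, recs[0].data, rtol=1e-5, atol=1e-8)
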