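"""Monte Carlo engine: free paths, channel sampling, pair kinematics,
Compton sampling, positron transport, annihilation emission, full chain."""

import numpy as np
import pytest
from scipy import integrate, stats

import pptsim
from pptsim import nucdata
from pptsim.phantom import PhantomGrid, build_cube
from pptsim.transport import (
    CHANNEL_NONE,
    MEC2_MEV,
    PhotonState,
    TransportConfig,
    _track_batch,
    emit_annihilation_photons,
    isotropic_directions,
    run_simulation,
    sample_compton,
    sample_pair_energies,
    trace_photon,
    transport_positron,
)


def _infinite_water():
    return build_cube(50.0, "water", "point", voxel_size=5.0)


class TestPhotonTracking:
    def test_free_path_in_infinite_water_matches_mean_free_path(self, rng):
        grid = _infinite_water()
        n = 200_000
        pos = np.zeros((n, 3))
        dirs = isotropic_directions(rng, n)
        ch, end, path = _track_batch(
            grid, pos, dirs, np.full(n, 2.617), rng, infinite_medium=True
        )
        assert np.all(ch > 0)
        expect = 10.0 * nucdata.mean_free_path("water", 2.617)  # mm
        assert path.mean() == pytest.approx(expect, rel=0.01)

    def test_delta_tracking_free_paths_are_exponential(self, rng):
        """Two-sample KS against direct exponential sampling."""
        grid = _infinite_water()
        n = 10_000
        ch, end, path = _track_batch(
            grid,
            np.zeros((n, 3)),
            isotropic_directions(rng, n),
            np.full(n, 2.617),
            rng,
            infinite_medium=True,
        )
        mfp_mm = 10.0 * nucdata.mean_free_path("water", 2.617)
        direct = rng.exponential(mfp_mm, n)
        assert stats.ks_2samp(path, direct).pvalue > 0.01

    def test_vacuum_grid_always_escapes(self, rng):
        grid = build_cube(100.0, "air", "point")
        photon = PhotonState(np.zeros(3), np.array([0.0, 0.0, 1.0]), 2.617)
        channel, _ = trace_photon(grid, photon, rng)
        assert channel == "none"

    def test_two_material_slab_transmission(self, rng):
        """Transmission through a water|bone slab matches the closed form."""
        mat = np.zeros((20, 20, 20), dtype=np.uint8)
        mat[10:, :, :] = 1  # second half bone
        grid = PhantomGrid(mat, np.full(3, 5.0), ("water", "bone"))
        n = 50_000
        pos = np.tile(np.array([-49.99, 0.0, 0.0]), (n, 1))
        dirs = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
        ch, _, _ = _track_batch(grid, pos, dirs, np.full(n, 2.617), rng)
        trans = np.mean(ch == CHANNEL_NONE)
        mu_w = 1.0 / nucdata.mean_free_path("water", 2.617)
        mu_b = 1.0 / nucdata.mean_free_path("bone", 2.617)
        expect = np.exp(-mu_w * 5.0 - mu_b * 5.0)  # 5 cm each
        sigma = np.sqrt(expect * (1 - expect) / n)
        assert abs(trans - expect) < 3 * sigma

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit vector"):
            PhotonState(np.zeros(3), np.array([1.0, 1.0, 0.0]), 2.617)


class TestPairKinematics:
    def test_energy_conservation_is_exact(self, rng):
        tp, tm = sample_pair_energies(2.617, rng, 10_000)
        np.testing.assert_allclose(tp + tm, 2.617 - 2 * MEC2_MEV, atol=1e-12)
        assert np.all(tp >= 0) and np.all(tm >= 0)

    def test_threshold_photon_gives_zero_energies(self, rng):
        tp, tm = sample_pair_energies(2 * MEC2_MEV, rng)
        assert tp == 0.0 and tm == 0.0

    def test_below_threshold_raises(self, rng):
        with pytest.raises(ValueError, match="threshold"):
            sample_pair_energies(1.0, rng)

    def test_mean_positron_energy_in_published_band(self, rng):
        tp, _ = sample_pair_energies(2.617, rng, 100_000)
        assert 0.76 <= tp.mean() <= 0.80

    def test_sharing_is_symmetric(self, rng):
        """The sharing distribution is invariant under e+ <-> e-."""
        tp, tm = sample_pair_energies(2.617, rng, 100_000)
        assert stats.ks_2samp(tp, tm).pvalue > 0.01

    def test_flat_model_mean(self, rng):
        tp, _ = sample_pair_energies(2.617, rng, 50_000, model="flat")
        assert tp.mean() == pytest.approx((2.617 - 1.022) / 2, abs=0.01)


class TestCompton:
    def test_scattered_energy_bounds(self, rng):
        e, cos_t = sample_compton(2.617, rng, 20_000)
        k = 2.617 / MEC2_MEV
        e_min = 2.617 / (1 + 2 * k)  # backscatter limit
        assert np.all(e <= 2.617 + 1e-12)
        assert np.all(e >= e_min - 1e-12)
        assert np.all(np.abs(cos_t) <= 1)

    def test_mean_scattered_energy_matches_klein_nishina_quadrature(self, rng):
        from pptsim.transport import _kn_pdf_eps

        e_gamma = 2.617
        k = e_gamma / MEC2_MEV
        eps_min = 1 / (1 + 2 * k)
        norm, _ = integrate.quad(lambda x: _kn_pdf_eps(k, np.array([x]))[0],
                                 eps_min, 1)
        mean_eps, _ = integrate.quad(
            lambda x: x * _kn_pdf_eps(k, np.array([x]))[0], eps_min, 1
        )
        expect = e_gamma * mean_eps / norm
        e, _ = sample_compton(e_gamma, rng, 100_000)
        assert e.mean() == pytest.approx(expect, rel=0.02)


class TestPositronTransport:
    def test_zero_energy_stays_put(self, rng):
        grid = _infinite_water()
        r_a, t, escaped = transport_positron(0.0, np.zeros(3), grid, rng)
        np.testing.assert_array_equal(r_a, np.zeros(3))
        assert not escaped

    def test_displacement_bounded_by_csda_range(self, positron_sample):
        t_plus, ranges, escaped = positron_sample
        csda_mm = 10.0 * nucdata.csda_range("water", t_plus)
        assert np.all(ranges[~escaped] <= csda_mm[~escaped] + 1e-6)

    def test_mean_range_matches_study(self, positron_sample):
        _, ranges, escaped = positron_sample
        assert ranges[~escaped].mean() == pytest.approx(2.2, rel=0.15)

    def test_range_endpoint_matches_study(self, positron_sample):
        _, ranges, escaped = positron_sample
        assert np.percentile(ranges[~escaped], 99.9) == pytest.approx(7.0, rel=0.2)

    def test_start_outside_grid_rejected(self, rng):
        grid = _infinite_water()
        with pytest.raises(ValueError, match="outside"):
            transport_positron(0.5, np.array([1000.0, 0, 0]), grid, rng)


class TestAnnihilationEmission:
    def test_back_to_back_by_default(self, rng):
        d1, d2 = emit_annihilation_photons(
            np.zeros((500, 3)), np.zeros(500), rng, n=500
        )
        np.testing.assert_allclose(d1 + d2, 0.0, atol=1e-9)

    def test_emission_axes_uniform_on_sphere(self, rng):
        """Rayleigh test of uniformity at alpha = 0.01."""
        d1, _ = emit_annihilation_photons(
            np.zeros((10_000, 3)), np.zeros(10_000), rng, n=10_000
        )
        resultant = d1.mean(axis=0)
        statistic = 3 * len(d1) * np.sum(resultant**2)  # ~ chi2(3) under H0
        assert stats.chi2.sf(statistic, df=3) > 0.01

    def test_acollinearity_fwhm(self, rng):
        fwhm_deg = 0.5
        d1, d2 = emit_annihilation_photons(
            np.zeros((200_000, 3)), np.zeros(200_000), rng,
            acollinearity_fwhm_deg=fwhm_deg, n=200_000,
        )
        ang = np.degrees(np.arccos(np.clip(np.sum(-d1 * d2, axis=1), -1, 1)))
        # half-normal sample: recover the Gaussian sigma from E|x|
        sigma = ang.mean() * np.sqrt(np.pi / 2)
        assert sigma * 2.3548 == pytest.approx(fwhm_deg, rel=0.1)


class TestFullChain:
    def test_empty_run(self, water10_grid):
        log = run_simulation(water10_grid, 0, seed=1)
        assert log.n_primaries == 0 and log.n_pairs == 0

    def test_seeded_runs_are_identical(self, water10_grid):
        a = run_simulation(water10_grid, 20_000, seed=7)
        b = run_simulation(water10_grid, 20_000, seed=7)
        np.testing.assert_array_equal(a.first_channel, b.first_channel)
        np.testing.assert_array_equal(a.pair_r_p, b.pair_r_p)
        np.testing.assert_array_equal(a.ann_r_a, b.ann_r_a)

    def test_pair_energy_bookkeeping_in_log(self, water10_log):
        """T+ + T- + 1.022 equals the photon energy at interaction."""
        log = water10_log
        e_at_pair = log.pair_t_plus + log.pair_t_minus + 2 * MEC2_MEV
        assert np.all(e_at_pair <= 2.617 + 1e-9)
        # primaries dominate: most pair events occur at the full energy
        primary = np.isclose(e_at_pair, 2.617, atol=1e-9)
        assert primary.mean() > 0.9

    def test_every_annihilation_has_parent_pair(self, water10_log):
        log = water10_log
        assert log.n_annihilations <= log.n_pairs
        assert np.all(log.ann_pair_index >= 0)
        assert np.all(log.ann_pair_index < log.n_pairs)
        np.testing.assert_array_equal(
            log.ann_history, log.pair_history[log.ann_pair_index]
        )

    def test_annihilation_displacement_within_csda(self, water10_log):
        log = water10_log
        ranges = np.linalg.norm(log.positron_range_vectors, axis=1)
        csda_mm = 10.0 * nucdata.csda_range(
            "water", log.pair_t_plus[log.ann_pair_index]
        )
        voxel_diag = np.sqrt(3.0)
        assert np.all(ranges <= csda_mm + voxel_diag)

    def test_channel_tags_partition_histories(self, budget_log):
        assert len(budget_log.first_channel) == budget_log.n_primaries
        assert set(np.unique(budget_log.first_channel)) <= {0, 1, 2, 3}

    def test_first_interaction_fractions_match_oracle(self, budget_log):
        """Monte Carlo budget vs direction-integrated analytic oracle."""
        frac = pptsim.interaction_fractions(budget_log)
        oracle = pptsim.first_interaction_oracle(10.0, "water", 2.617)
        n = budget_log.n_primaries
        for ch in ("none", "compton", "pair"):
            sigma = np.sqrt(oracle[ch] * (1 - oracle[ch]) / n)
            assert abs(frac[ch] - oracle[ch]) < 3 * sigma, ch

    @pytest.mark.parametrize("side", [10.0, 50.0, 100.0])
    def test_oracle_agreement_across_cube_sizes(self, side, rng):
        grid = build_cube(side, "water", "point")
        log = run_simulation(
            grid, 200_000, TransportConfig(track_secondaries=False), seed=int(side)
        )
        frac = pptsim.interaction_fractions(log)
        oracle = pptsim.first_interaction_oracle(side, "water", 2.617)
        for ch in ("none", "compton"):
            sigma = np.sqrt(oracle[ch] * (1 - oracle[ch]) / log.n_primaries)
            assert abs(frac[ch] - oracle[ch]) < 3.5 * sigma, (side, ch)

    def test_infinite_medium_everything_interacts(self):
        grid = build_cube(50.0, "water", "point", voxel_size=5.0)
        cfg = TransportConfig(infinite_medium=True, track_secondaries=False)
        log = run_simulation(grid, 5_000, cfg, seed=3)
        frac = pptsim.interaction_fractions(log)
        assert frac["none"] == 0.0

    def test_annihilation_profile_broader_than_production(self, water10_log):
        """Positron range only broadens the localization core (compare a
        robust core-width statistic rather than a noisy half-max crossing)."""
        log = water10_log

        def core_width(pos):
            x = pos[:, 0]
            x = x[np.abs(x) <= 10.0]
            return x.std()

        assert core_width(log.ann_r_a) >= core_width(log.pair_r_p)

    def test_event_log_hdf5_roundtrip(self, tmp_path, water10_grid):
        cfg = TransportConfig(track_annihilation_photons=True)
        log = run_simulation(water10_grid, 50_000, cfg, seed=9)
        path = tmp_path / "events.h5"
        log.save(path)
        loaded = pptsim.EventLog.load(path)
        assert loaded.n_primaries == log.n_primaries
        np.testing.assert_array_equal(loaded.pair_r_p, log.pair_r_p)
        np.testing.assert_array_equal(loaded.phot_escaped1, log.phot_escaped1)

    def test_event_table_text_export(self, tmp_path, water10_grid):
        import gzip

        log = run_simulation(water10_grid, 50_000, seed=9)
        path = tmp_path / "events.tsv.gz"
        log.save_table(path)
        with gzip.open(path, "rt") as f:
            header = f.readline().split()
        assert header[:3] == ["type", "history_id", "x_mm"]
        df = log.to_dataframe()
        assert (df["type"] == "pair").sum() == log.n_pairs
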