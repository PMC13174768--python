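"""Siddon ray tracing, list-mode MLEM/OSEM, TOF weighting, post-filter."""

import numpy as np
import pytest

from pptsim.recon import (
    Image3D,
    ImageGeometry,
    geometric_sensitivity,
    lor_path,
    mlem_reconstruct,
    postfilter,
)
from pptsim.transport import C_MM_PER_NS, emit_annihilation_photons


GEOM = ImageGeometry((32, 32, 32), (2.0, 2.0, 2.0))


class TestLorPath:
    def test_axis_aligned_row(self):
        geom = ImageGeometry((10, 3, 3), (1.0, 1.0, 1.0))
        idx, ln = lor_path(geom, [-20.0, 0.1, 0.1], [20.0, 0.1, 0.1])
        assert len(ln) == 10
        np.testing.assert_allclose(ln, 1.0, rtol=1e-9)

    def test_single_voxel_diagonal(self):
        geom = ImageGeometry((1, 1, 1), (1.0, 1.0, 1.0))
        idx, ln = lor_path(geom, [-0.5, -0.5, -0.5], [0.5, 0.5, 0.5])
        assert len(ln) == 1
        assert ln[0] == pytest.approx(np.sqrt(3.0), rel=1e-9)

    def test_degenerate_lor_is_empty(self):
        idx, ln = lor_path(GEOM, [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert len(ln) == 0

    def test_random_lors_match_dense_sampling_oracle(self, rng):
        """Per-LOR length sums equal the chord length measured by dense
        point sampling inside the grid box."""
        half = 32.0
        for _ in range(25):
            p1 = rng.uniform(-90, 90, 3)
            p1 *= 90.0 / max(np.abs(p1).max(), 1e-9)  # push outside
            p2 = -p1 + rng.uniform(-30, 30, 3)
            idx, ln = lor_path(GEOM, p1, p2)
            ts = np.linspace(0.0, 1.0, 20001)
            pts = p1[None, :] + ts[:, None] * (p2 - p1)[None, :]
            inside = np.all(np.abs(pts) < half, axis=1)
            chord = inside.mean() * np.linalg.norm(p2 - p1)
            assert ln.sum() == pytest.approx(chord, abs=0.05 * np.linalg.norm(p2 - p1) / 100)

    def test_lengths_sum_to_in_grid_chord_exactly(self):
        p1 = np.array([-100.0, 5.0, -3.0])
        p2 = np.array([100.0, -7.0, 11.0])
        idx, ln = lor_path(GEOM, p1, p2)
        # analytic chord through the box
        d = p2 - p1
        t0, t1 = 0.0, 1.0
        for ax in range(3):
            ta = (-32.0 - p1[ax]) / d[ax]
            tb = (32.0 - p1[ax]) / d[ax]
            t0 = max(t0, min(ta, tb))
            t1 = min(t1, max(ta, tb))
        chord = (t1 - t0) * np.linalg.norm(d)
        assert ln.sum() == pytest.approx(chord, rel=1e-6)


def _synthetic_coincidences(rng, sources, n, ring_radius=200.0, weights=None):
    """Back-to-back pairs from point sources, projected to a cylinder."""
    sources = np.atleast_2d(sources)
    which = rng.choice(len(sources), n, p=weights)
    origin = sources[which]
    d1, d2 = emit_annihilation_photons(origin, np.zeros(n), rng, n=n)
    ends = []
    for d in (d1, d2):
        a = d[:, 0] ** 2 + d[:, 1] ** 2
        b = origin[:, 0] * d[:, 0] + origin[:, 1] * d[:, 1]
        c = origin[:, 0] ** 2 + origin[:, 1] ** 2 - ring_radius**2
        s = (-b + np.sqrt(b**2 - a * c)) / np.maximum(a, 1e-12)
        ends.append(origin + s[:, None] * d)
    p1, p2 = ends
    ok = a > 1e-6
    dt = (np.linalg.norm(p1 - origin, axis=1) - np.linalg.norm(p2 - origin, axis=1)) / C_MM_PER_NS
    return p1[ok], p2[ok], dt[ok]


class TestMLEM:
    def test_point_source_peak_within_one_voxel(self, rng):
        src = np.array([6.0, -4.0, 2.0])
        p1, p2, dt = _synthetic_coincidences(rng, src, 10_000)
        img = mlem_reconstruct(None, GEOM, n_iter=20, endpoints=(p1, p2))
        peak = np.unravel_index(np.argmax(img.values), img.values.shape)
        center = (np.asarray(peak) + 0.5) * 2.0 - 32.0
        assert np.all(np.abs(center - src) <= 2.0 + 1e-9)

    def test_nonnegative_and_finite(self, rng):
        p1, p2, dt = _synthetic_coincidences(rng, [0.0, 0.0, 0.0], 500)
        img = mlem_reconstruct(None, GEOM, n_iter=5, n_subsets=5, endpoints=(p1, p2))
        assert np.all(img.values >= 0)
        assert np.all(np.isfinite(img.values))

    def test_single_lor_update_supported_on_lor_only(self):
        p1 = np.array([[-200.0, 1.0, 1.0]])
        p2 = np.array([[200.0, 1.0, 1.0]])
        img = mlem_reconstruct(None, GEOM, n_iter=1, endpoints=(p1, p2))
        idx, _ = lor_path(GEOM, p1[0], p2[0])
        on_lor = np.zeros(GEOM.shape, dtype=bool)
        on_lor[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        assert np.all(img.values[~on_lor] == 0)
        assert img.values[on_lor].sum() > 0

    def test_total_intensity_stable_after_second_iteration(self, rng):
        p1, p2, dt = _synthetic_coincidences(rng, [0.0, 0.0, 0.0], 2_000)
        sums = []
        for it in (2, 3, 5, 8):
            img = mlem_reconstruct(None, GEOM, n_iter=it, endpoints=(p1, p2))
            sums.append(img.values.sum())
        for s in sums[1:]:
            assert s == pytest.approx(sums[0], rel=1e-3)

    def test_two_point_sources_resolved(self, rng):
        """Forward-simulate two sources 20 mm apart, reconstruct, find
        both peaks at the true positions within one voxel."""
        sources = np.array([[-10.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        p1, p2, dt = _synthetic_coincidences(rng, sources, 20_000)
        img = mlem_reconstruct(None, GEOM, n_iter=25, endpoints=(p1, p2))
        mid = GEOM.shape[0] // 2
        left = img.values[:mid]
        right = img.values[mid:]
        pl = np.unravel_index(np.argmax(left), left.shape)
        pr = np.unravel_index(np.argmax(right), right.shape)
        xl = (pl[0] + 0.5) * 2.0 - 32.0
        xr = (pr[0] + mid + 0.5) * 2.0 - 32.0
        assert xl == pytest.approx(-10.0, abs=2.0)
        assert xr == pytest.approx(10.0, abs=2.0)

    def test_empty_coincidence_list_raises(self):
        with pytest.raises(ValueError, match="empty"):
            mlem_reconstruct(
                None, GEOM, endpoints=(np.zeros((0, 3)), np.zeros((0, 3)))
            )

    def test_tof_suppresses_cold_region_background(self, rng):
        """An off-center hot spot: with exact TOF the cold mirror region
        must hold no more intensity than without TOF (matched events)."""
        src = np.array([12.0, 0.0, 0.0])
        p1, p2, dt = _synthetic_coincidences(rng, src, 4_000)
        img_nt = mlem_reconstruct(None, GEOM, n_iter=8, endpoints=(p1, p2))
        img_t = mlem_reconstruct(
            None, GEOM, n_iter=8, endpoints=(p1, p2), tof=True, dt_ns=dt,
            tof_fwhm_ps=214.0,
        )
        x = (np.arange(32) + 0.5) * 2.0 - 32.0
        cold = np.abs(x + 12.0) <= 6.0  # mirror position of the source
        cold_nt = img_nt.values[cold].sum() / img_nt.values.sum()
        cold_t = img_t.values[cold].sum() / img_t.values.sum()
        assert cold_t <= cold_nt


class TestSensitivityAndFilter:
    def test_geometric_sensitivity_positive_in_center(self):
        from pptsim.detector import DetectorRing

        ring = DetectorRing(radius_mm=200.0, axial_length_mm=200.0,
                            pitch_trans_mm=8.0, pitch_axial_mm=8.0)
        sens = geometric_sensitivity(GEOM, ring, n_lors=5_000)
        assert sens[16, 16, 16] > 0
        assert np.all(sens >= 0)

    def test_postfilter_identity_at_zero_fwhm(self, rng):
        img = Image3D(rng.random(GEOM.shape), np.asarray(GEOM.voxel_size))
        out = postfilter(img, 0.0)
        np.testing.assert_array_equal(out.values, img.values)

    def test_postfilter_delta_fwhm(self):
        vals = np.zeros((41, 41, 41))
        vals[20, 20, 20] = 1.0
        img = Image3D(vals, np.array([1.0, 1.0, 1.0]))
        out = postfilter(img, 9.0)
        prof = out.values[:, 20, 20]
        half = prof.max() / 2
        above = np.flatnonzero(prof >= half)
        x = np.arange(41.0)
        left = np.interp(half, prof[above[0] - 1:above[0] + 1], x[above[0] - 1:above[0] + 1])
        right = np.interp(half, prof[above[-1] + 1:above[-1] - 1:-1], x[above[-1] + 1:above[-1] - 1:-1])
        assert right - left == pytest.approx(9.0, abs=0.5)

    def test_postfilter_preserves_total_intensity(self, rng):
        img = Image3D(rng.random((20, 20, 20)), np.ones(3))
        out = postfilter(img, 5.0)
        assert out.values.sum() == pytest.approx(img.values.sum(), rel=1e-6)
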