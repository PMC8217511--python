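"""Height-map rendering, circle fitting, ring detection and height profiles."""

import math

import numpy as np
import pytest

from cartwheel import afm
from cartwheel import geometry as g


def make_ring_assembly(diameter=23.0, n=9):
    chord = diameter * math.sin(math.pi / n)
    step = g.interface_step(360.0 / n, 0.0, chord)
    return g.propagate(g.default_seed_unit(step=step), step, n)


@pytest.fixture
def ring_map():
    return afm.render_heightmap(make_ring_assembly(), tip_sigma=2.0, field_nm=100.0)


class TestRender:
    def test_empty_assembly_gives_blank_map(self):
        hm = afm.render_heightmap(None, field_nm=50.0)
        assert not hm.heights.any()

    def test_ring_crest_diameter(self, ring_map):
        rings = afm.detect_rings(ring_map, threshold=2.0)
        assert len(rings) == 1
        assert 2 * rings[0].radius == pytest.approx(23.0, abs=ring_map.pixel_size)

    def test_crest_height_preserved_under_tip_blur(self, ring_map):
        assert ring_map.heights.max() == pytest.approx(afm.CREST_HEIGHT_NM, rel=0.02)

    def test_helix_renders_parallel_spokes_at_pitch_spacing(self):
        step = g.interface_step(90.0, 6.5)
        asm = g.propagate(g.default_seed_unit(step=step), step, 12)
        hm = afm.render_heightmap(asm, tip_sigma=2.0, field_nm=120.0)
        spacings = afm.line_scan_spacings(hm, (0.0, 65.0), (120.0, 65.0),
                                          min_prominence=1.0)
        assert max(spacings) == pytest.approx(26.0, abs=hm.pixel_size)

    def test_clipping_warns(self):
        with pytest.warns(RuntimeWarning, match="field of view"):
            afm.render_heightmap(make_ring_assembly(diameter=40.0), field_nm=30.0)


class TestNoise:
    def test_zero_sigma_is_identity(self, ring_map):
        out = afm.add_noise(ring_map, 0.0, 1)
        assert np.array_equal(out.heights, ring_map.heights)

    def test_seed_reproducibility(self, ring_map):
        a = afm.add_noise(ring_map, 0.2, 42)
        b = afm.add_noise(ring_map, 0.2, 42)
        assert np.array_equal(a.heights, b.heights)

    def test_sample_sd_matches_requested(self):
        flat = afm.HeightMap(np.zeros((128, 128)), 1.0)
        noisy = afm.add_noise(flat, 0.2, 0)
        assert noisy.heights.std() == pytest.approx(0.2, rel=0.05)


class TestFitCircle:
    def test_three_points_exact(self):
        (cx, cy), r = afm.fit_circle([(1, 0), (0, 1), (-1, 0)])
        assert (cx, cy, r) == (pytest.approx(0, abs=1e-12),
                               pytest.approx(0, abs=1e-12),
                               pytest.approx(1.0))

    def test_noiseless_ring_radius(self):
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([11.5 * np.cos(th), 11.5 * np.sin(th)])
        _, r = afm.fit_circle(pts)
        assert r == pytest.approx(11.5, abs=1e-6)

    def test_noisy_radius_within_two_percent(self):
        rng = np.random.default_rng(1)
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([11.5 * np.cos(th), 11.5 * np.sin(th)])
        errs = [abs(afm.fit_circle(pts + rng.normal(0, 0.3, pts.shape))[1] - 11.5)
                for _ in range(100)]
        assert np.median(errs) / 11.5 < 0.02

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            afm.fit_circle([(0, 0), (1, 0), (2, 0)])


class TestDetect:
    def test_blank_map_empty(self):
        assert afm.detect_rings(afm.HeightMap(np.zeros((64, 64)), 1.0)) == []

    def test_one_noisy_ring_one_detection(self, ring_map):
        noisy = afm.add_noise(ring_map, 0.3, 5)
        assert len(afm.detect_rings(noisy, threshold=2.0)) == 1

    def test_open_arc_rejected_by_coverage(self):
        step = g.interface_step(40.0, 0.0)
        arc = g.propagate(g.default_seed_unit(step=step), step, 4)  # 120 deg
        hm = afm.add_noise(
            afm.render_heightmap(arc, tip_sigma=2.0, field_nm=100.0), 0.3, 6)
        assert afm.detect_rings(hm, threshold=2.0) == []

    def test_helices_never_detected_as_rings(self):
        step = g.interface_step(90.0, 6.5)
        asm = g.propagate(g.default_seed_unit(step=step), step, 12)
        for seed in range(5):
            hm = afm.add_noise(
                afm.render_heightmap(asm, tip_sigma=2.0, field_nm=120.0), 0.3, seed)
            assert afm.detect_rings(hm, threshold=2.0) == []


class TestProfiles:
    def test_forty_profiles_at_nine_degree_spacing(self, ring_map):
        profs = afm.radial_profiles(ring_map, (49.2, 49.2), 11.5)
        assert profs.shape[0] == 40

    def test_symmetric_ring_profiles_agree(self):
        # ideal circular ridge drawn directly, no polygon or spokes
        n = 201
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - 100, yy - 100)
        hm = afm.HeightMap(4.5 * np.exp(-((r - 40.0) ** 2) / 18.0), 0.25)
        profs = afm.radial_profiles(hm, (25.0, 25.0), 10.0)
        heights = [afm.profile_height(p) for p in profs]
        assert np.ptp(heights) < 0.1  # bilinear interpolation error

    def test_profile_height_basics(self):
        assert afm.profile_height([0, 1, 4, 1, 0]) == 4.0
        assert afm.profile_height(np.array([0, 1, 4, 1, 0]) + 7.3) == pytest.approx(4.0)

    def test_height_difference(self):
        flat = np.full(40, 4.5)
        assert afm.ring_height_difference(flat) == 0.0
        flat[13] = 5.0
        assert afm.ring_height_difference(flat) == pytest.approx(0.5)

    def test_height_analysis_invariant_to_constant_offset(self, ring_map):
        m1 = afm.measure_ring(ring_map, (49.2, 49.2), 11.5)
        shifted = afm.HeightMap(ring_map.heights + 3.0, ring_map.pixel_size)
        m2 = afm.measure_ring(shifted, (49.2, 49.2), 11.5)
        assert m2.height_difference == pytest.approx(m1.height_difference, abs=1e-12)
        assert np.allclose(m2.profile_heights, m1.profile_heights)

    def test_rotating_map_90deg_preserves_measurements(self, ring_map):
        noisy = afm.add_noise(ring_map, 0.2, 9)
        rot = afm.HeightMap(np.rot90(noisy.heights).copy(), noisy.pixel_size)
        r1 = afm.detect_rings(noisy, threshold=2.0)
        r2 = afm.detect_rings(rot, threshold=2.0)
        assert len(r1) == len(r2) == 1
        assert r2[0].radius == pytest.approx(r1[0].radius, abs=0.15)
        assert r2[0].height_difference == pytest.approx(
            r1[0].height_difference, abs=0.15)


class TestLineScan:
    def test_flat_line_empty(self):
        hm = afm.HeightMap(np.zeros((64, 64)), 1.0)
        assert afm.line_scan_spacings(hm, (0, 32), (63, 32)) == []

    def test_two_ridges_26nm_apart(self):
        hm = afm.HeightMap(np.zeros((96, 96)), 1.0)
        hm.heights[:, 30] = 4.0
        hm.heights[:, 56] = 4.0
        spac = afm.line_scan_spacings(hm, (0, 48), (95, 48), min_prominence=1.0)
        assert len(spac) == 1
        assert spac[0] == pytest.approx(26.0, abs=1.0)

    def test_three_equal_ridges_at_13nm(self):
        hm = afm.HeightMap(np.zeros((96, 96)), 1.0)
        for col in (30, 43, 56):
            hm.heights[:, col] = 4.0
        spac = afm.line_scan_spacings(hm, (0, 48), (95, 48), min_prominence=1.0)
        assert np.allclose(spac, [13.0, 13.0], atol=1.0)


class TestTiffIO:
    def test_round_trip(self, ring_map, tmp_path):
        path = str(tmp_path / "map.tiff")
        ring_map.write_tiff(path)
        back = afm.HeightMap.read_tiff(path)
        assert back.pixel_size == ring_map.pixel_size
        assert np.allclose(back.heights, ring_map.heights, atol=1e-6)
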