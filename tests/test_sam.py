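"""Spectral-angle mapping, fill factors, OSCA determination and segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsdfm import (
    AngleMap,
    EndmemberLibrary,
    FillFactorCurve,
    ReflectanceCube,
    SceneSpec,
    WavelengthGrid,
    angle_map,
    build_library,
    coverage_vs_threshold,
    determine_osca,
    extract_endmember,
    fill_factor_curve,
    generate_reference_cube,
    integrate_segmentation,
    normalize_cube,
    segment_type,
    spectral_angle,
)
from hsdfm.sam import DegeneratePixelError, Endmember, LibraryEntry, RIGHT_ANGLE

from conftest import brute_spectral_angle


def two_band_cube(pixels):
    g = WavelengthGrid(np.array([500.0, 510.0]))
    arr = np.asarray(pixels, dtype=float).reshape(1, -1, 2)
    return ReflectanceCube(arr, g)


class TestSpectralAngle:
    @pytest.mark.parametrize(
        "x, mu, expect",
        [
            ((1.0, 1.0), (1.0, 1.0), 0.0),
            ((1.0, 0.0), (0.0, 1.0), np.pi / 2),
            ((1.0, 1.0), (1.0, 0.0), np.pi / 4),
        ],
    )
    def test_closed_forms(self, x, mu, expect):
        assert spectral_angle(np.array(x), np.array(mu)) == pytest.approx(expect, abs=1e-7)

    def test_zero_norm_raises(self):
        with pytest.raises(DegeneratePixelError):
            spectral_angle(np.zeros(3), np.ones(3))

    @settings(max_examples=50, deadline=None)
    @given(
        scale_x=st.floats(0.01, 100.0),
        scale_mu=st.floats(0.01, 100.0),
        seed=st.integers(0, 1000),
    )
    def test_scale_invariance(self, scale_x, scale_mu, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 2.0, size=10)
        mu = rng.uniform(0.1, 2.0, size=10)
        base = spectral_angle(x, mu)
        assert spectral_angle(scale_x * x, scale_mu * mu) == pytest.approx(base, abs=1e-9)


class TestExtractEndmember:
    def test_identical_spectra(self, grid):
        vals = np.tile(np.linspace(1, 2, grid.n_bands), (3, 3, 1))
        cube = ReflectanceCube(vals, grid)
        em = extract_endmember(cube, np.ones((3, 3), bool), "x")
        assert np.allclose(em.mu, vals[0, 0])
        assert np.allclose(em.spread, 0.0)
        assert em.n_pixels == 9

    def test_two_pixel_mean(self):
        cube = two_band_cube([[1.0, 3.0], [3.0, 1.0]])
        em = extract_endmember(cube, np.ones((1, 2), bool), "x")
        assert np.allclose(em.mu, [2.0, 2.0])

    def test_random_roi_matches_brute_force(self, grid):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0.1, 3.0, size=(12, 12, grid.n_bands))
        cube = ReflectanceCube(vals, grid)
        roi = rng.random((12, 12)) < 0.7
        em = extract_endmember(cube, roi, "x")
        sel = vals[roi]
        assert np.allclose(em.mu, sel.mean(axis=0))
        assert np.allclose(em.spread, sel.std(axis=0))

    def test_empty_roi_raises(self, grid):
        cube = ReflectanceCube(np.ones((2, 2, grid.n_bands)), grid)
        with pytest.raises(Exception):
            extract_endmember(cube, np.zeros((2, 2), bool), "x")


class TestAngleMap:
    def test_copies_of_mu_give_zero_map(self, grid):
        mu = np.linspace(1, 2, grid.n_bands)
        cube = ReflectanceCube(np.tile(mu, (4, 5, 1)), grid)
        em = Endmember("x", mu, np.zeros_like(mu), 1)
        am = angle_map(cube, em)
        assert np.allclose(am.values, 0.0, atol=1e-7)

    def test_equals_elementwise_brute_force(self, grid):
        rng = np.random.default_rng(10)
        vals = rng.uniform(0.1, 2.0, size=(8, 8, grid.n_bands))
        cube = ReflectanceCube(vals, grid)
        mu = rng.uniform(0.1, 2.0, size=grid.n_bands)
        am = angle_map(cube, Endmember("x", mu, np.zeros_like(mu), 1))
        for i in range(8):
            for j in range(8):
                assert am.values[i, j] == pytest.approx(
                    brute_spectral_angle(vals[i, j], mu), abs=1e-9
                )

    def test_degenerate_pixels_get_right_angle(self, grid):
        vals = np.ones((2, 2, grid.n_bands))
        vals[0, 0] = 0.0
        cube = ReflectanceCube(vals, grid)
        am = angle_map(cube, Endmember("x", np.ones(grid.n_bands), np.zeros(grid.n_bands), 1))
        assert am.values[0, 0] == pytest.approx(np.pi / 2)
        assert am.n_degenerate == 1

    def test_planted_region_closer_than_rest(self, templates, template_map, noiseless_cube, noiseless_scene):
        em = Endmember("blood", template_map["blood"].spectrum,
                       np.zeros(noiseless_cube.grid.n_bands), 1)
        am = angle_map(noiseless_cube, em)
        blood_idx = noiseless_scene.label_names.index("blood")
        inside = am.values[noiseless_scene.labels == blood_idx].mean()
        outside = am.values[noiseless_scene.labels != blood_idx].mean()
        assert inside < outside


class TestSegmentAndCurves:
    def make_map(self, values):
        return AngleMap(np.asarray(values, dtype=float), "x")

    def test_threshold_counting(self):
        am = self.make_map([[0.1, 0.2], [0.3, 0.4]])
        assert segment_type(am, 0.25).sum() == 2

    def test_strict_inequality_at_boundary(self):
        am = self.make_map([[0.1, 0.2], [0.3, 0.4]])
        assert segment_type(am, 0.3).sum() == 2  # 0.3 itself excluded
        assert segment_type(am, RIGHT_ANGLE).sum() == 4

    def test_fill_factor_examples(self):
        am = self.make_map([[0.1, 0.2], [0.3, 0.4]])
        curve = fill_factor_curve(am, np.array([0.05, 0.25, RIGHT_ANGLE]))
        assert curve.fractions[0] == 0.0
        assert curve.fractions[1] == 0.5
        assert curve.fractions[2] == 1.0

    def test_fill_factor_matches_brute_force(self):
        rng = np.random.default_rng(11)
        beta = rng.uniform(0, np.pi / 2, size=(9, 9))
        am = self.make_map(beta)
        grid_t = np.linspace(0.01, RIGHT_ANGLE, 40)
        curve = fill_factor_curve(am, grid_t)
        for t, f in zip(grid_t, curve.fractions):
            assert f == pytest.approx((beta <= t).mean(), abs=1e-12)

    def test_coverage_strict_and_degenerate(self, grid):
        vals = np.ones((4, 4, grid.n_bands))
        vals[0, 0] = 0.0  # one degenerate pixel at pi/2
        cube = ReflectanceCube(vals, grid)
        am = angle_map(cube, Endmember("x", np.ones(grid.n_bands), np.zeros(grid.n_bands), 1))
        cov = coverage_vs_threshold(am, np.array([0.01, RIGHT_ANGLE]))
        assert cov.fractions[-1] == pytest.approx(1 - 1 / 16)
        rng = np.random.default_rng(12)
        beta = rng.uniform(0, 1.5, size=(6, 6))
        am2 = self.make_map(beta)
        grid_t = np.linspace(0.05, 1.5, 20)
        cov2 = coverage_vs_threshold(am2, grid_t)
        for t, f in zip(grid_t, cov2.fractions):
            assert f == pytest.approx((beta < t).mean(), abs=1e-12)


class TestDetermineOsca:
    def make_curve(self, beta_values, step=0.01):
        am = AngleMap(np.asarray(beta_values, dtype=float), "x")
        grid_t = np.round(np.arange(step, RIGHT_ANGLE + step, step), 10)
        return fill_factor_curve(am, grid_t)

    def test_on_grid_minimum(self):
        assert determine_osca(self.make_curve([[0.1, 0.5]])) == pytest.approx(0.10)

    def test_off_grid_minimum_rounds_up(self):
        assert determine_osca(self.make_curve([[0.103, 0.5]])) == pytest.approx(0.11)

    def test_all_zero_curve_raises(self):
        curve = FillFactorCurve(np.array([0.1, 0.2]), np.array([0.0, 0.0]), 4)
        with pytest.raises(Exception):
            determine_osca(curve)


@pytest.fixture(scope="module")
def library_setup(template_map):
    """Endmembers plus noisy synthetic fat / fibroadenoma reference cubes."""
    refs = {}
    for ref_id, label in ((1, "fat"), (2, "ICTf")):
        spec = SceneSpec(shape=(24, 24), regions=[], noise_sd=0.02, seed=20 + ref_id)
        scene = generate_reference_cube(template_map[label], spec)
        refs[ref_id] = normalize_cube(scene.sample, scene.dark, scene.reference)
    ems = [
        Endmember(lbl, template_map[lbl].spectrum,
                  np.zeros_like(template_map[lbl].spectrum), 10)
        for lbl in ("blood", "fat", "ICT1", "IDC")
    ]
    return ems, refs


class TestBuildLibrary:
    def test_fat_routed_to_reference_two(self, library_setup):
        ems, refs = library_setup
        lib = build_library(ems, refs)
        for entry in lib.entries:
            expected = 2 if entry.endmember.label == "fat" else 1
            assert entry.reference_id == expected

    def test_stored_osca_matches_recomputation(self, library_setup):
        ems, refs = library_setup
        lib = build_library(ems, refs)
        for entry in lib.entries:
            beta = angle_map(refs[entry.reference_id], entry.endmember)
            exact_grid = np.unique(np.append(beta.values.ravel(), RIGHT_ANGLE))
            exact_grid = exact_grid[exact_grid > 0]
            recomputed = determine_osca(fill_factor_curve(beta, exact_grid))
            assert entry.osca == pytest.approx(recomputed, abs=0)

    def test_osca_zero_false_positives_on_reference(self, library_setup):
        """Segmenting the reference cube at its own OSCA marks no pixel."""
        ems, refs = library_setup
        lib = build_library(ems, refs)
        for entry in lib.entries:
            beta = angle_map(refs[entry.reference_id], entry.endmember)
            assert segment_type(beta, entry.osca).sum() == 0

    def test_endmember_present_in_reference_gives_tiny_osca(self, template_map, library_setup):
        _, refs = library_setup
        fat_em = Endmember("fat_like", template_map["fat"].spectrum,
                           np.zeros_like(template_map["fat"].spectrum), 5)
        lib = build_library([fat_em], refs, fat_labels=[])  # route to ref 1 = fat-only
        absent = build_library(
            [Endmember("blood", template_map["blood"].spectrum,
                       np.zeros_like(template_map["blood"].spectrum), 5)],
            refs,
        )
        assert lib.entries[0].osca < 0.05
        assert absent.entries[0].osca > lib.entries[0].osca

    def test_serialization_round_trip_identical(self, library_setup, tmp_path):
        ems, refs = library_setup
        lib = build_library(ems, refs, threshold_overrides={"IDC": 0.08})
        text = lib.to_json()
        again = EndmemberLibrary.from_json(text).to_json()
        assert text == again
        assert EndmemberLibrary.from_json(text)["IDC"].threshold == 0.08

    def test_threshold_defaults_to_osca(self, library_setup):
        ems, refs = library_setup
        lib = build_library(ems, refs)
        for entry in lib.entries:
            assert entry.threshold == entry.osca


class TestIntegrateSegmentation:
    def library_of(self, specs):
        entries = [
            LibraryEntry(
                endmember=Endmember(lbl, np.array(mu, float), np.zeros(len(mu)), 1),
                osca=thr, threshold=thr, reference_id=1,
            )
            for lbl, mu, thr in specs
        ]
        return EndmemberLibrary(entries)

    def test_min_rule_and_background(self):
        lib = self.library_of([
            ("A", (1.0, 0.05), 0.2),
            ("B", (1.0, 0.12), 0.2),
        ])
        cube = two_band_cube([[1.0, 0.07], [1.0, 5.0]])
        seg = integrate_segmentation(cube, lib)
        assert seg.label_names[seg.labels[0, 0]] == "A"
        assert seg.labels[0, 1] == -1  # passes no threshold

    def test_tie_broken_by_library_order(self):
        lib = self.library_of([
            ("A", (1.0, 1.0), 0.5),
            ("B", (1.0, 1.0), 0.5),
        ])
        cube = two_band_cube([[2.0, 2.0]])
        seg = integrate_segmentation(cube, lib)
        assert seg.label_names[seg.labels[0, 0]] == "A"
        assert seg.n_ties == 1

    def test_area_monotone_in_threshold_and_bounded_by_solo(self, grid):
        rng = np.random.default_rng(13)
        vals = rng.uniform(0.1, 2.0, size=(10, 10, grid.n_bands))
        cube = ReflectanceCube(vals, grid)
        mu = rng.uniform(0.1, 2.0, size=grid.n_bands)
        em = Endmember("x", mu, np.zeros_like(mu), 1)
        am = angle_map(cube, em)
        areas = [segment_type(am, t).sum() for t in (0.1, 0.2, 0.4, 0.8)]
        assert areas == sorted(areas)
        other = Endmember("y", rng.uniform(0.1, 2.0, size=grid.n_bands),
                          np.zeros(grid.n_bands), 1)
        lib = EndmemberLibrary([
            LibraryEntry(em, 0.4, 0.4, 1),
            LibraryEntry(other, 0.4, 0.4, 1),
        ])
        seg = integrate_segmentation(cube, lib)
        solo = segment_type(am, 0.4).sum()
        assert (seg.labels == 0).sum() <= solo

    def test_rescaled_pixels_and_endmembers_change_nothing(self, grid):
        rng = np.random.default_rng(14)
        vals = rng.uniform(0.1, 2.0, size=(6, 6, grid.n_bands))
        gains = rng.uniform(0.5, 3.0, size=(6, 6, 1))
        mu = rng.uniform(0.1, 2.0, size=grid.n_bands)
        em1 = Endmember("x", mu, np.zeros_like(mu), 1)
        em2 = Endmember("x", 4.2 * mu, np.zeros_like(mu), 1)
        am1 = angle_map(ReflectanceCube(vals, grid), em1)
        am2 = angle_map(ReflectanceCube(vals * gains, grid), em2)
        assert np.allclose(am1.values, am2.values, atol=1e-9)
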