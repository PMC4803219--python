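"""Mean-linear-intercept pipeline: grid arithmetic, preprocessing,
skeleton topology, and intercept counting checked against a brute-force
pixel-run oracle and the lattice closed form pitch - wall."""

import numpy as np
import pytest
from scipy import ndimage

from pulmomech.errors import (ConfigurationError, EmptyTissueError,
                              InvalidSpecError, UndefinedLmError)
from pulmomech.morpho import (HistologyImage, MorphoConfig, ProbeGrid,
                              airspace_probe_length, build_grid, compute_lm,
                              count_intercepts, preprocess, skeletonize_walls)
from pulmomech.synthgen import AlveolarImageSpec, generate_alveolar_image


def brute_force_count(skeleton, grid):
    """Independent oracle: walk every probe pixel by pixel and count
    maximal tissue runs."""
    total = 0
    for c in grid.v_cols:
        prev = False
        for r in range(grid.row_lo, grid.row_hi):
            cur = bool(skeleton[r, c])
            if cur and not prev:
                total += 1
            prev = cur
    for r in grid.h_rows:
        prev = False
        for c in range(grid.col_lo, grid.col_hi):
            cur = bool(skeleton[r, c])
            if cur and not prev:
                total += 1
            prev = cur
    return total


def brute_force_chords(tissue, grid):
    """Independent oracle for interior airspace chords: walk each probe and
    accumulate air runs bounded by tissue on both sides."""
    total_px = 0
    chords = 0

    def walk(values):
        nonlocal total_px, chords
        run = 0
        seen_tissue = False
        for v in values:
            if v:  # tissue
                if run and seen_tissue:
                    total_px += run
                    chords += 1
                run = 0
                seen_tissue = True
            else:
                run += 1

    for c in grid.v_cols:
        walk(tissue[grid.row_lo:grid.row_hi, c])
    for r in grid.h_rows:
        walk(tissue[r, grid.col_lo:grid.col_hi])
    return total_px, chords


def lattice(pitch=40.0, wall=2.0, size=1000, noise=0.0, seed=0, **kw):
    spec = AlveolarImageSpec(width_px=size, height_px=size, cell_pitch=pitch,
                             wall_thickness=wall, noise_sd=noise, seed=seed,
                             **kw)
    return generate_alveolar_image(spec)


class TestBuildGrid:
    def test_zero_margin_arithmetic(self):
        cfg = MorphoConfig(margin_frac=0.0)
        grid = build_grid((1000, 1000), 1.0, cfg)
        assert grid.total_length == 11 * 1000 + 9 * 1000

    def test_two_percent_margins(self):
        grid = build_grid((1000, 1000), 1.0, MorphoConfig())
        assert grid.v_len_px == 960
        assert grid.h_len_px == 960

    def test_non_square_image(self):
        grid = build_grid((400, 800), 1.0, MorphoConfig())
        assert grid.v_cols.size == 11 and grid.h_rows.size == 9
        assert grid.v_len_px == 400 - 2 * 8
        assert grid.h_len_px == 800 - 2 * 16

    def test_too_small_image(self):
        with pytest.raises(ConfigurationError):
            build_grid((8, 8), 1.0, MorphoConfig())


class TestPreprocess:
    def test_vessels_removed_lattice_preserved(self):
        """The three vessel discs vanish; wall structure away from them is
        untouched."""
        img_v = lattice(noise=0.0, vessel_count=3, vessel_diameter=80.0, seed=2)
        img_0 = lattice(noise=0.0)
        mask_v = preprocess(img_v)
        mask_0 = preprocess(img_0)
        # no solid blob of vessel scale survives
        from skimage import morphology as skmorph
        opened = skmorph.opening(mask_v, skmorph.disk(5))
        assert int(np.sum(np.bincount(skmorph.label(opened).ravel())[1:] > 5000)) == 0
        # walls outside the vessel neighborhoods are identical
        tissue_v = img_v.pixels < 150
        vessel_zone = skmorph.dilation(tissue_v & ~(img_0.pixels < 150),
                                       skmorph.disk(10))
        assert np.array_equal(mask_v & ~vessel_zone, mask_0 & ~vessel_zone)

    def test_no_vessels_is_plain_binarization(self):
        img = lattice(noise=0.0)
        mask = preprocess(img)
        assert np.array_equal(mask, img.pixels < 150)

    def test_polarity_invariance(self):
        img = lattice(noise=0.0)
        inverted = HistologyImage(pixels=255 - img.pixels, px_size=1.0)
        a = preprocess(img, MorphoConfig(polarity="dark_tissue"))
        b = preprocess(inverted, MorphoConfig(polarity="light_tissue"))
        assert np.array_equal(a, b)

    def test_blank_image_raises(self):
        img = HistologyImage(pixels=np.full((100, 100), 200, np.uint8),
                             px_size=1.0)
        with pytest.raises(EmptyTissueError):
            preprocess(img)

    def test_exclusion_mask_applied(self):
        img = lattice(noise=0.0, size=400)
        excl = np.zeros((400, 400), bool)
        excl[:200] = True
        img.exclusion_mask = excl
        mask = preprocess(img)
        assert not mask[:200].any()
        assert mask[200:].any()


class TestSkeleton:
    def test_straight_wall_reduces_to_one_pixel_line(self):
        binary = np.zeros((50, 50), bool)
        binary[:, 20:22] = True
        skel = skeletonize_walls(binary)
        # one pixel per interior row (skeletonization trims the endpoints),
        # all on the wall axis
        assert np.all(skel[2:-2].sum(axis=1) == 1)
        assert set(np.flatnonzero(skel.any(axis=0))) <= {20, 21}

    def test_lattice_face_count_preserved(self):
        """Euler-characteristic oracle: the skeleton keeps the number of
        enclosed faces of the lattice."""
        img = lattice(noise=0.0, size=400)
        binary = preprocess(img)
        skel = skeletonize_walls(binary)

        def faces(mask):
            # holes = background components not touching the border
            inv, n = ndimage.label(~mask)
            border = set(inv[0]) | set(inv[-1]) | set(inv[:, 0]) | set(inv[:, -1])
            return len(set(range(1, n + 1)) - border)

        assert faces(skel) == faces(binary)

    def test_empty_mask(self):
        assert not skeletonize_walls(np.zeros((20, 20), bool)).any()


class TestCountIntercepts:
    def test_ten_walls_one_probe(self):
        skel = np.zeros((30, 200), bool)
        cols = np.arange(10, 200, 19)[:10]
        skel[:, cols] = True
        grid = ProbeGrid(v_cols=np.array([], int), h_rows=np.array([15]),
                         row_lo=0, row_hi=30, col_lo=0, col_hi=200, px_size=1.0)
        n, flagged, _ = count_intercepts(skel, grid)
        assert n == 10 and flagged == 0

    def test_empty_skeleton(self):
        grid = build_grid((100, 100), 1.0, MorphoConfig())
        n, _, _ = count_intercepts(np.zeros((100, 100), bool), grid)
        assert n == 0

    def test_oblique_wall_counts_once(self):
        skel = np.zeros((50, 50), bool)
        for i in range(40):  # a 45-degree wall
            skel[5 + i, 5 + i] = True
        grid = ProbeGrid(v_cols=np.array([20]), h_rows=np.array([], int),
                         row_lo=0, row_hi=50, col_lo=0, col_hi=50, px_size=1.0)
        n, _, _ = count_intercepts(skel, grid)
        assert n == 1

    def test_probe_parallel_wall_flagged(self):
        skel = np.zeros((50, 50), bool)
        skel[25, :] = True
        grid = ProbeGrid(v_cols=np.array([], int), h_rows=np.array([25]),
                         row_lo=0, row_hi=50, col_lo=0, col_hi=50, px_size=1.0)
        n, flagged, _ = count_intercepts(skel, grid)
        assert n == 1 and flagged == 1

    def test_matches_brute_force_oracle(self):
        """Skeleton-run count and airspace-chord count/length both agree
        with an independent per-pixel walk on noiseless and noisy fixtures."""
        for seed, noise in ((0, 0.0), (3, 8.0)):
            res = compute_lm(lattice(noise=noise, seed=seed))
            skel = res.intermediates["skeleton"]
            tissue = res.intermediates["binary"]
            grid = res.intermediates["grid"]
            assert res.n_skeleton_runs == brute_force_count(skel, grid)
            length, chords = brute_force_chords(tissue, grid)
            assert res.n_intercepts == chords
            assert res.total_probe_length == pytest.approx(length)


class TestComputeLm:
    def test_lattice_closed_form(self):
        """Square lattice pitch 40, wall 2, 1 um/px: Lm = 38 within 1 px."""
        res = compute_lm(lattice(noise=0.0))
        assert res.Lm == pytest.approx(38.0, abs=1.0)

    def test_noise_does_not_move_lm(self):
        res = compute_lm(lattice(noise=8.0, seed=5))
        assert res.Lm == pytest.approx(38.0, abs=1.0)

    def test_gray_rescaling_invariance(self):
        img = lattice(noise=0.0)
        rescaled = HistologyImage(
            pixels=(img.pixels.astype(float) * 0.5 + 40).astype(np.uint8),
            px_size=1.0)
        assert compute_lm(rescaled).Lm == compute_lm(img).Lm

    def test_scale_invariance(self):
        """Doubling resolution (half px_size) leaves Lm unchanged."""
        a = compute_lm(lattice(pitch=40.0, wall=2.0, size=500, noise=0.0))
        b = compute_lm(generate_alveolar_image(AlveolarImageSpec(
            width_px=1000, height_px=1000, px_size=0.5, cell_pitch=40.0,
            wall_thickness=2.0, noise_sd=0.0)))
        assert b.Lm == pytest.approx(a.Lm, rel=0.03)

    def test_rotation_invariance(self):
        img = lattice(noise=0.0)
        rot = HistologyImage(pixels=np.rot90(img.pixels).copy(), px_size=1.0)
        assert compute_lm(rot).Lm == pytest.approx(compute_lm(img).Lm, rel=0.01)

    def test_pitch_ratio_recovered(self):
        """Lattices with pitches p and 1.65p: Lm ratio ~ 1.65 within 3%.

        Each lattice is measured at three phase offsets (three fields per
        animal, as in practice) to average out probe/wall phase accidents.
        """
        def mean_lm(pitch):
            vals = [compute_lm(lattice(pitch=pitch, wall=2.0, size=1200,
                                       noise=0.0, origin_offset_um=f * pitch)).Lm
                    for f in (0.0, 1 / 3, 2 / 3)]
            return np.mean(vals)

        assert mean_lm(42.4 * 1.65) / mean_lm(42.4) == pytest.approx(1.65,
                                                                     rel=0.03)

    def test_vessel_removal_never_shrinks_lm(self):
        plain = compute_lm(lattice(noise=0.0))
        with_vessels = compute_lm(lattice(noise=0.0, vessel_count=3,
                                          vessel_diameter=80.0, seed=2))
        assert with_vessels.Lm >= plain.Lm - 1e-9

    def test_all_tissue_degenerate(self):
        """Wall thickness = pitch - 1 px: nearly no airspace, Lm ~ 1 px.

        The vessel remover must not treat the dense field as one huge
        vessel (guarded by the tissue-fraction cap)."""
        res = compute_lm(lattice(pitch=8.0, wall=7.0, size=400, noise=0.0))
        assert res.Lm == pytest.approx(1.0, abs=0.5)

    def test_zero_intercepts_raises(self):
        img = HistologyImage(pixels=np.full((300, 300), 220, np.uint8),
                             px_size=1.0)
        img.pixels[:40, :40] = 90  # lone tissue patch outside every probe
        cfg = MorphoConfig(vessel_area_um2=1e9)
        grid_safe = img.pixels.copy()
        with pytest.raises((UndefinedLmError, EmptyTissueError)):
            compute_lm(HistologyImage(pixels=grid_safe, px_size=1.0), cfg)

    def test_lm_identity(self):
        res = compute_lm(lattice(noise=0.0))
        assert res.Lm == pytest.approx(res.total_probe_length / res.n_intercepts)
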