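"""Target-mask construction, pixel extraction and file I/O."""

import numpy as np
import pandas as pd
import pytest
import tifffile

from censpot import (
    GridSpec,
    build_masks,
    extract_pixels,
    read_centers,
    read_image,
    read_results,
    write_results,
)
from .conftest import brute_force_assignment


def hex_lattice(n_rows=3, n_cols=3, pitch=10.0, origin=(15.0, 15.0)):
    """Orange-crate (hexagonally offset) center layout, row-wise."""
    centers = []
    dy = pitch * np.sqrt(3) / 2
    for i in range(n_rows):
        for j in range(n_cols):
            x = origin[0] + j * pitch + (pitch / 2 if i % 2 else 0.0)
            y = origin[1] + i * dy
            centers.append((x, y))
    return np.asarray(centers)


class TestBuildMasks:
    def test_single_center_rect_covers_clipped_rectangle(self):
        grid = GridSpec("rect", [(4.0, 4.0)], pitch=3.0, image_shape=(9, 9))
        masks = build_masks(grid)
        mr, mc = masks.masks[0]
        # all pixels within one pitch of the center, nothing else
        d = np.hypot(mc - 4.0, mr - 4.0)
        assert np.all(d <= 3.0)
        assert mr.size == np.sum(
            np.hypot(*np.meshgrid(np.arange(9) - 4.0, np.arange(9) - 4.0)) <= 3.0)

    def test_assignment_equals_brute_force_scan(self, rng):
        import warnings
        shape = (40, 40)
        centers = rng.uniform(5, 34, size=(6, 2))
        grid = GridSpec("hex", centers, pitch=9.0, image_shape=shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # irregular spacing
            masks = build_masks(grid)
        ref = brute_force_assignment(centers, 9.0, shape)
        got = np.full(shape, -1, int)
        for s, (mr, mc) in enumerate(masks.masks):
            got[mr, mc] = s
        assert np.array_equal(got, ref)

    def test_hex_lattice_interior_cell_has_six_neighbors(self):
        centers = hex_lattice(5, 5, pitch=12.0, origin=(20.0, 20.0))
        grid = GridSpec("hex", centers, pitch=12.0, image_shape=(110, 110))
        masks = build_masks(grid)
        # pick the central spot; count distinct masks touching its boundary
        mid = 12  # row 2, col 2 of the 5x5 lattice
        lab = np.full(grid.image_shape, -1, int)
        for s, (mr, mc) in enumerate(masks.masks):
            lab[mr, mc] = s
        neigh = set()
        mr, mc = masks.masks[mid]
        for r, c in zip(mr, mc):
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                v = lab[r + dr, c + dc]
                if v >= 0 and v != mid:
                    neigh.add(v)
        assert len(neigh) == 6
        assert not masks.clipped[mid]

    def test_masks_disjoint_in_bounds_and_contain_centers(self):
        for seed in range(30):
            r = np.random.default_rng(seed)
            shape = (30, 30)
            n = int(r.integers(1, 6))
            centers = np.column_stack([r.uniform(2, 27, n), r.uniform(2, 27, n)])
            # enforce the minimum separation any real grid has
            keep = np.ones(n, bool)
            for i in range(n):
                for j in range(i):
                    if keep[j] and np.hypot(*(centers[i] - centers[j])) < 2.0:
                        keep[i] = False
            centers = centers[keep]
            grid = GridSpec("hex", centers, pitch=6.0, image_shape=shape)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                masks = build_masks(grid)
            seen = set()
            for s, (mr, mc) in enumerate(masks.masks):
                assert np.all((mr >= 0) & (mr < 30) & (mc >= 0) & (mc < 30))
                pix = set(zip(mr.tolist(), mc.tolist()))
                assert not (pix & seen)  # pairwise disjoint
                seen |= pix
                cx, cy = grid.centers[s]
                assert (int(round(cy)), int(round(cx))) in pix

    def test_translation_equivariance_for_interior_spots(self):
        centers = hex_lattice(3, 3, pitch=10.0, origin=(25.0, 25.0))
        g1 = GridSpec("hex", centers, pitch=10.0, image_shape=(80, 80))
        g2 = GridSpec("hex", centers + [3.0, 2.0], pitch=10.0, image_shape=(80, 80))
        m1, m2 = build_masks(g1), build_masks(g2)
        mid = 4
        a = set(zip(*[x.tolist() for x in m1.masks[mid]]))
        b = set(zip(*[x.tolist() for x in m2.masks[mid]]))
        assert {(r + 2, c + 3) for r, c in a} == b

    def test_duplicate_and_out_of_bounds_centers_rejected(self):
        with pytest.raises(ValueError):
            GridSpec("hex", [(5.0, 5.0), (5.0, 5.0)], pitch=3.0, image_shape=(20, 20))
        with pytest.raises(ValueError):
            GridSpec("hex", [(25.0, 5.0)], pitch=3.0, image_shape=(20, 20))


class TestExtractPixels:
    def test_constant_image_extracts_constant_values(self):
        img = np.full((20, 20), 1234, dtype=np.uint16)
        grid = GridSpec("rect", [(5.0, 5.0), (14.0, 14.0)], pitch=12.7,
                        image_shape=(20, 20))
        pm = extract_pixels(img, build_masks(grid), S=65535.0)
        assert len(pm) == 2
        for mask in pm:
            assert np.all(mask.values == 1234.0)
            assert mask.coords.shape == (mask.n, 2)

    def test_bright_disk_contained_in_its_mask(self):
        img = np.full((30, 30), 100, dtype=np.uint16)
        rr, cc = np.mgrid[0:30, 0:30]
        disk = np.hypot(rr - 10, cc - 10) <= 3
        img[disk] = 50000
        grid = GridSpec("rect", [(10.0, 10.0), (10.0, 22.0)], pitch=12.0,
                        image_shape=(30, 30))
        pm = extract_pixels(img, build_masks(grid), S=65535.0)
        assert np.sum(pm[0].values == 50000.0) == int(disk.sum())
        assert np.all(pm[1].values == 100.0)

    def test_saturated_pixels_counted_at_default_threshold(self):
        img = np.full((10, 10), 65535, dtype=np.uint16)
        grid = GridSpec("rect", [(5.0, 5.0)], pitch=4.0, image_shape=(10, 10))
        pm = extract_pixels(img, build_masks(grid), S=65535.0)
        assert pm[0].n_saturated == pm[0].n


class TestIO:
    def test_image_round_trip_and_validation(self, tmp_path):
        img = np.arange(100, dtype=np.uint16).reshape(10, 10)
        path = tmp_path / "img.tif"
        tifffile.imwrite(path, img)
        assert read_image(path).shape == (10, 10)

        rgb = np.zeros((5, 5, 3), dtype=np.uint16)
        tifffile.imwrite(tmp_path / "rgb.tif", rgb)
        with pytest.raises(ValueError):
            read_image(tmp_path / "rgb.tif")

        f32 = np.zeros((5, 5), dtype=np.float32)
        tifffile.imwrite(tmp_path / "f32.tif", f32)
        with pytest.raises(ValueError):
            read_image(tmp_path / "f32.tif")

    def test_centers_csv_to_gridspec(self, tmp_path):
        df = pd.DataFrame({"spot_id": ["a", "b", "c"],
                           "x": [5.0, 15.0, 25.0], "y": [5.0, 5.0, 5.0]})
        path = tmp_path / "centers.csv"
        df.to_csv(path, index=False)
        grid = read_centers(path, image_shape=(30, 30))
        assert grid.n_spots == 3
        assert grid.pitch == pytest.approx(10.0)  # estimated from spacing
        assert grid.spot_ids == ["a", "b", "c"]

    def test_center_outside_image_rejected(self, tmp_path):
        path = tmp_path / "centers.csv"
        pd.DataFrame({"spot_id": ["a", "b"], "x": [5.0, 99.0],
                      "y": [5.0, 5.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError):
            read_centers(path, image_shape=(30, 30))

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "centers.csv"
        pd.DataFrame({"spot": ["a"], "col": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError):
            read_centers(path, image_shape=(30, 30))

    def test_genepix_style_columns_with_unit_conversion(self, tmp_path):
        path = tmp_path / "centers.csv"
        pd.DataFrame({"Name": ["a", "b"], "X": [50.0, 150.0],
                      "Y": [50.0, 50.0]}).to_csv(path, index=False)
        grid = read_centers(path, image_shape=(30, 30), pitch=10.0,
                            microns_per_pixel=10.0)
        assert np.allclose(grid.centers, [[5.0, 5.0], [15.0, 5.0]])

    def test_results_round_trip(self, tmp_path):
        rows = [
            {"spot_id": "a", "K": 2, "bg": 1000.0, "fg": 70000.0,
             "corrected": 69000.0, "n_pixels": 400, "n_fg": 60,
             "n_intermediate": 0, "n_saturated": 40,
             "fg_empirical_median": 65535.0, "flags": ""},
            {"spot_id": "b", "K": 1, "bg": 900.0, "fg": np.nan,
             "corrected": np.nan, "n_pixels": 380, "n_fg": 0,
             "n_intermediate": 0, "n_saturated": 0,
             "fg_empirical_median": np.nan, "flags": "blank"},
            {"spot_id": "c", "K": 3, "bg": 1100.0, "fg": 50000.0,
             "corrected": 48900.0, "n_pixels": 410, "n_fg": 80,
             "n_intermediate": 30, "n_saturated": 0,
             "fg_empirical_median": 49000.0, "flags": ""},
        ]
        path = tmp_path / "out.tsv"
        write_results(path, rows, manifest={"seed": 1})
        back = read_results(path)
        assert len(back) == 3
        assert back.loc[0, "fg"] == pytest.approx(70000.0)
        assert np.isnan(back.loc[1, "corrected"])
        assert back.loc[1, "flags"] == "blank"
        assert (tmp_path / "out.tsv.manifest.json").exists()
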