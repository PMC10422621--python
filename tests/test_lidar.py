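"""Point-cloud operations checked against brute-force recomputation."""

import numpy as np
import pandas as pd
import pytest

from necroscan import (
    GridSpec,
    clip_rectangle,
    compute_grid_metrics,
    normalize_heights,
    pulse_count_change,
    read_point_cloud,
    stratify_return,
    vertical_profile,
    write_point_cloud,
)
from necroscan.lidar import TREE_HEIGHT_THRESHOLD, EmptyCloudError

from conftest import make_cloud


class TestReadWrite:
    def test_reads_xyz_table_with_return_numbers(self, tmp_path):
        p = tmp_path / "cloud.xyz"
        p.write_text("# x y z rn nr\n1.0 2.0 3.0 1 2\n1.5 2.5 0.1 2 2\n9 9 9 1 1\n")
        cloud = read_point_cloud(p)
        assert len(cloud) == 3
        assert list(cloud.points["return_number"]) == [1, 2, 1]

    def test_invariant_violation_names_record(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("0 0 0 1 1\n0 0 1 2 1\n")
        with pytest.raises(ValueError, match="record 2"):
            read_point_cloud(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.xyz"
        p.write_text("")
        with pytest.raises(EmptyCloudError):
            read_point_cloud(p)

    def test_round_trip_preserves_coordinates(self, tmp_path, rng):
        n = 200
        cloud = make_cloud(
            x=rng.uniform(0, 50, n), y=rng.uniform(0, 50, n),
            z=rng.uniform(0, 25, n),
            return_number=rng.integers(1, 3, n), n_returns=np.full(n, 2),
            ground=rng.uniform(size=n) < 0.3,
        )
        path = tmp_path / "rt.xyz"
        write_point_cloud(cloud, path)
        back = read_point_cloud(path)
        for col in ("x", "y", "z"):
            np.testing.assert_allclose(back.points[col], cloud.points[col], atol=1e-6)
        assert (back.points["ground"] == cloud.points["ground"]).all()


class TestClip:
    def test_closed_bounds_keep_corner_returns(self):
        cloud = make_cloud(x=[-5, 5, -5, 5], y=[-5, -5, 5, 5], z=[1] * 4)
        assert len(clip_rectangle(cloud, (0, 0), side=10)) == 4
        assert len(clip_rectangle(cloud, (0, 0), side=5)) == 0

    def test_buffer_extends_window(self):
        cloud = make_cloud(x=[7.0], y=[0.0], z=[1.0])
        assert len(clip_rectangle(cloud, (0, 0), side=10, buffer=0)) == 0
        assert len(clip_rectangle(cloud, (0, 0), side=10, buffer=2)) == 1

    def test_matches_brute_force_membership(self, random_cloud):
        center, side = (42.0, 57.0), 10.0
        clipped = clip_rectangle(random_cloud, center, side)
        p = random_cloud.points
        expected = (
            (np.abs(p["x"] - center[0]) <= side / 2)
            & (np.abs(p["y"] - center[1]) <= side / 2)
        ).sum()
        assert len(clipped) == expected
        assert 0 < len(clipped) < len(random_cloud)

    def test_rejects_bad_window(self, random_cloud):
        with pytest.raises(ValueError):
            clip_rectangle(random_cloud, (0, 0), side=-1)


class TestNormalizeHeights:
    def test_flat_classified_ground(self):
        cloud = make_cloud(
            x=[0, 5, 10, 5], y=[0, 5, 10, 5], z=[2.0, 2.0, 2.0, 17.0],
            ground=[True, True, True, False],
        )
        norm = normalize_heights(cloud, ground="classified_returns")
        assert norm.points["height"].iloc[3] == pytest.approx(15.0, abs=1e-9)

    def test_below_ground_clamped_to_zero(self):
        cloud = make_cloud(
            x=[0, 10, 5], y=[0, 10, 5], z=[2.0, 2.0, 1.9],
            ground=[True, True, False],
        )
        norm = normalize_heights(cloud, ground="classified_returns")
        assert norm.points["height"].iloc[2] == 0.0

    def test_planar_ground_lowest_point_surface(self, rng):
        # 5-degree sloping ground densely sampled; known tree heights on top
        slope = np.tan(np.radians(5.0))
        n = 8000
        gx = rng.uniform(0, 50, n)
        gy = rng.uniform(0, 50, n)
        gz = slope * gx
        tx = np.array([10.0, 25.0, 40.0])
        ty = np.array([10.0, 25.0, 40.0])
        true_h = np.array([8.0, 14.0, 18.0])
        cloud = make_cloud(
            x=np.concatenate([gx, tx]), y=np.concatenate([gy, ty]),
            z=np.concatenate([gz, slope * tx + true_h]),
        )
        norm = normalize_heights(cloud, ground="lowest_point_surface", grid_resolution=1.0)
        got = norm.points["height"].iloc[-3:].to_numpy()
        np.testing.assert_allclose(got, true_h, atol=0.1)

    def test_no_ground_information_raises(self):
        cloud = make_cloud(x=[0.0], y=[0.0], z=[5.0])
        with pytest.raises(ValueError):
            normalize_heights(cloud, ground="classified_returns")


class TestStratify:
    @pytest.mark.parametrize(
        "height, stratum",
        [(0.0, "ground"), (0.5, "shrub"), (1.37, "shrub"), (1.38, "tree"), (20.0, "tree")],
    )
    def test_threshold_and_tie_rule(self, height, stratum):
        assert stratify_return(height) == stratum

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError):
            stratify_return(-0.01)


def brute_force_metrics(cloud, grid):
    """Independent per-cell recomputation over raw returns."""
    p = cloud.points
    out = {m: np.full((grid.n_rows, grid.n_cols), np.nan) for m in
           ("FCover", "TreeMean", "ShrubMean", "PulseDensity")}
    out["CHM"] = np.zeros((grid.n_rows, grid.n_cols))
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            x0 = grid.origin[0] + c * grid.cell_size
            y0 = grid.origin[1] + r * grid.cell_size
            hi_x = x0 + grid.cell_size
            hi_y = y0 + grid.cell_size
            in_x = (p["x"] >= x0) & ((p["x"] < hi_x) | ((c == grid.n_cols - 1) & (p["x"] == hi_x)))
            in_y = (p["y"] >= y0) & ((p["y"] < hi_y) | ((r == grid.n_rows - 1) & (p["y"] == hi_y)))
            cell = p[in_x & in_y]
            h = cell["height"]
            first = cell["return_number"] == 1
            tree = h > TREE_HEIGHT_THRESHOLD
            shrub = (h > 0) & ~tree
            if first.sum() > 0:
                out["FCover"][r, c] = (first & tree).sum() / first.sum()
                out["PulseDensity"][r, c] = first.sum() / grid.cell_area_m2
            if tree.sum() > 0:
                out["TreeMean"][r, c] = h[tree].mean()
                out["CHM"][r, c] = h[tree].max()
            if shrub.sum() > 0:
                out["ShrubMean"][r, c] = h[shrub].mean()
    return out


class TestGridMetrics:
    def test_single_cell_hand_values(self):
        # 10 first returns, 9 tree stratum -> FCover 0.9
        h = np.array([15.0] * 9 + [0.5])
        cloud = make_cloud(
            x=np.full(10, 5.0), y=np.full(10, 5.0), z=h, height=h,
        )
        grid = GridSpec(origin=(0, 0), cell_size=13.0, n_rows=1, n_cols=1)
        m = compute_grid_metrics(cloud, grid)
        assert m["FCover"].values[0, 0] == pytest.approx(0.9)
        assert m["PulseDensity"].values[0, 0] == pytest.approx(10 / 169)

    def test_pulse_density_338_returns_is_2(self):
        h = np.zeros(338)
        cloud = make_cloud(x=np.full(338, 1.0), y=np.full(338, 1.0), z=h, height=h)
        grid = GridSpec(origin=(0, 0), cell_size=13.0, n_rows=1, n_cols=1)
        m = compute_grid_metrics(cloud, grid)
        assert m["PulseDensity"].values[0, 0] == pytest.approx(2.0)

    def test_matches_brute_force(self, random_cloud):
        grid = GridSpec.from_extent(0, 0, 100, 100, 13.0)
        fast = compute_grid_metrics(random_cloud, grid)
        slow = brute_force_metrics(random_cloud, grid)
        for name in fast:
            np.testing.assert_allclose(
                fast[name].values, slow[name], rtol=1e-9, equal_nan=True,
                err_msg=name,
            )

    def test_permutation_invariant(self, random_cloud, rng):
        grid = GridSpec.from_extent(0, 0, 100, 100, 13.0)
        perm = rng.permutation(len(random_cloud))
        shuffled = make_cloud(
            **{
                k: random_cloud.points[k].to_numpy()[perm]
                for k in ("x", "y", "z", "return_number", "n_returns", "height")
            }
        )
        a = compute_grid_metrics(random_cloud, grid)
        b = compute_grid_metrics(shuffled, grid)
        for name in a:
            np.testing.assert_allclose(a[name].values, b[name].values, equal_nan=True)

    def test_fcover_bounds_and_chm_dominates_treemean(self, random_cloud):
        grid = GridSpec.from_extent(0, 0, 100, 100, 13.0)
        m = compute_grid_metrics(random_cloud, grid)
        fc = m["FCover"].values
        assert np.nanmin(fc) >= 0 and np.nanmax(fc) <= 1
        both = np.isfinite(m["TreeMean"].values)
        assert (m["CHM"].values[both] >= m["TreeMean"].values[both] - 1e-12).all()

    def test_requires_normalized_heights(self):
        cloud = make_cloud(x=[1.0], y=[1.0], z=[5.0])
        grid = GridSpec(origin=(0, 0), n_rows=1, n_cols=1)
        with pytest.raises(ValueError, match="normalize"):
            compute_grid_metrics(cloud, grid)


class TestVerticalProfile:
    def test_hand_counts(self):
        cloud = make_cloud(x=[0, 0, 0], y=[0, 0, 0], z=[0, 0, 0],
                           height=[0.5, 1.5, 1.5])
        prof = vertical_profile(cloud, bin_height=1.0)
        assert list(prof["count"]) == [1, 2]

    def test_counts_conserved_with_empty_bins(self, random_cloud):
        prof = vertical_profile(random_cloud, bin_height=1.0)
        assert prof["count"].sum() == len(random_cloud)
        assert (prof["count"] == 0).any()  # 2..4 m band is empty by construction


class TestPulseCountChange:
    def test_difference_is_post_minus_pre(self, random_cloud):
        sub = clip_rectangle(random_cloud, (50, 50), side=60)
        n_pre, n_post, diff = pulse_count_change(random_cloud, sub)
        assert (n_pre, n_post) == (len(random_cloud), len(sub))
        assert diff == n_post - n_pre
        assert pulse_count_change(random_cloud, random_cloud)[2] == 0

    def test_first_returns_only_switch(self, random_cloud):
        n_pre, _, _ = pulse_count_change(random_cloud, random_cloud,
                                         first_returns_only=True)
        assert n_pre == (random_cloud.points["return_number"] == 1).sum()
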