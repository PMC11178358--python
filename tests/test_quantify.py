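import numpy as np
import pandas as pd
import pytest

from saberspot.quantify import CellCounts, Polyline, assign_spots, kymograph_all, \
    make_nuclear_image, polyline_kymograph
from saberspot.spots import NucleusSet, SpotSet


def nucleus_set(positions):
    positions = np.asarray(positions)
    return NucleusSet(positions, np.ones(len(positions)))


def spot_set(**per_gene):
    pos = {g: np.asarray(p).reshape(-1, 3) for g, p in per_gene.items()}
    return SpotSet(pos, {g: np.ones(len(p)) for g, p in pos.items()})


class TestAssignSpots:
    def test_single_nucleus_collects_everything(self, rng):
        spots = spot_set(Sox10=rng.uniform(0, 50, (7, 3)))
        counts = assign_spots(spots, nucleus_set([[25, 25]]))
        assert counts.table["Sox10"].tolist() == [7]

    def test_nearest_neighbour_in_2d(self):
        spots = spot_set(g=[[5, 0, 4]])  # z ignored; (y, x) = (0, 4)
        counts = assign_spots(spots, nucleus_set([[0, 0], [0, 10]]))
        assert counts.table["g"].tolist() == [1, 0]

    def test_tie_goes_to_lowest_id(self):
        spots = spot_set(g=[[0, 0, 5]])  # equidistant from both nuclei
        counts = assign_spots(spots, nucleus_set([[0, 0], [0, 10]]))
        assert counts.table["g"].tolist() == [1, 0]

    def test_conservation_with_unlimited_radius(self, rng):
        spots = spot_set(a=rng.uniform(0, 100, (37, 3)), b=rng.uniform(0, 100, (11, 3)))
        counts = assign_spots(spots, nucleus_set(rng.uniform(0, 100, (5, 2))))
        assert counts.total("a") == 37 and counts.total("b") == 11
        assert counts.unassigned == {"a": 0, "b": 0}

    def test_finite_radius_reports_unassigned(self):
        spots = spot_set(g=[[0, 0, 0], [0, 60, 60]])
        counts = assign_spots(spots, nucleus_set([[0, 0]]), max_radius=10.0)
        assert counts.table["g"].tolist() == [1]
        assert counts.unassigned["g"] == 1

    def test_spot_order_is_irrelevant(self, rng):
        pts = rng.uniform(0, 100, (40, 3))
        nuclei = nucleus_set(rng.uniform(0, 100, (6, 2)))
        c1 = assign_spots(spot_set(g=pts), nuclei)
        c2 = assign_spots(spot_set(g=pts[::-1]), nuclei)
        pd.testing.assert_frame_equal(c1.table, c2.table)

    def test_no_nuclei_all_unassigned(self):
        counts = assign_spots(spot_set(g=[[0, 1, 2]]), nucleus_set(np.empty((0, 2))))
        assert counts.unassigned["g"] == 1


class TestMakeNuclearImage:
    def test_empty_counts_zero_image(self):
        counts = CellCounts(pd.DataFrame(columns=["y", "x", "g"]))
        img = make_nuclear_image(counts, (32, 32), "g")
        assert img.sum() == 0

    def test_disk_value_equals_count(self):
        counts = CellCounts(pd.DataFrame({"y": [16], "x": [16], "g": [12]}))
        img = make_nuclear_image(counts, (32, 32), "g", disk_radius=5)
        assert img[16, 16] == 12
        assert img[16, 25] == 0

    def test_disjoint_disks_sum(self):
        counts = CellCounts(pd.DataFrame({"y": [10, 40], "x": [10, 40], "g": [3, 8]}))
        img = make_nuclear_image(counts, (64, 64), "g", disk_radius=6)
        assert set(np.unique(img)) == {0.0, 3.0, 8.0}

    def test_overlap_resolved_by_maximum(self):
        counts = CellCounts(pd.DataFrame({"y": [20, 20], "x": [20, 26], "g": [3, 9]}))
        img = make_nuclear_image(counts, (40, 40), "g", disk_radius=6)
        assert img[20, 23] == 9


class TestPolyline:
    def test_validation(self):
        with pytest.raises(ValueError):
            Polyline([[0, 0]])
        with pytest.raises(ValueError):
            Polyline([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            Polyline([[0, 0], [0, 5]], width=0.5)

    def test_arc_length_and_sampling(self):
        line = Polyline([[0, 0], [0, 10], [10, 10]], width=3, step=1.0)
        assert line.arc_length() == pytest.approx(20.0)
        pts, tans, s = line.sample()
        assert len(s) == 21  # floor(L / step) + 1
        np.testing.assert_allclose(pts[0], [0, 0])
        np.testing.assert_allclose(pts[-1], [10, 10])
        # vertex tangent is the bisector of the two segment directions
        np.testing.assert_allclose(tans[10], [np.sqrt(0.5), np.sqrt(0.5)])


class TestPolylineKymograph:
    def test_constant_image_constant_kymograph(self):
        img = np.full((80, 120), 6.5)
        line = Polyline([[40, 10], [40, 110], [70, 110]], width=20)
        row = polyline_kymograph(img, line)
        np.testing.assert_allclose(row, 6.5, atol=1e-9)

    def test_linear_ramp_recovered(self):
        yy, xx = np.mgrid[0:200, 0:200]
        img = xx.astype(float)
        line = Polyline([[100, 20], [100, 180]], width=100)
        row = polyline_kymograph(img, line)
        want = 20 + np.arange(len(row))
        assert np.abs(row - want).max() <= 0.5

    def test_gaussian_stripe_profile(self):
        yy, xx = np.mgrid[0:120, 0:240]
        peak = 50.0
        img = peak * np.exp(-((xx - 120) ** 2) / (2 * 8.0**2))  # vertical stripe
        line = Polyline([[60, 20], [60, 220]], width=40)
        row = polyline_kymograph(img, line)
        x = 20 + np.arange(len(row))
        want = peak * np.exp(-((x - 120) ** 2) / (2 * 8.0**2))
        assert np.abs(row - want).max() <= 1e-2 * peak

    def test_out_of_bounds_samples_average_in_bounds_only(self):
        img = np.full((30, 60), 4.0)
        line = Polyline([[1, 5], [1, 55]], width=20)  # wide track near the edge
        row = polyline_kymograph(img, line)
        np.testing.assert_allclose(row, 4.0, atol=1e-9)


class TestKymographAll:
    def test_rows_stacked_in_requested_order(self):
        imgs = {"a": np.full((20, 50), 1.0), "b": np.full((20, 50), 2.0)}
        line = Polyline([[10, 5], [10, 45]], width=5)
        k = kymograph_all(imgs, line, order=["b", "a"])
        assert k.genes == ["b", "a"]
        np.testing.assert_allclose(k.values[0], 2.0)
        np.testing.assert_allclose(k.values[1], 1.0)
        assert k.values.shape[1] == len(k.arc_positions)

    def test_mismatched_shapes_raise(self):
        imgs = {"a": np.zeros((20, 50)), "b": np.zeros((10, 50))}
        with pytest.raises(ValueError):
            kymograph_all(imgs, Polyline([[5, 5], [5, 45]]))

    def test_tsv_round_trip(self, tmp_path):
        imgs = {"a": np.random.default_rng(0).uniform(size=(30, 60))}
        line = Polyline([[15, 5], [15, 55]], width=9)
        k = kymograph_all(imgs, line)
        k.to_tsv(tmp_path / "k.tsv")
        df = pd.read_csv(tmp_path / "k.tsv", sep="\t")
        np.testing.assert_allclose(df["a"].to_numpy(), k.values[0])

    def test_expression_transition_monotone_after_smoothing(self):
        """A track crossing from a high-rate territory into a low-rate
        territory yields a non-increasing smoothed count-map kymograph
        (the qualitative premigratory -> migratory marker transition)."""
        xs = np.arange(20, 281, 8)
        ys = np.full(len(xs), 60.0)
        counts = np.where(xs < 150, 30, 4)
        cc = CellCounts(pd.DataFrame({"y": ys, "x": xs, "g": counts}))
        img = make_nuclear_image(cc, (120, 300), "g", disk_radius=12)
        line = Polyline([[60, 30], [60, 270]], width=100)
        row = polyline_kymograph(img, line)
        smooth = np.convolve(row, np.ones(5) / 5, mode="valid")
        drop = np.diff(smooth)
        # monotone non-increasing up to tiny numerical wiggle
        assert (drop <= 1e-6 + 0.05 * np.abs(smooth[:-1])).all()
        assert smooth[0] > smooth[-1]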