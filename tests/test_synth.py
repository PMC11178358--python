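import numpy as np
import pytest

from saberspot.register import RigidTransform
from saberspot.synth import SceneParams, SceneTooCrowdedError, generate_scene, \
    read_truth_tables, render_round, simulate_marker_cells, write_truth_tables

from conftest import small_scene_params
from _oracles import cross_correlation_shift

GENES = ("Sox10", "Wnt1", "Sp5", "Pak3", "Dlc1")


class TestSceneParams:
    def test_validation_rejects_bad_configs(self):
        with pytest.raises(ValueError, match="debris_amplitude"):
            SceneParams(debris_amplitude=10.0, spot_amplitude=100.0).validate()
        with pytest.raises(ValueError, match="round 1 or 2"):
            SceneParams(round_assignment={g: 1 for g in GENES[:-1]} | {GENES[-1]: 3}).validate()
        with pytest.raises(ValueError, match=">= 0"):
            SceneParams(expression_rate={g: -1.0 for g in GENES}).validate()

    def test_yaml_round_trip(self, tmp_path):
        p = small_scene_params(seed=9)
        p.to_yaml(tmp_path / "scene.yaml")
        q = SceneParams.from_yaml(tmp_path / "scene.yaml")
        assert q.to_dict() == p.to_dict()


class TestGenerateScene:
    def test_empty_scene(self):
        p = small_scene_params(n_nuclei=0)
        t = generate_scene(p)
        assert all(len(t.puncta[g]) == 0 for g in GENES)

    def test_zero_rates_give_zero_counts(self):
        p = small_scene_params(expression_rate={g: 0.0 for g in GENES})
        t = generate_scene(p)
        assert all((t.counts[g] == 0).all() for g in GENES)

    def test_count_conservation_and_regeneration(self):
        p = small_scene_params(seed=21, expression_rate={g: 30.0 for g in GENES})
        t1 = generate_scene(p)
        t2 = generate_scene(p)  # independently re-drawn with the same seed
        for g in GENES:
            assert int(t1.counts[g].sum()) == len(t1.puncta[g])
            np.testing.assert_array_equal(t1.counts[g], t2.counts[g])
            np.testing.assert_array_equal(t1.puncta[g], t2.puncta[g])

    def test_minimum_nucleus_spacing_respected(self):
        t = generate_scene(small_scene_params(seed=4))
        c = t.nucleus_centers
        d = np.linalg.norm(c[:, None] - c[None], axis=-1)
        d[np.diag_indices(len(c))] = np.inf
        assert d.min() >= 90.0

    def test_crowded_scene_raises(self):
        p = small_scene_params(n_nuclei=40)  # cannot fit at 90 px spacing
        with pytest.raises(SceneTooCrowdedError):
            generate_scene(p)

    def test_rate_doubling_doubles_expected_totals(self):
        """Expected total puncta scale linearly with the expression rate
        (checked within 3 SD of the Poisson prediction over 60 seeds)."""
        lo, hi = [], []
        for seed in range(60):
            p1 = small_scene_params(seed=seed, expression_rate={g: 5.0 for g in GENES})
            p2 = small_scene_params(seed=1000 + seed,
                                    expression_rate={g: 10.0 for g in GENES})
            lo.append(sum(len(generate_scene(p1).puncta[g]) for g in GENES))
            hi.append(sum(len(generate_scene(p2).puncta[g]) for g in GENES))
        lo, hi = np.array(lo), np.array(hi)
        diff = hi.mean() - 2 * lo.mean()
        sd = np.sqrt(hi.var() / len(hi) + 4 * lo.var() / len(lo))
        assert abs(diff) <= 3 * sd


class TestRenderRound:
    def test_invalid_round_raises(self):
        p = small_scene_params()
        with pytest.raises(ValueError):
            render_round(generate_scene(p), p, 3)

    def test_single_punctum_argmax(self):
        p = small_scene_params(n_nuclei=1, noise_sd=0.0, n_debris=0,
                               expression_rate={g: 0.0 for g in GENES})
        t = generate_scene(p)
        t.puncta["Sox10"] = np.array([[6.0, 150.0, 100.0]])
        t.puncta_owner["Sox10"] = np.array([0])
        t.puncta_amplitude["Sox10"] = np.array([100.0])
        t.counts["Sox10"] = np.array([1])
        img = render_round(t, p, 1).channel("Sox10")
        assert np.unravel_index(np.argmax(img), img.shape) == (6, 150, 100)

    def test_identity_transform_rounds_identical_without_noise(self):
        p = small_scene_params(noise_sd=0.0,
                               inter_round_transform=RigidTransform())
        t = generate_scene(p)
        d1 = render_round(t, p, 1).channel("DAPI")
        d2 = render_round(t, p, 2).channel("DAPI")
        np.testing.assert_array_equal(d1, d2)

    def test_known_shift_recovered_by_cross_correlation_oracle(self):
        p = small_scene_params(noise_sd=0.0, n_debris=0,
                               inter_round_transform=RigidTransform(0.0, -3.0, 5.0))
        t = generate_scene(p)
        a = render_round(t, p, 1).channel("DAPI").sum(axis=0)
        b = render_round(t, p, 2).channel("DAPI").sum(axis=0)
        # b is a translated by (dy=-3, dx=+5); the oracle reports the shift of b vs a
        dy, dx = cross_correlation_shift(b, a)
        assert (dy, dx) == (-3, 5)

    def test_seed_determinism_bit_identical_stacks(self):
        p = small_scene_params(seed=13)
        s1 = render_round(generate_scene(p), p, 1)
        s2 = render_round(generate_scene(p), p, 1)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_debris_present_in_every_gene_channel(self):
        p = small_scene_params(noise_sd=0.0,
                               expression_rate={g: 0.0 for g in GENES})
        t = generate_scene(p)
        stk = render_round(t, p, 1)
        for g in ("Sox10", "Wnt1", "Sp5"):
            img = stk.channel(g) - p.background_level
            for z, y, x in t.debris:
                assert img[round(z), round(y), round(x)] > 0.5 * p.debris_amplitude * 0.8


class TestTruthTables:
    def test_round_trip_exact(self, tmp_path):
        p = small_scene_params(seed=17)
        t = generate_scene(p)
        write_truth_tables(t, tmp_path)
        back = read_truth_tables(tmp_path)
        np.testing.assert_array_equal(back.nucleus_centers, t.nucleus_centers)
        assert back.transform == t.transform
        for g in GENES:
            np.testing.assert_array_equal(back.counts[g], t.counts[g])
            np.testing.assert_array_equal(back.puncta[g], t.puncta[g])
            np.testing.assert_array_equal(back.puncta_owner[g], t.puncta_owner[g])
            np.testing.assert_array_equal(back.puncta_amplitude[g], t.puncta_amplitude[g])

    def test_empty_scene_round_trip(self, tmp_path):
        p = small_scene_params(n_nuclei=0, n_debris=0)
        t = generate_scene(p)
        write_truth_tables(t, tmp_path)
        back = read_truth_tables(tmp_path)
        assert back.nucleus_centers.shape == (0, 2)
        assert all(len(back.puncta[g]) == 0 for g in GENES)

    def test_writes_byte_identical_for_same_seed(self, tmp_path):
        p = small_scene_params(seed=19)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_truth_tables(generate_scene(p), d1)
        write_truth_tables(generate_scene(p), d2)
        for name in ("truth_cells.tsv", "truth_puncta.tsv", "truth_debris.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


class TestMarkerCells:
    def test_positive_rate_realized(self):
        _, markers, centers, truth = simulate_marker_cells(80, 0.5, seed=2)
        assert len(centers) == 80
        assert 20 <= truth["A"].sum() <= 60
        # positive cells are bright, negative dim
        assert markers["A"].max() > 200
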