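"""Grid geometry, super-SOM training/prediction, codebook analysis."""

import numpy as np
import pandas as pd
import pytest

import somtag as st
from somtag.supersom import ModelValidationError


def _toy_table(X, labels):
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
    df.insert(0, "behaviour", labels)
    return df


def _two_cluster_table(n=60, d=4, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 0.3, size=(n, d))
    b = rng.normal(5.0, 0.3, size=(n, d))
    return _toy_table(np.vstack([a, b]), ["lying"] * n + ["walking"] * n)


class TestMakeGrid:
    def test_default_study_grid_has_49_units(self):
        grid = st.make_grid(7, 7, "hexagonal")
        assert grid.n_units == 49
        assert grid.unit_dist.shape == (49, 49)

    def test_single_unit_grid(self):
        grid = st.make_grid(1, 1)
        assert grid.n_units == 1
        np.testing.assert_array_equal(grid.unit_dist, [[0.0]])

    def test_hexagonal_geometry(self):
        grid = st.make_grid(2, 2, "hexagonal")
        # second row offset by 0.5, spacing sqrt(3)/2
        np.testing.assert_allclose(grid.unit_coords[2], [0.5, np.sqrt(3) / 2])
        off_diag = grid.unit_dist[np.triu_indices(4, k=1)]
        assert off_diag.min() == pytest.approx(1.0)
        assert np.all(np.abs(grid.unit_dist - grid.unit_dist.T) < 1e-12)

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            st.make_grid(0, 3)


class TestOneHot:
    def test_indicator_properties(self):
        labels = ["walking", "lying", "walking", "trotting"]
        classes = list(st.BEHAVIOURS)
        M = st.one_hot(labels, classes)
        assert M.shape == (4, 12)
        np.testing.assert_array_equal(M.sum(axis=1), np.ones(4))
        # argmax round-trip and column sums = class frequencies
        assert [classes[j] for j in M.argmax(axis=1)] == labels
        assert M.sum(axis=0)[classes.index("walking")] == 2

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            st.one_hot(["flying"], list(st.BEHAVIOURS))


class TestTraining:
    def test_identical_rows_collapse_codebooks(self):
        X = np.tile([1.0, 2.0, 3.0], (40, 1))
        table = _toy_table(X, ["lying"] * 40)
        with pytest.warns(UserWarning, match="constant"):
            model = st.train_supersom(table, st.make_grid(3, 3), seed=0)
        # scaled encoding of the unique row is the zero vector
        np.testing.assert_allclose(model.codebook_meas, 0.0, atol=1e-12)
        onehot = np.zeros(len(model.class_names))
        onehot[model.class_names.index("lying")] = 1.0
        np.testing.assert_allclose(model.codebook_act, np.tile(onehot, (9, 1)), atol=1e-12)
        assert st.quantisation_error(model, table) == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_reproduces_bit_identical_model(self):
        table = _two_cluster_table()
        p = st.TrainParams(rlen=20)
        m1 = st.train_supersom(table, st.make_grid(3, 3), params=p, seed=42)
        m2 = st.train_supersom(table, st.make_grid(3, 3), params=p, seed=42)
        assert np.array_equal(m1.codebook_meas, m2.codebook_meas)
        assert np.array_equal(m1.codebook_act, m2.codebook_act)

    def test_radius_zero_equals_online_vq_oracle(self):
        """With radius 0, constant alpha and the activity layer switched
        off, training must replay an online vector-quantisation oracle
        exactly, step by step."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        table = _toy_table(X, ["lying"] * 15 + ["walking"] * 15)
        k = 4
        grid = st.make_grid(1, k)
        alpha = 0.05
        params = st.TrainParams(
            rlen=6, alpha_start=alpha, alpha_end=alpha,
            radius0=0.0, user_weights=(1.0, 0.0), scale=False,
        )
        init_m = X[:k].copy()
        init_a = st.one_hot(["lying"] * k, sorted({"lying", "walking"}))
        order = np.tile(np.arange(30), 6)
        model = st.train_supersom(
            table, grid, params=params, seed=0,
            class_names=sorted({"lying", "walking"}),
            init=(init_m.copy(), init_a.copy()), order=order,
        )
        # independent plain-python online VQ replay
        cb = init_m.copy()
        for i in order:
            d = ((X[i] - cb) ** 2).sum(axis=1)
            b = int(np.argmin(d))
            cb[b] = cb[b] + alpha * (X[i] - cb[b])
        np.testing.assert_allclose(model.codebook_meas, cb, rtol=0, atol=1e-12)

    def test_quantisation_error_improves_with_longer_training(self):
        table = _two_cluster_table(n=80, seed=5)
        grid = st.make_grid(3, 3)
        qe = {rlen: [] for rlen in (2, 40)}
        for seed in range(10):
            for rlen in qe:
                m = st.train_supersom(table, grid, params=st.TrainParams(rlen=rlen), seed=seed)
                qe[rlen].append(st.quantisation_error(m, table))
        assert np.median(qe[40]) <= np.median(qe[2]) + 1e-9

    def test_empty_table_rejected(self):
        table = _toy_table(np.empty((0, 3)), [])
        with pytest.raises(ValueError):
            st.train_supersom(table, st.make_grid(2, 2), seed=0)


class TestPrediction:
    def test_separable_classes_recovered(self):
        table = _two_cluster_table()
        model = st.train_supersom(table, st.make_grid(3, 3), seed=1)
        pred = st.predict(model, table)
        train_acc = np.mean(np.array(pred.behaviour) == table["behaviour"].to_numpy())
        test = _two_cluster_table(seed=99)
        test_acc = np.mean(
            np.array(st.predict(model, test).behaviour) == test["behaviour"].to_numpy()
        )
        assert train_acc >= test_acc - 1e-9
        assert test_acc > 0.95

    def test_codebook_row_is_its_own_bmu(self):
        table = _two_cluster_table()
        model = st.train_supersom(table, st.make_grid(3, 3), seed=1)
        probe = model.codebook_meas[5] * model.spread + model.centre
        df = pd.DataFrame([probe], columns=model.feature_names)
        assert st.predict(model, df).unit[0] == 5

    def test_uniform_activity_codebook_returns_first_class(self):
        table = _two_cluster_table()
        model = st.train_supersom(table, st.make_grid(1, 1), seed=0)
        model.codebook_act[:] = 0.5
        pred = st.predict(model, table.head(3))
        assert pred.behaviour == [model.class_names[0]] * 3

    def test_feature_name_mismatch_rejected(self):
        table = _two_cluster_table()
        model = st.train_supersom(table, st.make_grid(2, 2), seed=0)
        bad = table.rename(columns={"f0": "other"})
        with pytest.raises(ValueError, match="missing model features"):
            st.predict(model, bad)


class TestCodebookAnalysis:
    def test_identical_codebooks_have_zero_distance(self):
        table = _toy_table(np.tile([0.0, 1.0], (20, 1)), ["lying"] * 20)
        with pytest.warns(UserWarning):
            model = st.train_supersom(table, st.make_grid(2, 2), seed=0)
        np.testing.assert_allclose(st.codebook_distances(model), 0.0, atol=1e-9)

    def test_two_unit_distance_matches_hand_computation(self):
        table = _two_cluster_table()
        model = st.train_supersom(table, st.make_grid(1, 2), seed=0)
        wm, wa = model.params.user_weights
        sm, sa = model.dist_scale
        want = np.sqrt(
            wm * ((model.codebook_meas[0] - model.codebook_meas[1]) ** 2).sum() / sm
            + wa * ((model.codebook_act[0] - model.codebook_act[1]) ** 2).sum() / sa
        )
        D = st.codebook_distances(model)
        assert D[0, 1] == pytest.approx(want)
        assert D[1, 0] == pytest.approx(want)
        assert D[0, 0] == 0.0

    def test_triangle_inequality(self):
        table = _two_cluster_table(seed=8)
        model = st.train_supersom(table, st.make_grid(3, 3), seed=2)
        D = st.codebook_distances(model)
        U = D.shape[0]
        for i in range(U):
            for j in range(U):
                assert np.all(D[i, j] <= D[i, :] + D[:, j] + 1e-9)

    def test_cluster_trivial_cuts(self):
        table = _two_cluster_table()
        model = st.train_supersom(table, st.make_grid(2, 2), seed=0)
        assert set(st.cluster_codebook(model, k=4)) == {1, 2, 3, 4}
        assert set(st.cluster_codebook(model, k=1)) == {1}
        with pytest.raises(ValueError):
            st.cluster_codebook(model, k=5)

    def test_two_tight_pairs_grouped_like_exhaustive_linkage(self):
        table = _two_cluster_table()
        model = st.train_supersom(table, st.make_grid(2, 2), seed=0)
        # hand-set codebooks: two tight pairs far apart
        model.codebook_meas[:] = 0.0
        model.codebook_meas[:, 0] = [0.0, 0.1, 5.0, 5.1]
        model.codebook_act[:] = 0.5
        clusters = st.cluster_codebook(model, k=2)
        assert clusters[0] == clusters[1]
        assert clusters[2] == clusters[3]
        assert clusters[0] != clusters[2]
        # brute force: complete linkage over all merge orders on 4 points
        D = st.codebook_distances(model)
        best_pairing = min(
            (
                (max(D[0, 1], D[2, 3]), ((0, 1), (2, 3))),
                (max(D[0, 2], D[1, 3]), ((0, 2), (1, 3))),
                (max(D[0, 3], D[1, 2]), ((0, 3), (1, 2))),
            )
        )[1]
        assert best_pairing == ((0, 1), (2, 3))

    def test_component_plane_inverts_scaling(self):
        table = _two_cluster_table()
        model = st.train_supersom(table, st.make_grid(2, 2), seed=0)
        j = model.feature_names.index("f1")
        np.testing.assert_allclose(
            st.component_plane(model, "f1"),
            model.codebook_meas[:, j] * model.spread[j] + model.centre[j],
        )
        with pytest.raises(ValueError):
            st.component_plane(model, "nope")

    def test_plane_peaks_on_the_separating_behaviour(self, model7):
        # lying is the only posture lying on its side: mean_y is maximal
        plane = st.component_plane(model7, "mean_y")
        dominant = np.argmax(model7.codebook_act, axis=1)
        best_unit = int(np.argmax(plane))
        assert model7.class_names[dominant[best_unit]] == "lying"


class TestSerialisation:
    def test_round_trip_preserves_predictions_and_distances(self, tmp_path):
        table = _two_cluster_table()
        model = st.train_supersom(table, st.make_grid(3, 3), seed=3)
        p = tmp_path / "model.json"
        st.save_model(model, p)
        back = st.load_model(p)
        pred0 = st.predict(model, table)
        pred1 = st.predict(back, table)
        assert pred0.behaviour == pred1.behaviour
        np.testing.assert_array_equal(pred0.unit, pred1.unit)
        np.testing.assert_allclose(
            st.codebook_distances(back), st.codebook_distances(model), atol=1e-12
        )

    def test_tampered_class_count_rejected(self, tmp_path):
        import json

        table = _two_cluster_table()
        model = st.train_supersom(table, st.make_grid(2, 2), seed=0)
        p = tmp_path / "model.json"
        st.save_model(model, p)
        doc = json.loads(p.read_text())
        doc["class_names"] = doc["class_names"][:-1]
        p.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError):
            st.load_model(p)

    def test_version_mismatch_rejected(self, tmp_path):
        import json

        table = _two_cluster_table()
        model = st.train_supersom(table, st.make_grid(2, 2), seed=0)
        p = tmp_path / "model.json"
        st.save_model(model, p)
        doc = json.loads(p.read_text())
        doc["version"] = 99
        p.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError):
            st.load_model(p)
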