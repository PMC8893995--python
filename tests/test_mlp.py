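"""MLP forward pass, training, splitting, and subset ranking."""

import numpy as np
import pytest

from possireg.data import ConfigurationError
from possireg.mlp import (
    InsufficientDataError,
    MLPConfig,
    MLPModel,
    mse,
    predict,
    select_variables,
    split_train_test,
    train_mlp,
)


def hand_model(v, b1, w, b2, scaling, activation="logistic"):
    v = np.atleast_2d(np.asarray(v, float))
    names = ("x",) if v.shape[1] == 1 else tuple(f"x{i}" for i in range(v.shape[1]))
    return MLPModel(
        input_columns=names,
        input_to_hidden_weights=v,
        hidden_bias=np.asarray(b1, float),
        hidden_to_output_weights=np.asarray(w, float),
        output_bias=b2,
        activation=activation,
        input_scaling=tuple(scaling),
    )


class TestForwardPass:
    def test_zero_output_weights_return_bias(self):
        model = hand_model([[1.0, 2.0]], [0.3], [0.0], 4.5, [(0, 1), (0, 1)])
        out = predict(model, np.array([[0.2, 0.9], [5.0, -3.0]]))
        assert np.allclose(out, 4.5)

    def test_logistic_closed_form_at_scaled_zero(self):
        """v=1, E1=0, w=1, E2=0 at an input scaling to 0 gives g(0) = 0.5."""
        model = hand_model([[1.0]], [0.0], [1.0], 0.0, [(2.0, 4.0)])
        assert predict(model, np.array([[2.0]]))[0] == pytest.approx(0.5)

    def test_forward_pass_deterministic(self):
        model = hand_model([[1.0, -1.0], [0.5, 2.0]], [0.1, -0.2], [1.0, 2.0], 0.3,
                           [(0, 1), (0, 1)])
        X = np.random.default_rng(0).uniform(0, 1, (10, 2))
        assert np.array_equal(predict(model, X), predict(model, X))


class TestSplit:
    def test_seventy_thirty_on_ten_rows(self, make_design):
        d = make_design({"x": np.arange(10.0)}, np.arange(10.0))
        train, test = split_train_test(d, 0.7, seed=0)
        assert (train.n_rows, test.n_rows) == (7, 3)

    def test_minimal_two_row_split(self, make_design):
        d = make_design({"x": [1.0, 2.0]}, [1.0, 2.0])
        train, test = split_train_test(d, 0.5, seed=0)
        assert (train.n_rows, test.n_rows) == (1, 1)

    def test_partition_is_disjoint_and_exhaustive(self, make_design):
        y = np.arange(23.0)
        d = make_design({"x": y.copy()}, y)
        train, test = split_train_test(d, 0.7, seed=5)
        combined = sorted(np.concatenate([train.y, test.y]).tolist())
        assert combined == y.tolist()

    def test_same_seed_same_partition(self, make_design):
        d = make_design({"x": np.arange(15.0)}, np.arange(15.0))
        a = split_train_test(d, 0.7, seed=11)
        b = split_train_test(d, 0.7, seed=11)
        assert np.array_equal(a[0].y, b[0].y)

    def test_single_row_rejected(self, make_design):
        d = make_design({"x": [1.0]}, [1.0])
        with pytest.raises(InsufficientDataError):
            split_train_test(d, 0.7, seed=0)


class TestTraining:
    def test_learns_noise_free_linear_relation(self, make_design):
        """Test MSE falls below 1% of the response variance, and the trained
        net approaches the least-squares oracle fit on the same data."""
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 80)
        y = 3.0 * x
        d = make_design({"x": x}, y)
        train, test = split_train_test(d, 0.7, seed=1)
        model = train_mlp(train, MLPConfig(hidden_nodes=2, max_iterations=2000, seed=3))
        # least-squares oracle: exact fit exists, so its residual is 0
        coef, res, *_ = np.linalg.lstsq(train.X, train.y, rcond=None)
        assert float(res[0]) < 1e-18
        assert mse(model, test) < 0.01 * y.var()

    def test_training_deterministic_under_seed(self, make_design):
        rng = np.random.default_rng(4)
        d = make_design({"x": rng.uniform(0, 1, 30)}, rng.uniform(0, 1, 30))
        cfg = MLPConfig(max_iterations=200, seed=8)
        a, b = train_mlp(d, cfg), train_mlp(d, cfg)
        assert np.array_equal(a.input_to_hidden_weights, b.input_to_hidden_weights)
        assert a.output_bias == b.output_bias

    def test_scaling_stored_per_input(self, make_design):
        d = make_design({"x1": [1.0, 5.0, 3.0], "x2": [-2.0, 0.0, 4.0]}, [1.0, 2.0, 3.0])
        model = train_mlp(d, MLPConfig(max_iterations=10, seed=0))
        assert model.input_scaling == ((1.0, 5.0), (-2.0, 4.0))

    def test_nonfinite_data_rejected(self, make_design):
        d = make_design({"x": [1.0, np.nan, 3.0]}, [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="non-finite"):
            train_mlp(d, MLPConfig(seed=0))

    def test_unreducible_loss_warns(self, make_design):
        """An absurd learning rate makes every step uphill; the model is
        still returned, flagged unconverged."""
        d = make_design({"x": [0.0, 1.0]}, [0.0, 1.0])
        with pytest.warns(UserWarning, match="failed to reduce"):
            model = train_mlp(d, MLPConfig(max_iterations=2, learning_rate=1e30, seed=0))
        assert not model.converged


class TestMse:
    def test_zero_for_perfect_predictions(self, make_design):
        # a constant net predicting 0 scored against an all-zero response
        model = hand_model([[0.0]], [0.0], [0.0], 0.0, [(1.0, 4.0)])
        d = make_design({"x": [1.0, 2.0, 4.0]}, np.zeros(3))
        assert mse(model, d) == 0.0

    def test_constant_predictor_gives_variance(self, make_design):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        model = hand_model([[0.0]], [0.0], [0.0], float(y.mean()), [(0.0, 1.0)])
        d = make_design({"x": np.zeros(4)}, y)
        assert mse(model, d) == pytest.approx(y.var())

    def test_symmetric_errors_average(self, make_design):
        model = hand_model([[0.0]], [0.0], [0.0], 0.0, [(0.0, 1.0)])
        d = make_design({"x": [0.0, 0.0]}, [1.0, -1.0])  # errors (1, -1)
        assert mse(model, d) == pytest.approx(1.0)

    def test_row_order_invariant(self, make_design):
        rng = np.random.default_rng(2)
        x, y = rng.uniform(0, 1, 12), rng.uniform(0, 1, 12)
        model = hand_model([[0.7]], [0.1], [1.3], 0.2, [(0.0, 1.0)])
        d = make_design({"x": x}, y)
        perm = rng.permutation(12)
        dp = make_design({"x": x[perm]}, y[perm])
        assert mse(model, d) == pytest.approx(mse(model, dp))

    def test_column_mismatch_rejected(self, make_design):
        model = hand_model([[0.0]], [0.0], [0.0], 0.0, [(0.0, 1.0)])
        d = make_design({"other": [0.0, 1.0]}, [0.0, 1.0])
        with pytest.raises(ConfigurationError):
            mse(model, d)


class TestSelectVariables:
    def test_single_candidate_single_score(self, make_design):
        rng = np.random.default_rng(0)
        d = make_design({"x": rng.uniform(0, 1, 20)}, rng.uniform(0, 1, 20))
        scores = select_variables(d, ["x"], MLPConfig(max_iterations=50, seed=0))
        assert len(scores) == 1 and scores[0].subset == ("x",)

    def test_subset_count_is_power_of_two_minus_one(self, cohort20):
        from possireg.data import encode_dummies

        d = encode_dummies(cohort20)
        scores = select_variables(
            d, list(d.groups), MLPConfig(max_iterations=30, seed=0)
        )
        assert len(scores) == 2 ** len(d.groups) - 1  # 7 for 3 blocks
        mses = [s.test_mse for s in scores]
        assert mses == sorted(mses)
        # indicator columns of the categorical variable move as one block
        for s in scores:
            if "BloodPressure" in s.subset:
                break
        sub = d.subset(list(s.subset))
        assert {"Border", "Hyper"} <= set(sub.columns)

    def test_active_predictor_beats_inactive(self, make_design):
        """With y a function of x1 only, the {x1} subset scores no worse than
        any subset that excludes x1 (here: {x2})."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x1, x2 = rng.uniform(0, 10, 60), rng.uniform(0, 10, 60)
            y = 2.0 + 3.0 * x1 + rng.normal(0, 0.2, 60)
            d = make_design({"x1": x1, "x2": x2}, y)
            scores = {
                s.subset: s.test_mse
                for s in select_variables(d, ["x1", "x2"],
                                          MLPConfig(max_iterations=800, seed=seed))
            }
            wins += scores[("x1",)] <= scores[("x2",)]
        assert wins >= 9

    def test_subset_cap_enforced(self, make_design):
        rng = np.random.default_rng(0)
        cols = {f"x{i}": rng.uniform(0, 1, 10) for i in range(3)}
        d = make_design(cols, rng.uniform(0, 1, 10))
        with pytest.raises(ConfigurationError, match="forward-selection"):
            select_variables(d, list(cols), MLPConfig(seed=0), max_subsets=3)

    def test_unknown_candidate_rejected(self, make_design):
        d = make_design({"x": [0.0, 1.0, 2.0]}, [0.0, 1.0, 2.0])
        with pytest.raises(ConfigurationError):
            select_variables(d, ["nope"], MLPConfig(seed=0))
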