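"""Autoencoder construction, forward/backward correctness, and training."""

import numpy as np
import pytest
from scipy.special import expit

import decoyfeat as df
from decoyfeat.autoencoders import TrainedModel, _loss_and_grads
from decoyfeat.errors import InvalidSpecError, TrainingFailureError


def vanilla_spec(enc="identity", dec="identity", **kw):
    return df.AEArchitectureSpec(
        family="vanilla", code_dim=2, encoder_activation=enc,
        decoder_activation=dec, **kw,
    )


class TestSizingRules:
    @pytest.mark.parametrize(
        "input_dim,expected",
        [(159, (250, 125)), (438, (468, 125)), (250, (280, 125)), (249, (250, 125))],
    )
    def test_hidden_layer_sizes(self, input_dim, expected):
        assert df.hidden_layer_sizes(input_dim) == expected

    def test_deep_layer_dims(self):
        spec = df.AEArchitectureSpec(
            family="deep", code_dim=10, encoder_activation="sigmoid",
            decoder_activation="sigmoid",
        )
        assert spec.layer_dims(159) == [159, 250, 125, 10]


class TestBuildModel:
    def test_untied_vanilla_parameter_count(self):
        model = df.build_model(vanilla_spec(), input_dim=6, seed=0)
        assert df.count_free_weights(model) == 2 * 6 * 2
        assert df.count_free_parameters(model) == 24 + 2 + 6

    def test_tying_halves_weight_count_but_not_biases(self):
        tied = df.build_model(vanilla_spec(tie_weights=True), input_dim=6, seed=0)
        assert df.count_free_weights(tied) == 6 * 2
        assert df.count_free_parameters(tied) == 12 + 2 + 6

    def test_parametric_slope_adds_one_alpha_per_layer(self):
        spec = df.AEArchitectureSpec(
            family="deep", code_dim=2,
            encoder_activation="parametric_leaky_relu",
            decoder_activation="parametric_leaky_relu",
        )
        model = df.build_model(spec, input_dim=30, seed=0)
        n_alphas = sum(a is not None for a in model.enc_alpha + model.dec_alpha)
        assert n_alphas == 6

    def test_same_seed_identical_initialization(self):
        a = df.build_model(vanilla_spec(), input_dim=9, seed=5)
        b = df.build_model(vanilla_spec(), input_dim=9, seed=5)
        for (_, x), (_, y) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(x, y)

    def test_code_dim_must_be_below_input_dim(self):
        with pytest.raises(InvalidSpecError):
            df.build_model(vanilla_spec(), input_dim=2, seed=0)

    def test_tying_and_orthogonality_mutually_exclusive(self):
        with pytest.raises(InvalidSpecError):
            vanilla_spec(tie_weights=True, orthogonality=True)


class TestForward:
    def test_identity_network_reconstructs_exactly(self, rng):
        # hand-built square model with identity weights
        spec = vanilla_spec()
        model = TrainedModel(
            architecture=spec, input_dim=2,
            enc_W=[np.eye(2)], enc_b=[np.zeros(2)],
            dec_W=[np.eye(2)], dec_b=[np.zeros(2)],
            enc_alpha=[None], dec_alpha=[None],
        )
        X = rng.normal(size=(5, 2))
        _, recon = df.forward(model, X)
        assert np.array_equal(recon, X)

    def test_sigmoid_decoder_output_in_unit_interval(self, rng):
        model = df.build_model(vanilla_spec(dec="sigmoid"), input_dim=8, seed=1)
        _, recon = df.forward(model, rng.normal(size=(10, 8)))
        assert np.all((recon > 0) & (recon < 1))

    def test_single_affine_layer_matches_hand_computation(self):
        model = df.build_model(vanilla_spec(), input_dim=3, seed=2)
        x = np.array([1.0, -2.0, 0.5])
        code, _ = df.forward(model, x)
        assert np.abs(code[0] - (x @ model.enc_W[0] + model.enc_b[0])).max() < 1e-12

    def test_leaky_relu_negative_slope_applied(self):
        spec = vanilla_spec(enc=df.ActivationKind("leaky_relu", alpha=0.3))
        model = df.build_model(spec, input_dim=3, seed=0)
        model.enc_W[0][:] = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        code, _ = df.forward(model, np.array([-2.0, 4.0, 0.0]))
        assert code[0] == pytest.approx([-0.6, 4.0])


class TestLoss:
    def test_zero_for_perfect_reconstruction(self):
        model = TrainedModel(
            architecture=vanilla_spec(), input_dim=2,
            enc_W=[np.eye(2)], enc_b=[np.zeros(2)],
            dec_W=[np.eye(2)], dec_b=[np.zeros(2)],
            enc_alpha=[None], dec_alpha=[None],
        )
        assert df.loss(model, np.ones((3, 2))) == 0.0

    def test_orthogonality_penalty_zero_at_exact_inverse(self, rng):
        W = rng.normal(size=(2, 2))
        model = TrainedModel(
            architecture=vanilla_spec(orthogonality=True), input_dim=2,
            enc_W=[W], enc_b=[np.zeros(2)],
            dec_W=[np.linalg.inv(W)], dec_b=[np.zeros(2)],
            enc_alpha=[None], dec_alpha=[None],
        )
        assert df.orthogonality_residual(model) < 1e-10

    def test_matches_hand_arithmetic_on_two_samples(self):
        model = TrainedModel(
            architecture=vanilla_spec(), input_dim=2,
            enc_W=[np.eye(2)], enc_b=[np.zeros(2)],
            dec_W=[np.eye(2)], dec_b=[np.array([1.0, 0.0])],
            enc_alpha=[None], dec_alpha=[None],
        )
        X = np.array([[0.0, 0.0], [1.0, 2.0]])
        # reconstructions are X + (1,0): per-row summed SE = 1 and 1
        assert df.loss(model, X) == pytest.approx(1.0, abs=1e-12)


class TestGradients:
    @pytest.mark.parametrize(
        "enc,dec,tie,orth",
        [
            ("identity", "identity", False, False),
            ("sigmoid", "leaky_relu", False, False),
            ("parametric_leaky_relu", "sigmoid", True, False),
            ("sigmoid", "parametric_leaky_relu", False, True),
        ],
    )
    def test_analytic_gradients_match_finite_differences(self, enc, dec, tie, orth):
        spec = vanilla_spec(enc=enc, dec=dec, tie_weights=tie, orthogonality=orth)
        model = df.build_model(spec, input_dim=4, seed=3)
        X = np.random.default_rng(0).normal(size=(5, 4)) + 0.05
        _, grads = _loss_and_grads(model, X, beta=1.0)
        for name, arr in model.parameters():
            indices = list(np.ndindex(arr.shape)) if arr.ndim else [()]
            for idx in indices:
                eps = 1e-6
                orig = float(arr[idx]) if arr.ndim else float(arr)

                def setv(v):
                    if arr.ndim:
                        arr[idx] = v
                    else:
                        arr[...] = v

                setv(orig + eps)
                lp = df.loss(model, X, beta=1.0)
                setv(orig - eps)
                lm = df.loss(model, X, beta=1.0)
                setv(orig)
                numeric = (lp - lm) / (2 * eps)
                analytic = float(grads[name][idx]) if arr.ndim else float(grads[name])
                assert abs(numeric - analytic) <= 1e-5 * max(
                    1.0, abs(numeric) + abs(analytic)
                ), f"{name}[{idx}]: {numeric} vs {analytic}"


class TestTrain:
    def test_linear_tied_vanilla_fits_planted_subspace(self, clean_ensemble):
        ensemble, _ = clean_ensemble
        dataset = df.split_dataset(df.centralize(ensemble), seed=5)
        model = df.build_model(
            vanilla_spec(tie_weights=True), dataset.input_dim, seed=1
        )
        df.train(model, dataset, df.TrainConfig(seed=1))
        assert model.history["train"][-1] < 1e-2 * model.history["train"][0]

    def test_history_length_equals_epochs(self, noisy_dataset):
        dataset, _, _ = noisy_dataset
        model = df.build_model(vanilla_spec(), dataset.input_dim, seed=2)
        df.train(model, dataset, df.TrainConfig(epochs=7, seed=2))
        assert len(model.history["train"]) == 7
        assert len(model.history["validation"]) == 7

    def test_training_deterministic_under_seed(self, noisy_dataset):
        dataset, _, _ = noisy_dataset
        outs = []
        for _ in range(2):
            model = df.build_model(vanilla_spec(), dataset.input_dim, seed=4)
            df.train(model, dataset, df.TrainConfig(epochs=3, seed=4))
            outs.append([arr.copy() for _, arr in model.parameters()])
        for x, y in zip(*outs):
            assert np.array_equal(x, y)

    @pytest.mark.filterwarnings("ignore:overflow:RuntimeWarning")
    @pytest.mark.filterwarnings("ignore:invalid value:RuntimeWarning")
    def test_divergence_reports_epoch(self, noisy_dataset):
        dataset, _, _ = noisy_dataset
        model = df.build_model(vanilla_spec(), dataset.input_dim, seed=0)
        # an absurd learning rate overflows the squared loss to inf
        with pytest.raises(TrainingFailureError) as err:
            df.train(model, dataset, df.TrainConfig(epochs=5, learning_rate=1e200))
        assert err.value.epoch is not None

    def test_tying_holds_after_every_optimizer_step(self, clean_ensemble):
        ensemble, _ = clean_ensemble
        dataset = df.split_dataset(df.centralize(ensemble), seed=5)
        model = df.build_model(
            vanilla_spec(enc="sigmoid", tie_weights=True), dataset.input_dim, seed=1
        )

        def assert_tied(m, step):
            assert m.decoder_weight(0).base is m.enc_W[0]

        df.train(model, dataset, df.TrainConfig(epochs=2, seed=1), step_callback=assert_tied)

    def test_orthogonality_residual_decreases(self, noisy_dataset):
        dataset, _, _ = noisy_dataset
        spec = vanilla_spec(enc="sigmoid", dec="sigmoid", orthogonality=True)
        model = df.build_model(spec, dataset.input_dim, seed=1)
        before = df.orthogonality_residual(model)
        df.train(model, dataset, df.TrainConfig(epochs=15, seed=1))
        assert df.orthogonality_residual(model) < before


class TestReconstructionMse:
    def test_identity_model_scores_zero(self, rng):
        model = TrainedModel(
            architecture=vanilla_spec(), input_dim=2,
            enc_W=[np.eye(2)], enc_b=[np.zeros(2)],
            dec_W=[np.eye(2)], dec_b=[np.zeros(2)],
            enc_alpha=[None], dec_alpha=[None],
        )
        mean, per = df.reconstruction_mse(model, rng.normal(size=(4, 2)))
        assert mean == 0.0 and np.all(per == 0.0)

    def test_single_row_hand_computed(self):
        model = df.build_model(vanilla_spec(), input_dim=3, seed=7)
        x = np.array([0.5, -1.0, 2.0])
        _, recon = df.forward(model, x)
        mean, per = df.reconstruction_mse(model, x)
        assert mean == pytest.approx(((recon[0] - x) ** 2).sum(), abs=1e-12)
        assert per.shape == (1,)

    def test_empty_test_set_rejected(self):
        model = df.build_model(vanilla_spec(), input_dim=3, seed=0)
        with pytest.raises(InvalidSpecError):
            df.reconstruction_mse(model, np.empty((0, 3)))


class TestSerialization:
    def test_checkpoint_round_trip(self, tmp_path, rng):
        from decoyfeat.autoencoders import load_model, save_model

        spec = vanilla_spec(enc="parametric_leaky_relu", dec="sigmoid")
        model = df.build_model(spec, input_dim=6, seed=9)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        X = rng.normal(size=(3, 6))
        assert np.array_equal(df.forward(model, X)[1], df.forward(back, X)[1])
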