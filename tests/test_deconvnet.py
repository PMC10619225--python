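"""Ensemble network: loss oracle, gradients, simplex contract, training."""

import numpy as np
import pytest

from hascad import bulksim
from hascad.deconvnet import (
    DeconvolutionEnsemble,
    EnsembleSpec,
    ModuleSpec,
    _loss_grad,
    _Module,
    composite_loss,
    loss_components,
)
from hascad.vocabulary import DEFAULT_VOCABULARY


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        y = np.array([[0.6, 0.3, 0.1]])
        assert composite_loss(y, y) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_two_type_toy(self):
        # MSE = 1, r = -1 so PCC loss = 2, total 3
        assert composite_loss([1.0, 0.0], [0.0, 1.0]) == pytest.approx(3.0)

    def test_uniform_truth_degenerate_variance(self):
        y = np.full((1, 15), 1 / 15)
        p = np.random.default_rng(0).dirichlet(np.ones(15))[None]
        mse, pcc_loss = loss_components(y, p)
        assert pcc_loss[0] == pytest.approx(1.0)

    def test_pcc_term_bounded(self, rng):
        y = rng.dirichlet(np.ones(15), size=40)
        p = rng.dirichlet(np.ones(15), size=40)
        _, pcc_loss = loss_components(y, p)
        assert ((pcc_loss >= 0) & (pcc_loss <= 2)).all()

    def test_loss_nonnegative_zero_iff_exact(self, rng):
        y = rng.dirichlet(np.ones(15), size=10)
        p = y + rng.normal(0, 0.01, size=y.shape)
        assert composite_loss(y, p) > 0
        assert composite_loss(y, y) == pytest.approx(0.0, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            loss_components(np.ones((2, 15)), np.ones((3, 15)))


def test_loss_gradient_matches_finite_differences(rng):
    spec = ModuleSpec(hidden_sizes=(32, 32, 32), input_dim=10)
    mod = _Module(spec, np.random.default_rng(0))
    # float64 weights so the central-difference probe is not dominated by
    # storage precision
    mod.W = [w.astype(np.float64) for w in mod.W]
    mod.b = [b.astype(np.float64) for b in mod.b]
    X = rng.standard_normal((4, 10))
    Y = rng.dirichlet(np.ones(15), size=4)

    P, cache = mod.forward(X)
    _, dP = _loss_grad(Y, P)
    gW, gb = mod.backward(cache, dP)

    def loss_now():
        P, _ = mod.forward(X)
        return _loss_grad(Y, P)[0]

    eps = 1e-6
    for l in [0, 3]:
        flat, gflat = mod.W[l].ravel(), gW[l].ravel()
        for i in rng.choice(flat.size, size=8, replace=False):
            old = flat[i]
            flat[i] = old + eps
            lp = loss_now()
            flat[i] = old - eps
            lm = loss_now()
            flat[i] = old
            fd = (lp - lm) / (2 * eps)
            assert gflat[i] == pytest.approx(fd, rel=1e-3, abs=1e-6)


class TestSpecs:
    def test_hidden_size_bounds(self):
        with pytest.raises(ValueError):
            ModuleSpec(hidden_sizes=(16, 64, 64), input_dim=10)
        with pytest.raises(ValueError):
            ModuleSpec(hidden_sizes=(2048, 64, 64), input_dim=10)
        with pytest.raises(ValueError):
            ModuleSpec(hidden_sizes=(64, 64), input_dim=10)

    def test_first_layer_sizes_enforced(self):
        with pytest.raises(ValueError, match="first-layer"):
            EnsembleSpec(hidden_sizes=((512, 256, 128), (512, 256, 128), (256, 128, 64)))

    def test_output_dim_fixed_at_15(self):
        with pytest.raises(ValueError):
            ModuleSpec(hidden_sizes=(64, 64, 64), input_dim=10, output_dim=10)

    def test_module_parameter_counts_strictly_decrease(self):
        specs = EnsembleSpec().module_specs(input_dim=100)
        counts = [s.n_parameters for s in specs]
        assert counts[0] > counts[1] > counts[2]


def _toy_bulk(rng, n_genes=60, n_samples=400, seed=0):
    vocab = DEFAULT_VOCABULARY
    profiles = np.abs(rng.normal(2.0, 1.5, size=(n_genes, 15)))
    expr = np.repeat(profiles, 3, axis=1)
    labels = np.array(sum([[t] * 3 for t in vocab], []))
    return bulksim.build_set(
        expr, labels, [f"g{i}" for i in range(n_genes)],
        n_samples=n_samples, cells_per_sample=60, seed=seed,
    )


class TestEnsemble:
    def test_untrained_predictions_on_simplex(self, rng):
        ens = DeconvolutionEnsemble.build(EnsembleSpec(seed=1), [f"g{i}" for i in range(30)])
        X = rng.normal(size=(30, 9))
        P = ens.predict(X)
        assert (P >= 0).all()
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_initial_weights(self):
        genes = [f"g{i}" for i in range(20)]
        e1 = DeconvolutionEnsemble.build(EnsembleSpec(seed=5), genes)
        e2 = DeconvolutionEnsemble.build(EnsembleSpec(seed=5), genes)
        for m1, m2 in zip(e1.modules, e2.modules):
            for w1, w2 in zip(m1.W, m2.W):
                assert np.array_equal(w1, w2)

    def test_early_stopping_patience_contract(self, rng):
        """With a zero learning rate the validation loss never improves, so
        training halts after exactly patience + 1 evaluation epochs."""
        bulk = _toy_bulk(rng, n_samples=80)
        spec = EnsembleSpec(seed=0, learning_rate=0.0, patience=3)
        ens = DeconvolutionEnsemble.build(spec, bulk.gene_ids)
        ens.train(bulk.subset(np.arange(60)), bulk.subset(np.arange(60, 80)), max_epochs=50)
        assert len(ens.history["val_loss"]) == 4

    def test_training_improves_and_fits_toy(self, rng):
        bulk = _toy_bulk(rng)
        train = bulk.subset(np.arange(320))
        val = bulk.subset(np.arange(320, 400))
        ens = DeconvolutionEnsemble.build(EnsembleSpec(seed=0), bulk.gene_ids)
        ens.train(train, val, max_epochs=25)
        hist = ens.history
        assert hist["val_loss"][-1] < hist["val_loss"][0]
        pred = ens.predict(train.expression)
        _, pcc_loss = loss_components(train.truth, pred)
        assert np.median(1 - pcc_loss) > 0.9
        # trained predictions stay on the simplex
        assert (pred >= 0).all()
        assert np.allclose(pred.sum(axis=1), 1.0, atol=1e-6)

    def test_gene_permutation_invariance(self, rng):
        bulk = _toy_bulk(rng, n_samples=60)
        ens = DeconvolutionEnsemble.build(EnsembleSpec(seed=0), bulk.gene_ids)
        ens.train(bulk.subset(np.arange(40)), bulk.subset(np.arange(40, 60)), max_epochs=2)
        X = bulk.expression[:, :5]
        p1 = ens.predict(X, bulk.gene_ids)
        perm = rng.permutation(len(bulk.gene_ids))
        p2 = ens.predict(X[perm], [bulk.gene_ids[i] for i in perm])
        assert np.allclose(p1, p2, atol=1e-10)

    def test_missing_genes_rejected_unless_imputed(self, rng):
        ens = DeconvolutionEnsemble.build(EnsembleSpec(seed=0), [f"g{i}" for i in range(10)])
        ens.input_mean = np.zeros(10)
        ens.input_scale = np.ones(10)
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="missing"):
            ens.predict(X, [f"g{i}" for i in range(5)])
        P = ens.predict(X, [f"g{i}" for i in range(5)], impute_missing=True)
        assert P.shape == (3, 15)

    def test_gene_list_mismatch_on_train(self, rng):
        bulk = _toy_bulk(rng, n_samples=40)
        ens = DeconvolutionEnsemble.build(EnsembleSpec(seed=0), ["other"] + bulk.gene_ids[1:])
        with pytest.raises(ValueError, match="gene"):
            ens.train(bulk.subset(np.arange(30)), bulk.subset(np.arange(30, 40)))

    def test_save_load_roundtrip(self, tmp_path, rng):
        bulk = _toy_bulk(rng, n_samples=60)
        ens = DeconvolutionEnsemble.build(EnsembleSpec(seed=3), bulk.gene_ids)
        ens.train(bulk.subset(np.arange(40)), bulk.subset(np.arange(40, 60)), max_epochs=3)
        path = tmp_path / "model.h5"
        ens.save(path)
        loaded = DeconvolutionEnsemble.load(path)
        X = bulk.expression[:, :7]
        assert np.allclose(loaded.predict(X), ens.predict(X), atol=1e-7)
        assert loaded.trained
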