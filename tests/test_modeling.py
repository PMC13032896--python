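"""Splits, metrics, tuning, learning curves, inflection and error profiles."""

import numpy as np
import pytest

from udpep.errors import CapabilityError, DomainError
from udpep.modeling import (
    BackendSpec,
    SplitSpec,
    error_profile,
    evaluate,
    inflection_points,
    learning_curve,
    make_splits,
    tune_and_train,
)
from udpep.peptide_space import SpaceSpec, encode_matrix, index_to_peptide
from udpep.transformer import TransformerConfig, torch_available, train_transformer
from udpep.uniform_design import (
    DesignSeries,
    SoatConfig,
    design_to_peptides,
    soat_optimize,
)


class TestSplits:
    def test_size_contracts_small_space(self):
        space = SpaceSpec(3)  # 8000 sequences
        design = [index_to_peptide(i, 3) for i in range(0, 2000, 2)]  # 1000 runs
        spec = SplitSpec(fixed_test_size=500, seed=1)
        s = make_splits(space, design, spec)
        assert s.train.size == 800 and s.validation.size == 200
        assert s.fixed_test.size == 500
        assert s.nonfixed_test.size == 8000 - np.unique(s.train).size

    def test_fixed_test_excludes_whole_design(self):
        space = SpaceSpec(3)
        design = [index_to_peptide(i, 3) for i in range(1000)]
        for seed in range(10):
            s = make_splits(space, design, SplitSpec(fixed_test_size=300, seed=seed))
            assert not set(s.fixed_test) & set(range(1000))

    def test_nonfixed_complement_spans(self):
        # full-design sizes reproduce the published complement span at k=4
        space = SpaceSpec(4)
        for n, expect in ((1000, 159_000), (2000, 158_000)):
            design_idx = np.random.default_rng(0).choice(160000, n, replace=False)
            design = [index_to_peptide(int(i), 4) for i in design_idx]
            s = make_splits(space, design, SplitSpec(train_fraction=0.999999, seed=0))
            assert s.nonfixed_test.size == expect

    def test_reproducible_under_seed(self):
        space = SpaceSpec(3)
        design = [index_to_peptide(i, 3) for i in range(500)]
        a = make_splits(space, design, SplitSpec(fixed_test_size=100, seed=3))
        b = make_splits(space, design, SplitSpec(fixed_test_size=100, seed=3))
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.fixed_test, b.fixed_test)

    def test_design_too_large_rejected(self):
        space = SpaceSpec(2)  # 400 sequences
        design = [index_to_peptide(i, 2) for i in range(390)]
        with pytest.raises(DomainError):
            make_splits(space, design, SplitSpec(fixed_test_size=50))


class TestMetrics:
    def test_perfect_and_mean_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        perfect = evaluate(y, y)
        assert perfect.mae == 0 and perfect.r2 == 1
        mean_pred = evaluate(y, np.full(4, y.mean()))
        assert mean_pred.r2 == pytest.approx(0.0, abs=1e-12)

    def test_internal_consistency_hand_fixture(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p = np.array([1.1, 1.9, 3.2, 3.7, 5.4])
        m = evaluate(y, p)
        err = y - p
        assert m.mse == pytest.approx(np.mean(err**2), abs=1e-12)
        assert m.rmse**2 == pytest.approx(m.mse, abs=1e-12)
        assert m.r2 == pytest.approx(1 - np.sum(err**2) / np.sum((y - y.mean()) ** 2))

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            evaluate(np.array([]), np.array([]))


class TestTuneAndTrain:
    def test_noiseless_linear_signal_learned(self, rng):
        X = rng.integers(0, 2, size=(300, 10)).astype(float)
        y = 3.0 * X[:, 4]
        tuned = tune_and_train(X, y, BackendSpec("random_forest", n_search=3, seed=0))
        pred = tuned.predict(X)
        assert evaluate(y, pred).r2 > 0.99

    def test_constant_response_warns_and_fits(self, rng):
        X = rng.random((50, 4))
        with pytest.warns(UserWarning, match="zero variance"):
            tuned = tune_and_train(
                X, np.ones(50), BackendSpec("random_forest", n_search=2, seed=0)
            )
        assert evaluate(np.ones(50), tuned.predict(X)).mae == pytest.approx(0.0)

    def test_seed_contract_identical_winner(self, rng):
        X = rng.random((120, 6))
        y = X[:, 0] + rng.normal(0, 0.1, 120)
        a = tune_and_train(X, y, BackendSpec("support_vector", n_search=5, seed=4))
        b = tune_and_train(X, y, BackendSpec("support_vector", n_search=5, seed=4))
        assert a.best_params == b.best_params

    def test_cv_report_lists_every_configuration(self, rng):
        X = rng.random((80, 5))
        y = X[:, 1]
        tuned = tune_and_train(X, y, BackendSpec("random_forest", n_search=4, seed=0))
        assert len(tuned.cv_report) == 4
        assert any(c.startswith("split") for c in tuned.cv_report.columns)


@pytest.fixture(scope="module")
def toy_curve():
    sizes = (200, 400, 600)
    designs = tuple(
        soat_optimize(n, 3, 20, SoatConfig(outer_loops=2, inner_loops=60, seed=i))
        for i, n in enumerate(sizes)
    )
    series = DesignSeries(sizes, designs)
    # linear-in-one-hot composition signal, learnable
    weights = np.linspace(-1, 1, 20)

    def label_of(seqs):
        M = encode_matrix(seqs)
        return M.reshape(len(seqs), 3, 20).sum(axis=1) @ weights

    labels = {}
    for d in designs:
        for s in design_to_peptides(d):
            labels[s] = float(label_of([s])[0])
    return learning_curve(
        series,
        labels,
        [BackendSpec("random_forest", n_search=2, seed=0,
                     fixed_params={"n_estimators": 60})],
        SplitSpec(fixed_test_size=300, seed=0),
        space=SpaceSpec(3),
        label_fn=label_of,
    )


class TestLearningCurve:
    def test_schema_covers_both_test_modes(self, toy_curve):
        tab = toy_curve.table
        assert set(tab["split"]) == {"fixed_test", "nonfixed_test"}
        assert len(tab) == 3 * 2  # sizes x splits for one backend
        assert {"mae", "mse", "rmse", "r2"} <= set(tab.columns)

    def test_r2_improves_with_size(self, toy_curve):
        sub = toy_curve.table[toy_curve.table.split == "fixed_test"].sort_values("size")
        from scipy.stats import spearmanr

        rho = spearmanr(sub["size"], sub["r2"]).statistic
        assert rho > 0

    def test_best_point_recorded(self, toy_curve):
        assert toy_curve.best_points["random_forest"] in {200, 400, 600}


class TestInflection:
    def test_exact_quadratic_has_no_inflection(self):
        sizes = np.arange(1000, 16001, 500)
        vals = 2.0 + 0.001 * (sizes / 1000.0) ** 2
        assert inflection_points(sizes, vals) == []

    def test_logistic_curve_inflection_near_transition(self):
        sizes = np.arange(1000, 16001, 500, dtype=float)
        vals = 1.0 / (1.0 + np.exp(-(sizes - 5000) / 800.0))
        top = inflection_points(sizes, vals)[0]
        # brute-force |second difference| maximum over the same grid
        d2 = np.abs(vals[2:] - 2 * vals[1:-1] + vals[:-2])
        interior = sizes[1:-1]
        peaks = [i for i in range(1, d2.size - 1) if d2[i] > d2[i - 1] and d2[i] > d2[i + 1]]
        best = interior[max(peaks, key=lambda i: d2[i])]
        assert top == best
        assert abs(top - 5000) <= 1300  # within ~1 grid step of mu +- sigma

    def test_affine_rescaling_invariance(self):
        sizes = np.arange(1000, 16001, 500, dtype=float)
        vals = 1.0 / (1.0 + np.exp(-(sizes - 7000) / 1500.0))
        assert inflection_points(sizes, vals) == inflection_points(sizes, 5.0 * vals - 3.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            inflection_points(np.arange(4), np.arange(4.0))


class TestErrorProfile:
    def test_formula_single_sample(self):
        df = error_profile([2.0], [1.9], [1.0, 3.0])
        assert df.iloc[0]["mean_pct_error"] == pytest.approx(5.0)

    def test_near_zero_excluded_and_reported(self):
        df = error_profile([0.0, 2.0], [0.5, 2.0], [-1.0, 1.0, 3.0])
        assert df.attrs["excluded_near_zero"] == 1
        assert df.iloc[-1]["count"] == 1

    def test_two_bin_hand_computation(self):
        actual = np.array([1.0, 2.0, 4.0, 5.0])
        pred = np.array([1.1, 1.8, 4.4, 4.0])
        df = error_profile(actual, pred, [0.0, 3.0, 6.0])
        # bin 1: (10% + 10%) / 2 ; bin 2: (10% + 20%) / 2
        assert df.iloc[0]["mean_pct_error"] == pytest.approx(10.0)
        assert df.iloc[1]["mean_pct_error"] == pytest.approx(15.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            error_profile([1.0], [1.0, 2.0], [0, 2])


class TestTransformerBackend:
    def test_capability_gate(self):
        if torch_available():  # pragma: no cover - torch not in the test image
            model, predict, history = train_transformer(
                ["AAAA"] * 8 + ["WWWW"] * 8, [1.0] * 8 + [2.0] * 8,
                TransformerConfig(epochs=1, batch_size=4),
            )
            assert predict(["AAAA"]).shape == (1,)
        else:
            with pytest.raises(CapabilityError, match="torch"):
                train_transformer(["AAAA"], [1.0])

    def test_config_defaults_match_protocol(self):
        cfg = TransformerConfig()
        assert cfg.n_layers == 6 and cfg.n_heads == 8 and cfg.head_dim == 64
        assert cfg.ff_dim == 2048 and cfg.embed_dim == 512
        assert cfg.mlp_dims == (512, 256, 64, 32)
        assert cfg.dropout == 0.3 and cfg.momentum == 0.9
        assert cfg.warmup_start_lr == 0.001 and cfg.peak_lr == 0.2
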