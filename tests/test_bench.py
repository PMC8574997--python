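"""Combination aggregation, featurization, cross-validation and CI machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fpbench.bench import (
    SCORES,
    aggregate_tuples,
    benchmark,
    build_design,
    featurize_combination,
    make_regressor,
    nrmse,
    nrmse_ci,
    pcc_ci,
    run_cv,
    shapiro_gate,
)
from fpbench.rulefp import FingerprintMatrix
from fpbench.simulate import ScreenSpec, gen_screen


def _table(rows):
    return pd.DataFrame(rows, columns=["drug_a", "drug_b", "cell_line", "replicate",
                                       *SCORES])


class TestAggregate:
    def test_replicates_averaged(self):
        t = _table([
            ("A", "B", "CL1", 1, 10, 1, 1, 2.0, 1),
            ("A", "B", "CL1", 2, 12, 1, 1, 4.0, 1),
        ])
        out = aggregate_tuples(t)
        assert len(out) == 1
        assert out.loc[0, "loewe"] == pytest.approx(3.0)
        assert out.loc[0, "css"] == pytest.approx(11.0)

    def test_pair_orders_collapse(self):
        t = _table([
            ("B", "A", "CL1", 1, 10, 0, 0, 2.0, 0),
            ("A", "B", "CL1", 1, 20, 0, 0, 6.0, 0),
        ])
        out = aggregate_tuples(t)
        assert len(out) == 1
        assert (out.loc[0, "drug_a"], out.loc[0, "drug_b"]) == ("A", "B")
        assert out.loc[0, "loewe"] == pytest.approx(4.0)

    def test_no_replicates_identity_up_to_canonical_order(self):
        t = _table([
            ("A", "B", "CL1", 1, 1, 2, 3, 4, 5),
            ("A", "C", "CL2", 1, 5, 4, 3, 2, 1),
        ])
        out = aggregate_tuples(t)
        assert len(out) == 2
        assert np.allclose(out[list(SCORES)].to_numpy(), t[list(SCORES)].to_numpy())


class TestFeaturize:
    def test_concat_default_length(self, rng):
        a, b = rng.random(300), rng.random(300)
        cell = np.eye(5)[2]
        v = featurize_combination(a, b, cell, "circular-2D")
        assert v.shape == (605,)
        assert np.array_equal(v[:300], a) and np.array_equal(v[300:600], b)

    def test_path_bit_averaged(self, rng):
        a, b = (rng.random(1024) > 0.5).astype(float), (rng.random(1024) > 0.5).astype(float)
        v = featurize_combination(a, b, np.eye(5)[0], "path")
        assert v.shape == (1029,)
        assert np.array_equal(v[:1024], 0.5 * (a + b))

    def test_identical_drugs_path_block(self, rng):
        a = (rng.random(16) > 0.5).astype(float)
        v = featurize_combination(a, a, np.zeros(2), "path")
        assert np.array_equal(v[:16], a)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            featurize_combination(np.zeros(4), np.zeros(5), np.zeros(2))

    def test_missing_drug_raises(self):
        fp = FingerprintMatrix(
            values=np.zeros((1, 4)), data_format="binary", fp_type="rule",
            fp_subtype="path", n_bits=4, compound_ids=["A"],
        )
        t = aggregate_tuples(_table([("A", "Z", "CL1", 1, 1, 1, 1, 1, 1)]))
        with pytest.raises(ValueError, match="absent"):
            build_design(t, fp)


class TestRunCV:
    def test_kfold_sizes_and_determinism(self, rng):
        x = rng.normal(size=(100, 3))
        y = rng.normal(size=(100, 2))
        folds = run_cv(x, y, make_regressor("ridge"), split="90:10", k=10, seed=4)
        assert len(folds) == 10
        assert all(f["css"][0].shape == (10,) for f in folds)
        again = run_cv(x, y, make_regressor("ridge"), split="90:10", k=10, seed=4)
        assert np.array_equal(folds[0]["css"][1], again[0]["css"][1])

    def test_6040_holdout_fraction(self, rng):
        x = rng.normal(size=(100, 3))
        y = rng.normal(size=(100, 1))
        folds = run_cv(x, y, make_regressor("ridge"), split="60:40", k=10, seed=0)
        assert len(folds) == 10
        assert all(f["css"][0].shape == (40,) for f in folds)

    def test_unknown_split(self, rng):
        with pytest.raises(ValueError):
            run_cv(rng.normal(size=(20, 2)), rng.normal(size=20),
                   make_regressor("ridge"), split="50:50")


class TestPccCI:
    def test_all_zero_folds(self):
        mean, half, degen = pcc_ci([0.0, 0.0, 0.0])
        assert mean == 0.0 and half == 0.0 and not degen

    def test_identical_folds_zero_width(self):
        mean, half, _ = pcc_ci([0.42, 0.42, 0.42, 0.42])
        assert mean == pytest.approx(0.42) and half == 0.0

    def test_hand_computed_t_interval(self):
        # independent arithmetic oracle on the z scale
        r = np.array([0.5, 0.6, 0.7])
        z = np.arctanh(r)
        zm, se = z.mean(), z.std(ddof=1) / np.sqrt(3)
        tcrit = stats.t.ppf(0.975, df=2)
        exp_mean = np.tanh(zm)
        exp_half = (np.tanh(zm + tcrit * se) - np.tanh(zm - tcrit * se)) / 2
        mean, half, degen = pcc_ci([0.5, 0.6, 0.7])
        assert mean == pytest.approx(exp_mean, abs=1e-12)
        assert half == pytest.approx(exp_half, abs=1e-12)
        assert not degen

    def test_perfect_correlation_degenerate(self):
        with pytest.warns(UserWarning, match="infinite"):
            _, half, degen = pcc_ci([1.0, 0.5])
        assert degen and np.isinf(half)


class TestNrmse:
    def test_mean_predictor_exactly_one(self, rng):
        y = rng.normal(size=57) * 13 + 5
        pred = np.full_like(y, y.mean())
        assert nrmse(y, pred) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_prediction_zero(self, rng):
        y = rng.normal(size=20)
        assert nrmse(y, y) == 0.0

    def test_scale_invariance(self, rng):
        y, p = rng.normal(size=30), rng.normal(size=30)
        assert nrmse(3.5 * y, 3.5 * p) == pytest.approx(nrmse(y, p))

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            nrmse(np.ones(5), np.zeros(5))

    def test_bootstrap_interval(self, rng):
        y = rng.normal(size=200)
        p = y + rng.normal(scale=0.3, size=200)
        point, half = nrmse_ci(y, p, b=300, seed=1)
        assert 0 < point < 1
        assert half > 0
        # deterministic under fixed seed
        assert nrmse_ci(y, p, b=300, seed=1) == (point, half)


class TestShapiroGate:
    def test_normal_sample_passes(self):
        v = np.random.default_rng(7).normal(size=50)
        p, ok = shapiro_gate(v)
        assert ok and p > 0.05

    def test_skewed_sample_warns(self):
        v = np.random.default_rng(7).exponential(size=200)
        with pytest.warns(UserWarning, match="normality"):
            p, ok = shapiro_gate(v)
        assert not ok and p < 0.05

    def test_constant_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            p, ok = shapiro_gate(np.ones(10))
        assert not ok

    def test_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_gate([1.0, 2.0])


@pytest.fixture(scope="module")
def small_screen(molecule_items):
    spec = ScreenSpec(n_molecules=40, n_cell_lines=3, n_tuples=400,
                      replicate_rate=0.2, signal_fraction=0.6, seed=21)
    return gen_screen(molecule_items[:40], spec)


class TestBenchmark:
    def _fps(self, molecule_items):
        from fpbench.rulefp import fingerprint_molecules
        items = molecule_items[:40]
        return {
            "morgan300": fingerprint_molecules(items, "morgan300"),
            "topo1024": fingerprint_molecules(items, "topo1024"),
        }

    def test_result_grid_shape(self, molecule_items, small_screen):
        table, _ = small_screen
        df = benchmark(self._fps(molecule_items), table,
                       regressor=make_regressor("ridge"), k=5, seed=0, bootstrap=100)
        assert len(df) == 2 * 5  # fingerprints x scores
        assert df["best"].sum() == 5  # one best per score
        assert ((df["pcc_mean"] >= -1) & (df["pcc_mean"] <= 1)).all()
        assert (df["nrmse"] >= 0).all()

    def test_pair_swap_invariance(self, molecule_items, small_screen):
        table, _ = small_screen
        swapped = table.rename(columns={"drug_a": "drug_b", "drug_b": "drug_a"})
        fps = {"morgan300": self._fps(molecule_items)["morgan300"]}
        kw = dict(regressor=make_regressor("ridge"), k=5, seed=3, bootstrap=50)
        a = benchmark(fps, table, **kw)
        b = benchmark(fps, swapped, **kw)
        assert np.allclose(a["pcc_mean"], b["pcc_mean"], atol=1e-10)
        assert np.allclose(a["nrmse"], b["nrmse"], atol=1e-10)

    def test_signal_monotonicity(self, molecule_items):
        """Measured PCC grows with the planted signal fraction."""
        means = []
        for rho in (0.1, 0.4, 0.8):
            pccs = []
            for seed in (1, 2, 3):
                spec = ScreenSpec(n_molecules=40, n_cell_lines=3, n_tuples=500,
                                  replicate_rate=0.0, signal_fraction=rho, seed=seed)
                table, truth = gen_screen(molecule_items[:40], spec)
                agg = aggregate_tuples(table)
                key_to_row = {k: i for i, k in enumerate(truth["keys"])}
                order = [key_to_row[(a, b, c)] for a, b, c in
                         zip(agg["drug_a"], agg["drug_b"], agg["cell_line"])]
                x = truth["design"][order]
                y = agg["loewe"].to_numpy()
                folds = run_cv(x, y, make_regressor("ridge"), split="90:10",
                               k=5, seed=seed)
                fold_pccs = [stats.pearsonr(*f["css"]).statistic for f in folds]
                pccs.append(np.mean(fold_pccs))
            means.append(np.mean(pccs))
        assert means[0] < means[1] < means[2]
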