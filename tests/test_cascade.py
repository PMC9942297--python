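"""Cascade mechanics: per-cycle negative resampling, the unanimous-vote
pass rule, survivor monotonicity, determinism, and persistence."""

import numpy as np
import pandas as pd
import pytest

from genesieve.cascade import (
    CascadeModel,
    FittedLevel,
    LevelConfig,
    default_level_configs,
    grid_search,
    predict_level,
    run_cascade,
    train_level,
)
from genesieve.sequence_io import POSITIVE

from conftest import random_feature_frame


def blobs(rng, n_per_class, n_features=6, sep=3.0):
    """Two well-separated Gaussian clouds as (positives, negatives) frames."""
    pos = random_feature_frame(rng, n_per_class, n_features) + sep
    neg = random_feature_frame(rng, n_per_class, n_features)
    neg.index = pd.MultiIndex.from_tuples(
        [(f"N{i // 2}", f"N{i // 2}.c{i % 2}") for i in range(n_per_class)],
        names=["gene_id", "cds_id"],
    )
    return pos, neg


def quick_config(n_cycles=3, seed=0, **kw):
    kw.setdefault("hidden_units", 4)
    kw.setdefault("max_iter", 300)
    return LevelConfig(n_cycles=n_cycles, seed=seed, **kw)


class StubNet:
    """Fixed-probability classifier standing in for a fitted network."""

    def __init__(self, proba_by_sample):
        self.p = np.asarray(proba_by_sample, dtype=float)

    def predict_proba(self, x):
        p = self.p[: len(x)]
        return np.column_stack([1 - p, p])


def stub_level(vote_matrix, pass_threshold=None):
    """A FittedLevel whose cycle c assigns probability vote_matrix[c]."""
    vote_matrix = np.asarray(vote_matrix, dtype=float)
    cfg = LevelConfig(n_cycles=len(vote_matrix), pass_threshold=pass_threshold)
    nets = [StubNet(row) for row in vote_matrix]
    return FittedLevel(cfg, nets, feature_names=["f0"])


def stub_frame(n):
    return random_feature_frame(np.random.default_rng(0), n, 1).rename(columns={"f0": "f0"})


class TestTrainLevel:
    def test_each_cycle_draws_a_distinct_negative_subset(self):
        rng = np.random.default_rng(0)
        pos, _ = blobs(rng, 10)
        pool = random_feature_frame(rng, 60)
        cfg = quick_config(n_cycles=5, max_iter=50)
        subsets = []
        for cycle in range(1, cfg.n_cycles + 1):
            draw_rng = np.random.default_rng(cfg.seed + cycle)
            subsets.append(tuple(sorted(draw_rng.choice(60, size=10, replace=False))))
        assert len(set(subsets)) == 5
        level = train_level(pos, pool, cfg)
        assert len(level.networks) == 5

    def test_pool_smaller_than_positives_is_error(self):
        rng = np.random.default_rng(0)
        pos, _ = blobs(rng, 10)
        with pytest.raises(ValueError):
            train_level(pos, pos.head(4), quick_config())

    def test_same_seed_gives_identical_votes(self):
        rng = np.random.default_rng(1)
        pos, neg = blobs(rng, 12)
        test = pd.concat([pos.head(4), neg.head(4)])
        votes = []
        for _ in range(2):
            level = train_level(pos, neg, quick_config(seed=33))
            votes.append(predict_level(level, test)[0])
        assert np.array_equal(votes[0], votes[1])

    def test_single_cycle_equals_directly_fitted_network(self):
        rng = np.random.default_rng(2)
        pos, neg = blobs(rng, 10)
        cfg = quick_config(n_cycles=1, seed=7)
        level = train_level(pos, neg.head(10), cfg)
        # reproduce: cycle 1 draws all 10 pool rows with seed cfg.seed+1
        draw = np.random.default_rng(cfg.seed + 1).choice(10, size=10, replace=False)
        x = np.vstack([pos.to_numpy(), neg.head(10).to_numpy()[draw]])
        y = np.array([1] * 10 + [0] * 10)
        direct = cfg.make_network(seed=cfg.seed + 1).fit(x, y)
        test = random_feature_frame(rng, 8)
        assert np.array_equal(
            direct.predict_proba(test.to_numpy())[:, 1],
            level.networks[0].predict_proba(test.to_numpy())[:, 1],
        )


class TestUnanimityRule:
    def test_unanimous_sample_survives_49_does_not(self):
        votes = np.ones((50, 2))
        votes[0, 1] = 0.0  # sample 2 loses one cycle
        level = stub_level(votes)
        v, _, survived = predict_level(level, stub_frame(2))
        assert v.tolist() == [50, 49]
        assert survived.tolist() == [True, False]

    def test_configurable_pass_threshold(self):
        votes = np.ones((10, 1))
        votes[:3, 0] = 0.0
        level = stub_level(votes, pass_threshold=7)
        v, _, survived = predict_level(level, stub_frame(1))
        assert v[0] == 7 and survived[0]

    def test_cutoff_is_inclusive(self):
        level = stub_level(np.full((5, 1), 0.5))
        v, _, _ = predict_level(level, stub_frame(1))
        assert v[0] == 5

    def test_schema_mismatch_is_error(self):
        level = stub_level(np.ones((2, 3)))
        bad = stub_frame(3).rename(columns={"f0": "other"})
        with pytest.raises(ValueError, match="schema"):
            predict_level(level, bad)


class TestRunCascade:
    def _model(self, vote_rows):
        return CascadeModel([stub_level(np.asarray(rows)) for rows in vote_rows])

    def test_survivor_monotonicity_over_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 12))
            model = CascadeModel([
                stub_level(rng.random((3, n)).round()) for _ in range(3)
            ])
            trace = run_cascade(model, stub_frame(n))
            c = trace.survivor_counts
            assert n >= c[0] >= c[1] >= c[2] >= 0

    def test_only_survivors_advance(self):
        # sample 0 unanimous at level 1; sample 1 not
        l1 = stub_level(np.array([[1.0, 0.0]] * 2))
        l2 = stub_level(np.array([[1.0, 1.0]] * 2))
        trace = run_cascade(CascadeModel([l1, l2]), stub_frame(2))
        assert trace.samples["votes_L2"].tolist() == [2, 0]

    def test_non_surviving_gene_is_still_scored(self):
        # gene G0 (samples 0-1) survives unanimously; gene G1 (samples 2-3) does not
        l1 = stub_level(np.array([[1.0, 1.0, 0.0, 0.0], [1.0, 1.0, 0.0, 1.0]]))
        trace = run_cascade(CascadeModel([l1]), stub_frame(4))
        genes = trace.genes
        assert not genes["candidate"].all() and genes["candidate"].any()
        assert (genes["score"] >= 0).all() and len(genes) == 2

    def test_empty_input_gives_empty_trace(self):
        model = self._model([np.ones((2, 1))])
        trace = run_cascade(model, stub_frame(1).iloc[:0])
        assert len(trace.samples) == 0 and len(trace.genes) == 0

    def test_vote_bounds_and_score_cap(self, small_screen):
        result, _ = small_screen
        trace = result.heldout_trace
        n_cycles = result.model.levels[0].config.n_cycles
        for li in (1, 2, 3):
            assert trace.samples[f"votes_L{li}"].between(0, n_cycles).all()
        per_gene_samples = trace.samples.groupby(level="gene_id").size()
        cap = 3 * n_cycles * per_gene_samples
        assert (trace.genes["score"] <= cap.loc[trace.genes.index]).all()

    def test_planted_positives_lead_the_ranking(self, small_screen):
        result, _ = small_screen
        genes = result.heldout_trace.genes
        candidates = genes[genes["candidate"]]
        assert len(candidates) > 0
        assert all(g.startswith("POS") for g in candidates.index)
        assert genes.index[0].startswith("POS")


class TestPersistence:
    def test_save_load_round_trip_is_bit_identical(self, tmp_path, small_screen):
        result, _ = small_screen
        model = result.model
        feats = result.heldout_trace.samples.index
        heldout = result.features.loc[result.features.index.isin(feats)]
        from genesieve.preprocessing import transform
        x = transform(heldout, model.norm_params)
        before = run_cascade(model, x)
        model.save(tmp_path / "bundle")
        loaded = CascadeModel.load(tmp_path / "bundle")
        after = run_cascade(loaded, x)
        pd.testing.assert_frame_equal(before.samples, after.samples)
        pd.testing.assert_frame_equal(before.genes, after.genes)

    def test_bundle_contains_config_params_and_weights(self, tmp_path, small_screen):
        result, _ = small_screen
        result.model.save(tmp_path / "b")
        names = {p.name for p in (tmp_path / "b").iterdir()}
        assert {"config.yaml", "normalization.json", "level1.joblib"} <= names


class TestGridSearch:
    def _data(self):
        rng = np.random.default_rng(3)
        pos, neg = blobs(rng, 20, sep=2.0)
        x = pd.concat([pos, neg])
        y = np.array([1] * 20 + [0] * 20)
        return x, y

    def test_single_point_grid_returns_it(self):
        x, y = self._data()
        cfg = grid_search(x, y, x, y, hidden_range=range(3, 4), lr_values=[0.05],
                          activations=("relu",), base=LevelConfig(max_iter=100))
        assert (cfg.hidden_units, cfg.learning_rate, cfg.activation) == (3, 0.05, "relu")

    def test_returns_argmax_of_validation_auc(self):
        x, y = self._data()
        cfg = grid_search(x, y, x, y, hidden_range=range(2, 6, 2), lr_values=[0.01, 0.1],
                          activations=("relu", "tanh"), base=LevelConfig(max_iter=200))
        assert cfg.hidden_units in (2, 4) and cfg.activation in ("relu", "tanh")

    def test_zero_hidden_units_rejected_with_warning(self):
        x, y = self._data()
        with pytest.warns(UserWarning, match="degenerate"):
            cfg = grid_search(x, y, x, y, hidden_range=range(0, 2), lr_values=[0.05],
                              activations=("relu",), base=LevelConfig(max_iter=100))
        assert cfg.hidden_units == 1

    def test_level_config_validation(self):
        with pytest.raises(ValueError):
            LevelConfig(hidden_units=0)
        with pytest.raises(ValueError):
            LevelConfig(activation="gelu")
        with pytest.raises(ValueError):
            LevelConfig(n_cycles=5, pass_threshold=9)

    def test_default_level_configs_match_tuned_settings(self):
        cfgs = default_level_configs()
        got = [(c.hidden_units, c.activation, c.learning_rate, c.max_iter, c.momentum) for c in cfgs]
        assert got == [
            (21, "relu", 0.048, 5000, 0.8),
            (20, "tanh", 0.048, 5000, 0.8),
            (37, "logistic", 0.098, 5000, 0.9),
        ]
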