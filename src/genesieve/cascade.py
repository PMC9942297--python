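"""The cascaded classifier: three sequential levels of small single-hidden-
layer feed-forward networks. Each level is trained over many replicate
cycles, every cycle re-drawing a fresh 1:1 negative subset from the
unlabeled-derived pool; at prediction time a sample's vote is the number of
cycles that call it positive, and only unanimously-positive samples advance
to the next level. Genes are scored by the summed votes of their samples
across all levels reached and ranked.

The per-cycle resampling is the positive-unlabeled safeguard: any single
potential positive hiding in the unlabeled pool rarely recurs across draws,
so it cannot consistently poison the negative class.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml
from sklearn.neural_network import MLPClassifier

from .evaluation import MetricsReport, full_report, roc_auc
from .features import SCHEMA_VERSION, feature_columns
from .preprocessing import NormalizationParams

ACTIVATIONS = ("relu", "tanh", "logistic")


@dataclass
class LevelConfig:
    """Hyper-parameters of one cascade level.

    Defaults for the three levels (see :data:`DEFAULT_LEVEL_CONFIGS`) are the
    tuned settings: (21, relu, 0.048), (20, tanh, 0.048), (37, logistic,
    0.098), each with 5000 iterations, SGD momentum 0.8/0.8/0.9, 50 cycles
    and a unanimity pass rule at decision cutoff 0.5.
    """

    hidden_units: int = 21
    activation: str = "relu"
    learning_rate: float = 0.048
    max_iter: int = 5000
    momentum: float = 0.8
    n_cycles: int = 50
    pass_threshold: int | None = None  # None -> unanimity (= n_cycles)
    decision_cutoff: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1 (a 0-unit hidden layer is degenerate)")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.pass_threshold is None:
            self.pass_threshold = self.n_cycles
        if not 1 <= self.pass_threshold <= self.n_cycles:
            raise ValueError("pass_threshold must be in [1, n_cycles]")

    def make_network(self, seed: int) -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=(self.hidden_units,),
            activation=self.activation,
            solver="sgd",
            learning_rate="constant",
            learning_rate_init=self.learning_rate,
            momentum=self.momentum,
            max_iter=self.max_iter,
            random_state=seed,
        )


def default_level_configs(n_cycles: int = 50, max_iter: int = 5000, seed: int = 0) -> list[LevelConfig]:
    """The three tuned per-level settings."""
    base = [
        dict(hidden_units=21, activation="relu", learning_rate=0.048, momentum=0.8),
        dict(hidden_units=20, activation="tanh", learning_rate=0.048, momentum=0.8),
        dict(hidden_units=37, activation="logistic", learning_rate=0.098, momentum=0.9),
    ]
    return [
        LevelConfig(n_cycles=n_cycles, max_iter=max_iter, seed=seed + 1000 * (i + 1), **kw)
        for i, kw in enumerate(base)
    ]


@dataclass
class FittedLevel:
    """One trained cascade level: its config, the per-cycle networks, and
    per-cycle validation reports (when a validation set was supplied)."""

    config: LevelConfig
    networks: list[MLPClassifier]
    cycle_reports: list[MetricsReport] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)


def _as_array(matrix: pd.DataFrame, feature_names: list[str] | None = None) -> np.ndarray:
    cols = feature_names or feature_columns(matrix)
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"feature schema mismatch, missing columns: {missing[:5]}")
    return matrix[cols].to_numpy(dtype=float)


def train_level(
    positives: pd.DataFrame,
    negative_pool: pd.DataFrame,
    config: LevelConfig,
    validation: tuple[pd.DataFrame, np.ndarray] | None = None,
) -> FittedLevel:
    """Fit one level: ``n_cycles`` networks, each on the positives plus a
    fresh seeded draw of ``len(positives)`` negatives (without replacement
    within a cycle) from the pool."""
    if len(negative_pool) < len(positives):
        raise ValueError("negative pool smaller than the positive set")
    cols = feature_columns(positives)
    x_pos = _as_array(positives, cols)
    x_pool = _as_array(negative_pool, cols)
    networks, reports = [], []
    for cycle in range(1, config.n_cycles + 1):
        rng = np.random.default_rng(config.seed + cycle)
        idx = rng.choice(len(x_pool), size=len(x_pos), replace=False)
        x = np.vstack([x_pos, x_pool[idx]])
        y = np.concatenate([np.ones(len(x_pos), dtype=int), np.zeros(len(idx), dtype=int)])
        net = config.make_network(seed=config.seed + cycle)
        net.fit(x, y)
        networks.append(net)
        if validation is not None:
            x_val, y_val = validation
            proba = net.predict_proba(_as_array(x_val, cols))[:, 1]
            reports.append(full_report(y_val, (proba >= config.decision_cutoff).astype(int), proba))
    return FittedLevel(config, networks, reports, feature_names=list(cols))


def predict_level(level: FittedLevel, samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample (votes, mean positive probability, survivor flags).

    A vote is a cycle whose network assigns positive-class probability at or
    above the decision cutoff; a sample survives when its votes reach the
    pass threshold (unanimity by default)."""
    x = _as_array(samples, level.feature_names)
    votes = np.zeros(len(x), dtype=int)
    proba_sum = np.zeros(len(x))
    for net in level.networks:
        proba = net.predict_proba(x)[:, 1]
        votes += (proba >= level.config.decision_cutoff).astype(int)
        proba_sum += proba
    mean_proba = proba_sum / len(level.networks)
    survived = votes >= level.config.pass_threshold
    return votes, mean_proba, survived


@dataclass
class CascadeModel:
    """Three fitted levels plus the preprocessing parameters they expect."""

    levels: list[FittedLevel]
    norm_params: NormalizationParams | None = None
    schema_version: str = SCHEMA_VERSION

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        config = {
            "schema_version": self.schema_version,
            "levels": [asdict(lv.config) for lv in self.levels],
        }
        (directory / "config.yaml").write_text(yaml.safe_dump(config))
        if self.norm_params is not None:
            self.norm_params.save(directory / "normalization.json")
        for i, lv in enumerate(self.levels, 1):
            joblib.dump(
                {"networks": lv.networks, "feature_names": lv.feature_names},
                directory / f"level{i}.joblib",
            )

    @classmethod
    def load(cls, directory: str | Path) -> "CascadeModel":
        directory = Path(directory)
        config = yaml.safe_load((directory / "config.yaml").read_text())
        levels = []
        for i, level_cfg in enumerate(config["levels"], 1):
            blob = joblib.load(directory / f"level{i}.joblib")
            levels.append(FittedLevel(LevelConfig(**level_cfg), blob["networks"],
                                      feature_names=blob["feature_names"]))
        norm_path = directory / "normalization.json"
        params = NormalizationParams.load(norm_path) if norm_path.exists() else None
        return cls(levels, params, config["schema_version"])


@dataclass
class PredictionTrace:
    """Per-sample votes/survival per level plus the gene-level ranking."""

    samples: pd.DataFrame  # index (gene_id, cds_id); votes_L*, mean_proba_L*, survived_L*
    genes: pd.DataFrame    # index gene_id; score, mean_proba, candidate, rank
    survivor_counts: list[int]

    def to_tsv(self, path: str | Path) -> None:
        merged = self.samples.join(
            self.genes[["score", "candidate", "rank"]], on="gene_id"
        )
        merged.to_csv(path, sep="\t", float_format="%.6g")


def run_cascade(model: CascadeModel, features: pd.DataFrame) -> PredictionTrace:
    """Push a (preprocessed) feature matrix through all levels.

    Every sample is voted on at level 1; only a level's survivors are voted
    on at the next. A gene is a final candidate iff at least one of its
    CDS/protein samples survives all levels; its score is the sum of its
    samples' votes over the levels they reached (<= 150 per sample at the
    50-cycle default).
    """
    n_levels = len(model.levels)
    n = len(features)
    trace = pd.DataFrame(index=features.index)
    votes_all = np.zeros((n, n_levels), dtype=int)
    proba_all = np.full((n, n_levels), np.nan)
    alive = np.ones(n, dtype=bool)
    survivor_counts = []
    for li, level in enumerate(model.levels, 1):
        if alive.any():
            votes, proba, survived = predict_level(level, features.loc[alive])
            votes_all[alive, li - 1] = votes
            proba_all[alive, li - 1] = proba
            new_alive = alive.copy()
            new_alive[alive] = survived
            alive = new_alive
        else:
            alive = np.zeros(n, dtype=bool)
        survivor_counts.append(int(alive.sum()))
        trace[f"votes_L{li}"] = votes_all[:, li - 1]
        trace[f"mean_proba_L{li}"] = proba_all[:, li - 1]
        trace[f"survived_L{li}"] = alive

    trace["total_votes"] = votes_all.sum(axis=1)
    trace["survived_all"] = alive

    if n == 0:
        genes = pd.DataFrame(columns=["score", "mean_proba", "candidate", "rank"])
        return PredictionTrace(trace, genes, survivor_counts)

    by_gene = trace.groupby(level="gene_id", sort=False)
    genes = pd.DataFrame({
        "score": by_gene["total_votes"].sum(),
        "mean_proba": by_gene[[f"mean_proba_L{li}" for li in range(1, n_levels + 1)]]
        .apply(lambda d: np.nanmean(d.to_numpy())),
        "candidate": by_gene["survived_all"].any(),
    })
    genes = genes.sort_values(
        by=["score", "mean_proba", "gene_id"], ascending=[False, False, True],
        kind="mergesort",
    )
    genes["rank"] = np.arange(1, len(genes) + 1)
    return PredictionTrace(trace, genes, survivor_counts)


def train_cascade(
    positives: pd.DataFrame,
    negative_pool: pd.DataFrame,
    configs: list[LevelConfig] | None = None,
    validation: tuple[pd.DataFrame, np.ndarray] | None = None,
    norm_params: NormalizationParams | None = None,
) -> CascadeModel:
    """Train all levels on the same labeled training data, each level (and
    each cycle within it) drawing fresh negative subsets from the pool."""
    configs = configs or default_level_configs()
    levels = [train_level(positives, negative_pool, cfg, validation) for cfg in configs]
    return CascadeModel(levels, norm_params)


def grid_search(
    train_x: pd.DataFrame,
    train_y: np.ndarray,
    val_x: pd.DataFrame,
    val_y: np.ndarray,
    hidden_range: range = range(1, 101),
    lr_values: list[float] | None = None,
    activations: tuple[str, ...] = ACTIVATIONS,
    base: LevelConfig | None = None,
) -> LevelConfig:
    """Pick the (hidden units, learning rate, activation) combination with
    the best validation AUC; ties prefer fewer hidden units, then lower
    learning rate. A hidden-unit value of 0 is rejected with a warning.

    The full tuning grid is hidden 1..100 step 1 by learning rate
    0.001..0.1 step 0.001 by the three activations; pass reduced ranges for
    desk-scale runs.
    """
    base = base or LevelConfig()
    if lr_values is None:
        lr_values = [round(0.001 * i, 3) for i in range(1, 101)]
    x_tr = _as_array(train_x)
    x_val = _as_array(val_x, feature_columns(train_x))
    best: tuple | None = None
    for act in activations:
        for h in hidden_range:
            if h < 1:
                warnings.warn("hidden-unit value 0 is degenerate; skipped")
                continue
            for lr in lr_values:
                cfg = LevelConfig(
                    hidden_units=h, activation=act, learning_rate=lr,
                    max_iter=base.max_iter, momentum=base.momentum,
                    n_cycles=base.n_cycles, decision_cutoff=base.decision_cutoff,
                    seed=base.seed,
                )
                net = cfg.make_network(seed=base.seed)
                net.fit(x_tr, train_y)
                _, auc_val = roc_auc(val_y, net.predict_proba(x_val)[:, 1])
                key = (-auc_val, h, lr)
                if best is None or key < best[0]:
                    best = (key, cfg)
    assert best is not None, "empty grid"
    return best[1]
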