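"""End-to-end workflows gluing the modules together: build a labeled
dataset (real or synthetic), extract and preprocess features, train the
three-level cascade, and screen/rank genes. Used by the command-line
interface, and directly importable for scripted runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import (
    CascadeModel,
    LevelConfig,
    PredictionTrace,
    default_level_configs,
    run_cascade,
    train_cascade,
)
from .evaluation import MetricsReport, full_report, replicate_summary
from .features import FeatureConfig, compute_backgrounds, extract_features
from .preprocessing import fit_params, transform
from .sequence_io import (
    NEGATIVE,
    POSITIVE,
    DatasetSplit,
    GeneRecord,
    make_split,
    sample_negatives,
)
from .synthetic import SyntheticSpec, apply_missingness, generate


@dataclass
class ScreenResult:
    """Everything a trained-and-evaluated screen produces."""

    model: CascadeModel
    split: DatasetSplit
    features: pd.DataFrame                 # raw (pre-normalization) labeled matrix
    heldout_trace: PredictionTrace         # cascade run on validation+test
    heldout_report: MetricsReport          # score = summed votes, prediction = full survival
    cycle_summary: dict                    # level-1 per-cycle validation means
    survivor_counts: list[int]
    positive_gene_survival: float          # fraction of held-out positive genes surviving all levels
    heldout_labels: pd.Series = field(default_factory=pd.Series)


def build_labeled_set(
    positives: list[GeneRecord],
    unlabeled: list[GeneRecord],
    multiplier: int = 1,
    seed: int = 0,
) -> list[GeneRecord]:
    """Positives plus a chromosome-proportional negative draw from the
    unlabeled pool."""
    negatives = sample_negatives(unlabeled, positives, multiplier=multiplier, seed=seed)
    return list(positives) + negatives


def featurize(
    labeled: list[GeneRecord],
    background_genes: list[GeneRecord] | None = None,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Extract the feature matrix for a labeled set, pooling the KL/CE
    background over ``background_genes`` (default: the labeled set itself)."""
    config = config or FeatureConfig()
    if config.backgrounds is None:
        config.backgrounds = compute_backgrounds(background_genes or labeled)
    return extract_features(labeled, config)


def _partition(features: pd.DataFrame, keys) -> pd.DataFrame:
    return features.loc[pd.MultiIndex.from_tuples(keys, names=features.index.names)]


def _labels_array(df: pd.DataFrame) -> np.ndarray:
    return (df["label"] == POSITIVE).to_numpy(dtype=int)


def train_screen(
    features: pd.DataFrame,
    configs: list[LevelConfig] | None = None,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> ScreenResult:
    """Split, preprocess, train the cascade, and evaluate on held-out data.

    The labeled matrix is split 6:2:2 stratified by class (1:1 in train);
    imputation means and min-max bounds are fitted on the training partition
    only. Each level trains ``n_cycles`` networks against fresh negative
    draws from the training negatives; per-cycle validation metrics are
    averaged into ``cycle_summary``. The cascade is then run on the combined
    validation+test partition: the held-out AUC uses the summed votes as the
    ranking score, and the confusion metrics use full three-level survival
    as the positive call.
    """
    samples = [(key, lab) for key, lab in zip(features.index, features["label"])]
    split = make_split(samples, ratios, seed=seed)

    train_df = _partition(features, split.train)
    val_df = _partition(features, split.validation)
    test_df = _partition(features, split.test)

    params = fit_params(train_df)
    train_n, val_n, test_n = (transform(d, params) for d in (train_df, val_df, test_df))

    configs = configs or default_level_configs(seed=seed)
    pos = train_n[train_n["label"] == POSITIVE]
    neg_pool = train_n[train_n["label"] == NEGATIVE]
    model = train_cascade(pos, neg_pool, configs, validation=(val_n, _labels_array(val_n)), norm_params=params)

    heldout = pd.concat([val_n, test_n])
    y_heldout = _labels_array(heldout)
    trace = run_cascade(model, heldout)
    report = full_report(
        y_heldout,
        trace.samples["survived_all"].to_numpy(dtype=int),
        trace.samples["total_votes"].to_numpy(dtype=float),
    )

    pos_genes = heldout[heldout["label"] == POSITIVE].index.get_level_values("gene_id").unique()
    surviving = trace.genes.loc[trace.genes["candidate"]].index
    survival = float(np.mean([g in set(surviving) for g in pos_genes])) if len(pos_genes) else float("nan")

    return ScreenResult(
        model=model,
        split=split,
        features=features,
        heldout_trace=trace,
        heldout_report=report,
        cycle_summary=replicate_summary(model.levels[0].cycle_reports),
        survivor_counts=trace.survivor_counts,
        positive_gene_survival=survival,
        heldout_labels=pd.Series(y_heldout, index=heldout.index),
    )


def run_synthetic_screen(
    spec: SyntheticSpec,
    n_cycles: int = 50,
    max_iter: int = 500,
    negative_multiplier: int = 1,
    configs: list[LevelConfig] | None = None,
) -> tuple[ScreenResult, pd.DataFrame]:
    """Generate a synthetic dataset under ``spec`` and run the full screen.

    Returns the screen result and the generator's truth table. All
    randomness flows from ``spec.seed``.
    """
    records, truth = generate(spec)
    positives = [g for g in records if g.label == POSITIVE]
    unlabeled = [g for g in records if g.label != POSITIVE]
    labeled = build_labeled_set(positives, unlabeled, multiplier=negative_multiplier, seed=spec.seed + 1)
    features = featurize(labeled, background_genes=records)
    features = apply_missingness(features, spec.missing_rate, seed=spec.seed + 2)
    configs = configs or default_level_configs(n_cycles=n_cycles, max_iter=max_iter, seed=spec.seed + 3)
    result = train_screen(features, configs=configs, seed=spec.seed + 4)
    return result, truth


def rank_genes(model: CascadeModel, features_norm: pd.DataFrame, top_k: int = 20) -> pd.DataFrame:
    """Screen a (preprocessed) feature matrix and return the top-k ranked
    gene table (all candidates if fewer)."""
    trace = run_cascade(model, features_norm)
    return trace.genes.head(top_k)
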