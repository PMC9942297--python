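"""Feature-vector assembly: one named, fixed-order numeric descriptor per
CDS/protein pair, spanning six families — inherent lengths, codon bias,
amino-acid usage, physicochemical summaries, transmembrane summaries, the
Hurst exponent, and the information-entropy block. 79 slots in total; the
optional nats-scaled total-MI slot can be enabled to round the layout up to
80 (off by default).

Feature matrices are plain pandas DataFrames indexed by (gene_id, cds_id)
with a schema-version attribute, so they serialize to TSV untouched.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_features import codon_feature_block
from .infotheory import KmerDistribution, infotheory_feature_block, kmer_distribution, pool_distributions
from .protein_features import DEFAULT_RARE_AAS, TMFeatures, parse_tmhmm, protein_feature_block
from .sequence_io import GeneRecord
from .tables import AMINO_ACIDS, BASES

SCHEMA_VERSION = "1"

INHERENT_SLOTS = ("CDS_size", "Protein_size")
CODON_SLOTS = ("T3s", "C3s", "A3s", "G3s", "CAI", "CBI", "Fop", "Nc",
               "GC3s", "GC", "L_sym", "Gravy", "Aromo")
AA_USAGE_SLOTS = tuple(f"aa_{aa}" for aa in AMINO_ACIDS) + ("Rare_aa_ratio", "Close_aa_ratio")
PHYSCHEM_SLOTS = ("M_weight", "I_Point", "Tiny", "Small", "Aliphatic", "Aromatic",
                  "Nonpolar", "Polar", "Charged", "Basic", "Acidic", "A_R_Weight")
TM_SLOTS = ("ExpAA", "First60", "PredHel")
HURST_SLOTS = ("Hurst",)
INFO_SLOTS = ("H1", "H2", "H3") + tuple(
    f"mi_{x}{y}" for x, y in itertools.product(BASES, repeat=2)
) + ("mi_total", "KL1", "KL2", "KL3", "CE1", "CE2", "CE3")

FEATURE_SLOTS: tuple[str, ...] = (
    INHERENT_SLOTS + CODON_SLOTS + AA_USAGE_SLOTS + PHYSCHEM_SLOTS
    + TM_SLOTS + HURST_SLOTS + INFO_SLOTS
)
assert len(FEATURE_SLOTS) == 79


@dataclass
class FeatureConfig:
    """Extraction knobs: reference tables, rare-residue set, background
    distributions, the TM override map, and the optional 80th slot."""

    reference_weights: dict[str, float] | None = None
    optimal_set: frozenset[str] | None = None
    rare_set: frozenset[str] = DEFAULT_RARE_AAS
    tm_overrides: dict[str, TMFeatures] = field(default_factory=dict)
    backgrounds: dict[int, KmerDistribution] | None = None
    include_mi_nats: bool = False

    @property
    def slots(self) -> tuple[str, ...]:
        return FEATURE_SLOTS + (("mi_total_nats",) if self.include_mi_nats else ())


def compute_backgrounds(genes: list[GeneRecord]) -> dict[int, KmerDistribution]:
    """Pool every CDS's k-mer distributions (k = 1, 2, 3) into the dataset
    background used by the KL/cross-entropy slots."""
    out = {}
    for k in (1, 2, 3):
        out[k] = pool_distributions(
            [kmer_distribution(p.cds, k) for g in genes for p in g.pairs]
        )
    return out


def extract_pair(cds: str, protein: str, config: FeatureConfig,
                 tm_override: TMFeatures | None = None) -> dict[str, float]:
    """All feature slots for one CDS/protein pair (plus '_tm_source')."""
    if config.backgrounds is None:
        raise ValueError("config.backgrounds must be set (see compute_backgrounds)")
    row: dict[str, float] = {
        "CDS_size": float(len(cds)),
        "Protein_size": float(len(protein)),
    }
    row.update(codon_feature_block(cds, protein, config.reference_weights, config.optimal_set))
    row.update(protein_feature_block(cds, protein, config.rare_set, tm_override))
    row.update(infotheory_feature_block(cds, config.backgrounds, config.include_mi_nats))
    return row


def extract_features(genes: list[GeneRecord], config: FeatureConfig | None = None) -> pd.DataFrame:
    """Feature matrix for a gene set: one row per CDS/protein pair, indexed
    by (gene_id, cds_id), columns in fixed schema order plus ``tm_source``
    and ``label``. Missing values are NaN (imputed downstream).
    """
    config = config or FeatureConfig()
    if config.backgrounds is None:
        config.backgrounds = compute_backgrounds(genes)
    rows, index, tm_sources, labels = [], [], [], []
    for g in genes:
        for p in g.pairs:
            override = config.tm_overrides.get(p.cds_id) or config.tm_overrides.get(p.protein_id)
            row = extract_pair(p.cds, p.protein, config, override)
            tm_sources.append(row.pop("_tm_source"))
            rows.append([row[s] for s in config.slots])
            index.append((g.gene_id, p.cds_id))
            labels.append(g.label)
    df = pd.DataFrame(
        rows,
        columns=list(config.slots),
        index=pd.MultiIndex.from_tuples(index, names=["gene_id", "cds_id"]),
        dtype=float,
    )
    df["tm_source"] = tm_sources
    df["label"] = labels
    df.attrs["schema_version"] = SCHEMA_VERSION
    return df


def feature_columns(df: pd.DataFrame) -> list[str]:
    """The numeric feature columns of a matrix (schema order, metadata
    columns excluded)."""
    return [c for c in df.columns if c not in ("tm_source", "label")]


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.insert(0, "schema_version", df.attrs.get("schema_version", SCHEMA_VERSION))
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=[0, 1])
    version = str(df.pop("schema_version").iloc[0])
    df.attrs["schema_version"] = version
    return df


def load_tm_overrides(path: str | Path) -> dict[str, TMFeatures]:
    """TM-feature overrides, either TMHMM short format or a 4-column TSV
    (``seq_id  ExpAA  First60  PredHel``)."""
    text = Path(path).read_text()
    if "ExpAA=" in text:
        return parse_tmhmm(path)
    out: dict[str, TMFeatures] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith(("#", "seq_id")):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns")
        out[fields[0]] = TMFeatures(float(fields[1]), float(fields[2]), float(fields[3]), source="tmhmm")
    return out
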