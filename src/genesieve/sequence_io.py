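"""Gene-centric I/O: pairing CDS and protein FASTA records, negative-set
sampling proportional to chromosome, and stratified train/validation/test
splitting.

A *sample* is one CDS/protein pair; a gene may contribute several samples
(one per annotated isoform CDS). Pairing is explicit through a four-column
mapping table ``gene_id  cds_id  protein_id  chromosome`` — never inferred
from FASTA header dialects.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
import numpy as np

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE, UNLABELED = "positive", "negative", "unlabeled"
_LABELS = {POSITIVE, NEGATIVE, UNLABELED}


@dataclass
class SequencePair:
    """One CDS and its translated protein product."""

    cds_id: str
    cds: str
    protein_id: str
    protein: str
    translation_mismatch: bool = False

    def __post_init__(self) -> None:
        if not self.cds or not self.protein:
            raise ValueError(f"empty sequence in pair {self.cds_id}/{self.protein_id}")
        self.cds = self.cds.upper()
        self.protein = self.protein.upper()
        self.translation_mismatch = not self._translation_ok()

    def _translation_ok(self) -> bool:
        # Only checkable for N-free, in-frame CDSs; others are taken on trust.
        if len(self.cds) % 3 != 0 or "N" in self.cds:
            return True
        translated = str(Seq(self.cds).translate())
        if translated.endswith("*"):
            translated = translated[:-1]
        return translated == self.protein


@dataclass
class GeneRecord:
    """A gene symbol, its chromosome, and its CDS/protein sample pairs."""

    gene_id: str
    chromosome: str
    pairs: list[SequencePair]
    label: str = UNLABELED

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"invalid label {self.label!r}")
        if not self.pairs:
            raise ValueError(f"gene {self.gene_id} has no sequence pairs")

    @property
    def n_samples(self) -> int:
        return len(self.pairs)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions of (gene_id, cds_id) keys."""

    train: list[tuple[str, str]]
    validation: list[tuple[str, str]]
    test: list[tuple[str, str]]
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split partitions overlap")


def _read_fasta(path: str | Path) -> dict[str, str]:
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_mapping_table(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Read the ``gene_id  cds_id  protein_id  chromosome`` pairing TSV."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if i == 0 and fields[0] == "gene_id":
                continue
            if len(fields) != 4:
                raise ValueError(f"{path}:{i + 1}: expected 4 tab-separated columns, got {len(fields)}")
            rows.append(tuple(fields))
    if not rows:
        raise ValueError(f"empty pairing table {path}")
    return rows


def load_gene_set(
    cds_fasta: str | Path,
    protein_fasta: str | Path,
    mapping: str | Path,
    label: str = UNLABELED,
) -> list[GeneRecord]:
    """Pair CDS and protein FASTA records into GeneRecords.

    Exact duplicate pairs within a gene are dropped; any mapping row whose
    CDS or protein id is absent from the FASTA files is a hard error.
    """
    cds_seqs = _read_fasta(cds_fasta)
    prot_seqs = _read_fasta(protein_fasta)
    rows = read_mapping_table(mapping)

    missing = [
        f"{cid if cid not in cds_seqs else pid}"
        for _, cid, pid, _ in rows
        if cid not in cds_seqs or pid not in prot_seqs
    ]
    if missing:
        raise ValueError(f"unpaired sequence ids in mapping: {', '.join(sorted(set(missing)))}")

    genes: dict[str, GeneRecord] = {}
    seen: dict[str, set[tuple[str, str]]] = {}
    n_dupes = 0
    for gene_id, cds_id, protein_id, chrom in rows:
        key = (cds_seqs[cds_id], prot_seqs[protein_id])
        if key in seen.setdefault(gene_id, set()):
            n_dupes += 1
            continue
        seen[gene_id].add(key)
        pair = SequencePair(cds_id, cds_seqs[cds_id], protein_id, prot_seqs[protein_id])
        if pair.translation_mismatch:
            logger.warning("pair %s/%s: CDS translation does not match protein", cds_id, protein_id)
        if gene_id in genes:
            if genes[gene_id].chromosome != chrom:
                raise ValueError(f"gene {gene_id} mapped to two chromosomes")
            genes[gene_id].pairs.append(pair)
        else:
            genes[gene_id] = GeneRecord(gene_id, chrom, [pair], label)
    if n_dupes:
        logger.info("removed %d exact duplicate pairs", n_dupes)
    return list(genes.values())


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion `total` into integer quotas proportional to `weights`."""
    if weights.sum() == 0:
        return np.zeros_like(weights, dtype=int)
    exact = weights / weights.sum() * total
    quotas = np.floor(exact).astype(int)
    remainder = total - quotas.sum()
    order = np.argsort(-(exact - quotas), kind="stable")
    quotas[order[:remainder]] += 1
    return quotas


def sample_negatives(
    unlabeled: list[GeneRecord],
    positives: list[GeneRecord],
    multiplier: int = 10,
    seed: int = 0,
    exclude: set[str] | None = None,
) -> list[GeneRecord]:
    """Draw ``multiplier x |positives|`` unlabeled genes as the negative pool,
    apportioned across chromosomes in proportion to the positive set.

    Chromosomes whose unlabeled pool is exhausted have their residual quota
    redistributed proportionally over the remaining chromosomes.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    exclude = set(exclude or ())
    exclude |= {g.gene_id for g in positives}

    pools: dict[str, list[GeneRecord]] = {}
    for g in unlabeled:
        if g.gene_id not in exclude:
            pools.setdefault(g.chromosome, []).append(g)
    for pool in pools.values():
        pool.sort(key=lambda g: g.gene_id)  # stable basis for seeded draws

    chroms = sorted({g.chromosome for g in positives})
    pos_counts = np.array([sum(g.chromosome == c for g in positives) for c in chroms], dtype=float)
    target = multiplier * len(positives)
    quotas = _largest_remainder(pos_counts, target)

    rng = np.random.default_rng(seed)
    chosen: list[GeneRecord] = []
    deficits = 0
    avail = {c: list(pools.get(c, [])) for c in chroms}
    for c, q in zip(chroms, quotas):
        pool = avail[c]
        if len(pool) < q:
            warnings.warn(f"chromosome {c}: only {len(pool)} unlabeled genes for quota {q}; redistributing")
            deficits += q - len(pool)
            q = len(pool)
        idx = rng.choice(len(pool), size=q, replace=False) if q else []
        taken = [pool[i] for i in sorted(idx)]
        chosen.extend(taken)
        avail[c] = [g for i, g in enumerate(pool) if i not in set(idx)]
    # proportional redistribution of unmet quotas
    while deficits:
        spare = {c: pool for c, pool in avail.items() if pool}
        if not spare:
            warnings.warn(f"unlabeled pool exhausted; returning {len(chosen)} negatives")
            break
        w = np.array([len(spare[c]) for c in sorted(spare)], dtype=float)
        extra = _largest_remainder(w, min(deficits, int(w.sum())))
        deficits -= int(extra.sum())
        for c, q in zip(sorted(spare), extra):
            pool = avail[c]
            idx = rng.choice(len(pool), size=min(q, len(pool)), replace=False) if q else []
            chosen.extend(pool[i] for i in sorted(idx))
            avail[c] = [g for i, g in enumerate(pool) if i not in set(idx)]

    return [GeneRecord(g.gene_id, g.chromosome, g.pairs, NEGATIVE) for g in chosen]


def make_split(
    samples: list[tuple[tuple[str, str], str]],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Stratified 6:2:2-style split of ``((gene_id, cds_id), label)`` samples.

    Each class is split by `ratios` (largest-remainder rounding); if the
    training partition ends up class-imbalanced, the larger class is
    down-sampled there to restore the 1:1 positive:negative ratio.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    by_class: dict[str, list[tuple[str, str]]] = {}
    for key, lab in samples:
        by_class.setdefault(lab, []).append(key)
    if len(samples) < 3 or any(len(v) < 1 for v in by_class.values()):
        raise ValueError("too few samples to split")

    rng = np.random.default_rng(seed)
    parts: list[list[tuple[str, str]]] = [[], [], []]
    for lab in sorted(by_class):
        keys = sorted(by_class[lab])
        perm = rng.permutation(len(keys))
        quotas = _largest_remainder(np.asarray(ratios, dtype=float), len(keys))
        start = 0
        for p, q in enumerate(quotas):
            parts[p].extend(keys[i] for i in perm[start:start + q])
            start += q

    # enforce 1:1 in train when both classes are present
    if {POSITIVE, NEGATIVE} <= set(by_class):
        lab_of = dict(samples)
        tr_pos = [k for k in parts[0] if lab_of[k] == POSITIVE]
        tr_neg = [k for k in parts[0] if lab_of[k] == NEGATIVE]
        n = min(len(tr_pos), len(tr_neg))
        keep_pos = [tr_pos[i] for i in sorted(rng.choice(len(tr_pos), n, replace=False))]
        keep_neg = [tr_neg[i] for i in sorted(rng.choice(len(tr_neg), n, replace=False))]
        others = [k for k in parts[0] if lab_of[k] not in (POSITIVE, NEGATIVE)]
        parts[0] = keep_pos + keep_neg + others

    return DatasetSplit(train=parts[0], validation=parts[1], test=parts[2], seed=seed)


def write_gene_set(
    genes: list[GeneRecord],
    cds_fasta: str | Path,
    protein_fasta: str | Path,
    mapping: str | Path,
) -> None:
    """Write GeneRecords back to CDS/protein FASTA plus the pairing TSV."""
    with open(cds_fasta, "w") as cf, open(protein_fasta, "w") as pf, open(mapping, "w") as mf:
        mf.write("gene_id\tcds_id\tprotein_id\tchromosome\n")
        for g in sorted(genes, key=lambda g: g.gene_id):
            for p in g.pairs:
                cf.write(f">{p.cds_id}\n{p.cds}\n")
                pf.write(f">{p.protein_id}\n{p.protein}\n")
                mf.write(f"{g.gene_id}\t{p.cds_id}\t{p.protein_id}\t{g.chromosome}\n")


def write_manifest(genes: list[GeneRecord], path: str | Path, seed: int | None = None) -> None:
    manifest = {
        "seed": seed,
        "n_genes": len(genes),
        "n_samples": sum(g.n_samples for g in genes),
        "genes": [
            {"gene_id": g.gene_id, "chromosome": g.chromosome, "label": g.label, "n_pairs": g.n_samples}
            for g in sorted(genes, key=lambda g: g.gene_id)
        ],
    }
    Path(path).write_text(json.dumps(manifest, indent=1))
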