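"""Synthetic paired CDS/protein gene sets with a controllable class signal.

Every CDS is built codon-by-codon from a first-order Markov chain over
bases, restricted to sense codons, with three tunable class-effect
channels for the positive class:

* a GC-content shift (``gc_shift``): the chain's single-base stationary
  distribution is re-calibrated by a 1-D root solve so that the *expected*
  GC content of emitted codons — conditioned on stop-codon exclusion and
  including the codon-preference tilt — hits ``0.5 + gc_shift`` exactly;
* a codon-usage bias (``codon_bias``): an exponential tilt toward the
  bundled human-optimal codon of each synonym family, moving CAI/Fop/CBI;
* a dinucleotide correlation (``markov_alpha``): a self-transition mixture
  component that induces nonzero mutual information between consecutive
  bases, with a closed-form stationary value for verification.

Proteins are exact translations of their CDS, so every generated pair
passes the pairing validator. Negatives come from the same machinery with
all effects at zero (GC 0.5, uniform synonyms, i.i.d. bases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .sequence_io import GeneRecord, SequencePair, POSITIVE, UNLABELED
from .tables import BASES, CODON_TABLE, SENSE_CODONS, STOP_CODONS, default_optimal_codons

_HYDROPHOBIC = frozenset("LIVFA")
_TM_CODONS = tuple(c for c in SENSE_CODONS if CODON_TABLE[c] in _HYDROPHOBIC)


@dataclass
class ClassEffect:
    """Per-channel effect sizes separating positives from the null class."""

    gc_shift: float = 0.15
    codon_bias: float = 1.0
    markov_alpha: float = 0.2
    tm_insert_prob: float = 0.3

    def is_null(self) -> bool:
        return (self.gc_shift == 0 and self.codon_bias == 0
                and self.markov_alpha == 0 and self.tm_insert_prob == 0)


@dataclass
class SyntheticSpec:
    """Study conditions for one generated dataset."""

    n_genes_per_class: int = 200
    cds_length_range: tuple[int, int] = (300, 1500)  # nt, multiples of 3
    pairs_per_gene: tuple[int, int] = (1, 2)
    class_effect: ClassEffect = field(default_factory=ClassEffect)
    missing_rate: float = 0.02
    n_chromosomes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cds_length_range
        if lo > hi or lo < 90 or lo % 3 or hi % 3:
            raise ValueError("cds_length_range must be ordered multiples of 3, >= 90")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be a probability")


def _base_pi(g: float) -> np.ndarray:
    """Stationary single-base distribution with GC weight g, A/G/C/T order."""
    return np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])


def _transition_matrix(g: float, alpha: float) -> np.ndarray:
    """M(b'|b) = (1-alpha) pi(b') + alpha [b'=b]; stationary law is pi."""
    pi = _base_pi(g)
    return (1 - alpha) * pi[None, :] + alpha * np.eye(4)


_CODON_IDX = {b: i for i, b in enumerate(BASES)}
_SENSE = np.array([[_CODON_IDX[b] for b in c] for c in SENSE_CODONS])
_SENSE_GC = np.array([sum(b in "GC" for b in c) for c in SENSE_CODONS], dtype=float)


def _codon_kernel(g: float, alpha: float, codon_bias: float) -> np.ndarray:
    """Q[b, j]: probability of emitting sense codon j given previous last
    base b, proportional to the base-chain path probability times the
    optimal-codon tilt."""
    m = _transition_matrix(g, alpha)
    optimal = default_optimal_codons()
    tilt = np.array([np.exp(codon_bias) if c in optimal else 1.0 for c in SENSE_CODONS])
    q = np.empty((4, len(SENSE_CODONS)))
    for b in range(4):
        path = m[b, _SENSE[:, 0]] * m[_SENSE[:, 0], _SENSE[:, 1]] * m[_SENSE[:, 1], _SENSE[:, 2]]
        q[b] = path * tilt
        q[b] /= q[b].sum()
    return q


def _expected_gc(g: float, alpha: float, codon_bias: float) -> float:
    """Exact expected per-base GC of the stationary sense-codon chain."""
    q = _codon_kernel(g, alpha, codon_bias)
    # last-base process: T[b, b'] = sum over codons ending in b'
    t = np.zeros((4, 4))
    for j in range(len(SENSE_CODONS)):
        t[:, _SENSE[j, 2]] += q[:, j]
    evals, evecs = np.linalg.eig(t.T)
    rho = np.real(evecs[:, np.argmin(np.abs(evals - 1))])
    rho = rho / rho.sum()
    return float(rho @ (q @ (_SENSE_GC / 3)))


def calibrate_gc_weight(target_gc: float, alpha: float, codon_bias: float) -> float:
    """Solve for the GC weight g whose emitted codon stream has the target
    expected GC content."""
    return brentq(lambda g: _expected_gc(g, alpha, codon_bias) - target_gc, 0.02, 0.98, xtol=1e-10)


def stationary_base_mi(g: float, alpha: float) -> float:
    """Closed-form mutual information (bits) between consecutive bases of
    the unrestricted chain — the verification target for the MI channel."""
    pi = _base_pi(g)
    m = _transition_matrix(g, alpha)
    joint = pi[:, None] * m
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (pi[:, None] * pi[None, :]))
    return float(np.nansum(terms))


class _CodonSampler:
    def __init__(self, effect: ClassEffect, target_gc: float):
        self.g = calibrate_gc_weight(target_gc, effect.markov_alpha, effect.codon_bias)
        self.q = _codon_kernel(self.g, effect.markov_alpha, effect.codon_bias)
        stop_path = _transition_matrix(self.g, effect.markov_alpha)
        self._stops = sorted(STOP_CODONS)
        stop_idx = np.array([[_CODON_IDX[b] for b in c] for c in self._stops])
        sp = np.empty((4, 3))
        for b in range(4):
            sp[b] = (stop_path[b, stop_idx[:, 0]] * stop_path[stop_idx[:, 0], stop_idx[:, 1]]
                     * stop_path[stop_idx[:, 1], stop_idx[:, 2]])
            sp[b] /= sp[b].sum()
        self._stop_probs = sp
        tm_mask = np.array([c in _TM_CODONS for c in SENSE_CODONS])
        self.q_tm = self.q * tm_mask[None, :]
        self.q_tm /= self.q_tm.sum(axis=1, keepdims=True)

    def body(self, n_codons: int, rng: np.random.Generator, kernel: np.ndarray | None = None) -> list[str]:
        kernel = self.q if kernel is None else kernel
        codons = ["ATG"]
        prev = _CODON_IDX["G"]
        for _ in range(n_codons - 1):
            j = rng.choice(len(SENSE_CODONS), p=kernel[prev])
            codons.append(SENSE_CODONS[j])
            prev = _SENSE[j, 2]
        return codons

    def stop(self, prev_base: str, rng: np.random.Generator) -> str:
        return self._stops[rng.choice(3, p=self._stop_probs[_CODON_IDX[prev_base]])]


def _translate(codons: list[str]) -> str:
    return "".join(CODON_TABLE[c] for c in codons)


def generate(spec: SyntheticSpec) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Generate ``2 x n_genes_per_class`` genes: positives with the class
    effects applied, plus a null-class pool labeled *unlabeled* (it stands
    for the genome background from which negatives are later sampled).
    Returns the records and a truth table (gene_id, chromosome, true_class).
    """
    rng = np.random.default_rng(spec.seed)
    effect = spec.class_effect
    pos_sampler = _CodonSampler(effect, 0.5 + effect.gc_shift)
    null_sampler = _CodonSampler(ClassEffect(0, 0, 0, 0), 0.5)

    records: list[GeneRecord] = []
    truth_rows = []
    lo, hi = spec.cds_length_range
    for cls, sampler, label in (("positive", pos_sampler, POSITIVE),
                                ("null", null_sampler, UNLABELED)):
        for i in range(spec.n_genes_per_class):
            gene_id = f"{'POS' if cls == 'positive' else 'NUL'}{i:04d}"
            chrom = f"chr{i % spec.n_chromosomes + 1}"
            n_pairs = int(rng.integers(spec.pairs_per_gene[0], spec.pairs_per_gene[1] + 1))
            pairs = []
            for p in range(n_pairs):
                n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
                codons = sampler.body(n_codons, rng)
                if cls == "positive" and effect.tm_insert_prob > 0 and rng.random() < effect.tm_insert_prob:
                    seg = sampler.body(22, rng, kernel=sampler.q_tm)[1:]  # drop the ATG
                    at = int(rng.integers(1, len(codons)))
                    codons = codons[:at] + seg + codons[at:]
                codons.append(sampler.stop(codons[-1][2], rng))
                cds = "".join(codons)
                pairs.append(SequencePair(
                    cds_id=f"{gene_id}.c{p + 1}", cds=cds,
                    protein_id=f"{gene_id}.p{p + 1}", protein=_translate(codons[:-1]),
                ))
            records.append(GeneRecord(gene_id, chrom, pairs, label))
            truth_rows.append({"gene_id": gene_id, "chromosome": chrom, "true_class": cls})
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return records, truth


#: feature slots that real pipelines most often lose (undefined codon-bias
#: statistics, absent transmembrane-predictor output)
MASKABLE_SLOTS = ("Nc", "ExpAA", "First60", "PredHel")


def apply_missingness(matrix: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Mask a random ``rate`` fraction of the maskable slots, emulating the
    occasional missing feature values of real extractions."""
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    for col in MASKABLE_SLOTS:
        if col in out.columns:
            mask = rng.random(len(out)) < rate
            out.loc[mask, col] = np.nan
    out.attrs.update(matrix.attrs)
    return out


WORKED_FIXTURE_SPEC = SyntheticSpec(
    n_genes_per_class=6,
    cds_length_range=(150, 450),
    pairs_per_gene=(1, 2),
    class_effect=ClassEffect(gc_shift=0.15, codon_bias=1.0, markov_alpha=0.2, tm_insert_prob=0.5),
    missing_rate=0.0,
    n_chromosomes=3,
    seed=20230220,
)

_FIXTURE_DIR = Path(__file__).parent / "fixtures"


def worked_fixture() -> tuple[list[GeneRecord], pd.DataFrame]:
    """The frozen 12-gene (6 positive + 6 null) regression dataset shipped
    with the package; regenerating :data:`WORKED_FIXTURE_SPEC` reproduces
    it exactly."""
    from .sequence_io import load_gene_set  # local import to avoid cycles

    genes = load_gene_set(
        _FIXTURE_DIR / "cds.fasta", _FIXTURE_DIR / "protein.fasta",
        _FIXTURE_DIR / "pairing.tsv",
    )
    truth = pd.read_csv(_FIXTURE_DIR / "truth.tsv", sep="\t", index_col=0,
                        keep_default_na=False)
    for g in genes:
        g.label = POSITIVE if truth.loc[g.gene_id, "true_class"] == "positive" else UNLABELED
    return genes, truth


def worked_fixture_dir() -> Path:
    return _FIXTURE_DIR
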