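"""Information-theoretic sequence descriptors and the Hurst exponent.

Shannon entropy of the overlapping 1/2/3-mer distributions, the 16 per-pair
mutual-information terms between consecutive bases plus their total,
Kullback-Leibler divergence and cross entropy of the sequence's k-mer
distributions against a background, and a rescaled-range Hurst estimate of
the digitized (A,G,C,T -> 0,1,2,3) base series. All logarithms are base 2,
so the cross-entropy identity CE = H + D_KL holds exactly across features.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .tables import BASES

NAN = float("nan")

#: pseudocount added to empty background cells before renormalizing, since
#: D_KL and CE are undefined where q = 0 but p > 0
BACKGROUND_EPSILON = 1e-6


@dataclass
class KmerDistribution:
    """Overlapping k-mer frequencies of a DNA string; windows containing
    ambiguity codes are skipped."""

    k: int
    probs: dict[str, float]
    n_windows: int


def kmer_distribution(seq: str, k: int) -> KmerDistribution:
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    counts: dict[str, int] = {}
    n = 0
    valid = set(BASES)
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if set(kmer) <= valid:
            counts[kmer] = counts.get(kmer, 0) + 1
            n += 1
    probs = {kmer: c / n for kmer, c in counts.items()} if n else {}
    return KmerDistribution(k, probs, n)


def pool_distributions(dists: list[KmerDistribution]) -> KmerDistribution:
    """Window-weighted pooling of per-sequence distributions into one
    background distribution."""
    if not dists:
        raise ValueError("nothing to pool")
    k = dists[0].k
    if any(d.k != k for d in dists):
        raise ValueError("mixed k in pool")
    counts: dict[str, float] = {}
    n = 0
    for d in dists:
        n += d.n_windows
        for kmer, p in d.probs.items():
            counts[kmer] = counts.get(kmer, 0.0) + p * d.n_windows
    probs = {kmer: c / n for kmer, c in counts.items()} if n else {}
    return KmerDistribution(k, probs, n)


def shannon_entropy(dist: KmerDistribution) -> float:
    """H = -sum p log2 p, in bits; 0 <= H <= 2k."""
    if dist.n_windows < 1:
        return NAN
    return -sum(p * math.log2(p) for p in dist.probs.values() if p > 0)


def mutual_information(seq: str) -> dict[str, float]:
    """The 16 per-pair terms P(x,y) log2(P(x,y)/(P(x)P(y))) over consecutive
    base pairs, in A/G/C/T order, plus their sum ``mi_total`` (17 slots).

    The joint distribution comes from overlapping consecutive pairs; the
    marginals are the single-base frequencies of the whole sequence. A term
    with P(x,y) = 0 contributes 0.
    """
    joint = kmer_distribution(seq, 2)
    marginal = kmer_distribution(seq, 1)
    names = [f"mi_{x}{y}" for x, y in itertools.product(BASES, repeat=2)]
    if joint.n_windows == 0:
        return dict.fromkeys(names + ["mi_total"], NAN)
    out: dict[str, float] = {}
    total = 0.0
    for x, y in itertools.product(BASES, repeat=2):
        pxy = joint.probs.get(x + y, 0.0)
        if pxy > 0:
            term = pxy * math.log2(pxy / (marginal.probs.get(x, 0.0) * marginal.probs.get(y, 0.0)))
        else:
            term = 0.0
        out[f"mi_{x}{y}"] = term
        total += term
    out["mi_total"] = total
    return out


def _smoothed_background(q: KmerDistribution) -> dict[str, float]:
    cells = ["".join(t) for t in itertools.product(BASES, repeat=q.k)]
    raw = {c: q.probs.get(c, 0.0) for c in cells}
    smoothed = {c: v if v > 0 else BACKGROUND_EPSILON for c, v in raw.items()}
    z = sum(smoothed.values())
    return {c: v / z for c, v in smoothed.items()}


def kl_divergence(p: KmerDistribution, q: KmerDistribution) -> float:
    """D_KL(p || q) in bits; q receives pseudocount smoothing on empty cells
    (p never does)."""
    if p.k != q.k:
        raise ValueError("mismatched k")
    if p.n_windows == 0 or q.n_windows == 0:
        return NAN
    qs = _smoothed_background(q)
    return sum(pv * math.log2(pv / qs[c]) for c, pv in p.probs.items() if pv > 0)


def cross_entropy(p: KmerDistribution, q: KmerDistribution) -> float:
    """CE(p, q) = -sum p log2 q = H(p) + D_KL(p || q)."""
    if p.k != q.k:
        raise ValueError("mismatched k")
    if p.n_windows == 0 or q.n_windows == 0:
        return NAN
    qs = _smoothed_background(q)
    return -sum(pv * math.log2(qs[c]) for c, pv in p.probs.items() if pv > 0)


DIGITS = {"A": 0, "G": 1, "C": 2, "T": 3}


def digitize(seq: str) -> np.ndarray:
    """Map the N-free subsequence onto the integer series A,G,C,T -> 0..3."""
    return np.array([DIGITS[b] for b in seq if b in DIGITS], dtype=float)


def hurst_exponent(values: np.ndarray, min_window: int = 8) -> float:
    """Rescaled-range (R/S) Hurst estimate of an integer/float series.

    For each window size n on a log-spaced grid between ``min_window`` and
    len/2, R/S is averaged over non-overlapping blocks (blocks with zero
    standard deviation are skipped); H is the least-squares slope of
    log(R/S) on log(n), clipped to [0, 1]. Series shorter than 32 or with no
    variation anywhere return NaN.
    """
    x = np.asarray(values, dtype=float)
    n_total = len(x)
    if n_total < 32:
        return NAN
    sizes = np.unique(
        np.geomspace(min_window, n_total // 2, num=12).round().astype(int)
    )
    log_n, log_rs = [], []
    for n in sizes:
        rs_vals = []
        for start in range(0, n_total - n + 1, n):
            block = x[start:start + n]
            s = block.std()
            if s == 0:
                continue
            dev = np.cumsum(block - block.mean())
            r = dev.max() - dev.min()
            rs_vals.append(r / s)
        if rs_vals:
            log_n.append(math.log(n))
            log_rs.append(math.log(np.mean(rs_vals)))
    if len(log_n) < 2:
        return NAN
    slope = np.polyfit(log_n, log_rs, 1)[0]
    return float(min(max(slope, 0.0), 1.0))


def infotheory_feature_block(
    cds: str,
    backgrounds: dict[int, KmerDistribution],
    include_mi_nats: bool = False,
) -> dict[str, float]:
    """The 26 information-entropy slots plus the Hurst slot.

    ``backgrounds`` maps k -> reference distribution for the KL and
    cross-entropy slots (typically pooled over the dataset).
    """
    out: dict[str, float] = {"Hurst": hurst_exponent(digitize(cds))}
    dists = {k: kmer_distribution(cds, k) for k in (1, 2, 3)}
    for k in (1, 2, 3):
        out[f"H{k}"] = shannon_entropy(dists[k])
    out.update(mutual_information(cds))
    for k in (1, 2, 3):
        out[f"KL{k}"] = kl_divergence(dists[k], backgrounds[k])
        out[f"CE{k}"] = cross_entropy(dists[k], backgrounds[k])
    if include_mi_nats:
        mt = out["mi_total"]
        out["mi_total_nats"] = mt * math.log(2) if not math.isnan(mt) else NAN
    return out
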