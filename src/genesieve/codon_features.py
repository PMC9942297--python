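"""Codon-usage-bias statistics computed directly from their classical
definitions: third-position base fractions, RSCU, CAI, CBI, Fop, Wright's
effective number of codons, GC/GC3s, plus the protein GRAVY and aromaticity
summaries that round out the codon-bias feature family.

Missing values are returned as NaN; e.g. Nc is undefined when too few
synonym families are observed at least twice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .tables import (
    CODON_TABLE,
    KYTE_DOOLITTLE,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYM_FAMILIES,
    VARIABLE_AAS,
    default_cai_weights,
    default_optimal_codons,
)

NAN = float("nan")


@dataclass
class CodonCounts:
    """Codon occurrence counts for one CDS read in frame 0."""

    counts: dict[str, int]
    n_codons: int

    def sense_items(self):
        return ((c, n) for c, n in self.counts.items() if c not in STOP_CODONS)


def count_codons(cds: str) -> CodonCounts:
    """Count frame-0 codons; a trailing partial codon is dropped and codons
    containing ambiguity codes are skipped (the frame is not shifted)."""
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    counts: dict[str, int] = {}
    n = 0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        if codon in CODON_TABLE:
            counts[codon] = counts.get(codon, 0) + 1
            n += 1
    return CodonCounts(counts, n)


def _variable_codon_items(counts: CodonCounts):
    """(codon, count) over codons of synonymously-variable amino acids."""
    return (
        (c, n) for c, n in counts.sense_items() if CODON_TABLE[c] in VARIABLE_AAS
    )


def base3_synonymous(counts: CodonCounts) -> tuple[float, float, float, float]:
    """T3s, C3s, A3s, G3s: third-position base usage among codons of amino
    acids with synonymous choice, with the CodonW denominator convention —
    for base b, only codons whose family offers a codon ending in b count."""
    num = dict.fromkeys("TCAG", 0)
    den = dict.fromkeys("TCAG", 0)
    for codon, n in _variable_codon_items(counts):
        family_ends = {c[2] for c in SYNONYM_FAMILIES[CODON_TABLE[codon]]}
        for b in "TCAG":
            if b in family_ends:
                den[b] += n
        num[codon[2]] += n
    if all(v == 0 for v in den.values()):
        return (NAN, NAN, NAN, NAN)
    return tuple(num[b] / den[b] if den[b] else NAN for b in "TCAG")  # type: ignore[return-value]


def rscu(counts: CodonCounts) -> dict[str, float]:
    """Relative synonymous codon usage: observed count over the family mean.
    Families never observed get NaN for all their codons."""
    out: dict[str, float] = {}
    for fam in SYNONYM_FAMILIES.values():
        total = sum(counts.counts.get(c, 0) for c in fam)
        if total == 0:
            out.update({c: NAN for c in fam})
        else:
            mean = total / len(fam)
            out.update({c: counts.counts.get(c, 0) / mean for c in fam})
    return out


def cai(counts: CodonCounts, reference_weights: dict[str, float] | None = None) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness over
    the CDS's codons, excluding Met, Trp and stop codons."""
    w = reference_weights if reference_weights is not None else default_cai_weights()
    if any(v <= 0 for v in w.values()):
        raise ValueError("reference weights must be positive")
    log_sum = 0.0
    n = 0
    for codon, count in _variable_codon_items(counts):
        log_sum += count * math.log(w[codon])
        n += count
    return math.exp(log_sum / n) if n else NAN


def cbi_fop(counts: CodonCounts, optimal_set: frozenset[str] | set[str] | None = None) -> tuple[float, float]:
    """Codon bias index and frequency of optimal codons.

    Fop = N_opt / N_tot over synonymously-variable codons; CBI rescales Fop
    against N_rand, the optimal count expected under uniform synonym usage,
    so that no bias scores 0 and exclusive optimal-codon use scores 1.
    """
    opt = frozenset(optimal_set) if optimal_set is not None else default_optimal_codons()
    if not opt:
        raise ValueError("optimal codon set is empty")
    n_tot = n_opt = 0
    n_rand = 0.0
    for codon, count in _variable_codon_items(counts):
        fam = SYNONYM_FAMILIES[CODON_TABLE[codon]]
        n_tot += count
        if codon in opt:
            n_opt += count
        n_rand += count * sum(c in opt for c in fam) / len(fam)
    if n_tot == 0:
        return (NAN, NAN)
    fop = n_opt / n_tot
    cbi_val = (n_opt - n_rand) / (n_tot - n_rand) if n_tot != n_rand else NAN
    return (cbi_val, fop)


# degeneracy class -> number of synonym families in the standard code
_DEGENERACY_CLASSES: dict[int, list[str]] = {}
for _aa, _fam in SYNONYM_FAMILIES.items():
    _DEGENERACY_CLASSES.setdefault(len(_fam), []).append(_aa)


def enc(counts: CodonCounts) -> float:
    """Wright's effective number of codons,
    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,
    with F-hat the bias-corrected homozygosity averaged within each
    degeneracy class. Families observed fewer than twice are excluded; a
    missing 3-fold class falls back to the mean of the 2- and 4-fold classes
    (the standard single-family workaround for Ile); a missing 2-, 4- or
    6-fold class leaves Nc undefined.
    """
    class_f: dict[int, float] = {}
    for k, aas in _DEGENERACY_CLASSES.items():
        if k == 1:
            continue
        fs = []
        for aa in aas:
            fam = SYNONYM_FAMILIES[aa]
            n = sum(counts.counts.get(c, 0) for c in fam)
            if n < 2:
                continue
            s = sum((counts.counts.get(c, 0) / n) ** 2 for c in fam)
            f_hat = (n * s - 1) / (n - 1)
            if f_hat > 0:
                fs.append(f_hat)
        if fs:
            class_f[k] = sum(fs) / len(fs)
    if 2 not in class_f or 4 not in class_f or 6 not in class_f:
        return NAN
    if 3 not in class_f:
        class_f[3] = (class_f[2] + class_f[4]) / 2
    nc = 2 + 9 / class_f[2] + 1 / class_f[3] + 5 / class_f[4] + 3 / class_f[6]
    return min(max(nc, 20.0), 61.0)


def gc_stats(counts: CodonCounts, cds: str) -> tuple[float, float, int]:
    """(GC, GC3s, L_sym): overall G+C fraction over unambiguous bases, G+C
    fraction at third positions of synonymously-variable codons, and the
    count of synonymously-variable codons."""
    bases = [b for b in cds if b in "ACGT"]
    gc = sum(b in "GC" for b in bases) / len(bases) if bases else NAN
    l_sym = 0
    gc3 = 0
    for codon, n in _variable_codon_items(counts):
        l_sym += n
        if codon[2] in "GC":
            gc3 += n
    gc3s = gc3 / l_sym if l_sym else NAN
    return (gc, gc3s, l_sym)


def gravy_aromo(protein: str) -> tuple[float, float]:
    """GRAVY (mean Kyte-Doolittle hydropathy) and aromaticity (fraction of
    F/W/Y). Residues outside the 20-letter alphabet are skipped."""
    residues = [aa for aa in protein if aa in KYTE_DOOLITTLE]
    if not residues:
        return (NAN, NAN)
    gravy = sum(KYTE_DOOLITTLE[aa] for aa in residues) / len(residues)
    aromo = sum(aa in "FWY" for aa in residues) / len(residues)
    return (gravy, aromo)


def codon_feature_block(cds: str, protein: str,
                        reference_weights: dict[str, float] | None = None,
                        optimal_set: frozenset[str] | None = None) -> dict[str, float]:
    """The 13 codon-bias feature slots for one CDS/protein pair."""
    counts = count_codons(cds)
    t3s, c3s, a3s, g3s = base3_synonymous(counts)
    cbi_val, fop = cbi_fop(counts, optimal_set)
    gc, gc3s, l_sym = gc_stats(counts, cds)
    gravy, aromo = gravy_aromo(protein)
    return {
        "T3s": t3s, "C3s": c3s, "A3s": a3s, "G3s": g3s,
        "CAI": cai(counts, reference_weights),
        "CBI": cbi_val, "Fop": fop,
        "Nc": enc(counts),
        "GC3s": gc3s, "GC": gc, "L_sym": float(l_sym),
        "Gravy": gravy, "Aromo": aromo,
    }
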