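"""Protein-side descriptors: the 20 amino-acid usage frequencies, rare-residue
and stop-adjacent-codon ratios, twelve physicochemical summaries, and the
three transmembrane-helix summaries.

The physicochemical block mirrors the classical pepstats output (molecular
weight, isoelectric point, residue-class fractions, average residue weight).
Transmembrane summaries accept genuine TMHMM short-format output when the
user has it; otherwise a clearly-tagged Kyte-Doolittle sliding-window
heuristic stands in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from Bio.SeqUtils import molecular_weight

from .codon_features import count_codons
from .tables import (
    AA_CLASSES,
    AMINO_ACIDS,
    KYTE_DOOLITTLE,
    PKA_NEGATIVE,
    PKA_POSITIVE,
    STOP_CODONS,
)

NAN = float("nan")

DEFAULT_RARE_AAS = frozenset("WCHM")

TM_WINDOW = 19
TM_THRESHOLD = 1.6


@dataclass
class AAComposition:
    freq: dict[str, float]
    n_residues: int


@dataclass
class TMFeatures:
    """Transmembrane summaries: expected helix residues, helix residues in
    the first 60 positions, and a 0..1 helix-presence indicator/probability."""

    exp_aa: float
    first60: float
    predhel: float
    source: str = "heuristic"


def aa_frequencies(protein: str) -> AAComposition:
    """Relative frequency of each of the 20 standard residues; ambiguous
    letters (X/B/Z) are excluded from the denominator."""
    residues = [aa for aa in protein if aa in KYTE_DOOLITTLE]
    n = len(residues)
    freq = {aa: 0.0 for aa in AMINO_ACIDS}
    for aa in residues:
        freq[aa] += 1
    if n:
        for aa in freq:
            freq[aa] /= n
    return AAComposition(freq, n)


def rare_aa_ratio(protein: str, rare_set: frozenset[str] = DEFAULT_RARE_AAS) -> float:
    residues = [aa for aa in protein if aa in KYTE_DOOLITTLE]
    if not residues:
        return NAN
    return sum(aa in rare_set for aa in residues) / len(residues)


def close_aa_ratio(cds: str, raw_count: bool = False) -> float:
    """Fraction of sense codons one third-position substitution away from a
    stop codon (``raw_count=True`` returns the unnormalized count)."""
    counts = count_codons(cds)
    n_sense = 0
    n_close = 0
    for codon, n in counts.sense_items():
        n_sense += n
        mutants = (codon[:2] + b for b in "ACGT" if b != codon[2])
        if any(m in STOP_CODONS for m in mutants):
            n_close += n
    if raw_count:
        return float(n_close)
    return n_close / n_sense if n_sense else NAN


def net_charge(protein: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH with the EMBOSS pKa
    set (N/C termini plus K, R, H, D, E, C, Y side chains)."""
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["Cterm"] - ph))
    for aa in protein:
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(protein: str, tol: float = 1e-6) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = (lo + hi) / 2
        q = net_charge(protein, mid)
        if abs(q) < tol or hi - lo < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def physicochemical(protein: str) -> dict[str, float]:
    """The 12 pepstats-style slots. Residue-class fractions count B and Z
    where their class lists them; mass and pI use the 20 standard letters."""
    standard = "".join(aa for aa in protein if aa in KYTE_DOOLITTLE)
    class_residues = [aa for aa in protein if aa in KYTE_DOOLITTLE or aa in "BZ"]
    if not standard:
        return dict.fromkeys(
            ["M_weight", "I_Point", *AA_CLASSES, "A_R_Weight"], NAN
        )
    m_weight = molecular_weight(standard, seq_type="protein")
    out = {
        "M_weight": m_weight,
        "I_Point": isoelectric_point(standard),
    }
    n_cls = len(class_residues)
    for name, members in AA_CLASSES.items():
        out[name] = sum(aa in members for aa in class_residues) / n_cls
    out["A_R_Weight"] = m_weight / len(standard)
    return out


def tm_heuristic(protein: str) -> TMFeatures:
    """Sliding Kyte-Doolittle window (length 19, mean hydropathy >= 1.6)
    marks putative transmembrane residues; ambiguous letters score 0."""
    values = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in protein]
    n = len(values)
    marked = [False] * n
    any_window = False
    if n >= TM_WINDOW:
        window_sum = sum(values[:TM_WINDOW])
        for start in range(n - TM_WINDOW + 1):
            if start > 0:
                window_sum += values[start + TM_WINDOW - 1] - values[start - 1]
            if window_sum / TM_WINDOW >= TM_THRESHOLD:
                any_window = True
                for i in range(start, start + TM_WINDOW):
                    marked[i] = True
    exp_aa = float(sum(marked))
    first60 = float(sum(marked[:60]))
    return TMFeatures(exp_aa, first60, 1.0 if any_window else 0.0, source="heuristic")


def tm_features(protein: str, override: TMFeatures | None = None) -> TMFeatures:
    """Return the TMHMM-derived summaries verbatim when supplied, otherwise
    the hydropathy-window heuristic."""
    if override is not None:
        return TMFeatures(override.exp_aa, override.first60, override.predhel, source="tmhmm")
    return tm_heuristic(protein)


_TMHMM_FIELD = re.compile(r"(len|ExpAA|First60|PredHel|Topology)=([^\s]+)")


def parse_tmhmm(path: str | Path) -> dict[str, TMFeatures]:
    """Parse TMHMM short-format output into per-sequence TMFeatures keyed by
    sequence id. Raises on lines missing the expected ``key=value`` fields."""
    out: dict[str, TMFeatures] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = dict(_TMHMM_FIELD.findall(line))
            seq_id = line.split()[0]
            try:
                out[seq_id] = TMFeatures(
                    exp_aa=float(fields["ExpAA"]),
                    first60=float(fields["First60"]),
                    predhel=float(fields["PredHel"]),
                    source="tmhmm",
                )
            except KeyError as e:
                raise ValueError(f"{path}:{lineno}: missing TMHMM field {e.args[0]}") from None
    return out


def protein_feature_block(
    cds: str,
    protein: str,
    rare_set: frozenset[str] = DEFAULT_RARE_AAS,
    tm_override: TMFeatures | None = None,
) -> dict[str, float]:
    """The 22 usage + 12 physicochemical + 3 transmembrane feature slots."""
    comp = aa_frequencies(protein)
    out = {f"aa_{aa}": comp.freq[aa] if comp.n_residues else NAN for aa in AMINO_ACIDS}
    out["Rare_aa_ratio"] = rare_aa_ratio(protein, rare_set)
    out["Close_aa_ratio"] = close_aa_ratio(cds)
    out.update(physicochemical(protein))
    tm = tm_features(protein, tm_override)
    out.update({"ExpAA": tm.exp_aa, "First60": tm.first60, "PredHel": tm.predhel})
    out["_tm_source"] = tm.source  # carried out-of-band by the assembler
    return out
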