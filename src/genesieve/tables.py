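"""Static biochemical lookup tables shared across the feature extractors.

Standard genetic code only (inputs are annotated coding sequences read in
frame 0), Kyte-Doolittle hydropathy, and the EMBOSS ionizable-group pKa set
used by the isoelectric-point solver.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

BASES = "AGCT"  # canonical order, matching the 0/1/2/3 digitization
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

# Standard genetic code, DNA alphabet. '*' marks stop codons.
CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in CODON_TABLE if c not in STOP_CODONS))

#: amino acid -> tuple of synonymous codons (stops excluded)
SYNONYM_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TABLE.items():
    if _aa != "*":
        SYNONYM_FAMILIES.setdefault(_aa, ())
for _codon in SENSE_CODONS:
    _aa = CODON_TABLE[_codon]
    SYNONYM_FAMILIES[_aa] = SYNONYM_FAMILIES[_aa] + (_codon,)

#: amino acids whose synonym family has more than one member (codon-bias
#: statistics are defined over these; Met and Trp carry no choice).
VARIABLE_AAS = frozenset(aa for aa, fam in SYNONYM_FAMILIES.items() if len(fam) > 1)

# Kyte & Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# EMBOSS (pepstats/iep) ionizable-group pKa values.
PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

# Residue-class memberships for the physicochemical class fractions.
# B (Asx) and Z (Glx) contribute only to the classes that list them.
AA_CLASSES: dict[str, frozenset[str]] = {
    "Tiny": frozenset("ACGST"),
    "Small": frozenset("ABCDGNPSTV"),
    "Aliphatic": frozenset("AILV"),
    "Aromatic": frozenset("FHWY"),
    "Nonpolar": frozenset("ACFGILMPVWY"),
    "Polar": frozenset("DEHKNQRSTZ"),
    "Charged": frozenset("BDEHKRZ"),
    "Basic": frozenset("HKR"),
    "Acidic": frozenset("BDEZ"),
}


@lru_cache(maxsize=None)
def human_codon_usage() -> dict[str, float]:
    """Bundled human codon-usage frequencies (occurrences per thousand)."""
    usage: dict[str, float] = {}
    text = resources.files("genesieve.data").joinpath("human_codon_usage.tsv").read_text()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        codon, value = line.split("\t")
        usage[codon] = float(value)
    return usage


@lru_cache(maxsize=None)
def default_cai_weights() -> dict[str, float]:
    """Relative adaptiveness w(c) = f(c) / max f over c's synonym family."""
    usage = human_codon_usage()
    weights: dict[str, float] = {}
    for fam in SYNONYM_FAMILIES.values():
        top = max(usage[c] for c in fam)
        for c in fam:
            # CodonW floors unused codons at a small positive weight so the
            # geometric mean stays defined.
            weights[c] = max(usage[c] / top, 0.01)
    return weights


@lru_cache(maxsize=None)
def default_optimal_codons() -> frozenset[str]:
    """The most frequent codon of every multi-codon synonym family."""
    usage = human_codon_usage()
    optimal = set()
    for aa, fam in SYNONYM_FAMILIES.items():
        if len(fam) > 1:
            optimal.add(max(fam, key=lambda c: usage[c]))
    return frozenset(optimal)


def read_codon_value_table(path) -> dict[str, float]:
    """Parse a two-column ``codon<TAB>value`` TSV (header optional)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{i + 1}: expected two tab-separated columns")
            codon = fields[0].upper()
            if i == 0 and codon not in CODON_TABLE:
                continue  # header row
            if codon not in CODON_TABLE:
                raise ValueError(f"{path}:{i + 1}: unknown codon {fields[0]!r}")
            out[codon] = float(fields[1])
    return out
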