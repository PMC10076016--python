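"""Standard genetic code (NCBI translation table 1) and codon helpers.

The table is hard-coded so that codon classification does not depend on any
external library; the test suite cross-checks it against Biopython.
"""

from __future__ import annotations

from itertools import product

BASES = "ACGT"

GENETIC_CODE: dict[str, str] = {
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

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str:
    """Amino acid (one letter, '*' for stop) for an unambiguous codon."""
    try:
        return GENETIC_CODE[codon]
    except KeyError:
        raise ValueError(f"not an unambiguous codon: {codon!r}") from None


def codons_of(seq: str) -> list[str]:
    """Split an in-frame nucleotide string into codons (length must be %3==0)."""
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def neighbors(codon: str):
    """All nine single-nucleotide mutants of a codon, with position and base."""
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                yield pos, b, codon[:pos] + b + codon[pos + 1:]


assert len(GENETIC_CODE) == 64 == len(set(product(BASES, repeat=3)))
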