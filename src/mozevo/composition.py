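"""Sequence I/O plus GC-content and amino-acid-composition analyses.

GC content is a proxy for gene/transcript thermal stability; amino-acid
composition is computed on mature (post signal-peptide cleavage) proteins so
that secreted proteins are compared in their functional form.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO

NUC_ALPHABET = frozenset("ACGTN")
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
AA_ALPHABET = frozenset(AA_LETTERS + "X")


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over {A,C,G,T,N} (upper-cased on construction)."""

    id: str
    residues: str
    description: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - NUC_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: non-nucleotide characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence, optionally annotated with a predicted signal-peptide
    cleavage index (number of N-terminal residues forming the signal peptide)."""

    id: str
    residues: str
    cleavage_index: int | None = None
    description: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: non-amino-acid characters {sorted(bad)}")
        if self.cleavage_index is not None and not (
            0 <= self.cleavage_index < len(self.residues)
        ):
            raise ValueError(
                f"{self.id}: cleavage_index {self.cleavage_index} outside "
                f"[0, {len(self.residues)})"
            )

    def __len__(self) -> int:
        return len(self.residues)


class FastaError(ValueError):
    pass


def read_fasta(
    path: str | Path, kind: Literal["nucleotide", "protein"] = "nucleotide"
) -> list[NucleotideSequence] | list[ProteinRecord]:
    """Read a FASTA file into typed records, preserving order.

    Raises FastaError on an empty file, a file whose first non-blank line is
    not a header, or duplicate record ids.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}: line {lineno} is not a FASTA header: {line.strip()!r}"
                    )
                break
        else:
            raise FastaError(f"{path}: empty FASTA file")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"{path}: no FASTA records")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
    cls = NucleotideSequence if kind == "nucleotide" else ProteinRecord
    out = []
    for rec in records:
        desc = rec.description[len(rec.id):].strip() or None
        if kind == "nucleotide":
            out.append(NucleotideSequence(rec.id, str(rec.seq), description=desc))
        else:
            out.append(ProteinRecord(rec.id, str(rec.seq), description=desc))
    return out


def write_fasta(records: Iterable, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = rec.residues
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def gc_content(seq: NucleotideSequence | str) -> float:
    """Percent G+C among unambiguous bases; N residues are ignored entirely."""
    residues = seq if isinstance(seq, str) else seq.residues
    residues = residues.upper()
    gc = residues.count("G") + residues.count("C")
    total = gc + residues.count("A") + residues.count("T")
    if total == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return 100.0 * gc / total


def percentile_rank(value: float, population: Sequence[float]) -> float:
    """Midpoint-tie percentile of value within population, in [0, 100].

    100 * (#{x < value} + 0.5 * #{x == value}) / N. Stable under duplicates;
    the midpoint rule means a value equal to the whole population sits at 50.
    """
    if len(population) == 0:
        raise ValueError("percentile_rank: empty population")
    below = sum(1 for x in population if x < value)
    ties = sum(1 for x in population if x == value)
    return 100.0 * (below + 0.5 * ties) / len(population)


def cleave_signal(protein: ProteinRecord) -> ProteinRecord:
    """Remove the predicted N-terminal signal peptide, returning the mature protein."""
    if protein.cleavage_index is None:
        raise ValueError(f"{protein.id}: no cleavage_index set")
    mature = protein.residues[protein.cleavage_index:]
    if not mature:
        raise ValueError(f"{protein.id}: cleavage removes the whole sequence")
    return replace(protein, residues=mature, cleavage_index=0)


def aa_composition(proteins: Sequence[ProteinRecord]) -> dict[str, float]:
    """Mean percent of each residue across proteins (mean of per-protein percents).

    Each protein's composition is normalized to 100 over its own length before
    averaging, so short and long proteins weigh equally. All 20 standard
    residues appear in the output (zeros included); X is reported separately
    when present.
    """
    if not proteins:
        raise ValueError("aa_composition: empty protein list")
    letters = list(AA_LETTERS)
    if any("X" in p.residues for p in proteins):
        letters.append("X")
    totals = {aa: 0.0 for aa in letters}
    for p in proteins:
        n = len(p.residues)
        if n == 0:
            raise ValueError(f"{p.id}: empty sequence")
        for aa in letters:
            totals[aa] += 100.0 * p.residues.count(aa) / n
    return {aa: t / len(proteins) for aa, t in totals.items()}


def read_cleavage_table(path: str | Path) -> dict[str, int]:
    """TSV (protein_id, cleavage_index) -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (protein_id, cleavage_index)")
    ids, idx = df.columns[0], df.columns[1]
    return dict(zip(df[ids], df[idx].astype(int)))


def attach_cleavage(
    proteins: Sequence[ProteinRecord], table: dict[str, int]
) -> list[ProteinRecord]:
    return [
        replace(p, cleavage_index=table[p.id]) if p.id in table else p
        for p in proteins
    ]


def secreted_composition(
    proteins: Sequence[ProteinRecord], min_mature_length: int = 60
) -> dict[str, float]:
    """Composition of mature secreted proteins.

    Signal peptides are cleaved in silico; proteins whose mature form is
    shorter than ``min_mature_length`` residues are excluded before averaging
    (the length filter applies to the sequence that is actually averaged).
    """
    cleaved = [cleave_signal(p) for p in proteins if p.cleavage_index is not None]
    kept = [p for p in cleaved if len(p) >= min_mature_length]
    if not kept:
        raise ValueError("no proteins pass the mature-length filter")
    return aa_composition(kept)
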