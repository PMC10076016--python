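"""McDonald-Kreitman tests: site classification, alpha, and Fisher's exact test.

The MK test contrasts within-species polymorphism with between-species fixed
divergence in a 2x2 table split by functional class (nonsynonymous vs
synonymous). Under neutrality Dn/Ds ~ Pn/Ps; an excess of nonsynonymous
divergence indicates adaptive protein evolution, summarized by
alpha = 1 - (Ds*Pn)/(Dn*Ps), the estimated proportion of amino-acid
substitutions fixed by positive selection.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from math import comb

from .dnds import CodonAlignment, VALID_BASES
from .genetic_code import codons_of, is_stop, translate_codon


@dataclass
class PopulationAlignment:
    """An ingroup sample of >=2 aligned in-frame haplotypes plus one outgroup row."""

    ingroup: CodonAlignment
    outgroup_id: str
    outgroup_row: str

    def __post_init__(self):
        self.outgroup_row = self.outgroup_row.upper()
        if len(self.outgroup_row) != len(self.ingroup.rows[0]):
            raise ValueError("outgroup row length differs from ingroup alignment")

    @classmethod
    def from_alignment(cls, aln: CodonAlignment, outgroup_id: str) -> "PopulationAlignment":
        """Split one multi-FASTA alignment into ingroup + the named outgroup."""
        if outgroup_id not in aln.ids:
            raise ValueError(f"outgroup id {outgroup_id!r} not in alignment")
        k = aln.ids.index(outgroup_id)
        ids = [i for j, i in enumerate(aln.ids) if j != k]
        rows = [r for j, r in enumerate(aln.rows) if j != k]
        return cls(CodonAlignment(ids, rows), outgroup_id, aln.rows[k])


@dataclass(frozen=True)
class MKTable:
    Dn: int
    Ds: int
    Pn: int
    Ps: int

    def __post_init__(self):
        if min(self.Dn, self.Ds, self.Pn, self.Ps) < 0:
            raise ValueError("MK counts must be non-negative")


@dataclass(frozen=True)
class MKResult:
    table: MKTable
    alpha: float | None
    p_value: float
    p_flagged: bool = False  # True when a zero margin forced p = 1


def _is_synonymous(context: str, pos: int, base: str) -> bool:
    """Class of substituting `base` at codon position `pos` of `context`.

    A substitution creating a stop codon is treated as nonsynonymous
    (it alters the protein).
    """
    mutant = context[:pos] + base + context[pos + 1:]
    if is_stop(mutant):
        return False
    return translate_codon(mutant) == translate_codon(context)


def classify_sites(popaln: PopulationAlignment) -> MKTable:
    """Build the MK 2x2 from an ingroup sample and one outgroup sequence.

    Per codon column with clean data in every row: each segregating ingroup
    position contributes polymorphisms (one per non-major allele), classified
    by substituting the allele into the ingroup major-allele codon context;
    each monomorphic position differing from the outgroup contributes one
    divergence, classified by substituting the outgroup base into the ingroup
    codon. Positions both polymorphic and divergent count as polymorphism
    only. Major-allele ties break lexicographically (deterministic).
    """
    ing = popaln.ingroup.rows
    out = popaln.outgroup_row
    n_codons = len(out) // 3
    Dn = Ds = Pn = Ps = 0
    analyzable = 0
    for c in range(n_codons):
        lo, hi = 3 * c, 3 * c + 3
        cods = [r[lo:hi] for r in ing]
        outc = out[lo:hi]
        if any(set(cd) - VALID_BASES for cd in cods + [outc]):
            continue
        if any(is_stop(cd) for cd in cods + [outc]):
            continue
        analyzable += 1
        # ingroup major-allele codon context, per position
        major = "".join(
            min(Counter(cd[p] for cd in cods).most_common(),
                key=lambda kv: (-kv[1], kv[0]))[0]
            for p in range(3)
        )
        for p in range(3):
            alleles = Counter(cd[p] for cd in cods)
            if len(alleles) > 1:
                for allele in sorted(alleles):
                    if allele == major[p]:
                        continue
                    if _is_synonymous(major, p, allele):
                        Ps += 1
                    else:
                        Pn += 1
            elif major[p] != outc[p]:
                if _is_synonymous(major, p, outc[p]):
                    Ds += 1
                else:
                    Dn += 1
    if analyzable == 0:
        raise ValueError("no analyzable codons (all contain gaps, N, or stops)")
    return MKTable(Dn=Dn, Ds=Ds, Pn=Pn, Ps=Ps)


def mk_alpha(table: MKTable) -> float:
    """alpha = 1 - (Ds*Pn)/(Dn*Ps); requires Dn > 0 and Ps > 0."""
    if table.Dn == 0 or table.Ps == 0:
        raise ValueError(f"alpha undefined for table {table} (Dn=0 or Ps=0)")
    return 1.0 - (table.Ds * table.Pn) / (table.Dn * table.Ps)


def fisher_exact_2x2(table: MKTable) -> tuple[float, bool]:
    """Two-sided Fisher's exact p for [[Dn, Ds], [Pn, Ps]].

    Exact rational hypergeometric enumeration with the probability-mass rule:
    sum P(k) over all tables with the observed margins whose probability is
    <= that of the observed table, with 1e-7 relative slack on the comparison.
    A zero row or column margin gives p = 1, flagged.
    """
    a, b, c, d = table.Dn, table.Ds, table.Pn, table.Ps
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if 0 in (r1, r2, c1, c2):
        return 1.0, True
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    threshold = p_obs * (Fraction(10**7 + 1, 10**7))
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if p_k <= threshold:
            total += p_k
    return float(min(total, Fraction(1))), False


def mk_test(popaln: PopulationAlignment) -> MKResult:
    """Classify sites, compute alpha (None when undefined) and the Fisher p."""
    table = classify_sites(popaln)
    try:
        alpha = mk_alpha(table)
    except ValueError:
        alpha = None
    p, flagged = fisher_exact_2x2(table)
    return MKResult(table=table, alpha=alpha, p_value=p, p_flagged=flagged)
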