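"""GC content and mature-protein amino-acid composition on synthetic genes.

Generates 300 random coding sequences, reports each gene's GC content and the
percentile of the most GC-rich gene, then translates the sequences into
proteins, assigns synthetic signal-peptide cleavage indices, cleaves them in
silico, and computes the mean amino-acid composition of the mature proteins
(minimum mature length 60 residues).

Writes results/gc_content.tsv and results/aa_composition.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from mozevo.composition import (
    NucleotideSequence,
    ProteinRecord,
    gc_content,
    percentile_rank,
    secreted_composition,
)
from mozevo.genetic_code import SENSE_CODONS, translate_codon

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 17
rng = np.random.default_rng(seed)
out = Path("results")
out.mkdir(exist_ok=True)

genes = []
for g in range(300):
    n_codons = int(rng.integers(80, 300))
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    genes.append(NucleotideSequence(f"gene{g:03d}", "".join(codons)))

gc = pd.DataFrame(
    [(s.id, gc_content(s)) for s in genes], columns=["gene", "gc_percent"]
)
gc.to_csv(out / "gc_content.tsv", sep="\t", index=False)
top = gc.loc[gc.gc_percent.idxmax()]
print(f"GC content: mean {gc.gc_percent.mean():.1f}%, most GC-rich gene "
      f"{top.gene} at {top.gc_percent:.1f}% "
      f"({percentile_rank(top.gc_percent, gc.gc_percent.values):.1f}th percentile)")

proteins = []
for s in genes:
    aas = "".join(
        translate_codon(s.residues[i:i + 3]) for i in range(0, len(s.residues), 3)
    )
    cleave = int(rng.integers(15, 30))  # synthetic signal-peptide length
    proteins.append(ProteinRecord(s.id, aas, cleavage_index=cleave))

comp = secreted_composition(proteins, min_mature_length=60)
pd.DataFrame(sorted(comp.items()), columns=["residue", "mean_percent"]).to_csv(
    out / "aa_composition.tsv", sep="\t", index=False
)
top3 = sorted(comp.items(), key=lambda kv: -kv[1])[:3]
print("mature-protein composition (mean percent), top residues: "
      + ", ".join(f"{aa} {pct:.1f}%" for aa, pct in top3))
print(f"composition sums to {sum(comp.values()):.6f}% -> results/aa_composition.tsv")
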