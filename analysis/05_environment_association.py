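"""Gene-environment association: the harmonic-mean-p correlation test with
percentile ranking and the variant-count-matched permutation test.

Correlates every variant's per-population alternate-allele frequency with each
ecological variable (two-tailed Pearson), combines per-gene variant p-values
with the harmonic mean p-value, ranks genes by -log10(combined p), and runs
the permutation test (B=1000 draws of equally many variants from the
genome-wide pool; statistic = mean |r|) for the planted signal genes.

Writes results/variant_correlations.tsv and results/gene_association.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from mozevo.association import associate_genes, correlate_variants, read_eco_table
from mozevo.simulate import SimConfig, simulate_study
from mozevo.variants import (
    PopulationPanel,
    filter_variants,
    frequency_matrix,
    read_vcf,
    split_multiallelic,
)

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 17
data = Path("results/data")
if not (data / "variants.vcf").exists():
    simulate_study(SimConfig(seed=seed), data)

records, _ = read_vcf(data / "variants.vcf")
records = [r for rec in records for r in split_multiallelic(rec)]
panel = PopulationPanel.from_tsv(data / "panel.tsv")
survivors, _ = filter_variants(records, panel)
freq = frequency_matrix(survivors, panel)
eco = read_eco_table(data / "eco.tsv")

# variant ids in the VCF are positional; map them back to genes by interval
from mozevo.variants import assign_genes, read_gene_intervals

gene_of_variant = assign_genes(survivors, read_gene_intervals(data / "gene_intervals.tsv"))

truth = pd.read_csv(data / "truth.tsv", sep="\t")
signal = list(truth[truth.is_signal]["gene_id"])

vc, skipped = correlate_variants(freq, eco)
gdf = associate_genes(vc, gene_of_variant, B=1000, seed=seed, perm_genes=signal)
vc.to_csv("results/variant_correlations.tsv", sep="\t", index=False)
gdf.to_csv("results/gene_association.tsv", sep="\t", index=False, na_rep="NA")

sub = gdf[(gdf.variable == "var1") & (gdf.gene_id.isin(signal))]
print(f"{len(vc)} variant x variable correlations ({skipped} undefined skipped)")
print(f"signal genes on the causal variable (var1): "
      f"{(sub.percentile >= 90).sum()}/{len(sub)} in the top decile, "
      f"{(sub.perm_p < 0.05).sum()}/{len(sub)} with permutation p < 0.05")
null_top = gdf[(gdf.variable == "var1") & (~gdf.gene_id.isin(signal))].percentile.max()
print(f"highest percentile among null genes: {null_top:.1f}")
print("tables -> results/variant_correlations.tsv, results/gene_association.tsv")
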