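"""Generate the synthetic study data used by the downstream analyses.

Writes, under results/data/: a VCF of diploid genotypes for 200 genes x 20
variants across 25 populations (20 individuals each), the population panel,
an ecological-variable table (3 correlated standard-normal variables), gene
intervals, and the planted truth labels (10 signal genes with a logit-scale
environment effect of 1.5 on variable var1).

Run from the repository root: python analysis/01_simulate_data.py [seed]
"""

import sys
from pathlib import Path

from mozevo.simulate import SimConfig, simulate_study

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 17
out = Path("results/data")
cfg = SimConfig(seed=seed)
paths = simulate_study(cfg, out)

print(f"simulated study (seed={seed}): {cfg.n_genes} genes x "
      f"{cfg.variants_per_gene} variants, {cfg.n_pops} populations")
for key, path in paths.items():
    print(f"  {key:10s} {path}")
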