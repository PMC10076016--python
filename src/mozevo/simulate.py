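"""Synthetic data generators for every stage of the pipeline.

The generators plant the statistical structure each analysis assumes rather
than simulating population-genetic processes: coding pairs diverge at a
controlled nonsynonymous/synonymous rate ratio, population alignments carry a
planted polymorphism/divergence table, and per-population allele frequencies
follow a logistic model in an ecological covariate for "signal" genes with
binomial sampling noise. Every generator is a pure function of its
configuration: the same seed yields identical output bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dnds import CodonAlignment
from .genetic_code import BASES, SENSE_CODONS, is_stop, translate_codon
from .mk import MKTable, PopulationAlignment
from .variants import PopulationPanel, VariantRecord


@dataclass
class SimConfig:
    """Study conditions for the generators (defaults mirror the study design:
    25 populations of ~20 sampled diploid genomes each)."""

    seed: int
    # coding-pair divergence
    n_codons: int = 2000
    omega_target: float = 0.2
    divergence: float = 0.05  # target proportion of differing nucleotide sites
    # population alignment (MK)
    n_samples: int = 20
    n_polymorphisms: int = 150
    n_divergences: int = 150
    prop_nonsyn_poly: float = 0.5
    prop_nonsyn_div: float = 0.5
    # environment association
    n_pops: int = 25
    n_variables: int = 3
    eco_corr: float = 0.5  # shared-latent loading mimicking correlated Bioclim variables
    n_genes: int = 200
    variants_per_gene: int = 20
    frac_signal: float = 0.05
    beta_effect: float = 1.5
    mean_AN: int = 40  # called alleles per population (2 x 20 diploids)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("an explicit integer seed is required")
        if self.omega_target < 0:
            raise ValueError("omega_target must be >= 0")
        if self.mean_AN < 2:
            raise ValueError("mean_AN must be >= 2")
        for name in ("n_codons", "n_samples", "n_pops", "n_genes",
                     "variants_per_gene", "n_variables"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("prop_nonsyn_poly", "prop_nonsyn_div", "frac_signal", "divergence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class TruthLabels:
    """Ground truth of a simulated dataset, for test harnesses."""

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_of_variant: dict[str, str] = field(default_factory=dict)
    expected_mk: MKTable | None = None
    omega_target: float | None = None

    def to_tsv(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *tags]))


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return [SENSE_CODONS[i] for i in idx]


def simulate_coding_pair(cfg: SimConfig) -> tuple[CodonAlignment, TruthLabels]:
    """An ancestral/derived CDS pair diverged at rate ratio omega_target.

    Single-nucleotide changes are proposed uniformly; synonymous proposals are
    accepted with probability min(1, 1/omega), nonsynonymous with
    min(1, omega), so the realized nonsynonymous/synonymous substitution-rate
    ratio equals omega for any omega >= 0. Proposals creating stop codons are
    rejected. Mutation continues until the target proportion of nucleotide
    sites differ from the ancestor (default 5%).
    """
    if cfg.n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    rng = _rng(cfg.seed, 1)
    omega = cfg.omega_target
    p_nonsyn = min(1.0, omega)
    p_syn = 1.0 if omega <= 1.0 else min(1.0, 1.0 / omega)
    ancestral = _random_cds(rng, cfg.n_codons)
    derived = list(ancestral)
    L = 3 * cfg.n_codons
    target = max(1, math.ceil(cfg.divergence * L))
    n_diff = 0
    while n_diff < target:
        pos = int(rng.integers(0, L))
        ci, off = divmod(pos, 3)
        codon = derived[ci]
        others = [b for b in BASES if b != codon[off]]
        base = others[int(rng.integers(0, 3))]
        mutant = codon[:off] + base + codon[off + 1:]
        if is_stop(mutant):
            continue
        syn = translate_codon(mutant) == translate_codon(codon)
        if rng.random() >= (p_syn if syn else p_nonsyn):
            continue
        was_diff = derived[ci][off] != ancestral[ci][off]
        derived[ci] = mutant
        is_diff = mutant[off] != ancestral[ci][off]
        n_diff += int(is_diff) - int(was_diff)
    aln = CodonAlignment(
        ids=["ancestral", "derived"], rows=["".join(ancestral), "".join(derived)]
    )
    return aln, TruthLabels(omega_target=omega)


def _mutation_candidates(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    """(position, base) single-nucleotide changes of the requested class that do
    not create a stop codon."""
    out = []
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if is_stop(mut):
                continue
            if (translate_codon(mut) == translate_codon(codon)) == synonymous:
                out.append((pos, b))
    return out


def simulate_population_cds(
    cfg: SimConfig, exact_table: MKTable | None = None
) -> tuple[PopulationAlignment, TruthLabels]:
    """An ingroup sample plus outgroup with a planted MK structure.

    ``n_divergences`` fixed differences versus the outgroup and
    ``n_polymorphisms`` segregating sites (derived-allele count uniform on
    1..n_samples-1) are planted at distinct codons; each event is
    nonsynonymous with the configured class proportion (Bernoulli), or with
    the exact counts of ``exact_table`` when given. The expected MK table
    equals the configured counts; with ``exact_table`` recovery is exact.
    """
    if cfg.n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = _rng(cfg.seed, 2)
    if exact_table is not None:
        n_div = exact_table.Dn + exact_table.Ds
        n_poly = exact_table.Pn + exact_table.Ps
        div_classes = [False] * exact_table.Dn + [True] * exact_table.Ds
        poly_classes = [False] * exact_table.Pn + [True] * exact_table.Ps
        rng.shuffle(div_classes)
        rng.shuffle(poly_classes)
    else:
        n_div, n_poly = cfg.n_divergences, cfg.n_polymorphisms
        div_classes = list(rng.random(n_div) >= cfg.prop_nonsyn_div)
        poly_classes = list(rng.random(n_poly) >= cfg.prop_nonsyn_poly)
    if n_div + n_poly > cfg.n_codons:
        raise ValueError(
            f"{n_div + n_poly} events exceed {cfg.n_codons} available codons"
        )
    cds = _random_cds(rng, cfg.n_codons)
    codon_idx = rng.permutation(cfg.n_codons)
    events = [("D", synonymous) for synonymous in div_classes] + [
        ("P", synonymous) for synonymous in poly_classes
    ]
    ingroup = [list(cds) for _ in range(cfg.n_samples)]
    outgroup = list(cds)
    dn = ds = pn = ps = 0
    for (kind, synonymous), ci in zip(events, codon_idx):
        ci = int(ci)
        cands = _mutation_candidates(cds[ci], synonymous)
        while not cands:  # redraw the ancestral codon until the class is available
            new = SENSE_CODONS[int(rng.integers(0, len(SENSE_CODONS)))]
            cds[ci] = new
            for row in ingroup:
                row[ci] = new
            outgroup[ci] = new
            cands = _mutation_candidates(new, synonymous)
        pos, base = cands[int(rng.integers(0, len(cands)))]
        mutant = cds[ci][:pos] + base + cds[ci][pos + 1:]
        if kind == "D":
            outgroup[ci] = mutant
            if synonymous:
                ds += 1
            else:
                dn += 1
        else:
            u = int(rng.integers(1, cfg.n_samples))
            carriers = rng.choice(cfg.n_samples, size=u, replace=False)
            for s in carriers:
                ingroup[int(s)][ci] = mutant
            if synonymous:
                ps += 1
            else:
                pn += 1
    aln = CodonAlignment(
        ids=[f"hap{i:03d}" for i in range(cfg.n_samples)],
        rows=["".join(r) for r in ingroup],
    )
    popaln = PopulationAlignment(
        ingroup=aln, outgroup_id="outgroup", outgroup_row="".join(outgroup)
    )
    return popaln, TruthLabels(expected_mk=MKTable(Dn=dn, Ds=ds, Pn=pn, Ps=ps))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_env_dataset(cfg: SimConfig):
    """Allele frequencies with a planted environment association.

    Ecological variables are standard normal per population, optionally
    sharing a latent factor (loading ``eco_corr``) to mimic correlated
    Bioclim variables. For signal genes every variant has
    logit(AF_p) = a + beta_effect * z_p with a ~ Normal(-1, 0.5) and z_p the
    first variable's value; null genes have beta = 0. Observed counts are
    AC ~ Binomial(mean_AN, AF_p), AF = AC/AN.

    Returns (FrequencyMatrix, eco DataFrame, TruthLabels). Per-gene random
    streams are independent, so growing n_genes leaves earlier genes unchanged.
    """
    from .variants import FrequencyMatrix

    if cfg.n_pops < 5:
        raise ValueError("n_pops must be >= 5")
    pops = [f"pop{i + 1:02d}" for i in range(cfg.n_pops)]
    eco_rng = _rng(cfg.seed, 3)
    latent = eco_rng.standard_normal(cfg.n_pops)
    rho = cfg.eco_corr
    eco = pd.DataFrame(
        {
            f"var{j + 1}": rho * latent
            + math.sqrt(max(0.0, 1 - rho**2)) * eco_rng.standard_normal(cfg.n_pops)
            for j in range(cfg.n_variables)
        },
        index=pd.Index(pops, name="population_id"),
    )
    z = eco["var1"].values
    n_signal = int(round(cfg.frac_signal * cfg.n_genes))
    gene_rows, vids, ac_rows = [], [], []
    gene_of_variant: dict[str, str] = {}
    for g in range(cfg.n_genes):
        gene = f"gene{g + 1:03d}"
        is_signal = g < n_signal
        beta = cfg.beta_effect if is_signal else 0.0
        grng = _rng(cfg.seed, 4, g)
        for v in range(cfg.variants_per_gene):
            a = grng.normal(-1.0, 0.5)
            af = _sigmoid(a + beta * z)
            ac = grng.binomial(cfg.mean_AN, af)
            vid = f"{gene}:v{v + 1:03d}"
            vids.append(vid)
            ac_rows.append(ac)
            gene_of_variant[vid] = gene
        gene_rows.append((gene, is_signal, beta))
    ac = pd.DataFrame(np.asarray(ac_rows, dtype=float), index=vids, columns=pops)
    an = pd.DataFrame(
        np.full((len(vids), cfg.n_pops), float(cfg.mean_AN)), index=vids, columns=pops
    )
    freq = FrequencyMatrix(AF=ac / an, AC=ac, AN=an)
    labels = TruthLabels(
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "is_signal", "beta"]),
        gene_of_variant=gene_of_variant,
    )
    return freq, eco, labels


def write_toy_vcf(
    records: list[VariantRecord], panel: PopulationPanel, path: str | Path
) -> None:
    """Write records as a plain-text VCF 4.2 with per-individual GT fields."""
    individuals = [i for pop in panel.populations.values() for i in pop]
    chroms = sorted({r.chrom for r in records})
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(individuals)
            + "\n"
        )
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            alt = ",".join(rec.alts) if rec.alts else "."
            qual = "." if math.isnan(rec.qual) else f"{rec.qual:g}"
            gts = []
            for ind in individuals:
                a, b = rec.genotypes.get(ind, (None, None))
                gts.append(
                    f"{'.' if a is None else a}/{'.' if b is None else b}"
                )
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{alt}\t{qual}\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def toy_filter_panel() -> PopulationPanel:
    """Two populations of five diploid individuals each."""
    mapping = {f"A{i}": "popA" for i in range(1, 6)}
    mapping.update({f"B{i}": "popB" for i in range(1, 6)})
    return PopulationPanel(mapping)


def toy_filter_records() -> list[VariantRecord]:
    """Six biallelic records exercising every filter rule.

    Two fail the quality filter, one is fully missing in popA (over the 90%
    per-population missingness bound), one has alternate-allele frequency
    below 5% in every population, and two clean records survive.
    """
    panel = toy_filter_panel()
    inds = [i for pop in panel.populations.values() for i in pop]

    def gts(pattern: dict | None = None, default=(0, 1)):
        base = {i: default for i in inds}
        if pattern:
            base.update(pattern)
        return base

    miss = (None, None)
    return [
        VariantRecord("chr1", 100, "A", ("G",), 10.0, gts()),  # low qual
        VariantRecord("chr1", 200, "C", ("T",), 29.9, gts()),  # low qual
        VariantRecord(  # popA entirely missing
            "chr1", 300, "G", ("A",), 50.0,
            gts({f"A{i}": miss for i in range(1, 6)}),
        ),
        VariantRecord(  # alt absent everywhere -> AF < 5% in all populations
            "chr1", 400, "T", ("C",), 50.0, gts(default=(0, 0))
        ),
        VariantRecord("chr1", 500, "A", ("T",), 45.0, gts()),  # clean
        VariantRecord(  # clean, mixed genotypes
            "chr1", 600, "G", ("C",), 60.0,
            gts({"A1": (1, 1), "B1": miss, "B2": (0, 0)}),
        ),
    ]


def simulate_study(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic study: VCF with per-individual genotypes,
    population panel, ecological table, gene intervals, and truth labels.

    Genotypes are drawn per individual from the per-population allele
    frequencies of :func:`simulate_env_dataset` (two Bernoulli(AF) alleles),
    so the VCF -> frequencies -> association chain reproduces the planted
    structure. Gene g occupies positions [g*10000+1, g*10000+variants*10+10]
    on chrom "2"; variants sit 10 bp apart.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    freq, eco, labels = simulate_env_dataset(cfg)
    n_ind = cfg.mean_AN // 2
    panel_map: dict[str, str] = {}
    for p, pop in enumerate(freq.AF.columns):
        for i in range(n_ind):
            panel_map[f"{pop}_ind{i + 1:02d}"] = pop
    panel = PopulationPanel(panel_map)
    grng = _rng(cfg.seed, 5)
    records = []
    gene_ids = sorted({g for g in labels.gene_of_variant.values()})
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    intervals = []
    for g in gene_ids:
        start = gene_index[g] * 10000 + 1
        end = start + cfg.variants_per_gene * 10 + 9
        intervals.append((g, "2", start, end))
    pos_in_gene: dict[str, int] = {g: 0 for g in gene_ids}
    for vid in freq.AF.index:
        gene = labels.gene_of_variant[vid]
        pos_in_gene[gene] += 1
        pos = gene_index[gene] * 10000 + pos_in_gene[gene] * 10
        gts = {}
        for pop in freq.AF.columns:
            af = freq.AF.loc[vid, pop]
            for ind in panel.populations[pop]:
                gts[ind] = tuple(int(a) for a in grng.random(2) < af)
        records.append(
            VariantRecord(
                chrom="2", pos=pos, ref="A", alts=("T",),
                qual=float(grng.integers(35, 100)), genotypes=gts,
            )
        )
    paths = {
        "vcf": out / "variants.vcf",
        "panel": out / "panel.tsv",
        "eco": out / "eco.tsv",
        "intervals": out / "gene_intervals.tsv",
        "truth": out / "truth.tsv",
    }
    write_toy_vcf(records, panel, paths["vcf"])
    pd.DataFrame(
        [(i, p) for i, p in panel_map.items()],
        columns=["individual_id", "population_id"],
    ).to_csv(paths["panel"], sep="\t", index=False)
    eco.to_csv(paths["eco"], sep="\t", na_rep="NA")
    pd.DataFrame(
        intervals, columns=["gene_id", "chrom", "start_1based", "end_1based"]
    ).to_csv(paths["intervals"], sep="\t", index=False)
    labels.to_tsv(paths["truth"])
    return paths
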