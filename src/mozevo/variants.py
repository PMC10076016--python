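"""Variant-call handling: VCF parsing, multiallelic splitting, per-population
alternate-allele frequencies, and the population-genetic filters.

The module consumes called genotypes (VCF 4.x); alignment and variant calling
are upstream concerns. Frequencies are AC/AN per population, where AN counts
called alleles and AC alternate alleles, so half-missing diploid calls
contribute their one called allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

Genotype = tuple[int | None, int | None]


@dataclass
class PopulationPanel:
    """Mapping individual -> population, with a stable per-population roster."""

    individual_to_population: dict[str, str]
    populations: dict[str, list[str]] = field(init=False)

    def __post_init__(self):
        if not self.individual_to_population:
            raise ValueError("empty population panel")
        pops: dict[str, list[str]] = {}
        for ind, pop in self.individual_to_population.items():
            pops.setdefault(pop, []).append(ind)
        self.populations = pops

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationPanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected columns (individual_id, population_id)")
        ind, pop = df.columns[0], df.columns[1]
        dup = df[ind][df[ind].duplicated()]
        if not dup.empty:
            raise ValueError(f"{path}: duplicate individuals {sorted(dup)}")
        return cls(dict(zip(df[ind], df[pop])))


@dataclass
class VariantRecord:
    """One VCF site. Genotype alleles are indices (0 = ref, j = alts[j-1]),
    None = missing; diploid only."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    genotypes: dict[str, Genotype]

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >=1, got {self.pos}")
        for ind, gt in self.genotypes.items():
            if len(gt) != 2:
                raise ValueError(
                    f"{self.chrom}:{self.pos} {ind}: only diploid calls are "
                    f"supported, got ploidy {len(gt)}"
                )

    @property
    def variant_id(self) -> str:
        alt = self.alts[0] if len(self.alts) == 1 else ",".join(self.alts)
        return f"{self.chrom}:{self.pos}:{self.ref}:{alt}"

    @property
    def alt(self) -> str:
        if len(self.alts) != 1:
            raise ValueError("record is not biallelic; split it first")
        return self.alts[0]


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF (plain or gzipped) into records; returns (records, sample ids)."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            gts: dict[str, Genotype] = {}
            for s in samples:
                gt = rec.samples[s].get("GT", (None, None))
                if gt is None:
                    gt = (None, None)
                gts[s] = tuple(gt)  # type: ignore[assignment]
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    qual=float(rec.qual) if rec.qual is not None else math.nan,
                    genotypes=gts,
                )
            )
    return records, samples


def split_multiallelic(record: VariantRecord) -> list[VariantRecord]:
    """One biallelic record per alternate allele (bcftools norm -m - semantics).

    In the record for alt j, genotype alleles other than ref or alt j become
    missing; qual is copied.
    """
    if len(record.alts) == 0:
        return []
    if len(record.alts) == 1:
        return [record]
    out = []
    for j, alt in enumerate(record.alts, start=1):
        gts = {
            ind: tuple(
                (0 if a == 0 else 1 if a == j else None) if a is not None else None
                for a in gt
            )
            for ind, gt in record.genotypes.items()
        }
        out.append(replace(record, alts=(alt,), genotypes=gts))  # type: ignore[arg-type]
    return out


def population_allele_frequency(
    record: VariantRecord, panel: PopulationPanel
) -> dict[str, tuple[int, int, float]]:
    """Per population: (AC, AN, AF) with AF = AC/AN, NaN when AN = 0."""
    missing_panel = [i for i in record.genotypes if i not in panel.individual_to_population]
    if missing_panel:
        raise ValueError(
            f"{record.variant_id}: individuals absent from panel: {sorted(missing_panel)}"
        )
    out = {}
    for pop, members in panel.populations.items():
        ac = an = 0
        for ind in members:
            for allele in record.genotypes.get(ind, (None, None)):
                if allele is not None:
                    an += 1
                    ac += allele
        out[pop] = (ac, an, ac / an if an > 0 else math.nan)
    return out


@dataclass
class FrequencyMatrix:
    """Variants x populations alternate-allele frequencies with AC/AN backing."""

    AF: pd.DataFrame  # NaN where AN == 0
    AC: pd.DataFrame
    AN: pd.DataFrame

    @property
    def variant_ids(self) -> list[str]:
        return list(self.AF.index)

    @property
    def population_ids(self) -> list[str]:
        return list(self.AF.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.AF.to_csv(path, sep="\t", index_label="variant_id", na_rep="NA")


def frequency_matrix(
    records: list[VariantRecord], panel: PopulationPanel
) -> FrequencyMatrix:
    pops = list(panel.populations)
    ids, ac_rows, an_rows = [], [], []
    for rec in records:
        paf = population_allele_frequency(rec, panel)
        ids.append(rec.variant_id)
        ac_rows.append([paf[p][0] for p in pops])
        an_rows.append([paf[p][1] for p in pops])
    ac = pd.DataFrame(ac_rows, index=ids, columns=pops, dtype=float)
    an = pd.DataFrame(an_rows, index=ids, columns=pops, dtype=float)
    af = ac / an.where(an > 0, np.nan)
    return FrequencyMatrix(AF=af, AC=ac, AN=an)


def filter_variants(
    records: list[VariantRecord],
    panel: PopulationPanel,
    missing_frac: float = 0.9,
    qual_min: float = 30.0,
    af_min: float = 0.05,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the study's post-calling filters to biallelic records.

    A record is dropped when (a) in ANY population the fraction of individuals
    with a fully missing genotype exceeds ``missing_frac`` (strict), or (b)
    qual < ``qual_min``, or (c) its alternate-allele frequency is below
    ``af_min`` in EVERY population with a defined frequency (strict "less
    than", so AF exactly at the threshold is kept). Survivors keep input
    order; the tally counts the first matching reason per dropped record.
    """
    survivors: list[VariantRecord] = []
    tally = {"missing": 0, "qual": 0, "af": 0}
    for rec in records:
        if len(rec.alts) != 1:
            raise ValueError(f"{rec.variant_id}: split multiallelic records first")
        over_missing = False
        for pop, members in panel.populations.items():
            if not members:
                continue
            n_missing = sum(
                1
                for ind in members
                if all(a is None for a in rec.genotypes.get(ind, (None, None)))
            )
            if n_missing / len(members) > missing_frac:
                over_missing = True
                break
        if over_missing:
            tally["missing"] += 1
            continue
        if rec.qual < qual_min:  # NaN qual compares False -> retained
            tally["qual"] += 1
            continue
        paf = population_allele_frequency(rec, panel)
        afs = [af for _, _, af in paf.values() if not math.isnan(af)]
        if afs and all(af < af_min for af in afs):
            tally["af"] += 1
            continue
        survivors.append(rec)
    return survivors, tally


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """Gene spans TSV (gene_id, chrom, start_1based, end_1based), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "start_1based", "end_1based"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return df


def assign_genes(
    records: list[VariantRecord], intervals: pd.DataFrame
) -> dict[str, str]:
    """Map variant_id -> gene_id by 1-based inclusive span containment.

    A variant inside several (overlapping) genes is assigned to the first
    interval in file order; variants outside every gene are omitted.
    """
    out: dict[str, str] = {}
    for rec in records:
        hit = intervals[
            (intervals["chrom"] == rec.chrom)
            & (intervals["start_1based"] <= rec.pos)
            & (rec.pos <= intervals["end_1based"])
        ]
        if not hit.empty:
            out[rec.variant_id] = str(hit.iloc[0]["gene_id"])
    return out
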