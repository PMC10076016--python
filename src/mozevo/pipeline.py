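"""Pipeline orchestration: run the variant -> frequency -> filter ->
association chain plus the sequence analyses from a single configuration,
echoing thresholds into every output and writing a run report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .association import associate_genes, correlate_variants, read_eco_table
from .composition import (
    attach_cleavage,
    gc_content,
    read_cleavage_table,
    read_fasta,
    secreted_composition,
)
from .dnds import CodonAlignment, pairwise_dnds, rank_dnds, sliding_window_dnds
from .mk import PopulationAlignment, mk_test
from .variants import (
    PopulationPanel,
    assign_genes,
    filter_variants,
    frequency_matrix,
    read_gene_intervals,
    read_vcf,
    split_multiallelic,
)

log = logging.getLogger("mozevo")


@dataclass
class RunConfig:
    out_dir: str
    seed: int | None = None
    # association chain inputs
    vcf: str | None = None
    panel: str | None = None
    eco: str | None = None
    gene_intervals: str | None = None
    # sequence inputs
    dnds_fastas: dict[str, str] = field(default_factory=dict)  # gene -> aligned FASTA
    mk_fastas: dict[str, str] = field(default_factory=dict)
    outgroup_id: str | None = None
    protein_fasta: str | None = None
    cleavage_tsv: str | None = None
    nucleotide_fasta: str | None = None
    tpm_table: str | None = None
    # thresholds
    missing_frac: float = 0.9
    qual_min: float = 30.0
    af_min: float = 0.05
    tpm_min: float = 2.0
    window_codons: int = 34
    step_codons: int = 31
    permutations: int = 0
    perm_genes: list[str] | None = None
    stages: list[str] = field(default_factory=list)  # empty = all applicable

    def validate(self) -> None:
        for name in ("vcf", "panel", "eco", "gene_intervals", "protein_fasta",
                     "cleavage_tsv", "nucleotide_fasta", "tpm_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p}")
        for mapping in (self.dnds_fastas, self.mk_fastas):
            for gene, p in mapping.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"{gene}: no such file {p}")
        if self.permutations > 0 and self.seed is None:
            raise ValueError("a seed is required when permutations > 0")


@dataclass
class RunReport:
    version: str
    config: dict
    stage_counts: dict[str, int] = field(default_factory=dict)
    filter_tally: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    failed_stage: str | None = None


def subset_by_expression(
    genes: list[str], tpm_table: pd.DataFrame, tpm_min: float = 2.0
) -> tuple[list[str], int]:
    """Genes whose maximum TPM across conditions is strictly above tpm_min.

    ``tpm_table`` is indexed by gene id with one column per condition. Genes
    absent from the table are excluded and counted, not an error.
    Returns (kept genes in input order, number absent from the table).
    """
    absent = [g for g in genes if g not in tpm_table.index]
    kept = [
        g
        for g in genes
        if g in tpm_table.index and tpm_table.loc[g].max() > tpm_min
    ]
    return kept, len(absent)


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mozevo {__version__}\n")
        fh.write(
            f"# thresholds: missing_frac={cfg.missing_frac} qual_min={cfg.qual_min} "
            f"af_min={cfg.af_min} tpm_min={cfg.tpm_min} "
            f"window_codons={cfg.window_codons} step_codons={cfg.step_codons} "
            f"permutations={cfg.permutations} seed={cfg.seed}\n"
        )
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order and write all outputs.

    Deterministic stages reproduce byte-identical outputs on rerun; stochastic
    stages reproduce given the same seed. A stage failure aborts with the
    stage name; partial outputs are kept and marked FAILED in the report.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config=asdict(cfg))
    want = set(cfg.stages)

    def enabled(stage: str, *inputs) -> bool:
        if want and stage not in want:
            return False
        return all(x for x in inputs)

    stage = "start"
    try:
        freq = gene_of_variant = None
        if enabled("freqs", cfg.vcf, cfg.panel):
            stage = "freqs"
            t0 = time.perf_counter()
            records, _ = read_vcf(cfg.vcf)
            records = [r for rec in records for r in split_multiallelic(rec)]
            panel = PopulationPanel.from_tsv(cfg.panel)
            survivors, tally = filter_variants(
                records, panel, cfg.missing_frac, cfg.qual_min, cfg.af_min
            )
            freq = frequency_matrix(survivors, panel)
            path = out / "allele_frequencies.tsv"
            _write_tsv(freq.AF, path, cfg, index=True)
            report.outputs["allele_frequencies"] = str(path)
            report.stage_counts["variants_in"] = len(records)
            report.stage_counts["variants_kept"] = len(survivors)
            report.filter_tally = tally
            report.timings_s[stage] = time.perf_counter() - t0
            log.info("freqs: %d/%d variants kept %s", len(survivors), len(records), tally)
            if cfg.gene_intervals:
                gene_of_variant = assign_genes(
                    survivors, read_gene_intervals(cfg.gene_intervals)
                )
        if enabled("assoc", freq is not None, cfg.eco, gene_of_variant):
            stage = "assoc"
            t0 = time.perf_counter()
            eco = read_eco_table(cfg.eco)
            vc, skipped = correlate_variants(freq, eco)
            gene_df = associate_genes(
                vc,
                gene_of_variant,
                B=cfg.permutations,
                seed=cfg.seed,
                perm_genes=cfg.perm_genes,
            )
            vpath, gpath = out / "variant_correlations.tsv", out / "gene_association.tsv"
            _write_tsv(vc, vpath, cfg)
            _write_tsv(gene_df, gpath, cfg)
            report.outputs["variant_correlations"] = str(vpath)
            report.outputs["gene_association"] = str(gpath)
            report.stage_counts["variant_correlations"] = len(vc)
            report.stage_counts["correlations_skipped"] = skipped
            report.stage_counts["gene_association_rows"] = len(gene_df)
            report.timings_s[stage] = time.perf_counter() - t0
            log.info("assoc: %d correlations, %d gene rows", len(vc), len(gene_df))
        if enabled("dnds", cfg.dnds_fastas):
            stage = "dnds"
            t0 = time.perf_counter()
            rows, windows = [], []
            for gene, path in sorted(cfg.dnds_fastas.items()):
                recs = read_fasta(path)
                aln = CodonAlignment([r.id for r in recs], [r.residues for r in recs])
                r = pairwise_dnds(aln)
                rows.append(
                    (gene, r.S, r.N, r.Sd, r.Nd, r.dS, r.dN, r.omega, r.status, r.method)
                )
                if aln.n_codons >= cfg.window_codons:
                    track = sliding_window_dnds(
                        aln, window_codons=cfg.window_codons, step_codons=cfg.step_codons
                    )
                    for s, e, wr in track.windows:
                        windows.append((gene, s, e, wr.dN, wr.dS, wr.omega))
            df = pd.DataFrame(
                rows,
                columns=["gene", "S", "N", "Sd", "Nd", "dS", "dN", "omega", "status", "method"],
            )
            omegas = dict(zip(df["gene"], df["omega"]))
            if sum(w is not None for w in omegas.values()) >= 2:
                pct, _ = rank_dnds(omegas)
                df["percentile"] = df["gene"].map(pct)
            path = out / "dnds.tsv"
            _write_tsv(df, path, cfg)
            report.outputs["dnds"] = str(path)
            report.stage_counts["dnds_genes"] = len(df)
            if windows:
                wdf = pd.DataFrame(
                    windows, columns=["gene", "start_codon", "end_codon", "dN", "dS", "omega"]
                )
                wpath = out / "dnds_windows.tsv"
                _write_tsv(wdf, wpath, cfg)
                report.outputs["dnds_windows"] = str(wpath)
                report.stage_counts["dnds_windows"] = len(wdf)
            report.timings_s[stage] = time.perf_counter() - t0
        if enabled("mk", cfg.mk_fastas, cfg.outgroup_id):
            stage = "mk"
            t0 = time.perf_counter()
            rows = []
            for gene, path in sorted(cfg.mk_fastas.items()):
                recs = read_fasta(path)
                aln = CodonAlignment([r.id for r in recs], [r.residues for r in recs])
                res = mk_test(PopulationAlignment.from_alignment(aln, cfg.outgroup_id))
                t = res.table
                rows.append((gene, t.Dn, t.Ds, t.Pn, t.Ps, res.alpha, res.p_value))
            df = pd.DataFrame(
                rows, columns=["gene", "Dn", "Ds", "Pn", "Ps", "alpha", "p_value"]
            )
            path = out / "mk.tsv"
            _write_tsv(df, path, cfg)
            report.outputs["mk"] = str(path)
            report.stage_counts["mk_genes"] = len(df)
            report.timings_s[stage] = time.perf_counter() - t0
        if enabled("gc", cfg.nucleotide_fasta):
            stage = "gc"
            seqs = read_fasta(cfg.nucleotide_fasta, kind="nucleotide")
            df = pd.DataFrame(
                [(s.id, gc_content(s)) for s in seqs], columns=["gene", "gc_percent"]
            )
            path = out / "gc_content.tsv"
            _write_tsv(df, path, cfg)
            report.outputs["gc_content"] = str(path)
            report.stage_counts["gc_genes"] = len(df)
        if enabled("composition", cfg.protein_fasta, cfg.cleavage_tsv):
            stage = "composition"
            prots = read_fasta(cfg.protein_fasta, kind="protein")
            prots = attach_cleavage(prots, read_cleavage_table(cfg.cleavage_tsv))
            comp = secreted_composition([p for p in prots if p.cleavage_index is not None])
            df = pd.DataFrame(sorted(comp.items()), columns=["residue", "mean_percent"])
            path = out / "aa_composition.tsv"
            _write_tsv(df, path, cfg)
            report.outputs["aa_composition"] = str(path)
            report.stage_counts["composition_residues"] = len(df)
    except Exception as err:
        report.failed_stage = stage
        with open(out / "run_report.json", "w") as fh:
            json.dump({**asdict(report), "error": f"{stage}: {err}"}, fh, indent=2)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    rpath = out / "run_report.json"
    with open(rpath, "w") as fh:
        json.dump(asdict(report), fh, indent=2, default=str)
    report.outputs["run_report"] = str(rpath)
    return report
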