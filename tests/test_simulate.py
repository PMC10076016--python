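"""Generator properties: determinism, stop-free coding sequences, and
planted-truth recovery by each downstream stage."""

import numpy as np
import pytest

from mozevo.dnds import pairwise_dnds, rank_dnds
from mozevo.genetic_code import codons_of, is_stop
from mozevo.mk import MKTable, classify_sites, mk_alpha
from mozevo.simulate import (
    SimConfig,
    simulate_coding_pair,
    simulate_env_dataset,
    simulate_population_cds,
    simulate_study,
)


def assert_stop_free(row: str):
    assert not any(is_stop(c) for c in codons_of(row) if "-" not in c and "N" not in c)


class TestSimulateCodingPair:
    def test_same_seed_identical_alignment(self):
        cfg = SimConfig(seed=9, n_codons=200)
        a1, _ = simulate_coding_pair(cfg)
        a2, _ = simulate_coding_pair(cfg)
        assert a1.rows == a2.rows

    def test_stop_free_rows(self):
        aln, _ = simulate_coding_pair(SimConfig(seed=2, n_codons=300, omega_target=5.0))
        for row in aln.rows:
            assert_stop_free(row)

    def test_omega_zero_gives_dn_exactly_zero(self):
        aln, _ = simulate_coding_pair(SimConfig(seed=4, n_codons=500, omega_target=0.0))
        r = pairwise_dnds(aln)
        assert r.Nd == 0 and r.dN == 0.0

    def test_divergence_close_to_target(self):
        cfg = SimConfig(seed=6, n_codons=1000, divergence=0.05)
        aln, _ = simulate_coding_pair(cfg)
        diff = sum(a != b for a, b in zip(*aln.rows)) / len(aln.rows[0])
        assert diff == pytest.approx(0.05, abs=0.002)

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, omega_target=-0.5)

    def test_planted_fast_gene_ranks_high(self):
        """A gene evolving at omega=5 among 200 neutral-ish (omega=0.2) genes
        lands above the 95th percentile of the genome-wide distribution."""
        omegas = {}
        for g in range(200):
            aln, _ = simulate_coding_pair(
                SimConfig(seed=g, n_codons=300, omega_target=0.2)
            )
            omegas[f"null{g}"] = pairwise_dnds(aln).omega
        aln, _ = simulate_coding_pair(SimConfig(seed=999, n_codons=300, omega_target=5.0))
        omegas["fast"] = pairwise_dnds(aln).omega
        pct, _ = rank_dnds(omegas)
        assert pct["fast"] >= 95


class TestSimulatePopulationCds:
    def test_same_seed_identical(self):
        cfg = SimConfig(seed=12, n_codons=400)
        p1, _ = simulate_population_cds(cfg)
        p2, _ = simulate_population_cds(cfg)
        assert p1.ingroup.rows == p2.ingroup.rows
        assert p1.outgroup_row == p2.outgroup_row

    def test_planted_table_recovered_exactly(self):
        planted = MKTable(Dn=40, Ds=20, Pn=10, Ps=20)
        pa, labels = simulate_population_cds(
            SimConfig(seed=3, n_codons=400), exact_table=planted
        )
        assert labels.expected_mk == planted
        assert classify_sites(pa) == planted

    def test_no_polymorphisms_gives_undefined_alpha(self):
        pa, _ = simulate_population_cds(
            SimConfig(seed=5, n_codons=300, n_polymorphisms=0, n_divergences=50)
        )
        table = classify_sites(pa)
        assert table.Pn == table.Ps == 0
        with pytest.raises(ValueError):
            mk_alpha(table)

    def test_too_many_events_rejected(self):
        with pytest.raises(ValueError):
            simulate_population_cds(
                SimConfig(seed=1, n_codons=50, n_polymorphisms=40, n_divergences=40)
            )

    def test_rows_stop_free(self):
        pa, _ = simulate_population_cds(SimConfig(seed=8, n_codons=400))
        for row in pa.ingroup.rows + [pa.outgroup_row]:
            assert_stop_free(row)


class TestSimulateEnvDataset:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=21, n_genes=10)
        f1, e1, _ = simulate_env_dataset(cfg)
        f2, e2, _ = simulate_env_dataset(cfg)
        assert f1.AF.equals(f2.AF) and e1.equals(e2)

    def test_adding_genes_leaves_earlier_genes_unchanged(self):
        # frac_signal=0 so the signal/null split cannot reassign early genes
        f_small, _, _ = simulate_env_dataset(
            SimConfig(seed=21, n_genes=10, frac_signal=0.0)
        )
        f_big, _, _ = simulate_env_dataset(
            SimConfig(seed=21, n_genes=20, frac_signal=0.0)
        )
        common = f_small.AF.index
        assert f_big.AF.loc[common].equals(f_small.AF.loc[common])

    def test_labels_cover_every_gene(self):
        cfg = SimConfig(seed=2, n_genes=15, frac_signal=0.2)
        freq, _, labels = simulate_env_dataset(cfg)
        assert len(labels.genes) == 15
        assert labels.genes["is_signal"].sum() == 3
        assert set(labels.gene_of_variant.values()) == set(labels.genes["gene_id"])

    def test_frequencies_in_unit_interval(self):
        freq, _, _ = simulate_env_dataset(SimConfig(seed=2, n_genes=10))
        af = freq.AF.values
        assert ((af >= 0) & (af <= 1)).all()

    def test_mean_an_below_two_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, mean_AN=1)


class TestSimulateStudy:
    def test_written_files_reproducible_bytes(self, tmp_path):
        cfg = SimConfig(seed=33, n_genes=5, variants_per_gene=4, n_pops=5)
        p1 = simulate_study(cfg, tmp_path / "a")
        p2 = simulate_study(cfg, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_vcf_variant_count_matches_config(self, tmp_path):
        from mozevo.variants import read_vcf

        cfg = SimConfig(seed=33, n_genes=5, variants_per_gene=4, n_pops=5)
        paths = simulate_study(cfg, tmp_path / "s")
        records, samples = read_vcf(paths["vcf"])
        assert len(records) == 20
        assert len(samples) == 5 * (cfg.mean_AN // 2)
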