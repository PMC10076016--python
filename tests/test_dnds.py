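"""Codon-counting dN/dS tests, anchored on independent brute-force oracles.

The oracles translate codons with Biopython (not the package's own code
table) and enumerate mutational pathways recursively, so agreement is a
genuine two-route check.
"""

import math
from itertools import product

import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from mozevo.dnds import (
    CodonAlignment,
    codon_site_counts,
    count_differences,
    jukes_cantor,
    pairwise_dnds,
    rank_dnds,
    sliding_window_dnds,
)

BASES = "ACGT"
NON_STOP = [
    "".join(c) for c in product(BASES, repeat=3)
    if str(Seq("".join(c)).translate()) != "*"
]


def bio_aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_site_counts(codon: str) -> tuple[float, float]:
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if bio_aa(mut) == "*":
                continue
            tot += 1
            syn += bio_aa(mut) == bio_aa(codon)
        if tot:
            s += syn / tot
    return s, 3.0 - s


def oracle_count_differences(a: str, b: str) -> tuple[float, float]:
    """Recursive pathway enumeration (structurally unlike the implementation)."""

    def walk(cur, sd, nd):
        rest = [i for i in range(3) if cur[i] != b[i]]
        if not rest:
            return [(sd, nd, False)]
        out = []
        for i in rest:
            nxt = cur[:i] + b[i] + cur[i + 1:]
            step_syn = bio_aa(nxt) == bio_aa(cur)
            hits_stop = bio_aa(nxt) == "*"
            for s2, n2, stop2 in walk(nxt, sd + step_syn, nd + (not step_syn)):
                out.append((s2, n2, stop2 or hits_stop))
        return out

    paths = walk(a, 0, 0)
    clean = [p for p in paths if not p[2]] or paths
    return (
        sum(p[0] for p in clean) / len(clean),
        sum(p[1] for p in clean) / len(clean),
    )


class TestCodonSiteCounts:
    def test_phenylalanine_third_position(self):
        s, n = codon_site_counts("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_methionine_fully_nonsynonymous(self):
        assert codon_site_counts("ATG") == (0.0, 3.0)

    @pytest.mark.parametrize("codon", NON_STOP)
    def test_sites_sum_to_three_and_match_oracle(self, codon):
        s, n = codon_site_counts(codon)
        assert s + n == pytest.approx(3.0, abs=1e-12)
        os, on = oracle_site_counts(codon)
        assert s == pytest.approx(os, abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_site_counts("TAA")

    def test_ambiguous_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_site_counts("ATN")


class TestCountDifferences:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("GGG", "GGA", (1.0, 0.0)),  # Gly->Gly synonymous
            ("AAA", "CAA", (0.0, 1.0)),  # Lys->Gln
            ("TTT", "GTA", (0.5, 1.5)),  # two pathways averaged
            ("AAA", "AAA", (0.0, 0.0)),
        ],
    )
    def test_hand_derived_pairs(self, a, b, expected):
        assert count_differences(a, b) == pytest.approx(expected)

    def test_symmetry_and_hamming_sample(self):
        for a, b in [("TTT", "GTA"), ("ATG", "CCC"), ("GGG", "GGA")]:
            assert count_differences(a, b) == count_differences(b, a)
            sd, nd = count_differences(a, b)
            assert sd + nd == sum(x != y for x, y in zip(a, b))


class TestJukesCantor:
    def test_zero_is_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_hand_value(self):
        assert jukes_cantor(0.3) == pytest.approx(0.383119, abs=1e-6)

    @pytest.mark.parametrize("p", [0.75, 0.9])
    def test_saturation_boundary(self, p):
        with pytest.raises(ArithmeticError):
            jukes_cantor(p)

    @given(st.floats(0.0, 0.74))
    def test_distance_at_least_proportion(self, p):
        assert jukes_cantor(p) >= p - 1e-12


class TestPairwiseDnds:
    def test_identical_rows(self):
        aln = CodonAlignment(["a", "b"], ["ATGAAAGGG", "ATGAAAGGG"])
        r = pairwise_dnds(aln)
        assert r.Sd == r.Nd == 0
        assert r.dS == r.dN == 0.0
        assert r.omega is None and r.status == "dS_zero"

    def test_single_synonymous_difference_gives_omega_zero(self):
        # long enough that pS stays below the Jukes-Cantor saturation bound
        a = "ATGAAAGGGTTTCCC"
        b = "ATGAAAGGATTTCCC"
        r = pairwise_dnds(CodonAlignment(["a", "b"], [a, b]))
        assert r.Nd == 0 and r.Sd == 1
        assert r.dN == 0.0 and r.dS > 0
        assert r.omega == 0.0

    def test_nonsynonymous_only_dS_zero_status(self):
        r = pairwise_dnds(CodonAlignment(["a", "b"], ["ATGAAA", "ATGCAA"]))
        assert r.Sd == 0 and r.dS == 0.0
        assert r.omega is None and r.status == "dS_zero"

    def test_sites_sum_to_three_per_codon(self):
        aln = CodonAlignment(["a", "b"], ["ATGAAAGGGTTT", "ATGAAAGGATTT"])
        r = pairwise_dnds(aln)
        assert r.S + r.N == pytest.approx(3 * r.n_codons)

    def test_gap_and_n_codons_excluded_pairwise(self):
        aln = CodonAlignment(["a", "b"], ["ATG---GGGTTT", "ATGAAAGGNTTT"])
        r = pairwise_dnds(aln)
        assert r.n_codons == 2  # only ATG and TTT columns comparable

    def test_all_excluded_errors(self):
        aln = CodonAlignment(["a", "b"], ["---", "AAA"])
        with pytest.raises(ValueError):
            pairwise_dnds(aln)


class TestSlidingWindow:
    @staticmethod
    def _aln(n_codons):
        row = "ATGAAAGGGTTTCCC" * math.ceil(n_codons / 5)
        row = row[: 3 * n_codons]
        return CodonAlignment(["a", "b"], [row, row])

    def test_exactly_one_window_at_window_length(self):
        track = sliding_window_dnds(self._aln(34))
        assert [(s, e) for s, e, _ in track.windows] == [(0, 34)]

    def test_end_anchored_final_window_at_100_codons(self):
        track = sliding_window_dnds(self._aln(100))
        assert [(s, e) for s, e, _ in track.windows] == [
            (0, 34), (31, 65), (62, 96), (66, 100),
        ]

    def test_windows_tile_the_alignment(self):
        for L in (34, 50, 100, 137):
            track = sliding_window_dnds(self._aln(L))
            covered = set()
            for s, e, _ in track.windows:
                covered.update(range(s, e))
            assert covered == set(range(L))

    def test_short_alignment_single_window_with_warning(self):
        with pytest.warns(UserWarning):
            track = sliding_window_dnds(self._aln(10))
        assert [(s, e) for s, e, _ in track.windows] == [(0, 10)]

    def test_identical_window_reports_missing_omega(self):
        track = sliding_window_dnds(self._aln(34))
        assert track.windows[0][2].omega is None


class TestRankDnds:
    def test_two_genes_midpoint_percentiles(self):
        pct, excluded = rank_dnds({"g1": 0.1, "g2": 2.0})
        assert pct == {"g1": 25.0, "g2": 75.0}
        assert excluded == []

    def test_ties_saturate_at_50(self):
        pct, _ = rank_dnds({f"g{i}": 0.5 for i in range(5)})
        assert all(v == 50.0 for v in pct.values())

    def test_undefined_omegas_excluded_and_reported(self):
        pct, excluded = rank_dnds({"g1": 0.1, "g2": 2.0, "g3": None})
        assert excluded == ["g3"] and "g3" not in pct

    def test_all_undefined_errors(self):
        with pytest.raises(ValueError):
            rank_dnds({"g1": None, "g2": None})
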