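"""Pairwise dN/dS by codon counting, with a sliding-window scan.

The estimator is the classical counting approach: expected synonymous (S) and
nonsynonymous (N) sites from per-codon neighbor enumeration, observed
synonymous (Sd) and nonsynonymous (Nd) differences averaged over all minimal
mutational pathways between codon pairs, proportions corrected for multiple
hits with the Jukes-Cantor formula, and omega = dN/dS. Counting is
deterministic and verifiable by brute-force enumeration, which is why it is
used here instead of a likelihood codon model; output rows carry a method
label so another backend can coexist.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Sequence

from .composition import percentile_rank
from .genetic_code import BASES, codons_of, is_stop, neighbors, translate_codon

VALID_BASES = frozenset(BASES)


@dataclass
class CodonAlignment:
    """An in-frame codon alignment: >=2 equal-length rows over {A,C,G,T,N,-}."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("codon alignment needs >=2 rows")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3

    def row(self, key: int | str) -> str:
        if isinstance(key, str):
            key = self.ids.index(key)
        return self.rows[key]


@dataclass
class PairwiseRates:
    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    n_codons: int = 0  # comparable codons
    status: str = "ok"  # ok | dS_zero | dS_saturated | dN_saturated | no_codons
    method: str = "NG-counting+JC"

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else float("nan")

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else float("nan")

    @property
    def dS(self) -> float | None:
        try:
            return jukes_cantor(self.pS)
        except (ValueError, ArithmeticError):
            return None

    @property
    def dN(self) -> float | None:
        try:
            return jukes_cantor(self.pN)
        except (ValueError, ArithmeticError):
            return None

    @property
    def omega(self) -> float | None:
        """dN/dS, or None when dS is zero or undefined (never infinity)."""
        dS, dN = self.dS, self.dN
        if dS is None or dN is None or dS == 0.0:
            return None
        return dN / dS


@dataclass
class WindowTrack:
    windows: list[tuple[int, int, PairwiseRates]] = field(default_factory=list)


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Expected synonymous and nonsynonymous sites of one codon.

    Per position, the synonymous fraction of the single-nucleotide neighbors;
    neighbors creating stop codons are dropped from both numerator and
    denominator at that position. Always sums to 3.
    """
    codon = codon.upper()
    if set(codon) - VALID_BASES or len(codon) != 3:
        raise ValueError(f"ambiguous or invalid codon {codon!r}")
    if is_stop(codon):
        raise ValueError(f"stop codon {codon!r}")
    aa = translate_codon(codon)
    s_sites = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if is_stop(mut):
                continue
            tot += 1
            if translate_codon(mut) == aa:
                syn += 1
        if tot:
            s_sites += syn / tot
    return s_sites, 3.0 - s_sites


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons.

    Averages over all minimal single-step pathways; pathways through a stop
    codon are excluded unless every pathway hits a stop. sd+nd equals the
    Hamming distance.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if set(c) - VALID_BASES or len(c) != 3:
            raise ValueError(f"ambiguous or invalid codon {c!r}")
        if is_stop(c):
            raise ValueError(f"stop codon {c!r}")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways: list[tuple[float, float, bool]] = []  # (sd, nd, passes_stop)
    for order in permutations(diff_pos):
        cur = a
        sd = nd = 0.0
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if is_stop(nxt):
                hits_stop = True
            if translate_codon(nxt) == translate_codon(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        pathways.append((sd, nd, hits_stop))
    usable = [p for p in pathways if not p[2]] or pathways
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3); undefined at p >= 3/4."""
    if math.isnan(p):
        raise ValueError("proportion is undefined (no sites)")
    if p < 0:
        raise ValueError(f"negative proportion {p}")
    if p >= 0.75:
        raise ArithmeticError(f"saturated: p={p} >= 3/4, distance undefined")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def _comparable(codon_a: str, codon_b: str) -> bool:
    return (
        not (set(codon_a) - VALID_BASES)
        and not (set(codon_b) - VALID_BASES)
        and not is_stop(codon_a)
        and not is_stop(codon_b)
    )


def pairwise_dnds(
    aln: CodonAlignment,
    row_i: int | str = 0,
    row_j: int | str = 1,
    start_codon: int = 0,
    end_codon: int | None = None,
) -> PairwiseRates:
    """Counting dN/dS between two rows of an alignment (optionally a codon range).

    Codons with a gap, ambiguous base, or stop in either row are excluded
    pairwise. S and N are the mean of the two rows' site counts.
    """
    a = codons_of(aln.row(row_i))
    b = codons_of(aln.row(row_j))
    if end_codon is None:
        end_codon = len(a)
    rates = PairwiseRates()
    for ca, cb in zip(a[start_codon:end_codon], b[start_codon:end_codon]):
        if not _comparable(ca, cb):
            continue
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        rates.S += 0.5 * (sa + sb)
        rates.N += 0.5 * (na + nb)
        sd, nd = count_differences(ca, cb)
        rates.Sd += sd
        rates.Nd += nd
        rates.n_codons += 1
    if rates.n_codons == 0:
        raise ValueError("no comparable codons between the two rows")
    dS, dN = rates.dS, rates.dN
    if dS is None:
        rates.status = "dS_saturated" if rates.S > 0 else "no_syn_sites"
    elif dN is None:
        rates.status = "dN_saturated" if rates.N > 0 else "no_nonsyn_sites"
    elif dS == 0.0:
        rates.status = "dS_zero"
    return rates


def sliding_window_dnds(
    aln: CodonAlignment,
    row_i: int | str = 0,
    row_j: int | str = 1,
    window_codons: int = 34,
    step_codons: int = 31,
) -> WindowTrack:
    """dN/dS in 34-codon (102-nt) windows stepping 31 codons (3-codon overlap).

    A final window anchored at L - window_codons is added when the last regular
    window does not reach the end, so no tail is dropped. Windows where omega
    is undefined are reported with omega missing, not removed.
    """
    L = aln.n_codons
    track = WindowTrack()
    if L < window_codons:
        warnings.warn(
            f"alignment of {L} codons shorter than window ({window_codons}); "
            "reporting one whole-alignment window"
        )
        track.windows.append((0, L, pairwise_dnds(aln, row_i, row_j, 0, L)))
        return track
    starts = list(range(0, L - window_codons + 1, step_codons))
    if starts[-1] + window_codons < L:
        starts.append(L - window_codons)
    for s in starts:
        e = s + window_codons
        track.windows.append((s, e, pairwise_dnds(aln, row_i, row_j, s, e)))
    return track


def rank_dnds(
    per_gene_omega: dict[str, float | None],
) -> tuple[dict[str, float], list[str]]:
    """Percentile of each gene's omega among all genes with defined omega.

    Returns (gene -> percentile, list of genes excluded for undefined omega).
    """
    defined = {g: w for g, w in per_gene_omega.items() if w is not None}
    excluded = sorted(g for g in per_gene_omega if g not in defined)
    if len(defined) < 2:
        raise ValueError("need >=2 genes with defined omega to rank")
    values = list(defined.values())
    return {g: percentile_rank(w, values) for g, w in defined.items()}, excluded
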