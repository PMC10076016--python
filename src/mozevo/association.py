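"""Gene-level genotype-environment association.

Per-variant Pearson correlations between per-population alternate-allele
frequencies and ecological variables are combined per gene with the harmonic
mean p-value (HMP), summarized as -log10(combined p), percentile-ranked across
genes, and tested against a variant-count-matched permutation null (draw the
same number of variants from the genome-wide pool and recompute the gene
statistic).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .composition import percentile_rank
from .variants import FrequencyMatrix


class UndefinedCorrelation(ValueError):
    """Raised when a correlation is undefined (constant vector or n_used < 3)."""


@dataclass(frozen=True)
class VariantCorrelation:
    variant_id: str
    variable: str
    r: float
    p: float
    n_used: int


@dataclass
class GeneAssociation:
    gene_id: str
    variable: str
    L: int
    combined_p: float  # raw HMP
    combined_p_adjusted: float  # asymptotically exact HMP p
    metric: float  # -log10(raw HMP)
    percentile: float | None = None
    perm_p: float | None = None


def read_eco_table(path: str | Path) -> pd.DataFrame:
    """Ecological-variable TSV (population_id, then one column per variable)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df = df.set_index(df.columns[0])
    if df.shape[0] < 3:
        raise ValueError(f"{path}: need >=3 populations")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate variable names")
    return df.astype(float)


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Two-tailed Pearson correlation with pairwise deletion of missing values.

    Returns (r, p, n_used); p comes from t = r*sqrt((n-2)/(1-r^2)) on n-2
    degrees of freedom, clamped into (0, 1]. Raises UndefinedCorrelation for
    constant input or fewer than 3 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise UndefinedCorrelation(f"only {n} complete pairs (need >=3)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelation("constant vector")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = np.finfo(float).tiny
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(max(p, np.finfo(float).tiny), 1.0)), n


def harmonic_mean_p(ps, weights=None) -> float:
    """Raw harmonic mean p-value: 1 / sum(w_i / p_i), weights summing to 1.

    Lies between min(ps) and max(ps) for equal weights. Zero p-values are
    clamped to the smallest positive float with a warning.
    """
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise ValueError("harmonic_mean_p: empty p-value list")
    if np.any(ps < 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(ps == 0):
        warnings.warn("zero p-values clamped to the smallest positive float")
        ps = np.maximum(ps, np.finfo(float).tiny)
    if weights is None:
        w = np.full(ps.size, 1.0 / ps.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != ps.size or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("weights must match ps and sum to 1")
    return float(1.0 / np.sum(w / ps))


def hmp_adjusted(ps, weights=None) -> float:
    """Asymptotically exact HMP p-value for L combined tests.

    The reciprocal of the raw HMP is compared with a Landau distribution
    (stable alpha=1, beta=1, location ln(L)+0.874, scale pi/2, S0
    parameterization). For a single p-value it is that p-value.
    """
    ps = np.asarray(ps, dtype=float)
    raw = harmonic_mean_p(ps, weights)
    L = ps.size
    if L < 2:
        return raw
    old = stats.levy_stable.parameterization
    try:
        stats.levy_stable.parameterization = "S0"
        p = float(
            stats.levy_stable.sf(
                1.0 / raw, 1.0, 1.0, loc=math.log(L) + 0.874, scale=math.pi / 2
            )
        )
    finally:
        stats.levy_stable.parameterization = old
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def gene_metric(
    gene_id: str, variable: str, variant_ps, adjust: bool = True
) -> GeneAssociation:
    """Combine one gene's variant p-values for one variable into the gene metric.

    metric = -log10(raw HMP); the multiplicity-adjusted p is reported
    alongside (equal to the raw value when adjust=False or only one variant).
    """
    ps = np.asarray(variant_ps, dtype=float)
    if ps.size == 0:
        raise ValueError(f"{gene_id}/{variable}: no usable variant p-values")
    raw = harmonic_mean_p(ps)
    adj = hmp_adjusted(ps) if (adjust and ps.size >= 2) else raw
    return GeneAssociation(
        gene_id=gene_id,
        variable=variable,
        L=int(ps.size),
        combined_p=raw,
        combined_p_adjusted=adj,
        metric=-math.log10(raw),
    )


def rank_genes(metrics: pd.DataFrame, top_percentile: float = 90.0):
    """Percentile-rank gene metrics per variable and flag the top decile.

    ``metrics``: genes x variables DataFrame. Returns (percentiles, flags)
    DataFrames of the same shape; flag = percentile >= top_percentile.
    """
    if metrics.shape[0] < 2:
        raise ValueError("need >=2 genes to rank")
    pct = pd.DataFrame(index=metrics.index, columns=metrics.columns, dtype=float)
    for var in metrics.columns:
        col = metrics[var].dropna()
        pct[var] = metrics[var].map(
            lambda v: percentile_rank(v, col.values) if not np.isnan(v) else np.nan
        )
    return pct, pct >= top_percentile


def permutation_pvalue(
    obs_stats: np.ndarray,
    pool: np.ndarray,
    B: int,
    seed: int | np.random.Generator,
) -> float:
    """Variant-count-matched permutation p for one gene and one variable.

    T = mean of the gene's per-variant statistics (|r| by convention). The
    null is B independent draws of len(obs_stats) values sampled without
    replacement from the genome-wide pool;
    perm_p = (1 + #{T_null >= T_obs}) / (1 + B).
    """
    obs = np.asarray(obs_stats, dtype=float)
    pool = np.asarray(pool, dtype=float)
    k, M = obs.size, pool.size
    if B < 1:
        raise ValueError("B must be >= 1")
    if k == 0:
        raise ValueError("no observed variant statistics")
    if M < k:
        raise ValueError(f"pool of {M} smaller than gene's {k} variants")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_obs = obs.mean()
    if k == M:
        return 1.0  # every draw is the full pool
    exceed = 0
    chunk = max(1, min(B, int(4e6) // M))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        keys = rng.random((b, M))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        t_null = pool[idx].mean(axis=1)
        exceed += int((t_null >= t_obs).sum())
        done += b
    return (1 + exceed) / (1 + B)


def correlate_variants(
    freq: FrequencyMatrix, eco: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Pearson r/p for every variant x ecological variable.

    Populations are matched by id between the frequency matrix and the
    ecological table. Variants with undefined correlations are skipped and
    counted. Returns (long DataFrame, n_skipped pairs).
    """
    common = [p for p in freq.AF.columns if p in eco.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 populations shared with the eco table")
    af = freq.AF[common]
    rows, skipped = [], 0
    for var in eco.columns:
        y = eco.loc[common, var].values
        for vid in af.index:
            try:
                r, p, n = pearson_with_p(af.loc[vid].values, y)
            except UndefinedCorrelation:
                skipped += 1
                continue
            rows.append((vid, var, r, p, n))
    df = pd.DataFrame(rows, columns=["variant_id", "variable", "r", "p", "n_used"])
    return df, skipped


def associate_genes(
    variant_corr: pd.DataFrame,
    gene_of_variant: dict[str, str],
    B: int = 0,
    seed: int | None = None,
    perm_genes: list[str] | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Gene x variable association table from per-variant correlations.

    Combines each gene's variant p-values (raw HMP -> metric), percentile-ranks
    the metric per variable, and, when B > 0, runs the count-matched
    permutation test (statistic: mean |r|) for ``perm_genes`` (all genes when
    None) against the pool of all usable variants of that variable. The seed
    is required whenever B > 0.
    """
    vc = variant_corr.copy()
    vc["gene_id"] = vc["variant_id"].map(gene_of_variant)
    vc = vc.dropna(subset=["gene_id"])
    if B > 0 and seed is None:
        raise ValueError("an explicit seed is required for the permutation test")
    records: list[GeneAssociation] = []
    for (gene, var), grp in vc.groupby(["gene_id", "variable"], sort=True):
        records.append(gene_metric(str(gene), str(var), grp["p"].values, adjust=adjust))
    gene_df = pd.DataFrame(
        [
            (a.gene_id, a.variable, a.L, a.combined_p, a.combined_p_adjusted, a.metric)
            for a in records
        ],
        columns=["gene_id", "variable", "L", "combined_p", "combined_p_adjusted", "metric"],
    )
    wide = gene_df.pivot(index="gene_id", columns="variable", values="metric")
    pct, flags = rank_genes(wide)
    gene_df["percentile"] = [
        pct.loc[g, v] for g, v in zip(gene_df["gene_id"], gene_df["variable"])
    ]
    gene_df["top_decile"] = gene_df["percentile"] >= 90.0
    gene_df["perm_p"] = np.nan
    if B > 0:
        rng = np.random.default_rng(seed)
        targets = set(perm_genes) if perm_genes is not None else set(gene_df["gene_id"])
        for var, grp in vc.groupby("variable", sort=True):
            pool = np.abs(grp["r"].values)
            by_gene = {g: np.abs(sub["r"].values) for g, sub in grp.groupby("gene_id")}
            for g in sorted(by_gene):
                if g not in targets:
                    continue
                p = permutation_pvalue(by_gene[g], pool, B, rng)
                sel = (gene_df["gene_id"] == g) & (gene_df["variable"] == var)
                gene_df.loc[sel, "perm_p"] = p
    gene_df["significant"] = gene_df["perm_p"] < 0.05
    return gene_df
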