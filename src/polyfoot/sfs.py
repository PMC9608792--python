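"""Per-gene, per-population site-frequency-spectrum statistics from pooled counts.

The statistics here summarise segregating variation within one population:
segregating non-synonymous sites S, Tajima's theta_pi and theta_w, Tajima's D
restricted to non-synonymous sites (D_NS), per-site diversity at
non-synonymous (pi_N) and synonymous (pi_S) sites, and the log10 pi_N/pi_S
ratio used as a constraint covariate.

Pooled data have two sampling layers (individuals into the pool, reads from
the pool).  The estimators below use folded minor-allele read frequencies and
an effective sample size per site, ``n_eff = min(haploid pool size, biallelic
depth)``: the number of chromosomes the reads can at most represent.  Tajima's
variance normaliser is evaluated at the gene's median site n_eff.  This is an
approximation to full pool-aware corrections; the genotype-count limit (reads
= chromosomes, no pooling noise) is exact and is what the test oracles pin
down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import SyncRecord

logger = logging.getLogger(__name__)

_BASE_IDX = {"A": 0, "T": 1, "C": 2, "G": 3}


@dataclass(frozen=True)
class FilterParams:
    """Site-filtering thresholds for pooled counts.

    min_minor_count
        Reads of the minor allele required to call a site polymorphic in a
        pool (popoolation convention; default 2).  Sites below it are kept as
        monomorphic so they still count toward per-site denominators.
    min_depth, max_depth
        Per-pool coverage window; sites outside it are dropped entirely for
        that pool.
    """

    min_minor_count: int = 2
    min_depth: int = 10
    max_depth: int = 500

    def __post_init__(self) -> None:
        if self.min_minor_count < 1 or self.min_depth < 1:
            raise ValueError("thresholds must be positive")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")


def filter_sites(
    records: Iterable[SyncRecord],
    site_classes: pd.DataFrame,
    pool_sizes: list[int] | tuple[int, ...],
    params: FilterParams = FilterParams(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Reduce raw sync records to classified biallelic pooled sites.

    Allele choice is global: the two alleles of a site are the two bases with
    the highest read totals summed over all pools, so variant labels are
    consistent across pools (a requirement for the pairwise divergence
    statistics).  A site with three or more bases reaching
    ``min_minor_count`` in the pooled totals is triallelic and dropped.

    Returns a long-format frame with one row per (site, pool):

    ``pool, contig, pos, gene_id, site_class, a1, a2, c1, c2, depth,
    minor_count, freq_hat, n_eff, is_snp``

    where ``c1/c2`` are raw read counts of the two alleles, ``minor_count``
    is the *called* minor count (zeroed when below ``min_minor_count``),
    ``freq_hat = minor_count / depth`` is the folded frequency and ``is_snp``
    flags called polymorphisms.  The second element of the returned tuple is
    a counter dict (``n_sites, n_triallelic, n_unclassified, n_depth_dropped``).
    """
    class_key = {
        (c, p): (g, k)
        for c, p, g, k in site_classes[
            ["contig", "pos", "gene_id", "site_class"]
        ].itertuples(index=False)
    }
    n_pools = len(pool_sizes)
    counters = {"n_sites": 0, "n_triallelic": 0, "n_unclassified": 0, "n_depth_dropped": 0}
    rows: list[tuple] = []
    for rec in records:
        counters["n_sites"] += 1
        key = (rec.contig, rec.pos)
        if key not in class_key:
            counters["n_unclassified"] += 1
            continue
        gene_id, klass = class_key[key]
        if rec.counts.shape[0] != n_pools:
            raise ValueError(
                f"record {rec.contig}:{rec.pos} has {rec.counts.shape[0]} pools, "
                f"expected {n_pools}"
            )
        base_counts = rec.counts[:, :4]  # drop N and deletions
        totals = base_counts.sum(axis=0)
        if int((totals >= params.min_minor_count).sum()) >= 3:
            counters["n_triallelic"] += 1
            continue
        # top-2 alleles by pooled total; ties broken by base order (A,T,C,G)
        order = np.argsort(-totals, kind="stable")
        i1, i2 = int(order[0]), int(order[1])
        bases = "ATCG"
        for pool in range(n_pools):
            cov = int(base_counts[pool].sum())
            if cov < params.min_depth or cov > params.max_depth:
                counters["n_depth_dropped"] += 1
                continue
            c1 = int(base_counts[pool, i1])
            c2 = int(base_counts[pool, i2])
            depth = c1 + c2
            if depth == 0:
                counters["n_depth_dropped"] += 1
                continue
            minor = min(c1, c2)
            is_snp = minor >= params.min_minor_count
            minor_called = minor if is_snp else 0
            n_eff = min(int(pool_sizes[pool]), depth)
            rows.append(
                (
                    pool,
                    rec.contig,
                    rec.pos,
                    gene_id,
                    klass,
                    bases[i1],
                    bases[i2],
                    c1,
                    c2,
                    depth,
                    minor_called,
                    minor_called / depth,
                    n_eff,
                    is_snp,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "pool",
            "contig",
            "pos",
            "gene_id",
            "site_class",
            "a1",
            "a2",
            "c1",
            "c2",
            "depth",
            "minor_count",
            "freq_hat",
            "n_eff",
            "is_snp",
        ],
    )
    return df, counters


def tajima_constants(n_eff: int) -> dict[str, float]:
    """Tajima's (1989) a1..e2 constants for sample size ``n_eff`` chromosomes."""
    n = int(n_eff)
    if n < 2:
        raise ValueError("n_eff must be >= 2")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def theta_estimates(
    freqs: np.ndarray,
    n_effs: np.ndarray,
    gene_n_eff: int,
) -> tuple[int, float, float]:
    """(S, theta_pi, theta_w) for one gene/class from folded site frequencies.

    ``freqs`` are folded minor-allele frequencies of *all* class sites
    (monomorphic sites contribute 0), ``n_effs`` the per-site effective
    sample sizes and ``gene_n_eff`` the gene-level n_eff at which theta_w's
    a1 is evaluated.

    theta_pi = sum_sites 2 p(1-p) n/(n-1);  theta_w = S / a1(gene_n_eff).
    """
    freqs = np.asarray(freqs, dtype=float)
    n_effs = np.asarray(n_effs, dtype=float)
    if freqs.size == 0:
        return 0, 0.0, 0.0
    if (n_effs < 2).any():
        raise ValueError("per-site n_eff must be >= 2")
    poly = freqs > 0
    s = int(poly.sum())
    theta_pi = float(
        (2.0 * freqs * (1.0 - freqs) * n_effs / (n_effs - 1.0)).sum()
    )
    if s == 0:
        return 0, theta_pi, 0.0
    a1 = tajima_constants(int(gene_n_eff))["a1"]
    theta_w = s / a1
    return s, theta_pi, theta_w


def tajimas_d(
    s: int,
    theta_pi: float,
    theta_w: float,
    n_eff: int,
    min_snps: int = 3,
) -> float:
    """Tajima's D from its components.

    D = (theta_pi - theta_w) / sqrt(e1*S + e2*S*(S-1)) with the 1989
    constants evaluated at ``n_eff``.  Returns NaN when S < ``min_snps``
    (unstable normaliser) or when ``n_eff`` < 4 (no finite variance term).
    """
    if s < min_snps or s == 0:
        return float("nan")
    if n_eff < 4:
        logger.warning("tajimas_d: n_eff=%d < 4, returning NaN", n_eff)
        return float("nan")
    k = tajima_constants(int(n_eff))
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var <= 0:
        return float("nan")
    return float((theta_pi - theta_w) / np.sqrt(var))


def standardize_d(d: np.ndarray | pd.Series) -> np.ndarray:
    """Z-score finite entries (mean 0, variance 1, ddof=0); NaN preserved.

    Raises on fewer than two finite values or zero variance.
    """
    arr = np.asarray(d, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 2:
        raise ValueError("need >= 2 finite values to standardize")
    vals = arr[finite]
    sd = vals.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    out = np.full_like(arr, np.nan, dtype=float)
    out[finite] = (vals - vals.mean()) / sd
    return out


def pi_ratio(pi_n: float, pi_s: float) -> float:
    """log10(pi_N / pi_S); NaN when either class diversity is zero."""
    if pi_n < 0 or pi_s < 0:
        raise ValueError("per-site diversities must be non-negative")
    if pi_n == 0 or pi_s == 0:
        return float("nan")
    return float(np.log10(pi_n / pi_s))


def gene_population_stats(
    sites: pd.DataFrame,
    pool: int,
    min_snps: int = 3,
) -> pd.DataFrame:
    """Per-gene SFS statistics for one population (pool).

    ``sites`` is the frame returned by :func:`filter_sites`.  Output columns:
    ``gene_id, pop, S, theta_pi, theta_w, D_ns, D_ns_std, pi_n, pi_s,
    ratio_log10, n_sites_ns, n_sites_syn``.  ``D_ns_std`` is the across-gene
    z-score of D_ns within this population.
    """
    sub = sites[sites["pool"] == pool]
    out_rows = []
    for gene_id, g in sub.groupby("gene_id", sort=True):
        ns = g[g["site_class"] == "NS"]
        syn = g[g["site_class"] == "SYN"]
        n_ns, n_syn = len(ns), len(syn)
        if n_ns:
            gene_n_eff = int(np.median(ns["n_eff"]))
            s, tpi, tw = theta_estimates(
                ns["freq_hat"].to_numpy(), ns["n_eff"].to_numpy(), gene_n_eff
            )
            d = tajimas_d(s, tpi, tw, gene_n_eff, min_snps=min_snps)
            pi_n = tpi / n_ns
        else:
            s, tpi, tw, d, pi_n = 0, 0.0, 0.0, float("nan"), float("nan")
        if n_syn:
            het_s = (
                2.0
                * syn["freq_hat"]
                * (1.0 - syn["freq_hat"])
                * syn["n_eff"]
                / (syn["n_eff"] - 1.0)
            ).sum()
            pi_s = float(het_s) / n_syn
        else:
            pi_s = float("nan")
        ratio = (
            pi_ratio(pi_n, pi_s)
            if np.isfinite(pi_n) and np.isfinite(pi_s)
            else float("nan")
        )
        out_rows.append(
            (gene_id, pool, s, tpi, tw, d, pi_n, pi_s, ratio, n_ns, n_syn)
        )
    out = pd.DataFrame(
        out_rows,
        columns=[
            "gene_id",
            "pop",
            "S",
            "theta_pi",
            "theta_w",
            "D_ns",
            "pi_n",
            "pi_s",
            "ratio_log10",
            "n_sites_ns",
            "n_sites_syn",
        ],
    )
    if np.isfinite(out["D_ns"]).sum() >= 2 and out["D_ns"].std(ddof=0) > 0:
        out["D_ns_std"] = standardize_d(out["D_ns"].to_numpy())
    else:
        out["D_ns_std"] = np.nan
    cols = [
        "gene_id", "pop", "S", "theta_pi", "theta_w", "D_ns", "D_ns_std",
        "pi_n", "pi_s", "ratio_log10", "n_sites_ns", "n_sites_syn",
    ]
    return out[cols]
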