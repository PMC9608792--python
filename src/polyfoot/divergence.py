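"""Per-gene pairwise divergence between populations from pooled counts.

Two complementary statistics:

F_ST (relative divergence)
    The pool-aware unbiased identity-probability estimator.  For a site with
    read counts (c1, c2) of the two alleles at biallelic depth d in a pool of
    n haploid chromosomes:

    * read identity within a pool, unbiased over read pairs:
      ``q_reads = (c1(c1-1) + c2(c2-1)) / (d(d-1))``;
    * two distinct reads resample the same pool chromosome with probability
      1/n, so the identity of two *distinct chromosomes* is
      ``Q1_hat = (q_reads - 1/n) / (1 - 1/n)``;
    * reads from different pools always come from different chromosomes, so
      ``Q2_hat = (c1x*c1y + c2x*c2y) / (dx*dy)`` is already unbiased.

    The gene estimate is a ratio of sums over its SNPs,
    ``F_ST = sum(Q1_hat - Q2_hat) / sum(1 - Q2_hat)`` with Q1_hat averaged
    over the two pools per site.  In the infinite-depth, infinite-pool limit
    this reduces to the Hudson frequency-based estimator
    (1 - Hw/Hb); at finite depth it is unbiased in the numerator, so pools
    drawn from identical frequencies average to F_ST ~ 0 (possibly slightly
    negative, which is retained raw for class means).

d_XY (absolute divergence)
    ``d_XY = sum_sites (A_X*B_Y + A_Y*B_X) / n_sites_total`` where A and B
    are the two variant frequencies at a site and the denominator counts all
    sites passing depth filters in both populations, variable or not.
    Monomorphic-identical sites contribute 0 and fixed differences 1.

For statistical modelling, F_ST is logit transformed (after clamping to
[eps, 1-eps]) and d_XY log10 transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FST_LOGIT_EPS = 1e-4
DXY_LOG_EPS = 1e-6


@dataclass
class PairCounters:
    n_bad_denominator: int = 0


def join_pair_sites(sites_x: pd.DataFrame, sites_y: pd.DataFrame) -> pd.DataFrame:
    """Join single-pool site frames of two populations on (contig, pos).

    Inputs are per-pool slices of the frame produced by
    :func:`polyfoot.sfs.filter_sites`; allele labels are consistent across
    pools by construction there (chosen from counts pooled over all pools).
    Only sites passing depth filters in *both* populations survive the join.
    Adds ``is_snp_pair`` = polymorphic in either pool.
    """
    cols = ["contig", "pos", "gene_id", "site_class", "a1", "a2", "c1", "c2",
            "depth", "n_eff", "is_snp"]
    x = sites_x[cols].rename(
        columns={"c1": "c1x", "c2": "c2x", "depth": "dx", "n_eff": "nx",
                 "is_snp": "snp_x"}
    )
    y = sites_y[cols].rename(
        columns={"c1": "c1y", "c2": "c2y", "depth": "dy", "n_eff": "ny",
                 "is_snp": "snp_y"}
    )
    j = x.merge(y, on=["contig", "pos", "gene_id", "site_class", "a1", "a2"])
    j["is_snp_pair"] = j["snp_x"] | j["snp_y"]
    return j


def _q1_site(c1: np.ndarray, c2: np.ndarray, n_pool: int) -> np.ndarray:
    d = c1 + c2
    with np.errstate(invalid="ignore", divide="ignore"):
        q_reads = (c1 * (c1 - 1.0) + c2 * (c2 - 1.0)) / (d * (d - 1.0))
    return (q_reads - 1.0 / n_pool) / (1.0 - 1.0 / n_pool)


def fst_gene(
    pair_sites: pd.DataFrame,
    n_pool_x: int,
    n_pool_y: int,
    counters: PairCounters | None = None,
) -> tuple[float, float, float, int]:
    """Unbiased pooled F_ST for one gene: (fst, q1_hat, q2_hat, n_snps).

    Uses the gene's SNPs (polymorphic in either pool) and aggregates as a
    ratio of per-SNP sums.  Returns NaN when the gene has no SNPs or the
    summed denominator is non-positive.
    """
    snps = pair_sites[pair_sites["is_snp_pair"]]
    n_snps = len(snps)
    if n_snps == 0:
        return float("nan"), float("nan"), float("nan"), 0
    c1x = snps["c1x"].to_numpy(float)
    c2x = snps["c2x"].to_numpy(float)
    c1y = snps["c1y"].to_numpy(float)
    c2y = snps["c2y"].to_numpy(float)
    q1 = 0.5 * (_q1_site(c1x, c2x, n_pool_x) + _q1_site(c1y, c2y, n_pool_y))
    q2 = (c1x * c1y + c2x * c2y) / ((c1x + c2x) * (c1y + c2y))
    denom = float((1.0 - q2).sum())
    if denom <= 0:
        if counters is not None:
            counters.n_bad_denominator += 1
        return float("nan"), float(q1.mean()), float(q2.mean()), n_snps
    fst = float((q1 - q2).sum() / denom)
    return fst, float(q1.mean()), float(q2.mean()), n_snps


def dxy_gene(pair_sites: pd.DataFrame) -> tuple[float, int]:
    """d_XY for one gene: (dxy, n_sites_total).

    Frequencies are pool read frequencies of allele a1; at sites not called
    polymorphic in the pair, each pool is treated as fixed for its majority
    allele (so monomorphic-identical sites contribute exactly 0 and fixed
    differences exactly 1).  Symmetric in the two populations and invariant
    to which allele is labelled A.
    """
    n_total = len(pair_sites)
    if n_total == 0:
        return float("nan"), 0
    ax = pair_sites["c1x"].to_numpy(float) / (
        pair_sites["c1x"].to_numpy(float) + pair_sites["c2x"].to_numpy(float)
    )
    ay = pair_sites["c1y"].to_numpy(float) / (
        pair_sites["c1y"].to_numpy(float) + pair_sites["c2y"].to_numpy(float)
    )
    mono = ~pair_sites["is_snp_pair"].to_numpy()
    ax[mono] = np.round(ax[mono])
    ay[mono] = np.round(ay[mono])
    dxy = float((ax * (1.0 - ay) + ay * (1.0 - ax)).sum() / n_total)
    return dxy, n_total


def transform_divergence(stats: pd.DataFrame) -> pd.DataFrame:
    """Add ``fst_logit`` and ``dxy_log10`` columns (raw values retained).

    fst is clamped to [eps, 1-eps] (eps=1e-4) before the logit; dxy is
    floored at 1e-6 before log10.
    """
    out = stats.copy()
    f = np.clip(out["fst"].to_numpy(float), FST_LOGIT_EPS, 1.0 - FST_LOGIT_EPS)
    out["fst_logit"] = np.where(
        np.isfinite(out["fst"]), np.log(f / (1.0 - f)), np.nan
    )
    d = np.maximum(out["dxy"].to_numpy(float), DXY_LOG_EPS)
    out["dxy_log10"] = np.where(np.isfinite(out["dxy"]), np.log10(d), np.nan)
    return out


def pair_divergence_table(
    sites: pd.DataFrame,
    pool_x: int,
    pool_y: int,
    n_pool_x: int,
    n_pool_y: int,
    pair_name: str | None = None,
) -> pd.DataFrame:
    """Per-gene F_ST and d_XY for one population pair.

    ``sites`` is the full multi-pool frame from ``filter_sites``.  Output
    columns: ``gene_id, pair, fst, fst_logit, q1_hat, q2_hat, dxy,
    dxy_log10, n_snps, n_sites_total``.
    """
    pair_name = pair_name or f"{pool_x}-{pool_y}"
    joined = join_pair_sites(
        sites[sites["pool"] == pool_x], sites[sites["pool"] == pool_y]
    )
    counters = PairCounters()
    rows = []
    for gene_id, g in joined.groupby("gene_id", sort=True):
        fst, q1, q2, n_snps = fst_gene(g, n_pool_x, n_pool_y, counters)
        dxy, n_total = dxy_gene(g)
        rows.append((gene_id, pair_name, fst, q1, q2, dxy, n_snps, n_total))
    if counters.n_bad_denominator:
        logger.warning(
            "pair %s: %d genes with non-positive F_ST denominator",
            pair_name,
            counters.n_bad_denominator,
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "pair", "fst", "q1_hat", "q2_hat", "dxy",
                 "n_snps", "n_sites_total"],
    )
    out = transform_divergence(out)
    return out[
        ["gene_id", "pair", "fst", "fst_logit", "q1_hat", "q2_hat",
         "dxy", "dxy_log10", "n_snps", "n_sites_total"]
    ]


def hudson_fst(p_x: np.ndarray, p_y: np.ndarray) -> float:
    """Frequency-based (Hudson-type) multilocus F_ST, ratio of sums.

    ``1 - Hw/Hb`` with Hw the mean within-population heterozygosity and
    Hb = p_x*q_y + p_y*q_x, summed over loci.  This is the infinite-depth,
    infinite-pool limit of :func:`fst_gene` and doubles as the ground-truth
    divergence measure for simulated allele frequencies.
    """
    p_x = np.asarray(p_x, float)
    p_y = np.asarray(p_y, float)
    hw = p_x * (1 - p_x) + p_y * (1 - p_y)  # = 2*mean(2pq)/2
    hb = p_x * (1 - p_y) + p_y * (1 - p_x)
    denom = hb.sum()
    if denom <= 0:
        return float("nan")
    return float((hb - hw).sum() / denom)
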