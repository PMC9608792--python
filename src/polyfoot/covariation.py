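"""Inference layer: models of covariation between within-population variation
and between-population divergence.

This module carries the study's statistical machinery:

* interaction general linear models — does the *imbalance* in Tajima's D_NS
  between two populations (positive in one, negative in the other, i.e. a
  negative D1 x D2 product) predict relative divergence (logit F_ST)?  The
  same design with d_XY (log10) as response asks whether absolute divergence
  is instead dominated by the quadratic terms (highest for near-neutral
  spectra in both populations);
* repeatability of gene-specific divergence across the three population
  pairs (PCA of the three divergence vectors + one-way-ANOVA intraclass
  correlation with gene as the grouping factor);
* 8 x 8 Tajima's-D binned surfaces (the mesh-plot construction);
* imbalance gene sets (|D1 - D2| > d_diff and F_ST > fst_min) and
  hypergeometric over-representation tests of functional terms;
* gene-class contrasts (Welch t, bias-corrected bootstrap CIs), sex-bias
  expression-bin permutation ANOVAs, and the quasi-Poisson GLM of
  non-synonymous polymorphism counts (0-3 populations) on expression level.

All model fits are ordinary least squares / IRLS through statsmodels; the
quantities authored here are the designs, the effect-size and repeatability
computations, and the resampling schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# linear fits
# ---------------------------------------------------------------------------


@dataclass
class LinearFit:
    """An OLS fit: per-term coefficient table plus fit summary."""

    response: str
    terms: list[str]
    table: pd.DataFrame  # columns: term, beta, se, t, p
    r2: float
    n: int
    df_resid: int

    def beta(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "beta"])

    def se(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])

    def pvalue(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the offending columns via QR: near-zero diagonal of R
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [design.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")


def ols_fit(df: pd.DataFrame, response: str, terms: list[str]) -> LinearFit:
    """OLS of ``response`` on ``terms`` (plus intercept), listwise-complete rows."""
    data = df[[response] + terms].dropna()
    n = len(data)
    if n <= len(terms) + 1:
        raise ValueError(f"too few complete rows (n={n}) for {len(terms)} terms")
    design = sm.add_constant(data[terms], has_constant="add")
    _check_rank(design)
    res = sm.OLS(data[response], design).fit()
    table = pd.DataFrame(
        {
            "term": ["const"] + terms,
            "beta": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "t": res.tvalues.to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )
    return LinearFit(
        response=response,
        terms=list(terms),
        table=table,
        r2=float(res.rsquared),
        n=n,
        df_resid=int(res.df_resid),
    )


def _divergence_design(table: pd.DataFrame, model: int) -> pd.DataFrame:
    df = table.copy()
    df["D1_sq"] = df["D1"] ** 2
    df["D2_sq"] = df["D2"] ** 2
    df["D1xD2"] = df["D1"] * df["D2"]
    return df


DIVERGENCE_TERMS_M1 = ["D1", "D2", "D1_sq", "D2_sq", "D1xD2"]
DIVERGENCE_TERMS_M2 = DIVERGENCE_TERMS_M1 + [
    "gc_content",
    "length",
    "ratio1",
    "ratio2",
]


def fit_fst_model(pair_table: pd.DataFrame, model: int = 1) -> LinearFit:
    """GLM of logit F_ST on within-population Tajima's D_NS.

    ``pair_table`` must carry ``fst_logit``, standardized ``D1``/``D2`` for
    the two populations and, for model 2, the covariates ``gc_content``,
    ``length`` and the log10 pi_N/pi_S ratios ``ratio1``/``ratio2``.

    Model 1 terms: D1, D2, D1^2, D2^2 and the interaction D1 x D2 (the
    imbalance signal: genes with opposite-signed D in the two populations
    have a negative product).  Model 2 adds the covariates.  Rows with any
    missing term are dropped listwise.
    """
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    terms = DIVERGENCE_TERMS_M1 if model == 1 else DIVERGENCE_TERMS_M2
    return ols_fit(_divergence_design(pair_table, model), "fst_logit", terms)


def fit_dxy_model(pair_table: pd.DataFrame, model: int = 1) -> LinearFit:
    """As :func:`fit_fst_model` with log10 d_XY as the response."""
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    terms = DIVERGENCE_TERMS_M1 if model == 1 else DIVERGENCE_TERMS_M2
    return ols_fit(_divergence_design(pair_table, model), "dxy_log10", terms)


def cohens_f2(fit_full: LinearFit, fit_reduced: LinearFit) -> float:
    """Cohen's local effect size f2 = (R2_full - R2_reduced) / (1 - R2_full).

    The reduced model must nest in the full one (same response, terms a
    subset of the full terms).
    """
    if fit_reduced.response != fit_full.response:
        raise ValueError("fits have different responses")
    if not set(fit_reduced.terms) <= set(fit_full.terms):
        raise ValueError("reduced model does not nest in full model")
    if fit_full.r2 >= 1.0:
        raise ValueError("R2_full >= 1: f2 undefined")
    return (fit_full.r2 - fit_reduced.r2) / (1.0 - fit_full.r2)


def interaction_f2(pair_table: pd.DataFrame, model: int = 1,
                   response: str = "fst_logit") -> float:
    """f2 of the D1 x D2 interaction: full model vs the model without it."""
    terms = DIVERGENCE_TERMS_M1 if model == 1 else DIVERGENCE_TERMS_M2
    design = _divergence_design(pair_table, model)
    full = ols_fit(design, response, terms)
    reduced = ols_fit(
        design.dropna(subset=[response] + terms),
        response,
        [t for t in terms if t != "D1xD2"],
    )
    return cohens_f2(full, reduced)


def pc1_regression(
    pc1: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
) -> LinearFit:
    """Regression of PC1 scores on gene covariates, fully standardized.

    Response and covariates are z-scored on their complete rows, so the
    reported betas are standardized coefficients (beta-prime).
    """
    df = covariates.copy()
    df["pc1"] = np.asarray(pc1, dtype=float)
    df = df.dropna()
    if len(df) < len(covariates.columns) + 2:
        raise ValueError("too few complete rows for pc1 regression")
    z = (df - df.mean()) / df.std(ddof=0)
    return ols_fit(z, "pc1", [c for c in covariates.columns])


# ---------------------------------------------------------------------------
# repeatability (PCA + ICC)
# ---------------------------------------------------------------------------


@dataclass
class RepeatabilityResult:
    pc1_variance_fraction: float
    pc1_loadings: np.ndarray
    variance_fractions: np.ndarray
    icc_R: float
    F: float
    df1: int
    df2: int
    p: float
    ms_between: float
    ms_within: float
    n_genes: int


def repeatability(vectors: pd.DataFrame) -> RepeatabilityResult:
    """Repeatability of gene-specific divergence across population pairs.

    ``vectors`` has one column per population pair (k columns, typically 3)
    and one row per gene; rows with any NaN are dropped listwise.

    PCA is computed on the centered, unscaled columns (covariance PCA);
    loadings are sign-fixed so their sum is positive.  The intraclass
    correlation is the one-way-ANOVA ICC(1) with gene as the grouping
    factor: R = (MS_B - MS_W) / (MS_B + (k-1) MS_W); negative estimates are
    reported as-is.
    """
    x = vectors.dropna().to_numpy(float)
    n, k = x.shape
    if n < 3:
        raise ValueError("need >= 3 complete genes")
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    fracs = evals / evals.sum()
    load = evecs[:, 0]
    if load.sum() < 0:
        load = -load
    grand = x.mean()
    gene_means = x.mean(axis=1)
    ms_b = k * ((gene_means - grand) ** 2).sum() / (n - 1)
    ms_w = ((x - gene_means[:, None]) ** 2).sum() / (n * (k - 1))
    icc = (ms_b - ms_w) / (ms_b + (k - 1) * ms_w)
    f_stat = ms_b / ms_w if ms_w > 0 else np.inf
    df1, df2 = n - 1, n * (k - 1)
    p = float(sps.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    return RepeatabilityResult(
        pc1_variance_fraction=float(fracs[0]),
        pc1_loadings=load,
        variance_fractions=fracs,
        icc_R=float(icc),
        F=float(f_stat),
        df1=df1,
        df2=df2,
        p=p,
        ms_between=float(ms_b),
        ms_within=float(ms_w),
        n_genes=n,
    )


def pc1_scores(vectors: pd.DataFrame) -> pd.Series:
    """PC1 scores (covariance PCA, loadings sign-fixed) aligned to the index.

    Rows with any NaN get NaN scores.
    """
    complete = vectors.dropna()
    x = complete.to_numpy(float)
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (len(x) - 1)
    evals, evecs = np.linalg.eigh(cov)
    load = evecs[:, np.argmax(evals)]
    if load.sum() < 0:
        load = -load
    scores = pd.Series(np.nan, index=vectors.index, dtype=float)
    scores.loc[complete.index] = xc @ load
    return scores


# ---------------------------------------------------------------------------
# binned surfaces
# ---------------------------------------------------------------------------


@dataclass
class BinSurface:
    edges1: np.ndarray
    edges2: np.ndarray
    mean: np.ndarray  # (n_bins, n_bins)
    counts: np.ndarray
    flagged: np.ndarray  # cells with < min_cell genes
    marginal1: np.ndarray
    marginal2: np.ndarray
    n_genes: int


def _rank_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-size bins by stable rank (ties broken by original order)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(values))
    return (ranks * n_bins) // len(values)


def bin_surface(
    d1: np.ndarray,
    d2: np.ndarray,
    stat: np.ndarray,
    n_bins: int = 8,
    min_cell: int = 5,
) -> BinSurface:
    """Mean of ``stat`` over an n_bins x n_bins grid of D1/D2 octiles.

    Genes are assigned to equal-size quantile bins per axis by stable rank
    (half-open intervals, last closed), so marginal counts are n/n_bins up
    to rounding.  Cells with fewer than ``min_cell`` genes are flagged.
    """
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    stat = np.asarray(stat, float)
    ok = np.isfinite(d1) & np.isfinite(d2) & np.isfinite(stat)
    n = int(ok.sum())
    if n < n_bins * n_bins:
        raise ValueError(f"need >= {n_bins * n_bins} complete genes, got {n}")
    d1, d2, stat = d1[ok], d2[ok], stat[ok]
    b1 = _rank_bins(d1, n_bins)
    b2 = _rank_bins(d2, n_bins)
    q = np.linspace(0, 1, n_bins + 1)
    edges1 = np.quantile(d1, q)
    edges2 = np.quantile(d2, q)
    counts = np.zeros((n_bins, n_bins), dtype=int)
    sums = np.zeros((n_bins, n_bins), dtype=float)
    np.add.at(counts, (b1, b2), 1)
    np.add.at(sums, (b1, b2), stat)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinSurface(
        edges1=edges1,
        edges2=edges2,
        mean=mean,
        counts=counts,
        flagged=counts < min_cell,
        marginal1=np.bincount(b1, minlength=n_bins),
        marginal2=np.bincount(b2, minlength=n_bins),
        n_genes=n,
    )


# ---------------------------------------------------------------------------
# imbalance gene sets and enrichment
# ---------------------------------------------------------------------------


@dataclass
class ImbalanceSet:
    pair: str
    genes: tuple[str, ...]
    d_diff: float
    fst_min: float


def select_imbalance(
    pair_table: pd.DataFrame,
    d_diff: float = 2.5,
    fst_min: float = 0.3,
    use_std: bool = True,
) -> ImbalanceSet:
    """Genes with |D1 - D2| > d_diff and F_ST > fst_min (strict inequalities).

    With ``use_std`` (default) the difference is taken on the standardized
    D_NS scale used in the models (columns D1/D2); otherwise raw D_NS
    (columns D1_raw/D2_raw).  Output gene order is deterministic (sorted).
    """
    c1, c2 = ("D1", "D2") if use_std else ("D1_raw", "D2_raw")
    t = pair_table.dropna(subset=[c1, c2, "fst"])
    keep = ((t[c1] - t[c2]).abs() > d_diff) & (t["fst"] > fst_min)
    genes = tuple(sorted(t.loc[keep, "gene_id"].astype(str)))
    pair = str(pair_table["pair"].iloc[0]) if len(pair_table) else ""
    return ImbalanceSet(pair=pair, genes=genes, d_diff=d_diff, fst_min=fst_min)


def hypergeom_enrichment(
    gene_set: set[str],
    universe: set[str],
    term_map: dict[str, set[str]],
    p_cut: float = 0.05,
    min_genes: int = 2,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation test of each term in ``gene_set``.

    For a term with K genes in the universe of N, and a set of n genes of
    which k are in the term, p = P(X >= k) with X ~ Hypergeom(N, K, n).
    Terms with no universe genes are skipped.  Rows with p < ``p_cut`` (or
    Benjamini-Hochberg-adjusted p when ``bh_correct``) and k >= ``min_genes``
    are returned sorted by (p, term_id).
    """
    if not gene_set <= universe:
        raise ValueError("gene set is not a subset of the universe")
    n_univ = len(universe)
    n_set = len(gene_set)
    rows = []
    for term_id in sorted(term_map):
        term_genes = term_map[term_id] & universe
        big_k = len(term_genes)
        if big_k == 0:
            continue
        k = len(gene_set & term_genes)
        p = float(sps.hypergeom.sf(k - 1, n_univ, big_k, n_set))
        rows.append((term_id, k, big_k, n_set, n_univ, p))
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    if df.empty:
        return df
    if bh_correct:
        m = len(df)
        order = np.argsort(df["p"].to_numpy(), kind="stable")
        adj = np.empty(m)
        prev = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            i = m - rank_from_end  # 1-based rank of this p
            prev = min(prev, df["p"].iloc[idx] * m / i)
            adj[idx] = prev
        df["p_bh"] = adj
        keep = (df["p_bh"] < p_cut) & (df["k"] >= min_genes)
    else:
        keep = (df["p"] < p_cut) & (df["k"] >= min_genes)
    out = df[keep].sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# class comparisons and resampling
# ---------------------------------------------------------------------------


def bc_bootstrap_ci(
    values: np.ndarray,
    B: int = 2000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected percentile bootstrap CI of the mean.

    The bias correction shifts the percentile endpoints by
    z0 = Phi^-1(fraction of bootstrap means below the observed mean).
    A constant input yields a zero-width interval at the constant.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    n = len(values)
    if n == 0:
        return float("nan"), float("nan")
    if np.ptp(values) == 0:
        return float(values[0]), float(values[0])
    idx = rng.integers(0, n, size=(B, n))
    boot = values[idx].mean(axis=1)
    obs = values.mean()
    prop = np.clip((boot < obs).mean(), 1.0 / (2 * B), 1 - 1.0 / (2 * B))
    z0 = sps.norm.ppf(prop)
    lo = sps.norm.cdf(2 * z0 + sps.norm.ppf(alpha / 2))
    hi = sps.norm.cdf(2 * z0 + sps.norm.ppf(1 - alpha / 2))
    return (
        float(np.quantile(boot, lo)),
        float(np.quantile(boot, hi)),
    )


@dataclass
class ClassComparison:
    label: str
    pair: str
    n_in: int
    n_out: int
    mean_in: float
    mean_out: float
    ci_in: tuple[float, float]
    ci_out: tuple[float, float]
    t: float
    df: float
    p: float


def class_compare(
    values_in: np.ndarray,
    values_out: np.ndarray,
    label: str = "",
    pair: str = "",
    B: int = 2000,
    seed: int = 0,
    min_members: int = 5,
) -> ClassComparison:
    """Welch two-sample comparison of a gene class against its complement.

    Unequal-variance t with Welch-Satterthwaite df, plus bias-corrected
    percentile bootstrap CIs of each class mean (resampling genes within
    class, seeded).
    """
    vin = np.asarray(values_in, float)
    vin = vin[np.isfinite(vin)]
    vout = np.asarray(values_out, float)
    vout = vout[np.isfinite(vout)]
    if len(vin) < min_members:
        raise ValueError(f"class {label!r} has {len(vin)} members < {min_members}")
    t, p = sps.ttest_ind(vin, vout, equal_var=False)
    # Welch-Satterthwaite df
    s1, s2 = vin.var(ddof=1) / len(vin), vout.var(ddof=1) / len(vout)
    df = (s1 + s2) ** 2 / (s1**2 / (len(vin) - 1) + s2**2 / (len(vout) - 1))
    rng = np.random.default_rng(seed)
    return ClassComparison(
        label=label,
        pair=pair,
        n_in=len(vin),
        n_out=len(vout),
        mean_in=float(vin.mean()),
        mean_out=float(vout.mean()),
        ci_in=bc_bootstrap_ci(vin, B=B, seed=rng),
        ci_out=bc_bootstrap_ci(vout, B=B, seed=rng),
        t=float(t),
        df=float(df),
        p=float(p),
    )


def _anova_f(y: np.ndarray, groups: np.ndarray, k: int) -> float:
    n = len(y)
    counts = np.bincount(groups, minlength=k).astype(float)
    sums = np.bincount(groups, weights=y, minlength=k)
    means = sums / counts
    grand = y.mean()
    ssb = (counts * (means - grand) ** 2).sum()
    sst = ((y - grand) ** 2).sum()
    ssw = sst - ssb
    return float((ssb / (k - 1)) / (ssw / (n - k)))


@dataclass
class SexBiasResult:
    bins: pd.DataFrame  # bin, bias_class, quartile, n, mean, ci_lo, ci_hi
    F: float
    p_perm: float
    n_perm: int


def sexbias_bins(
    expression: pd.DataFrame,
    gene_table: pd.DataFrame,
    response: str,
    n_perm: int = 10000,
    seed: int = 0,
    B_ci: int = 1000,
) -> SexBiasResult:
    """Divergence across eight sex-bias expression bins with a permutation test.

    Female-biased (FBG) and male-biased (MBG) genes are each split into four
    equal-size quantile bins by their log2 fold-change (stable rank order),
    giving eight bins.  A one-way ANOVA F statistic of the transformed
    response across bins is referred to its permutation distribution
    (response shuffled across genes, add-one p).  Per-bin means carry
    bias-corrected bootstrap CIs.
    """
    merged = expression.merge(gene_table, on="gene_id")
    merged = merged[merged["bias_class"].isin(["FBG", "MBG"])]
    merged = merged.dropna(subset=[response, "log2fc_sex"]).reset_index(drop=True)
    bins = np.full(len(merged), -1)
    for offset, cls in ((0, "FBG"), (4, "MBG")):
        mask = (merged["bias_class"] == cls).to_numpy()
        if mask.sum() < 8:
            raise ValueError(f"too few {cls} genes to form quartile bins")
        bins[mask] = offset + _rank_bins(merged.loc[mask, "log2fc_sex"].to_numpy(), 4)
    merged["bin"] = bins
    counts = merged.groupby("bin").size()
    if (counts < 2).any() or len(counts) < 8:
        raise ValueError("every sex-bias bin needs >= 2 genes")
    y = merged[response].to_numpy(float)
    g = merged["bin"].to_numpy()
    f_obs = _anova_f(y, g, 8)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if _anova_f(rng.permutation(y), g, 8) >= f_obs:
            exceed += 1
    p_perm = (1 + exceed) / (1 + n_perm)
    rows = []
    for b in range(8):
        vals = y[g == b]
        lo, hi = bc_bootstrap_ci(vals, B=B_ci, seed=rng)
        rows.append(
            (b, "FBG" if b < 4 else "MBG", b % 4, len(vals), vals.mean(), lo, hi)
        )
    bins_df = pd.DataFrame(
        rows, columns=["bin", "bias_class", "quartile", "n", "mean", "ci_lo", "ci_hi"]
    )
    return SexBiasResult(bins=bins_df, F=f_obs, p_perm=p_perm, n_perm=n_perm)


# ---------------------------------------------------------------------------
# fixation GLM (quasi-Poisson)
# ---------------------------------------------------------------------------


@dataclass
class FixationFit:
    form: str
    dispersion: float
    tests: pd.DataFrame  # term, llr_scaled, df, p
    coefficients: pd.DataFrame
    n: int
    convention: str = "scaled-deviance LLR vs chi2 (quasi-likelihood)"


def _poisson_fit(y: np.ndarray, x: np.ndarray):
    return sm.GLM(y, x, family=sm.families.Poisson()).fit()


def fixation_glm(
    table: pd.DataFrame,
    form: str = "binned9",
    n_bins: int = 9,
) -> FixationFit:
    """Quasi-Poisson GLM of NS-polymorphism counts on expression and class.

    ``table`` needs columns ``n_pops_poly`` (number of populations, 0-3, in
    which the gene segregates at non-synonymous sites), ``fpkm`` and the
    boolean ``is_focal`` gene-class flag.  Fitted with Poisson errors and a
    log link; inference uses likelihood-ratio (deviance) statistics scaled
    by the empirical dispersion (Pearson chi2 / df of the full model),
    referred to chi-square.

    form="binned9"
        nine equal-size expression bins x class x interaction; tests the
        expression effect (df 8), the class effect (df 1) and their
        interaction (df 8).
    form="quadratic"
        mean-centered log FPKM, its square, class, and the class x square
        interaction; tests the curvature difference between classes (df 1).
    """
    df = table.dropna(subset=["n_pops_poly", "fpkm", "is_focal"]).copy()
    y = df["n_pops_poly"].to_numpy()
    if not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("response must be integer counts")
    y = y.astype(int)
    if y.min() < 0 or y.max() > 3:
        raise ValueError("response must be in 0..3 (populations polymorphic)")
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: all genes identical (zero deviance)")
    cls = df["is_focal"].to_numpy(bool).astype(float)
    n = len(df)

    def _design(cols: dict[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
        names = ["const"] + list(cols)
        x = np.column_stack([np.ones(n)] + [cols[c] for c in cols])
        return x, names

    if form == "binned9":
        b = _rank_bins(df["fpkm"].to_numpy(float), n_bins)
        bin_dummies = {f"bin{i}": (b == i).astype(float) for i in range(1, n_bins)}
        inter = {f"bin{i}:class": (b == i).astype(float) * cls for i in range(1, n_bins)}
        full_cols = {**bin_dummies, "class": cls, **inter}
        comparisons = [
            ("expression", {**{f"bin{i}": bin_dummies[f"bin{i}"] for i in range(1, n_bins)}}),
            ("class", {"class": cls}),
            ("expression:class", inter),
        ]
    elif form == "quadratic":
        x1 = np.log(np.maximum(df["fpkm"].to_numpy(float), 1e-9))
        x1 = x1 - x1.mean()
        x2 = x1**2
        full_cols = {"logfpkm": x1, "logfpkm_sq": x2, "class": cls,
                     "class:logfpkm_sq": cls * x2}
        comparisons = [("class:logfpkm_sq", {"class:logfpkm_sq": cls * x2})]
    else:
        raise ValueError("form must be 'binned9' or 'quadratic'")

    x_full, names = _design(full_cols)
    res_full = _poisson_fit(y, x_full)
    dispersion = float(res_full.pearson_chi2 / res_full.df_resid)
    tests = []
    for term, dropped in comparisons:
        red_cols = {k: v for k, v in full_cols.items() if k not in dropped}
        x_red, _ = _design(red_cols)
        res_red = _poisson_fit(y, x_red)
        ddf = len(dropped)
        llr = float((res_red.deviance - res_full.deviance) / dispersion)
        tests.append((term, llr, ddf, float(sps.chi2.sf(llr, ddf))))
    coef = pd.DataFrame(
        {
            "term": names,
            "beta": res_full.params,
            "se": res_full.bse * np.sqrt(dispersion),
        }
    )
    return FixationFit(
        form=form,
        dispersion=dispersion,
        tests=pd.DataFrame(tests, columns=["term", "llr_scaled", "df", "p"]),
        coefficients=coef,
        n=n,
    )


def correlate(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r over pairwise-complete observations (NaN on zero variance)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need >= 3 complete pairs")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
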