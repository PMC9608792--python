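"""Orchestration: simulate -> SFS stats -> divergence -> covariation models.

A single YAML config drives the whole run; every stage writes TSVs into the
output directory together with a JSON run manifest (config snapshot, seeds,
input hashes, versions, per-stage row counts) and a plain-text report.  All
randomness derives from the one global seed; deterministic stages re-run
bit-identically from the manifest.

Config schema (all sections optional unless noted)::

    seed: 7
    simulate:                  # either this ...
      scenario: DISCORDANT_ENGINEERED
      n_genes: 300
      ...                      # any ScenarioConfig field
    inputs:                    # ... or this (paths to existing files)
      sync: counts.sync        # required when no simulate section
      bed: genes.bed           # required
      site_classes: site_classes.tsv   # required
      gene_classes: gene_classes.tsv
      term_map: term_map.tsv
      expression: expression.tsv
    pools:
      names: [B, C, Y]
      haploid_sizes: [400, 400, 400]
    filters: {min_minor_count: 2, min_depth: 10, max_depth: 500}
    models:
      min_snps: 3
      imbalance: {d_diff: 2.5, fst_min: 0.3}
      bootstrap_B: 2000
      n_perm: 10000
      focal_label: DISCORDANT
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import covariation as cov
from .divergence import pair_divergence_table
from .io_formats import (
    read_expression,
    read_gene_annotation,
    read_gene_classes,
    read_sync,
    read_term_map,
    write_table,
)
from .sfs import FilterParams, filter_sites, gene_population_stats
from .simulate import ScenarioConfig, SimDataset, emit_dataset

logger = logging.getLogger(__name__)

_REQUIRED_INPUTS = ("sync", "bed", "site_classes")


class ConfigError(ValueError):
    """Raised when the run config violates the schema."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    known = {"seed", "simulate", "inputs", "pools", "filters", "models"}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "simulate" not in cfg:
        inputs = cfg.get("inputs")
        if not isinstance(inputs, dict):
            raise ConfigError("config needs either 'simulate' or 'inputs'")
        missing = [k for k in _REQUIRED_INPUTS if k not in inputs]
        if missing:
            raise ConfigError(f"missing input keys: {missing}")
    if "simulate" in cfg:
        valid = {f.name for f in dataclasses.fields(ScenarioConfig)}
        bad = set(cfg["simulate"]) - valid
        if bad:
            raise ConfigError(f"unknown simulate keys: {sorted(bad)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_pair_table(
    gene_stats: pd.DataFrame,
    divergence: pd.DataFrame,
    genes: pd.DataFrame,
    pop_x: int,
    pop_y: int,
) -> pd.DataFrame:
    """Merge per-gene statistics of one population pair into a model table.

    Columns: gene-level covariates plus ``D1/D2`` (standardized D_NS of the
    two populations), ``D1_raw/D2_raw``, ``ratio1/ratio2`` (log10 pi_N/pi_S)
    and the pair's divergence statistics.
    """
    sx = gene_stats[gene_stats["pop"] == pop_x][
        ["gene_id", "D_ns", "D_ns_std", "ratio_log10", "S"]
    ].rename(
        columns={"D_ns": "D1_raw", "D_ns_std": "D1", "ratio_log10": "ratio1", "S": "S1"}
    )
    sy = gene_stats[gene_stats["pop"] == pop_y][
        ["gene_id", "D_ns", "D_ns_std", "ratio_log10", "S"]
    ].rename(
        columns={"D_ns": "D2_raw", "D_ns_std": "D2", "ratio_log10": "ratio2", "S": "S2"}
    )
    t = divergence.merge(sx, on="gene_id").merge(sy, on="gene_id")
    t = t.merge(genes[["gene_id", "length", "gc_content"]], on="gene_id")
    return t


def _fit_rows(fit: cov.LinearFit, pair: str, model: int) -> pd.DataFrame:
    t = fit.table.copy()
    t.insert(0, "response", fit.response)
    t.insert(1, "pair", pair)
    t.insert(2, "model", model)
    t["r2"] = fit.r2
    t["n"] = fit.n
    return t


def run_all(cfg: dict, outdir: str | Path) -> dict:
    """Execute every stage in dependency order; returns a result summary dict.

    Writes into ``outdir``: the simulated input bundle (when configured),
    ``gene_stats.tsv``, ``divergence.tsv``, ``pair_table_<pair>.tsv``,
    ``fits.tsv``, ``repeatability.tsv``, ``surface_<pair>.tsv``,
    ``imbalance.tsv``, ``enrichment.tsv``, ``class_compare.tsv``,
    ``sexbias.tsv``, ``fixation.tsv`` (as applicable), ``manifest.json`` and
    ``report.txt``.
    """
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    models_cfg = cfg.get("models", {})
    row_counts: dict[str, int] = {}

    # ---- stage: inputs (simulated or on disk) ---------------------------
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"])
        sim_kwargs.setdefault("seed", seed)
        if "optima" in sim_kwargs:
            sim_kwargs["optima"] = tuple(sim_kwargs["optima"])
        scen = ScenarioConfig(**sim_kwargs)
        dataset: SimDataset = emit_dataset(scen, outdir / "inputs")
        inputs = {k: str(v) for k, v in dataset.paths.items()}
        n_pools = scen.n_pops
        pool_sizes = [scen.n_pool_haploid] * n_pools
        pool_names = list(dataset.pool_names)
    else:
        inputs = dict(cfg["inputs"])
        pools = cfg.get("pools", {})
        pool_sizes = list(pools.get("haploid_sizes", [400, 400, 400]))
        pool_names = list(pools.get("names", [str(i) for i in range(len(pool_sizes))]))
        n_pools = len(pool_sizes)
    if "pools" in cfg and "simulate" in cfg:
        pool_names = list(cfg["pools"].get("names", pool_names))

    for key in _REQUIRED_INPUTS:
        if not Path(inputs[key]).exists():
            raise ConfigError(f"input file missing: {key} = {inputs[key]}")

    genes, site_classes = read_gene_annotation(inputs["bed"], inputs["site_classes"])
    row_counts["genes"] = len(genes)
    row_counts["classified_sites"] = len(site_classes)

    # ---- stage: site filtering -----------------------------------------
    fcfg = cfg.get("filters", {})
    params = FilterParams(
        min_minor_count=int(fcfg.get("min_minor_count", 2)),
        min_depth=int(fcfg.get("min_depth", 10)),
        max_depth=int(fcfg.get("max_depth", 500)),
    )
    sites, counters = filter_sites(
        read_sync(inputs["sync"], pool_sizes), site_classes, pool_sizes, params
    )
    row_counts["filtered_site_rows"] = len(sites)
    logger.info("site filtering: %s", counters)

    # ---- stage: per-population SFS statistics --------------------------
    min_snps = int(models_cfg.get("min_snps", 3))
    stats = pd.concat(
        [gene_population_stats(sites, pool, min_snps=min_snps) for pool in range(n_pools)],
        ignore_index=True,
    )
    stats["pop_name"] = stats["pop"].map(dict(enumerate(pool_names)))
    write_table(stats, outdir / "gene_stats.tsv")
    row_counts["gene_stats"] = len(stats)

    # ---- stage: pairwise divergence ------------------------------------
    pairs = [(x, y) for x in range(n_pools) for y in range(x + 1, n_pools)]
    pair_names = {p: f"{pool_names[p[0]]}-{pool_names[p[1]]}" for p in pairs}
    div = pd.concat(
        [
            pair_divergence_table(
                sites, x, y, pool_sizes[x], pool_sizes[y], pair_names[(x, y)]
            )
            for x, y in pairs
        ],
        ignore_index=True,
    )
    write_table(div, outdir / "divergence.tsv")
    row_counts["divergence"] = len(div)

    # ---- stage: covariation models -------------------------------------
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    boot_b = int(models_cfg.get("bootstrap_B", 2000))
    imb_cfg = models_cfg.get("imbalance", {})
    d_diff = float(imb_cfg.get("d_diff", 2.5))
    fst_min = float(imb_cfg.get("fst_min", 0.3))

    pair_tables: dict[str, pd.DataFrame] = {}
    fit_frames, surface_rows, imb_rows, enrich_frames = [], [], [], []
    summary: dict = {"pairs": {}, "seed": seed}
    for (x, y) in pairs:
        pname = pair_names[(x, y)]
        pt = build_pair_table(stats, div[div["pair"] == pname], genes, x, y)
        pair_tables[pname] = pt
        write_table(pt, outdir / f"pair_table_{pname}.tsv")

        fst_vals = pt["fst"].dropna().to_numpy()
        ci = cov.bc_bootstrap_ci(fst_vals, B=boot_b, seed=rng)
        psum = {
            "mean_fst": float(fst_vals.mean()),
            "mean_fst_ci": ci,
            "n_genes_fst": int(len(fst_vals)),
        }

        for model in (1, 2):
            for fitter, resp in ((cov.fit_fst_model, "fst"), (cov.fit_dxy_model, "dxy")):
                try:
                    fit = fitter(pt, model=model)
                except ValueError as exc:
                    logger.warning("%s model %d (%s) skipped: %s", resp, model, pname, exc)
                    continue
                fit_frames.append(_fit_rows(fit, pname, model))
                if resp == "fst" and model == 1:
                    psum["interaction_beta"] = fit.beta("D1xD2")
                    psum["interaction_p"] = fit.pvalue("D1xD2")
                    psum["fst_model1_r2"] = fit.r2
        try:
            psum["interaction_f2"] = cov.interaction_f2(pt, model=1)
        except ValueError:
            psum["interaction_f2"] = float("nan")

        surf = cov.bin_surface(
            pt["D1"].to_numpy(), pt["D2"].to_numpy(), pt["fst"].to_numpy()
        ) if pt[["D1", "D2", "fst"]].dropna().shape[0] >= 64 else None
        if surf is not None:
            sdf = pd.DataFrame(surf.mean)
            sdf.insert(0, "d1_bin", range(8))
            sdf.columns = ["d1_bin"] + [f"d2_bin{j}" for j in range(8)]
            sdf.insert(0, "pair", pname)
            surface_rows.append(sdf)

        imb = cov.select_imbalance(pt, d_diff=d_diff, fst_min=fst_min)
        imb_rows.extend((pname, g) for g in imb.genes)
        psum["n_imbalance"] = len(imb.genes)

        if "term_map" in inputs and Path(inputs["term_map"]).exists():
            term_map = read_term_map(inputs["term_map"])
            universe = set(pt.dropna(subset=["D1", "D2", "fst"])["gene_id"].astype(str))
            enr = cov.hypergeom_enrichment(
                set(imb.genes) & universe, universe, term_map
            )
            if not enr.empty:
                enr.insert(0, "pair", pname)
                enrich_frames.append(enr)
        summary["pairs"][pname] = psum

    write_table(pd.concat(fit_frames, ignore_index=True), outdir / "fits.tsv")
    if surface_rows:
        write_table(pd.concat(surface_rows, ignore_index=True), outdir / "surfaces.tsv")
    write_table(
        pd.DataFrame(imb_rows, columns=["pair", "gene_id"]), outdir / "imbalance.tsv"
    )
    if enrich_frames:
        write_table(pd.concat(enrich_frames, ignore_index=True), outdir / "enrichment.tsv")

    # ---- repeatability (PCA + ICC) -------------------------------------
    rep_rows = []
    for metric, col in (("fst_logit", "fst_logit"), ("dxy_log10", "dxy_log10")):
        mat = pd.DataFrame(
            {p: t.set_index("gene_id")[col] for p, t in pair_tables.items()}
        )
        if len(mat.dropna()) >= 3:
            rep = cov.repeatability(mat)
            rep_rows.append(
                {
                    "metric": metric,
                    "icc_R": rep.icc_R,
                    "F": rep.F,
                    "df1": rep.df1,
                    "df2": rep.df2,
                    "p": rep.p,
                    "pc1_fraction": rep.pc1_variance_fraction,
                    "pc1_loadings": ";".join(f"{v:.4f}" for v in rep.pc1_loadings),
                    "n_genes": rep.n_genes,
                }
            )
            summary[f"icc_{metric}"] = rep.icc_R
            summary[f"pc1_{metric}"] = rep.pc1_variance_fraction
    if rep_rows:
        write_table(pd.DataFrame(rep_rows), outdir / "repeatability.tsv")

    # ---- gene-class contrasts ------------------------------------------
    if "gene_classes" in inputs and Path(inputs["gene_classes"]).exists():
        classes = read_gene_classes(inputs["gene_classes"])
        cc_rows = []
        for label, members in classes.groupby("label"):
            gene_set = set(members["gene_id"])
            for pname, pt in pair_tables.items():
                mask = pt["gene_id"].isin(gene_set)
                for respcol in ("fst_logit", "dxy_log10"):
                    try:
                        res = cov.class_compare(
                            pt.loc[mask, respcol].to_numpy(),
                            pt.loc[~mask, respcol].to_numpy(),
                            label=label,
                            pair=pname,
                            B=boot_b,
                            seed=seed,
                        )
                    except ValueError:
                        continue
                    cc_rows.append(
                        {
                            "label": label,
                            "pair": pname,
                            "response": respcol,
                            "n_in": res.n_in,
                            "mean_in": res.mean_in,
                            "ci_lo": res.ci_in[0],
                            "ci_hi": res.ci_in[1],
                            "mean_out": res.mean_out,
                            "t": res.t,
                            "df": res.df,
                            "p": res.p,
                        }
                    )
        if cc_rows:
            write_table(pd.DataFrame(cc_rows), outdir / "class_compare.tsv")

    # ---- sex-bias bins and fixation GLM --------------------------------
    if "expression" in inputs and Path(inputs["expression"]).exists():
        expr = read_expression(inputs["expression"])
        n_perm = int(models_cfg.get("n_perm", 10000))
        sb_rows = []
        for pname, pt in pair_tables.items():
            try:
                sb = cov.sexbias_bins(
                    expr, pt[["gene_id", "fst_logit", "dxy_log10"]],
                    response="fst_logit", n_perm=n_perm, seed=seed,
                )
            except ValueError as exc:
                logger.warning("sexbias (%s) skipped: %s", pname, exc)
                continue
            b = sb.bins.copy()
            b.insert(0, "pair", pname)
            b["F"] = sb.F
            b["p_perm"] = sb.p_perm
            sb_rows.append(b)
        if sb_rows:
            write_table(pd.concat(sb_rows, ignore_index=True), outdir / "sexbias.tsv")

        focal = models_cfg.get("focal_label")
        if focal is None and "gene_classes" in inputs and Path(inputs["gene_classes"]).exists():
            cls = read_gene_classes(inputs["gene_classes"])
            focal = cls["label"].iloc[0] if len(cls) else None
        if focal is not None:
            cls = read_gene_classes(inputs["gene_classes"])
            focal_set = set(cls.loc[cls["label"] == focal, "gene_id"])
            npoly = (
                stats.assign(poly=(stats["S"] > 0).astype(int))
                .groupby("gene_id")["poly"]
                .sum()
                .rename("n_pops_poly")
                .reset_index()
            )
            fx = npoly.merge(expr[["gene_id", "fpkm"]], on="gene_id")
            fx["is_focal"] = fx["gene_id"].isin(focal_set)
            fx_rows = []
            for form in ("binned9", "quadratic"):
                try:
                    fit = cov.fixation_glm(fx, form=form)
                except ValueError as exc:
                    logger.warning("fixation GLM (%s) skipped: %s", form, exc)
                    continue
                t = fit.tests.copy()
                t.insert(0, "form", form)
                t["dispersion"] = fit.dispersion
                fx_rows.append(t)
            if fx_rows:
                write_table(pd.concat(fx_rows, ignore_index=True), outdir / "fixation.tsv")

    # ---- manifest and report -------------------------------------------
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "inputs": {k: {"path": str(v), "sha256": _sha256(Path(v))}
                   for k, v in inputs.items() if Path(v).exists()},
        "row_counts": row_counts,
        "pool_names": pool_names,
        "pool_sizes": pool_sizes,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    (outdir / "report.txt").write_text(report(outdir))
    return summary


@dataclasses.dataclass
class ScenarioRun:
    """Result bundle of :func:`run_scenario`."""

    dataset: SimDataset
    genes: pd.DataFrame
    sites: pd.DataFrame
    gene_stats: pd.DataFrame
    divergence: pd.DataFrame
    pair_tables: dict[str, pd.DataFrame]

    @property
    def truth(self) -> pd.DataFrame:
        return self.dataset.truth.genes


def run_scenario(
    scenario_config: ScenarioConfig,
    workdir: str | Path,
    params: FilterParams = FilterParams(),
    min_snps: int = 3,
) -> ScenarioRun:
    """Simulate one scenario and push it through stats + divergence.

    End-to-end through the text formats: the dataset is written to
    ``workdir`` and read back exactly as external data would be.  Pair
    tables are keyed ``"<x>-<y>"`` by population index.
    """
    dataset = emit_dataset(scenario_config, workdir)
    pool_sizes = [scenario_config.n_pool_haploid] * scenario_config.n_pops
    genes, site_classes = read_gene_annotation(
        dataset.paths["bed"], dataset.paths["site_classes"]
    )
    sites, _ = filter_sites(
        read_sync(dataset.paths["sync"], pool_sizes), site_classes, pool_sizes, params
    )
    stats = pd.concat(
        [
            gene_population_stats(sites, pool, min_snps=min_snps)
            for pool in range(scenario_config.n_pops)
        ],
        ignore_index=True,
    )
    pair_tables = {}
    div_frames = []
    for x in range(scenario_config.n_pops):
        for y in range(x + 1, scenario_config.n_pops):
            name = f"{x}-{y}"
            d = pair_divergence_table(
                sites, x, y, pool_sizes[x], pool_sizes[y], name
            )
            div_frames.append(d)
            pair_tables[name] = build_pair_table(stats, d, genes, x, y)
    return ScenarioRun(
        dataset=dataset,
        genes=genes,
        sites=sites,
        gene_stats=stats,
        divergence=pd.concat(div_frames, ignore_index=True),
        pair_tables=pair_tables,
    )


def report(outdir: str | Path) -> str:
    """Plain-text summary of a finished run directory."""
    outdir = Path(outdir)
    if not (outdir / "manifest.json").exists():
        raise FileNotFoundError(f"no manifest.json in {outdir}")
    manifest = json.loads((outdir / "manifest.json").read_text())
    lines = [
        "polyfoot run report",
        "===================",
        f"version {manifest['version']}  seed {manifest['seed']}",
        "",
    ]
    div_path = outdir / "divergence.tsv"
    if div_path.exists():
        div = pd.read_csv(div_path, sep="\t", na_values="NA")
        lines.append("mean F_ST / d_XY per pair:")
        for pair, g in div.groupby("pair"):
            lines.append(
                f"  {pair}: F_ST = {g['fst'].mean():.4f}  "
                f"d_XY = {g['dxy'].mean():.6f}  (n = {g['fst'].notna().sum()})"
            )
        lines.append("")
    rep_path = outdir / "repeatability.tsv"
    if rep_path.exists():
        rep = pd.read_csv(rep_path, sep="\t", na_values="NA")
        for _, r in rep.iterrows():
            lines.append(
                f"repeatability ({r['metric']}): ICC R = {r['icc_R']:.3f}  "
                f"PC1 = {100 * r['pc1_fraction']:.1f}%  "
                f"F({r['df1']:.0f},{r['df2']:.0f}) = {r['F']:.2f}, p = {r['p']:.3g}"
            )
        lines.append("")
    fits_path = outdir / "fits.tsv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path, sep="\t", na_values="NA")
        m1 = fits[(fits["model"] == 1) & (fits["term"] == "D1xD2")]
        if len(m1):
            lines.append("D1 x D2 interaction (model 1):")
            for _, r in m1.iterrows():
                lines.append(
                    f"  {r['response']} {r['pair']}: beta = {r['beta']:.3f} "
                    f"(SE {r['se']:.3f}), t = {r['t']:.2f}, p = {r['p']:.3g}, "
                    f"R2 = {r['r2']:.3f}"
                )
            lines.append("")
    imb_path = outdir / "imbalance.tsv"
    if imb_path.exists():
        imb = pd.read_csv(imb_path, sep="\t", na_values="NA")
        if len(imb):
            counts = imb.groupby("pair").size()
            lines.append(
                "imbalance gene sets: "
                + "  ".join(f"{p}: {n}" for p, n in counts.items())
            )
        else:
            lines.append("imbalance gene sets: empty")
        lines.append("")
    enr_path = outdir / "enrichment.tsv"
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t", na_values="NA")
        lines.append("top enrichment rows:")
        for _, r in enr.sort_values("p").head(5).iterrows():
            lines.append(
                f"  {r['pair']} {r['term_id']}: k={r['k']}/{r['n']} "
                f"K={r['K']}/{r['N']}  p = {r['p']:.3g}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
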