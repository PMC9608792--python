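"""Forward Wright-Fisher simulator of multi-gene population divergence plus a
two-stage pool-sequencing emulator.

The generator produces the study conditions the pipeline is designed for:
three populations diverged from a common ancestor, pooled sequencing of 200
diploid males per population (400 haploid genomes) at ~125x mean depth,
genes carrying non-synonymous (potentially selected) and synonymous (always
neutral) sites, within-population synonymous diversity around pi_S ~ 0.022
and called SNP densities of a few per kb.

Model
-----
Each gene carries ``n_ns_loci`` non-synonymous and ``n_syn_loci`` synonymous
biallelic loci inside a ``gene_length``-bp interval, freely recombining (no
linkage map).  Mutation is reversible at per-site rate ``mu`` in each
direction, so the neutral stationary allele-frequency distribution is
Beta(4N*mu, 4N*mu); loci are initialised by drawing from it, which places the
ancestor exactly at mutation-drift equilibrium without a long burn-in.  An
optional ``burn_in`` settle phase then runs forward (used to let selected
scenarios reach their own balance) before the ancestor is copied into
``n_pops`` daughter populations that evolve independently for ``g_split``
generations.

Scenarios
---------
NEUTRAL_INDEPENDENT
    No selection anywhere (omega = infinity).  Neutral unlinked loci evolve
    by the exact marginal binomial allele-frequency update, which is
    identical in law to the individual-based diploid model with free
    recombination.
STABILIZING_SHARED / STABILIZING_SHIFTED
    The gene's NS loci additively encode a trait z = sum(alpha * allele
    count) under Gaussian stabilizing viability selection
    w(z) = exp(-(z - theta_opt)^2 / (2 omega^2)); effect sizes |alpha| are
    exponential with random signs.  SHARED keeps one optimum in all
    populations, SHIFTED moves the optima apart after the split.  These
    scenarios run the individual-based diploid simulation for NS loci.
DISCORDANT_ENGINEERED
    For a labelled fraction of genes, after the split one population
    receives directional selection driving each NS locus's ancestral-major
    allele up (the default coefficient satisfies s * g_split ~ 3, so swept
    loci end at low but sequencing-detectable minor frequencies — an excess
    of rare variants, negative Tajima's D) while a second population
    receives heterozygote advantage at the same loci (frequencies pulled to
    1/2, positive D).  Selected NS loci
    of these genes start from engineered mid-frequency standing variation
    (Beta(2, 2)) so the contrast has material to act on.  This is the
    deterministic generator of the imbalance footprint; remaining genes and
    the third population are neutral.

Pool sequencing is two-stage per site: ``n_pool_haploid`` chromosomes are
drawn binomially from the population frequency, then a Poisson(depth_mean)
number of reads is drawn binomially from the pool frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .divergence import hudson_fst
from .io_formats import SyncRecord, write_gene_bed, write_sync, write_table

logger = logging.getLogger(__name__)

SCENARIOS = (
    "NEUTRAL_INDEPENDENT",
    "STABILIZING_SHARED",
    "STABILIZING_SHIFTED",
    "DISCORDANT_ENGINEERED",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Simulator parameters.

    Defaults are the study conditions: N = 500 diploids (desk-scale stand-in
    for a large laboratory population), 3 populations, 250 generations since
    the split (pairwise F_ST around 0.2), theta_site = 4*N*mu = 0.022
    matching the synonymous diversity anchor, 30 NS + 30 SYN informative
    sites per 1-kb gene (a called SNP density of a few per kb at 125x,
    200-male pools).
    """

    scenario: str = "NEUTRAL_INDEPENDENT"
    n_diploid: int = 500
    n_pops: int = 3
    g_split: int = 250
    n_genes: int = 300
    n_ns_loci: int = 30
    n_syn_loci: int = 30
    gene_length: int = 1000
    theta_site: float = 0.022
    mu: float | None = None
    omega: float = math.inf
    optima: tuple[float, ...] = (0.0, 0.0, 0.0)
    effect_scale: float = 0.25
    discordant_fraction: float = 0.2
    shared_sweep_fraction: float = 0.1
    shared_balancing_fraction: float = 0.1
    discordant_loci_fraction: float = 0.5
    s_directional: float = 0.016
    s_balancing: float = 0.1
    burn_in: int = 0
    depth_mean: float = 125.0
    n_pool_haploid: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_diploid < 2:
            raise ValueError("n_diploid must be >= 2")
        if self.mu is not None and self.mu <= 0:
            raise ValueError("mu must be positive")
        if not (self.omega > 0):
            raise ValueError("omega must be positive (math.inf for neutral)")
        if self.depth_mean <= 0 or self.n_pool_haploid < 2:
            raise ValueError("invalid pooling parameters")
        if len(self.optima) < self.n_pops:
            raise ValueError("need one optimum per population")
        if not 0.0 <= self.discordant_fraction <= 1.0:
            raise ValueError("discordant_fraction must be in [0, 1]")

    @property
    def mutation_rate(self) -> float:
        """Per-site, per-generation, per-direction mutation rate."""
        if self.mu is not None:
            return self.mu
        return self.theta_site / (4.0 * self.n_diploid)

    @property
    def loci_per_gene(self) -> int:
        return self.n_ns_loci + self.n_syn_loci


@dataclass
class SimTruth:
    """Ground truth of one simulation run.

    ``genes`` has one row per gene (scenario class, selected-loci count and
    true per-pair F_ST / d_XY computed from the final true frequencies);
    ``selected_loci`` marks which NS locus columns were under selection.
    """

    genes: pd.DataFrame
    selected_loci: np.ndarray  # (n_genes, n_loci) bool
    true_freqs: np.ndarray  # (n_pops, n_genes, n_loci)
    effect_sizes: np.ndarray | None = None  # (n_genes, n_ns_loci) for trait scenarios


@dataclass
class SimResult:
    config: ScenarioConfig
    freqs: np.ndarray  # (n_pops, n_genes, n_loci); NS loci first
    truth: SimTruth


# ---------------------------------------------------------------------------
# Wright-Fisher machinery
# ---------------------------------------------------------------------------


def neutral_wf_evolve(
    p: np.ndarray,
    n_diploid: int,
    mu: float,
    generations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve allele frequencies by the neutral Wright-Fisher update.

    Each generation applies symmetric reversible mutation then binomial
    resampling of 2N allele copies.  This is the exact marginal law of the
    individual-based diploid model for unlinked neutral loci.
    """
    p = np.array(p, dtype=float)
    two_n = 2 * n_diploid
    for _ in range(generations):
        p = p * (1.0 - mu) + (1.0 - p) * mu
        p = rng.binomial(two_n, p) / two_n
    return p


def _selection_directional(p: np.ndarray, s: float, favor: np.ndarray) -> np.ndarray:
    """Deterministic genic directional selection toward the favoured allele."""
    q = np.where(favor, p, 1.0 - p)  # frequency of the favoured allele
    q = q * (1.0 + s) / (1.0 + s * q)
    return np.where(favor, q, 1.0 - q)


def _selection_overdominant(p: np.ndarray, s: float) -> np.ndarray:
    """Deterministic symmetric heterozygote advantage (pull toward 1/2)."""
    het = 2.0 * p * (1.0 - p)
    wbar = 1.0 + s * het
    return p * (1.0 + s * (1.0 - p)) / wbar


def _selected_wf_evolve(
    p: np.ndarray,
    n_diploid: int,
    mu: float,
    generations: int,
    rng: np.random.Generator,
    mode: str,
    s: float,
    favor: np.ndarray | None = None,
) -> np.ndarray:
    """Per-locus selection (directional / overdominant) + mutation + drift."""
    p = np.array(p, dtype=float)
    two_n = 2 * n_diploid
    for _ in range(generations):
        if mode == "directional":
            p = _selection_directional(p, s, favor)
        elif mode == "overdominant":
            p = _selection_overdominant(p, s)
        else:
            raise ValueError(mode)
        p = p * (1.0 - mu) + (1.0 - p) * mu
        p = rng.binomial(two_n, p) / two_n
    return p


def _stabilizing_wf_evolve(
    geno: np.ndarray,
    alpha: np.ndarray,
    theta_opt: float,
    omega: float,
    mu: float,
    generations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Individual-based diploid WF with Gaussian stabilizing viability selection.

    ``geno`` is (n_genes, N, L) allele counts in {0,1,2}; the trait of an
    individual is z = sum_l alpha[g, l] * geno[g, i, l]; fitness
    w = exp(-(z - theta_opt)^2 / (2 omega^2)).  Loci recombine freely:
    each offspring draws two parents (probability proportional to w) and one
    allele per parent per locus.  Genes are independent.
    """
    geno = np.array(geno, dtype=np.int8)
    n_genes, n, _ = geno.shape
    inv2w2 = 0.0 if math.isinf(omega) else 1.0 / (2.0 * omega * omega)
    for _ in range(generations):
        z = np.einsum("gnl,gl->gn", geno, alpha)
        w = np.exp(-((z - theta_opt) ** 2) * inv2w2)
        parents = np.empty((2, n_genes, n), dtype=np.int64)
        for g in range(n_genes):
            tot = w[g].sum()
            prob = w[g] / tot if tot > 0 else np.full(n, 1.0 / n)
            parents[:, g, :] = rng.choice(n, size=(2, n), p=prob)
        gidx = np.arange(n_genes)[:, None]
        gam1 = rng.binomial(1, geno[gidx, parents[0]] / 2.0)
        gam2 = rng.binomial(1, geno[gidx, parents[1]] / 2.0)
        child = (gam1 + gam2).astype(np.int8)
        gain = rng.binomial(2 - child, mu)
        loss = rng.binomial(child, mu)
        geno = (child + gain - loss).astype(np.int8)
    return geno


# ---------------------------------------------------------------------------
# scenario driver
# ---------------------------------------------------------------------------


def simulate_populations(config: ScenarioConfig) -> SimResult:
    """Run one scenario and return final true allele frequencies + ground truth.

    The returned frequency array has shape (n_pops, n_genes, loci_per_gene)
    with the NS loci in the leading columns.  All randomness flows from
    ``config.seed``; identical configs are bit-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    g, l_ns, l_syn = config.n_genes, config.n_ns_loci, config.n_syn_loci
    l_tot = l_ns + l_syn
    n = config.n_diploid
    mu = config.mutation_rate
    a = 4.0 * n * mu

    p0 = rng.beta(a, a, size=(g, l_tot))
    selected = np.zeros((g, l_tot), dtype=bool)
    scenario_class = np.array(["NEUTRAL"] * g, dtype=object)

    sweep_pop = np.full(g, -1)
    l_sel = int(round(config.discordant_loci_fraction * l_ns))
    if config.scenario == "DISCORDANT_ENGINEERED":
        # three selected gene classes on a neutral background: discordant
        # genes (the footprint generator) plus genes under *shared* positive
        # or shared balancing selection, the heterogeneous-selection
        # background a real genome carries (and which populates the
        # concordant corners of the D1 x D2 surface)
        n_disc = int(round(config.discordant_fraction * g))
        n_ssw = int(round(config.shared_sweep_fraction * g))
        n_sbal = int(round(config.shared_balancing_fraction * g))
        chosen = rng.choice(g, size=n_disc + n_ssw + n_sbal, replace=False)
        disc_idx = chosen[:n_disc]
        ssw_idx = chosen[n_disc:n_disc + n_ssw]
        sbal_idx = chosen[n_disc + n_ssw:]
        scenario_class[disc_idx] = "DISCORDANT"
        scenario_class[ssw_idx] = "SHARED_SWEEP"
        scenario_class[sbal_idx] = "SHARED_BALANCED"
        # selection touches a subset of the gene's NS loci (the same loci in
        # every population), so the gene's D lands in the tail of the
        # neutral cloud rather than far outside it
        selected[chosen, :l_sel] = True
        # engineered mid-frequency standing variation at the selected loci
        p0[chosen, :l_sel] = rng.beta(2.0, 2.0, size=(len(chosen), l_sel))
        # either of the first two populations may be the swept one (per gene),
        # so the imbalance loads on the D1 x D2 interaction, not main effects
        sweep_pop[disc_idx] = rng.integers(0, 2, size=n_disc)
    elif config.scenario in ("STABILIZING_SHARED", "STABILIZING_SHIFTED"):
        scenario_class[:] = "STABILIZING"
        selected[:, :l_ns] = True

    alpha = None
    if config.scenario in ("STABILIZING_SHARED", "STABILIZING_SHIFTED"):
        alpha = rng.exponential(config.effect_scale, size=(g, l_ns)) * rng.choice(
            [-1.0, 1.0], size=(g, l_ns)
        )

    # --- ancestral phase -------------------------------------------------
    if config.scenario in ("STABILIZING_SHARED", "STABILIZING_SHIFTED"):
        geno0 = rng.binomial(2, np.broadcast_to(p0[:, None, :l_ns], (g, n, l_ns))).astype(
            np.int8
        )
        geno0 = _stabilizing_wf_evolve(
            geno0, alpha, config.optima[0], config.omega, mu, config.burn_in, rng
        )
        p_syn0 = neutral_wf_evolve(p0[:, l_ns:], n, mu, config.burn_in, rng)
    else:
        p_anc = neutral_wf_evolve(p0, n, mu, config.burn_in, rng)

    # --- split and per-population evolution ------------------------------
    freqs = np.empty((config.n_pops, g, l_tot), dtype=float)
    if config.scenario in ("STABILIZING_SHARED", "STABILIZING_SHIFTED"):
        for pop in range(config.n_pops):
            theta_opt = (
                config.optima[0]
                if config.scenario == "STABILIZING_SHARED"
                else config.optima[pop]
            )
            geno = _stabilizing_wf_evolve(
                geno0, alpha, theta_opt, config.omega, mu, config.g_split, rng
            )
            freqs[pop, :, :l_ns] = geno.mean(axis=1) / 2.0
            freqs[pop, :, l_ns:] = neutral_wf_evolve(
                p_syn0, n, mu, config.g_split, rng
            )
        n_fixed = int(
            ((freqs[:, :, :l_ns] == 0) | (freqs[:, :, :l_ns] == 1)).all(axis=(0, 2)).sum()
        )
        if n_fixed:
            logger.info("%d genes monomorphic at all NS loci after run", n_fixed)
    else:
        shared_sweep = scenario_class == "SHARED_SWEEP"
        shared_bal = scenario_class == "SHARED_BALANCED"
        for pop in range(config.n_pops):
            p = p_anc.copy()
            swept = (sweep_pop == pop) | shared_sweep
            balanced = shared_bal | (
                (sweep_pop >= 0) & (sweep_pop == 1 - pop) & (pop < 2)
            )
            if swept.any() or balanced.any():
                if swept.any():  # drive the ancestral-major allele up
                    favor = p_anc[swept][:, :l_sel] >= 0.5
                    p[np.ix_(swept.nonzero()[0], np.arange(l_sel))] = _selected_wf_evolve(
                        p[swept][:, :l_sel], n, mu, config.g_split, rng,
                        "directional", config.s_directional, favor,
                    )
                if balanced.any():  # heterozygote advantage at the same loci
                    p[np.ix_(balanced.nonzero()[0], np.arange(l_sel))] = _selected_wf_evolve(
                        p[balanced][:, :l_sel], n, mu, config.g_split, rng,
                        "overdominant", config.s_balancing,
                    )
                rest = np.ones_like(p, dtype=bool)
                rest[(swept | balanced), :l_sel] = False
                p[rest] = neutral_wf_evolve(p[rest], n, mu, config.g_split, rng)
            else:
                p = neutral_wf_evolve(p, n, mu, config.g_split, rng)
            freqs[pop] = p

    truth = _build_truth(config, freqs, selected, scenario_class, sweep_pop)
    truth.effect_sizes = alpha
    return SimResult(config=config, freqs=freqs, truth=truth)


def _build_truth(
    config: ScenarioConfig,
    freqs: np.ndarray,
    selected: np.ndarray,
    scenario_class: np.ndarray,
    sweep_pop: np.ndarray,
) -> SimTruth:
    g = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(g)]
    rows: dict[str, list] = {
        "gene_id": gene_ids,
        "scenario_class": list(scenario_class),
        "n_selected_loci": list(selected.sum(axis=1)),
        "sweep_pop": list(sweep_pop),
    }
    for x in range(config.n_pops):
        for y in range(x + 1, config.n_pops):
            fst_col, dxy_col = [], []
            for gi in range(g):
                px, py = freqs[x, gi], freqs[y, gi]
                fst_col.append(hudson_fst(px, py))
                dxy_col.append(float((px * (1 - py) + py * (1 - px)).mean()))
            rows[f"fst_true_{x}-{y}"] = fst_col
            rows[f"dxy_true_{x}-{y}"] = dxy_col
    return SimTruth(
        genes=pd.DataFrame(rows), selected_loci=selected, true_freqs=freqs
    )


# ---------------------------------------------------------------------------
# pool sequencing emulator
# ---------------------------------------------------------------------------


def pool_sequence(
    freqs: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage pooled read counts from true frequencies.

    Per population and site: (1) draw ``n_pool_haploid`` chromosomes from the
    population frequency (binomial), (2) draw Poisson(depth_mean) reads from
    the realised pool frequency (binomial).  Returns ``(alt_reads, depth)``
    arrays with the same leading shape as ``freqs``.
    """
    n_pool = config.n_pool_haploid
    pool_alt = rng.binomial(n_pool, freqs) / n_pool
    depth = rng.poisson(config.depth_mean, size=freqs.shape)
    alt_reads = rng.binomial(depth, pool_alt)
    return alt_reads, depth


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------

_GENES_PER_CONTIG = 50
_GENE_GAP = 200


@dataclass
class SimDataset:
    """Paths of an emitted dataset plus the in-memory ground truth."""

    paths: dict[str, Path]
    config: ScenarioConfig
    truth: SimTruth
    pool_names: tuple[str, ...]


def _gene_layout(config: ScenarioConfig, rng: np.random.Generator):
    """Gene intervals and per-gene locus positions.

    Gene lengths vary uniformly in [0.6, 1.4] x ``gene_length`` (so length
    is a usable model covariate); genes are laid end-to-end with a gap on
    contigs of ``_GENES_PER_CONTIG`` genes each.
    """
    g, l_tot = config.n_genes, config.loci_per_gene
    lengths = rng.integers(
        max(l_tot + 1, int(0.6 * config.gene_length)),
        int(1.4 * config.gene_length) + 1,
        size=g,
    )
    contigs, starts, ends = [], [], []
    cursor = 100
    for gi in range(g):
        if gi % _GENES_PER_CONTIG == 0:
            cursor = 100
        contigs.append(f"ctg{gi // _GENES_PER_CONTIG:04d}")
        starts.append(cursor)
        ends.append(cursor + int(lengths[gi]))
        cursor += int(lengths[gi]) + _GENE_GAP
    offsets = np.empty((g, l_tot), dtype=int)
    for gi in range(g):
        offsets[gi] = rng.choice(int(lengths[gi]), size=l_tot, replace=False)
    return contigs, np.array(starts), np.array(ends), offsets


def emit_dataset(config: ScenarioConfig, outdir: str | Path) -> SimDataset:
    """Simulate one scenario and write the full input bundle to ``outdir``.

    Files written: ``counts.sync`` (one pool column per population),
    ``genes.bed`` (BED4 + gc), ``site_classes.tsv``, ``gene_classes.tsv``
    (truth labels), ``term_map.tsv`` (one term per truth class plus random
    decoy terms), ``expression.tsv`` (log-normal FPKM, normal log2
    fold-change) and ``truth.tsv``.  Every sync site is classified and every
    gene has sites in the sync file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = simulate_populations(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2718]))
    return _emit_from_result(result, outdir, rng)


def _emit_from_result(
    result: SimResult, outdir: Path, rng: np.random.Generator
) -> SimDataset:
    config = result.config
    g, l_ns, l_tot = config.n_genes, config.n_ns_loci, config.loci_per_gene
    contigs, starts, ends, offsets = _gene_layout(config, rng)
    gene_ids = result.truth.genes["gene_id"].tolist()

    # genes.bed with synthetic GC content
    gc = rng.uniform(0.30, 0.60, size=g)
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "contig": contigs,
            "start": starts,
            "end": ends,
            "gc_content": np.round(gc, 4),
        }
    )
    bed_path = outdir / "genes.bed"
    write_gene_bed(genes, bed_path)

    # site classes: NS loci are the leading columns of the freq array
    klass = np.array(["NS"] * l_ns + ["SYN"] * (l_tot - l_ns))
    sc_rows = []
    for gi in range(g):
        pos = starts[gi] + offsets[gi] + 1  # 1-based
        for li in range(l_tot):
            sc_rows.append((contigs[gi], int(pos[li]), gene_ids[gi], klass[li]))
    site_classes = pd.DataFrame(
        sc_rows, columns=["contig", "pos", "gene_id", "site_class"]
    )
    sc_path = outdir / "site_classes.tsv"
    write_table(site_classes, sc_path)

    # pooled counts -> sync
    alt_reads, depth = pool_sequence(result.freqs, config, rng)
    ref_idx = rng.integers(0, 4, size=(g, l_tot))
    alt_idx = (ref_idx + rng.integers(1, 4, size=(g, l_tot))) % 4
    bases = "ATCG"
    records = []
    for gi in range(g):
        order = np.argsort(offsets[gi], kind="stable")
        for li in order:
            counts = np.zeros((config.n_pops, 6), dtype=np.int64)
            for pop in range(config.n_pops):
                d = int(depth[pop, gi, li])
                alt = int(alt_reads[pop, gi, li])
                counts[pop, ref_idx[gi, li]] = d - alt
                counts[pop, alt_idx[gi, li]] += alt
            records.append(
                SyncRecord(
                    contig=contigs[gi],
                    pos=int(starts[gi] + offsets[gi][li] + 1),
                    ref_base=bases[ref_idx[gi, li]],
                    counts=counts,
                )
            )
    sync_path = outdir / "counts.sync"
    write_sync(records, sync_path)

    # gene classes from truth + term map with decoys
    labels = result.truth.genes["scenario_class"]
    class_rows = [
        (gid, lab) for gid, lab in zip(gene_ids, labels) if lab != "NEUTRAL"
    ]
    gene_classes = pd.DataFrame(class_rows, columns=["gene_id", "label"])
    gc_path = outdir / "gene_classes.tsv"
    write_table(gene_classes, gc_path)

    term_rows = [(f"CLASS:{lab}", gid) for gid, lab in class_rows]
    for t in range(10):  # decoy terms: random gene sets
        size = int(rng.integers(10, max(11, g // 10)))
        for gid in rng.choice(gene_ids, size=min(size, g), replace=False):
            term_rows.append((f"RND:{t:03d}", gid))
    term_map = pd.DataFrame(term_rows, columns=["term_id", "gene_id"])
    tm_path = outdir / "term_map.tsv"
    write_table(term_map, tm_path)

    # expression: log-normal FPKM, normal sex bias (female - male log2FC)
    fpkm = rng.lognormal(mean=2.0, sigma=1.5, size=g)
    log2fc = rng.normal(0.0, 2.0, size=g)
    bias = np.where(log2fc > 0.5, "FBG", np.where(log2fc < -0.5, "MBG", "UNBIASED"))
    expression = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "fpkm": np.round(fpkm, 4),
            "log2fc_sex": np.round(log2fc, 4),
            "bias_class": bias,
        }
    )
    expr_path = outdir / "expression.tsv"
    write_table(expression, expr_path)

    truth_path = outdir / "truth.tsv"
    write_table(result.truth.genes, truth_path)

    pool_names = tuple(f"pop{i}" for i in range(config.n_pops))
    return SimDataset(
        paths={
            "sync": sync_path,
            "bed": bed_path,
            "site_classes": sc_path,
            "gene_classes": gc_path,
            "term_map": tm_path,
            "expression": expr_path,
            "truth": truth_path,
        },
        config=config,
        truth=result.truth,
        pool_names=pool_names,
    )
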