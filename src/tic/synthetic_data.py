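"""Synthetic genomes, expression, counts, coverage and litters with a
ground-truth transcriptional-interference effect.

The generator emulates the statistical structure the analysis modules
assume, at desk scale:

* gene placement in tandem runs, divergent pairs and isolated genes,
  with log-uniform intergenic distances and wide spacers between blocks;
* log-normal baseline expression (FPKM-like);
* a repression effect on downstream tandem genes that decays
  exponentially with the TSS-to-upstream-TTS distance and grows with the
  upstream gene's expression:
  ``log2FC = -beta * h(E_up) * exp(-d / lambda) + N(0, noise_sd)``,
  with ``h`` normalized to [0, 1];
* negative-binomial replicate counts for two conditions;
* per-base Poisson coverage with a promoter peak controlling the Pol II
  pausing index, a gene-body plateau proportional to expression, and a
  TTS-downstream occupancy bump over a flat input;
* litter genotype draws with genotype-specific viability.

Every draw is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .coverage_metrics import CoverageTrack
from .expression_tables import CountMatrix
from .genome_model import GeneModel
from .mendelian_stats import GenotypeCounts
from .neighbor_topology import compute_contexts


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Distances and lengths in bases; expression in FPKM-like units.
    ``tandem_fraction``/``divergent_fraction``/``isolated_fraction``
    control the share of genes created inside tandem runs, divergent
    pairs and isolated placements; they must sum to <= 1 (any remainder
    goes to isolated genes).
    """

    n_genes: int = 2000
    n_chromosomes: int = 2
    seed: int = 0

    # layout
    tandem_fraction: float = 0.8
    divergent_fraction: float = 0.1
    isolated_fraction: float = 0.1
    tandem_run_length: int = 8
    d_min: int = 200
    d_max: int = 50_000
    short_fraction: float | None = 0.35  # share of tandem gaps below 2 kb
    divergent_d_max: int = 50_000
    spacer_min: int = 60_000
    spacer_max: int = 100_000
    gene_length_min: int = 2000
    gene_length_max: int = 30_000

    # expression
    expr_mu: float = 1.0      # log-normal location (natural log scale)
    expr_sigma: float = 1.5

    # interference effect
    beta: float = 0.8         # maximal log2 repression depth
    decay_length: float = 2000.0
    h_mode: str = "step"      # or "linear-in-log"
    h_quantile: float = 0.5
    noise_sd: float = 0.2

    # counts
    nb_dispersion: float = 0.02
    replicates: int = 5
    counts_scale: float = 25.0      # expected control counts per expression unit
    libsize_jitter: float = 0.0

    # coverage
    read_length: int = 50
    input_depth: float = 2.0
    pol2_background: float = 0.05
    pol2_body_per_expr: float = 0.3
    chd2_body_per_expr: float = 0.02
    pi_star: float = 8.0
    tts_bump_fold: float = 4.0

    def __post_init__(self) -> None:
        fr = self.tandem_fraction + self.divergent_fraction + self.isolated_fraction
        if fr > 1.0 + 1e-9:
            raise ValueError("arrangement fractions must sum to <= 1")
        for name in ("d_min", "d_max", "decay_length", "gene_length_min",
                     "gene_length_max", "counts_scale", "expr_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_min > self.d_max:
            raise ValueError("d_min > d_max")
        if self.beta < 0 or self.noise_sd < 0 or self.nb_dispersion < 0:
            raise ValueError("beta, noise_sd and nb_dispersion must be >= 0")
        if self.tandem_run_length < 2:
            raise ValueError("tandem_run_length must be >= 2")


@dataclass
class GroundTruth:
    true_log2fc: dict[str, float]
    interfered: dict[str, bool]
    pi_star: dict[str, float]
    tts_bump_fold: dict[str, float]


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg_seed) % (2**31), stream])


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return float(lo)
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def _draw_gap(rng: np.random.Generator, cfg: SyntheticConfig) -> int:
    """Tandem intergenic distance: log-uniform, optionally forcing a
    fixed share of gaps below 2 kb."""
    if cfg.short_fraction is not None and cfg.d_min < 2000 < cfg.d_max:
        if rng.random() < cfg.short_fraction:
            return int(round(_log_uniform(rng, cfg.d_min, 2000)))
        return int(round(_log_uniform(rng, 2000, cfg.d_max)))
    return int(round(_log_uniform(rng, cfg.d_min, cfg.d_max)))


def generate_genome(cfg: SyntheticConfig) -> list[GeneModel]:
    """Place genes in blocks (tandem runs, divergent pairs, isolated) on
    ``n_chromosomes`` chromosomes; deterministic given ``cfg.seed``.

    Gene expression is drawn log-normal and attached to each model.
    Arrangement quotas are met exactly (up to block granularity).
    """
    rng = _rng(cfg.seed, 1)
    n = cfg.n_genes
    run = cfg.tandem_run_length
    n_tandem_blocks = int(round(cfg.tandem_fraction * n / run))
    n_div_blocks = int(round(cfg.divergent_fraction * n / 2))
    n_assigned = n_tandem_blocks * run + n_div_blocks * 2
    if n_assigned > n:
        raise ValueError("arrangement quotas exceed n_genes; reduce fractions")
    n_isolated = n - n_assigned

    blocks = (
        ["tandem"] * n_tandem_blocks + ["divergent"] * n_div_blocks + ["isolated"] * n_isolated
    )
    rng.shuffle(blocks)

    expr_all = rng.lognormal(cfg.expr_mu, cfg.expr_sigma, size=n)

    genes: list[GeneModel] = []
    gi = 0
    per_chrom = max(1, math.ceil(len(blocks) / cfg.n_chromosomes))
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        chunk = blocks[ci * per_chrom : (ci + 1) * per_chrom]
        cursor = int(rng.integers(cfg.spacer_min, cfg.spacer_max + 1))
        for block in chunk:
            if block == "tandem":
                strand = "+" if rng.random() < 0.5 else "-"
                lengths = [
                    int(round(_log_uniform(rng, cfg.gene_length_min, cfg.gene_length_max)))
                    for _ in range(run)
                ]
                gaps = [_draw_gap(rng, cfg) for _ in range(run - 1)]
                if strand == "+":
                    x = cursor
                    for k, L in enumerate(lengths):
                        genes.append(GeneModel(f"g{gi:05d}", chrom, "+", x, x + L,
                                               expression=float(expr_all[gi])))
                        gi += 1
                        if k < run - 1:
                            x = x + L + gaps[k]   # next TSS = prev TTS + gap
                        else:
                            x = x + L
                    cursor = x
                else:
                    # transcription right-to-left: later-placed gene is the
                    # upstream neighbor of the one before it
                    x = cursor
                    for k, L in enumerate(lengths):
                        genes.append(GeneModel(f"g{gi:05d}", chrom, "-",
                                               tss=x + L - 1, tts=x,
                                               expression=float(expr_all[gi])))
                        gi += 1
                        if k < run - 1:
                            x = x + L - 1 + gaps[k]  # next TTS = prev TSS + gap
                        else:
                            x = x + L
                    cursor = x
            elif block == "divergent":
                L1 = int(round(_log_uniform(rng, cfg.gene_length_min, cfg.gene_length_max)))
                L2 = int(round(_log_uniform(rng, cfg.gene_length_min, cfg.gene_length_max)))
                dd = int(round(_log_uniform(rng, cfg.d_min, cfg.divergent_d_max)))
                x = cursor
                left = GeneModel(f"g{gi:05d}", chrom, "-", tss=x + L1 - 1, tts=x,
                                 expression=float(expr_all[gi]))
                genes.append(left)
                gi += 1
                x2 = left.tss + dd
                genes.append(GeneModel(f"g{gi:05d}", chrom, "+", tss=x2, tts=x2 + L2,
                                       expression=float(expr_all[gi])))
                gi += 1
                cursor = x2 + L2
            else:  # isolated
                L = int(round(_log_uniform(rng, cfg.gene_length_min, cfg.gene_length_max)))
                strand = "+" if rng.random() < 0.5 else "-"
                x = cursor
                if strand == "+":
                    genes.append(GeneModel(f"g{gi:05d}", chrom, "+", x, x + L,
                                           expression=float(expr_all[gi])))
                else:
                    genes.append(GeneModel(f"g{gi:05d}", chrom, "-", tss=x + L - 1,
                                           tts=x, expression=float(expr_all[gi])))
                gi += 1
                cursor = x + L
            cursor += int(rng.integers(cfg.spacer_min, cfg.spacer_max + 1))
    return genes


def chrom_sizes_of(genes: Sequence[GeneModel], margin: int = 10_000) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.end + margin)
    return sizes


def _h_weights(cfg: SyntheticConfig, upstream_expr: np.ndarray,
               all_expr: np.ndarray) -> np.ndarray:
    """Upstream-expression weighting h(E) in [0, 1]."""
    if cfg.h_mode == "linear-in-log":
        ref = math.log1p(float(all_expr.max()))
        return np.log1p(upstream_expr) / ref if ref > 0 else np.zeros_like(upstream_expr)
    if cfg.h_mode == "step":
        cut = float(np.quantile(all_expr, cfg.h_quantile))
        return (upstream_expr >= cut).astype(float)
    raise ValueError(f"unknown h_mode: {cfg.h_mode!r}")


def apply_interference(genes: Sequence[GeneModel], cfg: SyntheticConfig) -> GroundTruth:
    """Assign each gene its true log2 fold change under the interference law.

    Genes with a tandem upstream neighbor at distance ``d`` receive
    ``-beta * h(E_up) * exp(-d / decay_length)`` plus Gaussian noise;
    all other genes receive pure noise.
    """
    rng = _rng(cfg.seed, 2)
    ctx = compute_contexts(genes)
    all_expr = np.array([g.expression for g in genes])
    noise = rng.normal(0.0, cfg.noise_sd, size=len(genes))

    true_lfc: dict[str, float] = {}
    interfered: dict[str, bool] = {}
    for i, (g, c) in enumerate(zip(genes, ctx)):
        effect = 0.0
        flag = False
        if (
            cfg.beta > 0
            and c.tandem_distance is not None
            and c.tandem_upstream_expression is not None
        ):
            h = float(
                _h_weights(cfg, np.array([c.tandem_upstream_expression]), all_expr)[0]
            )
            effect = -cfg.beta * h * math.exp(-c.tandem_distance / cfg.decay_length)
            flag = h > 0 and c.tandem_distance <= 3 * cfg.decay_length
        true_lfc[g.gene_id] = effect + float(noise[i])
        interfered[g.gene_id] = flag
    return GroundTruth(
        true_log2fc=true_lfc,
        interfered=interfered,
        pi_star={g.gene_id: cfg.pi_star for g in genes},
        tts_bump_fold={g.gene_id: cfg.tts_bump_fold for g in genes},
    )


def simulate_counts(
    genes: Sequence[GeneModel], truth: GroundTruth, cfg: SyntheticConfig
) -> CountMatrix:
    """Negative-binomial counts for control and mutant replicates.

    Control mean is ``counts_scale * expression``; the mutant mean is
    scaled by ``2^true_log2fc``.  ``nb_dispersion`` is the NB
    overdispersion alpha (variance ``mu + alpha mu^2``); alpha = 0 falls
    back to Poisson.
    """
    rng = _rng(cfg.seed, 3)
    n_rep = cfg.replicates
    expr = np.array([g.expression for g in genes])
    lfc = np.array([truth.true_log2fc[g.gene_id] for g in genes])
    base = cfg.counts_scale * expr
    means = np.concatenate(
        [np.tile(base[:, None], (1, n_rep)), np.tile((base * 2.0**lfc)[:, None], (1, n_rep))],
        axis=1,
    )
    if cfg.libsize_jitter > 0:
        factors = rng.lognormal(0.0, cfg.libsize_jitter, size=means.shape[1])
        means = means * factors[None, :]
    if cfg.nb_dispersion < 1e-8:
        counts = rng.poisson(means)
    else:
        r = 1.0 / cfg.nb_dispersion
        p = r / (r + means)
        counts = rng.negative_binomial(r, p)
    sample_ids = [f"ctrl_{j + 1}" for j in range(n_rep)] + [
        f"mut_{j + 1}" for j in range(n_rep)
    ]
    condition = {s: ("control" if s.startswith("ctrl") else "mutant") for s in sample_ids}
    return CountMatrix(
        gene_ids=[g.gene_id for g in genes],
        sample_ids=sample_ids,
        counts=counts,
        condition=condition,
    )


def simulate_coverage(
    genes: Sequence[GeneModel],
    cfg: SyntheticConfig,
    kind: str,
    truth: GroundTruth | None = None,
) -> CoverageTrack:
    """Per-base Poisson coverage for one track kind.

    ``input``: flat expected depth.  ``pol2``: gene-body plateau
    proportional to expression with the promoter window raised to
    ``pi_star`` times the body level.  ``chd2``: input-like background
    plus a body plateau proportional to expression and a TTS-downstream
    bump of ``tts_bump_fold`` times the local input level.
    """
    if kind not in {"input", "pol2", "chd2"}:
        raise ValueError(f"unknown track kind: {kind!r}")
    stream = {"input": 4, "pol2": 5, "chd2": 6}[kind]
    rng = _rng(cfg.seed, stream)
    sizes = chrom_sizes_of(genes)
    from .genome_model import region_of

    expected = {c: np.zeros(n) for c, n in sizes.items()}
    if kind == "input":
        for c in expected:
            expected[c][:] = cfg.input_depth
    elif kind == "pol2":
        for c in expected:
            expected[c][:] = cfg.pol2_background
        for g in genes:
            body_level = cfg.pol2_body_per_expr * (g.expression or 0.0)
            arr = expected[g.chrom]
            arr[g.start : g.end] = body_level
            pi = truth.pi_star[g.gene_id] if truth else cfg.pi_star
            prom = region_of(g, "promoter", chrom_length=sizes[g.chrom])
            arr[prom.start : prom.end] = pi * body_level
    else:  # chd2
        for c in expected:
            expected[c][:] = cfg.input_depth
        for g in genes:
            arr = expected[g.chrom]
            arr[g.start : g.end] += cfg.chd2_body_per_expr * (g.expression or 0.0)
            fold = truth.tts_bump_fold[g.gene_id] if truth else cfg.tts_bump_fold
            tts = region_of(g, "tts_downstream", chrom_length=sizes[g.chrom])
            arr[tts.start : tts.end] += (fold - 1.0) * cfg.input_depth

    depths = {c: rng.poisson(e).astype(float) for c, e in expected.items()}
    library_size = sum(a.sum() for a in depths.values()) / cfg.read_length
    return CoverageTrack(
        depths=depths,
        library_size=float(max(library_size, 1.0)),
        label=kind,
        read_length=cfg.read_length,
    )


def simulate_litters(
    n_pups: int,
    genotype_probs: Sequence[float],
    viability: Sequence[float],
    seed: int,
    categories: Sequence[str] | None = None,
) -> GenotypeCounts:
    """Multinomial genotype draw followed by per-genotype binomial survival.

    ``genotype_probs`` must sum to 1 and give the Mendelian expectation
    at conception; ``viability`` gives each genotype's survival
    probability to the observation point.
    """
    probs = np.asarray(genotype_probs, dtype=float)
    viab = np.asarray(viability, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("genotype_probs must sum to 1")
    if ((viab < 0) | (viab > 1)).any():
        raise ValueError("viabilities must lie in [0, 1]")
    rng = np.random.default_rng([int(seed) % (2**31), 7])
    conceived = rng.multinomial(n_pups, probs)
    observed = rng.binomial(conceived, viab)
    if categories is None:
        categories = [f"G{i + 1}" for i in range(len(probs))]
    return GenotypeCounts(
        categories=list(categories),
        observed=[int(o) for o in observed],
        expected_ratio=list(probs),
    )


# ---------------------------------------------------------------------------
# Presets: named study conditions used by the pipeline and the examples.

def preset(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Named configurations: ``interference`` (effect present), ``null``
    (beta = 0), ``pausing`` (compact genome for coverage metrics)."""
    if name == "interference":
        cfg = SyntheticConfig(seed=seed)
    elif name == "null":
        cfg = SyntheticConfig(seed=seed, beta=0.0)
    elif name == "pausing":
        cfg = SyntheticConfig(
            seed=seed,
            n_genes=200,
            n_chromosomes=1,
            tandem_fraction=0.5,
            divergent_fraction=0.0,
            isolated_fraction=0.5,
            d_max=6000,
            spacer_min=40_000,
            spacer_max=60_000,
            gene_length_min=4000,
            gene_length_max=15_000,
        )
    else:
        raise ValueError(f"unknown preset: {name!r}")
    return replace(cfg, **overrides) if overrides else cfg
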