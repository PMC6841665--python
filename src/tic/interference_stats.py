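"""Statistics that quantify the transcriptional-interference signature.

The signature of interference from a highly expressed upstream tandem
gene onto its downstream neighbor's promoter has three readouts:

* expression changes of downstream genes correlate positively with the
  distance to the upstream gene's TTS (repression fades with distance);
* within the shortest distance stratum, repression deepens with the
  upstream gene's absolute expression level;
* no comparable effect appears for divergent (opposite-strand, 5'-5')
  neighbors, which serve as the orientation control.

Group comparisons use the two-sided Wilcoxon rank-sum test against the
most distal distance bin; rank correlations are Spearman with midrank
ties.  P values are reported raw (no multiple-testing correction across
bins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._stats import ranksum_p, spearman
from .expression_tables import DiffExprRecord
from .neighbor_topology import NeighborContext

logger = logging.getLogger(__name__)

DEFAULT_DISTANCE_BINS = (0, 2000, 6000, 20000)
DEFAULT_MAX_DISTANCE = 10_000
DEFAULT_UPSTREAM_MAX_DISTANCE = 2000
DEFAULT_EXPR_SPLIT_QUANTILE = 0.5


@dataclass
class BinResult:
    label: str
    lo: int
    hi: float
    expr_stratum: str | None
    n: int
    median_log2fc: float
    wilcoxon_p: float | None


@dataclass
class InterferenceReport:
    spearman_rho: float | None = None
    spearman_p: float | None = None
    n_genes: int = 0
    bins: list[BinResult] = field(default_factory=list)
    upstream_expr_rho: float | None = None
    upstream_expr_p: float | None = None


@dataclass
class AccessibilityAssociation:
    groups: dict[str, dict[str, float | int | None]]
    pairwise_p: dict[str, dict[tuple[str, str], float | None]]


def _join(
    de: Sequence[DiffExprRecord],
    ctx: Sequence[NeighborContext],
) -> list[tuple[DiffExprRecord, NeighborContext]]:
    by_id = {c.gene_id: c for c in ctx}
    return [(r, by_id[r.gene_id]) for r in de if r.gene_id in by_id]


def distance_expression_correlation(
    de: Sequence[DiffExprRecord],
    ctx: Sequence[NeighborContext],
    max_distance: int = DEFAULT_MAX_DISTANCE,
    min_n: int = 10,
) -> tuple[float | None, float | None, int]:
    """Spearman correlation of log2FC with tandem upstream distance.

    Restricted to genes with a tandem context closer than
    ``max_distance``.  Positive rho means repression concentrates at
    short distances.
    """
    pairs = [
        (c.tandem_distance, r.log2fc)
        for r, c in _join(de, ctx)
        if c.tandem_distance is not None and c.tandem_distance < max_distance
    ]
    if len(pairs) < min_n:
        raise ValueError(f"too few genes with tandem context < {max_distance}: {len(pairs)}")
    d, lfc = zip(*pairs)
    rho, p = spearman(d, lfc)
    if rho is None:
        logger.warning("degenerate ranks; distance correlation undefined")
    return rho, p, len(pairs)


def upstream_expression_correlation(
    de: Sequence[DiffExprRecord],
    ctx: Sequence[NeighborContext],
    max_distance: int = DEFAULT_UPSTREAM_MAX_DISTANCE,
    min_n: int = 10,
) -> tuple[float | None, float | None, int]:
    """Spearman correlation of downstream log2FC with upstream expression
    among genes with a tandem neighbor closer than ``max_distance``."""
    pairs = [
        (c.tandem_upstream_expression, r.log2fc)
        for r, c in _join(de, ctx)
        if c.tandem_distance is not None
        and c.tandem_distance < max_distance
        and c.tandem_upstream_expression is not None
    ]
    if len(pairs) < min_n:
        raise ValueError(f"too few genes with upstream expression: {len(pairs)}")
    e, lfc = zip(*pairs)
    rho, p = spearman(e, lfc)
    if rho is None:
        logger.warning("upstream expression constant; correlation undefined")
    return rho, p, len(pairs)


def _bin_edges(distance_bins: Sequence[int]) -> list[tuple[int, float]]:
    edges = list(distance_bins)
    return [
        (edges[i], edges[i + 1] if i + 1 < len(edges) else float("inf"))
        for i in range(len(edges))
    ]


def stratified_interference(
    de: Sequence[DiffExprRecord],
    ctx: Sequence[NeighborContext],
    distance_bins: Sequence[int] = DEFAULT_DISTANCE_BINS,
    expr_split_quantile: float = DEFAULT_EXPR_SPLIT_QUANTILE,
) -> InterferenceReport:
    """Distance-binned medians of log2FC, the shortest bin split by
    upstream expression, each bin tested against the most distal bin.

    The first bin (shortest distances) is divided into low/high strata
    at the given quantile of upstream expression within that bin.  Each
    bin's two-sided rank-sum P compares its log2FC values with the most
    distal bin (reference, P reported as None for the reference itself).
    """
    joined = [
        (r, c) for r, c in _join(de, ctx) if c.tandem_distance is not None
    ]
    bins = _bin_edges(distance_bins)
    groups: list[tuple[str, int, float, str | None, np.ndarray]] = []

    ref_lo, ref_hi = bins[-1]
    ref_vals = np.array(
        [r.log2fc for r, c in joined if ref_lo <= c.tandem_distance < ref_hi]
    )
    if ref_vals.size == 0:
        raise ValueError("reference (most distal) bin is empty")

    for i, (lo, hi) in enumerate(bins):
        members = [(r, c) for r, c in joined if lo <= c.tandem_distance < hi]
        if i == 0 and members:
            exprs = np.array(
                [
                    c.tandem_upstream_expression
                    if c.tandem_upstream_expression is not None
                    else np.nan
                    for _, c in members
                ]
            )
            known = exprs[~np.isnan(exprs)]
            if known.size:
                cut = float(np.quantile(known, expr_split_quantile))
                low = [m for m, e in zip(members, exprs) if not np.isnan(e) and e <= cut]
                high = [m for m, e in zip(members, exprs) if not np.isnan(e) and e > cut]
                for stratum, mem in (("low_upstream", low), ("high_upstream", high)):
                    vals = np.array([r.log2fc for r, _ in mem])
                    groups.append((_label(lo, hi), lo, hi, stratum, vals))
                continue
        vals = np.array([r.log2fc for r, _ in members])
        groups.append((_label(lo, hi), lo, hi, None, vals))

    results = []
    for label, lo, hi, stratum, vals in groups:
        is_ref = (lo, hi) == (ref_lo, ref_hi)
        results.append(
            BinResult(
                label=label,
                lo=lo,
                hi=hi,
                expr_stratum=stratum,
                n=int(vals.size),
                median_log2fc=float(np.median(vals)) if vals.size else float("nan"),
                wilcoxon_p=None if is_ref or vals.size == 0 else ranksum_p(vals, ref_vals),
            )
        )
    n_genes = len(joined)
    report = InterferenceReport(n_genes=n_genes, bins=results)
    return report


def _label(lo: int, hi: float) -> str:
    if np.isinf(hi):
        return f">={lo // 1000}kb"
    return f"[{lo // 1000}kb,{int(hi) // 1000}kb)"


def divergent_control(
    de: Sequence[DiffExprRecord],
    ctx: Sequence[NeighborContext],
    distance_bins: Sequence[int] = DEFAULT_DISTANCE_BINS,
) -> InterferenceReport:
    """Distance-binned log2FC medians on divergent (5'-5') distances.

    Same binning and reference-bin rank-sum testing as the tandem
    analysis but without the expression split; an input without
    divergent pairs yields an empty report with a warning.
    """
    joined = [(r, c) for r, c in _join(de, ctx) if c.divergent_distance is not None]
    if not joined:
        logger.warning("no divergent pairs in input; empty report")
        return InterferenceReport(n_genes=0, bins=[])
    bins = _bin_edges(distance_bins)
    ref_lo, ref_hi = bins[-1]
    ref_vals = np.array(
        [r.log2fc for r, c in joined if ref_lo <= c.divergent_distance < ref_hi]
    )
    results = []
    for lo, hi in bins:
        vals = np.array(
            [r.log2fc for r, c in joined if lo <= c.divergent_distance < hi]
        )
        is_ref = (lo, hi) == (ref_lo, ref_hi)
        results.append(
            BinResult(
                label=_label(lo, hi),
                lo=lo,
                hi=hi,
                expr_stratum=None,
                n=int(vals.size),
                median_log2fc=float(np.median(vals)) if vals.size else float("nan"),
                wilcoxon_p=None
                if is_ref or vals.size == 0 or ref_vals.size == 0
                else ranksum_p(vals, ref_vals),
            )
        )
    return InterferenceReport(n_genes=len(joined), bins=results)


def interference_report(
    de: Sequence[DiffExprRecord],
    ctx: Sequence[NeighborContext],
    max_distance: int = DEFAULT_MAX_DISTANCE,
    distance_bins: Sequence[int] = DEFAULT_DISTANCE_BINS,
    upstream_max_distance: int = DEFAULT_UPSTREAM_MAX_DISTANCE,
) -> InterferenceReport:
    """Full interference summary: correlation + stratified bins."""
    report = stratified_interference(de, ctx, distance_bins=distance_bins)
    rho, p, n = distance_expression_correlation(de, ctx, max_distance=max_distance)
    report.spearman_rho, report.spearman_p, report.n_genes = rho, p, n
    try:
        urho, up, _ = upstream_expression_correlation(
            de, ctx, max_distance=upstream_max_distance
        )
        report.upstream_expr_rho, report.upstream_expr_p = urho, up
    except ValueError:
        logger.warning("too few genes for upstream-expression correlation")
    return report


def accessibility_association(
    de: Sequence[DiffExprRecord],
    ctx: Sequence[NeighborContext],
    expression: Mapping[str, float],
    reduced_promoter_genes: set[str],
    genes_with_promoter_peak: set[str],
) -> AccessibilityAssociation:
    """Compare reduced-accessibility promoter genes, their tandem upstream
    neighbors, and all other promoter-peak genes.

    Groups are disjoint: genes appearing both as reduced and as an
    upstream neighbor stay in the reduced group (logged).  Per-group
    medians of log2FC, tandem distance and expression are reported with
    pairwise two-sided rank-sum P values per metric.
    """
    if not reduced_promoter_genes <= genes_with_promoter_peak:
        raise ValueError("reduced_promoter_genes must be a subset of promoter-peak genes")
    by_id = {c.gene_id: c for c in ctx}
    lfc = {r.gene_id: r.log2fc for r in de}

    upstream = {
        by_id[g].tandem_upstream_id
        for g in reduced_promoter_genes
        if g in by_id and by_id[g].tandem_upstream_id is not None
    }
    overlap = upstream & reduced_promoter_genes
    if overlap:
        logger.info(
            "%d gene(s) are both reduced and upstream neighbors; kept as reduced",
            len(overlap),
        )
    upstream -= reduced_promoter_genes
    other = genes_with_promoter_peak - reduced_promoter_genes - upstream

    def metrics(gene_set: set[str]) -> dict[str, np.ndarray]:
        rows = {"log2fc": [], "tandem_distance": [], "expression": []}
        for g in sorted(gene_set):
            if g in lfc:
                rows["log2fc"].append(lfc[g])
            c = by_id.get(g)
            if c is not None and c.tandem_distance is not None:
                rows["tandem_distance"].append(c.tandem_distance)
            if g in expression:
                rows["expression"].append(expression[g])
        return {k: np.array(v, dtype=float) for k, v in rows.items()}

    named = {
        "reduced_promoters": metrics(reduced_promoter_genes),
        "upstream_neighbors": metrics(upstream),
        "other": metrics(other),
    }
    groups_out = {}
    for name, m in named.items():
        groups_out[name] = {
            "n": int(len(m["log2fc"])),
            **{
                f"median_{k}": (float(np.median(v)) if v.size else None)
                for k, v in m.items()
            },
        }
    pairwise: dict[str, dict[tuple[str, str], float | None]] = {}
    for metric in ("log2fc", "tandem_distance", "expression"):
        pairwise[metric] = {}
        names = list(named)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = named[names[i]][metric], named[names[j]][metric]
                pairwise[metric][(names[i], names[j])] = (
                    ranksum_p(a, b) if a.size and b.size else None
                )
    return AccessibilityAssociation(groups=groups_out, pairwise_p=pairwise)


def group_accessibility_shift(
    atac_log2fc: Mapping[str, float],
    candidate_genes: set[str],
    promoter_assignment: Mapping[str, str],
    min_n: int = 5,
) -> tuple[float | None, int, float]:
    """One-sample two-sided Wilcoxon signed-rank test of candidate genes'
    promoter accessibility shifts against zero.

    Every candidate must map, via ``promoter_assignment``, to a region
    with a log2 accessibility shift.  All-zero shifts are degenerate and
    report ``p = None`` with a warning.
    """
    from scipy import stats as sps

    shifts = []
    for g in sorted(candidate_genes):
        if g not in promoter_assignment:
            raise KeyError(f"candidate gene {g} has no promoter assignment")
        region = promoter_assignment[g]
        if region not in atac_log2fc:
            raise KeyError(f"promoter region {region} has no accessibility shift")
        shifts.append(float(atac_log2fc[region]))
    if len(shifts) < min_n:
        raise ValueError(f"too few candidate genes with shifts: {len(shifts)}")
    arr = np.array(shifts)
    median = float(np.median(arr))
    if np.allclose(arr, 0.0):
        logger.warning("all accessibility shifts are zero; signed-rank test degenerate")
        return None, len(arr), median
    p = float(sps.wilcoxon(arr, alternative="two-sided").pvalue)
    return p, len(arr), median
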