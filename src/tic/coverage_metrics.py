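"""Library-normalized coverage quantification and derived occupancy metrics.

A :class:`CoverageTrack` holds per-chromosome per-base read depth plus
the library size (total mapped reads) and the read length used to
convert depth sums back into read counts.  Region totals are expressed
as reads scaled to a library of 10^7 mapped reads, so every downstream
metric is invariant to sequencing depth.

Derived metrics:

* pausing index — promoter over gene-body occupancy density, with a
  0.5-read pseudocount on each region total and an eligibility filter of
  at least 5 normalized reads per kb of gene body;
* TTS-downstream enrichment vs input — normalized log2 ratio with an
  exact binomial test on raw read counts and Benjamini-Hochberg
  adjustment over the gene set;
* metagene profiles by expression quartile;
* exonic/intronic/intergenic read partitioning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, spearman
from .expression_tables import DiffExprRecord
from .genome_model import GeneModel, GeneRegion, region_of

logger = logging.getLogger(__name__)

LIBRARY_SCALE = 1e7
DEFAULT_READ_LENGTH = 50
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_BODY_DENSITY = 5.0


@dataclass
class CoverageTrack:
    """Per-base, unstranded read depth with library metadata."""

    depths: dict[str, np.ndarray]
    library_size: float
    label: str = ""
    read_length: int = DEFAULT_READ_LENGTH

    def __post_init__(self) -> None:
        for chrom, arr in self.depths.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative depth on {chrom}")
            self.depths[chrom] = arr
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")


@dataclass(frozen=True)
class RegionQuant:
    gene_id: str
    kind: str
    total: float          # reads scaled to 10^7 mapped
    density: float        # total per kb
    length: int
    raw_reads: float      # un-normalized read-count equivalent


@dataclass(frozen=True)
class PausingRecord:
    gene_id: str
    pi: float | None
    eligible: bool
    body_density: float


@dataclass(frozen=True)
class EnrichmentRecord:
    gene_id: str
    signal_total: float
    control_total: float
    log2_enrichment: float
    p: float
    padj: float = float("nan")


def quantify_region(track: CoverageTrack, region: GeneRegion) -> RegionQuant:
    """Sum depth over a region and normalize to reads per 10^7 mapped."""
    if region.chrom not in track.depths:
        raise KeyError(f"chromosome {region.chrom!r} absent from track {track.label!r}")
    arr = track.depths[region.chrom]
    start = max(0, region.start)
    end = min(len(arr), region.end)
    depth_sum = float(arr[start:end].sum()) if end > start else 0.0
    raw_reads = depth_sum / track.read_length
    total = raw_reads * LIBRARY_SCALE / track.library_size
    length = region.end - region.start
    density = total / (length / 1000.0) if length > 0 else 0.0
    return RegionQuant(
        gene_id=region.gene_id, kind=region.kind, total=total,
        density=density, length=length, raw_reads=raw_reads,
    )


def pausing_index(
    promoter: RegionQuant,
    body: RegionQuant,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_body_density: float = DEFAULT_MIN_BODY_DENSITY,
) -> PausingRecord:
    """Promoter/body occupancy density ratio with pseudocounted totals.

    ``pi = ((promoter.total + pc)/promoter.length) / ((body.total + pc)/body.length)``.
    Genes whose body density falls below ``min_body_density`` normalized
    reads per kb are ineligible and carry ``pi = None``.
    """
    if promoter.gene_id != body.gene_id:
        raise ValueError("promoter and body quants are from different genes")
    if body.length <= 0:
        raise ValueError(f"zero-length gene body for {body.gene_id}")
    eligible = body.density >= min_body_density
    pi = None
    if eligible:
        pi = ((promoter.total + pseudocount) / promoter.length) / (
            (body.total + pseudocount) / body.length
        )
    return PausingRecord(
        gene_id=promoter.gene_id, pi=pi, eligible=eligible, body_density=body.density
    )


def pausing_change(
    wt: PausingRecord, mut: PausingRecord, change_threshold: float = 0.25
) -> tuple[float, bool]:
    """Log2 pausing-index ratio (mutant over wild type) and a >threshold flag."""
    if not (wt.eligible and mut.eligible):
        raise ValueError(
            f"{wt.gene_id}: pausing change needs both records eligible "
            f"(wt={wt.eligible}, mut={mut.eligible})"
        )
    ratio = mut.pi / wt.pi
    changed = ratio >= 1.0 + change_threshold or ratio <= 1.0 / (1.0 + change_threshold)
    return float(np.log2(ratio)), bool(changed)


def count_enrichment(
    signal: RegionQuant,
    control: RegionQuant,
    libsizes: tuple[float, float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> EnrichmentRecord:
    """Signal-vs-control enrichment for one region.

    The two-sided exact binomial test asks whether the raw signal reads
    deviate from the library-size share of the pooled raw count; the
    log2 enrichment compares normalized totals with a pseudocount.
    """
    ls_signal, ls_control = libsizes
    k = int(round(signal.raw_reads))
    n = int(round(signal.raw_reads + control.raw_reads))
    log2_enr = float(
        np.log2((signal.total + pseudocount) / (control.total + pseudocount))
    )
    if n == 0:
        return EnrichmentRecord(signal.gene_id, signal.total, control.total, 0.0, 1.0)
    p0 = ls_signal / (ls_signal + ls_control)
    p = float(stats.binomtest(min(k, n), n, p0).pvalue)
    return EnrichmentRecord(signal.gene_id, signal.total, control.total, log2_enr, p)


def enrichment_table(records: Sequence[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """Apply Benjamini-Hochberg adjustment over a batch of enrichment tests."""
    padj = bh_adjust([r.p for r in records])
    return [
        EnrichmentRecord(r.gene_id, r.signal_total, r.control_total,
                         r.log2_enrichment, r.p, float(q))
        for r, q in zip(records, padj)
    ]


def tts_enrichment(
    signal: CoverageTrack,
    control: CoverageTrack,
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[EnrichmentRecord]:
    """TTS-downstream (2 kb past the TTS) enrichment of signal vs control."""
    records = []
    for g in genes:
        clen = chrom_sizes[g.chrom] if chrom_sizes else len(signal.depths[g.chrom])
        region = region_of(g, "tts_downstream", chrom_length=clen)
        sq = quantify_region(signal, region)
        cq = quantify_region(control, region)
        records.append(
            count_enrichment(sq, cq, (signal.library_size, control.library_size))
        )
    return enrichment_table(records)


def _rebin(arr: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean depth in n_bins equal fractional slices (reversal-symmetric)."""
    L = len(arr)
    cum = np.concatenate([[0.0], np.cumsum(arr, dtype=float)])
    edges = np.linspace(0.0, L, n_bins + 1)
    f = np.interp(edges, np.arange(L + 1), cum)
    widths = np.diff(edges)
    return np.diff(f) / widths


def metagene_profile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    n_bins: int = 100,
    flank: int = 2000,
    expression_groups: int = 4,
) -> dict[str, np.ndarray]:
    """Per-expression-quartile mean coverage over scaled gene bodies.

    Each gene span (TSS to TTS) is rescaled to ``n_bins`` bins flanked by
    fixed-width windows of ``flank`` bases (``n_bins // 2`` bins each),
    oriented 5'->3'.  Genes are split into ``expression_groups`` quantile
    groups by expression; groups that end up empty are omitted with a
    warning.  Depth is normalized to reads per 10^7 mapped.
    """
    usable = [g for g in genes if g.expression is not None and g.length > n_bins]
    if not usable:
        raise ValueError("no usable genes (need expression and length > n_bins)")
    flank_bins = max(1, n_bins // 2)
    scale = LIBRARY_SCALE / (track.library_size * track.read_length)

    profiles = []
    for g in usable:
        arr = track.depths[g.chrom]
        lo, hi = g.start - flank, g.end + flank
        padded = np.zeros(hi - lo)
        s, e = max(0, lo), min(len(arr), hi)
        if e > s:
            padded[s - lo : e - lo] = arr[s:e]
        left = _rebin(padded[:flank], flank_bins)
        body = _rebin(padded[flank : flank + (g.end - g.start)], n_bins)
        right = _rebin(padded[flank + (g.end - g.start) :], flank_bins)
        prof = np.concatenate([left, body, right]) * scale
        if g.strand == "-":
            prof = prof[::-1]
        profiles.append(prof)

    expr = np.array([g.expression for g in usable])
    ranks = stats.rankdata(expr, method="average")
    qs = np.minimum(
        (ranks - 1) / len(ranks) * expression_groups, expression_groups - 1
    ).astype(int)
    out: dict[str, np.ndarray] = {}
    mat = np.vstack(profiles)
    for q in range(expression_groups):
        mask = qs == q
        if not mask.any():
            logger.warning("expression group %d is empty; omitted", q + 1)
            continue
        out[f"Q{q + 1}"] = mat[mask].mean(axis=0)
    return out


def exon_intron_fractions(
    track: CoverageTrack, genes: Sequence[GeneModel]
) -> tuple[float, float, float]:
    """Partition depth into exonic / intronic / intergenic fractions.

    Depth overlapping any exon counts as exonic; depth within a gene
    span but outside exons as intronic; the rest as intergenic.
    Fractions sum to 1 (all-zero track yields zeros).
    """
    totals = np.zeros(3)  # intergenic, intronic, exonic
    for chrom, arr in track.depths.items():
        mask = np.zeros(len(arr), dtype=np.uint8)
        for g in genes:
            if g.chrom != chrom:
                continue
            s, e = max(0, g.start), min(len(arr), g.end)
            mask[s:e] = np.maximum(mask[s:e], 1)
            for xs, xe in g.exons:
                xs, xe = max(0, xs), min(len(arr), xe)
                if xe > xs:
                    mask[xs:xe] = 2
        for level in (0, 1, 2):
            totals[level] += arr[mask == level].sum()
    total = totals.sum()
    if total == 0:
        return 0.0, 0.0, 0.0
    return float(totals[2] / total), float(totals[1] / total), float(totals[0] / total)


def promoter_genebody_occupancy_correlation(
    de: Sequence[DiffExprRecord],
    wt_track: CoverageTrack,
    mut_track: CoverageTrack,
    genes: Sequence[GeneModel],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_n: int = 10,
) -> tuple[float | None, float | None]:
    """Spearman rho of expression change vs occupancy change, per region.

    Occupancy change is ``log2((mut.total + pc) / (wt.total + pc))`` for
    the promoter and gene-body regions separately.  Returns
    ``(rho_promoter, rho_body)``; a region with constant change reports
    ``None`` with a warning.
    """
    lfc = {r.gene_id: r.log2fc for r in de}
    rows = {"promoter": ([], []), "gene_body": ([], [])}
    for g in genes:
        if g.gene_id not in lfc or g.length <= 1000:
            continue
        for kind in ("promoter", "gene_body"):
            region = region_of(g, kind, chrom_length=len(wt_track.depths[g.chrom]))
            wq = quantify_region(wt_track, region)
            mq = quantify_region(mut_track, region)
            change = np.log2((mq.total + pseudocount) / (wq.total + pseudocount))
            rows[kind][0].append(lfc[g.gene_id])
            rows[kind][1].append(change)
    rhos = []
    for kind in ("promoter", "gene_body"):
        x, y = rows[kind]
        if len(x) < min_n:
            raise ValueError(f"too few genes ({len(x)}) for {kind} correlation")
        rho, _ = spearman(x, y)
        if rho is None:
            logger.warning("%s occupancy change is degenerate; rho undefined", kind)
        rhos.append(rho)
    return rhos[0], rhos[1]


# ---------------------------------------------------------------------------
# bedGraph I/O (4-column, 0-based half-open) with a JSON sidecar carrying
# library_size and read_length.

def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in sorted(track.depths):
            arr = track.depths[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
    sidecar = {
        "library_size": track.library_size,
        "read_length": track.read_length,
        "label": track.label,
        "chrom_sizes": {c: int(len(a)) for c, a in track.depths.items()},
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_bedgraph(
    path: str | Path,
    chrom_sizes: Mapping[str, int] | None = None,
    library_size: float | None = None,
    read_length: int | None = None,
    label: str = "",
) -> CoverageTrack:
    """Read a bedGraph; metadata comes from the sidecar JSON unless given."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    chrom_sizes = chrom_sizes or meta.get("chrom_sizes")
    if chrom_sizes is None:
        raise ValueError("chrom_sizes required (no sidecar JSON found)")
    library_size = library_size if library_size is not None else meta.get("library_size")
    if library_size is None:
        raise ValueError("library_size required (no sidecar JSON found)")
    read_length = read_length if read_length is not None else meta.get("read_length", DEFAULT_READ_LENGTH)
    label = label or meta.get("label", "")
    depths = {c: np.zeros(int(n)) for c, n in chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    for _, r in df.iterrows():
        arr = depths.get(str(r["chrom"]))
        if arr is None:
            raise ValueError(f"{path}: unknown chromosome {r['chrom']!r}")
        arr[int(r["start"]) : int(r["end"])] = float(r["value"])
    return CoverageTrack(depths=depths, library_size=float(library_size),
                         label=label, read_length=int(read_length))
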