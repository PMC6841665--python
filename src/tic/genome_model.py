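"""Strand-aware gene models and the analysis regions derived from them.

Each gene is collapsed to a single transcription start site (TSS) and a
single, most-distal transcription termination site (TTS), both held as
0-based base positions.  Three analysis regions are derived per gene:

* ``promoter`` — ±300 bases around the TSS (601 bases, TSS base included);
* ``gene_body`` — from 1 kb downstream of the TSS to the TTS;
* ``tts_downstream`` — the 2 kb window past the TTS.

All derived intervals are half-open ``[start, end)`` on the forward
coordinate axis regardless of strand; strand only determines which side
of the TSS/TTS each region falls on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

PROMOTER_FLANK = 300
BODY_TSS_OFFSET = 1000
TTS_DOWNSTREAM_SPAN = 2000

REGION_KINDS = ("promoter", "gene_body", "tts_downstream")


class AnnotationError(ValueError):
    """Raised for malformed annotation records or inconsistent gene models."""


@dataclass
class GeneModel:
    """A gene collapsed to one TSS and one TTS (0-based positions).

    On the ``+`` strand ``tss < tts``; on ``-`` the order is reversed.
    ``expression`` is an optional FPKM-like abundance used by topology
    and coverage analyses.  ``exons`` are half-open intervals within the
    gene span.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    expression: float | None = None
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+" and self.tss >= self.tts:
            raise AnnotationError(f"{self.gene_id}: + strand requires tss < tts")
        if self.strand == "-" and self.tss <= self.tts:
            raise AnnotationError(f"{self.gene_id}: - strand requires tss > tts")

    @property
    def length(self) -> int:
        return abs(self.tts - self.tss)

    @property
    def start(self) -> int:
        """Leftmost coordinate of the gene span (half-open)."""
        return self.tss if self.strand == "+" else self.tts

    @property
    def end(self) -> int:
        """Right half-open edge of the gene span."""
        return self.tts if self.strand == "+" else self.tss + 1


@dataclass(frozen=True)
class GeneRegion:
    gene_id: str
    kind: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def parse_annotation(
    path: str | Path,
    fmt: str = "gtf",
    tss_table: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Parse a GTF or BED12 annotation into single-TSS/single-TTS gene models.

    The TSS is the strand-aware 5'-most isoform start and the TTS the
    most-distal isoform end, unless ``tss_table`` supplies a per-gene
    override (1-based TSS position, taking precedence over isoforms).
    GTF coordinates (1-based closed) are shifted to the internal 0-based
    convention on read.
    """
    if fmt == "gtf":
        spans = _read_gtf_spans(path)
    elif fmt == "bed12":
        spans = _read_bed12_spans(path)
    else:
        raise ValueError(f"unknown annotation format: {fmt!r}")

    genes: list[GeneModel] = []
    for gene_id, grp in spans.groupby("gene_id", sort=True):
        strands = grp["strand"].unique()
        if len(strands) > 1:
            raise AnnotationError(
                f"gene {gene_id}: isoforms on conflicting strands {sorted(strands)}"
            )
        strand = strands[0]
        chroms = grp["chrom"].unique()
        if len(chroms) > 1:
            raise AnnotationError(f"gene {gene_id}: isoforms on multiple chromosomes")
        left = int(grp["start"].min())
        right = int(grp["end"].max())  # half-open right edge
        if strand == "+":
            tss, tts = left, right
        else:
            tss, tts = right - 1, left
        if tss_table is not None and gene_id in tss_table:
            tss = int(tss_table[gene_id]) - 1  # 1-based override
        exons = _collect_exons(grp)
        genes.append(
            GeneModel(gene_id=str(gene_id), chrom=str(chroms[0]), strand=strand,
                      tss=tss, tts=tts, exons=exons)
        )
    return genes


def _read_gtf_spans(path: str | Path) -> pd.DataFrame:
    import pyranges as pr

    try:
        gr = pr.read_gtf(str(path))
    except Exception as exc:  # pragma: no cover - message wrapping
        raise AnnotationError(f"failed to parse GTF {path}: {exc}") from exc
    df = gr.df if hasattr(gr, "df") else pd.DataFrame(gr)
    if "gene_id" not in df.columns:
        raise AnnotationError(f"{path}: GTF attributes lack gene_id")
    feats = df[df["Feature"].isin(["transcript", "exon"])]
    if feats.empty:
        feats = df
    out = pd.DataFrame(
        {
            "gene_id": feats["gene_id"],
            "chrom": feats["Chromosome"].astype(str),
            "start": feats["Start"].astype(int),
            "end": feats["End"].astype(int),
            "strand": feats["Strand"].astype(str),
            "feature": feats["Feature"].astype(str),
        }
    )
    bad = ~out["strand"].isin(["+", "-"])
    if bad.any():
        line = out.index[bad][0]
        raise AnnotationError(f"{path}: record {line} has no usable strand")
    return out


def _read_bed12_spans(path: str | Path) -> pd.DataFrame:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
    ]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except Exception as exc:
        raise AnnotationError(f"failed to parse BED12 {path}: {exc}") from exc
    if df.shape[1] < 6:
        raise AnnotationError(f"{path}: BED12 needs >= 6 columns, found {df.shape[1]}")
    df = df.iloc[:, : min(12, df.shape[1])]
    df.columns = cols[: df.shape[1]]
    rows = []
    for i, rec in df.iterrows():
        if rec["strand"] not in {"+", "-"}:
            raise AnnotationError(f"{path}: line {i + 1}: bad strand {rec['strand']!r}")
        rows.append(
            {
                "gene_id": str(rec["name"]),
                "chrom": str(rec["chrom"]),
                "start": int(rec["start"]),
                "end": int(rec["end"]),
                "strand": rec["strand"],
                "feature": "transcript",
                "blockSizes": rec.get("blockSizes"),
                "blockStarts": rec.get("blockStarts"),
            }
        )
    return pd.DataFrame(rows)


def _collect_exons(grp: pd.DataFrame) -> list[tuple[int, int]]:
    exons: set[tuple[int, int]] = set()
    if "feature" in grp.columns:
        ex = grp[grp["feature"] == "exon"]
        for _, rec in ex.iterrows():
            exons.add((int(rec["start"]), int(rec["end"])))
    if "blockSizes" in grp.columns:
        for _, rec in grp.iterrows():
            sizes, starts = rec.get("blockSizes"), rec.get("blockStarts")
            if isinstance(sizes, str) and isinstance(starts, str):
                szs = [int(s) for s in sizes.rstrip(",").split(",") if s]
                sts = [int(s) for s in starts.rstrip(",").split(",") if s]
                for sz, st in zip(szs, sts):
                    exons.add((int(rec["start"]) + st, int(rec["start"]) + st + sz))
    return sorted(exons)


def filter_genes(genes: Sequence[GeneModel], min_length: int = 2000) -> list[GeneModel]:
    """Retain genes at least ``min_length`` bases long (order preserved)."""
    return [g for g in genes if g.length >= min_length]


def region_of(
    gene: GeneModel,
    kind: str,
    chrom_length: int | None = None,
    promoter_flank: int = PROMOTER_FLANK,
    body_tss_offset: int = BODY_TSS_OFFSET,
    tts_downstream_span: int = TTS_DOWNSTREAM_SPAN,
) -> GeneRegion:
    """Derive one analysis region of a gene, clipped to ``[0, chrom_length)``."""
    if kind == "promoter":
        start = gene.tss - promoter_flank
        end = gene.tss + promoter_flank + 1
    elif kind == "gene_body":
        if gene.length <= body_tss_offset:
            raise ValueError(
                f"gene_body undefined for {gene.gene_id}: length {gene.length} <= {body_tss_offset}"
            )
        if gene.strand == "+":
            start, end = gene.tss + body_tss_offset, gene.tts
        else:
            start, end = gene.tts, gene.tss - body_tss_offset
    elif kind == "tts_downstream":
        if gene.strand == "+":
            start, end = gene.tts, gene.tts + tts_downstream_span
        else:
            start, end = gene.tts - tts_downstream_span, gene.tts
    else:
        raise ValueError(f"unknown region kind: {kind!r}")

    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    end = max(end, start)
    return GeneRegion(gene_id=gene.gene_id, kind=kind, chrom=gene.chrom, start=start, end=end)


def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (one record per gene, exons as blocks)."""
    rows = []
    for g in genes:
        start, end = g.start, g.end
        exons = g.exons or [(start, end)]
        sizes = ",".join(str(e - s) for s, e in exons) + ","
        starts = ",".join(str(s - start) for s, e in exons) + ","
        rows.append(
            [g.chrom, start, end, g.gene_id, 0, g.strand, start, end, "0",
             len(exons), sizes, starts]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "tic") -> None:
    """Write gene models as GTF (transcript + exon records, 1-based closed)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            span = (g.start + 1, g.end)  # back to 1-based closed
            fh.write(
                f"{g.chrom}\t{source}\ttranscript\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons or [(g.start, g.end)]:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_tss_table(path: str | Path) -> dict[str, int]:
    """Read a 2-column TSV of per-gene TSS overrides (gene_id, 1-based TSS)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "tss"])
    return dict(zip(df["gene_id"].astype(str), df["tss"].astype(int)))


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))
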