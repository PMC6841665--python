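"""Strand-aware neighbor context: tandem upstream and divergent partners.

For every focal gene we ask two questions about its local gene
architecture:

* which same-strand gene terminates closest upstream of the focal TSS
  (tandem context — the configuration in which readthrough transcription
  or termination-associated chromatin activity from the upstream gene
  can interfere with the focal promoter), and at what TSS-to-TTS
  distance;
* which opposite-strand gene transcribing away from the focal gene has
  the closest 5' end (divergent context — the control configuration in
  which no interference is expected).

Distances are in bases and always nonnegative.  Upstream genes whose
3' end passes the focal TSS (overlap) disqualify the focal gene by
default; nested genes never qualify.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_model import GeneModel

logger = logging.getLogger(__name__)

DEFAULT_DIVERGENT_MAX_DISTANCE = 50_000


@dataclass
class NeighborContext:
    gene_id: str
    tandem_upstream_id: str | None = None
    tandem_distance: int | None = None
    tandem_upstream_expression: float | None = None
    divergent_partner_id: str | None = None
    divergent_distance: int | None = None


def _check_unique_ids(genes: Sequence[GeneModel]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id: {g.gene_id}")
        seen.add(g.gene_id)


def _is_nested(a: GeneModel, b: GeneModel) -> bool:
    """True if one gene's span lies fully within the other's."""
    return (a.start >= b.start and a.end <= b.end) or (b.start >= a.start and b.end <= a.end)


def closest_upstream_tandem(
    genes: Sequence[GeneModel],
    include_overlaps: bool = False,
) -> list[NeighborContext]:
    """Find, per gene, the same-strand neighbor terminating closest upstream.

    The candidate set for a focal gene comprises same-chromosome,
    same-strand genes whose TSS lies strictly upstream of the focal TSS
    (in the focal transcription direction), excluding nested pairs.  The
    candidate whose TTS is closest to the focal TSS wins, with ties
    broken by lexicographic gene_id.  If that nearest candidate's TTS
    passes the focal TSS (overlap, negative distance) the focal gene is
    reported without a tandem neighbor, unless ``include_overlaps``
    clamps such distances to 0.
    """
    _check_unique_ids(genes)
    out = []
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_key.setdefault((g.chrom, g.strand), []).append(g)

    # sort each group by TTS along transcription direction once, then
    # scan down from the focal TSS per gene
    prepared: dict[tuple[str, str], tuple[list[float], list[GeneModel]]] = {}
    for key, grp in by_key.items():
        strand = key[1]
        # order candidates by signed TTS coordinate in transcription direction
        grp_sorted = sorted(
            grp, key=lambda g: (g.tts if strand == "+" else -g.tts, g.gene_id)
        )
        keys = [g.tts if strand == "+" else -g.tts for g in grp_sorted]
        prepared[key] = (keys, grp_sorted)

    for g in genes:
        ctx = NeighborContext(gene_id=g.gene_id)
        keys, grp_sorted = prepared[(g.chrom, g.strand)]
        focal_tss_key = g.tss if g.strand == "+" else -g.tss
        # candidates: TSS strictly upstream, not nested, not the gene itself.
        # Scan from the largest TTS-key downward: the first qualifying
        # candidate is the nearest one (and determines overlap status).
        best = None
        i = len(keys) - 1
        while i >= 0:
            cand = grp_sorted[i]
            if cand.gene_id == g.gene_id or _is_nested(cand, g):
                i -= 1
                continue
            cand_tss_key = cand.tss if g.strand == "+" else -cand.tss
            if cand_tss_key >= focal_tss_key:
                i -= 1
                continue
            # among equal TTS keys prefer lexicographically smallest id
            j = i
            best = cand
            while j - 1 >= 0 and keys[j - 1] == keys[i]:
                j -= 1
                c2 = grp_sorted[j]
                c2_tss_key = c2.tss if g.strand == "+" else -c2.tss
                if (
                    c2.gene_id != g.gene_id
                    and not _is_nested(c2, g)
                    and c2_tss_key < focal_tss_key
                    and c2.gene_id < best.gene_id
                ):
                    best = c2
            break
        if best is not None:
            d = focal_tss_key - (best.tts if g.strand == "+" else -best.tts)
            if d < 0:
                if include_overlaps:
                    ctx.tandem_upstream_id = best.gene_id
                    ctx.tandem_distance = 0
            else:
                ctx.tandem_upstream_id = best.gene_id
                ctx.tandem_distance = int(d)
        out.append(ctx)
    return out


def closest_divergent(
    genes: Sequence[GeneModel],
    max_distance: int = DEFAULT_DIVERGENT_MAX_DISTANCE,
) -> list[NeighborContext]:
    """Find, per gene, the nearest opposite-strand divergent partner.

    A partner must transcribe away from the focal gene: its TSS lies at
    or upstream of the focal TSS (against the focal transcription
    direction) and it runs in the opposite direction.  Distance is the
    absolute 5'-5' separation; partners beyond ``max_distance`` are
    dropped.  Ties broken by lexicographic gene_id.
    """
    _check_unique_ids(genes)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    out = []
    for g in genes:
        ctx = NeighborContext(gene_id=g.gene_id)
        best: tuple[int, str, GeneModel] | None = None
        for cand in by_chrom[g.chrom]:
            if cand.strand == g.strand or cand.gene_id == g.gene_id:
                continue
            if g.strand == "+":
                ok = cand.tss <= g.tss  # partner 5' end on the upstream (left) side
            else:
                ok = cand.tss >= g.tss
            if not ok:
                continue
            d = abs(g.tss - cand.tss)
            if d > max_distance:
                continue
            key = (d, cand.gene_id)
            if best is None or key < (best[0], best[1]):
                best = (d, cand.gene_id, cand)
        if best is not None:
            ctx.divergent_partner_id = best[1]
            ctx.divergent_distance = int(best[0])
        out.append(ctx)
    return out


def merge_contexts(
    tandem: Sequence[NeighborContext], divergent: Sequence[NeighborContext]
) -> list[NeighborContext]:
    """Combine tandem and divergent context lists on gene_id."""
    div = {c.gene_id: c for c in divergent}
    merged = []
    for t in tandem:
        d = div.get(t.gene_id)
        merged.append(
            NeighborContext(
                gene_id=t.gene_id,
                tandem_upstream_id=t.tandem_upstream_id,
                tandem_distance=t.tandem_distance,
                tandem_upstream_expression=t.tandem_upstream_expression,
                divergent_partner_id=d.divergent_partner_id if d else None,
                divergent_distance=d.divergent_distance if d else None,
            )
        )
    return merged


def attach_upstream_expression(
    contexts: Sequence[NeighborContext], expression: Mapping[str, float]
) -> list[NeighborContext]:
    """Populate each context's tandem-upstream expression from a gene_id map."""
    out = []
    missing = []
    for c in contexts:
        expr = None
        if c.tandem_upstream_id is not None:
            if c.tandem_upstream_id in expression:
                expr = float(expression[c.tandem_upstream_id])
            else:
                missing.append(c.tandem_upstream_id)
        out.append(
            NeighborContext(
                gene_id=c.gene_id,
                tandem_upstream_id=c.tandem_upstream_id,
                tandem_distance=c.tandem_distance,
                tandem_upstream_expression=expr,
                divergent_partner_id=c.divergent_partner_id,
                divergent_distance=c.divergent_distance,
            )
        )
    if missing:
        logger.warning(
            "expression missing for %d upstream gene(s): %s%s",
            len(missing), ", ".join(missing[:5]), "..." if len(missing) > 5 else "",
        )
    return out


def compute_contexts(
    genes: Sequence[GeneModel],
    expression: Mapping[str, float] | None = None,
    divergent_max_distance: int = DEFAULT_DIVERGENT_MAX_DISTANCE,
    include_overlaps: bool = False,
) -> list[NeighborContext]:
    """Tandem + divergent context with upstream expression in one call."""
    tandem = closest_upstream_tandem(genes, include_overlaps=include_overlaps)
    divergent = closest_divergent(genes, max_distance=divergent_max_distance)
    merged = merge_contexts(tandem, divergent)
    if expression is None:
        expression = {g.gene_id: g.expression for g in genes if g.expression is not None}
    return attach_upstream_expression(merged, expression)


def contexts_to_frame(contexts: Iterable[NeighborContext]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "tandem_upstream_id": c.tandem_upstream_id,
                "tandem_distance": c.tandem_distance,
                "tandem_upstream_expression": c.tandem_upstream_expression,
                "divergent_partner_id": c.divergent_partner_id,
                "divergent_distance": c.divergent_distance,
            }
            for c in contexts
        ]
    )


def write_contexts(contexts: Iterable[NeighborContext], path: str | Path) -> None:
    contexts_to_frame(contexts).to_csv(path, sep="\t", index=False)


def read_contexts(path: str | Path) -> list[NeighborContext]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            NeighborContext(
                gene_id=str(r["gene_id"]),
                tandem_upstream_id=None if pd.isna(r["tandem_upstream_id"]) else str(r["tandem_upstream_id"]),
                tandem_distance=None if pd.isna(r["tandem_distance"]) else int(r["tandem_distance"]),
                tandem_upstream_expression=None if pd.isna(r["tandem_upstream_expression"]) else float(r["tandem_upstream_expression"]),
                divergent_partner_id=None if pd.isna(r["divergent_partner_id"]) else str(r["divergent_partner_id"]),
                divergent_distance=None if pd.isna(r["divergent_distance"]) else int(r["divergent_distance"]),
            )
        )
    return out
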