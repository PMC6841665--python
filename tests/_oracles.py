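"""Independent brute-force oracles for neighbor topology.

These apply the neighbor definitions literally, by exhaustive all-pairs
scan, with no shared code with the package's sweep implementation.
"""

from tic.genome_model import GeneModel


def _nested(a: GeneModel, b: GeneModel) -> bool:
    return (a.start >= b.start and a.end <= b.end) or (
        b.start >= a.start and b.end <= a.end
    )


def brute_force_tandem(genes, include_overlaps=False):
    """(upstream_id, distance) per gene_id by exhaustive scan."""
    result = {}
    for focal in genes:
        sign = 1 if focal.strand == "+" else -1
        best = None  # (tts_key, gene_id)
        for cand in genes:
            if cand.gene_id == focal.gene_id:
                continue
            if cand.chrom != focal.chrom or cand.strand != focal.strand:
                continue
            if sign * cand.tss >= sign * focal.tss:
                continue  # candidate must start upstream
            if _nested(cand, focal):
                continue
            key = (sign * cand.tts, cand.gene_id)
            if best is None or key[0] > best[0] or (key[0] == best[0] and key[1] < best[1]):
                best = key
        if best is None:
            result[focal.gene_id] = (None, None)
            continue
        d = sign * focal.tss - best[0]
        if d < 0:
            result[focal.gene_id] = (best[1], 0) if include_overlaps else (None, None)
        else:
            result[focal.gene_id] = (best[1], int(d))
    return result


def brute_force_divergent(genes, max_distance):
    """(partner_id, distance) per gene_id by exhaustive scan."""
    result = {}
    for focal in genes:
        sign = 1 if focal.strand == "+" else -1
        best = None  # (distance, gene_id)
        for cand in genes:
            if cand.gene_id == focal.gene_id:
                continue
            if cand.chrom != focal.chrom or cand.strand == focal.strand:
                continue
            if sign * cand.tss > sign * focal.tss:
                continue  # partner 5' end must sit upstream of the focal TSS
            d = abs(focal.tss - cand.tss)
            if d > max_distance:
                continue
            if best is None or (d, cand.gene_id) < best:
                best = (d, cand.gene_id)
        result[focal.gene_id] = (best[1], best[0]) if best else (None, None)
    return result
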