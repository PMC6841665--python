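"""Count normalization, simple fold-change estimation, and DE classification.

Size factors follow the median-of-ratios convention: each sample's
factor is the median, over genes positive in every sample, of the ratio
of its count to the per-gene geometric mean.  The built-in fold-change
estimator is a point estimator on normalized group means with a
pseudocount; adjusted P values are accepted from external differential
expression tools and treated as authoritative.

A gene is classed ``down`` when its fold change is at most 0.75 and the
adjusted P is below alpha, ``up`` when the fold change is at least 1.25
under the same alpha, and ``unchanged`` otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FC_THRESHOLD = 0.25
DEFAULT_ALPHA = 0.05


@dataclass
class CountMatrix:
    """Nonnegative integer counts, genes x samples, with group labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    condition: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match gene/sample labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    def samples_in_group(self, group: str) -> list[int]:
        idx = [j for j, s in enumerate(self.sample_ids) if self.condition.get(s) == group]
        if not idx:
            raise ValueError(f"unknown or empty group label: {group!r}")
        return idx


@dataclass
class DiffExprRecord:
    gene_id: str
    base_mean: float
    log2fc: float
    padj: float | None = None
    de_class: str = "unchanged"


def size_factors(matrix: CountMatrix) -> dict[str, float]:
    """Median-of-ratios scale factor per sample.

    Computed over genes with all-positive counts; raises if no such
    gene exists.
    """
    counts = matrix.counts.astype(float)
    pos = (counts > 0).all(axis=1)
    if not pos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "add a pseudocount or filter samples"
        )
    sub = counts[pos]
    log_geo = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    return dict(zip(matrix.sample_ids, factors.tolist()))


def normalized_counts(matrix: CountMatrix) -> np.ndarray:
    sf = size_factors(matrix)
    f = np.array([sf[s] for s in matrix.sample_ids])
    return matrix.counts / f


def estimate_log2fc(
    matrix: CountMatrix,
    groups: tuple[str, str],
    pseudocount: float = 1.0,
) -> list[DiffExprRecord]:
    """Point log2 fold change (second group over first) on normalized means.

    ``groups`` is (control, treatment); ``padj`` is left unset — this
    estimator serves synthetic tests, not inference.
    """
    ctrl, mut = groups
    norm = normalized_counts(matrix)
    ci = matrix.samples_in_group(ctrl)
    mi = matrix.samples_in_group(mut)
    ctrl_mean = norm[:, ci].mean(axis=1)
    mut_mean = norm[:, mi].mean(axis=1)
    base_mean = norm.mean(axis=1)
    lfc = np.log2((mut_mean + pseudocount) / (ctrl_mean + pseudocount))
    return [
        DiffExprRecord(gene_id=g, base_mean=float(b), log2fc=float(f))
        for g, b, f in zip(matrix.gene_ids, base_mean, lfc)
    ]


def classify_de(
    records: Sequence[DiffExprRecord],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> list[DiffExprRecord]:
    """Assign up/down/unchanged classes by fold change and adjusted P.

    ``down``: linear fold <= 1 - fc_threshold and padj < alpha;
    ``up``: linear fold >= 1 + fc_threshold and padj < alpha.
    Records lacking padj become ``unchanged`` with a warning.
    """
    lo = 1.0 - fc_threshold
    hi = 1.0 + fc_threshold
    missing = 0
    out = []
    for r in records:
        cls = "unchanged"
        if r.padj is None or (isinstance(r.padj, float) and np.isnan(r.padj)):
            missing += 1
        else:
            fold = 2.0 ** r.log2fc
            if fold <= lo and r.padj < alpha:
                cls = "down"
            elif fold >= hi and r.padj < alpha:
                cls = "up"
        out.append(DiffExprRecord(r.gene_id, r.base_mean, r.log2fc, r.padj, cls))
    if missing:
        logger.warning("%d record(s) lack padj; classified as unchanged", missing)
    return out


def read_count_matrix(path: str | Path, condition: Mapping[str, str]) -> CountMatrix:
    """Read a genes x samples TSV (first column gene ids, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=df.to_numpy(),
        condition=dict(condition),
    )


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(
        matrix.counts, index=matrix.gene_ids, columns=matrix.sample_ids
    ).to_csv(path, sep="\t", index_label="gene_id")


def read_de_table(path: str | Path) -> list[DiffExprRecord]:
    """Read a DE table TSV with columns gene_id, base_mean, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "base_mean", "log2fc", "padj"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: DE table needs columns {sorted(required)}")
    return [
        DiffExprRecord(
            gene_id=str(r["gene_id"]),
            base_mean=float(r["base_mean"]),
            log2fc=float(r["log2fc"]),
            padj=None if pd.isna(r["padj"]) else float(r["padj"]),
        )
        for _, r in df.iterrows()
    ]


def write_de_table(records: Sequence[DiffExprRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "base_mean": r.base_mean,
                "log2fc": r.log2fc,
                "padj": r.padj,
                "de_class": r.de_class,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
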