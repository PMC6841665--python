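"""End-to-end orchestration: validated YAML config, staged execution,
TSV + JSON outputs with provenance (config hash, seed, versions)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from . import coverage_metrics as cm
from . import expression_tables as et
from . import genome_model as gm
from . import interference_stats as istats
from . import mendelian_stats as ms
from . import neighbor_topology as nt

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "annotation", "annotation_format", "tss_table", "chrom_sizes",
    "de_table", "atac_table", "promoter_assignment", "litter_table",
    "pol2_wt", "pol2_mut", "chd2", "input",
    "out_dir", "seed", "log_level",
    "min_gene_length", "divergent_max_distance", "include_overlaps",
    "max_distance", "distance_bins", "expr_split_quantile",
    "upstream_max_distance", "promoter_flank", "pausing_pseudocount",
    "min_body_density",
}

_FILE_KEYS = (
    "annotation", "tss_table", "chrom_sizes", "de_table", "atac_table",
    "promoter_assignment", "litter_table", "pol2_wt", "pol2_mut", "chd2", "input",
)


@dataclass
class RunConfig:
    annotation: str | None = None
    annotation_format: str = "gtf"
    tss_table: str | None = None
    chrom_sizes: str | None = None
    de_table: str | None = None
    atac_table: str | None = None
    promoter_assignment: str | None = None
    litter_table: str | None = None
    pol2_wt: str | None = None
    pol2_mut: str | None = None
    chd2: str | None = None
    input: str | None = None
    out_dir: str = "tic_out"
    seed: int = 0
    log_level: str = "INFO"
    min_gene_length: int = 2000
    divergent_max_distance: int = nt.DEFAULT_DIVERGENT_MAX_DISTANCE
    include_overlaps: bool = False
    max_distance: int = istats.DEFAULT_MAX_DISTANCE
    distance_bins: list[int] = field(
        default_factory=lambda: list(istats.DEFAULT_DISTANCE_BINS)
    )
    expr_split_quantile: float = istats.DEFAULT_EXPR_SPLIT_QUANTILE
    upstream_max_distance: int = istats.DEFAULT_UPSTREAM_MAX_DISTANCE
    promoter_flank: int = gm.PROMOTER_FLANK
    pausing_pseudocount: float = cm.DEFAULT_PSEUDOCOUNT
    min_body_density: float = cm.DEFAULT_MIN_BODY_DENSITY


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config, collecting all errors at once."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except Exception as exc:
        raise ValueError(f"unreadable config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")

    errors: list[str] = []
    for key in raw:
        if key not in _KNOWN_KEYS:
            errors.append(f"unknown config key: {key!r}")
    cfg_kwargs = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
    cfg = RunConfig(**cfg_kwargs)

    base = Path(path).parent
    for key in _FILE_KEYS:
        val = getattr(cfg, key)
        if val is not None:
            p = Path(val)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                errors.append(f"{key}: file not found: {val}")
            else:
                setattr(cfg, key, str(p))
    if any(edge < 0 for edge in cfg.distance_bins):
        errors.append("distance_bins edges must be nonnegative")
    if sorted(cfg.distance_bins) != list(cfg.distance_bins):
        errors.append("distance_bins edges must be increasing")
    if not 0 < cfg.expr_split_quantile < 1:
        errors.append("expr_split_quantile must lie in (0, 1)")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all stages whose inputs exist; write per-stage TSVs and a
    JSON summary under ``cfg.out_dir``.

    A stage error aborts the run, leaving partial outputs under the
    output directory with a ``failed`` marker naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "parameters": dataclasses.asdict(cfg),
        "stages": {},
        "skipped": [],
    }
    stage = "init"
    try:
        genes = None
        contexts = None
        de = None

        if cfg.annotation:
            stage = "genome_model"
            tss = gm.read_tss_table(cfg.tss_table) if cfg.tss_table else None
            genes = gm.parse_annotation(cfg.annotation, fmt=cfg.annotation_format,
                                        tss_table=tss)
            genes = gm.filter_genes(genes, min_length=cfg.min_gene_length)
            summary["stages"]["genome_model"] = {"n_genes": len(genes)}
        else:
            summary["skipped"].append("genome_model")

        if cfg.de_table:
            stage = "expression"
            de = et.classify_de(et.read_de_table(cfg.de_table))
            et.write_de_table(de, out / "de_classified.tsv")
            counts = {c: sum(1 for r in de if r.de_class == c)
                      for c in ("up", "down", "unchanged")}
            summary["stages"]["expression"] = {"n_records": len(de), **counts}
        else:
            summary["skipped"].append("expression")

        if genes is not None:
            stage = "neighbor_topology"
            expression = None
            if de is not None:
                expression = {r.gene_id: r.base_mean for r in de}
            contexts = nt.compute_contexts(
                genes,
                expression=expression,
                divergent_max_distance=cfg.divergent_max_distance,
                include_overlaps=cfg.include_overlaps,
            )
            nt.write_contexts(contexts, out / "neighbors.tsv")
            n_tandem = sum(1 for c in contexts if c.tandem_distance is not None)
            summary["stages"]["neighbor_topology"] = {
                "n_genes": len(contexts), "n_with_tandem": n_tandem,
            }

        if contexts is not None and de is not None:
            stage = "interference_stats"
            report = istats.interference_report(
                de, contexts,
                max_distance=cfg.max_distance,
                distance_bins=cfg.distance_bins,
                upstream_max_distance=cfg.upstream_max_distance,
            )
            div = istats.divergent_control(de, contexts,
                                           distance_bins=cfg.distance_bins)
            summary["stages"]["interference_stats"] = {
                "tandem": _jsonify(report), "divergent": _jsonify(div),
            }
            import pandas as pd

            pd.DataFrame([dataclasses.asdict(b) for b in report.bins]).to_csv(
                out / "interference_bins.tsv", sep="\t", index=False
            )
        elif "interference_stats" not in summary["stages"]:
            summary["skipped"].append("interference_stats")

        if genes is not None and cfg.pol2_wt and cfg.pol2_mut:
            stage = "pausing"
            wt = cm.read_bedgraph(cfg.pol2_wt)
            mut = cm.read_bedgraph(cfg.pol2_mut)
            rows = []
            for g in genes:
                if g.length <= 1000:
                    continue
                clen = len(wt.depths[g.chrom])
                prom = gm.region_of(g, "promoter", clen)
                body = gm.region_of(g, "gene_body", clen)
                recs = {}
                for label, track in (("wt", wt), ("mut", mut)):
                    recs[label] = cm.pausing_index(
                        cm.quantify_region(track, prom),
                        cm.quantify_region(track, body),
                        pseudocount=cfg.pausing_pseudocount,
                        min_body_density=cfg.min_body_density,
                    )
                row = {"gene_id": g.gene_id,
                       "pi_wt": recs["wt"].pi, "pi_mut": recs["mut"].pi}
                if recs["wt"].eligible and recs["mut"].eligible:
                    lr, changed = cm.pausing_change(recs["wt"], recs["mut"])
                    row.update(log2_ratio=lr, changed=changed)
                rows.append(row)
            import pandas as pd

            pd.DataFrame(rows).to_csv(out / "pausing.tsv", sep="\t", index=False)
            n_changed = sum(1 for r in rows if r.get("changed"))
            summary["stages"]["pausing"] = {
                "n_genes": len(rows), "n_changed": n_changed,
            }
        else:
            summary["skipped"].append("pausing")

        if genes is not None and cfg.chd2 and cfg.input:
            stage = "tts_enrichment"
            chd2 = cm.read_bedgraph(cfg.chd2)
            inp = cm.read_bedgraph(cfg.input)
            records = cm.tts_enrichment(chd2, inp, genes)
            import pandas as pd

            pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
                out / "tts_enrichment.tsv", sep="\t", index=False
            )
            med = float(np.median([r.log2_enrichment for r in records]))
            n_sig = sum(1 for r in records if r.padj < 0.05)
            summary["stages"]["tts_enrichment"] = {
                "n_genes": len(records),
                "median_log2_enrichment": med,
                "n_significant": n_sig,
            }
        else:
            summary["skipped"].append("tts_enrichment")

        if cfg.litter_table:
            stage = "mendelian"
            litters = ms.read_litter_table(cfg.litter_table)
            table = ms.litter_report(litters)
            table.to_csv(out / "mendelian.tsv", sep="\t", index=False)
            summary["stages"]["mendelian"] = table.to_dict(orient="records")
        else:
            summary["skipped"].append("mendelian")

    except Exception as exc:
        (out / "failed").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonify(summary), fh, indent=1, sort_keys=True)
    return summary
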