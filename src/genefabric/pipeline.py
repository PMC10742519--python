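"""End-to-end orchestration: probes -> filter -> normalize -> descriptors
-> coordination -> regulation -> fabric, with deterministic TSV reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from genefabric import coordination, descriptors, fabric, pathways, preprocess, regulation

__all__ = ["RunConfig", "load_config", "run_pipeline"]

log = logging.getLogger("genefabric")

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``reference`` must be one of the condition labels present in the probe
    table; every other condition is contrasted against it.
    """

    probes: str | Path
    gmt: str | Path | None = None
    reference: str = "NOR"
    alpha: float = 0.05
    ind_cut: float = 0.05
    uniform_cut: float = 1.5
    spot_mode: str = "replica"
    filter_ratio: float = 2.0
    outdir: str | Path = "gfp_out"

    def validate(self, conditions: list[str]) -> None:
        if self.reference not in conditions:
            raise ValueError(
                f"reference {self.reference!r} not among conditions {conditions}"
            )


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a flat key-value YAML config; keyword overrides win."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def _write(df: pd.DataFrame, path: Path, sort_by: list[str]) -> None:
    df.sort_values(sort_by).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and emit the report bundle under ``config.outdir``.

    Returns the stage tables keyed by report name. Every output is sorted
    and printed at 6 significant digits so reruns are byte-identical.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    raw = preprocess.read_probe_table(config.probes)
    n_probes = raw["probe_id"].nunique()
    filtered = preprocess.filter_probes(raw, ratio=config.filter_ratio)
    n_kept = filtered["probe_id"].nunique()
    log.info("filter: %d of %d probes survive (ratio %.2f)", n_kept, n_probes, config.filter_ratio)

    es = preprocess.normalize(filtered)
    conditions = es.conditions
    config.validate(conditions)
    log.info("normalize: N = %d distinct genes across %d conditions x %d replicas",
             es.n_genes, len(conditions), es.n_replicas)
    preprocess.write_expression_set(es, outdir / "expression.tsv")

    stats_df = descriptors.compute_descriptors(es)
    descriptors.write_descriptors(stats_df, outdir / "descriptors.tsv")

    pathway_sets = pathways.load_gmt(config.gmt) if config.gmt else []
    if pathway_sets:
        union = pathways.distinct_genes(pathway_sets)
        quantified_union = union & set(es.genes)
        log.info("pathways: %d sets, %d distinct genes (%d quantified)",
                 len(pathway_sets), len(union), len(quantified_union))

    # region-wide correlation matrices (GCH context) per condition
    cormats: dict[str, pd.DataFrame] = {}
    m_pairs = 0
    for cond in conditions:
        cormats[cond], m_pairs = coordination.correlation_matrix(es, cond, mode=config.spot_mode)
        labels = coordination.classify_matrix(
            cormats[cond], m_pairs, alpha=config.alpha, ind_cut=config.ind_cut
        )
        coordination.write_adjacency(labels, outdir / f"adjacency_{cond}.tsv")
    log.info("coordination: m = %d paired values, |COR| cutoff %.3f",
             m_pairs, coordination.critical_cor(m_pairs, config.alpha))

    coord_rows = []
    for ps in pathway_sets:
        quantified = ps.quantified(es.genes)
        if len(quantified) < 2:
            log.warning("pathway %s: fewer than 2 quantified genes, skipped", ps.name)
            continue
        for cond in conditions:
            summary = coordination.coord_score(
                cormats[cond].loc[list(quantified), list(quantified)],
                m_pairs,
                pathway=ps.name,
                condition=cond,
                alpha=config.alpha,
                ind_cut=config.ind_cut,
            )
            coord_rows.append(
                {
                    "pathway": summary.pathway,
                    "condition": summary.condition,
                    "n_quantified": len(quantified),
                    "n_total": len(ps.genes),
                    "pct_syn": summary.pct_syn,
                    "pct_ant": summary.pct_ant,
                    "pct_ind": summary.pct_ind,
                    "COORD": summary.coord,
                }
            )
    coord_df = pd.DataFrame(coord_rows)

    cancers = [c for c in conditions if c != config.reference]
    reg_parts, audit_parts, fabric_parts, pathsum_parts = [], [], [], []
    for cancer in cancers:
        rec = regulation.build_regulation_table(
            stats_df, es, cancer, config.reference, alpha=config.alpha
        )
        reg_parts.append(rec)
        fp, fn = regulation.false_hit_audit(rec, uniform_cut=config.uniform_cut, alpha=config.alpha)
        fp = fp.assign(kind="false_positive")
        fn = fn.assign(kind="false_negative")
        audit_parts.extend([fp, fn])
        log.info("regulation %s->%s: %d significant, %d uniform-rule false positives, %d false negatives",
                 cancer, config.reference, int(rec["significant"].sum()), len(fp), len(fn))

        fabric_parts.append(
            fabric.build_fabric_table(
                rec, stats_df, cormats[cancer], cormats[config.reference],
                cancer, config.reference,
            )
        )
        if pathway_sets:
            pathsum_parts.append(regulation.pathway_regulation_summary(pathway_sets, rec, alpha=config.alpha))

    reg_df = pd.concat(reg_parts, ignore_index=True)
    audit_df = (
        pd.concat(audit_parts, ignore_index=True)
        if audit_parts and any(len(a) for a in audit_parts)
        else pd.DataFrame(columns=[*reg_df.columns, "kind"])
    )
    fabric_df = pd.concat(fabric_parts, ignore_index=True)

    gch_parts = []
    for cond in conditions:
        g = fabric.compute_gch(stats_df, cormats[cond], cond)
        gch_parts.append(g)
        log.info("hierarchy %s: GMR = %s", cond, fabric.gmr(g))
    gch_df = pd.concat(gch_parts, ignore_index=True)

    _write(reg_df, outdir / "regulome.tsv", ["contrast", "gene"])
    _write(audit_df, outdir / "audit.tsv", ["contrast", "gene"] if len(audit_df) else ["gene"])
    fabric.write_fabric_table(fabric_df, outdir / "fabric.tsv")
    _write(gch_df, outdir / "gch.tsv", ["condition", "rank", "gene"])
    if len(coord_df):
        _write(coord_df, outdir / "coordination.tsv", ["pathway", "condition"])
    if pathsum_parts:
        pathsum_df = pd.concat(pathsum_parts, ignore_index=True)
        _write(pathsum_df, outdir / "pathway_summary.tsv", ["pathway", "contrast"])
    else:
        pathsum_df = pd.DataFrame()

    return {
        "expression": es.a,
        "descriptors": stats_df,
        "coordination": coord_df,
        "regulome": reg_df,
        "audit": audit_df,
        "fabric": fabric_df,
        "gch": gch_df,
        "pathway_summary": pathsum_df,
    }
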