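"""Fabric-level remodeling metrics and the gene hierarchy.

A gene's transcriptomic alteration between a cancer nodule and its
reference tissue has three orthogonal components: the weighted expression
regulation (WIR), the change in homeostatic control (delta_control, the
difference of the 100/REV control values; the field also calls this
delta-REC since the condition medians cancel), and the net change in
expression coordination (delta_cor). The transcriptomic distance TDI is
the Euclidean norm of the three. Within one condition, the gene
commanding height GCH rewards low variability and strong coordination
with the rest of the quantified transcriptome; the top-ranked gene is the
region's gene master regulator (GMR).
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from genefabric.coordination import DeltaCorResult, delta_cor

__all__ = [
    "delta_control",
    "tdi",
    "gch_score",
    "compute_gch",
    "gmr",
    "build_fabric_table",
    "write_fabric_table",
]

#: weight of the coordination term in the GCH exponent
GCH_COR_WEIGHT = 4.0


def delta_control(rev_cancer: float, rev_ref: float) -> float:
    """Change in expression control: 100/REV_cancer - 100/REV_ref.

    Positive values mean the gene's transcript abundance is more tightly
    controlled in the cancer nodule than in the reference tissue.
    """
    if rev_cancer <= 0 or rev_ref <= 0:
        raise ValueError("REV values must be positive")
    return 100.0 / rev_cancer - 100.0 / rev_ref


def tdi(wir: float, d_control: float, d_cor: float) -> float:
    """Transcriptomic distance: Euclidean norm of (WIR, delta_control, delta_cor)."""
    return math.sqrt(wir**2 + d_control**2 + d_cor**2)


def gch_score(rev: float, median_rev: float, cor_row: np.ndarray) -> float:
    """Gene commanding height of one gene in one condition.

    ``(median_REV / REV) * exp(4 * mean(COR^2))`` over the gene's
    correlations with every other quantified gene: the first factor
    rewards tight homeostatic control (low REV), the exponential rewards
    broad coordination strength. Undefined correlations are skipped.
    """
    if rev <= 0:
        raise ValueError("REV must be positive")
    c = np.asarray(cor_row, dtype=float)
    c = c[~np.isnan(c)]
    mean_sq = float(np.mean(c**2)) if c.size else 0.0
    return (median_rev / rev) * math.exp(GCH_COR_WEIGHT * mean_sq)


def compute_gch(
    stats_df: pd.DataFrame, cormat: pd.DataFrame, condition: str
) -> pd.DataFrame:
    """GCH and rank for every quantified gene of one condition.

    ``cormat`` should cover all quantified genes (the hierarchy is
    region-wide, not pathway-restricted). Genes with REV = 0 are excluded
    with a flag column.
    """
    sub = stats_df[stats_df["condition"] == condition].set_index("gene")
    genes = [g for g in cormat.index if g in sub.index]
    rev = sub.loc[genes, "REV"]
    ok = rev > 0
    median_rev = float(rev[ok].median())
    C = cormat.loc[genes, genes].to_numpy(dtype=float)
    np.fill_diagonal(C, np.nan)  # own correlation excluded from the average
    rows = []
    for i, g in enumerate(genes):
        if not ok.loc[g]:
            rows.append({"gene": g, "condition": condition, "GCH": np.nan, "excluded": True})
            continue
        rows.append(
            {
                "gene": g,
                "condition": condition,
                "GCH": gch_score(float(rev.loc[g]), median_rev, C[i]),
                "excluded": False,
            }
        )
    out = pd.DataFrame(rows)
    out["rank"] = out["GCH"].rank(ascending=False, method="min")
    return out.sort_values(["rank", "gene"]).reset_index(drop=True)


def gmr(gch_df: pd.DataFrame) -> str:
    """Gene master regulator: the gene with the highest GCH.

    Ties are broken lexicographically by symbol, with a warning.
    """
    valid = gch_df[~gch_df["GCH"].isna()]
    if valid.empty:
        raise ValueError("no genes with a defined GCH")
    top = valid["GCH"].max()
    winners = sorted(valid.loc[valid["GCH"] == top, "gene"])
    if len(winners) > 1:
        warnings.warn(f"GCH tie among {winners}; returning {winners[0]!r}")
    return winners[0]


def build_fabric_table(
    records: pd.DataFrame,
    stats_df: pd.DataFrame,
    cor_cancer: pd.DataFrame,
    cor_ref: pd.DataFrame,
    cancer: str,
    ref: str,
    pathway_genes: Sequence[str] | None = None,
    context: str = "all",
) -> pd.DataFrame:
    """Per-gene fabric metrics for one contrast.

    Combines the regulation records (WIR), the descriptor table (REV for
    delta_control), and the two conditions' correlation matrices
    (delta_cor, restricted to ``pathway_genes`` when a pathway context is
    given). Output columns: gene, contrast, context, WIR, delta_control,
    delta_cor, TDI.
    """
    wide = stats_df.pivot(index="gene", columns="condition", values="REV")
    rec = records.set_index("gene")
    genes = [g for g in rec.index if g in cor_cancer.index]
    if pathway_genes is not None:
        partner_set = [g for g in pathway_genes if g in cor_cancer.index]
        genes = [g for g in genes if g in set(pathway_genes)]
    else:
        partner_set = list(cor_cancer.index)
    rows = []
    for gene in genes:
        dcor: DeltaCorResult = delta_cor(gene, partner_set, cor_cancer, cor_ref)
        d_ctrl = delta_control(float(wide.loc[gene, cancer]), float(wide.loc[gene, ref]))
        w = float(rec.loc[gene, "WIR"])
        rows.append(
            {
                "gene": gene,
                "contrast": f"{cancer}->{ref}",
                "context": context,
                "WIR": w,
                "delta_control": d_ctrl,
                "delta_cor": dcor.value,
                "n_cor_pairs": dcor.n_pairs,
                "TDI": tdi(w, d_ctrl, dcor.value),
            }
        )
    return pd.DataFrame(rows)


def write_fabric_table(fabric_df: pd.DataFrame, path) -> None:
    fabric_df.sort_values(["contrast", "gene"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
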