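"""Cancer-vs-reference expression regulation with per-gene adaptive cutoffs.

The signed fold change x is the ratio of condition AVEs, folded through
the reciprocal for down-regulation (x = -AVE_ref/AVE_cancer when the
ratio drops below 1, so |x| >= 1 always). Instead of a uniform fold-change
threshold, each gene gets CUT = 1 + sqrt((REV_cancer/100)^2 +
(REV_ref/100)^2): noisy genes must clear a higher bar, stable genes a
lower one. A gene is significantly regulated when |x| > CUT and the
two-tailed Welch (heteroscedastic) t-test of its replicate expressions
gives p < 0.05. WIR weighs each gene's regulation by its reference
expression level and significance; WPR averages |WIR| over a pathway.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from genefabric.preprocess import ExpressionSet

__all__ = [
    "fold_change",
    "cut_value",
    "regulation_test",
    "build_regulation_table",
    "call_regulome",
    "false_hit_audit",
    "wir",
    "wpr",
    "pathway_regulation_summary",
]

ALPHA = 0.05


def fold_change(ave_cancer: float, ave_ref: float) -> float:
    """Signed expression ratio; negative for down-regulation, |x| >= 1."""
    if ave_cancer <= 0 or ave_ref <= 0:
        raise ValueError("AVE values must be positive")
    rho = ave_cancer / ave_ref
    return rho if rho >= 1.0 else -1.0 / rho


def cut_value(rev_cancer: float, rev_ref: float) -> float:
    """Per-gene absolute fold-change cutoff from the two conditions' REVs (%)."""
    if rev_cancer < 0 or rev_ref < 0:
        raise ValueError("REV values must be non-negative")
    return 1.0 + math.hypot(rev_cancer / 100.0, rev_ref / 100.0)


def regulation_test(
    values_cancer: Sequence[float], values_ref: Sequence[float], log2: bool = False
) -> float:
    """Two-tailed Welch t-test p-value on replicate expression values.

    Run on the linear normalized values by default (the scale on which the
    condition means are compared); ``log2=True`` tests the logged values
    instead. Degenerate zero-variance-on-both-sides input returns p = 1
    for equal means and p = 0 otherwise.
    """
    x = np.asarray(values_cancer, dtype=float)
    y = np.asarray(values_ref, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 replicas per condition")
    if log2:
        x = np.log2(x)
        y = np.log2(y)
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def wir(ave_ref: float, x: float, p: float) -> float:
    """Weighted individual regulation: sign(x) * AVE_ref * (|x| - 1) * (1 - p)."""
    magnitude = ave_ref * (abs(x) - 1.0) * (1.0 - p)
    return math.copysign(magnitude, x) if abs(x) > 1.0 else 0.0


def build_regulation_table(
    stats_df: pd.DataFrame,
    es: ExpressionSet,
    cancer: str,
    ref: str,
    alpha: float = ALPHA,
    log2_test: bool = False,
) -> pd.DataFrame:
    """Per-gene regulation records for one cancer-vs-reference contrast.

    Requires the descriptor table (AVE, REV per gene and condition) and
    the expression set for the replicate-level t-test. Output columns:
    gene, contrast, x, CUT, p, significant, WIR.
    """
    wide = stats_df.pivot(index="gene", columns="condition", values=["AVE", "REV"])
    mat_c = es.matrix(cancer)
    mat_r = es.matrix(ref)
    rows = []
    for gene in wide.index:
        ave_c = wide.loc[gene, ("AVE", cancer)]
        ave_r = wide.loc[gene, ("AVE", ref)]
        x = fold_change(ave_c, ave_r)
        cut = cut_value(wide.loc[gene, ("REV", cancer)], wide.loc[gene, ("REV", ref)])
        p = regulation_test(mat_c.loc[gene].to_numpy(), mat_r.loc[gene].to_numpy(), log2=log2_test)
        rows.append(
            {
                "gene": gene,
                "contrast": f"{cancer}->{ref}",
                "x": x,
                "CUT": cut,
                "p": p,
                "significant": bool(abs(x) > cut and p < alpha),
                "WIR": wir(ave_r, x, p),
            }
        )
    return pd.DataFrame(rows)


def call_regulome(records: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Significantly regulated genes with direction (|x| > CUT and p < alpha)."""
    sig = records[(records["x"].abs() > records["CUT"]) & (records["p"] < alpha)].copy()
    sig["direction"] = np.where(sig["x"] > 0, "up", "down")
    return sig.reset_index(drop=True)


def false_hit_audit(
    records: pd.DataFrame, uniform_cut: float = 1.5, alpha: float = ALPHA
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes the uniform fold-change rule would mis-call versus the CUT rule.

    A false positive passes the uniform |x| > uniform_cut (with p < alpha)
    screen but is not significant under the per-gene CUT; a false negative
    fails the uniform screen yet is significant under CUT. Returns
    (false_positives, false_negatives).
    """
    sig = (records["x"].abs() > records["CUT"]) & (records["p"] < alpha)
    uniform = (records["x"].abs() > uniform_cut) & (records["p"] < alpha)
    fp = records[uniform & ~sig].reset_index(drop=True)
    fn = records[(records["x"].abs() < uniform_cut) & sig].reset_index(drop=True)
    return fp, fn


def wpr(pathway_genes: Sequence[str], records: pd.DataFrame) -> float:
    """Weighted pathway regulation: mean |WIR| over the quantified pathway genes."""
    sub = records[records["gene"].isin(set(pathway_genes))]
    if sub.empty:
        raise ValueError("no quantified genes from the pathway in the records")
    return float(sub["WIR"].abs().mean())


def pathway_regulation_summary(
    pathway_sets, records: pd.DataFrame, alpha: float = ALPHA
) -> pd.DataFrame:
    """Per-pathway regulation summary for one contrast.

    Percentages of significantly up-/down-regulated genes use the
    *quantified* gene count of the pathway as the denominator.
    """
    rec = records.set_index("gene")
    rows = []
    for ps in pathway_sets:
        quantified = [g for g in ps.genes if g in rec.index]
        if not quantified:
            continue
        sub = rec.loc[quantified]
        sig = (sub["x"].abs() > sub["CUT"]) & (sub["p"] < alpha)
        n_q = len(quantified)
        rows.append(
            {
                "pathway": ps.name,
                "contrast": sub["contrast"].iloc[0],
                "n_quantified": n_q,
                "n_total": len(ps.genes),
                "pct_up": 100.0 * np.sum(sig & (sub["x"] > 0)) / n_q,
                "pct_down": 100.0 * np.sum(sig & (sub["x"] < 0)) / n_q,
                "WPR": float(sub["WIR"].abs().mean()),
            }
        )
    return pd.DataFrame(rows)
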