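"""Per-gene, per-condition descriptors: AVE, REV, and expression control.

AVE is the arithmetic mean of the normalized expression over the
biological replicas of a condition. REV is the relative expression
variability: the midpoint of the chi-square confidence interval of the
coefficient of variation, pooled over the ``upsilon * n`` spot-level
values of the gene in that condition, expressed in percent. Low REV marks
a tightly controlled (homeostatically protected) gene. The control scale
is 100/REV, and REC references it to the condition median so positive REC
means more-than-median control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from genefabric.preprocess import ExpressionSet

__all__ = [
    "rev_correction_factor",
    "compute_ave",
    "compute_rev",
    "compute_rec",
    "compute_descriptors",
    "write_descriptors",
]


def rev_correction_factor(r: int | np.ndarray, ci: float = 0.95) -> float | np.ndarray:
    """Mid-chi-square interval factor applied to the sample CV.

    ``factor = 0.5 * (sqrt(r / chi2_lo) + sqrt(r / chi2_hi))`` where
    chi2_lo/hi are the (1-ci)/2 and (1+ci)/2 quantiles of the chi-square
    distribution with ``r`` degrees of freedom. The factor is > 1 for
    finite r and tends to 1 as r grows, compensating the downward bias of
    the sample CV at few replicas.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 1):
        raise ValueError("degrees of freedom must be >= 1")
    lo = stats.chi2.ppf((1.0 - ci) / 2.0, r)
    hi = stats.chi2.ppf((1.0 + ci) / 2.0, r)
    factor = 0.5 * (np.sqrt(r / lo) + np.sqrt(r / hi))
    return float(factor) if factor.ndim == 0 else factor


def compute_ave(es: ExpressionSet) -> pd.DataFrame:
    """Mean normalized expression per (gene, condition)."""
    ave = (
        es.a.groupby(["gene", "condition"], sort=True)["a"]
        .mean()
        .rename("AVE")
        .reset_index()
    )
    return ave


def compute_rev(es: ExpressionSet, ci: float = 0.95) -> pd.DataFrame:
    """Relative expression variability (%) per (gene, condition).

    Pools all spot-level normalized values of the gene in the condition
    (``r = upsilon * n - 1`` degrees of freedom).
    """
    grouped = es.spots.groupby(["gene", "condition"], sort=True)["value"]
    agg = grouped.agg(mu="mean", s=lambda v: v.std(ddof=1), m="count").reset_index()
    if (agg["mu"] <= 0).any():
        bad = agg.loc[agg["mu"] <= 0, "gene"].iloc[0]
        raise ValueError(f"non-positive mean expression for gene {bad!r}")
    r = agg["m"].to_numpy() - 1
    if (r < 1).any():
        raise ValueError("need at least 2 pooled values per (gene, condition)")
    factor = rev_correction_factor(r, ci=ci)
    agg["REV"] = factor * (agg["s"] / agg["mu"]) * 100.0
    return agg[["gene", "condition", "REV"]]


def compute_rec(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Add expression control (100/REV) and median-referenced REC.

    Genes with REV = 0 get infinite control; they are flagged and excluded
    from the per-condition median so they do not distort REC.
    """
    out = stats_df.copy()
    rev = out["REV"].to_numpy()
    with np.errstate(divide="ignore"):
        out["control"] = np.where(rev > 0, 100.0 / rev, np.inf)
    out["control_flagged"] = ~np.isfinite(out["control"])
    med = (
        out[~out["control_flagged"]]
        .groupby("condition")["control"]
        .median()
        .rename("median_control")
    )
    out = out.merge(med, on="condition", how="left")
    out["REC"] = out["control"] - out["median_control"]
    return out.drop(columns="median_control")


def compute_descriptors(es: ExpressionSet, ci: float = 0.95) -> pd.DataFrame:
    """AVE, REV, control, and REC for every (gene, condition)."""
    ave = compute_ave(es)
    rev = compute_rev(es, ci=ci)
    return compute_rec(ave.merge(rev, on=["gene", "condition"]))


def write_descriptors(stats_df: pd.DataFrame, path) -> None:
    cols = ["gene", "condition", "AVE", "REV", "control", "REC"]
    stats_df.sort_values(["condition", "gene"])[cols].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
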