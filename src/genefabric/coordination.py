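"""Pairwise expression coordination and pathway coordination scores.

Two genes are coordinated through the Pearson correlation (COR) of their
log2 normalized expressions across the biological replicas of one
condition. With m paired values, the two-tailed significance of COR comes
from the t transform ``t = |COR| * sqrt((m-2) / (1-COR^2))`` on m-2
degrees of freedom; the corresponding critical magnitude at level alpha
is ``r* = t* / sqrt(t*^2 + m - 2)``, which decreases as more redundant
spots contribute paired values. A pair is synergistic (SYN) when COR
reaches +r*, antagonistic (ANT) below -r*, independent (IND) when
|COR| <= 0.05, and unclassified (NONE) otherwise. The coordination score
of a pathway is %SYN + %ANT - %IND over all its gene pairs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from genefabric.preprocess import ExpressionSet

__all__ = [
    "PairClass",
    "CorRecord",
    "CoordinationSummary",
    "cor_pair",
    "pearson_pvalue",
    "critical_cor",
    "classify_pair",
    "correlation_matrix",
    "classify_matrix",
    "coord_score",
    "coordination_score",
    "coordination_profile",
    "delta_cor",
    "DeltaCorResult",
    "write_adjacency",
    "to_graph",
]

#: magnitude below which a significant-by-t-test-or-not pair counts as independent
DEFAULT_IND_CUT = 0.05


class PairClass(str, enum.Enum):
    SYN = "SYN"
    ANT = "ANT"
    IND = "IND"
    NONE = "NONE"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


class CorRecord(NamedTuple):
    cor: float
    m: int
    p: float


def pearson_pvalue(cor: float, m: int) -> float:
    """Two-tailed p-value of a Pearson coefficient from m paired values."""
    if m < 3:
        raise ValueError("need at least 3 paired values")
    if math.isnan(cor):
        return math.nan
    if abs(cor) >= 1.0:
        return 0.0
    t = abs(cor) * math.sqrt((m - 2) / (1.0 - cor**2))
    return 2.0 * stats.t.sf(t, m - 2)


def cor_pair(x_i: Sequence[float], x_j: Sequence[float], log2: bool = True) -> CorRecord:
    """COR, paired-value count, and p-value for two replicate profiles.

    Profiles must come from the same condition with equal length m >= 3.
    Correlation is computed on the log2 values (the analysis convention);
    pass ``log2=False`` for already-logged input. Zero variance in either
    profile yields an undefined record (NaN cor and p) that downstream
    percentage counts treat as unclassified.
    """
    x = np.asarray(x_i, dtype=float)
    y = np.asarray(x_j, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    m = len(x)
    if m < 3:
        raise ValueError("need at least 3 paired values")
    if log2:
        x = np.log2(x)
        y = np.log2(y)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return CorRecord(math.nan, m, math.nan)
    cor = float(np.corrcoef(x, y)[0, 1])
    cor = max(-1.0, min(1.0, cor))
    return CorRecord(cor, m, pearson_pvalue(cor, m))


def critical_cor(m: int, alpha: float = 0.05) -> float:
    """Two-tailed critical Pearson magnitude at level alpha for m pairs.

    ``r* = t* / sqrt(t*^2 + m - 2)`` with t* the (1 - alpha/2) quantile of
    the t distribution on m - 2 degrees of freedom; strictly decreasing
    in m (0.95 at m=4, 0.71 at m=8, 0.58 at m=12 for alpha = 0.05).
    """
    if m < 3:
        raise ValueError("need at least 3 paired values")
    t_star = stats.t.ppf(1.0 - alpha / 2.0, m - 2)
    return float(t_star / math.sqrt(t_star**2 + m - 2))


def classify_pair(
    rec: CorRecord, alpha: float = 0.05, ind_cut: float = DEFAULT_IND_CUT
) -> PairClass:
    """SYN / ANT / IND / NONE label for one correlation record.

    Ties exactly at a threshold are classified significant. Undefined
    correlations (NaN) are never IND — independence is a claim about a
    near-zero correlation, not about missingness — and come back NONE.
    """
    if math.isnan(rec.cor):
        return PairClass.NONE
    r_star = critical_cor(rec.m, alpha)
    if rec.cor >= r_star:
        return PairClass.SYN
    if rec.cor <= -r_star:
        return PairClass.ANT
    if abs(rec.cor) <= ind_cut:
        return PairClass.IND
    return PairClass.NONE


def correlation_matrix(
    es: ExpressionSet,
    condition: str,
    genes: Sequence[str] | None = None,
    mode: str = "replica",
) -> tuple[pd.DataFrame, int]:
    """COR matrix of log2 expression for a condition; returns (matrix, m).

    ``mode='replica'`` (default) correlates the replica-aggregated values
    (m = n). ``mode='spot'`` pairs the k-th spot of each gene, giving
    m = upsilon * n paired values, and requires every selected gene to
    carry the same spot count. Zero-variance genes get NaN rows/columns;
    the diagonal is 1 where defined.
    """
    if mode not in ("replica", "spot"):
        raise ValueError("mode must be 'replica' or 'spot'")
    if mode == "replica":
        mat = es.matrix(condition)
        if genes is not None:
            present = [g for g in genes if g in mat.index]
            mat = mat.loc[present]
        X = np.log2(mat.to_numpy())
        index = mat.index
    else:
        sel = genes if genes is not None else es.genes
        ups = {es.upsilon[g] for g in sel if g in es.upsilon.index}
        if len(ups) > 1:
            raise ValueError("spot mode requires equal spot counts across genes")
        rows = []
        index = []
        for g in sel:
            if g not in es.upsilon.index:
                continue
            rows.append(np.log2(es.pooled_values(g, condition)))
            index.append(g)
        X = np.asarray(rows)
        index = pd.Index(index, name="gene")
    X = np.atleast_2d(X)
    m = X.shape[1]
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    C[sd == 0.0, :] = np.nan
    C[:, sd == 0.0] = np.nan
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, np.where(sd == 0.0, np.nan, 1.0))
    return pd.DataFrame(C, index=index, columns=index), m


def classify_matrix(
    cormat: pd.DataFrame, m: int, alpha: float = 0.05, ind_cut: float = DEFAULT_IND_CUT
) -> pd.DataFrame:
    """Element-wise SYN/ANT/IND/NONE labels for a COR matrix."""
    r_star = critical_cor(m, alpha)
    C = cormat.to_numpy()
    labels = np.full(C.shape, PairClass.NONE.value, dtype=object)
    with np.errstate(invalid="ignore"):
        labels[C >= r_star] = PairClass.SYN.value
        labels[C <= -r_star] = PairClass.ANT.value
        labels[(np.abs(C) <= ind_cut)] = PairClass.IND.value
    labels[np.isnan(C)] = PairClass.NONE.value
    return pd.DataFrame(labels, index=cormat.index, columns=cormat.columns)


@dataclass
class CoordinationSummary:
    pathway: str
    condition: str
    pct_syn: float
    pct_ant: float
    pct_ind: float
    n_pairs: int

    @property
    def coord(self) -> float:
        return coordination_score(self.pct_syn, self.pct_ant, self.pct_ind)


def coordination_score(pct_syn: float, pct_ant: float, pct_ind: float) -> float:
    """Pathway coordination score: %synergistic + %antagonistic - %independent."""
    return pct_syn + pct_ant - pct_ind


def coord_score(
    cormat: pd.DataFrame,
    m: int,
    pathway: str = "",
    condition: str = "",
    alpha: float = 0.05,
    ind_cut: float = DEFAULT_IND_CUT,
) -> CoordinationSummary:
    """Classify all unordered gene pairs of a pathway and summarize.

    Percentages are over all C(|genes|, 2) pairs; pairs with undefined COR
    stay in the denominator as unclassified.
    """
    g = len(cormat)
    if g < 2:
        raise ValueError("need at least 2 genes for a coordination score")
    labels = classify_matrix(cormat, m, alpha, ind_cut).to_numpy()
    iu = np.triu_indices(g, k=1)
    upper = labels[iu]
    total = len(upper)
    pct = {
        cls: 100.0 * np.sum(upper == cls.value) / total
        for cls in (PairClass.SYN, PairClass.ANT, PairClass.IND)
    }
    return CoordinationSummary(
        pathway=pathway,
        condition=condition,
        pct_syn=pct[PairClass.SYN],
        pct_ant=pct[PairClass.ANT],
        pct_ind=pct[PairClass.IND],
        n_pairs=total,
    )


def coordination_profile(
    gene: str,
    cormat: pd.DataFrame,
    m: int,
    alpha: float = 0.05,
    ind_cut: float = DEFAULT_IND_CUT,
) -> list[tuple[str, PairClass]]:
    """Significant partners (SYN/ANT/IND) of one gene within a gene set."""
    if gene not in cormat.index:
        raise KeyError(f"gene {gene!r} not in the correlation matrix")
    out = []
    for partner in cormat.columns:
        if partner == gene:
            continue
        c = cormat.loc[gene, partner]
        rec = CorRecord(float(c), m, pearson_pvalue(float(c), m) if not math.isnan(c) else math.nan)
        cls = classify_pair(rec, alpha, ind_cut)
        if cls is not PairClass.NONE:
            out.append((partner, cls))
    return out


class DeltaCorResult(NamedTuple):
    value: float
    n_pairs: int
    n_skipped: int


def delta_cor(
    gene: str,
    pathway_genes: Sequence[str],
    cor_cancer: pd.DataFrame,
    cor_ref: pd.DataFrame,
) -> DeltaCorResult:
    """Net coordination change of a gene with a pathway between conditions.

    Sum over the pathway partners j != gene of |COR(cancer)| - |COR(ref)|;
    positive values mean an overall coordination gain in cancer. Pairs with
    an undefined COR in either condition are skipped and counted.
    """
    total = 0.0
    used = 0
    skipped = 0
    for j in pathway_genes:
        if j == gene:
            continue
        try:
            c1 = float(cor_cancer.loc[gene, j])
            c0 = float(cor_ref.loc[gene, j])
        except KeyError:
            skipped += 1
            continue
        if math.isnan(c1) or math.isnan(c0):
            skipped += 1
            continue
        total += abs(c1) - abs(c0)
        used += 1
    return DeltaCorResult(total, used, skipped)


def write_adjacency(labels: pd.DataFrame, path) -> None:
    """Square TSV of pair-class labels (rows and columns are genes)."""
    labels.to_csv(path, sep="\t")


def to_graph(labels: pd.DataFrame):
    """Significant-pair graph (SYN/ANT/IND edges) as a networkx Graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(labels.index)
    genes = list(labels.index)
    for i, gi in enumerate(genes):
        for gj in genes[i + 1 :]:
            cls = labels.loc[gi, gj]
            if cls != PairClass.NONE.value:
                g.add_edge(gi, gj, cls=cls)
    return g
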