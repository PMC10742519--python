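"""Spot filtering, redundant-spot aggregation, and median-gene normalization.

A spot whose foreground fluorescence is below twice its background in even
one sample is considered unreliable and is dropped from *every* sample, so
all profiled samples retain the identical probe (and hence gene) set. Net
fluorescence (foreground minus background) is summed over a gene's
redundant spots within each sample and divided by the sample's median
gene-level value, yielding the normalized expression ``a`` with the
convention that ``a > 1`` marks above-median expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from genefabric.synthetic import PROBE_COLUMNS

__all__ = [
    "PreprocessError",
    "ExpressionSet",
    "read_probe_table",
    "write_probe_table",
    "filter_probes",
    "normalize",
    "write_expression_set",
    "load_geo_series_matrix",
]

# relative floor applied to net fluorescence so every value stays positive
# for the log2 steps downstream; the reliability filter makes true
# non-positive nets rare
NET_FLOOR_FRACTION = 1e-6


class PreprocessError(ValueError):
    """Raised for malformed or degenerate probe tables."""


def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Read a probe-level TSV with columns probe_id, gene, condition, replica, fg, bg."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene": str, "condition": str})
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise PreprocessError(f"probe table missing columns: {sorted(missing)}")
    return df[PROBE_COLUMNS]


def write_probe_table(table: pd.DataFrame, path: str | Path) -> None:
    table[PROBE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6f")


def filter_probes(raw: pd.DataFrame, ratio: float = 2.0) -> pd.DataFrame:
    """Drop every probe with fg < ratio*bg in at least one sample, from all samples.

    Genes losing all their probes disappear entirely, so the surviving
    probe and gene sets are identical across samples.
    """
    bad = raw.loc[raw["fg"] < ratio * raw["bg"], "probe_id"].unique()
    out = raw[~raw["probe_id"].isin(set(bad))].reset_index(drop=True)
    if out.empty:
        raise PreprocessError("no probes survive the reliability filter")
    return out


@dataclass
class ExpressionSet:
    """Filtered, normalized expression values with spot-level detail.

    Attributes
    ----------
    a:
        Long table (gene, condition, replica, a) of aggregated normalized
        expression; within each sample the median of ``a`` over genes is 1.
    spots:
        Long table (probe_id, gene, condition, replica, value) of
        spot-level normalized net fluorescence on the same per-sample scale.
    upsilon:
        Series gene -> number of redundant spots (identical across samples).
    conditions:
        Condition labels in input order.
    n_replicas:
        Replicas per condition.
    """

    a: pd.DataFrame
    spots: pd.DataFrame
    upsilon: pd.Series
    conditions: list[str]
    n_replicas: int

    @property
    def genes(self) -> list[str]:
        return sorted(self.upsilon.index)

    @property
    def n_genes(self) -> int:
        return len(self.upsilon)

    def matrix(self, condition: str) -> pd.DataFrame:
        """Gene x replica matrix of aggregated normalized expression."""
        sub = self.a[self.a["condition"] == condition]
        if sub.empty:
            raise KeyError(f"unknown condition {condition!r}")
        return sub.pivot(index="gene", columns="replica", values="a").sort_index()

    def pooled_values(self, gene: str, condition: str) -> np.ndarray:
        """All upsilon*n spot-level normalized values of a gene in one condition."""
        sub = self.spots[(self.spots["gene"] == gene) & (self.spots["condition"] == condition)]
        if sub.empty:
            raise KeyError(f"no values for gene {gene!r} in condition {condition!r}")
        return sub.sort_values(["replica", "probe_id"])["value"].to_numpy()

    def replicate_profile(self, gene: str, condition: str) -> np.ndarray:
        """Aggregated values a_i^(c;k), k = 1..n, in replica order."""
        sub = self.a[(self.a["gene"] == gene) & (self.a["condition"] == condition)]
        if sub.empty:
            raise KeyError(f"no values for gene {gene!r} in condition {condition!r}")
        return sub.sort_values("replica")["a"].to_numpy()


def normalize(filtered: pd.DataFrame) -> ExpressionSet:
    """Aggregate redundant spots and normalize each sample to its median gene.

    Per sample: net = fg - bg, floored at a small positive fraction of the
    sample's median net; a gene's value is the sum of its spots' nets; the
    sample is rescaled so the median of the gene-level values equals 1 and
    spot-level values are kept on the same scale.
    """
    df = filtered.copy()
    df["net"] = df["fg"] - df["bg"]

    upsilon = df.groupby("gene")["probe_id"].nunique()
    conditions = list(pd.unique(df["condition"]))
    n_replicas = df.groupby("condition")["replica"].nunique()
    if n_replicas.nunique() != 1:
        raise PreprocessError("replica count differs between conditions")
    n = int(n_replicas.iloc[0])

    a_parts = []
    spot_parts = []
    for (cond, rep), sample in df.groupby(["condition", "replica"], sort=False):
        med_net = float(np.median(sample["net"]))
        floor = NET_FLOOR_FRACTION * max(med_net, 1e-12)
        net = np.maximum(sample["net"].to_numpy(), floor)
        sample = sample.assign(net=net)
        gene_sum = sample.groupby("gene")["net"].sum()
        if len(gene_sum) < 2:
            raise PreprocessError(f"sample ({cond}, {rep}) has fewer than 2 genes")
        scale = float(np.median(gene_sum))
        a_parts.append(
            pd.DataFrame(
                {
                    "gene": gene_sum.index,
                    "condition": cond,
                    "replica": rep,
                    "a": gene_sum.to_numpy() / scale,
                }
            )
        )
        spot_parts.append(
            pd.DataFrame(
                {
                    "probe_id": sample["probe_id"].to_numpy(),
                    "gene": sample["gene"].to_numpy(),
                    "condition": cond,
                    "replica": rep,
                    "value": sample["net"].to_numpy() / scale,
                }
            )
        )

    a = pd.concat(a_parts, ignore_index=True)
    spots = pd.concat(spot_parts, ignore_index=True)
    return ExpressionSet(a=a, spots=spots, upsilon=upsilon, conditions=conditions, n_replicas=n)


def write_expression_set(es: ExpressionSet, path: str | Path) -> None:
    """Write the expression set as TSV: gene, condition, replica, a, spot_values."""
    spot_strings = (
        es.spots.sort_values(["gene", "condition", "replica", "probe_id"])
        .groupby(["gene", "condition", "replica"])["value"]
        .apply(lambda v: ";".join(f"{x:.6g}" for x in v))
        .rename("spot_values")
    )
    out = es.a.set_index(["gene", "condition", "replica"]).join(spot_strings).reset_index()
    out.sort_values(["gene", "condition", "replica"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def load_geo_series_matrix(
    path: str | Path, mapping_path: str | Path
) -> pd.DataFrame:
    """Build a probe table from a GEO series-matrix text file.

    ``mapping_path`` is a TSV with columns gsm_id, condition, replica that
    assigns each sample column to a (condition, replica) slot. Series
    matrices carry processed intensities rather than raw foreground and
    background, so the returned table has ``bg = 0`` and ``fg`` set to the
    matrix value; rows with missing values are dropped.
    """
    mapping = pd.read_csv(mapping_path, sep="\t", dtype=str)
    for col in ("gsm_id", "condition", "replica"):
        if col not in mapping.columns:
            raise PreprocessError(f"mapping file missing column {col!r}")

    header: list[str] | None = None
    rows = []
    with open(path) as fh:
        in_table = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if not in_table or not line:
                continue
            fields = [f.strip('"') for f in line.split("\t")]
            if header is None:
                header = fields
            else:
                rows.append(fields)
    if header is None:
        raise PreprocessError("no series-matrix table found")

    matrix = pd.DataFrame(rows, columns=header)
    id_col = header[0]
    records = []
    by_gsm = mapping.set_index("gsm_id")
    for gsm in header[1:]:
        if gsm not in by_gsm.index:
            continue
        cond = by_gsm.loc[gsm, "condition"]
        rep = int(by_gsm.loc[gsm, "replica"])
        vals = pd.to_numeric(matrix[gsm], errors="coerce")
        ok = vals.notna()
        records.append(
            pd.DataFrame(
                {
                    "probe_id": matrix.loc[ok, id_col],
                    "gene": matrix.loc[ok, id_col],
                    "condition": cond,
                    "replica": rep,
                    "fg": vals[ok],
                    "bg": 0.0,
                }
            )
        )
    if not records:
        raise PreprocessError("no samples in the matrix matched the mapping file")
    return pd.concat(records, ignore_index=True)[PROBE_COLUMNS]
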