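"""Synthetic probe-level microarray data with known ground truth.

The generator emulates a replicated single-color microarray design: a
small number of tissue conditions, a few biological replicas per
condition, and one to three redundant probing spots per gene. Expression
is lognormal per gene with a configurable per-gene coefficient of
variation; fold changes between conditions and block-wise pairwise
correlation structure can be planted, and a controlled fraction of spots
can be made to fail the foreground-vs-background reliability filter.

Every random draw flows from a single integer seed, so the same
configuration always produces byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ConfigError", "SyntheticConfig", "GroundTruth", "generate_dataset", "write_fixture", "read_fixture_truth"]

#: column order of the probe-level table, shared with the preprocess reader
PROBE_COLUMNS = ["probe_id", "gene", "condition", "replica", "fg", "bg"]

# multiplicative spot-level noise on top of the gene's replicate value;
# redundant spots must be near-replicates because downstream analysis sums them
SPOT_CV = 0.05

_DEFAULT_LABELS = ["NOR", "PTA", "PTB", "CWM"]


class ConfigError(ValueError):
    """Raised when a synthetic configuration field is invalid."""


def _condition_labels(n: int) -> list[str]:
    if n <= len(_DEFAULT_LABELS):
        return _DEFAULT_LABELS[:n]
    return _DEFAULT_LABELS + [f"C{j}" for j in range(5, n + 1)]


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    Parameters
    ----------
    n_genes:
        Number of distinct genes, named ``G0001`` .. ``G{n}``.
    n_conditions, n_replicas:
        Study design; defaults mirror a 4-region x 4-replica biopsy layout.
    spots_per_gene:
        Either a single spot count in {1, 2, 3} applied to every gene or a
        mapping gene name -> count for genes that deviate from 1.
    baseline_mean:
        Median gene-level net fluorescence of the array, in fluorescence
        units. Per-gene baselines are spread lognormally around it so the
        median-gene normalization has a realistic dynamic range.
    cv_range:
        Interval from which each gene's biological coefficient of
        variation is drawn uniformly; must sit inside (0, 2].
    cv_overrides:
        Mapping gene -> fixed CV for genes whose variability should not be
        drawn from ``cv_range`` (e.g. a planted tightly-controlled hub).
    planted_folds:
        Mapping ``(gene, condition) -> signed fold``; |fold| >= 1 and a
        negative value means down-regulation relative to the first
        (reference) condition.
    correlation_blocks:
        List of ``(genes, loading)`` or ``(genes, loading, condition)``.
        Genes of a block share a per-replica latent factor on the log
        scale with the given loading in [-1, 1]; with a third element the
        factor acts only in that condition (a condition-specific hub). A
        negative loading alternates sign across the block's genes, which
        plants antagonistic (negative) pairwise correlations between genes
        of opposite sign; the true pair sign is the sign of the product of
        the two loadings.
    background_level:
        Mean background fluorescence per spot; each spot's background gets
        10% Gaussian jitter, truncated at zero.
    failing_spot_fraction:
        Fraction of probes forced to fail the fg >= 2*bg reliability
        criterion in exactly one randomly chosen sample.
    seed:
        Fixes all randomness.
    """

    n_genes: int
    n_conditions: int = 4
    n_replicas: int = 4
    spots_per_gene: int | Mapping[str, int] = 1
    baseline_mean: float = 1000.0
    cv_range: tuple[float, float] = (0.05, 0.5)
    cv_overrides: Mapping[str, float] = field(default_factory=dict)
    planted_folds: Mapping[tuple[str, str], float] = field(default_factory=dict)
    correlation_blocks: Sequence[tuple[Sequence[str], float]] = field(default_factory=list)
    background_level: float = 30.0
    failing_spot_fraction: float = 0.0
    baseline_log2_spread: float = 1.5
    seed: int = 0

    @property
    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def condition_labels(self) -> list[str]:
        return _condition_labels(self.n_conditions)

    def spot_count(self, gene: str) -> int:
        if isinstance(self.spots_per_gene, Mapping):
            return int(self.spots_per_gene.get(gene, 1))
        return int(self.spots_per_gene)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_conditions < 1:
            raise ConfigError("n_conditions must be >= 1")
        if self.n_replicas < 2:
            raise ConfigError("n_replicas must be >= 2")
        lo, hi = self.cv_range
        if not (0.0 < lo <= hi <= 2.0):
            raise ConfigError("cv_range must satisfy 0 < lo <= hi <= 2")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be positive")
        if self.background_level <= 0:
            raise ConfigError("background_level must be positive")
        if not (0.0 <= self.failing_spot_fraction < 1.0):
            raise ConfigError("failing_spot_fraction must be in [0, 1)")
        genes = set(self.gene_names)
        labels = set(self.condition_labels)
        for gene in genes:
            v = self.spot_count(gene)
            if v not in (1, 2, 3):
                raise ConfigError(f"spots_per_gene for {gene} must be in {{1,2,3}}")
        for gene, cv in self.cv_overrides.items():
            if gene not in genes:
                raise ConfigError(f"cv_overrides refers to unknown gene {gene!r}")
            if not (0.0 < cv <= 2.0):
                raise ConfigError(f"cv_overrides[{gene}] must lie in (0, 2]")
        for (gene, cond), fold in self.planted_folds.items():
            if gene not in genes:
                raise ConfigError(f"planted_folds refers to unknown gene {gene!r}")
            if cond not in labels:
                raise ConfigError(f"planted_folds refers to unknown condition {cond!r}")
            if abs(fold) < 1.0:
                raise ConfigError(f"planted_folds[{gene},{cond}]: |fold| must be >= 1")
        for block in self.correlation_blocks:
            block_genes, loading = block[0], block[1]
            if not -1.0 <= loading <= 1.0:
                raise ConfigError("correlation_blocks loading must lie in [-1, 1]")
            unknown = set(block_genes) - genes
            if unknown:
                raise ConfigError(f"correlation_blocks refers to unknown genes {sorted(unknown)}")
            if len(block) > 2 and block[2] not in labels:
                raise ConfigError(f"correlation_blocks refers to unknown condition {block[2]!r}")


@dataclass
class GroundTruth:
    """Planted parameters of a generated dataset.

    ``true_fold`` maps (gene, condition) to the signed fold relative to the
    reference condition (1.0 where nothing was planted), ``true_cv`` maps
    gene to its biological coefficient of variation, ``true_pair_sign``
    maps within-block gene pairs to the sign of their planted correlation,
    and ``failing_probes`` lists the probe ids forced below the
    reliability threshold.
    """

    true_fold: dict[tuple[str, str], float]
    true_cv: dict[str, float]
    true_pair_sign: dict[tuple[str, str, str], int]
    failing_probes: list[str]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "condition": c, "true_fold": f, "true_cv": self.true_cv[g]}
            for (g, c), f in sorted(self.true_fold.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "condition", "true_fold", "true_cv"])


def _fold_factor(fold: float) -> float:
    # signed fold convention: -2 means half the reference mean
    return fold if fold >= 1 else -1.0 / fold


def _gene_loadings(config: SyntheticConfig) -> dict[str, tuple[int, float, str | None]]:
    """Map gene -> (block index, signed loading, condition restriction)."""
    out: dict[str, tuple[int, float, str | None]] = {}
    for b, block in enumerate(config.correlation_blocks):
        block_genes, loading = block[0], block[1]
        restrict = block[2] if len(block) > 2 else None
        for j, gene in enumerate(block_genes):
            lam = abs(loading)
            if loading < 0 and j % 2 == 1:
                lam = -lam
            out[gene] = (b, lam, restrict)
    return out


def generate_dataset(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a probe-level table and its ground truth.

    Returns one record per (gene, spot, condition, replica) with columns
    ``probe_id, gene, condition, replica, fg, bg``. Expression is lognormal
    per gene with log-sd chosen so the coefficient of variation of the net
    fluorescence matches the gene's drawn CV; genes in a correlation block
    share a per-replica latent factor so their log expressions co-vary with
    the configured sign.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = config.gene_names
    conditions = config.condition_labels
    reference = conditions[0]
    n = config.n_replicas

    # per-gene baseline and CV
    base_log2 = rng.normal(0.0, config.baseline_log2_spread, size=config.n_genes)
    baselines = config.baseline_mean * np.exp2(base_log2)
    lo, hi = config.cv_range
    cvs = rng.uniform(lo, hi, size=config.n_genes)
    for i, g in enumerate(genes):
        if g in config.cv_overrides:
            cvs[i] = config.cv_overrides[g]

    loadings = _gene_loadings(config)
    n_blocks = len(config.correlation_blocks)
    # one latent factor per block per sample (condition x replica)
    latent = rng.standard_normal((n_blocks, config.n_conditions, n)) if n_blocks else None

    spot_sigma = math.sqrt(math.log1p(SPOT_CV**2))

    records: list[dict] = []
    true_fold: dict[tuple[str, str], float] = {}
    for gi, gene in enumerate(genes):
        cv = float(cvs[gi])
        sigma = math.sqrt(math.log1p(cv**2))
        upsilon = config.spot_count(gene)
        block = loadings.get(gene)
        eps = rng.standard_normal((config.n_conditions, n))
        spot_eps = rng.standard_normal((config.n_conditions, n, upsilon))
        for ci, cond in enumerate(conditions):
            fold = float(config.planted_folds.get((gene, cond), 1.0)) if cond != reference else 1.0
            true_fold[(gene, cond)] = fold
            mean_c = baselines[gi] * _fold_factor(fold)
            mu = math.log(mean_c) - 0.5 * sigma**2
            for k in range(n):
                if block is not None and (block[2] is None or block[2] == cond):
                    b, lam, _ = block
                    u = lam * latent[b, ci, k] + math.sqrt(max(0.0, 1.0 - lam**2)) * eps[ci, k]
                else:
                    u = eps[ci, k]
                net_gene = math.exp(mu + sigma * u)
                for s in range(upsilon):
                    # first spot carries the replicate value exactly; redundant
                    # spots are near-replicates with small multiplicative noise
                    if s == 0:
                        net = net_gene
                    else:
                        net = net_gene * math.exp(spot_sigma * spot_eps[ci, k, s] - 0.5 * spot_sigma**2)
                    records.append(
                        {
                            "probe_id": f"{gene}_s{s + 1}",
                            "gene": gene,
                            "condition": cond,
                            "replica": k + 1,
                            "net": net,
                        }
                    )

    table = pd.DataFrame.from_records(records)

    # background: constant level with 10% Gaussian jitter, truncated at 0
    bg = config.background_level * (1.0 + 0.1 * rng.standard_normal(len(table)))
    table["bg"] = np.maximum(bg, 0.0)
    table["fg"] = table["net"] + table["bg"]

    # guard: a non-failing probe must pass the fg >= 2*bg filter in every
    # sample, so the planted failing set is exactly the filtered set
    table["fg"] = np.maximum(table["fg"], 2.0001 * table["bg"])

    probe_ids = table["probe_id"].unique()
    n_fail = int(math.floor(config.failing_spot_fraction * len(probe_ids)))
    failing = sorted(rng.choice(probe_ids, size=n_fail, replace=False).tolist())
    for pid in failing:
        idx = table.index[table["probe_id"] == pid]
        hit = idx[rng.integers(0, len(idx))]
        table.loc[hit, "fg"] = 1.5 * table.loc[hit, "bg"]

    table = table[PROBE_COLUMNS].reset_index(drop=True)

    true_pair_sign: dict[tuple[str, str, str], int] = {}
    for block in config.correlation_blocks:
        bg_list = list(block[0])
        restrict = block[2] if len(block) > 2 else None
        for i in range(len(bg_list)):
            for j in range(i + 1, len(bg_list)):
                gi_, gj_ = sorted((bg_list[i], bg_list[j]))
                li = loadings[gi_][1]
                lj = loadings[gj_][1]
                s = int(np.sign(li * lj)) if li * lj != 0 else 0
                for cond in conditions:
                    active = restrict is None or restrict == cond
                    true_pair_sign[(gi_, gj_, cond)] = s if active else 0

    truth = GroundTruth(
        true_fold=true_fold,
        true_cv={g: float(cvs[i]) for i, g in enumerate(genes)},
        true_pair_sign=true_pair_sign,
        failing_probes=failing,
    )
    return table, truth


def write_fixture(table: pd.DataFrame, truth: GroundTruth, path: str | Path) -> tuple[Path, Path]:
    """Write a probe table and its ground truth as TSV under ``path``.

    Returns the two file paths (``probes.tsv``, ``truth.tsv``). Floats are
    printed at fixed precision so regeneration from the same (config, seed)
    is byte-identical.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    probes = out / "probes.tsv"
    truth_path = out / "truth.tsv"
    table.to_csv(probes, sep="\t", index=False, float_format="%.6f")
    truth.as_frame().to_csv(truth_path, sep="\t", index=False, float_format="%.6f")
    return probes, truth_path


def read_fixture_truth(path: str | Path) -> pd.DataFrame:
    """Read back the ground-truth TSV written by :func:`write_fixture`."""
    return pd.read_csv(path, sep="\t")
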