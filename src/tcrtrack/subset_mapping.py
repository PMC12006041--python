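"""Subset-to-cluster mapping matrices and the normalized Shannon-Wiener
accuracy index.

For each sorted subset j and scRNA-seq cluster i the mapping is summarized
by three matrices: raw match counts n_ij, the stained proportion of the
cluster (intensity, n_ij / cluster size), and the distribution of the
subset's matched cells over clusters (size, p_ij = n_ij / sum_i n_ij).

The mapping accuracy of subset j is the normalized Shannon-Wiener index

    S_j = - sum_{i: p_ij>0} p_ij ln(p_ij) / ln(N_j)

where N_j is the number of clusters with at least one hit for subset j.
S is 1 for a uniform spread over occupied clusters and 0 when all cells sit
in one cluster, so lower values mean a more focused mapping.  Subsets with
fewer than ``min_cells`` matched cells (default 8, i.e. more than seven
cells required) are excluded as unreliable.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io import IntegrityError

logger = logging.getLogger("tcrtrack")


@dataclass(frozen=True)
class ShannonConfig:
    """Parameters of the accuracy index: minimum matched cells per subset
    (subsets below it are reported as undefined) and the probability
    tolerance when validating a distribution row."""

    min_cells: int = 8
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")


@dataclass
class MappingResult:
    """Subset x cluster mapping summary; see the module docstring for the
    definitions of the three matrices."""

    subsets: list[str]
    clusters: list[str]
    counts: pd.DataFrame     # n_ij, subsets as rows
    intensity: pd.DataFrame  # n_ij / cluster_size_i
    size: pd.DataFrame       # p_ij, row-stochastic over a subset's matches
    shannon: pd.DataFrame    # subset, S, n_cells, n_clusters, defined
    subsample: dict = field(default_factory=dict)

    def dot_plot_table(self) -> pd.DataFrame:
        """Long-format (subset, cluster, intensity, size) table for plotting."""
        rows = []
        for s in self.subsets:
            for c in self.clusters:
                rows.append((s, c, self.intensity.loc[s, c], self.size.loc[s, c]))
        return pd.DataFrame(rows, columns=["subset", "cluster", "intensity", "size"])


def subsample_matched_cells(cell_keys: pd.DataFrame, n: int = 20000,
                            seed: int = 0) -> pd.DataFrame:
    """Uniformly sample ``n`` annotated cells without replacement.

    ``cell_keys`` holds one row per annotated cell (any columns, typically
    donor_id + barcode).  If fewer than ``n`` cells are available all are
    used, with a logged note.  Seeded and reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(cell_keys) <= n:
        if len(cell_keys) < n:
            logger.info("only %d annotated cells available (< %d); using all",
                        len(cell_keys), n)
        return cell_keys.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cell_keys), size=n, replace=False)
    return cell_keys.iloc[np.sort(idx)].reset_index(drop=True)


def shannon_accuracy(p: np.ndarray, config: ShannonConfig = ShannonConfig(),
                     n_cells: int | None = None) -> float:
    """Normalized Shannon-Wiener index of one subset's cluster distribution.

    ``p`` is the subset's distribution over clusters (zeros allowed, must sum
    to 1).  Returns NaN (not defined) when the subset has fewer than
    ``config.min_cells`` matched cells; returns 0.0 when a single cluster is
    occupied.  The log base cancels in the ratio; natural log is used.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative proportion in distribution row")
    if abs(p.sum() - 1.0) > max(config.tol, 1e-6):
        raise ValueError(f"distribution sums to {p.sum()}, not 1")
    if n_cells is not None and n_cells < config.min_cells:
        return float("nan")
    nz = p[p > 0]
    n_occupied = len(nz)
    if n_occupied <= 1:
        return 0.0
    return float(-(nz * np.log(nz)).sum() / math.log(n_occupied))


def compute_mapping_matrices(match_table: pd.DataFrame, meta: pd.DataFrame,
                             subsets: list[str] | None = None,
                             clusters: list[str] | None = None,
                             subsample_n: int | None = 20000,
                             seed: int = 0,
                             config: ShannonConfig = ShannonConfig()) -> MappingResult:
    """Build the counts / intensity / size matrices and per-subset Shannon
    accuracy from a match table plus per-cell cluster labels.

    Cluster sizes and match counts are computed on the same universe: the
    (optionally subsampled) set of cells that carry a match.  Cells matched
    to several subsets contribute to each subset's row independently but are
    counted once in the cluster-size denominator.
    """
    mt = match_table.copy()
    annotated = (mt[["donor_id", "barcode"]].drop_duplicates()
                 .reset_index(drop=True))
    if subsample_n is not None and not annotated.empty:
        universe = subsample_matched_cells(annotated, n=subsample_n, seed=seed)
    else:
        universe = annotated
    universe = universe.merge(meta[["donor_id", "barcode", "cluster_id"]],
                              on=["donor_id", "barcode"], how="left")
    missing = universe["cluster_id"].isna()
    if missing.any():
        bc = universe.loc[missing, "barcode"].iloc[0]
        raise IntegrityError(f"matched cell {bc!r} has no cluster label")

    mt = mt.merge(universe, on=["donor_id", "barcode"], how="inner")
    if subsets is None:
        subsets = sorted(match_table["subset_label"].unique()) if len(match_table) else []
    if clusters is None:
        clusters = sorted(universe["cluster_id"].unique()) if len(universe) else []

    counts = pd.DataFrame(0, index=pd.Index(subsets, name="subset"),
                          columns=pd.Index(clusters, name="cluster"), dtype=np.int64)
    if len(mt):
        tab = (mt.groupby(["subset_label", "cluster_id"], observed=True)
               .size().unstack(fill_value=0))
        counts.loc[tab.index.intersection(subsets),
                   tab.columns.intersection(clusters)] = tab
    cluster_sizes = universe["cluster_id"].value_counts().reindex(clusters).fillna(0)

    with np.errstate(divide="ignore", invalid="ignore"):
        intensity = counts / cluster_sizes.to_numpy()[None, :]
        intensity = intensity.fillna(0.0)
        row_tot = counts.sum(axis=1)
        size = counts.div(row_tot.replace(0, np.nan), axis=0).fillna(0.0)

    records = []
    for s in subsets:
        n_cells = int(row_tot.loc[s])
        n_occ = int((counts.loc[s] > 0).sum())
        if n_cells == 0:
            val, defined = float("nan"), False
        else:
            val = shannon_accuracy(size.loc[s].to_numpy(), config, n_cells=n_cells)
            defined = not math.isnan(val)
        records.append((s, val, n_cells, n_occ, defined))
    shannon = pd.DataFrame(records,
                           columns=["subset", "S", "n_cells", "n_clusters", "defined"])

    return MappingResult(subsets=list(subsets), clusters=list(clusters),
                         counts=counts, intensity=intensity, size=size,
                         shannon=shannon,
                         subsample={"n_cells": len(universe), "seed": seed})


def _exact_ranksum_pvalue(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exhaustive two-sided permutation rank-sum test (midranks for ties).

    Enumerates every assignment of the pooled values into groups of sizes
    (n, m); the p-value is the fraction of assignments whose rank-sum
    deviates from its expectation at least as much as the observed one.
    """
    from itertools import combinations
    from scipy.stats import rankdata

    n, m = len(a), len(b)
    ranks = rankdata(np.concatenate([a, b]))
    w_obs = ranks[:n].sum()
    expected = n * (n + m + 1) / 2.0
    d_obs = abs(w_obs - expected)
    hits = total = 0
    for comb in combinations(range(n + m), n):
        total += 1
        if abs(ranks[list(comb)].sum() - expected) >= d_obs - 1e-12:
            hits += 1
    return float(w_obs), hits / total


def compare_accuracy(values_a, values_b, max_exact: int = 20000) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of two methods' accuracy values.

    NaN (undefined) entries are dropped.  For small samples (at most
    ``max_exact`` distinct group assignments) the p-value is computed by
    exhaustive permutation enumeration, which handles ties exactly; larger
    samples fall back to the asymptotic normal approximation.  Returns
    per-method medians, the rank-sum statistic and p-value, and a low-n flag
    when either side has fewer than 3 defined values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("all accuracy values undefined on one side")
    low_n = min(len(a), len(b)) < 3
    if low_n:
        logger.warning("rank-sum comparison with n=%d vs m=%d values", len(a), len(b))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        stat, p = len(a) * len(b) / 2.0, 1.0
    elif math.comb(len(a) + len(b), len(a)) <= max_exact:
        stat, p = _exact_ranksum_pvalue(a, b)
    else:
        stat, p = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return {"median_a": float(np.median(a)), "median_b": float(np.median(b)),
            "n_a": len(a), "n_b": len(b),
            "statistic": float(stat), "pvalue": float(p), "low_n": low_n}
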