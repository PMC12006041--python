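"""Cluster-level repertoire statistics.

Three statistics are computed on the clonotype content of scRNA-seq clusters
and sorted-subset repertoires:

* clonality of a cluster — unique TCR CDR3 count divided by cell count
  (lower means more clonal expansion);
* pairwise clonal overlap between clusters of the same donor — the D metric,
  D = |A n B| / (|A| * |B|), multiplied by 1e6 and log2(1 + x) transformed
  for display;
* the shared-clonotype partition of two sorted repertoires (top-2,000
  slices): overlapping clonotypes whose two frequencies have a standard
  deviation below 0.001 are kept as genuinely shared, the rest (highly
  abundant in one subset, marginal in the other) are rejected as
  sort-contamination candidates.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BulkRepertoire

logger = logging.getLogger("tcrtrack")

DEFAULT_OVERLAP_SCALE = 1e6


@dataclass
class ClusterRepertoire:
    """Nucleotide CDR3 set of one donor's cells in one cluster."""

    donor_id: str
    cluster_id: str
    clonotypes: frozenset
    cell_count: int

    def __post_init__(self) -> None:
        self.clonotypes = frozenset(self.clonotypes)
        if len(self.clonotypes) > self.cell_count:
            raise ValueError("clonotype set larger than cell count")


def build_cluster_repertoires(cells: pd.DataFrame, meta: pd.DataFrame,
                              chain: str = "TRB") -> list[ClusterRepertoire]:
    """Collect per-donor, per-cluster CDR3nt sets from resolved cells.

    ``cells`` is the resolved-cell table (one row per donor/barcode/chain);
    ``meta`` supplies cluster labels.  Cells without a resolved clonotype on
    ``chain`` do not contribute clonotypes but are absent from the cell count
    too (the count is of TCR-resolved cells, matching the CDR3/cell ratio).
    """
    sub = cells[cells["chain"] == chain].merge(
        meta[["donor_id", "barcode", "cluster_id"]],
        on=["donor_id", "barcode"], how="inner")
    out = []
    for (donor, cluster), grp in sub.groupby(["donor_id", "cluster_id"], sort=True):
        out.append(ClusterRepertoire(donor_id=donor, cluster_id=cluster,
                                     clonotypes=frozenset(grp["cdr3nt"]),
                                     cell_count=len(grp)))
    return out


def cluster_clonality(rep: ClusterRepertoire) -> float:
    """Unique CDR3 / cell-count ratio in (0, 1]; NaN for an empty cluster."""
    if rep.cell_count == 0:
        return float("nan")
    return len(rep.clonotypes) / rep.cell_count


def clonality_table(cluster_reps: list[ClusterRepertoire]) -> pd.DataFrame:
    """Long table (donor_id, cluster_id, n_cells, n_clonotypes, clonality)."""
    rows = [(r.donor_id, r.cluster_id, r.cell_count, len(r.clonotypes),
             cluster_clonality(r)) for r in cluster_reps]
    return pd.DataFrame(rows, columns=["donor_id", "cluster_id", "n_cells",
                                       "n_clonotypes", "clonality"])


def pairwise_overlap_D(rep_a: ClusterRepertoire, rep_b: ClusterRepertoire,
                       scale: float = DEFAULT_OVERLAP_SCALE) -> tuple[float, float]:
    """D metric between two same-donor cluster repertoires.

    Returns (raw D, log2(1 + scale*D)).  D = |A n B| / (|A| * |B|), i.e. the
    shared-clonotype count normalized by both repertoire sizes.
    """
    if rep_a.donor_id != rep_b.donor_id:
        raise ValueError("overlap is defined within a donor only")
    if not rep_a.clonotypes or not rep_b.clonotypes:
        raise ValueError("overlap undefined for an empty clonotype set")
    shared = len(rep_a.clonotypes & rep_b.clonotypes)
    d = shared / (len(rep_a.clonotypes) * len(rep_b.clonotypes))
    return d, math.log2(1.0 + scale * d)


def donor_overlap_matrix(cluster_reps: list[ClusterRepertoire],
                         scale: float = DEFAULT_OVERLAP_SCALE,
                         include_diagonal: bool = True) -> pd.DataFrame:
    """Symmetric cluster x cluster matrix of transformed D for one donor.

    Pairs involving an empty repertoire are NaN.  The diagonal (self-overlap,
    a clonality proxy) is computed unless ``include_diagonal`` is False.
    """
    donors = {r.donor_id for r in cluster_reps}
    if len(donors) != 1:
        raise ValueError(f"expected repertoires from one donor, got {sorted(donors)}")
    clusters = sorted(r.cluster_id for r in cluster_reps)
    by_cluster = {r.cluster_id: r for r in cluster_reps}
    mat = pd.DataFrame(np.nan, index=pd.Index(clusters, name="cluster"),
                       columns=pd.Index(clusters, name="cluster"))
    for ca, cb in itertools.combinations_with_replacement(clusters, 2):
        if ca == cb and not include_diagonal:
            continue
        ra, rb = by_cluster[ca], by_cluster[cb]
        if not ra.clonotypes or not rb.clonotypes:
            continue
        _, t = pairwise_overlap_D(ra, rb, scale=scale)
        mat.loc[ca, cb] = mat.loc[cb, ca] = t
    return mat


@dataclass
class OverlapMatrix:
    """Aggregate of per-donor transformed-D matrices plus per-pair donor counts."""

    aggregate: pd.DataFrame
    donor_counts: pd.DataFrame
    per_donor: dict[str, pd.DataFrame]
    parameters: dict = field(default_factory=dict)


def aggregate_overlap(per_donor: dict[str, pd.DataFrame],
                      aggregator: str = "mean",
                      scale: float = DEFAULT_OVERLAP_SCALE) -> OverlapMatrix:
    """Combine per-donor matrices cellwise over donors where the pair is
    defined (``mean`` by default; ``median`` and ``sum`` available).  Cells
    defined in no donor stay NaN; donor counts are reported alongside."""
    if not per_donor:
        raise ValueError("no donor matrices to aggregate")
    if aggregator not in ("mean", "median", "sum"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    clusters = sorted(set().union(*(m.index for m in per_donor.values())))
    aligned = [m.reindex(index=clusters, columns=clusters) for m in per_donor.values()]
    stack = np.stack([m.to_numpy(dtype=float) for m in aligned])
    counts = (~np.isnan(stack)).sum(axis=0)
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        agg = getattr(np, "nan" + aggregator)(stack, axis=0)
    agg = np.where(counts > 0, agg, np.nan)  # nansum maps all-NaN to 0 otherwise
    idx = pd.Index(clusters, name="cluster")
    return OverlapMatrix(
        aggregate=pd.DataFrame(agg, index=idx, columns=idx),
        donor_counts=pd.DataFrame(counts, index=idx, columns=idx),
        per_donor=dict(per_donor),
        parameters={"scale": scale, "transform": "log2(1+x)",
                    "aggregator": aggregator})


@dataclass
class SharedPartition:
    """Partition of two top-N repertoire slices by shared-clonotype status.

    ``records`` has one row per clonotype in either slice with its frequency
    in each subset, the SD of the two frequencies, and the assigned bin
    (A_only / B_only / shared_kept / shared_rejected).
    """

    a_only: frozenset
    b_only: frozenset
    shared_kept: frozenset
    shared_rejected: frozenset
    records: pd.DataFrame
    parameters: dict = field(default_factory=dict)


def _two_value_sd(fa: np.ndarray, fb: np.ndarray, convention: str) -> np.ndarray:
    if convention == "sample":       # n-1 denominator: |delta| / sqrt(2)
        return np.abs(fa - fb) / math.sqrt(2.0)
    if convention == "population":   # n denominator: |delta| / 2
        return np.abs(fa - fb) / 2.0
    raise ValueError(f"unknown sd convention {convention!r}")


def shared_clonotype_partition(rep_a: BulkRepertoire, rep_b: BulkRepertoire,
                               top_n: int = 2000, sd_threshold: float = 0.001,
                               sd_convention: str = "sample") -> SharedPartition:
    """Partition two sorted-subset repertoires into shared vs exclusive clones.

    Both repertoires are sliced to their top-``top_n`` clonotypes (nucleotide
    CDR3 identity).  For each overlapping clonotype the SD of its two
    whole-repertoire frequencies is computed (sample convention for two
    observations: |f_A - f_B| / sqrt(2)); clonotypes with SD below
    ``sd_threshold`` are genuinely shared (``shared_kept``), the rest —
    abundant in one subset but marginal in the other — are rejected.
    """
    if rep_a.donor_id != rep_b.donor_id:
        raise ValueError("partition is defined within a donor only")
    from .clonotype_core import select_top_clonotypes

    slice_a = select_top_clonotypes(rep_a, n=top_n).clonotypes
    slice_b = select_top_clonotypes(rep_b, n=top_n).clonotypes
    fa = slice_a.groupby("cdr3nt")["frequency"].sum()
    fb = slice_b.groupby("cdr3nt")["frequency"].sum()
    both = fa.index.intersection(fb.index)
    a_only = frozenset(fa.index.difference(fb.index))
    b_only = frozenset(fb.index.difference(fa.index))

    sd = pd.Series(_two_value_sd(fa[both].to_numpy(), fb[both].to_numpy(),
                                 sd_convention), index=both)
    kept = frozenset(sd.index[sd < sd_threshold])
    rejected = frozenset(sd.index[sd >= sd_threshold])

    rows = []
    for nt in fa.index.union(fb.index):
        in_a, in_b = nt in fa.index, nt in fb.index
        status = ("shared_kept" if nt in kept else
                  "shared_rejected" if nt in rejected else
                  "A_only" if in_a else "B_only")
        rows.append((nt, fa.get(nt, np.nan), fb.get(nt, np.nan),
                     sd.get(nt, np.nan), status))
    records = pd.DataFrame(rows, columns=["cdr3nt", "freq_a", "freq_b", "sd", "status"])
    return SharedPartition(
        a_only=a_only, b_only=b_only, shared_kept=kept, shared_rejected=rejected,
        records=records.sort_values("cdr3nt", kind="mergesort").reset_index(drop=True),
        parameters={"top_n": top_n, "sd_threshold": sd_threshold,
                    "sd_convention": sd_convention,
                    "subset_a": rep_a.subset_label, "subset_b": rep_b.subset_label})
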