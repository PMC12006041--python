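"""Contig QC, per-cell chain resolution, top-N selection, and donor-scoped
exact clonotype matching — the clonal-barcode machinery.

A cell is assigned to a sorted subset when its resolved CDR3 nucleotide
sequence (optionally with V/J genes) is identical to a clonotype in that
subset's selected top-N bulk repertoire *from the same donor*.  Matching is
an exact hash join; no fuzzy neighborhood matching is offered.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import BulkRepertoire

logger = logging.getLogger("tcrtrack")

#: Columns of the resolved-cell table: at most one row per (donor, barcode, chain).
CELL_COLUMNS = ["donor_id", "barcode", "chain", "cdr3nt", "cdr3aa",
                "v_gene", "j_gene", "umi_count"]

#: Columns of the match table.
MATCH_COLUMNS = ["donor_id", "barcode", "subset_label", "cdr3nt",
                 "bulk_frequency", "bulk_rank"]


@dataclass(frozen=True)
class MatchKey:
    """Granularity and chain of the clonotype identity used for matching.

    The default granularity is the CDR3 nucleotide sequence alone: V/J call
    conventions differ between bulk and single-cell pipelines, so V/J-augmented
    matching (``cdr3nt_vj``) is opt-in.
    """

    granularity: str = "cdr3nt"  # "cdr3nt" | "cdr3nt_vj"
    chain: str = "TRB"

    def __post_init__(self) -> None:
        if self.granularity not in ("cdr3nt", "cdr3nt_vj"):
            raise ValueError(f"unknown granularity {self.granularity!r}")
        if self.chain not in ("TRA", "TRB"):
            raise ValueError(f"unknown chain {self.chain!r}")

    @property
    def join_columns(self) -> list[str]:
        cols = ["donor_id", "cdr3nt"]
        if self.granularity == "cdr3nt_vj":
            cols += ["v_gene", "j_gene"]
        return cols


def filter_contigs(contigs: pd.DataFrame) -> pd.DataFrame:
    """Keep only productive, V/J-spanning TRA/TRB contigs with an in-frame
    CDR3 and no stop codon in the amino-acid sequence."""
    if contigs.empty:
        return contigs
    keep = (
        contigs["chain"].isin(["TRA", "TRB"])
        & contigs["is_productive"]
        & contigs["is_full_length"]
        & contigs["has_cdr3"]
        & ~contigs["cdr3aa"].astype(str).str.contains(r"\*", regex=True)
    )
    return contigs[keep].reset_index(drop=True)


def resolve_cell_chains(contigs: pd.DataFrame) -> pd.DataFrame:
    """Resolve one clonotype per chain per cell.

    For cells with several surviving contigs of the same chain, the contig
    with the highest UMI count is kept; ties break to the lexicographically
    smallest cdr3nt so the result is deterministic.  Input is expected to be
    QC-filtered.  Returns a table with :data:`CELL_COLUMNS`.
    """
    if contigs.empty:
        return pd.DataFrame(columns=CELL_COLUMNS)
    ordered = contigs.sort_values(
        ["donor_id", "barcode", "chain", "umi_count", "cdr3nt"],
        ascending=[True, True, True, False, True], kind="mergesort")
    resolved = ordered.groupby(["donor_id", "barcode", "chain"], as_index=False,
                               sort=False).head(1)
    return resolved[CELL_COLUMNS].reset_index(drop=True)


def select_top_clonotypes(rep: BulkRepertoire, n: int = 500,
                          rank_window: tuple[int, int] | None = None) -> BulkRepertoire:
    """Slice a repertoire to its top-``n`` clonotypes, or to a 1-based
    inclusive rank window such as (101, 500).

    Ranking is by count descending with ties broken by lexicographic cdr3nt.
    Frequencies keep their whole-repertoire values: they are later used as
    per-cell alpha weights, so they must not be renormalized to the slice.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    df = rep.clonotypes
    if df.empty:
        logger.warning("repertoire %s/%s is empty", rep.donor_id, rep.subset_label)
        out = df.copy()
        out["rank"] = pd.Series(dtype=np.int64)
        return BulkRepertoire(rep.donor_id, rep.subset_label, rep.chain, out)
    out = df.sort_values(["count", "cdr3nt"], ascending=[False, True],
                         kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    lo, hi = rank_window if rank_window is not None else (1, n)
    out = out[(out["rank"] >= lo) & (out["rank"] <= hi)].reset_index(drop=True)
    return BulkRepertoire(rep.donor_id, rep.subset_label, rep.chain, out)


def match_cells(subset_reps: Iterable[BulkRepertoire], cells: pd.DataFrame,
                key: MatchKey = MatchKey()) -> pd.DataFrame:
    """Donor-scoped exact matching of resolved cells to sorted-subset repertoires.

    A cell matches subset S iff its resolved clonotype on ``key.chain`` is
    identical (under ``key.granularity``) to a clonotype in S's selected list
    from the same donor.  All (cell, subset) matches are emitted, so a cell
    may appear in several subsets' rows.  Returns :data:`MATCH_COLUMNS`.
    """
    reps = list(subset_reps)
    chain_cells = cells[cells["chain"] == key.chain] if len(cells) else cells
    rep_donors = {r.donor_id for r in reps}
    if len(chain_cells):
        for donor in sorted(set(chain_cells["donor_id"]) - rep_donors):
            logger.warning("donor %s has cells but no bulk repertoire; zero matches",
                           donor)
    pieces = []
    for rep in reps:
        if rep.chain != key.chain:
            raise ValueError(
                f"repertoire {rep.donor_id}/{rep.subset_label} is chain "
                f"{rep.chain}, match key wants {key.chain}")
        if not len(rep) or chain_cells.empty:
            continue
        lut = rep.clonotypes.copy()
        lut["donor_id"] = rep.donor_id
        if "rank" not in lut.columns:
            lut["rank"] = np.arange(1, len(lut) + 1)
        lut = lut.rename(columns={"frequency": "bulk_frequency", "rank": "bulk_rank"})
        hit = chain_cells.merge(
            lut[key.join_columns + ["bulk_frequency", "bulk_rank"]],
            on=key.join_columns, how="inner")
        if hit.empty:
            continue
        hit["subset_label"] = rep.subset_label
        pieces.append(hit[MATCH_COLUMNS])
    if not pieces:
        return pd.DataFrame(columns=MATCH_COLUMNS)
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["donor_id", "barcode", "subset_label"],
                           kind="mergesort").reset_index(drop=True)


def best_subset_assignment(match_table: pd.DataFrame) -> pd.DataFrame:
    """Unique per-cell assignment: among a cell's matched subsets keep the one
    whose bulk clonal frequency is highest (ties to the alphabetically first
    subset).  Convenience for users needing one label per cell."""
    if match_table.empty:
        return match_table.copy()
    ordered = match_table.sort_values(
        ["donor_id", "barcode", "bulk_frequency", "subset_label"],
        ascending=[True, True, False, True], kind="mergesort")
    return (ordered.groupby(["donor_id", "barcode"], as_index=False, sort=False)
            .head(1).reset_index(drop=True))
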