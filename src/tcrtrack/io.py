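"""Readers and writers for every external table the pipeline touches.

Normalizes the common on-disk dialects (VDJtools / AIRR / MiXCR clonotype
tables, the 10x ``filtered_contig_annotations.csv`` contig dialect, dense or
MatrixMarket ADT matrices) into a small internal data model built on pandas
DataFrames with fixed schemas.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger("tcrtrack")

# Floating point columns in all TSV outputs are serialized with 6 significant
# digits; this is the single knob.
FLOAT_FORMAT = "%.6g"

#: The 16 cluster labels used in the reference Th atlas; purely a convenience
#: vocabulary — cluster labels are free strings everywhere in the code.
REFERENCE_TH_CLUSTERS = [
    "Naive", "Naive RTE", "Tcm", "Th1", "Th1-17", "Th17", "Th22", "Th2",
    "Th2a", "Tfh", "Treg", "Treg memory", "Temra cytotoxic", "Stress response",
    "Cycling", "IFN response",
]

#: The eight sorted helper subsets tracked by default.
TH_SUBSETS = ["Th1", "Th1-17", "Th17", "Th22", "Th2", "Th2a", "Tfh", "Treg"]

CLONOTYPE_COLUMNS = ["cdr3nt", "cdr3aa", "v_gene", "j_gene", "count", "frequency"]

CONTIG_COLUMNS = [
    "barcode", "donor_id", "chain", "cdr3nt", "cdr3aa", "v_gene", "j_gene",
    "umi_count", "is_productive", "is_full_length", "has_cdr3",
]

_ACGT = frozenset("ACGT")


class FormatError(ValueError):
    """A table does not conform to the expected dialect."""


class IntegrityError(ValueError):
    """A table is well-formed but internally inconsistent."""


# ---------------------------------------------------------------------------
# bulk repertoires
# ---------------------------------------------------------------------------

# Column aliases, all matched case-insensitively.  First group is VDJtools
# (the default dialect), then AIRR rearrangement, then MiXCR exports.
_BULK_ALIASES: dict[str, tuple[str, ...]] = {
    "cdr3nt": ("cdr3nt", "junction", "nseqcdr3", "n_seq_cdr3", "cdr3_nt"),
    "cdr3aa": ("cdr3aa", "junction_aa", "aaseqcdr3", "aa_seq_cdr3", "cdr3_aa"),
    "v_gene": ("v", "v_call", "allvhitswithscore", "v_gene", "bestvhit"),
    "j_gene": ("j", "j_call", "alljhitswithscore", "j_gene", "bestjhit"),
    "count": ("count", "duplicate_count", "clonecount", "clone_count", "reads"),
    "frequency": ("freq", "frequency", "duplicate_frequency", "clonefraction",
                  "clone_fraction"),
}


@dataclass
class Clonotype:
    """One TCR rearrangement with its abundance in a bulk repertoire."""

    cdr3nt: str
    cdr3aa: str = ""
    v_gene: str = ""
    j_gene: str = ""
    count: int = 0
    frequency: float = 0.0


@dataclass
class BulkRepertoire:
    """A sorted-subset bulk TCR repertoire for one donor.

    ``clonotypes`` is a DataFrame with :data:`CLONOTYPE_COLUMNS`, sorted by
    count descending with ties broken by lexicographic cdr3nt.  An optional
    ``rank`` column (1-based rank in the full repertoire) is added by
    top-N selection.
    """

    donor_id: str
    subset_label: str
    chain: str  # "TRA" | "TRB"
    clonotypes: pd.DataFrame = field(default_factory=lambda: _empty_clonotypes())

    def __len__(self) -> int:
        return len(self.clonotypes)


def _empty_clonotypes() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        CLONOTYPE_COLUMNS, [str, str, str, str, np.int64, float])})


def _resolve_columns(columns: Sequence[str], aliases: Mapping[str, tuple[str, ...]],
                     column_map: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical field names to actual column names (case-insensitive)."""
    lower = {c.lower(): c for c in columns}
    out: dict[str, str] = {}
    for canon, cands in aliases.items():
        if column_map and canon in column_map:
            if column_map[canon] in columns:
                out[canon] = column_map[canon]
            continue
        for cand in cands:
            if cand in lower:
                out[canon] = lower[cand]
                break
    return out


def read_bulk_repertoire(
    source,
    donor_id: str,
    subset_label: str,
    chain: str = "TRB",
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> BulkRepertoire:
    """Read one clonotype table into a :class:`BulkRepertoire`.

    Rows with identical (cdr3nt, v_gene, j_gene) are merged by summing
    counts; frequencies are recomputed from counts when counts exist; rows
    whose CDR3 nucleotide sequence contains non-ACGT characters are dropped
    with a warning.  The result is sorted by count descending, ties broken
    by lexicographic cdr3nt.
    """
    df = pd.read_csv(source, sep=sep, dtype=str)
    cols = _resolve_columns(df.columns, _BULK_ALIASES, column_map)
    if "cdr3nt" not in cols:
        raise FormatError("no column resolvable to cdr3nt in clonotype table")
    if "count" not in cols and "frequency" not in cols:
        raise FormatError("clonotype table has neither a count nor a frequency column")

    out = pd.DataFrame({"cdr3nt": df[cols["cdr3nt"]].astype(str).str.upper()})
    for fld in ("cdr3aa", "v_gene", "j_gene"):
        out[fld] = df[cols[fld]].astype(str) if fld in cols else ""
    out["count"] = (pd.to_numeric(df[cols["count"]], errors="coerce")
                    if "count" in cols else np.nan)
    out["frequency"] = (pd.to_numeric(df[cols["frequency"]], errors="coerce")
                        if "frequency" in cols else np.nan)

    bad = ~out["cdr3nt"].map(lambda s: bool(s) and set(s) <= _ACGT)
    if bad.any():
        for nt in out.loc[bad, "cdr3nt"].head(10):
            logger.warning("dropping clonotype with non-ACGT cdr3nt %r (%s/%s)",
                           nt, donor_id, subset_label)
        out = out[~bad]

    has_counts = out["count"].notna().any()
    agg = {"cdr3aa": "first", "count": "sum", "frequency": "sum"}
    out = (out.groupby(["cdr3nt", "v_gene", "j_gene"], as_index=False, sort=False)
           .agg(agg))
    if has_counts:
        out["count"] = out["count"].fillna(0).round().astype(np.int64)
        total = out["count"].sum()
        out["frequency"] = out["count"] / total if total > 0 else 0.0
    else:
        out["count"] = 0
        out["frequency"] = out["frequency"].fillna(0.0)

    sort_key = "count" if has_counts else "frequency"
    out = (out.sort_values([sort_key, "cdr3nt"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True))
    out = out[CLONOTYPE_COLUMNS]
    return BulkRepertoire(donor_id=donor_id, subset_label=subset_label,
                          chain=chain, clonotypes=out)


def write_bulk_repertoire(rep: BulkRepertoire, path) -> None:
    """Write a repertoire as a VDJtools-style TSV (count, freq, cdr3nt, ...)."""
    df = rep.clonotypes.rename(columns={
        "count": "count", "frequency": "freq", "v_gene": "v", "j_gene": "j"})
    df = df[["count", "freq", "cdr3nt", "cdr3aa", "v", "j"]]
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# single-cell contigs
# ---------------------------------------------------------------------------

_CONTIG_ALIASES: dict[str, tuple[str, ...]] = {
    "barcode": ("barcode",),
    "chain": ("chain",),
    "cdr3nt": ("cdr3_nt", "cdr3nt"),
    "cdr3aa": ("cdr3", "cdr3aa"),
    "v_gene": ("v_gene",),
    "j_gene": ("j_gene",),
    "umi_count": ("umis", "umi_count"),
    "is_productive": ("productive",),
    "is_full_length": ("full_length",),
}

_TRUE_STRINGS = {"true", "t", "1", "yes"}


def _to_flag(series: pd.Series) -> pd.Series:
    """10x boolean dialect: 'True'/'true' are truthy; 'None', 'False', '' are not."""
    return series.astype(str).str.strip().str.lower().isin(_TRUE_STRINGS)


def read_sc_contigs(source, donor_id: str,
                    column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a 10x ``filtered_contig_annotations.csv`` table.

    Returns one row per contig with :data:`CONTIG_COLUMNS`.  Chain values
    other than TRA/TRB are mapped to ``"other"`` (they are retained here and
    removed later by QC filtering).
    """
    df = pd.read_csv(source, dtype=str)
    if df.empty:
        logger.warning("contig table %s is empty", source)
        return pd.DataFrame(columns=CONTIG_COLUMNS)
    return normalize_contigs(df, donor_id, column_map=column_map)


def normalize_contigs(df: pd.DataFrame, donor_id: str | None = None,
                      column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Normalize an in-memory 10x-dialect contig frame to :data:`CONTIG_COLUMNS`."""
    if df.empty:
        return pd.DataFrame(columns=CONTIG_COLUMNS)
    cols = _resolve_columns(df.columns, _CONTIG_ALIASES, column_map)
    missing = [c for c in ("barcode", "chain", "cdr3nt", "umi_count") if c not in cols]
    if missing:
        raise FormatError(f"contig table missing columns for {missing}")

    out = pd.DataFrame({
        "barcode": df[cols["barcode"]].astype(str),
        "donor_id": (df["donor_id"].astype(str) if "donor_id" in df.columns
                     else donor_id),
        "chain": df[cols["chain"]].astype(str),
        "cdr3nt": df[cols["cdr3nt"]].astype(str) if "cdr3nt" in cols else "",
        "cdr3aa": df[cols["cdr3aa"]].astype(str) if "cdr3aa" in cols else "",
        "v_gene": df[cols["v_gene"]].astype(str) if "v_gene" in cols else "",
        "j_gene": df[cols["j_gene"]].astype(str) if "j_gene" in cols else "",
        "umi_count": pd.to_numeric(df[cols["umi_count"]], errors="coerce")
        .fillna(0).astype(np.int64),
    })
    out.loc[~out["chain"].isin(["TRA", "TRB"]), "chain"] = "other"
    out["is_productive"] = (_to_flag(df[cols["is_productive"]])
                            if "is_productive" in cols else False)
    out["is_full_length"] = (_to_flag(df[cols["is_full_length"]])
                             if "is_full_length" in cols else False)
    out["has_cdr3"] = out["cdr3nt"].map(
        lambda s: bool(s) and s.lower() != "none" and set(s.upper()) <= _ACGT)
    if (out["umi_count"] < 0).any():
        raise FormatError("negative UMI count in contig table")
    return out[CONTIG_COLUMNS]


# ---------------------------------------------------------------------------
# cluster assignments
# ---------------------------------------------------------------------------

def read_cluster_assignments(source, sep: str = "\t") -> pd.DataFrame:
    """Read the per-cell metadata table (barcode, donor_id, cluster_id).

    Extra columns are preserved as passthrough attributes.  Duplicate
    (barcode, donor_id) pairs raise :class:`IntegrityError`.
    """
    df = pd.read_csv(source, sep=sep, dtype=str)
    required = {"barcode", "donor_id", "cluster_id"}
    if not required <= set(df.columns):
        raise FormatError(f"cluster table must contain columns {sorted(required)}")
    dup = df.duplicated(subset=["barcode", "donor_id"])
    if dup.any():
        pair = df.loc[dup, ["barcode", "donor_id"]].iloc[0]
        raise IntegrityError(
            f"duplicate cell {pair.barcode!r} within donor {pair.donor_id!r}")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# ADT matrices
# ---------------------------------------------------------------------------

@dataclass
class ADTMatrix:
    """Raw antibody-derived-tag counts: cells x markers, plus per-cell batch."""

    cells: list[str]
    markers: list[str]
    counts: np.ndarray  # (n_cells, n_markers), non-negative
    batch_id: np.ndarray | None = None  # (n_cells,) str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.cells), len(self.markers)):
            raise FormatError(
                f"ADT dimensions {self.counts.shape} inconsistent with "
                f"{len(self.cells)} cells x {len(self.markers)} markers")
        if (self.counts < 0).any():
            raise FormatError("negative ADT count")
        if len(set(self.markers)) != len(self.markers):
            raise FormatError("marker names not unique")
        if self.batch_id is None:
            self.batch_id = np.full(len(self.cells), "batch0", dtype=object)
        else:
            self.batch_id = np.asarray(self.batch_id, dtype=object)


def read_adt_matrix(source, features=None, barcodes=None,
                    batch: Sequence[str] | None = None) -> ADTMatrix:
    """Read ADT counts from a dense TSV or a MatrixMarket triplet.

    Dense dialect: first column is the cell barcode, remaining columns are
    markers.  Sparse dialect: ``source`` is an ``.mtx`` file in the 10x
    orientation (markers x cells) with ``features``/``barcodes`` name files,
    one name per line.
    """
    path = Path(source)
    if path.suffix == ".mtx":
        if features is None or barcodes is None:
            raise FormatError("MatrixMarket ADT input requires feature and barcode name files")
        mat = np.asarray(mmread(path).todense(), dtype=float)
        markers = Path(features).read_text().split()
        cells = Path(barcodes).read_text().split()
        if mat.shape != (len(markers), len(cells)):
            raise FormatError(
                f"MTX shape {mat.shape} does not match {len(markers)} features "
                f"x {len(cells)} barcodes")
        return ADTMatrix(cells=cells, markers=markers, counts=mat.T, batch_id=batch)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ADTMatrix(cells=[str(c) for c in df.index],
                     markers=[str(m) for m in df.columns],
                     counts=df.to_numpy(dtype=float), batch_id=batch)


def write_adt_matrix(adt: ADTMatrix, out_prefix) -> None:
    """Write an ADT matrix as MatrixMarket triplet + name files (10x layout)."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out_prefix) + ".mtx", coo_matrix(adt.counts.T))
    Path(str(out_prefix) + "_features.tsv").write_text("\n".join(adt.markers) + "\n")
    Path(str(out_prefix) + "_barcodes.tsv").write_text("\n".join(adt.cells) + "\n")


# ---------------------------------------------------------------------------
# mapping report
# ---------------------------------------------------------------------------

def write_mapping_report(result, match_table: pd.DataFrame, out_dir,
                         metadata: Mapping | None = None) -> list[Path]:
    """Serialize a MappingResult: subset x cluster matrices, per-subset
    Shannon table, the per-cell match table (with the bulk clonal frequency
    used as the per-cell alpha weight), and a run-metadata file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in ("counts", "intensity", "size"):
        p = out / f"{name}.tsv"
        getattr(result, name).to_csv(p, sep="\t", float_format=FLOAT_FORMAT)
        written.append(p)
    p = out / "shannon.tsv"
    result.shannon.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
    written.append(p)
    p = out / "per_cell.tsv"
    if match_table.empty:
        logger.warning("match table is empty; writing headers only")
    match_table.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
    written.append(p)
    p = out / "run_metadata.txt"
    meta = dict(metadata or {})
    meta.setdefault("subsample_n", result.subsample.get("n_cells"))
    meta.setdefault("seed", result.subsample.get("seed"))
    with open(p, "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}\t{v}\n")
    written.append(p)
    return written
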