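"""Ground-truth simulator for donor-structured clonal repertoires.

Generates everything the pipeline consumes — sorted-subset bulk repertoires,
10x-dialect single-cell contig tables, per-cell cluster labels and ADT
counts — from an explicit ground truth, so every stage is testable without
external data.

The generative model: each donor carries a registry of T-cell clones, each
belonging to one helper subset and carrying a unique in-frame CDR3
nucleotide sequence.  Clone sizes follow a discrete power law (default
exponent 2.5), the heavy-tailed clonality the tracking method relies on.
Each subset has a *program*: a probability vector over scRNA-seq clusters
(default: 0.85 concentrated on a subset-specific home cluster).  Bulk
sequencing of a sorted tube draws reads multinomially from the clones routed
to that tube; a configurable sorting-impurity matrix can route clones of one
subset into another subset's tube (with their full clone size, emulating
phenotypically mis-sorted bona fide clones).  Single cells sample a clone
size-weighted, draw their cluster from the clone's subset program, and yield
a TRB contig with the configured capture probability; a fraction of cells
receives a lower-UMI decoy contig to exercise chain resolution.  ADT counts
are negative-binomial with subset-dependent means given by the classic
surface-marker signatures (CD25/CD127 for Treg, CXCR5 for Tfh, CCR10 for
Th22, CCR6/CXCR3/CCR4/CRTh2 for the effector splits).

What this generator does not emulate: transcriptome counts (clusters are
labels, not expression profiles), doublets, ambient ADT background, or
clonal program switching over time (two time points can be emulated by
resampling cells from the same truth).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import (ADTMatrix, BulkRepertoire, CLONOTYPE_COLUMNS, TH_SUBSETS,
                 write_adt_matrix, write_bulk_repertoire)

logger = logging.getLogger("tcrtrack")

_SENSE_CODONS = [a + b + c for a, b, c in itertools.product("ACGT", repeat=3)
                 if a + b + c not in ("TAA", "TAG", "TGA")]
_TRBV = [f"TRBV{i}" for i in range(2, 31)]
_TRBJ = [f"TRBJ{i}-{j}" for i in (1, 2) for j in range(1, 7)]

#: Positive surface markers per subset; everything else in the panel is at
#: the negative baseline.  CD127 is expressed by all memory helper cells
#: except Tregs (the CD25 high / CD127 low sort gate).
ADT_SIGNATURES: dict[str, frozenset] = {
    "Treg": frozenset({"CD25"}),
    "Tfh": frozenset({"CD127", "CXCR5"}),
    "Th22": frozenset({"CD127", "CCR10", "CCR4"}),
    "Th1": frozenset({"CD127", "CXCR3"}),
    "Th1-17": frozenset({"CD127", "CCR6", "CXCR3"}),
    "Th17": frozenset({"CD127", "CCR6", "CCR4"}),
    "Th2": frozenset({"CD127", "CCR4"}),
    "Th2a": frozenset({"CD127", "CCR4", "CRTh2"}),
}

DEFAULT_ADT_PANEL = ["CD25", "CD127", "CXCR5", "CXCR3", "CCR6", "CCR4",
                     "CRTh2", "CCR10"]


@dataclass
class ADTConfig:
    """Negative-binomial ADT model: positive markers at ``pos_mean``,
    negative at ``neg_mean``, NB size parameter ``dispersion`` (None means
    Poisson).  ``batch_multipliers`` scales every marker mean per batch."""

    markers: list[str] = field(default_factory=lambda: list(DEFAULT_ADT_PANEL))
    pos_mean: float = 60.0
    neg_mean: float = 5.0
    dispersion: float | None = 10.0
    batch_multipliers: dict[str, float] = field(
        default_factory=lambda: {"batch0": 1.0})


def noisy_adt_config() -> ADTConfig:
    """A high-noise ADT regime: overlapping positive/negative intensities
    and strong overdispersion, under which surface gating degrades while
    clonotype matching is unaffected."""
    return ADTConfig(pos_mean=25.0, neg_mean=12.0, dispersion=1.5)


@dataclass
class SyntheticConfig:
    """Study-design parameters of the simulator; defaults emulate three
    donors with eight sorted subsets concentrated on distinct clusters."""

    n_donors: int = 3
    cluster_labels: list[str] = field(
        default_factory=lambda: [f"C{i:02d}" for i in range(16)])
    subsets: list[str] = field(default_factory=lambda: list(TH_SUBSETS))
    concentration: float = 0.85      # program mass on the home cluster
    programs: dict[str, np.ndarray] | None = None  # overrides concentration
    clones_per_subset: int = 600
    clone_size_exponent: float = 2.5  # discrete power law
    clone_size_max: int = 10000
    bulk_depth: int = 30000
    cells_per_donor: int = 2000
    capture_rate: float = 0.9
    decoy_fraction: float = 0.1
    #: (source_subset, tube) -> probability a source clone is also sorted
    #: into that tube; the diagonal is implicitly 1.
    impurity: dict[tuple[str, str], float] = field(default_factory=dict)
    cross_donor_collision_rate: float = 0.0
    adt: ADTConfig = field(default_factory=ADTConfig)
    seed: int = 0

    @property
    def donors(self) -> list[str]:
        return [f"D{i + 1:02d}" for i in range(self.n_donors)]

    def program_vector(self, subset: str) -> np.ndarray:
        if self.programs is not None and subset in self.programs:
            p = np.asarray(self.programs[subset], dtype=float)
        else:
            k = len(self.cluster_labels)
            home = self.subsets.index(subset) % k
            p = np.full(k, (1.0 - self.concentration) / (k - 1))
            p[home] = self.concentration
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"program for {subset} sums to {p.sum()}, not 1")
        return p

    def home_cluster(self, subset: str) -> str:
        return self.cluster_labels[int(np.argmax(self.program_vector(subset)))]


@dataclass
class SyntheticTruth:
    """Ground truth: the clone registry and per-subset programs (per-cell
    truth is attached by :func:`sample_single_cells`)."""

    config: SyntheticConfig
    clones: pd.DataFrame  # clone_id, donor_id, subset, cdr3nt, cdr3aa, v, j, size
    programs: dict[str, np.ndarray]


def _random_cdr3nt(rng: np.random.Generator) -> str:
    """Random in-frame CDR3: length 36–54 nt, a multiple of 3, built from
    sense codons so the translation contains no stop."""
    n_codons = int(rng.integers(12, 19))  # 36..54 nt
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def make_truth(config: SyntheticConfig,
               rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Generate the clone registry: unique in-frame CDR3nt per clone within
    each donor, power-law clone sizes, random V/J calls."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    first_donor_nts: list[str] = []
    for donor in config.donors:
        seen: set[str] = set()
        for subset in config.subsets:
            for k in range(config.clones_per_subset):
                if (donor != config.donors[0] and first_donor_nts
                        and rng.random() < config.cross_donor_collision_rate):
                    nt = first_donor_nts[int(rng.integers(0, len(first_donor_nts)))]
                    if nt in seen:
                        nt = None
                else:
                    nt = None
                attempts = 0
                while nt is None or nt in seen:
                    nt = _random_cdr3nt(rng)
                    attempts += 1
                    if attempts > 1000:
                        raise RuntimeError(
                            "cannot generate enough unique CDR3 sequences")
                seen.add(nt)
                size = min(int(rng.zipf(config.clone_size_exponent)),
                           config.clone_size_max)
                rows.append((f"{donor}:{subset}:{k:04d}", donor, subset, nt,
                             str(Seq(nt).translate()),
                             _TRBV[int(rng.integers(0, len(_TRBV)))],
                             _TRBJ[int(rng.integers(0, len(_TRBJ)))], size))
        if donor == config.donors[0]:
            first_donor_nts = [r[3] for r in rows]
    clones = pd.DataFrame(rows, columns=["clone_id", "donor_id", "subset",
                                         "cdr3nt", "cdr3aa", "v_gene", "j_gene",
                                         "size"])
    programs = {s: config.program_vector(s) for s in config.subsets}
    return SyntheticTruth(config=config, clones=clones, programs=programs)


def sample_bulk_repertoires(truth: SyntheticTruth,
                            rng: np.random.Generator | None = None
                            ) -> list[BulkRepertoire]:
    """Bulk-sequence each donor's sorted tubes.

    Each tube pools its own subset's clones plus, per the impurity matrix,
    a Bernoulli-routed share of other subsets' clones (full clone size —
    a mis-sorted clone is present, not diluted).  Reads are drawn
    multinomially at the configured depth.
    """
    config = truth.config
    if config.bulk_depth < 1:
        raise ValueError("bulk sequencing depth must be >= 1")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    reps = []
    for donor in config.donors:
        dclones = truth.clones[truth.clones["donor_id"] == donor]
        for tube in config.subsets:
            parts = [dclones[dclones["subset"] == tube]]
            for src in config.subsets:
                p = config.impurity.get((src, tube), 0.0)
                if p <= 0 or src == tube:
                    continue
                cand = dclones[dclones["subset"] == src]
                routed = rng.random(len(cand)) < p
                parts.append(cand[routed])
            pool = pd.concat(parts, ignore_index=True)
            sizes = pool["size"].to_numpy(dtype=float)
            counts = rng.multinomial(config.bulk_depth, sizes / sizes.sum())
            keep = counts > 0
            df = pd.DataFrame({
                "cdr3nt": pool["cdr3nt"].to_numpy()[keep],
                "cdr3aa": pool["cdr3aa"].to_numpy()[keep],
                "v_gene": pool["v_gene"].to_numpy()[keep],
                "j_gene": pool["j_gene"].to_numpy()[keep],
                "count": counts[keep].astype(np.int64),
            })
            df["frequency"] = df["count"] / config.bulk_depth
            df = (df.sort_values(["count", "cdr3nt"], ascending=[False, True],
                                 kind="mergesort").reset_index(drop=True))
            reps.append(BulkRepertoire(donor_id=donor, subset_label=tube,
                                       chain="TRB",
                                       clonotypes=df[CLONOTYPE_COLUMNS]))
    return reps


def sample_single_cells(truth: SyntheticTruth,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw single cells and emit (contigs, cell metadata, per-cell truth).

    Contigs are in the 10x ``filtered_contig_annotations.csv`` dialect.
    Every cell gets a cluster label (metadata covers non-captured cells
    too); only captured cells yield a TRB contig, and decoy cells get a
    second, strictly lower-UMI TRB contig from another clone.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    contig_rows, meta_rows, truth_rows = [], [], []
    clusters = np.asarray(config.cluster_labels, dtype=object)
    for donor in config.donors:
        dclones = truth.clones[truth.clones["donor_id"] == donor].reset_index(drop=True)
        sizes = dclones["size"].to_numpy(dtype=float)
        probs = sizes / sizes.sum()
        clone_idx = rng.choice(len(dclones), size=config.cells_per_donor, p=probs)
        for i, ci in enumerate(clone_idx):
            clone = dclones.iloc[ci]
            cluster = str(rng.choice(clusters, p=truth.programs[clone["subset"]]))
            barcode = "".join("ACGT"[b] for b in rng.integers(0, 4, 10)) \
                + f"{i:05d}-1"
            captured = rng.random() < config.capture_rate
            decoy = bool(captured and rng.random() < config.decoy_fraction)
            decoy_nt = ""
            if captured:
                umi = 2 + int(rng.poisson(3.0))
                contig_rows.append((barcode, donor, "TRB", clone["v_gene"],
                                    clone["j_gene"], clone["cdr3aa"],
                                    clone["cdr3nt"], umi, "True", "True"))
                if decoy:
                    other = dclones.iloc[int(rng.integers(0, len(dclones)))]
                    decoy_nt = other["cdr3nt"]
                    contig_rows.append((barcode, donor, "TRB", other["v_gene"],
                                        other["j_gene"], other["cdr3aa"],
                                        decoy_nt, int(rng.integers(1, umi)),
                                        "True", "True"))
            meta_rows.append((barcode, donor, cluster))
            truth_rows.append((barcode, donor, clone["clone_id"], clone["subset"],
                               cluster, captured, decoy, decoy_nt))
    contigs = pd.DataFrame(contig_rows, columns=[
        "barcode", "donor_id", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt",
        "umis", "productive", "full_length"])
    meta = pd.DataFrame(meta_rows, columns=["barcode", "donor_id", "cluster_id"])
    cell_truth = pd.DataFrame(truth_rows, columns=[
        "barcode", "donor_id", "clone_id", "true_subset", "true_cluster",
        "captured", "has_decoy", "decoy_cdr3nt"])
    return contigs, meta, cell_truth


def sample_adt(cell_truth: pd.DataFrame, config: SyntheticConfig,
               rng: np.random.Generator | None = None) -> ADTMatrix:
    """Draw ADT counts for every cell from the subset-signature NB model."""
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    adt = config.adt
    n = len(cell_truth)
    batches = list(adt.batch_multipliers)
    batch_id = np.asarray(batches, dtype=object)[rng.integers(0, len(batches), n)]
    mult = np.array([adt.batch_multipliers[b] for b in batch_id])
    counts = np.zeros((n, len(adt.markers)))
    subsets = cell_truth["true_subset"].to_numpy()
    for j, marker in enumerate(adt.markers):
        pos = np.array([marker in ADT_SIGNATURES.get(s, frozenset())
                        for s in subsets])
        mu = np.where(pos, adt.pos_mean, adt.neg_mean) * mult
        nz = mu > 0
        if adt.dispersion is None:
            counts[nz, j] = rng.poisson(mu[nz])
        else:
            r = adt.dispersion
            counts[nz, j] = rng.negative_binomial(r, r / (r + mu[nz]))
    cells = (cell_truth["donor_id"] + ":" + cell_truth["barcode"]).tolist()
    return ADTMatrix(cells=cells, markers=list(adt.markers), counts=counts,
                     batch_id=batch_id)


@dataclass
class SyntheticDataset:
    """One simulated study: truth plus every table the pipeline reads."""

    truth: SyntheticTruth
    bulk: list[BulkRepertoire]
    contigs: pd.DataFrame
    meta: pd.DataFrame
    cell_truth: pd.DataFrame
    adt: ADTMatrix


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run the whole generator with one master seed (fully deterministic)."""
    truth = make_truth(config)
    bulk = sample_bulk_repertoires(truth)
    contigs, meta, cell_truth = sample_single_cells(truth)
    adt = sample_adt(cell_truth, config)
    return SyntheticDataset(truth=truth, bulk=bulk, contigs=contigs, meta=meta,
                            cell_truth=cell_truth, adt=adt)


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write the dataset in exactly the formats the io module reads, plus a
    ``truth/`` directory with the ground-truth tables."""
    out = Path(out_dir)
    (out / "bulk").mkdir(parents=True, exist_ok=True)
    for rep in ds.bulk:
        write_bulk_repertoire(
            rep, out / "bulk" / f"{rep.donor_id}_{rep.subset_label}.tsv")
    for donor, grp in ds.contigs.groupby("donor_id"):
        grp.drop(columns=["donor_id"]).to_csv(
            out / f"{donor}_filtered_contig_annotations.csv", index=False)
    ds.meta.to_csv(out / "cell_meta.tsv", sep="\t", index=False)
    write_adt_matrix(ds.adt, out / "adt")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    ds.truth.clones.to_csv(truth_dir / "clones.tsv", sep="\t", index=False)
    ds.cell_truth.to_csv(truth_dir / "cells.tsv", sep="\t", index=False)
    prog = pd.DataFrame(ds.truth.programs, index=ds.truth.config.cluster_labels)
    prog.to_csv(truth_dir / "programs.tsv", sep="\t")
    with open(out / "run_metadata.txt", "w") as fh:
        fh.write(f"seed\t{ds.truth.config.seed}\n")
        fh.write(f"n_donors\t{ds.truth.config.n_donors}\n")
        fh.write(f"cells_per_donor\t{ds.truth.config.cells_per_donor}\n")
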