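"""End-to-end pipelines binding the processing stages together.

These functions are the programmatic equivalents of the CLI subcommands and
are what the test-bench experiments call: the clonotype-tracking arm
(filter -> resolve -> top-N select -> match -> mapping matrices -> Shannon),
the CITE-seq gating arm (CLR -> threshold optimization -> gate -> the same
mapping matrices), and the seeded head-to-head comparison of the two.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .citeseq_gating import (GateSpec, NormalizedADT, apply_gate_sequence,
                             clr_normalize, optimize_gate_thresholds,
                             quantile_grids, UNGATED)
from .clonotype_core import (MatchKey, filter_contigs, match_cells,
                             resolve_cell_chains, select_top_clonotypes)
from .io import ADTMatrix, BulkRepertoire, normalize_contigs
from .subset_mapping import MappingResult, ShannonConfig, compute_mapping_matrices
from .synthetic_data import (SyntheticConfig, SyntheticDataset, noisy_adt_config,
                             simulate_dataset)

logger = logging.getLogger("tcrtrack")


def run_tcr_track(bulk: Sequence[BulkRepertoire], contigs: pd.DataFrame,
                  meta: pd.DataFrame, top_n: int = 500,
                  rank_window: tuple[int, int] | None = None,
                  key: MatchKey = MatchKey(), subsample_n: int | None = 20000,
                  seed: int = 0, shannon: ShannonConfig = ShannonConfig()
                  ) -> tuple[MappingResult, pd.DataFrame]:
    """The clonotype-tracking arm; returns the mapping result and the match
    table.  Chain-relevant repertoires are selected by ``key.chain``.
    Accepts raw 10x-dialect contig frames and normalizes them on the fly."""
    if "is_productive" not in contigs.columns:
        contigs = normalize_contigs(contigs)
    cells = resolve_cell_chains(filter_contigs(contigs))
    selected = [select_top_clonotypes(r, n=top_n, rank_window=rank_window)
                for r in bulk if r.chain == key.chain]
    matches = match_cells(selected, cells, key=key)
    result = compute_mapping_matrices(matches, meta, subsample_n=subsample_n,
                                      seed=seed, config=shannon)
    return result, matches


def align_clusters_to_adt(adt: ADTMatrix, meta: pd.DataFrame) -> np.ndarray:
    """Cluster label per ADT cell; ADT cell ids are ``donor:barcode``."""
    lut = dict(zip(meta["donor_id"] + ":" + meta["barcode"], meta["cluster_id"]))
    missing = [c for c in adt.cells if c not in lut]
    if missing:
        raise ValueError(f"{len(missing)} ADT cells lack cluster labels "
                         f"(first: {missing[0]!r})")
    return np.asarray([lut[c] for c in adt.cells], dtype=object)


def run_citeseq_gating(adt: ADTMatrix, meta: pd.DataFrame,
                       grids: Mapping[str, Sequence[float]] | None = None,
                       quantiles: Sequence[float] = (0.5, 0.7, 0.85),
                       margin: str = "cell", batchwise: bool = True,
                       rna_fallback: Mapping[str, np.ndarray] | None = None,
                       subsample_n: int | None = 20000, seed: int = 0,
                       shannon: ShannonConfig = ShannonConfig()
                       ) -> tuple[MappingResult, pd.DataFrame, GateSpec]:
    """The comparator arm: CLR-normalize, optimize gate thresholds by
    minimizing mean normalized Shannon index, gate, and score with exactly
    the same mapping/Shannon machinery as the clonotype arm."""
    norm = clr_normalize(adt, margin=margin, batchwise=batchwise)
    cluster_ids = align_clusters_to_adt(adt, meta)
    if grids is None:
        markers = [m for m in norm.markers]
        grids = quantile_grids(norm, markers, quantiles=quantiles,
                               rna_fallback=rna_fallback)
    spec, _, _ = optimize_gate_thresholds(norm, grids, cluster_ids,
                                          config=shannon,
                                          rna_fallback=rna_fallback)
    labels = apply_gate_sequence(norm, spec, rna_fallback=rna_fallback)
    gated = pd.DataFrame({
        "cell": adt.cells, "subset_label": labels}).loc[lambda d: d["subset_label"] != UNGATED]
    parts = gated["cell"].str.split(":", n=1, expand=True)
    gate_table = pd.DataFrame({"donor_id": parts[0], "barcode": parts[1],
                               "subset_label": gated["subset_label"].to_numpy()})
    result = compute_mapping_matrices(gate_table, meta, subsample_n=subsample_n,
                                      seed=seed, config=shannon)
    return result, gate_table, spec


@dataclass
class ComparatorOutcome:
    """One seeded replicate of the two-arm comparison."""

    seed: int
    mean_shannon_tcr: float
    mean_shannon_gating: float

    @property
    def tcr_wins(self) -> bool:
        return self.mean_shannon_tcr < self.mean_shannon_gating


def _mean_defined_shannon(result: MappingResult) -> float:
    vals = result.shannon.loc[result.shannon["defined"], "S"]
    return float(vals.mean()) if len(vals) else float("nan")


def comparator_experiment(n_replicates: int = 20, seed: int = 0,
                          base_config: SyntheticConfig | None = None
                          ) -> list[ComparatorOutcome]:
    """Head-to-head accuracy comparison under high ADT noise.

    For each replicate a dataset is simulated with a clean clonal structure
    but a noisy ADT layer; both arms are run and their mean defined Shannon
    indices compared.  Lower is better, so the clonotype arm "wins" a
    replicate when its mean index is smaller.
    """
    outcomes = []
    for r in range(n_replicates):
        config = base_config if base_config is not None else SyntheticConfig(
            n_donors=1, cells_per_donor=1500, clones_per_subset=300,
            bulk_depth=20000)
        config = SyntheticConfig(**{**config.__dict__,
                                    "adt": noisy_adt_config(),
                                    "seed": seed + 1000 * r})
        ds = simulate_dataset(config)
        tcr_result, _ = run_tcr_track(ds.bulk, ds.contigs, ds.meta,
                                      subsample_n=None, seed=config.seed)
        gate_result, _, _ = run_citeseq_gating(ds.adt, ds.meta,
                                               quantiles=(0.6, 0.85),
                                               subsample_n=None,
                                               seed=config.seed)
        outcomes.append(ComparatorOutcome(
            seed=config.seed,
            mean_shannon_tcr=_mean_defined_shannon(tcr_result),
            mean_shannon_gating=_mean_defined_shannon(gate_result)))
    return outcomes
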