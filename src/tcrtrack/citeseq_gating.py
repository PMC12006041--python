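"""The CITE-seq comparator arm: CLR normalization of ADT counts, sequential
in-silico surface-marker gating, and threshold optimization.

Cells are assigned to helper subsets by thresholding normalized antibody
tag intensities in a fixed hierarchy that mirrors the FACS sorting gates:
Tregs (CD25 high, CD127 low) are consumed first, then Tfh (CXCR5+), then
Th22 (CCR10+), and the remaining cells are split on the CCR6/CXCR3/CCR4
chemokine-receptor axes, with CRTh2 separating Th2a from Th2.  Gate
thresholds are chosen to minimize the mean normalized Shannon-Wiener index
of the gated subsets' cluster distributions — the same accuracy measure
used for the clonotype-based mapping, so the two arms are directly
comparable.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import ADTMatrix
from .subset_mapping import ShannonConfig, shannon_accuracy

logger = logging.getLogger("tcrtrack")

UNGATED = "ungated"


class ConfigurationError(ValueError):
    """A gate references a marker that is not available."""


class OptimizationError(RuntimeError):
    """No threshold combination yields any scorable subset."""


@dataclass
class NormalizedADT:
    """ADT intensities on the CLR scale, same shape as the raw matrix."""

    cells: list[str]
    markers: list[str]
    values: np.ndarray
    batch_id: np.ndarray
    normalization: dict = field(default_factory=dict)

    def marker_values(self, marker: str) -> np.ndarray:
        return self.values[:, self.markers.index(marker)]


def _clr_vector(x: np.ndarray) -> np.ndarray:
    """clr_i = ln(1 + x_i / g), g the geometric mean over positive entries
    with the full vector length (zeros included) in the denominator.

    This is the ADT convention popularized by Seurat: an all-zero vector
    maps to zero (g defaults to 1), and zero entries stay exactly zero.
    """
    pos = x > 0
    if not pos.any():
        return np.zeros_like(x, dtype=float)
    g = math.exp(np.log(x[pos]).sum() / len(x))
    return np.log1p(x / g)


def clr_normalize(adt: ADTMatrix, margin: str = "cell",
                  batchwise: bool = True) -> NormalizedADT:
    """Centered-log-ratio normalization of ADT counts.

    ``margin="cell"`` normalizes each cell's vector across the marker panel;
    ``margin="marker"`` normalizes each marker's vector across the cells of a
    batch.  When ``batchwise`` the normalization is applied within each batch
    separately (only meaningful for the marker margin; the cell margin is
    batch-local by construction).
    """
    if margin not in ("cell", "marker"):
        raise ValueError(f"unknown CLR margin {margin!r}")
    counts = np.asarray(adt.counts, dtype=float)
    values = np.empty_like(counts)
    if margin == "cell":
        for i in range(counts.shape[0]):
            values[i, :] = _clr_vector(counts[i, :])
    else:
        batches = (np.unique(adt.batch_id) if batchwise
                   else np.array(["__all__"], dtype=object))
        for b in batches:
            rows = (adt.batch_id == b) if batchwise else np.ones(len(adt.cells), bool)
            for j in range(counts.shape[1]):
                values[np.where(rows)[0], j] = _clr_vector(counts[rows, j])
    return NormalizedADT(cells=list(adt.cells), markers=list(adt.markers),
                         values=values, batch_id=np.asarray(adt.batch_id),
                         normalization={"method": "CLR", "margin": margin,
                                        "batchwise": batchwise})


@dataclass(frozen=True)
class GateConstraint:
    marker: str
    direction: str  # "above" | "below"
    threshold: float

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValueError(f"unknown gate direction {self.direction!r}")
        if not math.isfinite(self.threshold):
            raise ValueError("gate threshold must be finite")


@dataclass(frozen=True)
class GateNode:
    subset_label: str
    constraints: tuple[GateConstraint, ...]
    consume: bool = True


@dataclass
class GateSpec:
    """Ordered gate hierarchy; earlier consuming nodes remove their cells
    from all later nodes."""

    nodes: list[GateNode]

    @property
    def markers(self) -> list[str]:
        seen: list[str] = []
        for node in self.nodes:
            for c in node.constraints:
                if c.marker not in seen:
                    seen.append(c.marker)
        return seen

    def to_yaml(self, path) -> None:
        payload = [{"subset": n.subset_label, "consume": n.consume,
                    "gates": [{"marker": c.marker, "direction": c.direction,
                               "threshold": float(c.threshold)}
                              for c in n.constraints]}
                   for n in self.nodes]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GateSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        nodes = [GateNode(subset_label=e["subset"],
                          consume=bool(e.get("consume", True)),
                          constraints=tuple(
                              GateConstraint(g["marker"], g["direction"],
                                             float(g["threshold"]))
                              for g in e["gates"]))
                 for e in payload]
        return cls(nodes=nodes)


#: (subset, [(marker, direction), ...]) rows of the default sort-gate
#: hierarchy; order matters — each consuming node removes its cells from the
#: nodes below it, which encodes the leading "NOT CD25 high CD127 low" of
#: every non-Treg sort gate.
DEFAULT_GATE_HIERARCHY: list[tuple[str, list[tuple[str, str]]]] = [
    ("Treg", [("CD25", "above"), ("CD127", "below")]),
    ("Tfh", [("CXCR5", "above"), ("CCR10", "below")]),
    ("Th22", [("CCR10", "above"), ("CXCR5", "below")]),
    ("Th1", [("CCR6", "below"), ("CXCR3", "above"), ("CCR4", "below")]),
    ("Th1-17", [("CCR6", "above"), ("CXCR3", "above"), ("CCR4", "below")]),
    ("Th17", [("CCR6", "above"), ("CXCR3", "below"), ("CCR4", "above")]),
    ("Th2a", [("CCR6", "below"), ("CXCR3", "below"), ("CCR4", "above"),
              ("CRTh2", "above")]),
    ("Th2", [("CCR6", "below"), ("CXCR3", "below"), ("CCR4", "above"),
             ("CRTh2", "below")]),
]


def default_gate_spec(thresholds: Mapping[str, float]) -> GateSpec:
    """Instantiate the default hierarchy with one threshold per marker."""
    nodes = []
    for subset, gates in DEFAULT_GATE_HIERARCHY:
        constraints = tuple(GateConstraint(m, d, float(thresholds[m]))
                            for m, d in gates)
        nodes.append(GateNode(subset_label=subset, constraints=constraints))
    return GateSpec(nodes=nodes)


def apply_gate_sequence(norm: NormalizedADT, spec: GateSpec,
                        rna_fallback: Mapping[str, np.ndarray] | None = None
                        ) -> np.ndarray:
    """Assign each cell a subset label by testing gate nodes in order.

    The first satisfied consuming node labels the cell and removes it from
    later nodes; cells satisfying no node are labelled ``"ungated"``.
    Markers absent from the ADT panel are looked up in ``rna_fallback``
    (per-cell expression vectors, e.g. CCR10 from RNA); a marker missing
    from both raises :class:`ConfigurationError`.
    """
    n = len(norm.cells)
    values: dict[str, np.ndarray] = {}
    for marker in spec.markers:
        if marker in norm.markers:
            values[marker] = norm.marker_values(marker)
        elif rna_fallback is not None and marker in rna_fallback:
            v = np.asarray(rna_fallback[marker], dtype=float)
            if v.shape != (n,):
                raise ConfigurationError(
                    f"RNA fallback for {marker} has shape {v.shape}, expected ({n},)")
            values[marker] = v
        else:
            raise ConfigurationError(
                f"marker {marker!r} not in ADT panel and no RNA fallback given")
    labels = np.full(n, UNGATED, dtype=object)
    available = np.ones(n, dtype=bool)
    for node in spec.nodes:
        mask = available.copy()
        for c in node.constraints:
            v = values[c.marker]
            mask &= (v > c.threshold) if c.direction == "above" else (v <= c.threshold)
        labels[mask] = node.subset_label
        if node.consume:
            available &= ~mask
    return labels


def _gating_objective(labels: np.ndarray, cluster_ids: np.ndarray,
                      config: ShannonConfig) -> float:
    """Mean normalized Shannon index over gated subsets passing the
    min-cells rule; +inf when no subset is scorable."""
    scores = []
    for subset in np.unique(labels):
        if subset == UNGATED:
            continue
        clusters = cluster_ids[labels == subset]
        if len(clusters) < config.min_cells:
            continue
        counts = np.unique(clusters, return_counts=True)[1].astype(float)
        scores.append(shannon_accuracy(counts / counts.sum(), config,
                                       n_cells=len(clusters)))
    return float(np.mean(scores)) if scores else float("inf")


def optimize_gate_thresholds(norm: NormalizedADT,
                             grids: Mapping[str, Sequence[float]],
                             cluster_ids: Sequence[str],
                             config: ShannonConfig = ShannonConfig(),
                             rna_fallback: Mapping[str, np.ndarray] | None = None,
                             hierarchy: list | None = None,
                             method: str = "exhaustive",
                             ) -> tuple[GateSpec, float, pd.DataFrame]:
    """Choose per-marker gate thresholds minimizing the mean normalized
    Shannon-Wiener index of the gated subsets.

    ``grids`` maps each marker to its candidate thresholds (on the CLR
    scale).  ``method="exhaustive"`` scores every combination (the default;
    grids are small), ``"coordinate"`` runs coordinate descent from the
    first grid point and may settle in a local minimum (logged).  Ties break
    to the first combination in grid order, so the result is deterministic.

    Returns the winning :class:`GateSpec`, its objective value, and a report
    table with one row per evaluated combination.
    """
    cluster_ids = np.asarray(cluster_ids, dtype=object)
    if cluster_ids.shape != (len(norm.cells),):
        raise ValueError("cluster_ids must align with the ADT cells")
    markers = list(grids)
    rows = DEFAULT_GATE_HIERARCHY if hierarchy is None else hierarchy

    def build(thresholds: Mapping[str, float]) -> GateSpec:
        return GateSpec(nodes=[
            GateNode(subset_label=s,
                     constraints=tuple(GateConstraint(m, d, float(thresholds[m]))
                                       for m, d in gates))
            for s, gates in rows])

    def score(combo: tuple[float, ...]) -> float:
        spec = build(dict(zip(markers, combo)))
        labels = apply_gate_sequence(norm, spec, rna_fallback=rna_fallback)
        return _gating_objective(labels, cluster_ids, config)

    report_rows = []
    if method == "exhaustive":
        best_combo, best_obj = None, float("inf")
        for combo in itertools.product(*(grids[m] for m in markers)):
            obj = score(combo)
            report_rows.append((*combo, obj))
            if obj < best_obj:
                best_combo, best_obj = combo, obj
    elif method == "coordinate":
        combo = [grids[m][0] for m in markers]
        best_obj = score(tuple(combo))
        report_rows.append((*combo, best_obj))
        improved = True
        while improved:
            improved = False
            for k, m in enumerate(markers):
                for cand in grids[m]:
                    if cand == combo[k]:
                        continue
                    trial = list(combo)
                    trial[k] = cand
                    obj = score(tuple(trial))
                    report_rows.append((*trial, obj))
                    if obj < best_obj:
                        combo, best_obj, improved = trial, obj, True
        best_combo = tuple(combo)
        logger.info("coordinate descent finished; result may be a local minimum")
    else:
        raise ValueError(f"unknown optimization method {method!r}")

    if best_combo is None or not math.isfinite(best_obj):
        raise OptimizationError(
            "no threshold combination produced a subset above the min-cells rule")
    report = pd.DataFrame(report_rows, columns=[*markers, "objective"])
    return build(dict(zip(markers, best_combo))), best_obj, report


def quantile_grids(norm: NormalizedADT, markers: Sequence[str],
                   quantiles: Sequence[float] = (0.5, 0.7, 0.85),
                   rna_fallback: Mapping[str, np.ndarray] | None = None
                   ) -> dict[str, list[float]]:
    """Data-driven candidate thresholds: per-marker CLR quantiles."""
    grids = {}
    for m in markers:
        if m in norm.markers:
            v = norm.marker_values(m)
        elif rna_fallback is not None and m in rna_fallback:
            v = np.asarray(rna_fallback[m], dtype=float)
        else:
            raise ConfigurationError(f"marker {m!r} unavailable for grid building")
        grids[m] = [float(np.quantile(v, q)) for q in quantiles]
    return grids
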