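import itertools
import math

import numpy as np
import pytest

from tcrtrack import (ADTMatrix, GateConstraint, GateNode, GateSpec,
                      ShannonConfig, apply_gate_sequence, clr_normalize,
                      default_gate_spec, optimize_gate_thresholds)
from tcrtrack.citeseq_gating import (ConfigurationError, OptimizationError,
                                     UNGATED, _gating_objective)


def adt(counts, markers=None, batch=None):
    counts = np.asarray(counts, dtype=float)
    markers = markers or [f"M{j}" for j in range(counts.shape[1])]
    return ADTMatrix(cells=[f"c{i}" for i in range(counts.shape[0])],
                     markers=markers, counts=counts, batch_id=batch)


class TestCLR:
    def test_worked_example(self):
        """x=(1,4,0): g = 4^(1/3); clr = (ln(1+1/g), ln(1+4/g), 0)."""
        g = 4 ** (1 / 3)
        oracle = [math.log(1 + 1 / g), math.log(1 + 4 / g), 0.0]
        norm = clr_normalize(adt([[1, 4, 0]]), margin="cell")
        np.testing.assert_allclose(norm.values[0], oracle, atol=1e-12)
        np.testing.assert_allclose(norm.values[0], [0.488556, 1.258413, 0.0],
                                   atol=1e-5)

    def test_constant_vector_maps_to_ln2(self):
        norm = clr_normalize(adt([[7, 7, 7]]), margin="cell")
        np.testing.assert_allclose(norm.values[0], math.log(2), atol=1e-12)

    def test_zero_vector_stays_zero(self):
        norm = clr_normalize(adt([[0, 0, 0]]), margin="cell")
        np.testing.assert_array_equal(norm.values[0], 0.0)

    def test_marker_margin_batchwise(self):
        counts = [[10, 1], [20, 1], [100, 1], [200, 1]]
        batch = ["A", "A", "B", "B"]
        norm = clr_normalize(adt(counts, batch=batch), margin="marker",
                             batchwise=True)
        # within each batch the same 1:2 ratio -> identical normalized pairs
        np.testing.assert_allclose(norm.values[:2, 0], norm.values[2:, 0],
                                   atol=1e-12)
        whole = clr_normalize(adt(counts, batch=batch), margin="marker",
                              batchwise=False)
        assert not np.allclose(whole.values[:2, 0], whole.values[2:, 0])

    def test_metadata_recorded(self):
        norm = clr_normalize(adt([[1, 2, 3]]), margin="cell")
        assert norm.normalization == {"method": "CLR", "margin": "cell",
                                      "batchwise": True}


class TestGateSequence:
    def _norm(self, values, markers):
        a = adt(np.zeros_like(np.asarray(values, dtype=float)), markers=markers)
        n = clr_normalize(a, margin="cell")
        n.values = np.asarray(values, dtype=float)
        return n

    def test_treg_consumed_first(self):
        markers = ["CD25", "CD127", "CXCR5", "CCR10", "CCR6", "CXCR3",
                   "CCR4", "CRTh2"]
        # cell 0: CD25 high CD127 low (Treg), even though CXCR5 also high
        # cell 1: CCR10 high (Th22); cell 2: nothing above threshold
        vals = [[2.0, 0.1, 2.0, 0.0, 0, 0, 0, 0],
                [0.1, 2.0, 0.1, 2.0, 0, 0, 0, 0],
                [0.1, 2.0, 0.1, 0.0, 0, 0, 0, 0]]
        spec = default_gate_spec({m: 1.0 for m in markers})
        labels = apply_gate_sequence(self._norm(vals, markers), spec)
        assert labels.tolist() == ["Treg", "Th22", UNGATED]

    def test_chemokine_splits(self):
        markers = ["CD25", "CD127", "CXCR5", "CCR10", "CCR6", "CXCR3",
                   "CCR4", "CRTh2"]
        rows = {
            "Th1": [0, 2, 0, 0, 0, 2, 0, 0],
            "Th1-17": [0, 2, 0, 0, 2, 2, 0, 0],
            "Th17": [0, 2, 0, 0, 2, 0, 2, 0],
            "Th2": [0, 2, 0, 0, 0, 0, 2, 0],
            "Th2a": [0, 2, 0, 0, 0, 0, 2, 2],
            "Tfh": [0, 2, 2, 0, 0, 0, 0, 0],
        }
        spec = default_gate_spec({m: 1.0 for m in markers})
        labels = apply_gate_sequence(
            self._norm(list(rows.values()), markers), spec)
        assert labels.tolist() == list(rows)

    def test_sequential_exclusivity(self, rng):
        markers = ["CD25", "CD127", "CXCR5", "CCR10", "CCR6", "CXCR3",
                   "CCR4", "CRTh2"]
        vals = rng.normal(1.0, 1.0, size=(500, 8))
        spec = default_gate_spec({m: 1.0 for m in markers})
        labels = apply_gate_sequence(self._norm(vals, markers), spec)
        assert labels.shape == (500,)  # exactly one label per cell

    def test_threshold_monotonicity(self, rng):
        """Raising a positive-direction threshold never grows the subset."""
        markers = ["CD25", "CD127"]
        vals = rng.normal(1.0, 1.0, size=(400, 2))
        spec_lo = GateSpec([GateNode("Treg", (GateConstraint("CD25", "above", 0.5),
                                              GateConstraint("CD127", "below", 1.0)))])
        spec_hi = GateSpec([GateNode("Treg", (GateConstraint("CD25", "above", 1.5),
                                              GateConstraint("CD127", "below", 1.0)))])
        norm = self._norm(vals, markers)
        n_lo = (apply_gate_sequence(norm, spec_lo) == "Treg").sum()
        n_hi = (apply_gate_sequence(norm, spec_hi) == "Treg").sum()
        assert n_hi <= n_lo

    def test_missing_marker_raises(self):
        norm = self._norm([[1.0]], ["CD25"])
        spec = GateSpec([GateNode("Tfh", (GateConstraint("CXCR5", "above", 1.0),))])
        with pytest.raises(ConfigurationError):
            apply_gate_sequence(norm, spec)

    def test_rna_fallback_supplies_marker(self):
        norm = self._norm([[1.5], [0.2]], ["CXCR5"])
        spec = GateSpec([
            GateNode("Tfh", (GateConstraint("CXCR5", "above", 1.0),
                             GateConstraint("CCR10", "below", 1.0))),
            GateNode("Th22", (GateConstraint("CCR10", "above", 1.0),))])
        labels = apply_gate_sequence(norm, spec,
                                     rna_fallback={"CCR10": np.array([0.0, 2.0])})
        assert labels.tolist() == ["Tfh", "Th22"]


class TestOptimizer:
    def _toy(self, rng, n=300):
        """Two well-separated populations: Tregs (CD25 hi, CD127 lo) in
        cluster K0, others in K1."""
        half = n // 2
        cd25 = np.concatenate([rng.normal(3, 0.3, half), rng.normal(0.3, 0.3, half)])
        cd127 = np.concatenate([rng.normal(0.3, 0.3, half), rng.normal(3, 0.3, half)])
        counts = np.clip(np.column_stack([cd25, cd127]), 0, None)
        a = adt(counts, markers=["CD25", "CD127"])
        norm = clr_normalize(a, margin="cell")
        norm.values = np.column_stack([cd25, cd127])
        clusters = np.array(["K0"] * half + ["K1"] * half, dtype=object)
        return norm, clusters

    HIER = [("Treg", [("CD25", "above"), ("CD127", "below")])]

    def test_single_candidate_grid(self, rng):
        norm, clusters = self._toy(rng)
        grids = {"CD25": [1.5], "CD127": [1.5]}
        spec, obj, report = optimize_gate_thresholds(norm, grids, clusters,
                                                     hierarchy=self.HIER)
        assert len(report) == 1
        assert spec.nodes[0].constraints[0].threshold == 1.5

    def test_argmin_matches_exhaustive_enumeration(self, rng):
        norm, clusters = self._toy(rng)
        grids = {"CD25": [0.0, 1.5, 2.8], "CD127": [0.5, 1.5, 4.0]}
        spec, obj, report = optimize_gate_thresholds(norm, grids, clusters,
                                                     hierarchy=self.HIER)
        # independent enumeration over all 9 combinations
        from tcrtrack.citeseq_gating import GateConstraint, GateNode, GateSpec
        best = math.inf
        for t25, t127 in itertools.product(grids["CD25"], grids["CD127"]):
            s = GateSpec([GateNode("Treg",
                                   (GateConstraint("CD25", "above", t25),
                                    GateConstraint("CD127", "below", t127)))])
            labels = apply_gate_sequence(norm, s)
            o = _gating_objective(labels, clusters, ShannonConfig())
            best = min(best, o)
        assert obj == best
        assert (report["objective"] >= obj).all()

    def test_deterministic_rerun(self, rng):
        norm, clusters = self._toy(rng)
        grids = {"CD25": [0.0, 1.5, 2.8], "CD127": [0.5, 1.5, 4.0]}
        a = optimize_gate_thresholds(norm, grids, clusters, hierarchy=self.HIER)
        b = optimize_gate_thresholds(norm, grids, clusters, hierarchy=self.HIER)
        assert a[0] == b[0] and a[1] == b[1]

    def test_coordinate_descent_on_toy_finds_exhaustive_min(self, rng):
        norm, clusters = self._toy(rng)
        grids = {"CD25": [0.0, 1.5, 2.8], "CD127": [0.5, 1.5, 4.0]}
        _, obj_ex, _ = optimize_gate_thresholds(norm, grids, clusters,
                                                hierarchy=self.HIER)
        _, obj_cd, _ = optimize_gate_thresholds(norm, grids, clusters,
                                                hierarchy=self.HIER,
                                                method="coordinate")
        assert obj_cd >= obj_ex - 1e-12  # may be local; never better

    def test_no_scorable_subset_raises(self, rng):
        norm, clusters = self._toy(rng, n=10)
        grids = {"CD25": [100.0], "CD127": [-100.0]}  # gates nothing
        with pytest.raises(OptimizationError):
            optimize_gate_thresholds(norm, grids, clusters, hierarchy=self.HIER)


class TestGateSpecYaml:
    def test_roundtrip(self, tmp_path):
        spec = default_gate_spec({m: float(i) for i, m in enumerate(
            ["CD25", "CD127", "CXCR5", "CCR10", "CCR6", "CXCR3", "CCR4",
             "CRTh2"])})
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = GateSpec.from_yaml(path)
        assert back.nodes == spec.nodes
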