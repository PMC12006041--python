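import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrtrack import (BulkRepertoire, ClusterRepertoire, aggregate_overlap,
                      build_cluster_repertoires, clonality_table,
                      cluster_clonality, donor_overlap_matrix,
                      pairwise_overlap_D, shared_clonotype_partition)

from conftest import _nt_code, make_repertoire_frame


def crep(clonotypes, cell_count=None, donor="D01", cluster="Th17"):
    clonotypes = set(clonotypes)
    return ClusterRepertoire(donor_id=donor, cluster_id=cluster,
                             clonotypes=clonotypes,
                             cell_count=cell_count or len(clonotypes))


class TestClonality:
    def test_all_unique_is_one(self):
        rep = crep({_nt_code(i) for i in range(10)}, cell_count=10)
        assert cluster_clonality(rep) == 1.0

    def test_expanded_cluster(self):
        rep = crep({_nt_code(i) for i in range(4)}, cell_count=10)
        assert cluster_clonality(rep) == pytest.approx(0.4)

    def test_empty_cluster_not_defined(self):
        rep = crep(set(), cell_count=0)
        assert math.isnan(cluster_clonality(rep))

    def test_build_from_cells(self):
        cells = pd.DataFrame({
            "donor_id": ["D01"] * 3, "barcode": ["a", "b", "c"],
            "chain": "TRB", "cdr3nt": ["X", "X", "Y"], "cdr3aa": "C",
            "v_gene": "V", "j_gene": "J", "umi_count": 1})
        meta = pd.DataFrame({"barcode": ["a", "b", "c"], "donor_id": "D01",
                             "cluster_id": ["K", "K", "K"]})
        reps = build_cluster_repertoires(cells, meta)
        assert len(reps) == 1 and reps[0].cell_count == 3
        assert clonality_table(reps)["clonality"].iloc[0] == pytest.approx(2 / 3)


class TestPairwiseOverlap:
    def test_disjoint_sets(self):
        a = crep({_nt_code(i) for i in range(10)})
        b = crep({_nt_code(i + 100) for i in range(10)}, cluster="Th22")
        d, t = pairwise_overlap_D(a, b)
        assert d == 0 and t == 0

    def test_worked_example(self):
        """|A|=100, |B|=200, 5 shared -> log2(1 + 1e6*5/20000) = log2(251)."""
        a = crep({_nt_code(i) for i in range(100)})
        b = crep({_nt_code(i + 95) for i in range(200)}, cluster="Th22")
        d, t = pairwise_overlap_D(a, b)
        assert d == pytest.approx(5 / 20000)
        assert t == pytest.approx(math.log2(251), abs=1e-5)
        assert t == pytest.approx(7.97154, abs=1e-5)

    def test_identical_sets(self):
        s = {_nt_code(i) for i in range(100)}
        t = pairwise_overlap_D(crep(s), crep(s, cluster="Th22"))[1]
        assert t == pytest.approx(math.log2(1 + 1e6 / 100), abs=1e-5)
        assert t == pytest.approx(13.287857, abs=1e-5)

    def test_cross_donor_rejected(self):
        with pytest.raises(ValueError):
            pairwise_overlap_D(crep({"X"}), crep({"X"}, donor="D02"))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            pairwise_overlap_D(crep({"X"}), crep(set(), cluster="Th22"))

    @given(st.integers(1, 500), st.integers(1, 500), st.integers(0, 200))
    @settings(max_examples=100, deadline=None)
    def test_closed_form_and_symmetry(self, na, nb, shared):
        shared = min(shared, na, nb)
        a_set = {_nt_code(i) for i in range(na)}
        b_set = {_nt_code(i) for i in range(shared)} | {
            _nt_code(i + 1000) for i in range(nb - shared)}
        a, b = crep(a_set), crep(b_set, cluster="Th22")
        d_ab, t_ab = pairwise_overlap_D(a, b)
        d_ba, t_ba = pairwise_overlap_D(b, a)
        assert d_ab == d_ba and t_ab == t_ba  # exact symmetry
        # sorted-merge intersection oracle
        n_shared = len(sorted(set(sorted(a_set)) & set(sorted(b_set))))
        expect = math.log2(1 + 1e6 * n_shared / (len(a_set) * len(b_set)))
        assert t_ab == pytest.approx(expect, abs=1e-9)

    @given(st.integers(1, 1000))
    @settings(max_examples=50, deadline=None)
    def test_self_overlap_closed_form(self, n):
        s = {_nt_code(i) for i in range(n)}
        _, t = pairwise_overlap_D(crep(s), crep(s, cluster="same"))
        assert t == pytest.approx(math.log2(1 + 1e6 / n), abs=1e-9)

    def test_transform_monotone_in_shared(self):
        vals = []
        for shared in range(0, 50, 5):
            a = crep({_nt_code(i) for i in range(100)})
            b = crep({_nt_code(i) for i in range(shared)}
                     | {_nt_code(i + 500) for i in range(100 - shared)},
                     cluster="Th22")
            vals.append(pairwise_overlap_D(a, b)[1])
        assert all(x < y for x, y in zip(vals, vals[1:]))


class TestAggregateOverlap:
    def _donor_matrix(self, vals, clusters=("A", "B")):
        idx = pd.Index(clusters, name="cluster")
        return pd.DataFrame(vals, index=idx, columns=idx)

    def test_mean_over_defined_donors(self):
        m1 = self._donor_matrix([[np.nan, 2.0], [2.0, np.nan]])
        m2 = self._donor_matrix([[np.nan, 4.0], [4.0, np.nan]])
        agg = aggregate_overlap({"D01": m1, "D02": m2})
        assert agg.aggregate.loc["A", "B"] == pytest.approx(3.0)
        assert agg.donor_counts.loc["A", "B"] == 2

    def test_pair_defined_in_one_donor(self):
        m1 = self._donor_matrix([[np.nan, 2.0], [2.0, np.nan]])
        m2 = self._donor_matrix([[np.nan, np.nan], [np.nan, np.nan]])
        agg = aggregate_overlap({"D01": m1, "D02": m2})
        assert agg.aggregate.loc["A", "B"] == pytest.approx(2.0)
        assert agg.donor_counts.loc["A", "B"] == 1

    def test_pair_defined_nowhere_is_nan(self):
        m = self._donor_matrix([[np.nan, np.nan], [np.nan, np.nan]])
        for aggregator in ("mean", "median", "sum"):
            agg = aggregate_overlap({"D01": m}, aggregator=aggregator)
            assert math.isnan(agg.aggregate.loc["A", "B"])

    def test_single_donor_aggregate_equals_input(self, small_dataset):
        from tcrtrack import filter_contigs, resolve_cell_chains
        from tcrtrack.io import normalize_contigs
        ds = small_dataset
        cells = resolve_cell_chains(filter_contigs(normalize_contigs(ds.contigs)))
        donor = ds.truth.config.donors[0]
        reps = [r for r in build_cluster_repertoires(cells, ds.meta)
                if r.donor_id == donor]
        m = donor_overlap_matrix(reps)
        agg = aggregate_overlap({donor: m})
        pd.testing.assert_frame_equal(agg.aggregate, m)


class TestSharedPartition:
    def _rep(self, freqs, donor="D01", subset="Th17", offset=0):
        n = len(freqs)
        df = pd.DataFrame({
            "cdr3nt": [_nt_code(i + offset) for i in range(n)],
            "cdr3aa": "C", "v_gene": "V", "j_gene": "J",
            "count": (np.asarray(freqs) * 1e6).astype(int),
            "frequency": freqs})
        df = df.sort_values(["count", "cdr3nt"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
        return BulkRepertoire(donor, subset, "TRB", df)

    def test_sd_keep_and_reject_worked_examples(self):
        """sd = |f_A - f_B|/sqrt(2): 0.002 vs 0.0015 -> 0.000354 (kept);
        0.01 vs 0.0001 -> 0.007 (rejected)."""
        a = self._rep([0.002, 0.01, 0.5])
        b = self._rep([0.0015, 0.0001, 0.3], subset="Th22")
        part = shared_clonotype_partition(a, b)
        rec = part.records.set_index("cdr3nt")
        kept = rec.loc[_nt_code(0)]
        assert kept["sd"] == pytest.approx(0.000354, abs=1e-6)
        assert kept["status"] == "shared_kept"
        rej = rec.loc[_nt_code(1)]
        assert rej["sd"] == pytest.approx(0.007000, abs=1e-6)
        assert rej["status"] == "shared_rejected"

    def test_population_convention_flag(self):
        a = self._rep([0.002])
        b = self._rep([0.0015], subset="Th22")
        part = shared_clonotype_partition(a, b, sd_convention="population")
        assert part.records["sd"].iloc[0] == pytest.approx(0.00025)

    def test_exclusive_clonotypes_binned(self):
        a = self._rep([0.5, 0.3])
        b = self._rep([0.5, 0.3], subset="Th22", offset=1)  # overlap on 1 only
        part = shared_clonotype_partition(a, b)
        assert part.a_only == {_nt_code(0)}
        assert part.b_only == {_nt_code(2)}
        assert part.shared_kept | part.shared_rejected == {_nt_code(1)}

    @given(st.integers(1, 60), st.integers(1, 60), st.integers(0, 40),
           st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_partition_completeness(self, na, nb, n_shared, seed):
        """Every clonotype of A's top-n slice lands in exactly one bin."""
        rng = np.random.default_rng(seed)
        n_shared = min(n_shared, na, nb)
        fa = rng.dirichlet(np.ones(na))
        fb = rng.dirichlet(np.ones(nb))
        a = self._rep(fa)
        b_nts = ([_nt_code(i) for i in range(n_shared)]
                 + [_nt_code(i + 5000) for i in range(nb - n_shared)])
        df_b = pd.DataFrame({"cdr3nt": b_nts, "cdr3aa": "C", "v_gene": "V",
                             "j_gene": "J", "count": (fb * 1e6).astype(int),
                             "frequency": fb})
        b = BulkRepertoire("D01", "Th22", "TRB",
                           df_b.sort_values(["count", "cdr3nt"],
                                            ascending=[False, True],
                                            kind="mergesort"))
        part = shared_clonotype_partition(a, b, top_n=50)
        from tcrtrack import select_top_clonotypes
        top_a = set(select_top_clonotypes(a, n=50).clonotypes["cdr3nt"])
        # the four bins are disjoint
        bins = [part.a_only, part.b_only, part.shared_kept, part.shared_rejected]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not (bins[i] & bins[j])
        # A-side completeness: shared bins are within A's slice, and every
        # top-slice A clonotype lands in exactly one bin
        assert part.shared_kept | part.shared_rejected <= top_a
        assert part.a_only | part.shared_kept | part.shared_rejected == top_a
        assert len(part.a_only) + len(part.shared_kept) \
            + len(part.shared_rejected) == len(top_a)
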