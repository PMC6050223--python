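"""Binary TF matrix, unique-combination enumeration, interaction ANOVA."""

from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import rgcsub as rs
from rgcsub.io import GenePanel
from rgcsub.markers import ClusterProfile
from rgcsub.tfcombo import TFBinaryMatrix, TFComboError, TFComboRecord


def profile_from(mean_matrix, genes):
    M = pd.DataFrame(
        np.asarray(mean_matrix, dtype=float),
        index=genes,
        columns=range(1, np.asarray(mean_matrix).shape[1] + 1),
    )
    return ClusterProfile(mean_ne=M, median_ne=M.copy(),
                          n_cells=pd.Series([10] * M.shape[1], index=M.columns))


def bm_from(rows, tf_names=None):
    rows = np.asarray(rows, dtype=int)
    ind = pd.DataFrame(
        rows,
        index=tf_names or [f"T{i}" for i in range(rows.shape[0])],
        columns=range(1, rows.shape[1] + 1),
    )
    return TFBinaryMatrix(indicator=ind, fold_threshold=2.0, min_ne=0.5, dropped=[])


def brute_force_unique(rows, max_k):
    """Independent exhaustive oracle: all subsets, AND, sum == 1, then
    minimality by pairwise subset comparison (no pruning shortcuts)."""
    names = list(rows.index)
    uniq = []
    for k in range(1, max_k + 1):
        for combo in combinations(names, k):
            pattern = np.ones(rows.shape[1], dtype=bool)
            for t in combo:
                pattern &= rows.loc[t].to_numpy(dtype=bool)
            if pattern.sum() == 1:
                uniq.append((frozenset(combo), int(rows.columns[pattern.argmax()])))
    minimal = []
    for cset, cluster in uniq:
        if not any(o < cset for o, _ in uniq):
            minimal.append((cset, cluster))
    return set(minimal)


class TestBinarize:
    def test_threshold_arithmetic(self):
        prof = profile_from([[4.0, 0.1, 0.1]], ["T0"])
        bm = rs.binarize(prof, GenePanel("tf", ("T0",), "tf"))
        # cross-cluster mean 1.4; 4.0 > 0.5 and > 2.8 -> 1; others 0
        assert bm.indicator.loc["T0"].tolist() == [1, 0, 0]

    def test_uniform_tf_dropped(self):
        prof = profile_from([[2.0, 2.0, 2.0], [4.0, 0.1, 0.1]], ["T0", "T1"])
        bm = rs.binarize(prof, GenePanel("tf", ("T0", "T1"), "tf"))
        assert bm.dropped == ["T0"]
        assert list(bm.indicator.index) == ["T1"]

    def test_rows_have_one_and_zero(self, truth_profile, panels):
        bm = rs.binarize(truth_profile, panels["tf"])
        s = bm.indicator.sum(axis=1)
        assert ((s > 0) & (s < bm.indicator.shape[1])).all()

    def test_planted_patterns_recovered_exactly(self, truth_profile, panels, desk_sim):
        _, _, truth = desk_sim
        bm = rs.binarize(truth_profile, panels["tf"])
        # every member of a planted combination is on in its target cluster
        for cluster, tfs in truth.combo_map.items():
            for t in tfs:
                assert bm.indicator.loc[t, cluster] == 1
            # the AND of the members is exactly the target cluster
            pattern = np.ones(bm.indicator.shape[1], dtype=bool)
            for t in tfs:
                pattern &= bm.indicator.loc[t].to_numpy(dtype=bool)
            assert pattern.sum() == 1
            assert int(bm.indicator.columns[pattern.argmax()]) == cluster

    def test_empty_panel_raises(self, truth_profile):
        with pytest.raises(TFComboError):
            rs.binarize(truth_profile, GenePanel("tf", ("Nope",), "tf"))


class TestUniqueCombos:
    def test_hand_enumerable_three_tfs(self):
        bm = bm_from([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        recs = rs.unique_combos(bm, max_k=3)
        got = {(frozenset(r.tfs), r.cluster) for r in recs}
        assert got == {
            (frozenset({"T0", "T1"}), 2),
            (frozenset({"T0", "T2"}), 1),
            (frozenset({"T1", "T2"}), 3),
        }

    def test_singleton_minimality(self):
        bm = bm_from([[0, 1, 0], [1, 1, 0]])
        recs = rs.unique_combos(bm, max_k=2)
        got = {(frozenset(r.tfs), r.cluster) for r in recs}
        assert (frozenset({"T0"}), 2) in got
        # no superset of the singleton reported for cluster 2
        assert not any(len(c) > 1 and cl == 2 for c, cl in got)

    def test_pattern_sum_invariant(self, truth_profile, panels):
        bm = rs.binarize(truth_profile, panels["tf"])
        for r in rs.unique_combos(bm, max_k=3):
            pattern = np.ones(bm.indicator.shape[1], dtype=bool)
            for t in r.tfs:
                pattern &= bm.indicator.loc[t].to_numpy(dtype=bool)
            assert pattern.sum() == 1

    def test_row_and_column_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 2, size=(8, 5))
        rows[rows.sum(axis=1) == 0, 0] = 1
        rows[rows.sum(axis=1) == 5, 0] = 0
        bm = bm_from(rows)
        base = {(frozenset(r.tfs), r.cluster) for r in rs.unique_combos(bm, max_k=3)}
        perm = rng.permutation(8)
        ind = bm.indicator.iloc[perm, rng.permutation(5)]
        bm2 = TFBinaryMatrix(indicator=ind, fold_threshold=2.0, min_ne=0.5, dropped=[])
        got = {(frozenset(r.tfs), int(r.cluster)) for r in rs.unique_combos(bm2, max_k=3)}
        assert got == base

    def test_matches_bruteforce_oracle_hypothesis(self):
        from hypothesis import given, settings, strategies as st
        from hypothesis.extra.numpy import arrays

        @settings(max_examples=60, deadline=None, derandomize=True)
        @given(arrays(np.int8, (6, 4), elements=st.integers(0, 1)))
        def check(rows):
            keep = (rows.sum(axis=1) > 0) & (rows.sum(axis=1) < 4)
            if not keep.any():
                return
            bm = bm_from(rows[keep], tf_names=[f"T{i}" for i in np.flatnonzero(keep)])
            got = {(frozenset(r.tfs), r.cluster) for r in rs.unique_combos(bm, max_k=3)}
            assert got == brute_force_unique(bm.indicator, max_k=3)

        check()

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 2, size=(12, 6))
        keep = (rows.sum(axis=1) > 0) & (rows.sum(axis=1) < 6)
        bm = bm_from(rows[keep], tf_names=[f"T{i}" for i in np.flatnonzero(keep)])
        got = {(frozenset(r.tfs), r.cluster) for r in rs.unique_combos(bm, max_k=3)}
        assert got == brute_force_unique(bm.indicator, max_k=3)


class TestCrossReference:
    def test_intersection_contract(self):
        # T0 unique at the strict 2x fold (only cluster 1 clears 2x the row
        # mean 2.675) but at the relaxed 1.5x fold cluster 2 joins the
        # pattern -> no longer unique -> excluded by cross-referencing
        prof = profile_from([[6.0, 4.5, 0.2, 0.2]], ["T0"])
        panel = GenePanel("tf", ("T0",), "tf")
        strict = {(frozenset(r.tfs), r.cluster)
                  for r in rs.unique_combos(rs.binarize(prof, panel, fold=2.0), max_k=2)}
        xref = {(frozenset(r.tfs), r.cluster)
                for r in rs.cross_reference(prof, panel, max_k=2)}
        assert strict == {(frozenset({"T0"}), 1)}
        assert xref == set()

    def test_planted_combos_survive_both_thresholds(self, truth_profile, panels, desk_sim):
        _, _, truth = desk_sim
        recs = rs.cross_reference(truth_profile, panels["tf"], max_k=3)
        got = {(r.cluster, frozenset(r.tfs)) for r in recs}
        want = {(k, frozenset(t)) for k, t in truth.combo_map.items()}
        assert want <= got  # recall 1.0

    def test_bad_threshold_order(self, truth_profile, panels):
        with pytest.raises(TFComboError):
            rs.cross_reference(truth_profile, panels["tf"], fold_strict=1.5,
                               fold_relaxed=2.0)


class TestInteractionAnova:
    def _ne_with_labels(self, X, labels, genes):
        n = len(labels)
        adata = ad.AnnData(
            X=np.asarray(X, dtype=float),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(n)]),
            var=pd.DataFrame(index=genes),
        )
        emb = rs.Embedding(np.zeros((n, 3)), adata.obs_names.tolist(), 0)
        return adata, rs.ClusterResult(labels=np.asarray(labels), embedding=emb)

    def test_identical_group_values_give_p_one(self):
        rng = np.random.default_rng(0)
        block = rng.gamma(2, 1, size=(30, 2))
        X = np.vstack([block, block])  # cluster 2 duplicates cluster 1
        adata, cr = self._ne_with_labels(X, [1] * 30 + [2] * 30, ["Ta", "Tb"])
        combo = TFComboRecord(cluster=1, tfs=("Ta", "Tb"))
        p_focal, _ = rs.interaction_anova(adata, cr, combo)
        assert p_focal == pytest.approx(1.0, abs=1e-6)

    def test_crossing_pattern_detected(self):
        rng = np.random.default_rng(1)
        n = 60
        X = np.empty((2 * n, 2))
        X[:n, 0] = rng.normal(3.0, 0.5, n)   # focal: Ta high, Tb low
        X[:n, 1] = rng.normal(0.5, 0.5, n)
        X[n:, 0] = rng.normal(0.5, 0.5, n)   # other: reversed
        X[n:, 1] = rng.normal(3.0, 0.5, n)
        adata, cr = self._ne_with_labels(X, [1] * n + [2] * n, ["Ta", "Tb"])
        combo = TFComboRecord(cluster=1, tfs=("Ta", "Tb"))
        p_focal, p_between = rs.interaction_anova(adata, cr, combo)
        assert p_focal < 0.05
        assert np.isnan(p_between)  # no non-focal pair exists with K = 2

    def test_single_tf_not_applicable(self, truth_clustered):
        ne_t, crt = truth_clustered
        combo = TFComboRecord(cluster=7, tfs=("Tf01",))
        p_focal, p_between = rs.interaction_anova(ne_t, crt, combo)
        assert np.isnan(p_focal) and np.isnan(p_between)

    def test_planted_combo_focal_p_below_background(self, truth_clustered, desk_sim):
        _, _, truth = desk_sim
        ne_t, crt = truth_clustered
        cluster, tfs = next((k, t) for k, t in truth.combo_map.items() if len(t) == 2)
        combo = TFComboRecord(cluster=cluster, tfs=tfs)
        p_focal, p_between = rs.interaction_anova(ne_t, crt, combo)
        # the planted joint pattern interacts against every other cluster,
        # while among non-focal clusters the interaction is mostly absent
        assert p_focal < 0.1
        assert p_focal < p_between
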