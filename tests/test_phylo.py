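import numpy as np
import pytest

from pokeyrec import phylo
from pokeyrec.core_io import InputError
from pokeyrec.synthetic_data import (
    SimConfig,
    simulate_parent_pools,
    simulate_recombinants,
    pool_to_alignment,
)
from .conftest import make_aln, random_acgt


def random_additive_tree(rng, n):
    """Random caterpillar-ish topology with positive lengths; returns the
    leaf path-distance matrix computed by explicit path sums (oracle)."""
    # build a random binary tree over n leaves as a merge sequence
    nodes = list(range(n))
    parent = {}
    blen = {}
    nxt = n
    order = list(rng.permutation(n))
    active = [order.pop()] if False else list(range(n))
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        for x in (a, b):
            parent[x] = nxt
            blen[x] = float(rng.uniform(0.1, 2.0))
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1

    def path_to_root(x):
        out = {}
        d = 0.0
        while x in parent:
            d += blen[x]
            x = parent[x]
            out[x] = d
        return out

    D = np.zeros((n, n))
    for i in range(n):
        pi = path_to_root(i)
        for j in range(i + 1, n):
            pj = path_to_root(j)
            shared = set(pi) & set(pj)
            d = min(pi[a] + pj[a] for a in shared)
            D[i, j] = D[j, i] = d
    return D


class TestDistances:
    def test_identical_pair_zero_under_every_model(self):
        aln = make_aln({"a": "ACGT" * 10, "b": "ACGT" * 10})
        for model in ("p", "JC69", "K2P"):
            assert phylo.pairwise_distances(aln, model).matrix[0, 1] == 0.0

    def test_jc69_closed_form(self):
        # p = 3/80 = 0.0375 -> d = -(3/4) ln(1 - 0.05)
        aln = make_aln({"a": "A" * 80, "b": "G" * 3 + "A" * 77})
        d = phylo.pairwise_distances(aln, "JC69").matrix[0, 1]
        assert d == pytest.approx(-0.75 * np.log(1 - 0.05), abs=1e-12)

    def test_k2p_with_zero_transversions(self):
        # transitions only (A<->G): K2P reduces to -(1/2) ln(1 - 2P)
        aln = make_aln({"a": "A" * 100, "b": "G" * 10 + "A" * 90})
        d = phylo.pairwise_distances(aln, "K2P").matrix[0, 1]
        assert d == pytest.approx(-0.5 * np.log(1 - 0.2), abs=1e-12)

    def test_saturated_pair_flagged_with_p_fallback(self):
        aln = make_aln({"a": "A" * 10, "b": "C" * 10})
        with pytest.warns(UserWarning):
            dm = phylo.pairwise_distances(aln, "JC69")
        assert dm.saturated == [("a", "b")]
        assert dm.matrix[0, 1] == 1.0  # p-distance fallback

    def test_unknown_model_rejected(self):
        with pytest.raises(InputError):
            phylo.pairwise_distances(make_aln({"a": "AC", "b": "AC"}), "LogDet")


class TestNeighborJoining:
    def test_exact_recovery_of_fixed_tree(self):
        # ((A:1,B:2):1,(C:3,D:4)) path distances
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        t = phylo.nj_tree(phylo.DistanceMatrix(list("ABCD"), D))
        tt = t.tip_tip_distances(list("ABCD"))
        assert np.allclose(np.asarray(tt.data), D)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_recovery_of_random_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        D = random_additive_tree(rng, n)
        labels = [f"L{i:02d}" for i in range(n)]
        t = phylo.nj_tree(phylo.DistanceMatrix(labels, D))
        tt = t.tip_tip_distances(labels)
        assert np.allclose(np.asarray(tt.data), D, atol=1e-9)

    def test_star_distances_resolve_without_error(self):
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        t = phylo.nj_tree(phylo.DistanceMatrix(list("ABCD"), D))
        assert sorted(x.name for x in t.tips()) == list("ABCD")
        assert all((x.length or 0) >= 0 for x in t.traverse())

    def test_leaf_order_invariance(self):
        rng = np.random.default_rng(3)
        D = random_additive_tree(rng, 7)
        labels = [f"L{i}" for i in range(7)]
        t1 = phylo.nj_tree(phylo.DistanceMatrix(labels, D))
        perm = rng.permutation(7)
        t2 = phylo.nj_tree(
            phylo.DistanceMatrix([labels[i] for i in perm], D[np.ix_(perm, perm)])
        )
        d1 = t1.tip_tip_distances(labels)
        d2 = t2.tip_tip_distances(labels)
        assert np.allclose(np.asarray(d1.data), np.asarray(d2.data))

    def test_too_few_taxa(self):
        with pytest.raises(InputError):
            phylo.nj_tree(phylo.DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_newick_round_trip_is_stable(self):
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        t = phylo.nj_tree(phylo.DistanceMatrix(list("ABCD"), D))
        nwk = phylo.tree_to_newick(t)
        again = phylo.tree_to_newick(phylo.newick_to_tree(nwk))
        assert nwk == again


class TestFragmentTrees:
    def test_three_fragments_from_two_breakpoints(self, mosaic_scenario):
        aln, _, _ = mosaic_scenario
        out = phylo.fragment_trees(aln, [540, 820])
        assert [span for span, _ in out] == [(1, 540), (541, 820), (821, 1450)]
        assert all(t is not None for _, t in out)

    def test_no_breakpoints_gives_single_tree(self, mosaic_scenario):
        aln, _, _ = mosaic_scenario
        out = phylo.fragment_trees(aln, [])
        assert len(out) == 1 and out[0][0] == (1, aln.length)

    def test_uninformative_fragment_skipped(self):
        aln = make_aln({"a": "A" * 50 + "ACGTACGTAA" * 5,
                        "b": "A" * 50 + "GCGTACCTAA" * 5,
                        "c": "A" * 50 + "ACGAACGTCA" * 5})
        with pytest.warns(UserWarning):
            out = phylo.fragment_trees(aln, [50])
        assert out[0][1] is None and out[1][1] is not None

    def test_mosaic_clusters_with_each_donor_per_fragment(self):
        cfg = SimConfig(n_parents=4, L=1000, d=0.08, seed=17, alleles_per_parent=2)
        pool, truth = simulate_parent_pools(cfg)
        rec, _ = simulate_recombinants(pool, truth, [("P1_a1", "P2_a1", [500])], seed=3)
        rid = next(iter(rec))
        aln = pool_to_alignment({**pool, **rec})
        for span, donor in (((1, 500), "P1"), ((501, 1000), "P2")):
            idx = np.flatnonzero(
                (aln.column_map >= span[0]) & (aln.column_map <= span[1])
            )
            dm = phylo.pairwise_distances(aln.take_columns(idx))
            i = dm.labels.index(rid)
            dists = {l: dm.matrix[i, j] for j, l in enumerate(dm.labels) if l != rid}
            nearest = min(dists, key=dists.get)
            assert nearest.startswith(donor)


class TestAssignParents:
    def _dms(self, aln, breakpoints):
        out = []
        for span in phylo.fragment_spans(breakpoints, aln.length):
            idx = np.flatnonzero(
                (aln.column_map >= span[0]) & (aln.column_map <= span[1])
            )
            out.append((span, phylo.pairwise_distances(aln.take_columns(idx))))
        return out

    def test_deep_divergence_gives_clean_donor_pair(self):
        cfg = SimConfig(n_parents=4, L=1000, d=0.10, seed=29, alleles_per_parent=2)
        pool, truth = simulate_parent_pools(cfg)
        rec, _ = simulate_recombinants(pool, truth, [("P3_a1", "P1_a1", [480])], seed=5)
        rid = next(iter(rec))
        aln = pool_to_alignment({**pool, **rec})
        groups = {sid: sid.split("_")[0] for sid in pool}
        groups[rid] = "recombinant"
        a = phylo.assign_parents(rid, self._dms(aln, [480]), groups)
        assert a.best_donors() == ["P3", "P1"]
        assert all(m > 0 for m in a.margins)
        assert a.assignment == "P3 : P1"

    def test_equidistant_groups_reported_as_alternatives(self):
        # two donor groups carrying identical sequences: a perfect tie
        base = "ACGT" * 25
        other = "GGTT" * 25
        aln = make_aln({"x1": base, "y1": base, "z1": other, "r": base})
        groups = {"x1": "x", "y1": "y", "z1": "z", "r": "recombinant"}
        a = phylo.assign_parents("r", self._dms(aln, []), groups)
        assert set(a.donors[0]) == {"x", "y"}
        assert a.margins[0] == 0.0
        assert " or " in a.assignment

    def test_no_candidate_groups_is_an_error(self):
        aln = make_aln({"r": "ACGT" * 10, "s": "ACGA" * 10})
        with pytest.raises(InputError):
            phylo.assign_parents(
                "r", self._dms(aln, []), {"r": "recombinant", "s": "ungrouped"}
            )
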