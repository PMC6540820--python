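import itertools
import math
from collections import deque

import dendropy
import numpy as np
import pytest
from scipy import stats as sps

from evescan.association import (
    ai_permutation_test,
    association_index,
    pearson_test,
    reconcile,
    reconcile_significance,
    tanglegram_export,
)
from evescan.io import read_newick
from evescan.simulate import (
    SimConfig,
    codivergence_study_config,
    host_switch_study_config,
    random_yule_tree,
    simulate_tree_pair,
)


class TestPearson:
    def test_perfect_correlation(self):
        res = pearson_test([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p_two_sided < 1e-12

    def test_matches_direct_formula_and_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.3 * x
            res = pearson_test(x, y)
            r_direct = float(np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std()))
            assert res.r == pytest.approx(r_direct, abs=1e-12)
            r_sp, p_sp = sps.pearsonr(x, y)
            assert res.r == pytest.approx(float(r_sp), abs=1e-12)
            assert res.p_two_sided == pytest.approx(float(p_sp), rel=1e-9, abs=1e-12)
            assert res.df == n - 2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 2.0], [1.0, 2.0])


def _exhaustive_ai(tree, states):
    """Independent per-node recomputation from explicit leaf sets."""
    ai = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        tips = [l.taxon.label for l in node.leaf_iter()]
        counts = {}
        for t in tips:
            counts[states[t]] = counts.get(states[t], 0) + 1
        f = max(counts.values()) / len(tips)
        ai += (1 - f) / 2 ** (len(tips) - 1)
    return ai


class TestAssociationIndex:
    def test_hand_derived_values(self):
        mono = read_newick("((A1,A2),(B1,B2));")
        assert association_index(mono, {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}) == 0.0625
        mixed = read_newick("((A1,B1),(A2,B2));")
        assert association_index(mixed, {"A1": "A", "B1": "B", "A2": "A", "B2": "B"}) == 0.5625

    def test_uniform_states_give_zero(self):
        for seed in range(5):
            tree = random_yule_tree(int(np.random.default_rng(seed).integers(3, 20)), seed)
            states = {l.taxon.label: "only" for l in tree.leaf_node_iter()}
            assert association_index(tree, states) == 0.0

    def test_matches_exhaustive_oracle_on_small_trees(self):
        rng = np.random.default_rng(1)
        for seed in range(40):
            n = int(rng.integers(3, 9))
            tree = random_yule_tree(n, seed)
            states = {f"T{i + 1}": f"S{rng.integers(3)}" for i in range(n)}
            assert association_index(tree, states) == pytest.approx(
                _exhaustive_ai(tree, states), abs=1e-12
            )

    def test_invariant_under_child_rotation(self):
        rng = np.random.default_rng(2)
        for seed in range(10):
            tree = random_yule_tree(10, seed)
            states = {f"T{i + 1}": f"S{rng.integers(3)}" for i in range(10)}
            before = association_index(tree, states)
            rotated = tree.clone(depth=1)
            for node in rotated.preorder_node_iter():
                kids = node.child_nodes()
                if len(kids) == 2:
                    node.set_child_nodes([kids[1], kids[0]])
            assert association_index(rotated, states) == pytest.approx(before, abs=1e-12)

    def test_breaking_a_monophyletic_pair_increases_ai(self):
        # swapping two tips of different states across a pure cherry
        # strictly increases the index
        tree = read_newick("(((A1,A2),(B1,B2)),((A3,A4),(B3,B4)));")
        pure = {f"A{i}": "A" for i in range(1, 5)} | {f"B{i}": "B" for i in range(1, 5)}
        base = association_index(tree, pure)
        for a, b in itertools.product(["A1", "A2", "A3", "A4"], ["B1", "B2", "B3", "B4"]):
            swapped = dict(pure)
            swapped[a], swapped[b] = swapped[b], swapped[a]
            assert association_index(tree, swapped) > base

    def test_unlabeled_tip_rejected(self):
        tree = read_newick("((A,B),C);")
        with pytest.raises(ValueError):
            association_index(tree, {"A": "x", "B": "y"})


class TestAiPermutation:
    def test_host_structured_tree_gives_minimal_p(self):
        host, eve, tip_map = simulate_tree_pair(codivergence_study_config(7))
        res = ai_permutation_test(eve, tip_map, n_perm=200, seed=0)
        assert res.p_value == pytest.approx(1 / 201)
        assert res.ai_ratio < 0.2

    def test_degenerate_single_state_rejected(self):
        tree = read_newick("((A,B),C);")
        with pytest.raises(ValueError):
            ai_permutation_test(tree, {"A": "x", "B": "x", "C": "x"}, n_perm=10, seed=0)

    def test_exhaustive_enumeration_matches_permutation_null(self):
        """On a 5-tip tree the permutation null converges to the
        exhaustive distribution over distinct labelings."""
        tree = read_newick("(((a,b),c),(d,e));")
        states = {"a": "X", "b": "X", "c": "Y", "d": "Y", "e": "Y"}
        tips = list(states)
        values = list(states.values())
        exact = [
            _exhaustive_ai(tree, dict(zip(tips, perm)))
            for perm in itertools.permutations(values)
        ]
        res = ai_permutation_test(tree, states, n_perm=4000, seed=1)
        assert res.null_mean == pytest.approx(float(np.mean(exact)), rel=0.05)
        exact_p = (1 + sum(v <= res.ai_observed for v in exact)) / (len(exact) + 1)
        assert res.p_value == pytest.approx(exact_p, abs=0.05)

    def test_random_labels_give_ratio_near_one(self):
        ratios = []
        for seed in range(10):
            tree = random_yule_tree(60, seed)
            rng = np.random.default_rng(seed + 100)
            states = {f"T{i + 1}": f"S{rng.integers(4)}" for i in range(60)}
            res = ai_permutation_test(tree, states, n_perm=200, seed=seed)
            ratios.append(res.ai_ratio)
        assert 0.8 < float(np.median(ratios)) < 1.2


def _bf_depth_tools(tree):
    nodes = list(tree.postorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    desc = [set() for _ in nodes]
    for i, n in enumerate(nodes):
        desc[i].add(i)
        for ch in n.child_nodes():
            desc[i] |= desc[idx[id(ch)]]

    def dist(a, g):
        if g not in desc[a]:
            return None
        dq = deque([(a, 0)])
        while dq:
            cur, d = dq.popleft()
            if cur == g:
                return d
            for ch in nodes[cur].child_nodes():
                dq.append((idx[id(ch)], d + 1))

    return nodes, idx, desc, dist


def brute_force_reconcile_cost(host_tree, eve_tree, tip_to_host):
    """Exhaustive enumeration over all host placements of the internal
    element-tree nodes; events costed per node from the mapping."""
    hn, hidx, desc, dist = _bf_depth_tools(host_tree)
    leafmap = {n.taxon.label: hidx[id(n)] for n in hn if n.is_leaf()}
    pn = list(eve_tree.postorder_node_iter())
    internal = [n for n in pn if not n.is_leaf()]
    fixed = {id(n): leafmap[tip_to_host[n.taxon.label]] for n in pn if n.is_leaf()}
    best = math.inf
    for assign in itertools.product(range(len(hn)), repeat=len(internal)):
        m = dict(fixed)
        m.update({id(n): h for n, h in zip(internal, assign)})
        total = 0
        feasible = True
        for n in internal:
            h = m[id(n)]
            c1, c2 = n.child_nodes()
            g1, g2 = m[id(c1)], m[id(c2)]
            opts = []
            kids = hn[h].child_nodes()
            if len(kids) == 2:
                a, b = hidx[id(kids[0])], hidx[id(kids[1])]
                for x, y in ((g1, g2), (g2, g1)):
                    da, db = dist(a, x), dist(b, y)
                    if da is not None and db is not None:
                        opts.append(da + db)  # co-divergence costs 0
            d1, d2 = dist(h, g1), dist(h, g2)
            if d1 is not None and d2 is not None:
                opts.append(1 + d1 + d2)  # duplication
            for stay, jump in ((g1, g2), (g2, g1)):
                ds = dist(h, stay)
                if ds is not None and jump not in desc[h] and h not in desc[jump]:
                    opts.append(1 + ds)  # host switch
            if not opts:
                feasible = False
                break
            total += min(opts)
            if total >= best:
                feasible = False
                break
        if feasible:
            best = total
    return best


class TestReconcile:
    def test_congruent_pair_costs_zero(self):
        host = read_newick("((A,B),(C,D));")
        eve = read_newick("((a,b),(c,d));")
        res = reconcile(host, eve, {"a": "A", "b": "B", "c": "C", "d": "D"})
        assert res.total_cost == 0
        assert res.counts["codivergence"] == 3
        assert res.counts["failure_to_diverge"] == 0

    def test_regraft_adds_exactly_one_switch(self):
        host = read_newick("((A,B),C);")
        mapping = {"a": "A", "b": "B", "c": "C"}
        assert reconcile(host, read_newick("((a,b),c);"), mapping).total_cost == 0
        res = reconcile(host, read_newick("((a,c),b);"), mapping)
        assert res.total_cost == 1
        assert res.counts["host_switch"] == 1

    def test_matches_brute_force_on_small_trees(self):
        rng = np.random.default_rng(4)
        for seed in range(25):
            nh = int(rng.integers(3, 7))
            ne = int(rng.integers(2, 6))
            host = random_yule_tree(nh, seed, prefix="H")
            eve = random_yule_tree(ne, seed + 500, prefix="e")
            mapping = {f"e{i + 1}": f"H{rng.integers(nh) + 1}" for i in range(ne)}
            res = reconcile(host, eve, mapping)
            assert res.total_cost == brute_force_reconcile_cost(host, eve, mapping)
            implied = (res.counts["duplication"] + res.counts["host_switch"]
                       + res.counts["loss"])
            assert implied == res.total_cost

    def test_invariant_under_eve_child_order(self):
        host = random_yule_tree(6, 9, prefix="H")
        eve = random_yule_tree(6, 10, prefix="e")
        rng = np.random.default_rng(11)
        mapping = {f"e{i + 1}": f"H{rng.integers(6) + 1}" for i in range(6)}
        base = reconcile(host, eve, mapping).total_cost
        swapped = eve.clone(depth=1)
        for node in swapped.preorder_node_iter():
            kids = node.child_nodes()
            if len(kids) == 2:
                node.set_child_nodes([kids[1], kids[0]])
        assert reconcile(host, swapped, mapping).total_cost == base

    def test_unmapped_tip_rejected(self):
        host = read_newick("((A,B),C);")
        eve = read_newick("((a,b),c);")
        with pytest.raises(ValueError):
            reconcile(host, eve, {"a": "A", "b": "B"})


class TestReconcileSignificance:
    def test_single_randomization_p_values(self):
        host = read_newick("((A,B),(C,D));")
        eve = read_newick("((a,b),(c,d));")
        mapping = {"a": "A", "b": "B", "c": "C", "d": "D"}
        p = reconcile_significance(host, eve, mapping, n_rand=1, seed=0)
        assert p in (0.5, 1.0)

    def test_pure_codivergence_is_significant(self):
        for seed in (0, 1, 2):
            host, eve, tip_map = simulate_tree_pair(codivergence_study_config(seed))
            p = reconcile_significance(host, eve, tip_map, n_rand=99, seed=seed)
            assert p <= 0.05

    def test_random_mappings_are_not_systematically_extreme(self):
        """Under the switch regime the observed map is itself a draw
        from the randomization null, so small p-values should be the
        exception, not the rule."""
        pvals = []
        for seed in range(6):
            host, eve, tip_map = simulate_tree_pair(host_switch_study_config(seed))
            pvals.append(reconcile_significance(host, eve, tip_map, n_rand=49, seed=seed))
        assert max(pvals) > 0.1


class TestTreeRegimes:
    def test_codivergence_regime_shows_host_structure(self):
        for seed in (0, 1):
            host, eve, tip_map = simulate_tree_pair(codivergence_study_config(seed))
            res = ai_permutation_test(eve, tip_map, n_perm=100, seed=seed)
            assert res.ai_ratio < 0.2

    def test_switch_regime_erases_host_structure(self):
        ratios = []
        for seed in range(8):
            host, eve, tip_map = simulate_tree_pair(host_switch_study_config(seed))
            if len(set(tip_map.values())) < 2:
                continue
            ratios.append(ai_permutation_test(eve, tip_map, n_perm=100, seed=seed).ai_ratio)
        assert 0.7 < float(np.median(ratios)) < 1.3


class TestTanglegram:
    def test_bundle_roundtrip(self, tmp_path):
        host, eve, tip_map = simulate_tree_pair(SimConfig(tree_n_hosts=6, seed=2))
        paths = tanglegram_export(host, eve, tip_map, tmp_path)
        back_host = read_newick(paths["host"])
        back_eve = read_newick(paths["eve"])
        assert {l.taxon.label for l in back_host.leaf_node_iter()} == {
            l.taxon.label for l in host.leaf_node_iter()
        }
        assert {l.taxon.label for l in back_eve.leaf_node_iter()} == set(tip_map)
        lines = paths["assoc"].read_text().strip().splitlines()
        assert len(lines) == len(tip_map) + 1  # header + one row per tip

    def test_empty_association_rejected(self, tmp_path):
        host = read_newick("((A,B),C);")
        with pytest.raises(ValueError):
            tanglegram_export(host, host, {}, tmp_path)
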