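"""LCA duplication-loss reconciliation against a DP oracle and
birth-death simulations."""

import itertools

import dendropy
import pytest

from grevol.reconcile import STEM, lca_map, reconcile
from grevol.seqio import read_tree
from grevol.simulate import FamilySimConfig, simulate_gene_family

PREFIX = {"A": "A", "B": "B", "C": "C"}
SPECIES_NEWICK = "((A:1,B:1)AB:1,C:2)ABC;"


def dl_cost_oracle(gene_newick, species_tree):
    """Minimum duplication+loss cost by DP over all consistent mappings.

    Independent of the LCA construction: for every gene node and every
    species node, the cheapest embedding cost is computed bottom-up.
    """
    gt = read_tree(gene_newick)
    snodes = list(species_tree.preorder_node_iter())
    sindex = {id(n): i for i, n in enumerate(snodes)}
    parent = [None if n.parent_node is None else sindex[id(n.parent_node)] for n in snodes]
    label = {}
    for i, n in enumerate(snodes):
        label[i] = n.taxon.label if n.taxon else n.label

    def ancestors(i):
        out = []
        while i is not None:
            out.append(i)
            i = parent[i]
        return out

    anc = {i: set(ancestors(i)) for i in range(len(snodes))}

    def dist(hi, lo):
        d = 0
        while lo != hi:
            lo = parent[lo]
            d += 1
        return d

    INF = 10 ** 9

    def solve(node):
        if node.is_leaf():
            sp = node.taxon.label.split("_")[0]
            leaf_i = next(i for i in range(len(snodes)) if label[i] == sp)
            return {i: (0 if i == leaf_i else INF) for i in range(len(snodes))}
        left, right = node.child_nodes()
        cl, cr = solve(left), solve(right)
        out = {}
        for s in range(len(snodes)):
            best = INF
            for sl in range(len(snodes)):
                if cl[sl] >= INF or s not in anc[sl]:
                    continue
                for sr in range(len(snodes)):
                    if cr[sr] >= INF or s not in anc[sr]:
                        continue
                    # duplication unless sl and sr descend through
                    # different children of s (a true speciation at s)
                    s_node = snodes[s]
                    kids = [sindex[id(k)] for k in s_node.child_nodes()]
                    sides = []
                    for sx in (sl, sr):
                        side = next((k for k in kids if k in anc[sx] or sx == k), None)
                        sides.append(side)
                    speciation = (
                        sl != s and sr != s
                        and sides[0] is not None and sides[1] is not None
                        and sides[0] != sides[1]
                    )
                    if speciation:
                        cost = (dist(s, sl) - 1) + (dist(s, sr) - 1)
                    else:
                        cost = 1 + dist(s, sl) + dist(s, sr)  # duplication at s
                    best = min(best, cost + cl[sl] + cr[sr])
            out[s] = best
        return out

    table = solve(gt.seed_node)
    return min(table.values())


def all_gene_trees(n_leaves, species=("A", "B", "C")):
    """All rooted binary topologies with all species labelings."""

    def topologies(leaves):
        if len(leaves) == 1:
            return [leaves[0]]
        out = []
        for i in range(1, len(leaves)):
            for split in itertools.combinations(range(len(leaves)), i):
                if 0 not in split:
                    continue  # fix leaf 0 on the left: avoids mirror duplicates
                left = [leaves[j] for j in split]
                right = [leaves[j] for j in range(len(leaves)) if j not in split]
                for lt in topologies(left):
                    for rt in topologies(right):
                        out.append((lt, rt))
        return out

    def render(t):
        if isinstance(t, str):
            return t
        return f"({render(t[0])},{render(t[1])})"

    for assignment in itertools.product(species, repeat=n_leaves):
        leaves = [f"{sp}_g{i}" for i, sp in enumerate(assignment)]
        for topo in topologies(leaves):
            yield render(topo) + ";"


class TestLcaMap:
    def test_congruent_single_copy_tree_is_isomorphism(self, three_species_tree):
        gt = read_tree("((A_g1,B_g1),C_g1);")
        mapping = lca_map(gt, three_species_tree, PREFIX)
        labels = {}
        for g, s in mapping.items():
            name = g.taxon.label if g.taxon else "internal"
            labels[name] = s.taxon.label if s.taxon else s.label
        assert labels["A_g1"] == "A" and labels["C_g1"] == "C"

    def test_duplicated_family_maps_to_root(self):
        st = read_tree("(A:1,B:1)AB;")
        gt = read_tree("((A_g1,B_g1),(A_g2,B_g2));")
        mapping = lca_map(gt, st, {"A": "A", "B": "B"})
        root = gt.seed_node
        assert mapping[root].label == "AB"
        for child in root.child_nodes():
            assert mapping[child].label == "AB"

    def test_mapping_respects_ancestry(self, three_species_tree, rng):
        for newick in itertools.islice(all_gene_trees(4), 0, 200, 7):
            gt = read_tree(newick)
            mapping = lca_map(gt, three_species_tree, PREFIX)
            for node in gt.preorder_node_iter():
                for child in node.child_nodes():
                    s = mapping[child]
                    anc = set()
                    while s is not None:
                        anc.add(s)
                        s = s.parent_node
                    assert mapping[node] in anc

    def test_non_binary_gene_tree_rejected(self, three_species_tree):
        gt = read_tree("(A_g1,B_g1,C_g1);")
        with pytest.raises(ValueError, match="non-binary"):
            lca_map(gt, three_species_tree, PREFIX)

    def test_unmapped_leaf_rejected(self, three_species_tree):
        gt = read_tree("((A_g1,B_g1),X_g1);")
        with pytest.raises(KeyError):
            lca_map(gt, three_species_tree, PREFIX)


class TestReconcile:
    def test_two_copy_family_one_duplication(self):
        st = read_tree("(A:1,B:1)AB;")
        r = reconcile(read_tree("((A_g1,B_g1),(A_g2,B_g2));"), st, {"A": "A", "B": "B"})
        assert r.n_duplications == 1 and r.n_losses == 0
        assert r.gains[STEM] == 1
        assert r.ancestral_count == {"AB": 2, "A": 2, "B": 2}

    def test_asymmetric_family_one_dup_one_loss(self):
        st = read_tree("(A:1,B:1)AB;")
        r = reconcile(read_tree("(A_g1,(A_g2,B_g1));"), st, {"A": "A", "B": "B"})
        assert r.n_duplications == 1 and r.n_losses == 1
        assert r.dl_cost == 2
        assert r.ancestral_count["B"] == 1

    def test_self_reconciliation_is_event_free(self, three_species_tree):
        r = reconcile(read_tree("((A_g1,B_g1),C_g1);"), three_species_tree, PREFIX)
        assert r.dl_cost == 0
        assert set(r.ancestral_count.values()) == {1}

    def test_dl_cost_matches_oracle_exhaustively(self, three_species_tree):
        checked = 0
        for n in (1, 2, 3, 4, 5):
            step = 1 if n <= 4 else 9  # all instances up to 4 leaves, a
            trees = list(all_gene_trees(n))  # deterministic slice at 5
            for newick in trees[::step]:
                r = reconcile(read_tree(newick), three_species_tree, PREFIX)
                assert r.dl_cost == dl_cost_oracle(newick, three_species_tree), newick
                checked += 1
        assert checked > 3000

    def test_leaf_counts_equal_observed_repertoires(self, three_species_tree):
        for newick in list(all_gene_trees(4))[::5]:
            gt = read_tree(newick)
            r = reconcile(gt, three_species_tree, PREFIX)
            observed = {"A": 0, "B": 0, "C": 0}
            for leaf in gt.leaf_node_iter():
                observed[leaf.taxon.label.split("_")[0]] += 1
            for sp, count in observed.items():
                assert r.ancestral_count[sp] == count, newick


class TestBirthDeathFamilies:
    SPECIES = "((A:0.8,B:0.8)AB:0.5,C:1.3)ABC;"

    def test_no_event_limit_gives_congruent_tree(self):
        cfg = FamilySimConfig(self.SPECIES, 0.0, 0.0, seed=1)
        fam = simulate_gene_family(cfg)
        assert fam.leaf_counts == {"A": 1, "B": 1, "C": 1}
        assert fam.truth.duplications.sum() == 0
        assert fam.truth.losses.sum() == 0
        st = read_tree(self.SPECIES)
        r = reconcile(fam.gene_tree, st, PREFIX)
        assert r.dl_cost == 0

    def test_conservation_identity_on_simulated_families(self):
        st_newick = self.SPECIES
        checked = 0
        for seed in range(200):
            cfg = FamilySimConfig(st_newick, 0.4, 0.2, seed=seed)
            fam = simulate_gene_family(cfg)
            if sum(fam.leaf_counts.values()) < 2:
                continue
            st = read_tree(st_newick)
            try:
                r = reconcile(fam.gene_tree, st, PREFIX)
            except ValueError:
                continue  # single-leaf gene tree: nothing to reconcile
            # identity count(child) = count(parent) + gains - losses within
            # the subtree of the family origin (the origin itself adds the
            # founding lineage)
            labels = {"AB": "ABC", "A": "AB", "B": "AB", "C": "ABC"}
            for child, parent in labels.items():
                expected = r.ancestral_count[parent] + r.gains[child] - r.losses[child]
                if child == r.origin:
                    expected = 1 + r.gains[child] - r.losses[child]
                if r.ancestral_count[child] or r.ancestral_count[parent] or child == r.origin:
                    assert r.ancestral_count[child] == expected
            # parsimony can never exceed the true event count
            true_events = int(fam.truth.duplications.sum() + fam.truth.losses.sum())
            assert r.dl_cost <= true_events
            checked += 1
        assert checked >= 150

    def test_pure_birth_recovers_exact_duplication_count(self):
        st_newick = self.SPECIES
        for seed in range(40):
            cfg = FamilySimConfig(st_newick, 0.5, 0.0, seed=seed)
            fam = simulate_gene_family(cfg)
            st = read_tree(st_newick)
            r = reconcile(fam.gene_tree, st, PREFIX)
            assert r.n_duplications == int(fam.truth.duplications.sum())
            assert r.n_losses == 0

    def test_determinism(self):
        cfg = FamilySimConfig(self.SPECIES, 0.4, 0.2, seed=9)
        a = simulate_gene_family(cfg)
        b = simulate_gene_family(cfg)
        assert a.gene_tree.as_string(schema="newick") == b.gene_tree.as_string(schema="newick")
        assert a.truth.equals(b.truth)

    def test_extinction_is_resampled_or_raises(self):
        cfg = FamilySimConfig("(A:5,B:5)AB;", 0.0, 3.0, seed=2)
        with pytest.raises(RuntimeError):
            simulate_gene_family(
                FamilySimConfig("(A:50,B:50)AB;", 0.0, 5.0, seed=2), max_resamples=3
            )
        del cfg
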