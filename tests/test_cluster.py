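"""p-distances, neighbor joining and bootstrap monophyly support."""

import dendropy
import numpy as np
import pytest

from ndhscan.cluster import (DistanceMatrix, is_clade, monophyly_support,
                             nj_tree, p_distance_matrix,
                             project_to_reference)
from ndhscan.simulate import simulate_gene_copies


def test_p_distance_basic_cases():
    aligned = {"a": "A" * 100, "b": "A" * 100,
               "c": "A" * 95 + "C" * 5}
    d = p_distance_matrix(aligned)
    i, j, k = (d.labels.index(x) for x in "abc")
    assert d.matrix[i, j] == 0.0
    assert d.matrix[i, k] == pytest.approx(0.05)


def test_p_distance_pairwise_deletion():
    aligned = {"a": "A" * 50 + "-" * 50 + "A" * 20,
               "b": "A" * 120,
               "c": "C" * 25 + "A" * 95}
    d = p_distance_matrix(aligned)
    i, k = d.labels.index("a"), d.labels.index("c")
    # comparable columns for (a,c): 70 total minus the 50 gapped = 70; of
    # the first 25 columns only those outside a's gap count as mismatches
    assert d.matrix[i, k] == pytest.approx(25 / 70)


def test_p_distance_matches_recount_oracle():
    rng = np.random.default_rng(0)
    aligned = {f"s{i}": "".join(rng.choice(list("ACGT-"), size=200,
                                           p=[.24, .24, .24, .24, .04]))
               for i in range(5)}
    d = p_distance_matrix(aligned)
    for i, a in enumerate(d.labels):
        for j, b in enumerate(d.labels):
            if i >= j:
                continue
            sa, sb = aligned[a], aligned[b]
            comp = [(x, y) for x, y in zip(sa, sb) if "-" not in (x, y)]
            expect = sum(x != y for x, y in comp) / len(comp)
            assert d.matrix[i, j] == pytest.approx(expect)


def test_p_distance_insufficient_overlap_names_pair():
    aligned = {"a": "A" * 30 + "-" * 70, "b": "-" * 70 + "A" * 30,
               "c": "A" * 100}
    with pytest.raises(ValueError, match="a.*b|b.*a"):
        p_distance_matrix(aligned)


def test_nj_recovers_four_taxon_split():
    d = DistanceMatrix(list("ABCD"), np.array([
        [0.00, 0.02, 0.10, 0.11],
        [0.02, 0.00, 0.10, 0.11],
        [0.10, 0.10, 0.00, 0.03],
        [0.11, 0.11, 0.03, 0.00]]))
    t = nj_tree(d)
    assert is_clade(t, {"A", "B"}) and is_clade(t, {"C", "D"})


def test_nj_three_taxa_closed_form():
    dab, dac, dbc = 0.10, 0.16, 0.14
    d = DistanceMatrix(list("ABC"), np.array([
        [0, dab, dac], [dab, 0, dbc], [dac, dbc, 0]]))
    t = nj_tree(d)
    lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
    assert lengths["A"] == pytest.approx((dab + dac - dbc) / 2)
    assert lengths["B"] == pytest.approx((dab + dbc - dac) / 2)
    assert lengths["C"] == pytest.approx((dac + dbc - dab) / 2)


def _random_additive_matrix(rng, n):
    """Random binary tree with positive branch lengths -> additive matrix."""
    taxa = [f"t{i}" for i in range(n)]
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        rng=__import__("random").Random(int(rng.integers(1 << 30))))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = taxa[i]
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.01, 0.1))
    pdm = tree.phylogenetic_distance_matrix()
    m = np.zeros((n, n))
    tx = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                m[i, j] = m[j, i] = pdm.distance(tx[a], tx[b])
    m = np.minimum(m, 1.0)
    return tree, DistanceMatrix(taxa, m)


def _topologies_agree(t1, t2):
    s1 = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
          for e in t1.preorder_edge_iter()}
    labels = {l.taxon.label for l in t1.leaf_node_iter()}
    s2 = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
          for e in t2.preorder_edge_iter()}

    def norm(splits):
        return {min(f, frozenset(labels - f), key=sorted) for f in splits
                if 1 < len(f) < len(labels) - 1}
    return norm(s1) == norm(s2)


def test_nj_exact_on_additive_matrices():
    """NJ reproduces the generating topology of additive 6-taxon matrices."""
    rng = np.random.default_rng(1)
    for _ in range(10):
        true_tree, d = _random_additive_matrix(rng, 6)
        out = nj_tree(d)
        assert _topologies_agree(true_tree, out)


def test_nj_agrees_with_dendropy_reference_implementation():
    rng = np.random.default_rng(2)
    for _ in range(5):
        _, d = _random_additive_matrix(rng, 7)
        mine = nj_tree(d)
        csv = "," + ",".join(d.labels) + "\n" + "\n".join(
            lab + "," + ",".join(str(x) for x in row)
            for lab, row in zip(d.labels, d.matrix))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv))
        theirs = pdm.nj_tree()
        assert _topologies_agree(mine, theirs)


def test_bootstrap_is_reproducible():
    seqs, mt = simulate_gene_copies(seed=3)
    r1 = monophyly_support(seqs, mt, n_boot=50, seed=9)
    r2 = monophyly_support(seqs, mt, n_boot=50, seed=9)
    assert r1["support"] == r2["support"]


def test_monophyly_group_validation():
    seqs, mt = simulate_gene_copies(seed=4)
    with pytest.raises(ValueError):
        monophyly_support(seqs, {"mt_0"}, n_boot=10, seed=0)
    with pytest.raises(ValueError):
        monophyly_support(seqs, set(seqs), n_boot=10, seed=0)


def test_strong_signal_gives_high_support():
    seqs, mt = simulate_gene_copies(shared_mt_subs=15, seed=5)
    res = monophyly_support(seqs, mt, n_boot=100, seed=5)
    assert res["is_clade"] and res["support"] >= 0.95


def test_no_signal_gives_low_support():
    seqs, mt = simulate_gene_copies(shared_mt_subs=0, noise_subs=4, seed=6)
    res = monophyly_support(seqs, mt, n_boot=100, seed=6)
    assert res["support"] < 0.5


def test_project_to_reference_columns(reference):
    ref = reference.genes["ndhE"].cds
    seqs = {"full": ref, "indel": ref[:100] + ref[103:]}
    proj = project_to_reference(ref, seqs)
    assert len(proj["full"]) == len(ref) == len(proj["indel"])
    assert proj["full"] == ref
    assert proj["indel"].count("-") == 3
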