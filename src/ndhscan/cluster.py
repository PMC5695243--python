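"""Distance-based clustering of plastid and mitochondrial gene copies.

Gene copies are projected onto the reference CDS coordinate frame (introns
and insertions never enter the distance), p-distances are computed with
pairwise deletion of gap/N columns, and an unrooted tree is built with
Saitou-Nei neighbor joining.  Clade support comes from site resampling
(bootstrap over projected columns).  This is the desk-scale stand-in for a
full Bayesian gene-tree analysis: topology-level claims such as "the
mitochondrial copies form a clade" are what it is designed to test.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .align import AlignParams, global_align

MIN_COMPARABLE = 50


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if m.min() < 0 or m.max() > 1:
            raise ValueError("p-distances must lie in [0,1]")
        self.matrix = m


def project_to_reference(ref_cds: str, seqs: dict[str, str],
                         params: AlignParams | None = None) -> dict[str, str]:
    """Project each sequence onto reference CDS columns.

    Output strings all have ``len(ref_cds)`` columns: the query base at each
    reference position (M or X), or '-' where the reference position is
    deleted or unaligned.  Insertions relative to the reference are dropped.
    """
    params = params or AlignParams()
    out = {}
    for label, seq in seqs.items():
        t = global_align(ref_cds, seq, params)
        row = ["-"] * len(ref_cds)
        rpos = 0
        qpos = 0
        for op, n in t.ops:
            if op in "MX":
                for i in range(n):
                    row[rpos + i] = seq[qpos + i]
                rpos += n; qpos += n
            elif op == "D":
                rpos += n
            else:
                qpos += n
        out[label] = "".join(row)
    return out


def p_distance_matrix(aligned: dict[str, str]) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gap/N columns."""
    labels = sorted(aligned)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences")
    ncol = {len(s) for s in aligned.values()}
    if len(ncol) != 1:
        raise ValueError("aligned sequences must have equal length")
    arrs = {k: np.frombuffer(v.encode(), dtype=np.uint8)
            for k, v in aligned.items()}
    gapmask = {k: (a == ord("-")) | (a == ord("N")) for k, a in arrs.items()}
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[labels[i]], arrs[labels[j]]
            ok = ~(gapmask[labels[i]] | gapmask[labels[j]])
            comp = int(ok.sum())
            if comp < MIN_COMPARABLE:
                raise ValueError(
                    f"pair ({labels[i]}, {labels[j]}): only {comp} comparable columns")
            m[i, j] = m[j, i] = np.count_nonzero(a[ok] != b[ok]) / comp
    return DistanceMatrix(labels, m)


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with lexicographic tie-breaking.

    Negative branch-length estimates are clamped to zero.  Returns an
    unrooted dendropy tree.
    """
    labels = list(d.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = {}
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        nodes[lab] = node
    active = list(labels)
    dist = {(a, b): d.matrix[i, j]
            for i, a in enumerate(labels) for j, b in enumerate(labels)}

    def D(a, b):
        return dist[(a, b)] if a != b else 0.0

    cluster_id = 0
    while len(active) > 2:
        r = len(active)
        net = {a: sum(D(a, b) for b in active) for a in active}
        best = None
        for ia in range(r):
            for ib in range(ia + 1, r):
                a, b = active[ia], active[ib]
                q = (r - 2) * D(a, b) - net[a] - net[b]
                key = (q, min(a, b), max(a, b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = D(a, b)
        va = 0.5 * dab + (net[a] - net[b]) / (2 * (r - 2))
        vb = dab - va
        va, vb = max(va, 0.0), max(vb, 0.0)
        new = f"__c{cluster_id}"
        cluster_id += 1
        parent = dendropy.Node()
        na, nb = nodes.pop(a), nodes.pop(b)
        na.edge.length = va
        nb.edge.length = vb
        parent.add_child(na)
        parent.add_child(nb)
        nodes[new] = parent
        for c in active:
            if c in (a, b):
                continue
            dd = 0.5 * (D(a, c) + D(b, c) - dab)
            dist[(new, c)] = dist[(c, new)] = max(dd, 0.0)
        active = [c for c in active if c not in (a, b)] + [new]
    a, b = sorted(active)
    # the last two nodes connect by one edge carrying the full distance;
    # root the dendropy structure at whichever of them is internal
    if nodes[a].is_leaf() and not nodes[b].is_leaf():
        a, b = b, a
    na, nb = nodes.pop(a), nodes.pop(b)
    dab = max(D(a, b), 0.0)
    nb.edge.length = dab
    na.add_child(nb)
    tree.seed_node = na
    tree.is_rooted = False
    return tree


def is_clade(tree: dendropy.Tree, group: set[str]) -> bool:
    """Does ``group`` | complement appear as a bipartition of the tree?"""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if not group < leaves or len(group) < 2:
        raise ValueError("group must be a proper subset with >= 2 members")
    target = frozenset(group)
    comp = frozenset(leaves - group)
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if side == target or side == comp:
            return True
    return False


def monophyly_support(aligned: dict[str, str], group: set[str],
                      n_boot: int = 100, seed: int = 0
                      ) -> dict:
    """Point-tree monophyly plus site-resampled bootstrap support."""
    labels = sorted(aligned)
    if not 1 < len(group) < len(labels):
        raise ValueError("degenerate group size")
    point = nj_tree(p_distance_matrix(aligned))
    clade = is_clade(point, set(group))
    ncol = len(next(iter(aligned.values())))
    cols = {k: np.frombuffer(v.encode(), dtype=np.uint8)
            for k, v in aligned.items()}
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_boot):
        idx = rng.integers(0, ncol, size=ncol)
        resampled = {k: a[idx].tobytes().decode() for k, a in cols.items()}
        try:
            t = nj_tree(p_distance_matrix(resampled))
        except ValueError:
            continue
        if is_clade(t, set(group)):
            hits += 1
    return {"is_clade": clade, "support": hits / n_boot,
            "tree": point}
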