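"""Identity matrices, neighbor-joining trees, bootstrap and grouping.

Candidates are placed among labelled reference enzymes: a percent-identity
matrix over all sequences is turned into distances (``d = 1 - pid/100``),
a neighbor-joining (NJ) tree is built, internal-edge supports are
estimated by resampling alignment columns, and each candidate inherits
the group label of the smallest supported clade that contains it together
with references of a single label.

NJ is deterministic: Q-criterion ties are broken by the lexicographically
smallest pair of cluster labels (a cluster is labelled by its smallest
leaf id), and negative branch lengths are clamped to zero.  Trees are
`skbio.TreeNode` objects, so newick round-trips go through scikit-bio.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from ehmine.alignment import (AlignmentParams, DEFAULT_PARAMS, global_align,
                              percent_identity, percent_identity_cols)


@dataclass
class IdentityMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, diagonal 100, entries in [0, 100]

    def to_distance(self) -> np.ndarray:
        """Distance transform ``d = 1 - pid/100`` (zero diagonal)."""
        return 1.0 - self.matrix / 100.0

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for name, row in zip(self.ids, self.matrix):
                fh.write(name + "\t" + "\t".join(f"{v:.2f}" for v in row) + "\n")


def identity_matrix(ids: list[str], seqs: list[str],
                    params: AlignmentParams = DEFAULT_PARAMS) -> IdentityMatrix:
    """All-against-all percent identity from pairwise global alignments."""
    if len(ids) != len(seqs):
        raise ValueError("ids and sequences differ in length")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in identity matrix input")
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(seqs)
    M = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            # orient each pair by id so the matrix depends only on the
            # (id, sequence) set, not input order: co-optimal alignments
            # are tie-broken asymmetrically, so orientation matters at ties
            if ids[i] <= ids[j]:
                a, b = seqs[i], seqs[j]
            else:
                a, b = seqs[j], seqs[i]
            pid = percent_identity(global_align(a, b, params))
            M[i, j] = M[j, i] = pid
    return IdentityMatrix(list(ids), M)


def msa_identity_matrix(ids: list[str], rows: list[str]) -> IdentityMatrix:
    """Percent identities read off MSA rows (used for bootstrap replicates)."""
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids")
    n = len(rows)
    M = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity_cols(rows[i], rows[j])
            M[i, j] = M[j, i] = pid
    return IdentityMatrix(list(ids), M)


def to_distance(idm: IdentityMatrix) -> np.ndarray:
    return idm.to_distance()


def nj_tree(ids: list[str], dist: np.ndarray) -> TreeNode:
    """Neighbor joining with the Q-criterion.

    Returns an unrooted tree (trifurcating root).  Deterministic: ties in
    Q are broken by the lexicographically smallest (label_i, label_j)
    pair, where a cluster's label is its smallest leaf id; negative
    branch lengths are clamped to 0.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if len(set(ids)) != n:
        raise ValueError("duplicate ids")

    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]
    labels: list[str] = list(ids)  # cluster label = smallest member leaf id
    D = dist.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] <= qmin + 1e-12:
                    la, lb = labels[active[a]], labels[active[b]]
                    key = (min(la, lb), max(la, lb))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        d_ij = sub[a, b]
        li = 0.5 * d_ij + (r[a] - r[b]) / (2 * (m - 2))
        lj = d_ij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_row = 0.5 * (D[i, active] + D[j, active] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        D[k, active] = new_row
        D[active, k] = new_row
        D[k, k] = 0.0
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    # three-way join: l_i = (d_ij + d_ik - d_jk) / 2, cyclically
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = max(length, 0.0)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Nontrivial bipartitions of an unrooted tree, canonicalised.

    Each internal edge splits the leaves in two; the canonical form is
    the side *not* containing the lexicographically smallest leaf.
    """
    names = {t.name for t in tree.tips()}
    anchor = min(names)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(names) - len(side) < 2:
            continue
        if anchor in side:
            side = frozenset(names - side)
        out.add(side)
    return out


def bootstrap_supports(ids: list[str], msa_rows: list[str], n_reps: int = 500,
                       seed: int = 0) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ tree from an MSA with column-resampling bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; each
    replicate is re-reduced to identities, distances and an NJ tree.  The
    support of an internal edge is the percentage of replicate trees that
    contain its bipartition.  Supports are stored on the corresponding
    internal nodes (``node.support``) of the full-data tree.
    """
    if len(msa_rows) < 4:
        raise ValueError("bootstrap supports need at least 4 sequences "
                         "(no internal edges otherwise)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    width = len(msa_rows[0])
    if any(len(r) != width for r in msa_rows):
        raise ValueError("MSA rows differ in length")
    rng = np.random.default_rng(seed)
    base = nj_tree(ids, msa_identity_matrix(ids, msa_rows).to_distance())
    target = bipartitions(base)
    counts = {bp: 0 for bp in target}
    cols = np.array([list(r) for r in msa_rows])  # rows x columns
    for _ in range(n_reps):
        pick = rng.integers(0, width, size=width)
        rep_rows = ["".join(row) for row in cols[:, pick]]
        try:
            rep_tree = nj_tree(ids, msa_identity_matrix(ids, rep_rows).to_distance())
        except ValueError:
            continue  # degenerate replicate (e.g. all-gap pair)
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    _attach_supports(base, supports)
    return base, supports


def _attach_supports(tree: TreeNode, supports: dict[frozenset, float]) -> None:
    names = {t.name for t in tree.tips()}
    anchor = min(names)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(names) - len(side) < 2:
            node.support = None
            continue
        key = frozenset(names - side) if anchor in side else side
        node.support = supports.get(key)


def write_newick(tree: TreeNode) -> str:
    """Serialise with bootstrap supports as internal node labels.

    scikit-bio writes a ``support`` attribute as the internal node label
    when the node is otherwise unnamed, which is exactly the convention
    wanted here.
    """
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    """Parse newick produced by `write_newick`; supports restored from
    internal labels."""
    tree = TreeNode.read(io.StringIO(text), format="newick")
    for node in tree.non_tips(include_self=True):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return tree


@dataclass
class GroupAssignment:
    """Per-candidate phylogenetic group label with supporting references."""

    labels: dict[str, str]                  # candidate id -> group or "ungrouped"
    supporting: dict[str, list[str]]        # candidate id -> reference ids

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tgroup\tsupporting_references\n")
            for cid in sorted(self.labels):
                sup = ",".join(self.supporting.get(cid, [])) or "-"
                fh.write(f"{cid}\t{self.labels[cid]}\t{sup}\n")


def assign_groups(tree: TreeNode, ref_groups: dict[str, str],
                  min_support: float = 50.0) -> GroupAssignment:
    """Label candidates by the smallest supported reference-pure clade.

    ``ref_groups`` maps reference leaf ids to their group labels; all
    other leaves are candidates.  A candidate takes label L iff the
    smallest clade that (a) has bootstrap support >= ``min_support``,
    (b) contains the candidate and at least one reference, contains
    references of label L only.  Mixed-label clades, or no qualifying
    clade, give "ungrouped".
    """
    leaf_names = [t.name for t in tree.tips()]
    refs_in_tree = [n for n in leaf_names if n in ref_groups]
    if not refs_in_tree:
        raise ValueError("tree contains no labelled references")
    candidates = [n for n in leaf_names if n not in ref_groups]
    all_names = set(leaf_names)
    # collect candidate clades: each supported bipartition side
    clades: list[tuple[int, set]] = []
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if len(side) < 2 or len(all_names) - len(side) < 2:
            continue
        support = getattr(node, "support", None)
        if support is None or support < min_support:
            continue
        for group_side in (side, all_names - side):
            clades.append((len(group_side), group_side))
    # deterministic preference among equal-sized clades
    clades.sort(key=lambda x: (x[0], tuple(sorted(x[1]))))
    labels: dict[str, str] = {}
    supporting: dict[str, list[str]] = {}
    for cid in candidates:
        labels[cid] = "ungrouped"
        supporting[cid] = []
        for _, clade in clades:
            if cid not in clade:
                continue
            refs_here = [r for r in refs_in_tree if r in clade]
            if not refs_here:
                continue
            groups_here = {ref_groups[r] for r in refs_here}
            if len(groups_here) == 1:
                labels[cid] = groups_here.pop()
                supporting[cid] = sorted(refs_here)
            break  # smallest qualifying clade decides, pure or mixed
    return GroupAssignment(labels=labels, supporting=supporting)
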