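"""Independent brute-force reference implementations used only by tests.

Each oracle deliberately takes the dumbest correct route (per-base set
intersection, all-pairs union-find, full dynamic-programming tables,
exhaustive enumeration over tree nodes) so that agreement with the package
is evidence, not tautology.
"""

from __future__ import annotations

import dendropy


# --------------------------------------------------------------- intervals

def overlap_per_base(a, b) -> int:
    """Overlap as the size of the per-base position-set intersection."""
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end)))


def screen_all_pairs(repeats, elements, min_overlap_bp=30, min_lod=100,
                     per_element=False):
    """Quadratic all-pairs reference for the TE-CNE screen.

    Returns {repeat index: (overlap_bp, max_lod, sorted element ids)} for
    qualifying repeats, using per-pair arithmetic overlap and the same
    strict thresholds.
    """
    result = {}
    for i, r in enumerate(repeats):
        if not r.is_te:
            continue
        total = 0
        best = 0
        max_lod = 0
        ids = []
        for e in elements:
            if e.lod <= min_lod:
                continue
            if e.interval.chrom != r.interval.chrom:
                continue
            ov = max(
                0,
                min(r.interval.end, e.interval.end)
                - max(r.interval.start, e.interval.start),
            )
            if ov > 0:
                total += ov
                best = max(best, ov)
                max_lod = max(max_lod, e.lod)
                ids.append(e.element_id)
        qualifying = best if per_element else total
        if qualifying > min_overlap_bp:
            result[i] = (
                min(total, r.interval.length),
                max_lod,
                tuple(sorted(ids)),
            )
    return result


# --------------------------------------------------------------- clustering

def cluster_union_find(tecnes, max_gap_bp=600):
    """Partition by union-find over ALL pairs with gap < max_gap_bp.

    Returns a set of frozensets of input indices.
    """
    n = len(tecnes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = tecnes[i], tecnes[j]
            if a.chrom != b.chrom:
                continue
            gap = max(0, max(a.start, b.start) - min(a.end, b.end))
            if gap < max_gap_bp:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return {frozenset(g) for g in groups.values()}


# --------------------------------------------------------------- alignment

def local_affine_score(seq_a, seq_b, match=2.0, mismatch=-3.0,
                       gap_open=-5.0, gap_extend=-2.0):
    """Best local affine-gap alignment score by the full O(n*m*3) DP.

    Gap of length k costs gap_open + k*gap_extend; N matches nothing.
    """
    n, m = len(seq_a), len(seq_b)
    NEG = float("-inf")
    first_gap = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in seq_a
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in seq_b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + first_gap, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + first_gap, F[i - 1][j] + gap_extend)
            a, b = seq_a[i - 1], seq_b[j - 1]
            s = match if (a == b and a != "N") else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# --------------------------------------------------------------- phylogeny

def _subtree_losses(candidate: dendropy.Node, present: set[str]) -> int:
    """Loss events = maximal all-absent subtrees below the candidate."""

    def has_present(node) -> bool:
        if node.is_leaf():
            return node.taxon.label in present
        return any(has_present(c) for c in node.child_nodes())

    losses = 0
    stack = [candidate]
    while stack:
        node = stack.pop()
        for child in node.child_nodes():
            if has_present(child):
                stack.append(child)
            else:
                losses += 1
    return losses


def dollo_exhaustive(tree: dendropy.Tree, present: set[str]):
    """Exhaustively pick the gain node minimizing losses while covering all
    present leaves; returns (node, n_losses)."""
    best = None
    for node in tree.preorder_node_iter():
        leaves = {l.taxon.label for l in node.leaf_iter()}
        if not present <= leaves:
            continue
        losses = _subtree_losses(node, present)
        if best is None or losses < best[1]:
            best = (node, losses)
    return best


def order_by_path_comparison(assignments):
    """Group elements by pairwise ancestor relations computed from explicit
    root paths; returns list of sorted name-lists, oldest group first."""

    def path_to_root(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    paths = {a.element: path_to_root(a.gain_node) for a in assignments}

    def strictly_before(x, y):
        # x's gain node is a proper ancestor of y's
        return paths[x][0] is not paths[y][0] and paths[x][0] in paths[y][1:]

    names = [a.element for a in assignments]
    parent = {n: n for n in names}

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    for i, x in enumerate(names):
        for y in names[i + 1:]:
            if not strictly_before(x, y) and not strictly_before(y, x):
                parent[find(x)] = find(y)
    groups = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)
    ordered = sorted(
        groups.values(),
        key=lambda g: (min(len(paths[n]) for n in g), sorted(g)),
    )
    return [sorted(g) for g in ordered]
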