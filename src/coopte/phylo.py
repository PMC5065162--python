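"""Dating TE integrations from ortholog presence/absence on a species tree.

A TE insertion at an orthologous genomic position is effectively
homoplasy-free: it arises once and can only be lost.  Under that single-gain
(Dollo) model the branch of integration for an element is the most recent
common ancestor of all species carrying the ortholog, and the minimal number
of loss events is the number of maximal all-absent subtrees below that node.

Relative integration order between elements follows from clade nesting: an
element whose gain node is a proper ancestor of another's integrated
earlier.  Elements whose gain nodes are equal or incomparable (neither
contains the other) cannot be ordered from presence data alone and are
reported as tie groups, never silently broken.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import dendropy

from .model import GainAssignment, PresenceMatrix

__all__ = [
    "infer_gain",
    "infer_gains",
    "integration_order",
    "call_presence_from_identity",
]


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _clade_name(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return "+".join(leaves)


def infer_gain(
    presence: Mapping[str, bool],
    tree: dendropy.Tree,
    element: str = "",
) -> GainAssignment:
    """Infer the integration branch of one element under single-gain Dollo.

    Parameters
    ----------
    presence
        Species -> present mapping (one row of a presence matrix).  Species
        must all be leaves of ``tree``; at least one must be present.
    tree
        Rooted species tree (dendropy), unique leaf labels.
    element
        Name carried through to the result.

    Returns a :class:`GainAssignment` whose ``gain_node`` is the MRCA of all
    present species and whose ``n_losses`` is the minimal number of edges
    below it that must be cut to explain every absent descendant.
    """
    leaves = set(_leaf_labels(tree))
    unknown = [s for s in presence if s not in leaves]
    if unknown:
        raise ValueError(
            f"species not in tree: {', '.join(sorted(unknown))}"
        )
    present = sorted(s for s, p in presence.items() if p)
    if not present:
        raise ValueError(f"element {element or '<row>'} absent everywhere")

    present_set = set(present)
    if len(present) == 1:
        gain = next(
            l for l in tree.leaf_node_iter() if l.taxon.label in present_set
        )
    else:
        gain = tree.mrca(taxon_labels=present)

    # bottom-up: count child edges leading to all-absent subtrees, among
    # nodes whose own subtree still carries a presence
    n_losses = 0
    has_present: dict[int, bool] = {}
    for node in gain.postorder_iter():
        if node.is_leaf():
            has_present[id(node)] = node.taxon.label in present_set
        else:
            has_present[id(node)] = any(
                has_present[id(c)] for c in node.child_nodes()
            )
    for node in gain.preorder_iter():
        if not has_present[id(node)]:
            continue
        for child in node.child_nodes():
            if not has_present[id(child)]:
                n_losses += 1
    return GainAssignment(
        element=element,
        clade_name=_clade_name(gain),
        n_losses=n_losses,
        present_species=tuple(present),
        gain_node=gain,
    )


def infer_gains(
    matrix: PresenceMatrix, tree: dendropy.Tree
) -> list[GainAssignment]:
    """Infer the gain branch for every element of a presence matrix."""
    return [infer_gain(matrix.row(e), tree, element=e) for e in matrix.elements]


def _depth(node: dendropy.Node) -> int:
    d = 0
    while node.parent_node is not None:
        node = node.parent_node
        d += 1
    return d


def _is_proper_ancestor(a: dendropy.Node, b: dendropy.Node) -> bool:
    node = b.parent_node
    while node is not None:
        if node is a:
            return True
        node = node.parent_node
    return False


def integration_order(
    assignments: Sequence[GainAssignment],
    tree: dendropy.Tree,
) -> list[list[str]]:
    """Order elements oldest-first by the nesting of their gain clades.

    Element a strictly precedes b iff a's gain node is a proper ancestor of
    b's.  Elements whose gain nodes are equal, or incomparable (sister
    clades), are merged into one tie group; groups are returned oldest
    first, each an alphabetically sorted list of element names.
    """
    n = len(assignments)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    nodes = [a.gain_node for a in assignments]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = nodes[i], nodes[j]
            if a is b:
                union(i, j)
            elif not _is_proper_ancestor(a, b) and not _is_proper_ancestor(b, a):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(
        groups.values(),
        key=lambda idxs: (min(_depth(nodes[i]) for i in idxs),
                          sorted(assignments[i].element for i in idxs)),
    )
    return [sorted(assignments[i].element for i in idxs) for idxs in ordered]


def call_presence_from_identity(
    identities: Mapping[str, float], threshold: float = 60.0
) -> dict[str, bool]:
    """Call an ortholog present when its percent identity reaches a cutoff.

    The cutoff (default 60%) is a pragmatic calling rule for alignments of
    orthologous TE relics; presence is monotone non-increasing in the
    threshold.  Identities must lie in [0, 100].
    """
    for sp, v in identities.items():
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"identity {v} for {sp!r} outside [0, 100]")
    return {sp: v >= threshold for sp, v in identities.items()}
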