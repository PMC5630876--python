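"""Newick parsing/writing and tree surgery on dendropy trees.

All tree-valued functions in the package operate on :class:`dendropy.Tree`
objects.  Tip labels are sequence ids; for gene-family trees the convention
``species@contig`` ties a tip to its species (see :mod:`endoselect.genetree`).

A single branch may be marked as the *foreground* branch for branch-site
tests.  In memory the mark is the ``is_foreground`` attribute on the child
node of the branch; on disk it is the PAML-style ``#1`` suffix on the node
label, which :func:`parse_newick` recognises and strips.
"""

from __future__ import annotations

from collections import Counter

import dendropy

FOREGROUND_SUFFIX = "#1"


def parse_newick(text: str) -> dendropy.Tree:
    """Parse one Newick tree, honouring ``#1`` foreground marks.

    Raises ``ValueError`` on malformed input or duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise ValueError(f"newick parse error: {exc}") from exc
    marked = []
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon is not None else node.label
        if label and label.endswith(FOREGROUND_SUFFIX):
            stripped = label[: -len(FOREGROUND_SUFFIX)]
            if node.taxon is not None:
                node.taxon.label = stripped
            else:
                node.label = stripped
            node.is_foreground = True
            marked.append(node)
    if len(marked) > 1:
        raise ValueError("more than one branch marked as foreground")
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    dupes = [lab for lab, k in Counter(labels).items() if k > 1]
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree, precision: int = 17) -> str:
    """Serialise with ``#1`` appended to the foreground node's label."""
    fg = foreground_node(tree)
    restore = None
    if fg is not None:
        if fg.taxon is not None:
            restore = ("taxon", fg, fg.taxon.label)
            fg.taxon.label = fg.taxon.label + FOREGROUND_SUFFIX
        else:
            restore = ("node", fg, fg.label)
            fg.label = (fg.label or "") + FOREGROUND_SUFFIX
    try:
        text = tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=f".{precision}g",
        ).strip()
    finally:
        if restore is not None:
            kind, node, old = restore
            if kind == "taxon":
                node.taxon.label = old
            else:
                node.label = old
    return text + "\n"


# ---------------------------------------------------------------------------
# Accessors
# ---------------------------------------------------------------------------

def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [l.taxon.label for l in tree.leaf_node_iter()]


def total_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter() if e.tail_node)


def foreground_node(tree: dendropy.Tree):
    hits = [n for n in tree.preorder_node_iter() if getattr(n, "is_foreground", False)]
    if len(hits) > 1:
        raise ValueError("more than one foreground branch")
    return hits[0] if hits else None


def clear_foreground(tree: dendropy.Tree) -> None:
    for n in tree.preorder_node_iter():
        if getattr(n, "is_foreground", False):
            n.is_foreground = False


def path_length(tree: dendropy.Tree, a: str, b: str) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(a)
    tb = tree.taxon_namespace.get_taxon(b)
    return pdm.patristic_distance(ta, tb)


def clone(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep-copy a tree; foreground marks survive via node correspondence."""
    fg = foreground_node(tree)
    fg_leaves = (
        frozenset(l.taxon.label for l in fg.leaf_iter()) if fg is not None else None
    )
    t2 = dendropy.Tree(tree)
    if fg_leaves is not None:
        for n in t2.preorder_node_iter():
            leaves = frozenset(l.taxon.label for l in n.leaf_iter())
            n.is_foreground = leaves == fg_leaves and getattr(fg, "is_foreground", False)
        # keep only the shallowest matching node (child of the marked branch)
        matches = [n for n in t2.preorder_node_iter() if getattr(n, "is_foreground", False)]
        for extra in matches[1:]:
            extra.is_foreground = False
    return t2


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def prune_taxa(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    """Restrict a tree to ``keep``, preserving tip-to-tip path lengths.

    Degree-two nodes created by tip removal are collapsed with their branch
    lengths summed, so patristic distances among kept taxa are unchanged.
    """
    keep = set(keep)
    have = set(tip_labels(tree))
    unknown = keep - have
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")
    t2 = dendropy.Tree(tree)
    t2.retain_taxa_with_labels(sorted(keep))
    # dendropy's retain prunes and suppresses unifurcations (summing lengths);
    # drop a dangling root edge so the result is a clean rooted/unrooted tree
    if t2.seed_node.edge.length is not None and t2.seed_node.parent_node is None:
        t2.seed_node.edge.length = None
    return t2
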