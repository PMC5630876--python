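"""Ortholog extraction from homolog (gene-family) trees.

A homolog tree is a dendropy tree whose tips are contigs labelled
``species@contig``; per-tip aligned-character counts may be supplied as a
mapping used for tie-breaking.  The operations implement the standard
phylogenomic cleaning cascade for RNA-seq ortholog inference:

* spurious long tips are trimmed (absolute or sister-relative length rules),
* same-species monophyletic/paraphyletic tip groups are collapsed to the
  best-supported contig,
* deep paralog stems are cut, splitting the family into subfamilies,
* single-copy ortholog sets are extracted from the rooted tree by resolving
  duplication nodes (species-set overlap between the children), rooting on
  outgroups which are then discarded.

All functions leave their input tree untouched and return new trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy

from .trees import clone, tip_labels


def leaf_species(leaf, species_map: Mapping[str, str] | None = None) -> str:
    label = leaf.taxon.label
    if species_map is not None:
        return species_map[label]
    return label.split("@")[0]


def _chars(label: str, chars: Mapping[str, float] | None) -> float:
    if chars is None:
        return 0.0
    return chars.get(label, 0.0)


# ---------------------------------------------------------------------------
# Tip trimming
# ---------------------------------------------------------------------------

def trim_spurious_tips(
    tree: dendropy.Tree,
    abs_threshold: float = 2.0,
    rel_threshold: float = 10.0,
) -> dendropy.Tree | None:
    """Iteratively drop tips on suspiciously long terminal branches.

    A tip offends when its branch length strictly exceeds ``abs_threshold``,
    or exceeds ``rel_threshold`` times the length of its sister branch (the
    sibling edge at its parent; the shortest sibling under a polytomy).  The
    longest offender is removed first and the rules are re-evaluated until a
    fixed point.  Returns ``None`` when fewer than two tips survive.
    """
    t = clone(tree)
    while True:
        leaves = list(t.leaf_node_iter())
        if len(leaves) < 2:
            return None
        offenders = []
        for leaf in leaves:
            length = leaf.edge.length or 0.0
            parent = leaf.parent_node
            bad = length > abs_threshold
            if not bad and parent is not None:
                sibs = [c for c in parent.child_nodes() if c is not leaf]
                if sibs:
                    sister = min(c.edge.length or 0.0 for c in sibs)
                    bad = length > rel_threshold * sister and length > 0.0
            if bad:
                offenders.append((length, leaf.taxon.label, leaf))
        if not offenders:
            return t
        offenders.sort(key=lambda o: (-o[0], o[1]))
        worst = offenders[0][2]
        t.prune_taxa([worst.taxon], suppress_unifurcations=True)


def collapse_species_repeats(
    tree: dendropy.Tree,
    chars: Mapping[str, float] | None = None,
    species_map: Mapping[str, str] | None = None,
) -> dendropy.Tree:
    """Collapse same-species tip groups (mono- or paraphyletic) to one tip.

    Whenever a tip's sibling subtree contains another tip of the same species,
    only the tip with the most aligned characters is kept (ties break to the
    lexicographically smallest id).  Applied iteratively to a fixed point, this
    removes isoform/splice-variant repeats that form grades as well as clades.
    """
    t = clone(tree)
    changed = True
    while changed:
        changed = False
        leaves = sorted(t.leaf_node_iter(), key=lambda l: l.taxon.label)
        by_label = {l.taxon.label: l for l in leaves}
        for leaf in leaves:
            if leaf.taxon.label not in by_label:
                continue
            parent = leaf.parent_node
            if parent is None:
                continue
            sp = leaf_species(leaf, species_map)
            group = [leaf]
            for sib in parent.child_nodes():
                if sib is leaf:
                    continue
                for other in sib.leaf_iter():
                    if leaf_species(other, species_map) == sp:
                        group.append(other)
            if len(group) < 2:
                continue
            keep = min(
                group, key=lambda l: (-_chars(l.taxon.label, chars), l.taxon.label)
            )
            drop = [l for l in group if l is not keep]
            t.prune_taxa([l.taxon for l in drop], suppress_unifurcations=True)
            changed = True
            break
    return t


# ---------------------------------------------------------------------------
# Deep paralog cutting
# ---------------------------------------------------------------------------

def cut_deep_paralogs(
    tree: dendropy.Tree, threshold: float = 0.5
) -> list[dendropy.Tree]:
    """Sever internal branches longer than ``threshold``.

    Every internal branch with length strictly greater than the threshold is
    cut; the tips of each resulting component with at least two tips are
    extracted as an induced subtree of the original.  Components are returned
    ordered by their smallest tip label.
    """
    cut_edges = set()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None or edge.head_node.is_leaf():
            continue
        if (edge.length or 0.0) > threshold:
            cut_edges.add(edge)
    comp_of: dict = {}
    next_comp = [0]

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            comp_of[node] = 0
        elif node.edge in cut_edges:
            next_comp[0] += 1
            comp_of[node] = next_comp[0]
        else:
            comp_of[node] = comp_of[node.parent_node]
    groups: dict[int, list[str]] = {}
    for leaf in tree.leaf_node_iter():
        groups.setdefault(comp_of[leaf], []).append(leaf.taxon.label)
    out = []
    for labels in groups.values():
        if len(labels) < 2:
            continue
        sub = clone(tree)
        sub.retain_taxa_with_labels(labels)
        out.append(sub)
    out.sort(key=lambda t: min(tip_labels(t)))
    return out


# ---------------------------------------------------------------------------
# RT ortholog pruning
# ---------------------------------------------------------------------------

@dataclass
class OrthologSet:
    """A single-copy mapping species → sequence id, with provenance."""

    species_to_id: dict[str, str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = list(self.species_to_id.values())
        if len(set(ids)) != len(ids):
            raise ValueError("ortholog set contains a repeated sequence id")

    @property
    def species(self) -> set[str]:
        return set(self.species_to_id)

    def __len__(self) -> int:
        return len(self.species_to_id)


def prune_rt_orthologs(
    tree: dendropy.Tree,
    outgroup_species: set[str],
    chars: Mapping[str, float] | None = None,
    species_map: Mapping[str, str] | None = None,
) -> list[OrthologSet]:
    """Extract single-copy ingroup ortholog sets from a gene-family tree.

    The tree is rooted on the outgroup tips (which must be single-copy) and
    traversed root-ward: a node whose children share species is a duplication,
    resolved by keeping the child covering more ingroup species (ties break to
    the larger summed aligned-character count, then the smallest tip label).
    Outgroups are removed from the reported sets.
    """
    out_leaves = [
        l for l in tree.leaf_node_iter() if leaf_species(l, species_map) in outgroup_species
    ]
    if not out_leaves:
        raise ValueError("no outgroup tips present; cannot root")
    seen: dict[str, int] = {}
    for l in out_leaves:
        sp = leaf_species(l, species_map)
        seen[sp] = seen.get(sp, 0) + 1
    dup_out = [sp for sp, k in seen.items() if k > 1]
    if dup_out:
        raise ValueError(f"outgroup species duplicated: {sorted(dup_out)}")

    t = clone(tree)
    anchor_label = sorted(l.taxon.label for l in out_leaves)[0]
    anchor = next(
        l for l in t.leaf_node_iter() if l.taxon.label == anchor_label
    )
    if anchor.parent_node is not None and anchor.parent_node.parent_node is not None:
        t.reroot_at_edge(anchor.edge, update_bipartitions=False)
    out_labels = {l.taxon.label for l in out_leaves}
    ingroup_labels = [lab for lab in tip_labels(t) if lab not in out_labels]
    if len(ingroup_labels) < 1:
        raise ValueError("no ingroup tips after outgroup removal")
    if len(ingroup_labels) >= 2:
        t.retain_taxa_with_labels(ingroup_labels)
        root = t.seed_node
    else:
        root = next(
            l for l in t.leaf_node_iter() if l.taxon.label == ingroup_labels[0]
        )

    def resolve(node):
        if node.is_leaf():
            return [node]
        resolved = [resolve(c) for c in node.child_nodes()]
        spsets = [
            {leaf_species(l, species_map) for l in leaves} for leaves in resolved
        ]
        overlap = False
        for i in range(len(spsets)):
            for j in range(i + 1, len(spsets)):
                if spsets[i] & spsets[j]:
                    overlap = True
        if not overlap:
            return [l for leaves in resolved for l in leaves]
        best = min(
            range(len(resolved)),
            key=lambda i: (
                -len(spsets[i]),
                -sum(_chars(l.taxon.label, chars) for l in resolved[i]),
                min(l.taxon.label for l in resolved[i]),
            ),
        )
        return resolved[best]

    kept = resolve(root)
    mapping = {
        leaf_species(l, species_map): l.taxon.label
        for l in sorted(kept, key=lambda l: l.taxon.label)
    }
    prov = [f"rooted on {anchor_label}", f"outgroups removed: {sorted(out_labels)}"]
    return [OrthologSet(mapping, prov)]


# ---------------------------------------------------------------------------
# Taxon-occupancy filter
# ---------------------------------------------------------------------------

def filter_ortholog_taxa(
    ortholog: OrthologSet | set[str],
    classes: Mapping[str, str],
    required_sisters: set[str] = frozenset(),
    min_species: int = 5,
    min_endo: int = 2,
    min_ecto: int = 2,
) -> bool:
    """Occupancy rule for a candidate ortholog set.

    True iff the set covers at least ``min_species`` species with at least
    ``min_endo`` endothermic and ``min_ecto`` ectothermic members, and every
    required sister taxon is present.  ``classes`` maps species to ``endo`` or
    ``ecto``; an unclassified species raises.
    """
    species = ortholog.species if isinstance(ortholog, OrthologSet) else set(ortholog)
    unclassified = [sp for sp in species if sp not in classes]
    if unclassified:
        raise ValueError(f"unclassified species: {sorted(unclassified)}")
    bad = {sp for sp in species if classes[sp] not in ("endo", "ecto")}
    if bad:
        raise ValueError(f"unknown class for species: {sorted(bad)}")
    n_endo = sum(1 for sp in species if classes[sp] == "endo")
    n_ecto = sum(1 for sp in species if classes[sp] == "ecto")
    return (
        len(species) >= min_species
        and n_endo >= min_endo
        and n_ecto >= min_ecto
        and set(required_sisters) <= species
    )
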