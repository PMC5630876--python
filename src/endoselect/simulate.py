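"""Synthetic data with known truth for every pipeline input.

Generates species trees with a monophyletic endothermic clade, codon
alignments evolved under the same site-class models the scan fits (so
parameter-recovery and test-calibration experiments are exact), gene-family
trees with duplications/losses/spurious tips for the ortholog-pruning rules,
and perturbed alternative alignments plus residue confidences for the two
filtering pipelines.

Every generator takes an explicit ``numpy.random.Generator`` or integer seed
and is bit-reproducible for a fixed seed.  Codon evolution samples child
states from exact transition probabilities (matrix exponentials via the
eigendecomposition) on each branch, so simulation is exact at any branch
length; site classes are drawn i.i.d. per codon, matching the mixture model's
exchangeability assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .codonmodel import (
    CodonModelParams,
    N_STATES,
    SENSE_CODONS,
    build_rate_matrix,
    decompose,
    uniform_frequencies,
)
from .seqio import Alignment, Sequence
from .trees import foreground_node, parse_newick
from .selection import mark_foreground


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """Generating conditions for one synthetic gene.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 8 taxa (2 endothermic), moderately diverged balanced trees, 300
    codons, uniform codon frequencies, transition/transversion ratio 2 and a
    branch-site mixture with mostly purifying sites.
    """

    n_taxa: int = 8
    shape: str = "balanced"  # balanced | pectinate | random
    branch_scale: float = 0.15  # mean branch length, subs/codon
    stem_length: float = 0.4  # length of the (tested) endotherm stem branch
    n_codons: int = 300
    kappa: float = 2.0
    pi: np.ndarray = field(default_factory=uniform_frequencies)
    p0: float = 0.6
    p1: float = 0.25
    omega0: float = 0.2
    omega2: float = 1.0  # 1.0 simulates the null; > 1 simulates selection
    n_endo: int = 2
    seed: int = 0


def simulate_tree(spec: SimulationSpec, rng=None) -> tuple[dendropy.Tree, dict[str, str]]:
    """Random species tree with a monophyletic endothermic clade.

    Returns the tree (foreground branch marked on the endotherm stem) and the
    species -> {endo, ecto} class table.  Branch lengths are exponential with
    mean ``branch_scale``.
    """
    if spec.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if not (2 <= spec.n_endo <= spec.n_taxa - 2):
        raise ValueError("need >= 2 endotherms and >= 2 ectotherms")
    rng = _rng(spec.seed if rng is None else rng)
    names = [f"sp{i + 1:02d}" for i in range(spec.n_taxa)]
    endo = names[: spec.n_endo]
    ecto = names[spec.n_endo :]

    def join(subtrees):
        # sequential pairing => balanced; fold-in => pectinate; random joins
        subtrees = list(subtrees)
        while len(subtrees) > 1:
            if spec.shape == "balanced":
                nxt = []
                for k in range(0, len(subtrees) - 1, 2):
                    nxt.append(f"({subtrees[k]},{subtrees[k + 1]})")
                if len(subtrees) % 2:
                    nxt.append(subtrees[-1])
                subtrees = nxt
            elif spec.shape == "pectinate":
                subtrees = [f"({subtrees[0]},{subtrees[1]})"] + subtrees[2:]
            elif spec.shape == "random":
                i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
                merged = f"({subtrees[i]},{subtrees[j]})"
                subtrees = [
                    s for k, s in enumerate(subtrees) if k not in (i, j)
                ] + [merged]
            else:
                raise ValueError(f"unknown tree shape {spec.shape!r}")
        return subtrees[0]

    newick = f"({join(endo)},{join(ecto)});"
    tree = parse_newick(newick)
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = float(rng.exponential(spec.branch_scale))
    classes = {sp: "endo" for sp in endo} | {sp: "ecto" for sp in ecto}
    tree = mark_foreground(tree, set(endo))
    # the endotherm stem is the branch under test: pinned, so power
    # experiments are not confounded by stem-length variance
    foreground_node(tree).edge.length = float(spec.stem_length)
    return tree, classes


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    spec: SimulationSpec
    site_class: np.ndarray  # class index per codon (0, 1, 2=2a, 3=2b)
    newick: str
    internal_states: dict | None = None


def simulate_codon_alignment(
    tree: dendropy.Tree,
    spec: SimulationSpec,
    rng=None,
    record_internal: bool = False,
) -> tuple[Alignment, SyntheticTruth]:
    """Evolve a codon alignment down ``tree`` under the branch-site mixture.

    A site class is drawn i.i.d. per codon from the model A proportions; each
    site then evolves by sampling from exact transition matrices of its
    class's generator, with the foreground omega switching on the marked
    branch (required whenever ``omega2 != 1``).  The true class per site (and
    optionally all internal node states) is recorded for recovery tests.
    """
    rng = _rng(spec.seed if rng is None else rng)
    params = CodonModelParams(
        "bsA",
        spec.kappa,
        spec.pi,
        {"omega0": spec.omega0, "omega2": spec.omega2, "p0": spec.p0, "p1": spec.p1},
    )
    classes = params.site_classes()
    fg = foreground_node(tree)
    if spec.omega2 != 1.0 and fg is None:
        raise ValueError("omega2 != 1 requires a marked foreground branch")
    props = np.array([c[0] for c in classes])
    props = props / props.sum()
    site_class = rng.choice(len(classes), size=spec.n_codons, p=props)

    decomps = {}
    rates = {}
    for _p, wbg, wfg in classes:
        for w in (wbg, wfg):
            if w not in decomps:
                Q, rate = build_rate_matrix(spec.kappa, w, spec.pi)
                decomps[w] = decompose(Q, spec.pi)
                rates[w] = rate
    sigma = sum(p * rates[wbg] for p, wbg, _ in classes)  # background mixture rate

    root = tree.seed_node
    states: dict[int, np.ndarray] = {
        id(root): rng.choice(N_STATES, size=spec.n_codons, p=spec.pi)
    }
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = (node.edge.length or 0.0) / sigma
        parent_states = states[id(node.parent_node)]
        child = np.empty(spec.n_codons, dtype=np.int64)
        is_fg = node is fg
        for k, (_p, wbg, wfg) in enumerate(classes):
            sites = np.nonzero(site_class == k)[0]
            if sites.size == 0:
                continue
            w = wfg if is_fg else wbg
            P = decomps[w].transition(t)
            P = P / P.sum(axis=1, keepdims=True)
            cum = np.cumsum(P[parent_states[sites]], axis=1)
            u = rng.random(sites.size)
            child[sites] = (cum > u[:, None]).argmax(axis=1)
        states[id(node)] = child

    rows = []
    for leaf in tree.leaf_node_iter():
        codons = "".join(SENSE_CODONS[s] for s in states[id(leaf)])
        rows.append(Sequence(leaf.taxon.label, codons, leaf.taxon.label))
    rows.sort(key=lambda s: s.id)
    aln = Alignment(rows, "dna")
    internal = None
    if record_internal:
        internal = {}
        for k, node in enumerate(
            n for n in tree.postorder_node_iter() if not n.is_leaf()
        ):
            label = node.label if node.label else f"node{k}"
            internal[label] = states[id(node)].copy()
    truth = SyntheticTruth(
        spec,
        site_class,
        tree.as_string(schema="newick"),
        internal_states=internal,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# Gene families
# ---------------------------------------------------------------------------

@dataclass
class GeneFamilyTruth:
    ortholog_tips: set[str]  # single-copy tips expected to survive pruning
    duplicated_clades: list[set[str]]
    spurious_tips: set[str]
    lost_tips: set[str]


def simulate_gene_family(
    species_tree: dendropy.Tree,
    dup_rate: float = 0.5,
    loss_rate: float = 0.1,
    spurious_tip_rate: float = 0.1,
    seed=0,
    deep_paralog_prob: float = 0.5,
) -> tuple[dendropy.Tree, GeneFamilyTruth, dict[str, float]]:
    """Gene-family tree grafted with duplications, losses and spurious tips.

    Tips are labelled ``species@c<k>``; the returned truth records the
    original-copy tips that a correct ortholog-pruning cascade should retain,
    which clades are duplicates, which tips were artificially lengthened
    (length > 2) and which were lost.  Duplicate subtree stems exceed the
    deep-paralog threshold (0.5) with probability ``deep_paralog_prob``.
    The per-tip aligned-character counts used for tie-breaking are returned
    as a mapping (original copies get the largest counts).
    """
    rng = _rng(seed)

    # nested representation: leaf = [label, length]; internal = [children, length]
    def to_nested(node):
        length = node.edge.length or 0.1
        if node.is_leaf():
            return [node.taxon.label + "@c1", length]
        return [[to_nested(c) for c in node.child_nodes()], length]

    def leaves(sub):
        if isinstance(sub[0], str):
            return [sub[0]]
        return [l for c in sub[0] for l in leaves(c)]

    def to_newick(sub):
        if isinstance(sub[0], str):
            return f"{sub[0]}:{sub[1]:.6f}"
        inner = ",".join(to_newick(c) for c in sub[0])
        return f"({inner}):{sub[1]:.6f}"

    root = [
        [to_nested(c) for c in species_tree.seed_node.child_nodes()],
        0.0,
    ]
    copy_count = {lab.split("@")[0]: 1 for lab in leaves(root)}

    import copy as _copy

    def relabel(sub):
        if isinstance(sub[0], str):
            sp = sub[0].split("@")[0]
            copy_count[sp] = copy_count.get(sp, 0) + 1
            sub[0] = f"{sp}@c{copy_count[sp]}"
            return
        for c in sub[0]:
            relabel(c)

    def all_subtrees(sub, acc):
        acc.append(sub)
        if not isinstance(sub[0], str):
            for c in sub[0]:
                all_subtrees(c, acc)
        return acc

    n_dups = int(rng.poisson(dup_rate))
    dup_clades: list[set[str]] = []
    for _ in range(n_dups):
        pool = all_subtrees(root, [])[1:]  # exclude the root itself
        src = pool[int(rng.integers(len(pool)))]
        dup = _copy.deepcopy(src)
        relabel(dup)
        if rng.random() < deep_paralog_prob:
            dup[1] = float(0.55 + rng.exponential(0.3))
        else:
            dup[1] = float(rng.uniform(0.05, 0.4))
        # replace src in place with (src, dup) under a new internal node
        old_len = src[1]
        inner_src = [src[0], old_len * 0.5]
        src[0] = [inner_src, dup]
        src[1] = old_len * 0.5
        dup_clades.append(set(leaves(dup)))

    all_tips = sorted(leaves(root))
    originals = {t for t in all_tips if t.endswith("@c1")}
    lost: set[str] = set()
    for t in all_tips:
        if rng.random() < loss_rate and len(all_tips) - len(lost) > 4:
            lost.add(t)
    if not (originals - lost):  # keep at least one original copy
        lost.discard(sorted(originals)[0])

    tree = parse_newick(to_newick(root)[: to_newick(root).rfind(":")] + ";")
    if lost:
        tree.prune_taxa_with_labels(sorted(lost), suppress_unifurcations=True)

    spurious: set[str] = set()
    for leaf in sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label):
        if rng.random() < spurious_tip_rate:
            leaf.edge.length = float(2.2 + rng.exponential(0.5))
            spurious.add(leaf.taxon.label)

    chars = {}
    for t in all_tips:
        base = 1000 if t.endswith("@c1") else 500
        chars[t] = float(base + rng.integers(0, 100))
    truth = GeneFamilyTruth(
        ortholog_tips=originals - lost - spurious,
        duplicated_clades=dup_clades,
        spurious_tips=spurious,
        lost_tips=lost,
    )
    return tree, truth, chars


# ---------------------------------------------------------------------------
# Alternative alignments and confidences
# ---------------------------------------------------------------------------

def make_alternative_alignments(
    aln: Alignment,
    k: int = 3,
    corruption_frac: float = 0.0,
    seed=0,
) -> tuple[list[Alignment], list[int], np.ndarray]:
    """Perturbed re-alignments of ``aln`` plus residue confidences.

    Produces ``k`` alternatives; in a ``corruption_frac`` subset of columns
    each alternative independently slides one randomly chosen residue out of
    the column (emulating a local alignment ambiguity), so corrupted columns
    lose total concordance while clean columns keep identical residue
    pairings.  Also returns the list of corrupted column indices and a
    per-residue confidence matrix for the masking pipeline: 1.0 for clean
    residues, uniform on [0.3, 0.93] inside corrupted columns.
    """
    if k < 2:
        raise ValueError("need at least 2 alternatives")
    if not (0.0 <= corruption_frac <= 1.0):
        raise ValueError("corruption_frac must lie in [0, 1]")
    rng = _rng(seed)
    ncol = aln.ncol
    n = len(aln)
    candidates = [
        j
        for j in range(ncol)
        if sum(1 for c in aln.column(j) if c != "-") >= 2
    ]
    n_corrupt = int(round(corruption_frac * ncol))
    n_corrupt = min(n_corrupt, len(candidates))
    corrupted = sorted(
        rng.choice(candidates, size=n_corrupt, replace=False).tolist()
    ) if n_corrupt else []

    alternatives = []
    for _copy in range(k):
        rows = [list(s.residues) for s in aln]
        for j in sorted(corrupted, reverse=True):
            present = [i for i in range(n) if rows[i][j] != "-"]
            victim = int(present[int(rng.integers(len(present)))])
            residue = rows[victim][j]
            rows[victim][j] = "-"
            for i in range(n):
                rows[i].insert(j + 1, residue if i == victim else "-")
        alternatives.append(
            Alignment(
                [
                    Sequence(s.id, "".join(rows[i]), s.species)
                    for i, s in enumerate(aln)
                ],
                aln.alphabet,
            )
        )

    conf = np.ones((n, ncol))
    for j in corrupted:
        for i in range(n):
            if aln.sequences[i].residues[j] != "-":
                conf[i, j] = float(rng.uniform(0.3, 0.93))
    return alternatives, list(corrupted), conf
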