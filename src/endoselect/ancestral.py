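"""Marginal ancestral amino-acid reconstruction on a fixed tree.

Empirical-Bayes marginal reconstruction by two-pass pruning over the 20
amino-acid states: a post-order pass computes the conditional likelihood of
the data below each node, a pre-order pass the likelihood of everything
outside, and their product (which carries the stationary frequencies through
the root) gives the posterior state distribution at every internal node and
column.  Gap and ``X`` residues are missing data.

The default substitution model is the Poisson model (equal exchangeabilities
and frequencies), scaled to one expected substitution per unit branch length;
any reversible model can be supplied as an exchangeability matrix plus
frequency vector.  Marginal posteriors of internal nodes are root-placement
invariant for reversible models, so unrooted inputs are handled by treating
their basal node as the root.

The substitution lister compares the maximum-posterior ancestral sequences of
two nodes — here the endotherm ancestor and its closest ectotherm ancestor —
and reports differing columns in reference coordinates (e.g. positions in the
human protein) when a mapping is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .seqio import Alignment

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
N_AA = 20


@dataclass
class AminoAcidModel:
    """Reversible 20-state model: symmetric exchangeabilities + frequencies."""

    exchangeability: np.ndarray  # (20, 20) symmetric, zero diagonal
    frequencies: np.ndarray  # (20,) summing to 1

    @classmethod
    def poisson(cls) -> "AminoAcidModel":
        R = np.ones((N_AA, N_AA)) - np.eye(N_AA)
        return cls(R, np.full(N_AA, 1.0 / N_AA))

    def generator(self) -> np.ndarray:
        pi = self.frequencies
        Q = self.exchangeability * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -float(np.dot(pi, np.diag(Q)))
        return Q / rate

    def transition(self, t: float) -> np.ndarray:
        pi = self.frequencies
        Q = self.generator()
        s = np.sqrt(pi)
        A = (s[:, None] * Q) / s[None, :]
        w, U = np.linalg.eigh(0.5 * (A + A.T))
        P = ((U / s[:, None]) * np.exp(w * t)) @ (U.T * s[None, :])
        return np.maximum(P, 0.0)


@dataclass
class AncestralStates:
    """Posterior state distributions and map states per internal node/column."""

    node_labels: list[str]
    posteriors: np.ndarray  # (n_nodes, n_columns, 20)
    map_states: list[str]  # max-posterior residue strings, '-' where subtree empty
    column_support: np.ndarray  # (n_nodes, n_columns) bool: any data below

    def index_of(self, label: str) -> int:
        try:
            return self.node_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node {label!r}") from None

    def sequence(self, label: str) -> str:
        return self.map_states[self.index_of(label)]


def _encode_tips(aln: Alignment) -> dict[str, np.ndarray]:
    out = {}
    for s in aln:
        M = np.ones((len(s.residues), N_AA))
        for j, c in enumerate(s.residues):
            if c in AA_INDEX:
                M[j] = 0.0
                M[j, AA_INDEX[c]] = 1.0
        out[s.id] = M
    return out


def marginal_asr(
    aln: Alignment,
    tree: dendropy.Tree,
    model: AminoAcidModel | None = None,
) -> AncestralStates:
    """Marginal ancestral reconstruction for every internal node.

    Internal nodes are labelled by their dendropy label when present, else
    assigned ``node<k>`` in post-order.  Posteriors at each node/column sum to
    one; when a node's entire subtree (and the rest of the tree) carries no
    data in a column the posterior falls back to the stationary frequencies.
    """
    if model is None:
        model = AminoAcidModel.poisson()
    pi = model.frequencies
    tips = _encode_tips(aln)
    ncol = aln.ncol
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in tips:
            raise ValueError(f"tip {leaf.taxon.label!r} missing from alignment")

    internal = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    labels = []
    for k, n in enumerate(internal):
        labels.append(n.label if n.label else f"node{k}")

    P_of: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            P_of[id(node)] = model.transition(node.edge.length or 0.0)

    # post-order: conditional likelihood of data below each node
    F: dict[int, np.ndarray] = {}
    has_data: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            F[id(node)] = tips[node.taxon.label]
            has_data[id(node)] = ~np.all(F[id(node)] == 1.0, axis=1)
            continue
        acc = np.ones((ncol, N_AA))
        hd = np.zeros(ncol, dtype=bool)
        for ch in node.child_nodes():
            acc *= F[id(ch)] @ P_of[id(ch)].T
            hd |= has_data[id(ch)]
        mx = acc.max(axis=1, keepdims=True)
        mx[mx == 0] = 1.0
        F[id(node)] = acc / mx  # rescaled; posteriors renormalise anyway
        has_data[id(node)] = hd

    # pre-order: likelihood of everything outside the node's subtree
    U: dict[int, np.ndarray] = {id(tree.seed_node): np.tile(pi, (ncol, 1))}
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            out = U[id(node)].copy()
            for sib in node.child_nodes():
                if sib is ch:
                    continue
                out *= F[id(sib)] @ P_of[id(sib)].T
            res = out @ P_of[id(ch)]
            mx = res.max(axis=1, keepdims=True)
            mx[mx == 0] = 1.0
            U[id(ch)] = res / mx

    posteriors = np.empty((len(internal), ncol, N_AA))
    map_states = []
    support = np.zeros((len(internal), ncol), dtype=bool)
    for k, node in enumerate(internal):
        joint = F[id(node)] * U[id(node)]
        total = joint.sum(axis=1, keepdims=True)
        empty = total[:, 0] == 0
        total[empty] = 1.0
        post = joint / total
        post[empty] = pi
        posteriors[k] = post
        support[k] = has_data[id(node)]
        states = [
            AA_ORDER[int(np.argmax(post[j]))] if support[k, j] else "-"
            for j in range(ncol)
        ]
        map_states.append("".join(states))
    return AncestralStates(labels, posteriors, map_states, support)


@dataclass
class SubstitutionRecord:
    position: int | str  # reference coordinate, or 'col<j>' when unmapped
    column: int
    state_a: str
    state_b: str
    posterior_a: float
    posterior_b: float


def ancestral_diffs(
    states: AncestralStates,
    node_a: str,
    node_b: str,
    ref_map: dict[int, int] | None = None,
) -> tuple[list[SubstitutionRecord], list[int]]:
    """Substitutions between the reconstructed sequences of two nodes.

    Lists every column whose maximum-posterior states differ, translated to
    reference coordinates via ``ref_map`` (column -> reference position);
    unmapped columns are reported as ``col<j>``.  Columns where either node
    has no reconstructed state (no data in its subtree) are skipped and their
    indices returned separately.
    """
    ia, ib = states.index_of(node_a), states.index_of(node_b)
    seq_a, seq_b = states.map_states[ia], states.map_states[ib]
    records: list[SubstitutionRecord] = []
    skipped: list[int] = []
    for j, (a, b) in enumerate(zip(seq_a, seq_b)):
        if a == b:
            continue
        if a == "-" or b == "-":
            skipped.append(j)
            continue
        pos: int | str
        if ref_map is not None and j in ref_map:
            pos = ref_map[j]
        else:
            pos = f"col{j}"
        records.append(
            SubstitutionRecord(
                position=pos,
                column=j,
                state_a=a,
                state_b=b,
                posterior_a=float(states.posteriors[ia, j].max()),
                posterior_b=float(states.posteriors[ib, j].max()),
            )
        )
    return records, skipped


def write_substitution_report(records, handle_or_path) -> None:
    def _write(fh):
        fh.write("position\tcolumn\tstate_a\tstate_b\tposterior_a\tposterior_b\n")
        for r in records:
            fh.write(
                f"{r.position}\t{r.column}\t{r.state_a}\t{r.state_b}"
                f"\t{r.posterior_a:.4f}\t{r.posterior_b:.4f}\n"
            )

    if hasattr(handle_or_path, "write"):
        _write(handle_or_path)
    else:
        with open(handle_or_path, "w") as fh:
            _write(fh)
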