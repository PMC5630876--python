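"""Codon substitution models, pruning likelihood and maximum-likelihood fits.

The models are the classical reversible 61-state codon models used for
dN/dS inference.  Instantaneous rates between codons differing at a single
position are

    q_ij = pi_j                 synonymous transversion
    q_ij = kappa * pi_j         synonymous transition
    q_ij = omega * pi_j         non-synonymous transversion
    q_ij = omega * kappa * pi_j non-synonymous transition

with q_ij = 0 for multi-position changes and the diagonal set so rows sum to
zero.  Generators are scaled so one unit of branch length equals one expected
substitution per codon under the model's site-class mixture evaluated with
background omegas (the bulk of the tree), which keeps branch lengths
comparable between the one-ratio and branch-site fits of the same gene.

Supported models:

* ``M0`` (one-ratio): a single omega shared by all branches and sites.
* ``free_ratio``: one omega per branch.
* ``bsA`` (branch-site model A): four site classes; omega on the designated
  foreground branch may exceed 1 in classes 2a/2b.
* ``bsA_null``: model A with the foreground omega fixed at 1.

Likelihoods are computed by Felsenstein pruning over the 61 sense codons with
per-node rescaling, alignment-column pattern compression and transition
probabilities from the eigendecomposition of the (reversible) generator.
Gap and ambiguous codons are missing data (partial likelihood one over all
states).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .seqio import Alignment, GeneticCode, STANDARD_CODE
from .trees import foreground_node

NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(NT)}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

SENSE_CODONS: list[str] = STANDARD_CODE.sense_codons
N_STATES = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_AA = [STANDARD_CODE.forward[c] for c in SENSE_CODONS]


def _pair_tables():
    ii, jj, ts, syn = [], [], [], []
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if a[k] != b[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            ii.append(i)
            jj.append(j)
            ts.append((a[k], b[k]) in _TRANSITIONS)
            syn.append(_AA[i] == _AA[j])
    return (
        np.array(ii, dtype=np.intp),
        np.array(jj, dtype=np.intp),
        np.array(ts, dtype=bool),
        np.array(syn, dtype=bool),
    )


_PAIR_I, _PAIR_J, _PAIR_TS, _PAIR_SYN = _pair_tables()


# ---------------------------------------------------------------------------
# Codon frequencies
# ---------------------------------------------------------------------------

_FREQ_FLOOR = 1e-8


def uniform_frequencies() -> np.ndarray:
    return np.full(N_STATES, 1.0 / N_STATES)


def _nt_counts(aln: Alignment, per_position: bool) -> np.ndarray:
    counts = np.zeros((3, 4)) if per_position else np.zeros(4)
    for s in aln:
        r = s.residues
        for k in range(0, len(r), 3):
            codon = r[k : k + 3]
            if any(c not in _NT_INDEX for c in codon):
                continue
            for pos, c in enumerate(codon):
                if per_position:
                    counts[pos, _NT_INDEX[c]] += 1
                else:
                    counts[_NT_INDEX[c]] += 1
    return counts


def _freqs_from_nt(ntf) -> np.ndarray:
    pi = np.empty(N_STATES)
    for i, codon in enumerate(SENSE_CODONS):
        p = 1.0
        for pos, c in enumerate(codon):
            p *= ntf[pos][_NT_INDEX[c]] if ntf.ndim == 2 else ntf[_NT_INDEX[c]]
        pi[i] = p
    pi = np.maximum(pi, _FREQ_FLOOR)
    return pi / pi.sum()


def f3x4_frequencies(aln: Alignment) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies.

    Stop codons are excluded and frequencies floored at a tiny positive value
    (absent codons would otherwise break the reversible eigendecomposition);
    the vector is renormalised to sum to one.
    """
    counts = _nt_counts(aln, per_position=True)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return _freqs_from_nt(counts / totals)


def f1x4_frequencies(aln: Alignment) -> np.ndarray:
    counts = _nt_counts(aln, per_position=False)
    total = counts.sum() or 1.0
    return _freqs_from_nt(counts / total)


def empirical_codon_frequencies(aln: Alignment) -> np.ndarray:
    pi = np.zeros(N_STATES)
    for s in aln:
        r = s.residues
        for k in range(0, len(r), 3):
            idx = CODON_INDEX.get(r[k : k + 3])
            if idx is not None:
                pi[idx] += 1
    pi = np.maximum(pi, _FREQ_FLOOR)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Rate matrix and transition probabilities
# ---------------------------------------------------------------------------

def build_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray
) -> tuple[np.ndarray, float]:
    """Unscaled generator Q and its substitution rate ``-sum(pi_i q_ii)``.

    Q is reversible with respect to ``pi`` by construction; rows sum to zero.
    Callers divide by a (possibly mixture-averaged) rate so branch lengths are
    expected substitutions per codon.
    """
    rates = np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_SYN, 1.0, omega)
    Q = np.zeros((N_STATES, N_STATES))
    Q[_PAIR_I, _PAIR_J] = rates * pi[_PAIR_J]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(np.dot(pi, np.diag(Q)))
    return Q, rate


@dataclass
class _Decomp:
    w: np.ndarray
    V: np.ndarray  # U scaled: P(t) = (V * exp(w t)) @ Vinv
    Vinv: np.ndarray

    def transition(self, t: float) -> np.ndarray:
        P = (self.V * np.exp(self.w * t)) @ self.Vinv
        np.maximum(P, 0.0, out=P)
        return P


def decompose(Q: np.ndarray, pi: np.ndarray) -> _Decomp:
    s = np.sqrt(pi)
    A = (s[:, None] * Q) / s[None, :]
    A = 0.5 * (A + A.T)
    w, U = np.linalg.eigh(A)
    V = U / s[:, None]
    Vinv = U.T * s[None, :]
    return _Decomp(w, V, Vinv)


def transition_matrix(
    kappa: float, omega: float, pi: np.ndarray, t: float, scale: float | None = None
) -> np.ndarray:
    """P(t) for a single-omega generator scaled to ``scale`` subs/codon/unit
    (its own rate when ``scale`` is None)."""
    Q, rate = build_rate_matrix(kappa, omega, pi)
    sigma = rate if scale is None else scale
    return decompose(Q, pi).transition(t / sigma)


# ---------------------------------------------------------------------------
# Site-class schemes
# ---------------------------------------------------------------------------

@dataclass
class CodonModelParams:
    """Parameters of a named codon model.

    ``omegas`` holds the model-specific omega parameters: ``{"omega": w}``
    for M0, ``{"omega0": w0, "omega2": w2, "p0": p0, "p1": p1}`` for the
    branch-site models, and per-branch values (keyed by branch id) for the
    free-ratio model.
    """

    model: str
    kappa: float
    pi: np.ndarray
    omegas: dict = field(default_factory=dict)

    def site_classes(self) -> list[tuple[float, float, float]]:
        """(proportion, omega_background, omega_foreground) per class."""
        if self.model == "M0":
            w = self.omegas["omega"]
            return [(1.0, w, w)]
        if self.model in ("bsA", "bsA_null"):
            p0, p1 = self.omegas["p0"], self.omegas["p1"]
            w0 = self.omegas["omega0"]
            w2 = 1.0 if self.model == "bsA_null" else self.omegas["omega2"]
            p2 = max(0.0, 1.0 - p0 - p1)
            denom = p0 + p1
            if denom <= 0:
                p2a = p2b = 0.5 * p2
            else:
                p2a = p2 * p0 / denom
                p2b = p2 * p1 / denom
            return [(p0, w0, w0), (p1, 1.0, 1.0), (p2a, w0, w2), (p2b, 1.0, w2)]
        raise ValueError(f"no site-class scheme for model {self.model!r}")


# ---------------------------------------------------------------------------
# Pruning likelihood engine
# ---------------------------------------------------------------------------

class CodonPruner:
    """Felsenstein pruning over 61 codon states for one alignment + tree.

    The tree's branch lengths are supplied at call time so the same pruner
    serves branch-length optimisation.  Tip codons are encoded once, columns
    compressed to unique patterns with weights.
    """

    def __init__(self, aln: Alignment, tree: dendropy.Tree):
        ids = set(aln.ids)
        # branch-site mixtures share every transition matrix except the
        # foreground edge's across site-class pairs; anchoring the traversal
        # at the foreground node's parent lets one background pass serve two
        # classes (valid for any root placement: each branch's generator is
        # reversible w.r.t. the shared stationary frequencies)
        fg0 = foreground_node(tree)
        if fg0 is not None and fg0.parent_node is not tree.seed_node:
            from .trees import clone as _clone

            tree = _clone(tree)
            fg0 = foreground_node(tree)
            tree.reroot_at_node(fg0.parent_node, update_bipartitions=False)
            tree.suppress_unifurcations()
        tips = [l for l in tree.leaf_node_iter()]
        missing = [l.taxon.label for l in tips if l.taxon.label not in ids]
        if missing:
            raise ValueError(f"tree tips absent from alignment: {sorted(missing)}")
        self.tree = tree
        # postorder node indexing: tips first (alignment-row order irrelevant)
        self.tip_labels = [l.taxon.label for l in tips]
        tip_index = {l.taxon.label: k for k, l in enumerate(tips)}
        post_internal = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
        self.n_tips = len(tips)
        self.n_internal = len(post_internal)
        node_index = dict()
        for k, n in enumerate(post_internal):
            node_index[id(n)] = self.n_tips + k
        for l in tips:
            node_index[id(l)] = tip_index[l.taxon.label]
        # edges: one per non-root node, identified by child node index
        self.edges = []  # (child_idx, is_tip, is_foreground, label)
        self.children: list[list[int]] = [[] for _ in range(self.n_tips + self.n_internal)]
        fg = foreground_node(tree)
        for n in tree.postorder_node_iter():
            if n.parent_node is None:
                self.root_index = node_index[id(n)]
                continue
            ci = node_index[id(n)]
            label = (
                n.taxon.label
                if n.is_leaf()
                else "|".join(sorted(l.taxon.label for l in n.leaf_iter())[:2]) + "..."
            )
            self.edges.append((ci, n.is_leaf(), n is fg, label, n))
            self.children[node_index[id(n.parent_node)]].append(len(self.edges) - 1)
        self.edge_lengths0 = np.array(
            [e[4].edge.length if e[4].edge.length is not None else 0.1 for e in self.edges]
        )
        self.has_foreground = fg is not None

        # encode tips and compress patterns
        ncod = aln.ncodons
        states = np.full((self.n_tips, ncod), -1, dtype=np.int16)
        rows = {s.id: s.residues for s in aln}
        for lab, k in tip_index.items():
            r = rows[lab]
            for j in range(ncod):
                states[k, j] = CODON_INDEX.get(r[3 * j : 3 * j + 3], -1)
        patt, inverse, counts = np.unique(
            states.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patt.T  # (n_tips, n_patterns)
        self.pattern_of_site = inverse.ravel()
        self.weights = counts.astype(float)
        self.n_patterns = self.patterns.shape[1]
        self.n_sites = ncod

    # -- likelihood --------------------------------------------------------
    def _class_site_loglik(
        self, P_of_edge: list[np.ndarray], pi: np.ndarray
    ) -> np.ndarray:
        """Per-pattern log-likelihoods, batched over site classes.

        ``P_of_edge[e]`` has shape (C, 61, 61) with one transition matrix per
        site class; returns an array of shape (C, n_patterns).
        """
        npat = self.n_patterns
        C = P_of_edge[0].shape[0]
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros((C, npat))
        for idx in range(len(self.children)):
            kids = self.children[idx]
            if not kids:
                continue
            acc = np.ones((C, npat, N_STATES))
            for e in kids:
                ci, is_tip, _fg, _lab, _node = self.edges[e]
                P = P_of_edge[e]
                if is_tip:
                    obs = self.patterns[ci]
                    contrib = np.ones((C, npat, N_STATES))
                    known = obs >= 0
                    contrib[:, known, :] = P[:, :, obs[known]].transpose(0, 2, 1)
                else:
                    contrib = np.matmul(partial.pop(ci), P.transpose(0, 2, 1))
                acc *= contrib
            mx = acc.max(axis=2)
            mx[mx == 0] = 1.0
            acc /= mx[:, :, None]
            logscale += np.log(mx)
            partial[idx] = acc
        root = partial[self.root_index]
        return np.log(np.maximum(root @ pi, 1e-300)) + logscale

    def loglik(
        self,
        t: np.ndarray,
        params: CodonModelParams,
        per_branch_omega: np.ndarray | None = None,
        per_site: bool = False,
    ):
        """Total (and optionally per-site) log-likelihood.

        ``t`` is the vector of branch lengths in edge order.  For the
        free-ratio model pass ``per_branch_omega``; for branch-site models the
        tree must carry a foreground mark.
        """
        pi = params.pi
        if params.model == "free_ratio":
            if per_branch_omega is None:
                per_branch_omega = np.array(
                    [params.omegas[lab] for (_c, _it, _fg, lab, _n) in self.edges]
                )
            P_of_edge = []
            for e, (ci, _it, _fg, _lab, _n) in enumerate(self.edges):
                Q, rate = build_rate_matrix(params.kappa, per_branch_omega[e], pi)
                P_of_edge.append(decompose(Q, pi).transition(t[e] / rate)[None, :, :])
            site_ll = self._class_site_loglik(P_of_edge, pi)[0]
            total = float(np.dot(self.weights, site_ll))
            return (total, site_ll[self.pattern_of_site]) if per_site else total

        classes = params.site_classes()
        if params.model in ("bsA", "bsA_null") and not self.has_foreground:
            raise ValueError("branch-site model requires a marked foreground branch")
        # one eigendecomposition per distinct omega
        distinct = {}
        for _p, wbg, wfg in classes:
            for w in (wbg, wfg):
                if w not in distinct:
                    Q, rate = build_rate_matrix(params.kappa, w, pi)
                    distinct[w] = (decompose(Q, pi), rate)
        # scale: expected rate of the background mixture
        sigma = sum(p * distinct[wbg][1] for p, wbg, _ in classes)
        if sigma <= 0:
            sigma = 1.0
        fg_edge = next(
            (e for e, (_c, _it, is_fg, _l, _n) in enumerate(self.edges) if is_fg),
            None,
        )
        # one background pass per distinct background omega; only the
        # foreground edge's transition matrix is swapped per class
        groups: dict[float, list[int]] = {}
        for k, (_p, wbg, _wfg) in enumerate(classes):
            groups.setdefault(wbg, []).append(k)
        per_class_ll = np.empty((len(classes), self.n_patterns))
        for wbg, ks in groups.items():
            dec = distinct[wbg][0]
            P_bg = [dec.transition(te / sigma) for te in t]
            others, fg_child, F, logscale = self._background_pass(P_bg, fg_edge)
            for k in ks:
                wfg = classes[k][2]
                if fg_edge is None or fg_child is None:
                    acc = others
                else:
                    Pfg = distinct[wfg][0].transition(t[fg_edge] / sigma)
                    ci, is_tip = fg_child
                    if is_tip:
                        obs = self.patterns[ci]
                        contrib = np.ones((self.n_patterns, N_STATES))
                        known = obs >= 0
                        contrib[known] = Pfg[:, obs[known]].T
                    else:
                        contrib = F[ci] @ Pfg.T
                    acc = others * contrib
                per_class_ll[k] = (
                    np.log(np.maximum(acc @ pi, 1e-300)) + logscale
                )
        props = np.array([max(p, 0.0) for p, _w, _v in classes])
        props = props / props.sum() if props.sum() > 0 else props
        with np.errstate(divide="ignore"):
            logp = np.where(props > 0, np.log(np.maximum(props, 1e-300)), -np.inf)
        m = per_class_ll.max(axis=0)
        site_ll = m + np.log(
            np.sum(np.exp(per_class_ll - m[None, :] + logp[:, None]), axis=0)
        )
        total = float(np.dot(self.weights, site_ll))
        return (total, site_ll[self.pattern_of_site]) if per_site else total


    def _background_pass(self, P_of_edge: list[np.ndarray], fg_edge: int | None):
        """Down-pass with one (background) generator on every edge.

        Stops short of combining at the root: returns the product of the
        non-foreground root-child contributions, the foreground child's
        identity (node index, is_tip), all internal partials ``F`` and the
        accumulated log-scalers, so callers can recombine the root with a
        different foreground-edge transition matrix per site class.
        """
        npat = self.n_patterns
        F: dict[int, np.ndarray] = {}
        logscale = np.zeros(npat)
        for idx in range(len(self.children)):
            if idx == self.root_index:
                continue
            kids = self.children[idx]
            if not kids:
                continue
            acc = np.ones((npat, N_STATES))
            for e in kids:
                ci, is_tip, _fg, _lab, _node = self.edges[e]
                P = P_of_edge[e]
                if is_tip:
                    obs = self.patterns[ci]
                    contrib = np.ones((npat, N_STATES))
                    known = obs >= 0
                    contrib[known] = P[:, obs[known]].T
                else:
                    contrib = F[ci] @ P.T
                acc *= contrib
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            acc /= mx[:, None]
            logscale += np.log(mx)
            F[idx] = acc
        others = np.ones((npat, N_STATES))
        fg_child = None
        for e in self.children[self.root_index]:
            ci, is_tip, _fg, _lab, _node = self.edges[e]
            if e == fg_edge:
                fg_child = (ci, is_tip)
                continue
            P = P_of_edge[e]
            if is_tip:
                obs = self.patterns[ci]
                contrib = np.ones((npat, N_STATES))
                known = obs >= 0
                contrib[known] = P[:, obs[known]].T
            else:
                contrib = F[ci] @ P.T
            others *= contrib
        mx = others.max(axis=1)
        mx[mx == 0] = 1.0
        others = others / mx[:, None]
        logscale += np.log(mx)
        return others, fg_child, F, logscale

    # -- single-class likelihood with analytic branch-length gradient -------
    def loglik_and_tgrad(
        self, t: np.ndarray, params: CodonModelParams
    ) -> tuple[float, np.ndarray]:
        """(lnL, d lnL / d t_e) for the one-class M0 model.

        Uses the standard inside/outside decomposition: for any edge e with
        child partial F and outside partial U, d lnL_s/dt_e =
        (U . (Q P F)) / (U . (P F)); rescaling factors cancel in the ratio.
        The optimiser needs ~17x fewer likelihood evaluations than numeric
        differentiation over all branch lengths.
        """
        pi = params.pi
        w = params.omegas["omega"]
        Q, rate = build_rate_matrix(params.kappa, w, pi)
        Qs = Q / rate
        dec = decompose(Q, pi)
        npat = self.n_patterns
        P_of_edge = [dec.transition(te / rate) for te in t]

        # down pass, keeping each edge's contribution to its parent
        contrib: list[np.ndarray | None] = [None] * len(self.edges)
        F: dict[int, np.ndarray] = {}
        for idx in range(len(self.children)):
            kids = self.children[idx]
            if not kids:
                continue
            acc = np.ones((npat, N_STATES))
            for e in kids:
                ci, is_tip, _fg, _lab, _node = self.edges[e]
                P = P_of_edge[e]
                if is_tip:
                    obs = self.patterns[ci]
                    c = np.ones((npat, N_STATES))
                    known = obs >= 0
                    c[known] = P[:, obs[known]].T
                else:
                    c = F[ci] @ P.T
                contrib[e] = c
                acc *= c
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            acc /= mx[:, None]
            F[idx] = acc
        # total lnL needs the discarded scalers; redo cheaply via plain loglik
        total = float(
            np.dot(self.weights, self._class_site_loglik(
                [P[None, :, :] for P in P_of_edge], pi)[0])
        )

        # up pass: outside partial at the child end of every edge's tail
        U: dict[int, np.ndarray] = {
            self.root_index: np.broadcast_to(pi, (npat, N_STATES)).copy()
        }
        grad = np.zeros(len(self.edges))
        # process nodes root-down so parents' U exists before children's
        for idx in reversed(range(len(self.children))):
            kids = self.children[idx]
            if not kids or idx not in U:
                continue
            k = len(kids)
            cons = [contrib[e] for e in kids]
            # prefix/suffix products over sibling contributions
            prefix = [None] * (k + 1)
            prefix[0] = np.ones((npat, N_STATES))
            for i in range(k):
                prefix[i + 1] = prefix[i] * cons[i]
            suffix = [None] * (k + 1)
            suffix[k] = np.ones((npat, N_STATES))
            for i in range(k - 1, -1, -1):
                suffix[i] = suffix[i + 1] * cons[i]
            for i, e in enumerate(kids):
                ci, is_tip, _fg, _lab, _node = self.edges[e]
                Uprime = U[idx] * prefix[i] * suffix[i + 1]
                P = P_of_edge[e]
                A = Qs @ P
                if is_tip:
                    obs = self.patterns[ci]
                    dcon = np.zeros((npat, N_STATES))
                    known = obs >= 0
                    dcon[known] = A[:, obs[known]].T
                else:
                    dcon = F[ci] @ A.T
                den = np.einsum("ij,ij->i", Uprime, contrib[e])
                num = np.einsum("ij,ij->i", Uprime, dcon)
                den[den == 0] = 1e-300
                grad[e] = float(np.dot(self.weights, num / den))
                if not is_tip:
                    res = Uprime @ P
                    mx = res.max(axis=1)
                    mx[mx == 0] = 1.0
                    U[ci] = res / mx[:, None]
        return total, grad


def site_log_likelihood(
    aln: Alignment, tree: dendropy.Tree, params: CodonModelParams
) -> tuple[np.ndarray, float]:
    """Per-site log-likelihoods and their total for fixed parameters,
    using the branch lengths stored on the tree."""
    pruner = CodonPruner(aln, tree)
    total, per_site = pruner.loglik(pruner.edge_lengths0, params, per_site=True)
    return per_site, total


# ---------------------------------------------------------------------------
# dN/dS flow decomposition
# ---------------------------------------------------------------------------

def _flow_fractions(kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    """(synonymous flow fraction, total rate) of the unscaled generator."""
    rates = np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_SYN, 1.0, omega)
    flow = rates * pi[_PAIR_J] * pi[_PAIR_I]
    total = flow.sum()
    syn = flow[_PAIR_SYN].sum()
    return syn / total, total


def branch_dn_ds(
    kappa: float, omega: float, pi: np.ndarray, t: float
) -> tuple[float, float]:
    """Per-branch (dN, dS) from the expected substitution flow.

    ``t`` is the branch length in substitutions per codon under the branch's
    own omega.  Synonymous/non-synonymous site proportions follow the neutral
    (omega = 1) flow with the same kappa and frequencies, mirroring the usual
    counting convention of codon-model software.
    """
    fS, _ = _flow_fractions(kappa, omega, pi)
    pS, _ = _flow_fractions(kappa, 1.0, pi)
    dS = t * fS / (3.0 * pS)
    dN = t * (1.0 - fS) / (3.0 * (1.0 - pS))
    return dN, dS


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: str
    lnL: float
    params: CodonModelParams
    branch_table: pd.DataFrame  # branch label, t, omega, dN, dS, foreground
    converged: bool
    start_omega: float
    n_evaluations: int

    @property
    def kappa(self) -> float:
        return self.params.kappa

    @property
    def tree_dS(self) -> float:
        """Synonymous substitutions per synonymous site summed over branches
        (the 'overall dS' of a one-ratio fit)."""
        return float(self.branch_table["dS"].sum())

    @property
    def foreground_dS(self) -> float:
        fg = self.branch_table[self.branch_table["foreground"]]
        if fg.empty:
            raise ValueError("no foreground branch in this fit")
        return float(fg["dS"].iloc[0])

    @property
    def branch_lengths(self) -> np.ndarray:
        return self.branch_table["t"].to_numpy()


_LOG_T_BOUNDS = (np.log(1e-6), np.log(30.0))
_LOG_K_BOUNDS = (np.log(0.02), np.log(100.0))
_LOG_W_BOUNDS = (np.log(1e-4), np.log(50.0))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def fit_model(
    aln: Alignment,
    tree: dendropy.Tree,
    model: str = "M0",
    start_omega: float = 0.5,
    freqs: str | np.ndarray = "f3x4",
    branch_lengths: np.ndarray | None = None,
    kappa0: float = 2.0,
    fix_kappa: float | None = None,
    init: Mapping[str, float] | None = None,
    refit_foreground_branch: bool = True,
    max_iter: int = 500,
) -> FitResult:
    """Maximum-likelihood fit of one codon model.

    For ``M0`` the branch lengths are optimised jointly with kappa and omega.
    For ``free_ratio``, ``bsA`` and ``bsA_null`` the background branch
    lengths are held fixed (pass ``branch_lengths`` from a prior M0 fit, else
    the input tree's lengths are used); the foreground branch length is
    re-optimised inside the branch-site fits unless
    ``refit_foreground_branch=False`` — the M0 estimate conflates foreground
    selection with branch length, and both the alternative and the null free
    it, so the LRT degrees of freedom are unchanged.  Parameters are
    optimised on transformed scales (log kappa, log omega, logit omega0,
    log(omega2 - 1), softmax class weights) with L-BFGS-B; the three-point
    starting-omega grid of the scan protocol is applied by the caller, one
    fit per start.
    """
    pruner = CodonPruner(aln, tree)
    if isinstance(freqs, np.ndarray):
        pi = freqs
    elif freqs == "f3x4":
        pi = f3x4_frequencies(aln)
    elif freqs == "f1x4":
        pi = f1x4_frequencies(aln)
    elif freqs == "uniform":
        pi = uniform_frequencies()
    elif freqs == "f61":
        pi = empirical_codon_frequencies(aln)
    else:
        raise ValueError(f"unknown frequency model {freqs!r}")

    t_fixed = (
        np.asarray(branch_lengths, dtype=float)
        if branch_lengths is not None
        else pruner.edge_lengths0.copy()
    )
    n_edges = len(pruner.edges)
    nev = [0]

    if model == "M0":
        def unpack(theta):
            t = np.exp(theta[:n_edges])
            kappa = float(np.exp(theta[n_edges]))
            omega = float(np.exp(theta[n_edges + 1]))
            return t, CodonModelParams("M0", kappa, pi, {"omega": omega})

        theta0 = np.concatenate(
            [
                np.log(np.clip(t_fixed, 1e-4, 20.0)),
                [np.log(kappa0), np.log(max(start_omega, 1e-3))],
            ]
        )
        bounds = [_LOG_T_BOUNDS] * n_edges + [_LOG_K_BOUNDS, _LOG_W_BOUNDS]
    elif model == "free_ratio":
        koff = 0 if fix_kappa is not None else 1

        def unpack(theta):
            kappa = fix_kappa if fix_kappa is not None else float(np.exp(theta[0]))
            omegas = np.exp(theta[koff:])
            return t_fixed, CodonModelParams("free_ratio", kappa, pi, {}), omegas

        theta0 = np.concatenate(
            [
                [] if fix_kappa is not None else [np.log(kappa0)],
                np.full(n_edges, np.log(max(start_omega, 1e-3))),
            ]
        )
        bounds = ([] if fix_kappa is not None else [_LOG_K_BOUNDS]) + (
            [_LOG_W_BOUNDS] * n_edges
        )
    elif model in ("bsA", "bsA_null"):
        koff = 0 if fix_kappa is not None else 1
        fg_idx = next(
            (e for e, (_c, _it, isfg, _l, _n) in enumerate(pruner.edges) if isfg),
            None,
        )
        free_fg = refit_foreground_branch and fg_idx is not None

        def unpack(theta):
            kappa = fix_kappa if fix_kappa is not None else float(np.exp(theta[0]))
            w0 = float(_sigmoid(theta[koff]))
            w0 = min(max(w0, 1e-6), 1.0 - 1e-9)
            if model == "bsA":
                w2 = 1.0 + float(np.exp(theta[koff + 1]))
                a, b = theta[koff + 2], theta[koff + 3]
            else:
                w2 = 1.0
                a, b = theta[koff + 1], theta[koff + 2]
            ea, eb = np.exp(a), np.exp(b)
            denom = 1.0 + ea + eb
            p0, p1 = float(ea / denom), float(eb / denom)
            t = t_fixed
            if free_fg:
                t = t_fixed.copy()
                t[fg_idx] = float(np.exp(theta[-1]))
            return t, CodonModelParams(
                model, kappa, pi,
                {"omega0": w0, "omega2": w2, "p0": p0, "p1": p1},
            )

        w0_init = float(np.clip(start_omega, 0.05, 0.9))
        a_init, b_init = 0.6, 0.2
        w2_init = max(start_omega, 1.001)
        if init is not None:
            w0_init = float(np.clip(init.get("omega0", w0_init), 1e-4, 1 - 1e-6))
            w2_init = max(float(init.get("omega2", w2_init)), 1.0 + 1e-8)
            p0i = float(np.clip(init.get("p0", 0.45), 1e-5, 1 - 2e-5))
            p1i = float(np.clip(init.get("p1", 0.3), 1e-5, 1 - p0i - 1e-5))
            p2i = max(1.0 - p0i - p1i, 1e-5)
            a_init, b_init = np.log(p0i / p2i), np.log(p1i / p2i)
        logit_w0 = np.log(w0_init / (1.0 - w0_init))
        head = [] if fix_kappa is not None else [np.log(kappa0)]
        head_b = [] if fix_kappa is not None else [_LOG_K_BOUNDS]
        if model == "bsA":
            theta0 = np.array(
                head + [logit_w0, np.log(w2_init - 1.0), a_init, b_init]
            )
            bounds = head_b + [
                (-12.0, 12.0),
                (np.log(1e-8), np.log(60.0)),
                (-12.0, 12.0),
                (-12.0, 12.0),
            ]
        else:
            theta0 = np.array(head + [logit_w0, a_init, b_init])
            bounds = head_b + [(-12.0, 12.0), (-12.0, 12.0), (-12.0, 12.0)]
        if free_fg:
            t_fg0 = float(np.clip(t_fixed[fg_idx], 1e-5, 20.0))
            theta0 = np.append(theta0, np.log(t_fg0))
            bounds = bounds + [_LOG_T_BOUNDS]
    else:
        raise ValueError(f"unknown model {model!r}")

    def objective(theta):
        nev[0] += 1
        if model == "free_ratio":
            t, params, omegas = unpack(theta)
            ll = pruner.loglik(t, params, per_branch_omega=omegas)
        else:
            t, params = unpack(theta)
            ll = pruner.loglik(t, params)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    def objective_m0_grad(theta):
        """Value and gradient: analytic for branch lengths, forward
        differences for the two scalar parameters."""
        nev[0] += 3
        t, params = unpack(theta)
        ll, tgrad = pruner.loglik_and_tgrad(t, params)
        g = np.empty_like(theta)
        g[:n_edges] = tgrad * t  # chain rule through log t
        h = 1e-5
        for j, pos in enumerate((n_edges, n_edges + 1)):
            bumped = theta.copy()
            bumped[pos] += h
            tb, pb = unpack(bumped)
            g[pos] = (pruner.loglik(tb, pb) - ll) / h
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(theta)
        return -ll, -g

    def _run(theta_init):
        if model == "M0":
            return minimize(
                objective_m0_grad,
                theta_init,
                method="L-BFGS-B",
                jac=True,
                bounds=bounds,
                options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-6},
            )
        return minimize(
            objective,
            theta_init,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-6},
        )

    res = _run(theta0)
    # the branch-site likelihood surface has a well-known boundary mode at
    # omega2 = 1; when the primary fit lands near that boundary, restart once
    # from its optimum with omega2 pushed into the selection regime.  The
    # null gets an analogous omega0-shifted restart only when omega0 ended at
    # an extreme (its surface is otherwise unimodal in practice).
    if model == "bsA":
        w2_now = 1.0 + float(np.exp(res.x[koff + 1]))
        if w2_now < 2.0:
            aux = res.x.copy()
            aux[koff + 1] = np.log(3.0)  # omega2 -> 4
            res_aux = _run(aux)
            if res_aux.fun < res.fun:
                res = res_aux
    elif model == "bsA_null":
        w0_now = _sigmoid(res.x[koff])
        if w0_now < 0.02 or w0_now > 0.95:
            aux = res.x.copy()
            aux[koff] = np.log(0.5 / (1 - 0.5))
            res_aux = _run(aux)
            if res_aux.fun < res.fun:
                res = res_aux
    converged = bool(res.success) or res.status == 1  # status 1: iteration cap
    if model == "free_ratio":
        t_hat, params, omegas = unpack(res.x)
        params.omegas = {
            lab: float(w)
            for (_c, _it, _fg, lab, _n), w in zip(pruner.edges, omegas)
        }
        per_branch_w = omegas
    else:
        t_hat, params = unpack(res.x)
        classes = params.site_classes()
        per_branch_w = None

    rows = []
    for e, (ci, _it, is_fg, lab, _n) in enumerate(pruner.edges):
        if model == "free_ratio":
            w_b = float(per_branch_w[e])
        elif model == "M0":
            w_b = params.omegas["omega"]
        else:
            # expected background omega of the mixture on this branch
            w_b = sum(
                p * (wfg if is_fg else wbg) for p, wbg, wfg in classes
            )
        dN, dS = branch_dn_ds(params.kappa, w_b, pi, float(t_hat[e]))
        rows.append(
            {
                "branch": lab,
                "t": float(t_hat[e]),
                "omega": w_b,
                "dN": dN,
                "dS": dS,
                "foreground": bool(is_fg),
            }
        )
    table = pd.DataFrame(rows)
    return FitResult(
        model=model,
        lnL=float(-res.fun),
        params=params,
        branch_table=table,
        converged=converged,
        start_omega=start_omega,
        n_evaluations=nev[0],
    )
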