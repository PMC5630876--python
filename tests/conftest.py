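"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from endoselect.codonmodel import (
    CODON_INDEX,
    N_STATES,
    build_rate_matrix,
    decompose,
)
from endoselect.seqio import Alignment, Sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20160910)


def make_codon_alignment(rows: dict[str, str]) -> Alignment:
    return Alignment(
        [Sequence(k, v, k) for k, v in rows.items()], "dna"
    )


# ---------------------------------------------------------------------------
# Brute-force likelihood oracle: exhaustive enumeration of internal states
# ---------------------------------------------------------------------------

def _P(kappa, omega, pi, t, sigma):
    Q, _rate = build_rate_matrix(kappa, omega, pi)
    return decompose(Q, pi).transition(t / sigma)


def mixture_sigma(kappa, pi, classes):
    """Background-mixture substitution rate, the package's time scale."""
    out = 0.0
    for p, wbg, _wfg in classes:
        _Q, rate = build_rate_matrix(kappa, wbg, pi)
        out += p * rate
    return out


def brute_force_lnL_star3(aln, t_by_tip, kappa, pi, classes, fg_tip=None):
    """Exhaustive-sum likelihood for a 3-taxon star tree.

    ``classes`` is a list of (proportion, omega_bg, omega_fg); the branch to
    ``fg_tip`` (if any) uses the foreground omega.  Enumerates the root state
    explicitly — no pruning.
    """
    sigma = mixture_sigma(kappa, pi, classes)
    ids = aln.ids
    total = 0.0
    for site in range(aln.ncodons):
        obs = {s.id: CODON_INDEX[s.residues[3 * site : 3 * site + 3]] for s in aln}
        site_like = 0.0
        for p, wbg, wfg in classes:
            Ps = {
                tid: _P(kappa, wfg if tid == fg_tip else wbg, pi, t_by_tip[tid], sigma)
                for tid in ids
            }
            class_like = 0.0
            for r in range(N_STATES):
                term = pi[r]
                for tid in ids:
                    term *= Ps[tid][r, obs[tid]]
                class_like += term
            site_like += p * class_like
        total += math.log(site_like)
    return total


def brute_force_lnL_quartet(
    aln, lengths, kappa, pi, classes, fg_edge=None
):
    """Exhaustive-sum likelihood for ((A,B),(C,D)) with named edges.

    ``lengths`` maps edge names {"A","B","C","D","AB","CD"} to branch
    lengths; ``fg_edge`` names the foreground edge.  Sums over the root state
    and the two internal states explicitly (61^3 terms per class per site).
    """
    sigma = mixture_sigma(kappa, pi, classes)
    a, b, c, d = (aln.row(x) for x in ("A", "B", "C", "D"))
    total = 0.0
    for site in range(aln.ncodons):
        oa, ob, oc, od = (
            CODON_INDEX[s.residues[3 * site : 3 * site + 3]] for s in (a, b, c, d)
        )
        site_like = 0.0
        for p, wbg, wfg in classes:
            def om(edge):
                return wfg if edge == fg_edge else wbg

            PA = _P(kappa, om("A"), pi, lengths["A"], sigma)
            PB = _P(kappa, om("B"), pi, lengths["B"], sigma)
            PC = _P(kappa, om("C"), pi, lengths["C"], sigma)
            PD = _P(kappa, om("D"), pi, lengths["D"], sigma)
            PAB = _P(kappa, om("AB"), pi, lengths["AB"], sigma)
            PCD = _P(kappa, om("CD"), pi, lengths["CD"], sigma)
            # vectorised but still the plain triple sum over (root, x, y)
            left = PA[:, oa] * PB[:, ob]  # indexed by x
            right = PC[:, oc] * PD[:, od]  # indexed by y
            class_like = float(pi @ ((PAB @ left) * (PCD @ right)))
            site_like += p * class_like
        total += math.log(site_like)
    return total


def chi2_1df_sf(x: float) -> float:
    """Upper tail of chi-square with 1 df, via the error function."""
    return math.erfc(math.sqrt(x / 2.0))


def hypergeom_fisher_two_sided(table) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration (math.comb)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-12))
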