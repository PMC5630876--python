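"""Branch-site selection scan: tests, multiplicity control and consensus.

The scan protocol for one gene:

1. prune the all-taxa base tree to the species present in the gene,
2. mark the foreground branch — the stem of the endothermic clade (the branch
   above the most recent common ancestor of the surviving endothermic tips;
   genes whose endotherms are not monophyletic in the pruned tree are
   excluded),
3. for each surviving alignment variant (the two filtering pipelines) and
   each starting omega in {0.5, 1, 1.5}, fit branch-site model A and its null
   and form the likelihood-ratio test against chi-square with one degree of
   freedom,
4. Benjamini–Hochberg-adjust the (up to six) p-values *within the gene*, and
5. call the gene selected only when all six adjusted p-values are below
   alpha.  A gene with fewer than six tests (e.g. one pipeline rejected it)
   is reported as untested, not as negative.

Saturation screening uses the one-ratio (overall dS) and free-ratio
(foreground-branch dS) fits: either exceeding 1 flags the gene as potentially
affected by synonymous-site saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .codonmodel import CodonModelParams, FitResult, fit_model
from .seqio import Alignment
from .trees import clear_foreground, clone, foreground_node, prune_taxa, tip_labels

DEFAULT_STARTS = (0.5, 1.0, 1.5)


def branch_site_test(
    aln: Alignment,
    tree: dendropy.Tree,
    start_omega: float = 1.0,
    freqs: str = "f3x4",
    m0: FitResult | None = None,
) -> tuple[FitResult, FitResult, FitResult, float]:
    """One branch-site test on a marked tree: M0 -> (alt, null) -> p.

    Branch lengths and kappa are estimated once under M0 and held fixed for
    the branch-site pair; pass a precomputed ``m0`` to reuse it across the
    starting-omega grid.  Returns (m0, alt, null, p).
    """
    if m0 is None:
        m0 = fit_model(aln, tree, "M0", start_omega=1.0, freqs=freqs)
    alt = fit_model(
        aln, tree, "bsA", start_omega=start_omega, freqs=freqs,
        branch_lengths=m0.branch_lengths, fix_kappa=m0.kappa,
    )
    null = fit_model(
        aln, tree, "bsA_null", start_omega=start_omega, freqs=freqs,
        branch_lengths=m0.branch_lengths, fix_kappa=m0.kappa,
    )
    if alt.lnL < null.lnL:
        # the null optimum is a feasible point of the alternative; refitting
        # from it guarantees the nesting inequality up to machine tolerance
        reseed = fit_model(
            aln, tree, "bsA", start_omega=start_omega, freqs=freqs,
            branch_lengths=m0.branch_lengths, fix_kappa=m0.kappa,
            init=dict(null.params.omegas, omega2=1.0),
        )
        if reseed.lnL > alt.lnL:
            alt = reseed
        if alt.lnL < null.lnL:  # still under by optimiser slop: pin at null
            alt = FitResult(
                model="bsA",
                lnL=null.lnL,
                params=CodonModelParams(
                    "bsA", null.params.kappa, null.params.pi,
                    dict(null.params.omegas, omega2=1.0),
                ),
                branch_table=null.branch_table,
                converged=null.converged,
                start_omega=start_omega,
                n_evaluations=alt.n_evaluations,
            )
    return m0, alt, null, branch_site_lrt(alt, null)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def branch_site_lrt(fit_alt: FitResult, fit_null: FitResult) -> float:
    """LRT p-value comparing branch-site model A to its null.

    The statistic ``2 (lnL_alt - lnL_null)`` is clamped at zero and referred
    to the upper tail of chi-square with one degree of freedom.
    """
    if fit_alt.model != "bsA" or fit_null.model != "bsA_null":
        raise ValueError(
            f"expected (bsA, bsA_null), got ({fit_alt.model}, {fit_null.model})"
        )
    stat = max(0.0, 2.0 * (fit_alt.lnL - fit_null.lnL))
    return float(stats.chi2.sf(stat, df=1))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def consensus_call(adjusted_p, alpha: float = 0.05, n_required: int = 6):
    """All-tests consensus: True iff ``n_required`` adjusted p's are all < alpha.

    Returns ``None`` ("untested") when fewer than ``n_required`` tests are
    available, e.g. because one alignment pipeline rejected the gene.
    """
    p = list(adjusted_p)
    if len(p) < n_required:
        return None
    return bool(all(x < alpha for x in p))


def saturation_screen(one_ratio: FitResult, free_ratio: FitResult) -> bool:
    """Synonymous-site saturation flag.

    True when the one-ratio fit's overall dS exceeds 1, or the free-ratio
    fit's dS on the foreground (endothermic stem) branch exceeds 1.
    """
    fg = free_ratio.branch_table[free_ratio.branch_table["foreground"]]
    if fg.empty:
        raise ValueError("free-ratio fit has no foreground branch")
    return bool(one_ratio.tree_dS > 1.0 or float(fg["dS"].iloc[0]) > 1.0)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Sums hypergeometric probabilities no larger than the observed table's.
    Degenerate margins give p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        import warnings

        warnings.warn("degenerate margin in 2x2 table; p = 1")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def overlap_probability(a: int, b: int, n: int) -> float:
    """Probability of one gene being selected in both lineages independently.

    With ``a`` of ``n`` shared genes selected in one group and ``b`` in the
    other, the independent-overlap probability per gene is ``(a/n) * (b/n)``.
    Reporting layers round to one significant figure.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= a <= n and 0 <= b <= n):
        raise ValueError("counts must lie in [0, n]")
    return (a / n) * (b / n)


def round_to_sig_figs(x: float, sig: int = 1) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


# ---------------------------------------------------------------------------
# Foreground marking
# ---------------------------------------------------------------------------

def mark_foreground(tree: dendropy.Tree, endo_species: set[str]) -> dendropy.Tree:
    """Mark the stem branch of the endothermic clade.

    The branch above the MRCA of the endothermic tips present in the tree is
    marked; raises when the endotherms are not monophyletic (the MRCA then
    subtends ectothermic tips too) — such genes are excluded from the scan.
    """
    present = set(tip_labels(tree)) & set(endo_species)
    if len(present) < 1:
        raise ValueError("no endothermic tips in tree")
    t = clone(tree)
    t.is_rooted = True  # MRCA semantics: treat the seed node as the root
    clear_foreground(t)
    if len(present) == 1:
        mrca = next(
            l for l in t.leaf_node_iter() if l.taxon.label in present
        )
    else:
        mrca = t.mrca(taxon_labels=sorted(present))
    under = {l.taxon.label for l in mrca.leaf_iter()}
    if under != present:
        raise ValueError(
            f"endothermic tips not monophyletic: clade also contains "
            f"{sorted(under - present)}"
        )
    mrca.is_foreground = True
    return t


# ---------------------------------------------------------------------------
# Per-gene scan
# ---------------------------------------------------------------------------

@dataclass
class GeneScanResult:
    """All per-gene evidence: six tests, adjusted p's, consensus, saturation."""

    gene_id: str
    tests: pd.DataFrame  # variant, start_omega, lnL_alt, lnL_null, p_raw, p_adj
    consensus: bool | None
    status: str  # tested | untested | excluded
    reason: str | None = None
    overall_dS: float | None = None
    foreground_dS: float | None = None
    saturated: bool | None = None


def scan_gene(
    gene_id: str,
    variants: dict[str, Alignment],
    base_tree: dendropy.Tree,
    classes: dict[str, str],
    starts=DEFAULT_STARTS,
    alpha: float = 0.05,
    freqs: str = "f3x4",
    compute_saturation: str = "auto",
    n_required: int | None = None,
) -> GeneScanResult:
    """Run the full six-test protocol on one gene.

    ``variants`` maps an alignment-variant name (e.g. ``"A"``, ``"B"``) to
    the filtered codon alignment surviving that pipeline; a rejected pipeline
    is simply absent and the gene then comes out untested.  Branch lengths are
    estimated once per variant under M0 and held fixed for the branch-site
    fits.  ``compute_saturation`` is ``"auto"`` (only for consensus-positive
    genes), ``"always"`` or ``"never"``.
    """
    endo = {sp for sp, c in classes.items() if c == "endo"}
    if n_required is None:
        n_required = len(variants) * len(starts)
    rows = []
    per_variant: dict[str, tuple[Alignment, dendropy.Tree, np.ndarray, object]] = {}
    for vname, aln in sorted(variants.items()):
        species = [s.species or s.id for s in aln]
        tree = prune_taxa(base_tree, set(species))
        try:
            tree = mark_foreground(tree, endo)
        except ValueError as exc:
            return GeneScanResult(
                gene_id,
                pd.DataFrame(),
                None,
                "excluded",
                reason=str(exc),
            )
        m0 = fit_model(aln, tree, "M0", start_omega=1.0, freqs=freqs)
        per_variant[vname] = (aln, tree, m0.branch_lengths, m0)
        for start in starts:
            _m0, alt, null, p = branch_site_test(
                aln, tree, start_omega=start, freqs=freqs, m0=m0
            )
            rows.append(
                {
                    "gene": gene_id,
                    "variant": vname,
                    "start_omega": start,
                    "lnL_alt": alt.lnL,
                    "lnL_null": null.lnL,
                    "p_raw": p,
                    "converged": alt.converged and null.converged,
                }
            )
    tests = pd.DataFrame(rows)
    if not tests.empty:
        tests["p_adj"] = bh_adjust(tests["p_raw"].to_numpy())
    call = consensus_call(
        tests["p_adj"].tolist() if not tests.empty else [], alpha, n_required
    )
    status = "tested" if call is not None else "untested"
    result = GeneScanResult(gene_id, tests, call, status)
    want_sat = compute_saturation == "always" or (
        compute_saturation == "auto" and call is True
    )
    if want_sat and per_variant:
        vname = sorted(per_variant)[0]
        aln, tree, bl, m0 = per_variant[vname]
        fr = fit_model(
            aln, tree, "free_ratio", start_omega=0.5, freqs=freqs,
            branch_lengths=bl, fix_kappa=m0.kappa,
        )
        result.overall_dS = m0.tree_dS
        result.foreground_dS = fr.foreground_dS
        result.saturated = saturation_screen(m0, fr)
    return result


def scan_study(
    genes: dict[str, dict[str, Alignment]],
    base_tree: dendropy.Tree,
    classes: dict[str, str],
    starts=DEFAULT_STARTS,
    alpha: float = 0.05,
    freqs: str = "f3x4",
    compute_saturation: str = "auto",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every gene; returns (per-test table, per-gene summary table)."""
    test_rows, summary_rows = [], []
    for gene_id in sorted(genes):
        res = scan_gene(
            gene_id,
            genes[gene_id],
            base_tree,
            classes,
            starts=starts,
            alpha=alpha,
            freqs=freqs,
            compute_saturation=compute_saturation,
        )
        if not res.tests.empty:
            test_rows.append(res.tests)
        summary_rows.append(
            {
                "gene": gene_id,
                "n_tests": 0 if res.tests.empty else len(res.tests),
                "min_p_adj": (
                    float(res.tests["p_adj"].min()) if not res.tests.empty else np.nan
                ),
                "consensus": res.consensus,
                "status": res.status,
                "reason": res.reason,
                "overall_dS": res.overall_dS,
                "foreground_dS": res.foreground_dS,
                "saturated": res.saturated,
            }
        )
    tests = (
        pd.concat(test_rows, ignore_index=True) if test_rows else pd.DataFrame()
    )
    return tests, pd.DataFrame(summary_rows)
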