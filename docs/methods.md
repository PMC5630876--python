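# Methods

`endoselect` reimplements, at desk scale, a comparative pipeline for
detecting convergent positive selection between independently endothermic
fish clades (tunas within Scombridae; lamnid sharks).  This note documents
the models, the numerical choices, the synthetic-data conditions, and the
limitations of what the test suite can and cannot show.

## Codon substitution model

All selection inference uses reversible 61-state codon models.  For codons
*i*, *j* differing at exactly one position,

    q_ij = pi_j * kappa^[transition] * omega^[non-synonymous],

zero for multi-position changes, diagonal set so rows sum to zero.  `kappa`
is the transition/transversion rate ratio, `pi` the codon frequencies
(F3x4 computed from each alignment by default; F1x4, F61 and uniform are
options), and `omega = dN/dS` the selection parameter.  Generators are
scaled so one unit of branch length is one expected substitution per codon
under the model's site-class mixture evaluated with *background* omegas;
simulation and inference share this convention exactly.

Supported models: `M0` (one ratio), `free_ratio` (one omega per branch),
branch-site model A (`bsA`) and its null (`bsA_null`).  Model A has four
site classes with proportions `p0, p1, p2a, p2b` where
`p2a = (1-p0-p1) p0/(p0+p1)` and `p2b = (1-p0-p1) p1/(p0+p1)`, and
per-class (background, foreground) omegas `(w0,w0), (1,1), (w0,w2), (1,w2)`
with `0 < w0 < 1 <= w2`.  The null fixes `w2 = 1`.  The foreground branch is
the stem of the endothermic clade: the branch above the most recent common
ancestor of the endothermic tips present in the (pruned) gene tree.  Genes
whose endotherms are not monophyletic after pruning are excluded.

Likelihoods use Felsenstein pruning over the 61 sense codons with per-node
rescaling, alignment-column pattern compression, and transition matrices
from the eigendecomposition of the symmetrised generator.  Gap and
ambiguous codons are missing data.  Because every branch's generator is
reversible with respect to the shared stationary frequencies, the traversal
may be anchored at the foreground node's parent; one down-pass per distinct
background omega then serves two site classes, with only the foreground
edge's matrix swapped.  Pruning is verified against exhaustive
internal-state enumeration on 3- and 4-taxon fixtures to 1e-8.

## Fitting and the six-test protocol

`M0` optimises branch lengths, `kappa` and `omega` jointly (L-BFGS-B on log
scales, with an analytic gradient for the branch lengths and finite
differences for the two scalars).  Background branch lengths and `kappa`
are then held fixed at their M0 estimates for the `free_ratio`, `bsA` and
`bsA_null` fits of the same gene — a stability/runtime decision.  The
foreground branch length, however, is re-optimised inside both branch-site
fits: the M0 estimate conflates foreground selection with stem length, and
holding it fixed measurably reduces power (0.30 vs 0.54 at the default
study conditions).  Both the alternative and the null free the same
parameter, so the LRT degrees of freedom are unchanged, and the null
rejection rate stays far below the nominal level (~0.02).  Branch-site parameters are
transformed (logit `w0`, log `w2-1`, softmax class weights) and bounded.
Convergence is a relative tolerance equivalent to a log-likelihood change
below ~1e-6.

The branch-site surface has a well-known boundary mode at `w2 = 1` that
traps quasi-Newton optimisers.  Each fit therefore performs one auxiliary
restart — from the primary optimum with `w2` pushed to 4 (alternative
model) or with `omega0` shifted (null) — and keeps the better likelihood.
If the alternative still lands below the null (possible only through
optimiser slop, since the models nest), it is refit from the null's optimum
and, as a last resort, pinned there, so the LRT statistic is never negative
for numerical reasons.

The scan protocol per gene: two filtered alignment variants (the two
pipelines below) x three starting omegas {0.5, 1, 1.5}, each start yielding
its own (alt, null) pair and p-value from `max(0, 2*dlnL)` against
chi-square with 1 df (the chi-square reference, not the 50:50 mixture).
The six p-values are Benjamini–Hochberg adjusted *within the gene* — an
unusual scope retained deliberately as part of the protocol; a genome-wide
FDR is not layered on top.  A gene is called selected only when
all six adjusted p-values are below alpha = 0.05; a gene with fewer than
six tests (a pipeline rejected it) is "untested", not negative.

Saturation screening: per-branch `dN`/`dS` come from partitioning the
fitted generator's expected flow into synonymous and non-synonymous parts,
with site proportions taken from the neutral (`omega = 1`) flow at the same
`kappa` and frequencies.  A gene is flagged when the one-ratio tree-wide
`dS` exceeds 1 or the free-ratio foreground-branch `dS` exceeds 1.

## Ortholog extraction from gene-family trees

The cleaning cascade mirrors standard RNA-seq phylogenomics practice:

* tips with branch length strictly greater than 2, or more than 10x their
  sister branch, are removed iteratively (longest first) to a fixed point;
* same-species monophyletic or paraphyletic tip groups collapse to the
  contig with the most aligned characters (ties to the smallest id);
* internal branches longer than 0.5 are cut, splitting the family;
* single-copy ortholog sets are extracted from the outgroup-rooted tree by
  resolving duplication nodes — nodes whose children share species — in
  favour of the child covering more ingroup species (ties by summed
  aligned characters).  Duplications are inferred from species-set overlap
  alone; no reconciliation against a dated species tree is attempted.

Thresholds use strict `>` where the boundary is unstated; trimming is
iterative.  An ortholog set is analysed only if it covers at least 5
species with at least 2 endothermic and 2 ectothermic members and contains
every required sister taxon.

## Alignment filtering

Two independent pipelines, both operating on the translated protein
alignment and projected back to codons:

* **Pipeline A** — a concordance filter against alternative alignments of
  the same sequences (a column scores `floor(9*f)` with `f` the fraction of
  its residue pairs co-aligned in every alternative; only score-9 columns
  survive), then a transitive-consistency filter against a library of
  optimal pairwise global alignments (BLOSUM62, gap open -11 / extend -1
  for proteins).  These scores are operational surrogates for the
  m-coffee/TCS internals, whose exact formulas are unpublished; the
  keep-only-score-9 contract is the fixed part.  A column holding a single
  residue is unsupported by definition (score 0) in the consistency filter
  and vacuously concordant (score 9) in the concordance filter.  External
  aligners are not reimplemented: alternatives come from the caller or the
  perturbation generator.
* **Pipeline B** — per-residue confidences in [0,1] (e.g. a
  perturbation-robustness score); residues with confidence <= 0.93
  (inclusive) are masked to gaps, then columns with >= 40% gaps (inclusive)
  or mean pairwise identity < 0.001 are trimmed.

Both pipelines then remove codon columns absent in at least half of the
species (inclusive) and run a greedy alignment-area heuristic (gap-free
columns x retained rows) that drops gap-rich rows.  If rows are dropped the
species-occupancy rule is re-checked; a still-valid gene is re-filtered
without those rows (no re-alignment, since no aligner is bundled),
otherwise the gene is rejected.

## 4-fold degenerate supermatrix

A codon column contributes its third positions only when every non-gap
codon shares the same first two nucleotides and that doublet is one of the
eight 4-fold families — the strict criterion, so no retained site can ever
change an amino acid (a per-sequence variant exists behind a flag).
Concatenation fills absent species with gaps, trims columns with strictly
fewer than half the species present (exactly half is kept, complementing
the inclusive codon filter), recomputes partition ranges, reports
per-species gap fractions, and writes relaxed PHYLIP plus a RAxML-style
partition file.  Tree estimation itself is out of scope; trees are inputs.

## Ancestral reconstruction

Empirical-Bayes marginal reconstruction over the 20 amino acids by two-pass
pruning (inside conditionals, outside partials, product normalised per
node/column).  The default model is Poisson (equal exchangeabilities and
frequencies, scaled to 1 substitution/site) with a pluggable
exchangeability matrix for richer models (WAG, LG, ...).
A node/column with no data anywhere below reports `-` rather than a
frequency-driven guess.  The substitution lister compares two nodes'
maximum-posterior sequences and maps columns to reference coordinates
(e.g. positions in the human protein) through an explicit table.

## Synthetic data: what it emulates and what it does not

Generator defaults are the study conditions used throughout the tests:
8 taxa (2 endothermic, monophyletic), balanced trees, branch lengths
exponential with mean 0.15 substitutions/codon, `kappa = 2`, uniform codon
frequencies (F3x4-realistic option available), `p0 = 0.6`, `p1 = 0.25`,
`omega0 = 0.2`; selection scenarios use `omega2 = 4` with 15% of sites in
the selected classes (`p0 = 0.5`, `p1 = 0.35`).  The endotherm stem — the
tested branch — is pinned at 0.4 substitutions/codon, representing the deep
split between each endothermic clade and its sister and keeping power
experiments free of stem-length variance; the power of the branch-site test
collapses on substitutionally short stems (see Limitations).  Site classes
are drawn i.i.d. per codon; branches evolve by sampling from exact
transition matrices, so simulation is exact at any branch length and never
produces stop codons.  Alternative-alignment corruption slides one residue
out of a corrupted column per copy, which breaks total concordance there
while leaving clean-column pairings intact; corrupted residues receive
confidences uniform on [0.3, 0.93].

The generator does **not** emulate assembly artifacts, isoform mixtures,
sequencing error, alignment uncertainty beyond the column-local scheme,
among-site rate variation beyond the omega classes, or non-stationary
composition.  Green tests therefore demonstrate correctness of the
implemented statistics under the model's own assumptions, not robustness of
the biological conclusions to real transcriptome noise.

## Problem sizes

The acceptance experiments use: 200 null genes and 40 selected genes
(8 taxa x 300 codons) for LRT calibration and power in the test suite;
`scripts/acceptance.py` reruns the same experiments at 60/30 genes, omega
recovery with 50 (suite) or 20 (script) replicates per truth value
(8 taxa x 500 codons), five 120-codon genes per filtering experiment, and
end-to-end scans through both filters and the six-test consensus (a 6-gene
study at 6 taxa x 150 codons in the suite; 8 taxa x 240 codons with
`omega2 = 8` in the script, where the demonstration aims to recover the
truly selected genes).  These sizes are the package's choices for a
single-CPU desk-scale study.

## Limitations

* Branch-site power depends strongly on the substitutional length of the
  tested branch: under the default conditions detection at `omega2 = 4` is
  ~0.5, but it falls below 0.15 when the stem is ~0.15 subs/codon.  Real
  studies face the same constraint.
* Background branch lengths and `kappa` are not re-estimated under each
  model; full CodeML-style fits re-optimise everything per model.  The LRT compares
  models sharing the same constraint, so calibration is unaffected, but
  per-model estimates can differ slightly from a full joint fit.
* The chi-square(1) reference is conservative for a boundary-constrained
  alternative; observed null rejection rates well below 0.05 are expected.
* BH adjustment within a gene across its six (correlated) tests, followed
  by the all-six rule, is a very conservative composite; its formal error
  rate is not characterised here.
* The concordance/consistency scores are surrogates; only the "keep total
  agreement" behaviour is contractually fixed.
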