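"""Stringent alignment filtering: two pipelines plus gap-rich row removal.

Alignment error is a dominant source of false positives in branch-site tests,
so candidate alignments are filtered twice, by two independent pipelines, and
a gene is only scanned when both survive.

Pipeline A (concordance/consistency):
  1. *Concordance filter* — the primary protein alignment is compared with
     alternative alignments of the same sequences (different aligners, or the
     synthetic perturbation generator).  A column scores 9 only when every
     residue pair it aligns is co-aligned identically in every alternative;
     only score-9 (totally concordant) columns are kept.
  2. *Consistency filter* — a transitive-consistency score against a library
     of all pairwise global alignments of the ungapped sequences; again only
     columns with the maximum score of 9 survive.

Pipeline B (confidence masking):
  Per-residue confidences in [0, 1] (e.g. from a perturbation-robustness
  scheme) mask residues with confidence <= 0.93 to gaps; columns with >= 40%
  gaps or mean pairwise identity < 0.001 are then trimmed.

Both pipelines finish on the codon alignment with the codon-occupancy filter
(codon columns absent in at least half of the species are removed) and a
greedy alignment-area heuristic that drops poorly aligned gap-rich rows; if
rows were dropped, the species-occupancy criteria are re-checked and the gene
is either re-filtered without those rows or rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence as TSequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genetree import filter_ortholog_taxa
from .seqio import Alignment, GAP_CODON, Sequence

__all__ = [
    "FilterReport",
    "concordance_filter",
    "consistency_filter",
    "occupancy_filter_codons",
    "maxalign_select",
    "confidence_mask_and_trim",
    "run_filter_pipeline",
]


@dataclass
class FilterReport:
    """What each filtering stage removed, and the species re-check outcome."""

    status: str = "passed"  # passed | rejected
    columns_removed: dict[str, list[int]] = field(default_factory=dict)
    codon_columns_removed: dict[str, list[int]] = field(default_factory=dict)
    residues_masked: int = 0
    sequences_removed: list[str] = field(default_factory=list)
    recheck: str | None = None

    def record_columns(self, stage: str, removed: TSequence[int]) -> None:
        self.columns_removed.setdefault(stage, []).extend(sorted(removed))

    def to_tsv(self) -> str:
        lines = [f"status\t{self.status}"]
        for stage, cols in self.columns_removed.items():
            lines.append(f"columns_removed\t{stage}\t{len(cols)}\t{','.join(map(str, cols))}")
        for stage, cols in self.codon_columns_removed.items():
            lines.append(
                f"codon_columns_removed\t{stage}\t{len(cols)}\t{','.join(map(str, cols))}"
            )
        lines.append(f"residues_masked\t{self.residues_masked}")
        lines.append(f"sequences_removed\t{','.join(self.sequences_removed)}")
        if self.recheck:
            lines.append(f"recheck\t{self.recheck}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Residue bookkeeping
# ---------------------------------------------------------------------------

def _residue_columns(aln: Alignment) -> list[dict[int, int]]:
    """Per row: residue ordinal -> column index."""
    out = []
    for s in aln:
        m: dict[int, int] = {}
        k = 0
        for j, c in enumerate(s.residues):
            if c != "-":
                m[k] = j
                k += 1
        out.append(m)
    return out


def _check_same_content(primary: Alignment, other: Alignment) -> list[int]:
    """Map primary row order onto ``other``; sequences must match ungapped."""
    theirs = {s.id: s.ungapped() for s in other}
    order = []
    their_order = {s.id: i for i, s in enumerate(other)}
    for s in primary:
        if s.id not in theirs:
            raise ValueError(f"alternative alignment missing sequence {s.id!r}")
        if theirs[s.id] != s.ungapped():
            raise ValueError(
                f"alternative alignment disagrees on the residues of {s.id!r}"
            )
        order.append(their_order[s.id])
    return order


# ---------------------------------------------------------------------------
# Pipeline A filters
# ---------------------------------------------------------------------------

def concordance_filter(
    primary: Alignment, alternatives: TSequence[Alignment]
) -> tuple[Alignment, np.ndarray, list[int]]:
    """Keep only totally concordant columns across alternative alignments.

    A primary column's score is ``floor(9 * f)`` where ``f`` is the fraction
    of its residue pairs co-aligned (placed in one column) in *every*
    alternative; columns with fewer than two residues score 9 vacuously.
    Returns (filtered alignment, per-column scores, removed column indices).
    """
    prim_cols = _residue_columns(primary)
    alt_maps = []
    for alt in alternatives:
        order = _check_same_content(primary, alt)
        cols = _residue_columns(alt)
        alt_maps.append([cols[order[i]] for i in range(len(primary))])
    ncol = primary.ncol
    scores = np.full(ncol, 9, dtype=int)
    residues_at = [[] for _ in range(ncol)]  # (row, ordinal)
    for i, m in enumerate(prim_cols):
        for ordinal, j in m.items():
            residues_at[j].append((i, ordinal))
    for j in range(ncol):
        res = residues_at[j]
        if len(res) < 2:
            continue
        total = agree = 0
        for (i1, o1), (i2, o2) in combinations(res, 2):
            total += 1
            ok = all(am[i1][o1] == am[i2][o2] for am in alt_maps)
            agree += ok
        scores[j] = int(np.floor(9 * agree / total))
    keep = [j for j in range(ncol) if scores[j] == 9]
    removed = [j for j in range(ncol) if scores[j] != 9]
    return primary.keep_columns(keep), scores, removed


def _pairwise_library(
    aln: Alignment,
    match: float = 1.0,
    mismatch: float = -1.0,
    open_gap: float = -5.0,
    extend_gap: float = -0.5,
):
    """One optimal global alignment per sequence pair, as residue-index pairs."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if aln.alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
        aligner.open_gap_score = open_gap
        aligner.extend_gap_score = extend_gap
    library: dict[tuple[int, int], set[tuple[int, int]]] = {}
    ungapped = [s.ungapped().replace("*", "X") for s in aln]
    for i1, i2 in combinations(range(len(aln)), 2):
        alignment = aligner.align(ungapped[i1], ungapped[i2])[0]
        pairs = set()
        for (s1, e1), (s2, e2) in zip(*alignment.aligned):
            for k in range(e1 - s1):
                pairs.add((s1 + k, s2 + k))
        library[(i1, i2)] = pairs
    return library


def consistency_filter(
    aln: Alignment, **scoring
) -> tuple[Alignment, np.ndarray, list[int]]:
    """Transitive-consistency column filter.

    Each column's score is ``floor(9 * f)`` with ``f`` the fraction of its
    residue pairs supported by the library of optimal pairwise global
    alignments of the ungapped sequences.  Only score-9 columns are retained.
    With fewer than three sequences the alignment passes through unchanged.
    """
    if len(aln) < 3:
        warnings.warn("consistency filter needs >= 3 sequences; passing through")
        return aln, np.full(aln.ncol, 9, dtype=int), []
    library = _pairwise_library(aln, **scoring)
    prim_cols = _residue_columns(aln)
    inverse = [
        {j: ordinal for ordinal, j in m.items()} for m in prim_cols
    ]
    ncol = aln.ncol
    scores = np.full(ncol, 9, dtype=int)
    for j in range(ncol):
        res = [(i, inverse[i][j]) for i in range(len(aln)) if j in inverse[i]]
        if len(res) == 1:
            scores[j] = 0  # a lone inserted residue has no supporting pair
            continue
        if not res:
            continue
        total = supported = 0
        for (i1, o1), (i2, o2) in combinations(res, 2):
            total += 1
            supported += (o1, o2) in library[(i1, i2)]
        scores[j] = int(np.floor(9 * supported / total))
    keep = [j for j in range(ncol) if scores[j] == 9]
    removed = [j for j in range(ncol) if scores[j] != 9]
    return aln.keep_columns(keep), scores, removed


# ---------------------------------------------------------------------------
# Codon occupancy and gap-rich row removal
# ---------------------------------------------------------------------------

def _codon_absent(codon: str) -> bool:
    return all(c in "-N" for c in codon)


def occupancy_filter_codons(
    codon_aln: Alignment, min_present_frac: float = 0.5
) -> tuple[Alignment, list[int]]:
    """Drop codon columns absent in at least ``1 - min_present_frac`` of rows.

    'Absent in at least half' is inclusive: with 6 rows, a column missing from
    exactly 3 is removed.
    """
    n = len(codon_aln)
    keep, removed = [], []
    for j in range(codon_aln.ncodons):
        absent = sum(_codon_absent(c) for c in codon_aln.codon_column(j))
        if absent >= (1.0 - min_present_frac) * n:
            removed.append(j)
        else:
            keep.append(j)
    return codon_aln.keep_codon_columns(keep), removed


def _alignment_area(rows: list[str]) -> int:
    if not rows:
        return 0
    ncol = len(rows[0])
    gap_free = sum(
        1 for j in range(ncol) if all(r[j] != "-" for r in rows)
    )
    return gap_free * len(rows)


def maxalign_select(aln: Alignment) -> tuple[Alignment, list[str]]:
    """Greedy removal of gap-rich rows to maximise alignment area.

    Area = (number of gap-free columns) x (number of retained rows).  At each
    step the single removal that most increases the area is applied (ties
    break to input order); the loop stops when no removal helps.
    """
    rows = [s.residues for s in aln]
    active = list(range(len(rows)))
    removed_idx: list[int] = []
    while len(active) > 2:
        base = _alignment_area([rows[i] for i in active])
        best_gain, best_i = 0, None
        for i in active:
            trial = [rows[k] for k in active if k != i]
            gain = _alignment_area(trial) - base
            if gain > best_gain:
                best_gain, best_i = gain, i
        if best_i is None:
            break
        active.remove(best_i)
        removed_idx.append(best_i)
    removed_ids = [aln.sequences[i].id for i in sorted(removed_idx)]
    kept = Alignment(
        [aln.sequences[i] for i in sorted(active)], aln.alphabet
    )
    return kept, removed_ids


# ---------------------------------------------------------------------------
# Pipeline B
# ---------------------------------------------------------------------------

def _column_similarity(column: str) -> float:
    """Mean pairwise identity of the non-gap residues; 1.0 when fewer than
    two residues are present."""
    res = [c for c in column if c != "-"]
    if len(res) < 2:
        return 1.0
    total = same = 0
    for a, b in combinations(res, 2):
        total += 1
        same += a == b
    return same / total


def confidence_mask_and_trim(
    aln: Alignment,
    residue_conf: np.ndarray,
    conf_threshold: float = 0.93,
    gap_frac: float = 0.4,
    sim_threshold: float = 0.001,
) -> tuple[Alignment, dict]:
    """Mask low-confidence residues, then trim gappy/dissimilar columns.

    Residues with confidence <= ``conf_threshold`` (inclusive, the
    conventional default of 0.93) become gaps; columns whose gap fraction is
    at least ``gap_frac`` (inclusive) or whose mean pairwise identity is below
    ``sim_threshold`` are then removed.  ``residue_conf`` has one value per
    alignment cell (values at gap cells are ignored).
    """
    conf = np.asarray(residue_conf, dtype=float)
    if conf.shape != (len(aln), aln.ncol):
        raise ValueError(
            f"confidence shape {conf.shape} != alignment shape {(len(aln), aln.ncol)}"
        )
    masked = 0
    rows = []
    for i, s in enumerate(aln):
        chars = list(s.residues)
        for j, c in enumerate(chars):
            if c != "-" and conf[i, j] <= conf_threshold:
                chars[j] = "-"
                masked += 1
        rows.append(Sequence(s.id, "".join(chars), s.species))
    masked_aln = Alignment(rows, aln.alphabet)
    n = len(masked_aln)
    keep, removed_gap, removed_sim = [], [], []
    for j in range(masked_aln.ncol):
        col = masked_aln.column(j)
        gaps = col.count("-")
        if gaps >= gap_frac * n:
            removed_gap.append(j)
        elif _column_similarity(col) < sim_threshold:
            removed_sim.append(j)
        else:
            keep.append(j)
    out = masked_aln.keep_columns(keep)
    report = {
        "residues_masked": masked,
        "columns_removed_gap": removed_gap,
        "columns_removed_similarity": removed_sim,
        "kept_columns": keep,
    }
    return out, report


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _apply_protein_filter_to_codons(
    codon_aln: Alignment,
    kept_protein_cols: list[int],
    masked_cells: set[tuple[int, int]] | None = None,
) -> Alignment:
    """Project a protein-level column selection (and optional residue masks,
    keyed by (row, protein column)) onto the codon alignment."""
    rows = []
    for i, s in enumerate(codon_aln):
        parts = []
        for k in kept_protein_cols:
            if masked_cells and (i, k) in masked_cells:
                parts.append(GAP_CODON)
            else:
                parts.append(s.residues[3 * k : 3 * k + 3])
        rows.append(Sequence(s.id, "".join(parts), s.species))
    return Alignment(rows, "dna")


def run_filter_pipeline(
    codon_aln: Alignment,
    pipeline: str,
    alternatives: TSequence[Alignment] | None = None,
    residue_conf: np.ndarray | None = None,
    classes: Mapping[str, str] | None = None,
    required_sisters: set[str] = frozenset(),
    min_species: int = 5,
    conf_threshold: float = 0.93,
    gap_frac: float = 0.4,
    sim_threshold: float = 0.001,
    min_present_frac: float = 0.5,
    _depth: int = 0,
) -> tuple[Alignment | None, FilterReport]:
    """Run one full filtering pipeline on an in-frame codon alignment.

    ``pipeline`` is ``"A"`` (concordance + consistency; requires
    ``alternatives``, protein alignments of the same sequences) or ``"B"``
    (confidence masking; requires ``residue_conf`` per protein residue).
    Filtering happens on the translated protein alignment and is projected
    back onto codons, followed by the codon-occupancy filter and gap-rich row
    removal.  If rows are removed, the species-occupancy rule is re-checked
    (when ``classes`` is given): a still-valid gene is re-filtered without
    those rows, otherwise the gene is rejected (``None`` plus a report whose
    status is ``"rejected"``).
    """
    from .seqio import translate_alignment

    report = FilterReport()
    protein = translate_alignment(codon_aln)
    if pipeline == "A":
        if alternatives is None:
            raise ValueError("pipeline A needs alternative alignments")
        filt1, _scores, removed1 = concordance_filter(protein, alternatives)
        kept1 = [j for j in range(protein.ncol) if j not in set(removed1)]
        report.record_columns("concordance", removed1)
        filt2, _scores2, removed2 = consistency_filter(filt1)
        kept_final = [kept1[j] for j in range(len(kept1)) if j not in set(removed2)]
        report.record_columns("consistency", [kept1[j] for j in removed2])
        codon_filtered = _apply_protein_filter_to_codons(codon_aln, kept_final)
    elif pipeline == "B":
        if residue_conf is None:
            raise ValueError("pipeline B needs per-residue confidences")
        filtered, info = confidence_mask_and_trim(
            protein,
            residue_conf,
            conf_threshold=conf_threshold,
            gap_frac=gap_frac,
            sim_threshold=sim_threshold,
        )
        report.residues_masked = info["residues_masked"]
        report.record_columns("gap_trim", info["columns_removed_gap"])
        report.record_columns("similarity_trim", info["columns_removed_similarity"])
        masked_cells = {
            (i, j)
            for i in range(len(protein))
            for j in range(protein.ncol)
            if protein.sequences[i].residues[j] != "-"
            and residue_conf[i, j] <= conf_threshold
        }
        codon_filtered = _apply_protein_filter_to_codons(
            codon_aln, info["kept_columns"], masked_cells
        )
    else:
        raise ValueError(f"unknown pipeline {pipeline!r}")

    codon_filtered, removed_codons = occupancy_filter_codons(
        codon_filtered, min_present_frac
    )
    report.codon_columns_removed.setdefault("occupancy", []).extend(removed_codons)
    codon_filtered, dropped_ids = maxalign_select(codon_filtered)
    report.sequences_removed.extend(dropped_ids)

    if dropped_ids:
        surviving_species = {
            s.species or s.id for s in codon_filtered
        }
        if classes is not None:
            ok = filter_ortholog_taxa(
                surviving_species, classes, required_sisters, min_species
            )
            if not ok:
                report.status = "rejected"
                report.recheck = "species criteria failed after row removal"
                return None, report
            report.recheck = "species criteria still met; re-filtered without dropped rows"
        if _depth < 2:
            keep_ids = [s.id for s in codon_filtered]
            sub = codon_aln.keep_rows(keep_ids)
            sub_alt = (
                [a.keep_rows(keep_ids) for a in alternatives]
                if pipeline == "A"
                else None
            )
            sub_conf = None
            if pipeline == "B":
                row_of = {s.id: i for i, s in enumerate(codon_aln)}
                sub_conf = residue_conf[[row_of[i] for i in keep_ids], :]
            refiltered, sub_report = run_filter_pipeline(
                sub,
                pipeline,
                alternatives=sub_alt,
                residue_conf=sub_conf,
                classes=classes,
                required_sisters=required_sisters,
                min_species=min_species,
                conf_threshold=conf_threshold,
                gap_frac=gap_frac,
                sim_threshold=sim_threshold,
                min_present_frac=min_present_frac,
                _depth=_depth + 1,
            )
            sub_report.sequences_removed = (
                report.sequences_removed + sub_report.sequences_removed
            )
            sub_report.recheck = report.recheck
            return refiltered, sub_report
    return codon_filtered, report
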