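"""4-fold degenerate site extraction and supermatrix concatenation.

Third codon positions are phylogenetically convenient: at a 4-fold degenerate
site any nucleotide encodes the same amino acid, so changes there are
synonymous and a tree built from them is independent of the protein-level
selection analyses.  A codon column qualifies only when every non-gap codon
shares the same first two nucleotides and that doublet is a 4-fold family
(the strict column-wide criterion; a per-sequence variant is available behind
``per_sequence=True``).  Qualifying columns contribute their third positions;
gap or ambiguous codons contribute gaps.

Per-gene extracted sites are concatenated into a species x sites supermatrix
with occupancy trimming (columns with fewer than half the species present are
dropped — exactly half is kept) and per-species gap statistics, exported as
relaxed PHYLIP plus a RAxML-style partition file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import Alignment, GeneticCode, STANDARD_CODE, Sequence


def fourfold_sites(
    codon_aln: Alignment,
    code: GeneticCode = STANDARD_CODE,
    per_sequence: bool = False,
) -> tuple[Alignment, list[int]]:
    """Extract third positions of 4-fold degenerate codon columns.

    Returns the nucleotide alignment of extracted sites and the codon-column
    indices they came from.  Under the default strict criterion a column is
    used only if all non-gap codons are 4-fold and share one doublet, so no
    third-position substitution can ever change any row's amino acid; with
    ``per_sequence=True`` non-qualifying codons in a qualifying column are
    emitted as gaps instead.
    """
    n = len(codon_aln)
    cols: list[int] = []
    pieces: list[list[str]] = [[] for _ in range(n)]
    for j in range(codon_aln.ncodons):
        codons = codon_aln.codon_column(j)
        informative = [c for c in codons if all(ch in "ACGT" for ch in c)]
        if not informative:
            continue
        if per_sequence:
            ok = any(code.is_fourfold(c) for c in informative)
        else:
            doublets = {c[:2] for c in informative}
            ok = len(doublets) == 1 and next(iter(doublets)) in code.fourfold_prefixes
        if not ok:
            continue
        cols.append(j)
        for i, c in enumerate(codons):
            if all(ch in "ACGT" for ch in c) and (
                not per_sequence or code.is_fourfold(c)
            ):
                pieces[i].append(c[2])
            else:
                pieces[i].append("-")
    rows = [
        Sequence(s.id, "".join(pieces[i]), s.species)
        for i, s in enumerate(codon_aln)
    ]
    return Alignment(rows, "dna"), cols


@dataclass
class Supermatrix:
    alignment: Alignment  # rows ordered by species label
    partitions: list[tuple[str, int, int]]  # (gene, start, end) 1-based inclusive
    gap_fraction: dict[str, float]

    @property
    def species(self) -> list[str]:
        return self.alignment.ids

    def write_phylip(self, path) -> None:
        from .seqio import write_phylip

        write_phylip(self.alignment, path)

    def write_partitions(self, path) -> None:
        def _write(fh):
            for gene, start, end in self.partitions:
                fh.write(f"DNA, {gene} = {start}-{end}\n")

        if hasattr(path, "write"):
            _write(path)
        else:
            with open(path, "w") as fh:
                _write(fh)


def build_supermatrix(
    genes: list[tuple[str, Alignment]],
    min_present_frac: float = 0.5,
) -> Supermatrix:
    """Concatenate per-gene nucleotide alignments into one species matrix.

    Rows are keyed by species (each gene must have at most one row per
    species); species absent from a gene are filled with gaps.  Columns with
    strictly fewer than ``min_present_frac`` of species present are trimmed,
    partition ranges are recomputed over the surviving columns, and the
    per-species gap fraction of the final matrix is reported.  Row order is
    lexicographic in species, so output is deterministic.
    """
    all_species: set[str] = set()
    for gname, aln in genes:
        sp = [s.species or s.id for s in aln]
        if len(set(sp)) != len(sp):
            dupes = sorted({x for x in sp if sp.count(x) > 1})
            raise ValueError(f"gene {gname!r} has duplicate species rows: {dupes}")
        all_species.update(sp)
    species = sorted(all_species)
    nsp = len(species)
    row_chunks: dict[str, list[str]] = {s: [] for s in species}
    col_gene: list[str] = []
    for gname, aln in genes:
        by_sp = {s.species or s.id: s.residues for s in aln}
        ncol = aln.ncol
        for sp in species:
            row_chunks[sp].append(by_sp.get(sp, "-" * ncol))
        col_gene.extend([gname] * ncol)
    matrix = np.array(
        [list("".join(row_chunks[sp])) for sp in species], dtype="U1"
    )
    present = (matrix != "-") & (matrix != "N")
    keep = present.sum(axis=0) >= min_present_frac * nsp
    matrix = matrix[:, keep]
    kept_genes = [g for g, k in zip(col_gene, keep) if k]
    # genes stay contiguous after trimming, so partition ranges follow from
    # each gene's surviving column count, in concatenation order
    partitions = []
    pos = 1
    for gname, _aln in genes:
        width = sum(1 for g in kept_genes if g == gname)
        if width:
            partitions.append((gname, pos, pos + width - 1))
            pos += width
    rows = [
        Sequence(sp, "".join(matrix[i]), sp) for i, sp in enumerate(species)
    ]
    aln = Alignment(rows, "dna")
    gap_fraction = {
        sp: float(
            sum(1 for c in rows[i].residues if c in "-N") / max(1, aln.ncol)
        )
        for i, sp in enumerate(species)
    }
    return Supermatrix(aln, partitions, gap_fraction)
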