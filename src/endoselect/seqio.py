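"""Sequence, alignment and genetic-code primitives shared across the pipeline.

In-memory containers are deliberately thin: a :class:`Sequence` is an id, an
optional species label and a residue string; an :class:`Alignment` is a list of
equal-length sequences with column-level accessors.  Codon alignments are
ordinary alignments whose length is divisible by three and whose columns are
addressed in codon units where that matters.

FASTA reading goes through Biopython; the writer emits 60-column wrapped
records and is byte-stable for a fixed input order.  The genetic code is the
standard nuclear code by default but any NCBI table id can be injected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence as TSequence

from Bio import SeqIO
from Bio.Data import CodonTable

DNA_ALPHABET = set("ACGTN-")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | set("X-*")

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

GAP_CODON = "---"


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass
class Sequence:
    """A named DNA or protein sequence, optionally tagged with its species."""

    id: str
    residues: str
    species: str | None = None

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


class Alignment:
    """Equal-length sequences plus an alphabet tag (``dna`` or ``protein``)."""

    def __init__(self, sequences: TSequence[Sequence], alphabet: str = "dna"):
        sequences = list(sequences)
        if not sequences:
            raise ValueError("alignment needs at least one sequence")
        ncol = len(sequences[0].residues)
        for s in sequences:
            if len(s.residues) != ncol:
                raise ValueError(
                    f"row {s.id!r} has length {len(s.residues)}, expected {ncol}"
                )
        if alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {alphabet!r}")
        self.sequences = sequences
        self.alphabet = alphabet

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def ncol(self) -> int:
        return len(self.sequences[0].residues)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    @property
    def species(self) -> list[str | None]:
        return [s.species for s in self.sequences]

    def row(self, seq_id: str) -> Sequence:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)

    def column(self, j: int) -> str:
        return "".join(s.residues[j] for s in self.sequences)

    # -- codon view --------------------------------------------------------
    @property
    def ncodons(self) -> int:
        if self.ncol % 3:
            raise ValueError("alignment length not divisible by 3")
        return self.ncol // 3

    def codon_column(self, j: int) -> list[str]:
        return [s.residues[3 * j : 3 * j + 3] for s in self.sequences]

    # -- subsetting --------------------------------------------------------
    def keep_columns(self, indices: Iterable[int]) -> "Alignment":
        idx = list(indices)
        return Alignment(
            [
                Sequence(s.id, "".join(s.residues[j] for j in idx), s.species)
                for s in self.sequences
            ],
            self.alphabet,
        )

    def keep_codon_columns(self, indices: Iterable[int]) -> "Alignment":
        nt_idx: list[int] = []
        for j in indices:
            nt_idx.extend((3 * j, 3 * j + 1, 3 * j + 2))
        return self.keep_columns(nt_idx)

    def keep_rows(self, ids: Iterable[str]) -> "Alignment":
        keep = set(ids)
        rows = [s for s in self.sequences if s.id in keep]
        if len(rows) != len(keep):
            missing = keep - {s.id for s in rows}
            raise KeyError(f"unknown sequence ids: {sorted(missing)}")
        return Alignment(rows, self.alphabet)


# ---------------------------------------------------------------------------
# FASTA / PHYLIP
# ---------------------------------------------------------------------------

def read_fasta(
    source,
    alphabet: str = "dna",
    species_of: Callable[[str], str | None] | None = None,
) -> Alignment:
    """Read an aligned FASTA file (path, handle or string) into an Alignment.

    ``species_of`` maps a record id to a species label; by default the part of
    the id before the first ``@`` is used when the id contains one.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    records = list(SeqIO.parse(source, "fasta"))
    if species_of is None:
        species_of = lambda rid: rid.split("@")[0] if "@" in rid else None
    seqs = [
        Sequence(r.id, str(r.seq).upper(), species_of(r.id)) for r in records
    ]
    return Alignment(seqs, alphabet)


def read_fasta_sequences(source, species_of=None) -> dict[str, Sequence]:
    """Read (possibly unaligned) FASTA records into an id-keyed mapping."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    if species_of is None:
        species_of = lambda rid: rid.split("@")[0] if "@" in rid else None
    out: dict[str, Sequence] = {}
    for r in SeqIO.parse(source, "fasta"):
        if r.id in out:
            raise ValueError(f"duplicate FASTA id {r.id!r}")
        out[r.id] = Sequence(r.id, str(r.seq).upper(), species_of(r.id))
    return out


def write_fasta(seqs: Iterable[Sequence] | Alignment, handle_or_path) -> None:
    seqs = list(seqs)

    def _write(fh):
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")

    if hasattr(handle_or_path, "write"):
        _write(handle_or_path)
    else:
        with open(handle_or_path, "w") as fh:
            _write(fh)


def write_phylip(aln: Alignment, handle_or_path) -> None:
    """Relaxed (long-name) sequential PHYLIP."""

    def _write(fh):
        fh.write(f"{len(aln)} {aln.ncol}\n")
        width = max(len(s.id) for s in aln) + 2
        for s in aln:
            fh.write(s.id.ljust(width) + s.residues + "\n")

    if hasattr(handle_or_path, "write"):
        _write(handle_or_path)
    else:
        with open(handle_or_path, "w") as fh:
            _write(fh)


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

class GeneticCode:
    """Codon → amino-acid mapping with degeneracy services.

    Wraps an NCBI translation table (standard nuclear code by default): 61
    sense codons, 3 stops, plus the set of 4-fold degenerate codon families
    (doublets whose four completions encode the same amino acid).
    """

    def __init__(self, table_id: int = 1):
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.forward: dict[str, str] = dict(tbl.forward_table)
        self.stop_codons: frozenset[str] = frozenset(tbl.stop_codons)
        self.sense_codons: list[str] = sorted(self.forward)
        prefixes = []
        for n1 in "ACGT":
            for n2 in "ACGT":
                fam = [n1 + n2 + n3 for n3 in "ACGT"]
                if all(c in self.forward for c in fam):
                    aas = {self.forward[c] for c in fam}
                    if len(aas) == 1:
                        prefixes.append(n1 + n2)
        self.fourfold_prefixes: frozenset[str] = frozenset(prefixes)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def is_fourfold(self, codon: str) -> bool:
        return codon[:2] in self.fourfold_prefixes and codon in self.forward

    def aa(self, codon: str) -> str:
        """Translate one codon; ``---`` → ``-``; anything ambiguous → ``X``."""
        if codon == GAP_CODON:
            return "-"
        if codon in self.forward:
            return self.forward[codon]
        if codon in self.stop_codons:
            return "*"
        return "X"


STANDARD_CODE = GeneticCode(1)


# ---------------------------------------------------------------------------
# ORF extraction and translation
# ---------------------------------------------------------------------------

@dataclass
class OrfInfo:
    strand: str  # "+" or "-"
    frame: int  # 0, 1 or 2 on the reported strand
    start: int  # nt offset of the first codon on that strand
    n_codons: int


def extract_longest_orf(
    dna: Sequence,
    code: GeneticCode = STANDARD_CODE,
    both_strands: bool = True,
) -> tuple[Sequence, OrfInfo] | None:
    """Longest open reading frame across frames (and strands).

    An ORF runs from a start codon (ATG) to the next in-frame stop codon or
    the end of the frame; the terminal stop is never part of the reported
    protein.  All three frames of the forward strand are scanned and, unless
    ``both_strands=False``, of the reverse complement too.  Ties are broken
    in favour of the forward strand, then the lowest frame index, then the
    leftmost start.  Returns ``None`` when no frame contains a start codon.
    """
    s = dna.residues.upper()
    strands = [("+", s)]
    if both_strands:
        strands.append(("-", reverse_complement(s)))
    best: tuple[int, int, int, int, str] | None = None  # (len, srank, frame, start, seq)
    for srank, (strand, text) in enumerate(strands):
        for frame in range(3):
            n_codons = (len(text) - frame) // 3
            codons = [text[frame + 3 * i : frame + 3 * i + 3] for i in range(n_codons)]
            i = 0
            while i < n_codons:
                if codons[i] != "ATG":
                    i += 1
                    continue
                j = i
                while j < n_codons and not code.is_stop(codons[j]):
                    j += 1
                run_len = j - i
                if run_len > 0 and (
                    best is None
                    or run_len > best[0]
                    or (run_len == best[0] and (srank, frame) < (best[1], best[2]))
                ):
                    start_nt = frame + 3 * i
                    best = (
                        run_len,
                        srank,
                        frame,
                        start_nt,
                        "".join(codons[i:j]),
                    )
                i = j + 1  # later ATGs inside this ORF are strictly shorter
                # continue after the stop
    if best is None:
        return None
    run_len, srank, frame, start_nt, orf_nt = best
    protein = translate_codons(orf_nt, code)
    strand = "+" if srank == 0 else "-"
    return (
        Sequence(dna.id, protein, dna.species),
        OrfInfo(strand=strand, frame=frame, start=start_nt, n_codons=run_len),
    )


def translate_codons(
    codon_seq: str | Sequence,
    code: GeneticCode = STANDARD_CODE,
    allow_stop: bool = False,
) -> str:
    """Translate an in-frame codon string; gap codons map to ``-``, ambiguous
    codons to ``X``.  Internal stops raise unless ``allow_stop``.
    """
    text = codon_seq.residues if isinstance(codon_seq, Sequence) else codon_seq
    if len(text) % 3:
        raise ValueError("codon sequence length not divisible by 3")
    out = []
    for i in range(0, len(text), 3):
        codon = text[i : i + 3]
        aa = code.aa(codon)
        if aa == "*" and not allow_stop:
            raise ValueError(f"internal stop codon at codon index {i // 3}")
        if "-" in codon and codon != GAP_CODON:
            aa = "X"
        out.append(aa)
    return "".join(out)


def translate_alignment(codon_aln: Alignment, code: GeneticCode = STANDARD_CODE) -> Alignment:
    return Alignment(
        [
            Sequence(s.id, translate_codons(s.residues, code), s.species)
            for s in codon_aln
        ],
        "protein",
    )


def back_translate(
    protein_aln: Alignment,
    cds_by_id: Mapping[str, Sequence | str],
    code: GeneticCode = STANDARD_CODE,
) -> Alignment:
    """Expand a protein alignment back to codons using each row's CDS.

    Every ungapped protein row must translate exactly from its CDS (``X``
    matches any codon).  Gaps expand 1 → 3, so protein column *k* maps to
    codon column *k*.
    """
    rows = []
    for s in protein_aln:
        cds = cds_by_id[s.id]
        cds_text = cds.residues if isinstance(cds, Sequence) else cds
        ungapped = s.residues.replace("-", "")
        if len(cds_text) != 3 * len(ungapped):
            raise ValueError(
                f"CDS for {s.id!r} has {len(cds_text)} nt, expected {3 * len(ungapped)}"
            )
        for k, aa in enumerate(ungapped):
            codon = cds_text[3 * k : 3 * k + 3]
            trans = code.aa(codon)
            if aa not in ("X", trans):
                raise ValueError(
                    f"CDS/protein mismatch for {s.id!r} at residue {k}: "
                    f"{codon} encodes {trans}, protein has {aa}"
                )
        out = []
        k = 0
        for aa in s.residues:
            if aa == "-":
                out.append(GAP_CODON)
            else:
                out.append(cds_text[3 * k : 3 * k + 3])
                k += 1
        rows.append(Sequence(s.id, "".join(out), s.species))
    return Alignment(rows, "dna")
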