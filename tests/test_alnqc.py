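"""Both alignment-filtering pipelines and the gap-rich row heuristic."""

from itertools import combinations

import numpy as np
import pytest

from endoselect.alnqc import (
    concordance_filter,
    confidence_mask_and_trim,
    consistency_filter,
    maxalign_select,
    occupancy_filter_codons,
    run_filter_pipeline,
)
from endoselect.seqio import Alignment, Sequence, translate_alignment
from endoselect.simulate import (
    SimulationSpec,
    make_alternative_alignments,
    simulate_codon_alignment,
    simulate_tree,
)


def prot(rows: dict[str, str]) -> Alignment:
    return Alignment([Sequence(k, v, k) for k, v in rows.items()], "protein")


def dna(rows: dict[str, str]) -> Alignment:
    return Alignment([Sequence(k, v, k) for k, v in rows.items()], "dna")


class TestConcordance:
    BASE = {"a": "MKLV", "b": "MKLV", "c": "MK-V", "d": "MKLV"}

    def test_identical_alternatives_keep_everything(self):
        p = prot(self.BASE)
        alts = [prot(self.BASE), prot(self.BASE)]
        out, scores, removed = concordance_filter(p, alts)
        assert removed == []
        assert (scores == 9).all()
        assert out.ncol == p.ncol

    def test_single_shift_removes_column(self):
        p = prot({"a": "MKLV", "b": "MKLV"})
        shifted = prot({"a": "MKLV-", "b": "MKL-V"})  # b's V moved off-column
        out, scores, removed = concordance_filter(p, [shifted])
        assert removed == [3]
        assert scores[3] < 9

    def test_scores_equal_pair_counting_oracle(self):
        """Scores match an explicit enumeration of co-aligned residue pairs."""
        p = prot({"a": "MKV", "b": "MKV", "c": "MKV", "d": "M-V"})
        alt1 = prot({"a": "MKV-", "b": "MKV-", "c": "MK-V", "d": "M--V"})
        alt2 = prot({"a": "MKV", "b": "MKV", "c": "MKV", "d": "M-V"})
        _out, scores, _removed = concordance_filter(p, [alt1, alt2])

        def residue_cols(aln):
            maps = []
            for s in aln:
                m, k = {}, 0
                for j, ch in enumerate(s.residues):
                    if ch != "-":
                        m[k] = j
                        k += 1
                maps.append(m)
            return maps

        pm = residue_cols(p)
        for j in range(p.ncol):
            residues = [
                (i, k) for i, m in enumerate(pm) for k, col in m.items() if col == j
            ]
            pairs = list(combinations(residues, 2))
            if not pairs:
                assert scores[j] == 9
                continue
            agree = 0
            for (i1, k1), (i2, k2) in pairs:
                ok = True
                for alt in (alt1, alt2):
                    am = residue_cols(alt)
                    ok = ok and am[i1][k1] == am[i2][k2]
                agree += ok
            assert scores[j] == int(np.floor(9 * agree / len(pairs)))

    def test_different_content_rejected(self):
        p = prot({"a": "MKV", "b": "MKV"})
        with pytest.raises(ValueError, match="disagrees|missing"):
            concordance_filter(p, [prot({"a": "MKV", "b": "MLV"})])


class TestConsistency:
    def test_identical_sequences_all_nine(self):
        p = prot({"a": "MKLVW", "b": "MKLVW", "c": "MKLVW"})
        out, scores, removed = consistency_filter(p)
        assert removed == [] and (scores == 9).all()

    def test_unique_insertion_column_drops(self):
        p = prot(
            {"a": "MKL-VW", "b": "MKL-VW", "c": "MKLQVW", "d": "MKL-VW"}
        )
        _out, scores, removed = consistency_filter(p)
        assert 3 in removed

    def test_fewer_than_three_passthrough(self):
        p = prot({"a": "MK", "b": "MK"})
        with pytest.warns(UserWarning):
            out, scores, removed = consistency_filter(p)
        assert out.ncol == 2 and removed == []


class TestOccupancy:
    def test_absent_in_majority_removed(self):
        rows = {f"s{i}": ("ATG" if i < 2 else "---") + "AAA" for i in range(6)}
        out, removed = occupancy_filter_codons(dna(rows))
        assert removed == [0] and out.ncodons == 1

    def test_absent_in_exactly_half_removed(self):
        rows = {f"s{i}": ("ATG" if i < 3 else "---") + "AAA" for i in range(6)}
        _out, removed = occupancy_filter_codons(dna(rows))
        assert removed == [0]

    def test_fully_occupied_kept(self):
        rows = {f"s{i}": "ATGAAA" for i in range(6)}
        _out, removed = occupancy_filter_codons(dna(rows))
        assert removed == []


class TestMaxalign:
    def test_gapless_identity(self):
        a = prot({"a": "MKLV", "b": "MKIV", "c": "MRLV"})
        out, removed = maxalign_select(a)
        assert removed == [] and len(out) == 3

    def test_gap_rich_row_removed_matches_exhaustive_search(self):
        rows = {
            "a": "MKLVWMKLVW",
            "b": "MKIVWMKIVW",
            "c": "MRLVWMRLVW",
            "d": "MKLVWMKLVY",
            "e": "M---------",
        }
        a = prot(rows)
        out, removed = maxalign_select(a)
        assert removed == ["e"]

        # exhaustive subset oracle: no subset beats the greedy area
        def area(keys):
            if not keys:
                return 0
            ncol = len(next(iter(rows.values())))
            gf = sum(
                1
                for j in range(ncol)
                if all(rows[k][j] != "-" for k in keys)
            )
            return gf * len(keys)

        best = max(
            (
                area(sub)
                for r in range(1, 6)
                for sub in combinations(rows, r)
            ),
        )
        assert area([s.id for s in out]) == best

    def test_stepwise_greedy_matches_single_removal_oracle(self):
        rows = {
            "a": "MKLVWMKL",
            "b": "MKIVWMKI",
            "c": "MRLVWMRL",
            "d": "--LVW--L",
            "e": "MK--WMK-",
        }
        a = prot(rows)
        out, removed = maxalign_select(a)

        def area(keys):
            ncol = 8
            gf = sum(
                1 for j in range(ncol) if all(rows[k][j] != "-" for k in keys)
            )
            return gf * len(keys)

        # replay: every removal recorded must have been the best available
        active = list(rows)
        for rid in removed:
            base = area(active)
            gains = {
                i: area([k for k in active if k != i]) - base for i in active
            }
            best_gain = max(gains.values())
            assert gains[rid] == best_gain and best_gain > 0
            active.remove(rid)
        assert all(
            area([k for k in active if k != i]) <= area(active) for i in active
        )


class TestConfidenceMask:
    def test_boundary_confidence_masked_inclusive(self):
        a = prot({"a": "MK", "b": "MK", "c": "MK"})
        conf = np.ones((3, 2))
        conf[1, 1] = 0.93  # exactly at the threshold -> masked
        out, info = confidence_mask_and_trim(a, conf, gap_frac=0.9)
        assert info["residues_masked"] == 1
        assert out.sequences[1].residues[1] == "-"

    def test_gap_fraction_boundary_inclusive(self):
        rows = {f"s{i}": ("K" if i >= 4 else "-") + "M" for i in range(10)}
        a = prot(rows)
        conf = np.ones((10, 2))
        out, info = confidence_mask_and_trim(a, conf)
        assert info["columns_removed_gap"] == [0]  # 4/10 = 40% gaps
        assert out.ncol == 1

    def test_identity_when_confident_and_gapless(self):
        a = prot({"a": "MKL", "b": "MKL", "c": "MRL"})
        out, info = confidence_mask_and_trim(a, np.ones((3, 3)))
        assert out.ncol == 3 and info["residues_masked"] == 0

    def test_shape_mismatch(self):
        a = prot({"a": "MK", "b": "MK"})
        with pytest.raises(ValueError, match="shape"):
            confidence_mask_and_trim(a, np.ones((2, 3)))


class TestPipelines:
    CLASSES = {f"sp{i + 1:02d}": ("endo" if i < 2 else "ecto") for i in range(8)}

    def _gene(self, corruption=0.0, seed=3):
        spec = SimulationSpec(n_codons=60, seed=seed)
        tree, _ = simulate_tree(spec)
        aln, _ = simulate_codon_alignment(tree, spec)
        protein = translate_alignment(aln)
        alts, corrupted, conf = make_alternative_alignments(
            protein, k=3, corruption_frac=corruption, seed=seed
        )
        return aln, alts, corrupted, conf

    def test_clean_gene_passes_unchanged(self):
        aln, alts, corrupted, conf = self._gene(0.0)
        outA, repA = run_filter_pipeline(
            aln, "A", alternatives=alts, classes=self.CLASSES
        )
        outB, repB = run_filter_pipeline(
            aln, "B", residue_conf=conf, classes=self.CLASSES
        )
        assert corrupted == []
        assert repA.status == repB.status == "passed"
        assert outA.ncol == aln.ncol and outB.ncol == aln.ncol
        assert [s.residues for s in outA] == [s.residues for s in aln]

    def test_corrupted_columns_removed_with_truth(self):
        aln, alts, corrupted, conf = self._gene(0.2, seed=11)
        assert len(corrupted) > 0
        outA, repA = run_filter_pipeline(
            aln, "A", alternatives=alts, classes=self.CLASSES
        )
        removedA = set(repA.columns_removed.get("concordance", []))
        assert set(corrupted) <= removedA
        outB, repB = run_filter_pipeline(
            aln, "B", residue_conf=conf, classes=self.CLASSES
        )
        # pipeline B masks whole corrupted columns -> gap-trimmed out
        trimmedB = set(repB.columns_removed.get("gap_trim", []))
        assert set(corrupted) <= trimmedB

    def test_outputs_in_frame_and_stop_free(self):
        aln, alts, corrupted, conf = self._gene(0.15, seed=21)
        for pipe, kw in (
            ("A", {"alternatives": alts}),
            ("B", {"residue_conf": conf}),
        ):
            out, _rep = run_filter_pipeline(aln, pipe, classes=self.CLASSES, **kw)
            assert out.ncol % 3 == 0
            translate_alignment(out)  # raises on internal stops

    def test_rejection_when_species_rule_fails(self):
        # one endotherm made unalignable: maxalign drops it, leaving 1 endo
        spec = SimulationSpec(n_codons=40, seed=5)
        tree, _ = simulate_tree(spec)
        aln, _ = simulate_codon_alignment(tree, spec)
        rows = []
        for s in aln:
            if s.id == "sp01":
                rows.append(
                    type(s)(s.id, "ATG" + "-" * (aln.ncol - 3), s.species)
                )
            else:
                rows.append(s)
        broken = Alignment(rows, "dna")
        conf = np.ones((len(broken), broken.ncol // 3))
        out, rep = run_filter_pipeline(
            broken, "B", residue_conf=conf, classes=self.CLASSES
        )
        assert rep.status == "rejected" and out is None
        assert "sp01" in rep.sequences_removed
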