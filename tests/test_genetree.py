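"""Gene-family tree cleaning and single-copy ortholog extraction."""

import pytest

from endoselect.genetree import (
    OrthologSet,
    collapse_species_repeats,
    cut_deep_paralogs,
    filter_ortholog_taxa,
    prune_rt_orthologs,
    trim_spurious_tips,
)
from endoselect.simulate import SimulationSpec, simulate_gene_family, simulate_tree
from endoselect.trees import parse_newick, tip_labels


class TestTrimSpuriousTips:
    def test_absolute_threshold(self):
        t = parse_newick("((a@1:2.5,b@1:0.1):0.1,(c@1:0.1,d@1:0.1):0.1);")
        out = trim_spurious_tips(t)
        assert sorted(tip_labels(out)) == ["b@1", "c@1", "d@1"]

    def test_boundary_exactly_two_kept(self):
        t = parse_newick("((a@1:2.0,b@1:0.5):0.1,c@1:0.5);")
        out = trim_spurious_tips(t)
        assert "a@1" in tip_labels(out)  # strict '>', 2.0 survives

    def test_relative_threshold(self):
        t = parse_newick("((a@1:0.50,b@1:0.04):0.1,(c@1:0.1,d@1:0.1):0.1);")
        out = trim_spurious_tips(t)  # 0.50 / 0.04 = 12.5 > 10
        assert "a@1" not in tip_labels(out)

    def test_fixed_point_and_idempotence(self):
        t = parse_newick("((a@1:0.1,b@1:0.1):0.1,(c@1:0.1,d@1:0.1):0.1);")
        out = trim_spurious_tips(t)
        assert sorted(tip_labels(out)) == sorted(tip_labels(t))
        again = trim_spurious_tips(out)
        assert sorted(tip_labels(again)) == sorted(tip_labels(out))

    def test_all_removed_signals_empty(self):
        t = parse_newick("(a@1:3.0,b@1:4.0);")
        assert trim_spurious_tips(t) is None


class TestCollapseSpeciesRepeats:
    def test_sister_tips_keep_most_characters(self):
        t = parse_newick("((spA@c1:0.1,spA@c2:0.1):0.1,spB@c1:0.1);")
        out = collapse_species_repeats(t, chars={"spA@c1": 100, "spA@c2": 80})
        assert sorted(tip_labels(out)) == ["spA@c1", "spB@c1"]

    def test_paraphyletic_grade(self):
        t = parse_newick("(spA@c1:0.1,(spA@c2:0.1,spB@c1:0.1):0.1);")
        out = collapse_species_repeats(t, chars={"spA@c1": 50, "spA@c2": 90})
        assert sorted(tip_labels(out)) == ["spA@c2", "spB@c1"]

    def test_distinct_species_identity(self):
        t = parse_newick("((spA@c1:0.1,spB@c1:0.1):0.1,spC@c1:0.1);")
        out = collapse_species_repeats(t)
        assert sorted(tip_labels(out)) == sorted(tip_labels(t))

    def test_tie_breaks_lexicographic(self):
        t = parse_newick("((spA@c2:0.1,spA@c1:0.1):0.1,spB@c1:0.1);")
        out = collapse_species_repeats(t, chars={"spA@c1": 10, "spA@c2": 10})
        assert "spA@c1" in tip_labels(out)


class TestCutDeepParalogs:
    def test_single_cut(self):
        t = parse_newick(
            "(((a@1:.1,b@1:.1):.6,(c@1:.1,d@1:.1):.1):.1,(e@1:.1,f@1:.1):.1);"
        )
        parts = cut_deep_paralogs(t)
        assert len(parts) == 2
        sizes = sorted(len(tip_labels(p)) for p in parts)
        assert sizes == [2, 4]

    def test_no_op_below_threshold(self):
        t = parse_newick("((a@1:.1,b@1:.1):.5,(c@1:.1,d@1:.1):.1);")
        parts = cut_deep_paralogs(t)  # 0.5 not > 0.5
        assert len(parts) == 1 and len(tip_labels(parts[0])) == 4

    def test_partition_matches_edge_removal_oracle(self):
        """Chained cuts on a 10-tip tree equal the connected components left
        after deleting the long internal edges, computed by hand."""
        text = (
            "(((a@1:.1,b@1:.1):.7,((c@1:.1,d@1:.1):.6,e@1:.1):.1):.1,"
            "((f@1:.1,g@1:.1):.1,(h@1:.1,(i@1:.1,j@1:.1):.9):.1):.1);"
        )
        t = parse_newick(text)
        parts = cut_deep_paralogs(t)
        got = sorted(tuple(sorted(tip_labels(p))) for p in parts)
        # removing the .7, .6 and .9 edges disconnects:
        # {a,b}, {c,d}, {i,j}, and the remainder {e,f,g,h}
        want = sorted(
            [
                ("a@1", "b@1"),
                ("c@1", "d@1"),
                ("i@1", "j@1"),
                ("e@1", "f@1", "g@1", "h@1"),
            ]
        )
        assert got == want


class TestRtPruning:
    def test_no_duplication_keeps_all_ingroup(self):
        t = parse_newick(
            "((out@1:.1,((a@1:.1,b@1:.1):.1,c@1:.1):.1):.1,out2@1:.1);"
        )
        sets = prune_rt_orthologs(t, {"out", "out2"})
        assert len(sets) == 1
        assert sets[0].species == {"a", "b", "c"}

    def test_duplication_keeps_larger_species_side(self):
        """One duplication: 5-species copy vs 3-species copy."""
        five = "((a@1:.1,b@1:.1):.1,((c@1:.1,d@1:.1):.1,e@1:.1):.1)"
        three = "((a@2:.1,b@2:.1):.1,c@2:.1)"
        t = parse_newick(f"(out@1:.1,({five}:.2,{three}:.2):.1);")
        sets = prune_rt_orthologs(t, {"out"})
        assert sets[0].species == {"a", "b", "c", "d", "e"}
        assert all(v.endswith("@1") for v in sets[0].species_to_id.values())

    def test_equal_species_tie_breaks_on_characters(self):
        t = parse_newick(
            "(out@1:.1,((a@1:.1,b@1:.1):.2,(a@2:.1,b@2:.1):.2):.1);"
        )
        chars = {"a@1": 200, "b@1": 200, "a@2": 150, "b@2": 150}
        sets = prune_rt_orthologs(t, {"out"}, chars=chars)
        assert set(sets[0].species_to_id.values()) == {"a@1", "b@1"}

    def test_no_outgroup_raises(self):
        t = parse_newick("(a@1:.1,b@1:.1);")
        with pytest.raises(ValueError, match="outgroup"):
            prune_rt_orthologs(t, {"zz"})

    def test_duplicated_outgroup_raises(self):
        t = parse_newick("((out@1:.1,out@2:.1):.1,(a@1:.1,b@1:.1):.1);")
        with pytest.raises(ValueError, match="duplicated"):
            prune_rt_orthologs(t, {"out"})

    def test_single_copy_on_simulated_families(self):
        """Pruned sets are single-copy across many simulated gene families."""
        spec = SimulationSpec(n_taxa=8, seed=1)
        sptree, _classes = simulate_tree(spec)
        out_text = "(outA@c1:0.05,outB@c1:0.05)"
        for seed in range(300):
            fam, truth, chars = simulate_gene_family(
                sptree, dup_rate=1.0, loss_rate=0.1, spurious_tip_rate=0.0,
                seed=seed,
            )
            # graft outgroups below the family root
            from endoselect.trees import write_newick

            fam_text = write_newick(fam).strip().rstrip(";")
            t = parse_newick(f"({out_text}:0.3,{fam_text}:0.05);")
            sets = prune_rt_orthologs(t, {"outA", "outB"}, chars=chars)
            ids = list(sets[0].species_to_id.values())
            species = [i.split("@")[0] for i in ids]
            assert len(set(species)) == len(species)  # single copy
            assert not any(sp in ("outA", "outB") for sp in species)


class TestFilterOrthologTaxa:
    CLASSES = {
        "a": "endo", "b": "endo", "c": "ecto", "d": "ecto", "e": "ecto",
        "f": "endo", "g": "ecto", "h": "ecto",
    }

    def test_minimum_species_count(self):
        assert not filter_ortholog_taxa({"a", "b", "c", "d"}, self.CLASSES)

    def test_all_criteria_met(self):
        assert filter_ortholog_taxa(
            {"a", "b", "c", "d", "e"}, self.CLASSES, required_sisters={"c"}
        )

    def test_endotherm_count(self):
        # six species but only one endotherm
        assert not filter_ortholog_taxa(
            {"a", "c", "d", "e", "g", "h"}, self.CLASSES
        )

    def test_missing_sister_fails(self):
        classes = dict(self.CLASSES, zz="ecto")
        assert not filter_ortholog_taxa(
            {"a", "b", "c", "d", "e"}, classes, required_sisters={"zz"}
        )

    def test_unclassified_raises(self):
        with pytest.raises(ValueError, match="unclassified"):
            filter_ortholog_taxa({"a", "mystery"}, self.CLASSES)

    def test_ortholog_set_rejects_repeated_ids(self):
        with pytest.raises(ValueError):
            OrthologSet({"a": "x@1", "b": "x@1"})
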