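import pandas as pd
import pytest

from treeplace.adna_pileup import SiteCall
from treeplace.branch_assign import BranchAssignedSNP
from treeplace.haplogroup import (
    label_branches,
    load_markers,
    refine_below,
)
from treeplace.simulate import SimConfig, sim_markers, sim_query, sim_reference

from conftest import branch_by_clade


def marker_frame(rows):
    return pd.DataFrame(
        rows, columns=["name", "haplogroup", "chrom", "pos", "ancestral", "derived"]
    )


class TestLoadMarkers:
    def test_basic_row(self):
        ms = load_markers(
            marker_frame([["M51", "A1b1b2a", "chrY", 100, "A", "G"]])
        )
        assert len(ms) == 1
        assert ms[0].haplogroup == "A1b1b2a"
        assert ms[0].derived_allele == "G"

    def test_indel_rows_skipped(self):
        ms = load_markers(
            marker_frame(
                [
                    ["M1", "A1", "chrY", 100, "A", "G"],
                    ["M2", "A2", "chrY", 200, "AT", "A"],
                    ["M3", "A3", "chrY", 300, "C", "C"],
                ]
            )
        )
        assert [m.names[0] for m in ms] == ["M1"]

    def test_duplicate_position_collapsed_keeping_names(self):
        ms = load_markers(
            marker_frame(
                [
                    ["M51", "A1b1b2a", "chrY", 100, "A", "G"],
                    ["PF123", "A1b1b2a", "chrY", 100, "A", "G"],
                ]
            )
        )
        assert len(ms) == 1
        assert set(ms[0].names) == {"M51", "PF123"}

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            load_markers(marker_frame([]))

    def test_provisional_flagged(self):
        ms = load_markers(
            marker_frame([["PF2535~", "E1b1b1b1a1~", "chrY", 10, "C", "A"]])
        )
        assert ms[0].provisional
        assert ms[0].haplogroup == "E1b1b1b1a1"

    def test_synonyms_applied(self):
        ms = load_markers(
            marker_frame([["M293", "E-M293", "chrY", 5, "A", "T"]]),
            synonyms={"E-M293": "E1b1b1b2b2a1"},
        )
        assert ms[0].haplogroup == "E1b1b1b2b2a1"


class TestLabelBranches:
    def _assignments(self, four_tip_tree):
        ab = branch_by_clade(four_tip_tree, {"A", "B"})
        return [
            BranchAssignedSNP("chrY", 100, "A", "G", "assigned",
                              derived_allele="G", branch=ab, loglik=0.0),
            BranchAssignedSNP("chrY", 200, "C", "T", "excluded_multiallelic"),
        ], ab

    def test_coinciding_marker_labels_branch(self, four_tip_tree):
        assignments, ab = self._assignments(four_tip_tree)
        markers = load_markers(
            marker_frame([["M51", "H1a", "chrY", 100, "A", "G"]])
        )
        assert label_branches(four_tip_tree, assignments, markers) == {
            ab: {"H1a"}
        }

    def test_excluded_site_contributes_nothing(self, four_tip_tree):
        assignments, _ = self._assignments(four_tip_tree)
        markers = load_markers(
            marker_frame([["M1", "H2", "chrY", 200, "C", "T"]])
        )
        assert label_branches(four_tip_tree, assignments, markers) == {}

    def test_two_labels_retained(self, four_tip_tree):
        assignments, ab = self._assignments(four_tip_tree)
        markers = load_markers(
            marker_frame(
                [
                    ["M51", "H1a", "chrY", 100, "A", "G"],
                    ["M52", "H1a1", "chrY", 100, "A", "G"],
                ]
            )
        )
        # same position, same derived allele: collapsed to one marker,
        # but distinct derived alleles at one position stay distinct
        markers2 = load_markers(
            marker_frame(
                [
                    ["M51", "H1a", "chrY", 100, "A", "G"],
                    ["M53", "H1b", "chrY", 100, "A", "C"],
                ]
            )
        )
        got = label_branches(four_tip_tree, assignments, markers)
        assert got[ab] == {"H1a"}
        got2 = label_branches(four_tip_tree, assignments, markers2)
        assert got2[ab] == {"H1a"}  # C-derived marker does not match


class TestRefineBelow:
    markers = load_markers(
        marker_frame(
            [
                ["M1", "A1b1b2", "chrY", 100, "A", "G"],
                ["M2", "A1b1b2a", "chrY", 200, "C", "A"],
                ["M3", "A1b1b2b", "chrY", 300, "T", "G"],
                ["M4", "A1b1b2a1", "chrY", 400, "G", "T"],
            ]
        )
    )

    def _anchor(self, four_tip_tree):
        ab = branch_by_clade(four_tip_tree, {"A", "B"})
        return ab, {ab: {"A1b1b2"}}

    def test_one_step_refinement(self, four_tip_tree):
        ab, labels = self._anchor(four_tip_tree)
        calls = [SiteCall("chrY", 200, "derived", base="A")]
        call = refine_below(ab, calls, self.markers, labels, four_tip_tree)
        assert call.terminal == "A1b1b2a"
        assert call.supporting == ["M2"]

    def test_no_marker_data_keeps_anchor(self, four_tip_tree):
        ab, labels = self._anchor(four_tip_tree)
        call = refine_below(ab, [], self.markers, labels, four_tip_tree)
        assert call.terminal == "A1b1b2"
        assert "no-sublineage-data" in call.flags

    def test_sibling_conflict_falls_back_with_alternates(self, four_tip_tree):
        ab, labels = self._anchor(four_tip_tree)
        calls = [
            SiteCall("chrY", 200, "derived", base="A"),
            SiteCall("chrY", 300, "derived", base="G"),
        ]
        call = refine_below(ab, calls, self.markers, labels, four_tip_tree)
        assert call.terminal == "A1b1b2"
        assert set(call.alternates) == {"A1b1b2a", "A1b1b2b"}

    def test_two_step_refinement_with_conflict_listing(self, four_tip_tree):
        ab, labels = self._anchor(four_tip_tree)
        calls = [
            SiteCall("chrY", 400, "derived", base="T"),
            SiteCall("chrY", 200, "ancestral", base="C"),
        ]
        call = refine_below(ab, calls, self.markers, labels, four_tip_tree)
        assert call.terminal == "A1b1b2a1"
        assert "M2" in call.conflicting  # ancestral on the chosen path

    def test_unlabeled_anchor_flagged(self, four_tip_tree):
        ab = branch_by_clade(four_tip_tree, {"A", "B"})
        call = refine_below(ab, [], self.markers, {}, four_tip_tree)
        assert call.terminal is None
        assert "tree-only-placement" in call.flags

    def test_never_escapes_anchor_lineage(self, four_tip_tree):
        ab, labels = self._anchor(four_tip_tree)
        # derived marker for an unrelated lineage must be ignored
        markers = load_markers(
            marker_frame(
                [
                    ["M2", "A1b1b2a", "chrY", 200, "C", "A"],
                    ["MX", "B2b1", "chrY", 500, "A", "T"],
                ]
            )
        )
        calls = [
            SiteCall("chrY", 200, "derived", base="A"),
            SiteCall("chrY", 500, "derived", base="T"),
        ]
        call = refine_below(ab, calls, markers, labels, four_tip_tree)
        assert call.terminal.startswith("A1b1b2")

    def test_provisional_only_support_flagged(self, four_tip_tree):
        ab, labels = self._anchor(four_tip_tree)
        markers = load_markers(
            marker_frame([["M9~", "A1b1b2a", "chrY", 200, "C", "A"]])
        )
        calls = [SiteCall("chrY", 200, "derived", base="A")]
        call = refine_below(ab, calls, markers, labels, four_tip_tree)
        assert call.terminal == "A1b1b2a"
        assert "provisional-support" in call.flags

    def test_monotone_under_added_consistent_data(self, four_tip_tree):
        ab, labels = self._anchor(four_tip_tree)
        calls = [SiteCall("chrY", 200, "derived", base="A")]
        before = refine_below(ab, calls, self.markers, labels, four_tip_tree)
        calls.append(SiteCall("chrY", 400, "derived", base="T"))
        after = refine_below(ab, calls, self.markers, labels, four_tip_tree)
        assert after.terminal.startswith(before.terminal)


class TestSimulatorConsistency:
    def test_terminal_label_matches_true_clade(self):
        cfg = SimConfig(seed=21, n_leaves=16, coverage=8.0)
        ref = sim_reference(cfg)
        mdf = sim_markers(ref)
        branch_label = mdf.attrs["branch_labels"]
        markers = load_markers(mdf)
        query = sim_query(cfg, ref)
        # perfect calls straight from the simulated truth
        calls = []
        for pos, state in query.truth.query_genotype.items():
            base = (
                query.truth.site_der[pos]
                if state == "derived"
                else query.truth.site_anc[pos]
            )
            calls.append(SiteCall(cfg.chrom, pos, state, base=base))
        b_star = query.truth.attachment_branch
        labels = {b: {branch_label[b]} for b in ref.tree.branches}
        call = refine_below(b_star, calls, markers, labels, ref.tree)
        # anchored at the true branch with complete data, the terminal
        # label is the true attachment clade's label
        assert call.terminal == branch_label[b_star]
        assert call.terminal.startswith(call.anchor_label)
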