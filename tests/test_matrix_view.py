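"""Matrix assembly, the three drug sorts, highlighting and SVG rendering."""

import math
import random
from pathlib import Path

import pytest

from medisyn import (
    ConsistencyState,
    RenderConfig,
    TargetKey,
    UnknownTargetError,
    assemble_matrix,
    build_store,
    highlight_sets,
    pactivity,
    render,
    sort_by_potency_sum,
    sort_by_responsive_count,
    sort_by_target,
)
from medisyn.synthesis import canonicalize
from medisyn.uncertainty import cell_effect

from conftest import ba, bm, random_small_store

GOLDEN_SVG = Path(__file__).parent / "data" / "golden_matrix.svg"


class TestAssembleMatrix:
    def test_wild_type_column_auto_added(self):
        store = build_store(
            [bm("D1", "G1(M1A)", "responsive", "guidelines")],
            [ba("D2", "G1(M1A)", 5), ba("D2", "G1", 7)],
        )
        m = assemble_matrix(store, [TargetKey.parse("G1(M1A)")])
        assert [c.display for c in m.columns] == ["G1(M1A)", "G1"]
        assert m.drug_rows == [canonicalize("D1"), canonicalize("D2")]

    def test_no_wild_type_data_means_single_column(self):
        store = build_store([bm("D1", "G1(M1A)", "responsive", "guidelines")], [])
        m = assemble_matrix(store, [TargetKey.parse("G1(M1A)")])
        assert [c.display for c in m.columns] == ["G1(M1A)"]

    def test_same_gene_mutations_share_one_wild_type_column(self):
        store = build_store(
            [
                bm("D1", "G1(M1A)", "responsive", "guidelines"),
                bm("D1", "G1(M2B)", "resistant", "guidelines"),
            ],
            [ba("D1", "G1", 5)],
        )
        m = assemble_matrix(
            store, [TargetKey.parse("G1(M1A)"), TargetKey.parse("G1(M2B)")]
        )
        assert [c.display for c in m.columns] == ["G1(M1A)", "G1(M2B)", "G1"]

    def test_unknown_mutation_suggests_nearest(self):
        store = build_store([bm("D1", "ABL1(T315I)", "responsive", "guidelines")], [])
        with pytest.raises(UnknownTargetError, match=r"ABL1\(T315I\)"):
            assemble_matrix(store, [TargetKey.parse("ABL1(T315X)")])

    def test_wild_type_selection_rejected(self):
        store = build_store([bm("D1", "ABL1(T315I)", "responsive", "guidelines")], [])
        with pytest.raises(ValueError, match="wild-type"):
            assemble_matrix(store, [TargetKey.parse("ABL1")])

    def test_rows_are_union_of_drugs_related_to_any_column(self, golden_store):
        m = assemble_matrix(golden_store, [TargetKey.parse("ABL1(T315I)")])
        expected = set()
        for col in m.columns:
            expected |= golden_store.drugs_of_target(col)
        assert set(m.drug_rows) == expected

    def test_tumor_rows_follow_selected_mutations(self, golden_matrix):
        assert golden_matrix.tumor_rows == [canonicalize("Chronic Myeloid Leukemia")]
        assert (
            canonicalize("Chronic Myeloid Leukemia"),
            TargetKey.parse("ABL1(T315I)"),
        ) in golden_matrix.tumor_cells

    def test_states_partition_all_cells(self, golden_matrix):
        counts = golden_matrix.state_counts()
        assert sum(counts.values()) == len(golden_matrix.drug_rows) * len(
            golden_matrix.columns
        )
        missing = counts[ConsistencyState.MISSING]
        nonempty = sum(
            1
            for c in golden_matrix.cells.values()
            if c.cgi or c.dtc is not None
        )
        assert missing == len(golden_matrix.cells) - nonempty


# ---------------------------------------------------------------------------
# Independent brute-force sort oracles, built from the store (not the model)
# ---------------------------------------------------------------------------


def oracle_sort_by_target(store, matrix, target):
    def info(d):
        pair = (d, target)
        in_cgi = pair in store.cgi_cells
        in_dtc = pair in store.dtc_cells
        if in_cgi and in_dtc:
            g = 0
        elif in_cgi:
            g = 1
        elif in_dtc:
            g = 2
        else:
            g = 3
        med = store.dtc_cells[pair].median_value_nM if in_dtc else None
        return g, med

    out = []
    for idx, d in enumerate(matrix.drug_rows):
        g, med = info(d)
        if g in (0, 2):
            out.append((g, med, d, 0, d))
        elif g == 1:
            out.append((g, 0.0, d, 0, d))
        else:
            out.append((g, 0.0, "", idx, d))
    return [t[-1] for t in sorted(out, key=lambda t: t[:4])]


def oracle_sort_by_potency_sum(store, matrix):
    def score(d):
        total = 0.0
        for mut in matrix.selected_mutations:
            s = store.dtc_cells.get((d, mut))
            if s is not None:
                total += 9.0 - math.log10(s.median_value_nM)
        return total

    return sorted(matrix.drug_rows, key=lambda d: (-score(d), d))


def oracle_sort_by_responsive_count(store, matrix):
    def count(d):
        n = 0
        for mut in matrix.selected_mutations:
            recs = store.cgi_cells.get((d, mut))
            if recs and cell_effect(recs)[0].value == "responsive":
                n += 1
        return n

    return sorted(matrix.drug_rows, key=lambda d: (-count(d), d))


class TestSorting:
    def _three_group_store(self):
        return build_store(
            [
                bm("d1", "G1(M1A)", "responsive", "guidelines"),
                bm("d2", "G1(M1A)", "resistant", "guidelines"),
            ],
            [ba("d1", "G1(M1A)", 50), ba("d3", "G1(M1A)", 5)],
        )

    def test_both_then_cgi_only_then_dtc_only(self):
        store = self._three_group_store()
        m = assemble_matrix(store, [TargetKey.parse("G1(M1A)")])
        assert sort_by_target(m, TargetKey.parse("G1(M1A)")) == ["d1", "d2", "d3"]

    def test_dtc_only_group_most_potent_first(self):
        store = build_store(
            [], [ba("slow", "G1(M1A)", 50), ba("fast", "G1(M1A)", 5)]
        )
        m = assemble_matrix(store, [TargetKey.parse("G1(M1A)")])
        assert sort_by_target(m, TargetKey.parse("G1(M1A)")) == ["fast", "slow"]

    def test_unrelated_drugs_keep_original_order(self):
        store = build_store(
            [
                bm("zz", "G1(M1A)", "responsive", "guidelines"),
                bm("aa", "G2(M2B)", "responsive", "guidelines"),
                bm("mm", "G2(M2B)", "responsive", "guidelines"),
            ],
            [],
        )
        m = assemble_matrix(
            store, [TargetKey.parse("G1(M1A)"), TargetKey.parse("G2(M2B)")]
        )
        order = sort_by_target(m, TargetKey.parse("G1(M1A)"))
        assert order[0] == "zz"
        unrelated = [d for d in m.drug_rows if d != "zz"]
        assert order[1:] == unrelated  # stable

    def test_sort_on_non_column_rejected(self, golden_matrix):
        with pytest.raises(UnknownTargetError):
            sort_by_target(golden_matrix, TargetKey.parse("KIT(D816V)"))

    def test_pactivity_sum_example(self):
        store = build_store(
            [],
            [
                ba("A", "G1(M1A)", 10),
                ba("A", "G2(M2B)", 100),
                ba("B", "G1(M1A)", 10),
            ],
        )
        m = assemble_matrix(
            store, [TargetKey.parse("G1(M1A)"), TargetKey.parse("G2(M2B)")]
        )
        assert pactivity(10) == pytest.approx(8.0)
        assert pactivity(100) == pytest.approx(7.0)
        assert sort_by_potency_sum(m) == ["a", "b"]  # 15 beats 8

    def test_no_dtc_data_falls_back_to_alphabetical(self):
        store = build_store(
            [
                bm("zeta", "G1(M1A)", "responsive", "guidelines"),
                bm("alpha", "G1(M1A)", "responsive", "guidelines"),
            ],
            [],
        )
        m = assemble_matrix(store, [TargetKey.parse("G1(M1A)")])
        assert sort_by_potency_sum(m) == ["alpha", "zeta"]

    def test_responsive_count_descending(self):
        store = build_store(
            [
                bm("A", "G1(M1A)", "responsive", "guidelines"),
                bm("A", "G2(M2B)", "responsive", "guidelines"),
                bm("B", "G1(M1A)", "responsive", "guidelines"),
                bm("C", "G1(M1A)", "resistant", "guidelines"),
            ],
            [],
        )
        m = assemble_matrix(
            store, [TargetKey.parse("G1(M1A)"), TargetKey.parse("G2(M2B)")]
        )
        assert sort_by_responsive_count(m) == ["a", "b", "c"]

    @pytest.mark.parametrize("seed", range(25))
    def test_all_sorts_match_brute_force_on_random_stores(self, seed):
        rng = random.Random(seed)
        store, muts = random_small_store(rng)
        matrix = assemble_matrix(store, muts)
        target = muts[rng.randrange(len(muts))]
        assert sort_by_target(matrix, target) == oracle_sort_by_target(
            store, matrix, target
        )
        assert sort_by_potency_sum(matrix) == oracle_sort_by_potency_sum(store, matrix)
        assert sort_by_responsive_count(matrix) == oracle_sort_by_responsive_count(
            store, matrix
        )
        # every sort is a permutation of the rows
        for order in (
            sort_by_target(matrix, target),
            sort_by_potency_sum(matrix),
            sort_by_responsive_count(matrix),
        ):
            assert sorted(order) == sorted(matrix.drug_rows)


class TestHighlighting:
    def test_drug_focus_highlights_targets_and_their_tumors(self, golden_matrix):
        h = highlight_sets(golden_matrix, ("drug", "axitinib"))
        assert TargetKey.parse("ABL1(T315I)") in h.targets
        assert TargetKey.parse("ABL1") in h.targets  # has wild-type data too
        assert canonicalize("Chronic Myeloid Leukemia") in h.tumors

    def test_cell_focus_highlights_mutation_drug_and_wild_type(self, golden_matrix):
        h = highlight_sets(
            golden_matrix, ("cell", ("bosutinib", TargetKey.parse("ABL1(T315I)")))
        )
        assert h.drugs == {"bosutinib"}
        assert h.targets == {TargetKey.parse("ABL1(T315I)"), TargetKey.parse("ABL1")}

    def test_tumor_focus_highlights_related_mutations(self, golden_matrix):
        h = highlight_sets(
            golden_matrix, ("tumor", canonicalize("Chronic Myeloid Leukemia"))
        )
        assert h.targets == {TargetKey.parse("ABL1(T315I)")}

    def test_unknown_focus_rejected(self, golden_matrix):
        with pytest.raises(KeyError):
            highlight_sets(golden_matrix, ("drug", "nosuchdrug"))


class TestRender:
    def test_identical_input_gives_identical_bytes(self, golden_matrix):
        svg1, json1 = render(golden_matrix)
        svg2, json2 = render(golden_matrix)
        assert svg1 == svg2 and json1 == json2

    def test_golden_file_3x2_matrix(self, golden_matrix):
        svg, _ = render(golden_matrix)
        assert svg == GOLDEN_SVG.read_text(encoding="utf-8")

    def test_conflicting_cell_has_red_bar_with_black_overlay(self, golden_matrix):
        svg, _ = render(golden_matrix)
        cell = next(
            part
            for part in svg.splitlines()
            if 'id="cell:bosutinib:ABL1(T315I)"' in part
        )
        assert 'data-state="conflicting"' in cell
        assert "#C0392B" in cell  # resistant hue at full saturation (rank 5)
        assert 'fill="black"' in cell  # potency overlay bar

    def test_inactive_cell_renders_slash(self, golden_matrix):
        svg, _ = render(golden_matrix)
        cell = next(
            part for part in svg.splitlines() if 'id="cell:axitinib:ABL1"' in part
        )
        assert "<line" in cell and 'stroke="black"' in cell

    def test_missing_cell_has_no_marks(self, golden_matrix):
        svg, _ = render(golden_matrix)
        cell = next(
            part for part in svg.splitlines() if 'id="cell:nilotinib:ABL1"' in part
        )
        assert 'data-state="missing"' in cell
        assert "black" not in cell and "#" not in cell.replace("#DDDDDD", "")

    def test_zero_columns_rejected(self, golden_matrix):
        golden_matrix.columns = []
        with pytest.raises(ValueError):
            render(golden_matrix)

    def test_config_ramps_must_be_monotone(self):
        with pytest.raises(ValueError):
            RenderConfig(saturation_ramp=(0.2, 0.4, 0.4, 0.8, 1.0))
        with pytest.raises(ValueError):
            RenderConfig(potency_width_fractions=(0.3, 0.6, 1.0))
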