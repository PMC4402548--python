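"""Tests for the three enrichment strategies against brute-force oracles."""

import numpy as np
import pytest

from miropa import (
    FixtureSpec,
    PathwayCollection,
    PathwayEntry,
    Signature,
    TargetMap,
    convert_pathways,
    generate,
    map_signature_to_targets,
    strategy1,
    strategy2,
    strategy3,
    tailor_pathways,
)

from _oracles import enumerate_upper_tail


class TestMapSignatureToTargets:
    def test_single_mirna(self, tiny_tmap):
        sig = Signature("s", ("mir-1",))
        assert map_signature_to_targets(sig, tiny_tmap) == {"g1", "g2", "g3"}

    def test_union_of_overlapping_target_sets(self, tiny_tmap):
        sig = Signature("s", ("mir-1", "mir-2"))
        assert map_signature_to_targets(sig, tiny_tmap) == {"g1", "g2", "g3", "g4"}

    def test_no_match_is_an_error(self, tiny_tmap):
        with pytest.raises(ValueError, match="no miRNA"):
            map_signature_to_targets(Signature("s", ("mir-99",)), tiny_tmap)


class TestStrategy1:
    def test_row_p_matches_enumeration(self):
        """12-gene universe, pathway of 5, query of 4 overlapping by 3."""
        genes = [f"g{i}" for i in range(12)]
        # one miRNA targeting exactly 4 genes, 3 of them in the pathway
        tmap = TargetMap.from_pairs([("m1", g) for g in ["g0", "g1", "g2", "g11"]])
        pathways = PathwayCollection(
            entries=[PathwayEntry("P1", "p", frozenset(genes[:5]))],
            member_kind="genes",
        )
        # the annotation universe must span all 12 genes: add a pathway
        # covering the whole gene list
        pathways_full = PathwayCollection(
            entries=[
                PathwayEntry("P1", "p", frozenset(genes[:5])),
                PathwayEntry("P2", "rest", frozenset(genes)),
            ],
            member_kind="genes",
        )
        table = strategy1(Signature("s", ("m1",)), tmap, pathways_full)
        row = table.rows.set_index("pathway_id").loc["P1"]
        assert (row["N"], row["R"], row["n"], row["r"]) == (12, 4, 5, 3)
        assert row["p_value"] == pytest.approx(
            enumerate_upper_tail(12, 4, 5, 3), abs=1e-12
        )

    def test_pathway_disjoint_from_universe_dropped(self, tiny_tmap, tiny_pathways):
        # targeted-gene universe excludes P3 = {g6, g7} entirely
        table = strategy1(
            Signature("s", ("mir-1",)), tiny_tmap, tiny_pathways,
            universe_mode="targeted",
        )
        assert "P3" not in set(table.rows["pathway_id"])
        assert table.metadata["n_pathways_dropped"] == 1

    def test_query_equal_to_universe_forces_p_one(self, tiny_tmap, tiny_pathways):
        # all three miRNAs cover every targeted gene -> query == universe
        sig = Signature("s", ("mir-1", "mir-2", "mir-3"))
        table = strategy1(sig, tiny_tmap, tiny_pathways, universe_mode="targeted")
        assert np.all(table.rows["p_value"] == 1.0)
        assert np.all(table.rows["r"] == table.rows["n"])

    def test_overlap_members_have_length_r(self, tiny_tmap, tiny_pathways):
        table = strategy1(Signature("s", ("mir-1",)), tiny_tmap, tiny_pathways)
        for _, row in table.rows.iterrows():
            assert len(row["overlap_members"]) == row["r"]
            assert list(row["overlap_members"]) == sorted(row["overlap_members"])

    def test_requires_gene_level_collection(self, tiny_tmap):
        converted = PathwayCollection(
            entries=[PathwayEntry("P1", "p", frozenset({"mir-1"}))],
            member_kind="mirnas",
        )
        with pytest.raises(ValueError, match="gene-level"):
            strategy1(Signature("s", ("mir-1",)), tiny_tmap, converted)

    def test_pathway_order_does_not_change_p_values(self, tiny_tmap, tiny_pathways):
        sig = Signature("s", ("mir-1", "mir-2"))
        fwd = strategy1(sig, tiny_tmap, tiny_pathways)
        rev = strategy1(
            sig,
            tiny_tmap,
            PathwayCollection(
                entries=list(reversed(tiny_pathways.entries)), member_kind="genes"
            ),
        )
        a = fwd.rows.set_index("pathway_id")[["p_value", "fdr"]]
        b = rev.rows.set_index("pathway_id")[["p_value", "fdr"]]
        assert a.sort_index().equals(b.sort_index())


class TestTailorPathways:
    def test_intersects_with_targeted_genes(self, tiny_tmap):
        pathways = PathwayCollection(
            entries=[PathwayEntry("P1", "p", frozenset({"g1", "g2", "g9"}))],
            member_kind="genes",
        )
        tailored = tailor_pathways(pathways, tiny_tmap)
        assert tailored.entries[0].members == {"g1", "g2"}

    def test_untargeted_pathway_dropped(self, tiny_tmap, tiny_pathways):
        tailored = tailor_pathways(tiny_pathways, tiny_tmap)
        assert set(tailored.ids) == {"P1", "P2"}

    def test_full_coverage_is_identity(self, tiny_tmap):
        pathways = PathwayCollection(
            entries=[PathwayEntry("P1", "p", frozenset({"g1", "g5"}))],
            member_kind="genes",
        )
        tailored = tailor_pathways(pathways, tiny_tmap)
        assert tailored.entries[0].members == {"g1", "g5"}

    def test_all_emptied_is_an_error(self, tiny_tmap):
        pathways = PathwayCollection(
            entries=[PathwayEntry("P1", "p", frozenset({"gX"}))], member_kind="genes"
        )
        with pytest.raises(ValueError, match="emptied"):
            tailor_pathways(pathways, tiny_tmap)


class TestStrategy2:
    def test_reduces_to_strategy1_when_tmap_covers_all_pathway_genes(self, tiny_tmap):
        pathways = PathwayCollection(
            entries=[
                PathwayEntry("P1", "p", frozenset({"g1", "g2", "g3"})),
                PathwayEntry("P2", "q", frozenset({"g4", "g5"})),
            ],
            member_kind="genes",
        )
        sig = Signature("s", ("mir-1",))
        s2 = strategy2(sig, tiny_tmap, pathways)
        s1 = strategy1(sig, tiny_tmap, pathways, universe_mode="targeted")
        a = s2.rows.set_index("pathway_id")[["N", "R", "n", "r", "p_value", "fdr"]]
        b = s1.rows.set_index("pathway_id")[["N", "R", "n", "r", "p_value", "fdr"]]
        assert a.sort_index().equals(b.sort_index())

    def test_small_instance_matches_enumeration(self):
        # 6 targeted genes; tailored pathway keeps 3; query of 2 overlaps by 1
        tmap = TargetMap.from_pairs(
            [("m1", "g1"), ("m1", "g4"), ("m2", "g2"), ("m2", "g3"),
             ("m3", "g5"), ("m3", "g6")]
        )
        pathways = PathwayCollection(
            entries=[PathwayEntry("P1", "p", frozenset({"g1", "g2", "g3", "gX"}))],
            member_kind="genes",
        )
        table = strategy2(Signature("s", ("m1",)), tmap, pathways)
        row = table.rows.iloc[0]
        assert (row["N"], row["R"], row["n"], row["r"]) == (6, 2, 3, 1)
        assert row["p_value"] == pytest.approx(
            enumerate_upper_tail(6, 2, 3, 1), abs=1e-12
        )

    def test_signature_missing_all_tailored_genes_gives_p_one(self, tiny_tmap):
        pathways = PathwayCollection(
            entries=[PathwayEntry("P1", "p", frozenset({"g5"}))], member_kind="genes"
        )
        table = strategy2(Signature("s", ("mir-1",)), tiny_tmap, pathways)
        assert np.all(table.rows["r"] == 0)
        assert np.all(table.rows["p_value"] == 1.0)


class TestConvertPathways:
    def test_mirna_counted_once_whatever_its_target_count(self):
        tmap = TargetMap.from_pairs([("m1", "g1"), ("m1", "g2"), ("m1", "g3")])
        pathways = PathwayCollection(
            entries=[PathwayEntry("P1", "p", frozenset({"g1", "g2", "g3"}))],
            member_kind="genes",
        )
        converted = convert_pathways(pathways, tmap)
        assert converted.entries[0].members == {"m1"}
        assert len(converted.entries[0].members) == 1

    def test_untargeted_pathway_dropped(self, tiny_tmap, tiny_pathways):
        converted = convert_pathways(tiny_pathways, tiny_tmap)
        assert set(converted.ids) == {"P1", "P2"}
        assert converted.member_kind == "mirnas"

    def test_shared_targeted_gene_appears_in_both_conversions(self, tiny_tmap, tiny_pathways):
        converted = convert_pathways(tiny_pathways, tiny_tmap)
        by_id = {e.pathway_id: e.members for e in converted}
        # g3 is in both P1 and P2 and is hit by mir-1 and mir-2
        assert {"mir-1", "mir-2"} <= by_id["P1"]
        assert {"mir-1", "mir-2"} <= by_id["P2"]

    def test_conversion_contract_on_generated_fixtures(self):
        """Converted size bounded by distinct-miRNA count and by the sum of
        per-gene targeter counts; adding an in-pathway interaction never
        shrinks the converted set."""
        for seed in range(3):
            fx = generate(
                FixtureSpec(n_genes=60, n_mirnas=15, n_pathways=8,
                            pathway_size_range=(3, 10),
                            base_target_prob=0.08, seed=seed)
            )
            converted = convert_pathways(fx.pathways, fx.tmap)
            for entry in converted:
                native = fx.pathways.get(entry.pathway_id).members
                bound = sum(
                    len(fx.tmap.targeters_of.get(g, ())) for g in native
                )
                assert len(entry.members) <= len(fx.tmap.targets_of)
                assert len(entry.members) <= bound
            # monotonicity: add an interaction into the first pathway
            first = converted.entries[0]
            native = fx.pathways.get(first.pathway_id).members
            gene = sorted(native)[0]
            bigger = TargetMap.from_pairs(
                set(fx.tmap.interactions) | {("mir-new", gene)}
            )
            reconverted = convert_pathways(fx.pathways, bigger)
            assert first.members <= reconverted.get(first.pathway_id).members


class TestStrategy3:
    def _world(self):
        """12-miRNA universe; converted pathway of 5; signature of 4, overlap 3."""
        mirnas = [f"m{i}" for i in range(12)]
        tmap = TargetMap.from_pairs(
            [(m, "gP") for m in mirnas[:5]] + [(m, "gQ") for m in mirnas[5:]]
        )
        converted = PathwayCollection(
            entries=[PathwayEntry("P1", "p", frozenset(mirnas[:5]))],
            member_kind="mirnas",
        )
        signature = Signature("s", ("m0", "m1", "m2", "m11"))
        return signature, converted, tmap

    def test_row_p_matches_enumeration(self):
        signature, converted, tmap = self._world()
        table = strategy3(signature, converted, tmap)
        row = table.rows.iloc[0]
        assert (row["N"], row["R"], row["n"], row["r"]) == (12, 4, 5, 3)
        assert row["p_value"] == pytest.approx(
            enumerate_upper_tail(12, 4, 5, 3), abs=1e-12
        )

    def test_disjoint_signature_gives_all_p_one(self):
        _, converted, tmap = self._world()
        table = strategy3(Signature("s", ("m8", "m9")), converted, tmap)
        assert np.all(table.rows["p_value"] == 1.0)
        assert len(table.selected()) == 0

    def test_exact_pathway_signature_ranks_first(self):
        """A signature equal to one converted pathway attains the minimal
        p-value across all rows (checked against the enumeration oracle)."""
        mirnas = [f"m{i}" for i in range(10)]
        tmap = TargetMap.from_pairs([(m, "g0") for m in mirnas])
        converted = PathwayCollection(
            entries=[
                PathwayEntry("A", "a", frozenset(mirnas[:4])),
                PathwayEntry("B", "b", frozenset(mirnas[3:8])),
                PathwayEntry("C", "c", frozenset(mirnas[8:])),
            ],
            member_kind="mirnas",
        )
        signature = Signature("s", tuple(mirnas[:4]))
        table = strategy3(signature, converted, tmap)
        rows = table.rows.set_index("pathway_id")
        for pid, n, r in [("A", 4, 4), ("B", 5, 1), ("C", 2, 0)]:
            assert rows.loc[pid, "p_value"] == pytest.approx(
                enumerate_upper_tail(10, 4, n, r), abs=1e-12
            )
        assert rows["p_value"].idxmin() == "A"

    def test_requires_converted_collection(self, tiny_tmap, tiny_pathways):
        with pytest.raises(ValueError, match="miRNA-level"):
            strategy3(Signature("s", ("mir-1",)), tiny_pathways, tiny_tmap)
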