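"""Ortholog filtering, block detection, inversion distance and scenarios."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpmap.simulate import RearrangementScenario, apply_reversal, derive_reference_orders
from fpmap.synteny import (
    OrthologHit,
    Projection,
    call_inversions,
    detect_blocks,
    filter_ortholog_hits,
    inversion_distance,
    project_markers,
    scenario_consistent,
    search_scenarios,
)


def hit(marker, species="rice", gene="LOC1", pos=100.0, strand=1, evalue=1e-30):
    return OrthologHit(marker, species, gene, pos, strand, evalue)


class TestFilterHits:
    THRESHOLDS = {"rice": 1e-10, "barley": 1e-20}

    def test_weak_hit_removed(self):
        assert filter_ortholog_hits([hit("m1", evalue=1e-5)], self.THRESHOLDS) == []

    def test_best_hit_kept_per_marker_species(self):
        hits = [hit("m1", gene="A", evalue=1e-15), hit("m1", gene="B", evalue=1e-30)]
        (kept,) = filter_ortholog_hits(hits, self.THRESHOLDS)
        assert kept.reference_gene_id == "B"

    def test_boundary_evalue_retained(self):
        (kept,) = filter_ortholog_hits([hit("m1", evalue=1e-10)], self.THRESHOLDS)
        assert kept.evalue == 1e-10

    def test_evalue_tie_broken_lexicographically(self):
        hits = [hit("m1", gene="Z", evalue=1e-30), hit("m1", gene="A", evalue=1e-30)]
        (kept,) = filter_ortholog_hits(hits, self.THRESHOLDS)
        assert kept.reference_gene_id == "A"

    def test_species_without_threshold_dropped(self):
        assert filter_ortholog_hits([hit("m1", species="maize")], self.THRESHOLDS) == []

    def test_per_species_thresholds(self):
        hits = [hit("m1", species="rice", evalue=1e-12), hit("m1", species="barley", evalue=1e-12)]
        kept = filter_ortholog_hits(hits, self.THRESHOLDS)
        assert [h.species for h in kept] == ["rice"]


class TestProjection:
    def test_map_order_preserved(self):
        hits = [hit(f"m{i}", pos=10.0 * i) for i in range(5)]
        proj = project_markers([f"m{i}" for i in range(5)], hits, "rice")
        assert [p for _, p, _ in proj.entries] == [0.0, 10.0, 20.0, 30.0, 40.0]

    def test_unmatched_markers_counted(self):
        hits = [hit("m0")]
        proj = project_markers(["m0", "m1", "m2"], hits, "rice")
        assert len(proj.entries) == 1 and proj.unmatched_count == 2

    def test_absent_species_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            project_markers(["m0"], [hit("m0")], "maize")

    def test_projection_matches_scenario_derived_truth(self):
        sc = RearrangementScenario((1, 2, 3, 4), {"barley": ((2, 3),)})
        (order,) = derive_reference_orders(sc).values()
        # one marker per segment, reference position = rank in lineage order
        rank = {abs(seg): i for i, seg in enumerate(order)}
        hits = [
            hit(f"m{seg}", species="barley", pos=(rank[seg] + 1) * 10.0)
            for seg in (1, 2, 3, 4)
        ]
        proj = project_markers([f"m{s}" for s in (1, 2, 3, 4)], hits, "barley")
        assert [p for _, p, _ in proj.entries] == [10.0, 30.0, 20.0, 40.0]


def projection_from_positions(positions, species="rice"):
    return Projection(
        species, tuple((f"m{i}", float(p), 1) for i, p in enumerate(positions))
    )


class TestBlocks:
    def test_ascending_single_block(self):
        blocks, un = detect_blocks(projection_from_positions([1, 2, 3, 4]))
        assert len(blocks) == 1 and blocks[0].orientation == 1 and not un

    def test_descending_single_block(self):
        blocks, _ = detect_blocks(projection_from_positions([9, 7, 4, 2]))
        assert len(blocks) == 1 and blocks[0].orientation == -1

    def test_embedded_inversion_three_blocks(self):
        blocks, un = detect_blocks(
            projection_from_positions([1, 2, 3, 4, 5, 8, 7, 6, 9, 10, 11, 12])
        )
        assert [b.orientation for b in blocks] == [1, -1, 1]
        assert blocks[1].marker_ids == ("m5", "m6", "m7")
        assert not un

    def test_short_runs_reported_unassigned(self):
        blocks, un = detect_blocks(projection_from_positions([1, 2, 3, 9, 4, 5, 6]), min_len=3)
        assert "m3" in un

    def test_large_gap_splits_block(self):
        blocks, _ = detect_blocks(
            projection_from_positions([1, 2, 3, 500, 501, 502]), max_gap_kb=100
        )
        assert len(blocks) == 2

    def test_every_marker_in_exactly_one_block_or_unassigned(self):
        positions = [5, 1, 2, 3, 9, 8, 7, 4, 6, 10]
        proj = projection_from_positions(positions)
        blocks, un = detect_blocks(proj)
        covered = [m for b in blocks for m in b.marker_ids] + un
        assert sorted(covered) == sorted(m for m, _, _ in proj.entries)

    def test_orientation_flips_under_sequence_reversal(self):
        positions = [1, 2, 3, 4, 8, 7, 6, 5, 9, 10, 11]
        fwd, _ = detect_blocks(projection_from_positions(positions))
        rev, _ = detect_blocks(projection_from_positions(positions[::-1]))
        assert [b.orientation for b in rev] == [-b.orientation for b in reversed(fwd)]


class TestInversionCalls:
    def test_minus_block_between_plus_blocks(self):
        blocks, _ = detect_blocks(
            projection_from_positions([1, 2, 3, 8, 7, 6, 9, 10])
        )
        calls = call_inversions(blocks)
        assert len(calls) == 1
        assert calls[0].map_span == ("m3", "m5")
        assert calls[0].reference_interval_kb == (6.0, 8.0)

    def test_distal_window_inversion_structure(self):
        """Markers of three distal contigs hitting a reference window in
        descending order yield one inversion call on that window."""
        window = [1105.0, 1000.0, 920.0, 834.0]  # descending kb in the window
        context = [1500.0, 1600.0, 1700.0]
        blocks, _ = detect_blocks(projection_from_positions(window + context))
        calls = call_inversions(blocks)
        assert len(calls) == 1
        assert calls[0].reference_interval_kb == (834.0, 1105.0)

    def test_applied_reversal_redetected_with_same_extent(self):
        identity = list(range(1, 13))
        start, end = 4, 9  # 1-based inclusive segment positions
        rearranged = identity[: start - 1] + identity[start - 1 : end][::-1] + identity[end:]
        blocks, _ = detect_blocks(projection_from_positions(rearranged))
        (call,) = call_inversions(blocks)
        assert call.marker_ids == tuple(f"m{i}" for i in range(start - 1, end))
        assert call.reference_interval_kb == (float(start), float(end))


def oracle_distance(perm):
    """Independent exhaustive search: iterative deepening over reversals."""
    identity = tuple(range(1, len(perm) + 1))

    def reversals(order):
        n = len(order)
        for i in range(n):
            for j in range(i, n):
                yield order[:i] + tuple(-x for x in reversed(order[i : j + 1])) + order[j + 1 :]

    frontier = {perm}
    depth = 0
    seen = {perm}
    while identity not in frontier:
        depth += 1
        frontier = {nxt for cur in frontier for nxt in reversals(cur)} - seen
        seen |= frontier
    return depth


def all_signed_perms(n):
    for perm in itertools.permutations(range(1, n + 1)):
        for signs in itertools.product((1, -1), repeat=n):
            yield tuple(p * s for p, s in zip(perm, signs))


class TestInversionDistance:
    def test_identity_is_zero(self):
        assert inversion_distance((1, 2, 3)) == 0

    def test_single_flip(self):
        assert inversion_distance((1, -2, 3)) == 1

    def test_guard_on_large_n(self):
        with pytest.raises(ValueError, match="max_n"):
            inversion_distance(tuple(range(1, 10)), max_n=8)

    def test_invalid_permutation_rejected(self):
        with pytest.raises(ValueError):
            inversion_distance((1, 1, 2))

    def test_all_n3_match_independent_oracle(self):
        for perm in all_signed_perms(3):
            assert inversion_distance(perm) == oracle_distance(perm)

    def test_distance_properties_n3(self):
        for perm in all_signed_perms(3):
            d = inversion_distance(perm)
            assert (d == 0) == (perm == (1, 2, 3))
            assert d <= 4  # n + 1 bound
            # distance to sort the inverse permutation is identical
            inv = [0] * 3
            for pos, val in enumerate(perm, start=1):
                inv[abs(val) - 1] = pos if val > 0 else -pos
            assert inversion_distance(tuple(inv)) == d


FIG_SCENARIO = RearrangementScenario(
    (1, 2, 3, 4, 5),
    {"Aegilops": ((5, 5), (1, 2)), "Hordeum": ((5, 5), (2, 3))},
)

# observed pairwise orientation pattern: the proximal segment is collinear
# between the two Triticeae lineages but inverted against the ancestral
# (rice/Brachypodium-like) order; segment 3 is collinear Aegilops~ancestor
# yet inverted Hordeum~ancestor.
OBSERVED = {
    ("5", ("Aegilops", "Hordeum")): "collinear",
    ("5", ("Aegilops", "ancestor")): "inverted",
    ("5", ("Hordeum", "ancestor")): "inverted",
    ("3", ("Aegilops", "ancestor")): "collinear",
    ("3", ("Hordeum", "ancestor")): "inverted",
    ("3", ("Aegilops", "Hordeum")): "inverted",
    ("4", ("Aegilops", "Hordeum")): "unknown",
}


class TestScenarioConsistency:
    def test_nested_inversion_scenario_matches_observed_pattern(self):
        report = scenario_consistent(FIG_SCENARIO, OBSERVED, ancestor_lineages=("ancestor",))
        assert report.consistent
        verdicts = {(seg, pair): v for seg, pair, _, _, v in report.details}
        assert verdicts[("5", "Aegilops~Hordeum")] == "match"
        assert verdicts[("4", "Aegilops~Hordeum")] == "unknown"

    def test_empty_scenario_conflicts_with_observed_inversion(self):
        empty = RearrangementScenario((1, 2, 3, 4, 5), {"Aegilops": (), "Hordeum": ()})
        report = scenario_consistent(empty, OBSERVED, ancestor_lineages=("ancestor",))
        assert not report.consistent

    def test_unknown_segment_label_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            scenario_consistent(
                FIG_SCENARIO, {("9", ("Aegilops", "ancestor")): "collinear"},
                ancestor_lineages=("ancestor",),
            )

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_scenario_self_consistency(self, data):
        """Observations generated from a scenario's own derived orders are
        always consistent with that scenario."""
        n = data.draw(st.integers(2, 5))
        lineages = ("A", "B")
        ops = {
            lin: tuple(
                data.draw(
                    st.lists(
                        st.tuples(st.integers(1, n), st.integers(1, n)).map(
                            lambda ab: (min(ab), max(ab))
                        ),
                        max_size=2,
                    )
                )
            )
            for lin in lineages
        }
        sc = RearrangementScenario(tuple(range(1, n + 1)), ops)
        orders = derive_reference_orders(sc)
        signs = {
            lin: {abs(x): (1 if x > 0 else -1) for x in order}
            for lin, order in orders.items()
        }
        observed = {
            (str(seg), ("A", "B")): (
                "collinear" if signs["A"][seg] == signs["B"][seg] else "inverted"
            )
            for seg in range(1, n + 1)
        }
        assert scenario_consistent(sc, observed).consistent

    def test_search_recovers_a_consistent_scenario(self):
        observed = {
            ("1", ("A", "ancestor")): "inverted",
            ("2", ("A", "ancestor")): "collinear",
            ("3", ("A", "ancestor")): "collinear",
        }
        found = search_scenarios(observed, 3, ("A",), ancestor_lineages=("ancestor",), max_ops_per_lineage=1)
        assert found
        assert all(
            scenario_consistent(s, observed, ancestor_lineages=("ancestor",)).consistent
            for s in found
        )


class TestEndToEnd:
    def test_simulate_project_detect_call_recovers_reversal(self):
        """A lineage-specific reversal survives the whole chain: scenario ->
        reference order -> projection -> block detection -> inversion call."""
        n = 12
        sc = RearrangementScenario(tuple(range(1, n + 1)), {"barley": ((4, 9),)})
        (order,) = derive_reference_orders(sc).values()
        rank = {abs(seg): i for i, seg in enumerate(order)}
        hits = [
            OrthologHit(f"m{seg}", "barley", f"HV_{seg}", (rank[seg] + 1) * 10.0,
                        1 if order[rank[seg]] > 0 else -1)
            for seg in range(1, n + 1)
        ]
        proj = project_markers([f"m{s}" for s in range(1, n + 1)], hits, "barley")
        blocks, unassigned = detect_blocks(proj)
        assert not unassigned
        (call,) = call_inversions(blocks)
        assert call.marker_ids == tuple(f"m{s}" for s in range(4, 10))
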