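import pytest

from attapriori.annotation import (
    EC_MARKER_SCHEME,
    AnnotationConfigError,
    ExclusiveGroup,
    MarkerScheme,
    absent_components,
    call_viability,
    check_validity,
    classify_behavior,
    dedupe_and_census,
)
from attapriori.dynamics import Attractor, canonical_cycle

NODES = ("AKT", "JAGa", "NRP1", "DLL4a")


def att(*states):
    return Attractor(canonical_cycle(tuple(tuple(s) for s in states)))


class TestClassifyBehavior:
    def test_phalanx_signature(self):
        # AKT=1, JAGa=0, NRP1=0 stable across the cycle
        a = att((1, 0, 0, 0), (1, 0, 0, 1))
        assert classify_behavior(a, EC_MARKER_SCHEME, NODES) == "phalanx"

    def test_tip_signature(self):
        a = att((0, 0, 1, 1))
        assert classify_behavior(a, EC_MARKER_SCHEME, NODES) == "tip"

    def test_stalk_signature(self):
        a = att((0, 1, 0, 0))
        assert classify_behavior(a, EC_MARKER_SCHEME, NODES) == "stalk"

    def test_oscillating_marker_is_atypical(self):
        # JAGa alternates 0/1: no stable signature
        a = att((1, 0, 0, 0), (1, 1, 0, 0))
        assert classify_behavior(a, EC_MARKER_SCHEME, NODES) == "atypical"

    def test_non_matching_stable_signature_is_atypical(self):
        a = att((1, 1, 1, 0))
        assert classify_behavior(a, EC_MARKER_SCHEME, NODES) == "atypical"

    def test_phase_invariance(self):
        a = att((1, 0, 0, 0), (1, 0, 0, 1))
        b = att((1, 0, 0, 1), (1, 0, 0, 0))
        assert classify_behavior(a, EC_MARKER_SCHEME, NODES) == classify_behavior(
            b, EC_MARKER_SCHEME, NODES
        )

    def test_unknown_marker_node(self):
        scheme = MarkerScheme(behaviors={"x": {"GHOST": 1}})
        with pytest.raises(AnnotationConfigError):
            classify_behavior(att((0, 0, 0, 0)), scheme, NODES)

    def test_overlapping_user_scheme_raises(self):
        scheme = MarkerScheme(behaviors={"a": {"AKT": 1}, "b": {"JAGa": 0}})
        with pytest.raises(AnnotationConfigError, match="overlap"):
            classify_behavior(att((1, 0, 0, 0)), scheme, NODES)


STAGES = ("licensed", "replicating", "replicated", "other")
GROUP = ExclusiveGroup("DNA", ("licensed", "replicating", "replicated"))


class TestValidity:
    def test_exactly_one_true_everywhere_is_valid(self):
        a = att((1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0))
        verdict, violations = check_validity(a, [GROUP], STAGES)
        assert verdict == "valid" and violations == []

    def test_two_true_members_invalid(self):
        a = att((1, 1, 0, 0))
        verdict, violations = check_validity(a, [GROUP], STAGES)
        assert verdict == "invalid"
        assert "DNA" in violations[0] and "2 true" in violations[0]

    def test_zero_true_members_invalid(self):
        a = att((1, 0, 0, 0), (0, 0, 0, 1))
        verdict, violations = check_validity(a, [GROUP], STAGES)
        assert verdict == "invalid"

    def test_required_component_must_be_present(self):
        a = att((1, 0, 0, 0))
        verdict, violations = check_validity(
            a, [GROUP], STAGES, required_components={"polymerase": ("other",)}
        )
        assert verdict == "invalid" and "polymerase" in violations[0]

    def test_matches_exhaustive_checker(self):
        """Spot-check against a direct state-by-state re-implementation."""
        import itertools

        for cycle_bits in itertools.product(range(8), repeat=2):
            cycle = tuple(
                tuple(int(c) for c in f"{v:03b}") + (0,) for v in cycle_bits
            )
            if len(set(cycle)) != len(cycle):
                continue
            a = Attractor(canonical_cycle(cycle))
            verdict, _ = check_validity(a, [GROUP], STAGES)
            brute = all(
                sum(s[:3]) == 1 for s in a.cycle
            )
            assert (verdict == "valid") == brute


class TestViability:
    def test_point_attractor_is_lethal(self):
        a = att((1, 0, 0, 0))
        assert call_viability(a, [GROUP], STAGES) == "lethal"

    def test_traversing_cycle_is_viable(self):
        a = att((1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0))
        assert call_viability(a, [GROUP], STAGES) == "viable"

    def test_stuck_cycle_is_lethal(self):
        # periodic but never leaves 'licensed' (the 4th node oscillates)
        a = att((1, 0, 0, 0), (1, 0, 0, 1))
        assert call_viability(a, [GROUP], STAGES) == "lethal"

    def test_invalid_attractor_rejected(self):
        a = att((1, 1, 0, 0))
        with pytest.raises(ValueError):
            call_viability(a, [GROUP], STAGES)

    def test_viable_implies_periodic_and_valid(self):
        import itertools

        for cycle_len in (1, 2, 3):
            for combo in itertools.combinations(range(8), cycle_len):
                cycle = tuple(tuple(int(c) for c in f"{v:03b}") + (0,) for v in combo)
                a = Attractor(canonical_cycle(cycle))
                verdict, _ = check_validity(a, [GROUP], STAGES)
                if verdict != "valid":
                    continue
                if call_viability(a, [GROUP], STAGES) == "viable":
                    assert not a.is_point


CMAP = {"geneA": ("A_p", "A_0"), "geneB": ("B_0",)}
CNODES = ("A_p", "A_0", "B_0", "stage1", "stage2")


class TestAbsentComponents:
    def test_identical_attractors_yield_no_absences(self):
        a = att((1, 0, 1, 1, 0))
        report = absent_components(a, a, CMAP, CNODES)
        assert report.absent == []
        # residue lists constitutively-zero uncovered nodes regardless of ref
        assert report.residue == ["stage2"]

    def test_deleted_component_reported(self):
        ref = att((0, 1, 1, 1, 0))  # geneA present via A_0
        mut = att((0, 0, 1, 1, 0))  # both A nodes constitutively 0
        report = absent_components(mut, ref, CMAP, CNODES)
        assert report.absent == ["geneA"]

    def test_component_absent_in_reference_not_reported(self):
        ref = att((0, 0, 1, 1, 0))
        mut = att((0, 0, 1, 0, 1))
        report = absent_components(mut, ref, CMAP, CNODES)
        assert report.absent == []

    def test_uncovered_zero_node_in_residue(self):
        ref = att((1, 0, 1, 1, 0))
        mut = att((1, 0, 1, 0, 1))  # stage1 constitutively 0, not in any component
        report = absent_components(mut, ref, CMAP, CNODES)
        assert report.residue == ["stage1"]

    def test_unknown_node_in_map(self):
        with pytest.raises(AnnotationConfigError):
            absent_components(att((0,) * 5), att((0,) * 5), {"g": ("GHOST",)}, CNODES)


class TestCensus:
    def test_phase_copies_collapse(self):
        a = att((0, 1, 1), (1, 0, 0))
        b = att((1, 0, 0), (0, 1, 1))
        df = dedupe_and_census([a, b, a])
        assert len(df) == 1 and int(df["count"].iloc[0]) == 3

    def test_example_census(self, net3):
        from attapriori.dynamics import enumerate_all_attractors

        df = dedupe_and_census(sorted(enumerate_all_attractors(net3), key=lambda x: x.cycle))
        assert df["count"].sum() == 3
        assert sorted(df["period"]) == [1, 1, 2]
        assert (df[df["period"] == 1]["kind"] == "point").all()

    def test_counts_partition_input_with_labels(self):
        a = att((0, 0, 0))
        b = att((1, 0, 1))
        df = dedupe_and_census([a, b, a, b, b], labels=["x", "y", "x", "y", "y"])
        assert df["count"].sum() == 5
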