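import itertools
import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemlit.model import CompoundEntity
from chemlit.structure_map import (
    NOT_A_LABEL,
    BoundingBox,
    ComponentKind,
    LabelPattern,
    MappingEntry,
    PageComponent,
    RomanParseError,
    classify_label,
    join_entities_with_structures,
    map_structures_to_labels,
    read_mapping_table,
    roman_to_int,
    write_mapping_table,
)


def _component(cid, kind, x, y, w=10.0, h=10.0, payload="C"):
    return PageComponent(
        component_id=cid, page=1, kind=kind,
        box=BoundingBox(x, y, x + w, y + h), payload=payload,
    )


def brute_force_min_cost(structures, labels):
    """Independent oracle: minimum total centroid distance over all
    injective assignments of the smaller side into the larger."""
    def dist(s, l):
        (ax, ay), (bx, by) = s.box.centroid, l.box.centroid
        return math.hypot(ax - bx, ay - by)

    n, m = len(structures), len(labels)
    best = math.inf
    if n <= m:
        for perm in itertools.permutations(range(m), n):
            best = min(best, sum(dist(structures[i], labels[perm[i]])
                                 for i in range(n)))
    else:
        for perm in itertools.permutations(range(n), m):
            best = min(best, sum(dist(structures[perm[j]], labels[j])
                                 for j in range(m)))
    return best


class TestClassifyLabel:
    @pytest.mark.parametrize(
        "text,normalized,pattern_parts,numeric",
        [
            ("VI", "VI", {LabelPattern.ROMAN}, 6),
            ("(5')", "5'", {LabelPattern.ARABIC, LabelPattern.PRIMED,
                            LabelPattern.PARENTHESIZED}, 5),
            ("1-1", "1-1", {LabelPattern.DASHED}, None),
            ("XIV", "XIV", {LabelPattern.ROMAN}, 14),
            ("10", "10", {LabelPattern.ARABIC}, 10),
            ("(VI)", "VI", {LabelPattern.ROMAN, LabelPattern.PARENTHESIZED}, 6),
            ("3-10'", "3-10'", {LabelPattern.DASHED, LabelPattern.PRIMED}, None),
        ],
    )
    def test_accepted(self, text, normalized, pattern_parts, numeric):
        parse = classify_label(text)
        assert parse is not NOT_A_LABEL
        assert parse.normalized == normalized
        for part in pattern_parts:
            assert part in parse.pattern
        assert parse.numeric_value == numeric

    @pytest.mark.parametrize(
        "text", ["Figure", "", "R1", "1a", "IIV", "((1))", "1''", "(1", "-3"]
    )
    def test_rejected(self, text):
        assert classify_label(text) is NOT_A_LABEL

    def test_closed_under_one_wrap_only(self):
        for core in ["1", "VI", "3-10"]:
            assert classify_label(core) is not NOT_A_LABEL
            assert classify_label(f"({core})") is not NOT_A_LABEL
            assert classify_label(f"{core}'") is not NOT_A_LABEL
            assert classify_label(f"(({core}))") is NOT_A_LABEL
            assert classify_label(f"{core}''") is NOT_A_LABEL


class TestRoman:
    def test_examples(self):
        assert roman_to_int("I") == 1
        assert roman_to_int("X") == 10
        assert roman_to_int("IX") == 9

    def test_against_brute_force_table(self):
        # independent oracle: compose canonical numerals additively
        tens = ["", "X", "XX", "XXX", "XL", "L", "LX", "LXX", "LXXX", "XC"]
        ones = ["", "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX"]
        for n in range(1, 100):
            numeral = tens[n // 10] + ones[n % 10]
            assert roman_to_int(numeral) == n

    def test_malformed(self):
        for bad in ["IIV", "VX", "", "IIII", "ABC"]:
            with pytest.raises(RomanParseError):
                roman_to_int(bad)


class TestAssignment:
    def test_single_pair_distance(self):
        s = _component("s1", ComponentKind.STRUCTURE, 95, 95, payload="CCO")
        l = _component("l1", ComponentKind.LABEL_CANDIDATE, 95, 135, payload="1")
        entries = map_structures_to_labels([s], [l])
        assert len(entries) == 1
        assert entries[0].distance == pytest.approx(40.0)
        assert entries[0].smiles == "CCO"

    @pytest.mark.parametrize("n,m", [(3, 3), (2, 3), (3, 2), (4, 4), (1, 5)])
    def test_optimal_vs_brute_force(self, n, m):
        rng = random.Random(n * 100 + m)
        for _ in range(20):
            structures = [
                _component(f"s{i}", ComponentKind.STRUCTURE,
                           rng.uniform(0, 500), rng.uniform(0, 500))
                for i in range(n)
            ]
            labels = [
                _component(f"l{j}", ComponentKind.LABEL_CANDIDATE,
                           rng.uniform(0, 500), rng.uniform(0, 500),
                           payload=str(j + 1))
                for j in range(m)
            ]
            entries = map_structures_to_labels(structures, labels)
            assert len(entries) == min(n, m)
            total = sum(e.distance for e in entries)
            assert total == pytest.approx(brute_force_min_cost(structures, labels))

    def test_rectangular_reports_unmatched(self):
        structures = [
            _component("s1", ComponentKind.STRUCTURE, 0, 0),
            _component("s2", ComponentKind.STRUCTURE, 100, 0),
        ]
        labels = [
            _component(f"l{j}", ComponentKind.LABEL_CANDIDATE, j * 100, 30,
                       payload=str(j + 1))
            for j in range(3)
        ]
        warnings = []
        entries = map_structures_to_labels(structures, labels, warnings=warnings)
        assert len(entries) == 2
        assert any("unmatched label" in w for w in warnings)

    def test_empty_structures_warns(self):
        warnings = []
        assert map_structures_to_labels([], [], warnings=warnings) == []
        assert warnings

    def test_assignment_is_injective_both_ways(self):
        rng = random.Random(5)
        structures = [
            _component(f"s{i}", ComponentKind.STRUCTURE,
                       rng.uniform(0, 300), rng.uniform(0, 300))
            for i in range(5)
        ]
        labels = [
            _component(f"l{j}", ComponentKind.LABEL_CANDIDATE,
                       rng.uniform(0, 300), rng.uniform(0, 300),
                       payload=str(j + 1))
            for j in range(5)
        ]
        entries = map_structures_to_labels(structures, labels)
        assert len({e.structure_id for e in entries}) == 5
        assert len({e.label_normalized for e in entries}) == 5

    @given(dx=st.floats(-1000, 1000), dy=st.floats(-1000, 1000),
           seed=st.integers(0, 20))
    @settings(max_examples=40, derandomize=True)
    def test_translation_invariance(self, dx, dy, seed):
        rng = random.Random(seed)
        coords = [(rng.uniform(0, 300), rng.uniform(0, 300)) for _ in range(6)]
        structures = [
            _component(f"s{i}", ComponentKind.STRUCTURE, x, y)
            for i, (x, y) in enumerate(coords[:3])
        ]
        labels = [
            _component(f"l{j}", ComponentKind.LABEL_CANDIDATE, x, y,
                       payload=str(j + 1))
            for j, (x, y) in enumerate(coords[3:])
        ]
        base = map_structures_to_labels(structures, labels)
        shifted_s = [
            _component(s.component_id, s.kind, s.box.x_min + dx, s.box.y_min + dy,
                       payload=s.payload)
            for s in structures
        ]
        shifted_l = [
            _component(l.component_id, l.kind, l.box.x_min + dx, l.box.y_min + dy,
                       payload=l.payload)
            for l in labels
        ]
        shifted = map_structures_to_labels(shifted_s, shifted_l)
        assert [(e.structure_id, e.label_normalized) for e in base] == [
            (e.structure_id, e.label_normalized) for e in shifted
        ]


class TestMappingTableAndJoin:
    def test_round_trip(self, tmp_path):
        entries = [
            MappingEntry("1", "s1", "CCO", "m/s1.mol", 40.0),
            MappingEntry("2", "s2", "c1ccccc1", None, 12.5),
        ]
        path = tmp_path / "mapping.tsv"
        write_mapping_table(entries, path)
        assert read_mapping_table(path) == entries

    def test_empty_table_is_header_only(self, tmp_path):
        path = tmp_path / "mapping.tsv"
        write_mapping_table([], path)
        assert path.read_text().strip().count("\n") == 0
        assert read_mapping_table(path) == []

    def test_join_attaches_structure(self):
        compounds = [CompoundEntity("taxol", label="1"),
                     CompoundEntity("foolide", label="7")]
        mapping = [MappingEntry("1", "s1", "CCO")]
        join_entities_with_structures(compounds, mapping)
        assert compounds[0].structure.smiles == "CCO"
        assert compounds[1].structure is None

    def test_join_normalizes_parenthesized_labels(self):
        compounds = [CompoundEntity("taxol", label="1")]
        mapping = [MappingEntry("(1)", "s1", "CCO")]
        join_entities_with_structures(compounds, mapping)
        assert compounds[0].structure.smiles == "CCO"

    def test_duplicate_label_keeps_first_and_warns(self):
        compounds = [CompoundEntity("taxol", label="1")]
        mapping = [MappingEntry("1", "s1", "CCO"), MappingEntry("1", "s2", "CCN")]
        warnings = []
        join_entities_with_structures(compounds, mapping, warnings)
        assert compounds[0].structure.structure_id == "s1"
        assert warnings
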