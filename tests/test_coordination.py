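import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemlit.config import DEFAULT_CONFIG
from chemlit.coordination import (
    RangeError,
    RangeKind,
    RangeSpec,
    expand_range,
    resolve,
    singularize_head,
)
from chemlit.tokenizer import tag_chemicals, tokenize


def run(text, warnings=None):
    return resolve(tag_chemicals(tokenize(text)), DEFAULT_CONFIG, warnings)


@pytest.mark.parametrize(
    "spec,expected",
    [
        (RangeSpec("A", "C", RangeKind.LETTER), ["A", "B", "C"]),
        (RangeSpec("1", "3", RangeKind.NUMBER), ["1", "2", "3"]),
        (RangeSpec("C", "G", RangeKind.LETTER), ["C", "D", "E", "F", "G"]),
        (RangeSpec("5", "5", RangeKind.NUMBER), ["5"]),
    ],
)
def test_expand_range(spec, expected):
    assert expand_range(spec) == expected


def test_expand_range_errors():
    with pytest.raises(RangeError):
        expand_range(RangeSpec("C", "A", RangeKind.LETTER))
    with pytest.raises(RangeError):
        expand_range(RangeSpec("1", "1000", RangeKind.NUMBER))


@pytest.mark.parametrize(
    "name,distributing,expected",
    [
        ("multiplolides", True, "multiplolide"),
        ("drechslerines", True, "drechslerine"),
        ("taxol", False, "taxol"),
        ("glass", True, "glass"),  # double-s heads are never stripped
    ],
)
def test_singularize_head(name, distributing, expected):
    assert singularize_head(name, distributing) == expected


@pytest.mark.parametrize(
    "text,expected",
    [
        (
            "multiplolides A (1) and B (2)",
            [("multiplolide A", "1"), ("multiplolide B", "2")],
        ),
        (
            "drechslerines C-G (6-10)",
            [
                ("drechslerine C", "6"), ("drechslerine D", "7"),
                ("drechslerine E", "8"), ("drechslerine F", "9"),
                ("drechslerine G", "10"),
            ],
        ),
        (
            "compounds A to C",
            [("compound A", None), ("compound B", None), ("compound C", None)],
        ),
        ("taxol (1)", [("taxol", "1")]),
        (
            "aigialomycins A-E (2-6)",
            [
                ("aigialomycin A", "2"), ("aigialomycin B", "3"),
                ("aigialomycin C", "4"), ("aigialomycin D", "5"),
                ("aigialomycin E", "6"),
            ],
        ),
    ],
)
def test_resolve_worked_examples(text, expected):
    assert [(e.display_name, e.label) for e in run(text)] == expected


def test_resolve_multiword_name():
    toks = tag_chemicals(
        tokenize("methyl multiplolides A (1) and B (2)"), {"methyl"}
    )
    ents = resolve(toks)
    assert [e.display_name for e in ents] == [
        "methyl multiplolide A", "methyl multiplolide B",
    ]


def test_resolve_series_label_mismatch_warns_but_emits():
    warnings = []
    ents = resolve(
        tag_chemicals(tokenize("drechslerines C-E (6-7)")),
        DEFAULT_CONFIG, warnings,
    )
    assert [(e.series, e.label) for e in ents] == [("C", "6"), ("D", "7")]
    assert any("mismatch" in w for w in warnings)


def test_resolve_bare_generic_head_emits_nothing():
    assert run("Two compounds were studied") == []


def test_resolve_ignores_surrounding_prose():
    ents = run("The known taxol (1) was re-isolated in good yield")
    assert [(e.display_name, e.label) for e in ents] == [("taxol", "1")]


def test_resolve_two_chunks_in_one_sentence():
    ents = run("multiplolides A (1) and B (2) and drechslerines C-D (3-4)")
    assert [(e.display_name, e.label) for e in ents] == [
        ("multiplolide A", "1"), ("multiplolide B", "2"),
        ("drechslerine C", "3"), ("drechslerine D", "4"),
    ]


@given(
    start=st.integers(0, 20),
    length=st.integers(1, 6),
    label_start=st.integers(1, 50),
)
@settings(max_examples=100, derandomize=True)
def test_resolve_round_trip_idempotence(start, length, label_start):
    """Formatting an expanded entity back to 'name S (L)' text and
    re-resolving reproduces it."""
    letters = [chr(ord("A") + start % 21 + i) for i in range(length)]
    labels = [str(label_start + i) for i in range(length)]
    if length == 1:
        text = f"fooline {letters[0]} ({labels[0]})"
    else:
        text = f"foolines {letters[0]}-{letters[-1]} ({labels[0]}-{labels[-1]})"
    ents = run(text)
    assert [(e.series, e.label) for e in ents] == list(zip(letters, labels))
    for ent in ents:
        again = run(f"fooline {ent.series} ({ent.label})")
        assert [(e.series, e.label) for e in again] == [(ent.series, ent.label)]
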