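import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemlit.dict_tagger import (
    Dictionary,
    DictionaryDomain,
    DictionaryEntry,
    DictionarySchemaError,
    DomainError,
    DuplicateVariantError,
    NoAbbreviationError,
    Variant,
    abbreviate_scientific_name,
    read_dictionary_xml,
    tag_assays,
    tag_organisms,
    write_dictionary_xml,
)
from chemlit.model import AnnotatedDocument, OrganismRank
from chemlit.synthetic import generate_dictionary
from chemlit.tokenizer import tokenize
from tests.conftest import SIROBASIDIUM_XML


def make_doc(text):
    doc = AnnotatedDocument(doc_id="d", text=text)
    doc.tokens = tokenize(text)
    return doc


class TestDictionaryXml:
    def test_read_paper_style_listing(self, organism_dict):
        assert len(organism_dict.entries) == 2
        species = organism_dict.entries[1]
        assert species.source_id == "8439178"
        assert species.species == "brefeldianum"
        assert len(species.variants) == 2
        assert species.variants[1].status == "synonym"

    def test_empty_dictionary(self):
        assert read_dictionary_xml("<synonym/>").entries == []

    def test_missing_id_is_schema_error(self):
        with pytest.raises(DictionarySchemaError):
            read_dictionary_xml('<synonym><token canonical="x"/></synonym>')

    def test_missing_canonical_is_schema_error(self):
        with pytest.raises(DictionarySchemaError):
            read_dictionary_xml('<synonym><token id="1"/></synonym>')

    def test_duplicate_variant_rejected(self):
        xml = (
            '<synonym><token canonical="a" id="1"><variant base="x"/></token>'
            '<token canonical="b" id="2"><variant base="X"/></token></synonym>'
        )
        with pytest.raises(DuplicateVariantError):
            read_dictionary_xml(xml)

    def test_round_trip_on_listing(self, organism_dict):
        again = read_dictionary_xml(write_dictionary_xml(organism_dict))
        assert again.entries == organism_dict.entries

    @given(n_genera=st.integers(1, 3), spg=st.integers(1, 3), seed=st.integers(0, 50))
    @settings(max_examples=40, derandomize=True)
    def test_round_trip_on_random_dictionaries(self, n_genera, spg, seed):
        d = generate_dictionary(n_genera, spg, seed)
        assert read_dictionary_xml(write_dictionary_xml(d)).entries == d.entries

    def test_write_empty(self):
        xml = write_dictionary_xml(Dictionary(entries=[]))
        assert read_dictionary_xml(xml).entries == []


class TestAbbreviation:
    @pytest.mark.parametrize(
        "full,abbrev",
        [
            ("Escherichia coli", "E. coli"),
            ("Sirobasidium brefeldianum", "S. brefeldianum"),
            ("xylaria multiplex var minor", "X. multiplex var minor"),
        ],
    )
    def test_abbreviate(self, full, abbrev):
        assert abbreviate_scientific_name(full) == abbrev

    def test_single_word_has_no_abbreviation(self):
        with pytest.raises(NoAbbreviationError):
            abbreviate_scientific_name("Penicillium")


class TestOrganismTagging:
    def test_full_then_abbreviated_two_pass(self, organism_dict):
        doc = make_doc(
            "Sirobasidium brefeldianum was studied and S. brefeldianum grew."
        )
        anns = tag_organisms(doc, organism_dict)
        assert len(anns) == 2
        assert {a.source_id for a in anns} == {"8439178"}
        assert anns[1].surface == "S. brefeldianum"

    def test_synonym_variant_maps_to_canonical(self, organism_dict):
        doc = make_doc("Sirobasidium intermediae was isolated.")
        anns = tag_organisms(doc, organism_dict)
        assert len(anns) == 1
        assert anns[0].canonical == "sirobasidium brefeldianum"

    def test_genus_with_unspecified_species_marker(self, organism_dict):
        doc = make_doc("Sirobasidium sp. produces metabolites.")
        anns = tag_organisms(doc, organism_dict)
        assert len(anns) == 1
        assert anns[0].rank is OrganismRank.GENUS_ONLY
        assert anns[0].surface == "Sirobasidium sp."

    def test_abbreviation_without_prior_full_mention_is_not_tagged(
        self, organism_dict
    ):
        doc = make_doc("S. brefeldianum grew on agar.")
        assert tag_organisms(doc, organism_dict) == []

    def test_longest_match_no_sub_spans(self, organism_dict):
        doc = make_doc("Sirobasidium brefeldianum and Sirobasidium sp. were found.")
        anns = tag_organisms(doc, organism_dict)
        spans = [(a.span.start, a.span.end) for a in anns]
        for i, a in enumerate(anns):
            for j, b in enumerate(anns):
                if i != j:
                    assert not (
                        b.span.start <= a.span.start and a.span.end <= b.span.end
                    )
        assert len(anns) == 2

    def test_case_insensitive_matching(self, organism_dict):
        doc = make_doc("SIROBASIDIUM BREFELDIANUM was examined.")
        anns = tag_organisms(doc, organism_dict)
        assert len(anns) == 1
        assert anns[0].surface == "SIROBASIDIUM BREFELDIANUM"

    def test_domain_mismatch(self, assay_dict):
        with pytest.raises(DomainError):
            tag_organisms(make_doc("x"), assay_dict)


class TestAssayTagging:
    def test_single_word_match(self, assay_dict):
        doc = make_doc("The extract showed antifungal activity.")
        anns = tag_assays(doc, assay_dict)
        assert len(anns) == 1
        assert anns[0].canonical == "antifungal"

    def test_whole_token_boundary(self, assay_dict):
        doc = make_doc("cytotoxicity was observed")
        assert tag_assays(doc, assay_dict) == []

    def test_empty_text(self, assay_dict):
        assert tag_assays(make_doc(""), assay_dict) == []

    def test_multiword_assay_variant_dropped_with_warning(self, caplog):
        entries = [
            DictionaryEntry(
                canonical="x", source_id="1",
                variants=[Variant("growth inhibition"), Variant("cytostatic")],
            )
        ]
        with caplog.at_level("WARNING"):
            d = Dictionary(entries=entries, name="a", domain=DictionaryDomain.ASSAY)
        assert [v.base for v in d.entries[0].variants] == ["cytostatic"]
        assert "multi-word" in caplog.text

    def test_domain_mismatch(self, organism_dict):
        with pytest.raises(DomainError):
            tag_assays(make_doc("x"), organism_dict)
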