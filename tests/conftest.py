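import pytest

from chemlit.dict_tagger import DictionaryDomain, read_dictionary_xml

# A realistic two-entry taxonomic dictionary: a genus-level entry and a
# species entry carrying a synonym variant.
SIROBASIDIUM_XML = """\
<synonym>
<token canonical="sirobasidium" id="2403010"
 phylum="basidiomycota" family="sirobasidiaceae" genus="sirobasidium">
<variant base="sirobasidium"/>
</token>
<token canonical="sirobasidium brefeldianum" id="8439178"
 phylum="basidiomycota" family="sirobasidiaceae" genus="sirobasidium"
 species="brefeldianum">
<variant base="sirobasidium brefeldianum"/>
<variant base="sirobasidium intermediae" status="synonym"/>
</token>
</synonym>
"""

ASSAY_XML = """\
<synonym>
<token canonical="antifungal" id="a1"><variant base="antifungal"/></token>
<token canonical="cytotoxic" id="a2"><variant base="cytotoxic"/></token>
</synonym>
"""


@pytest.fixture
def organism_dict():
    return read_dictionary_xml(SIROBASIDIUM_XML, name="sirobasidium")


@pytest.fixture
def assay_dict():
    return read_dictionary_xml(ASSAY_XML, name="assays", domain=DictionaryDomain.ASSAY)
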