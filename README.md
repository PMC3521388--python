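# chemlit

Curating natural-product chemistry from the literature means, for every
publication: list the compounds it reports, which organism they were
isolated from, and what bioactivity they showed — then tie each compound
back to the 2D structure drawing printed in the figures. Abstracts make
this hard in two specific ways: compound families are compressed into
coordinated chunks ("drechslerines C-G (6-10)" names five compounds),
and structures live in images, referenced from text only through short
labels like "(6)".

`chemlit` is a pipeline for exactly this curation task:

* **Preprocessing** — repair the PDF-extraction artifact that turns the
  dash in "Aigialomycins A-E (2-6)" into "?", and prefer the BibTeX
  abstract over noisy extracted full text.
* **Chemistry-aware tokenization** — systematic names like
  `2-Amino-2-(hydroxymethyl)-1,3-propanediol` stay one token;
  scientific-name abbreviations (`P. pacificum`, `sp.`) keep their
  period.
* **Tagging** — a gazetteer + morphology baseline for chemical tokens,
  and dictionary-based tagging of organisms (with a second pass for
  abbreviated scientific names and genus-level `"Genus sp."` mentions)
  and one-word assay terms.
* **Coordination resolution** — a state machine expands compound chunks:
  series and label ranges (`A-C` → A, B, C; `1-3` → 1, 2, 3), `and`
  enumerations, `to` ranges, positional series↔label pairing, and
  plural-head singularization ("multiplolides A (1) and B (2)" →
  *multiplolide A*, labeled 1, and *multiplolide B*, labeled 2).
* **Relation extraction** — the passive isolation idiom
  "… was/were isolated|extracted|obtained|purified|produced from
  *organism*" links compounds to their source organism.
* **Structure-label mapping** — OCR strings that parse as reference
  labels (Roman/Arabic numerals, dashed digits, one optional prime, one
  optional pair of parentheses) are assigned to structure boxes
  one-to-one by minimum-weight bipartite matching on box distance, per
  page; the resulting table joins SMILES/Molfile payloads onto the
  extracted compounds by label.
* **Evaluation** — exact/partial/FP/FN scoring of predicted vs gold term
  lists with `precision = 100·TP/(TP+FP)` and
  `recall = 100·TP/(TP+FN)`, where exact matches are the TPs and, under
  the default policy, partial matches count into the miss denominator;
  an alternative policy credits partials as TPs.

A seeded synthetic-fixture generator (documents, taxonomic dictionaries,
page layouts) makes every stage testable without downloading anything.

## Worked example

`abstract.txt`:

```
Multiplolides A (1) and B (2) and drechslerines C-G (6-10) were isolated
from the fungus Sirobasidium brefeldianum. S. brefeldianum also afforded
taxol (11). The compounds showed antifungal activity.
```

with a two-entry organism dictionary (`organisms.xml`, the
`<synonym>/<token>/<variant>` format) and a one-term assay dictionary:

```
chemlit annotate --input abstract.txt --organism-dict organisms.xml \
    --assay-dict assays.xml --out annotations.xml
```

produces (abridged):

```xml
<collection schema="1.0">
  <document id="doc">
    <entities>
      <compound name="Multiplolide" series="A" label="1" />
      <compound name="Multiplolide" series="B" label="2" />
      <compound name="drechslerine" series="C" label="6" />
      ...
      <compound name="drechslerine" series="G" label="10" />
      <compound name="taxol" label="11" />
      <organism canonical="sirobasidium brefeldianum" id="8439178"
                rank="SPECIES" surface="Sirobasidium brefeldianum" />
      <organism canonical="sirobasidium brefeldianum" id="8439178"
                rank="SPECIES" surface="S. brefeldianum" />
      <assay term="antifungal" id="a1" />
    </entities>
    <relations>
      <produces compound_label="1"
                organism_canonical="sirobasidium brefeldianum" verb="isolated" />
      ...
    </relations>
  </document>
</collection>
```

The two coordinated chunks expanded to seven compounds plus the single
`taxol (11)`; the abbreviated mention `S. brefeldianum` was recognized
because the full name was detected first (abbreviations are re-scanned
document-wide only after a full-name hit); all seven chunk compounds were
linked to the organism through the passive "were isolated from" pattern.

Given a page-component table (structure boxes with SMILES payloads, OCR
boxes), `chemlit map --components components.tsv --out mapping.tsv`
builds the label → structure table and
`chemlit integrate --annotations annotations.xml --mapping mapping.tsv
--out merged.xml` attaches `smiles=` to every compound whose label has a
mapped structure. `chemlit evaluate --pred pred.tsv --gold gold.tsv`
scores term lists, and `chemlit synth --seed 1 --n-docs 5 --out dir`
writes a synthetic corpus with its gold standard.

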