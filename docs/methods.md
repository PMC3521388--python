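# Methods

This note documents the models and procedures implemented in `chemlit`,
the choices made where the design was genuinely open, and what the
synthetic fixtures do and do not establish about real literature.

## Text model

Documents are plain decoded text; every token and entity annotation is
anchored by a 0-based, half-open character span, and surfaces are
validated against spans at construction so annotations cannot drift from
the text. Tokens are whitespace-delimited, then repaired for chemistry:

* runs with internal hyphens/commas/parentheses/primes attached to
  alphanumerics stay one token (systematic names);
* trailing sentence punctuation (`. , ; : ! ?`) is peeled off unless the
  token is a scientific-name abbreviation (`sp.`, `spec.`, `spp.`, or a
  single capital + period);
* tokens shaped like a series range (single capital, dash, single
  capital) or a label range (digits, dash, digits, optionally primed and
  parenthesized) are split around the dash, with parentheses emitted as
  separate punctuation tokens. This is the one deliberate exception to
  the keep-hyphenated-runs rule: the coordination state machine needs to
  see the dash between two letters or two numbers as a token, and no
  real chemical name has the single-capital-dash-single-capital or pure
  digits-dash-digits shape.

Sentence boundaries fall at standalone `.` `!` `?` tokens; abbreviation
periods never split because they are part of their token.

## Chemical tagging baseline

Downstream stages consume only a tag stream, so the chemical recognizer
is a pluggable contract. The shipped baseline tags a token CHEMICAL when
it (i) is in a user-supplied gazetteer (case-insensitive, optional
plural *s*), (ii) carries one of sixteen chemical suffixes (`-ol, -ole,
-ine, -ide, -in, -ane, -ene, -yne, -one, -ate, -mycin, -olide, -oside,
-icin, -azole, -idine`; token length ≥ 5), or (iii) has systematic-name
shape (letters interleaved with ≥ 2 of digit/hyphen/comma/parenthesis).
The suffix list and threshold live in `PipelineConfig` and a key=value
config file can override them. The literal heads "compound"/"compounds"
are tagged CHEMICAL so chunks like "compounds A to C" resolve; a bare
generic head with neither series nor label emits no entity, which keeps
ubiquitous "the compounds were…" sentences from flooding the output.

A single capital letter is a SERIES_LETTER only in chemical context
(after a chemical token, or inside a running series/label enumeration);
sentence-initial "A" stays a word. Pure-digit tokens, optionally primed
or parenthesized, are LABEL_NUMBERs.

The suffix heuristic deliberately over-accepts ordinary English words
ending in, e.g., `-ine`; precision of compound extraction on real prose
depends on the gazetteer supplied. This mirrors the architecture where a
trained recognizer can be swapped in behind the same contract.

## Dictionary tagging

Taxonomic dictionaries use a `<synonym>/<token>/<variant>` XML schema:
entries carry a canonical name, a source identifier, optional
phylum/family/genus/species ranks, and one or more variants (synonyms).
Variant strings must be unique after case-folding; duplicates are
rejected at load. Matching is case-insensitive (dictionaries are stored
lowercase; text capitalizes genus names) and longest-match-first, with
three passes:

1. full variant token sequences;
2. abbreviations (`G. species`) of the variant surfaces *detected* in
   pass 1 — an abbreviation with no prior full mention is not tagged;
3. `Genus sp.|spec.|spp.` for every genus in the dictionary, annotated
   at genus rank. Genus extensions are generated for all dictionary
   genera up front (a dictionary capability, not a per-document one).

After all passes, any annotation strictly contained in another's span is
dropped, preserving the longest-match invariant. Equal-length ties go to
dictionary order. Assay dictionaries hold one-word terms only
(multi-word variants are dropped at load with a warning) and match whole
tokens, so "cytotoxicity" does not match "cytotoxic". Organism and
chemical annotations may overlap (different entity types); organism
tokens are claimed before coordination runs, so pseudo-chemical-looking
genus words do not open compound chunks.

Open points resolved here: pass-2 abbreviates the detected variant
surface (not the canonical); when several dictionaries are loaded the
first-loaded wins on overlapping spans.

## Coordination resolution

A four-state machine (prose-text / chemical-name / series / label) walks
the tagged stream. Names accumulate over consecutive chemical tokens;
series letters and labels accumulate in their states, with parentheses
and commas transparent inside a chunk. A dash or "to" between two
letters or two numbers expands to the inclusive consecutive range
("A-C" → A, B, C; "1-3" → 1, 2, 3); "and" enumerates. Expansion is
capped (26 letters, 100 numbers) to stop OCR garbage like "1-1000" from
exploding; a capped or inverted range warns and falls back to plain
enumeration. Only pure-digit labels expand; primed or Roman labels are
recognized as labels elsewhere but pass through unexpanded.

On chunk close, one entity is emitted per series letter, paired
positionally with labels (`series[i] ↔ label[i]`); a series/label count
mismatch emits entities for the shorter list plus a document warning
rather than failing or silently dropping. Series-less chunks emit one
entity per label; a bare name emits one entity. When distributing over
two or more items, a plural head ending in single *s* is singularized
("multiplolides" → "multiplolide"; "glass"-type heads are untouched).
Emitted series letters are uppercase and labels carry no parentheses.

The full transition table is reconstructed from the worked readings
("multiplolides A (1) and B (2)", "drechslerines C-G (6-10)",
"compounds A and B", "compounds A to C"); every reconstructed transition
is covered by a test so any deviation is visible.

## Isolation relations

Within one sentence, a relation is emitted for each resolved compound
entity ending before a trigger verb (`isolated, extracted, obtained,
purified, produced`) in passive voice (`was|were` within 2 tokens before
the verb, both config-exposed), followed by `from` and then the first
organism annotation of the sentence. Linking only the first organism
avoids spurious links in multi-organism sentences. Sentences like
"Compound 1 was extracted from compound 2" produce nothing because no
organism follows `from`.

## Structure-label mapping

OCR strings count as reference labels when they match: a Roman numeral
over I/V/X/L/C (validated by canonical-form grammar, valued
subtractively), an Arabic digit string, or digits joined by one dash;
then at most one prime; then at most one pair of parentheses around the
whole. Normalization for joining strips the parentheses and keeps the
prime.

Assignment is one-to-one per page, minimizing total Euclidean distance
between box centroids via the Hungarian algorithm
(`scipy.optimize.linear_sum_assignment`), which handles rectangular
instances; leftover structures or labels are reported through warnings,
never dropped silently. Choices made where the upstream formulation was
open: centroid distance is the weight (nearest-edge distance is a config
alternative), matching is page-scoped, and a structure with several
nearby labels wins exactly one — the extras surface as unmatched-label
warnings for the curator. Ties are broken deterministically by sorting
components on identifier and label text. Optimality is checked in tests
against a brute-force enumeration over all injective assignments for up
to 6 components per side.

The join attaches a mapping row's SMILES/Molfile payload to every
compound whose normalized label equals the row's label; a label mapped
to two structures keeps the first and warns.

## Evaluation scheme

Terms are case-folded, whitespace-normalized, and deduplicated per
document (set semantics — whether repeated mentions should count twice
is unspecified upstream, and unique-term scoring is the convention the
report header documents). Alignment is greedy one-to-one: exact string
equality first (TP), then leftover pairs sharing ≥ 1 word (partial);
remaining predictions are FP, remaining gold terms FN. Under the default
policy partial matches count as misses: precision = 100·exact/(exact+fp)
and recall = 100·exact/(exact+partial+fn) — the partials sit in the
denominator of recall, which is what the published count rows require
(203 exact, 15 partial, 105 FN gives 203/323 = 62.85). The alternative
policy treats partials as TPs on both axes. Percentages are reported
half-up at 2 decimals; unrounded ratios remain available
(`precision_ratio`, `recall_ratio`) and are what the strict
monotonicity properties hold for.

## Synthetic fixtures

Generators are pure functions of (parameters, seed). Dictionaries hold
pseudo-Latin binomials whose endings (`-us, -a, -um, -ix`; epithets
`-ensis, -icola, -orum, -alis`) deliberately avoid the chemical suffix
list. Abstracts mix compound chunks — series+label ranges (50%), and/to
enumerations (25%), single compounds (25%), sizes 2–5, labels numbered
consecutively across chunks — each tied to a dictionary organism by a
passive isolation sentence, plus one assay word; gold entities,
compounds, and relations are recorded by construction, and recorded
spans always equal the surface at that offset. Page layouts place
structures on a 200 px grid with each label 100 px below its structure,
jittered uniformly; below half the grid spacing the nearest-label
assignment provably recovers every pair, and larger jitter logs a
warning.

Because the corpus is closed-world (every organism comes from the
dictionary, every compound name bears a recognized suffix), perfect
precision/recall on it is the designed outcome. Passing therefore
demonstrates internal consistency of tokenizer + taggers + resolver +
scorer — not performance on real abstracts, which depends on dictionary
coverage and recognizer quality. Test and acceptance problem sizes (50
documents, 200 random matching instances ≤ 6 per side) were chosen as
the smallest scales at which every code path and pairing permutation is
exercised.

## Known limitations

* Roman-numeral and letter labels are recognized on the image side but
  not expanded by coordination (digits only).
* The relation extractor is a surface pattern, not a parser; unusual
  word orders or active-voice reporting are missed by design.
* No PDF segmentation, raster-image processing, or structure recognition
  is performed; the pipeline consumes extracted text and component
  tables.
* BibTeX values pass LaTeX escapes through unmodified.
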