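# Methods

This note documents the models, conventions and numerical choices behind
hedgekit, in the order the pipeline runs them.

## Record model and I/O

A `BibRecord` is one MEDLINE citation: id, title, abstract (possibly
empty), MeSH headings, publication types, provenance tags, year. MeSH
headings are normalized on ingest: the leading asterisk that marks a
major-topic focus becomes the `major` flag, subheadings after `/` are split
out, and the stored descriptor never embeds either — frequency analysis and
`.sh.` matching operate on bare main headings only. Substance-name fields
(RN/NM) are parsed but never treated as MeSH. Case is preserved in storage;
all matching is case-insensitive; text is NFC-composed on read so visually
identical strings compare equal.

MEDLINE flat files are parsed through Biopython's `Bio.Medline` behind a
normalization pass that (a) accepts both the standard `MH  - ` and the
tighter `MH - ` separator dialects seen in exports, (b) rejects structurally
malformed lines with their line number, and (c) joins continuation lines
with single spaces. Records without a PMID are skipped with a warning
rather than aborting a whole file. The companion writer emits one field per
line, so `parse(write(x)) == x` holds field-for-field; guideline provenance
travels in the `SI` tag. RIS support maps keywords to bare descriptors and
is deliberately lossy for subheadings/major flags (reference-manager
keyword fields have no such structure); MEDLINE is the lossless format.

## Corpus assembly

Sub-corpora are merged first-occurrence-wins by record id; the survivor's
provenance tags become the union of all duplicates' tags, so a record cited
by several guidelines remembers each of them. Duplicate detection is by id
only — records come from a single database, so ids suffice and title-based
fuzzy matching would only add failure modes. Records without abstracts are
partitioned out at corpus level (term identification needs abstract text),
never rejected at parse time.

The three-way split draws a seeded permutation (`numpy.random.default_rng`)
and slices prefixes, which yields a uniform random partition with
deterministic sizes: the term-identification set gets its fraction rounded
half-up to the nearest record (876 × 0.10 = 87.6 → 88), and when equal
development/validation fractions leave an odd remainder, the extra record
goes to development. The odd-remainder rule is a convention; it is recorded
in the split manifest (record id, set, seed) from which any split can be
reconstructed.

## Matching semantics

Matching reduces text to lowercase token sequences (letters/digits with
internal hyphens; no stemming, no truncation, ever). Two scopes emulate
Ovid field suffixes:

* `.mp.` — the term's token sequence occurs contiguously in the title, the
  abstract, or the word sequence of a MeSH descriptor. This is why
  *cardiomyopathy* retrieves records indexed *Cardiomyopathy, Dilated* with
  no textword hit. Ovid's extra `.mp.` fields (original title, substance
  name) are out of scope because parsed records may lack them — a
  documented divergence.
* `.sh.` — token-sequence equality with a descriptor (so punctuation and
  case differences are immaterial: `ventricular dysfunction, left` equals
  `Ventricular Dysfunction, Left`). Subheadings and major flags are
  ignored. Subheading *text* is not searched; descriptor words only. There
  is no tree explosion — none is wanted (unexploded searching is part of
  the method) and no MeSH tree ships with the package.

Strategies are OR-only by design; AND/NOT/adjacency are non-goals. A
single-term strategy renders without a combining line because Ovid has no
`Or/1-1` idiom.

## Term identification

Record occurrence of every candidate — MeSH, textword or phrase — is
computed with the query engine's own `.mp.`/`.sh.` semantics, so the
invariant `record_occurrence == |retrieve({term})|` holds by construction
across modules. (A title/abstract-only scan would differ for words that
also appear in descriptors; using engine semantics means the shortlist is
ranked by exactly what the filter will later retrieve.)

Textwords are ranked by total token frequency (the concordance ordering)
with a bundled, overridable English stopword list; digits-only tokens are
dropped. Phrase discovery is an n-gram proposal: contiguous 2..k-grams
containing at least one top-frequency word, trimmed so they never start or
end on a stopword. "Meaningful phrase" is a human judgment the miner cannot
make, so the curated-list override is the primary path: given a reviewed
list, each entry is scored by engine scan. MeSH frequency drops descriptors
on an editable semantic exclusion list (species/gender/age check tags,
study-design headings) — frequent everywhere, topical nowhere.

The cutoff keeps candidates retrieving at least `round(f × |T|)` records
(f = 0.15 by default; 88 records → 13). Note 13/88 = 14.8%: with small sets
the count threshold and the nominal percentage disagree slightly; the count
governs. Percentages are reported half-up to one decimal everywhere, with
raw counts always retained, because mixed rounding conventions in published
tables are a known reconciliation hazard (e.g. 15/88 = 17.045% prints as
17.0 here, and 382/394 = 96.95% prints as 97.0).

## Greedy development

Forward selection maximizes retrieval count: T1 is the best single
candidate; each later step adds the candidate with the largest marginal
gain; candidates with zero marginal gain are eliminated at first
evaluation and never reconsidered — under monotone OR a term that adds
nothing now can never add anything later, so early elimination is lossless
(a property the tests verify by ablation). Termination is on zero best
gain, not a recall target: the objective is maximal coverage, and
precision is assessed afterwards, not optimized.

Ties are real in small development sets. The builder explores every tied
best candidate as a separate branch (recursively, bounded) and records all
branches' trials in the trace, then continues along the branch chosen by
the tie policy: `alphabetical` (default, reproducible with no further
input) or `sh_first` (prefer a subject heading on ties — the convention
that reproduces the published heart-failure trace's term order). All
branches of a tie converge to the same final retrieved set whenever every
tied term ends up selected, which the OR objective makes the common case.

## Fixture reconstruction

`reconstruct_fixture` inverts a printed permutation table. Inputs are union
cardinalities of an anchor term with subsets of satellites. Outside the
anchor, pairwise and higher intersections follow by inclusion–exclusion
and exact region sizes by Möbius inversion; any negative region or
over-full corpus rejects the table as infeasible, naming the violated
constraint. Two quantities such a table cannot determine are fixed
deterministically and recorded: (a) unions the table omits default to
maximal nesting (the smaller satellite inside the larger), and (b)
satellite membership *inside* the anchor is supplied explicitly — the
shipped development fixture sizes these at the candidate-table proportions
scaled to the set size. Planted phrases are joined with the stopword "and"
so no term's token sequence can straddle two plantings, and noise
vocabulary is collision-filtered against every planted term's tokens.
Every emitted fixture re-verifies itself by running the query engine
against the stated counts before it is returned.

## Synthetic corpora

`generate(CorpusSpec)` emulates the statistical structure the method
cares about, not biomedical language: independent terms appear per
occurrence probability in title, abstract or MeSH; dependent terms appear
only where their anchor does (perfect nesting, with a conditional
probability) — this is what produces zero-marginal-gain candidates;
noise text is drawn from a fixed bundled word list. Same seed, same corpus,
byte for byte. What passing on such corpora does *not* show: robustness to
real indexing variation, synonymy beyond exact token sequences, or OCR/
transcription noise — the generator has none of these.

## Evaluation

Recall is retrieved/set-size with missed ids listed in corpus order;
"first N" screening uses corpus order as loaded, standing in for a
database's default sort (the order is a recorded parameter, and screening
requires a label for every screened record, failing loudly otherwise).
Precision is relevant/screened. Specificity is provided as a formula but
only computable when an irrelevant-labelled corpus is supplied; a
relevant-only gold standard cannot yield it. The missed-record report
tallies MeSH over missed records (each descriptor once per record); the
false-positive attribution table gives per-term match counts and unique
contributions (leave-one-term-out differences), which is how one checks
whether any single term drives the irrelevant retrievals.

## Problem sizes and defaults

Shipped fixtures are exactly the sizes of the study design they replay:
88 / 394 / 394 / 269 records, a 200-record screening stream, a 50-record
irrelevant set. Property suites use generated corpora of ≤ 30 records with
≤ 6 candidates (small enough for exhaustive per-step oracles) and the
planted-recovery experiment runs 100 seeds at 120 records. Defaults:
split fractions 0.10/0.45/0.45; cutoff fraction 0.15; tie policy
alphabetical; first-N 200.

## Known limitations

* Ovid emulation is partial by intent: no explosion, no truncation, no
  AND/NOT, no limits, and `.mp.` covers three fields, not Ovid's full list.
* RIS round-trips lose subheading/major structure (flat keywords only).
* The n-gram phrase miner proposes; it does not decide meaningfulness.
* Reconstruction fixes under-determined overlaps by convention; fixtures
  reproduce printed counts, not the unpublished record-level memberships.
* Relevance judgments are always inputs (label files); the package never
  classifies relevance itself.
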