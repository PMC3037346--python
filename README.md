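# hedgekit

A toolkit for the **objective development and validation of Boolean search
filters** ("hedges") for bibliographic databases such as Ovid MEDLINE.

Clinicians and information specialists use topic filters — pre-tested OR
combinations of subject headings and textwords with known retrieval
performance — to find the literature on a condition without hand-crafting a
search each time. Building one objectively requires a *gold standard* set of
known-relevant records (for example, the studies cited by several
evidence-based clinical practice guidelines), a frequency analysis that
proposes candidate terms, a selection procedure that combines them, and
held-out validation. hedgekit implements that entire workflow on plain-text
MEDLINE records, for methodologists building filters and for anyone who
wants to replay or audit a published filter-development trace.

## Method

Given a gold standard *G* split into a term-identification set *T*, a
development set *D*, and a validation set *V*:

1. **Term identification.** Rank MeSH descriptors by *record occurrence* —
   the number of distinct records in *T* a term retrieves — after dropping
   non-topical check tags (gender, age, study design); rank textwords and
   reviewed phrases from titles/abstracts the same way. Shortlist terms with
   occurrence ≥ ⌈f·|T|⌋ (default f = 0.15).
2. **Greedy filter development.** With OvidSP semantics (`.mp.` = title,
   abstract, or subject-heading words; `.sh.` = subject-heading field,
   unexploded, untruncated), pick T1 = argmax |retrieve({t}, D)|; then
   repeatedly add the candidate with the largest marginal gain
   |retrieve(S ∪ {t}, D)| − |retrieve(S, D)|, eliminating zero-gain
   candidates (under pure OR they can never contribute later), until no
   candidate adds records. Every trial and both branches of any tie are
   recorded in a development trace.
3. **Validation.** recall = retrieved/|V|; precision is estimated *post
   hoc* by human-labelling the first N records the filter retrieves from an
   unscreened corpus. Missed-record MeSH reports and per-term
   false-positive attribution complete the error analysis.

Because real gold standards cannot be redistributed, the
`hedgekit.synthetic` module generates corpora with planted term structure
(anchor terms, overlapping satellites, perfectly nested synonyms) and can
*reconstruct* a development corpus from a published permutation table's
retrieval counts by inclusion–exclusion, so a published trace can be
replayed exactly.

## Worked example

```python
from hedgekit.builder import greedy_build
from hedgekit.evaluate import precision_screen, recall_eval
from hedgekit.synthetic import table_fixtures

fx = table_fixtures()  # deterministic, self-verified corpora

trace = greedy_build(fx.dev_candidates, fx.development)
print([t.render() for t in trace.selected])
print(trace.selected_counts)

val = recall_eval(trace.selected, fx.validation)
print(val.retrieved, val.set_size, val.recall_pct)

screen = precision_screen(trace.selected, fx.screening, 200, fx.screening_labels)
print(screen.relevant_n, screen.screened_n, screen.precision_pct)
```

prints

```
['heart failure.mp.', 'cardiomyopathy.mp.', 'ventricular dysfunction, left.sh.', 'left ventricular ejection fraction.mp.']
[365, 373, 380, 382]
387 394 98.2
150 200 75.0
```

Reading: of nine shortlisted heart-failure candidate terms, `heart
failure.mp.` alone retrieves 365/394 development records; greedy selection
adds `cardiomyopathy.mp.`, `ventricular dysfunction, left.sh.` and `left
ventricular ejection fraction.mp.` (382/394), eliminating five candidates —
`chf`, `congestive heart failure`, `chronic heart failure`, `new york heart
association`, `heart failure.sh.` — that never occur outside the anchor
term's records. The four-term filter then retrieves 387/394 (recall 98.2%)
in the held-out validation set, and 150 of the first 200 records screened
from an unscreened stream are relevant (precision 75.0%).

The same pipeline is available from a shell:

```sh
hedgekit fixtures --out fx
hedgekit evaluate --input fx/filter-validation.medline --filter fx/filter.txt --out eval
hedgekit run --config run.yaml   # split → identify-terms → build → evaluate
```

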