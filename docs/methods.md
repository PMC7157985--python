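# Methods

## The coding procedure

`icdcoder` implements a one-rule-per-code coding engine. A *description
model* is a single regular expression intended to accept every clinician
phrasing of one diagnosis; it is bound to exactly one ICD-10 code, and a
rule base is a set of such bindings with pairwise-distinct codes. Historical
(description, code) pairs with coder-agreement counts can be pre-resolved
with `majority_resolve`: each description maps to the code with strictly
greatest total support, and ties go to an unresolved queue rather than being
broken arbitrarily — a tie means the coders themselves disagree.

Coding a batch is deterministic and order-independent. Each record's
description is normalized, then tested against *every* rule. Exactly one
match assigns that rule's code and appends to the coding log; zero matches
or two-plus matches append a `no_match` / `ambiguous` entry to the failure
log, with the full candidate set (in code order) preserved for the auditor.
Ambiguity is deliberately never tie-broken by rule order, pattern length or
specificity: two matching description models indicate a rule-base defect,
and silently picking one would convert a visible failure into a potential
miscode. This is the semantics of a containment-style `REGEXP_LIKE`
deployment: patterns match as unanchored substrings unless they carry their
own `^`/`$` anchors. Fully anchored matching is available as a compile
switch (`anchored=True`, `--anchored`) for rule bases written against
whole-string semantics.

### Code syntax

Codes follow the extended ICD-10 shape used by national adaptations: a
chapter letter, two digits, an optional `.`-separated subdivision of 1–4
alphanumerics, and an optional space-separated two-digit extension
(`I25.101`, `I10 06`, `F09 01`). The chapter letter (first character)
defines the cluster used by the analytics.

### Rule dialect

Only a conservative construct set is *guaranteed* portable across regex
dialects: `^`, `$`, `*`, `.`, alternation `|`, optional `?`, grouping, and
literal characters (including escaped metacharacters). Everything else —
character classes, `+`, bounded repeats, `\d`-style shorthands — compiles
under Python's `re` but draws a portability warning from the validator, so a
rule base meant to run under another engine can be kept inside the agreed
symbol set.

### Normalization

Normalization is applied to descriptions before matching (and to canonical
labels at compile time), in a fixed order: full-width→half-width character
folding (U+FF01–U+FF5E and the ideographic space), Latin case folding,
optional punctuation stripping, whitespace collapse. Each step is idempotent
and no later step reintroduces material for an earlier one, so the composite
is idempotent — normalizing twice equals once (property-tested). Defaults:
whitespace collapse ON, width folding ON, case folding ON, punctuation
stripping OFF; this removes encoding and spacing noise without altering
clinical wording. The compiled rule base records a fingerprint of the
configuration it was compiled with, and the matcher refuses a mismatched
configuration rather than silently coding differently-normalized text.

## Audit and metrics

Given gold codes and the *modeled set* S (the codes the rule base covers),
each record is classified: emitted = gold → TP; emitted ≠ gold → FP; nothing
emitted and gold ∈ S → FN; nothing emitted and gold ∉ S → TN. Operationally,
condition negativity *is* membership of the gold code outside S: when no
description model exists, emitting nothing is the correct behaviour. The
choice of S is the auditor's: auditing against the rule base's own coverage
treats out-of-coverage records as correct absences, while auditing against a
larger code universe treats them as misses. Both are legitimate questions
("did the system do what its rules allow?" vs "how much of the stream does
it cover?") and `tabulate(run, records, modeled=...)` exposes the set
explicitly rather than fixing one.

Metrics are P = TP/(TP+FP), R = TP/(TP+FN), the weighted harmonic mean
F = 1/(α/P + (1−α)/R) with α = 0.5 by default (equal weight: F = 2PR/(P+R)),
and A = (TP+TN)/total, all as percentages. They are computed on exact
rationals (`fractions.Fraction`) and rounded half-up to two decimals only at
reporting, so the harmonic-mean identity holds exactly and rounding never
compounds (F is taken on the unrounded P and R). Zero denominators produce
an explicit `None` marker — never a silent 0 or 100. The failure breakdown
reports `mismatch` (= FP) and `loss` (= FN) alongside `repeated`, the number
of (patient-group, code) pairs assigned more than once within a group; with
single-valued per-record assignment, repetition is only observable at the
group level.

Analytics: `code_frequency` ranks codes by occurrence (ties broken
lexicographically so the ranking is total and deterministic) and
`cluster_summary` tallies distinct code categories and total occurrences per
chapter letter; both conserve their input counts.

## Synthetic corpora

The generator produces gold-labelled corpora whose coding outcome is known
record by record, emulating the statistical shape of a hospital diagnosis
stream rather than its language:

- **Code universe** — `n_codes` distinct valid codes with Zipf(`s`) sampling
  weights, w_k ∝ k^(−s); `s = 1.0` by default, matching the strong
  head-concentration of real diagnosis streams (a short head of codes
  carries most of the volume); `s = 0` degenerates to uniform.
- **Coverage** — the top `coverage` fraction of codes *by frequency rank*
  get rules, emulating the practice of modeling the high-frequency head
  first. Default 1.0.
- **Surface text** — each covered code owns unique synthetic tokens; its
  rule is `((head|syn) tail)( qualifier)?`, inside the portable construct
  set. Records vary the canonical label by synonym substitution (p = 0.3),
  optional-token insertion (p = 0.3), and spacing/width noise (p = 0.15)
  that normalization must absorb. Token uniqueness makes cross-matches
  impossible, so every in-coverage, non-ambiguous record matches exactly its
  own rule.
- **Ambiguity** — a random `ambiguity_rate` fraction (default 0) of
  in-coverage records get a second rule's core phrase appended, guaranteeing
  ≥ 2 matches.
- **Defaults** — 500 code categories, 10,000 records, seed 0. All sampling
  goes through one seeded `numpy` generator; the same seed yields a
  byte-identical corpus.

What passing on synthetic corpora does **not** show: real clinical text has
synonymy and abbreviation patterns that are not token-disjoint across codes,
hierarchical near-miss codes, and combination-coding rules; the generator's
clean token separation means its 100% full-coverage precision is a check of
the engine's mechanics, not a forecast of rule quality on real descriptions.
Writing description models that actually cover clinician phrasing remains
manual, expert work.

## Numerical and design choices

- Metric arithmetic is exact; display rounding is half-up (`decimal`),
  matching how printed percentage tables round.
- The audit of a deployed two-stage system whose confusion counts are used
  as the metric layer's golden fixture has one internal inconsistency: the
  second stage's counts give R = 27.80 while 27.90 was printed alongside
  them (the printed F is consistent with 27.90). The package pins the
  counts-derived value; tests assert second-stage P and A (which are
  consistent) and the harmonic identity on the counts-derived R.
- Timestamps in logs come from an injectable clock, so identical runs can be
  made byte-identical (`--reproducible`).
- Degenerate inputs: empty batches and empty rule bases are valid (all
  records `no_match`); an empty audit yields undefined metrics, not zeros;
  duplicate record ids and records missing gold codes are rejected by name.
- Acceptance-script problem sizes (5,000–10,000 records, 100–200 codes)
  were chosen so binomial sampling error on realized recall is well under a
  percentage point while a full run stays near a second.

## Known limitations

- One description per record: multi-diagnosis free text must be split
  upstream (`group_id` preserves the patient grouping).
- The matcher scans all rules per record (O(rules × records)); real
  deployments at database scale would push matching into the database
  engine, which is out of scope here.
- Scheduling (batch runs at fixed hours), database integration, and the
  human audit workflow itself are outside the package: it codes batches on
  demand and leaves every emitted code to be audited.
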