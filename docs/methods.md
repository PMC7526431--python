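# Methods

This note documents the matching model, its tunables, the synthetic-data
generator, and the design decisions that were genuinely open.

## The matching model

A backbone is a static table of name records; each record is either accepted,
a synonym pointing at an accepted record through `acceptedNameUsageID`, or
something else ("unchecked", unplaced names). Matching a submitted name means
finding the backbone record whose scientific name it denotes, despite
misspellings, qualifiers, embedded authorities, and case noise.

### Cleaning

Per name, in order: optional edge-whitespace trim (off by default); optional
case fold that lowercases every character except the first (off by default —
backbones themselves are consistently capitalised, and the exact-match key
already folds case); bracket-tail stripping (on by default) — everything from
the first `(` is dropped, since brackets usually open an authority or a
parenthesised synonym; qualifier deletion; collapse of internal space runs.

Qualifier deletion only fires on delimited tokens (preceded by start-of-string
or a space, followed by a space or end-of-string), so an epithet containing a
qualifier substring is never mangled. The default list is
`cf. aff. sp. spp. ssp. indet. ined. nom. nov. nom. nud. nom. inval. s.l. s.s.`
— fully punctuated forms only. Bare `cf` / `aff` are deliberately absent:
deleting them blindly would eat two-letter tokens inside legitimate strings,
and practice shows such records are better repaired explicitly (the pattern
list is user-extensible, `--qualifier` on the CLI). Rank markers `var.` and
`subsp.` are also *not* qualifiers here: they are structural parts of
infraspecific names on both sides of the comparison.

Edge whitespace is preserved unless trimming is requested or qualifier
deletion itself created it. A trailing space therefore defeats exact matching
and resurfaces as a fuzzy hit at distance exactly 1 — deliberately visible
rather than silently repaired, because a curator reviewing output should see
that the submitted string was not identical.

### Distance kernels

Plain Levenshtein distance (unit-cost substitution/insertion/deletion) is the
matching metric. It is computed with edlib (code-point level, verified to
count `é` or the hybrid sign `×` as single characters) with a `k`-bounded
early-abandon mode for backbone scans; a pure-Python DP covers the
(practically unreachable) case of more than 256 distinct code points in a
pair. Distances are case-sensitive; case handling belongs to cleaning.

The modified Damerau–Levenshtein kernel extends the operation set with
adjacent **block transpositions at half weight**: if a prefix of one string
ends in blocks `X Y` where the other ends in `Y X`, the exchange is one
operation costing `(|X|+|Y|)/2`. This yields 2 for the canonical
*vecusilosus*/*vesiculosus* pair (block exchange `cusi`/`sicu`) against 4 for
plain Levenshtein, and 1 for a single adjacent swap. The exact block
weighting in the Taxamatch lineage is underdetermined by the published worked
values; the `L/2` rule is the minimal one consistent with both (cost 2 for
the four-character exchange, cost 1 for a swap) and is implemented as a DP
whose transposition move is validated in O(1) per block pair through a
longest-common-suffix table. Costs are half-integral, hence the float return.
The kernel is diagnostic (it is exposed and tested, and always ≤ the plain
distance); candidate gating uses the plain distance.

### The fuzzy bound

A candidate passes when `d(pattern, name) ≤ allowed`, with
`allowed = ⌈max_distance · |pattern|⌉` in the default fractional mode
(`max_distance = 0.1`) or the literal integer in absolute mode. The ceiling
is computed with a `1e-9` guard because `0.1 * 20` is
`2.0000000000000004` in binary floating point and must allow 2 edits, not 3.
A 5-character pattern therefore gets 1 edit, a 17-character binomial 2.

A deliberate semantic choice: `agrep`-style engines common in this task do
approximate *substring* matching, under which a one-word pattern can hit
thousands of longer names. Here the bound is a whole-string comparison — the
pattern competes against the full scientific name. This makes the candidate semantics uniform across
stages and keeps reported distances identical to the gating distances; the
cost is that a bare genus pattern only fuzzy-matches genus-length records,
which is why the generator can emit genus-rank records.

### The cascade

Stages run in a fixed order, each exact-then-fuzzy, stopping at the first
stage with candidates: number shortcut (first word only, when the raw name
contains a digit and `nonumber` is on), full cleaned name, first two words,
first word. A fallback stage is skipped when its search string equals one
already tried. Exact lookup uses a key that folds case beyond the first
character and collapses internal space runs (but keeps edge spaces), so
`ULMUS  GLABRA` matches directly while `Ulmus glabra ` is an LD-1 fuzzy case.

Overflow (more than `fuzzy_max` within-bound candidates, default 250)
terminates the cascade and reports the count. The alternative — treating
overflow like "no candidates" and falling through to shorter prefixes — was
rejected: overflow means matches *exist*, and backing off to an even less
specific pattern would compound the ambiguity behind the user's back.
`fuzzy_min` (default on) keeps only minimal-distance candidates *after* the
overflow check, so the cap measures the raw ambiguity of the query.
Candidates are ordered by (distance, numeric taxon ID): stable and
reproducible.

Authority distances are computed before synonym resolution, against the
authorship of the record as originally matched — that is the name the
submitted author string belongs to. Resolution then replaces a synonym
candidate's record by its accepted record, filling `Old.status` / `Old.ID` /
`Old.name` from the original; a dangling pointer leaves the record in place
and sets `Old.status = "dangling"`. Resolution never changes the match
distance or stage.

### Selection

Rules apply in the order author distance → status preference → smallest
numeric ID, recording the first rule that achieves uniqueness. Status is
ranked accepted (0) < synonym (1) < anything else (2), case-insensitively,
judged on the *original* match (a synonym resolved to an accepted record
still loses to a record matched as accepted outright). The ID rule compares
the numeric suffix of `wfo-`-style IDs of the record as originally matched:
when two different synonyms of one submitted name resolve to two different
accepted species, the synonyms' own IDs decide, which reproduces the
documented *Ulmus campestris* outcome. Non-conforming IDs compare
lexicographically, after all conforming ones. Each rule only removes
candidates and keeps minimizers of a fixed key, so the outcome is invariant
under permutation of the candidate list, and the ID rule is a total
tie-break because IDs are unique.

## Tunables

| Parameter | Default | Meaning |
|---|---|---|
| `max_distance` | 0.1 (fraction) | fuzzy edit allowance per unit pattern length; absolute integer mode available |
| `fuzzy_max` | 250 | within-bound candidate cap before overflow is declared |
| `fuzzy_min` | true | keep only minimal-distance candidates |
| `fuzzy_two`, `fuzzy_one` | true | enable the two-word / one-word fallback stages |
| `tolower` | false | fold case after the first character during cleaning |
| `nonumber` | true | digit in the name ⇒ search first word only |
| `nobrackets` | true | strip from the first `(` |
| `sub_pattern` | see above | qualifier patterns deleted during cleaning |
| `accepted_name_match` | true | resolve matched synonyms to accepted records |
| `trim` | false | strip edge whitespace before matching |

## The synthetic generator

Real backbone dumps are hundreds of megabytes and cannot ship with the
package, so tests and calibration use generated ones. Names are built from
consonant–vowel syllables as "Genus epithet" pairs; the generator emulates
the structural features the matcher actually depends on: accepted species
records, synonym records with valid `acceptedNameUsageID` pointers
(`synonym_rate` default 0.5 — backbones of this kind carry roughly as many
synonym names as accepted ones), optional homonym duplicates (same name,
different authorship; default rate 0, since exact duplicates necessarily
violate the separation floor and are opted into by selection tests),
optional genus-rank records, zero-padded `wfo-` IDs assigned sequentially,
and plausible authorship strings. A rejection-sampling floor
(`min_separation`, default 3) guarantees all distinct names are pairwise at
Levenshtein distance ≥ 3, which is what makes 1-edit recovery provable:
a query one edit from its source is at least two edits from every other name,
so the minimal-distance candidate set is a singleton.

Query perturbations: `k_edits` (random letter substitutions/insertions/
deletions; `k = 1` yields distance exactly 1 by construction),
`last_char_deletion`, `trailing_space`, `uppercase`, `qualifier_insertion`,
`bracket_suffix`, `number_suffix` (for which the ground truth is the
genus-rank record when one exists). Everything is driven by one integer
seed; identical specs produce byte-identical output, and query draws can be
re-seeded independently of the backbone.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: real epithet morphology and its error statistics
(Latin gender endings, doubled consonants), authority-string typography and
abbreviation conventions, the skewed synonym network of real genera, and
natural near-collisions between valid names (real backbones contain pairs at
distance 1–2, e.g. *Scottellia*/*Scotellia*-type variants, where unique
recovery is impossible in principle). Success rates on generated data are
therefore a correctness check of the machinery, not an estimate of
real-world match rates.

## Problem sizes and numerics

The default verification runs use a 500-accepted / 250-synonym backbone with
two independent 750-query draws (1,500 one-typo trials), 10,000 random string
pairs (length ≤ 20) for kernel/oracle agreement, and 100 queries for the
brute-force minimality comparison — sizes chosen so the whole suite completes
in well under a minute while still exceeding the trial counts the
guarantees are stated over. Degenerate inputs (empty or cleaned-to-empty
names) are recorded as unmatched, never raised, in table mode; unmatched
names are data, not errors (the CLI exits 0). Ties anywhere are broken by
the numeric taxon ID, never by insertion order.

## Known limitations

- Whole-string fuzzy semantics (see above): one-word patterns do not
  fuzzy-reach longer names; genus rescue relies on exact first-word hits or
  genus-rank records.
- Authority strings are compared by raw edit distance with no abbreviation
  expansion ("Hutch." vs "Hutchinson" scores as 6 edits).
- No phonetic or keyboard-aware error model; all edits cost the same.
- `match_parts` compares epithet fields by literal equality; it does not
  consult the rank label, by design, but also applies no fuzzy tolerance.
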