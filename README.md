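# taxomatch

Standardize plant names against a taxonomic backbone.

Species lists from herbaria, vegetation plots, and trade inventories are full
of misspellings, superseded synonyms, embedded authority strings, and
open-nomenclature qualifiers ("*Miconia* cf. *aspera*", "Miconia sp. 2",
"MICONIA ASPERRIMA"). Before such lists can be joined to any reference
database, each submitted name has to be resolved to exactly one record of a
**taxonomic backbone** — a static reference table, in the Darwin Core dialect
used by the World Flora Online `classification.txt` dumps, in which every
record carries a scientific name, rank, taxonomic status, and (for synonyms)
a pointer to the accepted record via `acceptedNameUsageID`.

`taxomatch` does this resolution for people who curate species lists:
it cleans each submitted name, matches it through a staged cascade, resolves
synonyms to accepted names, and deterministically reduces multi-candidate
matches to a single best match with a recorded rationale.

## Method

**Cleaning.** Open-nomenclature qualifiers (`cf.`, `aff.`, `sp.`, `indet.`,
`nom. nov.`, ...) are deleted wherever they occur as delimited tokens;
optionally all characters after the first are lowercased and everything from
the first `(` onward is stripped. Names containing a digit are flagged as
morphospecies; names containing a bracket are flagged too. Whitespace at the
edges is kept by default, so a trailing space surfaces honestly as a fuzzy
match at distance 1.

**Matching cascade.** Each cleaned name is matched in stages, stopping at the
first stage that yields candidates:

1. *number shortcut* — a name with a digit is searched by its first word only;
2. *full name* — exact lookup (case-folded beyond the first character,
   internal space runs collapsed), then a bounded fuzzy scan of the whole
   backbone;
3. *first two words* — for names that drag an authority behind the binomial;
4. *first word* — genus-level rescue.

The fuzzy scan admits a candidate at Levenshtein distance
d(q, s) ≤ ⌈α·|q|⌉, with α = 0.1 by default (or an absolute edit count). If
more than `fuzzy_max` (default 250) candidates qualify, the name is reported
as an *overflow* with the count instead of being silently truncated; with
`fuzzy_min` (default) only candidates at the minimal distance survive.

**Distances.** The plain Levenshtein distance d(·,·) counts unit-cost
substitutions, insertions and deletions. The package also implements the
modified Damerau–Levenshtein distance of the Taxamatch tradition, in which
exchanging two adjacent blocks X, Y is a single operation costing
(|X|+|Y|)/2: for *vecusilosus* vs. *vesiculosus* the plain distance is 4
(four substitutions) but the block exchange `cusi`↔`sicu` gives 2.

**Synonym resolution and selection.** A matched synonym is replaced by its
accepted record, with the original match preserved in `Old.status` /
`Old.ID` / `Old.name`. When several candidates survive, a single best match
is chosen by the first rule that achieves uniqueness: smallest edit distance
between submitted and matched authorship; then accepted status over synonym
over anything else (judged on the record as originally matched); then the
smallest numeric taxon ID — a total tie-break. The deciding rule is recorded
in `One.Reason`.

## Worked example

Generate a small synthetic backbone (8 accepted species, 2 synonyms) plus a
query list in which every name carries one random typo, then match it:

```bash
taxomatch synth --n-accepted 8 --synonym-rate 0.25 --seed 4 \
    --perturb k_edits --k 1 --out-backbone backbone.txt --out-queries queries.csv
taxomatch match --backbone backbone.txt --input queries.csv \
    --name-col spec.name --one --out matched.csv
```

which prints

```
Taxa:                  10
Unique direct matches: 0
Multiple direct matches: 0
Unique fuzzy matches:  10
Multiple fuzzy matches: 0
No match:              0
```

— all ten perturbed names were recovered, none exactly (every query contains
one typo, so every match is fuzzy), and each was unique. The output table
carries the input columns, the match bookkeeping, and the matched record:

```
     spec.name Matched Fuzzy Fuzzy.dist       One.Reason        taxonID  scientificName
   Dacaxu cifa    True  True          1 single_candidate wfo-0000000001     Dacamu cifa
Vafupi lariope    True  True          1 single_candidate wfo-0000000002 Vafupi larisope
    Gato ivufo    True  True          1 single_candidate wfo-0000000003     Gato rivufo
```

The same pipeline is available as a scikit-learn style estimator:

```python
>>> from taxomatch import Backbone, BackboneRecord, TaxonNameMatcher
>>> backbone = Backbone([
...     BackboneRecord("wfo-0000642021", "Dysoxylum alliaceum", "(Blume) Blume",
...                    "species", "Accepted"),
...     BackboneRecord("wfo-0000642022", "Dysoxylum euphlebium", "Merr.",
...                    "species", "Synonym", "wfo-0000642021"),
... ])
>>> m = TaxonNameMatcher().fit(backbone)
>>> m.predict(["Dysoxylum euphlebium (Dysoxylum alliaceum)"])
array(['wfo-0000642021'], dtype=object)
```

The bracketed tail is stripped, the synonym is matched exactly, and the
prediction is the *accepted* record's ID; `m.transform(...)` returns the full
bookkeeping (here `Old.name = "Dysoxylum euphlebium"`, `Old.status =
"Synonym"`).

```python
>>> from taxomatch import levenshtein, modified_dl
>>> levenshtein("vecusilosus", "vesiculosus"), modified_dl("vecusilosus", "vesiculosus")
(4, 2.0)
```

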