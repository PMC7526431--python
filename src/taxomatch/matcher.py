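"""The staged matching cascade: exact -> fuzzy -> two-word -> one-word fallbacks.

A submitted name is cleaned, then matched against the backbone in stages:

1. Names containing a number (morphospecies such as "Miconia sp. 2") shortcut
   straight to a first-word search — the rest of the string is assumed to
   label an unidentified specimen.
2. Otherwise the full cleaned name is looked up exactly; failing that, a
   bounded fuzzy scan of the whole backbone runs (default allowance: 10% of
   the pattern length, rounded up).
3. If the full name found nothing, the first two words are tried (submitted
   names often drag an authority string behind the binomial), then the first
   word alone (genus-level rescue).

Fuzzy scans respect a candidate cap (default 250): exceeding it is reported
as an overflow with the count rather than silently truncated, so the user
raises the cap knowingly. With ``fuzzy_min`` (default) only candidates at the
minimal edit distance survive. Matched synonyms are resolved to their
accepted record, with the original match preserved in the ``old_*`` fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .backbone_io import Backbone, BackboneRecord, wfo_id_sort_key
from .distance import DistanceBound, bounded_levenshtein, levenshtein
from .normalize import CleanedName, clean_name, default_qualifiers, match_key

__all__ = [
    "MatchConfig",
    "MatchCandidate",
    "MatchResult",
    "match_exact",
    "match_parts",
    "match_fuzzy",
    "match_cascade",
    "resolve_accepted",
]

STAGE_FULL = "full"
STAGE_TWO = "two_words"
STAGE_ONE = "one_word"
STAGE_NONE = "none"


@dataclass
class MatchConfig:
    """All tunables of the matching cascade.

    max_distance
        Edit allowance for fuzzy candidates; by default a fraction (0.1) of
        the pattern length, rounded up.
    fuzzy_max
        Cap on the number of within-bound fuzzy candidates (default 250);
        beyond it the query is reported as an overflow.
    fuzzy_min
        Keep only candidates achieving the minimal edit distance (default).
    fuzzy_two / fuzzy_one
        Enable the first-two-words / first-word fallback stages.
    tolower
        Lowercase every character of the submitted name except the first.
    nonumber
        Treat names containing a digit as morphospecies: search only the
        first word.
    nobrackets
        Strip everything from the first "(" onward before matching.
    sub_pattern
        Open-nomenclature qualifiers deleted during cleaning.
    accepted_name_match
        Resolve matched synonyms to their accepted record.
    authorship_column
        Name of the submitted-authority column in table mode; when present,
        the edit distance between submitted and matched authorship is
        reported per candidate.
    trim
        Strip leading/trailing whitespace before matching (off by default; a
        trailing space then shows up honestly as an LD-1 fuzzy match).
    """

    max_distance: DistanceBound = field(default_factory=DistanceBound)
    fuzzy_max: int = 250
    fuzzy_min: bool = True
    fuzzy_two: bool = True
    fuzzy_one: bool = True
    tolower: bool = False
    nonumber: bool = True
    nobrackets: bool = True
    sub_pattern: list[str] = field(default_factory=default_qualifiers)
    accepted_name_match: bool = True
    authorship_column: Optional[str] = None
    trim: bool = False

    def __post_init__(self) -> None:
        if self.fuzzy_max < 1:
            raise ValueError("fuzzy_max must be >= 1")
        if not isinstance(self.max_distance, DistanceBound):
            self.max_distance = DistanceBound(float(self.max_distance))


@dataclass
class MatchCandidate:
    """One backbone record considered a match for a submitted name.

    ``fuzzy_dist`` is the edit distance between the searched string (the full
    cleaned name, or the two-/one-word prefix at fallback stages) and the
    scientific name of the ORIGINAL matched record — synonym resolution never
    rewrites it. When a synonym was resolved, ``old_status``/``old_id``/
    ``old_name`` hold the original record's status, ID, and name ("dangling"
    in ``old_status`` flags an unresolvable pointer).
    """

    record: BackboneRecord
    fuzzy: bool
    fuzzy_dist: int
    stage: str = STAGE_FULL
    old_status: str = ""
    old_id: str = ""
    old_name: str = ""
    auth_dist: Optional[int] = None

    def original_id(self) -> str:
        """Taxon ID of the record as originally matched (pre-resolution)."""
        return self.old_id if self.old_id else self.record.taxon_id


@dataclass
class MatchResult:
    """A submitted name with its ordered candidate set."""

    query: CleanedName
    candidates: list[MatchCandidate]
    matched: bool
    unique: bool
    stage_used: str
    overflow: Optional[int] = None
    selection: Optional[object] = None  # SelectionOutcome, set by the driver

    @property
    def direct(self) -> bool:
        """True for an exact (edit distance 0) match at the full-name stage."""
        return (
            self.matched
            and self.stage_used == STAGE_FULL
            and not self.candidates[0].fuzzy
        )


def _sorted_candidates(cands: list[MatchCandidate]) -> list[MatchCandidate]:
    return sorted(
        cands, key=lambda c: (c.fuzzy_dist, wfo_id_sort_key(c.record.taxon_id))
    )


def match_exact(
    backbone: Backbone, name: str, stage: str = STAGE_FULL
) -> list[MatchCandidate]:
    """All records whose normalized full name equals the normalized query.

    Normalization (see :func:`taxomatch.normalize.match_key`) folds case
    beyond the first character and collapses internal space runs, so exact
    matching tolerates capitalisation and double spaces but not a trailing
    space. Backbone row order is preserved.
    """
    records = backbone.by_name.get(match_key(name), [])
    return [
        MatchCandidate(record=r, fuzzy=False, fuzzy_dist=0, stage=stage)
        for r in records
    ]


def match_parts(
    backbone: Backbone, genus: str, species: str = "", infraspecific: str = ""
) -> list[MatchCandidate]:
    """Exact matching simultaneously at genus / species / infraspecific level.

    A record matches when all three fields equal the given values (empty
    matches empty), regardless of its rank label — so a variety record is
    found for a name submitted as a subspecies, as long as the epithets agree.
    """
    if not genus:
        raise ValueError("genus must be non-empty")
    out = []
    for rec in backbone:
        if (
            rec.genus == genus
            and rec.specific_epithet == species
            and rec.infraspecific_epithet == infraspecific
        ):
            out.append(MatchCandidate(record=rec, fuzzy=False, fuzzy_dist=0))
    return out


def match_fuzzy(
    backbone: Backbone, name: str, config: MatchConfig, stage: str = STAGE_FULL
) -> tuple[list[MatchCandidate], Optional[int]]:
    """Bounded fuzzy scan of the whole backbone.

    Returns ``(candidates, overflow)``. If more than ``config.fuzzy_max``
    records fall within the edit allowance, no candidates are returned and
    ``overflow`` carries the count — a reportable condition, not an error.
    With ``fuzzy_min``, only candidates achieving the minimal distance
    survive. Candidates are sorted by (distance, taxon ID).
    """
    allowed = config.max_distance.allowed(name)
    nlen = len(name)
    hits: list[tuple[int, BackboneRecord]] = []
    for rec in backbone:
        target = rec.scientific_name
        if abs(len(target) - nlen) > allowed:
            continue
        d = bounded_levenshtein(name, target, allowed)
        if d is not None:
            hits.append((d, rec))
    if len(hits) > config.fuzzy_max:
        return [], len(hits)
    if config.fuzzy_min and hits:
        dmin = min(d for d, _ in hits)
        hits = [(d, r) for d, r in hits if d == dmin]
    cands = [
        MatchCandidate(record=r, fuzzy=d > 0, fuzzy_dist=d, stage=stage)
        for d, r in hits
    ]
    return _sorted_candidates(cands), None


def resolve_accepted(backbone: Backbone, candidate: MatchCandidate) -> MatchCandidate:
    """Map a matched synonym to its accepted record.

    The returned candidate's record is the accepted one; ``old_status``,
    ``old_id``, ``old_name`` preserve the original match. A dangling pointer
    leaves the record unchanged and flags ``old_status = "dangling"``.
    Non-synonym candidates pass through untouched. ``fuzzy_dist`` and
    ``stage`` always refer to the original match.
    """
    rec = candidate.record
    if "synonym" not in rec.status_norm() or not rec.accepted_id:
        return candidate
    accepted = backbone.by_id.get(rec.accepted_id)
    if accepted is None:
        return replace(
            candidate,
            old_status="dangling",
            old_id=rec.taxon_id,
            old_name=rec.scientific_name,
        )
    return replace(
        candidate,
        record=accepted,
        old_status=rec.status,
        old_id=rec.taxon_id,
        old_name=rec.scientific_name,
    )


def _run_stage(
    backbone: Backbone, text: str, config: MatchConfig, stage: str
) -> tuple[list[MatchCandidate], Optional[int]]:
    """Exact lookup, then fuzzy scan if the exact lookup found nothing."""
    cands = match_exact(backbone, text, stage=stage)
    if cands:
        return _sorted_candidates(cands), None
    return match_fuzzy(backbone, text, config, stage=stage)


def match_cascade(
    backbone: Backbone,
    raw_name: str,
    raw_authority: Optional[str] = None,
    config: Optional[MatchConfig] = None,
) -> MatchResult:
    """Run the full staged cascade for one submitted name.

    Stages (each exact-then-fuzzy): number shortcut to the first word, else
    the full cleaned name, then the first two words, then the first word.
    A fallback stage only runs when every earlier stage produced zero
    candidates and its search string differs from what was already tried.
    An overflow terminates the cascade. Candidates are then resolved to
    accepted names (if configured) and, when an authority was submitted,
    annotated with the edit distance to the originally matched record's
    authorship. A name that cleans to the empty string is unmatched.
    """
    if config is None:
        config = MatchConfig()
    query = clean_name(raw_name, config)

    candidates: list[MatchCandidate] = []
    overflow: Optional[int] = None
    stage_used = STAGE_NONE

    if query.cleaned:
        tried: set[str] = set()
        plan: list[tuple[str, str]] = []
        if query.number_detected and config.nonumber:
            plan.append((query.first_word, STAGE_ONE))
        else:
            plan.append((query.cleaned, STAGE_FULL))
            if config.fuzzy_two:
                plan.append((query.first_two_words, STAGE_TWO))
            if config.fuzzy_one:
                plan.append((query.first_word, STAGE_ONE))
        for text, stage in plan:
            if not text or text in tried:
                continue
            tried.add(text)
            candidates, overflow = _run_stage(backbone, text, config, stage)
            if candidates:
                stage_used = stage
                break
            if overflow is not None:
                # matches exist but exceed the cap: stop and report the count
                break

    if raw_authority is not None:
        for cand in candidates:
            cand.auth_dist = levenshtein(raw_authority, cand.record.authorship)
    if config.accepted_name_match:
        candidates = [resolve_accepted(backbone, c) for c in candidates]

    return MatchResult(
        query=query,
        candidates=candidates,
        matched=bool(candidates),
        unique=len(candidates) == 1,
        stage_used=stage_used,
        overflow=overflow,
    )
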