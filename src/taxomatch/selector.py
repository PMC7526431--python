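"""Reduce a multi-candidate match to exactly one record, with a rationale.

Homonyms and near-ties are common: the same binomial published by different
authorities, or several backbone records within the same edit distance of a
misspelt query. The selection cascade applies filters in a fixed order and
records the FIRST rule that achieved uniqueness:

1. ``author_distance`` — keep candidates whose authorship is closest (by edit
   distance) to the submitted authority, when one was submitted;
2. ``status_preference`` — prefer accepted names over synonyms over anything
   else, judged on the status of the record as originally matched;
3. ``smallest_id`` — keep the candidate whose taxon ID has the smallest
   numeric part (a total tie-break, since IDs are unique).

A single-candidate result is returned as-is with reason ``single_candidate``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .backbone_io import wfo_id_sort_key
from .matcher import MatchCandidate, MatchResult

__all__ = ["SelectionOutcome", "select_one"]

REASON_SINGLE = "single_candidate"
REASON_AUTHOR = "author_distance"
REASON_STATUS = "status_preference"
REASON_ID = "smallest_id"

_STATUS_RANK = {"accepted": 0, "synonym": 1}


def _status_rank(cand: MatchCandidate) -> int:
    # Judge the status of the ORIGINAL match: a synonym resolved to an
    # accepted record still loses to a record matched as accepted outright.
    status = cand.old_status if cand.old_status else cand.record.status
    status = status.strip().lower()
    if status in _STATUS_RANK:
        return _STATUS_RANK[status]
    if "synonym" in status:  # homotypic/heterotypic synonym variants
        return 1
    return 2


def _id_key(cand: MatchCandidate):
    # Compare the ID of the record as originally matched (old_id when the
    # candidate went through synonym resolution): two different synonyms
    # resolving to different accepted species are tied on everything else and
    # the submitted name is the synonym, so its own ID decides.
    return wfo_id_sort_key(cand.original_id())


@dataclass(frozen=True)
class SelectionOutcome:
    """The chosen candidate, the deciding rule, and how many were discarded."""

    chosen: MatchCandidate
    reason: str
    eliminated: int


def select_one(result: MatchResult, use_author: bool = True) -> SelectionOutcome:
    """Reduce a matched result to exactly one candidate.

    Raises ``ValueError`` on an unmatched result. Deterministic and invariant
    under permutation of the candidate list: every rule keeps the minimizers
    of a fixed key, and the final ID comparison is a total order.
    """
    if not result.matched:
        raise ValueError("select_one requires a matched result")
    cands = list(result.candidates)
    n0 = len(cands)
    if n0 == 1:
        return SelectionOutcome(cands[0], REASON_SINGLE, 0)

    if use_author and any(c.auth_dist is not None for c in cands):
        with_auth = [c for c in cands if c.auth_dist is not None]
        dmin = min(c.auth_dist for c in with_auth)  # type: ignore[type-var]
        cands = [c for c in with_auth if c.auth_dist == dmin]
        if len(cands) == 1:
            return SelectionOutcome(cands[0], REASON_AUTHOR, n0 - 1)

    rmin = min(_status_rank(c) for c in cands)
    cands = [c for c in cands if _status_rank(c) == rmin]
    if len(cands) == 1:
        return SelectionOutcome(cands[0], REASON_STATUS, n0 - 1)

    chosen = min(cands, key=_id_key)
    return SelectionOutcome(chosen, REASON_ID, n0 - 1)
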