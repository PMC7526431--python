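"""Cleaning of submitted plant names before matching.

Field data rarely contains pristine binomials. Recorders embed
open-nomenclature qualifiers ("Miconia cf. aspera"), morphospecies numbers
("Miconia sp. 2"), parenthesised synonyms or authorities, and inconsistent
capitalisation. Cleaning deletes the qualifiers, optionally folds case and
strips bracketed tails, flags numbers and brackets (which steer the matching
cascade), and derives the one- and two-word prefixes used by the fallback
stages.

Cleaning is deliberately conservative: leading/trailing whitespace is kept
unless trimming is requested (a trailing space then surfaces as an honest
fuzzy match at edit distance 1 rather than being silently repaired), and the
hybrid sign ``×`` passes through untouched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .matcher import MatchConfig

__all__ = ["CleanedName", "clean_name", "default_qualifiers", "match_key"]

# Open-nomenclature and nomenclatural qualifiers deleted from submitted names.
# Only fully punctuated forms are listed: bare "cf" / "aff" are left for the
# user to map explicitly (via extra patterns), since deleting them blindly
# would mangle epithets.
_DEFAULT_QUALIFIERS = (
    "cf.",
    "aff.",
    "sp.",
    "spp.",
    "ssp.",
    "indet.",
    "ined.",
    "nom. nov.",
    "nom. nud.",
    "nom. inval.",
    "s.l.",
    "s.s.",
)

_DIGITS = set("0123456789")


def default_qualifiers() -> list[str]:
    """Default list of qualifier patterns deleted during cleaning."""
    return list(_DEFAULT_QUALIFIERS)


@dataclass(frozen=True)
class CleanedName:
    """A submitted name together with its cleaned form and steering flags."""

    raw: str
    cleaned: str
    number_detected: bool
    brackets_detected: bool

    @property
    def first_word(self) -> str:
        toks = self.cleaned.split()
        return toks[0] if toks else ""

    @property
    def first_two_words(self) -> str:
        toks = self.cleaned.split()
        return " ".join(toks[:2]) if toks else ""


def _qualifier_regex(pattern: str) -> re.Pattern[str]:
    # A qualifier only matches as a delimited token: preceded by start-of-string
    # or a space and followed by a space or end-of-string, so "cf." inside
    # "cfXanthium" is never touched.
    return re.compile(r"(?:^|(?<= ))" + re.escape(pattern) + r"(?= |$)")


def clean_name(raw: str, config: "MatchConfig") -> CleanedName:
    """Clean one submitted name according to the configuration.

    Order of operations: optional trim, case folding (every character after
    the first lowercased), bracket-tail stripping, qualifier deletion (longest
    pattern first), whitespace repair. Number/bracket flags are computed on the
    raw string. An empty or cleaned-to-empty name yields ``cleaned == ""``,
    which the matcher records as unmatched — no exception in table mode.
    """
    number_detected = any(c in _DIGITS for c in raw)
    brackets_detected = "(" in raw

    s = raw
    if config.trim:
        s = s.strip()
    if config.tolower and len(s) > 1:
        s = s[0] + s[1:].lower()
    if config.nobrackets and "(" in s:
        s = s.split("(", 1)[0].rstrip(" ")

    deleted = False
    for q in sorted(config.sub_pattern, key=len, reverse=True):
        rx = _qualifier_regex(q)
        s2 = rx.sub("", s)
        if s2 != s:
            deleted = True
            s = s2
    # Internal runs of spaces (typically left by qualifier deletion) collapse
    # to one; edge spaces are stripped only when deletion created them, so a
    # genuine trailing space in the input survives to become an LD-1 fuzzy hit.
    s = re.sub(" {2,}", " ", s)
    if deleted:
        s = s.strip(" ")

    return CleanedName(
        raw=raw,
        cleaned=s,
        number_detected=number_detected,
        brackets_detected=brackets_detected,
    )


def match_key(name: str) -> str:
    """Normalization applied to both sides of an exact-match lookup.

    Internal runs of spaces collapse to one and every character after the
    first is lowercased; edge whitespace is preserved, so a trailing space
    still defeats exact matching (and is then caught by the fuzzy stage).
    """
    s = re.sub(" {2,}", " ", name)
    if len(s) > 1:
        s = s[0] + s[1:].lower()
    return s
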