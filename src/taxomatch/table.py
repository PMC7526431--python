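"""Table-level driver: match every row of a user table and summarise the run.

The run summary mirrors the standard way name-standardization exercises are
reported: each submitted name lands in exactly one of five categories —
unique direct match, multiple direct matches, unique fuzzy match, multiple
fuzzy matches, or no match. "Direct" means an exact (edit distance 0) hit at
the full-name stage; anything found by the bounded scan or by a fallback
stage counts as fuzzy. Names whose fuzzy candidate count exceeded the cap are
counted as unmatched and listed separately with their counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .backbone_io import Backbone
from .errors import ConfigError
from .matcher import MatchConfig, MatchResult, match_cascade
from .selector import select_one

logger = logging.getLogger(__name__)

__all__ = ["RunSummary", "match_table"]


@dataclass
class RunSummary:
    """Per-category tallies of one table run; the five counts sum to the row count."""

    unique_direct: int = 0
    multiple_direct: int = 0
    unique_fuzzy: int = 0
    multiple_fuzzy: int = 0
    no_match: int = 0
    overflow_names: list[tuple[str, int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return (
            self.unique_direct
            + self.multiple_direct
            + self.unique_fuzzy
            + self.multiple_fuzzy
            + self.no_match
        )

    def add(self, result: MatchResult) -> None:
        if not result.matched:
            self.no_match += 1
            if result.overflow is not None:
                self.overflow_names.append((result.query.raw, result.overflow))
        elif result.direct:
            if result.unique:
                self.unique_direct += 1
            else:
                self.multiple_direct += 1
        else:
            if result.unique:
                self.unique_fuzzy += 1
            else:
                self.multiple_fuzzy += 1


def match_table(
    backbone: Backbone,
    table: pd.DataFrame,
    name_column: str,
    authority_column: Optional[str] = None,
    config: Optional[MatchConfig] = None,
    select: bool = False,
) -> tuple[list[MatchResult], RunSummary]:
    """Match every row of ``table`` against the backbone.

    Row order is preserved; input values pass through untouched (writing the
    augmented table is :func:`taxomatch.backbone_io.write_results`). With
    ``select=True``, matched rows additionally get a single chosen candidate
    with its rationale. An unmatched name is data, not an error.
    """
    if config is None:
        config = MatchConfig()
    if name_column not in table.columns:
        raise ConfigError(f"name column {name_column!r} not found in input table")
    if authority_column is not None and authority_column not in table.columns:
        raise ConfigError(
            f"authority column {authority_column!r} not found in input table"
        )

    results: list[MatchResult] = []
    summary = RunSummary()
    for i, (_, row) in enumerate(table.iterrows(), start=1):
        raw = "" if pd.isna(row[name_column]) else str(row[name_column])
        authority = None
        if authority_column is not None:
            val = row[authority_column]
            if not pd.isna(val) and str(val) != "":
                authority = str(val)
        result = match_cascade(backbone, raw, authority, config)
        if select and result.matched:
            result.selection = select_one(result, use_author=True)
        summary.add(result)
        results.append(result)
        logger.debug(
            "matched %r: stage=%s candidates=%d",
            raw,
            result.stage_used,
            len(result.candidates),
        )
        if i % 1000 == 0:
            logger.info("matched %d names", i)
    return results, summary
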