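"""Scikit-learn style estimator wrapping the matching cascade.

``TaxonNameMatcher`` treats name standardization as a fit/predict problem:
``fit`` indexes a labelled reference (the taxonomic backbone), ``predict``
maps an array of submitted name strings to accepted taxon IDs, and
``transform`` returns the full per-name match bookkeeping as a DataFrame.
Parameters follow the scikit-learn contract (``get_params``/``set_params``,
fitted attributes with a trailing underscore), so the matcher composes with
``sklearn.base.clone`` and pipeline-style tooling.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .backbone_io import Backbone, RESULT_COLUMNS, record_to_row
from .distance import DistanceBound
from .matcher import MatchConfig, MatchResult, match_cascade
from .normalize import default_qualifiers
from .selector import select_one

__all__ = ["TaxonNameMatcher"]


class TaxonNameMatcher(BaseEstimator):
    """Match submitted plant names to a taxonomic backbone.

    Parameters mirror the cascade tunables: ``max_distance`` is the fuzzy
    edit allowance (a fraction of the pattern length unless
    ``absolute_distance``), ``fuzzy_max`` caps the fuzzy candidate count,
    ``fuzzy_min`` keeps only minimal-distance candidates, ``fuzzy_two`` /
    ``fuzzy_one`` enable the prefix fallback stages, ``tolower`` /
    ``nonumber`` / ``nobrackets`` / ``sub_pattern`` / ``trim`` control name
    cleaning, and ``accepted_name_match`` resolves synonyms to accepted
    records. ``use_author`` lets a submitted authority string break ties
    during single-match selection.

    Examples
    --------
    >>> from taxomatch import TaxonNameMatcher
    >>> from taxomatch.synthgen import SynthSpec, generate_backbone
    >>> backbone, _ = generate_backbone(SynthSpec(n_accepted=20, seed=7))
    >>> m = TaxonNameMatcher().fit(backbone)
    >>> ids = m.predict([backbone.records[0].scientific_name])
    """

    def __init__(
        self,
        max_distance: float = 0.1,
        absolute_distance: bool = False,
        fuzzy_max: int = 250,
        fuzzy_min: bool = True,
        fuzzy_two: bool = True,
        fuzzy_one: bool = True,
        tolower: bool = False,
        nonumber: bool = True,
        nobrackets: bool = True,
        sub_pattern: Optional[Sequence[str]] = None,
        accepted_name_match: bool = True,
        trim: bool = False,
        use_author: bool = True,
    ):
        self.max_distance = max_distance
        self.absolute_distance = absolute_distance
        self.fuzzy_max = fuzzy_max
        self.fuzzy_min = fuzzy_min
        self.fuzzy_two = fuzzy_two
        self.fuzzy_one = fuzzy_one
        self.tolower = tolower
        self.nonumber = nonumber
        self.nobrackets = nobrackets
        self.sub_pattern = sub_pattern
        self.accepted_name_match = accepted_name_match
        self.trim = trim
        self.use_author = use_author

    def _config(self) -> MatchConfig:
        bound = DistanceBound(
            self.max_distance,
            "absolute" if self.absolute_distance else "fraction",
        )
        patterns = (
            default_qualifiers()
            if self.sub_pattern is None
            else list(self.sub_pattern)
        )
        return MatchConfig(
            max_distance=bound,
            fuzzy_max=self.fuzzy_max,
            fuzzy_min=self.fuzzy_min,
            fuzzy_two=self.fuzzy_two,
            fuzzy_one=self.fuzzy_one,
            tolower=self.tolower,
            nonumber=self.nonumber,
            nobrackets=self.nobrackets,
            sub_pattern=patterns,
            accepted_name_match=self.accepted_name_match,
            trim=self.trim,
        )

    def fit(self, X, y=None) -> "TaxonNameMatcher":
        """Index the backbone. ``X`` is a :class:`Backbone` or a path to a
        tab-delimited backbone table in the WFO dialect."""
        if isinstance(X, Backbone):
            backbone = X
        elif isinstance(X, (str, Path)):
            from .backbone_io import load_backbone

            backbone = load_backbone(X)
        else:
            raise TypeError(
                "fit expects a Backbone or a path to a backbone table, "
                f"got {type(X).__name__}"
            )
        self.backbone_ = backbone
        self.n_records_ = len(backbone)
        return self

    def match(
        self,
        names: Iterable[str],
        authorities: Optional[Iterable[Optional[str]]] = None,
    ) -> list[MatchResult]:
        """Run the cascade per name; no single-match selection."""
        check_is_fitted(self, "backbone_")
        config = self._config()
        names = list(names)
        auths: list[Optional[str]]
        if authorities is None:
            auths = [None] * len(names)
        else:
            auths = list(authorities)
            if len(auths) != len(names):
                raise ValueError("authorities must align with names")
        return [
            match_cascade(self.backbone_, str(n), a, config)
            for n, a in zip(names, auths)
        ]

    def predict(self, X: Iterable[str]) -> np.ndarray:
        """Accepted taxon ID per submitted name ('' when unmatched).

        Multi-candidate matches are reduced by the selection cascade
        (author distance when available, then status preference, then
        smallest numeric ID).
        """
        results = self.match(X)
        out = []
        for r in results:
            if not r.matched:
                out.append("")
            else:
                out.append(select_one(r, use_author=self.use_author).chosen.record.taxon_id)
        return np.asarray(out, dtype=object)

    def transform(self, X: Iterable[str]) -> pd.DataFrame:
        """Full match bookkeeping per name, one row per name.

        Columns: the submitted name, the standard result flags, the selected
        record's backbone fields, and the selection rationale.
        """
        results = self.match(X)
        for r in results:
            if r.matched:
                r.selection = select_one(r, use_author=self.use_author)
        from .backbone_io import _result_rows

        rows = []
        for r in results:
            row: dict[str, object] = {"spec.name": r.query.raw}
            row.update(_result_rows(r)[0])
            if r.matched:
                row.update(record_to_row(r.selection.chosen.record))
            rows.append(row)
        return pd.DataFrame(rows)

    def fit_predict(self, X, names: Iterable[str]) -> np.ndarray:
        return self.fit(X).predict(names)
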