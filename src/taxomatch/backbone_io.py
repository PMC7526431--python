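"""Reading, validating, indexing, and writing taxonomic-backbone tables.

The backbone is a static tab-delimited dump in the World Flora Online
``classification.txt`` dialect: one row per name record, Darwin Core headers
(``taxonID``, ``scientificName``, ``scientificNameAuthorship``, ``taxonRank``,
``taxonomicStatus``, ``acceptedNameUsageID``, ``family``, ``genus``, ...).
Synonym records point at their accepted record via ``acceptedNameUsageID``.

Real dumps are imperfect — dangling accepted-name pointers exist — so loading
favours robustness: dangling pointers are warned about and tolerated, and rows
without a scientific name are dropped with a warning. Duplicate taxon IDs and
missing mandatory columns are hard errors.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import BackboneFormatError, BackboneValidationError
from .normalize import match_key

logger = logging.getLogger(__name__)

__all__ = [
    "BackboneRecord",
    "Backbone",
    "load_backbone",
    "write_backbone",
    "write_results",
    "wfo_id_sort_key",
    "RESULT_COLUMNS",
]

# Darwin Core header -> internal field, for the WFO classification.txt dialect.
WFO_COLUMN_MAP: dict[str, str] = {
    "taxonID": "taxon_id",
    "scientificName": "scientific_name",
    "scientificNameAuthorship": "authorship",
    "taxonRank": "rank",
    "taxonomicStatus": "status",
    "acceptedNameUsageID": "accepted_id",
    "family": "family",
    "genus": "genus",
    "specificEpithet": "specific_epithet",
    "infraspecificEpithet": "infraspecific_epithet",
}
_FIELD_TO_WFO = {v: k for k, v in WFO_COLUMN_MAP.items()}

_MANDATORY = ("taxon_id", "scientific_name", "status")

# Result columns appended after the input columns, before the backbone columns.
RESULT_COLUMNS = [
    "Matched",
    "Fuzzy",
    "Fuzzy.dist",
    "Auth.dist",
    "Unique",
    "Number.detected",
    "Brackets.detected",
    "Fuzzy.two",
    "Fuzzy.one",
    "Old.status",
    "Old.ID",
    "Old.name",
    "One.Reason",
]

_WFO_ID_RE = re.compile(r"^wfo-(\d+)$")


def wfo_id_sort_key(taxon_id: str) -> tuple[int, int | str]:
    """Sort key implementing 'smallest WFO ID'.

    Conforming IDs (``wfo-`` + digits) compare by the integer value of the
    digit suffix; anything else falls back to lexicographic comparison and
    sorts after all conforming IDs.
    """
    m = _WFO_ID_RE.match(taxon_id)
    if m:
        return (0, int(m.group(1)))
    return (1, taxon_id)


@dataclass
class BackboneRecord:
    """One row of the taxonomic backbone."""

    taxon_id: str
    scientific_name: str
    authorship: str = ""
    rank: str = ""
    status: str = ""
    accepted_id: str = ""
    family: str = ""
    genus: str = ""
    specific_epithet: str = ""
    infraspecific_epithet: str = ""
    extras: dict[str, str] = field(default_factory=dict)

    def status_norm(self) -> str:
        """Case-insensitive, trimmed status label."""
        return self.status.strip().lower()


class Backbone:
    """Indexed collection of backbone records.

    Indexes:

    - ``by_id``: taxon_id -> record (unique),
    - ``by_name``: exact-match key of the full scientific name -> records,
    - ``by_first_word``: exact-match key of the first name token -> records.

    ``dangling_ids`` holds IDs of synonym records whose accepted-name pointer
    does not resolve within this backbone; they are tolerated (the synonym is
    simply unresolvable), not rejected.
    """

    def __init__(self, records: Iterable[BackboneRecord]):
        self.records: list[BackboneRecord] = list(records)
        self.by_id: dict[str, BackboneRecord] = {}
        self.by_name: dict[str, list[BackboneRecord]] = {}
        self.by_first_word: dict[str, list[BackboneRecord]] = {}
        for rec in self.records:
            if not rec.taxon_id:
                raise BackboneValidationError("record with empty taxon_id")
            if not rec.scientific_name:
                raise BackboneValidationError(
                    f"record {rec.taxon_id!r} has an empty scientific name"
                )
            if rec.taxon_id in self.by_id:
                raise BackboneValidationError(f"duplicate taxon_id: {rec.taxon_id!r}")
            self.by_id[rec.taxon_id] = rec
            self.by_name.setdefault(match_key(rec.scientific_name), []).append(rec)
            first = rec.scientific_name.split()
            if first:
                self.by_first_word.setdefault(match_key(first[0]), []).append(rec)
        self.dangling_ids: set[str] = set()
        for rec in self.records:
            if (
                "synonym" in rec.status_norm()
                and rec.accepted_id
                and rec.accepted_id not in self.by_id
            ):
                self.dangling_ids.add(rec.taxon_id)
        if self.dangling_ids:
            warnings.warn(
                f"{len(self.dangling_ids)} synonym record(s) have dangling "
                "acceptedNameUsageID pointers and will not be resolved",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _map_columns(columns: Sequence[str], dialect: str) -> dict[str, str]:
    if dialect == "wfo":
        return {c: WFO_COLUMN_MAP.get(c, c) for c in columns}
    if dialect == "generic":
        return {c: c for c in columns}
    raise ValueError(f"unknown dialect: {dialect!r}")


def load_backbone(path: str | Path, dialect: str = "wfo") -> Backbone:
    """Load and index a tab-delimited backbone table.

    Mandatory columns (after dialect mapping): taxon ID, scientific name,
    taxonomic status. Missing optional columns become empty strings; unknown
    columns are carried through verbatim in ``extras``. Row order is
    preserved. Rows with an empty scientific name are dropped with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
        )
    except pd.errors.EmptyDataError:
        raise BackboneFormatError(f"backbone file is empty: {path}") from None
    colmap = _map_columns(list(df.columns), dialect)
    present = set(colmap.values())
    for needed in _MANDATORY:
        if needed not in present:
            wanted = _FIELD_TO_WFO.get(needed, needed) if dialect == "wfo" else needed
            raise BackboneFormatError(f"backbone is missing mandatory column {wanted!r}")

    core_fields = set(WFO_COLUMN_MAP.values())
    records: list[BackboneRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        values = dict(zip(df.columns, row))
        kwargs: dict[str, str] = {}
        extras: dict[str, str] = {}
        for col, val in values.items():
            fld = colmap[col]
            if fld in core_fields:
                kwargs[fld] = val
            else:
                extras[col] = val
        if not kwargs.get("scientific_name", ""):
            n_dropped += 1
            continue
        records.append(BackboneRecord(extras=extras, **kwargs))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} backbone row(s) with an empty scientific name",
            stacklevel=2,
        )
    backbone = Backbone(records)
    logger.info("loaded backbone %s: %d records", path.name, len(backbone))
    return backbone


def backbone_columns(backbone_or_records) -> list[str]:
    """Output column order for backbone fields: WFO core headers then extras."""
    records = list(backbone_or_records)
    cols = list(WFO_COLUMN_MAP.keys())
    seen = set(cols)
    for rec in records:
        for k in rec.extras:
            if k not in seen:
                seen.add(k)
                cols.append(k)
    return cols


def record_to_row(rec: BackboneRecord) -> dict[str, str]:
    """Flatten a record back to its WFO-dialect column values."""
    row = {wfo: getattr(rec, fld) for wfo, fld in WFO_COLUMN_MAP.items()}
    row.update(rec.extras)
    return row


def write_backbone(backbone: Backbone, path: str | Path) -> Path:
    """Write a backbone in the same tab-delimited dialect ``load_backbone`` reads."""
    path = Path(path)
    cols = backbone_columns(backbone)
    rows = [record_to_row(rec) for rec in backbone]
    df = pd.DataFrame(rows, columns=cols).fillna("")
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def _result_rows(result) -> list[dict[str, object]]:
    """Expand one MatchResult into output-row dictionaries (no input columns)."""
    base: dict[str, object] = {c: "" for c in RESULT_COLUMNS}
    base["Matched"] = result.matched
    base["Unique"] = result.unique
    base["Number.detected"] = result.query.number_detected
    base["Brackets.detected"] = result.query.brackets_detected
    base["Fuzzy.two"] = result.stage_used == "two_words"
    base["Fuzzy.one"] = result.stage_used == "one_word"
    base["Fuzzy"] = False
    if not result.matched:
        return [base]

    candidates = result.candidates
    if result.selection is not None:
        candidates = [result.selection.chosen]
    rows = []
    for cand in candidates:
        row = dict(base)
        row["Fuzzy"] = cand.fuzzy
        row["Fuzzy.dist"] = cand.fuzzy_dist
        row["Auth.dist"] = cand.auth_dist if cand.auth_dist is not None else ""
        row["Old.status"] = cand.old_status
        row["Old.ID"] = cand.old_id
        row["Old.name"] = cand.old_name
        if result.selection is not None:
            row["One.Reason"] = result.selection.reason
        row.update(record_to_row(cand.record))
        rows.append(row)
    return rows


def write_results(results, input_table: pd.DataFrame, path: str | Path) -> Path:
    """Write the augmented result table.

    Output rows carry all original input columns, then the match bookkeeping
    columns (``Matched``, ``Fuzzy``, ``Fuzzy.dist``, ``Auth.dist``,
    ``Unique``, ``Number.detected``, ``Brackets.detected``, ``Fuzzy.two``,
    ``Fuzzy.one``, ``Old.status``, ``Old.ID``, ``Old.name``, ``One.Reason``),
    then every backbone column of the matched record (empty when unmatched).
    A result whose candidate set was not reduced to one expands to one output
    row per surviving candidate, all sharing the input values. Delimiter is
    chosen by extension: tab for ``.tsv``/``.txt``, comma otherwise.
    """
    if len(results) != len(input_table):
        raise ValueError(
            f"{len(results)} results do not align with {len(input_table)} input rows"
        )
    path = Path(path)
    matched_records = [
        c.record for r in results for c in (r.candidates if r.matched else [])
    ]
    bb_cols = backbone_columns(matched_records)
    out_rows: list[dict[str, object]] = []
    for (_, in_row), result in zip(input_table.iterrows(), results):
        in_values = in_row.to_dict()
        for row in _result_rows(result):
            merged = dict(in_values)
            merged.update(row)
            out_rows.append(merged)
    columns = list(input_table.columns) + RESULT_COLUMNS + bb_cols
    df = pd.DataFrame(out_rows, columns=columns).fillna("")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df.to_csv(path, sep=sep, index=False, encoding="utf-8")
    except OSError as exc:
        raise IOError(f"cannot write results to {path}: {exc}") from exc
    return path
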