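"""Deterministic generator of synthetic backbones and perturbed query lists.

Real backbone dumps cannot ship with the package, so tests and calibration
runs use synthetic ones that reproduce the structural features the matcher
relies on: accepted species records, synonym records pointing at accepted IDs,
optional homonym pairs (same name, different authorship), zero-padded
``wfo-``-style IDs, authorship strings, and optional genus-rank records.

Names are built from consonant-vowel syllables ("Baro tilusa"), which keeps
the generator dependency-free and makes the pairwise edit-distance floor
(``min_separation``) enforceable by rejection sampling. Query lists apply a
chosen perturbation (random edits, last-character deletion, trailing space,
uppercasing, qualifier insertion, bracketed tails, morphospecies numbers) to
each record's name and carry the ground-truth taxon ID.

Everything is driven by a single integer seed: same spec, same bytes out.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Optional

from .backbone_io import Backbone, BackboneRecord
from .distance import bounded_levenshtein
from .errors import GenerationError

__all__ = ["SynthSpec", "generate_backbone", "perturb_queries", "PERTURBATIONS"]

PERTURBATIONS = (
    "none",
    "k_edits",
    "last_char_deletion",
    "trailing_space",
    "uppercase",
    "qualifier_insertion",
    "bracket_suffix",
    "number_suffix",
)

_CONS = "bcdfglmnprstv"
_VOWELS = "aeiou"
_EDIT_ALPHABET = "abcdefghijklmnopqrstuvwxyz"
_MAX_TRIES = 500


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic backbone / query generation.

    n_accepted
        Number of accepted species records.
    synonym_rate
        Additional synonym records as a fraction of ``n_accepted`` (default
        0.5: backbones of the WFO kind carry roughly as many synonym names as
        accepted ones).
    homonym_rate
        Fraction of accepted names duplicated under a second authorship
        (default 0: homonyms are exact duplicates, so they are opted into by
        tests that exercise selection, not part of the separation-controlled
        baseline).
    min_separation
        Minimum pairwise edit distance enforced among all distinct generated
        names (accepted and synonym), by rejection sampling.
    seed
        Integer seed; identical specs generate identical output.
    perturbation / k
        Query perturbation mode, and the edit count for ``k_edits``.
    genus_records
        Also emit one genus-rank record per genus, giving first-word fallback
        searches a matchable target.
    """

    n_accepted: int = 100
    synonym_rate: float = 0.5
    homonym_rate: float = 0.0
    min_separation: int = 3
    seed: int = 1
    perturbation: str = "none"
    k: int = 1
    genus_records: bool = False

    def __post_init__(self) -> None:
        if self.n_accepted < 1:
            raise ValueError("n_accepted must be >= 1")
        if not (0 <= self.synonym_rate < 1):
            raise ValueError("synonym_rate must be in [0, 1)")
        if not (0 <= self.homonym_rate < 1):
            raise ValueError("homonym_rate must be in [0, 1)")
        if self.perturbation not in PERTURBATIONS:
            raise ValueError(f"unknown perturbation: {self.perturbation!r}")


def _syllable(rng: random.Random) -> str:
    return rng.choice(_CONS) + rng.choice(_VOWELS)


def _word(rng: random.Random, n_syll: int) -> str:
    return "".join(_syllable(rng) for _ in range(n_syll))


def _authorship(rng: random.Random) -> str:
    name = _word(rng, rng.randint(1, 2)).capitalize() + "."
    if rng.random() < 0.3:
        return f"({_word(rng, 1).capitalize()}.) {name}"
    return name


def _separated(name: str, existing: list[str], floor: int) -> bool:
    if floor <= 0:
        return name not in existing
    for other in existing:
        if bounded_levenshtein(name, other, floor - 1) is not None:
            return False
    return True


def _new_name(
    rng: random.Random, make, existing: list[str], floor: int, what: str
) -> str:
    for _ in range(_MAX_TRIES):
        name = make()
        if _separated(name, existing, floor):
            return name
    raise GenerationError(
        f"could not generate a {what} at pairwise distance >= {floor} "
        f"after {_MAX_TRIES} tries ({len(existing)} names present)"
    )


def generate_backbone(spec: SynthSpec) -> tuple[Backbone, dict[str, str]]:
    """Generate a synthetic backbone and its resolution ground truth.

    Returns ``(backbone, truth)`` where ``truth`` maps every record's taxon ID
    to the ID of its accepted record (itself for non-synonyms). Record layout:
    accepted species, then synonyms, then homonym duplicates, then optional
    genus records; IDs are ``wfo-`` + zero-padded sequence in that order.
    """
    rng = random.Random(spec.seed)
    floor = spec.min_separation

    n_genera = max(1, round(spec.n_accepted ** 0.5))
    genera: list[str] = []
    for _ in range(n_genera):
        genera.append(
            _new_name(
                rng,
                lambda: _word(rng, rng.randint(2, 3)).capitalize(),
                genera,
                floor,
                "genus name",
            )
        )

    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"wfo-{counter:010d}"

    names: list[str] = []
    records: list[BackboneRecord] = []
    truth: dict[str, str] = {}

    def species_name() -> tuple[str, str, str]:
        genus = rng.choice(genera)
        epithet = _word(rng, rng.randint(2, 4))
        return f"{genus} {epithet}", genus, epithet

    accepted: list[BackboneRecord] = []
    for _ in range(spec.n_accepted):
        holder: dict[str, tuple[str, str, str]] = {}

        def make() -> str:
            holder["v"] = species_name()
            return holder["v"][0]

        name = _new_name(rng, make, names, floor, "species name")
        _, genus, epithet = holder["v"]
        rec = BackboneRecord(
            taxon_id=next_id(),
            scientific_name=name,
            authorship=_authorship(rng),
            rank="species",
            status="Accepted",
            family=genus + "aceae",
            genus=genus,
            specific_epithet=epithet,
        )
        names.append(name)
        records.append(rec)
        accepted.append(rec)
        truth[rec.taxon_id] = rec.taxon_id

    n_syn = round(spec.n_accepted * spec.synonym_rate)
    for _ in range(n_syn):
        holder = {}

        def make() -> str:
            holder["v"] = species_name()
            return holder["v"][0]

        name = _new_name(rng, make, names, floor, "synonym name")
        _, genus, epithet = holder["v"]
        target = rng.choice(accepted)
        rec = BackboneRecord(
            taxon_id=next_id(),
            scientific_name=name,
            authorship=_authorship(rng),
            rank="species",
            status="Synonym",
            accepted_id=target.taxon_id,
            family=genus + "aceae",
            genus=genus,
            specific_epithet=epithet,
        )
        names.append(name)
        records.append(rec)
        truth[rec.taxon_id] = target.taxon_id

    n_hom = round(spec.n_accepted * spec.homonym_rate)
    if n_hom:
        for src in rng.sample(accepted, min(n_hom, len(accepted))):
            target = rng.choice(accepted)
            rec = BackboneRecord(
                taxon_id=next_id(),
                scientific_name=src.scientific_name,
                authorship=_authorship(rng),
                rank="species",
                status="Synonym",
                accepted_id=target.taxon_id,
                family=src.family,
                genus=src.genus,
                specific_epithet=src.specific_epithet,
            )
            records.append(rec)
            truth[rec.taxon_id] = target.taxon_id

    if spec.genus_records:
        for genus in genera:
            rec = BackboneRecord(
                taxon_id=next_id(),
                scientific_name=genus,
                authorship=_authorship(rng),
                rank="genus",
                status="Accepted",
                family=genus + "aceae",
                genus=genus,
            )
            records.append(rec)
            truth[rec.taxon_id] = rec.taxon_id

    return Backbone(records), truth


def _k_edits(rng: random.Random, name: str, k: int) -> str:
    s = name
    for _ in range(k):
        ops = ["substitute", "insert"]
        if len(s) > 1:
            ops.append("delete")
        op = rng.choice(ops)
        if op == "delete":
            i = rng.randrange(len(s))
            s = s[:i] + s[i + 1 :]
        elif op == "insert":
            i = rng.randrange(len(s) + 1)
            s = s[:i] + rng.choice(_EDIT_ALPHABET) + s[i:]
        else:
            i = rng.randrange(len(s))
            c = rng.choice([x for x in _EDIT_ALPHABET if x != s[i]])
            s = s[:i] + c + s[i + 1 :]
    return s


def perturb_queries(
    backbone: Backbone, spec: SynthSpec, seed: Optional[int] = None
) -> list[tuple[str, str]]:
    """One perturbed query per species-rank record, with ground truth.

    Returns ``(query, true_taxon_id)`` pairs in backbone order. ``seed``
    overrides ``spec.seed`` for the query stream, so several independent
    query sets can be drawn over one fixed backbone. For ``number_suffix``
    the true target is the genus-rank record when the backbone has one
    (a numbered morphospecies resolves to the genus, not to any species).
    """
    if seed is None:
        seed = spec.seed
    rng = random.Random(f"queries-{seed}")
    genus_ids = {
        rec.genus: rec.taxon_id for rec in backbone if rec.rank == "genus"
    }
    out: list[tuple[str, str]] = []
    for rec in backbone:
        if rec.rank == "genus":
            continue
        name = rec.scientific_name
        truth = rec.taxon_id
        mode = spec.perturbation
        if mode == "none":
            q = name
        elif mode == "k_edits":
            q = _k_edits(rng, name, spec.k)
        elif mode == "last_char_deletion":
            q = name[:-1] if len(name) > 1 else name
        elif mode == "trailing_space":
            q = name + " "
        elif mode == "uppercase":
            q = name.upper()
        elif mode == "qualifier_insertion":
            toks = name.split()
            if len(toks) > 1:
                q = toks[0] + " cf. " + " ".join(toks[1:])
            else:
                q = name + " sp."
        elif mode == "bracket_suffix":
            other = rng.choice(backbone.records)
            q = f"{name} ({other.scientific_name})"
        elif mode == "number_suffix":
            toks = name.split()
            q = toks[0] + " sp. " + str(rng.randint(1, 9))
            truth = genus_ids.get(rec.genus, rec.taxon_id)
        else:  # pragma: no cover - guarded by SynthSpec validation
            raise ValueError(mode)
        out.append((q, truth))
    return out
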