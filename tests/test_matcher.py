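"""The staged matching cascade: exact, parts, fuzzy, fallbacks, resolution."""

from __future__ import annotations

import random

from oracles import brute_force_min_candidates, dp_levenshtein
from taxomatch.backbone_io import Backbone, BackboneRecord
from taxomatch.distance import DistanceBound
from taxomatch.matcher import (
    MatchConfig,
    match_cascade,
    match_exact,
    match_fuzzy,
    match_parts,
    resolve_accepted,
)
from taxomatch.synthgen import SynthSpec, generate_backbone, perturb_queries


def test_exact_single_hit(vignette_backbone):
    cands = match_exact(vignette_backbone, "Ulmus glabra")
    assert len(cands) == 1
    assert cands[0].fuzzy_dist == 0 and not cands[0].fuzzy
    assert cands[0].record.taxon_id == "wfo-0000416717"


def test_exact_no_hit(vignette_backbone):
    assert match_exact(vignette_backbone, "Nothofagus dombeyi") == []


def test_exact_homonyms_both_returned(vignette_backbone):
    cands = match_exact(vignette_backbone, "Bauhinia grandifolia")
    assert len(cands) == 2
    assert {c.record.authorship for c in cands} == {"(Bong.) D. Dietr.", "Steud."}


def test_exact_is_insensitive_to_case_beyond_first_char(vignette_backbone):
    assert len(match_exact(vignette_backbone, "ULMUS GLABRA")) == 1
    assert len(match_exact(vignette_backbone, "Ulmus  glabra")) == 1
    # trailing space defeats exact matching (it is a fuzzy, LD-1 case)
    assert match_exact(vignette_backbone, "Ulmus glabra ") == []


def test_parts_matching(vignette_backbone):
    hit = match_parts(vignette_backbone, "Ulmus", "glabra")
    assert [c.record.taxon_id for c in hit] == ["wfo-0000416717"]
    # rank label is irrelevant: the variety is found for subspecies-style parts
    hit = match_parts(vignette_backbone, "Keckiella", "antirrhinoides", "microphylla")
    assert [c.record.taxon_id for c in hit] == ["wfo-0000577112"]
    # empty epithets match only records with empty epithets
    hit = match_parts(vignette_backbone, "Miconia")
    assert [c.record.taxon_id for c in hit] == ["wfo-0000947218"]


def test_fuzzy_single_candidate(vignette_backbone):
    cands, overflow = match_fuzzy(
        vignette_backbone, "Upuna borneensis", MatchConfig()
    )
    assert overflow is None
    assert [c.record.scientific_name for c in cands] == ["Upuna boreensis"]
    assert cands[0].fuzzy_dist == 1 and cands[0].fuzzy


def test_fuzzy_min_keeps_only_zero_distance_on_exact_query(vignette_backbone):
    cands, _ = match_fuzzy(vignette_backbone, "Ulmus glabra", MatchConfig())
    assert [c.fuzzy_dist for c in cands] == [0]


def test_fuzzy_overflow_reports_count():
    records = [
        BackboneRecord(taxon_id=f"wfo-{i:010d}", scientific_name=f"Aa{chr(97 + i % 26)}a",
                       status="Accepted")
        for i in range(30)
    ]
    bb = Backbone(records)
    config = MatchConfig(max_distance=DistanceBound(3, "absolute"), fuzzy_max=10)
    cands, overflow = match_fuzzy(bb, "Aaaa", config)
    assert cands == []
    assert overflow is not None and overflow > 10


def test_fuzzy_minimality_matches_brute_force():
    spec = SynthSpec(n_accepted=60, synonym_rate=0.3, seed=11, perturbation="k_edits", k=2)
    bb, _ = generate_backbone(spec)
    names = [r.scientific_name for r in bb]
    config = MatchConfig()
    for query, _truth in perturb_queries(bb, spec)[:40]:
        allowed = config.max_distance.allowed(query)
        dmin, expected = brute_force_min_candidates(query, names, allowed)
        cands, overflow = match_fuzzy(bb, query, config)
        assert overflow is None
        got = {c.record.scientific_name for c in cands}
        assert got == expected
        if dmin is not None:
            assert all(c.fuzzy_dist == dmin for c in cands)


def test_cascade_number_shortcut_goes_to_first_word(vignette_backbone):
    res = match_cascade(vignette_backbone, "Miconia sp. 2")
    assert res.stage_used == "one_word"
    assert res.matched and res.candidates[0].record.scientific_name == "Miconia"
    assert res.query.number_detected


def test_cascade_full_stage_fuzzy(vignette_backbone):
    res = match_cascade(vignette_backbone, "Populus canescens")
    assert res.stage_used == "full"
    assert res.candidates[0].record.scientific_name == "Populus ×canescens"
    assert res.candidates[0].fuzzy and res.candidates[0].fuzzy_dist == 1


def test_cascade_wide_absolute_bound_catches_truncated_epithet(vignette_backbone):
    config = MatchConfig(max_distance=DistanceBound(9, "absolute"))
    res = match_cascade(vignette_backbone, "Solanum schlechtendali", config=config)
    assert res.candidates[0].record.scientific_name == "Solanum schlechtendalianum"
    assert res.candidates[0].fuzzy_dist == dp_levenshtein(
        "Solanum schlechtendali", "Solanum schlechtendalianum"
    )


def test_cascade_two_word_fallback(vignette_backbone):
    # authority dragged into the name field: full name fails, first two words hit
    res = match_cascade(vignette_backbone, "Ulmus glabra Hudson 1762 ex auct.",
                        config=MatchConfig(nonumber=False))
    assert res.stage_used == "two_words"
    assert res.candidates[0].record.taxon_id == "wfo-0000416717"


def test_cascade_one_word_fallback(vignette_backbone):
    res = match_cascade(vignette_backbone, "Miconia unheardofepithet")
    assert res.stage_used == "one_word"
    assert res.candidates[0].record.rank == "genus"


def test_cascade_stage_order_skips_fallbacks_when_full_matches(vignette_backbone):
    res = match_cascade(vignette_backbone, "Ulmus glabra")
    assert res.stage_used == "full"
    assert res.unique


def test_cascade_degenerate_name_unmatched(vignette_backbone):
    res = match_cascade(vignette_backbone, "sp.")
    assert not res.matched and res.stage_used == "none"
    res = match_cascade(vignette_backbone, "   ")
    assert not res.matched


def test_cascade_brackets_vignette(vignette_backbone):
    res = match_cascade(vignette_backbone, "Dysoxylum euphlebium (Dysoxylum alliaceum)")
    assert res.query.brackets_detected
    # matched the synonym, resolved to the accepted name
    c = res.candidates[0]
    assert c.record.scientific_name == "Dysoxylum alliaceum"
    assert c.old_name == "Dysoxylum euphlebium"
    assert c.old_id == "wfo-0000642022"
    assert c.old_status == "Synonym"


def test_resolution_preserves_distance_and_stage(vignette_backbone):
    res = match_cascade(vignette_backbone, "Dysoxylum euphlebium ")  # trailing space
    c = res.candidates[0]
    assert c.fuzzy_dist == 1 and c.stage == "full"
    assert c.record.scientific_name == "Dysoxylum alliaceum"


def test_resolution_leaves_accepted_untouched(vignette_backbone):
    res = match_cascade(vignette_backbone, "Ulmus glabra")
    c = res.candidates[0]
    assert c.old_status == c.old_id == c.old_name == ""


def test_dangling_pointer_flagged():
    import pytest

    with pytest.warns(UserWarning, match="dangling"):
        bb = Backbone([
            BackboneRecord(taxon_id="wfo-0000000001", scientific_name="Aa bb",
                           status="Synonym", accepted_id="wfo-9999999999"),
        ])
    res = match_cascade(bb, "Aa bb")
    c = res.candidates[0]
    assert c.old_status == "dangling"
    assert c.record.taxon_id == "wfo-0000000001"  # unchanged


def test_auth_dist_computed_against_original_record(vignette_backbone):
    res = match_cascade(vignette_backbone, "Dysoxylum euphlebium", "Merr.")
    c = res.candidates[0]
    # authority compared to the synonym's ("Merr."), not the accepted record's
    assert c.auth_dist == 0
    assert c.record.scientific_name == "Dysoxylum alliaceum"


def test_determinism(vignette_backbone):
    a = match_cascade(vignette_backbone, "Scottellia coriacea", "A. Chev.")
    b = match_cascade(vignette_backbone, "Scottellia coriacea", "A. Chev.")
    assert a == b


def test_candidate_order_is_distance_then_numeric_id(vignette_backbone):
    res = match_cascade(vignette_backbone, "Scottellia coriacea")
    ids = [c.record.taxon_id for c in res.candidates]
    assert ids == ["wfo-0000913932", "wfo-0000913938"]


def test_recovery_of_one_edit_perturbations():
    spec = SynthSpec(n_accepted=60, synonym_rate=0.4, min_separation=3, seed=5,
                     perturbation="k_edits", k=1)
    bb, _ = generate_backbone(spec)
    rng = random.Random(99)
    queries = perturb_queries(bb, spec)
    for query, truth in rng.sample(queries, 50):
        res = match_cascade(bb, query)
        assert res.unique, query
        assert res.candidates[0].original_id() == truth
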