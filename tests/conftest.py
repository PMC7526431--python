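from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from taxomatch.backbone_io import Backbone, BackboneRecord

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


def rec(taxon_id, name, authorship="", rank="species", status="Accepted",
        accepted_id="", family="", genus="", species="", infra=""):
    if not genus and " " in name:
        genus = name.split()[0]
    if not species and len(name.split()) >= 2:
        species = name.split()[1]
    return BackboneRecord(
        taxon_id=taxon_id,
        scientific_name=name,
        authorship=authorship,
        rank=rank,
        status=status,
        accepted_id=accepted_id,
        family=family,
        genus=genus,
        specific_epithet=species,
        infraspecific_epithet=infra,
    )


@pytest.fixture
def vignette_backbone() -> Backbone:
    """Hand-built backbone covering the documented worked examples:
    homonymous Bauhinia records, the Scottellia ID tie, the Dysoxylum
    synonym, the Upuna misspelling target, the Populus hybrid, a genus-rank
    Miconia record, and an infraspecific Keckiella variety."""
    return Backbone([
        rec("wfo-0000416717", "Ulmus glabra", "Huds."),
        rec("wfo-0000212101", "Bauhinia grandifolia", "(Bong.) D. Dietr."),
        rec("wfo-0000212102", "Bauhinia grandifolia", "Steud.",
            status="Synonym", accepted_id="wfo-0000212101"),
        rec("wfo-0000913932", "Scottellia coriacea", "A. Chev. ex Hutch. & Dalziel"),
        rec("wfo-0000913938", "Scottellia coriacea", "A. Chev."),
        rec("wfo-0000642021", "Dysoxylum alliaceum", "(Blume) Blume"),
        rec("wfo-0000642022", "Dysoxylum euphlebium", "Merr.",
            status="Synonym", accepted_id="wfo-0000642021"),
        rec("wfo-0000411203", "Upuna boreensis", "Sym."),
        rec("wfo-0000928401", "Populus ×canescens", "(Aiton) Sm."),
        rec("wfo-0001032105", "Solanum schlechtendalianum", "Walp."),
        rec("wfo-0000947218", "Miconia", "Ruiz & Pav.", rank="genus", genus="Miconia"),
        rec("wfo-0000577112", "Keckiella antirrhinoides var. microphylla",
            "(A. Gray) N. H. Holmgren", rank="variety",
            genus="Keckiella", species="antirrhinoides", infra="microphylla"),
        rec("wfo-0000577113", "Xylosma intermedia", "(Seem.) Griseb."),
        rec("wfo-0000577114", "Xylosma intermedia", "(Seem.) Triana & Planch.",
            status="Synonym", accepted_id="wfo-0000577113"),
    ])


@pytest.fixture
def ulmus_campestris_backbone() -> Backbone:
    """Two different synonyms of the same submitted name resolving to two
    different accepted species; the smallest original ID must decide."""
    return Backbone([
        rec("wfo-0000416800", "Ulmus glabra", "Huds."),
        rec("wfo-0000475800", "Planera aquatica", "J.F. Gmel."),
        rec("wfo-0000475766", "Ulmus campestris", "auct.",
            status="Synonym", accepted_id="wfo-0000475800"),
        rec("wfo-0000416717", "Ulmus campestris", "L.",
            status="Synonym", accepted_id="wfo-0000416800"),
    ])
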