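"""The seven novel-taxon case studies bundled with the package.

Seven isolates of a 43-member chicken gut culture collection turned out to
be taxonomically novel: three required new genera (Gallibacter,
Gallalistipes, Ructibacterium) and four were new species within existing
genera (Gemmiger, Olsenella, Pseudoflavonifractor, Sellimonas). Their formal
descriptions report the pairwise delineation metrics against the closest
relatives — 16S identities, ANI, type-species POCP, dDDH, genomic G+C —
and those printed values are encoded here verbatim as MetricBundles.

Running ``classify`` on these bundles reproduces the published verdicts and
serves as the reference regression set for the decision engine. Where a
description states only a qualitative fact (e.g. "POCP did not exceed 50%
for any close relative" without a number) the metric is left absent rather
than invented, and the engine decides from the evidence that was printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from polytax.delineation import MetricBundle, DelineationVerdict, classify


@dataclass(frozen=True)
class NovelTaxonCase:
    isolate_id: str
    candidate_name: str
    expected_rank: str                  # novel_genus | novel_species
    expected_genus: Optional[str]       # None => proposed-new genus
    gc: float                           # genomic G+C of the isolate, percent
    bundles: tuple[MetricBundle, ...]
    notes: tuple[str, ...] = ()


def _b(isolate: str, relative: str, identity=None, genus=None, ani=None,
       pocp=None, type_sp=False, dddh=None, gc_diff=None) -> MetricBundle:
    return MetricBundle(
        isolate_id=isolate, relative_name=relative, identity16S=identity,
        relative_genus=genus, ani=ani, pocp=pocp,
        pocp_is_to_type_species=type_sp, dddh=dddh, gc_diff=gc_diff,
    )


GALLIBACTER = NovelTaxonCase(
    isolate_id="Cla-CZ-54",
    candidate_name="Gallibacter intestinalis gen. nov., sp. nov.",
    expected_rank="novel_genus",
    expected_genus=None,
    gc=40.9,
    bundles=(
        _b("Cla-CZ-54", "Eubacterium brachy", identity=93.3, pocp=54.8),
        _b("Cla-CZ-54", "Eubacterium infirmum", identity=90.7),
        _b("Cla-CZ-54", "Anaerovorax odorimutans", identity=90.7),
        # type species of Eubacterium; its 16S identity to the isolate is
        # not reported, only the POCP
        _b("Cla-CZ-54", "Eubacterium limosum", pocp=22.5, type_sp=True),
    ),
    notes=("POCP of 54.8% to a non-type species does not anchor genus "
           "membership; the type-species value of 22.5% decides",),
)

GALLALISTIPES = NovelTaxonCase(
    isolate_id="Cla-CZ-119",
    candidate_name="Gallalistipes aquisgranensis gen. nov., sp. nov.",
    expected_rank="novel_genus",
    expected_genus=None,
    gc=58.0,
    bundles=(
        _b("Cla-CZ-119", "Alistipes onderdonkii", identity=92.5),
        _b("Cla-CZ-119", "Alistipes finegoldii", identity=92.3),
        _b("Cla-CZ-119", "Alistipes timonensis", identity=92.2),
        _b("Cla-CZ-119", "Alistipes indistinctus", identity=91.6, pocp=56.0),
        _b("Cla-CZ-119", "Alistipes putredinis", pocp=48.1, type_sp=True),
    ),
    notes=("POCP of 56% to the non-type Alistipes indistinctus; the "
           "type-species value of 48.1% supports a sister genus",),
)

GEMMIGER = NovelTaxonCase(
    isolate_id="Cla-CZ-245",
    candidate_name="Gemmiger gallinarum sp. nov.",
    expected_rank="novel_species",
    expected_genus="Gemmiger",
    gc=59.2,
    bundles=(
        _b("Cla-CZ-245", "Gemmiger formicilis", identity=96.2, ani=79.7,
           pocp=61.2, type_sp=True, dddh=22.0),
        _b("Cla-CZ-245", "Subdoligranulum variabile", identity=94.8,
           ani=81.7, dddh=25.3),
        _b("Cla-CZ-245", "Fournierella massiliensis", identity=94.7,
           dddh=20.2),
        _b("Cla-CZ-245", "Butyricicoccus pullicaecorum", ani=79.7),
    ),
)

OLSENELLA = NovelTaxonCase(
    isolate_id="Cla-CZ-62",
    candidate_name="Olsenella gallinarum sp. nov.",
    expected_rank="novel_species",
    expected_genus="Olsenella",
    gc=68.0,
    bundles=(
        _b("Cla-CZ-62", "Olsenella umbonata", identity=96.6),
        _b("Cla-CZ-62", "Olsenella profusa", identity=96.2),
        _b("Cla-CZ-62", "Olsenella uli", identity=95.8, pocp=54.9,
           type_sp=True),
        _b("Cla-CZ-62", "Olsenella scatoligenes", ani=80.4),
    ),
)

PSEUDOFLAVONIFRACTOR = NovelTaxonCase(
    isolate_id="Cla-CZ-98",
    candidate_name="Pseudoflavonifractor gallinarum sp. nov.",
    expected_rank="novel_species",
    expected_genus="Pseudoflavonifractor",
    gc=59.9,
    bundles=(
        _b("Cla-CZ-98", "Pseudoflavonifractor capillosus", identity=98.2,
           ani=82.2, pocp=56.9, type_sp=True),
        _b("Cla-CZ-98", "Flavonifractor plautii", identity=97.7),
        _b("Cla-CZ-98", "Intestinimonas butyriciproducens", identity=95.3),
    ),
    notes=("phylogenomic placement disagrees between Pseudoflavonifractor "
           "and Flavonifractor; this isolate group may be reclassified",),
)

RUCTIBACTERIUM = NovelTaxonCase(
    isolate_id="Cla-CZ-49",
    candidate_name="Ructibacterium gallinarum gen. nov., sp. nov.",
    expected_rank="novel_genus",
    expected_genus=None,
    gc=43.5,
    bundles=(
        _b("Cla-CZ-49", "Acetivibrio cellulolyticus", identity=89.7),
        _b("Cla-CZ-49", "Acetivibrio thermocellus", identity=89.6),
        _b("Cla-CZ-49", "Acetivibrio straminisolvens", identity=89.4),
    ),
    notes=("POCP stayed below 50% for every close relative; no numeric "
           "value was reported, so the genus call rests on the 16S "
           "threshold",),
)

SELLIMONAS = NovelTaxonCase(
    isolate_id="Cla-CZ-80",
    candidate_name="Sellimonas monacensis sp. nov.",
    expected_rank="novel_species",
    expected_genus="Sellimonas",
    gc=50.3,
    bundles=(
        _b("Cla-CZ-80", "Faecalicatena contorta", identity=94.4, pocp=44.8,
           type_sp=True),
        _b("Cla-CZ-80", "Faecalicatena orotica", identity=93.9),
        _b("Cla-CZ-80", "Coprococcus comes", identity=93.9),
        _b("Cla-CZ-80", "Sellimonas intestinalis", identity=93.7, pocp=52.9,
           type_sp=True),
        _b("Cla-CZ-80", "Dorea formicigenerans", pocp=51.7, type_sp=True),
        _b("Cla-CZ-80", "Dorea longicatena", pocp=56.4),
        _b("Cla-CZ-80", "Clostridium scindens", pocp=54.7),
        _b("Cla-CZ-80", "Clostridium hylemonae", pocp=53.1),
        _b("Cla-CZ-80", "Ruminococcus lactaris", ani=78.3),
    ),
    notes=("highest dDDH (84.6%, G+C difference 0.3) is to a bacterium "
           "without a validly published name and cannot anchor an "
           "assignment; Sellimonas wins the type-species POCP comparison "
           "(52.9% > 51.7% to Dorea)",),
)

SEVEN_CASES: tuple[NovelTaxonCase, ...] = (
    GALLIBACTER, GALLALISTIPES, GEMMIGER, OLSENELLA,
    PSEUDOFLAVONIFRACTOR, RUCTIBACTERIUM, SELLIMONAS,
)


def run_case_studies() -> dict[str, DelineationVerdict]:
    """Classify all seven case studies with default thresholds."""
    return {case.isolate_id: classify(list(case.bundles))
            for case in SEVEN_CASES}
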