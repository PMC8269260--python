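"""Polyphasic taxonomic-novelty decision engine.

Given an isolate's 16S rRNA gene (and, when available, genome and proteome),
the engine ranks candidate relatives from a reference set, assembles the
classical delineation metrics against each relative, and applies the
threshold logic of polyphasic taxonomy:

* 16S identity <= 98.7%  -> evidence for a novel species,
  16S identity <= 94.5%  -> evidence for a novel genus;
* ANI < 95% separates species; values close to 95% (the [93, 97] band) or
  values contradicting the 16S assignment escalate to dDDH (<= 70% separates
  species);
* POCP <= 50% against the *type species* of every candidate genus separates
  at genus level — genus membership is anchored on type species only, since
  high POCP to a non-type species is routinely observed across genus
  boundaries;
* a G+C difference >= 1 percentage point is recorded as supporting evidence
  for species-level separation, never as a decisive signal.

dDDH is consumed, never computed: when the decision branch requires it and
no value was supplied, the verdict is "ambiguous" rather than a guess.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from polytax.seq_core import (
    NucleotideSequence,
    KmerSketch,
    pairwise_identity,
    kmer_sketch,
    sketch_distance,
)
from polytax.genome_metrics import (
    GenomeRecord,
    AniParams,
    PocpParams,
    fragment_ani,
    pocp,
    gc_difference,
)


@dataclass(frozen=True)
class ReferenceEntry:
    """One reference taxon: name, validity, genus anchoring, sequences."""

    taxon_name: str
    is_valid_name: bool
    is_type_species_of_genus: bool
    genus: str
    sixteenS: NucleotideSequence
    genome: Optional[GenomeRecord] = None
    proteome: Optional[tuple] = None


@dataclass(frozen=True)
class RelativeSet:
    isolate_id: str
    ranked: tuple  # of (ReferenceEntry, PairwiseAlignmentResult)

    def __post_init__(self) -> None:
        ids = [r.percent_identity for _, r in self.ranked]
        if any(b > a for a, b in zip(ids, ids[1:])):
            raise ValueError("relatives not sorted by identity descending")


@dataclass
class MetricBundle:
    """All pairwise delineation metrics between an isolate and one relative."""

    isolate_id: str
    relative_name: str
    # None when a metric value is known for this relative but its 16S
    # identity to the isolate is not; ranking treats None as lowest.
    identity16S: Optional[float]
    relative_genus: Optional[str] = None
    ani: Optional[float] = None
    pocp: Optional[float] = None
    pocp_is_to_type_species: bool = False
    dddh: Optional[float] = None
    gc_diff: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("identity16S", "ani", "pocp", "dddh"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.relative_genus is None:
            self.relative_genus = self.relative_name.split()[0]


@dataclass(frozen=True)
class DelineationThresholds:
    species16S: float = 98.7
    genus16S: float = 94.5
    ani_species: float = 95.0
    ani_band: tuple[float, float] = (93.0, 97.0)
    dddh_species: float = 70.0
    gc_diff_support: float = 1.0
    pocp_genus: float = 50.0
    mag_match_distance: float = 0.05

    def __post_init__(self) -> None:
        if self.genus16S >= self.species16S:
            raise ValueError("genus16S must lie below species16S")
        lo, hi = self.ani_band
        if not lo <= self.ani_species <= hi:
            raise ValueError("ani_band must contain ani_species")


@dataclass(frozen=True)
class EvidenceRow:
    criterion: str
    value: float
    threshold: float
    passed: bool  # True = signal in favour of novelty/separation


@dataclass
class DelineationVerdict:
    isolate_id: str
    rank: str  # known_species | novel_species | novel_genus | ambiguous
    assigned_genus: Optional[str]  # None => proposed-new genus
    evidence: list[EvidenceRow]
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class Protologue:
    """A scaffold for the formal description of a proposed novel taxon."""

    candidate_name: str
    verdict: DelineationVerdict
    metric_table: list[dict]
    gc: Optional[float]
    isolation_source: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "Protologue":
        d = json.loads(payload)
        v = d["verdict"]
        verdict = DelineationVerdict(
            isolate_id=v["isolate_id"], rank=v["rank"],
            assigned_genus=v["assigned_genus"],
            evidence=[EvidenceRow(**e) for e in v["evidence"]],
            notes=list(v["notes"]),
        )
        return cls(candidate_name=d["candidate_name"], verdict=verdict,
                   metric_table=d["metric_table"], gc=d["gc"],
                   isolation_source=d["isolation_source"])


def rank_relatives(
    isolate16S: NucleotideSequence,
    refs: Sequence[ReferenceEntry],
    n: int = 50,
) -> RelativeSet:
    """Top-n reference relatives by 16S identity.

    Entries without a validly published name or without a genome are
    excluded before ranking (only genome-backed references can support the
    genomic metrics downstream). Ties break lexicographically by taxon name.
    """
    eligible = [r for r in refs if r.is_valid_name and r.genome is not None]
    if not eligible:
        raise ValueError("no eligible reference (valid name + genome) found")
    scored = [
        (ref, pairwise_identity(isolate16S, ref.sixteenS))
        for ref in eligible
    ]
    scored.sort(key=lambda t: (-t[1].percent_identity, t[0].taxon_name))
    return RelativeSet(isolate_id=isolate16S.id, ranked=tuple(scored[:n]))


def assemble_metrics(
    isolate_id: str,
    isolate16S: NucleotideSequence,
    relative: ReferenceEntry,
    isolate_genome: Optional[GenomeRecord] = None,
    isolate_proteome: Optional[Sequence] = None,
    dddh: Optional[float] = None,
    identity: Optional[float] = None,
    ani_params: AniParams = AniParams(),
    pocp_params: PocpParams = PocpParams(),
) -> MetricBundle:
    """Fill a MetricBundle with whatever evidence the inputs allow.

    16S identity is always computed (or taken from ``identity`` when the
    ranking step already aligned the pair); ANI/POCP/G+C difference require
    the respective genome/proteome on both sides; dDDH is recorded verbatim
    if supplied.
    """
    if identity is None:
        identity = pairwise_identity(isolate16S, relative.sixteenS).percent_identity
    ani = None
    gc_diff = None
    if isolate_genome is not None and relative.genome is not None:
        ani_res = fragment_ani(isolate_genome, relative.genome, ani_params)
        ani = ani_res.ani
        gc_diff = gc_difference(isolate_genome, relative.genome)
    pocp_value = None
    if isolate_proteome and relative.proteome:
        pocp_value = pocp(list(isolate_proteome), list(relative.proteome),
                          pocp_params).pocp
    return MetricBundle(
        isolate_id=isolate_id,
        relative_name=relative.taxon_name,
        relative_genus=relative.genus,
        identity16S=identity,
        ani=ani,
        pocp=pocp_value,
        pocp_is_to_type_species=relative.is_type_species_of_genus,
        dddh=dddh,
        gc_diff=gc_diff,
    )


def _sorted_bundles(bundles: Sequence[MetricBundle]) -> list[MetricBundle]:
    return sorted(
        bundles,
        key=lambda b: (-(b.identity16S if b.identity16S is not None else -1.0),
                       b.relative_name),
    )


def _best_identity(bundles: Sequence[MetricBundle]) -> Optional[float]:
    ids = [b.identity16S for b in bundles if b.identity16S is not None]
    return max(ids) if ids else None


def classify(
    bundles: Sequence[MetricBundle],
    thresholds: DelineationThresholds = DelineationThresholds(),
) -> DelineationVerdict:
    """Apply the polyphasic threshold logic to one isolate's metric bundles.

    Decision order: first the genus question (type-species POCP, falling
    back to the 16S genus threshold when no POCP is available), then the
    species question within the assigned genus (16S species threshold and
    ANI, escalating to dDDH inside the ANI grey band or on a 16S/ANI
    conflict). Genome evidence outranks 16S on conflict.
    """
    if not bundles:
        raise ValueError("classify requires at least one metric bundle")
    bundles = _sorted_bundles(bundles)
    isolate_id = bundles[0].isolate_id
    evidence: list[EvidenceRow] = []
    notes: list[str] = []

    # ---- genus decision -------------------------------------------------
    type_pocp: dict[str, float] = {}
    for b in bundles:
        if b.pocp_is_to_type_species and b.pocp is not None:
            g = b.relative_genus
            if g not in type_pocp or b.pocp > type_pocp[g]:
                type_pocp[g] = b.pocp

    assigned_genus: Optional[str] = None
    if type_pocp:
        for genus in sorted(type_pocp):
            value = type_pocp[genus]
            evidence.append(EvidenceRow(
                criterion=f"pocp_to_type_species[{genus}]",
                value=value, threshold=thresholds.pocp_genus,
                passed=value <= thresholds.pocp_genus,
            ))
        admissible = {g: v for g, v in type_pocp.items()
                      if v > thresholds.pocp_genus}
        if admissible:
            assigned_genus = max(admissible, key=lambda g: (admissible[g], g))
        else:
            notes.append("type-species POCP <= genus threshold for every "
                         "candidate genus")
            return DelineationVerdict(isolate_id, "novel_genus", None,
                                      evidence, notes)
    else:
        best16 = _best_identity(bundles)
        if best16 is None:
            raise ValueError("no POCP and no 16S identity: nothing to decide on")
        evidence.append(EvidenceRow(
            criterion="identity16S_genus", value=best16,
            threshold=thresholds.genus16S,
            passed=best16 <= thresholds.genus16S,
        ))
        if best16 <= thresholds.genus16S:
            notes.append("no POCP available; genus novelty by 16S identity")
            return DelineationVerdict(isolate_id, "novel_genus", None,
                                      evidence, notes)
        assigned_genus = bundles[0].relative_genus
        notes.append("no POCP available; genus assigned by best 16S hit")

    # ---- species decision within the assigned genus ---------------------
    in_genus = [b for b in bundles if b.relative_genus == assigned_genus]
    subset = in_genus if in_genus else list(bundles)
    if not in_genus:
        notes.append("no bundle for assigned genus; species decision on "
                     "best overall relative")
    best = subset[0]
    best_id = _best_identity(subset)
    anis = [b.ani for b in subset if b.ani is not None]
    ani = max(anis) if anis else None
    dddhs = [b.dddh for b in subset if b.dddh is not None]
    dddh = max(dddhs) if dddhs else None

    if best_id is not None:
        evidence.append(EvidenceRow(
            criterion="identity16S_species", value=best_id,
            threshold=thresholds.species16S,
            passed=best_id <= thresholds.species16S,
        ))

    gc_best = best.gc_diff
    if gc_best is not None:
        evidence.append(EvidenceRow(
            criterion="gc_diff_support", value=gc_best,
            threshold=thresholds.gc_diff_support,
            passed=gc_best >= thresholds.gc_diff_support,
        ))

    lo, _hi = thresholds.ani_band

    def _verdict(rank: str) -> DelineationVerdict:
        return DelineationVerdict(isolate_id, rank, assigned_genus,
                                  evidence, notes)

    if best_id is None and ani is None:
        notes.append("neither 16S identity nor ANI available for the "
                     "assigned genus")
        return _verdict("ambiguous")

    if (best_id is not None and best_id > thresholds.species16S
            and (ani is None or ani >= thresholds.ani_species)):
        if ani is not None:
            evidence.append(EvidenceRow(
                criterion="ani_species", value=ani,
                threshold=thresholds.ani_species, passed=False,
            ))
        return _verdict("known_species")

    if ani is None:
        # best_id <= species16S and no genome evidence: 16S decides
        return _verdict("novel_species")

    evidence.append(EvidenceRow(
        criterion="ani_species", value=ani,
        threshold=thresholds.ani_species,
        passed=ani < thresholds.ani_species,
    ))
    if ani < lo:
        return _verdict("novel_species")
    if best_id is None and ani >= thresholds.ani_species:
        return _verdict("known_species")

    # ANI in the grey band, or ANI and 16S point in opposite directions:
    # dDDH arbitrates; without it the case stays open.
    notes.append("ANI in grey band or in conflict with 16S; dDDH consulted")
    if dddh is None:
        notes.append("dDDH required but not supplied")
        return _verdict("ambiguous")
    evidence.append(EvidenceRow(
        criterion="dddh_species", value=dddh,
        threshold=thresholds.dddh_species,
        passed=dddh <= thresholds.dddh_species,
    ))
    return _verdict("novel_species" if dddh <= thresholds.dddh_species
                    else "known_species")


def protologue_scaffold(
    verdict: DelineationVerdict,
    bundles: Sequence[MetricBundle],
    gc: Optional[float] = None,
    source_text: str = "",
    candidate_name: str = "",
) -> Protologue:
    """Structured description scaffold for a verdict proposing a novel taxon."""
    if verdict.rank not in ("novel_species", "novel_genus"):
        raise ValueError(
            f"protologue requires a novel-taxon verdict, got {verdict.rank!r}"
        )
    table = [
        {
            "relative": b.relative_name,
            "identity16S": b.identity16S,
            "ani": b.ani,
            "pocp": b.pocp,
            "pocp_is_to_type_species": b.pocp_is_to_type_species,
            "dddh": b.dddh,
            "gc_diff": b.gc_diff,
        }
        for b in _sorted_bundles(bundles)
    ]
    return Protologue(
        candidate_name=candidate_name or f"{verdict.isolate_id} sp. nov.",
        verdict=verdict,
        metric_table=table,
        gc=gc,
        isolation_source=source_text,
    )


def mag_match(
    genome: GenomeRecord,
    mag_sketches: Sequence[KmerSketch],
    thresholds: DelineationThresholds = DelineationThresholds(),
) -> list[tuple[str, float]]:
    """Metagenome-assembled genomes matching the isolate by sketch distance.

    Returns (mag_id, distance) pairs with distance below the match cutoff,
    sorted by ascending distance (ties by id). The isolate genome is
    sketched at the k and s of the supplied MAG sketches.
    """
    if not mag_sketches:
        return []
    k = mag_sketches[0].k
    if any(sk.k != k for sk in mag_sketches):
        raise ValueError("MAG sketches disagree on k")
    s = max(sk.s for sk in mag_sketches)
    concat = "".join(c.residues for c in genome.contigs)
    own = kmer_sketch(NucleotideSequence(genome.id, concat), k=k, s=s)
    hits = []
    for sk in mag_sketches:
        d = sketch_distance(own, sk)
        if d < thresholds.mag_match_distance:
            hits.append((sk.source_id, d))
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits
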