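"""OTU/ASV relative-abundance tables: member detection, ecology, diversity.

Tables are taxa x samples matrices of relative abundances in percent, as
produced by standard amplicon pipelines after clustering (97% OTUs) or
denoising (ASVs). The module matches table taxa to the reference 16S
sequences of defined community members, summarises prevalence and abundance
per member, and computes Shannon-based effective diversity (the effective
number of species, exp(H)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from polytax.seq_core import NucleotideSequence, pairwise_identity


@dataclass(frozen=True)
class AmpliconParams:
    """Matching and inclusion thresholds for amplicon tables.

    * OTU-level member matching: local-alignment identity >= 97%.
    * ASV-level member matching: identity > 99% AND query coverage >= 80%
      (the identity+coverage pair replaces a database-size-dependent
      E-value cutoff).
    * Taxa below 0.25% relative abundance in every sample are excluded.
    """

    otu_identity: float = 97.0
    asv_identity: float = 99.0
    asv_query_coverage: float = 80.0
    min_rel_abundance: float = 0.25

    def __post_init__(self) -> None:
        if self.asv_identity <= self.otu_identity:
            raise ValueError("asv_identity must exceed otu_identity")


class AbundanceTable:
    """Taxa x samples relative abundances (percent) with sample group labels."""

    def __init__(self, values: pd.DataFrame, groups: dict[str, str],
                 level: str = "OTU"):
        if (values.values < 0).any():
            raise ValueError("negative relative abundance")
        colsums = values.sum(axis=0)
        if (colsums > 100.0 + 1e-6).any():
            bad = colsums[colsums > 100.0 + 1e-6].index.tolist()
            raise ValueError(f"per-sample abundances exceed 100%: {bad}")
        missing = set(values.columns) - set(groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        if level not in ("OTU", "ASV"):
            raise ValueError(f"unknown table level {level!r}")
        self.values = values.astype(float)
        self.groups = {s: groups[s] for s in values.columns}
        self.level = level

    @property
    def taxa_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    @classmethod
    def from_tsv(cls, table_path: str | Path, groups_path: str | Path,
                 level: str = "OTU") -> "AbundanceTable":
        values = pd.read_csv(table_path, sep="\t", index_col=0)
        gdf = pd.read_csv(groups_path, sep="\t", header=None,
                          names=["sample", "group"])
        groups = dict(zip(gdf["sample"].astype(str), gdf["group"].astype(str)))
        return cls(values, groups, level=level)

    def to_tsv(self, table_path: str | Path, groups_path: str | Path) -> None:
        self.values.to_csv(table_path, sep="\t")
        with open(groups_path, "w") as fh:
            for s in self.sample_ids:
                fh.write(f"{s}\t{self.groups[s]}\n")


@dataclass(frozen=True)
class MemberHit:
    member_id: str
    taxon_id: str
    percent_identity: float
    query_coverage: float
    level: str


@dataclass(frozen=True)
class EcologyProfile:
    member_id: str
    prevalence: float                 # percent of samples positive
    mean_abundance_in_positives: Optional[float]
    max_abundance: float
    n_samples: int


@dataclass(frozen=True)
class DiversitySummary:
    sample_id: str
    richness: int
    shannon_H: float       # nats
    shannon_effective: float


@dataclass(frozen=True)
class VennCounts:
    unique: dict[str, int]   # group -> taxa detected only in that group
    shared: int              # taxa detected in two or more groups
    total: int

    def __post_init__(self) -> None:
        if sum(self.unique.values()) + self.shared != self.total:
            raise ValueError("Venn counts do not add up to total")


def filter_low_abundance(table: AbundanceTable,
                         params: AmpliconParams = AmpliconParams()
                         ) -> AbundanceTable:
    """Keep taxa reaching the inclusion threshold in at least one sample.

    The rule is inclusive (max >= threshold) and idempotent.
    """
    keep = table.values.max(axis=1) >= params.min_rel_abundance
    return AbundanceTable(table.values.loc[keep], table.groups, table.level)


def match_members(
    member_refs: Sequence[NucleotideSequence],
    rep_seqs: Sequence[NucleotideSequence],
    level: str = "OTU",
    params: AmpliconParams = AmpliconParams(),
) -> list[MemberHit]:
    """Assign representative sequences to community members.

    OTU level: local-alignment identity >= otu_identity.
    ASV level: identity > asv_identity AND coverage of the representative
    sequence >= asv_query_coverage. Each taxon goes to at most one member
    (best identity; ties break lexicographically by member id).
    """
    if level not in ("OTU", "ASV"):
        raise ValueError(f"unknown level {level!r}")
    hits = []
    for rep in rep_seqs:
        best = None
        for member in sorted(member_refs, key=lambda m: m.id):
            aln = pairwise_identity(rep, member, mode="local",
                                    canonicalize=True)
            if best is None or aln.percent_identity > best[1].percent_identity:
                best = (member.id, aln)
        if best is None:
            continue
        member_id, aln = best
        if level == "OTU":
            ok = aln.percent_identity >= params.otu_identity
        else:
            ok = (aln.percent_identity > params.asv_identity
                  and aln.query_coverage >= params.asv_query_coverage)
        if ok:
            hits.append(MemberHit(
                member_id=member_id, taxon_id=rep.id,
                percent_identity=aln.percent_identity,
                query_coverage=aln.query_coverage, level=level,
            ))
    return hits


def ecology_profile(
    hits: Sequence[MemberHit],
    table: AbundanceTable,
    members: Optional[Sequence[str]] = None,
) -> list[EcologyProfile]:
    """Prevalence and abundance summary per member.

    Taxa matched to the same member are summed per sample (one member may
    split over several OTUs/ASVs). A sample is positive when that sum is
    strictly > 0; the mean abundance is taken over positive samples only and
    is undefined (None) for members never detected.
    """
    unknown = [h.taxon_id for h in hits if h.taxon_id not in table.values.index]
    if unknown:
        raise ValueError(f"hit taxa absent from table: {unknown}")
    member_ids = sorted(members) if members is not None else sorted(
        {h.member_id for h in hits})
    n = len(table.sample_ids)
    profiles = []
    for member in member_ids:
        taxa = [h.taxon_id for h in hits if h.member_id == member]
        if taxa:
            summed = table.values.loc[taxa].sum(axis=0)
        else:
            summed = pd.Series(0.0, index=table.sample_ids)
        positives = summed[summed > 0]
        prevalence = 100.0 * len(positives) / n
        mean_pos = float(positives.mean()) if len(positives) else None
        profiles.append(EcologyProfile(
            member_id=member, prevalence=prevalence,
            mean_abundance_in_positives=mean_pos,
            max_abundance=float(summed.max()), n_samples=n,
        ))
    return profiles


def alpha_diversity(table: AbundanceTable, sample_id: str) -> DiversitySummary:
    """Richness, Shannon entropy (nats) and the effective species count exp(H).

    Abundances are renormalized to proportions over the detected taxa of the
    sample before computing H, so the result does not depend on how much of
    the community the table accounts for.
    """
    if sample_id not in table.values.columns:
        raise KeyError(f"sample {sample_id!r} not in table")
    col = table.values[sample_id]
    detected = col[col > 0]
    if detected.empty:
        raise ValueError(f"sample {sample_id!r} has no detected taxa")
    p = (detected / detected.sum()).to_numpy()
    h = float(-(p * np.log(p)).sum())
    return DiversitySummary(
        sample_id=sample_id, richness=int(len(detected)),
        shannon_H=h, shannon_effective=float(math.exp(h)),
    )


def venn_counts(table: AbundanceTable,
                group_labels: Optional[Sequence[str]] = None) -> VennCounts:
    """Unique and shared detected taxa across sample groups.

    A taxon belongs to a group when detected (>0) in at least one of its
    samples. "Shared" counts taxa detected in two or more groups, so
    uniques + shared equals the total number of distinct detected taxa.
    """
    groups = list(group_labels) if group_labels else sorted(
        set(table.groups.values()))
    if len(groups) < 2:
        raise ValueError("venn_counts needs at least two groups")
    membership: dict[str, set[str]] = {}
    for g in groups:
        samples = table.samples_in_group(g)
        if not samples:
            raise ValueError(f"group {g!r} has no samples")
        present = table.values[samples].max(axis=1) > 0
        membership[g] = set(table.values.index[present])
    all_detected = set().union(*membership.values())
    unique = {
        g: len(membership[g]
               - set().union(*(membership[o] for o in groups if o != g)))
        for g in groups
    }
    shared = len(all_detected) - sum(unique.values())
    return VennCounts(unique=unique, shared=shared, total=len(all_detected))


def group_rank_test(table: AbundanceTable, taxon_id: str,
                    group_a: str, group_b: str):
    """Wilcoxon rank-sum comparison of one taxon's abundances between groups."""
    a = table.values.loc[taxon_id, table.samples_in_group(group_a)]
    b = table.values.loc[taxon_id, table.samples_in_group(group_b)]
    return stats.mannwhitneyu(a, b, alternative="two-sided")


def group_presence_test(table: AbundanceTable, taxon_id: str,
                        group_a: str, group_b: str):
    """Fisher exact test on presence/absence of one taxon between groups."""
    a = table.values.loc[taxon_id, table.samples_in_group(group_a)] > 0
    b = table.values.loc[taxon_id, table.samples_in_group(group_b)] > 0
    contingency = [[int(a.sum()), int((~a).sum())],
                   [int(b.sum()), int((~b).sum())]]
    return stats.fisher_exact(contingency)
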