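"""Seeded generators for every fixture class the pipeline consumes.

All generators are deterministic per (parameters, seed) and return a
``SyntheticTruth`` sidecar recording the design parameters and the derived
expectations (expected ANI, expected POCP, designed prevalence, ...) so
recovery tests can be written without re-running the generator.

The mutation model is substitution-only (no indels): that keeps identity
and ANI ground truths exact. Community abundance follows a log-normal
model, mimicking the long-tailed taxon-abundance profiles of real gut
amplicon data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from polytax.seq_core import NucleotideSequence, ProteinSequence, write_fasta
from polytax.genome_metrics import GenomeRecord
from polytax.amplicon import AbundanceTable
from polytax.delineation import ReferenceEntry

_BASES = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SyntheticTruth:
    """Ground truth of a generated fixture."""

    generator: str
    seed: int
    parameters: dict
    expectations: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


@dataclass(frozen=True)
class SpikeSpec:
    """Design of one community member spiked into a generated table.

    presence: per-group Bernoulli probability that a sample carries the
    member; abundance (when present) is log-normal with the given log-scale
    parameters; rep_identity is the designed 16S identity (percent) of the
    representative sequence to the member reference.
    """

    member_id: str
    presence: dict[str, float]
    abundance_mu: float = 0.0     # ln(percent) scale
    abundance_sigma: float = 1.0
    rep_identity: float = 100.0

    def __post_init__(self) -> None:
        for g, p in self.presence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"presence probability {p} for {g!r}")
        if not 0.0 < self.rep_identity <= 100.0:
            raise ValueError("rep_identity must be in (0, 100]")


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def gen_genome(length: int, gc_target: float, seed: int,
               genome_id: str = "synthetic_genome",
               n_contigs: int = 1) -> GenomeRecord:
    """An i.i.d. random genome at the target G+C composition."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must lie strictly between 0 and 1")
    if n_contigs < 1 or n_contigs > length // 1000:
        raise ValueError("invalid contig count")
    rng = np.random.default_rng(seed)
    bounds = np.linspace(0, length, n_contigs + 1).astype(int)
    contigs = [
        NucleotideSequence(
            f"{genome_id}.c{i+1}",
            _random_dna(rng, int(hi - lo), gc_target),
        )
        for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]))
    ]
    return GenomeRecord(id=genome_id, contigs=tuple(contigs))


def mutate(seq: NucleotideSequence, substitution_rate: float,
           seed: int) -> tuple[NucleotideSequence, SyntheticTruth]:
    """Substitute each site to a different letter with the given probability.

    No indels; N sites are left untouched. The truth records the realized
    substitution count (equal to the Hamming distance to the input).
    """
    if not 0.0 <= substitution_rate < 1.0:
        raise ValueError("substitution rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    arr = np.array(list(seq.residues))
    mutable = np.isin(arr, _BASES)
    hit = mutable & (rng.random(arr.size) < substitution_rate)
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    mutated = NucleotideSequence(f"{seq.id}_mut", "".join(arr),
                                 seq.description)
    truth = SyntheticTruth(
        generator="mutate", seed=seed,
        parameters={"substitution_rate": substitution_rate,
                    "length": len(seq), "source_id": seq.id},
        expectations={"realized_count": int(idx.size),
                      "realized_fraction": float(idx.size / arr.size)},
    )
    return mutated, truth


def mutate_genome(genome: GenomeRecord, substitution_rate: float,
                  seed: int) -> tuple[GenomeRecord, SyntheticTruth]:
    """Apply ``mutate`` contig-wise; one truth for the whole genome."""
    rng = np.random.default_rng(seed)
    contigs = []
    total = 0
    for contig in genome.contigs:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        mut, t = mutate(contig, substitution_rate, sub_seed)
        contigs.append(NucleotideSequence(contig.id, mut.residues))
        total += t.expectations["realized_count"]
    mutated = GenomeRecord(id=f"{genome.id}_mut", contigs=tuple(contigs))
    truth = SyntheticTruth(
        generator="mutate_genome", seed=seed,
        parameters={"substitution_rate": substitution_rate,
                    "length": genome.total_length, "source_id": genome.id},
        expectations={
            "realized_count": total,
            "realized_fraction": total / genome.total_length,
            "expected_ani": 100.0 * (1.0 - substitution_rate),
        },
    )
    return mutated, truth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def gen_proteome_pair(
    n_shared: int, n_unique_each: int, protein_len: int = 150, seed: int = 0,
) -> tuple[list[ProteinSequence], list[ProteinSequence], SyntheticTruth]:
    """Two proteomes sharing ``n_shared`` identical proteins.

    Unique proteins are independent random sequences (unrelated under any
    homology test), so the designed POCP is exact:
    100 * 2*n_shared / (2*(n_shared + n_unique_each)).
    """
    if n_shared < 0 or n_unique_each < 0 or n_shared + n_unique_each == 0:
        raise ValueError("need at least one protein per proteome")
    rng = np.random.default_rng(seed)
    shared = [ProteinSequence(f"shared_{i}", _random_protein(rng, protein_len))
              for i in range(n_shared)]
    uniq_a = [ProteinSequence(f"uniqA_{i}", _random_protein(rng, protein_len))
              for i in range(n_unique_each)]
    uniq_b = [ProteinSequence(f"uniqB_{i}", _random_protein(rng, protein_len))
              for i in range(n_unique_each)]
    total = n_shared + n_unique_each
    truth = SyntheticTruth(
        generator="gen_proteome_pair", seed=seed,
        parameters={"n_shared": n_shared, "n_unique_each": n_unique_each,
                    "protein_len": protein_len},
        expectations={"expected_pocp": 100.0 * 2 * n_shared / (2 * total)},
    )
    return shared + uniq_a, shared + uniq_b, truth


@dataclass
class CommunityFixture:
    table: AbundanceTable
    rep_seqs: list[NucleotideSequence]
    member_refs: list[NucleotideSequence]
    truth: SyntheticTruth


def gen_member_table(
    n_samples_per_group: dict[str, int],
    spikes: Sequence[SpikeSpec],
    n_background_taxa: int = 40,
    seed: int = 0,
    ref_len: int = 420,
    background_sigma: float = 1.5,
) -> CommunityFixture:
    """A community abundance table with designed member spikes.

    Background taxa get log-normal mean abundances with per-sample
    log-normal noise; each spike is present per its Bernoulli probability
    and log-normal abundance. Representative sequences for spiked taxa are
    generated at the designed identity to the member reference (reference
    length ~ an amplicon, default 420 bp); per-sample columns are
    renormalized to sum to 100%.
    """
    if not n_samples_per_group:
        raise ValueError("need at least one sample group")
    rng = np.random.default_rng(seed)
    member_refs = []
    rep_seqs = []
    spike_rows = []
    realized_presence: dict[str, dict[str, float]] = {}

    samples = []
    groups: dict[str, str] = {}
    for g, n in n_samples_per_group.items():
        for i in range(n):
            sid = f"{g}_{i+1:03d}"
            samples.append(sid)
            groups[sid] = g

    # background community
    base = rng.lognormal(mean=0.0, sigma=background_sigma,
                         size=n_background_taxa)
    bg = np.empty((n_background_taxa, len(samples)))
    for j in range(len(samples)):
        noise = rng.lognormal(mean=0.0, sigma=0.5, size=n_background_taxa)
        bg[:, j] = base * noise
    bg_ids = [f"bgOTU_{i+1:03d}" for i in range(n_background_taxa)]

    # spiked members
    for spike in spikes:
        ref = NucleotideSequence(spike.member_id, _random_dna(rng, ref_len, 0.5))
        member_refs.append(ref)
        rate = 1.0 - spike.rep_identity / 100.0
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if rate > 0:
            rep, _t = mutate(ref, rate, rep_seed)
            rep_res = rep.residues
        else:
            rep_res = ref.residues
        taxon_id = f"spiked_{spike.member_id}"
        rep_seqs.append(NucleotideSequence(taxon_id, rep_res))
        row = np.zeros(len(samples))
        pres: dict[str, int] = {}
        tot: dict[str, int] = {}
        for j, sid in enumerate(samples):
            g = groups[sid]
            tot[g] = tot.get(g, 0) + 1
            if rng.random() < spike.presence.get(g, 0.0):
                row[j] = rng.lognormal(spike.abundance_mu,
                                       spike.abundance_sigma)
                pres[g] = pres.get(g, 0) + 1
        spike_rows.append(row)
        realized_presence[spike.member_id] = {
            g: 100.0 * pres.get(g, 0) / tot[g] for g in tot}

    values = np.vstack([bg] + spike_rows) if spike_rows else bg
    taxa = bg_ids + [f"spiked_{s.member_id}" for s in spikes]
    # renormalize every sample to 100%
    values = 100.0 * values / values.sum(axis=0, keepdims=True)
    df = pd.DataFrame(values, index=taxa, columns=samples)
    table = AbundanceTable(df, groups, level="OTU")
    truth = SyntheticTruth(
        generator="gen_member_table", seed=seed,
        parameters={
            "n_samples_per_group": dict(n_samples_per_group),
            "n_background_taxa": n_background_taxa,
            "spikes": [asdict(s) for s in spikes],
        },
        expectations={
            "designed_presence": {s.member_id: dict(s.presence)
                                  for s in spikes},
            "realized_prevalence": realized_presence,
            "designed_rep_identity": {s.member_id: s.rep_identity
                                      for s in spikes},
        },
    )
    return CommunityFixture(table=table, rep_seqs=rep_seqs,
                            member_refs=member_refs, truth=truth)


@dataclass(frozen=True)
class DivergencePlan:
    """Designed divergences for a synthetic reference hierarchy.

    All 16S genes descend from one ancestral sequence (real 16S genes are
    homologous across bacteria), with genus roots at ``between_genus_16s``
    from the ancestor and congeners at multiples of ``within_genus_16s``
    from their root. Genomes are independent random sequences per genus
    (ANI is genuinely undefined between genera) and mutated copies within.
    """

    within_genus_16s: float = 0.02     # substitution rate between congeners
    between_genus_16s: float = 0.10    # genus root vs common ancestor
    sixteens_len: int = 1500
    genome_len: int = 30000
    genome_rate_per_16s: float = 2.0   # genome diverges faster than 16S


def gen_reference_db(
    n_genera: int,
    species_per_genus: int,
    plan: DivergencePlan = DivergencePlan(),
    seed: int = 0,
) -> tuple[list[ReferenceEntry], SyntheticTruth]:
    """A synthetic reference hierarchy of genera and species.

    Each genus has an independent random 16S/genome ancestor; species within
    a genus are substitution-mutated copies at the planned divergence, with
    the first species flagged as the genus type species. Proteomes are not
    generated: genus novelty in tests on this database is exercised through
    the 16S fallback branch of the classifier.
    """
    if n_genera < 1 or species_per_genus < 1:
        raise ValueError("need at least one genus and one species")
    rng = np.random.default_rng(seed)
    refs: list[ReferenceEntry] = []
    layout: dict[str, list[str]] = {}
    ancestor16 = NucleotideSequence(
        "ancestor_16S", _random_dna(rng, plan.sixteens_len, 0.5))
    for gi in range(n_genera):
        genus = f"Genus{gi+1:02d}"
        root16, _ = mutate(ancestor16, plan.between_genus_16s,
                           int(rng.integers(0, 2**31 - 1)))
        root16 = NucleotideSequence(f"{genus}_16S_root", root16.residues)
        root_genome = gen_genome(
            plan.genome_len, 0.5, int(rng.integers(0, 2**31 - 1)),
            genome_id=f"{genus}_genome_root")
        layout[genus] = []
        for si in range(species_per_genus):
            name = f"{genus} species{si+1:02d}"
            rate16 = plan.within_genus_16s * si
            if rate16 > 0:
                s16, _ = mutate(root16, rate16, int(rng.integers(0, 2**31 - 1)))
                genome, _ = mutate_genome(
                    root_genome, min(0.45, rate16 * plan.genome_rate_per_16s),
                    int(rng.integers(0, 2**31 - 1)))
            else:
                s16, genome = root16, root_genome
            s16 = NucleotideSequence(name.replace(" ", "_") + "_16S",
                                     s16.residues)
            genome = GenomeRecord(
                id=name.replace(" ", "_") + "_genome",
                contigs=tuple(NucleotideSequence(
                    f"{name.replace(' ', '_')}.c{i+1}", c.residues)
                    for i, c in enumerate(genome.contigs)),
            )
            refs.append(ReferenceEntry(
                taxon_name=name, is_valid_name=True,
                is_type_species_of_genus=(si == 0), genus=genus,
                sixteenS=s16, genome=genome,
            ))
            layout[genus].append(name)
    truth = SyntheticTruth(
        generator="gen_reference_db", seed=seed,
        parameters={"n_genera": n_genera,
                    "species_per_genus": species_per_genus,
                    "plan": asdict(plan)},
        expectations={"layout": layout},
    )
    return refs, truth


def write_reference_db(refs: Sequence[ReferenceEntry],
                       out_dir: str | Path) -> Path:
    """Write a reference set as a directory: FASTAs plus a TSV index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for ref in refs:
        stem = ref.taxon_name.replace(" ", "_")
        p16 = out / f"{stem}_16S.fasta"
        write_fasta([ref.sixteenS], p16)
        pg = ""
        if ref.genome is not None:
            pg_path = out / f"{stem}_genome.fasta"
            write_fasta(ref.genome.contigs, pg_path)
            pg = pg_path.name
        index_rows.append((ref.taxon_name, int(ref.is_valid_name),
                           int(ref.is_type_species_of_genus), ref.genus,
                           p16.name, pg))
    index = out / "index.tsv"
    with open(index, "w") as fh:
        fh.write("taxon_name\tis_valid_name\tis_type_species\tgenus\t"
                 "sixteens_fasta\tgenome_fasta\n")
        for row in index_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return index


def load_reference_db(index_path: str | Path) -> list[ReferenceEntry]:
    """Load a reference directory written by ``write_reference_db``."""
    from polytax.seq_core import read_fasta

    index_path = Path(index_path)
    base = index_path.parent
    df = pd.read_csv(index_path, sep="\t")
    refs = []
    for _, row in df.iterrows():
        s16 = read_fasta(base / row.sixteens_fasta)[0]
        genome = None
        if isinstance(row.genome_fasta, str) and row.genome_fasta:
            contigs = read_fasta(base / row.genome_fasta)
            genome = GenomeRecord(
                id=Path(row.genome_fasta).stem, contigs=tuple(contigs))
        refs.append(ReferenceEntry(
            taxon_name=row.taxon_name,
            is_valid_name=bool(row.is_valid_name),
            is_type_species_of_genus=bool(row.is_type_species),
            genus=row.genus, sixteenS=s16, genome=genome,
        ))
    return refs
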