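"""Genome-scale comparison metrics: fragment ANI, POCP, G+C difference, ORFs.

ANI follows the classical fragment-based recipe: the query genome is chopped
into non-overlapping 1020-bp fragments, each fragment is placed on the
subject by exact 15-mer seeding and scored with a local alignment, and the
ANI is the mean identity of fragments aligning at >=30% identity over >=70%
of their length. POCP counts, in both directions, proteins with a qualifying
best hit (BLOSUM62 local alignment, identity >=40%, alignable region >=50%
of the query protein) and reports 100*(C1+C2)/(T1+T2).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from polytax.seq_core import (
    NucleotideSequence,
    ProteinSequence,
    _make_aligner,
    _identity_from_alignment,
    gc_content,
    kmer_integers,
)


@dataclass(frozen=True)
class GenomeRecord:
    """A (draft) genome: an id plus its contigs."""

    id: str
    contigs: tuple[NucleotideSequence, ...]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"genome {self.id!r} has no contigs")
        object.__setattr__(self, "contigs", tuple(self.contigs))

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def gc(self) -> float:
        gc_count = 0
        acgt = 0
        for c in self.contigs:
            s = c.residues
            g = s.count("G") + s.count("C")
            gc_count += g
            acgt += g + s.count("A") + s.count("T")
        if acgt == 0:
            raise ValueError(f"G+C undefined for genome {self.id!r}")
        return 100.0 * gc_count / acgt


@dataclass(frozen=True)
class AniResult:
    query_id: str
    subject_id: str
    ani: Optional[float]  # None when no fragment qualified (no evidence)
    fragments_used: int
    fragments_total: int

    def __post_init__(self) -> None:
        if self.fragments_used > self.fragments_total:
            raise ValueError("fragments_used exceeds fragments_total")
        if self.fragments_used == 0 and self.ani is not None:
            raise ValueError("ani must be undefined with no used fragments")
        if self.ani is not None and not 0.0 <= self.ani <= 100.0:
            raise ValueError("ani outside [0, 100]")


@dataclass(frozen=True)
class PocpResult:
    query_id: str
    subject_id: str
    c1: int
    c2: int
    t1: int
    t2: int

    def __post_init__(self) -> None:
        if self.c1 > self.t1 or self.c2 > self.t2:
            raise ValueError("conserved counts exceed totals")

    @property
    def pocp(self) -> float:
        return 100.0 * (self.c1 + self.c2) / (self.t1 + self.t2)


@dataclass(frozen=True)
class AniParams:
    """Fragment-ANI parameters (classical defaults)."""

    fragment_len: int = 1020
    seed_k: int = 15
    min_identity: float = 30.0   # percent, per fragment
    min_coverage: float = 70.0   # percent of fragment length
    window_margin: int = 150     # subject bp added around the seeded placement


@dataclass(frozen=True)
class PocpParams:
    """Conserved-protein test parameters.

    The expectation-value cutoff of the textbook definition depends on
    database size and is replaced by a raw BLOSUM62 local-alignment score
    floor; unrelated random protein pairs of a few hundred residues stay
    well below 50.
    """

    min_identity: float = 40.0
    min_coverage: float = 50.0   # percent of the query protein length
    min_score: float = 50.0


def _genome_fragments(genome: GenomeRecord, fragment_len: int) -> list[str]:
    """Non-overlapping fragments per contig; trailing partials dropped."""
    frags = []
    for contig in genome.contigs:
        s = contig.residues
        for start in range(0, len(s) - fragment_len + 1, fragment_len):
            frags.append(s[start:start + fragment_len])
    return frags


_RC = str.maketrans("ACGTN", "TGCAN")


def _seed_index(subject: str, k: int) -> dict:
    index: dict[int, list[int]] = defaultdict(list)
    ints = kmer_integers(subject, k)
    # kmer_integers drops N windows; recover positions by re-walking valid mask
    codes_ok = np.frombuffer(subject.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(codes_ok, k)
    # positions of N-free windows, aligned with ints
    is_acgt = np.isin(codes_ok, np.frombuffer(b"ACGT", dtype=np.uint8))
    valid = np.lib.stride_tricks.sliding_window_view(is_acgt, k).all(axis=1)
    positions = np.nonzero(valid)[0]
    for pos, kint in zip(positions, ints):
        index[int(kint)].append(int(pos))
    return index


def _best_diagonal(frag: str, index: dict, k: int) -> Optional[int]:
    """Most-voted subject offset for the fragment, or None without seeds."""
    ints = kmer_integers(frag, k)
    if ints.size == 0:
        return None
    is_acgt = np.isin(np.frombuffer(frag.encode(), dtype=np.uint8),
                      np.frombuffer(b"ACGT", dtype=np.uint8))
    valid = np.lib.stride_tricks.sliding_window_view(is_acgt, k).all(axis=1)
    offsets = np.nonzero(valid)[0]
    votes: dict[int, int] = defaultdict(int)
    for off, kint in zip(offsets, ints):
        for pos in index.get(int(kint), ()):
            votes[pos - int(off)] += 1
    if not votes:
        return None
    # deterministic: most votes, then smallest diagonal
    return min(votes, key=lambda d: (-votes[d], d))


def fragment_ani(
    query: GenomeRecord,
    subject: GenomeRecord,
    params: AniParams = AniParams(),
) -> AniResult:
    """Fragment-based average nucleotide identity of ``query`` against ``subject``.

    Direction matters: fragments come from the query. With no qualifying
    fragment the result carries ``ani=None`` ("no evidence"), which is
    deliberately distinct from an ANI of 0.
    """
    fragments = _genome_fragments(query, params.fragment_len)
    subject_seq = ("N" * params.seed_k).join(c.residues for c in subject.contigs)
    index = _seed_index(subject_seq, params.seed_k)
    aligner = _make_aligner("local")
    identities = []
    for frag in fragments:
        best = None
        for oriented in (frag, frag.translate(_RC)[::-1]):
            diag = _best_diagonal(oriented, index, params.seed_k)
            if diag is None:
                continue
            lo = max(0, diag - params.window_margin)
            hi = min(len(subject_seq),
                     diag + len(oriented) + params.window_margin)
            window = subject_seq[lo:hi]
            aln = aligner.align(oriented, window)[0]
            matched, aligned, coverage = _identity_from_alignment(
                aln, len(oriented))
            if aligned == 0:
                continue
            pid = 100.0 * matched / aligned
            if best is None or matched > best[1]:
                best = (pid, matched, coverage)
        if best is None:
            continue
        pid, _, coverage = best
        if pid >= params.min_identity and coverage >= params.min_coverage:
            identities.append(pid)
    used = len(identities)
    ani = float(np.mean(identities)) if used else None
    return AniResult(query_id=query.id, subject_id=subject.id, ani=ani,
                     fragments_used=used, fragments_total=len(fragments))


_blosum_aligner = None


def _protein_aligner() -> PairwiseAligner:
    global _blosum_aligner
    if _blosum_aligner is None:
        aligner = PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        aligner.mode = "local"
        _blosum_aligner = aligner
    return _blosum_aligner


def _sanitize(residues: str) -> str:
    # BLOSUM62 matrix has no column for X; map the unknown residue to the
    # wildcard '*'-free closest behaviour by replacing with 'A'-scored gapless
    # placeholder. Replacing X with a rare residue would bias scores, so X is
    # dropped at both ends of the comparison instead.
    return residues.replace("X", "")


def _is_conserved(query: ProteinSequence, targets: Sequence[ProteinSequence],
                  params: PocpParams) -> bool:
    aligner = _protein_aligner()
    q = _sanitize(query.residues)
    if not q:
        return False
    scored = []
    for t in targets:
        tres = _sanitize(t.residues)
        if not tres:
            continue
        scored.append((aligner.score(q, tres), tres))
    scored.sort(key=lambda x: -x[0])
    for score, tres in scored:
        if score < params.min_score:
            break
        aln = aligner.align(q, tres)[0]
        matched, aligned, _cov = _identity_from_alignment(aln, len(q))
        if aligned == 0:
            continue
        pid = 100.0 * matched / aligned
        # alignable region relative to the query protein
        qblocks = aln.aligned[0]
        qspan = int(qblocks[-1][1] - qblocks[0][0]) if len(qblocks) else 0
        coverage = 100.0 * qspan / len(q)
        if pid >= params.min_identity and coverage >= params.min_coverage:
            return True
    return False


def pocp(
    proteome_a: Sequence[ProteinSequence],
    proteome_b: Sequence[ProteinSequence],
    params: PocpParams = PocpParams(),
    query_id: str = "A",
    subject_id: str = "B",
) -> PocpResult:
    """Percentage of conserved proteins between two proteomes (symmetric)."""
    if not proteome_a or not proteome_b:
        raise ValueError("POCP requires two non-empty proteomes")
    c1 = sum(_is_conserved(p, proteome_b, params) for p in proteome_a)
    c2 = sum(_is_conserved(p, proteome_a, params) for p in proteome_b)
    return PocpResult(query_id=query_id, subject_id=subject_id,
                      c1=c1, c2=c2, t1=len(proteome_a), t2=len(proteome_b))


def gc_difference(a: GenomeRecord, b: GenomeRecord) -> float:
    """Absolute difference in genomic G+C content, in percentage points."""
    return abs(a.gc - b.gc)


_STOP_TABLE = 11  # bacterial / archaeal code


def orf_translate(genome: GenomeRecord, min_aa: int = 100) -> list[ProteinSequence]:
    """Stop-to-stop open reading frames on all six frames, translated.

    A crude proteome surrogate for genomes without gene predictions: every
    run between stop codons of at least ``min_aa`` residues, bacterial code,
    in a deterministic order (contig, strand, frame, position).
    """
    proteins = []
    for contig in genome.contigs:
        for strand, seq in (("+", contig.residues),
                            ("-", str(Seq(contig.residues).reverse_complement()))):
            for frame in range(3):
                sub = seq[frame:]
                sub = sub[: len(sub) - len(sub) % 3]
                if not sub:
                    continue
                translated = str(Seq(sub).translate(table=_STOP_TABLE))
                start = 0
                for segment in translated.split("*"):
                    if len(segment) >= min_aa:
                        proteins.append(ProteinSequence(
                            id=f"{contig.id}|{strand}{frame}|{start}",
                            residues=segment,
                            description=f"orf len={len(segment)}aa",
                        ))
                    start += len(segment) + 1
    return proteins
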