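"""Sequence records, FASTA I/O, pairwise identity, G+C and MinHash sketches.

Everything downstream (ANI, POCP, amplicon matching, sketch-based genome
matching) is built on the primitives in this module. Identities are reported
the way 16S databases report them: matches over aligned columns of an
end-gap-free global alignment, terminal gap runs excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.Align import PairwiseAligner

NUCLEOTIDE_LETTERS = frozenset("ACGTN")
PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

AlignmentMode = Literal["global-endfree", "local"]


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA sequence over the alphabet {A, C, G, T, N}.

    Ambiguity codes other than N are rejected at construction so that every
    reported identity is reproducible (no scored wildcards).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - NUCLEOTIDE_LETTERS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-{{A,C,G,T,N}} letters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(
            self.id, self.residues.translate(_COMPLEMENT)[::-1], self.description
        )


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence (standard 20 letters plus X; * allowed as stop)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.id!r} is empty")
        bad = set(self.residues) - PROTEIN_LETTERS
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains unexpected letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairwiseAlignmentResult:
    query_id: str
    subject_id: str
    percent_identity: float
    matched_columns: int
    aligned_columns: int
    query_coverage: float
    method_tag: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")
        if self.query_coverage > 100.0 + 1e-9:
            raise ValueError("query_coverage above 100")


def read_fasta(path: str | Path, alphabet: str = "nucleotide"):
    """Read a FASTA file into sequence records.

    Residues are uppercased; record order is preserved. Raises on an empty
    file and on duplicated record ids (naming the offending id).
    """
    path = Path(path)
    cls = NucleotideSequence if alphabet == "nucleotide" else ProteinSequence
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(cls(rec.id, str(rec.seq).upper(), desc))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[NucleotideSequence | ProteinSequence],
                path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def gc_content(seq: NucleotideSequence) -> float:
    """G+C content in percent, with N excluded from both counts.

    Undefined (raises) for an all-N sequence.
    """
    s = seq.residues
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        raise ValueError(f"G+C undefined for all-N sequence {seq.id!r}")
    return 100.0 * gc / acgt


def _make_aligner(mode: AlignmentMode) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    if mode == "global-endfree":
        aligner.mode = "global"
        # terminal gaps free: end-gap-free global alignment
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    elif mode == "local":
        aligner.mode = "local"
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    return aligner


def _identity_from_alignment(alignment, query_len: int):
    """Matches / aligned columns excluding terminal gap runs, plus coverage."""
    counts = alignment.counts()
    matched = counts.identities
    aligned = (counts.identities + counts.mismatches
               + counts.internal_insertions + counts.internal_deletions)
    # query span actually aligned (for coverage)
    qblocks = alignment.aligned[1] if hasattr(alignment, "aligned") else None
    if qblocks is not None and len(qblocks):
        qspan = int(qblocks[-1][1] - qblocks[0][0])
    else:  # pragma: no cover - degenerate all-gap alignment
        qspan = 0
    coverage = 100.0 * qspan / query_len
    return matched, aligned, coverage


def pairwise_identity(
    a: NucleotideSequence,
    b: NucleotideSequence,
    mode: AlignmentMode = "global-endfree",
    canonicalize: bool = False,
) -> PairwiseAlignmentResult:
    """Percent identity between two DNA sequences.

    Scoring is match +1 / mismatch -1 / gap open -2 / gap extend -1; identity
    is matches over aligned columns with terminal gap runs excluded. With
    ``canonicalize=True`` the reverse complement of ``a`` is also tried and
    the higher-scoring orientation is reported (strand-insensitive identity).
    """
    for seq in (a, b):
        bad = set(seq.residues) - NUCLEOTIDE_LETTERS
        if bad:
            raise ValueError(f"non-IUPAC letters in {seq.id!r}: {sorted(bad)}")
    aligner = _make_aligner(mode)
    candidates = [a.residues]
    if canonicalize:
        candidates.append(a.reverse_complement().residues)
    best = None
    for qres in candidates:
        alignments = aligner.align(qres, b.residues)
        aln = alignments[0]
        if best is None or aln.score > best.score:
            best = aln
    matched, aligned, coverage = _identity_from_alignment(best, len(a))
    pid = 100.0 * matched / aligned if aligned else 0.0
    return PairwiseAlignmentResult(
        query_id=a.id,
        subject_id=b.id,
        percent_identity=pid,
        matched_columns=matched,
        aligned_columns=aligned,
        query_coverage=min(coverage, 100.0),
        method_tag="global-endfree" if mode == "global-endfree" else "local",
    )


# ---------------------------------------------------------------------------
# MinHash sketches
#
# Canonical k-mers (lexicographic minimum of a k-mer and its reverse
# complement, on the 2-bit encoding A=0, C=1, G=2, T=3) are hashed with
# splitmix64 — a fixed, unseeded 64-bit finalizer — so sketches are
# bit-stable across runs and platforms. The sketch keeps the s smallest
# distinct hash values.
# ---------------------------------------------------------------------------

_SPLITMIX_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SPLITMIX_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SPLITMIX_M2 = np.uint64(0x94D049BB133111EB)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer over uint64 values."""
    z = x + _SPLITMIX_GAMMA
    z = (z ^ (z >> np.uint64(30))) * _SPLITMIX_M1
    z = (z ^ (z >> np.uint64(27))) * _SPLITMIX_M2
    return z ^ (z >> np.uint64(31))


def _kmer_codes(residues: str) -> np.ndarray:
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]  # 255 marks N / invalid


def kmer_integers(residues: str, k: int) -> np.ndarray:
    """2-bit packed integers of all valid (N-free) forward k-mers, in order.

    Windows overlapping an N are dropped. k is limited to 31 so the packed
    k-mer fits a 64-bit word.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    codes = _kmer_codes(residues)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~(win == 255).any(axis=1)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    ints = (win.astype(np.uint64) * powers).sum(axis=1)
    return ints[valid]


def canonical_kmer_integers(residues: str, k: int) -> np.ndarray:
    """Strand-canonical (min of forward / reverse complement) packed k-mers.

    The reverse complement of a window codes[i:i+k] packs as
    sum_j (3 - codes[i+j]) * 4**j, i.e. complemented letters with ascending
    powers, so both orientations come from the same window view.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    codes = _kmer_codes(residues)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~(win == 255).any(axis=1)
    win64 = win.astype(np.uint64)
    powers_fwd = np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    powers_rev = np.uint64(4) ** np.arange(k, dtype=np.uint64)
    fwd = (win64 * powers_fwd).sum(axis=1)
    rc = ((np.uint64(3) - (win64 & np.uint64(3))) * powers_rev).sum(axis=1)
    return np.minimum(fwd, rc)[valid]


@dataclass(frozen=True)
class KmerSketch:
    """Bottom-s MinHash sketch over canonical k-mers."""

    k: int
    s: int
    hashes: tuple[int, ...]
    source_id: str

    def __post_init__(self) -> None:
        if len(self.hashes) > self.s:
            raise ValueError("sketch holds more than s hashes")
        if any(b <= a for a, b in zip(self.hashes, self.hashes[1:])):
            raise ValueError("sketch hashes must be strictly increasing")

    def to_json(self) -> str:
        return json.dumps(
            {"k": self.k, "s": self.s, "hashes": list(self.hashes),
             "source_id": self.source_id}
        )

    @classmethod
    def from_json(cls, payload: str) -> "KmerSketch":
        d = json.loads(payload)
        return cls(d["k"], d["s"], tuple(d["hashes"]), d["source_id"])


def kmer_sketch(seq: NucleotideSequence, k: int = 21, s: int = 1000) -> KmerSketch:
    """Sketch a sequence: the s smallest splitmix64 hashes of canonical k-mers."""
    if len(seq) < k:
        raise ValueError(
            f"sequence {seq.id!r} shorter than k={k}; cannot sketch"
        )
    canon = canonical_kmer_integers(seq.residues, k)
    if canon.size == 0:
        raise ValueError(f"sequence {seq.id!r} has no N-free k-mers")
    hashes = np.unique(splitmix64(canon))  # unique + sorted
    bottom = hashes[:s]
    return KmerSketch(k=k, s=s, hashes=tuple(int(h) for h in bottom),
                      source_id=seq.id)


def sketch_jaccard(a: KmerSketch, b: KmerSketch) -> float:
    """Jaccard estimate from the merged bottom-s of two sketches."""
    if a.k != b.k:
        raise ValueError(f"sketch k mismatch: {a.k} != {b.k}")
    s = min(a.s, b.s)
    ha, hb = set(a.hashes), set(b.hashes)
    merged = sorted(ha | hb)[:s]
    if not merged:
        return 0.0
    shared = sum(1 for h in merged if h in ha and h in hb)
    return shared / len(merged)


def sketch_distance(a: KmerSketch, b: KmerSketch) -> float:
    """Mash-style distance d = -(1/k) ln(2J / (1+J)), capped at 1.

    d estimates per-site substitution divergence between the two source
    sequences under a Poisson model of k-mer survival.
    """
    j = sketch_jaccard(a, b)
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    d = -(1.0 / a.k) * np.log(2.0 * j / (1.0 + j))
    return float(min(d, 1.0))
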