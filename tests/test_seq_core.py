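"""Sequence primitives: FASTA I/O, G+C, pairwise identity, MinHash sketches."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polytax.seq_core import (
    NucleotideSequence,
    canonical_kmer_integers,
    gc_content,
    kmer_sketch,
    pairwise_identity,
    read_fasta,
    sketch_distance,
    sketch_jaccard,
    write_fasta,
)
from polytax.synthetic import gen_genome, mutate

dna = st.text(alphabet="ACGT", min_size=1, max_size=120)


class TestFastaIO:
    def test_roundtrip_preserves_order_and_case(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">b first\nacgtACGT\n>a second\nTTTT\nGGGG\n")
        records = read_fasta(p)
        assert [r.id for r in records] == ["b", "a"]
        assert records[0].residues == "ACGTACGT"  # uppercased
        assert records[1].residues == "TTTTGGGG"  # multi-line joined
        out = tmp_path / "out.fasta"
        write_fasta(records, out)
        assert [r.residues for r in read_fasta(out)] == \
               [r.residues for r in records]

    def test_crlf_tolerated(self, tmp_path):
        p = tmp_path / "crlf.fasta"
        p.write_bytes(b">x\r\nACGT\r\nACGT\r\n")
        assert read_fasta(p)[0].residues == "ACGTACGT"

    def test_duplicate_id_rejected_naming_it(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">same\nACGT\n>same\nTTTT\n")
        with pytest.raises(ValueError, match="same"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)


class TestGcContent:
    @pytest.mark.parametrize("residues,expected", [
        ("ATGC", 50.0),
        ("GGGG", 100.0),
        ("ATAT", 0.0),
        ("GCNNNAT", 50.0),  # N excluded from both counts
    ])
    def test_known_values(self, residues, expected):
        assert gc_content(NucleotideSequence("x", residues)) == expected

    def test_all_n_undefined(self):
        with pytest.raises(ValueError):
            gc_content(NucleotideSequence("x", "NNNN"))

    def test_random_sequence_near_target(self):
        # 10 kb generated at G+C 0.409; oracle = direct letter counting
        genome = gen_genome(10000, 0.409, seed=42, genome_id="gc")
        seq = genome.contigs[0]
        direct = 100.0 * sum(seq.residues.count(b) for b in "GC") / len(seq)
        assert gc_content(seq) == pytest.approx(direct)
        # binomial 99% half-width at n=10000, p=0.409: ~1.27 points
        assert abs(gc_content(seq) - 40.9) < 1.3

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(dna)
    def test_invariant_under_reverse_complement(self, residues):
        seq = NucleotideSequence("x", residues)
        assert gc_content(seq) == pytest.approx(
            gc_content(seq.reverse_complement()))


class TestPairwiseIdentity:
    def test_identical_sequences(self, random_16s):
        r = pairwise_identity(random_16s, random_16s)
        assert r.percent_identity == 100.0
        assert r.aligned_columns == len(random_16s)
        assert r.query_coverage == 100.0

    def test_three_substitutions_in_100nt(self):
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), size=100))
        alt = list(base)
        for i in (10, 50, 90):
            alt[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[alt[i]]
        r = pairwise_identity(NucleotideSequence("a", base),
                              NucleotideSequence("b", "".join(alt)))
        assert r.percent_identity == pytest.approx(97.0)
        assert r.aligned_columns == 100

    def test_symmetry_of_identity(self, random_16s):
        other, _ = mutate(random_16s, 0.02, seed=3)
        fwd = pairwise_identity(random_16s, other)
        rev = pairwise_identity(other, random_16s)
        assert fwd.percent_identity == pytest.approx(rev.percent_identity)

    def test_terminal_gaps_excluded(self):
        # 20-nt query inside a 30-nt subject: end-free global alignment
        inner = "ACGTACGTACGTACGTACGT"
        subject = "TTTTT" + inner + "GGGGG"
        r = pairwise_identity(NucleotideSequence("q", inner),
                              NucleotideSequence("s", subject))
        assert r.percent_identity == 100.0
        assert r.aligned_columns == 20

    def test_strand_canonicalization(self):
        seq = NucleotideSequence("p", "ACGTAACCGGTTACGT")
        rc = seq.reverse_complement()
        plain = pairwise_identity(seq, rc)
        canon = pairwise_identity(seq, rc, canonicalize=True)
        assert canon.percent_identity == 100.0
        assert canon.percent_identity >= plain.percent_identity

    def test_bad_letters_rejected(self):
        seq = NucleotideSequence("ok", "ACGT")
        with pytest.raises(ValueError):
            NucleotideSequence("bad", "ACRT")  # R is not allowed
        bad = object.__new__(NucleotideSequence)
        object.__setattr__(bad, "id", "bad")
        object.__setattr__(bad, "residues", "ACRT")
        object.__setattr__(bad, "description", "")
        with pytest.raises(ValueError):
            pairwise_identity(seq, bad)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(dna)
    def test_self_identity_is_100(self, residues):
        seq = NucleotideSequence("x", residues)
        assert pairwise_identity(seq, seq).percent_identity == 100.0


class TestSketches:
    def test_deterministic(self, random_16s):
        a = kmer_sketch(random_16s, k=21, s=200)
        b = kmer_sketch(random_16s, k=21, s=200)
        assert a.hashes == b.hashes

    def test_reverse_complement_invariant(self, random_16s):
        a = kmer_sketch(random_16s, k=21, s=200)
        b = kmer_sketch(random_16s.reverse_complement(), k=21, s=200)
        assert a.hashes == b.hashes
        assert sketch_distance(a, b) == 0.0

    def test_sketch_size(self):
        genome = gen_genome(50000, 0.5, seed=11, genome_id="sk")
        sk = kmer_sketch(genome.contigs[0], k=21, s=1000)
        assert len(sk.hashes) == 1000
        assert list(sk.hashes) == sorted(set(sk.hashes))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            kmer_sketch(NucleotideSequence("x", "ACGT"), k=21)

    def test_mismatched_k_rejected(self, random_16s):
        a = kmer_sketch(random_16s, k=21, s=50)
        b = kmer_sketch(random_16s, k=15, s=50)
        with pytest.raises(ValueError):
            sketch_distance(a, b)

    def test_disjoint_sketches_capped_at_one(self, random_16s):
        other = gen_genome(2000, 0.5, seed=77, genome_id="o").contigs[0]
        a = kmer_sketch(random_16s, k=21, s=100)
        b = kmer_sketch(other, k=21, s=100)
        assert sketch_jaccard(a, b) == 0.0
        assert sketch_distance(a, b) == 1.0

    def test_distance_tracks_divergence_with_exact_jaccard_oracle(self):
        # 50-kb genome mutated at 3%: Mash distance approximates the
        # per-site divergence; the exact Jaccard over full k-mer sets is
        # the oracle for the sketch estimate.
        genome = gen_genome(50000, 0.5, seed=21, genome_id="m")
        seq = genome.contigs[0]
        mut, _ = mutate(seq, 0.03, seed=22)
        d = sketch_distance(kmer_sketch(seq, 21, 1000),
                            kmer_sketch(mut, 21, 1000))
        ka = set(canonical_kmer_integers(seq.residues, 21).tolist())
        kb = set(canonical_kmer_integers(mut.residues, 21).tolist())
        j_exact = len(ka & kb) / len(ka | kb)
        d_exact = -(1 / 21) * math.log(2 * j_exact / (1 + j_exact))
        assert d == pytest.approx(d_exact, abs=0.005)
        assert d == pytest.approx(0.03, abs=0.01)

    def test_monotone_in_divergence(self):
        genome = gen_genome(20000, 0.5, seed=31, genome_id="mono")
        seq = genome.contigs[0]
        dists = []
        for rate in (0.01, 0.03, 0.06, 0.10):
            # average over seeds to test expected monotonicity
            ds = []
            for seed in range(3):
                mut, _ = mutate(seq, rate, seed=100 + seed)
                ds.append(sketch_distance(kmer_sketch(seq, 21, 500),
                                          kmer_sketch(mut, 21, 500)))
            dists.append(np.mean(ds))
        assert all(b > a for a, b in zip(dists, dists[1:]))

    def test_json_roundtrip(self, random_16s):
        from polytax.seq_core import KmerSketch
        sk = kmer_sketch(random_16s, k=17, s=64)
        back = KmerSketch.from_json(sk.to_json())
        assert back == sk
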