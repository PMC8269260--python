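# Methods

This note documents the models, parameter choices and numerical conventions
behind `polytax`, and what the synthetic-data tests do and do not establish
about behaviour on real data.

## Pairwise identity

Nucleotide identities are computed from an **end-gap-free global
alignment** (Needleman–Wunsch with free terminal gaps) under match +1,
mismatch −1, gap open −2, gap extend −1. Identity is *matches / aligned
columns*, with terminal gap runs excluded from the column count — the
convention of 16S identity servers, where two homologous genes of unequal
length should not be penalised for their overhangs. A local
(Smith–Waterman) mode with the same scores is used where a partial match is
the question being asked (amplicon representative sequences against member
references, ANI fragments).

Two consequences worth knowing:

* The exact scores are irrelevant to the thresholded decisions at the
  divergences that matter here (a 93 % vs 98.7 % call does not hinge on
  gap-open −2 vs −3); they are fixed and documented for reproducibility.
* End-gap-free identity is only meaningful between **homologous**
  sequences. For two unrelated random sequences the optimal end-free
  alignment is a short spurious overlap with near-100 % "identity" over a
  handful of columns. Real 16S genes are universally homologous so this
  does not arise in ranking; the synthetic reference generator therefore
  also derives all 16S sequences from one common ancestor.
* Ambiguity codes other than N are rejected rather than scored, so a
  reported identity never depends on wildcard-scoring policy.

## Fragment ANI

ANI follows the classical fragment recipe: the query genome is cut into
non-overlapping 1020-bp fragments (trailing partial fragments dropped),
each fragment is placed on the subject by exact 15-mer seeding (diagonal
voting, both strands), and scored by a local alignment inside a ±150-bp
window around the seeded placement. Fragments aligning at ≥ 30 % identity
over ≥ 70 % of their length count as *used*; ANI is the mean identity of
used fragments. With no usable fragment the result is **undefined** (`None`)
— deliberately distinct from 0, and treated downstream as "no evidence",
never as evidence for separation. ANI is directional (query → subject); the
delineation engine uses the isolate-as-query direction.

This is a fragment/best-hit re-implementation, not a FastANI clone: ANI
values for distant pairs can differ from FastANI's by more than a point.
Every downstream use is a threshold test at 95 % (with a grey band, below),
and the recovery property — mean |ANI − 100(1−p)| ≤ 0.5 over substitution
rates p ∈ {0.01 … 0.08}, ten seeds each — is part of the test suite.

## POCP

A protein of proteome A is *conserved* in B when some protein of B aligns
(BLOSUM62, local, gap open −11 / extend −1) with identity ≥ 40 % over an
alignable region ≥ 50 % of the query protein length, and raw score ≥ 50.
POCP = 100·(C1+C2)/(T1+T2), counted in both directions. The textbook
definition uses a BLAST E-value cutoff; E-values depend on database size
and are not reproducible in a self-contained library, so a raw-score floor
replaces it. The floor sits well above the maximal local score of unrelated
random protein pairs at the lengths involved (~30–40 at a few hundred
residues) and far below any score a 40 %-identity/50 %-coverage hit
produces, so within the identity/coverage rules it only suppresses noise.
Residue X is removed before alignment (BLOSUM62 carries no X column).

For genomes lacking a predicted proteome, `orf_translate` provides a crude
surrogate: stop-to-stop open reading frames ≥ 100 aa on all six frames,
bacterial genetic code, deterministic order. It over- and under-calls genes
relative to a real gene finder and is meant for threshold-level POCP, not
annotation.

## MinHash sketches

Sketches are bottom-s MinHash over canonical k-mers (lexicographic minimum
of the 2-bit-packed k-mer and its reverse complement; k ≤ 31). The hash is
**splitmix64**, unseeded, applied to the packed integer — fixed and
documented so sketches are bit-stable across runs and platforms. Defaults
k = 21, s = 1000. The distance is d = −(1/k)·ln(2J/(1+J)) with J estimated
from the merged bottom-s, capped at 1 (and d = 1 when J = 0). d estimates
per-site divergence under a Poisson substitution model; the test suite
checks it against the exact Jaccard over full k-mer sets and against
designed substitution rates (±0.01 at p ≤ 0.05). Genome-to-MAG matching
reports sketches at d < 0.05.

## The delineation decision engine

Decision order, with every consulted threshold recorded as one evidence
row:

1. **Genus.** Genus membership is anchored on POCP to *type species* only.
   If type-species POCP values exist and all are ≤ 50 %, the verdict is
   novel genus; otherwise the isolate is assigned to the genus with the
   highest type-species POCP above 50 %. High POCP to a non-type species
   never anchors a genus — it is routinely observed across genus boundaries
   and choosing the type species is the only rule consistent with all seven
   bundled case studies. With no POCP at all, the 16S genus threshold
   (best identity ≤ 94.5 % → novel genus) decides, and otherwise the genus
   of the best 16S hit is assigned.
2. **Species within the assigned genus.** Known species requires best
   within-genus 16S identity > 98.7 % *and* ANI (if available) ≥ 95 %.
   ANI < 93 % is decisively novel. ANI inside the [93, 97] grey band — the
   literature says "close to 95 %" without quantifying it; the band is this
   package's reading — or an ANI/16S conflict escalates to dDDH: ≤ 70 %
   novel, > 70 % known. dDDH is consumed, never computed; when the branch
   requires it and none was supplied, the verdict is **ambiguous** rather
   than a guess. Genome evidence outranks 16S on conflict, mirroring how
   practitioners escalate exactly in such cases.
3. A G+C difference ≥ 1 point is recorded as supporting evidence only.

Relative ranking filters references to validly named, genome-backed entries
before taking the top 50 by 16S identity (filter-then-cap; ties break
lexicographically by taxon name). Multi-copy 16S inputs are reduced to the
longest copy, with a warning. Two published judgment calls the engine
cannot (and should not) reproduce mechanically — overriding a
phylogenomic-placement disagreement, and discounting a high dDDH to an
invalidly named relative — are carried as notes on the case studies; final
naming is human judgment.

## Amplicon tracking

Tables are relative abundances in percent, accepted as given (no
rarefaction). The 0.25 %-in-at-least-one-sample inclusion filter is applied
before diversity and Venn computations, and "detected" means strictly > 0
after it. Member matching: OTU level at local identity ≥ 97 %, ASV level at
identity > 99 % **and** representative-sequence coverage ≥ 80 % (the
identity+coverage pair replaces a database-size-dependent E-value). Each
taxon is assigned to at most one member (best identity, ties to the
lexicographically first member id); several taxa may map to one member and
their abundances are **summed** per sample — published per-taxon abundance
ranges imply members can split across molecular species. A sample is
positive for a member when that sum is > 0; prevalence is the percentage of
positive samples; the mean abundance is over positives only (undefined when
never detected); the maximum is over all samples. Alpha diversity is
richness, Shannon H (nats, renormalized over detected taxa) and the
effective species number exp(H). Group-difference testing is a thin
pass-through to scipy's rank-sum and Fisher exact tests.

## Synthetic data

Generators are deterministic per (parameters, seed) and write a
`SyntheticTruth` sidecar with the design and realized values.

* **Mutation is substitution-only** (uniform per-site, no indels), so
  identity/ANI/sketch ground truths are exact Hamming quantities. Indel
  robustness is exercised separately with small hand-built constructs
  (truncations, chimeric tails) in the test suite.
* **Proteome pairs** share identical proteins and carry independent random
  uniques, so the designed POCP is exact by construction.
* **Community tables**: background taxa draw log-normal mean abundances
  (σ = 1.5) with per-sample log-normal noise (σ = 0.5) — a long-tailed
  profile like real gut amplicon data; spiked members follow per-group
  Bernoulli presence and log-normal abundance; columns renormalize to
  100 %. Representative sequences are generated at designed identities to
  the member references.
* **Reference hierarchies**: all 16S genes descend from one random
  ancestor (genus roots at 10 % from it, congeners at multiples of 2 %);
  genomes are independent per genus (between-genus ANI is genuinely
  undefined) and mutated copies within. Proteomes are not generated, so
  genus novelty on this database exercises the engine's 16S fallback
  branch rather than the POCP branch (the POCP branch is covered by the
  bundled case studies and constructed bundles).

What passing these tests shows: the implementation recovers its own design
parameters and reproduces the bundled published verdicts. What they do not
show: robustness to real-data phenomena the generators omit — indels and
rearrangements, horizontal transfer, multi-copy 16S heterogeneity,
chimeras, compositional noise from sequencing depth.

## Problem sizes and numerical conventions

Test and demonstration sizes are chosen for desk-scale runs: 8–50 kb
genomes for ANI/sketch recoveries, proteomes of 40–60 proteins of ~120 aa
for POCP, 200 samples for prevalence recovery (checked against the exact
binomial 99 % interval). Percentages in collection tallies round half-up to
one decimal, matching printed conventions. Sample sums may exceed 100 % by
at most 1e−6 before a table is rejected. All randomness flows through
`numpy.random.default_rng` seeds; derived seeds stay below 2^31.
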