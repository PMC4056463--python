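# Methods

This note documents the models, parameter semantics, numerical choices
and known limitations of splitmap. It complements the README, which
gives the high-level picture.

## Seeding

The index is a plain suffix array over the concatenated chromosomes
(sentinel-separated, so matches never cross records), built by numpy
prefix doubling. Queries return the longest exact prefix of a pattern
and its occurrence interval; reverse-strand seeds come from querying
the reverse complement of the read and are stored in forward
coordinates with strand `-`.

Seeding scans each read orientation greedily: the suffix at the current
position contributes its maximal exact match as a seed, and the scan
restarts one position past the match end, so a sequencing error or a
splice boundary costs at most one skipped base and at most 2(m−ℓ)
suffixes are ever considered. For unique seeds a single mismatch is
bridged when at least four bases continue to match behind it
(`max_seed_errors = 1`). This replaces full error-tolerant
suffix-array matching with E-value control; the specificity filters
here are the minimum seed length ℓ (default 20 nt), the occurrence cap
(default 50; seeds exceeding it are treated as repeats and dropped) and
the Shannon-entropy threshold (default 1.5 bits, computed over
mononucleotide frequencies of the read substring). Note the practical
consequence: a junction flanked by fewer than ℓ matching bases on one
side cannot be seeded from that read; recovery then relies on other
reads with longer anchors.

## Chaining

Chain score: σ(c) = Σ ψ(c[k]) − Σ_{k≥2} |π_e(c[k−1]) − π_s(c[k])|.
The gap term penalizes both gaps and overlaps in read coordinates;
genomic positions play no role, which is exactly what lets a chain span
strands and chromosomes. The greedy sweep (seeds sorted by read start,
each seed extended by its best predecessor) is exact: an extension's
score depends on the preceding chain only through its total score and
its last read end, so the best chain ending at each seed dominates.
The predecessor relation uses the strict read-start order rather than
read-end order; with read-end order a chain over contained seeds can
beat the sweep by one point, and the sweep would no longer equal
exhaustive enumeration (the oracle the tests check against).

Only the top chain is used (ties: fewer seeds, then leftmost genomic
coordinate) and only when it covers strictly more than
`min_coverage = 0.80` of the read. Multi-hit seeds are then fixed to
single loci by a small exact dynamic program minimizing, in
lexicographic order, (summed genomic distance between consecutive
seeds, number of strand switches, position tuple); different
chromosomes count as a large constant distance. This replaces
left-to-right greedy fixing because the exact optimum is what the
stated behaviour ("minimize the distance on the genome, prefer the same
strand") describes, and it is just as cheap at these occurrence counts.

Read-adjacent seeds on (nearly) the same genomic diagonal — the typical
result of a sequencing error splitting one locus into two seeds — are
merged into one locus before alignment (diagonal tolerance 30 nt, far
below any plausible intron), so the aligner never sees one exon as two
windows.

## Local transition alignment

Windows are the merged loci widened by `boundary_extension` (10 nt) on
both sides, plus the unseeded read gap towards neighbouring loci: if
errors pushed a seed k nt away from the true boundary, the window still
contains the breakpoint. Minus-strand windows hold the reverse
complement of the forward slice, so the read aligns against all windows
in its own orientation.

The DP fills M[i, k, j] with the local-alignment recursions (match +1,
mismatch −1, indel δ = 1, scores clamped at 0) plus the transition
move: M[i,k,j] may take lms[k′, i−1] − τ + s(r_i, w_j) for any earlier
locus k′ < k, where lms[k, i] is the running maximum of M over the
first i read rows of locus k. The transition move scores the first
aligned pair of the new fragment, so an error-free two-locus read of
length m scores m·match − τ; a formulation without the s(a,b) term
would lose one match per transition and could not reproduce that total.
τ defaults to 3; transitions are only taken when the score gain exceeds
it. Transitions run forward in chain order only — backward jumps (as in
back-splices) are expressed by the chain's window order, not by the DP.

Traceback starts at the global maximum (ties: lowest locus index, then
the first-filled cell) and prefers, at equal score, continuing
diagonally, then ending the alignment, then gaps, then a transition —
so equal-scoring alignments resolve to fewer transitions. Fragments
covering fewer than `min_fragment_length = 15` read bases are dropped
with score recomputation; they are almost always window-edge artifacts.
The kernel is a dense numba loop; laziness is unnecessary at window
sizes proportional to the read.

`semi_global_align` (read vs. any window substring, edit distance) is
delegated to edlib's infix mode with a leftmost-end tie rule; the test
suite checks it against an independent quadratic DP.

## Junctions

Donor = last aligned base (in transcription direction) of the
earlier-in-read fragment; acceptor = first base of the later fragment;
0-based forward coordinates plus strand. Classes are purely geometric:
strand-reversing (strands differ), long-range (different chromosomes or
span > 200 kb), circular (acceptor upstream of donor on the shared
strand), else regular.

Breakpoints are often ambiguous: when the reference continues
identically across the break, several (donor, acceptor) pairs describe
the same alignment. Junctions are therefore normalized by sliding the
pair through its genomic equivalence interval, and — because the
simulated libraries are non-strand-specific, so a junction cannot be
oriented — the lexicographically smaller of the two flip-equivalent
representations is kept. The simulator normalizes its truth junctions
with the same function; without a shared canonical form,
exact-tolerance evaluation would be ill-defined. Support aggregation
merges identical canonical junctions (optionally within
`merge_tolerance` nt, default exact) and drops junctions below
`min_support` (default 1).

## Simulator

Genomes are i.i.d. uniform A/C/G/T (optionally salted with poly-A decoy
tracts for entropy-filter tests). Isoforms are exon chains (defaults:
3–8 exons of 150–450 nt, introns 200–2,000 nt, random strand; minus
isoforms run right-to-left so their internal junctions are regular).
With probability `irregular_fraction` (0.20 in the mixed protocols) an
exon is strand-flipped in place or replaced by a uniformly drawn exon
> 200 kb away or on another chromosome; circularized isoforms add the
end-to-start junction and are read-sampled from their doubled sequence
so reads cross the back-splice point. Junction truth classes come from
the same geometric classifier used for predictions — note that if
*every* exon is flipped, adjacent exons are again on one strand and the
junctions are not strand-reversing; only flipped/unflipped boundaries
are.

Error models are distributional stand-ins for read-simulator error
profiles, validated statistically rather than byte-compatible:
Illumina-like — position-independent substitutions at 0.005 with rare
indels (2·10⁻⁴ each); 454-like — indel-dominated (substitutions 0.001,
indels 0.002 each scaled by homopolymer run length, capped at 5×, with
insertions realized as base duplications). Reads are drawn uniformly
along each isoform to the target coverage (default 10×), reverse
complemented with probability 0.5; `full_length_reads` emits one
transcript-length read per pass for the long-read protocol. A read
witnesses a junction only with ≥ `anchor` nt (default 10) on both
sides; the evaluation denominator is the set of witnessed junction
loci, since an unwitnessed junction is unrecoverable by any mapper. The
zero-error exactness fixtures raise the anchor to 25 nt (minimum seed
length plus boundary slack) so that every witnessed junction is also
seedable in principle. Everything is driven by one seed;
identical configurations produce byte-identical FASTQ and truth tables.

## Evaluation and benchmark protocol

Recall = matched truth loci / truth loci; FPR = unmatched predictions /
predictions; precision = 1 − FPR; matching is greedy nearest-first with
each truth junction used at most once, at exact tolerance by default
(the tolerance is a parameter; monotonicity in it is property-tested).
Per-class breakdowns use the truth class for recall and the predicted
(geometric) class for precision.

Benchmark runs (`splitmap.benchmarks`, used by the test suite and
`scripts/acceptance.py`) apply the default mapping parameters with a
split-read support filter of 2. The filter is part of the benchmark
protocol, not the package default: single-read junction calls are
dominated by breakpoints shifted a few nt by an error adjacent to the
junction, while a true junction at ≥10× coverage has ~8–10 spanning
reads, so requiring two concordant reads suppresses those artifacts at
negligible recall cost (a stricter support-of-three filter is the
natural choice for noisy real data). Full-size runs use a 4 Mb genome
with 200 isoforms (t1–t5 protocols), a 2 Mb genome with 100 circular
isoforms (short-circular protocol) and 2 Mb with 50 + 50 long
transcripts (long-read protocol); the `small` preset halves the isoform
count and quarters the genome for fast tests. These sizes are the
package's desk-scale stand-in for genome-wide benchmarks.

## Known limitations

- Seeds are exact matches (plus a one-mismatch bridge): junction
  anchors shorter than ℓ, or error bursts denser than one per ℓ bases,
  are invisible to seeding. Coverage hides this for junction calling
  but single reads may map partially.
- Linear gap costs only; no base-quality awareness; no affine gaps.
- Single-end reads only; no paired-end rescue.
- One scalar transition penalty τ regardless of transition type
  (intra- vs inter-chromosomal).
- The uniform random genome has no repeat structure beyond chance;
  occurrence-cap and entropy filters are exercised by construction
  (decoy tracts), but mapping ambiguity in true repeat families is not
  represented, so benchmark numbers here are an upper bound on
  repeat-rich genomes.
- SAM output stores per-fragment records (primary + supplementary) with
  soft clips; mate/SA-tag conventions beyond that are not emitted.
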