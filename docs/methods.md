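# Methods

## The analysis in one paragraph

`spacerlink` links viruses to a dominant host in a metagenome through the host's own
CRISPR record. Spacers are mined from raw reads anchored on exact copies of the host's
direct-repeat (DR) consensus, deduplicated into 99%-identity clusters, and the cluster
representatives are aligned against candidate scaffolds; scaffolds hit at ≥ 80%
spacer similarity are the host's past or present viruses. A rule-based classifier
separates confident viruses from putative ones and removes false positives, and
coverage-based statistics (normalized abundance, host–virus ratio, per-virus spacer
diversification) track the arms race across samples and timepoints.

## Spacer extraction

A read contributes spacers only if it carries at least one complete, exact DR copy;
matching is strict string equality, so an `N` anywhere in the aligned window disqualifies
that occurrence (spacers themselves may contain `N`). Both DR orientations are scanned.
When a read carries hits on both strands, the strand with more hits wins (tie → forward):
a CRISPR array is single-stranded per locus, so mixed-strand reads are chimeric
artifacts. A spacer is the segment between two consecutive same-strand DR copies;
read-terminal fragments bounded by a single DR have an unknown boundary and are dropped
by default (`allow_partial` re-enables them). Spacers outside 20–60 nt are discarded.
Reverse-strand spacers are reverse-complemented into DR-forward orientation so both
strands cluster together.

Note the strand tie-break is not symmetric for the pathological read that carries
exactly equal numbers of DR copies on both strands; for biologically planted arrays
(one orientation per read) extraction is strand-symmetric, and the property test covers
that case.

## Clustering (Cd-hit semantics)

Unique sequences are sorted length-descending (ties lexicographic) and greedily join the
first cluster whose representative they match at ≥ 99% identity, else found a new
cluster; the sort makes the outcome independent of input order and makes each
representative the longest member. Identity is **matches in the minimum-edit-distance
end-gap-free (semi-global) alignment divided by the shorter length** (computed with
edlib, matches read from the extended CIGAR): an exact prefix scores 1.0, one
substitution in a 40-mer scores 0.975. A match-maximizing zero-cost alignment was
rejected as the definition because with free gaps it degenerates to the longest common
subsequence — a random 21-mer "contains" in an unrelated 53-mer at identity 1.0 —
whereas the distance-optimal alignment counts matches of the biologically aligned
placement. At the 99% threshold on ≤ 60 nt spacers the practical effect is that only
identical sequences and exact containments merge.

Singletons are clusters with exactly one occurrence across the whole sample set; they
are almost exclusively born from a single sequencing error inside a spacer copy and are
tracked as their own statistic.

## Short-query alignment (protospacer matching)

The aligner follows the short-query BLAST recipe — exact word-7 seeds on both strands,
then gapped extension under match +1, mismatch −3, gap open 5, gap extend 2 (a length-k
gap costs 5 + 2k) — but the extension is an exact local Gotoh DP, vectorized row-wise in
numpy over a window around the seeded diagonals, so within a window the reported
alignment is the true Smith–Waterman optimum. Two deliberate departures from a plain
word-seeded design:

- **Exhaustive diagonal sweep.** Word-7 seeding has a hard sensitivity floor: a 40-mer
  with 8 evenly spaced substitutions contains no intact 7-mer, yet sits exactly at the
  80% identity boundary the threshold rule must adjudicate. For subjects up to 60 kb the
  seeder additionally scores every ungapped diagonal with one vectorized comparison and
  admits offsets whose full-query identity reaches 0.7. Large subjects rely on word
  seeds alone (with an optional ungapped Kadane-score prefilter used by the matching
  stage to skip hopeless diagonals, the classic X-drop economy).
- **Full-spacer similarity accounting.** Under the +1/−3 scoring the *optimal* local
  alignment clips mismatch-dense spacer ends (for 8 substitutions in a 40-mer the
  optimum is a short clipped HSP, not the 32-identity full span), so similarity computed
  on the raw HSP could never reach 80% in exactly the cases the threshold is about.
  Similarity is therefore counted over the HSP extended ungapped to full spacer coverage
  at its locus: identities / spacer length (the conservative, partial-hit-penalizing
  denominator; identities / alignment length is available as an option). The 80%
  threshold is inclusive: 8 substitutions in a 40-mer are kept at exactly 0.80, 9 are
  rejected at 0.775.

Overlapping hits sharing more than half of the shorter subject span are deduplicated,
keeping the best. Matching uses cluster representatives only.

## Scaffold classification

Rules apply in a fixed order to per-scaffold features; the first applicable rule wins,
so classification is a total function:

1. length ≤ 3 kb → `not_considered`;
2. CRISPR array with ≥ 5 spacers → `rejected` (a host fragment mis-assembled as viral;
   genuine viral mini-CRISPR arrays carry 1–2 spacers and do not trigger this);
3. ≥ 3 bacterial database hits and no hallmark gene → `rejected`;
4. ≥ 1 viral hallmark gene and circular → `virus`;
5. spacer-targeted → `putative_virus`;
6. otherwise `not_considered`.

The exact decision tree of the original scheme this reconstructs is not published in
full; the order above reproduces its stated outcomes and is flagged as a reconstruction.
Hallmark/VOG/bacterial evidence arrives as an external annotation TSV — gene prediction
and database search are out of scope by design. Circularity is an exact terminal direct
repeat of ≥ 20 bp (prefix = suffix, searched up to 500 bp), the standard assembler
signature of a closed circle; lytic/lysogenic labels are passthrough metadata.

Mini-CRISPR detection anchors on an exact 23-mer recurring at CRISPR-like spacing
(period 43–110 bp), walks downstream collecting unit copies, and derives the repeat as
the minimal common left/right extension across all units; repeats of 23–50 bp with
spacers of 20–60 bp qualify. Random sequence essentially never anchors.

Intergenomic similarity is `100 · 2 · matches / (len_a + len_b)`: exact 15-mer anchors
grouped by diagonal delimit the alignable regions (snapped to the sequence ends across
short unanchored tails), each region is globally aligned and its identical bases summed.
Unrelated genomes share no 15-mer and score 0; identical genomes score 100. Species and
genus demarcation are single-linkage cuts of the similarity matrix at 95% and 15.8%;
single linkage is monotone in the threshold, so species clusters always refine genera.

## Read assignment and normalization

The abundance stage needs depth ratios, not base-perfect alignments, so reads are
assigned by a purpose-built best-hit mapper: exact 15-mer probes (3 per read, both
orientations) against a reference index propose candidate offsets, each candidate is
scored ungapped, and the location with the most aligned bases (ties: fewest mismatches,
then first reference in input order; `multi` = first/discard/fractional for cross-
reference ties) wins if its mismatches are ≤ 2% of the aligned length. End-clipped
placements (≥ 30 bp overlap) are allowed so reads spanning a circular replicon's
junction are not dropped wholesale. Indels are not modeled — the simulator's error model
is substitution-only and the 2% filter concerns substitutions.

Coverage is mapped bp / reference length. Cross-sample normalization multiplies each
sample's coverages by min(total bp) / total bp(sample); within-sample ratios are
invariant under this scaling, so the host–virus ratio (host / virus normalized coverage)
is unaffected by sequencing depth. A virus with zero coverage yields an explicit
undefined sentinel (`None`), never an infinity that could propagate.

Spacer dynamics rescale per-sample spacer abundances by host coverage relative to the
minimum host coverage across samples (a sample with twice the host contributes half the
weight per count). Distinct and singleton cluster counts stay un-normalized. A cluster
counts as *present* in a sample for the per-virus distinct-matching statistic when it
has **≥ 2 occurrences there**: genuine spacers at the simulated depths are sampled tens
of times per sample while single-error artifact clusters are seen once, so the
seen-more-than-once rule separates repertoire from read noise (the unfiltered count is
reported alongside). Without this rule the per-sample presence of error clusters is
Poisson noise of magnitude several clusters, which can mask a few genuinely acquired
spacers per timepoint.

## Synthetic community generator

The generator emulates the study system at desk scale: one dominant host genome
(default 100 kb, weight 20) carrying a single CRISPR array of 30 spacers (30–45 nt,
inside the 20–60 nt filter) separated by exact copies of a 30 bp DR; three viruses
(5–25 kb, weights 8/4/2, so planted host–virus ratios 2.5/5/10 — within the broad range
field studies report) each carrying 5 protospacers copied from host spacers with 2%
per-base substitutions on random strands; one third of viruses circular, emitted in
assembly convention with a 55 bp duplicated terminus; two background genomes
(20–50 kb, weight 2); and 10⁵ single-end 150 bp reads per sample with uniform 0.2%
per-base substitution errors and flat quality strings. Reads are drawn per replicon
proportionally to weight × length (multinomial), uniform start, uniform strand; circular
replicons wrap.

Across timepoints the default demo halves virus weights and the host acquires 3 spacers
(losing 1) per step. Acquisition is leader-polarized — new repeat-spacer units enter at
the array start, the canonical acquisition mode — and half of new spacers are sampled
from resident virus genomes (the biological source of acquisition; the fraction is
configurable), the other half random. Deletions remove uniformly chosen existing
spacers. All randomness derives from one integer seed via `numpy.random.SeedSequence`
spawns, so identical config + seed reproduces every emitted byte.

What the generator does **not** emulate: quality-dependent or indel errors, GC bias,
host strain mixtures, assembly artifacts beyond the terminal-repeat convention, and any
realistic spacer-turnover process (the acquisition/loss model is a parameterized
stand-in, not calibrated to field data). Tests passing on this generator therefore
demonstrate the pipeline's correctness and its qualitative trend recovery, not
performance on real Illumina data.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere; FASTA/FASTQ ids are taken up to the
  first whitespace; sequence inputs are gzip-transparent.
- Alignment tie-breaks: the DP optimum resolves ties to the end cell first in
  row-major (query, subject) order; greedy cluster-overlap matching is best-first by
  identity with index tie-breaks; multi-mapping reads default to first-reference.
- Zero-coverage hosts, empty sequences, asymmetric similarity matrices, out-of-range
  thresholds, and losses exceeding the spacer repertoire raise explicit `ValueError`s;
  unknown sample ids in dynamics inputs are rejected rather than silently dropped.
- The pipeline writes outputs into a temporary directory and promotes files atomically;
  a run manifest records the package version, seed, config echo and its SHA-256.

## Problem sizes

The bundled verification runs use 1000 random reads for the extraction oracle, 500
spacer/subject pairs (200 nt subjects) for the alignment oracle, ~300 spacers for the
clustering brute-force comparison, and two pipeline runs of 1–3 samples × 10⁵ reads
each; together they complete in a few minutes on one CPU. Larger communities scale
linearly in reads for extraction and assignment and in clusters × scaffold length for
matching.

## Known limitations

- The seeded aligner's sweep augmentation bounds its sensitivity guarantee to subjects
  ≤ 60 kb; on larger subjects recall below ~85% spacer identity depends on an intact
  7-mer word, exactly as for blastn-short.
- Identity-by-distance-optimal-alignment can differ from match-maximizing identity for
  length-discrepant pairs; at the 99% threshold this is immaterial, but users lowering
  the clustering threshold far below 0.9 should reconsider the definition.
- The read assigner is substitution-only and ungapped; it is not a general-purpose
  mapper and should not be used where indel tolerance matters.
- Intergenomic similarity approximates alignment-fraction-weighted similarity with a
  single anchored global alignment per diagonal group; highly rearranged genome pairs
  are under-counted.
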