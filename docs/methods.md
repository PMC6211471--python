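# Methods

## Overview

`fuseqlite` discovers fusion genes from paired-end RNA-seq by mapping read
pairs against an annotated transcriptome rather than the genome. Two evidence
pipelines run over the same mapping results:

* **Mapped reads (MR, spanning pairs)** — pairs whose two mates map
  (near-)fully to transcripts of two *different* genes. Their fragment must
  straddle the fusion junction, but neither read touches it.
* **Split reads (SR)** — single reads that match two genes with at least one
  k-mer's worth of sequence on each side of the junction. These pinpoint the
  breakpoint at base resolution.

Candidates from both pipelines pass a cascade of false-positive filters and
are merged into a single scored, ranked list.

## Quasi-mapping model

The transcriptome is stored as a hash of canonical k-mers, each posting the
transcripts and offsets where it occurs (with an orientation bit). Mapping a
read is greedy maximal extension: from the leftmost read position whose k-mer
is indexed, the match is extended base by base along each candidate
transcript as long as bases agree; the segment's hit set is the transcripts
supporting the longest extension, and the scan resumes after the segment.
Both read orientations are attempted and the orientation covering more bases
wins (ties go to forward). This is a deliberately simple mapper: downstream
logic depends only on the ordered segment/hit-set structure, not on the
indexing scheme, and no base-quality or gapped alignment is used.

Mismatch tolerance is expressed solely through the near-full threshold
`r − k − 1` (read length minus k-mer length minus one): a transcript enters a
mate's hit set T1/T2 only when the mate's matched bases on it reach that
bound. One unindexed k-mer's worth of slop is thereby allowed without scored
alignment.

Two practical details:

* k-mers occurring more than `max_postings` times (default 200) are masked
  and behave as mismatches — standard pseudo-alignment practice to bound
  worst-case cost on repeats.
* `k` defaults to 21 for reads shorter than 70 bp and 31 otherwise; split
  detection requires `k < r/2` (each side of a split must carry a full
  k-mer) and is disabled with a warning otherwise.

## Read-pair classes

With T1/T2 the near-full hit sets and S = T1 ∩ T2:

1. **concordant** — S non-empty (both mates explained by one transcript);
2. **mapped read** — S empty, both hit sets non-empty, and the hit genes are
   not a single shared gene;
3. **split read** — one mate carries ≥ 2 match segments of ≥ k bases whose
   first and last segments hit different genes, and the other mate maps
   near-fully to a transcript of one of those genes (the anchor);
4. **unmapped/other** — everything else.

Classification precedence is the order above: a junction-straddling read
whose minority side stays below k still looks near-fully mapped to one
transcript and is (correctly, under the threshold model) concordant. Only
the first and last segments of a split mate are used; middle segments are
ignored.

## Fusion equivalence classes

Each mapped-read pair generates the ordered cross product of its discordant
sets, S1 × S2 — its *fusion transcripts*. Pairs generating the identical set
form one *fusion equivalence class* with fragment count c_j. Gene-level
evidence is then read off the class table:

    supportCount(fge)   = Σ_j c_j                 over classes containing ≥1
                                                  fusion transcript of the pair
    correctedCount(fge) = Σ_j c_j / |feq_j|       |feq_j| = number of fusion
                                                  transcripts in class j

A class contributes its weight **once per fusion gene**, no matter how many
of its member fusion transcripts map to that gene pair; the alternative
(once per member) is arguable from the defining formula, but the sum-over-
classes form is the natural reading and keeps corrected ≤ support. Fragments
whose two sides contain transcripts of the same gene are discarded outright:
that pattern is intra-gene ambiguity (shared exons between isoforms), not
fusion evidence.

**Direction.** The 5' side of a fragment is the mate that mapped in forward
(sense) orientation — for a fragment drawn from any sense transcript,
fusion product included, the sense mate carries the 5' end. When
orientations are uninformative (both mates same orientation), mate 1 is
taken as 5'. Residual direction errors surface as (B,A) candidates and are
resolved by the inverted-fusion filter.

## Split-read junctions

For each split read the end of its first segment and the start of its last
segment give transcript-coordinate breakpoints, converted to genomic
coordinates through the exon chain. Evidence is grouped per ordered gene
pair; the modal breakpoint wins, ties breaking toward the smaller genomic
coordinate for determinism. Two screens run per read before grouping:

* **misalignment** — if more than 85% of the read matches a single
  constituent transcript contiguously (strict >), the "split" is an ordinary
  read with a chance second hit and is dropped;
* **overlap** — if the two sides' query intervals overlap by more than
  `max_overlap` bases (default 10; strict >), the dual-mapped stretch
  indicates paralog-like similarity rather than a junction.

When a genome FASTA is supplied, the dinucleotides flanking the junction are
read strand-aware and classified as GT-AG / GC-AG / AT-AC / none. The motif
is annotative only — a confidence flag, never an eliminating filter, since
genuine fusion breakpoints need not fall on annotated splice sites.

## Filter cascade

Applied in fixed order: general → positional → similarity → inverted →
consistency/annotation. No filter ever increases a candidate's support or
score; with all thresholds at zero, duplicate collapse off and empty
references the stage is the identity.

**General features** — candidates are restricted to chromosomes 1–22/X/Y and
protein-coding partners (both configurable); same-chromosome partners closer
than `min_gene_distance` (default 100 kb — read-through territory) are
dropped; MR candidates need `min_mr_support` fragments (default 2), SR
candidates `min_sr_support` reads (default 1).

**Positional distribution** — supporting pairs with identical start-position
pairs collapse to one (PCR/quasi-duplicates); when a breakpoint is known,
implied fragment lengths are screened with a robust z-score
(|x − median| / (1.4826·MAD), drop at z > 5; skipped when MAD = 0 or fewer
than 3 fragments); same-chromosome breakpoints closer than
`min_junction_distance` (default = `min_gene_distance`) drop the candidate;
support thresholds are re-applied to the deduplicated counts.

**Sequence similarity** — a candidate whose unordered gene pair appears in a
paralog database, a read-through database, or the *simulated similarity
reference* is dropped. The reference is built once per transcriptome: a
uniform-abundance paired-end sample (default 1000 fragments per transcript,
seeded) is mapped back, reads are grouped by their concordant hit set
(collected in both orientations so opposite-strand similarity also
surfaces), and any two genes whose transcripts co-occur in a class are
recorded as sequence-similar. MR candidates sharing more than half of their
supporting fragments with a higher-scoring candidate are also dropped
(multi-mapping, not two fusions).

**Inverted fusions** — when both (A,B) and (B,A) survive, only the
higher-scoring direction is kept; an exact tie is a circular pattern and
both are dropped with a `circular` flag.

**Flag-only tests** — when a candidate has both evidence types, a two-sided
binomial test compares the split-read fraction against an expected p0
(default 0.5); p < 0.01 adds an `mr_sr_inconsistent` flag but never drops,
because single-evidence candidates are legitimate. Special gene lists
(ribosomal, mitochondrial, ribonucleoprotein — user-supplied TSVs) likewise
only add flags.

## Scoring and export

score = corrected MR count + corrected SR count (the SR corrected count is
the deduplicated split-read support). Candidates scoring below 3 are
removed — applied last, after inverted-fusion resolution. Ranking is by
score, then split-read support, then lexicographic gene ids (the tie rules
are ours; only the score ordering is principled). Export is a deterministic
TSV: gene ids/symbols, breakpoint coordinates, support counts, score, motif
and flags.

## Evaluation statistics

recall = TP/validated, precision = TP/total discovered, F1 their harmonic
mean; printed values round half away from zero to 2 decimals. With an
incomplete validated list recall is unbiased while precision is a lower
bound. Precision of two callers is compared with a two-sided exact test on
the 2×2 table whose columns are **(TP, total discovered)** — note, not
(TP, total − TP); the two-sided p-value sums hypergeometric probabilities no
larger than the observed table's. Operating-characteristic curves report
cumulative distinct true positives per rank, with multi-sample input
aggregated at each fusion's maximum score.

## Synthetic data generator

The simulator emulates a spike-in style benchmark: a multi-gene,
multi-isoform transcriptome of i.i.d. random sequence (so cross-gene k-mer
collisions are negligible at k ≥ 21), genes laid out on chromosomes 1–22
with ≥ 1 Mb spacing, one full isoform per gene plus skip-one-exon isoforms,
and optional planting of an identical exon in two genes (a paralog-like
pair). Fusions join a 5' transcript prefix to a 3' transcript suffix between
inter-chromosomal partners, breakpoints uniform in the middle 60% of each
transcript. The 3' breakpoint is shifted until the junction carries no
microhomology — inside a homologous stretch the breakpoint coordinate is
not identifiable from reads, so the generator guarantees the implanted
coordinate is the unique correct call.

Fragments are drawn per source in proportion to abundance (exact counts by
default, for reproducibility), with truncated-normal fragment lengths
(default 250 ± 25 bp), error-free reads of the fragment's two ends (mate 2
reverse-complemented), optional strandedness ('fr', 'rf', or random), and an
optional exact-duplication rate for duplicate-collapse testing. Fusion
fragments are constrained to cover the junction.

What the generator does *not* emulate — sequencing errors and quality,
coverage bias, intron retention, genomic background reads, realistic
paralog families, expression covariance — bounds what passing tests show:
they validate the combinatorial and statistical machinery under the
threshold model, not robustness to real-data noise. The error-free choice is
deliberate: all detection definitions are thresholds on exactly matched
bases, so an error model changes sensitivity constants, not logic.

## Standard synthetic study

Tests and the acceptance script use a fixed-size study chosen to exercise
every pipeline stage in minutes on one CPU: 50 genes × 2 isoforms, five
inter-chromosomal fusions at 100 junction-covering fragments each, 50,000
background fragments, 100-bp reads, k = 31. Under these conditions all five
fusions are recovered at the top of the ranking with exact breakpoints, and
background-only samples yield zero candidates.

## Numerical and degenerate-input choices

* Index lookup of k-mers containing N returns nothing; all-N reads map to
  empty segment lists.
* Greedy segmentation resumes exactly at a segment's end (no overlap between
  segments on the query).
* Mode ties in junction calling, score ties in ranking and export ordering
  are all resolved deterministically (smaller coordinate / more SR support /
  lexicographic).
* MAD = 0 in the fragment-length screen disables the z-test rather than
  dividing by zero.
* Zero-margin tables in the exact test return p = 1; zero denominators in
  confusion metrics return NaN explicitly.

## Known limitations

* The mapper is exact-match/greedy: a single sequencing error inside a
  k-mer-sparse region can split or truncate segments; real-data use would
  want the thresholds loosened or an error-tolerant seeder.
* Mixed-orientation chimeras (sense–antisense fusions) are not called: each
  read is mapped in one orientation.
* MR-only candidates have no breakpoint, so the junction-distance and
  fragment-length screens only act when split-read evidence exists.
* Fusions from unpaired reads, de novo assembly verification of fusion
  contigs, and transcript abundance estimation are out of scope.
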