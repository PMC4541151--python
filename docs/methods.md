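# Methods

## Scope and model

`copatrace` implements homology-driven recovery of full-length genes from
assembled metagenomic contigs, followed by conserved-motif screening of the
encoded proteins. The pipeline assumes contigs are given (assembly is out
of scope), that the reference database is a curated set of nucleotide genes
of one functional theme (the motivating case is *copA*), and that the
organisms are prokaryotic (genetic code table 11, alternative starts ATG,
GTG, TTG).

## Local search

The search is a classic seed-and-extend local nucleotide aligner run on
both strands of every contig:

* **Seeding.** Exact words of length `word_size` (default 11) against a
  hash index of the reference database. Words containing N are never
  indexed or seeded, which avoids spurious seeding on ambiguous bases.
* **Ungapped extension.** Two-way X-drop extension (drop-off 12) from each
  seed, skipping seeds already covered by a previous extension on the same
  diagonal.
* **Gapped extension.** Segments scoring ≥ 18 trigger a banded
  Smith–Waterman pass with affine gaps, the band covering the cluster's
  seed diagonals ± 32. A gap run of length L costs
  `gap_open + L·gap_extend` (defaults 5 and 2, scores +1/−2), mirroring
  legacy blastn. Sub-trigger segments are reported as ungapped hits; the
  E-value screen removes them downstream. On homologous pairs whose indels
  fit inside the band the best-hit score equals the full Smith–Waterman
  optimum (verified against an independent aligner in the test suite).
* **Statistics.** λ is solved from the Karlin–Altschul identity
  Σᵢⱼ pᵢpⱼ e^(λ·sᵢⱼ) = 1 under uniform base frequencies (residual < 1e-12);
  K comes from a fixed lookup for supported score pairs after reduction by
  gcd (K is invariant under uniform score scaling). The ungapped (λ, K)
  pair is applied to gapped scores — a documented approximation; only the
  10⁻⁴ cutoff matters downstream and cutoff-level decisions are insensitive
  to it at these search-space sizes. The search space is m·n with m the
  contig length and n the summed database length, with no edge-effect
  correction.
* **Screening.** Hits are kept when alignment length ≥ 40 bp (threshold
  inclusive: a 40 bp alignment passes — "threshold" is read as the lowest
  accepted value; the boundary is configurable) and E ≤ 10⁻⁴, sorted by
  alignment length, then E-value, then subject.

## Gene recovery

Candidate contigs are scanned exhaustively in all six frames: every maximal
start-to-stop interval of ≥ 300 nt (including the stop codon) is an ORF,
taking the most upstream start when several share a stop. A
probabilistic gene finder would need training material a planted-gene
benchmark cannot supply; exhaustive scanning is deterministic,
training-free, and sufficient because recovery is anchored on homology
hits, not on ab initio calls. ORFs running off the contig edge without a
stop are not reported — "full-length" requires both gene ends. Codons
containing N translate to X and never act as starts or stops.

Each screened hit is assigned to the same-strand ORF maximizing
hit–ORF overlap (ties to the Jaccard ratio, then the leftmost ORF),
provided the ORF covers ≥ 50% of the hit interval; hits covering no ORF are
kept separately as fragment-only evidence. Manual curation is
operationalized as the only quantitative criterion reported for it: genes
must reach ≥ 70% identity to their nearest reference, which also donates
its family label (ATPase / MCO / unknown).

## Alignment and trees

Pairwise protein alignment is global affine-gap DP (Gotoh) under BLOSUM62
(gap run of length L costs 10 + L·1), with deterministic traceback
preferring diagonal, then up, then left. The multiple aligner is a
single-pass progressive profile–profile alignment over a neighbor-joining
guide tree built from pairwise-identity distances (d = 1 − pid/100, no
correction) and midpoint-rooted so the deepest split is crossed last.
Iterative refinement is deliberately omitted: the package needs stable,
reproducible column bookkeeping for motif localization, not
benchmark-grade alignment accuracy, and a single deterministic pass keeps
every downstream column index reproducible.

Neighbor joining uses the standard Q criterion with ties broken by the
lexicographically smallest (minimum-leaf-name) pair; negative branch
lengths are clamped to zero with the deficit moved to the sister branch,
preserving the pair's summed length. Maximum-likelihood tree estimation is
intentionally not provided — the phylogenetic claims this package supports
are topological, and NJ on p-distances carries them; congruence between
trees is quantified by the Robinson–Foulds symmetric difference over
non-trivial bipartitions, normalized by 2(n−3). Star-like (unresolved)
nodes simply contribute fewer bipartitions.

Conserved-block trimming classifies a column conserved when its most
frequent non-gap residue reaches `cons_frac` (default 0.5) of the rows
(strict at 0.85) and its gap fraction is ≤ 0.5. High-gap columns and runs
of more than 8 consecutive non-conserved columns break blocks; block flanks
are trimmed to strictly conserved columns; blocks shorter than 10 columns
are dropped. The exact settings of the original web-based trimming tools
are unrecoverable, so all five parameters are exposed.

## Evolutionary trace

The reference tree is midpoint-rooted; internal nodes are ordered by edge
depth from the root (earliest-diverging first, ties by smallest contained
leaf name). The k-group partition is produced by k−1 binary splits in that
order, peeling multifurcations one child at a time so every step adds
exactly one group. A column's rank is the smallest k at which every group
is internally invariant; a gap counts as a distinct symbol that breaks
invariance (conservative for motif calling). Columns still variable at
`max_rank` (default: the leaf count) are reported unranked.

Class-specific columns are those invariant within each of the two top-level
groups but with different residues between them — the group-diagnostic
signal that separates Cys-based ATPase metal binding (CXXC/CPC) from
His-based MCO binding (HXH). Motif windows are located per group in the
concatenated consensus of that group's conserved columns (columns invariant
within the group, plus any column globally ranked ≤ `rank_cutoff`,
default 3); group-level invariance matters here because a class-specific
motif is by definition not conserved across the whole family. Because the
consensus skips gaps and non-conserved columns, a reported window can span
non-adjacent MSA columns; the per-window column list is reported so such
matches can be judged.

## Motif screening

Patterns are strings over the 20 amino acids plus X (pattern X matches any
residue; a query X never satisfies any position — conservative under
assembly ambiguity). The default set: CXXC and its HXXH variant
(N-terminal metal binding, optional), CPC and its accepted alternative YPC
(transmembrane metal binding, required for ATPases), GDGIN (ATP binding,
required for ATPases), HXH (MCO metal binding). The high-potential rule —
ATPase: (CPC or YPC) and GDGIN; MCO: ≥ 2 distinct HXH; unknown family:
never — is a declared reconstruction: no printed source fully specifies the
boolean rule, so it is configurable (`ScreenRules`) and every decision is
enumerated in the per-candidate rationale string. Screening runs on the
ungapped candidate; mapping to reference-alignment columns is provided as
annotation only.

## Synthetic benchmark

The generator emulates the study conditions rather than any particular real
metagenome:

* **Reference set** — two families (default 10 + 10 genes, 600–1200 nt).
  Each family descends from a random ancestor protein carrying its motifs
  at family-fixed sites; members substitute non-motif residues at 25%
  (≈ 75% within-family protein identity), and half the ATPase members have
  the CXXC site randomized, echoing real pumps. Proteins are
  reverse-translated with uniform synonymous codons; genes start with ATG
  and end with a stop.
* **Mutants** — substitution-only, frame-preserving mutation to a target
  nucleotide identity (± 1 point), with motif codons, start and stop exempt
  and no in-frame stop ever introduced, so planted genes remain intact ORFs
  with analyzable motif coordinates. Indels are deliberately excluded from
  the default model; they would decouple truth coordinates from recovered
  ORFs.
* **Contigs** — each planted gene is embedded at a uniform offset and
  uniform strand in an i.i.d. background at 62% GC (the composition of
  thermo/halophile-dominated communities); decoys are pure background,
  1500–3000 bp. No repeats, chimeras or coverage structure are modeled, so
  passing benchmarks demonstrates correctness of the method, not robustness
  to misassembly.
* **Evaluation** — a recovered gene is a true positive when it overlaps a
  truth interval on the same contig and strand with interval Jaccard ≥ 0.5;
  sensitivity = TP/planted, precision = TP/recovered, specificity =
  clean decoys/decoys, each carried with its numerator and denominator.
  An empty truth set leaves sensitivity undefined rather than zero.

Benchmark sizes used by the test suite and the acceptance script (20 genes
planted at 85% identity among 50 decoys; 4 unmutated members among 20
decoys for self-identification) keep a full run under a few seconds while
leaving dozens of independent planted/decoy trials per run.

## Numerical and degenerate-input choices

* Contigs shorter than the word size yield an empty hit list with a
  warning, not an error; an empty contig file runs the whole pipeline to a
  zero-count report.
* An empty reference database, duplicate record ids, or non-IUPAC
  characters are hard errors with the offending record named.
* E-values decrease strictly with raw score for fixed search space;
  overlapping hits to one reference merge only when they overlap on both
  query and subject on the same strand, keeping tandem copies separate.
* All randomness flows from explicit integer seeds (numpy Generators);
  reruns are byte-identical.

## Known limitations

* The aligner has no two-hit seeding, masking of low-complexity sequence,
  or translated search; very diverged homologs (< ~70% nucleotide
  identity) lose seeds and ungapped extensions fail first, which is the
  observed mechanism of the sensitivity fall-off at low planted identity.
* Frameshifted or pseudogenized genes spanning assembly errors are not
  recovered (no ORF will cover the hit).
* Progressive alignment without refinement can misplace highly diverged
  rows; the trimming and ET stages inherit any such error, as manual
  inspection did in the original analyses this design follows.
* The screen's boolean rules are a reconstruction; with other rule
  settings the high-potential count changes, which is why the rationale
  string records each rule's status per candidate.
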