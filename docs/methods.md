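# Methods

This note records the models, default parameters and design choices behind
`taarminer`, and what the synthetic benchmarks do and do not demonstrate.

## Translated homology search

Candidate loci are found by aligning bait proteins against the six-frame
translation of each contig. Instead of a seeded-heuristic BLAST
re-implementation, the scan uses exact amino-acid 5-mer seeding: seed
matches are clustered along the target, and only clustered windows (≥2
seeds) are scored by Smith–Waterman (BLOSUM62; affine gaps in the BLAST
convention, a gap of length k costs 11 + k). At the divergences the bait
sets are built for (baits ≥ ~60% identical to their targets), a true match
of ≥150 codons carries dozens of exact 5-mers, so seeding loses essentially
nothing while reducing the dynamic programming to candidate windows.
Alignment itself is delegated to Biopython's `PairwiseAligner` (C
implementation); the test suite checks it against an exhaustive pure-Python
affine-gap oracle.

Significance uses the Karlin–Altschul approximation E = K·m·n·e^(−λS) with
the ungapped BLOSUM62 parameters λ = 0.267, K = 0.041 applied to gapped
scores — a deliberate approximation, so absolute E-values differ from NCBI
BLAST. The filter criteria are relative and configurable; the default
cutoff is 10⁻⁵⁰ for both bait sets: a locus is retained iff its best
positive-bait E-value is at or below the cutoff and it has no negative-bait
match at or below the cutoff. Loci are built by merging same-strand hits
within 2,000 nt (bridging intron-scale gaps while staying below typical
intergene distances); for model building and bait adjudication each locus
is then split into per-gene hit groups at 800 nt, so a decoy gene within
2 kb of a real gene cannot veto it, and tandem genes each get a model.

## Gene-model reconstruction

Reconstruction works in a strand-local window of ±6 kb around each gene
group, with the intervals of *other* gene groups on the contig masked to N
so that exons cannot be borrowed from a neighbouring homolog. Three
interpretations compete on their alignment score against the best-matching
bait:

* **Contiguous ORF** — the longest ATG→stop ORF of 250–400 codons that
  covers ≥80% of the best hit and reaches both of its ends (within 30 nt).
* **Two-exon model** — exon 2 is anchored on the hit's reading frame
  (several anchor points along the hit, because a short in-frame intron can
  let one alignment bridge both exons); candidate acceptors are in-frame AG
  dinucleotides inside the stop-free extension, donors are GT dinucleotides
  a phase-0 codon boundary (20–120 codons, soft window 40–80) downstream of
  an ATG, with intron length 50–5,000 nt. Candidates are pre-ranked by
  exon-wise alignment scores penalised for unaligned residues, the best ~30
  fully scored, ties broken by shorter intron then smaller donor
  coordinate. A winning model must leave the bait alignment *colinear
  across the junction* (bait jump ≤3 residues, no gap run >6 anywhere): a
  genuine intron removes only non-coding sequence, whereas an "intron" that
  bridges a frameshift or skips an in-frame stop swallows ~17+ codons of
  coding sequence and fails the test.
* **Disruption chain** — bait alignments of all three frames, chained when
  genomically adjacent (frameshifted genes align each frame a little past
  the break, so chains tolerate overlap); frame changes between chained
  segments are frameshifts, '*' columns inside segments (≥15 columns from a
  segment edge) are in-frame stops.

A two-exon model wins if it beats the chain by ≥20 points (the score a real
intron recovers by removing its read-through penalty) and any contiguous
ORF by ≥15; a contiguous ORF wins if it matches the chain and covers ≥80%
of the bait *in the alignment* (protein length alone over-credits ORFs
extended by flanking sequence). Remaining loci are pseudogenes (disruptions
present, locus internal), edge genes (alignment reaching within 30 nt of a
contig boundary with the corresponding bait terminus uncovered — the margin
allows for local-alignment trimming of noisy terminal residues), or
fragments. Start-codon choice takes the first ATG of the stop-free segment
(maximising coverage without upstream stops); when an in-frame ATG directly
follows the true start the choice is genuinely ambiguous, which is why
recovery is scored on intron boundaries rather than the start coordinate.

Genes are named `<Sp>TAR<s|p|e|f>.<family><NNN>` (s = spliced, p =
pseudogene, e = edge, f = fragment; unsuffixed = intronless complete), with
three-digit serials per species in genomic order.

## Classification, orthologs, tree

Percent identity is computed from a global (Needleman–Wunsch) alignment
(BLOSUM62, gaps 10/1) as identical columns over mutually aligned (both
non-gap) columns — the closest convention to ClustalW-style percent
identity; the denominator choice matters only for gapped pairs. Families
are single-linkage connected components at ≥40% identity and subfamilies
the components at ≥60% within each family: single linkage is the
deterministic, permutation-invariant closure of reading related pairs off a
tree. Family letters are assigned by decreasing size (the largest family is
"A"); letters are presentation only — tests compare partitions. Partial
genes (pseudogenes, edges, fragments) inherit the family of their closest
complete relative when that identity clears the family threshold.

Ortholog groups are maximal cliques of size 2–3 at ≥99% identity; groups
spanning ≥2 species are orthologs, single-species groups paralogs; a
triplet's contained pairs are not double-reported. The guide tree is
neighbor joining (scikit-bio) on d = 1 − identity/100, with negative branch
estimates clamped to zero; on additive matrices NJ reproduces path
distances exactly, which the suite verifies against randomly generated
trees. Maximum-likelihood inference and bootstrap support are out of scope.

## dN/dS (modified Nei–Gojobori)

Synonymous sites per codon weight each alternative base by R (transition)
or 1 (transversion): s_pos = Σ w·syn / Σ w, so s + n = 3 per codon and
R = 1 is plain NG86. The default R is 1.0; `--tstv-weight` exposes it.
Mutations to stop codons count as nonsynonymous in site counting.
Differences are averaged over the 1, 2 or 6 mutational pathways between two
codons; pathways through stop codons are excluded with renormalisation by
default (configurable to `count`, under which a step into or out of a stop
is a nonsynonymous step). Codon pairs are aligned by back-threading the
protein-level global alignment; codons opposite a gap, containing N, or
terminal stops are dropped. Proportions pS = Sd/S and pN = Nd/N are
Jukes–Cantor corrected (domain guard p < 0.749999; saturated pairs are
flagged rather than raised). ω = dN/dS when dS > 0; dS = 0 with dN > 0 is
flagged unbounded and printed ">10"; such pairs never enter means. Family
summaries report mean/min/max of finite ω over all within-family pairs
(tree-adjacent-pairs selection is not implemented; with all pairs, deeply
diverged within-family pairs contribute saturated, flagged records that are
excluded from the means).

## Protein features

TM segments are maximal runs of ≥threshold windowed Kyte–Doolittle means
(window 19, threshold 1.5, runs merged across gaps <5 residues, trimmed to
a 17–35 residue band, flagged canonical at 21–28). These are soft
annotations, not an acceptance gate for real sequences. Sequons follow the
grammar N-[^P]-[S/T] only (no neural "potential" scoring); overlapping
sequons are reported. Conserved motifs are found on the repertoire
alignment as the top-k non-overlapping ungapped windows (widths 6–15) by
mean column information content, gap-penalised — deterministic, and
appropriate for motifs at fixed alignment positions; it is not an EM motif
finder for unaligned sequences. The repertoire alignment itself is a
reference-threaded stack: each protein is globally aligned to a
modal-length reference and threaded onto its columns (insertions relative
to the reference dropped) — adequate for colinear receptor homologs, not a
general MSA. Splice logos use a 9 nt donor window (last 3 exon + first 6
intron nt) and a 15 nt acceptor window (last 12 intron + first 3 exon nt);
information content is 2 − H bits per position.

## Synthetic study conditions

The generator plants, per species: 25 complete genes (19 spliced across
five spliced subfamilies, 6 intronless — ~76% spliced), 3 frameshift and 2
stop pseudogenes, 4 edge genes, 3 fragments, and 5 decoy GPCR genes, on
~33 contigs drawn lognormal (median 25 kb); four tail-to-head gene pairs
per species sit 1.2–6.1 kb apart on shared contigs. Two families are
planted (A: 5 subfamilies, ω = 0.4; B: 2 subfamilies, ω = 0.5).

All receptor genes descend from one ancestor with a seven-transmembrane
architecture (7 hydrophobic stretches of 21–28 codons, hydrophilic loops,
an N-terminal NGS sequon) and five frozen 6-codon motif blocks. Divergence
is a codon-level accept/reject walk: point mutations proposed uniformly
(transition:transversion weight configurable, default 1), stop-creating
proposals rejected, synonymous proposals accepted, nonsynonymous accepted
with probability ω — so the planted ω is measurable by the package's own
dN/dS engine, closing the verification loop. The identity ladder is
87% (gene vs subfamily ancestor), 78% (subfamily vs family ancestor) and
45% (family ancestor vs root), which realizes within-subfamily pairs at
~74–76%, cross-subfamily pairs at ~44–57% and cross-family pairs at ≤37% —
margins of several points around the 60/40 thresholds even for the extreme
pair among thousands, which single-linkage clustering is sensitive to.
Cross-family identity cannot go much lower: the shared architecture and the
family-wide frozen motifs place a floor near 30–35%.

Spliced genes carry one GT–AG intron (70–3,000 nt) after a subfamily-fixed
codon drawn near 55 (clipped normal, window 40–80). The junction dipeptide
is drawn per gene (FR 0.79, FK 0.14, YR 0.04, FE 0.03); the dominant FR is
also written into the subfamily ancestor and its baits, mirroring the
family-wide conservation of the aromatic–basic junction. Intron interiors
are random DNA with a donor-consensus head and pyrimidine-rich acceptor
tail, and with in-frame AG (acceptor side) or GT (donor side) within 6 nt
of the true sites rejected, so equal-scoring alternative splicings cannot
arise by construction. Ortholog plants copy a donor gene into 1–2 other
species at 99.4% (pairs) or 99.75% (triplet members) protein identity; the
triplet target is tight enough that every within-triplet pair stays above
the 99% threshold at any ancestor length in range. Pseudogene disruptions
(1–2 nt indels, or a sense→stop rewrite) are placed at codons 40..n−40 so
both flanks remain alignable; edge genes keep 50–70% of the CDS abutting a
contig end; fragments keep an interior 50–65%. With ω = 0 the protein
cannot change, so the divergence target switches to nucleotide identity
(purely synonymous evolution).

What passing these benchmarks shows: the search, splice, classification and
counting machinery is correct on sequences whose generative process matches
the model's assumptions (substitution-only divergence, canonical unique
splice sites, uniform base composition, no repeats or assembly gaps). What
it does not show: robustness to real-genome features the generator omits —
indel-rich divergence, non-canonical or ambiguous splice sites, repetitive
DNA, N-runs, sequencing error, or compositional heterogeneity. Thresholds
that are printed constants of the method (1e-50, 40/60/99%, phase-0 GT–AG)
are defaults, not claims of optimality for other gene families.

## Benchmark problem sizes

The default end-to-end benchmark mines 5 species × ~33 contigs (~5.5 Mb)
against 7 positive and 3 negative baits in a few minutes on one CPU. The ω
recovery experiment uses 300-codon ancestors, 5 descendants (10 pairs) per
replicate and 10 replicates per ω, with divergence scaled to ω (identity
targets 95/85/80% for ω = 0.1/0.5/1.0) so synonymous sites stay clear of
Jukes–Cantor saturation — at ω = 0.1 a lineage fixes roughly three
synonymous changes per nonsynonymous one, and deeper divergence would bias
ω low. NJ exactness uses 100 random additive matrices of 6–10 taxa; the
dN/dS engine is checked against an exhaustive-enumeration oracle on 200
random codon-sequence pairs.

## Known limitations

* At most one intron per model; genes with >1 intron would surface as
  fragments or atypical models.
* E-values are Karlin–Altschul approximations with ungapped parameters;
  only their ordering and the configurable cutoffs are meaningful.
* The stack alignment and IC motif finder assume colinear homologs; highly
  indel-divergent repertoires would need a true MSA upstream.
* Family letters and gene serials depend on repertoire composition; only
  partitions and boundaries are stable identifiers.
* dN/dS family means over *all* within-family pairs mix time scales;
  saturated pairs are excluded via the JC domain flag rather than modelled.
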