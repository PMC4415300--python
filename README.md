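# taarminer

Mining and characterisation of trace amine-associated receptor (TAAR) gene
repertoires from fragmented genome assemblies.

TAARs are class-A (rhodopsin-like) GPCRs expressed in the olfactory
epithelium; teleost genomes carry large, rapidly evolving TAAR repertoires,
and in several percomorph lineages most TAAR genes are split by a single
phase-0 intron near codon 55. Annotating such a family in a draft assembly
means solving several coupled problems: finding candidate loci by translated
homology search while excluding the far larger background of non-TAAR GPCRs,
reconstructing gene models across introns, telling pseudogenes and
contig-boundary truncations apart from intact genes, organising the
repertoire into families and subfamilies, and measuring the selective
pressure it evolves under. `taarminer` implements that pipeline as a tested,
reusable library with a command-line front end, and ships a synthetic-genome
generator with planted ground truth so every stage can be validated
end to end.

## What the pipeline does

1. **Translated search** (`translated_search`). Bait proteins — a positive
   set of TAARs and a negative set of non-TAAR class-A GPCRs — are aligned
   against all six reading frames of every contig (Smith–Waterman, BLOSUM62,
   affine gaps 11/1, located via exact 5-mer seeding). Significance uses the
   Karlin–Altschul approximation E = K·m·n·e^(−λS). A candidate locus is
   kept iff it matches the positive set at E ≤ 10⁻⁵⁰ and has no negative-set
   match at that cutoff.
2. **Gene models** (`gene_models`). Each locus becomes a single-exon
   ATG→stop model, a two-exon model with one canonical phase-0 GT–AG intron
   (donor searched near the family-typical position, codons 40–80), a
   pseudogene (frameshift and/or in-frame stop), an edge gene (alignment
   truncated at a contig boundary) or a fragment. Competing interpretations
   are adjudicated by their bait alignment score; a candidate intron must
   also leave the bait alignment colinear across the splice junction, which
   cleanly separates real introns from frameshift- or stop-skipping
   artefacts.
3. **Repertoire classification** (`repertoire_classify`). Pairwise global
   percent identity; families = single-linkage components at ≥40% identity,
   subfamilies at ≥60%; ortholog pairs/triplets = maximal cliques at ≥99%
   identity spanning ≥2 species; neighbor-joining tree on d = 1 − identity/100
   with Newick output.
4. **Selective pressure** (`evolution_dnds`). Pairwise dN/dS by the
   Nei–Gojobori counting method with Zhang's transition/transversion site
   weighting: each of a codon's nine single-base mutants is weighted R for a
   transition and 1 for a transversion when counting synonymous sites
   (R = 1 recovers plain NG86); observed differences are averaged over
   mutational pathways (stop-passing pathways excluded); proportions are
   Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3); ω = dN/dS, with
   unbounded ratios (dS = 0, dN > 0) reported as ">10".
5. **Protein features** (`protein_features`). Kyte–Doolittle hydropathy TM
   segmentation, N-glycosylation sequons (Asn-X-Ser/Thr, X ≠ Pro),
   maximum-information conserved motifs from the repertoire alignment, and
   donor/acceptor splice-site logos (position frequency matrices with
   per-position information content).
6. **Synthetic truth** (`synthetic_repertoire`). Deterministic generation of
   multi-species assemblies with planted single- and two-exon genes,
   pseudogenes, edge genes, fragments and decoy GPCRs, evolved from common
   ancestors by a codon-level accept/reject process whose nonsynonymous
   acceptance probability is the planted ω.

## Worked example

Simulate a five-species assembly and mine one species:

```bash
taar-miner simulate --seed 11 --out sim
taar-miner mine --assembly sim/Til_assembly.fasta \
    --pos-baits sim/baits_positive.fasta \
    --neg-baits sim/baits_negative.fasta --out mined
```

prints the per-species gene status tally:

```
species  complete_1exon  complete_2exon  pseudogene  edge  fragment  total
    Til               6              19           5     4         3     37
```

which here equals the planted composition exactly: 25 complete genes (19 of
them spliced — ~76%, as in percomorph TAAR repertoires), 5 pseudogenes,
4 edge genes and 3 fragments; the 5 planted decoy GPCR genes were rejected
by the negative bait filter. `mined/` contains the GFF3 gene models, complete
protein/CDS FASTA, the junction-dipeptide census, family×species table,
ortholog matrix, per-pair and per-family dN/dS tables, the NJ tree (Newick),
motif summaries and splice-site logo PFMs.

The dN/dS engine on the 4-codon pair `ATGTTTGTGCTG` / `ATGTTTGTACTG`
(one synonymous third-position difference) gives S = 8/3, N = 28/3, Sd = 1,
Nd = 0, pS = 0.375, dS = 0.5199, dN = 0, ω = 0:

```bash
taar-miner dnds --cds pair.fasta --out dnds.tsv
```

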