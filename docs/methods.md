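# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `oakdiff`. It is written for users who want to judge
what the package computes and what its tests do and do not demonstrate.

## The marker system

The panel covers four nuclear regions of the *Q. robur* reference genome
amplified with the published primer pairs, carrying six variants that
showed a 100% allele-frequency difference between a *Q. petraea* and a
*Q. robur* sequencing pool:

| region | method | loci | diagnostic behaviour |
|---|---|---|---|
| QP_miSeq14a | CAPS, MboI (^GATC) | SNP1 T→C, SNP2 C→T (2 bp apart) | petraea alleles create the MboI site: 187 bp uncut (robur) vs 80+107 |
| QP_miSeq32 | amplicon sizing | InDel −→GCTTC | 188 bp (robur, and Caucasus-origin petraea) vs 193 bp |
| QP_miSeq36 | CAPS, MseI (T^TAA) | SNP A→G (alleles typed as T/C in primer orientation) | robur T completes the MseI site: 86+83 vs 169 bp uncut |
| QP_miSeq38 | Sanger | SNP1 G→A, SNP2 A→C (30 bp apart) | read directly from base calls |

The QP_miSeq36 primers bind the reverse complement of the reference, so
marker-orientation alleles are the complement of the reference alleles;
the panel definition stores both and the conversion is explicit. The two
QP_miSeq14a SNPs fall in the coding sequence of a detoxification-56-like
gene on the minus strand; the codon spanning them is GCA (Ala) in robur
and ACG (Thr) in petraea, i.e. a missense exchange at protein position
125, which `insilico.coding_effect` reproduces by translating both CDS
alleles and reporting the first differing residue.

## In-silico genotyping operators

PCR is exact-match primer search on both strands; the product must be
unique or an error names the marker and the candidate count. No mismatch
tolerance is modelled: primers were validated by real PCR, and exactness
keeps the operators deterministic. Digestion cuts at every site occurrence
(MboI 5′ of GATC, MseI after the first T of TTAA, from a small built-in
catalogue); fragment lengths always sum to the amplicon length. Genotype
calling maps observations to unordered allele pairs: length multisets for
the InDel marker, fragment-pattern multisets for CAPS markers (the union
pattern of both alleles reads as a heterozygote; anything else yields a
missing call with a warning rather than a forced genotype), and IUPAC
ambiguity codes for Sanger mode. MNV-like adjacent SNPs are typed as two
separate columns, mirroring the published genotype table.

## The fixed-difference cascade

`pooldiff` merges the petraea pool's variants with robur evidence keyed by
(reference, position, ref allele, alt allele). Where the robur pool called
a variant at the position, the robur reference-allele frequency is
100 − Σ(alternative frequencies); otherwise a coverage-track depth > 0
counts as 100% reference and depth 0 as "no coverage". The cascade applies,
in order: alternative frequency = 100%, petraea coverage ≥ 13, removal of
zero-robur-coverage variants, then robur reference frequency = 100% jointly
with robur coverage ≥ 5, reporting counts after every stage. Frequencies
are compared exactly after rounding to one decimal (the precision of
caller tables): a fixed difference is a definition, not a tolerance band.
Coordinates are 1-based throughout; VCF anchor bases are stripped on read
to the dash convention ("−" → inserted sequence) and restored on write.
The published downstream attrition by primer design and BLAST specificity
is not a computation and is represented only by the declared marker panel.

## Assignment model

Scores use the Rannala–Mountain posterior-predictive genotype probability
with a symmetric Dirichlet prior of τ = 1/k per allele, where k counts the
distinct alleles at the locus across all reference panels and the query —
this choice (over Dirichlet(1), also available via `prior_style`) follows
the method's source and prevents zero-probability queries. Loci are
treated as unlinked and independent; missing loci are skipped in every
group symmetrically, and samples typed at fewer than `min_typed` loci
(default 4 of the 6) are rejected. Scores are computed in log space with
max-subtraction; exact ties are reported, never silently broken. The
hybrid group is an ordinary third reference panel with its own allele
counts — no explicit admixture model is fitted.

The exclusion probability is the Monte-Carlo tail probability that a
genotype simulated from the group is *strictly* more likely than the
query. Simulants draw two alleles per locus independently from the
posterior-mean frequencies (n_a + τ)/(n + 1) rather than resimulating
Dirichlet frequency vectors per draw; this is an approximation, documented
here because the reference implementation used for the original analysis
does not publish its exact algorithm, so printed exclusion values are not
expected to be matched digit for digit. The query's likelihood is computed
through the identical vectorized code path as the simulants' so that exact
ties are preserved (a monomorphic panel therefore gives exclusion 0). The
default is 10,000 simulations per (sample, group); the demo pipeline uses
2,000, which stabilizes the third decimal adequately for its purpose.
For panel-drawn queries the exclusion probability is approximately
Uniform(0,1) (probability-integral transform), which the test suite checks
by Kolmogorov–Smirnov on 250 seeded replicates.

## Synthetic data: what it emulates, what it does not

The generator's defaults are the study conditions: pool depths Poisson
around 29X (petraea) and 19X (robur) — the only depth information
available; panel sizes 39/45/20 with the InDel marker extended to 77/77 by
individuals typed only at that marker; and genotype-class percentages
equal to the published validation table. Integer counts are reconstructed
as the split whose rounded percentages match the printed values,
ambiguities resolved toward the larger homozygote class; two printed cells
(the three-class QP_miSeq36 columns) are not exactly realizable as integer
counts of 39 or 45 individuals, so reconstruction is accepted within one
percentage point. Genotype classes are assigned to individuals
independently per locus, because only marginal class frequencies are
published — real multilocus correlations (e.g. introgressed individuals
divergent at several markers at once) are therefore not reproduced.

Amplicon-internal layout is unpublished; the generator fixes the MboI site
at amplicon offsets 81–84 (fragments 80+107), the MseI site at 86–89
(fragments 86+83), the InDel at offset 100 and the Sanger SNPs at offsets
80/110, which satisfies every published fragment length, and records the
layout in a sidecar manifest. Filler sequence is seeded-random and redrawn
until no spurious primer match or enzyme site exists. Templates are plain
sequence: no read-level simulation, mapping or base-error model, so the
pipeline's variant tables are taken as given, exactly as the analysis
consumed caller output.

The hybrid reference panel defaults to 20 seeded F1 simulants (one allele
per locus from each species' posterior-mean frequencies), the conservative
reading of "first or next generation" hybrids; backcrosses can be
simulated and user panels substituted via CSV. Consequence worth knowing:
against an F1-only hybrid panel, a genotype homozygous for every
petraea-modal allele scores ≈ 0.9994 for the petraea group (the hybrid
panel concedes it ~6×10⁻⁴ of the likelihood); a hybrid panel containing
backcrosses, as the original reference set plausibly did, would push this
to ≥ 0.9995. The multilocus genotypes of the original 20 reference hybrids
are unpublished, so their per-sample assignment rows cannot be reproduced,
only the panel-level behaviour (all 20 simulated F1s return to the hybrid
group under leave-one-out self-assignment, which they do robustly).

The real discovery count chain (thousands of pool variants down to the
final panel) depends on the raw sequencing pools and is not reproducible
at desk scale; the cascade is instead validated by exact recovery of
planted truth: every planted diagnostic variant survives and every planted
background variant is removed at exactly its tagged stage.

## Numerical and reproducibility choices

All randomness flows from numpy `SeedSequence` spawning, so batch order
never changes per-sample results; identical seeds give byte-identical
output files, and the pipeline manifest records tool version, seed and a
SHA-256 of the configuration. Score tables round to 3 decimals (matching
the reported tables) while JSON output keeps full precision. Degenerate
inputs fail loudly with file/line context (malformed tables, duplicate
variant keys, empty panels, single-member panels under leave-one-out);
unrecognized genotyping patterns degrade to missing calls with warnings
instead of errors, since partial genotypes are routine in practice.
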