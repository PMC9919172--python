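# Six-locus diagnostic panel for Quercus robur / Q. petraea, four amplified regions.
#
# Schema (one record per region under `markers:`):
#   region              amplified-region name; locus ids derive from it
#   fwd_primer/rev_primer  primer sequences 5'->3' (exact-match search, both strands)
#   method              caps | fragment_size | sanger
#   enzyme              restriction enzyme for caps markers (catalogue in oakdiff.insilico)
#   reverse_to_reference   true when the primers bind the reverse complement of the
#                       reference genome; locus alleles below are then given in primer
#                       (marker) orientation, ref_allele/alt_allele in reference orientation
#   amplicon_len        per-species amplicon length in bp
#   fragments           per-species fragment sizes after digestion (caps) or sizing
#   cut_species         which species' allele carries the intact recognition site
#   loci                the individual variants typed from the amplicon:
#     id                locus (marker) identifier, one genotype column each
#     reference/position  1-based coordinate on the robur reference
#     vtype             SNV | InDel
#     ref_allele/alt_allele  reference-orientation alleles; "-" marks an insertion
#     offset            1-based position of the variant inside the robur amplicon,
#                       primer orientation (insertion: first inserted base)
#     robur_allele/petraea_allele  allele labels in marker orientation as genotyped
markers:
- region: QP_miSeq14a
  fwd_primer: TGTTGACCAAAATGGATAAGAATT
  rev_primer: GTTTGTCTGTCTTGAATGGCC
  method: caps
  enzyme: MboI
  reverse_to_reference: false
  amplicon_len: {robur: 187, petraea: 187}
  fragments: {robur: [187], petraea: [80, 107]}
  cut_species: petraea
  loci:
  - id: QP_miSeq14a_SNP1
    reference: Chr9
    position: 45479689
    vtype: SNV
    ref_allele: T
    alt_allele: C
    offset: 84
    robur_allele: T
    petraea_allele: C
  - id: QP_miSeq14a_SNP2
    reference: Chr9
    position: 45479691
    vtype: SNV
    ref_allele: C
    alt_allele: T
    offset: 86
    robur_allele: C
    petraea_allele: T
- region: QP_miSeq32
  fwd_primer: TGAGGGGAAATCACAATTATGTC
  rev_primer: TGATGTTCTGTTCTGATGAATGAC
  method: fragment_size
  enzyme: null
  reverse_to_reference: false
  amplicon_len: {robur: 188, petraea: 193}
  fragments: {robur: [188], petraea: [193]}
  cut_species: null
  loci:
  - id: QP_miSeq32_InDel
    reference: Chr7
    position: 38644432
    vtype: InDel
    ref_allele: "-"
    alt_allele: GCTTC
    offset: 100
    robur_allele: "188"
    petraea_allele: "193"
- region: QP_miSeq36
  fwd_primer: TCACTTGTTCTATTTGCAACATAT
  rev_primer: TATTCTGTGTCTGAGTAGGTGATAC
  method: caps
  enzyme: MseI
  reverse_to_reference: true
  amplicon_len: {robur: 169, petraea: 169}
  fragments: {robur: [86, 83], petraea: [169]}
  cut_species: robur
  loci:
  - id: QP_miSeq36_SNP
    reference: Chr2
    position: 31588494
    vtype: SNV
    ref_allele: A
    alt_allele: G
    offset: 86
    robur_allele: T
    petraea_allele: C
- region: QP_miSeq38
  fwd_primer: GTAAATGGTAATTGAAAAGGCAT
  rev_primer: CCTGAAACTCTTGTTCAGAAGAT
  method: sanger
  enzyme: null
  reverse_to_reference: false
  amplicon_len: {robur: 193, petraea: 193}
  fragments: {robur: [193], petraea: [193]}
  cut_species: null
  loci:
  - id: QP_miSeq38_SNP1
    reference: scaffold492
    position: 52257
    vtype: SNV
    ref_allele: G
    alt_allele: A
    offset: 80
    robur_allele: G
    petraea_allele: A
  - id: QP_miSeq38_SNP2
    reference: scaffold492
    position: 52287
    vtype: SNV
    ref_allele: A
    alt_allele: C
    offset: 110
    robur_allele: A
    petraea_allele: C
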