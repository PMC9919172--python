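"""In-silico PCR, restriction digestion and genotype calling.

These operators mirror the laboratory steps used to genotype the six-locus
oak panel: PCR with exact-matching primers (both strands), CAPS digestion
with MboI / MseI, InDel sizing on a capillary sequencer, and Sanger base
reading (IUPAC ambiguity codes as heterozygotes), plus translation of the
coding variant pair into its predicted amino-acid exchange.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .genotypes import Genotype, make_genotype
from .panel import MarkerDef

IUPAC_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition site and cut offset within it.

    ``cut_offset`` counts bases from the 5' start of the recognition site to
    the cut position on the top strand (MboI cuts ^GATC, MseI cuts T^TAA).
    """

    name: str
    site: str
    cut_offset: int


#: small built-in catalogue; extend by constructing Enzyme directly
ENZYMES = {
    "MboI": Enzyme("MboI", "GATC", 0),
    "MseI": Enzyme("MseI", "TTAA", 1),
}


class AmpliconError(ValueError):
    """Raised when in-silico PCR does not yield exactly one product."""


@dataclass(frozen=True)
class Amplicon:
    """A PCR product, reported with the forward primer at its 5' end."""

    marker_id: str
    sequence: str
    template_span: tuple[int, int]  # 1-based inclusive, template coordinates
    strand: str  # '+' if the forward primer matched the template as given

    @property
    def length(self) -> int:
        return len(self.sequence)


def _products_on_strand(template: str, fwd: str, rev_rc: str) -> list[tuple[int, int]]:
    """All (start, end) 0-based half-open products fwd...rev_rc on one strand."""
    products = []
    for m in re.finditer(f"(?={re.escape(fwd)})", template):
        start = m.start()
        for r in re.finditer(f"(?={re.escape(rev_rc)})", template):
            end = r.start() + len(rev_rc)
            if r.start() >= start + len(fwd):
                products.append((start, end))
    return products


def extract_amplicon(template: str, marker: MarkerDef) -> Amplicon:
    """In-silico PCR: locate the primer pair on either strand of *template*.

    Primers are matched exactly. The product includes both primer sequences.
    Exactly one candidate product (over both orientations) is required;
    otherwise an :class:`AmpliconError` names the marker and the count.
    """
    template = template.upper()
    fwd = marker.fwd_primer.upper()
    rev_rc = revcomp(marker.rev_primer.upper())

    n = len(template)
    plus = [(s, e, "+") for s, e in _products_on_strand(template, fwd, rev_rc)]
    minus = [
        (n - e, n - s, "-")
        for s, e in _products_on_strand(revcomp(template), fwd, rev_rc)
    ]
    candidates = plus + minus
    if len(candidates) != 1:
        raise AmpliconError(
            f"{marker.region}: expected exactly one amplification product, "
            f"found {len(candidates)}"
        )
    s, e, strand = candidates[0]
    seq = template[s:e] if strand == "+" else revcomp(template[s:e])
    return Amplicon(marker.region, seq, (s + 1, e), strand)


def apply_variant(sequence: str, offset: int, ref_allele: str, alt_allele: str) -> str:
    """Apply one variant at a 1-based *offset*.

    Substitutions replace in place (the sequence must carry ``ref_allele`` at
    the offset); insertions (``ref_allele == '-'``) insert ``alt_allele``
    beginning at the offset; deletions (``alt_allele == '-'``) remove
    ``ref_allele``.
    """
    if offset < 1 or offset > len(sequence) + (1 if ref_allele == "-" else 0):
        raise ValueError(f"offset {offset} outside sequence of length {len(sequence)}")
    i = offset - 1
    if ref_allele == "-":  # insertion
        return sequence[:i] + alt_allele + sequence[i:]
    observed = sequence[i : i + len(ref_allele)]
    if observed != ref_allele:
        raise ValueError(
            f"reference mismatch at offset {offset}: observed {observed!r}, "
            f"expected {ref_allele!r}"
        )
    insert = "" if alt_allele == "-" else alt_allele
    return sequence[:i] + insert + sequence[i + len(ref_allele) :]


def digest(sequence: str, enzyme: Enzyme) -> list[int]:
    """Cut *sequence* at every occurrence of the recognition site.

    Returns fragment lengths 5'->3'. With no site the whole length is a
    single fragment. Fragment lengths always sum to the input length.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    sequence = sequence.upper()
    cuts = [
        m.start() + enzyme.cut_offset
        for m in re.finditer(f"(?={enzyme.site})", sequence)
        if 0 < m.start() + enzyme.cut_offset < len(sequence)
    ]
    bounds = [0] + sorted(set(cuts)) + [len(sequence)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


# ---------------------------------------------------------------------------
# genotype calling


def _read_locus_from_amplicon(marker: MarkerDef, amplicon_seq: str, locus) -> str | None:
    """Allele label carried by one haplotype amplicon at *locus*."""
    if locus.vtype == "InDel":
        length = len(amplicon_seq)
        for species in ("robur", "petraea"):
            if length == marker.amplicon_len[species]:
                return locus.allele_for(species)
        return None
    base = amplicon_seq[locus.offset - 1]
    if base in (locus.robur_allele, locus.petraea_allele):
        return base
    return None


def call_from_haplotypes(
    marker: MarkerDef, hap1: str, hap2: str
) -> dict[str, Genotype | None]:
    """Genotype every locus of *marker* from two haplotype sequences."""
    out: dict[str, Genotype | None] = {}
    amps = []
    for hap in (hap1, hap2):
        try:
            amps.append(extract_amplicon(hap, marker).sequence)
        except AmpliconError:
            amps.append(None)
    for locus in marker.loci:
        alleles = []
        for amp in amps:
            if amp is None:
                alleles.append(None)
                continue
            seq = amp
            # SNP offsets shift when the haplotype carries the upstream insertion
            if locus.vtype == "SNV":
                shift = 0
                for other in marker.loci:
                    if other.vtype == "InDel" and other.offset <= locus.offset:
                        shift = len(seq) - marker.amplicon_len["robur"]
                seq = seq[shift:] if shift else seq
            alleles.append(_read_locus_from_amplicon(marker, seq, locus))
        if None in alleles:
            warnings.warn(
                f"{locus.locus_id}: haplotype not consistent with a defined allele; "
                "reporting missing genotype"
            )
            out[locus.locus_id] = None
        else:
            out[locus.locus_id] = make_genotype(alleles[0], alleles[1])
    return out


def call_from_fragments(
    marker: MarkerDef, lengths: list[int]
) -> dict[str, Genotype | None]:
    """Genotype from observed fragment lengths (InDel sizing or CAPS patterns).

    For fragment-size markers the observation is the multiset of amplicon
    lengths; for CAPS markers it is the multiset of restriction-fragment
    lengths from the pooled digestion (a partial pattern combining both
    alleles' fragments is read as a heterozygote). Patterns matching no
    defined allele yield a missing genotype with a warning.
    """
    observed = Counter(lengths)
    rob = Counter(marker.fragments["robur"])
    pet = Counter(marker.fragments["petraea"])
    if marker.method == "fragment_size":
        locus = marker.loci[0]
        labels = []
        for length in sorted(observed):
            for species in ("robur", "petraea"):
                if length == marker.amplicon_len[species]:
                    labels.append(locus.allele_for(species))
                    break
        uniq = sorted(set(labels))
        if len(uniq) == 1:
            return {locus.locus_id: make_genotype(uniq[0], uniq[0])}
        if len(uniq) == 2:
            return {locus.locus_id: make_genotype(uniq[0], uniq[1])}
    elif marker.method == "caps":
        locus = marker.site_locus
        hom_rob, hom_pet, het = rob, pet, rob | pet
        gt = None
        if observed in (hom_rob, hom_rob + hom_rob):
            gt = make_genotype(locus.robur_allele, locus.robur_allele)
        elif observed in (hom_pet, hom_pet + hom_pet):
            gt = make_genotype(locus.petraea_allele, locus.petraea_allele)
        elif set(observed) == set(het):
            gt = make_genotype(locus.robur_allele, locus.petraea_allele)
        if gt is not None:
            return {locus.locus_id: gt}
    else:
        raise ValueError(f"{marker.region}: fragment observation for a sanger marker")
    locus = marker.loci[0] if marker.method == "fragment_size" else marker.site_locus
    warnings.warn(
        f"{marker.region}: fragment pattern {sorted(lengths)} matches no defined "
        "allele combination; reporting missing genotype"
    )
    return {locus.locus_id: None}


def call_from_sanger(
    marker: MarkerDef, base_calls: dict[str, str]
) -> dict[str, Genotype | None]:
    """Genotype from Sanger base calls at the variant offsets.

    ``base_calls`` maps locus id to the called base; IUPAC two-base
    ambiguity codes are read as heterozygotes (Y -> C/T).
    """
    out: dict[str, Genotype | None] = {}
    for locus in marker.loci:
        call = base_calls.get(locus.locus_id)
        if call is None:
            out[locus.locus_id] = None
            continue
        call = call.upper()
        if call in IUPAC_HET:
            a, b = IUPAC_HET[call]
            out[locus.locus_id] = make_genotype(a, b)
        elif call in "ACGT":
            out[locus.locus_id] = make_genotype(call, call)
        else:
            warnings.warn(
                f"{locus.locus_id}: base call {call!r} not interpretable; missing"
            )
            out[locus.locus_id] = None
    return out


def call_locus(
    marker: MarkerDef, observed, mode: str
) -> dict[str, Genotype | None]:
    """Dispatch genotype calling by observation mode.

    mode 'haplotypes': ``observed = (hap1, hap2)`` template/amplicon sequences;
    mode 'fragments': ``observed`` is an iterable of fragment lengths;
    mode 'sanger': ``observed`` maps locus id -> called base (IUPAC allowed).
    """
    if mode == "haplotypes":
        return call_from_haplotypes(marker, *observed)
    if mode == "fragments":
        return call_from_fragments(marker, list(observed))
    if mode == "sanger":
        return call_from_sanger(marker, dict(observed))
    raise ValueError(f"unknown observation mode {mode!r}")


# ---------------------------------------------------------------------------
# coding effect


@dataclass(frozen=True)
class CodingEffect:
    gene: str
    protein_position: int
    ref_aa: str  # three-letter code
    alt_aa: str
    consequence: str  # missense | synonymous | other
    note: str = ""


def genomic_variants_to_cds(
    variants: list[tuple[int, str, str]],
    cds_span: tuple[int, int],
    strand: str,
) -> list[tuple[int, str, str]]:
    """Map genomic-fragment substitutions into CDS-relative coordinates.

    ``cds_span`` is the 1-based inclusive span of the CDS on the fragment;
    minus-strand CDSs get reverse-complemented alleles and mirrored offsets.
    """
    s, e = cds_span
    out = []
    for pos, ref, alt in variants:
        if not s <= pos <= e:
            raise ValueError(f"variant position {pos} outside CDS span {cds_span}")
        if strand == "+":
            out.append((pos - s + 1, ref, alt))
        elif strand == "-":
            out.append((e - pos + 1, revcomp(ref), revcomp(alt)))
        else:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return sorted(out)


def coding_effect(
    cds_sequence: str,
    variants: list[tuple[int, str, str]],
    protein_offset_base: int = 1,
    gene: str = "",
) -> CodingEffect:
    """Translate reference and variant CDS and report the first changed residue.

    *variants* are CDS-relative substitutions ``(offset, ref, alt)`` (1-based,
    CDS strand). ``protein_offset_base`` gives the protein position of the
    first supplied codon, so CDS fragments can be analysed. A premature stop
    introduced by the variants is reported with consequence ``other``.
    """
    cds_sequence = cds_sequence.upper()
    if len(cds_sequence) % 3:
        raise ValueError("CDS length must be divisible by 3")
    alt_seq = cds_sequence
    for off, ref, alt in variants:
        if len(ref) != len(alt):
            return CodingEffect(gene, protein_offset_base, "", "", "other",
                                "length-changing variant (frameshift not modelled)")
        alt_seq = apply_variant(alt_seq, off, ref, alt)
    prot_ref = str(Seq(cds_sequence).translate())
    prot_alt = str(Seq(alt_seq).translate())
    ref_stop = prot_ref.find("*")
    alt_stop = prot_alt.find("*")
    if alt_stop != -1 and (ref_stop == -1 or alt_stop < ref_stop):
        pos = protein_offset_base + alt_stop
        ref_aa = seq3(prot_ref[alt_stop]) if prot_ref[alt_stop] != "*" else "Ter"
        return CodingEffect(gene, pos, ref_aa, "Ter", "other", "premature stop codon")
    for i, (a, b) in enumerate(zip(prot_ref, prot_alt)):
        if a != b:
            return CodingEffect(
                gene, protein_offset_base + i, seq3(a), seq3(b), "missense"
            )
    return CodingEffect(gene, protein_offset_base, "", "", "synonymous")
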