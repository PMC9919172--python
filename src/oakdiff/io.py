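"""Readers and writers for the pipeline's file formats.

Variant tables travel in two dialects: a CLC-style CSV (columns Reference,
Position, Type, Reference allele, Allele, Count, Coverage, Frequency) and a
VCF v4.2 subset (INFO DP/AO/TYPE, one record per alternative allele). The
dialect is auto-detected from the header. Internally InDels use the dash
convention ("-" -> inserted sequence at the first inserted base); VCF
anchor bases are stripped on read and restored on write.

Lines starting with '#' at the top of CSV/TSV files carry provenance
(tool version, seed, config hash) and are skipped by every reader.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from . import __version__
from .pooldiff import PoolVariant

CLC_COLUMNS = [
    "Reference",
    "Position",
    "Type",
    "Reference allele",
    "Allele",
    "Count",
    "Coverage",
    "Frequency",
]

_CLC_TYPE_ALIASES = {"SNP": "SNV", "SNV": "SNV", "MNV": "MNV", "INDEL": "InDel",
                     "INSERTION": "InDel", "DELETION": "InDel"}


def provenance_lines(seed: int | None = None, config: Mapping | None = None) -> list[str]:
    lines = [f"oakdiff {__version__}"]
    if seed is not None:
        lines.append(f"seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()
        lines.append(f"config_sha256={digest}")
    return lines


# ---------------------------------------------------------------------------
# dialect detection and variant tables


def detect_dialect(path: str | Path) -> str:
    """'vcf' or 'clc_csv', decided from the first non-comment header line."""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("##fileformat=VCF"):
            return "vcf"
        while first.startswith("#"):
            first = fh.readline()
    if first.split(",")[0].strip() == "Reference":
        return "clc_csv"
    raise ValueError(
        f"{path}: line 1: header matches neither the VCF v4 subset nor the "
        "CLC-style CSV dialect"
    )


def _normalize_vcf_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str, str]:
    """Strip the VCF anchor base, returning (position, ref, alt, anchor).

    REF=A ALT=AGCTTC at p becomes the dash-style insertion '-'->GCTTC at p+1;
    REF=AG ALT=A the deletion G->'-' at p+1. Same-length alleles pass through.
    """
    if len(ref) == len(alt):
        return pos, ref, alt, "N"
    if ref[0] != alt[0]:
        raise ValueError(f"unsupported unanchored indel {ref}>{alt} at {pos}")
    if len(ref) == 1 and len(alt) > 1:  # insertion
        return pos + 1, "-", alt[1:], ref[0]
    if len(alt) == 1 and len(ref) > 1:  # deletion
        return pos + 1, ref[1:], "-", alt[0]
    raise ValueError(f"unsupported complex allele {ref}>{alt} at {pos}")


def _denormalize_to_vcf(v: PoolVariant) -> tuple[int, str, str]:
    """Restore the anchor-base convention for writing to VCF."""
    if v.ref_allele == "-":  # insertion
        return v.position - 1, v.anchor_base, v.anchor_base + v.alt_allele
    if v.alt_allele == "-":  # deletion
        return v.position - 1, v.anchor_base + v.ref_allele, v.anchor_base
    return v.position, v.ref_allele, v.alt_allele


def _vtype_of(ref: str, alt: str) -> str:
    if ref == "-" or alt == "-" or len(ref) != len(alt):
        return "InDel"
    return "SNV" if len(ref) == 1 else "MNV"


def read_variant_table(path: str | Path, dialect: str | None = None) -> list[PoolVariant]:
    """Read a pool variant table, auto-detecting the dialect by default."""
    if dialect is None:
        dialect = detect_dialect(path)
    if dialect == "clc_csv":
        return _read_clc_csv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown variant-table dialect {dialect!r}")


def _read_clc_csv(path: str | Path) -> list[PoolVariant]:
    variants = []
    with open(path, newline="") as fh:
        lineno = 0
        header: list[str] | None = None
        for row in csv.reader(fh):
            lineno += 1
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in row]
                missing = [c for c in CLC_COLUMNS[:7] if c not in header]
                if missing:
                    raise ValueError(
                        f"{path}: line {lineno}: missing columns {missing}"
                    )
                continue
            rec = dict(zip(header, row))
            try:
                vtype = _CLC_TYPE_ALIASES[rec["Type"].strip().upper()]
                count = int(rec["Count"])
                coverage = int(rec["Coverage"])
                freq = rec.get("Frequency", "").strip()
                alt_freq = (
                    float(freq) if freq else 100.0 * count / coverage
                )
                variants.append(
                    PoolVariant(
                        reference=rec["Reference"].strip(),
                        position=int(rec["Position"]),
                        vtype=vtype,
                        ref_allele=rec["Reference allele"].strip(),
                        alt_allele=rec["Allele"].strip(),
                        alt_count=count,
                        coverage=coverage,
                        alt_freq=alt_freq,
                    )
                )
            except (KeyError, ValueError, ZeroDivisionError) as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from err
    if header is None:
        raise ValueError(f"{path}: empty file without a header")
    return variants


def _read_vcf(path: str | Path) -> list[PoolVariant]:
    variants = []
    vcf = VCF(str(path))
    try:
        for record in vcf:
            depth = record.INFO.get("DP")
            ao = record.INFO.get("AO")
            alts = record.ALT
            if ao is None:
                ao_list = [None] * len(alts)
            elif isinstance(ao, (tuple, list)):
                ao_list = list(ao)
            else:
                ao_list = [ao]
            for alt, ao_i in zip(alts, ao_list):
                pos, ref, alt_n, anchor = _normalize_vcf_allele(
                    record.POS, record.REF, alt
                )
                coverage = int(depth) if depth is not None else 0
                count = int(ao_i) if ao_i is not None else coverage
                freq = 100.0 * count / coverage if coverage else 0.0
                variants.append(
                    PoolVariant(
                        reference=record.CHROM,
                        position=pos,
                        vtype=_vtype_of(ref, alt_n),
                        ref_allele=ref,
                        alt_allele=alt_n,
                        alt_count=count,
                        coverage=coverage,
                        alt_freq=freq,
                        anchor_base=anchor,
                    )
                )
    finally:
        vcf.close()
    return variants


def write_variant_table_csv(
    variants: Iterable[PoolVariant],
    path: str | Path,
    provenance: list[str] | None = None,
) -> None:
    with open(path, "w", newline="") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(CLC_COLUMNS)
        for v in variants:
            writer.writerow(
                [
                    v.reference,
                    v.position,
                    v.vtype,
                    v.ref_allele,
                    v.alt_allele,
                    v.alt_count,
                    v.coverage,
                    f"{v.alt_freq:.1f}",
                ]
            )


def write_variant_table_vcf(
    variants: Iterable[PoolVariant],
    path: str | Path,
    provenance: list[str] | None = None,
) -> None:
    variants = list(variants)
    contigs = sorted({v.reference for v in variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in provenance or []:
            fh.write(f"##oakdiff={line}\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Pool coverage">\n'
            '##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternative allele count">\n'
            '##INFO=<ID=TYPE,Number=A,Type=String,Description="Variant type">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.reference, v.position, v.alt_allele)):
            pos, ref, alt = _denormalize_to_vcf(v)
            info = f"DP={v.coverage};AO={v.alt_count};TYPE={v.vtype}"
            fh.write(f"{v.reference}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


# ---------------------------------------------------------------------------
# coverage track


def write_coverage_track(
    depths: Mapping[tuple[str, int], int],
    path: str | Path,
    provenance: list[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        fh.write("reference\tposition\tdepth\n")
        for (ref, pos), depth in sorted(depths.items()):
            fh.write(f"{ref}\t{pos}\t{depth}\n")


def read_coverage_track(path: str | Path) -> dict[tuple[str, int], int]:
    depths: dict[tuple[str, int], int] = {}
    with open(path) as fh:
        lineno = 0
        header_seen = False
        for line in fh:
            lineno += 1
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if not header_seen:
                if fields != ["reference", "position", "depth"]:
                    raise ValueError(
                        f"{path}: line {lineno}: expected header "
                        "'reference<TAB>position<TAB>depth'"
                    )
                header_seen = True
                continue
            try:
                depths[(fields[0], int(fields[1]))] = int(fields[2])
            except (IndexError, ValueError) as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from err
    return depths


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
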