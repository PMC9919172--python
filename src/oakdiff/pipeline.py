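"""End-to-end pipeline orchestration: simulate -> discover -> type -> assign.

Every stage is a pure function of (inputs, config, seed); re-runs with the
same seed produce byte-identical artifacts. Output files carry a provenance
header (tool version, seed, config hash) and a manifest lists every
artifact with its SHA-256 digest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .assign import (
    AssignmentConfig,
    assign_samples,
    results_table,
    summarize_panel,
)
from .genotypes import write_genotype_csv
from .insilico import call_from_haplotypes, extract_amplicon
from .panel import GROUP_HYBRID, GROUP_PETRAEA, GROUP_ROBUR, Panel, default_panel
from .pooldiff import FilterThresholds, apply_filter_cascade, merge_pools
from .simulate import (
    PanelConfig,
    build_haplotype,
    make_marker_templates,
    make_pool_variant_tables,
    make_reference_panels,
    simulate_hybrid,
    simulate_pure,
    templates_manifest,
)

log = logging.getLogger("oakdiff")


@dataclass
class RunConfig:
    seed: int = 1
    outdir: Path = Path("oakdiff_demo")
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    assignment: AssignmentConfig = field(default_factory=AssignmentConfig)
    panel_cfg: PanelConfig = field(default_factory=PanelConfig)
    n_diagnostic: int = 6
    n_background: int = 24
    n_queries_per_group: int = 3

    def to_dict(self) -> dict:
        # output location is not part of the scientific configuration
        d = asdict(self)
        d.pop("outdir")
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_demo(cfg: RunConfig, panel: Panel | None = None) -> dict:
    """Run the whole pipeline on simulated data; returns the manifest."""
    panel = panel or default_panel()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    prov = io.provenance_lines(cfg.seed, cfg.to_dict())
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    # --- simulate -----------------------------------------------------------
    templates = make_marker_templates(seeds[0], panel)
    io.write_fasta(
        [(t.fasta_id, t.sequence) for t in templates], out / "templates.fasta"
    )
    (out / "templates_manifest.json").write_text(
        json.dumps(
            {"provenance": prov, **templates_manifest(templates)}, indent=1
        )
    )
    pet_rows, rob_rows, coverage, truth = make_pool_variant_tables(
        seeds[1], cfg.n_diagnostic, cfg.n_background, panel=panel
    )
    io.write_variant_table_csv(pet_rows, out / "pet_variants.csv", prov)
    io.write_variant_table_vcf(pet_rows, out / "pet_variants.vcf", prov)
    io.write_variant_table_csv(rob_rows, out / "rob_variants.csv", prov)
    io.write_coverage_track(coverage, out / "rob_coverage.tsv", prov)
    (out / "truth.json").write_text(
        json.dumps(
            {
                "provenance": prov,
                "planted_diagnostic": sorted(map(list, truth.planted_diagnostic)),
                "planted_background": {
                    "|".join(map(str, k)): v
                    for k, v in sorted(truth.planted_background.items())
                },
            },
            indent=1,
        )
    )

    ref_panels = make_reference_panels(cfg.panel_cfg, panel)
    all_refs = [m for g in (GROUP_ROBUR, GROUP_PETRAEA, GROUP_HYBRID)
                for m in ref_panels[g].members]
    write_genotype_csv(all_refs, out / "references.csv", panel.locus_ids, prov)

    # query samples with haplotype sequences for the typing stage
    rng = np.random.default_rng(seeds[2])
    queries = []
    for i in range(cfg.n_queries_per_group):
        queries.append(
            simulate_pure(rng, ref_panels[GROUP_ROBUR],
                          f"QUERY_R{i + 1}", panel.locus_ids)
        )
        queries.append(
            simulate_pure(rng, ref_panels[GROUP_PETRAEA],
                          f"QUERY_P{i + 1}", panel.locus_ids)
        )
        queries.append(
            simulate_hybrid(
                rng, "F1", (ref_panels[GROUP_ROBUR], ref_panels[GROUP_PETRAEA]),
                sample_id=f"QUERY_H{i + 1}", loci=panel.locus_ids,
            )
        )
        queries[-1].group = "unknown"
    robur_amp = {
        t.marker_id: extract_amplicon(t.sequence, panel.region(t.marker_id)).sequence
        for t in templates
        if t.species_allele == "robur"
    }
    hap_records = []
    for q in queries:
        for marker in panel:
            phased: dict[int, dict[str, str]] = {0: {}, 1: {}}
            for locus in marker.loci:
                g = q.loci.get(locus.locus_id)
                if g is None:
                    continue
                order = [0, 1] if rng.random() < 0.5 else [1, 0]
                phased[order[0]][locus.locus_id] = g[0]
                phased[order[1]][locus.locus_id] = g[1]
            for hap in (0, 1):
                seq = build_haplotype(marker, robur_amp[marker.region], phased[hap])
                hap_records.append((f"{q.sample_id}|{marker.region}|hap{hap + 1}", seq))
    io.write_fasta(hap_records, out / "query_haplotypes.fasta")

    # --- discover -----------------------------------------------------------
    merged = merge_pools(pet_rows, rob_rows, coverage)
    survivors, report = apply_filter_cascade(merged, cfg.thresholds)
    log.info("cascade counts: %s", report.to_dict())
    io.write_variant_table_csv([m.pet for m in survivors], out / "survivors.csv", prov)
    io.write_variant_table_vcf([m.pet for m in survivors], out / "survivors.vcf", prov)
    (out / "cascade_report.json").write_text(
        json.dumps({"provenance": prov, **report.to_dict()}, indent=1)
    )

    # --- type ---------------------------------------------------------------
    typed = type_haplotype_fasta(out / "query_haplotypes.fasta", panel)
    write_genotype_csv(typed, out / "query_genotypes.csv", panel.locus_ids, prov)

    # --- summarize ----------------------------------------------------------
    frames = []
    for group in (GROUP_ROBUR, GROUP_PETRAEA, GROUP_HYBRID):
        df = summarize_panel(ref_panels[group])
        df.insert(0, "group", group)
        frames.append(df)
    with open(out / "panel_summary.tsv", "w") as fh:
        for line in prov:
            fh.write(f"# {line}\n")
        pd.concat(frames).to_csv(fh, sep="\t", index=False)

    # --- assign -------------------------------------------------------------
    results = assign_samples(typed, ref_panels, cfg.assignment)
    table = results_table(results, cfg.assignment)
    with open(out / "assignments.tsv", "w") as fh:
        for line in prov:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)
    (out / "assignments.json").write_text(
        json.dumps(
            {
                "provenance": prov,
                "results": [
                    {
                        "sample_id": r.sample_id,
                        "scores": r.scores,
                        "exclusion": r.exclusion,
                        "assigned": r.assigned,
                        "ties": r.ties,
                        "divergent": r.divergent,
                    }
                    for r in results
                ],
            },
            indent=1,
        )
    )

    manifest = {
        "tool": f"oakdiff {__version__}",
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "cascade": report.to_dict(),
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def type_haplotype_fasta(path: str | Path, panel: Panel | None = None):
    """In-silico typing of a haplotype FASTA (ids ``sample|region|hapN``)."""
    from .genotypes import MultilocusGenotype

    panel = panel or default_panel()
    haps: dict[tuple[str, str], list[str]] = {}
    order: list[str] = []
    for name, seq in io.read_fasta(path):
        try:
            sample, region, _ = name.split("|")
        except ValueError:
            raise ValueError(
                f"{path}: record {name!r} does not follow 'sample|region|hap'"
            ) from None
        haps.setdefault((sample, region), []).append(seq)
        if sample not in order:
            order.append(sample)
    samples = {s: MultilocusGenotype(s, "unknown", {}) for s in order}
    for (sample, region), seqs in haps.items():
        if len(seqs) != 2:
            raise ValueError(
                f"{path}: sample {sample} region {region}: expected 2 haplotypes, "
                f"got {len(seqs)}"
            )
        marker = panel.region(region)
        calls = call_from_haplotypes(marker, seqs[0], seqs[1])
        samples[sample].loci.update(calls)
    return [samples[s] for s in order]
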