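"""End-to-end orchestration: simulate -> demux -> align -> call -> cohort -> dmr.

One global seed deterministically derives per-stage seeds (stable string
hashing), so any stage can be reproduced in isolation.  The run manifest
records per-stage record counts and asserts each module's conservation
identity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import align as _align
from . import calling as _calling
from . import cohort as _cohort
from . import demux as _demux
from . import genome as _genome
from . import simulate as _sim


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2**31 from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    # inputs (empty -> simulate a fixture genome)
    fasta: str = ""
    whitelist_file: str = ""
    # simulation stage
    n_cells: int = 4
    reads_per_cell: int = 2000
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 60000})
    insert_window: tuple = (30, 200)
    conversion_failure: float = 0.004
    error_rate: float = 0.001
    spike_fraction: float = 0.05
    read_length: int = 150
    # demux / trim
    marker: str = _sim.DEFAULT_MARKER
    min_barcode_quality: float = 20.0
    min_retained_length: int = 20
    # alignment / calling
    max_mismatch: int = 2
    min_sites: int = 200_000
    # cohort
    window_bp: int = 200
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["insert_window"] = list(d["insert_window"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["insert_window"] = tuple(d["insert_window"])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the run-defining parameters; output paths excluded."""
        d = asdict(self)
        d.pop("out_dir")
        d["insert_window"] = list(d["insert_window"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on a (simulated or provided) pool; returns manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "stages": {}}

    if config.whitelist_file:
        wl_path = Path(config.whitelist_file)
        if not wl_path.exists():
            raise PipelineError(f"whitelist file {wl_path} not found")
        whitelist = [l.strip() for l in wl_path.read_text().splitlines() if l.strip()]
    else:
        whitelist = _sim.make_barcode_whitelist(
            config.n_cells, seed=stage_seed(config.seed, "barcodes"))

    if config.fasta:
        fa = Path(config.fasta)
        if not fa.exists():
            raise PipelineError(f"FASTA {fa} not found")
        genome = _genome.Genome.from_fasta(fa)
    else:
        genome = _sim.simulate_genome(config.chrom_lengths,
                                      seed=stage_seed(config.seed, "genome"))

    # --- reference model
    catalog = _genome.select_inserts(_genome.digest_mspi(genome),
                                     *config.insert_window)
    cpg_index = _genome.index_cpgs(genome)
    cgis = _genome.call_cgis(genome)

    # --- simulate
    archetype = _sim.MethylomeArchetype()
    profiles = [
        _sim.simulate_cell_methylome(
            cpg_index, cgis, archetype,
            seed=stage_seed(config.seed, f"methylome:{i}"),
            cell_id=f"cell{i}")
        for i in range(config.n_cells)
    ]
    pool_cfg = _sim.PoolConfig(
        barcodes=whitelist[:config.n_cells],
        conversion_failure=config.conversion_failure,
        error_rate=config.error_rate,
        read_length=config.read_length,
        insert_window=tuple(config.insert_window),
        reads_per_cell=config.reads_per_cell,
        spike_fraction=config.spike_fraction,
        marker=config.marker,
        seed=stage_seed(config.seed, "reads"),
    )
    control = _sim.lambda_like_control()
    pairs, truth = _sim.simulate_reads(profiles, catalog, pool_cfg,
                                       control_sequence=control)
    if len(truth) != len(pairs):
        raise PipelineError("simulate: truth rows != emitted pairs")
    manifest["stages"]["simulate"] = {"pairs": len(pairs),
                                      "truth_rows": len(truth)}

    # --- demux + trim
    dconf = _demux.DemuxConfig(whitelist=pool_cfg.barcodes,
                               marker=config.marker,
                               min_barcode_quality=config.min_barcode_quality,
                               min_retained_length=config.min_retained_length)
    by_cell, unassigned, report = _demux.demultiplex(pairs, dconf)
    if not report.conservation_holds():
        raise PipelineError("demux: conservation identity violated")
    clean = _demux.trim_reads(by_cell, dconf, report)
    n_clean = _demux.clean_read_count(report)
    manifest["stages"]["demux"] = {
        "total": report.total_pairs, "assigned": report.assigned_total,
        "unassigned": report.unassigned,
        "quality_filtered": report.quality_filtered, "clean": n_clean,
    }

    # --- align (genomic + spike fragments share the index)
    spike_cat = _genome.select_inserts(
        _genome.digest_mspi(_genome.Genome({"spike": control})),
        *config.insert_window)
    full_catalog = _genome.FragmentCatalog(catalog.fragments
                                           + spike_cat.fragments)
    index = _align.build_bs_index(full_catalog)
    aligned = _align.align_pool(clean, index, config.max_mismatch)
    n_unique = sum(1 for aps in aligned.values()
                   for ap in aps if ap.alignment.status == "unique")
    n_aligned_inputs = sum(len(v) for v in aligned.values())
    if n_aligned_inputs > n_clean:
        raise PipelineError("align: more alignments than clean pairs")
    manifest["stages"]["align"] = {
        "input_pairs": n_aligned_inputs, "unique": n_unique,
        "mapping_rate_clean": (n_unique / n_clean) if n_clean else None,
    }

    # --- call
    spike_index = _genome.index_cpgs(_genome.Genome({"spike": control}))
    merged_index = _merge_indices(cpg_index, spike_index)
    callsets = {}
    for barcode, aps in aligned.items():
        cs = _calling.pileup_calls(aps, full_catalog, merged_index,
                                   cell_id=barcode)
        callsets[barcode] = cs
    merged = _cohort.merge_callsets(list(callsets.values()))
    conv = _calling.estimate_conversion_rate(merged, spike_chroms={"spike"})
    genomic = _restrict(merged, exclude={"spike"})
    levels = _calling.context_levels(genomic)
    manifest["stages"]["call"] = {
        "cells": len(callsets),
        "conversion_rate": conv,
        "context_levels": levels,
        "sites_merged": genomic.n_sites(),
    }

    # --- cohort summary
    window = _cohort.window_methylation(
        [_restrict(cs, exclude={"spike"}) for cs in callsets.values()],
        config.window_bp, genome.lengths)
    manifest["stages"]["cohort"] = {"windows": int(window.shape[1])}

    config.to_yaml(out / "run_config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["_runtime"] = {
        "truth": truth, "callsets": callsets, "merged": merged,
        "genome": genome, "catalog": catalog, "cpg_index": cpg_index,
        "aligned": aligned, "clean": clean, "report": report,
        "profiles": profiles, "window": window,
    }
    return manifest


def _merge_indices(a: _genome.CpGSiteIndex, b: _genome.CpGSiteIndex
                   ) -> _genome.CpGSiteIndex:
    sites = {**a.sites, **b.sites}
    plus = {**a._plus, **b._plus}
    minus = {**a._minus, **b._minus}
    return _genome.CpGSiteIndex(sites, plus, minus)


def _restrict(cs: _calling.MethylationCallSet, exclude: set[str]
              ) -> _calling.MethylationCallSet:
    out = _calling.MethylationCallSet(cs.cell_id)
    out.cpg = {k: list(v) for k, v in cs.cpg.items() if k[0] not in exclude}
    out.noncpg = {k: list(v) for k, v in cs.noncpg.items()
                  if k[0] not in exclude}
    return out


def make_fixture(profile: str = "tiny", seed: int = 0, out_dir=None) -> dict:
    """Bundled synthetic dataset: genome, TSS table, whitelist, pool, truth.

    tiny: 1 x 40-kb chromosome, 4 cells x 300 pairs (sub-minute end to end).
    small: 2 chromosomes, 8 cells x 1500 pairs.
    """
    sizes = {
        "tiny": ({"chr1": 40000}, 4, 300),
        "small": ({"chr1": 60000, "chr2": 40000}, 8, 1500),
    }
    if profile not in sizes:
        raise ValueError(f"unknown fixture profile {profile!r}")
    chrom_lengths, n_cells, rpc = sizes[profile]
    genome = _sim.simulate_genome(chrom_lengths,
                                  seed=stage_seed(seed, "genome"))
    whitelist = _sim.make_barcode_whitelist(n_cells,
                                            seed=stage_seed(seed, "barcodes"))
    cpg_index = _genome.index_cpgs(genome)
    cgis = _genome.call_cgis(genome)
    archetype = _sim.MethylomeArchetype()
    profiles = [_sim.simulate_cell_methylome(
        cpg_index, cgis, archetype, seed=stage_seed(seed, f"methylome:{i}"),
        cell_id=f"cell{i}") for i in range(n_cells)]
    catalog = _genome.select_inserts(_genome.digest_mspi(genome), 30, 200)
    cfg = _sim.PoolConfig(barcodes=whitelist, reads_per_cell=rpc,
                          seed=stage_seed(seed, "reads"))
    control = _sim.lambda_like_control()
    pairs, truth = _sim.simulate_reads(profiles, catalog, cfg,
                                       control_sequence=control)
    # simple TSS table: one plus- and one minus-strand gene per chromosome
    rng_positions = [(c, L // 3, "+", f"{c}_geneA")
                     for c, L in chrom_lengths.items()]
    rng_positions += [(c, 2 * L // 3, "-", f"{c}_geneB")
                      for c, L in chrom_lengths.items()]
    bundle = {
        "genome": genome, "whitelist": whitelist, "profiles": profiles,
        "catalog": catalog, "cpg_index": cpg_index, "cgis": cgis,
        "config": cfg, "pairs": pairs, "truth": truth,
        "tss": rng_positions, "control": control,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genome.to_fasta(out / "genome.fa")
        _genome.Genome({"spike": control}).to_fasta(out / "control.fa")
        (out / "whitelist.txt").write_text("\n".join(whitelist) + "\n")
        _genome.write_tss_table(rng_positions, out / "tss.tsv")
        _sim.write_fastq_pair(pairs, out / "pool")
        _sim.write_truth(truth, out / "truth.tsv")
    return bundle
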