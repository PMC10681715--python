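"""The inverse pipeline: demultiplex -> trim -> align -> call -> QC.

Round-trips a simulated pool: exact-match barcode splitting with the Q20
barcode filter, structural trimming, three-letter alignment into fragment
space, destranded CpG calling, and the spike-in conversion-rate estimate.
"""

import msrrbs as M
from msrrbs.genome import FragmentCatalog, Genome, digest_mspi, index_cpgs, select_inserts
from msrrbs.pipeline import _merge_indices, _restrict

genome = M.simulate_genome({"chr1": 40000}, seed=4)
catalog = select_inserts(digest_mspi(genome), 30, 200)
idx = index_cpgs(genome)
cgis = M.call_cgis(genome)
whitelist = M.make_barcode_whitelist(4, seed=4)
archetype = M.MethylomeArchetype()
profiles = [M.simulate_cell_methylome(idx, cgis, archetype, seed=20 + i,
                                      cell_id=f"cell{i}") for i in range(4)]
config = M.PoolConfig(barcodes=whitelist, reads_per_cell=2000, seed=5)
control = M.lambda_like_control()
pairs, truth = M.simulate_reads(profiles, catalog, config,
                                control_sequence=control)

dconf = M.DemuxConfig(whitelist=whitelist)
by_cell, unassigned, report = M.demultiplex(pairs, dconf)
clean = M.trim_reads(by_cell, dconf, report)
print(f"demux: {report.assigned_total}/{report.total_pairs} assigned, "
      f"{report.unassigned} unassigned, {report.quality_filtered} Q-filtered "
      f"(conservation holds: {report.conservation_holds()})")

spike_cat = select_inserts(digest_mspi(Genome({'spike': control})), 30, 200)
full_cat = FragmentCatalog(catalog.fragments + spike_cat.fragments)
aligned = M.align_pool(clean, M.build_bs_index(full_cat))
n_clean = M.clean_read_count(report)
n_unique = sum(ap.alignment.status == "unique"
               for aps in aligned.values() for ap in aps)
print(f"alignment: {n_unique}/{n_clean} unique "
      f"(mapping rate {n_unique / n_clean:.3f} of clean pairs)")

merged_idx = _merge_indices(idx, index_cpgs(Genome({'spike': control})))
callsets = [M.pileup_calls(aps, full_cat, merged_idx, cell_id=bc)
            for bc, aps in aligned.items()]
merged = M.merge_callsets(callsets)
conv = M.estimate_conversion_rate(merged, spike_chroms={"spike"})
levels = M.context_levels(_restrict(merged, exclude={"spike"}))
print(f"conversion rate from spike-in: {100 * conv:.2f}% "
      f"(simulated failure {config.conversion_failure})")
print(f"context levels: CpG {levels['CpG']:.3f}, "
      f"CHG {100 * levels['CHG']:.2f}%, CHH {100 * levels['CHH']:.2f}%")
# CHG/CHH should sit near the conversion-failure rate (0.4%): non-CpG
# cytosines are unmethylated, so any retained C there is a conversion failure.
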