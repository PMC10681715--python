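"""In-silico MspI digestion and genomic-element derivation.

Builds a small synthetic genome with planted CpG islands, digests it at CCGG,
size-selects the 30-200 bp library window, and derives CGIs (GC >= 50%,
length >= 200 bp, observed/expected CpG > 0.6), their 2-kb shores/shelves and
TSS-anchored promoters.
"""

import msrrbs as M
from msrrbs.genome import derive_promoters, derive_shores_shelves, digest_mspi, select_inserts

genome = M.simulate_genome({"chr1": 60000}, seed=1)
catalog = digest_mspi(genome)
inserts = select_inserts(catalog, 30, 200)
cgis = M.call_cgis(genome)
shores, shelves = derive_shores_shelves(cgis, genome)
promoters = derive_promoters([("chr1", 20000, "+", "geneA"),
                              ("chr1", 45000, "-", "geneB")], genome, cgis=cgis)

print(f"MspI fragments: {len(catalog)} total, "
      f"{len(inserts)} inside the 30-200 bp library window")
print(f"CpG islands called: {len(cgis)} "
      f"(planted: 3); shores: {len(shores)}, shelves: {len(shelves)}")
for iv in cgis:
    print(f"  CGI {iv.chrom}:{iv.start}-{iv.end} ({iv.end - iv.start} bp)")
print(f"promoters: {len(promoters)}; contains-CGI flags: "
      f"{[a['contains_cgi'] for a in promoters.attrs]}")
# The fragment count tells you how much of the genome the size-selected RRBS
# library can ever see; the CGI calls should recover the planted islands.
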