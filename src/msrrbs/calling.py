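"""Per-cell methylation calling, conversion-rate estimation and QC.

Calls are made from uniquely aligned pairs.  On OT molecules a read C over a
reference C is a methylated observation and a read T an unmethylated one; OB
molecules report the bottom-strand cytosine under the plus-strand G.  CpG
observations from the two strands are merged (destranded) onto the plus-
strand C of the CG dinucleotide, following the CGmap convention; non-CpG
cytosine observations accumulate into per-chromosome CHG/CHH totals used for
conversion QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .align import AlignedPair
from .genome import CpGSiteIndex, FragmentCatalog, revcomp


@dataclass
class MethylationCallSet:
    """Per-cell (methylated, unmethylated) counts.

    ``cpg``   : (chrom, plus-strand C position) -> [meth, unmeth]
    ``noncpg``: (chrom, context in {CHG, CHH}) -> [meth, unmeth]
    """

    cell_id: str
    cpg: dict[tuple[str, int], list[int]] = field(default_factory=dict)
    noncpg: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    def n_sites(self) -> int:
        return len(self.cpg)

    def add(self, key, meth: bool, table: str = "cpg"):
        d = self.cpg if table == "cpg" else self.noncpg
        rec = d.setdefault(key, [0, 0])
        rec[0 if meth else 1] += 1

    def level(self, key) -> float:
        m, u = self.cpg[key]
        return m / (m + u)

    def site_table(self) -> pd.DataFrame:
        rows = [{"chrom": c, "pos": p, "meth": v[0], "unmeth": v[1],
                 "level": v[0] / (v[0] + v[1])}
                for (c, p), v in sorted(self.cpg.items())]
        return pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth",
                                           "level"])


@dataclass
class CellQC:
    cell_id: str
    detected_sites: int
    mean_coverage: float
    conversion_rate: float | None
    passed: bool


def pileup_calls(aligned: list[AlignedPair], catalog: FragmentCatalog,
                 cpg_index: CpGSiteIndex, cell_id: str = "cell",
                 destrand: bool = True, collapse_duplicates: bool = False
                 ) -> MethylationCallSet:
    """Accumulate methylation observations from unique alignments.

    Each pair contributes one observation per covered cytosine; in the mate
    overlap region the observation is counted once and only if the two mates
    agree on the base (disagreements, i.e. sequencing errors, are dropped).
    With
    ``destrand=False`` bottom-strand CpG observations stay at the G position
    with their strand recorded via separate keys (chrom, pos) on the minus
    strand being encoded as (chrom, -pos-1).
    """
    frag_by_id = catalog.by_id()
    cs = MethylationCallSet(cell_id)
    seen: set[tuple] = set()
    for ap in aligned:
        a = ap.alignment
        if a.status != "unique":
            continue
        if a.fragment_id not in frag_by_id:
            raise KeyError(f"alignment references unknown fragment {a.fragment_id}")
        if collapse_duplicates:
            key = (a.fragment_id, a.strand, a.offset,
                   len(ap.pair.seq1), len(ap.pair.seq2))
            if key in seen:
                continue
            seen.add(key)
        frag = frag_by_id[a.fragment_id]
        frame_len = len(frag)
        r1, r2 = ap.pair.seq1, revcomp(ap.pair.seq2)
        chrom, start = frag.interval.chrom, frag.interval.start
        # molecule-frame base calls: read 1 covers [o, o+L1), read 2 the tail
        # one observation per covered position; where both mates cover a
        # position they must agree, otherwise the observation is discarded
        # (suppresses sequencing-error miscalls in the overlap region)
        covered: dict[int, str] = {}
        conflicts: set[int] = set()
        for i, b in enumerate(r2):
            q = frame_len - len(r2) + i
            if 0 <= q < frame_len:
                covered[q] = b
        for i, b in enumerate(r1):
            q = a.offset + i
            if 0 <= q < frame_len:
                if q in covered and covered[q] != b:
                    conflicts.add(q)
                covered[q] = b
        for q in conflicts:
            del covered[q]
        frame_seq = frag.sequence if a.strand == "OT" else revcomp(frag.sequence)
        for q, read_base in covered.items():
            if frame_seq[q] != "C" or read_base not in "CT":
                continue
            meth = read_base == "C"
            if a.strand == "OT":
                p = start + q
                ctx = cpg_index.context(chrom, p, "+")
                if ctx == "CpG":
                    cs.add((chrom, p), meth)
                elif ctx is not None:
                    cs.add((chrom, ctx), meth, table="noncpg")
            else:
                p = start + (frame_len - 1 - q)   # plus-strand G position
                ctx = cpg_index.context(chrom, p, "-")
                if ctx == "CpG":
                    key = (chrom, p - 1) if destrand else (chrom, -p - 1)
                    cs.add(key, meth)
                elif ctx is not None:
                    cs.add((chrom, ctx), meth, table="noncpg")
    return cs


def estimate_conversion_rate(callset: MethylationCallSet,
                             spike_chroms: set[str] | None = None
                             ) -> float | None:
    """converted / (converted + retained) over all cytosine observations.

    Intended for call sets (or chromosome subsets) of the fully unmethylated
    control, where every context is informative.
    """
    conv = ret = 0
    for (chrom, pos), (m, u) in callset.cpg.items():
        if spike_chroms is None or chrom in spike_chroms:
            ret += m
            conv += u
    for (chrom, _ctx), (m, u) in callset.noncpg.items():
        if spike_chroms is None or chrom in spike_chroms:
            ret += m
            conv += u
    if conv + ret == 0:
        warnings.warn("no spike-in cytosine observations; conversion rate missing")
        return None
    return conv / (conv + ret)


def context_levels(callset: MethylationCallSet
                   ) -> dict[str, float | None]:
    """Aggregate CpG / CHG / CHH methylation levels (count-weighted)."""
    out: dict[str, float | None] = {}
    m = sum(v[0] for v in callset.cpg.values())
    t = sum(v[0] + v[1] for v in callset.cpg.values())
    out["CpG"] = m / t if t else None
    for ctx in ("CHG", "CHH"):
        m = sum(v[0] for (c, x), v in callset.noncpg.items() if x == ctx)
        t = sum(v[0] + v[1] for (c, x), v in callset.noncpg.items() if x == ctx)
        out[ctx] = m / t if t else None
    return out


def cell_qc(callset: MethylationCallSet, min_sites: int = 200_000,
            conversion_rate: float | None = None) -> CellQC:
    """Pass iff detected CpG sites >= min_sites (inclusive)."""
    n = callset.n_sites()
    cov = (np.mean([v[0] + v[1] for v in callset.cpg.values()])
           if n else 0.0)
    return CellQC(callset.cell_id, n, float(cov), conversion_rate,
                  passed=n >= min_sites)


# ---------------------------------------------------------------------------
# CGmap-style / bedGraph text output
# ---------------------------------------------------------------------------

def write_cgmap(callset: MethylationCallSet, path) -> None:
    """CGmap-style TSV: chrom, nuc, 1-based pos, context, dinuc, level, meth, total."""
    if not callset.cpg:
        raise ValueError("cannot write an empty call set")
    with open(path, "w") as fh:
        for (chrom, pos), (m, u) in sorted(callset.cpg.items()):
            total = m + u
            fh.write(f"{chrom}\tC\t{pos + 1}\tCG\tCG\t"
                     f"{m / total:.6g}\t{m}\t{total}\n")


def read_cgmap(path, cell_id: str = "cell") -> MethylationCallSet:
    cs = MethylationCallSet(cell_id)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 8:
                raise ValueError(f"{path}:{ln}: expected 8 CGmap columns")
            chrom, _nuc, pos1, _ctx, _dinuc, _lvl, m, total = parts
            m, total = int(m), int(total)
            cs.cpg[(chrom, int(pos1) - 1)] = [m, total - m]
    return cs


def write_bedgraph(callset: MethylationCallSet, path) -> None:
    """0-based half-open bedGraph of methylation level x 100."""
    if not callset.cpg:
        raise ValueError("cannot write an empty call set")
    with open(path, "w") as fh:
        for (chrom, pos), (m, u) in sorted(callset.cpg.items()):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{100 * m / (m + u):.4g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "level_pct"])


def write_qc_table(qcs: list[CellQC], path) -> None:
    rows = [{"cell_id": q.cell_id, "detected_sites": q.detected_sites,
             "mean_coverage": q.mean_coverage,
             "conversion_rate": q.conversion_rate, "passed": q.passed}
            for q in qcs]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
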