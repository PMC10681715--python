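"""Differential methylation: per-CpG tests and region construction.

Single-cell mode compares per-cell methylation levels at each CpG between
two groups with a Mann-Whitney U test (exact enumeration for small samples,
tie-corrected normal approximation otherwise).  Significant same-direction
sites are chained into differentially methylated regions under the stated
criteria: p < 0.05, >= 3 member CpGs, member gap < 100 bp, span >= 50 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats

from .genome import ElementSet, Interval

EXACT_MAX_N = 20


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks with ties (1-based)."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


@lru_cache(maxsize=32)
def _combo_matrix(total: int, n: int) -> np.ndarray:
    """All C(total, n) index subsets of size n, as an array of rows."""
    return np.array(list(combinations(range(total), n)), dtype=np.intp)


def exact_mwu_pvalue(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of group assignments.

    Enumerates all C(n+m, n) ways of assigning the pooled (midranked) values
    to group A and counts assignments whose U deviates from the null mean
    n*m/2 at least as much as the observed one.  Exact under ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    base = n * (n + 1) / 2
    u_obs = ranks[:n].sum() - base
    center = n * m / 2
    dev = abs(u_obs - center)
    combos = _combo_matrix(n + m, n)
    u_all = ranks[combos].sum(axis=1) - base
    return float(np.mean(np.abs(u_all - center) >= dev - 1e-9))


def mwu_pvalue(x, y) -> float:
    """Exact enumeration for n+m <= 20, else tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) + len(y) <= EXACT_MAX_N:
        return exact_mwu_pvalue(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return float(res.pvalue)


@dataclass
class DMCRecord:
    chrom: str
    pos: int
    levels_a: np.ndarray
    levels_b: np.ndarray
    p_value: float
    difference: float  # mean(A) - mean(B), in [-1, 1]


@dataclass
class DMR:
    interval: Interval
    sites: list[int]
    mean_difference: float
    direction: str      # hyper (A above B) / hypo
    summary_p: float


@dataclass
class DMRSet:
    regions: list[DMR]

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


def test_dmc(chrom: str, pos: int, levels_a, levels_b, mode: str = "mwu",
             min_cells: int = 3) -> DMCRecord | None:
    """Per-site two-group test; None when too few covered cells (mwu mode).

    mwu: per-cell methylation levels, Mann-Whitney U.
    fisher: pooled (meth, unmeth) counts per group, Fisher's exact test;
    ``levels_a``/``levels_b`` are then (meth, unmeth) tuples.
    """
    if mode == "mwu":
        a = np.asarray(levels_a, dtype=float)
        b = np.asarray(levels_b, dtype=float)
        if len(a) < min_cells or len(b) < min_cells:
            return None
        p = mwu_pvalue(a, b)
        diff = float(a.mean() - b.mean())
        return DMCRecord(chrom, pos, a, b, p, diff)
    if mode == "fisher":
        (ma, ua), (mb, ub) = levels_a, levels_b
        _, p = stats.fisher_exact([[ma, ua], [mb, ub]])
        la = ma / (ma + ua) if ma + ua else 0.0
        lb = mb / (mb + ub) if mb + ub else 0.0
        return DMCRecord(chrom, pos, np.array([la]), np.array([lb]),
                         float(p), la - lb)
    raise ValueError(f"unknown mode {mode!r}")


def test_dmcs_between_groups(group_a, group_b, mode: str = "mwu",
                             min_cells: int = 3, min_cov: int = 1
                             ) -> list[DMCRecord]:
    """All-site DMC scan between two lists of MethylationCallSets."""
    records: list[DMCRecord] = []
    keys = set()
    for cs in group_a + group_b:
        keys.update(cs.cpg.keys())
    for chrom, pos in sorted(keys):
        ca = [cs.cpg[(chrom, pos)] for cs in group_a if (chrom, pos) in cs.cpg]
        cb = [cs.cpg[(chrom, pos)] for cs in group_b if (chrom, pos) in cs.cpg]
        ca = [(m, u) for m, u in ca if m + u >= min_cov]
        cb = [(m, u) for m, u in cb if m + u >= min_cov]
        if mode == "fisher":
            if not ca or not cb:
                continue
            pooled_a = (sum(m for m, _ in ca), sum(u for _, u in ca))
            pooled_b = (sum(m for m, _ in cb), sum(u for _, u in cb))
            records.append(test_dmc(chrom, pos, pooled_a, pooled_b,
                                    mode="fisher"))
            continue
        la = [m / (m + u) for m, u in ca]
        lb = [m / (m + u) for m, u in cb]
        rec = test_dmc(chrom, pos, la, lb, mode="mwu", min_cells=min_cells)
        if rec is not None:
            records.append(rec)
    return records


def call_dmrs(records: list[DMCRecord], p_threshold: float = 0.05,
              min_cpg: int = 3, merge_gap: int = 100, min_len: int = 50
              ) -> DMRSet:
    """Chain significant same-direction DMCs into regions.

    Consecutive significant sites closer than ``merge_gap`` bp with the same
    direction extend a chain; a direction flip or a gap >= merge_gap starts a
    new one.  A chain becomes a DMR iff it has >= min_cpg sites and spans
    >= min_len bp (first to last member C, inclusive).
    """
    sig = [r for r in records if r.p_value < p_threshold and r.difference != 0]
    sig.sort(key=lambda r: (r.chrom, r.pos))
    regions: list[DMR] = []
    chain: list[DMCRecord] = []

    def flush():
        if len(chain) >= min_cpg:
            span = chain[-1].pos - chain[0].pos + 1
            if span >= min_len:
                diffs = [r.difference for r in chain]
                regions.append(DMR(
                    interval=Interval(chain[0].chrom, chain[0].pos,
                                      chain[-1].pos + 1),
                    sites=[r.pos for r in chain],
                    mean_difference=float(np.mean(diffs)),
                    direction="hyper" if np.mean(diffs) > 0 else "hypo",
                    summary_p=float(np.median([r.p_value for r in chain])),
                ))
        chain.clear()

    for rec in sig:
        if chain:
            prev = chain[-1]
            same_chrom = rec.chrom == prev.chrom
            close = same_chrom and (rec.pos - prev.pos) < merge_gap
            same_dir = (rec.difference > 0) == (prev.difference > 0)
            if not (close and same_dir):
                flush()
        chain.append(rec)
    flush()
    return DMRSet(regions)


def annotate_dmrs(dmrs: DMRSet, element_sets: dict[str, ElementSet]
                  ) -> list[dict]:
    """Per DMR, all element kinds overlapping by >= 1 bp; else 'intergenic'."""
    table = []
    for dmr in dmrs:
        kinds = [kind for kind, es in element_sets.items()
                 if any(dmr.interval.overlaps(iv) for iv in es)]
        table.append({
            "chrom": dmr.interval.chrom,
            "start": dmr.interval.start,
            "end": dmr.interval.end,
            "n_cpg": len(dmr.sites),
            "direction": dmr.direction,
            "summary_p": dmr.summary_p,
            "mean_difference": dmr.mean_difference,
            "annotation": ",".join(sorted(kinds)) if kinds else "intergenic",
        })
    return table


def write_dmr_bed(dmrs: DMRSet, path) -> None:
    """BED6+: name = direction, score = -10*log10(summary p)."""
    with open(path, "w") as fh:
        for d in dmrs:
            score = 0 if d.summary_p <= 0 else min(1000, round(
                -10 * math.log10(max(d.summary_p, 1e-100))))
            fh.write(f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}"
                     f"\t{d.direction}\t{score}\t.\t{len(d.sites)}"
                     f"\t{d.mean_difference:.4f}\n")
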