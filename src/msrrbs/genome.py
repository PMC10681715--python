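"""Reference model: sequences, in-silico MspI digestion, CpG indexing and genomic elements.

RRBS enriches CpG-dense regions because MspI cuts at CCGG (C^CGG), which is
strongly over-represented in CpG islands.  Everything downstream of the
simulator and mapper lives in the coordinate system defined here: 0-based,
half-open intervals on the plus strand (BED convention); 1-based positions
appear only in CGmap-style text output.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ELEMENT_KINDS = {
    "CGI", "shore", "shelf", "promoter", "gene", "exon",
    "transcript", "CTCF", "enhancer", "window", "fragment",
}


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


class Genome:
    """Uppercase DNA sequences keyed by chromosome name."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"chromosome {name} has invalid bases {bad}")
            self.sequences[name] = seq

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def fetch(self, iv: Interval) -> str:
        return self.sequences[iv.chrom][iv.start:iv.end]

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
        if not seqs:
            raise ValueError(f"no FASTA records in {path}")
        return cls(seqs)

    def to_fasta(self, path, width: int = 80) -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


@dataclass
class ElementSet:
    """Typed, sorted, coordinate-deduplicated genomic intervals.

    ``attrs`` carries optional per-interval metadata (e.g. gene ids or the
    promoter contains-CGI flag) aligned with ``intervals``.
    """

    kind: str
    intervals: list[Interval]
    source: str = "derived"
    attrs: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.attrs and len(self.attrs) != len(self.intervals):
            raise ValueError("attrs length must match intervals")
        order = sorted(range(len(self.intervals)),
                       key=lambda i: (self.intervals[i].chrom,
                                      self.intervals[i].start,
                                      self.intervals[i].end))
        self.intervals = [self.intervals[i] for i in order]
        if self.attrs:
            self.attrs = [self.attrs[i] for i in order]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass(frozen=True)
class Fragment:
    id: str
    interval: Interval
    sequence: str
    has_n: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FragmentCatalog:
    """The in-silico MspI fragment universe of a genome.

    Before size selection the fragments of each chromosome tile it without
    gaps or overlaps; every internal boundary falls immediately after the
    first C of a CCGG site.
    """

    fragments: list[Fragment]
    digest_enzyme: str = "MspI"

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def by_id(self) -> dict[str, Fragment]:
        return {f.id: f for f in self.fragments}

    def lengths(self) -> np.ndarray:
        return np.array([len(f) for f in self.fragments], dtype=int)


CONTEXTS = ("CpG", "CHG", "CHH")


class CpGSiteIndex:
    """Plus-strand CpG positions and cytosine context on both strands.

    ``sites[chrom]`` holds sorted 0-based positions p with genome[p:p+2]=="CG".
    ``context(chrom, pos, strand)`` returns CpG/CHG/CHH for a cytosine at
    ``pos`` on the given strand ('-' means the base at pos is a G on the plus
    strand, i.e. a C on the bottom strand).  Cytosines truncated by a
    chromosome edge fall through to CHH.
    """

    def __init__(self, sites: dict[str, np.ndarray],
                 plus_ctx: dict[str, dict[int, str]],
                 minus_ctx: dict[str, dict[int, str]]):
        self.sites = sites
        self._plus = plus_ctx
        self._minus = minus_ctx

    def context(self, chrom: str, pos: int, strand: str) -> str | None:
        table = self._plus if strand == "+" else self._minus
        return table.get(chrom, {}).get(pos)

    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())

    def site_keys(self):
        for chrom in self.sites:
            for pos in self.sites[chrom]:
                yield chrom, int(pos)


def index_cpgs(genome: Genome) -> CpGSiteIndex:
    sites: dict[str, np.ndarray] = {}
    plus_ctx: dict[str, dict[int, str]] = {}
    minus_ctx: dict[str, dict[int, str]] = {}
    for chrom, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        is_c = arr == b"C"
        is_g = arr == b"G"
        n = len(arr)
        cg = np.zeros(n, dtype=bool)
        if n >= 2:
            cg[:-1] = is_c[:-1] & is_g[1:]
        sites[chrom] = np.flatnonzero(cg).astype(int)

        # plus-strand cytosine contexts: C followed by next two plus bases
        pc: dict[int, str] = {}
        for p in np.flatnonzero(is_c):
            p = int(p)
            if p + 1 < n and is_g[p + 1]:
                pc[p] = "CpG"
            elif p + 2 < n and is_g[p + 2]:
                pc[p] = "CHG"
            else:
                pc[p] = "CHH"
        plus_ctx[chrom] = pc

        # bottom-strand cytosines sit under plus-strand Gs; their 3' neighbours
        # are the complements of the preceding plus-strand bases
        mc: dict[int, str] = {}
        for p in np.flatnonzero(is_g):
            p = int(p)
            if p - 1 >= 0 and is_c[p - 1]:
                mc[p] = "CpG"
            elif p - 2 >= 0 and is_c[p - 2]:
                mc[p] = "CHG"
            else:
                mc[p] = "CHH"
        minus_ctx[chrom] = mc
    return CpGSiteIndex(sites, plus_ctx, minus_ctx)


# ---------------------------------------------------------------------------
# MspI digestion and size selection
# ---------------------------------------------------------------------------

_CCGG = re.compile(r"(?=CCGG)")


def digest_mspi(genome: Genome) -> FragmentCatalog:
    """Cut every chromosome at CCGG (between the first C and CGG).

    Fragments tile each chromosome exactly; fragments containing N are kept
    but flagged.
    """
    fragments: list[Fragment] = []
    for chrom, seq in genome.sequences.items():
        if not seq:
            warnings.warn(f"empty chromosome {chrom} skipped")
            continue
        cuts = [m.start() + 1 for m in _CCGG.finditer(seq)]
        bounds = [0] + cuts + [len(seq)]
        for i, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
            if s == e:
                continue
            frag_seq = seq[s:e]
            fragments.append(Fragment(
                id=f"{chrom}:{s}-{e}",
                interval=Interval(chrom, s, e),
                sequence=frag_seq,
                has_n="N" in frag_seq,
            ))
    return FragmentCatalog(fragments)


def select_inserts(catalog: FragmentCatalog, min_len: int, max_len: int) -> FragmentCatalog:
    """Keep fragments with min_len <= length <= max_len (library size selection)."""
    if not (0 < min_len <= max_len):
        raise ValueError(f"invalid size window [{min_len}, {max_len}]")
    kept = [f for f in catalog.fragments if min_len <= len(f) <= max_len]
    return FragmentCatalog(kept, catalog.digest_enzyme)


# ---------------------------------------------------------------------------
# interval-set arithmetic (plus-strand, per chromosome)
# ---------------------------------------------------------------------------

def _merge_pairs(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(pairs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract_pairs(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """a minus b; both lists of merged (start, end) pairs."""
    out: list[tuple[int, int]] = []
    b = _merge_pairs(b)
    for s, e in _merge_pairs(a):
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _by_chrom(intervals) -> dict[str, list[tuple[int, int]]]:
    d: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        d.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return d


# ---------------------------------------------------------------------------
# CpG islands, shores, shelves, promoters
# ---------------------------------------------------------------------------

def _cgi_stats(c_cum, g_cum, cg_cum, start, end):
    length = end - start
    n_c = c_cum[end] - c_cum[start]
    n_g = g_cum[end] - g_cum[start]
    n_cg = cg_cum[min(end - 1, len(cg_cum) - 1)] - cg_cum[start]
    gc = (n_c + n_g) / length
    expected = n_c * n_g / length
    oe = n_cg / expected if expected > 0 else 0.0
    return gc, oe


def call_cgis(genome: Genome, min_len: int = 200, min_gc: float = 0.50,
              min_oe: float = 0.6) -> ElementSet:
    """Sliding-window CpG-island caller.

    A 200-bp window (step 1) qualifies when GC fraction >= min_gc and the
    observed/expected CpG ratio exceeds min_oe, with expected = (#C * #G) /
    length.  Overlapping qualifying windows are merged and the merged region
    re-validated against all three criteria, trimming one base at a time from
    the worse-scoring end when validation fails.  N counts as neither C nor G.
    """
    if min_len < 1 or not (0 < min_gc <= 1) or not (0 < min_oe):
        raise ValueError("invalid CGI thresholds")
    results: list[Interval] = []
    win = min_len
    for chrom, seq in genome.sequences.items():
        n = len(seq)
        if n < win:
            continue
        arr = np.frombuffer(seq.encode(), dtype="S1")
        is_c = (arr == b"C").astype(np.int64)
        is_g = (arr == b"G").astype(np.int64)
        is_cg = np.zeros(n, dtype=np.int64)
        is_cg[:-1] = is_c[:-1] & is_g[1:]
        c_cum = np.concatenate(([0], np.cumsum(is_c)))
        g_cum = np.concatenate(([0], np.cumsum(is_g)))
        cg_cum = np.concatenate(([0], np.cumsum(is_cg)))

        starts = np.arange(0, n - win + 1)
        n_c = c_cum[starts + win] - c_cum[starts]
        n_g = g_cum[starts + win] - g_cum[starts]
        # CG dinucleotides fully inside the window: C positions in [s, s+win-1)
        n_cg = cg_cum[starts + win - 1] - cg_cum[starts]
        gc_ok = (n_c + n_g) / win >= min_gc
        expected = n_c * n_g / win
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(expected > 0, n_cg / np.where(expected > 0, expected, 1), 0.0)
        ok = gc_ok & (oe > min_oe)
        qual = np.flatnonzero(ok)
        if qual.size == 0:
            continue
        # merge overlapping qualifying windows into candidate regions
        regions = _merge_pairs([(int(s), int(s) + win) for s in qual])
        for s, e in regions:
            s, e = _trim_validate(c_cum, g_cum, cg_cum, s, e, win, min_gc, min_oe)
            if s is not None:
                results.append(Interval(chrom, s, e))
    return dedupe_elements(ElementSet("CGI", results, source="derived"))


def _trim_validate(c_cum, g_cum, cg_cum, s, e, min_len, min_gc, min_oe,
                   max_iter: int = 10000):
    """Greedy 1-bp end trimming until the region meets all three criteria."""
    for _ in range(max_iter):
        if e - s < min_len:
            return None, None
        gc, oe = _cgi_stats(c_cum, g_cum, cg_cum, s, e)
        if gc >= min_gc and oe > min_oe:
            return s, e
        gc_l, oe_l = _cgi_stats(c_cum, g_cum, cg_cum, s + 1, e)
        gc_r, oe_r = _cgi_stats(c_cum, g_cum, cg_cum, s, e - 1)
        # drop the end whose removal yields the better combined score
        if (gc_l - min_gc) + (oe_l - min_oe) >= (gc_r - min_gc) + (oe_r - min_oe):
            s += 1
        else:
            e -= 1
    return None, None


def derive_shores_shelves(cgis: ElementSet, genome: Genome) -> tuple[ElementSet, ElementSet]:
    """2-kb shores flanking CGIs and the next 2-kb shelves outward.

    Per-base precedence CGI > shore > shelf falls out of set arithmetic:
    shores = union(CGI +/- 2kb) - union(CGI), shelves = union(CGI +/- 4kb)
    minus both.  Clipped to chromosome bounds.
    """
    if cgis.kind != "CGI":
        raise ValueError("derive_shores_shelves expects a CGI ElementSet")
    lengths = genome.lengths
    shores: list[Interval] = []
    shelves: list[Interval] = []
    for chrom, pairs in _by_chrom(cgis).items():
        L = lengths[chrom]
        cgi_u = _merge_pairs(pairs)
        exp2 = _merge_pairs([(max(0, s - 2000), min(L, e + 2000)) for s, e in pairs])
        exp4 = _merge_pairs([(max(0, s - 4000), min(L, e + 4000)) for s, e in pairs])
        for s, e in _subtract_pairs(exp2, cgi_u):
            shores.append(Interval(chrom, s, e))
        for s, e in _subtract_pairs(exp4, exp2):
            shelves.append(Interval(chrom, s, e))
    return (ElementSet("shore", shores), ElementSet("shelf", shelves))


def derive_promoters(tss_table, genome: Genome, cgis: ElementSet | None = None,
                     upstream: int = 1500, downstream: int = 500) -> ElementSet:
    """Strand-aware TSS-1500/+500 promoters, clipped and coordinate-deduped.

    When a CGI set is given, each promoter gets a ``contains_cgi`` attribute
    (any overlap) rather than being filtered on it.
    """
    lengths = genome.lengths
    intervals: list[Interval] = []
    attrs: list[dict] = []
    cgi_pairs = {c: _merge_pairs(p) for c, p in _by_chrom(cgis).items()} if cgis else {}
    for chrom, tss, strand, gene_id in tss_table:
        if chrom not in lengths:
            warnings.warn(f"promoter TSS on unknown chromosome {chrom} skipped")
            continue
        L = lengths[chrom]
        if strand == "+":
            s, e = tss - upstream, tss + downstream
        else:
            s, e = tss - downstream, tss + upstream
        s, e = max(0, s), min(L, e)
        if s >= e:
            continue
        contains = any(bs < e and s < be for bs, be in cgi_pairs.get(chrom, []))
        intervals.append(Interval(chrom, s, e, strand))
        attrs.append({"gene_id": gene_id, "contains_cgi": contains})
    return dedupe_elements(ElementSet("promoter", intervals, attrs=attrs))


def dedupe_elements(elements: ElementSet) -> ElementSet:
    """Keep one interval per distinct (chrom, start, end), ignoring strand."""
    seen: set[tuple[str, int, int]] = set()
    intervals: list[Interval] = []
    attrs: list[dict] = []
    for i, iv in enumerate(elements.intervals):
        key = (iv.chrom, iv.start, iv.end)
        if key in seen:
            continue
        seen.add(key)
        intervals.append(iv)
        if elements.attrs:
            attrs.append(elements.attrs[i])
    return ElementSet(elements.kind, intervals, elements.source, attrs)


# ---------------------------------------------------------------------------
# text IO: BED6 and TSS tables
# ---------------------------------------------------------------------------

def write_bed(elements: ElementSet, path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(elements.intervals):
            name = elements.attrs[i].get("gene_id", elements.kind) if elements.attrs \
                else elements.kind
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path, kind: str) -> ElementSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    intervals = []
    for _, row in df.iterrows():
        strand = str(row[5]) if len(row) > 5 and str(row[5]) in "+-" else "."
        intervals.append(Interval(str(row[0]), int(row[1]), int(row[2]), strand))
    return ElementSet(kind, intervals, source="loaded")


def read_tss_table(path) -> list[tuple[str, int, str, str]]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "strand", "gene_id"], comment="#")
    return [(str(r.chrom), int(r.pos), str(r.strand), str(r.gene_id))
            for r in df.itertuples()]


def write_tss_table(rows, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, strand, gene_id in rows:
            fh.write(f"{chrom}\t{pos}\t{strand}\t{gene_id}\n")
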