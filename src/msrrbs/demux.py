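"""Barcode demultiplexing and structural trimming of msRRBS read pairs.

Both mates start with [4-bp marker][6-bp barcode].  Assignment requires an
exact whitelist match of the barcode on both mates (no mismatches); a pair
whose barcode bases average below Q20 on either mate is removed outright.
Trimming removes the 10 leading structural bases and any 3' read-through of
the far adapter (reverse complement of barcode+marker, then the sequencing
adapter stub).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genome import revcomp
from .simulate import ADAPTER_STUB, DEFAULT_MARKER, ReadPair

STRUCT_LEN = 10  # marker (4) + barcode (6)


@dataclass
class DemuxConfig:
    whitelist: list[str]
    marker: str = DEFAULT_MARKER          # fixed-marker mode; None -> any4 mode
    min_barcode_quality: float = 20.0
    min_retained_length: int = 20
    adapter_stub: str = ADAPTER_STUB
    readthrough_mismatches: int = 1

    def __post_init__(self):
        if len(set(self.whitelist)) != len(self.whitelist):
            raise ValueError("whitelist barcodes must be distinct")
        if any(len(b) != 6 for b in self.whitelist):
            raise ValueError("whitelist barcodes must be 6 bp")


@dataclass
class DemuxReport:
    total_pairs: int = 0
    unassigned: int = 0
    quality_filtered: int = 0
    assigned: dict[str, int] = field(default_factory=dict)       # barcode -> pairs
    dropped_short: dict[str, int] = field(default_factory=dict)  # after trimming
    trimmed_bases: dict[str, int] = field(default_factory=dict)

    @property
    def assigned_total(self) -> int:
        return sum(self.assigned.values())

    def conservation_holds(self) -> bool:
        return (self.assigned_total + self.unassigned + self.quality_filtered
                == self.total_pairs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "total_pairs": self.total_pairs,
                "unassigned": self.unassigned,
                "quality_filtered": self.quality_filtered,
                "assigned": self.assigned,
                "dropped_short": self.dropped_short,
                "trimmed_bases": self.trimmed_bases,
            }, fh, indent=2)


def _mean_phred(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual)


def demultiplex(pairs, config: DemuxConfig
                ) -> tuple[dict[str, list[ReadPair]], list[ReadPair], DemuxReport]:
    """Split a pooled stream of read pairs by cell barcode.

    Returns (per-barcode pairs, unassigned pairs, report).  The accounting
    identity assigned + unassigned + quality_filtered == total holds exactly.
    """
    report = DemuxReport(assigned={b: 0 for b in config.whitelist},
                         dropped_short={b: 0 for b in config.whitelist},
                         trimmed_bases={b: 0 for b in config.whitelist})
    by_cell: dict[str, list[ReadPair]] = {b: [] for b in config.whitelist}
    unassigned: list[ReadPair] = []
    wl = set(config.whitelist)
    for pair in pairs:
        report.total_pairs += 1
        if len(pair.seq1) < STRUCT_LEN or len(pair.seq2) < STRUCT_LEN:
            unassigned.append(pair)
            report.unassigned += 1
            continue
        if (_mean_phred(pair.qual1[4:10]) < config.min_barcode_quality
                or _mean_phred(pair.qual2[4:10]) < config.min_barcode_quality):
            report.quality_filtered += 1
            continue
        if config.marker is not None and (pair.seq1[:4] != config.marker
                                          or pair.seq2[:4] != config.marker):
            unassigned.append(pair)
            report.unassigned += 1
            continue
        bc1, bc2 = pair.seq1[4:10], pair.seq2[4:10]
        if bc1 != bc2 or bc1 not in wl:
            unassigned.append(pair)
            report.unassigned += 1
            continue
        by_cell[bc1].append(pair)
        report.assigned[bc1] += 1
    return by_cell, unassigned, report


def _find_readthrough(seq: str, pattern: str, max_mm: int, min_overlap: int = 3
                      ) -> int | None:
    """Leftmost start of a (possibly end-overhanging) occurrence of pattern."""
    n, m = len(seq), len(pattern)
    for pos in range(n):
        ov = min(m, n - pos)
        if ov < min_overlap:
            break
        allowed = max_mm if ov >= 6 else 0
        mm = 0
        for a, b in zip(seq[pos:pos + ov], pattern[:ov]):
            if a != b:
                mm += 1
                if mm > allowed:
                    break
        else:
            return pos
    return None


def trim_pair(pair: ReadPair, barcode: str, config: DemuxConfig
              ) -> tuple[ReadPair | None, int]:
    """Remove structural bases; returns (clean pair or None, bases trimmed)."""
    rt = revcomp(barcode + config.marker) if config.marker else None
    out_seqs = []
    trimmed = 0
    for seq, qual in ((pair.seq1, pair.qual1), (pair.seq2, pair.qual2)):
        s, q = seq[STRUCT_LEN:], qual[STRUCT_LEN:]
        cut = len(s)
        for pat in filter(None, (rt, config.adapter_stub)):
            pos = _find_readthrough(s, pat, config.readthrough_mismatches)
            if pos is not None and pos < cut:
                cut = pos
        trimmed += STRUCT_LEN + (len(s) - cut)
        out_seqs.append((s[:cut], q[:cut]))
    (s1, q1), (s2, q2) = out_seqs
    if len(s1) < config.min_retained_length or len(s2) < config.min_retained_length:
        return None, trimmed
    return ReadPair(pair.read_id, s1, q1, s2, q2), trimmed


def trim_reads(by_cell: dict[str, list[ReadPair]], config: DemuxConfig,
               report: DemuxReport | None = None
               ) -> dict[str, list[ReadPair]]:
    """Trim all assigned pairs; drops pairs shorter than the retained minimum."""
    clean: dict[str, list[ReadPair]] = {}
    for barcode, pairs in by_cell.items():
        kept = []
        for pair in pairs:
            trimmed_pair, n_bases = trim_pair(pair, barcode, config)
            if report is not None:
                report.trimmed_bases[barcode] = (
                    report.trimmed_bases.get(barcode, 0) + n_bases)
            if trimmed_pair is None:
                if report is not None:
                    report.dropped_short[barcode] = (
                        report.dropped_short.get(barcode, 0) + 1)
                continue
            kept.append(trimmed_pair)
        clean[barcode] = kept
    return clean


def clean_read_count(report: DemuxReport) -> int:
    """Clean pairs = assigned - dropped-by-length (downstream denominator)."""
    return report.assigned_total - sum(report.dropped_short.values())


# ---------------------------------------------------------------------------
# FASTQ IO
# ---------------------------------------------------------------------------

def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    def _open(p):
        return gzip.open(p, "rt") if str(p).endswith(".gz") else open(p)

    pairs = []
    with _open(r1_path) as f1, _open(r2_path) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(FastqGeneralIterator(f1),
                                              FastqGeneralIterator(f2)):
            if len(s1) != len(q1) or len(s2) != len(q2):
                raise ValueError(f"malformed FASTQ record {t1}")
            rid = t1.split()[0].rsplit("/", 1)[0]
            pairs.append(ReadPair(rid, s1, q1, s2, q2))
    return pairs


def write_demux_outputs(by_cell, unassigned, report: DemuxReport, out_dir,
                        pool_name: str = "pool") -> None:
    from pathlib import Path
    from .simulate import write_fastq_pair
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for barcode, pairs in by_cell.items():
        if pairs:
            write_fastq_pair(pairs, out / f"{pool_name}_{barcode}")
    if unassigned:
        write_fastq_pair(unassigned, out / f"{pool_name}_unassigned")
    report.to_json(out / "demux_report.json")
    with open(out / "demux_report.tsv", "w") as fh:
        fh.write("barcode\tassigned\tdropped_short\ttrimmed_bases\n")
        for b in report.assigned:
            fh.write(f"{b}\t{report.assigned[b]}\t{report.dropped_short.get(b, 0)}"
                     f"\t{report.trimmed_bases.get(b, 0)}\n")
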