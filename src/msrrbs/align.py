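"""Desk-scale three-letter bisulfite alignment into MspI fragment space.

msRRBS reads start at MspI cut sites by construction, so the mapping space is
the size-selected fragment catalog rather than the whole genome.  Read 1 is
C->T converted and matched against C->T-converted fragment frames: the OT
frame is the fragment's top strand, the OB frame its reverse complement (the
original bottom strand read 5'->3').  Mismatches are counted only at
positions that are not bisulfite-ambiguous: reference C against read T is
free.  Mate concordance requires read 2 to match the opposite end of the
same frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import FragmentCatalog, revcomp
from .simulate import ReadPair

_CT = str.maketrans("C", "T")


def ct_convert(seq: str) -> str:
    return seq.translate(_CT)


@dataclass
class BSIndex:
    frames: dict[tuple[str, str], str]        # (fragment_id, OT/OB) -> sequence
    seeds: dict[str, list[tuple[str, str, int]]]  # converted k-mer -> placements
    k: int
    short_frames: list[tuple[str, str]]       # frames shorter than k
    species: dict[str, str]                   # fragment_id -> species label


def build_bs_index(catalog: FragmentCatalog, k: int = 20,
                   species: dict[str, str] | None = None) -> BSIndex:
    """Seed table over C->T-converted k-mers of both strand frames."""
    if len(catalog) == 0:
        raise ValueError("empty fragment catalog")
    frames: dict[tuple[str, str], str] = {}
    seeds: dict[str, list[tuple[str, str, int]]] = {}
    short: list[tuple[str, str]] = []
    for frag in catalog:
        for strand, seq in (("OT", frag.sequence), ("OB", revcomp(frag.sequence))):
            frames[(frag.id, strand)] = seq
            conv = ct_convert(seq)
            if len(conv) < k:
                short.append((frag.id, strand))
                continue
            for off in range(len(conv) - k + 1):
                seeds.setdefault(conv[off:off + k], []).append(
                    (frag.id, strand, off))
    return BSIndex(frames, seeds, k,
                   short_frames=short,
                   species=species or {})


def bs_mismatches(ref: str, read: str, cap: int) -> int:
    """Bisulfite-aware mismatch count; reference C vs read T is free.

    Returns cap+1 as soon as the cap is exceeded.
    """
    mm = 0
    for r, q in zip(ref, read):
        if r == q or (r == "C" and q == "T"):
            continue
        mm += 1
        if mm > cap:
            return mm
    return mm


@dataclass
class Alignment:
    read_id: str
    fragment_id: str | None
    strand: str | None          # OT / OB
    offset: int | None          # read-1 start within the strand frame
    mismatches: int | None
    status: str                 # unique / ambiguous / unmapped


@dataclass
class AlignedPair:
    """Unique alignment bundled with the clean reads it places."""
    alignment: Alignment
    pair: ReadPair


def _candidates(read1_conv: str, index: BSIndex):
    cands = set()
    L = len(read1_conv)
    for seed_start in (0, index.k, 2 * index.k):
        if seed_start + index.k > L:
            break
        kmer = read1_conv[seed_start:seed_start + index.k]
        for fid, strand, off in index.seeds.get(kmer, ()):
            o = off - seed_start
            if o >= 0:
                cands.add((fid, strand, o))
    for fid, strand in index.short_frames:
        frame = index.frames[(fid, strand)]
        for o in range(0, max(0, len(frame) - L) + 1):
            cands.add((fid, strand, o))
    return cands


MAX_OVERHANG = 2  # residual sub-overlap read-through bases clipped at verify


def _verify(frame: str, o: int, r1: str, r2rc: str, cap: int) -> int | None:
    """Bisulfite-aware mismatch total for a candidate placement, or None.

    Reads may overhang the fragment frame by up to MAX_OVERHANG bases
    (read-through shorter than the trimmer's minimum overlap); the overhang
    is clipped.  Read 2 must read the far end of the same molecule.
    """
    flen = len(frame)
    over1 = o + len(r1) - flen
    if over1 > MAX_OVERHANG:
        return None
    r1_eff = r1[:len(r1) - over1] if over1 > 0 else r1
    mm1 = bs_mismatches(frame[o:o + len(r1_eff)], r1_eff, cap)
    if mm1 > cap:
        return None
    over2 = len(r2rc) - flen
    if over2 > MAX_OVERHANG:
        return None
    r2_eff = r2rc[over2:] if over2 > 0 else r2rc
    mm2 = bs_mismatches(frame[flen - len(r2_eff):], r2_eff, cap)
    if mm2 > cap:
        return None
    return mm1 + mm2


def align_pair(pair: ReadPair, index: BSIndex, max_mismatch: int = 2
               ) -> Alignment:
    """Place a trimmed read pair; ties are ambiguous, none within cap unmapped."""
    r1, r2 = pair.seq1, pair.seq2
    r2rc = revcomp(r2)
    scored: list[tuple[int, str, str, int]] = []
    for fid, strand, o in _candidates(ct_convert(r1), index):
        frame = index.frames[(fid, strand)]
        mm = _verify(frame, o, r1, r2rc, max_mismatch)
        if mm is None:
            continue
        scored.append((mm, fid, strand, o))
    if not scored:
        return Alignment(pair.read_id, None, None, None, None, "unmapped")
    scored.sort(key=lambda t: t[0])
    best = scored[0]
    if len(scored) > 1 and scored[1][0] == best[0]:
        return Alignment(pair.read_id, None, None, None, None, "ambiguous")
    return Alignment(pair.read_id, best[1], best[2], best[3], best[0], "unique")


def align_pool(clean_by_cell: dict[str, list[ReadPair]], index: BSIndex,
               max_mismatch: int = 2) -> dict[str, list[AlignedPair]]:
    """Align every clean pair of every cell; keeps all statuses."""
    out: dict[str, list[AlignedPair]] = {}
    for cell, pairs in clean_by_cell.items():
        out[cell] = [AlignedPair(align_pair(p, index, max_mismatch), p)
                     for p in pairs]
    return out


def brute_force_align(pair: ReadPair, index: BSIndex, max_mismatch: int = 2
                      ) -> Alignment:
    """All-frames, all-offsets scan; test oracle for align_pair."""
    r1, r2 = pair.seq1, pair.seq2
    r2rc = revcomp(r2)
    scored = []
    for (fid, strand), frame in index.frames.items():
        for o in range(max(0, len(frame) - len(r1) + MAX_OVERHANG) + 1):
            mm = _verify(frame, o, r1, r2rc, max_mismatch)
            if mm is None:
                continue
            scored.append((mm, fid, strand, o))
    if not scored:
        return Alignment(pair.read_id, None, None, None, None, "unmapped")
    scored.sort(key=lambda t: t[0])
    best = scored[0]
    if len(scored) > 1 and scored[1][0] == best[0]:
        return Alignment(pair.read_id, None, None, None, None, "ambiguous")
    return Alignment(pair.read_id, best[1], best[2], best[3], best[0], "unique")


def mapping_rate(alignments, denominator_count: int) -> float:
    """Unique alignments over a caller-chosen denominator (raw or clean pairs)."""
    if denominator_count <= 0:
        raise ValueError("mapping rate denominator must be positive")
    unique = sum(1 for a in alignments
                 if (a.alignment if isinstance(a, AlignedPair) else a).status
                 == "unique")
    return unique / denominator_count


def species_assign(aligned_by_cell: dict[str, list[AlignedPair]],
                   species: dict[str, str],
                   labels: tuple[str, str]) -> dict[str, tuple[float, float] | None]:
    """Per-cell fractions of unique alignments per species.

    Works on alignments against a combined two-species index: pairs mappable
    to both species are already ambiguous there and thus excluded.  Cells
    with no unique alignment get None.
    """
    out: dict[str, tuple[float, float] | None] = {}
    for cell, aps in aligned_by_cell.items():
        counts = {labels[0]: 0, labels[1]: 0}
        for ap in aps:
            a = ap.alignment
            if a.status != "unique":
                continue
            sp = species.get(a.fragment_id)
            if sp in counts:
                counts[sp] += 1
        total = sum(counts.values())
        out[cell] = None if total == 0 else (counts[labels[0]] / total,
                                             counts[labels[1]] / total)
    return out


def combine_catalogs(catalogs: dict[str, FragmentCatalog]
                     ) -> tuple[FragmentCatalog, dict[str, str]]:
    """Concatenate per-species catalogs, tagging fragment ids with species."""
    from .genome import Fragment
    frags, species = [], {}
    for sp, cat in catalogs.items():
        for f in cat:
            fid = f"{sp}|{f.id}"
            frags.append(Fragment(fid, f.interval, f.sequence, f.has_n))
            species[fid] = sp
    return FragmentCatalog(frags), species


def write_alignment_table(aligned_by_cell, path) -> None:
    import pandas as pd
    rows = []
    for cell, aps in aligned_by_cell.items():
        for ap in aps:
            a = ap.alignment
            rows.append({"cell": cell, "read_id": a.read_id,
                         "fragment_id": a.fragment_id, "strand": a.strand,
                         "offset": a.offset, "mismatches": a.mismatches,
                         "status": a.status})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
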