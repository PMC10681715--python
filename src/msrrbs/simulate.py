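"""Forward simulator of the msRRBS library.

The wet-lab chemistry (barcode-adapter ligation, Sulfolobus fill-in with
methylated C, BciVI excision, sequencing-adapter ligation) is modeled only
through its data-facing consequence: every read pair carries

    [4-bp marker][6-bp cell barcode][bisulfite-converted insert][read-through]

on both mates, where the insert is an MspI fragment within the library size
window and the read-through (when the insert is shorter than the read) is the
reverse complement of the far end's barcode+marker followed by a sequencing
adapter stub.  Adapter cytosines are methylated during library construction,
so marker, barcode and read-through survive bisulfite conversion unchanged.

Ground truth (cell, fragment, species, spike-in status, strand) is recorded
per read pair for round-trip testing of the inverse pipeline.
"""

from __future__ import annotations

import gzip
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (CpGSiteIndex, ElementSet, FragmentCatalog, Genome,
                     digest_mspi, revcomp, select_inserts)

ADAPTER_STUB = "AGATCGGAAGAGC"  # Illumina TruSeq adapter prefix
DEFAULT_MARKER = "GGTG"
LAMBDA_CONTROL_LENGTH = 48502
_LAMBDA_SEED = 485020


class FeasibilityError(ValueError):
    """Raised when a barcode design request cannot be satisfied."""


# ---------------------------------------------------------------------------
# barcode design
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _has_homopolymer(seq: str, run: int = 4) -> bool:
    return any(len(list(g)) >= run for _, g in itertools.groupby(seq))


def make_barcode_whitelist(n: int, length: int = 6, min_hamming: int = 3,
                           seed: int = 0, max_attempts: int | None = None
                           ) -> list[str]:
    """Greedy random design of n distinct barcodes.

    Pairwise Hamming distance >= min_hamming and no homopolymer run of 4+.
    Deterministic given the seed; raises FeasibilityError when the request
    cannot be met within a bounded number of attempts (e.g. n beyond the
    sphere-packing capacity of the barcode space).
    """
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    if n > 4 ** length:
        raise FeasibilityError(f"{n} barcodes cannot exist at length {length}")
    rng = np.random.default_rng(seed)
    attempts = max_attempts if max_attempts is not None else 2000 * n
    bases = np.array(list("ACGT"))
    out: list[str] = []
    for _ in range(attempts):
        cand = "".join(rng.choice(bases, size=length))
        if _has_homopolymer(cand):
            continue
        if all(_hamming(cand, b) >= min_hamming for b in out):
            out.append(cand)
            if len(out) == n:
                return out
    raise FeasibilityError(
        f"could not place {n} barcodes (length {length}, min Hamming "
        f"{min_hamming}) within {attempts} attempts; got {len(out)}")


# ---------------------------------------------------------------------------
# per-cell methylomes
# ---------------------------------------------------------------------------

@dataclass
class MethylomeArchetype:
    """Beta-distributed per-CpG methylation probabilities.

    CpGs inside CGIs draw from a low-methylation Beta, all others from a
    high-methylation Beta, emulating the canonical hypomethylation of islands
    against a methylated genomic background.
    """

    cgi_beta: tuple[float, float] = (1.0, 9.0)   # mean 0.10
    background_beta: tuple[float, float] = (6.0, 2.0)  # mean 0.75

    def validate(self):
        for a, b in (self.cgi_beta, self.background_beta):
            if a <= 0 or b <= 0:
                raise ValueError("beta parameters must be positive")


@dataclass
class CellProfile:
    """Ground-truth per-cell methylome: P(methylated) per plus-strand CpG."""

    cell_id: str
    species: str
    probs: dict[tuple[str, int], float]
    archetype: MethylomeArchetype | None = None

    def n_sites(self) -> int:
        return len(self.probs)


def simulate_cell_methylome(index: CpGSiteIndex, cgis: ElementSet,
                            archetype: MethylomeArchetype, seed: int,
                            cell_id: str = "cell", species: str = "synthetic"
                            ) -> CellProfile:
    """Draw a per-CpG methylation probability for every indexed CpG site."""
    archetype.validate()
    rng = np.random.default_rng(seed)
    cgi_pairs: dict[str, list[tuple[int, int]]] = {}
    for iv in cgis:
        cgi_pairs.setdefault(iv.chrom, []).append((iv.start, iv.end))
    probs: dict[tuple[str, int], float] = {}
    for chrom, positions in index.sites.items():
        pairs = cgi_pairs.get(chrom, [])
        in_cgi = np.zeros(len(positions), dtype=bool)
        for s, e in pairs:
            in_cgi |= (positions >= s) & (positions < e)
        lo = rng.beta(*archetype.cgi_beta, size=len(positions))
        hi = rng.beta(*archetype.background_beta, size=len(positions))
        vals = np.where(in_cgi, lo, hi)
        for p, v in zip(positions, vals):
            probs[(chrom, int(p))] = float(v)
    return CellProfile(cell_id, species, probs, archetype)


# ---------------------------------------------------------------------------
# bisulfite chemistry
# ---------------------------------------------------------------------------

def bisulfite_convert(sequence: str, methylation_state, conversion_failure: float,
                      overconversion: float, rng: np.random.Generator) -> str:
    """Convert a single molecule's top strand.

    methylation_state maps each C position in ``sequence`` to True
    (methylated) / False.  Unmethylated C -> T with probability
    1-conversion_failure; methylated C -> T with probability overconversion.
    """
    out = list(sequence)
    for i, base in enumerate(out):
        if base != "C":
            continue
        meth = methylation_state[i]
        if meth:
            if overconversion > 0 and rng.random() < overconversion:
                out[i] = "T"
        else:
            if rng.random() >= conversion_failure:
                out[i] = "T"
    return "".join(out)


# ---------------------------------------------------------------------------
# pool configuration and read simulation
# ---------------------------------------------------------------------------

@dataclass
class PoolConfig:
    barcodes: list[str] = field(default_factory=list)
    marker: str = DEFAULT_MARKER
    conversion_failure: float = 0.004
    overconversion: float = 0.0
    read_length: int = 150
    insert_window: tuple[int, int] = (30, 200)
    reads_per_cell: int = 2000
    error_rate: float = 0.001
    pcr_duplication_rate: float = 0.0
    spike_fraction: float = 0.05
    ob_strand: bool = True          # emit original-bottom-strand molecules 50/50
    noncpg_meth: float = 0.0        # P(methylated) for non-CpG cytosines
    seed: int = 0

    def __post_init__(self):
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be distinct")
        if any(len(b) != 6 for b in self.barcodes):
            raise ValueError("barcodes must be 6 bp")
        for p in (self.conversion_failure, self.overconversion, self.error_rate,
                  self.pcr_duplication_rate, self.spike_fraction, self.noncpg_meth):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.insert_window
        if not (0 < lo <= hi):
            raise ValueError("invalid insert window")


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, round(-10 * math.log10(error_rate)))
    return chr(33 + q)


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


def _assemble_pair(marker: str, barcode: str, converted: str, read_length: int
                   ) -> tuple[str, str]:
    """Build both mates of one molecule from its converted top strand."""
    tail = revcomp(barcode + marker) + ADAPTER_STUB
    r1 = (marker + barcode + converted + tail)[:read_length]
    r2 = (marker + barcode + revcomp(converted) + tail)[:read_length]
    return r1, r2


def _simulate_molecule(frag, profile: CellProfile | None, config: PoolConfig,
                       rng: np.random.Generator) -> tuple[str, str]:
    """Pick a strand, draw methylation states and convert; returns
    (converted molecule top-strand-as-sequenced, strand label)."""
    use_ob = config.ob_strand and rng.random() < 0.5
    strand = "OB" if use_ob else "OT"
    molecule = revcomp(frag.sequence) if use_ob else frag.sequence
    L = len(molecule)
    chrom, start = frag.interval.chrom, frag.interval.start
    states: dict[int, bool] = {}
    for q, base in enumerate(molecule):
        if base != "C":
            continue
        if strand == "OT":
            key = (chrom, start + q)               # plus-strand C
        else:
            p = start + (L - 1 - q)                # plus-strand G under this C
            key = (chrom, p - 1)                   # CpG's plus-strand C
        if profile is not None and key in profile.probs:
            states[q] = bool(rng.random() < profile.probs[key])
        else:
            states[q] = bool(rng.random() < config.noncpg_meth) \
                if profile is not None else False
    converted = bisulfite_convert(molecule, states, config.conversion_failure,
                                  config.overconversion, rng)
    return converted, strand


def simulate_reads(profiles: list[CellProfile],
                   catalogs: FragmentCatalog | dict[str, FragmentCatalog],
                   config: PoolConfig,
                   control_sequence: str | None = None,
                   pool_name: str = "pool"
                   ) -> tuple[list[ReadPair], pd.DataFrame]:
    """Emit the pooled paired-end library plus its truth table.

    ``catalogs`` is either one size-selected FragmentCatalog or a mapping
    species -> catalog (barnyard mode).  When ``control_sequence`` is given
    and spike_fraction > 0, fully unmethylated control reads are appended,
    carrying the barcodes of the pooled cells (the control is spiked into
    each cell's digestion in the protocol).
    """
    if len(profiles) > len(config.barcodes):
        raise ValueError("more cells than barcodes")
    rng = np.random.default_rng(config.seed)
    if isinstance(catalogs, FragmentCatalog):
        catalogs = {p.species: catalogs for p in profiles}
    for sp, cat in catalogs.items():
        lo, hi = config.insert_window
        if len(cat) == 0:
            raise ValueError(f"empty catalog for species {sp}")

    qchar = _phred_char(config.error_rate)
    pairs: list[ReadPair] = []
    truth_rows: list[dict] = []
    serial = 0

    def emit(profile, barcode, frag, species, is_spike):
        nonlocal serial
        converted, strand = _simulate_molecule(frag, profile, config, rng)
        s1, s2 = _assemble_pair(config.marker, barcode, converted,
                                config.read_length)
        s1 = _inject_errors(s1, config.error_rate, rng)
        s2 = _inject_errors(s2, config.error_rate, rng)
        rid = f"{pool_name}:{serial}"
        serial += 1
        pairs.append(ReadPair(rid, s1, qchar * len(s1), s2, qchar * len(s2)))
        truth_rows.append({
            "read_id": rid,
            "cell_id": profile.cell_id if profile else "spike",
            "barcode": barcode,
            "fragment_id": frag.id,
            "species": species,
            "is_spikein": is_spike,
            "strand": strand,
            "insert_len": len(frag),
        })

    for i, profile in enumerate(profiles):
        barcode = config.barcodes[i]
        cat = catalogs[profile.species]
        frags = cat.fragments
        idx = rng.integers(0, len(frags), size=config.reads_per_cell)
        for j in idx:
            emit(profile, barcode, frags[int(j)], profile.species, False)
        if config.pcr_duplication_rate > 0:
            n_dup = rng.binomial(config.reads_per_cell,
                                 config.pcr_duplication_rate)
            for j in rng.integers(0, len(frags), size=n_dup):
                emit(profile, barcode, frags[int(j)], profile.species, False)

    if control_sequence is not None and config.spike_fraction > 0:
        n_genomic = len(truth_rows)
        n_spike = round(config.spike_fraction * n_genomic)
        spike_cat = select_inserts(digest_mspi(Genome({"spike": control_sequence})),
                                   *config.insert_window)
        if len(spike_cat) == 0:
            raise ValueError("no control fragments in the insert window")
        sfrags = spike_cat.fragments
        for _ in range(n_spike):
            cell_i = int(rng.integers(0, len(profiles)))
            frag = sfrags[int(rng.integers(0, len(sfrags)))]
            emit(None, config.barcodes[cell_i], frag, "spike", True)
            truth_rows[-1]["cell_id"] = profiles[cell_i].cell_id

    truth = pd.DataFrame(truth_rows)
    return pairs, truth


def spike_lambda(config: PoolConfig, control_sequence: str, n_pairs: int,
                 barcodes: list[str] | None = None, seed: int | None = None,
                 pool_name: str = "spike") -> tuple[list[ReadPair], pd.DataFrame]:
    """Generate unmethylated control read pairs through the standard path."""
    cfg = PoolConfig(**{**config.__dict__,
                        "barcodes": (barcodes or config.barcodes)[:1],
                        "reads_per_cell": n_pairs,
                        "spike_fraction": 0.0,
                        "seed": config.seed if seed is None else seed})
    profile = CellProfile("spike", "spike", {})
    cat = select_inserts(digest_mspi(Genome({"spike": control_sequence})),
                         *cfg.insert_window)
    pairs, truth = simulate_reads([profile], {"spike": cat}, cfg,
                                  pool_name=pool_name)
    truth["is_spikein"] = True
    truth["species"] = "spike"
    return pairs, truth


def simulate_barnyard(genome_a: Genome, genome_b: Genome, config: PoolConfig,
                      n_cells_a: int, n_cells_b: int,
                      index_a: CpGSiteIndex, index_b: CpGSiteIndex,
                      cgis_a: ElementSet, cgis_b: ElementSet,
                      archetype: MethylomeArchetype | None = None,
                      pool_name: str = "barnyard"):
    """Two-species pool: each cell's reads come only from its own genome."""
    archetype = archetype or MethylomeArchetype()
    lo, hi = config.insert_window
    cat_a = select_inserts(digest_mspi(genome_a), lo, hi)
    cat_b = select_inserts(digest_mspi(genome_b), lo, hi)
    profiles = []
    for i in range(n_cells_a):
        profiles.append(simulate_cell_methylome(
            index_a, cgis_a, archetype, seed=config.seed * 1000 + i,
            cell_id=f"A{i}", species="speciesA"))
    for i in range(n_cells_b):
        profiles.append(simulate_cell_methylome(
            index_b, cgis_b, archetype, seed=config.seed * 1000 + 500 + i,
            cell_id=f"B{i}", species="speciesB"))
    catalogs = {"speciesA": cat_a, "speciesB": cat_b}
    pairs, truth = simulate_reads(profiles, catalogs, config,
                                  pool_name=pool_name)
    return pairs, truth, profiles, catalogs


# ---------------------------------------------------------------------------
# synthetic sequences
# ---------------------------------------------------------------------------

def lambda_like_control(length: int = LAMBDA_CONTROL_LENGTH,
                        seed: int = _LAMBDA_SEED) -> str:
    """Packaged synthetic unmethylated control sequence (48,502 bp).

    A seeded random sequence standing in for the phage-lambda spike-in; it is
    synthetic by construction and only its cytosine positions matter to the
    conversion-rate estimator.
    """
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate_genome(chrom_lengths: dict[str, int], seed: int,
                    gc: float = 0.5, n_cgis_per_chrom: int = 3,
                    cgi_length: int = 400,
                    cpg_depletion: float = 0.8) -> Genome:
    """Random genome with CpG-depleted background and planted CpG islands.

    The background is drawn at the requested GC and then CpG-depleted
    (``cpg_depletion`` of CG dinucleotides destroyed, echoing the methylation-
    driven CpG decay of vertebrate genomes, observed/expected ~0.2); planted
    segments are CpG-dense so islands stand out against the background the
    way they do in real genomes, and MspI sites concentrate inside them.
    """
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = {}
    for chrom, L in chrom_lengths.items():
        arr = rng.choice(list("ACGT"), size=L, p=p)
        # deplete background CpGs: replace the G of most CG dinucleotides
        cg = np.flatnonzero((arr[:-1] == "C") & (arr[1:] == "G"))
        kill = cg[rng.random(len(cg)) < cpg_depletion]
        arr[kill + 1] = rng.choice(list("AT"), size=len(kill))
        # plant islands roughly every 6 kb so the size-selected fragment
        # catalog has enough diversity at desk scale
        n_cgi = max(n_cgis_per_chrom, L // 6000) if L > 4 * cgi_length else 0
        for k in range(n_cgi):
            lo = cgi_length + k * (L - 3 * cgi_length) // max(n_cgi, 1)
            s = int(rng.integers(lo, lo + max(1, (L - 3 * cgi_length)
                                              // max(n_cgi, 1) // 2)))
            block = []
            while len(block) < cgi_length:
                r = rng.random()
                if r < 0.12:
                    block.extend("CCGG")   # MspI sites concentrate in islands
                elif r < 0.5:
                    block.extend("CG")
                elif r < 0.78:
                    block.append(rng.choice(list("CG")))
                else:
                    block.append(rng.choice(list("AT")))
            arr[s:s + cgi_length] = block[:cgi_length]
        seqs[chrom] = "".join(arr)
    return Genome(seqs)


# ---------------------------------------------------------------------------
# direct call-set sampling (statistical studies without read-level simulation)
# ---------------------------------------------------------------------------

def sample_callset(probs: dict[tuple[str, int], float], mean_coverage: float,
                   rng: np.random.Generator, cell_id: str = "cell",
                   min_coverage: int = 0):
    """Binomial call-set draw at Poisson coverage from a per-site methylome.

    Bypasses read simulation: for cohort/differential-methylation statistics
    the sampling distribution of a call set is fully specified by per-site
    coverage and methylation probability.
    """
    from .calling import MethylationCallSet
    cs = MethylationCallSet(cell_id)
    for key, p in probs.items():
        n = int(rng.poisson(mean_coverage))
        if n < min_coverage:
            n = min_coverage
        if n == 0:
            continue
        m = int(rng.binomial(n, p))
        cs.cpg[key] = [m, n - m]
    return cs


# ---------------------------------------------------------------------------
# FASTQ / truth IO
# ---------------------------------------------------------------------------

def write_fastq_pair(pairs: list[ReadPair], prefix) -> tuple[str, str]:
    p1, p2 = f"{prefix}_R1.fastq.gz", f"{prefix}_R2.fastq.gz"
    with gzip.open(p1, "wt") as f1, gzip.open(p2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")
    return p1, p2


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
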