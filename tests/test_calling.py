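"""Methylation calling, conversion-rate estimation, QC and text output."""

import numpy as np
import pytest

import msrrbs as M
from msrrbs.align import AlignedPair, Alignment, build_bs_index
from msrrbs.calling import (MethylationCallSet, cell_qc, context_levels,
                            estimate_conversion_rate, pileup_calls,
                            read_cgmap, write_bedgraph, write_cgmap)
from msrrbs.genome import (Fragment, FragmentCatalog, Genome, Interval,
                           index_cpgs, revcomp)
from msrrbs.simulate import ReadPair


def aligned_pair(fid, strand, r1, r2, read_id="r", offset=0):
    return AlignedPair(Alignment(read_id, fid, strand, offset, 0, "unique"),
                       ReadPair(read_id, r1, "I" * len(r1), r2, "I" * len(r2)))


@pytest.fixture
def toy_reference():
    # one fragment covering the whole toy chromosome
    seq = "CGGTACGTAACCAGGTACGA"
    genome = Genome({"t": seq})
    frag = Fragment("f0", Interval("t", 0, len(seq)), seq)
    return genome, FragmentCatalog([frag]), index_cpgs(genome), seq


class TestPileup:
    def test_counts_and_level(self, toy_reference):
        genome, cat, idx, seq = toy_reference
        # CpG at position 5 (C5 G6); three methylated reads, one not
        reads = []
        for i in range(3):
            r1 = "".join("C" if j == 5 else ("T" if b == "C" else b)
                         for j, b in enumerate(seq))
            reads.append(aligned_pair("f0", "OT", r1, revcomp(r1), f"m{i}"))
        r1_un = seq.replace("C", "T")
        reads.append(aligned_pair("f0", "OT", r1_un, revcomp(r1_un), "u"))
        cs = pileup_calls(reads, cat, idx)
        assert cs.cpg[("t", 5)] == [3, 1]
        assert cs.level(("t", 5)) == 0.75

    def test_uncovered_site_absent(self, toy_reference):
        genome, cat, idx, seq = toy_reference
        r1 = seq.replace("C", "T")[:4]     # covers positions 0-3
        r2 = revcomp(seq.replace("C", "T"))[:2]  # covers positions 18-19
        cs = pileup_calls([aligned_pair("f0", "OT", r1, r2)], cat, idx)
        assert ("t", 0) in cs.cpg
        assert ("t", 5) not in cs.cpg and ("t", 17) not in cs.cpg

    def test_ot_and_ob_merge_destranded(self, toy_reference):
        """A methylated OT read plus a methylated OB read give (2, 0)."""
        genome, cat, idx, seq = toy_reference
        # OT read: methylated at the CpG C (pos 5)
        r1_ot = "".join("C" if j == 5 else ("T" if b == "C" else b)
                        for j, b in enumerate(seq))
        # OB molecule: bottom strand; its C pairing the G at pos 6 stays C
        frame_ob = revcomp(seq)
        q = len(seq) - 1 - 6  # frame position of the bottom-strand C under G6
        r1_ob = "".join("C" if j == q else ("T" if b == "C" else b)
                        for j, b in enumerate(frame_ob))
        reads = [aligned_pair("f0", "OT", r1_ot, revcomp(r1_ot), "a"),
                 aligned_pair("f0", "OB", r1_ob, revcomp(r1_ob), "b")]
        cs = pileup_calls(reads, cat, idx)
        assert cs.cpg[("t", 5)] == [2, 0]

    def test_destrand_off_splits_strands_additively(self, toy_reference):
        genome, cat, idx, seq = toy_reference
        r1_ot = "".join("C" if j == 5 else ("T" if b == "C" else b)
                        for j, b in enumerate(seq))
        frame_ob = revcomp(seq)
        q = len(seq) - 1 - 6
        r1_ob = "".join("C" if j == q else ("T" if b == "C" else b)
                        for j, b in enumerate(frame_ob))
        reads = [aligned_pair("f0", "OT", r1_ot, revcomp(r1_ot), "a"),
                 aligned_pair("f0", "OB", r1_ob, revcomp(r1_ob), "b")]
        merged = pileup_calls(reads, cat, idx, destrand=True)
        split = pileup_calls(reads, cat, idx, destrand=False)
        plus = split.cpg.get(("t", 5), [0, 0])
        minus = split.cpg.get(("t", -7), [0, 0])  # encoded minus key for G at 6
        assert [plus[0] + minus[0], plus[1] + minus[1]] == merged.cpg[("t", 5)]

    def test_unknown_fragment_rejected(self, toy_reference):
        genome, cat, idx, seq = toy_reference
        ap = aligned_pair("nope", "OT", "ACGT", "ACGT")
        with pytest.raises(KeyError):
            pileup_calls([ap], cat, idx)

    def test_pair_counts_each_site_once(self, toy_reference):
        """Mates overlapping the same site contribute one observation."""
        genome, cat, idx, seq = toy_reference
        r1 = seq.replace("C", "T")
        r2 = revcomp(seq.replace("C", "T"))
        cs = pileup_calls([aligned_pair("f0", "OT", r1, r2)], cat, idx)
        assert cs.cpg[("t", 5)] == [0, 1]
        assert sum(m + u for m, u in cs.cpg.values()) == 3  # sites 0, 5, 17


class TestConversionRate:
    @pytest.mark.parametrize("m,u,expected", [
        (4, 996, 0.996), (0, 1000, 1.0),
    ])
    def test_arithmetic(self, m, u, expected):
        cs = MethylationCallSet("c")
        cs.noncpg[("spike", "CHH")] = [m, u]
        assert estimate_conversion_rate(cs) == pytest.approx(expected)

    def test_zero_observations_missing_with_warning(self):
        cs = MethylationCallSet("c")
        with pytest.warns(UserWarning):
            assert estimate_conversion_rate(cs) is None

    @pytest.mark.parametrize("failure", [0.0, 0.004, 0.02])
    def test_recovers_simulated_failure_rate(self, failure, whitelist):
        control = M.lambda_like_control(length=20000, seed=9)
        cfg = M.PoolConfig(barcodes=whitelist[:1], reads_per_cell=600,
                           error_rate=0.0, conversion_failure=failure, seed=13)
        pairs, _ = M.spike_lambda(cfg, control, 600)
        dcfg = M.DemuxConfig(whitelist=whitelist[:1])
        by_cell, _, rep = M.demultiplex(pairs, dcfg)
        clean = M.trim_reads(by_cell, dcfg, rep)
        sg = Genome({"spike": control})
        from msrrbs.genome import digest_mspi, select_inserts
        cat = select_inserts(digest_mspi(sg), 30, 200)
        aligned = M.align_pool(clean, build_bs_index(cat))
        cs = pileup_calls(aligned[whitelist[0]], cat, index_cpgs(sg))
        n_obs = (sum(m + u for m, u in cs.cpg.values())
                 + sum(m + u for m, u in cs.noncpg.values()))
        rate = estimate_conversion_rate(cs, spike_chroms={"spike"})
        sd = np.sqrt(max(failure * (1 - failure), 1e-9) / n_obs)
        assert n_obs > 10000
        assert abs(rate - (1 - failure)) <= max(3 * sd, 3 / n_obs)


class TestContextLevels:
    def test_aggregates(self):
        cs = MethylationCallSet("c")
        cs.cpg[("t", 1)] = [3, 1]
        cs.noncpg[("t", "CHG")] = [4, 996]
        cs.noncpg[("t", "CHH")] = [0, 500]
        lv = context_levels(cs)
        assert lv["CpG"] == 0.75
        assert lv["CHG"] == pytest.approx(0.004)
        assert lv["CHH"] == 0.0

    def test_empty_callset_all_missing(self):
        lv = context_levels(MethylationCallSet("c"))
        assert lv == {"CpG": None, "CHG": None, "CHH": None}


class TestCellQC:
    def test_inclusive_threshold(self):
        cs = MethylationCallSet("c")
        cs.cpg = {("t", i): [1, 0] for i in range(10)}
        assert cell_qc(cs, min_sites=10).passed          # boundary inclusive
        assert cell_qc(cs, min_sites=11).passed is False
        assert cell_qc(cs, min_sites=5).passed

    def test_default_threshold_is_200k(self):
        cs = MethylationCallSet("c")
        cs.cpg = {("t", i): [1, 0] for i in range(100)}
        assert cell_qc(cs).passed is False


class TestTextFormats:
    def test_cgmap_line_format(self, tmp_path):
        cs = MethylationCallSet("c")
        cs.cpg[("chr1", 1)] = [3, 1]
        path = tmp_path / "x.cgmap"
        write_cgmap(cs, path)
        chrom, nuc, pos, ctx, dinuc, lvl, m, tot = \
            path.read_text().strip().split("\t")
        assert (chrom, nuc, pos, ctx) == ("chr1", "C", "2", "CG")
        assert float(lvl) == 0.75 and (m, tot) == ("3", "4")

    def test_empty_callset_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_cgmap(MethylationCallSet("c"), tmp_path / "x.cgmap")
        with pytest.raises(ValueError):
            write_bedgraph(MethylationCallSet("c"), tmp_path / "x.bg")

    def test_cgmap_round_trip_random_callsets(self, tmp_path, rng):
        for i in range(30):
            cs = MethylationCallSet("c")
            for _ in range(rng.integers(1, 40)):
                key = (f"chr{rng.integers(1, 3)}", int(rng.integers(0, 10000)))
                cs.cpg[key] = [int(rng.integers(0, 20)),
                               int(rng.integers(1, 20))]
            path = tmp_path / f"{i}.cgmap"
            write_cgmap(cs, path)
            assert read_cgmap(path).cpg == cs.cpg

    def test_bedgraph_level_scaled_by_100(self, tmp_path):
        cs = MethylationCallSet("c")
        cs.cpg[("chr1", 9)] = [1, 3]
        path = tmp_path / "x.bg"
        write_bedgraph(cs, path)
        from msrrbs.calling import read_bedgraph
        df = read_bedgraph(path)
        assert df.iloc[0].tolist() == ["chr1", 9, 10, 25.0]


class TestPerSiteRecovery:
    def test_levels_converge_to_truth(self, callsets, profiles, whitelist):
        """|estimate - p| <= 3 sd(p, n) holds at the binomial-expected rate."""
        from scipy import stats
        violations = expected = n_checked = 0
        for i, barcode in enumerate(whitelist[:4]):
            cs = callsets[barcode]
            truth = profiles[i].probs
            for key, (m, u) in cs.cpg.items():
                n = m + u
                if n < 10 or key not in truth:
                    continue
                p = truth[key]
                bound = 3 * np.sqrt(p * (1 - p) / n)
                n_checked += 1
                if abs(m / n - p) > bound + 1e-12:
                    violations += 1
                # non-violating X range is [ceil(n(p-bound)), floor(n(p+bound))]
                lo = int(np.ceil(n * (p - bound) - 1e-12))
                hi = int(np.floor(n * (p + bound) + 1e-12))
                expected += (1.0 - (stats.binom.cdf(hi, n, p)
                                    - stats.binom.cdf(lo - 1, n, p)))
        assert n_checked > 500
        sd = np.sqrt(max(expected, 1.0))
        assert violations <= expected + 3 * sd
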