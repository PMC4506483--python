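"""De novo discovery: split alignment, binning, consensus score S,
breakpoint refinement, and splice-signal annotation."""

import numpy as np
import pytest

from circjunct import denovo
from circjunct.index import ExonRecord, revcomp
from tests.conftest import random_genome


def _split(read_id, seq, five_pos, three_pos, strand="+", chrom="chr1"):
    return denovo.SplitAlignment(read_id, seq, chrom, strand, five_pos, three_pos, 0, 0)


@pytest.fixture(scope="module")
def cryptic_genome():
    """10 kb genome with two planted un-annotated GT-AG circles."""
    g = list(random_genome(10_000, seed=7))
    regions = [(2_000, 2_600), (6_000, 6_500)]
    for lo, hi in regions:
        g[hi], g[hi + 1] = "G", "T"
        g[lo - 2], g[lo - 1] = "A", "G"
    return {"chr1": "".join(g)}, regions


def backsplice_pairs(genome, lo, hi, n, seed, prefix, frag_len=250):
    """Read pairs from the rolled circle [lo, hi), R1 crossing 35-65 nt in."""
    rng = np.random.default_rng(seed)
    circ = genome["chr1"][lo:hi]
    L = len(circ)
    pairs = []
    for i in range(n):
        start = int(rng.integers(L - 65, L - 34))
        frag = (circ * 3)[start:start + frag_len]
        pairs.append((f"{prefix}{i}", frag[:100], revcomp(frag[-100:])))
    return pairs


class TestFindSplitAlignments:
    def test_backsplice_read_has_inverted_hits(self, cryptic_genome):
        genome, regions = cryptic_genome
        lo, hi = regions[0]
        pairs = backsplice_pairs(genome, lo, hi, 5, seed=1, prefix="bs")
        splits = denovo.find_split_alignments(((r, s) for r, s, _ in pairs), genome)
        assert splits
        for s in splits:
            assert s.three_pos < s.five_pos  # acceptor upstream of donor

    def test_linear_read_is_excluded(self, cryptic_genome):
        genome, _ = cryptic_genome
        seq = genome["chr1"][3_000:3_100]  # contiguous genomic read
        assert denovo.find_split_alignments([("lin", seq)], genome) == []

    def test_split_linear_splice_is_excluded(self, cryptic_genome):
        # canonical-order splice: 3' segment downstream of 5' segment
        genome, _ = cryptic_genome
        seq = genome["chr1"][3_000:3_050] + genome["chr1"][4_000:4_050]
        assert denovo.find_split_alignments([("sp", seq)], genome) == []

    def test_opposite_strand_segments_excluded(self, cryptic_genome):
        genome, _ = cryptic_genome
        seq = genome["chr1"][4_000:4_050] + revcomp(genome["chr1"][3_000:3_050])
        assert denovo.find_split_alignments([("xs", seq)], genome) == []


class TestBinPairs:
    def test_three_unique_offsets_retained(self):
        splits = [_split(f"r{i}", "ACGT" * 25, 1000 + o, 500) for i, o in enumerate([0, 7, 19])]
        groups = denovo.collect_bin_pairs(splits, bin_size=50)
        assert len(groups) == 1 and len(next(iter(groups.values()))) == 3

    def test_duplicate_offsets_dropped(self):
        splits = [_split(f"r{i}", "ACGT" * 25, 1000 + o, 500) for i, o in enumerate([0, 7, 7])]
        assert denovo.collect_bin_pairs(splits, bin_size=50) == {}

    def test_bin_size_splits_groups_at_edges(self):
        # offsets straddle a 25-nt bin edge but share one 50-nt bin
        splits = [_split(f"r{i}", "ACGT" * 25, 1020 + o, 500) for i, o in enumerate([0, 3, 6])]
        assert len(denovo.collect_bin_pairs(splits, bin_size=50)) == 1
        assert len(denovo.collect_bin_pairs(splits, bin_size=25, min_unique_offsets=1)) == 2


class TestConsensusScore:
    def test_unanimous_reads_score_zero(self):
        seq = random_genome(100, seed=3)
        members = [_split(f"r{i}", seq, 1000, 500) for i in range(4)]
        consensus, s, _ = denovo.consensus_and_score(members)
        assert s == 0.0 and consensus == seq

    def test_one_disagreement_at_depth_two(self):
        seq = random_genome(100, seed=4)
        other = ("A" if seq[50] != "A" else "C") + ""
        seq2 = seq[:50] + other + seq[51:]
        members = [_split("r1", seq, 1000, 500), _split("r2", seq2, 1000, 500)]
        _, s, _ = denovo.consensus_and_score(members)
        assert s == pytest.approx(0.5)

    def test_score_invariant_to_read_order(self):
        rng = np.random.default_rng(8)
        seq = random_genome(100, seed=5)
        members = []
        for i in range(6):
            off = int(rng.integers(0, 20))
            read = list(seq[off:off + 80])
            for p in rng.integers(0, 80, size=2):
                read[p] = "T" if read[p] != "T" else "G"
            members.append(_split(f"r{i}", "".join(read), 1000 + off, 500))
        _, s1, _ = denovo.consensus_and_score(members)
        _, s2, _ = denovo.consensus_and_score(members[::-1])
        assert s1 == pytest.approx(s2)

    def test_expected_score_grows_with_error_rate(self):
        """Depth-2 stacks: E[S] ~ (number of multi-covered positions) * p."""
        rng = np.random.default_rng(9)
        seq = random_genome(100, seed=6)
        for p_err, expect in [(0.01, 1.0), (0.03, 3.0)]:
            scores = []
            for _ in range(300):
                reads = []
                for r in range(2):
                    arr = list(seq)
                    hits = np.nonzero(rng.random(100) < p_err)[0]
                    for h in hits:
                        arr[h] = rng.choice([b for b in "ACGT" if b != arr[h]])
                    reads.append(_split(f"x{r}", "".join(arr), 1000, 500))
                scores.append(denovo.consensus_and_score(reads)[1])
            # each disagreeing depth-2 column contributes 1/2; P(disagree) ~ 2p
            assert np.mean(scores) == pytest.approx(expect, rel=0.25)


class TestScreening:
    def _assembly(self, s):
        return denovo.BinPairAssembly(
            chrom="chr1", strand="+", bin_a=20, bin_b=10, bin_size=50,
            member_reads=[], consensus="A" * 60, score_s=s,
        )

    def test_score_threshold_is_strict(self):
        kept = denovo.screen_candidates([self._assembly(4.9), self._assembly(5.0)])
        assert [a.score_s for a in kept] == [4.9]

    def test_mixed_breakpoint_groups_dropped(self):
        # two distinct splices 6 nt apart mixed in one bin pair produce a
        # block of well-supported conflicting columns
        seqA = random_genome(100, seed=12)
        seqB = seqA[:40] + random_genome(30, seed=13) + seqA[70:]
        members = [
            _split("a1", seqA, 1000, 500), _split("a2", seqA, 1000, 500),
            _split("b1", seqB, 1000, 500), _split("b2", seqB, 1000, 500),
            _split("b3", seqB[1:], 1001, 500),
        ]
        groups = {("chr1", "+", 20, 10): members}
        consensus, s, cols = denovo.consensus_and_score(members)
        asm = self._assembly(min(s, 4.0))
        assert denovo.screen_candidates([asm], groups=groups) == []


class TestBreakpointMapping:
    def test_exact_recovery_with_u2_signal(self, cryptic_genome):
        genome, regions = cryptic_genome
        lo, hi = regions[0]
        pairs = backsplice_pairs(genome, lo, hi, 15, seed=2, prefix="u2")
        splits = denovo.find_split_alignments(((r, s) for r, s, _ in pairs), genome)
        assemblies = denovo.assemble_bin_pairs(splits)
        refined = [denovo.map_breakpoint(a, genome) for a in assemblies]
        refined = [a for a in refined if a is not None]
        assert refined
        for a in refined:
            assert a.breakpoint == (hi, lo + 1)  # 1-based donor/acceptor sites
            assert a.signal_class == "U2"
            assert a.flanking_dinucleotides == ("GT", "AG")

    def test_short_consensus_has_no_valid_split(self, cryptic_genome):
        genome, _ = cryptic_genome
        a = denovo.BinPairAssembly(
            chrom="chr1", strand="+", bin_a=51, bin_b=40, bin_size=50,
            member_reads=[], consensus=genome["chr1"][2560:2595], score_s=0.0,
        )
        assert denovo.map_breakpoint(a, genome) is None

    def test_canonical_breakpoint_preferred(self):
        """When two splits map, the GT-AG-flanked one wins."""
        g = list(random_genome(3_000, seed=21))
        # donor exon end at 1000 with GT after; acceptor start at 300 with AG before
        g[1000], g[1001] = "G", "T"
        g[298], g[299] = "A", "G"
        genome = {"chr1": "".join(g)}
        consensus = genome["chr1"][960:1000] + genome["chr1"][300:340]
        a = denovo.BinPairAssembly(
            chrom="chr1", strand="+", bin_a=19, bin_b=6, bin_size=50,
            member_reads=[], consensus=consensus, score_s=0.0,
        )
        r = denovo.map_breakpoint(a, genome)
        assert r is not None and r.signal_class == "U2"
        assert r.breakpoint == (1000, 301)


class TestNaming:
    @pytest.fixture()
    def assembly(self):
        a = denovo.BinPairAssembly(
            chrom="chr1", strand="+", bin_a=20, bin_b=10, bin_size=50,
            member_reads=[], consensus="A" * 60, score_s=0.0,
        )
        a.breakpoint = (1_000, 540)
        return a

    def test_named_when_within_1kb(self, assembly):
        ann = [ExonRecord("chr1", 1_400, 1_700, "+", "nearby", "e1")]
        assert denovo.name_and_classify(assembly, ann).name == "nearby"

    def test_unan_when_distant(self, assembly):
        ann = [ExonRecord("chr1", 6_000, 6_300, "+", "far", "e1")]
        assert denovo.name_and_classify(assembly, ann).name == "UNAN"

    def test_named_when_inside_gene(self, assembly):
        ann = [ExonRecord("chr1", 400, 1_200, "+", "host", "e1")]
        assert denovo.name_and_classify(assembly, ann).name == "host"


class TestEndToEnd:
    def test_all_planted_circles_recovered_exactly(self, cryptic_genome):
        genome, regions = cryptic_genome
        pairs = []
        for k, (lo, hi) in enumerate(regions):
            pairs += backsplice_pairs(genome, lo, hi, 15, seed=30 + k, prefix=f"c{k}_")
        calls, _ = denovo.discover_denovo(pairs, genome)
        found = {c.extras["breakpoint"] for c in calls}
        assert found == {(hi, lo + 1) for lo, hi in regions}
        assert all(c.extras["signal_class"] == "U2" for c in calls)
        assert all(c.p_value > 0.9 for c in calls)

    def test_linear_only_reads_produce_no_junctions(self, cryptic_genome):
        genome, _ = cryptic_genome
        rng = np.random.default_rng(40)
        pairs = []
        for i in range(30):
            start = int(rng.integers(0, 9_700))
            frag = genome["chr1"][start:start + 250]
            pairs.append((f"g{i}", frag[:100], revcomp(frag[-100:])))
        calls, refined = denovo.discover_denovo(pairs, genome)
        assert calls == []

    def test_decoy_ratio_filter(self, cryptic_genome):
        """Mates on the wrong chromosome turn reads into decoys and the
        junction fails the decoy/circle < 0.1 rule."""
        genome, regions = cryptic_genome
        lo, hi = regions[0]
        genome = dict(genome)
        genome["chr2"] = random_genome(2_000, seed=50)
        pairs = backsplice_pairs(genome, lo, hi, 15, seed=41, prefix="d")
        # replace mates with foreign-chromosome sequence
        bad = [(rid, r1, revcomp(genome["chr2"][500:600])) for rid, r1, _ in pairs]
        calls, _ = denovo.discover_denovo(bad, genome)
        assert calls == []
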