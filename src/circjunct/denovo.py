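"""De novo backsplice discovery from reads unaligned to every reference.

Reads failing the genome and all junction databases are split into a 5'
and a 3' segment; each segment must place uniquely on the genome (at
most two mismatches) on the same strand, in the inverted orientation
diagnostic of a backsplice (the 3' segment upstream of the 5' segment
in transcript direction).  Split reads are grouped by the disjoint
50-nt genome bin pair their segments hit; groups with at least three
distinct stacking offsets are assembled into a consensus.  The
consensus score S sums, over every column covered by two or more reads,
the fraction of bases disagreeing with the column consensus, so S = 0
means unanimity and the null expectation under a per-base error rate p
is (number of multi-covered columns) * p.  Low-scoring assemblies are
breakpoint-refined by re-mapping every >= 20 nt split of the consensus
near the bins, annotated with flanking splice dinucleotides (preferring
canonical GT-AG, then the U12 minor-spliceosome signature), named by
the nearest gene, and finally re-scored by realigning all unaligned
read pairs against the consensus junctions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from circjunct.classify import ReadFeatureRecord, build_feature_records
from circjunct.glm import JunctionCall, naive_mismatch_pvalue
from circjunct.index import AnnotatedJunction, ExonRecord, revcomp

logger = logging.getLogger(__name__)

U12_DONOR_SIGNATURE = "TATCCT"


@dataclass(frozen=True)
class SplitAlignment:
    read_id: str
    seq: str
    chrom: str
    strand: str
    five_pos: int  # genomic start of the 5' segment placement
    three_pos: int  # genomic start of the 3' segment placement
    mm5: int
    mm3: int


@dataclass
class BinPairAssembly:
    chrom: str
    strand: str
    bin_a: int  # bin of the 5' (donor-side) segment
    bin_b: int  # bin of the 3' (acceptor-side) segment
    bin_size: int
    member_reads: list[tuple[str, int]]  # (read_id, stacking column)
    consensus: str
    score_s: float
    breakpoint: tuple[int, int] | None = None  # 1-based (donor site, acceptor site)
    flanking_dinucleotides: tuple[str, str] | None = None
    signal_class: str = "other"
    name: str = "UNAN"
    boundary_index: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def junction_id(self) -> str:
        if self.breakpoint is None:
            return f"{self.chrom}:bin{self.bin_a}:bin{self.bin_b}:{self.strand}"
        d, a = self.breakpoint
        return f"{self.chrom}:{d}:{a}:{self.strand}"


# ---------------------------------------------------------------------------
# split alignment

def find_split_alignments(
    reads: Iterable[tuple[str, str]],
    genome: Mapping[str, str],
    segment_trim: int = 65,
    max_mm: int = 2,
) -> list[SplitAlignment]:
    """Place the 5' and 3' segments of each read uniquely on the genome.

    The segment length is read length minus ``segment_trim`` (matching
    trimming 65 nt off either end of ~100-nt reads).  Both segments must
    align uniquely with at most ``max_mm`` mismatches, on the same
    strand and chromosome, with the 3' segment upstream of the 5'
    segment in transcript orientation -- the inverted geometry of a
    backsplice.
    """
    from circjunct.align import SeedMatcher

    if not genome:
        raise ValueError("genome is required for split alignment")
    matcher = SeedMatcher(genome)
    out: list[SplitAlignment] = []
    for read_id, seq in reads:
        seg_len = len(seq) - segment_trim
        if seg_len < 12:
            continue
        hits5 = matcher.find(seq[:seg_len], max_mm=max_mm)
        hits3 = matcher.find(seq[-seg_len:], max_mm=max_mm)
        if len(hits5) != 1 or len(hits3) != 1:
            continue
        h5, h3 = hits5[0], hits3[0]
        if h5.ref_name != h3.ref_name or h5.strand != h3.strand:
            continue
        if h5.strand == "+":
            inverted = h3.pos < h5.pos
        else:
            inverted = h3.pos > h5.pos
        if not inverted:
            continue
        out.append(
            SplitAlignment(
                read_id=read_id, seq=seq.upper(), chrom=h5.ref_name, strand=h5.strand,
                five_pos=h5.pos, three_pos=h3.pos, mm5=h5.mismatches, mm3=h3.mismatches,
            )
        )
    return out


# ---------------------------------------------------------------------------
# binning and consensus

def collect_bin_pairs(
    splits: Sequence[SplitAlignment],
    bin_size: int = 50,
    min_unique_offsets: int = 3,
) -> dict[tuple[str, str, int, int], list[SplitAlignment]]:
    """Group split reads by (chrom, strand, 5' bin, 3' bin).

    Only groups with at least ``min_unique_offsets`` distinct stacking
    offsets survive: identical offsets are consistent with PCR
    duplicates and carry no independent evidence.
    """
    groups: dict[tuple[str, str, int, int], list[SplitAlignment]] = {}
    for s in splits:
        key = (s.chrom, s.strand, s.five_pos // bin_size, s.three_pos // bin_size)
        groups.setdefault(key, []).append(s)
    return {
        key: members
        for key, members in groups.items()
        if len({m.five_pos for m in members}) >= min_unique_offsets
    }


def _stack_columns(members: Sequence[SplitAlignment]) -> list[tuple[str, int]]:
    """Stacking column of each read: reads share the breakpoint, so the
    5'-segment genomic positions give their relative transcript offsets."""
    if members[0].strand == "+":
        lo = min(m.five_pos for m in members)
        return [(m.read_id, m.five_pos - lo) for m in members]
    hi = max(m.five_pos for m in members)
    return [(m.read_id, hi - m.five_pos) for m in members]


def consensus_and_score(members: Sequence[SplitAlignment]) -> tuple[str, float, list[tuple[str, int]]]:
    """Offset-stack the reads; majority consensus and the score S.

    S adds, for each column with two or more overlapping reads, the
    fraction of bases that disagree with the column consensus.  Ties are
    broken lexicographically (and logged).
    """
    cols = _stack_columns(members)
    width = max(c + len(m.seq) for m, (_, c) in zip(members, cols))
    columns: list[dict[str, int]] = [dict() for _ in range(width)]
    for m, (_, c) in zip(members, cols):
        for i, base in enumerate(m.seq):
            col = columns[c + i]
            col[base] = col.get(base, 0) + 1
    consensus_chars: list[str] = []
    score = 0.0
    for col in columns:
        if not col:
            consensus_chars.append("N")
            continue
        top = max(col.values())
        winners = sorted(b for b, n in col.items() if n == top)
        if len(winners) > 1:
            logger.debug("consensus tie among %s; choosing %s", winners, winners[0])
        best = winners[0]
        consensus_chars.append(best)
        depth = sum(col.values())
        if depth >= 2:
            score += (depth - col[best]) / depth
    return "".join(consensus_chars), score, cols


def assemble_bin_pairs(
    splits: Sequence[SplitAlignment],
    bin_size: int = 50,
    min_unique_offsets: int = 3,
) -> list[BinPairAssembly]:
    assemblies = []
    for (chrom, strand, ba, bb), members in sorted(collect_bin_pairs(splits, bin_size, min_unique_offsets).items()):
        consensus, s, cols = consensus_and_score(members)
        assemblies.append(
            BinPairAssembly(
                chrom=chrom, strand=strand, bin_a=ba, bin_b=bb, bin_size=bin_size,
                member_reads=cols, consensus=consensus, score_s=s,
            )
        )
    return assemblies


def _conflicting_columns(members: Sequence[SplitAlignment], min_depth: int = 3,
                         minority_frac: float = 1 / 3) -> int:
    """Columns of depth >= min_depth whose minority fraction exceeds the cut.

    Several such well-supported disagreements indicate reads from more
    than one distinct breakpoint mixed in a single bin pair.
    """
    cols = _stack_columns(members)
    width = max(c + len(m.seq) for m, (_, c) in zip(members, cols))
    counts: list[dict[str, int]] = [dict() for _ in range(width)]
    for m, (_, c) in zip(members, cols):
        for i, base in enumerate(m.seq):
            col = counts[c + i]
            col[base] = col.get(base, 0) + 1
    n_conflict = 0
    for col in counts:
        depth = sum(col.values())
        if depth >= min_depth and (depth - max(col.values())) / depth > minority_frac:
            n_conflict += 1
    return n_conflict


def screen_candidates(
    assemblies: Sequence[BinPairAssembly],
    groups: Mapping[tuple[str, str, int, int], Sequence[SplitAlignment]] | None = None,
    s_max: float = 5.0,
    max_conflicting_columns: int = 1,
) -> list[BinPairAssembly]:
    """Keep assemblies with S strictly below ``s_max`` and a single breakpoint."""
    kept = []
    for a in assemblies:
        if not a.score_s < s_max:
            continue
        if groups is not None:
            members = groups.get((a.chrom, a.strand, a.bin_a, a.bin_b))
            if members and _conflicting_columns(members) > max_conflicting_columns:
                continue
        kept.append(a)
    return kept


# ---------------------------------------------------------------------------
# breakpoint refinement and splice-signal annotation

def _find_fragment(fragment: str, region: str, strand: str, max_mm: int = 1) -> list[int]:
    """Positions (within region) of ungapped matches with <= max_mm mismatches."""
    query = fragment if strand == "+" else revcomp(fragment)
    n, out = len(query), []
    for i in range(len(region) - n + 1):
        mm = 0
        for rb, qb in zip(region[i:i + n], query):
            if rb != qb:
                mm += 1
                if mm > max_mm:
                    break
        else:
            out.append(i)
    return out


def _flanks(genome_seq: str, strand: str, donor_end: int, acceptor_start: int) -> tuple[str, str, bool]:
    """Flanking intronic dinucleotides and the U12 donor-signature flag.

    ``donor_end`` is the 0-based exclusive end of the donor exonic
    segment in transcript orientation; ``acceptor_start`` the 0-based
    start of the acceptor segment.
    """
    if strand == "+":
        donor_di = genome_seq[donor_end:donor_end + 2]
        acceptor_di = genome_seq[acceptor_start - 2:acceptor_start]
        u12 = genome_seq[donor_end + 1:donor_end + 7] == U12_DONOR_SIGNATURE
    else:
        donor_di = revcomp(genome_seq[donor_end - 2:donor_end])
        acceptor_di = revcomp(genome_seq[acceptor_start:acceptor_start + 2])
        u12 = revcomp(genome_seq[donor_end - 7:donor_end - 1]) == U12_DONOR_SIGNATURE
    return donor_di, acceptor_di, u12


def map_breakpoint(
    assembly: BinPairAssembly,
    genome: Mapping[str, str],
    search_pad: int = 500,
    min_fragment: int = 20,
    max_mm: int = 1,
) -> BinPairAssembly | None:
    """Refine the breakpoint by re-mapping every >= 20 nt consensus split.

    Each candidate split is aligned near its bin (within ``search_pad``
    nt); among mappable breakpoints a GT-AG-flanked one is preferred,
    then a U12-signature one.  Returns ``None`` (assembly dropped) when
    no split maps.
    """
    gseq = genome[assembly.chrom].upper()
    bs = assembly.bin_size
    a_lo = max(0, assembly.bin_a * bs - search_pad)
    a_hi = min(len(gseq), (assembly.bin_a + 1) * bs + search_pad)
    b_lo = max(0, assembly.bin_b * bs - search_pad)
    b_hi = min(len(gseq), (assembly.bin_b + 1) * bs + search_pad)
    region_a = gseq[a_lo:a_hi]
    region_b = gseq[b_lo:b_hi]
    consensus = assembly.consensus
    candidates = []
    for split in range(min_fragment, len(consensus) - min_fragment + 1):
        left, right = consensus[:split], consensus[split:]
        if "N" in left or "N" in right:
            continue
        for la in _find_fragment(left, region_a, assembly.strand, max_mm):
            for rb in _find_fragment(right, region_b, assembly.strand, max_mm):
                if assembly.strand == "+":
                    donor_end = a_lo + la + len(left)
                    acceptor_start = b_lo + rb
                    donor_site, acceptor_site = donor_end, acceptor_start + 1
                else:
                    donor_end = a_lo + la
                    acceptor_start = b_lo + rb + len(right)
                    donor_site, acceptor_site = donor_end + 1, acceptor_start
                d_di, a_di, u12_sig = _flanks(gseq, assembly.strand, donor_end, acceptor_start)
                if d_di == "GT" and a_di == "AG":
                    signal = "U2"
                elif u12_sig or (d_di == "AT" and a_di == "AC"):
                    signal = "U12"
                else:
                    signal = "other"
                candidates.append((signal, split, donor_site, acceptor_site, d_di, a_di))
    if not candidates:
        return None
    rank = {"U2": 0, "U12": 1, "other": 2}
    signal, split, donor_site, acceptor_site, d_di, a_di = min(
        candidates, key=lambda c: (rank[c[0]], c[1])
    )
    assembly.breakpoint = (donor_site, acceptor_site)
    assembly.flanking_dinucleotides = (d_di, a_di)
    assembly.signal_class = signal
    assembly.boundary_index = split
    return assembly


def name_and_classify(
    assembly: BinPairAssembly,
    annotation: Sequence[ExonRecord],
    max_distance: int = 1000,
) -> BinPairAssembly:
    """Name the assembly by the nearest gene within 1 kb, else UNAN."""
    if assembly.breakpoint is None:
        raise ValueError("breakpoint must be mapped before naming")
    pos = min(assembly.breakpoint)
    spans: dict[str, tuple[str, int, int]] = {}
    for e in annotation:
        if e.chrom != assembly.chrom:
            continue
        cur = spans.get(e.gene_id)
        spans[e.gene_id] = (
            e.gene_id,
            min(e.start, cur[1]) if cur else e.start,
            max(e.end, cur[2]) if cur else e.end,
        )
    best_name, best_dist = "UNAN", max_distance + 1
    for gene_id, lo, hi in sorted(spans.values()):
        dist = max(lo - pos, pos - hi, 0)
        if dist < best_dist:
            best_name, best_dist = gene_id, dist
    if best_dist > max_distance:
        best_name = "UNAN"
    assembly.name = best_name
    return assembly


# ---------------------------------------------------------------------------
# realignment and final filtering

def _pseudo_junction(assembly: BinPairAssembly) -> AnnotatedJunction:
    """Represent a refined assembly as a junction record for read realignment."""
    d_site, a_site = assembly.breakpoint
    split = assembly.boundary_index
    left_len = split
    right_len = len(assembly.consensus) - split
    if assembly.strand == "+":
        donor = ExonRecord(assembly.chrom, d_site - left_len, d_site, "+", assembly.name, "denovo_d")
        acceptor = ExonRecord(assembly.chrom, a_site - 1, a_site - 1 + right_len, "+", assembly.name, "denovo_a")
    else:
        donor = ExonRecord(assembly.chrom, d_site - 1, d_site - 1 + left_len, "-", assembly.name, "denovo_d")
        acceptor = ExonRecord(assembly.chrom, a_site - right_len, a_site, "-", assembly.name, "denovo_a")
    return AnnotatedJunction(
        junction_id=assembly.junction_id, chrom=assembly.chrom,
        donor_exon=donor, acceptor_exon=acceptor, cls="denovo",
        sequence=assembly.consensus, boundary_index=split,
    )


def realign_and_filter(
    read_pairs: Sequence[tuple[str, str, str]],
    assemblies: Sequence[BinPairAssembly],
    genome: Mapping[str, str],
    min_overlap: int = 10,
    buffer: int = 50,
    naive_threshold: float = 0.9,
    max_decoy_ratio: float = 0.1,
    min_breakpoint_sep: int = 200,
    error_rate: float = 0.01,
) -> tuple[list[JunctionCall], list[ReadFeatureRecord]]:
    """Realign unaligned pairs to consensus junctions and apply final filters.

    Mates are judged with a 50-nt buffer (candidates were located only
    to 50-nt bins); junctions must show a naive mismatch p-value above
    0.9, a decoy/circle ratio below 0.1, and a breakpoint bin separation
    above 200 nt, and are collapsed to unique chromosomal breakpoints.
    """
    from circjunct.align import ReadAligner, align_read_set

    refined = [a for a in assemblies if a.breakpoint is not None]
    if not refined:
        return [], []
    juncs = {a.junction_id: _pseudo_junction(a) for a in refined}
    by_id = {a.junction_id: a for a in refined}
    refs = {jid: j.sequence for jid, j in juncs.items()}
    refs.update(genome)
    kinds = {jid: "denovo_junction" for jid in juncs}
    kinds.update({chrom: "genome" for chrom in genome})

    r1_aligner = ReadAligner({jid: j.sequence for jid, j in juncs.items()},
                             {jid: "denovo_junction" for jid in juncs})
    r2_aligner = ReadAligner(refs, kinds)
    r1_alns, _ = align_read_set(r1_aligner, ((rid, "R1", s1) for rid, s1, _ in read_pairs))
    r2_alns, _ = align_read_set(r2_aligner, ((rid, "R2", s2) for rid, _, s2 in read_pairs))

    boundary_by_jid = {jid: j.boundary_index for jid, j in juncs.items()}
    features: list[ReadFeatureRecord] = []
    by_read1: dict[str, list] = {}
    for a in r1_alns:
        by_read1.setdefault(a.read_id, []).append(a)
    by_read2: dict[str, list] = {}
    for a in r2_alns:
        by_read2.setdefault(a.read_id, []).append(a)
    from circjunct.classify import categorize_pair, compute_offset, resolve_r1, resolve_r2

    for rid in sorted(by_read1):
        # consensus junctions have per-assembly boundaries, so resolve per
        # candidate boundary rather than at a fixed index
        best = None
        for a in sorted(by_read1[rid], key=lambda a: -a.alignment_score):
            off = compute_offset(a.pos, a.aligned_len, boundary_by_jid[a.target_id])
            if off is not None and off >= min_overlap:
                best = (a, off)
                break
        if best is None:
            continue
        anchor, off = best
        r2 = resolve_r2(by_read2.get(rid, []))
        category, _ = categorize_pair(anchor, r2, juncs, buffer=buffer)
        if category is None:
            continue
        features.append(
            ReadFeatureRecord(
                read_id=rid, junction_id=anchor.target_id, category=category,
                offset=int(off), alignment_score=anchor.alignment_score,
                mapq=anchor.mapq, mismatches=anchor.mismatches, junction_cls="denovo",
            )
        )

    counts: dict[str, dict[str, int]] = {}
    mism: dict[str, int] = {}
    bases: dict[str, int] = {}
    for f in features:
        c = counts.setdefault(f.junction_id, {"circular": 0, "decoy": 0, "linear": 0})
        c[f.category] += 1
        if f.category != "decoy":
            mism[f.junction_id] = mism.get(f.junction_id, 0) + f.mismatches
            bases[f.junction_id] = bases.get(f.junction_id, 0) + 100

    calls: list[JunctionCall] = []
    seen_breakpoints: set[tuple[str, int, int]] = set()
    for jid in sorted(counts, key=lambda j: -counts[j]["circular"]):
        a = by_id[jid]
        n_circ = counts[jid]["circular"]
        n_dec = counts[jid]["decoy"]
        if n_circ == 0:
            continue
        p = naive_mismatch_pvalue(mism.get(jid, 0), bases.get(jid, 100), error_rate)
        decoy_ratio = n_dec / n_circ
        sep = abs(a.bin_a - a.bin_b) * a.bin_size
        key = (a.chrom, *a.breakpoint)
        ok = (
            p > naive_threshold
            and decoy_ratio < max_decoy_ratio
            and sep > min_breakpoint_sep
            and key not in seen_breakpoints
        )
        if not ok:
            continue
        seen_breakpoints.add(key)
        calls.append(
            JunctionCall(
                junction_id=jid, cls="denovo", n_reads=n_circ,
                posterior=float("nan"), p_value=p, fdr=float("nan"),
                verdict="pass", decoy_count=n_dec,
                extras={
                    "breakpoint": a.breakpoint,
                    "dinucleotides": a.flanking_dinucleotides,
                    "signal_class": a.signal_class,
                    "score_s": a.score_s,
                    "decoy_ratio": decoy_ratio,
                    "name": a.name,
                },
            )
        )
    return calls, features


def discover_denovo(
    read_pairs: Sequence[tuple[str, str, str]],
    genome: Mapping[str, str],
    annotation: Sequence[ExonRecord] = (),
    segment_trim: int = 65,
    bin_size: int = 50,
    s_max: float = 5.0,
    **filter_kwargs,
) -> tuple[list[JunctionCall], list[BinPairAssembly]]:
    """Full de novo chain: split, bin, assemble, screen, refine, realign."""
    splits = find_split_alignments(
        ((rid, s1) for rid, s1, _ in read_pairs), genome, segment_trim=segment_trim
    )
    groups = collect_bin_pairs(splits, bin_size=bin_size)
    assemblies = assemble_bin_pairs(splits, bin_size=bin_size)
    assemblies = screen_candidates(assemblies, groups=groups, s_max=s_max)
    refined = []
    for a in assemblies:
        r = map_breakpoint(a, genome)
        if r is not None:
            refined.append(name_and_classify(r, annotation))
    calls, _ = realign_and_filter(read_pairs, refined, genome, **filter_kwargs)
    return calls, refined
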