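"""Built-in ungapped read placement for desk-scale genomes.

This is a deliberately small exact/low-mismatch matcher, not a general
read aligner: it places reads and read segments on toy genomes and
junction databases so the full pipeline can run end to end without an
external aligner.  Placement is ungapped and full-length, found by a
pigeonhole seed scheme (a query with at most m mismatches must contain
at least one exact chunk when split into m+1 chunks).  Reference Ns
(junction padding) match any base at no penalty, mirroring the
near-zero N penalty used when aligning against padded junction
references.  Scores are Bowtie2-like: 0 for a perfect hit minus 6 per
mismatch; mapping quality reflects the score gap between the best and
second-best placement within a reference set.

For real genomes users supply precomputed alignments (SAM or TSV)
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from circjunct.classify import MISMATCH_PENALTY, AlignmentRecord
from circjunct.index import revcomp

MAX_MAPQ = 42.0


@dataclass(frozen=True)
class Placement:
    ref_name: str
    pos: int
    strand: str
    mismatches: int

    @property
    def score(self) -> float:
        return -MISMATCH_PENALTY * self.mismatches


class SeedMatcher:
    """Exact-chunk seeded search for ungapped placements with <= m mismatches."""

    def __init__(self, references: Mapping[str, str]):
        self.refs = {name: seq.upper() for name, seq in references.items()}
        self._kmer_cache: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _kmer_index(self, k: int) -> dict[str, list[tuple[str, int]]]:
        idx = self._kmer_cache.get(k)
        if idx is None:
            idx = {}
            for name, seq in self.refs.items():
                for i in range(len(seq) - k + 1):
                    kmer = seq[i:i + k]
                    if "N" in kmer:
                        continue
                    idx.setdefault(kmer, []).append((name, i))
            self._kmer_cache[k] = idx
        return idx

    @staticmethod
    def _count_mismatches(ref: str, pos: int, query: str, limit: int) -> int | None:
        mm = 0
        for rb, qb in zip(ref[pos:pos + len(query)], query):
            if rb != qb and rb != "N":
                mm += 1
                if mm > limit:
                    return None
        return mm

    def _find_oriented(self, query: str, max_mm: int) -> dict[tuple[str, int], int]:
        n = len(query)
        n_chunks = max_mm + 1
        k = n // n_chunks
        if k < 4:
            raise ValueError("query too short for the requested mismatch tolerance")
        idx = self._kmer_index(k)
        hits: dict[tuple[str, int], int] = {}
        for c in range(n_chunks):
            off = c * k
            for name, i in idx.get(query[off:off + k], ()):
                pos = i - off
                key = (name, pos)
                if key in hits or pos < 0 or pos + n > len(self.refs[name]):
                    continue
                mm = self._count_mismatches(self.refs[name], pos, query, max_mm)
                if mm is not None:
                    hits[key] = mm
        return hits

    def find(self, query: str, max_mm: int = 0, both_strands: bool = True) -> list[Placement]:
        """All full-length ungapped placements of ``query`` with <= max_mm mismatches."""
        query = query.upper()
        out = [
            Placement(name, pos, "+", mm)
            for (name, pos), mm in self._find_oriented(query, max_mm).items()
        ]
        if both_strands:
            out += [
                Placement(name, pos, "-", mm)
                for (name, pos), mm in self._find_oriented(revcomp(query), max_mm).items()
            ]
        out.sort(key=lambda p: (p.mismatches, p.ref_name, p.pos, p.strand))
        return out


def _mapqs(placements: Sequence[Placement]) -> list[float]:
    """Mapping quality from the score gap to the second-best placement."""
    if not placements:
        return []
    scores = sorted((p.score for p in placements), reverse=True)
    best = scores[0]
    second = scores[1] if len(scores) > 1 else None
    out = []
    for p in placements:
        if p.score < best:
            out.append(3.0)
        elif second is None:
            out.append(MAX_MAPQ)
        else:
            gap = best - second
            out.append(min(MAX_MAPQ, 3.0 + gap * (MAX_MAPQ - 3.0) / (4 * MISMATCH_PENALTY)))
    return out


class ReadAligner:
    """Align reads against the genome and junction references jointly.

    ``kind_of`` maps each reference name to its target kind (genome,
    rRNA, linear_junction, scrambled_junction, denovo_junction); mapping
    quality is assessed within each kind, as separate indexes would.
    """

    def __init__(self, references: Mapping[str, str], kind_of: Mapping[str, str],
                 max_mismatch_per_100: float = 4.0):
        self.matcher = SeedMatcher(references)
        self.kind_of = dict(kind_of)
        self.max_mismatch_per_100 = max_mismatch_per_100

    def align(self, read_id: str, mate: str, seq: str) -> list[AlignmentRecord]:
        max_mm = int(self.max_mismatch_per_100 * len(seq) / 100)
        placements = self.matcher.find(seq, max_mm=max_mm)
        by_kind: dict[str, list[Placement]] = {}
        for p in placements:
            by_kind.setdefault(self.kind_of[p.ref_name], []).append(p)
        records: list[AlignmentRecord] = []
        for kind, group in by_kind.items():
            # one reported alignment per reference, as an aligner would emit
            best_per_ref: dict[str, Placement] = {}
            for p in group:
                cur = best_per_ref.get(p.ref_name)
                if cur is None or p.mismatches < cur.mismatches:
                    best_per_ref[p.ref_name] = p
            chosen = sorted(best_per_ref.values(), key=lambda p: (p.mismatches, p.ref_name))
            mapqs = _mapqs(chosen)
            for p, q in zip(chosen, mapqs):
                records.append(
                    AlignmentRecord(
                        read_id=read_id, mate=mate, target_kind=kind, target_id=p.ref_name,
                        pos=p.pos, aligned_len=len(seq), alignment_score=p.score,
                        mapq=q, mismatches=p.mismatches, strand=p.strand,
                    )
                )
        return records


def align_read_set(
    aligner: ReadAligner,
    reads: Iterable[tuple[str, str, str]],
) -> tuple[list[AlignmentRecord], list[str]]:
    """Align (read_id, mate, sequence) triples; also return unaligned read ids."""
    records: list[AlignmentRecord] = []
    unaligned: list[str] = []
    for read_id, mate, seq in reads:
        recs = aligner.align(read_id, mate, seq)
        if recs:
            records.extend(recs)
        else:
            unaligned.append(read_id)
    return records, unaligned
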