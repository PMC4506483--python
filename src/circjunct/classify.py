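"""Classification of junction-anchored read pairs as linear, circular, or decoy.

R1 and R2 of each pair are aligned independently (as single-end reads) to
the genome and the junction databases.  An R1 that spans a junction
boundary anchors the pair; the mate's placement then decides the
category.  A linear-junction anchor with a concordant mate supports a
linear transcript.  A scrambled-junction anchor is ``circular`` when the
mate falls inside the genomic region of the presumed circle (the span of
the two junctional exons plus a small buffer for reverse-transcription
artifacts) and ``decoy`` otherwise.  Decoys are read pairs whose
geometry is consistent with neither a linear nor a circular transcript;
they are the artifact training class for the GLM scorer rather than
being discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from circjunct.index import AnnotatedJunction

#: Bowtie2-style mismatch penalty used to express the minimum acceptable
#: alignment score as a mismatch-equivalent rate per 100 nt.
MISMATCH_PENALTY = 6.0

TARGET_KINDS = ("genome", "rRNA", "linear_junction", "scrambled_junction", "denovo_junction")
_JUNCTION_KINDS = ("linear_junction", "scrambled_junction", "denovo_junction")
_R2_TIE_ORDER = {"genome": 0, "rRNA": 1, "linear_junction": 2, "scrambled_junction": 3, "denovo_junction": 4}


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    mate: str  # R1 | R2
    target_kind: str
    target_id: str
    pos: int  # 0-based position on target
    aligned_len: int
    alignment_score: float
    mapq: float
    mismatches: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.aligned_len <= 0:
            raise ValueError("aligned_len must be positive")
        if self.mismatches < 0:
            raise ValueError("mismatches must be non-negative")


@dataclass(frozen=True)
class ReadFeatureRecord:
    """R1 features of one categorized pair; GLM predictors come from R1 only."""

    read_id: str
    junction_id: str
    category: str  # linear | circular | decoy
    offset: int
    alignment_score: float
    mapq: float
    mismatches: int
    junction_cls: str = ""  # linear | scrambled | denovo


@dataclass(frozen=True)
class CircleRegion:
    chrom: str
    lo: int
    hi: int
    buffer: int = 15

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("lo must be <= hi")

    def contains(self, pos: int) -> bool:
        return self.lo <= pos <= self.hi


# ---------------------------------------------------------------------------
# scoring threshold

def min_alignment_score(aligned_len: int, max_mismatch_per_100: float = 4.0) -> float:
    """Minimum acceptable score: up to 4 mismatch-equivalents per 100 nt."""
    return -MISMATCH_PENALTY * max_mismatch_per_100 * aligned_len / 100.0


def passes_score(aln: AlignmentRecord, max_mismatch_per_100: float = 4.0) -> bool:
    return aln.alignment_score >= min_alignment_score(aln.aligned_len, max_mismatch_per_100)


# ---------------------------------------------------------------------------
# offsets

def compute_offset(pos: int, aligned_len: int, boundary_index: int = 150) -> int | None:
    """Nucleotides of boundary overlap: min of the two flank lengths.

    Returns ``None`` when the alignment does not cross the boundary.
    """
    left = boundary_index - pos
    right = pos + aligned_len - boundary_index
    if left <= 0 or right <= 0:
        return None
    return min(left, right)


# ---------------------------------------------------------------------------
# R1/R2 resolution

def resolve_r1(
    alignments: Sequence[AlignmentRecord],
    min_overlap: int = 10,
    max_mismatch_per_100: float = 4.0,
    boundary_index: int = 150,
) -> tuple[AlignmentRecord | None, str]:
    """Pick the junction anchor for R1, or discard with a reason code.

    R1 is discarded outright if it has a high-scoring genome or rRNA
    alignment.  Among junction alignments passing the score threshold,
    a linear-junction alignment takes precedence over a scrambled one;
    the anchor must overlap the boundary by at least ``min_overlap``.
    """
    if not alignments:
        return None, "no_alignment"
    rid = alignments[0].read_id
    if any(a.read_id != rid or a.mate != "R1" for a in alignments):
        raise ValueError("resolve_r1 expects alignments of a single R1")

    for a in alignments:
        if a.target_kind in ("genome", "rRNA") and passes_score(a, max_mismatch_per_100):
            return None, f"{a.target_kind}_alignment"

    candidates = [
        a for a in alignments
        if a.target_kind in _JUNCTION_KINDS and passes_score(a, max_mismatch_per_100)
    ]
    if not candidates:
        return None, "no_junction_alignment"

    linear = [a for a in candidates if a.target_kind == "linear_junction"]
    pool = linear if linear else candidates
    anchor = max(pool, key=lambda a: a.alignment_score)
    off = compute_offset(anchor.pos, anchor.aligned_len, boundary_index)
    if off is None or off < min_overlap:
        return None, "insufficient_overlap"
    return anchor, "anchored"


def resolve_r2(alignments: Sequence[AlignmentRecord]) -> AlignmentRecord | None:
    """Best R2 alignment by score; ties prefer genome, then linear, then scrambled."""
    if not alignments:
        return None
    rid = alignments[0].read_id
    if any(a.read_id != rid or a.mate != "R2" for a in alignments):
        raise ValueError("resolve_r2 expects alignments of a single R2")
    return min(alignments, key=lambda a: (-a.alignment_score, _R2_TIE_ORDER.get(a.target_kind, 9)))


# ---------------------------------------------------------------------------
# circle geometry and pair categorization

def circle_region(j: AnnotatedJunction, buffer: int = 15) -> CircleRegion:
    """Genomic region of the presumed circle: the exon span plus a buffer.

    The circle may include or exclude any introns/exons between the
    junctional exons, so the region is the full min-to-max coordinate
    span of the two exons, expanded by ``buffer`` on each side.
    """
    if j.cls == "linear":
        raise ValueError("circle_region is defined only for scrambled/denovo junctions")
    lo = min(j.donor_exon.start, j.acceptor_exon.start) - buffer
    hi = max(j.donor_exon.end, j.acceptor_exon.end) + buffer
    return CircleRegion(chrom=j.chrom, lo=lo, hi=hi, buffer=buffer)


def project_to_genome(
    aln: AlignmentRecord,
    junctions_by_id: Mapping[str, AnnotatedJunction],
) -> tuple[str, int, int, str] | None:
    """Project an alignment onto the genome as (chrom, lo, hi, strand).

    Genome alignments project to themselves.  For a junction alignment
    the covered reference interval is split at the boundary and each
    side is mapped back into its exon (N-padding clipped); the genomic
    strand is the junction strand flipped if the read aligned in
    reverse.
    """
    if aln.target_kind == "genome":
        return aln.target_id, aln.pos, aln.pos + aln.aligned_len, aln.strand
    j = junctions_by_id.get(aln.target_id)
    if j is None:
        return None
    b = j.boundary_index
    left = max(0, min(b - aln.pos, aln.aligned_len))
    right = max(0, min(aln.pos + aln.aligned_len - b, aln.aligned_len))
    left = min(left, j.donor_exon.length)
    right = min(right, j.acceptor_exon.length)
    intervals = []
    d, a = j.donor_exon, j.acceptor_exon
    if left > 0:
        if j.strand == "+":
            intervals.append((d.end - left, d.end))
        else:
            intervals.append((d.start, d.start + left))
    if right > 0:
        if j.strand == "+":
            intervals.append((a.start, a.start + right))
        else:
            intervals.append((a.end - right, a.end))
    if not intervals:
        return None
    lo = min(s for s, _ in intervals)
    hi = max(e for _, e in intervals)
    if aln.strand == "+":
        strand = j.strand
    else:
        strand = "-" if j.strand == "+" else "+"
    return j.chrom, lo, hi, strand


def categorize_pair(
    anchor: AlignmentRecord,
    r2: AlignmentRecord | None,
    junctions_by_id: Mapping[str, AnnotatedJunction],
    buffer: int = 15,
    max_fragment: int = 1000,
) -> tuple[str | None, str]:
    """Categorize one R1-anchored pair as linear, circular, or decoy.

    Returns (category, reason); category is ``None`` when the pair is
    unusable (no mate, or a discordant linear anchor).
    """
    j = junctions_by_id.get(anchor.target_id)
    if j is None:
        return None, "unknown_junction"
    if r2 is None:
        return None, "no_mate"
    p1 = project_to_genome(anchor, junctions_by_id)
    p2 = project_to_genome(r2, junctions_by_id)
    if p1 is None or p2 is None:
        return None, "unprojectable"
    chrom1, lo1, hi1, strand1 = p1
    chrom2, lo2, hi2, strand2 = p2

    if j.cls == "linear":
        if chrom1 != chrom2:
            return None, "discordant_chrom"
        if strand1 == strand2:
            return None, "discordant_strand"
        gap = max(lo1, lo2) - min(hi1, hi2)
        if max(hi1, hi2) - min(lo1, lo2) > max_fragment and gap > max_fragment:
            return None, "discordant_span"
        return "linear", "concordant"

    region = circle_region(j, buffer)
    if chrom2 != region.chrom:
        return "decoy", "other_chromosome"
    if strand1 == strand2:
        return "decoy", "same_orientation"
    if lo2 >= region.lo and hi2 <= region.hi:
        return "circular", "inside_circle"
    return "decoy", "outside_circle"


def build_feature_records(
    r1_alignments: Iterable[AlignmentRecord],
    r2_alignments: Iterable[AlignmentRecord],
    junctions_by_id: Mapping[str, AnnotatedJunction],
    min_overlap: int = 10,
    max_mismatch_per_100: float = 4.0,
    buffer: int = 15,
    max_fragment: int = 1000,
    boundary_index: int = 150,
) -> tuple[list[ReadFeatureRecord], dict[str, int]]:
    """Run anchor resolution and pair categorization over all read pairs.

    Returns the retained feature records plus a tally of drop reasons.
    """
    by_r1: dict[str, list[AlignmentRecord]] = {}
    for a in r1_alignments:
        by_r1.setdefault(a.read_id, []).append(a)
    by_r2: dict[str, list[AlignmentRecord]] = {}
    for a in r2_alignments:
        by_r2.setdefault(a.read_id, []).append(a)

    records: list[ReadFeatureRecord] = []
    reasons: dict[str, int] = {}
    for rid in sorted(by_r1):
        anchor, why = resolve_r1(by_r1[rid], min_overlap, max_mismatch_per_100, boundary_index)
        if anchor is None:
            reasons[why] = reasons.get(why, 0) + 1
            continue
        r2 = resolve_r2(by_r2.get(rid, []))
        category, why = categorize_pair(anchor, r2, junctions_by_id, buffer, max_fragment)
        if category is None:
            reasons[why] = reasons.get(why, 0) + 1
            continue
        j = junctions_by_id[anchor.target_id]
        off = compute_offset(anchor.pos, anchor.aligned_len, boundary_index)
        records.append(
            ReadFeatureRecord(
                read_id=rid,
                junction_id=anchor.target_id,
                category=category,
                offset=int(off),
                alignment_score=anchor.alignment_score,
                mapq=anchor.mapq,
                mismatches=anchor.mismatches,
                junction_cls=j.cls,
            )
        )
        reasons[category] = reasons.get(category, 0) + 1
    return records, reasons


# ---------------------------------------------------------------------------
# I/O: SAM and TSV dialects

def read_sam_alignments(
    path: str | Path,
    mate: str,
    junctions_by_id: Mapping[str, AnnotatedJunction] | None = None,
    rrna_names: Sequence[str] = (),
) -> list[AlignmentRecord]:
    """Ingest single-end alignments from SAM; AS->score, NM->mismatches.

    The target kind is inferred from the reference name: junction ids
    map to their class, names in ``rrna_names`` to rRNA, and everything
    else to the genome.
    """
    import pysam

    junctions_by_id = junctions_by_id or {}
    rrna = set(rrna_names)
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            ref = rec.reference_name
            j = junctions_by_id.get(ref)
            if j is not None:
                kind = {"linear": "linear_junction", "scrambled": "scrambled_junction"}.get(
                    j.cls, "denovo_junction"
                )
            elif ref in rrna:
                kind = "rRNA"
            else:
                kind = "genome"
            out.append(
                AlignmentRecord(
                    read_id=rec.query_name,
                    mate=mate,
                    target_kind=kind,
                    target_id=ref,
                    pos=int(rec.reference_start),
                    aligned_len=int(rec.query_alignment_length),
                    alignment_score=float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0,
                    mapq=float(rec.mapping_quality),
                    mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    strand="-" if rec.is_reverse else "+",
                )
            )
    return out


_ALN_COLS = [
    "read_id", "mate", "target_kind", "target_id", "pos",
    "aligned_len", "aln_score", "mapq", "mismatches", "strand",
]


def read_alignment_tsv(path: str | Path) -> list[AlignmentRecord]:
    """Aligner-free TSV dialect with the documented alignment columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_ALN_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment TSV missing columns: {sorted(missing)}")
    return [
        AlignmentRecord(
            read_id=str(r.read_id), mate=str(r.mate), target_kind=str(r.target_kind),
            target_id=str(r.target_id), pos=int(r.pos), aligned_len=int(r.aligned_len),
            alignment_score=float(r.aln_score), mapq=float(r.mapq),
            mismatches=int(r.mismatches), strand=str(r.strand),
        )
        for r in df.itertuples(index=False)
    ]


def write_alignment_tsv(alignments: Iterable[AlignmentRecord], path: str | Path) -> None:
    rows = [
        (a.read_id, a.mate, a.target_kind, a.target_id, a.pos,
         a.aligned_len, a.alignment_score, a.mapq, a.mismatches, a.strand)
        for a in alignments
    ]
    pd.DataFrame(rows, columns=_ALN_COLS).to_csv(path, sep="\t", index=False)


_FEATURE_COLS = ["read_id", "junction_id", "category", "offset", "aln_score", "mapq", "mismatches", "junction_cls"]


def write_feature_tsv(records: Iterable[ReadFeatureRecord], path: str | Path) -> None:
    rows = [
        (r.read_id, r.junction_id, r.category, r.offset,
         r.alignment_score, r.mapq, r.mismatches, r.junction_cls)
        for r in records
    ]
    pd.DataFrame(rows, columns=_FEATURE_COLS).to_csv(path, sep="\t", index=False)


def read_feature_tsv(path: str | Path) -> list[ReadFeatureRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "junction_cls" not in df.columns:
        df["junction_cls"] = ""
    return [
        ReadFeatureRecord(
            read_id=str(r.read_id), junction_id=str(r.junction_id), category=str(r.category),
            offset=int(r.offset), alignment_score=float(r.aln_score), mapq=float(r.mapq),
            mismatches=int(r.mismatches), junction_cls=str(r.junction_cls),
        )
        for r in df.itertuples(index=False)
    ]
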