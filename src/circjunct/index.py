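"""Linear and scrambled junction database construction.

A junction reference sequence is built from 150 nt on each side of the
splice boundary (the transcript-orientation 3' end of the donor exon and
5' end of the acceptor exon).  Exons shorter than 150 nt are padded with
Ns distal to the boundary so that every junction sequence is exactly
300 nt with the boundary fixed at index 150.  Fixed-length references
remove the alignment bias against circles formed from short exons.

All exon pairs on the same chromosome and strand whose starts lie within
a sliding window (default 1 Mb) produce one junction in canonical
transcript order (``linear``) and one in inverted order (``scrambled``);
each single exon additionally produces a scrambled self-junction
representing circularization of that exon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ExonRecord:
    """One exon interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    exon_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"exon {self.exon_id}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"exon {self.exon_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotatedJunction:
    """A donor/acceptor exon pair and its fixed-length reference sequence.

    ``junction_id`` is "chrom:pos5:pos3:strand" where pos5/pos3 are the
    1-based genomic positions of the donor and acceptor splice sites.
    ``boundary_index`` is the 0-based index of the first acceptor-side
    base within ``sequence`` (always ``pad_side``, 150 by default).
    """

    junction_id: str
    chrom: str
    donor_exon: ExonRecord
    acceptor_exon: ExonRecord
    cls: str  # linear | scrambled | denovo
    sequence: str
    boundary_index: int
    cross_gene: bool = False

    @property
    def strand(self) -> str:
        return self.donor_exon.strand


@dataclass
class JunctionSet:
    linear: list[AnnotatedJunction] = field(default_factory=list)
    scrambled: list[AnnotatedJunction] = field(default_factory=list)
    window: int = 1_000_000
    pad_side: int = 150

    def __len__(self) -> int:
        return len(self.linear) + len(self.scrambled)

    def all(self) -> list[AnnotatedJunction]:
        return list(self.linear) + list(self.scrambled)

    def by_id(self) -> dict[str, AnnotatedJunction]:
        return {j.junction_id: j for j in self.all()}


# ---------------------------------------------------------------------------
# annotation and genome access

def read_gtf_exons(path: str | Path) -> list[ExonRecord]:
    """Read exon records from a GTF file (collapsed over transcripts)."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    if df.empty:
        return []
    df = df[df.Feature == "exon"]
    out: list[ExonRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        exon_id = getattr(row, "exon_id", None) or f"exon{i}"
        out.append(
            ExonRecord(
                chrom=str(row.Chromosome),
                start=int(row.Start),
                end=int(row.End),
                strand=str(row.Strand),
                gene_id=str(row.gene_id),
                exon_id=str(exon_id),
            )
        )
    return out


def read_bed12_exons(path: str | Path) -> list[ExonRecord]:
    """Read exon records from a BED12 file (blocks become exons)."""
    names = [
        "chrom", "start", "end", "name", "score", "strand",
        "thickStart", "thickEnd", "rgb", "blockCount", "blockSizes", "blockStarts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    out: list[ExonRecord] = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        for k, (bs, sz) in enumerate(zip(starts, sizes)):
            s = int(row.start) + bs
            out.append(
                ExonRecord(
                    chrom=str(row.chrom),
                    start=s,
                    end=s + sz,
                    strand=str(row.strand),
                    gene_id=str(row.name),
                    exon_id=f"{row.name}.e{k + 1}",
                )
            )
    return out


def open_genome(source) -> Mapping[str, str]:
    """Return a chrom -> sequence mapping from a dict, FASTA path, or pyfaidx.Fasta."""
    if isinstance(source, Mapping):
        return source
    import pyfaidx

    if isinstance(source, pyfaidx.Fasta):
        fa = source
    else:
        fa = pyfaidx.Fasta(str(source))
    return {name: str(fa[name][:]) for name in fa.keys()}


def _fetch(genome: Mapping[str, str], exon: ExonRecord) -> str:
    try:
        chrom_seq = genome[exon.chrom]
    except KeyError:
        raise ValueError(f"exon {exon.exon_id}: chromosome {exon.chrom} not in genome") from None
    if exon.start < 0 or exon.end > len(chrom_seq):
        raise ValueError(
            f"exon {exon.exon_id} ({exon.chrom}:{exon.start}-{exon.end}) "
            f"outside genome bounds (length {len(chrom_seq)})"
        )
    return chrom_seq[exon.start:exon.end].upper()


# ---------------------------------------------------------------------------
# junction construction

def classify_pair_order(a: ExonRecord, b: ExonRecord) -> str:
    """Classify the junction with donor ``a`` and acceptor ``b``.

    ``linear`` iff the donor precedes the acceptor in transcript
    orientation; a self-pair is ``scrambled`` (a single-exon circle).
    """
    if a.chrom != b.chrom or a.strand != b.strand:
        raise ValueError("exon pair must share chromosome and strand")
    if (a.chrom, a.start, a.end) == (b.chrom, b.start, b.end):
        return "scrambled"
    if a.strand == "+":
        return "linear" if a.start < b.start else "scrambled"
    return "linear" if a.start > b.start else "scrambled"


def donor_site(exon: ExonRecord) -> int:
    """1-based genomic position of the donor splice site (last exonic base)."""
    return exon.end if exon.strand == "+" else exon.start + 1


def acceptor_site(exon: ExonRecord) -> int:
    """1-based genomic position of the acceptor splice site (first exonic base)."""
    return exon.start + 1 if exon.strand == "+" else exon.end


def _donor_side_seq(genome: Mapping[str, str], exon: ExonRecord, pad: int) -> str:
    """Last ``pad`` transcript-orientation nt of the exon, N-padded distally."""
    take = min(pad, exon.length)
    if exon.strand == "+":
        seq = genome[exon.chrom][exon.end - take:exon.end].upper()
    else:
        seq = revcomp(genome[exon.chrom][exon.start:exon.start + take].upper())
    return "N" * (pad - take) + seq


def _acceptor_side_seq(genome: Mapping[str, str], exon: ExonRecord, pad: int) -> str:
    """First ``pad`` transcript-orientation nt of the exon, N-padded distally."""
    take = min(pad, exon.length)
    if exon.strand == "+":
        seq = genome[exon.chrom][exon.start:exon.start + take].upper()
    else:
        seq = revcomp(genome[exon.chrom][exon.end - take:exon.end].upper())
    return seq + "N" * (pad - take)


def make_junction(
    genome: Mapping[str, str],
    donor: ExonRecord,
    acceptor: ExonRecord,
    pad_side: int = 150,
    cls: str | None = None,
) -> AnnotatedJunction:
    """Assemble the junction of ``donor`` spliced into ``acceptor``."""
    _fetch(genome, donor)
    _fetch(genome, acceptor)
    if cls is None:
        cls = classify_pair_order(donor, acceptor)
    seq = _donor_side_seq(genome, donor, pad_side) + _acceptor_side_seq(genome, acceptor, pad_side)
    jid = f"{donor.chrom}:{donor_site(donor)}:{acceptor_site(acceptor)}:{donor.strand}"
    return AnnotatedJunction(
        junction_id=jid,
        chrom=donor.chrom,
        donor_exon=donor,
        acceptor_exon=acceptor,
        cls=cls,
        sequence=seq,
        boundary_index=pad_side,
        cross_gene=donor.gene_id != acceptor.gene_id,
    )


def dedupe_exons(exons: Iterable[ExonRecord]) -> list[ExonRecord]:
    """Collapse exons sharing (chrom, start, end, strand) across transcripts."""
    seen: dict[tuple, ExonRecord] = {}
    for e in exons:
        seen.setdefault((e.chrom, e.start, e.end, e.strand), e)
    return list(seen.values())


def build_junction_db(
    exons: Sequence[ExonRecord],
    genome,
    window: int = 1_000_000,
    pad_side: int = 150,
) -> JunctionSet:
    """Build the full linear + scrambled junction database.

    Every same-strand exon pair whose start coordinates are within
    ``window`` yields one linear and one scrambled junction; every exon
    yields one scrambled self-junction.  Pairs spanning different genes
    are kept and flagged ``cross_gene``.
    """
    genome = open_genome(genome)
    exons = dedupe_exons(exons)
    js = JunctionSet(window=window, pad_side=pad_side)
    if not exons:
        warnings.warn("empty annotation: junction database is empty", stacklevel=2)
        return js

    groups: dict[tuple[str, str], list[ExonRecord]] = {}
    for e in exons:
        groups.setdefault((e.chrom, e.strand), []).append(e)

    for (_, strand), group in sorted(groups.items()):
        group.sort(key=lambda e: (e.start, e.end))
        for i, a in enumerate(group):
            js.scrambled.append(make_junction(genome, a, a, pad_side, cls="scrambled"))
            for b in group[i + 1:]:
                if abs(b.start - a.start) > window:
                    break
                # a upstream of b in genome; transcript order depends on strand
                up, down = (a, b) if strand == "+" else (b, a)
                js.linear.append(make_junction(genome, up, down, pad_side, cls="linear"))
                js.scrambled.append(make_junction(genome, down, up, pad_side, cls="scrambled"))
    return js


# ---------------------------------------------------------------------------
# FASTA round-trip

def write_junction_fasta(js: JunctionSet, outdir: str | Path) -> dict[str, Path]:
    """Write one FASTA per class; headers carry id|class|exon metadata."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cls, juncs in (("linear", js.linear), ("scrambled", js.scrambled)):
        path = outdir / f"{cls}_junctions.fa"
        records = []
        for j in juncs:
            d, a = j.donor_exon, j.acceptor_exon
            desc = (
                f"cls={j.cls} donor={d.gene_id},{d.exon_id},{d.start},{d.end} "
                f"acceptor={a.gene_id},{a.exon_id},{a.start},{a.end} "
                f"boundary={j.boundary_index} cross_gene={int(j.cross_gene)}"
            )
            records.append(SeqRecord(Seq(j.sequence), id=j.junction_id, description=desc))
        SeqIO.write(records, str(path), "fasta")
        paths[cls] = path
    return paths


def read_junction_fasta(outdir: str | Path, window: int = 1_000_000) -> JunctionSet:
    """Inverse of :func:`write_junction_fasta`."""
    from Bio import SeqIO

    outdir = Path(outdir)
    js = JunctionSet(window=window)
    for cls in ("linear", "scrambled"):
        path = outdir / f"{cls}_junctions.fa"
        if not path.exists():
            continue
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = dict(kv.split("=", 1) for kv in rec.description.split()[1:])
            chrom, _, _, strand = rec.id.rsplit(":", 3)

            def _exon(key: str) -> ExonRecord:
                gene, exid, s, e = fields[key].split(",")
                return ExonRecord(chrom, int(s), int(e), strand, gene, exid)

            j = AnnotatedJunction(
                junction_id=rec.id,
                chrom=chrom,
                donor_exon=_exon("donor"),
                acceptor_exon=_exon("acceptor"),
                cls=fields["cls"],
                sequence=str(rec.seq),
                boundary_index=int(fields["boundary"]),
                cross_gene=bool(int(fields.get("cross_gene", "0"))),
            )
            js.pad_side = j.boundary_index
            getattr(js, cls).append(j)
    return js
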