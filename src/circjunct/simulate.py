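"""Synthetic genomes, read pairs, feature tables, and count tables.

The generator produces desk-scale inputs exhibiting the phenomena the
pipeline is built to handle: paired-end reads from linear and circular
isoforms (circular templates wrap around the backsplice, so small
circles yield doubly-junctional reads), per-base substitution
sequencing errors, homologous exon pairs differing by a few bases
(whose convolution with errors produces decoy and false-positive
circular alignments), aligner-free read feature tables with the
linear-vs-decoy contrasts seen in real data (decoys skew to small
boundary offsets, depressed alignment scores, and low mapping quality),
and multi-timepoint count tables with planted induction slopes.  Every
entry point is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from circjunct.classify import ReadFeatureRecord
from circjunct.index import ExonRecord, revcomp

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Geometry and rates for the toy genome / read simulator.

    Defaults give a compact genome whose reads exercise every read
    category: several multi-exon genes, one homologous exon pair
    (``homolog_pairs`` copies of exon 2 pasted onto exon 3 with
    ``homolog_divergence`` substitutions, mirroring ALU-derived exon
    homology), one circular isoform per gene spanning exons 2-3, and an
    Illumina-like 1% substitution error rate.
    """

    seed: int = 0
    n_genes: int = 4
    exons_per_gene: int = 4
    exon_len: int = 300
    intron_len: int = 500
    intergenic_len: int = 800
    homolog_pairs: int = 2
    homolog_divergence: int = 2
    circle_exons: tuple[int, int] = (0, 0)  # 0-based exon index range, inclusive
    frags_linear_per_gene: int = 60
    frags_circular_per_gene: int = 40
    artifact_frags_per_homolog: int = 30
    artifact_decoy_fraction: float = 0.5
    artifact_extra_errors: int = 4
    read_len: int = 100
    fragment_mean: float = 250.0
    fragment_sd: float = 30.0
    error_rate: float = 0.01
    chrom: str = "chr1"

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# genome

def simulate_genome(cfg: SimConfig) -> tuple[dict[str, str], list[ExonRecord], dict]:
    """Random genome with planted genes, GT-AG introns, and homologous exons.

    Returns (genome, exons, truth) where truth records the circle
    planted in each gene and the homologous exon pairs.
    """
    rng = cfg.rng()
    gene_span = cfg.exons_per_gene * cfg.exon_len + (cfg.exons_per_gene - 1) * cfg.intron_len
    genome_len = cfg.n_genes * (gene_span + cfg.intergenic_len) + cfg.intergenic_len
    seq = rng.choice(BASES, size=genome_len)

    exons: list[ExonRecord] = []
    truth: dict = {"circles": {}, "homologs": [], "genome_len": genome_len}
    pos = cfg.intergenic_len
    for g in range(cfg.n_genes):
        gene_id = f"gene{g + 1}"
        gene_exons = []
        for e in range(cfg.exons_per_gene):
            start = pos + e * (cfg.exon_len + cfg.intron_len)
            end = start + cfg.exon_len
            if end > genome_len:
                raise ValueError("gene geometry exceeds genome length")
            gene_exons.append(ExonRecord(cfg.chrom, start, end, "+", gene_id, f"{gene_id}.e{e + 1}"))
            if e < cfg.exons_per_gene - 1:
                # canonical U2 splice signals in the intron
                seq[end], seq[end + 1] = "G", "T"
                intron_end = end + cfg.intron_len
                seq[intron_end - 2], seq[intron_end - 1] = "A", "G"
        exons.extend(gene_exons)
        lo_i, hi_i = cfg.circle_exons
        hi_i = min(hi_i, cfg.exons_per_gene - 1)
        truth["circles"][gene_id] = (lo_i, hi_i)
        pos += gene_span + cfg.intergenic_len

    # paste exon 2 onto exon 3 (within-gene homology) with d substitutions
    # at fixed quarter positions, so each junction flank carries exactly one
    # discriminating base within read range of the boundary
    by_gene: dict[str, list[ExonRecord]] = {}
    for e in exons:
        by_gene.setdefault(e.gene_id, []).append(e)
    div_positions = _divergence_positions(cfg.exon_len, cfg.homolog_divergence)
    for g in range(min(cfg.homolog_pairs, cfg.n_genes)):
        ge = by_gene[f"gene{g + 1}"]
        if len(ge) < 3:
            continue
        src, dst = ge[1], ge[2]
        seq[dst.start:dst.end] = seq[src.start:src.end]
        for p in div_positions:
            old = seq[dst.start + p]
            seq[dst.start + p] = rng.choice([b for b in BASES if b != old])
        truth["homologs"].append((src.exon_id, dst.exon_id))
    truth["divergence_positions"] = div_positions

    genome = {cfg.chrom: "".join(seq)}
    return genome, exons, truth


def _divergence_positions(exon_len: int, d: int) -> list[int]:
    """Fixed substitution positions for a homolog pair.

    The first two sit at the quarter points (one within 150 nt of each
    exon end, i.e. inside the junction flanks); further positions are
    spread evenly between them.
    """
    if d <= 0:
        return []
    q = exon_len // 4
    if d == 1:
        return [exon_len - q]
    inner = [q + round(i * (exon_len - 2 * q) / (d - 1)) for i in range(d)]
    return sorted(set(inner))


# ---------------------------------------------------------------------------
# reads

def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = rng.choice([b for b in BASES if b != arr[i]])
    return "".join(arr), len(hits)


def _transcript(genome: Mapping[str, str], exons: Sequence[ExonRecord]) -> str:
    seq = "".join(genome[e.chrom][e.start:e.end] for e in exons)
    if exons[0].strand == "-":
        seq = revcomp(seq)
    return seq


def simulate_reads(
    cfg: SimConfig,
    genome: Mapping[str, str],
    exons: Sequence[ExonRecord],
    truth: dict,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Paired reads from linear transcripts and circular isoforms.

    R1 is the sense mate.  Circular fragments are drawn on the infinite
    rolling of the circle (modulo its length), so a fragment or read
    longer than the circle wraps the backsplice more than once.

    For genes carrying a homologous exon 2/3 pair, a set of
    artifact-generating fragments is drawn from the exon2-exon3 linear
    junction: their R1 carries one substitution at the discriminating
    position (turning the exon-2 flank into the exon-3 flank) plus
    enough extra errors to push the true linear-junction alignment past
    the score threshold while the scrambled exon3->exon2 alignment
    survives.  Depending on where the mate lands these become
    false-positive circular reads or decoys -- the mechanism by which
    sequencing error convolved with exon homology fabricates circles.
    Returns (read pairs as (read_id, r1, r2), truth table).
    """
    from circjunct.index import acceptor_site, donor_site

    rng = np.random.default_rng(cfg.seed + 1)
    by_gene: dict[str, list[ExonRecord]] = {}
    for e in exons:
        by_gene.setdefault(e.gene_id, []).append(e)

    homolog_genes = {src.rsplit(".e", 1)[0] for src, _ in truth["homologs"]}
    truth["artifact_junctions"] = {}
    pairs: list[tuple[str, str, str]] = []
    rows = []
    counter = 0

    def _emit(r1, r2, gene_id, isoform, start, flen, junction, category, rng,
              r1_errors=None):
        nonlocal counter
        if r1_errors is None:
            r1e, ne1 = _apply_errors(r1, cfg.error_rate, rng)
        else:
            r1e, ne1 = r1, r1_errors
        r2e, ne2 = _apply_errors(r2, cfg.error_rate, rng)
        rid = f"read{counter:06d}"
        counter += 1
        pairs.append((rid, r1e, r2e))
        rows.append(
            {
                "read_id": rid, "gene_id": gene_id, "isoform": isoform,
                "frag_start": start, "frag_len": flen,
                "r1_junction": junction or "", "true_category": category,
                "errors_r1": ne1, "errors_r2": ne2,
            }
        )

    for gene_id in sorted(by_gene):
        ge = sorted(by_gene[gene_id], key=lambda e: e.start)
        linear_tpl = _transcript(genome, ge)
        lo_i, hi_i = truth["circles"][gene_id]
        circ_exons = ge[lo_i:hi_i + 1]
        circ_tpl = _transcript(genome, circ_exons)
        circ_len = len(circ_tpl)
        donor, acceptor = circ_exons[-1], circ_exons[0]
        backsplice_id = f"{donor.chrom}:{donor_site(donor)}:{acceptor_site(acceptor)}:{donor.strand}"
        for kind, n_frags, template in (
            ("linear", cfg.frags_linear_per_gene, linear_tpl),
            ("circular", cfg.frags_circular_per_gene, circ_tpl),
        ):
            for _ in range(n_frags):
                flen = int(np.clip(rng.normal(cfg.fragment_mean, cfg.fragment_sd),
                                   cfg.read_len, None))
                if kind == "linear":
                    if flen >= len(template):
                        flen = len(template)
                        start = 0
                    else:
                        start = int(rng.integers(0, len(template) - flen + 1))
                    frag = template[start:start + flen]
                    cross = _crossed_linear_junction(ge, start, cfg.read_len)
                else:
                    start = int(rng.integers(0, circ_len))
                    reps = -(-(start + flen) // circ_len) + 1
                    frag = (template * reps)[start:start + flen]
                    r1_end = start + cfg.read_len
                    cross = backsplice_id if any(
                        start < k * circ_len < r1_end for k in range(1, reps + 1)
                    ) or circ_len < cfg.read_len else None
                r1 = frag[:cfg.read_len]
                r2 = revcomp(frag[-cfg.read_len:])
                category = (
                    "circular" if kind == "circular" and cross else
                    ("linear" if kind == "linear" and cross else "genomic")
                )
                _emit(r1, r2, gene_id, kind, start, flen, cross, category, rng)

        if gene_id in homolog_genes and cfg.artifact_frags_per_homolog > 0:
            e2, e3 = ge[1], ge[2]
            # transcript coordinate of the exon2|exon3 boundary
            bound = sum(e.length for e in ge[:2])
            # discriminating base nearest the exon-2 3' end
            disc = max(p for p in truth["divergence_positions"] if p < cfg.exon_len)
            disc_from_end = cfg.exon_len - disc
            art_jid = f"{e3.chrom}:{donor_site(e3)}:{acceptor_site(e2)}:{e3.strand}"
            truth["artifact_junctions"][gene_id] = art_jid
            n_decoy = int(round(cfg.artifact_frags_per_homolog * cfg.artifact_decoy_fraction))
            for k in range(cfg.artifact_frags_per_homolog):
                as_decoy = k < n_decoy
                left = int(rng.integers(disc_from_end + 1, cfg.read_len - 10 + 1))
                start = bound - left
                flen = 500 if as_decoy else 250
                frag = linear_tpl[start:start + flen]
                r1 = list(frag[:cfg.read_len])
                # flip the discriminating base to the exon-3 version
                r1[left - disc_from_end] = genome[e3.chrom][e3.end - disc_from_end]
                # extra errors; only reads with enough of them lose their
                # linear-junction alignment and surface as artifacts, the
                # rest stay linear with degraded scores (class overlap)
                n_extra = int(rng.choice(
                    [cfg.artifact_extra_errors - 2, cfg.artifact_extra_errors - 1,
                     cfg.artifact_extra_errors],
                    p=[0.2, 0.2, 0.6],
                ))
                err_pos = rng.choice(
                    [i for i in range(cfg.read_len) if i != left - disc_from_end],
                    size=n_extra, replace=False,
                )
                for p in err_pos:
                    r1[p] = rng.choice([b for b in BASES if b != r1[p]])
                r2 = revcomp(frag[-cfg.read_len:])
                breaks_linear = n_extra >= cfg.artifact_extra_errors
                category = (
                    ("decoy" if as_decoy else "artifact_circular")
                    if breaks_linear else "linear"
                )
                _emit("".join(r1), r2, gene_id, "artifact", start, flen, art_jid,
                      category, rng, r1_errors=n_extra + 1)
    return pairs, pd.DataFrame(rows)


def _crossed_linear_junction(ge: Sequence[ExonRecord], start: int, read_len: int) -> str | None:
    """Junction id if R1 (transcript coords [start, start+read_len)) crosses one."""
    from circjunct.index import acceptor_site, donor_site

    bound = 0
    for a, b in zip(ge, ge[1:]):
        bound += a.length
        if start < bound < start + read_len:
            return f"{a.chrom}:{donor_site(a)}:{acceptor_site(b)}:{a.strand}"
    return None


# ---------------------------------------------------------------------------
# aligner-free feature tables

@dataclass
class FeatureSimConfig:
    """Feature distributions for the separable linear-vs-decoy scenario.

    True reads (linear and real circles) have boundary offsets spread
    over 10-50 nt, near-zero alignment scores, and high mapping
    quality; decoys and homology-artifact reads skew to offsets <= 15,
    depressed scores, and low mapping quality.  ``separation = 0``
    collapses both classes onto the true-read distributions.
    """

    seed: int = 0
    n_linear_junctions: int = 200
    reads_per_linear: int = 10
    n_decoy_reads: int = 400
    n_true_circles: int = 50
    reads_per_circle: int = 4
    n_artifact_circles: int = 50
    reads_per_artifact: int = 4
    separation: float = 1.0
    read_len: int = 100


def _draw_true(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    offset = rng.integers(10, 51, size=n)
    mism = rng.binomial(2, 0.05, size=n)
    score = -6.0 * mism
    mapq = np.clip(42 - rng.exponential(1.5, size=n), 20, 42)
    return offset, score, mapq, mism


def _draw_decoy(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    offset = np.clip(10 + rng.geometric(0.45, size=n) - 1, 10, 15)
    mism = 1 + rng.poisson(1.2, size=n)
    score = -6.0 * np.minimum(mism, 4)
    mapq = rng.uniform(3, 25, size=n)
    return offset, score, mapq, mism


def simulate_feature_table(
    cfg: FeatureSimConfig,
) -> tuple[list[ReadFeatureRecord], pd.DataFrame]:
    """Draw R1 feature records directly, bypassing alignment.

    Returns (records, junction truth table with true circle status).
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[ReadFeatureRecord] = []
    truth_rows = []
    counter = 0

    def _emit(jid, category, jcls, draw, n):
        nonlocal counter
        offset, score, mapq, mism = draw(rng, n)
        for k in range(n):
            records.append(
                ReadFeatureRecord(
                    read_id=f"fread{counter:06d}", junction_id=jid, category=category,
                    offset=int(offset[k]), alignment_score=float(score[k]),
                    mapq=float(mapq[k]), mismatches=int(mism[k]), junction_cls=jcls,
                )
            )
            counter += 1

    decoy_draw = _draw_true if cfg.separation == 0 else _draw_decoy
    for j in range(cfg.n_linear_junctions):
        _emit(f"lin{j}", "linear", "linear", _draw_true, cfg.reads_per_linear)
    n_dj = max(1, cfg.n_decoy_reads // 4)
    for j in range(n_dj):
        n = cfg.n_decoy_reads // n_dj + (1 if j < cfg.n_decoy_reads % n_dj else 0)
        _emit(f"dec{j}", "decoy", "scrambled", decoy_draw, n)
    for j in range(cfg.n_true_circles):
        jid = f"circ{j}"
        _emit(jid, "circular", "scrambled", _draw_true, cfg.reads_per_circle)
        truth_rows.append({"junction_id": jid, "true_status": "real", "n_reads": cfg.reads_per_circle})
    for j in range(cfg.n_artifact_circles):
        jid = f"art{j}"
        _emit(jid, "circular", "scrambled", decoy_draw, cfg.reads_per_artifact)
        truth_rows.append({"junction_id": jid, "true_status": "artifact", "n_reads": cfg.reads_per_artifact})
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# count tables with planted induction

@dataclass
class CountSimConfig:
    """Multi-timepoint Poisson counts emulating a fetal time course.

    Ages span 10-21 weeks; per-junction means follow
    mu_ij = base_j * (1 + slope_j * age_i) with slopes planted on the
    circular junctions only.
    """

    seed: int = 0
    ages: tuple[float, ...] = (10, 12, 14, 16, 18, 19, 20, 21)
    n_circular: int = 200
    n_linear: int = 800
    base_mean: float = 30.0
    circular_slope: float = 0.05
    linear_slope: float = 0.0


def simulate_count_table(cfg: CountSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Returns (counts junctions x samples, sample sheet, junction truth)."""
    rng = np.random.default_rng(cfg.seed)
    ages = np.asarray(cfg.ages, dtype=float)
    samples = [f"s{i + 1}" for i in range(len(ages))]
    ids = [f"circ{j}" for j in range(cfg.n_circular)] + [f"lin{j}" for j in range(cfg.n_linear)]
    slopes = np.concatenate([
        np.full(cfg.n_circular, cfg.circular_slope),
        np.full(cfg.n_linear, cfg.linear_slope),
    ])
    base = rng.gamma(2.0, cfg.base_mean / 2.0, size=len(ids))
    mu = base[:, None] * (1 + slopes[:, None] * ages[None, :])
    if np.any(mu < 0):
        raise ValueError("negative Poisson mean; reduce |slope|")
    counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="junction_id"), columns=samples)
    sheet = pd.DataFrame({"sample_id": samples, "age_weeks": ages,
                          "tissue": "sim", "timepoint": [f"t{i}" for i in range(len(ages))]})
    truth = pd.DataFrame({"junction_id": ids, "slope": slopes,
                          "cls": ["circular"] * cfg.n_circular + ["linear"] * cfg.n_linear})
    return counts_df, sheet, truth


# ---------------------------------------------------------------------------
# text-format writers

def write_genome_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(exons: Sequence[ExonRecord], path: str | Path, source: str = "circjunct_sim") -> None:
    with open(path, "w") as fh:
        for e in exons:
            attrs = (
                f'gene_id "{e.gene_id}"; transcript_id "{e.gene_id}.t1"; '
                f'exon_id "{e.exon_id}";'
            )
            fh.write(
                f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n"
            )


def write_fastq_pairs(
    pairs: Sequence[tuple[str, str, str]], r1_path: str | Path, r2_path: str | Path
) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for rid, r1, r2 in pairs:
            f1.write(f"@{rid}\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}\n{r2}\n+\n{'I' * len(r2)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((header[1:].split()[0], seq))
    return out
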