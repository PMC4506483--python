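"""End-to-end pipeline: index -> classify -> score -> de novo -> reports.

The stages mirror the analysis order: build the junction databases from
the annotation, align both mates independently (with the built-in
matcher, or ingest precomputed SAM/TSV alignments), categorize
R1-anchored pairs, score junctions with the GLM (paired-end) or the
naive Poisson mismatch test (single-end), then run de novo discovery on
the reads no reference explained.  Reports are TSVs with a commented
header carrying the package version, a config hash, and the seed so a
run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml


@dataclass
class PipelineConfig:
    genome_fasta: str = ""
    gtf: str = ""
    r1_fastq: str = ""
    r2_fastq: str = ""  # empty -> single-end mode, naive scorer
    out_dir: str = "circjunct_out"
    window: int = 1_000_000
    pad_side: int = 150
    min_overlap: int = 10
    max_mismatch_per_100: float = 4.0
    posterior_threshold: float = 0.9
    n_min: int = 2
    buffer_annotated: int = 15
    buffer_denovo: int = 50
    max_fragment: int = 1000
    bin_size: int = 50
    s_max: float = 5.0
    max_decoy_ratio: float = 0.1
    min_breakpoint_sep: int = 200
    k_min: int = 10
    fdr_level: float = 0.001
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window", "pad_side", "min_overlap", "n_min", "bin_size",
                     "min_breakpoint_sep", "max_fragment"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**yaml.safe_load(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def write_report(df: pd.DataFrame, path: str | Path, cfg: PipelineConfig) -> None:
    from circjunct import __version__

    with open(path, "w") as fh:
        fh.write(f"# circjunct {__version__}\n")
        fh.write(f"# config_sha256 {cfg.digest()}\n")
        fh.write(f"# seed {cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


class StageError(RuntimeError):
    def __init__(self, stage: str, source: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {source!r}: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns the machine-readable summary."""
    from circjunct import align, classify, denovo, glm
    from circjunct import index as jidx
    from circjunct.simulate import read_fastq

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_sha256": cfg.digest(), "stages": {}}

    try:
        genome = jidx.open_genome(cfg.genome_fasta)
        exons = jidx.read_gtf_exons(cfg.gtf)
    except Exception as e:  # noqa: BLE001
        raise StageError("load_inputs", cfg.gtf or cfg.genome_fasta, e) from e

    try:
        js = jidx.build_junction_db(exons, genome, window=cfg.window, pad_side=cfg.pad_side)
        jidx.write_junction_fasta(js, out / "index")
        summary["stages"]["index"] = {"linear": len(js.linear), "scrambled": len(js.scrambled)}
    except Exception as e:  # noqa: BLE001
        raise StageError("build_index", cfg.gtf, e) from e

    r1_reads = read_fastq(cfg.r1_fastq) if cfg.r1_fastq else []
    r2_reads = read_fastq(cfg.r2_fastq) if cfg.r2_fastq else []
    paired = bool(r2_reads)

    refs = {j.junction_id: j.sequence for j in js.all()}
    kinds = {
        j.junction_id: ("linear_junction" if j.cls == "linear" else "scrambled_junction")
        for j in js.all()
    }
    refs.update(genome)
    kinds.update({c: "genome" for c in genome})
    aligner = align.ReadAligner(refs, kinds, cfg.max_mismatch_per_100)

    try:
        r1_alns, unaligned1 = align.align_read_set(
            aligner, ((rid, "R1", s) for rid, s in r1_reads)
        )
        r2_alns, _ = align.align_read_set(
            aligner, ((rid, "R2", s) for rid, s in r2_reads)
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("align", cfg.r1_fastq, e) from e

    try:
        features, reasons = classify.build_feature_records(
            r1_alns, r2_alns, js.by_id(),
            min_overlap=cfg.min_overlap,
            max_mismatch_per_100=cfg.max_mismatch_per_100,
            buffer=cfg.buffer_annotated,
            max_fragment=cfg.max_fragment,
            boundary_index=cfg.pad_side,
        )
        classify.write_feature_tsv(features, out / "features.tsv")
        summary["stages"]["classify"] = dict(sorted(reasons.items()))
    except Exception as e:  # noqa: BLE001
        raise StageError("classify", cfg.r1_fastq, e) from e

    try:
        mode = "glm" if paired else "naive"
        n_lin = sum(1 for f in features if f.category == "linear")
        n_dec = sum(1 for f in features if f.category == "decoy")
        if mode == "glm" and (n_lin < 10 or n_dec < 10):
            mode = "naive"  # too little training data for the GLM
        calls = glm.score_junctions(features, mode=mode, error_rate=cfg.error_rate) if features else []
        passing = glm.report_calls(calls, cfg.posterior_threshold, cfg.n_min)
        write_report(glm.calls_to_dataframe(calls), out / "calls.tsv", cfg)
        summary["stages"]["score"] = {
            "mode": mode,
            "junctions": len(calls),
            "pass": sum(1 for c in calls if c.verdict == "pass"),
            "pass_circular": sum(1 for c in passing if c.cls != "linear"),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("score", "features", e) from e

    try:
        id_set = set(unaligned1)
        r1_by_id = dict(r1_reads)
        r2_by_id = dict(r2_reads)
        unaligned_pairs = [
            (rid, r1_by_id[rid], r2_by_id.get(rid, r1_by_id[rid]))
            for rid in sorted(id_set)
        ]
        dn_calls, assemblies = denovo.discover_denovo(
            unaligned_pairs, genome, exons,
            bin_size=cfg.bin_size, s_max=cfg.s_max,
            buffer=cfg.buffer_denovo,
            max_decoy_ratio=cfg.max_decoy_ratio,
            min_breakpoint_sep=cfg.min_breakpoint_sep,
            error_rate=cfg.error_rate,
        ) if unaligned_pairs else ([], [])
        rows = [
            {
                "junction_id": c.junction_id,
                "n_reads": c.n_reads,
                "decoy_count": c.decoy_count,
                "p_value": c.p_value,
                "signal_class": c.extras.get("signal_class", ""),
                "score_s": c.extras.get("score_s", float("nan")),
                "name": c.extras.get("name", ""),
            }
            for c in dn_calls
        ]
        write_report(
            pd.DataFrame(rows, columns=["junction_id", "n_reads", "decoy_count",
                                        "p_value", "signal_class", "score_s", "name"]),
            out / "denovo.tsv", cfg,
        )
        summary["stages"]["denovo"] = {
            "unaligned_reads": len(unaligned_pairs),
            "assemblies": len(assemblies),
            "junctions": len(dn_calls),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("denovo", "unaligned reads", e) from e

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
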