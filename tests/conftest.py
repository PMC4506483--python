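import numpy as np
import pytest

from circjunct.index import ExonRecord, build_junction_db
from circjunct.simulate import SimConfig, simulate_genome, simulate_reads

BASES = np.array(list("ACGT"))


def random_genome(length: int, seed: int = 0) -> str:
    return "".join(np.random.default_rng(seed).choice(BASES, size=length))


@pytest.fixture(scope="session")
def toy_genome():
    """50 kb random chromosome shared by hand-built annotation tests."""
    return {"chr1": random_genome(50_000, seed=11)}


@pytest.fixture(scope="session")
def toy_exons():
    """Two genes on opposite strands, exon lengths 200/300/150."""
    return [
        ExonRecord("chr1", 1_000, 1_200, "+", "geneA", "geneA.e1"),
        ExonRecord("chr1", 11_000, 11_300, "+", "geneA", "geneA.e2"),
        ExonRecord("chr1", 20_000, 20_150, "-", "geneB", "geneB.e1"),
        ExonRecord("chr1", 22_000, 22_300, "-", "geneB", "geneB.e2"),
    ]


@pytest.fixture(scope="session")
def sim_bundle():
    """One deterministic simulated dataset run through index construction."""
    cfg = SimConfig(seed=1)
    genome, exons, truth = simulate_genome(cfg)
    js = build_junction_db(exons, genome)
    pairs, truth_df = simulate_reads(cfg, genome, exons, truth)
    return cfg, genome, exons, truth, js, pairs, truth_df


def classify_simulated(cfg, genome, js, pairs):
    """Align simulated pairs against genome + junction DBs and categorize."""
    from circjunct.align import ReadAligner, align_read_set
    from circjunct.classify import build_feature_records

    refs = {j.junction_id: j.sequence for j in js.all()}
    kinds = {
        j.junction_id: ("linear_junction" if j.cls == "linear" else "scrambled_junction")
        for j in js.all()
    }
    refs.update(genome)
    kinds.update({c: "genome" for c in genome})
    aligner = ReadAligner(refs, kinds)
    r1, un1 = align_read_set(aligner, ((rid, "R1", s1) for rid, s1, _ in pairs))
    r2, _ = align_read_set(aligner, ((rid, "R2", s2) for rid, _, s2 in pairs))
    feats, reasons = build_feature_records(r1, r2, js.by_id())
    return feats, reasons, un1
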