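"""Shared fixtures: small deterministic simulations and databases.

Everything is generated programmatically from fixed seeds; the heavier
session-scoped fixtures (a deep-coverage simulation and a 20-replicate
study) are shared across the property and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mmes_splice import build_erj, build_esj, build_resj
from mmes_splice.pipeline import RunConfig, run_all
from mmes_splice.synth import SimConfig, simulate_genome_and_genes, simulate_reads

N_STUDY_SEEDS = 20


def naive_oracle(reads, db, max_mismatch, min_overlap):
    """Reference mapper: scan every (junction, offset) pair directly."""
    from mmes_splice.junction_map import admissible_offsets

    hits = []
    offsets = admissible_offsets(db.read_len, db.arm_len, min_overlap)
    for rid, seq in reads:
        for rec in db.records:
            for off in offsets:
                window = rec.sequence[off : off + db.read_len]
                mm = sum(a != b or a not in "ACGT" for a, b in zip(seq, window))
                if mm <= max_mismatch:
                    l_arm = db.arm_len - off
                    l_mm = sum(
                        a != b or a not in "ACGT"
                        for a, b in zip(seq[:l_arm], window[:l_arm])
                    )
                    hits.append((rid, rec.junction_id, off, mm, l_mm))
    return sorted(hits)


@pytest.fixture(scope="session")
def tiny_sim():
    """Small clean simulation: 12 genes, exact reads (no errors)."""
    cfg = SimConfig(
        n_genes=12,
        exons_per_gene=(2, 5),
        exon_len=(60, 120),
        intron_len=(50, 150),
        skip_fraction=0.5,
        expression_range=(5.0, 50.0),
        per_base_error=0.0,
        seed=7,
    )
    genome, genes = simulate_genome_and_genes(cfg)
    reads, truth = simulate_reads(genome, genes, cfg)
    return cfg, genome, genes, reads, truth


@pytest.fixture(scope="session")
def tiny_dbs(tiny_sim):
    cfg, genome, genes, reads, truth = tiny_sim
    esj = build_esj(genes, genome, cfg.read_len, 4)
    erj = build_erj(esj, genes, genome, seed=42)
    resj = build_resj(esj)
    return esj, erj, resj


@pytest.fixture(scope="session")
def mapping_fixture():
    """50 junctions and 500 reads for mapper-vs-oracle comparisons.

    Reads are a mixture of mutated junction windows (0-3 substitutions,
    some straddling the admissible-window boundary) and pure random
    sequence, so hits, near-misses and non-hits are all represented.
    """
    from mmes_splice._seq import BASES
    from mmes_splice.junction_db import JunctionDB, JunctionRecord

    rng = np.random.default_rng(2024)
    arm, rl = 21, 25

    def rand_seq(n):
        return "".join(np.array(list(BASES))[rng.integers(0, 4, n)])

    records = [
        JunctionRecord(
            f"j{i:03d}", "ESJ", f"gA{i}", 0, f"gA{i}", 1, arm, rand_seq(2 * arm),
            ("chr1", 0, "chr1", 0), True,
        )
        for i in range(50)
    ]
    db = JunctionDB(records, arm_len=arm, read_len=rl, min_overlap=4, db_class="ESJ")

    reads = []
    for i in range(500):
        if i % 5 == 4:
            seq = rand_seq(rl)
        else:
            rec = records[int(rng.integers(50))]
            off = int(rng.integers(0, 2 * arm - rl + 1))  # incl. inadmissible
            seq = list(rec.sequence[off : off + rl])
            for p in rng.choice(rl, size=int(rng.integers(0, 4)), replace=False):
                seq[p] = BASES[(BASES.index(seq[p]) + int(rng.integers(1, 4))) % 4]
            seq = "".join(seq)
        reads.append((f"r{i:04d}", seq))
    return reads, db


@pytest.fixture(scope="session")
def deep_sim_result():
    """One deep simulation (> 100k reads) under the study conditions."""
    cfg = RunConfig(
        sim=SimConfig(seed=11, n_genes=150, expression_range=(5.0, 4000.0)),
        run_baselines=False,
    )
    return run_all(cfg)


@pytest.fixture(scope="session")
def study20():
    """Twenty seeded replicates of the full pipeline (study conditions)."""
    return [
        run_all(RunConfig(sim=SimConfig(seed=seed)))
        for seed in range(1, N_STUDY_SEEDS + 1)
    ]
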