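"""Synthetic RNA-seq data with known splice-junction ground truth.

Generates a random genome, multi-exon gene models, expressed transcripts
(every gene expresses its full isoform; a configurable fraction of genes
additionally expresses an exon-skipping isoform), and fixed-length
single-end reads carrying independent substitution errors.  The regime
emulated is short-read (25-27 bp) RNA-seq mapped with a <=2 mismatch
budget: substitution errors only, no indels, constant base quality.

Ground truth (`SimTruth`) records every junction that at least one read
spans with a minimum overlap on both sides, which is exactly the set of
junctions a perfect junction-mapper could recover from the reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from ._seq import BASES, random_dna
from .gene_models import GeneModel, as_genome_dict
from .junction_db import junction_name

__all__ = [
    "SimConfig",
    "SimTruth",
    "Transcript",
    "ReadRecord",
    "simulate_genome_and_genes",
    "simulate_reads",
    "write_fastq",
    "read_fastq",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation.

    Ranges are inclusive (lo, hi) pairs.  ``expression_range`` gives the
    expected read count per transcript, drawn log-uniformly so that
    low-abundance transcripts — the one-read-junction regime — are well
    represented.  Defaults describe the standard conditions used
    throughout the test-suite and the reproduction scripts.
    """

    n_genes: int = 120
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (100, 600)
    skip_fraction: float = 0.3
    expression_range: tuple[float, float] = (1.0, 1000.0)
    read_len: int = 25
    per_base_error: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len", "expression_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range ({lo}, {hi}) is empty")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.exons_per_gene[0] < 1:
            raise ValueError("exons_per_gene must be >= 1")
        if self.exon_len[0] < self.read_len - 4:
            raise ValueError(
                "min exon_len must be >= read_len - 4 so every exon can "
                "donate a full junction arm"
            )
        if not 0.0 <= self.per_base_error <= 0.25:
            raise ValueError("per_base_error must lie in [0, 0.25]")
        if not 0.0 <= self.skip_fraction <= 1.0:
            raise ValueError("skip_fraction must lie in [0, 1]")
        if self.expression_range[0] <= 0:
            raise ValueError("expression_range must be positive")


@dataclass
class Transcript:
    """One expressed isoform: an ordered subset of a gene's exons."""

    transcript_id: str
    gene_id: str
    exon_indices: list[int]  # gene exon indices in transcript order
    sequence: str

    @property
    def junctions(self) -> list[tuple[str, int, int]]:
        return [
            (self.gene_id, i, j)
            for i, j in zip(self.exon_indices, self.exon_indices[1:])
        ]


class ReadRecord(NamedTuple):
    read_id: str
    sequence: str


@dataclass
class SimTruth:
    """Ground-truth expressed junctions and their simulated read support.

    A junction (gene, up exon, down exon) is *expressed* if at least one
    emitted read spans it with >= ``min_overlap`` bases on both sides.
    """

    expressed_junctions: set[tuple[str, int, int]] = field(default_factory=set)
    reads_per_junction: dict[tuple[str, int, int], int] = field(default_factory=dict)
    min_overlap: int = 4

    def junction_ids(self) -> set[str]:
        return {junction_name(g, i, j) for (g, i, j) in self.expressed_junctions}

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tup_exon\tdown_exon\tn_reads\n")
            for key in sorted(self.reads_per_junction):
                g, i, j = key
                fh.write(f"{g}\t{i}\t{j}\t{self.reads_per_junction[key]}\n")

    @classmethod
    def read_tsv(cls, path: str, min_overlap: int = 4) -> "SimTruth":
        truth = cls(min_overlap=min_overlap)
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("gene")
            for line in fh:
                g, i, j, n = line.rstrip("\n").split("\t")
                key = (g, int(i), int(j))
                truth.reads_per_junction[key] = int(n)
                if int(n) > 0:
                    truth.expressed_junctions.add(key)
        return truth


def simulate_genome_and_genes(
    config: SimConfig,
) -> tuple[str, list[GeneModel]]:
    """Random genome (one chromosome) plus non-overlapping gene models.

    Loci are laid out left to right with intergenic gaps drawn from the
    intron-length range; all sequence is uniform i.i.d. over {A,C,G,T}.
    Returns the genome as a plain string (chromosome name ``chr1``).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    genes: list[GeneModel] = []
    pos = 0
    width = max(4, len(str(config.n_genes)))
    for gi in range(config.n_genes):
        pos += int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons = []
        for k in range(n_ex):
            if k > 0:
                pos += int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            elen = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
        genes.append(GeneModel(f"g{gi:0{width}d}", "chr1", "+", exons))
    pos += int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
    genome = random_dna(rng, pos)
    return genome, genes


def expressed_transcripts(
    genome: str | dict[str, str], genes: list[GeneModel], config: SimConfig
) -> list[Transcript]:
    """Isoform set: one full transcript per gene, plus a skipping isoform
    (one internal exon removed) for a ``skip_fraction`` of eligible genes.

    Deterministic given the config seed; the skipping draw uses its own
    stream so read simulation does not perturb isoform choice.
    """
    gdict = as_genome_dict(genome)
    rng = np.random.default_rng([config.seed, 1])
    transcripts = []
    for g in genes:
        full = list(range(g.n_exons))
        transcripts.append(
            Transcript(f"{g.gene_id}.t1", g.gene_id, full, g.transcript_sequence(gdict))
        )
        if g.n_exons >= 3 and rng.random() < config.skip_fraction:
            skipped = int(rng.integers(1, g.n_exons - 1))
            idx = [i for i in full if i != skipped]
            transcripts.append(
                Transcript(
                    f"{g.gene_id}.t2",
                    g.gene_id,
                    idx,
                    g.transcript_sequence(gdict, idx),
                )
            )
    return transcripts


def simulate_reads(
    genome: str | dict[str, str],
    genes: list[GeneModel],
    config: SimConfig,
) -> tuple[list[ReadRecord], SimTruth]:
    """Sample error-bearing reads uniformly along each expressed transcript.

    Per-transcript read counts are Poisson with a log-uniform mean from
    ``expression_range``; each base substitutes independently with
    probability ``per_base_error`` (uniform over the three alternatives).
    Read names encode transcript of origin and start position.
    """
    config.validate()
    transcripts = expressed_transcripts(genome, genes, config)
    if not transcripts:
        raise ValueError("no expressed transcripts")
    min_tx = min(len(t.sequence) for t in transcripts)
    if config.read_len > min_tx:
        raise ValueError(
            f"read_len {config.read_len} exceeds shortest transcript ({min_tx} bp)"
        )

    rng = np.random.default_rng([config.seed, 2])
    rl = config.read_len
    mo = 4  # truth bookkeeping overlap; matches the junction-database default
    base_codes = np.frombuffer(BASES.encode(), dtype=np.uint8)
    gdict = as_genome_dict(genome)
    gene_index = {g.gene_id: g for g in genes}

    reads: list[ReadRecord] = []
    truth = SimTruth(min_overlap=mo)
    lo, hi = config.expression_range
    serial = 0
    for t in transcripts:
        lam = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        enc = np.frombuffer(t.sequence.encode(), dtype=np.uint8)
        starts = rng.integers(0, len(enc) - rl + 1, size=n)
        mat = enc[starts[:, None] + np.arange(rl)[None, :]].copy()
        if config.per_base_error > 0:
            err = rng.random((n, rl)) < config.per_base_error
            n_err = int(err.sum())
            if n_err:
                # substitute with one of the 3 other bases, uniformly
                cur = np.searchsorted(base_codes, mat[err])
                shift = rng.integers(1, 4, size=n_err)
                mat[err] = base_codes[(cur + shift) % 4]
        for k in range(n):
            reads.append(
                ReadRecord(
                    f"{t.transcript_id}:{int(starts[k])}:{serial}",
                    mat[k].tobytes().decode("ascii"),
                )
            )
            serial += 1
        # junction coverage bookkeeping
        g = gene_index[t.gene_id]
        for (up, down), boundary in _junction_boundaries(g, gdict, t):
            cover = int(
                np.count_nonzero(
                    (starts >= boundary - rl + mo) & (starts <= boundary - mo)
                )
            )
            key = (t.gene_id, up, down)
            truth.reads_per_junction[key] = truth.reads_per_junction.get(key, 0) + cover
            if truth.reads_per_junction[key] > 0:
                truth.expressed_junctions.add(key)
    # junctions never covered still appear with count 0
    for t in transcripts:
        for key in t.junctions:
            truth.reads_per_junction.setdefault(key, 0)
    return reads, truth


def _junction_boundaries(g, gdict, t: Transcript):
    """Yield ((up_exon, down_exon), transcript position of the joint)."""
    cum = 0
    lens = [len(g.exon_sequence(gdict, i)) for i in t.exon_indices]
    for k in range(len(t.exon_indices) - 1):
        cum += lens[k]
        yield (t.exon_indices[k], t.exon_indices[k + 1]), cum


def write_fastq(reads: list[ReadRecord], path: str, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality_char * len(r.sequence)}\n")


def read_fastq(path: str) -> list[ReadRecord]:
    from Bio import SeqIO

    return [
        ReadRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fastq")
    ]


def read_fasta_reads(path: str) -> list[ReadRecord]:
    from Bio import SeqIO

    return [
        ReadRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]
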