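"""Exon-junction sequence databases: ESJ targets and ERJ / rESJ decoys.

ESJ (Exon Spliced Junction): for every locus, every ordered exon pair
(i, j), i < j, contributes the last ``arm_len`` bases of exon i joined to
the first ``arm_len`` bases of exon j — a 2*arm_len-mer a junction-spanning
read can map onto ungapped.  ERJ (Exon Random Junction) pairs exons from
two *different* loci and serves as the empirical negative control; rESJ
swaps the two arms of each ESJ record, preserving base composition.

The arm length is read_len - min_overlap, which guarantees that any
read placed across the joint overlaps both exons by at least
``min_overlap`` bases (21 bp arms for 25 bp reads with a 4 bp overlap).
Exons shorter than one arm cannot donate a full arm; such candidate
junctions are discarded, and duplicate sequences are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import encode_ref
from .gene_models import GeneModel, as_genome_dict

__all__ = [
    "JunctionRecord",
    "JunctionDB",
    "arm_length",
    "junction_name",
    "build_esj",
    "build_erj",
    "build_resj",
    "composition_profile",
]


def junction_name(gene_id: str, up_exon: int, down_exon: int) -> str:
    """Canonical id for a same-locus junction, e.g. ``g0007:2-4``."""
    return f"{gene_id}:{up_exon}-{down_exon}"


def arm_length(read_len: int, min_overlap: int) -> int:
    """Arm length (bp) so every spanning read overlaps both exons enough.

    Returns ``read_len - min_overlap``.  Raises if the geometry admits no
    valid spanning placement (read_len <= 2 * min_overlap).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if read_len <= 2 * min_overlap:
        raise ValueError(
            f"infeasible geometry: read_len={read_len} admits no placement "
            f"with >= {min_overlap} bp overlap on both sides"
        )
    return read_len - min_overlap


@dataclass(frozen=True)
class JunctionRecord:
    """One junction sequence: two exon arms joined end to end."""

    junction_id: str
    db_class: str  # ESJ | ERJ | rESJ
    up_locus: str
    up_exon_index: int
    down_locus: str
    down_exon_index: int
    arm_len: int
    sequence: str
    genomic_breakpoints: tuple[str, int, str, int]
    consecutive: bool | None = None  # ESJ only: down == up + 1

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.arm_len:
            raise ValueError(
                f"{self.junction_id}: sequence length {len(self.sequence)} "
                f"!= 2 * arm_len ({2 * self.arm_len})"
            )


@dataclass
class JunctionDB:
    """A set of same-geometry junction records plus their provenance."""

    records: list[JunctionRecord]
    arm_len: int
    read_len: int
    min_overlap: int
    db_class: str
    provenance: str = ""
    seed: int | None = None
    _by_id: dict = field(default=None, repr=False, compare=False)
    _matrix: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.arm_len != arm_length(self.read_len, self.min_overlap):
            raise ValueError("arm_len must equal read_len - min_overlap")
        ids = [r.junction_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("junction ids are not unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.junction_id for r in self.records]

    def sequences(self) -> set[str]:
        return {r.sequence for r in self.records}

    def __getitem__(self, junction_id: str) -> JunctionRecord:
        if self._by_id is None:
            self._by_id = {r.junction_id: r for r in self.records}
        return self._by_id[junction_id]

    def sequence_matrix(self) -> np.ndarray:
        """(n_junctions, 2*arm_len) uint8 encoding, cached."""
        if self._matrix is None:
            mat = np.empty((len(self.records), 2 * self.arm_len), dtype=np.uint8)
            for i, r in enumerate(self.records):
                mat[i] = encode_ref(r.sequence)
            self._matrix = mat
        return self._matrix

    # ---------------------------------------------------------------- I/O

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(
                    f">{r.junction_id}|{r.db_class}"
                    f"|{r.up_locus}:{r.up_exon_index}"
                    f"|{r.down_locus}:{r.down_exon_index}|{r.arm_len}\n"
                    f"{r.sequence}\n"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "junction_id": [r.junction_id for r in self.records],
                "db_class": [r.db_class for r in self.records],
                "up_locus": [r.up_locus for r in self.records],
                "up_exon_index": [r.up_exon_index for r in self.records],
                "down_locus": [r.down_locus for r in self.records],
                "down_exon_index": [r.down_exon_index for r in self.records],
                "arm_len": [r.arm_len for r in self.records],
                "chrom_donor": [r.genomic_breakpoints[0] for r in self.records],
                "donor_pos": [r.genomic_breakpoints[1] for r in self.records],
                "chrom_acceptor": [r.genomic_breakpoints[2] for r in self.records],
                "acceptor_pos": [r.genomic_breakpoints[3] for r in self.records],
                "consecutive": [r.consecutive for r in self.records],
                "sequence": [r.sequence for r in self.records],
            }
        )

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"#db_class={self.db_class}\tread_len={self.read_len}"
                f"\tmin_overlap={self.min_overlap}\tarm_len={self.arm_len}"
                f"\tseed={self.seed if self.seed is not None else ''}\n"
            )
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str) -> "JunctionDB":
        with open(path) as fh:
            meta_line = fh.readline()
            if not meta_line.startswith("#"):
                raise ValueError("missing metadata header line")
            meta = dict(
                kv.split("=", 1) for kv in meta_line.lstrip("#").rstrip("\n").split("\t")
            )
            df = pd.read_csv(fh, sep="\t")
        records = [
            JunctionRecord(
                row.junction_id,
                row.db_class,
                row.up_locus,
                int(row.up_exon_index),
                row.down_locus,
                int(row.down_exon_index),
                int(row.arm_len),
                row.sequence,
                (row.chrom_donor, int(row.donor_pos), row.chrom_acceptor, int(row.acceptor_pos)),
                None if pd.isna(row.consecutive) else bool(row.consecutive),
            )
            for row in df.itertuples()
        ]
        return cls(
            records,
            arm_len=int(meta["arm_len"]),
            read_len=int(meta["read_len"]),
            min_overlap=int(meta["min_overlap"]),
            db_class=meta["db_class"],
            seed=int(meta["seed"]) if meta.get("seed") else None,
        )


def _dedupe(records: list[JunctionRecord]) -> list[JunctionRecord]:
    """Sequence-level redundancy removal keeping the lexicographically
    first junction_id per duplicate sequence; output sorted by id."""
    best: dict[str, JunctionRecord] = {}
    for r in records:
        kept = best.get(r.sequence)
        if kept is None or r.junction_id < kept.junction_id:
            best[r.sequence] = r
    return sorted(best.values(), key=lambda r: r.junction_id)


def _eligible_exons(
    genes: list[GeneModel], gdict: dict[str, str], arm: int
) -> dict[str, list[tuple[int, str, tuple[str, int], tuple[str, int]]]]:
    """Per locus: (tx exon index, exon sequence, donor bp, acceptor bp) for
    exons long enough to donate a full arm."""
    out = {}
    for g in genes:
        rows = []
        tx_exons = g.exons_transcript_order()
        for i in range(g.n_exons):
            start, end = tx_exons[i]
            if end - start < arm:
                continue
            seq = g.exon_sequence(gdict, i)
            donor = (g.chrom, end if g.strand == "+" else start)
            acceptor = (g.chrom, start if g.strand == "+" else end)
            rows.append((i, seq, donor, acceptor))
        if rows:
            out[g.gene_id] = rows
    return out


def build_esj(
    genes: list[GeneModel],
    genome: str | dict[str, str],
    read_len: int = 25,
    min_overlap: int = 4,
) -> JunctionDB:
    """All ordered same-locus exon pairs (i < j) joined arm to arm.

    Pairs with j == i + 1 are consecutive junctions; j > i + 1 are
    skipped-exon candidates.  Candidates with an exon shorter than one arm
    are discarded; duplicate sequences are removed.
    """
    arm = arm_length(read_len, min_overlap)
    gdict = as_genome_dict(genome)
    records = []
    for g in genes:
        tx_exons = g.exons_transcript_order()
        for s, e in g.exons:
            if e > len(gdict[g.chrom]):
                raise ValueError(f"{g.gene_id}: exon ({s}, {e}) outside genome")
        seqs = [g.exon_sequence(gdict, i) for i in range(g.n_exons)]
        for i in range(g.n_exons):
            if len(seqs[i]) < arm:
                continue
            up_start, up_end = tx_exons[i]
            donor = (g.chrom, up_end if g.strand == "+" else up_start)
            for j in range(i + 1, g.n_exons):
                if len(seqs[j]) < arm:
                    continue
                dn_start, dn_end = tx_exons[j]
                acceptor = (g.chrom, dn_start if g.strand == "+" else dn_end)
                records.append(
                    JunctionRecord(
                        junction_name(g.gene_id, i, j),
                        "ESJ",
                        g.gene_id,
                        i,
                        g.gene_id,
                        j,
                        arm,
                        seqs[i][-arm:] + seqs[j][:arm],
                        (donor[0], donor[1], acceptor[0], acceptor[1]),
                        consecutive=(j == i + 1),
                    )
                )
    return JunctionDB(
        _dedupe(records),
        arm_len=arm,
        read_len=read_len,
        min_overlap=min_overlap,
        db_class="ESJ",
    )


def build_erj(
    esj: JunctionDB,
    genes: list[GeneModel],
    genome: str | dict[str, str],
    seed: int | list[int] = 0,
    max_attempts: int = 1000,
) -> JunctionDB:
    """Negative-control decoys: arm pairs from two distinct loci.

    Exactly ``len(esj)`` records are drawn (decoy and target databases are
    kept the same size so raw counts are directly comparable).  Any draw
    whose sequence equals an ESJ sequence — or repeats an earlier decoy —
    is rejected and redrawn, up to ``max_attempts`` per record.
    """
    arm = esj.arm_len
    gdict = as_genome_dict(genome)
    eligible = _eligible_exons(genes, gdict, arm)
    loci = sorted(eligible)
    if len(loci) < 2:
        raise ValueError("ERJ construction requires >= 2 loci with usable exons")
    rng = np.random.default_rng(seed)
    esj_seqs = esj.sequences()
    taken: set[str] = set()
    records = []
    for k in range(len(esj)):
        for _ in range(max_attempts):
            a = int(rng.integers(len(loci)))
            b = int(rng.integers(len(loci) - 1))
            if b >= a:
                b += 1
            up_gene, dn_gene = loci[a], loci[b]
            ui, useq, udonor, _ = eligible[up_gene][
                int(rng.integers(len(eligible[up_gene])))
            ]
            di, dseq, _, dacceptor = eligible[dn_gene][
                int(rng.integers(len(eligible[dn_gene])))
            ]
            seq = useq[-arm:] + dseq[:arm]
            if seq in esj_seqs or seq in taken:
                continue
            taken.add(seq)
            records.append(
                JunctionRecord(
                    f"erj{k:06d}",
                    "ERJ",
                    up_gene,
                    ui,
                    dn_gene,
                    di,
                    arm,
                    seq,
                    (udonor[0], udonor[1], dacceptor[0], dacceptor[1]),
                )
            )
            break
        else:
            raise RuntimeError(
                f"could not draw a fresh decoy after {max_attempts} attempts"
            )
    return JunctionDB(
        records,
        arm_len=arm,
        read_len=esj.read_len,
        min_overlap=esj.min_overlap,
        db_class="ERJ",
        seed=seed if isinstance(seed, int) else None,
    )


def build_resj(esj: JunctionDB) -> JunctionDB:
    """Arm-swapped decoys: each ESJ with upstream and downstream arms
    exchanged.  Swapped sequences that collide with a real ESJ sequence
    are dropped, so len(rESJ) <= len(ESJ)."""
    if not len(esj):
        raise ValueError("ESJ database is empty")
    arm = esj.arm_len
    esj_seqs = esj.sequences()
    records = []
    for r in esj.records:
        swapped = r.sequence[arm:] + r.sequence[:arm]
        if swapped in esj_seqs:
            continue
        records.append(
            JunctionRecord(
                r.junction_id + "_rev",
                "rESJ",
                r.down_locus,
                r.down_exon_index,
                r.up_locus,
                r.up_exon_index,
                arm,
                swapped,
                (
                    r.genomic_breakpoints[2],
                    r.genomic_breakpoints[3],
                    r.genomic_breakpoints[0],
                    r.genomic_breakpoints[1],
                ),
            )
        )
    return JunctionDB(
        _dedupe(records),
        arm_len=arm,
        read_len=esj.read_len,
        min_overlap=esj.min_overlap,
        db_class="rESJ",
    )


def composition_profile(db: JunctionDB) -> pd.DataFrame:
    """Per-position A/C/G/T frequencies across a junction database.

    Positions are indexed -arm_len..-1 over the upstream arm (5'->3') and
    1..arm_len over the downstream arm; each row sums to 1.
    """
    if not len(db):
        raise ValueError("empty junction database")
    mat = db.sequence_matrix()
    arm = db.arm_len
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)], axis=1)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    positions = list(range(-arm, 0)) + list(range(1, arm + 1))
    return pd.DataFrame(freqs, index=pd.Index(positions, name="position"),
                        columns=list("ACGT"))
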