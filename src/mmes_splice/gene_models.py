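"""Gene models with exon structure, plus BED12 / genePred text I/O.

Coordinates are 0-based half-open throughout the package; 1-based
conventions appear only at SAM boundaries.  Exons are stored in genomic
order; transcript order equals genomic order on '+' and reversed on '-'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import revcomp


@dataclass
class GeneModel:
    """One locus: an ordered set of exons on a chromosome.

    Attributes
    ----------
    gene_id : str
        Unique locus identifier.
    chrom : str
        Chromosome / contig name.
    strand : str
        '+' or '-'.
    exons : list of (start, end)
        0-based half-open exon intervals in genomic order, strictly
        increasing and non-overlapping.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(f"{self.gene_id}: bad exon ({start}, {end})")
            if start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exons_transcript_order(self) -> list[tuple[int, int]]:
        """Exons ordered 5'->3' along the transcript."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def exon_sequence(self, genome: dict[str, str], tx_index: int) -> str:
        """Sequence of one exon in transcript (5'->3') orientation.

        ``tx_index`` counts exons in transcript order, 0 = 5'-most.
        """
        start, end = self.exons_transcript_order()[tx_index]
        seq = genome[self.chrom][start:end]
        return seq if self.strand == "+" else revcomp(seq)

    def transcript_sequence(
        self, genome: dict[str, str], exon_indices: list[int] | None = None
    ) -> str:
        """Spliced mRNA sequence for a subset of exons (transcript order)."""
        idx = exon_indices if exon_indices is not None else range(self.n_exons)
        return "".join(self.exon_sequence(genome, i) for i in idx)


def as_genome_dict(genome: dict[str, str] | str, chrom: str = "chr1") -> dict[str, str]:
    """Accept either a {chrom: seq} mapping or a bare single-chromosome string."""
    if isinstance(genome, str):
        return {chrom: genome}
    return dict(genome)


# --------------------------------------------------------------------------
# BED12
# --------------------------------------------------------------------------

def write_bed12(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.start) for s, _ in g.exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        str(g.n_exons),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 requires 12 columns, got {len(f)}")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{name}: blockCount disagrees with lists")
            exons = [
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            genes.append(GeneModel(name, chrom, strand, exons))
    return genes


# --------------------------------------------------------------------------
# genePred (UCSC table dialect: name chrom strand txStart txEnd cdsStart
# cdsEnd exonCount exonStarts exonEnds)
# --------------------------------------------------------------------------

def read_genepred(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"genePred requires >=10 columns, got {len(f)}")
            name, chrom, strand = f[0], f[1], f[2]
            n = int(f[7])
            starts = [int(x) for x in f[8].rstrip(",").split(",")][:n]
            ends = [int(x) for x in f[9].rstrip(",").split(",")][:n]
            genes.append(GeneModel(name, chrom, strand, list(zip(starts, ends))))
    return genes
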