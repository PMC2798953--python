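"""Ungapped placement of short reads on junction sequences + MMES scoring.

A read placement is a (junction, offset) pair such that the read spans the
joint point with at least ``min_overlap`` bases on each side; only
substitutions are considered (Hamming distance, no gaps).  The MMES score
of a placement — Minimal Match on Either Side of the junction — is

    N = min(L_arm - L_mismatch, R_arm - R_mismatch)

where L_arm / R_arm are the portions of the read left and right of the
joint and L_mismatch / R_mismatch the mismatches falling on each.  Exact,
centered reads score highest; mismatches on the *long* arm usually leave
the score unchanged, while short-arm mismatches always reduce it.

The mapper uses a pigeonhole seed index (max_mismatch + 1 read chunks; at
least one chunk of a within-budget placement matches exactly), with
candidate verification vectorized over numpy, and is exactly equivalent to
scanning every admissible (junction, offset) pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode_read_matrix
from .junction_db import JunctionDB

__all__ = [
    "JunctionAlignment",
    "MMESRecord",
    "admissible_offsets",
    "map_reads",
    "map_reads_frame",
    "compute_mmes",
    "score_alignments",
    "mmes_histogram",
    "ingest_sam",
    "export_sam",
]

FRAME_COLUMNS = [
    "read_id",
    "junction_id",
    "offset",
    "read_len",
    "L_arm",
    "R_arm",
    "L_mismatch",
    "R_mismatch",
    "M",
    "N",
    "is_unique",
]


@dataclass(frozen=True)
class JunctionAlignment:
    """One ungapped placement of one read on one junction sequence."""

    read_id: str
    junction_id: str
    offset: int  # 0-based start of the read on the junction sequence
    read_len: int
    L_arm: int
    R_arm: int
    L_mismatch: int
    R_mismatch: int
    mismatch_positions: tuple[int, ...]  # 0-based read coordinates
    is_unique: bool

    @property
    def M(self) -> int:
        return self.L_mismatch + self.R_mismatch


@dataclass(frozen=True)
class MMESRecord:
    alignment: JunctionAlignment
    N: int


def compute_mmes(aln: JunctionAlignment) -> int:
    """MMES score: matched bases on the weaker side of the joint."""
    return min(aln.L_arm - aln.L_mismatch, aln.R_arm - aln.R_mismatch)


def score_alignments(alignments: list[JunctionAlignment]) -> list[MMESRecord]:
    return [MMESRecord(a, compute_mmes(a)) for a in alignments]


def admissible_offsets(read_len: int, arm_len: int, min_overlap: int) -> range:
    """Offsets at which a read spans the joint with >= min_overlap on both
    sides: [arm_len - read_len + min_overlap, arm_len - min_overlap]."""
    return range(arm_len - read_len + min_overlap, arm_len - min_overlap + 1)


def _normalize_reads(reads) -> tuple[list[str], list[str]]:
    ids, seqs = [], []
    for r in reads:
        if hasattr(r, "read_id"):
            ids.append(r.read_id)
            seqs.append(str(r.sequence).upper())
        elif hasattr(r, "id") and hasattr(r, "seq"):  # Bio.SeqRecord
            ids.append(r.id)
            seqs.append(str(r.seq).upper())
        else:
            rid, seq = r
            ids.append(rid)
            seqs.append(str(seq).upper())
    return ids, seqs


def _map_arrays(
    read_mat: np.ndarray,
    junc_mat: np.ndarray,
    arm: int,
    min_overlap: int,
    max_mismatch: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All within-budget placements of every read on every junction.

    Returns (read_index, junction_index, offset, M, L_mismatch) sorted by
    (read_index, junction_index, offset).
    """
    n_reads, rl = read_mat.shape
    n_j, jlen = junc_mat.shape
    offs = admissible_offsets(rl, arm, min_overlap)
    off_lo, n_off = offs.start, len(offs)
    empty = (np.array([], dtype=np.int64),) * 3 + (
        np.array([], dtype=np.int64),
        np.array([], dtype=np.int64),
    )
    if n_reads == 0 or n_j == 0 or n_off <= 0:
        return empty

    # all admissible windows, as a strided view: (n_j, n_off, rl)
    win = np.lib.stride_tricks.sliding_window_view(junc_mat, rl, axis=1)[
        :, off_lo : off_lo + n_off, :
    ]

    # pigeonhole seed chunks: with k mismatches and k+1 chunks, at least
    # one chunk of any within-budget placement is an exact match
    chunks = np.array_split(np.arange(rl), max_mismatch + 1)
    cand_r, cand_w = [], []
    n_windows = n_j * n_off
    for chunk in chunks:
        pows = 6 ** np.arange(len(chunk), dtype=np.int64)
        w_codes = np.tensordot(
            win[:, :, chunk].astype(np.int64), pows, axes=([2], [0])
        ).ravel()
        r_codes = read_mat[:, chunk].astype(np.int64) @ pows
        order = np.argsort(w_codes, kind="stable")
        sorted_codes = w_codes[order]
        lo = np.searchsorted(sorted_codes, r_codes, side="left")
        hi = np.searchsorted(sorted_codes, r_codes, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            continue
        cand_r.append(np.repeat(np.arange(n_reads), counts))
        cand_w.append(
            np.concatenate([order[a:b] for a, b in zip(lo, hi) if b > a])
        )
    if not cand_r:
        return empty
    key = np.concatenate(cand_r) * n_windows + np.concatenate(cand_w)
    key = np.unique(key)

    r_idx = key // n_windows
    w_idx = key % n_windows
    j_idx = w_idx // n_off
    o_idx = w_idx % n_off
    offset = o_idx + off_lo

    # verify candidates in batches
    keep_r, keep_j, keep_o, keep_m, keep_lm = [], [], [], [], []
    span = np.arange(rl)
    batch = max(1, 4_000_000 // rl)
    for s in range(0, len(key), batch):
        sl = slice(s, s + batch)
        rj, jj, oo = r_idx[sl], j_idx[sl], offset[sl]
        ref = junc_mat[jj[:, None], oo[:, None] + span[None, :]]
        mism = ref != read_mat[rj]
        m = mism.sum(axis=1).astype(np.int64)
        ok = m <= max_mismatch
        if not ok.any():
            continue
        l_arm = arm - oo[ok]
        lm = (mism[ok] & (span[None, :] < l_arm[:, None])).sum(axis=1)
        keep_r.append(rj[ok])
        keep_j.append(jj[ok])
        keep_o.append(oo[ok])
        keep_m.append(m[ok])
        keep_lm.append(lm.astype(np.int64))
    if not keep_r:
        return empty
    r, j, o, m, lm = (np.concatenate(x) for x in (keep_r, keep_j, keep_o, keep_m, keep_lm))
    order = np.lexsort((o, j, r))
    return r[order], j[order], o[order], m[order], lm[order]


def _best_hit_filter(
    r: np.ndarray, m: np.ndarray, n_reads: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mask of placements in each read's minimum-mismatch set, and the
    per-read size of that set (for uniqueness flags)."""
    min_m = np.full(n_reads, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(min_m, r, m)
    best = m == min_m[r]
    n_best = np.bincount(r[best], minlength=n_reads)
    return best, n_best


def map_reads_frame(
    reads,
    db: JunctionDB,
    max_mismatch: int = 2,
    min_overlap: int | None = None,
    hit_policy: str = "best",
) -> pd.DataFrame:
    """Map reads onto a junction database; tabular output.

    ``hit_policy='best'`` keeps, per read, only the placements attaining
    the database-wide minimum mismatch count (``is_unique`` true iff that
    set is a singleton); ``'all'`` keeps every within-budget placement.
    One row per kept placement, sorted by (read, junction, offset).
    """
    if hit_policy not in ("best", "all"):
        raise ValueError(f"unknown hit_policy {hit_policy!r}")
    mo = db.min_overlap if min_overlap is None else min_overlap
    ids, seqs = _normalize_reads(reads)
    for s in seqs:
        if len(s) != db.read_len:
            raise ValueError(
                f"read length {len(s)} != database read length {db.read_len}"
            )
    read_mat = encode_read_matrix(seqs, db.read_len)
    junc_mat = db.sequence_matrix()
    r, j, o, m, lm = _map_arrays(read_mat, junc_mat, db.arm_len, mo, max_mismatch)

    best, n_best = _best_hit_filter(r, m, len(ids))
    if hit_policy == "best":
        r, j, o, m, lm = r[best], j[best], o[best], m[best], lm[best]
        unique = n_best[r] == 1
    else:
        # a read is uniquely mapped iff its best-hit set is a singleton
        unique = n_best[r] == 1

    l_arm = db.arm_len - o
    r_arm = db.read_len - l_arm
    n = np.minimum(l_arm - lm, r_arm - (m - lm))
    jid = np.asarray(db.ids, dtype=object)
    return pd.DataFrame(
        {
            "read_id": np.asarray(ids, dtype=object)[r],
            "junction_id": jid[j],
            "offset": o,
            "read_len": db.read_len,
            "L_arm": l_arm,
            "R_arm": r_arm,
            "L_mismatch": lm,
            "R_mismatch": m - lm,
            "M": m,
            "N": n,
            "is_unique": unique,
        }
    )


def map_reads(
    reads,
    db: JunctionDB,
    max_mismatch: int = 2,
    min_overlap: int | None = None,
    hit_policy: str = "best",
) -> list[JunctionAlignment]:
    """Like :func:`map_reads_frame` but returning alignment objects with
    explicit mismatch positions (0-based read coordinates)."""
    frame = map_reads_frame(reads, db, max_mismatch, min_overlap, hit_policy)
    ids, seqs = _normalize_reads(reads)
    read_seq = dict(zip(ids, seqs))
    out = []
    for row in frame.itertuples(index=False):
        ref = db[row.junction_id].sequence
        rd = read_seq[row.read_id]
        pos = tuple(
            p
            for p in range(row.read_len)
            if rd[p] != ref[row.offset + p] or rd[p] not in "ACGT"
        )
        out.append(
            JunctionAlignment(
                row.read_id,
                row.junction_id,
                int(row.offset),
                int(row.read_len),
                int(row.L_arm),
                int(row.R_arm),
                int(row.L_mismatch),
                int(row.R_mismatch),
                pos,
                bool(row.is_unique),
            )
        )
    return out


def alignments_to_frame(alignments: list[JunctionAlignment]) -> pd.DataFrame:
    rows = [
        (
            a.read_id,
            a.junction_id,
            a.offset,
            a.read_len,
            a.L_arm,
            a.R_arm,
            a.L_mismatch,
            a.R_mismatch,
            a.M,
            compute_mmes(a),
            a.is_unique,
        )
        for a in alignments
    ]
    return pd.DataFrame(rows, columns=FRAME_COLUMNS)


def mmes_histogram(
    records,
    read_len: int,
    min_overlap: int,
    max_mismatch: int = 2,
    unique_only: bool = False,
) -> pd.DataFrame:
    """Count table over (mismatch count M, MMES score N).

    Rows are N from ``min_overlap - max_mismatch`` to ``read_len // 2``;
    columns are M = 0..max_mismatch.  Accepts an alignment frame, a list
    of :class:`MMESRecord`, or a list of :class:`JunctionAlignment`.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = alignments_to_frame(
            [r.alignment if isinstance(r, MMESRecord) else r for r in records]
        )
    if unique_only and len(frame):
        frame = frame[frame["is_unique"]]
    n_vals = range(min_overlap - max_mismatch, read_len // 2 + 1)
    hist = pd.DataFrame(
        0,
        index=pd.Index(n_vals, name="N"),
        columns=pd.Index(range(max_mismatch + 1), name="M"),
    )
    if len(frame):
        counts = frame.groupby(["N", "M"]).size()
        for (n, m), c in counts.items():
            if n in hist.index and m in hist.columns:
                hist.loc[n, m] = c
            else:
                raise ValueError(f"(N={n}, M={m}) outside histogram support")
    return hist


# --------------------------------------------------------------------------
# SAM interchange
# --------------------------------------------------------------------------

def export_sam(
    frame: pd.DataFrame, reads, db: JunctionDB, path: str
) -> None:
    """Write placements as SAM with junctions as references (NM + MD tags)."""
    import pysam

    ids, seqs = _normalize_reads(reads)
    read_seq = dict(zip(ids, seqs))
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": r.junction_id, "LN": 2 * db.arm_len} for r in db.records
        ],
    }
    tid = {r.junction_id: i for i, r in enumerate(db.records)}
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for row in frame.itertuples(index=False):
            ref = db[row.junction_id].sequence
            rd = read_seq[row.read_id]
            a = pysam.AlignedSegment(out.header)
            a.query_name = row.read_id
            a.query_sequence = rd
            a.flag = 0 if row.is_unique else 256  # non-unique hits -> secondary
            a.reference_id = tid[row.junction_id]
            a.reference_start = int(row.offset)
            a.mapping_quality = 255
            a.cigarstring = f"{len(rd)}M"
            md, nm = _md_tag(rd, ref[row.offset : row.offset + len(rd)])
            a.set_tag("NM", nm)
            a.set_tag("MD", md)
            out.write(a)


def _md_tag(read: str, ref: str) -> tuple[str, int]:
    parts, run, nm = [], 0, 0
    for rb, fb in zip(read, ref):
        if rb == fb and rb in "ACGT":
            run += 1
        else:
            parts.append(str(run))
            parts.append(fb)
            run = 0
            nm += 1
    parts.append(str(run))
    return "".join(parts), nm


def ingest_sam(
    sam, db: JunctionDB, min_overlap: int | None = None
) -> list[JunctionAlignment]:
    """Recover junction alignments from a SAM file of reads mapped onto
    junction sequences.

    Only ungapped records (single-M CIGAR) carrying an MD or NM tag are
    accepted; mismatch positions are recomputed against the junction
    sequence.  Placements violating the minimum-overlap window, gapped
    records, and records lacking both tags are dropped with a warning.
    """
    import pysam

    mo = db.min_overlap if min_overlap is None else min_overlap
    if isinstance(sam, (str, bytes)):
        handle = pysam.AlignmentFile(str(sam), "r", check_sq=False)
        records = handle
    else:
        records = sam
    out = []
    n_gapped = n_window = n_untagged = 0
    window = admissible_offsets(db.read_len, db.arm_len, mo)
    for rec in records:
        if rec.is_unmapped:
            continue
        cig = rec.cigartuples
        if cig is None or len(cig) != 1 or cig[0][0] not in (0, 7, 8):
            n_gapped += 1
            continue
        if not (rec.has_tag("MD") or rec.has_tag("NM")):
            n_untagged += 1
            continue
        offset = rec.reference_start
        if offset not in window:
            n_window += 1
            continue
        ref = db[rec.reference_name].sequence
        rd = rec.query_sequence.upper()
        rl = len(rd)
        pos = tuple(
            p for p in range(rl) if rd[p] != ref[offset + p] or rd[p] not in "ACGT"
        )
        l_arm = db.arm_len - offset
        out.append(
            JunctionAlignment(
                rec.query_name,
                rec.reference_name,
                offset,
                rl,
                l_arm,
                rl - l_arm,
                sum(1 for p in pos if p < l_arm),
                sum(1 for p in pos if p >= l_arm),
                pos,
                not rec.is_secondary,
            )
        )
    dropped = n_gapped + n_window + n_untagged
    if dropped:
        warnings.warn(
            f"ingest_sam dropped {dropped} records "
            f"({n_gapped} gapped, {n_window} outside overlap window, "
            f"{n_untagged} missing MD/NM)",
            stacklevel=2,
        )
    return out
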