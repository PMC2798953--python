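"""Empirical per-read error rates and per-junction 'pseudo' p-values.

The per-read mapping error rate P_read is estimated per (MMES score N,
mismatch count M) cell as the decoy-to-target count ratio

    P_read(N, M) = min(1, (counts_ERJ(N, M) + a) / (counts_ESJ(N, M) + a))

with additive pseudocount a (default 1) so empty cells stay defined.  The
target and decoy databases are built to the same size, so raw counts are
directly comparable; an optional scale factor supports unequal databases.

A junction's pseudo p-value is the product of P_read over its covering
reads, accumulated in log10 domain — each read weighs in according to its
mapping quality, and every additional read can only lower the p-value.
The false discovery rate at a threshold is calibrated against the decoy
database: the number of decoy junctions passing the same criterion,
relative to the number of target junctions passing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ErrorRateTable",
    "JunctionCall",
    "estimate_error_rates",
    "junction_pvalue",
    "score_junctions",
    "call_junctions",
    "estimate_fdr",
    "fdr_curve",
    "categorize_calls",
    "CATEGORIES",
]

CATEGORIES = ("Common", "P0.01_uniq", "R2_uniq", "neither")


@dataclass
class ErrorRateTable:
    """Empirical P_read over the (N, M) support, plus provenance."""

    p_read: pd.DataFrame  # index N, columns M
    counts_esj: pd.DataFrame
    counts_erj: pd.DataFrame
    pseudocount: float
    read_len: int
    min_overlap: int
    max_mismatch: int

    def lookup(self, N, M) -> np.ndarray:
        """Vectorized P_read lookup for arrays of (N, M)."""
        n_min = int(self.p_read.index.min())
        dense = self.p_read.to_numpy()
        n_idx = np.asarray(N, dtype=int) - n_min
        m_idx = np.asarray(M, dtype=int)
        if (n_idx < 0).any() or (n_idx >= dense.shape[0]).any():
            raise KeyError("MMES score outside error-rate table support")
        if (m_idx < 0).any() or (m_idx >= dense.shape[1]).any():
            raise KeyError("mismatch count outside error-rate table support")
        return dense[n_idx, m_idx]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in self.p_read.index:
            for m in self.p_read.columns:
                rows.append(
                    (
                        n,
                        m,
                        int(self.counts_esj.loc[n, m]),
                        int(self.counts_erj.loc[n, m]),
                        float(self.p_read.loc[n, m]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["N", "M", "counts_esj", "counts_erj", "p_read"]
        )

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class JunctionCall:
    junction_id: str
    R: int
    log10_p: float
    p_value: float
    passed: bool | None = None
    category: str | None = None


def estimate_error_rates(
    hist_esj: pd.DataFrame,
    hist_erj: pd.DataFrame,
    pseudocount: float = 1.0,
    erj_scale: float = 1.0,
    read_len: int | None = None,
    min_overlap: int | None = None,
) -> ErrorRateTable:
    """P_read table from target (observation) and decoy (control) MMES
    histograms on an identical (N, M) support."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if not hist_esj.index.equals(hist_erj.index) or not hist_esj.columns.equals(
        hist_erj.columns
    ):
        raise ValueError("histograms must share the same (N, M) support")
    p = (hist_erj * erj_scale + pseudocount) / (hist_esj + pseudocount)
    p = p.clip(upper=1.0)
    max_m = int(hist_esj.columns.max())
    if read_len is None:
        read_len = 2 * int(hist_esj.index.max())  # N max == floor(RL/2)
    if min_overlap is None:
        min_overlap = int(hist_esj.index.min()) + max_m
    return ErrorRateTable(
        p_read=p.astype(float),
        counts_esj=hist_esj,
        counts_erj=hist_erj,
        pseudocount=pseudocount,
        read_len=read_len,
        min_overlap=min_overlap,
        max_mismatch=max_m,
    )


def junction_pvalue(alignments, table: ErrorRateTable) -> JunctionCall:
    """Pseudo p-value of a single junction from its covering reads."""
    if isinstance(alignments, pd.DataFrame):
        frame = alignments
        if frame.empty:
            raise ValueError("junction with zero covering reads is not called")
        jid = frame["junction_id"].iloc[0]
        n_vals, m_vals = frame["N"].to_numpy(), frame["M"].to_numpy()
    else:
        from .junction_map import MMESRecord, compute_mmes

        alns = list(alignments)
        if not alns:
            raise ValueError("junction with zero covering reads is not called")
        recs = [
            r if isinstance(r, MMESRecord) else MMESRecord(r, compute_mmes(r))
            for r in alns
        ]
        jid = recs[0].alignment.junction_id
        n_vals = np.array([r.N for r in recs])
        m_vals = np.array([r.alignment.M for r in recs])
    log10_p = float(np.log10(table.lookup(n_vals, m_vals)).sum())
    return JunctionCall(jid, len(n_vals), log10_p, 10.0 ** log10_p)


def score_junctions(
    aln_frame: pd.DataFrame,
    table: ErrorRateTable,
    unique_only: bool = True,
) -> pd.DataFrame:
    """Per-junction calls (junction_id, R, log10_p, p_value) for every
    junction with at least one covering read.

    By default only uniquely mapped reads contribute (conservative); pass
    ``unique_only=False`` to weight every within-policy hit.
    """
    frame = aln_frame[aln_frame["is_unique"]] if unique_only else aln_frame
    if frame.empty:
        return pd.DataFrame(columns=["junction_id", "R", "log10_p", "p_value"])
    lp = pd.Series(
        np.log10(table.lookup(frame["N"].to_numpy(), frame["M"].to_numpy())),
        index=frame.index,
    )
    grouped = pd.DataFrame(
        {"junction_id": frame["junction_id"], "log10_p": lp}
    ).groupby("junction_id", sort=True)
    out = grouped.agg(R=("log10_p", "size"), log10_p=("log10_p", "sum")).reset_index()
    out["p_value"] = 10.0 ** out["log10_p"]
    return out[["junction_id", "R", "log10_p", "p_value"]]


def call_junctions(calls: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Flag junctions passing the p-value threshold (boundary inclusive:
    a junction passes iff p_value <= threshold).  Output is stably sorted
    by (log10_p, junction_id)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    out = calls.copy()
    out["passed"] = out["p_value"] <= threshold
    return out.sort_values(
        ["log10_p", "junction_id"], kind="stable", ignore_index=True
    )


def estimate_fdr(
    esj_calls: pd.DataFrame,
    erj_calls: pd.DataFrame,
    threshold: float = 0.01,
) -> float:
    """Decoy-calibrated FDR at one threshold: decoy passes over target
    passes (clipped to [0, 1]); both call sets must come from the same
    error-rate table and equal-size databases."""
    n_erj = int((erj_calls["p_value"] <= threshold).sum())
    n_esj = int((esj_calls["p_value"] <= threshold).sum())
    return min(1.0, n_erj / max(1, n_esj))


def fdr_curve(
    esj_calls: pd.DataFrame, erj_calls: pd.DataFrame, thresholds=None
) -> pd.DataFrame:
    """FDR as a function of the p-value threshold (sweep over observed
    p-values by default)."""
    if thresholds is None:
        thresholds = np.unique(
            np.concatenate(
                [esj_calls["p_value"].to_numpy(), erj_calls["p_value"].to_numpy(), [1.0]]
            )
        )
    rows = []
    esj_p = np.sort(esj_calls["p_value"].to_numpy())
    erj_p = np.sort(erj_calls["p_value"].to_numpy())
    for t in thresholds:
        n_esj = int(np.searchsorted(esj_p, t, side="right"))
        n_erj = int(np.searchsorted(erj_p, t, side="right"))
        rows.append((t, n_esj, n_erj, min(1.0, n_erj / max(1, n_esj))))
    return pd.DataFrame(rows, columns=["threshold", "n_esj_pass", "n_erj_pass", "fdr"])


def categorize_calls(
    calls: pd.DataFrame,
    R_threshold: int = 2,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Three-way comparison categories between the empirical model and the
    read-counting rule:

    - ``Common``      p <= p_threshold and R >= R_threshold (both methods)
    - ``P0.01_uniq``  p <= p_threshold and R == 1 (empirical model only)
    - ``R2_uniq``     p >  p_threshold and R >= R_threshold (counting only)
    - ``neither``     everything else (R == 1 and p > p_threshold)
    """
    out = calls.copy()
    p = out["p_value"].to_numpy()
    r = out["R"].to_numpy()
    cat = np.full(len(out), "neither", dtype=object)
    cat[(p <= p_threshold) & (r >= R_threshold)] = "Common"
    cat[(p <= p_threshold) & (r == 1)] = "P0.01_uniq"
    cat[(p > p_threshold) & (r >= R_threshold)] = "R2_uniq"
    out["category"] = cat
    return out
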