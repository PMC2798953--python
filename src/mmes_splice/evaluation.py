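"""Performance metrics against simulated truth or sequence whitelists.

On simulated data the full confusion matrix is available, so sensitivity
and specificity can be reported alongside the positive predictive value.
Against an external transcript whitelist only PPV is meaningful — the set
of actually expressed junctions is unknown — and even that is a lower
bound, since whitelists under-represent low-abundance transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import hamming

__all__ = [
    "EvalCounts",
    "ppv_against_truth",
    "per_category_ppv",
    "match_whitelist",
    "mapped_distribution_correlation",
]


@dataclass(frozen=True)
class EvalCounts:
    """Confusion-matrix counts over an evaluated junction universe."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def ppv(self) -> float:
        """TP / (TP + FP); NaN when nothing was predicted positive."""
        denom = self.TP + self.FP
        return self.TP / denom if denom else math.nan

    @property
    def sensitivity(self) -> float:
        denom = self.TP + self.FN
        return self.TP / denom if denom else math.nan

    @property
    def specificity(self) -> float:
        denom = self.TN + self.FP
        return self.TN / denom if denom else math.nan


def _predicted_set(calls) -> tuple[set[str], set[str]]:
    """(predicted positives, evaluated universe) from a calls frame with a
    ``passed`` column, or from a plain set/sequence of accepted ids."""
    if isinstance(calls, pd.DataFrame):
        predicted = set(calls.loc[calls["passed"], "junction_id"])
        universe = set(calls["junction_id"])
    elif isinstance(calls, pd.Series):
        predicted = set(calls.index[calls.astype(bool)])
        universe = set(calls.index)
    else:
        predicted = set(calls)
        universe = set(calls)
    return predicted, universe


def ppv_against_truth(calls, truth, universe: set[str] | None = None) -> EvalCounts:
    """Confusion counts of a call set against a truth set of junction ids.

    ``truth`` may be a SimTruth (its junction_ids() are used) or any set of
    ids.  The evaluated universe defaults to the junctions appearing in
    the calls plus the truth set; sensitivity over that universe counts a
    truth junction with no call as a false negative.
    """
    truth_ids = truth.junction_ids() if hasattr(truth, "junction_ids") else set(truth)
    predicted, call_universe = _predicted_set(calls)
    if universe is None:
        universe = call_universe | truth_ids
    predicted &= universe
    truth_in = truth_ids & universe
    tp = len(predicted & truth_in)
    fp = len(predicted - truth_in)
    fn = len(truth_in - predicted)
    tn = len(universe) - tp - fp - fn
    return EvalCounts(tp, fp, tn, fn)


def per_category_ppv(categorized_calls: pd.DataFrame, truth) -> pd.DataFrame:
    """PPV per comparison category (Common / P0.01_uniq / R2_uniq / ...)."""
    truth_ids = truth.junction_ids() if hasattr(truth, "junction_ids") else set(truth)
    rows = []
    for cat, sub in categorized_calls.groupby("category", sort=True):
        ids = set(sub["junction_id"])
        n_true = len(ids & truth_ids)
        rows.append(
            {
                "category": cat,
                "n": len(ids),
                "n_verified": n_true,
                "ppv": n_true / len(ids) if ids else math.nan,
            }
        )
    return pd.DataFrame(rows)


def match_whitelist(
    sequences: dict[str, str], whitelist: list[str], max_mismatch: int = 2
) -> set[str]:
    """Ids whose sequence matches some whitelist sequence within a Hamming
    budget (whitelist entries of other lengths are compared window-wise)."""
    matched = set()
    for jid, seq in sequences.items():
        for w in whitelist:
            w = w.upper()
            if len(w) < len(seq):
                continue
            for start in range(len(w) - len(seq) + 1):
                if hamming(seq, w[start : start + len(seq)]) <= max_mismatch:
                    matched.add(jid)
                    break
            if jid in matched:
                break
    return matched


def mapped_distribution_correlation(
    aln_a: pd.DataFrame,
    aln_b: pd.DataFrame,
    by_mismatch: bool = True,
) -> dict[int | str, float]:
    """Pearson correlation of mapped-read positional distributions between
    two junction databases, per mismatch class.

    Each read is represented by the midpoint of its placement relative to
    the joint (equivalently its offset, since reads share one length);
    reads are counted per position and the two count vectors correlated.
    Zero-variance vectors yield NaN.
    """
    offsets = sorted(
        set(aln_a["offset"].unique()) | set(aln_b["offset"].unique())
    )
    if not offsets:
        return {}

    def vec(frame: pd.DataFrame) -> np.ndarray:
        counts = frame["offset"].value_counts()
        return np.array([counts.get(o, 0) for o in offsets], dtype=float)

    classes = (
        sorted(set(aln_a["M"].unique()) | set(aln_b["M"].unique()))
        if by_mismatch
        else ["all"]
    )
    out: dict[int | str, float] = {}
    for m in classes:
        fa = aln_a if m == "all" else aln_a[aln_a["M"] == m]
        fb = aln_b if m == "all" else aln_b[aln_b["M"] == m]
        va, vb = vec(fa), vec(fb)
        if va.std() == 0 or vb.std() == 0:
            out[m] = math.nan
        else:
            out[m] = float(np.corrcoef(va, vb)[0, 1])
    return out
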