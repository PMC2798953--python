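"""Comparison methods: the read-counting rule and a logistic classifier.

The read-counting rule accepts a junction iff it is covered by at least R
reads (R = 2 by default) and ignores every qualitative property of the
alignments.  The logistic-regression classifier summarises each junction's
alignments into six features spanning the quantity and quality of its read
support — read count, distinct offsets, maximum overhang, minimum and mean
mismatch counts, and the Shannon entropy of the offset distribution — and
can be augmented with the junction's maximum MMES score as a seventh
feature.  Training uses arm-swapped decoy junctions as negatives and
consecutive (adjacent-exon) junctions as positives; skipped-exon junctions
are scored but never trained on.

The fit is plain maximum likelihood via iteratively reweighted least
squares on internally z-scored features, with explicit detection of
perfect separation (coefficients capped, fit flagged).  AUC uses the
Mann-Whitney rank form with midranks for ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "JunctionFeatures",
    "LogitModel",
    "BASE_FEATURES",
    "read_count_call",
    "extract_features",
    "fit_logit",
    "rank_auc",
    "cross_validated_auc",
    "compare_methods",
]

BASE_FEATURES = [
    "n_reads",
    "n_distinct_offsets",
    "max_overhang",
    "min_mismatches",
    "mean_mismatches",
    "offset_entropy",
]


@dataclass(frozen=True)
class JunctionFeatures:
    junction_id: str
    n_reads: int
    n_distinct_offsets: int
    max_overhang: int
    min_mismatches: int
    mean_mismatches: float
    offset_entropy: float
    max_mmes: int | None = None
    label: str = "unlabeled"  # positive | negative | unlabeled


def read_count_call(calls: pd.DataFrame, R_threshold: int = 2) -> pd.Series:
    """Accept a junction iff it has at least R_threshold covering reads."""
    if R_threshold < 1:
        raise ValueError("R_threshold must be >= 1")
    return pd.Series(
        (calls["R"] >= R_threshold).to_numpy(),
        index=calls["junction_id"],
        name="accepted",
    )


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def extract_features(
    aln_frame: pd.DataFrame,
    include_mmes: bool = False,
    unique_only: bool = False,
) -> pd.DataFrame:
    """Per-junction feature table from an alignment frame.

    Junctions with zero alignments simply do not appear.  ``max_overhang``
    is the best (largest) minimum-side overlap any single read achieves,
    bounded by floor(read_len / 2); ``offset_entropy`` is 0 exactly when
    all reads stack at one offset.
    """
    frame = aln_frame[aln_frame["is_unique"]] if unique_only else aln_frame
    if frame.empty:
        cols = ["junction_id"] + BASE_FEATURES + (["max_mmes"] if include_mmes else [])
        return pd.DataFrame(columns=cols)
    overhang = np.minimum(frame["L_arm"], frame["R_arm"])
    work = pd.DataFrame(
        {
            "junction_id": frame["junction_id"],
            "offset": frame["offset"],
            "M": frame["M"],
            "overhang": overhang,
            "N": frame["N"],
        }
    )
    g = work.groupby("junction_id", sort=True)
    out = g.agg(
        n_reads=("offset", "size"),
        n_distinct_offsets=("offset", "nunique"),
        max_overhang=("overhang", "max"),
        min_mismatches=("M", "min"),
        mean_mismatches=("M", "mean"),
        max_mmes=("N", "max"),
    )
    out["offset_entropy"] = g["offset"].apply(
        lambda s: _entropy_bits(s.value_counts().to_numpy())
    )
    cols = BASE_FEATURES + (["max_mmes"] if include_mmes else [])
    return out.reset_index()[["junction_id"] + cols]


@dataclass
class LogitModel:
    """Maximum-likelihood logistic regression fit (z-scored internally)."""

    feature_names: list[str]
    coef: np.ndarray  # on the standardized scale, intercept first
    mean: np.ndarray
    scale: np.ndarray
    converged: bool
    separated: bool
    wald_z: np.ndarray | None
    llf: float
    llnull: float
    n_pos: int
    n_neg: int
    seed: int | None = None

    @property
    def lrt_chi2(self) -> float:
        """Likelihood-ratio statistic vs the intercept-only model."""
        return 2.0 * (self.llf - self.llnull)

    @property
    def lrt_df(self) -> int:
        return len(self.feature_names)

    @property
    def lrt_pvalue(self) -> float:
        return float(stats.chi2.sf(self.lrt_chi2, self.lrt_df))

    @property
    def coef_raw(self) -> np.ndarray:
        """Coefficients on the original feature scale, intercept first."""
        slopes = self.coef[1:] / self.scale
        intercept = self.coef[0] - float((self.coef[1:] * self.mean / self.scale).sum())
        return np.concatenate([[intercept], slopes])

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        z = (X - self.mean) / self.scale
        eta = self.coef[0] + z @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))


def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float((y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def fit_logit(
    X,
    y,
    feature_names: list[str] | None = None,
    seed: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    coef_cap: float = 30.0,
) -> LogitModel:
    """IRLS maximum-likelihood logistic fit with an intercept.

    Features are z-scored internally (zero-variance columns pass through
    unscaled).  Perfect separation is detected when coefficients diverge
    past ``coef_cap`` on the standardized scale; the fit is then flagged
    and the last iterate kept.  ``seed`` is recorded for provenance only —
    the fit itself is deterministic.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        feature_names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = np.column_stack([np.ones(len(y)), (X - mean) / scale])

    beta = np.zeros(Z.shape[1])
    converged = separated = False
    cov = None
    for _ in range(max_iter):
        eta = Z @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        w = np.maximum(w, 1e-12)
        # Newton step in working-response form
        z_work = eta + (y - p) / w
        A = Z.T @ (Z * w[:, None])
        b = Z.T @ (w * z_work)
        try:
            new_beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            new_beta = np.linalg.solve(A + 1e-8 * np.eye(len(beta)), b)
        step = np.abs(new_beta - beta).max()
        if np.abs(new_beta).max() > coef_cap:
            # (quasi-)separation: keep the last stable iterate, whose
            # direction already orders the classes, rather than a clipped
            # vector with distorted relative weights
            separated = True
            break
        beta = new_beta
        if step < tol:
            converged = True
            break
    p = 1.0 / (1.0 + np.exp(-(Z @ beta)))
    if not separated:
        w = np.maximum(p * (1 - p), 1e-12)
        A = Z.T @ (Z * w[:, None])
        try:
            cov = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            cov = None
    wald = beta / np.sqrt(np.diag(cov)) if cov is not None else None
    pbar = n_pos / (n_pos + n_neg)
    llnull = _log_likelihood(y, np.full_like(y, pbar))
    return LogitModel(
        feature_names=feature_names,
        coef=beta,
        mean=mean,
        scale=scale,
        converged=converged,
        separated=separated,
        wald_z=wald,
        llf=_log_likelihood(y, p),
        llnull=llnull,
        n_pos=n_pos,
        n_neg=n_neg,
        seed=seed,
    )


def rank_auc(scores, labels) -> float:
    """AUC by the Mann-Whitney rank statistic (midranks for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def cross_validated_auc(
    features: pd.DataFrame,
    labels,
    k_folds: int = 10,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """Stratified k-fold cross-validated AUC of the logistic classifier.

    Folds are junction-level and stratified; every fold must contain both
    classes.  Returns (mean AUC, per-fold AUCs).
    """
    from sklearn.model_selection import StratifiedKFold

    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y = np.asarray(labels).astype(int)
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    names = list(features.columns) if isinstance(features, pd.DataFrame) else None
    if min(int(y.sum()), int((1 - y).sum())) < k_folds:
        raise ValueError("too few members of the minority class to stratify")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    aucs = []
    for train, test in skf.split(X, y):
        model = fit_logit(X[train], y[train], feature_names=names)
        aucs.append(rank_auc(model.predict_proba(X[test]), y[test]))
    return float(np.mean(aucs)), aucs


def compare_methods(
    calls_a,
    calls_b,
    truth: set[str] | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Partition two boolean call sets over one junction universe into
    Common / A-unique / B-unique / BothUnsig, with per-category positive
    predictive value when a truth set is supplied."""
    a = pd.Series(calls_a).astype(bool)
    b = pd.Series(calls_b).astype(bool)
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError("call sets cover different junction universes")
    b = b.reindex(a.index)
    cats = {
        "Common": a & b,
        f"{labels[0]}_uniq": a & ~b,
        f"{labels[1]}_uniq": ~a & b,
        "BothUnsig": ~a & ~b,
    }
    rows = []
    for name, mask in cats.items():
        ids = set(a.index[mask])
        row = {"category": name, "n": len(ids)}
        if truth is not None:
            n_true = len(ids & truth)
            row["n_verified"] = n_true
            row["ppv"] = n_true / len(ids) if ids else math.nan
        rows.append(row)
    return pd.DataFrame(rows)
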