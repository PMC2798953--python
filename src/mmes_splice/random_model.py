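"""Random-match model: expected spurious junction hits per million reads.

Under a uniform i.i.d. model of DNA, a read of length RL placed at one
position matches with at most m mismatches with probability

    4^(-RL) * sum_{k=0}^{m} C(RL, k) * 3^k .

A junction sequence admits RL - 2*min_overlap + 1 spanning placements, so
the expected number of random hits per junction per million reads is

    X(RL, m) = 1e6 * (RL - 2*min_overlap + 1) * 4^(-RL) * sum_{k<=m} C(RL, k) 3^k .

X falls by roughly four orders of magnitude between RL = 25 and RL = 32 at
m = 2, which is why longer reads map to junctions so much more
specifically.  A Monte-Carlo estimator over random read/junction pairs
serves as an independent numerical check of the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RandomModelQuery",
    "random_hits_closed_form",
    "random_hits_monte_carlo",
    "random_hits_table",
]


@dataclass(frozen=True)
class RandomModelQuery:
    RL: int
    m: int
    min_overlap: int
    X: float


def _check_geometry(RL: int, m: int, min_overlap: int) -> None:
    if RL <= 2 * min_overlap:
        raise ValueError(
            f"infeasible geometry: RL={RL} admits no spanning placement "
            f"with min_overlap={min_overlap}"
        )
    if m < 0:
        raise ValueError("mismatch budget must be >= 0")


def random_hits_closed_form(RL: int, m: int, min_overlap: int = 4) -> float:
    """Expected random hits per junction per million reads, X(RL, m)."""
    _check_geometry(RL, m, min_overlap)
    positions = RL - 2 * min_overlap + 1
    p_match = sum(math.comb(RL, k) * 3**k for k in range(min(m, RL) + 1)) / 4**RL
    return 1e6 * positions * min(p_match, 1.0)


def random_hits_monte_carlo(
    RL: int,
    m: int,
    min_overlap: int = 4,
    n_trials: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of X with its standard error.

    Each trial draws an i.i.d. read and junction and counts admissible
    placements within the mismatch budget; the per-trial hit count is
    scaled to per-million-reads.  The SE is the sample standard error of
    the per-trial count (binomial-like, exact in the n_trials limit).
    """
    _check_geometry(RL, m, min_overlap)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    jlen = 2 * (RL - min_overlap)
    positions = RL - 2 * min_overlap + 1
    hits = np.zeros(n_trials)
    batch = max(1, 2_000_000 // (jlen * positions))
    span = np.arange(RL)
    done = 0
    while done < n_trials:
        nb = min(batch, n_trials - done)
        reads = rng.integers(0, 4, size=(nb, RL), dtype=np.int8)
        juncs = rng.integers(0, 4, size=(nb, jlen), dtype=np.int8)
        count = np.zeros(nb, dtype=np.int64)
        for off in range(positions):
            mism = (juncs[:, off + span] != reads).sum(axis=1)
            count += mism <= m
        hits[done : done + nb] = count
        done += nb
    mean = float(hits.mean())
    se = float(hits.std(ddof=1) / math.sqrt(n_trials)) if n_trials > 1 else math.inf
    return 1e6 * mean, 1e6 * se


def random_hits_table(
    rl_range=range(10, 51),
    m_range=range(0, 6),
    min_overlap: int = 4,
) -> pd.DataFrame:
    """Grid of X over read lengths and mismatch budgets (long format)."""
    rows = [
        (rl, m, random_hits_closed_form(rl, m, min_overlap))
        for rl in rl_range
        for m in m_range
        if rl > 2 * min_overlap
    ]
    return pd.DataFrame(rows, columns=["RL", "m", "X"])
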