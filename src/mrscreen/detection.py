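"""MAS5-style detection calls: Present / Marginal / Absent per probe set.

For one probe set and one sample, each probe pair yields a discrimination
score R = (PM - MM)/(PM + MM) in (-1, 1).  A one-sided Wilcoxon
signed-rank test of  median(R) > tau  produces a detection p-value; the
call is Present when p < alpha1, Absent when p > alpha2 and Marginal in
between.  Calls are computed on raw (un-normalized) intensities,
independently of the RMA expression path.

The signed-rank p-value is exact (enumeration over all sign assignments,
implemented as a rank-polynomial convolution that also handles midranks
for ties) for n <= 12 scores after zero removal, and a tie-corrected
normal approximation above.  Scores equal to tau are discarded before
ranking; if none remain the p-value is 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .containers import CallMatrix, ProbeLevelDataset

__all__ = [
    "DetectionParams",
    "discrimination_scores",
    "wilcoxon_signed_rank_p",
    "detection_call",
    "detection_calls",
    "EXACT_MAX_N",
]

#: Largest post-zero-removal sample size for which the exact signed-rank
#: distribution is enumerated; typical probe sets have 11 pairs, so real
#: calls are always exact.
EXACT_MAX_N = 12


@dataclass
class DetectionParams:
    """Thresholds of the detection call.

    ``tau`` is the discrimination threshold the scores are tested against;
    ``alpha1``/``alpha2`` are the Present and Absent p-value cutoffs.
    Defaults are the Affymetrix Statistical Algorithms values.
    """

    tau: float = 0.015
    alpha1: float = 0.04
    alpha2: float = 0.06

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha1 < self.alpha2 < 1.0):
            raise ValueError("require 0 < alpha1 < alpha2 < 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


def discrimination_scores(pm, mm) -> np.ndarray:
    """Element-wise (PM - MM)/(PM + MM); each score lies in (-1, 1)."""
    pm_arr = np.asarray(pm, dtype=np.float64)
    mm_arr = np.asarray(mm, dtype=np.float64)
    if pm_arr.shape != mm_arr.shape:
        raise ValueError(
            f"pm and mm shapes differ: {pm_arr.shape} vs {mm_arr.shape}"
        )
    if not (np.all(pm_arr > 0) and np.all(mm_arr > 0)):
        raise ValueError("intensities must be positive")
    return (pm_arr - mm_arr) / (pm_arr + mm_arr)


@lru_cache(maxsize=4096)
def _exact_sf(ranks2: Tuple[int, ...]) -> np.ndarray:
    """Survival function of 2W over all sign assignments of given ranks.

    ``ranks2`` are the doubled ranks (midranks are half-integers, so the
    doubled values are integers).  Entry ``sf[w2]`` is
    P(2W >= w2) where W is the sum of the ranks assigned a positive sign,
    each sign independently +/- with probability 1/2.
    """
    total = int(sum(ranks2))
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    sf = np.cumsum(counts[::-1])[::-1] / counts.sum()
    return sf


def _signed_rank_p_from_devs(d: np.ndarray) -> float:
    """One-sided signed-rank p for deviations ``d`` (zeros already removed)."""
    n = d.size
    if n == 0:
        return 1.0
    absd = np.abs(d)
    ranks = rankdata(absd)
    w = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        ranks2 = tuple(int(round(2 * r)) for r in sorted(ranks))
        sf = _exact_sf(ranks2)
        return float(sf[int(round(2 * w))])
    # normal approximation with tie correction (no continuity correction)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    if var <= 0:
        return 1.0 if w <= mean else 0.0
    return float(norm.sf((w - mean) / np.sqrt(var)))


def wilcoxon_signed_rank_p(scores, tau: float) -> float:
    """One-sided p-value that the median discrimination score exceeds tau.

    P(W >= w_obs) for the signed-rank statistic of (score - tau), exact by
    enumeration for n <= 12 after zero removal.  Scores equal to tau are
    discarded; if all are, the p-value is 1.
    """
    s = np.asarray(scores, dtype=np.float64).ravel()
    if s.size == 0:
        raise ValueError("empty score vector")
    d = s - tau
    return _signed_rank_p_from_devs(d[d != 0])


def _call_from_p(p: float, params: DetectionParams) -> str:
    if p < params.alpha1:
        return "P"
    if p > params.alpha2:
        return "A"
    return "M"


def detection_call(pm, mm, params: DetectionParams = None) -> Tuple[str, float]:
    """Detection call for one probe set in one sample.

    Returns ``(call, p)`` with call 'P' iff p < alpha1, 'A' iff
    p > alpha2, 'M' otherwise.
    """
    if params is None:
        params = DetectionParams()
    p = wilcoxon_signed_rank_p(discrimination_scores(pm, mm), params.tau)
    return _call_from_p(p, params), p


def detection_calls(
    dataset: ProbeLevelDataset, params: DetectionParams = None
) -> CallMatrix:
    """Detection calls for every (probe set, sample) cell of a dataset.

    Probe sets are returned lexicographically sorted, matching the RMA
    expression matrix.
    """
    if params is None:
        params = DetectionParams()
    blocks = dataset.blocks()
    probesets = sorted(blocks)
    n_ps, n_s = len(probesets), dataset.n_samples
    pvals = np.empty((n_ps, n_s))
    for i, ps in enumerate(probesets):
        rows = blocks[ps]
        scores = discrimination_scores(dataset.pm[rows], dataset.mm[rows])
        d = scores - params.tau
        nonzero_ok = not np.any(d == 0)
        if nonzero_ok and d.shape[0] <= EXACT_MAX_N:
            ranks = rankdata(np.abs(d), axis=0)
            for j in range(n_s):
                ranks2 = tuple(
                    int(round(2 * r)) for r in np.sort(ranks[:, j])
                )
                sf = _exact_sf(ranks2)
                w = float(ranks[:, j][d[:, j] > 0].sum())
                pvals[i, j] = sf[int(round(2 * w))]
        else:
            for j in range(n_s):
                dj = d[:, j]
                pvals[i, j] = _signed_rank_p_from_devs(dj[dj != 0])
    calls = np.full((n_ps, n_s), "M", dtype=object)
    calls[pvals < params.alpha1] = "P"
    calls[pvals > params.alpha2] = "A"
    index = pd.Index(probesets)
    return CallMatrix(
        calls=pd.DataFrame(calls, index=index, columns=dataset.samples),
        pvalues=pd.DataFrame(pvals, index=index, columns=dataset.samples),
    )
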