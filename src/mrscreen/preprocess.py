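"""RMA preprocessing: background correction, normalization, summarization.

The robust multiarray average (RMA) turns probe-level PM intensities into
one log2 expression value per probe set and sample in four steps:

1. per-array background correction under a normal + exponential
   convolution model (observed = N(mu, sigma^2) background + Exp(alpha)
   signal), replacing each PM intensity by E[signal | observed];
2. quantile normalization across arrays;
3. log2 transformation;
4. per-probe-set summarization by Tukey's median polish of the additive
   model  log2(PM) = overall + probe effect + sample effect.

MM intensities are never used on this path; they feed the detection-call
path in :mod:`mrscreen.detection`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr

from .containers import ExpressionMatrix, ProbeLevelDataset

__all__ = [
    "NormexpParams",
    "estimate_normexp_params",
    "normexp_adjust",
    "quantile_normalize",
    "median_polish_summarize",
    "rma",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class NormexpParams:
    """Parameters of the normal + exponential convolution.

    ``mu``/``sigma`` describe the additive normal background, ``alpha_inv``
    is the mean of the exponential true-signal component (the inverse of
    the exponential rate), all in raw intensity units.
    """

    mu: float
    sigma: float
    alpha_inv: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not self.alpha_inv > 0:
            raise ValueError("alpha_inv must be > 0")


def _normexp_nll(theta: np.ndarray, x: np.ndarray) -> float:
    """Negative log-likelihood of the N+Exp convolution.

    ``theta = (mu, log sigma, log alpha)``.  The density is

        f(x) = (1/alpha) exp((mu - x)/alpha + sigma^2/(2 alpha^2))
               * Phi((x - mu - sigma^2/alpha) / sigma)

    evaluated through ``log_ndtr`` for numerical stability.
    """
    mu = theta[0]
    sigma = np.exp(theta[1])
    alpha = np.exp(theta[2])
    z = (x - mu - sigma * sigma / alpha) / sigma
    ll = (
        -np.log(alpha)
        + (mu - x) / alpha
        + sigma * sigma / (2.0 * alpha * alpha)
        + log_ndtr(z)
    )
    total = ll.sum()
    if not np.isfinite(total):
        return 1e300
    return -total


def estimate_normexp_params(
    pm_intensities: Sequence[float], *, tol: float = 1e-8
) -> NormexpParams:
    """Fit the normal + exponential convolution to one array's intensities.

    Maximum-likelihood fit started from method-of-moments values (the
    exponential mean from the third central moment, the normal variance
    from the remainder of the variance).  The data are rescaled by their
    mean before optimization, which makes the estimate exactly
    scale-equivariant for power-of-two scalings and numerically so
    otherwise.

    Raises
    ------
    ValueError
        If the input is degenerate (all values equal); background
        correction should be skipped for such data.
    """
    x = np.asarray(pm_intensities, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty intensity vector")
    if not np.all(np.isfinite(x)) or not np.all(x > 0):
        raise ValueError("intensities must be finite and > 0")
    if np.ptp(x) == 0.0:
        raise ValueError(
            "all intensities identical; skip background correction for this array"
        )
    scale = float(np.mean(x))
    y = x / scale

    m = float(np.mean(y))
    v = float(np.var(y))
    m3 = float(np.mean((y - m) ** 3))
    alpha0 = max((max(m3, 1e-12) / 2.0) ** (1.0 / 3.0), 1e-6)
    sigma0 = np.sqrt(max(v - alpha0 * alpha0, 0.05 * v, 1e-12))
    mu0 = m - alpha0

    theta0 = np.array([mu0, np.log(sigma0), np.log(alpha0)])
    res = optimize.minimize(
        _normexp_nll,
        theta0,
        args=(y,),
        method="L-BFGS-B",
        options={"ftol": tol * 1e-4, "gtol": tol, "maxiter": 500},
    )
    mu, log_sigma, log_alpha = res.x
    return NormexpParams(
        mu=mu * scale,
        sigma=float(np.exp(log_sigma)) * scale,
        alpha_inv=float(np.exp(log_alpha)) * scale,
    )


def normexp_adjust(x, params: NormexpParams):
    """Background-adjust observed intensities: E[signal | observed = x].

    Closed form for the N+Exp posterior mean,

        E[S | X = x] = a + sigma * phi(a/sigma) / Phi(a/sigma),
        a = x - mu - sigma^2 / alpha_inv,

    which is strictly positive and strictly increasing in ``x``.  Accepts
    scalars or arrays.
    """
    x_arr = np.asarray(x, dtype=np.float64)
    a = x_arr - params.mu - params.sigma**2 / params.alpha_inv
    z = a / params.sigma
    # sigma * phi(z) / Phi(z), computed in log space to survive z << 0
    log_ratio = -0.5 * z * z - _LOG_SQRT_2PI - log_ndtr(z)
    out = a + params.sigma * np.exp(log_ratio)
    # the exact expression is positive; guard against rounding at extremes
    out = np.maximum(out, np.finfo(np.float64).tiny)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def quantile_normalize(matrix) -> np.ndarray:
    """Force every column (array) to share the same empirical distribution.

    Each column's values are replaced, rank for rank, by the across-column
    means of the sorted columns.  Ties within a column keep their original
    order (stable sort), so repeated application is a no-op.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got ndim={m.ndim}")
    if m.size == 0:
        raise ValueError("empty matrix")
    order = np.argsort(m, axis=0, kind="stable")
    sorted_cols = np.take_along_axis(m, order, axis=0)
    means = sorted_cols.mean(axis=1)
    # mean of identical order stats must be that value bit-exactly, so a
    # second application is a true no-op
    same = (sorted_cols == sorted_cols[:, :1]).all(axis=1)
    means[same] = sorted_cols[same, 0]
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        out[order[:, j], j] = means
    return out


def median_polish_summarize(
    probeset_block, *, tol: float = 1e-13, max_iter: int = 2000
) -> np.ndarray:
    """Summarize one probe set's log2 PM block into one value per sample.

    Alternating median sweeps fit  value = overall + probe + sample
    robustly; the returned summaries are overall + sample effects.  Sweeps
    stop when the largest absolute change of the residual matrix falls
    below ``tol`` or after ``max_iter`` iterations.  Medians of even-length
    vectors are the mean of the central pair.
    """
    z = np.asarray(probeset_block, dtype=np.float64)
    if z.ndim == 1:
        z = z[np.newaxis, :]
    if z.ndim != 2 or z.size == 0:
        raise ValueError("probeset block must be a non-empty 2-D array")
    z = z.copy()
    overall = 0.0
    row_eff = np.zeros(z.shape[0])
    col_eff = np.zeros(z.shape[1])
    for _ in range(max_iter):
        z_old = z.copy()
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, np.newaxis]
        row_eff += rdelta
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta
        cdelta = np.median(z, axis=0)
        z -= cdelta[np.newaxis, :]
        col_eff += cdelta
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta
        if np.max(np.abs(z - z_old)) < tol:
            break
    return overall + col_eff


def _median_polish_batch(
    blocks: np.ndarray, *, tol: float = 1e-13, max_iter: int = 2000
) -> np.ndarray:
    """Vectorized median polish of many equally-shaped blocks.

    ``blocks`` has shape (B, n_probes, n_samples); returns (B, n_samples).
    Each block follows exactly the per-block iteration schedule of
    :func:`median_polish_summarize` (blocks that converge stop sweeping).
    """
    z = np.array(blocks, dtype=np.float64)
    if z.ndim != 3 or z.size == 0:
        raise ValueError("expected a non-empty (B, probes, samples) array")
    B, _, S = z.shape
    overall = np.zeros(B)
    row_eff = np.zeros(z.shape[:2])
    col_eff = np.zeros((B, S))
    active = np.arange(B)
    for _ in range(max_iter):
        za = z[active]
        z_old = za.copy()
        rdelta = np.median(za, axis=2)
        za -= rdelta[:, :, np.newaxis]
        row_eff[active] += rdelta
        delta = np.median(col_eff[active], axis=1)
        col_eff[active] -= delta[:, np.newaxis]
        overall[active] += delta
        cdelta = np.median(za, axis=1)
        za -= cdelta[:, np.newaxis, :]
        col_eff[active] += cdelta
        delta = np.median(row_eff[active], axis=1)
        row_eff[active] -= delta[:, np.newaxis]
        overall[active] += delta
        z[active] = za
        changed = np.max(np.abs(za - z_old), axis=(1, 2)) >= tol
        active = active[changed]
        if active.size == 0:
            break
    return overall[:, np.newaxis] + col_eff


def rma(
    dataset: ProbeLevelDataset,
    *,
    medpolish_tol: float = 1e-13,
    medpolish_max_iter: int = 2000,
) -> ExpressionMatrix:
    """Run the full RMA chain on a probe-level dataset.

    Per-sample normexp background adjustment of PM, quantile normalization
    across samples, log2, and per-probe-set median polish.  Probe sets are
    returned lexicographically sorted so the output is invariant to input
    row order.
    """
    corrected = np.empty_like(dataset.pm)
    for j in range(dataset.n_samples):
        params = estimate_normexp_params(dataset.pm[:, j])
        corrected[:, j] = normexp_adjust(dataset.pm[:, j], params)
    normalized = quantile_normalize(corrected)
    log2m = np.log2(normalized)

    blocks = dataset.blocks()
    probesets = sorted(blocks)
    values = np.empty((len(probesets), dataset.n_samples))
    # group probe sets by pair count so each group polishes as one 3-D batch
    by_size: Dict[int, list] = {}
    for i, ps in enumerate(probesets):
        by_size.setdefault(len(blocks[ps]), []).append(i)
    for size, idxs in by_size.items():
        stacked = np.stack([log2m[blocks[probesets[i]]] for i in idxs])
        values[idxs] = _median_polish_batch(
            stacked, tol=medpolish_tol, max_iter=medpolish_max_iter
        )
    df = pd.DataFrame(values, index=probesets, columns=dataset.samples)
    return ExpressionMatrix(df)
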