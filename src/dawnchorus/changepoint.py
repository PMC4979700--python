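"""Bayesian change-point analysis of the daily ACI series.

The model is the Barry–Hartigan normal product-partition model: the series
``x_1 .. x_n`` is partitioned into contiguous blocks, observations within a
block are iid N(mu_block, sigma^2), block means draw from a common normal
prior, and each of the n-1 positions is a change point independently with
probability p.  With uniform priors p ~ U(0, p0) and w ~ U(0, w0) — where
``w = sigma^2 / (sigma^2 + sigma0^2)`` is the within/total variance ratio —
and flat priors on the grand mean and log sigma^2, the marginal weight of a
partition rho with b blocks (k = b - 1 change points) is::

    g(rho)  =  [ int_0^p0 p^k (1-p)^(n-1-k) dp ]
             * [ int_0^w0 w^(k/2) (W + w B)^(-(n-1)/2) dw ]

with W the within-block and B the between-block sum of squares.  The
posterior probability of a change at position i is the g-weighted fraction
of partitions with a boundary there.

Two routes compute it:

* :func:`bcp_fit` — Gibbs sampling over the change indicators (the
  conditional odds of toggling one indicator follow from g), with the
  conventional 10,000 iterations after 5,000 burn-in.  A "high" probability
  of change is > 0.5.
* :func:`exact_change_probabilities` — exhaustive summation over all
  2^(n-1) partitions, feasible for n <= ~16; the calibration oracle for the
  sampler.

The w-integral has no closed form and is evaluated by midpoint quadrature on
a fixed 64-point grid shared by both routes, so they target the identical
posterior.  Hyperparameter caps default to p0 = w0 = 0.2, the convention of
the established R implementation lineage of this model.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as date_type

import numpy as np
import pandas as pd
from numba import njit
from scipy import special

#: Default caps of the uniform priors on p (change probability) and w.
P0_MAX = 0.2
W0_MAX = 0.2

_N_GRID = 64
_TINY = 1e-300


def _w_grid(w0: float, n_points: int = _N_GRID):
    """Midpoint quadrature nodes/weight on (0, w0]."""
    dw = w0 / n_points
    w = (np.arange(n_points) + 0.5) * dw
    return w, np.log(w), np.log(dw)


def _log_p_table(n: int, p0: float) -> np.ndarray:
    """log int_0^p0 p^k (1-p)^(n-1-k) dp for k = 0 .. n-1."""
    m = n - 1
    k = np.arange(m + 1)
    a, b = k + 1.0, m - k + 1.0
    reg = special.betainc(a, b, p0)
    return special.betaln(a, b) + np.log(np.maximum(reg, _TINY))


@njit(cache=True)
def _log_iw(k, W, B, half_nm1, logw, w, logdw):  # pragma: no cover - jit
    """log of the w-integral for k change points, by midpoint quadrature."""
    m = -1e308
    vals = np.empty(logw.size)
    for j in range(logw.size):
        s = W + w[j] * B
        if s < _TINY:
            s = _TINY
        v = 0.5 * k * logw[j] - half_nm1 * np.log(s)
        vals[j] = v
        if v > m:
            m = v
    acc = 0.0
    for j in range(vals.size):
        acc += np.exp(vals[j] - m)
    return m + np.log(acc) + logdw


@njit(cache=True)
def _gibbs(x, logp_tab, logw, w, logdw, iterations, burn_in, rand):  # pragma: no cover - jit
    """Gibbs sweeps over change indicators; returns (probs, posterior_mean).

    ``x`` is mean-centred.  ``rand`` holds pre-drawn uniforms of shape
    (iterations, n-1).  Probabilities are post-burn-in inclusion fractions;
    the posterior mean averages, per sweep, the blockwise shrinkage estimate
    ``(1 - w_hat) * blockmean`` with ``w_hat`` the conditional posterior mean
    of w given the partition.
    """
    n = x.size
    half_nm1 = 0.5 * (n - 1)
    cs1 = np.zeros(n + 1)
    cs2 = 0.0
    for i in range(n):
        cs1[i + 1] = cs1[i] + x[i]
        cs2 += x[i] * x[i]
    u = np.zeros(n, dtype=np.int64)
    u[0] = 1
    k = 0  # free change points
    T = cs1[n] ** 2 / n  # sum over blocks of s^2/c (single block start)
    counts = np.zeros(n)
    pm = np.zeros(n)
    kept = 0
    for it in range(iterations):
        for i in range(1, n):
            l = i - 1
            while u[l] == 0:
                l -= 1
            r = i + 1
            while r < n and u[r] == 0:
                r += 1
            s_li = cs1[i] - cs1[l]
            s_ir = cs1[r] - cs1[i]
            s_lr = cs1[r] - cs1[l]
            t_split = s_li * s_li / (i - l) + s_ir * s_ir / (r - i)
            t_merge = s_lr * s_lr / (r - l)
            if u[i] == 1:
                t_rest = T - t_split
                k1, k0 = k, k - 1
            else:
                t_rest = T - t_merge
                k1, k0 = k + 1, k
            T1 = t_rest + t_split
            T0 = t_rest + t_merge
            W1 = cs2 - T1
            if W1 < 0.0:
                W1 = 0.0
            W0 = cs2 - T0
            if W0 < 0.0:
                W0 = 0.0
            B1 = T1  # x centred: n*xbar^2 = cs1[n]^2/n ~ 0
            B0 = T0
            if B1 < 0.0:
                B1 = 0.0
            if B0 < 0.0:
                B0 = 0.0
            logodds = (
                logp_tab[k1]
                - logp_tab[k0]
                + _log_iw(k1, W1, B1, half_nm1, logw, w, logdw)
                - _log_iw(k0, W0, B0, half_nm1, logw, w, logdw)
            )
            if logodds > 35.0:
                p_change = 1.0
            elif logodds < -35.0:
                p_change = 0.0
            else:
                p_change = 1.0 / (1.0 + np.exp(-logodds))
            if rand[it, i - 1] < p_change:
                u[i] = 1
                T = T1
                k = k1
            else:
                u[i] = 0
                T = T0
                k = k0
        if it >= burn_in:
            kept += 1
            # conditional posterior mean of w given the partition
            W = cs2 - T
            if W < 0.0:
                W = 0.0
            B = T if T > 0.0 else 0.0
            mmax = -1e308
            vals = np.empty(w.size)
            for j in range(w.size):
                s = W + w[j] * B
                if s < _TINY:
                    s = _TINY
                v = 0.5 * k * logw[j] - half_nm1 * np.log(s)
                vals[j] = v
                if v > mmax:
                    mmax = v
            num = 0.0
            den = 0.0
            for j in range(w.size):
                e = np.exp(vals[j] - mmax)
                num += w[j] * e
                den += e
            w_hat = num / den
            l = 0
            for r in range(1, n + 1):
                if r == n or u[r] == 1:
                    bm = (cs1[r] - cs1[l]) / (r - l)
                    for t in range(l, r):
                        pm[t] += (1.0 - w_hat) * bm
                    l = r
            for i in range(1, n):
                counts[i] += u[i]
    return counts / kept, pm / kept


@dataclass(frozen=True)
class ChangePointResult:
    """Posterior summaries of the product-partition change-point fit."""

    dates: tuple
    posterior_mean: np.ndarray
    posterior_prob: np.ndarray
    iterations: int
    burn_in: int
    seed: int
    p0: float
    w0: float

    def to_frame(self, series: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "date": list(self.dates),
                "posterior_mean": self.posterior_mean,
                "posterior_prob": self.posterior_prob,
            }
        )
        if series is not None:
            df.insert(1, "aci", np.asarray(series, dtype=float))
        return df


def _validate_series(series) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.size < 3:
        raise ValueError(f"series too short for change-point analysis (n={x.size})")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains NaN/inf; drop excluded days first")
    return x


def bcp_fit(
    series,
    dates=None,
    iterations: int = 10000,
    burn_in: int = 5000,
    seed: int = 0,
    p0: float = P0_MAX,
    w0: float = W0_MAX,
) -> ChangePointResult:
    """Fit the product-partition change-point model by Gibbs sampling.

    Parameters
    ----------
    series : array
        Daily values (e.g. ACI), no missing entries, length >= 3.
    dates : sequence, optional
        Aligned labels carried through to the result (defaults to indices).
    iterations, burn_in : int
        Total MCMC sweeps and the number discarded; iterations > burn_in.
    seed : int
        Seeds the pre-drawn uniforms; a fixed seed reproduces the result.
    p0, w0 : float
        Caps of the uniform priors on the change probability and the
        variance ratio.

    Returns
    -------
    ChangePointResult
        ``posterior_prob[i]`` is the post-burn-in fraction of sweeps with a
        block boundary immediately before observation ``i``
        (``posterior_prob[0]`` is 0 by convention); ``posterior_mean`` is the
        per-day posterior estimate of the underlying mean.
    """
    x = _validate_series(series)
    n = x.size
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    if dates is None:
        dates = tuple(range(n))
    else:
        dates = tuple(dates)
        if len(dates) != n:
            raise ValueError("dates and series lengths differ")
    mu = float(np.mean(x))
    xc = x - mu
    w, logw, logdw = _w_grid(w0)
    logp_tab = _log_p_table(n, p0)
    rng = np.random.default_rng(seed)
    rand = rng.random((iterations, n - 1))
    probs, pm = _gibbs(
        xc, logp_tab, logw, w, logdw, int(iterations), int(burn_in), rand
    )
    return ChangePointResult(
        dates=dates,
        posterior_mean=pm + mu,
        posterior_prob=probs,
        iterations=int(iterations),
        burn_in=int(burn_in),
        seed=int(seed),
        p0=float(p0),
        w0=float(w0),
    )


def exact_change_probabilities(
    series, p0: float = P0_MAX, w0: float = W0_MAX, max_n: int = 16
) -> np.ndarray:
    """Exact per-position change probabilities by partition enumeration.

    Sums the partition weights g(rho) over all 2^(n-1) partitions — the
    brute-force counterpart of :func:`bcp_fit`, identical priors and
    quadrature.  Only feasible for small n (guarded by ``max_n``).
    """
    x = _validate_series(series)
    n = x.size
    if n > max_n:
        raise ValueError(f"exact enumeration limited to n <= {max_n}")
    xc = x - np.mean(x)
    cs1 = np.concatenate([[0.0], np.cumsum(xc)])
    ss = float(np.sum(xc**2))
    w, logw, logdw = _w_grid(w0)
    logp_tab = _log_p_table(n, p0)
    half_nm1 = 0.5 * (n - 1)

    m = n - 1
    log_weights = np.empty(2**m)
    members = np.zeros((2**m, n), dtype=bool)
    for code in range(2**m):
        bounds = [0]
        for i in range(1, n):
            if code >> (i - 1) & 1:
                bounds.append(i)
                members[code, i] = True
        bounds.append(n)
        T = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            s = cs1[b] - cs1[a]
            T += s * s / (b - a)
        W = max(ss - T, 0.0)
        B = max(T, 0.0)
        k = len(bounds) - 2
        vals = 0.5 * k * logw - half_nm1 * np.log(np.maximum(W + w * B, _TINY))
        vmax = vals.max()
        log_iw = vmax + np.log(np.sum(np.exp(vals - vmax))) + logdw
        log_weights[code] = logp_tab[k] + log_iw

    log_weights -= log_weights.max()
    weights = np.exp(log_weights)
    weights /= weights.sum()
    return weights @ members


@dataclass(frozen=True)
class Transition:
    """A detected high-probability change in the daily series."""

    date: object
    index: int
    prob: float
    fold_change: float
    baseline_days: int


def detect_transition(
    result: ChangePointResult,
    series,
    threshold: float = 0.5,
    baseline: int | None = None,
) -> Transition | None:
    """Earliest high-probability change peak and its ACI fold-change.

    A peak is the earliest strict local maximum of ``posterior_prob`` whose
    value strictly exceeds ``threshold`` (a plateau counts once, at its
    earliest index; series ends count as -inf neighbours).  The fold-change
    is the series value on the peak day divided by the mean over the
    preceding days (all of them, or the last ``baseline`` of them).  Peaks at
    the first position have no baseline and are not eligible.

    Returns ``None`` when no peak exceeds the threshold.
    """
    x = np.asarray(series, dtype=float)
    prob = np.asarray(result.posterior_prob, dtype=float)
    if x.size != prob.size:
        raise ValueError("series and result are not aligned")
    n = prob.size
    i = 1
    while i < n:
        j = i
        while j + 1 < n and prob[j + 1] == prob[i]:
            j += 1
        left = prob[i - 1] if i > 0 else -np.inf
        right = prob[j + 1] if j + 1 < n else -np.inf
        if prob[i] > threshold and prob[i] > left and prob[i] > right:
            lo = 0 if baseline is None else max(0, i - baseline)
            base = float(np.mean(x[lo:i]))
            return Transition(
                date=result.dates[i],
                index=int(i),
                prob=float(prob[i]),
                fold_change=float(x[i] / base),
                baseline_days=int(i - lo),
            )
        i = j + 1
    return None
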