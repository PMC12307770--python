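"""Uni- vs multi-modality of endpoint distributions via 1-D Gaussian
mixtures and BIC model selection.

A K-component Gaussian mixture is fitted by EM with random restarts; the
number of modes is decided by fitting K = 1..K_max and taking the K with
the highest BIC, where BIC is oriented higher-is-better:

    BIC = 2 * loglik - p * ln(n)

with p = 3K - 1 free parameters (K weights summing to one, K means,
K variances) or p = 2K under the equal-variance restriction.  BIC values
are additionally min-max scaled to [0, 1] over the K grid for plotting, so
the winning K sits at 1 and the worst at 0.

EM details: initial means at spread quantiles of the data (jittered across
restarts), equal initial weights, pooled-variance initialisation; a
variance floor of 1e-6 times the sample variance guards against components
collapsing onto repeated values; convergence when the log-likelihood gain
drops below ``tol``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_N_STARTS = 10
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 500
VARIANCE_FLOOR_FRAC = 1e-6


@dataclass
class MixtureFit:
    """One EM fit: parameters sorted by component mean."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    bic: float
    converged: bool
    n_iter: int
    n_obs: int
    loglik_trace: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < -1e-12):
            raise ValueError("negative mixture weight")
        if np.any(self.variances <= 0):
            raise ValueError("non-positive component variance")

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        comp = np.exp(
            -0.5 * (x - self.means) ** 2 / self.variances
        ) / np.sqrt(2 * math.pi * self.variances)
        return np.sum(self.weights * comp, axis=-1)


@dataclass
class ModalityDecision:
    best_k: int
    bic_by_k: dict[int, float]
    scaled_bic_by_k: dict[int, float]
    fits: dict[int, MixtureFit] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "best_K": self.best_k,
            "bic_by_K": {str(k): v for k, v in self.bic_by_k.items()},
            "scaled_bic_by_K": {
                str(k): v for k, v in self.scaled_bic_by_k.items()
            },
        }


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _log_gauss(x, mean, var):
    return -0.5 * ((x - mean) ** 2 / var + np.log(2 * math.pi * var))


def _logsumexp_last(a):
    """log-sum-exp over the last axis (max-subtract, no scipy overhead)."""
    m = a.max(axis=-1, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=-1, keepdims=True)))[..., 0]


def _em_batch(x, k, means0, var0, floor, tol, max_iter, equal_variance):
    """EM for all restarts at once (batch axis = restart).

    Each restart follows the sequential algorithm exactly: E step, check
    the log-likelihood gain (convergence freezes that restart's
    parameters), M step.  Returns per-restart parameter arrays, final
    log-likelihoods, convergence flags, iteration counts and the
    log-likelihood trace matrix.
    """
    n = x.size
    S = means0.shape[0]
    weights = np.full((S, k), 1.0 / k)
    means = means0.copy()
    variances = np.full((S, k), max(var0, floor))
    xx = x[None, :, None]  # (1, n, 1)
    trace = np.full((max_iter, S), np.nan)
    prev = np.full(S, -np.inf)
    loglik = np.full(S, -np.inf)
    converged = np.zeros(S, dtype=bool)
    n_iter = np.zeros(S, dtype=int)
    active = np.ones(S, dtype=bool)
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        # E step
        log_comp = (
            np.log(weights[idx])[:, None, :]
            + _log_gauss(xx, means[idx][:, None, :],
                         variances[idx][:, None, :])
        )
        log_norm = _logsumexp_last(log_comp)  # (A, n)
        ll = log_norm.sum(axis=1)
        trace[it - 1, idx] = ll
        loglik[idx] = ll
        n_iter[idx] = it
        if it > 1:
            done = ll - prev[idx] < tol
            converged[idx[done]] = True
            active[idx[done]] = False
            keep = ~done
            idx = idx[keep]
            if idx.size == 0:
                break
            log_comp = log_comp[keep]
            log_norm = log_norm[keep]
            ll = ll[keep]
        prev[idx] = ll
        # M step
        resp = np.exp(log_comp - log_norm[:, :, None])  # (A, n, k)
        nk = np.maximum(resp.sum(axis=1), 1e-300)  # (A, k)
        weights[idx] = nk / n
        means[idx] = (resp * xx).sum(axis=1) / nk
        dev2 = (xx - means[idx][:, None, :]) ** 2
        if equal_variance:
            v = np.maximum((resp * dev2).sum(axis=(1, 2)) / n, floor)
            variances[idx] = v[:, None]
        else:
            variances[idx] = np.maximum((resp * dev2).sum(axis=1) / nk,
                                        floor)
    return weights, means, variances, loglik, converged, n_iter, trace


def fit_gmm_1d(
    x,
    k: int,
    n_starts: int = DEFAULT_N_STARTS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
    equal_variance: bool = False,
) -> MixtureFit:
    """EM fit of a K-component univariate Gaussian mixture.

    Runs ``n_starts`` restarts (the first from exact quantile means, the
    rest jittered) and keeps the best by log-likelihood.  Requires at least
    3K observations.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    n = x.size
    if n < 3 * k:
        raise ValueError(f"need >= {3 * k} samples to fit K = {k}, got {n}")
    samp_var = float(np.var(x))
    floor = max(VARIANCE_FLOOR_FRAC * samp_var, 1e-300)
    rng = np.random.default_rng(seed)

    # K = 1 has a closed-form ML solution; EM would converge to it anyway
    if k == 1:
        mean = float(np.mean(x))
        var = max(samp_var, floor)
        loglik = float(np.sum(_log_gauss(x, mean, var)))
        bic = 2 * loglik - 2 * math.log(n)  # p = 2 either way at K = 1
        return MixtureFit(
            k=1, weights=np.array([1.0]), means=np.array([mean]),
            variances=np.array([var]), loglik=loglik, bic=bic,
            converged=True, n_iter=0, n_obs=n,
            loglik_trace=np.array([loglik]),
        )

    base_q = np.linspace(0.5 / k, 1 - 0.5 / k, k)
    qs = [base_q] + [
        np.sort(rng.uniform(0.02, 0.98, size=k)) for _ in range(n_starts - 1)
    ]
    means0 = np.stack([np.quantile(x, q) for q in qs])
    w_all, m_all, v_all, ll_all, conv_all, it_all, trace_all = _em_batch(
        x, k, means0, samp_var, floor, tol, max_iter, equal_variance
    )
    best_s = int(np.argmax(ll_all))
    weights, means, variances = w_all[best_s], m_all[best_s], v_all[best_s]
    loglik, converged, n_iter = ll_all[best_s], conv_all[best_s], \
        it_all[best_s]
    trace = trace_all[: n_iter, best_s]
    if not conv_all.any():
        warnings.warn(f"EM did not converge in any of {n_starts} restarts "
                      f"for K = {k}", stacklevel=2)

    order = np.argsort(means)
    p = 2 * k if equal_variance else 3 * k - 1
    bic = 2 * loglik - p * math.log(n)
    return MixtureFit(
        k=k, weights=weights[order], means=means[order],
        variances=variances[order], loglik=float(loglik), bic=float(bic),
        converged=bool(converged), n_iter=int(n_iter), n_obs=n,
        loglik_trace=trace,
    )


# ---------------------------------------------------------------------------
# modality decision
# ---------------------------------------------------------------------------

def select_modality(
    x,
    k_max: int = 3,
    n_starts: int = DEFAULT_N_STARTS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
    equal_variance: bool = False,
) -> ModalityDecision:
    """Fit K = 1..k_max mixtures and pick the K with the highest BIC.

    Scaled BIC is the min-max rescaling of the raw BICs over the K grid
    (winner = 1, worst = 0).  K values that cannot be fitted (too few
    samples) are excluded with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    fits: dict[int, MixtureFit] = {}
    rng = np.random.default_rng(seed)
    for k in range(1, k_max + 1):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            fits[k] = fit_gmm_1d(x, k, n_starts=n_starts, tol=tol,
                                 max_iter=max_iter, seed=sub_seed,
                                 equal_variance=equal_variance)
        except ValueError as exc:
            warnings.warn(f"K = {k} excluded: {exc}", stacklevel=2)
    if not fits:
        raise ValueError("no component count could be fitted")
    bic = {k: f.bic for k, f in fits.items()}
    vals = np.array(list(bic.values()))
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        scaled = {k: (v - lo) / (hi - lo) for k, v in bic.items()}
    else:
        scaled = {k: 0.0 for k in bic}
    best_k = max(bic, key=lambda k: (bic[k], -k))
    return ModalityDecision(best_k=best_k, bic_by_k=bic,
                            scaled_bic_by_k=scaled, fits=fits)
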