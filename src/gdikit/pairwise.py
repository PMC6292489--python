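"""Pairwise (two sequences per locus) JC likelihoods under isolation models.

Each locus contributes two sequences, one from each population, reduced to
the sufficient statistic (x, n): the mismatch count over n sites.  Under the
two-species isolation model H2 with divergence time ``tau`` and ancestral
size ``theta_AB``, the pair coalesces at ``tau + v`` with ``v`` exponential
of rate ``2/theta_AB``, and the per-site mismatch probability at one-lineage
depth ``t`` is the JC saturation curve ``p(t) = (3/4)(1 - exp(-8t/3))``
(total path length ``2t``).  The one-species model H1 is the ``tau = 0``
special case with ``theta = theta_AB``.

The module also provides the coalescence-time law of a pair under the
isolation-with-migration model (from the reduced 5-state chain), Monte-Carlo
generation of mismatch data under that law, maximum-likelihood fitting of
H1/H2, and the infinite-data (Kullback-Leibler) best-fitting parameters of
H2 when the data truly come from the IM model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln

from . import ctmc
from .ctmc import IMParams

__all__ = [
    "PairwiseLocusData",
    "H1Params",
    "H2Params",
    "H2Fit",
    "jc_mismatch_prob",
    "loglik_H1",
    "loglik_H2",
    "fit_H1",
    "fit_H2",
    "PairCoalescenceTimeLaw",
    "im_pair_time_law",
    "im_mismatch_distribution",
    "best_fit_expected",
    "simulate_pairwise_dataset",
    "simulate_h2_dataset",
]

N_QUAD = 64  # Gauss-Legendre nodes for the exponential ancestral-time integral


def jc_mismatch_prob(t):
    """Per-site mismatch probability for two sequences at one-lineage depth t.

    Total path length between the sequences is 2t, so
    ``p = (3/4)(1 - exp(-8t/3))``.
    """
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("t must be >= 0")
    return 0.75 * -np.expm1(-8.0 * t / 3.0)


@dataclass(frozen=True)
class PairwiseLocusData:
    """Histogram of per-locus mismatch counts for a fixed site count n.

    ``counts[x]`` is the number of loci with exactly x mismatching sites;
    the likelihood only depends on this histogram (loci are exchangeable).
    """

    counts: np.ndarray
    n_sites: int

    def __post_init__(self):
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (self.n_sites + 1,):
            raise ValueError("counts must have length n_sites + 1")
        if (counts < 0).any():
            raise ValueError("counts must be >= 0")

    @classmethod
    def from_mismatches(cls, x: np.ndarray, n_sites: int) -> "PairwiseLocusData":
        x = np.asarray(x, dtype=int)
        if (x < 0).any() or (x > n_sites).any():
            raise ValueError("mismatch counts must lie in [0, n_sites]")
        return cls(np.bincount(x, minlength=n_sites + 1), n_sites)

    @property
    def n_loci(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class H1Params:
    theta: float

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


@dataclass(frozen=True)
class H2Params:
    tau: float
    theta_AB: float

    def __post_init__(self):
        if self.tau < 0 or self.theta_AB <= 0:
            raise ValueError("need tau >= 0 and theta_AB > 0")


# Gauss-Legendre nodes on (0,1) with the substitution v = theta*u/(2(1-u)),
# under which (2/theta) exp(-2v/theta) dv = exp(-u/(1-u))/(1-u)^2 du.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(N_QUAD)
_UQ = 0.5 * (_GL_X + 1.0)
_WQ = 0.5 * _GL_W * np.exp(-_UQ / (1.0 - _UQ)) / (1.0 - _UQ) ** 2


def _log_binom_pmf(x: np.ndarray, n: int, p: np.ndarray) -> np.ndarray:
    """log Binom(x | n, p) broadcast over x (rows) and p (columns)."""
    x = x[:, None].astype(float)
    p = np.clip(p[None, :], 1e-300, 1.0 - 1e-16)
    return (
        gammaln(n + 1)
        - gammaln(x + 1)
        - gammaln(n - x + 1)
        + x * np.log(p)
        + (n - x) * np.log1p(-p)
    )


def _mismatch_probs_H2(x: np.ndarray, n: int, params: H2Params) -> np.ndarray:
    """P(X = x) under H2 for each requested mismatch count x."""
    v = params.theta_AB * _UQ / (2.0 * (1.0 - _UQ))
    p = jc_mismatch_prob(params.tau + v)
    pmf = np.exp(_log_binom_pmf(x, n, p))
    return pmf @ _WQ


def loglik_H2(data: PairwiseLocusData, params: H2Params) -> float:
    """Log-likelihood of the mismatch histogram under the isolation model.

    The per-locus likelihood integrates the JC binomial over the exponential
    coalescent time in the ancestor (64-node Gauss-Legendre after the
    log-compressing substitution); the histogram restricts the sum to
    observed mismatch counts.
    """
    xs = np.flatnonzero(data.counts)
    q = _mismatch_probs_H2(xs, data.n_sites, params)
    if (q <= 0).any():
        return -np.inf
    return float(data.counts[xs] @ np.log(q))


def loglik_H1(data: PairwiseLocusData, params: H1Params) -> float:
    """H1 equals H2 with tau = 0 and theta_AB = theta."""
    return loglik_H2(data, H2Params(0.0, params.theta))


def _moment_theta(data: PairwiseLocusData) -> float:
    """JC-corrected mean distance as a rough scale for theta."""
    xs = np.arange(data.n_sites + 1)
    pbar = float((data.counts @ xs) / (data.n_loci * data.n_sites))
    pbar = min(pbar, 0.74)
    tbar = -3.0 / 8.0 * np.log1p(-4.0 * pbar / 3.0)  # one-lineage depth
    return max(2.0 * tbar, 1e-6)


@dataclass(frozen=True)
class H2Fit:
    tau: float
    theta_AB: float
    loglik: float
    at_boundary: bool  # tau = 0 optimal (model collapses to H1)
    converged: bool


def _fit_objective_factory(weighted_counts, xs, n):
    def nll(logparams):
        tau, theta = np.exp(logparams)
        q = _mismatch_probs_H2(xs, n, H2Params(tau, theta))
        if (q <= 0).any() or not np.all(np.isfinite(q)):
            return np.inf
        return -float(weighted_counts @ np.log(q))

    return nll


def _maximize_H2(weighted_counts, xs, n, theta_scale) -> H2Fit:
    nll = _fit_objective_factory(weighted_counts, xs, n)
    starts = [
        (np.log(tau0), np.log(th0))
        for tau0 in (1e-5, 1e-4, 1e-3, 5e-3)
        for th0 in (0.5 * theta_scale, 2.0 * theta_scale)
    ]
    best = None
    for s in starts:
        r = minimize(nll, s, method="Nelder-Mead",
                     options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000})
        if best is None or r.fun < best.fun:
            best = r
    tau, theta = np.exp(best.x)
    # profile the tau = 0 boundary explicitly (H1 nested in H2)
    def nll0(logth):
        return nll((-np.inf, logth))

    r0 = minimize_scalar(
        nll0, bracket=(np.log(theta_scale * 0.5), np.log(theta_scale * 2.0))
    )
    if r0.fun <= best.fun:
        return H2Fit(0.0, float(np.exp(r0.x)), -float(r0.fun), True, True)
    return H2Fit(float(tau), float(theta), -float(best.fun), False, bool(best.success))


def fit_H2(data: PairwiseLocusData) -> H2Fit:
    """Maximum-likelihood (tau, theta_AB) under the isolation model.

    Deterministic multistart (tau in {1e-5, 1e-4, 1e-3, 5e-3} crossed with a
    moment estimate of theta times {0.5, 2}) over log-transformed parameters;
    the tau = 0 boundary is profiled separately and flagged when optimal.
    """
    xs = np.flatnonzero(data.counts)
    return _maximize_H2(data.counts[xs].astype(float), xs, data.n_sites,
                        _moment_theta(data))


def fit_H1(data: PairwiseLocusData) -> tuple[float, float]:
    """MLE of theta under the one-species model; returns (theta_hat, loglik)."""
    scale = _moment_theta(data)

    def nll(logth):
        return -loglik_H1(data, H1Params(float(np.exp(logth))))

    r = minimize_scalar(nll, bracket=(np.log(scale * 0.5), np.log(scale * 2.0)))
    return float(np.exp(r.x)), -float(r.fun)


# --- coalescence-time law under the IM model --------------------------------


class PairCoalescenceTimeLaw:
    """Law of the coalescence time of one sequence from each population.

    Before ``tau`` the law follows the reduced 5-state chain (density =
    probability of the two co-resident configurations times the local
    coalescent rate); lineages surviving to ``tau`` coalesce in the ancestor
    at rate ``2/theta_AB``.  The sampler inverts the CDF on a dense grid
    over [0, tau] and draws the exponential tail analytically.
    """

    _GRID = 4096

    def __init__(self, params: IMParams):
        self.params = params
        self.theta_AB = params.require_ancestral()
        Q = ctmc.build_pair_rate_matrix(params)
        self._ts = np.linspace(0.0, params.tau, self._GRID + 1)
        dec = ctmc.SpectralDecomposition.from_matrix(Q)
        start = ctmc.PAIR_STATES.index("AB")
        Ps = np.stack(
            [ctmc.transition_matrix(Q, t, dec) for t in self._ts]
        )  # (grid+1, 5, 5)
        row = Ps[:, start, :]
        iAA = ctmc.PAIR_STATES.index("AA")
        iBB = ctmc.PAIR_STATES.index("BB")
        iC = ctmc.PAIR_STATES.index("C")
        self._cdf_grid = row[:, iC]
        self._pdf_grid = row[:, iAA] * params.c_A + row[:, iBB] * params.c_B
        self.cdf_tau = float(self._cdf_grid[-1])

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        tau = self.params.tau
        before = np.interp(t, self._ts, self._pdf_grid)
        rate = 2.0 / self.theta_AB
        after = (1.0 - self.cdf_tau) * rate * np.exp(-rate * (t - tau))
        return np.where(t < tau, before, after)

    def pdf_exact(self, t: np.ndarray) -> np.ndarray:
        """Density at t < tau evaluated from the chain itself (no grid)."""
        Q = ctmc.build_pair_rate_matrix(self.params)
        dec = ctmc.SpectralDecomposition.from_matrix(Q)
        start = ctmc.PAIR_STATES.index("AB")
        iAA = ctmc.PAIR_STATES.index("AA")
        iBB = ctmc.PAIR_STATES.index("BB")
        out = np.empty(len(t))
        for k, tk in enumerate(np.asarray(t, dtype=float)):
            row = ctmc.transition_matrix(Q, tk, dec)[start]
            out[k] = row[iAA] * self.params.c_A + row[iBB] * self.params.c_B
        return out

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        tau = self.params.tau
        before = np.interp(t, self._ts, self._cdf_grid)
        rate = 2.0 / self.theta_AB
        after = 1.0 - (1.0 - self.cdf_tau) * np.exp(-rate * np.maximum(t - tau, 0.0))
        return np.where(t < tau, before, after)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(size)
        out = np.empty(size)
        early = u < self.cdf_tau
        out[early] = np.interp(u[early], self._cdf_grid, self._ts)
        k = int((~early).sum())
        out[~early] = self.params.tau + rng.exponential(self.theta_AB / 2.0, size=k)
        return out


def im_pair_time_law(params: IMParams) -> PairCoalescenceTimeLaw:
    return PairCoalescenceTimeLaw(params)


def im_mismatch_distribution(params: IMParams, n: int) -> np.ndarray:
    """Exact-to-quadrature distribution of the mismatch count under IM.

    ``q(x) = int f_IM(t) Binom(x | n, p(t)) dt`` split at tau: Gauss-Legendre
    on [0, tau] against the chain density plus the exponential ancestral tail.
    """
    law = PairCoalescenceTimeLaw(params)
    xs = np.arange(n + 1)
    # before tau: 128-node Gauss-Legendre
    gx, gw = np.polynomial.legendre.leggauss(128)
    t_nodes = 0.5 * params.tau * (gx + 1.0)
    w_nodes = 0.5 * params.tau * gw * law.pdf_exact(t_nodes)
    pmf_before = np.exp(_log_binom_pmf(xs, n, jc_mismatch_prob(t_nodes)))
    q = pmf_before @ w_nodes
    # after tau: exponential in the ancestor
    v = law.theta_AB * _UQ / (2.0 * (1.0 - _UQ))
    pmf_after = np.exp(_log_binom_pmf(xs, n, jc_mismatch_prob(params.tau + v)))
    q = q + (1.0 - law.cdf_tau) * (pmf_after @ _WQ)
    return q


def best_fit_expected(params_true: IMParams, n: int) -> H2Fit:
    """Infinite-data (KL-optimal) H2 parameters against the true IM model.

    Maximizes the expected log-likelihood ``E_q[log p(x | tau, theta_AB)]``
    where ``q`` is the analytic IM mismatch distribution — the limit of
    ``fit_H2`` as the number of loci grows, free of Monte-Carlo noise.
    """
    q = im_mismatch_distribution(params_true, n)
    xs = np.flatnonzero(q > 1e-16)
    theta_scale = max(2.0 * float(q @ np.arange(n + 1)) / n, 1e-4)
    return _maximize_H2(q[xs], xs, n, theta_scale)


# --- data generators --------------------------------------------------------


def simulate_pairwise_dataset(
    params: IMParams, n_loci: int, n_sites: int, rng: np.random.Generator
) -> PairwiseLocusData:
    """Mismatch counts for loci of two sequences (one per population) under IM.

    The coalescence time is drawn from the analytic pair law and sites are
    i.i.d. JC, so the mismatch count is binomial given the time — equivalent
    to (and much faster than) simulating the full alignment.
    """
    law = PairCoalescenceTimeLaw(params)
    t = law.sample(n_loci, rng)
    x = rng.binomial(n_sites, jc_mismatch_prob(t))
    return PairwiseLocusData.from_mismatches(x, n_sites)


def simulate_h2_dataset(
    params: H2Params, n_loci: int, n_sites: int, rng: np.random.Generator
) -> PairwiseLocusData:
    """Mismatch counts under the two-species isolation model itself."""
    t = params.tau + rng.exponential(params.theta_AB / 2.0, size=n_loci)
    x = rng.binomial(n_sites, jc_mismatch_prob(t))
    return PairwiseLocusData.from_mismatches(x, n_sites)
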