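"""Analytic gene-tree probability P1 and the genealogical divergence index.

For a sample of two sequences from a focal population A and one from
population B, ``P1`` is the probability that the two A sequences coalesce
with each other first, so that the gene tree is ``G1 = ((a1,a2),b)``.  P1
ranges from 1/3 (three exchangeable sequences, e.g. infinite migration) to 1,
and the genealogical divergence index rescales it to [0, 1]:

    gdi = (3*P1 - 1) / 2.

Without migration ``P1 = 1 - (2/3) exp(-2 tau/theta_A)`` and
``gdi = 1 - exp(-2 tau/theta_A)``, where ``2 tau/theta_A`` is the population
divergence in coalescent units.  With migration, P1 is computed from the
21-state coalescent-with-migration chain: the first coalescence may happen
before the populations merge (density ``f(t)``, integrated over ``(0,tau)``)
or all three lineages may survive to the ancestral population, where each
of the three topologies is equally likely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ctmc
from .ctmc import IMParams, SpectralDecomposition

__all__ = [
    "GeneTreeProbResult",
    "GdiValue",
    "first_coal_density",
    "prob_gene_tree_G1",
    "gdi_from_P1",
    "gdi_no_migration",
    "P1_no_migration",
    "pair_coal_prob_before_tau",
    "gdi_surface",
    "threshold_map",
]


@dataclass(frozen=True)
class GeneTreeProbResult:
    """P1 split into its before- and after-divergence contributions."""

    P1: float
    part_before_tau: float
    part_after_tau: float


@dataclass(frozen=True)
class GdiValue:
    gdi: float
    provenance: str = "analytic_IM"


_SS = ctmc.enumerate_states()
_AAB = _SS.index["AAB"]


def _chain(params: IMParams):
    Q = ctmc.build_rate_matrix(params)
    return Q, SpectralDecomposition.from_matrix(Q)


def first_coal_density(params: IMParams, t: float) -> float:
    """Density f(t) of the first coalescence (between a1 and a2) at t < tau.

    ``f(t) = [p_AAB,AAA(t) + p_AAB,AAB(t)] * 2/theta_A
           + [p_AAB,BBA(t) + p_AAB,BBB(t)] * 2/theta_B``:
    the two A-sequences must be co-resident right before t (in A or in B)
    and then coalesce at that deme's pairwise rate.
    """
    if not 0 <= t < params.tau:
        raise ValueError("t must lie in [0, tau)")
    Q, dec = _chain(params)
    P = ctmc.transition_matrix(Q, t, dec)
    i = _SS.index
    return float(
        (P[_AAB, i["AAA"]] + P[_AAB, i["AAB"]]) * params.c_A
        + (P[_AAB, i["BBA"]] + P[_AAB, i["BBB"]]) * params.c_B
    )


def prob_gene_tree_G1(params: IMParams) -> GeneTreeProbResult:
    """Probability of gene tree ((a1,a2),b) under the IM model.

    The before-tau part integrates ``f(t)`` via the time-integrated
    transition probabilities; the after-tau part is one third of the
    probability that no coalescence occurs by ``tau`` (all three lineages
    entering the ancestral population are exchangeable).
    """
    tau = params.tau
    if tau == 0:
        return GeneTreeProbResult(1.0 / 3.0, 0.0, 1.0 / 3.0)
    Q, dec = _chain(params)
    I = ctmc.integrated_transition(Q, tau, dec)
    P = ctmc.transition_matrix(Q, tau, dec)
    i = _SS.index
    before = float(
        (I[_AAB, i["AAA"]] + I[_AAB, i["AAB"]]) * params.c_A
        + (I[_AAB, i["BBA"]] + I[_AAB, i["BBB"]]) * params.c_B
    )
    after = float(P[_AAB, list(_SS.S3)].sum()) / 3.0
    return GeneTreeProbResult(before + after, before, after)


def gdi_from_P1(P1: float, provenance: str = "analytic_IM") -> GdiValue:
    """Rescale P1 in [1/3, 1] to the index gdi = (3*P1 - 1)/2 in [0, 1]."""
    if P1 < 1.0 / 3.0 - 1e-9 or P1 > 1.0 + 1e-9:
        raise ValueError(f"P1 = {P1} outside [1/3, 1]")
    return GdiValue(min(max((3.0 * P1 - 1.0) / 2.0, 0.0), 1.0), provenance)


def P1_no_migration(tau: float, theta_A: float) -> float:
    """Closed form P1 = 1 - (2/3) exp(-2 tau/theta_A) for M = 0."""
    if tau < 0 or theta_A <= 0:
        raise ValueError("need tau >= 0 and theta_A > 0")
    return 1.0 - (2.0 / 3.0) * np.exp(-2.0 * tau / theta_A)


def gdi_no_migration(tau: float, theta_A: float) -> GdiValue:
    """Closed form gdi = 1 - exp(-2 tau/theta_A) for M = 0."""
    if tau < 0 or theta_A <= 0:
        raise ValueError("need tau >= 0 and theta_A > 0")
    return GdiValue(float(1.0 - np.exp(-2.0 * tau / theta_A)), "closed_form_no_migration")


def pair_coal_prob_before_tau(params: IMParams) -> float:
    """P(two sequences, one per population, coalesce before tau).

    Uses the reduced 5-state two-sequence chain (an independent instantiation
    of the movement/coalescence rules): the probability of absorption into
    the coalesced state by time tau, starting from one lineage in each deme.
    Zero when both migration rates are zero.
    """
    if params.M_AB == 0 and params.M_BA == 0:
        return 0.0
    Q = ctmc.build_pair_rate_matrix(params)
    P = ctmc.transition_matrix(Q, params.tau)
    return float(P[ctmc.PAIR_STATES.index("AB"), ctmc.PAIR_STATES.index("C")])


def gdi_surface(
    grid_2tau_over_theta=None,
    grid_M=None,
    theta: float = 0.01,
) -> "pandas.DataFrame":
    """P1 (and gdi) on a grid of divergence (coalescent units) x migration.

    Evaluates the symmetric model theta_A = theta_B = theta,
    M_AB = M_BA = M at every grid point.  Default grid spans divergences
    2*tau/theta in [0, 5] (51 points) and M in [0, 10] (41 points).
    """
    import pandas as pd

    if grid_2tau_over_theta is None:
        grid_2tau_over_theta = np.linspace(0.0, 5.0, 51)
    if grid_M is None:
        grid_M = np.linspace(0.0, 10.0, 41)
    grid_2tau_over_theta = np.asarray(grid_2tau_over_theta, dtype=float)
    grid_M = np.asarray(grid_M, dtype=float)
    if grid_2tau_over_theta.size == 0 or grid_M.size == 0:
        raise ValueError("grids must be non-empty")
    if (grid_2tau_over_theta < 0).any() or (grid_M < 0).any():
        raise ValueError("grid values must be >= 0")
    rows = []
    for d in grid_2tau_over_theta:
        tau = d * theta / 2.0
        for M in grid_M:
            if M == 0:
                p1 = P1_no_migration(tau, theta)
            else:
                p1 = prob_gene_tree_G1(IMParams(theta, theta, tau, M, M)).P1
            rows.append((d, M, p1, gdi_from_P1(p1).gdi))
    return pd.DataFrame(rows, columns=["div_coalescent_units", "M", "P1", "gdi"])


def threshold_map(gdi_bounds: tuple[float, float], direction: str = "gdi->P1"):
    """Map gdi thresholds to P1 or to no-migration coalescent-unit divergence.

    ``P1 = (2*gdi + 1)/3``; ``2*tau/theta = -log(1 - gdi)`` (infinite when
    gdi = 1).  The conventional single/distinct bounds (0.2, 0.7) map to P1
    (0.47, 0.80) and to divergences (0.22, 1.20).
    """
    lo, hi = gdi_bounds
    for g in (lo, hi):
        if not 0 <= g <= 1:
            raise ValueError("gdi bounds must lie in [0, 1]")
    if direction == "gdi->P1":
        return tuple((2.0 * g + 1.0) / 3.0 for g in (lo, hi))
    if direction == "gdi->coalescent_units":
        return tuple(
            float("inf") if g >= 1.0 else -np.log1p(-g) for g in (lo, hi)
        )
    raise ValueError(f"unknown direction {direction!r}")
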