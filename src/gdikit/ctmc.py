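"""Coalescent-with-migration continuous-time Markov chains for two populations.

Tracing a sample of up to three sequences (``a1``, ``a2`` from population A,
``b`` from population B) backwards in time, each lineage currently residing
in a population can migrate to the other population and each pair of
co-resident lineages can coalesce.  The genealogical process is a CTMC on 21
states: 8 states with three lineages (labelled by the populations holding
``a1, a2, b``, e.g. ``AAB``), 12 states with two lineages (one free sequence
and one coalesced pair, e.g. ``AB_b`` = pair ``a1a2`` in A, ``b`` in B), and
one absorbing state ``A|B`` reached after the second coalescence.

All rates and times are in expected mutations per site.  The mutation-scaled
lineage movement rates are ``w_AB = 4*M_AB/theta_B`` (a lineage in B traces
its ancestry into A) and ``w_BA = 4*M_BA/theta_A``; the per-pair coalescent
rates are ``c_A = 2/theta_A`` and ``c_B = 2/theta_B``.

A reduced 5-state chain for a single sequence per population (used for the
pair coalescence probability and the coalescence-time law) is built from the
same movement/coalescence rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.integrate import quad_vec

__all__ = [
    "IMParams",
    "StateSpace",
    "SpectralDecomposition",
    "enumerate_states",
    "build_rate_matrix",
    "build_pair_rate_matrix",
    "PAIR_STATES",
    "transition_matrix",
    "integrated_transition",
]

#: condition-number threshold above which the eigenvector route is distrusted
COND_LIMIT = 1e8
#: maximum tolerated deviation of U @ inv(U) from the identity
INVERSE_TOL = 1e-8


@dataclass(frozen=True)
class IMParams:
    """Two-population isolation-with-migration parameterization.

    Parameters
    ----------
    theta_A, theta_B : float
        Population-size parameters (4*N*mu), expected mutations/site, > 0.
    tau : float
        Population divergence time, expected mutations/site, >= 0.
    M_AB, M_BA : float
        Scaled migration rates M_ij = N_j * m_ij, expected immigrants per
        generation into population j from population i, >= 0.
    theta_AB : float, optional
        Ancestral population size; only needed by operations that follow
        lineages beyond ``tau`` (simulators, pair coalescence-time law).
    """

    theta_A: float
    theta_B: float
    tau: float
    M_AB: float = 0.0
    M_BA: float = 0.0
    theta_AB: float | None = None

    def __post_init__(self) -> None:
        if not (self.theta_A > 0 and self.theta_B > 0):
            raise ValueError("theta_A and theta_B must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.M_AB < 0 or self.M_BA < 0:
            raise ValueError("migration rates must be >= 0")
        if self.theta_AB is not None and self.theta_AB <= 0:
            raise ValueError("theta_AB must be > 0 when given")

    # mutation-scaled movement rates (backwards in time): a lineage now in A
    # traces into B at rate w_BA = 4 M_BA / theta_A = m_BA / mu, and vice versa.
    @property
    def w_AB(self) -> float:
        return 4.0 * self.M_AB / self.theta_B

    @property
    def w_BA(self) -> float:
        return 4.0 * self.M_BA / self.theta_A

    @property
    def c_A(self) -> float:
        return 2.0 / self.theta_A

    @property
    def c_B(self) -> float:
        return 2.0 / self.theta_B

    def require_ancestral(self) -> float:
        if self.theta_AB is None:
            raise ValueError("this operation needs theta_AB (ancestral size)")
        return self.theta_AB

    def movement_rate(self, deme: str) -> float:
        """Backward-time emigration rate for a lineage currently in `deme`."""
        return self.w_BA if deme == "A" else self.w_AB

    def coal_rate(self, deme: str) -> float:
        return self.c_A if deme == "A" else self.c_B


# --- state space ------------------------------------------------------------

_SEQ_NAMES = ("a1", "a2", "b")


@dataclass(frozen=True)
class StateSpace:
    """Canonical ordering of the 21 states of the three-sequence chain."""

    ordered_states: tuple[str, ...]
    structured: tuple[tuple, ...]  # parallel machine-readable encodings
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "index", {s: i for i, s in enumerate(self.ordered_states)}
        )

    @property
    def n_states(self) -> int:
        return len(self.ordered_states)

    @property
    def triple_states(self) -> tuple[str, ...]:
        return self.ordered_states[:8]

    @property
    def S3(self) -> tuple[int, ...]:
        """Indices of the 8 states in which all three lineages survive."""
        return tuple(range(8))

    @property
    def absorbing_index(self) -> int:
        return self.n_states - 1


def enumerate_states() -> StateSpace:
    """Enumerate the 21 states in the canonical (documented) order.

    Order: the 8 triple-lineage states ``AAA .. BBB`` (demes of ``a1,a2,b``
    in binary order with A < B), then the 12 pair states grouped by location
    pattern — free-and-pair both in A (``A_a1A``, ``A_a2A``, ``A_bA``), both
    in B, free in A / pair in B, pair in A / free in B (``AB_a1`` ..) — and
    finally the absorbing state ``A|B``.
    """
    labels: list[str] = []
    structured: list[tuple] = []
    for d1 in "AB":
        for d2 in "AB":
            for d3 in "AB":
                labels.append(d1 + d2 + d3)
                structured.append(("triple", (d1, d2, d3)))
    # (free deme, pair deme) patterns in the canonical order
    for free_deme, pair_deme, fmt in (
        ("A", "A", "A_{0}A"),
        ("B", "B", "B_{0}B"),
        ("A", "B", "A_{0}B"),
        ("B", "A", "AB_{0}"),
    ):
        for free in _SEQ_NAMES:
            labels.append(fmt.format(free))
            structured.append(("pair", free, free_deme, pair_deme))
    labels.append("A|B")
    structured.append(("absorbed",))
    return StateSpace(tuple(labels), tuple(structured))


_STATE_SPACE = enumerate_states()


def _pair_label(free: str, free_deme: str, pair_deme: str) -> str:
    if free_deme == "A" and pair_deme == "A":
        return f"A_{free}A"
    if free_deme == "B" and pair_deme == "B":
        return f"B_{free}B"
    if free_deme == "A" and pair_deme == "B":
        return f"A_{free}B"
    return f"AB_{free}"


def build_rate_matrix(params: IMParams, states: StateSpace | None = None) -> np.ndarray:
    """Build the 21x21 generator from the movement/coalescence rules.

    The matrix is generated programmatically rather than transcribed: each
    lineage in A jumps to B at rate ``w_BA`` (and B to A at ``w_AB``); each
    co-resident pair in A coalesces at rate ``c_A`` (in B at ``c_B``).  The
    first coalescence moves a triple state to the corresponding pair state;
    the second moves any pair state to ``A|B``.  Diagonal = -row sum.
    """
    if states is None:
        states = _STATE_SPACE
    n = states.n_states
    Q = np.zeros((n, n))
    idx = states.index
    other = {"A": "B", "B": "A"}
    for i, enc in enumerate(states.structured):
        kind = enc[0]
        if kind == "triple":
            demes = enc[1]
            # migrations: move one lineage at a time
            for k in range(3):
                new = list(demes)
                new[k] = other[demes[k]]
                Q[i, idx["".join(new)]] += params.movement_rate(demes[k])
            # coalescences of co-resident pairs
            for p, q_ in ((0, 1), (0, 2), (1, 2)):
                if demes[p] == demes[q_]:
                    free_k = 3 - p - q_
                    lbl = _pair_label(_SEQ_NAMES[free_k], demes[free_k], demes[p])
                    Q[i, idx[lbl]] += params.coal_rate(demes[p])
        elif kind == "pair":
            free, fd, pd = enc[1], enc[2], enc[3]
            Q[i, idx[_pair_label(free, other[fd], pd)]] += params.movement_rate(fd)
            Q[i, idx[_pair_label(free, fd, other[pd])]] += params.movement_rate(pd)
            if fd == pd:
                Q[i, idx["A|B"]] += params.coal_rate(fd)
        # absorbed: no exits
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


# --- reduced chain: one sequence in each population -------------------------

#: states of the two-sequence chain: demes of (a, b), then coalesced.
PAIR_STATES: tuple[str, ...] = ("AB", "AA", "BB", "BA", "C")


def build_pair_rate_matrix(params: IMParams) -> np.ndarray:
    """5-state generator for two sequences, one initially in each population.

    State labels give the demes of lineages ``a`` and ``b``; ``C`` is the
    absorbing coalesced state.  Built from the same movement/coalescence
    rules as the 21-state chain, as an independent small-scale cross-check.
    """
    idx = {s: i for i, s in enumerate(PAIR_STATES)}
    other = {"A": "B", "B": "A"}
    Q = np.zeros((5, 5))
    for s in PAIR_STATES[:-1]:
        i = idx[s]
        da, db = s[0], s[1]
        Q[i, idx[other[da] + db]] += params.movement_rate(da)
        Q[i, idx[da + other[db]]] += params.movement_rate(db)
        if da == db:
            Q[i, idx["C"]] += params.coal_rate(da)
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


# --- spectral machinery -----------------------------------------------------


@dataclass
class SpectralDecomposition:
    """Eigensystem Q = U diag(lambda) V with V = U^-1."""

    eigenvalues: np.ndarray
    U: np.ndarray
    V: np.ndarray
    cond: float

    @classmethod
    def from_matrix(cls, Q: np.ndarray) -> "SpectralDecomposition":
        lam, U = np.linalg.eig(Q)
        cond = np.linalg.cond(U)
        V = np.linalg.inv(U)
        return cls(lam, U, V, float(cond))

    @property
    def reliable(self) -> bool:
        """Whether the eigenvector route is numerically trustworthy.

        The chain's a1/a2 exchange symmetry forces genuinely repeated
        eigenvalues at every parameter value, so multiplicity alone is not
        a defect: what matters is that the eigenvector basis is complete and
        well-conditioned.  A near-defective generator shows up as a huge
        condition number of U or an inaccurate inverse, in which case
        callers fall back to ``expm``/quadrature.
        """
        if not np.isfinite(self.cond) or self.cond >= COND_LIMIT:
            return False
        resid = np.abs(self.U @ self.V - np.eye(self.U.shape[0])).max()
        return bool(resid < INVERSE_TOL)


def _assert_real(M: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    if np.iscomplexobj(M):
        if np.max(np.abs(M.imag)) > tol:
            raise ArithmeticError("imaginary residue exceeds tolerance")
        return np.ascontiguousarray(M.real)
    return M


def transition_matrix(
    Q: np.ndarray, t: float, decomp: SpectralDecomposition | None = None
) -> np.ndarray:
    """Transition probabilities P(t) = exp(Qt).

    Uses the spectral form ``p_ij(t) = sum_k u_ik v_kj exp(lambda_k t)``
    when the eigensystem is well-conditioned, otherwise scaling-and-squaring
    ``expm``.  The output is real (imaginary residue < 1e-10 discarded) and
    row-stochastic.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return np.eye(Q.shape[0])
    if decomp is None:
        decomp = SpectralDecomposition.from_matrix(Q)
    if decomp.reliable:
        P = (decomp.U * np.exp(decomp.eigenvalues * t)) @ decomp.V
        P = _assert_real(P)
    else:
        P = expm(Q * t)
    return P


def integrated_transition(
    Q: np.ndarray, tau: float, decomp: SpectralDecomposition | None = None
) -> np.ndarray:
    """Time-integrated transition probabilities ``int_0^tau P(t) dt``.

    Spectral route: ``sum_k u_ik v_kj (exp(lambda_k tau) - 1)/lambda_k``,
    with the term replaced by its limit ``u_ik v_kj tau`` when
    ``|lambda_k| < 1e-10``.  Falls back to adaptive quadrature of ``expm``
    for ill-conditioned eigensystems.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    n = Q.shape[0]
    if tau == 0:
        return np.zeros((n, n))
    if decomp is None:
        decomp = SpectralDecomposition.from_matrix(Q)
    if decomp.reliable:
        lam = decomp.eigenvalues
        small = np.abs(lam) < 1e-10
        lam_safe = np.where(small, 1.0, lam)
        coef = np.where(small, tau, (np.exp(lam_safe * tau) - 1.0) / lam_safe)
        M = (decomp.U * coef) @ decomp.V
        return _assert_real(M)
    M, _ = quad_vec(lambda t: expm(Q * t), 0.0, tau, epsabs=1e-12, epsrel=1e-11)
    return M
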