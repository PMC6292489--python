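"""Hierarchical gdi-based species delimitation from posterior samples.

Bayesian MSC analyses (e.g. bpp's A00 run) produce MCMC samples of
divergence times (tau) and population sizes (theta).  Applying the
no-migration transform ``gdi = 1 - exp(-2 tau/theta)`` to every draw turns
the posterior of (tau, theta) into a posterior of gdi for a focal
population.  The conventional rule of thumb classifies a population pair as
a single species when gdi < 0.2, as distinct species when gdi > 0.7, and as
ambiguous in between.

The hierarchical procedure walks a guide tree: the gdi is computed for both
members of every cherry (each anchored on its own theta), sister pairs
classified single in both directions are collapsed, a new posterior is
obtained for the collapsed tree, and the process repeats until no cherry
collapses or the root is reached.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PosteriorSample",
    "GdiPosterior",
    "DelimitationDecision",
    "Topology",
    "parse_posterior_table",
    "gdi_posterior",
    "point_gdi",
    "classify",
    "hierarchical_collapse",
    "synthetic_posterior",
]


@dataclass
class PosteriorSample:
    """MCMC draws of MSC parameters, one column per parameter."""

    table: pd.DataFrame
    source: str = "unknown"

    def __post_init__(self):
        for col in self.table.columns:
            vals = self.table[col].to_numpy()
            if not np.issubdtype(vals.dtype, np.number):
                raise ValueError(f"non-numeric column {col!r}")
            if col.startswith("theta") and (vals <= 0).any():
                bad = int(np.flatnonzero(vals <= 0)[0]) + 2  # 1-based + header
                raise ValueError(f"non-positive theta in column {col!r}, line {bad}")
            if col.startswith("tau") and (vals < 0).any():
                bad = int(np.flatnonzero(vals < 0)[0]) + 2
                raise ValueError(f"negative tau in column {col!r}, line {bad}")

    @property
    def n_draws(self) -> int:
        return len(self.table)

    def column(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"no column {name!r} in posterior sample")
        return self.table[name].to_numpy(dtype=float)


def parse_posterior_table(
    path_or_buffer, column_map: dict[str, str] | None = None
) -> PosteriorSample:
    """Read a whitespace-delimited MCMC sample table (header row = names).

    bpp-style names (``tau_*``, ``theta_*``) are recognized as is; other
    layouts can be adapted with ``column_map`` (file name -> canonical name).
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        text = open(path_or_buffer).read()
    header = next((ln for ln in text.splitlines() if ln.strip()), "")
    names = header.split()
    if len(set(names)) != len(names):
        raise ValueError("duplicate column names in posterior table")
    df = pd.read_csv(_io.StringIO(text), sep=r"\s+")
    if column_map:
        missing = set(column_map) - set(df.columns)
        if missing:
            raise ValueError(f"column_map refers to missing columns: {sorted(missing)}")
        df = df.rename(columns=column_map)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"non-numeric cell in column {col!r}, line {line}")
    name = getattr(path_or_buffer, "name", str(path_or_buffer))
    return PosteriorSample(df, source=name)


@dataclass
class GdiPosterior:
    """Per-draw gdi values for a focal population, with summaries."""

    draws: np.ndarray
    theta_anchor: str

    def __post_init__(self):
        d = np.asarray(self.draws, dtype=float)
        if ((d < -1e-12) | (d > 1 + 1e-12)).any():
            raise ValueError("gdi draws must lie in [0, 1]")
        object.__setattr__(self, "draws", np.clip(d, 0.0, 1.0))

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.draws))

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.draws, q)

    def summary(self) -> dict[str, float]:
        lo, hi = self.quantile([0.025, 0.975])
        return {
            "mean": self.mean,
            "median": self.median,
            "q2.5%": float(lo),
            "q97.5%": float(hi),
        }


def _gdi_transform(tau: np.ndarray, theta: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(-2.0 * tau / theta)


def gdi_posterior(
    samples: PosteriorSample,
    tau_col: str,
    theta_col: str | None = None,
    theta_pair: tuple[str, str] | None = None,
) -> GdiPosterior:
    """Posterior of gdi = 1 - exp(-2 tau/theta) applied draw by draw.

    Anchor the index either on the focal population's theta (``theta_col``)
    or on the average of a pair of thetas (``theta_pair``).
    """
    if (theta_col is None) == (theta_pair is None):
        raise ValueError("give exactly one of theta_col or theta_pair")
    tau = samples.column(tau_col)
    if theta_col is not None:
        theta = samples.column(theta_col)
        anchor = theta_col
    else:
        theta = 0.5 * (samples.column(theta_pair[0]) + samples.column(theta_pair[1]))
        anchor = f"mean({theta_pair[0]},{theta_pair[1]})"
    return GdiPosterior(_gdi_transform(tau, theta), anchor)


def point_gdi(
    samples: PosteriorSample,
    tau_col: str,
    theta_col: str | None = None,
    theta_pair: tuple[str, str] | None = None,
) -> float:
    """gdi evaluated at the posterior means of the parameters.

    Not identical to the mean of the gdi posterior (Jensen gap); this is the
    point-estimate variant used when only parameter summaries are available.
    """
    if (theta_col is None) == (theta_pair is None):
        raise ValueError("give exactly one of theta_col or theta_pair")
    tau = samples.column(tau_col).mean()
    if theta_col is not None:
        theta = samples.column(theta_col).mean()
    else:
        theta = 0.5 * (
            samples.column(theta_pair[0]).mean() + samples.column(theta_pair[1]).mean()
        )
    return float(_gdi_transform(np.array(tau), np.array(theta)))


@dataclass(frozen=True)
class DelimitationDecision:
    verdict: str  # single | ambiguous | distinct
    statistic: float
    lower: float
    upper: float


def classify(
    gdi_stat: float, lower: float = 0.2, upper: float = 0.7
) -> DelimitationDecision:
    """Three-way decision: < lower -> single; > upper -> distinct; else ambiguous."""
    if lower >= upper:
        raise ValueError("lower threshold must be < upper")
    if not 0 <= gdi_stat <= 1:
        raise ValueError("gdi statistic must lie in [0, 1]")
    if gdi_stat < lower:
        verdict = "single"
    elif gdi_stat > upper:
        verdict = "distinct"
    else:
        verdict = "ambiguous"
    return DelimitationDecision(verdict, gdi_stat, lower, upper)


# --- guide-tree topology and hierarchical collapse --------------------------


class Topology:
    """Rooted guide-tree topology, collapsible cherry by cherry."""

    def __init__(self, structure):
        # structure: tip name (str) or tuple of two substructures
        self.structure = structure

    @classmethod
    def from_newick(cls, text: str) -> "Topology":
        text = text.strip().rstrip(";")

        def parse(s: str):
            s = s.strip()
            if not s.startswith("("):
                name = re.split(r"[:\[]", s, 1)[0].strip()
                if not name:
                    raise ValueError("empty tip name in newick")
                return name
            depth = 0
            parts, last = [], 1
            end = s.rindex(")")
            for i, ch in enumerate(s[1:end], start=1):
                if ch == "(":
                    depth += 1
                elif ch == ")":
                    depth -= 1
                elif ch == "," and depth == 0:
                    parts.append(s[last:i])
                    last = i + 1
            parts.append(s[last:end])
            if len(parts) != 2:
                raise ValueError("guide tree must be binary")
            return tuple(parse(p) for p in parts)

        return cls(parse(text))

    @property
    def tips(self) -> list[str]:
        out = []

        def rec(s):
            if isinstance(s, str):
                out.append(s)
            else:
                for c in s:
                    rec(c)

        rec(self.structure)
        return out

    def cherries(self) -> list[tuple[str, str]]:
        out = []

        def rec(s):
            if isinstance(s, str):
                return
            a, b = s
            if isinstance(a, str) and isinstance(b, str):
                out.append((a, b))
            else:
                rec(a)
                rec(b)

        rec(self.structure)
        return out

    def collapse(self, pair: tuple[str, str]) -> "Topology":
        merged = "+".join(pair)

        def rec(s):
            if isinstance(s, str):
                return s
            if s == pair or s == (pair[1], pair[0]):
                return merged
            return tuple(rec(c) for c in s)

        return Topology(rec(self.structure))

    def newick(self) -> str:
        def rec(s):
            return s if isinstance(s, str) else "(" + ",".join(map(rec, s)) + ")"

        return rec(self.structure) + ";"

    def __eq__(self, other):
        return isinstance(other, Topology) and self.structure == other.structure


@dataclass
class CherryDecision:
    pair: tuple[str, str]
    gdi: dict[str, float]  # per-direction decision statistic
    decisions: dict[str, DelimitationDecision]
    collapsed: bool


@dataclass
class DelimitationTrace:
    iterations: list[list[CherryDecision]] = field(default_factory=list)
    final_tree: Topology | None = None

    @property
    def final_species(self) -> list[str]:
        return self.final_tree.tips


def hierarchical_collapse(
    guide_tree: Topology,
    posterior_provider: Callable[[Topology], PosteriorSample],
    lower: float = 0.2,
    upper: float = 0.7,
    statistic: str = "mean",
) -> DelimitationTrace:
    """Iteratively collapse guide-tree cherries whose gdi says "single".

    At each iteration the provider supplies a posterior sample for the
    current tree (columns ``tau_{A}_{B}`` or ``tau_{AB-node}`` resolved as
    ``tau_<A>+<B>`` sorted; see below) and the gdi posterior is computed for
    both members of every cherry, each anchored on its own theta
    (``theta_<name>``).  A cherry collapses only when both directions
    classify as single; collapsing is strictly nested in the guide tree.
    Iteration stops when nothing collapses or only two tips remain
    uncollapsed at the root.

    Provider column conventions: for a cherry (A, B) the divergence-time
    column is ``tau_A_B`` and the theta columns ``theta_A`` and ``theta_B``.
    """
    tree = guide_tree
    trace = DelimitationTrace()
    max_iter = max(len(tree.tips) - 1, 1)
    for _ in range(max_iter):
        samples = posterior_provider(tree)
        decisions: list[CherryDecision] = []
        for a, b in tree.cherries():
            tau_col = f"tau_{a}_{b}"
            if tau_col not in samples.table.columns:
                tau_col = f"tau_{b}_{a}"
            stats: dict[str, float] = {}
            decs: dict[str, DelimitationDecision] = {}
            for focal in (a, b):
                post = gdi_posterior(samples, tau_col, theta_col=f"theta_{focal}")
                stat = post.mean if statistic == "mean" else post.median
                stats[focal] = stat
                decs[focal] = classify(stat, lower, upper)
            collapse = all(d.verdict == "single" for d in decs.values())
            decisions.append(CherryDecision((a, b), stats, decs, collapse))
        trace.iterations.append(decisions)
        to_collapse = [d.pair for d in decisions if d.collapsed]
        if not to_collapse:
            break
        for pair in to_collapse:
            tree = tree.collapse(pair)
        if isinstance(tree.structure, str):
            break
    trace.final_tree = tree
    return trace


# --- synthetic posterior generator ------------------------------------------

_DISTS = {
    "point": lambda rng, n, v: np.full(n, float(v)),
    "lognormal": lambda rng, n, m, s: rng.lognormal(m, s, n),
    "gamma": lambda rng, n, shape, scale: rng.gamma(shape, scale, n),
    "uniform": lambda rng, n, lo, hi: rng.uniform(lo, hi, n),
}


def synthetic_posterior(
    spec: dict[str, tuple],
    n_draws: int,
    rng: np.random.Generator,
    order_constraints: Sequence[tuple[str, str]] = (),
    max_rejections: int = 1000,
) -> PosteriorSample:
    """Seeded synthetic MCMC-style sample honoring per-draw ordering.

    ``spec`` maps column names to distribution tuples such as
    ``("lognormal", mu, sigma)``, ``("gamma", shape, scale)``,
    ``("uniform", lo, hi)`` or ``("point", value)``.  Order constraints
    ``(ancestor, descendant)`` require ancestor >= descendant per draw and
    are enforced by rejection.
    """

    def draw(n: int) -> pd.DataFrame:
        cols = {}
        for name, d in spec.items():
            kind, *args = d
            if kind not in _DISTS:
                raise ValueError(f"unknown distribution {kind!r}")
            cols[name] = _DISTS[kind](rng, n, *args)
        return pd.DataFrame(cols)

    df = draw(n_draws)
    for _ in range(max_rejections):
        bad = np.zeros(len(df), dtype=bool)
        for anc, desc in order_constraints:
            bad |= df[anc].to_numpy() < df[desc].to_numpy()
        if not bad.any():
            return PosteriorSample(df, source="synthetic")
        replacement = draw(int(bad.sum()))
        df.loc[bad, :] = replacement.to_numpy()
    raise RuntimeError("order constraints unsatisfiable within rejection budget")
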