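"""Structured-coalescent simulation on a dated species tree with migration.

Gene genealogies are simulated backwards in time, epoch by epoch between
species-tree nodes.  Within an epoch the lineage configuration evolves by
competing exponentials: every co-resident pair in population ``d`` coalesces
at rate ``2/theta_d`` and every lineage currently in population ``d`` is
traced (backwards) into population ``s`` at rate ``4*M_sd/theta_d`` for each
migration band with destination ``d`` — the backward-time counterpart of
forward migration at rate ``M_sd`` immigrants per generation into ``d``.
At a species-tree node the daughter populations merge into the ancestor.

Sequence alignments are evolved site-i.i.d. down the simulated genealogy
under JC or HKY, with branch lengths in expected substitutions per site.

A vectorized jump-chain simulator for the (2 + 1)-sample two-population case
(`simulate_topology_counts`) provides the Monte-Carlo counterpart of the
analytic gene-tree probability at the scale of 1e5-1e6 loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import ctmc
from .ctmc import IMParams

__all__ = [
    "SpeciesNode",
    "SpeciesTree",
    "MigrationBand",
    "GeneNode",
    "GeneTree",
    "SubstModel",
    "simulate_gene_tree",
    "simulate_alignment",
    "simulate_dataset",
    "simulate_topology_counts",
    "two_population_tree",
]


# --- species tree -----------------------------------------------------------


@dataclass
class SpeciesNode:
    name: str
    age: float
    theta: float
    children: list["SpeciesNode"] = field(default_factory=list)
    parent: "SpeciesNode | None" = None

    @property
    def is_tip(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted, dated, binary population phylogeny with per-branch theta.

    A branch is identified by the name of the node at its tipward end and
    spans the interval [node.age, parent.age) (the root branch is unbounded).
    Tip ages are 0 and ages strictly increase rootward; every theta > 0.
    """

    def __init__(self, root: SpeciesNode):
        self.root = root
        self.nodes: dict[str, SpeciesNode] = {}
        for node in self.preorder():
            if node.name in self.nodes:
                raise ValueError(f"duplicate node name {node.name!r}")
            self.nodes[node.name] = node
        self.validate()

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    @property
    def tips(self) -> list[SpeciesNode]:
        return [n for n in self.preorder() if n.is_tip]

    def validate(self) -> None:
        for node in self.preorder():
            if node.theta <= 0:
                raise ValueError(f"theta must be > 0 on branch {node.name!r}")
            if node.age < 0:
                raise ValueError("node ages must be >= 0")
            for ch in node.children:
                ch.parent = node
                if ch.age >= node.age:
                    raise ValueError(
                        f"child {ch.name!r} age {ch.age} not below parent age {node.age}"
                    )

    def epochs(self) -> list[float]:
        """Sorted distinct internal-node ages (epoch boundaries)."""
        return sorted({n.age for n in self.preorder() if not n.is_tip})

    def branches_alive(self, t: float) -> list[SpeciesNode]:
        """Branches whose interval contains time t (half-open at the top)."""
        out = []
        for node in self.preorder():
            top = node.parent.age if node.parent is not None else np.inf
            if node.age <= t < top:
                out.append(node)
        return out


def two_population_tree(params: IMParams) -> SpeciesTree:
    """The (A,B) species tree implied by an :class:`IMParams`."""
    theta_ab = params.require_ancestral()
    root = SpeciesNode("AB", params.tau, theta_ab)
    root.children = [
        SpeciesNode("A", 0.0, params.theta_A),
        SpeciesNode("B", 0.0, params.theta_B),
    ]
    return SpeciesTree(root)


@dataclass(frozen=True)
class MigrationBand:
    """Forward migration at rate M immigrants/generation from ``source``
    into ``dest``; active only while both branches coexist."""

    source: str
    dest: str
    M: float

    def __post_init__(self):
        if self.M < 0:
            raise ValueError("M must be >= 0")


def im_bands(params: IMParams) -> list[MigrationBand]:
    bands = []
    if params.M_AB > 0:
        bands.append(MigrationBand("A", "B", params.M_AB))
    if params.M_BA > 0:
        bands.append(MigrationBand("B", "A", params.M_BA))
    return bands


# --- gene tree --------------------------------------------------------------


@dataclass
class GeneNode:
    name: str
    time: float
    children: list["GeneNode"] = field(default_factory=list)
    species: str | None = None  # sampling species for tips
    migrations: list[tuple[float, str, str]] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


class GeneTree:
    def __init__(self, root: GeneNode):
        self.root = root

    def preorder(self):
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    @property
    def tips(self) -> list[GeneNode]:
        return [n for n in self.preorder() if n.is_tip]

    def newick(self, precision: int = 17) -> str:
        def rec(n: GeneNode) -> str:
            if n.is_tip:
                lab = n.name
            else:
                lab = "(" + ",".join(rec(c) for c in n.children) + ")"
            if n is self.root:
                return lab
            bl = n.parent_time - n.time
            return f"{lab}:{bl:.{precision}g}"

        # annotate parent times for branch lengths
        for n in self.preorder():
            for c in n.children:
                c.parent_time = n.time
        return rec(self.root) + ";"

    def mrca(self, names: list[str]) -> GeneNode:
        want = set(names)
        best = None

        def clade(n: GeneNode) -> set[str]:
            nonlocal best
            s = (
                {n.name}
                if n.is_tip
                else set().union(*(clade(c) for c in n.children))
            )
            if want <= s and best is None:
                best = n
            return s

        clade(self.root)
        if best is None:
            raise ValueError("tips not found")
        return best

    def is_clade(self, names: list[str]) -> bool:
        node = self.mrca(names)
        return sum(1 for t in self._subtips(node)) == len(names)

    @staticmethod
    def _subtips(node: GeneNode):
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                yield n
            stack.extend(n.children)


# --- coalescent-with-migration simulation -----------------------------------


def simulate_gene_tree(
    tree: SpeciesTree,
    migration: list[MigrationBand],
    sample: dict[str, int],
    rng: np.random.Generator,
) -> GeneTree:
    """Simulate one genealogy under the structured coalescent with migration.

    ``sample`` maps species (tip) names to sequence counts; sequence names
    are ``{species}{i}`` for i = 1..count.  Migration bands are clipped to
    the interval over which both named branches exist; bands naming ancestral
    branches must be given explicitly.
    """
    tip_names = {t.name for t in tree.tips}
    for sp in sample:
        if sp not in tip_names:
            raise ValueError(f"sample references unknown species {sp!r}")
    for band in migration:
        if band.source not in tree.nodes or band.dest not in tree.nodes:
            raise ValueError(f"migration band references unknown branch: {band}")

    lineages: list[GeneNode] = []
    deme: dict[int, str] = {}  # id(node) -> current branch name
    for sp, cnt in sample.items():
        for i in range(1, cnt + 1):
            node = GeneNode(f"{sp}{i}", 0.0, species=sp)
            lineages.append(node)
            deme[id(node)] = sp

    t = 0.0
    boundaries = tree.epochs() + [np.inf]
    next_label = itertools.count(1)
    for t_end in boundaries:
        while len(lineages) > 1:
            alive = {n.name: n for n in tree.branches_alive(t)}
            groups: dict[str, list[GeneNode]] = {d: [] for d in alive}
            for lin in lineages:
                groups[deme[id(lin)]].append(lin)
            # competing exponentials
            events: list[tuple[float, str, object]] = []
            for d, lins in groups.items():
                k = len(lins)
                if k >= 2:
                    events.append((k * (k - 1) / 2 * 2.0 / alive[d].theta, "coal", d))
            for band in migration:
                if band.dest in alive and band.source in alive and band.M > 0:
                    k = len(groups[band.dest])
                    if k:
                        rate = k * 4.0 * band.M / alive[band.dest].theta
                        events.append((rate, "mig", band))
            total = sum(r for r, *_ in events)
            if total == 0:
                t = t_end
                break
            dt = rng.exponential(1.0 / total)
            if t + dt >= t_end:
                t = t_end
                break
            t += dt
            r = rng.random() * total
            for rate, kind, obj in events:
                if r < rate:
                    break
                r -= rate
            if kind == "coal":
                d = obj
                i1, i2 = rng.choice(len(groups[d]), size=2, replace=False)
                c1, c2 = groups[d][i1], groups[d][i2]
                parent = GeneNode(f"n{next(next_label)}", t, children=[c1, c2])
                lineages = [x for x in lineages if x is not c1 and x is not c2]
                lineages.append(parent)
                deme[id(parent)] = d
            else:
                band = obj
                lin = groups[band.dest][rng.integers(len(groups[band.dest]))]
                deme[id(lin)] = band.source
                lin.migrations.append((t, band.dest, band.source))
        if len(lineages) == 1:
            break
        if np.isfinite(t_end):
            # merge demes that end at this boundary into their ancestor
            for node in tree.preorder():
                if not node.is_tip and node.age == t_end:
                    kids = {c.name for c in node.children}
                    for lin in lineages:
                        if deme[id(lin)] in kids:
                            deme[id(lin)] = node.name
    if len(lineages) != 1:
        raise RuntimeError("simulation ended with more than one lineage")
    return GeneTree(lineages[0])


# --- substitution models ----------------------------------------------------

_BASES = "TCAG"


@dataclass(frozen=True)
class SubstModel:
    """JC or HKY substitution model, normalized to unit substitution rate.

    Base frequencies are in T, C, A, G order.  Transitions are T<->C and
    A<->G, scaled by kappa relative to transversions.
    """

    kind: str = "JC"
    kappa: float = 1.0
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.kind not in ("JC", "HKY"):
            raise ValueError("kind must be 'JC' or 'HKY'")
        f = np.asarray(self.freqs, dtype=float)
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must be >= 0 and sum to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.kind == "JC" and (self.kappa != 1.0 or tuple(self.freqs) != (0.25,) * 4):
            raise ValueError("JC requires kappa=1 and uniform frequencies")

    def rate_matrix(self) -> np.ndarray:
        f = np.asarray(self.freqs, dtype=float)
        Q = np.zeros((4, 4))
        transitions = {(0, 1), (1, 0), (2, 3), (3, 2)}
        for i in range(4):
            for j in range(4):
                if i != j:
                    Q[i, j] = f[j] * (self.kappa if (i, j) in transitions else 1.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -(f * np.diag(Q)).sum()
        return Q / mean_rate

    def transition_probs(self, t: float) -> np.ndarray:
        """P(t) via the eigensystem of the reversible generator."""
        if t < 0:
            raise ValueError("t must be >= 0")
        Q = self.rate_matrix()
        f = np.asarray(self.freqs, dtype=float)
        # symmetrize: S = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
        d = np.sqrt(f)
        S = (Q * d[:, None]) / d[None, :]
        lam, W = np.linalg.eigh((S + S.T) / 2.0)
        P = (W * np.exp(lam * t)) @ W.T
        P = P / d[:, None] * d[None, :]
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)


def simulate_alignment(
    genetree: GeneTree,
    n_sites: int,
    model: SubstModel,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Evolve i.i.d. sites down the genealogy; returns name -> base indices.

    Root states are drawn from the stationary frequencies; each branch
    applies the model's transition probabilities over its time span.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    f = np.asarray(model.freqs, dtype=float)
    states = {id(genetree.root): rng.choice(4, size=n_sites, p=f)}
    out: dict[str, np.ndarray] = {}
    stack = [genetree.root]
    while stack:
        node = stack.pop()
        s = states.pop(id(node))
        if node.is_tip:
            out[node.name] = s
            continue
        for child in node.children:
            dt = node.time - child.time
            P = model.transition_probs(dt)
            child_s = np.empty_like(s)
            for base in range(4):
                mask = s == base
                k = int(mask.sum())
                if k:
                    child_s[mask] = rng.choice(4, size=k, p=P[base])
            states[id(child)] = child_s
            stack.append(child)
    return out


def bases_to_str(arr: np.ndarray) -> str:
    return "".join(_BASES[i] for i in arr)


@dataclass
class MultiLocusDataset:
    """Per-locus alignments plus the genealogies that generated them."""

    alignments: list[dict[str, np.ndarray]]
    gene_trees: list[GeneTree]
    species_of: dict[str, str]  # sequence name -> species

    @property
    def n_loci(self) -> int:
        return len(self.alignments)


def simulate_dataset(
    tree: SpeciesTree,
    migration: list[MigrationBand],
    sample: dict[str, int],
    n_loci: int,
    n_sites: int,
    model: SubstModel,
    rng: np.random.Generator,
) -> MultiLocusDataset:
    """Independent loci: a gene tree and alignment per locus."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    alns, gts = [], []
    species_of: dict[str, str] = {}
    for _ in range(n_loci):
        gt = simulate_gene_tree(tree, migration, sample, rng)
        gts.append(gt)
        alns.append(simulate_alignment(gt, n_sites, model, rng))
        for tip in gt.tips:
            species_of[tip.name] = tip.species
    return MultiLocusDataset(alns, gts, species_of)


# --- fast (2,1) topology simulation via the 21-state jump chain -------------


def simulate_topology_counts(
    params: IMParams, n_loci: int, rng: np.random.Generator
) -> int:
    """Number of loci (out of ``n_loci``) with gene tree ((a1,a2),b).

    Simulates the embedded jump chain of the 21-state process, vectorized
    across loci, up to the first coalescence or the divergence time ``tau``;
    loci in which all three lineages survive to the ancestral population
    yield topology G1 with probability 1/3.  This is the Monte-Carlo
    counterpart of the analytic P1 (spectral/quadrature) computation.
    """
    ss = ctmc.enumerate_states()
    Q = ctmc.build_rate_matrix(params)
    n3 = 8
    exit_rate = -np.diag(Q)[:n3]
    jump = Q[:n3].copy()
    np.fill_diagonal(jump[:, :n3], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump = jump / jump.sum(axis=1, keepdims=True)
    cum = np.cumsum(jump, axis=1)
    # a pair state whose free lineage is b means (a1,a2) coalesced first
    g1_pair = np.zeros(ss.n_states, dtype=bool)
    for lbl in ("A_bA", "B_bB", "A_bB", "AB_b"):
        g1_pair[ss.index[lbl]] = True

    state = np.full(n_loci, ss.index["AAB"], dtype=np.int64)
    t = np.zeros(n_loci)
    active = np.ones(n_loci, dtype=bool)
    n_g1 = 0
    n_survived = 0
    while active.any():
        idx = np.flatnonzero(active)
        s = state[idx]
        rates = exit_rate[s]
        if (rates <= 0).any():  # M = 0 split states cannot move: survive
            stuck = idx[rates <= 0]
            n_survived += stuck.size
            active[stuck] = False
            idx = np.flatnonzero(active)
            if idx.size == 0:
                break
            s = state[idx]
            rates = exit_rate[s]
        t[idx] += rng.exponential(1.0 / rates)
        past = t[idx] >= params.tau
        n_survived += int(past.sum())
        active[idx[past]] = False
        idx = idx[~past]
        if idx.size == 0:
            continue
        u = rng.random(idx.size)
        nxt = (u[:, None] > cum[state[idx]]).sum(axis=1)
        coalesced = nxt >= n3
        n_g1 += int(g1_pair[nxt[coalesced]].sum())
        active[idx[coalesced]] = False
        state[idx[~coalesced]] = nxt[~coalesced]
    n_g1 += int(rng.binomial(n_survived, 1.0 / 3.0))
    return n_g1
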