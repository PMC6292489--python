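"""Protracted speciation model: birth-death population trees with conversion.

Populations (incipient species) arise by a branching process and are
promoted to recognized ("true") species by conversion events that fall as a
Poisson process of rate ``beta`` along the branches of the population tree.
In the simplified model implemented here the initiation rate ``lambda`` and
extinction rate ``mu`` do not depend on species status, so the population
tree can be simulated first (a conventional birth-death tree) and the
conversion process superimposed afterwards.

Given a tree with total branch length T, a configuration of k conversion
events has density ``beta^k * exp(-beta * T)``; the joint prior over
(tree, delimitation) factorizes into the birth-death tree density times this
conversion term.  A tip's species is set by the most recent conversion event
on its root-to-tip path (tips with none share the root's ancestral status),
so the delimitation is a deterministic coloring of the tree by the event
set — sequence data simulated on the same tree never depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PSMParams",
    "PSMNode",
    "PSMTree",
    "ConversionEvent",
    "simulate_psm_tree",
    "place_conversion_events",
    "tip_species_labels",
    "conversion_density",
    "prior_factorization_demo",
]

REJECTION_CAP = 100_000


@dataclass(frozen=True)
class PSMParams:
    """Rates per lineage per unit time: initiation, extinction, conversion."""

    lambda_init: float
    mu_ext: float = 0.0
    beta: float = 0.0

    def __post_init__(self):
        if self.lambda_init < 0 or self.mu_ext < 0 or self.beta < 0:
            raise ValueError("all rates must be >= 0")


@dataclass
class PSMNode:
    name: str
    age: float  # time before present; extant tips have age 0
    children: list["PSMNode"] = field(default_factory=list)
    parent: "PSMNode | None" = None

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class ConversionEvent:
    """A conversion on the branch above ``branch`` (named by its lower node),
    at the given age; the descendant portion becomes a new true species."""

    branch: str
    age: float


class PSMTree:
    """Dated population tree with conversion events and induced tip species."""

    def __init__(self, root: PSMNode, events: list[ConversionEvent] | None = None):
        self.root = root
        self.nodes: dict[str, PSMNode] = {}
        for n in self.preorder():
            self.nodes[n.name] = n
            for c in n.children:
                c.parent = n
        self.events = list(events or [])
        self._validate_events()

    def preorder(self):
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    @property
    def tips(self) -> list[PSMNode]:
        return [n for n in self.preorder() if n.is_tip]

    def branch_interval(self, name: str) -> tuple[float, float]:
        node = self.nodes[name]
        if node.parent is None:
            return (node.age, node.age)  # the root has no branch above it
        return (node.age, node.parent.age)

    def total_length(self) -> float:
        """Sum of all branch lengths (root stem excluded)."""
        return sum(
            n.parent.age - n.age for n in self.preorder() if n.parent is not None
        )

    def _validate_events(self) -> None:
        for ev in self.events:
            if ev.branch not in self.nodes:
                raise ValueError(f"event on unknown branch {ev.branch!r}")
            lo, hi = self.branch_interval(ev.branch)
            if not (lo <= ev.age <= hi):
                raise ValueError(
                    f"event age {ev.age} outside branch {ev.branch!r} interval"
                )

    @property
    def tip_species(self) -> dict[str, str]:
        return tip_species_labels(self)

    def newick(self) -> str:
        events_on: dict[str, int] = {}
        for ev in self.events:
            events_on[ev.branch] = events_on.get(ev.branch, 0) + 1

        def rec(n: PSMNode) -> str:
            lab = n.name if n.is_tip else "(" + ",".join(map(rec, n.children)) + ")" + n.name
            if n.parent is None:
                return lab
            note = f"[&conversions={events_on[n.name]}]" if n.name in events_on else ""
            return f"{lab}:{n.parent.age - n.age:.12g}{note}"

        return rec(self.root) + ";"


def tip_species_labels(tree: PSMTree) -> dict[str, str]:
    """Species label of each tip: the most recent conversion on its path.

    Each conversion event founds a new true species comprising the connected
    subtree below it, until overridden by a more recent event.  Tips with no
    event on their root-to-tip path keep the root's (ancestral) status,
    labelled ``"anc"``.
    """
    best_on_branch: dict[str, ConversionEvent] = {}
    for ev in tree.events:
        cur = best_on_branch.get(ev.branch)
        if cur is None or ev.age < cur.age:
            best_on_branch[ev.branch] = ev
    labels: dict[str, str] = {}
    names = {}

    def event_id(ev: ConversionEvent) -> str:
        if ev not in names:
            names[ev] = f"sp{len(names) + 1}"
        return names[ev]

    def walk(node: PSMNode, current: str) -> None:
        ev = best_on_branch.get(node.name)
        if ev is not None:
            current = event_id(ev)
        if node.is_tip:
            labels[node.name] = current
        for c in node.children:
            walk(c, current)

    walk(tree.root, "anc")
    return labels


# --- simulation -------------------------------------------------------------


def _simulate_bd_tree(
    params: PSMParams,
    rng: np.random.Generator,
    n_tips: int | None,
    max_time: float | None,
) -> PSMNode | None:
    """One forward Gillespie run; returns the pruned extant tree or None."""
    # records: [parent, t_birth, t_end, alive]
    recs: list[list] = [[-1, 0.0, None, True]]
    alive = [0]
    t = 0.0
    while True:
        k = len(alive)
        if k == 0:
            return None
        if n_tips is not None and k >= n_tips:
            # extend the final epoch to the next (discarded) event so that
            # pendant branches have positive length
            t += rng.exponential(1.0 / (k * (params.lambda_init + params.mu_ext)))
            break
        total = k * (params.lambda_init + params.mu_ext)
        if total == 0:
            if max_time is None:
                return None
            t = max_time
            break
        dt = rng.exponential(1.0 / total)
        if max_time is not None and t + dt >= max_time:
            t = max_time
            break
        t += dt
        i = alive[rng.integers(k)]
        if rng.random() < params.lambda_init / (params.lambda_init + params.mu_ext):
            recs[i][2] = t
            recs[i][3] = False
            for _ in range(2):
                recs.append([i, t, None, True])
                alive.append(len(recs) - 1)
            alive.remove(i)
        else:
            recs[i][2] = t
            recs[i][3] = False
            alive.remove(i)
    t_end = t
    for i in alive:
        recs[i][2] = t_end
    # keep lineages with extant descendants
    keep = [False] * len(recs)
    for i in alive:
        j = i
        while j != -1 and not keep[j]:
            keep[j] = True
            j = recs[j][0]
    children: dict[int, list[int]] = {i: [] for i in range(len(recs))}
    for i, r in enumerate(recs):
        if keep[i] and r[0] != -1:
            children[r[0]].append(i)

    counter = iter(range(1, len(recs) + 1))

    def build(i: int) -> PSMNode:
        # collapse chains of single-surviving-child lineages
        kids = [c for c in children[i] if keep[c]]
        while len(kids) == 1:
            i = kids[0]
            kids = [c for c in children[i] if keep[c]]
        if not kids:
            return PSMNode(f"t{next(counter)}", t_end - recs[i][2])
        node = PSMNode(f"n{next(counter)}", t_end - recs[i][2] if kids else 0.0)
        # internal node age = time of the birth event ending this lineage
        node.age = t_end - recs[i][2]
        node.children = [build(c) for c in kids]
        return node

    root = build(0)
    if root.is_tip:
        return None if n_tips is not None and n_tips > 1 else root
    return root


def place_conversion_events(
    tree: PSMTree, beta: float, rng: np.random.Generator
) -> list[ConversionEvent]:
    """Poisson(beta * branch length) conversion events, uniform on branches."""
    events = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        length = node.parent.age - node.age
        for _ in range(rng.poisson(beta * length)):
            events.append(
                ConversionEvent(node.name, node.age + rng.random() * length)
            )
    return events


def simulate_psm_tree(
    params: PSMParams,
    rng: np.random.Generator,
    n_tips: int | None = None,
    max_time: float | None = None,
) -> PSMTree:
    """Simulate a population tree and superimpose conversion events.

    The tree is conditioned on survival (and, with ``n_tips``, on reaching
    that many extant populations) by rejection, capped at 1e5 attempts.
    Conversion events are laid on the reconstructed (pruned) tree only:
    events on extinct lineages cannot affect tip labels.
    """
    if (n_tips is None) == (max_time is None):
        raise ValueError("give exactly one of n_tips or max_time")
    if n_tips is not None and n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    for _ in range(REJECTION_CAP):
        root = _simulate_bd_tree(params, rng, n_tips, max_time)
        if root is not None and not root.is_tip:
            tree = PSMTree(root)
            tree.events = place_conversion_events(tree, params.beta, rng)
            return tree
    raise RuntimeError(
        "no surviving tree in 1e5 attempts; parameters are extinction-dominated"
    )


# --- densities --------------------------------------------------------------


def conversion_density(tree: PSMTree, events: list[ConversionEvent], beta: float) -> float:
    """Density of a conversion-event configuration: beta^k exp(-beta*T)."""
    PSMTree(tree.root, events)  # validates event placement
    T = tree.total_length()
    k = len(events)
    if beta == 0.0:
        return 1.0 if k == 0 else 0.0
    return float(beta**k * np.exp(-beta * T))


def prior_factorization_demo(
    tree: PSMTree,
    events: list[ConversionEvent],
    birth_death_density,
    beta: float,
) -> tuple[float, float, float]:
    """Joint prior factors: f(tree) * f(events | tree, beta).

    ``birth_death_density`` supplies the population-tree density; the product
    is the joint prior of (tree, delimitation) — the delimitation prior is
    conditionally independent of everything the sequence data see.
    """
    f_tree = float(birth_death_density(tree))
    f_conv = conversion_density(tree, events, beta)
    return f_tree, f_conv, f_tree * f_conv
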