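"""File formats shared by the toolkit.

Conventions (single source of truth): tips have age 0, time increases into
the past, and all times/rates are in expected mutations per site.  Species
trees travel as a newick topology (internal nodes labelled) plus a node
table of ages and thetas; alignments as bpp-style sequential phylip with
``name^species`` labels and an Imap file mapping individuals to species.
Numbers are serialized with 17 significant digits so that write/read
round-trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy

from .simulate import MultiLocusDataset, SpeciesNode, SpeciesTree, bases_to_str

__all__ = [
    "read_species_tree",
    "write_species_tree",
    "read_node_table",
    "write_phylip_bpp",
    "read_phylip_bpp",
    "write_imap",
    "write_gene_trees",
    "write_manifest",
]

_FMT = "{:.17g}"


def read_node_table(text: str) -> tuple[dict[str, float], dict[str, float]]:
    """Parse a node sidecar TSV with columns ``node  age  theta``."""
    ages: dict[str, float] = {}
    thetas: dict[str, float] = {}
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    header = lines[0].split()
    if header[:3] != ["node", "age", "theta"]:
        raise ValueError("node table must have columns: node age theta")
    for ln in lines[1:]:
        name, age, theta = ln.split()[:3]
        ages[name] = float(age)
        thetas[name] = float(theta)
    return ages, thetas


def read_species_tree(
    newick_text: str,
    thetas: dict[str, float],
    ages: dict[str, float],
) -> SpeciesTree:
    """Build a validated :class:`SpeciesTree` from newick + node annotations.

    The newick supplies the topology (internal nodes may be labelled;
    unlabelled ones are named by their sorted tip names joined without a
    separator).  ``ages`` must cover every internal node (tips default to
    age 0) and ``thetas`` every node.
    """
    dtree = dendropy.Tree.get(data=newick_text, schema="newick")
    if len(dtree.seed_node.leaf_nodes()) < 2:
        raise ValueError("species tree needs at least two tips")

    def convert(dnode) -> SpeciesNode:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            name = dnode.label
        if not name:
            name = "".join(
                sorted(lf.taxon.label for lf in dnode.leaf_iter())
            )
        if dnode.is_leaf():
            age = ages.get(name, 0.0)
        else:
            if name not in ages:
                raise ValueError(f"missing age for internal node {name!r}")
            age = ages[name]
        if name not in thetas:
            raise ValueError(f"missing theta for node {name!r}")
        node = SpeciesNode(name, age, thetas[name])
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return SpeciesTree(convert(dtree.seed_node))


def write_species_tree(tree: SpeciesTree) -> tuple[str, str]:
    """Serialize to (newick with internal labels, node table TSV)."""

    def rec(node: SpeciesNode) -> str:
        if node.is_tip:
            return node.name
        return "(" + ",".join(rec(c) for c in node.children) + ")" + node.name

    newick = rec(tree.root) + ";"
    rows = ["node\tage\ttheta"]
    for node in sorted(tree.preorder(), key=lambda n: (n.age, n.name)):
        rows.append(
            f"{node.name}\t{_FMT.format(node.age)}\t{_FMT.format(node.theta)}"
        )
    return newick, "\n".join(rows) + "\n"


# --- sequential phylip (bpp dialect) ----------------------------------------


def write_phylip_bpp(dataset: MultiLocusDataset) -> str:
    """Concatenated sequential phylip, one block per locus.

    Labels are ``name^species`` per the bpp convention.  Raises on ragged
    sequences or duplicate labels within a locus.
    """
    blocks = []
    for aln in dataset.alignments:
        names = list(aln)
        if len(set(names)) != len(names):
            raise ValueError("duplicate sequence labels within a locus")
        lengths = {len(seq) for seq in aln.values()}
        if len(lengths) != 1:
            raise ValueError("ragged sequence lengths within a locus")
        (n_sites,) = lengths
        lines = [f"{len(names)} {n_sites}"]
        width = max(len(f"{n}^{dataset.species_of[n]}") for n in names) + 2
        for name in names:
            label = f"{name}^{dataset.species_of[name]}"
            lines.append(label.ljust(width) + bases_to_str(aln[name]))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def read_phylip_bpp(text: str) -> list[dict[str, str]]:
    """Parse concatenated sequential phylip back into per-locus dicts.

    Returns one ``{label: sequence}`` dict per locus with the full
    ``name^species`` labels preserved.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    loci: list[dict[str, str]] = []
    i = 0
    while i < len(lines):
        head = lines[i].split()
        if len(head) != 2:
            raise ValueError(f"malformed locus header: {lines[i]!r}")
        n_seq, n_sites = int(head[0]), int(head[1])
        if i + n_seq >= len(lines):
            raise ValueError(
                f"locus header promises {n_seq} sequences but the file ends early"
            )
        aln: dict[str, str] = {}
        for j in range(n_seq):
            parts = lines[i + 1 + j].split()
            if len(parts) != 2:
                raise ValueError(f"malformed sequence line: {lines[i + 1 + j]!r}")
            label, seq = parts
            if label in aln:
                raise ValueError(f"duplicate label {label!r}")
            if len(seq) != n_sites:
                raise ValueError(
                    f"sequence {label!r} has {len(seq)} sites, expected {n_sites}"
                )
            aln[label] = seq
        loci.append(aln)
        i += 1 + n_seq
    return loci


def write_imap(dataset: MultiLocusDataset) -> str:
    """Imap text: one ``individual species`` line per sampled sequence."""
    rows = [f"{name} {sp}" for name, sp in sorted(dataset.species_of.items())]
    return "\n".join(rows) + "\n"


def write_gene_trees(dataset: MultiLocusDataset) -> str:
    return "\n".join(gt.newick() for gt in dataset.gene_trees) + "\n"


def write_manifest(outdir: Path, config: dict, seed: int | None) -> Path:
    """Record the run configuration and seed alongside the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    payload = {"config": config, "seed": seed}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
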