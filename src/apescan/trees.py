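"""Species tree with foreground-branch labeling.

The scan runs on a fixed six-taxon primate topology

    (((((human, chimpanzee)Hominini, gorilla)Homininae,
        orangutan)Hominidae, gibbon), rhesus);

with gibbon and rhesus as outgroups.  Each branch-site test designates
exactly one branch as *foreground* — one of the four great-ape terminal
branches or one of the three great-ape stem branches (Hominini,
Homininae, Hominidae) — and all remaining branches as background.

Internally the tree is stored rooted at the basal trifurcation
(rhesus, gibbon, great-ape clade), which gives the 9 identifiable edges
of the unrooted 6-taxon tree under a reversible model.  Newick output
marks the foreground branch with codeml's ``#1`` convention.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

#: Canonical tip names in fixed order.
GREAT_APE_TAXA = ("human", "chimpanzee", "gorilla", "orangutan", "gibbon", "rhesus")

#: The seven foreground labelings tested per gene.
FOREGROUND_BRANCHES = (
    "human",
    "chimpanzee",
    "Hominini",
    "gorilla",
    "Homininae",
    "orangutan",
    "Hominidae",
)

_CLADE_NAMES = {
    frozenset({"human", "chimpanzee"}): "Hominini",
    frozenset({"human", "chimpanzee", "gorilla"}): "Homininae",
    frozenset({"human", "chimpanzee", "gorilla", "orangutan"}): "Hominidae",
}

#: Default branch lengths (expected codon substitutions per site).  Chosen
#: to give clearly resolvable divergence on synthetic data; see the
#: package methods note.
DEFAULT_BRANCH_LENGTHS = {
    "human": 0.25,
    "chimpanzee": 0.25,
    "Hominini": 0.10,
    "gorilla": 0.30,
    "Homininae": 0.10,
    "orangutan": 0.35,
    "Hominidae": 0.15,
    "gibbon": 0.45,
    "rhesus": 0.50,
}


@dataclass(frozen=True)
class LabeledTree:
    """Rooted tree in index form with one designated foreground branch set.

    Nodes ``0..n_tips-1`` are tips (order = ``taxa``); internal nodes
    follow in postorder; the last node is the root.  ``parent[i]`` is the
    parent index (-1 for the root) and ``lengths[i]`` the length of the
    edge above node ``i`` (0 for the root).  ``branch_names`` maps a
    human-readable branch name to the node index below that edge.
    """

    taxa: tuple[str, ...]
    parent: tuple[int, ...]
    lengths: tuple[float, ...]
    branch_names: dict[str, int] = field(compare=False)
    foreground: frozenset[str] = frozenset()

    def __post_init__(self):
        if any(l < 0 for l in self.lengths):
            raise ValueError("branch lengths must be >= 0")
        unknown = set(self.foreground) - set(self.branch_names)
        if unknown:
            raise ValueError(f"unknown foreground branch(es): {sorted(unknown)}")

    # -- basic structure ---------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def postorder_edges(self) -> list[int]:
        """Child-node indices in postorder (every edge exactly once)."""
        return [i for i in range(self.n_nodes - 1)]

    def children(self, node: int) -> list[int]:
        return [i for i, p in enumerate(self.parent) if p == node]

    def foreground_nodes(self) -> frozenset[int]:
        return frozenset(self.branch_names[name] for name in self.foreground)

    def clade_tips(self, node: int) -> frozenset[str]:
        stack, tips = [node], []
        while stack:
            n = stack.pop()
            if n < self.n_tips:
                tips.append(self.taxa[n])
            else:
                stack.extend(self.children(n))
        return frozenset(tips)

    # -- derived trees -----------------------------------------------------
    def with_foreground(self, *branches: str) -> "LabeledTree":
        return replace(self, foreground=frozenset(branches))

    def with_lengths(self, lengths_by_branch: dict[str, float]) -> "LabeledTree":
        lengths = list(self.lengths)
        for name, value in lengths_by_branch.items():
            lengths[self.branch_names[name]] = float(value)
        return replace(self, lengths=tuple(lengths))

    def with_length_vector(self, vector: np.ndarray) -> "LabeledTree":
        """Replace the 9 edge lengths (postorder over non-root nodes)."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.n_nodes - 1,):
            raise ValueError("length vector has wrong size")
        return replace(self, lengths=tuple(vector) + (0.0,))

    def length_vector(self) -> np.ndarray:
        return np.asarray(self.lengths[:-1], dtype=float)

    # -- newick ------------------------------------------------------------
    def to_newick(self) -> str:
        fg = self.foreground_nodes()

        def render(node: int) -> str:
            if node < self.n_tips:
                label = self.taxa[node]
            else:
                kids = ",".join(render(c) for c in sorted(self.children(node)))
                name = _CLADE_NAMES.get(self.clade_tips(node), "")
                label = f"({kids}){name}"
            mark = " #1" if node in fg else ""
            if node == self.root:
                return f"{label};"
            return f"{label}{mark}:{self.lengths[node]:.6f}"

        return render(self.root)

    @classmethod
    def from_newick(cls, newick: str) -> "LabeledTree":
        """Parse a newick string; ``#1`` after a label marks foreground."""
        marked = set(re.findall(r"([A-Za-z_][\w.]*)\s*#1", newick))
        clean = re.sub(r"\s*#1", "", newick)
        tree = dendropy.Tree.get(data=clean, schema="newick",
                                 suppress_internal_node_taxa=False)
        return cls._from_dendropy(tree, marked)

    @classmethod
    def _from_dendropy(cls, tree: dendropy.Tree, marked: set[str]) -> "LabeledTree":
        nodes = [nd for nd in tree.postorder_node_iter()]
        tips = [nd for nd in nodes if nd.is_leaf()]
        taxa = tuple(nd.taxon.label.replace(" ", "_") for nd in tips)
        order = tips + [nd for nd in nodes if not nd.is_leaf()]
        index = {id(nd): i for i, nd in enumerate(order)}
        parent = [
            index[id(nd.parent_node)] if nd.parent_node is not None else -1
            for nd in order
        ]
        lengths = [
            float(nd.edge.length) if nd.edge.length is not None else 0.0
            for nd in order
        ]
        lengths[-1] = 0.0
        out = cls(taxa=taxa, parent=tuple(parent), lengths=tuple(lengths),
                  branch_names={}, foreground=frozenset())
        names = _name_branches(out)
        fg = set()
        for nd in order:
            label = None
            if nd.is_leaf():
                label = nd.taxon.label.replace(" ", "_")
            elif nd.taxon is not None:
                label = nd.taxon.label.replace(" ", "_")
            elif nd.label:
                label = nd.label.replace(" ", "_")
            if label in marked:
                node_idx = index[id(nd)]
                for bname, bidx in names.items():
                    if bidx == node_idx:
                        fg.add(bname)
        return cls(taxa=taxa, parent=tuple(parent), lengths=tuple(lengths),
                   branch_names=names, foreground=frozenset(fg))


def _name_branches(tree: LabeledTree) -> dict[str, int]:
    names: dict[str, int] = {}
    for node in range(tree.n_nodes - 1):
        if node < tree.n_tips:
            names[tree.taxa[node]] = node
        else:
            clade = tree.clade_tips(node)
            name = _CLADE_NAMES.get(clade)
            if name is None:
                name = "clade_" + "+".join(sorted(clade))
            names[name] = node
    return names


def great_ape_tree(
    branch_lengths: dict[str, float] | None = None,
    foreground: str | None = None,
) -> LabeledTree:
    """The fixed six-primate species tree.

    Node layout: tips 0–5 in :data:`GREAT_APE_TAXA` order, then internal
    nodes Hominini (6), Homininae (7), Hominidae (8), root (9, basal
    trifurcation of the great-ape clade, gibbon and rhesus).
    """
    lengths = dict(DEFAULT_BRANCH_LENGTHS)
    if branch_lengths:
        unknown = set(branch_lengths) - set(lengths)
        if unknown:
            raise ValueError(f"unknown branches: {sorted(unknown)}")
        lengths.update(branch_lengths)
    parent = (
        6,  # human -> Hominini
        6,  # chimpanzee -> Hominini
        7,  # gorilla -> Homininae
        8,  # orangutan -> Hominidae
        9,  # gibbon -> root
        9,  # rhesus -> root
        7,  # Hominini -> Homininae
        8,  # Homininae -> Hominidae
        9,  # Hominidae -> root
        -1,
    )
    branch_names = {
        "human": 0, "chimpanzee": 1, "gorilla": 2, "orangutan": 3,
        "gibbon": 4, "rhesus": 5,
        "Hominini": 6, "Homininae": 7, "Hominidae": 8,
    }
    length_tuple = tuple(
        lengths[name]
        for name in ("human", "chimpanzee", "gorilla", "orangutan", "gibbon",
                     "rhesus", "Hominini", "Homininae", "Hominidae")
    ) + (0.0,)
    fg = frozenset({foreground}) if foreground else frozenset()
    return LabeledTree(
        taxa=GREAT_APE_TAXA,
        parent=parent,
        lengths=length_tuple,
        branch_names=branch_names,
        foreground=fg,
    )
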