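"""Gain/loss inference for TR structural elements on a phylogeny.

Presence/absence of structural elements (P1.1, P2.1, P6.1, P2a, P2a.1, ...)
across taxa is reconciled with a species tree under Dollo parsimony: each
element arises exactly once (on the edge above the most recent common
ancestor of the taxa that have it) and is lost independently on the minimal
set of edges explaining every absence.  Unordered Fitch parsimony is
provided as a cross-check lower bound on the number of events.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy


class EvolutionError(ValueError):
    pass


@dataclass
class ElementMatrix:
    """taxon x element boolean presence matrix."""

    taxa: list[str]
    elements: list[str]
    states: dict[tuple[str, str], bool]

    def __post_init__(self) -> None:
        for t in self.taxa:
            for e in self.elements:
                if (t, e) not in self.states:
                    raise EvolutionError(f"missing state for taxon {t!r}, element {e!r}")

    def presence(self, element: str) -> set[str]:
        return {t for t in self.taxa if self.states[(t, element)]}

    @classmethod
    def from_delimited(cls, text_or_path: str | Path, sep: str = "\t",
                       ) -> "ElementMatrix":
        """Parse a delimited matrix: header = element names, rows = taxa.

        States are 1/0, true/false, +/-, yes/no (case-insensitive).
        """
        p = Path(text_or_path)
        text = p.read_text() if p.exists() else str(text_or_path)
        truthy = {"1", "true", "+", "yes", "present"}
        falsy = {"0", "false", "-", "no", "absent"}
        lines = [ln for ln in io.StringIO(text) if ln.strip()]
        header = lines[0].rstrip("\n").split(sep)
        elements = header[1:]
        taxa, states = [], {}
        for ln in lines[1:]:
            fields = ln.rstrip("\n").split(sep)
            taxon = fields[0]
            taxa.append(taxon)
            if len(fields) != len(header):
                raise EvolutionError(f"row {taxon!r} has {len(fields) - 1} states, "
                                     f"expected {len(elements)}")
            for e, v in zip(elements, fields[1:]):
                v = v.strip().lower()
                if v in truthy:
                    states[(taxon, e)] = True
                elif v in falsy:
                    states[(taxon, e)] = False
                else:
                    raise EvolutionError(f"unrecognised state {v!r}")
        return cls(taxa=taxa, elements=elements, states=states)


@dataclass
class ElementEvents:
    element: str
    gain_edges: list[str]          # child-clade labels of gain edges
    loss_edges: list[str]

    @property
    def n_events(self) -> int:
        return len(self.gain_edges) + len(self.loss_edges)


@dataclass
class EventSet:
    per_element: dict[str, ElementEvents] = field(default_factory=dict)

    @property
    def total_events(self) -> int:
        return sum(e.n_events for e in self.per_element.values())


def _clade_label(node: dendropy.Node) -> str:
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    if len(leaves) == 1:
        return leaves[0]
    return "{" + ",".join(leaves) + "}"


def load_tree(source: str | Path, outgroup: str | None = None) -> dendropy.Tree:
    """Read a newick tree; root on the outgroup taxon if given."""
    p = Path(source)
    data = p.read_text() if p.exists() else str(source)
    tree = dendropy.Tree.get(data=data, schema="newick")
    tree.is_rooted = True
    if outgroup is not None:
        node = tree.find_node_with_taxon_label(outgroup)
        if node is None:
            raise EvolutionError(f"outgroup {outgroup!r} not found in tree")
        tree.to_outgroup_position(node, update_bipartitions=False,
                                  suppress_unifurcations=True)
    return tree


def _check_taxa(tree: dendropy.Tree, matrix: ElementMatrix) -> None:
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = [t for t in matrix.taxa if t not in leaves]
    if missing:
        raise EvolutionError(f"matrix taxa missing from tree: {missing}")


def _mrca(tree: dendropy.Tree, taxa: set[str]) -> dendropy.Node:
    """Most recent common ancestor of the named leaves (root-directed walk)."""
    target = set(taxa)
    for node in tree.postorder_node_iter():
        leaves = {lf.taxon.label for lf in node.leaf_iter()}
        if target <= leaves:
            return node
    return tree.seed_node


def dollo_events(tree: dendropy.Tree, matrix: ElementMatrix) -> EventSet:
    """Single-gain (Dollo) reconstruction of gains and losses per element.

    The gain is placed on the edge above the MRCA of the presence taxa;
    losses are the minimal edges below the MRCA whose entire leaf set lacks
    the element.
    """
    _check_taxa(tree, matrix)
    out = EventSet()
    for element in matrix.elements:
        present = matrix.presence(element)
        if not present:
            out.per_element[element] = ElementEvents(element, [], [])
            continue
        mrca = _mrca(tree, present)
        losses: list[str] = []

        def walk(node: dendropy.Node) -> None:
            leaves = {lf.taxon.label for lf in node.leaf_iter()}
            if leaves.isdisjoint(present):
                losses.append(_clade_label(node))   # maximal absent subtree
                return
            for child in node.child_nodes():
                walk(child)

        for child in mrca.child_nodes():
            walk(child)
        out.per_element[element] = ElementEvents(
            element, gain_edges=[_clade_label(mrca)], loss_edges=sorted(losses))
    return out


def fitch_events(tree: dendropy.Tree, matrix: ElementMatrix) -> dict[str, int]:
    """Unordered (Fitch) parsimony change count per element.

    A lower bound on the Dollo event count minus the gain; used as a
    consistency cross-check, not as the headline reconstruction.
    """
    _check_taxa(tree, matrix)
    counts: dict[str, int] = {}
    inf = float("inf")
    for element in matrix.elements:
        # unit-cost small parsimony (exact on polytomies, unlike the
        # intersection/union shortcut which is binary-tree only)
        cost: dict[dendropy.Node, tuple[float, float]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                state = matrix.states[(node.taxon.label, element)]
                cost[node] = (inf, 0.0) if state else (0.0, inf)
            else:
                c0 = c1 = 0.0
                for child in node.child_nodes():
                    k0, k1 = cost[child]
                    c0 += min(k0, k1 + 1)
                    c1 += min(k1, k0 + 1)
                cost[node] = (c0, c1)
        counts[element] = int(min(cost[tree.seed_node]))
    return counts


def event_table(events: EventSet) -> str:
    lines = ["\t".join(["element", "n_gains", "n_losses", "gain_clades",
                        "loss_clades"])]
    for element, ev in events.per_element.items():
        lines.append("\t".join([
            element, str(len(ev.gain_edges)), str(len(ev.loss_edges)),
            ";".join(ev.gain_edges) or "-", ";".join(ev.loss_edges) or "-"]))
    return "\n".join(lines) + "\n"
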