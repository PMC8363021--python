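"""Complement matrices and Dollo-parsimony gain/loss reconstruction.

Each ortholog group is assumed to have arisen once (a single gain, by gene
duplication) and to have been lost independently any number of times.
Under that model the gain maps to the edge above the most recent common
ancestor of all lineages carrying the group (the outgroup, placed as a
direct child of the root, supplies evidence that pushes ancient gains above
the ingroup ancestor), and the minimal loss set is one loss at the root of
every maximal carrier-free subtree below the gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

#: Canonical column order: subfamilies NR1 -> NR6, then 2DBD-NRs, then the
#: unassigned/divergent bins, mirroring the complement-table layout.
GROUP_ORDER = [
    "TR", "TRb", "E78", "HR96a", "HR96b", "HR96c", "HR96d", "NR1a", "NR1b",
    "HNF4", "RXR1", "RXR2", "TR4", "TLX", "PNR", "DSF", "fax1", "NHR236",
    "CoupTFI", "CoupTFII",
    "ERR",
    "NR4A",
    "FTZF1", "HR39",
    "GCNF",
    "2DBDa", "2DBDb", "2DBDg",
    "unassigned", "divergent",
]


def label_nodes(tree: dendropy.Tree) -> None:
    """Give every internal node a stable preorder label (N0, N1, ...)."""
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.label is None:
            node.label = f"N{counter}"
        counter += 1


def node_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


@dataclass(frozen=True)
class ComplementMatrix:
    """Species x ortholog-group count matrix (Table-style complement)."""

    counts: pd.DataFrame  # index: species, columns: groups, integer counts

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate species rows")

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts.drop(columns=["total"], errors="ignore") > 0

    @property
    def totals(self) -> pd.Series:
        if "total" in self.counts.columns:
            return self.counts["total"]
        return self.counts.sum(axis=1)


def build_matrix(rows: Mapping[str, Mapping[str, int]]) -> ComplementMatrix:
    """Assemble per-species complement rows into one matrix.

    Column order is deterministic: the canonical group order first, then
    any other labels sorted, then ``total``.
    """
    species = list(rows)
    if len(species) != len(set(species)):
        raise ValueError("duplicate species")
    labels: set[str] = set()
    for counts in rows.values():
        labels.update(counts)
    labels.discard("total")
    ordered = [g for g in GROUP_ORDER if g in labels]
    ordered += sorted(labels - set(ordered))
    data = {
        sp: [rows[sp].get(g, 0) for g in ordered] + [rows[sp].get("total", 0)]
        for sp in species
    }
    frame = pd.DataFrame.from_dict(
        data, orient="index", columns=ordered + ["total"]
    )
    return ComplementMatrix(counts=frame)


@dataclass(frozen=True)
class GainLossReconstruction:
    tree: dendropy.Tree
    gain_edge: dict[str, str]          # group -> child label of the gain edge
    loss_edges: dict[str, tuple[str, ...]]
    ancestral: dict[str, dict[str, bool]]  # group -> node label -> present
    skipped: tuple[str, ...] = ()

    def loss_count(self, group: str) -> int:
        return len(self.loss_edges[group])


def dollo_gain_loss(
    presence: pd.DataFrame,
    tree: dendropy.Tree,
) -> GainLossReconstruction:
    """Single-gain / minimal-loss reconstruction for every group.

    ``presence`` is a boolean species x group frame; every species must be
    a leaf of ``tree``.  Groups absent everywhere are skipped with a
    warning.  A node is reconstructed as carrying a group iff it lies at or
    below the gain node and still has at least one carrier among its
    descendant leaves; losses sit on the edges to maximal carrier-free
    subtrees.  Leaf states are reproduced exactly by construction.
    """
    label_nodes(tree)
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(presence.index) - leaf_labels
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)}")

    gain_edge: dict[str, str] = {}
    loss_edges: dict[str, tuple[str, ...]] = {}
    ancestral: dict[str, dict[str, bool]] = {}
    skipped: list[str] = []

    import warnings as _warnings

    for group in presence.columns:
        carriers = set(presence.index[presence[group]])
        if not carriers:
            _warnings.warn(f"group {group!r} absent everywhere; skipped")
            skipped.append(group)
            continue
        mrca = _mrca(tree, carriers)
        states: dict[str, bool] = {}
        losses: list[str] = []

        def has_carrier(node) -> bool:
            if node.is_leaf():
                return node.taxon.label in carriers
            return any(has_carrier(c) for c in node.child_nodes())

        def walk(node, inside: bool) -> None:
            lbl = node_label(node)
            if node is mrca:
                inside = True
            if not inside:
                states[lbl] = False
            else:
                carrier_below = (
                    node.taxon.label in carriers if node.is_leaf() else has_carrier(node)
                )
                states[lbl] = carrier_below
            for child in node.child_nodes():
                walk(child, inside)
                if inside and states[node_label(node)] and not states[node_label(child)]:
                    losses.append(node_label(child))

        walk(tree.seed_node, False)
        gain_edge[group] = node_label(mrca)
        # deterministic order: preorder appearance
        loss_edges[group] = tuple(losses)
        ancestral[group] = states
    return GainLossReconstruction(
        tree=tree,
        gain_edge=gain_edge,
        loss_edges=loss_edges,
        ancestral=ancestral,
        skipped=tuple(skipped),
    )


def _mrca(tree: dendropy.Tree, leaf_names: set[str]) -> dendropy.Node:
    paths = []
    for lf in tree.leaf_node_iter():
        if lf.taxon.label in leaf_names:
            path = []
            node = lf
            while node is not None:
                path.append(node)
                node = node.parent_node
            paths.append(list(reversed(path)))
    if not paths:
        raise ValueError("no carriers")
    mrca = None
    for nodes in zip(*paths):
        first = nodes[0]
        if all(n is first for n in nodes):
            mrca = first
        else:
            break
    return mrca


def ancestral_complement(
    recon: GainLossReconstruction, node: str
) -> set[str]:
    """Groups reconstructed as present at the named node."""
    known = {node_label(n) for n in recon.tree.preorder_node_iter()}
    if node not in known:
        raise ValueError(f"unknown node {node!r}")
    return {
        g for g, states in recon.ancestral.items() if states.get(node, False)
    }


@dataclass(frozen=True)
class PropagationResult:
    leaf_sets: dict[str, set[str]]
    node_sets: dict[str, set[str]]
    inconsistencies: tuple[str, ...]
    mismatches: tuple[str, ...] = ()


def propagate_events(
    root_set: Iterable[str],
    events: Sequence[Mapping[str, str]],
    tree: dendropy.Tree,
    observed: pd.DataFrame | None = None,
) -> PropagationResult:
    """Replay per-edge gain/loss events from the root down.

    ``events`` rows carry ``edge`` (the child-node label of the edge),
    ``event`` (``gain``/``loss``) and ``group``.  Losing a group that is
    not present on the path is recorded as an inconsistency, not an error.
    When an observed presence matrix is given, per-leaf mismatches against
    the propagated states are reported.
    """
    label_nodes(tree)
    by_edge: dict[str, list[tuple[str, str]]] = {}
    for ev in events:
        by_edge.setdefault(ev["edge"], []).append((ev["event"], ev["group"]))
    inconsistencies: list[str] = []
    leaf_sets: dict[str, set[str]] = {}
    node_sets: dict[str, set[str]] = {}

    def walk(node, state: set[str]) -> None:
        lbl = node_label(node)
        state = set(state)
        for event, group in by_edge.get(lbl, []):
            if event == "gain":
                state.add(group)
            elif event == "loss":
                if group not in state:
                    inconsistencies.append(
                        f"loss of {group} on edge {lbl}: group not present"
                    )
                state.discard(group)
            else:
                raise ValueError(f"unknown event {event!r}")
        node_sets[lbl] = state
        if node.is_leaf():
            leaf_sets[lbl] = state
        for child in node.child_nodes():
            walk(child, state)

    walk(tree.seed_node, set(root_set))
    mismatches: list[str] = []
    if observed is not None:
        pres = observed if observed.dtypes.eq(bool).all() else observed > 0
        for sp in pres.index:
            expected = {g for g in pres.columns if pres.loc[sp, g]}
            got = leaf_sets.get(sp, set())
            extra = got - expected
            lacking = expected - got
            for g in sorted(extra):
                mismatches.append(f"{sp}: propagated {g} not observed")
            for g in sorted(lacking):
                mismatches.append(f"{sp}: observed {g} not propagated")
    return PropagationResult(
        leaf_sets=leaf_sets,
        node_sets=node_sets,
        inconsistencies=tuple(inconsistencies),
        mismatches=tuple(mismatches),
    )
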