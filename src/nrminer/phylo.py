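"""Anchor-based DBD alignment, p-distances, neighbor joining and monophyly.

NR DBDs share eight chelating positions (four per zinc finger).  Instead of
a general-purpose aligner, DBDs are aligned by forcing those eight anchors
into shared columns and right-padding the variable segments between them —
deterministic, reversible per row, and sufficient for the p-distances the
classifier and the co-clustering checks need.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from nrminer.config import DEFAULT_CONFIG, RunConfig

GAP = "-"


@dataclass(frozen=True)
class AnchoredDBD:
    """A DBD string plus its eight chelator offsets (relative to the string)."""

    id: str
    sequence: str
    anchors: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.anchors) != 8:
            raise ValueError(f"{self.id}: need 8 anchor positions")
        if list(self.anchors) != sorted(self.anchors):
            raise ValueError(f"{self.id}: anchors must increase")
        if self.anchors[-1] >= len(self.sequence) or self.anchors[0] < 0:
            raise ValueError(f"{self.id}: anchor outside sequence")


@dataclass(frozen=True)
class AnchorAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]
    anchor_columns: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degap(self, index: int) -> str:
        return self.rows[index].replace(GAP, "")


def from_hit(hit, sequence: str) -> AnchoredDBD:
    """Build an :class:`AnchoredDBD` from a scanner DBD hit and its protein."""
    rel = tuple(p - hit.start for p in hit.chelator_positions)
    return AnchoredDBD(
        id=hit.record_id, sequence=sequence[hit.start : hit.end], anchors=rel
    )


def anchor_align(dbds: Sequence[AnchoredDBD]) -> AnchorAlignment:
    """Align DBDs on their eight chelator columns.

    The nine segments around the anchors (prefix, seven inter-anchor runs,
    suffix) are right-padded with gaps to their per-segment maxima; every
    anchor column is gap-free by construction and degapping a row returns
    its source string.
    """
    if not dbds:
        return AnchorAlignment(ids=(), rows=(), anchor_columns=())

    def segments(d: AnchoredDBD) -> list[str]:
        a = d.anchors
        segs = [d.sequence[: a[0]]]
        for i in range(7):
            segs.append(d.sequence[a[i] + 1 : a[i + 1]])
        segs.append(d.sequence[a[7] + 1 :])
        return segs

    seg_rows = [segments(d) for d in dbds]
    widths = [max(len(r[k]) for r in seg_rows) for k in range(9)]
    rows = []
    for d, segs in zip(dbds, seg_rows):
        parts = []
        for k in range(9):
            parts.append(segs[k].ljust(widths[k], GAP))
            if k < 8:
                parts.append(d.sequence[d.anchors[k]])
        rows.append("".join(parts))
    anchor_cols = []
    col = 0
    for k in range(8):
        col += widths[k]
        anchor_cols.append(col)
        col += 1
    return AnchorAlignment(
        ids=tuple(d.id for d in dbds),
        rows=tuple(rows),
        anchor_columns=tuple(anchor_cols),
    )


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.values[i, j])


def pairwise_p_distance(
    alignment: AnchorAlignment,
    config: RunConfig = DEFAULT_CONFIG,
) -> DistanceMatrix:
    """p-distance over columns where neither row has a gap.

    Pairs sharing fewer than ``config.min_comparable_columns`` comparable
    columns are assigned distance 1.0 with a warning.
    """
    n = len(alignment)
    rows = alignment.rows
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = 0
            mismatch = 0
            for a, b in zip(rows[i], rows[j]):
                if a == GAP or b == GAP:
                    continue
                comparable += 1
                if a != b:
                    mismatch += 1
            if comparable < config.min_comparable_columns:
                warnings.warn(
                    f"{alignment.ids[i]} vs {alignment.ids[j]}: only "
                    f"{comparable} comparable columns; distance set to 1.0"
                )
                d = 1.0
            else:
                d = mismatch / comparable
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids=alignment.ids, values=mat)


def p_distance(a: AnchoredDBD, b: AnchoredDBD, config: RunConfig = DEFAULT_CONFIG) -> float:
    aln = anchor_align([a, b])
    return float(pairwise_p_distance(aln, config).values[0, 1])


def write_alignment_fasta(alignment: AnchorAlignment, path) -> None:
    """Gapped FASTA export of an anchor alignment."""
    with open(path, "w") as fh:
        for rid, row in zip(alignment.ids, alignment.rows):
            fh.write(f">{rid}\n{row}\n")


def write_alignment_phylip(alignment: AnchorAlignment, path) -> None:
    """Relaxed PHYLIP export for external tree-inference tools."""
    with open(path, "w") as fh:
        fh.write(f" {len(alignment)} {alignment.n_columns}\n")
        for rid, row in zip(alignment.ids, alignment.rows):
            fh.write(f"{rid}  {row}\n")


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor joining with deterministic tie-breaking.

    Ties on the Q criterion go to the lexicographically smallest index
    pair (indices in node-creation order).  Negative branch lengths are
    clamped to zero with the deficit moved onto the sibling branch, so the
    cherry's length sum is preserved.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    taxa = dendropy.TaxonNamespace([str(x) for x in dist.ids])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[int, dendropy.Node] = {}
    for i, name in enumerate(dist.ids):
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(str(name))
        nodes[i] = node

    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(dist.values[i, j])

    def d(i: int, j: int) -> float:
        if i == j:
            return 0.0
        return D[(min(i, j), max(i, j))]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        nodes[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            D[(min(k, next_id), max(k, next_id))] = 0.5 * (
                d(i, k) + d(j, k) - d(i, j)
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    center = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[k])
        nodes[k].edge.length = max(lk, 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


# ---------------------------------------------------------------------------
# Monophyly


def check_monophyly(
    tree: dendropy.Tree,
    label_map: Mapping[str, str],
    label: str,
) -> tuple[bool, dendropy.Edge | None]:
    """Does some edge separate exactly the leaves carrying ``label``?

    The tree is treated as unrooted: an edge qualifies if the leaf set on
    either side equals the labelled set.  Returns the splitting edge when
    one exists.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    target = {name for name, lab in label_map.items() if lab == label}
    if not target:
        raise ValueError(f"label {label!r} absent from label map")
    missing = target - leaves
    if missing:
        raise ValueError(f"labelled leaves not in tree: {sorted(missing)}")
    if target == leaves:
        return True, tree.seed_node.edge
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == target or (leaves - below) == target:
            return True, node.edge
    return False, None
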