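"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a result through a mechanism deliberately different
from the production code: regex window scanning for the finger patterns,
exhaustive enumeration for pairing, Dollo assignments and monophyly, and a
from-scratch naive neighbor joining.
"""

from __future__ import annotations

import itertools
import re

import dendropy
import numpy as np

# --- zinc-finger scanning -------------------------------------------------

_ORACLE_PATTERNS = {
    "CI": re.compile(r"(?=(C[A-Z]{2}C[A-Z]{13}C[A-Z]{2}C))"),
    "CII_C4": re.compile(r"(?=(C[A-Z]{5}C[A-Z]{9}C[A-Z]{2}C))"),
    "CII_CHC2": re.compile(r"(?=(C[A-Z]{5}H[A-Z]{9}C[A-Z]{2}C))"),
}
_OFFSETS = {"CI": (0, 3, 17, 20), "CII_C4": (0, 6, 16, 19), "CII_CHC2": (0, 6, 16, 19)}
_LENGTHS = {"CI": 21, "CII_C4": 20, "CII_CHC2": 20}


def oracle_fingers(seq: str, allow_chc2: bool = True) -> set[tuple]:
    """Exhaustive regex-based finger scan: {(kind, start, end, chelators)}."""
    out = set()
    for kind, pat in _ORACLE_PATTERNS.items():
        if kind == "CII_CHC2" and not allow_chc2:
            continue
        for m in pat.finditer(seq):
            s = m.start()
            out.add(
                (kind, s, s + _LENGTHS[kind], tuple(s + o for o in _OFFSETS[kind]))
            )
    return out


# --- CI/CII pairing -------------------------------------------------------


def oracle_max_pairing(cis, ciis, gap_min: int, gap_max: int) -> int:
    """Maximum number of disjoint-span CI->CII pairs, by exhaustive search.

    Fingers are (start, end) tuples.  A pair uses a CI and a downstream CII
    with gap in bounds; the combined spans of chosen pairs must not
    overlap.
    """
    pairs = [
        (i, j)
        for i, ci in enumerate(cis)
        for j, cii in enumerate(ciis)
        if cii[0] >= ci[1] and gap_min <= cii[0] - ci[1] <= gap_max
    ]

    best = 0
    for r in range(len(pairs), 0, -1):
        if r <= best:
            break
        for combo in itertools.combinations(pairs, r):
            used_ci = {i for i, _ in combo}
            used_cii = {j for _, j in combo}
            if len(used_ci) < r or len(used_cii) < r:
                continue
            spans = sorted(
                (cis[i][0], ciis[j][1]) for i, j in combo
            )
            if all(spans[k][1] <= spans[k + 1][0] for k in range(len(spans) - 1)):
                best = max(best, r)
                break
    return best


# --- neighbor joining -----------------------------------------------------


def oracle_nj(ids, matrix: np.ndarray):
    """Naive O(n^3) neighbor joining, written independently.

    Returns {frozenset(leaf_side): branch_length} over all edges, with the
    same tie-breaking (lowest creation-order index pair) and negative
    branch clamping (deficit moved to the sibling) as the production code
    is specified to use.
    """
    n = len(ids)
    D = matrix.astype(float).copy()
    clusters: list[set[str]] = [{x} for x in ids]
    order = list(range(n))  # creation order identifiers
    edges: dict[frozenset, float] = {}
    next_order = n
    live = list(range(len(clusters)))

    def join(i_pos, j_pos, li, lj):
        nonlocal next_order
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        edges[frozenset(clusters[i_pos])] = max(li, 0.0)
        edges[frozenset(clusters[j_pos])] = max(lj, 0.0)

    while len(live) > 3:
        m = len(live)
        r = {p: sum(D[p, q] for q in live if q != p) for p in live}
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                p, q = live[a], live[b]
                i_ord, j_ord = order[p], order[q]
                lo, hi = min(i_ord, j_ord), max(i_ord, j_ord)
                key = ((m - 2) * D[p, q] - r[p] - r[q], lo, hi)
                if best is None or key < best[0:3]:
                    best = key + (p, q)
        _, _, _, p, q = best
        if order[p] > order[q]:
            p, q = q, p
        li = 0.5 * D[p, q] + (r[p] - r[q]) / (2 * (m - 2))
        lj = D[p, q] - li
        join(p, q, li, lj)
        new_cluster = clusters[p] | clusters[q]
        newD = np.zeros((D.shape[0] + 1, D.shape[1] + 1))
        newD[: D.shape[0], : D.shape[1]] = D
        for k in live:
            if k in (p, q):
                continue
            newD[k, -1] = newD[-1, k] = 0.5 * (D[p, k] + D[q, k] - D[p, q])
        D = newD
        clusters.append(new_cluster)
        order.append(next_order)
        next_order += 1
        live = [k for k in live if k not in (p, q)] + [len(clusters) - 1]

    a, b, c = live
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for pos, l in ((a, la), (b, lb), (c, lc)):
        edges[frozenset(clusters[pos])] = max(l, 0.0)
    return edges


def tree_edges(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Edge set of an unrooted dendropy tree as leaf-side splits."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = min(below, leaves - below, key=lambda s: (len(s), sorted(s)))
        length = node.edge.length or 0.0
        out[side] = out.get(side, 0.0) + length
    return out


# --- monophyly ------------------------------------------------------------


def oracle_monophyly(tree: dendropy.Tree, target: set[str]) -> bool:
    """Edge enumeration through dendropy's bipartition encoding."""
    tns = tree.taxon_namespace
    target_bitmask = tns.taxa_bitmask(labels=target)
    full = tns.all_taxa_bitmask()
    for bp in tree.encode_bipartitions():
        mask = bp.leafset_bitmask
        if mask == target_bitmask or (full & ~mask) == target_bitmask:
            return True
    return target_bitmask == full


# --- Dollo gain/loss ------------------------------------------------------


def oracle_min_losses(tree: dendropy.Tree, carriers: set[str]) -> int:
    """Minimal loss count over all (gain edge, loss edge set) assignments
    that reproduce the leaf states, by exhaustive enumeration."""
    nodes = list(tree.preorder_node_iter())
    non_root = [n for n in nodes if n.parent_node is not None]
    leaves = [n for n in nodes if n.is_leaf()]
    best = None
    gain_candidates = nodes  # gain on the edge above any node (incl. root)
    for gain_node in gain_candidates:
        gain_subtree = set(gain_node.preorder_iter())
        loss_pool = [n for n in non_root if n in gain_subtree and n is not gain_node]
        for r in range(len(loss_pool) + 1):
            if best is not None and r >= best:
                break
            for combo in itertools.combinations(loss_pool, r):
                lost_below = set()
                for l in combo:
                    lost_below |= set(l.preorder_iter())
                ok = True
                for lf in leaves:
                    present = lf in gain_subtree and lf not in lost_below
                    if present != (lf.taxon.label in carriers):
                        ok = False
                        break
                if ok:
                    best = r if best is None else min(best, r)
                    break
    return best
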