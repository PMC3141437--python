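"""Parsimony ancestral reconstruction on rooted phylogenies.

Three flavours are implemented:

* **Fitch / unit-cost parsimony** for discrete characters
  (:func:`fitch_states`): minimum number of state changes, with exact
  most-parsimonious-reconstruction (MPR) state sets at every node from an
  up-down dynamic program.
* **Sankoff parsimony with linear cost** ``|i - j|`` for copy numbers
  (:func:`sankoff_linear`).
* **Squared-change parsimony** for continuous characters
  (:func:`squared_change`), minimising the sum of (optionally
  branch-length-weighted) squared changes along edges; the optimum is the
  unique solution of a linear system.

:func:`root_content_interval` applies presence/absence parsimony across all
ortholog groups of a matrix to bound the gene content of the root ancestor:
groups whose root MPR set is {present} count toward the minimum, groups with
an ambiguous root set {absent, present} toward the maximum only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datamodel import OrthologMatrix, ValidationError
from .trees import Phylogeny

_INF = float("inf")


@dataclass
class AncestralReconstruction:
    """Node states (sets, discrete) or values (reals, continuous) plus cost."""

    node_states: dict  # node label -> frozenset (discrete) or float (continuous)
    total_cost: float
    equivocal_branches: dict = field(default_factory=dict)  # child label -> bool
    kind: str = "discrete"


@dataclass
class RootContentInterval:
    """Bounds on the root ancestor's gene (or gene-copy) content."""

    min_genes: int
    max_genes: int
    sure_groups: list
    ambiguous_groups: list
    unique_counts: Optional[dict] = None  # cyano-unique tallies per list

    def __post_init__(self):
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes > max_genes")
        if set(self.sure_groups) & set(self.ambiguous_groups):
            raise ValueError("sure and ambiguous group lists overlap")


# ---------------------------------------------------------------------------
# discrete parsimony
# ---------------------------------------------------------------------------

def _unit_cost_dp(idx, tip_states: dict, alphabet: list):
    """Down/up dynamic program under unit change cost.

    Returns (down, up, total) where down[v, s] is the minimal cost of the
    subtree rooted at v given state s at v, and up[v, s] the minimal cost of
    the rest of the tree. Works on polytomies.
    """
    k = len(alphabet)
    aindex = {a: i for i, a in enumerate(alphabet)}
    down = np.zeros((idx.n_nodes, k))
    for v in range(idx.n_nodes):
        if idx.is_tip[v]:
            label = idx.labels[v]
            if label not in tip_states:
                raise ValidationError(f"tip {label!r} has no state")
            down[v, :] = _INF
            down[v, aindex[tip_states[label]]] = 0.0
        else:
            for c in idx.children[v]:
                # cost of child given parent state s: min over child state
                best = down[c].min()
                contrib = np.minimum(down[c], best + 1.0)
                down[v] += contrib
    up = np.zeros((idx.n_nodes, k))
    for v in reversed(range(idx.n_nodes)):  # preorder
        if idx.is_tip[v]:
            continue
        sibsum = np.empty((len(idx.children[v]), k))
        for ci, c in enumerate(idx.children[v]):
            best = down[c].min()
            sibsum[ci] = np.minimum(down[c], best + 1.0)
        total_children = sibsum.sum(axis=0)
        for ci, c in enumerate(idx.children[v]):
            other = up[v] + total_children - sibsum[ci]
            best = other.min()
            up[c] = np.minimum(other, best + 1.0)
    total = (down[idx.root] + up[idx.root]).min()
    return down, up, total


def fitch_states(tree: Phylogeny, tip_states: dict) -> AncestralReconstruction:
    """Minimum-change reconstruction of a discrete character.

    ``tip_states`` maps every tip label to a hashable state. The bottom-up
    Fitch pass (iterated pairwise intersection-else-union on polytomies)
    yields the change count on binary trees; node state sets are the exact
    MPR sets from the unit-cost dynamic program, so they are correct on
    polytomies as well. A branch is flagged equivocal when either of its
    endpoints has an ambiguous (multi-state) MPR set.
    """
    idx = tree.index()
    for label in idx.tip_index:
        if label not in tip_states:
            raise ValidationError(f"tip {label!r} has no state")
    alphabet = sorted({tip_states[t] for t in idx.tip_index})
    down, up, total = _unit_cost_dp(idx, tip_states, alphabet)
    node_states = {}
    for v in range(idx.n_nodes):
        score = down[v] + up[v]
        states = frozenset(
            a for a, s in zip(alphabet, score) if s <= total + 1e-9
        )
        node_states[idx.labels[v]] = states
    equivocal = {}
    for v in range(idx.n_nodes):
        p = idx.parent[v]
        if p < 0:
            continue
        equivocal[idx.labels[v]] = (
            len(node_states[idx.labels[v]]) > 1
            or len(node_states[idx.labels[p]]) > 1
        )
    return AncestralReconstruction(
        node_states=node_states,
        total_cost=float(total),
        equivocal_branches=equivocal,
        kind="discrete",
    )


def fitch_union_count(tree: Phylogeny, tip_states: dict) -> int:
    """Number of union operations in the classic bottom-up Fitch pass.

    On binary trees this equals the parsimony minimum; on polytomies the
    iterated pairwise intersection/union generalisation may overcount.
    """
    idx = tree.index()
    sets = [None] * idx.n_nodes
    unions = 0
    for v in range(idx.n_nodes):
        if idx.is_tip[v]:
            label = idx.labels[v]
            if label not in tip_states:
                raise ValidationError(f"tip {label!r} has no state")
            sets[v] = frozenset([tip_states[label]])
        else:
            acc = None
            for c in idx.children[v]:
                if acc is None:
                    acc = sets[c]
                    continue
                inter = acc & sets[c]
                if inter:
                    acc = inter
                else:
                    acc = acc | sets[c]
                    unions += 1
            sets[v] = acc
    return unions


def _binary_presence_dp(idx, tip_matrix: np.ndarray):
    """Vectorised unit-cost DP for many 0/1 characters at once.

    ``tip_matrix``: shape (n_families, n_tips) of 0/1, tip columns ordered by
    node index of the tips. Returns root cost arrays (c0, c1), each of shape
    (n_families,).
    """
    n_fam = tip_matrix.shape[0]
    big = np.float64(1e9)
    cost0 = np.zeros((idx.n_nodes, n_fam))
    cost1 = np.zeros((idx.n_nodes, n_fam))
    tip_col = {}
    t = 0
    for v in range(idx.n_nodes):
        if idx.is_tip[v]:
            tip_col[v] = t
            t += 1
    for v in range(idx.n_nodes):
        if idx.is_tip[v]:
            present = tip_matrix[:, tip_col[v]].astype(bool)
            cost0[v] = np.where(present, big, 0.0)
            cost1[v] = np.where(present, 0.0, big)
        else:
            a0 = np.zeros(n_fam)
            a1 = np.zeros(n_fam)
            for c in idx.children[v]:
                a0 += np.minimum(cost0[c], cost1[c] + 1.0)
                a1 += np.minimum(cost1[c], cost0[c] + 1.0)
            cost0[v] = a0
            cost1[v] = a1
    return cost0[idx.root], cost1[idx.root], tip_col


def root_content_interval(matrix: OrthologMatrix, tree: Phylogeny,
                          presence_mode: str = "any_copy") -> RootContentInterval:
    """Bound the root ancestor's gene content by presence/absence parsimony.

    Each ortholog group contributes a 0/1 character; groups whose root MPR
    set is exactly {1} are surely present (minimum), groups with root set
    {0, 1} are ambiguous and count toward the maximum only.
    """
    idx = tree.index()
    tips = [idx.labels[v] for v in range(idx.n_nodes) if idx.is_tip[v]]
    missing = set(tips) - set(matrix.genome_ids)
    if missing:
        raise ValidationError(f"tree tips not in matrix: {sorted(missing)}")
    presence = matrix.presence(presence_mode)
    tip_matrix = presence[tips].to_numpy().astype(np.int8)
    c0, c1, _ = _binary_presence_dp(idx, tip_matrix)
    best = np.minimum(c0, c1)
    sure = c1 <= best + 1e-9
    maybe_absent = c0 <= best + 1e-9
    group_ids = np.asarray(matrix.group_ids)
    sure_groups = list(group_ids[sure & ~maybe_absent])
    ambiguous_groups = list(group_ids[sure & maybe_absent])
    return RootContentInterval(
        min_genes=len(sure_groups),
        max_genes=len(sure_groups) + len(ambiguous_groups),
        sure_groups=sure_groups,
        ambiguous_groups=ambiguous_groups,
    )


def sankoff_linear(tree: Phylogeny, tip_copy_numbers: dict,
                   max_state: Optional[int] = None) -> AncestralReconstruction:
    """Copy-number parsimony with linear change cost ``|i - j|``.

    States are integers 0..max_state (default: the maximum observed copy
    number, outside of which no assignment can be optimal under linear
    cost). Node state sets are the exact MPR sets; the total cost is the
    minimal weighted number of copy gains/losses.
    """
    idx = tree.index()
    for label, v in tip_copy_numbers.items():
        if v < 0:
            raise ValidationError(f"tip {label!r}: negative copy number")
    observed_max = max(tip_copy_numbers.values())
    if max_state is None:
        max_state = observed_max
    if observed_max > max_state:
        raise ValidationError("tip copy number exceeds max_state")
    k = max_state + 1
    states = np.arange(k)
    cost_matrix = np.abs(states[:, None] - states[None, :]).astype(float)
    down = np.zeros((idx.n_nodes, k))
    for v in range(idx.n_nodes):
        if idx.is_tip[v]:
            label = idx.labels[v]
            if label not in tip_copy_numbers:
                raise ValidationError(f"tip {label!r} has no copy number")
            down[v, :] = _INF
            down[v, tip_copy_numbers[label]] = 0.0
        else:
            for c in idx.children[v]:
                down[v] += (cost_matrix + down[c][None, :]).min(axis=1)
    up = np.zeros((idx.n_nodes, k))
    for v in reversed(range(idx.n_nodes)):
        if idx.is_tip[v]:
            continue
        contribs = np.empty((len(idx.children[v]), k))
        for ci, c in enumerate(idx.children[v]):
            contribs[ci] = (cost_matrix + down[c][None, :]).min(axis=1)
        total_children = contribs.sum(axis=0)
        for ci, c in enumerate(idx.children[v]):
            other = up[v] + total_children - contribs[ci]
            up[c] = (cost_matrix + other[None, :]).min(axis=1)
    score_root = down[idx.root] + up[idx.root]
    total = score_root.min()
    node_states = {}
    for v in range(idx.n_nodes):
        score = down[v] + up[v]
        node_states[idx.labels[v]] = frozenset(
            int(s) for s in states[score <= total + 1e-9]
        )
    equivocal = {}
    for v in range(idx.n_nodes):
        p = idx.parent[v]
        if p < 0:
            continue
        equivocal[idx.labels[v]] = (
            len(node_states[idx.labels[v]]) > 1
            or len(node_states[idx.labels[p]]) > 1
        )
    return AncestralReconstruction(
        node_states=node_states,
        total_cost=float(total),
        equivocal_branches=equivocal,
        kind="discrete",
    )


def copy_number_interval(matrix: OrthologMatrix, tree: Phylogeny,
                         presence_mode: str = "any_copy") -> RootContentInterval:
    """Root gene-copy interval from per-group linear-cost copy parsimony.

    Sums, over groups, the smallest and largest root copy numbers attainable
    in a most-parsimonious reconstruction.
    """
    idx = tree.index()
    tips = [idx.labels[v] for v in range(idx.n_nodes) if idx.is_tip[v]]
    missing = set(tips) - set(matrix.genome_ids)
    if missing:
        raise ValidationError(f"tree tips not in matrix: {sorted(missing)}")
    counts = matrix.counts(presence_mode)
    lo = hi = 0
    sure, ambiguous = [], []
    for gid in matrix.group_ids:
        tip_copies = {t: int(counts.at[gid, t]) for t in tips}
        rec = sankoff_linear(tree, tip_copies)
        root_set = rec.node_states[idx.labels[idx.root]]
        lo += min(root_set)
        hi += max(root_set)
        if min(root_set) > 0:
            sure.append(gid)
        elif max(root_set) > 0:
            ambiguous.append(gid)
    return RootContentInterval(
        min_genes=lo, max_genes=hi,
        sure_groups=sure, ambiguous_groups=ambiguous,
    )


# ---------------------------------------------------------------------------
# continuous parsimony
# ---------------------------------------------------------------------------

def squared_change(tree: Phylogeny, tip_values: dict,
                   weighted: bool = False) -> AncestralReconstruction:
    """Squared-change parsimony for a continuous character.

    Minimises ``sum_e (x_parent - x_child)^2 / w_e`` over internal-node
    values, with ``w_e`` the branch length when ``weighted`` else 1. The
    objective is strictly convex, so the solution (a linear system) is
    unique.
    """
    idx = tree.index()
    for label in idx.tip_index:
        if label not in tip_values:
            raise ValidationError(f"tip {label!r} has no value")
    weights = {}
    for v in range(idx.n_nodes):
        if idx.parent[v] < 0:
            continue
        if weighted:
            ln = idx.length[v]
            if ln is None or ln <= 0:
                raise ValidationError(
                    f"weighted squared-change needs positive branch length "
                    f"above node {idx.labels[v]!r}"
                )
            weights[v] = 1.0 / ln
        else:
            weights[v] = 1.0
    internal = [v for v in range(idx.n_nodes) if not idx.is_tip[v]]
    ipos = {v: i for i, v in enumerate(internal)}
    n = len(internal)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for v in range(idx.n_nodes):
        p = idx.parent[v]
        if p < 0:
            continue
        w = weights[v]
        # edge between v and p contributes w*(x_v - x_p)^2
        for u, other in ((v, p), (p, v)):
            if idx.is_tip[u]:
                continue
            i = ipos[u]
            A[i, i] += w
            if idx.is_tip[other]:
                b[i] += w * tip_values[idx.labels[other]]
            else:
                A[i, ipos[other]] -= w
    x = np.linalg.solve(A, b)
    values = {}
    for v in range(idx.n_nodes):
        if idx.is_tip[v]:
            values[idx.labels[v]] = float(tip_values[idx.labels[v]])
        else:
            values[idx.labels[v]] = float(x[ipos[v]])
    cost = 0.0
    for v in range(idx.n_nodes):
        p = idx.parent[v]
        if p < 0:
            continue
        d = values[idx.labels[v]] - values[idx.labels[p]]
        cost += weights[v] * d * d
    return AncestralReconstruction(
        node_states=values, total_cost=float(cost), kind="continuous",
    )
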