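"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration and per-group
scans — and shares no code with the package implementations it checks.
"""

from itertools import product

import numpy as np
import pandas as pd

from pancestor.datamodel import GenomeRecord, OrthologMatrix, PHENOTYPE_FLAGS


# ---------------------------------------------------------------------------
# parsimony by exhaustive enumeration
# ---------------------------------------------------------------------------

def enumerate_parsimony(tree, tip_states, alphabet, cost_fn):
    """Minimise total edge cost over all internal-node state assignments.

    Returns (min_cost, node_sets) where node_sets maps every node label to
    the set of states it takes in at least one minimum-cost assignment.
    """
    idx = tree.index()
    internal = [v for v in range(idx.n_nodes) if not idx.is_tip[v]]
    state = {}
    for v in range(idx.n_nodes):
        if idx.is_tip[v]:
            state[v] = tip_states[idx.labels[v]]
    best = float("inf")
    argmin = []
    for combo in product(alphabet, repeat=len(internal)):
        for v, s in zip(internal, combo):
            state[v] = s
        cost = 0
        for v in range(idx.n_nodes):
            p = idx.parent[v]
            if p >= 0:
                cost += cost_fn(state[p], state[v])
        if cost < best - 1e-12:
            best = cost
            argmin = [dict(zip(internal, combo))]
        elif abs(cost - best) <= 1e-12:
            argmin.append(dict(zip(internal, combo)))
    node_sets = {}
    for v in range(idx.n_nodes):
        if idx.is_tip[v]:
            node_sets[idx.labels[v]] = {tip_states[idx.labels[v]]}
        else:
            node_sets[idx.labels[v]] = {a[v] for a in argmin}
    return best, node_sets


def unit_cost(a, b):
    return 0 if a == b else 1


def linear_cost(a, b):
    return abs(a - b)


# ---------------------------------------------------------------------------
# set operations by per-group scan
# ---------------------------------------------------------------------------

def _present(matrix, gid, genome, mode):
    f = matrix.functional.at[gid, genome]
    p = matrix.pseudo.at[gid, genome]
    return (f + p > 0) if mode == "any_copy" else (f > 0)


def brute_core(matrix, spec):
    finished = [g for g in matrix.genome_ids if matrix.genomes[g].finished]
    drafts = [g for g in matrix.genome_ids if not matrix.genomes[g].finished]
    out = set()
    for gid in matrix.group_ids:
        absent = sum(
            not _present(matrix, gid, g, spec.presence_mode) for g in finished
        )
        if absent > spec.k_missing_finished:
            continue
        if not spec.draft_wildcard and any(
            not _present(matrix, gid, g, spec.presence_mode) for g in drafts
        ):
            continue
        if spec.single_copy:
            bad = False
            for g in matrix.genome_ids:
                if _present(matrix, gid, g, spec.presence_mode) and \
                        matrix.functional.at[gid, g] != 1:
                    bad = True
            if bad:
                continue
        out.add(gid)
    return out


def brute_phenotype_signature(matrix, flag, mode="finished_positive"):
    positives = [
        g for g in matrix.genome_ids if flag in matrix.genomes[g].phenotypes
    ]
    negatives = [
        g for g in matrix.genome_ids if flag not in matrix.genomes[g].phenotypes
    ]
    required = positives if mode == "all_positive" else [
        g for g in positives if matrix.genomes[g].finished
    ]
    out = set()
    for gid in matrix.group_ids:
        if all(_present(matrix, gid, g, "any_copy") for g in required) and \
                all(matrix.functional.at[gid, g] == 0 for g in negatives):
            out.add(gid)
    return out


def brute_clade_signature(matrix, cladeA, cladeB):
    required = [
        g for g in matrix.genome_ids
        if matrix.genomes[g].clade == cladeA and matrix.genomes[g].finished
    ]
    negatives = [
        g for g in matrix.genome_ids if matrix.genomes[g].clade == cladeB
    ]
    out = set()
    for gid in matrix.group_ids:
        if all(_present(matrix, gid, g, "any_copy") for g in required) and \
                all(matrix.functional.at[gid, g] == 0 for g in negatives):
            out.add(gid)
    return out


def brute_missing(matrix, genome_id):
    out = set()
    for gid in matrix.group_ids:
        if matrix.functional.at[gid, genome_id] > 0:
            continue
        if all(matrix.functional.at[gid, g] > 0
               for g in matrix.genome_ids if g != genome_id):
            out.add(gid)
    return out


def brute_paralog_counts(matrix, genome_id, mode="any_copy"):
    """(n_paralogous_groups, total_copies, pseudo_copies) by direct scan."""
    n = copies = pseudo = 0
    for gid in matrix.group_ids:
        f = matrix.functional.at[gid, genome_id]
        p = matrix.pseudo.at[gid, genome_id]
        c = f + p if mode == "any_copy" else f
        if c >= 2:
            n += 1
            copies += c
            pseudo += p
    return n, copies, pseudo


# ---------------------------------------------------------------------------
# random instances
# ---------------------------------------------------------------------------

def random_matrix(rng, n_groups=50, n_genomes=8, p_absent=0.3,
                  p_pseudo=0.15, max_copies=3):
    """Random ortholog matrix with random finished/clade/phenotype labels."""
    ids = [f"g{j + 1}" for j in range(n_genomes)]
    func = rng.integers(0, max_copies + 1, size=(n_groups, n_genomes))
    func = np.where(rng.random(func.shape) < p_absent, 0, func)
    pseudo = np.where(
        rng.random(func.shape) < p_pseudo,
        rng.integers(1, 3, size=func.shape), 0,
    )
    genomes = {}
    for j, g in enumerate(ids):
        genomes[g] = GenomeRecord(
            id=g,
            # keep at least four finished genomes so k in 0..3 is always valid
            finished=bool(j < 4 or rng.random() < 0.7),
            clade=("clade1", "clade2", "outgroup")[int(rng.integers(3))],
            phenotypes={
                f for f in PHENOTYPE_FLAGS if rng.random() < 0.4
            },
        )
    group_ids = [f"G{i + 1}" for i in range(n_groups)]
    return OrthologMatrix(
        functional=pd.DataFrame(func, index=group_ids, columns=ids),
        pseudo=pd.DataFrame(pseudo, index=group_ids, columns=ids),
        genomes=genomes,
    )
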