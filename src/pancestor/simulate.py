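"""Synthetic ortholog/tree datasets with known ground truth.

Emulates, at desk scale, a comparative dataset of several dozen bacterial
genomes: a Yule tree whose two root subtrees play the role of the two major
clades; ortholog families evolving by a two-state gain/loss Markov chain
with within-lineage duplication (in-paralogs); per-genome nucleotide
partitions derived from functional gene counts; binary phenotypes evolving
on the same tree (with optional "planted" families that exactly track a
phenotype); massive lineage-specific pseudogenization of one target tip
(an eroding obligate-symbiont genome); and noisy per-gene COG best hits.

Every generator is a pure function of its inputs and a seed, and the emitted
files re-parse into exactly the in-memory objects, so each downstream stage
can be tested against the recorded truth without any external data.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from . import datamodel as dm
from .trees import Phylogeny

COG_CATEGORIES = list("JKLDOMNPTCGEFHIQRSUV")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset generator.

    Rates are per unit branch length. The defaults describe the standard
    default scenario: 58 tips, most genomes finished, a moderately dynamic
    gene content (about two presence flips per family across the whole
    tree), and one heavily pseudogenized target tip.
    """

    n_tips: int = 58
    birth_rate: float = 1.0
    n_families: int = 2000
    root_presence_prob: float = 0.30
    gain_rate: float = 0.03
    loss_rate: float = 0.06
    dup_rate: float = 0.05
    mean_gene_length_bp: float = 1000.0
    gene_length_noise_sd: float = 0.05  # lognormal sd of per-genome length factor
    noncoding_frac_mean: float = 0.15
    noncoding_frac_sd: float = 0.25  # lognormal sd of the per-tip fraction
    bm_sigma2: float = 1.0
    phenotype_gain_rate: float = 0.05
    phenotype_loss_rate: float = 0.05
    phenotype_root_prob: float = 0.5
    pseudo_target: Optional[str] = None  # default: first clade1 tip
    pseudo_fraction: float = 0.64
    finished_fraction: float = 39 / 58
    planted_signatures: dict = field(default_factory=dict)  # flag -> n families
    gamma_rate_shape: Optional[float] = None  # per-family rate multipliers
    cog_none_prob: float = 0.2
    cog_error_prob: float = 0.1
    cyano_unique_prob: float = 0.31
    seed: int = 0

    def __post_init__(self):
        for name in ("birth_rate",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gain_rate", "loss_rate", "dup_rate",
                     "phenotype_gain_rate", "phenotype_loss_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.root_presence_prob <= 1:
            raise ValueError("root_presence_prob must be in [0, 1]")
        if not 0 <= self.pseudo_fraction <= 1:
            raise ValueError("pseudo_fraction must be in [0, 1]")
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating a dataset."""

    root_presence: np.ndarray  # (F,) bool
    node_presence: dict  # node label -> (F,) bool
    node_copies: dict  # node label -> (F,) int
    node_trait: dict = field(default_factory=dict)  # node label -> float
    node_phenotypes: dict = field(default_factory=dict)  # flag -> {label: bool}
    family_categories: dict = field(default_factory=dict)  # group id -> COG letter
    config: Optional[SimulationConfig] = None

    @property
    def true_root_gene_count(self) -> int:
        return int(self.root_presence.sum())


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, birth_rate: float, seed=None,
                  rng: Optional[np.random.Generator] = None,
                  prefix: str = "t") -> Phylogeny:
    """Yule (pure-birth) tree with ``n_tips`` tips.

    Lineages split at rate ``birth_rate`` each; the process stops when
    ``n_tips`` lineages exist and runs for one further exponential waiting
    time so that every pendant branch has positive length. Deterministic
    given the seed. Tips are labelled ``t01, t02, ...`` in birth order.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    width = max(2, len(str(n_tips)))
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = root.new_child()
        child.birth_time = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = rng.integers(len(active))
        node = active.pop(i)
        node.edge.length = t - node.birth_time
        for _ in range(2):
            child = node.new_child()
            child.birth_time = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    # label tips in birth order for reproducible naming
    active.sort(key=lambda n: n.birth_time)
    for k, node in enumerate(active, start=1):
        node.edge.length = t - node.birth_time
        node.taxon = taxa.new_taxon(f"{prefix}{k:0{width}d}")
    root.edge.length = None
    return Phylogeny(tree)


def clade_assignment(tree: Phylogeny) -> dict:
    """Tip label -> "clade1"/"clade2" from the root bipartition.

    The root subtree with more tips (ties: the one holding the
    lexicographically first tip) is clade1.
    """
    idx = tree.index()
    root_children = idx.children[idx.root]
    sides = []
    for c in root_children:
        tips = _subtree_tips(idx, c)
        sides.append(tips)
    sides.sort(key=lambda s: (-len(s), min(s)))
    out = {}
    for name, tips in zip(("clade1", "clade2"), sides[:2]):
        for t in tips:
            out[t] = name
    for tips in sides[2:]:  # polytomy at the root: extra subtrees -> outgroup
        for t in tips:
            out[t] = "outgroup"
    return out


def _subtree_tips(idx, v) -> set:
    stack, tips = [v], set()
    while stack:
        u = stack.pop()
        if idx.is_tip[u]:
            tips.add(idx.labels[u])
        else:
            stack.extend(idx.children[u])
    return tips


# ---------------------------------------------------------------------------
# discrete two-state chain on the tree
# ---------------------------------------------------------------------------

def two_state_transition(gain: float, loss: float, t: float):
    """(p01, p11): presence probability after time t given absent/present."""
    s = gain + loss
    if s == 0:
        return 0.0, 1.0
    e = math.exp(-s * t)
    pi1 = gain / s
    return pi1 * (1 - e), pi1 + (1 - pi1) * e


def _sample_binary_chain(idx, n: int, gain: float, loss: float,
                         root_prob: float, rng) -> dict:
    """Presence (n characters) at every node; node index -> bool array."""
    states = {}
    for v in reversed(range(idx.n_nodes)):  # root first
        if idx.parent[v] < 0:
            states[v] = rng.random(n) < root_prob
            continue
        t = idx.length[v]
        if t is None:
            raise dm.ValidationError("tree is missing branch lengths")
        p01, p11 = two_state_transition(gain, loss, t)
        parent = states[idx.parent[v]]
        u = rng.random(n)
        states[v] = np.where(parent, u < p11, u < p01)
    return states


def simulate_gene_content(tree: Phylogeny, config: SimulationConfig,
                          rng: Optional[np.random.Generator] = None):
    """Evolve family presence and copy number along the tree.

    Presence follows a continuous-time two-state chain (gain ``lambda``,
    loss ``mu``) from a Bernoulli(p0) root draw. Conditional on presence at
    both ends of a branch, copies duplicate by a linear birth process at
    rate ``delta`` (each copy leaves a geometric number of descendants); a
    family gained on a branch enters with a single copy. With
    ``gamma_rate_shape`` set, each family scales both rates by an
    independent mean-one Gamma multiplier (rate heterogeneity across
    families); by default families are i.i.d. Returns the ortholog matrix
    (tips only, placeholder genome records) and the full node-level truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    idx = tree.index()
    if not tree.has_branch_lengths():
        raise dm.ValidationError("tree is missing branch lengths")
    F = config.n_families
    mult = np.ones(F)
    if config.gamma_rate_shape is not None:
        if config.gamma_rate_shape <= 0:
            raise ValueError("gamma_rate_shape must be positive")
        mult = rng.gamma(config.gamma_rate_shape,
                         1.0 / config.gamma_rate_shape, size=F)
    s = (config.gain_rate + config.loss_rate) * mult
    pi1 = config.gain_rate / (config.gain_rate + config.loss_rate) \
        if config.gain_rate + config.loss_rate > 0 else 0.0
    presence = {}
    for v in reversed(range(idx.n_nodes)):  # root first
        if idx.parent[v] < 0:
            presence[v] = rng.random(F) < config.root_presence_prob
            continue
        e = np.exp(-s * idx.length[v])
        p01 = pi1 * (1 - e)
        p11 = pi1 + (1 - pi1) * e
        parent = presence[idx.parent[v]]
        u = rng.random(F)
        presence[v] = np.where(parent, u < p11, u < p01)
    copies = {}
    for v in reversed(range(idx.n_nodes)):
        if idx.parent[v] < 0:
            copies[v] = presence[v].astype(np.int64)
            continue
        parent_copies = copies[idx.parent[v]]
        here = presence[v]
        out = np.zeros(F, dtype=np.int64)
        retained = here & (parent_copies > 0)
        if retained.any():
            n_par = parent_copies[retained]
            p_keep = math.exp(-config.dup_rate * idx.length[v])
            extra = rng.negative_binomial(n_par, p_keep) \
                if config.dup_rate > 0 else 0
            out[retained] = n_par + extra
        gained = here & (parent_copies == 0)
        out[gained] = 1
        copies[v] = out
    group_ids = [f"G{i + 1:05d}" for i in range(F)]
    tips = sorted(idx.tip_index)
    func = np.zeros((F, len(tips)), dtype=int)
    for j, t in enumerate(tips):
        func[:, j] = copies[idx.tip_index[t]]
    import pandas as pd
    functional = pd.DataFrame(func, index=group_ids, columns=tips)
    pseudo = pd.DataFrame(0, index=group_ids, columns=tips)
    genomes = {t: dm.GenomeRecord(id=t) for t in tips}
    matrix = dm.OrthologMatrix(functional, pseudo, genomes)
    truth = SyntheticTruth(
        root_presence=presence[idx.root].copy(),
        node_presence={idx.labels[v]: presence[v] for v in presence},
        node_copies={idx.labels[v]: copies[v] for v in copies},
        config=config,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# continuous trait (Brownian motion)
# ---------------------------------------------------------------------------

def simulate_continuous(tree: Phylogeny, bm_sigma2: float, root_value: float,
                        seed=None, rng: Optional[np.random.Generator] = None,
                        rate_by_clade: Optional[dict] = None,
                        clade_map: Optional[dict] = None,
                        size: Optional[int] = None) -> dict:
    """Brownian motion on the tree: child ~ Normal(parent, sigma2 * length).

    ``rate_by_clade`` (clade label -> sigma2) overrides the base rate on
    branches whose descendant tips all belong to one clade, which is how the
    two-clade unequal-rate scenario is generated. With ``size`` set, that
    many independent replicate traits are simulated at once and each node
    maps to an array.
    """
    if bm_sigma2 < 0:
        raise ValueError("bm_sigma2 must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = tree.index()
    scalar = size is None
    n = 1 if scalar else size
    clades = None
    if rate_by_clade:
        if clade_map is None:
            raise ValueError("rate_by_clade requires clade_map")
        clades = [None] * idx.n_nodes
        for v in range(idx.n_nodes):
            if idx.is_tip[v]:
                clades[v] = {clade_map.get(idx.labels[v], "unassigned")}
            else:
                acc = set()
                for c in idx.children[v]:
                    acc |= clades[c]
                clades[v] = acc
    values = {}
    for v in reversed(range(idx.n_nodes)):
        if idx.parent[v] < 0:
            values[v] = np.full(n, float(root_value))
            continue
        t = idx.length[v]
        if t is None:
            raise dm.ValidationError("tree is missing branch lengths")
        rate = bm_sigma2
        if clades is not None and len(clades[v]) == 1:
            rate = rate_by_clade.get(next(iter(clades[v])), bm_sigma2)
        sd = math.sqrt(rate * t)
        values[v] = values[idx.parent[v]] + rng.normal(0.0, sd, size=n) \
            if sd > 0 else values[idx.parent[v]].copy()
    out = {}
    for v in range(idx.n_nodes):
        out[idx.labels[v]] = float(values[v][0]) if scalar else values[v]
    return out


# ---------------------------------------------------------------------------
# phenotypes, metadata, COG hits, full dataset
# ---------------------------------------------------------------------------

def simulate_phenotypes(tree: Phylogeny, config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None):
    """Binary phenotype states at every node for the four standard flags.

    Each flag evolves as its own gain/loss chain; biological nesting is
    imposed afterwards (heterocyst formation requires filaments, plant
    symbiosis requires heterocysts), mirroring how the traits co-occur in
    cyanobacteria.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    idx = tree.index()
    raw = {}
    for flag in dm.PHENOTYPE_FLAGS:
        states = _sample_binary_chain(
            idx, 1, config.phenotype_gain_rate, config.phenotype_loss_rate,
            config.phenotype_root_prob, rng,
        )
        raw[flag] = {idx.labels[v]: bool(states[v][0]) for v in states}
    for label in raw["filamentous"]:
        raw["heterocystous"][label] &= raw["filamentous"][label]
        raw["plant_symbiont"][label] &= raw["heterocystous"][label]
    return raw


def simulate_genome_metadata(tree: Phylogeny, matrix: dm.OrthologMatrix,
                             config: SimulationConfig,
                             rng: Optional[np.random.Generator] = None,
                             phenotypes: Optional[dict] = None,
                             truth: Optional[SyntheticTruth] = None) -> list:
    """Derive per-genome metadata and apply target-tip pseudogenization.

    Coding nucleotides are (functional gene count) x (per-genome gene
    length drawn around the configured mean); non-coding nucleotides are a
    per-tip lognormal fraction of genic nucleotides; at the target tip each
    functional copy independently pseudogenizes with probability
    ``pseudo_fraction``, moving copies (and nucleotides) into the pseudogene
    compartment. Updates ``matrix`` counts in place and returns the genome
    records (also installed into the matrix).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    idx = tree.index()
    tips = sorted(idx.tip_index)
    clade_map = clade_assignment(tree)
    target = config.pseudo_target
    if target is None and config.pseudo_fraction > 0:
        clade1 = sorted(t for t in tips if clade_map.get(t) == "clade1")
        target = clade1[0] if clade1 else tips[0]
    if target is not None and target not in idx.tip_index:
        raise dm.ValidationError(f"pseudogenization target {target!r} not a tip")
    # pseudogenize the target tip's functional copies
    if target is not None and config.pseudo_fraction > 0:
        col = matrix.functional[target].to_numpy()
        moved = rng.binomial(col, config.pseudo_fraction)
        matrix.functional[target] = col - moved
        matrix.pseudo[target] = matrix.pseudo[target].to_numpy() + moved
    n_finished = int(round(config.finished_fraction * len(tips)))
    finished_tips = set(
        rng.choice(tips, size=n_finished, replace=False)
    ) if n_finished else set()
    if target is not None:
        finished_tips.add(target)  # the eroding genome is a finished assembly
    records = []
    for t in tips:
        n_func = int(matrix.functional[t].sum())
        n_pseudo = int(matrix.pseudo[t].sum())
        length = config.mean_gene_length_bp * math.exp(
            rng.normal(0.0, config.gene_length_noise_sd)
        )
        coding = int(round(n_func * length))
        pseudo_bp = int(round(n_pseudo * length))
        frac = config.noncoding_frac_mean * math.exp(
            rng.normal(0.0, config.noncoding_frac_sd)
        )
        noncoding = int(round((coding + pseudo_bp) * frac))
        flags = set()
        if phenotypes is not None:
            flags = {f for f in dm.PHENOTYPE_FLAGS if phenotypes[f][t]}
        records.append(dm.GenomeRecord(
            id=t,
            name=f"Synthetic genome {t}",
            finished=t in finished_tips,
            clade=clade_map.get(t, "unassigned"),
            genome_size_bp=coding + noncoding + pseudo_bp,
            coding_bp=coding,
            noncoding_bp=noncoding,
            pseudogene_bp=pseudo_bp,
            gene_count=n_func,
            phenotypes=flags,
            habitat="synthetic",
        ))
    matrix.genomes = {r.id: r for r in records}
    if truth is not None:
        truth.node_phenotypes = phenotypes or {}
    return records


@dataclass
class SyntheticDataset:
    """A complete generated dataset plus its ground truth."""

    config: SimulationConfig
    tree: Phylogeny
    groups: list  # OrthologGroup
    genomes: list  # GenomeRecord
    matrix: dm.OrthologMatrix
    pseudogene_ids: set
    cog_hits: dm.CogHitTable
    truth: SyntheticTruth

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        dm.write_groups(self.groups, os.path.join(out_dir, "groups.txt"))
        dm.write_genomes(self.genomes, os.path.join(out_dir, "genomes.tsv"))
        dm.write_pseudogenes(
            self.pseudogene_ids, os.path.join(out_dir, "pseudogenes.tsv")
        )
        self.tree.write(os.path.join(out_dir, "tree.nwk"))
        dm.write_coghits(self.cog_hits, os.path.join(out_dir, "coghits.tsv"))
        with open(os.path.join(out_dir, "truth.json"), "w",
                  encoding="utf-8") as fh:
            json.dump(self.truth_summary(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def truth_summary(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        return {
            "config": cfg,
            "true_root_gene_count": self.truth.true_root_gene_count,
            "root_presence": [int(x) for x in self.truth.root_presence],
            "family_categories": self.truth.family_categories,
            "node_phenotypes": {
                flag: {k: int(v) for k, v in states.items()}
                for flag, states in self.truth.node_phenotypes.items()
            },
        }


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full dataset: tree, matrix, metadata, phenotypes, COG hits."""
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=6)
    tree = simulate_tree(config.n_tips, config.birth_rate,
                         rng=np.random.default_rng(seeds[0]))
    matrix, truth = simulate_gene_content(
        tree, config, rng=np.random.default_rng(seeds[1])
    )
    phenotypes = simulate_phenotypes(
        tree, config, rng=np.random.default_rng(seeds[2])
    )
    # planted signature families: presence exactly tracks a phenotype flag
    planted_rows = []
    for flag, n_plant in sorted(config.planted_signatures.items()):
        for k in range(n_plant):
            gid = f"SIG_{flag}_{k + 1:02d}"
            row = {
                t: 1 if phenotypes[flag][t] else 0
                for t in matrix.genome_ids
            }
            planted_rows.append((gid, row))
    if planted_rows:
        import pandas as pd
        add = pd.DataFrame(
            {gid: row for gid, row in planted_rows}
        ).T[matrix.genome_ids]
        functional = pd.concat([matrix.functional, add])
        pseudo = pd.concat(
            [matrix.pseudo, add * 0]
        )
        matrix = dm.OrthologMatrix(functional, pseudo, matrix.genomes)
    genomes = simulate_genome_metadata(
        tree, matrix, config, rng=np.random.default_rng(seeds[3]),
        phenotypes=phenotypes, truth=truth,
    )
    # families extinct at every tip leave no genes and are unobservable
    observed = (matrix.functional + matrix.pseudo).sum(axis=1) > 0
    matrix = matrix.subset_groups(matrix.functional.index[observed])
    groups, pseudogene_ids = _matrix_to_groups(
        matrix, rng=np.random.default_rng(seeds[4]),
        cyano_unique_prob=config.cyano_unique_prob,
    )
    cog_hits = _simulate_cog_hits(
        groups, config, truth, rng=np.random.default_rng(seeds[5])
    )
    return SyntheticDataset(
        config=config, tree=tree, groups=groups, genomes=genomes,
        matrix=matrix, pseudogene_ids=pseudogene_ids, cog_hits=cog_hits,
        truth=truth,
    )


def _matrix_to_groups(matrix: dm.OrthologMatrix, rng,
                      cyano_unique_prob: float):
    """Materialise gene ids behind the copy counts of a matrix."""
    groups = []
    pseudogene_ids = set()
    func = matrix.functional.to_numpy()
    pseudo = matrix.pseudo.to_numpy()
    genome_ids = matrix.genome_ids
    for i, gid in enumerate(matrix.group_ids):
        members = []
        for j, genome in enumerate(genome_ids):
            k = 0
            for _ in range(func[i, j]):
                k += 1
                members.append((genome, f"{genome}_{gid}_{k}", True))
            for _ in range(pseudo[i, j]):
                k += 1
                gene = f"{genome}_{gid}_{k}"
                members.append((genome, gene, False))
                pseudogene_ids.add(gene)
        if not members:
            continue
        groups.append(dm.OrthologGroup(
            id=gid, members=members,
            cyano_unique=bool(rng.random() < cyano_unique_prob),
        ))
    return groups, pseudogene_ids


def _simulate_cog_hits(groups, config: SimulationConfig,
                       truth: SyntheticTruth, rng) -> dm.CogHitTable:
    """Assign each family a true category; corrupt per-gene best hits.

    A gene gets no passing hit with probability ``cog_none_prob`` (emitted
    with a failing e-value so the cutoff rule is exercised), and a wrong
    category with probability ``cog_error_prob``.
    """
    hits = {}
    cats = COG_CATEGORIES
    for group in groups:
        true_cat = cats[int(rng.integers(len(cats)))]
        truth.family_categories[group.id] = true_cat
        for _, gene_id, _ in group.members:
            u = rng.random()
            if u < config.cog_none_prob:
                hits[gene_id] = (cats[int(rng.integers(len(cats)))], 0.5)
            elif u < config.cog_none_prob + config.cog_error_prob:
                wrong = [c for c in cats if c != true_cat]
                hits[gene_id] = (wrong[int(rng.integers(len(wrong)))], 1e-6)
            else:
                hits[gene_id] = (true_cat, 1e-6)
    return dm.CogHitTable(hits=hits)
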