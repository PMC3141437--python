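"""In-paralog statistics and COG functional distributions.

A group is *paralogous* in a genome when it holds two or more gene copies
there (in-paralogs: post-speciation duplicates clustered into the same
ortholog group). Per genome we report how many groups contain paralogs, the
total number of paralogous gene copies, the mean copy number over those
groups, and the pseudogene share among the paralogous copies — the quantity
that exposes eroding genomes, where most duplicated copies are pseudogenes.

COG categories are attached to groups by a majority rule over per-gene best
hits and rolled up into per-genome functional distributions, with transposase
COGs broken out as a separate "t" subcolumn of category L.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import CogHitTable, OrthologGroup, OrthologMatrix


@dataclass
class ParalogSummary:
    """Per-genome in-paralog statistics (one row per genome)."""

    table: pd.DataFrame
    presence_mode: str
    denominator: str

    def row(self, genome_id: str) -> pd.Series:
        return self.table.loc[genome_id]


def paralog_stats(matrix: OrthologMatrix, presence_mode: str = "any_copy",
                  denominator: str = "per_genome") -> ParalogSummary:
    """Tabulate paralog abundance per genome.

    ``denominator`` controls the basis of ``prop_groups_with_paralogs``:
    ``per_genome`` divides by the number of groups with at least one copy in
    that genome, ``matrix_wide`` by the total number of groups.
    """
    if denominator not in ("per_genome", "matrix_wide"):
        raise ValueError(f"unknown denominator {denominator!r}")
    counts = matrix.counts(presence_mode)
    pseudo = matrix.pseudo
    rows = []
    for g in matrix.genome_ids:
        col = counts[g]
        para = col >= 2
        n_para = int(para.sum())
        copies = int(col[para].sum())
        present = int((col >= 1).sum())
        denom = present if denominator == "per_genome" else len(col)
        pseudo_copies = int(pseudo[g][para].sum())
        rows.append({
            "genome_id": g,
            "n_groups_with_paralogs": n_para,
            "prop_groups_with_paralogs": n_para / denom if denom else 0.0,
            "paralogous_copies": copies,
            "mean_copies_per_paralogous_group": copies / n_para if n_para else 0.0,
            "pseudogene_share": pseudo_copies / copies if copies else 0.0,
        })
    table = pd.DataFrame(rows).set_index("genome_id")
    return ParalogSummary(table=table, presence_mode=presence_mode,
                          denominator=denominator)


def assign_cog(group: OrthologGroup, hit_table: CogHitTable,
               evalue_cutoff: float = 0.01) -> Optional[str]:
    """Majority-rule COG assignment for one ortholog group.

    Hits at or above the e-value cutoff are discarded. Members without a
    passing hit count as a pseudo-category "none": when a real COG is the
    plurality it wins; when "none" is the plurality the most abundant real
    COG (if any) is assigned instead; ties among real COGs break
    lexicographically.
    """
    passing = hit_table.passing(evalue_cutoff)
    tally = Counter()
    n_none = 0
    for _, gene_id, _ in group.members:
        cat = passing.get(gene_id)
        if cat is None:
            n_none += 1
        else:
            tally[cat] += 1
    if not tally:
        return None
    best_count = max(tally.values())
    best = min(c for c, n in tally.items() if n == best_count)
    # best real COG wins unless unassigned members form a strict plurality,
    # in which case it *still* wins as "second most abundant" fallback
    return best


def assign_cogs(groups, hit_table: CogHitTable,
                evalue_cutoff: float = 0.01) -> dict:
    """group id -> category (or None) for a collection of groups."""
    return {g.id: assign_cog(g, hit_table, evalue_cutoff) for g in groups}


@dataclass
class FunctionalDistribution:
    """Genome x COG-category proportion table.

    Rows sum to 1 over real categories plus an ``unassigned`` bin. The ``t``
    column is a subset of L (transposase COGs) and is reported in addition
    to, not instead of, its share inside L.
    """

    table: pd.DataFrame
    categories: list


def functional_distribution(matrix: OrthologMatrix, cog_map: dict,
                            exclude_pseudogenes: bool = True,
                            transposase_groups: Optional[set] = None,
                            categories: Optional[list] = None) -> FunctionalDistribution:
    """Per-genome proportions of gene copies by COG category of their group.

    ``cog_map`` maps group id to a single-letter category (or None).
    ``transposase_groups`` is the configured set of group ids whose hits are
    transposase COGs; their copies stay inside L and are additionally
    reported as subcolumn "t". With ``exclude_pseudogenes`` only functional
    copies enter numerator and denominator.
    """
    unknown = set(cog_map) - set(matrix.group_ids)
    if unknown:
        raise ValueError(f"cog_map has unknown groups: {sorted(unknown)[:5]}")
    transposase_groups = transposase_groups or set()
    counts = matrix.functional if exclude_pseudogenes \
        else matrix.functional + matrix.pseudo
    cats = sorted({c for c in cog_map.values() if c is not None}) \
        if categories is None else list(categories)
    columns = cats + ["t", "unassigned"]
    data = pd.DataFrame(0.0, index=matrix.genome_ids, columns=columns)
    for gid in matrix.group_ids:
        cat = cog_map.get(gid)
        row = counts.loc[gid]
        if cat is None:
            data["unassigned"] += row
        else:
            if cat not in data.columns:
                raise ValueError(f"category {cat!r} not in category list")
            data[cat] += row
            if gid in transposase_groups:
                data["t"] += row
    totals = data.drop(columns=["t"]).sum(axis=1)
    totals = totals.replace(0, np.nan)
    out = data.div(totals, axis=0).fillna(0.0)
    return FunctionalDistribution(table=out, categories=cats)
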