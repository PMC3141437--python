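"""Domain types and file I/O for ortholog-cluster datasets.

The central object is :class:`OrthologMatrix`: per ortholog group and genome,
counts of functional and pseudogenized gene copies, linked to per-genome
metadata (:class:`GenomeRecord`). Readers cover the OrthoMCL groups-file
dialect, a tab-separated genome table, a pseudogene list and a per-gene COG
best-hit table. All TSVs are UTF-8, tab-delimited; lines starting with ``#``
are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

PHENOTYPE_FLAGS = ("filamentous", "heterocystous", "diazotroph", "plant_symbiont")
CLADES = ("clade1", "clade2", "outgroup", "unassigned")


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input parsed but violates a dataset invariant."""


@dataclass
class GenomeRecord:
    """Metadata for one genome.

    ``coding_bp + noncoding_bp + pseudogene_bp`` must equal ``genome_size_bp``
    (the nucleotide partition of the assembly); ``finished`` separates
    complete assemblies from drafts, which downstream core computations may
    treat as wildcards.
    """

    id: str
    name: str = ""
    finished: bool = True
    clade: str = "unassigned"
    genome_size_bp: int = 0
    coding_bp: int = 0
    noncoding_bp: int = 0
    pseudogene_bp: int = 0
    gene_count: int = 0
    phenotypes: set = field(default_factory=set)
    habitat: str = ""

    def __post_init__(self):
        if self.clade not in CLADES:
            raise ValidationError(
                f"genome {self.id!r}: unknown clade {self.clade!r}"
            )
        bad = set(self.phenotypes) - set(PHENOTYPE_FLAGS)
        if bad:
            raise ValidationError(f"genome {self.id!r}: unknown phenotypes {bad}")
        for attr in ("genome_size_bp", "coding_bp", "noncoding_bp",
                     "pseudogene_bp", "gene_count"):
            if getattr(self, attr) < 0:
                raise ValidationError(f"genome {self.id!r}: negative {attr}")
        total = self.coding_bp + self.noncoding_bp + self.pseudogene_bp
        if total != self.genome_size_bp:
            raise ValidationError(
                f"genome {self.id!r}: coding+noncoding+pseudogene = {total} "
                f"!= genome_size_bp = {self.genome_size_bp}"
            )


@dataclass
class OrthologGroup:
    """One ortholog cluster: (genome, gene, functional?) member triples."""

    id: str
    members: list  # of (genome_id, gene_id, functional: bool)
    cyano_unique: Optional[bool] = None

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"group {self.id!r} has no members")
        pairs = [(g, gene) for g, gene, _ in self.members]
        if len(set(pairs)) != len(pairs):
            raise ValidationError(f"group {self.id!r} has duplicate members")

    @property
    def genomes(self) -> set:
        return {g for g, _, _ in self.members}


class OrthologMatrix:
    """Group x genome copy-count matrix, split by functional status.

    ``functional`` and ``pseudo`` are integer DataFrames indexed by group id
    with one column per genome id; ``genomes`` maps genome id to its
    :class:`GenomeRecord`. Presence of a group in a genome can be evaluated
    in two modes used throughout the package: ``any_copy`` (functional or
    pseudogene copies count) and ``functional_only``.
    """

    def __init__(self, functional: pd.DataFrame, pseudo: pd.DataFrame,
                 genomes: dict):
        if list(functional.index) != list(pseudo.index) or \
                list(functional.columns) != list(pseudo.columns):
            raise ValidationError("functional/pseudo matrices not aligned")
        if set(functional.columns) != set(genomes):
            raise ValidationError("matrix columns != genome table ids")
        if (functional.to_numpy() < 0).any() or (pseudo.to_numpy() < 0).any():
            raise ValidationError("negative copy counts")
        self.functional = functional.astype(int)
        self.pseudo = pseudo.astype(int)
        self.genomes = dict(genomes)

    # -- accessors ---------------------------------------------------------

    @property
    def group_ids(self) -> list:
        return list(self.functional.index)

    @property
    def genome_ids(self) -> list:
        return list(self.functional.columns)

    def counts(self, mode: str = "any_copy") -> pd.DataFrame:
        if mode == "any_copy":
            return self.functional + self.pseudo
        if mode == "functional_only":
            return self.functional
        raise ValueError(f"unknown presence mode {mode!r}")

    def presence(self, mode: str = "any_copy") -> pd.DataFrame:
        """Boolean group x genome presence under the given mode."""
        return self.counts(mode) > 0

    def finished_ids(self) -> list:
        return [g for g in self.genome_ids if self.genomes[g].finished]

    def draft_ids(self) -> list:
        return [g for g in self.genome_ids if not self.genomes[g].finished]

    def subset_groups(self, group_ids: Iterable[str]) -> "OrthologMatrix":
        ids = list(group_ids)
        return OrthologMatrix(
            self.functional.loc[ids], self.pseudo.loc[ids], self.genomes
        )

    def record(self, genome_id: str) -> GenomeRecord:
        try:
            return self.genomes[genome_id]
        except KeyError:
            raise ValidationError(f"unknown genome {genome_id!r}") from None


@dataclass
class CogHitTable:
    """Per-gene best COG hit (single-letter category) with its e-value."""

    hits: dict  # gene_id -> (category: str | None, evalue: float)

    def __post_init__(self):
        for gene, (cat, ev) in self.hits.items():
            if ev is not None and ev < 0:
                raise ValidationError(f"gene {gene!r}: negative e-value")

    def passing(self, evalue_cutoff: float = 0.01) -> dict:
        """gene_id -> category for hits strictly below the cutoff."""
        return {
            gene: cat
            for gene, (cat, ev) in self.hits.items()
            if cat is not None and ev is not None and ev < evalue_cutoff
        }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def parse_groups(path) -> list:
    """Read an OrthoMCL-style groups file.

    Each line is ``groupId: taxon|gene taxon|gene ...``. Members default to
    functional; pseudogene status is applied later from the pseudogene list.
    """
    groups = []
    seen = set()
    for lineno, line in _data_lines(path):
        if ":" not in line:
            raise ParseError(f"{path}:{lineno}: missing ':' after group id")
        gid, _, rest = line.partition(":")
        gid = gid.strip()
        if not gid:
            raise ParseError(f"{path}:{lineno}: empty group id")
        if gid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate group id {gid!r}")
        seen.add(gid)
        members = []
        for token in rest.split():
            if "|" not in token:
                raise ParseError(
                    f"{path}:{lineno}: member {token!r} lacks 'genome|gene'"
                )
            genome_id, _, gene_id = token.partition("|")
            if not genome_id or not gene_id:
                raise ParseError(
                    f"{path}:{lineno}: member {token!r} lacks 'genome|gene'"
                )
            members.append((genome_id, gene_id, True))
        if not members:
            raise ParseError(f"{path}:{lineno}: group {gid!r} has no members")
        groups.append(OrthologGroup(id=gid, members=members))
    return groups


def write_groups(groups: Iterable[OrthologGroup], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for group in groups:
            tokens = " ".join(f"{g}|{gene}" for g, gene, _ in group.members)
            fh.write(f"{group.id}: {tokens}\n")


_GENOME_COLUMNS = [
    "id", "name", "finished", "clade", "genome_size_bp", "coding_bp",
    "noncoding_bp", "pseudogene_bp", "gene_count",
    *PHENOTYPE_FLAGS, "habitat",
]


def parse_genomes(path) -> list:
    """Read the genome metadata table (TSV with header)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = set(_GENOME_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    seen = set()
    for _, row in df.iterrows():
        gid = row["id"]
        if gid in seen:
            raise ValidationError(f"{path}: duplicate genome id {gid!r}")
        seen.add(gid)
        phenotypes = {f for f in PHENOTYPE_FLAGS if row[f].strip() == "1"}
        records.append(GenomeRecord(
            id=gid,
            name=row["name"],
            finished=row["finished"].strip() == "1",
            clade=row["clade"],
            genome_size_bp=int(row["genome_size_bp"]),
            coding_bp=int(row["coding_bp"]),
            noncoding_bp=int(row["noncoding_bp"]),
            pseudogene_bp=int(row["pseudogene_bp"]),
            gene_count=int(row["gene_count"]),
            phenotypes=phenotypes,
            habitat=row["habitat"],
        ))
    return records


def write_genomes(records: Iterable[GenomeRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "id": r.id, "name": r.name, "finished": int(r.finished),
            "clade": r.clade, "genome_size_bp": r.genome_size_bp,
            "coding_bp": r.coding_bp, "noncoding_bp": r.noncoding_bp,
            "pseudogene_bp": r.pseudogene_bp, "gene_count": r.gene_count,
            "habitat": r.habitat,
        }
        for f in PHENOTYPE_FLAGS:
            row[f] = int(f in r.phenotypes)
        rows.append(row)
    pd.DataFrame(rows, columns=_GENOME_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def parse_pseudogenes(path) -> set:
    """One gene id per line; an optional second column (genome id) is ignored."""
    ids = set()
    for _, line in _data_lines(path):
        ids.add(line.split("\t")[0].split()[0])
    return ids


def write_pseudogenes(gene_ids: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(gene_ids):
            fh.write(f"{gene}\n")


def parse_coghits(path) -> CogHitTable:
    """TSV of gene_id, COG category letter (may be empty), e-value."""
    hits = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if parts[0] == "gene_id":  # header
            continue
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns")
        gene, cat, ev = parts[0], parts[1].strip() or None, float(parts[2])
        if gene in hits:
            raise ValidationError(f"{path}:{lineno}: duplicate gene {gene!r}")
        hits[gene] = (cat, ev)
    return CogHitTable(hits=hits)


def write_coghits(table: CogHitTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tcategory\tevalue\n")
        for gene in sorted(table.hits):
            cat, ev = table.hits[gene]
            fh.write(f"{gene}\t{cat or ''}\t{ev:g}\n")


def build_matrix(groups: Iterable[OrthologGroup], genomes: Iterable[GenomeRecord],
                 pseudogene_ids: Optional[set] = None) -> OrthologMatrix:
    """Tabulate per-group functional and pseudogene copy counts per genome.

    Members whose gene id appears in ``pseudogene_ids`` count as pseudogene
    copies; genomes without a member of a group get zeros.
    """
    pseudogene_ids = pseudogene_ids or set()
    records = {r.id: r for r in genomes}
    if not records:
        raise ValidationError("empty genome table")
    groups = list(groups)
    genome_ids = list(records)
    gindex = {g: j for j, g in enumerate(genome_ids)}
    func = np.zeros((len(groups), len(genome_ids)), dtype=int)
    pseudo = np.zeros_like(func)
    for i, group in enumerate(groups):
        for genome_id, gene_id, functional in group.members:
            if genome_id not in gindex:
                raise ValidationError(
                    f"group {group.id!r}: member genome {genome_id!r} "
                    "not in genome table"
                )
            j = gindex[genome_id]
            if gene_id in pseudogene_ids or not functional:
                pseudo[i, j] += 1
            else:
                func[i, j] += 1
    index = [g.id for g in groups]
    return OrthologMatrix(
        functional=pd.DataFrame(func, index=index, columns=genome_ids),
        pseudo=pd.DataFrame(pseudo, index=index, columns=genome_ids),
        genomes=records,
    )
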