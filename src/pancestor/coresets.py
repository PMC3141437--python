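"""Core genomes, phenotype signatures and per-genome missing-ortholog reports.

The strict core is the set of ortholog groups present in every genome; the
relaxed cores (RCF, RCF1..RCF3) demand presence in the finished genomes only
(drafts are wildcards) and allow absence from up to k finished genomes.
Signature sets tie ortholog groups to phenotypes (e.g. heterocyst
differentiation) or to one of the two major clades: present in every
(finished) flag-positive genome and functionally absent from every
flag-negative genome. Everything here is deterministic set algebra over the
ortholog matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .datamodel import OrthologMatrix, PHENOTYPE_FLAGS, ValidationError


@dataclass
class CoreSpec:
    """Parameters of a (relaxed) core computation.

    ``k_missing_finished``: how many finished genomes may lack the group.
    ``draft_wildcard``: when true, draft genomes are ignored entirely;
    when false the group must additionally be present in every draft.
    ``presence_mode``: how presence is counted (pseudogene copies count under
    ``any_copy``). ``single_copy``: additionally require exactly one
    functional copy wherever the group is present.
    """

    k_missing_finished: int = 0
    draft_wildcard: bool = False
    presence_mode: str = "any_copy"
    single_copy: bool = False

    def __post_init__(self):
        if self.k_missing_finished < 0:
            raise ValueError("k_missing_finished must be >= 0")

    @classmethod
    def strict(cls) -> "CoreSpec":
        return cls(0, False, "any_copy", False)

    @classmethod
    def relaxed(cls, k: int = 0, single_copy: bool = False) -> "CoreSpec":
        """RCF (k=0) and RCF1..3 (k=1..3): drafts are wildcards."""
        return cls(k, True, "any_copy", single_copy)


@dataclass
class CoreResult:
    spec: CoreSpec
    group_ids: set
    missing_finished: dict = field(default_factory=dict)  # gid -> [genomes]
    functional_loss: dict = field(default_factory=dict)  # gid -> [pseudo-only]

    def __len__(self) -> int:
        return len(self.group_ids)


def compute_core(matrix: OrthologMatrix, spec: CoreSpec) -> CoreResult:
    """Groups satisfying the (relaxed) core definition of ``spec``.

    A group is in the core iff the number of finished genomes where it is
    absent (under ``spec.presence_mode``) is at most ``k_missing_finished``
    and, unless drafts are wildcards, it is present in every draft genome.
    Genomes where the group is present only as pseudogene copies are
    annotated as functional losses, not excluded (the strict core keeps
    groups with pseudogenized members).
    """
    finished = matrix.finished_ids()
    if spec.k_missing_finished > len(finished):
        raise ValidationError(
            "k_missing_finished exceeds the number of finished genomes"
        )
    presence = matrix.presence(spec.presence_mode)
    func_presence = matrix.presence("functional_only")
    absent_finished = (~presence[finished]).sum(axis=1)
    ok = absent_finished <= spec.k_missing_finished
    drafts = matrix.draft_ids()
    if not spec.draft_wildcard and drafts:
        ok &= presence[drafts].all(axis=1)
    if spec.single_copy:
        func = matrix.functional
        single = ((func == 1) | ~presence).all(axis=1)
        ok &= single
    group_ids = set(presence.index[ok])
    missing = {}
    loss = {}
    for gid in group_ids:
        lacking = [g for g in finished if not presence.at[gid, g]]
        if lacking:
            missing[gid] = lacking
        pseudo_only = [
            g for g in matrix.genome_ids
            if presence.at[gid, g] and not func_presence.at[gid, g]
        ]
        if pseudo_only:
            loss[gid] = pseudo_only
    return CoreResult(
        spec=spec, group_ids=group_ids,
        missing_finished=missing, functional_loss=loss,
    )


@dataclass
class SignatureResult:
    """Signature set with pseudogene annotations for positive genomes."""

    group_ids: set
    pseudo_only_positives: dict = field(default_factory=dict)  # gid -> [genomes]

    def __len__(self) -> int:
        return len(self.group_ids)


def phenotype_signature(matrix: OrthologMatrix, flag: str,
                        mode: str = "finished_positive",
                        positive_presence: str = "any_copy") -> SignatureResult:
    """Ortholog groups tracking a phenotype flag.

    Returned groups have at least one gene copy (``positive_presence`` mode,
    default ``any_copy``) in every required flag-positive genome — all of
    them under ``all_positive``, the finished ones only under
    ``finished_positive`` — and zero functional copies in every flag-negative
    genome regardless of assembly status. Positive genomes where the group
    survives only as pseudogene copies are reported alongside, since such
    members argue against the group being required for the phenotype.
    """
    if flag not in PHENOTYPE_FLAGS:
        raise ValidationError(f"unknown phenotype flag {flag!r}")
    if mode not in ("finished_positive", "all_positive"):
        raise ValueError(f"unknown signature mode {mode!r}")
    positives = [
        g for g in matrix.genome_ids if flag in matrix.genomes[g].phenotypes
    ]
    negatives = [
        g for g in matrix.genome_ids if flag not in matrix.genomes[g].phenotypes
    ]
    required = positives if mode == "all_positive" else [
        g for g in positives if matrix.genomes[g].finished
    ]
    return _signature(matrix, required, negatives, positive_presence)


def clade_signature(matrix: OrthologMatrix, cladeA: str, cladeB: str,
                    positive_presence: str = "any_copy") -> SignatureResult:
    """Groups present in all finished cladeA genomes and absent from cladeB.

    Outgroup and unassigned genomes are ignored on both sides; the symmetric
    call gives the reverse signature.
    """
    members_a = [g for g in matrix.genome_ids if matrix.genomes[g].clade == cladeA]
    members_b = [g for g in matrix.genome_ids if matrix.genomes[g].clade == cladeB]
    if not members_a:
        raise ValidationError(f"no genomes labelled clade {cladeA!r}")
    if not members_b:
        raise ValidationError(f"no genomes labelled clade {cladeB!r}")
    required = [g for g in members_a if matrix.genomes[g].finished]
    return _signature(matrix, required, members_b, positive_presence)


def _signature(matrix, required_positives, negatives, positive_presence):
    presence_pos = matrix.presence(positive_presence)
    func_presence = matrix.presence("functional_only")
    ok = presence_pos[required_positives].all(axis=1) if required_positives \
        else presence_pos.iloc[:, :0].notna().all(axis=1)
    if negatives:
        ok &= ~func_presence[negatives].any(axis=1)
    group_ids = set(presence_pos.index[ok])
    annotations = {}
    for gid in group_ids:
        pseudo_only = [
            g for g in required_positives
            if presence_pos.at[gid, g] and not func_presence.at[gid, g]
        ]
        if pseudo_only:
            annotations[gid] = pseudo_only
    return SignatureResult(group_ids=group_ids,
                           pseudo_only_positives=annotations)


@dataclass
class MissingReport:
    """Groups a genome lacks while all other genomes retain function."""

    genome_id: str
    absent: set  # no copies at all in the genome
    pseudogenized: set  # pseudogene copies only

    @property
    def group_ids(self) -> set:
        return self.absent | self.pseudogenized

    def __len__(self) -> int:
        return len(self.absent) + len(self.pseudogenized)


def missing_in_genome(matrix: OrthologMatrix, genome_id: str) -> MissingReport:
    """Groups with no functional copy in ``genome_id`` but functional copies
    in every other genome, split into truly absent vs pseudogene-only."""
    if genome_id not in matrix.genomes:
        raise ValidationError(f"unknown genome {genome_id!r}")
    func_presence = matrix.presence("functional_only")
    others = [g for g in matrix.genome_ids if g != genome_id]
    elsewhere = func_presence[others].all(axis=1)
    lacking = ~func_presence[genome_id]
    candidates = func_presence.index[elsewhere & lacking]
    pseudo_presence = matrix.pseudo > 0
    pseudogenized = {
        gid for gid in candidates if pseudo_presence.at[gid, genome_id]
    }
    absent = set(candidates) - pseudogenized
    return MissingReport(genome_id=genome_id, absent=absent,
                         pseudogenized=pseudogenized)
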