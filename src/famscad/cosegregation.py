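"""Transmission-model verdicts for single variants and variant pairs.

Three models are judged from genotypes alone (frequency and annotation
gates live in the filter cascade):

* ``AD`` — autosomal dominant with incomplete penetrance: every affected
  individual and every obligate carrier must be heterozygous; unaffected
  carriers elsewhere in the family are tolerated.
* ``AR_hom`` — recessive homozygous: all affected homozygous for the
  alternate allele, every genotyped unaffected parent heterozygous.
* ``AR_comphet`` — compound heterozygous: affected siblings heterozygous
  for two variants in the same gene, in trans when parental genotypes can
  establish phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .pedigree import PedigreeGraph
from .variant_io import VariantRecord

__all__ = [
    "SegregationVerdict",
    "ad_cosegregates",
    "ar_hom_cosegregates",
    "comphet_pairs",
]


@dataclass(frozen=True)
class SegregationVerdict:
    model: str  # AD | AR_hom | AR_comphet
    passes: bool
    required_carriers_checked: frozenset[str]
    reason: str = ""

    def __post_init__(self) -> None:
        if not self.passes and not self.reason:
            raise ValueError("failing verdict requires a reason code")


def ad_cosegregates(
    v: VariantRecord,
    ped: PedigreeGraph,
    affected: set[str],
    obligates: set[str] = frozenset(),
) -> SegregationVerdict:
    """Dominant-model verdict: heterozygous in all affected and obligates.

    Unaffected non-obligate carriers never fail the variant (incomplete
    penetrance); individuals with unknown affection are ignored.
    """
    required = frozenset(affected) | frozenset(obligates)
    for iid in sorted(required):
        ac = v.allele_count(iid)
        role = "affected" if iid in affected else "obligate"
        if ac is None or ac == 0:
            return SegregationVerdict(
                "AD", False, required, reason=f"absent_in_{role}"
            )
        if ac == 2:
            return SegregationVerdict(
                "AD", False, required, reason=f"homozygous_in_{role}"
            )
    return SegregationVerdict("AD", True, required)


def _genotyped_unaffected_parents(
    ped: PedigreeGraph, affected: set[str], v: VariantRecord
) -> set[str]:
    parents: set[str] = set()
    for iid in affected:
        parents.update(ped.parents(iid))
    return {
        p
        for p in parents
        if ped.members[p].affection == "unaffected"
        and v.allele_count(p) is not None
    }


def ar_hom_cosegregates(
    v: VariantRecord, ped: PedigreeGraph, affected: set[str]
) -> SegregationVerdict:
    """Recessive verdict: affected hom-alt, genotyped unaffected parents het."""
    if not affected:
        raise ValueError("affected set must be non-empty")
    required = frozenset(affected)
    for iid in sorted(affected):
        if v.allele_count(iid) != 2:
            return SegregationVerdict(
                "AR_hom", False, required, reason="not_homozygous_in_affected"
            )
    for p in sorted(_genotyped_unaffected_parents(ped, affected, v)):
        if v.allele_count(p) != 1:
            return SegregationVerdict(
                "AR_hom", False, required, reason="parent_incompatible"
            )
    return SegregationVerdict("AR_hom", True, required)


def _shared_genotyped_parents(
    ped: PedigreeGraph, affected: set[str], v1: VariantRecord, v2: VariantRecord
) -> tuple[str, ...] | None:
    """Both parents, if shared by all affected and genotyped for both variants."""
    parent_sets = {tuple(sorted(ped.parents(iid))) for iid in affected}
    if len(parent_sets) != 1:
        return None
    parents = parent_sets.pop()
    if len(parents) != 2:
        return None
    for p in parents:
        if v1.allele_count(p) is None or v2.allele_count(p) is None:
            return None
    return parents


def comphet_pairs(
    gene_variants: Iterable[VariantRecord],
    ped: PedigreeGraph,
    affected: set[str],
) -> list[tuple[VariantRecord, VariantRecord, SegregationVerdict]]:
    """Candidate compound-heterozygous pairs among same-gene variants.

    All affected individuals must be heterozygous for both variants. When
    both parents of the affected siblings are genotyped, trans phase is
    required: each parent must carry exactly one variant of the pair. Pairs
    whose phase cannot be established are returned passing with reason
    ``phase_unknown``.
    """
    if not affected:
        raise ValueError("affected set must be non-empty")
    variants = list(gene_variants)
    required = frozenset(affected)
    out = []
    for v1, v2 in combinations(variants, 2):
        if any(
            v.allele_count(iid) != 1 for v in (v1, v2) for iid in affected
        ):
            continue
        parents = _shared_genotyped_parents(ped, affected, v1, v2)
        if parents is None:
            verdict = SegregationVerdict(
                "AR_comphet", True, required, reason="phase_unknown"
            )
        else:
            carried = {
                p: {
                    i
                    for i, v in enumerate((v1, v2))
                    if (v.allele_count(p) or 0) >= 1
                }
                for p in parents
            }
            if any(len(c) > 1 for c in carried.values()):
                verdict = SegregationVerdict(
                    "AR_comphet", False, required, reason="phase_cis_possible"
                )
            elif set().union(*carried.values()) != {0, 1}:
                verdict = SegregationVerdict(
                    "AR_comphet", False, required, reason="parent_incompatible"
                )
            else:
                verdict = SegregationVerdict("AR_comphet", True, required)
        out.append((v1, v2, verdict))
    return out
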