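"""The primary variant filter: QC, repeat masking, rarity, co-segregation,
consequence, deleteriousness and gene-constraint gates, with a per-stage
funnel, plus the ancillary regulatory-variant filter.

Stage order for the dominant branch: QC -> repeat mask -> rarity(AD) ->
AD co-segregation -> consequence -> deleteriousness -> constraint. For
families with two or more affected siblings a recessive branch runs in
parallel with the 1% rarity cutoff and homozygous / compound-heterozygous
genotype models. The rarity, consequence, deleteriousness and constraint
gates are pure per-variant predicates, so their relative order only
affects funnel counts, never the surviving set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

from .annotation import (
    CODING_CLASSES,
    TRUNCATING_CLASSES,
    CaddDistribution,
    GeneEvidence,
    VariantAnnotation,
    VariantKey,
    default_cadd_distribution,
)
from .cosegregation import (
    SegregationVerdict,
    ad_cosegregates,
    ar_hom_cosegregates,
    comphet_pairs,
)
from .pedigree import PedigreeGraph, affected_set, obligate_carriers
from .variant_io import QCThresholds, RepeatMask, VariantRecord, qc_pass

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "RegulatoryConfig",
    "FilterFunnel",
    "Candidate",
    "FamilyFilterResult",
    "rarity_gate",
    "consequence_gate",
    "deleteriousness_gate",
    "constraint_gate",
    "regulatory_gate",
    "run_primary_filter",
]


@dataclass(frozen=True)
class RegulatoryConfig:
    pwm_min: float = 0.75
    cadd_min: float = 7.0
    regdb_rank_max: int = 3
    fathmm_min: float = 0.5


@dataclass(frozen=True)
class FilterConfig:
    maf_dominant: float = 0.001  # < 0.1 %
    maf_recessive: float = 0.01  # < 1 %
    cadd_quartile: float = 0.25
    #: fixed operating threshold; set to None to recompute the class
    #: quartile from the CADD distribution on every run
    cadd_threshold_override: float | None = 24.5
    pli_min: float = 0.9
    oe_max: float = 0.35
    z_min: float = 2.0
    regulatory: RegulatoryConfig = RegulatoryConfig()
    qc: QCThresholds = QCThresholds()
    affection_spectrum: str = "scad_plus_arteriopathy"

    def __post_init__(self) -> None:
        for name in ("maf_dominant", "maf_recessive", "cadd_quartile"):
            val = getattr(self, name)
            if not 0.0 < val < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {val}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        reg = RegulatoryConfig(**raw.pop("regulatory", {}))
        qc = QCThresholds(**raw.pop("qc", {}))
        return cls(regulatory=reg, qc=qc, **raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FunnelStage:
    name: str
    n_in: int
    n_out: int


class FilterFunnel:
    """Ordered per-stage (in, out) variant counts for one branch."""

    def __init__(self, branch: str):
        self.branch = branch
        self.stages: list[FunnelStage] = []

    def record(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: out {n_out} > in {n_in}")
        if self.stages and self.stages[-1].n_out != n_in:
            raise ValueError(f"stage {name}: in {n_in} != previous out")
        self.stages.append(FunnelStage(name, n_in, n_out))

    def stage(self, name: str) -> FunnelStage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def percent_reduction(self, name: str) -> float | None:
        """Percent of variants entering a stage that it removed."""
        s = self.stage(name)
        if s.n_in == 0:
            return None
        return 100.0 * (s.n_in - s.n_out) / s.n_in

    def as_rows(self) -> list[dict]:
        return [
            {"branch": self.branch, "stage": s.name, "in": s.n_in, "out": s.n_out}
            for s in self.stages
        ]


@dataclass(frozen=True)
class Candidate:
    variant_key: VariantKey
    gene_symbol: str
    model: str  # AD | AR_hom | AR_comphet
    verdict: SegregationVerdict
    partner_key: VariantKey | None = None  # comp-het partner


@dataclass
class FamilyFilterResult:
    family_id: str
    candidates: list[Candidate]
    funnels: list[FilterFunnel]
    n_missing_annotation: int = 0

    @property
    def candidate_genes(self) -> set[str]:
        return {c.gene_symbol for c in self.candidates}


# ---------------------------------------------------------------- gates


def rarity_gate(a: VariantAnnotation, model: str, cfg: FilterConfig) -> bool:
    """Population-frequency gate; unreported frequency counts as passing."""
    cutoff = cfg.maf_dominant if model == "AD" else cfg.maf_recessive
    return a.maf is None or a.maf < cutoff


def consequence_gate(a: VariantAnnotation) -> bool:
    """Keep only the six protein-altering consequence classes."""
    return a.consequence in CODING_CLASSES


def deleteriousness_gate(
    a: VariantAnnotation, dist: CaddDistribution, cfg: FilterConfig
) -> bool:
    """Predicted-deleterious gate.

    Loss-of-function classes pass outright. Missense and canonical-splice
    variants must exceed the class lower-quartile CADD threshold or carry
    a curated disease-mutation (HGMD) link.
    """
    if a.consequence in TRUNCATING_CLASSES:
        return True
    if a.hgmd_deleterious:
        return True
    if a.cadd_phred is None:
        return False
    if cfg.cadd_threshold_override is not None:
        threshold = cfg.cadd_threshold_override
    else:
        from .annotation import class_quartile_threshold

        threshold = class_quartile_threshold(dist, a.consequence, cfg.cadd_quartile)
    return a.cadd_phred > threshold


def constraint_gate(
    g: GeneEvidence | None, consequence: str, cfg: FilterConfig
) -> bool:
    """Gene variation-intolerance gate, class-specific.

    Truncating variants require pLI >= 0.9 and/or o/e < 0.35; missense and
    canonical-splice variants require missense Z >= 2. Genes without an
    evidence row fail (conservative).
    """
    if g is None:
        return False
    if consequence in TRUNCATING_CLASSES:
        pli_ok = g.pli is not None and g.pli >= cfg.pli_min
        oe_ok = g.oe_lof is not None and g.oe_lof < cfg.oe_max
        return pli_ok or oe_ok
    return g.mis_z is not None and g.mis_z >= cfg.z_min


def regulatory_gate(
    a: VariantAnnotation, dist: CaddDistribution, cfg: FilterConfig
) -> bool:
    """Ancillary non-coding filter.

    The variant must sit in a miRNA binding/coding site or a transcription
    factor binding site (TFBS with motif PWM score > 0.75), score in the
    regulatory-class CADD upper quartile (>= 7), rank <= 3 in RegulomeDB,
    and be called pathogenic (>= 0.5) by FATHMM-XF.
    """
    r = cfg.regulatory
    if not a.site_context:
        return False
    if "tfbs" in a.site_context and (a.pwm_score is None or a.pwm_score <= r.pwm_min):
        return False
    if a.cadd_phred is None or a.cadd_phred < r.cadd_min:
        return False
    if a.regulomedb_rank is None or a.regulomedb_rank > r.regdb_rank_max:
        return False
    return a.fathmm_xf is not None and a.fathmm_xf >= r.fathmm_min


# ------------------------------------------------------------- cascade


def _affected_siblings(ped: PedigreeGraph, affected: set[str]) -> set[str]:
    """Largest group of affected individuals sharing both recorded parents."""
    groups: dict[tuple[str, ...], set[str]] = {}
    for iid in affected:
        parents = tuple(sorted(ped.parents(iid)))
        if len(parents) == 2:
            groups.setdefault(parents, set()).add(iid)
    best = max(groups.values(), key=len, default=set())
    return best if len(best) >= 2 else set()


def run_primary_filter(
    variants: Iterable[VariantRecord],
    ped: PedigreeGraph,
    annotations: dict[VariantKey, VariantAnnotation],
    gene_evidence: dict[str, GeneEvidence],
    mask: RepeatMask | None = None,
    cfg: FilterConfig = FilterConfig(),
    dist: CaddDistribution | None = None,
    drop_from_required: set[str] | None = None,
) -> FamilyFilterResult:
    """Run the full primary filter for one family.

    ``drop_from_required`` removes specific individuals from the required
    carrier set (used when co-segregation in an ungenotyped relative is
    inferred rather than observed).
    """
    dist = dist or default_cadd_distribution()
    mask = mask or RepeatMask()
    variants = list(variants)

    affected = affected_set(ped, cfg.affection_spectrum)
    if drop_from_required:
        affected = affected - drop_from_required
    obligates = obligate_carriers(ped, affected) if affected else set()
    required = affected | obligates

    funnel_ad = FilterFunnel("AD")
    n_missing_annotation = 0

    # QC: a variant fails for the family if any required member's call fails
    qc_ok = [
        v
        for v in variants
        if all(qc_pass(v.calls.get(iid), v.site_quality, cfg.qc) for iid in required)
    ]
    funnel_ad.record("qc", len(variants), len(qc_ok))

    unmasked = [v for v in qc_ok if not mask.contains(v.chrom, v.pos)]
    funnel_ad.record("repeat_mask", len(qc_ok), len(unmasked))

    def annotated(v: VariantRecord) -> VariantAnnotation | None:
        a = annotations.get(v.key)
        if a is None:
            logger.warning("no annotation for %s; dropped", v.key)
        return a

    def downstream_gates(
        branch: list[VariantRecord], funnel: FilterFunnel
    ) -> list[VariantRecord]:
        survivors = [v for v in branch if consequence_gate(annotations[v.key])]
        funnel.record("consequence", len(branch), len(survivors))
        prev, survivors = survivors, [
            v
            for v in survivors
            if deleteriousness_gate(annotations[v.key], dist, cfg)
        ]
        funnel.record("deleteriousness", len(prev), len(survivors))
        prev, survivors = survivors, [
            v
            for v in survivors
            if constraint_gate(
                gene_evidence.get(annotations[v.key].gene_symbol),
                annotations[v.key].consequence,
                cfg,
            )
        ]
        funnel.record("constraint", len(prev), len(survivors))
        return survivors

    # -- dominant branch
    rare_ad = []
    for v in unmasked:
        a = annotated(v)
        if a is None:
            n_missing_annotation += 1
        elif rarity_gate(a, "AD", cfg):
            rare_ad.append(v)
    funnel_ad.record("rarity_AD", len(unmasked), len(rare_ad))

    ad_pass = [
        v
        for v in rare_ad
        if ad_cosegregates(v, ped, affected, obligates).passes
    ]
    funnel_ad.record("ad_cosegregation", len(rare_ad), len(ad_pass))

    ad_final = downstream_gates(ad_pass, funnel_ad)
    candidates = [
        Candidate(
            v.key,
            annotations[v.key].gene_symbol,
            "AD",
            ad_cosegregates(v, ped, affected, obligates),
        )
        for v in ad_final
    ]
    funnels = [funnel_ad]

    # -- recessive branch (multi-sibling families only)
    siblings = _affected_siblings(ped, affected)
    if siblings:
        funnel_ar = FilterFunnel("AR")
        funnel_ar.record("qc", len(variants), len(qc_ok))
        funnel_ar.record("repeat_mask", len(qc_ok), len(unmasked))
        rare_ar = [
            v
            for v in unmasked
            if v.key in annotations and rarity_gate(annotations[v.key], "AR", cfg)
        ]
        funnel_ar.record("rarity_AR", len(unmasked), len(rare_ar))

        hom_pass = {
            v.key: v
            for v in rare_ar
            if ar_hom_cosegregates(v, ped, siblings).passes
        }
        by_gene: dict[str, list[VariantRecord]] = {}
        for v in rare_ar:
            by_gene.setdefault(annotations[v.key].gene_symbol, []).append(v)
        comphet_keys: dict[VariantKey, tuple[VariantKey, SegregationVerdict]] = {}
        for gene_vars in by_gene.values():
            for v1, v2, verdict in comphet_pairs(gene_vars, ped, siblings):
                if verdict.passes:
                    comphet_keys[v1.key] = (v2.key, verdict)
                    comphet_keys[v2.key] = (v1.key, verdict)
        ar_pass = [v for v in rare_ar if v.key in hom_pass or v.key in comphet_keys]
        funnel_ar.record("ar_cosegregation", len(rare_ar), len(ar_pass))

        ar_final = downstream_gates(ar_pass, funnel_ar)
        final_keys = {v.key for v in ar_final}
        for v in ar_final:
            if v.key in hom_pass:
                candidates.append(
                    Candidate(
                        v.key,
                        annotations[v.key].gene_symbol,
                        "AR_hom",
                        ar_hom_cosegregates(v, ped, siblings),
                    )
                )
            if v.key in comphet_keys:
                partner, verdict = comphet_keys[v.key]
                if partner in final_keys:  # both pair members must survive
                    candidates.append(
                        Candidate(
                            v.key,
                            annotations[v.key].gene_symbol,
                            "AR_comphet",
                            verdict,
                            partner_key=partner,
                        )
                    )
        funnels.append(funnel_ar)

    return FamilyFilterResult(
        family_id=ped.family_id,
        candidates=candidates,
        funnels=funnels,
        n_missing_annotation=n_missing_annotation,
    )
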