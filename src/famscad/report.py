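"""Assemble per-family candidate reports: filter funnels, secondary scores
and top candidate genes, serialized to JSON and TSV."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .annotation import GeneEvidence
from .filter_cascade import FamilyFilterResult
from .prioritization import (
    PRIOR_SCAD_GENES,
    InteractionNetwork,
    SecondaryScore,
    network_degree,
    secondary_score,
    select_top,
    shared_gene_flag,
)

__all__ = ["FamilyReport", "CandidateReport", "build_report"]


@dataclass
class FamilyReport:
    family_id: str
    filter_result: FamilyFilterResult
    scores: dict[str, SecondaryScore]
    top_candidates: set[str]

    @property
    def cosegregation_reduction_pct(self) -> float | None:
        """Percent of rare variants removed by the co-segregation stage."""
        for funnel in self.filter_result.funnels:
            if funnel.branch == "AD":
                return funnel.percent_reduction("ad_cosegregation")
        return None


@dataclass
class CandidateReport:
    families: dict[str, FamilyReport] = field(default_factory=dict)

    def consistency_audit(self, printed: dict[str, str]) -> dict[str, bool]:
        """For each family, does the given gene attain the family-maximal
        secondary score? (Audit of published per-family assignments.)"""
        out = {}
        for fam, gene in printed.items():
            rep = self.families.get(fam)
            out[fam] = rep is not None and gene in rep.top_candidates
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {}
        for fam, rep in sorted(self.families.items()):
            payload[fam] = {
                "funnel": [
                    row for f in rep.filter_result.funnels for row in f.as_rows()
                ],
                "candidates": [
                    {
                        "variant": list(c.variant_key),
                        "gene": c.gene_symbol,
                        "model": c.model,
                        "passes": c.verdict.passes,
                        "reason": c.verdict.reason,
                        "partner": list(c.partner_key) if c.partner_key else None,
                    }
                    for c in rep.filter_result.candidates
                ],
                "scores": {
                    g: {"score": s.score, "flags": s.flags}
                    for g, s in sorted(rep.scores.items())
                },
                "top_candidates": sorted(rep.top_candidates),
                "cosegregation_reduction_pct": rep.cosegregation_reduction_pct,
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def candidates_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("family\tgene\tvariant\tmodel\tscore\tflags\ttop_candidate\n")
            for fam, rep in sorted(self.families.items()):
                for c in rep.filter_result.candidates:
                    s = rep.scores[c.gene_symbol]
                    chrom, pos, ref, alt = c.variant_key
                    flags = ",".join(k for k, v in s.flags.items() if v) or "."
                    fh.write(
                        f"{fam}\t{c.gene_symbol}\t{chrom}:{pos}:{ref}:{alt}\t"
                        f"{c.model}\t{s.score}\t{flags}\t"
                        f"{c.gene_symbol in rep.top_candidates}\n"
                    )

    def funnel_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("family\tbranch\tstage\tin\tout\n")
            for fam, rep in sorted(self.families.items()):
                for funnel in rep.filter_result.funnels:
                    for row in funnel.as_rows():
                        fh.write(
                            f"{fam}\t{row['branch']}\t{row['stage']}\t"
                            f"{row['in']}\t{row['out']}\n"
                        )


def build_report(
    family_results: list[FamilyFilterResult],
    gene_evidence: dict[str, GeneEvidence],
    network: InteractionNetwork | None = None,
    seeds: set[str] | None = None,
    conf_min: float = 0.7,
) -> CandidateReport:
    """Score every family's surviving genes and select top candidates.

    The shared-gene flag is computed across all supplied families. The
    protein-interaction flag uses ``network`` (degree <= 2 to the seed
    genes at the confidence threshold) when given, otherwise the recorded
    per-gene association sets.
    """
    seeds = set(seeds) if seeds is not None else set(PRIOR_SCAD_GENES)
    per_family_genes = {r.family_id: r.candidate_genes for r in family_results}

    report = CandidateReport()
    for result in family_results:
        scores: dict[str, SecondaryScore] = {}
        for gene in sorted(result.candidate_genes):
            evidence = gene_evidence.get(gene, GeneEvidence(gene_symbol=gene))
            if network is not None:
                # degree 0 encodes "queried the network, no association",
                # so the recorded-evidence fallback is not taken
                degree = network_degree(network, gene, seeds, conf_min=conf_min) or 0
            else:
                degree = None
            scores[gene] = secondary_score(
                evidence,
                shared=shared_gene_flag(gene, per_family_genes),
                ppi_degree=degree,
            )
        report.families[result.family_id] = FamilyReport(
            family_id=result.family_id,
            filter_result=result,
            scores=scores,
            top_candidates=select_top(scores.values()),
        )
    return report
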