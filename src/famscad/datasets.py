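"""Packaged study fixtures.

Two small text tables ship with the package: the familial SCAD cohort
roster (demographics, clinical features, event ages, approximate pedigree
topology for the distantly-related families) and the twelve prioritized
candidate variants with their per-variant annotations and per-gene
secondary evidence. Genomic coordinates in the variant table are synthetic
placeholders on each gene's true chromosome; the study published no
machine-readable coordinates.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .annotation import (
    GeneEvidence,
    VariantAnnotation,
    VariantKey,
    load_annotations,
    load_gene_evidence,
)
from .pedigree import Individual, PedigreeGraph, parse_pedigree
from .variant_io import GenotypeCall, VariantRecord

__all__ = [
    "load_cohort_pedigrees",
    "load_cohort_individuals",
    "load_candidate_annotations",
    "load_candidate_gene_evidence",
    "candidate_family_assignments",
    "cosegregating_family_records",
]

#: family in which each prioritized variant was identified
CANDIDATE_FAMILIES: dict[VariantKey, str] = {
    ("chr2", 169127394, "T", "A"): "SCAD-01",  # LRP2
    ("chr2", 26524783, "CCGCGCGCTGCTCAC", "C"): "SCAD-02",  # KCNK3
    ("chr13", 110424391, "C", "T"): "SCAD-03",  # COL4A1
    ("chr15", 90981842, "A", "G"): "SCAD-04",  # IQGAP1
    ("chr7", 100804815, "G", "A"): "SCAD-05",  # EPHB4
    ("chr20", 61851254, "T", "C"): "SCAD-06",  # CDH4
    ("chr13", 110512122, "G", "A"): "SCAD-07",  # COL4A2 G151S
    ("chr2", 188994187, "C", "T"): "SCAD-09",  # COL3A1
    ("chr3", 41224610, "A", "G"): "SCAD-12",  # CTNNB1
    ("chr9", 136505484, "C", "T"): "SCAD-13",  # NOTCH1
    ("chr13", 110560855, "G", "A"): "SCAD-14",  # COL4A2 G413R
    ("chr2", 189134501, "A", "C"): "SCAD-15",  # COL5A2
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("famscad").joinpath("data", name)))


def load_cohort_pedigrees() -> list[PedigreeGraph]:
    """The 15 familial SCAD pedigrees (inferred connecting relatives included)."""
    return parse_pedigree(_data_path("cohort_roster.ped"))


def load_cohort_individuals() -> list[Individual]:
    """All cohort members as a flat list."""
    return [
        ind for ped in load_cohort_pedigrees() for ind in ped.members.values()
    ]


def load_candidate_annotations() -> dict[VariantKey, VariantAnnotation]:
    """Per-variant annotations for the 12 prioritized candidate variants."""
    return load_annotations(_data_path("candidate_variants.tsv"))


def load_candidate_gene_evidence() -> dict[str, GeneEvidence]:
    """Per-gene constraint and secondary evidence for the 11 candidate genes."""
    return load_gene_evidence(_data_path("candidate_gene_evidence.tsv"))


def candidate_family_assignments() -> dict[str, set[str]]:
    """family -> set of candidate gene symbols, per the published assignments."""
    annotations = load_candidate_annotations()
    out: dict[str, set[str]] = {}
    for key, fam in CANDIDATE_FAMILIES.items():
        out.setdefault(fam, set()).add(annotations[key].gene_symbol)
    return out


def cosegregating_family_records(
    qc: tuple[float, int, float] = (99.0, 50, 100.0),
) -> tuple[PedigreeGraph, list[VariantRecord]]:
    """A synthetic one-family genotype set in which every candidate variant
    co-segregates: two affected sisters heterozygous for all 12 variants,
    a heterozygous unaffected mother (the transmitting carrier) and a
    non-carrier father. ``qc`` gives (GQ, DP, site QUAL)."""
    gq, dp, qual = qc
    members = [
        Individual("I.1", "SYN-01", None, None, "male", "unaffected"),
        Individual("I.2", "SYN-01", None, None, "female", "unaffected"),
        Individual("II.1", "SYN-01", "I.1", "I.2", "female", "scad"),
        Individual("II.2", "SYN-01", "I.1", "I.2", "female", "scad"),
    ]
    ped = PedigreeGraph("SYN-01", members)
    counts = {"I.1": 0, "I.2": 1, "II.1": 1, "II.2": 1}
    records = []
    for chrom, pos, ref, alt in sorted(load_candidate_annotations()):
        calls = {
            iid: GenotypeCall(iid, ac, genotype_quality=gq, read_depth=dp)
            for iid, ac in counts.items()
        }
        records.append(VariantRecord(chrom, pos, ref, alt, qual, calls))
    return ped, records
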