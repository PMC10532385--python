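from __future__ import annotations

import numpy as np
import pytest

from famscad import datasets
from famscad.pedigree import Individual, PedigreeGraph
from famscad.variant_io import GenotypeCall, VariantRecord


def make_variant(
    counts: dict[str, int | None],
    chrom: str = "chr1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "G",
    gq: float = 99.0,
    dp: int = 50,
    qual: float = 100.0,
) -> VariantRecord:
    calls = {
        iid: GenotypeCall(iid, ac, genotype_quality=gq, read_depth=dp)
        for iid, ac in counts.items()
    }
    return VariantRecord(chrom, pos, ref, alt, qual, calls)


def make_family(
    rows: list[tuple[str, str | None, str | None, str]],
    family_id: str = "FAM",
) -> PedigreeGraph:
    """rows: (individual_id, father, mother, affection)"""
    return PedigreeGraph(
        family_id,
        [
            Individual(iid, family_id, father, mother, "unknown", affection)
            for iid, father, mother, affection in rows
        ],
    )


def random_outbred_pedigree(
    rng: np.random.Generator, n_members: int, n_affected: int
) -> tuple[PedigreeGraph, set[str]]:
    """Random loop-free pedigree: each non-founder has one existing parent
    and one married-in founder. Affected individuals are sampled from the
    descendants-or-self of the first founder so a common origin exists."""
    rows: list[tuple[str, str | None, str | None, str]] = [("P0", None, None)]
    lineage = {"P0"}  # descendants-or-self of P0
    i = 1
    while i < n_members:
        parent = f"P{int(rng.integers(len(rows)))}"
        spouse = f"P{i}"
        rows.append((spouse, None, None))
        i += 1
        if i >= n_members:
            break
        child = f"P{i}"
        rows.append((child, spouse, parent))
        if parent in lineage:
            lineage.add(child)
        i += 1
    candidates = sorted(lineage)
    k = min(n_affected, len(candidates))
    affected = set(rng.choice(candidates, size=k, replace=False))
    ped = make_family(
        [
            (iid, f, m, "scad" if iid in affected else "unaffected")
            for iid, f, m in rows
        ]
    )
    return ped, affected


@pytest.fixture(scope="session")
def candidate_annotations():
    return datasets.load_candidate_annotations()


@pytest.fixture(scope="session")
def candidate_evidence():
    return datasets.load_candidate_gene_evidence()


@pytest.fixture(scope="session")
def cohort_pedigrees():
    return datasets.load_cohort_pedigrees()


@pytest.fixture()
def cousin_pedigree() -> PedigreeGraph:
    """Two affected first cousins linked through unaffected siblings."""
    return make_family(
        [
            ("GP1", None, None, "unaffected"),
            ("GP2", None, None, "unaffected"),
            ("A1", "GP1", "GP2", "unaffected"),
            ("A1s", None, None, "unaffected"),
            ("A2", "GP1", "GP2", "unaffected"),
            ("A2s", None, None, "unaffected"),
            ("C1", "A1s", "A1", "scad"),
            ("C2", "A2s", "A2", "scad"),
        ]
    )
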