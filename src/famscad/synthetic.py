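"""Seedable synthetic cohorts: pedigrees, genotypes with planted causal
variants, background variation, annotation/evidence tables and a small
interaction network, in the same file formats the pipeline consumes.

The generator emulates the study design: small families ascertained
through affected relatives (sister pairs, sibling trios, mother-daughter
pairs, first-cousin pairs), a dominant or recessive causal variant planted
so that it is carried by every affected-spectrum member and obligate
carrier, and background variants gene-dropped from founder genotypes drawn
at Hardy-Weinberg frequencies. A truth table records the planted keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pedigree import Individual, PedigreeGraph, affected_set, obligate_carriers
from .variant_io import GenotypeCall, VariantRecord, write_variants

__all__ = [
    "SimConfig",
    "SimBundle",
    "FAMILY_TEMPLATES",
    "build_template_family",
    "mendelian_drop",
    "simulate_cohort",
]

#: template name -> rows of (individual_id, father, mother, sex, affection)
FAMILY_TEMPLATES: dict[str, list[tuple[str, str | None, str | None, str, str]]] = {
    "sister_pair": [
        ("I.1", None, None, "male", "unaffected"),
        ("I.2", None, None, "female", "unaffected"),
        ("II.1", "I.1", "I.2", "female", "scad"),
        ("II.2", "I.1", "I.2", "female", "scad"),
    ],
    "sibling_trio": [
        ("I.1", None, None, "male", "unaffected"),
        ("I.2", None, None, "female", "unaffected"),
        ("II.1", "I.1", "I.2", "female", "scad"),
        ("II.2", "I.1", "I.2", "male", "scad"),
        ("II.3", "I.1", "I.2", "male", "arteriopathy"),
    ],
    "mother_daughter": [
        ("I.1", None, None, "male", "unaffected"),
        ("I.2", None, None, "female", "scad"),
        ("II.1", "I.1", "I.2", "female", "scad"),
    ],
    "cousin_pair": [
        ("I.1", None, None, "male", "unaffected"),
        ("I.2", None, None, "female", "unaffected"),
        ("II.1", "I.1", "I.2", "female", "unaffected"),
        ("II.1s", None, None, "male", "unaffected"),
        ("II.2", "I.1", "I.2", "female", "unaffected"),
        ("II.2s", None, None, "male", "unaffected"),
        ("III.1", "II.1s", "II.1", "female", "scad"),
        ("III.2", "II.2s", "II.2", "female", "scad"),
    ],
}

_AFF_CODE = {"unknown": "0", "unaffected": "1", "scad": "2", "arteriopathy": "3"}
_SEX_CODE = {"unknown": "0", "male": "1", "female": "2"}


@dataclass(frozen=True)
class SimConfig:
    n_families: int = 6
    family_templates: tuple[str, ...] = ("sister_pair",)  # cycled over families
    planted_model: str = "AD"  # AD | AR_hom | AR_comphet | none
    penetrance: float = 1.0
    n_background_variants: int = 500
    #: Beta shape parameters for background founder allele frequencies,
    #: truncated to (0, maf_max]
    background_maf_beta: tuple[float, float] = (0.2, 20.0)
    maf_max: float = 0.05
    qc_noise: float = 0.0  # per-call probability of a sub-threshold GQ/DP
    seed: int = 0
    #: secondary-evidence flags granted to the planted genes
    planted_gene_evidence: tuple[str, ...] = (
        "ppi_talin1",
        "mgi",
        "hgmd_vasc",
        "gwas_trait",
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.penetrance <= 1.0:
            raise ValueError("penetrance must be in (0, 1]")
        if self.n_background_variants < 0:
            raise ValueError("n_background_variants must be >= 0")
        for t in self.family_templates:
            if t not in FAMILY_TEMPLATES:
                raise ValueError(f"unknown family template {t!r}")
        if self.planted_model not in ("AD", "AR_hom", "AR_comphet", "none"):
            raise ValueError(f"unknown planted model {self.planted_model!r}")
        if self.planted_model in ("AR_hom", "AR_comphet"):
            bad = [
                t
                for t in self.family_templates
                if t not in ("sister_pair", "sibling_trio")
            ]
            if bad:
                raise ValueError(
                    f"recessive planting needs genotyped-parent sibships; "
                    f"templates {bad} unsupported"
                )


@dataclass
class SimBundle:
    vcf: Path
    pedigree: Path
    annotations: Path
    gene_evidence: Path
    network: Path
    truth_table: Path
    pedigrees: list[PedigreeGraph] = field(default_factory=list)
    #: (chrom, pos, ref, alt, family_id, model) for each planted variant
    planted: list[tuple] = field(default_factory=list)

    def paths(self) -> list[Path]:
        return [
            self.vcf,
            self.pedigree,
            self.annotations,
            self.gene_evidence,
            self.network,
            self.truth_table,
        ]


def build_template_family(family_id: str, template: str) -> PedigreeGraph:
    members = [
        Individual(
            individual_id=f"{family_id}_{iid}",
            family_id=family_id,
            father_id=None if father is None else f"{family_id}_{father}",
            mother_id=None if mother is None else f"{family_id}_{mother}",
            sex=sex,
            affection=affection,
        )
        for iid, father, mother, sex, affection in FAMILY_TEMPLATES[template]
    ]
    return PedigreeGraph(family_id, members)


def mendelian_drop(
    ped: PedigreeGraph, founder_freq: float, rng: np.random.Generator
) -> dict[str, int]:
    """Gene-drop a biallelic variant through one family.

    Founders are drawn at Hardy-Weinberg equilibrium at ``founder_freq``;
    each child inherits one allele chosen uniformly from each parent. An
    unrecorded parent contributes a population-frequency allele.
    """
    if not 0.0 <= founder_freq <= 1.0:
        raise ValueError("founder_freq must be in [0, 1]")
    alleles: dict[str, tuple[int, int]] = {}

    def resolve(iid: str) -> tuple[int, int]:
        if iid in alleles:
            return alleles[iid]
        ind = ped.members[iid]
        pair = []
        for pid in (ind.father_id, ind.mother_id):
            if pid is None:
                pair.append(int(rng.random() < founder_freq))
            else:
                parental = resolve(pid)
                pair.append(parental[int(rng.integers(2))])
        alleles[iid] = (pair[0], pair[1])
        return alleles[iid]

    return {iid: sum(resolve(iid)) for iid in sorted(ped.members)}


def _transmission_path(ped: PedigreeGraph, origin: str, targets: set[str]) -> set[str]:
    """Vertices of parent->child paths from origin to each target (BFS)."""
    carriers = {origin}
    for t in targets:
        # walk up from target to origin through ancestors reachable from origin
        chain = _ancestor_chain(ped, origin, t)
        if chain is None:
            raise ValueError(f"{origin} cannot transmit to {t}")
        carriers.update(chain)
    return carriers


def _ancestor_chain(ped: PedigreeGraph, origin: str, target: str) -> set[str] | None:
    if target == origin:
        return {target}
    for pid in ped.parents(target):
        chain = _ancestor_chain(ped, origin, pid)
        if chain is not None:
            return chain | {target}
    return None


def _plant_ad(
    ped: PedigreeGraph, cfg: SimConfig, rng: np.random.Generator
) -> dict[str, int]:
    """Heterozygous in all affected-spectrum members and obligate carriers,
    transmitted along a single-founder path; with penetrance < 1, other
    descendants of carriers may inherit (unaffected carriers)."""
    affected = affected_set(ped, "scad_plus_arteriopathy")
    obligates = obligate_carriers(ped, affected)
    targets = affected | obligates
    origins = [
        f
        for f in sorted(ped.founders())
        if all(_ancestor_chain(ped, f, t) is not None for t in targets)
    ]
    origin = origins[int(rng.integers(len(origins)))]
    carriers = _transmission_path(ped, origin, targets)
    counts = {iid: (1 if iid in carriers else 0) for iid in sorted(ped.members)}
    if cfg.penetrance < 1.0:
        # Mendelian transmission to unaffected relatives off the forced path
        for iid in sorted(ped.members):
            if counts[iid] == 0 and any(
                counts.get(p, 0) >= 1 for p in ped.parents(iid)
            ):
                if ped.members[iid].affection in ("unaffected", "unknown"):
                    counts[iid] = int(rng.random() < 0.5)
    return counts


def _plant_ar_hom(ped: PedigreeGraph) -> dict[str, int]:
    affected = affected_set(ped, "scad_plus_arteriopathy")
    counts = {}
    for iid in sorted(ped.members):
        if iid in affected:
            counts[iid] = 2
        elif ped.children(iid):  # template parents
            counts[iid] = 1
        else:
            counts[iid] = 0
    return counts


def _calls(
    counts: dict[str, int],
    rng: np.random.Generator,
    qc_noise: float,
) -> dict[str, GenotypeCall]:
    out = {}
    for iid, ac in counts.items():
        gq = int(rng.integers(60, 100))
        dp = int(rng.integers(20, 61))
        if qc_noise > 0 and rng.random() < qc_noise:
            if rng.random() < 0.5:
                gq = int(rng.integers(0, 30))
            else:
                dp = int(rng.integers(0, 10))
        out[iid] = GenotypeCall(iid, ac, genotype_quality=gq, read_depth=dp)
    return out


def _trunc_beta(
    rng: np.random.Generator, a: float, b: float, upper: float
) -> float:
    for _ in range(1000):
        x = float(rng.beta(a, b))
        if 0.0 < x <= upper:
            return x
    return upper / 2.0


def simulate_cohort(cfg: SimConfig, out_dir: str | Path) -> SimBundle:
    """Generate a complete input bundle under ``out_dir``.

    Identical configurations (including seed) produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    templates = cfg.family_templates
    pedigrees = [
        build_template_family(f"FAM{i + 1:02d}", templates[i % len(templates)])
        for i in range(cfg.n_families)
    ]
    samples = [iid for ped in pedigrees for iid in sorted(ped.members)]

    records: list[VariantRecord] = []
    ann_rows: list[dict] = []
    gene_rows: list[dict] = []
    truth_rows: list[dict] = []
    planted: list[tuple] = []

    chroms = [f"chr{c}" for c in range(1, 23)]
    next_pos = {c: 10_000 for c in chroms}

    def place(idx: int) -> tuple[str, int]:
        chrom = chroms[idx % len(chroms)]
        next_pos[chrom] += int(rng.integers(500, 5000))
        return chrom, next_pos[chrom]

    consequences = np.array(
        ["missense", "other", "frameshift", "canonical_splice", "stop_gain", "regulatory"]
    )
    consequence_p = np.array([0.45, 0.30, 0.05, 0.05, 0.05, 0.10])

    # ---- planted causal variants, one gene per family
    if cfg.planted_model != "none":
        for fam_i, ped in enumerate(pedigrees):
            gene = f"PLANT{fam_i + 1:02d}"
            chrom, pos = place(fam_i)
            if cfg.planted_model == "AD":
                variant_counts = [("T", "C", _plant_ad(ped, cfg, rng))]
            elif cfg.planted_model == "AR_hom":
                variant_counts = [("T", "C", _plant_ar_hom(ped))]
            else:  # AR_comphet: two variants, one from each parent
                affected = affected_set(ped, "scad_plus_arteriopathy")
                father, mother = (f"{ped.family_id}_I.1", f"{ped.family_id}_I.2")
                c1 = {
                    iid: (1 if iid in affected or iid == father else 0)
                    for iid in sorted(ped.members)
                }
                c2 = {
                    iid: (1 if iid in affected or iid == mother else 0)
                    for iid in sorted(ped.members)
                }
                variant_counts = [("T", "C", c1), ("G", "A", c2)]
            for v_i, (ref, alt, counts) in enumerate(variant_counts):
                vpos = pos + v_i * 100
                calls = {s: GenotypeCall(s, 0, 90, 40) for s in samples}
                calls.update(_calls(counts, rng, qc_noise=0.0))
                records.append(
                    VariantRecord(chrom, vpos, ref, alt, site_quality=80.0, calls=calls)
                )
                ann_rows.append(
                    {
                        "chrom": chrom,
                        "pos": vpos,
                        "ref": ref,
                        "alt": alt,
                        "gene": gene,
                        "consequence": "missense",
                        "maf": "0.00001",
                        "cadd_phred": "32.0",
                        "hgmd": ".",
                        "fathmm_xf": ".",
                        "regdb_rank": ".",
                        "pwm": ".",
                        "site_context": ".",
                    }
                )
                truth_rows.append(
                    {
                        "chrom": chrom,
                        "pos": vpos,
                        "ref": ref,
                        "alt": alt,
                        "family": ped.family_id,
                        "model": cfg.planted_model,
                        "is_planted": 1,
                    }
                )
                planted.append((chrom, vpos, ref, alt, ped.family_id, cfg.planted_model))
            flags = cfg.planted_gene_evidence
            gene_rows.append(
                {
                    "gene": gene,
                    "pli": "0.95",
                    "oe_lof": "0.1",
                    "mis_z": "3.5",
                    "rank_coronary": 3,
                    "rank_aorta": 4,
                    "rank_tibial": 5,
                    "ctd_aor_panel": int("ctd_aor_panel" in flags),
                    "mgi": int("mgi" in flags),
                    "hgmd_vasc": int("hgmd_vasc" in flags),
                    "gwas_trait": int("gwas_trait" in flags),
                    "ppi_talin1": int("ppi_talin1" in flags),
                    "ppi_gwas": int("ppi_gwas" in flags),
                }
            )

    # ---- background variants under the site-frequency model; like a real
    # multi-sample VCF, only sites actually carried by someone are emitted,
    # so drops are rejection-sampled until a cohort member has the allele
    a, b = cfg.background_maf_beta
    for i in range(cfg.n_background_variants):
        gene = f"GENE{i + 1:04d}"
        chrom, pos = place(cfg.n_families + i)
        freq = _trunc_beta(rng, a, b, cfg.maf_max)
        all_counts: dict[str, int] = {}
        if pedigrees:
            for _ in range(10_000):
                freq = _trunc_beta(rng, a, b, cfg.maf_max)
                all_counts = {}
                for ped in pedigrees:
                    all_counts.update(mendelian_drop(ped, freq, rng))
                if any(all_counts.values()):
                    break
        calls: dict[str, GenotypeCall] = {}
        for ped in pedigrees:
            counts = {iid: all_counts[iid] for iid in sorted(ped.members)}
            calls.update(_calls(counts, rng, cfg.qc_noise))
        consequence = str(rng.choice(consequences, p=consequence_p))
        cadd = round(float(rng.uniform(0.5, 48.0)), 1)
        records.append(
            VariantRecord(chrom, pos, "A", "G", site_quality=70.0, calls=calls)
        )
        is_reg = consequence == "regulatory"
        ann_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": "A",
                "alt": "G",
                "gene": gene,
                "consequence": consequence,
                "maf": f"{freq:.6f}",
                "cadd_phred": f"{cadd}",
                "hgmd": ".",
                "fathmm_xf": f"{rng.uniform():.2f}" if is_reg else ".",
                "regdb_rank": int(rng.integers(1, 8)) if is_reg else ".",
                "pwm": f"{rng.uniform():.2f}" if is_reg else ".",
                "site_context": "tfbs" if is_reg else ".",
            }
        )
        truth_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": "A",
                "alt": "G",
                "family": ".",
                "model": ".",
                "is_planted": 0,
            }
        )
        gene_rows.append(
            {
                "gene": gene,
                "pli": f"{rng.uniform():.2f}",
                "oe_lof": f"{rng.uniform(0.05, 1.5):.2f}",
                "mis_z": f"{rng.normal(0.0, 1.0):.2f}",
                "rank_coronary": int(rng.integers(1, 55)),
                "rank_aorta": int(rng.integers(1, 55)),
                "rank_tibial": int(rng.integers(1, 55)),
                "ctd_aor_panel": int(rng.random() < 0.02),
                "mgi": int(rng.random() < 0.1),
                "hgmd_vasc": int(rng.random() < 0.05),
                "gwas_trait": int(rng.random() < 0.1),
                "ppi_talin1": int(rng.random() < 0.05),
                "ppi_gwas": int(rng.random() < 0.05),
            }
        )

    records.sort(key=lambda r: (chroms.index(r.chrom), r.pos, r.alt))

    bundle = SimBundle(
        vcf=out_dir / "cohort.vcf",
        pedigree=out_dir / "cohort.ped",
        annotations=out_dir / "annotations.tsv",
        gene_evidence=out_dir / "gene_evidence.tsv",
        network=out_dir / "network.tsv",
        truth_table=out_dir / "truth_table.tsv",
        pedigrees=pedigrees,
        planted=planted,
    )

    contigs = "".join(f"##contig=<ID={c}>\n" for c in chroms)
    write_variants(records, bundle.vcf, samples, extra_header=contigs)

    with open(bundle.pedigree, "w") as fh:
        for ped in pedigrees:
            for iid in sorted(ped.members):
                ind = ped.members[iid]
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            ind.individual_id,
                            ind.father_id or "0",
                            ind.mother_id or "0",
                            _SEX_CODE[ind.sex],
                            _AFF_CODE[ind.affection],
                        ]
                    )
                    + "\n"
                )

    import pandas as pd

    pd.DataFrame(
        ann_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "consequence", "maf",
            "cadd_phred", "hgmd", "fathmm_xf", "regdb_rank", "pwm", "site_context",
        ],
    ).to_csv(bundle.annotations, sep="\t", index=False)
    pd.DataFrame(
        gene_rows,
        columns=[
            "gene", "pli", "oe_lof", "mis_z", "rank_coronary", "rank_aorta",
            "rank_tibial", "ctd_aor_panel", "mgi", "hgmd_vasc", "gwas_trait",
            "ppi_talin1", "ppi_gwas",
        ],
    ).to_csv(bundle.gene_evidence, sep="\t", index=False)
    pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "family", "model", "is_planted"],
    ).to_csv(bundle.truth_table, sep="\t", index=False)

    # small interaction network: planted genes wired to the talin-1 seed
    with open(bundle.network, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for fam_i in range(cfg.n_families if cfg.planted_model != "none" else 0):
            fh.write(f"PLANT{fam_i + 1:02d}\tTLN1\t900\n")
        fh.write("TLN1\tFBN1\t850\n")
        fh.write("FBN1\tLRP1\t750\n")

    return bundle
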