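"""Synthetic cohort generation: determinism, Mendelian consistency,
gene-dropping statistics, and pipeline recovery of planted variants."""

from __future__ import annotations

import hashlib

import numpy as np
import pytest

from famscad.annotation import load_annotations, load_gene_evidence
from famscad.filter_cascade import run_primary_filter
from famscad.pedigree import parse_pedigree
from famscad.synthetic import (
    FAMILY_TEMPLATES,
    SimConfig,
    build_template_family,
    mendelian_drop,
    simulate_cohort,
)
from famscad.variant_io import read_variants

from oracles import mendelian_consistent


def digest(path):
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_bundle(bundle):
    """Run the primary filter on every family of a simulated bundle."""
    annotations = load_annotations(bundle.annotations)
    evidence = load_gene_evidence(bundle.gene_evidence)
    results = {}
    for ped in parse_pedigree(bundle.pedigree):
        variants = list(read_variants(bundle.vcf, samples=set(ped.members)))
        results[ped.family_id] = run_primary_filter(
            variants, ped, annotations, evidence
        )
    return results


class TestMendelianDrop:
    def test_frequency_zero_gives_all_reference(self):
        ped = build_template_family("F", "sibling_trio")
        counts = mendelian_drop(ped, 0.0, np.random.default_rng(0))
        assert set(counts.values()) == {0}

    def test_frequency_one_gives_all_homozygous(self):
        ped = build_template_family("F", "cousin_pair")
        counts = mendelian_drop(ped, 1.0, np.random.default_rng(0))
        assert set(counts.values()) == {2}

    def test_child_allele_frequency_matches_founder_frequency(self):
        # 10,000 replicates on a trio: child alt frequency 0.5 +- 0.01
        ped = build_template_family("F", "mother_daughter")
        rng = np.random.default_rng(42)
        total = sum(
            mendelian_drop(ped, 0.5, rng)["F_II.1"] for _ in range(10_000)
        )
        assert total / 20_000 == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("template", sorted(FAMILY_TEMPLATES))
    def test_drops_are_mendelian_consistent(self, template):
        ped = build_template_family("F", template)
        rng = np.random.default_rng(1)
        for _ in range(200):
            counts = mendelian_drop(ped, 0.3, rng)
            assert mendelian_consistent(ped, counts)


class TestSimulateCohort:
    def test_identical_seeds_give_byte_identical_bundles(self, tmp_path):
        cfg = SimConfig(n_families=2, n_background_variants=50, seed=7)
        b1 = simulate_cohort(cfg, tmp_path / "a")
        b2 = simulate_cohort(cfg, tmp_path / "b")
        assert [digest(p) for p in b1.paths()] == [digest(p) for p in b2.paths()]

    def test_different_seeds_differ(self, tmp_path):
        b1 = simulate_cohort(SimConfig(n_families=1, n_background_variants=50, seed=1), tmp_path / "a")
        b2 = simulate_cohort(SimConfig(n_families=1, n_background_variants=50, seed=2), tmp_path / "b")
        assert digest(b1.vcf) != digest(b2.vcf)

    def test_empty_cohort_has_valid_header_and_empty_truth(self, tmp_path):
        cfg = SimConfig(n_families=0, n_background_variants=0, seed=0)
        bundle = simulate_cohort(cfg, tmp_path)
        assert bundle.vcf.read_text().startswith("##fileformat=VCFv4.2")
        truth_lines = bundle.truth_table.read_text().strip().splitlines()
        assert len(truth_lines) == 1  # header only

    def test_all_emitted_genotypes_are_mendelian(self, tmp_path):
        cfg = SimConfig(
            n_families=2,
            family_templates=("sibling_trio", "cousin_pair"),
            n_background_variants=60,
            seed=5,
        )
        bundle = simulate_cohort(cfg, tmp_path)
        for ped in bundle.pedigrees:
            for v in read_variants(bundle.vcf, samples=set(ped.members)):
                counts = {s: v.allele_count(s) for s in ped.members}
                assert None not in counts.values()
                assert mendelian_consistent(ped, counts)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(penetrance=0.0)
        with pytest.raises(ValueError):
            SimConfig(family_templates=("nonexistent",))
        with pytest.raises(ValueError):
            SimConfig(planted_model="AR_hom", family_templates=("cousin_pair",))


class TestPlantedRecovery:
    @pytest.mark.parametrize("template", ["sister_pair", "sibling_trio", "cousin_pair"])
    def test_planted_dominant_variant_recovered(self, tmp_path, template):
        cfg = SimConfig(
            n_families=1,
            family_templates=(template,),
            n_background_variants=150,
            seed=11,
        )
        bundle = simulate_cohort(cfg, tmp_path)
        results = run_bundle(bundle)
        (chrom, pos, ref, alt, fam, model) = bundle.planted[0]
        assert (chrom, pos, ref, alt) in {
            c.variant_key for c in results[fam].candidates
        }

    def test_incomplete_penetrance_does_not_block_recovery(self, tmp_path):
        cfg = SimConfig(
            n_families=2,
            family_templates=("sister_pair", "cousin_pair"),
            n_background_variants=100,
            penetrance=0.6,
            seed=13,
        )
        bundle = simulate_cohort(cfg, tmp_path)
        results = run_bundle(bundle)
        for chrom, pos, ref, alt, fam, _ in bundle.planted:
            assert (chrom, pos, ref, alt) in {
                c.variant_key for c in results[fam].candidates
            }

    def test_planted_recessive_homozygote_recovered_on_ar_branch(self, tmp_path):
        cfg = SimConfig(
            n_families=1,
            family_templates=("sibling_trio",),
            planted_model="AR_hom",
            n_background_variants=100,
            seed=17,
        )
        bundle = simulate_cohort(cfg, tmp_path)
        results = run_bundle(bundle)
        (chrom, pos, ref, alt, fam, _) = bundle.planted[0]
        ar = [c for c in results[fam].candidates if c.model == "AR_hom"]
        assert (chrom, pos, ref, alt) in {c.variant_key for c in ar}

    def test_planted_comphet_pair_recovered_in_trans(self, tmp_path):
        cfg = SimConfig(
            n_families=1,
            family_templates=("sister_pair",),
            planted_model="AR_comphet",
            n_background_variants=100,
            seed=19,
        )
        bundle = simulate_cohort(cfg, tmp_path)
        results = run_bundle(bundle)
        fam = bundle.planted[0][4]
        comphet = [
            c for c in results[fam].candidates if c.model == "AR_comphet"
        ]
        planted_keys = {(c, p, r, a) for c, p, r, a, _, _ in bundle.planted}
        assert planted_keys <= {c.variant_key for c in comphet}
        for c in comphet:
            assert c.partner_key in planted_keys

    def test_qc_noise_prunes_variants_at_qc_stage(self, tmp_path):
        noisy = simulate_cohort(
            SimConfig(n_families=1, n_background_variants=200, qc_noise=0.2, seed=23),
            tmp_path / "noisy",
        )
        clean = simulate_cohort(
            SimConfig(n_families=1, n_background_variants=200, qc_noise=0.0, seed=23),
            tmp_path / "clean",
        )
        qc_out = {
            name: run_bundle(b)["FAM01"].funnels[0].stage("qc").n_out
            for name, b in (("noisy", noisy), ("clean", clean))
        }
        assert qc_out["noisy"] < qc_out["clean"]

    def test_cosegregation_pruning_grows_with_informative_members(self, tmp_path):
        # more informative members -> background variants survive less often
        rates = {}
        for template in ("mother_daughter", "sister_pair", "cousin_pair"):
            survived = total = 0
            for seed in range(8):
                cfg = SimConfig(
                    n_families=1,
                    family_templates=(template,),
                    planted_model="none",
                    n_background_variants=120,
                    seed=100 + seed,
                )
                bundle = simulate_cohort(cfg, tmp_path / f"{template}{seed}")
                result = run_bundle(bundle)["FAM01"]
                stage = result.funnels[0].stage("ad_cosegregation")
                survived += stage.n_out
                total += stage.n_in
            rates[template] = survived / max(total, 1)
        # the cousin pair requires four informative carriers (two affected
        # plus two obligate parents) versus two for the small templates
        assert rates["cousin_pair"] < rates["mother_daughter"]
        assert rates["cousin_pair"] < rates["sister_pair"]
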