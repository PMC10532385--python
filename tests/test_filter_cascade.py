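"""Per-variant gates and the end-to-end primary filter funnel."""

from __future__ import annotations

from itertools import permutations, product

import pytest

from famscad import datasets
from famscad.annotation import GeneEvidence, VariantAnnotation, default_cadd_distribution
from famscad.filter_cascade import (
    FilterConfig,
    FilterFunnel,
    RegulatoryConfig,
    consequence_gate,
    constraint_gate,
    deleteriousness_gate,
    rarity_gate,
    regulatory_gate,
    run_primary_filter,
)

CFG = FilterConfig()
DIST = default_cadd_distribution()


def ann(**kw) -> VariantAnnotation:
    base = dict(
        variant_key=("chr1", 100, "A", "G"),
        gene_symbol="X",
        consequence="missense",
    )
    base.update(kw)
    return VariantAnnotation(**base)


class TestRarityGate:
    def test_ultra_rare_passes_dominant(self):
        assert rarity_gate(ann(maf=4e-6), "AD", CFG)  # 0.0004 %

    def test_not_reported_counts_as_passing(self):
        assert rarity_gate(ann(maf=None), "AD", CFG)

    def test_intermediate_frequency_splits_models(self):
        a = ann(maf=0.005)  # 0.5 %
        assert not rarity_gate(a, "AD", CFG)
        assert rarity_gate(a, "AR", CFG)

    def test_cutoffs_are_strict(self):
        assert not rarity_gate(ann(maf=0.001), "AD", CFG)
        assert not rarity_gate(ann(maf=0.01), "AR", CFG)


class TestConsequenceGate:
    @pytest.mark.parametrize(
        "consequence,expected",
        [
            ("missense", True),
            ("frameshift", True),
            ("start_loss", True),
            ("stop_gain", True),
            ("stop_loss", True),
            ("canonical_splice", True),
            ("other", False),
            ("regulatory", False),
        ],
    )
    def test_six_coding_classes(self, consequence, expected):
        assert consequence_gate(ann(consequence=consequence)) is expected


class TestDeleteriousnessGate:
    def test_low_cadd_with_hgmd_link_passes(self):
        a = ann(maf=9e-4, cadd_phred=21.2, hgmd_deleterious=True, hgmd_accession="CM043757")
        assert deleteriousness_gate(a, DIST, CFG)

    def test_high_cadd_passes(self):
        assert deleteriousness_gate(ann(cadd_phred=34.0), DIST, CFG)

    def test_low_cadd_without_hgmd_fails(self):
        assert not deleteriousness_gate(ann(cadd_phred=20.0), DIST, CFG)

    def test_threshold_is_exclusive(self):
        assert not deleteriousness_gate(ann(cadd_phred=24.5), DIST, CFG)
        assert deleteriousness_gate(ann(cadd_phred=24.8), DIST, CFG)

    def test_loss_of_function_needs_no_cadd(self):
        assert deleteriousness_gate(ann(consequence="frameshift", cadd_phred=None), DIST, CFG)

    def test_missense_without_cadd_or_hgmd_fails(self):
        assert not deleteriousness_gate(ann(cadd_phred=None), DIST, CFG)

    def test_recomputed_threshold_matches_override(self):
        cfg = FilterConfig(cadd_threshold_override=None)
        assert deleteriousness_gate(ann(cadd_phred=24.8), DIST, cfg)
        assert not deleteriousness_gate(ann(cadd_phred=24.5), DIST, cfg)


class TestConstraintGate:
    def test_frameshift_passes_on_pli(self):
        g = GeneEvidence("KCNK3", pli=0.90)
        assert constraint_gate(g, "frameshift", CFG)

    def test_frameshift_passes_on_oe(self):
        g = GeneEvidence("X", pli=0.1, oe_lof=0.2)
        assert constraint_gate(g, "frameshift", CFG)

    def test_missense_governed_by_z_not_pli(self):
        g = GeneEvidence("X", pli=0.99, mis_z=1.5)
        assert not constraint_gate(g, "missense", CFG)
        assert constraint_gate(GeneEvidence("X", mis_z=2.02), "missense", CFG)

    def test_missing_evidence_row_fails(self):
        assert not constraint_gate(None, "missense", CFG)


class TestRegulatoryGate:
    def test_tfbs_with_all_criteria_passes(self):
        a = ann(
            consequence="regulatory",
            site_context=frozenset({"tfbs"}),
            pwm_score=0.8,
            cadd_phred=9.0,
            regulomedb_rank=2,
            fathmm_xf=0.6,
        )
        assert regulatory_gate(a, DIST, CFG)

    def test_mirna_site_needs_no_pwm(self):
        a = ann(
            consequence="regulatory",
            site_context=frozenset({"mirna_site"}),
            cadd_phred=8.0,
            regulomedb_rank=3,
            fathmm_xf=0.55,
        )
        assert regulatory_gate(a, DIST, CFG)

    def test_weak_pwm_fails(self):
        a = ann(
            consequence="regulatory",
            site_context=frozenset({"tfbs"}),
            pwm_score=0.7,
            cadd_phred=9.0,
            regulomedb_rank=2,
            fathmm_xf=0.6,
        )
        assert not regulatory_gate(a, DIST, CFG)

    def test_decision_table_enumeration(self):
        # all combinations of the five criteria; gate iff all are satisfied
        for context, pwm, cadd, rank, fathmm in product(
            ({"tfbs"}, {"mirna_site"}, set()),
            (0.8, 0.7),
            (9.0, 5.0),
            (2, 5),
            (0.6, 0.3),
        ):
            a = ann(
                consequence="regulatory",
                site_context=frozenset(context),
                pwm_score=pwm,
                cadd_phred=cadd,
                regulomedb_rank=rank,
                fathmm_xf=fathmm,
            )
            expected = (
                bool(context)
                and ("tfbs" not in context or pwm > 0.75)
                and cadd >= 7
                and rank <= 3
                and fathmm >= 0.5
            )
            assert regulatory_gate(a, DIST, CFG) is expected, (
                context, pwm, cadd, rank, fathmm,
            )


class TestPrimaryFilter:
    def test_cosegregating_candidate_fixture_all_survive(
        self, candidate_annotations, candidate_evidence
    ):
        ped, records = datasets.cosegregating_family_records()
        result = run_primary_filter(records, ped, candidate_annotations, candidate_evidence)
        ad = [c for c in result.candidates if c.model == "AD"]
        assert len(ad) == 12
        assert len(result.candidate_genes) == 11

    def test_common_variant_removed_at_rarity(
        self, candidate_annotations, candidate_evidence
    ):
        ped, records = datasets.cosegregating_family_records()
        modified = dict(candidate_annotations)
        key = ("chr9", 136505484, "C", "T")  # NOTCH1 row
        a = modified[key]
        from dataclasses import replace

        modified[key] = replace(a, maf=0.05)
        result = run_primary_filter(records, ped, modified, candidate_evidence)
        assert len(result.candidates) == 11
        assert "NOTCH1" not in result.candidate_genes

    def test_empty_input_gives_empty_funnel_of_zeros(
        self, candidate_annotations, candidate_evidence
    ):
        ped, _ = datasets.cosegregating_family_records()
        result = run_primary_filter([], ped, candidate_annotations, candidate_evidence)
        assert result.candidates == []
        ad = result.funnels[0]
        assert all(s.n_in == 0 and s.n_out == 0 for s in ad.stages)

    def test_qc_failure_in_affected_drops_variant(
        self, candidate_annotations, candidate_evidence
    ):
        ped, records = datasets.cosegregating_family_records(qc=(25.0, 50, 100.0))
        result = run_primary_filter(records, ped, candidate_annotations, candidate_evidence)
        assert result.candidates == []
        assert result.funnels[0].stage("qc").n_out == 0

    def test_funnel_conservation(self, candidate_annotations, candidate_evidence):
        ped, records = datasets.cosegregating_family_records()
        result = run_primary_filter(records, ped, candidate_annotations, candidate_evidence)
        for funnel in result.funnels:
            for prev, nxt in zip(funnel.stages, funnel.stages[1:]):
                assert nxt.n_in == prev.n_out
                assert nxt.n_out <= nxt.n_in

    def test_missing_annotation_counted_and_dropped(
        self, candidate_annotations, candidate_evidence
    ):
        ped, records = datasets.cosegregating_family_records()
        partial = {
            k: v
            for k, v in candidate_annotations.items()
            if v.gene_symbol != "NOTCH1"
        }
        result = run_primary_filter(records, ped, partial, candidate_evidence)
        assert result.n_missing_annotation == 1
        assert len(result.candidates) == 11

    def test_pure_gates_are_order_independent(self, candidate_annotations, candidate_evidence):
        # rarity / consequence / deleteriousness / constraint are pure
        # per-variant predicates: any ordering yields the same survivors
        gates = {
            "rarity": lambda a: rarity_gate(a, "AD", CFG),
            "consequence": consequence_gate,
            "deleteriousness": lambda a: deleteriousness_gate(a, DIST, CFG),
            "constraint": lambda a: constraint_gate(
                candidate_evidence.get(a.gene_symbol), a.consequence, CFG
            ),
        }
        annotations = list(candidate_annotations.values())
        reference = None
        for order in permutations(gates):
            survivors = annotations
            for name in order:
                survivors = [a for a in survivors if gates[name](a)]
            keys = {a.variant_key for a in survivors}
            reference = keys if reference is None else reference
            assert keys == reference


class TestFunnelStructure:
    def test_out_greater_than_in_rejected(self):
        funnel = FilterFunnel("AD")
        with pytest.raises(ValueError):
            funnel.record("qc", 5, 6)

    def test_stage_chaining_enforced(self):
        funnel = FilterFunnel("AD")
        funnel.record("qc", 10, 8)
        with pytest.raises(ValueError):
            funnel.record("mask", 9, 9)

    def test_percent_reduction(self):
        funnel = FilterFunnel("AD")
        funnel.record("qc", 100, 50)
        assert funnel.percent_reduction("qc") == 50.0


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "maf_dominant: 0.002\nregulatory:\n  pwm_min: 0.8\nqc:\n  min_read_depth: 20\n"
        )
        cfg = FilterConfig.from_yaml(p)
        assert cfg.maf_dominant == 0.002
        assert cfg.regulatory == RegulatoryConfig(pwm_min=0.8)
        assert cfg.qc.min_read_depth == 20
        assert cfg.maf_recessive == 0.01  # defaults retained

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(maf_dominant=1.5)
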