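"""Run the primary variant filter over the packaged candidate variants.

The 12 published candidate variants are encoded as a synthetic
co-segregating family (two affected sisters heterozygous for every
variant, carrier mother, non-carrier father) and pushed through the full
cascade: QC -> repeat mask -> rarity -> co-segregation -> consequence ->
deleteriousness -> gene constraint. All 12 variants in 11 genes survive;
the recessive branch correctly returns nothing for heterozygous variants.
"""

from famscad import datasets, run_primary_filter

annotations = datasets.load_candidate_annotations()
evidence = datasets.load_candidate_gene_evidence()
ped, records = datasets.cosegregating_family_records()

result = run_primary_filter(records, ped, annotations, evidence)

for funnel in result.funnels:
    print(f"{funnel.branch} branch funnel:")
    for stage in funnel.stages:
        print(f"  {stage.name:18s} {stage.n_in:3d} -> {stage.n_out:3d}")

print(f"\nsurviving variants: {len(result.candidates)}")
print(f"distinct genes    : {len(result.candidate_genes)}")
for c in result.candidates:
    chrom, pos, ref, alt = c.variant_key
    print(f"  {c.gene_symbol:8s} {chrom}:{pos} {ref}>{alt}  [{c.model}]")
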