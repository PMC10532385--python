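"""Score candidate genes on the seven secondary evidence parameters.

Each gene surviving the primary filter is scored 0-7 on: high arterial
tissue expression (rank 1-5 in coronary/aorta/tibial artery), candidacy in
two or more families, protein-interaction association with previously
implicated SCAD genes (one parameter regardless of seed set), membership
of connective-tissue-disorder/aortopathy panels, mouse vascular phenotype,
human vascular mutation record, and a vascular GWAS trait. The top
candidate per family is the argmax; ties are reported, not broken.
"""

from famscad import datasets
from famscad.prioritization import secondary_score, select_top, shared_gene_flag

evidence = datasets.load_candidate_gene_evidence()
families = datasets.candidate_family_assignments()

scores = {
    gene: secondary_score(ev, shared=shared_gene_flag(gene, families))
    for gene, ev in evidence.items()
}

print("gene      score  fulfilled parameters")
for gene in sorted(scores, key=lambda g: -scores[g].score):
    s = scores[gene]
    fulfilled = ", ".join(k for k, v in s.flags.items() if v)
    print(f"{gene:9s} {s.score}      {fulfilled}")

print("\ntop candidate per family:")
for fam in sorted(families):
    top = select_top([scores[g] for g in families[fam]])
    print(f"  {fam}: {', '.join(sorted(top))}")
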