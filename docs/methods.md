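# Methods

## The transmission model

Families are modelled as directed parent graphs. The dominant model assumes
a single founder origin of the risk allele within each family (no bilineal
inheritance): the allele enters through exactly one founder and is
transmitted along parent→child links. Under this assumption the **obligate
carriers** of a variant observed in a set of carriers are the unaffected
individuals present in *every* carrier set consistent with single-founder
transmission. `famscad.pedigree.obligate_carriers` computes them per
candidate origin as the vertices that cut all transmission paths from the
origin to some assumed carrier, intersected over consistent origins; the
test suite checks this against exhaustive subset enumeration on random
pedigrees of up to 10 members. When the assumed carriers admit no common
single-founder origin (e.g. two carrier founders), a warning is emitted and
no obligate carriers are reported.

Co-segregation verdicts are genotype logic only (frequency and annotation
gates live in the cascade):

* **AD** — heterozygous in every affected-spectrum member and obligate
  carrier. Homozygous-alternate in an affected fails the dominant model
  (such variants are recessive candidates instead). Unaffected carriers
  elsewhere never fail the variant: penetrance is incomplete, so carriage
  without disease carries no evidence against the allele. Individuals with
  unknown affection are ignored throughout.
* **AR hom** — all affected homozygous-alternate; every genotyped
  unaffected parent heterozygous.
* **AR compound-het** — all affected heterozygous for two same-gene
  variants; when both parents are genotyped, each parent must carry exactly
  one of the pair (trans phase). With ungenotyped parents the pair is
  reported flagged `phase_unknown` rather than dropped. The carried-set
  rule coincides with full haplotype enumeration whenever parents are
  reference or heterozygous at both loci — the realistic regime for
  sub-1 %-frequency alleles; a parent homozygous at one locus can in
  principle force trans phase while carrying both variants, a configuration
  the rule conservatively rejects.

The affected spectrum defaults to SCAD **plus** extra-coronary arteriopathy
relatives (`scad_plus_arteriopathy`), since those relatives were genotyped
as part of the affected set; `scad_only` is available. A per-family
`drop_from_required` option removes specific individuals from the required
carrier set, for families where co-segregation in an ungenotyped relative
is inferred rather than observed.

## Filter cascade parameters

| parameter | default | role |
| --- | --- | --- |
| site quality / GQ / depth | ≥ 20 / ≥ 30 / ≥ 10 | per-genotype QC, inclusive bounds; a variant fails for the family if any required member's call fails |
| MAF, dominant | < 0.001 | population rarity (fraction); unreported frequency passes |
| MAF, recessive | < 0.01 | recessive-branch rarity |
| CADD threshold | 24.5 (exclusive) | missense/splice lower quartile within the consequence class; fixed operating constant by default, recomputable from the class distribution (`cadd_threshold_override=None`) |
| pLI / o-e | ≥ 0.9, < 0.35 (either) | constraint for truncating variants |
| missense Z | ≥ 2.0 | constraint for missense/splice |
| regulatory | PWM > 0.75 (TFBS), CADD ≥ 7, RegulomeDB ≤ 3, FATHMM-XF ≥ 0.5 | ancillary non-coding filter |
| interaction confidence | ≥ 0.7, degree ≤ 2 | network association with prior SCAD genes |
| arterial expression | rank ≤ 5 in coronary/aorta/tibial | expression flag |

"Base call quality" is read as the VCF site QUAL field — the only
variant-level phred quality available. Coordinates follow VCF (1-based) and
BED (0-based half-open) conventions; a variant is masked iff its POS anchor
base lies inside an interval (`start < pos ≤ end`), so indel overlap is
judged by the anchor base only. Repeat intervals are consumed as a BED
mask; detecting them is an upstream concern.

CADD percentiles use the empirical-CDF convention 100 · P(X ≤ score) within
the consequence class, which makes "score ≤ threshold excluded" and "lower
quartile" consistent. The genome-wide per-class histograms are not shipped;
`default_cadd_distribution()` provides 100-point surrogate grids pinned so
the missense/splice 25th percentile is exactly 24.5 and the regulatory 75th
percentile exactly 7 — the two operating points the gates use. Percentile
values quoted for individual variants by external annotation pipelines are
*not* reproduced (they depend on proprietary histograms and are mutually
inconsistent in places); no code path or test relies on them. Truncating
variants (frameshift, start/stop events) carry no CADD requirement.

Gates other than QC and co-segregation are pure per-variant predicates;
their order affects only the funnel's intermediate counts, never the
surviving set (property-tested over all gate permutations). Variants whose
gene lacks an evidence row fail the constraint gate (conservative), and
variants missing from the annotation table are dropped at the first
annotation-dependent stage with a logged count.

## Secondary scoring

Seven boolean parameters, summed. Protein-interaction association with
prior SCAD genes counts as **one** parameter even when both the talin-1 set
and the GWAS-derived set are hit — the only convention under which the
published per-family counts are internally consistent. When an interaction
network is supplied, the flag is first/second-degree BFS distance to the
seed set on the confidence-thresholded graph; without a network, recorded
per-gene association sets are used. Edge files with 0–1000 integer scores
(STRING convention) are rescaled to [0, 1] on load. Tied maximal scores
yield multiple top candidates; the scoring is non-iterative.

## Cohort statistics

Age statistics use the first recorded event age per individual (recurrent
cases contribute their first event only); unknown ages are excluded from
means/SDs but individuals remain counted. SDs are sample (n−1) values;
means/SDs are reported to one decimal and percentages rounded half-up.
Clinical feature counts are tallied over SCAD-affected individuals;
relatives whose only finding is an extra-coronary arteriopathy enter
through their affection class instead (counting their features would
double-represent the phenotype that defines their affection status).
Two-group proportion comparisons use Pearson chi-square without continuity
correction, falling back to Fisher's exact test when any expected cell is
below 5; the method used is recorded in the result.

## Synthetic data: what it emulates and what it does not

`simulate_cohort` generates the study's input shapes end to end: template
families (sister pair, sibling trio, mother–daughter, first-cousin pair), a
planted causal variant transmitted from a single founder so that every
affected member and obligate carrier is a het (AD) or the configured
recessive genotypes (AR hom / trans compound-het), background variants
gene-dropped from Hardy–Weinberg founder genotypes at beta(0.2, 20) allele
frequencies truncated to (0, 0.05], QUAL/GQ/DP drawn comfortably above the
QC thresholds, and an optional `qc_noise` rate injecting sub-threshold
calls. Like a real multi-sample VCF, only sites carried by at least one
cohort member are emitted (drops are rejection-sampled on observation).
With `penetrance < 1`, unaffected relatives of carriers may inherit the
planted allele, exercising the incomplete-penetrance tolerance; note that
templates whose affected members share no genotyped affected ancestor (e.g.
a sister pair) necessarily route the planted allele through an unaffected
carrier parent regardless. Identical configurations produce byte-identical
bundles; every emitted genotype configuration is Mendelian-consistent
(validated independently in the tests).

Passing tests on this generator show that the pipeline's logic is correct
under its own model assumptions. They do not probe: linkage disequilibrium
or haplotype structure among background variants, sequencing artefacts
beyond threshold-style QC noise, population stratification of allele
frequencies, mis-specified pedigrees or non-paternity, de novo variation,
or annotation error — all of which affect real cohorts.

## Problem sizes and numerical choices

The packaged fixtures are tiny (15 families / 78 roster rows; 12 variants /
11 genes) and run in milliseconds. Oracle-equivalence checks use random
pedigrees of ≤ 10 members (exhaustive subset enumeration is exact there),
interaction graphs of ≤ 200 nodes, and score distributions of ≤ 50 points.
Recovery experiments use 100 seeded single-family cohorts with 60
background variants each per penetrance setting, and a six-family
multi-sibling cohort with 300 background variants for the recessive-branch
null; these sizes give exact (not asymptotic) expectations — recovery is
required in 100 % of runs, not on average. Ties in `select_top` are
reported rather than broken; empty inputs yield empty outputs (and funnels
of zeros) rather than errors wherever a scientific zero is well-defined.

## Known limitations

* Pedigree topologies for the three distantly-related families in the
  packaged roster are approximate (generation labels only); they do not
  affect the cohort statistics, only illustrative co-segregation runs.
* The dominant model assumes a single founder origin; bilineal families
  would need a different obligate-carrier analysis.
* X-linked and mitochondrial models, kinship checks from genotypes, and
  statistical linkage are out of scope.
* Variant normalization beyond multiallelic splitting (e.g. full left
  alignment) is assumed done upstream.
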