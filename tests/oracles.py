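"""Independent brute-force oracles used to validate the implementation.

These deliberately use naive enumeration / scanning and share no code with
the package internals beyond the public data types.
"""

from __future__ import annotations

from itertools import product

from famscad.pedigree import PedigreeGraph


def consistent_carrier_sets(
    ped: PedigreeGraph, required: set[str]
) -> list[set[str]]:
    """All carrier sets with a single founder origin and parent-closure
    that contain every required carrier (exhaustive subset enumeration)."""
    members = sorted(ped.members)
    founders = ped.founders()
    out = []
    for bits in product((0, 1), repeat=len(members)):
        s = {m for m, b in zip(members, bits) if b}
        if not required <= s:
            continue
        if len(s & founders) != 1:
            continue
        if any(
            ped.parents(i) and not any(p in s for p in ped.parents(i))
            for i in s
        ):
            continue
        out.append(s)
    return out


def obligate_oracle(ped: PedigreeGraph, carriers_assumed: set[str]) -> set[str]:
    """Intersection over all consistent single-origin carrier sets."""
    sets = consistent_carrier_sets(ped, carriers_assumed)
    if not sets:
        return set()
    inter = set.intersection(*sets)
    return {
        i
        for i in inter - carriers_assumed
        if ped.members[i].affection == "unaffected"
    }


def ad_oracle(variant, ped: PedigreeGraph, affected: set[str]) -> bool:
    """Dominant model by exhaustive enumeration of single-founder
    transmission assignments.

    Passes iff a consistent assignment exists, every affected individual is
    heterozygous, and every unaffected individual present in *all*
    consistent assignments (the obligate carriers, derived here by direct
    enumeration) is heterozygous too. Genotypes of other unaffected
    relatives are not conditioned on: under incomplete penetrance their
    carriage status carries no evidence either way.
    """
    sets = consistent_carrier_sets(ped, affected)
    if not sets:
        return False
    if any(variant.allele_count(i) != 1 for i in affected):
        return False
    forced = set.intersection(*sets)
    return all(
        variant.allele_count(i) == 1
        for i in forced - affected
        if ped.members[i].affection == "unaffected"
    )


def comphet_phase_oracle(v1, v2, affected: set[str], father: str, mother: str) -> bool:
    """Trans compound heterozygosity by haplotype enumeration.

    Enumerates parental haplotype phasings consistent with the observed
    two-locus genotypes and every way the affected children could inherit;
    the pair qualifies iff some assignment makes every affected carry the
    two variants in trans and no assignment allows a cis configuration.
    """

    def haplotype_pairs(ac1: int, ac2: int):
        """All unordered phasings of a two-locus genotype into 2 haplotypes."""
        pairs = []
        for h1 in product((0, 1), repeat=2):
            for h2 in product((0, 1), repeat=2):
                if h1[0] + h2[0] == ac1 and h1[1] + h2[1] == ac2:
                    pairs.append((h1, h2))
        return pairs

    f1, f2 = v1.allele_count(father), v2.allele_count(father)
    m1, m2 = v1.allele_count(mother), v2.allele_count(mother)
    if None in (f1, f2, m1, m2):
        return False  # phase cannot be established

    trans_possible = False
    cis_possible = False
    for fhap in haplotype_pairs(f1, f2):
        for mhap in haplotype_pairs(m1, m2):
            # each child independently inherits one haplotype per parent;
            # check a joint assignment exists matching observed genotypes
            per_child_options = []
            for child_unused in affected:
                opts = []
                for hp in fhap:
                    for hm in mhap:
                        if hp[0] + hm[0] == 1 and hp[1] + hm[1] == 1:
                            opts.append((hp, hm))
                per_child_options.append(opts)
            if any(not o for o in per_child_options):
                continue
            for combo in product(*per_child_options):
                if all(hp in ((1, 0), (0, 1)) and hm in ((1, 0), (0, 1)) for hp, hm in combo):
                    trans_possible = True
                if any(
                    (hp == (1, 1) or hm == (1, 1)) for hp, hm in combo
                ):
                    cis_possible = True
    return trans_possible and not cis_possible


def repeat_mask_oracle(
    variants, intervals: list[tuple[str, int, int]]
) -> list:
    """Brute-force interval scan: keep pos unless start < pos <= end."""
    kept = []
    for v in variants:
        masked = any(
            chrom == v.chrom and start < v.pos <= end
            for chrom, start, end in intervals
        )
        if not masked:
            kept.append(v)
    return kept


def cadd_percentile_oracle(score: float, values: list[float]) -> float:
    return 100.0 * sum(1 for x in values if x <= score) / len(values)


def bfs_degree_oracle(
    edges: list[tuple[str, str, float]],
    gene: str,
    seeds: set[str],
    conf_min: float,
    max_degree: int = 2,
) -> int | None:
    adj: dict[str, set[str]] = {}
    for a, b, c in edges:
        if c >= conf_min:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    frontier = {gene}
    seen = {gene}
    for depth in range(1, max_degree + 1):
        frontier = {n for f in frontier for n in adj.get(f, ())} - seen
        if frontier & seeds:
            return depth
        seen |= frontier
    return None


def mendelian_consistent(ped: PedigreeGraph, counts: dict[str, int]) -> bool:
    """Can each genotype arise from one allele per (possibly unrecorded) parent?"""
    transmissible = {0: {0}, 1: {0, 1}, 2: {1}}
    for iid, ac in counts.items():
        ind = ped.members[iid]
        options = []
        for pid in (ind.father_id, ind.mother_id):
            if pid is None or pid not in counts:
                options.append({0, 1})
            else:
                options.append(transmissible[counts[pid]])
        if not any(a + b == ac for a in options[0] for b in options[1]):
            return False
    return True
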