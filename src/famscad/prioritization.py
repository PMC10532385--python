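"""Secondary evidence scoring and network-degree association.

Genes surviving the primary filter are scored against seven gene- and
disease-level parameters: high arterial tissue expression (GTEx-style rank
1-5 in coronary, aorta or tibial artery), candidacy shared by two or more
families, protein-level association with previously implicated SCAD genes
(one parameter regardless of which seed set is hit), membership of
connective-tissue-disorder/aortopathy diagnostic panels, vascular phenotype
in mouse models, an established human vascular-disease mutation, and a
vascular GWAS trait. Top candidates per family are the argmax set; the
scoring is non-iterative and ties are reported, not broken.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .annotation import GeneEvidence

__all__ = [
    "PRIOR_SCAD_GENES",
    "FLAG_NAMES",
    "InteractionNetwork",
    "SecondaryScore",
    "load_network",
    "expression_flag",
    "shared_gene_flag",
    "network_degree",
    "secondary_score",
    "select_top",
    "ARTERIAL_RANK_MAX",
]

#: SCAD candidate genes implicated by earlier familial and GWAS work,
#: used as the seed set for protein-interaction association.
PRIOR_SCAD_GENES = (
    "TLN1",
    "EDN1",
    "PHACTR1",
    "ADAMTSL4",
    "C1orf54",
    "ECM1",
    "FBN1",
    "LINC00310",
    "LRP1",
    "MRPS21",
    "AFAP1",
)

FLAG_NAMES = (
    "expression",
    "shared_gene",
    "ppi_prior_scad",
    "ctd_aortopathy",
    "mgi_vascular",
    "hgmd_vascular",
    "gwas_trait",
)

ARTERIAL_RANK_MAX = 5


class InteractionNetwork:
    """Undirected protein-interaction graph with per-edge confidence."""

    def __init__(self, edges: Iterable[tuple[str, str, float]] = ()):
        self.graph = nx.Graph()
        for a, b, conf in edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if not 0.0 <= conf <= 1.0:
                raise ValueError(f"confidence {conf} outside [0,1] for {a}-{b}")
            self.graph.add_edge(a, b, confidence=conf)

    def thresholded(self, conf_min: float) -> nx.Graph:
        keep = [
            (a, b)
            for a, b, c in self.graph.edges(data="confidence")
            if c >= conf_min
        ]
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from(keep)
        return g


def load_network(path: str | Path) -> InteractionNetwork:
    """Read a protein-interaction edge TSV (protein1, protein2, combined_score).

    Scores on a 0-1000 integer scale (STRING convention) are divided by
    1000; scores already in [0, 1] are taken as-is.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=r"\s+", engine="python")
    cols = list(df.columns[:3])
    edges = []
    for a, b, score in df[cols].itertuples(index=False):
        score = float(score)
        if score > 1.0:
            score /= 1000.0
        edges.append((str(a), str(b), score))
    return InteractionNetwork(edges)


def expression_flag(g: GeneEvidence, rank_max: int = ARTERIAL_RANK_MAX) -> bool:
    """High arterial expression: rank <= 5 in any of the three arterial tissues."""
    ranks = g.expression_rank.values()
    return bool(ranks) and min(ranks) <= rank_max


def shared_gene_flag(
    gene: str, per_family_candidates: Mapping[str, set[str]]
) -> bool:
    """Gene appears in the candidate sets of two or more families."""
    return sum(gene in genes for genes in per_family_candidates.values()) >= 2


def network_degree(
    net: InteractionNetwork,
    gene: str,
    seeds: set[str],
    conf_min: float = 0.7,
    max_degree: int = 2,
) -> int | None:
    """Shortest-path degree (1 or 2) from gene to any seed on the
    confidence-thresholded graph, or None beyond ``max_degree``."""
    if not 0.0 <= conf_min <= 1.0:
        raise ValueError("conf_min must be in [0, 1]")
    g = net.thresholded(conf_min)
    if gene not in g:
        return None
    lengths = nx.single_source_shortest_path_length(g, gene, cutoff=max_degree)
    best = min(
        (d for node, d in lengths.items() if node in seeds and node != gene),
        default=None,
    )
    return best if best and best >= 1 else None


@dataclass(frozen=True)
class SecondaryScore:
    gene_symbol: str
    flags: dict[str, bool]

    @property
    def score(self) -> int:
        return sum(self.flags.values())


def secondary_score(
    g: GeneEvidence,
    shared: bool = False,
    ppi_degree: int | None = None,
) -> SecondaryScore:
    """Score a gene on the seven secondary parameters.

    ``ppi_degree`` is a first- or second-degree network association with the
    prior SCAD seed genes; if None, the gene's recorded ``ppi_association``
    sets are used instead. Either way the interaction evidence counts as a
    single parameter.
    """
    if ppi_degree is not None:
        ppi = ppi_degree in (1, 2)
    else:
        ppi = bool(g.ppi_association)
    flags = {
        "expression": expression_flag(g),
        "shared_gene": shared,
        "ppi_prior_scad": ppi,
        "ctd_aortopathy": g.ctd_aortopathy_panel,
        "mgi_vascular": g.mgi_vascular,
        "hgmd_vascular": g.hgmd_vascular,
        "gwas_trait": g.gwas_vascular_trait,
    }
    return SecondaryScore(gene_symbol=g.gene_symbol, flags=flags)


def select_top(scores: Iterable[SecondaryScore]) -> set[str]:
    """All genes attaining the maximal secondary score; ties are reported."""
    scores = list(scores)
    if not scores:
        return set()
    best = max(s.score for s in scores)
    return {s.gene_symbol for s in scores if s.score == best}
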