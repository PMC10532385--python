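"""Variant- and gene-level annotation tables and consequence-stratified
CADD percentiles.

Deleteriousness of missense and canonical splice variants is judged on the
CADD PHRED scale indexed as an empirical percentile among variants of the
same consequence class. The genome-wide per-class score histograms are not
shipped; small surrogate distributions are calibrated so that the
missense/splice lower quartile sits at 24.5 and the regulatory upper
quartile at 7 — the operating points the coding and regulatory filters use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONSEQUENCE_CLASSES",
    "CODING_CLASSES",
    "TRUNCATING_CLASSES",
    "VariantAnnotation",
    "GeneEvidence",
    "CaddDistribution",
    "AnnotationError",
    "load_annotations",
    "load_gene_evidence",
    "write_annotations",
    "cadd_percentile",
    "class_quartile_threshold",
    "default_cadd_distribution",
]

CONSEQUENCE_CLASSES = (
    "missense",
    "frameshift",
    "start_loss",
    "stop_gain",
    "stop_loss",
    "canonical_splice",
    "regulatory",
    "other",
)
#: the six protein-altering classes retained by the consequence filter
CODING_CLASSES = frozenset(
    ("missense", "frameshift", "start_loss", "stop_gain", "stop_loss", "canonical_splice")
)
#: classes judged by loss-of-function constraint (pLI / o-e) rather than missense Z
TRUNCATING_CLASSES = frozenset(("frameshift", "start_loss", "stop_gain", "stop_loss"))

VariantKey = tuple[str, int, str, str]


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation table."""


@dataclass(frozen=True)
class VariantAnnotation:
    variant_key: VariantKey
    gene_symbol: str
    consequence: str
    maf: float | None = None  # population fraction; None = not reported
    cadd_phred: float | None = None
    hgmd_deleterious: bool = False
    hgmd_accession: str | None = None
    fathmm_xf: float | None = None
    regulomedb_rank: int | None = None
    pwm_score: float | None = None
    site_context: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise AnnotationError(f"{self.variant_key}: MAF {self.maf} outside [0,1]")
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise AnnotationError(
                f"{self.variant_key}: unknown consequence {self.consequence!r}"
            )


@dataclass(frozen=True)
class GeneEvidence:
    gene_symbol: str
    pli: float | None = None
    oe_lof: float | None = None
    mis_z: float | None = None
    expression_rank: dict[str, int] = field(default_factory=dict)
    ctd_aortopathy_panel: bool = False
    mgi_vascular: bool = False
    hgmd_vascular: bool = False
    gwas_vascular_trait: bool = False
    ppi_association: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if any(r < 1 for r in self.expression_rank.values()):
            raise AnnotationError(f"{self.gene_symbol}: expression rank < 1")


_NA = {"", ".", "NR", "NA", "nan", "None"}


def _opt_float(value, where: str) -> float | None:
    s = "" if value is None or (isinstance(value, float) and np.isnan(value)) else str(value).strip()
    if s in _NA:
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise AnnotationError(f"{where}: non-numeric value {s!r}") from exc


def _opt_bool(value) -> bool:
    s = str(value).strip()
    return s not in _NA and s not in ("0", "False", "false", "no")


def load_annotations(path: str | Path) -> dict[VariantKey, VariantAnnotation]:
    """Load the per-variant annotation TSV keyed by (chrom, pos, ref, alt).

    Expected columns: chrom, pos, ref, alt, gene, consequence, maf,
    cadd_phred, hgmd, fathmm_xf, regdb_rank, pwm, site_context. 'NR', '.'
    or empty mean not reported.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    out: dict[VariantKey, VariantAnnotation] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        key: VariantKey = (row.chrom, int(row.pos), row.ref, row.alt)
        if key in out:
            raise AnnotationError(f"{path}: duplicate variant key {key}")
        where = f"{path} row {row_no}"
        hgmd = getattr(row, "hgmd", ".").strip()
        context_raw = getattr(row, "site_context", ".").strip()
        context = (
            frozenset() if context_raw in _NA else frozenset(context_raw.split(","))
        )
        regdb = _opt_float(getattr(row, "regdb_rank", "."), where)
        out[key] = VariantAnnotation(
            variant_key=key,
            gene_symbol=row.gene,
            consequence=row.consequence,
            maf=_opt_float(getattr(row, "maf", "."), where),
            cadd_phred=_opt_float(getattr(row, "cadd_phred", "."), where),
            hgmd_deleterious=hgmd not in _NA,
            hgmd_accession=None if hgmd in _NA else hgmd,
            fathmm_xf=_opt_float(getattr(row, "fathmm_xf", "."), where),
            regulomedb_rank=None if regdb is None else int(regdb),
            pwm_score=_opt_float(getattr(row, "pwm", "."), where),
            site_context=context,
        )
    return out


def write_annotations(
    annotations: dict[VariantKey, VariantAnnotation], path: str | Path
) -> None:
    """Inverse of :func:`load_annotations` (round-trip safe)."""
    rows = []
    for (chrom, pos, ref, alt), a in annotations.items():
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": a.gene_symbol,
                "consequence": a.consequence,
                "maf": "NR" if a.maf is None else repr(a.maf),
                "cadd_phred": "." if a.cadd_phred is None else repr(a.cadd_phred),
                "hgmd": a.hgmd_accession if a.hgmd_deleterious else ".",
                "fathmm_xf": "." if a.fathmm_xf is None else repr(a.fathmm_xf),
                "regdb_rank": "." if a.regulomedb_rank is None else a.regulomedb_rank,
                "pwm": "." if a.pwm_score is None else repr(a.pwm_score),
                "site_context": ",".join(sorted(a.site_context)) or ".",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_gene_evidence(path: str | Path) -> dict[str, GeneEvidence]:
    """Load the per-gene evidence TSV keyed by gene symbol.

    Expected columns: gene, pli, oe_lof, mis_z, rank_coronary, rank_aorta,
    rank_tibial, ctd_aor_panel, mgi, hgmd_vasc, gwas_trait, ppi_talin1,
    ppi_gwas.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, GeneEvidence] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        if row.gene in out:
            raise AnnotationError(f"{path}: duplicate gene {row.gene!r}")
        where = f"{path} row {row_no}"
        ranks: dict[str, int] = {}
        for tissue in ("coronary", "aorta", "tibial"):
            r = _opt_float(getattr(row, f"rank_{tissue}", "."), where)
            if r is not None:
                ranks[tissue] = int(r)
        ppi = set()
        if _opt_bool(getattr(row, "ppi_talin1", "0")):
            ppi.add("talin1_set")
        if _opt_bool(getattr(row, "ppi_gwas", "0")):
            ppi.add("gwas_set")
        out[row.gene] = GeneEvidence(
            gene_symbol=row.gene,
            pli=_opt_float(getattr(row, "pli", "."), where),
            oe_lof=_opt_float(getattr(row, "oe_lof", "."), where),
            mis_z=_opt_float(getattr(row, "mis_z", "."), where),
            expression_rank=ranks,
            ctd_aortopathy_panel=_opt_bool(getattr(row, "ctd_aor_panel", "0")),
            mgi_vascular=_opt_bool(getattr(row, "mgi", "0")),
            hgmd_vascular=_opt_bool(getattr(row, "hgmd_vasc", "0")),
            gwas_vascular_trait=_opt_bool(getattr(row, "gwas_trait", "0")),
            ppi_association=frozenset(ppi),
        )
    return out


class CaddDistribution:
    """Per-consequence-class empirical distributions of CADD PHRED scores."""

    def __init__(self, scores_by_class: dict[str, "np.ndarray | list[float]"]):
        self._sorted: dict[str, np.ndarray] = {
            cls: np.sort(np.asarray(vals, dtype=float))
            for cls, vals in scores_by_class.items()
        }

    def scores(self, consequence: str) -> np.ndarray:
        try:
            arr = self._sorted[consequence]
        except KeyError as exc:
            raise KeyError(f"no CADD distribution for class {consequence!r}") from exc
        if arr.size == 0:
            raise ValueError(f"empty CADD distribution for class {consequence!r}")
        return arr

    def classes(self) -> set[str]:
        return set(self._sorted)


def cadd_percentile(score: float, consequence: str, dist: CaddDistribution) -> float:
    """Empirical-CDF percentile: 100 * P(X <= score) within the class."""
    arr = dist.scores(consequence)
    return 100.0 * float(np.searchsorted(arr, score, side="right")) / arr.size


def class_quartile_threshold(
    dist: CaddDistribution, consequence: str, q: float
) -> float:
    """Smallest observed score whose empirical percentile >= 100*q."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    arr = dist.scores(consequence)
    for value in np.unique(arr):
        if cadd_percentile(float(value), consequence, dist) >= 100.0 * q:
            return float(value)
    return float(arr[-1])  # unreachable: last value has percentile 100


def default_cadd_distribution() -> CaddDistribution:
    """Surrogate per-class score distributions.

    100-point grids shaped like plausible PHRED-score spreads, pinned so
    that the 25th percentile of the missense and canonical-splice classes
    is exactly 24.5 and the 75th percentile of the regulatory class is
    exactly 7. Truncating classes carry no CADD requirement and get a
    generic high-score spread.
    """
    missense = np.concatenate(
        [np.linspace(0.6, 24.5, 25), np.linspace(24.9, 48.0, 75)]
    )
    regulatory = np.concatenate(
        [np.linspace(0.05, 7.0, 75), np.linspace(7.2, 25.0, 25)]
    )
    truncating = np.linspace(10.0, 50.0, 100)
    return CaddDistribution(
        {
            "missense": missense,
            "canonical_splice": missense.copy(),
            "regulatory": regulatory,
            "frameshift": truncating,
            "start_loss": truncating.copy(),
            "stop_gain": truncating.copy(),
            "stop_loss": truncating.copy(),
        }
    )
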