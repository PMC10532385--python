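"""Multi-sample variant input, per-genotype QC, and simple-repeat masking.

Variants are read from VCF (plain or bgzipped) with cyvcf2, split into one
biallelic record per alternate allele, and filtered against quality
thresholds (site quality >= 20, genotype quality >= 30, depth >= 10 by
default) and a BED mask of simple-repeat intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCall",
    "VariantRecord",
    "RepeatMask",
    "QCThresholds",
    "read_variants",
    "read_repeat_mask",
    "qc_pass",
    "apply_repeat_mask",
    "write_variants",
]


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    allele_count: int | None  # 0/1/2 copies of the alt allele; None = missing
    genotype_quality: float = 0.0
    read_depth: int = 0


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    site_quality: float
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def allele_count(self, sample_id: str) -> int | None:
        call = self.calls.get(sample_id)
        return None if call is None else call.allele_count


@dataclass(frozen=True)
class QCThresholds:
    min_site_quality: float = 20.0
    min_genotype_quality: float = 30.0
    min_read_depth: int = 10


class RepeatMask:
    """Simple-repeat intervals, BED convention (0-based, half-open).

    A variant whose 1-based POS anchor base falls inside an interval
    (``start < pos <= end``) is masked; indel overlap is judged by the
    anchor base only.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self.n_intervals = 0
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
            self.n_intervals += 1

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        # pos in (start, end]  <=>  pos-1 in [start, end)
        return bool(tree is not None and tree.overlaps(pos - 1))


def read_repeat_mask(path: str | Path) -> RepeatMask:
    """Load a BED3 file of repeat intervals."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            intervals.append((chrom, int(start), int(end)))
    return RepeatMask(intervals)


class SampleMissingError(KeyError):
    """A requested sample is absent from the VCF header."""


def read_variants(
    path: str | Path, samples: Iterable[str] | None = None
) -> Iterator[VariantRecord]:
    """Stream biallelic :class:`VariantRecord` objects from a VCF.

    Multiallelic sites are split into one record per alternate allele; the
    per-sample allele count for each record counts copies of that alternate
    only. Unparsable records are skipped with a logged warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    if samples is None:
        wanted = header_samples
    else:
        wanted = list(samples)
        missing = set(wanted) - set(header_samples)
        if missing:
            raise SampleMissingError(
                f"samples absent from VCF header: {sorted(missing)}"
            )
    idx = {s: header_samples.index(s) for s in wanted}

    n_skipped = 0
    for var in vcf:
        try:
            gqs = var.format("GQ")
            dps = var.format("DP")
            genotypes = var.genotypes  # [allele_a, allele_b, phased]
            qual = float(var.QUAL) if var.QUAL is not None else 0.0
            for alt_i, alt in enumerate(var.ALT, start=1):
                calls: dict[str, GenotypeCall] = {}
                for s in wanted:
                    i = idx[s]
                    alleles = genotypes[i][:-1]
                    if any(a < 0 for a in alleles):
                        ac: int | None = None
                    else:
                        ac = sum(1 for a in alleles if a == alt_i)
                    calls[s] = GenotypeCall(
                        sample_id=s,
                        allele_count=ac,
                        genotype_quality=(
                            float(gqs[i][0]) if gqs is not None else 0.0
                        ),
                        read_depth=int(dps[i][0]) if dps is not None else 0,
                    )
                yield VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    site_quality=qual,
                    calls=calls,
                )
        except (ValueError, TypeError, IndexError) as exc:
            n_skipped += 1
            logger.warning(
                "skipping unparsable record %s:%s (%s)", var.CHROM, var.POS, exc
            )
    if n_skipped:
        logger.warning("skipped %d unparsable records", n_skipped)


def qc_pass(
    call: GenotypeCall | None,
    site_quality: float,
    thresholds: QCThresholds = QCThresholds(),
) -> bool:
    """Inclusive per-genotype quality filter; missing calls never pass."""
    if call is None or call.allele_count is None:
        return False
    return (
        site_quality >= thresholds.min_site_quality
        and call.genotype_quality >= thresholds.min_genotype_quality
        and call.read_depth >= thresholds.min_read_depth
    )


def apply_repeat_mask(
    variants: Iterable[VariantRecord], mask: RepeatMask
) -> Iterator[VariantRecord]:
    """Drop records whose POS anchor base lies inside a masked interval."""
    for v in variants:
        if not mask.contains(v.chrom, v.pos):
            yield v


def write_variants(
    records: Iterable[VariantRecord],
    path: str | Path,
    samples: list[str],
    extra_header: str = "",
) -> None:
    """Write records back to a minimal VCF 4.2 with GT:GQ:DP fields."""
    gt_strings = {None: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if extra_header:
            fh.write(extra_header)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in records:
            fields = [
                rec.chrom,
                str(rec.pos),
                ".",
                rec.ref,
                rec.alt,
                f"{rec.site_quality:g}",
                ".",
                ".",
                "GT:GQ:DP",
            ]
            for s in samples:
                call = rec.calls.get(s)
                if call is None:
                    fields.append("./.:0:0")
                else:
                    fields.append(
                        f"{gt_strings[call.allele_count]}:"
                        f"{int(call.genotype_quality)}:{call.read_depth}"
                    )
            fh.write("\t".join(fields) + "\n")
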