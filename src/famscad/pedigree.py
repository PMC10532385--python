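"""Pedigree structures, affection spectra, and obligate-carrier inference.

Families are modelled as directed parent graphs. Co-segregation under an
autosomal-dominant model requires a risk allele to be present in every
affected family member and in every *obligate carrier*: an unaffected
individual who must transmit the allele under any single-founder origin
consistent with the observed carriers (e.g. the unaffected parent linking
two affected first cousins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "Individual",
    "PedigreeGraph",
    "PedigreeError",
    "parse_pedigree",
    "obligate_carriers",
    "affected_set",
    "NoCommonOriginWarning",
]

Affection = Literal["scad", "arteriopathy", "unaffected", "unknown"]
Sex = Literal["female", "male", "unknown"]

_SEX_CODES = {"0": "unknown", "1": "male", "2": "female"}
_AFFECTION_CODES = {"0": "unknown", "1": "unaffected", "2": "scad", "3": "arteriopathy"}


class PedigreeError(ValueError):
    """Malformed pedigree file or structurally invalid family."""


class NoCommonOriginWarning(UserWarning):
    """No single-founder transmission assignment covers all assumed carriers."""


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = "unknown"
    affection: Affection = "unknown"
    clinical_features: frozenset[str] = field(default_factory=frozenset)
    event_ages: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.event_ages):
            raise PedigreeError(
                f"{self.individual_id}: event ages must be strictly positive"
            )
        if list(self.event_ages) != sorted(self.event_ages):
            raise PedigreeError(
                f"{self.individual_id}: event ages must be non-decreasing"
            )

    @property
    def first_event_age(self) -> float | None:
        return self.event_ages[0] if self.event_ages else None


class PedigreeGraph:
    """One family: members plus child -> (father, mother) links."""

    def __init__(self, family_id: str, members: Iterable[Individual]):
        self.family_id = family_id
        self.members: dict[str, Individual] = {}
        for ind in members:
            if ind.individual_id in self.members:
                raise PedigreeError(
                    f"{family_id}: duplicate individual {ind.individual_id!r}"
                )
            self.members[ind.individual_id] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self.members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.members:
                    raise PedigreeError(
                        f"{self.family_id}: {ind.individual_id} references "
                        f"missing parent {pid!r}"
                    )
        # parent links must be acyclic
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                raise PedigreeError(f"{self.family_id}: cycle through {iid!r}")
            if state.get(iid) == 2:
                return
            state[iid] = 1
            for pid in self.parents(iid):
                visit(pid)
            state[iid] = 2

        for iid in self.members:
            visit(iid)

    def parents(self, individual_id: str) -> tuple[str, ...]:
        ind = self.members[individual_id]
        return tuple(p for p in (ind.father_id, ind.mother_id) if p is not None)

    def children(self, individual_id: str) -> set[str]:
        return {
            i.individual_id
            for i in self.members.values()
            if individual_id in (i.father_id, i.mother_id)
        }

    def founders(self) -> set[str]:
        return {iid for iid in self.members if not self.parents(iid)}

    def edges(self) -> list[tuple[str, str]]:
        """(child, parent) pairs, one per recorded parent link."""
        return [
            (iid, pid) for iid in sorted(self.members) for pid in self.parents(iid)
        ]

    def descendants(self, individual_id: str) -> set[str]:
        out: set[str] = set()
        stack = [individual_id]
        while stack:
            for child in self.children(stack.pop()):
                if child not in out:
                    out.add(child)
                    stack.append(child)
        return out

    def __len__(self) -> int:
        return len(self.members)

    def __repr__(self) -> str:
        return f"PedigreeGraph({self.family_id!r}, n={len(self)})"


def _parse_ages(tok: str, line_no: int) -> tuple[float, ...]:
    if tok in (".", "-", ""):
        return ()
    try:
        return tuple(float(a) for a in tok.split(",") if a not in ("", ".", "Unk"))
    except ValueError as exc:
        raise PedigreeError(f"line {line_no}: bad event ages {tok!r}") from exc


def parse_pedigree(path: str | Path) -> list[PedigreeGraph]:
    """Parse a PED-like file into one :class:`PedigreeGraph` per family.

    Columns (whitespace/tab-delimited): family_id, individual_id, father_id
    (0 = unknown), mother_id (0 = unknown), sex (1=male, 2=female,
    0=unknown), affection (0=unknown, 1=unaffected, 2=SCAD, 3=other
    arteriopathy); optional column 7: comma-separated clinical feature
    codes ('.' = none); optional column 8: comma-separated event ages.
    """
    by_family: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise PedigreeError(
                    f"line {line_no}: expected >= 6 columns, got {len(cols)}"
                )
            fam, iid, fid, mid, sex_code, aff_code = cols[:6]
            if sex_code not in _SEX_CODES:
                raise PedigreeError(f"line {line_no}: bad sex code {sex_code!r}")
            if aff_code not in _AFFECTION_CODES:
                raise PedigreeError(f"line {line_no}: bad affection code {aff_code!r}")
            features: frozenset[str] = frozenset()
            if len(cols) >= 7 and cols[6] not in (".", "-"):
                features = frozenset(cols[6].split(","))
            ages: tuple[float, ...] = ()
            if len(cols) >= 8:
                ages = _parse_ages(cols[7], line_no)
            by_family.setdefault(fam, []).append(
                Individual(
                    individual_id=iid,
                    family_id=fam,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=_SEX_CODES[sex_code],
                    affection=_AFFECTION_CODES[aff_code],
                    clinical_features=features,
                    event_ages=ages,
                )
            )
    return [PedigreeGraph(fam, members) for fam, members in by_family.items()]


def affected_set(
    ped: PedigreeGraph,
    spectrum: Literal["scad_only", "scad_plus_arteriopathy"] = "scad_plus_arteriopathy",
) -> set[str]:
    """Individuals in the affected spectrum used for co-segregation.

    ``scad_plus_arteriopathy`` (the default) also counts relatives with an
    extra-coronary arteriopathy as affected, since those relatives were
    genotyped as part of the affected set.
    """
    classes = {"scad"} if spectrum == "scad_only" else {"scad", "arteriopathy"}
    return {iid for iid, ind in ped.members.items() if ind.affection in classes}


def _path_exists(
    ped: PedigreeGraph, src: str, dst: str, excluded: str | None = None
) -> bool:
    """Is there a parent-to-child transmission path src -> ... -> dst?"""
    if src == excluded or dst == excluded:
        return False
    if src == dst:
        return True
    stack = [src]
    seen = {src}
    while stack:
        for child in ped.children(stack.pop()):
            if child == excluded or child in seen:
                continue
            if child == dst:
                return True
            seen.add(child)
            stack.append(child)
    return False


def obligate_carriers(
    ped: PedigreeGraph, carriers_assumed: set[str]
) -> set[str]:
    """Unaffected individuals who must carry the allele.

    Assumes a single founder origin within the family. An individual is
    obligate iff, for every founder origin consistent with all assumed
    carriers carrying, it lies on every transmission path from the origin
    to some assumed carrier. Affected and unknown-affection individuals are
    never reported.

    If no single-founder origin can reach all assumed carriers, a
    :class:`NoCommonOriginWarning` is emitted and the empty set returned.
    """
    if not carriers_assumed:
        raise ValueError("carriers_assumed must be non-empty")
    missing = carriers_assumed - set(ped.members)
    if missing:
        raise ValueError(f"unknown individuals: {sorted(missing)}")

    founders = ped.founders()
    assumed_founders = carriers_assumed & founders
    if len(assumed_founders) > 1:
        warnings.warn(
            f"{ped.family_id}: assumed carriers include {len(assumed_founders)} "
            "founders; no single-founder origin exists",
            NoCommonOriginWarning,
        )
        return set()

    # candidate origins: founders that can transmit to every assumed carrier
    if assumed_founders:
        candidates = list(assumed_founders)
    else:
        candidates = sorted(founders)
    origins = [
        f
        for f in candidates
        if all(_path_exists(ped, f, c) for c in carriers_assumed)
    ]
    if not origins:
        warnings.warn(
            f"{ped.family_id}: no common single-founder origin for "
            f"{sorted(carriers_assumed)}",
            NoCommonOriginWarning,
        )
        return set()

    result: set[str] | None = None
    for origin in origins:
        # forced under this origin: individuals that every transmission
        # path from the origin to some assumed carrier must pass through
        forced = {origin} | set(carriers_assumed)
        for x in ped.members:
            if x in forced:
                continue
            if any(
                not _path_exists(ped, origin, c, excluded=x)
                for c in carriers_assumed
            ):
                forced.add(x)
        result = forced if result is None else result & forced

    assert result is not None
    return {
        iid
        for iid in result - carriers_assumed
        if ped.members[iid].affection == "unaffected"
    }
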