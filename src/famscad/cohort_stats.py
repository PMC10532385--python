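"""Cohort demographic and clinical summaries plus two-group proportion tests.

Age statistics use the first recorded event/diagnosis age per individual
(recurrent cases contribute only their first event). Individuals with an
unknown age are excluded from age statistics but still counted. Clinical
feature counts are tallied over SCAD-affected individuals; relatives whose
only finding is an extra-coronary arteriopathy are represented by their
affection class instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter
from typing import Iterable, NamedTuple

import numpy as np
from scipy import stats

from .pedigree import Individual

__all__ = ["CohortSummary", "summarize_cohort", "compare_proportions"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CohortSummary:
    n_total: int  # affected-spectrum individuals (SCAD or arteriopathy)
    n_with_scad: int
    n_female: int
    pct_female: int
    mean_age_first_scad: float | None
    sd_age_first_scad: float | None
    age_range_scad: tuple[float, float] | None
    mean_age_diagnosis_all: float | None
    sd_age_diagnosis_all: float | None
    age_range_all: tuple[float, float] | None
    feature_counts: dict[str, int]
    n_recurrent_families: int

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def _age_stats(
    ages: list[float],
) -> tuple[float | None, float | None, tuple[float, float] | None]:
    if not ages:
        return None, None, None
    mean = round(float(np.mean(ages)), 1)
    sd = round(float(np.std(ages, ddof=1)), 1) if len(ages) >= 2 else None
    return mean, sd, (min(ages), max(ages))


def summarize_cohort(individuals: Iterable[Individual]) -> CohortSummary:
    """Demographic/clinical summary over the affected-spectrum individuals.

    Unaffected or unknown-affection members (e.g. inferred connecting
    parents) are ignored. Means and SDs (sample, n-1) are reported to one
    decimal; the female percentage is rounded half-up to an integer.
    """
    affected = [
        ind for ind in individuals if ind.affection in ("scad", "arteriopathy")
    ]
    scad = [ind for ind in affected if ind.affection == "scad"]

    scad_ages = [i.first_event_age for i in scad if i.first_event_age is not None]
    all_ages = [i.first_event_age for i in affected if i.first_event_age is not None]

    mean_s, sd_s, range_s = _age_stats(scad_ages)
    mean_a, sd_a, range_a = _age_stats(all_ages)

    features: Counter[str] = Counter()
    for ind in scad:
        features.update(ind.clinical_features - {"SCAD"})

    n_female = sum(1 for i in affected if i.sex == "female")
    recurrent_families = {
        i.family_id for i in scad if "R" in i.clinical_features
    }

    return CohortSummary(
        n_total=len(affected),
        n_with_scad=len(scad),
        n_female=n_female,
        pct_female=_round_half_up(100.0 * n_female / len(affected)) if affected else 0,
        mean_age_first_scad=mean_s,
        sd_age_first_scad=sd_s,
        age_range_scad=range_s,
        mean_age_diagnosis_all=mean_a,
        sd_age_diagnosis_all=sd_a,
        age_range_all=range_a,
        feature_counts=dict(features),
        n_recurrent_families=len(recurrent_families),
    )


class ProportionTest(NamedTuple):
    statistic: float
    p_value: float
    method: str  # "chi2" or "fisher_exact"


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> ProportionTest:
    """Compare k1/n1 against k2/n2 on a 2x2 table.

    Pearson chi-square without continuity correction; falls back to
    Fisher's exact test when any expected cell count is below 5.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("require 0 <= k <= n for both groups")
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate margin: empty group")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table.sum(axis=0).min() == 0:
        # all successes or all failures in both groups: no association testable
        return ProportionTest(0.0, 1.0, "chi2")
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        odds, p = stats.fisher_exact(table)
        return ProportionTest(float(odds), float(p), "fisher_exact")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ProportionTest(float(chi2), float(p), "chi2")
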