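"""Genotype-phenotype segregation: hearing classes, cross tables, penetrance,
and exact tests for Mendelian ratios and homozygote deficit.

Hearing phenotype is defined from the auditory-brainstem-response (ABR) click
threshold: animals at or above 50 dB SPL are affected, at or below 30 dB SPL
unaffected, and the open interval in between is an intermediate class (both
endpoints are claimed by the neighbouring classes, so the three classes
partition the threshold axis). Penetrance is the fraction of carriers of a
genotype that fall in a chosen set of phenotype classes, with a Wilson score
interval for its uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError, ParameterError
from .variants import COHORT_GENOTYPES, CohortRecord

AFFECTED_MIN = 50.0  # dB SPL, inclusive
UNAFFECTED_MAX = 30.0  # dB SPL, inclusive

HEARING_CLASSES = ("unaffected", "intermediate", "affected")


def classify_hearing(
    threshold: float,
    affected_min: float = AFFECTED_MIN,
    unaffected_max: float = UNAFFECTED_MAX,
) -> str:
    """Assign a click threshold (dB SPL) to a hearing class."""
    if not np.isfinite(threshold):
        raise DataError(f"click threshold {threshold!r} is not finite")
    if threshold >= affected_min:
        return "affected"
    if threshold <= unaffected_max:
        return "unaffected"
    return "intermediate"


@dataclass
class CrossTable:
    """Genotype x hearing-class counts for one cross type.

    ``counts`` is indexed by genotype (wt/het/hom) with hearing-class columns;
    row percentages are of the cross grand total (as are column percentages),
    matching how such segregation tables are conventionally printed. Per-cell
    sex counts are carried alongside but never tested.
    """

    cross_type: str
    counts: pd.DataFrame
    sex_counts: pd.DataFrame | None = None

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def row_percent(self, genotype: str) -> float:
        """Percent of all offspring with this genotype (one-decimal rounding)."""
        if self.grand_total == 0:
            return 0.0
        return round(100.0 * self.row_totals[genotype] / self.grand_total, 1)

    def column_percent(self, hearing_class: str) -> float:
        if self.grand_total == 0:
            return 0.0
        return round(100.0 * self.column_totals[hearing_class] / self.grand_total, 1)

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        df["total"] = self.row_totals
        df["percent"] = [self.row_percent(g) for g in df.index]
        return df


def build_cross_table(cohort: Iterable[CohortRecord], cross_type: str) -> CrossTable:
    """Tabulate genotype x hearing class for one cross type."""
    counts = pd.DataFrame(
        0, index=list(COHORT_GENOTYPES), columns=list(HEARING_CLASSES), dtype=int
    )
    sexes = pd.DataFrame(
        "", index=list(COHORT_GENOTYPES), columns=list(HEARING_CLASSES), dtype=object
    )
    tally: dict[tuple[str, str], list[int]] = {}
    for rec in cohort:
        if rec.cross_type != cross_type:
            continue
        if rec.genotype not in COHORT_GENOTYPES:
            raise DataError(f"unknown genotype {rec.genotype!r}")
        cls = classify_hearing(rec.click_threshold)
        counts.loc[rec.genotype, cls] += 1
        m_f = tally.setdefault((rec.genotype, cls), [0, 0])
        if rec.sex == "m":
            m_f[0] += 1
        elif rec.sex == "f":
            m_f[1] += 1
    for (g, cls), (m, f) in tally.items():
        sexes.loc[g, cls] = f"{m}/{f}"
    return CrossTable(cross_type=cross_type, counts=counts, sex_counts=sexes)


@dataclass(frozen=True)
class PenetranceEstimate:
    """A proportion of carriers expressing the phenotype, with a 95% Wilson CI."""

    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> float:
        return round(100.0 * self.proportion, 1)


def penetrance(
    cohort: Iterable[CohortRecord],
    genotype: str = "het",
    affected_classes: Sequence[str] = ("affected",),
    cross_types: Sequence[str] | None = None,
) -> PenetranceEstimate:
    """Penetrance of the phenotype among carriers of ``genotype``.

    By default carriers are pooled across cross types. ``affected_classes``
    selects which hearing classes count as expressing the phenotype (e.g.
    include ``intermediate`` to count mildly affected animals).
    """
    bad = set(affected_classes) - set(HEARING_CLASSES)
    if bad:
        raise ParameterError(f"unknown hearing classes {sorted(bad)}")
    num = den = 0
    for rec in cohort:
        if cross_types is not None and rec.cross_type not in cross_types:
            continue
        if rec.genotype != genotype:
            continue
        den += 1
        if classify_hearing(rec.click_threshold) in affected_classes:
            num += 1
    if den == 0:
        raise ParameterError(f"no {genotype!r} carriers: penetrance undefined")
    lo, hi = proportion_confint(num, den, alpha=0.05, method="wilson")
    return PenetranceEstimate(num, den, num / den, float(lo), float(hi))


def homozygote_deficit_test(
    n_offspring: int, n_hom: int, expected_fraction: float = 0.25
) -> float:
    """One-sided exact binomial tail: P(X <= n_hom) under Mendelian expectation.

    A small p-value indicates fewer homozygotes than a viable-homozygote
    intercross would produce, i.e. reduced homozygote viability.
    """
    if not 0.0 < expected_fraction < 1.0:
        raise ParameterError(f"expected_fraction {expected_fraction} outside (0, 1)")
    if not 0 <= n_hom <= n_offspring:
        raise ParameterError(f"need 0 <= n_hom <= n_offspring, got {n_hom}/{n_offspring}")
    if n_offspring == 0:
        return 1.0
    return float(stats.binom.cdf(n_hom, n_offspring, expected_fraction))


def _compositions(n: int, k: int):
    """All k-tuples of non-negative integers summing to n."""
    for cuts in combinations(range(n + k - 1), k - 1):
        prev = -1
        parts = []
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(n + k - 2 - prev)
        yield tuple(parts)


def mendelian_ratio_test(
    observed: Sequence[int],
    expected_ratio: Sequence[float],
    exact_max_n: int = 200,
) -> float:
    """Goodness of fit of genotype counts to a Mendelian ratio.

    Exact multinomial test (sum of outcome probabilities no larger than the
    observed outcome's) when the total count is at most ``exact_max_n``,
    otherwise a chi-square goodness-of-fit test.
    """
    observed = [int(x) for x in observed]
    if any(x < 0 for x in observed):
        raise ParameterError("observed counts must be non-negative")
    if len(observed) != len(expected_ratio):
        raise ParameterError("observed and expected_ratio lengths differ")
    if any(r <= 0 for r in expected_ratio):
        raise ParameterError("expected ratio cells must be positive")
    n = sum(observed)
    if n == 0:
        return 1.0
    p = np.asarray(expected_ratio, dtype=float)
    p = p / p.sum()

    if n <= exact_max_n and comb(n + len(p) - 1, len(p) - 1) <= 500_000:
        dist = stats.multinomial(n, p)
        p_obs = dist.pmf(observed)
        total = 0.0
        for outcome in _compositions(n, len(p)):
            q = dist.pmf(outcome)
            if q <= p_obs * (1 + 1e-9):
                total += q
        return float(min(total, 1.0))
    chi2 = stats.chisquare(observed, f_exp=n * p)
    return float(chi2.pvalue)
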