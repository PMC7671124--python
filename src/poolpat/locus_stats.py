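"""Marker-panel diagnostics for codominant microsatellite loci.

Computes, per locus, the summary statistics a parentage study reports before
trusting a panel: allele frequencies, observed/expected heterozygosity, a
chi-square goodness-of-fit test against Hardy–Weinberg genotype proportions,
a moment estimate of null-allele frequency, and parent-exclusion
probabilities, combined across loci as 1 − Π(1 − P_l).

Exclusion probabilities are defined operationally.  P_excl (no parent known)
is the probability that a random unrelated individual shares no allele with
a random offspring of a random HWE mating, and hence could not be either of
its parents.  With the true mother known, a candidate sire is excluded when
it carries none of the alleles that could have been the paternal
contribution; P_excl (one parent known) is that probability for a random
unrelated candidate.  Both are implemented twice — a direct closed-form
summation and a brute-force enumeration over all genotype configurations —
and the two routes are required to agree to machine precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .msat_data import AdultGenotype, Locus

logger = logging.getLogger("poolpat")


class NoDataAtLocusError(ValueError):
    """No adult in the sample is typed at the requested locus."""


@dataclass(frozen=True)
class AlleleFrequencies:
    """Sample allele frequencies at one locus.

    ``n_adults_typed`` is the number of adults with a genotype call, so
    frequencies are counts over ``2 * n_adults_typed`` gene copies.
    """

    locus: Locus
    freqs: dict[int, float]
    n_adults_typed: int

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {total}, not 1")
        if any(f <= 0 for f in self.freqs.values()):
            raise ValueError("every listed allele must have frequency > 0")

    @property
    def alleles(self) -> list[int]:
        return sorted(self.freqs)

    def as_array(self) -> np.ndarray:
        return np.array([self.freqs[a] for a in self.alleles])


class HweResult(NamedTuple):
    chi2: float
    df: int
    p: float  # NaN when the test is not computable


@dataclass(frozen=True)
class LocusSummary:
    locus: Locus
    Na: int
    N: int
    Ho: float
    He: float
    hwe_p: float
    hwe_p_bonferroni: float
    Fnull: float
    Pexcl_no_parent: float
    Pexcl_one_parent: float


@dataclass(frozen=True)
class PanelSummary:
    per_locus: list[LocusSummary]
    combined_Pexcl_no_parent: float
    combined_Pexcl_one_parent: float


# ---------------------------------------------------------------------------
# Frequencies and heterozygosity
# ---------------------------------------------------------------------------

def _typed(adults: Iterable[AdultGenotype], locus_name: str) -> list[tuple[int, int]]:
    return [a.calls[locus_name] for a in adults if locus_name in a.calls]


def allele_frequencies(adults: Sequence[AdultGenotype], locus: Locus) -> AlleleFrequencies:
    """Count-based allele frequencies over the typed adults' gene copies."""
    calls = _typed(adults, locus.name)
    if not calls:
        raise NoDataAtLocusError(f"no adult typed at locus {locus.name!r}")
    counts: dict[int, int] = {}
    for a, b in calls:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    n2 = 2 * len(calls)
    return AlleleFrequencies(
        locus=locus,
        freqs={allele: c / n2 for allele, c in sorted(counts.items())},
        n_adults_typed=len(calls),
    )


def heterozygosities(adults: Sequence[AdultGenotype], locus: Locus) -> tuple[float, float]:
    """Observed and unbiased expected heterozygosity.

    Ho is the fraction of typed adults carrying two distinct alleles.
    He uses the small-sample-corrected estimator
    ``(2N / (2N - 1)) * (1 - sum p_i^2)``.
    """
    calls = _typed(adults, locus.name)
    n = len(calls)
    if n < 2:
        raise ValueError(f"locus {locus.name!r}: He requires >=2 typed adults, got {n}")
    ho = sum(1 for a, b in calls if a != b) / n
    p = allele_frequencies(adults, locus).as_array()
    he = (2 * n) / (2 * n - 1) * (1.0 - float(np.sum(p * p)))
    return ho, he


def null_allele_frequency(adults: Sequence[AdultGenotype], locus: Locus) -> float:
    """Moment estimate of null-allele frequency from homozygote excess.

    ``Fnull = (He - Ho) / (He + Ho)``: a non-amplifying allele hides
    heterozygotes as apparent homozygotes, depressing Ho below He.  The
    estimate can be negative when the sample shows heterozygote excess.
    """
    ho, he = heterozygosities(adults, locus)
    if he + ho == 0:
        logger.warning("locus %s: He + Ho = 0; Fnull undefined, returning 0", locus.name)
        return 0.0
    return (he - ho) / (he + ho)


# ---------------------------------------------------------------------------
# Hardy–Weinberg goodness of fit
# ---------------------------------------------------------------------------

def hwe_test(
    adults: Sequence[AdultGenotype], locus: Locus, min_expected: float = 1.0
) -> HweResult:
    """Chi-square goodness of fit of genotype counts to HWE proportions.

    Expected counts come from the sample allele frequencies.  Genotype
    classes with expected count below ``min_expected`` are pooled, lowest
    expected first, into a single "rare" class until every class (including
    the pooled one) meets the threshold.  Degrees of freedom are
    ``n_classes - n_alleles`` (floored at 1), and the Yates continuity
    correction is applied when df = 1.  The returned p-value is uncorrected;
    apply a Bonferroni factor panel-wide (see :func:`panel_summary`).
    """
    calls = _typed(adults, locus.name)
    n = len(calls)
    if n < 5:
        raise ValueError(f"locus {locus.name!r}: HWE test requires >=5 typed adults")
    af = allele_frequencies(adults, locus)
    alleles = af.alleles
    k = len(alleles)

    observed: dict[tuple[int, int], int] = {}
    for pair in calls:
        observed[pair] = observed.get(pair, 0) + 1

    classes = []
    for i, j in combinations_with_replacement(range(k), 2):
        a, b = alleles[i], alleles[j]
        pi, pj = af.freqs[a], af.freqs[b]
        exp = n * (pi * pi if i == j else 2 * pi * pj)
        classes.append([exp, observed.get((a, b), 0)])

    # pool lowest-expected classes until all >= min_expected
    classes.sort(key=lambda c: c[0])
    while len(classes) >= 2 and classes[0][0] < min_expected:
        e0, o0 = classes.pop(0)
        e1, o1 = classes.pop(0)
        classes.append([e0 + e1, o0 + o1])
        classes.sort(key=lambda c: c[0])

    if len(classes) < 2:
        logger.warning("locus %s: HWE test not computable after pooling", locus.name)
        return HweResult(math.nan, 0, math.nan)

    df = max(len(classes) - k, 1)
    yates = 0.5 if df == 1 else 0.0
    chi2 = sum(
        (max(abs(o - e) - yates, 0.0)) ** 2 / e for e, o in classes
    )
    p = float(stats.chi2.sf(chi2, df))
    return HweResult(chi2, df, p)


# ---------------------------------------------------------------------------
# Exclusion probabilities
# ---------------------------------------------------------------------------

def _freq_array(freqs: AlleleFrequencies) -> np.ndarray:
    return freqs.as_array()


def _paternal_allele_set(mother: tuple[int, int], offspring: tuple[int, int]) -> set[int]:
    """Alleles of the offspring that could be the paternal contribution,
    given the maternal genotype: x is a possible paternal allele when the
    complementary offspring allele is carried by the mother."""
    x, y = offspring
    s: set[int] = set()
    if y in mother:
        s.add(x)
    if x in mother:
        s.add(y)
    return s


def exclusion_probabilities(freqs: AlleleFrequencies) -> tuple[float, float]:
    """Closed-form single-locus exclusion probabilities (P1, P2).

    P1 — no parent known: a random candidate is excluded when it shares no
    allele with the offspring, so conditioning on the offspring genotype,

        P1 = sum_i p_i^2 (1 - p_i)^2  +  sum_{i<j} 2 p_i p_j (1 - p_i - p_j)^2.

    P2 — mother known: conditioning on (mother, offspring), the candidate is
    excluded when it carries none of the possible paternal alleles S, an
    event of probability ``(1 - sum_{a in S} p_a)^2``; P2 averages this over
    HWE mothers, Mendelian maternal transmission, and an HWE paternal allele.

    A fixed single-allele locus excludes nobody: (0, 0).
    """
    p = _freq_array(freqs)
    alleles = freqs.alleles
    k = len(alleles)
    if k == 1:
        return 0.0, 0.0

    p1 = float(np.sum(p**2 * (1 - p) ** 2))
    for i in range(k):
        for j in range(i + 1, k):
            p1 += 2 * p[i] * p[j] * (1 - p[i] - p[j]) ** 2

    p2 = 0.0
    index = {a: idx for idx, a in enumerate(alleles)}
    for i in range(k):
        for j in range(i, k):
            w_m = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            mother = (alleles[i], alleles[j])
            # Mendelian maternal transmission (a homozygote transmits its
            # single distinct allele with certainty)
            transmissions = [(i, 1.0)] if i == j else [(i, 0.5), (j, 0.5)]
            for m_idx, w_t in transmissions:
                for f in range(k):
                    off = (alleles[m_idx], alleles[f])
                    s = _paternal_allele_set(mother, off)
                    ps = sum(p[index[a]] for a in s)
                    p2 += w_m * w_t * p[f] * (1.0 - ps) ** 2
    return p1, p2


def exclusion_probabilities_enumeration(freqs: AlleleFrequencies) -> tuple[float, float]:
    """Brute-force oracle for :func:`exclusion_probabilities`.

    Enumerates mother x father x maternal transmission x paternal
    transmission x candidate genotype, weighting each configuration by its
    HWE/Mendelian probability, and counts exclusion events directly.
    Exponential in nothing but allele count; intended for <=8 alleles.
    """
    p = _freq_array(freqs)
    k = len(p)
    if k == 1:
        return 0.0, 0.0
    genotypes = [(i, j) for i in range(k) for j in range(k)]  # ordered, weight p_i p_j
    p1 = 0.0
    p2 = 0.0
    for mi, mj in genotypes:
        w_mother = p[mi] * p[mj]
        for fi, fj in genotypes:
            w_father = p[fi] * p[fj]
            for m_allele in (mi, mj):
                for f_allele in (fi, fj):
                    w_off = w_mother * w_father * 0.25
                    off = {m_allele, f_allele}
                    # candidate excluded as (either) parent: no shared allele
                    for ci, cj in genotypes:
                        w_c = p[ci] * p[cj]
                        if ci not in off and cj not in off:
                            p1 += w_off * w_c
                    # mother known: candidate must carry a possible paternal allele
                    s = _paternal_allele_set(
                        (mi, mj), (m_allele, f_allele)
                    )
                    for ci, cj in genotypes:
                        w_c = p[ci] * p[cj]
                        if ci not in s and cj not in s:
                            p2 += w_off * w_c
    return p1, p2


def combined_exclusion(per_locus: Sequence[float]) -> float:
    """Multi-locus exclusion probability, 1 - prod(1 - P_l)."""
    out = 1.0
    for pl in per_locus:
        out *= 1.0 - pl
    return 1.0 - out


# ---------------------------------------------------------------------------
# Panel summary
# ---------------------------------------------------------------------------

def summarize_locus(
    adults: Sequence[AdultGenotype], locus: Locus, n_loci_for_bonferroni: int = 1
) -> LocusSummary:
    af = allele_frequencies(adults, locus)
    ho, he = heterozygosities(adults, locus)
    hwe = hwe_test(adults, locus)
    fnull = null_allele_frequency(adults, locus)
    p1, p2 = exclusion_probabilities(af)
    return LocusSummary(
        locus=locus,
        Na=len(af.freqs),
        N=af.n_adults_typed,
        Ho=ho,
        He=he,
        hwe_p=hwe.p,
        hwe_p_bonferroni=min(hwe.p * n_loci_for_bonferroni, 1.0)
        if not math.isnan(hwe.p)
        else math.nan,
        Fnull=fnull,
        Pexcl_no_parent=p1,
        Pexcl_one_parent=p2,
    )


def panel_summary(
    adults: Sequence[AdultGenotype], loci: Sequence[Locus]
) -> PanelSummary:
    """Per-locus summaries plus combined exclusion probabilities.

    A locus whose statistics cannot be computed (too few typed adults)
    contributes an all-NaN row and is dropped from the combined exclusion
    product rather than aborting the panel.
    """
    if not loci:
        raise ValueError("panel_summary requires >=1 locus")
    rows: list[LocusSummary] = []
    for locus in loci:
        try:
            rows.append(summarize_locus(adults, locus, n_loci_for_bonferroni=len(loci)))
        except (ValueError, NoDataAtLocusError) as exc:
            logger.warning("locus %s: %s; reporting NA row", locus.name, exc)
            rows.append(
                LocusSummary(
                    locus=locus, Na=0, N=0, Ho=math.nan, He=math.nan,
                    hwe_p=math.nan, hwe_p_bonferroni=math.nan, Fnull=math.nan,
                    Pexcl_no_parent=math.nan, Pexcl_one_parent=math.nan,
                )
            )
    valid = [r for r in rows if r.Na > 0]
    return PanelSummary(
        per_locus=rows,
        combined_Pexcl_no_parent=combined_exclusion([r.Pexcl_no_parent for r in valid]),
        combined_Pexcl_one_parent=combined_exclusion([r.Pexcl_one_parent for r in valid]),
    )
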