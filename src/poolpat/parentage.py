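"""Sire-number estimation and monogamy classification from pooled broods.

Because a brood is genotyped as a pool, each locus yields only the set of
alleles segregating among the offspring.  Alleles absent from the known
mother must have come from sires, so the number of non-maternal alleles per
locus bounds the number of sires from below:

* conservative — every sire assumed heterozygous, contributing up to two
  distinct non-maternal alleles: ``ceil(k / 2)`` sires for ``k``
  non-maternal alleles;
* liberal — every sire assumed homozygous, contributing one: ``k`` sires.

The mass-level estimate is the maximum over informative loci (sire alleles
at different loci come from the same sires, so loci are not additive), and
is floored at one: a brood exists, so at least one sire does.

When the mother was never genotyped, the two alleles that explain the most
of the brood set are assumed maternal: ``k = max(0, |set| - 2)``.

For a mass produced by a paired individual whose social partner was
genotyped, the brood is classified as consistent with sexual monogamy (MO)
when every brood allele occurs in the mother or the partner, and as
extra-pair (EP) when at least one locus carries an allele found in neither.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Union

from .msat_data import AdultGenotype, EggMassRecord, Panel

#: Sentinel for an unknown (unsampled) maternal genotype.
UNKNOWN = None

#: Sentinel for a locus that contributes no information (NO_DATA).
NA = None


class PairCall(str, Enum):
    MO = "MO"            # consistent with sexual monogamy
    EP = "EP"            # extra-pair paternity
    UNDETERMINED = "UNDETERMINED"  # putative sire not genotyped


@dataclass(frozen=True)
class SireEstimate:
    mass_id: str
    per_locus_nonmaternal: dict[str, Optional[int]]
    min_sires_conservative: int
    sires_liberal: int
    maternal_known: bool

    def __post_init__(self) -> None:
        c, l = self.min_sires_conservative, self.sires_liberal
        if not (1 <= c <= l <= 2 * c):
            raise ValueError(
                f"mass {self.mass_id!r}: sire estimates must satisfy "
                f"1 <= conservative <= liberal <= 2*conservative, got ({c}, {l})"
            )


@dataclass(frozen=True)
class PairClassification:
    mass_id: str
    call: PairCall
    evidence_loci: frozenset[str]       # loci with >=1 allele outside mother ∪ partner
    sire_excluded_loci: frozenset[str]  # loci where the partner explains no required allele


def nonmaternal_alleles(
    mass_alleles: Optional[frozenset[int]],
    maternal: Union[tuple[int, int], None],
) -> Optional[int]:
    """Count brood alleles that cannot be maternal at one locus.

    ``maternal=UNKNOWN`` applies the unknown-mother rule (assume the two
    most-explaining alleles are maternal).  Returns ``NA`` for a locus
    without data.
    """
    if mass_alleles is None:
        return NA
    if maternal is UNKNOWN:
        return max(0, len(mass_alleles) - 2)
    return len(mass_alleles - frozenset(maternal))


def estimate_sires(
    mass: EggMassRecord,
    mother: Union[AdultGenotype, None],
) -> SireEstimate:
    """Minimum-sires estimate for one egg mass under both sire assumptions."""
    per_locus: dict[str, Optional[int]] = {}
    cons: list[int] = []
    lib: list[int] = []
    for locus, aset in mass.alleles.items():
        if mother is not UNKNOWN:
            pair = mother.call(locus)
            k = nonmaternal_alleles(aset, pair if pair is not None else UNKNOWN)
        else:
            k = nonmaternal_alleles(aset, UNKNOWN)
        per_locus[locus] = k
        if k is not NA:
            cons.append(math.ceil(k / 2))
            lib.append(k)
    if not cons:
        raise ValueError(f"mass {mass.mass_id!r}: uninformative (all loci NO_DATA)")
    return SireEstimate(
        mass_id=mass.mass_id,
        per_locus_nonmaternal=per_locus,
        min_sires_conservative=max(1, max(cons)),
        sires_liberal=max(1, max(lib)),
        maternal_known=mother is not UNKNOWN,
    )


def estimate_sires_for_panel(panel: Panel) -> list[SireEstimate]:
    """Apply :func:`estimate_sires` to every mass, resolving mothers by id."""
    out = []
    for mass in panel.masses:
        mother = panel.adult(mass.maternal_id) if mass.maternal_sampled else UNKNOWN
        out.append(estimate_sires(mass, mother))
    return out


def count_multiple_paternity(
    panel: Panel, mode: str = "conservative"
) -> tuple[int, int, float]:
    """(n_multiple, n_total, frequency) of multiply-sired masses."""
    if mode not in ("conservative", "liberal"):
        raise ValueError(f"mode must be 'conservative' or 'liberal', got {mode!r}")
    estimates = estimate_sires_for_panel(panel)
    n_total = len(estimates)
    if mode == "conservative":
        n_multi = sum(1 for e in estimates if e.min_sires_conservative >= 2)
    else:
        n_multi = sum(1 for e in estimates if e.sires_liberal >= 2)
    return n_multi, n_total, (n_multi / n_total if n_total else 0.0)


def classify_pair(
    mass: EggMassRecord,
    mother: AdultGenotype,
    putative_sire: Union[AdultGenotype, None],
) -> PairClassification:
    """Monogamy (MO) vs extra-pair (EP) call for one paired mass.

    EP requires at least one brood allele outside mother ∪ partner at at
    least one locus.  Also reports loci at which the partner is excluded as
    the sole sire: non-maternal alleles exist there, but none of them is
    carried by the partner.
    """
    if putative_sire is UNKNOWN:
        return PairClassification(
            mass_id=mass.mass_id,
            call=PairCall.UNDETERMINED,
            evidence_loci=frozenset(),
            sire_excluded_loci=frozenset(),
        )
    evidence: set[str] = set()
    excluded: set[str] = set()
    for locus, aset in mass.alleles.items():
        if aset is None:
            continue
        mat = mother.alleles(locus)
        if not mat:
            continue
        sire_alleles = putative_sire.alleles(locus)
        if aset - (mat | sire_alleles):
            evidence.add(locus)
        nonmat = aset - mat
        if nonmat and not (nonmat & sire_alleles):
            excluded.add(locus)
    return PairClassification(
        mass_id=mass.mass_id,
        call=PairCall.EP if evidence else PairCall.MO,
        evidence_loci=frozenset(evidence),
        sire_excluded_loci=frozenset(excluded),
    )


def classify_pairs_for_panel(panel: Panel) -> list[PairClassification]:
    """Classify every mass that names a putative sire and has a known mother."""
    out = []
    for mass in panel.masses:
        if mass.putative_sire_id is None or not mass.maternal_sampled:
            continue
        mother = panel.adult(mass.maternal_id)
        if mother is None:
            continue
        sire = panel.adult(mass.putative_sire_id)
        out.append(classify_pair(mass, mother, sire))
    return out


def pair_summary(panel: Panel) -> tuple[int, int, int]:
    """(n_EP, n_MO, n_undetermined) over masses with putative sires."""
    calls = [c.call for c in classify_pairs_for_panel(panel)]
    return (
        calls.count(PairCall.EP),
        calls.count(PairCall.MO),
        calls.count(PairCall.UNDETERMINED),
    )
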