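"""Synthetic mating-system generator with full ground truth.

Emulates the statistical structure of a pair-living, hermaphroditic,
internally fertilizing limpet population typed on a small microsatellite
panel: Hardy–Weinberg adult genotypes on 4 polyallelic loci (4–7 alleles),
a paired/solitary social structure (~75% paired), within-pair and
extra-pair siring of egg masses, Mendelian inheritance into pooled broods
of ~500 embryos, and negative-binomial egg-mass production that differs by
social status and shell length.

Everything downstream of the generator (allele filtering, sire-number
estimation, monogamy classification, PrDM) can therefore be validated
against known truth: which sires produced each mass and how many embryos
each contributed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import parentage
from .msat_data import AdultGenotype, EggMassRecord, Locus, Panel, SocialStatus

_MOTIFS = ("AC", "TAA", "TC", "TTG")


class SynthConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults emulate the study population.

    Sire recruitment per mass: the number of sire slots is drawn from
    ``sires_per_mass_dist``.  For a paired mother the first slot is her
    partner with probability ``p_within_pair_use`` (otherwise an extra-pair
    adult); each further slot is extra-pair with probability
    ``p_extra_pair`` (otherwise the partner again).  Solitary mothers
    recruit only extra-pair sires.  Duplicate recruits collapse to one
    sire.  Embryos are allocated to slots by an equal-probability
    multinomial unless ``mass_skew`` is given.
    """

    seed: int = 0
    n_adults: int = 112
    n_loci: int = 4
    alleles_per_locus: tuple[int, int] = (4, 7)
    dirichlet_alpha: float = 1.0
    prop_paired: float = 0.75
    p_within_pair_use: float = 0.25
    p_extra_pair: float = 1.0
    sires_per_mass_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.8, 2: 0.2}
    )
    mass_skew: Optional[tuple[float, ...]] = None
    n_embryos_pooled: int = 500
    detection_min_count: int = 1
    eggmass_mean_paired: float = 1.57
    eggmass_mean_solitary: float = 0.81
    nb_dispersion: float = 5.0
    shell_length_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"paired": (50.6, 6.9), "solitary": (47.2, 6.0)}
    )
    length_effect_beta: float = 0.0471

    def __post_init__(self) -> None:
        for name in ("prop_paired", "p_within_pair_use", "p_extra_pair"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthConfigError(f"{name} must be in [0, 1], got {v}")
        total = sum(self.sires_per_mass_dist.values())
        if abs(total - 1.0) > 1e-9 or any(
            n < 1 or p < 0 for n, p in self.sires_per_mass_dist.items()
        ):
            raise SynthConfigError("sires_per_mass_dist must be a distribution over n >= 1")
        lo, hi = self.alleles_per_locus
        if not 2 <= lo <= hi:
            raise SynthConfigError("alleles_per_locus must satisfy 2 <= lo <= hi")
        if self.n_embryos_pooled < 1 or self.detection_min_count < 1:
            raise SynthConfigError("embryo and detection counts must be >= 1")
        if self.nb_dispersion <= 0:
            raise SynthConfigError("nb_dispersion must be positive")


@dataclass(frozen=True)
class MassTruth:
    mass_id: str
    maternal_id: str
    sire_ids: tuple[str, ...]
    embryo_counts: dict[str, int]  # per sire, sums to n_embryos_pooled

    @property
    def n_sires(self) -> int:
        return len(self.sire_ids)


@dataclass(frozen=True)
class GroundTruth:
    allele_freqs: dict[str, dict[int, float]]
    partner_of: dict[str, str]
    masses: dict[str, MassTruth] = field(default_factory=dict)


@dataclass(frozen=True)
class Population:
    panel: Panel
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def generate_population(config: SynthConfig, rng: Optional[np.random.Generator] = None) -> Population:
    """Dirichlet allele frequencies, HWE adults, pairing, shell lengths."""
    rng = np.random.default_rng(config.seed) if rng is None else rng

    loci: list[Locus] = []
    freqs: dict[str, dict[int, float]] = {}
    lo, hi = config.alleles_per_locus
    for li in range(config.n_loci):
        motif = _MOTIFS[li % len(_MOTIFS)]
        name = f"L{li + 1:02d}"
        loci.append(Locus(name=name, repeat_motif=motif))
        na = int(rng.integers(lo, hi + 1))
        base = 100 + 40 * li
        alleles = [base + len(motif) * a for a in range(na)]
        p = rng.dirichlet([config.dirichlet_alpha] * na)
        freqs[name] = {a: float(w) for a, w in zip(alleles, p)}

    n_paired = 2 * round(config.n_adults * config.prop_paired / 2)
    n_paired = min(n_paired, config.n_adults - config.n_adults % 2)
    statuses = [SocialStatus.PAIRED] * n_paired + [SocialStatus.SOLITARY] * (
        config.n_adults - n_paired
    )
    partner_of: dict[str, str] = {}
    adults: list[AdultGenotype] = []
    for i, status in enumerate(statuses):
        aid = f"A{i + 1:03d}"
        mu, sd = config.shell_length_params[status.value]
        length = float(np.clip(rng.normal(mu, sd), 1.0, None))
        calls = {}
        for locus in loci:
            f = freqs[locus.name]
            alleles = list(f)
            pair = rng.choice(alleles, size=2, p=list(f.values()))
            calls[locus.name] = (int(pair[0]), int(pair[1]))
        adults.append(
            AdultGenotype(adult_id=aid, social_status=status, shell_length_mm=length, calls=calls)
        )
    for i in range(0, n_paired, 2):
        a, b = adults[i].adult_id, adults[i + 1].adult_id
        partner_of[a] = b
        partner_of[b] = a

    panel = Panel(loci=tuple(loci), adults=tuple(adults))
    return Population(panel=panel, truth=GroundTruth(allele_freqs=freqs, partner_of=partner_of))


# ---------------------------------------------------------------------------
# Egg masses
# ---------------------------------------------------------------------------

def _recruit_sires(
    mother: AdultGenotype,
    population: Population,
    config: SynthConfig,
    rng: np.random.Generator,
) -> list[str]:
    """One sire id per slot (duplicates allowed; collapsed by the caller)."""
    ns = list(config.sires_per_mass_dist)
    ps = [config.sires_per_mass_dist[n] for n in ns]
    n_slots = int(rng.choice(ns, p=ps))
    partner = population.truth.partner_of.get(mother.adult_id)
    pool = [
        a.adult_id
        for a in population.panel.adults
        if a.adult_id not in (mother.adult_id, partner)
    ]
    if not pool:
        raise SynthConfigError("extra-pair sire pool is empty")

    slots: list[str] = []
    for slot in range(n_slots):
        if partner is not None:
            use_partner = (
                rng.random() < config.p_within_pair_use
                if slot == 0
                else rng.random() >= config.p_extra_pair
            )
        else:
            use_partner = False
        slots.append(partner if use_partner else str(rng.choice(pool)))
    return slots


def _pool_mass(
    mother: AdultGenotype,
    sires: Sequence[AdultGenotype],
    counts: Sequence[int],
    config: SynthConfig,
    rng: np.random.Generator,
) -> dict[str, Optional[frozenset[int]]]:
    """Mendelian gene-copy counts per allele; detected above threshold."""
    out: dict[str, Optional[frozenset[int]]] = {}
    n_total = int(sum(counts))
    for locus in mother.calls:
        copy_count: dict[int, int] = {}
        ma, mb = mother.calls[locus]
        n_a = int(rng.binomial(n_total, 0.5))
        copy_count[ma] = copy_count.get(ma, 0) + n_a
        copy_count[mb] = copy_count.get(mb, 0) + (n_total - n_a)
        for sire, c in zip(sires, counts):
            sa, sb = sire.calls[locus]
            k_a = int(rng.binomial(int(c), 0.5))
            copy_count[sa] = copy_count.get(sa, 0) + k_a
            copy_count[sb] = copy_count.get(sb, 0) + (int(c) - k_a)
        detected = frozenset(
            a for a, c in copy_count.items() if c >= config.detection_min_count
        )
        out[locus] = detected if detected else None
    return out


def generate_masses(
    population: Population,
    config: SynthConfig,
    mothers: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[EggMassRecord], GroundTruth]:
    """One pooled egg mass per requested mother (default: every adult).

    Returns the masses plus a GroundTruth carrying the true sires and
    per-sire embryo counts of every mass.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if mothers is None:
        mothers = [a.adult_id for a in population.panel.adults]
    by_id = {a.adult_id: a for a in population.panel.adults}

    masses: list[EggMassRecord] = []
    truths: dict[str, MassTruth] = {}
    for i, mid in enumerate(mothers):
        mother = by_id[mid]
        slots = _recruit_sires(mother, population, config, rng)
        if config.mass_skew is not None:
            if len(config.mass_skew) != len(slots):
                raise SynthConfigError(
                    f"mass_skew has {len(config.mass_skew)} entries but the mass "
                    f"drew {len(slots)} sire slots"
                )
            probs = np.array(config.mass_skew, dtype=float)
        else:
            probs = np.full(len(slots), 1.0 / len(slots))
        slot_counts = rng.multinomial(config.n_embryos_pooled, probs)

        embryo_counts: dict[str, int] = {}
        for sid, c in zip(slots, slot_counts):
            embryo_counts[sid] = embryo_counts.get(sid, 0) + int(c)
        # a slot may draw zero embryos; such a sire contributed nothing
        embryo_counts = {s: c for s, c in embryo_counts.items() if c > 0}
        sire_ids = tuple(sorted(embryo_counts))
        sires = [by_id[s] for s in sire_ids]
        counts = [embryo_counts[s] for s in sire_ids]

        mass_id = f"SM{i + 1:04d}"
        alleles = _pool_mass(mother, sires, counts, config, rng)
        partner = population.truth.partner_of.get(mid)
        masses.append(
            EggMassRecord(
                mass_id=mass_id,
                maternal_id=mid,
                maternal_status=mother.social_status,
                putative_sire_id=partner,
                alleles=alleles,
            )
        )
        truths[mass_id] = MassTruth(
            mass_id=mass_id, maternal_id=mid, sire_ids=sire_ids, embryo_counts=embryo_counts
        )
    truth = replace(population.truth, masses=truths)
    return masses, truth


# ---------------------------------------------------------------------------
# Egg-mass production counts
# ---------------------------------------------------------------------------

def _truncated_nb_mean(mu: float, r: float, cap: int = 2) -> float:
    """E[min(X, cap)] for X ~ NB(mean mu, dispersion r), cap = 2."""
    p0 = float(stats.nbinom.pmf(0, r, r / (r + mu)))
    p1 = float(stats.nbinom.pmf(1, r, r / (r + mu)))
    return p1 + 2.0 * (1.0 - p0 - p1)


def _solve_intercept(
    target_total: float,
    beta: float,
    length_mu: float,
    length_sd: float,
    r: float,
    n_cycles: int,
) -> float:
    """Intercept c such that E_L[n_cycles * E[min(NB(e^{c+beta L}/n_cycles), 2)]]
    equals the target total egg-mass count for that status."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(31)
    lengths = length_mu + length_sd * nodes
    w = weights / weights.sum()

    def expected_total(c: float) -> float:
        mus = np.exp(c + beta * lengths) / n_cycles
        per_cycle = np.array([_truncated_nb_mean(m, r) for m in mus])
        return float(n_cycles * np.sum(w * per_cycle))

    cap = expected_total(12.0)
    if target_total > cap - 1e-9:
        raise SynthConfigError(
            f"target mean {target_total} infeasible under the per-cycle cap of 2 "
            f"(max attainable ~{cap:.3f})"
        )
    return float(optimize.brentq(lambda c: expected_total(c) - target_total, -20.0, 12.0))


def generate_eggmass_counts(
    population: Population,
    config: SynthConfig,
    n_cycles: int = 4,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Total egg masses per adult over ``n_cycles`` reproductive cycles.

    Per-cycle counts are negative binomial on a log link in shell length,
    truncated at 2 masses per cycle (an individual deposits 0–2 masses per
    cycle).  Status-specific intercepts are solved numerically so that the
    status-marginal means (including the truncation) hit the configured
    targets.  Returns a DataFrame with adult_id, status, shell length and
    total count.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    r = config.nb_dispersion
    beta = config.length_effect_beta
    intercepts = {
        "paired": _solve_intercept(
            config.eggmass_mean_paired, beta, *config.shell_length_params["paired"], r, n_cycles
        ),
        "solitary": _solve_intercept(
            config.eggmass_mean_solitary, beta, *config.shell_length_params["solitary"], r, n_cycles
        ),
    }
    rows = []
    for a in population.panel.adults:
        status = a.social_status.value
        if status not in intercepts:
            continue
        mu = math.exp(intercepts[status] + beta * (a.shell_length_mm or 0.0)) / n_cycles
        p = r / (r + mu)
        per_cycle = np.minimum(rng.negative_binomial(r, p, size=n_cycles), 2)
        rows.append(
            {
                "adult_id": a.adult_id,
                "social_status": status,
                "shell_length_mm": a.shell_length_mm,
                "n_egg_masses": int(per_cycle.sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Recovery experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    n_masses: int
    true_multiple_fraction: float
    detected_multiple_fraction_conservative: float
    detected_multiple_fraction_liberal: float
    true_ep_fraction: float        # among masses of paired mothers
    detected_ep_fraction: float
    n_paired_masses: int
    conservative_never_overcounts: bool
    confusion: pd.DataFrame        # true sire count x conservative estimate


def recovery_experiment(
    config: SynthConfig, n_masses: int, rng: Optional[np.random.Generator] = None
) -> RecoveryReport:
    """Generate → estimate → classify, and compare estimates with truth."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    population = generate_population(config, rng=rng)
    mother_ids = rng.choice(
        [a.adult_id for a in population.panel.adults], size=n_masses, replace=True
    )
    masses, truth = generate_masses(population, config, mothers=list(mother_ids), rng=rng)
    panel = replace(population.panel, masses=tuple(masses))

    estimates = parentage.estimate_sires_for_panel(panel)
    true_counts = [truth.masses[e.mass_id].n_sires for e in estimates]
    est_cons = [e.min_sires_conservative for e in estimates]
    est_lib = [e.sires_liberal for e in estimates]

    n_true_multi = sum(1 for t in true_counts if t >= 2)
    n_det_cons = sum(1 for c in est_cons if c >= 2)
    n_det_lib = sum(1 for c in est_lib if c >= 2)

    classifications = parentage.classify_pairs_for_panel(panel)
    n_paired = len(classifications)
    n_ep_det = sum(1 for c in classifications if c.call is parentage.PairCall.EP)
    n_ep_true = 0
    for c in classifications:
        mt = truth.masses[c.mass_id]
        partner = truth.partner_of.get(mt.maternal_id)
        if any(s != partner for s in mt.sire_ids):
            n_ep_true += 1

    confusion = (
        pd.crosstab(
            pd.Series(true_counts, name="true_sires"),
            pd.Series(est_cons, name="estimated_conservative"),
        )
        if n_masses
        else pd.DataFrame()
    )
    return RecoveryReport(
        n_masses=n_masses,
        true_multiple_fraction=n_true_multi / n_masses if n_masses else 0.0,
        detected_multiple_fraction_conservative=n_det_cons / n_masses if n_masses else 0.0,
        detected_multiple_fraction_liberal=n_det_lib / n_masses if n_masses else 0.0,
        true_ep_fraction=n_ep_true / n_paired if n_paired else 0.0,
        detected_ep_fraction=n_ep_det / n_paired if n_paired else 0.0,
        n_paired_masses=n_paired,
        conservative_never_overcounts=all(c <= t for c, t in zip(est_cons, true_counts)),
        confusion=confusion,
    )
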