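"""Probability of detecting multiple paternity (PrDM) for a marker panel.

A brood sired by several individuals is *detected* as multiply sired only
when its pooled allele sets are incompatible with a single sire.  Under the
pooled-brood conservative rule (mother known), that means some locus shows
at least three non-maternal alleles, since one heterozygous sire explains at
most two.  PrDM is the probability of that event given the panel's allele
frequencies, the number of sires, the paternity skew (share of offspring
per sire), and the number of offspring sampled.

Two detection rules are supported, reflecting two study designs:

* ``"pooled"`` — the brood is genotyped as a single pooled DNA extract, so
  only the union of alleles is observed.  Detection requires >=3
  non-maternal alleles at some locus (the conservative minimum-sires rule
  applied to a pool); a sire allele also carried by the mother is invisible.
* ``"individual"`` — each offspring is genotyped separately, the classical
  power-model design.  The paternal allele of an offspring is identifiable
  unless the offspring is heterozygous for two maternal alleles, so
  paternal alleles shared with the mother still count.  Detection means the
  offspring array is incompatible with any single two-allele father at some
  locus: >=3 identified paternal alleles, or two identified paternal
  alleles disjoint from the maternal genotype alongside an ambiguous
  (double-maternal heterozygous) offspring.

The individual rule is strictly more powerful; published power tables for
multi-offspring broods are computed under it.  The pooled rule matches the
inference actually possible on pooled egg-mass extracts.

The main estimator is Monte Carlo over simulated broods: mother and sires
are drawn as Hardy–Weinberg genotypes from the panel frequencies, offspring
are assigned to sires by a multinomial draw over the skew, and each
offspring inherits one uniformly chosen allele from its mother and one from
its sire.  An exact enumeration (:func:`prdm_exact`) over the same
generative model serves as an oracle for small state spaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .locus_stats import AlleleFrequencies


class PrdmConfigError(ValueError):
    """The PrDM configuration is internally inconsistent."""


@dataclass(frozen=True)
class PrdmConfig:
    """Scenario for a PrDM computation.

    ``skew`` gives each sire's expected share of offspring and must sum
    to 1.  ``mother_known`` selects the detection rule: with the maternal
    genotype known, detection requires >=3 non-maternal alleles at some
    locus; without it, >=5 alleles in total at some locus (the two
    most-explaining alleles being attributed to the mother).
    ``mother_genotypes``, when given (one allele pair per locus), fixes the
    maternal genotype instead of drawing it per replicate.  ``detection``
    chooses the study design: ``"pooled"`` (pooled brood extract) or
    ``"individual"`` (each offspring genotyped separately; requires
    ``mother_known``).
    """

    freqs: tuple[AlleleFrequencies, ...]
    n_sires: int
    skew: tuple[float, ...]
    n_offspring: int
    seed: int
    mother_known: bool = True
    n_replicates: int = 20_000
    mother_genotypes: Optional[tuple[tuple[int, int], ...]] = None
    detection: str = "pooled"

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", tuple(self.freqs))
        object.__setattr__(self, "skew", tuple(float(s) for s in self.skew))
        if self.n_sires < 1:
            raise PrdmConfigError("n_sires must be >= 1")
        if len(self.skew) != self.n_sires:
            raise PrdmConfigError(
                f"skew has length {len(self.skew)} but n_sires = {self.n_sires}"
            )
        if any(s < 0 for s in self.skew) or abs(sum(self.skew) - 1.0) > 1e-9:
            raise PrdmConfigError("skew entries must be >= 0 and sum to 1")
        if self.n_offspring < 1:
            raise PrdmConfigError("n_offspring must be >= 1")
        if self.n_replicates < 1:
            raise PrdmConfigError("n_replicates must be >= 1")
        if self.mother_genotypes is not None and len(self.mother_genotypes) != len(self.freqs):
            raise PrdmConfigError("mother_genotypes must give one pair per locus")
        if self.detection not in ("pooled", "individual"):
            raise PrdmConfigError(f"unknown detection rule {self.detection!r}")
        if self.detection == "individual" and not self.mother_known:
            raise PrdmConfigError("individual detection requires a known mother")


@dataclass(frozen=True)
class PrdmResult:
    prdm: float
    mc_stderr: float
    n_replicates: int


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

def simulate_brood(config: PrdmConfig, rng: np.random.Generator) -> dict[str, frozenset[int]]:
    """Draw one brood and return its pooled allele set per locus."""
    sire_of = rng.choice(config.n_sires, size=config.n_offspring, p=config.skew)
    brood: dict[str, frozenset[int]] = {}
    for li, af in enumerate(config.freqs):
        alleles = np.array(af.alleles)
        p = af.as_array()
        if config.mother_genotypes is not None:
            mother = np.array(config.mother_genotypes[li])
        else:
            mother = rng.choice(alleles, size=2, p=p)
        sires = rng.choice(alleles, size=(config.n_sires, 2), p=p)
        pat = sires[sire_of, rng.integers(0, 2, size=config.n_offspring)]
        mat = mother[rng.integers(0, 2, size=config.n_offspring)]
        brood[af.locus.name] = frozenset(int(a) for a in np.concatenate([pat, mat]))
    return brood


def _mc_detect_fraction(config: PrdmConfig, rng: np.random.Generator) -> float:
    """Vectorized Monte Carlo over replicates; returns the detected fraction."""
    reps, n_off, n_sires = config.n_replicates, config.n_offspring, config.n_sires
    # one sire assignment per offspring, shared by all loci of a replicate
    sire_of = rng.choice(n_sires, size=(reps, n_off), p=np.array(config.skew))
    rows = np.arange(reps)[:, None]
    detected = np.zeros(reps, dtype=bool)
    for li, af in enumerate(config.freqs):
        p = af.as_array()
        k = len(p)
        if config.mother_genotypes is not None:
            a_sorted = af.alleles
            m_idx = np.array(
                [[a_sorted.index(a) for a in config.mother_genotypes[li]]] * reps
            )
        else:
            m_idx = rng.choice(k, size=(reps, 2), p=p)
        s_idx = rng.choice(k, size=(reps, n_sires, 2), p=p)
        pat = s_idx[rows, sire_of, rng.integers(0, 2, size=(reps, n_off))]
        mat = m_idx[rows, rng.integers(0, 2, size=(reps, n_off))]
        if config.detection == "pooled":
            present = np.zeros((reps, k), dtype=bool)
            present[rows, pat] = True
            if config.mother_known:
                present[np.arange(reps), m_idx[:, 0]] = False
                present[np.arange(reps), m_idx[:, 1]] = False
                detected |= present.sum(axis=1) >= 3
            else:
                present[rows, mat] = True
                detected |= present.sum(axis=1) >= 5
        else:
            # individual genotyping: paternal allele identified unless the
            # offspring is heterozygous for two maternal alleles
            pat_in_m = (pat == m_idx[:, :1]) | (pat == m_idx[:, 1:2])
            identified = ~pat_in_m | (pat == mat)
            ident = np.zeros((reps, k), dtype=bool)
            rep_idx = np.broadcast_to(rows, pat.shape)
            ident[rep_idx[identified], pat[identified]] = True
            n_ident = ident.sum(axis=1)
            ambiguous = (~identified).any(axis=1)
            u_meets_m = ident[np.arange(reps), m_idx[:, 0]] | ident[np.arange(reps), m_idx[:, 1]]
            detected |= (n_ident >= 3) | ((n_ident == 2) & ambiguous & ~u_meets_m)
    return float(detected.mean())


def prdm(config: PrdmConfig) -> PrdmResult:
    """Monte Carlo PrDM estimate with its binomial standard error.

    A single sire can never be detected as multiple, so ``n_sires = 1``
    (or a skew putting all weight on one sire) returns exactly 0.
    """
    if config.n_sires == 1 or max(config.skew) == 1.0:
        return PrdmResult(prdm=0.0, mc_stderr=0.0, n_replicates=0)
    rng = np.random.default_rng(config.seed)
    frac = _mc_detect_fraction(config, rng)
    se = math.sqrt(frac * (1.0 - frac) / config.n_replicates)
    return PrdmResult(prdm=frac, mc_stderr=se, n_replicates=config.n_replicates)


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------

def _hwe_genotypes(p: np.ndarray) -> list[tuple[tuple[int, int], float]]:
    """Unordered genotype index pairs with their HWE probabilities."""
    k = len(p)
    out = []
    for i, j in combinations_with_replacement(range(k), 2):
        w = p[i] * p[i] if i == j else 2 * p[i] * p[j]
        out.append(((i, j), float(w)))
    return out


def _transmitted_set_dist(genotype: tuple[int, int], n: int) -> dict[frozenset[int], float]:
    """Distribution of the set of distinct alleles transmitted by one parent
    to ``n`` offspring, each inheriting one uniformly chosen allele."""
    if n == 0:
        return {frozenset(): 1.0}
    a, b = genotype
    if a == b:
        return {frozenset((a,)): 1.0}
    p_single = 0.5 ** n
    return {
        frozenset((a,)): p_single,
        frozenset((b,)): p_single,
        frozenset((a, b)): 1.0 - 2.0 * p_single,
    }


def _individual_outcome_dist(
    mother: tuple[int, int], sire: tuple[int, int], n: int
) -> dict[tuple[frozenset[int], bool], float]:
    """Distribution of (identified paternal alleles, any-ambiguous flag) over
    ``n`` offspring of one sire under individual genotyping.

    An offspring's paternal allele is identified unless the offspring is
    heterozygous for two distinct maternal alleles (paternal allele in the
    mother, maternal pick different from it)."""
    m_set = set(mother)
    m_picks = [(mother[0], 1.0)] if mother[0] == mother[1] else [(mother[0], 0.5), (mother[1], 0.5)]
    p_picks = [(sire[0], 1.0)] if sire[0] == sire[1] else [(sire[0], 0.5), (sire[1], 0.5)]
    single: dict[tuple[frozenset[int], bool], float] = {}
    for m, wm in m_picks:
        for pp, wp in p_picks:
            if pp not in m_set or pp == m:
                key = (frozenset((pp,)), False)
            else:
                key = (frozenset(), True)
            single[key] = single.get(key, 0.0) + wm * wp
    state: dict[tuple[frozenset[int], bool], float] = {(frozenset(), False): 1.0}
    for _ in range(n):
        new: dict[tuple[frozenset[int], bool], float] = {}
        for (u, amb), w0 in state.items():
            for (u1, amb1), w1 in single.items():
                key = (u | u1, amb or amb1)
                new[key] = new.get(key, 0.0) + w0 * w1
        state = new
    return state


def _compositions(n: int, parts: int):
    """All ordered compositions of n into `parts` nonnegative integers."""
    if parts == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, parts - 1):
            yield (first,) + rest


def prdm_exact(config: PrdmConfig, max_states: int = 10_000_000) -> float:
    """Exact PrDM by full enumeration of the generative model.

    Conditions on the multinomial sire-assignment counts (which couple the
    loci), then treats loci independently: for each locus the distribution
    of the pooled paternal allele set is built by convolving per-sire
    transmitted-set distributions, marginalized over HWE sire genotypes.
    Practical for few loci, few alleles, and small broods; refuses
    configurations whose state-space estimate exceeds ``max_states``.
    """
    if config.n_sires == 1 or max(config.skew) == 1.0:
        return 0.0
    n_comp = math.comb(config.n_offspring + config.n_sires - 1, config.n_sires - 1)
    k_max = max(len(af.freqs) for af in config.freqs)
    est = n_comp * len(config.freqs) * (2 ** k_max) * (k_max ** 2) * config.n_sires * (k_max ** 2)
    if est > max_states:
        raise PrdmConfigError(
            f"state space too large for exact enumeration (~{est:.2e} > {max_states:.0e})"
        )

    skew = np.array(config.skew)
    p_no_detect_total = 0.0
    for counts in _compositions(config.n_offspring, config.n_sires):
        w_counts = math.exp(
            math.lgamma(config.n_offspring + 1)
            - sum(math.lgamma(c + 1) for c in counts)
        )
        logw = 0.0
        ok = True
        for c, s in zip(counts, skew):
            if c > 0 and s == 0.0:
                ok = False
                break
            if c > 0:
                logw += c * math.log(s)
        if not ok:
            continue
        w_counts *= math.exp(logw)
        if w_counts == 0.0:
            continue

        p_no_detect = 1.0
        for li, af in enumerate(config.freqs):
            p = af.as_array()
            alleles = af.alleles
            genos = _hwe_genotypes(p)
            if config.mother_genotypes is not None:
                mothers = [(config.mother_genotypes[li], 1.0)]
            else:
                mothers = [((alleles[gi], alleles[gj]), wg) for (gi, gj), wg in genos]

            if config.detection == "pooled":
                # distribution of the union of paternal allele sets across sires
                union: dict[frozenset[int], float] = {frozenset(): 1.0}
                for c in counts:
                    sire_dist: dict[frozenset[int], float] = {}
                    for (gi, gj), wg in genos:
                        g = (alleles[gi], alleles[gj])
                        for s_set, ws in _transmitted_set_dist(g, c).items():
                            sire_dist[s_set] = sire_dist.get(s_set, 0.0) + wg * ws
                    new_union: dict[frozenset[int], float] = {}
                    for u, wu in union.items():
                        for s_set, ws in sire_dist.items():
                            key = u | s_set
                            new_union[key] = new_union.get(key, 0.0) + wu * ws
                    union = new_union
                locus_no_detect = 0.0
                for m_geno, wm in mothers:
                    m_set = frozenset(m_geno)
                    if config.mother_known:
                        locus_no_detect += wm * sum(
                            wu for u, wu in union.items() if len(u - m_set) < 3
                        )
                    else:
                        # pooled set includes the maternal transmissions as well
                        for mat_set, wmat in _transmitted_set_dist(
                            m_geno, config.n_offspring
                        ).items():
                            locus_no_detect += wm * wmat * sum(
                                wu for u, wu in union.items() if len(u | mat_set) < 5
                            )
            else:
                locus_no_detect = 0.0
                for m_geno, wm in mothers:
                    state: dict[tuple[frozenset[int], bool], float] = {
                        (frozenset(), False): 1.0
                    }
                    for c in counts:
                        sire_dist2: dict[tuple[frozenset[int], bool], float] = {}
                        for (gi, gj), wg in genos:
                            g = (alleles[gi], alleles[gj])
                            for st, ws in _individual_outcome_dist(m_geno, g, c).items():
                                sire_dist2[st] = sire_dist2.get(st, 0.0) + wg * ws
                        new_state: dict[tuple[frozenset[int], bool], float] = {}
                        for (u, amb), w0 in state.items():
                            for (u1, amb1), w1 in sire_dist2.items():
                                key2 = (u | u1, amb or amb1)
                                new_state[key2] = new_state.get(key2, 0.0) + w0 * w1
                        state = new_state
                    m_set = frozenset(m_geno)
                    for (u, amb), w in state.items():
                        detected = len(u) >= 3 or (
                            len(u) == 2 and amb and not (u & m_set)
                        )
                        if not detected:
                            locus_no_detect += wm * w
            p_no_detect *= locus_no_detect
        p_no_detect_total += w_counts * p_no_detect
    return 1.0 - p_no_detect_total


# ---------------------------------------------------------------------------
# Scenario tables
# ---------------------------------------------------------------------------

def prdm_table(
    freqs: Sequence[AlleleFrequencies],
    scenarios: Iterable[tuple[int, Sequence[float]]],
    n_offspring: int = 100,
    n_replicates: int = 20_000,
    seed: int = 0,
    mother_known: bool = True,
    detection: str = "pooled",
) -> pd.DataFrame:
    """PrDM for a list of (n_sires, skew) scenarios, one row per scenario."""
    rows = []
    for i, (n_sires, skew) in enumerate(scenarios):
        cfg = PrdmConfig(
            freqs=tuple(freqs),
            n_sires=n_sires,
            skew=tuple(skew),
            n_offspring=n_offspring,
            n_replicates=n_replicates,
            seed=seed + i,
            mother_known=mother_known,
            detection=detection,
        )
        res = prdm(cfg)
        rows.append(
            {
                "n_sires": n_sires,
                "skew": ":".join(f"{100 * s:g}" for s in skew),
                "n_offspring": n_offspring,
                "prdm": res.prdm,
                "mc_stderr": res.mc_stderr,
                "n_replicates": res.n_replicates,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["n_sires", "skew", "n_offspring", "prdm", "mc_stderr", "n_replicates"],
    )
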