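# Methods

This note documents the models and estimators implemented in `poolpat`,
the defaults chosen where the design was open, and what the synthetic
generator does and does not emulate.

## Data model

Alleles are categorical integer labels (microsatellite fragment lengths in
bp). No arithmetic is ever performed on allele values: two loci happened to
carry substitutions and a poly-A run alongside repeat-number variation, so
length is an identifier, not a quantity. Missing data distinguish `ND` (a
genotyped sample with no call at a locus, e.g. low read depth) from `NS`
(an individual never sampled); the two behave differently downstream — an
`ND` locus is skipped, an `NS` mother triggers the unknown-mother rule.

The bundled dataset (`src/poolpat/data/`) transcribes the study's printed
tables; its README documents the transcription conventions and the handful
of egg-mass alleles whose adult carriers were genotyped in the full study
but not printed.

## Minimum sires and monogamy

With mother `M` known, the per-locus non-maternal count is `k = |O \ M|`
for brood allele set `O`. With an unsampled mother, the two alleles that
explain most of the brood are assumed maternal: `k = max(0, |O| − 2)`. This
rule reproduces the published estimates for the two unsampled-mother masses
and is flagged in output (`maternal_known = False`).

Estimates are `⌈k/2⌉` (conservative, all sires heterozygous) and `k`
(liberal, all sires homozygous), aggregated across loci by the **maximum**,
not the sum — sires at different loci are the same individuals, so loci are
not additive evidence. Both estimates are floored at 1 and satisfy
`conservative ≤ liberal ≤ 2·conservative`.

An allele shared by mother and true sire is unattributable; the estimators
do not attempt to resolve shared alleles and are therefore conservative by
construction (quantified by the PrDM model below).

EP classification requires ≥1 brood allele outside mother ∪ partner at ≥1
locus. The classifier additionally reports loci at which the partner is
excluded as sole sire (non-maternal alleles exist, none carried by the
partner). Masses whose putative sire was never genotyped are
`UNDETERMINED`.

Egg-mass alleles can be filtered against the adult panel
(`filter_alleles_to_adult_panel`), a guard against PCR artifacts in pooled
extracts. The filter is idempotent and monotone in the adult set. It is not
applied automatically before estimation: on a partially sampled adult panel
(such as the bundled one) it would discard genuine sire alleles whose
carriers happen to be unsampled.

## Panel diagnostics

- `H_o`: fraction of typed adults with two distinct alleles. `H_e`:
  small-sample-corrected `(2N/(2N−1))(1 − Σ p_i²)`. The study's reported
  values may differ in the third decimal depending on the estimator variant
  its software used; they are treated as calibration references.
- HWE: chi-square goodness of fit of genotype counts against HWE
  expectations from the sample frequencies. Genotype classes with expected
  count < 1 (configurable) are pooled lowest-first into a single rare
  class; df = classes − alleles (floored at 1); Yates continuity correction
  at df = 1. The returned p is raw; `panel_summary` adds a Bonferroni
  column (×number of loci, capped at 1). The pooling strategy is a
  deterministic reading of a "minimum expected frequency of one" rule;
  other poolings give slightly different p-values but identical conclusions
  on any panel far from significance.
- Null alleles: the closed-form homozygote-excess moment estimator
  `F_null = (H_e − H_o)/(H_e + H_o)`, which can be negative under
  heterozygote excess. Iterative ML estimators differ slightly; near zero
  (the only regime where a panel is usable anyway) all agree. Simulation
  with a true null at frequency 0.15 recovers it within ±0.05 at N = 500.
- Exclusion probabilities are defined operationally and computed by two
  independent routes that must agree to 1e-12:
  - *no parent known*: `P1 = Σ p_i²(1−p_i)² + Σ_{i<j} 2p_i p_j(1−p_i−p_j)²`
    — the probability a random HWE individual shares no allele with a
    random offspring of a random mating;
  - *one parent known*: averaging `(1 − Σ_{a∈S} p_a)²` over HWE mothers,
    Mendelian maternal transmission and an HWE paternal allele, where `S`
    is the set of offspring alleles that could be the paternal contribution
    given the mother;
  - the oracle route enumerates mother × father × transmissions × candidate
    genotypes outright.
  Multi-locus combination is `1 − Π(1 − P_l)`, nondecreasing in loci.

## PrDM (probability of detecting multiple paternity)

Generative model per replicate: mother and each of `s` sires drawn as HWE
genotypes from the panel frequencies (a fixed-mother variant is available
via `mother_genotypes`); each of `n` offspring assigned to a sire by a
multinomial over the skew (one assignment shared by all loci); Mendelian
inheritance per locus. PrDM is the probability the brood is detected as
multiply sired. Two detection rules:

- **pooled** (default): ≥3 non-maternal alleles at some locus — the
  conservative rule applied to a pooled extract, where a sire allele also
  carried by the mother is invisible. This matches what is actually
  inferable from pooled egg-mass genotyping, and is the rule the synthetic
  generator is validated against. With an unknown mother the threshold
  becomes ≥5 alleles in total.
- **individual**: each offspring genotyped separately, the design of
  classical power models. An offspring's paternal allele is identifiable
  unless the offspring is heterozygous for two maternal alleles, so
  paternal alleles shared with the mother still count. Detection means no
  single two-allele father is compatible: ≥3 identified paternal alleles,
  or exactly two identified paternal alleles disjoint from the maternal
  genotype together with an ambiguous offspring.

The individual rule is strictly more powerful. Published power tables for
100-embryo broods are computed under it, and this package reproduces them
with it (e.g. ~0.96 at two sires 50:50, ~0.93 at 95:5, ~0.51 at 99:1 on
the bundled panel); under the pooled rule the same 50:50 scenario has power
~0.45, which is the honest power of the pooled sampling design itself.

`prdm()` is Monte Carlo (default 20,000 replicates; binomial standard
error reported; seed mandatory). For one sire, or a skew degenerate on one
sire, it returns exactly 0 without simulation. `prdm_exact()` enumerates
the same model exactly — conditioning on the multinomial sire-assignment
counts (which couple loci), then convolving per-sire transmitted-allele-set
distributions — and refuses configurations whose state-space estimate
exceeds 10^7 (practical: few loci, ≲5 alleles, broods of ≲8). Monte Carlo
and enumeration agree within 3 standard errors on every tractable
configuration tested, and both were verified against a fully independent
brute-force enumeration to 1e-14. Exact PrDM is nondecreasing in offspring
and locus count and nonincreasing as skew concentrates.

Structural zeros worth knowing: under the pooled rule a locus with ≤3
alleles can never reveal multiple paternity (a homozygous mother leaves at
most 2 non-maternal alleles, a heterozygous one at most 1).

## Synthetic mating-system generator

Emulates the study's statistical structure with full ground truth
(`SynthConfig` defaults in parentheses):

- Per-locus allele frequencies from a symmetric Dirichlet (α = 1), allele
  counts uniform on 4–7; adults (112) as HWE genotypes; 75% paired, the
  rest solitary; shell lengths normal by status (paired 50.6 ± 6.9 mm,
  solitary 47.2 ± 6.0 mm).
- Sire recruitment per mass: the number of sire slots from
  `sires_per_mass_dist` (default {1: 0.8, 2: 0.2}; the study gives no
  distribution beyond "one to two" conservatively, so this is a labelled
  modeling choice). For a paired mother the first slot is her partner with
  probability `p_within_pair_use` (0.25, set so that roughly three quarters
  of paired masses carry extra-pair paternity, the observed rate), further
  slots extra-pair with probability `p_extra_pair` (1.0); solitary mothers
  recruit only extra-pair sires, drawn uniformly from the other adults
  (no spatial kernel: per-individual coordinates were not published).
  Duplicate recruits collapse to one sire.
- Broods: 500 embryos allocated to slots by an equal-probability
  multinomial (or an explicit `mass_skew`); each embryo inherits one
  maternal and one paternal allele; an allele enters the pooled set when
  its gene-copy count reaches `detection_min_count` (1; raise it to
  emulate read-depth dropout). Sperm storage is represented only
  implicitly through the sires-per-mass distribution, not as a time
  process.
- Egg-mass production: per-cycle negative binomial (dispersion 5) on a log
  link in shell length (β = 0.0471), truncated at 2 masses per cycle, four
  cycles. Status-specific intercepts are solved numerically
  (Gauss–Hermite quadrature over the length distribution + Brent root
  finding) so the status-marginal means equal the targets 1.57 (paired)
  and 0.81 (solitary) *after* truncation; infeasible targets (> the
  truncation ceiling) raise a config error.

Validated properties: a strictly monogamous configuration yields zero EP
and zero multiple-paternity calls; the conservative estimator never exceeds
the true sire count (the liberal estimator carries no such guarantee and
empirically overcounts, as its homozygosity assumption implies); the
empirical detection frequency of two-sire broods matches `prdm()` under
the pooled rule within Monte Carlo error; egg-mass count means recover
their targets within 2 standard errors at 10,000 adults.

What the generator does **not** emulate: genotyping error and allelic
dropout beyond the detection threshold, PCR artifacts, spatial structure
of mating, status transitions over time, and sperm-storage kinetics.
Passing recovery tests therefore show the inference chain is correct under
clean Mendelian sampling, not that it is robust to all field realities.

## Problem sizes and tolerances

Stochastic checks in the test suite and acceptance script use 2,000 masses
(recovery), 20,000–60,000 Monte Carlo replicates (PrDM), and 6,000–10,000
adults (calibration); comparisons use 3 binomial/combined standard errors
(2 for the calibrated egg-mass means, 4 for single-draw distributional
spot checks). Dual-route equalities use 1e-12. The HWE test needs ≥5 typed
adults, heterozygosity ≥2; degenerate single-allele loci report zero
exclusion power rather than erroring.

## Known limitations

- The bundled adult panel contains the 16 adults whose genotypes are
  printed; the full study genotyped 19. Panel-level statistics computed on
  the bundled adults (combined exclusion ~0.73 / ~0.91, mean `H_e` ~0.64)
  are therefore slightly below the full-panel values (0.764 / 0.926,
  0.691), and PrDM values on the bundled frequencies sit within ~0.02 of
  the published table.
- The liberal estimator can exceed the true sire count; it is an upper
  bracket on interpretation, not a bound.
- `F_null` is a moment estimator, not the ML fit some genotyping suites
  report.
- No likelihood-based parentage assignment (LOD scores), sibship
  reconstruction, or sire-number posterior is attempted.
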