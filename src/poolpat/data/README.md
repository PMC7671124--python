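# Bundled worked-example dataset

Adult microsatellite genotypes and pooled egg-mass allele sets for the
published *Siphonaria gigas* parentage study (Punta Culebra, Panama; four
microsatellite loci, alleles labelled by fragment length in bp). The tables
printed in the study report are transcribed here into the package's CSV
schemas.

Files:

- `loci.csv` — the four-locus marker panel (locus name, repeat motif).
- `adults.csv` — the 16 adults whose multilocus genotypes are printed in the
  study's maternal (M) and putative-paternal (PP) genotype columns.
  `M<k>` is the maternal parent of egg mass `<k>`; `PP<k>` is the social
  partner of `M<k>` where that partner is not itself a sampled mother.
  Masses 27 and 30 were produced by the two members of one pair, so each
  mother is the other's putative sire. Shell lengths were not printed per
  individual and are left blank.
- `masses.csv` — the 16 pooled egg-mass allele sets (~500 embryos pooled per
  mass). `ND` marks a locus that failed genotyping (low read depth); the
  maternal parents of masses 23 and 36 were never sampled (`NS`).

Notes:

- Homozygous maternal entries printed as concatenated strings (e.g. "5757")
  are pre-split into explicit allele pairs.
- Bold/plain typography marking non-maternal alleles is NOT transcribed;
  non-maternal status is always recomputed from the genotypes.
- The full study genotyped 19 adults; the 3 adults not appearing in any
  printed genotype column are absent here. Consequently a few egg-mass
  alleles have no carrier among the 16 bundled adults although they occur in
  the full adult panel: 269 at MS-26 (mass 32), 53 and 63 at MS-31 (masses
  26, 28, 34), and 234 at MS-34 (mass 26). Allele filtering against this
  reduced panel would therefore drop alleles the original analysis retained;
  the table-reproduction workflow uses the egg-mass sets as printed.
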