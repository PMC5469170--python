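# rescuegen

Conservation-genetics diagnostics and genetic-rescue simulation for
fragmented populations of long-lived freshwater fish.

Habitat fragmentation leaves riverine fish in small, isolated headwater
populations that lose genetic diversity to drift, accumulate inbreeding,
and face an elevated risk of extinction from inbreeding depression.
`rescuegen` packages the quantitative toolkit a management-genetics study
of such a system needs:

* **Diversity statistics** for microsatellite genotypes and mtDNA
  alignments — unbiased expected heterozygosity, rarefied allelic
  richness, private alleles, homozygosity-by-locus (HL), haplotype and
  nucleotide diversity, Tajima's D, Fu's Fs — plus differentiation
  (Weir–Cockerham F_ST, AMOVA Φ_ST, R_ST) and the allele-size permutation
  test for mutational (evolutionary-timescale) divergence.
* **Effective population size**: the single-sample linkage-disequilibrium
  method (Burrows composite r², P_crit screening, random-mating bias
  correction), the temporal drift-law inversion
  Ne = 1/(2(1 − (He_t/He_0)^{1/t})), the two-trait life-history
  approximation of N_b/N_e = 0.485 + 0.758·log₁₀(AL/α), and the
  multiplicative bias-adjustment chain for ABC-based estimates.
* **An age-structured, two-sex, individual-based simulator** of
  do-nothing versus translocation management, with exact pedigree
  inbreeding, lethal-equivalent inbreeding depression (unique recessive
  lethals per founder plus an exp(−bF) non-lethal component), 19 neutral
  diploid marker loci, a maternally inherited haplotype locus, and
  multi-year (AR(1)) environmental variation.
* **A hierarchical Bayesian spike-and-slab regression** of individual HL
  on standardized riverscape variables with basin/site random effects,
  prior inclusion probability 0.5, and cluster-fold cross-validation.
* **Synthetic-data generators** (Balding–Nichols genotypes, star-genealogy
  haplotypes, environment tables with planted effects) so every stage is
  testable with known truth.

## Worked example

```python
import numpy as np
from rescuegen import sim
from rescuegen.ne import temporal_ne, nb_ne_ratio

# initial marker frequencies matching a depleted population:
# 19 loci, ~3.5 alleles/locus, expected heterozygosity 0.426
rng = np.random.default_rng(0)
freqs = sim.marker_frequencies_for_he(19, 3.52, 0.426, rng)

cfg = sim.SimConfig(
    populations=[sim.PopulationInit("king_parrot", 500, marker_freqs=freqs,
                                    mt_freqs=np.ones(4) / 4)],
    years=100, replicates=250, seed=17,
)
summary = sim.run_scenario(cfg)[0]
print(f"P(extinct by year 100) = {summary.p_extinction:.2f}")
print(f"He retained            = {summary.he_final / summary.he_year0:.2f}")
print(f"Ne from He decline     = {summary.ne_final:.0f}")
print(f"Nb/Ne (alpha=3, AL=23) = {nb_ne_ratio(alpha=3, adult_lifespan=23):.3f}")
```

prints (seed 17):

```
P(extinct by year 100) = 0.16
He retained            = 0.90
Ne from He decline     = 66
Nb/Ne (alpha=3, AL=23) = 1.156
```

A population of 500 adults, left alone for a century, loses ~10% of its
expected heterozygosity (behaving like an ideal population of ~66 — an
Ne/N ratio near 0.18) and goes extinct in roughly a sixth of replicates
through the interaction of drought years and inbreeding depression. The
same scenario with six adults translocated annually from a larger donor
population (a `TranslocationPlan`) shows the rescue effect: higher
terminal heterozygosity and a many-fold lower extinction probability.

A command-line interface exposes the stages as subcommands:

```bash
rescuegen synth    --seed 1 --out fixtures/          # synthetic bundle + truth manifest
rescuegen stats    --genotypes fixtures/genotypes.gen --out stats/
rescuegen ne       --genotypes fixtures/genotypes.gen --out ne/
rescuegen simulate --config scenario.yaml --out sim/
rescuegen envmodel --env fixtures/environment.csv --hl fixtures/hl_response.csv --out env/
```

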