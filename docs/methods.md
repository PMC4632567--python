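# Methods

## The model

`sexgames` implements a deterministic evolutionary-game model of why costly
sexual reproduction is not displaced by asexuality. The population is
infinite, diploid, with discrete non-overlapping generations. Two unlinked
autosomal loci determine reproduction:

* **Locus S** (alleles a, s): genotype `aa` reproduces clonally
  (parthenogenesis, strategy S1); `ss` reproduces sexually; `as`
  heterozygotes reproduce sexually with probability `alpha` and clonally
  otherwise.
* **Locus M** (alleles n, c), expressed only in sexuals: `nn` males are
  monogamous and match the female's parental investment ("non-costly" sex,
  S2); `cc` males are polygynous, invest everything in mate competition and
  provide no care ("costly" sex, S3 — this is where the twofold cost of sex
  lives); `nc` is intermediate through the dominance `k` of allele c.

The state is the 9-vector of genotype frequencies P(G1..G9), ordered
(aa, as, ss) × (nn, nc, cc). One generation is the composition of:

1. **Clonal copying.** `aa` genotypes and a fraction `1 − alpha` of `as`
   genotypes copy themselves with fitness 1.
2. **Mating.** All sexual females (half of the sexual fraction
   τ = α(P4+P5+P6) + P7+P8+P9) mate exactly once. Male mating success
   depends on M genotype: with X = αP6 + P9 + k(αP5 + P8) and
   D = 1 + (m−1)X, polygynous males average (1 + (m−1)τ)/D mates,
   heterozygotes (1 + kτ(m−1))/D, monogamous males 1/D. These are the
   unique rates of this form that conserve mates (male successes weighted
   by male frequencies equal the number of females) and reproduce the
   limits m (polygynous males rare) and 1/m (monogamous males rare).
3. **Pair fitness.** A pair contributes in proportion to
   `R · (1 + b_m · b_f)`: `R ≥ 0` is the mechanism-agnostic recombination
   benefit of sexually produced offspring relative to clones; `b_m` is the
   male's potential care (1, 1−k, 0 for nn, nc, cc) and `b_f` the fraction
   the female accepts (1, 1−k(1−b), b). A fully caring monogamous pair
   yields 2R; a polygynous male yields R with any female.
4. **Mendelian segregation.** Offspring genotypes follow independent fair
   meiosis at both loci (the 6×6×9 tensor is computed once, in exact
   rational arithmetic).
5. **Normalization.** Selection changes the total contribution, so the
   pooled clonal + sexual contributions are renormalized to a probability
   vector.

For intermediate recombination benefits (1 < R < 2) the three pure
strategies form an intransitive cycle — W(S2) > W(S1) since R > 1,
W(S1) > W(S3) since R < 2, and W(S3) > W(S2) once the polygyny potential m
is large enough — giving rock–paper–scissors dynamics in which the
costly-sex allele persists far below the twofold benefit it would need
against asexuality alone.

## Parameters

| name | meaning | range | default used in examples |
|------|---------|-------|--------------------------|
| R | recombination benefit relative to asexuality | ≥ 0, interesting in 1–2 | — |
| m | polygyny potential: max mean mates of a cc male | ≥ 1 | — |
| b | care acceptance by cc females | [0, 1] | 0.5 |
| k | dominance of allele c at locus M | [0, 1] | 0.5 |
| alpha | probability an `as` heterozygote is sexual | [0, 1] | 0.5 |

Relatedness (1 for clones, 1/2 per sexual parent) and the per-strategist
offspring number are structural constants, not knobs.

## Analytic reference layer

With the c allele absent every sexual pair has fitness 2R and the allele-a
dynamics collapse to
`a' = [a + ½α(R−1)P4] / [1 + (R−1)τ]`; with the n allele absent they
collapse to `a' = [a + ¼α(R−2)P6] / [1 + ½(R−2)τ]`. These closed forms are
implemented independently of the engine and used as oracles: the full
recursion restricted to either plane matches them to ~1e−15 per
generation, and R = 1 (respectively R = 2) holds allele a exactly constant.
The pairwise ESS classifier returns S1/S2/S3/neutral-line/bistable labels
from the thresholds R vs 1, R vs 2, and (for the two sexual strategies, at
the dominance extremes k ∈ {0, 1}) m vs 1 + b and 3 − b; for 0 < k < 1 the
monogamy–polygyny game has no closed-form thresholds and the classifier
refuses rather than guesses — use simulation there.

## Dynamics layer

Initial states are built from allele frequencies at Hardy–Weinberg
proportions within each locus and linkage equilibrium across loci — the
simplest convention consistent with specifying initial conditions as
allele frequencies only. "Generation t" means the state after t
applications of the map to the generation-0 state. Trajectories are exact
double-precision iterations; no randomness exists anywhere, so runs are
bit-reproducible. Frequencies are renormalized every step to absorb
rounding drift, and no extinction clamping is applied: trace frequencies
persist (as they would in an infinite population) and can re-ignite
cycles.

`classify_regime` looks at the final window (default 1000 generations) of
a trajectory: amplitude = max − min of each allele frequency. A quiescent
window (amplitude < `osc_tol`, default 1e−6) is *fixation* if allele a or
c lies within `fix_tol` (default 1e−3) of 0 or 1, else
*stable_equilibrium*; a moving window is *near_fixation_oscillation* if
any allele grazes the boundary within `fix_tol`, else *oscillation*. The
defaults separate cleanly converged parameter cells from cycling ones;
all three are configurable because the underlying distinction is graded,
not sharp.

`parameter_sweep` runs one trajectory per (R, m) cell from a common
initial state (default reporting generation: 10,000) and classifies each.
A failing cell is marked `failed` rather than aborting the sweep.

## Equilibrium reporting

Reported equilibria (and the values recomputed by
`scripts/acceptance.py`) use runs of 50,000 generations with the allele
frequency averaged over the final 1,000 generations; when the attractor
is a point the average equals the point value, and when a cell cycles the
average is a summary, not an equilibrium.

A structural property of the model worth knowing when reading such
numbers: at three-strategy attractors the `as` heterozygote classes decay
to ~1e−5, which effectively decouples the clonal `aa` pool from the
sexual pool. Within the sexual pool the equilibrium composition is pinned
by selection (the equilibrium frequency of c *among sexuals* depends
almost only on R; the sexual fraction depends mainly on m), but the
M-locus content of the clonal pool is selectively neutral — clones copy
themselves regardless of their silent M alleles — so the *population-wide*
frequency of allele c retains a memory of how much of the initial clonal
pool was purged and re-founded during the transient spirals. Different
initializations (and different but mathematically equivalent codings of
the transient) therefore converge to the same sexual-pool equilibrium yet
different total c; allele s is insensitive to this. Comparisons of total
allele-c values between implementations or initial conditions should be
read with this neutral direction in mind.

## Numerical notes

* The segregation tensor is exact (dyadic rationals); tests compare it to
  a brute-force 4×4 gamete enumeration in `fractions.Fraction`.
* Mating rates at τ = 0 are returned but multiply zero frequencies, so
  pure-asexual states are fixed points rather than errors.
* `GenotypeDistribution` renormalizes on construction when the sum is
  measurably off 1 but leaves machine-exact inputs untouched, keeping
  repeated construction and file round-trips bit-stable.
* CLI tables print frequencies with the shortest decimal representation
  that parses back to the identical double, so a trajectory's final row
  re-run as an explicit initial state reproduces itself exactly.
* Fixation approach rates differ qualitatively by dominance: a losing
  allele expressed in heterozygotes is removed geometrically, while a
  recessive one hides in heterozygotes and decays only as ~1/t — after
  1e5 generations it still sits at ~3e−5. Convergence checks must use
  dominance-appropriate tolerances.

## Known limitations

No mutation, drift, finite population size, linkage between the loci,
density dependence or spatial structure; the biological mechanism behind
R is deliberately unmodelled (R is a free parameter). The simulator
reproduces the deterministic infinite-population idealization only; in
any finite population the near-fixation cycles would end in absorption.
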