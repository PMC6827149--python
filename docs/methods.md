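# Methods

## Study design the package implements

The pipeline reconstructs maternal-lineage structure from short
mitochondrial D-loop fragments: fragments are anchored to a reference
mitogenome, collapsed into haplotypes, assigned to four clades by two
diagnostic sites, and summarized by per-population diversity and
neutrality statistics, a median-joining haplotype network, a
distance-based phylogeny and clade-by-region composition tables. The
real cohorts this design targets are not publicly recoverable, so the
package ships a synthetic-data generator whose defaults mirror the
study conditions; all empirical claims below are about what the code
computes on those synthetic cohorts.

## Synthetic cohorts

**Star-expansion model.** Each clade has a founder sequence derived
from the reference by the diagnostic T→C transitions (15,610 and/or
15,648; clade D is the reference itself). Every sampled lineage
descends independently from its founder carrying Poisson(λ) private
substitutions at uniformly chosen non-diagnostic sites; each
substitution is a transition with probability 0.9 (the catalogued
D-loop differences are almost exclusively transitions), otherwise a
uniform transversion. This is the simplest generator that produces the
star-shaped radiation and the excess of rare variants (negative
Tajima's D and Fu's Fs) characteristic of recently expanded
populations. Finite sites: a site may mutate repeatedly; the later
substitution acts on the current base. Diagnostic sites are
mutation-protected so the true clade of every sample is well defined;
homoplasy at diagnostic sites is an explicit non-goal.

**Defaults.** λ = 0.9 per lineage, chosen once so that the within-clade
mean pairwise difference 2λ ≈ 1.8 falls in the middle of the observed
per-population K range (≈1.5–2.4). Clade sizes default to the study's
membership counts (A 1107, B 339, C 591, D 429; total 2466). The
population mixture of clade A uses the reported shares (PT 62.15%,
SW 27.1%, remainder uniform); the other clades follow the qualitative
pattern (SW concentrated in clade B, NC in clade C, PT also in D) with
proportions chosen once as plausible values. No effective-size or
growth parameters are published for these populations; everything is
exposed in `SimulationConfig`.

**What the generator does not emulate.** Real D-loop variation is
concentrated at hypervariable hotspot positions, producing extensive
haplotype sharing (124 haplotypes among 2466 animals); independent
uniform mutation instead makes most mutated lineages unique, so the
synthetic cohort yields ~1200 haplotypes and near-1 haplotype
diversity. Likewise every synthetic population is a mixture of
star-expanded clades, so all six show the expansion signature, whereas
real populations differ in it. Passing tests therefore demonstrate the
correctness and calibration of the machinery, not population-genetic
realism of the cohort; indels, recombination, heteroplasmy and
sequencing error are out of scope.

**Neutral coalescent.** The null model for the neutrality tests is a
standard constant-size coalescent: with k lineages the waiting time to
the next coalescence is exponential with rate k(k−1)/2; mutations fall
on branches as a Poisson process of rate θ/2 per unit length (or with a
fixed total count placed multinomially by branch length, for the
conditional null of Tajima's D) and map to distinct alignment columns
(infinite sites; an error is raised if mutations exceed the requested
alignment length).

## Statistics

* **Site filters.** S and Tajima's D use complete deletion (columns
  containing any gap or N are dropped for all samples); K and Pi use
  pairwise deletion (each pair compared over its mutually unambiguous
  columns). L_eff is the mean number of compared columns per pair, so
  Pi = K/L_eff holds exactly by construction; it is reported rather
  than reverse-engineered from any external tool's unstated filter.
* **Tajima's D** = (θ_π − θ_W)/√(e₁S + e₂S(S−1)) with the standard
  coefficient chain a₁…e₂. Conventions: D = 0 with p = NA when S = 0;
  NA for n < 4, where the variance terms vanish. The p-value is
  two-sided Monte Carlo (double the smaller tail) from the coalescent
  null conditioned on the observed S; default 10,000 replicates,
  seeded.
* **Fu's Fs.** S′ = P(#alleles ≥ k_obs | θ̂, n) from the Ewens sampling
  formula with unsigned Stirling numbers of the first kind computed by
  the recurrence |S1(n,k)| = |S1(n−1,k−1)| + (n−1)|S1(n−1,k)|,
  evaluated in log space (both tails, so Fs = ln(S′/(1−S′)) is finite
  far into either tail); θ̂ is θ_π = K, following the statistic's
  original definition. Fs is undefined (NA) for k_obs = 1 or K = 0.
  The p-value is the lower-tail fraction of coalescent replicates at
  θ = θ̂ with Fs_sim ≤ Fs_obs; monomorphic replicates (Fs undefined)
  count against rejection. Significance is starred at p < 0.05 to match
  the reporting convention of the study design, and a second column
  applies the statistic's own stricter 0.02 convention.
* **Hd** is Nei's estimator n(1−Σp²)/(n−1) with his small-sample
  variance formula; the SD is its square root.

The test suite pins D, Hd ± SD, Pi/K to an independent exact-rational
(Fraction-based) evaluation at 1e-12 on random small alignments, Fs to
exact Ewens values, and the log-space Stirling row to the direct
integer recursion.

## Networks

Distances between haplotypes are mutation steps: Hamming over mutually
unambiguous columns, with each maximal one-sided gap run counted as a
single step, consistent with the one-event-per-indel calling decision.
The minimum spanning network is the union of all minimum spanning
trees, computed by the cycle-property test (an edge of weight w joins
iff its endpoints are separated by the graph of all strictly lighter
edges); ε > 0 relaxes the comparison to w − ε. Median-joining iterates:
build the ε-relaxed MSN; for every triplet joined by at least two MSN
edges form the site-wise majority median (a three-way tie keeps the
state of the first sequence in deterministic order — the behaviour of
the original desktop implementation is unpublished, so this tie-break
is the package's own, documented choice); add all new medians whose
connection cost is within ε of the minimum; repeat to a fixed point
(iteration cap with a diagnostic); finally prune medians of degree < 2
or off every shortest observed-pair connection. Observed haplotypes
are never pruned; ties break lexicographically by haplotype id;
ε defaults to 0 and transitions/transversions are weighted equally
(the weights used by the original study's software are unstated). The
containment property verified in tests is that the final network
retains every MSN edge over its own node set.

## Phylogeny

The study design's maximum-likelihood tree search is replaced by K2P
distances + neighbor joining + bootstrap: this preserves the
substitution model and the bootstrap design at a fraction of the
complexity, and the acceptance surface is clade-group recovery on
synthetic data, not likelihoods. K2P uses pairwise deletion and raises
a saturation error when a logarithm argument is non-positive. NJ
follows Saitou–Nei with Q(i,j) = (r−2)d(i,j) − R_i − R_j, ties broken
lexicographically by the smallest leaf label of each cluster; negative
branch lengths are clamped to zero and flagged. Bootstrap resamples
columns with replacement, rebuilds K2P+NJ, and counts bipartition
recovery as percentages; replicates with degenerate matrices are
skipped and counted, and the replicate stream is drawn in a
taxon-order-independent order so supports are permutation invariant.
Rooting bisects the outgroup's pendant edge. Newick IO is round-trip
stable (supports as internal labels, lengths at 10 significant
digits).

## Pipeline and problem sizes

`run_all` chains the stages, writes six artifacts plus a manifest
(seed, parameters, SHA-256 input checksums) and deletes partial
outputs on stage failure, so a bundle on disk is always complete and
reproducible byte for byte from its manifest. The analysis scripts run
haplotype accounting, geography and population statistics on the
full-size cohort (2466 samples), and the network/tree stages on a
1/20-scale cohort (123 samples, ~80 haplotypes) — the package's choice
of a size at which the quadratic-and-worse network and bootstrap
stages stay interactive while every qualitative result (clade
recovery, star structure, composition shares) is unchanged. The
acceptance script uses the same sizes, with 1000–2000 replicates for
the calibration studies and 200–500 for the power study.

## Known limitations

* The per-population statistics on synthetic data are not comparable
  to the study's printed table beyond sign and significance patterns
  (see the generator's realism caveats above).
* The haplotype naming scheme (clade letter + frequency rank +
  lowercase network-child suffixes) is the package's own; the naming
  used in the study is undefined.
* The indel locus in the reference catalog is recorded by its leftmost
  anchor position without interpreting insertion vs deletion
  orientation, which the source material does not state.
* One published methods sentence names a different neutrality test
  (Fu and Li's F) than the reported table column (Fu's Fs); the
  package implements Fs, matching the reported column, and does not
  implement Fu & Li's D*/F*.
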