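# Methods

This note documents the models, numerical choices and known limitations of
`favamap`. Genotypes are coded 0/1/2 for the common-parent homozygote,
heterozygote and other-parent homozygote; `-1` is missing.

## Population model

All computations assume a biparental cross of fully homozygous, fully
contrasting parents: the F1 is a double heterozygote in complete coupling
phase at every marker pair. F2 plants are formed from two independent F1
gametes; each F3 individual is one progeny of a selfed F2 plant (single-seed
descent). Meioses follow Haldane's no-interference model: along a
chromosome, the transmitted strand switches between adjacent markers with
probability equal to the interval's recombination fraction *r*, so cM
distances and recombination fractions interconvert exactly through
*d* = −50 ln(1 − 2*r*).

Under this model the single-locus F3 genotype distribution is
(0.375, 0.25, 0.375): the F2 is (¼, ½, ¼) and one selfing halves the
heterozygote class, donating equally to both homozygotes. This marginal is
independent of linkage and anchors both the distortion statistics and the
simulator checks.

## F3 two-locus model and the F2 → F3 correction (`f3model`)

`f3_joint(r)` propagates the coupling F1 through two generations with exact
4 × 4 gamete-transition enumeration: F1 gamete probabilities
((1−r)/2 parental, r/2 recombinant), all 16 ordered F2 diplotypes, and for
each the meiosis gamete distribution again; the result is the exact unphased
3 × 3 F3 genotype distribution. An independent test-suite oracle recomputes
it by exhaustive rational-arithmetic enumeration of strand choices; the two
agree to < 10⁻¹².

Mapping software that treats an F3 population as F2 converges (in the large-
sample limit) to the maximizer of the *expected* F2 log-likelihood under the
true F3 class frequencies. We therefore *define*

  rF2(r) = argmax_ρ Σ_classes f3_joint(r) · log f2_joint(ρ),

computed by bounded scalar optimization (tolerance 10⁻¹⁰), with fixed points
at 0 and 0.5 and rF2(r) > r in between (the F2→F3 meioses add observable
recombinants; e.g. rF2(0.1) ≈ 0.140). `correct_r` inverts this monotone map
by bisection (tolerance 10⁻⁸); the round trip is accurate to < 10⁻⁶. The
correction is applied to adjacent map intervals **after** ordering (convert
interval cM back to F2-scale r, correct, re-accumulate through Haldane);
applying it to two-point estimates before ordering is also supported but is
not the default, since ordering only needs a monotone distance surrogate.

## Marker QC (`markerqc`)

The distortion index is ½·Σ|f_obs − f_exp| / (1 − min f_exp) with
f_exp = (0.375, 0.25, 0.375) over non-missing calls. The normalization
makes the worst case — all mass on the heterozygote, the least-expected
class — score exactly 1; a marker fixed for one homozygote scores 5/6.
Markers are dropped when the index is ≥ 0.8 (inclusive comparison;
configurable) or when the missing fraction exceeds 0.2 (the missingness
ceiling is a config default; no published value exists for it). The χ²
profile uses the plain Pearson statistic against the same expectation,
df = 2, no continuity correction; with ~150 individuals the trinomial cell
expectations are large enough that the null rate at p < 0.05 calibrates at
~5%, which the test suite checks on distortion-free simulations.

## Two-point estimation and grouping (`linkage`)

For each marker pair the 3 × 3 joint genotype table (individuals non-missing
at both markers) enters an EM for the F2-model recombination fraction in
known coupling phase: every class except the double heterozygote has a known
recombinant-gamete count; the double heterozygote contributes
2r²/((1−r)² + r²) expected recombinants. EM starts at r = 0.25 and stops at
|Δr| < 10⁻⁶ (≤ 200 iterations); estimates are clipped to [0, 0.5]. The
all-pairs computation is vectorized over the full pair matrix.

Two LOD statistics are computed:

* `lod_f2` — log₁₀ L(r̂)/L(0.5) under the F2 model, the statistic that
  matches the F2-scale estimate;
* `lod` — a grid-profile LOD under the *F3* two-locus model (501-point r
  grid of exact class probabilities), used for grouping and as the linkage-
  strength score in ordering.

The distinction matters: the F2 model expects 50% heterozygotes where F3
data carry 25%, and this misspecification inflates the F2 LOD's null tail by
roughly an order of magnitude (measured: P(LOD ≥ 5) ≈ 5·10⁻⁶ per independent
F3 pair at n ≈ 150, versus effectively 0 for true F2 data). With tens of
thousands of pairs per population, that tail produces occasional spurious
bridges between chromosomes under single-linkage grouping. The F3-model LOD
is correctly specified, so a threshold of 5.0 again means what it should;
on 2·10⁵ simulated independent pairs its maximum was < 4.

Grouping forms connected components of the LOD ≥ 5 graph (networkx);
singletons are reported unassigned. Components are labelled from an anchor
file (marker → chromosome, majority vote) when given, else by size rank.
Markers with byte-identical call vectors are collapsed to one representative
before pair estimation and re-attached during bin-mapping.

## Multipoint likelihood and ordering (`ordering`)

The multipoint model is a hidden Markov chain over the four **ordered strand
pairs** (maternal allele, paternal allele); the genotype is the pair sum.
Transitions factorize as the Kronecker square of the 2-state switch chain, so
the likelihood equals the usual 3-genotype-state F2 HMM but the Baum–Welch
M-step for each interval r is closed form: expected strand switches divided
by 2n. Emissions: a call equals the underlying genotype with probability
1 − ε and each other class with ε/2; missing calls emit 1. Emission
probabilities are floored at 10⁻¹² so ε = 0 on contradictory data degrades
the likelihood instead of producing −∞. Interval estimates are clipped to
[10⁻⁶, 0.4999]; Baum–Welch stops at |Δr| < 10⁻⁴ (≤ 40 sweeps), initialized
from the adjacent two-point estimates. Reversing an order leaves the
likelihood exactly invariant (uniform initial state, symmetric transitions).

Ordering proceeds per linkage group:

1. **Scaffold.** From each of 10 randomly drawn seed markers (seeded RNG), a
   skeleton grows by repeatedly attaching, to whichever end it is more
   strongly linked (higher LOD), the marker at estimated Haldane distance
   ≥ 10 cM from every current scaffold member. Replicates are scored by
   *mean per-marker* multipoint log-likelihood — replicates can hold
   different marker sets, so raw likelihoods are not comparable — and the
   best is kept; inter-replicate order concordance (mean pairwise |Kendall
   τ| on shared markers) is reported.
2. **Framework.** Remaining markers are tried in decreasing order of their
   best LOD to the group. Each candidate is scored at every insertion
   interval in O(n) per interval using the fitted chain's forward/backward
   arrays, with flanking r taken from two-point estimates; it is inserted at
   the best interval only if log₁₀ LR(best vs second-best) > 3, else
   deferred. After each insertion the chain is re-fit.
3. **Polish.** A window-3 permutation hill-climb (accept on likelihood
   improvement) runs after scaffold selection and after framework
   construction — the standard local companion to this family of serial
   ordering heuristics.
4. **Bin-mapping.** Each deferred marker takes the position of the framework
   marker with the smallest two-point r̂ (ties: higher LOD, then
   lexicographic id); markers with LOD below the grouping threshold to every
   framework marker are reported unplaced. Collapsed cosegregating markers
   rejoin at their representative's position.

Positions are accumulated Haldane distances of the fitted interval r's on
the F2-assumed scale, then rescaled by `correct_r` as a post-processing
step. Group orientation is made deterministic (lexicographically smaller
end-marker first); relative orientation across maps is resolved at the
consensus stage.

## Consensus (`consensus`)

D(M, M′) sums squared differences of signed inter-marker distances over
markers common to both maps, for pairs eligible in the map supplying the
constraint: 0.5 cM ≤ |d| ≤ 100 cM, at most 10 neighbours per side, each
unordered pair counted once. The lower cutoff removes poorly determined
tiny intervals, the upper cutoff and per-side cap bound the work and treat
all markers evenly.

The window defaults deserve a note. A narrow window (e.g. 30 cM) constrains
only local distances; the consensus then integrates local information and
its long-wavelength error accumulates like a random walk. On synthetic maps
whose position errors are independent per marker, a 30 cM/5-neighbour window
made the consensus *worse* than every input map, while 100 cM/10 neighbours
recovers the expected averaging gain (consensus RMSE below every individual
map in 11–12 of 12 replicates). Real maps built by summing interval
estimates carry their own random-walk error, which masks the effect, but the
wider window is strictly safer and still sparse; both are configurable.

The consensus minimizes I_D = Σₙ wₙ D(M\*, Mₙ), wₙ = population size —
larger populations estimate distances more precisely and should pull
harder. Since eligibility and target distances are fixed by the individual
maps, I_D is quadratic in consensus positions; the minimizer solves the
weighted-Laplacian normal equations per connected constraint component
(sparse direct solve) with one position anchored, then shifts each component
to start at 0. Every marker of every input map appears exactly once: markers
whose chromosome label differs across maps go to the label with the larger
population weight; markers with no usable constraint are translated in from
their heaviest source map and flagged. Exact position ties are ordered by
mean normalized source position, then marker id. Inputs are first oriented
against a reference map (flip a group when that raises the shared-marker
Spearman correlation; ties keep the original orientation).

## Simulator (`popsim`)

The generator's defaults are the study conditions the pipeline is tested
under: three populations of 102, 147 and 96 F3 individuals; six linkage
groups of 480/255/245/215/200/170 cM (~1 565 cM total); 0.5% genotyping
error (a wrong call becomes one of the other two classes uniformly); 5%
missing data; and one distortion region spanning the last 40 cM of LG1 with
viability weights (0.5, 0.75, 1.0) favouring the male-parent homozygote.
Distortion is implemented as rejection sampling of whole individuals against
the product of per-locus genotype viability weights, so linked neighbours of
a selected locus are distorted through hitchhiking, reproducing clustered
regional distortion without a mechanistic model.

Markers are placed on a jittered regular grid (uniform jitter up to ±45% of
the mean spacing) rather than uniformly at random: at a few hundred markers,
Poisson scattering routinely leaves 25–40 cM gaps that no grouping threshold
can bridge at n ≈ 100, which says nothing about the method; dense real maps
are described by their authors as well distributed, and the jittered grid
keeps the largest gap near twice the mean spacing. One F1 is simulated per
population (descent from two F1s of homozygous parents gives the identical
genotype distribution).

What the simulator does **not** emulate: residual parental heterozygosity,
genotype-call errors correlated along the genome or between individuals
(e.g. shared low-coverage bias), segregating structural variation,
crossover interference, and non-random missingness. Passing parameter-
recovery tests therefore demonstrates correctness of the computation under
the stated model, not robustness to those real-data pathologies.

## Pipeline determinism and problem sizes

A run owns one integer seed; each stage draws from a stream forked by a
stable label (CRC of "stage:population:group"), so full reruns are
byte-identical and stages rerun in isolation reproduce their in-run
behaviour. The packaged parameter-recovery check runs the complete pipeline
at the study's population sizes with ~300 markers — the density per cM is
about a fifth of the real data's, which makes the recovery problem harder
per marker while keeping the run to a couple of minutes on one core; at this
size the pipeline recovers all six groups, ≥ 99% co-assignment, per-group
|Kendall τ| ≥ 0.95 and total corrected lengths within 10% of truth.

The pipeline's HMM error rate ε defaults to the simulator's error rate
(0.005): a mismatched ε biases map length in the direction of the mismatch
(ε too small inflates maps by explaining miscalls as double crossovers;
ε too large shrinks them by absorbing real recombination). With matched ε
the corrected totals come out 3–9% *short* of truth, dominated by end
truncation: terminal markers that defer to bin-mapping attach inward to
their closest framework marker, so a map cannot extend past its outermost
framework positions.

## Known limitations

* Phase is assumed known (coupling) throughout; dominant markers and
  repulsion-phase bookkeeping are out of scope.
* The F2→F3 correction addresses the generation mismatch exactly for two
  loci; multilocus residual effects (the F3 genotype process along a
  chromosome is not exactly Markov) are absorbed into the interval
  estimates and are small at typical densities.
* Consensus quality degrades gracefully but is not guaranteed when input
  maps disagree structurally (translocations); the method only averages
  distances, it does not detect rearrangements.
* `rf2_from_f3`/`correct_r` are specific to one selfing generation past the
  F2; other F_k would need the corresponding joint model (the gamete-
  transition machinery generalizes, an additional selfing round per k).
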