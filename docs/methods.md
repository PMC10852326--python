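# Methods

`corerecomb` measures homologous recombination in bacterial core genomes
from quasi-phased strain haplotypes. This note records the models it
implements, the parameters that matter, what the synthetic-data generators
do and do not emulate, and the numerical and design choices that were
genuinely open.

## Setting and data model

All analyses run on a `CoreGenomeSet`: an alignment of core-genome
haplotypes (one per strain) with per-column annotations (contig, position,
synonymous flag, gene). Strain metadata carries a host identifier and an
optional clade label. Downstream statistics are computed almost entirely on
synonymous sites, where selection on the sites themselves is weakest, and
always on pairwise *difference profiles*: the ordered 0/1 vector of allele
mismatches between two strains at compared sites. A site missing in either
strain is excluded from both the numerator and the denominator of
divergence, which keeps divergence unbiased under missingness that is
unrelated to genotype. Genomic coordinates are 1-based inclusive bp;
internal site indices are 0-based half-open. Blocks and windows never span
contig boundaries.

## Pairwise segmentation: the close-pair HMM (CP-HMM)

For a *closely related* pair — one whose clonal (vertically inherited)
frame still covers most of the genome — point mutations and recombined
fragments are spatially separable: mutations arrive as isolated mismatches
at per-site rate `d_clonal`, while a homologous recombination event
overwrites a contiguous tract with DNA from a donor lineage, importing that
donor's divergence (typically 100-1000x higher than `d_clonal`).

The CP-HMM is a hidden Markov chain over the synonymous sites of one pair:

* state 0, **clonal**: mismatches are Bernoulli(`d_clonal`);
* states 1..K, **recombined sub-states**: Bernoulli(`d_k`) with `d_k` the
  (geometric-mean) centre of bin k of an *empirical distribution of local
  divergence*, estimated by pooling sliding-window (default 1000 bp)
  divergences of typically diverged strain pairs into 12 log-spaced bins.
  Close pairs are excluded from that pool by an identical-block criterion
  (fraction of identical 1000-site blocks > 0.1), which — unlike a cutoff
  relative to the median divergence — keeps both modes of two-clade species
  in a pooled histogram.

Transitions: clonal -> recombined with per-site probability
`t_enter * w_k` (`w_k` the bin probabilities), recombined -> clonal with
`t_exit` (~1 / mean tract length in sites), no direct bin-to-bin moves.
The emission bins are fixed; (`d_clonal`, `t_enter`, `t_exit`) are
re-estimated per pair by EM (forward-backward with scaling; the
log-likelihood is checked to be non-decreasing every iteration and the
fit stops when it improves by less than `tol`, default 0.01 nats).
Initialization is a moment match on 1000-site block counts: `d_clonal`
from the low-count blocks, `t_exit = 1/2000`, and
`t_enter = (1 - clonal-block fraction) * t_exit`. Segmentation is by
Viterbi; ties prefer the clonal state, which biases toward fewer events.

Post-processing of the decoded path:

* events separated by < 100 bp of clonal path are merged (micro-gaps from
  emission noise inside long transfers);
* decoded segments carrying < 2 SNVs are discarded — a one-SNV segment is
  indistinguishable from a point mutation, so two imported SNVs are the
  sensitivity floor by construction;
* each event's local divergence is re-computed from the data inside it
  (SNVs / sites), not taken from the decoded sub-state;
* the reported clonal divergence is re-computed from the sites outside the
  final events; the clonal fraction `f_c` satisfies
  `f_c + (recombined sites)/(total sites) = 1` exactly.

Pairs whose block-level initial clonal divergence exceeds 2e-3 are rejected
(`NotAClosePairError`): outside the close-pair regime transfers overlap and
individual events are not resolvable.

Close pairs are selected by `d_clonal <= d*` and `f_c >= fc*`
(defaults 1e-4 and 0.2, configurable per species). Transfers in species
with an annotated two-clade structure are labelled within/between clade by
comparing their local divergence to the geometric midpoint
`sqrt(within_div * between_div)` — geometric because divergences are
log-spread. Transfers detected twice (their pairs share a strain,
reciprocal overlap >= 0.8, local divergences within 30% relative) are
clustered and all but one flagged as duplicates; duplicates are excluded
from all rate and length statistics.

Validation (also the acceptance suite): on 200 simulated pairs with 1 Mb of
synonymous sites, clonal divergence 5e-5, 10 transfers per pair of
geometric mean 20k sites and two-mode donor divergence (1% / 10%),
sensitivity for transfers carrying >= 5 SNVs exceeds 0.9 with < 0.5 false
events per pair and < 10% bias on the clonal divergence.

## The accumulated-transfers (mosaic) model

Over time a pair's clonal fraction decays as transfers accumulate. With
transfers arriving in proportion to clonal divergence `d_cl` and covering
the genome as a Poisson process, the clonal fraction is

    c = exp(-kappa * d_cl),

with `kappa` the overwrite rate per unit clonal divergence. Genome-wide
divergence interpolates between the clonal and recombined levels,

    d = c * d_cl + (1 - c) * d_bar_r,      d_cl = -ln(c) / kappa,

and the fraction of identical blocks of B synonymous sites is

    f_id = c * exp(-B * d_cl)

(block identical iff clonal and mutation-free). Fitting the (f_id, d)
cloud of all strain pairs by weighted least squares yields `kappa` and
`d_bar_r`. Two deliberate parameterization choices:

* the decay is parameterized against clonal *divergence*, not generations,
  so neither the mutation rate nor generation time enters the fit — only
  observable quantities do;
* `d_cl` is inferred from `f_id` by inverting
  `f_id = exp(-(kappa + B) d_cl)` *jointly inside the fit*, not by a
  two-step plug-in, avoiding bias when `d_cl B` is not small.

Weights are the inverse local density of points along the f_id axis, so
the dense near-clonal cloud does not dominate. Two optional refinements
(used by the validation experiments, off by default): a Jensen correction
for `-ln(f_hat)` when f_id is estimated from finitely many blocks, and a
block-edge correction replacing `kappa` by `kappa * (1 + B/fragment)` in
the f_id exponent, because a block is identical only if *no* transfer
overlaps it. Both are exact consequences of the Poisson-coverage model.

Timescales: `T_mosaic` (time for recombination to overwrite the genome)
corresponds to clonal divergence `1/kappa`; `T_mrca` (typical pair
coalescence) is proxied by `d_bar_r`, the clonal divergence a typical pair
would have accumulated; their ratio is `kappa * d_bar_r`. A fit with
`kappa * d_bar_r < 0.5` is flagged unidentifiable: below that the curve is
within noise of the pure-mutation line `d = -ln(f_id)/B` and the two
parameters are not separately meaningful. The neutral expectation for the
fraction of partially recombined ("close") pairs in a sample is
`P(Exp(1) < T_mosaic/T_mrca)`, evaluated by Monte-Carlo with the closed
form `1 - exp(-ratio)` as cross-check.

Recovery: on 200-pair cohorts with kappa=500, d_bar_r=0.02, 3000-site
(~20 kb) fragments and clonal divergences sampled so f_id is roughly
uniform on its measurable range, kappa and d_bar_r come back within 20%
and the timescale ratio within 25%; the weighted variance explained
exceeds 0.5 by a wide margin (~0.97).

## Cohort statistics over detected transfers

* **Trend curves** of event count (or cumulative recombined length) versus
  clonal divergence use a Nadaraya-Watson kernel mean with a Gaussian
  kernel in log10 divergence, bandwidth 0.25 decades (the smoother and
  bandwidth are declared choices; the local SD provides the spread band).
* **Apparent recombination rates** are transfers / clonal divergence /
  genome length, evaluated from the trend at reference divergences
  {2.5, 5, 7.5, 10} x 1e-5 when >= 100 close pairs are available, or as
  the per-pair distribution (each pair normalized by its own clonal
  divergence) otherwise.
* **Transfer lengths** are summarized by median and IQR over non-duplicate
  events.
* **Donor-divergence null**: each detected transfer is matched by random
  segments of the same bp length drawn at uniform positions from uniformly
  chosen non-focal strains; the segment's divergence to the focal
  background approximates what a "random donor" would look like. The
  observed transfer divergences are compared to this null by the K-S
  distance (two-sided sup-difference, the summary statistic) and a
  one-sided K-S p-value oriented to detect a *deficit* of high-divergence
  transfers — the signature of genetic isolation between clades.

## Runs of shared ancestry and the sharing landscape

A *run* is a maximal stretch of zero pairwise SNVs; a pair with k SNVs has
k+1 runs and `sum(runs) + k = compared sites` exactly. The longest run is
the test statistic for recent within-host recombination: its null under
randomly scattered mutations is simulated directly (uniform scatter of the
observed SNV count), and within-host versus between-host longest runs are
compared by a one-sided two-sample K-S test oriented so that significance
means within-host runs are stochastically *longer*.

The **sharing landscape** evaluates, at every synonymous site with a full
centered window, the fraction of eligible strain pairs identical across
the window. The window is `ceil(15 / d_bar)` synonymous sites by default,
so a typically diverged pair has probability ~e^-15 of chance identity.
"Identical" requires zero mismatches on observed sites and >= 90% of the
window observed in both strains. Pairings: between-host (optionally within
or between clades) and within-host (one pair per dual-colonized host, to
avoid pseudo-replication). The landscape's coefficient of variation
(SD/mean over positions) summarizes hotspot structure; neutral simulation
replicates provide its null band.

For a neutral recombining population the expected number of shared
fragments longer than `ell` between a random pair follows

    E[N(>ell)] = C * L / (d_bar * ell^2 * (1 + r/mu)^2),

with `r` the per-site recombination *initiation* rate. The scaling
exponents are taken as exact; the constant C = 2.6 was calibrated once
against the Moran simulator at a reference point (N=200, mu=1e-4,
rho=1e-4, 300-site fragments, ell = 5/d_bar) and is not re-fit.

**A documented discrepancy.** In the closed-population Moran simulator the
measured `ell`-scaling matches (log-log slope -2 within 0.3 on the
recombining ensemble), but the `(1+r/mu)^2` suppression does not: raising
r/mu from 0 to 1 changes fragment counts by only ~0.9-1.5x across the
counted range instead of 4x. Two opposing effects are responsible. A
conversion arriving on a young tract imports donor SNVs and ends it — a
boundary-rate argument in which mutation (rate mu) and conversion
initiation (rate r) compete gives one factor of `(1+r/mu)`, i.e. a 2x
asymptotic reduction. But in a closed population every conversion also
*creates* identity: the child shares the copied fragment with the donor
lineage at age zero, and these young donor-child tracts replenish the
count at shorter lengths. The squared suppression corresponds to a model
in which transfers only import typically diverged sequence (an open donor
pool) and no creation pathway exists. The package reports both the
measured ratio and the closed-form prediction; the corresponding
acceptance check is expected to fail against the closed-population
simulator, and we prefer that honest failure to switching the simulator
away from a self-consistent population model.

The **rotation-permutation test** for hotspot concordance correlates two
landscapes (Spearman by default, or a top-k mean) and builds the null by
cyclically rotating one landscape by uniform random offsets — preserving
its spatial autocorrelation, where site-wise shuffles would be
anti-conservative. Both orientations are exposed (`concordant`:
observed >= rotations; `discordant`: observed <= rotations) and the one
used is echoed in the result. Power for the discordance direction needs
*many* hotspots: a single displaced hotspot cannot be distinguished from a
random rotation (almost all rotations also misalign it). The validation
scenario therefore plants ~30 narrow sweeps per cohort at irregular,
mutually disjoint loci, so that nearly every rotation aligns some pair of
hotspots and the engineered disjoint arrangement sits ~3 null SDs into the
low tail (p ~ 0.004 with 3000 rotations).

## Within-host analyses

From a per-sample SNV table (contig, position, ref/alt, alt count, depth;
sites below depth 10 are masked):

* **Dual colonization**: >= 100 covered SNVs with alt frequency strictly
  inside (0.2, 0.8); the dominant strain's frequency is the mode of the
  folded intermediate-frequency histogram. Fewer than 500 covered sites is
  indeterminate rather than negative.
* **Quasi-phasing**: the dominant strain's allele is called where the
  major allele exceeds 80% frequency; intermediate sites are masked. On a
  simulated 85/15 two-strain mixture with binomial read sampling at depth
  100, > 90% of sites are called with < 1% error.
* **Gene-specific sweeps**: maximal gaps >= 10 kb between consecutive
  intermediate-frequency SNVs, with three guards — each 10 kb flank must
  keep >= 1 intermediate SNV per 2 kb (otherwise the "gap" is just a
  region where the two strains are identical); the regional median depth
  must stay within (0.6, 1.5) of the genome-wide median (a depletion with
  halved coverage is a deletion, not a sweep); and in longitudinal mode
  the region must additionally have been polymorphic at the earlier
  timepoint, which makes longitudinal calls a strict subset of
  single-timepoint calls.

## Neutral simulators

**Pair simulator** (`simulate_pair`): Bernoulli(mu_t) clonal backbone;
Poisson(gamma_t) transfers at uniform starts with geometric lengths
(memoryless — the simplest model consistent with ~20 kb mean-length
summaries; a constant-length switch exists for unit tests); interior
mismatches Bernoulli(donor divergence) with the donor divergence drawn per
transfer from a constant, finite-mixture, or empirical-sample
distribution; overlaps resolved last-writer-wins. Ground truth records the
*visible* post-overlap segments — what any detector could possibly see —
plus each segment's realized SNV count.

**Population simulator** (`simulate_population`): a forward-time Moran
model. Each birth event replaces a uniformly chosen individual with a copy
of a uniformly chosen parent; the newborn receives Poisson(mu L) point
mutations and Poisson(rho-weighted) gene conversions copying
geometric-length fragments from another uniformly chosen individual; an
optional hotspot multiplies the conversion initiation rate on a region.
Rates are per site per birth event; one generation is N events; the
default run length of 10N generations is ~20x the mean pair coalescence
time (N/2 generations), so sampled diversity is at equilibrium — verified
by the pairwise divergence plateau at `mu * N`. A forward model was chosen
over a coalescent with gene conversion because it is much simpler to
implement correctly and adequate at the scales used here (N <= 500,
L <= 1e6); for larger populations, rescale N down and mu, rho up keeping
`mu*N`, `rho*N` fixed. Seeded runs are bit-reproducible; the genome rows
are padded to 8-byte multiples internally so the per-event row copy (the
hot path) runs through an int64 view.

**Sweep injection** (`inject_sweep`): copies one donor's region into a
fraction of strains (hard) or k donors' regions into fraction/k each
(soft), leaving everything else untouched.

What the generators deliberately do not emulate: gene gain/loss and
accessory genomes, selection other than injected sweeps, demographic
structure, sequencing error, and reference/mapping artifacts. Passing
tests therefore demonstrate the statistical machinery under the stated
generative models, not robustness to upstream bioinformatic noise.

## Problem sizes of the validation experiments

The validation experiments (also run by `scripts/acceptance.py`) use: 200
close pairs of 1e6 synonymous sites for event recovery; 40 pure-mutation
pairs of 1e5 sites per divergence point for the gray line; 200-pair
cohorts of 4e5 sites for the mosaic fit; 2 x 50 Moran replicates (N=200,
L=2e4) for the shared-fragment scaling; 200 null + 200 power replicates of
n=30 hosts for the longest-run test; 100 neutral Moran replicates (N=100,
L=2e4) for the CV null band; 40 hotspot replicates; and 60 planted events
for the donor-divergence test. These sizes were chosen so each experiment
resolves its target quantity with comfortable Monte-Carlo margin on a
single CPU.

## Known limitations

* Close pairs within a species are not phylogenetically independent; the
  cohort statistics treat them as exchangeable (duplicate flagging removes
  the most direct double counting, nothing more).
* The sensitivity floor of two SNVs per event means short or very
  low-divergence transfers are invisible; rate estimates are apparent
  rates above that floor.
* The longest-run K-S comparison has essentially no power when only ~10%
  of n=30 within-host pairs carry an extra long tract: the one-sided
  two-sample K-S statistic is then bounded near 0.1, which cannot reach
  p < 0.05 at those sample sizes. The corresponding acceptance check
  documents this limit rather than replacing the prescribed test.
* The `(1+r/mu)^2` shared-fragment suppression is not reproduced by the
  closed-population simulator (see above).
* `T_mrca` is proxied by `d_bar_r`; if recombined fragments come from a
  biased subset of donors the ratio `kappa * d_bar_r` inherits that bias.
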