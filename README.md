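# corerecomb

Detection and interpretation of homologous recombination in bacterial core
genomes, built for strain-resolved metagenomics of host-associated
communities (e.g., prevalent human-gut commensals) but applicable to any
aligned collection of conspecific core-genome haplotypes.

Within a bacterial species, point mutation changes single sites while
homologous recombination overwrites whole tracts with DNA from a donor
lineage. Between a *closely related* pair of strains the two processes are
spatially separable: the clonal frame carries isolated mutations at per-site
divergence `d_clonal`, while each recombined fragment is a contiguous block
of much higher local divergence. `corerecomb` provides:

* **CP-HMM** — a per-pair hidden Markov model with one clonal state
  (Bernoulli `d_clonal`) and a recombined macro-state expanded into
  sub-states over the *empirical distribution of local divergence*, fit by
  EM and decoded by Viterbi. It outputs clonal divergence, clonal fraction
  `f_c`, and individual transfer events with coordinates, lengths, local
  divergences, within/between-clade labels, and duplicate flags.
* **Accumulated-transfers model** — the clonal fraction decays with clonal
  divergence as `c = exp(-kappa * d_cl)`; genome-wide divergence follows
  `d = c * d_cl + (1 - c) * d_bar_r`, and the fraction of identical
  1000-site blocks is `f_id = c * exp(-B * d_cl)`. Fitting the (f_id, d)
  cloud of all strain pairs yields `kappa`, `d_bar_r`, and the timescale
  ratio `T_mrca / T_mosaic = kappa * d_bar_r`.
* **Transfer statistics** — local-regression trends of transfer counts vs
  clonal divergence, apparent recombination rates
  (transfers / clonal divergence / genome length) at reference divergences,
  transfer-length summaries, and a one-sided Kolmogorov–Smirnov comparison
  of transfer divergences against a random-segment null.
* **Selection scans** — runs of shared ancestry (longest zero-SNV run,
  within- vs between-host K-S test), the haplotype-sharing landscape
  (per-site probability that a random strain pair is identical over a
  window of `15 / d_bar` synonymous sites), its coefficient of variation
  against neutral null bands, the closed-form shared-fragment count
  `~ L / (d_bar * ell^2 * (1 + r/mu)^2)`, and a rotation-permutation test
  for hotspot concordance between landscapes.
* **Within-host analyses** — dual-colonization detection from intermediate
  allele frequencies, quasi-phasing of the dominant strain, and
  gene-specific sweep detection (local depletion of intermediate-frequency
  SNVs at preserved read coverage).
* **Neutral simulators** — a single-pair generator with known planted
  transfers (the detection oracle) and a forward-time Moran model with gene
  conversion (population-level nulls), plus hard/soft sweep injection.

See `docs/methods.md` for models, assumptions, parameter defaults, and
known limitations.

## Worked example

Simulate one closely related pair (1 Mb of synonymous sites, clonal
divergence `5e-5`, ten ~20 kb transfers whose donors are a 70/30 mixture of
1%- and 10%-diverged lineages) and decode it:

```python
import numpy as np
from corerecomb.cphmm import EmpiricalDivDist, fit_decode_pair
from corerecomb.neutral_sim import DonorDivergence, PairSimConfig, simulate_pair

cfg = PairSimConfig(
    L_sites=1_000_000, mu_t=5e-5, gamma_t=10, mean_frag_sites=2e4,
    donor_div_dist=DonorDivergence(values=(0.01, 0.10), weights=(0.7, 0.3)),
    seed=1,
)
profile, truth = simulate_pair(cfg)

rng = np.random.default_rng(0)
emissions = EmpiricalDivDist.from_samples(
    rng.choice([0.01, 0.10], 3000, p=[0.7, 0.3]) * np.exp(rng.normal(0, 0.2, 3000))
)
dec = fit_decode_pair(profile, emissions)
print(f"clonal divergence: {dec.d_clonal_hat:.2e}   clonal fraction: {dec.clonal_fraction:.3f}")
print(f"events detected: {dec.n_events}   (visible in truth: {len(truth.segments)})")
for e in dec.events[:3]:
    print(f"  {e.start_bp:>7}-{e.end_bp:<7} {e.length_bp:>6} bp  {e.n_snvs:>5} SNVs  divergence {e.local_div:.3f}")
```

This prints:

```
clonal divergence: 4.53e-05   clonal fraction: 0.817
events detected: 9   (visible in truth: 9)
    85426-96584    11159 bp   1158 SNVs  divergence 0.104
   202715-216864   14150 bp    159 SNVs  divergence 0.011
   238638-244952    6315 bp     68 SNVs  divergence 0.011
```

All nine visible transfers are recovered with boundaries within a few sites
of truth; the estimated clonal divergence (4.5e-5 vs the generating 5e-5)
reflects the ~41 clonal SNVs actually realized on this backbone, and the
decoded events separate cleanly into the 1% (within-clade-like) and 10%
(between-clade-like) donor modes.

A command-line pipeline wraps the same machinery for on-disk data
(`corerecomb simulate | detect | stats | sharing | withinhost`); inputs are
an aligned FASTA (record ids `strain|host[|clade]`) plus a site-annotation
TSV, and all outputs are TSV tables with a JSON run manifest.

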