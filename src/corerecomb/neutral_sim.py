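"""Neutral generative models for recombining bacterial core genomes.

Two levels of simulation are provided:

* :func:`simulate_pair` draws the mismatch profile of a single closely
  related strain pair: a clonal backbone of Bernoulli point mutations, plus a
  Poisson number of recombined fragments with geometric lengths whose
  interior mismatch density follows a configurable donor-divergence
  distribution.  The realized (possibly overlapping, last-writer-wins)
  fragments are returned as ground truth for validating event detection.

* :func:`simulate_population` runs a forward-time Moran model with gene
  conversion, producing a whole sample of core-genome haplotypes under
  neutrality.  It supplies the null ensembles for haplotype-sharing
  statistics and for the shared-fragment scaling law.

:func:`inject_sweep` plants hard or soft gene-specific sweeps into a
simulated population for power analyses of the selection scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .core_data import CoreGenomeSet, DiffProfile, profile_from_diff

__all__ = [
    "DonorDivergence",
    "PairSimConfig",
    "PopSimConfig",
    "TruthSegment",
    "SimTruth",
    "simulate_pair",
    "simulate_population",
    "inject_sweep",
]


@dataclass(frozen=True)
class DonorDivergence:
    """Distribution of per-site donor divergence of transferred fragments.

    A finite mixture: ``values[i]`` is drawn with probability ``weights[i]``.
    Use a single value for a constant distribution, or many values with equal
    weights for an empirical sample.
    """

    values: tuple
    weights: tuple | None = None

    def __post_init__(self):
        vals = np.asarray(self.values, float)
        if np.any((vals <= 0) | (vals >= 1)):
            raise ValueError("donor divergences must lie in (0, 1)")
        if self.weights is not None and len(self.weights) != len(vals):
            raise ValueError("weights must match values")

    @classmethod
    def constant(cls, d: float) -> "DonorDivergence":
        return cls(values=(float(d),))

    @classmethod
    def empirical(cls, samples: Sequence[float]) -> "DonorDivergence":
        return cls(values=tuple(float(s) for s in samples))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        vals = np.asarray(self.values, float)
        if len(vals) == 1:
            return np.full(size, vals[0])
        p = None
        if self.weights is not None:
            w = np.asarray(self.weights, float)
            p = w / w.sum()
        return rng.choice(vals, size=size, p=p)


@dataclass(frozen=True)
class PairSimConfig:
    """Parameters of a single-pair simulation.

    ``mu_t`` is the expected clonal divergence 2*mu*T per synonymous site;
    ``gamma_t`` the expected number of transfers accumulated over the pair's
    joint history; fragment lengths are geometric with mean
    ``mean_frag_sites``.  ``clade_frac_between`` sends that fraction of
    transfers to ``donor_div_between`` instead of ``donor_div_dist``.
    """

    L_sites: int
    mu_t: float
    gamma_t: float
    mean_frag_sites: float = 2.0e4
    donor_div_dist: DonorDivergence = field(
        default_factory=lambda: DonorDivergence.constant(0.01)
    )
    donor_div_between: DonorDivergence | None = None
    clade_frac_between: float = 0.0
    constant_frag: bool = False  # constant instead of geometric lengths
    seed: int = 0

    def __post_init__(self):
        if self.L_sites < 1:
            raise ValueError("L_sites must be positive")
        if self.mu_t < 0 or self.gamma_t < 0 or self.clade_frac_between < 0:
            raise ValueError("rates must be non-negative")
        if self.mean_frag_sites < 1:
            raise ValueError("mean_frag_sites must be >= 1")
        if self.clade_frac_between > 0 and self.donor_div_between is None:
            raise ValueError("clade_frac_between > 0 requires donor_div_between")


@dataclass(frozen=True)
class TruthSegment:
    """One visible (post-overlap) recombined segment of a simulated pair."""

    start_site: int  # 0-based, half-open
    end_site: int
    donor_div: float
    is_between: bool
    n_snvs: int

    @property
    def length_sites(self) -> int:
        return self.end_site - self.start_site


@dataclass
class SimTruth:
    """Ground truth attached to a simulation run."""

    segments: list
    d_clonal_true: float
    recombined_fraction: float = 0.0
    params: dict = field(default_factory=dict)


def simulate_pair(cfg: PairSimConfig) -> tuple[DiffProfile, SimTruth]:
    """Simulate the synonymous-site mismatch profile of one close pair."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.L_sites
    diff = (rng.random(L) < cfg.mu_t).astype(np.uint8)

    n_tr = rng.poisson(cfg.gamma_t)
    owner = np.full(L, -1, dtype=np.int64)
    info = []  # (donor_div, is_between) per transfer
    if n_tr > 0:
        starts = rng.integers(0, L, size=n_tr)
        if cfg.constant_frag:
            lengths = np.full(n_tr, int(round(cfg.mean_frag_sites)))
        else:
            lengths = rng.geometric(1.0 / cfg.mean_frag_sites, size=n_tr)
        between = rng.random(n_tr) < cfg.clade_frac_between
        n_b = int(between.sum())
        divs = np.empty(n_tr)
        divs[~between] = cfg.donor_div_dist.sample(rng, n_tr - n_b)
        if n_b:
            divs[between] = cfg.donor_div_between.sample(rng, n_b)
        for i in range(n_tr):
            s = int(starts[i])
            e = min(s + int(lengths[i]), L)
            diff[s:e] = rng.random(e - s) < divs[i]
            owner[s:e] = i
            info.append((float(divs[i]), bool(between[i])))

    segments = []
    recombined_sites = 0
    if n_tr > 0:
        boundaries = np.flatnonzero(np.diff(owner)) + 1
        edges = np.concatenate(([0], boundaries, [L]))
        for lo, hi in zip(edges[:-1], edges[1:]):
            o = owner[lo]
            if o >= 0:
                d, b = info[o]
                segments.append(
                    TruthSegment(
                        start_site=int(lo),
                        end_site=int(hi),
                        donor_div=d,
                        is_between=b,
                        n_snvs=int(diff[lo:hi].sum()),
                    )
                )
                recombined_sites += hi - lo

    profile = profile_from_diff(diff, pair=("sim_a", "sim_b"))
    truth = SimTruth(
        segments=segments,
        d_clonal_true=cfg.mu_t,
        recombined_fraction=recombined_sites / L,
        params={"config": cfg},
    )
    return profile, truth


# ---------------------------------------------------------------------------
# Population-level Moran simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopSimConfig:
    """Forward Moran model parameters.

    Rates ``mu`` and ``rho`` are per site per birth event (i.e., per newborn
    genome).  One "generation" is N birth events; the default run length of
    ``10 * N`` generations comfortably exceeds the mean pair coalescence time
    of N/2 generations, so sampled diversity is at mutation-drift(-conversion)
    equilibrium.  Expected pairwise synonymous divergence is ``mu * N``.
    """

    N: int
    n_sample: int
    L_sites: int
    mu: float
    rho: float
    mean_frag_sites: float = 300.0
    generations: int | None = None  # default 10 * N
    hotspot: tuple[tuple[int, int], float] | None = None  # ((lo, hi), multiplier)
    seed: int = 0

    def __post_init__(self):
        if not (self.N >= self.n_sample >= 2):
            raise ValueError("need N >= n_sample >= 2")
        if self.generations is not None and self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.mu < 0 or self.rho < 0:
            raise ValueError("rates must be non-negative")
        if self.hotspot is not None:
            (lo, hi), mult = self.hotspot
            if not (0 <= lo < hi <= self.L_sites) or mult < 0:
                raise ValueError("invalid hotspot specification")

    @property
    def expected_pairwise_divergence(self) -> float:
        return self.mu * self.N

    @property
    def r_over_mu(self) -> float:
        """Conversion initiation rate relative to mutation rate (per site).

        This is the ``r/mu`` of the shared-fragment scaling law: what ends a
        zero-SNV run is the *arrival* of a conversion (one arrival imports
        SNVs regardless of fragment length), so the initiation rate, not the
        coverage rate rho * fragment length, is the relevant competitor of
        the per-site mutation rate.
        """
        if self.mu == 0:
            return float("inf") if self.rho > 0 else 0.0
        return self.rho / self.mu


def simulate_population(cfg: PopSimConfig) -> tuple[CoreGenomeSet, SimTruth]:
    """Run the Moran model and sample ``n_sample`` haplotypes.

    Returns a :class:`CoreGenomeSet` whose sites are all synonymous (single
    contig, 1 bp per site) with each sampled strain assigned to its own host,
    plus a :class:`SimTruth` echoing the generating parameters (individual
    conversion events are not logged at population scale).
    """
    gens = cfg.generations if cfg.generations is not None else 10 * cfg.N
    n_events = int(gens) * cfg.N
    if cfg.hotspot is not None:
        (hot_lo, hot_hi), hot_mult = cfg.hotspot
    else:
        hot_lo, hot_hi, hot_mult = 0, 0, 1.0
    pop = _kernels.moran_simulate(
        cfg.N,
        cfg.L_sites,
        cfg.mu,
        cfg.rho,
        cfg.mean_frag_sites,
        n_events,
        hot_lo,
        hot_hi,
        hot_mult,
        int(cfg.seed) % (2**31 - 1),
    )
    rng = np.random.default_rng(cfg.seed)
    idx = rng.choice(cfg.N, size=cfg.n_sample, replace=False)
    haps = pop[np.sort(idx)].copy()

    sites = pd.DataFrame(
        {
            "contig": np.repeat("sim", cfg.L_sites),
            "pos_bp": np.arange(1, cfg.L_sites + 1, dtype=np.int64),
            "is_synonymous": np.ones(cfg.L_sites, dtype=bool),
            "gene_id": [None] * cfg.L_sites,
        }
    )
    meta = pd.DataFrame(
        {
            "strain_id": [f"s{i:03d}" for i in range(cfg.n_sample)],
            "host_id": [f"h{i:03d}" for i in range(cfg.n_sample)],
            "clade_id": [None] * cfg.n_sample,
        }
    )
    genomes = CoreGenomeSet(
        species_name="moran_sim", sites=sites, haplotypes=haps, strain_meta=meta
    )
    truth = SimTruth(
        segments=[],
        d_clonal_true=float("nan"),
        params={"config": cfg, "n_events": n_events},
    )
    return genomes, truth


def inject_sweep(
    genomes: CoreGenomeSet,
    region: tuple[int, int],
    mode: str = "hard",
    donor: str | None = None,
    carrier_fraction: float = 0.5,
    seed: int = 0,
) -> CoreGenomeSet:
    """Copy donor haplotype(s) over ``region`` into a fraction of strains.

    ``mode='hard'`` copies a single donor's region into
    ``carrier_fraction`` of the strains (the donor among them).
    ``mode='soft_k'`` (e.g. ``'soft_3'``) uses k distinct donors, each copied
    into carrier_fraction/k of the strains.  ``region`` is a 0-based
    half-open site-index range.  Returns a new CoreGenomeSet.
    """
    lo, hi = region
    if not (0 <= lo < hi <= genomes.n_sites):
        raise ValueError(f"empty or out-of-bounds region {region}")
    if not (0 < carrier_fraction <= 1):
        raise ValueError("carrier_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = genomes.n_strains
    haps = genomes.haplotypes.copy()

    if mode == "hard":
        k = 1
    elif mode.startswith("soft_"):
        k = int(mode.split("_", 1)[1])
        if k < 2:
            raise ValueError("soft sweeps need k >= 2 donors")
    else:
        raise ValueError(f"unknown sweep mode {mode!r}")

    n_carriers = max(k, int(round(carrier_fraction * n)))
    carriers = rng.choice(n, size=n_carriers, replace=False)
    if donor is not None and k == 1:
        d_idx = genomes.strain_index(donor)
        if d_idx not in carriers:
            carriers[0] = d_idx
        donors = np.array([d_idx])
    else:
        donors = rng.choice(carriers, size=k, replace=False)
    groups = np.array_split(carriers, k)
    for d, grp in zip(donors, groups):
        haps[grp, lo:hi] = haps[d, lo:hi]
    return CoreGenomeSet(
        species_name=genomes.species_name,
        sites=genomes.sites,
        haplotypes=haps,
        strain_meta=genomes.strain_meta.copy(),
    )
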