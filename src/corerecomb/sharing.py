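"""Identity-tract statistics and the haplotype-sharing landscape.

Runs of shared ancestry are maximal stretches of zero pairwise SNVs; their
lengths (especially the longest run per pair) distinguish recent within-host
recombination from the background sharing expected between unrelated strains.
The sharing landscape generalizes this genome-wide: for each core position,
the fraction of eligible strain pairs identical across a window of
``Delta-l`` synonymous sites (chosen so window * typical divergence >> 1).
Hotspots of elevated sharing across many pairs indicate selection on
transferred haplotypes; the coefficient of variation of the landscape
summarizes this against neutral-simulation null bands, and a
rotation-permutation test compares hotspot locations between two landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import CoreGenomeSet, DiffProfile

__all__ = [
    "RunSet",
    "SharingLandscape",
    "identical_runs",
    "runs_null_random_scatter",
    "compare_within_between_runs",
    "sharing_landscape",
    "landscape_cv",
    "expected_shared_fragments",
    "calibrate_shared_fragment_constant",
    "hotspot_permutation_test",
]


@dataclass
class RunSet:
    """Maximal zero-SNV runs of one pair, in compared-site units."""

    pair: tuple[str, str]
    run_lengths_sites: np.ndarray  # one entry per maximal run (can be 0)
    run_bounds_bp: np.ndarray  # (n_runs, 2) genomic bp spans
    n_sites: int

    @property
    def longest_run(self) -> int:
        return int(self.run_lengths_sites.max()) if len(self.run_lengths_sites) else 0

    def total_above(self, min_sites: int) -> int:
        r = self.run_lengths_sites
        return int(r[r >= min_sites].sum())


@dataclass
class SharingLandscape:
    """Per-core-site probability of window identity over eligible pairs."""

    site_index: np.ndarray  # 0-based indices of evaluated sites
    pos_bp: np.ndarray
    p_share: np.ndarray
    window_syn_sites: int
    pairing: str
    n_pairs: int
    mean_pair_divergence: float = float("nan")
    per_pair_share: np.ndarray | None = None  # mean window identity per pair


def identical_runs(profile: DiffProfile) -> RunSet:
    """Maximal gaps between consecutive SNVs (and the genome ends).

    A profile with k SNVs yields k+1 runs (some possibly of length 0);
    the bookkeeping identity sum(runs) + #SNVs == #compared sites holds.
    """
    diff_idx = np.flatnonzero(profile.diff)
    n = profile.n_sites
    edges = np.concatenate(([-1], diff_idx, [n]))
    lengths = np.diff(edges) - 1
    pos = profile.syn_site_index
    bounds = []
    for lo_e, hi_e in zip(edges[:-1], edges[1:]):
        lo, hi = lo_e + 1, hi_e  # half-open site range of the run
        if hi > lo:
            bounds.append((int(pos[lo]), int(pos[hi - 1])))
        else:
            bounds.append((0, -1))  # empty run
    return RunSet(
        pair=profile.pair,
        run_lengths_sites=lengths.astype(np.int64),
        run_bounds_bp=np.asarray(bounds, dtype=np.int64),
        n_sites=n,
    )


def runs_null_random_scatter(
    n_snvs: int,
    L_sites: int,
    reps: int = 1000,
    seed: int = 0,
):
    """Null distribution of the longest zero-SNV run under uniform scatter.

    Returns ``(null_longest, p_value_fn)`` where ``p_value_fn(observed)``
    gives the (add-one) upper-tail probability of a run at least as long.
    """
    if n_snvs > L_sites:
        raise ValueError("cannot place more SNVs than sites")
    rng = np.random.default_rng(seed)
    if n_snvs == 0:
        null = np.full(reps, L_sites, dtype=np.int64)
    else:
        null = np.empty(reps, dtype=np.int64)
        for r in range(reps):
            pos = np.sort(rng.choice(L_sites, size=n_snvs, replace=False))
            edges = np.concatenate(([-1], pos, [L_sites]))
            null[r] = (np.diff(edges) - 1).max()

    def p_value(observed: float) -> float:
        return float((1 + np.sum(null >= observed)) / (reps + 1))

    return null, p_value


def compare_within_between_runs(
    within_longest,
    between_longest,
    min_n: int = 5,
):
    """One-sided two-sample K-S test: within-host runs longer than between?

    Tests whether the within-host longest-run distribution stochastically
    dominates the between-host one (the direction expected if within-host
    recombination plus gene-specific sweeps create recent long tracts).
    Returns ``(p_value, low_power_flag)``.
    """
    within = np.asarray(within_longest, float)
    between = np.asarray(between_longest, float)
    if len(within) < min_n or len(between) < min_n:
        raise ValueError(f"need at least {min_n} values in each sample")
    # alternative='less': alternative is F_within(x) < F_between(x),
    # i.e. within-host runs stochastically LARGER
    res = stats.ks_2samp(within, between, alternative="less", method="auto")
    low_power = len(within) < 10 or len(between) < 10
    return float(res.pvalue), low_power


# ---------------------------------------------------------------------------
# Sharing landscape
# ---------------------------------------------------------------------------


def _eligible_pairs(genomes: CoreGenomeSet, pairing: str):
    meta = genomes.strain_meta
    hosts = meta["host_id"].to_list()
    clades = meta["clade_id"].to_list()
    n = len(hosts)
    pairs = []
    if pairing == "within_host":
        # one pair per dual-colonized host to avoid pseudo-replication
        by_host: dict = {}
        for i, h in enumerate(hosts):
            by_host.setdefault(h, []).append(i)
        for h, members in by_host.items():
            if len(members) >= 2:
                pairs.append((members[0], members[1]))
        return pairs
    for i in range(n):
        for j in range(i + 1, n):
            if hosts[i] == hosts[j]:
                continue
            same_clade = (
                clades[i] is not None
                and clades[j] is not None
                and clades[i] == clades[j]
            )
            if pairing == "between_host_within_clade":
                no_clades = clades[i] is None and clades[j] is None
                if same_clade or no_clades:
                    pairs.append((i, j))
            elif pairing == "between_host_between_clade":
                if (
                    clades[i] is not None
                    and clades[j] is not None
                    and clades[i] != clades[j]
                ):
                    pairs.append((i, j))
            elif pairing == "between_host":
                pairs.append((i, j))
            else:
                raise ValueError(f"unknown pairing {pairing!r}")
    return pairs


def sharing_landscape(
    genomes: CoreGenomeSet,
    pairing: str = "between_host",
    window_syn_sites: int | None = None,
    min_pairs: int = 10,
    max_pairs: int | None = None,
    min_coverage: float = 0.9,
    window_over_dbar: float = 15.0,
    seed: int = 0,
) -> SharingLandscape:
    """Per-position probability that a random eligible pair is identical
    across a centered window of synonymous sites.

    The automatic window is ``ceil(window_over_dbar / d_bar)`` synonymous
    sites, with ``d_bar`` the mean pairwise divergence of the eligible pairs,
    so that identity across a window is vanishingly unlikely for typically
    diverged sequence.  "Identical" requires zero mismatches on the
    non-missing sites of the window and at least ``min_coverage`` of its
    sites observed in both strains.  Only positions with a full window are
    evaluated.
    """
    pairs = _eligible_pairs(genomes, pairing)
    if len(pairs) < min_pairs:
        raise ValueError(f"only {len(pairs)} eligible pairs (need {min_pairs})")
    rng = np.random.default_rng(seed)
    if max_pairs is not None and len(pairs) > max_pairs:
        sel = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sel]

    syn_cols = np.flatnonzero(genomes.syn_mask)
    L = len(syn_cols)
    haps = genomes.haplotypes[:, syn_cols]
    pos = genomes.sites["pos_bp"].to_numpy()[syn_cols]

    # mean divergence of eligible pairs (observed sites only)
    divs = []
    for i, j in pairs:
        a, b = haps[i], haps[j]
        ok = (a >= 0) & (b >= 0)
        if ok.sum():
            divs.append(np.mean(a[ok] != b[ok]))
    d_bar = float(np.mean(divs)) if divs else float("nan")

    if window_syn_sites is None:
        if not np.isfinite(d_bar) or d_bar <= 0:
            raise ValueError("cannot auto-size window: pairs are identical")
        window_syn_sites = int(np.ceil(window_over_dbar / d_bar))
    if window_syn_sites > L:
        raise ValueError(
            f"window of {window_syn_sites} sites exceeds the {L} available"
        )

    w = window_syn_sites
    n_eval = L - w + 1
    share_counts = np.zeros(n_eval, dtype=np.int64)
    per_pair = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        a, b = haps[i], haps[j]
        both = (a >= 0) & (b >= 0)
        mism = both & (a != b)
        cs_m = np.concatenate(([0], np.cumsum(mism, dtype=np.int64)))
        cs_c = np.concatenate(([0], np.cumsum(both, dtype=np.int64)))
        n_mism = cs_m[w:] - cs_m[:-w]
        n_cov = cs_c[w:] - cs_c[:-w]
        ident = (n_mism == 0) & (n_cov >= min_coverage * w)
        share_counts += ident
        per_pair[k] = ident.mean()
    p_share = share_counts / len(pairs)
    centers = np.arange(n_eval) + w // 2
    return SharingLandscape(
        site_index=syn_cols[centers],
        pos_bp=pos[centers],
        p_share=p_share,
        window_syn_sites=w,
        pairing=pairing,
        n_pairs=len(pairs),
        mean_pair_divergence=d_bar,
        per_pair_share=per_pair,
    )


def landscape_cv(landscape: SharingLandscape, min_positions: int = 100) -> float:
    """Coefficient of variation (SD/mean) of sharing across the genome."""
    p = landscape.p_share
    if len(p) < min_positions:
        raise ValueError(f"need >= {min_positions} evaluated positions")
    m = p.mean()
    if m == 0:
        raise ValueError("mean sharing probability is zero; CV undefined")
    return float(p.std() / m)


# Calibration constant for the closed-form shared-fragment count, fixed once
# against the Moran simulator at the reference point N=200, mu=1e-4,
# rho=1e-4 (r/mu=1), fragment mean 300 sites, ell=5/d_bar=250 sites
# (see docs/methods.md).
SHARED_FRAGMENT_CALIBRATION = 2.6


def expected_shared_fragments(
    L_sites: float,
    d_bar: float,
    r_over_mu: float,
    ell: float,
    calibration: float = SHARED_FRAGMENT_CALIBRATION,
) -> float:
    """Closed-form expected number of shared fragments longer than ``ell``.

    Scales as L / (d_bar * ell^2 * (1 + r/mu)^2): longer thresholds and more
    recombination both suppress long shared tracts, each quadratically.  The
    overall constant is calibrated once against the neutral simulator; the
    scaling exponents are exact.
    """
    if min(L_sites, d_bar, ell) <= 0 or r_over_mu < 0:
        raise ValueError("all arguments must be positive (r/mu non-negative)")
    return calibration * L_sites / (d_bar * ell**2 * (1.0 + r_over_mu) ** 2)


def count_shared_fragments(genomes: CoreGenomeSet, ell: int) -> float:
    """Mean number of zero-SNV runs >= ell sites per strain pair (observed)."""
    syn_cols = np.flatnonzero(genomes.syn_mask)
    haps = genomes.haplotypes[:, syn_cols]
    n = genomes.n_strains
    total = 0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = (haps[i] != haps[j]) & (haps[i] >= 0) & (haps[j] >= 0)
            idx = np.flatnonzero(d)
            edges = np.concatenate(([-1], idx, [len(d)]))
            runs = np.diff(edges) - 1
            total += int((runs >= ell).sum())
            n_pairs += 1
    return total / n_pairs


def calibrate_shared_fragment_constant(observed_count, L_sites, d_bar, r_over_mu, ell):
    """Back out the calibration constant from one simulator measurement."""
    raw = L_sites / (d_bar * ell**2 * (1.0 + r_over_mu) ** 2)
    return observed_count / raw


def hotspot_permutation_test(
    landscape_a,
    landscape_b,
    reps: int = 1000,
    seed: int = 0,
    statistic: str = "spearman",
    alternative: str = "discordant",
) -> dict:
    """Rotation-permutation test for hotspot concordance of two landscapes.

    The statistic correlates the two landscapes position-by-position
    (``spearman``) or measures the mean of ``a`` at ``b``'s top-k positions
    (``topk``); the null is built by cyclically rotating landscape ``b`` by a
    uniform random offset, preserving its spatial autocorrelation.
    ``alternative='discordant'`` (hotspots at *different* loci) counts null
    statistics <= observed; ``'concordant'`` counts >= observed.  The chosen
    orientation is echoed in the result for reporting.
    """
    a = landscape_a.p_share if isinstance(landscape_a, SharingLandscape) else np.asarray(landscape_a, float)
    b = landscape_b.p_share if isinstance(landscape_b, SharingLandscape) else np.asarray(landscape_b, float)
    if len(a) != len(b):
        raise ValueError("landscapes must share a coordinate system (equal length)")
    if reps < 1000:
        raise ValueError("need reps >= 1000 for stable tail estimates")
    if alternative not in ("discordant", "concordant"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(seed)
    n = len(a)

    if statistic == "spearman":
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        ra = (ra - ra.mean()) / ra.std()
        rb = (rb - rb.mean()) / rb.std()

        def stat(shift):
            return float(np.mean(ra * np.roll(rb, shift)))

    elif statistic == "topk":
        k = max(1, n // 100)
        order_b = np.argsort(b)[::-1][:k]

        def stat(shift):
            return float(np.mean(a[(order_b + shift) % n]))

    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = stat(0)
    shifts = rng.integers(1, n, size=reps)
    null = np.array([stat(int(s)) for s in shifts])
    if alternative == "discordant":
        p = float((1 + np.sum(null <= observed)) / (reps + 1))
    else:
        p = float((1 + np.sum(null >= observed)) / (reps + 1))
    return {
        "p_value": p,
        "observed": observed,
        "statistic": statistic,
        "alternative": alternative,
        "n_rotations": reps,
    }
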