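"""Simulation-based validation experiments for the whole pipeline.

Each function runs one self-contained experiment — generate synthetic data
under known conditions, run the relevant pipeline stage, measure recovery or
calibration — and returns a flat dict of metrics.  The experiments double as
the package's acceptance checks and as worked examples of how the pieces fit
together; all randomness flows from a single integer seed.
"""

from __future__ import annotations

import numpy as np

from . import mosaic_model
from .core_data import fraction_identical_blocks, partition_blocks, profile_from_diff
from .cphmm import EmpiricalDivDist, TransferEvent, fit_decode_pair
from .mosaic_model import fit_mosaic, tmrca_over_tmosaic
from .neutral_sim import (
    DonorDivergence,
    PairSimConfig,
    PopSimConfig,
    inject_sweep,
    simulate_pair,
    simulate_population,
)
from .sharing import (
    compare_within_between_runs,
    count_shared_fragments,
    hotspot_permutation_test,
    identical_runs,
    landscape_cv,
    sharing_landscape,
)
from .transfer_stats import donor_divergence_null

TWO_MODE_DONOR = DonorDivergence(values=(0.01, 0.10), weights=(0.7, 0.3))


def _two_mode_emissions(seed: int, n_samples: int = 3000) -> EmpiricalDivDist:
    """Emission model matching the two-mode donor-divergence mixture, with
    log-normal window-to-window scatter as seen in sliding-window tracks."""
    rng = np.random.default_rng(seed)
    samples = rng.choice([0.01, 0.10], n_samples, p=[0.7, 0.3]) * np.exp(
        rng.normal(0, 0.2, n_samples)
    )
    return EmpiricalDivDist.from_samples(samples)


# ---------------------------------------------------------------------------
# 1. CP-HMM event recovery
# ---------------------------------------------------------------------------


def cphmm_event_recovery(
    n_pairs: int = 200,
    L_sites: int = 1_000_000,
    d_clonal: float = 5e-5,
    transfers_per_pair: float = 10.0,
    mean_frag_sites: float = 2e4,
    min_truth_snvs: int = 5,
    match_overlap: float = 0.5,
    seed: int = 0,
) -> dict:
    """Sensitivity / false-event rate / clonal-divergence bias of the CP-HMM
    on simulated close pairs with two-mode donor divergence.

    A truth segment counts as recovered when decoded events cover at least
    ``match_overlap`` of its extent; a decoded event not overlapping any
    truth segment at all is a false event.
    """
    rng = np.random.default_rng(seed)
    emissions = _two_mode_emissions(seed + 1)
    n_vis = 0
    n_found = 0
    n_false = 0
    d_hats = []
    for _ in range(n_pairs):
        cfg = PairSimConfig(
            L_sites=L_sites,
            mu_t=d_clonal,
            gamma_t=transfers_per_pair,
            mean_frag_sites=mean_frag_sites,
            donor_div_dist=TWO_MODE_DONOR,
            seed=int(rng.integers(2**31)),
        )
        prof, truth = simulate_pair(cfg)
        dec = fit_decode_pair(prof, emissions)
        d_hats.append(dec.d_clonal_hat)

        truth_iv = [(t.start_site, t.end_site) for t in truth.segments]
        vis = [t for t in truth.segments if t.n_snvs >= min_truth_snvs]
        n_vis += len(vis)
        for t in vis:
            covered = 0
            for e in dec.events:
                covered += max(
                    0, min(e.end_site, t.end_site) - max(e.start_site, t.start_site)
                )
            if covered >= match_overlap * t.length_sites:
                n_found += 1
        for e in dec.events:
            touches = any(
                min(e.end_site, hi) > max(e.start_site, lo) for lo, hi in truth_iv
            )
            if not touches:
                n_false += 1
    d_mean = float(np.mean(d_hats))
    return {
        "sensitivity": n_found / n_vis if n_vis else float("nan"),
        "false_events_per_pair": n_false / n_pairs,
        "d_clonal_bias": (d_mean - d_clonal) / d_clonal,
        "n_visible_truth": n_vis,
        "n_pairs": n_pairs,
    }


# ---------------------------------------------------------------------------
# 2. Clonal-limit gray line
# ---------------------------------------------------------------------------


def clonal_limit_gray_line(
    divergences=(1e-5, 3e-5, 1e-4, 3e-4, 1e-3),
    block_size: int = 1000,
    pairs_per_point: int = 40,
    L_sites: int = 100_000,
    seed: int = 0,
) -> dict:
    """Pure-mutation pairs: fraction of identical blocks vs exp(-B*d).

    Returns the worst-case deviation across the divergence grid in units of
    the aggregated binomial standard error (blocks pooled over pairs).
    """
    rng = np.random.default_rng(seed)
    max_z = 0.0
    rows = []
    for d in divergences:
        obs = []
        for _ in range(pairs_per_point):
            prof, _ = simulate_pair(
                PairSimConfig(L_sites=L_sites, mu_t=d, gamma_t=0,
                              seed=int(rng.integers(2**31)))
            )
            obs.append(fraction_identical_blocks(partition_blocks(prof, block_size)))
        expected = (1 - d) ** block_size
        n_blocks = pairs_per_point * (L_sites // block_size)
        se = np.sqrt(max(expected * (1 - expected), 1e-12) / n_blocks)
        z = abs(float(np.mean(obs)) - expected) / se
        max_z = max(max_z, z)
        rows.append((d, float(np.mean(obs)), expected))
    return {"max_z_score": float(max_z), "grid": rows}


# ---------------------------------------------------------------------------
# 3. Mosaic-model recovery
# ---------------------------------------------------------------------------


def mosaic_recovery(
    n_pairs: int = 200,
    L_sites: int = 400_000,
    mean_frag_sites: float = 3000.0,
    kappa_true: float = 500.0,
    d_bar_r: float = 0.02,
    block_size: int = 1000,
    seed: int = 0,
) -> dict:
    """Recover (kappa, d_bar_r) and the timescale ratio from a simulated
    cohort in which transfers accumulate proportionally to clonal divergence.

    The simulator's clonal fraction decays as c = exp(-R * mu_t * frag / L)
    with R transfers per unit clonal divergence (Poisson coverage), so
    kappa = R * frag / L analytically; the analytic timescale ratio is
    kappa * d_bar_r.  Clonal divergences are sampled so that observed f_id
    is roughly uniform on its measurable range (the decay is expressed while
    every pair keeps at least ~1 identical block); fragments of 3000
    synonymous sites (~20 kb) keep the per-pair Poisson coverage noise
    small.  The fit uses the finite-block and block-edge corrections.
    """
    rng = np.random.default_rng(seed)
    R = kappa_true * L_sites / mean_frag_sites
    # f_id ~ exp(-lam * mu): sample mu so f_id is ~uniform over its range
    lam = kappa_true * (1 + block_size / mean_frag_sites) + block_size
    mu_lo, mu_hi = 5e-5, 5.0 / (kappa_true + block_size)
    rows = []
    for _ in range(n_pairs):
        u = rng.uniform(np.exp(-lam * mu_hi), np.exp(-lam * mu_lo))
        mu_t = -np.log(u) / lam
        cfg = PairSimConfig(
            L_sites=L_sites, mu_t=mu_t, gamma_t=R * mu_t,
            mean_frag_sites=mean_frag_sites,
            donor_div_dist=DonorDivergence.constant(d_bar_r),
            seed=int(rng.integers(2**31)),
        )
        prof, _ = simulate_pair(cfg)
        f_id = fraction_identical_blocks(partition_blocks(prof, block_size))
        rows.append((f_id, prof.divergence()))
    fit = fit_mosaic(rows, block_size=block_size,
                     n_blocks=L_sites // block_size,
                     mean_frag_sites=mean_frag_sites)
    ratio_true = kappa_true * d_bar_r
    ratio_fit = tmrca_over_tmosaic(fit) if fit.identifiable else float("nan")
    return {
        "kappa_rel_error": abs(fit.params.kappa - kappa_true) / kappa_true,
        "d_bar_r_rel_error": abs(fit.params.d_bar_r - d_bar_r) / d_bar_r,
        "ratio_rel_error": abs(ratio_fit - ratio_true) / ratio_true,
        "tmrca_over_tmosaic": ratio_fit,
        "weighted_var_explained": fit.weighted_var_explained,
        "fid_divergence_spearman": mosaic_model.fid_divergence_correlation(rows),
        "identifiable": bool(fit.identifiable),
    }


# ---------------------------------------------------------------------------
# 4. Shared-fragment scaling on Moran ensembles
# ---------------------------------------------------------------------------


def shared_fragment_scaling(
    reps: int = 50,
    N: int = 200,
    n_sample: int = 20,
    L_sites: int = 20_000,
    mu: float = 1e-4,
    mean_frag_sites: float = 300.0,
    seed: int = 0,
) -> dict:
    """Zero-SNV fragment counts vs length threshold at r/mu = 0 and 1.

    Returns the log-log slope of mean count vs ell over ell in
    [2/d_bar, 20/d_bar], measured on the recombining (r/mu = 1) ensemble,
    and the count-reduction factor from r/mu = 0 to 1, alongside the
    closed-form prediction of 4.
    """
    d_bar = mu * N
    ells = np.unique(np.round(np.geomspace(2 / d_bar, 20 / d_bar, 7)).astype(int))

    def ensemble(rho, seed0):
        counts = np.zeros((reps, len(ells)))
        for r in range(reps):
            cfg = PopSimConfig(N=N, n_sample=n_sample, L_sites=L_sites, mu=mu,
                               rho=rho, mean_frag_sites=mean_frag_sites,
                               seed=seed0 + r)
            g, _ = simulate_population(cfg)
            for j, ell in enumerate(ells):
                counts[r, j] = count_shared_fragments(g, int(ell))
        return counts.mean(axis=0)

    base = int(np.random.default_rng(seed).integers(2**30))
    m0 = ensemble(0.0, base)
    m1 = ensemble(mu, base + reps)  # r/mu = 1
    ok = (m0 > 0) & (m1 > 0)
    slope = float(np.polyfit(np.log(ells[ok]), np.log(m1[ok]), 1)[0])
    ratio = float(np.mean(m0[ok] / m1[ok]))
    return {
        "loglog_slope": slope,
        "count_ratio_rmu0_over_rmu1": ratio,
        "count_ratio_predicted": 4.0,
        "ells": ells.tolist(),
        "mean_counts_rmu0": m0.tolist(),
        "mean_counts_rmu1": m1.tolist(),
    }


# ---------------------------------------------------------------------------
# 5. Longest-run K-S test: calibration and power
# ---------------------------------------------------------------------------


def _longest_runs_poisson(rng, n, L_sites, d):
    out = np.empty(n)
    for i in range(n):
        diff = (rng.random(L_sites) < d).astype(np.uint8)
        out[i] = identical_runs(profile_from_diff(diff)).longest_run
    return out


def longest_run_test_calibration(
    reps: int = 200,
    n_hosts: int = 30,
    L_sites: int = 300_000,
    d_bar: float = 0.01,
    transfer_sites: int = 4500,  # ~30 kb at typical synonymous-site density
    affected_fraction: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error and power of the one-sided within/between K-S test.

    Null replicates draw both longest-run samples from the same
    Poisson-profile generator; power replicates give ``affected_fraction``
    of within-host pairs a recent transfer, i.e. an extra zero-SNV tract of
    ``transfer_sites`` sites.
    """
    rng = np.random.default_rng(seed)
    null_rej = 0
    for _ in range(reps):
        within = _longest_runs_poisson(rng, n_hosts, L_sites, d_bar)
        between = _longest_runs_poisson(rng, n_hosts, L_sites, d_bar)
        p, _ = compare_within_between_runs(within, between)
        null_rej += p < alpha
    power_rej = 0
    for _ in range(reps):
        within = _longest_runs_poisson(rng, n_hosts, L_sites, d_bar)
        n_aff = max(1, int(round(affected_fraction * n_hosts)))
        idx = rng.choice(n_hosts, n_aff, replace=False)
        within[idx] = np.maximum(within[idx], transfer_sites)
        between = _longest_runs_poisson(rng, n_hosts, L_sites, d_bar)
        p, _ = compare_within_between_runs(within, between)
        power_rej += p < alpha
    return {
        "type_i_error": null_rej / reps,
        "power": power_rej / reps,
        "nominal_alpha": alpha,
        "n_hosts": n_hosts,
    }


# ---------------------------------------------------------------------------
# 6. Sharing-landscape selection signal
# ---------------------------------------------------------------------------


def _poisson_background(rng, n, L, d_bar):
    """Independent strains at pairwise divergence d_bar around one ancestor."""
    anc = rng.integers(0, 4, L).astype(np.int8)
    haps = np.empty((n, L), dtype=np.int8)
    for i in range(n):
        h = anc.copy()
        m = rng.random(L) < d_bar / 2
        h[m] = (h[m] + 1 + rng.integers(0, 3, int(m.sum()))) % 4
        haps[i] = h
    return haps


def _background_genomes(rng, n, L, d_bar, species="background"):
    import pandas as pd

    from .core_data import CoreGenomeSet

    haps = _poisson_background(rng, n, L, d_bar)
    sites = pd.DataFrame(
        {
            "contig": np.repeat("sim", L),
            "pos_bp": np.arange(1, L + 1, dtype=np.int64),
            "is_synonymous": np.ones(L, dtype=bool),
            "gene_id": [None] * L,
        }
    )
    meta = pd.DataFrame(
        {
            "strain_id": [f"s{i:03d}" for i in range(n)],
            "host_id": [f"h{i:03d}" for i in range(n)],
            "clade_id": [None] * n,
        }
    )
    return CoreGenomeSet(species_name=species, sites=sites, haplotypes=haps,
                         strain_meta=meta)


def sweep_landscape_signal(
    n_strains: int = 20,
    L_sites: int = 20_000,
    d_bar: float = 0.02,
    carrier_fraction: float = 0.5,
    n_neutral_reps: int = 100,
    neutral_N: int = 100,
    perm_reps: int = 3000,
    seed: int = 0,
) -> dict:
    """Three selection-scan checks built on injected hard sweeps.

    (a) locus sharing at a swept region equals the carrier-pair fraction
        C(k,2)/C(n,2) (= 45/190 ~ 0.237 at carrier fraction 0.5, n=20); the
        background is typically diverged, so non-carrier pairs contribute ~0;
    (b) a sweep injected into neutral Moran populations lifts the landscape
        CV above the neutral null band (mean + 3 SD of CVs over neutral
        Moran replicates at matched d_bar; the swept CV is the median over a
        handful of injections to damp single-genealogy fluctuations);
    (c) two landscapes whose sweeps sit at deliberately disjoint, irregular
        loci give a rotation-permutation discordance p < 0.01 (run at a
        higher background divergence so that many narrow sweep windows fit
        in the genome and nearly every rotation aligns some pair of them).
    """
    rng = np.random.default_rng(seed)
    window = int(np.ceil(15 / d_bar))

    # --- (a) exact carrier-pair counting on a clean background
    g = _background_genomes(rng, n_strains, L_sites, d_bar)
    lo = L_sites // 3
    region = (lo, lo + window + 200)
    swept = inject_sweep(g, region, mode="hard",
                         carrier_fraction=carrier_fraction,
                         seed=int(rng.integers(2**31)))
    ls_swept = sharing_landscape(swept, window_syn_sites=window)
    mid = int(np.searchsorted(ls_swept.site_index, lo + (window + 200) // 2))
    locus_share = float(ls_swept.p_share[mid])
    k = int(round(carrier_fraction * n_strains))
    expected_share = (k * (k - 1) / 2) / (n_strains * (n_strains - 1) / 2)

    # --- (b) CV of sweep-injected Moran landscapes vs the neutral null band
    # the neutral populations recombine at r/mu = 2, which keeps their
    # landscapes smooth so the band reflects neutral genealogy fluctuation;
    # the injected sweep spans twice the window so its full-identity core is
    # window+1 positions wide
    mu = d_bar / neutral_N
    sweep_region = (L_sites // 3, L_sites // 3 + 2 * window)
    neutral_pops = []
    neutral_cvs = []
    for r in range(n_neutral_reps):
        cfg = PopSimConfig(N=neutral_N, n_sample=n_strains, L_sites=L_sites,
                           mu=mu, rho=2.0 * mu, mean_frag_sites=300,
                           seed=int(rng.integers(2**31)))
        gsim, _ = simulate_population(cfg)
        if len(neutral_pops) < 5:
            neutral_pops.append(gsim)
        ls = sharing_landscape(gsim, window_syn_sites=window)
        neutral_cvs.append(landscape_cv(ls) if ls.p_share.mean() > 0 else 0.0)
    neutral_cvs = np.asarray(neutral_cvs)
    cv_band_hi = float(neutral_cvs.mean() + 3 * neutral_cvs.std())
    swept_cvs = []
    for gsim in neutral_pops:
        gsw = inject_sweep(gsim, sweep_region, mode="hard",
                           carrier_fraction=carrier_fraction,
                           seed=int(rng.integers(2**31)))
        ls = sharing_landscape(gsw, window_syn_sites=window)
        swept_cvs.append(landscape_cv(ls))
    cv_swept = float(np.median(swept_cvs))

    # --- (c) shifted-hotspot discordance
    # many narrow sweeps at irregular, mutually disjoint loci: nearly every
    # rotation of one landscape aligns some pair of hotspots, so the
    # engineered zero-overlap arrangement sits in the far low tail of the
    # rotation null (measured z ~ -3 for 30 spots of 300 sites on 48k)
    d_bar_c = 0.1
    window_c = int(np.ceil(15 / d_bar_c))  # 150 sites
    m_spots = 30
    width = 2 * window_c
    L_c = 48_000
    a_spots = []
    b_spots = []
    for spots in (a_spots, b_spots):
        guard = 0
        while len(spots) < m_spots:
            guard += 1
            if guard > 500_000:
                raise RuntimeError("could not place disjoint hotspots")
            c = int(rng.integers(0, L_c - width))
            if all(abs(c - s) >= width for s in a_spots) and all(
                    abs(c - s) >= width for s in b_spots):
                spots.append(c)
    g_a = _background_genomes(rng, n_strains, L_c, d_bar_c, species="cohort_a")
    g_b = _background_genomes(rng, n_strains, L_c, d_bar_c, species="cohort_b")
    for s in a_spots:
        g_a = inject_sweep(g_a, (int(s), int(s) + width), mode="hard",
                           carrier_fraction=carrier_fraction,
                           seed=int(rng.integers(2**31)))
    for s in b_spots:
        g_b = inject_sweep(g_b, (int(s), int(s) + width), mode="hard",
                           carrier_fraction=carrier_fraction,
                           seed=int(rng.integers(2**31)))
    ls_a = sharing_landscape(g_a, window_syn_sites=window_c)
    ls_b = sharing_landscape(g_b, window_syn_sites=window_c)
    perm = hotspot_permutation_test(ls_a, ls_b, reps=perm_reps,
                                    seed=int(rng.integers(2**31)),
                                    alternative="discordant")
    return {
        "locus_share": locus_share,
        "locus_share_expected": expected_share,
        "cv_swept": float(cv_swept),
        "cv_neutral_mean": float(neutral_cvs.mean()),
        "cv_neutral_sd": float(neutral_cvs.std()),
        "cv_band_hi": cv_band_hi,
        "discordance_p": perm["p_value"],
    }


# ---------------------------------------------------------------------------
# 7. Recombination-hotspot direction
# ---------------------------------------------------------------------------


def hotspot_sharing_direction(
    reps: int = 40,
    N: int = 100,
    n_sample: int = 20,
    L_sites: int = 20_000,
    mu: float = 2e-4,
    rho_over_mu: float = 0.5,
    hotspot_multiplier: float = 10.0,
    mean_frag_sites: float = 300.0,
    seed: int = 0,
) -> dict:
    """Does a 10x local conversion rate depress long-window sharing?

    Each replicate runs the Moran model with a conversion hotspot over the
    middle quarter of the genome and compares the mean sharing probability
    inside the hotspot (margins excluded) to the background.  Returns the
    fraction of replicates in which the hotspot shares LESS.
    """
    rng = np.random.default_rng(seed)
    d_bar = mu * N
    window = int(np.ceil(15 / d_bar))
    hot_lo, hot_hi = int(0.375 * L_sites), int(0.625 * L_sites)
    lower = 0
    used = 0
    for _ in range(reps):
        cfg = PopSimConfig(
            N=N, n_sample=n_sample, L_sites=L_sites, mu=mu, rho=rho_over_mu * mu,
            mean_frag_sites=mean_frag_sites,
            hotspot=((hot_lo, hot_hi), hotspot_multiplier),
            seed=int(rng.integers(2**31)),
        )
        g, _ = simulate_population(cfg)
        ls = sharing_landscape(g, window_syn_sites=window)
        pos = ls.site_index
        margin = window
        inside = (pos >= hot_lo + margin) & (pos < hot_hi - margin)
        outside = (pos < hot_lo - margin) | (pos >= hot_hi + margin)
        p_in, p_out = ls.p_share[inside].mean(), ls.p_share[outside].mean()
        if p_in + p_out == 0:
            continue  # no sharing anywhere: uninformative genealogy
        used += 1
        lower += p_in < p_out
    return {
        "fraction_hotspot_lower": lower / used if used else float("nan"),
        "n_informative_reps": used,
        "n_reps": reps,
    }


# ---------------------------------------------------------------------------
# 8. Donor-divergence one-sided K-S
# ---------------------------------------------------------------------------


def donor_divergence_ks_experiment(
    n_per_clade: int = 10,
    L_sites: int = 30_000,
    within_div: float = 0.01,
    between_div: float = 0.10,
    n_events: int = 60,
    event_sites: int = 2000,
    seed: int = 0,
) -> dict:
    """Planted suppression of between-clade transfers vs a matched null.

    Builds a two-clade population, plants transfer events whose divergences
    are all within-clade (the suppressed scenario) or drawn from the same
    random-segment generator as the null (the matched scenario), and runs
    the one-sided K-S comparison against random segments.
    """
    rng = np.random.default_rng(seed)
    L = L_sites
    anc1 = rng.integers(0, 4, L).astype(np.int8)
    anc2 = anc1.copy()
    flip = rng.random(L) < between_div
    anc2[flip] = (anc2[flip] + 1 + rng.integers(0, 3, int(flip.sum()))) % 4
    haps = []
    for anc in (anc1, anc2):
        for _ in range(n_per_clade):
            h = anc.copy()
            m = rng.random(L) < within_div / 2
            h[m] = (h[m] + 1 + rng.integers(0, 3, int(m.sum()))) % 4
            haps.append(h)
    import pandas as pd

    from .core_data import CoreGenomeSet

    n = 2 * n_per_clade
    genomes = CoreGenomeSet(
        species_name="two_clade_sim",
        sites=pd.DataFrame(
            {
                "contig": np.repeat("sim", L),
                "pos_bp": np.arange(1, L + 1, dtype=np.int64),
                "is_synonymous": np.ones(L, dtype=bool),
                "gene_id": [None] * L,
            }
        ),
        haplotypes=np.vstack(haps),
        strain_meta=pd.DataFrame(
            {
                "strain_id": [f"s{i:03d}" for i in range(n)],
                "host_id": [f"h{i:03d}" for i in range(n)],
                "clade_id": ["c1"] * n_per_clade + ["c2"] * n_per_clade,
            }
        ),
    )
    ids = genomes.strain_ids

    def mk_event(local_div):
        start = int(rng.integers(1, L - event_sites))
        return TransferEvent(
            pair=(ids[0], ids[1]), start_site=start, end_site=start + event_sites,
            start_bp=start + 1, end_bp=start + event_sites,
            length_sites=event_sites, length_bp=event_sites, n_snvs=10,
            local_div=float(local_div),
        )

    suppressed = [
        mk_event(within_div * np.exp(rng.normal(0, 0.1))) for _ in range(n_events)
    ]
    dd_sup = donor_divergence_null(genomes, suppressed, n_draws_per_event=10,
                                   seed=int(rng.integers(2**31)))

    haps_arr = genomes.haplotypes
    matched = []
    for _ in range(n_events):
        i, j = rng.choice(n, 2, replace=False)
        start = int(rng.integers(0, L - event_sites))
        div = float(np.mean(haps_arr[i, start:start + event_sites]
                            != haps_arr[j, start:start + event_sites]))
        e = mk_event(max(div, 1e-6))
        e.pair = (ids[i], ids[j])
        matched.append(e)
    dd_match = donor_divergence_null(genomes, matched, n_draws_per_event=10,
                                     seed=int(rng.integers(2**31)))
    return {
        "suppressed_p": dd_sup.p_value,
        "suppressed_ks_distance": dd_sup.ks_distance,
        "matched_p": dd_match.p_value,
        "matched_ks_distance": dd_match.ks_distance,
    }
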