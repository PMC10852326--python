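"""Run statistics, sharing landscape, CV, scaling law, permutation test."""

import numpy as np
import pytest
from scipy import stats

from corerecomb.core_data import profile_from_diff
from corerecomb.neutral_sim import PopSimConfig, inject_sweep, simulate_population
from corerecomb.sharing import (
    SHARED_FRAGMENT_CALIBRATION,
    compare_within_between_runs,
    expected_shared_fragments,
    hotspot_permutation_test,
    identical_runs,
    landscape_cv,
    runs_null_random_scatter,
    sharing_landscape,
)

from conftest import make_genomes


# ---------------------------------------------------------------------------
# Runs
# ---------------------------------------------------------------------------


def test_identical_runs_limits():
    rs = identical_runs(profile_from_diff(np.zeros(1000, dtype=np.uint8)))
    assert rs.longest_run == 1000
    assert len(rs.run_lengths_sites) == 1
    rs = identical_runs(profile_from_diff(np.ones(100, dtype=np.uint8)))
    assert rs.longest_run == 0


def test_identical_runs_bookkeeping_identity():
    """sum(runs) + #SNVs == #compared sites, for random profiles."""
    rng = np.random.default_rng(0)
    for d in (0.001, 0.01, 0.3):
        diff = (rng.random(20_000) < d).astype(np.uint8)
        rs = identical_runs(profile_from_diff(diff))
        assert rs.run_lengths_sites.sum() + diff.sum() == 20_000
        assert len(rs.run_lengths_sites) == diff.sum() + 1


def test_identical_runs_longest_gap_order_statistics(rng):
    """Poisson-scattered SNVs: E[longest gap] ~ ln(n)/d (order statistics),
    checked against a Monte-Carlo scatter."""
    d, L = 0.005, 100_000
    longest = []
    for _ in range(40):
        diff = (rng.random(L) < d).astype(np.uint8)
        longest.append(identical_runs(profile_from_diff(diff)).longest_run)
    n = d * L
    expected = np.log(n) / d
    assert np.mean(longest) == pytest.approx(expected, rel=0.25)


def test_runs_null_scatter_limits_and_planted_tract():
    null, _ = runs_null_random_scatter(0, 1000, reps=50, seed=0)
    assert (null == 1000).all()
    null, _ = runs_null_random_scatter(1000, 1000, reps=50, seed=0)
    assert (null == 0).all()
    # planted 30k-site identical tract on a 1% background
    rng = np.random.default_rng(1)
    L = 300_000
    diff = (rng.random(L) < 0.01).astype(np.uint8)
    diff[100_000:130_000] = 0
    obs = identical_runs(profile_from_diff(diff)).longest_run
    null, p_fn = runs_null_random_scatter(int(diff.sum()), L, reps=999, seed=2)
    assert p_fn(obs) <= 1e-3  # add-one estimate floor at 1/(reps+1)


def test_compare_runs_orientation():
    """One-sided: significant only when within-host runs are LONGER."""
    rng = np.random.default_rng(3)
    short = rng.integers(100, 500, 30)
    long_ = rng.integers(2000, 5000, 30)
    p_enriched, _ = compare_within_between_runs(long_, short)
    p_reversed, _ = compare_within_between_runs(short, long_)
    assert p_enriched < 0.001
    assert p_reversed > 0.5
    with pytest.raises(ValueError, match="at least"):
        compare_within_between_runs([1, 2], [1, 2, 3, 4, 5])


def test_compare_runs_same_generator_not_significant():
    rng = np.random.default_rng(4)
    ps = []
    for _ in range(20):
        a = rng.exponential(1000, 30)
        b = rng.exponential(1000, 30)
        p, _ = compare_within_between_runs(a, b)
        ps.append(p)
    # p-values roughly uniform: mean near 0.5, few small
    assert 0.3 < np.mean(ps) < 0.8
    assert np.mean(np.array(ps) < 0.05) <= 0.15


# ---------------------------------------------------------------------------
# Sharing landscape
# ---------------------------------------------------------------------------


def test_landscape_identical_strains_all_one():
    g = make_genomes(np.zeros((12, 5000), dtype=np.int8))
    ls = sharing_landscape(g, window_syn_sites=500)
    assert (ls.p_share == 1.0).all()


def test_landscape_independent_poisson_profiles_near_zero(rng):
    """Unrelated strains at divergence d with window 15/d: per-pair window
    identity probability ~ e^-15, so the landscape is essentially zero."""
    d = 0.02
    n, L = 12, 20_000
    anc = rng.integers(0, 4, L).astype(np.int8)
    haps = []
    for _ in range(n):
        h = anc.copy()
        m = rng.random(L) < d / 2
        h[m] = (h[m] + 1 + rng.integers(0, 3, int(m.sum()))) % 4
        haps.append(h)
    g = make_genomes(np.vstack(haps))
    ls = sharing_landscape(g)  # auto window = 15 / d_bar
    assert ls.p_share.max() <= 1.0 / ls.n_pairs + 1e-12  # at most a stray pair
    assert ls.p_share.mean() < 1e-3


def test_landscape_sweep_carrier_pair_counting():
    """Hard sweep at carrier fraction 0.5 in n=20: locus sharing equals the
    carrier-pair fraction C(10,2)/C(20,2) = 45/190 ~= 0.237 exactly, because
    non-carrier pairs are typically diverged."""
    rng = np.random.default_rng(8)
    n, L, d = 20, 20_000, 0.02
    anc = rng.integers(0, 4, L).astype(np.int8)
    haps = []
    for _ in range(n):
        h = anc.copy()
        m = rng.random(L) < d / 2
        h[m] = (h[m] + 1 + rng.integers(0, 3, int(m.sum()))) % 4
        haps.append(h)
    g = make_genomes(np.vstack(haps))
    w = 750  # = 15 / d
    region = (8000, 8000 + w + 200)
    swept = inject_sweep(g, region, mode="hard", carrier_fraction=0.5, seed=9)
    ls = sharing_landscape(swept, window_syn_sites=w)
    mid = np.searchsorted(ls.site_index, 8000 + (w + 200) // 2)
    assert ls.p_share[mid] == pytest.approx(45 / 190, abs=0.02)


def test_landscape_mean_equals_mean_per_pair_share():
    """Exchange of summation order: position-mean of p_i equals the mean
    per-pair window-identity probability."""
    cfg = PopSimConfig(N=60, n_sample=12, L_sites=10_000, mu=2e-4, rho=1e-4,
                       mean_frag_sites=200, seed=11)
    g, _ = simulate_population(cfg)
    ls = sharing_landscape(g, window_syn_sites=400)
    assert ls.p_share.mean() == pytest.approx(ls.per_pair_share.mean(), abs=1e-12)


def test_landscape_window_validation():
    g = make_genomes(np.zeros((12, 1000), dtype=np.int8))
    with pytest.raises(ValueError, match="window"):
        sharing_landscape(g, window_syn_sites=5000)
    with pytest.raises(ValueError, match="eligible pairs"):
        sharing_landscape(make_genomes(np.zeros((3, 1000), dtype=np.int8)),
                          window_syn_sites=100)


def test_landscape_cv_arithmetic():
    from corerecomb.sharing import SharingLandscape

    def mk(p):
        return SharingLandscape(site_index=np.arange(len(p)),
                                pos_bp=np.arange(len(p)) + 1, p_share=np.asarray(p),
                                window_syn_sites=10, pairing="between_host",
                                n_pairs=10)

    assert landscape_cv(mk(np.full(200, 0.3))) == pytest.approx(0.0, abs=1e-12)
    # {0.01 on 99%, 0.5 on 1%}: CV ~= 3.27 by direct arithmetic
    p = np.concatenate([np.full(990, 0.01), np.full(10, 0.5)])
    expected = p.std() / p.mean()
    assert landscape_cv(mk(p)) == pytest.approx(expected)
    assert expected == pytest.approx(3.27, abs=0.05)
    with pytest.raises(ValueError, match="undefined|zero"):
        landscape_cv(mk(np.zeros(200)))


# ---------------------------------------------------------------------------
# Shared-fragment formula
# ---------------------------------------------------------------------------


def test_expected_shared_fragments_scalings():
    base = expected_shared_fragments(1e6, 0.01, 0.0, 1000)
    assert expected_shared_fragments(1e6, 0.01, 0.0, 2000) == pytest.approx(base / 4)
    assert expected_shared_fragments(1e6, 0.01, 1.0, 1000) == pytest.approx(base / 4)
    assert expected_shared_fragments(2e6, 0.01, 0.0, 1000) == pytest.approx(2 * base)
    assert expected_shared_fragments(1e6, 0.02, 0.0, 1000) == pytest.approx(base / 2)
    with pytest.raises(ValueError):
        expected_shared_fragments(1e6, 0.0, 0.0, 1000)


# ---------------------------------------------------------------------------
# Hotspot permutation test
# ---------------------------------------------------------------------------


def _noisy_landscape(rng, L=20_000, hotspots=(), base=0.01, amp=0.3, width=400):
    p = rng.uniform(0, base, L)
    for h in hotspots:
        p[h:h + width] += amp
    return p


def test_hotspot_permutation_identity_concordant():
    rng = np.random.default_rng(5)
    a = _noisy_landscape(rng, hotspots=(2000, 9000, 15_000))
    res_c = hotspot_permutation_test(a, a.copy(), reps=1000, seed=1,
                                     alternative="concordant")
    res_d = hotspot_permutation_test(a, a.copy(), reps=1000, seed=1,
                                     alternative="discordant")
    assert res_c["p_value"] <= 2 / 1000
    assert res_d["p_value"] > 0.9


def test_hotspot_permutation_independent_uniform(rng):
    """Independent landscapes: discordance p roughly uniform over replicates."""
    ps = []
    for _ in range(20):
        a = _noisy_landscape(rng, hotspots=(int(rng.integers(0, 19_000)),))
        b = _noisy_landscape(rng, hotspots=(int(rng.integers(0, 19_000)),))
        ps.append(hotspot_permutation_test(a, b, reps=1000, seed=3)["p_value"])
    assert 0.2 < np.mean(ps) < 0.8


def test_hotspot_permutation_shifted_hotspots_discordant():
    """Many hotspots deliberately placed at disjoint loci: nearly every
    rotation aligns some hotspots by chance, so the observed (zero-overlap)
    concordance sits in the extreme low tail."""
    rng = np.random.default_rng(6)
    L, width, m = 30_000, 400, 15
    # irregular placements: a rigid rotation then decorrelates the overlap
    # events of different hotspot pairs (a periodic lattice would not)
    a_spots = tuple(sorted(rng.choice(L - width, m, replace=False)))
    b_spots = []
    while len(b_spots) < m:
        c = int(rng.integers(0, L - width))
        if all(abs(c - s) >= width for s in a_spots) and all(
                abs(c - s) >= width for s in b_spots):
            b_spots.append(c)
    a = _noisy_landscape(rng, L=L, hotspots=a_spots, width=width)
    b = _noisy_landscape(rng, L=L, hotspots=tuple(b_spots), width=width)
    res = hotspot_permutation_test(a, b, reps=2000, seed=7,
                                   alternative="discordant")
    assert res["p_value"] < 0.01


def test_hotspot_permutation_validation():
    with pytest.raises(ValueError, match="equal length"):
        hotspot_permutation_test(np.zeros(100), np.zeros(101), reps=1000, seed=0)
    with pytest.raises(ValueError, match="reps"):
        hotspot_permutation_test(np.zeros(100), np.zeros(100), reps=10, seed=0)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=50, derandomize=True, deadline=None)
@given(diff=st.lists(st.integers(0, 1), min_size=1, max_size=500))
def test_runs_partition_any_profile(diff):
    """Runs + SNVs partition the compared sites for arbitrary profiles, and
    the longest run never exceeds the profile."""
    arr = np.asarray(diff, dtype=np.uint8)
    rs = identical_runs(profile_from_diff(arr))
    assert rs.run_lengths_sites.sum() + arr.sum() == len(arr)
    assert 0 <= rs.longest_run <= len(arr)
    assert len(rs.run_lengths_sites) == arr.sum() + 1
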