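"""CP-HMM: emission estimation, EM/Viterbi decoding, clade labels, filters."""

import numpy as np
import pytest

from corerecomb import cphmm
from corerecomb.core_data import profile_from_diff
from corerecomb.cphmm import (
    EmpiricalDivDist,
    NotAClosePairError,
    TransferEvent,
    classify_transfer_clade,
    estimate_empirical_divergence,
    fit_decode_pair,
    flag_duplicate_transfers,
    select_close_pairs,
)
from corerecomb.neutral_sim import DonorDivergence, PairSimConfig, simulate_pair


@pytest.fixture(scope="module")
def mixture_emissions():
    """Two-mode emission model (1% and 10%) with log-normal local scatter."""
    rng = np.random.default_rng(2)
    samples = rng.choice([0.01, 0.10], 3000, p=[0.7, 0.3]) * np.exp(
        rng.normal(0, 0.2, 3000)
    )
    return EmpiricalDivDist.from_samples(samples)


# ---------------------------------------------------------------------------
# EmpiricalDivDist
# ---------------------------------------------------------------------------


def test_empirical_dist_normalization_and_centers(mixture_emissions):
    em = mixture_emissions
    assert em.bin_probs.sum() == pytest.approx(1.0)
    assert (np.diff(em.bin_edges) > 0).all()
    assert 0 < em.bin_edges[0] and em.bin_edges[-1] <= 0.5
    # mass concentrates around the two modes
    assert 0.005 < em.mean() < 0.06


def test_empirical_dist_validation():
    with pytest.raises(ValueError):
        EmpiricalDivDist(bin_edges=np.array([0.01, 0.1]), bin_probs=np.array([0.5]))
    with pytest.raises(ValueError):
        EmpiricalDivDist(bin_edges=np.array([0.1, 0.01, 0.2]),
                         bin_probs=np.array([0.5, 0.5]))


def test_estimate_empirical_divergence_unimodal(two_clade_genomes):
    """Within-clade pairing: distribution concentrated near 1%."""
    em = estimate_empirical_divergence(two_clade_genomes, clade_pairing="within",
                                       window_bp=1000)
    assert 0.005 < em.mean() < 0.02


def test_estimate_empirical_divergence_between_clades(two_clade_genomes):
    em = estimate_empirical_divergence(two_clade_genomes, clade_pairing="between",
                                       window_bp=1000)
    assert 0.07 < em.mean() < 0.15


def test_estimate_empirical_divergence_pooled_bimodal(two_clade_genomes):
    em = estimate_empirical_divergence(two_clade_genomes, clade_pairing="pooled",
                                       window_bp=1000)
    # both modes represented: probability mass below 3% and above 5%
    lo = em.bin_probs[em.centers < 0.03].sum()
    hi = em.bin_probs[em.centers > 0.05].sum()
    assert lo > 0.2 and hi > 0.2


def test_estimate_empirical_divergence_too_few_pairs():
    from conftest import make_genomes

    rng = np.random.default_rng(0)
    g = make_genomes(rng.integers(0, 4, (3, 5000)))
    with pytest.raises(ValueError, match="parametric"):
        estimate_empirical_divergence(g, min_pairs=10)


# ---------------------------------------------------------------------------
# fit_decode_pair
# ---------------------------------------------------------------------------


def test_decode_zero_snv_profile(mixture_emissions):
    prof = profile_from_diff(np.zeros(50_000, dtype=np.uint8))
    dec = fit_decode_pair(prof, mixture_emissions)
    assert dec.n_events == 0
    assert dec.clonal_fraction == 1.0
    assert dec.d_clonal_hat == 0.0


def test_decode_single_transfer_reciprocal_overlap(mixture_emissions):
    """One 20 kb-site transfer at 1% on a 5e-5 backbone: exactly one event,
    >= 90% reciprocal overlap with truth."""
    cfg = PairSimConfig(L_sites=1_000_000, mu_t=5e-5, gamma_t=1,
                        mean_frag_sites=1, constant_frag=False, seed=123)
    # plant the transfer deterministically instead: backbone + explicit block
    rng = np.random.default_rng(123)
    diff = (rng.random(1_000_000) < 5e-5).astype(np.uint8)
    lo, hi = 300_000, 320_000
    diff[lo:hi] = rng.random(hi - lo) < 0.01
    prof = profile_from_diff(diff)
    dec = fit_decode_pair(prof, mixture_emissions)
    assert dec.n_events == 1
    ev = dec.events[0]
    inter = min(ev.end_site, hi) - max(ev.start_site, lo)
    assert inter / (hi - lo) >= 0.9
    assert inter / ev.length_sites >= 0.9
    assert ev.local_div == pytest.approx(0.01, rel=0.3)
    assert dec.d_clonal_hat == pytest.approx(5e-5, rel=0.4)


def test_decode_reversal_invariance(mixture_emissions):
    """Decoding is invariant to flipping the genome coordinate."""
    rng = np.random.default_rng(7)
    diff = (rng.random(200_000) < 5e-5).astype(np.uint8)
    diff[50_000:60_000] = rng.random(10_000) < 0.01
    dec_f = fit_decode_pair(profile_from_diff(diff), mixture_emissions)
    dec_r = fit_decode_pair(profile_from_diff(diff[::-1].copy()), mixture_emissions)
    assert dec_f.n_events == dec_r.n_events
    L = len(diff)
    for ef, er in zip(dec_f.events, reversed(dec_r.events)):
        assert ef.start_site == L - er.end_site
        assert ef.end_site == L - er.start_site


def test_decode_bookkeeping_identity(mixture_emissions):
    """Total recombined length equals (1 - f_c) * compared sites."""
    prof, _ = simulate_pair(
        PairSimConfig(L_sites=300_000, mu_t=5e-5, gamma_t=5, mean_frag_sites=10_000,
                      donor_div_dist=DonorDivergence.constant(0.02), seed=3)
    )
    dec = fit_decode_pair(prof, mixture_emissions)
    rec = sum(e.length_sites for e in dec.events)
    assert rec == pytest.approx((1 - dec.clonal_fraction) * dec.n_sites, abs=1e-6)
    # events sorted, non-overlapping
    for a, b in zip(dec.events, dec.events[1:]):
        assert a.end_site <= b.start_site


def test_decode_replicates_recover_events_and_dclonal(mixture_emissions):
    """Replicate oracle at unit-test scale: mean detected events close to
    mean visible truth events; clonal divergence nearly unbiased."""
    n_det, n_truth, d_hats = [], [], []
    for s in range(15):
        prof, truth = simulate_pair(
            PairSimConfig(L_sites=200_000, mu_t=5e-5, gamma_t=4,
                          mean_frag_sites=5000,
                          donor_div_dist=DonorDivergence(values=(0.01, 0.10),
                                                         weights=(0.7, 0.3)),
                          seed=50 + s)
        )
        dec = fit_decode_pair(prof, mixture_emissions)
        visible = [t for t in truth.segments if t.n_snvs >= 2]
        n_det.append(dec.n_events)
        n_truth.append(len(visible))
        d_hats.append(dec.d_clonal_hat)
    assert np.mean(n_det) == pytest.approx(np.mean(n_truth), rel=0.2)
    assert np.mean(d_hats) == pytest.approx(5e-5, rel=0.15)


def test_decode_rejects_typically_diverged_pair(mixture_emissions):
    rng = np.random.default_rng(1)
    diff = (rng.random(100_000) < 0.02).astype(np.uint8)
    with pytest.raises(NotAClosePairError, match="close-pair"):
        fit_decode_pair(profile_from_diff(diff), mixture_emissions)


def test_decode_loglik_reported_and_em_converges(mixture_emissions):
    prof, _ = simulate_pair(
        PairSimConfig(L_sites=100_000, mu_t=5e-5, gamma_t=2, mean_frag_sites=5000,
                      seed=8)
    )
    dec = fit_decode_pair(prof, mixture_emissions, max_iters=50)
    assert np.isfinite(dec.loglik)
    assert dec.converged
    assert 0 <= dec.posterior_recombined_mean <= 1


# ---------------------------------------------------------------------------
# Clade classification, close-pair selection, duplicates
# ---------------------------------------------------------------------------


def _event(pair=("a", "b"), start=1000, end=5000, div=0.01, n_snvs=40):
    return TransferEvent(
        pair=pair, start_site=start, end_site=end, start_bp=start, end_bp=end,
        length_sites=end - start, length_bp=end - start + 1, n_snvs=n_snvs,
        local_div=div,
    )


def test_classify_transfer_clade_midpoint_rule():
    # geometric midpoint of (0.01, 0.10) is ~0.0316
    assert classify_transfer_clade(_event(div=0.009), 0.01, 0.10) == "within"
    assert classify_transfer_clade(_event(div=0.09), 0.01, 0.10) == "between"
    assert classify_transfer_clade(_event(div=0.02), None, None) == "NA"
    with pytest.raises(ValueError):
        classify_transfer_clade(_event(), 0.10, 0.01)


def test_select_close_pairs_thresholds(mixture_emissions):
    from corerecomb.cphmm import PairDecoding

    def dec(d, fc):
        return PairDecoding(pair=("a", "b"), d_clonal_hat=d, clonal_fraction=fc,
                            events=[], loglik=0.0, n_em_iters=1, converged=True,
                            n_sites=1000)

    kept, excl = select_close_pairs(
        [dec(5e-5, 0.9), dec(2e-4, 0.9), dec(5e-5, 0.05)],
        d_star=1e-4, fc_star=0.2,
    )
    assert len(kept) == 1 and kept[0].d_clonal_hat == 5e-5
    assert len(excl) == 2


def test_flag_duplicates_shared_strain_only():
    """Identical coordinates flag a duplicate only when pairs share a strain,
    and duplicate clusters chain through shared strains."""
    e1 = _event(pair=("A", "B"))
    e2 = _event(pair=("A", "C"))
    e3 = _event(pair=("E", "F"))
    flagged = flag_duplicate_transfers({("A", "B"): [e1], ("A", "C"): [e2],
                                        ("E", "F"): [e3]})
    assert sum(e.is_duplicate for e in flagged) == 1  # one of e1/e2
    assert not e3.is_duplicate
    # chained cluster: (A,B)-(A,C)-(C,D) all collapse to one kept event
    e4, e5, e6 = (_event(pair=("A", "B")), _event(pair=("A", "C")),
                  _event(pair=("C", "D")))
    flagged = flag_duplicate_transfers({("A", "B"): [e4], ("A", "C"): [e5],
                                        ("C", "D"): [e6]})
    assert sum(e.is_duplicate for e in flagged) == 2


def test_flag_duplicates_overlap_threshold():
    e1 = _event(pair=("A", "B"), start=0, end=1000)
    e2 = _event(pair=("A", "C"), start=400, end=1400)  # 60% overlap
    flagged = flag_duplicate_transfers({("A", "B"): [e1], ("A", "C"): [e2]},
                                       overlap_frac=0.8)
    assert sum(e.is_duplicate for e in flagged) == 0


def test_flag_duplicates_divergence_tolerance():
    e1 = _event(pair=("A", "B"), div=0.01)
    e2 = _event(pair=("A", "C"), div=0.10)  # same coords, very different div
    flagged = flag_duplicate_transfers({("A", "B"): [e1], ("A", "C"): [e2]},
                                       div_tol=0.3)
    assert sum(e.is_duplicate for e in flagged) == 0
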