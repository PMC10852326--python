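"""Close-pair hidden Markov model (CP-HMM) for recombination detection.

For a closely related strain pair, genetic differences along the core genome
come from two processes: point mutations on the clonal frame (sparse,
uniform) and homologous recombination events that import fragments carrying
the donor lineage's divergence (dense, localized).  The CP-HMM segments the
per-synonymous-site mismatch profile into a clonal state (Bernoulli
``d_clonal``) and a recombined macro-state expanded into one sub-state per
bin of the *empirical* distribution of local divergence, so fragments
imported from donors at very different genetic distances are all captured by
a single pass of standard forward--backward machinery.

Transition parameters (``t_enter``, ``t_exit``) and the clonal divergence are
re-estimated per pair by EM; segmentation is by Viterbi decoding with ties
resolved toward the clonal state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from . import _kernels
from .core_data import (
    CoreGenomeSet,
    DiffProfile,
    pair_difference_profile,
    partition_blocks,
    sliding_divergence,
)

__all__ = [
    "EmpiricalDivDist",
    "HMMParams",
    "TransferEvent",
    "PairDecoding",
    "NotAClosePairError",
    "estimate_empirical_divergence",
    "fit_decode_pair",
    "classify_transfer_clade",
    "select_close_pairs",
    "flag_duplicate_transfers",
]


class NotAClosePairError(ValueError):
    """Raised when a profile's divergence is outside the close-pair regime."""


@dataclass(frozen=True)
class EmpiricalDivDist:
    """Discretized distribution of local divergence of recombined sequence."""

    bin_edges: np.ndarray  # length K+1, increasing, within (0, 0.5)
    bin_probs: np.ndarray  # length K, sums to 1
    source: str = "pooled"  # within_clade | between_clade | pooled
    window_bp: int = 1000

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, float)
        probs = np.asarray(self.bin_probs, float)
        if len(edges) != len(probs) + 1:
            raise ValueError("need len(bin_edges) == len(bin_probs) + 1")
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("bin_probs must be non-negative and sum to 1")
        if edges[0] <= 0 or edges[-1] > 0.5 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be increasing within (0, 0.5]")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "bin_probs", probs)

    @property
    def centers(self) -> np.ndarray:
        """Geometric-mean bin centers (divergences are log-spread)."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.bin_probs)

    def mean(self) -> float:
        return float(np.sum(self.centers * self.bin_probs))

    @classmethod
    def from_samples(
        cls,
        samples,
        n_bins: int = 12,
        source: str = "pooled",
        window_bp: int = 1000,
    ) -> "EmpiricalDivDist":
        """Histogram samples of local divergence into log-spaced bins."""
        s = np.asarray(samples, float)
        s = s[(s > 0) & (s < 0.5)]
        if len(s) == 0:
            raise ValueError("no positive divergence samples")
        lo = max(s.min() * 0.9, 1e-5)
        hi = min(s.max() * 1.1, 0.5)
        if hi <= lo:
            hi = min(lo * 1.5, 0.5)
        edges = np.geomspace(lo, hi, n_bins + 1)
        counts, edges = np.histogram(s, bins=edges)
        keep = counts > 0
        # collapse empty bins by keeping only populated ones
        new_edges = [edges[0]]
        new_probs = []
        run_count = 0
        for i in range(len(counts)):
            run_count += counts[i]
            if keep[i] or i == len(counts) - 1:
                new_edges.append(edges[i + 1])
                new_probs.append(run_count)
                run_count = 0
        probs = np.asarray(new_probs, float)
        probs = probs / probs.sum()
        return cls(
            bin_edges=np.asarray(new_edges),
            bin_probs=probs,
            source=source,
            window_bp=window_bp,
        )

    @classmethod
    def constant(cls, d: float, source: str = "pooled") -> "EmpiricalDivDist":
        return cls(
            bin_edges=np.array([d * 0.8, d * 1.25]),
            bin_probs=np.array([1.0]),
            source=source,
        )


@dataclass
class HMMParams:
    """Per-pair CP-HMM parameters (all probabilities per synonymous site)."""

    d_clonal: float
    t_enter: float
    t_exit: float
    emissions: EmpiricalDivDist

    def __post_init__(self):
        if not (0 <= self.t_enter <= 1 and 0 <= self.t_exit <= 1):
            raise ValueError("transition probabilities must be in [0, 1]")


@dataclass
class TransferEvent:
    """One decoded recombined segment."""

    pair: tuple[str, str]
    start_site: int  # 0-based half-open indices into the compared-site vector
    end_site: int
    start_bp: int
    end_bp: int
    length_sites: int
    length_bp: int
    n_snvs: int
    local_div: float
    clade_label: str = "NA"  # within | between | NA
    is_duplicate: bool = False

    def __post_init__(self):
        if self.end_bp < self.start_bp or self.local_div < 0:
            raise ValueError("malformed transfer event")

    def reciprocal_overlap(self, other: "TransferEvent") -> float:
        inter = min(self.end_bp, other.end_bp) - max(self.start_bp, other.start_bp) + 1
        if inter <= 0:
            return 0.0
        return inter / max(self.length_bp, other.length_bp)


@dataclass
class PairDecoding:
    """CP-HMM output for one strain pair."""

    pair: tuple[str, str]
    d_clonal_hat: float
    clonal_fraction: float
    events: list
    loglik: float
    n_em_iters: int
    converged: bool
    n_sites: int
    posterior_recombined_mean: float = float("nan")
    params: HMMParams | None = None

    @property
    def n_events(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------


def estimate_empirical_divergence(
    genomes: CoreGenomeSet,
    window_bp: int = 1000,
    clade_pairing: str = "pooled",
    n_bins: int = 12,
    min_pairs: int = 10,
    max_pairs: int = 60,
    max_fid_typical: float = 0.1,
    seed: int = 0,
) -> EmpiricalDivDist:
    """Empirical distribution of local divergence among typical pairs.

    Pools sliding-window divergences over typically diverged pairs.  Close
    pairs — recognized by an appreciable fraction of identical 1000-site
    blocks (> ``max_fid_typical``) — are excluded so the clonal signal does
    not contaminate the recombined-fragment emission model.  The block
    criterion (rather than a divergence cutoff relative to the species
    median) keeps both modes of two-clade species in the pooled histogram.
    """
    if clade_pairing not in ("within", "between", "pooled"):
        raise ValueError(f"unknown clade_pairing {clade_pairing!r}")
    rng = np.random.default_rng(seed)
    ids = genomes.strain_ids
    clades = {s: genomes.clade_of(s) for s in ids}
    pairs = []
    for a, b in combinations(ids, 2):
        if clade_pairing == "within" and clades[a] != clades[b]:
            continue
        if clade_pairing == "between" and (
            clades[a] == clades[b] or clades[a] is None or clades[b] is None
        ):
            continue
        pairs.append((a, b))
    if len(pairs) > 4 * max_pairs:
        sel = rng.choice(len(pairs), size=4 * max_pairs, replace=False)
        pairs = [pairs[i] for i in sel]

    profs = [pair_difference_profile(genomes, a, b) for a, b in pairs]
    typical = []
    for p in profs:
        block = min(1000, max(100, p.n_sites // 10))
        if p.n_sites < block:
            continue
        blocks = partition_blocks(p, block)
        f_id = float(np.mean(blocks.snv_count_per_block == 0))
        if f_id <= max_fid_typical:
            typical.append(p)
    if len(typical) < min_pairs:
        raise ValueError(
            f"only {len(typical)} typically diverged pairs available "
            f"(need >= {min_pairs}); supply a parametric emission "
            "distribution instead (EmpiricalDivDist.constant or from_samples)"
        )
    if len(typical) > max_pairs:
        sel = rng.choice(len(typical), size=max_pairs, replace=False)
        typical = [typical[i] for i in sel]
    samples = []
    for p in typical:
        track = sliding_divergence(p, window_bp=window_bp)
        vals = track["divergence"].to_numpy()
        samples.append(vals[np.isfinite(vals) & (vals > 0)])
    pooled = np.concatenate(samples)
    return EmpiricalDivDist.from_samples(
        pooled, n_bins=n_bins, source={"within": "within_clade",
                                       "between": "between_clade",
                                       "pooled": "pooled"}[clade_pairing],
        window_bp=window_bp,
    )


def _initial_params(profile: DiffProfile, emissions: EmpiricalDivDist,
                    max_init_clonal_div: float) -> HMMParams:
    """Moment-matched initialization from coarse block statistics."""
    n = profile.n_sites
    block = min(1000, max(100, n // 20))
    n_blocks = n // block
    counts = np.add.reduceat(
        profile.diff[: n_blocks * block].astype(np.int64),
        np.arange(0, n_blocks * block, block),
    )
    med = np.median(counts)
    thr = max(2.0, 3.0 * med)
    clonal_blocks = counts <= thr
    c0 = float(np.mean(clonal_blocks))
    if clonal_blocks.any():
        d0 = counts[clonal_blocks].sum() / (clonal_blocks.sum() * block)
    else:
        d0 = profile.divergence()
    d0 = max(d0, 1e-7)
    if d0 > max_init_clonal_div:
        raise NotAClosePairError(
            f"initial clonal divergence estimate {d0:.2e} exceeds the "
            f"close-pair regime ({max_init_clonal_div:.1e}); pair "
            f"{profile.pair} is not decodable by the CP-HMM"
        )
    t_exit = 1.0 / 2000.0
    t_enter = max(1.0 - c0, 1e-4) * t_exit
    return HMMParams(d_clonal=d0, t_enter=t_enter, t_exit=t_exit, emissions=emissions)


def fit_decode_pair(
    profile: DiffProfile,
    emissions: EmpiricalDivDist,
    init: HMMParams | None = None,
    max_iters: int = 50,
    tol: float = 1e-2,
    min_snvs_per_event: int = 2,
    merge_gap_bp: int = 100,
    max_init_clonal_div: float = 2e-3,
) -> PairDecoding:
    """EM-fit and Viterbi-decode the CP-HMM on one pair's mismatch profile.

    Returns a :class:`PairDecoding` whose events are non-overlapping, sorted,
    merged across micro-gaps (< ``merge_gap_bp`` of decoded clonal path) and
    filtered to carry at least ``min_snvs_per_event`` SNVs (shorter decoded
    segments are indistinguishable from chance mutation clusters).  The
    returned clonal divergence is re-estimated from the data outside the
    final events; EM log-likelihood is checked to be non-decreasing.
    """
    if profile.n_sites == 0:
        raise ValueError("empty profile")
    obs = np.ascontiguousarray(profile.diff, dtype=np.uint8)
    params = init or _initial_params(profile, emissions, max_init_clonal_div)
    w = np.ascontiguousarray(emissions.bin_probs, float)
    divs = np.ascontiguousarray(emissions.centers, float)
    d_cl, t_en, t_ex = params.d_clonal, params.t_enter, params.t_exit
    min_div = float(divs.min())

    prev_ll = -np.inf
    converged = False
    n_iter = 0
    post_mean = float("nan")
    for n_iter in range(1, max_iters + 1):
        (
            ll,
            g0_sum,
            g0_x,
            xi_cr,
            xi_rc,
            gR_sum,
            g0_trans,
            gR_trans,
            post_recomb,
        ) = _kernels.hmm_forward_backward(obs, d_cl, t_en, t_ex, w, divs)
        if ll < prev_ll - 1e-6 * abs(prev_ll) - 1e-9:
            raise RuntimeError(
                f"EM log-likelihood decreased ({prev_ll:.6g} -> {ll:.6g})"
            )
        post_mean = float(post_recomb.mean())
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol:
            prev_ll = ll
            converged = True
            break
        prev_ll = ll
        # M-step
        if g0_sum > 0:
            d_cl = min(max(g0_x / g0_sum, 1e-10), 0.5 * min_div)
        if g0_trans > 0:
            t_en = min(max(xi_cr / g0_trans, 1e-12), 0.5)
        if gR_trans > 0:
            t_ex = min(max(xi_rc / gR_trans, 1e-12), 0.5)

    path = _kernels.hmm_viterbi(obs, d_cl, t_en, t_ex, w, divs)
    events = _events_from_path(
        profile, path, merge_gap_bp=merge_gap_bp, min_snvs=min_snvs_per_event
    )
    recombined_sites = sum(e.length_sites for e in events)
    f_c = 1.0 - recombined_sites / profile.n_sites

    clonal_mask = np.ones(profile.n_sites, dtype=bool)
    for e in events:
        clonal_mask[e.start_site : e.end_site] = False
    n_clonal = int(clonal_mask.sum())
    d_hat = float(obs[clonal_mask].sum() / n_clonal) if n_clonal else float("nan")

    return PairDecoding(
        pair=profile.pair,
        d_clonal_hat=d_hat,
        clonal_fraction=f_c,
        events=events,
        loglik=float(prev_ll),
        n_em_iters=n_iter,
        converged=converged,
        n_sites=profile.n_sites,
        posterior_recombined_mean=post_mean,
        params=HMMParams(d_clonal=d_cl, t_enter=t_en, t_exit=t_ex, emissions=emissions),
    )


def _events_from_path(profile, path, merge_gap_bp, min_snvs):
    pos = profile.syn_site_index
    changes = np.flatnonzero(np.diff(path)) + 1
    edges = np.concatenate(([0], changes, [len(path)]))
    raw = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if path[lo] == 1:
            raw.append([int(lo), int(hi)])
    # merge events separated by tiny clonal gaps (emission noise)
    merged = []
    for seg in raw:
        if merged and pos[seg[0]] - pos[merged[-1][1] - 1] - 1 < merge_gap_bp:
            merged[-1][1] = seg[1]
        else:
            merged.append(seg)
    events = []
    for lo, hi in merged:
        n_snvs = int(profile.diff[lo:hi].sum())
        if n_snvs < min_snvs:
            continue
        start_bp = int(pos[lo])
        end_bp = int(pos[hi - 1])
        events.append(
            TransferEvent(
                pair=profile.pair,
                start_site=lo,
                end_site=hi,
                start_bp=start_bp,
                end_bp=end_bp,
                length_sites=hi - lo,
                length_bp=end_bp - start_bp + 1,
                n_snvs=n_snvs,
                local_div=n_snvs / (hi - lo),
            )
        )
    return events


def classify_transfer_clade(
    event: TransferEvent,
    within_div: float | None,
    between_div: float | None,
) -> str:
    """Label a transfer within/between-clade by its local divergence.

    The decision boundary is the geometric midpoint sqrt(within * between),
    appropriate because divergences are log-spread.  Returns ``"NA"`` when
    the species has no annotated clade structure.
    """
    if within_div is None or between_div is None:
        return "NA"
    if within_div >= between_div:
        raise ValueError("need within_div < between_div")
    midpoint = float(np.sqrt(within_div * between_div))
    return "between" if event.local_div > midpoint else "within"


def select_close_pairs(
    decodings,
    d_star: float = 1e-4,
    fc_star: float = 0.2,
):
    """Split decodings into close pairs and excluded pairs.

    A close pair satisfies ``d_clonal_hat <= d_star`` and
    ``clonal_fraction >= fc_star``; only close pairs support resolved
    per-event statistics.  Returns ``(kept, excluded)``.
    """
    kept, excluded = [], []
    for d in decodings:
        if d.d_clonal_hat <= d_star and d.clonal_fraction >= fc_star:
            kept.append(d)
        else:
            excluded.append(d)
    return kept, excluded


def flag_duplicate_transfers(
    events_by_pair: dict,
    overlap_frac: float = 0.8,
    div_tol: float = 0.3,
):
    """Flag transfers that are likely the same historical event seen twice.

    Two events are duplicates when their strain pairs share a strain, their
    reciprocal bp overlap is at least ``overlap_frac``, and their local
    divergences agree within relative tolerance ``div_tol``.  Within each
    duplicate cluster all but one event get ``is_duplicate=True``.  Events
    are modified in place; the flat annotated list is returned.
    """
    flat = []
    for pair, events in events_by_pair.items():
        for e in events:
            flat.append((set(pair), e))
    n = len(flat)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        si, ei = flat[i]
        for j in range(i + 1, n):
            sj, ej = flat[j]
            if si == sj or not (si & sj):
                continue
            if ei.reciprocal_overlap(ej) < overlap_frac:
                continue
            hi = max(ei.local_div, ej.local_div)
            if hi > 0 and abs(ei.local_div - ej.local_div) / hi > div_tol:
                continue
            union(i, j)

    seen_roots = set()
    for i in range(n):
        r = find(i)
        if r in seen_roots:
            flat[i][1].is_duplicate = True
        else:
            seen_roots.add(r)
            flat[i][1].is_duplicate = False
    return [e for _, e in flat]
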