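"""Within-host analyses from per-sample SNV frequency/coverage tables.

A host co-colonized by two diverged conspecific strains shows many SNVs at
intermediate frequency.  From such tables we (i) detect dual colonization,
(ii) quasi-phase the dominant strain's haplotype when one strain exceeds a
frequency threshold, and (iii) detect gene-specific sweeps: regions where
intermediate-frequency SNVs are suddenly depleted while read coverage stays
near the genome-wide level (ruling out deletions), the footprint left when a
hybrid strain carrying a transferred fragment displaces its parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleSNVTable",
    "SweepCall",
    "read_snv_table",
    "detect_dual_colonization",
    "quasi_phase_dominant",
    "detect_sweep_regions",
]


@dataclass
class SampleSNVTable:
    """Per-site allele counts and depths for one metagenomic sample.

    ``data`` columns: contig, pos_bp, ref_allele, alt_allele, alt_count,
    depth.  Rows should cover all assayed core sites (monomorphic sites with
    alt_count 0 included) so that regional coverage is measurable.
    Frequencies are defined only where depth >= depth_min.
    """

    data: pd.DataFrame
    depth_min: int = 10

    def __post_init__(self):
        required = {"contig", "pos_bp", "ref_allele", "alt_allele", "alt_count", "depth"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"SNV table missing column(s): {sorted(missing)}")
        if (self.data["depth"] < 0).any():
            raise ValueError("negative depth")
        self.data = self.data.sort_values(["contig", "pos_bp"]).reset_index(drop=True)

    @property
    def covered(self) -> np.ndarray:
        return self.data["depth"].to_numpy() >= self.depth_min

    @property
    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency; NaN below the depth floor."""
        depth = self.data["depth"].to_numpy(float)
        alt = self.data["alt_count"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
        f[~self.covered] = np.nan
        return f

    @property
    def genome_wide_median_depth(self) -> float:
        return float(np.median(self.data["depth"].to_numpy()))


@dataclass
class SweepCall:
    """A candidate gene-specific sweep region."""

    contig: str
    start_bp: int
    end_bp: int
    n_intermediate_snvs_inside: int
    flank_density_left: float  # intermediate SNVs per bp on the left flank
    flank_density_right: float
    coverage_ratio: float
    mode: str = "single"  # single | longitudinal

    def __post_init__(self):
        if self.coverage_ratio <= 0:
            raise ValueError("coverage_ratio must be positive")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def read_snv_table(path, depth_min: int = 10) -> SampleSNVTable:
    """Read the flat per-sample SNV dialect (TSV with '#' comments)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"contig": str})
    return SampleSNVTable(data=df, depth_min=depth_min)


def detect_dual_colonization(
    table: SampleSNVTable,
    f_low: float = 0.2,
    f_high: float = 0.8,
    min_sites: int = 100,
    min_covered_sites: int = 500,
):
    """Is the sample co-colonized by two diverged strains?

    Dual iff at least ``min_sites`` covered SNVs have alt frequency strictly
    inside (f_low, f_high); the dominant-strain frequency estimate is the
    mode of the folded (major-allele) intermediate-frequency distribution.
    Returns ``(is_dual, strain_freq)``; strain_freq is NaN when not dual,
    and is_dual is None (indeterminate) with too few covered sites.
    """
    f = table.alt_freq
    covered = np.isfinite(f)
    if covered.sum() < min_covered_sites:
        return None, float("nan")
    inter = f[covered & (f > f_low) & (f < f_high)]
    if len(inter) < min_sites:
        return False, float("nan")
    folded = np.maximum(inter, 1.0 - inter)
    hist, edges = np.histogram(folded, bins=20, range=(0.5, 1.0))
    peak = int(np.argmax(hist))
    strain_freq = float(0.5 * (edges[peak] + edges[peak + 1]))
    return True, strain_freq


def quasi_phase_dominant(
    table: SampleSNVTable,
    threshold: float = 0.8,
):
    """Reconstruct the dominant strain's haplotype from allele frequencies.

    At each covered site the major allele is assigned to the dominant strain
    when its frequency exceeds ``threshold``; sites with intermediate
    frequencies (or below the depth floor) are masked.  Returns a DataFrame
    with columns contig, pos_bp, allele (ref/alt string or None when
    masked).
    """
    f = table.alt_freq
    alleles: list = []
    ref = table.data["ref_allele"].to_numpy()
    alt = table.data["alt_allele"].to_numpy()
    for i, freq in enumerate(f):
        if not np.isfinite(freq):
            alleles.append(None)
        elif freq > threshold:
            alleles.append(alt[i])
        elif 1.0 - freq > threshold:
            alleles.append(ref[i])
        else:
            alleles.append(None)
    return pd.DataFrame(
        {
            "contig": table.data["contig"],
            "pos_bp": table.data["pos_bp"],
            "allele": alleles,
        }
    )


def _intermediate_positions(table, f_low, f_high):
    f = table.alt_freq
    mask = np.isfinite(f) & (f > f_low) & (f < f_high)
    return table.data.loc[mask, ["contig", "pos_bp"]]


def _regional_coverage_ratio(table, contig, start_bp, end_bp):
    d = table.data
    sel = (d["contig"] == contig) & (d["pos_bp"] >= start_bp) & (d["pos_bp"] <= end_bp)
    depths = d.loc[sel, "depth"].to_numpy()
    if len(depths) == 0:
        return float("nan")
    gw = table.genome_wide_median_depth
    return float(np.median(depths) / gw) if gw > 0 else float("nan")


def detect_sweep_regions(
    tables,
    min_sweep_bp: int = 10_000,
    cov_band: tuple[float, float] = (0.6, 1.5),
    flank_bp: int = 10_000,
    flank_density_floor: float = 1.0 / 2000.0,
    f_low: float = 0.2,
    f_high: float = 0.8,
) -> list[SweepCall]:
    """Detect gene-specific sweep footprints in a dual-colonized sample.

    ``tables`` is one table (single-timepoint mode) or a (T0, T1) pair
    (longitudinal).  Single-timepoint calls are maximal gaps of length >=
    ``min_sweep_bp`` between consecutive intermediate-frequency SNVs whose
    10 kb flanks keep an intermediate-SNV density of at least one per 2 kb
    (distinguishing a sweep from regions where the co-colonizing strains are
    simply identical) and whose median coverage stays within ``cov_band`` of
    the genome-wide median (ruling out deletion).  Longitudinal mode keeps
    only T1 calls whose region was still polymorphic at T0, and is therefore
    strictly more conservative.
    """
    if isinstance(tables, SampleSNVTable):
        t0, t1, longitudinal = None, tables, False
    else:
        seq = list(tables)
        if len(seq) == 1:
            t0, t1, longitudinal = None, seq[0], False
        elif len(seq) == 2:
            t0, t1, longitudinal = seq[0], seq[1], True
        else:
            raise ValueError("tables must be one table or a (T0, T1) pair")

    inter = _intermediate_positions(t1, f_low, f_high)
    if len(inter) == 0:
        raise ValueError(
            "no intermediate-frequency SNVs at the calling timepoint; "
            "sample is not dual-colonized"
        )
    calls: list[SweepCall] = []
    for contig, grp in inter.groupby("contig", sort=False):
        pos = np.sort(grp["pos_bp"].to_numpy())
        gaps = np.diff(pos)
        for g_idx in np.flatnonzero(gaps >= min_sweep_bp):
            start = int(pos[g_idx]) + 1
            end = int(pos[g_idx + 1]) - 1
            n_left = int(
                np.sum((pos >= start - flank_bp) & (pos < start))
            )
            n_right = int(np.sum((pos > end) & (pos <= end + flank_bp)))
            dens_l = n_left / flank_bp
            dens_r = n_right / flank_bp
            if dens_l < flank_density_floor or dens_r < flank_density_floor:
                continue
            cov_ratio = _regional_coverage_ratio(t1, contig, start, end)
            if not np.isfinite(cov_ratio) or not (
                cov_band[0] <= cov_ratio <= cov_band[1]
            ):
                continue
            if longitudinal:
                # region must have been polymorphic at baseline
                i0 = _intermediate_positions(t0, f_low, f_high)
                p0 = i0.loc[i0["contig"] == contig, "pos_bp"].to_numpy()
                n0 = int(np.sum((p0 >= start) & (p0 <= end)))
                if n0 / max(end - start + 1, 1) < flank_density_floor:
                    continue
            calls.append(
                SweepCall(
                    contig=str(contig),
                    start_bp=start,
                    end_bp=end,
                    n_intermediate_snvs_inside=0,
                    flank_density_left=dens_l,
                    flank_density_right=dens_r,
                    coverage_ratio=cov_ratio,
                    mode="longitudinal" if longitudinal else "single",
                )
            )
    return calls
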