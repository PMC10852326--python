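"""Core-genome data containers and site-level primitives.

All downstream analyses operate on a :class:`CoreGenomeSet`: an aligned set of
core-genome haplotypes (one per strain) together with per-column site
annotations (synonymous flag, gene, contig/position).  Pairwise comparisons
are reduced to a :class:`DiffProfile` — the ordered binary vector of allele
mismatches at compared (usually synonymous) sites — from which divergence,
identical-block fractions, and sliding-window divergence tracks are computed.

Conventions
-----------
* Genomic coordinates are 1-based inclusive bp; site indices are 0-based
  half-open internally.
* A site missing in either strain of a pair is excluded from both the
  numerator and the denominator of divergence.
* Allele codes: 0..3 = A,C,G,T; -1 = missing/ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = -1

_ALLELE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_ALLELE = np.array(list("ACGT"))


def encode_alleles(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes; unknown characters -> missing."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, MISSING, dtype=np.int8)
    for base, code in _ALLELE_CODE.items():
        out[arr == ord(base)] = code
    return out


def decode_alleles(codes: np.ndarray, missing_char: str = "N") -> str:
    chars = np.full(codes.shape, missing_char, dtype="<U1")
    ok = codes >= 0
    chars[ok] = _CODE_ALLELE[codes[ok]]
    return "".join(chars)


@dataclass(frozen=True)
class CoreSite:
    """A single aligned core-genome column."""

    contig: str
    pos_bp: int  # 1-based
    is_synonymous: bool
    gene_id: str | None = None


@dataclass
class CoreGenomeSet:
    """Aligned core-genome haplotypes of one species plus site annotations.

    Attributes
    ----------
    species_name : str
    sites : pandas.DataFrame
        Columns ``contig`` (str), ``pos_bp`` (int, 1-based),
        ``is_synonymous`` (bool), ``gene_id`` (str or None); one row per
        alignment column, positions strictly increasing within each contig.
    haplotypes : numpy.ndarray
        int8 matrix (n_strains, n_sites); values 0..3 or -1 (missing).
    strain_meta : pandas.DataFrame
        Columns ``strain_id``, ``host_id``, ``clade_id`` (nullable).
    """

    species_name: str
    sites: pd.DataFrame
    haplotypes: np.ndarray
    strain_meta: pd.DataFrame
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        n_strains, n_sites = self.haplotypes.shape
        if len(self.sites) != n_sites:
            raise ValueError(
                f"annotation covers {len(self.sites)} sites but haplotypes "
                f"have {n_sites} columns"
            )
        if len(self.strain_meta) != n_strains:
            raise ValueError("strain_meta rows must match haplotype rows")
        ids = self.strain_meta["strain_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate strain_id {dup!r}")
        for contig, grp in self.sites.groupby("contig", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {contig}")
        self._index = {s: i for i, s in enumerate(ids)}

    # -- convenience accessors -------------------------------------------------
    @property
    def n_strains(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def L_bp(self) -> int:
        """Total core-genome length in bp (sum of per-contig spans)."""
        total = 0
        for _, grp in self.sites.groupby("contig", sort=False):
            total += int(grp["pos_bp"].max())
        return total

    @property
    def strain_ids(self) -> list[str]:
        return list(self.strain_meta["strain_id"])

    @property
    def syn_mask(self) -> np.ndarray:
        return self.sites["is_synonymous"].to_numpy(dtype=bool)

    def strain_index(self, strain_id: str) -> int:
        try:
            return self._index[strain_id]
        except KeyError:
            raise KeyError(f"unknown strain {strain_id!r}") from None

    def haplotype(self, strain_id: str) -> np.ndarray:
        return self.haplotypes[self.strain_index(strain_id)]

    def clade_of(self, strain_id: str):
        row = self.strain_meta.iloc[self.strain_index(strain_id)]
        return row.get("clade_id", None)


@dataclass
class DiffProfile:
    """Ordered mismatch indicators for one strain pair at compared sites.

    Sites missing in either strain are dropped entirely (they appear in
    ``n_missing`` only), so ``diff`` and ``syn_site_index`` cover exactly the
    sites that enter both the numerator and denominator of divergence.
    """

    pair: tuple[str, str]
    syn_site_index: np.ndarray  # genomic bp position of each compared site
    diff: np.ndarray  # uint8, 1 = mismatch
    n_missing: int = 0
    contig: np.ndarray | None = None  # optional per-site contig labels

    def __post_init__(self):
        if len(self.diff) != len(self.syn_site_index):
            raise ValueError("diff and syn_site_index must have equal length")

    @property
    def n_sites(self) -> int:
        return len(self.diff)

    def divergence(self) -> float:
        """Mean mismatch fraction over compared (non-missing) sites."""
        if self.n_sites == 0:
            return float("nan")
        return float(self.diff.mean())


@dataclass
class BlockSeries:
    """Non-overlapping blocks of consecutive compared sites with SNV counts."""

    block_size_sites: int
    snv_count_per_block: np.ndarray
    block_bounds: np.ndarray  # (n_blocks, 2) site-index ranges, half-open

    @property
    def n_blocks(self) -> int:
        return len(self.snv_count_per_block)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_core_alignment(fasta_path, annotation_path, species_name: str | None = None) -> CoreGenomeSet:
    """Load an aligned core genome (FASTA) plus its site-annotation TSV.

    FASTA record ids follow ``strain_id|host_id[|clade_id]``.  The annotation
    TSV has columns ``contig``, ``pos_bp``, ``is_synonymous`` (0/1) and
    ``gene_id``; its rows must cover every alignment column, in order.
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA file: {fasta_path}")
    length = len(records[0].seq)
    rows = []
    meta = []
    for rec in records:
        if len(rec.seq) != length:
            raise ValueError(
                f"record {rec.id!r} has length {len(rec.seq)}, expected {length}"
            )
        parts = rec.id.split("|")
        strain = parts[0]
        host = parts[1] if len(parts) > 1 else strain
        clade = parts[2] if len(parts) > 2 else None
        meta.append({"strain_id": strain, "host_id": host, "clade_id": clade})
        rows.append(encode_alleles(str(rec.seq)))
    haplotypes = np.vstack(rows)

    sites = pd.read_csv(annotation_path, sep="\t", comment="#", dtype={"contig": str})
    required = {"contig", "pos_bp", "is_synonymous"}
    missing_cols = required - set(sites.columns)
    if missing_cols:
        raise ValueError(f"annotation missing column(s): {sorted(missing_cols)}")
    if "gene_id" not in sites.columns:
        sites["gene_id"] = None
    if len(sites) != length:
        raise ValueError(
            f"annotation has {len(sites)} rows but alignment has {length} columns"
        )
    sites = sites.assign(is_synonymous=sites["is_synonymous"].astype(bool))
    return CoreGenomeSet(
        species_name=species_name or fasta_path.stem,
        sites=sites.reset_index(drop=True),
        haplotypes=haplotypes,
        strain_meta=pd.DataFrame(meta),
    )


def write_core_alignment(genomes: CoreGenomeSet, fasta_path, annotation_path) -> None:
    """Write a CoreGenomeSet back to the FASTA + site-TSV dialect."""
    records = []
    for i, row in genomes.strain_meta.iterrows():
        rid = str(row["strain_id"]) + "|" + str(row["host_id"])
        if row.get("clade_id") is not None and not pd.isna(row.get("clade_id")):
            rid += "|" + str(row["clade_id"])
        records.append(
            SeqRecord(Seq(decode_alleles(genomes.haplotypes[i])), id=rid, description="")
        )
    SeqIO.write(records, str(fasta_path), "fasta")
    out = genomes.sites.copy()
    out["is_synonymous"] = out["is_synonymous"].astype(int)
    out.to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pairwise primitives
# ---------------------------------------------------------------------------

def pair_difference_profile(
    genomes: CoreGenomeSet,
    a: str,
    b: str,
    synonymous_only: bool = True,
) -> DiffProfile:
    """Binary mismatch profile between strains ``a`` and ``b``.

    ``diff[i] = 1`` iff both alleles are observed and unequal; sites missing
    in either strain are removed from the profile (counted in ``n_missing``).
    """
    ha = genomes.haplotype(a)
    hb = genomes.haplotype(b)
    mask = genomes.syn_mask if synonymous_only else np.ones(genomes.n_sites, bool)
    observed = (ha >= 0) & (hb >= 0) & mask
    n_missing = int(mask.sum() - observed.sum())
    idx = np.flatnonzero(observed)
    diff = (ha[idx] != hb[idx]).astype(np.uint8)
    return DiffProfile(
        pair=(a, b),
        syn_site_index=genomes.sites["pos_bp"].to_numpy()[idx],
        diff=diff,
        n_missing=n_missing,
        contig=genomes.sites["contig"].to_numpy()[idx],
    )


def profile_from_diff(diff: np.ndarray, positions: np.ndarray | None = None,
                      pair=("a", "b")) -> DiffProfile:
    """Build a DiffProfile from a bare mismatch vector (simulation helper)."""
    diff = np.asarray(diff, dtype=np.uint8)
    if positions is None:
        positions = np.arange(1, len(diff) + 1, dtype=np.int64)
    return DiffProfile(pair=tuple(pair), syn_site_index=np.asarray(positions), diff=diff)


def partition_blocks(
    profile: DiffProfile,
    block_size_sites: int = 1000,
    drop_partial: bool = True,
) -> BlockSeries:
    """Partition a profile into consecutive fixed-size blocks of compared sites.

    Blocks never span contig boundaries; the trailing partial block of each
    contig is dropped by default (``drop_partial=False`` keeps it).
    """
    if block_size_sites < 1:
        raise ValueError("block_size_sites must be >= 1")
    if profile.n_sites < block_size_sites:
        raise ValueError(
            f"profile has {profile.n_sites} sites, shorter than one block "
            f"({block_size_sites})"
        )
    counts = []
    bounds = []
    for start, stop in _contig_runs(profile):
        n = stop - start
        n_blocks = n // block_size_sites if drop_partial else -(-n // block_size_sites)
        for k in range(n_blocks):
            lo = start + k * block_size_sites
            hi = min(start + (k + 1) * block_size_sites, stop)
            counts.append(int(profile.diff[lo:hi].sum()))
            bounds.append((lo, hi))
    return BlockSeries(
        block_size_sites=block_size_sites,
        snv_count_per_block=np.asarray(counts, dtype=np.int64),
        block_bounds=np.asarray(bounds, dtype=np.int64),
    )


def _contig_runs(profile: DiffProfile):
    """Half-open site-index ranges of each contig in a profile."""
    if profile.contig is None:
        yield 0, profile.n_sites
        return
    contigs = profile.contig
    change = np.flatnonzero(contigs[1:] != contigs[:-1]) + 1
    edges = np.concatenate(([0], change, [len(contigs)]))
    for lo, hi in zip(edges[:-1], edges[1:]):
        yield int(lo), int(hi)


def fraction_identical_blocks(blocks: BlockSeries) -> float:
    """Share of blocks carrying zero SNV differences."""
    if blocks.n_blocks == 0:
        raise ValueError("need at least one block")
    return float(np.mean(blocks.snv_count_per_block == 0))


def sliding_divergence(
    profile: DiffProfile,
    window_bp: int,
    step_bp: int | None = None,
) -> pd.DataFrame:
    """Per-window divergence track along the genome.

    Windows are laid on genomic bp coordinates; each window's value is
    (#mismatches)/(#compared sites) within the window, NaN where the window
    covers no compared site.  Returns a DataFrame with columns
    ``midpoint_bp``, ``n_sites``, ``divergence``.
    """
    if step_bp is None:
        step_bp = window_bp
    pos = profile.syn_site_index
    if len(pos) == 0:
        raise ValueError("empty profile")
    lo, hi = int(pos[0]), int(pos[-1])
    starts = np.arange(lo, max(hi - window_bp + 2, lo + 1), step_bp)
    csum = np.concatenate(([0], np.cumsum(profile.diff, dtype=np.int64)))
    left = np.searchsorted(pos, starts, side="left")
    right = np.searchsorted(pos, starts + window_bp, side="left")
    n_sites = right - left
    n_diff = csum[right] - csum[left]
    with np.errstate(invalid="ignore", divide="ignore"):
        div = np.where(n_sites > 0, n_diff / np.maximum(n_sites, 1), np.nan)
    return pd.DataFrame(
        {
            "midpoint_bp": starts + window_bp // 2,
            "n_sites": n_sites,
            "divergence": div,
        }
    )
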