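"""Shared fixtures: small synthetic genome sets built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from corerecomb.core_data import CoreGenomeSet


def make_genomes(haplotypes, hosts=None, clades=None, syn_mask=None,
                 species="test_sp", pos_step=1):
    """Assemble a CoreGenomeSet from an (n_strains, n_sites) allele matrix."""
    haps = np.asarray(haplotypes, dtype=np.int8)
    n, L = haps.shape
    if syn_mask is None:
        syn_mask = np.ones(L, dtype=bool)
    sites = pd.DataFrame(
        {
            "contig": np.repeat("c1", L),
            "pos_bp": np.arange(1, L + 1) * pos_step,
            "is_synonymous": np.asarray(syn_mask, bool),
            "gene_id": [None] * L,
        }
    )
    meta = pd.DataFrame(
        {
            "strain_id": [f"s{i}" for i in range(n)],
            "host_id": hosts if hosts is not None else [f"h{i}" for i in range(n)],
            "clade_id": clades if clades is not None else [None] * n,
        }
    )
    return CoreGenomeSet(species_name=species, sites=sites, haplotypes=haps,
                         strain_meta=meta)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240201)


@pytest.fixture(scope="session")
def two_clade_genomes():
    """20 strains in 2 clades: ~1% within-clade, ~10% between-clade divergence.

    Built from clade ancestral haplotypes plus independent per-strain
    mutations, so pairwise divergences are tightly concentrated.
    """
    rng = np.random.default_rng(7)
    L = 30_000
    n_per = 10
    anc1 = rng.integers(0, 4, L).astype(np.int8)
    # between-clade divergence ~10%: flip 10% of sites in clade-2 ancestor
    anc2 = anc1.copy()
    flip = rng.random(L) < 0.10
    anc2[flip] = (anc2[flip] + 1 + rng.integers(0, 3, int(flip.sum()))) % 4
    haps = []
    for anc in (anc1, anc2):
        for _ in range(n_per):
            h = anc.copy()
            m = rng.random(L) < 0.005  # ~1% pairwise within clade
            h[m] = (h[m] + 1 + rng.integers(0, 3, int(m.sum()))) % 4
            haps.append(h)
    clades = ["c1"] * n_per + ["c2"] * n_per
    return make_genomes(np.vstack(haps), clades=clades, species="two_clade")
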