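"""Shared fixtures: small validated locus panels, compact simulated
libraries (noise-free and noisy), and toy genotype matrices."""

from __future__ import annotations

import numpy as np
import pytest

import msatpipe as mp
from msatpipe.genotypes import GenotypeMatrix


SMALL_SITES = ["A", "B", "C"]
SMALL_ISLANDS = {"A": "I1", "B": "I1", "C": "I2"}


def small_sim_config(**overrides) -> mp.SimConfig:
    base = dict(
        sites=SMALL_SITES,
        islands=SMALL_ISLANDS,
        pop_sizes=[12, 12, 12],
        loci=mp.default_loci(4),
        mean_depth=30.0,
        depth_dispersion=5.0,
        theta_fst=0.08,
        seed=101,
    )
    base.update(overrides)
    return mp.SimConfig(**base)


def run_genotyping(config: mp.SimConfig, strategy: str = "depth", rng_seed: int = 0):
    """simulate -> demux -> trim -> collapse -> filter -> call."""
    truth = mp.simulate_truth(config)
    scheme = mp.default_barcode_scheme(config.sites)
    reads = mp.simulate_read_set(truth, config, scheme)
    rvs = {l.name: l.rvs_primer for l in config.loci}
    assignments = []
    for site in config.sites:
        assigned, _, _ = mp.demultiplex_reads(reads[site], scheme, config.loci)
        assignments.extend(mp.trim_read(a, rvs[a.locus]) for a in assigned)
    tally = mp.collapse_reads(assignments)
    tally, _ = mp.apply_length_filter(tally, loci=config.loci)
    tally, _ = mp.apply_depth_prevalence_filters(tally)
    calls = mp.call_genotypes(tally, strategy, np.random.default_rng(rng_seed))
    return truth, scheme, reads, tally, calls


@pytest.fixture(scope="session")
def small_loci():
    return mp.default_loci(4)


@pytest.fixture(scope="session")
def noise_free_small():
    """A compact noise-free library plus its genotyping results."""
    config = mp.SimConfig.noise_free(
        sites=SMALL_SITES,
        islands=SMALL_ISLANDS,
        pop_sizes=[12, 12, 12],
        loci=mp.default_loci(4),
        seed=42,
    )
    truth, scheme, reads, tally, calls = run_genotyping(config)
    return {
        "config": config,
        "truth": truth,
        "scheme": scheme,
        "reads": reads,
        "tally": tally,
        "calls": calls,
    }


def truth_pairs(truth: mp.TruthSet) -> dict:
    """(site, colony, locus) -> sorted pair of true allele sequences."""
    frame = truth.to_frame()
    return {
        (r.site, r.colony, r.locus): tuple(sorted([r.allele1_seq, r.allele2_seq]))
        for r in frame.itertuples()
    }


def toy_matrix(genotypes, populations, labels=None, loci=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from nested per-individual genotype lists.

    ``genotypes``: list over individuals of list over loci of (a1, a2) index
    pairs or None for missing.
    """
    n = len(genotypes)
    L = len(genotypes[0])
    loci = loci or [f"L{i + 1}" for i in range(L)]
    alle = np.full((n, L, 2), mp.MISSING, dtype=np.int64)
    for i, row in enumerate(genotypes):
        for l, pair in enumerate(row):
            if pair is not None:
                alle[i, l] = pair
    if labels is None:
        labels = {}
        for l, locus in enumerate(loci):
            k = int(max(alle[:, l, :].max(), 0)) + 1
            labels[locus] = list(range(1, k + 1))
    return GenotypeMatrix(
        individuals=[f"i{i}" for i in range(n)],
        populations=list(populations),
        loci=loci,
        alleles=alle,
        allele_labels=labels,
    )
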