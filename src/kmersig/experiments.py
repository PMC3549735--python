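"""Canned benchmark experiments: self-dissimilarity, independence limit,
gradient recovery and group recovery, all driven by a single seed.

These wire the simulators, measures and evaluation steps together the same
way the CLI does, and are what the acceptance harness runs.
"""

from __future__ import annotations

import numpy as np

from .background import fit_markov
from .beta_eval import gradient_pcc, parsimony_test, pcoa, upgma
from .community_sim import (
    CommunitySpec,
    SIM1_GROUP_CENTERS,
    gradient_design,
    group_design,
    iid_reads,
    sample_reads,
    synth_genomes,
)
from .measures import MeasureSpec, d2s, d2star, dissimilarity_matrix
from .signatures import count_kmers, supplement_complements

__all__ = [
    "self_dissimilarity",
    "independence_mean_d2s",
    "gradient_recovery",
    "group_recovery",
]


def self_dissimilarity(
    seed: int, k_values: tuple[int, ...] = (5,), n_reads: int = 1000, read_length: int = 200
) -> dict[int, tuple[float, float]]:
    """(d2S|M0, d2*|M0) between one i.i.d. sample and itself, per k."""
    rs = supplement_complements(iid_reads(n_reads, read_length, np.random.default_rng(seed)))
    bg = fit_markov(rs, 0)
    out = {}
    for k in k_values:
        cv = count_kmers(rs, k)
        out[k] = (d2s(cv, cv, bg, bg), d2star(cv, cv, bg, bg))
    return out


def independence_mean_d2s(
    seed: int, n_pairs: int = 50, depth: int = 10_000, read_length: int = 200, k: int = 5
) -> float:
    """Mean d2S|M0 over independent pairs drawn from one uniform i.i.d.
    source; approaches 0.5 as depth grows."""
    vals = []
    for pair in range(n_pairs):
        rng = np.random.default_rng([seed, pair])
        a = supplement_complements(iid_reads(depth, read_length, rng))
        b = supplement_complements(iid_reads(depth, read_length, rng))
        ca, cb = count_kmers(a, k), count_kmers(b, k)
        vals.append(d2s(ca, cb, fit_markov(a, 0), fit_markov(b, 0)))
    return float(np.mean(vals))


def gradient_recovery(
    seed: int,
    n_replicates: int = 10,
    depth: int = 10_000,
    read_length: int = 200,
    k: int = 5,
    genome_length: int = 1_000_000,
    distinctness: float = 0.7,
    n_samples: int = 20,
    sigma: float = 4.0,
) -> list[float]:
    """Per-replicate |PCC| between PCoA PC1 and the gradient axis for the
    five-genome Gaussian-bump gradient design with d2S|M0.

    ``sigma`` widens the abundance bumps relative to the sampling default
    so the composition path is smooth enough for PC1 to track the gradient
    rather than splitting it across axes."""
    spec = MeasureSpec("d2S", k, 0)
    out = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        pool = synth_genomes(5, genome_length, distinctness, rng)
        graded = gradient_design(n_samples, mode="bump5", seed=rng, sigma=sigma)
        cspec = CommunitySpec(
            pool=pool,
            profiles=[p for p, _ in graded],
            depth=depth,
            read_length=read_length,
            seed=int(rng.integers(1 << 31)),
        )
        samples = [sample_reads(cspec, i) for i in range(n_samples)]
        dm = dissimilarity_matrix(samples, spec)
        pcc = gradient_pcc(pcoa(dm), [v for _, v in graded])
        out.append(pcc)
    return out


def group_recovery(
    seed: int,
    n_replicates: int = 20,
    per_group: int = 10,
    depth: int = 10_000,
    read_length: int = 200,
    k: int = 5,
    genome_length: int = 1_000_000,
    distinctness: float = 0.7,
    n_perm: int = 1000,
) -> list[float]:
    """Per-replicate Monte Carlo parsimony p-values for the three-group
    five-genome design clustered by UPGMA on d2S|M0.

    Group centers are the fixed published realization of the multiplicative
    perturbation (SIM1_GROUP_CENTERS); members redraw additive noise per
    replicate."""
    spec = MeasureSpec("d2S", k, 0)
    out = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        pool = synth_genomes(5, genome_length, distinctness, rng)
        labeled = group_design(3, per_group, fixed_centers=SIM1_GROUP_CENTERS, seed=rng)
        cspec = CommunitySpec(
            pool=pool,
            profiles=[p for p, _ in labeled],
            depth=depth,
            read_length=read_length,
            seed=int(rng.integers(1 << 31)),
        )
        samples = [sample_reads(cspec, i) for i in range(len(labeled))]
        dm = dissimilarity_matrix(samples, spec)
        tree = upgma(dm)
        labels = {s.sample_id: g for s, (_, g) in zip(samples, labeled)}
        res = parsimony_test(tree, labels, n_perm=n_perm, seed=rng)
        out.append(res.p_value)
    return out
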