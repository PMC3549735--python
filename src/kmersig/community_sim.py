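"""Synthetic community and read-set generation.

Stands in for a platform-specific read simulator: genomes are synthetic
order-1 Markov sequences (a FASTA loader accepts real genomes instead),
abundance profiles follow the group / gradient / Zipf designs, and reads
are sampled error-free from either strand.  Four canned designs are
provided:

  sim1 -- 90 samples, 3 groups, 5 genomes; group centers are
          multiplicative perturbations of a base profile, members are
          additive half-normal perturbations of their center.
  sim2 -- 20 samples, 5 genomes; 4 species follow Gaussian bumps centered
          at sample indexes 0, 5, 10, 15 while one stays constant, giving
          a built-in gradient axis.
  sim3 -- 60 samples, 3 groups, 113 genomes; each group center is a Zipf
          profile (alpha = 0.3) over a random genome ordering.
  sim4 -- 20 samples, 113 genomes; Zipf profiles with alpha running
          0.275 .. 0.750 in steps of 0.025 as the gradient axis.

All randomness flows through numpy Generators seeded from the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .signatures import ReadSet, reverse_complement

__all__ = [
    "GenomePool",
    "AbundanceProfile",
    "CommunitySpec",
    "synth_genomes",
    "load_genomes",
    "zipf_profile",
    "perturb_multiplicative",
    "perturb_additive",
    "group_design",
    "gradient_design",
    "sample_reads",
    "iid_reads",
    "simulate_design",
    "write_fasta",
]

SIM1_BASE_PROFILE = (0.05, 0.10, 0.20, 0.25, 0.40)
# one published realization of the three multiplicative center perturbations
# of the base profile; usable as fixed, well-separated group centers
SIM1_GROUP_CENTERS = (
    (0.022, 0.058, 0.116, 0.507, 0.297),
    (0.042, 0.088, 0.281, 0.244, 0.345),
    (0.046, 0.066, 0.042, 0.320, 0.526),
)
ZIPF_ALPHA = 0.3
ZIPF_N = 113
READ_LENGTH = 200
_BASES = b"ACGT"


@dataclass
class GenomePool:
    genomes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for gid, seq in self.genomes:
            if not seq:
                raise ValueError(f"genome {gid!r} is empty")

    @property
    def lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.genomes]

    def __len__(self) -> int:
        return len(self.genomes)


@dataclass
class AbundanceProfile:
    """Relative abundances over the genomes of a pool (a simplex vector)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValueError("abundances must be non-negative")
        total = self.values.sum()
        if not np.isclose(total, 1.0, rtol=0, atol=1e-9):
            raise ValueError(f"abundances must sum to 1, got {total}")


@dataclass
class CommunitySpec:
    pool: GenomePool
    profiles: list[AbundanceProfile]
    depth: int
    read_length: int
    seed: int

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for p in self.profiles:
            if p.values.size != len(self.pool):
                raise ValueError("profile length does not match pool size")


def _markov_sequence(transitions: np.ndarray, length: int, rng: np.random.Generator) -> str:
    """Sample an order-1 chain; tight scalar loop for speed at Mb scale."""
    cum = np.cumsum(transitions, axis=1)
    cum[:, -1] = 1.0 + 1e-12
    rows = cum.tolist()
    u = rng.random(length).tolist()
    out = bytearray(length)
    state = int(rng.integers(4))
    bases = _BASES
    for i, x in enumerate(u):
        row = rows[state]
        state = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
        out[i] = bases[state]
    return out.decode("ascii")


def synth_genomes(
    n: int,
    length: int,
    distinctness: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> GenomePool:
    """Generate n genomes, each from its own order-1 Markov source.

    Each genome's transition matrix is a (1 - distinctness) : distinctness
    blend of the uniform matrix with an independent Dirichlet(1,1,1,1) draw
    per row; distinctness = 0 gives i.i.d. uniform genomes.
    """
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    if not 0.0 <= distinctness <= 1.0:
        raise ValueError("distinctness must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genomes = []
    for g in range(n):
        rand_rows = rng.dirichlet(np.ones(4), size=4)
        T = (1.0 - distinctness) * 0.25 + distinctness * rand_rows
        genomes.append((f"genome{g + 1}", _markov_sequence(T, length, rng)))
    return GenomePool(genomes=genomes)


def load_genomes(paths: Sequence[str | Path]) -> GenomePool:
    """Load user-supplied genomes (one FASTA per genome, records concatenated)."""
    from Bio import SeqIO

    genomes = []
    for path in paths:
        path = Path(path)
        seq = "".join(str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta"))
        genomes.append((path.stem, seq))
    return GenomePool(genomes=genomes)


def zipf_profile(alpha: float, N: int) -> AbundanceProfile:
    """Power-law profile: values_k = k**-alpha / sum_{n=1..N} n**-alpha."""
    if N < 1:
        raise ValueError("N must be >= 1")
    ranks = np.arange(1, N + 1, dtype=np.float64)
    weights = ranks**-alpha
    return AbundanceProfile(values=weights / weights.sum())


def perturb_multiplicative(p: AbundanceProfile, rng: int | np.random.Generator) -> AbundanceProfile:
    """Multiply each component by |Normal(1, component)| and renormalize."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    v = p.values * np.abs(rng.normal(1.0, p.values))
    return AbundanceProfile(values=v / v.sum())


def perturb_additive(p: AbundanceProfile, rng: int | np.random.Generator) -> AbundanceProfile:
    """Add |Normal(0, component)| to each component and renormalize; zero
    components stay zero."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    v = p.values + np.abs(rng.normal(0.0, p.values))
    return AbundanceProfile(values=v / v.sum())


def group_design(
    centers: int,
    per_group: int,
    base: AbundanceProfile | None = None,
    mode: str = "perturb",
    n_genomes: int = ZIPF_N,
    alpha: float = ZIPF_ALPHA,
    seed: int | np.random.Generator = 0,
    fixed_centers: Sequence[Sequence[float]] | None = None,
) -> list[tuple[AbundanceProfile, str]]:
    """Labeled grouped profiles.

    mode='perturb': centers are multiplicative perturbations of ``base``
    (which defaults to the 5-species base profile).  mode='zipf': each
    center assigns a Zipf(alpha, n_genomes) profile to a random genome
    ordering.  ``fixed_centers`` bypasses center drawing entirely (e.g. to
    reuse one published center realization).  Members are additive
    perturbations of their center.
    """
    if centers < 2:
        raise ValueError("need at least 2 group centers")
    if fixed_centers is not None and len(fixed_centers) != centers:
        raise ValueError("fixed_centers length must equal the number of centers")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[tuple[AbundanceProfile, str]] = []
    for c in range(centers):
        if fixed_centers is not None:
            vals = np.asarray(fixed_centers[c], dtype=np.float64)
            center = AbundanceProfile(values=vals / vals.sum())
        elif mode == "perturb":
            center = perturb_multiplicative(base or AbundanceProfile(np.array(SIM1_BASE_PROFILE)), rng)
        elif mode == "zipf":
            order = rng.permutation(n_genomes)
            vals = np.empty(n_genomes)
            vals[order] = zipf_profile(alpha, n_genomes).values
            center = AbundanceProfile(values=vals)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        label = f"G{c + 1}"
        for _ in range(per_group):
            out.append((perturb_additive(center, rng), label))
    return out


def gradient_design(
    n_samples: int = 20,
    mode: str = "bump5",
    seed: int | np.random.Generator = 0,
    sigma: float = 2.5,
    constant_level: float = 0.5,
    bump_centers: Sequence[float] = (0.0, 5.0, 10.0, 15.0),
    alpha_start: float = 0.275,
    alpha_step: float = 0.025,
    n_genomes: int = ZIPF_N,
) -> list[tuple[AbundanceProfile, float]]:
    """Profiles shifting along a gradient axis.

    mode='bump5': species 1 constant, species 2-5 Gaussian bumps over the
    sample index; gradient value = sample index.  mode='zipf_alpha': Zipf
    profiles with alpha_i = alpha_start + alpha_step * i; gradient value =
    alpha_i.  Additive half-normal noise is applied in both modes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[tuple[AbundanceProfile, float]] = []
    for i in range(n_samples):
        if mode == "bump5":
            bumps = np.exp(-((i - np.asarray(bump_centers)) ** 2) / (2.0 * sigma**2))
            raw = np.concatenate([[constant_level], bumps])
            profile = AbundanceProfile(values=raw / raw.sum())
            grad = float(i)
        elif mode == "zipf_alpha":
            alpha_i = alpha_start + alpha_step * i
            profile = zipf_profile(alpha_i, n_genomes)
            grad = alpha_i
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out.append((perturb_additive(profile, rng), grad))
    return out


def sample_reads(spec: CommunitySpec, sample_index: int) -> ReadSet:
    """Draw one sample's reads: genome by abundance, strand and start
    uniform, error-free substring of the chosen strand."""
    if not 0 <= sample_index < len(spec.profiles):
        raise ValueError("sample_index out of range")
    L = spec.read_length
    if L > min(spec.pool.lengths):
        raise ValueError("read_length exceeds the shortest genome")
    rng = np.random.default_rng([spec.seed, sample_index])
    profile = spec.profiles[sample_index].values
    genome_idx = rng.choice(len(spec.pool), size=spec.depth, p=profile)
    strands = rng.integers(2, size=spec.depth)
    u = rng.random(spec.depth)
    reads: list[str] = []
    seqs = [seq for _, seq in spec.pool.genomes]
    for g, strand, x in zip(genome_idx, strands, u):
        seq = seqs[g]
        start = int(x * (len(seq) - L + 1))
        frag = seq[start : start + L]
        reads.append(reverse_complement(frag) if strand else frag)
    return ReadSet(sample_id=f"S{sample_index + 1}", reads=reads)


def iid_reads(
    n_reads: int,
    length: int,
    rng: int | np.random.Generator,
    probs: Sequence[float] | None = None,
    sample_id: str = "iid",
) -> ReadSet:
    """Reads drawn i.i.d. per base (uniform by default); handy for nulls."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    codes = rng.choice(4, size=(n_reads, length), p=probs)
    lut = np.frombuffer(_BASES, dtype=np.uint8)
    rows = lut[codes]
    reads = [row.tobytes().decode("ascii") for row in rows]
    return ReadSet(sample_id=sample_id, reads=reads)


def simulate_design(
    design: str,
    depth: int,
    seed: int,
    read_length: int = READ_LENGTH,
    genome_length: int = 1_000_000,
    distinctness: float = 0.5,
    pool: GenomePool | None = None,
) -> tuple[CommunitySpec, list[dict]]:
    """Build one of the four canned designs.

    Returns the CommunitySpec plus one metadata dict per sample (sample id,
    group label or gradient value, profile).  Pass ``pool`` to reuse real
    or pre-built genomes instead of synthesizing new ones.
    """
    design_ids = {"sim1": 1, "sim2": 2, "sim3": 3, "sim4": 4}
    if design not in design_ids:
        raise ValueError(f"unknown design {design!r}; choose sim1..sim4")
    rng = np.random.default_rng([seed, design_ids[design]])
    n_genomes = 5 if design in ("sim1", "sim2") else ZIPF_N
    if pool is None:
        pool = synth_genomes(n_genomes, genome_length, distinctness, rng)
    elif len(pool) != n_genomes:
        raise ValueError(f"{design} needs exactly {n_genomes} genomes, got {len(pool)}")

    meta: list[dict] = []
    if design == "sim1":
        labeled = group_design(3, 30, mode="perturb", seed=rng)
        profiles = [p for p, _ in labeled]
        meta = [{"group": g} for _, g in labeled]
    elif design == "sim2":
        graded = gradient_design(20, mode="bump5", seed=rng)
        profiles = [p for p, _ in graded]
        meta = [{"gradient": v} for _, v in graded]
    elif design == "sim3":
        labeled = group_design(3, 20, mode="zipf", n_genomes=ZIPF_N, alpha=ZIPF_ALPHA, seed=rng)
        profiles = [p for p, _ in labeled]
        meta = [{"group": g} for _, g in labeled]
    else:  # sim4
        graded = gradient_design(20, mode="zipf_alpha", seed=rng, n_genomes=ZIPF_N)
        profiles = [p for p, _ in graded]
        meta = [{"gradient": v} for _, v in graded]

    spec = CommunitySpec(pool=pool, profiles=profiles, depth=depth, read_length=read_length, seed=seed)
    for i, m in enumerate(meta):
        m["sample_id"] = f"S{i + 1}"
        m["profile"] = spec.profiles[i].values.tolist()
    return spec, meta


def write_fasta(rs: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(rs.reads):
            fh.write(f">{rs.sample_id}_r{i + 1}\n{read}\n")
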