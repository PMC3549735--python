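"""Pairwise dissimilarity measures between sample signatures.

Fourteen measures are supported: d2 on raw counts; d2S and d2* on
centralized counts under Markov backgrounds of orders 0-3 (eight
configurations); Manhattan / Euclidean / Chebyshev on frequency vectors;
the Hao (composition vector) correlation distance with an order k-2
background; and the Willner relative-abundance odds-ratio measures for
k = 2, 3, 4.

Centralized counts are c~_i = c_i - n * p_i with p_i the tuple probability
under the sample's own background model.  d2-type measures are cosine-like:
0 for identical samples, 0.5 in expectation for independent same-source
samples, up to 1 for anti-correlated enrichment.

Zero handling: 0/0 terms in D2S, and tuples with zero expected frequency
in d2*, Hao or a Willner denominator, are skipped (they contribute
nothing); skip totals are logged at DEBUG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .background import MarkovBackground, expected_frequencies, fit_markov
from .signatures import (
    KmerCountVector,
    KmerFrequencyVector,
    ReadSet,
    count_kmers,
    count_pattern,
    supplement_complements,
    to_frequencies,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MeasureSpec",
    "DissimilarityMatrix",
    "MEASURE_NAMES",
    "roster",
    "d2",
    "d2s",
    "d2star",
    "centralize",
    "lp_distances",
    "hao",
    "willner",
    "odds_ratios",
    "dissimilarity",
    "dissimilarity_matrix",
]

MEASURE_NAMES = ("d2", "d2S", "d2star", "Ma", "Eu", "Ch", "Hao", "Willner")
_NEEDS_ORDER = ("d2S", "d2star")


@dataclass(frozen=True)
class MeasureSpec:
    """One measure/k/background-order configuration.

    ``markov_order`` applies only to d2S and d2star (0-3); Hao always uses
    order k-2 and the remaining measures use no background.
    """

    name: str
    k: int
    markov_order: int | None = None

    def __post_init__(self) -> None:
        if self.name not in MEASURE_NAMES:
            raise ValueError(f"unknown measure {self.name!r}; choose from {MEASURE_NAMES}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.name in _NEEDS_ORDER:
            if self.markov_order is None or not 0 <= self.markov_order <= 3:
                raise ValueError(f"{self.name} requires markov_order in 0..3")
            if self.k < self.markov_order + 1:
                raise ValueError(f"{self.name} requires k >= markov_order + 1")
        elif self.markov_order is not None:
            raise ValueError(f"{self.name} does not take a markov_order")
        if self.name == "Willner" and self.k not in (2, 3, 4):
            raise ValueError("Willner is only defined for k in {2, 3, 4}")
        if self.name == "Hao" and self.k < 2:
            raise ValueError("Hao requires k >= 2 (background order k-2 >= 0)")

    @property
    def label(self) -> str:
        if self.name in _NEEDS_ORDER:
            return f"{self.name}|M{self.markov_order}"
        return self.name


def roster(k: int) -> list[MeasureSpec]:
    """The fixed 14-measure roster at tuple size k (Willner included only
    when defined, i.e. k in {2, 3, 4})."""
    specs = [MeasureSpec("d2", k)]
    for order in range(4):
        if k >= order + 1:
            specs.append(MeasureSpec("d2S", k, order))
    for order in range(4):
        if k >= order + 1:
            specs.append(MeasureSpec("d2star", k, order))
    specs += [MeasureSpec("Ma", k), MeasureSpec("Eu", k), MeasureSpec("Ch", k)]
    if k >= 2:
        specs.append(MeasureSpec("Hao", k))
    if k in (2, 3, 4):
        specs.append(MeasureSpec("Willner", k))
    return specs


@dataclass
class DissimilarityMatrix:
    sample_ids: list[str]
    D: np.ndarray
    spec: MeasureSpec

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=np.float64)
        n = len(self.sample_ids)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape does not match sample count")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#measure=%s\tk=%d\n" % (self.spec.label, self.spec.k))
            fh.write("\t".join(["sample"] + self.sample_ids) + "\n")
            for sid, row in zip(self.sample_ids, self.D):
                fh.write(sid + "\t" + "\t".join(f"{x:.12g}" for x in row) + "\n")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.sample_ids)}\n")
            for sid, row in zip(self.sample_ids, self.D):
                fh.write(sid + "  " + "  ".join(f"{x:.12g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, spec: MeasureSpec | None = None) -> "DissimilarityMatrix":
        ids: list[str] = []
        rows: list[list[float]] = []
        meta = {"measure": "Eu", "k": 2}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for part in line[1:].split("\t"):
                        key, _, val = part.partition("=")
                        meta[key] = val
                    continue
                parts = line.split("\t")
                if parts[0] == "sample":
                    continue
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if spec is None:
            name, _, order = str(meta["measure"]).partition("|M")
            spec = MeasureSpec(name, int(meta["k"]), int(order) if order else None)
        return cls(sample_ids=ids, D=np.asarray(rows), spec=spec)


# ---------------------------------------------------------------------------
# d2-type measures


def _check_same_k(cX: KmerCountVector, cY: KmerCountVector) -> None:
    if cX.k != cY.k:
        raise ValueError(f"count vectors have different k ({cX.k} vs {cY.k})")
    if cX.n <= 0 or cY.n <= 0:
        raise ValueError("both samples must have n > 0")


def _check_same_order(bgX: MarkovBackground, bgY: MarkovBackground) -> None:
    if bgX.order != bgY.order:
        raise ValueError(f"backgrounds have different orders ({bgX.order} vs {bgY.order})")


def d2(cX: KmerCountVector, cY: KmerCountVector) -> float:
    _check_same_k(cX, cY)
    x = cX.counts.astype(np.float64)
    y = cY.counts.astype(np.float64)
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm count vector")
    return 0.5 * (1.0 - float(x @ y) / (nx * ny))


def centralize(cv: KmerCountVector, bg: MarkovBackground) -> np.ndarray:
    """c~_i = c_i - n * p_i under the sample's background model."""
    p = expected_frequencies(bg, cv.k)
    return cv.counts.astype(np.float64) - cv.n * p


def _d2s_from_centralized(ctX: np.ndarray, ctY: np.ndarray) -> float:
    denom = np.sqrt(ctX**2 + ctY**2)
    keep = denom > 0
    skipped = int((~keep).sum())
    if skipped:
        logger.debug("d2S: skipped %d tuples with 0/0 terms", skipped)
    if not keep.any():
        raise ValueError("degenerate signature: all centralized counts are zero")
    dx, dy, dd = ctX[keep], ctY[keep], denom[keep]
    num = float(np.sum(dx * dy / dd))
    nX = float(np.sum(dx**2 / dd))
    nY = float(np.sum(dy**2 / dd))
    if nX == 0 or nY == 0:
        raise ValueError("degenerate signature: all centralized counts are zero")
    return 0.5 * (1.0 - num / np.sqrt(nX * nY))


def d2s(
    cX: KmerCountVector,
    cY: KmerCountVector,
    bgX: MarkovBackground,
    bgY: MarkovBackground,
) -> float:
    _check_same_k(cX, cY)
    _check_same_order(bgX, bgY)
    return _d2s_from_centralized(centralize(cX, bgX), centralize(cY, bgY))


def d2star(
    cX: KmerCountVector,
    cY: KmerCountVector,
    bgX: MarkovBackground,
    bgY: MarkovBackground,
) -> float:
    _check_same_k(cX, cY)
    _check_same_order(bgX, bgY)
    eX = cX.n * expected_frequencies(bgX, cX.k)
    eY = cY.n * expected_frequencies(bgY, cY.k)
    keep = (eX > 0) & (eY > 0)
    skipped = int((~keep).sum())
    if skipped:
        logger.debug("d2*: skipped %d tuples with zero expectation", skipped)
    if not keep.any():
        raise ValueError("every tuple has zero expectation in one of the samples")
    ctX = (cX.counts.astype(np.float64) - eX)[keep]
    ctY = (cY.counts.astype(np.float64) - eY)[keep]
    eXk, eYk = eX[keep], eY[keep]
    num = float(np.sum(ctX * ctY / np.sqrt(eXk * eYk)))
    nX = float(np.sum(ctX**2 / eXk))
    nY = float(np.sum(ctY**2 / eYk))
    if nX == 0 or nY == 0:
        raise ValueError("degenerate signature: all centralized counts are zero")
    return 0.5 * (1.0 - num / np.sqrt(nX * nY))


# ---------------------------------------------------------------------------
# lp-norm measures on frequency vectors


def lp_distances(fX: KmerFrequencyVector, fY: KmerFrequencyVector) -> tuple[float, float, float]:
    """(Manhattan, Euclidean, Chebyshev) distances between frequency vectors."""
    if fX.k != fY.k:
        raise ValueError("frequency vectors have different k")
    diff = np.abs(fX.freqs - fY.freqs)
    return float(diff.sum()), float(np.sqrt(np.sum(diff**2))), float(diff.max())


# ---------------------------------------------------------------------------
# Hao (composition vector) measure


def hao(
    fX: KmerFrequencyVector,
    fY: KmerFrequencyVector,
    bgX: MarkovBackground,
    bgY: MarkovBackground,
) -> float:
    """Correlation distance (1 - C) / 2 of frequency deviations from an
    order k-2 background; tuples with zero expectation in either sample are
    skipped."""
    if fX.k != fY.k:
        raise ValueError("frequency vectors have different k")
    k = fX.k
    if bgX.order != k - 2 or bgY.order != k - 2:
        raise ValueError(f"Hao requires backgrounds of order exactly k-2 = {k - 2}")
    eX = expected_frequencies(bgX, k)
    eY = expected_frequencies(bgY, k)
    keep = (eX > 0) & (eY > 0)
    skipped = int((~keep).sum())
    if skipped:
        logger.debug("Hao: skipped %d tuples with zero expectation", skipped)
    if not keep.any():
        raise ValueError("every tuple has zero expectation in one of the samples")
    aX = fX.freqs[keep] / eX[keep] - 1.0
    aY = fY.freqs[keep] / eY[keep] - 1.0
    nX = np.linalg.norm(aX)
    nY = np.linalg.norm(aY)
    if nX == 0 or nY == 0:
        raise ValueError("zero-norm deviation vector")
    corr = float(aX @ aY) / (nX * nY)
    return 0.5 * (1.0 - corr)


# ---------------------------------------------------------------------------
# Willner odds-ratio measures

def _pattern_freq(rs: ReadSet, offsets: tuple[int, ...]) -> np.ndarray:
    counts, n = count_pattern(rs, offsets)
    if n == 0:
        raise ValueError(f"no valid windows of span {offsets[-1] + 1}")
    return counts / n


def odds_ratios(rs: ReadSet, k: int) -> np.ndarray:
    """Relative-abundance odds ratios for every word of length k in {2,3,4}.

    Returns a flat array over the 4**k words (lexicographic order); entries
    whose denominator involves a zero frequency are NaN.
    """
    if not rs.supplemented:
        raise ValueError("read set must be supplemented")
    with np.errstate(divide="ignore", invalid="ignore"):
        if k == 2:
            f1 = _pattern_freq(rs, (0,))
            f2 = _pattern_freq(rs, (0, 1)).reshape(4, 4)
            rho = f2 / (f1[:, None] * f1[None, :])
            return rho.ravel()
        if k == 3:
            f1 = _pattern_freq(rs, (0,))
            f2 = _pattern_freq(rs, (0, 1)).reshape(4, 4)
            f3 = _pattern_freq(rs, (0, 1, 2)).reshape(4, 4, 4)
            f_xnz = _pattern_freq(rs, (0, 2)).reshape(4, 4)
            num = f3 * f1[:, None, None] * f1[None, :, None] * f1[None, None, :]
            den = f2[:, :, None] * f2[None, :, :] * f_xnz[:, None, :]
            return (num / den).ravel()
        if k == 4:
            f1 = _pattern_freq(rs, (0,))
            f2 = _pattern_freq(rs, (0, 1)).reshape(4, 4)
            f3 = _pattern_freq(rs, (0, 1, 2)).reshape(4, 4, 4)
            f4 = _pattern_freq(rs, (0, 1, 2, 3)).reshape(4, 4, 4, 4)
            g1 = _pattern_freq(rs, (0, 2)).reshape(4, 4)  # X.Z over span 3
            g2 = _pattern_freq(rs, (0, 3)).reshape(4, 4)  # X..W over span 4
            t_xynw = _pattern_freq(rs, (0, 1, 3)).reshape(4, 4, 4)
            t_xnzw = _pattern_freq(rs, (0, 2, 3)).reshape(4, 4, 4)
            num = (
                f4
                * f2[:, :, None, None]  # f(XY)
                * g1[:, None, :, None]  # f(XNZ)
                * g2[:, None, None, :]  # f(XNMW)
                * f2[None, :, :, None]  # f(YZ)
                * g1[None, :, None, :]  # f(YNW)
                * f2[None, None, :, :]  # f(ZW)
            )
            den = (
                f3[:, :, :, None]  # f(XYZ)
                * t_xynw[:, :, None, :]  # f(XYNW)
                * t_xnzw[:, None, :, :]  # f(XNZW)
                * f3[None, :, :, :]  # f(YZW)
                * f1[:, None, None, None]
                * f1[None, :, None, None]
                * f1[None, None, :, None]
                * f1[None, None, None, :]
            )
            return (num / den).ravel()
    raise ValueError("Willner odds ratios are defined for k in {2, 3, 4} only")


def willner(rsX: ReadSet, rsY: ReadSet, k: int) -> float:
    """delta_k = 4**-k * sum over words of |odds_ratio_X - odds_ratio_Y|;
    words undefined (zero denominator) in either sample are skipped."""
    oX = odds_ratios(rsX, k)
    oY = odds_ratios(rsY, k)
    keep = np.isfinite(oX) & np.isfinite(oY)
    skipped = int((~keep).sum())
    if skipped:
        logger.warning("Willner k=%d: skipped %d words with zero denominator", k, skipped)
    return float(np.sum(np.abs(oX[keep] - oY[keep]))) / 4**k


# ---------------------------------------------------------------------------
# dispatch and matrix assembly


@dataclass
class _SampleBundle:
    """Per-sample quantities reused across pairwise comparisons."""

    rs: ReadSet
    counts: KmerCountVector
    freqs: KmerFrequencyVector | None = None
    backgrounds: dict[int, MarkovBackground] = field(default_factory=dict)
    ratios: np.ndarray | None = None

    @classmethod
    def build(cls, rs: ReadSet, spec: MeasureSpec) -> "_SampleBundle":
        if not rs.supplemented:
            rs = supplement_complements(rs)
        bundle = cls(rs=rs, counts=count_kmers(rs, spec.k))
        if spec.name in ("Ma", "Eu", "Ch", "Hao"):
            bundle.freqs = to_frequencies(bundle.counts)
        if spec.name in _NEEDS_ORDER:
            bundle.backgrounds[spec.markov_order] = fit_markov(rs, spec.markov_order)
        elif spec.name == "Hao":
            bundle.backgrounds[spec.k - 2] = fit_markov(rs, spec.k - 2)
        elif spec.name == "Willner":
            bundle.ratios = odds_ratios(rs, spec.k)
        return bundle


def _pair_dissimilarity(a: _SampleBundle, b: _SampleBundle, spec: MeasureSpec) -> float:
    if spec.name == "d2":
        return d2(a.counts, b.counts)
    if spec.name == "d2S":
        o = spec.markov_order
        return d2s(a.counts, b.counts, a.backgrounds[o], b.backgrounds[o])
    if spec.name == "d2star":
        o = spec.markov_order
        return d2star(a.counts, b.counts, a.backgrounds[o], b.backgrounds[o])
    if spec.name in ("Ma", "Eu", "Ch"):
        ma, eu, ch = lp_distances(a.freqs, b.freqs)
        return {"Ma": ma, "Eu": eu, "Ch": ch}[spec.name]
    if spec.name == "Hao":
        o = spec.k - 2
        return hao(a.freqs, b.freqs, a.backgrounds[o], b.backgrounds[o])
    if spec.name == "Willner":
        keep = np.isfinite(a.ratios) & np.isfinite(b.ratios)
        return float(np.sum(np.abs(a.ratios[keep] - b.ratios[keep]))) / 4**spec.k
    raise ValueError(f"unknown measure {spec.name!r}")


def dissimilarity(rsX: ReadSet, rsY: ReadSet, spec: MeasureSpec) -> float:
    """Compute one measure between two read sets, fitting backgrounds as
    needed.  Accepts supplemented or raw read sets (raw ones are
    supplemented on the fly)."""
    a = _SampleBundle.build(rsX, spec)
    b = _SampleBundle.build(rsY, spec)
    return _pair_dissimilarity(a, b, spec)


def dissimilarity_matrix(samples: list[ReadSet], spec: MeasureSpec) -> DissimilarityMatrix:
    """Symmetric all-pairs matrix; per-sample signatures and backgrounds are
    computed once and reused."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    bundles = [_SampleBundle.build(rs, spec) for rs in samples]
    n = len(bundles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                D[i, j] = D[j, i] = _pair_dissimilarity(bundles[i], bundles[j], spec)
            except ValueError as exc:
                raise ValueError(
                    f"failed for pair ({samples[i].sample_id}, {samples[j].sample_id}): {exc}"
                ) from exc
    return DissimilarityMatrix(sample_ids=[s.sample_id for s in samples], D=D, spec=spec)
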