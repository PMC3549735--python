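"""Markov background models for expected k-tuple frequencies.

An order-r model is estimated from a sample's supplemented reads: the
initial distribution is the observed frequency of each r-tuple over all
in-read windows (a stationary estimate, not read starts), and transition
probabilities come from (r+1)-tuple window counts.  Expected frequencies
are

    order 0:  E f(w1..wk) = prod_j p(wj)
    order r:  E f(w1..wk) = p(w1..wr) * prod_{j=1}^{k-r} p(w_{j+r} | w_j..w_{j+r-1})

Contexts never observed get zero transition mass (no pseudocounts by
default), so tuples through unseen contexts have expected frequency 0;
measure-level rules decide how zero expectations are handled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .signatures import ReadSet, count_kmers, kmer_to_index

__all__ = [
    "MarkovBackground",
    "ExpectedCounts",
    "fit_markov",
    "expected_frequency",
    "expected_frequencies",
    "expected_counts",
]


@dataclass
class MarkovBackground:
    """Fitted order-r Markov model over {A,C,G,T}.

    ``initial`` has length 4**order (a single cell of mass 1 for order 0)
    and ``transitions`` is a (4**order, 4) row-stochastic matrix (rows for
    unobserved contexts are all-zero); ``transitions`` is None for order 0,
    where ``base_probs`` plays that role.
    """

    order: int
    base_probs: np.ndarray
    initial: np.ndarray
    transitions: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "order": self.order,
            "base_probs": self.base_probs.tolist(),
            "initial": self.initial.tolist(),
            "transitions": None if self.transitions is None else self.transitions.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkovBackground":
        payload = json.loads(Path(path).read_text())
        trans = payload["transitions"]
        return cls(
            order=int(payload["order"]),
            base_probs=np.asarray(payload["base_probs"], dtype=np.float64),
            initial=np.asarray(payload["initial"], dtype=np.float64),
            transitions=None if trans is None else np.asarray(trans, dtype=np.float64),
        )


@dataclass
class ExpectedCounts:
    k: int
    expected: np.ndarray
    n: int


def fit_markov(rs: ReadSet, order: int, pseudocount: float = 0.0) -> MarkovBackground:
    """Estimate an order-r background from a supplemented read set.

    ``pseudocount`` is an optional additive smoothing constant applied to
    the (r+1)-tuple counts before normalization, for degenerate inputs.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if not rs.supplemented:
        raise ValueError("read set must be supplemented before fitting a background")
    base_cv = count_kmers(rs, 1)
    if base_cv.n == 0:
        raise ValueError("insufficient data for order 0: no valid bases")
    base = base_cv.counts.astype(np.float64) + pseudocount
    base_probs = base / base.sum()
    if order == 0:
        return MarkovBackground(order=0, base_probs=base_probs, initial=np.ones(1))

    high = count_kmers(rs, order + 1)
    if high.n == 0:
        raise ValueError(f"insufficient data for order {order}: no ({order + 1})-windows")
    joint = high.counts.astype(np.float64).reshape(4**order, 4) + pseudocount
    row_sums = joint.sum(axis=1)
    transitions = np.zeros_like(joint)
    seen = row_sums > 0
    transitions[seen] = joint[seen] / row_sums[seen, None]

    init_cv = count_kmers(rs, order)
    initial = init_cv.counts.astype(np.float64) + pseudocount
    initial /= initial.sum()
    return MarkovBackground(order=order, base_probs=base_probs, initial=initial, transitions=transitions)


def expected_frequency(bg: MarkovBackground, w: str) -> float:
    """Expected frequency of a single tuple string under the model."""
    codes = [kmer_to_index(ch) for ch in w]
    r = bg.order
    if r == 0:
        if len(codes) < 1:
            raise ValueError("tuple must be non-empty")
        return float(np.prod(bg.base_probs[codes]))
    if len(codes) < r + 1:
        raise ValueError(f"tuple length {len(codes)} < order {r} + 1")
    ctx = 0
    for c in codes[:r]:
        ctx = ctx * 4 + c
    p = float(bg.initial[ctx])
    mask = 4**r
    assert bg.transitions is not None
    for c in codes[r:]:
        p *= float(bg.transitions[ctx, c])
        ctx = (ctx * 4 + c) % mask
    return p


def expected_frequencies(bg: MarkovBackground, k: int) -> np.ndarray:
    """Expected frequencies of all 4**k tuples, in lexicographic index order."""
    r = bg.order
    if k < 1:
        raise ValueError("k must be >= 1")
    if r == 0:
        vec = bg.base_probs.copy()
        for _ in range(k - 1):
            vec = np.kron(vec, bg.base_probs)
        return vec
    assert bg.transitions is not None
    if k < r:
        # tuples shorter than the context: marginalize the initial r-tuple
        # distribution over its trailing letters
        return bg.initial.reshape(4**k, 4 ** (r - k)).sum(axis=1)
    vec = bg.initial.copy()
    ctx_dim = 4**r
    for _ in range(k - r):
        # context of a prefix is its last r letters = index mod 4**r
        ctx = np.arange(vec.size) % ctx_dim
        vec = (vec[:, None] * bg.transitions[ctx]).ravel()
    return vec


def expected_counts(bg: MarkovBackground, k: int, n: int) -> ExpectedCounts:
    if n < 0:
        raise ValueError("n must be >= 0")
    return ExpectedCounts(k=k, expected=n * expected_frequencies(bg, k), n=n)
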