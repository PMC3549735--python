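"""Independent brute-force reference implementations used as test oracles.

Everything here works on plain Python strings and dicts with explicit
loops, deliberately sharing no code with the package's vectorized paths.
"""

from __future__ import annotations

import itertools
import math

ALPHABET = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[ch] for ch in reversed(seq))


def all_words(k: int) -> list[str]:
    return ["".join(t) for t in itertools.product(ALPHABET, repeat=k)]


def naive_counts(reads: list[str], k: int) -> dict[str, int]:
    counts = {w: 0 for w in all_words(k)}
    for read in reads:
        for i in range(len(read) - k + 1):
            window = read[i : i + k]
            if all(ch in ALPHABET for ch in window):
                counts[window] += 1
    return counts


def naive_pattern_freqs(reads: list[str], offsets: tuple[int, ...]) -> dict[str, float]:
    span = offsets[-1] + 1
    counts: dict[str, int] = {}
    total = 0
    for read in reads:
        for i in range(len(read) - span + 1):
            window = read[i : i + span]
            if all(ch in ALPHABET for ch in window):
                word = "".join(window[o] for o in offsets)
                counts[word] = counts.get(word, 0) + 1
                total += 1
    return {w: c / total for w, c in counts.items()} if total else {}


# --- measures ---------------------------------------------------------------


def naive_d2(cx: dict[str, int], cy: dict[str, int]) -> float:
    words = sorted(cx)
    dot = sum(cx[w] * cy[w] for w in words)
    nx = math.sqrt(sum(cx[w] ** 2 for w in words))
    ny = math.sqrt(sum(cy[w] ** 2 for w in words))
    return 0.5 * (1 - dot / (nx * ny))


def naive_centralized(c: dict[str, int], p: dict[str, float]) -> dict[str, float]:
    n = sum(c.values())
    return {w: c[w] - n * p[w] for w in c}


def naive_d2s(ctx: dict[str, float], cty: dict[str, float]) -> float:
    num = sx = sy = 0.0
    for w in ctx:
        denom = math.sqrt(ctx[w] ** 2 + cty[w] ** 2)
        if denom == 0:
            continue
        num += ctx[w] * cty[w] / denom
        sx += ctx[w] ** 2 / denom
        sy += cty[w] ** 2 / denom
    return 0.5 * (1 - num / math.sqrt(sx * sy))


def naive_d2star(
    cx: dict[str, int], cy: dict[str, int], px: dict[str, float], py: dict[str, float]
) -> float:
    nx = sum(cx.values())
    ny = sum(cy.values())
    num = sx = sy = 0.0
    for w in cx:
        ex, ey = nx * px[w], ny * py[w]
        if ex == 0 or ey == 0:
            continue
        ctx, cty = cx[w] - ex, cy[w] - ey
        num += ctx * cty / math.sqrt(ex * ey)
        sx += ctx**2 / ex
        sy += cty**2 / ey
    return 0.5 * (1 - num / math.sqrt(sx * sy))


def naive_lp(fx: dict[str, float], fy: dict[str, float]) -> tuple[float, float, float]:
    diffs = [abs(fx[w] - fy[w]) for w in sorted(fx)]
    return sum(diffs), math.sqrt(sum(d**2 for d in diffs)), max(diffs)


def naive_hao(
    fx: dict[str, float], fy: dict[str, float], ex: dict[str, float], ey: dict[str, float]
) -> float:
    ax, ay = [], []
    for w in sorted(fx):
        if ex[w] == 0 or ey[w] == 0:
            continue
        ax.append(fx[w] / ex[w] - 1)
        ay.append(fy[w] / ey[w] - 1)
    dot = sum(a * b for a, b in zip(ax, ay))
    na = math.sqrt(sum(a * a for a in ax))
    nb = math.sqrt(sum(b * b for b in ay))
    return 0.5 * (1 - dot / (na * nb))


def naive_markov0_expected(reads: list[str], k: int) -> dict[str, float]:
    base = naive_counts(reads, 1)
    total = sum(base.values())
    p = {b: base[b] / total for b in ALPHABET}
    return {w: math.prod(p[ch] for ch in w) for w in all_words(k)}


def naive_markov_expected(reads: list[str], order: int, k: int) -> dict[str, float]:
    """Expected tuple frequencies under an order-r chain fitted by window
    counts; initial distribution from r-tuple window frequencies."""
    if order == 0:
        return naive_markov0_expected(reads, k)
    low = naive_counts(reads, order)
    n_low = sum(low.values())
    high = naive_counts(reads, order + 1)
    out = {}
    for w in all_words(k):
        p = low[w[:order]] / n_low
        for j in range(k - order):
            ctx = w[j : j + order]
            ctx_total = sum(high[ctx + b] for b in ALPHABET)
            if ctx_total == 0:
                p = 0.0
                break
            p *= high[ctx + w[j + order]] / ctx_total
        out[w] = p
    return out


def naive_odds_ratios(reads: list[str], k: int) -> dict[str, float]:
    f1 = naive_pattern_freqs(reads, (0,))
    get = lambda freqs, word: freqs.get(word, 0.0)
    out: dict[str, float] = {}
    if k == 2:
        f2 = naive_pattern_freqs(reads, (0, 1))
        for w in all_words(2):
            den = get(f1, w[0]) * get(f1, w[1])
            if den > 0:
                out[w] = get(f2, w) / den
    elif k == 3:
        f2 = naive_pattern_freqs(reads, (0, 1))
        f3 = naive_pattern_freqs(reads, (0, 1, 2))
        g = naive_pattern_freqs(reads, (0, 2))
        for w in all_words(3):
            x, y, z = w
            den = get(f2, x + y) * get(f2, y + z) * get(g, x + z)
            if den > 0:
                out[w] = get(f3, w) * get(f1, x) * get(f1, y) * get(f1, z) / den
    elif k == 4:
        f2 = naive_pattern_freqs(reads, (0, 1))
        f3 = naive_pattern_freqs(reads, (0, 1, 2))
        f4 = naive_pattern_freqs(reads, (0, 1, 2, 3))
        g1 = naive_pattern_freqs(reads, (0, 2))
        g2 = naive_pattern_freqs(reads, (0, 3))
        t_xynw = naive_pattern_freqs(reads, (0, 1, 3))
        t_xnzw = naive_pattern_freqs(reads, (0, 2, 3))
        for w in all_words(4):
            x, y, z, v = w
            num = (
                get(f4, w)
                * get(f2, x + y)
                * get(g1, x + z)
                * get(g2, x + v)
                * get(f2, y + z)
                * get(g1, y + v)
                * get(f2, z + v)
            )
            den = (
                get(f3, x + y + z)
                * get(t_xynw, x + y + v)
                * get(t_xnzw, x + z + v)
                * get(f3, y + z + v)
                * get(f1, x)
                * get(f1, y)
                * get(f1, z)
                * get(f1, v)
            )
            if den > 0:
                out[w] = num / den
    else:
        raise ValueError(k)
    return out


def naive_willner(reads_x: list[str], reads_y: list[str], k: int) -> float:
    ox = naive_odds_ratios(reads_x, k)
    oy = naive_odds_ratios(reads_y, k)
    common = set(ox) & set(oy)
    return sum(abs(ox[w] - oy[w]) for w in common) / 4**k


# --- trees ------------------------------------------------------------------


def naive_upgma_cophenetic(D) -> "list[list[float]]":
    """O(n^3) average linkage recomputing every cluster distance from the
    original matrix; returns the cophenetic distance matrix (2 * merge
    height between leaves)."""
    n = len(D)
    clusters = [[i] for i in range(n)]
    C = [[0.0] * n for _ in range(n)]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = sum(D[i][j] for i in clusters[a] for j in clusters[b]) / (
                    len(clusters[a]) * len(clusters[b])
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                C[i][j] = C[j][i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return C


def brute_force_parsimony(tree_root, labels: dict[str, str]) -> int:
    """Minimum label changes over all internal-state assignments.

    ``tree_root`` is a kmersig TreeNode; exponential enumeration, fine for
    <= 8 leaves.
    """
    states = sorted(set(labels.values()))
    internals: list = []

    def collect(node):
        if node.children is not None:
            internals.append(node)
            collect(node.children[0])
            collect(node.children[1])

    collect(tree_root)

    def cost(assignment: dict) -> int:
        total = 0
        for node in internals:
            for child in node.children:
                child_state = labels[child.name] if child.children is None else assignment[id(child)]
                if assignment[id(node)] != child_state:
                    total += 1
        return total

    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        assignment = {id(node): st for node, st in zip(internals, combo)}
        c = cost(assignment)
        if best is None or c < best:
            best = c
    return best
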