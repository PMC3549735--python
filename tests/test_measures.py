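import numpy as np
import pytest

from kmersig.background import MarkovBackground, fit_markov
from kmersig.measures import (
    MeasureSpec,
    d2,
    d2s,
    d2star,
    dissimilarity,
    dissimilarity_matrix,
    hao,
    lp_distances,
    odds_ratios,
    roster,
    willner,
)
from kmersig.measures import _d2s_from_centralized
from kmersig.signatures import (
    KmerCountVector,
    KmerFrequencyVector,
    ReadSet,
    count_kmers,
    kmer_strings,
    supplement_complements,
    to_frequencies,
)

from conftest import random_reads
from oracles import (
    naive_centralized,
    naive_counts,
    naive_d2,
    naive_d2s,
    naive_d2star,
    naive_hao,
    naive_lp,
    naive_markov_expected,
    naive_odds_ratios,
    naive_willner,
)


def uniform_m0():
    return MarkovBackground(order=0, base_probs=np.full(4, 0.25), initial=np.ones(1))


def cvec(k, values):
    arr = np.asarray(values, dtype=np.int64)
    return KmerCountVector(k, arr, int(arr.sum()))


class TestMeasureSpec:
    def test_valid_labels(self):
        assert MeasureSpec("d2S", 5, 0).label == "d2S|M0"
        assert MeasureSpec("Ma", 4).label == "Ma"

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(name="bogus", k=3),
            dict(name="Willner", k=5),
            dict(name="Hao", k=1),
            dict(name="d2S", k=3, markov_order=None),
            dict(name="d2S", k=3, markov_order=4),
            dict(name="d2S", k=2, markov_order=2),
            dict(name="Ma", k=3, markov_order=1),
        ],
    )
    def test_invalid_specs(self, kwargs):
        with pytest.raises(ValueError):
            MeasureSpec(**kwargs)

    def test_roster_is_14_measures_at_small_k(self):
        # d2 + 4x d2S + 4x d2star + Ma + Eu + Ch + Hao + Willner
        assert len(roster(4)) == 14
        assert len(roster(5)) == 13  # Willner undefined at k=5


class TestD2:
    def test_identity(self, rng):
        c = cvec(1, rng.integers(1, 50, size=4))
        assert d2(c, c) == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_support(self):
        assert d2(cvec(1, [2, 0, 0, 0]), cvec(1, [0, 3, 0, 0])) == pytest.approx(0.5)

    def test_hand_cosine(self):
        got = d2(cvec(1, [2, 0, 0, 0]), cvec(1, [1, 1, 0, 0]))
        assert got == pytest.approx(0.5 * (1 - 2 / (2 * np.sqrt(2))))

    def test_zero_norm_errors(self):
        with pytest.raises(ValueError):
            d2(cvec(1, [0, 0, 0, 0]), cvec(1, [1, 0, 0, 0]))


class TestD2S:
    def test_identical_samples_zero(self, rng):
        rs = supplement_complements(random_reads(rng, n_reads=30, max_len=50))
        c = count_kmers(rs, 4)
        bg = fit_markov(rs, 0)
        assert d2s(c, c, bg, bg) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_enrichment_is_one(self):
        a = 10.0
        ctX = np.array([a, -a, 0, 0])
        ctY = np.array([-a, a, 0, 0])
        assert _d2s_from_centralized(ctX, ctY) == pytest.approx(1.0)

    def test_degenerate_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            _d2s_from_centralized(np.zeros(4), np.zeros(4))

    def test_mismatched_orders_error(self, sample_pair):
        a, b = sample_pair
        ca, cb = count_kmers(a, 3), count_kmers(b, 3)
        with pytest.raises(ValueError, match="orders"):
            d2s(ca, cb, fit_markov(a, 0), fit_markov(b, 1))


class TestD2Star:
    def test_identical_samples_zero(self, rng):
        rs = supplement_complements(random_reads(rng, n_reads=30, max_len=50))
        c = count_kmers(rs, 4)
        bg = fit_markov(rs, 1)
        assert d2star(c, c, bg, bg) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluation(self):
        # uniform p, n=100: expected 25/cell; counts 35,15,25,25 -> ct (10,-10,0,0)
        bg = uniform_m0()
        c = cvec(1, [35, 15, 25, 25])
        # self comparison with identical centralized vectors: D2* = 8, norms sqrt(8) each
        assert d2star(c, c, bg, bg) == pytest.approx(0.0, abs=1e-14)

    def test_skips_zero_expectation(self):
        bg = MarkovBackground(order=0, base_probs=np.array([0.5, 0.5, 0, 0]), initial=np.ones(1))
        cX = cvec(1, [30, 20, 5, 0])  # G has p=0 -> skipped
        cY = cvec(1, [20, 30, 0, 5])
        val = d2star(cX, cY, bg, bg)
        assert 0.0 <= val <= 1.0


class TestLp:
    def test_identity(self):
        f = KmerFrequencyVector(1, np.array([0.25] * 4))
        assert lp_distances(f, f) == (0.0, 0.0, 0.0)

    def test_disjoint_point_masses(self):
        fx = KmerFrequencyVector(1, np.array([1.0, 0, 0, 0]))
        fy = KmerFrequencyVector(1, np.array([0, 1.0, 0, 0]))
        ma, eu, ch = lp_distances(fx, fy)
        assert (ma, ch) == (2.0, 1.0)
        assert eu == pytest.approx(np.sqrt(2))

    def test_hand_arithmetic(self):
        fx = KmerFrequencyVector(1, np.array([0.5, 0.5, 0, 0]))
        fy = KmerFrequencyVector(1, np.array([0.25] * 4))
        ma, eu, ch = lp_distances(fx, fy)
        assert ma == pytest.approx(1.0)
        assert eu == pytest.approx(0.5)
        assert ch == pytest.approx(0.25)


class TestHao:
    def test_identical_samples_zero(self, rng):
        rs = supplement_complements(random_reads(rng, n_reads=40, max_len=60, min_len=30))
        f = to_frequencies(count_kmers(rs, 3))
        bg = fit_markov(rs, 1)
        assert hao(f, f, bg, bg) == pytest.approx(0.0, abs=1e-12)

    def test_wrong_order_errors(self, rng):
        rs = supplement_complements(random_reads(rng, n_reads=20, max_len=40))
        f = to_frequencies(count_kmers(rs, 3))
        with pytest.raises(ValueError, match="k-2"):
            hao(f, f, fit_markov(rs, 0), fit_markov(rs, 0))

    def test_anticorrelation_is_one(self):
        # engineered frequency/expectation pairs giving aX = -aY
        bg = uniform_m0()
        ex = 1 / 16
        fx = KmerFrequencyVector(2, np.full(16, ex) * np.concatenate([np.full(8, 1.5), np.full(8, 0.5)]))
        fy = KmerFrequencyVector(2, np.full(16, ex) * np.concatenate([np.full(8, 0.5), np.full(8, 1.5)]))
        assert hao(fx, fy, bg, bg) == pytest.approx(1.0)

    def test_orthogonal_is_half(self):
        bg = uniform_m0()
        base = np.full(16, 1 / 16)
        mult_x = np.concatenate([[2.0, 1.0, 0.0, 1.0], np.ones(12)])
        mult_y = np.concatenate([[2.0, 1.0, 2.0, 1.0], np.ones(12)])
        fx = KmerFrequencyVector(2, base * mult_x)
        fy = KmerFrequencyVector(2, base * mult_y)
        # aX = (1,0,-1,0,...), aY = (1,0,1,0,...) -> C = 0 -> 0.5
        assert hao(fx, fy, bg, bg) == pytest.approx(0.5)


class TestWillner:
    def test_identical_samples_zero(self, rng):
        rs = supplement_complements(random_reads(rng, n_reads=30, max_len=60, min_len=20))
        for k in (2, 3, 4):
            assert willner(rs, rs, k) == pytest.approx(0.0, abs=1e-14)

    def test_iid_uniform_ratios_approach_one(self):
        rng = np.random.default_rng(11)
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, size=1_000_000))
        rs = ReadSet("s", [seq], supplemented=True)
        rho = odds_ratios(rs, 2)
        assert np.abs(rho - 1.0).max() < 0.01

    def test_single_term_toy(self):
        # delta2 = |rho_X - rho_Y| summed / 16; construct one word off by 1
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, size=200_000))
        rs = ReadSet("s", [seq], supplemented=True)
        oX = odds_ratios(rs, 2)
        oY = oX.copy()
        oY[0] += 1.0
        assert np.sum(np.abs(oX - oY)) / 16 == pytest.approx(1 / 16)

    def test_undefined_k_errors(self, sample_pair):
        a, b = sample_pair
        with pytest.raises(ValueError):
            willner(a, b, 5)


class TestOracleEquivalence:
    """Every formula vs the independent naive implementation, <= 1e-12."""

    def test_d2(self, sample_pair):
        a, b = sample_pair
        for k in (1, 2, 3):
            got = d2(count_kmers(a, k), count_kmers(b, k))
            want = naive_d2(naive_counts(a.reads, k), naive_counts(b.reads, k))
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("order", [0, 1])
    def test_d2s(self, sample_pair, order):
        a, b = sample_pair
        for k in (2, 3):
            ca, cb = count_kmers(a, k), count_kmers(b, k)
            got = d2s(ca, cb, fit_markov(a, order), fit_markov(b, order))
            pa = naive_markov_expected(a.reads, order, k)
            pb = naive_markov_expected(b.reads, order, k)
            want = naive_d2s(
                naive_centralized(naive_counts(a.reads, k), pa),
                naive_centralized(naive_counts(b.reads, k), pb),
            )
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("order", [0, 1])
    def test_d2star(self, sample_pair, order):
        a, b = sample_pair
        for k in (2, 3):
            ca, cb = count_kmers(a, k), count_kmers(b, k)
            got = d2star(ca, cb, fit_markov(a, order), fit_markov(b, order))
            want = naive_d2star(
                naive_counts(a.reads, k),
                naive_counts(b.reads, k),
                naive_markov_expected(a.reads, order, k),
                naive_markov_expected(b.reads, order, k),
            )
            assert got == pytest.approx(want, abs=1e-12)

    def test_lp(self, sample_pair):
        a, b = sample_pair
        for k in (1, 2, 3):
            fa = to_frequencies(count_kmers(a, k))
            fb = to_frequencies(count_kmers(b, k))
            got = lp_distances(fa, fb)
            n_a = {w: c for w, c in naive_counts(a.reads, k).items()}
            tot_a = sum(n_a.values())
            n_b = {w: c for w, c in naive_counts(b.reads, k).items()}
            tot_b = sum(n_b.values())
            want = naive_lp({w: c / tot_a for w, c in n_a.items()}, {w: c / tot_b for w, c in n_b.items()})
            for g, w in zip(got, want):
                assert g == pytest.approx(w, abs=1e-12)

    def test_hao(self, sample_pair):
        a, b = sample_pair
        k = 3
        fa = to_frequencies(count_kmers(a, k))
        fb = to_frequencies(count_kmers(b, k))
        got = hao(fa, fb, fit_markov(a, k - 2), fit_markov(b, k - 2))
        ca = naive_counts(a.reads, k)
        cb = naive_counts(b.reads, k)
        want = naive_hao(
            {w: c / sum(ca.values()) for w, c in ca.items()},
            {w: c / sum(cb.values()) for w, c in cb.items()},
            naive_markov_expected(a.reads, k - 2, k),
            naive_markov_expected(b.reads, k - 2, k),
        )
        assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_willner(self, sample_pair, k):
        a, b = sample_pair
        got = willner(a, b, k)
        want = naive_willner(a.reads, b.reads, k)
        assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_odds_ratios(self, sample_pair, k):
        a, _ = sample_pair
        got = odds_ratios(a, k)
        want = naive_odds_ratios(a.reads, k)
        for i, w in enumerate(kmer_strings(k)):
            if w in want:
                assert got[i] == pytest.approx(want[w], abs=1e-12)
            else:
                assert not np.isfinite(got[i])


class TestProperties:
    def test_symmetry_all_measures(self, sample_pair):
        a, b = sample_pair
        for spec in roster(3):
            assert dissimilarity(a, b, spec) == pytest.approx(dissimilarity(b, a, spec), abs=1e-12)

    def test_identity_all_measures(self, rng):
        rs = supplement_complements(random_reads(rng, n_reads=30, max_len=60, min_len=20))
        for spec in roster(3):
            assert dissimilarity(rs, rs, spec) == pytest.approx(0.0, abs=1e-10)

    def test_ranges(self, sample_pair):
        a, b = sample_pair
        bounds = {"d2": 0.5, "d2S": 1.0, "d2star": 1.0, "Hao": 1.0, "Ma": 2.0, "Ch": 1.0}
        for spec in roster(3):
            val = dissimilarity(a, b, spec)
            assert val >= 0.0
            if spec.name in bounds:
                assert val <= bounds[spec.name] + 1e-12


class TestDissimilarityMatrix:
    def test_two_identical_samples(self, rng):
        rs = supplement_complements(random_reads(rng, n_reads=20, max_len=40))
        rs2 = ReadSet("b", list(rs.reads), supplemented=True)
        dm = dissimilarity_matrix([rs, rs2], MeasureSpec("d2S", 3, 0))
        assert np.allclose(dm.D, 0.0, atol=1e-12)

    def test_shape_contract(self, rng):
        samples = [
            supplement_complements(random_reads(rng, n_reads=15, max_len=40, sample_id=f"s{i}"))
            for i in range(3)
        ]
        dm = dissimilarity_matrix(samples, MeasureSpec("Eu", 3))
        assert dm.D.shape == (3, 3)
        assert np.allclose(dm.D, dm.D.T)
        assert np.allclose(np.diag(dm.D), 0.0)

    def test_matches_per_pair_calls(self, rng):
        samples = [
            supplement_complements(random_reads(rng, n_reads=15, max_len=40, sample_id=f"s{i}"))
            for i in range(4)
        ]
        spec = MeasureSpec("d2star", 3, 1)
        dm = dissimilarity_matrix(samples, spec)
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert dm.D[i, j] == pytest.approx(
                        dissimilarity(samples[i], samples[j], spec), abs=1e-12
                    )

    def test_single_sample_errors(self, small_sample):
        with pytest.raises(ValueError, match="at least 2"):
            dissimilarity_matrix([small_sample], MeasureSpec("Eu", 2))

    def test_tsv_roundtrip(self, rng, tmp_path):
        samples = [
            supplement_complements(random_reads(rng, n_reads=15, max_len=40, sample_id=f"s{i}"))
            for i in range(3)
        ]
        from kmersig.measures import DissimilarityMatrix

        dm = dissimilarity_matrix(samples, MeasureSpec("d2S", 3, 2))
        path = tmp_path / "m.tsv"
        dm.to_tsv(path)
        back = DissimilarityMatrix.from_tsv(path)
        assert back.sample_ids == dm.sample_ids
        assert np.allclose(back.D, dm.D)
        assert back.spec == dm.spec


def test_dispatch_equivalences(sample_pair):
    a, b = sample_pair
    ma = dissimilarity(a, b, MeasureSpec("Ma", 2))
    fa = to_frequencies(count_kmers(a, 2))
    fb = to_frequencies(count_kmers(b, 2))
    assert ma == pytest.approx(lp_distances(fa, fb)[0], abs=1e-15)
    assert dissimilarity(a, b, MeasureSpec("Willner", 3)) == pytest.approx(willner(a, b, 3), abs=1e-15)


def test_independence_limit_small():
    """Mean d2S|M0 over independent same-source pairs approaches 0.5.

    Scaled-down version (full-size check lives in the acceptance suite)."""
    from kmersig.community_sim import iid_reads

    rng = np.random.default_rng(123)
    vals = []
    for _ in range(10):
        a = supplement_complements(iid_reads(1000, 100, rng))
        b = supplement_complements(iid_reads(1000, 100, rng))
        ca, cb = count_kmers(a, 5), count_kmers(b, 5)
        vals.append(d2s(ca, cb, fit_markov(a, 0), fit_markov(b, 0)))
    assert 0.45 < np.mean(vals) < 0.55
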