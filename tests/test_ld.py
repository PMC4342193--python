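"""LD statistics, pruning, D' classification and haplotype blocks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from popgenkit.fixtures import SimSpec, simulate
from popgenkit.genotype_io import Dataset, PackedGenotypeMatrix, SampleRecord, VariantRecord
from popgenkit.ld import (
    GabrielThresholds,
    classify_pair_fast,
    diplotype_counts,
    diplotype_mle,
    dprime_ci,
    gabriel_blocks,
    indep_pairwise,
    pair_r,
    precompute_nomissing_moments,
    r_matrix,
)

from oracles import em_diplotype, gabriel_blocks_bruteforce, r_naive


def _dataset_from(dosages, bp_step=1000):
    d = np.asarray(dosages, dtype=np.int8)
    m, n = d.shape
    return Dataset(
        [SampleRecord(f"F{i}", f"I{i}") for i in range(n)],
        [VariantRecord("1", f"v{j}", 0.0, 1 + bp_step * j, "A", "B")
         for j in range(m)],
        PackedGenotypeMatrix.from_dosages(d),
    )


class TestPairR:
    def test_self_correlation_is_one(self, rng):
        x = rng.integers(0, 3, size=100)
        while len(set(x)) == 1:
            x = rng.integers(0, 3, size=100)
        assert pair_r(x, x).r == pytest.approx(1.0, rel=1e-12)

    def test_hand_example_antiperfect(self):
        s = pair_r([0, 1, 2, -1], [2, 1, 0, 0])
        assert s.n_obs == 3
        assert s.r == pytest.approx(-1.0, rel=1e-12)

    def test_zero_variance_flagged(self):
        s = pair_r([1, 1, 1, 1], [0, 1, 2, 0])
        assert math.isnan(s.r)

    def test_zero_overlap_flagged(self):
        s = pair_r([0, -1], [-1, 2])
        assert s.n_obs == 0 and math.isnan(s.r)

    @given(st.integers(0, 2**32 - 1))
    def test_random_rows_match_naive_correlation(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 400))
        x = r.integers(-1, 3, size=n)
        y = r.integers(-1, 3, size=n)
        got = pair_r(x, y).r
        want = r_naive(x, y)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


class TestNoMissingFastPath:
    def test_moments_computed_once_match_direct(self, rng):
        g = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        ds = _dataset_from(g)
        mean, m2, has_missing = precompute_nomissing_moments(ds)
        assert not has_missing.any()
        v = 1.0 - g.astype(float)
        assert np.allclose(mean, v.mean(1), rtol=1e-15)
        assert np.allclose(m2, (v**2).mean(1), rtol=1e-15)

    def test_fast_path_bitwise_equals_general_path(self, rng):
        """On missing-free rows the precomputed-moment path must reproduce the
        per-pair masked-count path bit for bit."""
        from popgenkit.ld import _pair_stats, _r_from_counts, _VariantBits
        from popgenkit.bitkernels import dot_product_packed, popcount

        g = rng.integers(0, 3, size=(8, 120)).astype(np.int8)
        bits = [_VariantBits(row) for row in g]
        for i in range(8):
            for j in range(i, 8):
                bx, by = bits[i], bits[j]
                fast = _pair_stats(bx, by).r  # takes the fast path (no missing)
                n_obs = popcount(bx.nm & by.nm)
                general = _r_from_counts(
                    n_obs,
                    popcount(bx.d0 & by.nm),
                    popcount(bx.d2 & by.nm),
                    popcount(by.d0 & bx.nm),
                    popcount(by.d2 & bx.nm),
                    dot_product_packed(bx.dot_enc, by.dot_enc, bx.n),
                ).r
                assert (fast == general) or (math.isnan(fast) and math.isnan(general))

    def test_mixed_missingness_falls_back_equal(self, rng):
        g = rng.integers(-1, 3, size=(6, 60)).astype(np.int8)
        ds = _dataset_from(g)
        mat = r_matrix(ds)
        for i in range(6):
            for j in range(6):
                want = pair_r(g[i], g[j]).r
                assert (mat[i, j] == want) or (
                    math.isnan(mat[i, j]) and math.isnan(want)
                )


class TestIndepPairwise:
    def test_uncorrelated_variants_all_kept(self):
        ds, _ = simulate(SimSpec(n_samples=200, n_variants=30, maf_min=0.2, seed=31))
        kept, pruned = indep_pairwise(ds, 10, 3, 0.5)
        assert pruned == [] and len(kept) == 30

    def test_duplicate_variants_leave_one_survivor(self, rng):
        row = rng.integers(0, 3, size=80).astype(np.int8)
        while len(set(row)) == 1:
            row = rng.integers(0, 3, size=80).astype(np.int8)
        g = np.tile(row, (5, 1))
        ds = _dataset_from(g)
        kept, pruned = indep_pairwise(ds, 5, 2, 0.5)
        assert len(kept) == 1 and len(pruned) == 4

    def test_postcondition_on_blocked_fixture(self):
        ds, _ = simulate(
            SimSpec(
                n_samples=150,
                n_variants=200,
                maf_min=0.1,
                ld_blocks=((25, 0.9), (25, 0.85), (10, 0.95)),
                seed=41,
            )
        )
        kept, pruned = indep_pairwise(ds, 50, 5, 0.5)
        assert set(kept) | set(pruned) == {v.vid for v in ds.variants}
        # exhaustive within-window scan of the survivors
        g = ds.genotypes.dosages()
        vid_to_idx = {v.vid: j for j, v in enumerate(ds.variants)}
        alive = sorted(vid_to_idx[v] for v in kept)
        for wstart in range(0, len(ds.variants), 5):
            win = [j for j in alive if wstart <= j < wstart + 50]
            for a, b in itertools.combinations(win, 2):
                r = pair_r(g[a], g[b]).r
                assert math.isnan(r) or r * r <= 0.5 + 1e-12

    def test_parameter_validation(self, small_dataset):
        with pytest.raises(ValueError):
            indep_pairwise(small_dataset, 5, 5, 0.5)
        with pytest.raises(ValueError):
            indep_pairwise(small_dataset, 5, 1, 1.5)


def _counts_from_haps(n, p11, p10, p01, p00, rng):
    """Draw genotype-pair counts from known haplotype frequencies."""
    probs = np.array([p00, p01, p10, p11])
    haps = rng.choice(4, size=(n, 2), p=probs / probs.sum())
    x = (haps >= 2).sum(1)
    y = (haps % 2).sum(1)
    return np.bincount(3 * x + y, minlength=9).reshape(3, 3)


class TestDiplotypeMle:
    def test_no_double_hets_solved_by_counting(self, rng):
        c = np.array([[10, 4, 1], [3, 0, 2], [1, 5, 8]])
        res = diplotype_mle(c)
        n = c.sum()
        n_ab = 2 * c[2, 2] + c[2, 1] + c[1, 2]
        assert res.p11 == pytest.approx(n_ab / (2 * n), abs=1e-12)

    def test_complete_coupling_gives_dprime_one(self):
        c = np.zeros((3, 3), dtype=int)
        c[0, 0] = 30
        c[2, 2] = 10
        c[1, 1] = 5  # double hets consistent with full coupling
        res = diplotype_mle(c)
        assert abs(res.dprime) == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(0, 2**32 - 1))
    def test_cubic_mle_matches_em_likelihood(self, seed):
        r = np.random.default_rng(seed)
        pa, pb = r.uniform(0.15, 0.5, size=2)
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
        d = r.uniform(-0.5, 1.0) * dmax
        p11 = pa * pb + d
        c = _counts_from_haps(
            300, p11, pa - p11, pb - p11, 1 - pa - pb + p11, r
        )
        try:
            res = diplotype_mle(c)
        except ValueError:
            return  # monomorphic draw
        from popgenkit.ld import _hap_stats, _loglik_p11

        _, n_ab, n_a, n_b, n_0, ndh, qa, qb = _hap_stats(c)
        ll_em = _loglik_p11(em_diplotype(c), qa, qb, n_ab, n_a, n_b, n_0, ndh)
        assert res.loglik >= ll_em - 1e-10

    def test_monomorphic_rejected(self):
        c = np.zeros((3, 3), dtype=int)
        c[0, 0] = 20
        with pytest.raises(ValueError, match="monomorphic"):
            diplotype_mle(c)


def _all_tables(total_max):
    """Every 3x3 table with grand total <= total_max (polymorphic or not)."""
    for total in range(1, total_max + 1):
        for cuts in itertools.combinations(range(total + 8), 8):
            cells = []
            prev = -1
            for cut in cuts:
                cells.append(cut - prev - 1)
                prev = cut
            cells.append(total + 8 - prev - 1)
            yield np.array(cells).reshape(3, 3)


class TestDprimeCI:
    def test_perfect_ld_classified_strong(self, rng):
        c = np.zeros((3, 3), dtype=int)
        c[0, 0], c[1, 1], c[2, 2] = 60, 30, 20
        res = dprime_ci(c)
        assert res.ci_high == 1.0
        assert res.classification == "strong_LD"

    def test_equilibrium_pair_classified_recombination(self, rng):
        pa = pb = 0.4
        c = _counts_from_haps(800, pa * pb, pa * (1 - pb), (1 - pa) * pb,
                              (1 - pa) * (1 - pb), rng)
        res = dprime_ci(c)
        assert res.ci_high < 0.90
        assert res.classification == "recombination"

    def test_ci_bounds_ordered_on_grid(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            c = r.integers(0, 30, size=(3, 3))
            try:
                res = dprime_ci(c)
            except ValueError:
                continue
            assert 0.0 <= res.ci_low <= res.ci_high <= 1.0

    def test_fast_classification_matches_grid_exhaustively(self):
        """Lossless acceleration: identical class on every small table."""
        th = GabrielThresholds()
        checked = 0
        for c in _all_tables(6):
            try:
                full = dprime_ci(c, th).classification
            except ValueError:
                continue
            fast = classify_pair_fast(c, th)
            assert fast == full, f"mismatch on {c.tolist()}"
            checked += 1
        assert checked > 300

    def test_fast_classification_matches_grid_random(self):
        th = GabrielThresholds()
        r = np.random.default_rng(99)
        agree = 0
        for _ in range(1500):
            c = r.integers(0, 60, size=(3, 3))
            try:
                full = dprime_ci(c, th).classification
            except ValueError:
                continue
            assert classify_pair_fast(c, th) == full, c.tolist()
            agree += 1
        assert agree > 1000


@pytest.fixture(scope="module")
def block_fixture():
    return simulate(
        SimSpec(
            n_samples=150,
            n_variants=26,
            maf_min=0.2,
            ld_blocks=((10, 0.98), (10, 0.97)),
            seed=53,
        )
    )[0]


class TestGabrielBlocks:
    def test_two_planted_blocks_recovered(self, block_fixture):
        blocks = gabriel_blocks(block_fixture, max_span_kb=200, maf_min=0.05)
        spans = {(b.first, b.last) for b in blocks}
        assert (0, 9) in spans and (10, 19) in spans

    def test_blocks_disjoint_and_sorted(self, block_fixture):
        blocks = gabriel_blocks(block_fixture, max_span_kb=200, maf_min=0.05)
        for b1, b2 in zip(blocks, blocks[1:]):
            assert b1.last < b2.first or b1.chrom != b2.chrom

    def test_unlinked_variants_yield_no_blocks(self):
        ds, _ = simulate(SimSpec(n_samples=40, n_variants=12, maf_min=0.3, seed=61))
        assert gabriel_blocks(ds, max_span_kb=200, maf_min=0.05) == []

    def test_matches_bruteforce_reference(self, block_fixture):
        th = GabrielThresholds()
        blocks = gabriel_blocks(block_fixture, 200, 0.05, th)
        got = sorted((b.chrom, b.first, b.last) for b in blocks)
        want = gabriel_blocks_bruteforce(block_fixture, 200, 0.05, th)
        assert got == want

    def test_skip_bound_does_not_change_output(self, block_fixture):
        a = gabriel_blocks(block_fixture, 200, 0.05, use_skip_bound=True)
        b = gabriel_blocks(block_fixture, 200, 0.05, use_skip_bound=False)
        assert a == b

    def test_unsorted_input_rejected(self, rng):
        g = rng.integers(0, 3, size=(3, 30)).astype(np.int8)
        ds = _dataset_from(g)
        ds.variants[1], ds.variants[2] = ds.variants[2], ds.variants[1]
        with pytest.raises(ValueError, match="sorted"):
            gabriel_blocks(ds)
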