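"""Attractor discovery: windows, convergence, merging, re-seeding, filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from colocnv import final_filters, merge_ranges
from colocnv.attractor import (
    AttractorSignature,
    build_caches,
    first_pass,
    iterate_attractor,
    second_pass,
    window_bounds,
)

from conftest import BLOCK_RANGE, make_cohort_set


def brute_force_window(k, n_genes, window_size):
    half = window_size // 2
    return [p for p in range(n_genes) if abs(p - k) <= half]


class TestWindows:
    @given(
        st.integers(10, 500),
        st.integers(5, 100),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_match_bruteforce(self, n_genes, half):
        window_size = 2 * half
        for k in {0, 1, n_genes // 2, n_genes - 1}:
            lo, hi = window_bounds(k, n_genes, window_size)
            assert list(range(lo, hi + 1)) == brute_force_window(
                k, n_genes, window_size
            )

    def test_windows_truncate_at_chromosome_ends(self):
        assert window_bounds(0, 100, 20) == (0, 10)
        assert window_bounds(99, 100, 20) == (89, 99)
        assert window_bounds(50, 100, 20) == (40, 60)


class TestIteration:
    def test_planted_block_found_with_high_strength(self, block_caches):
        lo, hi = window_bounds(74, 151, 150)
        sig = iterate_attractor(74, np.arange(lo, hi + 1), block_caches)
        block = {f"g1_{i:04d}" for i in range(*BLOCK_RANGE)}
        assert sig.converged
        assert sig.strength >= 0.5
        top10 = set(sig.top_genes(10))
        assert top10 == block
        # weights off the block stay far below the membership threshold
        off = [w for g, w in zip(sig.window_genes, sig.weights) if g not in block]
        assert max(off) < 0.3

    def test_every_block_seed_reaches_identical_attractor(self, block_caches):
        lo, hi = window_bounds(74, 151, 150)
        window = np.arange(lo, hi + 1)
        sigs = [
            iterate_attractor(s, window, block_caches)
            for s in range(*BLOCK_RANGE)
        ]
        ref = sigs[0]
        assert {s.name for s in sigs} == {ref.name}
        for s in sigs[1:]:
            assert np.max(np.abs(s.weights - ref.weights)) < 1e-6

    def test_deterministic_bit_identical(self, block_caches):
        lo, hi = window_bounds(74, 151, 150)
        window = np.arange(lo, hi + 1)
        a = iterate_attractor(74, window, block_caches)
        b = iterate_attractor(74, window, block_caches)
        assert np.array_equal(a.weights, b.weights)

    def test_noise_windows_stay_weak(self, noise_caches):
        strengths = []
        for seed in range(0, 300, 15):
            lo, hi = window_bounds(seed, 300, 150)
            sig = iterate_attractor(seed, np.arange(lo, hi + 1), noise_caches)
            assert sig.converged or sig.degenerate
            strengths.append(sig.strength)
        assert np.mean(np.array(strengths) < 0.5) >= 0.95

    def test_seed_outside_window_rejected(self, block_caches):
        with pytest.raises(ValueError, match="inside"):
            iterate_attractor(0, np.arange(10, 20), block_caches)


class TestFirstPass:
    def test_recovers_only_the_planted_block(self, block_cohort_set, block_caches):
        sigs = first_pass(block_caches)
        assert len(sigs) >= 1
        block = set(range(*BLOCK_RANGE))
        for sig in sigs:
            lo, hi = sig.range_span
            assert set(range(lo, hi + 1)) & block

    def test_pure_noise_genome_yields_nothing(self, noise_caches):
        assert first_pass(noise_caches) == []


def _mk_sig(name, chrom, span, strength=0.8):
    return AttractorSignature(
        name=name,
        seed=name,
        chromosome=chrom,
        window_genes=[name],
        weights=np.array([1.0]),
        strength=strength,
        converged=True,
        range_span=span,
        range_genes=(name, name),
    )


def oracle_clusters(sigs):
    """Union-find over pairwise range overlap; returns frozenset partition."""
    parent = list(range(len(sigs)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, a in enumerate(sigs):
        for j, b in enumerate(sigs):
            if a.chromosome == b.chromosome and not (
                a.range_span[1] < b.range_span[0]
                or b.range_span[1] < a.range_span[0]
            ):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(sigs)):
        groups.setdefault(find(i), set()).add(sigs[i].name)
    return {frozenset(g) for g in groups.values()}


class TestMergeRanges:
    def test_overlapping_ranges_merge(self):
        clusters = merge_ranges(
            [_mk_sig("a", "1", (0, 9)), _mk_sig("b", "1", (7, 14))]
        )
        assert len(clusters) == 1
        assert clusters[0].span == (0, 14)

    def test_disjoint_ranges_stay_apart(self):
        clusters = merge_ranges(
            [_mk_sig("a", "1", (0, 4)), _mk_sig("b", "1", (6, 11))]
        )
        assert [c.span for c in clusters] == [(0, 4), (6, 11)]

    def test_transitive_chain_merges(self):
        # a overlaps b, b overlaps c, a does not overlap c
        clusters = merge_ranges(
            [
                _mk_sig("a", "1", (0, 5)),
                _mk_sig("b", "1", (4, 10)),
                _mk_sig("c", "1", (9, 15)),
            ]
        )
        assert len(clusters) == 1
        assert clusters[0].span == (0, 15)

    def test_same_span_different_chromosomes(self):
        clusters = merge_ranges(
            [_mk_sig("a", "1", (0, 5)), _mk_sig("b", "2", (0, 5))]
        )
        assert len(clusters) == 2

    def test_matches_union_find_oracle_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            sigs = []
            for i in range(int(rng.integers(1, 10))):
                lo = int(rng.integers(0, 50))
                sigs.append(
                    _mk_sig(f"s{i}", str(rng.integers(1, 3)), (lo, lo + int(rng.integers(0, 10))))
                )
            got = {
                frozenset(m.name for m in c.members) for c in merge_ranges(sigs)
            }
            assert got == oracle_clusters(sigs)


class TestSecondPass:
    def test_reproduces_first_pass_attractor_on_clean_cluster(self, block_caches):
        firsts = first_pass(block_caches)
        clusters = merge_ranges(firsts)
        reps = second_pass(clusters, block_caches)
        assert len(reps) == len(clusters) == 1
        assert reps[0].name == firsts[0].name
        assert reps[0].strength >= 0.5

    def test_stronger_of_two_blocks_wins(self):
        """A cluster holding two independent blocks picks the stronger one."""
        rng = np.random.default_rng(11)
        n = 120
        expr = {}
        for c in range(3):
            h1 = rng.normal(size=n)
            h2 = rng.normal(size=n)
            mat = rng.normal(5.0, 0.5, size=(20, n))
            mat[2:8] += 2.0 * h1  # strong block, genes 2..7
            mat[12:18] += 0.9 * h2  # weaker block, genes 12..17
            expr[f"c{c}"] = mat
        cs = make_cohort_set(expr)
        caches = build_caches(cs)
        from colocnv.attractor import RangeCluster

        cluster = RangeCluster(chromosome="1", span=(0, 19), members=[])
        reps = second_pass([cluster], caches)
        assert len(reps) == 1
        strong = {f"g_{i:04d}" for i in range(2, 8)}
        assert set(reps[0].top_genes(6)) == strong


class TestFinalFilters:
    def _cohort_set_with_zero_fraction(self, n_zero):
        """Gene g_0000 has raw value 0 in ``n_zero`` of 20 pooled samples."""
        rng = np.random.default_rng(5)
        expr = {"A": rng.normal(5, 1, size=(6, 10)), "B": rng.normal(5, 1, size=(6, 10))}
        raw = {k: np.clip(np.exp2(v) - 1, 0, None) for k, v in expr.items()}
        zeroed = 0
        for name in ("A", "B"):
            for j in range(10):
                if zeroed < n_zero:
                    raw[name][0, j] = 0.0
                    zeroed += 1
        return make_cohort_set(expr, raw_by_cohort=raw)

    def _sig(self, chrom="1"):
        return AttractorSignature(
            name="g_0000",
            seed="g_0000",
            chromosome=chrom,
            window_genes=[f"g_{i:04d}" for i in range(6)],
            weights=np.array([1.0, 0.9, 0.8, 0.7, 0.6, 0.1]),
            strength=0.6,
            converged=True,
            range_span=(0, 4),
            range_genes=("g_0000", "g_0004"),
        )

    def test_zero_in_exactly_half_is_retained(self):
        cs = self._cohort_set_with_zero_fraction(10)
        assert final_filters([self._sig()], cs) != []

    def test_zero_in_more_than_half_is_removed(self):
        cs = self._cohort_set_with_zero_fraction(11)
        assert final_filters([self._sig()], cs) == []

    def test_sex_chromosome_signature_removed(self):
        cs = self._cohort_set_with_zero_fraction(0)
        cs.annotation["chromosome"] = "X"
        for c in cs.cohorts:
            pass  # annotation chromosome is what the filter consults
        assert final_filters([self._sig(chrom="X")], cs) == []

    def test_expressed_autosomal_signature_retained(self):
        cs = self._cohort_set_with_zero_fraction(0)
        kept = final_filters([self._sig()], cs)
        assert [s.name for s in kept] == ["g_0000"]
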