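"""Driver calling: levels, permutation test, thresholds, frequency rules."""

import numpy as np
import pytest

from colocnv import (
    CallConfig,
    classify_frequencies,
    co_alteration,
    derive_thresholds,
    designate_drivers,
    permutation_test,
    signature_levels,
)
from colocnv.attractor import AttractorSignature
from colocnv.cna_calls import SignatureCall, SignatureLevels

from conftest import make_cohort_set


def _signature(n_genes=6):
    w = np.linspace(1.0, 0.4, n_genes)
    return AttractorSignature(
        name="g_0000",
        seed="g_0000",
        chromosome="1",
        window_genes=[f"g_{i:04d}" for i in range(n_genes)],
        weights=w,
        strength=float(w[4]) if n_genes >= 5 else float(w[-1]),
        converged=True,
        range_span=(0, n_genes - 1),
        range_genes=("g_0000", f"g_{n_genes - 1:04d}"),
    )


def _call(levels, **kw):
    c = SignatureCall(signature=_signature(), levels=levels)
    for k, v in kw.items():
        setattr(c, k, v)
    return c


class TestSignatureLevels:
    def test_equal_rows_reproduce_the_row(self):
        v = np.arange(10.0)
        expr = {"A": np.tile(v, (6, 1))}
        cna = {"A": np.tile(v * 0.5, (6, 1))}
        cs = make_cohort_set(expr, cna)
        levels = signature_levels(_signature(), cs, top_k=5)
        np.testing.assert_allclose(levels.expr["A"], v)
        np.testing.assert_allclose(levels.cna["A"], v * 0.5)

    def test_mean_of_two_rows(self):
        expr = {"A": np.array([[1.0, 3.0], [3.0, 1.0], [9.0, 9.0]])}
        cs = make_cohort_set(expr)
        levels = signature_levels(_signature(3), cs, top_k=2)
        np.testing.assert_allclose(levels.expr["A"], [2.0, 2.0])

    def test_top_k_one_is_the_name_gene_row(self):
        rng = np.random.default_rng(0)
        expr = {"A": rng.normal(size=(6, 12))}
        cs = make_cohort_set(expr)
        levels = signature_levels(_signature(), cs, top_k=1)
        np.testing.assert_allclose(levels.expr["A"], expr["A"][0])

    def test_missing_gene_error_names_the_gene(self):
        expr = {"A": np.zeros((6, 8))}
        cs = make_cohort_set(expr)
        cs.cohorts[0].cna = cs.cohorts[0].cna.drop(index="g_0001")
        with pytest.raises(KeyError, match="g_0001"):
            signature_levels(_signature(), cs, top_k=5)


class TestPermutationTest:
    def test_perfect_coupling_reaches_minimum_p(self):
        rng = np.random.default_rng(1)
        cfg = CallConfig(n_permutations=500, rng_seed=3)
        v = {f"c{i}": rng.normal(size=40) for i in range(3)}
        levels = SignatureLevels(expr=v, cna={k: x.copy() for k, x in v.items()})
        assoc, p = permutation_test(levels, [1 / 3] * 3, cfg)
        assert assoc == 1.0
        assert p == pytest.approx(1 / 501)

    def test_seeded_p_value_is_reproducible(self):
        rng = np.random.default_rng(2)
        cfg = CallConfig(n_permutations=300, rng_seed=11)
        levels = SignatureLevels(
            expr={"c": rng.normal(size=60)}, cna={"c": rng.normal(size=60)}
        )
        r1 = permutation_test(levels, [1.0], cfg)
        r2 = permutation_test(levels, [1.0], cfg)
        assert r1 == r2

    def test_single_cohort_null_is_nearly_uniform(self):
        """With one cohort the sorted-median construction is exact."""
        rng = np.random.default_rng(3)
        cfg = CallConfig(n_permutations=200, rng_seed=5)
        ps = []
        for i in range(100):
            levels = SignatureLevels(
                expr={"c": rng.normal(size=50)}, cna={"c": rng.normal(size=50)}
            )
            ps.append(permutation_test(levels, [1.0], cfg, rng=rng)[1])
        frac = np.mean(np.array(ps) < 0.2)
        assert 0.1 < frac < 0.35

    def test_strong_dosage_coupling_is_detected(self):
        rng = np.random.default_rng(4)
        cfg = CallConfig(n_permutations=500, rng_seed=7)
        hits = 0
        for i in range(20):
            cna = {f"c{j}": rng.normal(size=60) for j in range(3)}
            levels = SignatureLevels(
                expr={k: v + rng.normal(0, 0.3, v.size) for k, v in cna.items()},
                cna=cna,
            )
            _, p = permutation_test(levels, [1 / 3] * 3, cfg, rng=rng)
            hits += p < 0.05
        assert hits >= 19

    def test_too_few_permutations_rejected(self):
        from colocnv.config import ConfigError

        with pytest.raises(ConfigError):
            CallConfig(n_permutations=50)


class TestThresholds:
    def test_truncated_normal_closed_form(self):
        """Normal CNA ~ N(0, 0.25): decile-tail mean is 0.25*E[Z|Z>=q90]."""
        rng = np.random.default_rng(5)
        normals = {"A": rng.normal(0, 0.25, size=(500, 400))}
        cs = make_cohort_set(
            {"A": rng.normal(5, 1, size=(500, 10))}, normal_cna=normals
        )
        t_amp, t_del = derive_thresholds(cs, CallConfig())
        expected = 0.25 * 1.7550  # E[Z | Z >= z_0.9] for standard normal
        assert t_amp == pytest.approx(expected, rel=0.05)
        assert t_del == pytest.approx(-expected, rel=0.05)

    def test_symmetric_noise_gives_symmetric_thresholds(self):
        rng = np.random.default_rng(6)
        normals = {
            "A": rng.normal(0, 0.3, size=(300, 60)),
            "B": rng.normal(0, 0.3, size=(300, 40)),
        }
        cs = make_cohort_set(
            {"A": rng.normal(5, 1, size=(300, 12)), "B": rng.normal(5, 1, size=(300, 10))},
            normal_cna=normals,
        )
        t_amp, t_del = derive_thresholds(cs, CallConfig())
        assert abs(t_amp + t_del) < 0.05 * abs(t_amp)

    def test_constant_normal_sample_degenerates_to_zero(self):
        rng = np.random.default_rng(7)
        cs = make_cohort_set(
            {"A": rng.normal(5, 1, size=(20, 10))},
            normal_cna={"A": np.full((20, 1), 0.7)},
        )
        with pytest.warns(UserWarning, match="degenerate"):
            t_amp, t_del = derive_thresholds(cs, CallConfig())
        assert t_amp == 0.0 and t_del == 0.0

    def test_cohort_without_normals_excluded(self):
        rng = np.random.default_rng(8)
        normals = {"A": rng.normal(0, 0.2, size=(100, 30))}
        cs = make_cohort_set(
            {"A": rng.normal(5, 1, (100, 10)), "B": rng.normal(5, 1, (100, 10))},
            normal_cna=normals,
        )
        with pytest.warns(UserWarning, match="no normal samples"):
            t_amp, _ = derive_thresholds(cs, CallConfig())
        assert t_amp > 0

    def test_no_normals_anywhere_raises(self):
        rng = np.random.default_rng(9)
        cs = make_cohort_set({"A": rng.normal(5, 1, (10, 10))})
        with pytest.raises(ValueError, match="no cohort has normal samples"):
            derive_thresholds(cs, CallConfig())


class TestFrequencyRules:
    def _levels(self, cna_by_cohort):
        return SignatureLevels(
            expr={k: np.zeros_like(v) for k, v in cna_by_cohort.items()},
            cna=cna_by_cohort,
        )

    def test_four_percent_is_amplified_three_is_not(self):
        cna = np.zeros(100)
        cna[:4] = 1.0
        call = classify_frequencies(
            self._call_for(cna), (0.5, -0.5), CallConfig()
        )
        assert call.amp_freq["c0"] == pytest.approx(0.04)
        assert call.n_types_amp == 1
        # exactly 3%: strictly-larger rule excludes it
        cna3 = np.zeros(100)
        cna3[:3] = 1.0
        call = classify_frequencies(
            self._call_for(cna3), (0.5, -0.5), CallConfig()
        )
        assert call.amp_freq["c0"] == pytest.approx(0.03)
        assert call.n_types_amp == 0

    def _call_for(self, *cna_vectors):
        cna = {f"c{i}": v for i, v in enumerate(cna_vectors)}
        return _call(self._levels(cna))

    def test_six_cohorts_is_not_pan_seven_is(self):
        amped = np.concatenate([np.full(10, 2.0), np.zeros(90)])  # 10% > 3%
        flat = np.zeros(100)
        for n_amped, expected in [(6, False), (7, True)]:
            vectors = [amped] * n_amped + [flat] * (8 - n_amped)
            call = classify_frequencies(
                self._call_for(*vectors), (0.5, -0.5), CallConfig()
            )
            assert call.n_types_amp == n_amped
            assert call.is_pan_amp is expected

    def test_deletion_side_is_symmetric(self):
        deleted = np.concatenate([np.full(10, -2.0), np.zeros(90)])
        vectors = [deleted] * 7
        call = classify_frequencies(
            self._call_for(*vectors), (0.5, -0.5), CallConfig()
        )
        assert call.is_pan_del and not call.is_pan_amp

    def test_raising_t_amp_never_raises_frequency(self):
        rng = np.random.default_rng(10)
        cna = rng.normal(size=200)
        freqs = []
        for t in np.linspace(-1, 1, 9):
            call = classify_frequencies(self._call_for(cna), (t, -2.0), CallConfig())
            freqs.append(call.amp_freq["c0"])
        assert freqs == sorted(freqs, reverse=True)


class TestCoAlteration:
    def _pair(self, la, lb):
        a = _call(
            SignatureLevels(expr={"c": la}, cna={"c": la}),
            is_pan_amp=True,
            n_types_amp=7,
        )
        b = _call(
            SignatureLevels(expr={"c": lb}, cna={"c": lb}),
            is_pan_amp=True,
            n_types_amp=7,
        )
        return a, b

    def test_identical_levels_always_co_altered(self):
        la = np.concatenate([np.full(30, 2.0), np.zeros(70)])
        a, b = self._pair(la, la.copy())
        co, assoc = co_alteration(a, b, [1.0], (0.5, -0.5), CallConfig())
        assert co == 1.0
        assert assoc == 1.0

    def test_difference_exactly_point_one_not_co_altered(self):
        la = np.full(50, 2.0)
        lb = np.full(50, 2.1)
        lb[0] = 2.0999  # one strictly-closer sample
        a, b = self._pair(la, lb)
        co, _ = co_alteration(a, b, [1.0], (0.5, -0.5), CallConfig())
        assert co == pytest.approx(1 / 50)

    def test_partial_event_overlap_gives_partial_co_frequency(self):
        la = np.zeros(100)
        lb = np.zeros(100)
        la[:50] = 2.0
        lb[:40] = 2.0  # 40 shared events, 10 solo
        a, b = self._pair(la, lb)
        co, _ = co_alteration(a, b, [1.0], (0.5, -0.5), CallConfig())
        assert co == pytest.approx(0.8)

    def test_nothing_altered_reports_missing(self):
        a, b = self._pair(np.zeros(20), np.zeros(20))
        co, _ = co_alteration(a, b, [1.0], (0.5, -0.5), CallConfig())
        assert co is None

    def test_mixed_directions_rejected(self):
        a, b = self._pair(np.full(20, 2.0), np.full(20, 2.0))
        b.is_pan_amp = False
        b.is_pan_del = True
        with pytest.raises(ValueError, match="same direction"):
            co_alteration(a, b, [1.0], (0.5, -0.5), CallConfig())


class TestDriverDesignation:
    def _call_with(self, p_raw, pan_amp=False, pan_del=False):
        return _call(
            SignatureLevels(expr={}, cna={}),
            p_raw=p_raw,
            is_pan_amp=pan_amp,
            is_pan_del=pan_del,
        )

    def test_dual_condition_rule(self):
        calls = [
            self._call_with(0.01, pan_amp=True),  # both conditions
            self._call_with(0.01),  # frequency fails
            self._call_with(0.2, pan_amp=True),  # association fails
        ]
        designate_drivers(calls, CallConfig())
        assert [c.is_driver for c in calls] == [True, False, False]

    def test_bonferroni_multiplier_is_number_of_signatures(self):
        calls = [self._call_with(0.02, pan_amp=True) for _ in range(4)]
        designate_drivers(calls, CallConfig())
        assert all(c.p_bonferroni == pytest.approx(0.08) for c in calls)
        assert not any(c.is_driver for c in calls)

    def test_p_bonferroni_caps_at_one(self):
        calls = [self._call_with(0.6, pan_amp=True) for _ in range(5)]
        designate_drivers(calls, CallConfig())
        assert all(c.p_bonferroni == 1.0 for c in calls)
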