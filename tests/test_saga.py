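import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqtlboga import saga
from seqtlboga.saga import FitnessSummary, SAGAParams

from conftest import make_binary, make_qubit


class TestAdaptivePc:
    def test_lower_branch_returns_c3(self):
        s = FitnessSummary(f_max=1.0, f_min=0.2, f_avg=0.6, f_b=0.5)
        assert saga.adaptive_pc(s, SAGAParams(c3=0.7)) == 0.7

    def test_upper_branch_at_fb_equals_fmax(self):
        s = FitnessSummary(f_max=1.0, f_min=0.0, f_avg=0.5, f_b=1.0)
        p = SAGAParams(c1=0.5, c2=0.0)
        assert saga.adaptive_pc(s, p) == pytest.approx(1.0)

    def test_degenerate_guard(self):
        s = FitnessSummary(f_max=0.8, f_min=0.8, f_avg=0.8, f_b=0.8)
        assert saga.adaptive_pc(s, SAGAParams(c3=0.7)) == 0.7

    def test_floor_clamp(self):
        # bracketed expression can go negative; clamped at 0.01
        s = FitnessSummary(f_max=1.0, f_min=0.0, f_avg=0.5, f_b=0.5)
        p = SAGAParams(c1=1.0, c2=0.5)
        assert saga.adaptive_pc(s, p) == pytest.approx(0.01)


class TestAdaptivePm:
    def test_lower_branch_returns_c6(self):
        s = FitnessSummary(f_max=1.0, f_min=0.2, f_avg=0.6, f_b=0.5)
        assert saga.adaptive_pm(s, SAGAParams(c6=0.4)) == 0.4

    def test_hand_worked_value(self):
        # 1 - 0.5*0.9/(1 - 0.5 + 0.8) = 0.65385 (to 1e-5)
        s = FitnessSummary(f_max=1.0, f_min=0.5, f_avg=0.8, f_b=0.9)
        p = SAGAParams(c4=0.5, c5=0.0)
        assert saga.adaptive_pm(s, p) == pytest.approx(0.65385, abs=1e-5)

    def test_zero_denominator_guard(self):
        s = FitnessSummary(f_max=0.0, f_min=0.0, f_avg=0.0, f_b=0.0)
        assert saga.adaptive_pm(s, SAGAParams(c6=0.4)) == 0.4

    def test_constant_limit(self):
        # c4 = c5 = 0 reduces the upper branch to 1
        s = FitnessSummary(f_max=1.0, f_min=0.1, f_avg=0.5, f_b=0.9)
        assert saga.adaptive_pm(s, SAGAParams(c4=0.0, c5=0.0)) == 1.0


@settings(max_examples=200, deadline=None)
@given(
    f_min=st.floats(0.0, 1.0),
    spread=st.floats(0.0, 1.0),
    avg_frac=st.floats(0.0, 1.0),
    fb=st.floats(0.0, 1.0),
)
def test_adaptive_probabilities_in_unit_interval(f_min, spread, avg_frac, fb):
    f_max = f_min + spread
    f_avg = f_min + avg_frac * spread
    s = FitnessSummary(f_max=f_max, f_min=f_min, f_avg=f_avg, f_b=fb)
    p = SAGAParams()
    assert 0.0 <= saga.adaptive_pc(s, p) <= 1.0
    assert 0.0 <= saga.adaptive_pm(s, p) <= 1.0


class TestQuantumRates:
    def test_quantum_pc_values(self):
        q = make_qubit(np.array([1.0, 1 / math.sqrt(2), 0.6]))
        assert saga.quantum_pc(q, 0) == pytest.approx(1.0)
        assert saga.quantum_pc(q, 1) == pytest.approx(0.5)
        assert saga.quantum_pc(q, 2) == pytest.approx(0.36)

    def test_quantum_pm_endpoints(self):
        assert saga.quantum_pm(1.0) == 0.0
        assert saga.quantum_pm(0.0, scale=1.0) == pytest.approx(1.0)

    def test_quantum_pm_hand_worked(self):
        assert saga.quantum_pm(1 / math.sqrt(2), scale=1.0) == pytest.approx(0.5)

    def test_quantum_pm_clips_with_warning(self):
        with pytest.warns(UserWarning):
            assert saga.quantum_pm(1.5) == 0.0

    def test_self_overlap_pm_zero(self, rng):
        from seqtlboga.qpop import overlap

        for _ in range(10):
            q = make_qubit(rng.uniform(0.1, 0.9, 5))
            assert saga.quantum_pm(overlap(q, q)) == pytest.approx(0.0, abs=1e-7)


class TestCrossover:
    def test_pc_zero_copies_parents(self, rng):
        a, b = make_binary("1100"), make_binary("0011")
        out_a, out_b = saga.crossover(a, b, 0.0, "one_point", rng)
        assert out_a is a and out_b is b

    def test_one_point_hand_worked(self):
        # force the cut at 2: 1100 x 0011 -> 1111 and 0000-repaired
        class CutRng:
            def random(self, size=None):
                return np.zeros(size) if size is not None else 0.0

            def integers(self, lo, hi):
                return 2

        a, b = make_binary("1100"), make_binary("0011")
        out_a, out_b = saga.crossover(a, b, 1.0, "one_point", CutRng())
        assert out_a.mask.tolist() == [1, 1, 1, 1]
        assert out_b.n_selected == 1  # 0000 repaired to a single bit

    @pytest.mark.parametrize("kind", ["one_point", "two_point"])
    def test_allele_conservation(self, rng, kind):
        for _ in range(30):
            m1, m2 = rng.integers(0, 2, 6), rng.integers(0, 2, 6)
            m1[0] = m2[0] = 1
            a, b = make_binary(m1), make_binary(m2)
            out_a, out_b = saga.crossover(a, b, 1.0, kind, rng)
            # splicing conserves the per-position multiset unless repair fired
            if out_a.mask.sum() + out_b.mask.sum() == m1.sum() + m2.sum():
                combined = out_a.mask + out_b.mask
                assert combined.tolist() == (m1 + m2).tolist()

    def test_real_tail_blend_stays_between_parents(self, rng):
        a = make_binary("10", c=1.0, sigma=0.1)
        b = make_binary("01", c=10.0, sigma=1.0)
        out_a, out_b = saga.crossover(a, b, 1.0, "uniform", rng)
        for o in (out_a, out_b):
            assert 1.0 <= o.c_value <= 10.0
            assert 0.1 <= o.sigma_value <= 1.0

    def test_unknown_kind(self, rng):
        a = make_binary("10")
        with pytest.raises(ValueError):
            saga.crossover(a, a, 1.0, "pointless", rng)


class TestMutate:
    def test_pm_zero_unchanged(self, rng):
        b = make_binary("1010", c=2.0, sigma=0.5)
        out = saga.mutate(b, 0.0, rng)
        assert out.mask.tolist() == b.mask.tolist()
        assert (out.c_value, out.sigma_value) == (2.0, 0.5)

    def test_pm_one_full_flip(self, rng):
        b = make_binary("1010")
        out = saga.mutate(b, 1.0, rng)
        assert out.mask.tolist() == [0, 1, 0, 1]

    def test_expected_flip_count(self):
        rng = np.random.default_rng(8)
        b = make_binary("1111100000")
        total = 0
        trials = 20_000
        for _ in range(trials):
            out = saga.mutate(b, 0.1, rng)
            total += int(np.sum(out.mask != b.mask))
        assert total / trials == pytest.approx(1.0, abs=0.03)

    def test_bounds_respected(self, rng):
        b = make_binary("11", c=99.0, sigma=9.9)
        for _ in range(50):
            out = saga.mutate(b, 1.0, rng, real_sigma=2.0, bounds=((0.01, 100.0), (0.01, 10.0)))
            assert 0.01 <= out.c_value <= 100.0
            assert 0.01 <= out.sigma_value <= 10.0


class TestSelect:
    def test_full_tournament_returns_best(self, rng):
        fits = np.array([0.1, 0.9, 0.4, 0.2])
        idx = saga.select(list(range(4)), fits, 4, rng)
        assert np.all(idx == 1)

    def test_elitism_slot(self, rng):
        fits = np.array([0.5, 0.1, 0.8])
        idx = saga.select(list(range(3)), fits, 2, rng)
        assert idx[0] == 2

    def test_uniform_fitness_uniform_selection(self):
        rng = np.random.default_rng(13)
        fits = np.zeros(4)
        counts = np.zeros(4)
        draws = 40_000
        for _ in range(draws // 4):
            idx = saga.select(list(range(4)), fits, 2, rng)
            for i in idx[1:]:
                counts[i] += 1
        freqs = counts / counts.sum()
        assert np.all(np.abs(freqs - 0.25) < 0.02)

    def test_empty_population(self, rng):
        with pytest.raises(ValueError):
            saga.select([], np.array([]), 2, rng)
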