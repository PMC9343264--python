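"""Time-domain index formulas, closed-form limits, and masking semantics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bpvar import compute_indices, index_battery
from bpvar.errors import DataError

from conftest import make_clean


class TestFormulaValues:
    def test_simple_ramp(self):
        iset = compute_indices([1.0, 2.0, 3.0])
        assert iset.mean == 2.0
        assert iset.sd == 1.0
        assert iset.cv == 0.5
        assert iset.arv == 1.0
        assert iset.sv == 1.0
        assert iset.tc == 0.0
        assert iset.n == 3 and iset.n_diffs_used == 2

    def test_alternating_square(self):
        iset = compute_indices([100.0, 110.0, 100.0, 110.0])
        assert iset.arv == 10.0
        assert iset.sv == 10.0
        assert iset.tc == 2.0 / 4.0  # two strict sign changes among three diffs
        assert iset.mean == 105.0

    def test_monotone_series_has_no_trend_changes(self):
        assert compute_indices(np.linspace(0, 50, 200) ** 1.3).tc == 0.0

    def test_flat_steps_are_not_trend_changes(self):
        # zero products do not satisfy the strict < 0 criterion
        assert compute_indices([1.0, 2.0, 2.0, 3.0]).tc == 0.0


class TestClosedFormLimits:
    def test_sv_of_on_grid_sine(self):
        # n - 1 differences tiling whole cycles make the phase average exact
        n, m, amp, dt = 10001, 137, 3.0, 1.0
        f = m / ((n - 1) * dt)
        x = amp * np.sin(2 * np.pi * f * np.arange(n) * dt + 0.7)
        expected = math.sqrt(2.0) * amp * abs(math.sin(math.pi * f * dt))
        assert compute_indices(x).sv == pytest.approx(expected, abs=1e-6)

    def test_sv_nondecreasing_in_frequency_up_to_nyquist(self):
        # SV weighs frequencies near the sampling frequency more strongly
        n = 9001
        svs = []
        for m in (25, 100, 400, 1500, 3000, 4400):
            f = m / (n - 1)
            x = np.sin(2 * np.pi * f * np.arange(n) + 0.4)
            svs.append(compute_indices(x).sv)
        assert all(b >= a - 1e-9 for a, b in zip(svs, svs[1:]))

    def test_iid_trend_change_fraction_approaches_two_thirds(self, rng):
        x = rng.normal(size=100_000)
        assert compute_indices(x).tc == pytest.approx(2.0 / 3.0, abs=0.01)

    def test_iid_normal_successive_difference_moments(self, rng):
        sigma = 2.5
        x = rng.normal(0, sigma, size=500_000)
        iset = compute_indices(x)
        assert iset.sv == pytest.approx(sigma * math.sqrt(2.0), rel=0.01)
        assert iset.arv == pytest.approx(2.0 * sigma / math.sqrt(math.pi), rel=0.01)


finite_series = hnp.arrays(
    np.float64,
    st.integers(min_value=3, max_value=40),
    elements=st.floats(-500, 500, allow_nan=False, width=32),
)


class TestInvariants:
    @given(finite_series)
    def test_sv_dominates_arv(self, x):
        iset = compute_indices(x)
        assert iset.sv >= iset.arv - 1e-12

    @given(finite_series, st.floats(0.1, 10), st.floats(-50, 50))
    def test_scale_and_shift_equivariance(self, x, c, b):
        base = compute_indices(x)
        scaled = compute_indices(c * x)
        for name in ("sd", "arv", "sv"):
            assert getattr(scaled, name) == pytest.approx(
                c * getattr(base, name), rel=1e-9, abs=1e-9
            )
        assert scaled.tc == base.tc
        shifted = compute_indices(x + b)
        for name in ("sd", "arv", "sv"):
            assert getattr(shifted, name) == pytest.approx(
                getattr(base, name), rel=1e-6, abs=1e-6
            )

    @given(finite_series)
    def test_tc_bounds(self, x):
        iset = compute_indices(x)
        assert 0.0 <= iset.tc <= (iset.n - 2) / iset.n + 1e-12


class TestMaskingSemantics:
    def test_diffs_never_cross_gaps(self):
        # two segments [10, 20] and [1000, 1010]: the 980-jump pair is invalid
        x = [10.0, 20.0, np.nan, 1000.0, 1010.0]
        iset = compute_indices(make_clean(x))
        assert iset.n == 4
        assert iset.n_diffs_used == 2
        assert iset.arv == 10.0 and iset.sv == 10.0

    def test_excluded_differences_shrink_the_denominator(self):
        x = np.array([0.0, 1.0, 0.0, 50.0, 50.0 + 1.0, 50.0])
        excl = np.zeros(5, dtype=bool)
        excl[2] = True  # the +50 jump
        iset = compute_indices(make_clean(x, diff_excluded=excl))
        assert iset.n_diffs_used == 4
        assert iset.arv == 1.0 and iset.sv == 1.0

    def test_tc_denominator_counts_all_valid_samples(self):
        x = [1.0, 2.0, 1.0, 2.0, np.nan, 5.0]
        iset = compute_indices(make_clean(x))
        assert iset.tc == pytest.approx(2.0 / 5.0)

    def test_undefined_indices_are_nan_not_zero(self):
        iset = compute_indices(make_clean([5.0, np.nan, 7.0]))
        assert iset.n == 2
        # every adjacent pair spans the gap, so no successive diffs are usable
        assert iset.n_diffs_used == 0
        assert math.isnan(iset.arv) and math.isnan(iset.sv) and math.isnan(iset.tc)
        assert iset.sd == pytest.approx(np.std([5.0, 7.0], ddof=1))

    def test_cv_undefined_for_nonpositive_mean(self):
        assert math.isnan(compute_indices([-1.0, 0.0, 1.0]).cv)

    def test_all_invalid_raises(self):
        with pytest.raises(DataError):
            compute_indices(make_clean([np.nan, np.nan, np.nan]))


class TestBattery:
    def test_constant_trace_all_zero_variability(self):
        tr = make_clean(np.full(3600, 130.0))
        table = index_battery(tr, intervals=(1, 60, 300), methods=("instantaneous", "averaging"))
        assert (table[["sd", "cv", "arv", "sv", "tc"]].to_numpy() == 0).all()
        assert (table["mean"] == 130.0).all()

    def test_native_interval_row_equals_direct_computation(self):
        rng = np.random.default_rng(3)
        tr = make_clean(130 + rng.normal(0, 5, 2000))
        direct = compute_indices(tr)
        row = index_battery(tr, intervals=(1,), methods=("instantaneous",)).iloc[0]
        for name in ("mean", "sd", "cv", "arv", "sv", "tc"):
            assert row[name] == getattr(direct, name)

    def test_high_frequency_content_suppressed_by_averaging(self):
        # sinc-attenuation: averaged SV far below instantaneous SV at 5 min
        t = np.arange(6 * 3600)
        tr = make_clean(130 + 8 * np.cos(2 * np.pi * t / 40.0))
        table = index_battery(tr, intervals=(300,), methods=("instantaneous", "averaging"))
        sv = dict(zip(table.method, table.sv))
        assert sv["averaging"] < 0.1 * sv["instantaneous"]
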