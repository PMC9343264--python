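"""Group comparison against enumeration oracles; sweeps on known ground truth."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from bpvar import compare_groups, duration_sweep, fisher_exact, frequency_sweep, preprocess
from bpvar.errors import DataError
from bpvar.synthetic import SynthConfig, generate_cohort

from conftest import make_clean


def mann_whitney_oracle(favorable, unfavorable):
    """Exhaustive relabelling enumeration of U and its two-sided p."""
    pooled = list(unfavorable) + list(favorable)
    n_u = len(unfavorable)

    def u_stat(u, f):
        return sum((ui > fi) + 0.5 * (ui == fi) for ui in u for fi in f)

    u_obs = u_stat(unfavorable, favorable)
    idx = set(range(len(pooled)))
    us = []
    for comb in combinations(range(len(pooled)), n_u):
        u = [pooled[i] for i in comb]
        f = [pooled[i] for i in idx - set(comb)]
        us.append(u_stat(u, f))
    us = np.asarray(us)
    p = 2 * min(np.mean(us <= u_obs + 1e-12), np.mean(us >= u_obs - 1e-12))
    return u_obs, min(p, 1.0)


def fisher_oracle(table):
    """Two-sided Fisher p by enumerating all tables with the observed margins."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    pmf = stats.hypergeom(n, r1, c1).pmf
    p_obs = pmf(a)
    ks = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    return float(sum(pmf(k) for k in ks if pmf(k) <= p_obs * (1 + 1e-9)))


class TestCompareGroups:
    def test_identical_groups_auc_half(self):
        cmp_ = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert cmp_.auc == 0.5
        assert cmp_.p_value == pytest.approx(1.0, abs=0.05)

    def test_perfect_separation_auc_one(self):
        cmp_ = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert cmp_.auc == 1.0
        assert cmp_.auc_ci95[1] == 1.0

    @pytest.mark.parametrize(
        "favorable, unfavorable",
        [
            ([1, 2, 3], [4, 5]),
            ([1.5, 2.5, 9.0, 3.0], [4.0, 5.0, 0.5]),
            ([10, 20, 30, 40, 50], [15, 60, 70]),
            (list(range(8)), [3.5, 7.5, 11.0, 12.0, 13.0]),
        ],
    )
    def test_matches_exhaustive_enumeration(self, favorable, unfavorable):
        u_exp, p_exp = mann_whitney_oracle(favorable, unfavorable)
        cmp_ = compare_groups(favorable, unfavorable)
        assert cmp_.u_statistic == u_exp
        assert cmp_.p_value == pytest.approx(p_exp, rel=1e-12)
        assert cmp_.auc == pytest.approx(u_exp / (len(favorable) * len(unfavorable)))

    def test_auc_u_consistency_with_ties(self, rng):
        fav = rng.integers(0, 5, 12).astype(float)
        unf = rng.integers(0, 5, 9).astype(float)
        cmp_ = compare_groups(fav, unf)
        assert cmp_.auc * 12 * 9 == pytest.approx(cmp_.u_statistic)
        u = unf[:, None]
        assert cmp_.auc == pytest.approx(
            np.mean(u > fav[None, :]) + 0.5 * np.mean(u == fav[None, :])
        )

    def test_nan_values_dropped(self):
        cmp_ = compare_groups([1.0, np.nan, 2.0], [3.0, 4.0])
        assert cmp_.n_favorable == 2

    def test_empty_group_raises(self):
        with pytest.raises(DataError):
            compare_groups([], [1.0, 2.0])

    def test_bootstrap_ci_contains_auc_and_is_seeded(self):
        fav = [1.0, 3.0, 2.0, 5.0]
        unf = [4.0, 6.0, 7.0, 2.5]
        a = compare_groups(fav, unf, ci_method="bootstrap", n_boot=500, seed=3)
        b = compare_groups(fav, unf, ci_method="bootstrap", n_boot=500, seed=3)
        assert a.auc_ci95 == b.auc_ci95
        assert a.auc_ci95[0] <= a.auc <= a.auc_ci95[1]

    def test_type_i_error_calibrated(self, rng):
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            fav = rng.normal(0, 1, 10)
            unf = rng.normal(0, 1, 24)
            rejections += compare_groups(fav, unf).p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    @pytest.mark.parametrize("table", [[[10, 0], [0, 10]], [[8, 2], [3, 7]], [[1, 9], [5, 5]]])
    def test_matches_hypergeometric_enumeration(self, table):
        assert fisher_exact(table) == pytest.approx(fisher_oracle(table), rel=1e-9)

    def test_row_swap_symmetry(self):
        assert fisher_exact([[8, 2], [3, 7]]) == pytest.approx(
            fisher_exact([[3, 7], [8, 2]]), rel=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            fisher_exact([[1, -1], [2, 3]])


def _identical_cohort():
    rng = np.random.default_rng(0)
    x = 130 + rng.normal(0, 5, 3600)
    return [(make_clean(x.copy()), g) for g in ["favorable"] * 3 + ["unfavorable"] * 3]


class TestFrequencySweep:
    def test_identical_traces_yield_p_one(self):
        sweep = frequency_sweep(_identical_cohort(), intervals=(1, 60), methods=("averaging",))
        assert (sweep.p_value == 1.0).all()
        assert (sweep.auc == 0.5).all()

    def test_single_cell_equals_compare_groups(self, rng):
        cohort = [
            (make_clean(130 + rng.normal(0, s, 3600)), g)
            for s, g in [(4, "favorable")] * 3 + [(8, "unfavorable")] * 3
        ]
        sweep = frequency_sweep(cohort, intervals=(60,), methods=("averaging",),
                                index_names=("sv",))
        from bpvar import compute_indices, downsample
        values = [compute_indices(downsample(tr, 60, "averaging")).sv for tr, _ in cohort]
        direct = compare_groups(values[:3], values[3:])
        row = sweep.iloc[0]
        assert row.p_value == direct.p_value and row.auc == direct.auc

    def test_midrange_effect_found_at_averaged_midrange_portraying_intervals(self):
        """With a midrange-band group effect, the most discriminative SV cell
        is an *averaging* cell whose sampling rate portrays the midrange band
        (2-10 min), in the majority of replicates."""
        cfg = SynthConfig(
            duration_h=8.0, truncation_probs=(1, 0, 0), artifact_rate=0, gap_rate=0,
            band_sd={"favorable": (8.0, 2.6, 2.1, 1.3), "unfavorable": (8.0, 5.2, 2.1, 1.3)},
        )
        wins = 0
        n_rep = 9
        for rep in range(n_rep):
            cohort = [(preprocess(tr), g) for tr, g in generate_cohort(cfg.replace(seed=50 + rep))]
            sweep = frequency_sweep(
                cohort, intervals=(1, 30, 120, 300, 600, 1800), index_names=("sv",)
            )
            best = sweep.loc[sweep.p_value.idxmin()]
            wins += best.method == "averaging" and 120 <= best.interval_s <= 600
        assert wins > n_rep / 2


class TestDurationSweep:
    def test_full_duration_equals_full_record_analysis(self, rng):
        cohort = [
            (make_clean(130 + rng.normal(0, s, 7200)), g)
            for s, g in [(4, "favorable")] * 3 + [(8, "unfavorable")] * 3
        ]
        sweep = duration_sweep(cohort, hours=[2])
        from bpvar import compute_indices, downsample
        sv_vals = [compute_indices(downsample(tr, 300, "averaging")).sv for tr, _ in cohort]
        direct = compare_groups(sv_vals[:3], sv_vals[3:])
        row = sweep.loc[sweep.statistic == "sv"].iloc[0]
        assert row.p_value == direct.p_value

    def test_short_record_contributes_fully_beyond_its_length(self, rng):
        x = 130 + rng.normal(0, 5, 4 * 3600)
        from bpvar.traces import truncate
        tr = make_clean(x)
        assert truncate(tr, 6 * 3600).n == tr.n

    def test_sv_and_midrange_stay_predictive_while_sd_degrades(self):
        """A slow trend shared by both groups drowns SD but not SV/midrange."""
        cfg = SynthConfig(
            duration_h=24.0, truncation_probs=(1, 0, 0), artifact_rate=0, gap_rate=0,
            band_sd={"favorable": (16.0, 2.6, 2.1, 1.3), "unfavorable": (16.0, 5.2, 2.1, 1.3)},
            band_sigma=(0.6, 0.25, 0.25, 0.5),
        )
        hits = 0
        n_rep = 5
        for rep in range(n_rep):
            cohort = [(preprocess(tr), g) for tr, g in generate_cohort(cfg.replace(seed=300 + rep))]
            sweep = duration_sweep(cohort, hours=[24])
            p = dict(zip(sweep.statistic, sweep.p_value))
            hits += (p["sv"] < 0.05) and (p["midrange"] < 0.05) and (p["sd"] > p["sv"])
        assert hits > n_rep / 2
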