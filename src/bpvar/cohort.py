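"""Outcome-group comparison of variability statistics, and the two sweeps.

Per-patient statistics are compared between favorable and unfavorable outcome
groups with the two-sided Mann-Whitney U test (exact for small tie-free
samples, tie-corrected normal approximation otherwise).  Effect size is the
AUC: the probability that a randomly chosen unfavorable patient has the larger
value (ties count 1/2), which equals U / (n_fav * n_unf) for that orientation.
The 95% CI is Hanley-McNeil by default, with a seeded stratified bootstrap as
the alternative.  Categorical 2x2 tables use Fisher's exact test.

The frequency sweep evaluates every (sampling interval, downsampling method,
index) cell — the machine-readable p-value surface over sampling rates — and
the duration sweep recomputes selected statistics on record-start-anchored
windows of 1..24 h (patients with shorter records contribute whatever they
have).  No multiple-testing correction is applied across sweep grids; the
surfaces are exploratory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .indices import INDEX_NAMES, compute_indices, index_battery
from .resampling import DEFAULT_GRID, DEFAULT_MIN_COVERAGE, METHODS, downsample
from .spectral import BAND_NAMES, FrequencyBand, spectral_battery
from .traces import CleanTrace, truncate

logger = logging.getLogger(__name__)

CI_METHODS = ("hanley-mcneil", "bootstrap")


@dataclass
class CohortComparison:
    """Group medians/IQRs, U statistic, two-sided p, and AUC with 95% CI."""

    name: str
    n_favorable: int
    n_unfavorable: int
    median_favorable: float
    iqr_favorable: Tuple[float, float]
    median_unfavorable: float
    iqr_unfavorable: Tuple[float, float]
    u_statistic: float
    p_value: float
    auc: float
    auc_ci95: Tuple[float, float]
    ci_method: str

    def as_dict(self) -> dict:
        return {
            "statistic": self.name,
            "n_favorable": self.n_favorable,
            "n_unfavorable": self.n_unfavorable,
            "median_favorable": self.median_favorable,
            "q1_favorable": self.iqr_favorable[0],
            "q3_favorable": self.iqr_favorable[1],
            "median_unfavorable": self.median_unfavorable,
            "q1_unfavorable": self.iqr_unfavorable[0],
            "q3_unfavorable": self.iqr_unfavorable[1],
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci95[0],
            "auc_ci_high": self.auc_ci95[1],
            "ci_method": self.ci_method,
        }


def _auc(unfavorable: np.ndarray, favorable: np.ndarray) -> float:
    u = unfavorable[:, None]
    f = favorable[None, :]
    return float((np.mean(u > f) + 0.5 * np.mean(u == f)))


def _hanley_mcneil_ci(auc: float, n_unf: int, n_fav: int) -> Tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_unf - 1) * (q1 - auc ** 2)
        + (n_fav - 1) * (q2 - auc ** 2)
    ) / (n_unf * n_fav)
    se = np.sqrt(max(var, 0.0))
    return (max(auc - 1.959963984540054 * se, 0.0), min(auc + 1.959963984540054 * se, 1.0))


def _bootstrap_ci(
    unfavorable: np.ndarray, favorable: np.ndarray, n_boot: int, seed: int
) -> Tuple[float, float]:
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ub = rng.choice(unfavorable, size=unfavorable.size, replace=True)
        fb = rng.choice(favorable, size=favorable.size, replace=True)
        aucs[b] = _auc(ub, fb)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return (float(lo), float(hi))


def compare_groups(
    favorable: Sequence[float],
    unfavorable: Sequence[float],
    name: str = "",
    ci_method: str = "hanley-mcneil",
    n_boot: int = 2000,
    seed: int = 0,
    exact_max_n: int = 20,
) -> CohortComparison:
    """Mann-Whitney comparison of per-patient statistics between outcome groups.

    Missing (NaN) values — patients for whom the statistic was undefined —
    are dropped groupwise.  The exact null distribution is used when the
    pooled sample is tie-free and no larger than ``exact_max_n``.
    """
    if ci_method not in CI_METHODS:
        raise ConfigError(f"ci_method must be one of {CI_METHODS}")
    fav = np.asarray(favorable, dtype=float)
    unf = np.asarray(unfavorable, dtype=float)
    n_dropped = int(np.isnan(fav).sum() + np.isnan(unf).sum())
    if n_dropped:
        logger.info("%s: dropped %d patients with undefined values", name or "compare", n_dropped)
    fav = fav[~np.isnan(fav)]
    unf = unf[~np.isnan(unf)]
    if fav.size == 0 or unf.size == 0:
        raise DataError("both groups must be non-empty")

    pooled = np.concatenate([fav, unf])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(unf, fav, alternative="two-sided", method=method)
    auc = float(res.statistic) / (unf.size * fav.size)

    if ci_method == "hanley-mcneil":
        ci = _hanley_mcneil_ci(auc, unf.size, fav.size)
    else:
        ci = _bootstrap_ci(unf, fav, n_boot=n_boot, seed=seed)

    q1f, medf, q3f = np.percentile(fav, [25, 50, 75])
    q1u, medu, q3u = np.percentile(unf, [25, 50, 75])
    return CohortComparison(
        name=name,
        n_favorable=int(fav.size),
        n_unfavorable=int(unf.size),
        median_favorable=float(medf),
        iqr_favorable=(float(q1f), float(q3f)),
        median_unfavorable=float(medu),
        iqr_unfavorable=(float(q1u), float(q3u)),
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        auc=auc,
        auc_ci95=ci,
        ci_method=ci_method,
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise DataError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise DataError("table entries must be non-negative integers")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def _split_values(values: List[float], labels: List[str]):
    fav = [v for v, g in zip(values, labels) if g == "favorable"]
    unf = [v for v, g in zip(values, labels) if g == "unfavorable"]
    return fav, unf


def frequency_sweep(
    cohort: Sequence[Tuple[CleanTrace, str]],
    intervals: Sequence[float] = DEFAULT_GRID,
    methods: Sequence[str] = METHODS,
    index_names: Sequence[str] = INDEX_NAMES,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    **compare_kw,
) -> pd.DataFrame:
    """p-value / AUC surface over (sampling interval, method, index)."""
    if not cohort:
        raise DataError("cohort is empty")
    labels = [g for _, g in cohort]
    batteries = [
        index_battery(tr, intervals=intervals, methods=methods, min_coverage=min_coverage)
        for tr, _ in cohort
    ]
    rows = []
    for interval in intervals:
        for method in methods:
            cells = [
                b.loc[(b.interval_s == float(interval)) & (b.method == method)].iloc[0]
                for b in batteries
            ]
            for index in index_names:
                values = [float(c[index]) for c in cells]
                fav, unf = _split_values(values, labels)
                cmp_ = compare_groups(
                    fav, unf, name=f"{index}@{interval}s/{method}", **compare_kw
                )
                rows.append(
                    {
                        "interval_s": float(interval),
                        "method": method,
                        "index": index,
                        "p_value": cmp_.p_value,
                        "auc": cmp_.auc,
                        "n_favorable": cmp_.n_favorable,
                        "n_unfavorable": cmp_.n_unfavorable,
                    }
                )
    return pd.DataFrame(rows)


def duration_sweep(
    cohort: Sequence[Tuple[CleanTrace, str]],
    hours: Optional[Sequence[int]] = None,
    sd_interval_s: float = 120.0,
    sv_interval_s: float = 300.0,
    method: str = "averaging",
    bands: Optional[Sequence[FrequencyBand]] = None,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    **compare_kw,
) -> pd.DataFrame:
    """p-value / AUC versus monitoring duration for SD, SV and the band powers.

    SD and SV are evaluated at their reference time bins (2 min and 5 min,
    averaging) and band powers at the native resolution.  Every trace is
    truncated to its first ``d`` hours; shorter records contribute their full
    record to all longer durations.
    """
    if not cohort:
        raise DataError("cohort is empty")
    if hours is None:
        hours = range(1, 25)
    labels = [g for _, g in cohort]
    rows = []
    for d in hours:
        stat_values: Dict[str, List[float]] = {}
        for trace, _ in cohort:
            tr = truncate(trace, d * 3600.0)
            try:
                sd_val = compute_indices(
                    downsample(tr, sd_interval_s, method, min_coverage)
                ).sd
                sv_val = compute_indices(
                    downsample(tr, sv_interval_s, method, min_coverage)
                ).sv
            except DataError:
                sd_val = sv_val = np.nan
            stat_values.setdefault("sd", []).append(sd_val)
            stat_values.setdefault("sv", []).append(sv_val)
            try:
                bp = spectral_battery(tr, bands=bands)
                for band, p in bp.powers.items():
                    stat_values.setdefault(band, []).append(p)
            except DataError:
                for band in BAND_NAMES if bands is None else [b.name for b in bands]:
                    stat_values.setdefault(band, []).append(np.nan)
        for stat_name, values in stat_values.items():
            fav, unf = _split_values(values, labels)
            cmp_ = compare_groups(fav, unf, name=f"{stat_name}@{d}h", **compare_kw)
            rows.append(
                {
                    "duration_h": int(d),
                    "statistic": stat_name,
                    "p_value": cmp_.p_value,
                    "auc": cmp_.auc,
                    "median_favorable": cmp_.median_favorable,
                    "median_unfavorable": cmp_.median_unfavorable,
                }
            )
    return pd.DataFrame(rows)
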