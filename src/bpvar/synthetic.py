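"""Synthetic cohorts of 1 Hz arterial blood-pressure traces.

The generator emulates post-thrombectomy ICU monitoring records: ~24 h of
systolic pressure around 130 mmHg with a slow diurnal oscillation, band-limited
stochastic variability in four frequency bands (low < 1/20 min, midrange
1/20-1/5 min, high 1/5-1/1 min, very high > 1/1 min), measurement-artifact
spikes, monitoring gaps, and truncated records.  The dichotomous outcome label
selects the per-band target standard deviations, so a group effect can be
injected into any band (by default, higher midrange power in the unfavorable
group).

Band-limited noise is realized as a sum of K random-phase sinusoids per band.
Frequencies are drawn among the record's own DFT bins inside the band (so band
confinement is exact and the realized band power equals the target exactly over
the full record), with amplitudes weighted so the within-band power spectrum
falls off as ``f**-alpha``: the low band uses ``alpha = 2`` (a diurnal-
dominated red spectrum; slow trends, not 20-minute cycles, carry the sub-
1/20-min energy), the other bands are flat.  Between-patient heterogeneity of
variability is modelled by lognormal multipliers on each band's standard
deviation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError
from .traces import BPTrace

logger = logging.getLogger(__name__)

GROUPS = ("favorable", "unfavorable")

#: Band edges in Hz for a 1 Hz record: low, midrange, high, very high.
BAND_EDGES: Tuple[Tuple[float, float], ...] = (
    (0.0, 1.0 / 1200.0),
    (1.0 / 1200.0, 1.0 / 300.0),
    (1.0 / 300.0, 1.0 / 60.0),
    (1.0 / 60.0, 0.5),
)

#: Default per-group band SDs (mmHg): square roots of typical per-band power
#: medians observed in post-thrombectomy cohorts (band power in mmHg^2 equals
#: the squared band SD for this generator).
DEFAULT_BAND_SD: Dict[str, Tuple[float, float, float, float]] = {
    "favorable": (7.96, 2.60, 2.12, 1.26),
    "unfavorable": (8.58, 3.55, 2.22, 1.36),
}


@dataclass
class SynthConfig:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the reference cohort: 10 favorable vs 24 unfavorable
    patients, nominally 24 h at 1 Hz with a 23/33-5/33-5/33 split between
    complete, 12-24 h and <12 h records, mean SBP 130 mmHg with 18 mmHg
    between-patient spread, and per-band variability with higher midrange
    power in the unfavorable group.
    """

    n_favorable: int = 10
    n_unfavorable: int = 24
    duration_h: float = 24.0
    #: probabilities of (full record, 12-24 h record, short record)
    truncation_probs: Tuple[float, float, float] = (23 / 33, 5 / 33, 5 / 33)
    truncation_mid_h: Tuple[float, float] = (12.0, 24.0)
    truncation_short_h: Tuple[float, float] = (4.0, 12.0)
    fs: float = 1.0
    channel: str = "SBP"
    mean_sbp: float = 130.0
    mean_sd: float = 18.0  # between-patient SD of the patient mean level
    diurnal_amp: float = 5.0  # mmHg, amplitude of the slow diurnal oscillation
    diurnal_period_h: float = 24.0
    band_sd: Dict[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: {g: DEFAULT_BAND_SD[g] for g in GROUPS}
    )
    #: between-patient lognormal sigma of each band's SD multiplier
    band_sigma: Tuple[float, float, float, float] = (0.30, 0.25, 0.25, 0.50)
    #: within-band spectral slope (power spectrum ~ f**-alpha)
    band_alpha: Tuple[float, float, float, float] = (2.0, 0.0, 0.0, 0.0)
    sinusoids_per_band: int = 20
    artifact_rate: float = 1.0  # expected artifact spikes per hour
    artifact_amp: float = 60.0  # mmHg; must exceed the 30 mmHg filter threshold
    gap_rate: float = 2.0  # expected monitoring gaps per record
    gap_mean_s: float = 120.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_favorable < 1:
            raise ConfigError("n_favorable must be >= 1")
        if self.n_unfavorable < 1:
            raise ConfigError("n_unfavorable must be >= 1")
        if self.duration_h <= 0:
            raise ConfigError("duration_h must be > 0")
        if self.fs <= 0:
            raise ConfigError("fs must be > 0")
        if self.sinusoids_per_band < 1:
            raise ConfigError("sinusoids_per_band must be >= 1")
        if not np.isclose(sum(self.truncation_probs), 1.0):
            raise ConfigError("truncation_probs must sum to 1")
        if any(p < 0 for p in self.truncation_probs):
            raise ConfigError("truncation_probs must be non-negative")
        for group in GROUPS:
            if group not in self.band_sd:
                raise ConfigError(f"band_sd missing group {group!r}")
            sds = self.band_sd[group]
            if len(sds) != len(BAND_EDGES) or any(s < 0 for s in sds):
                raise ConfigError(f"band_sd[{group!r}] must hold 4 values >= 0")
        if any(s < 0 for s in self.band_sigma):
            raise ConfigError("band_sigma values must be >= 0")
        if self.artifact_rate < 0:
            raise ConfigError("artifact_rate must be >= 0")
        if 0 < self.artifact_amp <= 30 and self.artifact_rate > 0:
            logger.warning(
                "artifact_amp %.1f mmHg does not exceed the 30 mmHg filter "
                "threshold; injected artifacts will not be removable",
                self.artifact_amp,
            )
        if self.gap_rate < 0:
            raise ConfigError("gap_rate must be >= 0")
        if self.gap_mean_s <= 0:
            raise ConfigError("gap_mean_s must be > 0")

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


def _draw_duration_h(config: SynthConfig, rng: np.random.Generator) -> float:
    cat = rng.choice(3, p=np.asarray(config.truncation_probs) / sum(config.truncation_probs))
    if cat == 0:
        return config.duration_h
    if cat == 1:
        lo, hi = config.truncation_mid_h
    else:
        lo, hi = config.truncation_short_h
    return float(rng.uniform(lo, min(hi, config.duration_h)))


def _band_bins(n: int, fs: float, f_lo: float, f_hi: float) -> np.ndarray:
    """DFT bin indices of an rFFT of length-n whose frequency lies in [f_lo, f_hi)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = (freqs >= f_lo) & (freqs < f_hi) & (freqs > 0)
    if n % 2 == 0:
        sel[n // 2] = False  # the Nyquist bin carries no phase freedom
    return np.flatnonzero(sel)


def generate_trace(
    config: SynthConfig,
    group: str,
    rng: np.random.Generator,
    patient_id: str = "P000",
    duration_h: Optional[float] = None,
) -> BPTrace:
    """One synthetic patient trace: baseline + diurnal + band noise + artifacts + gaps."""
    config.validate()
    if group not in GROUPS:
        raise ConfigError(f"group must be one of {GROUPS}, got {group!r}")
    if duration_h is None:
        duration_h = _draw_duration_h(config, rng)
    n = int(round(duration_h * 3600.0 * config.fs))
    if n < 2:
        raise ConfigError("duration_h too short for the configured fs")
    t = np.arange(n) / config.fs

    level = config.mean_sbp + (rng.normal(0.0, config.mean_sd) if config.mean_sd > 0 else 0.0)
    x = np.full(n, level)

    if config.diurnal_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += config.diurnal_amp * np.sin(
            2.0 * np.pi * t / (config.diurnal_period_h * 3600.0) + phase
        )

    spectrum = np.zeros(n // 2 + 1, dtype=complex)
    any_band = False
    for (f_lo, f_hi), sd, sigma, alpha in zip(
        BAND_EDGES, config.band_sd[group], config.band_sigma, config.band_alpha
    ):
        if sd == 0:
            continue
        f_hi = min(f_hi, config.fs / 2.0)
        bins = _band_bins(n, config.fs, f_lo, f_hi)
        if bins.size == 0:
            logger.warning(
                "record too short to host band [%g, %g) Hz; band skipped", f_lo, f_hi
            )
            continue
        sd_patient = sd * (rng.lognormal(0.0, sigma) if sigma > 0 else 1.0)
        k = min(config.sinusoids_per_band, bins.size)
        all_freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
        if alpha != 0:
            # importance-draw bins where the f**-alpha spectrum has its power,
            # so the dominant slow components are present in every record
            density = all_freqs[bins] ** (-alpha)
            chosen = rng.choice(bins, size=k, replace=False, p=density / density.sum())
        else:
            chosen = rng.choice(bins, size=k, replace=False)
        freqs = all_freqs[chosen]
        # amplitude ~ f**(-alpha/2) gives a power spectrum ~ f**-alpha within
        # the band; normalized so the total band variance is sd_patient**2
        w = freqs ** (-alpha / 2.0) if alpha != 0 else np.ones(k)
        amps = sd_patient * np.sqrt(2.0) * w / np.linalg.norm(w)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
        spectrum[chosen] += (n * amps / 2.0) * np.exp(1j * phases)
        any_band = True
    if any_band:
        x += np.fft.irfft(spectrum, n=n)

    valid = np.ones(n, dtype=bool)
    if config.gap_rate > 0:
        for _ in range(rng.poisson(config.gap_rate)):
            length = max(1, int(round(rng.exponential(config.gap_mean_s) * config.fs)))
            start = int(rng.integers(0, n))
            valid[start : start + length] = False

    if config.artifact_rate > 0 and config.artifact_amp != 0:
        n_art = rng.poisson(config.artifact_rate * duration_h)
        pool = np.flatnonzero(valid)
        if pool.size and n_art:
            pos = rng.choice(pool, size=min(n_art, pool.size), replace=False)
            x[pos] += rng.choice([-1.0, 1.0], size=pos.size) * config.artifact_amp

    x[~valid] = np.nan
    return BPTrace(patient_id=patient_id, channel=config.channel, t=t, x=x, valid=valid)


def generate_cohort(config: SynthConfig) -> List[Tuple[BPTrace, str]]:
    """Labelled cohort of ``n_favorable + n_unfavorable`` traces.

    Per-patient random streams are spawned from the master seed by patient
    index, so each patient's trace is independent of cohort composition order.
    """
    config.validate()
    labels = ["favorable"] * config.n_favorable + ["unfavorable"] * config.n_unfavorable
    children = np.random.SeedSequence(config.seed).spawn(len(labels))
    cohort = []
    for i, (label, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        trace = generate_trace(config, label, rng, patient_id=f"P{i + 1:03d}")
        cohort.append((trace, label))
    return cohort
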