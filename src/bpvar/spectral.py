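"""Band power of a blood-pressure series via the discrete Fourier transform.

The power of a frequency band is the sum of normalised squared DFT magnitudes
over the bins whose frequency ``f_k = k / (N * t_s)`` falls in the half-open
band ``[f_start, f_end)``::

    P = sum_{k: f_k in band} (1/N^2) |BP_hat_k|^2   [mmHg^2]

computed one-sided: the series is mean-subtracted (the mean is level, not
variability, so the DC bin is excluded), positive-frequency bins are doubled
to account for their conjugate-symmetric partners, and the Nyquist bin (when
present) is not doubled.  With this convention the powers of contiguous bands
add up exactly to the population variance of the series (Parseval), so
"power" is interpretable in mmHg^2.

The four default bands for a 1 Hz record are low (0, 1/20 min), midrange
[1/20 min, 1/5 min), high [1/5 min, 1/1 min) and very high [1/1 min, fs/2].
No taper or detrending beyond mean removal is applied, and series are
transformed at their full length (no zero padding, which would change the
frequency resolution and the per-bin band assignment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, DataError
from .preprocessing import interpolate_gaps
from .traces import BPTrace

BAND_NAMES = ("low", "midrange", "high", "very_high")


@dataclass(frozen=True)
class FrequencyBand:
    """Half-open frequency band [f_start, f_end) in Hz."""

    name: str
    f_start: float
    f_end: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_start < self.f_end:
            raise ConfigError(f"band {self.name!r}: need 0 <= f_start < f_end")


def default_bands(fs: float = 1.0) -> Tuple[FrequencyBand, ...]:
    """The four contiguous bands: low, midrange, high, very high."""
    return (
        FrequencyBand("low", 0.0, 1.0 / 1200.0),
        FrequencyBand("midrange", 1.0 / 1200.0, 1.0 / 300.0),
        FrequencyBand("high", 1.0 / 300.0, 1.0 / 60.0),
        FrequencyBand("very_high", 1.0 / 60.0, fs / 2.0),
    )


@dataclass
class BandPowerSet:
    """Per-band power (mmHg^2) with the transform geometry behind it."""

    powers: Dict[str, float]
    n_samples: int
    t_s: float  # sampling interval, seconds
    df: float  # frequency resolution 1/(N * t_s), Hz
    total_power_ex_dc: float

    def __getitem__(self, band: str) -> float:
        return self.powers[band]


def _series_of(series, fs):
    if isinstance(series, BPTrace):
        if not series.clean_valid.all():
            raise DataError(
                "series contains gaps or removed points; apply interpolate_gaps first"
            )
        return series.x, series.fs
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("series contains non-finite values; apply interpolate_gaps first")
    if fs is None:
        raise ConfigError("fs is required when passing a bare array")
    return x, float(fs)


def band_power(
    series,
    fs: Optional[float] = None,
    bands: Optional[Sequence[FrequencyBand]] = None,
) -> BandPowerSet:
    """One-sided DFT band power of a uniform gap-free series."""
    x, fs = _series_of(series, fs)
    n = x.size
    if n < 4:
        raise DataError("need at least 4 samples for band power")
    nyquist = fs / 2.0
    if bands is None:
        bands = default_bands(fs)
    for b in bands:
        if b.f_end > nyquist * (1 + 1e-12):
            raise ConfigError(f"band {b.name!r}: f_end {b.f_end} exceeds the Nyquist {nyquist}")

    spectrum = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    per_bin = np.abs(spectrum) ** 2 / n ** 2
    mult = np.full(freqs.size, 2.0)
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0  # Nyquist bin has no conjugate partner
    weighted = per_bin * mult

    powers = {}
    for b in bands:
        sel = (freqs >= b.f_start) & (freqs < b.f_end)
        if b.f_end >= nyquist * (1 - 1e-12):
            sel |= np.isclose(freqs, nyquist)  # close the top band at Nyquist
        sel[0] = False  # DC is level, not variability
        powers[b.name] = float(weighted[sel].sum())

    return BandPowerSet(
        powers=powers,
        n_samples=n,
        t_s=1.0 / fs,
        df=fs / n,
        total_power_ex_dc=float(weighted[1:].sum()),
    )


def spectral_battery(
    trace: BPTrace, bands: Optional[Sequence[FrequencyBand]] = None
) -> BandPowerSet:
    """Band power of a preprocessed trace at its native resolution.

    Internal gaps (monitoring gaps and removed artifacts) are filled by
    linear interpolation first; the spectral stage always works on the
    full-resolution series.
    """
    return band_power(interpolate_gaps(trace), bands=bands)
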