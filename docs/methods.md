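# Methods

## Scope and data model

`bpvar` operates on per-patient, per-channel BP time series (`BPTrace`):
pressures in mmHg on a uniform nominal grid (1 Hz by default), timestamps in
seconds from record start, and an explicit validity mask. Monitoring gaps
are invalid samples, never deleted rows, so binning and FFT can rely on the
uniform grid throughout. Preprocessing produces a `CleanTrace` carrying two
further annotations: points removed as artifacts and successive-difference
positions excluded from ARV/SV.

The pipeline order is fixed: threshold filter → 3-SD difference masking →
time-domain indices on the *non-interpolated* data, and gap interpolation →
spectral band power. Outcome labels enter only at the comparison stage;
per-patient computation never sees them.

## Preprocessing

**Threshold filter.** Each valid point is compared with the average of the
other valid points in a centred window; points deviating by more than
30 mmHg are removed and become gaps. The threshold is standard for 1 Hz
numerics; the window length is a free parameter and defaults to 61 s — long
enough that a single spike cannot drag the local average, short enough to
track genuine trends. The filter runs in a single pass; a sustained level
shift (> window length) is never removed, because the average adapts.

**3-SD difference mask.** Within contiguous valid segments, successive
differences `d_i = BP_{i+1} − BP_i` are computed; per patient, their SD is
computed once, and differences with `|d_i − mean(d)| > 3·SD(d)` are masked
from ARV/SV. Centring makes the rule idempotent and keeps a constant
nonzero drift (all diffs equal, SD = 0) unmasked. Masked pairs contribute
nothing; the ARV/SV denominator counts only differences actually used.
Differences are never formed across gaps or removed points — a gap-spanning
"difference" is not a successive measurement.

**Gap interpolation** (spectral stage only) fills internal gaps linearly
between flanking valid samples and trims leading/trailing gaps rather than
extrapolating. Valid samples pass through bit-identical.

## Indices under missingness

SD/CV use all valid samples. ARV/SV replace the printed `n − 1` denominator
by the count of usable differences (unbiased averaging under missingness);
TC keeps the total valid sample count `n` in its denominator, staying
literal to the printed formula, and counts only strict sign changes (flat
steps are not trend changes). Indices whose minimum sample count is not met
(2 for SD/CV/ARV/SV, 3 for TC) are reported as NaN with a logged reason —
never 0, since zero variability is informative.

## Downsampling

Bins are half-open `[kΔ, (k+1)Δ)` anchored at record start.
*Instantaneous*: the first valid sample in each bin (the reading a
low-frequency monitor would have kept); a bin with no valid sample is
invalid. *Averaging*: the arithmetic mean of the bin's valid samples;
bins with less than 50% of their nominal sample count (configurable) are
invalid, preventing single-sample "means" inside gappy bins. The sweep grid
{1 s, 5 s, 10 s, 30 s, 1, 2, 5, 10, 15, 30 min} spans the 1 s–30 min range
and contains every reference time bin used by the headline comparisons.

For a sinusoid at frequency `f`, discrete bin averaging applies the exact
Dirichlet gain `|sin(πfΔ) / (Δ·sin(πf))|` (→ the textbook `sinc(πfΔ)` for
small `f`), which is what makes averaged SV a band-limited variability
measure while instantaneous SV receives aliased full-amplitude noise.

## Spectral convention

The DFT is taken at full record length (no zero-padding, which would change
`Δf` and the per-bin band assignment), with no taper and no detrending
beyond mean subtraction; DC is excluded (the mean is level, not
variability). Summation is one-sided with doubled positive-frequency bins
(Nyquist undoubled), so the four contiguous band powers add exactly to the
series variance (Parseval; asserted to 1e−9 relative in tests). Band edges
are half-open `[f_start, f_end)` with the top band closed at Nyquist.
Whether a two-sided (halved) convention was intended by any given published
table is generally ambiguous; absolute powers under the other convention
differ by exactly a factor 2, while all group contrasts are unaffected.

## Group statistics

Mann–Whitney U, two-sided: exact null distribution when the pooled sample
is tie-free and ≤ 20, tie-corrected normal approximation with continuity
correction otherwise. AUC is oriented as `P(unfavorable > favorable)` with
ties counting 1/2 and equals `U/(n₁·n₂)` exactly. The 95% CI is
Hanley–McNeil by default; a stratified bootstrap (2000 resamples, seeded)
is available and the method used is recorded in every output row. Fisher's
exact test covers 2×2 tables. No multiple-testing correction is applied
across sweep grids — the p-value surfaces are exploratory, and this is
stated in the outputs' documentation rather than silently corrected.

The duration sweep truncates every record to its first *d* hours
(record-start anchored, d = 1…24); patients with shorter records contribute
whatever they have, so early durations include all patients.

## Synthetic cohort generator

The generator is the package's test bed and default input. Per patient it
sums:

- a constant level (mean 130 mmHg SBP, between-patient SD 18 mmHg);
- a diurnal sinusoid (default 5 mmHg amplitude, 24 h period, random phase);
- four independent band-limited processes, one per analysis band, each a
  sum of K = 20 random-phase sinusoids on the record's own DFT bins inside
  the band. On-grid frequencies make band confinement exact and the
  realized band power equal to the target SD squared over the full record,
  so spectral tests have exact oracles. Within the low band the power
  spectrum falls as `f⁻²` (bins importance-drawn and amplitude-weighted):
  the sub-1/20-min energy of real records is diurnal-scale trend, not
  20-minute cycles. The other bands are spectrally flat.
- artifact spikes (Poisson, default 1/h, ±60 mmHg — safely beyond the
  30 mmHg filter threshold) and monitoring gaps (Poisson, exponential
  lengths, mean 2 min).

Group structure: the outcome label selects the per-band target SDs.
Defaults are the square roots of typical per-band power medians in
post-thrombectomy cohorts — favorable (7.96, 2.60, 2.12, 1.26) mmHg vs
unfavorable (8.58, 3.55, 2.22, 1.36) mmHg, i.e. an unfavorable:favorable
midrange power ratio ≈ 1.9 and near-identical other bands. Between-patient
heterogeneity is lognormal per band with SD-scale sigmas (0.30, 0.25, 0.25,
0.50), matched to the interquartile spread such cohorts show per band.
Record lengths follow a 23:5:5 categorical split between complete 24 h,
uniform 12–24 h, and uniform 4–12 h. Per-patient RNG streams are spawned
from the master seed by patient index, so cohorts are bit-reproducible and
insertion-order independent.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: baroreflex and autoregulatory dynamics,
heartbeat-level waveform shape, atrial fibrillation, medication effects,
heavy-tailed artifact families, nonstationary band power. The generator
reproduces second-order (spectral) structure only; recovery results say the
*pipeline* detects the spectral contrasts it was given at realistic n, not
that real cohorts carry them.

## Numerical and design choices

- Moving-average filter excludes the candidate point from its own average
  (a spike must not vouch for itself) and uses only valid neighbours;
  points with no valid neighbour in the window are kept.
- Undefined statistics propagate as NaN and are dropped groupwise by the
  comparison stage, with counts logged.
- CSV outputs are written with a fixed float format; identical
  (config, seed, data) reruns produce byte-identical CSVs.
- Headline comparison bins (mean/ARV/SV at 5 min, SD/TC at 2 min, CV at
  1 min, averaging) are computed directly from the clean traces, so they
  need not lie on the sweep grid.
- Cohort storage is one CSV per patient-channel plus a manifest; gaps are
  explicit rows. No binary container format is used.

## Problem sizes used by the test suite

Simulation-based tests state their sizes explicitly as the package's chosen
study conditions: the end-to-end recovery property runs 100 replicates of
the full 34-patient, 24 h, 1 Hz cohort; generator detectability runs 100
replicates on 2 h records (record length does not enter that property);
type-I calibration uses 1000 null cohorts of per-patient values; sweep
pattern tests use 5–9 replicates on 8–24 h cohorts with a doubled midrange
SD. Stochastic tests are seeded and derandomized.

## Known limitations

- The instantaneous sampler anchors at bin starts; a nearest-to-centre
  variant would differ for asymmetric gap patterns.
- Hanley–McNeil CIs are distribution-based approximations; at n = 10 vs 24
  with AUC near 1 they clip at the boundary.
- Band powers from gap-interpolated series are biased low in proportion to
  gap fraction (interpolation inserts no variability); tests bound the
  perturbation for small gaps but long outages remain a caveat.
- The exact two-sided Mann–Whitney p is only used for pooled n ≤ 20 without
  ties; cohort-scale comparisons use the tie-corrected approximation.
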