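"""Artifact removal and gap handling for 1 Hz blood-pressure records.

Pipeline order is fixed: :func:`threshold_filter` (moving-average spike
removal) -> :func:`mask_extreme_diffs` (3-SD masking of successive differences
for ARV/SV) -> either the time-domain indices on the non-interpolated data, or
:func:`interpolate_gaps` followed by the spectral stage.

The moving-average filter compares each valid point to the centred average of
the other valid points within a window (default 61 s) and removes points
deviating by more than a threshold (default 30 mmHg); removed points become
gaps.  The difference mask computes, per patient, the SD of all successive
differences within contiguous segments once, and excludes differences farther
than 3 SD from their mean — differences are never taken across gaps.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .errors import DataError
from .traces import BPTrace, CleanTrace, as_clean

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 61.0
DEFAULT_THRESHOLD_MMHG = 30.0
DEFAULT_DIFF_SD_MULTIPLE = 3.0


def _centered_window_sums(a: np.ndarray, half: int) -> np.ndarray:
    """Sum of a[i-half .. i+half] (clipped at the edges) for every i."""
    csum = np.concatenate(([0.0], np.cumsum(a)))
    idx = np.arange(a.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, a.size)
    return csum[hi] - csum[lo]


def threshold_filter(
    trace: BPTrace,
    window_s: float = DEFAULT_WINDOW_S,
    threshold_mmhg: float = DEFAULT_THRESHOLD_MMHG,
) -> CleanTrace:
    """Remove points deviating more than ``threshold_mmhg`` from the local moving average.

    The average at a point is taken over valid points within a centred window
    of ``window_s`` seconds, excluding the point itself (a spike must not
    vouch for itself).  Applied in a single pass.
    """
    if window_s <= 0:
        raise DataError("window_s must be > 0")
    ct = as_clean(trace)
    valid = ct.clean_valid
    if not valid.any():
        raise DataError("no valid samples")
    half = max(int(round(window_s * ct.fs)) // 2, 1)
    vf = valid.astype(float)
    xv = np.where(valid, ct.x, 0.0)
    neighbour_sum = _centered_window_sums(xv, half) - xv
    neighbour_cnt = _centered_window_sums(vf, half) - vf
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = neighbour_sum / neighbour_cnt
        deviation = np.abs(ct.x - avg)
    removed = valid & (neighbour_cnt > 0) & (deviation > threshold_mmhg)
    logger.info(
        "%s/%s: threshold filter removed %d of %d valid points",
        ct.patient_id, ct.channel, int(removed.sum()), int(valid.sum()),
    )
    return replace(ct, removed=ct.removed | removed)


def mask_extreme_diffs(
    trace: CleanTrace, sd_multiple: float = DEFAULT_DIFF_SD_MULTIPLE
) -> CleanTrace:
    """Mask successive differences farther than ``sd_multiple`` SD from their mean.

    Differences are formed only between adjacent samples that are both usable
    (segment-wise; never across gaps or removed artifacts).  The SD is
    computed once per patient from all such differences; the criterion is
    applied to mean-centred differences in a single pass, so re-running the
    operation reproduces the same mask and a constant nonzero drift masks
    nothing.  Pressure values are unchanged; only ``diff_excluded`` is set.
    """
    cv = trace.clean_valid
    pair = cv[:-1] & cv[1:]
    d = np.diff(trace.x)
    dd = d[pair]
    if dd.size < 2:
        logger.warning(
            "%s/%s: fewer than 2 successive differences; nothing masked",
            trace.patient_id, trace.channel,
        )
        return replace(trace, diff_excluded=np.zeros(trace.n - 1, dtype=bool))
    sd = float(np.std(dd, ddof=1))
    centre = float(np.mean(dd))
    if sd == 0:
        excluded = np.zeros(trace.n - 1, dtype=bool)
    else:
        with np.errstate(invalid="ignore"):
            excluded = pair & (np.abs(d - centre) > sd_multiple * sd)
    logger.info(
        "%s/%s: masked %d of %d successive differences (SD %.3f mmHg)",
        trace.patient_id, trace.channel, int(excluded.sum()), int(dd.size), sd,
    )
    return replace(trace, diff_excluded=excluded)


def interpolate_gaps(trace: BPTrace) -> CleanTrace:
    """Fill internal gaps by linear interpolation between flanking valid samples.

    Leading and trailing gaps are trimmed, never extrapolated.  Valid samples
    are returned bit-identical; the result is a gap-free uniform series for
    the spectral stage only.
    """
    ct = as_clean(trace)
    cv = ct.clean_valid
    if cv.sum() < 2:
        raise DataError("need at least 2 valid samples to interpolate")
    idx = np.flatnonzero(cv)
    i0, i1 = idx[0], idx[-1] + 1
    tt = ct.t[i0:i1]
    xx = np.interp(tt, ct.t[cv], ct.x[cv])
    return CleanTrace(
        ct.patient_id, ct.channel, tt, xx, np.ones(tt.size, dtype=bool)
    )


def preprocess(
    trace: BPTrace,
    window_s: float = DEFAULT_WINDOW_S,
    threshold_mmhg: float = DEFAULT_THRESHOLD_MMHG,
    sd_multiple: float = DEFAULT_DIFF_SD_MULTIPLE,
) -> CleanTrace:
    """Standard preprocessing: threshold filter then difference masking."""
    return mask_extreme_diffs(
        threshold_filter(trace, window_s=window_s, threshold_mmhg=threshold_mmhg),
        sd_multiple=sd_multiple,
    )
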