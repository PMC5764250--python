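"""Targeted extracted-ion chromatograms and single-peak detection.

For each monitored peptide an XIC is built by summing, per MS1 scan, the
centroid intensities within ±5 ppm of the theoretical m/z, restricted to
scans within ±240 s of the expected retention time (both tolerances
configurable; the RT window defaults to the whole run when no expected RT
is configured). One chromatographic peak per target is then detected,
yielding apex RT, height, trapezoidal area, FWHM and the intensity-weighted
observed m/z — the per-run observations behind the peak-area, mass-accuracy,
RT-drift, resolution and peak-capacity metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d

from .mzml_io import RunData
from .peptide_chem import PeptideTarget

__all__ = ["Trace", "Feature", "extract_xic", "detect_peak", "PPM_TOL", "RT_TOL"]

#: Default matching-window tolerances.
PPM_TOL = 5.0
RT_TOL = 240.0

#: Peak-span threshold as a fraction of apex height.
SPAN_FRACTION = 0.05
#: Apex must exceed this multiple of the median nonzero intensity.
NOISE_MULTIPLE = 5.0


@dataclass
class Trace:
    """An extracted ion chromatogram for one target.

    ``mz_moment`` holds, per scan, the sum of (m/z × intensity) over the
    matched centroids, so the intensity-weighted observed m/z over any
    span is ``mz_moment.sum() / intensity.sum()``.
    """

    rt: np.ndarray
    intensity: np.ndarray
    mz_moment: np.ndarray
    target: PeptideTarget
    mz_window: tuple[float, float]
    rt_window: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.rt) != len(self.intensity):
            raise ValueError("rt and intensity arrays must have equal length")
        if len(self.rt) > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("rt array must be strictly ascending")


@dataclass
class Feature:
    """One detected chromatographic peak (or its absence)."""

    target: PeptideTarget
    found: bool
    apex_rt: Optional[float] = None
    height: Optional[float] = None
    area: Optional[float] = None
    fwhm: Optional[float] = None
    observed_mz: Optional[float] = None


def extract_xic(
    run: RunData,
    target: PeptideTarget,
    ppm_tol: float = PPM_TOL,
    rt_tol: float = RT_TOL,
) -> Trace:
    """Extract the target's ion chromatogram from a run.

    MS1 mode: per-scan summed intensity of centroids with
    |m/z − theoretical| ≤ ppm_tol·1e-6·theoretical, over scans with
    |RT − expected_rt| ≤ rt_tol (whole run when expected_rt is unset).
    SRM mode (runs carrying chromatograms and no MS1 spectra): returns the
    chromatogram whose annotation matches the target.
    """
    if target.theoretical_mz is None:
        raise ValueError(f"target {target.sequence} has no theoretical m/z")
    mz0 = target.theoretical_mz
    lo = mz0 * (1.0 - ppm_tol * 1e-6)
    hi = mz0 * (1.0 + ppm_tol * 1e-6)
    if target.expected_rt is not None:
        rt_lo, rt_hi = target.expected_rt - rt_tol, target.expected_rt + rt_tol
    else:
        rt_lo, rt_hi = -np.inf, np.inf

    ms1 = run.ms1_spectra()
    if not ms1 and run.chromatograms:
        return _srm_trace(run, target, lo, hi, (rt_lo, rt_hi))

    rts, ints, moments = [], [], []
    for s in ms1:
        if not rt_lo <= s.rt <= rt_hi:
            continue
        i0 = np.searchsorted(s.mz, lo, side="left")
        i1 = np.searchsorted(s.mz, hi, side="right")
        seg = s.intensity[i0:i1]
        rts.append(s.rt)
        ints.append(float(seg.sum()))
        moments.append(float((s.mz[i0:i1] * seg).sum()))
    return Trace(
        rt=np.asarray(rts, dtype=float),
        intensity=np.asarray(ints, dtype=float),
        mz_moment=np.asarray(moments, dtype=float),
        target=target,
        mz_window=(lo, hi),
        rt_window=(rt_lo, rt_hi),
    )


def _srm_trace(run, target, lo, hi, rt_window) -> Trace:
    match = None
    for c in run.chromatograms:
        if target.sequence in c.id:
            match = c
            break
        if c.precursor_mz is not None and lo <= c.precursor_mz <= hi:
            match = c
    if match is None:
        return Trace(
            rt=np.empty(0),
            intensity=np.empty(0),
            mz_moment=np.empty(0),
            target=target,
            mz_window=(lo, hi),
            rt_window=rt_window,
        )
    sel = (match.rt >= rt_window[0]) & (match.rt <= rt_window[1])
    inten = match.intensity[sel]
    mz_c = match.precursor_mz if match.precursor_mz is not None else target.theoretical_mz
    return Trace(
        rt=match.rt[sel],
        intensity=inten,
        mz_moment=inten * mz_c,
        target=target,
        mz_window=(lo, hi),
        rt_window=rt_window,
    )


def detect_peak(
    trace: Trace,
    span_fraction: float = SPAN_FRACTION,
    noise_multiple: float = NOISE_MULTIPLE,
) -> Feature:
    """Detect the single best chromatographic peak in a trace.

    The apex is located as the global maximum after 3-point moving-average
    smoothing (refined to the raw maximum among its immediate neighbours);
    the reported apex RT is then refined off the sampling grid by parabolic
    interpolation through the apex sample and its neighbours, so that
    longitudinal retention-time statistics are not quantized to the MS1
    scan interval.
    The peak span is the contiguous region above ``span_fraction`` of the
    apex height, extended outward while samples keep strictly decreasing so
    the tails are integrated down to baseline. Area is the trapezoidal
    integral of the raw intensities over the span; FWHM is the raw-trace
    width at half the apex height with linear interpolation at the
    crossings; observed m/z is the intensity-weighted mean over the span.

    A peak is reported only when the apex exceeds ``noise_multiple`` times
    the median nonzero intensity (any nonzero apex qualifies when the trace
    has fewer than 5 nonzero samples); otherwise ``found`` is False and the
    numeric fields are absent — absence is a value, not an error.
    """
    n = len(trace.intensity)
    if n == 0 or float(trace.intensity.max(initial=0.0)) <= 0.0:
        return Feature(target=trace.target, found=False)

    raw = trace.intensity
    smooth = uniform_filter1d(raw, size=3, mode="nearest") if n >= 3 else raw
    apex = int(np.argmax(smooth))
    lo_n = max(apex - 1, 0)
    apex = lo_n + int(np.argmax(raw[lo_n : apex + 2]))
    height = float(raw[apex])
    if height <= 0.0:
        return Feature(target=trace.target, found=False)

    nonzero = raw[raw > 0]
    if len(nonzero) >= 5 and height < noise_multiple * float(np.median(nonzero)):
        return Feature(target=trace.target, found=False)

    thr = span_fraction * height
    left = apex
    while left - 1 >= 0 and raw[left - 1] > thr:
        left -= 1
    while left - 1 >= 0 and raw[left - 1] < raw[left]:
        left -= 1
    right = apex
    while right + 1 < n and raw[right + 1] > thr:
        right += 1
    while right + 1 < n and raw[right + 1] < raw[right]:
        right += 1

    apex_rt = _parabolic_apex(trace.rt, raw, apex)

    span = slice(left, right + 1)
    area = float(np.trapezoid(raw[span], trace.rt[span]))
    fwhm = _width_at(trace.rt, raw, apex, left, right, height / 2.0)
    total = float(raw[span].sum())
    observed_mz = float(trace.mz_moment[span].sum()) / total if total > 0 else None

    return Feature(
        target=trace.target,
        found=True,
        apex_rt=apex_rt,
        height=height,
        area=area,
        fwhm=fwhm,
        observed_mz=observed_mz,
    )


def _parabolic_apex(rt, raw, apex: int) -> float:
    """Sub-sample apex RT via a parabola through the apex and neighbours.

    Falls back to the grid apex at trace edges or on a degenerate (flat)
    triple; the result is clamped to the neighbouring sample RTs.
    """
    if apex == 0 or apex == len(raw) - 1:
        return float(rt[apex])
    y0, y1, y2 = raw[apex - 1], raw[apex], raw[apex + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0.0:  # not concave: flat top or numerical tie
        return float(rt[apex])
    # uniform-grid vertex offset in units of the local spacing
    delta = 0.5 * (y0 - y2) / denom
    step = 0.5 * (rt[apex + 1] - rt[apex - 1])
    return float(np.clip(rt[apex] + delta * step, rt[apex - 1], rt[apex + 1]))


def _width_at(rt, raw, apex, left, right, level) -> float:
    """Peak width at ``level`` with linear interpolation at the crossings.

    When a side never drops below ``level`` inside the span (truncated
    peak), that side's span edge is used.
    """
    t_lo = rt[left]
    for i in range(apex, left, -1):
        if raw[i - 1] <= level < raw[i]:
            frac = (raw[i] - level) / (raw[i] - raw[i - 1])
            t_lo = rt[i] - frac * (rt[i] - rt[i - 1])
            break
    t_hi = rt[right]
    for i in range(apex, right):
        if raw[i + 1] <= level < raw[i]:
            frac = (raw[i] - level) / (raw[i] - raw[i + 1])
            t_hi = rt[i] + frac * (rt[i + 1] - rt[i])
            break
    return float(t_hi - t_lo)
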