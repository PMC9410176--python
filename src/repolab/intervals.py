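"""Interval measurement on lead V5: QT, Bazett QTc, Tp-e and ratios.

The end of the T wave is found with the tangent method: the line tangent to
the steepest post-peak slope of the T wave is intersected with the
isoelectric baseline (estimated from the 40 ms preceding the QRS onset).
QT runs from the QRS onset to that intersection; Tp-e from the T peak to
it.  QTc applies Bazett's correction QT / sqrt(RR) with RR in seconds.
Inverted T waves are handled symmetrically (steepest *rising* slope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decomposition import Landmarks
from .errors import InvalidRRError, NoTDownslopeError

#: Isoelectric estimation window before the QRS onset (s).
ISOELECTRIC_S = 0.040
#: Least-squares window for the local slope estimate (s).
SLOPE_FIT_S = 0.010
#: How far past the T peak to search for the steepest slope (s).
DOWNSLOPE_SEARCH_S = 0.300
#: T-peak refinement window around the hint (s).
PEAK_REFINE_S = 0.030


@dataclass
class IntervalMeasures:
    """V5 interval set for one beat."""
    qt: float        # ms
    qtc: float       # ms
    tpe: float       # ms
    tpe_qt: float    # unitless
    tpe_qtc: float   # unitless
    rr: float        # s

    @classmethod
    def from_measurements(cls, qt_ms: float, tpe_ms: float, rr_s: float
                          ) -> "IntervalMeasures":
        """Derive QTc and both ratios from raw QT / Tp-e / RR measurements."""
        if rr_s <= 0:
            raise InvalidRRError("invalid RR")
        qtc = qt_ms / np.sqrt(rr_s)
        return cls(qt=qt_ms, qtc=qtc, tpe=tpe_ms,
                   tpe_qt=tpe_ms / qt_ms, tpe_qtc=tpe_ms / qtc, rr=rr_s)

    def report(self) -> dict:
        """Rounded values as reported: intervals to 0.1 ms, ratios to 2 dp."""
        return {"qt_ms": round(self.qt, 1), "qtc_ms": round(self.qtc, 1),
                "tpe_ms": round(self.tpe, 1), "tpe_qt": round(self.tpe_qt, 2),
                "tpe_qtc": round(self.tpe_qtc, 2), "rr_s": round(self.rr, 3)}


def _local_slopes(y: np.ndarray, fs: float, fit_s: float) -> np.ndarray:
    """Least-squares slope of ``y`` (per second) in a centred window."""
    half = max(1, int(round(fit_s * fs / 2)))
    k = np.arange(-half, half + 1) / fs
    weights = k / np.sum(k ** 2)
    slopes = np.full(y.size, np.nan)
    valid = np.convolve(y, weights[::-1], mode="valid")
    slopes[half:y.size - half] = valid
    return slopes


def tangent_t_end(v5_beat: np.ndarray, fs: float, t_peak_hint: int,
                  qrs_onset: int, iso_s: float = ISOELECTRIC_S,
                  fit_s: float = SLOPE_FIT_S) -> int:
    """T-wave end by the tangent method, as a sample index.

    The isoelectric level is the mean of the ``iso_s`` window ending at the
    QRS onset.  The T peak is refined to the extremum of the
    baseline-corrected signal within 30 ms of the hint; the steepest
    returning slope (10 ms least-squares fit) after the peak defines the
    tangent, whose intersection with the isoelectric level is returned,
    rounded to the nearest sample.
    """
    y = np.asarray(v5_beat, dtype=float)
    n = y.size
    # the energy-based QRS onset marks the maximal upslope, i.e. a point
    # already inside the complex, so the isoelectric window is backed off by
    # its own width to sit on the PR segment
    iso_hi = max(1, qrs_onset - int(round(iso_s * fs)))
    iso_lo = max(0, iso_hi - int(round(iso_s * fs)))
    iso = float(np.mean(y[iso_lo:iso_hi]))

    half = max(1, int(round(PEAK_REFINE_S * fs)))
    lo, hi = max(0, t_peak_hint - half), min(n, t_peak_hint + half + 1)
    rel = y[lo:hi] - iso
    tp = lo + int(np.argmax(np.abs(rel)))
    upright = y[tp] >= iso

    search_hi = min(n, tp + int(round(DOWNSLOPE_SEARCH_S * fs)) + 1)
    slopes = _local_slopes(y, fs, fit_s)
    seg = slopes[tp + 1:search_hi]
    if seg.size == 0 or np.all(np.isnan(seg)):
        raise NoTDownslopeError("no T downslope")
    if upright:
        k = int(np.nanargmin(seg))
        slope = seg[k]
        if not slope < 0:
            raise NoTDownslopeError("no T downslope")
    else:
        k = int(np.nanargmax(seg))
        slope = seg[k]
        if not slope > 0:
            raise NoTDownslopeError("no T downslope")
    idx = tp + 1 + k
    # tangent through (idx, y[idx]); intersect with the isoelectric level
    x_cross = idx + (iso - y[idx]) / slope * fs
    return int(round(x_cross))


def measure_intervals(v5_beat: np.ndarray, landmarks: Landmarks, rr: float,
                      fs: float) -> IntervalMeasures:
    """QT, QTc, Tp-e and ratios from one V5 beat and its landmarks."""
    if rr <= 0:
        raise InvalidRRError("invalid RR")
    t_end = tangent_t_end(v5_beat, fs, t_peak_hint=landmarks.t_peak,
                          qrs_onset=landmarks.qrs_onset)
    qt = (t_end - landmarks.qrs_onset) / fs * 1000.0
    tpe = (t_end - landmarks.t_peak) / fs * 1000.0
    if not 0 < tpe < qt:
        raise NoTDownslopeError(
            f"inconsistent tangent intersection (qt={qt:.1f} ms, tpe={tpe:.1f} ms)")
    return IntervalMeasures.from_measurements(qt, tpe, rr)
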