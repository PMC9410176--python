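"""SVD reduction of the 8 independent leads and energy-based landmarking.

The 8xN beat matrix is factorised as ``X = U S V^T``; the first three
principal temporal components, scaled by their singular values, form the
3-D loop-space series ``s3 = (s1, s2, s3)``.  In well-recorded adult ECGs
these three components carry ~99% of the signal energy, so the beat's
spatial trajectory is faithfully represented by a 3-D loop.  The per-sample
squared norm of ``s3`` — the energy series ``e3d`` — is unimodal over the
QRS and T complexes and is used to place the six fiducial landmarks (QRS
onset/peak/offset from the maximum up/down slope, T start/peak/end from a
thresholded bump search).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import FlatTWaveError, ZeroEnergyBeatError

logger = logging.getLogger(__name__)

#: Duration (s) of the initial baseline window whose per-lead median is
#: subtracted before decomposition.
BASELINE_S = 0.08

#: Landmark search windows (s) and thresholds; operational defaults.
R_SEARCH_S = 0.06          # around the R hint
SLOPE_SEARCH_S = 0.10      # before/after R peak for QRS onset/offset
T_SEARCH_MIN_S = 0.08      # after QRS offset
T_SEARCH_MAX_S = 0.45
T_THRESHOLD_FRACTION = 0.05
T_DWELL_S = 0.02
#: Minimum T-peak energy relative to the R-peak energy for a T wave to count.
T_MIN_ENERGY_FRACTION = 0.01
#: Below this 3-component energy fraction a QC warning is logged.
ENERGY_FRACTION_WARN = 0.95


@dataclass
class DecomposedBeat:
    """Loop-space representation of one beat."""
    s3: np.ndarray                 # (3, N) components scaled by singular values
    weights: np.ndarray            # (8, 3) lead loadings (orthonormal columns)
    singular_values: np.ndarray    # (8,) descending
    energy_fraction_3: float       # in [0, 1]
    fs: float
    leads: np.ndarray              # (8, N) baseline-corrected input, for T-loop work

    def reconstruct(self) -> np.ndarray:
        """Rank-3 approximation of the 8-lead beat."""
        return self.weights @ self.s3


@dataclass
class EnergySeries:
    """Per-sample squared norm of the 3-D loop-space trajectory (mV^2)."""
    e3d: np.ndarray
    fs: float


@dataclass
class Landmarks:
    """Sample indices of the six fiducials, relative to the beat window."""
    qrs_onset: int
    r_peak: int
    qrs_offset: int
    t_start: int
    t_peak: int
    t_end: int

    def __post_init__(self) -> None:
        if not (self.qrs_onset < self.r_peak < self.qrs_offset
                < self.t_start <= self.t_peak < self.t_end):
            raise ValueError(f"landmark ordering violated: {self}")


def svd_decompose(eight_leads: np.ndarray, fs: float,
                  r_index: int | None = None) -> DecomposedBeat:
    """Reduce an (8, N) beat matrix to its top-3 loop-space components.

    The per-lead median of the first 80 ms is subtracted as a baseline
    estimate.  Component signs are fixed deterministically: each component is
    flipped so that its value at the R peak (``r_index``, defaulting to the
    energy argmax) is non-negative, with the maximum-absolute sample made
    positive as a tie-break.  A global sign convention does not affect any
    angle computed downstream; it exists so intermediates are reproducible.
    """
    x = np.asarray(eight_leads, dtype=float)
    if x.ndim != 2 or x.shape[0] != 8:
        raise ValueError("expected an (8, N) lead matrix")
    n = x.shape[1]
    if n <= 8:
        raise ValueError("beat too short: need more samples than leads")
    base = max(1, min(n, int(round(BASELINE_S * fs))))
    x = x - np.median(x[:, :base], axis=1, keepdims=True)
    if not np.any(x):
        raise ZeroEnergyBeatError("zero-energy beat")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    s3 = s[:3, None] * vt[:3]
    weights = u[:, :3].copy()
    ref = int(np.argmax(np.sum(s3 ** 2, axis=0))) if r_index is None else int(r_index)
    for k in range(3):
        val = s3[k, ref]
        if val < 0 or (val == 0 and s3[k, np.argmax(np.abs(s3[k]))] < 0):
            s3[k] *= -1
            weights[:, k] *= -1
    total = float(np.sum(s ** 2))
    frac = float(np.sum(s[:3] ** 2) / total)
    if frac < ENERGY_FRACTION_WARN:
        logger.warning("3-component energy fraction %.3f below %.2f",
                       frac, ENERGY_FRACTION_WARN)
    return DecomposedBeat(s3=s3, weights=weights, singular_values=s,
                          energy_fraction_3=frac, fs=fs, leads=x)


def energy_vector(decomposed: DecomposedBeat) -> EnergySeries:
    """The energy series e3d(t) = s1(t)^2 + s2(t)^2 + s3(t)^2."""
    return EnergySeries(e3d=np.sum(decomposed.s3 ** 2, axis=0), fs=decomposed.fs)


def _threshold_crossing(e3d: np.ndarray, t_peak: int, threshold: float,
                        dwell: int, direction: int) -> int:
    """First sample adjacent to t_peak's bump on the given side where e3d has
    stayed below ``threshold`` for at least ``dwell`` samples.

    ``direction`` is -1 for the T start (scan backwards) and +1 for the T
    end.  Returns the last above-threshold sample on that side, i.e. the
    bump boundary.  Falls back to the first sub-threshold sample (without the
    dwell requirement) and finally to the series edge.
    """
    n = e3d.size
    i = t_peak
    first_below = None
    while 0 <= i < n:
        if e3d[i] < threshold:
            if first_below is None:
                first_below = i
            lo = i + direction * (dwell - 1)
            seg = e3d[min(i, lo):max(i, lo) + 1] if 0 <= lo < n else None
            if seg is not None and seg.size >= dwell and np.all(seg < threshold):
                return i - direction
        else:
            first_below = None
        i += direction
    if first_below is not None:
        return first_below - direction
    return (0 if direction < 0 else n - 1)


def detect_landmarks(energy: EnergySeries, r_hint: int) -> Landmarks:
    """Locate QRS and T-wave fiducials on the energy series.

    * R peak: energy argmax within +/-60 ms of ``r_hint``.
    * QRS onset / offset: maximum up- / down-slope of e3d within 100 ms
      before / after the R peak.
    * T peak: energy argmax in [QRS offset + 80 ms, QRS offset + 450 ms];
      a candidate below 1% of the R-peak energy raises
      :class:`FlatTWaveError`.
    * T start / end: boundaries of the T bump at 5% of the T-peak energy,
      requiring the series to stay below threshold for >= 20 ms beyond the
      crossing.
    """
    e3d = energy.e3d
    fs = energy.fs
    n = e3d.size
    if not (0 <= r_hint < n):
        raise ValueError("r_hint outside the energy series")

    def samp(seconds: float) -> int:
        return max(1, int(round(seconds * fs)))

    lo = max(0, r_hint - samp(R_SEARCH_S))
    hi = min(n, r_hint + samp(R_SEARCH_S) + 1)
    r_peak = lo + int(np.argmax(e3d[lo:hi]))

    d = np.gradient(e3d)
    on_lo = max(0, r_peak - samp(SLOPE_SEARCH_S))
    if on_lo >= r_peak:
        on_lo = max(0, r_peak - 1)
    qrs_onset = on_lo + int(np.argmax(d[on_lo:r_peak]))
    off_hi = min(n, r_peak + samp(SLOPE_SEARCH_S) + 1)
    qrs_offset = r_peak + 1 + int(np.argmin(d[r_peak + 1:off_hi]))

    t_lo = qrs_offset + samp(T_SEARCH_MIN_S)
    t_hi = min(n, qrs_offset + samp(T_SEARCH_MAX_S) + 1)
    if t_lo >= t_hi:
        raise FlatTWaveError("flat T wave: no search window after QRS")
    t_peak = t_lo + int(np.argmax(e3d[t_lo:t_hi]))
    if e3d[t_peak] < T_MIN_ENERGY_FRACTION * e3d[r_peak]:
        raise FlatTWaveError("flat T wave: no candidate above threshold")

    threshold = T_THRESHOLD_FRACTION * e3d[t_peak]
    dwell = samp(T_DWELL_S)
    t_start = _threshold_crossing(e3d, t_peak, threshold, dwell, direction=-1)
    t_end = _threshold_crossing(e3d, t_peak, threshold, dwell, direction=+1)
    t_start = max(t_start, qrs_offset + 1)
    t_end = min(max(t_end, t_peak + 1), n - 1)
    if t_peak <= qrs_offset or t_end <= t_peak:
        raise FlatTWaveError("flat T wave: degenerate T bump")
    return Landmarks(qrs_onset=qrs_onset, r_peak=r_peak, qrs_offset=qrs_offset,
                     t_start=min(t_start, t_peak), t_peak=t_peak, t_end=t_end)
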