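"""Beat-level preprocessing: R detection, segmentation, averaging, QC.

R peaks are detected on the summed squared cross-lead signal (the same
energy-envelope philosophy used downstream for landmarking), which is robust
to individual lead placement and polarity.  Beats are cut with a fixed
window around each R peak, averaged sample-wise into a template beat, or one
interior beat is chosen at random for single-beat analysis.  A quality
report flags displaced leads and mains-like high-frequency interference;
recordings with any flagged required lead are excluded from analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .ecg_io import EcgRecord, INDEPENDENT_LEADS, derive_independent_leads
from .errors import InsufficientBeatsError, NoBeatsError

logger = logging.getLogger(__name__)

#: Default beat window around the R peak (seconds).  Covers P onset through
#: T end for heart rates of ~45 bpm and above.
PRE_R_S = 0.3
POST_R_S = 0.5

#: Minimum separation between detected R peaks (seconds).
REFRACTORY_S = 0.2


@dataclass
class Beat:
    """One segmented (or averaged) beat on the 8 independent leads."""
    samples: np.ndarray            # (8, window)
    r_index: int                   # R-peak offset within the window
    fs: float
    rr_local: float                # s; median adjacent RR at this beat
    mode: str | None = None        # "random" | "averaged" | None
    lead_names: tuple[str, ...] = INDEPENDENT_LEADS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not (0 <= self.r_index < self.samples.shape[1]):
            raise ValueError("r_index outside beat window")


@dataclass
class QualityReport:
    """Per-lead quality flags and summary metrics for one recording."""
    displaced_leads: tuple[str, ...]
    high_interference_leads: tuple[str, ...]
    usable: bool
    metrics: dict = field(default_factory=dict)


def _energy_envelope(eight: np.ndarray, fs: float,
                     differentiate: bool = False) -> np.ndarray:
    """Summed squared cross-lead signal, lightly smoothed (20 ms boxcar).

    With ``differentiate`` the per-lead first difference is squared instead,
    which strongly favours the steep QRS over the slow T wave and makes the
    peak picker immune to tall T waves.
    """
    centered = eight - np.median(eight, axis=1, keepdims=True)
    if differentiate:
        # pre-smooth at the QRS time scale so differentiation does not
        # amplify broadband noise
        pre = max(1, int(round(0.012 * fs)))
        centered = np.apply_along_axis(
            lambda x: np.convolve(x, np.ones(pre) / pre, mode="same"), 1,
            centered)
        centered = np.gradient(centered, axis=1) * fs
    energy = np.sum(centered ** 2, axis=0)
    width = max(1, int(round(0.02 * fs)))
    kernel = np.ones(width) / width
    return np.convolve(energy, kernel, mode="same")


def detect_r_peaks(record: EcgRecord) -> np.ndarray:
    """Detect R peaks as local maxima of the cross-lead energy envelope.

    Returns strictly increasing sample indices, one per heartbeat, with a
    200 ms refractory period.  Raises :class:`InsufficientBeatsError` when
    fewer than two peaks are found.
    """
    eight = derive_independent_leads(record)
    env = _energy_envelope(eight, record.fs, differentiate=True)
    peak = float(env.max())
    if peak <= 0:
        raise InsufficientBeatsError("insufficient beats: flat record")
    distance = max(1, int(round(REFRACTORY_S * record.fs)))
    idx, _ = sps.find_peaks(env, height=0.25 * peak, distance=distance)
    if idx.size < 2:
        raise InsufficientBeatsError(
            f"insufficient beats: found {idx.size} R peak(s)")
    # refine each peak to the raw (unsmoothed) energy maximum within 30 ms
    raw = np.sum((eight - np.median(eight, axis=1, keepdims=True)) ** 2, axis=0)
    half = int(round(0.03 * record.fs))
    refined = []
    for i in idx:
        lo, hi = max(0, i - half), min(raw.size, i + half + 1)
        refined.append(lo + int(np.argmax(raw[lo:hi])))
    refined = np.unique(refined)
    return refined


def segment_beats(record: EcgRecord, r_indices: np.ndarray,
                  pre_s: float = PRE_R_S, post_s: float = POST_R_S) -> list[Beat]:
    """Cut a fixed window around each R peak.

    Beats whose window would run past either end of the recording are
    dropped.  If the window exceeds the shortest RR interval, it is shrunk
    proportionally (with a warning) so adjacent beats never overlap into the
    next R peak's QRS.
    """
    r_indices = np.asarray(r_indices, dtype=int)
    if r_indices.size < 2:
        raise InsufficientBeatsError("insufficient beats: need >= 2 R indices")
    fs = record.fs
    rr = np.diff(r_indices) / fs
    min_rr = float(rr.min())
    if pre_s + post_s > min_rr:
        scale = min_rr / (pre_s + post_s)
        warnings.warn(
            f"window/RR conflict: beat window {pre_s + post_s:.2f}s exceeds "
            f"min RR {min_rr:.2f}s; truncated symmetrically", stacklevel=2)
        pre_s, post_s = pre_s * scale, post_s * scale
    pre = int(round(pre_s * fs))
    post = int(round(post_s * fs))
    eight = derive_independent_leads(record)
    n = eight.shape[1]
    beats = []
    for k, r in enumerate(r_indices):
        lo, hi = r - pre, r + post
        if lo < 0 or hi > n:
            continue
        neighbours = []
        if k > 0:
            neighbours.append(rr[k - 1])
        if k < rr.size:
            neighbours.append(rr[k])
        beats.append(Beat(samples=eight[:, lo:hi].copy(), r_index=pre, fs=fs,
                          rr_local=float(np.median(neighbours))))
    return beats


def average_beat(beats: list[Beat]) -> Beat:
    """Sample-wise mean of beats aligned on their R index (mode ``averaged``)."""
    if not beats:
        raise NoBeatsError("no beats")
    pre = min(b.r_index for b in beats)
    post = min(b.samples.shape[1] - b.r_index for b in beats)
    stack = np.stack([b.samples[:, b.r_index - pre:b.r_index + post] for b in beats])
    return Beat(samples=stack.mean(axis=0), r_index=pre, fs=beats[0].fs,
                rr_local=float(np.mean([b.rr_local for b in beats])),
                mode="averaged", lead_names=beats[0].lead_names)


def select_random_beat(beats: list[Beat], seed: int) -> Beat:
    """Uniform random choice among interior beats (mode ``random``).

    The first and last beats are excluded when at least three are available,
    to avoid window truncation artefacts near the recording edges.
    """
    if not beats:
        raise NoBeatsError("no beats")
    pool = beats[1:-1] if len(beats) >= 3 else beats
    rng = np.random.default_rng(seed)
    chosen = pool[int(rng.integers(len(pool)))]
    return replace(chosen, samples=chosen.samples.copy(), mode="random")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

#: A lead is "displaced" when its RMS falls below this fraction of the
#: median lead RMS, or when its rectified waveform correlates with the
#: cross-lead energy template below CORR_MIN.
RMS_FRACTION_MIN = 0.05
CORR_MIN = 0.2
#: "High interference": spectral power above HF_CUTOFF_HZ exceeding
#: HF_POWER_FRACTION_MAX of total (DC-excluded) lead power.
HF_CUTOFF_HZ = 40.0
HF_POWER_FRACTION_MAX = 0.30


def quality_check(record: EcgRecord,
                  rms_fraction_min: float = RMS_FRACTION_MIN,
                  corr_min: float = CORR_MIN,
                  hf_cutoff_hz: float = HF_CUTOFF_HZ,
                  hf_fraction_max: float = HF_POWER_FRACTION_MAX) -> QualityReport:
    """Flag displaced leads and high electrical interference.

    Operates on the 8 independent leads; the recording is ``usable`` only if
    no flag is raised on any of them.  Thresholds are operational defaults
    and are exposed as parameters.
    """
    eight = derive_independent_leads(record)
    centered = eight - np.median(eight, axis=1, keepdims=True)
    rms = np.sqrt(np.mean(centered ** 2, axis=1))
    median_rms = float(np.median(rms))
    template = np.sqrt(np.maximum(np.sum(centered ** 2, axis=0), 0.0))
    t_sd = template.std()

    displaced, interference = [], []
    metrics = {"lead_rms": dict(zip(INDEPENDENT_LEADS, map(float, rms)))}
    hf_ratios = {}
    for k, name in enumerate(INDEPENDENT_LEADS):
        x = centered[k]
        low_rms = median_rms > 0 and rms[k] < rms_fraction_min * median_rms
        corr = 0.0
        if rms[k] > 0 and t_sd > 0:
            corr = float(np.corrcoef(np.abs(x), template)[0, 1])
        if low_rms or corr < corr_min:
            displaced.append(name)
        power = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, d=1.0 / record.fs)
        total = float(power[1:].sum())  # exclude DC
        hf = float(power[(freqs > hf_cutoff_hz)].sum())
        ratio = hf / total if total > 0 else 0.0
        hf_ratios[name] = ratio
        if ratio > hf_fraction_max:
            interference.append(name)
    metrics["hf_power_ratio"] = hf_ratios
    usable = not displaced and not interference
    if not usable:
        logger.info("record %s failed QC (displaced=%s interference=%s)",
                    record.subject_id, displaced, interference)
    return QualityReport(displaced_leads=tuple(displaced),
                         high_interference_leads=tuple(interference),
                         usable=usable, metrics=metrics)
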