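"""T-wave morphology markers: TCRT, TMD, TMDpre, TMDpost.

TCRT (total cosine R-to-T) is the mean cosine of the angles between the
3-D loop-space QRS vectors and the single T-peak vector: a unitless value in
[-1, 1] whose negative range signals a large divergence between the
orientations of ventricular depolarization and repolarization.  TMD (T-wave
morphology dispersion) quantifies how differently the T wave is expressed
across leads: each lead gets a 2-D "reconstruction vector" (its loadings on
the first two components of an SVD of the T-window segment) and TMD is the
mean angle, in degrees, over all 28 unordered lead pairs.  TMDpre and
TMDpost restrict the window to before/after the T peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .beat_processing import Beat
from .decomposition import (DecomposedBeat, Landmarks, detect_landmarks,
                            energy_vector, svd_decompose)
from .errors import (DegenerateQrsLoopError, DegenerateTLoopError,
                     DegenerateTVectorError)

logger = logging.getLogger(__name__)

#: QRS samples below this fraction of the peak QRS energy are excluded from
#: the TCRT average (0.0 reproduces the literal start-to-end reading).
QRS_ENERGY_THRESHOLD = 0.7

#: Reconstruction vectors with a norm below this fraction of the largest one
#: are treated as zero and excluded from TMD pairing.
TMD_ZERO_NORM_FRACTION = 1e-6


@dataclass
class MorphologyMarkers:
    """TCRT and the three TMD variants for one beat in one mode."""
    tcrt: float                    # unitless, [-1, 1]
    tmd: float                     # degrees, [0, 180]
    tmd_pre: float
    tmd_post: float
    mode: str | None
    energy_fraction_3: float


def compute_tcrt(decomposed: DecomposedBeat, landmarks: Landmarks,
                 energy_threshold: float = QRS_ENERGY_THRESHOLD,
                 n_t_vectors: int = 1) -> float:
    """Mean cosine between high-energy QRS loop vectors and the T-peak vector.

    QRS samples between the QRS onset and offset whose energy reaches
    ``energy_threshold`` times the QRS peak energy contribute one cosine
    each, against the single loop-space vector at the T peak (setting
    ``n_t_vectors`` > 1 averages over that many samples centred on the T
    peak instead — a variant found in the morphology literature).
    """
    s3 = decomposed.s3
    e3d = np.sum(s3 ** 2, axis=0)
    qrs = np.arange(landmarks.qrs_onset, landmarks.qrs_offset + 1)
    peak = e3d[qrs].max()
    qrs = qrs[e3d[qrs] >= energy_threshold * peak]
    vectors = s3[:, qrs]
    norms = np.linalg.norm(vectors, axis=0)
    keep = norms > 0
    if not np.any(keep):
        raise DegenerateQrsLoopError("degenerate QRS loop")
    vectors, norms = vectors[:, keep], norms[keep]

    if n_t_vectors <= 1:
        t_idx = np.array([landmarks.t_peak])
    else:
        half = n_t_vectors // 2
        t_idx = np.arange(landmarks.t_peak - half, landmarks.t_peak + half + 1)
        t_idx = t_idx[(t_idx >= landmarks.t_start) & (t_idx <= landmarks.t_end)]
    t_vecs = s3[:, t_idx]
    t_norms = np.linalg.norm(t_vecs, axis=0)
    if np.all(t_norms == 0):
        raise DegenerateTVectorError("degenerate T vector")
    t_vecs, t_norms = t_vecs[:, t_norms > 0], t_norms[t_norms > 0]

    cosines = (vectors.T @ t_vecs) / np.outer(norms, t_norms)
    return float(np.clip(cosines, -1.0, 1.0).mean())


def _t_window(landmarks: Landmarks, window: str) -> tuple[int, int]:
    if window == "full":
        return landmarks.t_start, landmarks.t_end
    if window == "pre":
        return landmarks.t_start, landmarks.t_peak
    if window == "post":
        return landmarks.t_peak, landmarks.t_end
    raise ValueError(f"unknown TMD window {window!r}")


def compute_tmd(decomposed: DecomposedBeat, landmarks: Landmarks,
                window: str = "full", n_dims: int = 2) -> float:
    """Mean pairwise angle (degrees) between per-lead T reconstruction vectors.

    The T-window segment of the baseline-corrected 8-lead beat is decomposed
    with its own SVD; lead *i*'s reconstruction vector is row *i* of
    ``U S`` restricted to the first ``n_dims`` (default 2) columns.  Angles
    are taken in [0, 180] degrees over all unordered pairs of leads whose
    vectors have non-negligible norm; more than four negligible vectors make
    the T loop degenerate.
    """
    lo, hi = _t_window(landmarks, window)
    seg = decomposed.leads[:, lo:hi + 1]
    if seg.shape[1] < 3:
        raise ValueError("TMD window shorter than 3 samples")
    u, s, _ = np.linalg.svd(seg, full_matrices=False)
    recon = u[:, :n_dims] * s[:n_dims]
    norms = np.linalg.norm(recon, axis=1)
    max_norm = norms.max()
    if max_norm == 0:
        raise DegenerateTLoopError("degenerate T loop")
    keep = np.where(norms > TMD_ZERO_NORM_FRACTION * max_norm)[0]
    n_dropped = recon.shape[0] - keep.size
    if n_dropped > 4:
        raise DegenerateTLoopError(
            f"degenerate T loop: {n_dropped} zero-norm reconstruction vectors")
    if n_dropped:
        logger.warning("TMD: excluded %d zero-norm reconstruction vector(s)",
                       n_dropped)
    angles = []
    for i, j in combinations(keep, 2):
        c = np.dot(recon[i], recon[j]) / (norms[i] * norms[j])
        angles.append(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    return float(np.mean(angles))


def compute_markers(beat: Beat, energy_threshold: float = QRS_ENERGY_THRESHOLD
                    ) -> MorphologyMarkers:
    """Full morphology chain for one beat: SVD, landmarks, TCRT and TMD x3."""
    decomposed = svd_decompose(beat.samples, beat.fs, r_index=beat.r_index)
    energy = energy_vector(decomposed)
    landmarks = detect_landmarks(energy, r_hint=beat.r_index)
    return MorphologyMarkers(
        tcrt=compute_tcrt(decomposed, landmarks, energy_threshold=energy_threshold),
        tmd=compute_tmd(decomposed, landmarks, window="full"),
        tmd_pre=compute_tmd(decomposed, landmarks, window="pre"),
        tmd_post=compute_tmd(decomposed, landmarks, window="post"),
        mode=beat.mode,
        energy_fraction_3=decomposed.energy_fraction_3)
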