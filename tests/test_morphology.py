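"""TCRT and TMD: hand-computed cases, bounds, invariances, oracle agreement."""

import dataclasses

import numpy as np
import pytest

from repolab import (PROJECTION_MATRIX, average_beat, compute_markers,
                     compute_tcrt, compute_tmd, detect_r_peaks,
                     generate_record, segment_beats, select_random_beat,
                     svd_decompose)
from repolab.decomposition import DecomposedBeat, Landmarks
from repolab.errors import (DegenerateQrsLoopError, DegenerateTLoopError,
                            DegenerateTVectorError)
from repolab.synthetic_ecg import SyntheticConfig

from conftest import make_clean_config


def _decomposed_from_s3(s3: np.ndarray, leads: np.ndarray | None = None,
                        fs: float = 500.0) -> DecomposedBeat:
    s3 = np.asarray(s3, dtype=float)
    if leads is None:
        leads = np.zeros((8, s3.shape[1]))
    return DecomposedBeat(s3=s3, weights=np.eye(8, 3),
                          singular_values=np.zeros(8), energy_fraction_3=1.0,
                          fs=fs, leads=np.asarray(leads, dtype=float))


def _landmarks(**kw) -> Landmarks:
    base = dict(qrs_onset=0, r_peak=1, qrs_offset=2, t_start=5, t_peak=8,
                t_end=11)
    base.update(kw)
    return Landmarks(**base)


def test_tcrt_hand_case_two_orthogonal_qrs_vectors():
    # QRS vectors (1,0,0) and (0,1,0) vs T peak (1,0,0): (1 + 0)/2 = 0.5
    n = 12
    s3 = np.zeros((3, n))
    s3[:, 0] = [1, 0, 0]
    s3[:, 1] = [1, 0, 0]   # r peak sample (vector repeated; still cos 1)
    s3[:, 2] = [0, 1, 0]
    s3[:, 8] = [0.5, 0, 0]
    tcrt = compute_tcrt(_decomposed_from_s3(s3), _landmarks(),
                        energy_threshold=0.0)
    assert tcrt == pytest.approx((1.0 + 1.0 + 0.0) / 3)
    # restricting to exactly the two target vectors via landmark bounds
    s3b = np.zeros((3, n))
    s3b[:, 1] = [1, 0, 0]
    s3b[:, 2] = [0, 1, 0]
    s3b[:, 8] = [1, 0, 0]
    tcrt = compute_tcrt(_decomposed_from_s3(s3b),
                        _landmarks(qrs_onset=1, r_peak=2, qrs_offset=3),
                        energy_threshold=0.0)
    assert tcrt == pytest.approx(0.5)


@pytest.mark.parametrize("sense,expected", [(1.0, 1.0), (-1.0, -1.0)])
def test_tcrt_collinear_and_anticollinear(sense, expected):
    n = 12
    s3 = np.zeros((3, n))
    for k in range(3):
        s3[:, k] = [1.0, 0.5, -0.25]
    s3[:, 8] = sense * np.array([2.0, 1.0, -0.5])
    tcrt = compute_tcrt(_decomposed_from_s3(s3), _landmarks())
    assert tcrt == pytest.approx(expected, abs=1e-12)


def test_tcrt_degenerate_errors():
    n = 12
    s3 = np.zeros((3, n))
    with pytest.raises(DegenerateQrsLoopError, match="degenerate QRS loop"):
        compute_tcrt(_decomposed_from_s3(s3), _landmarks())
    s3[:, 1] = [1, 0, 0]
    with pytest.raises(DegenerateTVectorError, match="degenerate T vector"):
        compute_tcrt(_decomposed_from_s3(s3), _landmarks())


def _t_window_waveforms(n=67, start=3):
    """Two waveforms exactly orthogonal over the T window [start, n-1]."""
    length = n - start
    j = np.arange(length)
    f = np.zeros(n)
    g = np.zeros(n)
    f[start:] = np.sin(2 * np.pi * j / length)
    g[start:] = np.cos(2 * np.pi * j / length)
    lm = _landmarks(t_start=start, t_peak=start + length // 2, t_end=n - 1)
    return f, g, lm


def test_tmd_orthogonal_four_versus_four():
    # 4 leads carry waveform f, 4 carry g, with f orthogonal to g: the
    # reconstruction vectors split onto the two axes, so the mean pairwise
    # angle is (12 * 0 + 16 * 90) / 28 = 51.43 degrees
    f, g, lm = _t_window_waveforms()
    leads = np.vstack([a * f for a in (1.0, 0.8, 1.2, 0.6)]
                      + [a * g for a in (1.1, 0.9, 0.7, 1.3)])
    dec = _decomposed_from_s3(np.zeros((3, leads.shape[1])), leads=leads)
    tmd = compute_tmd(dec, lm, window="full")
    assert tmd == pytest.approx((16 * 90.0) / 28, abs=1e-9)


def test_tmd_parallel_leads_zero():
    f, _, lm = _t_window_waveforms()
    leads = np.vstack([a * f for a in (1.0, 0.5, 2.0, 0.3, 1.5, 0.9, 1.1, 0.7)])
    dec = _decomposed_from_s3(np.zeros((3, leads.shape[1])), leads=leads)
    assert compute_tmd(dec, lm) == pytest.approx(0.0, abs=1e-6)


def test_tmd_scale_invariance(clean_average):
    dec1 = svd_decompose(clean_average.samples, clean_average.fs,
                         r_index=clean_average.r_index)
    dec2 = svd_decompose(2.5 * clean_average.samples, clean_average.fs,
                         r_index=clean_average.r_index)
    from repolab import detect_landmarks, energy_vector
    lm = detect_landmarks(energy_vector(dec1), r_hint=clean_average.r_index)
    for window in ("full", "pre", "post"):
        assert compute_tmd(dec1, lm, window) == pytest.approx(
            compute_tmd(dec2, lm, window), abs=1e-9)


def test_tmd_degenerate_t_loop():
    f, _, lm = _t_window_waveforms()
    leads = np.zeros((8, f.size))
    leads[0] = f  # 7 zero-norm leads
    dec = _decomposed_from_s3(np.zeros((3, f.size)), leads=leads)
    with pytest.raises(DegenerateTLoopError, match="degenerate T loop"):
        compute_tmd(dec, lm)


@pytest.mark.parametrize("theta,expected", [(60.0, 0.5), (90.0, 0.0)])
def test_markers_recover_cos_theta(theta, expected):
    cfg = make_clean_config(theta=theta)
    rec = generate_record(cfg)
    beats = segment_beats(rec, detect_r_peaks(rec))
    m = compute_markers(average_beat(beats))
    assert m.tcrt == pytest.approx(expected, abs=0.02)
    assert m.energy_fraction_3 == pytest.approx(1.0, abs=1e-9)


def test_identical_beats_random_equals_averaged(clean_beats):
    m_avg = compute_markers(average_beat(clean_beats))
    m_rand = compute_markers(select_random_beat(clean_beats, seed=3))
    assert m_rand.tcrt == pytest.approx(m_avg.tcrt, abs=1e-12)
    assert m_rand.tmd == pytest.approx(m_avg.tmd, abs=1e-9)
    assert m_rand.mode == "random" and m_avg.mode == "averaged"


def test_tcrt_strictly_decreasing_in_theta():
    values = []
    for theta in range(0, 181, 15):
        cfg = make_clean_config(theta=float(theta), duration=4.0, fs=500.0)
        rec = generate_record(cfg)
        beats = segment_beats(rec, detect_r_peaks(rec))
        values.append(compute_markers(average_beat(beats)).tcrt)
    assert np.all(np.diff(values) < 0)


def test_marker_bounds_on_random_configs():
    rng = np.random.default_rng(99)
    for _ in range(40):
        cfg = SyntheticConfig(
            theta=float(rng.uniform(0, 180)),
            heart_rate=float(rng.uniform(50, 100)),
            qrs_loop_spread=float(rng.uniform(0, 30)),
            noise_sd=float(rng.uniform(0, 0.02)),
            duration=4.0, fs=500.0, seed=int(rng.integers(1 << 30)))
        rec = generate_record(cfg)
        beats = segment_beats(rec, detect_r_peaks(rec))
        m = compute_markers(average_beat(beats))
        assert -1.0 <= m.tcrt <= 1.0
        for v in (m.tmd, m.tmd_pre, m.tmd_post):
            assert 0.0 <= v <= 180.0


def test_tcrt_rotation_invariant(clean_config):
    # TCRT is an angle inside the rank-3 loop space, so a global rotation of
    # the generating dipole cannot change it.  TMD is deliberately *not*
    # rotation invariant: its reconstruction vectors are per-lead loadings,
    # and rotating the dipole re-mixes the leads.
    from scipy.spatial.transform import Rotation
    from repolab import generate_dipole, project_to_leads
    dip = generate_dipole(clean_config)
    rot = Rotation.from_euler("zyx", [17, 64, -123], degrees=True).as_matrix()
    markers = []
    for data in (np.asarray(dip), rot @ np.asarray(dip)):
        d = dataclasses.replace(dip, data=data)
        rec = project_to_leads(d, clean_config)
        beats = segment_beats(rec, detect_r_peaks(rec))
        markers.append(compute_markers(average_beat(beats)))
    a, b = markers
    assert a.tcrt == pytest.approx(b.tcrt, abs=1e-6)
    assert 0.0 <= b.tmd <= 180.0


def test_tcrt_agrees_with_brute_force_dipole_oracle():
    # oracle route: pseudo-invert the known mixing matrix back to dipole
    # space and average cosines there with an explicit loop
    for theta in (30.0, 75.0, 140.0):
        cfg = make_clean_config(theta=theta)
        rec = generate_record(cfg)
        beats = segment_beats(rec, detect_r_peaks(rec))
        beat = average_beat(beats)
        m = compute_markers(beat)

        from repolab import detect_landmarks, energy_vector
        dec = svd_decompose(beat.samples, beat.fs, r_index=beat.r_index)
        lm = detect_landmarks(energy_vector(dec), r_hint=beat.r_index)
        dipole = np.linalg.pinv(PROJECTION_MATRIX) @ dec.leads
        e = np.sum(dipole ** 2, axis=0)
        qrs = range(lm.qrs_onset, lm.qrs_offset + 1)
        emax = max(e[i] for i in qrs)
        tvec = dipole[:, lm.t_peak]
        cosines = []
        for i in qrs:
            if e[i] >= 0.7 * emax:
                v = dipole[:, i]
                cosines.append(np.dot(v, tvec)
                               / (np.linalg.norm(v) * np.linalg.norm(tvec)))
        assert m.tcrt == pytest.approx(np.mean(cosines), abs=0.02)
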