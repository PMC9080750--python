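"""Pulse detection: envelope arithmetic, -15 dB endpoints, recall/precision."""

import numpy as np
import pytest

from buzzpause.detect import (
    DetectionParams,
    Envelope,
    PulseDetector,
    SpectrogramParams,
    compute_envelope,
    detect_pulses,
    estimate_noise_floor,
    refine_endpoints,
)
from buzzpause.synth import Recording, render_dataset

FS = 500_000


def _match_events(events, truth):
    """Pair detections with truth pulses by midpoint proximity (1 ms)."""
    hits, used = 0, set()
    for ev in events:
        mid = (ev.start + ev.end) / 2
        for j, (_, row) in enumerate(truth.iterrows()):
            if j in used:
                continue
            if abs(mid - (row.onset_s + row.offset_s) / 2) < 1e-3:
                hits += 1
                used.add(j)
                break
    return hits


# --- envelope -------------------------------------------------------------


def test_pure_tone_lands_in_expected_bin():
    """50 kHz at 500 kHz sampling: max-energy bin is round(50000/3906.25) = 13."""
    t = np.arange(FS // 10) / FS
    rec = Recording("tone", 0.5 * np.sin(2 * np.pi * 50_000 * t), FS)
    seg = rec.samples[: 128]
    win = np.hanning(128)
    spec = np.abs(np.fft.rfft(seg * win)) ** 2
    assert np.argmax(spec) == 13
    env = compute_envelope(rec, SpectrogramParams(hop=64))
    narrow = compute_envelope(rec, SpectrogramParams(hop=64, band=(48_000, 54_000)))
    # bin 13 alone carries most of the in-band energy (rest is off-grid leakage)
    assert np.median(env.power_db) - np.median(narrow.power_db) < 3.0


def test_all_zero_input_sits_at_db_floor():
    rec = Recording("silence", np.zeros(4096), FS)
    env = compute_envelope(rec, SpectrogramParams(hop=16))
    assert np.all(env.power_db == -120.0)


def test_hop1_and_hop8_envelopes_agree_at_shared_frames():
    rng = np.random.default_rng(0)
    rec = Recording("noise", rng.normal(0, 0.01, 8192), FS)
    e1 = compute_envelope(rec, SpectrogramParams(hop=1))
    e8 = compute_envelope(rec, SpectrogramParams(hop=8))
    assert np.allclose(e1.power_db[:: 8][: len(e8.power_db)], e8.power_db, atol=1e-9)
    assert np.allclose(e1.times[:: 8][: len(e8.times)], e8.times, atol=1e-12)


def test_too_short_recording_rejected():
    with pytest.raises(ValueError):
        compute_envelope(Recording("short", np.zeros(64), FS))


# --- noise floor ----------------------------------------------------------


def test_noise_floor_of_constant_envelope():
    env = Envelope(np.arange(100.0), np.full(100, -60.0), FS, 1, 128)
    assert estimate_noise_floor(env) == -60.0


def test_noise_floor_robust_to_sparse_pulse():
    rng = np.random.default_rng(1)
    base = -60 + rng.normal(0, 1.0, 2000)
    clean = estimate_noise_floor(base)
    spiked = base.copy()
    spiked[1000:1080] = -20.0  # 4% of frames occupied by a pulse
    assert abs(estimate_noise_floor(spiked) - clean) < 1.0


def test_noise_floor_empty_is_an_error():
    with pytest.raises(ValueError):
        estimate_noise_floor(np.array([]))


# --- endpoint refinement --------------------------------------------------


def test_gaussian_envelope_crossing_matches_analytic_half_width():
    """-15 dB half-width of a Gaussian amplitude envelope is 1.858 * scale."""
    s = 40.0  # frames
    x = np.arange(-400, 401, dtype=float)
    power_db = 20.0 * np.log10(np.exp(-(x**2) / (2 * s**2)))
    start, end, clipped = refine_endpoints(power_db, peak_idx=400, threshold_db=-15.0)
    half_width = s * np.sqrt(2 * np.log(10 ** (15 / 20)))
    assert not clipped
    assert (end - start) / 2 == pytest.approx(half_width, rel=1e-3)
    assert half_width == pytest.approx(1.858 * s, rel=1e-3)


def test_rectangular_envelope_returns_full_extent():
    env = np.full(50, -20.0)
    start, end, clipped = refine_endpoints(env, peak_idx=25)
    assert (start, end, clipped) == (0.0, 49.0, True)


def test_level_below_floor_clips_to_floor_crossings():
    env = np.concatenate([np.full(20, -60.0), np.full(10, -50.0), np.full(20, -60.0)])
    start, end, clipped = refine_endpoints(env, peak_idx=25, floor_db=-55.0)
    assert clipped
    assert 19.0 <= start <= 20.0 and 29.0 <= end <= 30.0


# --- detection ------------------------------------------------------------


def test_detects_every_truth_pulse_with_tight_endpoints(clean_dataset):
    recordings, _, pulses = clean_dataset
    det = PulseDetector()
    rec = recordings[0]
    truth = pulses[pulses.recording_id == rec.recording_id].reset_index(drop=True)
    events = det.detect(rec)
    assert len(events) == len(truth)
    onset_err = [abs(ev.start - row.onset_s) for ev, (_, row) in zip(events, truth.iterrows())]
    offset_err = [abs(ev.end - row.offset_s) for ev, (_, row) in zip(events, truth.iterrows())]
    tol = 1 / FS + 1e-4  # one refinement frame + 0.1 ms
    assert np.median(onset_err) <= tol
    assert np.median(offset_err) <= tol
    assert all(ev.snr >= 20 for ev in events)


def test_pure_noise_yields_no_events():
    rng = np.random.default_rng(3)
    rec = Recording("noise", rng.normal(0, 0.01, FS // 2), FS)
    assert PulseDetector().detect(rec) == []


def test_close_subpulses_merge_into_one_event():
    """Two bursts 0.2 ms apart with a 0.5 ms merge gap come back as one event."""
    t = np.arange(int(0.001 * FS)) / FS
    burst = 0.4 * np.sin(2 * np.pi * 50_000 * t)
    wave = np.zeros(FS // 10)
    gap = int(0.0002 * FS)
    wave[10_000 : 10_000 + len(burst)] = burst
    wave[10_000 + len(burst) + gap : 10_000 + 2 * len(burst) + gap] = burst
    rng = np.random.default_rng(4)
    rec = Recording("twin", wave + rng.normal(0, 0.001, len(wave)), FS)
    events = PulseDetector().detect(rec)
    assert len(events) == 1
    assert (events[0].end - events[0].start) > 2 * len(burst) / FS * 0.9


def test_raising_floor_margin_never_adds_events(clean_dataset):
    recordings, _, _ = clean_dataset
    rec = recordings[1]
    counts = []
    for margin in (6.0, 12.0, 20.0, 35.0):
        det = PulseDetector(detection=DetectionParams(floor_margin_db=margin))
        counts.append(len(det.detect(rec)))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_detection_is_deterministic(clean_dataset):
    recordings, _, _ = clean_dataset
    det = PulseDetector()
    a = det.detect(recordings[2])
    b = det.detect(recordings[2])
    assert a == b


def test_recall_and_precision_on_default_dataset(clean_dataset):
    recordings, _, pulses = clean_dataset
    det = PulseDetector()
    tp = fp = fn = 0
    for rec in recordings:
        truth = pulses[pulses.recording_id == rec.recording_id]
        events = det.detect(rec)
        hits = _match_events(events, truth)
        tp += hits
        fp += len(events) - hits
        fn += len(truth) - hits
    recall = tp / (tp + fn)
    precision = tp / (tp + fp)
    assert recall >= 0.99
    assert precision >= 0.99
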