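"""Synthetic-data generator: call acoustics, schedules, dataset ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal, stats

from buzzpause.synth import (
    OutcomeModelParams,
    PulseSynthParams,
    Recording,
    SequenceTiming,
    draw_pause,
    render_dataset,
    sample_attack_sequence,
    sample_outcome_table,
    synthesize_pulse,
)
from buzzpause.synth import _instantaneous_freq

FS = 500_000


# --- draw_pause -----------------------------------------------------------


def test_draw_pause_minimum_under_tiny_rate():
    params = OutcomeModelParams(mean_pause_ms={"captured": 1e-6, "dropped": 1e-6, "failed": 1e-6})
    rng = np.random.default_rng(0)
    draws = draw_pause("captured", params=params, rng=rng, size=500)
    assert np.all(draws == 1)


def test_draw_pause_matches_truncated_mean_at_small_rate():
    params = OutcomeModelParams(mean_pause_ms={"captured": 0.5, "dropped": 0.5, "failed": 0.5})
    rng = np.random.default_rng(1)
    draws = draw_pause("captured", params=params, rng=rng, size=1_000_000)
    assert draws.mean() == pytest.approx(1.2707, rel=0.005)


def test_draw_pause_captured_mean_near_200ms():
    rng = np.random.default_rng(2)
    draws = draw_pause("captured", params=OutcomeModelParams(), rng=rng, size=100_000)
    assert draws.mean() == pytest.approx(200.0, rel=0.01)


def test_draw_pause_rejects_bad_rate():
    with pytest.raises(ValueError):
        draw_pause("captured", bat_effect=-np.inf, rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        draw_pause("eaten", rng=np.random.default_rng(0))


# --- pulse synthesis ------------------------------------------------------


def test_pulse_energy_peaks_at_50khz():
    """Welch peak (analysis resolution 3.906 kHz) lies within one bin of 50 kHz."""
    wave = synthesize_pulse()
    f, pxx = signal.welch(wave, fs=FS, nperseg=128, noverlap=64)
    assert abs(f[np.argmax(pxx)] - 50_000.0) <= FS / 128


def test_pulse_ridge_tracks_hyperbolic_sweep():
    """Per-frame spectrogram ridge within one bin of the instantaneous frequency."""
    params = PulseSynthParams()
    wave = synthesize_pulse(params)
    f, t, S = signal.stft(wave, fs=FS, window="hann", nperseg=128, noverlap=120,
                          boundary=None)
    power = np.abs(S) ** 2
    band = (f >= 30_000) & (f <= 100_000)
    in_band = power[band]
    total = in_band.sum(axis=0)
    strong = total > total.max() * 10 ** (-20 / 10)
    ridge = f[band][np.argmax(in_band[:, strong], axis=0)]
    expected = _instantaneous_freq(
        np.clip(t[strong], 0, params.duration_search), params.duration_search,
        params.f_start, params.f_end,
    )
    assert np.all(np.abs(ridge - expected) <= FS / 128)
    # the sweep itself spans 90 -> 40 kHz
    assert _instantaneous_freq(0.0, 0.004, 90e3, 40e3) == pytest.approx(90e3)
    assert _instantaneous_freq(0.004, 0.004, 90e3, 40e3) == pytest.approx(40e3)


def test_zero_amplitude_yields_silence():
    wave = synthesize_pulse(PulseSynthParams(amplitude=0.0))
    assert np.all(wave == 0.0)


def test_buzz_pulses_shorter_than_search():
    assert len(synthesize_pulse(kind="buzz")) < len(synthesize_pulse(kind="search"))


def test_aliasing_guard():
    with pytest.raises(ValueError):
        synthesize_pulse(PulseSynthParams(n_harmonics=3), sample_rate=FS)


def test_param_invariants():
    with pytest.raises(ValueError):
        PulseSynthParams(f_start=40_000, f_end=90_000)
    with pytest.raises(ValueError):
        PulseSynthParams(peak_freq=20_000)
    with pytest.raises(ValueError):
        OutcomeModelParams(outcome_probs={"captured": 0.5, "dropped": 0.5, "failed": 0.5})
    with pytest.raises(ValueError):
        SequenceTiming(buzz_ipi_ms=50.0)


# --- schedules ------------------------------------------------------------


def test_schedule_reproducible_given_seed():
    a = sample_attack_sequence("captured", rng=np.random.default_rng(42))
    b = sample_attack_sequence("captured", rng=np.random.default_rng(42))
    assert a == b


def test_schedule_structure_and_exact_pause():
    timing = SequenceTiming()
    sched = sample_attack_sequence("dropped", timing=timing, rng=np.random.default_rng(3))
    phases = [e[0] for e in sched.entries]
    assert phases[: timing.n_search] == ["search"] * timing.n_search
    buzz_entries = [e for e in sched.entries if e[0] == "buzz"]
    assert len(buzz_entries) >= 5
    assert all(ipi <= timing.buzz_ipi_ms for _, ipi, _ in buzz_entries)
    approach_ipis = [ipi for ph, ipi, _ in sched.entries if ph == "approach"]
    assert all(x >= y for x, y in zip(approach_ipis, approach_ipis[1:]))
    onsets, durs, phases = sched.realize()
    assert np.all(np.diff(onsets) > 0)
    last_buzz = max(i for i, p in enumerate(phases) if p == "buzz")
    gap = onsets[last_buzz + 1] - (onsets[last_buzz] + durs[last_buzz])
    assert gap == pytest.approx(float(sched.pause_ms), abs=1e-9)


def test_failed_pause_monte_carlo_mean():
    """Mean drawn pause for failed attacks converges to the 114 ms calibration."""
    rng = np.random.default_rng(9)
    pauses = [
        sample_attack_sequence("failed", rng=rng).pause_ms for _ in range(10_000)
    ]
    sem = np.std(pauses) / np.sqrt(len(pauses))
    assert np.mean(pauses) == pytest.approx(114.0, abs=4 * sem + 0.5)


# --- datasets -------------------------------------------------------------


def test_outcome_counts_within_binomial_band():
    df = sample_outcome_table(1000, seed=77)
    captured = (df["outcome"] == "captured").sum()
    lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.518)
    assert lo <= captured <= hi


def test_outcome_table_group_nesting():
    df = sample_outcome_table(400, n_bats=12, n_dates=4, seed=5)
    assert (df.groupby("bat_id")["date"].nunique() == 1).all()
    assert set(df["outcome"]) <= {"captured", "dropped", "failed"}
    assert (df["pause_ms"] >= 1).all()


def test_per_outcome_means_converge_to_calibration():
    params = OutcomeModelParams(sd_bat=0.0, sd_date=0.0)
    df = sample_outcome_table(2000, params=params, seed=21)
    means = df.groupby("outcome")["pause_ms"].mean()
    for level, target in [("captured", 200.0), ("dropped", 153.0), ("failed", 114.0)]:
        assert means[level] == pytest.approx(target, rel=0.02)


def test_render_ground_truth_consistency(clean_dataset):
    recordings, attacks, pulses = clean_dataset
    assert len(attacks) == 10
    for _, row in attacks.iterrows():
        gap_ms = (row["next_pulse_start_s"] - row["buzz_end_s"]) * 1e3
        assert round(gap_ms) == row["pause_ms"]
    for rid, sub in pulses.groupby("recording_id"):
        assert np.all(np.diff(sub["onset_s"]) > 0)


def test_render_empty_dataset_is_not_an_error(tmp_path):
    recordings, attacks, pulses = render_dataset(n_attacks=0, seed=0)
    assert recordings == [] and attacks.empty and pulses.empty


def test_wav_roundtrip_bit_identical(tmp_path, clean_dataset):
    recordings, _, _ = clean_dataset
    rec = recordings[0]
    path = tmp_path / "rec.wav"
    rec.to_wav(path)
    back = Recording.from_wav(path, recording_id=rec.recording_id)
    assert back.sample_rate == rec.sample_rate
    # quantize the original the same way the writer does: must be identical
    pcm = np.round(np.clip(rec.samples, -1, 1) * 32767).astype(np.int16)
    pcm_back = np.round(np.clip(back.samples, -1, 1) * 32767).astype(np.int16)
    assert np.array_equal(pcm, pcm_back)
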