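"""Synthetic ultrasonic foraging-bout generator.

Emulates single-channel recordings of a trawling *Myotis*-like bat attacking
prey at the water surface: downward FM pulses (fundamental ~90 -> 40 kHz,
spectral peak near 50 kHz, with harmonics), a search -> approach -> terminal
buzz phase structure, an outcome-dependent silent post-buzz pause drawn from
a zero-truncated Poisson on the integer-millisecond scale, and resumed search
pulses.  Every generated dataset carries exact ground truth (pulse times,
phases, pauses, outcomes) so the downstream measurement chain can be tested
without any field data.

Randomness is fanned out from a single seed into named substreams (outcomes,
pauses, effects, noise, assignment) so each stage is independently
reproducible.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .ztp import ztp_rvs

__all__ = [
    "PulseSynthParams",
    "OutcomeModelParams",
    "SequenceTiming",
    "PhaseSchedule",
    "Recording",
    "draw_pause",
    "synthesize_pulse",
    "sample_attack_sequence",
    "sample_outcome_table",
    "render_dataset",
]

OUTCOMES = ("captured", "dropped", "failed")
DEFAULT_SAMPLE_RATE = 500_000


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class PulseSynthParams:
    """Parameters of a single synthetic FM call.

    The fundamental sweeps hyperbolically from ``f_start`` down to ``f_end``
    (constant-period-slope FM, typical of vespertilionid calls) and carries
    ``n_harmonics`` harmonic components in total (the fundamental counts as
    the first).  The amplitude envelope is shaped so the energy spectrum
    peaks near ``peak_freq``.
    """

    f_start: float = 90_000.0
    f_end: float = 40_000.0
    peak_freq: float = 50_000.0
    n_harmonics: int = 2
    duration_search: float = 0.004
    duration_buzz: float = 0.0005
    amplitude: float = 0.3
    peak_bandwidth: float = 15_000.0  # Gaussian width (Hz) of the energy spectrum
    harmonic_rolloff: float = 0.35  # amplitude ratio between successive harmonics

    def __post_init__(self):
        if not (self.f_start > self.f_end > 0):
            raise ValueError("require f_start > f_end > 0")
        if not (self.f_end <= self.peak_freq <= self.f_start):
            raise ValueError("peak_freq must lie within [f_end, f_start]")
        if self.duration_search <= 0 or self.duration_buzz <= 0:
            raise ValueError("pulse durations must be positive")
        if self.duration_buzz >= self.duration_search:
            raise ValueError("buzz pulses must be shorter than search pulses")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics counts components and must be >= 1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class OutcomeModelParams:
    """Outcome frequencies and the pause-generating model.

    ``mean_pause_ms`` are the zero-truncated Poisson rates per outcome level
    (at rates this large the truncated mean differs negligibly from the
    rate).  Random intercepts act multiplicatively on the rate:
    ``lambda = mean * exp(bat_effect + date_effect)`` with independent
    Gaussian effects on the log scale, bat nested within date.
    """

    mean_pause_ms: dict = field(
        default_factory=lambda: {"captured": 200.0, "dropped": 153.0, "failed": 114.0}
    )
    outcome_probs: dict = field(
        default_factory=lambda: {"captured": 0.518, "dropped": 0.292, "failed": 0.190}
    )
    sd_bat: float = 0.10
    sd_date: float = 0.05

    def __post_init__(self):
        if set(self.mean_pause_ms) != set(OUTCOMES) or set(self.outcome_probs) != set(OUTCOMES):
            raise ValueError(f"outcome levels must be exactly {OUTCOMES}")
        if any(m <= 0 for m in self.mean_pause_ms.values()):
            raise ValueError("mean pauses must be positive")
        if abs(sum(self.outcome_probs.values()) - 1.0) > 1e-9:
            raise ValueError("outcome probabilities must sum to 1")
        if self.sd_bat < 0 or self.sd_date < 0:
            raise ValueError("random-effect SDs must be non-negative")


@dataclass
class SequenceTiming:
    """Inter-pulse-interval structure of one attack sequence.

    Defaults give the qualitative phase structure of a capture sequence:
    long search IPIs, an approach ramp of shortening IPIs, then a buzz at a
    few-millisecond repetition period.  All intervals are onset-to-onset.
    """

    n_search: int = 3
    search_ipi_ms: float = 90.0
    n_approach: int = 6
    approach_ipi_start_ms: float = 40.0
    approach_ipi_end_ms: float = 20.0
    n_buzz: int = 12
    buzz_ipi_ms: float = 6.0
    n_resume: int = 3
    resume_ipi_ms: float = 90.0

    def __post_init__(self):
        if min(self.n_search, self.n_resume) < 2 or self.n_buzz < 5 or self.n_approach < 1:
            raise ValueError("need >=3 search, >=5 buzz, >=2 resumption pulses")
        if not (
            self.buzz_ipi_ms
            < self.approach_ipi_end_ms
            <= self.approach_ipi_start_ms
            < self.search_ipi_ms
        ):
            raise ValueError("require buzz IPI < approach IPIs < search IPI")


@dataclass
class PhaseSchedule:
    """One attack's pulse schedule with its ground-truth pause.

    ``entries``/``resume_entries`` hold ``(phase, ipi_to_next_ms, duration_ms)``
    per pulse before/after the pause; the pause separates the offset of the
    last buzz pulse from the onset of the first resumption pulse.
    """

    entries: list
    pause_ms: int
    resume_entries: list

    def realize(self):
        """Expand the schedule to per-pulse (onset_ms, duration_ms, phase).

        The ground-truth invariant holds exactly by construction: the first
        resumption onset equals last-buzz offset + ``pause_ms``.
        """
        onsets, durs, phases = [], [], []
        t = 0.0
        for phase, ipi, dur in self.entries:
            onsets.append(t)
            durs.append(dur)
            phases.append(phase)
            t += ipi
        last_buzz_offset = onsets[-1] + durs[-1]
        t = last_buzz_offset + float(self.pause_ms)
        for phase, ipi, dur in self.resume_entries:
            onsets.append(t)
            durs.append(dur)
            phases.append(phase)
            t += ipi
        return np.asarray(onsets), np.asarray(durs), phases


@dataclass
class Recording:
    """A mono waveform with its sampling rate."""

    recording_id: str
    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def to_wav(self, path) -> None:
        """Write as 16-bit PCM mono WAV (samples clipped to [-1, 1])."""
        clipped = np.clip(self.samples, -1.0, 1.0)
        pcm = np.round(clipped * 32767.0).astype(np.int16)
        wavfile.write(path, self.sample_rate, pcm)

    @classmethod
    def from_wav(cls, path, recording_id=None) -> "Recording":
        rate, data = wavfile.read(path)
        if data.ndim != 1:
            raise ValueError("expected a mono WAV file")
        if data.dtype == np.int16:
            samples = data.astype(np.float64) / 32767.0
        else:
            samples = data.astype(np.float64)
        rid = recording_id if recording_id is not None else str(path)
        return cls(recording_id=rid, samples=samples, sample_rate=int(rate))


# ---------------------------------------------------------------------------
# pause draws


def draw_pause(outcome, bat_effect=0.0, date_effect=0.0, params=None, rng=None, size=None):
    """Draw post-buzz pause(s) in integer ms for one outcome level.

    The rate is ``mean_pause_ms[outcome] * exp(bat_effect + date_effect)``;
    draws are zero-truncated Poisson, hence always >= 1 ms.
    """
    params = params if params is not None else OutcomeModelParams()
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    lam = params.mean_pause_ms[outcome] * np.exp(bat_effect + date_effect)
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError("effective rate must be positive and finite")
    draws = ztp_rvs(lam, size=(size,) if np.isscalar(size) else size, rng=rng)
    if size is None:
        return int(draws[()])
    return draws


# ---------------------------------------------------------------------------
# waveform synthesis


def _instantaneous_freq(t, duration, f0, f1):
    """Hyperbolic-sweep instantaneous frequency at times ``t``."""
    return f0 * f1 * duration / ((f0 - f1) * t + f1 * duration)


def synthesize_pulse(params=None, kind="search", sample_rate=DEFAULT_SAMPLE_RATE):
    """Synthesize one FM call as a float waveform segment.

    The fundamental is a hyperbolic downward sweep ``f_start -> f_end``;
    harmonics are integer-multiple sweeps with geometrically decaying
    amplitude.  Because a hyperbolic sweep spends time dt/df proportional to
    1/f^2 at frequency f, the envelope ``(f/peak) * exp(-(f-peak)^2/(4 s^2))``
    yields a Gaussian energy spectrum centred on ``peak_freq`` with width
    ``s = peak_bandwidth``.  Short raised-cosine ramps suppress onset/offset
    clicks.
    """
    params = params if params is not None else PulseSynthParams()
    if kind not in ("search", "buzz"):
        raise ValueError("kind must be 'search' or 'buzz'")
    if sample_rate < 2 * params.n_harmonics * params.f_start:
        raise ValueError(
            "sample_rate too low for the highest harmonic: need >= "
            f"{2 * params.n_harmonics * params.f_start:.0f} Hz"
        )
    duration = params.duration_search if kind == "search" else params.duration_buzz
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    f_inst = _instantaneous_freq(t, duration, params.f_start, params.f_end)
    envelope = (f_inst / params.peak_freq) * np.exp(
        -((f_inst - params.peak_freq) ** 2) / (4.0 * params.peak_bandwidth**2)
    )
    # raised-cosine on/off ramps (20% of the pulse, at most 0.15 ms each)
    ramp = min(int(0.2 * n), int(round(0.00015 * sample_rate)))
    if ramp > 0:
        w = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        envelope[:ramp] *= w
        envelope[-ramp:] *= w[::-1]
    wave = np.zeros(n)
    for h in range(1, params.n_harmonics + 1):
        amp_h = params.harmonic_rolloff ** (h - 1)
        wave += amp_h * signal.chirp(
            t, f0=h * params.f_start, t1=duration, f1=h * params.f_end, method="hyperbolic"
        )
    wave *= envelope
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave *= params.amplitude / peak
    return wave


# ---------------------------------------------------------------------------
# schedules and datasets


def sample_attack_sequence(outcome, params=None, timing=None, synth=None, rng=None,
                           bat_effect=0.0, date_effect=0.0):
    """Draw one attack's :class:`PhaseSchedule` for a given outcome.

    Search pulses at the search IPI, an approach ramp of linearly
    shortening IPIs, a buzz run at the buzz IPI, the drawn pause, then
    resumed search pulses.  The returned schedule's ``pause_ms`` is the
    exact ground truth for the attack.
    """
    params = params if params is not None else OutcomeModelParams()
    timing = timing if timing is not None else SequenceTiming()
    synth = synth if synth is not None else PulseSynthParams()
    dur_s = synth.duration_search * 1000.0
    dur_b = synth.duration_buzz * 1000.0
    entries = [("search", timing.search_ipi_ms, dur_s)] * timing.n_search
    approach_ipis = np.linspace(
        timing.approach_ipi_start_ms, timing.approach_ipi_end_ms, timing.n_approach
    )
    entries += [("approach", float(ipi), dur_s) for ipi in approach_ipis]
    entries += [("buzz", timing.buzz_ipi_ms, dur_b)] * timing.n_buzz
    pause = draw_pause(outcome, bat_effect, date_effect, params, rng=rng)
    resume = [("search", timing.resume_ipi_ms, dur_s)] * timing.n_resume
    return PhaseSchedule(entries=entries, pause_ms=pause, resume_entries=resume)


def _substreams(seed, names):
    """Fan one seed out into named independent generators."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _assign_groups(n_bats, n_dates, n_attacks, rng, start_date="2016-06-10"):
    """Nested design: each bat observed on exactly one date; attacks -> bats."""
    if n_bats < n_dates:
        raise ValueError("need at least one bat per date")
    d0 = _dt.date.fromisoformat(start_date)
    dates = [(d0 + _dt.timedelta(days=i)).isoformat() for i in range(n_dates)]
    bat_ids = [f"bat{i + 1:02d}" for i in range(n_bats)]
    bat_date = {bat: dates[i % n_dates] for i, bat in enumerate(bat_ids)}
    attack_bats = [bat_ids[i] for i in rng.integers(0, n_bats, size=n_attacks)]
    return dates, bat_ids, bat_date, attack_bats


def sample_outcome_table(n_attacks, n_bats=12, n_dates=4, params=None, seed=None,
                         rng_effects=None):
    """Draw an attack/outcome/pause table without rendering audio.

    Returns a DataFrame with columns attack_idx, bat_id, date, outcome,
    pause_ms, weather, temperature.  Weather and temperature are per-date
    nuisance covariates with no effect on the pause, mirroring a study
    design in which only the attack outcome drives the response.
    """
    params = params if params is not None else OutcomeModelParams()
    streams = _substreams(seed, ["outcomes", "pauses", "effects", "assign", "covariates"])
    if n_attacks == 0:
        return pd.DataFrame(
            columns=["attack_idx", "bat_id", "date", "outcome", "pause_ms",
                     "weather", "temperature"]
        )
    dates, bat_ids, bat_date, attack_bats = _assign_groups(
        n_bats, n_dates, n_attacks, streams["assign"]
    )
    eff_rng = rng_effects if rng_effects is not None else streams["effects"]
    date_eff = {d: eff_rng.normal(0.0, params.sd_date) for d in dates}
    bat_eff = {b: eff_rng.normal(0.0, params.sd_bat) for b in bat_ids}
    probs = np.array([params.outcome_probs[o] for o in OUTCOMES])
    outcomes = [OUTCOMES[i] for i in streams["outcomes"].choice(3, size=n_attacks, p=probs)]
    cov_rng = streams["covariates"]
    weather = {d: ("sunny", "cloudy", "rainy")[cov_rng.integers(0, 3)] for d in dates}
    temperature = {d: float(np.round(cov_rng.normal(14.0, 2.0), 1)) for d in dates}
    rows = []
    for i, (bat, outcome) in enumerate(zip(attack_bats, outcomes)):
        date = bat_date[bat]
        pause = draw_pause(outcome, bat_eff[bat], date_eff[date], params,
                           rng=streams["pauses"])
        rows.append(
            {
                "attack_idx": i,
                "bat_id": bat,
                "date": date,
                "outcome": outcome,
                "pause_ms": pause,
                "weather": weather[date],
                "temperature": temperature[date],
            }
        )
    return pd.DataFrame(rows)


def render_dataset(n_bats=4, n_dates=2, n_attacks=8, params=None, timing=None,
                   synth=None, noise_rms=0.001, sample_rate=DEFAULT_SAMPLE_RATE,
                   seed=None, band_limit_noise=False, lead_s=0.05):
    """Render ground-truthed recordings for a set of attacks.

    One recording per attack: the scheduled pulse train embedded in additive
    Gaussian noise at the requested RMS (optionally high-pass filtered at
    10 kHz to mimic a hardware band-pass front end whose upper edge sits at
    Nyquist).  Returns ``(recordings, attacks, pulses)`` where ``attacks``
    is the ground-truth table (one row per attack) and ``pulses`` the
    per-pulse truth (onset/offset/phase).
    """
    params = params if params is not None else OutcomeModelParams()
    timing = timing if timing is not None else SequenceTiming()
    synth = synth if synth is not None else PulseSynthParams()
    streams = _substreams(seed, ["outcomes", "pauses", "effects", "assign",
                                 "covariates", "noise"])
    if n_attacks == 0:
        cols = ["recording_id", "bat_id", "date", "attack_idx", "outcome", "pause_ms",
                "buzz_end_s", "next_pulse_start_s", "weather", "temperature"]
        return [], pd.DataFrame(columns=cols), pd.DataFrame(
            columns=["recording_id", "onset_s", "offset_s", "phase"]
        )
    dates, bat_ids, bat_date, attack_bats = _assign_groups(
        n_bats, n_dates, n_attacks, streams["assign"]
    )
    eff_rng = streams["effects"]
    date_eff = {d: eff_rng.normal(0.0, params.sd_date) for d in dates}
    bat_eff = {b: eff_rng.normal(0.0, params.sd_bat) for b in bat_ids}
    probs = np.array([params.outcome_probs[o] for o in OUTCOMES])
    outcomes = [OUTCOMES[i] for i in streams["outcomes"].choice(3, size=n_attacks, p=probs)]
    cov_rng = streams["covariates"]
    weather = {d: ("sunny", "cloudy", "rainy")[cov_rng.integers(0, 3)] for d in dates}
    temperature = {d: float(np.round(cov_rng.normal(14.0, 2.0), 1)) for d in dates}

    search_wave = synthesize_pulse(synth, "search", sample_rate)
    buzz_wave = synthesize_pulse(synth, "buzz", sample_rate)
    sos = None
    if band_limit_noise:
        sos = signal.butter(4, 10_000.0, btype="highpass", fs=sample_rate, output="sos")

    recordings, attack_rows, pulse_rows = [], [], []
    for i, (bat, outcome) in enumerate(zip(attack_bats, outcomes)):
        date = bat_date[bat]
        schedule = sample_attack_sequence(
            outcome, params, timing, synth, rng=streams["pauses"],
            bat_effect=bat_eff[bat], date_effect=date_eff[date],
        )
        onsets_ms, durs_ms, phases = schedule.realize()
        onset_samples = np.round(onsets_ms / 1000.0 * sample_rate).astype(int)
        lead = int(round(lead_s * sample_rate))
        total = lead + onset_samples[-1] + len(search_wave) + lead
        wave = np.zeros(total)
        rid = f"rec{i:04d}"
        n_pre = len(schedule.entries)
        for j, (s0, phase) in enumerate(zip(onset_samples, phases)):
            pulse = buzz_wave if phase == "buzz" else search_wave
            start = lead + s0
            wave[start : start + len(pulse)] += pulse
            pulse_rows.append(
                {
                    "recording_id": rid,
                    "onset_s": start / sample_rate,
                    "offset_s": (start + len(pulse)) / sample_rate,
                    "phase": phase,
                }
            )
            if j == n_pre - 1:
                buzz_end = (start + len(pulse)) / sample_rate
            elif j == n_pre:
                next_start = start / sample_rate
        if noise_rms > 0:
            noise = streams["noise"].normal(0.0, noise_rms, size=total)
            if sos is not None:
                noise = signal.sosfiltfilt(sos, noise)
            wave += noise
        recordings.append(Recording(rid, wave, sample_rate))
        attack_rows.append(
            {
                "recording_id": rid,
                "bat_id": bat,
                "date": date,
                "attack_idx": i,
                "outcome": outcome,
                "pause_ms": int(schedule.pause_ms),
                "buzz_end_s": buzz_end,
                "next_pulse_start_s": next_start,
                "weather": weather[date],
                "temperature": temperature[date],
            }
        )
    return recordings, pd.DataFrame(attack_rows), pd.DataFrame(pulse_rows)
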