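"""Spectrogram-based echolocation pulse detection.

The measurement convention mirrors classic bioacoustic practice for FM
bats: a short-time power envelope from a 128-point FFT with a Han window,
candidate regions gated a fixed margin above a robust noise floor, and each
pulse's start/end refined to the points -15 dB below that pulse's peak
power.  A coarse-hop scan locates candidates cheaply; endpoints are then
refined on a hop-1 envelope restricted to a local window, which is
numerically identical to running the full overlap everywhere.

Frame times refer to window centres; threshold crossings are linearly
interpolated between frames for sub-frame timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator

from .synth import Recording

__all__ = [
    "SpectrogramParams",
    "DetectionParams",
    "PulseEvent",
    "Envelope",
    "compute_envelope",
    "estimate_noise_floor",
    "refine_endpoints",
    "detect_pulses",
    "PulseDetector",
    "events_to_frame",
]

DB_FLOOR = -120.0


@dataclass
class SpectrogramParams:
    """Short-time spectrum settings for the power envelope."""

    n_fft: int = 128
    window: str = "hann"
    hop: int = 1
    band: tuple = (30_000.0, 100_000.0)

    def __post_init__(self):
        if not (1 <= self.hop <= self.n_fft):
            raise ValueError("hop must satisfy 1 <= hop <= n_fft")
        if not (0 <= self.band[0] < self.band[1]):
            raise ValueError("band must satisfy 0 <= f_lo < f_hi")


@dataclass
class DetectionParams:
    """Event gating and endpoint rules.

    ``endpoint_threshold_db`` is the level below each pulse's own peak at
    which its start and end are read off (-15 dB); ``floor_margin_db`` gates
    candidate regions above the estimated noise floor; regions closer than
    ``merge_gap_ms`` are fused and events shorter than ``min_duration_ms``
    discarded.
    """

    endpoint_threshold_db: float = -15.0
    floor_margin_db: float = 6.0
    min_duration_ms: float = 0.2
    merge_gap_ms: float = 0.5
    coarse_hop: int = 8
    refine_pad_ms: float = 1.0

    def __post_init__(self):
        if self.endpoint_threshold_db >= 0:
            raise ValueError("endpoint threshold is relative to the peak and must be < 0")
        if self.min_duration_ms <= 0 or self.merge_gap_ms < 0:
            raise ValueError("min duration must be > 0 and merge gap >= 0")


@dataclass
class PulseEvent:
    """One detected call with sub-frame endpoint timing."""

    start: float
    end: float
    peak_time: float
    peak_power: float
    peak_freq: float
    snr: float
    clipped: bool = False  # endpoints fell back to region/floor bounds


@dataclass
class Envelope:
    """In-band short-time power (dB) at window-centre frame times."""

    times: np.ndarray
    power_db: np.ndarray
    sample_rate: int
    hop: int
    n_fft: int


def _band_bins(n_fft, sample_rate, band):
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= min(hi, sample_rate / 2))
    if not np.any(mask):
        raise ValueError("frequency band contains no FFT bins")
    return mask, freqs


def compute_envelope(recording, params=None, start_sample=0, end_sample=None):
    """In-band power envelope of a recording in dB re full scale.

    Frame ``i`` covers samples ``[i*hop, i*hop + n_fft)`` (offset by
    ``start_sample``) and is stamped at the window centre.  Power is the
    magnitude-squared short-time spectrum summed over bins inside
    ``params.band``, referenced to the peak-bin power of a full-scale sine
    (so 0 dB is the loudest narrowband signal the scale can hold), floored
    at -120 dB.
    """
    params = params if params is not None else SpectrogramParams()
    x = recording.samples if isinstance(recording, Recording) else np.asarray(recording)
    fs = recording.sample_rate if isinstance(recording, Recording) else None
    if fs is None:
        raise ValueError("pass a Recording (waveform + sample rate)")
    seg = x[start_sample : end_sample if end_sample is not None else len(x)]
    n_fft, hop = params.n_fft, params.hop
    if len(seg) < n_fft:
        raise ValueError(f"recording segment shorter than one {n_fft}-sample window")
    win = signal.get_window(params.window, n_fft, fftbins=True)
    ref = (win.sum() / 2.0) ** 2
    mask, _ = _band_bins(n_fft, fs, params.band)
    n_frames = (len(seg) - n_fft) // hop + 1
    power = np.empty(n_frames)
    view = np.lib.stride_tricks.sliding_window_view(seg, n_fft)
    block = 65536  # frames per chunk; bounds peak memory at hop=1
    for b0 in range(0, n_frames, block):
        b1 = min(b0 + block, n_frames)
        frames = view[b0 * hop : (b1 - 1) * hop + 1 : hop] * win
        spec = np.fft.rfft(frames, axis=1)
        power[b0:b1] = np.sum(np.abs(spec[:, mask]) ** 2, axis=1)
    power_db = 10.0 * np.log10(np.maximum(power / ref, 10 ** (DB_FLOOR / 10.0)))
    times = (start_sample + np.arange(n_frames) * hop + n_fft / 2.0) / fs
    return Envelope(times=times, power_db=power_db, sample_rate=fs, hop=hop, n_fft=n_fft)


def estimate_noise_floor(envelope):
    """Median of the envelope (dB): robust to sparse pulses (<~5% of frames)."""
    power = envelope.power_db if isinstance(envelope, Envelope) else np.asarray(envelope)
    if power.size == 0:
        raise ValueError("cannot estimate a noise floor from an empty envelope")
    return float(np.median(power))


def refine_endpoints(power_db, peak_idx, threshold_db=-15.0, floor_db=None):
    """Outermost crossings of (peak + threshold) around a peak, interpolated.

    Scans inward from the segment edges: the start is the first rising
    crossing of the level, the end the last falling crossing, both linearly
    interpolated between frames.  If the level is unreachable (flat segment,
    or the level lies below the noise floor), the affected bound clips to
    the segment edge (or to the floor crossing) and the result is flagged.

    Returns ``(start_idx, end_idx, clipped)`` in fractional frame indices.
    """
    env = np.asarray(power_db, dtype=float)
    n = len(env)
    if not (0 <= peak_idx < n):
        raise ValueError("peak index outside segment")
    level = env[peak_idx] + threshold_db
    clipped = False
    if floor_db is not None and level < floor_db:
        level = floor_db
        clipped = True

    above = env >= level
    if above.all() or not above[peak_idx]:
        return 0.0, float(n - 1), True

    # start: first rising crossing at or before the peak, scanning from the left
    start = 0.0
    left = above[: peak_idx + 1]
    if left[0]:
        clipped = True  # segment begins already above the level
    else:
        rises = np.flatnonzero(~left[:-1] & left[1:])
        i = rises[0]
        frac = (level - env[i]) / (env[i + 1] - env[i])
        start = i + frac
    # end: last falling crossing at or after the peak, scanning from the right
    end = float(n - 1)
    right = above[peak_idx:]
    if right[-1]:
        clipped = True
    else:
        falls = np.flatnonzero(right[:-1] & ~right[1:]) + peak_idx
        j = falls[-1]
        frac = (env[j] - level) / (env[j] - env[j + 1])
        end = j + frac
    return float(start), float(end), clipped


def _regions_above(mask):
    """Contiguous True runs as (first, last) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return list(zip(starts, ends))


def _merge_regions(regions, times, merge_gap_s):
    merged = []
    for a, b in regions:
        if merged and times[a] - times[merged[-1][1]] < merge_gap_s:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def detect_pulses(envelope, noise_floor, det=None):
    """Detect pulses on a single envelope (no re-refinement at finer hop).

    Candidate frames exceed ``noise_floor + floor_margin_db``; runs closer
    than the merge gap are fused; each region's endpoints are refined to the
    -15 dB-from-peak crossings (earliest frame wins among equal peaks) and
    regions shorter than the minimum duration are dropped.  Events come back
    sorted and non-overlapping.  ``peak_freq`` is not computable from a bare
    envelope and is NaN here; :class:`PulseDetector` fills it.
    """
    det = det if det is not None else DetectionParams()
    env, times = envelope.power_db, envelope.times
    threshold = noise_floor + det.floor_margin_db
    regions = _merge_regions(_regions_above(env > threshold), times, det.merge_gap_ms / 1e3)
    events = []
    for a, b in regions:
        seg = env[a : b + 1]
        peak_local = int(np.argmax(seg))  # argmax returns the earliest maximum
        s, e, clipped = refine_endpoints(
            seg, peak_local, det.endpoint_threshold_db, floor_db=noise_floor
        )
        frame_dt = envelope.hop / envelope.sample_rate
        t0 = times[a] + s * frame_dt
        t1 = times[a] + e * frame_dt
        if (t1 - t0) * 1e3 < det.min_duration_ms:
            continue
        events.append(
            PulseEvent(
                start=t0,
                end=t1,
                peak_time=times[a + peak_local],
                peak_power=float(seg[peak_local]),
                peak_freq=float("nan"),
                snr=float(seg[peak_local] - noise_floor),
                clipped=clipped,
            )
        )
    events.sort(key=lambda ev: ev.start)
    return events


class PulseDetector(BaseEstimator):
    """Two-stage pulse detector: coarse-hop scan, hop-1 endpoint refinement.

    Parameters mirror :class:`SpectrogramParams` and :class:`DetectionParams`.
    The coarse scan (default hop 8) finds candidate regions; each candidate
    is then re-enveloped at hop 1 in a padded local window, so endpoint
    timing matches a full hop-1 analysis without its memory cost.
    """

    def __init__(self, spectrogram=None, detection=None):
        self.spectrogram = spectrogram
        self.detection = detection

    def _params(self):
        spec = self.spectrogram if self.spectrogram is not None else SpectrogramParams()
        det = self.detection if self.detection is not None else DetectionParams()
        return spec, det

    def detect(self, recording):
        """Return the list of :class:`PulseEvent` found in one recording."""
        spec, det = self._params()
        coarse = SpectrogramParams(
            n_fft=spec.n_fft, window=spec.window, hop=det.coarse_hop, band=spec.band
        )
        env = compute_envelope(recording, coarse)
        floor = estimate_noise_floor(env)
        threshold = floor + det.floor_margin_db
        regions = _merge_regions(
            _regions_above(env.power_db > threshold), env.times, det.merge_gap_ms / 1e3
        )
        fine = SpectrogramParams(n_fft=spec.n_fft, window=spec.window, hop=1, band=spec.band)
        win = signal.get_window(spec.window, spec.n_fft, fftbins=True)
        mask, freqs = _band_bins(spec.n_fft, recording.sample_rate, spec.band)
        pad = int(round(det.refine_pad_ms / 1e3 * recording.sample_rate)) + spec.n_fft
        events = []
        for a, b in regions:
            s0 = max(0, a * det.coarse_hop - pad)
            s1 = min(len(recording.samples), b * det.coarse_hop + spec.n_fft + pad)
            local = compute_envelope(recording, fine, start_sample=s0, end_sample=s1)
            # confine the peak search to the gated region itself
            in_region = (local.times >= env.times[a] - det.coarse_hop / recording.sample_rate) & (
                local.times <= env.times[b]
            )
            if not in_region.any():
                continue
            idx_region = np.flatnonzero(in_region)
            peak_idx = idx_region[int(np.argmax(local.power_db[idx_region]))]
            s, e, clipped = refine_endpoints(
                local.power_db, peak_idx, det.endpoint_threshold_db, floor_db=floor
            )
            frame_dt = 1.0 / recording.sample_rate
            t0 = local.times[0] + s * frame_dt
            t1 = local.times[0] + e * frame_dt
            if (t1 - t0) * 1e3 < det.min_duration_ms:
                continue
            frame0 = s0 + peak_idx
            seg = recording.samples[frame0 : frame0 + spec.n_fft]
            spec_amp = np.abs(np.fft.rfft(seg * win)) ** 2
            peak_freq = float(freqs[mask][int(np.argmax(spec_amp[mask]))])
            events.append(
                PulseEvent(
                    start=t0,
                    end=t1,
                    peak_time=float(local.times[peak_idx]),
                    peak_power=float(local.power_db[peak_idx]),
                    peak_freq=peak_freq,
                    snr=float(local.power_db[peak_idx] - floor),
                    clipped=clipped,
                )
            )
        events.sort(key=lambda ev: ev.start)
        return events


def events_to_frame(events, recording_id=""):
    """Pulse events as the pulse-event table (one row per call)."""
    return pd.DataFrame(
        [
            {
                "recording_id": recording_id,
                "start_s": ev.start,
                "end_s": ev.end,
                "peak_time_s": ev.peak_time,
                "peak_power_db": ev.peak_power,
                "peak_freq_hz": ev.peak_freq,
                "snr_db": ev.snr,
            }
            for ev in events
        ],
        columns=[
            "recording_id",
            "start_s",
            "end_s",
            "peak_time_s",
            "peak_power_db",
            "peak_freq_hz",
            "snr_db",
        ],
    )
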