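"""Phase classification, terminal-buzz location and post-buzz pause measurement.

Echolocation attack sequences run search -> approach -> terminal buzz: the
inter-pulse interval (IPI, onset to onset) shortens from ~100 ms in search
to a few ms in the buzz.  Each pulse is labelled by the IPI to its
successor, so a label marks the interval the pulse opens; a maximal run of
buzz-labelled pulses therefore covers all but the last pulse emitted at
buzz rate, and the run is extended by that one trailing pulse when the
buzz is located.  The post-buzz pause is the silent gap from the end of the
last buzz pulse to the start of the next detected pulse, reported as an
integer number of milliseconds with a floor of 1 (the response can never
be 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "PhaseParams",
    "AttackRecord",
    "classify_phases",
    "find_terminal_buzzes",
    "measure_post_buzz_pause",
    "BuzzSegmenter",
    "attacks_to_frame",
]


@dataclass
class PhaseParams:
    """IPI thresholds separating the phases, and pause-validity limits.

    A pulse whose IPI to its successor is <= ``buzz_ipi_max_ms`` is buzz,
    >= ``search_ipi_min_ms`` is search, anything between is approach.
    ``max_pause_ms`` caps how long a silent gap may be and still count as a
    post-buzz pause rather than a bout boundary.
    """

    buzz_ipi_max_ms: float = 15.0
    search_ipi_min_ms: float = 40.0
    min_buzz_length: int = 5
    max_pause_ms: float = 2000.0
    strict_search_resume: bool = False  # require the next pulse to be search-labelled

    def __post_init__(self):
        if self.buzz_ipi_max_ms >= self.search_ipi_min_ms:
            raise ValueError("buzz IPI max must be below search IPI min")
        if self.min_buzz_length < 2:
            raise ValueError("a buzz needs at least 2 pulses")


@dataclass
class AttackRecord:
    """One terminal buzz and its (possibly unmeasurable) post-buzz pause."""

    buzz_indices: list
    buzz_start: float
    buzz_end: float
    next_pulse_start: float
    pause_ms: int
    measurable: bool
    outcome: str = "unknown"
    bat_id: str = ""
    date: str = ""


def _starts_ends(pulses):
    """Onset/offset arrays from PulseEvents or a pulse-event DataFrame."""
    if isinstance(pulses, pd.DataFrame):
        return pulses["start_s"].to_numpy(float), pulses["end_s"].to_numpy(float)
    starts = np.array([p.start for p in pulses], dtype=float)
    ends = np.array([p.end for p in pulses], dtype=float)
    return starts, ends


def classify_phases(pulses, params=None):
    """Label every pulse 'search' / 'approach' / 'buzz' by its onward IPI.

    The trailing pulse inherits its predecessor's label.  Fewer than two
    pulses cannot define an interval: all labels come back 'unknown'.
    """
    params = params if params is not None else PhaseParams()
    starts, _ = _starts_ends(pulses)
    n = len(starts)
    if n < 2:
        return ["unknown"] * n
    if np.any(np.diff(starts) < 0):
        raise ValueError("pulses must be sorted by start time")
    ipis_ms = np.diff(starts) * 1e3
    labels = np.where(
        ipis_ms <= params.buzz_ipi_max_ms,
        "buzz",
        np.where(ipis_ms >= params.search_ipi_min_ms, "search", "approach"),
    ).tolist()
    labels.append(labels[-1])
    return labels


def find_terminal_buzzes(pulses, params=None, labels=None):
    """Locate terminal buzzes: index lists of pulses emitted at buzz rate.

    A maximal run of >= (min_buzz_length - 1) consecutive buzz labels,
    extended by the one trailing pulse that closes the last buzz interval,
    yields a buzz of >= min_buzz_length pulses.  The pulse after the run is
    by construction more than the buzz IPI away (the run is maximal), i.e.
    every buzz is followed by a gap.  Runs are returned in time order.
    """
    params = params if params is not None else PhaseParams()
    if labels is None:
        labels = classify_phases(pulses, params)
    runs, current = [], []
    for i, lab in enumerate(labels[:-1]):  # last label is inherited, not an interval
        if lab == "buzz":
            current.append(i)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    out = []
    for run in runs:
        full = run + [run[-1] + 1]  # trailing pulse closing the final buzz interval
        if len(full) >= params.min_buzz_length:
            out.append(full)
    return out


def measure_post_buzz_pause(pulses, buzz_run, params=None, annotation=None):
    """Measure one buzz's post-buzz pause as an :class:`AttackRecord`.

    The pause is the gap from the last buzz pulse's end to the next
    detected pulse's start, rounded to the nearest integer millisecond and
    floored at 1.  If no pulse follows within ``max_pause_ms`` (or the buzz
    ends the recording) the attack is flagged unmeasurable.  With
    ``strict_search_resume`` the next pulse must also be search-labelled.
    """
    params = params if params is not None else PhaseParams()
    starts, ends = _starts_ends(pulses)
    last = buzz_run[-1]
    buzz_end = float(ends[last])
    record = AttackRecord(
        buzz_indices=list(buzz_run),
        buzz_start=float(starts[buzz_run[0]]),
        buzz_end=buzz_end,
        next_pulse_start=float("nan"),
        pause_ms=0,
        measurable=False,
    )
    nxt = last + 1
    if params.strict_search_resume:
        labels = classify_phases(pulses, params)
        while nxt < len(starts) and labels[nxt] != "search":
            nxt += 1
    if nxt >= len(starts):
        return record
    gap_ms = (starts[nxt] - buzz_end) * 1e3
    if gap_ms > params.max_pause_ms:
        return record
    record.next_pulse_start = float(starts[nxt])
    record.pause_ms = max(1, int(round(gap_ms)))
    record.measurable = True
    if annotation is not None:
        record.outcome = annotation.get("outcome", "unknown")
        record.bat_id = annotation.get("bat_id", "")
        record.date = annotation.get("date", "")
    return record


class BuzzSegmenter(BaseEstimator):
    """Pulse list -> attack records (phases, buzzes, pauses) in one call."""

    def __init__(self, phase=None):
        self.phase = phase

    def segment(self, pulses, annotation=None):
        """All attacks in one recording's pulse sequence, in time order."""
        params = self.phase if self.phase is not None else PhaseParams()
        if len(pulses) < 2:
            return []
        labels = classify_phases(pulses, params)
        return [
            measure_post_buzz_pause(pulses, run, params, annotation=annotation)
            for run in find_terminal_buzzes(pulses, params, labels=labels)
        ]


def attacks_to_frame(records, recording_id=""):
    """Attack records as the attack table (one row per terminal buzz)."""
    return pd.DataFrame(
        [
            {
                "recording_id": recording_id,
                "bat_id": r.bat_id,
                "date": r.date,
                "buzz_start_s": r.buzz_start,
                "buzz_end_s": r.buzz_end,
                "n_buzz_pulses": len(r.buzz_indices),
                "pause_ms": r.pause_ms if r.measurable else pd.NA,
                "measurable": r.measurable,
                "outcome": r.outcome,
            }
            for r in records
        ],
        columns=[
            "recording_id",
            "bat_id",
            "date",
            "buzz_start_s",
            "buzz_end_s",
            "n_buzz_pulses",
            "pause_ms",
            "measurable",
            "outcome",
        ],
    )
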