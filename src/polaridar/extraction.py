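"""Event extraction from raw time x range streams.

Insect transits are isolated by a robust per-pixel threshold: samples of the
summed (co+de) intensity exceeding the median plus ``k_iqr`` times the
interquartile range, both computed over the whole 5-second file.  Contiguous
above-threshold runs (after closing short gaps caused by flash nulls within a
transit) become event candidates; the run length in milliseconds is the
transit-time estimate, and observations are kept only if the transit strictly
exceeds the 40 ms minimum (the reciprocal of the lowest observable wingbeat
frequency, 25 Hz).

Each range pixel is processed independently; merging of events spanning
adjacent pixels is not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import FS_HZ
from .synthdata import RawStream

#: default threshold factor: median + 5 x IQR
DEFAULT_K_IQR = 5.0
#: default minimum transit time (strictly exceeded) in ms
DEFAULT_MIN_TRANSIT_MS = 40.0
#: gaps shorter than this are bridged within one transit
DEFAULT_MERGE_GAP_MS = 5.0

_SAMPLES_PER_MS = FS_HZ / 1000.0


@dataclass
class EventCandidate:
    """A contiguous above-threshold run on one range pixel."""

    start: int
    stop: int  # half-open sample interval [start, stop)
    pixel: int
    waveform_co: np.ndarray
    waveform_de: np.ndarray

    @property
    def transit_ms(self) -> float:
        return (self.stop - self.start) / _SAMPLES_PER_MS


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) intervals of True runs in a boolean vector."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[0::2], edges[1::2]))


def detect_events(
    stream: RawStream,
    k_iqr: float = DEFAULT_K_IQR,
    merge_gap_ms: float = DEFAULT_MERGE_GAP_MS,
) -> list[EventCandidate]:
    """Threshold a raw stream into event candidates.

    Per pixel, threshold = median + ``k_iqr`` x IQR of the summed (co+de)
    channel over the whole file.  Events contribute to the statistics; the
    robust median/IQR tolerate them.  Runs separated by gaps shorter than
    ``merge_gap_ms`` are merged into a single candidate.
    """
    total = stream.intensity_co + stream.intensity_de
    if total.size == 0:
        raise ValueError("stream is empty")
    n_samples, n_pixels = total.shape
    gap = int(round(merge_gap_ms * _SAMPLES_PER_MS))
    events: list[EventCandidate] = []
    for pixel in range(n_pixels):
        column = total[:, pixel]
        q1, med, q3 = np.percentile(column, [25.0, 50.0, 75.0])
        threshold = med + k_iqr * (q3 - q1)
        runs = _runs_above(column > threshold)
        if not runs:
            continue
        merged = [list(runs[0])]
        for start, stop in runs[1:]:
            if start - merged[-1][1] < gap:
                merged[-1][1] = stop
            else:
                merged.append([start, stop])
        for start, stop in merged:
            events.append(
                EventCandidate(
                    start=int(start),
                    stop=int(stop),
                    pixel=pixel,
                    waveform_co=stream.intensity_co[start:stop, pixel].copy(),
                    waveform_de=stream.intensity_de[start:stop, pixel].copy(),
                )
            )
    return events


def filter_min_transit(
    events: list[EventCandidate], min_transit_ms: float = DEFAULT_MIN_TRANSIT_MS
) -> list[EventCandidate]:
    """Keep events whose transit strictly exceeds ``min_transit_ms``; order preserved."""
    return [e for e in events if e.transit_ms > min_transit_ms]
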