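"""Single-unit discharge metrics and cell-type classification.

Hippocampal units are gated into putative pyramidal (complex-spike)
cells versus theta cells (putative interneurons) from waveform duration
and mean discharge rate; only pyramidal cells enter the place-coding
analyses. The burst ratio characterises burstiness but carries no
numeric classification threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: ISI bound defining a burst, seconds.
BURST_ISI_S = 0.030
#: Reference ISI window for the burst-ratio denominator, seconds (closed).
REFERENCE_ISI_S = (0.100, 0.130)
#: Waveform-duration gate separating pyramidal from theta cells, microseconds.
WAVEFORM_GATE_US = 250.0
#: Rate gates: pyramidal < 5 spikes/s, theta > 2 spikes/s.
PYRAMIDAL_MAX_RATE = 5.0
THETA_MIN_RATE = 2.0

VALID_REGIONS = ("hippocampus", "thalamus", "unknown")


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit plus waveform metadata."""

    unit_id: str
    spike_times: np.ndarray
    waveform_us: float | None = None
    region: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError(f"spike times of unit {self.unit_id} not strictly increasing")
        if self.waveform_us is not None and self.waveform_us < 0:
            raise ValueError("waveform duration must be non-negative")
        if self.region not in VALID_REGIONS:
            raise ValueError(f"region must be one of {VALID_REGIONS}, got {self.region!r}")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def mean_rate(train: SpikeTrain, session_length: float) -> float:
    """Mean discharge rate, spikes/s over the whole recording."""
    if session_length <= 0:
        raise ValueError("session_length must be positive")
    return train.n_spikes / session_length


def burst_ratio(train: SpikeTrain) -> float:
    """Count of ISIs <= 30 ms over count of ISIs in [100, 130] ms.

    Each inter-spike interval is attributed once. Returns NaN when the
    denominator is zero (undefined; such units are excluded from group
    means). Fewer than two spikes is an error.
    """
    if train.n_spikes < 2:
        raise ValueError("burst ratio needs at least two spikes")
    isi = np.diff(train.spike_times)
    num = int(np.count_nonzero(isi <= BURST_ISI_S))
    lo, hi = REFERENCE_ISI_S
    den = int(np.count_nonzero((isi >= lo) & (isi <= hi)))
    if den == 0:
        return float("nan")
    return num / den


def classify_unit(rate: float, waveform_us: float | None) -> str:
    """Classify a unit as 'pyramidal', 'theta' or 'unclassified'.

    Pyramidal (complex-spike) cells: waveform > 250 us and rate < 5
    spikes/s. Theta cells: waveform < 250 us and rate > 2 spikes/s.
    Anything else — including a missing waveform — is unclassified.
    """
    if waveform_us is None or not np.isfinite(waveform_us):
        warnings.warn("missing waveform duration; unit left unclassified")
        return "unclassified"
    if waveform_us > WAVEFORM_GATE_US and rate < PYRAMIDAL_MAX_RATE:
        return "pyramidal"
    if waveform_us < WAVEFORM_GATE_US and rate > THETA_MIN_RATE:
        return "theta"
    return "unclassified"


def unit_metrics_table(trains: list[SpikeTrain], session_length: float) -> pd.DataFrame:
    """Per-unit metrics: spike count, mean rate, burst ratio, class."""
    rows = []
    for tr in trains:
        r = mean_rate(tr, session_length)
        br = burst_ratio(tr) if tr.n_spikes >= 2 else float("nan")
        rows.append({
            "unit_id": tr.unit_id,
            "n_spikes": tr.n_spikes,
            "mean_rate_hz": r,
            "burst_ratio": br,
            "class": classify_unit(r, tr.waveform_us),
            "region": tr.region,
        })
    return pd.DataFrame(rows, columns=["unit_id", "n_spikes", "mean_rate_hz",
                                       "burst_ratio", "class", "region"])


def select_pyramidal(trains: list[SpikeTrain], session_length: float,
                     min_spikes: int = 50) -> list[SpikeTrain]:
    """Hippocampal pyramidal cells with at least ``min_spikes`` spikes.

    This is the gate into the overdispersion and frame-preference
    pipelines: only hippocampal units classified as pyramidal cells are
    studied there.
    """
    keep = []
    for tr in trains:
        if tr.region != "hippocampus" or tr.n_spikes < min_spikes:
            continue
        if classify_unit(mean_rate(tr, session_length), tr.waveform_us) == "pyramidal":
            keep.append(tr)
    return keep
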