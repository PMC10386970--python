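"""ERP component measures on the frontocentral virtual channel.

All measures operate on participant-level condition averages (one average
waveform per participant x context x duration) computed after a per-trial
baseline correction appropriate to each component:

=========  ======  =====================  ==================================
component  lock    baseline (re lock)     measures
=========  ======  =====================  ==================================
CNV        onset   [-200, 0] ms           climbing rate: OLS slope over
                                          [250, 650] ms (μV/s); peak: most
                                          negative sample in [0, 1600] ms;
                                          peak amplitude: mean of ±5 ms
                                          around the peak; mean amplitude
                                          over [250, 250 + D] ms; crossing
                                          latency: first negative-to-
                                          positive zero crossing after
                                          650 ms
offsetP2   offset  [-50, +50] ms          peak: most positive sample within
                                          [0, 500] ms after offset; peak
                                          amplitude: ±5 ms mean; mean
                                          amplitude over [140, 300] ms
                                          after offset
LPCt       cue     [-50, +50] ms          peak: most positive sample within
                                          [0, 500] ms after the response
                                          cue; peak amplitude: ±5 ms mean;
                                          mean amplitude over [300, 500] ms
                                          after *offset* (mixed convention,
                                          deliberate)
=========  ======  =====================  ==================================

Window rules are closed intervals on the sample grid.  Note that the CNV
mean-amplitude window [250, 250 + D] extends past the stimulus offset for
every duration; this is implemented literally.  Peak ties (plateaus)
resolve to the earliest sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import EpochSet

__all__ = [
    "ComponentSpec",
    "COMPONENTS",
    "PeakMeasure",
    "baseline_correct",
    "condition_average",
    "cnv_climbing_rate",
    "peak_measure",
    "windowed_mean_amplitude",
    "crossing_latency",
    "extract_feature_table",
]

_LOCKS = ("onset", "offset", "cue")


@dataclass(frozen=True)
class ComponentSpec:
    """Window constants for one ERP component."""

    component: str
    lock: str                       # "onset" | "offset" | "cue"
    baseline_window: tuple[float, float]   # ms relative to lock
    search_window: tuple[float, float]     # peak search, ms relative to lock
    polarity: str                   # "negative" | "positive"
    mean_window: tuple[float, float] | None  # None for the CNV's [250, 250+D]
    mean_lock: str = "offset"       # lock of the mean-amplitude window

    def __post_init__(self) -> None:
        for w in (self.baseline_window, self.search_window):
            if w[1] <= w[0]:
                raise ValueError(f"window {w} is not well-ordered")
        if self.lock not in _LOCKS or self.mean_lock not in _LOCKS:
            raise ValueError(f"lock must be one of {_LOCKS}")
        expected = 200.0 if self.component == "CNV" else 100.0
        if self.baseline_window[1] - self.baseline_window[0] != expected:
            raise ValueError(
                f"{self.component} baseline window must span {expected:g} ms"
            )


COMPONENTS: dict[str, ComponentSpec] = {
    "CNV": ComponentSpec(
        component="CNV", lock="onset", baseline_window=(-200.0, 0.0),
        search_window=(0.0, 1600.0), polarity="negative",
        mean_window=None, mean_lock="onset",
    ),
    "offsetP2": ComponentSpec(
        component="offsetP2", lock="offset", baseline_window=(-50.0, 50.0),
        search_window=(0.0, 500.0), polarity="positive",
        mean_window=(140.0, 300.0), mean_lock="offset",
    ),
    "LPCt": ComponentSpec(
        component="LPCt", lock="cue", baseline_window=(-50.0, 50.0),
        search_window=(0.0, 500.0), polarity="positive",
        mean_window=(300.0, 500.0), mean_lock="offset",
    ),
}


def _window_slice(times: np.ndarray, lo: float, hi: float) -> slice:
    """Indices of the closed interval [lo, hi] on the grid."""
    eps = 1e-9
    i0 = int(np.searchsorted(times, lo - eps, side="left"))
    i1 = int(np.searchsorted(times, hi + eps, side="right"))
    return slice(i0, i1)


def _lock_times(metadata: pd.DataFrame, lock: str) -> np.ndarray:
    if lock == "onset":
        return np.zeros(len(metadata))
    if lock == "offset":
        return metadata["duration_ms"].to_numpy(dtype=float)
    if lock == "cue":
        return metadata["cue_latency_ms"].to_numpy(dtype=float)
    raise ValueError(f"unknown lock {lock!r}; expected one of {_LOCKS}")


def baseline_correct(
    epochs: EpochSet, lock: str, window: tuple[float, float]
) -> EpochSet:
    """Subtract each trial's mean over ``window`` (ms relative to ``lock``).

    Offset- and cue-locked windows differ per trial because durations
    differ; the correction is applied per trial.  Afterwards every trial's
    mean over its own window is 0 to numeric precision.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"window {window} is not well-ordered")
    out = epochs.copy()
    events = _lock_times(epochs.metadata, lock)
    times = epochs.times_ms
    for i, ev in enumerate(events):
        sl = _window_slice(times, ev + lo, ev + hi)
        if (times[0] > ev + lo + 1e-9) or (times[-1] < ev + hi - 1e-9):
            raise ValueError(
                f"baseline window [{ev + lo:g}, {ev + hi:g}] ms lies outside "
                f"the epoch grid [{times[0]:g}, {times[-1]:g}] for trial {i}"
            )
        out.data[i] -= out.data[i, sl].mean()
    out.baseline = (lock, (float(lo), float(hi)))
    return out


def condition_average(
    epochs: EpochSet,
    by: tuple[str, ...] = ("participant", "context", "duration_ms"),
) -> EpochSet:
    """Pointwise mean waveform per cell; metadata records the trial count.

    Every requested cell must be non-empty (groupby only forms non-empty
    cells; an empty input raises).
    """
    if epochs.n_trials == 0:
        raise ValueError("cannot average an empty EpochSet")
    meta = epochs.metadata
    keys, rows, avgs = [], [], []
    for key, idx in meta.groupby(list(by)).indices.items():
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row["n_trials"] = len(idx)
        cell_meta = meta.iloc[idx]
        for col in ("duration_ms", "cue_latency_ms", "participant", "context"):
            if col not in row and col in cell_meta.columns:
                vals = cell_meta[col].unique()
                row[col] = vals[0] if len(vals) == 1 else np.nan
        rows.append(row)
        avgs.append(epochs.data[idx].mean(axis=0))
        keys.append(key)
    new_meta = pd.DataFrame(rows)
    order = new_meta.sort_values(list(by)).index.to_numpy()
    return EpochSet(
        data=np.stack(avgs)[order],
        times_ms=epochs.times_ms.copy(),
        metadata=new_meta.iloc[order].reset_index(drop=True),
        sfreq_hz=epochs.sfreq_hz,
        baseline=epochs.baseline,
    )


def _require_window(times: np.ndarray, lo: float, hi: float, what: str) -> slice:
    if times[0] > lo + 1e-9 or times[-1] < hi - 1e-9:
        raise ValueError(
            f"{what} window [{lo:g}, {hi:g}] ms is not covered by the grid "
            f"[{times[0]:g}, {times[-1]:g}] ms"
        )
    return _window_slice(times, lo, hi)


def cnv_climbing_rate(
    waveform: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = (250.0, 650.0),
) -> float:
    """OLS slope of amplitude vs time over the closed window, in μV/s.

    The default window [250, 650] ms covers the early climb of the CNV,
    after the onset P2 and before the negativity can level off.
    """
    sl = _require_window(times, window[0], window[1], "climbing-rate")
    t_s = times[sl] / 1000.0
    return float(np.polyfit(t_s, waveform[sl], 1)[0])


@dataclass(frozen=True)
class PeakMeasure:
    latency_ms: float
    amplitude_uv: float     # mean over [peak - 5, peak + 5] ms
    at_edge: bool           # extremum on a window edge, or ±5 ms clipped


def peak_measure(
    waveform: np.ndarray,
    times: np.ndarray,
    polarity: str,
    search_window: tuple[float, float],
) -> PeakMeasure:
    """Latency and ±5-ms mean amplitude of the extremum in a closed window.

    Ties resolve to the earliest sample.  An extremum exactly on a window
    edge, or a ±5 ms amplitude window clipped by the epoch edge, is still
    returned but flagged via ``at_edge``.
    """
    lo, hi = search_window
    sl = _require_window(times, lo, hi, "peak-search")
    seg = waveform[sl]
    if polarity == "negative":
        k = int(np.argmin(seg))
    elif polarity == "positive":
        k = int(np.argmax(seg))
    else:
        raise ValueError("polarity must be 'negative' or 'positive'")
    lat = float(times[sl][k])
    at_edge = k == 0 or k == len(seg) - 1
    a_lo, a_hi = lat - 5.0, lat + 5.0
    if times[0] > a_lo + 1e-9 or times[-1] < a_hi - 1e-9:
        at_edge = True
    amp_sl = _window_slice(times, a_lo, a_hi)
    return PeakMeasure(
        latency_ms=lat,
        amplitude_uv=float(waveform[amp_sl].mean()),
        at_edge=at_edge,
    )


def windowed_mean_amplitude(
    waveform: np.ndarray, times: np.ndarray, window: tuple[float, float]
) -> float:
    """Arithmetic mean of the samples in the closed window, μV."""
    sl = _require_window(times, window[0], window[1], "mean-amplitude")
    return float(waveform[sl].mean())


def crossing_latency(
    waveform: np.ndarray, times: np.ndarray, after_ms: float = 650.0
) -> float:
    """First negative-to-positive zero crossing at or after ``after_ms``.

    Scans for the first sample pair with v(t_i) < 0 <= v(t_{i+1}) and
    t_i >= after_ms, refined by linear interpolation to the zero.  Returns
    NaN when no crossing occurs before the end of the grid — a missing
    value, not an error.
    """
    start = int(np.searchsorted(times, after_ms - 1e-9, side="left"))
    v = waveform
    for i in range(start, len(times) - 1):
        if v[i] < 0.0 <= v[i + 1]:
            return float(
                times[i] + (0.0 - v[i]) * (times[i + 1] - times[i]) / (v[i + 1] - v[i])
            )
    return float("nan")


def extract_feature_table(epochs: EpochSet, single_trial: bool = False) -> pd.DataFrame:
    """Full per-cell ERP feature table.

    Applies, per component: per-trial baseline correction -> condition
    averaging -> measurement.  Returns one row per participant x context x
    duration (or per trial when ``single_trial=True``, an exploratory mode)
    with columns for the CNV (climbing rate, peak latency/amplitude, mean
    amplitude, crossing latency), the offset P2 and the LPCt.  Raises with
    the cell identity on any window failure.
    """
    if epochs.baseline is not None:
        raise ValueError(
            "extract_feature_table expects raw (un-baselined) epochs; each "
            "component applies its own baseline"
        )
    by = (
        ("participant", "context", "duration_ms", "trial_index")
        if single_trial
        else ("participant", "context", "duration_ms")
    )
    times = epochs.times_ms
    tables: list[pd.DataFrame] = []

    for name, spec in COMPONENTS.items():
        based = baseline_correct(epochs, spec.lock, spec.baseline_window)
        avg = condition_average(based, by=by)
        rows = []
        for i in range(avg.n_trials):
            meta = avg.metadata.iloc[i]
            cell = {k: meta[k] for k in by}
            wave = avg.data[i]
            dur = float(meta["duration_ms"])
            lock0 = {"onset": 0.0, "offset": dur, "cue": float(meta["cue_latency_ms"])}
            try:
                row = dict(cell)
                row["n_trials"] = meta["n_trials"]
                anchor = lock0[spec.lock]
                pk = peak_measure(
                    wave, times, spec.polarity,
                    (anchor + spec.search_window[0], anchor + spec.search_window[1]),
                )
                prefix = {"CNV": "cnv", "offsetP2": "offset_p2", "LPCt": "lpct"}[name]
                row[f"{prefix}_peak_latency_ms"] = pk.latency_ms - anchor
                row[f"{prefix}_peak_amplitude_uv"] = pk.amplitude_uv
                row[f"{prefix}_peak_at_edge"] = pk.at_edge
                if name == "CNV":
                    row["cnv_climbing_rate_uv_per_s"] = cnv_climbing_rate(wave, times)
                    row["cnv_mean_amplitude_uv"] = windowed_mean_amplitude(
                        wave, times, (250.0, 250.0 + dur)
                    )
                    row["crossing_latency_ms"] = crossing_latency(wave, times)
                else:
                    m0 = lock0[spec.mean_lock]
                    row[f"{prefix}_mean_amplitude_uv"] = windowed_mean_amplitude(
                        wave, times,
                        (m0 + spec.mean_window[0], m0 + spec.mean_window[1]),
                    )
                rows.append(row)
            except ValueError as err:
                raise ValueError(f"{name} measurement failed for cell {cell}: {err}") from err
        tables.append(pd.DataFrame(rows))

    out = tables[0]
    for t in tables[1:]:
        out = out.merge(t, on=[*by, "n_trials"], how="outer")
    return out.sort_values(list(by)).reset_index(drop=True)
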