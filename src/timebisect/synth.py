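"""Synthetic behavior and EEG epochs with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so that every downstream stage (psychometric fitting, ERP feature
extraction, group statistics) can be verified by parameter recovery:

* **Behavior** — each participant's probability of responding "long" to a
  probe duration follows a lapse-augmented logistic whose threshold is
  pulled toward the session's ensemble mean by a context weight ``w``.
* **Epochs** — each trial's frontocentral virtual-channel waveform is a
  deterministic template (onset N1/P2 complex, a linearly climbing negativity
  — the CNV — that saturates at a plateau and resolves linearly after
  stimulus offset, an offset-locked P2 whose amplitude grows with duration,
  and a cue-locked late positivity, LPCt, whose amplitude and latency shrink
  with duration) plus white Gaussian and 1/f noise.

All draws are reproducible under a fixed integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .designs import DesignSpec, TrialSchedule, ensemble_mean
from .psychometrics import psychometric_p

__all__ = [
    "BehaviorParams",
    "SimulatedBehavior",
    "ErpParams",
    "EpochSet",
    "simulate_responses",
    "erp_template",
    "simulate_epochs",
    "simulate_amplitude_table",
    "pink_noise",
    "read_epochs_text",
]


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorParams:
    """Ground-truth behavioral model for the bisection task.

    The per-participant, per-context threshold is

        alpha = (1 - w) * base_threshold + w * ensemble_mean(context) + delta_p

    with ``delta_p`` a participant trait shared across contexts, and the
    response probability P("long" | D) = lapse/2 + (1 - lapse) *
    logistic((D - alpha) / slope).

    ``base_threshold_ms`` defaults to the geometric mean of the anchors,
    sqrt(400 * 1600) = 800 ms — the classical context-free bisection point.
    """

    context_weight: float = 0.5          # w, pull toward the ensemble mean
    base_threshold_ms: float = 800.0
    slope_ms: float = 110.0              # logistic scale beta
    lapse: float = 0.0
    threshold_sd_ms: float = 60.0        # between-participant SD of alpha
    slope_sd_ms: float = 15.0            # between-participant SD of beta

    def __post_init__(self) -> None:
        if not 0.0 <= self.context_weight <= 1.0:
            raise ValueError("context_weight must lie in [0, 1]")
        if self.slope_ms <= 0:
            raise ValueError("slope_ms (logistic scale) must be positive")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        if self.threshold_sd_ms < 0 or self.slope_sd_ms < 0:
            raise ValueError("between-participant SDs must be non-negative")


@dataclass(frozen=True)
class SimulatedBehavior:
    """Simulated bisection trials plus the ground truth that generated them.

    ``trials`` is long-format (participant, context, trial_index,
    duration_ms, response in {"short", "long"}); ``truth`` has one row per
    participant x context with the realized threshold and slope.
    """

    trials: pd.DataFrame
    truth: pd.DataFrame

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)


def _participant_traits(params: BehaviorParams, n: int, rng: np.random.Generator):
    deltas = rng.normal(0.0, params.threshold_sd_ms, size=n)
    slopes = params.slope_ms + rng.normal(0.0, params.slope_sd_ms, size=n)
    slopes = np.clip(slopes, 20.0, None)  # keep the scale meaningfully positive
    return deltas, slopes


def simulate_responses(
    schedules: TrialSchedule | Sequence[TrialSchedule],
    params: BehaviorParams,
    n_participants: int,
    seed: int,
) -> SimulatedBehavior:
    """Draw Bernoulli "long" responses for every participant and schedule.

    When several schedules (contexts) are given, participant traits — the
    threshold offset and the logistic scale — are shared across contexts, as
    for a real participant who completes both sessions.
    """
    if isinstance(schedules, TrialSchedule):
        schedules = [schedules]
    if params.slope_ms <= 0:
        raise ValueError("slope_ms must be positive")
    rng = np.random.default_rng(seed)
    deltas, slopes = _participant_traits(params, n_participants, rng)

    lo = min(s.design.short_anchor_ms for s in schedules)
    hi = max(s.design.long_anchor_ms for s in schedules)

    trial_frames, truth_rows = [], []
    for p in range(n_participants):
        for sched in schedules:
            design = sched.design
            alpha = (
                (1.0 - params.context_weight) * params.base_threshold_ms
                + params.context_weight * ensemble_mean(design)
                + deltas[p]
            )
            # invariant: thresholds stay strictly inside the anchor range
            alpha = float(np.clip(alpha, lo + 20.0, hi - 20.0))
            d = sched.table["duration_ms"].to_numpy(dtype=float)
            p_long = psychometric_p(d, alpha, slopes[p], params.lapse)
            is_long = rng.random(len(d)) < p_long
            trial_frames.append(
                pd.DataFrame(
                    {
                        "participant": p,
                        "context": design.context_label,
                        "trial_index": sched.table["trial_index"].to_numpy(),
                        "duration_ms": d,
                        "response": np.where(is_long, "long", "short"),
                    }
                )
            )
            truth_rows.append(
                {
                    "participant": p,
                    "context": design.context_label,
                    "threshold_ms": alpha,
                    "slope_ms": float(slopes[p]),
                    "lapse": params.lapse,
                    # session order is counterbalanced bookkeeping only
                    "session_order": "short-first" if p % 2 == 0 else "long-first",
                }
            )
    return SimulatedBehavior(
        trials=pd.concat(trial_frames, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
    )


# --------------------------------------------------------------------------
# ERP templates
# --------------------------------------------------------------------------

_DEFAULT_CNV_SLOPES: Mapping[str, float] = {
    "PS": -23.0, "NS": -20.0, "DF": -19.0, "AF": -17.0,
}


@dataclass(frozen=True)
class ErpParams:
    """Ground-truth waveform model for the frontocentral virtual channel.

    Units: amplitudes in μV, latencies/widths in ms, rates in μV/s.  The
    single channel stands for the mean of the six frontocentral electrodes
    used for all component measures.

    CNV: a ramp starting at ``cnv_onset_ms`` with context-dependent slope
    ``cnv_slope`` (negative), clipped at ``plateau_level_uv`` and held until
    stimulus offset, then resolving linearly back to baseline over
    ``resolution_ramp_ms``.  Offset P2: a Gaussian ~200-350 ms after offset
    whose amplitude grows with duration.  LPCt: a Gaussian locked to the
    response cue with amplitude ``a0 + a1 * max(0, leveling - D)`` (a hinge:
    amplitude falls with duration, then levels off) and latency decreasing
    with duration.
    """

    sampling_rate_hz: float = 1000.0
    tmin_ms: float = -300.0
    tmax_ms: float = 2800.0

    cnv_onset_ms: float = 250.0
    cnv_slope: Mapping[str, float] | float = field(
        default_factory=lambda: dict(_DEFAULT_CNV_SLOPES)
    )
    cnv_slope_sd: float = 1.5            # between-participant SD, μV/s
    plateau_level_uv: float = -10.0
    resolution_ramp_ms: float = 300.0

    n1_amp_uv: float = -4.0
    n1_latency_ms: float = 90.0
    n1_width_ms: float = 18.0
    p2_amp_uv: float = 5.0
    p2_latency_ms: float = 180.0
    p2_width_ms: float = 25.0

    offset_p2_amp_intercept_uv: float = 3.5
    offset_p2_amp_gain_uv_per_s: float = 2.9
    offset_p2_latency_intercept_ms: float = 345.0
    offset_p2_latency_gain_ms_per_s: float = -78.0
    offset_p2_width_ms: float = 30.0

    lpct_amp_intercept_uv: float = 3.0
    lpct_amp_gain_uv_per_s: float = 6.0
    lpct_leveling_ms: float = 900.0      # hinge; defaults near the bisection point
    lpct_latency_intercept_ms: float = 330.0
    lpct_latency_gain_ms_per_s: float = -77.0
    lpct_width_ms: float = 70.0

    noise_sd_uv: float = 3.0
    pink_noise_sd_uv: float = 2.0
    pink_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        slopes = (
            self.cnv_slope.values()
            if isinstance(self.cnv_slope, Mapping)
            else [self.cnv_slope]
        )
        if any(s >= 0 for s in slopes):
            raise ValueError("cnv_slope must be negative (μV/s)")
        if self.plateau_level_uv >= 0:
            raise ValueError("plateau_level_uv must be negative")
        if self.noise_sd_uv < 0 or self.pink_noise_sd_uv < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.pink_exponent < 0:
            raise ValueError("pink_exponent must be non-negative")

    @property
    def step_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.tmin_ms, self.tmax_ms + 0.5 * self.step_ms, self.step_ms)

    def slope_for(self, context: str) -> float:
        if isinstance(self.cnv_slope, Mapping):
            try:
                return float(self.cnv_slope[context])
            except KeyError:
                raise ValueError(
                    f"no CNV slope configured for context {context!r}; "
                    f"known: {sorted(self.cnv_slope)}"
                ) from None
        return float(self.cnv_slope)


def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def erp_template(
    duration_ms: float,
    context: str,
    params: ErpParams,
    response_gap_ms: float = 0.0,
    cnv_slope: float | None = None,
) -> np.ndarray:
    """Noiseless single-trial waveform on the standard grid, μV.

    ``cnv_slope`` (μV/s) overrides the context's programmed slope, e.g. with
    a participant-specific value.  The template is exactly 0 for t <= 0.
    If the plateau is unreachable before the shortest offset the ramp simply
    truncates at the offset — not an error.
    """
    if not 400.0 <= duration_ms <= 1600.0:
        raise ValueError("duration_ms must lie within [400, 1600]")
    t = params.times_ms
    slope = params.slope_for(context) if cnv_slope is None else float(cnv_slope)
    slope_per_ms = slope / 1000.0

    v = np.zeros_like(t)
    v += params.n1_amp_uv * _gauss(t, params.n1_latency_ms, params.n1_width_ms)
    v += params.p2_amp_uv * _gauss(t, params.p2_latency_ms, params.p2_width_ms)

    # climbing negativity: ramp, clip at plateau, hold until offset
    ramp = np.maximum(slope_per_ms * (t - params.cnv_onset_ms), params.plateau_level_uv)
    during = (t >= params.cnv_onset_ms) & (t <= duration_ms)
    v += np.where(during, ramp, 0.0)

    # linear resolution back to baseline after offset
    if duration_ms > params.cnv_onset_ms:
        v_off = max(slope_per_ms * (duration_ms - params.cnv_onset_ms),
                    params.plateau_level_uv)
        resolving = (t > duration_ms) & (t < duration_ms + params.resolution_ramp_ms)
        frac = (t - duration_ms) / params.resolution_ramp_ms
        v += np.where(resolving, v_off * (1.0 - frac), 0.0)

    dur_s = duration_ms / 1000.0
    # offset-locked P2
    p2_amp = params.offset_p2_amp_intercept_uv + params.offset_p2_amp_gain_uv_per_s * dur_s
    p2_lat = (params.offset_p2_latency_intercept_ms
              + params.offset_p2_latency_gain_ms_per_s * dur_s)
    v += p2_amp * _gauss(t, duration_ms + p2_lat, params.offset_p2_width_ms)

    # cue-locked late positivity with a leveling hinge in duration
    cue_ms = duration_ms + response_gap_ms
    lpct_amp = (params.lpct_amp_intercept_uv
                + params.lpct_amp_gain_uv_per_s
                * max(0.0, params.lpct_leveling_ms - duration_ms) / 1000.0)
    lpct_lat = (params.lpct_latency_intercept_ms
                + params.lpct_latency_gain_ms_per_s * dur_s)
    v += lpct_amp * _gauss(t, cue_ms + lpct_lat, params.lpct_width_ms)

    v[t <= 0.0] = 0.0
    return v


# --------------------------------------------------------------------------
# noise
# --------------------------------------------------------------------------

def pink_noise(rng: np.random.Generator, shape: tuple[int, int],
               exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent noise, unit SD per row, by spectral shaping of white noise."""
    n = shape[-1]
    w = rng.standard_normal(shape)
    if exponent == 0.0:
        return w / w.std(axis=-1, keepdims=True)
    spec = np.fft.rfft(w, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# epoch container
# --------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Trial x time waveform array for the frontocentral virtual channel.

    All trials share one uniform onset-locked time grid (``times_ms``).
    ``metadata`` has one row per trial with at least participant, context,
    duration_ms and cue_latency_ms (= duration + response gap).  ``baseline``
    records the correction applied, as (lock, (lo, hi)) relative to that
    lock event, or None for raw data.
    """

    data: np.ndarray
    times_ms: np.ndarray
    metadata: pd.DataFrame
    sfreq_hz: float = 1000.0
    baseline: tuple | None = None
    ground_truth: pd.DataFrame | None = None

    _REQUIRED = ("participant", "context", "duration_ms", "cue_latency_ms")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.times_ms):
            raise ValueError("data must be (n_trials, n_times) matching times_ms")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata must have one row per trial")
        missing = [c for c in self._REQUIRED if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata lacks required columns: {missing}")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times_ms=self.times_ms.copy(),
            metadata=self.metadata.copy(),
            sfreq_hz=self.sfreq_hz,
            baseline=self.baseline,
            ground_truth=None if self.ground_truth is None else self.ground_truth.copy(),
        )

    @classmethod
    def concat(cls, parts: Sequence["EpochSet"]) -> "EpochSet":
        first = parts[0]
        for p in parts[1:]:
            if not np.array_equal(p.times_ms, first.times_ms):
                raise ValueError("cannot concatenate epochs on different time grids")
            if p.baseline != first.baseline:
                raise ValueError("cannot concatenate epochs with different baselines")
        truths = [p.ground_truth for p in parts if p.ground_truth is not None]
        return cls(
            data=np.concatenate([p.data for p in parts], axis=0),
            times_ms=first.times_ms.copy(),
            metadata=pd.concat([p.metadata for p in parts], ignore_index=True),
            sfreq_hz=first.sfreq_hz,
            baseline=first.baseline,
            ground_truth=pd.concat(truths, ignore_index=True) if truths else None,
        )

    # -- binary container + JSON sidecar ----------------------------------
    def save(self, prefix) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.save(prefix.with_suffix(".npy"), self.data)
        self.metadata.to_csv(prefix.with_suffix(".meta.csv"), index=False)
        sidecar = {
            "tmin_ms": float(self.times_ms[0]),
            "step_ms": float(self.times_ms[1] - self.times_ms[0]),
            "n_times": int(self.n_times),
            "sfreq_hz": self.sfreq_hz,
            "baseline": self.baseline,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, prefix) -> "EpochSet":
        prefix = Path(prefix)
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        times = sidecar["tmin_ms"] + sidecar["step_ms"] * np.arange(sidecar["n_times"])
        baseline = sidecar["baseline"]
        if baseline is not None:
            baseline = (baseline[0], tuple(baseline[1]))
        return cls(
            data=np.load(prefix.with_suffix(".npy")),
            times_ms=times,
            metadata=pd.read_csv(prefix.with_suffix(".meta.csv")),
            sfreq_hz=sidecar["sfreq_hz"],
            baseline=baseline,
        )


def simulate_epochs(
    schedules: TrialSchedule | Sequence[TrialSchedule],
    params: ErpParams,
    n_participants: int,
    seed: int,
) -> EpochSet:
    """Simulate per-trial epochs for every participant and schedule.

    Each trial is its noiseless template (with a participant-specific CNV
    slope, shared across contexts) plus white Gaussian noise of SD
    ``noise_sd_uv`` and, if ``pink_noise_sd_uv > 0``, 1/f^chi noise.  The
    returned EpochSet carries a ``ground_truth`` table with the realized
    per-participant, per-context CNV slope.
    """
    if isinstance(schedules, TrialSchedule):
        schedules = [schedules]
    rng = np.random.default_rng(seed)
    slope_offsets = rng.normal(0.0, params.cnv_slope_sd, size=n_participants)

    times = params.times_ms
    blocks, meta_frames, truth_rows = [], [], []
    for p in range(n_participants):
        for sched in schedules:
            design = sched.design
            ctx = design.context_label
            slope_p = min(params.slope_for(ctx) + slope_offsets[p], -5.0)
            templates = {
                float(d): erp_template(
                    float(d), ctx, params,
                    response_gap_ms=design.response_gap_ms, cnv_slope=slope_p,
                )
                for d in design.durations
            }
            durations = sched.table["duration_ms"].to_numpy(dtype=float)
            block = np.stack([templates[d] for d in durations])
            if params.noise_sd_uv > 0:
                block = block + rng.normal(0.0, params.noise_sd_uv, block.shape)
            if params.pink_noise_sd_uv > 0:
                block = block + params.pink_noise_sd_uv * pink_noise(
                    rng, block.shape, params.pink_exponent
                )
            blocks.append(block)
            meta_frames.append(
                pd.DataFrame(
                    {
                        "participant": p,
                        "context": ctx,
                        "trial_index": sched.table["trial_index"].to_numpy(),
                        "duration_ms": durations,
                        "cue_latency_ms": durations + design.response_gap_ms,
                    }
                )
            )
            truth_rows.append(
                {"participant": p, "context": ctx, "cnv_slope_uv_per_s": slope_p}
            )
    return EpochSet(
        data=np.concatenate(blocks, axis=0),
        times_ms=times,
        metadata=pd.concat(meta_frames, ignore_index=True),
        sfreq_hz=params.sampling_rate_hz,
        ground_truth=pd.DataFrame(truth_rows),
    )


# --------------------------------------------------------------------------
# direct generator for mixed-model calibration tables
# --------------------------------------------------------------------------

def simulate_amplitude_table(
    designs: Sequence[DesignSpec],
    n_participants: int,
    seed: int,
    b_duration_uv_per_s: float = -1.5,
    context_effect_uv: float = 0.0,
    interaction_uv_per_s: float = 0.0,
    intercept_uv: float = 0.2,
    participant_sd_uv: float = 1.0,
    residual_sd_uv: float = 1.0,
) -> pd.DataFrame:
    """One amplitude per participant x context x duration, from a known LMM.

    response = intercept + b_duration * D_s + context_effect * short
             + interaction * D_s * short + u_participant + noise,

    where ``short`` indicates the first design in ``designs`` (the short
    context) and u ~ N(0, participant_sd).  Used to calibrate fit_lmm.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, participant_sd_uv, size=n_participants)
    rows = []
    for p in range(n_participants):
        for k, design in enumerate(designs):
            short = 1.0 if k == 0 else 0.0
            for d in design.durations:
                d_s = d / 1000.0
                mu = (intercept_uv + b_duration_uv_per_s * d_s
                      + context_effect_uv * short
                      + interaction_uv_per_s * d_s * short + u[p])
                rows.append(
                    {
                        "participant": p,
                        "context": design.context_label,
                        "duration_ms": float(d),
                        "amplitude_uv": mu + rng.normal(0.0, residual_sd_uv),
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# convenience text reader
# --------------------------------------------------------------------------

def read_epochs_text(path) -> EpochSet:
    """Read epochs from a BrainVision-style text export.

    Expected layout (INI-like sections, ``;`` comments)::

        [Header]
        SamplingRate=1000
        TimeStart=-300
        [Metadata]
        participant,context,duration_ms,cue_latency_ms
        0,PS,800,800
        [Data]
        0.12 -0.31 ...   (one whitespace-separated row of μV per trial)
    """
    section = None
    header: dict[str, float] = {}
    meta_lines: list[str] = []
    data_rows: list[np.ndarray] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[]").lower()
            continue
        if section == "header":
            key, _, value = line.partition("=")
            header[key.strip().lower()] = float(value)
        elif section == "metadata":
            meta_lines.append(line)
        elif section == "data":
            data_rows.append(np.array(line.split(), dtype=float))
        else:
            raise ValueError(f"line outside any known section: {raw!r}")
    if not data_rows:
        raise ValueError("no [Data] rows found")
    data = np.stack(data_rows)
    sfreq = header.get("samplingrate", 1000.0)
    tmin = header.get("timestart", 0.0)
    times = tmin + (1000.0 / sfreq) * np.arange(data.shape[1])
    from io import StringIO

    metadata = pd.read_csv(StringIO("\n".join(meta_lines)))
    return EpochSet(data=data, times_ms=times, metadata=metadata, sfreq_hz=sfreq)
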