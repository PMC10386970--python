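"""Experimental designs for the two temporal-bisection context experiments.

Two experiments share the same anchors (400 ms "short", 1600 ms "long") and
total session length (336 trials) but manipulate the *ensemble context* of
the probe durations differently:

* Experiment 1 (stimulus spacing): seven log-spaced probes, each tested 48
  times.  The positively skewed (PS) set crowds probes near the short anchor,
  the negatively skewed (NS) set mirrors it toward the long anchor.
* Experiment 2 (sample frequency): seven equally spaced probes, tested with
  ascending (AF) or descending (DF) repetition counts, plus a 300-ms blank
  between stimulus offset and the response prompt.

The frequency-weighted mean of a session's duration multiset — its *ensemble
mean* — is the quantity toward which the behavioral bisection point is
expected to migrate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SHORT_ANCHOR_MS = 400.0
LONG_ANCHOR_MS = 1600.0

#: Probe duration sets (ms) for each experiment arm.
_DURATIONS = {
    ("exp1", "PS"): (400, 504, 636, 800, 1008, 1270, 1600),
    ("exp1", "NS"): (400, 730, 992, 1200, 1366, 1496, 1600),
    ("exp2", "AF"): (400, 600, 800, 1000, 1200, 1400, 1600),
    ("exp2", "DF"): (400, 600, 800, 1000, 1200, 1400, 1600),
}

#: Per-duration repetition counts, aligned with the ascending duration sets.
_REPETITIONS = {
    ("exp1", "PS"): (48,) * 7,
    ("exp1", "NS"): (48,) * 7,
    ("exp2", "AF"): (12, 24, 36, 48, 60, 72, 84),
    ("exp2", "DF"): (84, 72, 60, 48, 36, 24, 12),
}

#: Blank between stimulus offset and the response prompt (question mark), ms.
_RESPONSE_GAP = {"exp1": 0.0, "exp2": 300.0}

N_BLOCKS = 6


@dataclass(frozen=True)
class DesignSpec:
    """One experiment/context arm: durations, repetition counts, trial timing.

    Invariants (checked on construction): durations strictly increasing from
    the short anchor (400 ms) to the long anchor (1600 ms); one positive
    repetition count per duration; the response gap is 0 (experiment 1) or
    300 ms (experiment 2).
    """

    experiment_id: str
    context_label: str
    durations: tuple[float, ...]
    repetitions: tuple[int, ...]
    short_anchor_ms: float = SHORT_ANCHOR_MS
    long_anchor_ms: float = LONG_ANCHOR_MS
    fixation_ms: float = 500.0
    response_gap_ms: float = 0.0
    iti_ms: float = 1000.0

    def __post_init__(self) -> None:
        d = np.asarray(self.durations, dtype=float)
        if len(d) < 1 or np.any(np.diff(d) <= 0):
            raise ValueError("durations must be strictly increasing")
        if d[0] != self.short_anchor_ms or d[-1] != self.long_anchor_ms:
            raise ValueError(
                "duration set must run from the short anchor "
                f"({self.short_anchor_ms} ms) to the long anchor "
                f"({self.long_anchor_ms} ms); got [{d[0]}, {d[-1]}]"
            )
        if len(self.repetitions) != len(self.durations):
            raise ValueError("repetitions must align one-to-one with durations")
        if any(int(r) <= 0 or int(r) != r for r in self.repetitions):
            raise ValueError("all repetition counts must be positive integers")
        if self.response_gap_ms not in (0.0, 300.0):
            raise ValueError("response_gap_ms must be 0 or 300")

    @property
    def n_trials(self) -> int:
        """Total trials in one session (sum of repetition counts)."""
        return int(sum(self.repetitions))

    @property
    def block_size(self) -> int:
        return max(1, self.n_trials // N_BLOCKS)

    def to_text(self) -> str:
        """Serialize to the flat, commented key/value dialect."""
        buf = io.StringIO()
        buf.write(f"# design: {self.experiment_id}/{self.context_label}\n")
        buf.write(f"experiment_id = {self.experiment_id}\n")
        buf.write(f"context_label = {self.context_label}\n")
        buf.write("durations = " + ", ".join(f"{x:g}" for x in self.durations) + "\n")
        buf.write("repetitions = " + ", ".join(str(int(r)) for r in self.repetitions) + "\n")
        for key in ("short_anchor_ms", "long_anchor_ms", "fixation_ms",
                    "response_gap_ms", "iti_ms"):
            buf.write(f"{key} = {getattr(self, key):g}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "DesignSpec":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        return cls(
            experiment_id=kv["experiment_id"],
            context_label=kv["context_label"],
            durations=tuple(float(x) for x in kv["durations"].split(",")),
            repetitions=tuple(int(x) for x in kv["repetitions"].split(",")),
            short_anchor_ms=float(kv["short_anchor_ms"]),
            long_anchor_ms=float(kv["long_anchor_ms"]),
            fixation_ms=float(kv["fixation_ms"]),
            response_gap_ms=float(kv["response_gap_ms"]),
            iti_ms=float(kv["iti_ms"]),
        )


@dataclass(frozen=True)
class TrialSchedule:
    """An ordered realization of a design's duration multiset.

    ``table`` has one row per trial with columns ``trial_index`` (0-based),
    ``block`` (0..5), ``duration_ms`` and ``context``.  Per-duration tallies
    equal the design's repetition counts exactly.
    """

    design: DesignSpec
    table: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.table)

    def tally(self) -> pd.Series:
        """Trials per duration, indexed by duration_ms ascending."""
        return self.table["duration_ms"].value_counts().sort_index()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def arms() -> list[tuple[str, str]]:
    """The four printed (experiment_id, context_label) arms."""
    return list(_DURATIONS)


def build_design(experiment_id: str, context_label: str) -> DesignSpec:
    """Return the printed design for one experiment arm.

    Parameters
    ----------
    experiment_id : {"exp1", "exp2"}
    context_label : {"PS", "NS"} for exp1; {"AF", "DF"} for exp2.
        PS/DF are the "short" contexts (ensemble mean below the arithmetic
        midpoint), NS/AF the "long" contexts.
    """
    key = (experiment_id, context_label)
    if key not in _DURATIONS:
        known = ", ".join(f"{e}/{c}" for e, c in _DURATIONS)
        raise ValueError(
            f"unknown experiment arm {experiment_id!r}/{context_label!r}; "
            f"known arms: {known}"
        )
    return DesignSpec(
        experiment_id=experiment_id,
        context_label=context_label,
        durations=tuple(float(x) for x in _DURATIONS[key]),
        repetitions=_REPETITIONS[key],
        response_gap_ms=_RESPONSE_GAP[experiment_id],
    )


def ensemble_mean(design: DesignSpec) -> float:
    """Frequency-weighted arithmetic mean of the session durations, ms.

    ``Σ(dᵢ·rᵢ) / Σrᵢ`` — equal to the unweighted mean when repetition counts
    are uniform.  This is the statistic of the stimulus ensemble toward which
    the bisection threshold is biased.
    """
    d = np.asarray(design.durations, dtype=float)
    r = np.asarray(design.repetitions, dtype=float)
    return float(np.sum(d * r) / np.sum(r))


def enumerate_trials(design: DesignSpec, seed: int) -> TrialSchedule:
    """Expand a design into a randomly ordered trial schedule.

    The schedule is an unconstrained random permutation of the duration
    multiset (no run-length limits), reproducible under ``seed``, partitioned
    into 6 equal blocks.
    """
    rng = np.random.default_rng(seed)
    multiset = np.repeat(
        np.asarray(design.durations, dtype=float),
        np.asarray(design.repetitions, dtype=int),
    )
    order = rng.permutation(len(multiset))
    durations = multiset[order]
    idx = np.arange(len(durations))
    table = pd.DataFrame(
        {
            "trial_index": idx,
            "block": idx // design.block_size,
            "duration_ms": durations,
            "context": design.context_label,
        }
    )
    return TrialSchedule(design=design, table=table)
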