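"""End-to-end orchestration: design -> simulate -> fit -> extract -> test.

A run is fully determined by a ``RunConfig`` (which round-trips losslessly
through a flat, commented key/value text file) and produces trial tables,
psychometric fits, an ERP feature table, a tidy group-statistics table and
a per-context summary in the layout of the study's descriptive table.

Group summaries aggregate the CNV climbing rate per participant x context
over durations of at least 650 ms, so the regression window [250, 650] ms
lies fully within the stimulus; for shorter probes the window contains the
post-offset resolution/P2 complex and the early ramp is disrupted.  Per-
duration rates for all probes remain available in the feature table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import erp, psychometrics, stats
from .designs import build_design, enumerate_trials
from .synth import (
    BehaviorParams,
    EpochSet,
    ErpParams,
    simulate_epochs,
    simulate_responses,
)

__all__ = [
    "RunConfig",
    "ReportBundle",
    "run_experiment",
    "aggregate_climbing_rate",
    "summary_table",
]

#: short context first, long context second — the paired-test convention
CONTEXT_PAIRS = {"exp1": ("PS", "NS"), "exp2": ("DF", "AF")}

MIN_SLOPE_DURATION_MS = 650.0


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    experiment_id: str = "exp1"
    n_participants: int = 19
    seed: int = 1
    free_lapse: bool = False
    single_trial: bool = False
    bf_scale: float = stats.DEFAULT_BF_SCALE
    save_epochs: bool = False
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    erp: ErpParams = field(default_factory=ErpParams)

    def to_text(self) -> str:
        """Flat, commented key/value form; parses back losslessly."""
        lines = ["# timebisect run configuration"]
        for key in ("experiment_id", "n_participants", "seed", "free_lapse",
                    "single_trial", "bf_scale", "save_epochs"):
            lines.append(f"{key} = {_fmt_value(getattr(self, key))}")
        lines.append("# behavioral generator")
        for f in dataclasses.fields(BehaviorParams):
            lines.append(f"behavior.{f.name} = {_fmt_value(getattr(self.behavior, f.name))}")
        lines.append("# ERP generator")
        for f in dataclasses.fields(ErpParams):
            value = getattr(self.erp, f.name)
            if isinstance(value, Mapping):
                for ctx in sorted(value):
                    lines.append(f"erp.{f.name}.{ctx} = {_fmt_value(value[ctx])}")
            else:
                lines.append(f"erp.{f.name} = {_fmt_value(value)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kv: dict[str, str] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, sep, value = line.partition("=")
            if not sep:
                raise ValueError(f"malformed config line: {raw!r}")
            kv[key.strip()] = value.strip()

        top: dict = {}
        beh: dict = {}
        erp_kv: dict = {}
        slopes: dict[str, float] = {}
        beh_fields = {f.name: f for f in dataclasses.fields(BehaviorParams)}
        erp_fields = {f.name: f for f in dataclasses.fields(ErpParams)}
        for key, value in kv.items():
            if key.startswith("behavior."):
                name = key[len("behavior."):]
                if name not in beh_fields:
                    raise ValueError(f"unknown behavior parameter {name!r}")
                beh[name] = _parse_value(value)
            elif key.startswith("erp.cnv_slope."):
                slopes[key.rsplit(".", 1)[1]] = float(value)
            elif key.startswith("erp."):
                name = key[len("erp."):]
                if name not in erp_fields:
                    raise ValueError(f"unknown ERP parameter {name!r}")
                erp_kv[name] = _parse_value(value)
            else:
                if key not in ("experiment_id", "n_participants", "seed",
                               "free_lapse", "single_trial", "bf_scale",
                               "save_epochs"):
                    raise ValueError(f"unknown configuration key {key!r}")
                top[key] = _parse_value(value)
        if slopes:
            erp_kv["cnv_slope"] = slopes
        top["n_participants"] = int(top.get("n_participants", 19))
        top["seed"] = int(top.get("seed", 1))
        return cls(behavior=BehaviorParams(**beh), erp=ErpParams(**erp_kv), **top)


def _fmt_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_value(s: str):
    low = s.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            continue
    return s


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

@dataclass
class ReportBundle:
    config: RunConfig
    outdir: Path | None
    trials: pd.DataFrame
    behavior_truth: pd.DataFrame
    fits: pd.DataFrame
    features: pd.DataFrame
    erp_truth: pd.DataFrame
    group_stats: pd.DataFrame
    summary_text: str
    log: tuple[str, ...]


def aggregate_climbing_rate(
    features: pd.DataFrame, min_duration_ms: float = MIN_SLOPE_DURATION_MS
) -> pd.DataFrame:
    """Per participant x context mean CNV climbing rate (μV/s).

    Restricted to durations >= ``min_duration_ms`` so the regression window
    is fully covered by the stimulus.
    """
    sub = features[features["duration_ms"] >= min_duration_ms]
    return (
        sub.groupby(["participant", "context"], as_index=False)
        .agg(cnv_climbing_rate_uv_per_s=("cnv_climbing_rate_uv_per_s", "mean"))
    )


def _paired_frame(table: pd.DataFrame, value: str, contexts: tuple[str, str]):
    """Wide per-participant (short, long) columns for one measure."""
    wide = table.pivot_table(index="participant", columns="context", values=value)
    wide = wide.dropna()
    return wide[contexts[0]].to_numpy(), wide[contexts[1]].to_numpy()


def run_experiment(config: RunConfig, outdir=None) -> ReportBundle:
    """Execute the full synthetic analysis for one experiment.

    Stages: enumerate designs -> simulate responses and epochs -> fit
    psychometric functions -> extract ERP features -> group statistics.
    Re-running with the same config reproduces every output bit-for-bit.
    """
    log: list[str] = []

    def note(stage: str, msg: str) -> None:
        log.append(f"[{stage}] {msg}")

    contexts = CONTEXT_PAIRS.get(config.experiment_id)
    if contexts is None:
        raise ValueError(f"unknown experiment_id {config.experiment_id!r}")
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]
    note("config", f"experiment={config.experiment_id} n={config.n_participants} "
                   f"seed={config.seed}")

    designs_ = [build_design(config.experiment_id, c) for c in contexts]
    schedules = [enumerate_trials(d, s) for d, s in zip(designs_, seeds[:2])]
    for sched in schedules:
        note("designs", f"{sched.design.context_label}: {len(sched)} trials "
                        f"in {sched.design.block_size}-trial blocks")

    behavior = simulate_responses(
        schedules, config.behavior, config.n_participants, seeds[2]
    )
    note("simulate", f"behavior: {len(behavior.trials)} trials")
    fits = psychometrics.fit_table(behavior.trials, free_lapse=config.free_lapse)
    note("fit-behavior", f"{len(fits)} cells, "
                         f"{int(fits['converged'].sum())} converged")

    epochs = simulate_epochs(schedules, config.erp, config.n_participants, seeds[3])
    note("simulate", f"epochs: {epochs.n_trials} trials x {epochs.n_times} samples")
    features = erp.extract_feature_table(epochs, single_trial=config.single_trial)
    note("extract-erp", f"{len(features)} feature rows")

    group_stats = compute_group_stats(
        fits, features, config.experiment_id, bf_scale=config.bf_scale, log=log
    )

    summary = summary_table(fits, features, config.experiment_id)

    report = ReportBundle(
        config=config,
        outdir=None if outdir is None else Path(outdir),
        trials=behavior.trials,
        behavior_truth=behavior.truth,
        fits=fits,
        features=features,
        erp_truth=epochs.ground_truth,
        group_stats=group_stats,
        summary_text=summary,
        log=tuple(log),
    )
    if outdir is not None:
        _write_report(report, epochs if config.save_epochs else None)
    return report


def compute_group_stats(
    fits: pd.DataFrame,
    features: pd.DataFrame,
    experiment_id: str,
    bf_scale: float = stats.DEFAULT_BF_SCALE,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Tidy table of the group-level tests (short context minus long).

    Paired t-tests on PSE, JND and the aggregated CNV climbing rate; mixed
    models for the duration-resolved component amplitudes; for the gap
    experiment additionally the LPCt models and the brain-behavior
    correlation.  With fewer than 3 participants, tests are skipped with an
    explicit notice.
    """
    contexts = CONTEXT_PAIRS[experiment_id]
    log = [] if log is None else log
    rows: list[dict] = []
    n_participants = fits["participant"].nunique()
    if n_participants < 3:
        log.append("[stats] skipped: need >= 3 participants for group tests "
                   f"(have {n_participants}); per-participant tables written")
        return pd.DataFrame(
            columns=["measure", "test", "term", "estimate", "statistic",
                     "df", "p", "ci_low", "ci_high", "bf10"]
        )

    def add_t(measure: str, table: pd.DataFrame, col: str) -> None:
        x, y = _paired_frame(table, col, contexts)
        res = stats.paired_t(x, y, bf_scale=bf_scale)
        rows.append(
            {
                "measure": measure, "test": "paired_t",
                "term": f"{contexts[0]} - {contexts[1]}",
                "estimate": res.mean_diff, "statistic": res.t, "df": res.df,
                "p": res.p, "ci_low": res.ci[0], "ci_high": res.ci[1],
                "bf10": res.bf10,
            }
        )

    add_t("pse_ms", fits, "pse_ms")
    add_t("jnd_ms", fits, "jnd_ms")
    slopes = aggregate_climbing_rate(features)
    add_t("cnv_climbing_rate_uv_per_s", slopes, "cnv_climbing_rate_uv_per_s")

    def add_lmm(measure: str) -> None:
        if n_participants < 5:
            log.append(f"[stats] mixed model for {measure} skipped: "
                       f"needs >= 5 participants (have {n_participants})")
            return
        res = stats.fit_lmm(features, measure)
        for _, row in res.params.iterrows():
            rows.append(
                {
                    "measure": measure, "test": f"lmm({res.df_method})",
                    "term": row["term"], "estimate": row["estimate"],
                    "statistic": row["t"], "df": row["df"], "p": row["p"],
                    "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                    "bf10": np.nan,
                }
            )

    add_lmm("cnv_mean_amplitude_uv")
    add_lmm("offset_p2_mean_amplitude_uv")
    if experiment_id == "exp2":
        add_lmm("lpct_peak_latency_ms")
        add_lmm("lpct_mean_amplitude_uv")
        # brain-behavior: context difference of CNV mean amplitude vs of PSE
        amp = (
            features.groupby(["participant", "context"], as_index=False)
            .agg(v=("cnv_mean_amplitude_uv", "mean"))
        )
        amp_s, amp_l = _paired_frame(amp, "v", contexts)
        pse_s, pse_l = _paired_frame(fits, "pse_ms", contexts)
        r, df_r, p_r, bf_r = stats.pearson_corr(amp_l - amp_s, pse_l - pse_s)
        rows.append(
            {
                "measure": "cnv_mean_amp_diff_vs_pse_diff", "test": "pearson",
                "term": f"{contexts[1]} - {contexts[0]}", "estimate": r,
                "statistic": np.nan, "df": df_r, "p": p_r,
                "ci_low": np.nan, "ci_high": np.nan, "bf10": bf_r,
            }
        )
    log.append(f"[stats] {len(rows)} result rows")
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# summary table
# --------------------------------------------------------------------------

_CONTEXT_ROLE = {"PS": "Short", "DF": "Short", "NS": "Long", "AF": "Long"}


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    n = len(values)
    sem = values.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
    return float(values.mean()), float(sem)


def summary_table(
    fits: pd.DataFrame, features: pd.DataFrame, experiment_id: str
) -> str:
    """Per-context means ± SEM of the headline measures, fixed layout.

    Climbing rate uses the >= 650 ms aggregation rule; the other ERP
    measures average across all durations per participant.  Missing cells
    are reported as ``n/a``, never imputed.
    """
    contexts = CONTEXT_PAIRS[experiment_id]
    n = fits["participant"].nunique()
    slopes = aggregate_climbing_rate(features)
    per_part = features.groupby(["participant", "context"], as_index=False).agg(
        peak_latency_ms=("cnv_peak_latency_ms", "mean"),
        peak_amplitude_uv=("cnv_peak_amplitude_uv", "mean"),
        mean_amplitude_uv=("cnv_mean_amplitude_uv", "mean"),
    )

    cols = [
        ("Climbing rate (uV/s)", slopes, "cnv_climbing_rate_uv_per_s", 1),
        ("Peak latency (ms)", per_part, "peak_latency_ms", 1),
        ("Peak amplitude (uV)", per_part, "peak_amplitude_uv", 1),
        ("Mean amplitude (uV)", per_part, "mean_amplitude_uv", 2),
        ("PSE (ms)", fits, "pse_ms", 1),
        ("JND (ms)", fits, "jnd_ms", 1),
    ]
    header = ["Context".ljust(12)] + [c[0].rjust(22) for c in cols]
    lines = [
        f"{'Experiment 1 (spacing)' if experiment_id == 'exp1' else 'Experiment 2 (frequency)'}"
        f"  n = {n}",
        "".join(header),
    ]
    for ctx in contexts:
        cells = [f"{_CONTEXT_ROLE[ctx]} ({ctx})".ljust(12)]
        for _, table, col, nd in cols:
            vals = table.loc[table["context"] == ctx, col]
            if vals.empty or vals.isna().all():
                cells.append("n/a".rjust(22))
            else:
                m, s = _mean_sem(vals.to_numpy())
                cells.append(f"{m:.{nd}f} +/- {s:.{nd}f}".rjust(22))
        lines.append("".join(cells))
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# output
# --------------------------------------------------------------------------

def _write_report(report: ReportBundle, epochs: EpochSet | None) -> None:
    out = report.outdir
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.txt").write_text(report.config.to_text())
    report.trials.to_csv(out / "trials.csv", index=False)
    report.behavior_truth.to_csv(out / "behavior_truth.csv", index=False)
    report.fits.to_csv(out / "behavior_fits.csv", index=False)
    report.features.to_csv(out / "erp_features.csv", index=False)
    report.erp_truth.to_csv(out / "erp_truth.csv", index=False)
    report.group_stats.to_csv(out / "group_stats.csv", index=False)
    (out / "summary.txt").write_text(report.summary_text)
    (out / "run_log.txt").write_text("\n".join(report.log) + "\n")
    if epochs is not None:
        epochs.save(out / "epochs")
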