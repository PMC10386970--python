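"""Logistic psychometric fitting and PSE/JND estimation.

The bisection data for one participant and context are Bernoulli counts of
"long" responses per probe duration.  We fit

    P("long" | D) = lapse/2 + (1 - lapse) / (1 + exp(-(D - alpha) / beta))

by maximum likelihood (derivative-free simplex from four deterministic
starts spanning the duration range).  The point of subjective equality (PSE)
is the duration at which the fitted curve crosses 50%, and the just
noticeable difference (JND) is the distance between the 75% and 50%
thresholds; both are found by root-finding on the fitted curve, so the
free-lapse variant needs no special casing.  With lapse = 0 these reduce to
the closed forms PSE = alpha and JND = beta * ln 3.

The lapse rate is fixed at 0 by default; ``free_lapse=True`` frees it up to
``max_lapse`` (default 0.06).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

__all__ = [
    "NonIdentifiableError",
    "PsychometricFit",
    "psychometric_p",
    "fit_logistic",
    "threshold",
    "pse_jnd",
    "fit_table",
]

_LN3 = float(np.log(3.0))


class NonIdentifiableError(ValueError):
    """Raised when the data cannot pin down a psychometric function."""


def psychometric_p(
    d: np.ndarray | float, alpha: float, beta: float, lapse: float = 0.0
) -> np.ndarray | float:
    """Lapse-augmented logistic probability of a "long" response."""
    if beta <= 0:
        raise ValueError("beta (logistic scale) must be positive")
    from scipy.special import expit

    z = (np.asarray(d, dtype=float) - alpha) / beta
    p = lapse / 2.0 + (1.0 - lapse) * expit(z)
    return float(p) if np.isscalar(d) else p


@dataclass(frozen=True)
class PsychometricFit:
    """Maximum-likelihood logistic fit for one participant x context cell."""

    alpha: float                 # threshold, ms
    beta: float                  # scale, ms
    lapse: float
    lapse_free: bool
    nll: float                   # negative log-likelihood at the optimum
    converged: bool
    n_trials: int
    proportions: pd.DataFrame    # per-duration observed n, n_long, prop

    def predict(self, d):
        return psychometric_p(d, self.alpha, self.beta, self.lapse)


def _aggregate(trials: pd.DataFrame) -> pd.DataFrame:
    resp = trials["response"]
    if resp.dtype == object:
        is_long = resp.str.lower().eq("long")
        bad = ~resp.str.lower().isin(["long", "short"])
        if bad.any():
            raise ValueError(f"unrecognized response labels: {sorted(resp[bad].unique())}")
    else:
        is_long = resp.astype(bool)
    g = (
        pd.DataFrame({"duration_ms": trials["duration_ms"], "long": is_long})
        .groupby("duration_ms", as_index=False)
        .agg(n=("long", "size"), n_long=("long", "sum"))
    )
    g["n_long"] = g["n_long"].astype(float)
    g["prop"] = g["n_long"] / g["n"]
    return g


def fit_logistic(
    trials: pd.DataFrame | None = None,
    *,
    counts: pd.DataFrame | None = None,
    free_lapse: bool = False,
    max_lapse: float = 0.06,
) -> PsychometricFit:
    """Fit the logistic psychometric function for one participant x context.

    Parameters
    ----------
    trials
        Long-format records with ``duration_ms`` and ``response`` columns
        (labels "short"/"long", or a boolean/0-1 "long" indicator).
    counts
        Alternative aggregated input: columns ``duration_ms``, ``n``,
        ``n_long`` (``n_long`` may be fractional, e.g. expected counts).
    free_lapse, max_lapse
        Free the lapse rate, bounded to [0, max_lapse].

    Raises
    ------
    NonIdentifiableError
        If only one response category is present (no threshold information).
    ValueError
        If fewer than two distinct durations were tested.
    """
    if (trials is None) == (counts is None):
        raise ValueError("provide exactly one of trials or counts")
    agg = _aggregate(trials) if trials is not None else counts.copy()
    if not {"duration_ms", "n", "n_long"}.issubset(agg.columns):
        raise ValueError("counts needs columns duration_ms, n, n_long")
    agg = agg.sort_values("duration_ms").reset_index(drop=True)
    if "prop" not in agg.columns:
        agg["prop"] = agg["n_long"] / agg["n"]

    if len(agg) < 2:
        raise ValueError("need responses at >= 2 distinct durations")
    total = float(agg["n"].sum())
    total_long = float(agg["n_long"].sum())
    if total_long <= 0 or total_long >= total:
        raise NonIdentifiableError(
            "all responses fall in one category; threshold and scale are "
            "not identifiable from these data"
        )

    d = agg["duration_ms"].to_numpy(dtype=float)
    n = agg["n"].to_numpy(dtype=float)
    k = agg["n_long"].to_numpy(dtype=float)
    lo, hi = d.min(), d.max()
    span = hi - lo

    def nll(theta: np.ndarray) -> float:
        alpha = theta[0]
        beta = np.exp(theta[1])
        lapse = max_lapse / (1.0 + np.exp(-theta[2])) if free_lapse else 0.0
        p = psychometric_p(d, alpha, beta, lapse)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return float(-np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    log_beta0 = np.log(span / 6.0)
    starts = [
        np.array([lo + f * span, log_beta0, -2.0])
        for f in (0.2, 0.4, 0.6, 0.8)
    ]
    ndim = 3 if free_lapse else 2
    results = []
    for x0 in starts:
        res = minimize(
            nll, x0[:ndim], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000},
        )
        results.append(res)

    # lowest NLL wins; near-ties resolve to the smallest scale
    best = min(results, key=lambda r: (round(r.fun, 9), np.exp(r.x[1])))
    alpha = float(best.x[0])
    beta = float(np.exp(best.x[1]))
    lapse = float(max_lapse / (1.0 + np.exp(-best.x[2]))) if free_lapse else 0.0
    return PsychometricFit(
        alpha=alpha,
        beta=beta,
        lapse=lapse,
        lapse_free=free_lapse,
        nll=float(best.fun),
        converged=bool(best.success),
        n_trials=int(round(total)),
        proportions=agg,
    )


def threshold(fit: PsychometricFit, p: float) -> float:
    """Duration at which the fitted curve reaches probability ``p`` (ms).

    Strictly increasing in p.  Found by bracketed root-finding on the fitted
    curve, not the closed form, so it is exact for any lapse rate.
    """
    lo_p, hi_p = fit.lapse / 2.0, 1.0 - fit.lapse / 2.0
    if not lo_p < p < hi_p:
        raise ValueError(
            f"probability {p} is outside the attainable range "
            f"({lo_p:.3f}, {hi_p:.3f}) for lapse={fit.lapse:.3f}"
        )
    half = 200.0 * fit.beta + 1.0
    return float(brentq(lambda x: fit.predict(x) - p,
                        fit.alpha - half, fit.alpha + half, xtol=1e-9))


def pse_jnd(fit: PsychometricFit) -> tuple[float, float]:
    """(PSE, JND) in ms: the 50% threshold, and the 75%-50% threshold gap."""
    if not fit.converged:
        raise ValueError("fit did not converge; PSE/JND would be unreliable")
    pse = threshold(fit, 0.5)
    jnd = threshold(fit, 0.75) - pse
    return pse, jnd


def fit_table(
    trials: pd.DataFrame, free_lapse: bool = False, max_lapse: float = 0.06
) -> pd.DataFrame:
    """Fit every participant x context cell of a long-format trial table.

    Returns one row per cell with alpha, beta, lapse, PSE, JND, NLL and a
    convergence flag.  Non-identifiable cells (single response category)
    yield NaN estimates and ``converged = False`` rather than aborting the
    whole table.
    """
    rows = []
    for (participant, context), cell in trials.groupby(["participant", "context"]):
        row: dict = {"participant": participant, "context": context,
                     "n_trials": len(cell)}
        try:
            fit = fit_logistic(cell, free_lapse=free_lapse, max_lapse=max_lapse)
            pse, jnd = pse_jnd(fit) if fit.converged else (np.nan, np.nan)
            row.update(
                alpha_ms=fit.alpha, beta_ms=fit.beta, lapse=fit.lapse,
                pse_ms=pse, jnd_ms=jnd, nll=fit.nll, converged=fit.converged,
            )
        except NonIdentifiableError:
            row.update(
                alpha_ms=np.nan, beta_ms=np.nan, lapse=np.nan,
                pse_ms=np.nan, jnd_ms=np.nan, nll=np.nan, converged=False,
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["participant", "context"]).reset_index(drop=True)
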