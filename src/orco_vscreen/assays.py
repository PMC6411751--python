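"""Wet-lab quantifications: inhibition normalization, Hill fits, behavior RI.

Covers the electrophysiology-side analytics — percent-of-control response
with sham normalization, the 20%-inhibition-at-3-mM activity call, Hill
concentration-inhibition fitting I = Imax / (1 + (X/IC50)^n), the <500 uM
potency gate that defines the potent-actives training subset — and the
two-choice larval behavior Response Index RI = (S - C) / (S + C).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import warnings

from scipy.optimize import OptimizeWarning, curve_fit

ACTIVE = "active"
INACTIVE = "inactive"

INACTIVE_MAX_INHIBITION_PCT = 20.0
MODEL_B_IC50_CUTOFF_UM = 500.0


# ---------------------------------------------------------------------------
# percent-of-control normalization


@dataclass(frozen=True)
class InhibitionMeasurement:
    """One antagonist test: two agonist-alone currents, one co-application.

    ``sham_percent`` is the percent-of-control obtained in a vehicle-only
    run and corrects for response rundown.
    """

    i_pre1: float
    i_pre2: float
    i_test: float
    sham_percent: float = 100.0
    concentration_um: float | None = None

    def __post_init__(self) -> None:
        if min(self.i_pre1, self.i_pre2, self.i_test) < 0:
            raise ValueError("currents must be non-negative")
        if self.sham_percent <= 0:
            raise ValueError("sham_percent must be positive")


class PercentResponse(NamedTuple):
    raw_pct: float
    normalized_pct: float
    inhibition_pct: float


def percent_response(m: InhibitionMeasurement) -> PercentResponse:
    """Raw percent of control, sham-normalized percent, and inhibition.

    raw% = 100 * i_test / mean(i_pre1, i_pre2); normalized% = 100 * raw% /
    sham%; inhibition% = 100 - normalized%.  A zero pre-application mean
    means a dead oocyte and is a domain error.
    """
    pre = (m.i_pre1 + m.i_pre2) / 2.0
    if pre <= 0:
        raise ValueError("zero pre-application response (dead oocyte)")
    raw = 100.0 * m.i_test / pre
    normalized = 100.0 * raw / m.sham_percent
    return PercentResponse(raw, normalized, 100.0 - normalized)


def classify_antagonist(inhibition_pct: float) -> str:
    """Active iff inhibition at 3 mM exceeds 20 percent; <=20 is inactive."""
    return INACTIVE if inhibition_pct <= INACTIVE_MAX_INHIBITION_PCT else ACTIVE


# ---------------------------------------------------------------------------
# Hill concentration-inhibition fitting


@dataclass(frozen=True)
class DoseResponseFit:
    """Hill-fit result for one compound.

    ``within_tested_range`` is False when the fitted IC50 lies outside the
    tested concentration range (extrapolated potency — e.g. data with no
    inhibition at all).
    """

    ic50: float
    hill_n: float
    i_max: float
    se_ic50: float
    se_n: float
    converged: bool
    n_points: int
    within_tested_range: bool


def _hill_log(x: np.ndarray, log_imax: float, log_ic50: float, log_n: float) -> np.ndarray:
    return np.exp(log_imax) / (1.0 + (x / np.exp(log_ic50)) ** np.exp(log_n))


def fit_concentration_inhibition(
    concs_um: Sequence[float], responses_pct: Sequence[float], weighting: str = "relative"
) -> DoseResponseFit:
    """Nonlinear least-squares fit of I = Imax / (1 + (X/IC50)^n).

    Parameters are fit on the log scale, which enforces positivity; standard
    errors come from the asymptotic covariance at the optimum via the delta
    method.  Initial values: Imax0 = max response, IC50_0 = geometric mean of
    the tested concentrations, n0 = 1.  Percent-of-control responses show a
    roughly constant coefficient of variation, so the default weighting is
    ``"relative"`` (sigma proportional to the response); pass ``"none"`` for
    an unweighted fit.  Non-convergence returns a fit with
    ``converged=False`` rather than raising.
    """
    x = np.asarray(concs_um, dtype=float)
    yv = np.asarray(responses_pct, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 concentration points")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if weighting not in ("relative", "none"):
        raise ValueError("weighting must be 'relative' or 'none'")
    sigma = np.maximum(np.abs(yv), 1e-2) if weighting == "relative" else None
    p0 = (np.log(max(yv.max(), 1e-6)), float(np.mean(np.log(x))), 0.0)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(_hill_log, x, yv, p0=p0, sigma=sigma, maxfev=20000)
        # pcov can be singular on an exact (noise-free) fit; the parameter
        # estimate is still converged, only the SEs are undefined then.
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, ValueError):
        return DoseResponseFit(
            ic50=float("nan"),
            hill_n=float("nan"),
            i_max=float("nan"),
            se_ic50=float("nan"),
            se_n=float("nan"),
            converged=False,
            n_points=len(x),
            within_tested_range=False,
        )
    i_max, ic50, hill_n = np.exp(popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    # delta method: se(exp(theta)) = exp(theta) * se(theta)
    se_ic50 = float(ic50 * se[1])
    se_n = float(hill_n * se[2])
    return DoseResponseFit(
        ic50=float(ic50),
        hill_n=float(hill_n),
        i_max=float(i_max),
        se_ic50=se_ic50,
        se_n=se_n,
        converged=converged,
        n_points=len(x),
        within_tested_range=bool(x.min() <= ic50 <= x.max()),
    )


def fit_dose_response_table(df: pd.DataFrame) -> pd.DataFrame:
    """Fit every compound in a dose-response table.

    Expects columns compound_id, concentration_um, i_pre1, i_pre2, i_test,
    sham_percent; responses are sham-normalized percent of control.  Returns
    one row per compound with the fitted Hill parameters.
    """
    rows = []
    for cid, grp in df.groupby("compound_id", sort=True):
        responses = [
            percent_response(
                InhibitionMeasurement(r.i_pre1, r.i_pre2, r.i_test, r.sham_percent)
            ).normalized_pct
            for r in grp.itertuples()
        ]
        fit = fit_concentration_inhibition(grp["concentration_um"].to_numpy(), responses)
        rows.append(
            {
                "compound_id": cid,
                "ic50_um": fit.ic50,
                "se_ic50": fit.se_ic50,
                "hill_n": fit.hill_n,
                "i_max": fit.i_max,
                "converged": fit.converged,
                "n_points": fit.n_points,
            }
        )
    return pd.DataFrame(rows)


def select_model_b_actives(
    fits: Mapping[str, DoseResponseFit], cutoff_um: float = MODEL_B_IC50_CUTOFF_UM
) -> list[str]:
    """Ids of converged fits with IC50 strictly below the cutoff (500 uM)."""
    return sorted(cid for cid, f in fits.items() if f.converged and f.ic50 < cutoff_um)


# ---------------------------------------------------------------------------
# larval two-choice behavior


@dataclass(frozen=True)
class BehaviorTrial:
    """Counts from one two-choice larval plate.

    ``excluded`` larvae (still in the starting circle or touching the center
    line) never enter the stimulus/control counts.
    """

    s_count: int
    c_count: int
    excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.s_count, self.c_count, self.excluded) < 0:
            raise ValueError("counts must be non-negative")


def response_index(trial: BehaviorTrial) -> float:
    """RI = (S - C) / (S + C): +1 complete attraction, -1 complete repulsion."""
    total = trial.s_count + trial.c_count
    if total < 1:
        raise ValueError("undefined trial: no scored larvae (S + C = 0)")
    return (trial.s_count - trial.c_count) / total


def response_index_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-trial RI from a behavior table (trial_id, s_count, c_count, ...)."""
    out = df.copy()
    out["ri"] = [
        response_index(BehaviorTrial(int(r.s_count), int(r.c_count), int(getattr(r, "excluded", 0))))
        for r in df.itertuples()
    ]
    return out
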