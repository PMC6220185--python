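"""Response and progression calling rules for serial biomarker monitoring.

Two clinic-facing rules are implemented.  A *response* is called when an
on-treatment value falls below the pre-treatment baseline by more than the
biomarker's technical 95% CI (derived from duplicate pre-treatment
measurements) within a fixed early window (three treatment cycles).  A
*progression* is called when a value rises above the running nadir by more
than an alarm threshold; the optimal alarm threshold is selected by
repeated posterior-predictive "pseudo-trials" drawn from the fitted
hierarchical model on a monthly collection schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trajectory_model import PosteriorDraws, pseudo_trial

__all__ = [
    "VariationEstimate",
    "ResponseCall",
    "ProgressionCall",
    "ThresholdEvaluation",
    "estimate_intra_patient_variation",
    "round_threshold",
    "call_response",
    "call_progression",
    "optimize_progression_threshold",
    "combine_calls",
    "compute_lead_time",
    "normalize_time_pfs",
]


@dataclass(frozen=True)
class VariationEstimate:
    """Intra-patient replicate variation of one biomarker on the log2 scale."""

    biomarker: str
    sd_log2: float
    ci95_halfwidth_log2: float
    implied_response_fraction: float
    n_pairs: int


@dataclass(frozen=True)
class ResponseCall:
    patient_id: str
    biomarker: str
    responded: bool
    call_time_days: float | None
    window_days: float
    evaluable: bool = True


@dataclass(frozen=True)
class ProgressionCall:
    patient_id: str
    biomarker: str
    called: bool
    call_time_days: float | None
    nadir_value: float | None
    nadir_time_days: float | None
    threshold_fraction: float


@dataclass
class ThresholdEvaluation:
    """Per-threshold pseudo-trial performance and the selected optimum."""

    grid: list[float]
    fraction_predicted: dict[float, float]
    mean_lead_days: dict[float, float]
    median_abs_lead_days: dict[float, float]
    optimum: float
    n_reps: int
    seed: int
    max_lead_days: float
    call_times: dict[float, list[float]] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        def clean(d):
            return {f"{k:g}": (None if (v is None or not np.isfinite(v)) else float(v))
                    for k, v in d.items()}
        return {
            "grid": self.grid,
            "fraction_predicted": clean(self.fraction_predicted),
            "mean_lead_days": clean(self.mean_lead_days),
            "median_abs_lead_days": clean(self.median_abs_lead_days),
            "optimum": self.optimum,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "max_lead_days": self.max_lead_days,
        }


# ---------------------------------------------------------------------------
# Replicate variation and the implied response rule


def estimate_intra_patient_variation(pairs, biomarker: str = "") -> VariationEstimate:
    """Fit a zero-centred normal to log2 replicate ratios.

    ``pairs`` is a sequence of ``(value_1, value_2)`` duplicate pre-treatment
    measurements, one pair per patient (or a 2-column array/DataFrame).  The
    95% CI half-width is ``1.96 * sd`` of the log2 ratios and the implied
    response fraction ``1 - 2**(-half_width)`` — the smallest relative
    reduction distinguishable from technical variation.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of duplicate values")
    if arr.shape[0] < 5:
        raise ValueError("need replicate pairs from at least 5 patients")
    if np.any(arr <= 0):
        raise ValueError("replicate values must be strictly positive")
    ratios = np.log2(arr[:, 0] / arr[:, 1])
    # Zero-centred fit: sd is the RMS of the log2 ratios, which makes the
    # estimate symmetric under swapping replicate order.
    sd = float(np.sqrt(np.mean(ratios ** 2)))
    half = 1.96 * sd
    return VariationEstimate(
        biomarker=biomarker,
        sd_log2=sd,
        ci95_halfwidth_log2=half,
        implied_response_fraction=1.0 - 2.0 ** (-half),
        n_pairs=arr.shape[0],
    )


def round_threshold(fraction: float, step: float = 0.05) -> float:
    """Round a threshold fraction to the nearest 5 percentage points."""
    return round(round(fraction / step) * step, 10)


# ---------------------------------------------------------------------------
# Rule-based calls


def _split_series(series: pd.DataFrame):
    s = series.sort_values("time_days")
    base = s[(s["replicate"] > 0) | (s["time_days"] <= 0)]
    on = s[(s["replicate"] == 0) & (s["time_days"] > 0)]
    return base, on


def call_response(series: pd.DataFrame, threshold_fraction: float,
                  window_days: float = 63.0, *,
                  confirm_consecutive: bool = False) -> ResponseCall:
    """Call a response when a value falls below baseline * (1 - threshold).

    ``series`` is one patient/biomarker measurement table.  The baseline is
    the mean of the pre-treatment replicates.  The default window of 63
    days corresponds to three 21-day cycles (use 42 for 14-day cycles).
    With ``confirm_consecutive=True`` two consecutive qualifying visits are
    required (a confirmed reduction).
    """
    if series.empty:
        raise ValueError("empty series")
    pid = str(series["patient_id"].iloc[0])
    marker = str(series["biomarker"].iloc[0]) if "biomarker" in series else ""
    base, on = _split_series(series)
    if base.empty:
        raise ValueError(f"no pre-treatment baseline for patient {pid}")
    baseline = float(base["value"].mean())
    window = on[on["time_days"] <= window_days]
    if window.empty:
        return ResponseCall(pid, marker, False, None, window_days, evaluable=False)
    cut = baseline * (1.0 - threshold_fraction)
    qual = (window["value"].to_numpy(float) < cut)
    times = window["time_days"].to_numpy(float)
    if confirm_consecutive:
        hit = np.flatnonzero(qual[:-1] & qual[1:]) if len(qual) > 1 else np.array([], int)
        if hit.size:
            return ResponseCall(pid, marker, True, float(times[hit[0]]), window_days)
        return ResponseCall(pid, marker, False, None, window_days)
    hit = np.flatnonzero(qual)
    if hit.size:
        return ResponseCall(pid, marker, True, float(times[hit[0]]), window_days)
    return ResponseCall(pid, marker, False, None, window_days)


def call_progression(series: pd.DataFrame,
                     threshold_fraction: float) -> ProgressionCall:
    """Call progression at the first rise above the running nadir.

    Scans on-treatment points in time order; at each point the nadir is the
    minimum of strictly earlier on-treatment values, and progression is
    called at the first point whose value is at least
    ``nadir * (1 + threshold_fraction)``.  The baseline is not part of the
    nadir (on-treatment values only).
    """
    if series.empty:
        raise ValueError("empty series")
    pid = str(series["patient_id"].iloc[0])
    marker = str(series["biomarker"].iloc[0]) if "biomarker" in series else ""
    _, on = _split_series(series)
    if len(on) < 2:
        raise ValueError(
            f"patient {pid}: need >=2 on-treatment points to scan for progression"
        )
    t = on["time_days"].to_numpy(float)
    v = on["value"].to_numpy(float)
    nadir = v[0]
    nadir_t = t[0]
    for i in range(1, len(v)):
        if v[i] >= nadir * (1.0 + threshold_fraction):
            return ProgressionCall(pid, marker, True, float(t[i]), float(nadir),
                                   float(nadir_t), threshold_fraction)
        if v[i] < nadir:
            nadir = v[i]
            nadir_t = t[i]
    return ProgressionCall(pid, marker, False, None, None, None,
                           threshold_fraction)


# ---------------------------------------------------------------------------
# Pseudo-trial threshold optimization


def _prediction_ok(call: ProgressionCall, pfs: float, event: bool,
                   max_lead_days: float) -> bool:
    """A call counts as a correct prediction when the patient progressed and
    the alarm fired at or before the recorded progression date, within the
    maximum lead window of it."""
    if not (call.called and event):
        return False
    lead = pfs - call.call_time_days
    return 0.0 <= lead <= max_lead_days


def optimize_progression_threshold(
    draws: PosteriorDraws,
    survival: pd.DataFrame,
    grid: Sequence[float] = (0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5, 0.6),
    n_reps: int = 200,
    seed: int = 0,
    *,
    max_lead_days: float = 180.0,
) -> ThresholdEvaluation:
    """Select the alarm threshold by repeated monthly pseudo-trials.

    For each repetition a posterior-predictive pseudo-trial (monthly 30+/-5
    day schedule) is imputed for every patient and the nadir rule applied at
    every candidate threshold.  The optimum maximises the fraction of
    progressors correctly predicted, breaking ties toward the smaller
    median absolute lead-time.
    """
    if not len(grid):
        raise ValueError("grid must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    grid = [float(g) for g in grid]
    surv = survival.set_index("patient_id")
    rng = np.random.default_rng(seed)

    n_predicted = {g: 0 for g in grid}
    leads: dict[float, list[float]] = {g: [] for g in grid}
    n_progressors_total = 0

    for _ in range(n_reps):
        rep_seed = int(rng.integers(0, 2 ** 31 - 1))
        trial = pseudo_trial(draws, seed=rep_seed)
        for pid, grp in trial.groupby("patient_id", sort=False):
            pfs = float(surv.loc[pid, "pfs_days"])
            event = bool(surv.loc[pid, "event"])
            if event:
                n_progressors_total += 1
            if len(grp) < 2:
                continue
            for g in grid:
                call = call_progression(grp, g)
                if _prediction_ok(call, pfs, event, max_lead_days):
                    n_predicted[g] += 1
                    leads[g].append(pfs - call.call_time_days)

    denom = max(n_progressors_total, 1)
    frac = {g: n_predicted[g] / denom for g in grid}
    mean_lead = {g: (float(np.mean(leads[g])) if leads[g] else float("nan"))
                 for g in grid}
    med_abs = {g: (float(np.median(np.abs(leads[g]))) if leads[g] else float("inf"))
               for g in grid}
    best = max(grid, key=lambda g: (frac[g], -med_abs[g]))
    return ThresholdEvaluation(
        grid=grid,
        fraction_predicted=frac,
        mean_lead_days=mean_lead,
        median_abs_lead_days={g: (v if np.isfinite(v) else float("nan"))
                              for g, v in med_abs.items()},
        optimum=best,
        n_reps=n_reps,
        seed=seed,
        max_lead_days=max_lead_days,
        call_times={g: list(leads[g]) for g in grid},
    )


# ---------------------------------------------------------------------------
# Combining compartments


def combine_calls(call_a: ProgressionCall, call_b: ProgressionCall) -> ProgressionCall:
    """OR-combination of two compartments' progression calls.

    Called if either biomarker called; the combined time is the earliest
    call time among the called biomarkers.
    """
    if call_a.patient_id != call_b.patient_id:
        raise ValueError(
            f"patient mismatch: {call_a.patient_id!r} vs {call_b.patient_id!r}"
        )
    called = call_a.called or call_b.called
    times = [c.call_time_days for c in (call_a, call_b) if c.called]
    time = min(times) if times else None
    first = None
    if called:
        first = call_a if (call_a.called and call_a.call_time_days == time) else call_b
    return ProgressionCall(
        patient_id=call_a.patient_id,
        biomarker=f"{call_a.biomarker}+{call_b.biomarker}",
        called=called,
        call_time_days=time,
        nadir_value=first.nadir_value if first else None,
        nadir_time_days=first.nadir_time_days if first else None,
        threshold_fraction=first.threshold_fraction if first
        else call_a.threshold_fraction,
    )


def compute_lead_time(calls_vascular: Mapping[str, ProgressionCall],
                      calls_epithelial: Mapping[str, ProgressionCall]):
    """Mean lead-time (days) of the vascular alarm over the epithelial one.

    Averaged over patients called by both biomarkers; positive values mean
    the vascular call precedes the epithelial call.  Returns None when no
    patient is co-called (not evaluable).
    """
    diffs = []
    for pid, vc in calls_vascular.items():
        ec = calls_epithelial.get(pid)
        if ec is None or not (vc.called and ec.called):
            continue
        diffs.append(ec.call_time_days - vc.call_time_days)
    if not diffs:
        return None
    return float(np.mean(diffs))


def normalize_time_pfs(time_days: float, pfs_days: float) -> float:
    """Elapsed time as a percentage of the patient's PFS (%PFS)."""
    if pfs_days <= 0:
        raise ValueError("pfs_days must be > 0")
    if not 0.0 <= time_days <= pfs_days:
        raise ValueError("time_days must lie in [0, pfs_days]")
    return 100.0 * time_days / pfs_days
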