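"""Synthetic trial-cohort generator.

Emulates the longitudinal biomarker structure of a 70-patient anti-angiogenic
(VEGF-inhibitor) trial: per patient and biomarker a piecewise-linear
trajectory with a single inflection point, log-normal baselines, a
two-component (Bernoulli-mixture) slope population, quantity-proportional
technical noise, an irregular visit schedule with missingness, duplicate
pre-treatment replicates, and censored progression-free survival (PFS)
times.  Every downstream analysis stage in this package is testable against
cohorts produced here, with the generative truth retained.

Scale conventions
-----------------
Baselines are log-normal: ``log(alpha) ~ N(baseline_log_mean,
baseline_log_sd**2)``.  Slope mixture components are *relative rates per 365
days*: the per-day slope is ``beta = alpha * (b1 + sign * E1 * b2) / 365``
where ``b1`` is normal, ``b2`` log-normal and ``E1`` Bernoulli.  A relative
rate of -2/yr corresponds to roughly a 40% decline over 90 days, the scale
seen for vascular markers under bevacizumab.  Technical noise is additive
with standard deviation ``noise_sd * |C(t)|`` (proportional to biomarker
quantity).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerSpec",
    "PatientTruth",
    "Measurement",
    "CohortDataset",
    "DEFAULT_SCHEDULE",
    "SLOPE_TIME_SCALE",
    "TIE2_SPEC",
    "CK18_SPEC",
    "KTRANS_SPEC",
    "generate_cohort",
    "transform_biomarker",
    "write_cohort",
    "read_cohort",
]

#: Days over which the slope mixture components are expressed.
SLOPE_TIME_SCALE = 365.0

#: Nominal visit days: dense early sampling during the monotherapy window,
#: then roughly 4-weekly during combination treatment.
DEFAULT_SCHEDULE = (
    3, 8, 15, 22, 42, 70, 98, 126, 154, 182, 210, 238, 266, 294, 322, 350,
)

#: Days of the two pre-treatment replicate samples.
BASELINE_DAYS = (-7.0, 0.0)

#: Minimum PFS compatible with a proper inflection-point support
#: U(21, PFS - 21).
MIN_PFS_DAYS = 42.0


class CohortValidationError(ValueError):
    """Invalid generator specification or malformed cohort file."""


@dataclass(frozen=True)
class BiomarkerSpec:
    """Generative settings for one biomarker.

    The hyperparameters mirror the hierarchical model's population level:
    ``baseline_log_mean``/``baseline_log_sd`` play the mu_alpha/sigma_alpha
    role, the ``slope1``/``slope2`` fields the (mu_b1, sigma_b1, mu_b2,
    sigma_b2, p1) pre-inflection mixture and the ``postslope`` fields the
    post-inflection (gamma) analogues.  ``slope2_sign`` controls whether the
    positive log-normal component steepens the decline (-1, default) or the
    rise (+1); ``postslope2_sign`` likewise for the post-inflection slope.

    The default slope magnitudes are calibrated to the dynamics reported
    for vascular markers under bevacizumab (median ~15-20% reduction within
    two weeks to two months, partial rebound by progression): a slow
    component of about -0.6/yr and a steeper mixture component roughly
    doubling to tripling it.

    ``inflection_lag_days``, when set, anchors this biomarker's inflection
    at the first spec's inflection plus the lag (clipped to the valid
    support) instead of drawing it uniformly; this models compartments
    progressing in sequence (e.g. epithelial after vascular).
    """

    name: str
    baseline_log_mean: float = 4.3
    baseline_log_sd: float = 0.6
    slope1_mean: float = -0.6
    slope1_sd: float = 0.2
    slope2_logmean: float = 0.0
    slope2_logsd: float = 0.35
    mix_p1: float = 0.45
    postslope1_mean: float = 0.4
    postslope1_sd: float = 0.3
    postslope2_logmean: float = 0.0
    postslope2_logsd: float = 0.35
    mix_p2: float = 0.45
    noise_sd: float = 0.15
    units: str = "pg/ml"
    slope2_sign: float = -1.0
    postslope2_sign: float = 1.0
    inflection_lag_days: float | None = None

    def validate(self) -> None:
        errors = []
        if self.baseline_log_sd <= 0:
            errors.append("baseline_log_sd must be > 0")
        for f in ("slope1_sd", "slope2_logsd", "postslope1_sd", "postslope2_logsd"):
            if getattr(self, f) <= 0:
                errors.append(f"{f} must be > 0")
        for f in ("mix_p1", "mix_p2"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                errors.append(f"{f} must lie in [0, 1]")
        if self.noise_sd <= 0:
            errors.append("noise_sd must be > 0")
        if self.slope2_sign not in (-1.0, 1.0) or self.postslope2_sign not in (-1.0, 1.0):
            errors.append("slope signs must be -1 or +1")
        if errors:
            raise CohortValidationError(
                f"invalid BiomarkerSpec {self.name!r}: " + "; ".join(errors)
            )


# Ready-made specs used throughout the package.  The vascular-marker
# (Tie2-like) settings use log-baseline 4.3 (SD 0.6) and 15% proportional
# noise; the epithelial (CK18-like) and imaging (K-trans-like) specs scale
# the baselines and noise to those assays (K-trans in 1/min is of order
# 0.17, CK18 of order 1,100 pg/ml).
TIE2_SPEC = BiomarkerSpec(name="Tie2")
CK18_SPEC = BiomarkerSpec(
    name="CK18",
    baseline_log_mean=7.0,
    baseline_log_sd=0.55,
    slope1_mean=-0.7,
    postslope1_mean=0.5,
    noise_sd=0.18,
)
KTRANS_SPEC = BiomarkerSpec(
    name="Ktrans",
    baseline_log_mean=-1.8,
    baseline_log_sd=0.5,
    slope1_mean=-0.9,
    slope1_sd=0.25,
    noise_sd=0.12,
    units="1/min",
)


@dataclass(frozen=True)
class PatientTruth:
    """Generative ground truth for one patient and biomarker."""

    patient_id: str
    pfs_days: float
    event: bool
    biomarker: str
    alpha: float
    beta: float
    gamma: float
    t_inflection: float
    e1: int
    e2: int


@dataclass(frozen=True)
class Measurement:
    """One measured biomarker value.

    Pre-treatment replicates carry ``replicate`` 1 and 2 at non-positive
    times; on-treatment visits carry ``replicate`` 0.
    """

    patient_id: str
    biomarker: str
    time_days: float
    value: float
    replicate: int = 0


MEASUREMENT_COLUMNS = ["patient_id", "biomarker", "time_days", "value", "replicate"]
SURVIVAL_COLUMNS = ["patient_id", "pfs_days", "event"]
TRUTH_COLUMNS = [
    "patient_id", "pfs_days", "event", "biomarker",
    "alpha", "beta", "gamma", "t_inflection", "e1", "e2",
]


@dataclass
class CohortDataset:
    """Long-format measurements plus survival records and optional truth."""

    measurements: pd.DataFrame
    survival: pd.DataFrame
    truth: pd.DataFrame | None = None
    schedule_meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        known = set(self.survival["patient_id"])
        orphans = set(self.measurements["patient_id"]) - known
        if orphans:
            raise CohortValidationError(
                f"measurements reference patients absent from survival: {sorted(orphans)}"
            )

    def biomarkers(self) -> list[str]:
        return sorted(self.measurements["biomarker"].unique())

    def patient_series(self, patient_id: str, biomarker: str) -> pd.DataFrame:
        m = self.measurements
        out = m[(m["patient_id"] == patient_id) & (m["biomarker"] == biomarker)]
        return out.sort_values("time_days").reset_index(drop=True)

    def baseline_value(self, patient_id: str, biomarker: str) -> float:
        """Mean of the pre-treatment replicate measurements."""
        s = self.patient_series(patient_id, biomarker)
        base = s[s["replicate"] > 0]
        if base.empty:
            base = s[s["time_days"] <= 0]
        if base.empty:
            raise CohortValidationError(
                f"no pre-treatment baseline for {patient_id}/{biomarker}"
            )
        return float(base["value"].mean())


def _piecewise(alpha: float, beta: float, gamma: float, t_inf: float,
               t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    pre = alpha + beta * t
    post = alpha + beta * t_inf + gamma * (t - t_inf)
    return np.where(t < t_inf, pre, post)


def _draw_pfs(rng: np.random.Generator, median: float, log_sd: float) -> float:
    """Log-normal PFS truncated below the minimum compatible with the
    inflection-point support (redraw until valid)."""
    mu = math.log(median)
    while True:
        pfs = float(rng.lognormal(mu, log_sd))
        if pfs >= MIN_PFS_DAYS:
            return pfs


def generate_cohort(
    specs: Sequence[BiomarkerSpec],
    n_patients: int = 70,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    missing_rate: float = 0.1,
    seed: int = 0,
    *,
    pfs_median_days: float = 283.0,
    pfs_log_sd: float = 0.55,
    censor_rate: float = 0.1,
    min_on_treatment_visits: int = 3,
) -> CohortDataset:
    """Simulate a cohort of piecewise-linear biomarker trajectories.

    Parameters
    ----------
    specs
        One :class:`BiomarkerSpec` per biomarker to simulate.
    n_patients
        Cohort size (the trial design recruited 70 evaluable patients).
    schedule
        Nominal on-treatment visit days; visits after a patient's PFS are
        not observed.
    missing_rate
        Independent per-visit drop probability.  At least
        ``min_on_treatment_visits`` visits are always retained so that every
        patient remains modelable.
    seed
        Seeds all randomness; identical seeds give identical cohorts.
    pfs_median_days, pfs_log_sd
        Log-normal PFS calibration (median ~283 days as in the trial),
        truncated below 42 days so U(21, PFS-21) is proper.
    censor_rate
        Probability a patient's progression is censored (trial design
        anticipated a ~90% event rate).
    """
    if n_patients < 1:
        raise CohortValidationError("n_patients must be >= 1")
    if not len(schedule):
        raise CohortValidationError("schedule must be non-empty")
    if not 0.0 <= missing_rate < 1.0:
        raise CohortValidationError("missing_rate must lie in [0, 1)")
    if not specs:
        raise CohortValidationError("at least one BiomarkerSpec is required")
    for spec in specs:
        spec.validate()

    rng = np.random.default_rng(seed)
    schedule = np.asarray(sorted(schedule), dtype=float)

    meas_rows: list[tuple] = []
    surv_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    width = len(str(n_patients))
    for i in range(n_patients):
        pid = f"P{i + 1:0{width}d}"
        pfs = _draw_pfs(rng, pfs_median_days, pfs_log_sd)
        event = bool(rng.random() >= censor_rate)
        surv_rows.append((pid, pfs, event))

        anchor_t_inf: float | None = None
        for j, spec in enumerate(specs):
            alpha = float(np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd)))
            lo, hi = 21.0, pfs - 21.0
            anchored = spec.inflection_lag_days is not None and anchor_t_inf is not None
            # Mixture membership is drawn once (so the realized component
            # fractions follow mix_p1/mix_p2); the continuous magnitudes and
            # the inflection are redrawn until the noiseless trajectory stays
            # positive through follow-up — the hierarchical draw truncated to
            # physically valid (positive) concentration trajectories.
            e1 = int(rng.random() < spec.mix_p1)
            e2 = int(rng.random() < spec.mix_p2)
            for attempt in range(200):
                b1 = float(rng.normal(spec.slope1_mean, spec.slope1_sd))
                b2 = float(np.exp(rng.normal(spec.slope2_logmean, spec.slope2_logsd)))
                g1 = float(rng.normal(spec.postslope1_mean, spec.postslope1_sd))
                g2 = float(np.exp(rng.normal(spec.postslope2_logmean, spec.postslope2_logsd)))
                beta = alpha * (b1 + spec.slope2_sign * e1 * b2) / SLOPE_TIME_SCALE
                gamma = alpha * (g1 + spec.postslope2_sign * e2 * g2) / SLOPE_TIME_SCALE
                if anchored:
                    t_inf = float(np.clip(anchor_t_inf + spec.inflection_lag_days, lo, hi))
                else:
                    t_inf = float(rng.uniform(lo, hi))
                # Piecewise-linear minimum over [0, pfs] is attained at an
                # endpoint or the inflection.
                lowest = min(alpha, alpha + beta * t_inf,
                             alpha + beta * t_inf + gamma * (pfs - t_inf))
                if lowest > 0.05 * alpha:
                    break
            else:  # pragma: no cover - vanishingly rare under the defaults
                b1, b2, e1 = spec.slope1_mean, 0.0, 0
                g1, g2, e2 = abs(spec.postslope1_mean), 0.0, 0
                beta = alpha * b1 / SLOPE_TIME_SCALE
                gamma = alpha * g1 / SLOPE_TIME_SCALE
            if j == 0:
                anchor_t_inf = t_inf

            truth_rows.append((pid, pfs, event, spec.name, alpha, beta, gamma,
                               t_inf, e1, e2))

            # Two noisy pre-treatment replicates of the baseline quantity.
            for rep, day in enumerate(BASELINE_DAYS, start=1):
                noisy = alpha + abs(alpha) * spec.noise_sd * rng.standard_normal()
                meas_rows.append((pid, spec.name, float(day), noisy, rep))

            visits = schedule[schedule <= pfs]
            keep = rng.random(len(visits)) >= missing_rate
            if keep.sum() < min(min_on_treatment_visits, len(visits)):
                order = rng.permutation(len(visits))
                need = min(min_on_treatment_visits, len(visits))
                keep = np.zeros(len(visits), dtype=bool)
                keep[order[:need]] = True
            for t in visits[keep]:
                mean = float(_piecewise(alpha, beta, gamma, t_inf, np.array([t]))[0])
                noisy = mean + abs(mean) * spec.noise_sd * rng.standard_normal()
                meas_rows.append((pid, spec.name, float(t), noisy, 0))

    dataset = CohortDataset(
        measurements=pd.DataFrame(meas_rows, columns=MEASUREMENT_COLUMNS),
        survival=pd.DataFrame(surv_rows, columns=SURVIVAL_COLUMNS),
        truth=pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS),
        schedule_meta={
            "schedule": [float(t) for t in schedule],
            "missing_rate": float(missing_rate),
            "seed": int(seed),
            "baseline_days": list(BASELINE_DAYS),
        },
    )
    dataset.validate()
    return dataset


# ---------------------------------------------------------------------------
# Dynamic-range transforms


def transform_biomarker(values, rule: str, partner=None):
    """Apply one of the dynamic-range control transforms.

    Supported rules: ``identity``; ``log2``; ``square-times-10`` (value
    squared then multiplied by 10, used for the epithelial M65/CK18 assay);
    ``product-with-partner-div-1000`` (elementwise product with a partner
    series divided by 1000, used for the log2-Ang2 x Tie2 product).
    """
    arr = np.asarray(values, dtype=float)
    if rule == "identity":
        out = arr.copy()
    elif rule == "log2":
        if np.any(arr <= 0):
            raise ValueError("log2 transform requires strictly positive values")
        out = np.log2(arr)
    elif rule == "square-times-10":
        out = arr ** 2 * 10.0
    elif rule == "product-with-partner-div-1000":
        if partner is None:
            raise ValueError("rule 'product-with-partner-div-1000' needs a partner series")
        out = arr * np.asarray(partner, dtype=float) / 1000.0
    else:
        raise ValueError(f"unknown transform rule: {rule!r}")
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    if np.isscalar(values):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# CSV round-trip


def write_cohort(dataset: CohortDataset, path) -> None:
    """Write a cohort as plain CSV files under a directory.

    Produces ``measurements.csv``, ``survival.csv``, ``truth.csv`` (when
    truth is present) and ``schedule_meta.json``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.measurements.to_csv(path / "measurements.csv", index=False)
    dataset.survival.to_csv(path / "survival.csv", index=False)
    if dataset.truth is not None:
        dataset.truth.to_csv(path / "truth.csv", index=False)
    (path / "schedule_meta.json").write_text(
        json.dumps(dataset.schedule_meta, indent=2) + "\n"
    )


def _read_csv_checked(fname: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(fname)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise CohortValidationError(f"malformed CSV {fname.name}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(
            f"{fname.name} is missing required column(s): {', '.join(missing)}"
        )
    for col in required:
        if col in ("patient_id", "biomarker"):
            continue
        bad = df[col].apply(lambda v: not _is_number_like(v))
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based, plus header line
            raise CohortValidationError(
                f"{fname.name}: non-numeric value in column {col!r} at line {row}"
            )
    return df


def _is_number_like(v) -> bool:
    if isinstance(v, (int, float, np.integer, np.floating)):
        return not (isinstance(v, float) and math.isnan(v))
    if isinstance(v, (bool, np.bool_)):
        return True
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return str(v).strip().lower() in ("true", "false")


def read_cohort(path) -> CohortDataset:
    """Read a cohort previously written by :func:`write_cohort`."""
    path = Path(path)
    meas = _read_csv_checked(path / "measurements.csv", MEASUREMENT_COLUMNS)
    if meas.empty:
        meas = pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    else:
        meas = meas.astype({"time_days": float, "value": float, "replicate": int})
    surv = _read_csv_checked(path / "survival.csv", SURVIVAL_COLUMNS)
    if not surv.empty:
        surv = surv.astype({"pfs_days": float})
        surv["event"] = surv["event"].map(_to_bool)
    truth = None
    truth_path = path / "truth.csv"
    if truth_path.exists():
        truth = _read_csv_checked(truth_path, TRUTH_COLUMNS)
        if not truth.empty:
            truth = truth.astype({
                "pfs_days": float, "alpha": float, "beta": float,
                "gamma": float, "t_inflection": float, "e1": int, "e2": int,
            })
            truth["event"] = truth["event"].map(_to_bool)
    meta_path = path / "schedule_meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    ds = CohortDataset(measurements=meas, survival=surv, truth=truth,
                       schedule_meta=meta)
    ds.validate()
    return ds


def _to_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("true", "1", "1.0", "yes")
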