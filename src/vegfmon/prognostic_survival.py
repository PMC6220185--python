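"""Prognostic screen for pre-treatment covariates against PFS.

Univariate Cox proportional-hazards tests with proportionality (Schoenfeld
residual) and nonlinearity (Martingale residual) checks, backward-stepwise
multivariate selection, bootstrap-resampling validation with a strict
two-out-of-three (>66%) retention rule, a pre-treatment ratio covariate
(e.g. VEGFR2 : K-trans), percentile dichotomization with Kaplan-Meier /
log-rank comparison, and a Fisher's-exact association between the
trajectory clusters and a dichotomized covariate.

Cox, Kaplan-Meier and log-rank machinery is provided by ``lifelines``
(Efron tie handling); Fisher's exact test and the residual trend tests by
``scipy``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, proportional_hazard_test
from scipy import stats

__all__ = [
    "UnivariateResult",
    "MultivariateModel",
    "BootstrapReport",
    "KMSplitResult",
    "univariate_screen",
    "multivariate_select",
    "bootstrap_validate",
    "ratio_covariate",
    "percentile_split_km",
    "fisher_exact_table",
    "cluster_prognosis_association",
]

DURATION_COL = "pfs_days"
EVENT_COL = "event"
ENTRY_P = 0.05


@dataclass
class UnivariateResult:
    covariate: str
    hazard_ratio: float | None
    p_value: float | None
    enters: bool
    proportionality_flag: bool = False
    nonlinearity_flag: bool = False
    transformed: str | None = None
    skipped: bool = False
    reason: str | None = None


@dataclass
class MultivariateModel:
    covariates: list[str]
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    dropped: list[str] = field(default_factory=list)
    collinear_flag: list[str] = field(default_factory=list)
    empty: bool = False


@dataclass
class BootstrapReport:
    frequencies: dict[str, float]
    retained: dict[str, bool]
    n_boot: int
    n_skipped: int
    seed: int
    cutoff: float = 0.66


@dataclass
class KMSplitResult:
    percentile: float
    cut_value: float
    group_sizes: dict[str, int]
    medians: dict[str, float | None]
    logrank_p: float
    curves: pd.DataFrame


def _records_frame(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    needed = [DURATION_COL, EVENT_COL] + covariates
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise ValueError(f"records missing column(s): {missing}")
    df = records[needed].copy()
    df[EVENT_COL] = df[EVENT_COL].astype(bool)
    return df


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[[DURATION_COL, EVENT_COL] + covariates],
                duration_col=DURATION_COL, event_col=EVENT_COL,
                fit_options={"precision": 1e-9})
    return cph


def _trend_p(x: np.ndarray, y: np.ndarray) -> float:
    """p-value of the slope in a simple linear trend (residual check)."""
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return 1.0
    res = stats.linregress(x, y)
    return float(res.pvalue)


def univariate_screen(records: pd.DataFrame, covariates: list[str],
                      *, dichotomize: set[str] | None = None,
                      alpha: float = ENTRY_P) -> list[UnivariateResult]:
    """Per-covariate proportional-hazards screen with assumption checks.

    Each covariate is fitted alone (continuous, or median-dichotomized for
    names in ``dichotomize``).  Proportionality is flagged by a Schoenfeld
    residual trend test and nonlinearity by a Martingale-residual-vs-
    covariate trend; a flagged nonlinear positive covariate is refit on the
    log2 scale.  Covariates with Wald p < 0.05 are marked for multivariate
    entry.
    """
    df = _records_frame(records, covariates)
    if int(df[EVENT_COL].sum()) < 10:
        raise ValueError("univariate screen requires >= 10 events")
    dichotomize = dichotomize or set()
    results = []
    for cov in covariates:
        x = df[cov].to_numpy(float)
        if np.all(x == x[0]):
            results.append(UnivariateResult(cov, None, None, False,
                                            skipped=True,
                                            reason="constant covariate"))
            continue
        work = df[[DURATION_COL, EVENT_COL, cov]].copy()
        used_name = cov
        transformed = None
        if cov in dichotomize:
            med = float(np.median(x))
            work[cov] = (x > med).astype(float)
            transformed = "median-dichotomized"
        try:
            cph = _fit_cox(work, [cov])
        except (ConvergenceError, ValueError) as exc:
            results.append(UnivariateResult(cov, None, None, False,
                                            skipped=True, reason=str(exc)))
            continue

        # Martingale residual nonlinearity check on the continuous fit.
        nonlin = False
        if transformed is None:
            resid = cph.compute_residuals(work, "martingale")
            nonlin = _trend_p(work.loc[resid.index, cov].to_numpy(float),
                              resid["martingale"].to_numpy(float)) < 0.05
            # Quadratic-term check catches curvature a straight line misses.
            xs = work[cov].to_numpy(float)
            rs = resid.loc[work.index, "martingale"].to_numpy(float)
            if not nonlin and np.std(xs) > 0:
                nonlin = _trend_p((xs - xs.mean()) ** 2, rs) < 0.05
            if nonlin and np.all(xs > 0):
                work[cov] = np.log2(xs)
                transformed = "log2"
                try:
                    cph = _fit_cox(work, [cov])
                except (ConvergenceError, ValueError):
                    pass

        p = float(cph.summary.loc[used_name, "p"])
        hr = float(cph.summary.loc[used_name, "exp(coef)"])
        prop_flag = False
        try:
            pht = proportional_hazard_test(cph, work, time_transform="rank")
            prop_flag = float(np.atleast_1d(pht.p_value)[0]) < 0.05
        except Exception:
            pass
        results.append(UnivariateResult(
            covariate=cov, hazard_ratio=hr, p_value=p,
            enters=bool(p < alpha),
            proportionality_flag=prop_flag,
            nonlinearity_flag=nonlin,
            transformed=transformed,
        ))
    return results


def multivariate_select(records: pd.DataFrame,
                        entered: list[str],
                        *, alpha: float = ENTRY_P) -> MultivariateModel:
    """Backward stepwise Cox selection.

    Starting from all entered covariates, iteratively removes the least
    significant one (largest Wald p >= 0.05) until every remaining
    covariate is significant.  Perfectly collinear pairs are resolved by
    dropping the later-listed member (flagged).
    """
    if len(entered) < 1:
        raise ValueError("need at least one entered covariate")
    df = _records_frame(records, entered)
    current = list(entered)
    collinear = []
    # Resolve exact collinearity up-front.
    for i, a in enumerate(list(current)):
        for b in list(current[i + 1:]):
            if a in current and b in current:
                xa, xb = df[a].to_numpy(float), df[b].to_numpy(float)
                if np.std(xa) > 0 and np.std(xb) > 0:
                    if abs(np.corrcoef(xa, xb)[0, 1]) > 0.9999:
                        current.remove(b)
                        collinear.append(b)
    dropped = list(collinear)
    while current:
        try:
            cph = _fit_cox(df, current)
        except (ConvergenceError, ValueError):
            worst = current[-1]
            current.remove(worst)
            dropped.append(worst)
            continue
        pvals = cph.summary["p"]
        worst = str(pvals.idxmax())
        if float(pvals.max()) >= alpha and len(current) > 0:
            current.remove(worst)
            dropped.append(worst)
            if not current:
                break
            continue
        summ = cph.summary
        return MultivariateModel(
            covariates=list(current),
            hazard_ratios={c: float(summ.loc[c, "exp(coef)"]) for c in current},
            ci_lower={c: float(summ.loc[c, "exp(coef) lower 95%"]) for c in current},
            ci_upper={c: float(summ.loc[c, "exp(coef) upper 95%"]) for c in current},
            p_values={c: float(summ.loc[c, "p"]) for c in current},
            dropped=dropped,
            collinear_flag=collinear,
        )
    return MultivariateModel([], {}, {}, {}, {}, dropped=dropped,
                             collinear_flag=collinear, empty=True)


def bootstrap_validate(records: pd.DataFrame, covariates: list[str],
                       n_boot: int = 1000, seed: int = 0,
                       *, alpha: float = ENTRY_P,
                       cutoff: float = 0.66) -> BootstrapReport:
    """Bootstrap stability of a fitted model's covariates.

    Resamples patients with replacement ``n_boot`` times, refits the Cox
    model, and records per covariate the relative frequency of Wald
    p < 0.05 among successful resamples.  A covariate is retained when its
    frequency strictly exceeds the cutoff (66%: significant in at least two
    cases out of three).  Resamples with zero events are skipped and
    tallied.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not covariates:
        raise ValueError("need at least one covariate to validate")
    df = _records_frame(records, covariates)
    rng = np.random.default_rng(seed)
    counts = {c: 0 for c in covariates}
    n_used = 0
    n_skipped = 0
    n = len(df)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = df.iloc[idx].reset_index(drop=True)
        if int(boot[EVENT_COL].sum()) == 0:
            n_skipped += 1
            continue
        if any(np.std(boot[c].to_numpy(float)) == 0 for c in covariates):
            n_skipped += 1
            continue
        try:
            cph = _fit_cox(boot, covariates)
        except (ConvergenceError, ValueError):
            n_skipped += 1
            continue
        n_used += 1
        for c in covariates:
            if float(cph.summary.loc[c, "p"]) < alpha:
                counts[c] += 1
    denom = max(n_used, 1)
    freqs = {c: counts[c] / denom for c in covariates}
    return BootstrapReport(
        frequencies=freqs,
        retained={c: bool(freqs[c] > cutoff) for c in covariates},
        n_boot=n_boot,
        n_skipped=n_skipped,
        seed=seed,
        cutoff=cutoff,
    )


def ratio_covariate(records: pd.DataFrame, numerator: str, denominator: str,
                    name: str | None = None) -> pd.DataFrame:
    """Add a per-patient pre-treatment ratio covariate.

    Patients with a zero denominator are flagged (ratio set to NaN and
    listed in the returned frame's ``attrs['ratio_excluded']``) and should
    be excluded from ratio analyses.
    """
    for col in (numerator, denominator):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    name = name or f"{numerator}:{denominator}"
    out = records.copy()
    den = out[denominator].to_numpy(float)
    num = out[numerator].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den == 0.0, np.nan, num / den)
    out[name] = ratio
    excluded = out.loc[den == 0.0, "patient_id"].tolist() \
        if "patient_id" in out.columns else list(np.flatnonzero(den == 0.0))
    out.attrs["ratio_excluded"] = excluded
    out.attrs["ratio_name"] = name
    return out


def percentile_split_km(records: pd.DataFrame, covariate: str,
                        percentile: float = 33.0) -> KMSplitResult:
    """Dichotomize at a percentile and compare PFS by Kaplan-Meier/log-rank.

    The cut is the smallest observed covariate value at or above the
    requested percentile, and the ``low`` group includes the boundary order
    statistic — splitting 70 patients at the 33rd percentile places 24 in
    the low group.  A group with zero events has its median survival
    reported as None (not reached).
    """
    df = _records_frame(records, [covariate]).copy()
    x = df[covariate].to_numpy(float)
    if np.any(~np.isfinite(x)):
        raise ValueError(f"covariate {covariate!r} must be defined (finite) "
                         "for all included patients")
    cut = float(np.quantile(x, percentile / 100.0, method="higher"))
    low = x <= cut
    if low.all():  # heavy ties at the boundary: fall back to the lower cut
        cut = float(np.quantile(x, percentile / 100.0, method="lower"))
        low = x <= cut
    if low.all() or not low.any():
        raise ValueError(
            f"covariate {covariate!r} has too few distinct values to split "
            f"at the {percentile:g}th percentile"
        )
    groups = {"low": df[low], "high": df[~low]}
    medians: dict[str, float | None] = {}
    curve_frames = []
    for gname, gdf in groups.items():
        km = KaplanMeierFitter()
        km.fit(gdf[DURATION_COL], gdf[EVENT_COL], label=gname)
        med = km.median_survival_time_
        medians[gname] = None if np.isinf(med) else float(med)
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf["group"] = gname
        sf["at_risk"] = [int(km.event_table.loc[t, "at_risk"])
                         if t in km.event_table.index else np.nan
                         for t in sf["time"]]
        curve_frames.append(sf)
    lr = logrank_test(groups["low"][DURATION_COL], groups["high"][DURATION_COL],
                      groups["low"][EVENT_COL], groups["high"][EVENT_COL])
    return KMSplitResult(
        percentile=percentile,
        cut_value=cut,
        group_sizes={g: int(len(d)) for g, d in groups.items()},
        medians=medians,
        logrank_p=float(lr.p_value),
        curves=pd.concat(curve_frames, ignore_index=True),
    )


def fisher_exact_table(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns ``(odds_ratio, p_value)``.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    odds, p = stats.fisher_exact(arr)
    return float(odds), float(p)


def cluster_prognosis_association(cluster_labels, dichotomized) -> dict:
    """Fisher's exact association between two patient groupings.

    ``cluster_labels`` and ``dichotomized`` are mappings (or Series) from
    patient id to a binary group label.  Returns the 2x2 table, odds ratio
    and exact p-value; an empty row or column yields p = 1 with a flag.
    """
    a = pd.Series(dict(cluster_labels))
    b = pd.Series(dict(dichotomized))
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no patients shared between the two groupings")
    a, b = a.loc[common], b.loc[common]
    table = pd.crosstab(a, b)
    # Pad to 2x2 if one level is absent.
    degenerate = table.shape != (2, 2)
    if degenerate:
        return {"table": table, "odds_ratio": None, "p_value": 1.0,
                "degenerate": True, "n": int(len(common))}
    odds, p = fisher_exact_table(table.to_numpy())
    return {"table": table, "odds_ratio": odds, "p_value": p,
            "degenerate": False, "n": int(len(common))}
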