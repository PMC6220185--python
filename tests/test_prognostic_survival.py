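"""Cox screen, stepwise selection, bootstrap retention, KM split, Fisher."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

import vegfmon as v


def simulate_cohort(rng, n=70, beta=0.0, censor=0.1, extra=None):
    """Exponential PFS with a log-hazard-ratio ``beta`` per unit covariate."""
    x = rng.standard_normal(n)
    lam = 0.004 * np.exp(beta * x)
    t = rng.exponential(1.0 / lam)
    event = rng.random(n) >= censor
    df = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)],
                       "pfs_days": t, "event": event, "x": x})
    if extra:
        for name, vals in extra.items():
            df[name] = vals
    return df


def breslow_partial_loglik(beta, times, events, x):
    """Independent partial-likelihood oracle (no ties: Breslow = Efron)."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = x[i:]  # everyone with time >= t_i
        ll += beta * x[i] - math.log(np.exp(beta * risk).sum())
    return ll


class TestUnivariateScreen:
    def test_strong_effect_detected_in_most_cohorts(self, rng):
        hits = 0
        reps = 30
        for _ in range(reps):
            df = simulate_cohort(rng, beta=math.log(3.0))
            res = v.univariate_screen(df, ["x"])[0]
            hits += res.p_value < 0.05
        assert hits >= 0.9 * reps

    def test_null_covariate_type_i_rate(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            df = simulate_cohort(rng, beta=0.0)
            res = v.univariate_screen(df, ["x"])[0]
            hits += res.p_value < 0.05
        assert 0.01 <= hits / reps <= 0.10

    def test_entry_rule_boundary(self, rng):
        df = simulate_cohort(rng, beta=0.5)
        res = v.univariate_screen(df, ["x"])[0]
        assert res.enters == (res.p_value < 0.05)

    def test_constant_covariate_skipped(self, rng):
        df = simulate_cohort(rng)
        df["c"] = 1.0
        res = {r.covariate: r for r in v.univariate_screen(df, ["x", "c"])}
        assert res["c"].skipped and res["c"].reason == "constant covariate"

    def test_median_dichotomization(self, rng):
        df = simulate_cohort(rng, beta=math.log(2.0))
        res = v.univariate_screen(df, ["x"], dichotomize={"x"})[0]
        assert res.transformed == "median-dichotomized"
        assert res.hazard_ratio is not None

    def test_too_few_events_rejected(self, rng):
        df = simulate_cohort(rng, n=12, censor=0.5)
        df["event"] = [True] * 5 + [False] * 7
        with pytest.raises(ValueError, match="10 events"):
            v.univariate_screen(df, ["x"])

    def test_coefficient_matches_partial_likelihood_oracle(self, rng):
        # Small instance, no ties: lifelines-backed fit equals an
        # independent maximization of the Cox partial likelihood.
        df = simulate_cohort(rng, n=18, beta=0.7, censor=0.2)
        res = v.univariate_screen(df, ["x"])[0]
        t = df["pfs_days"].to_numpy()
        e = df["event"].to_numpy(bool)
        x = df["x"].to_numpy()
        opt = minimize_scalar(
            lambda b: -breslow_partial_loglik(b, t, e, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10})
        assert math.log(res.hazard_ratio) == pytest.approx(opt.x, abs=1e-6)


class TestMultivariateSelect:
    def test_noise_removed_strong_retained(self, rng):
        keep_both = 0
        reps = 25
        for _ in range(reps):
            n = 70
            x1 = rng.standard_normal(n)
            x2 = rng.standard_normal(n)
            noise = rng.standard_normal(n)
            lam = 0.004 * np.exp(1.1 * x1 + 1.1 * x2)
            df = pd.DataFrame({
                "pfs_days": rng.exponential(1.0 / lam),
                "event": rng.random(n) >= 0.1,
                "x1": x1, "x2": x2, "noise": noise})
            model = v.multivariate_select(df, ["x1", "x2", "noise"])
            if set(model.covariates) == {"x1", "x2"}:
                keep_both += 1
        assert keep_both >= 0.8 * reps

    def test_single_covariate_returned_unchanged(self, rng):
        df = simulate_cohort(rng, beta=1.0)
        model = v.multivariate_select(df, ["x"])
        assert model.covariates == ["x"]

    def test_collinear_pair_resolved_with_flag(self, rng):
        df = simulate_cohort(rng, beta=1.0)
        df["x_copy"] = 2.0 * df["x"] + 1.0
        model = v.multivariate_select(df, ["x", "x_copy"])
        assert model.collinear_flag == ["x_copy"]
        assert "x_copy" not in model.covariates


class TestBootstrapValidate:
    def test_overwhelming_effect_retained(self, rng):
        df = simulate_cohort(rng, beta=math.log(5.0))
        rep = v.bootstrap_validate(df, ["x"], n_boot=120, seed=4)
        assert rep.frequencies["x"] > 0.9
        assert rep.retained["x"]

    def test_null_covariate_not_retained(self, rng):
        df = simulate_cohort(rng, beta=0.0)
        rep = v.bootstrap_validate(df, ["x"], n_boot=120, seed=4)
        assert rep.frequencies["x"] < 0.5
        assert not rep.retained["x"]

    def test_boundary_is_strictly_exceeding(self):
        rep = v.BootstrapReport(frequencies={"x": 0.66}, retained={}, n_boot=0,
                                n_skipped=0, seed=0)
        # The retention rule itself: exactly 66% must NOT retain.
        assert not (rep.frequencies["x"] > rep.cutoff)

    def test_reproducible_under_seed(self, rng):
        df = simulate_cohort(rng, beta=0.8)
        r1 = v.bootstrap_validate(df, ["x"], n_boot=60, seed=11)
        r2 = v.bootstrap_validate(df, ["x"], n_boot=60, seed=11)
        assert r1.frequencies == r2.frequencies


class TestRatioCovariate:
    def test_ratio_arithmetic(self):
        df = pd.DataFrame({"patient_id": ["a"], "pfs_days": [100.0],
                           "event": [True], "VEGFR2": [11000.0],
                           "Ktrans": [0.17]})
        out = v.ratio_covariate(df, "VEGFR2", "Ktrans")
        assert out["VEGFR2:Ktrans"].iloc[0] == pytest.approx(11000.0 / 0.17)

    def test_zero_denominator_flagged(self):
        df = pd.DataFrame({"patient_id": ["a", "b"], "pfs_days": [1.0, 2.0],
                           "event": [True, True], "n": [1.0, 2.0],
                           "d": [0.0, 4.0]})
        out = v.ratio_covariate(df, "n", "d")
        assert np.isnan(out["n:d"].iloc[0])
        assert out.attrs["ratio_excluded"] == ["a"]

    def test_prognostic_ratio_detected(self, rng):
        hits = 0
        reps = 25
        for _ in range(reps):
            n = 70
            num = np.exp(rng.normal(9, 0.4, n))
            den = np.exp(rng.normal(-1.8, 0.4, n))
            ratio = num / den
            z = (np.log(ratio) - np.log(ratio).mean()) / np.log(ratio).std()
            lam = 0.004 * np.exp(1.0 * z)
            df = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)],
                               "pfs_days": rng.exponential(1.0 / lam),
                               "event": rng.random(n) >= 0.1,
                               "num": num, "den": den})
            df = v.ratio_covariate(df, "num", "den", name="r")
            df["r"] = np.log(df["r"])  # HR per log unit
            res = v.univariate_screen(df, ["r"])[0]
            hits += res.p_value < 0.05
        assert hits >= 0.8 * reps


class TestPercentileSplitKm:
    def test_33rd_percentile_of_70_gives_24_low(self, rng):
        df = simulate_cohort(rng, n=70)
        df["ratio"] = rng.uniform(1, 100, 70)
        km = v.percentile_split_km(df, "ratio", percentile=33.0)
        assert km.group_sizes == {"low": 24, "high": 46}

    def test_rate_ratio_three_detected_by_logrank(self, rng):
        hits = 0
        reps = 25
        for _ in range(reps):
            n = 70
            grp_marker = rng.uniform(0, 1, n)
            cut = np.quantile(grp_marker, 0.33, method="higher")
            lam = np.where(grp_marker <= cut, 0.012, 0.004)
            df = pd.DataFrame({"pfs_days": rng.exponential(1.0 / lam),
                               "event": True, "m": grp_marker})
            km = v.percentile_split_km(df, "m", percentile=33.0)
            hits += km.logrank_p < 0.01
        assert hits >= 0.9 * reps

    def test_null_split_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(100):
            df = simulate_cohort(rng, n=40, beta=0.0, censor=0.0)
            df["m"] = rng.uniform(0, 1, 40)
            km = v.percentile_split_km(df, "m", percentile=50.0)
            ps.append(km.logrank_p)
        # Kolmogorov-Smirnov against uniform at a lenient level.
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_zero_event_group_median_not_reached(self, rng):
        df = pd.DataFrame({"pfs_days": np.r_[rng.exponential(100, 35),
                                             rng.uniform(300, 400, 35)],
                           "event": [True] * 35 + [False] * 35,
                           "m": np.r_[rng.uniform(0, 0.4, 35),
                                      rng.uniform(0.6, 1.0, 35)]})
        km = v.percentile_split_km(df, "m", percentile=50.0)
        assert km.medians["high"] is None

    def test_km_restricted_mean_equals_sample_mean_no_censoring(self, rng):
        # With no censoring the KM step function integrates to the sample
        # mean of the event times.
        df = simulate_cohort(rng, n=50, censor=0.0)
        df["m"] = rng.uniform(0, 1, 50)
        km = v.percentile_split_km(df, "m", percentile=50.0)
        for gname in ("low", "high"):
            grp = km.curves[km.curves["group"] == gname]
            t = grp["time"].to_numpy()
            s = grp["survival"].to_numpy()
            # Left-continuous step integral of S(t) over [0, t_max].
            area = float(np.sum(s[:-1] * np.diff(t)))
            sel = df["m"] <= km.cut_value if gname == "low" \
                else df["m"] > km.cut_value
            assert area == pytest.approx(df.loc[sel, "pfs_days"].mean(),
                                         rel=1e-6)


def fisher_enumeration(table):
    """Exact two-sided Fisher p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)
                / math.comb(n, c1))

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-12):
            total += pk
    return total


class TestClusterPrognosisAssociation:
    def test_perfect_alignment_tiny_p(self):
        labels = {f"P{i}": (1 if i < 35 else 2) for i in range(70)}
        out = v.cluster_prognosis_association(labels, labels)
        assert out["p_value"] < 1e-10

    def test_diagonal_table_matches_enumeration(self):
        labels_a = {f"P{i}": int(i < 10) for i in range(20)}
        out = v.cluster_prognosis_association(labels_a, labels_a)
        want = fisher_enumeration([[10, 0], [0, 10]])
        assert out["p_value"] == pytest.approx(want, rel=1e-9)

    def test_independent_groupings_p_uniform(self, rng):
        ps = []
        for _ in range(300):
            a = {f"P{i}": int(rng.random() < 0.5) for i in range(40)}
            b = {f"P{i}": int(rng.random() < 0.5) for i in range(40)}
            ps.append(v.cluster_prognosis_association(a, b)["p_value"])
        # Fisher's exact p is conservative/discrete; just require that
        # small p-values are not over-produced under the null.
        assert np.mean(np.array(ps) < 0.05) <= 0.07

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(60):
            n = int(rng.integers(8, 41))
            a = {f"P{i}": int(rng.random() < 0.5) for i in range(n)}
            b = {f"P{i}": int(rng.random() < 0.5) for i in range(n)}
            out = v.cluster_prognosis_association(a, b)
            if out["degenerate"]:
                continue
            table = out["table"].to_numpy()
            assert out["p_value"] == pytest.approx(
                fisher_enumeration(table.tolist()), rel=1e-9)

    def test_empty_cell_row_gives_p_one_with_flag(self):
        a = {f"P{i}": 0 for i in range(10)}
        b = {f"P{i}": int(i < 5) for i in range(10)}
        out = v.cluster_prognosis_association(a, b)
        assert out["degenerate"] and out["p_value"] == 1.0
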