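"""Statistical analyses of the transmission, persistence, decay and fitness experiments.

The experimental designs analysed here are small and balanced: counts of
infected individuals out of tested individuals per generation (or per hour
since wasp contamination) and per replicate cage, and per-pair fitness
traits in four infected and four uninfected replicate cages.

Implemented tests
-----------------
* ``outcome_proportions`` — percentages with logit-scale confidence
  intervals (exact Clopper–Pearson at the boundary) for the
  visit-outcome counts.
* ``logit_prevalence_fit`` — per-group prevalence estimates and standard
  errors on the logit scale, back-transformed to proportions.
* ``lrt_heterogeneity`` — likelihood-ratio test for heterogeneity of a
  binomial probability across groups, with a replicate-level random
  intercept integrated by 15-node adaptive Gauss–Hermite quadrature
  (collapsing to the fixed-effects test when the variance estimate hits
  zero); df = groups - 1.
* ``logistic_trend`` — binomial GLM (logit link, IRLS) of infection on a
  quantitative covariate such as hours since contamination; Wald z for the
  slope, with a complete-separation flag.
* ``fitness_compare`` — per-trait comparisons between infection arms:
  replicate-means t-tests for Gaussian traits (the exact reduction of the
  balanced random-intercept linear mixed model, df = replicates - 2),
  over-dispersed binomial GLMs for ratio traits, and a replicate-stratified
  Cox partial likelihood (Breslow ties) for longevity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

__all__ = [
    "OutcomeCounts",
    "ProportionEstimate",
    "TestResult",
    "FitnessDataset",
    "validate_count_table",
    "outcome_proportions",
    "logit_prevalence_fit",
    "lrt_heterogeneity",
    "logistic_trend",
    "fitness_compare",
]

_Z95 = float(sps.norm.ppf(0.975))


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class OutcomeCounts:
    """Fate of parasitoid-visited nymphs and infection among survivors."""

    visited: int
    died: int
    parasitoid_emerged: int
    whitefly_emerged: int
    infected_of_emerged: int

    def __post_init__(self) -> None:
        for name in ("visited", "died", "parasitoid_emerged", "whitefly_emerged",
                     "infected_of_emerged"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.died + self.parasitoid_emerged + self.whitefly_emerged != self.visited:
            raise ValueError(
                "died + parasitoid_emerged + whitefly_emerged must equal visited"
            )
        if self.infected_of_emerged > self.whitefly_emerged:
            raise ValueError("infected_of_emerged cannot exceed whitefly_emerged")


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with a 95% interval.

    The interval is computed on the logit scale and back-transformed; when
    the count is at the boundary (0 or n) an exact Clopper–Pearson interval
    is used instead and ``boundary`` is set.
    """

    count: int
    total: int
    proportion: float
    percent: float  # rounded to one decimal, reporting style
    ci_low: float
    ci_high: float
    boundary: bool = False


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    statistic_kind: str  # chi_square | z | t
    df: int | None
    p_value: float
    estimate: float = float("nan")
    se: float = float("nan")
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.statistic_kind in ("chi_square", "t") and self.df is None:
            raise ValueError(f"df required for statistic_kind={self.statistic_kind}")


@dataclass
class FitnessDataset:
    """Per-pair fitness traits plus per-replicate offspring sex counts.

    ``pairs`` has one row per breeding pair with columns ``arm``
    ("infected"/"uninfected"), ``replicate``, ``pair``, ``development_time``
    (days), ``fecundity`` (eggs), ``longevity`` (days, no censoring),
    ``immature_total`` and ``immature_survived`` (counts).  ``sex`` has one
    row per replicate cage with columns ``arm``, ``replicate``, ``n_female``,
    ``n_male``.
    """

    pairs: pd.DataFrame
    sex: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    _PAIR_COLS = ("arm", "replicate", "pair", "development_time", "fecundity",
                  "longevity", "immature_total", "immature_survived")

    def __post_init__(self) -> None:
        missing = [c for c in self._PAIR_COLS if c not in self.pairs.columns]
        if missing:
            raise ValueError(f"pairs table missing columns: {missing}")
        arms = set(self.pairs["arm"].unique())
        if arms != {"infected", "uninfected"}:
            raise ValueError(f"both arms required, got {sorted(arms)}")
        for arm in arms:
            n_rep = self.pairs.loc[self.pairs["arm"] == arm, "replicate"].nunique()
            if n_rep < 2:
                raise ValueError(f"arm {arm!r} needs >= 2 replicates, has {n_rep}")

    def to_long(self) -> pd.DataFrame:
        """Tidy long format: arm, replicate, unit, trait, value."""
        rows = self.pairs.melt(
            id_vars=["arm", "replicate", "pair"],
            value_vars=["development_time", "fecundity", "longevity",
                        "immature_total", "immature_survived"],
            var_name="trait", value_name="value",
        ).rename(columns={"pair": "unit"})
        if self.sex is not None:
            sex_long = self.sex.melt(
                id_vars=["arm", "replicate"],
                value_vars=["n_female", "n_male"],
                var_name="trait", value_name="value",
            )
            sex_long["unit"] = "replicate"
            rows = pd.concat([rows, sex_long], ignore_index=True)
        return rows[["arm", "replicate", "unit", "trait", "value"]]

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "FitnessDataset":
        pair_rows = long[long["unit"] != "replicate"]
        pairs = pair_rows.pivot_table(
            index=["arm", "replicate", "unit"], columns="trait", values="value"
        ).reset_index().rename(columns={"unit": "pair"})
        pairs.columns.name = None
        sex_rows = long[long["unit"] == "replicate"]
        sex = None
        if len(sex_rows):
            sex = sex_rows.pivot_table(
                index=["arm", "replicate"], columns="trait", values="value"
            ).reset_index()
            sex.columns.name = None
            sex[["n_female", "n_male"]] = sex[["n_female", "n_male"]].astype(int)
        pairs[["immature_total", "immature_survived"]] = (
            pairs[["immature_total", "immature_survived"]].astype(int)
        )
        return cls(pairs=pairs, sex=sex)

    @classmethod
    def from_csv(cls, path) -> "FitnessDataset":
        return cls.from_long(pd.read_csv(path))


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format count table (group, replicate, infected, total)."""
    required = {"group", "replicate", "infected", "total"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("count table is empty")
    if (table["total"] <= 0).any():
        raise ValueError("all totals must be positive")
    if ((table["infected"] < 0) | (table["infected"] > table["total"])).any():
        raise ValueError("infected counts must lie in [0, total]")
    return table


# ---------------------------------------------------------------------------
# proportions

def _proportion_estimate(count: int, total: int) -> ProportionEstimate:
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    prop = count / total
    if count == 0 or count == total:
        # exact Clopper-Pearson at the boundary; the logit SE is undefined
        lo = 0.0 if count == 0 else float(sps.beta.ppf(0.025, count, total - count + 1))
        hi = 1.0 if count == total else float(sps.beta.ppf(0.975, count + 1, total - count))
        return ProportionEstimate(count, total, prop, round(100 * prop, 1),
                                  lo, hi, boundary=True)
    eta = np.log(count / (total - count))
    se = np.sqrt(1.0 / count + 1.0 / (total - count))
    lo = float(special.expit(eta - _Z95 * se))
    hi = float(special.expit(eta + _Z95 * se))
    return ProportionEstimate(count, total, prop, round(100 * prop, 1), lo, hi)


def outcome_proportions(counts: OutcomeCounts) -> dict[str, ProportionEstimate]:
    """Visit-outcome fractions and infection rate among emerged whitefly."""
    return {
        "died": _proportion_estimate(counts.died, counts.visited),
        "parasitoid_emerged": _proportion_estimate(
            counts.parasitoid_emerged, counts.visited),
        "whitefly_emerged": _proportion_estimate(
            counts.whitefly_emerged, counts.visited),
        "infected": _proportion_estimate(
            counts.infected_of_emerged, counts.whitefly_emerged),
    }


def logit_prevalence_fit(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group prevalence on the proportion scale via logit-scale estimation.

    Counts are pooled across replicates within each group; the point
    estimate back-transforms to the raw pooled proportion exactly, while the
    interval is symmetric on the logit scale and hence asymmetric on the
    proportion scale.  Boundary groups (0 or 100% infected) are flagged and
    given exact intervals.
    """
    validate_count_table(table)
    rows = []
    for group, sub in table.groupby("group", sort=True):
        est = _proportion_estimate(int(sub["infected"].sum()), int(sub["total"].sum()))
        rows.append({
            "group": group, "infected": est.count, "total": est.total,
            "estimate": est.proportion, "percent": est.percent,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "boundary": est.boundary,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binomial random-intercept likelihood (adaptive Gauss-Hermite, 15 nodes)

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(15)


def _binom_ll_terms(y, n, eta):
    """Binomial log-likelihood without the constant binomial coefficient."""
    return y * eta - n * np.logaddexp(0.0, eta)


def _glmm_marginal_ll(eta_fixed: np.ndarray, y: np.ndarray, n: np.ndarray,
                      rep_idx: np.ndarray, n_reps: int, sigma: float) -> float:
    """Marginal log-likelihood of y ~ Bin(n, expit(eta_fixed + u_rep)),
    u_rep ~ N(0, sigma^2), integrated per replicate by adaptive quadrature.
    """
    if sigma < 1e-8:
        return float(np.sum(_binom_ll_terms(y, n, eta_fixed)))

    # Laplace mode per replicate by vectorised Newton iterations
    u = np.zeros(n_reps)
    for _ in range(25):
        eta = eta_fixed + u[rep_idx]
        pi = special.expit(eta)
        grad = np.bincount(rep_idx, weights=y - n * pi, minlength=n_reps) - u / sigma**2
        hess = -np.bincount(rep_idx, weights=n * pi * (1 - pi), minlength=n_reps) \
            - 1.0 / sigma**2
        delta = grad / hess
        u = u - delta
        if np.max(np.abs(delta)) < 1e-10:
            break
    eta = eta_fixed + u[rep_idx]
    pi = special.expit(eta)
    curv = np.bincount(rep_idx, weights=n * pi * (1 - pi), minlength=n_reps) \
        + 1.0 / sigma**2
    scale = 1.0 / np.sqrt(curv)

    # u-values at quadrature points: shape (n_reps, n_nodes)
    pts = u[:, None] + np.sqrt(2.0) * scale[:, None] * _GH_NODES[None, :]
    ll_pts = np.zeros_like(pts)
    for j in range(pts.shape[1]):
        terms = _binom_ll_terms(y, n, eta_fixed + pts[rep_idx, j])
        ll_pts[:, j] = np.bincount(rep_idx, weights=terms, minlength=n_reps)
    log_integrand = ll_pts - pts**2 / (2.0 * sigma**2) + _GH_NODES[None, :] ** 2
    log_int = special.logsumexp(log_integrand, b=_GH_WEIGHTS[None, :], axis=1)
    log_int += np.log(np.sqrt(2.0) * scale) - 0.5 * np.log(2.0 * np.pi) - np.log(sigma)
    return float(np.sum(log_int))


def _fit_glmm(y, n, group_idx, n_groups, rep_idx, n_reps, pooled: bool):
    """Maximise the random-intercept binomial likelihood.

    ``pooled=True`` fits a single probability; otherwise one per group.
    Returns (max log-likelihood, sigma_hat).
    """
    k = 1 if pooled else n_groups
    p0 = np.clip(np.sum(y) / np.sum(n), 1e-6, 1 - 1e-6)
    x0 = np.concatenate([np.full(k, special.logit(p0)), [0.1]])

    def negll(theta):
        eta_fixed = theta[0] * np.ones_like(y, dtype=float) if pooled \
            else theta[group_idx]
        return -_glmm_marginal_ll(eta_fixed, y, n, rep_idx, n_reps,
                                  abs(theta[-1]))

    bounds = [(-15.0, 15.0)] * k + [(0.0, 5.0)]
    res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
    # restart from the boundary in case sigma wandered
    if res.x[-1] > 1e-6:
        x0b = res.x.copy()
        x0b[-1] = 0.0
        res_b = optimize.minimize(negll, x0b, method="L-BFGS-B", bounds=bounds)
        if res_b.fun < res.fun:
            res = res_b
    return -float(res.fun), float(res.x[-1])


def lrt_heterogeneity(table: pd.DataFrame, grouping: str = "group") -> TestResult:
    """Likelihood-ratio test for heterogeneity of prevalence across groups.

    Compares a per-group-probability binomial model against a
    common-probability model, both with a replicate-level random intercept
    integrated by adaptive Gauss–Hermite quadrature (15 nodes).  When the
    random-effect variance estimates to zero in both models the statistic
    equals the closed-form fixed-effects likelihood-ratio (G) statistic.
    df = number of groups - 1; p from the chi-square upper tail.
    """
    table = validate_count_table(
        table.rename(columns={grouping: "group"}) if grouping != "group" else table
    )
    groups = np.sort(table["group"].unique())
    if len(groups) < 2:
        raise ValueError("lrt_heterogeneity requires at least 2 groups")
    y = table["infected"].to_numpy(float)
    n = table["total"].to_numpy(float)
    group_idx = np.searchsorted(groups, table["group"].to_numpy())
    reps = np.sort(table["replicate"].unique())
    rep_idx = np.searchsorted(reps, table["replicate"].to_numpy())

    ll_alt, sig_alt = _fit_glmm(y, n, group_idx, len(groups), rep_idx, len(reps),
                                pooled=False)
    ll_null, sig_null = _fit_glmm(y, n, group_idx, len(groups), rep_idx, len(reps),
                                  pooled=True)
    stat = max(2.0 * (ll_alt - ll_null), 0.0)
    df = len(groups) - 1
    flags = ()
    if sig_alt < 1e-6 and sig_null < 1e-6:
        flags = ("random_intercept_variance_zero",)
    return TestResult(
        statistic=stat, statistic_kind="chi_square", df=df,
        p_value=float(sps.chi2.sf(stat, df)), flags=flags,
    )


# ---------------------------------------------------------------------------
# logistic trend (binomial GLM, IRLS)

def logistic_trend(table: pd.DataFrame, grouping: str = "group") -> TestResult:
    """Binomial regression of infected/total on a quantitative covariate.

    Fits logit(p) = a + b * x by iteratively reweighted least squares
    (statsmodels GLM) where x is the ``grouping`` column (e.g. hours since
    wasp contamination) and reports the Wald z for the slope b.  Complete or
    quasi-complete separation is flagged instead of returning a spurious z.
    """
    import statsmodels.api as sm

    table = validate_count_table(
        table.rename(columns={grouping: "group"}) if grouping != "group" else table
    )
    x = table["group"].to_numpy(float)
    if len(np.unique(x)) < 2:
        raise ValueError("logistic_trend requires >= 2 distinct covariate values")
    endog = np.column_stack([
        table["infected"].to_numpy(float),
        (table["total"] - table["infected"]).to_numpy(float),
    ])
    exog = sm.add_constant(x)

    flags: tuple[str, ...] = ()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(tol=1e-8)
        except Exception:
            return TestResult(statistic=float("nan"), statistic_kind="z", df=None,
                              p_value=float("nan"), flags=("separation",))
    slope, se = float(fit.params[1]), float(fit.bse[1])
    fitted = fit.fittedvalues
    if se > 1e3 or abs(slope) > 50 or np.all((fitted > 1 - 1e-8) | (fitted < 1e-8)):
        flags = ("separation",)
    z = slope / se if se > 0 else float("nan")
    return TestResult(
        statistic=z, statistic_kind="z", df=None,
        p_value=float(2.0 * sps.norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
        estimate=slope, se=se, flags=flags,
    )


# ---------------------------------------------------------------------------
# fitness comparisons

def _replicate_means_t(pairs: pd.DataFrame, trait: str) -> TestResult:
    """Two-sample t on per-replicate cage means.

    For the balanced design with a replicate random intercept this is the
    exact mixed-model test of the arm effect, with df = total replicates - 2.
    """
    means = pairs.groupby(["arm", "replicate"])[trait].mean()
    a = means.loc["infected"].to_numpy()
    b = means.loc["uninfected"].to_numpy()
    df = len(a) + len(b) - 2
    diff = float(a.mean() - b.mean())
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    se = float(np.sqrt(sp2 * (1.0 / len(a) + 1.0 / len(b))))
    t = diff / se if se > 0 else 0.0
    return TestResult(statistic=t, statistic_kind="t", df=df,
                      p_value=float(2.0 * sps.t.sf(abs(t), df)),
                      estimate=diff, se=se)


def _overdispersed_binomial_z(y: np.ndarray, n: np.ndarray,
                              arm: np.ndarray) -> TestResult:
    """Quasi-binomial Wald z for an arm effect, scale from the Pearson statistic."""
    import statsmodels.api as sm

    exog = sm.add_constant(arm.astype(float))
    endog = np.column_stack([y, n - y])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(scale="X2")
    slope, se = float(fit.params[1]), float(fit.bse[1])
    z = slope / se if se > 0 else 0.0
    return TestResult(statistic=z, statistic_kind="z", df=None,
                      p_value=float(2.0 * sps.norm.sf(abs(z))),
                      estimate=slope, se=se)


def _cox_stratified_breslow(time: np.ndarray, x: np.ndarray,
                            strata: np.ndarray) -> TestResult:
    """Stratified Cox partial likelihood for one binary covariate, Breslow ties.

    All subjects are events (no censoring in the longevity experiment).
    Newton-Raphson on the scalar log hazard ratio; Wald z from the observed
    information.
    """
    beta = 0.0
    for _ in range(50):
        grad, hess = 0.0, 0.0
        for s in np.unique(strata):
            mask = strata == s
            t_s, x_s = time[mask], x[mask]
            order = np.argsort(-t_s)  # longest-lived first: risk sets by suffix
            t_s, x_s = t_s[order], x_s[order]
            exb = np.exp(beta * x_s)
            s0 = np.cumsum(exb)
            s1 = np.cumsum(x_s * exb)
            s2 = np.cumsum(x_s**2 * exb)
            # Breslow: at tied event times every tied event uses the full
            # risk set (all with time >= t), i.e. the last cumsum index of
            # the tie block
            uniq, inv = np.unique(-t_s, return_inverse=True)
            last_idx = np.zeros(len(uniq), dtype=int)
            np.maximum.at(last_idx, inv, np.arange(len(t_s)))
            idx = last_idx[inv]
            r0, r1, r2 = s0[idx], s1[idx], s2[idx]
            grad += float(np.sum(x_s - r1 / r0))
            hess += float(np.sum(r2 / r0 - (r1 / r0) ** 2))
        if hess <= 0:
            break
        delta = grad / hess
        beta += delta
        if abs(delta) < 1e-12:
            break
    se = 1.0 / np.sqrt(hess) if hess > 0 else float("nan")
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    return TestResult(statistic=z, statistic_kind="z", df=None,
                      p_value=float(2.0 * sps.norm.sf(abs(z))),
                      estimate=beta, se=se)


def fitness_compare(data: FitnessDataset) -> dict[str, TestResult]:
    """Arm comparisons for every fitness trait.

    development_time, fecundity : replicate-means t-test (df = cages - 2).
    immature_survival, sex_ratio : over-dispersed binomial Wald z.
    longevity : Cox partial likelihood stratified by replicate index
        (pairing the contemporaneous cages of the two arms), Breslow ties.
    """
    pairs = data.pairs
    arm01 = (pairs["arm"] == "infected").to_numpy()

    results = {
        "development_time": _replicate_means_t(pairs, "development_time"),
        "fecundity": _replicate_means_t(pairs, "fecundity"),
        "immature_survival": _overdispersed_binomial_z(
            pairs["immature_survived"].to_numpy(float),
            pairs["immature_total"].to_numpy(float),
            arm01,
        ),
        "longevity": _cox_stratified_breslow(
            pairs["longevity"].to_numpy(float),
            arm01.astype(float),
            pairs["replicate"].to_numpy(),
        ),
    }
    if data.sex is not None:
        results["sex_ratio"] = _overdispersed_binomial_z(
            data.sex["n_female"].to_numpy(float),
            (data.sex["n_female"] + data.sex["n_male"]).to_numpy(float),
            (data.sex["arm"] == "infected").to_numpy(),
        )
    return results


def results_to_frame(results: dict[str, TestResult]) -> pd.DataFrame:
    """Tidy table of TestResults (one row per trait/test)."""
    rows = []
    for name, r in results.items():
        rows.append({
            "test": name, "statistic": r.statistic, "kind": r.statistic_kind,
            "df": r.df, "p_value": r.p_value, "estimate": r.estimate,
            "se": r.se, "flags": ";".join(r.flags),
        })
    return pd.DataFrame(rows)
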