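"""Paired multivariate and longitudinal tests on shape scores.

Two hypotheses drive the inference stage of the pipeline:

1. Did overall facial shape change between the first and last visit?
   Tested with a paired Hotelling's T² on the leading PC scores.  With n
   pairs and p dimensions, T² = n d̄ᵀ S⁻¹ d̄ (S the sample covariance of the
   paired differences) and F = (n−p)/(p(n−1)) · T² ~ F(p, n−p) under the
   null.  Small cohorts cap p: with 14 pairs at most 13 dimensions can be
   tested, giving the characteristic F(13, 1) reference distribution.

2. Does the phenotype score drift over treatment time?  Tested with a
   linear mixed model: score ~ protocol + time + protocol:time with a
   random intercept per individual, fitted by maximum likelihood; the time
   effect is assessed by a likelihood-ratio χ² (df = 1) against the same
   model with the time main effect deleted.  Per-term LRTs for protocol
   and the interaction are reported the same way.

The random-intercept ML fit is computed with a profiled likelihood: for a
fixed variance ratio θ = σ²_subject/σ²_resid the GLS coefficients and the
residual variance have closed forms (the per-subject blocks of V = I + θZZᵀ
invert analytically), leaving a one-dimensional optimization over θ.  This
makes a fit cost microseconds, which the simulation-based calibration
checks rely on; agreement with statsmodels' MixedLM is verified in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import (
    DegreesOfFreedomError,
    InsufficientDataError,
    ShapeMismatchError,
    SingularCovarianceError,
    SingularDesignError,
)

_LMM_TERMS = ("intercept", "protocol", "time", "protocol:time")


@dataclass
class HotellingResult:
    t2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n_pairs: int
    n_dims: int

    def as_dict(self) -> dict:
        return {
            "t2": self.t2, "f_stat": self.f_stat, "df1": self.df1,
            "df2": self.df2, "p_value": self.p_value,
            "n_pairs": self.n_pairs, "n_dims": self.n_dims,
        }


@dataclass
class LmmResult:
    """Mixed-model fit of score on treatment time.

    ``beta_time`` is in score units per year; the LRT fields refer to the
    time main effect.  Protocol and interaction terms carry their own
    single-term-deletion LRTs.
    """

    beta_intercept: float
    beta_protocol: float
    beta_time: float
    beta_interaction: float
    se_time: float
    random_intercept_var: float
    residual_var: float
    llf: float
    lrt_chisq: float
    lrt_df: int
    p_value: float
    protocol_chisq: float
    protocol_p: float
    interaction_chisq: float
    interaction_p: float
    n_subjects: int
    n_observations: int
    ols_fallback: bool = False

    def as_dict(self) -> dict:
        return {
            "beta_time": self.beta_time,
            "beta_protocol": self.beta_protocol,
            "beta_interaction": self.beta_interaction,
            "se_time": self.se_time,
            "random_intercept_var": self.random_intercept_var,
            "residual_var": self.residual_var,
            "lrt_chisq": self.lrt_chisq,
            "lrt_df": self.lrt_df,
            "p_value": self.p_value,
            "protocol_chisq": self.protocol_chisq,
            "protocol_p": self.protocol_p,
            "interaction_chisq": self.interaction_chisq,
            "interaction_p": self.interaction_p,
            "n_subjects": self.n_subjects,
            "n_observations": self.n_observations,
            "ols_fallback": self.ols_fallback,
        }

    def summary(self) -> str:
        """Human-readable report in the conventional χ²/df/p/β style."""
        return (
            f"score ~ protocol + time + protocol:time + (1 | individual), "
            f"ML, {self.n_subjects} subjects / {self.n_observations} obs\n"
            f"  time:          chi2 = {self.lrt_chisq:.3g}, df = {self.lrt_df}, "
            f"p = {self.p_value:.4g}, beta = {self.beta_time:.4g}\n"
            f"  protocol:      chi2 = {self.protocol_chisq:.3g}, "
            f"p = {self.protocol_p:.4g}\n"
            f"  protocol:time: chi2 = {self.interaction_chisq:.3g}, "
            f"p = {self.interaction_p:.4g}"
        )


@dataclass
class AgeRegressionResult:
    slope: float
    intercept: float
    t_stat: float
    p_value: float
    n: int


def paired_hotelling(first_scores, last_scores, n_dims: int | None = None) -> HotellingResult:
    """Paired Hotelling's T² on the first ``n_dims`` PC axes.

    ``first_scores`` and ``last_scores`` are (n, >= n_dims) arrays of PC
    scores for the same n individuals at two visits.
    """
    first = np.atleast_2d(np.asarray(first_scores, dtype=float))
    last = np.atleast_2d(np.asarray(last_scores, dtype=float))
    if first.shape != last.shape:
        raise ShapeMismatchError(
            f"paired score shapes differ: {first.shape} vs {last.shape}"
        )
    n, p_avail = first.shape
    if n_dims is None:
        n_dims = p_avail
    if n_dims < 1 or n_dims > p_avail:
        raise ValueError(f"n_dims must be in [1, {p_avail}], got {n_dims}")
    if n <= n_dims:
        raise DegreesOfFreedomError(
            f"need n_pairs > n_dims for the F transform; "
            f"got {n} pairs, {n_dims} dims"
        )
    d = (last - first)[:, :n_dims]
    if not np.any(d):
        return HotellingResult(0.0, 0.0, n_dims, n - n_dims, 1.0, n, n_dims)
    dbar = d.mean(axis=0)
    s_mat = np.atleast_2d(np.cov(d, rowvar=False, ddof=1))
    try:
        sol = np.linalg.solve(s_mat, dbar)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "difference covariance is singular; reduce n_dims"
        ) from exc
    t2 = float(n * dbar @ sol)
    if not np.isfinite(t2) or t2 < 0:
        raise SingularCovarianceError(
            "difference covariance is numerically singular; reduce n_dims"
        )
    df1, df2 = n_dims, n - n_dims
    f_stat = t2 * df2 / (df1 * (n - 1))
    p = float(stats.f.sf(f_stat, df1, df2))
    return HotellingResult(t2, float(f_stat), df1, df2, p, n, n_dims)


# ---------------------------------------------------------------------------
# random-intercept linear mixed model (profiled maximum likelihood)
# ---------------------------------------------------------------------------

def _group_sums(x, y, codes, n_groups):
    p = x.shape[1]
    sx = np.zeros((n_groups, p))
    sy = np.zeros(n_groups)
    np.add.at(sx, codes, x)
    np.add.at(sy, codes, y)
    ng = np.bincount(codes, minlength=n_groups).astype(float)
    return sx, sy, ng


def _profile_fit(theta, xtx, xty, yty, sx, sy, ng, n):
    """GLS fit and profile log-likelihood at a fixed variance ratio theta."""
    c = theta / (1.0 + theta * ng)
    a = xtx - (sx * c[:, None]).T @ sx
    b = xty - (c * sy) @ sx
    beta = np.linalg.solve(a, b)
    quad = yty - c @ sy**2 - beta @ b
    # relative floor keeps degenerate (zero-residual) fits finite and stable
    quad = max(quad, 1e-14 * (yty + 1.0))
    sigma2 = quad / n
    logdet = np.log1p(theta * ng).sum()
    llf = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return llf, beta, a, sigma2


def _fit_random_intercept_ml(x, y, codes):
    """ML fit of y = X beta + b_subject + e with b ~ N(0, tau2) i.i.d.

    Returns (beta, cov_beta, tau2, sigma2, llf).
    """
    n = len(y)
    n_groups = int(codes.max()) + 1
    xtx = x.T @ x
    xty = x.T @ y
    yty = float(y @ y)
    sx, sy, ng = _group_sums(x, y, codes, n_groups)

    def nll(log_theta):
        llf, *_ = _profile_fit(np.exp(log_theta), xtx, xty, yty, sx, sy, ng, n)
        return -llf

    res = optimize.minimize_scalar(
        nll, bounds=(-25.0, 15.0), method="bounded",
        options={"xatol": 1e-10},
    )
    theta_hat = float(np.exp(res.x))
    llf_opt = -float(res.fun)
    llf_zero, *_ = _profile_fit(0.0, xtx, xty, yty, sx, sy, ng, n)
    if llf_zero >= llf_opt:
        theta_hat = 0.0
    llf, beta, a, sigma2 = _profile_fit(
        theta_hat, xtx, xty, yty, sx, sy, ng, n
    )
    if not np.isfinite(llf):
        raise SingularDesignError("mixed-model likelihood is not finite")
    cov_beta = sigma2 * np.linalg.inv(a)
    return beta, cov_beta, theta_hat * sigma2, sigma2, float(llf)


def _encode_protocol(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "bifu":
        return arr.astype(float)
    levels = sorted(pd.unique(arr))
    if len(levels) > 2:
        raise ValueError(f"protocol has {len(levels)} levels; expected <= 2")
    return (arr == levels[-1]).astype(float)


def fit_score_lmm(
    score_table: pd.DataFrame,
    score_col: str = "normalized_score",
    time_col: str = "years_from_first_dose",
    protocol_col: str = "protocol",
    subject_col: str = "subject_id",
    test: str = "time",
) -> LmmResult:
    """Longitudinal mixed model of phenotype score in the treated group.

    Fixed effects: treatment protocol (0 = drug throughout, 1 = placebo
    first), years from first dose (negative values for pre-dose placebo
    scans are retained), and their interaction.  Random effect: an
    intercept per individual.  All fits by maximum likelihood; the time
    effect is tested by likelihood-ratio χ² with df = 1 (``test="time"``,
    single-term deletion of the main effect) or df = 2
    (``test="time_and_interaction"``, deleting main effect and interaction
    together).

    When no subject has repeated observations the random intercept is
    unidentifiable; the model falls back to OLS (θ pinned at 0) and flags
    ``ols_fallback``.
    """
    df = score_table
    for col in (score_col, time_col, protocol_col, subject_col):
        if col not in df.columns:
            raise ValueError(f"score table lacks required column '{col}'")
    if test not in ("time", "time_and_interaction"):
        raise ValueError(f"unknown test {test!r}")
    y = df[score_col].to_numpy(dtype=float)
    time = df[time_col].to_numpy(dtype=float)
    protocol = _encode_protocol(df[protocol_col])
    codes, uniques = pd.factorize(df[subject_col])
    codes = np.asarray(codes)
    n_subjects = len(uniques)
    if n_subjects < 2:
        raise InsufficientDataError("mixed model needs >= 2 subjects")
    max_obs = np.bincount(codes).max()
    ols_fallback = bool(max_obs < 2)
    x = np.column_stack([np.ones_like(y), protocol, time, protocol * time])

    def _fit(cols):
        xs = x[:, cols]
        if ols_fallback:
            llf0, beta, a, sigma2 = _profile_fit(
                0.0,
                xs.T @ xs,
                xs.T @ y,
                float(y @ y),
                *_group_sums(xs, y, codes, n_subjects),
                len(y),
            )
            cov = sigma2 * np.linalg.inv(a)
            return beta, cov, 0.0, sigma2, float(llf0)
        return _fit_random_intercept_ml(xs, y, codes)

    full_cols = [0, 1, 2, 3]
    beta, cov_beta, tau2, sigma2, llf_full = _fit(full_cols)

    def _lrt(drop_cols):
        cols = [c for c in full_cols if c not in drop_cols]
        *_, llf_reduced = _fit(cols)
        chisq = max(2.0 * (llf_full - llf_reduced), 0.0)
        dof = len(drop_cols)
        return chisq, dof, float(stats.chi2.sf(chisq, dof))

    if test == "time":
        lrt_chisq, lrt_df, p = _lrt([2])
    else:
        lrt_chisq, lrt_df, p = _lrt([2, 3])
    protocol_chisq, _, protocol_p = _lrt([1])
    interaction_chisq, _, interaction_p = _lrt([3])

    return LmmResult(
        beta_intercept=float(beta[0]),
        beta_protocol=float(beta[1]),
        beta_time=float(beta[2]),
        beta_interaction=float(beta[3]),
        se_time=float(np.sqrt(cov_beta[2, 2])),
        random_intercept_var=float(tau2),
        residual_var=float(sigma2),
        llf=llf_full,
        lrt_chisq=float(lrt_chisq),
        lrt_df=int(lrt_df),
        p_value=float(p),
        protocol_chisq=float(protocol_chisq),
        protocol_p=float(protocol_p),
        interaction_chisq=float(interaction_chisq),
        interaction_p=float(interaction_p),
        n_subjects=n_subjects,
        n_observations=len(y),
        ols_fallback=ols_fallback,
    )


def control_age_regression(scores, ages) -> AgeRegressionResult:
    """OLS of score on age in the untreated control group."""
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(scores) < 3:
        raise InsufficientDataError("age regression needs >= 3 points")
    if np.ptp(ages) == 0:
        raise SingularDesignError("ages are constant", column="age")
    fit = sm.OLS(scores, sm.add_constant(ages)).fit()
    return AgeRegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        t_stat=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        n=len(scores),
    )
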