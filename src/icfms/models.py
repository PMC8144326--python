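"""Validity checks: random-intercept logit and ordered logit models.

The grading scheme is validated by regressing (a) the 3-year death
indicator on covariates with a cluster-level random intercept (logit link)
and (b) the five-level disability grade on the same covariates with a
random-intercept proportional-odds model.  Both models are fitted by
maximum likelihood, integrating the Gaussian random intercept with
adaptive Gauss-Hermite quadrature (15 nodes by default): each cluster's
integrand is re-centred at its posterior mode and rescaled by the local
curvature before applying the quadrature rule.

When no grouping variable is given the models reduce to ordinary
fixed-effects fits (numerically identical to statsmodels ``Logit`` /
``OrderedModel``, which serve as the cross-check in the test suite).  The
fixed fit is also the null model of the likelihood-ratio test for the
random intercept, whose null distribution is the boundary mixture
0.5 chi2_0 + 0.5 chi2_1.

Parameterization of the ordered model: latent ``x @ beta + u + logistic
noise`` against strictly increasing thresholds, so positive coefficients
mean better function (a higher grade); thresholds are estimated as
(first threshold, log-differences) and reported with delta-method
standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2, norm
from statsmodels.tools.numdiff import approx_hess3

from .exceptions import EstimationError, ValidationError

DEFAULT_PREDICTORS: tuple[str, ...] = ("male", "urban", "widowed")
N_QUAD_NODES: int = 15


@dataclass(frozen=True)
class LogitSpec:
    """What to regress on what, and how to cluster the random intercept."""

    outcome: str
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    grouping: str | None = None
    age_stratum: str | None = None


@dataclass
class FitResult:
    """Estimates, uncertainty and fit statistics of one model."""

    kind: str  # "logit" | "ordered_logit"
    params: pd.Series
    bse: pd.Series
    thresholds: np.ndarray | None = None
    threshold_bse: np.ndarray | None = None
    sigma2_u: float = 0.0
    lnsig2u: float | None = None
    lnsig2u_se: float | None = None
    loglik: float = np.nan
    loglik_fixed: float | None = None
    lr_stat: float | None = None
    lr_pvalue: float | None = None
    n_obs: int = 0
    n_groups: int | None = None
    converged: bool = True
    stratum: str | None = None

    def __post_init__(self) -> None:
        if self.thresholds is not None:
            t = np.asarray(self.thresholds, dtype=float)
            if not np.all(np.diff(t) > 0):
                raise EstimationError("estimated thresholds are not increasing")
        if self.lr_stat is not None and self.lr_stat < -1e-8:
            raise EstimationError("negative LR statistic")


# -- quadrature machinery -----------------------------------------------------


def _ghq_loglik(
    obs_ll,
    obs_dll,
    groups: np.ndarray,
    n_groups: int,
    sigma: float,
    nodes: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Marginal log-likelihood with an N(0, sigma^2) cluster intercept.

    ``obs_ll(u_obs)`` / ``obs_dll(u_obs)`` return the per-observation
    conditional log-likelihood and its derivative in the intercept, given
    per-observation intercept values.  Adaptive: Newton mode-finding per
    cluster, then Gauss-Hermite around the mode.
    """
    s2 = sigma * sigma
    m = np.zeros(n_groups)

    def grad(mvec: np.ndarray) -> np.ndarray:
        per_obs = obs_dll(mvec[groups])
        return np.bincount(groups, weights=per_obs, minlength=n_groups) - mvec / s2

    h = 1e-4
    curv = np.full(n_groups, -1.0 / s2)
    for _ in range(40):
        g = grad(m)
        curv = (grad(m + h) - grad(m - h)) / (2 * h)
        curv = np.minimum(curv, -1e-10)
        step = np.clip(g / curv, -4.0, 4.0)
        m = m - step
        if np.max(np.abs(g)) < 1e-9:
            break
    sd = 1.0 / np.sqrt(-curv)

    A = np.empty((len(nodes), n_groups))
    sqrt2 = np.sqrt(2.0)
    for k, (z, w) in enumerate(zip(nodes, weights)):
        u = m + sqrt2 * sd * z
        hval = (
            np.bincount(groups, weights=obs_ll(u[groups]), minlength=n_groups)
            + norm.logpdf(u, 0.0, sigma)
        )
        A[k] = np.log(w) + z * z + hval
    ll = np.log(sqrt2 * sd) + logsumexp(A, axis=0)
    return float(ll.sum())


def _binary_obs_fns(eta: np.ndarray, y: np.ndarray):
    def obs_ll(u: np.ndarray) -> np.ndarray:
        lin = eta + u
        return y * lin - np.logaddexp(0.0, lin)

    def obs_dll(u: np.ndarray) -> np.ndarray:
        return y - expit(eta + u)

    return obs_ll, obs_dll


def _ordinal_obs_fns(eta: np.ndarray, y: np.ndarray, cuts: np.ndarray):
    # cuts extended with +-inf; y in 1..K
    lo = cuts[y - 1]
    hi = cuts[y]

    def _probs(u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = lo - eta - u
        b = hi - eta - u
        Fa = expit(a)
        Fb = expit(b)
        return Fa, Fb, np.clip(Fb - Fa, 1e-300, None)

    def obs_ll(u: np.ndarray) -> np.ndarray:
        _, _, p = _probs(u)
        return np.log(p)

    def obs_dll(u: np.ndarray) -> np.ndarray:
        Fa, Fb, p = _probs(u)
        fa = np.where(np.isfinite(lo), Fa * (1 - Fa), 0.0)
        fb = np.where(np.isfinite(hi), Fb * (1 - Fb), 0.0)
        return -(fb - fa) / p

    return obs_ll, obs_dll


# -- likelihoods --------------------------------------------------------------


def _binary_nll(theta, X, y, groups, n_groups, nodes, weights, sigma_fixed):
    p = X.shape[1]
    beta = theta[:p]
    eta = X @ beta
    sigma = (
        sigma_fixed if sigma_fixed is not None else np.exp(0.5 * theta[p])
    )
    if sigma == 0.0 or groups is None:
        return -(float(np.sum(y * eta - np.logaddexp(0.0, eta))))
    obs_ll, obs_dll = _binary_obs_fns(eta, y)
    return -_ghq_loglik(obs_ll, obs_dll, groups, n_groups, sigma, nodes, weights)


def _unpack_thresholds(raw: np.ndarray) -> np.ndarray:
    """(a1, log d2, ..., log dK-1) -> strictly increasing thresholds."""
    return np.concatenate([[raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))])


def _threshold_jacobian(raw: np.ndarray) -> np.ndarray:
    k = len(raw)
    J = np.zeros((k, k))
    J[:, 0] = 1.0
    for j in range(1, k):
        J[j:, j] = np.exp(raw[j])
    return J


def _ordinal_nll(theta, X, y, n_levels, groups, n_groups, nodes, weights, sigma_fixed):
    p = X.shape[1]
    beta = theta[:p]
    raw = theta[p : p + n_levels - 1]
    kappa = _unpack_thresholds(raw)
    cuts = np.concatenate([[-np.inf], kappa, [np.inf]])
    eta = X @ beta if p else np.zeros(len(y))
    sigma = (
        sigma_fixed
        if sigma_fixed is not None
        else np.exp(0.5 * theta[p + n_levels - 1])
    )
    obs_ll, obs_dll = _ordinal_obs_fns(eta, y, cuts)
    if sigma == 0.0 or groups is None:
        return -float(np.sum(obs_ll(np.zeros(len(y)))))
    return -_ghq_loglik(obs_ll, obs_dll, groups, n_groups, sigma, nodes, weights)


def _optimize(nll, x0):
    res = minimize(nll, x0, method="BFGS", options={"maxiter": 1000, "gtol": 1e-6})
    if not np.all(np.isfinite(res.x)):
        raise EstimationError("optimizer diverged (possible separation)")
    H = approx_hess3(res.x, nll)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return res, cov


# -- data preparation ---------------------------------------------------------


def _design(panel: pd.DataFrame, spec: LogitSpec, add_const: bool):
    df = panel
    if spec.age_stratum is not None:
        df = df[df["age_group"] == spec.age_stratum]
    df = df.dropna(subset=[spec.outcome, *spec.predictors])
    if df.empty:
        raise ValidationError("no complete observations for this model")
    y = df[spec.outcome].to_numpy()
    X = df[list(spec.predictors)].to_numpy(dtype=float)
    names = list(spec.predictors)
    if add_const:
        X = np.column_stack([np.ones(len(df)), X])
        names = ["const", *names]
    groups = None
    n_groups = None
    if spec.grouping is not None:
        codes, uniques = pd.factorize(df[spec.grouping])
        groups, n_groups = codes, len(uniques)
        if n_groups < 2:
            raise ValidationError("need >= 2 clusters for a random intercept")
        sizes = np.bincount(codes)
        if (sizes == 1).any():
            warnings.warn(
                f"{int((sizes == 1).sum())} singleton cluster(s); the random "
                "intercept is weakly identified",
                stacklevel=3,
            )
    return df, y, X, names, groups, n_groups


# -- public fitters -----------------------------------------------------------


def fit_death_logit(panel: pd.DataFrame, spec: LogitSpec) -> FitResult:
    """Random-intercept (or plain) logit for the 3-year death indicator."""
    df, y, X, names, groups, n_groups = _design(panel, spec, add_const=True)
    y = y.astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("death outcome must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome has no variation")

    nodes, weights = hermgauss(N_QUAD_NODES)

    def plain_nll(theta):
        return _binary_nll(theta, X, y, None, None, nodes, weights, 0.0)

    x0 = np.zeros(X.shape[1])
    res_fixed, cov_fixed = _optimize(plain_nll, x0)
    if np.max(np.abs(res_fixed.x)) > 30:
        raise EstimationError(
            "coefficients diverged: data are (quasi-)separated; drop the "
            "offending predictor or use a penalized fit"
        )
    ll_fixed = -res_fixed.fun

    if groups is None:
        return FitResult(
            kind="logit",
            params=pd.Series(res_fixed.x, index=names),
            bse=pd.Series(np.sqrt(np.diag(cov_fixed)), index=names),
            loglik=ll_fixed,
            n_obs=len(y),
            converged=bool(res_fixed.success),
            stratum=spec.age_stratum,
        )

    def mixed_nll(theta):
        return _binary_nll(theta, X, y, groups, n_groups, nodes, weights, None)

    x0 = np.concatenate([res_fixed.x, [np.log(0.5)]])
    res, cov = _optimize(mixed_nll, x0)
    se = np.sqrt(np.abs(np.diag(cov)))
    ll = -res.fun
    lr = max(0.0, 2.0 * (ll - ll_fixed))
    lnsig2u = res.x[-1]
    return FitResult(
        kind="logit",
        params=pd.Series(res.x[:-1], index=names),
        bse=pd.Series(se[:-1], index=names),
        sigma2_u=float(np.exp(lnsig2u)),
        lnsig2u=float(lnsig2u),
        lnsig2u_se=float(se[-1]),
        loglik=ll,
        loglik_fixed=ll_fixed,
        lr_stat=lr,
        lr_pvalue=float(0.5 * chi2.sf(lr, 1)),
        n_obs=len(y),
        n_groups=n_groups,
        converged=bool(res.success),
        stratum=spec.age_stratum,
    )


def fit_grade_ologit(
    panel: pd.DataFrame, spec: LogitSpec, levels: Sequence[int] = (1, 2, 3, 4, 5)
) -> FitResult:
    """Random-intercept (or plain) proportional-odds model for the grade."""
    df, y, X_const, names_const, groups, n_groups = _design(
        panel, spec, add_const=True
    )
    # ordered model: no intercept (absorbed by the thresholds)
    X = X_const[:, 1:]
    names = names_const[1:]
    y = y.astype(int)
    observed = set(np.unique(y))
    missing = sorted(set(levels) - observed)
    if missing:
        raise ValidationError(
            f"outcome level(s) {missing} unobserved; refusing to collapse "
            "categories — supply `levels` explicitly if intended"
        )
    if observed - set(levels):
        raise ValidationError(f"unexpected outcome values {observed - set(levels)}")
    n_levels = len(levels)
    # recode to 1..K
    level_pos = {lv: i + 1 for i, lv in enumerate(sorted(levels))}
    yk = np.asarray([level_pos[v] for v in y])

    nodes, weights = hermgauss(N_QUAD_NODES)

    # starting thresholds: logits of the cumulative outcome frequencies
    cumfreq = np.cumsum(np.bincount(yk, minlength=n_levels + 1)[1:])[:-1] / len(yk)
    kappa0 = np.log(cumfreq) - np.log1p(-cumfreq)
    raw0 = np.concatenate([[kappa0[0]], np.log(np.diff(kappa0))])

    def plain_nll(theta):
        return _ordinal_nll(theta, X, yk, n_levels, None, None, nodes, weights, 0.0)

    x0 = np.concatenate([np.zeros(X.shape[1]), raw0])
    res_fixed, cov_fixed = _optimize(plain_nll, x0)
    ll_fixed = -res_fixed.fun

    def _result(res, cov, mixed: bool) -> FitResult:
        p = X.shape[1]
        se = np.sqrt(np.abs(np.diag(cov)))
        raw = res.x[p : p + n_levels - 1]
        kappa = _unpack_thresholds(raw)
        J = _threshold_jacobian(raw)
        cov_raw = cov[p : p + n_levels - 1, p : p + n_levels - 1]
        kappa_se = np.sqrt(np.abs(np.diag(J @ cov_raw @ J.T)))
        kwargs = {}
        if mixed:
            ll = -res.fun
            lr = max(0.0, 2.0 * (ll - ll_fixed))
            kwargs = dict(
                sigma2_u=float(np.exp(res.x[-1])),
                lnsig2u=float(res.x[-1]),
                lnsig2u_se=float(se[-1]),
                loglik_fixed=ll_fixed,
                lr_stat=lr,
                lr_pvalue=float(0.5 * chi2.sf(lr, 1)),
                n_groups=n_groups,
            )
        return FitResult(
            kind="ordered_logit",
            params=pd.Series(res.x[:p], index=names),
            bse=pd.Series(se[:p], index=names),
            thresholds=kappa,
            threshold_bse=kappa_se,
            loglik=-res.fun,
            n_obs=len(yk),
            converged=bool(res.success),
            stratum=spec.age_stratum,
            **kwargs,
        )

    if groups is None:
        return _result(res_fixed, cov_fixed, mixed=False)

    def mixed_nll(theta):
        return _ordinal_nll(
            theta, X, yk, n_levels, groups, n_groups, nodes, weights, None
        )

    x0 = np.concatenate([res_fixed.x, [np.log(0.5)]])
    res, cov = _optimize(mixed_nll, x0)
    return _result(res, cov, mixed=True)


# -- pair-level data preparation and reporting --------------------------------


def prepare_validation_data(graded_panel: pd.DataFrame) -> pd.DataFrame:
    """One row per subject pair: baseline covariates/grade, wave-2 outcome."""
    from .transitions import _pair_panel

    pairs = _pair_panel(graded_panel)
    out = pd.DataFrame(
        {
            "subject_id": pairs["subject_id"],
            "age_group": pairs["age_group"],
            "male": pairs["male"],
            "urban": pairs["urban"],
            "widowed": pairs["widowed"],
            "grade_baseline": pairs["grade"],
            "dead": pairs["dead_2"],
            "grade": pairs["grade_2"],
        }
    )
    return out.dropna(subset=["dead"]).reset_index(drop=True)


_STARS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


def _star(coef: float, se: float) -> str:
    if se <= 0 or not np.isfinite(se):
        return ""
    p = 2 * norm.sf(abs(coef) / se)
    for cut, s in _STARS:
        if p < cut:
            return s
    return ""


def model_report(results: Mapping[str, FitResult]) -> str:
    """Side-by-side text table of fits (SEs in parentheses, stars at
    0.1 / 0.05 / 0.01)."""
    names = list(results)
    rows: list[str] = []
    width = 22

    def line(label: str, cells: list[str]) -> None:
        rows.append(f"{label:<24}" + "".join(f"{c:>{width}}" for c in cells))

    line("", names)
    all_params = []
    for r in results.values():
        for k in r.params.index:
            if k not in all_params:
                all_params.append(k)
    for param in all_params:
        coefs, ses = [], []
        for r in results.values():
            if param in r.params.index:
                c, s = r.params[param], r.bse[param]
                coefs.append(f"{c:.3f}{_star(c, s)}")
                ses.append(f"({s:.3f})")
            else:
                coefs.append("")
                ses.append("")
        line(param, coefs)
        line("", ses)
    n_thr = max(
        (len(r.thresholds) for r in results.values() if r.thresholds is not None),
        default=0,
    )
    for t in range(n_thr):
        cells, ses = [], []
        for r in results.values():
            if r.thresholds is not None and t < len(r.thresholds):
                cells.append(f"{r.thresholds[t]:.3f}{_star(r.thresholds[t], r.threshold_bse[t])}")
                ses.append(f"({r.threshold_bse[t]:.3f})")
            else:
                cells.append("")
                ses.append("")
        line(f"Threshold parameter {t + 1}", cells)
        line("", ses)
    if any(r.lnsig2u is not None for r in results.values()):
        line(
            "/lnsig2u",
            [
                f"{r.lnsig2u:.3f}" if r.lnsig2u is not None else ""
                for r in results.values()
            ],
        )
        line(
            "sigma2_u",
            [f"{r.sigma2_u:.3f}" if r.lnsig2u is not None else "" for r in results.values()],
        )
    line("Log likelihood", [f"{r.loglik:.4f}" for r in results.values()])
    line(
        "LR test",
        [
            f"{r.lr_stat:.2f} (p = {r.lr_pvalue:.2f})" if r.lr_stat is not None else ""
            for r in results.values()
        ],
    )
    line("Observations", [str(r.n_obs) for r in results.values()])
    rows.append("* p < 0.1, ** p < 0.05, *** p < 0.01")
    return "\n".join(rows)
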