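"""Normative growth-curve fitting for effective-connectome metrics.

The model for a metric y of subject i at transformed age t is

    y_i(t) = f1(t) + f2(t) * sex_i + a_i + b_site(i) + e_i(t)

with t = log2(age + 1), sex coded +1 (male) / -1 (female), cubic-spline
smooths f1 (main age effect) and f2 (age-by-sex interaction), and
Gaussian random intercepts for subject and acquisition site.  Smooths
use a cubic B-spline basis with an integrated-squared-second-derivative
penalty; the penalty's null space (constant and linear trends, and
their sex interactions) enters as fixed effects, and the penalized
range space is reparameterized to iid random effects, so the whole
model is a variance-components mixed model estimated by restricted
maximum likelihood (REML).  The basis dimension k is selected by
fitting k = 5..14 and keeping the lowest BIC.

The fitted object carries the joint coefficient posterior (point
estimate and covariance conditional on the variance components), which
downstream peak-age bootstrapping resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from lifespan_ec.synth import inverse_transform_age, transform_age

logger = logging.getLogger("lifespan_ec.trajectory")

DEFAULT_GRID_SIZE = 512


# ---------------------------------------------------------------------------
# Spline basis with curvature penalty
# ---------------------------------------------------------------------------


@dataclass
class CubicSplineBasis:
    """Cubic B-spline basis of dimension k on [t_min, t_max]."""

    k: int
    t_min: float
    t_max: float
    knots: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.k < 5:
            raise ValueError("basis dimension must be at least 5")
        if not self.t_max > self.t_min:
            raise ValueError("degenerate t range")
        n_interior = self.k - 4
        interior = np.linspace(self.t_min, self.t_max, n_interior + 2)[1:-1]
        self.knots = np.concatenate(
            [np.repeat(self.t_min, 4), interior, np.repeat(self.t_max, 4)]
        )

    def design(self, t: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(t, dtype=float), self.t_min, self.t_max)
        return BSpline.design_matrix(t, self.knots, 3).toarray()

    def penalty(self) -> np.ndarray:
        """Gram matrix of second derivatives, S_ij = int B_i'' B_j'' dt.

        Second derivatives of cubic B-splines are piecewise linear, so
        two-point Gauss-Legendre per inter-knot interval is exact.
        """
        S = np.zeros((self.k, self.k))
        breaks = np.unique(self.knots)
        gauss_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        coefs = np.eye(self.k)
        splines = [BSpline(self.knots, coefs[i], 3) for i in range(self.k)]
        d2 = [s.derivative(2) for s in splines]
        for a, b in zip(breaks[:-1], breaks[1:]):
            half = 0.5 * (b - a)
            mid = 0.5 * (a + b)
            for gx in gauss_x:
                x = mid + half * gx
                vals = np.array([f(x) for f in d2])
                S += half * np.outer(vals, vals)
        return S


def _reparameterize(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split the penalty into null-space (fixed) and whitened range space.

    Returns (U0, Up_scaled): basis coefficients beta = U0 a + Up_scaled b
    give penalty ||b||^2; a (dimension 2: constant + linear) is
    unpenalized.
    """
    lam, U = np.linalg.eigh(S)
    null_dim = 2
    U0 = U[:, :null_dim]
    lam_pos = lam[null_dim:]
    Up = U[:, null_dim:] / np.sqrt(lam_pos)
    return U0, Up


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


def _reml_neg_loglik(rho, y, X, grams, rho_bounds):
    """-2 * restricted log-likelihood at log-variances rho.

    rho[:-1] are component log-variances (one per Gram matrix), rho[-1]
    is the residual log-variance.  Components are kept inside
    ``rho_bounds`` (relative to the data variance) with a smooth
    quadratic penalty: the restricted likelihood of a near-saturated
    variance component (e.g. a 2-level site factor) has a flat upper
    tail along which the intercept split becomes indeterminate.
    """
    n, p = X.shape
    lo, hi = rho_bounds
    excess = np.maximum(rho - hi, 0.0) + np.maximum(lo - rho, 0.0)
    barrier = 1e4 * float(excess @ excess)
    rho = np.clip(rho, lo, hi)
    sig = np.exp(rho)
    V = sig[-1] * np.eye(n)
    for s2, G in zip(sig[:-1], grams):
        V += s2 * G
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return 1e10
    logdet_V = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_y = cho_solve(cf, y)
    Vi_X = cho_solve(cf, X)
    XtViX = X.T @ Vi_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e10
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    ytPy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    return logdet_V + logdet_XtViX + ytPy + (n - p) * np.log(2 * np.pi) + barrier


def _ml_loglik(sig, y, X, grams):
    """Marginal (ML) log-likelihood at variance components sig."""
    n = len(y)
    V = sig[-1] * np.eye(n)
    for s2, G in zip(sig[:-1], grams):
        V += s2 * G
    cf = cho_factor(V, lower=True)
    logdet_V = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_y = cho_solve(cf, y)
    Vi_X = cho_solve(cf, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    resid = y - X @ beta
    quad = float(resid @ cho_solve(cf, resid))
    return -0.5 * (logdet_V + quad + n * np.log(2 * np.pi))


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryFit:
    """Penalized-spline mixed-model fit of one metric's age trajectory."""

    k: int
    basis: CubicSplineBasis
    U0: np.ndarray
    Up: np.ndarray
    coef: np.ndarray                  # full coefficient vector (posterior mean)
    coef_cov: np.ndarray              # joint posterior covariance
    variance_components: dict
    bic: float
    edf: float
    log_lik: float
    n_obs: int
    t_range: tuple[float, float]
    has_sex_smooth: bool
    subject_levels: tuple
    site_levels: tuple
    grid_size: int = DEFAULT_GRID_SIZE

    # -- column layout -------------------------------------------------
    # [f1 null (2)] [f2 null (2)?] [f1 range (k-2)] [f2 range (k-2)?]
    # [subject intercepts] [site intercepts]

    @property
    def _n_null(self) -> int:
        return 2 + (2 if self.has_sex_smooth else 0)

    @property
    def _n_range(self) -> int:
        return self.k - 2

    def _curve_columns(self, t: np.ndarray, sex_value: float) -> np.ndarray:
        """Design columns of the fixed+smooth part at ages t and given sex."""
        B = self.basis.design(t)
        X0 = B @ self.U0
        Z1 = B @ self.Up
        blocks = [X0]
        if self.has_sex_smooth:
            blocks.append(sex_value * X0)
        blocks.append(Z1)
        if self.has_sex_smooth:
            blocks.append(sex_value * Z1)
        return np.hstack(blocks)

    @property
    def n_curve_coefs(self) -> int:
        return self._n_null + self._n_range * (2 if self.has_sex_smooth else 1)

    def age_smooth_indices(self) -> np.ndarray:
        """Indices of the coefficients that shape the sex-0 (age-only) curve."""
        idx = [0, 1]
        start_range = self._n_null
        idx.extend(range(start_range, start_range + self._n_range))
        return np.array(idx)

    def default_grid(self) -> np.ndarray:
        return np.linspace(self.t_range[0], self.t_range[1], self.grid_size)

    def predict(
        self,
        grid_t: np.ndarray | None = None,
        sex_value: float = 0.0,
        alpha: float = 0.05,
    ) -> pd.DataFrame:
        """Fixed-effect curve with standard errors and normal-quantile CI.

        Random intercepts are set to 0; CI = y_pred +/- qnorm(1-alpha/2)
        * y_se.  Grid points outside the fitted age range are flagged as
        extrapolation.
        """
        if grid_t is None:
            grid_t = self.default_grid()
        grid_t = np.asarray(grid_t, dtype=float)
        extrapolated = (grid_t < self.t_range[0]) | (grid_t > self.t_range[1])
        if extrapolated.any():
            logger.warning("%d grid points extrapolate beyond the fitted age range",
                           int(extrapolated.sum()))
        C = self._curve_columns(grid_t, sex_value)
        nc = self.n_curve_coefs
        theta = self.coef[:nc]
        cov = self.coef_cov[:nc, :nc]
        y_pred = C @ theta
        y_se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, cov, C), 0.0))
        q = norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {
                "t": grid_t,
                "age": inverse_transform_age(grid_t),
                "y_pred": y_pred,
                "y_se": y_se,
                "ci_low": y_pred - q * y_se,
                "ci_high": y_pred + q * y_se,
                "sex": sex_value,
                "extrapolated": extrapolated,
            }
        )

    def sample_age_curves(
        self, n_draws: int, rng: np.random.Generator, grid_t: np.ndarray | None = None
    ) -> np.ndarray:
        """Draw sex-0 curves from the age-smooth coefficient posterior.

        Returns an (n_draws, len(grid)) array; each row is the curve
        rebuilt from one multivariate-normal draw of the age-smooth
        coefficients (null + range parts of f1).
        """
        if grid_t is None:
            grid_t = self.default_grid()
        idx = self.age_smooth_indices()
        mean = self.coef[idx]
        cov = self.coef_cov[np.ix_(idx, idx)]
        draws = rng.multivariate_normal(mean, cov, size=n_draws, method="cholesky")
        B = self.basis.design(np.asarray(grid_t, dtype=float))
        C = np.hstack([B @ self.U0, B @ self.Up])
        return draws @ C.T


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _prepare(samples: pd.DataFrame) -> pd.DataFrame:
    df = samples.copy()
    if "t" not in df.columns:
        df["t"] = transform_age(df["age"].to_numpy(dtype=float))
    if not np.all(np.isfinite(df["value"])):
        raise ValueError("non-finite metric values")
    return df


def fit_trajectory_k(
    samples: pd.DataFrame,
    k: int,
    include_sex_smooth: bool = True,
    grid_size: int = DEFAULT_GRID_SIZE,
    reml_maxiter: int = 400,
) -> TrajectoryFit:
    """Fit the mixed model at a fixed basis dimension k."""
    df = _prepare(samples)
    y = df["value"].to_numpy(dtype=float)
    t = df["t"].to_numpy(dtype=float)
    sex = df["sex"].to_numpy(dtype=float) if "sex" in df.columns else np.zeros(len(df))
    n = len(y)
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct ages")
    has_sex = include_sex_smooth and len(np.unique(sex)) > 1
    if include_sex_smooth and not has_sex:
        logger.info("single sex present; age-by-sex smooth dropped")

    basis = CubicSplineBasis(k=k, t_min=float(t.min()), t_max=float(t.max()))
    B = basis.design(t)
    U0, Up = _reparameterize(basis.penalty())
    X0 = B @ U0
    Z1 = B @ Up

    X_blocks = [X0] + ([sex[:, None] * X0] if has_sex else [])
    X = np.hstack(X_blocks)

    rand_designs: list[np.ndarray] = [Z1]
    if has_sex:
        rand_designs.append(sex[:, None] * Z1)

    subjects = tuple(pd.unique(df["subject_id"])) if "subject_id" in df.columns else ()
    if len(subjects) > 1 and len(subjects) < n:
        Zs = pd.get_dummies(df["subject_id"]).reindex(columns=list(subjects)).to_numpy(float)
        rand_designs.append(Zs)
        use_subject = True
    else:
        use_subject = False
        if subjects:
            logger.info("subject random intercept dropped (no repeated structure)")
    sites = tuple(pd.unique(df["site"])) if "site" in df.columns else ()
    if len(sites) > 1:
        Zb = pd.get_dummies(df["site"]).reindex(columns=list(sites)).to_numpy(float)
        rand_designs.append(Zb)
        use_site = True
    else:
        use_site = False

    grams = [Z @ Z.T for Z in rand_designs]

    var_y = float(np.var(y)) or 1.0
    rho_bounds = (np.log(var_y) - 18.0, np.log(var_y) + 4.0)
    x0 = np.log(np.full(len(grams) + 1, var_y / (len(grams) + 1.0)))
    res = optimize.minimize(
        _reml_neg_loglik, x0, args=(y, X, grams, rho_bounds), method="Powell",
        bounds=[rho_bounds] * len(x0),
        options={"maxiter": reml_maxiter, "xtol": 1e-6},
    )
    sig = np.exp(np.clip(res.x, *rho_bounds))
    if not np.isfinite(res.fun) or res.fun >= 1e10:
        raise RuntimeError(f"REML failed at k={k}")

    # joint coefficient posterior given the variance components
    M = np.hstack([X] + rand_designs)
    p_fixed = X.shape[1]
    block_sizes = [Z.shape[1] for Z in rand_designs]

    def _coef_solve(sig_vec):
        prec_diag = np.concatenate(
            [np.zeros(p_fixed)]
            + [np.full(m, 1.0 / sig_vec[c]) for c, m in enumerate(block_sizes)]
        )
        P = M.T @ M / sig_vec[-1] + np.diag(prec_diag)
        P += 1e-10 * np.mean(np.diag(P)) * np.eye(P.shape[0])
        cf = cho_factor(P, lower=True)
        coef = cho_solve(cf, M.T @ y / sig_vec[-1])
        return coef, cf, P

    sigma_e = sig[-1]
    coef, cf, P = _coef_solve(sig)
    cov = cho_solve(cf, np.eye(P.shape[0]))
    cov = 0.5 * (cov + cov.T)

    # propagate smoothing/variance-parameter uncertainty into the
    # coefficient covariance: the conditional posterior understates the
    # width of functionals such as the peak age, so the covariance of
    # the REML log-variances (inverse Hessian of the restricted
    # deviance) is pushed through the coefficient solution numerically
    rho_hat = np.log(sig)
    n_rho = len(rho_hat)
    h = 0.05
    try:
        H = np.zeros((n_rho, n_rho))
        f0 = _reml_neg_loglik(rho_hat, y, X, grams, rho_bounds)
        for a in range(n_rho):
            for b in range(a, n_rho):
                ea, eb = np.eye(n_rho)[a] * h, np.eye(n_rho)[b] * h
                if a == b:
                    fp = _reml_neg_loglik(rho_hat + ea, y, X, grams, rho_bounds)
                    fm = _reml_neg_loglik(rho_hat - ea, y, X, grams, rho_bounds)
                    H[a, a] = (fp - 2 * f0 + fm) / h**2
                else:
                    fpp = _reml_neg_loglik(rho_hat + ea + eb, y, X, grams, rho_bounds)
                    fpm = _reml_neg_loglik(rho_hat + ea - eb, y, X, grams, rho_bounds)
                    fmp = _reml_neg_loglik(rho_hat - ea + eb, y, X, grams, rho_bounds)
                    fmm = _reml_neg_loglik(rho_hat - ea - eb, y, X, grams, rho_bounds)
                    H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4 * h**2)
        lam_H, vec_H = np.linalg.eigh(0.5 * H)  # Hessian of -l_R
        # floor flat directions: a near-unidentified log-variance is
        # assigned at most O(1) uncertainty instead of an unbounded one
        lam_H = np.maximum(lam_H, 0.5)
        cov_rho = vec_H @ np.diag(1.0 / lam_H) @ vec_H.T
        J = np.empty((len(coef), n_rho))
        for a in range(n_rho):
            sp = np.exp(rho_hat + np.eye(n_rho)[a] * h)
            sm = np.exp(rho_hat - np.eye(n_rho)[a] * h)
            cp, _, _ = _coef_solve(sp)
            cm, _, _ = _coef_solve(sm)
            J[:, a] = (cp - cm) / (2 * h)
        cov = cov + J @ cov_rho @ J.T
        cov = 0.5 * (cov + cov.T)
    except np.linalg.LinAlgError:
        logger.warning("hyperparameter-uncertainty correction skipped (singular Hessian)")

    # effective degrees of freedom of the fixed + smooth part
    n_smooth_cols = p_fixed + sum(Z.shape[1] for Z in rand_designs[: (2 if has_sex else 1)])
    hat_diag_block = (cov @ (M.T @ M) / sigma_e).diagonal()
    edf = float(hat_diag_block[:n_smooth_cols].sum())

    # BIC in the gamm4/lme4 convention: marginal ML deviance with one
    # parameter per fixed coefficient and per variance component (the
    # smooths contribute their null-space fixed effects plus a single
    # variance each), so k selection compares marginal likelihoods.
    ll = _ml_loglik(sig, y, X, grams)
    n_vc = len(sig)
    bic = -2.0 * ll + (p_fixed + n_vc) * np.log(n)

    names = ["f1_smooth"] + (["f2_smooth"] if has_sex else [])
    if use_subject:
        names.append("subject")
    if use_site:
        names.append("site")
    variance_components = dict(zip(names + ["residual"], sig))

    return TrajectoryFit(
        k=k, basis=basis, U0=U0, Up=Up, coef=coef, coef_cov=cov,
        variance_components=variance_components, bic=float(bic), edf=edf,
        log_lik=float(ll), n_obs=n, t_range=(float(t.min()), float(t.max())),
        has_sex_smooth=has_sex,
        subject_levels=subjects if use_subject else (),
        site_levels=sites if use_site else (),
        grid_size=grid_size,
    )


def fit_trajectory(
    samples: pd.DataFrame,
    k_range: range | tuple = range(5, 15),
    include_sex_smooth: bool = True,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> TrajectoryFit:
    """Fit the growth model for each k and return the lowest-BIC winner.

    Singular or failed fits at individual k are skipped with a warning;
    if every k fails, the error propagates.
    """
    best: TrajectoryFit | None = None
    errors: list[str] = []
    for k in k_range:
        try:
            fit = fit_trajectory_k(
                samples, k, include_sex_smooth=include_sex_smooth, grid_size=grid_size
            )
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("k=%d skipped: %s", k, exc)
            errors.append(f"k={k}: {exc}")
            continue
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise RuntimeError("trajectory fit failed for every k: " + "; ".join(errors))
    return best


def fit_nodal_trajectories(
    nodal: pd.DataFrame,
    value_column: str = "ecs",
    k_range: range | tuple = range(5, 15),
    grid_size: int = DEFAULT_GRID_SIZE,
    grid_t: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Fit one growth curve per region; return (curves, grid).

    ``nodal`` is the long per-region ECS table (columns region, age, sex,
    subject_id, site and the value column).  Returns a regions x grid
    DataFrame of sex-0 fitted values on a shared transformed-age grid.
    """
    regions = list(pd.unique(nodal["region"]))
    t_all = transform_age(nodal["age"].to_numpy(dtype=float))
    if grid_t is None:
        grid_t = np.linspace(t_all.min(), t_all.max(), grid_size)
    curves = {}
    for region in regions:
        sub = nodal[nodal["region"] == region].rename(columns={value_column: "value"})
        fit = fit_trajectory(sub[["value", "age", "sex", "subject_id", "site"]],
                             k_range=k_range, grid_size=grid_size)
        curves[region] = fit.predict(grid_t)["y_pred"].to_numpy()
    tm = pd.DataFrame(curves, index=grid_t).T
    return tm, np.asarray(grid_t)
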