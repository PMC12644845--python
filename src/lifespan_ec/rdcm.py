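"""Regression DCM: whole-brain effective connectivity from BOLD series.

Linear DCM (dx/dt = Ax + Cu) is moved to the frequency domain, where the
differential property of the DFT turns the coupled ODE into one multiple
linear regression per target region: the DFT of the temporal derivative
of a region's BOLD signal is regressed on the DFTs of all regions'
signals (and, when experimental inputs exist, on HRF-filtered input
spectra).  Each regression is inverted with conjugate Gaussian-Gamma
mean-field variational Bayes under a partial-independence assumption
across target regions, so the full R x R coupling matrix is assembled
row by row.

Sign convention: estimated entry (i, j) is the influence of source j on
target i; positive couplings are excitatory, negative inhibitory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from lifespan_ec.io import BoldRun, ECMatrix, Parcellation

logger = logging.getLogger("lifespan_ec.rdcm")


# ---------------------------------------------------------------------------
# Hemodynamic response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HrfKernel:
    """Canonical double-gamma HRF sampled at TR resolution."""

    samples: np.ndarray
    tr: float
    unit_sum: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("HRF kernel contains non-finite values")

    def __len__(self) -> int:
        return len(self.samples)


def canonical_hrf(
    tr: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
    unit_sum: bool = False,
) -> HrfKernel:
    """Double-gamma hemodynamic response sampled every ``tr`` seconds.

    Each lobe is a gamma density parameterized by the time of its mode
    (``peak_delay``/``undershoot_delay``, seconds) and a dispersion
    (gamma scale); the undershoot is subtracted with weight
    ``undershoot_ratio``.  With the defaults the kernel peaks at ~6 s.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    if duration < 16.0:
        raise ValueError("HRF duration must be at least 16 s")
    t = np.arange(0.0, duration, tr)

    def gamma_pdf_mode(x: np.ndarray, mode: float, disp: float) -> np.ndarray:
        # gamma density with shape chosen so the mode sits at `mode`
        shape = 1.0 + mode / disp
        logpdf = (
            (shape - 1.0) * np.log(np.maximum(x, 1e-300))
            - x / disp
            - shape * np.log(disp)
            - gammaln(shape)
        )
        out = np.exp(logpdf)
        out[x <= 0] = 0.0
        return out

    h = gamma_pdf_mode(t, peak_delay, peak_dispersion)
    if undershoot_ratio > 0:
        h = h - undershoot_ratio * gamma_pdf_mode(t, undershoot_delay, undershoot_dispersion)
    if unit_sum:
        s = h.sum()
        if s != 0:
            h = h / s
    return HrfKernel(samples=h, tr=tr, unit_sum=unit_sum)


# ---------------------------------------------------------------------------
# Frequency-domain GLM
# ---------------------------------------------------------------------------


@dataclass
class FrequencyDesign:
    """Per-region dependent vectors and the shared regressor matrix.

    Complex rows are expanded into stacked real and imaginary rows, so
    ``Y`` and ``X`` are real with ``2 * len(bins)`` rows.  Column order
    of ``X``: the R region spectra, then K HRF-filtered input spectra.
    """

    Y: np.ndarray            # (2*n_bins, R) stacked real/imag dependent vectors
    X: np.ndarray            # (2*n_bins, R + K) stacked real/imag regressors
    bins: np.ndarray         # retained DFT frequency indices m
    n_timepoints: int
    sampling_interval: float
    n_regions: int
    n_inputs: int = 0


def build_frequency_glm(
    run: BoldRun,
    hrf: HrfKernel | None = None,
    inputs: np.ndarray | None = None,
    nyquist_fraction: float = 1.0,
) -> FrequencyDesign:
    """Assemble the frequency-domain regression for one scan.

    The series is mean-centered per region, DFT'd, and the dependent
    vector for region i is ``(exp(2*pi*1j*m/N) - 1) * yhat_i / T`` — the
    discrete difference operator standing in for the time derivative.
    The DC bin is always dropped; bins above ``nyquist_fraction`` of the
    Nyquist index are dropped as well (the default keeps the full band:
    no low-pass).
    """
    series = run.series - run.series.mean(axis=0, keepdims=True)
    n, r = series.shape
    t_int = run.tr
    yhat = np.fft.fft(series, axis=0)

    m_max = int(np.floor(nyquist_fraction * (n // 2)))
    bins = np.arange(1, m_max + 1)
    if len(bins) < 2:
        raise ValueError("fewer than 2 frequency bins retained; series too short")

    z = (np.exp(2j * np.pi * bins / n) - 1.0) / t_int  # difference operator
    y_sel = yhat[bins, :]
    Y_c = z[:, None] * y_sel
    X_cols = [y_sel]
    k = 0
    if inputs is not None:
        if hrf is None:
            raise ValueError("inputs require an HRF kernel")
        u = np.atleast_2d(np.asarray(inputs, dtype=float))
        if u.shape[0] == n:
            u = u.T  # accept T x K
        k = u.shape[0]
        h_pad = np.zeros(n)
        h_pad[: min(len(hrf.samples), n)] = hrf.samples[:n]
        h_hat = np.fft.fft(h_pad)
        u_hat = np.fft.fft(u, axis=1)  # K x N
        X_cols.append((h_hat[bins] * u_hat[:, bins]).T)
    X_c = np.hstack(X_cols)

    Y = np.vstack([Y_c.real, Y_c.imag])
    X = np.vstack([X_c.real, X_c.imag])
    return FrequencyDesign(
        Y=Y, X=X, bins=bins, n_timepoints=n, sampling_interval=t_int,
        n_regions=r, n_inputs=k,
    )


# ---------------------------------------------------------------------------
# Variational Bayes linear regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionPosterior:
    """Gaussian-Gamma mean-field posterior for one target region."""

    mean: np.ndarray
    covariance: np.ndarray
    noise_shape: float
    noise_rate: float
    free_energy: float
    free_energy_trace: np.ndarray
    iterations: int
    converged: bool

    @property
    def noise_precision_mean(self) -> float:
        return self.noise_shape / self.noise_rate


def vb_linear_regression(
    y: np.ndarray,
    X: np.ndarray,
    prior_mean: np.ndarray,
    prior_precision: np.ndarray,
    noise_shape: float = 2.0,
    noise_rate: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 500,
    fixed_noise_precision: float | None = None,
) -> RegressionPosterior:
    """Mean-field VB for Bayesian linear regression.

    Model: y = X theta + v, v ~ N(0, tau^{-1} I), theta ~ N(m0, L0^{-1}),
    tau ~ Gamma(a0, b0).  The conjugate coordinate updates are iterated
    until the relative change in the negative free energy falls below
    ``tol``.  With ``fixed_noise_precision`` the Gamma factor is frozen
    (degenerate), which reduces the posterior mean to the closed-form
    ridge/Gaussian solution and serves as an analytic oracle hook.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    m0 = np.asarray(prior_mean, dtype=float).ravel()
    L0 = np.asarray(prior_precision, dtype=float)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    L0m0 = L0 @ m0

    sign, logdet_L0 = np.linalg.slogdet(L0)
    if sign <= 0:
        raise ValueError("prior precision must be positive definite")

    a0, b0 = noise_shape, noise_rate
    if fixed_noise_precision is not None:
        e_tau = float(fixed_noise_precision)
    else:
        e_tau = a0 / b0
    a = a0 + n / 2.0

    fe_trace: list[float] = []
    fe_prev = -np.inf
    converged = False
    mu = m0.copy()
    sigma = np.linalg.inv(L0)
    b = b0
    it = 0
    for it in range(1, max_iter + 1):
        # q(theta) update
        prec = e_tau * XtX + L0
        sigma = np.linalg.inv(prec)
        sigma = 0.5 * (sigma + sigma.T)
        mu = sigma @ (e_tau * Xty + L0m0)

        expected_sse = yty - 2.0 * mu @ Xty + mu @ XtX @ mu + np.sum(XtX * sigma)
        if fixed_noise_precision is None:
            # q(tau) update
            b = b0 + 0.5 * expected_sse
            e_tau = a / b
            e_ln_tau = digamma(a) - np.log(b)
        else:
            e_ln_tau = np.log(e_tau)

        # negative free energy (evidence lower bound)
        diff = mu - m0
        fe = (
            0.5 * n * (e_ln_tau - np.log(2 * np.pi))
            - 0.5 * e_tau * expected_sse
            + 0.5 * logdet_L0
            - 0.5 * p * np.log(2 * np.pi)
            - 0.5 * (np.sum(L0 * sigma) + diff @ L0 @ diff)
            + 0.5 * np.linalg.slogdet(sigma)[1]
            + 0.5 * p * (1.0 + np.log(2 * np.pi))
        )
        if fixed_noise_precision is None:
            fe += (
                a0 * np.log(b0) - gammaln(a0) + (a0 - 1.0) * e_ln_tau - b0 * e_tau
                + gammaln(a) - (a - 1.0) * digamma(a) - np.log(b) + a
            )
        fe_trace.append(fe)
        if np.isfinite(fe_prev) and abs(fe - fe_prev) <= tol * max(1.0, abs(fe_prev)):
            converged = True
            break
        fe_prev = fe

    if not converged:
        logger.warning("VB regression did not converge in %d iterations", max_iter)
    return RegressionPosterior(
        mean=mu,
        covariance=sigma,
        noise_shape=a if fixed_noise_precision is None else np.inf,
        noise_rate=b if fixed_noise_precision is None else np.inf,
        free_energy=fe_trace[-1],
        free_energy_trace=np.array(fe_trace),
        iterations=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Whole-matrix estimation
# ---------------------------------------------------------------------------


@dataclass
class RdcmConfig:
    """Priors, frequency policy, and convergence controls for rDCM."""

    prior_offdiag_mean: float = 0.0
    prior_offdiag_var: float = 1.0
    prior_self_mean: float = -1.0
    prior_self_var: float = 1.0
    prior_input_mean: float = 0.0
    prior_input_var: float = 1.0
    noise_shape: float = 2.0
    noise_rate: float = 1.0
    nyquist_fraction: float = 1.0
    tol: float = 1e-8
    max_iter: int = 500


@dataclass
class RegionSummary:
    region: str
    converged: bool
    iterations: int
    free_energy: float
    noise_precision_mean: float


def region_priors(
    region_index: int, n_regions: int, n_inputs: int, config: RdcmConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Prior mean vector and (diagonal) precision for one target region.

    Off-diagonal couplings are shrunk to zero; the self connection has a
    negative prior expectation encoding self-decay/stability.
    """
    p = n_regions + n_inputs
    mean = np.full(p, config.prior_offdiag_mean)
    var = np.full(p, config.prior_offdiag_var)
    mean[region_index] = config.prior_self_mean
    var[region_index] = config.prior_self_var
    if n_inputs:
        mean[n_regions:] = config.prior_input_mean
        var[n_regions:] = config.prior_input_var
    return mean, np.diag(1.0 / var)


def estimate_ec(
    run: BoldRun,
    parcellation: Parcellation | None = None,
    config: RdcmConfig | None = None,
    hrf: HrfKernel | None = None,
    inputs: np.ndarray | None = None,
) -> tuple[ECMatrix, list[RegionSummary], np.ndarray | None]:
    """Estimate the full directed EC matrix for one scan.

    One independent VB regression per target region (the regressions
    share the design matrix and are order-independent).  Returns the
    assembled EC matrix, per-region convergence summaries, and — when
    inputs are present — the estimated R x K input-weight matrix C.
    """
    config = config or RdcmConfig()
    region_ids = (
        parcellation.region_ids
        if parcellation is not None
        else (run.region_ids or tuple(f"R{i + 1}" for i in range(run.n_regions)))
    )
    if parcellation is not None and run.n_regions != parcellation.n_regions:
        raise ValueError("run/parcellation region count mismatch")

    design = build_frequency_glm(
        run, hrf=hrf, inputs=inputs, nyquist_fraction=config.nyquist_fraction
    )
    r, k = design.n_regions, design.n_inputs
    A = np.zeros((r, r))
    C = np.zeros((r, k)) if k else None
    summaries: list[RegionSummary] = []
    for i in range(r):
        mean0, prec0 = region_priors(i, r, k, config)
        post = vb_linear_regression(
            design.Y[:, i],
            design.X,
            prior_mean=mean0,
            prior_precision=prec0,
            noise_shape=config.noise_shape,
            noise_rate=config.noise_rate,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        A[i, :] = post.mean[:r]
        if k:
            C[i, :] = post.mean[r:]
        if not post.converged:
            logger.warning("region %s: VB not converged", region_ids[i])
        summaries.append(
            RegionSummary(
                region=region_ids[i],
                converged=post.converged,
                iterations=post.iterations,
                free_energy=post.free_energy,
                noise_precision_mean=post.noise_precision_mean,
            )
        )
    return ECMatrix(values=A, region_ids=tuple(region_ids)), summaries, C
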