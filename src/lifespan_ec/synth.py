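"""Synthetic lifespan cohorts with planted effective-connectivity truth.

The generator plants smooth lifespan trajectories on the edges of a
directed coupling matrix (inverted-U for excitatory edges, U-shaped for
inhibitory ones, in transformed age t = log2(age + 1)), adds sex, site,
and subject effects, and simulates BOLD from the linear DCM forward
model (Euler-Maruyama integration of dx/dt = Ax + u with white driving
noise, convolution with the canonical HRF, decimation to TR, and white
observation noise at a stated SNR).  Every downstream stage — rDCM,
metrics, growth curves, peaks, clustering, gradient — is thereby
testable against known ground truth without any data download.

The cohort age structure emulates a lifespan study assembled from four
sub-studies: an infancy cohort with longitudinal repeats, a development
cohort (8-22 y), a young-adult cohort (22-37 y), and an aging cohort
(36-100 y); each sub-study is a distinct acquisition site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from lifespan_ec.io import (
    BoldRun,
    CohortManifest,
    Parcellation,
    write_bold_series,
    write_manifest,
)
from lifespan_ec.rdcm import HrfKernel, canonical_hrf


def transform_age(age):
    """Transformed age t = log2(age + 1)."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    return np.log2(age + 1.0)


def inverse_transform_age(t):
    return np.exp2(np.asarray(t, dtype=float)) - 1.0


# ---------------------------------------------------------------------------
# Planted edge trajectories
# ---------------------------------------------------------------------------


@dataclass
class EdgeTrajectorySpec:
    """Parameters of one edge's smooth lifespan curve.

    The curve (in t = log2(age+1)) is a difference of logistics with the
    inflection offsets solved so the maximum sits exactly at
    ``transform_age(peak_age)``, plus an optional early-life Gaussian dip.
    ``sign`` fixes the edge as excitatory (+1) or inhibitory (-1) over
    the whole lifespan; for inhibitory edges the planted curve describes
    the magnitude, so the signed value is U-shaped.
    """

    baseline: float = 0.2
    amplitude: float = 0.2
    peak_age: float = 9.0
    rise_rate: float = 2.0
    fall_rate: float = 0.8
    early_dip_depth: float = 0.0
    early_dip_age: float = 0.7
    early_dip_width: float = 0.35
    sign: int = 1
    sex_effect: float = 0.0
    site_offsets: dict = field(default_factory=dict)
    subject_sd: float = 0.0
    residual_sd: float = 0.0
    rise_offset: float = 1.0  # delta1: distance (in t) from rise inflection to peak

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError("edge sign must be +1 or -1")

    def _offsets(self) -> tuple[float, float]:
        """Inflection offsets (delta1, delta2) placing the peak at peak_age."""
        r, s, d1 = self.rise_rate, self.fall_rate, self.rise_offset
        target = r * _dlogistic(r * d1)
        if target >= s / 4.0:
            # rise too steep relative to fall at this offset; push the rise
            # inflection further from the peak until a solution exists
            while target >= s / 4.0:
                d1 *= 1.5
                target = r * _dlogistic(r * d1)
        d2 = brentq(lambda d: s * _dlogistic(s * d) - target, 0.0, 500.0 / s)
        return d1, d2

    def bump(self, t) -> np.ndarray:
        """Unit-peak difference-of-logistics shape; maximum 1 at the peak."""
        t = np.asarray(t, dtype=float)
        tp = float(transform_age(self.peak_age))
        d1, d2 = self._offsets()
        g = expit(self.rise_rate * (t - (tp - d1))) - expit(self.fall_rate * (t - (tp + d2)))
        g_peak = expit(self.rise_rate * d1) - expit(-self.fall_rate * d2)
        return g / g_peak

    def curve(self, age) -> np.ndarray:
        """Noiseless signed edge value at chronological ``age`` (years)."""
        t = transform_age(age)
        value = self.baseline + self.amplitude * self.bump(t)
        if self.early_dip_depth:
            value = value - self.early_dip_depth * np.exp(
                -0.5 * ((t - self.early_dip_age) / self.early_dip_width) ** 2
            )
        return self.sign * value


def _dlogistic(x: float) -> float:
    s = expit(x)
    return s * (1.0 - s)


# ---------------------------------------------------------------------------
# Cohort truth
# ---------------------------------------------------------------------------


@dataclass
class CohortTruth:
    """Planted parameters backing a synthetic cohort."""

    edges: dict                    # (i, j) -> EdgeTrajectorySpec, i != j
    self_decay: float = -1.0
    subject_effects: dict = field(default_factory=dict)   # subject_id -> float
    planted_global_peak_age: float | None = None
    stability_margin: float = 0.05

    def global_curve(self, ages) -> np.ndarray:
        """Mean planted off-diagonal edge value as a function of age."""
        ages = np.asarray(ages, dtype=float)
        total = np.zeros_like(ages)
        for spec in self.edges.values():
            total += spec.curve(ages)
        return total / max(len(self.edges), 1)

    def brute_force_global_peak(self, age_grid=None) -> float:
        """Argmax of the noiseless mean edge curve on a dense age grid."""
        if age_grid is None:
            age_grid = inverse_transform_age(np.linspace(0.0, np.log2(101.0), 4001))
        curve = self.global_curve(age_grid)
        return float(age_grid[np.argmax(curve)])


def default_truth(
    parcellation: Parcellation,
    rng: np.random.Generator,
    edge_density: float = 0.12,
    inhibitory_fraction: float = 0.2,
    within_baseline: float = 0.35,
    between_baseline: float = 0.18,
    amplitude: float = 0.18,
    peak_age: float = 9.0,
    peak_age_jitter: float = 2.0,
    sex_effect_sd: float = 0.01,
    site_offset_sd: float = 0.01,
    subject_sd: float = 0.02,
    sites: tuple[str, ...] = ("BCP", "HCPD", "HCPYA", "HCPA"),
) -> CohortTruth:
    """Plant a random edge set with within > between coupling and a ~9 y peak."""
    r = parcellation.n_regions
    member = parcellation.membership()
    edges: dict = {}
    for i in range(r):
        for j in range(r):
            if i == j or rng.random() > edge_density:
                continue
            within = member[i] == member[j]
            sign = -1 if rng.random() < inhibitory_fraction else 1
            edges[(i, j)] = EdgeTrajectorySpec(
                baseline=(within_baseline if within else between_baseline)
                * rng.uniform(0.7, 1.3),
                amplitude=amplitude * rng.uniform(0.6, 1.4),
                peak_age=max(2.0, peak_age + rng.uniform(-peak_age_jitter, peak_age_jitter)),
                rise_rate=rng.uniform(1.5, 2.5),
                fall_rate=rng.uniform(0.5, 1.0),
                early_dip_depth=0.03 * rng.random(),
                sign=sign,
                sex_effect=rng.normal(0.0, sex_effect_sd),
                site_offsets={s: rng.normal(0.0, site_offset_sd) for s in sites},
                subject_sd=subject_sd,
            )
    truth = CohortTruth(edges=edges)
    truth.planted_global_peak_age = truth.brute_force_global_peak()
    return truth


def make_lifespan_ec(
    age: float,
    sex: int,
    site: str,
    subject_effect: float,
    truth: CohortTruth,
    n_regions: int,
    max_rescale_attempts: int = 60,
) -> tuple[np.ndarray, float]:
    """Generating coupling matrix for one scan; returns (A, applied scale).

    Off-diagonal entries follow the planted curve at t = log2(age+1) plus
    sex, site, and subject offsets; diagonal entries are negative
    self-decay terms.  If the spectral abscissa is not below the
    stability margin the off-diagonal block is shrunk geometrically and
    the applied scale recorded; failure after all attempts is an error.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    A = np.zeros((n_regions, n_regions))
    for (i, j), spec in truth.edges.items():
        value = float(spec.curve(age))
        value += spec.sex_effect * sex + spec.site_offsets.get(site, 0.0)
        value += subject_effect
        A[i, j] = value
    np.fill_diagonal(A, truth.self_decay)
    scale = 1.0
    off = ~np.eye(n_regions, dtype=bool)
    for _ in range(max_rescale_attempts):
        if np.max(np.linalg.eigvals(A).real) < -truth.stability_margin:
            return A, scale
        A[off] *= 0.9
        scale *= 0.9
    raise RuntimeError(
        f"could not stabilize generating matrix (spectral abscissa "
        f"{np.max(np.linalg.eigvals(A).real):.3f})"
    )


def hierarchical_network(
    n_regions: int = 10,
    seed: int | None = 0,
    feedforward: tuple[float, float] = (0.4, 0.7),
    feedback: tuple[float, float] = (0.15, 0.35),
    n_inhibitory: int = 5,
    inhibitory: tuple[float, float] = (0.2, 0.5),
    self_decay: float = -0.8,
    stability_margin: float = 0.05,
) -> np.ndarray:
    """Canonical coupling matrix for recovery benchmarks.

    A cortical-hierarchy motif: a feedforward chain with stronger
    ascending than descending (feedback) couplings plus a handful of
    long-range inhibitory edges — the directed, sign-mixed structure the
    effective-connectome analyses are about.  Weights are drawn once
    from the stated ranges; the off-diagonal block is shrunk if needed
    to keep the spectral abscissa below ``-stability_margin``.
    """
    rng = np.random.default_rng(seed)
    A = np.zeros((n_regions, n_regions))
    for i in range(n_regions - 1):
        A[i + 1, i] = rng.uniform(*feedforward)
        A[i, i + 1] = rng.uniform(*feedback)
    placed = 0
    while placed < n_inhibitory:
        i, j = rng.integers(0, n_regions, 2)
        if i != j and A[i, j] == 0:
            A[i, j] = -rng.uniform(*inhibitory)
            placed += 1
    A[np.diag_indices(n_regions)] = self_decay
    off = ~np.eye(n_regions, dtype=bool)
    for _ in range(60):
        if np.max(np.linalg.eigvals(A).real) < -stability_margin:
            return A
        A[off] *= 0.9
    raise RuntimeError("could not stabilize hierarchical network")


# ---------------------------------------------------------------------------
# BOLD forward model
# ---------------------------------------------------------------------------


@dataclass
class SimulationSpec:
    """Forward-model settings for one simulated scan."""

    n_regions: int
    tr: float = 0.72
    n_timepoints: int = 600
    neuronal_dt: float | None = None   # default TR / 16
    driving_noise_sd: float = 1.0
    snr: float = 3.0
    hrf_duration: float = 32.0
    burnin_volumes: int = 32
    parcellation: Parcellation | None = None

    def __post_init__(self) -> None:
        if self.neuronal_dt is None:
            self.neuronal_dt = self.tr / 16.0
        if self.neuronal_dt > self.tr:
            raise ValueError("neuronal_dt must not exceed TR")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if self.n_timepoints < 64:
            raise ValueError("n_timepoints must be at least 64")


def simulate_bold(
    A: np.ndarray,
    spec: SimulationSpec,
    seed: int,
    subject_id: str = "sim",
    age: float = 20.0,
    sex: int = 1,
    site: str = "SIM",
    initial_state: np.ndarray | None = None,
) -> BoldRun:
    """Simulate one BOLD run from coupling matrix ``A``.

    Euler-Maruyama integration of dx/dt = Ax + u at ``neuronal_dt`` with
    per-region white driving noise (the resting-state stand-in for
    experimental input), convolution with the canonical HRF at neuronal
    resolution, decimation to TR, and additive white observation noise
    scaled per region so SD(signal)/SD(noise) equals ``snr``.
    Deterministic given the seed.
    """
    A = np.asarray(A, dtype=float)
    r = A.shape[0]
    abscissa = float(np.max(np.linalg.eigvals(A).real))
    if abscissa >= 0:
        raise ValueError(f"unstable coupling matrix (spectral abscissa {abscissa:.4f})")
    rng = np.random.default_rng(seed)
    dt = spec.neuronal_dt
    oversample = int(round(spec.tr / dt))
    n_vol = spec.n_timepoints + spec.burnin_volumes
    n_steps = n_vol * oversample

    x = np.zeros(r) if initial_state is None else np.asarray(initial_state, dtype=float).copy()
    states = np.empty((n_steps, r))
    sqrt_dt = np.sqrt(dt)
    noise = (
        rng.standard_normal((n_steps, r)) * (spec.driving_noise_sd * sqrt_dt)
        if spec.driving_noise_sd > 0
        else np.zeros((n_steps, r))
    )
    eye_plus = np.eye(r) + dt * A
    for k in range(n_steps):
        x = eye_plus @ x + noise[k]
        if not np.all(np.isfinite(x)):
            raise RuntimeError(
                f"numerically divergent trajectory (spectral abscissa {abscissa:.4f})"
            )
        states[k] = x

    hrf = canonical_hrf(tr=dt, duration=spec.hrf_duration)
    kernel = hrf.samples
    bold_fine = np.empty_like(states)
    for j in range(r):
        bold_fine[:, j] = np.convolve(states[:, j], kernel)[:n_steps]
    bold = bold_fine[oversample - 1 :: oversample][spec.burnin_volumes :][: spec.n_timepoints]

    if np.isfinite(spec.snr):
        sd_signal = bold.std(axis=0, ddof=0)
        obs_noise = rng.standard_normal(bold.shape) * (sd_signal / spec.snr)
        bold = bold + obs_noise

    region_ids = (
        spec.parcellation.region_ids
        if spec.parcellation is not None
        else tuple(f"R{i + 1}" for i in range(r))
    )
    return BoldRun(
        subject_id=subject_id, age=age, sex=sex, site=site, tr=spec.tr,
        series=bold, region_ids=region_ids,
    )


def exact_discrete_dataset(
    A: np.ndarray,
    C: np.ndarray,
    u: np.ndarray,
    tr: float,
    hrf: HrfKernel,
) -> np.ndarray:
    """Series satisfying the discrete frequency-domain model exactly.

    Solves, bin by bin, z_m yhat_m = A yhat_m + C (hhat uhat)_m with
    z_m = (exp(2*pi*1j*m/N) - 1)/T, then inverse-transforms.  Conjugate
    symmetry makes the result real; the rDCM regression on this series
    (with the input regressors on) has an exact zero-residual solution
    at the generating parameters.
    """
    A = np.asarray(A, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    u = np.atleast_2d(np.asarray(u, dtype=float))
    r = A.shape[0]
    if u.shape[0] > u.shape[1]:
        u = u.T  # K x N
    n = u.shape[1]
    h_pad = np.zeros(n)
    h_pad[: min(len(hrf.samples), n)] = hrf.samples[:n]
    h_hat = np.fft.fft(h_pad)
    u_hat = np.fft.fft(u, axis=1)
    drive = C @ (h_hat * u_hat)  # R x N
    yhat = np.empty((r, n), dtype=complex)
    eye = np.eye(r)
    for m in range(n):
        z = (np.exp(2j * np.pi * m / n) - 1.0) / tr
        yhat[:, m] = np.linalg.solve(z * eye - A, drive[:, m])
    series = np.fft.ifft(yhat, axis=1)
    assert np.max(np.abs(series.imag)) < 1e-8 * max(np.max(np.abs(series.real)), 1.0)
    return series.real.T  # T x R


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Age-band boundaries (years) assigning scans to acquisition sites,
#: mirroring the sub-study structure: infancy/early childhood, development,
#: young adulthood, aging.
SITE_BANDS = (("BCP", 7.0), ("HCPD", 22.0), ("HCPYA", 37.0), ("HCPA", np.inf))


def sample_lifespan_ages(
    n: int,
    rng: np.random.Generator,
    age_range: tuple[float, float] = (0.03, 100.0),
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Draw a lifespan age sample, uniform in t = log2(age+1).

    Uniform-in-t coverage spans infancy through late adulthood with the
    early years emphasized (as in transformed-age lifespan designs).
    Scans are assigned to one of four acquisition sites by age band;
    infancy-band scans are eligible for longitudinal repeats.

    Returns (ages, sites, repeat_eligible flags).
    """
    lo, hi = age_range
    if not hi > lo:
        raise ValueError("degenerate age range")
    t = rng.uniform(np.log2(lo + 1.0), np.log2(hi + 1.0), size=n)
    ages = np.exp2(t) - 1.0
    sites = [next(name for name, upper in SITE_BANDS if a < upper) for a in ages]
    repeats = np.array([s == "BCP" for s in sites])
    return ages, sites, repeats


def generate_cohort(
    n_subjects: int,
    spec: SimulationSpec,
    seed: int,
    out_dir: str | Path,
    age_range: tuple[float, float] = (0.03, 100.0),
    truth: CohortTruth | None = None,
    longitudinal_fraction: float = 0.15,
    truth_kwargs: dict | None = None,
) -> tuple[CohortManifest, CohortTruth]:
    """Generate a full synthetic cohort: manifest, series TSVs, truth file.

    Sexes are balanced (counts differ by at most one); infancy-cohort
    subjects may receive one longitudinal repeat scan.  All randomness
    derives from ``seed``; identical seeds give byte-identical outputs.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if spec.parcellation is None:
        raise ValueError("SimulationSpec.parcellation is required for cohorts")
    out_dir = Path(out_dir)
    (out_dir / "series").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    if truth is None:
        truth = default_truth(spec.parcellation, rng, **(truth_kwargs or {}))

    ages, sites, repeat_ok = sample_lifespan_ages(n_subjects, rng, age_range)
    sexes = np.array([1, -1] * (n_subjects // 2 + 1))[:n_subjects]
    rng.shuffle(sexes)

    subject_sd = np.mean([e.subject_sd for e in truth.edges.values()]) if truth.edges else 0.0
    rows = []
    for s in range(n_subjects):
        sid = f"sub-{s + 1:04d}"
        truth.subject_effects[sid] = float(rng.normal(0.0, subject_sd))
        scan_ages = [ages[s]]
        if repeat_ok[s] and rng.random() < longitudinal_fraction:
            scan_ages.append(min(ages[s] + rng.uniform(0.5, 1.5), age_range[1]))
        for scan_idx, age in enumerate(scan_ages):
            A, scale = make_lifespan_ec(
                age, int(sexes[s]), sites[s], truth.subject_effects[sid],
                truth, spec.n_regions,
            )
            run = simulate_bold(
                A, spec, seed=int(rng.integers(2**31)), subject_id=sid,
                age=age, sex=int(sexes[s]), site=sites[s],
            )
            rel = f"series/{sid}_scan{scan_idx + 1}.tsv"
            write_bold_series(run.series, spec.parcellation.region_ids, out_dir / rel)
            rows.append(
                {
                    "subject_id": sid, "age": round(age, 6), "sex": int(sexes[s]),
                    "site": sites[s], "tr": spec.tr, "series_path": rel,
                    "mean_fd": round(float(rng.uniform(0.05, 0.45)), 4),
                    "ec_scale": scale,
                }
            )
    manifest = CohortManifest(pd.DataFrame(rows))
    write_manifest(manifest, out_dir / "manifest.tsv")
    save_truth(truth, out_dir / "truth.json")
    return manifest, truth


def save_truth(truth: CohortTruth, path: str | Path) -> None:
    payload = {
        "self_decay": truth.self_decay,
        "stability_margin": truth.stability_margin,
        "planted_global_peak_age": truth.planted_global_peak_age,
        "subject_effects": truth.subject_effects,
        "edges": [
            {"source": j, "target": i, **asdict(spec)}
            for (i, j), spec in sorted(truth.edges.items())
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_truth(path: str | Path) -> CohortTruth:
    payload = json.loads(Path(path).read_text())
    edges = {}
    for e in payload["edges"]:
        i, j = e.pop("target"), e.pop("source")
        edges[(i, j)] = EdgeTrajectorySpec(**e)
    return CohortTruth(
        edges=edges,
        self_decay=payload["self_decay"],
        stability_margin=payload["stability_margin"],
        planted_global_peak_age=payload["planted_global_peak_age"],
        subject_effects=payload["subject_effects"],
    )


# ---------------------------------------------------------------------------
# Metric-level cohort (for growth-curve recovery at scale)
# ---------------------------------------------------------------------------


def simulate_metric_cohort(
    n_scans: int = 400,
    seed: int = 0,
    peak_age: float = 9.0,
    baseline: float = 0.2,
    amplitude: float = 1.0,
    rise_rate: float = 2.0,
    fall_rate: float = 2.0,
    early_dip_depth: float = 0.0,
    sex_gain: float = 0.1,
    subject_sd: float = 0.15,
    site_offset_sd: float = 0.05,
    residual_sd: float = 0.25,
    longitudinal_fraction: float = 0.12,
    age_range: tuple[float, float] = (0.03, 100.0),
) -> tuple[pd.DataFrame, EdgeTrajectorySpec]:
    """Metric samples from a planted growth curve, bypassing the BOLD stage.

    y = curve(t) + sex_gain * bump(t) * sex + subject + site + noise.
    Used to exercise trajectory fitting and peak recovery at realistic
    cohort size without paying for per-scan EC estimation.
    """
    rng = np.random.default_rng(seed)
    spec = EdgeTrajectorySpec(
        baseline=baseline, amplitude=amplitude, peak_age=peak_age,
        rise_rate=rise_rate, fall_rate=fall_rate,
        early_dip_depth=early_dip_depth, subject_sd=subject_sd,
        residual_sd=residual_sd,
    )
    site_offsets = {
        name: float(rng.normal(0.0, site_offset_sd)) for name, _ in SITE_BANDS
    }

    rows: list[dict] = []
    s = 0
    while len(rows) < n_scans:
        s += 1
        sid = f"sub-{s:04d}"
        age, site, repeat_ok = (arr[0] for arr in sample_lifespan_ages(1, rng, age_range))
        sex = 1 if s % 2 else -1
        subj = rng.normal(0.0, subject_sd)
        scan_ages = [age]
        if repeat_ok and rng.random() < longitudinal_fraction / 0.3:
            scan_ages.append(min(age + rng.uniform(0.5, 1.5), age_range[1]))
        for a in scan_ages[: n_scans - len(rows)]:
            t = float(transform_age(a))
            value = (
                float(spec.curve(a))
                + sex_gain * float(spec.bump(t)) * sex
                + subj
                + site_offsets[site]
                + rng.normal(0.0, residual_sd)
            )
            rows.append(
                {"subject_id": sid, "age": float(a), "t": t, "sex": sex,
                 "site": site, "value": value}
            )
    return pd.DataFrame(rows), spec
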