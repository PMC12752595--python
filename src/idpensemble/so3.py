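"""Isotropic Gaussian diffusion on SO(3).

The rotation channel of the frame diffusion is a variance-exploding process
whose time-t perturbation kernel is the isotropic Gaussian on SO(3),

    IGSO3(R_t; R_0, sigma^2),   omega = Axis_angle(R_0^T R_t),

with the truncated character expansion

    f~(omega; sigma) = sum_{l=0}^{L} (2l+1) exp(-l(l+1) sigma^2)
                       sin((l+1/2) omega) / sin(omega/2).

``f~`` is the density of R_0^T R_t with respect to the Haar measure; the
marginal density of the rotation *angle* additionally carries the Haar
angle factor (1 - cos omega)/pi.  Both are tabulated: the angle marginal
drives inverse-CDF sampling, while d/d omega log f~ is the radial part of
the manifold score used for denoising score matching and reverse
integration.  For sigma below a small-noise crossover the series suffers
catastrophic cancellation and the tangent-space Gaussian asymptotic is used
instead (axis-angle vector ~ N(0, 2 sigma^2 I), i.e. Brownian time 2 sigma^2
matching the exponent above).

The noise level follows a logarithmic VE schedule,
``sigma(t) = log(t e^{sigma_max} + (T - t) e^{sigma_min})``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .geometry import matrix_to_rotvec, project_rotations, rotvec_to_matrix

#: below this sigma the truncated series is replaced by the small-noise asymptotic
SMALL_SIGMA_CROSSOVER = 0.05


@dataclass(frozen=True)
class SO3Schedule:
    """Logarithmic VE noise schedule for the rotation channel."""

    sigma_min: float = 0.1
    sigma_max: float = 1.5
    T: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.sigma_min < self.sigma_max):
            raise ValueError("need 0 < sigma_min < sigma_max")
        if self.T <= 0:
            raise ValueError("T must be positive")


def _check_t(t, T: float):
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > T + 1e-12):
        raise ValueError(f"time t={t} outside [0, {T}]")
    return np.clip(t, 0.0, T)


def sigma(t, sched: SO3Schedule = SO3Schedule()):
    """sigma(t) = log(t e^{sigma_max} + (T - t) e^{sigma_min})."""
    t = _check_t(t, sched.T)
    return np.log(t * np.exp(sched.sigma_max) + (sched.T - t) * np.exp(sched.sigma_min))


def dsigma_sq_dt(t, sched: SO3Schedule = SO3Schedule()):
    """d(sigma^2)/dt of the logarithmic schedule."""
    t = _check_t(t, sched.T)
    denom = t * np.exp(sched.sigma_max) + (sched.T - t) * np.exp(sched.sigma_min)
    dsigma_dt = (np.exp(sched.sigma_max) - np.exp(sched.sigma_min)) / denom
    return 2.0 * sigma(t, sched) * dsigma_dt


def g_squared(t, sched: SO3Schedule = SO3Schedule()):
    """Squared diffusion coefficient of the rotation VE SDE.

    The IGSO3 kernel exponent exp(-l(l+1) sigma^2) corresponds to Brownian
    time 2 sigma^2, so the forward SDE matching the kernel has
    g^2 = d(2 sigma^2)/dt.  (Reading the coefficient as d(sigma^2)/dt leaves
    the reverse process under-dispersed relative to the forward marginals.)
    """
    return 2.0 * dsigma_sq_dt(t, sched)


def _series_ftilde(omega: np.ndarray, sig: float, L: int) -> np.ndarray:
    """Truncated character series f~(omega; sigma) (density w.r.t. Haar)."""
    # adaptive cutoff: terms with (2l+1) e^{-l(l+1) sigma^2} < 1e-18 are dropped
    lmax = int(min(L, np.ceil(np.sqrt(42.0 / max(sig, 1e-3) ** 2)) + 10))
    l = np.arange(lmax + 1)
    coef = (2 * l + 1) * np.exp(-l * (l + 1) * sig**2)
    half = 0.5 * omega
    num = np.sin(np.outer(omega, l + 0.5))
    with np.errstate(invalid="ignore", divide="ignore"):
        val = num @ coef / np.sin(half)
    # omega -> 0 limit: sum (2l+1)^2 exp(-l(l+1) sigma^2)
    small = omega < 1e-8
    if np.any(small):
        val[small] = ((2 * l + 1) * coef).sum()
    if not np.isfinite(val).all():
        raise FloatingPointError(
            f"IGSO3 series not finite at sigma={sig} (truncation L={L}); "
            "use the small-sigma asymptotic"
        )
    return val


def _series_dftilde(omega: np.ndarray, sig: float, L: int) -> np.ndarray:
    """Termwise d/d omega of the character series."""
    lmax = int(min(L, np.ceil(np.sqrt(42.0 / max(sig, 1e-3) ** 2)) + 10))
    l = np.arange(lmax + 1)
    coef = (2 * l + 1) * np.exp(-l * (l + 1) * sig**2)
    a = l + 0.5
    s_half = np.sin(0.5 * omega)[:, None]
    c_half = np.cos(0.5 * omega)[:, None]
    om = omega[:, None]
    d = (a * np.cos(om * a) * s_half - 0.5 * np.sin(om * a) * c_half) / s_half**2
    return d @ coef


def _haar_factor(omega: np.ndarray) -> np.ndarray:
    return (1.0 - np.cos(omega)) / np.pi


def igso3_density(omega, sig: float, L: int = 2000):
    """Angle-marginal density (includes the Haar factor (1-cos w)/pi)."""
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if np.any(omega < 0) or np.any(omega > np.pi + 1e-12):
        raise ValueError("omega must lie in [0, pi]")
    if sig <= 0:
        raise ValueError("sigma must be positive")
    if sig < SMALL_SIGMA_CROSSOVER:
        # chi_3 angle marginal of a tangent Gaussian with per-axis variance 2 sigma^2
        v = 2.0 * sig**2
        dens = omega**2 * np.exp(-(omega**2) / (2 * v))
        dens /= np.sqrt(np.pi / 2) * v**1.5  # normalizes the chi_3 angle marginal
        return dens
    return _haar_factor(omega) * _series_ftilde(omega, sig, L)


def dlog_ftilde(omega, sig: float, L: int = 2000):
    """d/d omega of log f~ (score magnitude along the geodesic axis)."""
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if sig < SMALL_SIGMA_CROSSOVER:
        # log f~ = log(marginal) - log haar; with the chi_3 asymptotic:
        half = 0.5 * omega
        return 2.0 / omega - omega / (2.0 * sig**2) - np.cos(half) / np.sin(half)
    f = _series_ftilde(omega, sig, L)
    df = _series_dftilde(omega, sig, L)
    return df / np.maximum(f, 1e-300)


@dataclass
class IGSO3Table:
    """Tabulated IGSO3 angle marginal, CDF and score on an (omega, sigma) grid."""

    omega_grid: np.ndarray
    sigma_grid: np.ndarray
    density: np.ndarray        # (n_sigma, n_omega) angle marginal
    cdf: np.ndarray            # (n_sigma, n_omega), cdf[:, -1] == 1
    dlog_density: np.ndarray   # (n_sigma, n_omega) d/d omega log f~
    exp_sq_score: np.ndarray   # (n_sigma,) E_omega[(d log f~)^2]
    series_truncation: int = 2000
    norm_error: np.ndarray = field(default=None)  # |1 - raw trapezoid mass|

    @classmethod
    def build(
        cls,
        sigma_min: float = 0.02,
        sigma_max: float = 2.0,
        n_omega: int = 2048,
        n_sigma: int = 256,
        L: int = 2000,
    ) -> "IGSO3Table":
        omega = np.linspace(0.0, np.pi, n_omega + 1)[1:]
        sigmas = np.geomspace(sigma_min, sigma_max, n_sigma)
        dens = np.empty((n_sigma, n_omega))
        dlog = np.empty((n_sigma, n_omega))
        asym = (
            2.0 / omega
            - omega[None, :] / (2.0 * sigmas[:, None] ** 2)
            - np.cos(0.5 * omega) / np.sin(0.5 * omega)
        )
        for i, s in enumerate(sigmas):
            dens[i] = igso3_density(omega, s, L)
            dlog[i] = dlog_ftilde(omega, s, L)
        # far in the tail the truncated series underflows; the tangent-Gaussian
        # asymptotic is the correct smooth continuation of the score there
        tail = dens < 1e-30
        dlog[tail] = asym[tail]
        dens = np.maximum(dens, 0.0)  # clamp series-truncation noise
        raw_mass = np.trapezoid(dens, omega, axis=1)
        norm_error = np.abs(1.0 - raw_mass)
        cdf = np.concatenate(
            [np.zeros((n_sigma, 1)), np.cumsum(
                0.5 * (dens[:, 1:] + dens[:, :-1]) * np.diff(omega), axis=1)],
            axis=1,
        )
        cdf /= cdf[:, -1:]
        pdf_norm = dens / raw_mass[:, None]
        esq = np.trapezoid(pdf_norm * dlog**2, omega, axis=1)
        return cls(omega, sigmas, dens, cdf, dlog, esq, L, norm_error)

    # -- interpolation helpers -------------------------------------------------
    def _row(self, table: np.ndarray, sig: float) -> np.ndarray:
        """Linear blend of adjacent sigma rows."""
        sg = self.sigma_grid
        if sig < sg[0] - 1e-9 or sig > sg[-1] + 1e-9:
            raise ValueError(f"sigma={sig} outside table range [{sg[0]}, {sg[-1]}]")
        j = np.clip(np.searchsorted(sg, sig) - 1, 0, len(sg) - 2)
        w = np.clip((sig - sg[j]) / (sg[j + 1] - sg[j]), 0.0, 1.0)
        return (1 - w) * table[j] + w * table[j + 1]

    def pdf(self, omega, sig: float) -> np.ndarray:
        return np.interp(omega, self.omega_grid, self._row(self.density, sig))

    def cdf_fn(self, omega, sig: float) -> np.ndarray:
        return np.interp(omega, self.omega_grid, self._row(self.cdf, sig),
                         left=0.0, right=1.0)

    def sample_angles(self, sig: float, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF draws of the rotation angle at noise level sigma."""
        row = self._row(self.cdf, sig)
        u = rng.random(n)
        return np.interp(u, row, self.omega_grid)

    def dlogf(self, omega, sig: float) -> np.ndarray:
        return np.interp(omega, self.omega_grid, self._row(self.dlog_density, sig))

    def expected_sq_score(self, sig: float) -> float:
        return float(np.interp(sig, self.sigma_grid, self.exp_sq_score))


@lru_cache(maxsize=4)
def default_table(n_omega: int = 2048, n_sigma: int = 256) -> IGSO3Table:
    """Process-wide cached table covering the default schedule range."""
    return IGSO3Table.build(n_omega=n_omega, n_sigma=n_sigma)


def _uniform_axes(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_igso3(
    R0: np.ndarray,
    t: float,
    sched: SO3Schedule,
    table: IGSO3Table,
    rng: np.random.Generator,
) -> np.ndarray:
    """Forward-noise rotations: R_t = R_0 exp(omega a), omega ~ IGSO3 marginal."""
    R0 = np.asarray(R0, dtype=float)
    single = R0.ndim == 2
    mats = R0[None] if single else R0.reshape(-1, 3, 3)
    sig = float(sigma(t, sched))
    omega = table.sample_angles(sig, len(mats), rng)
    axes = _uniform_axes(len(mats), rng)
    out = mats @ rotvec_to_matrix(axes * omega[:, None])
    out = out.reshape(R0.shape)
    return out[0] if single else out


def score_so3(
    R_t: np.ndarray,
    R0: np.ndarray,
    t: float,
    sched: SO3Schedule,
    table: IGSO3Table,
) -> np.ndarray:
    """Manifold score of the conditional kernel, as right-tangent 3-vectors at R_t.

    score = d/d omega log f~(omega) * axis,  (axis, omega) = Axis_angle(R0^T R_t).
    Returns zeros where omega == 0 (the kernel mode).
    """
    R_t = np.asarray(R_t, dtype=float)
    R0 = np.broadcast_to(np.asarray(R0, dtype=float), R_t.shape)
    rel = np.swapaxes(R0, -1, -2) @ R_t
    rotvec = matrix_to_rotvec(rel)
    omega = np.linalg.norm(rotvec, axis=-1)
    sig = float(sigma(t, sched))
    out = np.zeros_like(rotvec)
    nz = omega > 1e-10
    if np.any(nz):
        mag = table.dlogf(omega[nz], sig)
        out[nz] = rotvec[nz] / omega[nz][..., None] * mag[..., None]
    return out


def reverse_step_so3(
    R_t: np.ndarray,
    predicted_score: np.ndarray,
    t: float,
    dt: float,
    sched: SO3Schedule,
    rng: np.random.Generator,
    add_noise: bool = True,
) -> np.ndarray:
    """One geodesic Euler step of the reverse VE SDE, t -> t - dt.

    Drift g^2(t) * score * dt plus (unless the step lands at t=0 or noise is
    disabled) tangent noise of covariance g^2(t) dt; g^2 = d(2 sigma^2)/dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > t + 1e-12:
        raise ValueError("step would cross t=0")
    g2 = float(g_squared(t, sched))
    tang = g2 * dt * np.asarray(predicted_score, dtype=float)
    if add_noise and (t - dt) > 1e-12:
        tang = tang + np.sqrt(g2 * dt) * rng.standard_normal(tang.shape)
    out = np.asarray(R_t, dtype=float) @ rotvec_to_matrix(tang)
    return project_rotations(out)


def denoise_tweedie(
    R: np.ndarray,
    score: np.ndarray,
    sig: float,
) -> np.ndarray:
    """Final denoising step: move along the score by the kernel's tangent
    variance 2 sigma^2 (the empirical-Bayes posterior-mean correction).

    Because the VE schedule has sigma(0) = sigma_min > 0, the reverse SDE
    alone leaves kernel-width rotational noise at t = 0; outputting the
    denoised estimate is the standard last step of score-based samplers.
    """
    step = 2.0 * sig**2 * np.asarray(score, dtype=float)
    return project_rotations(np.asarray(R, dtype=float) @ rotvec_to_matrix(step))
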