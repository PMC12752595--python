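"""Variance-preserving (Ornstein-Uhlenbeck) diffusion on translation vectors.

The translation channel of the frame diffusion uses a linear-beta VP SDE on
the center-of-mass-free subspace:

    beta(t) = beta_min + (t/T)(beta_max - beta_min)
    v_t | v_0 ~ N( v_0 exp(-1/2 int beta), (1 - exp(-int beta)) I )

with the projection P removing the center of mass applied to the initial
state, to every forward/reverse step, and to scores.  The kernel variance
is the standard VP form, the one consistent with the kernel converging to
N(0, I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class VPSchedule:
    """Linear beta schedule of the VP (OU) translation SDE."""

    beta_min: float = 0.1
    beta_max: float = 20.0
    T: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.beta_min < self.beta_max):
            raise ValueError("need 0 < beta_min < beta_max")
        if self.T <= 0:
            raise ValueError("T must be positive")


def _check_t(t, T: float):
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > T + 1e-12):
        raise ValueError(f"time t={t} outside [0, {T}]")
    return np.clip(t, 0.0, T)


def beta(t, sched: VPSchedule = VPSchedule()):
    t = _check_t(t, sched.T)
    return sched.beta_min + (t / sched.T) * (sched.beta_max - sched.beta_min)


def int_beta(t, sched: VPSchedule = VPSchedule()):
    """Closed-form accumulated rate int_0^t beta(s) ds."""
    t = _check_t(t, sched.T)
    return sched.beta_min * t + (sched.beta_max - sched.beta_min) * t**2 / (2 * sched.T)


def marginal_mean_scale(t, sched: VPSchedule = VPSchedule()):
    """exp(-1/2 int beta): shrink factor of the kernel mean."""
    return np.exp(-0.5 * int_beta(t, sched))


def marginal_variance(t, sched: VPSchedule = VPSchedule()):
    """1 - exp(-int beta): per-coordinate kernel variance."""
    return 1.0 - np.exp(-int_beta(t, sched))


def com_project(v: np.ndarray) -> np.ndarray:
    """Remove the mean vector over residues (last-but-one axis); idempotent, linear."""
    v = np.asarray(v, dtype=float)
    return v - v.mean(axis=-2, keepdims=True)


def forward_sample_r3(
    v0: np.ndarray,
    t: float,
    sched: VPSchedule,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw v_t from the forward kernel; returns (v_t, noise eps) for loss use."""
    v0 = np.asarray(v0, dtype=float)
    eps = rng.standard_normal(v0.shape)
    mean = v0 * marginal_mean_scale(t, sched)
    v_t = com_project(mean + np.sqrt(marginal_variance(t, sched)) * eps)
    return v_t, eps


def score_r3(v_t: np.ndarray, v0: np.ndarray, t: float, sched: VPSchedule) -> np.ndarray:
    """Gaussian kernel score -(v_t - v0 e^{-1/2 int beta}) / (1 - e^{-int beta}),
    projected onto the center-of-mass-free subspace."""
    var = marginal_variance(t, sched)
    if var <= 0:
        raise ValueError("score undefined at t=0 (zero kernel variance)")
    resid = np.asarray(v_t, dtype=float) - np.asarray(v0, dtype=float) * marginal_mean_scale(t, sched)
    return com_project(-resid / var)


def reverse_step_r3(
    v_t: np.ndarray,
    predicted_score: np.ndarray,
    t: float,
    dt: float,
    sched: VPSchedule,
    rng: np.random.Generator,
    add_noise: bool = True,
) -> np.ndarray:
    """Euler-Maruyama step of the reverse VP SDE, t -> t - dt, CoM-projected.

    dv = [-1/2 beta(t) P v - beta(t) score] dt reversed in time gives
    v_{t-dt} = v_t + (1/2 beta v + beta score) dt + sqrt(beta dt) P z,
    with the noise omitted on the final step (t - dt = 0).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > t + 1e-12:
        raise ValueError("step would cross t=0")
    b = float(beta(t, sched))
    v_t = np.asarray(v_t, dtype=float)
    out = v_t + (0.5 * b * v_t + b * np.asarray(predicted_score, dtype=float)) * dt
    if add_noise and (t - dt) > 1e-12:
        out = out + np.sqrt(b * dt) * rng.standard_normal(v_t.shape)
    return com_project(out)


def denoise_tweedie(v: np.ndarray, score: np.ndarray, t: float, sched: VPSchedule) -> np.ndarray:
    """Posterior-mean (Tweedie) estimate of the clean state from v_t and the score:
    v0_hat = (v_t + var * score) / mean_scale, CoM-projected."""
    var = marginal_variance(t, sched)
    scale = marginal_mean_scale(t, sched)
    return com_project((np.asarray(v, dtype=float) + var * np.asarray(score, dtype=float)) / scale)
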