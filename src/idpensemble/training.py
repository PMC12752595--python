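"""Denoising-score-matching objective and training loop.

The loss is

    L = L_dsm + omega1 * L_bb + omega2 * L_dist

where L_dsm is the lambda(t)-weighted squared error between predicted and
forward-kernel scores (rotation and translation channels separately),
lambda(t) = 1 / E ||true score||^2 so that a zero prediction scores 1 per
channel at every t, and the auxiliary backbone / distance-matrix MSE terms
are applied only at small noise (t < T/4) with omega1 = omega2 = 0.25.

The network predicts denoised frames; predicted scores are derived from
them through the analytic kernels (differentiably -- the rotation channel
interpolates the tabulated IGSO3 score).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import network as net
from . import r3, so3
from .autodiff import Tensor, einsum
from .geometry import FrameSet, LOCAL_C, LOCAL_N, frames_from_backbone
from .network import NetworkConfig

#: Eq-9 weights of the structure-quality terms and the time gate fraction
@dataclass(frozen=True)
class LossWeights:
    omega1: float = 0.25
    omega2: float = 0.25
    aux_time_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.omega1 < 0 or self.omega2 < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class LossReport:
    dsm_rot: float
    dsm_trans: float
    bb_mse: float
    dist_mse: float
    total: float
    t: float


def lambda_weight(
    t: float,
    process: str,
    so3_sched: so3.SO3Schedule | None = None,
    r3_sched: r3.VPSchedule | None = None,
    table: so3.IGSO3Table | None = None,
    n_res: int | None = None,
) -> float:
    """1 / E ||true forward-kernel score||^2 at time t (per-residue norms).

    Translation: closed form var * 3n/(3(n-1)) accounting for the CoM
    projection removing three degrees of freedom (n_res defaults to the
    large-n limit).  Rotation: quadrature over the tabulated IGSO3 marginal.
    """
    if process == "translation":
        r3_sched = r3_sched or r3.VPSchedule()
        var = float(r3.marginal_variance(t, r3_sched))
        if var <= 0:
            raise ValueError("lambda undefined at t=0")
        if n_res is None:
            return var / 3.0
        return var * n_res / (3.0 * (n_res - 1))
    if process == "rotation":
        so3_sched = so3_sched or so3.SO3Schedule()
        table = table or so3.default_table()
        esq = table.expected_sq_score(float(so3.sigma(t, so3_sched)))
        return 1.0 / esq
    raise ValueError(f"unknown process {process!r}")


def dsm_loss(
    predicted_scores: np.ndarray,
    true_scores: np.ndarray,
    t: float,
    process: str,
    **kwargs,
) -> float:
    """lambda(t)-weighted mean squared score residual over residues."""
    lam = lambda_weight(t, process, n_res=len(np.atleast_2d(predicted_scores)), **kwargs) \
        if process == "translation" else lambda_weight(t, process, **kwargs)
    diff = np.asarray(predicted_scores) - np.asarray(true_scores)
    return float(lam * (diff**2).sum(axis=-1).mean())


def _rebuild_bb(R: np.ndarray, v: np.ndarray) -> np.ndarray:
    locals_ = np.stack([LOCAL_N, np.zeros(3), LOCAL_C])  # (3 atoms, 3)
    return np.einsum("nij,aj->nai", R, locals_) + v[:, None, :]


def aux_losses(t0_hat: FrameSet, t0_true: FrameSet) -> tuple[float, float]:
    """Backbone-atom MSE (N/CA/C rebuilt from frames, same gauge) and
    all-pairs CA distance-matrix MSE (off-diagonal mean)."""
    bb_hat = _rebuild_bb(t0_hat.rotations, t0_hat.translations)
    bb_true = _rebuild_bb(t0_true.rotations, t0_true.translations)
    bb_mse = float(((bb_hat - bb_true) ** 2).mean() * 3)  # per-atom squared distance

    def dmat(v):
        d = v[:, None, :] - v[None, :, :]
        return np.sqrt((d**2).sum(-1))

    n = t0_hat.residue_count
    off = ~np.eye(n, dtype=bool)
    dd = dmat(t0_hat.translations) - dmat(t0_true.translations)
    dist_mse = float((dd[off] ** 2).mean())
    return bb_mse, dist_mse


def total_loss(
    dsm_rot: float,
    dsm_trans: float,
    bb_mse: float,
    dist_mse: float,
    t: float,
    weights: LossWeights = LossWeights(),
    T: float = 1.0,
) -> LossReport:
    """Combine the channels; structure terms count only when t < T/4."""
    gate = t < weights.aux_time_fraction * T
    bb = bb_mse if gate else 0.0
    dist = dist_mse if gate else 0.0
    total = dsm_rot + dsm_trans + weights.omega1 * bb + weights.omega2 * dist
    return LossReport(dsm_rot, dsm_trans, bb, dist, total, t)


# -- training loop -------------------------------------------------------------

@dataclass
class TrainConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig.desk)
    learning_rate: float = 1e-4
    batch_size: int = 8
    n_steps: int = 1000
    t_min: float = 0.01
    grad_clip: float = 1.0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    log_every: int = 10
    checkpoint_every: int = 0  # 0 = only at the end

    @staticmethod
    def pretrain(**kw) -> "TrainConfig":
        """Stage-1 preset (experimental-structure stage): lr 1e-4, batch 8."""
        return TrainConfig(**{"learning_rate": 1e-4, "batch_size": 8, **kw})

    @staticmethod
    def finetune(**kw) -> "TrainConfig":
        """Stage-2 preset (trajectory stage): lr 1e-5, batch 32."""
        return TrainConfig(**{"learning_rate": 1e-5, "batch_size": 32, **kw})

    @staticmethod
    def desk(**kw) -> "TrainConfig":
        """CPU-scale preset: small network, larger lr for few-thousand-step runs."""
        return TrainConfig(**{"learning_rate": 1e-3, "batch_size": 8, **kw})


def _prepare_dataset(dataset) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Normalize to a list of (aa_index, R0, v0) with centered translations."""
    items = []
    for entry in dataset:
        if isinstance(entry, tuple):
            seq, conf = entry
        else:
            conf, seq = entry, entry.sequence
        if isinstance(conf, FrameSet):
            frames = conf
        else:
            frames = frames_from_backbone(conf)
        if seq is None:
            seq = "X" * frames.residue_count
        v0 = r3.com_project(frames.translations)
        items.append((net.sequence_indices(seq), frames.rotations, v0))
    if not items:
        raise ValueError("empty training dataset")
    return items


def _adam_step(params, grads, state, lr, step, b1=0.9, b2=0.999, eps=1e-8):
    for k, g in grads.items():
        m, v = state.setdefault(k, (np.zeros_like(params[k]), np.zeros_like(params[k])))
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        state[k] = (m, v)
        mh = m / (1 - b1**step)
        vh = v / (1 - b2**step)
        params[k] -= (lr * mh / (np.sqrt(vh) + eps)).astype(params[k].dtype)


def _clip_grads(grads, max_norm):
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for k in grads:
            grads[k] = grads[k] * scale
    return total


def _score_tables(table: so3.IGSO3Table, sigmas: np.ndarray):
    """Per-sample rows of g(omega) = dlogf~/(2 sin omega) and its slope."""
    grid = table.omega_grid
    rows = np.stack([table._row(table.dlog_density, s) for s in sigmas])
    g = rows / (2.0 * np.sin(grid))
    g = np.clip(g, -50.0, 50.0)  # the omega ~ pi tail never matters in practice
    slope = np.gradient(g, grid, axis=1)
    return grid, g.astype(np.float32), slope.astype(np.float32)


def training_step(
    params: dict,
    items: list,
    config: TrainConfig,
    rng: np.random.Generator,
    so3_sched: so3.SO3Schedule,
    r3_sched: r3.VPSchedule,
    table: so3.IGSO3Table,
) -> tuple[LossReport, dict]:
    """One batched forward/backward pass; returns the report and raw grads."""
    lw = config.loss_weights
    T = so3_sched.T
    # draw a batch of equal-length items
    n_groups: dict[int, list[int]] = {}
    for i, (_, R0, _) in enumerate(items):
        n_groups.setdefault(len(R0), []).append(i)
    length = rng.choice(sorted(n_groups))
    pool = n_groups[length]
    pick = rng.choice(len(pool), size=config.batch_size,
                      replace=len(pool) < config.batch_size)
    batch = [items[pool[i]] for i in pick]
    B, n = len(batch), length

    aa = np.stack([b[0] for b in batch])
    R0 = np.stack([b[1] for b in batch])
    v0 = np.stack([b[2] for b in batch])
    t = rng.uniform(config.t_min, T, size=B)
    sig = np.array([float(so3.sigma(tb, so3_sched)) for tb in t])

    # forward-diffuse
    R_t = np.empty_like(R0)
    v_t = np.empty_like(v0)
    s_rot_true = np.empty((B, n, 3))
    s_tr_true = np.empty((B, n, 3))
    for b_ in range(B):
        R_t[b_] = so3.sample_igso3(R0[b_], t[b_], so3_sched, table, rng)
        v_t[b_], _ = r3.forward_sample_r3(v0[b_], t[b_], r3_sched, rng)
        s_rot_true[b_] = so3.score_so3(R_t[b_], R0[b_], t[b_], so3_sched, table)
        s_tr_true[b_] = r3.score_r3(v_t[b_], v0[b_], t[b_], r3_sched)

    R0h, v0h, pview = net.forward(params, config.network, aa, R_t, v_t, t, train=True)

    # predicted translation score (differentiable, CoM-projected)
    scale = r3.marginal_mean_scale(t, r3_sched)[:, None, None]
    var = r3.marginal_variance(t, r3_sched)[:, None, None]
    resid = Tensor(v_t.astype(np.float32)) - v0h * scale.astype(np.float32)
    s_tr = resid * (-1.0 / var.astype(np.float32))
    s_tr = s_tr - s_tr.mean(axis=-2, keepdims=True)

    # predicted rotation score: g(omega_hat) * vee(M - M^T), M = R0_hat^T R_t
    M = einsum("bnki,bnkj->bnij", R0h, Tensor(R_t.astype(np.float32)))
    tr = (M * Tensor(np.broadcast_to(np.eye(3, dtype=np.float32), M.shape).copy())).sum(axis=(-1, -2))
    omega_hat = ((tr - 1.0) * 0.5).arccos()
    vee = ad.stack(
        [M[..., 2, 1] - M[..., 1, 2], M[..., 0, 2] - M[..., 2, 0], M[..., 1, 0] - M[..., 0, 1]],
        axis=-1,
    )
    grid, g_rows, g_slopes = _score_tables(table, sig)
    gfac = ad.table_lookup(omega_hat, grid, g_rows, g_slopes)
    s_rot = vee * gfac.reshape(B, n, 1)

    lam_rot = np.array(
        [lambda_weight(tb, "rotation", so3_sched, table=table) for tb in t], dtype=np.float32)
    lam_tr = np.array(
        [lambda_weight(tb, "translation", r3_sched=r3_sched, n_res=n) for tb in t],
        dtype=np.float32)

    d_rot = s_rot - Tensor(s_rot_true.astype(np.float32))
    d_tr = s_tr - Tensor(s_tr_true.astype(np.float32))
    dsm_rot_b = (d_rot * d_rot).sum(axis=-1).mean(axis=-1) * lam_rot
    dsm_tr_b = (d_tr * d_tr).sum(axis=-1).mean(axis=-1) * lam_tr

    # auxiliary structure losses, gated at t < T/4
    gate = (t < lw.aux_time_fraction * T).astype(np.float32)
    locals_ = np.stack([LOCAL_N, np.zeros(3), LOCAL_C]).astype(np.float32)
    bb_hat = einsum("bnij,aj->bnai", R0h, locals_) + v0h.reshape(B, n, 1, 3)
    bb_true = np.einsum("bnij,aj->bnai", R0, locals_) + v0[:, :, None, :]
    bb_b = ((bb_hat - Tensor(bb_true.astype(np.float32))) ** 2.0).sum(axis=-1).mean(axis=(-1, -2))

    dv = v0h.reshape(B, n, 1, 3) - v0h.reshape(B, 1, n, 3)
    dhat = ((dv * dv).sum(axis=-1) + 1e-8).sqrt()
    dtrue = np.sqrt(((v0[:, :, None, :] - v0[:, None, :, :]) ** 2).sum(-1) + 1e-8)
    off = (~np.eye(n, dtype=bool)).astype(np.float32)
    dist_b = (((dhat - Tensor(dtrue.astype(np.float32))) ** 2.0) * off).sum(axis=(-1, -2)) \
        * (1.0 / off.sum())

    loss = (dsm_rot_b + dsm_tr_b
            + (bb_b * gate) * lw.omega1 + (dist_b * gate) * lw.omega2).mean()
    loss.backward()
    grads = {k: tt.grad for k, tt in pview.tensors().items() if tt.grad is not None}

    report = LossReport(
        float(dsm_rot_b.data.mean()),
        float(dsm_tr_b.data.mean()),
        float((bb_b.data * gate).mean()),
        float((dist_b.data * gate).mean()),
        float(loss.data),
        float(t.mean()),
    )
    return report, grads


def train(
    dataset,
    config: TrainConfig,
    weights_out: str | Path | None = None,
    seed: int = 0,
    params: dict | None = None,
    so3_sched: so3.SO3Schedule | None = None,
    r3_sched: r3.VPSchedule | None = None,
    table: so3.IGSO3Table | None = None,
    log_path: str | Path | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Optimize the denoiser on a dataset of conformations.

    dataset: iterable of BackboneConformation (with .sequence), FrameSet
    tuples (seq, frames/conf).  Returns (weights, training log).
    Deterministic for a fixed seed.
    """
    so3_sched = so3_sched or so3.SO3Schedule()
    r3_sched = r3_sched or r3.VPSchedule()
    table = table or so3.default_table()
    items = _prepare_dataset(dataset)
    rng = np.random.default_rng(seed)
    if params is None:
        params = net.init_params(config.network, seed=seed)
    else:
        params = {k: v.copy() for k, v in params.items()}
    state: dict = {}
    rows = []
    t_start = time.time()
    for step in range(1, config.n_steps + 1):
        report, grads = training_step(
            params, items, config, rng, so3_sched, r3_sched, table)
        if not np.isfinite(report.total):
            if weights_out is not None:
                net.save_weights(weights_out, params, config.network)
            raise RuntimeError(
                f"non-finite loss at step {step}; last checkpoint saved"
                if weights_out else f"non-finite loss at step {step}")
        gnorm = _clip_grads(grads, config.grad_clip)
        _adam_step(params, grads, state, config.learning_rate, step)
        if step % config.log_every == 0 or step == 1 or step == config.n_steps:
            rows.append({
                "step": step, "t_mean": report.t, "dsm_rot": report.dsm_rot,
                "dsm_trans": report.dsm_trans, "bb_mse": report.bb_mse,
                "dist_mse": report.dist_mse, "total": report.total,
                "grad_norm": gnorm, "wall_s": time.time() - t_start,
            })
        if config.checkpoint_every and step % config.checkpoint_every == 0 and weights_out:
            net.save_weights(weights_out, params, config.network)
    log = pd.DataFrame(rows)
    if weights_out is not None:
        net.save_weights(weights_out, params, config.network)
        if log_path is None:
            log_path = Path(weights_out).with_suffix(".log.csv")
    if log_path is not None:
        log.to_csv(log_path, index=False)
    return params, log
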