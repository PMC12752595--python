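"""Sequence-conditioned denoising network over backbone frames.

Architecture: an initialization block builds a per-residue single
representation s0 (residue-type embedding + sinusoidal position encoding +
sinusoidal time encoding) and a pair representation z0 (binned relative
positions + broadcast single features); a stack of denoising blocks then
refines the representations and the frames.  Each block runs invariant
point attention (IPA) over the current frames, a small transformer for
long-range context, a feed-forward transition, a pair update from the
outer combination of single representations, and finally predicts a
per-residue frame update (small-angle rotation + translation in the local
frame) applied right-multiplicatively.

All scalar representations are invariant and the output frames are
equivariant under global rigid motions; this holds by construction because
coordinates enter only through frame-relative quantities.

The network predicts *denoised* frames T0_hat; rotation/translation scores
are derived from T0_hat through the analytic perturbation kernels (see
``training.predicted_scores`` for the differentiable path).

Weights live in a flat ``{name: ndarray}`` dict (float32) and are saved as
an ``.npz`` archive with the config embedded as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, einsum, layer_norm, softmax
from .geometry import AMINO_ACIDS, FrameSet

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS + "X")}
N_AA = len(_AA_INDEX)


@dataclass(frozen=True)
class NetworkConfig:
    single_channels: int = 256
    pair_channels: int = 128
    hidden_channels: int = 256      # per-head IPA scalar channels
    ipa_layers: int = 4
    transformer_layers: int = 2
    heads: int = 8
    ffn_channels: int = 1024
    query_points: int = 4
    value_points: int = 8
    relpos_clip: int = 32
    time_channels: int = 64

    def __post_init__(self) -> None:
        if self.single_channels % self.heads:
            raise ValueError("single_channels must be divisible by heads")

    @staticmethod
    def desk() -> "NetworkConfig":
        """Small CPU-friendly preset with the same topology."""
        return NetworkConfig(
            single_channels=64,
            pair_channels=32,
            hidden_channels=64,
            ipa_layers=2,
            transformer_layers=1,
            heads=4,
            ffn_channels=128,
            query_points=4,
            value_points=4,
            time_channels=32,
        )


# -- parameter initialization --------------------------------------------------

def _linear_params(params, rng, name, d_in, d_out, zero=False, scale=None):
    if zero:
        w = np.zeros((d_in, d_out))
    else:
        s = scale if scale is not None else np.sqrt(1.0 / d_in)
        w = rng.normal(0.0, s, size=(d_in, d_out))
    params[f"{name}.w"] = w.astype(np.float32)
    params[f"{name}.b"] = np.zeros(d_out, dtype=np.float32)


def _ln_params(params, name, d):
    params[f"{name}.g"] = np.ones(d, dtype=np.float32)
    params[f"{name}.b"] = np.zeros(d, dtype=np.float32)


def init_params(config: NetworkConfig, seed: int = 0) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    p: dict[str, np.ndarray] = {}
    cs, cz, ch = config.single_channels, config.pair_channels, config.hidden_channels
    H, Pq, Pv = config.heads, config.query_points, config.value_points
    n_bins = 2 * config.relpos_clip + 1

    p["embed.aa"] = (rng.normal(0, 0.5, size=(N_AA, cs))).astype(np.float32)
    _linear_params(p, rng, "init.s", cs + config.time_channels, cs)
    _ln_params(p, "init.s_ln", cs)
    _linear_params(p, rng, "init.relpos", n_bins, cz)
    _linear_params(p, rng, "init.z_i", cs, cz)
    _linear_params(p, rng, "init.z_j", cs, cz)
    _ln_params(p, "init.z_ln", cz)

    for l in range(config.ipa_layers):
        b = f"block{l}"
        _linear_params(p, rng, f"{b}.ipa.q", cs, H * ch)
        _linear_params(p, rng, f"{b}.ipa.k", cs, H * ch)
        _linear_params(p, rng, f"{b}.ipa.v", cs, H * ch)
        _linear_params(p, rng, f"{b}.ipa.qp", cs, H * Pq * 3, scale=0.05)
        _linear_params(p, rng, f"{b}.ipa.kp", cs, H * Pq * 3, scale=0.05)
        _linear_params(p, rng, f"{b}.ipa.vp", cs, H * Pv * 3, scale=0.05)
        _linear_params(p, rng, f"{b}.ipa.bias", cz, H)
        p[f"{b}.ipa.head_w"] = np.zeros(H, dtype=np.float32)  # softplus -> ~0.69
        out_dim = H * (cz + ch + Pv * 4)
        _linear_params(p, rng, f"{b}.ipa.out", out_dim, cs)
        _ln_params(p, f"{b}.ipa.ln", cs)

        for tl in range(config.transformer_layers):
            tb = f"{b}.tf{tl}"
            _ln_params(p, f"{tb}.ln1", cs)
            _linear_params(p, rng, f"{tb}.q", cs, cs)
            _linear_params(p, rng, f"{tb}.k", cs, cs)
            _linear_params(p, rng, f"{tb}.v", cs, cs)
            _linear_params(p, rng, f"{tb}.out", cs, cs)
            _ln_params(p, f"{tb}.ln2", cs)
            _linear_params(p, rng, f"{tb}.ff1", cs, config.ffn_channels)
            _linear_params(p, rng, f"{tb}.ff2", config.ffn_channels, cs)

        _ln_params(p, f"{b}.trans.ln", cs)
        _linear_params(p, rng, f"{b}.trans.ff1", cs, config.ffn_channels)
        _linear_params(p, rng, f"{b}.trans.ff2", config.ffn_channels, cs)

        if l < config.ipa_layers - 1:  # the last block's pair output is unused
            _linear_params(p, rng, f"{b}.pair.a", cs, cz)
            _linear_params(p, rng, f"{b}.pair.b", cs, cz)
            _ln_params(p, f"{b}.pair.ln", cz)

        _linear_params(p, rng, f"{b}.frame", cs, 6, zero=True)
    return p


def n_parameters(params: dict[str, np.ndarray]) -> int:
    return int(sum(v.size for v in params.values()))


# -- weight archives -----------------------------------------------------------

def save_weights(path: str | Path, params: dict[str, np.ndarray], config: NetworkConfig) -> None:
    meta = json.dumps(asdict(config))
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **params)


def load_weights(path: str | Path) -> tuple[dict[str, np.ndarray], NetworkConfig]:
    with np.load(path) as arc:
        meta = json.loads(bytes(arc["__config__"]).decode())
        params = {k: arc[k] for k in arc.files if k != "__config__"}
    return params, NetworkConfig(**meta)


# -- feature construction ------------------------------------------------------

def _sinusoidal(x: np.ndarray, channels: int, max_period: float = 10000.0) -> np.ndarray:
    half = channels // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    ang = np.asarray(x, dtype=np.float64)[..., None] * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=-1).astype(np.float32)


def sequence_indices(seq: str) -> np.ndarray:
    """Map a sequence to embedding indices; unknown letters fall back to 'X'."""
    import warnings

    idx = np.empty(len(seq), dtype=int)
    for i, c in enumerate(seq.upper()):
        if c not in _AA_INDEX:
            warnings.warn(f"unknown residue letter {c!r}; treating as 'X'")
            c = "X"
        idx[i] = _AA_INDEX[c]
    return idx


def embed_sequence(
    seq: str,
    params: dict[str, np.ndarray],
    config: NetworkConfig,
    external: np.ndarray | None = None,
) -> np.ndarray:
    """Default per-residue features: learned residue-type embedding plus
    sinusoidal absolute position encoding.

    `external` attaches a precomputed (n, single_channels) feature array from
    a pretrained sequence encoder (loaded from disk by the caller); it is
    added to the default features, never fetched by this package.
    """
    idx = sequence_indices(seq)
    emb = params["embed.aa"][idx]
    pos = _sinusoidal(np.arange(len(seq)), config.single_channels)
    out = emb + pos
    if external is not None:
        external = np.asarray(external, dtype=np.float32)
        if external.shape != out.shape:
            raise ValueError(
                f"external embedding shape {external.shape} != {out.shape}")
        out = out + external
    return out


def _relpos_onehot(n: int, clip: int) -> np.ndarray:
    offs = np.clip(np.arange(n)[None, :] - np.arange(n)[:, None], -clip, clip) + clip
    eye = np.eye(2 * clip + 1, dtype=np.float32)
    return eye[offs]


# -- forward pass --------------------------------------------------------------

def _linear(p, name, x: Tensor) -> Tensor:
    return x @ p[f"{name}.w"] + p[f"{name}.b"]


def _ln(p, name, x: Tensor) -> Tensor:
    return layer_norm(x, p[f"{name}.g"], p[f"{name}.b"])


class _P:
    """Dict view exposing parameters as (cached) Tensors with grad."""

    def __init__(self, params: dict[str, np.ndarray], train: bool):
        self._t = {k: Tensor(v, requires_grad=train) for k, v in params.items()}

    def __getitem__(self, k: str) -> Tensor:
        return self._t[k]

    def tensors(self):
        return self._t


def init_block(
    p,
    config: NetworkConfig,
    emb: Tensor,
    t: np.ndarray,
) -> tuple[Tensor, Tensor]:
    """Build (s0, z0) for a batch. emb: (B, n, cs) Tensor; t: (B,) diffusion times."""
    B, n, _ = emb.shape
    t_enc = _sinusoidal(np.asarray(t, dtype=float) * 100.0, config.time_channels)
    t_feat = Tensor(np.broadcast_to(
        t_enc[:, None, :], (B, n, config.time_channels)).astype(np.float32).copy())
    s_in = ad.concatenate([emb, t_feat], axis=-1)
    s0 = _ln(p, "init.s_ln", _linear(p, "init.s", s_in))

    rel = Tensor(_relpos_onehot(n, config.relpos_clip)[None])
    z = _linear(p, "init.relpos", rel)
    zi = _linear(p, "init.z_i", s0)
    zj = _linear(p, "init.z_j", s0)
    z = z + zi.reshape(B, n, 1, config.pair_channels) + zj.reshape(B, 1, n, config.pair_channels)
    z0 = _ln(p, "init.z_ln", z)
    return s0, z0


def _ipa(p, b: str, config: NetworkConfig, s: Tensor, z: Tensor,
         R: Tensor, v: Tensor) -> Tensor:
    """Invariant point attention; returns the single-repr update."""
    B, n, cs = s.shape
    H, ch = config.heads, config.hidden_channels
    Pq, Pv = config.query_points, config.value_points

    q = _linear(p, f"{b}.ipa.q", s).reshape(B, n, H, ch)
    k = _linear(p, f"{b}.ipa.k", s).reshape(B, n, H, ch)
    val = _linear(p, f"{b}.ipa.v", s).reshape(B, n, H, ch)
    logits = einsum("bnhc,bmhc->bnmh", q, k) * (1.0 / np.sqrt(ch))
    logits = logits + _linear(p, f"{b}.ipa.bias", z)

    # point attention in the global frame
    qp = _linear(p, f"{b}.ipa.qp", s).reshape(B, n, H, Pq, 3)
    kp = _linear(p, f"{b}.ipa.kp", s).reshape(B, n, H, Pq, 3)
    qp_g = einsum("bnij,bnhpj->bnhpi", R, qp) + v.reshape(B, n, 1, 1, 3)
    kp_g = einsum("bnij,bnhpj->bnhpi", R, kp) + v.reshape(B, n, 1, 1, 3)
    # ||q - k||^2 expanded to avoid materializing an (B,n,n,H,P,3) tensor
    qn = (qp_g * qp_g).sum(axis=-1).sum(axis=-1)  # (B, n, H)
    kn = (kp_g * kp_g).sum(axis=-1).sum(axis=-1)
    cross = einsum("bnhpi,bmhpi->bnmh", qp_g, kp_g)
    d2 = qn.reshape(B, n, 1, H) + kn.reshape(B, 1, n, H) - 2.0 * cross
    gamma = p[f"{b}.ipa.head_w"].softplus()
    wc = np.sqrt(2.0 / (9.0 * Pq))
    logits = logits - gamma * (0.5 * wc) * d2
    att = softmax(logits * np.sqrt(1.0 / 3.0), axis=2)

    o_scal = einsum("bnmh,bmhc->bnhc", att, val).reshape(B, n, H * ch)
    o_pair = einsum("bnmh,bnmc->bnhc", att, z).reshape(B, n, H * config.pair_channels)
    vp = _linear(p, f"{b}.ipa.vp", s).reshape(B, n, H, Pv, 3)
    vp_g = einsum("bnij,bnhpj->bnhpi", R, vp) + v.reshape(B, n, 1, 1, 3)
    o_pt_g = einsum("bnmh,bmhpi->bnhpi", att, vp_g)
    # back to the local frame: R^T (o - v)
    o_rel = o_pt_g - v.reshape(B, n, 1, 1, 3)
    o_pt = einsum("bnji,bnhpj->bnhpi", R, o_rel)
    o_norm = ((o_pt * o_pt).sum(axis=-1) + 1e-8).sqrt()
    feats = ad.concatenate(
        [o_scal, o_pair, o_pt.reshape(B, n, H * Pv * 3), o_norm.reshape(B, n, H * Pv)],
        axis=-1,
    )
    return _linear(p, f"{b}.ipa.out", feats)


def _transformer_layer(p, tb: str, config: NetworkConfig, s: Tensor) -> Tensor:
    B, n, cs = s.shape
    H = config.heads
    dh = cs // H
    x = _ln(p, f"{tb}.ln1", s)
    q = _linear(p, f"{tb}.q", x).reshape(B, n, H, dh)
    k = _linear(p, f"{tb}.k", x).reshape(B, n, H, dh)
    v = _linear(p, f"{tb}.v", x).reshape(B, n, H, dh)
    att = softmax(einsum("bnhd,bmhd->bnmh", q, k) * (1.0 / np.sqrt(dh)), axis=2)
    o = einsum("bnmh,bmhd->bnhd", att, v).reshape(B, n, cs)
    s = s + _linear(p, f"{tb}.out", o)
    x = _ln(p, f"{tb}.ln2", s)
    s = s + _linear(p, f"{tb}.ff2", _linear(p, f"{tb}.ff1", x).relu())
    return s


def _rotvec_to_matrix_t(a: Tensor) -> Tensor:
    """Differentiable Rodrigues map, a: (..., 3) -> (..., 3, 3)."""
    eps = 1e-12
    theta2 = (a * a).sum(axis=-1, keepdims=True) + eps
    theta = theta2.sqrt()
    # skew(a)
    zero = Tensor(np.zeros(a.shape[:-1], dtype=a.data.dtype))
    ax, ay, az = a[..., 0], a[..., 1], a[..., 2]
    row0 = ad.stack([zero, -az, ay], axis=-1)
    row1 = ad.stack([az, zero, -ax], axis=-1)
    row2 = ad.stack([-ay, ax, zero], axis=-1)
    K = ad.stack([row0, row1, row2], axis=-2)
    K2 = K @ K
    sin_t = theta.sin()
    cos_t = theta.cos()
    A = (sin_t / theta).reshape(*theta.shape, 1)
    Bc = ((1.0 - cos_t) / theta2).reshape(*theta2.shape, 1)
    eye = Tensor(np.broadcast_to(np.eye(3, dtype=a.data.dtype), K.shape).copy())
    return eye + A * K + Bc * K2


def forward(
    params: dict[str, np.ndarray],
    config: NetworkConfig,
    aa_index: np.ndarray,
    frames_R: np.ndarray,
    frames_v: np.ndarray,
    t: np.ndarray,
    train: bool = False,
    external: np.ndarray | None = None,
    return_reprs: bool = False,
):
    """Run init + denoising blocks.

    aa_index (B,n) residue-type indices, frames_R (B,n,3,3), frames_v (B,n,3)
    in Angstrom, t (B,).  Returns predicted denoised frames (R0_hat, v0_hat)
    as Tensors and the parameter view (for gradient collection); with
    return_reprs also the final (single, pair) representations, which are
    invariant under global rigid motions.
    """
    p = _P(params, train)
    B, n = np.asarray(aa_index).shape
    emb = p["embed.aa"][np.asarray(aa_index)]
    pos = Tensor(np.broadcast_to(
        _sinusoidal(np.arange(n), config.single_channels)[None], emb.shape).copy())
    emb = emb + pos
    if external is not None:
        emb = emb + Tensor(np.asarray(external, dtype=np.float32))
    s, z = init_block(p, config, emb, np.asarray(t))
    R = Tensor(frames_R.astype(np.float32))
    # coordinates are fed at a 0.1 scale (nm-like) to keep activations O(1)
    v = Tensor((frames_v * 0.1).astype(np.float32))

    for l in range(config.ipa_layers):
        b = f"block{l}"
        s = _ln(p, f"{b}.ipa.ln", s + _ipa(p, b, config, s, z, R, v))
        for tl in range(config.transformer_layers):
            s = _transformer_layer(p, f"{b}.tf{tl}", config, s)
        x = _ln(p, f"{b}.trans.ln", s)
        s = s + _linear(p, f"{b}.trans.ff2", _linear(p, f"{b}.trans.ff1", x).relu())

        if l < config.ipa_layers - 1:
            za = _linear(p, f"{b}.pair.a", s)
            zb = _linear(p, f"{b}.pair.b", s)
            B_, n_, cz = za.shape
            z = z + za.reshape(B_, n_, 1, cz) * zb.reshape(B_, 1, n_, cz)
            z = _ln(p, f"{b}.pair.ln", z)

        upd = _linear(p, f"{b}.frame", s)
        rotvec = upd[..., :3]
        dv = upd[..., 3:]
        R = R @ _rotvec_to_matrix_t(rotvec)
        v = v + einsum("bnij,bnj->bni", R, dv)

    if not np.isfinite(v.data).all() or not np.isfinite(R.data).all():
        raise FloatingPointError("non-finite activations in denoising stack")
    if return_reprs:
        return R, v * 10.0, p, (s, z)
    return R, v * 10.0, p


def predict(
    seq: str,
    frames_t: FrameSet,
    t: float,
    params: dict[str, np.ndarray],
    config: NetworkConfig,
    so3_sched=None,
    r3_sched=None,
    table=None,
    external_embedding: np.ndarray | None = None,
):
    """Denoise one conformation: returns (T0_hat FrameSet, rot_scores, trans_scores).

    Scores are derived from the predicted clean frames through the analytic
    perturbation kernels at time t.
    """
    from . import r3 as _r3
    from . import so3 as _so3
    from .geometry import project_rotations

    so3_sched = so3_sched or _so3.SO3Schedule()
    r3_sched = r3_sched or _r3.VPSchedule()
    table = table or _so3.default_table()

    idx = sequence_indices(seq)[None]
    ext = None if external_embedding is None else external_embedding[None]
    with ad.no_grad():
        R0, v0, _ = forward(
            params, config, idx,
            frames_t.rotations[None], frames_t.translations[None],
            np.array([t]), external=ext,
        )
    R0 = project_rotations(R0.data[0].astype(float))
    v0 = v0.data[0].astype(float)
    t0 = FrameSet(R0, v0)
    if t <= 0:
        rot_scores = np.zeros((len(R0), 3))
        trans_scores = np.zeros_like(v0)
    else:
        rot_scores = _so3.score_so3(frames_t.rotations, R0, t, so3_sched, table)
        trans_scores = _r3.score_r3(frames_t.translations, v0, t, r3_sched)
    return t0, rot_scores, trans_scores
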