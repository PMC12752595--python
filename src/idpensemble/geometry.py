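"""Backbone geometry: frame parametrization and rigid-transform algebra.

A chain conformation is represented either by Cartesian backbone coordinates
(N, CA, C, O per residue, in Angstrom) or by per-residue rigid frames
``T_j = [R_j, v_j]`` mapping idealized local atom coordinates into the global
frame, ``c_global = R_j @ c_local + v_j``.  The frame origin is the CA atom.

Frame construction follows the structure-module convention: Gram-Schmidt on
(N, CA, C) with ``e1 = normalize(C - CA)``, ``e2`` the orthonormalized
``N - CA`` component, ``e3 = e1 x e2``, and ``v = CA``.

Idealized local geometry (documented constants, single-chain, trans peptide):
N-CA 1.458 A, CA-C 1.525 A, C-N 1.329 A, C=O 1.231 A, angle N-CA-C 111.0 deg.
The carbonyl O is not carried by the frame itself; it is rebuilt from the
following residue's frame through the psi torsion (terminal residue: a fixed
psi of 180 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _R

# Idealized backbone geometry, Angstrom / degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = set(AMINO_ACIDS) | {"X"}

# Local (frame) coordinates of N, CA, C with CA at the origin, C on +x and N
# in the xy-plane -- consistent with the Gram-Schmidt construction above.
_ang = np.deg2rad(ANGLE_N_CA_C)
LOCAL_N = np.array([BOND_N_CA * np.cos(_ang), BOND_N_CA * np.sin(_ang), 0.0])
LOCAL_CA = np.zeros(3)
LOCAL_C = np.array([BOND_CA_C, 0.0, 0.0])
del _ang


class DegenerateGeometryError(ValueError):
    """Raised when backbone atoms of a residue are collinear or coincident."""


def _as_xyz(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name} must have shape (n, 3), got {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class BackboneConformation:
    """Per-residue N/CA/C/O coordinates (Angstrom) of a single chain."""

    coords_N: np.ndarray
    coords_CA: np.ndarray
    coords_C: np.ndarray
    coords_O: np.ndarray
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.coords_N = _as_xyz(self.coords_N, "coords_N")
        self.coords_CA = _as_xyz(self.coords_CA, "coords_CA")
        self.coords_C = _as_xyz(self.coords_C, "coords_C")
        self.coords_O = _as_xyz(self.coords_O, "coords_O")
        n = len(self.coords_CA)
        for name in ("coords_N", "coords_C", "coords_O"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match residue count {n}")
        if self.sequence is not None:
            if len(self.sequence) != n:
                raise ValueError("sequence length does not match residue count")
            bad = set(self.sequence) - _ALPHABET
            if bad:
                raise ValueError(f"unknown residue letters: {sorted(bad)}")

    @property
    def residue_count(self) -> int:
        return len(self.coords_CA)

    def atoms(self) -> np.ndarray:
        """All backbone atoms as an (n, 4, 3) array ordered N, CA, C, O."""
        return np.stack(
            [self.coords_N, self.coords_CA, self.coords_C, self.coords_O], axis=1
        )

    def copy(self) -> "BackboneConformation":
        return BackboneConformation(
            self.coords_N.copy(),
            self.coords_CA.copy(),
            self.coords_C.copy(),
            self.coords_O.copy(),
            self.sequence,
        )


def _check_rotations(rot: np.ndarray, tol: float = 1e-6) -> None:
    eye = np.eye(3)
    err = np.abs(rot @ np.swapaxes(rot, -1, -2) - eye).max()
    if err > tol:
        raise ValueError(f"rotation matrices not orthonormal (max error {err:.2e})")
    det = np.linalg.det(rot)
    if np.abs(det - 1.0).max() > tol:
        raise ValueError("rotation matrices must have determinant +1")


@dataclass
class FrameSet:
    """Per-residue rigid transforms: rotations (n,3,3) and translations (n,3)."""

    rotations: np.ndarray
    translations: np.ndarray

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if self.rotations.ndim != 3 or self.rotations.shape[1:] != (3, 3):
            raise ValueError("rotations must have shape (n, 3, 3)")
        if self.translations.shape != (len(self.rotations), 3):
            raise ValueError("translations must have shape (n, 3)")
        if not np.isfinite(self.translations).all():
            raise ValueError("translations contain non-finite values")
        _check_rotations(self.rotations)

    @property
    def residue_count(self) -> int:
        return len(self.rotations)

    def copy(self) -> "FrameSet":
        return FrameSet(self.rotations.copy(), self.translations.copy())


@dataclass(frozen=True)
class RigidTransform:
    """A single global rotation + translation (rho in the equivariance contract)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("RigidTransform needs a 3x3 rotation and a 3-vector")
        _check_rotations(self.rotation[None])

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """(a o b)(x) = a(b(x))."""
    return RigidTransform(a.rotation @ b.rotation, a.rotation @ b.translation + a.translation)


def inverse(t: RigidTransform) -> RigidTransform:
    rt = t.rotation.T
    return RigidTransform(rt, -rt @ t.translation)


def apply(t: RigidTransform, obj):
    """Apply a rigid transform to a conformation or a frame set (same type out)."""
    if isinstance(obj, BackboneConformation):
        f = lambda x: x @ t.rotation.T + t.translation
        return BackboneConformation(
            f(obj.coords_N), f(obj.coords_CA), f(obj.coords_C), f(obj.coords_O), obj.sequence
        )
    if isinstance(obj, FrameSet):
        return FrameSet(
            np.einsum("ij,njk->nik", t.rotation, obj.rotations),
            obj.translations @ t.rotation.T + t.translation,
        )
    raise TypeError(f"cannot apply rigid transform to {type(obj).__name__}")


def frames_from_backbone(conf: BackboneConformation) -> FrameSet:
    """Gram-Schmidt frames from N/CA/C; the frame origin is CA."""
    if conf.residue_count < 2:
        raise ValueError("need at least 2 residues to define a chain")
    u1 = conf.coords_C - conf.coords_CA
    u2 = conf.coords_N - conf.coords_CA
    n1 = np.linalg.norm(u1, axis=1)
    bad = np.where(n1 < 1e-8)[0]
    if bad.size:
        raise DegenerateGeometryError(f"coincident CA/C atoms at residue {bad[0]}")
    e1 = u1 / n1[:, None]
    u2p = u2 - (u2 * e1).sum(axis=1, keepdims=True) * e1
    n2 = np.linalg.norm(u2p, axis=1)
    bad = np.where(n2 < 1e-8)[0]
    if bad.size:
        raise DegenerateGeometryError(f"collinear N/CA/C atoms at residue {bad[0]}")
    e2 = u2p / n2[:, None]
    e3 = np.cross(e1, e2)
    rot = np.stack([e1, e2, e3], axis=-1)  # columns are the local axes
    return FrameSet(rot, conf.coords_CA.copy())


def backbone_from_frames(frames: FrameSet, sequence: str | None = None) -> BackboneConformation:
    """Rebuild N/CA/C from idealized local coordinates; O via the next frame's psi."""
    rot, trans = frames.rotations, frames.translations
    coords_N = trans + np.einsum("nij,j->ni", rot, LOCAL_N)
    coords_CA = trans.copy()
    coords_C = trans + np.einsum("nij,j->ni", rot, LOCAL_C)
    n = frames.residue_count

    # psi_i from N_{i+1}; terminal residue uses psi = 180 deg.
    psi = np.full(n, np.pi)
    if n > 1:
        psi[:-1] = dihedral(coords_N[:-1], coords_CA[:-1], coords_C[:-1], coords_N[1:])
    coords_O = place_atom(
        coords_N,
        coords_CA,
        coords_C,
        BOND_C_O,
        np.deg2rad(ANGLE_CA_C_O),
        psi - np.pi,
    )
    return BackboneConformation(coords_N, coords_CA, coords_C, coords_O, sequence)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed torsion angle(s) in radians, (-pi, pi], IUPAC sign convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - (b0 * b1).sum(axis=-1, keepdims=True) * b1
    w = b2 - (b2 * b1).sum(axis=-1, keepdims=True) * b1
    x = (v * w).sum(axis=-1)
    y = (np.cross(b1, v) * w).sum(axis=-1)
    return np.arctan2(y, x)


def place_atom(a, b, c, bond: float, angle: float, torsion) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    torsion = np.asarray(torsion, dtype=float)
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d_local = np.stack(
        [
            -bond * np.cos(angle) * np.ones_like(torsion),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ],
        axis=-1,
    )
    basis = np.stack([bc, m, n], axis=-1)
    return c + np.einsum("...ij,...j->...i", basis, d_local)


def axis_angle(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis (unit vector) and angle in [0, pi]; identity maps to axis (0,0,1)."""
    rv = _R.from_matrix(R).as_rotvec()
    ang = np.linalg.norm(rv)
    if ang < 1e-12:
        return np.array([0.0, 0.0, 1.0]), 0.0
    return rv / ang, float(ang)


def rotation_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return _R.from_rotvec(axis * angle).as_matrix()


def rotvec_to_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Batched exponential map, rotvec (..., 3) -> matrices (..., 3, 3)."""
    shape = rotvec.shape[:-1]
    flat = np.asarray(rotvec, dtype=float).reshape(-1, 3)
    return _R.from_rotvec(flat).as_matrix().reshape(*shape, 3, 3)


def matrix_to_rotvec(mats: np.ndarray) -> np.ndarray:
    shape = mats.shape[:-2]
    flat = np.asarray(mats, dtype=float).reshape(-1, 3, 3)
    return _R.from_matrix(flat).as_rotvec().reshape(*shape, 3)


def project_rotations(mats: np.ndarray) -> np.ndarray:
    """Nearest rotation matrices (special orthogonal Procrustes via SVD)."""
    u, _, vt = np.linalg.svd(mats)
    det = np.linalg.det(u @ vt)
    u = u.copy()
    u[..., :, -1] *= np.sign(det)[..., None]
    return u @ vt


def random_rotation(rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Haar-uniform rotation matrices; angle density (1 - cos w)/pi on [0, pi]."""
    if size is None:
        return _R.random(rng=rng).as_matrix()
    return _R.random(size, rng=rng).as_matrix()
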