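"""Evaluation suite for backbone conformational ensembles.

Covers the standard ensemble-quality metrics for disordered proteins:

* validity -- fraction of conformations whose consecutive CA-CA distances
  all lie strictly inside (delta_vdw, delta_bond), with
  delta_vdw = 2 * 1.7 - 0.4 A (two CA van der Waals radii minus an
  acceptable overlap) and delta_bond supplied per system (by convention the
  maximum consecutive CA distance of a reference ensemble, else 4.5 A);
* epsilon_Rg -- relative error of the ensemble-average radius of gyration
  against an experimental value, (<Rg>_pred - Rg_exp) / Rg_exp;
* RMSD of ensemble-averaged per-residue observables (chemical shifts,
  J-couplings, ...) against experimental profiles;
* backbone geometry distributions (bond lengths/angles, phi/psi/omega);
* Ramachandran basin occupancies;
* Rg-RMSD projection against a reference conformation (Kabsch
  superposition on CA);
* k-medoids clustering on the pairwise CA-RMSD matrix.

All metrics are invariant under global rigid transforms of every
conformation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation as _R

from .geometry import BackboneConformation, dihedral

#: two CA van der Waals radii (1.7 A) minus an acceptable overlap of 0.4 A
DELTA_VDW = 2 * 1.7 - 0.4
#: fallback upper bound when no reference ensemble supplies one
DELTA_BOND_FALLBACK = 4.5

# Karplus coefficients for the 3J(HN-HA) coupling, 3J = A cos^2(phi - 60) +
# B cos(phi - 60) + C (Hz); an in-house stand-in for external predictors.
KARPLUS_A, KARPLUS_B, KARPLUS_C = 6.51, -1.76, 1.60

#: default rectangular Ramachandran basins (degrees)
DEFAULT_BASINS = {
    "alpha": ((-100.0, -30.0), (-67.0, -7.0)),
    "beta_ppii": ((-180.0, -45.0), (60.0, 180.0)),
}


@dataclass(frozen=True)
class ValiditySpec:
    delta_vdw: float = DELTA_VDW
    delta_bond: float = DELTA_BOND_FALLBACK

    def __post_init__(self) -> None:
        if not 0 < self.delta_vdw < self.delta_bond:
            raise ValueError("need 0 < delta_vdw < delta_bond")

    @staticmethod
    def from_reference(reference: list[BackboneConformation]) -> "ValiditySpec":
        """delta_bond = max consecutive CA-CA distance over a reference ensemble.

        A small margin keeps the reference's own extreme bond inside the
        strict inequality.
        """
        dmax = max(
            float(np.linalg.norm(np.diff(c.coords_CA, axis=0), axis=1).max())
            for c in reference
        )
        return ValiditySpec(delta_bond=dmax + 1e-6)


@dataclass
class EnsembleReport:
    validity: float
    rg_mean: float
    epsilon_rg: float | None
    rmsd_by_observable: dict[str, float]
    ramachandran_occupancy: dict[str, float]
    cluster_populations: list[float]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def radius_of_gyration(conf: BackboneConformation, atoms: str = "backbone") -> float:
    """Unit-mass RMS distance from the centroid.

    atoms="backbone" uses N/CA/C/O; atoms="ca" restricts to CA (for
    comparisons against coarse-grained models).
    """
    if atoms == "backbone":
        xyz = conf.atoms().reshape(-1, 3)
    elif atoms == "ca":
        xyz = conf.coords_CA
    else:
        raise ValueError("atoms must be 'backbone' or 'ca'")
    centered = xyz - xyz.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def epsilon_rg(
    ensemble: list[BackboneConformation], rg_exp: float, atoms: str = "backbone"
) -> float:
    """(<Rg>_pred - Rg_exp) / Rg_exp."""
    if rg_exp <= 0:
        raise ValueError("experimental Rg must be positive")
    mean_rg = float(np.mean([radius_of_gyration(c, atoms) for c in ensemble]))
    return (mean_rg - rg_exp) / rg_exp


def rmsd_observable(pred: np.ndarray, exp: np.ndarray) -> tuple[float, int]:
    """sqrt(mean((<A>_pred - <A>_exp)^2)) over residues with data.

    NaNs in `exp` mark missing values and are excluded; returns
    (rmsd, number of residues used).
    """
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape:
        raise ValueError("prediction and experiment must have equal length")
    ok = ~np.isnan(exp) & ~np.isnan(pred)
    if not ok.any():
        raise ValueError("no residues with experimental values")
    diff = pred[ok] - exp[ok]
    return float(np.sqrt((diff**2).mean())), int(ok.sum())


def conformation_valid(conf: BackboneConformation, spec: ValiditySpec) -> bool:
    d = np.linalg.norm(np.diff(conf.coords_CA, axis=0), axis=1)
    return bool(np.all((d > spec.delta_vdw) & (d < spec.delta_bond)))


def validity(
    ensemble: list[BackboneConformation],
    spec: ValiditySpec = ValiditySpec(),
    all_pairs_clash: bool = False,
) -> float:
    """Fraction of conformations with all consecutive CA-CA distances strictly
    inside (delta_vdw, delta_bond).

    The base criterion indexes consecutive pairs only; `all_pairs_clash`
    additionally rejects any non-bonded CA pair closer than delta_vdw (an
    opt-in extension, off by default).
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    ok = 0
    for conf in ensemble:
        good = conformation_valid(conf, spec)
        if good and all_pairs_clash:
            ca = conf.coords_CA
            dm = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
            n = len(ca)
            far = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) > 1
            good = bool((dm[far] > spec.delta_vdw).all())
        ok += good
    return ok / len(ensemble)


def backbone_torsions(conf: BackboneConformation) -> pd.DataFrame:
    """phi/psi/omega per residue in degrees, NaN where undefined (chain ends
    or degenerate geometry)."""
    n = conf.residue_count
    N, CA, C = conf.coords_N, conf.coords_CA, conf.coords_C
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    omega = np.full(n, np.nan)
    if n > 1:
        phi[1:] = np.rad2deg(dihedral(C[:-1], N[1:], CA[1:], C[1:]))
        psi[:-1] = np.rad2deg(dihedral(N[:-1], CA[:-1], C[:-1], N[1:]))
        omega[:-1] = np.rad2deg(dihedral(CA[:-1], C[:-1], N[1:], CA[1:]))
    # flag degenerate torsions (collinear atom quadruples give ~zero normals)
    for arr, quads in (
        (phi, (C[:-1], N[1:], CA[1:], C[1:])),
        (psi, (N[:-1], CA[:-1], C[:-1], N[1:])),
        (omega, (CA[:-1], C[:-1], N[1:], CA[1:])),
    ):
        p0, p1, p2, p3 = quads
        n1 = np.cross(p1 - p0, p2 - p1)
        n2 = np.cross(p2 - p1, p3 - p2)
        bad = (np.linalg.norm(n1, axis=-1) < 1e-8) | (np.linalg.norm(n2, axis=-1) < 1e-8)
        if arr is phi:
            arr[1:][bad] = np.nan
        else:
            arr[:-1][bad] = np.nan
    # map to (-180, 180]
    for arr in (phi, psi, omega):
        arr[arr <= -180.0] += 360.0
    return pd.DataFrame({"residue": np.arange(n), "phi": phi, "psi": psi, "omega": omega})


def geometry_distributions(ensemble: list[BackboneConformation]) -> dict[str, pd.DataFrame]:
    """Bond lengths, bond angles and torsions pooled over the ensemble."""
    bonds, angles, torsions = [], [], []

    def _angle(a, b, c):
        u = a - b
        w = c - b
        cosang = (u * w).sum(-1) / (
            np.linalg.norm(u, axis=-1) * np.linalg.norm(w, axis=-1))
        return np.rad2deg(np.arccos(np.clip(cosang, -1, 1)))

    for m, conf in enumerate(ensemble):
        N, CA, C, O = conf.coords_N, conf.coords_CA, conf.coords_C, conf.coords_O
        for name, a, b in (
            ("N-CA", N, CA), ("CA-C", CA, C), ("C-O", C, O),
        ):
            for val in np.linalg.norm(a - b, axis=1):
                bonds.append({"model": m, "bond": name, "length": float(val)})
        for val in np.linalg.norm(C[:-1] - N[1:], axis=1):
            bonds.append({"model": m, "bond": "C-N", "length": float(val)})
        for name, vals in (
            ("N-CA-C", _angle(N, CA, C)),
            ("CA-C-N+1", _angle(CA[:-1], C[:-1], N[1:])),
            ("C-N+1-CA+1", _angle(C[:-1], N[1:], CA[1:])),
        ):
            for val in np.atleast_1d(vals):
                angles.append({"model": m, "angle": name, "degrees": float(val)})
        tor = backbone_torsions(conf)
        tor.insert(0, "model", m)
        torsions.append(tor)
    return {
        "bonds": pd.DataFrame(bonds),
        "angles": pd.DataFrame(angles),
        "torsions": pd.concat(torsions, ignore_index=True),
    }


def ramachandran_occupancy(
    ensemble: list[BackboneConformation],
    basins: dict[str, tuple[tuple[float, float], tuple[float, float]]] | None = None,
) -> dict[str, float]:
    """Fraction of (phi, psi) pairs in each rectangular basin; residues with
    undefined torsions are excluded.  'other' collects the remainder."""
    basins = basins if basins is not None else DEFAULT_BASINS
    phis, psis = [], []
    for conf in ensemble:
        tor = backbone_torsions(conf)
        ok = tor.phi.notna() & tor.psi.notna()
        phis.append(tor.phi[ok].to_numpy())
        psis.append(tor.psi[ok].to_numpy())
    phi = np.concatenate(phis)
    psi = np.concatenate(psis)
    total = len(phi)
    if total == 0:
        raise ValueError("no defined phi/psi pairs in the ensemble")
    out = {}
    assigned = np.zeros(total, dtype=bool)
    for name, ((plo, phi_hi), (slo, shi)) in basins.items():
        inb = (phi >= plo) & (phi <= phi_hi) & (psi >= slo) & (psi <= shi) & ~assigned
        out[name] = float(inb.sum()) / total
        assigned |= inb
    out["other"] = float((~assigned).sum()) / total
    return out


def j_coupling_hn_ha(phi_degrees) -> np.ndarray:
    """Karplus 3J(HN-HA) in Hz from the phi torsion (degrees)."""
    ang = np.deg2rad(np.asarray(phi_degrees, dtype=float) - 60.0)
    return KARPLUS_A * np.cos(ang) ** 2 + KARPLUS_B * np.cos(ang) + KARPLUS_C


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Best-fit (rotation+translation) RMSD between two (n,3) point sets."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    _, rssd = _R.align_vectors(x, y)
    return float(rssd / np.sqrt(len(x)))


def rg_rmsd_projection(
    ensemble: list[BackboneConformation],
    reference: BackboneConformation,
    atoms: str = "backbone",
) -> pd.DataFrame:
    """Per-conformation (Rg, CA-RMSD vs reference) pairs."""
    rows = []
    for i, conf in enumerate(ensemble):
        rows.append({
            "model": i,
            "rg": radius_of_gyration(conf, atoms),
            "rmsd": kabsch_rmsd(conf.coords_CA, reference.coords_CA),
        })
    return pd.DataFrame(rows)


def free_energy_surface(
    projection: pd.DataFrame, bins: int = 25
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """-ln(p) over a 2D (Rg, RMSD) histogram; empty bins map to NaN."""
    h, xe, ye = np.histogram2d(projection.rg, projection.rmsd, bins=bins)
    p = h / h.sum()
    with np.errstate(divide="ignore"):
        fes = -np.log(p)
    fes[~np.isfinite(fes)] = np.nan
    return fes, xe, ye


def pairwise_ca_rmsd(ensemble: list[BackboneConformation]) -> np.ndarray:
    n = len(ensemble)
    cas = [c.coords_CA for c in ensemble]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = kabsch_rmsd(cas[i], cas[j])
    return out


def cluster_ensemble(
    ensemble: list[BackboneConformation],
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    dist: np.ndarray | None = None,
) -> dict:
    """k-medoids (alternating assignment / medoid refit) on pairwise CA RMSD.

    Returns populations sorted descending with the corresponding medoid
    indices and per-conformation labels.  Deterministic for a fixed seed.
    """
    n = len(ensemble)
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n_conformations")
    if dist is None:
        dist = pairwise_ca_rmsd(ensemble)
    rng = np.random.default_rng(seed)
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.where(labels == c)[0]
            if len(members) == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    labels = np.argmin(dist[:, medoids], axis=1)
    pops = np.bincount(labels, minlength=k) / n
    order = np.argsort(-pops, kind="stable")
    return {
        "populations": pops[order].tolist(),
        "medoid_indices": medoids[order].tolist(),
        "labels": order.argsort()[labels].tolist(),
    }


def evaluate_ensemble(
    ensemble: list[BackboneConformation],
    validity_spec: ValiditySpec = ValiditySpec(),
    rg_exp: float | None = None,
    exp_observables: dict[str, np.ndarray] | None = None,
    pred_observables: dict[str, np.ndarray] | None = None,
    basins: dict | None = None,
    n_clusters: int = 3,
    cluster_seed: int = 0,
    rg_atoms: str = "backbone",
) -> EnsembleReport:
    """One-stop report: validity, Rg statistics, observable RMSDs,
    Ramachandran occupancies and cluster populations."""
    rgs = [radius_of_gyration(c, rg_atoms) for c in ensemble]
    rg_mean = float(np.mean(rgs))
    eps = None if rg_exp is None else (rg_mean - rg_exp) / rg_exp
    rmsds = {}
    if exp_observables:
        for name, exp in exp_observables.items():
            pred = (pred_observables or {}).get(name)
            if pred is None:
                raise ValueError(f"no predicted profile for observable {name!r}")
            val, n_used = rmsd_observable(pred, exp)
            rmsds[name] = val
    occ = ramachandran_occupancy(ensemble, basins)
    clusters = cluster_ensemble(ensemble, min(n_clusters, len(ensemble)), seed=cluster_seed)
    return EnsembleReport(
        validity=validity(ensemble, validity_spec),
        rg_mean=rg_mean,
        epsilon_rg=eps,
        rmsd_by_observable=rmsds,
        ramachandran_occupancy=occ,
        cluster_populations=clusters["populations"],
    )


def read_shift_table(path) -> dict[str, np.ndarray]:
    """Read a per-residue observable CSV (residue_index, observable, value)
    into {observable: dense per-residue array with NaN gaps}."""
    df = pd.read_csv(path)
    required = {"residue_index", "observable", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"shift table needs columns {sorted(required)}")
    n = int(df.residue_index.max()) + 1
    out = {}
    for name, grp in df.groupby("observable"):
        arr = np.full(n, np.nan)
        arr[grp.residue_index.to_numpy(dtype=int)] = grp.value.to_numpy(dtype=float)
        out[name] = arr
    return out
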