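"""Synthetic backbone ensembles with known statistical structure.

These generators stand in for experimental/simulation training data: chains
are grown by natural-extension-reference-frame (NeRF) placement from
idealized bond geometry, with backbone torsions drawn from wrapped-Gaussian
Ramachandran basins.  Because the generating parameters (basin means,
spreads, mixture weights, state proportions) are known exactly, every
downstream statistic -- basin occupancy, per-state radius of gyration,
validity -- has a ground truth that the evaluation suite can be checked
against.

Default basin torsions: alpha-helix (phi, psi) = (-57, -47) deg, extended
beta/ppII (-135, 145) deg, omega fixed at 180 deg (no cis peptides), torsion
spread 10 deg unless stated otherwise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    ANGLE_C_N_CA,
    ANGLE_CA_C_N,
    ANGLE_CA_C_O,
    ANGLE_N_CA_C,
    BOND_C_N,
    BOND_C_O,
    BOND_CA_C,
    BOND_N_CA,
    BackboneConformation,
    place_atom,
)
from .io import write_ensemble_pdb

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-135.0, 145.0)


@dataclass(frozen=True)
class TorsionBasinSpec:
    """A wrapped-Gaussian phi/psi basin with a mixture weight."""

    name: str
    phi_mean: float
    psi_mean: float
    phi_sd: float = 10.0
    psi_sd: float = 10.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.phi_sd <= 0 or self.psi_sd <= 0:
            raise ValueError("torsion spreads must be positive")
        if self.weight < 0:
            raise ValueError("basin weight must be nonnegative")


HELIX_BASIN = TorsionBasinSpec("helix", *HELIX_PHI_PSI)
EXTENDED_BASIN = TorsionBasinSpec("extended", *EXTENDED_PHI_PSI)


@dataclass
class FixtureEnsemble:
    """Generated conformations plus full provenance (enough to regenerate)."""

    conformations: list[BackboneConformation]
    generator_params: dict
    labels: list[str] | None = None

    def __len__(self) -> int:
        return len(self.conformations)


def build_chain_from_torsions(phi, psi, omega=None, sequence: str | None = None) -> BackboneConformation:
    """Grow an idealized backbone by NeRF from per-residue torsions (degrees).

    phi[0] and psi[-1]/omega[-1] are not geometrically meaningful (chain ends)
    but must still be supplied with matching length.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    n = len(phi)
    if len(psi) != n:
        raise ValueError("phi and psi must have equal length")
    if omega is None:
        omega = np.full(n, 180.0)
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if len(omega) != n:
        raise ValueError("omega must match phi/psi length")
    if n < 1:
        raise ValueError("need at least one residue")

    phi_r, psi_r, omega_r = map(np.deg2rad, (phi, psi, omega))
    a_ncac = np.deg2rad(ANGLE_N_CA_C)
    a_cacn = np.deg2rad(ANGLE_CA_C_N)
    a_cnca = np.deg2rad(ANGLE_C_N_CA)

    coords_N = np.empty((n, 3))
    coords_CA = np.empty((n, 3))
    coords_C = np.empty((n, 3))

    # seed residue in a canonical pose
    coords_N[0] = [0.0, 0.0, 0.0]
    coords_CA[0] = [BOND_N_CA, 0.0, 0.0]
    coords_C[0] = coords_CA[0] + BOND_CA_C * np.array(
        [-np.cos(a_ncac), np.sin(a_ncac), 0.0]
    )
    for i in range(1, n):
        coords_N[i] = place_atom(
            coords_N[i - 1], coords_CA[i - 1], coords_C[i - 1],
            BOND_C_N, a_cacn, psi_r[i - 1],
        )
        coords_CA[i] = place_atom(
            coords_CA[i - 1], coords_C[i - 1], coords_N[i],
            BOND_N_CA, a_cnca, omega_r[i - 1],
        )
        coords_C[i] = place_atom(
            coords_C[i - 1], coords_N[i], coords_CA[i],
            BOND_CA_C, a_ncac, phi_r[i],
        )
    # carbonyl O from psi (terminal: psi-like torsion 180 deg)
    psi_o = np.concatenate([psi_r[:-1], [np.pi]])
    coords_O = place_atom(
        coords_N, coords_CA, coords_C, BOND_C_O, np.deg2rad(ANGLE_CA_C_O),
        psi_o - np.pi,
    )
    return BackboneConformation(coords_N, coords_CA, coords_C, coords_O, sequence)


def ideal_helix(n: int, sequence: str | None = None) -> BackboneConformation:
    """Canonical alpha-helix, (phi, psi) = (-57, -47) deg."""
    return build_chain_from_torsions(
        np.full(n, HELIX_PHI_PSI[0]), np.full(n, HELIX_PHI_PSI[1]), sequence=sequence
    )


def extended_chain(n: int, sequence: str | None = None) -> BackboneConformation:
    """Fully extended chain, phi = psi = 180 deg."""
    return build_chain_from_torsions(np.full(n, 180.0), np.full(n, 180.0), sequence=sequence)


def _consecutive_ca_ok(conf: BackboneConformation, lo: float = 3.0, hi: float = 4.5) -> bool:
    d = np.linalg.norm(np.diff(conf.coords_CA, axis=0), axis=1)
    return bool(np.all((d > lo) & (d < hi)))


def _draw_chain(
    n_res: int,
    basins: list[TorsionBasinSpec],
    rng: np.random.Generator,
    sequence: str | None,
    reject_steric: bool,
    max_resample: int,
    steric_bounds: tuple[float, float] = (3.0, 4.5),
) -> tuple[BackboneConformation, np.ndarray]:
    weights = np.array([b.weight for b in basins], dtype=float)
    weights /= weights.sum()
    for _ in range(max_resample):
        idx = rng.choice(len(basins), size=n_res, p=weights)
        phi = np.array([rng.normal(basins[i].phi_mean, basins[i].phi_sd) for i in idx])
        psi = np.array([rng.normal(basins[i].psi_mean, basins[i].psi_sd) for i in idx])
        # wrap into (-180, 180]
        phi = (phi + 180.0) % 360.0 - 180.0
        psi = (psi + 180.0) % 360.0 - 180.0
        conf = build_chain_from_torsions(phi, psi, sequence=sequence)
        if not reject_steric or _consecutive_ca_ok(conf, *steric_bounds):
            return conf, idx
    raise RuntimeError(
        "steric resampling cap exceeded; widen the torsion basins or disable rejection"
    )


def ramachandran_mixture_ensemble(
    n_res: int,
    basins: list[TorsionBasinSpec],
    n_conf: int,
    seed: int,
    sequence: str | None = None,
    reject_steric: bool = False,
    max_resample: int = 50,
    steric_bounds: tuple[float, float] = (3.0, 4.5),
) -> FixtureEnsemble:
    """Per-residue basin draws: each residue independently picks a basin by
    weight and draws phi/psi from that basin's wrapped Gaussian.

    With idealized bond geometry and trans peptides the consecutive CA-CA
    distance is essentially fixed near 3.8 A, so the default steric bounds
    reject only pathological inputs; tighter bounds may be supplied."""
    total = sum(b.weight for b in basins)
    if abs(total - 1.0) > 1e-9:
        raise ValueError("basin weights must sum to 1")
    rng = np.random.default_rng(seed)
    confs = []
    for _ in range(n_conf):
        conf, _idx = _draw_chain(n_res, basins, rng, sequence, reject_steric,
                                 max_resample, steric_bounds)
        confs.append(conf)
    params = {
        "generator": "ramachandran_mixture_ensemble",
        "n_res": n_res,
        "n_conf": n_conf,
        "seed": seed,
        "sequence": sequence,
        "reject_steric": reject_steric,
        "basins": [dataclasses.asdict(b) for b in basins],
    }
    return FixtureEnsemble(confs, params)


def two_state_ensemble(
    n_res: int,
    p_compact: float,
    n_conf: int,
    seed: int,
    sequence: str | None = None,
    phi_sd: float = 10.0,
    psi_sd: float = 10.0,
) -> FixtureEnsemble:
    """Mixture of compact (helix-basin) and extended-basin conformations.

    Each conformation is drawn whole from one state with probability
    p_compact; ground-truth state labels are stored alongside.
    """
    if not 0 <= p_compact <= 1:
        raise ValueError("p_compact must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    helix = [dataclasses.replace(HELIX_BASIN, phi_sd=phi_sd, psi_sd=psi_sd, weight=1.0)]
    ext = [dataclasses.replace(EXTENDED_BASIN, phi_sd=phi_sd, psi_sd=psi_sd, weight=1.0)]
    confs, labels = [], []
    for _ in range(n_conf):
        compact = rng.random() < p_compact
        conf, _ = _draw_chain(n_res, helix if compact else ext, rng, sequence, False, 1)
        confs.append(conf)
        labels.append("compact" if compact else "extended")
    params = {
        "generator": "two_state_ensemble",
        "n_res": n_res,
        "p_compact": p_compact,
        "n_conf": n_conf,
        "seed": seed,
        "sequence": sequence,
        "phi_sd": phi_sd,
        "psi_sd": psi_sd,
    }
    return FixtureEnsemble(confs, params, labels)


def make_training_set(spec: dict, out_dir: str | Path) -> pd.DataFrame:
    """Write fixture PDB files + a manifest CSV consumable by the trainer.

    `spec` maps system names to generator descriptions, e.g.::

        {"systems": [{"name": "twostate64", "generator": "two_state_ensemble",
                      "n_res": 64, "p_compact": 0.5, "n_conf": 50, "seed": 7}]}
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for system in spec["systems"]:
        system = dict(system)
        name = system.pop("name")
        kind = system.pop("generator")
        if kind == "two_state_ensemble":
            ens = two_state_ensemble(**system)
        elif kind == "ramachandran_mixture_ensemble":
            basins = [TorsionBasinSpec(**b) for b in system.pop("basins")]
            ens = ramachandran_mixture_ensemble(basins=basins, **system)
        else:
            raise ValueError(f"unknown generator '{kind}'")
        path = out_dir / f"{name}.pdb"
        write_ensemble_pdb(path, ens.conformations)
        for i in range(len(ens)):
            rows.append(
                {
                    "id": f"{name}/{i}",
                    "file": path.name,
                    "model": i,
                    "n_res": ens.conformations[i].residue_count,
                    "provenance": json.dumps(ens.generator_params, sort_keys=True),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
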