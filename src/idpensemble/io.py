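"""Multi-model PDB and FASTA input/output (backbone-only, single chain).

Ensembles are exchanged as multi-model PDB files with MODEL/ENDMDL records,
backbone atoms N/CA/C/O only, occupancy 1.00 and B-factor 0.00. Residue ids
are 1-based in files; everything in memory is 0-based.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
import biotite.sequence.io.fasta as fasta

from .geometry import BackboneConformation

_BACKBONE = ("N", "CA", "C", "O")
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}

_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}
_ONE = {v: k for k, v in _THREE.items()}


def _to_atom_array(conf: BackboneConformation) -> struc.AtomArray:
    n = conf.residue_count
    arr = struc.AtomArray(4 * n)
    seq = conf.sequence or "X" * n
    coords = conf.atoms().reshape(-1, 3)
    arr.coord = coords.astype(np.float32)
    arr.chain_id = np.full(4 * n, "A")
    arr.res_id = np.repeat(np.arange(1, n + 1), 4)
    arr.res_name = np.repeat([_THREE.get(c, "UNK") for c in seq], 4)
    arr.atom_name = np.tile(np.array(_BACKBONE), n)
    arr.element = np.tile(np.array([_ELEMENTS[a] for a in _BACKBONE]), n)
    arr.hetero = np.zeros(4 * n, dtype=bool)
    arr.set_annotation("occupancy", np.ones(4 * n, dtype=np.float32))
    arr.set_annotation("b_factor", np.zeros(4 * n, dtype=np.float32))
    return arr


def write_ensemble_pdb(path: str | Path, ensemble: list[BackboneConformation]) -> None:
    """Write an ensemble as a multi-model PDB file."""
    if not ensemble:
        raise ValueError("empty ensemble")
    stack = struc.stack([_to_atom_array(c) for c in ensemble])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_ensemble_pdb(path: str | Path) -> list[BackboneConformation]:
    """Read all models of a backbone PDB file into conformations."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    out = []
    for model in stack:
        model = model[np.isin(model.atom_name, _BACKBONE) & ~model.hetero]
        res_ids = np.unique(model.res_id)
        coords = {name: [] for name in _BACKBONE}
        seq = []
        for rid in res_ids:
            res = model[model.res_id == rid]
            for name in _BACKBONE:
                sel = res[res.atom_name == name]
                if len(sel) != 1:
                    raise ValueError(f"residue {rid}: expected one {name} atom, got {len(sel)}")
                coords[name].append(sel.coord[0])
            seq.append(_ONE.get(res.res_name[0], "X"))
        out.append(
            BackboneConformation(
                np.array(coords["N"]), np.array(coords["CA"]),
                np.array(coords["C"]), np.array(coords["O"]),
                "".join(seq),
            )
        )
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences from a FASTA file, keyed by header."""
    ff = fasta.FastaFile.read(str(path))
    return {header: str(seq).upper() for header, seq in ff.items()}
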