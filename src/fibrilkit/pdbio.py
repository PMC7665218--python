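"""PDB reading/writing for assemblies and multi-model trajectories (gemmi).

Subunit labels and repeat indices are stored in the PDB segment
identifier (columns 73-76) as e.g. ``A003``; files lacking segment ids
fall back to geometric reconstruction: repeat order from the axial
coordinate and a single subunit label.  The growth axis of a loaded
assembly is estimated as the principal axis of the per-chain Calpha
centroids, oriented from the first to the last chain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import gemmi

from .structure import ATOM_COLUMNS, FibrilAssembly, TrajectoryEnsemble

__all__ = [
    "write_assembly_pdb",
    "read_assembly_pdb",
    "write_trajectory_pdb",
    "read_trajectory_pdb",
]


def _to_gemmi_model(atoms: pd.DataFrame, coords: np.ndarray, name: str) -> gemmi.Model:
    model = gemmi.Model(name)
    for chain_id, chain_atoms in atoms.groupby("chain_id", sort=False):
        chain = gemmi.Chain(str(chain_id)[:2])
        for (resnum, resname), res_atoms in chain_atoms.groupby(
            ["resnum", "resname"], sort=False
        ):
            res = gemmi.Residue()
            res.name = str(resname)
            res.seqid = gemmi.SeqId(int(resnum), " ")
            sub = res_atoms["subunit"].iloc[0]
            rep = res_atoms["repeat_index"].iloc[0]
            res.segment = f"{sub}{int(rep):03d}"[:4]
            for i in res_atoms.index:
                atom = gemmi.Atom()
                atom.name = str(atoms.at[i, "atom_name"])
                atom.element = gemmi.Element(str(atoms.at[i, "atom_name"])[0])
                atom.pos = gemmi.Position(*coords[atoms.index.get_loc(i)])
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    return model


def _structure_from(atoms: pd.DataFrame, frames: list[np.ndarray]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "fibrilkit"
    for f, coords in enumerate(frames, start=1):
        st.add_model(_to_gemmi_model(atoms, coords, str(f)))
    st.setup_entities()
    return st


def write_assembly_pdb(assembly: FibrilAssembly, path) -> None:
    atoms = assembly.atoms.reset_index(drop=True)
    st = _structure_from(atoms, [assembly.coords])
    st.write_pdb(str(path))


def write_trajectory_pdb(traj: TrajectoryEnsemble, path) -> None:
    atoms = traj.atoms.reset_index(drop=True)
    st = _structure_from(atoms, [traj.frames[f] for f in range(traj.n_frames)])
    st.write_pdb(str(path))


def _model_to_table(model: gemmi.Model) -> pd.DataFrame:
    rows = []
    for chain in model:
        for res in chain:
            seg = res.segment.strip()
            if len(seg) >= 2 and seg[1:].isdigit():
                sub, rep = seg[0], int(seg[1:])
            else:
                sub, rep = "A", -1
            for atom in res:
                rows.append(
                    (
                        chain.name,
                        sub,
                        rep,
                        res.seqid.num,
                        res.name,
                        atom.name,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                    )
                )
    return pd.DataFrame(rows, columns=ATOM_COLUMNS)


def _estimate_axis(atoms: pd.DataFrame) -> np.ndarray:
    """Growth-axis direction of a helical stack of chains.

    For a twisted stack the screw axis is the rotation axis of the rigid
    rotation relating two chains (location-independent, and immune to
    the side-to-side alternation of chain centroids under 2-fold screw
    symmetry).  Untwisted stacks fall back to the principal axis of the
    per-chain Calpha centroids.
    """
    from scipy.spatial.transform import Rotation

    ca = atoms[atoms["atom_name"] == "CA"]
    cents = ca.groupby("chain_id", sort=False)[["x", "y", "z"]].mean()
    if len(cents) < 2:
        return np.array([0.0, 0.0, 1.0])
    c1, c2 = cents.index[0], cents.index[1]
    t1 = atoms[atoms["chain_id"] == c1].set_index(["resnum", "atom_name"])
    t2 = atoms[atoms["chain_id"] == c2].set_index(["resnum", "atom_name"])
    common = t1.index.intersection(t2.index)
    axis = None
    if len(common) >= 3:
        p1 = t1.loc[common, ["x", "y", "z"]].to_numpy(float)
        p2 = t2.loc[common, ["x", "y", "z"]].to_numpy(float)
        rot, _ = Rotation.align_vectors(p2 - p2.mean(axis=0), p1 - p1.mean(axis=0))
        rotvec = rot.as_rotvec(degrees=True)
        if np.linalg.norm(rotvec) > 5.0:
            axis = rotvec / np.linalg.norm(rotvec)
    if axis is None:
        centered = cents.to_numpy(float) - cents.to_numpy(float).mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
    step = cents.loc[c2].to_numpy(float) - cents.loc[c1].to_numpy(float)
    if np.dot(step, axis) < 0:
        axis = -axis
    return axis


def read_assembly_pdb(path) -> FibrilAssembly:
    st = gemmi.read_structure(str(path))
    atoms = _model_to_table(st[0])
    if (atoms["repeat_index"] < 0).any():
        # no segment metadata: repeats from axial order within each subunit
        axis = _estimate_axis(atoms)
        ca = atoms[atoms["atom_name"] == "CA"]
        z = (ca[["x", "y", "z"]].to_numpy(float) @ axis)
        order = ca.assign(_z=z).groupby("chain_id")["_z"].mean().sort_values()
        rep_of = {c: i for i, c in enumerate(order.index)}
        atoms["repeat_index"] = atoms["chain_id"].map(rep_of)
    else:
        axis = _estimate_axis(atoms)
    return FibrilAssembly(atoms, axis, provenance="loaded")


def read_trajectory_pdb(path, frame_interval: float = 0.1) -> TrajectoryEnsemble:
    st = gemmi.read_structure(str(path))
    atoms = _model_to_table(st[0])
    frames = []
    for model in st:
        coords = _model_to_table(model)[["x", "y", "z"]].to_numpy(float)
        frames.append(coords)
    return TrajectoryEnsemble(atoms, np.stack(frames), frame_interval)
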