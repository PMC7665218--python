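"""Structure and trajectory metrics for cross-beta fibril assemblies.

Containers
----------
:class:`FibrilAssembly`
    Labelled atomic coordinates (chain, subunit, repeat index, residue)
    with a fibril growth axis.
:class:`TrajectoryEnsemble`
    Time-ordered coordinate frames over a fixed atom roster, with water
    molecules identified by residue name (HOH/WAT/TIP3).

Metrics
-------
Hydrogen-bond detection and per-trajectory occupancy, in-register
parallel beta-strand assignment, strand-tilt angles, Gln side-chain-amide
pseudo-torsions, Tyr chi2 ring-flip counting, internal-water counts and
first-passage transport times, backbone RMSD, and recovery of helical
rise/twist from stacked chains.

Hydrogen bonds use the heavy-atom donor-acceptor distance (< 3.0 A by
default) together with the deviation from linearity of the
donor-H...acceptor arrangement (< 20 degrees by default), where the
deviation is 180 degrees minus the D-H...A angle at the hydrogen.
Backbone amide hydrogens are inferred from N/CA/C(prev) geometry when
the model carries no hydrogens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .helix import HelicalParams, wrap_angle
from .seqstats import SegmentSet

__all__ = [
    "ATOM_COLUMNS",
    "BACKBONE_ATOMS",
    "WATER_RESNAMES",
    "AtomRef",
    "FibrilAssembly",
    "TrajectoryEnsemble",
    "HBondSpec",
    "TorsionSeries",
    "dihedral",
    "wrap_deg",
    "detect_hbond",
    "hbond_occupancy",
    "assign_beta_strands",
    "strand_axis_angle",
    "gln_pseudo_torsion",
    "torsion_series",
    "ring_flip_count",
    "count_waters_near",
    "mean_waters_near",
    "transport_time_10A",
    "FirstPassage",
    "backbone_rmsd",
    "measure_helical_params",
    "infer_amide_hydrogen",
]

ATOM_COLUMNS = [
    "chain_id", "subunit", "repeat_index", "resnum", "resname",
    "atom_name", "x", "y", "z",
]
BACKBONE_ATOMS = ("N", "CA", "C", "O")
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3"})

#: (chain_id, resnum, atom_name)
AtomRef = tuple[str, int, str]

_CHI_ATOMS = {
    "chi1": ("N", "CA", "CB", "CG"),
    "chi2": ("CA", "CB", "CG", "CD1"),
}


def wrap_deg(a):
    """Wrap angle(s) in degrees to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = np.mod(a, 360.0)
    out = np.where(out > 180.0, out - 360.0, out)
    out = np.where(out <= -180.0, out + 360.0, out)
    return float(out) if out.ndim == 0 else out


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) over four points.

    IUPAC sign convention: looking from p2 to p3, the angle from the
    p1-p2-p3 plane to the p2-p3-p4 plane, positive clockwise.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    ang = math.degrees(math.atan2(y, x))
    return wrap_deg(ang)


def _angle_deg(v1, v2) -> float:
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def infer_amide_hydrogen(n_pos, ca_pos, c_prev_pos, bond_length: float = 1.01):
    """Ideal backbone amide H position from N, CA and the previous C.

    The N-H bond bisects the exterior of the C(prev)-N-CA angle, in the
    peptide plane -- the standard reconstruction for models without
    hydrogens.
    """
    n_pos, ca_pos, c_prev_pos = (np.asarray(p, float) for p in (n_pos, ca_pos, c_prev_pos))
    u1 = n_pos - c_prev_pos
    u2 = n_pos - ca_pos
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    d = u1 + u2
    norm = np.linalg.norm(d)
    if norm < 1e-8:
        raise ValueError("degenerate geometry for amide H inference")
    return n_pos + bond_length * d / norm


# ---------------------------------------------------------------------------
# Containers


@dataclass
class FibrilAssembly:
    """Labelled atomic coordinates of a fibril with a growth axis.

    ``atoms`` is a DataFrame with columns chain_id, subunit, repeat_index,
    resnum (biological numbering), resname, atom_name, x, y, z (Angstrom).
    Every chain must carry a complete backbone (N, CA, C, O) for each of
    its residues.
    """

    atoms: pd.DataFrame
    growth_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    provenance: str = "built"

    def __post_init__(self) -> None:
        missing = set(ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atoms table missing columns {sorted(missing)}")
        coords = self.coords
        if not np.isfinite(coords).all():
            raise ValueError("non-finite atom positions")
        axis = np.asarray(self.growth_axis, dtype=float)
        self.growth_axis = axis / np.linalg.norm(axis)
        protein = self.atoms[~self.atoms["resname"].isin(WATER_RESNAMES)]
        for (chain, resnum), grp in protein.groupby(["chain_id", "resnum"]):
            present = set(grp["atom_name"])
            if not set(BACKBONE_ATOMS) <= present:
                raise ValueError(
                    f"incomplete backbone for {chain}:{resnum} "
                    f"(has {sorted(present)})"
                )

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    def with_coords(self, coords: np.ndarray) -> "FibrilAssembly":
        atoms = self.atoms.copy()
        atoms[["x", "y", "z"]] = np.asarray(coords, float)
        return FibrilAssembly(atoms, self.growth_axis.copy(), self.provenance)

    def index(self, ref: AtomRef) -> int:
        chain, resnum, name = ref
        mask = (
            (self.atoms["chain_id"] == chain)
            & (self.atoms["resnum"] == resnum)
            & (self.atoms["atom_name"] == name)
        )
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) == 0:
            raise KeyError(f"atom {chain}:{resnum}:{name} not found")
        return int(idx[0])

    def position(self, ref: AtomRef) -> np.ndarray:
        return self.coords[self.index(ref)]

    def chain_ids_by_axis(self, subunit: str | None = None) -> list[str]:
        """Chain ids ordered by axial Calpha-centroid coordinate."""
        atoms = self.atoms
        if subunit is not None:
            atoms = atoms[atoms["subunit"] == subunit]
        ca = atoms[atoms["atom_name"] == "CA"]
        z = ca[["x", "y", "z"]].to_numpy(float) @ self.growth_axis
        order = ca.assign(_z=z).groupby("chain_id")["_z"].mean().sort_values()
        return list(order.index)

    def subunits(self) -> list[str]:
        return sorted(self.atoms["subunit"].unique())

    def chain_ca(self, chain: str) -> pd.DataFrame:
        c = self.atoms
        return c[(c["chain_id"] == chain) & (c["atom_name"] == "CA")].sort_values("resnum")


@dataclass
class TrajectoryEnsemble:
    """Coordinate frames over a fixed atom roster.

    ``frames`` has shape (n_frames, n_atoms, 3); ``frame_interval`` is in
    nanoseconds.  Waters are rows of ``atoms`` with residue name
    HOH/WAT/TIP3 (only their oxygen positions are used by the metrics).
    """

    atoms: pd.DataFrame
    frames: np.ndarray
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError("frame atom count does not match roster")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def water_oxygen_indices(self) -> np.ndarray:
        m = self.atoms["resname"].isin(WATER_RESNAMES) & self.atoms[
            "atom_name"
        ].str.startswith("O")
        return np.flatnonzero(m.to_numpy())

    def index(self, ref: AtomRef) -> int:
        chain, resnum, name = ref
        mask = (
            (self.atoms["chain_id"] == chain)
            & (self.atoms["resnum"] == resnum)
            & (self.atoms["atom_name"] == name)
        )
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) == 0:
            raise KeyError(f"atom {chain}:{resnum}:{name} not found")
        return int(idx[0])


@dataclass(frozen=True)
class HBondSpec:
    """A donor(heavy)-acceptor pair with geometric cutoffs.

    ``hydrogen`` may name an explicit H atom; otherwise attached
    hydrogens are searched in the roster and, for backbone amides, the H
    is inferred from N/CA/C(prev) geometry when ``infer_hydrogen``.
    """

    donor: AtomRef
    acceptor: AtomRef
    distance_cutoff: float = 3.0
    linearity_cutoff: float = 20.0
    hydrogen: AtomRef | None = None
    infer_hydrogen: bool = True

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.linearity_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


def detect_hbond(
    donor_pos,
    hydrogen_pos,
    acceptor_pos,
    distance_cutoff: float = 3.0,
    linearity_cutoff: float = 20.0,
) -> bool:
    """True iff D-A distance < cutoff and D-H...A deviates from linear by < cutoff."""
    d = np.asarray(donor_pos, float)
    h = np.asarray(hydrogen_pos, float)
    a = np.asarray(acceptor_pos, float)
    if np.linalg.norm(a - d) >= distance_cutoff:
        return False
    deviation = 180.0 - _angle_deg(d - h, a - h)
    return deviation < linearity_cutoff


class _ResolvedHBond(NamedTuple):
    donor: int
    acceptor: int
    hydrogens: tuple[int, ...]   # explicit H candidate indices; empty -> infer
    infer_from: tuple[int, int, int] | None  # (N, CA, C_prev) indices


def _resolve_hbond(obj, spec: HBondSpec) -> _ResolvedHBond:
    atoms = obj.atoms
    di = obj.index(spec.donor)
    ai = obj.index(spec.acceptor)
    if spec.hydrogen is not None:
        return _ResolvedHBond(di, ai, (obj.index(spec.hydrogen),), None)
    chain, resnum, dname = spec.donor
    same_res = atoms[
        (atoms["chain_id"] == chain)
        & (atoms["resnum"] == resnum)
        & atoms["atom_name"].str.startswith("H")
    ]
    if len(same_res):
        # keep hydrogens covalently close to the donor (reference frame 0)
        ref = obj.frames[0] if isinstance(obj, TrajectoryEnsemble) else obj.coords
        hidx = np.flatnonzero(
            (atoms["chain_id"] == chain).to_numpy()
            & (atoms["resnum"] == resnum).to_numpy()
            & atoms["atom_name"].str.startswith("H").to_numpy()
        )
        near = [int(i) for i in hidx if np.linalg.norm(ref[i] - ref[di]) < 1.3]
        if near:
            return _ResolvedHBond(di, ai, tuple(near), None)
    if dname == "N" and spec.infer_hydrogen:
        try:
            ca = obj.index((chain, resnum, "CA"))
            c_prev = obj.index((chain, resnum - 1, "C"))
        except KeyError as exc:
            raise ValueError(
                f"cannot infer amide H for {chain}:{resnum}: {exc}"
            ) from exc
        return _ResolvedHBond(di, ai, (), (di, ca, c_prev))
    raise ValueError(
        f"donor {spec.donor} has no hydrogen and inference is unavailable"
    )


def _hbond_in_coords(coords: np.ndarray, rb: _ResolvedHBond, spec: HBondSpec) -> bool:
    d, a = coords[rb.donor], coords[rb.acceptor]
    if rb.hydrogens:
        return any(
            detect_hbond(d, coords[h], a, spec.distance_cutoff, spec.linearity_cutoff)
            for h in rb.hydrogens
        )
    n_i, ca_i, cp_i = rb.infer_from
    h = infer_amide_hydrogen(coords[n_i], coords[ca_i], coords[cp_i])
    return detect_hbond(d, h, a, spec.distance_cutoff, spec.linearity_cutoff)


def hbond_occupancy(traj: TrajectoryEnsemble, spec: HBondSpec) -> float:
    """Fraction of frames in which the specified hydrogen bond is present."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    rb = _resolve_hbond(traj, spec)
    found = sum(_hbond_in_coords(traj.frames[f], rb, spec) for f in range(traj.n_frames))
    return found / traj.n_frames


# ---------------------------------------------------------------------------
# Beta-strand assignment


def _axial_neighbors(assembly: FibrilAssembly) -> dict[str, tuple[str | None, str | None]]:
    out: dict[str, tuple[str | None, str | None]] = {}
    for sub in assembly.subunits():
        chains = assembly.chain_ids_by_axis(sub)
        for i, c in enumerate(chains):
            prev = chains[i - 1] if i > 0 else None
            nxt = chains[i + 1] if i < len(chains) - 1 else None
            out[c] = (prev, nxt)
    return out


def _residue_hbonded_axially(
    assembly: FibrilAssembly,
    coords: np.ndarray,
    chain: str,
    resnum: int,
    neighbors: tuple[str | None, str | None],
    distance_cutoff: float,
    linearity_cutoff: float,
) -> bool:
    """In-register criterion: this residue's N-H donates to, and its C=O
    accepts from, the same residue of the axially adjacent chains."""

    def bond(donor_chain: str, donor_res: int, acc_chain: str) -> bool:
        spec = HBondSpec(
            (donor_chain, donor_res, "N"),
            (acc_chain, donor_res, "O"),
            distance_cutoff,
            linearity_cutoff,
        )
        try:
            rb = _resolve_hbond(assembly, spec)
        except (KeyError, ValueError):
            return False
        return _hbond_in_coords(coords, rb, spec)

    donates = any(bond(chain, resnum, nb) for nb in neighbors if nb)
    accepts = any(bond(nb, resnum, chain) for nb in neighbors if nb)
    return donates and accepts


def _sidechain_sides(
    assembly: FibrilAssembly, chain: str, resnums: Sequence[int]
) -> dict[int, int | None]:
    """Side (+1/-1) of the local sheet plane for each residue's Cbeta; None for Gly."""
    axis = assembly.growth_axis
    ca = assembly.chain_ca(chain).set_index("resnum")
    sides: dict[int, int | None] = {}
    for r in resnums:
        row = assembly.atoms[
            (assembly.atoms["chain_id"] == chain) & (assembly.atoms["resnum"] == r)
        ]
        if "CB" not in set(row["atom_name"]):
            sides[r] = None  # Gly (or missing Cbeta): exempt
            continue
        lo = r - 1 if (r - 1) in ca.index else r
        hi = r + 1 if (r + 1) in ca.index else r
        if lo == hi:
            sides[r] = None
            continue
        strand_dir = (
            ca.loc[hi, ["x", "y", "z"]].to_numpy(float)
            - ca.loc[lo, ["x", "y", "z"]].to_numpy(float)
        )
        normal = np.cross(strand_dir, axis)
        nn = np.linalg.norm(normal)
        if nn < 1e-8:
            sides[r] = None
            continue
        cb = row[row["atom_name"] == "CB"][["x", "y", "z"]].to_numpy(float)[0]
        ca_pos = ca.loc[r, ["x", "y", "z"]].to_numpy(float)
        sides[r] = 1 if float(np.dot(cb - ca_pos, normal / nn)) >= 0 else -1
    return sides


def _split_by_alternation(
    run: list[int], sides: dict[int, int | None]
) -> list[tuple[int, int]]:
    """Split a candidate residue run where Cbeta side alternation fails."""
    segments: list[tuple[int, int]] = []
    start = run[0]
    last: tuple[int, int] | None = None  # (resnum, side)
    prev = run[0]
    for r in run:
        s = sides.get(r)
        if s is not None:
            if last is not None:
                expected = last[1] * (-1) ** (r - last[0])
                if s != expected:
                    segments.append((start, prev))
                    start = r
            last = (r, s)
        prev = r
    segments.append((start, run[-1]))
    return segments


def assign_beta_strands(
    assembly: FibrilAssembly,
    distance_cutoff: float = 3.0,
    linearity_cutoff: float = 20.0,
    min_length: int = 3,
) -> dict[str, SegmentSet]:
    """Beta-strand segments per interior chain of an in-register parallel stack.

    A residue belongs to a strand when its backbone N-H and C=O each form
    a hydrogen bond to the same residue of an axially adjacent chain of
    the same sheet (subunit), and successive side chains fall on
    alternating faces of the local sheet plane (Gly, having no Cbeta, is
    exempt from the alternation test).  Maximal runs of at least
    ``min_length`` residues are reported; boundary chains (missing an
    axial neighbour) are excluded.
    """
    n_max = max(
        (len(assembly.chain_ids_by_axis(s)) for s in assembly.subunits()), default=0
    )
    if n_max < 3:
        raise ValueError("need at least 3 stacked repeats per subunit")
    coords = assembly.coords
    neighbors = _axial_neighbors(assembly)
    out: dict[str, SegmentSet] = {}
    for sub in assembly.subunits():
        chains = assembly.chain_ids_by_axis(sub)
        for chain in chains[1:-1]:
            resnums = sorted(assembly.chain_ca(chain)["resnum"].tolist())
            ok = [
                r
                for r in resnums
                if _residue_hbonded_axially(
                    assembly, coords, chain, r, neighbors[chain],
                    distance_cutoff, linearity_cutoff,
                )
            ]
            if not ok:
                out[chain] = SegmentSet(())
                continue
            sides = _sidechain_sides(assembly, chain, ok)
            runs: list[list[int]] = [[ok[0]]]
            for r in ok[1:]:
                if r == runs[-1][-1] + 1:
                    runs[-1].append(r)
                else:
                    runs.append([r])
            segments = [
                seg
                for run in runs
                for seg in _split_by_alternation(run, sides)
                if seg[1] - seg[0] + 1 >= min_length
            ]
            out[chain] = SegmentSet(tuple(segments))
    return out


def _strand_direction(assembly: FibrilAssembly, chain: str, strand: tuple[int, int]) -> np.ndarray:
    a, b = strand
    ca = assembly.chain_ca(chain)
    ca = ca[(ca["resnum"] >= a) & (ca["resnum"] <= b)]
    pts = ca[["x", "y", "z"]].to_numpy(float)
    if len(pts) < 4:
        raise ValueError("strand must have >= 4 Calpha atoms")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-8:
        raise ValueError("degenerate strand (zero extent)")
    return vt[0]


def strand_axis_angle(
    assembly: FibrilAssembly,
    strand: tuple[int, int],
    mode: str = "to_axis",
    chain: str | None = None,
    chains: tuple[str, str] | None = None,
) -> float:
    """Angle (degrees, in [0, 90]) of a strand's least-squares Calpha line.

    ``to_axis``: angle between the strand line of ``chain`` (default: the
    axially central chain of the first subunit) and the growth axis.
    ``between_subunits``: angle between the strand lines of one chain
    from each subunit (default: the central chain of each).
    """
    def central(sub: str) -> str:
        ids = assembly.chain_ids_by_axis(sub)
        return ids[len(ids) // 2]

    if mode == "to_axis":
        c = chain or central(assembly.subunits()[0])
        u = _strand_direction(assembly, c, strand)
        cosang = abs(float(np.dot(u, assembly.growth_axis)))
        return math.degrees(math.acos(min(1.0, cosang)))
    if mode == "between_subunits":
        subs = assembly.subunits()
        if len(subs) < 2:
            raise ValueError("between_subunits requires two subunits")
        ca, cb = chains if chains else (central(subs[0]), central(subs[1]))
        ua = _strand_direction(assembly, ca, strand)
        ub = _strand_direction(assembly, cb, strand)
        cosang = abs(float(np.dot(ua, ub)))
        return math.degrees(math.acos(min(1.0, cosang)))
    raise ValueError("mode must be 'to_axis' or 'between_subunits'")


# ---------------------------------------------------------------------------
# Torsions


def gln_pseudo_torsion(
    obj: FibrilAssembly | TrajectoryEnsemble,
    resnum: int,
    chain_k: str,
    chain_k1: str | None = None,
    frame: int = 0,
) -> float:
    """Side-chain-amide pseudo-torsion xi of a Gln/Asn-like residue.

    Dihedral over (NE2, OE1, CA of molecule k, CA of the same residue in
    the axially next molecule k+1 of the same subunit), wrapped to
    (-180, 180].  With the amide O->N direction parallel to the growth
    direction xi is ~0; antiparallel gives ~+/-180.
    """
    if isinstance(obj, TrajectoryEnsemble):
        coords = obj.frames[frame]
        atoms = obj.atoms
        index = obj.index
    else:
        coords = obj.coords
        atoms = obj.atoms
        index = obj.index
    if chain_k1 is None:
        if not isinstance(obj, FibrilAssembly):
            raise ValueError("chain_k1 required for trajectories")
        sub = atoms.loc[atoms["chain_id"] == chain_k, "subunit"].iloc[0]
        chains = obj.chain_ids_by_axis(sub)
        i = chains.index(chain_k)
        if i + 1 >= len(chains):
            raise ValueError(f"chain {chain_k} has no axially next chain")
        chain_k1 = chains[i + 1]
    try:
        ne2 = coords[index((chain_k, resnum, "NE2"))]
        oe1 = coords[index((chain_k, resnum, "OE1"))]
        ca_k = coords[index((chain_k, resnum, "CA"))]
        ca_k1 = coords[index((chain_k1, resnum, "CA"))]
    except KeyError as exc:
        raise ValueError(f"missing atom for pseudo-torsion: {exc}") from exc
    return dihedral(ne2, oe1, ca_k, ca_k1)


@dataclass
class TorsionSeries:
    """Per-frame values (degrees, wrapped to (-180, 180]) of one torsion."""

    residue: int | str
    name: str
    values: np.ndarray
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.values = wrap_deg(np.asarray(self.values, dtype=float))


def torsion_series(
    traj: TrajectoryEnsemble,
    chain: str,
    resnum: int,
    angle: str = "chi2",
    atom_names: tuple[str, str, str, str] | None = None,
) -> TorsionSeries:
    """Extract a named side-chain torsion (chi1/chi2) or a custom 4-atom dihedral."""
    names = atom_names or _CHI_ATOMS.get(angle)
    if names is None:
        raise ValueError(f"unknown angle {angle!r}; give atom_names explicitly")
    idx = [traj.index((chain, resnum, n)) for n in names]
    vals = np.array(
        [dihedral(*(traj.frames[f][i] for i in idx)) for f in range(traj.n_frames)]
    )
    return TorsionSeries(resnum, angle, vals, traj.frame_interval)


def _circdist(a: float, b: float) -> float:
    return abs(wrap_deg(a - b))


def ring_flip_count(
    series: TorsionSeries,
    well_centers: tuple[float, float] = (100.0, -100.0),
    band: float = 45.0,
) -> int:
    """Number of aromatic ring flips in a chi2 series.

    Flips appear as transitions between the +100- and -100-degree
    centred wells.  A hysteresis scheme -- a well is entered only when
    the angle comes within ``band`` degrees of its centre -- suppresses
    chatter from values oscillating inside one well or near the barrier.
    """
    if "chi2" not in str(series.name):
        raise ValueError("ring flips are defined on chi2 series")
    state: int | None = None
    flips = 0
    for v in series.values:
        for w, center in enumerate(well_centers):
            if _circdist(v, center) <= band:
                if state is not None and state != w:
                    flips += 1
                state = w
                break
    return flips


# ---------------------------------------------------------------------------
# Water


def _center_positions(obj, centers, coords) -> np.ndarray:
    pts = []
    for c in centers:
        if isinstance(c, tuple) and len(c) == 3 and isinstance(c[0], str):
            pts.append(coords[obj.index(c)])
        else:
            pts.append(np.asarray(c, dtype=float))
    return np.vstack(pts)


def count_waters_near(
    traj: TrajectoryEnsemble,
    centers: Iterable,
    cutoff: float = 7.0,
    frame: int = 0,
) -> int:
    """Water oxygens strictly within ``cutoff`` of any centre in one frame.

    ``centers`` mixes atom references (chain, resnum, atom_name) and raw
    coordinates.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = traj.frames[frame]
    wi = traj.water_oxygen_indices
    if len(wi) == 0:
        return 0
    pts = _center_positions(traj, centers, coords)
    d = cdist(coords[wi], pts)
    return int(np.sum(d.min(axis=1) < cutoff))


def mean_waters_near(
    traj: TrajectoryEnsemble,
    center_sets: Sequence[Iterable],
    cutoff: float = 7.0,
    frames: Sequence[int] | None = None,
) -> float:
    """Water count averaged over frames and over symmetric centre sets.

    Passing one centre set per symmetric chain reproduces the averaging
    over equivalent interior molecules of the two subunits.
    """
    frames = range(traj.n_frames) if frames is None else frames
    vals = [
        count_waters_near(traj, cs, cutoff, f) for f in frames for cs in center_sets
    ]
    return float(np.mean(vals))


class FirstPassage(NamedTuple):
    mean_time: float          # ns, over uncensored molecules
    times: np.ndarray         # ns, per uncensored molecule
    n_censored: int


def transport_time_10A(
    traj: TrajectoryEnsemble,
    water_indices: Sequence[int] | None = None,
    threshold: float = 10.0,
) -> FirstPassage:
    """Mean first-passage time for waters to move ``threshold`` Angstrom.

    For each water oxygen, the first frame at which its displacement from
    its initial position reaches the threshold defines the passage time
    (frames x frame interval).  Molecules that never reach it within the
    trajectory are censored: counted, reported, and excluded from the
    mean rather than averaged in.
    """
    wi = np.asarray(
        traj.water_oxygen_indices if water_indices is None else water_indices
    )
    if len(wi) == 0:
        raise ValueError("no water molecules selected")
    disp = np.linalg.norm(traj.frames[:, wi, :] - traj.frames[0, wi, :], axis=2)
    reached = disp >= threshold
    times = []
    censored = 0
    for j in range(len(wi)):
        hits = np.flatnonzero(reached[:, j])
        if len(hits) == 0:
            censored += 1
        else:
            times.append(hits[0] * traj.frame_interval)
    if not times:
        raise ValueError("no uncensored passage events")
    t = np.asarray(times, dtype=float)
    return FirstPassage(float(t.mean()), t, censored)


# ---------------------------------------------------------------------------
# RMSD and helical-parameter measurement


def backbone_rmsd(
    coords: np.ndarray, reference: np.ndarray, superpose: bool = True
) -> float:
    """RMSD between matched coordinate sets, optionally after least-squares
    superposition (Kabsch)."""
    a = np.asarray(coords, float)
    b = np.asarray(reference, float)
    if a.shape != b.shape:
        raise ValueError("coordinate rosters do not match")
    if superpose:
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        rot, _ = Rotation.align_vectors(bc, ac)
        a = rot.apply(ac)
        b = bc
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def assembly_backbone_rmsd(
    a: FibrilAssembly, b: FibrilAssembly, superpose: bool = True,
    chains: Sequence[str] | None = None,
) -> float:
    """Backbone RMSD between two assemblies sharing an atom roster."""
    def bb(asm: FibrilAssembly) -> np.ndarray:
        t = asm.atoms
        m = t["atom_name"].isin(BACKBONE_ATOMS)
        if chains is not None:
            m &= t["chain_id"].isin(chains)
        return t[m].sort_values(["chain_id", "resnum", "atom_name"])[
            ["x", "y", "z"]
        ].to_numpy(float)

    return backbone_rmsd(bb(a), bb(b), superpose)


def measure_helical_params(assembly: FibrilAssembly) -> HelicalParams:
    """Recover rise/twist from the stacked chains of an assembly.

    Rise is the mean axial spacing of consecutive per-chain Calpha
    centroids; twist is the circular mean of the per-atom rotation about
    the growth axis between consecutive chains (radius-weighted).  The
    symmetry is labelled quasi-2-fold screw when consecutive chains
    alternate between the two subunits with a twist near 180 degrees.
    """
    chains = assembly.chain_ids_by_axis()
    if len(chains) < 3:
        raise ValueError("need at least 3 repeats to measure helical parameters")
    axis = assembly.growth_axis

    per_chain: dict[str, pd.DataFrame] = {}
    for c in chains:
        t = assembly.atoms[assembly.atoms["chain_id"] == c]
        per_chain[c] = t.set_index(["resnum", "atom_name"])[["x", "y", "z"]]

    rises = []
    sin_sum = cos_sum = 0.0
    for c1, c2 in zip(chains, chains[1:]):
        t1, t2 = per_chain[c1], per_chain[c2]
        common = t1.index.intersection(t2.index)
        if len(common) < 3:
            raise ValueError(f"chains {c1} and {c2} share too few atoms")
        p1 = t1.loc[common].to_numpy(float)
        p2 = t2.loc[common].to_numpy(float)
        ca_mask = np.array([name == "CA" for (_, name) in common])
        rises.append(float((p2[ca_mask] - p1[ca_mask]).mean(axis=0) @ axis))
        # the screw rotation angle is location-independent: superpose the
        # centred chains and read the rotation about the growth axis
        rot, _ = Rotation.align_vectors(p2 - p2.mean(axis=0), p1 - p1.mean(axis=0))
        rotvec = rot.as_rotvec(degrees=True)
        ang = math.copysign(np.linalg.norm(rotvec), float(np.dot(rotvec, axis)))
        sin_sum += math.sin(math.radians(ang))
        cos_sum += math.cos(math.radians(ang))

    rise = float(np.mean(rises))
    twist = wrap_angle(math.degrees(math.atan2(sin_sum, cos_sum)))

    subs = [
        assembly.atoms.loc[assembly.atoms["chain_id"] == c, "subunit"].iloc[0]
        for c in chains
    ]
    alternating = (
        len(set(subs)) == 2
        and all(s1 != s2 for s1, s2 in zip(subs, subs[1:]))
        and abs(abs(twist) - 180.0) <= 90.0
    )
    symmetry = "quasi-21" if alternating else "C1"
    return HelicalParams(rise, twist if twist != -180.0 else 180.0, symmetry)
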