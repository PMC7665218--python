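"""Generators for synthetic fibrils, trajectories, and measurement tables.

Every analysis stage in this package has a matching generator here that
produces inputs with known ground truth: idealized in-register parallel
cross-beta assemblies with a prescribed screw operator, trajectories
with programmed hydrogen-bond occupancies / ring-flip counts / water
placements, INEPT delay curves with known J and T2 values, and
dark-field intensity tables with a programmed mass-per-length.  All
generators are deterministic functions of their seed.

The idealized monomer is not a stereochemically faithful peptide: it is
a lattice template whose backbone N-H and C=O groups exactly satisfy the
default hydrogen-bond criteria between axially stacked copies and whose
Cbeta atoms alternate sheet faces.  That is sufficient -- and designed --
for exercising the strand-assignment, occupancy, torsion and helical
metrics without any external coordinate file.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .darkfield import TMV_MPL
from .helix import HelicalParams
from .inept import INEPTModelParams, inept_amplitude, tau_max_from_t2
from .structure import (
    ATOM_COLUMNS,
    AtomRef,
    FibrilAssembly,
    HBondSpec,
    TrajectoryEnsemble,
)

__all__ = [
    "BuilderSpec",
    "TrajectorySpec",
    "WaterPlacement",
    "ChiFlipSpec",
    "build_fibril",
    "make_ideal_sheet",
    "make_trajectory",
    "SyntheticTrajectory",
    "make_brownian_waters",
    "make_inept_curve",
    "SyntheticINEPT",
    "make_darkfield_table",
    "SyntheticDarkField",
    "place_atom",
]

_CA_SPACING = 3.5      # Angstrom between successive Calpha along a strand
_NH_LENGTH = 1.0
_O_LIFT = 1.9          # carbonyl O sits this far above the backbone plane
_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def place_atom(a, b, c, bond_length: float, bond_angle_deg: float, dihedral_deg: float):
    """Position a fourth atom with given internal coordinates (NeRF).

    Returns the point d with |d-c| = bond_length, angle(b,c,d) =
    bond_angle_deg and dihedral(a,b,c,d) = dihedral_deg.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(bond_angle_deg)
    chi = math.radians(dihedral_deg)
    d_local = bond_length * np.array(
        [
            -math.cos(theta),
            math.sin(theta) * math.cos(chi),
            -math.sin(theta) * math.sin(chi),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.stack([bc, m, n], axis=1)
    return c + frame @ d_local


def _template_atoms(
    sequence: str, template: str, numbering_offset: int
) -> list[tuple[int, str, str, np.ndarray]]:
    """Idealized chain template: list of (resnum, resname3, atom_name, xyz)."""
    from Bio.SeqUtils import seq3

    n = len(sequence)
    if template == "hairpin" and n < 6:
        raise ValueError("hairpin template needs at least 6 residues")
    half = n // 2
    atoms: list[tuple[int, str, str, np.ndarray]] = []
    for i, aa in enumerate(sequence):
        resnum = numbering_offset + i
        resname = seq3(aa).upper()
        if template == "extended" or i < half:
            base = np.array([i * _CA_SPACING, 0.0, 0.0])
            direction = 1.0
            yoff = 0.0
        else:  # return leg of the U-shape
            j = i - half
            base = np.array([(half - 1 - j) * _CA_SPACING, 9.0, 0.0])
            direction = -1.0
            yoff = 9.0
        x = base[0]
        side = 1.0 if i % 2 == 0 else -1.0
        res = {
            "N": np.array([x - direction * 1.2, yoff + 0.45, 0.0]),
            "CA": base,
            "C": np.array([x + direction * 1.2, yoff + 0.45, 0.0]),
            "O": np.array([x - direction * 1.2, yoff + 0.45, _O_LIFT]),
            "H": np.array([x - direction * 1.2, yoff + 0.45, -_NH_LENGTH]),
        }
        if aa != "G":
            res["CB"] = np.array([x, yoff + side * 1.5, 0.45])
        if aa == "S":
            res["OG"] = np.array([x, yoff + side * 2.6, 0.45])
        if aa in "QN":
            res["CG"] = np.array([x, yoff + side * 2.8, 0.45])
            res["CD"] = np.array([x, yoff + side * 4.0, 0.45])
            res["OE1" if aa == "Q" else "OD1"] = np.array(
                [x, yoff + side * 4.4, -0.6]
            )
            res["NE2" if aa == "Q" else "ND2"] = np.array(
                [x, yoff + side * 4.4, 0.6]
            )
        if aa == "Y":
            res["CG"] = np.array([x, yoff + side * 2.8, 0.45])
            res["CD1"] = place_atom(
                res["CA"], res["CB"], res["CG"], 1.4, 120.0, 100.0
            )
            res["OH"] = np.array([x, yoff + side * 5.5, 0.45])
        for name, pos in res.items():
            atoms.append((resnum, resname, name, pos))
    return atoms


def _rotz(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array(
        [[math.cos(t), -math.sin(t), 0.0], [math.sin(t), math.cos(t), 0.0], [0.0, 0.0, 1.0]]
    )


@dataclass(frozen=True)
class BuilderSpec:
    """Recipe for an idealized cross-beta assembly.

    sequence : one-letter residues of the monomer template
    params : screw operator (rise/twist per helical step and symmetry)
    n_repeats : molecules per subunit (>= 3)
    template : "extended" (single strand) or "hairpin" (U-shaped)
    axis_offset : lateral displacement (A) of the template from the screw
        axis, so that the two subunits of a 2-fold screw assembly sit on
        opposite sides of the axis instead of overlapping
    """

    sequence: str
    params: HelicalParams
    n_repeats: int = 5
    template: str = "extended"
    numbering_offset: int = 1
    axis_offset: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 3:
            raise ValueError("n_repeats must be >= 3")
        if self.template not in ("extended", "hairpin"):
            raise ValueError("template must be 'extended' or 'hairpin'")


def build_fibril(spec: BuilderSpec) -> FibrilAssembly:
    """Stack screw-transformed template copies into a fibril assembly.

    The chain at step r is the template rotated by r*twist about +z and
    translated by r*rise along +z.  Quasi-2-fold screw symmetry
    alternates subunit labels A/B each step (so same-subunit neighbours
    are 2*rise apart); C2 adds a 180-degree-rotated partner at each
    step.  Chains whose atoms approach another chain within 1.5 A raise
    a warning, not an error.
    """
    p = spec.params
    template = [
        (resnum, resname, name, pos + np.array([0.0, spec.axis_offset, 0.0]))
        for resnum, resname, name, pos in _template_atoms(
            spec.sequence, spec.template, spec.numbering_offset
        )
    ]
    rows = []
    if p.symmetry == "quasi-21":
        steps = [(s, "A" if s % 2 == 0 else "B", s // 2) for s in range(2 * spec.n_repeats)]
    elif p.symmetry == "C1":
        steps = [(s, "A", s) for s in range(spec.n_repeats)]
    else:  # C2
        steps = []
        for r in range(spec.n_repeats):
            steps.append((r, "A", r))
            steps.append((r, "B", r))
    chain_coords = []
    for ci, (s, sub, rep) in enumerate(steps):
        rot = _rotz(s * p.twist)
        if sub == "B" and p.symmetry == "C2":
            rot = rot @ _rotz(180.0)
        shift = np.array([0.0, 0.0, s * p.rise])
        chain_id = _CHAIN_IDS[ci % len(_CHAIN_IDS)]
        coords = []
        for resnum, resname, name, pos in template:
            xyz = rot @ pos + shift
            rows.append((chain_id, sub, rep, resnum, resname, name, *xyz))
            coords.append(xyz)
        chain_coords.append(np.asarray(coords))
    for c1, c2 in zip(chain_coords, chain_coords[1:]):
        if cdist(c1, c2).min() < 1.5:
            warnings.warn("adjacent chains clash (< 1.5 A)", stacklevel=2)
            break
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return FibrilAssembly(atoms, np.array([0.0, 0.0, 1.0]), provenance="built")


def make_ideal_sheet(
    n_strands: int, n_residues: int, spacing: float = 4.8, sequence: str | None = None
) -> FibrilAssembly:
    """Untwisted in-register parallel beta-sheet fixture.

    The backbone hydrogen bonds between stacked strands satisfy the
    default criteria exactly at a 4.8 A spacing (and fail for spacings
    beyond ~4.9 A, e.g. 6 A), and Cbeta atoms alternate sheet faces.
    """
    if n_strands < 3:
        raise ValueError("n_strands must be >= 3")
    seq = sequence or "S" * n_residues
    if len(seq) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    return build_fibril(
        BuilderSpec(seq, HelicalParams(spacing, 0.0, "C1"), n_repeats=n_strands)
    )


@dataclass(frozen=True)
class WaterPlacement:
    """Place ``count`` waters uniformly within ``radius`` of a centre atom/point."""

    center: AtomRef | tuple[float, float, float]
    count: int
    radius: float = 6.0


@dataclass(frozen=True)
class ChiFlipSpec:
    chain: str
    resnum: int
    flips: int
    jitter_deg: float = 5.0


@dataclass(frozen=True)
class TrajectorySpec:
    """Recipe for a synthetic trajectory around a base assembly.

    Hydrogen-bond occupancies are realized by displacing the acceptor in
    an exact-count random subset of frames (not per-frame Bernoulli), so
    the measured occupancy equals round(occupancy * n_frames)/n_frames
    deterministically.  Atoms under direct control (controlled bonds,
    telegraph side chains, placed waters) are excluded from the Gaussian
    jitter applied to everything else.
    """

    base: FibrilAssembly
    n_frames: int = 100
    frame_interval: float = 0.1
    noise_amplitude: float = 0.05
    hbond_targets: tuple[tuple[HBondSpec, float], ...] = ()
    chi2_flips: tuple[ChiFlipSpec, ...] = ()
    waters: tuple[WaterPlacement, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 10:
            raise ValueError("n_frames must be >= 10")
        for _, occ in self.hbond_targets:
            if not 0.0 <= occ <= 1.0:
                raise ValueError("occupancies must lie in [0, 1]")


class SyntheticTrajectory(NamedTuple):
    trajectory: TrajectoryEnsemble
    occupancy_truth: dict[tuple[AtomRef, AtomRef], float]
    flip_truth: dict[tuple[str, int], int]
    chi2_series_truth: dict[tuple[str, int], np.ndarray]
    water_count_truth: dict[int, int]


def make_trajectory(spec: TrajectorySpec) -> SyntheticTrajectory:
    """Generate frames with programmed occupancies, flips and waters."""
    rng = np.random.default_rng(spec.seed)
    atoms = spec.base.atoms.copy().reset_index(drop=True)
    base_coords = atoms[["x", "y", "z"]].to_numpy(float)

    # waters appended to the roster
    water_truth: dict[int, int] = {}
    water_rows = []
    water_pos = []
    wres = 1
    for pi, placement in enumerate(spec.waters):
        if isinstance(placement.center, tuple) and isinstance(placement.center[0], str):
            center = spec.base.position(placement.center)
        else:
            center = np.asarray(placement.center, dtype=float)
        for _ in range(placement.count):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            r = placement.radius * rng.random() ** (1.0 / 3.0)
            water_rows.append(("W", "W", 0, wres, "HOH", "O"))
            water_pos.append(center + r * v)
            wres += 1
        water_truth[pi] = placement.count
    if water_rows:
        wdf = pd.DataFrame(
            [(*r, *p) for r, p in zip(water_rows, water_pos)], columns=ATOM_COLUMNS
        )
        atoms = pd.concat([atoms, wdf], ignore_index=True)

    n_atoms = len(atoms)
    coords0 = np.vstack([base_coords, np.asarray(water_pos)]) if water_pos else base_coords
    frames = np.repeat(coords0[None, :, :], spec.n_frames, axis=0)

    traj = TrajectoryEnsemble(atoms, frames, spec.frame_interval)

    controlled: set[int] = set(range(len(base_coords), n_atoms))  # waters fixed

    # programmed hydrogen bonds
    occupancy_truth: dict[tuple[AtomRef, AtomRef], float] = {}
    for hb, occ in spec.hbond_targets:
        di = traj.index(hb.donor)
        ai = traj.index(hb.acceptor)
        base_d = np.linalg.norm(coords0[ai] - coords0[di])
        if base_d >= hb.distance_cutoff:
            raise ValueError(
                f"unsatisfiable occupancy: bond {hb.donor}->{hb.acceptor} "
                f"absent in the base assembly (d = {base_d:.2f} A)"
            )
        n_broken = spec.n_frames - round(occ * spec.n_frames)
        broken = rng.choice(spec.n_frames, size=n_broken, replace=False)
        direction = coords0[ai] - coords0[di]
        direction /= np.linalg.norm(direction)
        frames[broken, ai, :] = coords0[ai] + direction * (hb.distance_cutoff + 1.5)
        controlled.update({di, ai})
        # keep the donor's resolved hydrogens and inference anchors stable
        chain, resnum, _ = hb.donor
        for name in ("H", "CA"):
            try:
                controlled.add(traj.index((chain, resnum, name)))
            except KeyError:
                pass
        try:
            controlled.add(traj.index((chain, resnum - 1, "C")))
        except KeyError:
            pass
        occupancy_truth[(hb.donor, hb.acceptor)] = round(occ * spec.n_frames) / spec.n_frames

    # programmed chi2 telegraph series
    flip_truth: dict[tuple[str, int], int] = {}
    series_truth: dict[tuple[str, int], np.ndarray] = {}
    for fs in spec.chi2_flips:
        idx = {n: traj.index((fs.chain, fs.resnum, n)) for n in ("CA", "CB", "CG", "CD1")}
        if fs.flips >= spec.n_frames:
            raise ValueError("more flips than frame transitions available")
        change = np.sort(
            rng.choice(np.arange(1, spec.n_frames), size=fs.flips, replace=False)
        )
        well = int(rng.integers(0, 2))  # 0 -> +100, 1 -> -100
        centers = (100.0, -100.0)
        target = np.empty(spec.n_frames)
        nxt = 0
        for f in range(spec.n_frames):
            if nxt < len(change) and f == change[nxt]:
                well = 1 - well
                nxt += 1
            target[f] = centers[well]
        target = target + rng.normal(0.0, fs.jitter_deg, size=spec.n_frames)
        for f in range(spec.n_frames):
            frames[f, idx["CD1"], :] = place_atom(
                frames[f, idx["CA"]],
                frames[f, idx["CB"]],
                frames[f, idx["CG"]],
                1.4,
                120.0,
                target[f],
            )
        controlled.update(idx.values())
        flip_truth[(fs.chain, fs.resnum)] = fs.flips
        series_truth[(fs.chain, fs.resnum)] = target

    if spec.noise_amplitude > 0:
        free = np.array(sorted(set(range(n_atoms)) - controlled), dtype=int)
        if len(free):
            frames[:, free, :] += rng.normal(
                0.0, spec.noise_amplitude, size=(spec.n_frames, len(free), 3)
            )

    return SyntheticTrajectory(traj, occupancy_truth, flip_truth, series_truth, water_truth)


def make_brownian_waters(
    n_molecules: int,
    diffusion: float,
    n_frames: int,
    frame_interval: float = 0.1,
    seed: int = 0,
    box: float = 200.0,
) -> TrajectoryEnsemble:
    """Water-only trajectory of independent Brownian walkers.

    ``diffusion`` is in A^2/ns; per-frame Gaussian steps have standard
    deviation sqrt(2 D dt) per coordinate.  Two such ensembles with
    diffusion constants differing 100-fold model internal versus bulk
    water mobility.
    """
    rng = np.random.default_rng(seed)
    start = rng.random((n_molecules, 3)) * box
    sigma = math.sqrt(2.0 * diffusion * frame_interval)
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, n_molecules, 3))
    frames = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    atoms = pd.DataFrame(
        [("W", "W", 0, i + 1, "HOH", "O", *start[i]) for i in range(n_molecules)],
        columns=ATOM_COLUMNS,
    )
    return TrajectoryEnsemble(atoms, frames, frame_interval)


class SyntheticINEPT(NamedTuple):
    curve: pd.DataFrame
    tau1_max: float
    tau2_max: float
    params: INEPTModelParams


def make_inept_curve(
    params: INEPTModelParams,
    tau1_grid: Sequence[float],
    tau2_grid: Sequence[float],
    noise: float = 0.0,
    seed: int = 0,
) -> SyntheticINEPT:
    """Two-scan INEPT peak-area table with known ground truth.

    The tau1 scan is taken at the analytic tau2 maximum and vice versa;
    ``noise`` is the Gaussian amplitude noise (absolute units of the
    ideal-maximum-normalized amplitude).
    """
    rng = np.random.default_rng(seed)
    t1m = tau_max_from_t2(params.T2H, params.J, params.k, "H")
    t2m = tau_max_from_t2(params.T2C, params.J, params.k, "C")
    cls = "Gly" if params.k == 2 else "other"
    rows = []
    for t1 in tau1_grid:
        rows.append((float(t1), t2m, inept_amplitude(t1, t2m, params), cls))
    for t2 in tau2_grid:
        rows.append((t1m, float(t2), inept_amplitude(t1m, t2, params), cls))
    curve = pd.DataFrame(rows, columns=["tau1_ms", "tau2_ms", "area", "residue_class"])
    if noise > 0:
        curve["area"] += rng.normal(0.0, noise, size=len(curve))
    return SyntheticINEPT(curve, t1m, t2m, params)


class SyntheticDarkField(NamedTuple):
    table: pd.DataFrame
    true_mpl: float
    I_TMV: float


def make_darkfield_table(
    true_mpl: float = 41.8,
    n_fibrils: int = 96,
    n_tmv: int = 52,
    n_background: int = 20,
    noise_sd_mpl: float = 3.0,
    seed: int = 0,
    background_level: float = 1000.0,
    i_tmv: float = 500.0,
) -> SyntheticDarkField:
    """Dark-field intensity table around a programmed true MPL.

    Box intensities carry additive Gaussian noise whose scale is chosen
    so a single MPL count has standard deviation ``noise_sd_mpl`` kDa/nm
    (each count combines one centre box and two background boxes, hence
    the sqrt(3/2) factor).  The default counts mirror a realistic study
    size (96 fibril segments calibrated against 52 TMV rods).
    """
    rng = np.random.default_rng(seed)
    sigma_box = noise_sd_mpl * i_tmv / (TMV_MPL * math.sqrt(1.5))
    rows = []

    def boxes(signal: float, kind: str, label: str, i: int):
        center = background_level + signal + rng.normal(0.0, sigma_box)
        b1 = background_level + rng.normal(0.0, sigma_box)
        b2 = background_level + rng.normal(0.0, sigma_box)
        rows.append((f"{label}{i:03d}", kind, center, b1, b2))

    for i in range(n_tmv):
        boxes(i_tmv, "TMV", "tmv", i)
    for i in range(n_fibrils):
        boxes(true_mpl / TMV_MPL * i_tmv, "fibril", "fib", i)
    for i in range(n_background):
        boxes(0.0, "background", "bg", i)
    table = pd.DataFrame(
        rows, columns=["segment_id", "kind", "I_center", "I_B1", "I_B2"]
    )
    return SyntheticDarkField(table, true_mpl, i_tmv)
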