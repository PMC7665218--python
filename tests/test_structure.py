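"""Structure/trajectory metrics: H-bonds, strands, torsions, water, RMSD."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from fibrilkit import structure as st
from fibrilkit import synth
from fibrilkit.helix import HelicalParams, wrap_angle
from fibrilkit.structure import ATOM_COLUMNS


class TestDetectHBond:
    def test_inside_both_cutoffs(self):
        assert st.detect_hbond([0, 0, 0], [0, 0, 1], [0, 0, 2.9])

    def test_distance_cutoff_is_strict(self):
        assert not st.detect_hbond([0, 0, 0], [0, 0, 1], [0, 0, 3.1])
        assert not st.detect_hbond([0, 0, 0], [0, 0, 1], [0, 0, 3.0])

    def test_linearity_cutoff(self):
        # put the acceptor 25 degrees off the D-H direction, within distance
        ang = math.radians(25.0)
        acc = np.array([0, 1.9 * math.sin(ang), 1 + 1.9 * math.cos(ang)])
        assert not st.detect_hbond([0, 0, 0], [0, 0, 1], acc, linearity_cutoff=20.0)
        assert st.detect_hbond([0, 0, 0], [0, 0, 1], acc, linearity_cutoff=30.0)


class TestOccupancy:
    def test_always_bonded(self, ideal_sheet):
        sy = synth.make_trajectory(
            synth.TrajectorySpec(ideal_sheet, n_frames=20, noise_amplitude=0.0, seed=0)
        )
        occ = st.hbond_occupancy(
            sy.trajectory, st.HBondSpec(("C", 3, "N"), ("B", 3, "O"))
        )
        assert occ == 1.0

    def test_programmed_occupancy(self, ideal_sheet):
        hb = st.HBondSpec(("C", 3, "N"), ("B", 3, "O"))
        sy = synth.make_trajectory(
            synth.TrajectorySpec(
                ideal_sheet, n_frames=500, hbond_targets=((hb, 0.6),), seed=3
            )
        )
        assert st.hbond_occupancy(sy.trajectory, hb) == pytest.approx(0.6, abs=1e-12)

    def test_matches_brute_force_scan(self, ideal_sheet):
        """Independent per-frame re-implementation on a small fuzz trajectory."""
        hb = st.HBondSpec(("C", 4, "N"), ("B", 4, "O"))
        sy = synth.make_trajectory(
            synth.TrajectorySpec(
                ideal_sheet,
                n_frames=20,
                noise_amplitude=0.3,
                hbond_targets=((hb, 0.55),),
                seed=8,
            )
        )
        tr = sy.trajectory
        di = tr.index(hb.donor)
        hi = tr.index(("C", 4, "H"))
        ai = tr.index(hb.acceptor)
        brute = 0
        for f in range(tr.n_frames):
            d, h, a = tr.frames[f][di], tr.frames[f][hi], tr.frames[f][ai]
            dist_ok = np.linalg.norm(a - d) < 3.0
            v1, v2 = d - h, a - h
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            dev = 180.0 - math.degrees(math.acos(max(-1, min(1, cosang))))
            brute += bool(dist_ok and dev < 20.0)
        assert st.hbond_occupancy(tr, hb) == pytest.approx(brute / tr.n_frames)

    def test_symmetric_pair_average_equals_mean(self, ideal_sheet):
        hb1 = st.HBondSpec(("C", 3, "N"), ("B", 3, "O"))
        hb2 = st.HBondSpec(("C", 5, "N"), ("B", 5, "O"))
        sy = synth.make_trajectory(
            synth.TrajectorySpec(
                ideal_sheet,
                n_frames=100,
                hbond_targets=((hb1, 0.8), (hb2, 0.4)),
                seed=4,
            )
        )
        o1 = st.hbond_occupancy(sy.trajectory, hb1)
        o2 = st.hbond_occupancy(sy.trajectory, hb2)
        assert (o1 + o2) / 2 == pytest.approx(0.6, abs=1e-12)

    def test_empty_trajectory_rejected(self, ideal_sheet):
        tr = st.TrajectoryEnsemble(
            ideal_sheet.atoms, np.empty((0, len(ideal_sheet.atoms), 3))
        )
        with pytest.raises(ValueError):
            st.hbond_occupancy(tr, st.HBondSpec(("C", 3, "N"), ("B", 3, "O")))

    def test_inferred_amide_hydrogen_used_when_absent(self):
        # bespoke geometry: the exterior bisector of C(prev)-N-CA points
        # along -y, straight at an acceptor 2.9 A away
        rows = [
            ("X", "A", 0, 1, "SER", "C", -1.2, 0.8, 0.0),
            ("X", "A", 0, 2, "SER", "N", 0.0, 0.0, 0.0),
            ("X", "A", 0, 2, "SER", "CA", 1.2, 0.8, 0.0),
            ("Y", "A", 1, 2, "SER", "O", 0.0, -2.9 + 1e-3, 0.0),
        ]
        atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
        tr = st.TrajectoryEnsemble(atoms, atoms[["x", "y", "z"]].to_numpy()[None])
        occ = st.hbond_occupancy(tr, st.HBondSpec(("X", 2, "N"), ("Y", 2, "O")))
        assert occ == 1.0
        # a donor whose preceding C is absent cannot be inferred
        with pytest.raises(ValueError):
            st.hbond_occupancy(tr, st.HBondSpec(("X", 2, "CA"), ("Y", 2, "O")))


class TestStrandAssignment:
    def test_ideal_sheet_single_strand_on_interior_chains(self, ideal_sheet):
        strands = st.assign_beta_strands(ideal_sheet)
        assert set(strands) == {"B", "C", "D"}  # boundary chains excluded
        for segs in strands.values():
            assert segs.segments == ((1, 10),)

    def test_wide_spacing_breaks_hbonds(self):
        sheet = synth.make_ideal_sheet(5, 10, 6.0)
        strands = st.assign_beta_strands(sheet)
        assert all(len(s.segments) == 0 for s in strands.values())

    def test_randomized_coil_has_no_strands(self, rng):
        sheet = synth.make_ideal_sheet(4, 8, 4.8)
        coil = sheet.with_coords(rng.uniform(-20, 20, size=sheet.coords.shape))
        strands = st.assign_beta_strands(coil)
        assert all(len(s.segments) == 0 for s in strands.values())

    def test_minimal_sheet(self):
        sheet = synth.make_ideal_sheet(3, 3, 4.8)
        strands = st.assign_beta_strands(sheet)
        assert strands["B"].segments == ((1, 3),)

    def test_too_few_repeats_rejected(self, ideal_sheet):
        two = ideal_sheet.atoms[ideal_sheet.atoms["chain_id"].isin(["A", "B"])]
        asm = st.FibrilAssembly(two.reset_index(drop=True))
        with pytest.raises(ValueError):
            st.assign_beta_strands(asm)

    def test_gly_exempt_from_alternation(self):
        sheet = synth.make_ideal_sheet(5, 9, 4.8, sequence="SSGSGSSSS")
        strands = st.assign_beta_strands(sheet)
        assert strands["C"].segments == ((1, 9),)


def tilted_two_subunit_assembly(tilt_deg=6.0):
    """Strands tilted off perpendicular by +/-tilt on the two subunits."""
    rows = []
    for sub, sign, y0, ids in (("A", 1, -5.0, "ABC"), ("B", -1, 5.0, "DEF")):
        u = np.array(
            [math.cos(math.radians(tilt_deg)), 0, sign * math.sin(math.radians(tilt_deg))]
        )
        for ci in range(3):
            origin = np.array([0.0, y0, ci * 4.8])
            for r in range(1, 7):
                ca = origin + r * 3.5 * u
                for name, off in (
                    ("N", [-1.2, 0.4, 0]),
                    ("CA", [0, 0, 0]),
                    ("C", [1.2, 0.4, 0]),
                    ("O", [-1.2, 0.4, 1.9]),
                ):
                    rows.append((ids[ci], sub, ci, r, "SER", name, *(ca + np.array(off))))
    return st.FibrilAssembly(pd.DataFrame(rows, columns=ATOM_COLUMNS))


class TestStrandAxisAngle:
    def test_parallel_and_perpendicular_limits(self):
        asm = tilted_two_subunit_assembly(90.0)  # strand along the axis
        assert st.strand_axis_angle(asm, (1, 6), "to_axis") == pytest.approx(0.0, abs=1e-6)
        asm = tilted_two_subunit_assembly(0.0)
        assert st.strand_axis_angle(asm, (1, 6), "to_axis") == pytest.approx(90.0, abs=1e-6)

    def test_opposite_tilts_reproduce_84_and_12(self):
        asm = tilted_two_subunit_assembly(6.0)
        assert st.strand_axis_angle(asm, (1, 6), "to_axis") == pytest.approx(84.0, abs=0.01)
        assert st.strand_axis_angle(asm, (1, 6), "between_subunits") == pytest.approx(
            12.0, abs=0.01
        )

    def test_too_few_calpha_rejected(self):
        asm = tilted_two_subunit_assembly(6.0)
        with pytest.raises(ValueError):
            st.strand_axis_angle(asm, (1, 3), "to_axis")


class TestPseudoTorsion:
    def test_amide_parallel_to_growth_gives_zero(self):
        ca_k, ca_k1 = np.array([0, 0, 0.0]), np.array([0, 0, 4.8])
        oe1 = np.array([3.0, 0, 0.5])
        xi = st.dihedral(oe1 + [0, 0, 1.23], oe1, ca_k, ca_k1)
        assert xi == pytest.approx(0.0, abs=1e-9)

    def test_amide_antiparallel_gives_180(self):
        ca_k, ca_k1 = np.array([0, 0, 0.0]), np.array([0, 0, 4.8])
        oe1 = np.array([3.0, 0, 0.5])
        xi = st.dihedral(oe1 - [0, 0, 1.23], oe1, ca_k, ca_k1)
        assert abs(xi) == pytest.approx(180.0, abs=1e-9)

    def test_cis_trans_limits_of_planar_points(self):
        a, b, c = [0, 1, 0], [0, 0, 0], [1, 0, 0]
        assert st.dihedral(a, b, c, [1, 1, 0]) == pytest.approx(0.0, abs=1e-9)
        assert abs(st.dihedral(a, b, c, [1, -1, 0])) == pytest.approx(180.0, abs=1e-9)

    def test_on_built_fibril_near_zero(self, quasi21_fibril):
        xi = st.gln_pseudo_torsion(quasi21_fibril, 2, "A")
        assert abs(xi) < 5.0  # template amide O->N points along +z

    def test_missing_atoms_rejected(self, quasi21_fibril):
        with pytest.raises(ValueError):
            st.gln_pseudo_torsion(quasi21_fibril, 1, "A")  # Ser: no NE2

    def test_wraparound_invariance(self):
        vals = np.array([170.0, 185.0, -170.0, 360.0 + 45.0])
        ts = st.TorsionSeries(1, "chi2", vals)
        assert np.all(ts.values > -180.0) and np.all(ts.values <= 180.0)
        assert ts.values[1] == pytest.approx(-175.0)
        assert ts.values[3] == pytest.approx(45.0)


class TestRingFlips:
    def test_constant_series(self):
        assert st.ring_flip_count(st.TorsionSeries(1, "chi2", np.full(100, 100.0))) == 0

    def test_oscillation_within_one_well(self, rng):
        vals = 100.0 + 30.0 * np.sin(np.linspace(0, 20, 200))
        assert st.ring_flip_count(st.TorsionSeries(1, "chi2", vals)) == 0

    def test_programmed_telegraph_flips(self, ideal_sheet):
        sy = synth.make_trajectory(
            synth.TrajectorySpec(
                ideal_sheet,
                n_frames=300,
                chi2_flips=(synth.ChiFlipSpec("C", 5, 7),),
                seed=6,
            )
        )
        series = st.torsion_series(sy.trajectory, "C", 5, "chi2")
        assert st.ring_flip_count(series) == 7

    def test_non_chi2_series_rejected(self):
        with pytest.raises(ValueError):
            st.ring_flip_count(st.TorsionSeries(1, "chi1", np.zeros(10)))


class TestWaterCounting:
    def test_strict_cutoff(self):
        atoms = pd.DataFrame(
            [
                ("W", "W", 0, 1, "HOH", "O", 6.9, 0.0, 0.0),
                ("W", "W", 0, 2, "HOH", "O", 7.1, 0.0, 0.0),
            ],
            columns=ATOM_COLUMNS,
        )
        tr = st.TrajectoryEnsemble(atoms, atoms[["x", "y", "z"]].to_numpy()[None])
        assert st.count_waters_near(tr, [np.zeros(3)], 7.0) == 1

    def test_placed_pore_waters(self, ideal_sheet):
        sy = synth.make_trajectory(
            synth.TrajectorySpec(
                ideal_sheet,
                n_frames=10,
                waters=(synth.WaterPlacement(("C", 3, "OG"), 12, 6.0),),
                seed=2,
            )
        )
        assert st.count_waters_near(sy.trajectory, [("C", 3, "OG")], 7.0) == 12

    def test_monotone_in_cutoff_and_rotation_invariant(self, ideal_sheet, rng):
        sy = synth.make_trajectory(
            synth.TrajectorySpec(
                ideal_sheet,
                n_frames=10,
                waters=(synth.WaterPlacement(("C", 3, "OG"), 20, 6.5),),
                seed=13,
            )
        )
        tr = sy.trajectory
        counts = [st.count_waters_near(tr, [("C", 3, "OG")], c) for c in (3.0, 5.0, 7.0)]
        assert counts == sorted(counts)
        rot = Rotation.random(rng=rng).as_matrix()
        rotated = st.TrajectoryEnsemble(tr.atoms, tr.frames @ rot.T, tr.frame_interval)
        assert st.count_waters_near(rotated, [("C", 3, "OG")], 5.0) == counts[1]

    def test_mean_over_symmetric_chains(self, ideal_sheet):
        # centres far enough apart (9.6 A) that the 3 A placement radius
        # plus the 3.5 A cutoff cannot leak waters between the two sets
        sy = synth.make_trajectory(
            synth.TrajectorySpec(
                ideal_sheet,
                n_frames=10,
                waters=(
                    synth.WaterPlacement(("B", 3, "OG"), 10, 3.0),
                    synth.WaterPlacement(("D", 3, "OG"), 6, 3.0),
                ),
                seed=3,
            )
        )
        mean = st.mean_waters_near(
            sy.trajectory, [[("B", 3, "OG")], [("D", 3, "OG")]], 3.5
        )
        assert mean == pytest.approx(8.0)


class TestTransportTimes:
    def test_ballistic_motion(self):
        n_frames, v = 40, 1.0  # 1 A per frame
        pos = np.zeros((n_frames, 1, 3))
        pos[:, 0, 0] = v * np.arange(n_frames)
        atoms = pd.DataFrame(
            [("W", "W", 0, 1, "HOH", "O", 0.0, 0.0, 0.0)], columns=ATOM_COLUMNS
        )
        tr = st.TrajectoryEnsemble(atoms, pos, frame_interval=0.5)
        res = st.transport_time_10A(tr)
        assert res.mean_time == pytest.approx(10 * 0.5)

    def test_stationary_water_censored(self):
        atoms = pd.DataFrame(
            [
                ("W", "W", 0, 1, "HOH", "O", 0.0, 0.0, 0.0),
                ("W", "W", 0, 2, "HOH", "O", 5.0, 0.0, 0.0),
            ],
            columns=ATOM_COLUMNS,
        )
        frames = np.zeros((30, 2, 3))
        frames[:, 1, 0] = 5.0 + np.arange(30)  # second water moves
        tr = st.TrajectoryEnsemble(atoms, frames, frame_interval=1.0)
        res = st.transport_time_10A(tr)
        assert res.n_censored == 1
        assert len(res.times) == 1

    def test_internal_vs_bulk_ratio_at_least_10(self):
        slow = synth.make_brownian_waters(40, 1.0, 400, 0.1, seed=100)
        fast = synth.make_brownian_waters(40, 100.0, 400, 0.1, seed=101)
        ratio = st.transport_time_10A(slow).mean_time / st.transport_time_10A(fast).mean_time
        assert ratio >= 10.0


class TestRMSD:
    def test_identical_structures(self, ideal_sheet):
        assert st.assembly_backbone_rmsd(ideal_sheet, ideal_sheet) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_rigid_translation(self, ideal_sheet):
        moved = ideal_sheet.with_coords(ideal_sheet.coords + [3.0, -2.0, 1.0])
        assert st.assembly_backbone_rmsd(moved, ideal_sheet, superpose=True) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_uniform_displacement_without_superposition(self, ideal_sheet):
        moved = ideal_sheet.with_coords(ideal_sheet.coords + [1.0, 0.0, 0.0])
        assert st.assembly_backbone_rmsd(
            moved, ideal_sheet, superpose=False
        ) == pytest.approx(1.0)

    def test_roster_mismatch_rejected(self, ideal_sheet):
        with pytest.raises(ValueError):
            st.backbone_rmsd(ideal_sheet.coords[:10], ideal_sheet.coords[:12])


class TestMeasureHelicalParams:
    def test_quasi21_roundtrip(self, quasi21_fibril):
        p = st.measure_helical_params(quasi21_fibril)
        assert p.rise == pytest.approx(2.44, abs=1e-6)
        assert p.twist == pytest.approx(178.94, abs=1e-6)
        assert p.symmetry == "quasi-21"

    def test_untwisted_stack(self):
        asm = synth.build_fibril(
            synth.BuilderSpec("SQYG", HelicalParams(4.8, 0.0, "C1"), n_repeats=4)
        )
        p = st.measure_helical_params(asm)
        assert p.twist == pytest.approx(0.0, abs=1e-9)
        assert p.symmetry == "C1"

    def test_per_dimer_left_handed_target(self):
        # -2.5 degrees per 4.82 A dimer repeat as the construction target
        quasi = HelicalParams(4.82 / 2, (-2.5 + 360.0) / 2, "quasi-21")
        asm = synth.build_fibril(synth.BuilderSpec("SQYG", quasi, n_repeats=4))
        from fibrilkit.helix import effective_dimer_operator

        dimer = effective_dimer_operator(st.measure_helical_params(asm))
        assert dimer.rise == pytest.approx(4.82, abs=1e-6)
        assert dimer.twist == pytest.approx(-2.5, abs=1e-6)
        assert dimer.left_handed

    def test_fuzzed_roundtrip(self, rng):
        for _ in range(5):
            rise = rng.uniform(2.0, 6.0)
            twist = rng.uniform(170.0, 190.0)
            twist_in = twist if twist <= 180.0 else twist - 360.0
            asm = synth.build_fibril(
                synth.BuilderSpec(
                    "SQY", HelicalParams(rise, twist_in, "quasi-21"), n_repeats=4
                )
            )
            p = st.measure_helical_params(asm)
            assert p.rise == pytest.approx(rise, abs=1e-8)
            assert wrap_angle(p.twist - twist) == pytest.approx(0.0, abs=1e-8)

    def test_too_few_repeats_rejected(self, ideal_sheet):
        two = ideal_sheet.atoms[ideal_sheet.atoms["chain_id"].isin(["A", "B"])]
        with pytest.raises(ValueError):
            st.measure_helical_params(st.FibrilAssembly(two.reset_index(drop=True)))
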