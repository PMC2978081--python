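"""Backbone construction, dihedral measurement, Rg and PDB round-trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import refratio as rr
from refratio.geometry import wrap_angle


def make_path(phi, psi, states=None):
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    phi[0] = np.nan
    psi[-1] = np.nan
    if states is None:
        states = np.zeros(len(phi), dtype=int)
    return rr.DihedralPath(phi, psi, states)


class TestMeasureDihedral:
    @pytest.mark.parametrize("p4,expected", [
        ((1, 1, 0), 0.0),        # cis
        ((-1, 1, 0), 180.0),     # trans
        ((0, 1, 1), -90.0),      # right-hand rule about p2->p3
        ((0, 1, -1), 90.0),
    ])
    def test_reference_configurations(self, p4, expected):
        ang = rr.measure_dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), p4)
        assert ang == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_independent_formula(self, rng):
        """Cross-check against an independent atan2-free implementation."""
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            cosv = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
            cosv = np.clip(cosv, -1, 1)
            mag = math.degrees(math.acos(cosv))
            sign = 1.0 if np.dot(np.cross(n1, n2), b2) > 0 else -1.0
            got = rr.measure_dihedral(*pts)
            assert abs(got) == pytest.approx(mag, abs=1e-8)
            if abs(mag) > 1e-6 and abs(mag - 180) > 1e-6:
                assert math.copysign(1, got) == sign

    def test_degenerate_geometry_raises(self):
        with pytest.raises(ValueError):
            rr.measure_dihedral((0, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 0))
        with pytest.raises(ValueError):
            rr.measure_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestBuildBackbone:
    def test_bond_lengths_match_ideal_values(self, rng):
        geo = rr.GeometryParams()
        seq = rr.Sequence("ADGKLMPQRS")
        phi = rng.uniform(-180, 180, 10)
        psi = rng.uniform(-180, 180, 10)
        conf = rr.build_backbone(make_path(phi, psi), seq)
        np.testing.assert_allclose(
            np.linalg.norm(conf.ca - conf.n, axis=1), geo.bond_n_ca, atol=1e-6)
        np.testing.assert_allclose(
            np.linalg.norm(conf.c - conf.ca, axis=1), geo.bond_ca_c, atol=1e-6)
        np.testing.assert_allclose(
            np.linalg.norm(conf.n[1:] - conf.c[:-1], axis=1), geo.bond_c_n,
            atol=1e-6)
        np.testing.assert_allclose(
            np.linalg.norm(conf.o - conf.c, axis=1), geo.bond_c_o, atol=1e-6)

    def test_bond_angles_match_ideal_values(self, rng):
        geo = rr.GeometryParams()
        seq = rr.Sequence("ADGKLM")
        conf = rr.build_backbone(
            make_path(rng.uniform(-180, 180, 6), rng.uniform(-180, 180, 6)), seq)

        def angle(p, q, r):
            a, b = p - q, r - q
            return math.degrees(math.acos(
                np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))))

        for i in range(6):
            assert angle(conf.n[i], conf.ca[i], conf.c[i]) == \
                pytest.approx(geo.angle_n_ca_c, abs=1e-6)
        for i in range(5):
            assert angle(conf.ca[i], conf.c[i], conf.n[i + 1]) == \
                pytest.approx(geo.angle_ca_c_n, abs=1e-6)
            assert angle(conf.c[i], conf.n[i + 1], conf.ca[i + 1]) == \
                pytest.approx(geo.angle_c_n_ca, abs=1e-6)

    def test_atom_count_rule(self):
        # 3 residues with one glycine: 4*3 + 2 side-chain atoms
        conf = rr.build_backbone(make_path([0, -60, -70], [120, 140, 0]),
                                 rr.Sequence("AGL"))
        assert conf.n_atoms == 14
        assert len(list(conf.atom_records())) == 14

    def test_dihedral_round_trip(self, default_params, ubiquitin, rng):
        path = rr.sample_path(default_params, ubiquitin, rng)
        conf = rr.build_backbone(path, ubiquitin)
        phi, psi = rr.measure_backbone_dihedrals(conf)
        assert np.nanmax(np.abs(wrap_angle(phi - path.phi))) < 1e-6
        assert np.nanmax(np.abs(wrap_angle(psi - path.psi))) < 1e-6

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 32 - 1))
    def test_rebuild_from_measured_dihedrals_superposes(self, seed):
        """Coordinates -> dihedrals -> coordinates reproduces the structure
        up to the rigid-body frame (the builder fixes the frame, so the
        rebuilt coordinates match directly)."""
        rng = np.random.default_rng(seed)
        L = int(rng.integers(3, 20))
        seq = rr.Sequence("".join(rng.choice(list("ACDGLP"), L)))
        path = make_path(rng.uniform(-180, 180, L), rng.uniform(-180, 180, L))
        conf = rr.build_backbone(path, seq)
        phi, psi = rr.measure_backbone_dihedrals(conf)
        conf2 = rr.build_backbone(rr.DihedralPath(phi, psi, path.states), seq)
        rmsd = np.sqrt(np.mean(np.sum(
            (conf.coords() - conf2.coords()) ** 2, axis=1)))
        assert rmsd < 1e-5

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            rr.build_backbone(make_path([0, -60], [120, 0]), rr.Sequence("AGL"))

    def test_out_of_range_angle_raises(self):
        with pytest.raises(ValueError):
            make_path([0, -60, 270.0], [120, 140, 0])


class TestRadiusOfGyration:
    def test_known_values(self):
        conf = rr.build_backbone(make_path([0, -60], [120, 0]),
                                 rr.Sequence("AA"))
        # single atom
        single = rr.Conformation(conf.n[:1], conf.ca[:1] * np.nan,
                                 conf.c[:1], conf.o[:1], conf.sc[:1],
                                 np.array([False]))
        assert rr.radius_of_gyration(single, roles=("N",)) == 0.0
        # two atoms 2 A apart -> 1 A; unit square -> sqrt(0.5)
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        r = np.sqrt(np.mean(np.sum((pts - pts.mean(0)) ** 2, axis=1)))
        assert r == pytest.approx(1.0)
        sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        r = np.sqrt(np.mean(np.sum((sq - sq.mean(0)) ** 2, axis=1)))
        assert r == pytest.approx(math.sqrt(0.5))

    def test_rigid_motion_invariance(self, default_params, ubiquitin, rng):
        path = rr.sample_path(default_params, ubiquitin, rng)
        conf = rr.build_backbone(path, ubiquitin)
        base = rr.radius_of_gyration(conf)
        for _ in range(5):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            moved = conf.transformed(q, rng.normal(size=3) * 50)
            assert abs(rr.radius_of_gyration(moved) - base) < 1e-9

    def test_matches_kernel_all_atoms(self, default_params, ubiquitin, rng):
        """The sampling kernel's Rg equals the public API on all atoms."""
        from refratio import _kernels as K
        path = rr.sample_path(default_params, ubiquitin, rng)
        conf = rr.build_backbone(path, ubiquitin)
        fast = K.rg_all_atoms(conf.n, conf.ca, conf.c, conf.o, conf.sc,
                              conf.sc_mask)
        assert fast == pytest.approx(rr.radius_of_gyration(conf), abs=1e-12)

    def test_empty_selection_raises(self, default_params, ubiquitin, rng):
        conf = rr.build_backbone(
            rr.sample_path(default_params, ubiquitin, rng), ubiquitin)
        with pytest.raises(ValueError):
            rr.radius_of_gyration(conf, roles=())


class TestPdbIO:
    def test_atom_records_and_end(self, tmp_path):
        conf = rr.build_backbone(make_path([0, -60], [120, 0]),
                                 rr.Sequence("AL"))
        out = tmp_path / "two.pdb"
        rr.write_pdb(conf, rr.Sequence("AL"), out)
        lines = out.read_text().splitlines()
        atoms = [l for l in lines if l.startswith("ATOM")]
        assert len(atoms) == 10
        assert lines[-1].startswith("END")
        # side-chain pseudo-atom emitted as CB
        assert sum(1 for l in atoms if l[12:16].strip() == "CB") == 2

    def test_round_trip_precision(self, tmp_path, default_params, ubiquitin,
                                  rng):
        from refratio.geometry import read_pdb_coords
        path = rr.sample_path(default_params, ubiquitin, rng)
        conf = rr.build_backbone(path, ubiquitin)
        out = tmp_path / "ubq.pdb"
        rr.write_pdb(conf, ubiquitin, out)
        coords = read_pdb_coords(out)
        original = np.array([pos for _, _, pos in conf.atom_records()])
        assert coords.shape == original.shape
        assert np.abs(coords - original).max() <= 1e-3 + 1e-9
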