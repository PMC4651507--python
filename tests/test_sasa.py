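"""Shrake–Rupley SASA against analytic and brute-force oracles."""

import numpy as np
import pytest

from tsbind import (
    RadiiTable,
    Trajectory,
    ValidationError,
    sasa_significance,
    shrake_rupley,
    sidechain_sasa,
    total_sasa_series,
)
from tsbind.sasa import BACKBONE_ATOMS, fibonacci_sphere

from conftest import make_frame, random_rotation


def single_element_table(**radii):
    return RadiiTable(radii=radii or None)


class TestSingleAndTwoSpheres:
    def test_isolated_sphere_is_analytic(self):
        frame = make_frame([[0, 0, 0]], names=["S"], elements=["S"])
        radii = RadiiTable(radii={"S": 1.6})
        result = shrake_rupley(frame, radii, n_points=64)
        assert result.total == pytest.approx(4 * np.pi * 3.0**2, rel=1e-12)

    def test_two_spheres_analytic_cap(self):
        """Symmetric pair r=1.7, probe 1.4, centers 3.1 Å apart.

        Each expanded sphere (R = 3.1) loses a cap of height h = R − d/2;
        accessible area per atom = 4πR² − 2πRh.
        """
        frame = make_frame([[0, 0, 0], [3.1, 0, 0]], names=["C", "C"], elements=["C", "C"])
        result = shrake_rupley(frame, RadiiTable(radii={"C": 1.7}), n_points=960)
        R, d = 3.1, 3.1
        expected = 4 * np.pi * R**2 - 2 * np.pi * R * (R - d / 2)
        assert expected == pytest.approx(90.57, abs=0.3)
        for area in result.per_atom:
            assert area == pytest.approx(expected, rel=0.02)

    def test_fully_buried_atom_is_zero(self):
        frame = make_frame([[0, 0, 0], [0, 0, 0.1]], names=["H", "S"], elements=["H", "S"])
        radii = RadiiTable(radii={"H": 0.5, "S": 5.0})
        result = shrake_rupley(frame, radii, n_points=240)
        assert result.per_atom[0] == 0.0

    def test_empty_frame_rejected(self):
        with pytest.raises(ValidationError):
            shrake_rupley(make_frame(np.empty((0, 3))))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            shrake_rupley(make_frame([[0, 0, 0]]), n_points=16)


class TestInvariants:
    def _toy_frame(self, rng, n=12):
        coords = rng.uniform(0, 8, size=(n, 3))
        elements = rng.choice(["C", "N", "O", "S"], n).tolist()
        return make_frame(coords, names=elements, elements=elements)

    def test_rigid_motion_invariance(self, rng):
        frame = self._toy_frame(rng)
        base = shrake_rupley(frame, n_points=960)
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        elements = [a.element for a in frame.atoms]
        moved = make_frame(frame.coord_array() @ R.T + t, names=elements, elements=elements)
        rotated = shrake_rupley(moved, n_points=960)
        rel = abs(rotated.total - base.total) / base.total
        assert rel <= 0.005
        assert np.allclose(rotated.per_atom, base.per_atom,
                           atol=0.005 * base.per_atom.max() + 0.5)

    def test_monotone_under_approach(self):
        """Moving a second atom closer never increases the first atom's SASA."""
        prev = None
        for d in np.linspace(7.0, 1.0, 13):
            frame = make_frame([[0, 0, 0], [d, 0, 0]], names=["C", "C"],
                               elements=["C", "C"])
            area = shrake_rupley(frame, n_points=960).per_atom[0]
            if prev is not None:
                assert area <= prev + 1e-9
            prev = area

    def test_lattice_convergence(self, rng):
        frame = self._toy_frame(rng, n=50)
        coarse = shrake_rupley(frame, n_points=1000)
        fine = shrake_rupley(frame, n_points=4000)
        assert abs(fine.total - coarse.total) / fine.total < 0.01

    def test_total_is_sum_of_per_atom(self, rng):
        frame = self._toy_frame(rng)
        result = shrake_rupley(frame)
        assert result.total == pytest.approx(result.per_atom.sum(), rel=1e-12)

    def test_brute_force_union_oracle(self, rng):
        """Dense uniform-direction sampling with a point-in-union test, ≤10 atoms."""
        frame = self._toy_frame(rng, n=8)
        result = shrake_rupley(frame, n_points=2000)
        coords = frame.coord_array()
        radii = RadiiTable()
        expanded = np.array([radii.radius_for(a.element) + radii.probe_radius
                             for a in frame.atoms])
        # independent oracle: random (seeded) directions instead of the lattice
        dirs = rng.normal(size=(6000, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        for i in range(len(coords)):
            pts = coords[i] + expanded[i] * dirs
            inside = np.zeros(len(pts), dtype=bool)
            for j in range(len(coords)):
                if j == i:
                    continue
                inside |= np.linalg.norm(pts - coords[j], axis=1) < expanded[j]
            oracle = 4 * np.pi * expanded[i] ** 2 * (~inside).mean()
            assert result.per_atom[i] == pytest.approx(oracle, abs=0.02 * 4 * np.pi * expanded[i] ** 2)

    def test_fibonacci_lattice_is_deterministic_and_uniform(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.allclose(pts, fibonacci_sphere(960))
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01


class TestSidechain:
    def _residue_frame(self):
        # one ARG-like residue: backbone N/CA/C/O + side chain CB/CG far away
        coords = [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [3.6, 1.1, 0],
                  [1.5, 1.5, 0], [60.0, 0, 0]]
        names = ["N", "CA", "C", "O", "CB", "CG"]
        return make_frame(coords, names=names, elements=["N", "C", "C", "O", "C", "C"],
                          res_seqs=[248] * 6, res_names=["ARG"] * 6)

    def test_sidechain_plus_backbone_equals_residue_total(self):
        frame = self._residue_frame()
        result = shrake_rupley(frame, n_points=960)
        sc = sidechain_sasa(result, frame, {248})[248]
        backbone = sum(result.per_atom[i] for i, a in enumerate(frame.atoms)
                       if a.name in BACKBONE_ATOMS)
        assert sc + backbone == pytest.approx(result.total, rel=1e-12)

    def test_isolated_sidechain_atom_is_full_sphere(self):
        frame = self._residue_frame()
        result = shrake_rupley(frame, n_points=960)
        # CG sits 60 Å away: it alone contributes a full expanded sphere
        full_cg = 4 * np.pi * (1.7 + 1.4) ** 2
        sc = sidechain_sasa(result, frame, {248})[248]
        cb = result.per_atom[4]
        assert sc == pytest.approx(cb + full_cg, rel=1e-9)

    def test_glycine_reports_zero(self):
        frame = make_frame([[0, 0, 0], [1.5, 0, 0]], names=["N", "CA"],
                           elements=["N", "C"], res_seqs=[10, 10],
                           res_names=["GLY", "GLY"])
        result = shrake_rupley(frame)
        assert sidechain_sasa(result, frame, {10})[10] == 0.0

    def test_unknown_residue_rejected(self):
        frame = self._residue_frame()
        result = shrake_rupley(frame)
        with pytest.raises(ValidationError):
            sidechain_sasa(result, frame, {248, 999})

    def test_buried_sidechain_near_zero(self):
        # CB enclosed by a shell of large atoms
        shell_dirs = fibonacci_sphere(30)
        coords = [[0, 0, 0]] + (2.0 * shell_dirs).tolist()
        names = ["CB"] + ["S"] * 30
        frame = make_frame(coords, names=names, elements=["C"] + ["S"] * 30,
                           res_seqs=[5] + [6] * 30, res_names=["ALA"] + ["CYS"] * 30)
        result = shrake_rupley(frame, n_points=500)
        assert sidechain_sasa(result, frame, {5})[5] == 0.0


class TestSignificance:
    def test_difference_beyond_sd_is_significant(self, rng):
        series = rng.normal(50.0, 5.0, 400)
        mean, sd, sig = sasa_significance(series, reference_mean=40.0)
        assert sig and abs(mean - 50.0) < 1.5

    def test_difference_within_sd_not_significant(self, rng):
        series = rng.normal(50.0, 15.0, 400)
        _, _, sig = sasa_significance(series, reference_mean=45.0)
        assert not sig

    def test_reference_equal_to_mean_not_significant(self):
        series = np.array([49.0, 51.0, 50.0, 50.0])
        _, _, sig = sasa_significance(series, reference_mean=50.0)
        assert not sig

    def test_singleton_series_rejected(self):
        with pytest.raises(ValidationError):
            sasa_significance(np.array([50.0]), 40.0)


def test_matches_third_party_shrake_rupley(rng):
    """Independent oracle: an established structure library with matched radii."""
    import biotite.structure as struc

    elements = rng.choice(["C", "N", "O", "S"], 20).tolist()
    coords = rng.uniform(0, 10, size=(20, 3))
    frame = make_frame(coords, names=elements, elements=elements)
    radii = RadiiTable()
    mine = shrake_rupley(frame, radii, n_points=960)

    arr = struc.AtomArray(20)
    arr.coord = coords.astype(np.float32)
    arr.element = np.array(elements)
    arr.atom_name = np.array(elements)
    arr.res_id = np.arange(1, 21)
    arr.res_name = np.array(["ALA"] * 20)
    arr.chain_id = np.array(["A"] * 20)
    vdw = np.array([radii.radius_for(e) for e in elements])
    other = struc.sasa(arr, probe_radius=1.4, vdw_radii=vdw, point_number=960)
    assert mine.total == pytest.approx(float(other.sum()), rel=2e-3)
    assert np.allclose(mine.per_atom, other, atol=0.02 * mine.per_atom.max() + 0.01)


def test_total_series_runs_over_trajectory(two_frame_traj):
    series = total_sasa_series(two_frame_traj, n_points=240)
    assert series.shape == (2,)
    assert np.all(series > 0)
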