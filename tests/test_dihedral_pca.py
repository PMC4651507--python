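"""Backbone torsions, circular PCA invariances, and the stability landscape."""

import numpy as np
import pytest

from tsbind import (
    DegenerateDataError,
    DihedralSeries,
    IntegrityError,
    ProteinStabilitySeries,
    Trajectory,
    ValidationError,
    circular_pca,
    compute_backbone_dihedrals,
    stability_landscape,
    torsion_angle,
    wrap_degrees,
)
from tsbind import synthetic

from conftest import make_frame


def backbone_frame(coords_by_residue, frame_index=0):
    """Frame with N/CA/C backbone per residue (consecutive author numbering)."""
    coords, names, res_seqs = [], [], []
    for i, triple in enumerate(coords_by_residue):
        for name, xyz in zip(("N", "CA", "C"), triple):
            coords.append(xyz)
            names.append(name)
            res_seqs.append(i + 1)
    return make_frame(coords, names=names, elements=["N" if n == "N" else "C" for n in names],
                      res_seqs=res_seqs, frame_index=frame_index)


from hypothesis import given, settings, strategies as st


@given(angle=st.floats(-720.0, 720.0, allow_nan=False), m=st.integers(-5, 5))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_wrap_degrees_principal_interval_and_periodicity(angle, m):
    w = float(wrap_degrees(angle))
    assert -180.0 < w <= 180.0
    assert float(wrap_degrees(angle + 360.0 * m)) == pytest.approx(w, abs=1e-9)


class TestTorsion:
    def test_planar_trans_is_180(self):
        # zig-zag in a plane: the classic trans arrangement
        p = [np.array(v, float) for v in
             [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]]
        assert torsion_angle(*p) == pytest.approx(180.0)

    def test_cis_is_zero(self):
        p = [np.array(v, float) for v in
             [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]]
        assert torsion_angle(*p) == pytest.approx(0.0, abs=1e-12)

    def test_mirror_flips_sign(self, rng):
        pts = [rng.normal(size=3) for _ in range(4)]
        mirrored = [p * np.array([1.0, 1.0, -1.0]) for p in pts]
        a = torsion_angle(*pts)
        b = torsion_angle(*mirrored)
        if abs(abs(a) - 180.0) > 1e-9:
            assert b == pytest.approx(-a, abs=1e-9)

    def test_matches_independent_atan2_oracle(self, rng):
        """1000 random quadruples against the textbook normal-vector atan2 form."""

        def oracle(p0, p1, p2, p3):
            b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
            y = np.linalg.norm(b2) * (b1 @ np.cross(b2, b3))
            x = np.cross(b1, b2) @ np.cross(b2, b3)
            return np.degrees(np.arctan2(y, x))

        for _ in range(1000):
            pts = rng.normal(size=(4, 3)) * 3
            if min(np.linalg.norm(pts[i + 1] - pts[i]) for i in range(3)) < 0.3:
                continue
            expected = wrap_degrees(oracle(*pts))
            assert torsion_angle(*pts) == pytest.approx(expected, abs=1e-9)

    def test_matches_third_party_convention(self, rng):
        """Cross-check the sign convention against an established structure library."""
        from biotite.structure import dihedral

        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            # biotite works in float32; compare at its precision
            expected = wrap_degrees(float(np.degrees(dihedral(*pts))))
            assert torsion_angle(*pts) == pytest.approx(expected, abs=1e-3)


class TestBackboneExtraction:
    def _traj(self, n_frames=3):
        frames = []
        for fi in range(n_frames):
            twist = 10.0 * fi
            residues = []
            for r in range(4):
                base = np.array([3.0 * r, 0.0, 0.0])
                residues.append([
                    base + [0.0, 1.0, 0.0],
                    base + [1.0, 0.0, 0.1 * twist * 0],
                    base + [2.0, 0.5 + 0.02 * twist, 0.3],
                ])
            frames.append(backbone_frame(residues, frame_index=fi))
        return Trajectory(frames)

    def test_phi_omits_first_residue_psi_omits_last(self):
        traj = self._traj()
        phi = compute_backbone_dihedrals(traj, "phi")
        psi = compute_backbone_dihedrals(traj, "psi")
        assert phi.residues == [2, 3, 4]
        assert psi.residues == [1, 2, 3]
        assert phi.values.shape == (3, 3)

    def test_missing_backbone_atom_omits_residue_with_warning(self):
        traj = self._traj()
        frame = traj[0]
        frame.atoms = [a for a in frame.atoms if not (a.res_seq == 3 and a.name == "CA")]
        with pytest.warns(UserWarning, match="residue"):
            phi = compute_backbone_dihedrals(Trajectory([frame]), "phi")
        assert 3 not in phi.residues

    def test_values_match_direct_torsion(self):
        traj = self._traj(2)
        phi = compute_backbone_dihedrals(traj, "phi")
        coords = traj[0].coord_array()
        # residue 2's phi: C(1), N(2), CA(2), C(2) = atoms 2, 3, 4, 5
        expected = torsion_angle(coords[2], coords[3], coords[4], coords[5])
        assert phi.values[0, 0] == pytest.approx(expected, abs=1e-12)


class TestCircularPCA:
    def _series(self, values, residues=None):
        values = np.asarray(values, dtype=float)
        residues = residues or list(range(values.shape[1]))
        return DihedralSeries(angle_kind="phi", residues=residues, values=values)

    def test_single_varying_angle_dominates_pc1(self, rng):
        n = 400
        values = np.full((n, 5), 60.0)
        values[:, 2] = np.where(rng.random(n) < 0.5, 179.0, 1.0) + rng.normal(0, 2, n)
        result = circular_pca(self._series(wrap_degrees(values)))
        assert result.variance_explained[0] >= 0.99

    def test_all_constant_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            circular_pca(self._series(np.full((50, 3), 42.0)))

    def test_wrap_invariance(self, rng):
        values = wrap_degrees(rng.uniform(-180, 180, size=(60, 4)) + 1e-6)
        base = circular_pca(self._series(values))
        shifted_raw = values + 360.0 * rng.integers(-2, 3, size=values.shape)
        shifted = circular_pca(self._series(wrap_degrees(shifted_raw)))
        assert np.allclose(base.component_scores, shifted.component_scores, atol=1e-9)
        assert np.allclose(base.variance_explained, shifted.variance_explained, atol=1e-12)

    def test_frame_permutation_invariance_of_variance(self, rng):
        values = wrap_degrees(rng.normal(100, 40, size=(80, 3)))
        base = circular_pca(self._series(values))
        perm = rng.permutation(80)
        permuted = circular_pca(self._series(values[perm]))
        assert np.allclose(base.variance_explained, permuted.variance_explained, atol=1e-12)

    def test_variance_matches_brute_force_eigensolve(self, rng):
        """Independent oracle: eigenvalues of the embedded covariance matrix."""
        values = wrap_degrees(rng.normal(0, 50, size=(40, 3)))
        result = circular_pca(self._series(values), n_components=6)
        theta = np.radians(values)
        X = np.hstack([np.sin(theta), np.cos(theta)])
        evals = np.linalg.svd(X - X.mean(0), compute_uv=False) ** 2 / (len(X) - 1)
        expected = np.sort(evals)[::-1] / evals.sum()
        assert np.allclose(result.variance_explained, expected[:6], atol=1e-10)

    def test_fewer_than_two_frames_rejected(self):
        with pytest.raises(ValidationError):
            circular_pca(self._series([[10.0, 20.0]]))

    def test_variance_fractions_sorted_and_bounded(self, rng):
        values = wrap_degrees(rng.normal(0, 60, size=(100, 4)))
        result = circular_pca(self._series(values), n_components=4)
        ve = result.variance_explained
        assert np.all(np.diff(ve) <= 1e-12)
        assert 0.0 < ve.sum() <= 1.0 + 1e-12


class TestStabilityLandscape:
    def test_pairs_and_count_conservation(self, rng):
        pc2 = rng.normal(size=30)
        dg = ProteinStabilitySeries(frame_index=list(range(30)),
                                    dg_protein=rng.normal(-2500, 20, 30))
        land = stability_landscape(pc2, dg, bins=8)
        assert len(land.pairs) == 30
        assert land.counts.sum() == 30

    def test_misalignment_rejected(self, rng):
        dg = ProteinStabilitySeries(frame_index=[0, 1, 2], dg_protein=[-1.0, -2.0, -3.0])
        with pytest.raises(IntegrityError):
            stability_landscape(np.zeros(4), dg)

    def test_two_cluster_generator_yields_two_modes(self):
        """cis/trans flips with distinct ΔG means produce two density modes."""
        cfg = synthetic.preset("WT", "T310", seed=7, n_frames=2000,
                               dihedral_clusters=((180.0, 25.0, 0.5), (0.0, 25.0, 0.5)))
        series, assignments = synthetic.generate_dihedral_series(cfg)
        result = circular_pca(series)
        pc = result.component_scores[:, 0]
        dg_values = np.where(assignments == 0, -2500.0, -2350.0) + \
            np.random.default_rng(0).normal(0, 10, len(assignments))
        dg = ProteinStabilitySeries(frame_index=list(range(len(pc))), dg_protein=dg_values)
        land = stability_landscape(pc, dg, bins=10)
        marginal = land.counts.sum(axis=1)
        # the score axis separates the two planted clusters: mass at both ends
        top_two = np.sort(marginal)[-2:]
        assert top_two.sum() >= 0.9 * len(pc)
        occupied = np.where(marginal > 0.05 * len(pc))[0]
        assert occupied.min() <= 2 and occupied.max() >= 7
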