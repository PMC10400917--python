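"""Superposition and geometric order parameters against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize

import efsam as E
from efsam import synth
from efsam.geometry import ATOMIC_MASSES, DegenerateFitError


def brute_force_min_rmsd(mobile, reference, n_axes=400, n_angles=180):
    """Independent superposition oracle: exhaustive axis/angle rotation grid
    (with optimal translation via centroids) refined by direct simplex search
    on the rotation vector. Never calls the Kabsch path."""

    def rot_from_vec(v):
        theta = np.linalg.norm(v)
        if theta < 1e-12:
            return np.eye(3)
        k = v / theta
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * kx @ kx

    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)

    def rmsd_of(v):
        r = rot_from_vec(v)
        return np.sqrt(np.mean(np.sum((mc @ r.T - rc) ** 2, axis=1)))

    # golden-spiral axes x angle grid
    k = np.arange(n_axes)
    z = 1 - (2 * k + 1) / n_axes
    phi = k * np.pi * (3 - np.sqrt(5))
    r = np.sqrt(1 - z**2)
    axes = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    best, best_v = np.inf, np.zeros(3)
    for ax in axes:
        for theta in np.linspace(0, np.pi, n_angles // 2):
            v = ax * theta
            val = rmsd_of(v)
            if val < best:
                best, best_v = val, v
    res = minimize(rmsd_of, best_v, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
    return min(best, res.fun)


class TestSuperpose:
    def test_identity(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        tf, fitted = E.superpose(pts, pts)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(fitted, pts, atol=1e-10)

    def test_rigid_motion_recovered(self, rotation_factory):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        rot = rotation_factory(rng)
        moved = pts @ rot.T + np.array([5.0, 0.0, 0.0])
        _, fitted = E.superpose(moved, pts)
        assert np.max(np.abs(fitted - pts)) < 1e-6

    def test_90deg_z_rotation_translation(self):
        pts = np.array([[0.0, 0, 0], [2, 0, 0], [0, 3, 0], [1, 1, 4]])
        rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        moved = pts @ rz.T + np.array([5.0, 0, 0])
        _, fitted = E.superpose(moved, pts)
        assert np.max(np.abs(fitted - pts)) < 1e-10

    def test_matches_brute_force_rotation_grid(self):
        pts = np.array([[0.0, 0, 0], [3, 0, 0], [0, 2, 0], [0, 0, 1.5]])
        mobile = pts.copy()
        mobile[3] += np.array([1.0, 0, 0])  # one atom displaced 1 A
        tf, fitted = E.superpose(mobile, pts)
        kabsch_rmsd = np.sqrt(np.mean(np.sum((fitted - pts) ** 2, axis=1)))
        oracle = brute_force_min_rmsd(mobile, pts)
        assert kabsch_rmsd == pytest.approx(oracle, abs=1e-4)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateFitError):
            E.superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateFitError):
            E.superpose(line, line)

    def test_fit_reduces_rmsd(self, toy_reference, rotation_factory):
        """Superposing on the fit selection never increases the RMSD."""
        rng = np.random.default_rng(3)
        ref = toy_reference.coords[0]
        noisy = ref + rng.normal(0, 1.0, ref.shape)
        moved = noisy @ rotation_factory(rng).T + rng.normal(0, 5.0, 3)
        _, fitted = E.superpose(moved, ref)
        before = np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))
        after = np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1)))
        assert after <= before + 1e-12


class TestRmsdSeries:
    def test_copies_give_zero(self, toy_reference):
        ens = E.Ensemble(toy_reference.atoms,
                         np.repeat(toy_reference.coords, 5, axis=0))
        s = E.rmsd_series(ens)
        assert np.allclose(s.values, 0.0, atol=1e-9)
        assert s.units == "nm"

    def test_uniform_displacement_after_disjoint_fit(self, point_ensemble_factory):
        """Atoms displaced by (delta,0,0) after fitting a rigid disjoint subset
        show RMSD exactly delta."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=(12, 3)) * 4
        delta = 2.5
        moved = base.copy()
        moved[8:] += np.array([delta, 0.0, 0.0])
        ens = point_ensemble_factory(np.stack([base, moved]))
        s = E.rmsd_series(ens, fit_sel=np.arange(8), measure_sel=np.arange(8, 12))
        assert s.values[1] == pytest.approx(delta / 10.0, abs=1e-9)  # nm

    def test_matches_per_pair_oracle(self, point_ensemble_factory):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(10, 15, 3)) * 3
        ens = point_ensemble_factory(coords)
        idx = np.arange(15)
        s = E.rmsd_series(ens, fit_sel=idx, measure_sel=idx)
        for m in range(10):
            tf, fitted = E.superpose(coords[m], coords[0], idx)
            oracle = np.sqrt(np.mean(np.sum((fitted - coords[0]) ** 2, axis=1))) / 10
            assert s.values[m] == pytest.approx(oracle, abs=1e-6)


class TestRmsf:
    def test_static_ensemble_is_zero(self, toy_reference):
        ens = E.Ensemble(toy_reference.atoms,
                         np.repeat(toy_reference.coords, 4, axis=0))
        p = E.rmsf_profile(ens)
        assert np.allclose(p.values, 0.0, atol=1e-9)

    def test_single_model_raises(self, toy_reference):
        with pytest.raises(Exception, match="single model"):
            E.rmsf_profile(toy_reference)

    def test_alternating_atom_has_rmsf_delta(self, point_ensemble_factory):
        """One atom alternating +/-delta along x over an even number of
        frames, the rest static; fitting on the static subset recovers
        RMSF = delta for the moving residue."""
        rng = np.random.default_rng(2)
        base = rng.normal(size=(10, 3)) * 5
        delta = 0.8
        frames = []
        for k in range(6):
            f = base.copy()
            f[9, 0] += delta if k % 2 == 0 else -delta
            frames.append(f)
        # static atoms inside the global fit range, the moving one outside it
        ens = point_ensemble_factory(
            np.stack(frames), resnums=list(range(101, 110)) + [30]
        )
        p = E.rmsf_profile(ens, measure_sel=np.arange(10), fit_mode="global",
                           units="A")
        moving = p.values[p.residue_numbers == 30][0]
        static = p.values[p.residue_numbers != 30]
        assert moving == pytest.approx(delta, abs=1e-9)
        assert np.allclose(static, 0.0, atol=1e-9)

    def test_duplicated_trajectory_is_stationary(self, toy_reference):
        rng = np.random.default_rng(4)
        frames = toy_reference.coords[0] + rng.normal(
            0, 0.4, (6,) + toy_reference.coords[0].shape
        )
        half = E.Ensemble(toy_reference.atoms, frames)
        double = E.Ensemble(toy_reference.atoms,
                            np.concatenate([frames, frames]))
        p1 = E.rmsf_profile(half)
        p2 = E.rmsf_profile(double)
        assert np.allclose(p1.values, p2.values, atol=1e-9)

    def test_local_fit_matches_direct_recomputation(self, toy_reference):
        rng = np.random.default_rng(5)
        frames = toy_reference.coords[0] + rng.normal(
            0, 0.3, (5,) + toy_reference.coords[0].shape
        )
        ens = E.Ensemble(toy_reference.atoms, frames)
        p = E.rmsf_profile(ens, fit_mode="local:alpha10")
        # direct straight-from-formula recomputation
        fit_idx = E.select(ens, "segment alpha10 and name CA",
                           E.default_subdomain_map())
        meas_idx = E.select(ens, "segment fit_global and name CA",
                            E.default_subdomain_map())
        oracle = _rmsf_with_indices(ens, fit_idx)
        uniq = np.unique(ens.residue_numbers[meas_idx])
        # measured atoms are all C-alpha, one per residue
        for r, v in zip(uniq, p.values):
            i = int(meas_idx[ens.residue_numbers[meas_idx] == r][0])
            assert v == pytest.approx(oracle[i] / 10.0, abs=1e-9)


def _rmsf_with_indices(ens, fit_idx, meas_idx=None):
    """Straight-from-formula per-atom RMSF oracle (Angstrom)."""
    ref = ens.coords[0]
    fitted = []
    for m in range(ens.n_models):
        tf = E.kabsch(ens.coords[m][fit_idx], ref[fit_idx])
        fitted.append(tf.apply(ens.coords[m]))
    fitted = np.stack(fitted)
    mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


class TestGyration:
    def test_single_atom_zero(self, point_ensemble_factory):
        ens = point_ensemble_factory(np.array([[1.0, 2, 3]]))
        s = E.gyration_radius(ens, np.array([0]))
        assert s.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_masses_two_angstrom_apart(self, point_ensemble_factory):
        ens = point_ensemble_factory(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        s = E.gyration_radius(ens, np.array([0, 1]))
        assert s.values[0] == pytest.approx(0.1, abs=1e-12)  # 1 A = 0.1 nm

    def test_five_atom_mass_weighted_oracle(self, point_ensemble_factory):
        coords = np.array(
            [[0.0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0, 0, 2.5], [1, 1, 1]]
        )
        elements = ["C", "N", "O", "S", "C"]
        ens = point_ensemble_factory(coords, elements=elements)
        s = E.gyration_radius(ens, np.arange(5))
        m = np.array([ATOMIC_MASSES[e] for e in elements])
        com = (m[:, None] * coords).sum(0) / m.sum()
        oracle = np.sqrt((m * np.sum((coords - com) ** 2, axis=1)).sum() / m.sum())
        assert s.values[0] == pytest.approx(oracle / 10.0, abs=1e-9)

    def test_unknown_element_raises(self, point_ensemble_factory):
        ens = point_ensemble_factory(np.zeros((1, 3)), elements=["Xx"])
        with pytest.raises(Exception, match="element"):
            E.gyration_radius(ens, np.array([0]))


class TestPairDistances:
    def test_same_atom_zero(self, toy_reference):
        s = E.pair_distance(toy_reference, (108, "CA"), (108, "CA"))
        assert s.values[0] == 0.0

    def test_three_four_five(self, point_ensemble_factory):
        ens = point_ensemble_factory(np.array([[0.0, 0, 0], [3.0, 4.0, 0]]))
        s = E.pair_distance(ens, (1, "CA"), (2, "CA"))
        assert s.values[0] == pytest.approx(5.0, abs=1e-12)

    def test_missing_atom_names_spec(self, helix15):
        with pytest.raises(Exception, match="87"):
            E.distance_d2(helix15)  # poly-ALA helix has no Glu87 CD

    def test_d1_expanded_loop_offset(self, toy_reference):
        base = toy_reference.coords[0]
        expanded = synth.expand_binding_loop(toy_reference, base, 12.0)
        ens = E.Ensemble(toy_reference.atoms, np.stack([base, expanded]))
        d1 = E.distance_d1(ens)
        assert d1.values[1] - d1.values[0] == pytest.approx(12.0, abs=1e-9)


class TestContacts:
    def test_min_heavy_atom_entry(self, point_ensemble_factory):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [4.0, 0, 0], [9.0, 0, 0]])
        ens = point_ensemble_factory(coords, resnums=[1, 1, 2, 2])
        cm = E.contact_map(ens)
        assert cm.distances[0, 1] == pytest.approx(3.0)

    def test_symmetry_and_zero_diagonal(self, toy_reference):
        cm = E.contact_map(toy_reference, selection="segment alpha10",
                           subdomain_map=E.default_subdomain_map())
        assert np.array_equal(cm.distances, cm.distances.T)
        assert np.all(np.diag(cm.distances) == 0)
        off = cm.distances[~np.eye(cm.distances.shape[0], dtype=bool)]
        assert np.all(off > 0)

    def test_probe_anchor_contact_present_then_lost_on_flip(self, toy_reference):
        probe, anchors = 108, [192, 195, 199]
        contacts = E.hydrophobic_contacts(toy_reference, [probe] + anchors)
        pairs = {(a, b) for a, b, _ in contacts}
        assert any((probe, a) in pairs for a in anchors)
        flipped = synth.flip_probe_ring(toy_reference, toy_reference.coords[0])
        ens = E.Ensemble(toy_reference.atoms, flipped[None])
        far = E.hydrophobic_contacts(ens, [probe] + anchors)
        assert not {(probe, a) for a in anchors} & {(a, b) for a, b, _ in far}


class TestRigidInvariance:
    def test_metrics_invariant_under_global_rigid_motion(
        self, toy_reference, rotation_factory
    ):
        rng = np.random.default_rng(9)
        frames = toy_reference.coords[0] + rng.normal(
            0, 0.3, (4,) + toy_reference.coords[0].shape
        )
        ens = E.Ensemble(toy_reference.atoms, frames)
        rot = rotation_factory(rng)
        moved = E.Ensemble(
            toy_reference.atoms, frames @ rot.T + np.array([10.0, -4.0, 2.0])
        )
        assert np.allclose(E.rmsd_series(ens).values,
                           E.rmsd_series(moved).values, atol=1e-8)
        assert np.allclose(E.rmsf_profile(ens).values,
                           E.rmsf_profile(moved).values, atol=1e-8)
        assert np.allclose(E.gyration_radius(ens).values,
                           E.gyration_radius(moved).values, atol=1e-8)
        assert np.allclose(E.distance_d1(ens).values,
                           E.distance_d1(moved).values, atol=1e-8)
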